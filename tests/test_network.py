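"""Species classification and reaction matching against a brute-force oracle."""

import io
import random

import pytest

from lipidpath.datasets import read_dataset
from lipidpath.network import (
    SpeciesIndex,
    build_network,
    classify_species,
    instantiate_reactions,
    match_reaction,
)
from lipidpath.nomenclature import parse_lipid


def make_dataset(names, n_samples=4, value=100.0):
    header = "Species," + ",".join(f"s{i}" for i in range(n_samples))
    lines = [header] + [f"{name},{','.join([str(value)] * n_samples)}" for name in names]
    return read_dataset(io.StringIO("\n".join(lines)))


def classification_of(dataset):
    return {rec.parsed.raw_name: rec.classification for rec in dataset.records}


def test_matching_pair_is_processed(db):
    ds = make_dataset(["PA 34:2", "DG 34:2"])
    classify_species(ds, db)
    assert classification_of(ds) == {"PA 34:2": "processed", "DG 34:2": "processed"}


def test_tg_without_fa_is_unprocessed(db):
    ds = make_dataset(["TG 52:2", "DG 34:1"])
    classify_species(ds, db)
    c = classification_of(ds)
    assert c["TG 52:2"] == "unprocessed"  # DG->TG needs an FA partner
    assert c["DG 34:1"] == "unprocessed"


def test_unrecognised_name(db):
    ds = make_dataset(["DG(aa-34:0", "PA 34:2", "DG 34:2"])
    rep = classify_species(ds, db)
    assert classification_of(ds)["DG(aa-34:0"] == "unrecognised"
    assert rep.n_unrecognised == 1 and rep.n_processed == 2


def test_partition_counts_sum(db):
    names = ["PA 34:2", "DG 34:2", "TG 52:2", "nonsense", "SM d18:1/16:0"]
    ds = make_dataset(names)
    rep = classify_species(ds, db)
    assert rep.total == len(names)


def test_acylation_triple(db):
    ds = make_dataset(["LPA 16:0", "FA 18:1", "PA 34:1"])
    matched = instantiate_reactions(ds, db)
    assert matched["LPA->PA"] == [("LPA(16:0)", "PA(34:1)", "FA(18:1)")]


def test_deacylation_needs_fa_by_default(db):
    ds = make_dataset(["PC 38:4", "LPC 18:0"])
    matched = instantiate_reactions(ds, db)
    assert "PC->LPC" not in matched  # 38:4 - 18:0 = FA 20:4 not in file
    ds2 = make_dataset(["PC 38:4", "LPC 18:0", "FA 20:4"])
    matched2 = instantiate_reactions(ds2, db)
    assert matched2["PC->LPC"] == [("PC(38:4)", "LPC(18:0)", "FA(20:4)")]


def test_deacylation_without_fa_switch(db):
    ds = make_dataset(["PC 38:4", "LPC 18:0"])
    matched = instantiate_reactions(ds, db, require_fa_for_deacylation=False)
    assert matched["PC->LPC"] == [("PC(38:4)", "LPC(18:0)")]


def test_fa_elongation_pair(db):
    ds = make_dataset(["FA 22:5", "FA 24:5"])
    matched = instantiate_reactions(ds, db)
    assert matched["FA(22:5)->FA(24:5)"] == [("FA(22:5)", "FA(24:5)")]


def test_monotonicity_adding_species(db):
    base = ["PA 34:2", "DG 34:2", "TG 52:2"]
    ds = make_dataset(base)
    classify_species(ds, db)
    before = {k: v for k, v in classification_of(ds).items() if v == "processed"}
    ds2 = make_dataset(base + ["FA 18:0"])  # TG 52:2 = DG 34:2 + FA 18:0
    classify_species(ds2, db)
    after = classification_of(ds2)
    for name in before:
        assert after[name] == "processed"
    assert after["TG 52:2"] == "processed"


def test_fa_dependence_of_acyl_edges(db):
    names = ["LPC 16:0", "PC 34:1", "FA 18:1", "PC 34:2", "PA 34:2", "DG 34:2"]
    with_fa = instantiate_reactions(make_dataset(names), db)
    without = instantiate_reactions(
        make_dataset([n for n in names if not n.startswith("FA")]), db
    )
    removed = set(with_fa) - set(without)
    kinds = {db.reactions[r].kind for r in removed}
    assert kinds <= {"acylation", "deacylation", "fa_elongation", "fa_desaturation"}
    for rid in without:  # composition-preserving edges are untouched
        if db.reactions[rid].kind in ("headgroup_transfer", "sphingoid_step"):
            assert without[rid] == with_fa[rid]


def test_empty_network_diagnostic(db):
    ds = make_dataset(["PC 38:4"])
    G = build_network(ds, db)
    assert G.number_of_edges() == 0
    assert "no reactions" in G.graph["diagnostic"]


def test_lipid_network_excludes_fa_nodes(db):
    ds = make_dataset(["FA 22:5", "FA 24:5", "PA 34:2", "DG 34:2"])
    lipid = build_network(ds, db, network_type="lipid")
    fa = build_network(ds, db, network_type="fa")
    assert all(not n.startswith("FA") for n in lipid.nodes)
    assert set(fa.nodes) == {"FA(22:5)", "FA(24:5)"}
    assert fa.graph["type"] == "fa"


def test_subclass_edge_unions_species_pairs(db):
    ds = make_dataset(["PA 34:2", "DG 34:2", "PA 36:1", "DG 36:1"])
    G = build_network(ds, db, level="subclass")
    assert len(G.edges["PA", "DG"]["species_pairs"]) == 2
    S = build_network(ds, db, level="species")
    assert S.has_edge("PA(34:2)", "DG(34:2)") and S.has_edge("PA(36:1)", "DG(36:1)")


def test_subset_restricts_reactions(db):
    ds = make_dataset(["dhSM 34:1", "dhCer 34:1", "Cer 34:1", "SM 34:1",
                       "PA 34:1", "DG 34:1"])
    G = build_network(ds, db, subset="Biosynthesis of Sphingomyelin")
    assert set(G.edges) <= {("dhSM", "dhCer"), ("dhCer", "Cer"),
                            ("Cer", "SM"), ("dhCer", "dhSM")}
    assert not G.has_edge("PA", "DG")


# ---------------------------------------------------------------------------
# Brute-force matching oracle: independent re-implementation of the balance
# rules by exhaustive scan over all species pairs/triples.

def brute_force(reaction, species):
    """species: list of (label, subclass, carbons, double_bonds)."""
    out = set()
    subs = [s for s in species if s[1] == reaction.substrate]
    prods = [s for s in species if s[1] == reaction.product]
    fas = [s for s in species if s[1] == "FA"]
    for ls, _, cs, ds in subs:
        for lp, _, cp, dp in prods:
            if reaction.kind in ("headgroup_transfer", "sphingoid_step"):
                if (cs, ds) == (cp, dp):
                    out.add((ls, lp))
            elif reaction.kind == "acylation":
                for lf, _, cf, df in fas:
                    if cp == cs + cf and dp == ds + df:
                        out.add((ls, lp, lf))
            elif reaction.kind == "deacylation":
                for lf, _, cf, df in fas:
                    if cs == cp + cf and ds == dp + df:
                        out.add((ls, lp, lf))
            else:  # fixed-composition FA step
                if ls == reaction.substrate_label and lp == reaction.product_label:
                    out.add((ls, lp))
    return sorted(out)


def test_matching_agrees_with_brute_force(db):
    rng = random.Random(20240917)
    codes = ["PC", "LPC", "PA", "LPA", "DG", "MG", "TG", "FA", "PE", "LPE",
             "Cer", "SM", "dhCer"]
    comps = ["16:0", "18:1", "20:4", "34:1", "34:2", "36:2", "50:2", "52:3",
             "22:5", "24:5"]
    for _ in range(25):
        names = sorted(
            {f"{rng.choice(codes)} {rng.choice(comps)}"
             for _ in range(rng.randint(2, 20))}
        )
        ds = make_dataset(names)
        index = SpeciesIndex.from_dataset(ds)
        species = [
            (rec.label, rec.parsed.subclass,
             rec.parsed.composition.carbons, rec.parsed.composition.double_bonds)
            for rec in ds.records if rec.label
        ]
        for reaction in db.reactions.values():
            assert match_reaction(reaction, index) == brute_force(reaction, species), (
                f"mismatch for {reaction.id} on {names}"
            )
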