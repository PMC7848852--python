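"""Synthetic two-condition lipidomics datasets with planted effects.

The generator emulates the tables produced by replicated quantitative
lipidomics experiments: per-sample abundances are drawn i.i.d. from a
lognormal baseline and a *planted effect* multiplies the product-side
species of a chosen reaction by a fold-change in the condition of
interest.  Because the per-reaction statistic is a log abundance ratio,
this generator makes the reaction activity exactly normal, with a
closed-form expected Z of roughly
``ln(fold) / sqrt(sigma_a^2/n_I + sigma_a^2/n_C)`` where ``sigma_a`` is
the activity standard deviation — which makes the generator usable as a
simulation oracle for power and type-I-error checks.

Defaults model a modest experiment: five replicates per condition,
lognormal noise with sigma = 0.1 on the natural-log scale, and a
two-fold planted change.  Every simulation includes a fatty-acid pool so
that acylation/deacylation reactions can be instantiated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reaction_db import ReactionDatabase, default_database
from .stats import ConditionDesign

__all__ = [
    "PlantedEffect",
    "SimulationSpec",
    "default_species",
    "simulate_dataset",
    "simulate_csv",
]

DEFAULT_SIGMA = 0.1
DEFAULT_N_PER_CONDITION = 5
DEFAULT_FOLD = 2.0


@dataclass(frozen=True)
class PlantedEffect:
    """Multiply the product species of ``reaction`` by ``fold`` (interest)."""

    reaction: str
    fold: float = DEFAULT_FOLD

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold-change must be positive")

    @property
    def expected_sign(self) -> int:
        return 1 if self.fold > 1 else (-1 if self.fold < 1 else 0)


def default_species() -> dict[str, tuple[str, ...]]:
    """A small mammalian-tissue-like species panel.

    Compositions are chosen so the core glycerophospholipid, glycerolipid,
    sphingolipid and fatty-acid reactions all instantiate (lyso + FA
    combinations balance their diacyl partners, TG balances DG + FA, and
    the FA panel spans elongation/desaturation steps).
    """
    gpl = ("32:1", "34:1", "34:2", "36:2", "36:4", "38:4")
    lyso = ("16:0", "16:1", "18:1", "18:2", "20:4")
    sph = ("34:1", "36:1", "42:2")
    return {
        "PC": gpl,
        "PE": gpl,
        "PS": gpl,
        "PA": gpl,
        "PG": gpl,
        "PI": gpl,
        "DG": gpl,
        "LPC": lyso,
        "LPE": lyso,
        "LPS": lyso,
        "LPG": lyso,
        "LPA": lyso,
        "MG": lyso,
        "TG": ("50:1", "50:2", "52:2", "54:5"),
        "FA": ("16:0", "16:1", "18:0", "18:1", "18:2", "18:3",
               "20:3", "20:4", "22:5", "24:5"),
        "dhSM": sph,
        "dhCer": sph,
        "Cer": sph,
        "Cer1P": sph,
        "SM": sph,
    }


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated experiment."""

    species: dict[str, tuple[str, ...]] = field(default_factory=default_species)
    n_interest: int = DEFAULT_N_PER_CONDITION
    n_control: int = DEFAULT_N_PER_CONDITION
    log_mean: float = math.log(100.0)
    sigma: float = DEFAULT_SIGMA
    effects: tuple[PlantedEffect, ...] = ()
    paired: bool = False
    seed: int = 0
    condition_of_interest: str = "treated"
    control: str = "control"

    def __post_init__(self) -> None:
        if self.n_interest < 2 or self.n_control < 2:
            raise ValueError("minimum of two replicates per condition")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.paired and self.n_interest != self.n_control:
            raise ValueError("paired simulations need equal replicate counts")

    def design(self) -> ConditionDesign:
        interest = [f"{self.condition_of_interest}{i+1}" for i in range(self.n_interest)]
        control = [f"{self.control}{i+1}" for i in range(self.n_control)]
        assignment = {s: self.condition_of_interest for s in interest}
        assignment.update({s: self.control for s in control})
        return ConditionDesign(
            condition_of_interest=self.condition_of_interest,
            control=self.control,
            sample_assignment=assignment,
            paired=self.paired,
            pairs=tuple(zip(interest, control)) if self.paired else (),
        )


def _affected_labels(effect: PlantedEffect, db: ReactionDatabase,
                     species: dict[str, tuple[str, ...]]) -> list[str]:
    if effect.reaction not in db.reactions:
        raise ValueError(f"planted effect names unknown reaction {effect.reaction!r}")
    r = db.reactions[effect.reaction]
    if r.product_comp:  # FA step: only the specific product composition
        labels = [r.product_label] if r.product_comp in species.get(r.product, ()) else []
    else:
        labels = [f"{r.product}({c})" for c in species.get(r.product, ())]
    if not labels:
        raise ValueError(
            f"planted effect on {effect.reaction!r}: spec contains no species "
            f"of product subclass {r.product!r}"
        )
    return labels


def simulate_dataset(
    spec: SimulationSpec, db: ReactionDatabase | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate the abundance table and a ground-truth manifest.

    Returns
    -------
    table:
        DataFrame in the input-CSV shape: a ``Species`` column of
        shorthand names followed by one numeric column per sample
        (interest samples first).
    manifest:
        ``{"seed", "sigma", "conditions", "effects": [{reaction, fold,
        expected_sign, affected_species}, ...]}`` — the planted truth
        against which recovery is measured.
    """
    db = db or default_database()
    rng = np.random.default_rng(spec.seed)
    design = spec.design()
    interest = design.samples(spec.condition_of_interest)
    control = design.samples(spec.control)
    samples = interest + control

    labels: list[str] = []
    for subclass in spec.species:
        for comp in spec.species[subclass]:
            labels.append(f"{subclass}({comp})")

    data = np.exp(rng.normal(spec.log_mean, spec.sigma, size=(len(labels), len(samples))))
    table = pd.DataFrame(data, columns=samples)
    table.insert(0, "Species", labels)

    effects_manifest = []
    for effect in spec.effects:
        affected = _affected_labels(effect, db, spec.species)
        mask = table["Species"].isin(affected)
        table.loc[mask, interest] *= effect.fold
        effects_manifest.append(
            {
                "reaction": effect.reaction,
                "fold": effect.fold,
                "expected_sign": effect.expected_sign,
                "affected_species": affected,
            }
        )

    manifest = {
        "seed": spec.seed,
        "sigma": spec.sigma,
        "n_interest": spec.n_interest,
        "n_control": spec.n_control,
        "paired": spec.paired,
        "conditions": {
            "condition_of_interest": spec.condition_of_interest,
            "control": spec.control,
        },
        "effects": effects_manifest,
    }
    return table, manifest


def simulate_csv(spec: SimulationSpec, path, db: ReactionDatabase | None = None) -> dict:
    """Write a simulated dataset as CSV (byte-stable per seed); return manifest."""
    table, manifest = simulate_dataset(spec, db)
    table.to_csv(path, index=False, float_format="%.6f")
    return manifest
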