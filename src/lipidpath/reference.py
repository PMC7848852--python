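"""Published reference results used for internal-consistency checks.

The tables below reproduce the active reaction chains, combined
Z-scores and predicted genes reported for a public aged-versus-young
mouse liver lipidomics comparison analysed at the lipid-subclass level
(and, for the fatty-acid table, at the FA-composition level) with
alpha = 0.05, unpaired.  They serve two purposes:

* the gene columns pin down the per-step gene annotations of the
  shipped reaction database (every chain's gene list must equal the
  concatenated, de-duplicated per-step lists);
* because chains share steps, the chain-level Z-scores over-determine
  the single-step Z-scores, so inverting the Stouffer combiner on some
  rows and recombining must reproduce the other rows — an internal
  consistency check of the pathway combiner that needs no raw data.

Chain Z-scores are printed to three decimal places, so recombined
values carry a propagated rounding error of order 1e-3.
"""

from __future__ import annotations

from .stats import combine_pathway, invert_chain_z

__all__ = [
    "LIVER_SUBCLASS_CHAINS",
    "LIVER_FA_CHAINS",
    "CORTEX_BRANCH_EXAMPLE",
    "solved_step_z",
    "consistency_fixture",
]

#: (chain label, combined Z, predicted genes) — aged vs young mouse liver,
#: lipid subclass level, active side.
LIVER_SUBCLASS_CHAINS: tuple[tuple[str, float, tuple[str, ...]], ...] = (
    ("PE→PC→PS→LPS", 3.978, ("PEMT", "PTDSS1", "PLA2G2E", "PLA2G2A", "PLA2G2F")),
    ("DG→PC→PS→LPS", 3.686, ("CHPT1", "PTDSS1", "PLA2G2E", "PLA2G2A", "PLA2G2F")),
    ("PE→PC→LPC", 3.519,
     ("PEMT", "PLA2G2E", "PLA2G2A", "PLA2G2D", "PLA2G2F", "PLA2G1B")),
    ("LPA→PA→PG→LPG", 3.367,
     ("AGPAT1", "AGPAT2", "AGPAT3", "AGPAT4", "AGPAT5", "CDS1", "CDS2",
      "PTPMT1", "PLA2G4D", "PLA2G4F", "CRLS1")),
    ("PE→PC→PA→PG→LPG", 3.179,
     ("PEMT", "PLD1", "PLD2", "CDS1", "CDS2", "PTPMT1", "PLA2G4D", "PLA2G4F",
      "CRLS1")),
    ("DG→PC→LPC", 3.161,
     ("CHPT1", "PLA2G2E", "PLA2G2A", "PLA2G2D", "PLA2G2F", "PLA2G1B")),
    ("PG→LPG", 3.077, ("PLA2G4D", "PLA2G4F", "CRLS1")),
    ("LPA→PA→PS→LPS", 2.898,
     ("AGPAT1", "AGPAT2", "AGPAT3", "AGPAT4", "AGPAT5", "CDS1", "PTDSS1",
      "PLA2G2E", "PLA2G2A", "PLA2G2F")),
    ("DG→PE→LPE", 2.815, ("CEPT1", "PLA2G4C")),
    ("PE→PS", 2.700, ("PTDSS2",)),
    ("PC→PS→LPS", 2.657, ("PTDSS1", "PLA2G2E", "PLA2G2A", "PLA2G2F")),
    ("DG→MG", 2.507, ("PNPLA2", "PNPLA3")),
    ("DG→TG", 2.301, ("DGAT2",)),
    ("DG→PC→PA", 2.280, ("CHPT1", "PLD1", "PLD2")),
    ("dhSM→dhCer→Cer→Cer1P", 2.218, ("SGMS1", "SGMS2", "DEGS1", "DEGS2", "CERK")),
    ("DG→PA", 2.050,
     ("DGKA", "DGKB", "DGKD", "DGKE", "DGKG", "DGKH", "DGKI", "DGKK", "DGKQ",
      "DGKZ")),
    ("O-PE→O-LPE", 1.942, ("PLA2G4A",)),
    ("LPA→PA→PI", 1.878,
     ("AGPAT1", "AGPAT2", "AGPAT3", "AGPAT4", "AGPAT5", "CDS1", "CDS2",
      "CDIPT")),
    ("PC→LPC", 1.843,
     ("PLA2G2E", "PLA2G2A", "PLA2G2D", "PLA2G2F", "PLA2G1B")),
    ("PE→PC→PA→PI", 1.837, ("PEMT", "PLD1", "PLD2", "CDS1", "CDS2", "CDIPT")),
    ("PS→LPS", 1.668, ("PLA2G2E", "PLA2G2A", "PLA2G2F")),
    ("PE→PC→CL", 1.667, ("PEMT", "TAZ")),
)

#: Fatty-acid network active chains for the same liver comparison.
LIVER_FA_CHAINS: tuple[tuple[str, float, tuple[str, ...]], ...] = (
    ("FA(22:5)→FA(24:5)", 2.108, ("ELOVL2",)),
    ("FA(18:3)→FA(20:3)", 1.831, ("ELOVL5", "ELOVL7")),
)

#: Branching example from the matching cerebral-cortex comparison: single
#: reaction z for PC→DG, DG→MG and DG→PA; the most-active rule must pick
#: PC→DG→MG over PC→DG→PA.
CORTEX_BRANCH_EXAMPLE: dict[str, float] = {
    "PC->DG": 3.083,
    "DG->MG": 2.054,
    "DG->PA": -0.408,
}


def _chain_z(label: str) -> float:
    for lab, z, _ in LIVER_SUBCLASS_CHAINS:
        if lab == label:
            return z
    raise KeyError(label)


def solved_step_z() -> dict[str, float]:
    """Single-step Z-scores recovered by inverting the Stouffer combiner.

    Uses only chain-level reference values: z(PC→PS) from the printed
    PC→PS→LPS and PS→LPS rows; z(DG→PC) from DG→PC→LPC and PC→LPC;
    z(PE→PC) from PE→PC→LPC and PC→LPC.
    """
    z_ps_lps = _chain_z("PS→LPS")
    z_pc_lpc = _chain_z("PC→LPC")
    return {
        "PC->PS": invert_chain_z(_chain_z("PC→PS→LPS"), 2, [z_ps_lps]),
        "DG->PC": invert_chain_z(_chain_z("DG→PC→LPC"), 2, [z_pc_lpc]),
        "PE->PC": invert_chain_z(_chain_z("PE→PC→LPC"), 2, [z_pc_lpc]),
        "PS->LPS": z_ps_lps,
        "PC->LPC": z_pc_lpc,
    }


def consistency_fixture() -> dict[str, float]:
    """Recombined 3-step chain Z-scores from solved single-step values.

    Returns the combined scores for DG→PC→PS→LPS and PE→PC→PS→LPS,
    each computed from single-step scores that were themselves solved
    from *other* reference rows.
    """
    step = solved_step_z()
    return {
        "DG→PC→PS→LPS": combine_pathway(
            [step["DG->PC"], step["PC->PS"], step["PS->LPS"]]
        ),
        "PE→PC→PS→LPS": combine_pathway(
            [step["PE->PC"], step["PC->PS"], step["PS->LPS"]]
        ),
    }
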