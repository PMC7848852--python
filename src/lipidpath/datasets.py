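"""Reading two-condition quantitative lipidomics tables.

The input is a CSV whose first column holds lipid species names in any
accepted shorthand dialect and whose remaining columns hold per-sample
numeric abundances (relative or molar), with a header row of sample
names.  Species names are normalised to canonical sum-composition labels
on load; duplicate species (identical canonical label) are summed with a
warning, and species observed in fewer than two replicates of either
condition are excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import ParsedLipid, canonical_label, parse_lipid
from .stats import ConditionDesign

log = logging.getLogger(__name__)

__all__ = ["Dataset", "SpeciesRecord", "ConfigurationError", "read_dataset"]


class ConfigurationError(ValueError):
    """Invalid input file or condition configuration (CLI exit code 2)."""


@dataclass
class SpeciesRecord:
    """One input row: the parsed name plus its downstream classification."""

    parsed: ParsedLipid
    label: str | None = None  # canonical label; None when unrecognised
    classification: str = "unrecognised"  # unrecognised | unprocessed | processed


@dataclass
class Dataset:
    """Abundance matrix (canonical species x samples) plus parse records."""

    abundances: pd.DataFrame
    records: list[SpeciesRecord]
    epsilon: float
    design: ConditionDesign | None = None
    excluded: list[str] = field(default_factory=list)

    @property
    def species_labels(self) -> list[str]:
        return list(self.abundances.index)

    def validate_design(self, design: ConditionDesign) -> None:
        missing = set(design.sample_assignment) - set(self.abundances.columns)
        if missing:
            raise ConfigurationError(f"assigned samples not in file: {sorted(missing)}")


def read_dataset(
    path, design: ConditionDesign | None = None
) -> Dataset:
    """Load a lipidomics CSV and normalise species names.

    Parameters
    ----------
    path:
        CSV file path or buffer.  First column: lipid names; remaining
        columns: numeric abundances; header row: sample names.
    design:
        Optional condition design; when given, each condition must keep at
        least two samples present in the file, and species observed in
        fewer than two replicates per condition are excluded.

    Raises
    ------
    ConfigurationError
        Empty file, non-numeric abundance cells (with the line number),
        negative abundances, or a design the file cannot satisfy.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ConfigurationError("input file is empty") from None
    if raw.shape[0] == 0 or raw.shape[1] < 2:
        raise ConfigurationError(
            "input must have a lipid-name column, at least one sample column "
            "and at least one species row"
        )
    name_col = raw.columns[0]
    sample_cols = list(raw.columns[1:])

    values = {}
    for col in sample_cols:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = raw[col].notna() & converted.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise ConfigurationError(
                f"non-numeric abundance in column {col!r}, line {line}: "
                f"{raw.loc[bad.idxmax(), col]!r}"
            )
        if (converted.dropna() < 0).any():
            line = int(converted.lt(0).idxmax()) + 2
            raise ConfigurationError(f"negative abundance in column {col!r}, line {line}")
        values[col] = converted
    numeric = pd.DataFrame(values, index=raw.index)

    records: list[SpeciesRecord] = []
    rows: dict[str, np.ndarray] = {}
    for i, raw_name in raw[name_col].items():
        parsed = parse_lipid(raw_name)
        if not parsed.parsed:
            records.append(SpeciesRecord(parsed=parsed))
            log.warning("unrecognised species %r: %s", raw_name, parsed.rejection_reason)
            continue
        label = canonical_label(parsed)
        records.append(SpeciesRecord(parsed=parsed, label=label, classification="unprocessed"))
        row = numeric.loc[i].to_numpy(dtype=float)
        if label in rows:
            log.warning("duplicate species %s: abundances summed", label)
            rows[label] = np.nansum([rows[label], row], axis=0)
        else:
            rows[label] = row

    abundances = pd.DataFrame.from_dict(rows, orient="index", columns=sample_cols)

    excluded: list[str] = []
    if design is not None:
        for lab in (design.condition_of_interest, design.control):
            cols = [s for s in design.samples(lab) if s in abundances.columns]
            if len(cols) < 2:
                raise ConfigurationError(
                    f"minimum of two replicates per condition; condition {lab!r} "
                    f"has {len(cols)} sample column(s) in the file"
                )
        for label in list(abundances.index):
            ok = all(
                abundances.loc[label, design.samples(lab)].notna().sum() >= 2
                for lab in (design.condition_of_interest, design.control)
            )
            if not ok:
                excluded.append(label)
                log.warning(
                    "species %s observed in <2 replicates per condition; excluded",
                    label,
                )
        abundances = abundances.drop(index=excluded)

    positive = abundances.to_numpy(dtype=float)
    positive = positive[np.isfinite(positive) & (positive > 0)]
    epsilon = float(positive.min()) / 2.0 if positive.size else 0.0
    if epsilon:
        log.info("pseudo-count epsilon = %g (half smallest positive abundance)", epsilon)

    return Dataset(
        abundances=abundances,
        records=records,
        epsilon=epsilon,
        design=design,
        excluded=excluded,
    )
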