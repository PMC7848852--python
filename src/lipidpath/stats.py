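"""Reaction and pathway Z-score statistics.

For each instantiated reaction edge, the per-sample *activity* is the log
ratio of total product abundance to total substrate abundance (a flux
proxy).  Activities are compared between the condition of interest and
the control condition with a Welch-type statistic (or a one-sample
statistic on per-pair differences for matched designs), interpreted on
the standard-normal scale: a reaction is called *active* when
Z > Phi^-1(1 - alpha) (1.645 at the default alpha = 0.05) and
*suppressed* when Z < -Phi^-1(1 - alpha).

Reaction Z-scores along a chain of consecutive reactions are combined
with the Stouffer rule, z_path = sum(z_i) / sqrt(k), giving a global
pathway Z-score on the same normal scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "ConditionDesign",
    "ReactionScore",
    "PathwayScore",
    "reaction_activity",
    "reaction_z",
    "combine_pathway",
    "invert_chain_z",
    "z_crit",
    "status_of",
]


@dataclass(frozen=True)
class ConditionDesign:
    """Assignment of samples to a condition of interest and a control.

    Each condition needs at least two replicates; three or more are
    recommended.  For matched designs, ``pairs`` lists
    (interest sample, control sample) tuples covering every sample.
    """

    condition_of_interest: str
    control: str
    sample_assignment: dict[str, str]
    paired: bool = False
    pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.condition_of_interest == self.control:
            raise ValueError("condition of interest and control must differ")
        labels = set(self.sample_assignment.values())
        for lab in (self.condition_of_interest, self.control):
            n = sum(1 for v in self.sample_assignment.values() if v == lab)
            if n < 2:
                raise ValueError(
                    f"minimum of two replicates per condition; {lab!r} has {n}"
                )
        unknown = labels - {self.condition_of_interest, self.control}
        if unknown:
            raise ValueError(f"samples assigned to unknown conditions: {unknown}")
        if self.paired:
            interest = self.samples(self.condition_of_interest)
            control = self.samples(self.control)
            if not self.pairs:
                raise ValueError("paired design requires explicit pairs")
            if len(self.pairs) != len(interest) or len(self.pairs) != len(control):
                raise ValueError("paired design requires a complete pairing")
            firsts = {a for a, _ in self.pairs}
            seconds = {b for _, b in self.pairs}
            if firsts != set(interest) or seconds != set(control):
                raise ValueError("pairs must cover every sample exactly once")

    def samples(self, label: str) -> list[str]:
        return [s for s, lab in self.sample_assignment.items() if lab == label]

    def swapped(self) -> "ConditionDesign":
        """The mirror design with the two condition labels exchanged."""
        return ConditionDesign(
            condition_of_interest=self.control,
            control=self.condition_of_interest,
            sample_assignment=dict(self.sample_assignment),
            paired=self.paired,
            pairs=tuple((b, a) for a, b in self.pairs),
        )


@dataclass(frozen=True)
class ReactionScore:
    """Signed Z, one-sided tail probability and status for one reaction."""

    z: float
    p: float
    status: str  # "active" | "suppressed" | "none"


@dataclass(frozen=True)
class PathwayScore:
    """A scored chain of consecutive reactions."""

    chain: tuple[str, ...]  # node labels, substrate first
    reactions: tuple[str, ...]  # reaction ids in order
    z: float
    p: float
    status: str
    genes: tuple[str, ...]

    @property
    def label(self) -> str:
        return "→".join(self.chain)


def reaction_activity(
    substrate: np.ndarray, product: np.ndarray, epsilon: float = 0.0
) -> np.ndarray:
    """Per-sample log product/substrate abundance ratio.

    ``substrate`` and ``product`` are per-sample totals over the species
    instantiating the edge (a single species each at species level).
    ``epsilon`` is a pseudo-count tolerating zero totals — by convention
    half the smallest positive abundance in the dataset.  Samples in which
    both totals are zero (and epsilon is zero) yield NaN and should be
    dropped by the caller.
    """
    s = np.asarray(substrate, dtype=float) + epsilon
    p = np.asarray(product, dtype=float) + epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(p) - np.log(s)


def status_of(z: float, alpha: float = 0.05) -> str:
    zc = z_crit(alpha)
    if z > zc:
        return "active"
    if z < -zc:
        return "suppressed"
    return "none"


def reaction_z(
    activity_interest,
    activity_control,
    paired: bool = False,
    alpha: float = 0.05,
) -> ReactionScore:
    """Z-score for the shift of one reaction between conditions.

    Unpaired: Welch-type ``(m_I - m_C) / sqrt(s_I^2/n_I + s_C^2/n_C)``
    with unbiased sample variances.  Paired: one-sample statistic
    ``mean(d) / (s_d / sqrt(n))`` on per-pair differences (interest minus
    control, given in pair order).  The statistic is read on the
    standard-normal scale; ``p = 1 - Phi(z)``.

    Degenerate inputs: zero pooled variance with equal means gives z = 0;
    zero variance with unequal means gives a signed infinity sentinel.
    """
    ai = np.asarray(activity_interest, dtype=float)
    ac = np.asarray(activity_control, dtype=float)
    if paired:
        if len(ai) != len(ac):
            raise ValueError("paired scoring needs equal-length, pair-ordered inputs")
        mask = np.isfinite(ai) & np.isfinite(ac)  # drop broken pairs jointly
        d = ai[mask] - ac[mask]
        if len(d) < 2:
            raise ValueError("need at least two pairs")
        m = float(np.mean(d))
        s = float(np.std(d, ddof=1))
        se = s / math.sqrt(len(d))
    else:
        ai = ai[np.isfinite(ai)]
        ac = ac[np.isfinite(ac)]
        if len(ai) < 2 or len(ac) < 2:
            raise ValueError("need at least two replicates per condition")
        m = float(np.mean(ai) - np.mean(ac))
        se = math.sqrt(
            np.var(ai, ddof=1) / len(ai) + np.var(ac, ddof=1) / len(ac)
        )
    if se == 0.0:
        z = 0.0 if m == 0.0 else math.copysign(math.inf, m)
    else:
        z = m / se
    p = float(norm.sf(z))
    return ReactionScore(z=z, p=p, status=status_of(z, alpha))


def combine_pathway(z_list) -> float:
    """Stouffer combination of reaction Z-scores along a chain.

    ``z_path = sum(z_i) / sqrt(k)`` for k reactions; the single-reaction
    chain returns its own z unchanged.
    """
    zs = [float(z) for z in z_list]
    if not zs:
        raise ValueError("cannot combine an empty chain")
    if not all(math.isfinite(z) for z in zs):
        raise ValueError("chain contains non-finite Z-scores")
    return sum(zs) / math.sqrt(len(zs))


def invert_chain_z(chain_z: float, n_steps: int, known_step_z) -> float:
    """Solve one unknown single-step z from a combined chain z.

    Given ``chain_z = (z_unknown + sum(known)) / sqrt(n_steps)``, returns
    ``z_unknown``.  Used to recover single-reaction scores from published
    chain-level tables for consistency checks.
    """
    known = [float(z) for z in known_step_z]
    if len(known) != n_steps - 1:
        raise ValueError("need exactly n_steps - 1 known step scores")
    return chain_z * math.sqrt(n_steps) - sum(known)


def z_crit(alpha: float) -> float:
    """One-sided standard-normal critical value, ``Phi^-1(1 - alpha)``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(norm.ppf(1.0 - alpha))
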