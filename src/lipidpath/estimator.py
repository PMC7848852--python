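"""Scikit-learn-style front end for the pathway analysis.

``LipidPathwayAnalysis`` is a fit-shaped estimator: ``X`` is a pandas
DataFrame of samples (rows) by lipid species (columns, shorthand names)
and ``y`` the per-sample condition labels.  Fitting parses and
classifies the species, builds the induced reaction network, scores
every reaction, and enumerates significant chains on both sides.  All
results live in trailing-underscore attributes; ``get_params`` /
``set_params`` follow sklearn conventions so the estimator composes
with ``clone`` and model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import ConfigurationError, Dataset
from .network import build_network, classify_species, score_network
from .pathways import (
    DEFAULT_MAX_CHAIN_LENGTH,
    ChainQuery,
    enumerate_chains,
    most_extreme_routes,
)
from .reaction_db import default_database, load_database
from .stats import ConditionDesign

__all__ = ["LipidPathwayAnalysis", "analyze"]


class LipidPathwayAnalysis(BaseEstimator):
    """Two-condition lipidome reaction-network pathway analysis.

    Parameters
    ----------
    condition_of_interest, control:
        Condition labels compared as interest vs control.  When omitted,
        the first label encountered in ``y`` is the condition of interest
        and the second the control.
    alpha:
        One-sided significance level; 0.05 corresponds to the critical
        Z of 1.645.
    paired:
        Matched-pairs design; pairs are formed by order of appearance
        within each condition unless ``pairs`` is given.
    pairs:
        Explicit (interest sample, control sample) index pairs.
    level:
        ``"subclass"`` or ``"species"`` aggregation of the lipid network.
    network_type:
        ``"lipid"`` or ``"fa"`` (fatty-acid elongation/desaturation
        network).
    subset:
        Optional named pathway subset from the database.
    mode:
        ``"all_significant"`` chains or one ``"most_extreme"`` route per
        starting substrate.
    max_chain_length:
        Cap on the number of reactions per enumerated chain.
    database:
        Path to a database override directory (``None`` = packaged).
    require_fa_for_deacylation:
        Whether deacylation edges need a balancing FA species, symmetric
        with acylation.

    Attributes
    ----------
    network_ : networkx.DiGraph
        Scored reaction network induced by the data.
    reaction_scores_ : pandas.DataFrame
        One row per instantiated reaction edge (z, p, status, genes).
    pathway_scores_ : dict
        ``{"active": [...], "suppressed": [...]}`` lists of
        :class:`~lipidpath.stats.PathwayScore`.
    classification_report_ : ClassificationReport
        Unrecognised / unprocessed / processed partition counts.
    design_ : ConditionDesign
    """

    def __init__(
        self,
        condition_of_interest: str | None = None,
        control: str | None = None,
        alpha: float = 0.05,
        paired: bool = False,
        pairs=None,
        level: str = "subclass",
        network_type: str = "lipid",
        subset: str | None = None,
        mode: str = "all_significant",
        max_chain_length: int = DEFAULT_MAX_CHAIN_LENGTH,
        database: str | None = None,
        require_fa_for_deacylation: bool = True,
    ):
        self.condition_of_interest = condition_of_interest
        self.control = control
        self.alpha = alpha
        self.paired = paired
        self.pairs = pairs
        self.level = level
        self.network_type = network_type
        self.subset = subset
        self.mode = mode
        self.max_chain_length = max_chain_length
        self.database = database
        self.require_fa_for_deacylation = require_fa_for_deacylation

    # ------------------------------------------------------------------

    def _resolve_design(self, samples: list[str], y) -> ConditionDesign:
        y = list(np.asarray(y).ravel())
        if len(y) != len(samples):
            raise ConfigurationError(
                f"y has {len(y)} labels for {len(samples)} samples"
            )
        assignment = {s: str(lab) for s, lab in zip(samples, y)}
        interest, control = self.condition_of_interest, self.control
        if interest is None or control is None:
            seen: list[str] = []
            for lab in assignment.values():
                if lab not in seen:
                    seen.append(lab)
            if len(seen) != 2:
                raise ConfigurationError(
                    f"need exactly two condition labels, got {seen}"
                )
            interest = interest or seen[0]
            control = control or (seen[1] if seen[1] != interest else seen[0])
        pairs = tuple(self.pairs) if self.pairs else ()
        if self.paired and not pairs:
            pairs = tuple(
                zip(
                    [s for s in samples if assignment[s] == interest],
                    [s for s in samples if assignment[s] == control],
                )
            )
        try:
            return ConditionDesign(
                condition_of_interest=str(interest),
                control=str(control),
                sample_assignment=assignment,
                paired=self.paired,
                pairs=pairs,
            )
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from exc

    def fit(self, X: pd.DataFrame, y):
        """Run the full analysis on samples ``X`` with condition labels ``y``."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a pandas DataFrame of samples x lipid species"
            )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        samples = [str(s) for s in X.index]
        design = self._resolve_design(samples, y)

        # lipids-as-rows table, as in the input CSV convention
        from .datasets import read_dataset
        import io as _io

        buf = _io.StringIO()
        wide = X.T
        wide.index.name = "Species"
        wide.columns = samples
        wide.to_csv(buf)
        buf.seek(0)
        dataset = read_dataset(buf, design=design)

        db = load_database(self.database) if self.database else default_database()
        self.classification_report_ = classify_species(
            dataset, db, self.require_fa_for_deacylation
        )
        G = build_network(
            dataset,
            db,
            level=self.level,
            network_type=self.network_type,
            subset=self.subset,
            require_fa_for_deacylation=self.require_fa_for_deacylation,
        )
        score_network(G, dataset, design, alpha=self.alpha)

        query_kwargs = dict(alpha=self.alpha, max_chain_length=self.max_chain_length)
        enum = most_extreme_routes if self.mode == "most_extreme" else enumerate_chains
        self.pathway_scores_ = {
            side: enum(G, ChainQuery(status_filter=side, mode=self.mode, **query_kwargs), db)
            for side in ("active", "suppressed")
        }

        rows = []
        for u, v in sorted(G.edges):
            attrs = G.edges[u, v]
            rows.append(
                {
                    "substrate": u,
                    "product": v,
                    "reaction": attrs["reaction"],
                    "kind": attrs["kind"],
                    "z": attrs["z"],
                    "p": attrs["p"],
                    "status": attrs["status"],
                    "genes": ", ".join(attrs["genes"]),
                }
            )
        self.reaction_scores_ = pd.DataFrame(
            rows,
            columns=["substrate", "product", "reaction", "kind", "z", "p",
                     "status", "genes"],
        )
        self.network_ = G
        self.dataset_ = dataset
        self.design_ = design
        self.database_ = db
        return self

    def fit_predict(self, X, y):
        """Fit and return the per-edge status Series (edge label -> status)."""
        self.fit(X, y)
        idx = self.reaction_scores_["substrate"] + "→" + self.reaction_scores_["product"]
        return pd.Series(self.reaction_scores_["status"].values, index=idx.values)


def analyze(X: pd.DataFrame, y, **params) -> LipidPathwayAnalysis:
    """Functional wrapper: fit a :class:`LipidPathwayAnalysis` and return it."""
    return LipidPathwayAnalysis(**params).fit(X, y)
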