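"""Machine-learning-based selection of disease-associated taxa.

Seven feature rankers, each returning the top ceil(top_frac * p) taxa for a
binary disease label (0 healthy / 1 diseased):

  f_test_kbest      one-way ANOVA F statistic per taxon (SelectKBest)
  mutual_info_kbest nonparametric MI between taxon and label (SelectKBest)
  rfe_logistic      recursive feature elimination, logistic-regression weights
  rfe_tree          RFE, decision-tree importances
  rfe_boosting      RFE, gradient-boosting importances
  rfe_forest        RFE, random-forest importances
  abundance_top     taxa whose maximum abundance reaches the top fraction
                    of the per-taxon maxima (catches dominant taxa that
                    model-driven rankers may ignore)

Each ranker is run per normalisation (CLR / raw / log / TSS); within one
normalisation, the TOTAL score of a taxon is the number of methods that
selected it (0-7), and the default selection keeps taxa with TOTAL
strictly greater than the majority-rule cutoff of 3, i.e. supported by more
than half of the seven methods.  The cross-normalisation intersection flags
taxa robust to the preprocessing choice.

Standard learners come from scikit-learn with pinned defaults (logistic:
L2, C=1, lbfgs; forest/boosting: 100 estimators; tree: unrestricted
depth), recorded in the report for reproducibility; the bespoke logic is
the top-fraction rule and the TOTAL aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import (
    RFE,
    SelectKBest,
    f_classif,
    mutual_info_classif,
)
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .abundance_io import AbundanceTable
from .normalize import NormalizedTable, normalize

__all__ = ["ML_METHODS", "MlConfig", "rank_features", "total_score", "ml_selected"]

ML_METHODS = (
    "f_test_kbest",
    "mutual_info_kbest",
    "rfe_logistic",
    "rfe_tree",
    "rfe_boosting",
    "rfe_forest",
    "abundance_top",
)


@dataclass
class MlConfig:
    methods: tuple[str, ...] = ML_METHODS
    top_frac: float = 0.20
    total_cutoff: int = 3
    normalizations: tuple[str, ...] = ("clr", "none", "log", "tss")
    pseudocount: float = 1.0
    seed: int = 0
    # pinned learner hyperparameters
    n_estimators: int = 100
    logistic_c: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ML_METHODS)
        if unknown:
            raise ValueError(f"unknown ML methods: {sorted(unknown)}")
        if not 0 < self.top_frac <= 1:
            raise ValueError("top_frac must lie in (0, 1]")
        if not 0 <= self.total_cutoff < len(self.methods):
            raise ValueError("total_cutoff must lie in [0, number of methods)")


def _validate_xy(table: NormalizedTable, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (table.n_samples,):
        raise ValueError("labels length must equal the number of samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    if table.n_samples < 10:
        raise ValueError("need at least 10 samples for ML-based ranking")
    if table.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    return labels


def rank_features(
    table: NormalizedTable,
    labels: np.ndarray,
    method: str,
    top_frac: float = 0.20,
    seed: int = 0,
    config: MlConfig | None = None,
) -> set[str]:
    """Run one ranker; returns the selected taxon set (size ceil(top_frac*p)).

    ``abundance_top`` may select more on ties at the quantile boundary.
    """
    config = config or MlConfig(top_frac=top_frac, seed=seed)
    labels = _validate_xy(table, labels)
    x = np.asarray(table.values, dtype=float)
    p = table.n_taxa
    k = ceil(top_frac * p)
    taxa = np.asarray(table.taxon_ids)

    if method == "abundance_top":
        maxima = x.max(axis=0)
        cutoff = np.quantile(maxima, 1 - top_frac)
        return set(taxa[maxima >= cutoff])
    if method == "f_test_kbest":
        sel = SelectKBest(f_classif, k=k).fit(x, labels)
        return set(taxa[sel.get_support()])
    if method == "mutual_info_kbest":
        score = lambda X, y: mutual_info_classif(X, y, random_state=seed)  # noqa: E731
        sel = SelectKBest(score, k=k).fit(x, labels)
        return set(taxa[sel.get_support()])
    estimators = {
        "rfe_logistic": lambda: LogisticRegression(
            penalty="l2", C=config.logistic_c, max_iter=2000
        ),
        "rfe_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "rfe_boosting": lambda: GradientBoostingClassifier(
            n_estimators=config.n_estimators, random_state=seed
        ),
        "rfe_forest": lambda: RandomForestClassifier(
            n_estimators=config.n_estimators, random_state=seed
        ),
    }
    if method not in estimators:
        raise ValueError(f"unknown ML method {method!r}")
    rfe = RFE(estimators[method](), n_features_to_select=k).fit(x, labels)
    return set(taxa[rfe.get_support()])


def total_score(
    table: AbundanceTable, labels: np.ndarray | None = None,
    config: MlConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every configured ranker under every normalisation.

    Returns one flag matrix per normalisation (taxa x methods, 0/1, plus a
    TOTAL column), and under the key ``"intersection"`` a one-column frame
    marking taxa selected (TOTAL > cutoff) under *all* normalisations.
    """
    config = config or MlConfig()
    if labels is None:
        labels = table.labels
    if labels is None:
        raise ValueError("disease labels are required for ML-based selection")
    out: dict[str, pd.DataFrame] = {}
    per_norm_selected: list[set[str]] = []
    for norm in config.normalizations:
        normalized = normalize(table, norm, config.pseudocount)
        flags = pd.DataFrame(
            0, index=list(table.taxon_ids), columns=list(config.methods), dtype=int
        )
        for method in config.methods:
            chosen = rank_features(
                normalized, labels, method, config.top_frac, config.seed, config
            )
            flags.loc[sorted(chosen), method] = 1
        flags["TOTAL"] = flags[list(config.methods)].sum(axis=1)
        out[norm] = flags
        per_norm_selected.append(
            set(flags.index[flags["TOTAL"] > config.total_cutoff])
        )
    inter = set.intersection(*per_norm_selected) if per_norm_selected else set()
    out["intersection"] = pd.DataFrame(
        {"selected": [t in inter for t in table.taxon_ids]},
        index=list(table.taxon_ids),
    )
    return out


def ml_selected(
    total_report: dict[str, pd.DataFrame],
    cutoff: int = 3,
    normalization: str = "log",
) -> set[str]:
    """Taxa with TOTAL strictly greater than ``cutoff`` in one normalisation.

    The headline set defaults to the log normalisation's TOTAL column.
    """
    if normalization not in total_report:
        raise ValueError(
            f"normalization {normalization!r} not present in the report "
            f"(have {sorted(total_report)})"
        )
    flags = total_report[normalization]
    return set(flags.index[flags["TOTAL"] > cutoff])
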