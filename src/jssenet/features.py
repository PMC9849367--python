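"""Feature assembly and in-fold connection selection with consensus reporting.

Each subject contributes three feature blocks: the upper-triangle connection
weights of the divergence matrix (fixed pair order, row-major i < j), the
eleven summed global metrics, and the six-per-region summed nodal metrics.
Connection features are screened per training fold with a two-sample t-test
at alpha = 0.05 with no multiplicity correction (the screening is part of a
cross-validated pipeline, not an inference procedure; an FDR column is
available for post-hoc reporting).  Connections selected in every fold form
the consensus set; the union across folds is retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from jssenet.metrics import MetricBundle
from jssenet.network import ConnectivityMatrix


@dataclass(frozen=True)
class FeatureBundle:
    """One subject's three feature blocks (connection, global, nodal)."""

    connection: np.ndarray  # n(n-1)/2
    global_: np.ndarray  # 11
    nodal: np.ndarray  # 6 n

    @property
    def block(self) -> dict[str, np.ndarray]:
        return {"C": self.connection, "G": self.global_, "N": self.nodal}


def connection_pair_index(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed (i, j) pair order of the connection block: row-major upper triangle."""
    return np.triu_indices(n_rois, k=1)


def assemble_features(W: ConnectivityMatrix, M: MetricBundle) -> FeatureBundle:
    if W.n_rois != M.n_rois:
        raise ValueError(f"ROI count mismatch: matrix {W.n_rois} vs metrics {M.n_rois}")
    iu, ju = connection_pair_index(W.n_rois)
    return FeatureBundle(
        connection=W.values[iu, ju].astype(np.float64),
        global_=np.asarray(M.global_sum, dtype=np.float64),
        nodal=np.asarray(M.nodal_sum, dtype=np.float64).ravel(order="C"),
    )


def ttest_connections(
    X: np.ndarray, labels: np.ndarray, welch: bool = False
) -> np.ndarray:
    """Two-sided two-sample t-test per connection feature.

    ``X`` is (n_subjects, n_features); ``labels`` a two-level vector.
    Student's equal-variance t by default (``welch=True`` switches).
    Features with zero variance in both groups and equal means get p = 1.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError("need exactly two groups in the training labels")
    a = X[labels == levels[0]]
    b = X[labels == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=np.float64)
    p[~np.isfinite(p)] = 1.0  # degenerate (constant) features
    return p


def select_features(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Indices with p strictly below alpha, sorted ascending; may be empty."""
    p = np.asarray(pvalues, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.flatnonzero(p < alpha)


@dataclass(frozen=True)
class SelectionResult:
    per_fold_selected: tuple[frozenset, ...]
    consensus: frozenset
    union: frozenset
    pvalues: tuple[np.ndarray, ...] = ()


def consensus(per_fold_selected, pvalues=()) -> SelectionResult:
    """Intersect per-fold selections (consensus) and keep the union alongside."""
    folds = [frozenset(int(i) for i in s) for s in per_fold_selected]
    if not folds:
        raise ValueError("need at least one fold")
    inter = frozenset.intersection(*folds)
    union = frozenset.union(*folds)
    return SelectionResult(
        per_fold_selected=tuple(folds),
        consensus=inter,
        union=union,
        pvalues=tuple(np.asarray(p) for p in pvalues),
    )


def consensus_table(
    result: SelectionResult,
    X: np.ndarray,
    labels: np.ndarray,
    roi_names,
    n_rois: int,
    fdr: bool = False,
) -> pd.DataFrame:
    """Tabulate consensus connections: region names, group means, p-value.

    The p-value column reports a whole-cohort two-sample t-test for each
    consensus connection (descriptive; the in-fold screening already
    happened).  ``fdr=True`` appends Benjamini-Hochberg adjusted values.
    """
    iu, ju = connection_pair_index(n_rois)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    rows = []
    idx = sorted(result.consensus)
    if idx:
        p_all = ttest_connections(X[:, idx], labels)
    else:
        p_all = np.array([])
    for k, e in enumerate(idx):
        rows.append(
            {
                "roi_i": roi_names[iu[e]],
                "roi_j": roi_names[ju[e]],
                f"mean_{levels[0]}": float(X[labels == levels[0], e].mean()),
                f"mean_{levels[1]}": float(X[labels == levels[1], e].mean()),
                "p_value": float(p_all[k]),
            }
        )
    table = pd.DataFrame(rows)
    if fdr and len(table):
        table["p_fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table
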