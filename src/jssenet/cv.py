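"""Nested leave-one-out cross-validation and performance reporting.

Every subject is held out once (outer loop).  On the remaining subjects the
connection block is screened by t-test, features are z-scored with
training-fold statistics, and the kernel weights beta (on a simplex grid)
and the SVM cost C are chosen by an inner leave-one-out loop over the
training set.  The winning model is refit on the full training fold and
applied to the held-out subject, so nothing downstream of the split ever
sees the test subject.  The positive class is the high-responder group.

Seven method variants are compared, mirroring the single-modality and
combined designs: G, N, C, N+G, C+G, C+N, C+G+N (C = connection weights,
G = global metrics, N = nodal metrics).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.metrics import roc_curve

from jssenet import __version__ as _pkg_version
from jssenet.cohort import GROUP_HIGH, GROUP_LOW, CohortSpec, generate_cohort
from jssenet.features import (
    FeatureBundle,
    assemble_features,
    consensus,
    consensus_table,
    select_features,
    ttest_connections,
)
from jssenet.metrics import metrics_over_grid
from jssenet.mksvm import (
    MKSVMModel,
    combine_kernels,
    decision_value,
    linear_kernel,
    simplex_grid,
    train,
)
from jssenet.network import NetworkConfig, build_connectivity_matrix

logger = logging.getLogger(__name__)

METHODS = ("G", "N", "C", "N+G", "C+G", "C+N", "C+G+N")
_MODALITY_ORDER = ("C", "G", "N")


def method_modalities(method: str) -> tuple[str, ...]:
    tokens = set(method.split("+"))
    if not tokens or tokens - set(_MODALITY_ORDER):
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return tuple(m for m in _MODALITY_ORDER if m in tokens)


@dataclass(frozen=True)
class CVConfig:
    """Model-selection settings for the nested loop.

    The default beta step (0.1, 66 simplex points for three modalities) and
    C grid {2^-5, 2^-3, ..., 2^5} give a thorough search; ``reduced`` is a
    coarser preset for simulation studies where many cohorts are run.
    """

    alpha: float = 0.05
    beta_step: float = 0.1
    c_grid: tuple[float, ...] = tuple(float(2.0**k) for k in range(-5, 6, 2))
    welch: bool = False
    inner_reselect: bool = False

    @classmethod
    def reduced(cls) -> "CVConfig":
        return cls(beta_step=0.5, c_grid=(1.0,))


@dataclass(frozen=True)
class FoldRecord:
    subject_id: str
    y_true: int
    y_pred: int
    decision: float
    selected: frozenset
    beta: tuple[float, ...]
    C: float
    selection_empty: bool


@dataclass(frozen=True)
class CVResult:
    method: str
    folds: tuple[FoldRecord, ...]

    @property
    def y_true(self) -> np.ndarray:
        return np.array([f.y_true for f in self.folds])

    @property
    def y_pred(self) -> np.ndarray:
        return np.array([f.y_pred for f in self.folds])

    @property
    def decisions(self) -> np.ndarray:
        return np.array([f.decision for f in self.folds])

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))

    def selection_result(self):
        return consensus([f.selected for f in self.folds])


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def labels_to_y(groups) -> np.ndarray:
    """Map group labels to {+1, -1} with the high-responder group positive."""
    y = np.empty(len(groups), dtype=np.float64)
    for k, g in enumerate(groups):
        if g == GROUP_HIGH:
            y[k] = 1.0
        elif g == GROUP_LOW:
            y[k] = -1.0
        else:
            raise ValueError(f"unknown group label {g!r}")
    return y


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _blocks_for_fold(
    bundles: list[FeatureBundle],
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    modalities: tuple[str, ...],
    config: CVConfig,
):
    """Select (connection block only), standardize, and stack per-modality data."""
    selected: np.ndarray | None = None
    selection_empty = False
    X_train: list[np.ndarray] = []
    X_test: list[np.ndarray] = []
    for mod in modalities:
        tr = np.stack([bundles[i].block[mod] for i in train_idx])
        te = np.stack([bundles[i].block[mod] for i in test_idx])
        if mod == "C":
            p = ttest_connections(tr, y[train_idx], welch=config.welch)
            sel = select_features(p, alpha=config.alpha)
            selected = sel
            if sel.size == 0:
                # keep the pipeline total: fall back to the full block
                selection_empty = True
                logger.warning("no connection passed screening; using full block")
            else:
                tr = tr[:, sel]
                te = te[:, sel]
        tr, te = _standardize(tr, te)
        X_train.append(tr)
        X_test.append(te)
    return X_train, X_test, selected, selection_empty


def _inner_accuracy(grams, y_tr, beta, C) -> float:
    """Leave-one-out accuracy of (beta, C) inside the training fold."""
    K = combine_kernels(grams, beta)
    n = y_tr.size
    correct = 0
    counted = 0
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        y_in = y_tr[mask]
        if np.unique(y_in).size < 2:
            logger.warning("inner fold lost a class; skipping it")
            continue
        # model selection only needs the decision sign; a looser dual
        # tolerance here cuts the search cost without changing picks
        model = train(
            K[np.ix_(mask, mask)], y_in, C, beta=np.asarray(beta),
            tol=1e-4, max_iter=20_000,
        )
        dv = float((model.alpha * model.y) @ K[mask, k] + model.b)
        pred = 1 if dv >= 0 else -1
        correct += int(pred == y_tr[k])
        counted += 1
    return correct / counted if counted else 0.0


def nested_loocv(
    bundles: list[FeatureBundle],
    groups,
    method: str = "C+G+N",
    config: CVConfig | None = None,
    subject_ids=None,
) -> CVResult:
    """Run the full nested leave-one-out loop for one method variant."""
    config = config or CVConfig()
    modalities = method_modalities(method)
    y = labels_to_y(groups)
    n = len(bundles)
    if n < 6:
        raise ValueError("need at least 6 subjects for nested cross-validation")
    if np.unique(y).size < 2:
        raise ValueError("cohort must contain both groups")
    subject_ids = list(subject_ids) if subject_ids is not None else [f"s{i}" for i in range(n)]
    M = len(modalities)
    betas = simplex_grid(M, config.beta_step) if M > 1 else [(1.0,)]
    folds: list[FoldRecord] = []
    for held in range(n):
        train_idx = np.array([i for i in range(n) if i != held])
        test_idx = np.array([held])
        X_tr, X_te, sel, sel_empty = _blocks_for_fold(
            bundles, y, train_idx, test_idx, modalities, config
        )
        grams = [linear_kernel(x) for x in X_tr]
        y_tr = y[train_idx]
        best = None  # (acc, C, beta)
        for beta in betas:
            for C in config.c_grid:
                acc = _inner_accuracy(grams, y_tr, beta, C)
                cand = (acc, C, beta)
                if best is None or _candidate_better(cand, best):
                    best = cand
        _, C_star, beta_star = best
        K = combine_kernels(grams, beta_star)
        model = train(K, y_tr, C_star, beta=np.asarray(beta_star))
        k_cols = [linear_kernel(xt, xe)[:, 0] for xt, xe in zip(X_tr, X_te)]
        dv = decision_value(model, k_cols)
        pred = 1 if dv >= 0 else -1
        folds.append(
            FoldRecord(
                subject_id=subject_ids[held],
                y_true=int(y[held]),
                y_pred=pred,
                decision=dv,
                selected=frozenset(int(i) for i in (sel if sel is not None else [])),
                beta=tuple(beta_star),
                C=float(C_star),
                selection_empty=sel_empty,
            )
        )
    return CVResult(method=method, folds=tuple(folds))


def _candidate_better(cand, best) -> bool:
    """Higher inner accuracy wins; ties prefer smaller C, then smaller beta."""
    acc_c, C_c, beta_c = cand
    acc_b, C_b, beta_b = best
    if acc_c != acc_b:
        return acc_c > acc_b
    if C_c != C_b:
        return C_c < C_b
    return beta_c < beta_b


# ---------------------------------------------------------------------------
# performance


def confusion(result: CVResult) -> ConfusionCounts:
    yt, yp = result.y_true, result.y_pred
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        FP=int(np.sum((yt == -1) & (yp == 1))),
        TN=int(np.sum((yt == -1) & (yp == -1))),
        FN=int(np.sum((yt == 1) & (yp == -1))),
    )


def performance(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where a denominator is zero."""
    total = counts.total
    acc = (counts.TP + counts.TN) / total if total else float("nan")
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    sen = counts.TP / pos if pos else float("nan")
    spe = counts.TN / neg if neg else float("nan")
    if pos == 0 or neg == 0:
        logger.warning("confusion counts leave a metric undefined (reported as NaN)")
    return acc, sen, spe


def roc_auc(decisions: np.ndarray, y_true: np.ndarray):
    """ROC points (from pooled decision values) and rank-statistic AUC.

    AUC is the Mann-Whitney probability that a random positive scores above
    a random negative, with tied scores counted one half.
    """
    d = np.asarray(decisions, dtype=np.float64)
    y = np.asarray(y_true)
    pos = d[y == 1]
    neg = d[y == -1]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes are required for a ROC curve")
    ranks = stats.rankdata(d)
    auc = (ranks[y == 1].sum() - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size)
    fpr, tpr, thresholds = roc_curve(y, d, pos_label=1)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, float(auc)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    methods: tuple[str, ...] = METHODS
    sparsity_grid: tuple[float, ...] | None = None
    n_null: int = 100
    grid_points: int = 128
    variant: str = "jeffreys"
    cv: CVConfig = field(default_factory=CVConfig)
    seed: int = 0
    fdr_report: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortSpec(**{
            k: (tuple(tuple(p) for p in v) if k == "effect_pairs" else v)
            for k, v in raw.pop("cohort", {}).items()
        })
        cv_raw = raw.pop("cv", {})
        if "c_grid" in cv_raw:
            cv_raw["c_grid"] = tuple(float(c) for c in cv_raw["c_grid"])
        cv = CVConfig(**cv_raw)
        methods = tuple(raw.pop("methods", METHODS))
        for m in methods:
            method_modalities(m)  # fail fast on typos, before any compute
        grid = raw.pop("sparsity_grid", None)
        return cls(
            cohort=cohort,
            methods=methods,
            sparsity_grid=tuple(grid) if grid is not None else None,
            cv=cv,
            **raw,
        )


def cohort_feature_bundles(
    cohort,
    net_config: NetworkConfig,
    sparsity_grid,
    n_null: int,
    seed,
) -> tuple[list[FeatureBundle], list, list[np.ndarray]]:
    """Networks + metric sums + feature blocks for every subject."""
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(len(cohort))
    bundles = []
    matrices = []
    for k, (_, roi_samples) in enumerate(cohort):
        W = build_connectivity_matrix(roi_samples, config=net_config)
        M = metrics_over_grid(W, grid=sparsity_grid, n_null=n_null, seed=subject_seeds[k])
        bundles.append(assemble_features(W, M))
        matrices.append(W.values)
    return bundles, [rec for rec, _ in cohort], matrices


def run_pipeline(config: PipelineConfig | str | Path, outdir) -> dict:
    """Run the whole analysis on a synthetic cohort and write the report.

    Outputs in ``outdir``: per-method performance table (TSV), pooled ROC
    points per method (TSV), the consensus-connection table for the
    connection-bearing methods (TSV), subject metadata, an edge-list export
    of the group-mean network, and a JSON manifest with seeds and versions.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in config.methods:
        method_modalities(m)

    cohort = generate_cohort(config.cohort)
    net_config = NetworkConfig(grid_points=config.grid_points, variant=config.variant)
    grid = np.asarray(config.sparsity_grid) if config.sparsity_grid is not None else None
    bundles, records, matrices = cohort_feature_bundles(
        cohort, net_config, grid, config.n_null, config.seed
    )
    groups = [r.group for r in records]
    ids = [r.subject_id for r in records]

    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "updrs_off": r.updrs_off,
                "updrs_on_peak": r.updrs_on_peak,
                "lr_percent": r.lr_percent,
                "group": r.group,
            }
            for r in records
        ]
    ).to_csv(outdir / "subjects.tsv", sep="\t", index=False)

    from jssenet.cohort import default_label_table
    from jssenet.network import ConnectivityMatrix

    label_table = default_label_table(config.cohort.n_rois)
    roi_names = list(label_table["name"])
    mean_net = ConnectivityMatrix(
        values=np.mean(matrices, axis=0), roi_labels=tuple(roi_names)
    )
    mean_net.to_edge_list().to_csv(outdir / "mean_network_edges.tsv", sep="\t", index=False)

    rows = []
    report: dict = {"methods": {}}
    for method in config.methods:
        result = nested_loocv(bundles, groups, method=method, config=config.cv, subject_ids=ids)
        counts = confusion(result)
        acc, sen, spe = performance(counts)
        points, auc = roc_auc(result.decisions, result.y_true)
        points.to_csv(outdir / f"roc_{method.replace('+', '_')}.tsv", sep="\t", index=False)
        rows.append(
            {"method": method, "accuracy": acc, "sensitivity": sen, "specificity": spe,
             "auc": auc, "TP": counts.TP, "FP": counts.FP, "TN": counts.TN, "FN": counts.FN}
        )
        report["methods"][method] = {
            "accuracy": acc, "sensitivity": sen, "specificity": spe, "auc": auc
        }
        if "C" in method_modalities(method):
            sel = result.selection_result()
            X = np.stack([b.connection for b in bundles])
            table = consensus_table(
                sel, X, np.asarray(groups), roi_names, config.cohort.n_rois,
                fdr=config.fdr_report,
            )
            table.to_csv(
                outdir / f"consensus_{method.replace('+', '_')}.tsv", sep="\t", index=False
            )
            report["methods"][method]["n_consensus"] = len(sel.consensus)
            report["methods"][method]["n_union"] = len(sel.union)
    pd.DataFrame(rows).to_csv(outdir / "performance.tsv", sep="\t", index=False)

    manifest = {
        "package_version": _pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "cohort_seed": config.cohort.seed,
        "methods": list(config.methods),
        "n_subjects": len(records),
        "variant": config.variant,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
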