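"""Leave-one-site cross-validation (LOSCV) and configuration comparison.

Each acquisition site in turn is the held-out test set; all remaining sites
train the fold.  Within a fold, edge selection (two-sample t-test), feature
standardization and class weights are computed from training subjects only —
the held-out site never influences them.  Accuracies are plain
correct/total per fold, reported in percent, and aggregated as an
unweighted mean ± sd across folds (a subject-weighted pooled accuracy is
also recorded).

For the DANN two reporting senses are kept: *test* (held-out accuracy at the
epoch of highest training accuracy) and *best_test* (maximum held-out
accuracy over epochs); best_test ≥ test by construction.

Configurations (layer set × classifier × p threshold) are compared with a
two-sided paired t-test across their per-site accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import DannConfig, predict, train_dann, train_svm
from .features import Standardizer, edgewise_ttest, fuse, select_edges
from .networks import build_feature_tables
from .types import EdgeFeatureTable, RoiTimeSeries, labels_to_binary

logger = logging.getLogger(__name__)

__all__ = [
    "EvalConfig",
    "FoldResult",
    "CvReport",
    "Comparison",
    "run_loscv",
    "compare_configurations",
    "summary_frame",
]


@dataclass
class EvalConfig:
    """One experimental configuration of the cross-validated pipeline."""

    layers: tuple[str, ...] = ("LOFC", "tHOFC", "aHOFC")
    classifier: str = "svm"  # "svm" | "dann"
    p_threshold: float = 0.05
    svm_c: float = 1.0
    dann: Optional[DannConfig] = None  # template; input_dim/seed set per fold
    seed: int = 0

    @property
    def name(self) -> str:
        return "Combined" if len(self.layers) > 1 else self.layers[0]


@dataclass
class FoldResult:
    site: str
    n_test: int
    n_features: int
    accuracy_test: float  # percent
    accuracy_best_test: float = float("nan")  # percent, dann only


@dataclass
class CvReport:
    configuration: EvalConfig
    per_fold: list[FoldResult] = field(default_factory=list)

    def accuracies(self, sense: str = "test") -> np.ndarray:
        if sense == "test":
            return np.array([f.accuracy_test for f in self.per_fold])
        if sense == "best_test":
            return np.array([f.accuracy_best_test for f in self.per_fold])
        raise ValueError(f"unknown reporting sense {sense!r}")

    def mean_sd(self, sense: str = "test") -> tuple[float, float]:
        acc = self.accuracies(sense)
        sd = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0
        return float(acc.mean()), sd

    def pooled_accuracy(self, sense: str = "test") -> float:
        """Subject-weighted accuracy across all held-out predictions, percent."""
        acc = self.accuracies(sense)
        n = np.array([f.n_test for f in self.per_fold])
        return float((acc * n).sum() / n.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "configuration": self.configuration.name,
                "classifier": self.configuration.classifier,
                "p_threshold": self.configuration.p_threshold,
                "site": f.site,
                "n_test": f.n_test,
                "n_features": f.n_features,
                "accuracy_test": f.accuracy_test,
                "accuracy_best_test": f.accuracy_best_test,
            }
            for f in self.per_fold
        ]
        return pd.DataFrame(rows)


def _subset(table: EdgeFeatureTable, idx: np.ndarray) -> EdgeFeatureTable:
    return EdgeFeatureTable(
        table.layer,
        [table.subjects[k] for k in idx],
        table.features[idx],
        table.edge_index,
    )


def run_loscv(
    cohort: list[RoiTimeSeries],
    config: EvalConfig,
    tables: Optional[dict[str, EdgeFeatureTable]] = None,
) -> CvReport:
    """Run the full leave-one-site protocol for one configuration.

    ``tables`` may carry precomputed per-layer feature tables for the whole
    cohort (networks are per-subject quantities, so sharing them across
    configurations and folds leaks nothing); otherwise they are built here.
    """
    sites = sorted({ts.site_id for ts in cohort})
    if len(sites) < 2:
        raise ValueError("leave-one-site cross-validation needs at least 2 sites")
    if tables is None:
        tables = build_feature_tables(cohort, tuple(config.layers))
    subj_site = np.array([ts.site_id for ts in cohort])
    y_all = labels_to_binary([ts.label for ts in cohort])

    fold_seeds = [int(s.generate_state(1)[0] % 2**31) for s in
                  np.random.SeedSequence(config.seed).spawn(len(sites))]
    report = CvReport(configuration=config)
    for fold_k, site in enumerate(sites):
        test_idx = np.flatnonzero(subj_site == site)
        train_idx = np.flatnonzero(subj_site != site)
        y_train, y_test = y_all[train_idx], y_all[test_idx]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"fold {site}: training sites contain a single diagnostic class"
            )

        selections = {}
        for layer in config.layers:
            p = edgewise_ttest(_subset(tables[layer], train_idx), y_train)
            selections[layer] = select_edges(
                p, config.p_threshold, layer=layer, fold_id=site
            )
        train_tabs = {lay: _subset(tables[lay], train_idx) for lay in config.layers}
        test_tabs = {lay: _subset(tables[lay], test_idx) for lay in config.layers}
        fused_train = fuse(train_tabs, selections, tuple(config.layers))
        fused_test = fuse(test_tabs, selections, tuple(config.layers))
        n_feat = fused_train.matrix.shape[1]

        if n_feat == 0:
            # nothing survived the threshold: fall back to the training-fold
            # majority class so null experiments stay alive
            logger.warning("fold %s: empty selection; predicting majority class", site)
            majority = int(np.bincount(y_train).argmax())
            acc = float((y_test == majority).mean()) * 100.0
            report.per_fold.append(FoldResult(site, len(test_idx), 0, acc, acc))
            continue

        scaler = Standardizer.fit(fused_train.matrix)
        x_train = scaler.transform(fused_train.matrix)
        x_test = scaler.transform(fused_test.matrix)

        if config.classifier == "svm":
            model = train_svm(x_train, y_train, c=config.svm_c)
            labels, _ = predict(model, x_test)
            acc = float((labels == y_test).mean()) * 100.0
            report.per_fold.append(FoldResult(site, len(test_idx), n_feat, acc))
        elif config.classifier == "dann":
            template = config.dann or DannConfig(input_dim=n_feat)
            dcfg = replace(template, input_dim=n_feat, seed=fold_seeds[fold_k])
            model = train_dann(
                x_train,
                y_train,
                dcfg,
                x_target=x_test if dcfg.expose_target else None,
                eval_x=x_test,
                eval_y=y_test,
            )
            log = model.training_log
            best_train_epoch = int(log["train_acc"].idxmax())
            acc_test = float(log.loc[best_train_epoch, "test_acc"]) * 100.0
            acc_best = float(log["test_acc"].max()) * 100.0
            report.per_fold.append(
                FoldResult(site, len(test_idx), n_feat, acc_test, acc_best)
            )
        else:
            raise ValueError(f"unknown classifier {config.classifier!r}")
    return report


@dataclass(frozen=True)
class Comparison:
    statistic: float
    p_value: float
    mean_diff: float  # a − b, percentage points
    direction: str  # "a>b" | "b>a" | "equal"


def compare_configurations(
    report_a: CvReport, report_b: CvReport, sense: str = "test"
) -> Comparison:
    """Two-sided paired t-test of per-site accuracies (paired by held-out site)."""
    sites_a = [f.site for f in report_a.per_fold]
    sites_b = [f.site for f in report_b.per_fold]
    if sites_a != sites_b:
        raise ValueError("reports do not share the same folds")
    a = report_a.accuracies(sense)
    b = report_b.accuracies(sense)
    diff = a - b
    mean_diff = float(diff.mean())
    if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
        return Comparison(0.0, 1.0, 0.0, "equal")
    t, p = stats.ttest_rel(a, b)
    if np.isnan(t):  # constant nonzero difference: direction certain
        t, p = np.inf * np.sign(mean_diff), 0.0
    direction = "equal" if mean_diff == 0.0 else ("a>b" if mean_diff > 0 else "b>a")
    return Comparison(float(t), float(p), mean_diff, direction)


def summary_frame(reports: list[CvReport]) -> pd.DataFrame:
    """Long-format summary: one row per configuration × reporting sense."""
    rows = []
    for r in reports:
        senses = ("test", "best_test") if r.configuration.classifier == "dann" else ("test",)
        for sense in senses:
            mean, sd = r.mean_sd(sense)
            rows.append(
                {
                    "configuration": r.configuration.name,
                    "classifier": r.configuration.classifier,
                    "p_threshold": r.configuration.p_threshold,
                    "sense": sense,
                    "mean_accuracy": mean,
                    "sd_accuracy": sd,
                    "pooled_accuracy": r.pooled_accuracy(sense),
                    "n_folds": len(r.per_fold),
                }
            )
    return pd.DataFrame(rows)
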