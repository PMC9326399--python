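"""Cluster characterization: marker scores, differential tests, survival.

The basal composite score summarizes a sample's epithelial/basal identity:
the summed z-scored expression of the basal marker panel minus the summed
z-scores of the mesenchymal and epithelial panels.  Differential
expression between clusters uses pairwise Wilcoxon rank-sum tests with
Holm step-down correction across the cluster pairs of each feature.
Survival comparisons use the Kaplan-Meier product-limit estimator
(median = smallest time at which S(t) drops to 0.5 or below) and the
g-sample log-rank test, with Benjamini-Hochberg q-values across a family
of survival tests.

The default marker panels reproduce a published HNSC marker list verbatim;
several symbols in it look like typographical variants of standard gene
names (e.g. H1F1A), so missing panel genes are skipped with a log message
and an alias map can be supplied to re-map them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterAssignment
from .omics_io import ClinicalTable, OmicsMatrix

logger = logging.getLogger("omicsfuse")

MESENCHYMAL_MARKERS = ["FN1", "VIM", "ZEB1", "CRS", "TWIST2", "SNAI2", "CDH2"]
EPITHELIAL_MARKERS = ["CLDN4", "CLDN7", "TJP3", "PEMT", "CDH1"]
BASAL_MARKERS = [
    "SLC2A", "SLC16A1", "H1F1A", "LAMC", "COL17A1", "ITGB1",
    "AREG", "EGFR", "CDH3", "KRT16", "KRT17", "KRT14",
]


@dataclass
class MarkerPanel:
    """Disjoint basal / mesenchymal / epithelial marker gene lists."""

    basal: list[str] = field(default_factory=lambda: list(BASAL_MARKERS))
    mesenchymal: list[str] = field(default_factory=lambda: list(MESENCHYMAL_MARKERS))
    epithelial: list[str] = field(default_factory=lambda: list(EPITHELIAL_MARKERS))

    def __post_init__(self) -> None:
        lists = [self.basal, self.mesenchymal, self.epithelial]
        if any(len(l) == 0 for l in lists):
            raise ValueError("marker panels must be nonempty")
        all_genes = list(itertools.chain(*lists))
        if len(set(all_genes)) != len(all_genes):
            raise ValueError("marker panels must be disjoint")

    def apply_aliases(self, aliases: Mapping[str, str]) -> "MarkerPanel":
        remap = lambda genes: [aliases.get(g, g) for g in genes]
        return MarkerPanel(remap(self.basal), remap(self.mesenchymal), remap(self.epithelial))


@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray  # distinct event/censor times, ascending
    at_risk: np.ndarray
    survival: np.ndarray  # S(t) just after each time
    median: float  # inf when S never reaches 0.5

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival function must be nonincreasing")


def _panel_sum(frame: pd.DataFrame, genes: Sequence[str], label: str) -> np.ndarray:
    present = [g for g in genes if g in frame.columns]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.info("composite_score: %d %s genes absent, skipped: %s", len(missing), label, missing)
    if not present:
        return np.zeros(len(frame))
    return frame[present].to_numpy(float).sum(axis=1)


def composite_score(expr: OmicsMatrix, panel: MarkerPanel | None = None) -> np.ndarray:
    """Basal composite score per sample on z-scored expression:
    sum(z basal) - (sum(z mesenchymal) + sum(z epithelial))."""
    panel = panel or MarkerPanel()
    frame = expr.to_frame()
    all_genes = panel.basal + panel.mesenchymal + panel.epithelial
    if not any(g in frame.columns for g in all_genes):
        raise ValueError("no marker-panel genes present in the expression matrix")
    basal = _panel_sum(frame, panel.basal, "basal")
    mes = _panel_sum(frame, panel.mesenchymal, "mesenchymal")
    epi = _panel_sum(frame, panel.epithelial, "epithelial")
    return basal - (mes + epi)


def emt_score(expr: OmicsMatrix, panel: MarkerPanel | None = None) -> np.ndarray:
    """Mesenchymal-minus-epithelial score (EMT estimate; the cited EMT
    score's exact gene weights are not reproduced here)."""
    panel = panel or MarkerPanel()
    frame = expr.to_frame()
    mes = _panel_sum(frame, panel.mesenchymal, "mesenchymal")
    epi = _panel_sum(frame, panel.epithelial, "epithelial")
    return mes - epi


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Exact enumeration when the combined sample size is <= 20 and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be nonempty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def pairwise_de(
    expr: OmicsMatrix, clusters: ClusterAssignment, features: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Wilcoxon tests for every feature across all cluster pairs,
    Holm-corrected within each feature."""
    if clusters.K < 2:
        raise ValueError("need at least two clusters")
    if expr.sample_ids != clusters.sample_ids:
        raise ValueError("expression and cluster sample ids must match")
    features = list(features) if features is not None else list(expr.feature_ids)
    frame = expr.to_frame()
    labels = clusters.labels
    rows = []
    pairs = list(itertools.combinations(range(1, clusters.K + 1), 2))
    for feat in features:
        if feat not in frame.columns:
            logger.warning("pairwise_de: feature %r absent, skipped", feat)
            continue
        vals = frame[feat].to_numpy(float)
        stats, praws = [], []
        for ga, gb in pairs:
            u, p = wilcoxon_rank_sum(vals[labels == ga], vals[labels == gb])
            stats.append(u)
            praws.append(p)
        padj = holm_adjust(praws)
        for (ga, gb), u, p, q in zip(pairs, stats, praws, padj):
            rows.append((feat, ga, gb, u, p, q))
    return pd.DataFrame(
        rows, columns=["feature_id", "group_a", "group_b", "statistic", "p_raw", "p_adj_holm"]
    )


def km_curve(times: np.ndarray, events: np.ndarray, group: str = "all") -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator for one group."""
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # the event table carries a synthetic baseline row at t=0; keep observed times
    table = kmf.event_table[kmf.event_table.index.isin(np.unique(times))]
    t_grid = np.asarray(table.index, float)
    surv = kmf.survival_function_at_times(t_grid).to_numpy(float)
    at_risk = table["at_risk"].to_numpy(float)
    median = float(kmf.median_survival_time_)
    return SurvivalCurve(group, t_grid, at_risk, surv, median)


def logrank_test(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, int, float]:
    """g-sample log-rank test; returns (chi2, df, p)."""
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if events.sum() < 1:
        raise ValueError("need at least one observed event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), int(uniq.size - 1), float(res.p_value)


def survival_by_cluster(
    clinical: ClinicalTable, clusters: ClusterAssignment
) -> tuple[list[SurvivalCurve], tuple[float, int, float]]:
    """Per-cluster KM curves plus the overall log-rank test."""
    if clinical.sample_ids != clusters.sample_ids:
        raise ValueError("clinical and cluster sample ids must match")
    curves = []
    for g in range(1, clusters.K + 1):
        m = clusters.labels == g
        curves.append(km_curve(clinical.os_time[m], clinical.os_event[m], group=str(g)))
    lr = logrank_test(clinical.os_time, clinical.os_event, clusters.labels)
    return curves, lr


def bh_qvalues(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values for a family of survival tests."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def write_survival(curves: list[SurvivalCurve], logrank: tuple[float, int, float], path) -> None:
    rows = []
    for c in curves:
        for t, r, s in zip(c.times, c.at_risk, c.survival):
            rows.append((c.group, t, r, s, c.median))
    df = pd.DataFrame(rows, columns=["group", "time", "at_risk", "survival", "median"])
    chi2, df_, p = logrank
    header = f"# logrank_chi2={chi2:.10g}\tdf={df_}\tp={p:.10g}\n"
    if hasattr(path, "write"):
        path.write(header)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
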