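"""Downstream statistics: stress-test bioenergetics, ROC, correlation.

Covers the quantitative analyses that sit behind the morphometry: reducing
a mitochondrial stress-test flux trace to basal/maximal/reserve respiration
and the OCR/ECAR ratio; empirical ROC curves with the rank-based (Mann-
Whitney) AUC; and Pearson correlation with its exact-t two-sided p-value,
assembled into a morphology-versus-sensitivity correlation panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "StressMetrics",
    "ROCResult",
    "CorrelationResult",
    "stress_test_metrics",
    "empirical_roc",
    "pearson_with_p",
    "correlation_panel",
]

PHASE_ORDER = ("baseline", "oligomycin", "fccp", "rotenone")


@dataclass(frozen=True)
class StressMetrics:
    """Protein-normalised stress-test summary (rates per ug protein).

    reserve_capacity = max_ocr - basal_ocr (spare respiratory capacity);
    ocr_ecar_ratio is unitless — a lower ratio marks a more glycolytic
    phenotype. Missing phases yield NaN sentinels.
    """

    basal_ocr: float
    max_ocr: float
    reserve_capacity: float
    basal_ecar: float
    ocr_ecar_ratio: float


def stress_test_metrics(trace: pd.DataFrame, protein: float) -> StressMetrics:
    """Reduce one stress-test trace to its bioenergetic parameters.

    `trace` needs columns (phase, ocr, ecar); rates are divided by `protein`.
    Basal values average the baseline cycles; maximal OCR is the highest
    FCCP-phase measurement. Without an FCCP phase the reserve is NaN; with
    zero basal ECAR the ratio is NaN.
    """
    if protein <= 0:
        raise ValueError("protein must be positive")
    required = {"phase", "ocr", "ecar"}
    if missing := required - set(trace.columns):
        raise ValueError(f"trace lacks columns {sorted(missing)}")
    phases = trace["phase"]
    if not (phases == "baseline").any():
        raise ValueError("trace has no baseline cycles")
    seen = [p for p in PHASE_ORDER if (phases == p).any()]
    order = [seen.index(p) for p in phases.drop_duplicates() if p in seen]
    if order != sorted(order):
        raise ValueError("phases out of canonical order (baseline, oligomycin, fccp, rotenone)")

    base = trace[phases == "baseline"]
    basal_ocr = float(base["ocr"].mean()) / protein
    basal_ecar = float(base["ecar"].mean()) / protein
    fccp = trace[phases == "fccp"]
    if fccp.empty:
        max_ocr = reserve = float("nan")
    else:
        max_ocr = float(fccp["ocr"].max()) / protein
        reserve = max_ocr - basal_ocr
    ratio = basal_ocr / basal_ecar if basal_ecar > 0 else float("nan")
    return StressMetrics(basal_ocr, max_ocr, reserve, basal_ecar, ratio)


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve and its rank-based AUC.

    `thresholds[i]` classifies as positive every score >= thresholds[i]
    (after orientation); sensitivity/specificity are evaluated at each.
    AUC is the normalised Mann-Whitney U statistic: the probability that a
    random positive outranks a random negative, ties counting one half.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: str

    def youden_threshold(self) -> float:
        """Threshold maximising sensitivity + specificity - 1."""
        return float(self.thresholds[np.argmax(self.sensitivity + self.specificity)])


def empirical_roc(scores, labels, orientation: str = "higher") -> ROCResult:
    """ROC analysis of a continuous score against binary labels.

    `labels` are truthy for the positive class. orientation="higher" means
    positives are expected to score higher; "lower" flips the score axis.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if orientation == "lower":
        scores = -scores
    elif orientation != "higher":
        raise ValueError("orientation must be 'higher' or 'lower'")

    ranks = _sps.rankdata(scores)  # average ranks handle ties -> U counts ties as 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    pos_scores, neg_scores = scores[labels], scores[~labels]
    sensitivity = np.array([(pos_scores >= t).mean() for t in thresholds])
    specificity = np.array([(neg_scores < t).mean() for t in thresholds])
    return ROCResult(thresholds, sensitivity, specificity, auc, orientation)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-sided exact-t p-value over n pairs."""

    r: float
    p: float
    n: int


def pearson_with_p(x, y, permutations: int = 0, seed: int = 0) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value.

    The p-value uses the exact t reference distribution
    t = r sqrt(n - 2) / sqrt(1 - r^2); pass `permutations > 0` for a
    permutation p-value instead (seeded, small-n option).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if permutations > 0:
        res = _sps.permutation_test(
            (x, y),
            lambda a, b: _sps.pearsonr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=permutations,
            rng=np.random.default_rng(seed),
        )
        r = float(_sps.pearsonr(x, y).statistic)
        return CorrelationResult(r=r, p=float(res.pvalue), n=n)
    res = _sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def correlation_panel(
    panel: pd.DataFrame,
    metrics: tuple[str, ...] = ("fd", "lacunarity", "basal_ocr", "basal_ecar"),
    ec50_prefix: str = "ec50_",
) -> pd.DataFrame:
    """Correlate every morphology/bioenergetic metric with every EC50 column.

    `panel` has one row per cell line with metric columns and EC50 columns
    named `<ec50_prefix><compound>`. Pairs are dropped pairwise-complete;
    pairs with < 3 complete rows, all-missing columns, or zero variance are
    reported with NaN r and p, never fabricated as zero.
    """
    ec50_cols = [c for c in panel.columns if c.startswith(ec50_prefix)]
    if not ec50_cols:
        raise ValueError(f"panel has no '{ec50_prefix}*' columns")
    rows = []
    for metric in metrics:
        if metric not in panel.columns:
            continue
        for col in ec50_cols:
            sub = panel[[metric, col]].dropna()
            if len(sub) >= 3 and np.ptp(sub[metric]) > 0 and np.ptp(sub[col]) > 0:
                res = pearson_with_p(sub[metric].to_numpy(), sub[col].to_numpy())
                r, p, n = res.r, res.p, res.n
            else:
                r, p, n = np.nan, np.nan, len(sub)
            rows.append((metric, col.removeprefix(ec50_prefix), r, p, n))
    return pd.DataFrame(rows, columns=["metric", "compound", "r", "p", "n"])
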