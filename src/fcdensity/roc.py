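"""ROC discrimination of cluster-mean FCD values between two groups.

For each significant cluster the per-subject mean of the smoothed,
normalized FCD map over the cluster's voxels is treated as a diagnostic
score.  The AUC is the Mann-Whitney statistic scaled to [0, 1] (ties count
one half), oriented so it is always >= 0.5, with the favoured group
recorded.  The 95% confidence interval comes from DeLong's structural-
components estimator by default, with a seeded bootstrap as alternative;
the p-value tests AUC = 0.5 by the corresponding normal approximation.

Accuracy is banded the way the source literature words it: AUC below 0.7 is
"low", 0.7 and above is "excellent" (values above 0.9 stay "excellent").

A note on interpretation the pipeline prints alongside its results:
clusters are selected by the same group contrast the ROC then evaluates, so
these AUCs are optimistically biased — they describe the selected regions,
not out-of-sample diagnostic performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fcd import FcdMap
from .group_stats import Cluster

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterValues",
    "RocResult",
    "cluster_mean_values",
    "roc_auc",
    "roc_curve_points",
    "accuracy_band",
    "CIRCULARITY_WARNING",
]

CIRCULARITY_WARNING = (
    "ROC clusters were selected by the same contrast the AUC evaluates; "
    "AUC values are optimistically biased and are not out-of-sample "
    "diagnostic accuracy."
)


@dataclass
class ClusterValues:
    """Per-subject cluster-mean FCD values for the two groups."""

    cluster_id: str
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float).ravel()
        self.values_b = np.asarray(self.values_b, dtype=float).ravel()
        if not (np.all(np.isfinite(self.values_a)) and np.all(np.isfinite(self.values_b))):
            raise ValueError("cluster values contain non-finite entries")


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    band: str  # "low" | "excellent"
    positive_group: str
    degenerate: bool = False


def cluster_mean_values(
    maps_a: list, maps_b: list, cluster: Cluster, cluster_id: str = ""
) -> ClusterValues:
    """Mean map value over the cluster voxels, per subject and group."""
    if cluster.size == 0:
        raise ValueError("empty cluster")
    vox = tuple(np.array(cluster.voxels).T)

    def means(maps: list) -> np.ndarray:
        out = []
        for m in maps:
            arr = m.values if isinstance(m, FcdMap) else np.asarray(m, float)
            out.append(arr[vox].mean())
        return np.array(out)

    return ClusterValues(
        cluster_id=cluster_id, values_a=means(maps_a), values_b=means(maps_b)
    )


def _pairwise_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) + 0.5 P(pos == neg) over all pairs (Mann-Whitney)."""
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def _delong_ci(
    pos: np.ndarray, neg: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """DeLong variance of the AUC via structural components.

    Returns (auc, ci_low, ci_high, se).
    """
    n, m = len(pos), len(neg)
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per positive subject
    v01 = psi.mean(axis=0)  # per negative subject
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    se = float(np.sqrt(s10 / n + s01 / m))
    z = stats.norm.isf(alpha / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, lo, hi, se


def _bootstrap_ci(
    pos: np.ndarray, neg: np.ndarray, n_boot: int, seed: int,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos, size=len(pos), replace=True)
        q = rng.choice(neg, size=len(neg), replace=True)
        aucs[i] = _pairwise_auc(p, q)
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi), float(aucs.std(ddof=1))


def roc_auc(
    values: ClusterValues,
    group_labels: tuple[str, str] = ("A", "B"),
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Oriented AUC with 95% CI and a test of AUC = 0.5.

    The positive class is the group the statistic favours, so the reported
    AUC is always >= 0.5 (exact ties broken toward the higher-mean group);
    ``positive_group`` records which.
    """
    a, b = values.values_a, values.values_b
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    auc_a = _pairwise_auc(a, b)
    if auc_a > 0.5 or (auc_a == 0.5 and a.mean() >= b.mean()):
        pos, neg, pos_label = a, b, group_labels[0]
    else:
        pos, neg, pos_label = b, a, group_labels[1]

    auc, lo, hi, se = _delong_ci(pos, neg)
    if ci_method == "bootstrap":
        lo, hi, _ = _bootstrap_ci(pos, neg, n_boot=n_boot, seed=seed)
    elif ci_method != "delong":
        raise ValueError(f"unknown ci_method {ci_method!r}")

    degenerate = se == 0.0
    if degenerate:
        logger.warning("degenerate AUC variance (all pair comparisons equal)")
        p_value = 1.0 if auc == 0.5 else 0.0
    else:
        z = abs(auc - 0.5) / se
        p_value = float(2.0 * stats.norm.sf(z))
    return RocResult(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        p_value=p_value,
        band=accuracy_band(auc),
        positive_group=pos_label,
        degenerate=degenerate,
    )


def roc_curve_points(values: ClusterValues, positive_group: str,
                     group_labels: tuple[str, str] = ("A", "B")) -> np.ndarray:
    """(false positive rate, true positive rate) pairs over all thresholds.

    Points for exporting/plotting the empirical ROC curve; thresholds sweep
    the observed values from high to low.
    """
    if positive_group == group_labels[0]:
        pos, neg = values.values_a, values.values_b
    else:
        pos, neg = values.values_b, values.values_a
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(np.r_[pos, neg]))[::-1]])
    pts = [
        (float(np.mean(neg >= thr)), float(np.mean(pos >= thr)))
        for thr in thresholds
    ]
    return np.array(pts)


def accuracy_band(auc: float) -> str:
    """Band an oriented AUC: < 0.7 is "low", >= 0.7 is "excellent"."""
    if auc < 0.5:
        raise ValueError("AUC below 0.5: orient the comparison first")
    if auc > 1.0 + 1e-12:
        raise ValueError("AUC above 1")
    return "low" if auc < 0.7 else "excellent"
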