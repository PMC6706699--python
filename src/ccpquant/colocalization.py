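"""Dual-channel colocalization statistics.

Two complementary summaries of the relationship between a master channel
(e.g. EGFP-CLCa marking CCPs) and a dependently measured slave channel
(e.g. AP2, P-AP2, NECAP):

* the Pearson correlation coefficient (PCC) of the paired spot intensities,
  computed over all master detections and their 1:1 slave measurements;
* the proportion-vs-intensity curve: master detections are sorted by
  intensity and split into equal-count bins; per bin, the fraction whose
  slave measurement passed the (shared, upstream) significance test is
  plotted against the bin intensity.  Because the significance flag is
  computed once upstream with a single alpha, compared conditions share the
  threshold by construction.

Condition-level comparisons use the two-tailed unpaired (Welch) t-test on
per-cell statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "ProportionCurve",
    "pearson",
    "proportion_curve",
    "summarize_condition",
]


@dataclass
class PairedMeasurements:
    """Paired master/slave intensities with the slave significance flags."""

    master_intensity: np.ndarray
    slave_intensity: np.ndarray
    slave_significant: np.ndarray

    def __post_init__(self):
        self.master_intensity = np.asarray(self.master_intensity, float)
        self.slave_intensity = np.asarray(self.slave_intensity, float)
        self.slave_significant = np.asarray(self.slave_significant, bool)
        n = len(self.master_intensity)
        if len(self.slave_intensity) != n or len(self.slave_significant) != n:
            raise ValueError("paired sequences must have equal length")

    def __len__(self) -> int:
        return len(self.master_intensity)


@dataclass
class ProportionCurve:
    """Proportion of slave-significant spots per equal-count intensity bin."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    counts: np.ndarray
    proportion_positive: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers,
            "count": self.counts,
            "proportion": self.proportion_positive,
        })


def pearson(paired: PairedMeasurements) -> float:
    """Sample Pearson correlation of the paired intensities."""
    if len(paired) < 2:
        raise ValueError("need at least 2 pairs")
    x, y = paired.master_intensity, paired.slave_intensity
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: PCC undefined")
    return float(np.corrcoef(x, y)[0, 1])


def proportion_curve(paired: PairedMeasurements, n_bins: int = 10) -> ProportionCurve:
    """Equal-count binning of masters by intensity; positive fraction per bin.

    Bin counts differ by at most one; the remainder goes to the lowest-
    intensity bins.  Ties are broken by stable sort on input order.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = len(paired)
    if n < 5 * n_bins:
        raise ValueError(f"need >= {5 * n_bins} pairs for {n_bins} bins")
    order = np.argsort(paired.master_intensity, kind="stable")
    x = paired.master_intensity[order]
    sig = paired.slave_significant[order]

    base, rem = divmod(n, n_bins)
    counts = np.full(n_bins, base)
    counts[:rem] += 1
    stops = np.cumsum(counts)
    starts = stops - counts

    centers = np.array([x[a:b].mean() for a, b in zip(starts, stops)])
    props = np.array([sig[a:b].mean() for a, b in zip(starts, stops)])
    edges = np.append(x[starts], x[-1])
    return ProportionCurve(edges, centers, counts, props)


def summarize_condition(group_a, group_b) -> dict:
    """Welch two-tailed unpaired t-test between per-cell statistics.

    Returns per-group mean and SD plus the t statistic and p-value.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 cells per condition")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)), "n_a": len(a),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)), "n_b": len(b),
        "t": float(t), "p_value": float(p),
    }
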