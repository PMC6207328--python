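"""Summary statistics, two-sample tests and histogram conventions.

Population comparisons throughout the pipeline follow the conventions used
for the imaging figures: samples are reported as mean +/- SD with n, compared
with a two-sided Mann-Whitney U test, and histogrammed with a fixed bin width
anchored at zero (velocities: 5 nm/s bins; filament lengths: 120 nm bins).
No multiple-testing correction is applied; each comparison is a single
pre-planned two-group test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SampleSummary",
    "ComparisonResult",
    "HistogramSpec",
    "summarize",
    "mann_whitney_u",
    "histogram",
]


@dataclass(frozen=True)
class SampleSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float

    def __str__(self) -> str:  # the figure-caption convention
        return f"{self.mean:.3g}±{self.sd:.3g}, n = {self.n}"


@dataclass(frozen=True)
class ComparisonResult:
    u_statistic: float
    p_value: float
    test_name: str
    summary_x: SampleSummary
    summary_y: SampleSummary


@dataclass(frozen=True)
class HistogramSpec:
    """Fixed-width bins [k*w, (k+1)*w) anchored at the origin 0."""

    bin_width: float
    origin: float = 0.0

    def __post_init__(self) -> None:
        if not (self.bin_width > 0):
            raise ValueError("bin_width must be positive")


def summarize(values) -> SampleSummary:
    """Mean, sample SD (n-1 denominator), median and quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return SampleSummary(
        n=int(v.size), mean=float(np.mean(v)), sd=sd,
        median=float(med), q1=float(q1), q3=float(q3),
    )


def mann_whitney_u(x, y, mode: str = "auto") -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    mode='exact' forces the exact null distribution (small, tie-free samples);
    mode='normal' forces the tie-corrected normal approximation with
    continuity correction; mode='auto' (default) uses the exact distribution
    when n1 + n2 <= 16 and there are no ties, otherwise the approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if mode == "auto":
        method = "exact" if (x.size + y.size <= 16 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return ComparisonResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=f"Mann-Whitney U ({method})",
        summary_x=summarize(x),
        summary_y=summarize(y),
    )


def histogram(values, spec: HistogramSpec) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with half-open bins [k*w, (k+1)*w) starting at the origin.

    Returns (edges, counts); counts always sum to the sample size.  Values
    below the origin extend the binning to the left with a warning.
    """
    import warnings

    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.array([spec.origin]), np.array([], dtype=int)
    w = spec.bin_width
    lo = np.floor((v.min() - spec.origin) / w)
    if lo < 0:
        warnings.warn("values below the histogram origin; extending bins left")
    lo = min(lo, 0.0)
    hi = np.floor((v.max() - spec.origin) / w) + 1
    edges = spec.origin + w * np.arange(lo, hi + 1)
    # np.histogram closes the last bin on the right; nudge the top edge so
    # every bin behaves half-open [a, b)
    counts, _ = np.histogram(v, bins=np.append(edges[:-1], edges[-1] + w * 1e-9))
    return edges, counts
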