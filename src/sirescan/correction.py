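"""Genomic control and Bonferroni multiple-testing correction.

Genomic control estimates a genome-wide inflation factor λ of the squared
association statistics; when λ > 1 every |z| is deflated by √λ before the
p-value is recomputed, which restores nominal calibration under polygenic or
structure-driven inflation. λ < 1 (deflation) is left uncorrected by
convention. Family-wise significance uses the Bonferroni threshold α/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: median of the chi-square(1) distribution, the null median of z²
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


@dataclass
class GcEstimate:
    """A genomic-control inflation factor and how it was obtained."""

    lam: float
    method: str  # "median" or "regression"
    n_stats: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam) or self.lam <= 0:
            raise ValueError(f"lambda must be positive and finite, got {self.lam}")


def estimate_lambda(z_stats: np.ndarray, method: str = "median") -> GcEstimate:
    """Estimate the inflation factor λ from a vector of z statistics.

    ``median``: λ = median(z²) / median(χ²₁) — robust to a small fraction of
    true signals. ``regression``: λ = zero-intercept regression slope of the
    sorted observed z² on the expected χ²₁ order statistics, trimmed to the
    lower 90% so true signals in the upper tail do not drive the slope.
    Non-finite statistics (untestable markers) are ignored.
    """
    z = np.asarray(z_stats, dtype=float).ravel()
    z = z[np.isfinite(z)]
    if z.size < 2:
        raise ValueError("need at least 2 finite statistics to estimate lambda")
    if z.size < 30:
        warnings.warn(
            f"lambda estimated from only {z.size} statistics; estimate is unstable",
            stacklevel=2,
        )
    if np.ptp(z) == 0:
        warnings.warn("all statistics identical; lambda estimate is degenerate", stacklevel=2)
    z2 = np.sort(z**2)
    if method == "median":
        lam = float(np.median(z2)) / CHI2_1_MEDIAN
    elif method == "regression":
        n = z2.size
        expected = stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df=1)
        k = max(int(np.floor(0.9 * n)), 2)
        obs, exp = z2[:k], expected[:k]
        lam = float(obs @ exp) / float(exp @ exp)
    else:
        raise ValueError(f"unknown lambda method {method!r}; use 'median' or 'regression'")
    lam = max(lam, np.finfo(float).tiny)
    return GcEstimate(lam=lam, method=method, n_stats=int(z.size))


def gc_adjust(z_stats: np.ndarray, gc: GcEstimate) -> np.ndarray:
    """Genomic-control-adjusted two-sided p-values.

    p_gc = 2·Φ(−|z|/√λ) when λ > 1; when λ ≤ 1 the raw p-values are returned
    unchanged (no deflation correction). Non-finite z yield nan p.
    """
    z = np.asarray(z_stats, dtype=float)
    scale = np.sqrt(gc.lam) if gc.lam > 1.0 else 1.0
    with np.errstate(invalid="ignore"):
        return 2.0 * stats.norm.sf(np.abs(z) / scale)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold α/m controlling the family-wise error
    rate over m tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m
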