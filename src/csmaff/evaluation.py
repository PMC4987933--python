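"""Evaluation statistics for affinity predictors.

Pearson and Spearman correlations, the benchmark residual standard
deviation (observed affinity about the least-squares line on the
prediction, n-2 denominator), and the two significance tests used to
compare scoring functions: Fisher's r-to-z for correlations and the
F-test for residual SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

__all__ = [
    "EvaluationReport",
    "MethodComparison",
    "pearson",
    "spearman",
    "residual_sd",
    "fisher_r_to_z",
    "f_test_sd",
    "evaluate",
]


def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return x, y


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation."""
    x, y = _check_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant input")
    return float((xc * yc).sum() / (sx * sy))


def _average_ranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), dtype=np.float64)
    sv = v[order]
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # average of 1-based ranks
        i = j + 1
    return ranks


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x, y = _check_pair(x, y)
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    return pearson(rx, ry)


def residual_sd(pred, obs, about_regression: bool = True) -> float:
    """Spread of observed values about the fit on predictions.

    Default (benchmark convention): standard deviation of residuals of
    ``obs`` about the least-squares line on ``pred``, with an n-2
    denominator.  ``about_regression=False`` gives the raw
    prediction-error SD instead.
    """
    pred, obs = _check_pair(pred, obs)
    if about_regression:
        if np.ptp(pred) == 0:
            raise ValueError("regression undefined for constant predictions")
        slope, intercept = np.polyfit(pred, obs, 1)
        resid = obs - (slope * pred + intercept)
        return float(np.sqrt((resid**2).sum() / (len(obs) - 2)))
    resid = obs - pred
    return float(np.sqrt(((resid - resid.mean()) ** 2).sum() / (len(obs) - 1)))


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided test of the difference between two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); p from the
    standard normal.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("need n >= 4 on both sides")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * _st.norm.sf(abs(z))
    return float(z), float(p)


def f_test_sd(
    sd1: float, n1: int, sd2: float, n2: int, two_sided: bool = False
) -> tuple[float, float]:
    """F-test comparing two residual standard deviations.

    F is the squared ratio of the larger SD to the smaller; degrees of
    freedom are the regression-residual n-2 on each side.  One-sided by
    default.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 on both sides")
    if sd1 >= sd2:
        big_sd, big_n, small_sd, small_n = sd1, n1, sd2, n2
    else:
        big_sd, big_n, small_sd, small_n = sd2, n2, sd1, n1
    F = (big_sd / small_sd) ** 2
    p = float(_st.f.sf(F, big_n - 2, small_n - 2))
    if two_sided:
        p = min(1.0, 2.0 * p)
    return float(F), p


@dataclass(frozen=True)
class MethodComparison:
    """Pairwise significance of two methods' correlation and residual SD."""

    method_a: str
    method_b: str
    fisher_z: float
    fisher_p: float
    f_stat: float
    f_p: float


@dataclass
class EvaluationReport:
    """Per-split performance summary."""

    n: int
    pearson_r: float
    spearman_rho: float
    residual_sd: float
    comparisons: list[MethodComparison] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"n\t{self.n}",
            f"pearson_r\t{self.pearson_r:.4f}",
            f"spearman_rho\t{self.spearman_rho:.4f}",
            f"residual_sd\t{self.residual_sd:.4f}",
        ]
        for c in self.comparisons:
            lines.append(
                f"vs\t{c.method_b}\tfisher_z={c.fisher_z:.3f}\t"
                f"fisher_p={c.fisher_p:.4f}\tF={c.f_stat:.3f}\tf_p={c.f_p:.4f}"
            )
        return "\n".join(lines)


def evaluate(obs, pred) -> EvaluationReport:
    """Standard report: n, Pearson r, Spearman rho, residual SD."""
    obs, pred = _check_pair(obs, pred)
    return EvaluationReport(
        n=len(obs),
        pearson_r=pearson(pred, obs),
        spearman_rho=spearman(pred, obs),
        residual_sd=residual_sd(pred, obs),
    )


def compare_methods(
    name_a: str,
    r_a: float,
    sd_a: float,
    n_a: int,
    name_b: str,
    r_b: float,
    sd_b: float,
    n_b: int,
    f_two_sided: bool = False,
) -> MethodComparison:
    """Significance of the difference between two published method summaries."""
    z, pz = fisher_r_to_z(r_a, n_a, r_b, n_b)
    F, pf = f_test_sd(sd_a, n_a, sd_b, n_b, two_sided=f_two_sided)
    return MethodComparison(
        method_a=name_a, method_b=name_b, fisher_z=z, fisher_p=pz, f_stat=F, f_p=pf
    )
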