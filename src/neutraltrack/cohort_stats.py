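"""Cohort validation statistics for the 2-D vs 3-D method comparison.

For each measured angle the procedure reports per-modality descriptives
(mean, sample SD), a Kolmogorov-Smirnov normality check against the normal
distribution with estimated parameters (Lilliefors-corrected p by Monte
Carlo, since the naive KS p is anticonservative when mean and SD come from
the sample), and a two-sided paired Student t-test of the 2-D minus 3-D
differences at alpha = 0.05.

The statistics are computed from their defining formulas; scipy supplies
only the t and normal distribution functions.  (Independent library
implementations are used as cross-checks in the test suite, never here.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, LengthMismatchError, ZeroVarianceError

__all__ = [
    "PairedSample",
    "VariableComparison",
    "CohortComparison",
    "descriptives",
    "ks_statistic",
    "ks_normality",
    "paired_t",
    "compare_2d_3d_cohort",
]

#: Default Monte-Carlo replicates for the Lilliefors null distribution.
LILLIEFORS_MC_REPS = 10_000
#: Fixed seed of the Lilliefors Monte-Carlo null table.
LILLIEFORS_MC_SEED = 20_230_403


def _as_sample(values, min_n: int) -> np.ndarray:
    a = np.asarray(values, dtype=float).ravel()
    if a.size < min_n:
        raise InsufficientDataError(f"need at least {min_n} observations, got {a.size}")
    if not np.all(np.isfinite(a)):
        raise ValueError("sample contains non-finite values")
    return a


def descriptives(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    a = _as_sample(values, 2)
    return float(np.mean(a)), float(np.std(a, ddof=1))


def ks_statistic(values) -> float:
    """KS sup-distance between the sample ECDF and the normal distribution
    with the sample's own mean and SD."""
    a = np.sort(_as_sample(values, 2))
    n = a.size
    sd = float(np.std(a, ddof=1))
    if sd <= 0:
        raise ZeroVarianceError("sample has zero variance; normality check undefined")
    z = (a - np.mean(a)) / sd
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def _null_ks_chunk(rng: np.random.Generator, rows: int, n: int) -> np.ndarray:
    x = rng.standard_normal((rows, n))
    x.sort(axis=1)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf((x - mean) / sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf, axis=1)
    d_minus = np.max(cdf - (i - 1) / n, axis=1)
    return np.maximum(d_plus, d_minus)


@lru_cache(maxsize=32)
def _lilliefors_null_table(n: int, reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors D statistic at size n."""
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    pos = 0
    chunk = max(1, min(reps, 2_000_000 // max(n, 1)))
    while pos < reps:
        rows = min(chunk, reps - pos)
        out[pos:pos + rows] = _null_ks_chunk(rng, rows, n)
        pos += rows
    return out


def ks_normality(values, method: Literal["lilliefors", "naive"] = "lilliefors",
                 mc_reps: int = LILLIEFORS_MC_REPS,
                 mc_seed: int = LILLIEFORS_MC_SEED) -> tuple[float, float]:
    """Normality check of a sample against N(sample mean, sample SD).

    Returns ``(D, p)``.  ``lilliefors`` (default) draws the null distribution
    of D by Monte Carlo with a fixed seed, accounting for the estimated
    parameters; ``naive`` uses the classical KS p-value, which is
    anticonservative here and exists only for strict literalism.

    Requires n >= 4 and a non-degenerate sample.
    """
    a = _as_sample(values, 4)
    d = ks_statistic(a)
    if method == "naive":
        p = float(sps.kstest(a, "norm", args=(np.mean(a), np.std(a, ddof=1))).pvalue)
    elif method == "lilliefors":
        null = _lilliefors_null_table(a.size, mc_reps, mc_seed)
        p = float((1 + np.sum(null >= d)) / (null.size + 1))
    else:
        raise ValueError(f"unknown normality method {method!r}")
    return d, p


def paired_t(values_2d, values_3d) -> tuple[float, int, float]:
    """Two-sided paired Student t-test on elementwise differences (2D - 3D).

    Returns ``(t, df, p)`` with ``t = mean(d) / (sd(d) / sqrt(n))`` and
    ``df = n - 1``.
    """
    a = _as_sample(values_2d, 2)
    b = np.asarray(values_3d, dtype=float).ravel()
    if a.size != b.size:
        raise LengthMismatchError(f"paired samples differ in length: {a.size} vs {b.size}")
    if not np.all(np.isfinite(b)):
        raise ValueError("sample contains non-finite values")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd <= 0:
        if np.allclose(a, b):
            raise ZeroVarianceError("samples are identical; paired differences have "
                                    "zero variance")
        raise ZeroVarianceError("paired differences are a constant shift; zero variance")
    n = d.size
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


@dataclass(eq=False)
class PairedSample:
    """Matched 2-D and 3-D measurements of one angle across a cohort."""

    name: str
    values_2d: np.ndarray
    values_3d: np.ndarray

    def __post_init__(self):
        self.values_2d = np.asarray(self.values_2d, dtype=float).ravel()
        self.values_3d = np.asarray(self.values_3d, dtype=float).ravel()
        if self.values_2d.size != self.values_3d.size:
            raise LengthMismatchError(
                f"{self.name}: {self.values_2d.size} 2-D vs {self.values_3d.size} 3-D values")

    @property
    def n(self) -> int:
        return int(self.values_2d.size)


@dataclass(eq=False)
class VariableComparison:
    name: str
    n: int
    mean_2d: float
    sd_2d: float
    mean_3d: float
    sd_3d: float
    ks_p_2d: float
    ks_p_3d: float
    t_stat: float
    df: int
    p_value: float
    significant: bool


@dataclass(eq=False)
class CohortComparison:
    """Per-angle 2-D vs 3-D comparison table (mean +/- SD, normality, paired p)."""

    rows: list[VariableComparison] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "Index": r.name, "n": r.n,
                "2D Mean": r.mean_2d, "2D SD": r.sd_2d,
                "3D Mean": r.mean_3d, "3D SD": r.sd_3d,
                "KS p (2D)": r.ks_p_2d, "KS p (3D)": r.ks_p_3d,
                "t": r.t_stat, "df": r.df, "p": r.p_value,
                "significant": r.significant,
            }
            for r in self.rows
        ])


def compare_2d_3d_cohort(samples, alpha: float = 0.05,
                         ks_method: Literal["lilliefors", "naive"] = "lilliefors",
                         ) -> CohortComparison:
    """Run the full validation procedure on a list of :class:`PairedSample`.

    Per-variable failures (too few subjects, zero variance, ...) are
    collected into ``errors`` rather than raised; an empty sample list yields
    an empty report.
    """
    comparison = CohortComparison(alpha=alpha)
    for sample in samples:
        try:
            mean2, sd2 = descriptives(sample.values_2d)
            mean3, sd3 = descriptives(sample.values_3d)
            _, ks_p2 = ks_normality(sample.values_2d, method=ks_method)
            _, ks_p3 = ks_normality(sample.values_3d, method=ks_method)
            t, df, p = paired_t(sample.values_2d, sample.values_3d)
        except (InsufficientDataError, ZeroVarianceError, LengthMismatchError,
                ValueError) as exc:
            comparison.errors[sample.name] = str(exc)
            continue
        comparison.rows.append(VariableComparison(
            name=sample.name, n=sample.n,
            mean_2d=mean2, sd_2d=sd2, mean_3d=mean3, sd_3d=sd3,
            ks_p_2d=ks_p2, ks_p_3d=ks_p3,
            t_stat=t, df=df, p_value=p, significant=bool(p < alpha),
        ))
    return comparison
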