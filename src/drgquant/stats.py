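"""Statistical layer: size-distribution fits and group comparisons.

Soma-size histograms (100 um^2 bins) are fit with a scaled Gaussian by
least squares, and pairs of distributions are compared with the
extra-sum-of-squares F-test: the null model fits one curve to both
datasets, the alternative fits each separately, and

.. math:: F = \\frac{(SS_c - SS_s) / (df_c - df_s)}{SS_s / df_s}

is referred to the F(df_c - df_s, df_s) upper tail.  Proportion
comparisons between conditions use the classical unpaired (pooled
variance) two-sample t-test with the DRG — not the neuron — as the
experimental unit; per-cell intensity comparisons across groups use
one-way ANOVA followed by Tukey's multiple-comparison test (delegated to
scipy/statsmodels).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CurveFit",
    "ComparisonResult",
    "gaussian_curve",
    "fit_size_distribution",
    "fit_gaussian_points",
    "extra_ss_f_test",
    "compare_size_distributions",
    "cumulative_curve",
    "compare_proportions",
    "compare_intensities",
]


def gaussian_curve(x: np.ndarray, amplitude: float, mean: float, sd: float) -> np.ndarray:
    """Scaled Gaussian bump: amplitude * exp(-(x - mean)^2 / (2 sd^2))."""
    return amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sd**2))


@dataclass
class CurveFit:
    model: str
    amplitude: float
    mean: float
    sd: float
    ss: float  # residual sum of squares
    n_points: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("fitted sd must be > 0")
        if self.df < 1:
            raise ValueError("fit needs df >= 1")

    @property
    def n_params(self) -> int:
        return 3

    @property
    def df(self) -> int:
        return self.n_points - self.n_params

    def predict(self, x: np.ndarray) -> np.ndarray:
        return gaussian_curve(np.asarray(x, dtype=float), self.amplitude, self.mean, self.sd)


@dataclass
class ComparisonResult:
    name: str
    statistic: float
    df: tuple[float, float] | float
    pvalue: float
    groups: dict[str, dict] = field(default_factory=dict)
    note: str = ""


def fit_gaussian_points(x: np.ndarray, y: np.ndarray, model: str = "gaussian-pdf-scaled") -> CurveFit:
    """Least-squares scaled-Gaussian fit to (x, y) points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter curve")
    w = np.clip(y, 0, None)
    if w.sum() <= 0:
        raise ValueError("all-zero weights; cannot seed the fit")
    mu0 = float(np.sum(x * w) / w.sum())
    sd0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2) / w.sum())) or float(np.ptp(x) / 4 or 1.0)
    sd0 = max(sd0, 1e-6)
    a0 = float(y.max())
    popt, _ = optimize.curve_fit(
        gaussian_curve, x, y, p0=(a0, mu0, sd0), maxfev=20000
    )
    amplitude, mean, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    ss = float(np.sum((y - gaussian_curve(x, amplitude, mean, sd)) ** 2))
    return CurveFit(model=model, amplitude=amplitude, mean=mean, sd=sd, ss=ss, n_points=len(x))


def histogram_points(areas: np.ndarray, bin_um2: float, lo: float | None = None, hi: float | None = None):
    """Fixed-bin histogram of soma areas; returns (bin centers, counts)."""
    areas = np.asarray(areas, dtype=float)
    lo = float(np.floor(areas.min() / bin_um2) * bin_um2) if lo is None else lo
    hi = float(np.ceil(areas.max() / bin_um2) * bin_um2) if hi is None else hi
    if hi <= lo:
        hi = lo + bin_um2
    edges = np.arange(lo, hi + bin_um2 / 2, bin_um2)
    counts, _ = np.histogram(areas, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts.astype(float)


def fit_size_distribution(areas, bin_um2: float = 100.0) -> CurveFit:
    """Histogram the areas on fixed bins and fit a scaled Gaussian.

    Mirrors the classical presentation of DRG soma-size data: counts per
    100 um^2 bin with a normal-distribution curve through them.
    """
    areas = np.asarray(areas, dtype=float)
    if len(areas) < 10:
        raise ValueError("need at least 10 areas")
    if bin_um2 <= 0:
        raise ValueError("bin must be > 0")
    if np.ptp(areas) == 0:
        raise ValueError("degenerate sample: all areas equal")
    centers, counts = histogram_points(areas, bin_um2)
    return fit_gaussian_points(centers, counts)


def extra_ss_f_test(
    fit_combined: CurveFit | tuple[float, float],
    fit_separate_total: tuple[float, float],
    name: str = "extra-SS F",
) -> ComparisonResult:
    """Nested-model F-test: one shared curve vs. separate curves.

    ``fit_combined`` is the pooled fit (or its (SS, df)); ``fit_separate_total``
    is the summed (SS, df) of the separate fits.  Small p rejects the
    single-curve null.
    """
    if isinstance(fit_combined, CurveFit):
        ss_c, df_c = fit_combined.ss, fit_combined.df
    else:
        ss_c, df_c = fit_combined
    ss_s, df_s = fit_separate_total
    if df_c <= df_s:
        raise ValueError(f"combined df ({df_c}) must exceed separate df ({df_s})")
    if df_s <= 0:
        raise ValueError("separate fit df must be > 0")
    if ss_s < 0 or ss_c < ss_s - 1e-9:
        raise ValueError("need SS_combined >= SS_separate >= 0")
    dfn = df_c - df_s
    f_val = max(0.0, (ss_c - ss_s) / dfn) / (ss_s / df_s)
    p = float(sps.f.sf(f_val, dfn, df_s))
    return ComparisonResult(name=name, statistic=float(f_val), df=(float(dfn), float(df_s)), pvalue=p)


def compare_size_distributions(
    areas_a, areas_b, bin_um2: float = 100.0
) -> tuple[ComparisonResult, CurveFit, CurveFit]:
    """Extra-SS F-test between two soma-size distributions.

    Both samples are histogrammed on the same fixed bins; the combined
    model fits one Gaussian through both histograms' points, the separate
    model fits each histogram on its own.
    """
    areas_a = np.asarray(areas_a, dtype=float)
    areas_b = np.asarray(areas_b, dtype=float)
    lo = float(np.floor(min(areas_a.min(), areas_b.min()) / bin_um2) * bin_um2)
    hi = float(np.ceil(max(areas_a.max(), areas_b.max()) / bin_um2) * bin_um2)
    xa, ya = histogram_points(areas_a, bin_um2, lo, hi)
    xb, yb = histogram_points(areas_b, bin_um2, lo, hi)
    fit_a = fit_gaussian_points(xa, ya)
    fit_b = fit_gaussian_points(xb, yb)
    fit_c = fit_gaussian_points(np.concatenate([xa, xb]), np.concatenate([ya, yb]))
    separate = (fit_a.ss + fit_b.ss, fit_a.df + fit_b.df)
    result = extra_ss_f_test(fit_c, separate, name="extra-SS F (size distribution)")
    result.groups = {
        "a": {"n": len(areas_a), "fit_mean": fit_a.mean, "fit_sd": fit_a.sd},
        "b": {"n": len(areas_b), "fit_mean": fit_b.mean, "fit_sd": fit_b.sd},
    }
    return result, fit_a, fit_b


def cumulative_curve(areas) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: (sorted areas, cumulative fraction)."""
    areas = np.asarray(areas, dtype=float)
    if len(areas) == 0:
        raise ValueError("need at least one area")
    x = np.sort(areas)
    frac = np.arange(1, len(x) + 1) / len(x)
    return x, frac


def _summaries(groups: dict[str, np.ndarray]) -> dict[str, dict]:
    out = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        out[name] = {
            "n": int(len(vals)),
            "mean": float(vals.mean()),
            "sem": float(sps.sem(vals)) if len(vals) > 1 else float("nan"),
        }
    return out


def compare_proportions(group_a, group_b, equal_var: bool = True) -> ComparisonResult:
    """Unpaired two-sample t-test on per-DRG percentages.

    The observations are DRG-level percent-positive values (one number
    per ganglion/section), not per-neuron indicators.  Pooled-variance by
    default; set ``equal_var=False`` for the Welch variant.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 DRG-level observations")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    return ComparisonResult(
        name="unpaired t" if equal_var else "Welch t",
        statistic=float(res.statistic),
        df=df,
        pvalue=float(res.pvalue),
        groups=_summaries({"a": a, "b": b}),
    )


def compare_intensities(groups: dict[str, np.ndarray]) -> list[ComparisonResult]:
    """One-way ANOVA across groups plus Tukey-adjusted pairwise tests.

    ``groups`` maps a label (e.g. 'sham:L4') to per-neuron corrected
    intensities.  Returns the ANOVA result first, then one result per
    Tukey pair.  A fully degenerate input (zero variance everywhere) is
    reported as a flagged no-variance case rather than a number.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    if all(np.ptp(v) == 0 for v in arrays.values()) and len({v[0] for v in arrays.values()}) == 1:
        return [
            ComparisonResult(
                name="one-way ANOVA",
                statistic=float("nan"),
                df=(float(len(arrays) - 1), float(sum(map(len, arrays.values())) - len(arrays))),
                pvalue=float("nan"),
                groups=_summaries(arrays),
                note="no variance in any group; F undefined",
            )
        ]
    f_res = sps.f_oneway(*arrays.values())
    k = len(arrays)
    n_tot = sum(len(v) for v in arrays.values())
    results = [
        ComparisonResult(
            name="one-way ANOVA",
            statistic=float(f_res.statistic),
            df=(float(k - 1), float(n_tot - k)),
            pvalue=float(f_res.pvalue),
            groups=_summaries(arrays),
        )
    ]
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[name] * len(v) for name, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    pairs = list(itertools.combinations(tukey.groupsunique, 2))
    for (g1, g2), p_adj, diff in zip(pairs, tukey.pvalues, tukey.meandiffs):
        results.append(
            ComparisonResult(
                name=f"Tukey {g1} vs {g2}",
                statistic=float(diff),
                df=float(n_tot - k),
                pvalue=float(p_adj),
                groups={str(g1): results[0].groups[str(g1)], str(g2): results[0].groups[str(g2)]},
            )
        )
    return results
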