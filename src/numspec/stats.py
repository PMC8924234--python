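"""Eccentricity-profile fitting, model-comparison statistics, and the
neural-network response-curve comparison.

Voxel model fits are binned by pRF eccentricity (0.2 deg bins, 0-5.5
deg); the decline (or not) of variance explained with eccentricity is
summarized by a four-parameter cumulative-Gaussian sigmoid or a
three-parameter quadratic, fit to 1000 bootstrap resamples of the
unbinned voxels with the per-parameter median as the point estimate.
Paired model comparisons across hemispheres use two-sided Wilcoxon
signed-rank tests with Benjamini-Hochberg FDR correction.  A separate
routine rescales candidate nonlinearities (the power-vs-numerosity
curve, log(numerosity), a free quadratic) to published network response
lines and compares per-line correlation coefficients with paired
t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EccentricityBinSeries",
    "SigmoidFit",
    "QuadraticFit",
    "ComparisonResult",
    "bin_by_eccentricity",
    "sigmoid_curve",
    "fit_sigmoid",
    "fit_quadratic",
    "fit_eccentricity_profile",
    "select_profile_family",
    "compare_models_wilcoxon",
    "benjamini_hochberg",
    "compare_nn_lines",
]

ECC_BIN_WIDTH_DEG = 0.2
ECC_RANGE_DEG = (0.0, 5.5)
N_BOOT_DEFAULT = 1000


@dataclass
class EccentricityBinSeries:
    bin_centers: np.ndarray
    mean_ve: np.ndarray
    sem_ve: np.ndarray
    n: np.ndarray


@dataclass
class SigmoidFit:
    inflection: float
    slope: float
    max_asymptote: float
    min_asymptote: float
    ci_curves: tuple[np.ndarray, np.ndarray] | None = None
    ci_ecc: np.ndarray | None = None

    def __call__(self, ecc: np.ndarray) -> np.ndarray:
        return sigmoid_curve(np.asarray(ecc, float), self.inflection,
                             self.slope, self.max_asymptote, self.min_asymptote)


@dataclass
class QuadraticFit:
    intercept: float
    slope: float
    quad: float
    ci_curves: tuple[np.ndarray, np.ndarray] | None = None
    ci_ecc: np.ndarray | None = None

    def __call__(self, ecc: np.ndarray) -> np.ndarray:
        e = np.asarray(ecc, float)
        return self.intercept + self.slope * e + self.quad * e**2


@dataclass
class ComparisonResult:
    median_a: float
    median_b: float
    median_difference: float
    z: float
    p_raw: float
    p_fdr: float
    n: int


# ----------------------------------------------------------------------
# binning and profile fits
# ----------------------------------------------------------------------

def bin_by_eccentricity(ve: np.ndarray, eccentricity: np.ndarray,
                        bin_width: float = ECC_BIN_WIDTH_DEG,
                        ecc_range: tuple[float, float] = ECC_RANGE_DEG,
                        ) -> EccentricityBinSeries:
    """Mean and SEM of variance explained in fixed-width eccentricity
    bins; empty bins are dropped."""
    ve = np.asarray(ve, dtype=float)
    ecc = np.asarray(eccentricity, dtype=float)
    if ((ecc < ecc_range[0]) | (ecc > ecc_range[1])).any():
        raise ValueError("eccentricities outside the binning range")
    edges = np.arange(ecc_range[0], ecc_range[1] - 1e-9, bin_width)
    edges = np.append(edges, ecc_range[1])  # last bin may be partial
    idx = np.clip(np.digitize(ecc, edges) - 1, 0, len(edges) - 2)
    centers, means, sems, counts = [], [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        k = int(sel.sum())
        if k == 0:
            continue
        centers.append((edges[b] + edges[b + 1]) / 2)
        means.append(float(ve[sel].mean()))
        sems.append(float(ve[sel].std(ddof=1) / math.sqrt(k)) if k > 1 else 0.0)
        counts.append(k)
    return EccentricityBinSeries(np.array(centers), np.array(means),
                                 np.array(sems), np.array(counts))


def sigmoid_curve(ecc: np.ndarray, inflection: float, slope: float,
                  vmax: float, vmin: float) -> np.ndarray:
    """Cumulative-Gaussian sigmoid decreasing with eccentricity:
    ``vmin + (vmax - vmin) * (1 - Phi((ecc - inflection)/slope))``."""
    return vmin + (vmax - vmin) * (1.0 - stats.norm.cdf((ecc - inflection) / slope))


def _sigmoid_starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    vmax0, vmin0 = float(y.max()), float(max(y.min(), 0.0))
    mid = float(np.median(x))
    starts = []
    for infl in (mid, 1.0, 2.0, float(x.min()) + 0.5, float(x.max()) - 0.5):
        starts.append(np.array([infl, 0.5, vmax0, vmin0]))
    return starts


def fit_sigmoid(x: np.ndarray, y: np.ndarray) -> SigmoidFit:
    """Bounded least-squares sigmoid fit with multi-start."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo = [ECC_RANGE_DEG[0], 1e-3, -1.0, -1.0]
    hi = [ECC_RANGE_DEG[1], 10.0, 1.5, 1.5]
    best = None
    for p0 in _sigmoid_starts(x, y):
        try:
            popt, _ = optimize.curve_fit(sigmoid_curve, x, y, p0=p0,
                                         bounds=(lo, hi), maxfev=2000)
        except RuntimeError:
            continue
        sse = float(((sigmoid_curve(x, *popt) - y) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("sigmoid fit did not converge from any start")
    infl, slope, vmax, vmin = best[1]
    if vmax < vmin:  # enforce max >= min by reparameterization
        vmax, vmin = vmin, vmax
    return SigmoidFit(float(infl), float(slope), float(vmax), float(vmin))


def fit_quadratic(x: np.ndarray, y: np.ndarray) -> QuadraticFit:
    c = np.polynomial.polynomial.polyfit(np.asarray(x, float),
                                         np.asarray(y, float), 2)
    return QuadraticFit(float(c[0]), float(c[1]), float(c[2]))


def fit_eccentricity_profile(ve: np.ndarray, eccentricity: np.ndarray,
                             family: str = "sigmoid",
                             n_boot: int = N_BOOT_DEFAULT,
                             rng: np.random.Generator | None = None,
                             ci_ecc: np.ndarray | None = None,
                             ) -> SigmoidFit | QuadraticFit:
    """Bootstrap profile fit.

    Each of ``n_boot`` resamples draws voxels with replacement from the
    unbinned (VE, eccentricity) pairs, bins them, and fits the requested
    family to the bin means.  The point estimate is the per-parameter
    median over resamples; the CI envelope is the 2.5/97.5 percentile of
    the fitted curves at each eccentricity.  Non-convergent resamples
    are redrawn (at most 10% extra draws).
    """
    ve = np.asarray(ve, float)
    ecc = np.asarray(eccentricity, float)
    if ve.size != ecc.size or ve.size == 0:
        raise ValueError("need matching non-empty VE and eccentricity arrays")
    if rng is None:
        rng = np.random.default_rng()
    if ci_ecc is None:
        ci_ecc = np.arange(ECC_RANGE_DEG[0], ECC_RANGE_DEG[1] + 1e-9, 0.1)
    fitter = {"sigmoid": fit_sigmoid, "quadratic": fit_quadratic}[family]

    series0 = bin_by_eccentricity(ve, ecc)
    if family == "sigmoid" and series0.bin_centers.size < 8:
        raise ValueError("sigmoid profile needs >= 8 occupied bins")

    params: list[tuple] = []
    curves = np.empty((n_boot, ci_ecc.size))
    redraws = 0
    max_redraws = max(1, n_boot // 10)
    b = 0
    while b < n_boot:
        sel = rng.integers(0, ve.size, ve.size)
        series = bin_by_eccentricity(ve[sel], ecc[sel])
        try:
            f = fitter(series.bin_centers, series.mean_ve)
        except RuntimeError:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many non-convergent bootstrap resamples")
            continue
        if isinstance(f, SigmoidFit):
            params.append((f.inflection, f.slope, f.max_asymptote, f.min_asymptote))
        else:
            params.append((f.intercept, f.slope, f.quad))
        curves[b] = f(ci_ecc)
        b += 1
    med = np.median(np.asarray(params), axis=0)
    lo = np.percentile(curves, 2.5, axis=0)
    hi = np.percentile(curves, 97.5, axis=0)
    if family == "sigmoid":
        return SigmoidFit(*map(float, med), ci_curves=(lo, hi), ci_ecc=ci_ecc)
    return QuadraticFit(*map(float, med), ci_curves=(lo, hi), ci_ecc=ci_ecc)


def select_profile_family(sigmoid_fit: SigmoidFit, quadratic_fit: QuadraticFit,
                          series: EccentricityBinSeries) -> str:
    """Choose the family whose fitted curve correlates best with the bin
    means; near-ties (and degenerate correlations) go to the quadratic,
    which makes fewer assumptions."""
    x = series.bin_centers
    y = series.mean_ve

    def corr(f) -> float:
        pred = f(x)
        if np.std(pred) == 0 or np.std(y) == 0:
            return -np.inf
        return float(np.corrcoef(pred, y)[0, 1])

    cs, cq = corr(sigmoid_fit), corr(quadratic_fit)
    if not np.isfinite(cs) and not np.isfinite(cq):
        return "quadratic"
    return "sigmoid" if cs > cq else "quadratic"


# ----------------------------------------------------------------------
# paired model comparisons
# ----------------------------------------------------------------------

def _signed_rank_z(diff: np.ndarray) -> float:
    """Normal-approximation Z of the Wilcoxon signed-rank statistic
    (signed so that positive Z means a > b on average)."""
    d = diff[diff != 0]
    n = d.size
    if n == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    sd_w = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    return (w_pos - mean_w) / sd_w if sd_w > 0 else 0.0


def compare_models_wilcoxon(ve_a: np.ndarray, ve_b: np.ndarray,
                            m_comparisons: int = 1,
                            p_siblings: Sequence[float] = (),
                            ) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank comparison of paired per-hemisphere
    model fits, with BH-FDR correction across the declared comparison
    family (this test's raw p plus ``p_siblings``, padded to
    ``m_comparisons``)."""
    a = np.asarray(ve_a, float)
    b = np.asarray(ve_b, float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired samples must align")
    diff = a - b
    if np.all(diff == 0):
        p_raw = 1.0
    else:
        method = "exact" if a.size <= 25 else "approx"
        p_raw = float(stats.wilcoxon(a, b, alternative="two-sided",
                                     method=method).pvalue)
    z = _signed_rank_z(diff)
    family = [p_raw, *p_siblings]
    while len(family) < m_comparisons:
        family.append(1.0)
    p_fdr = float(benjamini_hochberg(np.array(family))[0])
    return ComparisonResult(float(np.median(a)), float(np.median(b)),
                            float(np.median(diff)), z, p_raw, p_fdr, a.size)


def benjamini_hochberg(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """BH-adjusted p-values (delegates to statsmodels)."""
    p = np.asarray(p_values, float)
    return multipletests(p, alpha=q, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# neural-network line comparison
# ----------------------------------------------------------------------

def _normalize_lines(lines: pd.DataFrame) -> pd.DataFrame:
    """Global 0/1 normalization: the mean response at the smallest
    numerosity maps to 0 and the mean at the largest maps to 1, while
    between-line offsets are preserved."""
    ns = lines.columns.to_numpy(dtype=float)
    lo = float(lines.iloc[:, np.argmin(ns)].mean())
    hi = float(lines.iloc[:, np.argmax(ns)].mean())
    if hi == lo:
        raise ValueError("degenerate line set: no dynamic range")
    return (lines - lo) / (hi - lo)


def compare_nn_lines(lines: pd.DataFrame,
                     fourier_curve: Callable[[np.ndarray], np.ndarray],
                     ) -> dict:
    """Test which nonlinearity follows published network response lines.

    ``lines``: one row per response line, columns indexed by integer
    numerosity.  Candidates are the aggregate-power curve, log(n), and a
    free quadratic; each is linearly scaled to all data points at once,
    then correlated with each line.  Paired t-tests compare the
    correlation sets between candidates.  Constant lines are excluded.
    """
    if len(lines) < 2:
        raise ValueError("need at least two lines")
    keep = lines.std(axis=1) > 0
    if not keep.all():
        import warnings

        warnings.warn(f"excluding {int((~keep).sum())} constant line(s)")
        lines = lines.loc[keep]
    lines = _normalize_lines(lines)
    ns = lines.columns.to_numpy(dtype=float)

    y_all = lines.to_numpy().ravel()
    x_rep = np.tile(ns, len(lines))

    def scaled(fvals_at_ns: np.ndarray) -> np.ndarray:
        f_all = np.tile(fvals_at_ns, len(lines))
        A = np.c_[np.ones_like(f_all), f_all]
        coef, *_ = np.linalg.lstsq(A, y_all, rcond=None)
        return coef[0] + coef[1] * fvals_at_ns

    candidates = {
        "fourier": scaled(np.asarray(fourier_curve(ns), dtype=float)),
        "log": scaled(np.log(ns)),
    }
    quad_coef = np.polynomial.polynomial.polyfit(x_rep, y_all, 2)
    candidates["quadratic"] = (quad_coef[0] + quad_coef[1] * ns
                               + quad_coef[2] * ns**2)

    corrs = {
        name: np.array([stats.pearsonr(vals, row)[0]
                        for _, row in lines.iterrows()])
        for name, vals in candidates.items()
    }
    tests = {}
    for a, b in (("fourier", "log"), ("fourier", "quadratic"),
                 ("log", "quadratic")):
        t, p = stats.ttest_rel(corrs[a], corrs[b])
        tests[f"{a}_vs_{b}"] = {"t": float(t), "p": float(p)}
    return {
        "correlations": corrs,
        "tests": tests,
        "quadratic_coefficients": quad_coef.tolist(),
    }
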