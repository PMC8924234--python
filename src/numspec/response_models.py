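"""Monotonic and tuned response models for numerosity fMRI time series.

The experimental design presents numerosities 1-7 ascending (two 2.1 s
TRs each), a 16.8 s baseline of 20 items, 7-1 descending, and a second
baseline, giving a 44-TR averaged cycle.  A putative neural population
responds either monotonically to a stimulus feature (log- or
linearly-scaled amplitude) or with logarithmic-Gaussian tuning
(preferred numerosity mu, log-unit width sigma).  Neural amplitude time
courses are convolved with a canonical two-gamma HRF (circularly, since
the cycle repeats) and scaled to the data by a two-parameter GLM
(baseline + beta).  Tuned models grid-search (mu, sigma) by correlation
and then refit amplitude and baseline.  Split-half cross-validation
freezes tuning parameters and refits the scaling on the held-out half,
without letting a monotonic model's beta change sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = [
    "TR_S",
    "CYCLE_LEN",
    "BASELINE_NUMEROSITY",
    "MU_RANGE",
    "default_design_labels",
    "StimulusSequence",
    "HRFParams",
    "MonotonicFit",
    "TunedFit",
    "VoxelTimeSeries",
    "build_sequence",
    "hrf_kernel",
    "predicted_timecourse",
    "tuned_amplitudes",
    "fit_monotonic",
    "fit_tuned",
    "choose_scaling",
    "cross_validate",
    "pool_configurations",
    "default_mu_grid",
    "default_sigma_grid",
]

TR_S = 2.1
CYCLE_LEN = 44
BASELINE_NUMEROSITY = 20
MU_RANGE = (1.05, 6.95)


def default_design_labels() -> np.ndarray:
    """Per-TR numerosity labels of one averaged stimulus cycle:
    1-7 ascending at 2 TRs each, 8 TRs of 20, 7-1 descending, 8 TRs of
    20 (44 TRs)."""
    up = np.repeat(np.arange(1, 8), 2)
    base = np.full(8, BASELINE_NUMEROSITY)
    down = np.repeat(np.arange(7, 0, -1), 2)
    labels = np.concatenate([up, base, down, base])
    assert labels.size == CYCLE_LEN
    return labels


@dataclass
class StimulusSequence:
    values: np.ndarray              # per-TR feature amplitude
    labels: np.ndarray              # per-TR numerosity
    tr_s: float = TR_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != self.labels.shape:
            raise ValueError("values and labels must align")


@dataclass
class HRFParams:
    """SPM-convention double-gamma parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 30.0

    def __post_init__(self) -> None:
        if self.peak_delay <= 0 or self.undershoot_delay <= 0:
            raise ValueError("HRF delays must be positive")


@dataclass
class MonotonicFit:
    beta: float
    baseline: float
    scaling_mode: str
    r2_fit: float
    r2_cv: float | None = None

    @property
    def direction(self) -> int:
        return int(np.sign(self.beta))


@dataclass
class TunedFit:
    mu: float
    sigma: float
    beta: float
    baseline: float
    r2_fit: float
    r2_cv: float | None = None


@dataclass
class VoxelTimeSeries:
    bold: np.ndarray
    eccentricity_deg: float = 0.0
    map_label: str = ""
    hemisphere: str = ""
    voxel_id: int = 0

    def __post_init__(self) -> None:
        self.bold = np.asarray(self.bold, dtype=float)
        if not np.isfinite(self.bold).all():
            raise ValueError("BOLD series contains non-finite values")
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity must be >= 0")


# ----------------------------------------------------------------------

def build_sequence(feature_values_by_numerosity: Mapping[int, float],
                   labels: np.ndarray | None = None,
                   tr_s: float = TR_S) -> StimulusSequence:
    """Substitute per-numerosity feature values into the design labels.

    The mapping must cover every presented numerosity (1-7 and the
    20-item baseline).  For aggregate Fourier power the values should be
    the mean over all displays of the same numerosity and configuration.
    """
    if labels is None:
        labels = default_design_labels()
    missing = sorted(set(np.unique(labels).tolist()) -
                     set(feature_values_by_numerosity))
    if missing:
        raise KeyError(f"feature mapping lacks numerosities {missing}")
    values = np.array([feature_values_by_numerosity[int(l)] for l in labels],
                      dtype=float)
    return StimulusSequence(values, labels, tr_s)


def hrf_kernel(params: HRFParams | None = None, tr_s: float = TR_S) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR, truncated at
    ``params.duration`` seconds and normalized to unit peak."""
    if params is None:
        params = HRFParams()
    t = np.arange(0.0, params.duration + 1e-9, tr_s)
    peak = gamma_dist.pdf(t, params.peak_delay / params.peak_dispersion,
                          scale=params.peak_dispersion)
    under = gamma_dist.pdf(t, params.undershoot_delay / params.undershoot_dispersion,
                           scale=params.undershoot_dispersion)
    h = peak - params.undershoot_ratio * under
    m = np.abs(h).max()
    if m == 0:
        raise ValueError("degenerate HRF")
    return h / h.max()


def _circular_convolve(amplitudes: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve a periodic neural amplitude cycle with the HRF.  The
    stimulus cycles continuously, so the convolution wraps."""
    n = amplitudes.shape[-1]
    k = np.zeros(n)
    src = kernel[: n] if kernel.size > n else kernel
    k[: src.size] = src
    if kernel.size > n:  # fold the tail back (periodic stimulus)
        for start in range(n, kernel.size, n):
            seg = kernel[start : start + n]
            k[: seg.size] += seg
    return np.real(np.fft.ifft(np.fft.fft(amplitudes, axis=-1) * np.fft.fft(k),
                               axis=-1))


def predicted_timecourse(amplitudes: np.ndarray,
                         hrf: np.ndarray | None = None,
                         tr_s: float = TR_S) -> np.ndarray:
    if hrf is None:
        hrf = hrf_kernel(tr_s=tr_s)
    return _circular_convolve(np.asarray(amplitudes, dtype=float), hrf)


def _scaled_values(values: np.ndarray, scaling_mode: str) -> np.ndarray:
    if scaling_mode == "log":
        if (values <= 0).any():
            raise ValueError("log scaling requires positive feature values")
        return np.log(values)
    if scaling_mode == "linear":
        return values.astype(float)
    raise ValueError(f"unknown scaling_mode: {scaling_mode}")


def _glm(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on [1, x]; returns (baseline, beta, r2)."""
    X = np.c_[np.ones_like(x), x]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("zero-variance time series; r2 undefined")
    r2 = 1.0 - float((resid**2).sum()) / sst
    return float(coef[0]), float(coef[1]), r2


def fit_monotonic(ts: VoxelTimeSeries | np.ndarray, seq: StimulusSequence,
                  scaling_mode: str = "log",
                  hrf: np.ndarray | None = None) -> MonotonicFit:
    """GLM fit of a monotonic response model: the (log- or linearly-)
    scaled feature sequence is HRF-convolved and regressed against the
    BOLD cycle, estimating baseline and beta."""
    y = ts.bold if isinstance(ts, VoxelTimeSeries) else np.asarray(ts, float)
    if y.shape[-1] != seq.values.shape[-1]:
        raise ValueError("time series and sequence lengths differ")
    pred = predicted_timecourse(_scaled_values(seq.values, scaling_mode), hrf,
                                seq.tr_s)
    baseline, beta, r2 = _glm(y, pred)
    return MonotonicFit(beta, baseline, scaling_mode, r2)


def default_mu_grid(n: int = 60) -> np.ndarray:
    return np.geomspace(MU_RANGE[0], MU_RANGE[1], n)


def default_sigma_grid(n: int = 40) -> np.ndarray:
    return np.geomspace(0.05, 2.0, n)


def tuned_amplitudes(labels: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Logarithmic-Gaussian neural amplitude at each presented
    numerosity, including the far-tail response to the 20-item
    baseline."""
    x = np.asarray(labels, dtype=float)
    return np.exp(-((np.log(x) - math.log(mu)) ** 2) / (2.0 * sigma**2))


def fit_tuned(ts: VoxelTimeSeries | np.ndarray, labels: np.ndarray,
              mu_grid: np.ndarray | None = None,
              sigma_grid: np.ndarray | None = None,
              hrf: np.ndarray | None = None,
              tr_s: float = TR_S) -> TunedFit:
    """Grid-search logarithmic-Gaussian tuning.

    Every (mu, sigma) candidate produces an HRF-convolved predicted
    time course; the best candidate is chosen by Pearson correlation
    with the data, then amplitude and baseline are estimated by GLM.
    """
    y = ts.bold if isinstance(ts, VoxelTimeSeries) else np.asarray(ts, float)
    if mu_grid is None:
        mu_grid = default_mu_grid()
    if sigma_grid is None:
        sigma_grid = default_sigma_grid()
    if len(mu_grid) == 0 or len(sigma_grid) == 0:
        raise ValueError("empty parameter grid")
    if hrf is None:
        hrf = hrf_kernel(tr_s=tr_s)
    labels = np.asarray(labels, dtype=float)

    logx = np.log(labels)
    mus, sigmas = np.meshgrid(mu_grid, sigma_grid, indexing="ij")
    mus_f = mus.ravel()
    sigmas_f = sigmas.ravel()
    amp = np.exp(-((logx[None, :] - np.log(mus_f)[:, None]) ** 2)
                 / (2.0 * sigmas_f[:, None] ** 2))
    preds = _circular_convolve(amp, hrf)

    pc = preds - preds.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((pc**2).sum(axis=1)) * math.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (pc @ yc) / denom
    corr = np.nan_to_num(corr, nan=-np.inf)
    best = int(np.argmax(corr))
    baseline, beta, r2 = _glm(y, preds[best])
    return TunedFit(float(mus_f[best]), float(sigmas_f[best]), beta, baseline, r2)


def choose_scaling(fits_log: Sequence[MonotonicFit],
                   fits_linear: Sequence[MonotonicFit]) -> str:
    """Pick one global scaling mode per feature: the mode with the
    larger summed variance explained across all recording sites.  Ties
    go to log scaling."""
    if len(fits_log) != len(fits_linear):
        raise ValueError("fit populations must pair up")
    ve_log = sum(f.r2_fit for f in fits_log)
    ve_lin = sum(f.r2_fit for f in fits_linear)
    return "log" if ve_log >= ve_lin else "linear"


def cross_validate(fit: MonotonicFit | TunedFit,
                   ts_other: VoxelTimeSeries | np.ndarray,
                   seq: StimulusSequence,
                   hrf: np.ndarray | None = None) -> float:
    """Variance explained on the complementary half.

    Tuning parameters (and the scaling mode) transfer frozen; baseline
    and scaling are refit on the held-out half.  A monotonic model's
    beta may not change sign: if the refit flips it, beta is clamped to
    zero and the recorded r2_cv is non-positive.
    """
    y = ts_other.bold if isinstance(ts_other, VoxelTimeSeries) else np.asarray(
        ts_other, float)
    if isinstance(fit, MonotonicFit):
        pred = predicted_timecourse(
            _scaled_values(seq.values, fit.scaling_mode), hrf, seq.tr_s)
        sign = np.sign(fit.beta)
    else:
        pred = predicted_timecourse(
            tuned_amplitudes(seq.labels, fit.mu, fit.sigma), hrf, seq.tr_s)
        sign = 0.0
    baseline, beta, r2 = _glm(y, pred)
    if sign != 0.0 and np.sign(beta) not in (0.0, sign):
        beta = 0.0
        baseline = float(y.mean())
        resid = y - baseline
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / sst  # == 0 by construction
    fit.r2_cv = r2
    return r2


def pool_configurations(r2_by_config: Sequence[float],
                        total_variance_by_config: Sequence[float]) -> float:
    """Proportion of variance explained pooled over stimulus
    configurations: summed explained variance over summed total
    variance, so configurations with larger signal variance weigh
    more."""
    r2 = np.asarray(r2_by_config, dtype=float)
    tv = np.asarray(total_variance_by_config, dtype=float)
    if r2.shape != tv.shape or r2.size == 0:
        raise ValueError("need matching, non-empty inputs")
    return float((r2 * tv).sum() / tv.sum())
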