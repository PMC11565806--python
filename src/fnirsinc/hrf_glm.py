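"""Task pipeline: optical density, MBLL, and the short-separation GLM.

Raw CW intensities from the motor-task run are converted to optical density,
channels with SNR < 5 are excluded, the OD series is low-pass filtered
(6th-order Butterworth at 0.5 Hz, applied forward-backward), and converted
to ΔHbO₂/ΔHbR via the modified Beer-Lambert law *without* pathlength
correction (concentrations therefore carry an unknown pathlength factor and
are comparable across channels only in a relative sense).  The hemodynamic
response is estimated by ordinary least squares with a modified-gamma
response kernel per chromophore, the best-correlated short-separation
channel as a superficial-physiology nuisance regressor, intercept and linear
drift.  The t-statistic of the HbO₂ condition beta is the primary output.

Extinction coefficients at 760/850 nm are the standard literature
compilation (Gratzer/Prahl) used across fNIRS toolboxes, in cm^-1/(mol/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from ._types import IntensityRecording, StimDesign

__all__ = [
    "EXTINCTION_CM_PER_M",
    "OdSeries",
    "ConcSeries",
    "HrfSpec",
    "HRF_SPEC_HBO",
    "HRF_SPEC_HBR",
    "GlmResult",
    "intensity_to_od",
    "lowpass",
    "od_to_conc",
    "hrf_kernel",
    "hrf_regressor",
    "select_ss_regressor",
    "glm_fit",
]

# rows: wavelength (760, 850 nm); cols: (HbO2, HbR); units cm^-1 / (mol/L)
EXTINCTION_CM_PER_M = np.array([
    [586.0, 1548.52],
    [1058.0, 691.32],
])


@dataclass
class OdSeries:
    """Optical density per channel x wavelength x time (unitless)."""

    values: np.ndarray
    fs: float
    channels: list
    wavelengths: tuple


@dataclass
class ConcSeries:
    """ΔHbO₂/ΔHbR per channel x time.

    Without pathlength correction the units are mol/L scaled by the unknown
    differential pathlength; linear in OD.
    """

    hbo: np.ndarray   # (n_channels, n_times)
    hbr: np.ndarray
    fs: float
    channels: list


@dataclass(frozen=True)
class HrfSpec:
    """Modified-gamma response kernel parameters (tau, sigma, duration), s.

    The kernel is h(t) = e * u^2 * exp(-u^2) with u = (t - tau)/sigma for
    t >= tau and 0 before, which has unit peak at t = tau + sigma.
    ``duration`` is the boxcar length the kernel is convolved with.
    ``t_range`` is the estimation window around each onset.
    """

    tau: float
    sigma: float
    duration: float
    t_range: tuple[float, float] = (-2.0, 12.0)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        lo, hi = self.t_range
        if not (lo < 0 < hi):
            raise ValueError("t_range must straddle 0")


HRF_SPEC_HBO = HrfSpec(tau=0.1, sigma=3.0, duration=5.0)
HRF_SPEC_HBR = HrfSpec(tau=1.8, sigma=3.0, duration=5.0)


def intensity_to_od(rec: IntensityRecording) -> OdSeries:
    """OD(t) = -ln(I(t) / mean(I)) per channel and wavelength.

    Errors on non-positive samples, naming the offending channel.
    """
    data = rec.data
    for i, ch in enumerate(rec.channels):
        if np.any(data[i] <= 0):
            raise ValueError(f"non-positive intensity in channel {ch.label}")
    mean = data.mean(axis=-1, keepdims=True)
    od = -np.log(data / mean)
    return OdSeries(values=od, fs=rec.fs, channels=list(rec.channels),
                    wavelengths=rec.wavelengths)


def lowpass(values: np.ndarray, fs: float, cutoff: float = 0.5,
            order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis.

    The filter is designed at the stated order and applied forward-backward,
    which doubles the effective attenuation order and gives exactly unit DC
    gain with no phase distortion.
    """
    if fs <= 2 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    sos = signal.butter(order, cutoff / (fs / 2.0), btype="lowpass",
                        output="sos")
    padlen = 3 * (2 * order + 1)
    if values.shape[-1] <= padlen:
        raise ValueError("series too short for filter warm-up")
    return signal.sosfiltfilt(sos, values, axis=-1)


def od_to_conc(od: OdSeries, separations_mm,
               extinction: np.ndarray = EXTINCTION_CM_PER_M) -> ConcSeries:
    """Invert the 2x2 extinction system per channel (MBLL, no pathlength
    correction): ΔOD(λ) = ε(λ,·) @ Δc * d, with d the source-detector
    separation in cm."""
    extinction = np.asarray(extinction, dtype=float)
    if extinction.shape != (2, 2):
        raise ValueError("extinction must be 2x2 (wavelength x chromophore)")
    if abs(np.linalg.det(extinction)) < 1e-12:
        raise ValueError("singular extinction matrix")
    einv = np.linalg.inv(extinction)
    seps_cm = np.asarray(separations_mm, dtype=float) / 10.0
    if seps_cm.shape[0] != od.values.shape[0]:
        raise ValueError("one separation per channel required")
    # conc[c, :, t] = einv @ od[c, :, t] / d_c
    conc = np.einsum("ij,cjt->cit", einv, od.values) / seps_cm[:, None, None]
    return ConcSeries(hbo=conc[:, 0, :], hbr=conc[:, 1, :], fs=od.fs,
                      channels=list(od.channels))


def hrf_kernel(spec: HrfSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the modified-gamma kernel on the spec's time range.

    Returns (t, h); h has unit peak at t = tau + sigma and is 0 for t < tau.
    """
    lo, hi = spec.t_range
    t = np.arange(round(lo * fs), round(hi * fs) + 1) / fs
    u = (t - spec.tau) / spec.sigma
    h = np.where(t >= spec.tau, np.e * u ** 2 * np.exp(-(u ** 2)), 0.0)
    return t, h


def hrf_regressor(spec: HrfSpec, fs: float, n_times: int,
                  onsets) -> np.ndarray:
    """Condition regressor: kernel convolved with the stimulus boxcar of the
    spec's duration at each onset, normalized to unit peak."""
    x = np.zeros(n_times)
    for onset in np.asarray(onsets, dtype=float):
        i0 = int(round(onset * fs))
        i1 = min(n_times, i0 + int(round(spec.duration * fs)))
        if i0 < n_times:
            x[max(i0, 0):i1] = 1.0
    t, h = hrf_kernel(spec, fs)
    # causal part of the kernel only; the window's negative lags are the
    # pre-stimulus baseline, not part of the impulse response
    h_causal = h[t >= 0]
    reg = np.convolve(x, h_causal)[:n_times] / fs
    peak = np.max(np.abs(reg))
    return reg / peak if peak > 0 else reg


def select_ss_regressor(long_series: np.ndarray,
                        short_series: dict[str, np.ndarray]) -> tuple[str, np.ndarray]:
    """Pick the short-separation channel most correlated with the long
    channel (Pearson, zero lag); ties break on sorted channel label."""
    if not short_series:
        raise ValueError("no short-separation channels available")
    best_label, best_r = None, -np.inf
    for label in sorted(short_series):
        s = short_series[label]
        if np.std(s) == 0 or np.std(long_series) == 0:
            r = -np.inf
        else:
            r = np.corrcoef(long_series, s)[0, 1]
        if r > best_r:
            best_label, best_r = label, r
    return best_label, short_series[best_label]


@dataclass
class GlmResult:
    """OLS GLM output for one long channel and one chromophore."""

    betas: pd.Series              # per design column
    se: pd.Series
    tstats: pd.Series
    residual_variance: float
    df_resid: int
    hrf_time: np.ndarray          # (-2, 12) s grid
    hrf_estimates: dict[str, np.ndarray]   # baseline-corrected, per condition
    ss_channel: str | None


def glm_fit(conc_series: np.ndarray, fs: float, stim: StimDesign,
            spec: HrfSpec, ss_regressor: np.ndarray | None = None,
            ss_channel: str | None = None,
            filter_design: bool = True) -> GlmResult:
    """OLS GLM of one chromophore time course on condition regressors,
    an optional short-separation regressor, intercept and linear drift.

    ``filter_design`` applies the same 0.5 Hz low-pass to the condition
    regressors as the preprocessing applies to the data, keeping the
    estimator unbiased under the generative model.  The per-condition HRF
    estimate is beta times the kernel on the (-2, 12) s grid, baseline
    corrected by subtracting its mean over (-2, 0) s.
    """
    y = np.asarray(conc_series, dtype=float)
    n = y.size
    conditions = stim.conditions
    cols, names = [], []
    for cond in conditions:
        reg = hrf_regressor(spec, fs, n, stim.onsets(cond))
        if filter_design:
            reg = lowpass(reg, fs)
        cols.append(reg)
        names.append(f"cond:{cond}")
    if ss_regressor is not None:
        ss = np.asarray(ss_regressor, dtype=float)
        sd = ss.std()
        cols.append((ss - ss.mean()) / (sd if sd > 0 else 1.0))
        names.append("short_separation")
    cols.append(np.ones(n))
    names.append("intercept")
    cols.append(np.linspace(-1, 1, n))
    names.append("drift")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient GLM design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError("insufficient samples for the design")
    sigma2 = float(resid @ resid / df)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    t_grid, h = hrf_kernel(spec, fs)
    baseline = t_grid < 0
    hrfs = {}
    for cond in conditions:
        b = beta[names.index(f"cond:{cond}")]
        est = b * h
        hrfs[cond] = est - est[baseline].mean()
    return GlmResult(
        betas=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        tstats=pd.Series(tvals, index=names),
        residual_variance=sigma2,
        df_resid=int(df),
        hrf_time=t_grid,
        hrf_estimates=hrfs,
        ss_channel=ss_channel,
    )


def glm_tstat_p(result: GlmResult, name: str) -> float:
    """Two-sided p-value for one regressor's t-statistic."""
    return float(2 * stats.t.sf(abs(result.tstats[name]), result.df_resid))
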