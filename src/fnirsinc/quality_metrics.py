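"""Channel-level signal-quality metrics and run-to-run improvement statistics.

Three metrics characterize a channel:

* **Uncorrected Signal Mean** — mean raw intensity over time, averaged across
  the two wavelengths.  Comparable to absolute optical power; used by the
  NEP analysis and the capping comparison.
* **Corrected Signal Mean** — the wavelength means divided by the LED source
  power percentage, multiplied by 100, averaged across wavelengths, then
  log10-transformed.  Power correction undoes the instrument's source
  modulation so hair/skin attenuation becomes visible; the log roughly
  normalizes the distribution and linearizes factor effects.
* **Scalp Coupling Index (SCI)** — zero-lag correlation between the two
  wavelengths' cardiac-band (0.5-2.5 Hz) filtered, SD-normalized traces.
  The cardiac pulsation is present at both wavelengths when the optode is
  well coupled to the scalp, so SCI near 1 indicates good coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from ._types import IntensityRecording

__all__ = [
    "ChannelQuality",
    "uncorrected_signal_mean",
    "corrected_signal_mean",
    "scalp_coupling_index",
    "fisher_z",
    "snr",
    "prune_by_snr",
    "channel_quality_table",
    "compare_runs",
    "SCI_BAND_HZ",
    "SNR_THRESHOLD",
]

SCI_BAND_HZ = (0.5, 2.5)
SNR_THRESHOLD = 5.0
_FISHER_CLIP = 1.0 - 1e-12


@dataclass
class ChannelQuality:
    channel: str
    roi: str
    uncorrected_mean: float
    corrected_mean: float
    sci: float
    sci_fisher_z: float
    snr: float
    pass_snr: bool


def _channel_data(rec: IntensityRecording, channel: int) -> np.ndarray:
    data = rec.data[channel]
    if data.shape[-1] < 1:
        raise ValueError("empty intensity trace")
    return data


def uncorrected_signal_mean(rec: IntensityRecording, channel: int) -> float:
    """Mean raw intensity over time, averaged across the two wavelengths."""
    return float(_channel_data(rec, channel).mean())


def corrected_signal_mean(rec: IntensityRecording, channel: int,
                          log_before_average: bool = False) -> float:
    """Source-power-corrected, log10-transformed signal mean.

    Per wavelength the time mean is divided by the LED source power
    percentage and multiplied by 100.  By default the two corrected
    wavelength means are averaged and then log10-transformed;
    ``log_before_average`` switches to averaging the per-wavelength logs
    (the ordering is ambiguous in common usage, so both are provided).
    Returns NaN (flagged, not dropped) for non-positive means.
    """
    data = _channel_data(rec, channel)
    power = rec.source_power_pct[channel]
    corrected = data.mean(axis=-1) / power * 100.0
    if np.any(corrected <= 0):
        return float("nan")
    if log_before_average:
        return float(np.mean(np.log10(corrected)))
    return float(np.log10(np.mean(corrected)))


def _cardiac_bandpass(x: np.ndarray, fs: float,
                      band: tuple[float, float] = SCI_BAND_HZ) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass along the last axis.

    Zero-phase (forward-backward) filtering preserves the zero-lag
    cross-correlation structure the SCI relies on.
    """
    nyq = fs / 2.0
    lo, hi = band
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
    sos = signal.butter(3, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def scalp_coupling_index(rec: IntensityRecording, channel: int,
                         band: tuple[float, float] = SCI_BAND_HZ) -> float:
    """Zero-lag correlation of the cardiac-band-filtered wavelength pair.

    Requires at least 10 s of samples.  Returns NaN (flagged) when a
    filtered trace has zero variance.
    """
    data = _channel_data(rec, channel)
    if data.shape[-1] < 10 * rec.fs:
        raise ValueError("SCI needs at least 10 s of samples")
    raw_sd = data.std(axis=-1)
    if np.any(raw_sd <= 1e-12 * (np.abs(data.mean(axis=-1)) + 1e-300)):
        return float("nan")   # flat trace: correlation undefined
    filt = _cardiac_bandpass(data, rec.fs, band)
    sd = filt.std(axis=-1)
    if np.any(sd == 0):
        return float("nan")
    z = filt / sd[:, None]
    r = float(np.corrcoef(z[0], z[1])[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def fisher_z(r) -> float:
    """Variance-stabilizing Fisher transform z = atanh(r), with |r| clipped
    just inside 1 so degenerate perfect correlations stay finite."""
    r = np.clip(np.asarray(r, dtype=float), -_FISHER_CLIP, _FISHER_CLIP)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def snr(rec: IntensityRecording, channel: int) -> float:
    """Raw-intensity mean/SD per wavelength, averaged across wavelengths.

    A zero-SD (noiseless) trace yields +inf and is retained by the pruning
    rule: absence of noise is not a quality defect.
    """
    data = _channel_data(rec, channel)
    if data.shape[-1] < 2:
        raise ValueError("SNR needs at least 2 samples")
    means = data.mean(axis=-1)
    sds = data.std(axis=-1)
    flat = sds <= 1e-12 * (np.abs(means) + 1e-300)
    with np.errstate(divide="ignore"):
        vals = np.where(flat, np.inf, means / np.where(flat, 1.0, sds))
    return float(vals.mean())


def prune_by_snr(snr_values, threshold: float = SNR_THRESHOLD):
    """Indices of channels retained: SNR strictly below the threshold is
    excluded, the boundary is kept."""
    snr_values = np.asarray(snr_values, dtype=float)
    return [i for i, v in enumerate(snr_values) if not v < threshold]


def channel_quality_table(rec: IntensityRecording,
                          participant: str | None = None,
                          log_before_average: bool = False) -> pd.DataFrame:
    """Compute all quality metrics for every channel of a recording.

    Columns: participant, channel, roi, kind, usm, csm, sci, sci_z, snr,
    pass_snr (one row per channel).
    """
    rows = []
    for i, ch in enumerate(rec.channels):
        usm = uncorrected_signal_mean(rec, i)
        csm = corrected_signal_mean(rec, i, log_before_average)
        sci = scalp_coupling_index(rec, i)
        s = snr(rec, i)
        rows.append({
            "participant": participant, "channel": ch.label, "roi": ch.roi,
            "kind": ch.kind, "hemisphere": ch.hemisphere,
            "usm": usm, "csm": csm, "sci": sci,
            "sci_z": fisher_z(sci) if np.isfinite(sci) else np.nan,
            "snr": s, "pass_snr": not (s < SNR_THRESHOLD),
        })
    return pd.DataFrame(rows)


def compare_runs(run1_values, run2_values, paired_by=None) -> dict:
    """Fast-capping vs proper-capping improvement summary for one metric/ROI.

    ``run1_values``/``run2_values`` are matched per-channel (or
    per-participant-mean) metric values from the two runs.  Returns means,
    SDs, the percent increase of the mean, and the two-sided paired t-test
    p-value.  If ``paired_by`` is given (array of participant ids), values
    are first averaged within participant so the test is across participants.
    """
    v1 = np.asarray(run1_values, dtype=float)
    v2 = np.asarray(run2_values, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("run1 and run2 must have matching shapes")
    if paired_by is not None:
        df = pd.DataFrame({"g": np.asarray(paired_by), "v1": v1, "v2": v2})
        agg = df.groupby("g").mean()
        v1, v2 = agg["v1"].to_numpy(), agg["v2"].to_numpy()
    keep = np.isfinite(v1) & np.isfinite(v2)
    v1, v2 = v1[keep], v2[keep]
    mean1, mean2 = v1.mean(), v2.mean()
    diffs = v2 - v1
    if np.allclose(diffs, diffs[0]):
        # zero variance of differences: degenerate t
        p = 1.0 if math.isclose(diffs[0], 0.0, abs_tol=1e-300) else 0.0
    else:
        p = float(stats.ttest_rel(v2, v1).pvalue)
    return {
        "mean1": float(mean1), "sd1": float(v1.std(ddof=1)),
        "mean2": float(mean2), "sd2": float(v2.std(ddof=1)),
        "percent_increase": float((mean2 - mean1) / mean1 * 100.0),
        "p_paired_t": p,
        "n": int(v1.size),
    }
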