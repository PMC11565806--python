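"""Detector-sensitivity (NEP) inclusivity analysis.

A continuous-wave fNIRS channel is usable only if the detected optical power
sits sufficiently far above the detector's noise floor.  The detector's
sensitivity is summarized by its noise-equivalent power (NEP, W/sqrt(Hz)).
The measurement device pairs a raw-unit noise floor with a known NEP, which
lets raw signal means be expressed as equivalent optical power and compared
against a pruning threshold of NEP plus an SNR margin (default 20 dB, i.e.
two orders of magnitude in power).

Sweeping the NEP across a grid emulates devices of different sensitivity and
shows how channel retention varies across combined hair-skin metric groups:
less sensitive detectors disproportionately prune channels from participants
with darker skin and hair, an inclusivity failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NepModel",
    "raw_to_power",
    "snr_threshold",
    "channel_pass",
    "group_pass_percentages",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class NepModel:
    """Raw-unit <-> optical-power equivalence for one device.

    Defaults are the study device's constants: NEP 52 fW/sqrt(Hz) at an
    equivalent raw-unit input noise of 6.8e-6, detector area 9.6 mm^2.
    The sqrt(Hz) bandwidth normalization is absorbed into the paired
    (noise_floor_raw, nep_w) constants.
    """

    nep_w: float = 52e-15
    noise_floor_raw: float = 6.8e-6
    detector_area_mm2: float = 9.6
    margin_db: float = 20.0

    def __post_init__(self):
        if self.nep_w <= 0:
            raise ValueError("nep_w must be positive")
        if self.noise_floor_raw <= 0:
            raise ValueError("noise_floor_raw must be positive")
        if self.margin_db < 0:
            raise ValueError("margin_db must be non-negative")

    def with_nep(self, nep_w: float) -> "NepModel":
        return NepModel(nep_w=nep_w, noise_floor_raw=self.noise_floor_raw,
                        detector_area_mm2=self.detector_area_mm2,
                        margin_db=self.margin_db)


def raw_to_power(raw_value, model: NepModel | None = None):
    """Convert raw signal units to equivalent optical power in watts.

    Linear through the device equivalence: power = raw * nep_w / noise_floor_raw.
    """
    model = model or NepModel()
    return np.asarray(raw_value, dtype=float) * (model.nep_w / model.noise_floor_raw)


def snr_threshold(nep_w: float, margin_db: float = 20.0) -> float:
    """Pruning threshold in watts: the NEP raised by the dB power margin.

    dB is 10*log10 of a power ratio, so the default 20 dB margin is a factor
    of 100 (1 pW NEP -> 100 pW threshold).
    """
    if nep_w <= 0:
        raise ValueError("nep_w must be positive")
    if margin_db < 0:
        raise ValueError("margin_db must be non-negative")
    return nep_w * 10.0 ** (margin_db / 10.0)


def channel_pass(uncorrected_mean_raw, model: NepModel | None = None,
                 nep_w: float | None = None):
    """True where a channel's mean raw signal clears the NEP + margin threshold.

    ``model`` supplies the measurement device's raw-power equivalence;
    ``nep_w`` (default: the device's own NEP) is the — possibly virtual —
    system sensitivity the threshold is computed from.  Channels exactly at
    the threshold pass (the criterion is "at least").
    """
    model = model or NepModel()
    power = raw_to_power(uncorrected_mean_raw, model)
    return power >= snr_threshold(model.nep_w if nep_w is None else nep_w,
                                  model.margin_db)


def group_pass_percentages(uncorrected_means, groups,
                           model: NepModel | None = None,
                           nep_w: float | None = None) -> pd.Series:
    """Percent of channels passing the threshold per combined-metric group.

    Returns a Series indexed by group 1..5 plus ``"overall_suboptimal"``
    (100 minus the overall pass percentage).  Empty groups get NaN.
    """
    model = model or NepModel()
    means = np.asarray(uncorrected_means, dtype=float)
    groups = np.asarray(groups)
    if means.shape != groups.shape:
        raise ValueError("uncorrected_means and groups must have equal length")
    passed = channel_pass(means, model, nep_w)
    out = {}
    for g in range(1, 6):
        sel = groups == g
        out[g] = 100.0 * passed[sel].mean() if sel.any() else np.nan
    out["overall_suboptimal"] = 100.0 * (1.0 - passed.mean()) if means.size else np.nan
    return pd.Series(out)


def sensitivity_sweep(uncorrected_means, groups, nep_grid,
                      model: NepModel | None = None) -> pd.DataFrame:
    """Group pass-percentage curves across a grid of virtual NEP values.

    Rows are NEP values (in W/sqrt(Hz)), columns the group percentages.
    The raw-to-power conversion always uses the *measurement* device's
    equivalence constants; only the pruning threshold follows the swept NEP.
    Each curve is non-increasing in NEP: a less sensitive detector never
    retains more channels.
    """
    model = model or NepModel()
    nep_grid = np.asarray(nep_grid, dtype=float)
    if nep_grid.size == 0:
        raise ValueError("nep_grid is empty")
    if np.any(nep_grid <= 0) or np.any(np.diff(nep_grid) < 0):
        raise ValueError("nep_grid must be positive and sorted ascending")
    rows = [group_pass_percentages(uncorrected_means, groups, model, nep)
            for nep in nep_grid]
    return pd.DataFrame(rows, index=pd.Index(nep_grid, name="nep_w"))
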