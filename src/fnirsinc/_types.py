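"""Core domain containers shared across the pipeline.

These are re-exported by the public modules (``synthetic_data``,
``io_formats``); import them from there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROIS = ("forehead", "side", "back")
HEMISPHERES = ("left", "right")
WAVELENGTHS_NM = (760.0, 850.0)

LONG_SEPARATION_MM = 30.0
SHORT_SEPARATION_MM = 8.0


@dataclass(frozen=True)
class Optode:
    """A source or detector: a labeled logical position with ROI/hemisphere tags."""

    label: str
    roi: str
    hemisphere: str
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Channel:
    """A source-detector pair at one separation.

    ``kind`` is "long" (~30 mm, cortex-sensitive) or "short" (~8 mm, scalp
    physiology only).
    """

    source: str
    detector: str
    separation_mm: float
    kind: str
    roi: str
    hemisphere: str

    @property
    def label(self) -> str:
        return f"{self.source}-{self.detector}"


@dataclass
class Probe:
    """Montage: sources, detectors, channels and the measurement wavelengths."""

    sources: list[Optode]
    detectors: list[Optode]
    channels: list[Channel]
    wavelengths: tuple[float, ...] = WAVELENGTHS_NM

    def __post_init__(self):
        labels_s = {o.label for o in self.sources}
        labels_d = {o.label for o in self.detectors}
        for ch in self.channels:
            if ch.source not in labels_s:
                raise ValueError(f"channel {ch.label} references unknown source")
            if ch.detector not in labels_d:
                raise ValueError(f"channel {ch.label} references unknown detector")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_indices(self, roi: str | None = None, kind: str | None = None,
                        hemisphere: str | None = None) -> list[int]:
        out = []
        for i, ch in enumerate(self.channels):
            if roi is not None and ch.roi != roi:
                continue
            if kind is not None and ch.kind != kind:
                continue
            if hemisphere is not None and ch.hemisphere != hemisphere:
                continue
            out.append(i)
        return out


@dataclass
class StimDesign:
    """Task events: (onset s, duration s, condition) plus run duration."""

    events: list[tuple[float, float, str]]
    run_duration: float

    def onsets(self, condition: str | None = None) -> np.ndarray:
        return np.array([e[0] for e in self.events
                         if condition is None or e[2] == condition])

    @property
    def conditions(self) -> list[str]:
        return sorted({e[2] for e in self.events})


@dataclass
class IntensityRecording:
    """Raw CW intensities, channel x wavelength x time.

    ``source_power_pct`` is the per-channel, per-wavelength LED power
    percentage (0, 100] recorded by the instrument; it feeds the
    power-corrected signal mean.
    """

    data: np.ndarray                   # (n_channels, n_wavelengths, n_times)
    fs: float
    channels: list[Channel]
    wavelengths: tuple[float, ...] = WAVELENGTHS_NM
    source_power_pct: np.ndarray | None = None   # (n_channels, n_wavelengths)
    run_label: str = "rest_proper_cap"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, wavelengths, times)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("data/channels length mismatch")
        if self.data.shape[1] != len(self.wavelengths):
            raise ValueError("data/wavelengths mismatch")
        if self.source_power_pct is None:
            self.source_power_pct = np.full(self.data.shape[:2], 100.0)
        self.source_power_pct = np.asarray(self.source_power_pct, dtype=float)
        if self.source_power_pct.shape != self.data.shape[:2]:
            raise ValueError("source_power_pct must be (channels, wavelengths)")
        if np.any(self.source_power_pct <= 0) or np.any(self.source_power_pct > 100):
            raise ValueError("source_power_pct must lie in (0, 100]")

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    @property
    def duration(self) -> float:
        return self.n_times / self.fs
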