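"""Categorical scales for hair/skin factors and the combined hair-skin metric.

The combined hair-skin metric summarizes, per participant, the four factors
that dominate near-infrared light loss at the scalp: average hair-shaft
thickness, hair type (curl pattern), hair color, and skin pigmentation
(Melanin Index).  Each factor is min-max normalized to [0, 1] over its
observed range and the four normalized values are averaged with equal
weights.  Higher values indicate a more challenging optical measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CombinedMetricSpec",
    "HAIR_COLOR_CODES",
    "HAIR_TYPE_CODES",
    "HAIR_TEXTURE_CODES",
    "encode_hair_color",
    "encode_hair_type",
    "encode_hair_texture",
    "encode_fitzpatrick",
    "encode_scales",
    "normalize_metric",
    "combined_hair_skin_metric",
    "assign_group",
    "GROUP_EDGES",
]

# Fischer-Saller hair color scale (red and black share a code: pheomelanin in
# red hair absorbs at least as much NIR light as eumelanin).
HAIR_COLOR_CODES = {
    "no hair": 0,
    "grey": 1,
    "white": 1,
    "grey/white": 1,
    "blonde": 2,
    "brown": 3,
    "red": 4,
    "black": 4,
    "red/black": 4,
}

# Andre Walker hair typing system (curl pattern).
HAIR_TYPE_CODES = {
    "no hair": 0,
    "straight": 1,
    "wavy": 2,
    "curly": 3,
    "kinky": 4,
}

# FIA strand texture scale (strand coarseness).
HAIR_TEXTURE_CODES = {
    "no hair": 0,
    "fine": 1,
    "medium": 2,
    "coarse": 3,
}

# Fitzpatrick skin phototypes regrouped into three categories:
# I/II -> 1, III/IV -> 2, V/VI -> 3.
_FITZPATRICK_GROUPS = {
    "i": 1, "ii": 1, "1": 1, "2": 1,
    "iii": 2, "iv": 2, "3": 2, "4": 2,
    "v": 3, "vi": 3, "5": 3, "6": 3,
}


def _lookup(table: dict, label: str, what: str) -> int:
    key = str(label).strip().lower()
    if key not in table:
        raise ValueError(f"unknown {what} label: {label!r}")
    return table[key]


def encode_hair_color(label: str) -> int:
    return _lookup(HAIR_COLOR_CODES, label, "hair color")


def encode_hair_type(label: str) -> int:
    return _lookup(HAIR_TYPE_CODES, label, "hair type")


def encode_hair_texture(label: str) -> int:
    return _lookup(HAIR_TEXTURE_CODES, label, "hair texture")


def encode_fitzpatrick(label: str) -> int:
    """Map a Fitzpatrick phototype (I-VI) to its 3-level regrouping."""
    return _lookup(_FITZPATRICK_GROUPS, label, "Fitzpatrick type")


def encode_scales(labels: dict) -> dict:
    """Encode a dict of textual labels into ordinal codes.

    Recognized keys: ``hair_color``, ``hair_type``, ``hair_texture``,
    ``skin_type`` (Fitzpatrick I-VI).  A ``"no hair"`` value on any hair key
    forces all three hair codes to 0.
    """
    encoders = {
        "hair_color": encode_hair_color,
        "hair_type": encode_hair_type,
        "hair_texture": encode_hair_texture,
        "skin_type": encode_fitzpatrick,
    }
    out = {}
    for key, value in labels.items():
        if key not in encoders:
            raise ValueError(f"unknown scale: {key!r}")
        out[key] = encoders[key](value)
    hair_keys = [k for k in ("hair_color", "hair_type", "hair_texture") if k in out]
    if any(out[k] == 0 for k in hair_keys):
        for k in hair_keys:
            out[k] = 0
    return out


@dataclass(frozen=True)
class CombinedMetricSpec:
    """Normalization ranges for the four combined-metric components.

    Defaults are the study's observed ranges: shaft thickness 42-88 um,
    hair type and color 0-4 (categorical scales), Melanin Index 4.7-90.
    """

    thickness_range: tuple[float, float] = (42.0, 88.0)
    hair_type_range: tuple[float, float] = (0.0, 4.0)
    hair_color_range: tuple[float, float] = (0.0, 4.0)
    pigmentation_range: tuple[float, float] = (4.7, 90.0)

    @property
    def m(self) -> int:
        return 4

    def __post_init__(self):
        for name in ("thickness_range", "hair_type_range",
                     "hair_color_range", "pigmentation_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name}: max must exceed min, got ({lo}, {hi})")


def normalize_metric(x, lo: float, hi: float, clip: bool = True):
    """Min-max normalize ``x`` to [0, 1] over the range (lo, hi).

    Values outside the range are clipped after normalization (with a warning):
    the ranges are observed study extremes and new data may exceed them.
    """
    if not hi > lo:
        raise ValueError(f"max must exceed min, got ({lo}, {hi})")
    x = np.asarray(x, dtype=float)
    z = (x - lo) / (hi - lo)
    if clip:
        if np.any(z < 0) or np.any(z > 1):
            warnings.warn(
                f"values outside normalization range ({lo}, {hi}) were clipped",
                stacklevel=2,
            )
        z = np.clip(z, 0.0, 1.0)
    return float(z) if z.ndim == 0 else z


def combined_hair_skin_metric(thickness, hair_type, hair_color, pigmentation,
                              spec: CombinedMetricSpec | None = None):
    """Equal-weight mean of the four normalized hair/skin factors, in [0, 1]."""
    spec = spec or CombinedMetricSpec()
    parts = [
        normalize_metric(thickness, *spec.thickness_range),
        normalize_metric(hair_type, *spec.hair_type_range),
        normalize_metric(hair_color, *spec.hair_color_range),
        normalize_metric(pigmentation, *spec.pigmentation_range),
    ]
    return sum(np.asarray(p, dtype=float) for p in parts) / spec.m


# Five groups over the metric's range; the study's observed minimum is 0.15 so
# [0, 0.15) folds into group 1 to keep the assignment total on [0, 1].
GROUP_EDGES = (0.15, 0.30, 0.45, 0.60, 0.75, 1.0)


def assign_group(metric_value):
    """Assign a combined-metric value in [0, 1] to group 1..5.

    Bins are right-half-open except the last: [0.15, 0.30), [0.30, 0.45),
    [0.45, 0.60), [0.60, 0.75), [0.75, 1.0]; values below 0.15 map to group 1.
    """
    v = np.asarray(metric_value, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("combined metric value outside [0, 1]")
    # searchsorted over interior edges; edges are group lower bounds
    g = np.searchsorted(GROUP_EDGES[1:-1], v, side="right") + 1
    out = g.astype(int)
    return int(out) if out.ndim == 0 else out
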