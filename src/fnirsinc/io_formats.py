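"""Read/write the pipeline's on-disk formats: SNIRF recordings and
participant tables.

SNIRF (HDF5) is the single recording format; only continuous-wave raw
intensity (dataType 1) is supported.  Channel annotations (ROI, kind,
separation, hemisphere) and per-channel source-power percentages have no
canonical SNIRF slot, so they are stored as JSON strings inside
``metaDataTags`` and round-trip through this module's reader; standard
readers simply ignore them.

Participant tables are UTF-8 tab-separated files with "." decimals; the
column set follows the study's metadata recommendations (recommended
hair/skin/demographic fields plus optional trichoscopy blocks).
"""

from __future__ import annotations

import json
import logging
import warnings

import h5py
import numpy as np
import pandas as pd

from ._types import Channel, IntensityRecording, Optode, Probe, StimDesign
from .synthetic_data import ParticipantProfile, TrichoscopyBlock

logger = logging.getLogger(__name__)

__all__ = [
    "SnirfFormatError",
    "UnsupportedSnirfError",
    "ParticipantSchemaError",
    "write_snirf",
    "read_snirf",
    "write_participants",
    "read_participants",
    "participants_to_table",
    "table_to_participants",
    "validate_snirf",
    "REQUIRED_PARTICIPANT_COLUMNS",
    "TRICHOSCOPY_COLUMNS",
]


class SnirfFormatError(ValueError):
    """Missing or malformed mandatory SNIRF content."""


class UnsupportedSnirfError(ValueError):
    """Valid SNIRF but not CW raw intensity."""


class ParticipantSchemaError(ValueError):
    """Participant table violates the metadata schema."""


_STR = h5py.string_dtype(encoding="utf-8")


def _write_str(group, name, value):
    group.create_dataset(name, data=np.bytes_(value))


# ---------------------------------------------------------------------------
# SNIRF


def write_snirf(probe: Probe, recording: IntensityRecording,
                stim: StimDesign | None, path) -> None:
    """Write a CW recording as SNIRF v1.0.

    Measurement rows are ordered channel-major (each channel contributes one
    row per wavelength); an empty stim design writes no stim group.
    """
    with h5py.File(path, "w") as f:
        _write_str(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs1")

        meta = nirs.create_group("metaDataTags")
        _write_str(meta, "SubjectID", "synthetic")
        _write_str(meta, "MeasurementDate", "unknown")
        _write_str(meta, "MeasurementTime", "unknown")
        _write_str(meta, "LengthUnit", "mm")
        _write_str(meta, "TimeUnit", "s")
        _write_str(meta, "FrequencyUnit", "Hz")
        channel_info = [
            {"source": ch.source, "detector": ch.detector,
             "separation_mm": ch.separation_mm, "kind": ch.kind,
             "roi": ch.roi, "hemisphere": ch.hemisphere}
            for ch in recording.channels
        ]
        _write_str(meta, "ChannelInfo", json.dumps(channel_info))
        _write_str(meta, "SourcePowerPct",
                   json.dumps(recording.source_power_pct.tolist()))
        _write_str(meta, "RunLabel", recording.run_label)

        data = nirs.create_group("data1")
        n_ch, n_wl, n_t = recording.data.shape
        series = recording.data.reshape(n_ch * n_wl, n_t).T   # time x meas
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(n_t) / recording.fs)
        src_order = [s.label for s in probe.sources]
        det_order = [d.label for d in probe.detectors]
        m = 0
        for ch in recording.channels:
            for w in range(n_wl):
                m += 1
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex",
                                  data=src_order.index(ch.source) + 1)
                ml.create_dataset("detectorIndex",
                                  data=det_order.index(ch.detector) + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)       # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)

        pg = nirs.create_group("probe")
        pg.create_dataset("wavelengths",
                          data=np.asarray(probe.wavelengths, dtype=float))
        pg.create_dataset("sourcePos3D",
                          data=np.array([s.position for s in probe.sources]))
        pg.create_dataset("detectorPos3D",
                          data=np.array([d.position for d in probe.detectors]))
        pg.create_dataset("sourceLabels",
                          data=np.array(src_order, dtype=_STR))
        pg.create_dataset("detectorLabels",
                          data=np.array(det_order, dtype=_STR))
        _write_str(meta, "OptodeInfo", json.dumps({
            "sources": [{"label": s.label, "roi": s.roi,
                         "hemisphere": s.hemisphere} for s in probe.sources],
            "detectors": [{"label": d.label, "roi": d.roi,
                           "hemisphere": d.hemisphere} for d in probe.detectors],
        }))

        if stim is not None and stim.events:
            for j, cond in enumerate(stim.conditions, start=1):
                sg = nirs.create_group(f"stim{j}")
                _write_str(sg, "name", cond)
                rows = [[on, dur, 1.0] for on, dur, c in stim.events
                        if c == cond]
                sg.create_dataset("data", data=np.array(rows, dtype=float))


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path) -> tuple[Probe, IntensityRecording, StimDesign | None]:
    """Read a CW SNIRF file back into pipeline containers.

    Raises :class:`SnirfFormatError` on missing mandatory fields and
    :class:`UnsupportedSnirfError` for non-CW data types.  Unknown optional
    groups are ignored with a logged warning.
    """
    with h5py.File(path, "r") as f:
        if "nirs1" not in f:
            raise SnirfFormatError("missing /nirs1 group")
        nirs = f["nirs1"]
        for required in ("data1", "probe"):
            if required not in nirs:
                raise SnirfFormatError(f"missing /nirs1/{required}")
        data_g = nirs["data1"]
        for required in ("dataTimeSeries", "time"):
            if required not in data_g:
                raise SnirfFormatError(f"missing data1/{required}")
        if "wavelengths" not in nirs["probe"]:
            raise SnirfFormatError("missing probe/wavelengths")

        wavelengths = tuple(float(w) for w in nirs["probe"]["wavelengths"][()])
        series = np.asarray(data_g["dataTimeSeries"][()], dtype=float)
        time = np.asarray(data_g["time"][()], dtype=float)
        if time.size == 2 and series.shape[0] != 2:
            fs = 1.0 / time[1]
        else:
            dt = np.diff(time)
            if dt.size == 0 or np.any(dt <= 0):
                raise SnirfFormatError("non-increasing time vector")
            fs = 1.0 / float(np.mean(dt))

        ml_names = sorted((k for k in data_g if k.startswith("measurementList")),
                          key=lambda k: int(k[len("measurementList"):]))
        if not ml_names:
            raise SnirfFormatError("missing measurementList entries")
        measurements = []
        for name in ml_names:
            ml = data_g[name]
            dtype = int(ml["dataType"][()]) if "dataType" in ml else 1
            if dtype != 1:
                raise UnsupportedSnirfError(
                    f"measurement {name} has dataType {dtype}; only CW "
                    "amplitude (1) is supported")
            measurements.append((int(ml["sourceIndex"][()]),
                                 int(ml["detectorIndex"][()]),
                                 int(ml["wavelengthIndex"][()])))

        src_labels = [_read_str_item(s) for s in nirs["probe"]["sourceLabels"][()]] \
            if "sourceLabels" in nirs["probe"] else None
        det_labels = [_read_str_item(s) for s in nirs["probe"]["detectorLabels"][()]] \
            if "detectorLabels" in nirs["probe"] else None
        src_pos = np.asarray(nirs["probe"]["sourcePos3D"][()]) \
            if "sourcePos3D" in nirs["probe"] else None
        det_pos = np.asarray(nirs["probe"]["detectorPos3D"][()]) \
            if "detectorPos3D" in nirs["probe"] else None
        if src_labels is None:
            n_src = max(m[0] for m in measurements)
            src_labels = [f"S{i + 1}" for i in range(n_src)]
        if det_labels is None:
            n_det = max(m[1] for m in measurements)
            det_labels = [f"D{i + 1}" for i in range(n_det)]

        meta = nirs["metaDataTags"] if "metaDataTags" in nirs else {}
        channel_info = optode_info = None
        power = None
        run_label = "rest_proper_cap"
        if "ChannelInfo" in meta:
            channel_info = json.loads(_read_str(meta["ChannelInfo"]))
        if "OptodeInfo" in meta:
            optode_info = json.loads(_read_str(meta["OptodeInfo"]))
        if "SourcePowerPct" in meta:
            power = np.asarray(json.loads(_read_str(meta["SourcePowerPct"])))
        if "RunLabel" in meta:
            run_label = _read_str(meta["RunLabel"])

        # group measurement rows into channels (source, detector) preserving order
        chan_keys: list[tuple[int, int]] = []
        for s, d, _ in measurements:
            if (s, d) not in chan_keys:
                chan_keys.append((s, d))
        n_wl = len(wavelengths)
        n_ch = len(chan_keys)
        if series.shape[1] != len(measurements):
            raise SnirfFormatError("dataTimeSeries/measurementList mismatch")
        cube = np.empty((n_ch, n_wl, series.shape[0]))
        for col, (s, d, w) in enumerate(measurements):
            cube[chan_keys.index((s, d)), w - 1, :] = series[:, col]

        info_by_pair = {}
        if channel_info is not None:
            for ci in channel_info:
                info_by_pair[(ci["source"], ci["detector"])] = ci
        channels = []
        for s, d, in chan_keys:
            s_lab, d_lab = src_labels[s - 1], det_labels[d - 1]
            ci = info_by_pair.get((s_lab, d_lab))
            if ci is not None:
                channels.append(Channel(s_lab, d_lab, ci["separation_mm"],
                                        ci["kind"], ci["roi"], ci["hemisphere"]))
            else:
                sep = float(np.linalg.norm(src_pos[s - 1] - det_pos[d - 1])) \
                    if src_pos is not None and det_pos is not None else np.nan
                kind = "short" if sep < 15.0 else "long"
                logger.warning("no channel annotations for %s-%s; inferring "
                               "kind from geometry", s_lab, d_lab)
                channels.append(Channel(s_lab, d_lab, sep, kind,
                                        "unknown", "unknown"))

        def optode_meta(labels, positions, which):
            out = []
            lookup = {}
            if optode_info is not None:
                lookup = {o["label"]: o for o in optode_info[which]}
            for i, lab in enumerate(labels):
                pos = tuple(positions[i]) if positions is not None else (0, 0, 0)
                o = lookup.get(lab, {})
                out.append(Optode(lab, o.get("roi", "unknown"),
                                  o.get("hemisphere", "unknown"), pos))
            return out

        probe = Probe(sources=optode_meta(src_labels, src_pos, "sources"),
                      detectors=optode_meta(det_labels, det_pos, "detectors"),
                      channels=channels, wavelengths=wavelengths)
        rec = IntensityRecording(data=cube, fs=float(fs), channels=channels,
                                 wavelengths=wavelengths,
                                 source_power_pct=power, run_label=run_label)

        stim = None
        stim_names = sorted((k for k in nirs if k.startswith("stim")),
                            key=lambda k: int(k[len("stim"):]))
        if stim_names:
            events = []
            for name in stim_names:
                sg = nirs[name]
                cond = _read_str(sg["name"])
                for row in np.atleast_2d(np.asarray(sg["data"][()])):
                    events.append((float(row[0]), float(row[1]), cond))
            events.sort(key=lambda e: e[0])
            stim = StimDesign(events=events,
                              run_duration=float(time[-1] + 1.0 / fs))
        return probe, rec, stim


def _read_str_item(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)


def validate_snirf(path) -> dict:
    """Light validation: read the file and report shape/fs/channel summary."""
    probe, rec, stim = read_snirf(path)
    if np.any(rec.data < 0):
        warnings.warn("negative intensities present", stacklevel=2)
    return {
        "n_channels": rec.data.shape[0],
        "n_wavelengths": rec.data.shape[1],
        "n_times": rec.data.shape[2],
        "fs": rec.fs,
        "wavelengths": list(rec.wavelengths),
        "has_stim": stim is not None,
        "run_label": rec.run_label,
    }


# ---------------------------------------------------------------------------
# participant tables

REQUIRED_PARTICIPANT_COLUMNS = [
    "participant_id", "age", "sex",
    "head_circumference_cm", "nasion_inion_cm", "ear_to_ear_cm",
    "skin_pigmentation", "skin_type",
    "hair_color", "hair_type", "hair_texture",
]

TRICHOSCOPY_COLUMNS = [
    "avg_num_hairs", "avg_shaft_thickness_um",
    "thin_hairs_pct", "middle_hairs_pct", "thick_hairs_pct",
    "single_fu_pct", "double_fu_pct", "triple_fu_pct",
    "cumulative_thickness_mm_cm2", "n_follicular_units", "sinclair_scale",
]

_ORDINAL_RANGES = {
    "hair_color": (0, 4), "hair_type": (0, 4), "hair_texture": (0, 3),
    "skin_type": (1, 3),
}


def participants_to_table(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    """Flatten profiles into the tab-separated schema (one row each)."""
    rows = []
    for p in profiles:
        row = {
            "participant_id": p.id, "age": p.age, "sex": p.sex,
            "head_circumference_cm": p.head_circumference_cm,
            "nasion_inion_cm": p.nasion_inion_cm,
            "ear_to_ear_cm": p.ear_to_ear_cm,
            "skin_pigmentation": p.skin_pigmentation,
            "skin_type": p.skin_type, "hair_color": p.hair_color,
            "hair_type": p.hair_type, "hair_texture": p.hair_texture,
        }
        for region, block in p.trichoscopy.items():
            row.update({
                f"{region}_avg_num_hairs": block.avg_num_hairs,
                f"{region}_avg_shaft_thickness_um": block.avg_shaft_thickness,
                f"{region}_thin_hairs_pct": block.thin_pct,
                f"{region}_middle_hairs_pct": block.middle_pct,
                f"{region}_thick_hairs_pct": block.thick_pct,
                f"{region}_single_fu_pct": block.single_fu_pct,
                f"{region}_double_fu_pct": block.double_fu_pct,
                f"{region}_triple_fu_pct": block.triple_fu_pct,
                f"{region}_cumulative_thickness_mm_cm2": block.cumulative_thickness,
                f"{region}_n_follicular_units": block.n_follicular_units,
                f"{region}_sinclair_scale": block.sinclair_scale,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def _validate_participants(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParticipantSchemaError(f"missing required columns: {missing}")
    for col, (lo, hi) in _ORDINAL_RANGES.items():
        vals = df[col].to_numpy()
        bad = (vals < lo) | (vals > hi) | (vals != np.round(vals))
        if np.any(bad):
            raise ParticipantSchemaError(
                f"invalid {col} codes (allowed {lo}..{hi}): "
                f"{sorted(set(np.asarray(vals)[bad]))}")
    hair = df[["hair_color", "hair_type", "hair_texture"]].to_numpy()
    inconsistent = (hair == 0).any(axis=1) & ~(hair == 0).all(axis=1)
    if np.any(inconsistent):
        raise ParticipantSchemaError(
            '"no hair" rows must set hair_color, hair_type and hair_texture '
            "all to 0")
    return df


def write_participants(table, path) -> None:
    """Write a participant table (DataFrame or list of profiles) as TSV."""
    if not isinstance(table, pd.DataFrame):
        table = participants_to_table(table)
    _validate_participants(table)
    table.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_participants(path) -> pd.DataFrame:
    """Read and validate a participant TSV; optional trichoscopy columns may
    be absent."""
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    return _validate_participants(df)


def table_to_participants(df: pd.DataFrame) -> list[ParticipantProfile]:
    """Rebuild profile objects from a validated table (trichoscopy columns
    required for this direction)."""
    _validate_participants(df)
    out = []
    for _, row in df.iterrows():
        trich = {}
        for region in ("side", "back"):
            key = f"{region}_avg_num_hairs"
            if key not in df.columns:
                continue
            trich[region] = TrichoscopyBlock(
                avg_num_hairs=row[f"{region}_avg_num_hairs"],
                avg_shaft_thickness=row[f"{region}_avg_shaft_thickness_um"],
                thin_pct=row[f"{region}_thin_hairs_pct"],
                middle_pct=row[f"{region}_middle_hairs_pct"],
                thick_pct=row[f"{region}_thick_hairs_pct"],
                single_fu_pct=row[f"{region}_single_fu_pct"],
                double_fu_pct=row[f"{region}_double_fu_pct"],
                triple_fu_pct=row[f"{region}_triple_fu_pct"],
                n_follicular_units=row[f"{region}_n_follicular_units"],
                sinclair_scale=row[f"{region}_sinclair_scale"],
            )
        out.append(ParticipantProfile(
            id=str(row["participant_id"]), age=float(row["age"]),
            sex=str(row["sex"]),
            head_circumference_cm=float(row["head_circumference_cm"]),
            nasion_inion_cm=float(row["nasion_inion_cm"]),
            ear_to_ear_cm=float(row["ear_to_ear_cm"]),
            skin_pigmentation=float(row["skin_pigmentation"]),
            skin_type=int(row["skin_type"]),
            hair_color=int(row["hair_color"]),
            hair_type=int(row["hair_type"]),
            hair_texture=int(row["hair_texture"]),
            trichoscopy=trich,
        ))
    return out
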