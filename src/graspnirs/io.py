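"""File formats: SNIRF recordings, clinical tables, ROI configuration, results.

SNIRF (Shared Near Infrared Spectroscopy Format) is the community HDF5 container
for continuous-wave recordings; only the v1.x CW-amplitude subset needed by this
pipeline is read and written.  A plain tab-separated fallback (one intensity
file per wavelength plus a montage table) is provided for dependency-free
fixtures.  Clinical covariates and all result tables are delimited text with a
header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, UnsupportedDataError, ValidationError
from .types import ClinicalTable, Montage, RawIntensity, ROIConfig, StimulusDesign

__all__ = [
    "read_snirf",
    "write_snirf",
    "read_clinical_table",
    "write_clinical_table",
    "load_roi_config",
    "write_result_table",
    "read_intensity_tsv",
    "write_intensity_tsv",
]

_DEFAULT_CONDITION_MAP = {"LG": "LG", "RG": "RG"}


# ---------------------------------------------------------------------------
# SNIRF
# ---------------------------------------------------------------------------

def _require(group: h5py.Group | h5py.File, name: str):
    if name not in group:
        raise FormatError(f"SNIRF file missing required group or dataset {name!r}")
    return group[name]


def write_snirf(
    path: str | Path,
    raw: RawIntensity,
    montage: Montage,
    design: StimulusDesign,
) -> None:
    """Write a continuous-wave amplitude recording as SNIRF v1.0.

    Measurement columns are ordered channel-major, wavelength-minor, matching
    the (channel, wavelength, time) layout of :class:`RawIntensity`.
    """
    path = Path(path)
    n_ch, _, n_t = raw.data.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs1")
        meta = nirs.create_group("metaDataTags")
        for key, val in (
            ("SubjectID", "synthetic"),
            ("MeasurementDate", "unknown"),
            ("MeasurementTime", "unknown"),
            ("LengthUnit", "mm"),
            ("TimeUnit", "s"),
            ("FrequencyUnit", "Hz"),
        ):
            meta.create_dataset(key, data=val)
        data1 = nirs.create_group("data1")
        ts = raw.data.reshape(n_ch * 2, n_t).T  # time x measurement
        data1.create_dataset("dataTimeSeries", data=ts)
        data1.create_dataset("time", data=np.arange(n_t) / raw.fs)
        src_index = {s[0]: i + 1 for i, s in enumerate(montage.sources)}
        det_index = {d[0]: i + 1 for i, d in enumerate(montage.detectors)}
        m = 1
        for cid, sid, did, _dist in montage.channels:
            for wi in (1, 2):
                ml = data1.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=src_index[sid])
                ml.create_dataset("detectorIndex", data=det_index[did])
                ml.create_dataset("wavelengthIndex", data=wi)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                m += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths, dtype=float))
        spos = np.array(
            [s[2] if s[2] is not None else (np.nan,) * 3 for s in montage.sources], dtype=float
        )
        dpos = np.array(
            [d[2] if d[2] is not None else (np.nan,) * 3 for d in montage.detectors], dtype=float
        )
        probe.create_dataset("sourcePos3D", data=spos)
        probe.create_dataset("detectorPos3D", data=dpos)
        probe.create_dataset(
            "sourceLabels", data=np.array([s[1] for s in montage.sources], dtype=object),
            dtype=h5py.string_dtype(),
        )
        probe.create_dataset(
            "detectorLabels", data=np.array([d[1] for d in montage.detectors], dtype=object),
            dtype=h5py.string_dtype(),
        )
        # channel bookkeeping not in the SNIRF core: ids and stored distances
        aux = nirs.create_group("auxMontage")
        aux.create_dataset("channelIds", data=np.array(montage.channel_ids, dtype=np.int64))
        aux.create_dataset("distances", data=montage.distances())
        aux.create_dataset("sourceIds", data=np.array([s[0] for s in montage.sources]))
        aux.create_dataset("detectorIds", data=np.array([d[0] for d in montage.detectors]))
        for k, cond in enumerate(("LG", "RG"), start=1):
            evs = design.onsets(cond)
            stim = nirs.create_group(f"stim{k}")
            stim.create_dataset("name", data=cond)
            arr = np.array([[on, du, 1.0] for on, du in evs], dtype=float).reshape(-1, 3)
            stim.create_dataset("data", data=arr)
        nirs.create_group("stimMeta").create_dataset(
            "totalDuration", data=float(design.total_duration)
        )


def _as_str(v) -> str:
    v = v[()] if hasattr(v, "shape") else v
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.ndarray):
        return _as_str(v.item())
    return str(v)


def read_snirf(
    path: str | Path,
    condition_map: dict[str, str] | None = None,
) -> tuple[RawIntensity, Montage, StimulusDesign]:
    """Read a CW-amplitude SNIRF file written by this package (or compatible).

    ``condition_map`` translates on-disk stimulus names to the canonical
    {LG, RG}; it defaults to the identity on those two labels.
    """
    cmap = dict(_DEFAULT_CONDITION_MAP if condition_map is None else condition_map)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        _require(f, "formatVersion")
        nirs = _require(f, "nirs1")
        data1 = _require(nirs, "data1")
        probe = _require(nirs, "probe")
        wl = np.asarray(_require(probe, "wavelengths")[()], dtype=float)
        if wl.size != 2:
            raise UnsupportedDataError(
                f"only dual-wavelength recordings supported, file has {wl.size}"
            )
        ts = np.asarray(_require(data1, "dataTimeSeries")[()], dtype=float)
        time = np.asarray(_require(data1, "time")[()], dtype=float)
        if time.size < 2:
            raise FormatError("time vector too short")
        fs = 1.0 / float(np.median(np.diff(time)))
        ml_names = sorted(
            (k for k in data1 if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if not ml_names:
            raise FormatError("SNIRF file missing required group or dataset 'measurementList'")
        meas = []
        for k in ml_names:
            ml = data1[k]
            meas.append(
                (
                    int(_require(ml, "sourceIndex")[()]),
                    int(_require(ml, "detectorIndex")[()]),
                    int(_require(ml, "wavelengthIndex")[()]),
                )
            )
        if {m[2] for m in meas} - {1, 2}:
            raise UnsupportedDataError("wavelengthIndex outside {1, 2}")
        spos = np.asarray(_require(probe, "sourcePos3D")[()], dtype=float)
        dpos = np.asarray(_require(probe, "detectorPos3D")[()], dtype=float)
        slab = [_as_str(x) for x in _require(probe, "sourceLabels")[()]]
        dlab = [_as_str(x) for x in _require(probe, "detectorLabels")[()]]
        if "auxMontage" in nirs:
            aux = nirs["auxMontage"]
            ch_ids = [int(x) for x in aux["channelIds"][()]]
            dists = np.asarray(aux["distances"][()], dtype=float)
            src_ids = [int(x) for x in aux["sourceIds"][()]]
            det_ids = [int(x) for x in aux["detectorIds"][()]]
        else:
            src_ids = list(range(1, len(slab) + 1))
            det_ids = list(range(1, len(dlab) + 1))
            ch_ids, dists = None, None

        # group measurements into channels: consecutive (src, det) pairs
        pairs: list[tuple[int, int]] = []
        for s_i, d_i, _w in meas:
            if (s_i, d_i) not in pairs:
                pairs.append((s_i, d_i))
        n_ch = len(pairs)
        if len(meas) != 2 * n_ch:
            raise UnsupportedDataError("expected exactly 2 wavelengths per channel")
        data = np.empty((n_ch, 2, time.size), dtype=float)
        pair_pos = {p: i for i, p in enumerate(pairs)}
        for col, (s_i, d_i, w_i) in enumerate(meas):
            data[pair_pos[(s_i, d_i)], w_i - 1] = ts[:, col]
        if ch_ids is None:
            ch_ids = list(range(1, n_ch + 1))
        if dists is None:
            dists = np.array(
                [
                    float(np.linalg.norm(spos[s_i - 1] - dpos[d_i - 1]))
                    for s_i, d_i in pairs
                ]
            )
        sources = [
            (src_ids[i], slab[i], None if np.any(np.isnan(spos[i])) else spos[i])
            for i in range(len(slab))
        ]
        detectors = [
            (det_ids[i], dlab[i], None if np.any(np.isnan(dpos[i])) else dpos[i])
            for i in range(len(dlab))
        ]
        channels = [
            (ch_ids[i], src_ids[s_i - 1], det_ids[d_i - 1], float(dists[i]))
            for i, (s_i, d_i) in enumerate(pairs)
        ]
        montage = Montage(
            wavelengths=(float(wl[0]), float(wl[1])),
            sources=sources,
            detectors=detectors,
            channels=channels,
        )
        events: list[tuple[str, float, float]] = []
        total = time[-1] + 1.0 / fs
        if "stimMeta" in nirs and "totalDuration" in nirs["stimMeta"]:
            total = float(nirs["stimMeta"]["totalDuration"][()])
        for k in sorted(k for k in nirs if k.startswith("stim") and k[4:].isdigit()):
            stim = nirs[k]
            name = _as_str(_require(stim, "name"))
            if name not in cmap:
                raise ConfigError(f"stimulus name {name!r} not in condition map {sorted(cmap)}")
            for on, du, _amp in np.asarray(stim["data"][()], dtype=float).reshape(-1, 3):
                events.append((cmap[name], float(on), float(du)))
        events.sort(key=lambda e: e[1])
        design = StimulusDesign(events=events, total_duration=total)
        raw = RawIntensity(fs=fs, data=data, wavelengths=montage.wavelengths)
    return raw, montage, design


# ---------------------------------------------------------------------------
# Plain-text intensity fallback
# ---------------------------------------------------------------------------

def write_intensity_tsv(prefix: str | Path, raw: RawIntensity) -> list[Path]:
    """Write one TSV per wavelength (columns = channels) plus a small JSON sidecar."""
    prefix = Path(prefix)
    paths = []
    for wi, wl in enumerate(raw.wavelengths):
        p = prefix.with_name(prefix.name + f"_wl{int(round(wl))}.tsv")
        df = pd.DataFrame(
            raw.data[:, wi, :].T, columns=[f"ch{i}" for i in range(raw.n_channels)]
        )
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        paths.append(p)
    side = prefix.with_name(prefix.name + "_meta.json")
    side.write_text(json.dumps({"fs": raw.fs, "wavelengths": list(raw.wavelengths)}))
    paths.append(side)
    return paths


def read_intensity_tsv(prefix: str | Path) -> RawIntensity:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text())
    mats = []
    for wl in meta["wavelengths"]:
        p = prefix.with_name(prefix.name + f"_wl{int(round(wl))}.tsv")
        mats.append(pd.read_csv(p, sep="\t").to_numpy(dtype=float).T)
    data = np.stack(mats, axis=1)
    return RawIntensity(fs=meta["fs"], data=data, wavelengths=tuple(meta["wavelengths"]))


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

_CLINICAL_ALIASES = {
    "subject": "subject", "subject_id": "subject", "id": "subject",
    "group": "group",
    "age": "age",
    "criq": "criq",
    "duration": "duration", "disease_duration": "duration",
    "updrs": "updrs",
    "scwe": "scwe",
    "scwt": "scwt",
}


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a comma- or tab-delimited clinical covariate table.

    Group labels are normalized case-insensitively to {ePD, mPD}; empty cells
    become missing values; numeric columns must parse or an error names the
    offending row and column.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [
        _CLINICAL_ALIASES.get(c.strip().lower().replace(" ", "_"), c.strip().lower())
        for c in df.columns
    ]
    if "subject" not in df.columns or "group" not in df.columns:
        raise ValidationError("clinical table must name at least subject id and group")
    norm = {"epd": "ePD", "mpd": "mPD"}
    groups = df["group"].astype(str).str.strip()
    unknown = set(groups.str.lower()) - set(norm)
    if unknown:
        raise ValidationError(f"unknown group labels {sorted(unknown)}")
    df["group"] = groups.str.lower().map(norm)
    for col in df.columns:
        if col in ("subject", "group"):
            continue
        raw = df[col]
        parsed = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"unparseable numeric cell at row {row}, column {col!r}")
        df[col] = parsed
    return ClinicalTable(frame=df)


def write_clinical_table(path: str | Path, table: ClinicalTable) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# ROI configuration
# ---------------------------------------------------------------------------

def load_roi_config(path: str | Path, montage: Montage) -> ROIConfig:
    """Load ROI membership from YAML/JSON, resolving sensitivity matrices.

    The file lists ROI entries with explicit member channel ids (or
    source-detector pairs) and/or a sensitivity matrix; in the latter case
    membership is resolved by thresholding at ``threshold`` (default 0.20, the
    fraction of ROI signal a channel must collect).
    """
    from .roi import select_roi_channels_by_sensitivity

    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    rois_spec = cfg.get("rois", [])
    valid_channels = set(montage.channel_ids)
    pair_to_channel = {(sid, did): cid for cid, sid, did, _ in montage.channels}

    sens = None
    if "sensitivity" in cfg:
        s = cfg["sensitivity"]
        sens = pd.DataFrame(
            np.asarray(s["matrix"], dtype=float),
            index=list(s["rois"]), columns=[int(c) for c in s["channels"]],
        )
        unknown = set(sens.columns) - valid_channels
        if unknown:
            raise ConfigError(f"sensitivity references unknown channel ids {sorted(unknown)}")
    threshold = float(cfg.get("threshold", 0.20))
    sens_members = (
        select_roi_channels_by_sensitivity(sens, threshold) if sens is not None else {}
    )

    entries: list[tuple[str, str, str, list[int]]] = []
    seen: set[str] = set()
    for spec in rois_spec:
        label = str(spec["label"])
        if label in seen:
            raise ConfigError(f"duplicate ROI label {label!r}")
        seen.add(label)
        hemi = spec.get("hemisphere") or (label.split("-")[0] if "-" in label else "L")
        area = str(spec.get("area", ""))
        chans: list[int] = []
        for item in spec.get("channels", []):
            if isinstance(item, (list, tuple)):
                key = (int(item[0]), int(item[1]))
                if key not in pair_to_channel:
                    raise ConfigError(f"ROI {label}: unknown source-detector pair {key}")
                chans.append(pair_to_channel[key])
            else:
                cid = int(item)
                if cid not in valid_channels:
                    raise ConfigError(f"ROI {label}: unknown channel id {cid}")
                chans.append(cid)
        if label in sens_members:
            chans = sorted(set(chans) | set(sens_members[label]))
        entries.append((label, hemi, area, chans))
    for label, members in sens_members.items():
        if label not in seen:
            hemi = label.split("-")[0] if label.startswith(("L-", "R-")) else "L"
            entries.append((label, hemi, "", sorted(members)))
    return ROIConfig(rois=entries, sensitivity=sens)


def write_result_table(path: str | Path, df: pd.DataFrame) -> None:
    """Write a result table as TSV with stable float formatting (reproducible bytes)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
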