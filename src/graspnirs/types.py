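"""Core domain containers for continuous-wave fNIRS recordings.

A recording is a dual-wavelength intensity matrix indexed (channel, wavelength,
time) plus a :class:`Montage` describing the optode geometry and a
:class:`StimulusDesign` describing the block paradigm.  Preprocessing turns the
intensities into optical-density changes (:class:`OpticalDensity`) and then into
hemoglobin concentration changes (:class:`HbTimeSeries`), tracking the applied
steps in a provenance log whose order is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PipelineOrderError, ValidationError

#: Canonical preprocessing order; stages may be skipped but never reordered.
STEP_ORDER = (
    "intensity_to_od",
    "wavelet_motion_correct",
    "highpass",
    "pca_remove_superficial",
    "od_to_hb",
)

CONDITIONS = ("LG", "RG")


def check_step_order(provenance: list[str], step: str) -> None:
    """Raise unless *step* may legally follow the steps already applied."""
    if step in provenance:
        raise PipelineOrderError(f"step {step!r} already applied: {provenance}")
    idx = STEP_ORDER.index(step)
    for done in provenance:
        if done in STEP_ORDER and STEP_ORDER.index(done) > idx:
            raise PipelineOrderError(
                f"step {step!r} cannot follow {done!r}; required order is {STEP_ORDER}"
            )


@dataclass(frozen=True)
class Montage:
    """Optode geometry: sources, detectors and source-detector channels.

    Positions are millimetres; ``wavelengths`` is the ordered (nominal) pair of
    laser/LED wavelengths in nm.  ``channels`` rows are
    ``(channel_id, source_id, detector_id, distance_mm)``.
    """

    wavelengths: tuple[float, float]
    sources: list[tuple[int, str, np.ndarray | None]]
    detectors: list[tuple[int, str, np.ndarray | None]]
    channels: list[tuple[int, int, int, float]]

    def __post_init__(self) -> None:
        if len(self.wavelengths) != 2:
            raise ValidationError(f"exactly 2 wavelengths required, got {len(self.wavelengths)}")
        for w in self.wavelengths:
            if not 600.0 < w < 1000.0:
                raise ValidationError(f"wavelength {w} nm outside (600, 1000)")
        src = {s[0]: s for s in self.sources}
        det = {d[0]: d for d in self.detectors}
        seen: set[int] = set()
        for cid, sid, did, dist in self.channels:
            if cid in seen:
                raise ValidationError(f"duplicate channel id {cid}")
            seen.add(cid)
            if sid not in src:
                raise ValidationError(f"channel {cid} references unknown source {sid}")
            if did not in det:
                raise ValidationError(f"channel {cid} references unknown detector {did}")
            if dist <= 0:
                raise ValidationError(f"channel {cid} has nonpositive distance {dist}")
            spos, dpos = src[sid][2], det[did][2]
            if spos is not None and dpos is not None:
                geo = float(np.linalg.norm(np.asarray(spos) - np.asarray(dpos)))
                if abs(geo - dist) > 1e-6:
                    raise ValidationError(
                        f"channel {cid}: stored distance {dist} != geometric {geo}"
                    )

    @property
    def channel_ids(self) -> list[int]:
        return [c[0] for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def distances(self) -> np.ndarray:
        return np.array([c[3] for c in self.channels], dtype=float)


@dataclass(frozen=True)
class StimulusDesign:
    """Ordered block-design events ``(condition, onset_s, duration_s)``."""

    events: list[tuple[str, float, float]]
    total_duration: float

    def __post_init__(self) -> None:
        last_onset = -np.inf
        ends: dict[str, float] = {}
        for cond, onset, dur in self.events:
            if cond not in CONDITIONS:
                raise ValidationError(f"unknown condition {cond!r}")
            if dur <= 0:
                raise ValidationError(f"nonpositive duration {dur} at onset {onset}")
            if onset < last_onset:
                raise ValidationError("events not sorted by onset")
            last_onset = onset
            if onset < ends.get(cond, -np.inf):
                raise ValidationError(f"overlapping {cond} events at onset {onset}")
            ends[cond] = onset + dur
            if onset + dur > self.total_duration + 1e-9:
                raise ValidationError(f"event at {onset} s ends after total duration")

    def onsets(self, condition: str) -> list[tuple[float, float]]:
        return [(on, du) for c, on, du in self.events if c == condition]


@dataclass
class RawIntensity:
    """Nonnegative light intensities, shape ``(n_channels, 2, n_times)``."""

    fs: float
    data: np.ndarray
    wavelengths: tuple[float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling frequency must be > 0, got {self.fs}")
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValidationError(f"intensity must be (channels, 2, time), got {self.data.shape}")
        bad = np.argwhere(~(self.data > 0))
        if bad.size:
            c, w, t = bad[0]
            raise ValidationError(
                f"nonpositive intensity at channel index {c}, wavelength index {w}, sample {t}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]


@dataclass
class OpticalDensity:
    """Optical-density changes (natural log), shape ``(n_channels, 2, n_times)``."""

    fs: float
    data: np.ndarray
    wavelengths: tuple[float, float]
    provenance: list[str] = field(default_factory=lambda: ["intensity_to_od"])

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValidationError("sampling frequency must be > 0")
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValidationError(f"OD must be (channels, 2, time), got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("non-finite optical density")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]


@dataclass
class HbTimeSeries:
    """Hemoglobin concentration changes in µM: ``hbo`` and ``hbr``, (channels, time)."""

    fs: float
    hbo: np.ndarray
    hbr: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.fs <= 0:
            raise ValidationError("sampling frequency must be > 0")
        if self.hbo.shape != self.hbr.shape or self.hbo.ndim != 2:
            raise ValidationError("hbo and hbr must share shape (channels, time)")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValidationError("non-finite hemoglobin values")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_times(self) -> int:
        return self.hbo.shape[1]

    def chromophore(self, name: str) -> np.ndarray:
        if name == "hbo":
            return self.hbo
        if name == "hbr":
            return self.hbr
        raise ValidationError(f"unknown chromophore {name!r}")


CLINICAL_VARIABLES = ("age", "criq", "duration", "updrs", "scwe", "scwt")


@dataclass
class ClinicalTable:
    """One row per subject: id, group (ePD/mPD) and clinical covariates.

    SCW scores may be missing (NaN); other numeric fields are expected present.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"subject", "group"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns {sorted(missing)}")
        if df["subject"].duplicated().any():
            dup = df.loc[df["subject"].duplicated(), "subject"].iloc[0]
            raise ValidationError(f"duplicated subject id {dup!r}")
        if (df["group"].astype(str).str.len() == 0).any():
            raise ValidationError("empty group label")
        bad = set(df["group"]) - {"ePD", "mPD"}
        if bad:
            raise ValidationError(f"unknown group labels {sorted(bad)}")
        if "age" in df.columns and (df["age"].dropna() <= 0).any():
            raise ValidationError("nonpositive age")
        if "duration" in df.columns and (df["duration"].dropna() < 0).any():
            raise ValidationError("negative disease duration")

    def group_counts(self) -> tuple[int, int]:
        vc = self.frame["group"].value_counts()
        return int(vc.get("ePD", 0)), int(vc.get("mPD", 0))


ROI_CANONICAL_LABELS = (
    "L-SMN", "R-SMN", "L-VIS1", "R-VIS1", "L-VIS2",
    "R-VIS2", "L-PFC1", "R-PFC1", "L-PFC2", "R-PFC2",
)


@dataclass
class ROIConfig:
    """ROI membership: label -> (hemisphere, functional-area tag, channel ids)."""

    rois: list[tuple[str, str, str, list[int]]]
    sensitivity: pd.DataFrame | None = None  # ROI x channel fractions in [0, 1]

    def __post_init__(self) -> None:
        labels = [r[0] for r in self.rois]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate ROI label")
        for label, hemi, _area, _chs in self.rois:
            if hemi not in ("L", "R"):
                raise ValidationError(f"ROI {label}: hemisphere must be 'L' or 'R'")
        if self.sensitivity is not None:
            vals = self.sensitivity.to_numpy(dtype=float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValidationError("sensitivity fractions must lie in [0, 1]")

    @property
    def labels(self) -> list[str]:
        return [r[0] for r in self.rois]

    def members(self, label: str) -> list[int]:
        for lab, _h, _a, chs in self.rois:
            if lab == label:
                return list(chs)
        raise KeyError(label)

    def membership(self) -> dict[str, list[int]]:
        return {lab: list(chs) for lab, _h, _a, chs in self.rois}
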