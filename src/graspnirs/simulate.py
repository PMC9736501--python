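"""Synthetic whole-head fNIRS studies with known ground truth.

Emulates the study conditions of a block-design motor-grasping protocol in two
Parkinson's-disease groups: 10 s task / 20 s rest blocks, 10 trials per side in
seeded random order, ~1.95 Hz sampling, a 102-channel montage grouped into 10
regions of interest, canonical hemodynamic responses with group-dependent
amplitudes, serially correlated noise plus cardiac / Mayer-wave / respiratory
oscillations and slow drift, a shared superficial (scalp) component, motion
artifacts, and clinical covariates whose rank correlation with a chosen ROI
amplitude is planted through a Gaussian copula.

Everything is reproducible: identical ``(params, seed)`` give bit-identical
output, with one named substream per subject and noise component so that adding
subjects does not perturb existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .errors import ValidationError
from .extinction import extinction_matrix
from .glm import build_design
from .types import (
    ClinicalTable,
    HbTimeSeries,
    Montage,
    RawIntensity,
    ROIConfig,
    ROI_CANONICAL_LABELS,
    StimulusDesign,
)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "Study",
    "substream",
    "default_montage",
    "default_roi_config",
    "generate_design",
    "simulate_hb",
    "inject_artifacts",
    "forward_od",
    "forward_mbll",
    "generate_covariates",
    "simulate_study",
]


def substream(seed: int, *keys) -> np.random.Generator:
    """Named random substream: stable under changes elsewhere in the study."""
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


#: Group-dependent HbO2 response amplitudes in µM: ROI -> condition -> (ePD, mPD).
#: Contralateral sensorimotor responses dominate; prefrontal responses are larger
#: in the moderate group; secondary visual areas flip sign between groups.
DEFAULT_AMPLITUDES: dict[str, dict[str, tuple[float, float]]] = {
    "L-SMN": {"RG": (0.30, 0.20)},
    "R-SMN": {"LG": (0.30, 0.20)},
    "L-VIS2": {"RG": (0.05, -0.04)},
    "R-VIS2": {"RG": (0.05, -0.04)},
    "L-PFC1": {"LG": (0.05, 0.10), "RG": (0.05, 0.10)},
    "R-PFC1": {"LG": (0.05, 0.10), "RG": (0.05, 0.10)},
    "L-PFC2": {"LG": (0.05, 0.10), "RG": (0.05, 0.10)},
    "R-PFC2": {"LG": (0.05, 0.10), "RG": (0.05, 0.10)},
}

#: Clinical covariate marginals per group: (mean_ePD, sd_ePD, mean_mPD, sd_mPD,
#: n_missing).  Means/SDs derive from the printed group means and standard errors.
DEFAULT_COVARIATES: dict[str, tuple[float, float, float, float, int]] = {
    "age": (63.519, 5.967, 71.676, 6.961, 0),
    "criq": (131.385, 22.318, 122.577, 19.388, 0),
    "duration": (2.903, 2.886, 5.049, 2.394, 0),
    "updrs": (16.077, 5.634, 35.654, 12.234, 0),
    "scwe": (9.083, 11.733, 8.880, 8.504, 2),
    "scwt": (12.693, 8.700, 18.716, 15.808, 3),
}


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of the synthetic generator (defaults = protocol values)."""

    n_epd: int = 13
    n_mpd: int = 26
    n_channels: int = 102
    fs: float = 1.9531
    trials_per_condition: int = 10
    task_duration: float = 10.0
    rest_duration: float = 20.0
    lead_in: float = 10.0
    lead_out: float = 10.0
    peak_time: float = 6.0
    chromophore_ratio: float = 0.5
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    amp_subject_sd: float = 0.05
    ar_coef: float = 0.8
    ar_sd: float = 0.10
    hbr_noise_scale: float = 0.4
    cardiac: tuple[float, float] = (1.1, 0.20)
    mayer: tuple[float, float] = (0.1, 0.15)
    respiration: tuple[float, float] = (0.25, 0.10)
    drift: tuple[float, float] = (0.005, 0.20)
    #: phase random-walk step (rad/sample) of the physiological oscillations
    phase_diffusion: float = 0.15
    gain_jitter: float = 0.3
    superficial_amp: float = 0.5
    superficial_ar: float = 0.95
    loading_range: tuple[float, float] = (0.5, 1.5)
    artifact_rate_per_min: float = 1.0
    spike_od: float = 0.05
    shift_od: float = 0.02
    dpf: tuple[float, float] = (6.0, 6.0)
    baseline_intensity: float = 1.0
    wavelengths: tuple[float, float] = (760.0, 850.0)
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    target_covariate: str = "updrs"
    target_roi: str = "R-VIS2"
    target_condition: str = "RG"
    target_chromophore: str = "hbo"
    target_rho: float = 0.5
    #: pooled marginal of the designated covariate when a coupling is requested
    target_marginal: tuple[float, float] = (29.128, 14.0)
    roi_channels: dict | None = None

    def validate(self) -> None:
        if self.n_epd < 1 or self.n_mpd < 1:
            raise ValidationError("need at least one subject per group")
        if self.trials_per_condition < 1:
            raise ValidationError("trials_per_condition must be >= 1")
        for name in ("fs", "task_duration", "rest_duration"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not -1.0 < self.target_rho < 1.0:
            raise ValidationError("target_rho must lie in (-1, 1)")
        if self.artifact_rate_per_min < 0:
            raise ValidationError("artifact rate must be >= 0")
        for name in ("amp_subject_sd", "ar_sd", "superficial_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_epd + self.n_mpd

    def groups(self) -> list[str]:
        return ["ePD"] * self.n_epd + ["mPD"] * self.n_mpd

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


def default_montage(
    n_channels: int, wavelengths: tuple[float, float] = (760.0, 850.0)
) -> Montage:
    """Synthetic flat layout: one dedicated source-detector pair per channel, 30 mm apart."""
    sources, detectors, channels = [], [], []
    for k in range(n_channels):
        x = 40.0 * (k % 17)
        y = 40.0 * (k // 17)
        sources.append((k + 1, f"S{k + 1}", np.array([x, y, 0.0])))
        detectors.append((k + 1, f"D{k + 1}", np.array([x + 30.0, y, 0.0])))
        channels.append((k + 1, k + 1, k + 1, 30.0))
    return Montage(
        wavelengths=wavelengths, sources=sources, detectors=detectors, channels=channels
    )


_ROI_AREAS = {
    "SMN": "BA1-2-3-4 sensorimotor network",
    "VIS1": "BA17 primary visual",
    "VIS2": "BA18-19 secondary visual",
    "PFC1": "BA46-9 dorsolateral prefrontal",
    "PFC2": "BA45-47 ventrolateral prefrontal",
}


def default_roi_config(n_channels: int, roi_channels: dict | None = None) -> ROIConfig:
    """Assign channels to the 10 canonical ROIs in contiguous blocks.

    With ``n_channels`` not divisible by 10 the remainder channels stay outside
    every ROI (they model optodes over non-parcellated scalp).
    """
    if roi_channels is None:
        per = max(1, n_channels // len(ROI_CANONICAL_LABELS))
        roi_channels = {}
        for i, lab in enumerate(ROI_CANONICAL_LABELS):
            chans = [c for c in range(i * per + 1, (i + 1) * per + 1) if c <= n_channels]
            if chans:
                roi_channels[lab] = chans
    rois = []
    for lab, chans in roi_channels.items():
        hemi = lab.split("-")[0]
        area = _ROI_AREAS.get(lab.split("-", 1)[1], "")
        rois.append((lab, hemi, area, list(chans)))
    return ROIConfig(rois=rois)


def generate_design(params: SimulationParams, seed: int) -> StimulusDesign:
    """Randomized left/right block order; fixed 10 s task + 20 s rest timing."""
    params.validate()
    rng = substream(seed, "design")
    order = np.array(
        ["LG"] * params.trials_per_condition + ["RG"] * params.trials_per_condition
    )
    rng.shuffle(order)
    block = params.task_duration + params.rest_duration
    events = [
        (str(cond), params.lead_in + i * block, params.task_duration)
        for i, cond in enumerate(order)
    ]
    total = params.lead_in + order.size * block + params.lead_out
    return StimulusDesign(events=events, total_duration=total)


@dataclass
class GroundTruth:
    """Sidecar truth for a simulated study."""

    amplitudes: pd.DataFrame  # subject, group, channel, roi, chromophore, condition, amplitude
    noise_params: dict
    artifact_logs: dict = field(default_factory=dict)  # subject -> DataFrame
    components: dict = field(default_factory=dict)  # subject -> {name: (hbo, hbr)}
    covariate_truth: dict = field(default_factory=dict)

    def subject_amplitude(
        self, subject: str, roi_channels: list[int], chromophore: str, condition: str
    ) -> float:
        df = self.amplitudes
        sel = df[
            (df["subject"] == subject)
            & (df["channel"].isin(roi_channels))
            & (df["chromophore"] == chromophore)
            & (df["condition"] == condition)
        ]
        return float(sel["amplitude"].mean())


def _ar1(rng: np.random.Generator, n: int, coef: float, sd: float) -> np.ndarray:
    innov = rng.standard_normal(n + 200) * sd * np.sqrt(max(1.0 - coef**2, 1e-12))
    return scipy.signal.lfilter([1.0], [1.0, -coef], innov)[200:]


def _roi_of_channel(roi_config: ROIConfig) -> dict[int, str]:
    out: dict[int, str] = {}
    for lab, _h, _a, chans in roi_config.rois:
        for c in chans:
            out[c] = lab
    return out


def _simulate_one_subject(
    params: SimulationParams,
    design: StimulusDesign,
    roi_config: ROIConfig,
    group: str,
    subject: str,
    seed: int,
    store_components: bool,
) -> tuple[HbTimeSeries, pd.DataFrame, dict]:
    n = int(np.round(design.total_duration * params.fs))
    X = build_design(design, params.fs, n, peak_time=params.peak_time)
    gi = 0 if group == "ePD" else 1
    ch_roi = _roi_of_channel(roi_config)
    chan_ids = sorted({c for _l, _h, _a, chs in roi_config.rois for c in chs}) or []
    all_ids = list(range(1, params.n_channels + 1))

    # per-(ROI, condition) subject amplitude offsets, shared across member channels
    rng_amp = substream(seed, subject, "amplitude")
    offsets: dict[tuple[str, str], float] = {}
    for lab in roi_config.labels:
        for cond in ("LG", "RG"):
            offsets[(lab, cond)] = float(rng_amp.normal(0.0, params.amp_subject_sd))

    amp_rows = []
    clean_hbo = np.zeros((params.n_channels, n))
    for ci, cid in enumerate(all_ids):
        roi = ch_roi.get(cid)
        for cond in ("LG", "RG"):
            base = 0.0
            if roi is not None:
                base = params.amplitudes.get(roi, {}).get(cond, (0.0, 0.0))[gi]
            amp = base + offsets[(roi, cond)] if (roi is not None and base != 0.0) else 0.0
            if amp != 0.0 and cond in X.labels:
                clean_hbo[ci] += amp * X.column(cond)
            amp_rows.append(
                {"subject": subject, "group": group, "channel": cid,
                 "roi": roi or "", "chromophore": "hbo", "condition": cond,
                 "amplitude": amp}
            )
            amp_rows.append(
                {"subject": subject, "group": group, "channel": cid,
                 "roi": roi or "", "chromophore": "hbr", "condition": cond,
                 "amplitude": -params.chromophore_ratio * amp}
            )
    clean_hbr = -params.chromophore_ratio * clean_hbo

    t = np.arange(n) / params.fs
    rng_phase = substream(seed, subject, "phases")
    rng_gain = substream(seed, subject, "gains")
    # quasi-periodic physiology: each oscillation carries a random initial phase
    # plus a slow phase random walk (real cardiac/Mayer/respiratory rhythms
    # wander, so they decorrelate from the strictly periodic task harmonics),
    # and its own spatial gain pattern across channels
    osc_hbo = np.zeros((params.n_channels, n))
    for freq, amp in (params.cardiac, params.mayer, params.respiration, params.drift):
        phase0 = rng_phase.uniform(0.0, 2.0 * np.pi)
        walk = np.cumsum(rng_phase.standard_normal(n) * params.phase_diffusion)
        s = amp * np.sin(2.0 * np.pi * freq * t + phase0 + walk)
        g = 1.0 + params.gain_jitter * rng_gain.uniform(-1.0, 1.0, params.n_channels)
        osc_hbo += g[:, None] * s[None, :]
    rng_sup = substream(seed, subject, "superficial")
    sup = _ar1(rng_sup, n, params.superficial_ar, 1.0) * params.superficial_amp
    loadings = rng_gain.uniform(*params.loading_range, params.n_channels)

    rng_ar = substream(seed, subject, "arnoise")
    ar_hbo = np.stack(
        [_ar1(rng_ar, n, params.ar_coef, params.ar_sd) for _ in all_ids]
    )
    ar_hbr = np.stack(
        [_ar1(rng_ar, n, params.ar_coef, params.ar_sd * params.hbr_noise_scale)
         for _ in all_ids]
    )

    noise_hbo = ar_hbo + osc_hbo
    noise_hbr = ar_hbr + 0.4 * osc_hbo
    sup_hbo = loadings[:, None] * sup[None, :]
    sup_hbr = 0.4 * loadings[:, None] * sup[None, :]

    hbo = (clean_hbo + noise_hbo) + sup_hbo
    hbr = (clean_hbr + noise_hbr) + sup_hbr
    hb = HbTimeSeries(fs=params.fs, hbo=hbo, hbr=hbr, provenance=["simulated"])

    comps = {}
    if store_components:
        comps = {
            "clean": (clean_hbo, clean_hbr),
            "noise": (noise_hbo, noise_hbr),
            "superficial": (sup_hbo, sup_hbr),
        }
    return hb, pd.DataFrame(amp_rows), comps


def simulate_hb(
    params: SimulationParams,
    design: StimulusDesign,
    seed: int,
    store_components: bool = False,
) -> tuple[list[HbTimeSeries], GroundTruth]:
    """Simulate hemoglobin time series for all subjects under one shared design."""
    params.validate()
    roi_config = default_roi_config(params.n_channels, params.roi_channels)
    groups = params.groups()
    series, frames, components = [], [], {}
    for s, group in enumerate(groups):
        subject = f"sub{s + 1:03d}"
        hb, amps, comps = _simulate_one_subject(
            params, design, roi_config, group, subject, seed, store_components
        )
        series.append(hb)
        frames.append(amps)
        if comps:
            components[subject] = comps
    truth = GroundTruth(
        amplitudes=pd.concat(frames, ignore_index=True),
        noise_params={
            "ar_coef": params.ar_coef, "ar_sd": params.ar_sd,
            "superficial_amp": params.superficial_amp,
            "oscillations": {
                "cardiac": params.cardiac, "mayer": params.mayer,
                "respiration": params.respiration, "drift": params.drift,
            },
        },
        components=components,
    )
    return series, truth


def inject_artifacts(
    series: np.ndarray,
    fs: float,
    rate_per_min: float,
    spike_amplitude: float,
    shift_amplitude: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Add spike and baseline-shift motion artifacts at Poisson-distributed times.

    ``series`` has time on the last axis; with a leading channel axis the same
    artifact hits every wavelength row of the chosen channel (motion moves the
    optode, not one wavelength).  Returns the disturbed copy and an event log.
    """
    if rate_per_min < 0:
        raise ValidationError("artifact rate must be >= 0")
    out = np.array(series, dtype=float, copy=True)
    n = out.shape[-1]
    n_channels = out.shape[0] if out.ndim > 1 else 1
    minutes = n / fs / 60.0
    cols = ["sample", "time_s", "channel", "kind", "amplitude", "duration"]
    if rate_per_min == 0:
        return out, pd.DataFrame(columns=cols)
    n_events = int(rng.poisson(rate_per_min * minutes))
    rows = []
    for _ in range(n_events):
        ch = int(rng.integers(n_channels))
        t0 = int(rng.integers(n))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if rng.random() < 0.5:
            dur = int(rng.integers(1, 4))
            sl = slice(t0, min(n, t0 + dur))
            amp = sign * spike_amplitude
            kind = "spike"
        else:
            dur = n - t0
            sl = slice(t0, n)
            amp = sign * shift_amplitude
            kind = "shift"
        if out.ndim == 1:
            out[sl] += amp
        else:
            out[ch, ..., sl] += amp
        rows.append({"sample": t0, "time_s": t0 / fs, "channel": ch, "kind": kind,
                     "amplitude": amp, "duration": dur})
    return out, pd.DataFrame(rows, columns=cols)


def forward_od(
    hb: HbTimeSeries,
    montage: Montage,
    dpf: tuple[float, float] = (6.0, 6.0),
) -> np.ndarray:
    """Forward modified Beer-Lambert law: Hb (µM) -> ΔOD, shape (channels, 2, time)."""
    e = extinction_matrix(montage.wavelengths)
    d_cm = montage.distances() / 10.0
    conc = np.stack([hb.hbo, hb.hbr], axis=1) * 1e-6  # µM -> mol/L
    od = np.einsum("wx,cxt->cwt", e, conc)
    od *= d_cm[:, None, None] * np.asarray(dpf)[None, :, None]
    return od


def forward_mbll(
    hb: HbTimeSeries,
    montage: Montage,
    dpf: tuple[float, float] = (6.0, 6.0),
    baseline_intensity: float = 1.0,
    extra_od: np.ndarray | None = None,
) -> RawIntensity:
    """Emit intensities I = I0 · exp(−ΔOD), baseline-calibrated so mean_t I = I0.

    The calibration makes the emitted trace consistent with the mean-referenced
    optical-density definition used on the inverse path: a continuous-wave
    system measures concentration changes relative to the session baseline, so
    the round trip recovers the planted Hb up to its per-channel temporal mean
    (exactly zero offset when the planted signal is session-mean-centred).
    """
    od = forward_od(hb, montage, dpf)
    if extra_od is not None:
        od = od + extra_od
    atten = np.exp(-od)
    atten /= atten.mean(axis=2, keepdims=True)
    data = baseline_intensity * atten
    return RawIntensity(fs=hb.fs, data=data, wavelengths=montage.wavelengths)


def generate_covariates(
    params: SimulationParams, truth: GroundTruth, seed: int
) -> ClinicalTable:
    """Draw clinical covariates; plant the target rank correlation by copula.

    Non-designated covariates are drawn independently per group from their
    configured normal marginals.  The designated covariate is built from the
    designated ROI amplitudes' normal scores with Pearson coupling
    ``2·sin(π·ρ_target/6)``, so its population Spearman correlation with the
    amplitude equals the target; its marginal is the pooled one.
    """
    params.validate()
    df = truth.amplitudes
    subjects = list(dict.fromkeys(df["subject"]))
    groups = df.drop_duplicates("subject").set_index("subject")["group"]
    n = len(subjects)
    couple = params.target_rho != 0.0 and params.target_covariate is not None
    if couple and n < 3:
        raise ValidationError("target correlation needs at least 3 subjects")
    roi_cfg = default_roi_config(params.n_channels, params.roi_channels)
    rng = substream(seed, "covariates")
    out: dict[str, np.ndarray] = {}
    gi = np.array([0 if groups[s] == "ePD" else 1 for s in subjects])
    for name, (m_e, s_e, m_m, s_m, n_missing) in params.covariates.items():
        if couple and name == params.target_covariate:
            members = roi_cfg.members(params.target_roi)
            amps = np.array(
                [
                    truth.subject_amplitude(
                        s, members, params.target_chromophore, params.target_condition
                    )
                    for s in subjects
                ]
            )
            ranks = scipy.stats.rankdata(amps, method="average")
            z = scipy.stats.norm.ppf((ranks - 0.5) / n)
            z = z / max(z.std(), 1e-12)
            rho_p = 2.0 * np.sin(np.pi * params.target_rho / 6.0)
            zc = rho_p * z + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
            mean, sd = params.target_marginal
            vals = mean + sd * zc
        else:
            means = np.where(gi == 0, m_e, m_m)
            sds = np.where(gi == 0, s_e, s_m)
            vals = means + sds * rng.standard_normal(n)
        # physical bounds: durations cannot be negative, ages are positive
        if name == "duration":
            vals = np.maximum(vals, 0.0)
        elif name == "age":
            vals = np.maximum(vals, 18.0)
        if n_missing > 0:
            miss = rng.choice(n, size=min(n_missing, n), replace=False)
            vals = vals.astype(float)
            vals[miss] = np.nan
        out[name] = vals
    frame = pd.DataFrame({"subject": subjects, "group": [groups[s] for s in subjects], **out})
    return ClinicalTable(frame=frame)


@dataclass
class Study:
    """A complete simulated study: recordings, metadata and ground truth."""

    params: SimulationParams
    montage: Montage
    roi_config: ROIConfig
    designs: dict[str, StimulusDesign]
    raws: dict[str, RawIntensity]
    clinical: ClinicalTable
    truth: GroundTruth

    @property
    def subjects(self) -> list[str]:
        return list(self.designs)


def simulate_study(
    params: SimulationParams, seed: int, store_components: bool = False
) -> Study:
    """Generate the full study: per-subject randomized designs, dual-wavelength
    intensities with artifacts, clinical covariates and the truth sidecar."""
    params.validate()
    montage = default_montage(params.n_channels, params.wavelengths)
    roi_config = default_roi_config(params.n_channels, params.roi_channels)
    groups = params.groups()
    designs, raws, frames, components, logs = {}, {}, [], {}, {}
    for s, group in enumerate(groups):
        subject = f"sub{s + 1:03d}"
        rng_design = substream(seed, subject, "design")
        order = np.array(
            ["LG"] * params.trials_per_condition + ["RG"] * params.trials_per_condition
        )
        rng_design.shuffle(order)
        block = params.task_duration + params.rest_duration
        events = [
            (str(c), params.lead_in + i * block, params.task_duration)
            for i, c in enumerate(order)
        ]
        design = StimulusDesign(
            events=events,
            total_duration=params.lead_in + order.size * block + params.lead_out,
        )
        hb, amps, comps = _simulate_one_subject(
            params, design, roi_config, group, subject, seed, store_components
        )
        art_od = np.zeros((params.n_channels, 2, hb.n_times))
        art_od, log = inject_artifacts(
            art_od, params.fs, params.artifact_rate_per_min,
            params.spike_od, params.shift_od, substream(seed, subject, "artifacts"),
        )
        raw = forward_mbll(
            hb, montage, params.dpf, params.baseline_intensity, extra_od=art_od
        )
        designs[subject] = design
        raws[subject] = raw
        frames.append(amps)
        logs[subject] = log
        if comps:
            comps["artifact_od"] = art_od
            components[subject] = comps
    truth = GroundTruth(
        amplitudes=pd.concat(frames, ignore_index=True),
        noise_params={"ar_coef": params.ar_coef, "ar_sd": params.ar_sd},
        artifact_logs=logs,
        components=components,
        covariate_truth={
            "covariate": params.target_covariate, "roi": params.target_roi,
            "condition": params.target_condition,
            "chromophore": params.target_chromophore, "rho": params.target_rho,
        },
    )
    clinical = generate_covariates(params, truth, seed)
    return Study(
        params=params, montage=montage, roi_config=roi_config,
        designs=designs, raws=raws, clinical=clinical, truth=truth,
    )
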