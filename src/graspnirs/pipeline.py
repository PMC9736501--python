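"""End-to-end pipeline: simulate -> preprocess -> subject GLM -> group maps -> ROI-CA.

A single :class:`PipelineConfig` carries every stage parameter and one seed;
``run_all`` executes the stages in their fixed order, writes the five result
tables (clinical covariates, subject-level GLM contrasts, group-level maps,
ROI correlations, group characterization) as TSV plus a reproducibility
manifest, and is byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ValidationError
from .glm import contrast_map, fit_subject
from .group import fit_all_channels, group_activation_map, group_contrast_map
from .io import write_clinical_table, write_result_table
from .preprocess import (
    highpass,
    intensity_to_od,
    od_to_hb,
    pca_remove_superficial,
    wavelet_motion_correct,
)
from .roi import characterize_groups, roi_ca
from .simulate import SimulationParams, Study, simulate_study
from .types import HbTimeSeries

__all__ = ["PipelineConfig", "run_all", "preprocess_subject", "slsa_study", "glsa"]


@dataclass
class PipelineConfig:
    """All stage parameters for one pipeline run."""

    sim: SimulationParams = field(default_factory=SimulationParams)
    seed: int = 0
    cutoff_hz: float = 0.01
    variance_fraction: float = 0.80
    iqr_factor: float = 1.5
    dpf: tuple[float, float] = (6.0, 6.0)
    peak_time: float = 6.0
    max_ar_order: int | None = None
    alpha: float = 0.05
    sensitivity_threshold: float = 0.20
    condition_map: dict = field(default_factory=lambda: {"LG": "LG", "RG": "RG"})

    def validate(self) -> None:
        self.sim.validate()
        if not 0.0 < self.variance_fraction < 1.0:
            raise ValidationError(
                f"variance_fraction must lie in (0, 1), got {self.variance_fraction}"
            )
        if not self.iqr_factor > 0:
            raise ValidationError("iqr_factor must be > 0")
        if not 0.0 < self.cutoff_hz < self.sim.fs / 2.0:
            raise ValidationError("cutoff_hz must lie in (0, Nyquist)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0.0 < self.sensitivity_threshold <= 1.0:
            raise ValidationError("sensitivity_threshold must lie in (0, 1]")
        if self.peak_time <= 0:
            raise ValidationError("peak_time must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            for key in ("dpf", "wavelengths", "cardiac", "mayer", "respiration",
                        "drift", "loading_range", "target_marginal"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            covs = sim.get("covariates")
            if covs:
                sim["covariates"] = {k: tuple(v) for k, v in covs.items()}
            sim = SimulationParams(**sim)
        if "dpf" in d and isinstance(d["dpf"], list):
            d["dpf"] = tuple(d["dpf"])
        return cls(sim=sim, **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def preprocess_subject(raw, montage, config: PipelineConfig) -> HbTimeSeries:
    """Apply the fixed preprocessing chain to one subject's raw intensities."""
    od = intensity_to_od(raw)
    od = wavelet_motion_correct(od, iqr_factor=config.iqr_factor)
    od = highpass(od, cutoff=config.cutoff_hz)
    od = pca_remove_superficial(od, variance_fraction=config.variance_fraction)
    return od_to_hb(od, montage, dpf=config.dpf)


def slsa_study(
    study: Study,
    config: PipelineConfig,
    chromophores: tuple[str, ...] = ("hbo", "hbr"),
) -> pd.DataFrame:
    """Preprocess and fit the subject-level GLM for every subject.

    Returns the long table of task-vs-rest contrasts: one row per (subject,
    channel, chromophore, condition) with beta, se, t, p, q (BH within each
    subject's chromophore map), AR order and dof.
    """
    groups = dict(zip(study.clinical.frame["subject"], study.clinical.frame["group"]))
    frames = []
    for subject in study.subjects:
        hb = preprocess_subject(study.raws[subject], study.montage, config)
        glm = fit_subject(
            hb, study.designs[subject], peak_time=config.peak_time,
            max_ar_order=config.max_ar_order,
            channel_ids=study.montage.channel_ids,
            design_highpass=config.cutoff_hz,
            chromophores=chromophores,
        )
        for cond in ("LG", "RG"):
            cm = contrast_map(glm, cond)
            cm.insert(0, "subject", subject)
            cm.insert(1, "group", groups[subject])
            frames.append(cm)
    return pd.concat(frames, ignore_index=True)


def glsa(subject_betas: pd.DataFrame) -> pd.DataFrame:
    """Group-level maps: per-group activation and ePD-vs-mPD contrasts."""
    fits = fit_all_channels(subject_betas)
    maps = []
    for group in ("ePD", "mPD"):
        for cond in ("LG", "RG"):
            maps.append(group_activation_map(fits, group, cond))
    for cond in ("LG", "RG"):
        maps.append(group_contrast_map(fits, cond))
    return pd.concat(maps, ignore_index=True)


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and write result tables plus a manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        study = simulate_study(config.sim, config.seed)
        write_clinical_table(out / "clinical.tsv", study.clinical)

        stage = "slsa"
        betas = slsa_study(study, config)
        write_result_table(out / "subject_glm.tsv", betas)

        stage = "glsa"
        maps = glsa(betas)
        write_result_table(out / "group_maps.tsv", maps)

        stage = "roica"
        contrasts = maps[maps["map"] == "group-contrast"]
        roica = roi_ca(
            contrasts, betas, study.roi_config, study.clinical, alpha=config.alpha
        )
        write_result_table(out / "roica.tsv", roica)

        stage = "characterize"
        chars = characterize_groups(study.clinical)
        write_result_table(out / "group_characterization.tsv", chars)
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "rows": {
            "clinical": int(len(study.clinical.frame)),
            "subject_glm": int(len(betas)),
            "group_maps": int(len(maps)),
            "roica": int(len(roica)),
            "group_characterization": int(len(chars)),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
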