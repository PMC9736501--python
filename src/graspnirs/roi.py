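"""ROI analysis: channel selection, averaging, clinical correlations, group tests.

Regions of interest are channel groups mapped to cortical parcels (bilateral
sensorimotor, primary/secondary visual, dorsolateral/ventrolateral prefrontal).
The two-step ROI correlation analysis (ROI-CA) first notes, per ROI, the
channels whose early-vs-moderate group contrast is significant, then averages
each subject's task-vs-rest contrast coefficients over those channels and
correlates the averages with clinical variables by Spearman's rank correlation,
optionally partialling out age on mid-ranks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .types import ClinicalTable, CLINICAL_VARIABLES, ROIConfig
from .glm import fdr_bh

__all__ = [
    "select_roi_channels_by_sensitivity",
    "roi_average",
    "spearman",
    "partial_spearman",
    "roi_ca",
    "characterize_groups",
]


def select_roi_channels_by_sensitivity(
    sensitivity: pd.DataFrame, threshold: float = 0.20
) -> dict[str, list[int]]:
    """Channels collecting at least ``threshold`` of an ROI's signal belong to it.

    ``sensitivity`` is an ROI-by-channel frame of fractions in [0, 1]; the
    threshold is inclusive and a channel may belong to several ROIs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    vals = sensitivity.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValidationError("sensitivity fractions must lie in [0, 1]")
    out: dict[str, list[int]] = {}
    for roi in sensitivity.index:
        row = sensitivity.loc[roi]
        out[str(roi)] = [int(c) for c in sensitivity.columns if row[c] >= threshold]
    return out


def roi_average(
    values: dict[int, float] | pd.Series, membership: dict[str, list[int]]
) -> pd.DataFrame:
    """Unweighted arithmetic mean of per-channel values over each ROI's members.

    ROIs with no members present in ``values`` are omitted with a warning.
    """
    if isinstance(values, dict):
        values = pd.Series(values)
    rows = []
    for roi, members in membership.items():
        present = [c for c in members if c in values.index]
        if not present:
            warnings.warn(f"ROI {roi} has no member channels with values; omitted")
            continue
        rows.append({"roi": roi, "mean": float(values.loc[present].mean()),
                     "n_channels": len(present)})
    return pd.DataFrame(rows, columns=["roi", "mean", "n_channels"])


def _midranks(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation: Pearson on mid-ranks, t-approximate p (n−2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 complete pairs, got {n}")
    rx, ry = _midranks(x), _midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero rank variance; Spearman coefficient undefined")
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, float(2.0 * scipy.stats.t.sf(abs(t), n - 2))


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """Rank partial correlation of x and y given one covariate.

    All three variables are mid-rank transformed; the first-order partial
    formula is applied to the rank correlations and the two-sided p uses a t
    approximation at n − 3 dof.  A covariate with zero rank variance falls
    back to the plain Spearman coefficient with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[ok], y[ok], c[ok]
    n = x.size
    if n < 4:
        raise ValidationError(f"need at least 4 complete triples, got {n}")
    if np.ptp(_midranks(c)) == 0:
        warnings.warn("covariate has zero rank variance; returning plain Spearman")
        return spearman(x, y)
    rx, ry, rc = _midranks(x), _midranks(y), _midranks(c)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero rank variance; partial Spearman undefined")
        return float("nan"), float("nan")
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xc = np.corrcoef(rx, rc)[0, 1]
    r_yc = np.corrcoef(ry, rc)[0, 1]
    if min(1.0 - r_xc**2, 1.0 - r_yc**2) <= 1e-12:
        # covariate carries (almost) all the rank information of x or y
        warnings.warn("degenerate rank geometry; partial Spearman undefined")
        return float("nan"), float("nan")
    denom = np.sqrt((1.0 - r_xc**2) * (1.0 - r_yc**2))
    rho = float(np.clip((r_xy - r_xc * r_yc) / denom, -1.0, 1.0))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 3) / (1.0 - rho * rho))
    return rho, float(2.0 * scipy.stats.t.sf(abs(t), n - 3))


def roi_ca(
    contrast_maps: pd.DataFrame,
    subject_betas: pd.DataFrame,
    roi_config: ROIConfig,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    variables: tuple[str, ...] = CLINICAL_VARIABLES,
) -> pd.DataFrame:
    """Two-step ROI-based correlation analysis against clinical variables.

    Step 1: per (chromophore, condition), select channels with uncorrected
    p < alpha in the early-vs-moderate group contrast map, intersected with
    each ROI's membership.  Step 2: average each subject's task-vs-rest
    contrast betas over the selected channels.  Step 3: Spearman correlation
    (and its age-partialled companion) between the per-subject ROI averages and
    each clinical variable, pairwise-complete over missing values, pooling both
    groups.  ROIs with no selected channels are skipped; coefficients with
    fewer than 3 complete pairs are omitted with a warning.
    """
    clin = clinical.frame.set_index("subject")
    membership = roi_config.membership()
    rows = []
    for (chrom, cond), cmap in contrast_maps.groupby(["chromophore", "condition"]):
        significant = set(cmap.loc[cmap["p"] < alpha, "channel"].astype(int))
        betas = subject_betas[
            (subject_betas["chromophore"] == chrom)
            & (subject_betas["condition"] == cond)
        ]
        for roi, members in membership.items():
            selected = sorted(set(members) & significant)
            if not selected:
                continue
            sub = betas[betas["channel"].isin(selected)]
            avg = sub.groupby("subject")["beta"].mean()
            for var in variables:
                if var not in clin.columns:
                    continue
                joined = pd.concat([avg.rename("roi_beta"), clin[var]], axis=1).dropna()
                if len(joined) < 3:
                    warnings.warn(f"ROI {roi} / {var}: fewer than 3 complete pairs")
                    continue
                rho, p = spearman(joined["roi_beta"].to_numpy(), joined[var].to_numpy())
                if var != "age" and "age" in clin.columns:
                    tri = pd.concat(
                        [avg.rename("roi_beta"), clin[var], clin["age"]], axis=1
                    ).dropna()
                    if len(tri) >= 4:
                        prho, pp = partial_spearman(
                            tri["roi_beta"].to_numpy(), tri[var].to_numpy(),
                            tri["age"].to_numpy(),
                        )
                    else:
                        prho, pp = np.nan, np.nan
                else:
                    prho, pp = np.nan, np.nan
                rows.append({
                    "roi": roi, "chromophore": chrom, "condition": cond,
                    "variable": var, "rho": rho, "p": p,
                    "partial_rho": prho, "partial_p": pp,
                    "n": len(joined), "n_channels": len(selected),
                })
    out = pd.DataFrame(
        rows, columns=["roi", "chromophore", "condition", "variable", "rho", "p",
                       "partial_rho", "partial_p", "n", "n_channels"],
    )
    if len(out):
        # transparency companion: BH adjustment across the whole correlation grid
        out["q"] = fdr_bh(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def characterize_groups(
    clinical: ClinicalTable, variables: tuple[str, ...] = CLINICAL_VARIABLES
) -> pd.DataFrame:
    """Compare ePD vs mPD on each clinical variable.

    Normality of the pooled sample is gated by Shapiro-Wilk at p >= 0.05; the
    comparison is then an equal-variance two-sample t-test, otherwise a
    two-sided Mann-Whitney U test.
    """
    df = clinical.frame
    e = df[df["group"] == "ePD"]
    m = df[df["group"] == "mPD"]
    if len(e) < 3 or len(m) < 3:
        raise ValidationError("both groups need at least 3 subjects")
    rows = []
    for var in variables:
        if var not in df.columns:
            continue
        xe = e[var].dropna().to_numpy(dtype=float)
        xm = m[var].dropna().to_numpy(dtype=float)
        pooled = np.concatenate([xe, xm])
        if pooled.size < 3 or xe.size == 0 or xm.size == 0:
            warnings.warn(f"variable {var}: not enough data; skipped")
            continue
        if np.ptp(pooled) == 0:
            sw_p = 1.0
        else:
            sw_p = float(scipy.stats.shapiro(pooled).pvalue)
        if sw_p >= 0.05:
            stat, p = scipy.stats.ttest_ind(xe, xm, equal_var=True)
            test, dof = "t", xe.size + xm.size - 2
        else:
            res = scipy.stats.mannwhitneyu(xe, xm, alternative="two-sided")
            stat, p = res.statistic, res.pvalue
            test, dof = "mannwhitneyu", np.nan
        rows.append({"variable": var, "test": test, "statistic": float(stat),
                     "dof": dof, "p": float(p), "shapiro_p": sw_p,
                     "n_epd": xe.size, "n_mpd": xm.size})
    return pd.DataFrame(rows)
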