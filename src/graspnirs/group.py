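"""Group-level statistics: per-channel linear mixed-effects activation maps.

The subject-level task-vs-rest contrast coefficients are modelled per channel
and chromophore with a no-intercept cell-means fixed effect for the four
group x condition cells (ePD:LG, ePD:RG, mPD:LG, mPD:RG) and a random intercept
per subject, fitted by REML (``beta ~ -1 + group:cond + (1|subject)``).  From
the fitted cells we derive per-group activation maps (cell vs 0) and
early-vs-moderate contrast maps (ePD cell minus mPD cell; positive t means
higher activation in the early group), with BH-FDR across channels per map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import ValidationError
from .glm import fdr_bh

__all__ = ["GroupCellFit", "fit_lmem", "fit_all_channels", "group_activation_map",
           "group_contrast_map", "CELLS"]

CELLS = ("ePD:LG", "ePD:RG", "mPD:LG", "mPD:RG")


@dataclass
class GroupCellFit:
    """Fixed-effect cell estimates for one (channel, chromophore)."""

    estimates: np.ndarray  # aligned with CELLS (NaN for absent cells)
    cov: np.ndarray
    re_var: float
    resid_var: float
    dof: int
    cells: tuple[str, ...]
    converged: bool


def fit_lmem(subject_betas: pd.DataFrame, channel: int, chromophore: str) -> GroupCellFit:
    """Fit the cell-means random-intercept model for one channel/chromophore.

    ``subject_betas`` columns: subject, group, condition, channel, chromophore,
    beta.  Raises when a present group x condition cell has no data; with one
    observation per subject the random intercept is unidentifiable and the fit
    degenerates to the corresponding fixed-effects (one-sample) inference.
    """
    df = subject_betas[
        (subject_betas["channel"] == channel)
        & (subject_betas["chromophore"] == chromophore)
    ].copy()
    if df.empty:
        raise ValidationError(f"no betas for channel {channel} / {chromophore}")
    groups_present = sorted(df["group"].unique())
    conds_present = sorted(df["condition"].unique())
    for g in groups_present:
        for c in conds_present:
            if df[(df["group"] == g) & (df["condition"] == c)].empty:
                raise ValidationError(f"group x condition cell {g}:{c} has no data")
    cells = [f"{g}:{c}" for g in groups_present for c in conds_present]
    cells = [c for c in CELLS if c in cells]
    cell_of_row = (df["group"] + ":" + df["condition"]).to_numpy()
    exog = np.column_stack([(cell_of_row == c).astype(float) for c in cells])
    y = df["beta"].to_numpy(dtype=float)
    subjects = df["subject"].to_numpy()
    n_obs, n_fixed = exog.shape
    n_subjects = len(set(subjects))
    replicated = n_obs > n_subjects
    dof = n_obs - n_fixed - (n_subjects - 1 if replicated else 0)
    if dof < 1:
        dof = max(n_obs - n_fixed, 1)

    cell_means = np.array([y[cell_of_row == c].mean() for c in cells])
    resid0 = y - exog @ cell_means
    if float(resid0 @ resid0) < 1e-24 * max(float(y @ y), 1e-30):
        # degenerate: no residual variance, estimates are exactly the cell means
        est = _align(cell_means, cells)
        return GroupCellFit(est, np.zeros((4, 4)), 0.0, 0.0, dof, tuple(cells), True)

    if not replicated:
        # one observation per subject: random intercept unidentifiable; OLS cells
        cov = np.zeros((len(cells), len(cells)))
        s2 = float(resid0 @ resid0) / max(n_obs - n_fixed, 1)
        for i, c in enumerate(cells):
            cov[i, i] = s2 / int((cell_of_row == c).sum())
        return GroupCellFit(
            _align(cell_means, cells), _align_cov(cov, cells), 0.0, s2, dof,
            tuple(cells), True,
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=subjects)
            res = model.fit(reml=True, method=["lbfgs", "bfgs"], maxiter=200)
    except (np.linalg.LinAlgError, ValueError):
        # optimizer hit a singular profile (tiny or degenerate cells):
        # fall back to per-cell one-sample inference, flagged unconverged
        cov = np.zeros((len(cells), len(cells)))
        for i, c in enumerate(cells):
            yc = y[cell_of_row == c]
            cov[i, i] = yc.var(ddof=1) / yc.size if yc.size > 1 else np.nan
        return GroupCellFit(
            _align(cell_means, cells), _align_cov(cov, cells), 0.0,
            float(resid0 @ resid0) / max(n_obs - n_fixed, 1), dof, tuple(cells),
            False,
        )
    est = np.asarray(res.fe_params, dtype=float)
    cov = np.asarray(res.cov_params())[: len(cells), : len(cells)]
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    return GroupCellFit(
        _align(est, cells), _align_cov(cov, cells), re_var, float(res.scale),
        dof, tuple(cells), bool(res.converged),
    )


def _align(values: np.ndarray, cells: list[str]) -> np.ndarray:
    out = np.full(4, np.nan)
    for v, c in zip(values, cells):
        out[CELLS.index(c)] = v
    return out


def _align_cov(cov: np.ndarray, cells: list[str]) -> np.ndarray:
    out = np.full((4, 4), np.nan)
    idx = [CELLS.index(c) for c in cells]
    for i, ii in enumerate(idx):
        for j, jj in enumerate(idx):
            out[ii, jj] = cov[i, j]
    return out


def fit_all_channels(subject_betas: pd.DataFrame) -> dict[tuple[int, str], GroupCellFit]:
    """Fit the LMEM for every (channel, chromophore) present in the beta table."""
    fits = {}
    for (channel, chromophore), _sub in subject_betas.groupby(["channel", "chromophore"]):
        fits[(int(channel), str(chromophore))] = fit_lmem(
            subject_betas, int(channel), str(chromophore)
        )
    return fits


def _cell_index(group: str, condition: str) -> int:
    key = f"{group}:{condition}"
    if key not in CELLS:
        raise ValidationError(f"unknown group/condition {key!r}")
    return CELLS.index(key)


def group_activation_map(
    fits: dict[tuple[int, str], GroupCellFit], group: str, condition: str
) -> pd.DataFrame:
    """Per-channel activation (cell vs 0) for one group and condition.

    Positive t means activation against baseline.  BH-FDR (``q``) across
    channels, separately per chromophore.
    """
    i = _cell_index(group, condition)
    rows = []
    for (channel, chrom), fit in sorted(fits.items()):
        est = fit.estimates[i]
        var = fit.cov[i, i]
        if np.isnan(est):
            raise ValidationError(f"cell {group}:{condition} absent from fit")
        t, p = _t_p(est, var, fit.dof)
        rows.append({"channel": channel, "chromophore": chrom, "map": "group-activation",
                     "group": group, "condition": condition, "estimate": est,
                     "se": np.sqrt(max(var, 0.0)), "t": t, "p": p})
    return _with_q(pd.DataFrame(rows))


def group_contrast_map(
    fits: dict[tuple[int, str], GroupCellFit], condition: str
) -> pd.DataFrame:
    """ePD-minus-mPD contrast per channel for one condition.

    Positive t encodes higher mean activation in the early (ePD) group.  Both
    the uncorrected p and the BH-FDR q are reported.
    """
    ie = _cell_index("ePD", condition)
    im = _cell_index("mPD", condition)
    rows = []
    for (channel, chrom), fit in sorted(fits.items()):
        if np.isnan(fit.estimates[ie]) or np.isnan(fit.estimates[im]):
            raise ValidationError(f"both groups required for contrast on {condition}")
        est = fit.estimates[ie] - fit.estimates[im]
        var = fit.cov[ie, ie] + fit.cov[im, im] - 2.0 * fit.cov[ie, im]
        t, p = _t_p(est, var, fit.dof)
        rows.append({"channel": channel, "chromophore": chrom, "map": "group-contrast",
                     "group": "ePD-mPD", "condition": condition, "estimate": est,
                     "se": np.sqrt(max(var, 0.0)), "t": t, "p": p})
    return _with_q(pd.DataFrame(rows))


def _t_p(est: float, var: float, dof: int) -> tuple[float, float]:
    if est == 0:
        return 0.0, 1.0
    if var <= 0:
        return float(np.sign(est) * np.inf), 0.0
    t = est / np.sqrt(var)
    return float(t), float(2.0 * scipy.stats.t.sf(abs(t), dof))


def _with_q(df: pd.DataFrame) -> pd.DataFrame:
    df["q"] = np.nan
    for chrom in df["chromophore"].unique():
        mask = df["chromophore"] == chrom
        df.loc[mask, "q"] = fdr_bh(df.loc[mask, "p"].to_numpy())
    return df
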