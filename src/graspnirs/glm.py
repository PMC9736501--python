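"""Subject-level GLM: canonical HRF design, AR-IRLS pre-whitened fit, contrasts.

The hemodynamic response to each 10 s grasping block is modelled as a boxcar
convolved with a double-gamma canonical HRF (peak at 6 s) plus its first
temporal derivative; the serially correlated errors typical of fNIRS are
handled by AR(p) pre-whitening with iteratively reweighted (Tukey bisquare)
least squares.  Task-vs-rest inference per channel and chromophore is a t-test
on the canonical-HRF coefficient, with Benjamini-Hochberg FDR across channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.signal
import scipy.stats

from .errors import ValidationError
from .types import CONDITIONS, HbTimeSeries, StimulusDesign

__all__ = [
    "canonical_hrf",
    "build_design",
    "DesignMatrix",
    "fit_ar_irls",
    "fit_subject",
    "contrast_map",
    "fdr_bh",
    "GLMEntry",
    "SubjectGLMResult",
]


def canonical_hrf(
    t: np.ndarray,
    peak_time: float = 6.0,
    undershoot_time: float = 16.0,
    ratio: float = 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Double-gamma canonical HRF sampled at times ``t`` (s), unit peak.

    ``h(t) = g(t; peak) - g(t; undershoot) / ratio`` where each lobe is a gamma
    density with mode at the named time and the given dispersion (scale).  The
    response is zero at t = 0 and normalized so its maximum over a dense grid
    is 1, making a planted amplitude directly the peak response in µM.
    """
    t = np.asarray(t, dtype=float)
    if peak_time <= 0:
        raise ValidationError(f"peak_time must be > 0, got {peak_time}")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValidationError("time grid must be nonnegative and increasing")

    def shape(tt: np.ndarray) -> np.ndarray:
        a1 = peak_time / dispersion + 1.0
        a2 = undershoot_time / dispersion + 1.0
        pos = scipy.stats.gamma.pdf(tt, a=a1, scale=dispersion)
        under = scipy.stats.gamma.pdf(tt, a=a2, scale=dispersion)
        return pos - under / ratio

    dense = np.arange(0.0, undershoot_time + 24.0, 1e-3)
    peak = float(np.max(shape(dense)))
    return shape(t) / peak


@dataclass
class DesignMatrix:
    """Time-by-regressor matrix with labels (LG, RG, dLG, dRG, const)."""

    matrix: np.ndarray
    labels: list[str]
    fs: float

    @property
    def n_times(self) -> int:
        return self.matrix.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


def _hrf_kernel(fs: float, peak_time: float) -> tuple[np.ndarray, np.ndarray]:
    tk = np.arange(0.0, 40.0, 1.0 / fs)
    h = canonical_hrf(tk, peak_time=peak_time)
    dh = np.gradient(h, 1.0 / fs)
    return h, dh


def build_design(
    design: StimulusDesign,
    fs: float,
    length: int,
    peak_time: float = 6.0,
    highpass_cutoff: float | None = None,
) -> DesignMatrix:
    """Build the GLM design matrix for a block paradigm.

    Each condition contributes a boxcar (1 during its task blocks) convolved
    with the canonical HRF, normalized to unit peak so that coefficients are in
    the units of the data, plus the same boxcar convolved with the HRF's first
    derivative (latency-jitter companion).  A constant column is always last.

    When the data have been high-pass filtered, pass ``highpass_cutoff`` so the
    condition and derivative columns receive the identical zero-phase filter;
    otherwise the regressors retain low-frequency envelope power the data no
    longer have and the coefficients are attenuated.
    """
    t_end = length / fs
    for cond, onset, dur in design.events:
        if onset + dur > t_end + 1e-9:
            raise ValidationError(
                f"{cond} event at {onset} s ends after the recording ({t_end:.2f} s)"
            )
    h, dh = _hrf_kernel(fs, peak_time)
    cols, labels = [], []
    present = [c for c in CONDITIONS if design.onsets(c)]
    for cond in present:
        box = np.zeros(length)
        for onset, dur in design.onsets(cond):
            i0 = int(np.round(onset * fs))
            i1 = min(length, int(np.round((onset + dur) * fs)))
            box[i0:i1] = 1.0
        conv = np.convolve(box, h)[:length]
        scale = np.max(np.abs(conv))
        if scale > 0:
            conv = conv / scale
        cols.append(conv)
        labels.append(cond)
    for cond in present:
        box = np.zeros(length)
        for onset, dur in design.onsets(cond):
            i0 = int(np.round(onset * fs))
            i1 = min(length, int(np.round((onset + dur) * fs)))
            box[i0:i1] = 1.0
        dconv = np.convolve(box, dh)[:length]
        scale = np.max(np.abs(dconv))
        if scale > 0:
            dconv = dconv / scale
        cols.append(dconv)
        labels.append("d" + cond)
    if highpass_cutoff is not None and cols:
        from .preprocess import _butter_highpass

        stacked = np.column_stack(cols)
        stacked = _butter_highpass(stacked.T, fs, highpass_cutoff).T
        cols = [stacked[:, i] for i in range(stacked.shape[1])]
    cols.append(np.ones(length))
    labels.append("const")
    return DesignMatrix(matrix=np.column_stack(cols), labels=labels, fs=fs)


# ---------------------------------------------------------------------------
# AR-IRLS
# ---------------------------------------------------------------------------

def _levinson(acov: np.ndarray, max_order: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Levinson-Durbin recursion: AR coefficients and innovation variance per order."""
    sigma = np.empty(max_order + 1)
    sigma[0] = acov[0]
    coefs: list[np.ndarray] = [np.empty(0)]
    a = np.empty(0)
    for p in range(1, max_order + 1):
        if sigma[p - 1] <= 0:
            sigma[p:] = sigma[p - 1]
            coefs.extend(coefs[-1] for _ in range(p, max_order + 1))
            break
        k = (acov[p] - a @ acov[1:p][::-1]) / sigma[p - 1]
        a_new = np.empty(p)
        a_new[:p - 1] = a - k * a[::-1]
        a_new[p - 1] = k
        sigma[p] = sigma[p - 1] * (1.0 - k * k)
        coefs.append(a_new)
        a = a_new
    return coefs, sigma


def _select_ar(resid: np.ndarray, max_order: int) -> np.ndarray:
    """AR coefficients chosen by BIC over orders 0..max_order (Yule-Walker)."""
    n = resid.size
    r = resid - resid.mean()
    denom = float(r @ r)
    if denom <= 0 or n <= max_order + 1:
        return np.empty(0)
    acov = np.empty(max_order + 1)
    acov[0] = denom / n
    for lag in range(1, max_order + 1):
        acov[lag] = float(r[:-lag] @ r[lag:]) / n
    coefs, sigma = _levinson(acov, max_order)
    with np.errstate(divide="ignore"):
        bic = np.where(sigma > 0, n * np.log(sigma) + np.log(n) * (np.arange(max_order + 1) + 1), np.inf)
    best = int(np.argmin(bic))
    return coefs[best]


_TUKEY_C = 4.685


def _tukey_irls(
    y: np.ndarray,
    X: np.ndarray,
    beta0: np.ndarray | None = None,
    maxiter: int = 30,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-bisquare M-estimation with MAD scale; returns (beta, covariance).

    The covariance is the standard robust 'H1' form
    ``k^2 · (Σψ(u)^2·s^2/(n−p)) / (mean ψ'(u))^2 · (X'X)^{-1}`` with the small-
    sample correction ``k = 1 + (p/n)·var(ψ')/mean(ψ')^2``.
    """
    n, p = X.shape
    if beta0 is None:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    beta = beta0
    c = _TUKEY_C
    scale = 1.0
    for _ in range(maxiter):
        resid = y - X @ beta
        scale = float(np.median(np.abs(resid))) / 0.6744897501960817
        if scale <= 0:
            break
        u = resid / scale
        a = u / c
        w = np.where(np.abs(a) <= 1.0, (1.0 - a * a) ** 2, 0.0)
        Xw = X * w[:, None]
        try:
            beta_new = scipy.linalg.solve(X.T @ Xw, Xw.T @ y, assume_a="pos")
        except scipy.linalg.LinAlgError:
            sw = np.sqrt(w)
            beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol * max(1.0, float(np.max(np.abs(beta)))):
            break
    resid = y - X @ beta
    if scale <= 0:
        return beta, np.zeros((p, p))
    u = resid / scale
    a = u / c
    inside = np.abs(a) <= 1.0
    psi = np.where(inside, u * (1.0 - a * a) ** 2, 0.0)
    psi_d = np.where(inside, (1.0 - a * a) * (1.0 - 5.0 * a * a), 0.0)
    m = float(psi_d.mean())
    if m == 0:
        return beta, np.full((p, p), np.nan)
    k = 1.0 + (p / n) * float(psi_d.var()) / m**2
    num = float((psi**2).sum()) * scale**2 / (n - p)
    cov = k**2 * (num / m**2) * np.linalg.inv(X.T @ X)
    return beta, cov


@dataclass
class GLMEntry:
    """Per (channel, chromophore) regression result."""

    beta: np.ndarray
    cov: np.ndarray
    dof: int
    labels: list[str]
    ar_order: int
    converged: bool
    n_iter: int


@dataclass
class SubjectGLMResult:
    """All per-channel, per-chromophore GLM fits for one subject."""

    entries: dict[tuple[int, str], GLMEntry] = field(default_factory=dict)

    def channels(self) -> list[int]:
        return sorted({c for c, _ in self.entries})


def fit_ar_irls(
    y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    max_ar_order: int | None = None,
    labels: list[str] | None = None,
    fs: float | None = None,
    max_iter: int = 10,
    tol: float = 1e-4,
) -> GLMEntry:
    """Fit one trace by AR(p)-prewhitened iteratively reweighted least squares.

    Alternates (i) a Tukey-bisquare robust fit on the whitened system, (ii) an
    AR(p) fit to the raw-scale residuals with p selected by BIC in
    [0, max_ar_order], and (iii) re-whitening of both sides by the AR filter,
    until the coefficient change falls below ``tol``.  The coefficient
    covariance comes from the final whitened robust fit.
    """
    if isinstance(X, DesignMatrix):
        labels = X.labels
        fs = X.fs
        Xm = X.matrix
    else:
        Xm = np.asarray(X, dtype=float)
        if labels is None:
            labels = [f"x{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    n, k = Xm.shape
    rank = np.linalg.matrix_rank(Xm)
    if rank < k:
        raise ValidationError(f"design matrix rank-deficient (rank {rank} < {k})")
    if max_ar_order is None:
        max_ar_order = int(np.round(4.0 * (fs if fs else 2.0)))
    if n <= k + max_ar_order:
        raise ValidationError("trace shorter than regressors + AR order")
    dof = n - rank

    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ beta
    yscale = float(np.sqrt(np.mean(y * y))) or 1.0
    if np.sqrt(np.mean(resid * resid)) < 1e-12 * max(yscale, 1e-30):
        # exact interpolation: nothing to whiten or reweight
        return GLMEntry(beta=beta, cov=np.zeros((k, k)), dof=dof, labels=list(labels),
                        ar_order=0, converged=True, n_iter=0)

    ar = np.empty(0)
    converged = False
    cov = np.zeros((k, k))
    it = 0
    for it in range(1, max_iter + 1):
        ar = _select_ar(resid, max_ar_order)
        f = np.concatenate(([1.0], -ar))
        yw = scipy.signal.lfilter(f, [1.0], y)
        Xw = scipy.signal.lfilter(f, [1.0], Xm, axis=0)
        beta_new, cov = _tukey_irls(yw, Xw, beta0=beta)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        resid = y - Xm @ beta
        if delta < tol * max(1.0, float(np.max(np.abs(beta)))):
            converged = True
            break
    cov = (cov + cov.T) / 2.0
    return GLMEntry(beta=beta, cov=cov, dof=dof, labels=list(labels),
                    ar_order=int(ar.size), converged=converged, n_iter=it)


def fit_subject(
    hb: HbTimeSeries,
    design: StimulusDesign,
    peak_time: float = 6.0,
    max_ar_order: int | None = None,
    channel_ids: list[int] | None = None,
    design_highpass: float | None = None,
    chromophores: tuple[str, ...] = ("hbo", "hbr"),
) -> SubjectGLMResult:
    """Run the AR-IRLS GLM on every channel and chromophore of one subject.

    ``design_highpass`` should match the cutoff the data were filtered with so
    that design and data see the same transfer function.
    """
    X = build_design(
        design, hb.fs, hb.n_times, peak_time=peak_time, highpass_cutoff=design_highpass
    )
    ids = channel_ids if channel_ids is not None else list(range(hb.n_channels))
    out = SubjectGLMResult()
    for ci, cid in enumerate(ids):
        for chrom in chromophores:
            out.entries[(cid, chrom)] = fit_ar_irls(
                hb.chromophore(chrom)[ci], X, max_ar_order=max_ar_order
            )
    return out


# ---------------------------------------------------------------------------
# Contrasts and FDR
# ---------------------------------------------------------------------------

def _contrast_t(entry: GLMEntry, condition: str) -> tuple[float, float, float, float]:
    if condition not in entry.labels:
        raise ValidationError(f"unknown condition {condition!r}; design has {entry.labels}")
    c = np.zeros(len(entry.labels))
    c[entry.labels.index(condition)] = 1.0
    est = float(c @ entry.beta)
    var = float(c @ entry.cov @ c)
    if var <= 0:
        t = 0.0 if est == 0 else np.sign(est) * np.inf
    else:
        t = est / np.sqrt(var)
    p = float(2.0 * scipy.stats.t.sf(abs(t), entry.dof)) if np.isfinite(t) else 0.0
    if est == 0:
        t, p = 0.0, 1.0
    return est, float(np.sqrt(max(var, 0.0))), float(t), p


def contrast_map(glm: SubjectGLMResult, condition: str) -> pd.DataFrame:
    """Task-vs-rest contrast per channel and chromophore for one condition.

    The contrast selects the canonical-HRF coefficient (derivative excluded);
    positive t means activation.  BH-FDR (``q``) is applied across channels
    separately within each chromophore family.
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}")
    rows = []
    for (cid, chrom), entry in sorted(glm.entries.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        est, se, t, p = _contrast_t(entry, condition)
        rows.append(
            {"channel": cid, "chromophore": chrom, "condition": condition,
             "beta": est, "se": se, "t": t, "p": p,
             "ar_order": entry.ar_order, "dof": entry.dof}
        )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    for chrom in df["chromophore"].unique():
        mask = df["chromophore"] == chrom
        df.loc[mask, "q"] = fdr_bh(df.loc[mask, "p"].to_numpy())
    return df


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
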