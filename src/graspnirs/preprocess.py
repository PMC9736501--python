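"""Preprocessing chain: intensity -> OD -> wavelet -> high-pass -> PCA -> MBLL.

The chain turns raw dual-wavelength intensities into motion-corrected,
drift-free hemoglobin concentration changes:

1. optical density (natural-log, referenced to the channel's mean intensity);
2. wavelet-domain motion-artifact suppression (Daubechies-2, IQR outlier rule);
3. zero-phase 3rd-order Butterworth high-pass at 0.01 Hz;
4. PCA removal of the smallest leading component set explaining >= 80% of
   variance across channels (shared superficial/systemic confounds);
5. modified Beer-Lambert inversion to Δ[HbO2] / Δ[HbR] in µM.

Every stage is deterministic and records itself in the object's provenance;
applying stages out of order raises :class:`PipelineOrderError`.
"""

from __future__ import annotations

import numpy as np
import pywt
import scipy.signal

from .errors import ValidationError
from .extinction import extinction_matrix
from .types import HbTimeSeries, Montage, OpticalDensity, RawIntensity, check_step_order

__all__ = [
    "intensity_to_od",
    "wavelet_motion_correct",
    "highpass",
    "pca_remove_superficial",
    "od_to_hb",
]


def intensity_to_od(raw: RawIntensity) -> OpticalDensity:
    """ΔOD(c, λ, t) = −ln( I(c, λ, t) / mean_t I(c, λ, ·) ).

    A constant trace maps to identically zero OD.  RawIntensity construction
    already rejects nonpositive samples with their index.
    """
    ref = raw.data.mean(axis=2, keepdims=True)
    od = -np.log(raw.data / ref)
    return OpticalDensity(
        fs=raw.fs, data=od, wavelengths=raw.wavelengths, provenance=["intensity_to_od"]
    )


def _wavelet_correct_trace(x: np.ndarray, wavelet: str, iqr_factor: float) -> np.ndarray:
    n = x.size
    w = pywt.Wavelet(wavelet)
    level = pywt.dwt_max_level(n, w.dec_len)
    if level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, w, mode="symmetric", level=level)
    for i in range(1, len(coeffs)):
        d = coeffs[i]
        # quartiles from very few coefficients are unstable: leave the deepest
        # (lowest-frequency) levels untouched rather than zero real signal
        if d.size < 16 or not np.isfinite(iqr_factor):
            continue
        q1, q3 = np.percentile(d, [25.0, 75.0])
        iqr = q3 - q1
        lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
        d[(d < lo) | (d > hi)] = 0.0
    return pywt.waverec(coeffs, w, mode="symmetric")[:n]


def wavelet_motion_correct(
    od: OpticalDensity, iqr_factor: float = 1.5, wavelet: str = "db2"
) -> OpticalDensity:
    """Suppress motion artifacts by zeroing outlying wavelet detail coefficients.

    Each channel/wavelength trace is decomposed to its maximum dyadic depth;
    detail coefficients outside [q1 − f·IQR, q3 + f·IQR] of their own level are
    set to zero before reconstruction.  ``iqr_factor=inf`` is the identity (no
    coefficient removed).
    """
    if not iqr_factor > 0:
        raise ValidationError(f"iqr_factor must be > 0, got {iqr_factor}")
    check_step_order(od.provenance, "wavelet_motion_correct")
    out = np.empty_like(od.data)
    for c in range(od.n_channels):
        for wi in range(2):
            out[c, wi] = _wavelet_correct_trace(od.data[c, wi], wavelet, iqr_factor)
    return OpticalDensity(
        fs=od.fs, data=out, wavelengths=od.wavelengths,
        provenance=od.provenance + ["wavelet_motion_correct"],
    )


def _butter_highpass(x: np.ndarray, fs: float, cutoff: float, order: int = 3) -> np.ndarray:
    sos = scipy.signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, x, axis=-1)


def highpass(od: OpticalDensity, cutoff: float = 0.01, order: int = 3) -> OpticalDensity:
    """Zero-phase Butterworth high-pass (forward-backward), removing DC and drift."""
    nyq = od.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ValidationError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq:.4f})")
    check_step_order(od.provenance, "highpass")
    out = _butter_highpass(od.data, od.fs, cutoff, order)
    return OpticalDensity(
        fs=od.fs, data=out, wavelengths=od.wavelengths,
        provenance=od.provenance + ["highpass"],
    )


def pca_remove_superficial(
    od: OpticalDensity, variance_fraction: float = 0.80
) -> OpticalDensity:
    """Remove the leading principal components across channels.

    Both wavelengths' channel traces are pooled into one channels-by-time
    matrix; the smallest leading set of components whose cumulative explained
    variance reaches ``variance_fraction`` is subtracted.  Rank-one data
    (identical trace everywhere) is annihilated entirely; global superficial
    and systemic time courses concentrate in the leading components, so this is
    the intended remedy for scalp interference.
    """
    if not 0.0 < variance_fraction < 1.0:
        raise ValidationError(
            f"variance_fraction must lie in (0, 1), got {variance_fraction}"
        )
    if od.n_channels < 2:
        raise ValidationError("PCA removal requires at least 2 channels")
    check_step_order(od.provenance, "pca_remove_superficial")
    c, _, t = od.data.shape
    m = od.data.reshape(2 * c, t)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        cleaned = m.copy()
    else:
        cum = np.cumsum(var) / total
        n_remove = int(np.searchsorted(cum, variance_fraction) + 1)
        n_remove = min(n_remove, s.size)
        approx = (u[:, :n_remove] * s[:n_remove]) @ vt[:n_remove]
        cleaned = m - approx
    return OpticalDensity(
        fs=od.fs, data=cleaned.reshape(c, 2, t), wavelengths=od.wavelengths,
        provenance=od.provenance + ["pca_remove_superficial"],
    )


def od_to_hb(
    od: OpticalDensity,
    montage: Montage,
    dpf: tuple[float, float] = (6.0, 6.0),
    default_distance_mm: float = 30.0,
) -> HbTimeSeries:
    """Invert the modified Beer-Lambert law to Δ[HbO2]/Δ[HbR] in µM.

    Per channel and time point solves the 2x2 system
    ΔOD(λ) = Σ_x ε_x(λ) · Δ[x] · d · DPF(λ), with ε in cm^-1/M (base-e), d the
    source-detector distance (cm) and DPF the differential pathlength factor.
    """
    if any(d <= 0 for d in dpf):
        raise ValidationError("DPF values must be > 0")
    check_step_order(od.provenance, "od_to_hb")
    e = extinction_matrix(od.wavelengths)  # (2 wavelengths, 2 chromophores)
    dists = montage.distances() if montage.n_channels == od.n_channels else None
    if dists is None:
        dists = np.full(od.n_channels, default_distance_mm)
    d_cm = dists / 10.0
    # scaled OD: od / (d * dpf) per wavelength -> solve E @ conc = rhs
    rhs = od.data / (d_cm[:, None, None] * np.asarray(dpf)[None, :, None])
    e_inv = np.linalg.inv(e)
    conc = np.einsum("xw,cwt->cxt", e_inv, rhs) * 1e6  # mol/L -> µM
    return HbTimeSeries(
        fs=od.fs, hbo=conc[:, 0, :], hbr=conc[:, 1, :],
        provenance=od.provenance + ["od_to_hb"],
    )
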