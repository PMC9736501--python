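"""Hemoglobin extinction coefficients for the modified Beer-Lambert law.

The shipped table lists base-10 molar extinction coefficients (cm^-1/M) at the
wavelengths commonly used by continuous-wave instruments.  Because this package
defines optical density with the natural logarithm, the loader converts to
base-e.  Wavelengths are matched to the nearest tabulated entry within a small
tolerance; the 2x2 system is solved elsewhere (:mod:`graspnirs.preprocess`).
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .errors import ValidationError

_LN10 = float(np.log(10.0))
_MATCH_TOL_NM = 5.0


def _load_table() -> pd.DataFrame:
    ref = importlib.resources.files("graspnirs") / "data" / "hemoglobin_extinction.csv"
    with ref.open("r") as fh:
        return pd.read_csv(
            fh, comment="#", names=["wavelength_nm", "eps_hbo2", "eps_hbr"]
        )


_TABLE = _load_table()


def extinction_matrix(wavelengths: tuple[float, float]) -> np.ndarray:
    """Return the 2x2 base-e extinction matrix E with rows per wavelength.

    ``E[i] = [eps_HbO2(lambda_i), eps_HbR(lambda_i)]`` in cm^-1/M.  Raises if a
    wavelength has no tabulated entry within 5 nm, or if the matrix is
    numerically singular (wavelengths too close to separate the chromophores).
    """
    rows = []
    for w in wavelengths:
        idx = (_TABLE["wavelength_nm"] - w).abs().idxmin()
        if abs(_TABLE.loc[idx, "wavelength_nm"] - w) > _MATCH_TOL_NM:
            raise ValidationError(f"no extinction entry within {_MATCH_TOL_NM} nm of {w} nm")
        rows.append([_TABLE.loc[idx, "eps_hbo2"], _TABLE.loc[idx, "eps_hbr"]])
    e = np.asarray(rows, dtype=float) * _LN10
    if np.linalg.cond(e) > 1e8:
        raise ValidationError(f"extinction matrix singular for wavelengths {wavelengths}")
    return e
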