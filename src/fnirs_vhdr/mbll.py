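"""Modified Beer–Lambert law (MBLL) conversions.

The MBLL relates the change in optical density at a wavelength to the changes
in oxy- and deoxyhemoglobin concentration:

    dOD(lambda) = [eps_OHb(lambda) * dOHb + eps_DHb(lambda) * dDHb]
                  * DPF(lambda) * d

with molar extinction coefficients eps (cm^-1 M^-1), the differential
pathlength factor DPF (dimensionless), and the source–detector distance d
(cm).  With two wavelengths this is a 2x2 linear system per sample, solved in
closed form in both directions.
"""

from __future__ import annotations

import numpy as np

#: Tabulated molar extinction coefficients, cm^-1 M^-1, keyed by wavelength
#: (nm) -> (eps_OHb, eps_DHb).  Values from the standard hemoglobin
#: spectra compilation used throughout continuous-wave NIRS.
EXTINCTION_CM_PER_M: dict[float, tuple[float, float]] = {
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}

DEFAULT_DPF = {760.0: 6.0, 850.0: 6.0}


def extinction_matrix(wavelengths, extinction=None) -> np.ndarray:
    """2x2 matrix with rows per wavelength and columns (OHb, DHb)."""
    table = EXTINCTION_CM_PER_M if extinction is None else extinction
    try:
        rows = [table[float(w)] for w in wavelengths]
    except KeyError as exc:
        raise ValueError(f"no extinction coefficients for wavelength {exc}") from exc
    eps = np.asarray(rows, dtype=float)
    if eps.shape != (2, 2):
        raise ValueError("exactly two wavelengths are required")
    return eps


def _dpf_vector(wavelengths, dpf) -> np.ndarray:
    if dpf is None:
        dpf = DEFAULT_DPF
    if isinstance(dpf, dict):
        return np.array([float(dpf[float(w)]) for w in wavelengths])
    arr = np.asarray(dpf, dtype=float)
    if arr.shape == ():
        return np.array([float(arr)] * 2)
    if arr.shape != (2,):
        raise ValueError("dpf must be a scalar, a pair, or a wavelength-keyed dict")
    return arr


def _check_nonsingular(eps: np.ndarray) -> float:
    det = float(np.linalg.det(eps))
    scale = float(np.abs(eps).max())
    if abs(det) <= 1e-12 * scale**2:
        raise ValueError("extinction matrix is singular; chromophores are not separable")
    return det


def mbll_forward(
    ohb: np.ndarray,
    dhb: np.ndarray,
    distances_cm,
    wavelengths=(760.0, 850.0),
    dpf=None,
    extinction=None,
) -> np.ndarray:
    """Concentration changes (n_channels, n_samples) -> dOD (n_channels, 2, n_samples)."""
    ohb = np.atleast_2d(np.asarray(ohb, dtype=float))
    dhb = np.atleast_2d(np.asarray(dhb, dtype=float))
    if ohb.shape != dhb.shape:
        raise ValueError("OHb and DHb arrays must share a shape")
    eps = extinction_matrix(wavelengths, extinction)
    _check_nonsingular(eps)
    dpf_v = _dpf_vector(wavelengths, dpf)
    d = np.broadcast_to(np.asarray(distances_cm, dtype=float), (ohb.shape[0],))
    conc = np.stack([ohb, dhb], axis=1)  # (C, 2, T)
    od = np.einsum("wk,ckt->cwt", eps, conc)
    od *= dpf_v[None, :, None]
    od *= d[:, None, None]
    return od


def mbll_inverse(
    od: np.ndarray,
    distances_cm,
    wavelengths=(760.0, 850.0),
    dpf=None,
    extinction=None,
) -> tuple[np.ndarray, np.ndarray]:
    """dOD (n_channels, 2, n_samples) -> (dOHb, dDHb), each (n_channels, n_samples).

    Solves the per-sample 2x2 system in closed form.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim == 2:
        od = od[np.newaxis, ...]
    if od.ndim != 3 or od.shape[1] != 2:
        raise ValueError("od must have shape (n_channels, 2, n_samples)")
    eps = extinction_matrix(wavelengths, extinction)
    det = _check_nonsingular(eps)
    dpf_v = _dpf_vector(wavelengths, dpf)
    d = np.broadcast_to(np.asarray(distances_cm, dtype=float), (od.shape[0],))
    if np.any(d <= 0):
        raise ValueError("source–detector distances must be positive")
    # normalize out pathlength, then apply the analytic 2x2 inverse
    y = od / (dpf_v[None, :, None] * d[:, None, None])
    a, b = eps[0]
    c, e = eps[1]
    ohb = (e * y[:, 0, :] - b * y[:, 1, :]) / det
    dhb = (-c * y[:, 0, :] + a * y[:, 1, :]) / det
    return ohb, dhb
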