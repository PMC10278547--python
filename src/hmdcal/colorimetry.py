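"""CIE 1931 colorimetry: xyY/XYZ conversions, Lab/Luv, color difference.

All conversion functions are vectorised over a trailing axis of length 3
(``(..., 3)`` arrays) and also accept plain 3-sequences.  Luminance ``Y`` is
carried in cd/m² throughout; nothing here normalises it implicitly, with the
single deliberate exception of ``strict_paper`` mode in :func:`xyY_to_XYZ`
(see below).

Two conversion conventions coexist for xyY → XYZ:

``standard``
    X = xY/y, Y = Y, Z = (1 − x − y)Y/y — the textbook identity, and the one
    whose round trip with :func:`XYZ_to_xyY` is exact.

``strict_paper``
    X = xY/y, Y = Y/100, Z = (1 − x − y)Y — an audit mode reproducing a
    published variant of the equations literally.  It differs from
    ``standard`` by a factor of 100 on Y and a factor of y on Z; it is never
    used internally by the calibration pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChromaMeasurement",
    "LabColor",
    "DegenerateColorError",
    "xyY_to_XYZ",
    "XYZ_to_xyY",
    "XYZ_to_Lab",
    "XYZ_to_Luv",
    "Lab_to_XYZ",
    "delta_E",
    "delta_E_cie76",
    "delta_E_ciede2000",
    "XYZ_to_sRGB_display",
    "D65_WHITE_XYZ",
]

# D65 white, Y normalised to 1 (x = 0.3127, y = 0.3290)
D65_WHITE_XYZ = np.array([0.3127 / 0.3290, 1.0, (1.0 - 0.3127 - 0.3290) / 0.3290])

#: CIE L*a*b* / L*u*v* linear-branch threshold, (6/29)^3
_EPS = (6.0 / 29.0) ** 3
_KAPPA = (29.0 / 3.0) ** 3


class DegenerateColorError(ValueError):
    """Raised for chromaticities/tristimulus values with no valid conversion."""


@dataclass(frozen=True)
class ChromaMeasurement:
    """One photometric reading: CIE 1931 chromaticity (x, y) and luminance Y.

    Parameters
    ----------
    x, y : float
        CIE 1931 chromaticity coordinates; ``x >= 0``, ``x + y <= 1``.
    Y : float
        Luminance in cd/m², nonnegative.
    """

    x: float
    y: float
    Y: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.x, self.y, self.Y]).all():
            raise ValueError("chromaticity/luminance must be finite")
        if self.x < 0 or self.y < 0 or self.x + self.y > 1 + 1e-9:
            raise ValueError(
                f"({self.x}, {self.y}) is outside the chromaticity triangle"
            )
        if self.Y < 0:
            raise ValueError("luminance must be nonnegative")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])

    def to_XYZ(self, mode: str = "standard") -> np.ndarray:
        return xyY_to_XYZ([self.x, self.y, self.Y], mode=mode)


@dataclass(frozen=True)
class LabColor:
    """CIE 1976 L*a*b* coordinates tied to the reference white they were
    computed under (whites must match for a ΔE to be meaningful)."""

    L: float
    a: float
    b: float
    white: tuple[float, float, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b])


def _as_triplet(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) array, got shape {a.shape}")
    return a


def xyY_to_XYZ(xyY, mode: str = "standard") -> np.ndarray:
    """Convert xyY to XYZ tristimulus values.

    Parameters
    ----------
    xyY : array-like, shape (..., 3)
        Columns are x, y chromaticity and luminance Y (cd/m²).
    mode : {"standard", "strict_paper"}
        See module docstring.

    Raises
    ------
    DegenerateColorError
        If any y <= 0 (the projection back to XYZ is undefined).
    """
    a = _as_triplet(xyY)
    x, y, Y = a[..., 0], a[..., 1], a[..., 2]
    if np.any(y <= 0):
        raise DegenerateColorError("y must be > 0 to convert xyY to XYZ")
    X = x * Y / y
    if mode == "standard":
        Z = (1.0 - x - y) * Y / y
        out = np.stack([X, Y, Z], axis=-1)
    elif mode == "strict_paper":
        out = np.stack([X, Y / 100.0, (1.0 - x - y) * Y], axis=-1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def XYZ_to_xyY(XYZ) -> np.ndarray:
    """Convert XYZ to xyY: x = X/(X+Y+Z), y = Y/(X+Y+Z), Y preserved."""
    a = _as_triplet(XYZ)
    s = a.sum(axis=-1)
    if np.any(s <= 0):
        raise DegenerateColorError("X + Y + Z must be > 0 to form chromaticity")
    return np.stack([a[..., 0] / s, a[..., 1] / s, a[..., 1]], axis=-1)


def _f_lab(t: np.ndarray) -> np.ndarray:
    return np.where(t > _EPS, np.cbrt(t), (_KAPPA * t + 16.0) / 116.0)


def _f_lab_inv(u: np.ndarray) -> np.ndarray:
    return np.where(u**3 > _EPS, u**3, (116.0 * u - 16.0) / _KAPPA)


def _check_white(white) -> np.ndarray:
    w = _as_triplet(white)
    if np.any(w <= 0):
        raise ValueError("reference white must have strictly positive XYZ")
    return w


def XYZ_to_Lab(XYZ, white) -> np.ndarray:
    """CIE 1976 L*a*b* under the given reference white (same units as XYZ)."""
    a = _as_triplet(XYZ)
    w = _check_white(white)
    fx, fy, fz = (_f_lab(a[..., i] / w[..., i]) for i in range(3))
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def Lab_to_XYZ(lab, white) -> np.ndarray:
    """Inverse of :func:`XYZ_to_Lab`."""
    la = _as_triplet(lab)
    w = _check_white(white)
    fy = (la[..., 0] + 16.0) / 116.0
    fx = fy + la[..., 1] / 500.0
    fz = fy - la[..., 2] / 200.0
    return np.stack(
        [_f_lab_inv(fx) * w[..., 0], _f_lab_inv(fy) * w[..., 1], _f_lab_inv(fz) * w[..., 2]],
        axis=-1,
    )


def XYZ_to_Luv(XYZ, white) -> np.ndarray:
    """CIE 1976 L*u*v* under the given reference white."""
    a = _as_triplet(XYZ)
    w = _check_white(white)

    def uv(t):
        d = t[..., 0] + 15.0 * t[..., 1] + 3.0 * t[..., 2]
        d = np.where(d == 0, 1.0, d)  # u', v' of black is moot; L* = 0 anyway
        return 4.0 * t[..., 0] / d, 9.0 * t[..., 1] / d

    yr = a[..., 1] / w[..., 1]
    L = np.where(yr > _EPS, 116.0 * np.cbrt(yr) - 16.0, _KAPPA * yr)
    up, vp = uv(a)
    upw, vpw = uv(w)
    return np.stack([L, 13.0 * L * (up - upw), 13.0 * L * (vp - vpw)], axis=-1)


def delta_E_cie76(lab_a, lab_b) -> np.ndarray:
    """CIE 1976 color difference: Euclidean distance in L*a*b*."""
    return np.linalg.norm(_as_triplet(lab_a) - _as_triplet(lab_b), axis=-1)


def delta_E_ciede2000(lab_a, lab_b) -> np.ndarray:
    """CIEDE2000 color difference (kL = kC = kH = 1)."""
    a1 = _as_triplet(lab_a)
    a2 = _as_triplet(lab_b)
    L1, A1, B1 = a1[..., 0], a1[..., 1], a1[..., 2]
    L2, A2, B2 = a2[..., 0], a2[..., 1], a2[..., 2]

    C1 = np.hypot(A1, B1)
    C2 = np.hypot(A2, B2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * A1
    a2p = (1.0 + G) * A2
    C1p = np.hypot(a1p, B1)
    C2p = np.hypot(a2p, B2)

    h1p = np.degrees(np.arctan2(B1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(B2, a2p)) % 360.0

    dLp = L2 - L1
    dCp = C2p - C1p

    zero_chroma = (C1p * C2p) == 0
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(zero_chroma, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(habs <= 180.0, 0.5 * hsum,
                   np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)))
    hbp = np.where(zero_chroma, hsum, hbp)

    T = (1.0
         - 0.17 * np.cos(np.radians(hbp - 30.0))
         + 0.24 * np.cos(np.radians(2.0 * hbp))
         + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
         - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0)))
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    return np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )


def delta_E(a, b, formula: str = "cie76") -> np.ndarray:
    """Color difference between L*a*b* colors.

    Accepts :class:`LabColor` instances (reference whites are then checked
    for consistency) or raw (..., 3) L*a*b* arrays.
    """
    if isinstance(a, LabColor) and isinstance(b, LabColor):
        if not np.allclose(a.white, b.white, rtol=1e-9, atol=1e-12):
            raise ValueError("ΔE requires both colors under the same reference white")
        a, b = a.as_array(), b.as_array()
    elif isinstance(a, LabColor) or isinstance(b, LabColor):
        raise ValueError("mix of LabColor and raw array: reference white unknown")
    if formula == "cie76":
        return delta_E_cie76(a, b)
    if formula == "ciede2000":
        return delta_E_ciede2000(a, b)
    raise ValueError(f"unknown ΔE formula {formula!r}")


# sRGB (IEC 61966-2-1) matrix, linear sRGB <- XYZ with D65 white at Y = 1,
# derived from the primary chromaticities so white maps to (1,1,1) exactly
def _srgb_matrix() -> np.ndarray:
    prim_xy = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])
    cols = np.stack(
        [np.array([x / y, 1.0, (1 - x - y) / y]) for x, y in prim_xy], axis=1)
    scale = np.linalg.solve(cols, D65_WHITE_XYZ)
    return np.linalg.inv(cols * scale)


_XYZ_TO_SRGB = _srgb_matrix()


def XYZ_to_sRGB_display(XYZ, white=None) -> tuple[np.ndarray, np.ndarray]:
    """Encode XYZ as display sRGB in [0, 1] for report swatches.

    The input is scaled so the session white maps to sRGB white (a simple
    XYZ-ratio adaptation — adequate for illustrative swatches, not a CAT),
    passed through the sRGB matrix and transfer curve, then clipped.

    Returns
    -------
    rgb : ndarray, shape (..., 3)
        Encoded sRGB drive values, clipped to [0, 1].
    clipped : ndarray of bool, shape (...)
        True where any component fell outside [0, 1] before clipping
        (out of gamut or above white).
    """
    a = _as_triplet(XYZ)
    if white is None:
        w = D65_WHITE_XYZ
    else:
        w = _check_white(white)
    scaled = a / w * D65_WHITE_XYZ
    lin = scaled @ _XYZ_TO_SRGB.T
    clipped = np.any((lin < -1e-9) | (lin > 1 + 1e-9), axis=-1)
    lin = np.clip(lin, 0.0, 1.0)
    enc = np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055)
    return np.clip(enc, 0.0, 1.0), clipped
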