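"""Display calibration: primary matrix, chromaticity correction, inversion.

The calibration model is

    XYZ = M · ρ(drive),

where M is a 3×3 matrix whose columns are the (linearised) primaries'
tristimulus values, fit by least squares from primary measurements, and ρ is
the per-channel tonal response (identity, power law, or clipped linear)
normalised so ρ(1) = 1.

On displays measured with rendering-engine tonemapping disabled the
predicted chromaticities spread radially outward of the measured ones; the
radial correction

    α̃(xy) = xy_w + (xy − xy_w) / (1 + B·|xy − xy_w|)

pulls predictions inward toward the device white xy_w with strength B
(default 0.01).  Its exact inverse, r = r′/(1 − B·r′) on the radial
distance, is applied when solving for the drive that realises a target.

Validation drives the 16 corners of two nested RGB cubes ([0.2, 0.8]³ and
[0.4, 0.6]³) and scores predicted against measured colors with ΔE in L*a*b*
under the session white (< 1 imperceptible, 1–2 close observation, 2–10 at
a glance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .characterization import (
    ClippedLinearResponse,
    GammaResponse,
    IdentityResponse,
    fit_clipped_linear,
    fit_gamma,
)
from .colorimetry import (
    Lab_to_XYZ,
    XYZ_to_Lab,
    XYZ_to_xyY,
    delta_E,
    xyY_to_XYZ,
)

__all__ = [
    "PrimaryMatrix",
    "DisplayCalibrator",
    "ValidationReport",
    "fit_primary_matrix",
    "predict_xyY",
    "chromaticity_correction",
    "invert_chromaticity_correction",
    "luminance_correction",
    "rgb_for_target",
    "cube_targets",
    "validate",
]

MODES = ("default", "tonemap_disabled", "selective")

#: ΔE perceptibility band edges (imperceptible / close observation / at a glance)
DELTA_E_BANDS = (1.0, 2.0, 10.0)

# Gray-code path through the cube corners from (0,0,0) to (1,1,1): adjacent
# corners differ in one axis, the all-low corner comes first and the
# all-high (white/gray point) last.
_GRAY_PATH = [(0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1),
              (0, 1, 1), (0, 1, 0), (1, 1, 0), (1, 1, 1)]


def cube_targets() -> np.ndarray:
    """The 16 nested-cube validation drives: corners of [0.2, 0.8]³ then
    [0.4, 0.6]³, Gray-code order within each cube, ending on the cube's
    achromatic corner."""
    out = []
    for lo, hi in ((0.2, 0.8), (0.4, 0.6)):
        for bits in _GRAY_PATH:
            out.append([hi if b else lo for b in bits])
    return np.array(out)


def fit_primary_matrix(drives, measured_XYZ) -> np.ndarray:
    """Least-squares fit of the 3×3 RGB→XYZ matrix M.

    Minimises Σ‖XYZᵢ − M·RGBᵢ‖² over the supplied (drive, XYZ) pairs.  With
    exactly the three primaries as input, M's columns are their XYZ.

    Raises
    ------
    ValueError
        If fewer than 3 pairs are given or the drive set is rank deficient.
    """
    D = np.atleast_2d(np.asarray(drives, dtype=float))
    X = np.atleast_2d(np.asarray(measured_XYZ, dtype=float))
    if D.shape[0] < 3 or D.shape[1] != 3 or X.shape != D.shape:
        raise ValueError("need >= 3 matching RGB/XYZ triples")
    if np.linalg.matrix_rank(D) < 3:
        raise ValueError("drive set is rank deficient; cannot fit a 3x3 matrix")
    M, *_ = np.linalg.lstsq(D, X, rcond=None)
    return M.T


class PrimaryMatrix(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`fit_primary_matrix`.

    ``fit(X, y)`` takes drive triples X (n, 3) and measured XYZ y (n, 3);
    ``transform`` maps linear drives to XYZ, ``inverse_transform`` back.
    """

    def fit(self, X, y):
        self.matrix_ = fit_primary_matrix(X, y)
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.matrix_.T

    def inverse_transform(self, XYZ):
        return np.asarray(XYZ, dtype=float) @ np.linalg.inv(self.matrix_).T


def chromaticity_correction(xy, xy_w, B: float) -> np.ndarray:
    """Radial contraction of chromaticity toward the white point.

    α̃(xy) = xy_w + (xy − xy_w)/(1 + B·|xy − xy_w|); identity at B = 0, fixed
    point at xy_w, strictly inward otherwise while preserving direction.
    """
    if B < 0:
        raise ValueError("correction strength B must be >= 0")
    xy = np.asarray(xy, dtype=float)
    xy_w = np.asarray(xy_w, dtype=float)
    d = xy - xy_w
    r = np.linalg.norm(d, axis=-1, keepdims=True)
    return xy_w + d / (1.0 + B * r)


def invert_chromaticity_correction(xy_corrected, xy_w, B: float) -> np.ndarray:
    """Exact inverse of :func:`chromaticity_correction`.

    The radial map r ↦ r/(1 + B·r) inverts in closed form to
    r′ ↦ r′/(1 − B·r′), valid whenever B·r′ < 1 (always true for corrected
    points, whose radius is below 1/B by construction).
    """
    if B < 0:
        raise ValueError("correction strength B must be >= 0")
    xy = np.asarray(xy_corrected, dtype=float)
    xy_w = np.asarray(xy_w, dtype=float)
    d = xy - xy_w
    r = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(B * r >= 1):
        raise ValueError("point outside the range of the correction (B·r >= 1)")
    return xy_w + d / (1.0 - B * r)


def luminance_correction(x, fit: ClippedLinearResponse) -> np.ndarray:
    """Clipped-linear luminance map min(x·m, t) using a fitted response."""
    return fit.predict(x)


def predict_xyY(M, drive, response=None) -> np.ndarray:
    """Forward prediction: linearise the drive, map through M, convert to xyY.

    ``response`` maps per-channel drive to relative linear intensity; a
    mapping channel-index -> estimator with a ``normalized`` method, a single
    such estimator applied to all channels, or None for identity.
    """
    d = np.asarray(drive, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("drive components must lie in [0, 1]")
    M = np.asarray(M, dtype=float)
    u = _linearise(d, response)
    XYZ = np.atleast_2d(u @ M.T)
    s = XYZ.sum(axis=-1)
    out = np.empty_like(XYZ)
    ok = s > 0
    if np.any(ok):
        out[ok] = XYZ_to_xyY(XYZ[ok])
    if np.any(~ok):
        # black: luminance 0, chromaticity pinned to the matrix white
        out[~ok] = [*XYZ_to_xyY(M @ np.ones(3))[:2], 0.0]
    return out if d.ndim > 1 else out[0]


def _linearise(d: np.ndarray, response) -> np.ndarray:
    if response is None:
        return d
    if hasattr(response, "normalized"):
        return response.normalized(d)
    u = np.empty_like(d)
    for c in range(3):
        u[..., c] = response[c].normalized(d[..., c])
    return u


def _delinearise(u: np.ndarray, response) -> np.ndarray:
    if response is None:
        return np.clip(u, 0.0, 1.0)
    if hasattr(response, "normalized_inverse"):
        return response.normalized_inverse(u)
    x = np.empty_like(u)
    for c in range(3):
        x[..., c] = response[c].normalized_inverse(u[..., c])
    return x


@dataclass(frozen=True)
class ValidationReport:
    """Per-color predicted-vs-measured ΔE plus summary statistics."""

    drives: np.ndarray
    predicted_xyY: np.ndarray
    measured_xyY: np.ndarray
    delta_e: np.ndarray
    mean_delta_e: float
    max_delta_e: float
    band_counts: dict[str, int]
    formula: str = "cie76"

    def __post_init__(self):
        if np.any(self.delta_e < 0):
            raise ValueError("ΔE cannot be negative")

    @property
    def n_colors(self) -> int:
        return int(self.delta_e.size)


def _band_counts(de: np.ndarray) -> dict[str, int]:
    b1, b2, b3 = DELTA_E_BANDS
    return {
        "<1": int(np.sum(de < b1)),
        "1-2": int(np.sum((de >= b1) & (de < b2))),
        "2-10": int(np.sum((de >= b2) & (de < b3))),
        ">10": int(np.sum(de >= b3)),
    }


def validate(predicted_xyY, measured_xyY, white_XYZ, drives=None,
             formula: str = "cie76") -> ValidationReport:
    """Score predicted against measured colors with ΔE in L*a*b*.

    Both color lists are xyY; L*a*b* is taken under ``white_XYZ`` (the
    session's measured white converted to tristimulus values).
    """
    pred = np.atleast_2d(np.asarray(predicted_xyY, dtype=float))
    meas = np.atleast_2d(np.asarray(measured_xyY, dtype=float))
    if pred.shape != meas.shape or pred.shape[0] < 1:
        raise ValueError("need >= 1 matching predicted/measured pair")
    lab_p = XYZ_to_Lab(xyY_to_XYZ(pred), white_XYZ)
    lab_m = XYZ_to_Lab(xyY_to_XYZ(meas), white_XYZ)
    de = np.atleast_1d(delta_E(lab_p, lab_m, formula=formula))
    return ValidationReport(
        drives=None if drives is None else np.asarray(drives, dtype=float),
        predicted_xyY=pred,
        measured_xyY=meas,
        delta_e=de,
        mean_delta_e=float(de.mean()),
        max_delta_e=float(de.max()),
        band_counts=_band_counts(de),
        formula=formula,
    )


class DisplayCalibrator(BaseEstimator):
    """Full calibration estimator for one measurement session.

    Parameters
    ----------
    mode : {"default", "tonemap_disabled", "selective"}
        Rendering configuration the session was measured under.  Controls
        the per-channel response model (identity / power law / clipped
        linear) and whether the radial chromaticity correction is applied.
    B : float, default 0.01
        Strength of the radial chromaticity correction; used in
        ``tonemap_disabled`` mode only.
    delta_e_formula : {"cie76", "ciede2000"}
        Formula used by :meth:`validate_on`.

    Attributes
    ----------
    matrix_ : ndarray (3, 3)
        Fitted RGB→XYZ primary matrix (columns ≙ R, G, B primaries).
    white_xyY_ : ndarray (3,)
        Measured white point (x, y, Y).
    responses_ : dict
        Per-channel fitted tonal responses, keys "R", "G", "B", "W".
    """

    def __init__(self, mode: str = "tonemap_disabled", B: float = 0.01,
                 delta_e_formula: str = "cie76"):
        self.mode = mode
        self.B = B
        self.delta_e_formula = delta_e_formula

    # -- fitting -----------------------------------------------------------

    def fit(self, session):
        """Fit matrix, white point and tonal responses from a session.

        ``session`` is a :class:`hmdcal.session.MeasurementSession` (or any
        object with the same ``primaries``, ``white`` and ``ramps``
        attributes).
        """
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.B < 0:
            raise ValueError("B must be >= 0")

        prim_xyY = np.array([
            [session.primaries[c].x, session.primaries[c].y, session.primaries[c].Y]
            for c in "RGB"
        ])
        self.white_xyY_ = np.array([session.white.x, session.white.y, session.white.Y])
        self.white_XYZ_ = xyY_to_XYZ(self.white_xyY_)

        if self._use_alpha():
            # undo the device's radial compression on the measured primaries
            # so M is the underlying mixing matrix; predictions re-apply α̃
            xy = invert_chromaticity_correction(
                prim_xyY[:, :2], self.white_xyY_[:2], self.B)
            prim_xyY = np.column_stack([xy, prim_xyY[:, 2]])
        prim_XYZ = xyY_to_XYZ(prim_xyY)
        self.matrix_ = fit_primary_matrix(np.eye(3), prim_XYZ)

        ramp_map = (session.ramp_series_all
                    if hasattr(session, "ramp_series_all") else session.ramps)
        self.responses_ = {}
        for ch, series in ramp_map.items():
            if not hasattr(series, "luminances"):
                raise TypeError("session.ramps must map channel -> RampSeries")
            if self.mode == "tonemap_disabled":
                self.responses_[ch] = fit_gamma(series)
            else:
                self.responses_[ch] = fit_clipped_linear(series)
        return self

    def _use_alpha(self) -> bool:
        return self.mode == "tonemap_disabled" and self.B > 0

    def _prediction_response(self):
        # In default mode prediction is the naive matrix map on raw drives
        # (that is the point of the default-mode failure demonstration).
        if self.mode == "default":
            return None
        return [self.responses_[c] for c in "RGB"]

    # -- forward prediction ------------------------------------------------

    def predict(self, drives) -> np.ndarray:
        """Predict measured xyY for drive triples under the fitted model."""
        self._check_fitted()
        d = np.atleast_2d(np.asarray(drives, dtype=float))
        out = predict_xyY(self.matrix_, d, self._prediction_response())
        if self._use_alpha():
            xy = chromaticity_correction(out[:, :2], self.white_xyY_[:2], self.B)
            out = np.column_stack([xy, out[:, 2]])
        return out if np.asarray(drives).ndim > 1 else out[0]

    # -- inversion ---------------------------------------------------------

    def transform(self, targets, space: str = "xyY"):
        """Drive triples realising the target colors, with gamut flags.

        Parameters
        ----------
        targets : array-like (n, 3)
            Colors in ``space``: "xyY", "lab" or "luv" is not supported for
            input — "lab" values are taken under the session white.
        space : {"xyY", "lab"}

        Returns
        -------
        drives : ndarray (n, 3) in [0, 1]
        out_of_gamut : ndarray of bool (n,)
            True where a component had to be clipped (the target is not
            exactly realisable).
        """
        self._check_fitted()
        t = np.atleast_2d(np.asarray(targets, dtype=float))
        if space == "xyY":
            xyY = t.copy()
        elif space == "lab":
            xyY = XYZ_to_xyY(Lab_to_XYZ(t, self.white_XYZ_))
        else:
            raise ValueError(f"unsupported target space {space!r}")
        if np.any(xyY[:, 1] <= 0):
            raise ValueError("target with y <= 0 cannot be realised")

        if self._use_alpha():
            xy = invert_chromaticity_correction(
                xyY[:, :2], self.white_xyY_[:2], self.B)
            xyY = np.column_stack([xy, xyY[:, 2]])
        XYZ = xyY_to_XYZ(xyY)
        u = XYZ @ np.linalg.inv(self.matrix_).T
        oog = np.any((u < -1e-9) | (u > 1 + 1e-9), axis=1)
        u = np.clip(u, 0.0, 1.0)
        drives = _delinearise(u, self._prediction_response() or IdentityResponse())
        drives = np.clip(drives, 0.0, 1.0)
        single = np.asarray(targets).ndim == 1
        return (drives[0], bool(oog[0])) if single else (drives, oog)

    # -- validation --------------------------------------------------------

    def validate_on(self, session) -> ValidationReport:
        """Predict the session's cube measurements and score them with ΔE."""
        self._check_fitted()
        drives = np.array([c.drive for c in session.cube])
        measured = np.array([[c.x, c.y, c.Y] for c in session.cube])
        predicted = self.predict(drives)
        return validate(predicted, measured, self.white_XYZ_, drives=drives,
                        formula=self.delta_e_formula)

    def _check_fitted(self):
        if not hasattr(self, "matrix_"):
            raise RuntimeError("calibrator is not fitted; call fit(session) first")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-ready representation of the fitted calibration."""
        self._check_fitted()

        def resp(r):
            if isinstance(r, GammaResponse):
                return {"type": "gamma", "gain": float(r.gain_),
                        "gamma": float(r.gamma_), "rss": float(r.rss_)}
            return {"type": "clipped_linear", "m": float(r.m_),
                    "t": None if not np.isfinite(r.t_) else float(r.t_),
                    "rss": float(r.rss_),
                    "exposure_saturated": bool(r.exposure_saturated_)}

        return {
            "mode": self.mode,
            "B": self.B,
            "matrix_row_major": [[float(v) for v in row] for row in self.matrix_],
            "white": {"x": float(self.white_xyY_[0]), "y": float(self.white_xyY_[1]),
                      "Y": float(self.white_xyY_[2])},
            "responses": {ch: resp(r) for ch, r in self.responses_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisplayCalibrator":
        cal = cls(mode=d["mode"], B=d["B"])
        cal.matrix_ = np.array(d["matrix_row_major"], dtype=float)
        w = d["white"]
        cal.white_xyY_ = np.array([w["x"], w["y"], w["Y"]])
        cal.white_XYZ_ = xyY_to_XYZ(cal.white_xyY_)
        cal.responses_ = {}
        for ch, r in d["responses"].items():
            if r["type"] == "gamma":
                g = GammaResponse()
                g.gain_, g.gamma_, g.rss_ = r["gain"], r["gamma"], r["rss"]
                cal.responses_[ch] = g
            else:
                c = ClippedLinearResponse()
                c.m_ = r["m"]
                c.t_ = np.inf if r["t"] is None else r["t"]
                c.rss_ = r["rss"]
                c.exposure_saturated_ = bool(r.get("exposure_saturated", False))
                cal.responses_[ch] = c
        return cal


def rgb_for_target(cal: DisplayCalibrator, target, space: str = "xyY"):
    """Functional wrapper around :meth:`DisplayCalibrator.transform`."""
    return cal.transform(target, space=space)
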