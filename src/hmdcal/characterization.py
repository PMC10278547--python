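"""Tonal-response characterization from drive-level ramps.

The measurement protocol drives each channel (R, G, B and the combined
white W) through ten linearly spaced levels x ∈ {0.1, …, 1.0} and records
luminance at each.  Two response models are fit:

* clipped linear, ``L(x) = min(m·x, t)`` — slope m in cd/m² per unit drive,
  saturation threshold t in cd/m².  Fitting is a deterministic breakpoint
  grid search (closed-form slope per candidate split) followed by local
  refinement, so it is exactly checkable against a brute-force oracle.
* power law, ``L(x) = k·x^γ`` — fit in log–log space; describes displays
  whose gamma correction has been disabled.

Luminance additivity — whether the white ramp equals the sum of the three
channel ramps — is the paper-and-pencil diagnostic for whether a linear
(matrix) calibration can work at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .colorimetry import ChromaMeasurement

__all__ = [
    "RampSeries",
    "AdditivityResult",
    "ClippedLinearResponse",
    "GammaResponse",
    "generate_ramp_levels",
    "fit_clipped_linear",
    "fit_gamma",
    "additivity",
]


def generate_ramp_levels(n: int = 10) -> np.ndarray:
    """n linearly spaced drive levels spanning (0, 1]: {1/n, 2/n, …, 1}."""
    if n < 2:
        raise ValueError("need at least 2 ramp levels")
    return np.arange(1, n + 1) / n


@dataclass(frozen=True)
class RampSeries:
    """Drive ramp for one channel with one photometric reading per level."""

    channel: str
    levels: np.ndarray
    measurements: tuple[ChromaMeasurement, ...]

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        if np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be strictly ascending")
        if np.any(lv <= 0) or np.any(lv > 1):
            raise ValueError("levels must lie in (0, 1]")
        if len(self.measurements) != lv.size:
            raise ValueError("one measurement per level required")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "measurements", tuple(self.measurements))

    @property
    def luminances(self) -> np.ndarray:
        return np.array([m.Y for m in self.measurements])


@dataclass(frozen=True)
class AdditivityResult:
    """Per-level (L_R + L_G + L_B)/L_W ratios and their mean.

    Levels where the white luminance falls below ``floor`` are excluded from
    the mean (division blow-up on dark readings) and listed in
    ``excluded_levels``.
    """

    levels: np.ndarray
    ratios: np.ndarray
    mean_ratio: float
    excluded_levels: tuple[float, ...] = field(default_factory=tuple)


class ClippedLinearResponse(RegressorMixin, BaseEstimator):
    """Fit ``L(x) = min(m·x, t)`` to a luminance ramp.

    Parameters
    ----------
    refine : bool, default True
        After the breakpoint grid search, polish (m, t) with a bounded
        least-squares solve.  The grid search alone is already exact on
        noiseless data whose breakpoint sits between sample levels.
    saturation_margin : float, default 1e-9
        Relative slack used when deciding the no-saturation sentinel.

    Attributes
    ----------
    m_ : float
        Slope, cd/m² per unit drive.
    t_ : float
        Saturation threshold, cd/m²; ``np.inf`` when no clipping is
        detectable within the measured range.
    rss_ : float
        Residual sum of squares of the chosen fit.
    exposure_saturated_ : bool
        True for ramps flat from the very first level (the autoexposure
        signature); by convention m_ is then the minimal slope consistent
        with saturation at x₁, i.e. ``t_/x₁``.
    """

    def __init__(self, refine: bool = True, saturation_margin: float = 1e-9):
        self.refine = refine
        self.saturation_margin = saturation_margin

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        L = np.asarray(y, dtype=float).ravel()
        if x.size != L.size or x.size < 3:
            raise ValueError("need at least 3 (level, luminance) pairs")
        if np.any(x <= 0):
            raise ValueError("drive levels must be positive")
        if not np.any(L > 0):
            raise ValueError("all luminances are zero: nothing to fit")

        order = np.argsort(x)
        x, L = x[order], L[order]
        n = x.size

        best = None  # (rss, m, t, k)
        for k in range(n + 1):
            # first k points on the linear branch, rest saturated
            if k == 0:
                t = float(L.mean())
                m = t / x[0]
            else:
                m = float((x[:k] @ L[:k]) / (x[:k] @ x[:k]))
                t = float(L[k:].mean()) if k < n else np.inf
            pred = np.minimum(m * x, t)
            rss = float(((pred - L) ** 2).sum())
            if best is None or rss < best[0] - 1e-15:
                best = (rss, m, t, k)
        rss, m, t, k = best

        if self.refine and 0 < k < n:
            sol = least_squares(
                lambda p: np.minimum(p[0] * x, p[1]) - L,
                x0=[max(m, 1e-12), max(t, 1e-12)],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                method="trf",
            )
            rss_ref = float((sol.fun**2).sum())
            if rss_ref < rss:
                m, t, rss = float(sol.x[0]), float(sol.x[1]), rss_ref

        self.exposure_saturated_ = k == 0
        # sentinel: breakpoint at/above the top measured level -> unsaturated
        if np.isfinite(t) and t >= m * x[-1] * (1 - self.saturation_margin):
            t = np.inf
        self.m_ = float(m)
        self.t_ = float(t)
        self.rss_ = float(rss)
        self.n_levels_ = int(n)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        return np.minimum(self.m_ * x, self.t_)

    @property
    def saturated_(self) -> bool:
        return np.isfinite(self.t_)

    def normalized(self, X):
        """Response scaled so full drive maps to 1: L(x)/L(1)."""
        return self.predict(X) / self.predict(1.0)

    def normalized_inverse(self, u):
        """Drive level producing relative intensity u ∈ [0, 1].

        On the saturated branch the smallest drive reaching u is returned;
        u > 1 is unreachable and maps to the clipped drive at 1.0.
        """
        u = np.asarray(u, dtype=float)
        full = self.predict(1.0)
        x = np.clip(u * full / self.m_, 0.0, 1.0)
        return x


class GammaResponse(RegressorMixin, BaseEstimator):
    """Fit ``L(x) = k·x^γ`` by least squares in log–log space.

    Attributes
    ----------
    gain_ : float
        k, the luminance at full drive, cd/m².
    gamma_ : float
        γ, the power-law exponent.
    rss_ : float
        Residual sum of squares in luminance units.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        L = np.asarray(y, dtype=float).ravel()
        if x.size != L.size or x.size < 3:
            raise ValueError("need at least 3 (level, luminance) pairs")
        if np.any(x <= 0):
            raise ValueError("drive levels must be positive")
        if np.any(L <= 0):
            raise ValueError("power-law fit requires strictly positive luminances")
        g, logk = np.polyfit(np.log(x), np.log(L), 1)
        self.gamma_ = float(g)
        self.gain_ = float(np.exp(logk))
        self.rss_ = float(((self.predict(x) - L) ** 2).sum())
        return self

    def predict(self, X):
        return self.gain_ * np.asarray(X, dtype=float) ** self.gamma_

    def normalized(self, X):
        return np.asarray(X, dtype=float) ** self.gamma_

    def normalized_inverse(self, u):
        return np.clip(np.asarray(u, dtype=float), 0.0, 1.0) ** (1.0 / self.gamma_)


class IdentityResponse(BaseEstimator):
    """Linear pass-through response (drive is already the relative intensity)."""

    def fit(self, X=None, y=None):
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float)

    def normalized(self, X):
        return np.asarray(X, dtype=float)

    def normalized_inverse(self, u):
        return np.clip(np.asarray(u, dtype=float), 0.0, 1.0)


def fit_clipped_linear(ramp: RampSeries, **kwargs) -> ClippedLinearResponse:
    """Functional wrapper: fit the clipped-linear model to a :class:`RampSeries`."""
    return ClippedLinearResponse(**kwargs).fit(ramp.levels, ramp.luminances)


def fit_gamma(ramp: RampSeries) -> GammaResponse:
    """Functional wrapper: fit the power-law model to a :class:`RampSeries`."""
    return GammaResponse().fit(ramp.levels, ramp.luminances)


def additivity(
    r: RampSeries, g: RampSeries, b: RampSeries, w: RampSeries,
    floor: float = 0.01,
) -> AdditivityResult:
    """Per-level luminance additivity ratios (L_R + L_G + L_B)/L_W.

    A mean of exactly 1 indicates an additive (linear) display; > 1 is the
    subadditive signature of a saturating tonemap acting on the brighter
    combined-white stimulus.
    """
    for other in (g, b, w):
        if other.levels.shape != r.levels.shape or not np.allclose(other.levels, r.levels):
            raise ValueError("all four ramps must share the same level grid")
    Lw = w.luminances
    s = r.luminances + g.luminances + b.luminances
    ok = Lw >= floor
    if not np.any(ok):
        raise ValueError("white luminance below floor at every level")
    ratios = np.full_like(Lw, np.nan)
    ratios[ok] = s[ok] / Lw[ok]
    return AdditivityResult(
        levels=r.levels.copy(),
        ratios=ratios,
        mean_ratio=float(ratios[ok].mean()),
        excluded_levels=tuple(r.levels[~ok]),
    )
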