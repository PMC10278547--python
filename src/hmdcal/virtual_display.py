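"""Parametric virtual HMD display: the hardware stand-in.

The simulator reproduces, at desk scale, the three rendering configurations
a real headset is measured under:

``default``
    Engine autoexposure (a memoryless saturating gain on emissive drive)
    plus a filmic tonemap.  Emissive stimuli saturate almost immediately and
    the combined white is compressed more than the single channels, so the
    white ramp is subadditive — the signature that defeats standard matrix
    calibration.

``tonemap_disabled``
    Autoexposure and tonemap both off.  Disabling the tonemapper also drops
    the engine's gamma correction, so the native panel power law (γ ≈ 2.2)
    shows through, and the measured chromaticities of mixtures sit radially
    inward of matrix predictions (modelled here as an explicit radial
    compression toward the device white with strength matching the α̃
    correction's B).

``selective``
    Tonemapping re-enabled but countered per stimulus through the corrective
    postprocess: the net stimulus response is clipped linear with the
    saturation point at (or just below) full drive.

The tonemap is a fixed rational saturating curve τ(v) = (1+c)v/(1+cv)
(c = 4): monotone, τ(0) = 0, τ(1) = 1, concave — hence subadditive — and it
is applied as a luminance-ratio scale so chromaticity is preserved while
brighter (whiter) stimuli are compressed harder.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .calibration import chromaticity_correction, cube_targets
from .characterization import generate_ramp_levels
from .colorimetry import ChromaMeasurement, XYZ_to_xyY, xyY_to_XYZ
from .session import (
    ChromaReading,
    CubeReading,
    DeviceBlock,
    MeasurementSession,
    RampPoint,
    SpectrumRecord,
)
from .spectral import SpectralDistribution, cie_1931_cmf, KM

__all__ = [
    "SpdMode",
    "PrimarySpec",
    "DisplayModel",
    "VirtualDisplay",
    "tonemap_filmic",
    "simulate_measurement",
    "simulate_spd",
    "run_protocol",
    "load_display_model",
]

#: fixed filmic constant; τ(v) = (1 + C) v / (1 + C v)
TONEMAP_C = 4.0

_SPD_GRID = np.arange(380.0, 781.0, 4.0)

Channel = Literal["R", "G", "B"]


def tonemap_filmic(v, c: float = TONEMAP_C) -> np.ndarray:
    """Rational filmic curve: monotone, f(0) = 0, f(1) = 1, saturating."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("tonemap input must be nonnegative")
    return (1.0 + c) * v / (1.0 + c * v)


class SpdMode(BaseModel):
    """One Gaussian lobe of a primary's spectral basis."""
    model_config = ConfigDict(extra="forbid")
    center_nm: float = Field(gt=300, lt=900)
    width_nm: float = Field(gt=0)
    amplitude: float = Field(default=1.0, gt=0)


class PrimarySpec(BaseModel):
    """One primary: peak luminance, spectral basis, optional explicit (x, y).

    When ``xy`` is omitted the chromaticity is derived by integrating the
    spectral basis against the 2° observer, which keeps the spectral and
    colorimetric routes exactly consistent.
    """
    model_config = ConfigDict(extra="forbid")
    peak_Y: float = Field(gt=0)
    spd: list[SpdMode]
    xy: tuple[float, float] | None = None


class DisplayModel(BaseModel):
    """Parametric virtual display + rendering-pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    name: str = "virtual"
    primaries: dict[Channel, PrimarySpec]
    gamma_native: float = Field(default=2.2, gt=0)
    response: Literal["linear", "gamma", "clipped_linear"] = "linear"
    #: per-channel relative saturation point for the clipped_linear response
    clip_caps: dict[Channel, float] = Field(
        default_factory=lambda: {"R": 1.0, "G": 1.0, "B": 1.0})
    tonemap: Literal["none", "filmic", "countered"] = "none"
    tonemap_c: float = Field(default=TONEMAP_C, gt=0)
    autoexposure: Literal["off", "saturating"] = "off"
    ae_gain: float = Field(default=10.0, gt=0)
    #: radial inward chromaticity drift toward device white (the artifact
    #: the α̃ correction compensates); active in tonemap_disabled sessions
    chromatic_compression: float = Field(default=0.01, ge=0)
    noise_luminance_rel: float = Field(default=0.0, ge=0)
    noise_chromaticity: float = Field(default=0.0, ge=0)
    seed: int = 0

    def configured(self, mode: str) -> "DisplayModel":
        """Pipeline configuration for one of the three protocol modes."""
        cfg = self.model_copy(deep=True)
        if mode == "default":
            cfg.autoexposure = "saturating"
            cfg.tonemap = "filmic"
            cfg.response = "linear"
            cfg.chromatic_compression = 0.0
        elif mode == "tonemap_disabled":
            cfg.autoexposure = "off"
            cfg.tonemap = "none"
            cfg.response = "gamma"
        elif mode == "selective":
            cfg.autoexposure = "off"
            cfg.tonemap = "countered"
            cfg.response = "clipped_linear"
            cfg.chromatic_compression = 0.0
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return cfg


class VirtualDisplay:
    """Runtime simulator for a :class:`DisplayModel`.

    Holds the seeded noise generator and the precomputed primary matrix and
    spectral bases; one instance per simulated measurement run.
    """

    def __init__(self, model: DisplayModel, rng: np.random.Generator | None = None):
        self.model = model
        self.rng = rng if rng is not None else np.random.default_rng(model.seed)

        self._bases = {}
        cmf = cie_1931_cmf(_SPD_GRID)
        xys = {}
        for ch in "RGB":
            spec = model.primaries[ch]
            raw = np.zeros_like(_SPD_GRID)
            for mode_ in spec.spd:
                raw += mode_.amplitude * np.exp(
                    -0.5 * ((_SPD_GRID - mode_.center_nm) / mode_.width_nm) ** 2)
            XYZ = KM * np.trapezoid(cmf * raw[:, None], _SPD_GRID, axis=0)
            # scale so the basis carries the primary's peak luminance
            self._bases[ch] = raw * (spec.peak_Y / XYZ[1])
            xys[ch] = (XYZ / XYZ.sum())[:2]

        cols = []
        for ch in "RGB":
            spec = model.primaries[ch]
            xy = spec.xy if spec.xy is not None else tuple(xys[ch])
            cols.append(xyY_to_XYZ([xy[0], xy[1], spec.peak_Y]))
        self.matrix = np.column_stack(cols)  # linear intensities -> XYZ
        self.white_XYZ = self.matrix @ np.ones(3)
        self.white_xy = XYZ_to_xyY(self.white_XYZ)[:2]
        self._y_weights = self.matrix[1] / self.matrix[1].sum()

    # -- pipeline stages ---------------------------------------------------

    def _pipeline(self, drive) -> np.ndarray:
        """Drive [0,1]³ -> per-channel relative linear intensities."""
        m = self.model
        v = np.asarray(drive, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError("drive components must lie in [0, 1]")
        if m.autoexposure == "saturating":
            v = np.minimum(m.ae_gain * v, 1.0)
        if m.tonemap == "filmic":
            y = float(self._y_weights @ v)
            if y > 0:
                v = v * (tonemap_filmic(y, m.tonemap_c) / y)
        # "countered": tonemap followed by its exact inverse — net identity
        if m.response == "gamma":
            v = v**m.gamma_native
        elif m.response == "clipped_linear":
            caps = np.array([m.clip_caps.get(c, 1.0) for c in "RGB"])
            v = np.minimum(v, caps)
        return v

    def measure(self, drive) -> ChromaMeasurement:
        """Simulate one spectrophotometer reading of a drive triple."""
        m = self.model
        u = self._pipeline(drive)
        XYZ = self.matrix @ u
        if XYZ.sum() <= 0:
            return ChromaMeasurement(*self.white_xy, 0.0)
        xyY = XYZ_to_xyY(XYZ)
        xy, Y = xyY[:2], xyY[2]
        if m.chromatic_compression > 0:
            xy = chromaticity_correction(xy, self.white_xy, m.chromatic_compression)
        if m.noise_luminance_rel > 0:
            Y = max(0.0, Y * (1.0 + m.noise_luminance_rel * self.rng.standard_normal()))
        if m.noise_chromaticity > 0:
            xy = xy + m.noise_chromaticity * self.rng.standard_normal(2)
            xy = np.clip(xy, 1e-6, None)
            s = xy.sum()
            if s > 1.0 - 1e-6:
                xy = xy * (1.0 - 1e-6) / s
        return ChromaMeasurement(float(xy[0]), float(xy[1]), float(Y))

    def spd(self, drive) -> SpectralDistribution:
        """Simulated spectral distribution: basis sum weighted by the
        post-pipeline linear intensities (noiseless)."""
        u = self._pipeline(drive)
        values = sum(u[i] * self._bases[ch] for i, ch in enumerate("RGB"))
        d = np.asarray(drive, dtype=float)
        lit = np.nonzero(d > 0)[0]
        channel = "W" if lit.size != 1 else "RGB"[lit[0]]
        level = float(d.max())
        return SpectralDistribution(
            wavelengths=_SPD_GRID.copy(), values=np.asarray(values),
            channel=channel, level=level if level > 0 else 1.0,
        )


def simulate_measurement(d: DisplayModel, drive) -> ChromaMeasurement:
    """One-shot reading (fresh generator seeded from the model)."""
    return VirtualDisplay(d).measure(drive)


def simulate_spd(d: DisplayModel, drive) -> SpectralDistribution:
    """One-shot spectral distribution for a drive triple."""
    return VirtualDisplay(d).spd(drive)


_CHANNEL_BASIS = {
    "R": np.array([1.0, 0.0, 0.0]),
    "G": np.array([0.0, 1.0, 0.0]),
    "B": np.array([0.0, 0.0, 1.0]),
    "W": np.array([1.0, 1.0, 1.0]),
}


def run_protocol(model: DisplayModel, mode: str,
                 seed: int | None = None, n_levels: int = 10) -> MeasurementSession:
    """Execute the full measurement protocol on the virtual display.

    Ten-level ramps for R, G, B and W; per-shade spectra; primaries and
    white; the 16 nested-cube readings.  ``seed`` overrides the model's own
    seed; with the model's noise at 0 the output is deterministic.
    """
    cfg = model.configured(mode)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    disp = VirtualDisplay(cfg, rng=rng)
    levels = generate_ramp_levels(n_levels)

    ramps = {}
    spectra = []
    for ch, basis in _CHANNEL_BASIS.items():
        pts = []
        for lv in levels:
            m = disp.measure(lv * basis)
            pts.append(RampPoint(level=float(lv), x=m.x, y=m.y, Y=m.Y))
            s = disp.spd(lv * basis)
            spectra.append(SpectrumRecord(
                channel=ch, level=float(lv),
                wavelengths_nm=[float(w) for w in s.wavelengths],
                radiance=[float(v) for v in s.values],
            ))
        ramps[ch] = pts

    primaries = {}
    for ch in "RGB":
        m = disp.measure(_CHANNEL_BASIS[ch])
        primaries[ch] = ChromaReading(x=m.x, y=m.y, Y=m.Y)
    mw = disp.measure(_CHANNEL_BASIS["W"])
    white = ChromaReading(x=mw.x, y=mw.y, Y=mw.Y)

    cube = []
    for drive in cube_targets():
        m = disp.measure(drive)
        cube.append(CubeReading(drive=tuple(float(v) for v in drive),
                                x=m.x, y=m.y, Y=m.Y))

    return MeasurementSession(
        device=DeviceBlock(name=model.name, mode=mode,
                           notes=f"virtual display, seed={model.seed if seed is None else seed}"),
        ramps=ramps,
        spectra=spectra,
        primaries=primaries,
        white=white,
        cube=cube,
    )


def load_display_model(path) -> DisplayModel:
    """Load a :class:`DisplayModel` from a YAML or JSON config file."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return DisplayModel.model_validate(data)
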