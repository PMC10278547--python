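"""Measurement-session schema and serialization.

A session is one device measured under one rendering configuration
("mode"): four ten-level drive ramps (R, G, B, W), per-shade spectral
distributions, the primaries and white point, and the nested-cube
validation readings.  The schema is pydantic-validated JSON; unknown fields
are preserved on a load/save round trip so downstream annotations survive.

CSV companions use comma separation, UTF-8 and a header row.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .characterization import RampSeries
from .colorimetry import ChromaMeasurement
from .spectral import SpectralDistribution

__all__ = [
    "SCHEMA_VERSION",
    "ChromaReading",
    "RampPoint",
    "SpectrumRecord",
    "CubeReading",
    "DeviceBlock",
    "MeasurementSession",
    "load_session",
    "save_session",
    "load_ramp_csv",
    "save_ramp_csv",
]

SCHEMA_VERSION = "1"

Mode = Literal["default", "tonemap_disabled", "selective"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="allow")


class ChromaReading(_Model):
    x: float = Field(ge=0)
    y: float = Field(ge=0)
    Y: float = Field(ge=0)

    def to_measurement(self) -> ChromaMeasurement:
        return ChromaMeasurement(self.x, self.y, self.Y)


class RampPoint(_Model):
    level: float = Field(gt=0, le=1)
    x: float
    y: float
    Y: float = Field(ge=0)


class SpectrumRecord(_Model):
    channel: Literal["R", "G", "B", "W"]
    level: float = Field(gt=0, le=1)
    wavelengths_nm: list[float]
    radiance: list[float]

    @field_validator("radiance")
    @classmethod
    def _same_length(cls, v, info):
        wl = info.data.get("wavelengths_nm")
        if wl is not None and len(v) != len(wl):
            raise ValueError("radiance and wavelengths_nm must have equal length")
        return v

    def to_distribution(self) -> SpectralDistribution:
        return SpectralDistribution(
            wavelengths=np.array(self.wavelengths_nm),
            values=np.array(self.radiance),
            channel=self.channel,
            level=self.level,
        )


class CubeReading(_Model):
    drive: tuple[float, float, float]
    x: float
    y: float
    Y: float = Field(ge=0)


class DeviceBlock(_Model):
    name: str
    mode: Mode
    eye: Literal["left", "right"] = "right"
    notes: str = ""


class MeasurementSession(_Model):
    """One device × one rendering configuration worth of measurements."""

    schema_version: str = SCHEMA_VERSION
    device: DeviceBlock
    ramps: dict[Literal["R", "G", "B", "W"], list[RampPoint]]
    spectra: list[SpectrumRecord] = Field(default_factory=list)
    primaries: dict[Literal["R", "G", "B"], ChromaReading]
    white: ChromaReading
    cube: list[CubeReading] = Field(default_factory=list)

    @field_validator("ramps")
    @classmethod
    def _four_channels(cls, v):
        missing = {"R", "G", "B", "W"} - set(v)
        if missing:
            raise ValueError(f"ramps missing channels: {sorted(missing)}")
        return v

    # -- typed views -------------------------------------------------------

    def ramp_series(self, channel: str) -> RampSeries:
        pts = sorted(self.ramps[channel], key=lambda p: p.level)
        return RampSeries(
            channel=channel,
            levels=np.array([p.level for p in pts]),
            measurements=tuple(ChromaMeasurement(p.x, p.y, p.Y) for p in pts),
        )

    @property
    def ramp_series_all(self) -> dict[str, RampSeries]:
        return {ch: self.ramp_series(ch) for ch in ("R", "G", "B", "W")}

    def spectral_distributions(self, channel: str | None = None):
        recs = self.spectra if channel is None else [
            s for s in self.spectra if s.channel == channel]
        return [s.to_distribution() for s in recs]


def save_session(session: MeasurementSession, path) -> None:
    Path(path).write_text(session.model_dump_json(indent=1))


def load_session(path) -> MeasurementSession:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    data = json.loads(p.read_text())
    version = data.get("schema_version", SCHEMA_VERSION)
    if str(version).split(".")[0] != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported session schema version {version!r} (expected {SCHEMA_VERSION})")
    return MeasurementSession.model_validate(data)


def save_ramp_csv(ramp: RampSeries, path) -> None:
    """Write a ramp as CSV with columns level,x,y,Y."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["level", "x", "y", "Y"])
        for lv, m in zip(ramp.levels, ramp.measurements):
            w.writerow([repr(float(lv)), repr(m.x), repr(m.y), repr(m.Y)])


def load_ramp_csv(path, channel: str = "W") -> RampSeries:
    """Read a level,x,y,Y CSV into a :class:`RampSeries`."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError(f"{path}: empty ramp CSV")
    rows.sort(key=lambda r: float(r["level"]))
    return RampSeries(
        channel=channel,
        levels=np.array([float(r["level"]) for r in rows]),
        measurements=tuple(
            ChromaMeasurement(float(r["x"]), float(r["y"]), float(r["Y"]))
            for r in rows
        ),
    )
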