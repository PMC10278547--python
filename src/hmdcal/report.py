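"""Report generation: characterization, constancy and validation tables.

``characterize_session`` runs every diagnostic on a measurement session and
returns a plain-dict bundle; ``render_report`` turns a bundle into a
deterministic markdown or JSON document (ratios and slopes printed to two
decimals, matching standard practice for these tables).
"""

from __future__ import annotations

import json

import numpy as np

from .calibration import DELTA_E_BANDS, DisplayCalibrator, ValidationReport
from .characterization import additivity, fit_clipped_linear, fit_gamma
from .session import MeasurementSession
from .spectral import channel_constancy, peak_wavelength

__all__ = ["characterize_session", "validation_to_dict", "render_report"]


def characterize_session(session: MeasurementSession) -> dict:
    """Run the full diagnostic battery on one session.

    Returns a bundle with per-channel clipped-linear fits (slope m, cd/m²
    per unit drive; threshold t, cd/m²; None when unsaturated), power-law
    fits (gain k, exponent γ), the mean luminance-additivity ratio, channel
    constancy scaling factors/errors, and peak wavelengths of the primaries.
    """
    ramps = session.ramp_series_all
    add = additivity(ramps["R"], ramps["G"], ramps["B"], ramps["W"])

    clipped = {}
    gamma = {}
    for ch, series in ramps.items():
        fit = fit_clipped_linear(series)
        clipped[ch] = {
            "m": fit.m_,
            "t": None if not np.isfinite(fit.t_) else fit.t_,
            "rss": fit.rss_,
            "exposure_saturated": bool(fit.exposure_saturated_),
        }
        if np.all(series.luminances > 0):
            g = fit_gamma(series)
            gamma[ch] = {"gain": g.gain_, "gamma": g.gamma_, "rss": g.rss_}

    constancy = {}
    peaks = {}
    for ch in "RGB":
        spectra = session.spectral_distributions(ch)
        if not spectra:
            continue
        res = channel_constancy(spectra)
        constancy[ch] = {
            "error": res.error,
            "scaling_factors": {f"{lv:.1f}": c for lv, c in
                                sorted(res.scaling_factors.items())},
        }
        full = [s for s in spectra if s.level == max(x.level for x in spectra)]
        peaks[ch] = peak_wavelength(full[0])

    return {
        "device": session.device.model_dump(),
        "additivity": {
            "mean_ratio": add.mean_ratio,
            "ratios": {f"{lv:.1f}": (None if np.isnan(r) else float(r))
                       for lv, r in zip(add.levels, add.ratios)},
            "excluded_levels": list(add.excluded_levels),
        },
        "clipped_linear": clipped,
        "gamma": gamma,
        "channel_constancy": constancy,
        "peak_wavelengths_nm": peaks,
    }


def validation_to_dict(rep: ValidationReport) -> dict:
    return {
        "n_colors": rep.n_colors,
        "mean_delta_e": rep.mean_delta_e,
        "max_delta_e": rep.max_delta_e,
        "band_thresholds": list(DELTA_E_BANDS),
        "band_counts": rep.band_counts,
        "formula": rep.formula,
        "per_color": [
            {
                "drive": None if rep.drives is None else [float(v) for v in rep.drives[i]],
                "predicted_xyY": [float(v) for v in rep.predicted_xyY[i]],
                "measured_xyY": [float(v) for v in rep.measured_xyY[i]],
                "delta_e": float(rep.delta_e[i]),
            }
            for i in range(rep.n_colors)
        ],
    }


def _fmt(v, nd=2):
    if v is None:
        return "—"
    return f"{v:.{nd}f}"


def _md_characterization(bundle: dict) -> list[str]:
    dev = bundle["device"]
    lines = [f"# Characterization report — {dev['name']} ({dev['mode']})", ""]

    lines += ["## Tonal response (clipped linear, L = min(m·x, t))", "",
              "| channel | m (cd/m² per drive) | t (cd/m²) | RSS | saturated from x₁ |",
              "|---|---|---|---|---|"]
    for ch in "RGBW":
        if ch not in bundle["clipped_linear"]:
            continue
        f = bundle["clipped_linear"][ch]
        lines.append(
            f"| {ch} | {_fmt(f['m'])} | {_fmt(f['t'])} | {_fmt(f['rss'], 4)} | "
            f"{'yes' if f['exposure_saturated'] else 'no'} |")

    if bundle["gamma"]:
        lines += ["", "## Tonal response (power law, L = k·x^γ)", "",
                  "| channel | k (cd/m²) | γ | RSS |", "|---|---|---|---|"]
        for ch in "RGBW":
            if ch not in bundle["gamma"]:
                continue
            g = bundle["gamma"][ch]
            lines.append(f"| {ch} | {_fmt(g['gain'])} | {_fmt(g['gamma'])} | "
                         f"{_fmt(g['rss'], 4)} |")

    add = bundle["additivity"]
    lines += ["", "## Luminance additivity", "",
              f"Mean ratio (L_R + L_G + L_B)/L_W over the ramp: "
              f"**{_fmt(add['mean_ratio'])}**", ""]
    if add["excluded_levels"]:
        lines.append(f"Levels excluded (white below floor): {add['excluded_levels']}")

    if bundle["channel_constancy"]:
        lines += ["", "## Channel constancy", "",
                  "| channel | scaling MSE |", "|---|---|"]
        for ch in "RGB":
            if ch in bundle["channel_constancy"]:
                lines.append(
                    f"| {ch} | {_fmt(bundle['channel_constancy'][ch]['error'], 4)} |")

    if bundle["peak_wavelengths_nm"]:
        lines += ["", "## Spectral peaks", "",
                  "| channel | peak wavelength (nm) |", "|---|---|"]
        for ch in "RGB":
            if ch in bundle["peak_wavelengths_nm"]:
                lines.append(f"| {ch} | {bundle['peak_wavelengths_nm'][ch]:.0f} |")
    return lines


def _md_validation(val: dict) -> list[str]:
    b1, b2, b3 = val["band_thresholds"]
    bc = val["band_counts"]
    lines = ["## Validation (ΔE, predicted vs measured)", "",
             f"Colors: {val['n_colors']} — mean ΔE {_fmt(val['mean_delta_e'])}, "
             f"max ΔE {_fmt(val['max_delta_e'])} ({val['formula']})", "",
             f"| ΔE < {b1:.0f} (imperceptible) | {b1:.0f}–{b2:.0f} (close observation) "
             f"| {b2:.0f}–{b3:.0f} (at a glance) | ≥ {b3:.0f} |",
             "|---|---|---|---|",
             f"| {bc['<1']} | {bc['1-2']} | {bc['2-10']} | {bc['>10']} |"]
    return lines


def render_report(bundle: dict, fmt: str = "markdown",
                  validation: dict | None = None) -> str:
    """Render a characterization bundle (and optional validation block)."""
    if fmt == "json":
        doc = dict(bundle)
        if validation is not None:
            doc["validation"] = validation
        return json.dumps(doc, indent=1, sort_keys=True)
    if fmt != "markdown":
        raise ValueError(f"unknown report format {fmt!r}")
    lines = _md_characterization(bundle)
    if validation is not None:
        lines += [""] + _md_validation(validation)
    return "\n".join(lines) + "\n"


def calibrate_session(session: MeasurementSession, B: float = 0.01,
                      delta_e_formula: str = "cie76") -> DisplayCalibrator:
    """Fit a :class:`DisplayCalibrator` with the session's own mode."""
    return DisplayCalibrator(
        mode=session.device.mode, B=B, delta_e_formula=delta_e_formula
    ).fit(session)
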