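"""Illustrative virtual-display presets (fictional devices).

Use :func:`hmdcal.virtual_display.load_display_model` on one of the bundled
YAML files, e.g. ``preset_path("aurora-amoled")``.
"""

from pathlib import Path

__all__ = ["preset_path", "available_presets"]

_HERE = Path(__file__).parent


def available_presets() -> list[str]:
    return sorted(p.stem for p in _HERE.glob("*.yaml"))


def preset_path(name: str) -> Path:
    p = _HERE / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(
            f"no preset {name!r}; available: {available_presets()}")
    return p
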