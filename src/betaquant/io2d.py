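"""TIFF I/O for 2D sections (autoradiography, elemental maps, RGB merges).

Each map is stored as a single-page TIFF next to a plain-text sidecar
(`<name>.txt`) carrying the pixel size and, for elemental maps, the isotope
tag — enough metadata to rebuild the in-memory object.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .exvivo import AutoradImage, ElementalMap

__all__ = ["save_section", "load_autorad", "load_elemental", "save_rgb"]


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".txt")


def _write_sidecar(path, fields: dict) -> None:
    lines = [f"{k} = {v}" for k, v in fields.items()]
    _sidecar_path(path).write_text("\n".join(lines) + "\n")


def _read_sidecar(path) -> dict:
    fields = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                fields[k.strip()] = v.strip()
    return fields


def save_section(img: AutoradImage | ElementalMap, path) -> None:
    tifffile.imwrite(str(path), np.asarray(img.intensity, dtype=np.float32))
    fields = {"pixel_size_um": img.pixel_size_um,
              "kind": "elemental" if isinstance(img, ElementalMap) else "autoradiography"}
    if isinstance(img, ElementalMap):
        fields["isotope"] = img.isotope
    _write_sidecar(path, fields)


def load_autorad(path, pixel_size_um: float | None = None) -> AutoradImage:
    data = tifffile.imread(str(path)).astype(float)
    meta = _read_sidecar(path)
    px = pixel_size_um if pixel_size_um is not None else float(meta.get("pixel_size_um", 50.0))
    return AutoradImage(data, pixel_size_um=px)


def load_elemental(path, isotope: str | None = None,
                   pixel_size_um: float | None = None) -> ElementalMap:
    data = tifffile.imread(str(path)).astype(float)
    meta = _read_sidecar(path)
    iso = isotope or meta.get("isotope")
    if iso is None:
        raise ValueError(f"{path}: isotope not given and absent from sidecar")
    px = pixel_size_um if pixel_size_um is not None else float(meta.get("pixel_size_um", 60.0))
    return ElementalMap(data, isotope=iso, pixel_size_um=px)


def save_rgb(rgb: np.ndarray, path, pixel_size_um: float = 60.0) -> None:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3 or rgb.dtype != np.uint8:
        raise ValueError("expected an (H, W, 3) uint8 RGB array")
    tifffile.imwrite(str(path), rgb, photometric="rgb")
    _write_sidecar(path, {"pixel_size_um": pixel_size_um, "kind": "rgb_merge",
                          "channels": "44Ca=R,64Zn=G,55Mn=B"})
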