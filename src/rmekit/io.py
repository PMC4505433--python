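"""Standard-format adapters: TIFF images, CSV/JSON results, truth sidecars.

Scenes are written as multipage TIFF (one page per channel) with a JSON
sidecar holding the generating parameters and run-length-encoded ground-truth
masks, so a written scene can be reloaded without re-rendering.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from .scenes import CellSpec, CellTruth, Scene, SceneSpec

__all__ = [
    "read_image",
    "write_scene",
    "read_scene",
    "rle_encode",
    "rle_decode",
]

CHANNEL_ORDER = ("protein", "membrane_dye", "er_marker")


def rle_encode(mask: np.ndarray) -> dict:
    """Row-major run-length encoding of a boolean mask."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return {"shape": list(mask.shape), "runs": []}
    change = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if flat[a]:
            runs.append([int(a), int(b - a)])
    return {"shape": list(mask.shape), "runs": runs}


def rle_decode(enc: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(enc["shape"])), dtype=bool)
    for start, length in enc["runs"]:
        flat[start:start + length] = True
    return flat.reshape(enc["shape"])


def read_image(path, channel: str | int | None = None) -> np.ndarray:
    """Read a TIFF image or stack; select a channel by name or page index.

    Multipage files written by :func:`write_scene` use the canonical channel
    order (protein, membrane_dye, er_marker); asking for a missing channel
    raises an error naming what is available.
    """
    arr = tifffile.imread(str(path))
    if channel is None:
        return arr
    if arr.ndim == 2:
        raise ValueError("single-channel image has no channel axis")
    n = arr.shape[0]
    if isinstance(channel, int):
        if not 0 <= channel < n:
            raise ValueError(f"channel index {channel} out of range (0..{n - 1})")
        return arr[channel]
    names = CHANNEL_ORDER[:n]
    if channel not in names:
        raise ValueError(
            f"channel {channel!r} not present; available: {', '.join(names)}"
        )
    return arr[names.index(channel)]


def write_scene(scene: Scene, out_dir, stem: str = "scene") -> Path:
    """Write a scene as multipage TIFF + JSON truth sidecar; returns the TIFF path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif_path = out_dir / f"{stem}.tif"
    pages = np.stack([scene.channels[c] for c in CHANNEL_ORDER]).astype(np.float32)
    tifffile.imwrite(str(tif_path), pages, photometric="minisblack")
    sidecar = {
        "channels": list(CHANNEL_ORDER),
        "spec": _spec_to_json(scene.spec),
        "truth": [
            {
                "spec": asdict(t.spec),
                "cell": rle_encode(t.cell),
                "membrane": rle_encode(t.membrane),
                "interior": rle_encode(t.interior),
                "nucleus": rle_encode(t.nucleus),
                "er": rle_encode(t.er),
            }
            for t in scene.truth
        ],
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar))
    return tif_path


def _spec_to_json(spec: SceneSpec) -> dict:
    d = asdict(spec)
    d["cells"] = [asdict(c) for c in spec.cells]
    return d


def read_scene(tif_path) -> Scene:
    """Reload a scene written by :func:`write_scene` (channels + truth)."""
    tif_path = Path(tif_path)
    sidecar = json.loads(tif_path.with_suffix(".json").read_text())
    pages = tifffile.imread(str(tif_path)).astype(np.float64)
    channels = {c: pages[i] for i, c in enumerate(sidecar["channels"])}
    spec_d = dict(sidecar["spec"])
    cells = tuple(
        CellSpec(**{**c, "center": tuple(c["center"])}) for c in spec_d.pop("cells")
    )
    spec = SceneSpec(
        **{**spec_d, "image_shape": tuple(spec_d.pop("image_shape")), "cells": cells}
    )
    truth = [
        CellTruth(
            spec=CellSpec(**{**t["spec"], "center": tuple(t["spec"]["center"])}),
            cell=rle_decode(t["cell"]),
            membrane=rle_decode(t["membrane"]),
            interior=rle_decode(t["interior"]),
            nucleus=rle_decode(t["nucleus"]),
            er=rle_decode(t["er"]),
        )
        for t in sidecar["truth"]
    ]
    return Scene(spec=spec, channels=channels, truth=truth)
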