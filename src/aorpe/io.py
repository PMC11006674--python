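"""File I/O: TIFF stacks with JSON scale sidecars, CSV centers/traces/manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .acquire import TrainingPairSet
from .sim import SpeckleStack

__all__ = [
    "write_image", "read_image", "write_stack", "write_pairs", "read_pairs",
]


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image as 16-bit TIFF, recording the scale in a sidecar."""
    path = Path(path)
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scale = (hi - lo) or 1.0
    data = np.round((img - lo) / scale * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, data)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"offset": lo, "scale": scale, "dtype": "uint16"})
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG image to float in [0, 1] (or sidecar-restored units)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        from PIL import Image

        data = np.asarray(Image.open(path))
    data = data.astype(float)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return data / 65535.0 * meta["scale"] + meta["offset"]
    maxval = 65535.0 if data.max() > 255 else 255.0
    return data / maxval


def write_stack(stack: SpeckleStack, outdir: str | Path, prefix: str = "stack") -> dict:
    """Persist a simulated acquisition: frames, truth, centers and trace."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = stack.as_array()
    lo, hi = float(frames.min()), float(frames.max())
    scale = (hi - lo) or 1.0
    data = np.round((frames - lo) / scale * 65535.0).astype(np.uint16)
    stack_path = outdir / f"{prefix}_frames.tif"
    tifffile.imwrite(stack_path, data, photometric="minisblack")
    (outdir / f"{prefix}_frames.tif.json").write_text(
        json.dumps({"offset": lo, "scale": scale, "n_frames": stack.n_frames})
    )
    write_image(outdir / f"{prefix}_truth.tif", stack.mosaic.reflectance)
    pd.DataFrame(stack.mosaic.centers, columns=["row_px", "col_px"]).to_csv(
        outdir / f"{prefix}_centers.csv", index=False
    )
    tr = stack.trace.row_shifts
    rows = [
        (f, r, tr[f, r, 0], tr[f, r, 1])
        for f in range(tr.shape[0])
        for r in range(tr.shape[1])
    ]
    pd.DataFrame(rows, columns=["frame", "row", "dy_px", "dx_px"]).to_csv(
        outdir / f"{prefix}_trace.csv", index=False
    )
    return {
        "frames": str(stack_path),
        "truth": str(outdir / f"{prefix}_truth.tif"),
        "centers": str(outdir / f"{prefix}_centers.csv"),
        "trace": str(outdir / f"{prefix}_trace.csv"),
    }


def write_pairs(pairs: TrainingPairSet, outdir: str | Path, prefix: str = "pairs") -> dict:
    """Persist training pairs as paired multi-page TIFFs plus a CSV manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x, y = pairs.arrays()
    spk_path = outdir / f"{prefix}_speckled.tif"
    avg_path = outdir / f"{prefix}_averaged.tif"
    for arr, path in ((x, spk_path), (y, avg_path)):
        data = np.clip(arr, 0, None)
        hi = float(data.max()) or 1.0
        tifffile.imwrite(path, np.round(data / hi * 65535.0).astype(np.uint16),
                         photometric="minisblack")
        Path(str(path) + ".json").write_text(json.dumps({"offset": 0.0, "scale": hi}))
    manifest = pd.DataFrame(
        [
            {
                "pair_id": i,
                "stack": p.stack_id,
                "reference": p.reference_index,
                "offset_row": p.offset[0],
                "offset_col": p.offset[1],
                "flipped": p.flipped,
            }
            for i, p in enumerate(pairs.pairs)
        ]
    )
    manifest_path = outdir / f"{prefix}_manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return {"speckled": str(spk_path), "averaged": str(avg_path),
            "manifest": str(manifest_path)}


def read_pairs(speckled_path: str | Path, averaged_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    out = []
    for path in (speckled_path, averaged_path):
        path = Path(path)
        data = tifffile.imread(path).astype(float)
        meta = json.loads(Path(str(path) + ".json").read_text())
        out.append(data / 65535.0 * meta["scale"] + meta.get("offset", 0.0))
    return out[0], out[1]
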