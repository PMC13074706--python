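"""On-disk layout for synthetic datasets.

Scenes are written as 8-bit PNG (RGB) plus 16-bit TIFF (IR); the manifest
as CSV with box coordinates; the text corpus as JSON lines; the true
homography as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .scenes import SeedScene

__all__ = ["write_scene", "read_scene", "write_corpus", "read_corpus",
           "write_manifest_csv", "write_homography", "read_homography"]

_MANIFEST_COLUMNS = ["sample_id", "class_id", "class_name", "viability",
                     "scene_id", "box_x0", "box_y0", "box_x1", "box_y1"]


def write_scene(scene: SeedScene, out_dir: str | Path, scene_id: str) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rgb_path = out / f"{scene_id}_rgb.png"
    ir_path = out / f"{scene_id}_ir.tiff"
    iio.imwrite(rgb_path, (np.clip(scene.rgb_frame, 0, 1) * 255).astype(np.uint8))
    tifffile.imwrite(ir_path,
                     (np.clip(scene.ir_frame, 0, 1) * 65535).astype(np.uint16))
    write_homography(scene.true_homography, out / f"{scene_id}_homography.json")
    return {"rgb": str(rgb_path), "ir": str(ir_path)}


def read_scene(out_dir: str | Path, scene_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    out = Path(out_dir)
    rgb = iio.imread(out / f"{scene_id}_rgb.png").astype(np.float64) / 255.0
    ir = tifffile.imread(out / f"{scene_id}_ir.tiff").astype(np.float64) / 65535.0
    H = read_homography(out / f"{scene_id}_homography.json")
    return rgb, ir, H


def write_homography(H: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"matrix": np.asarray(H).tolist()}))


def read_homography(path: str | Path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text())["matrix"], dtype=float)


def write_manifest_csv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)


def write_corpus(corpus: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for class_id in sorted(corpus):
            for text in corpus[class_id]:
                fh.write(json.dumps({"class_id": class_id, "text": text}) + "\n")


def read_corpus(path: str | Path) -> dict[str, list[str]]:
    corpus: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            corpus.setdefault(rec["class_id"], []).append(rec["text"])
    return corpus
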