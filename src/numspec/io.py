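"""Reading and writing displays, images, and voxel tables.

Images are 8-bit grayscale PNG; display specs are JSON (one per file or
JSON-lines batches); voxel time series and model fits are delimited
tables (one row per voxel: metadata columns, then the per-TR BOLD
columns).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .stimuli import DisplaySpec, StimulusImage

__all__ = [
    "save_image_png",
    "load_image_png",
    "save_display_spec",
    "load_display_spec",
    "save_spec_batch",
    "load_spec_batch",
    "save_voxel_table",
    "load_voxel_table",
]


def save_image_png(img: StimulusImage, path: str | Path) -> None:
    arr = np.clip(np.rint(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def load_image_png(path: str | Path, background_level: float = 0.5) -> StimulusImage:
    arr = np.asarray(Image.open(Path(path)).convert("L"), dtype=float) / 255.0
    # snap near-background values to the exact level lost to 8-bit
    # quantization, so background pixels stay exactly at background
    snapped = np.where(np.abs(arr - background_level) <= 1.0 / 255.0,
                       background_level, arr)
    return StimulusImage(snapped, arr.shape[0], background_level)


def save_display_spec(spec: DisplaySpec, path: str | Path) -> None:
    Path(path).write_text(spec.to_json() + "\n")


def load_display_spec(path: str | Path) -> DisplaySpec:
    return DisplaySpec.from_json(Path(path).read_text())


def save_spec_batch(specs: list[DisplaySpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for spec in specs:
            fh.write(spec.to_json() + "\n")


def load_spec_batch(path: str | Path) -> list[DisplaySpec]:
    with open(path) as fh:
        return [DisplaySpec.from_json(line) for line in fh if line.strip()]


def save_voxel_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), index=False)


def load_voxel_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
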