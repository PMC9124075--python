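"""Exact-pixel training-set augmentation.

Histopathology patches have no canonical orientation, so right-angle
rotations and flips produce valid new training samples with unchanged
labels.  All operations are pure pixel permutations — no interpolation —
and only records in the train split are ever expanded.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
from PIL import Image

from .manifest import DatasetManifest, DatasetRecord

#: Default operation set: a 6x expansion counting the original image.
DEFAULT_OPS = ("rot90", "rot180", "rot270", "hflip", "vflip")


def augment_image(image: np.ndarray, op: str) -> np.ndarray:
    """Apply one exact augmentation operation.

    rot90/rot270 rotate counterclockwise and swap height and width;
    hflip mirrors left-right, vflip top-bottom.
    """
    image = np.asarray(image)
    if op == "rot90":
        return np.rot90(image, 1).copy()
    if op == "rot180":
        return np.rot90(image, 2).copy()
    if op == "rot270":
        return np.rot90(image, 3).copy()
    if op == "hflip":
        return image[:, ::-1].copy()
    if op == "vflip":
        return image[::-1, :].copy()
    raise ValueError(f"unknown augmentation op: {op!r}")


def expand_training_set(
    manifest: DatasetManifest,
    ops: tuple[str, ...] = DEFAULT_OPS,
    out_dir: str | Path = "augmented",
) -> DatasetManifest:
    """Write augmented copies of every train-split image.

    Each train record gains ``len(ops)`` derived records with identical
    labels and a provenance tag naming the operation and source; val/test
    records pass through untouched, so no augmented image can leak into
    evaluation splits.
    """
    for op in ops:
        augment_image(np.zeros((2, 2, 3), dtype=np.uint8), op)  # validate op names
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    new_records: list[DatasetRecord] = []
    for rec in manifest.records:
        new_records.append(rec)
        if rec.split != "train":
            continue
        img = np.asarray(Image.open(rec.path).convert("RGB"))
        stem = Path(rec.path).stem
        for op in ops:
            aug = augment_image(img, op)
            path = out / f"{stem}__{op}.png"
            Image.fromarray(aug).save(path)
            new_records.append(
                replace(
                    rec,
                    path=str(path),
                    provenance=f"augmented:{op}:{rec.path}",
                )
            )
    return DatasetManifest(
        new_records, seed=manifest.seed, provenance=f"{manifest.provenance}|augment:{','.join(ops)}"
    )
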