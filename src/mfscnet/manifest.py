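"""Dataset manifests for class-labeled histopathology image trees.

The canonical on-disk layout mirrors the BreakHis collection::

    root/
      benign/
        adenosis/
          40X/  100X/  200X/  400X/
        fibroadenoma/ ...
      malignant/
        ductal/ ...

Records carry the tumor class (benign/malignant), one of eight histological
subtypes, the optical magnification factor, and a train/val/test split
assignment.  All sampling and splitting is seeded and deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR_CLASSES = ("benign", "malignant")

#: The eight histological subtypes, keyed by their parent tumor class.
SUBTYPES_BY_CLASS = {
    "benign": ("adenosis", "fibroadenoma", "tubular_adenoma", "phyllodes_tumor"),
    "malignant": ("ductal", "lobular", "mucinous", "papillary"),
}
SUBTYPES = SUBTYPES_BY_CLASS["benign"] + SUBTYPES_BY_CLASS["malignant"]

MAGNIFICATIONS = (40, 100, 200, 400)

SPLITS = ("train", "val", "test")

UNKNOWN = "unknown"

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}

_CSV_COLUMNS = ["path", "tumor_class", "subtype", "magnification", "split", "provenance"]


@dataclass(frozen=True)
class DatasetRecord:
    """One image patch: its path, labels, and split assignment."""

    path: str
    tumor_class: str = UNKNOWN
    subtype: str = UNKNOWN
    magnification: int | str = UNKNOWN
    split: str = "unassigned"
    #: free text tracking derived images (e.g. "augmented:rot90:<source>")
    provenance: str = ""


@dataclass
class DatasetManifest:
    """Ordered collection of :class:`DatasetRecord` with provenance."""

    records: list[DatasetRecord] = field(default_factory=list)
    seed: int | None = None
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        recs = [r for r in self.records if r.split == split]
        return DatasetManifest(recs, seed=self.seed, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.records], columns=_CSV_COLUMNS)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "provenance": self.provenance,
            "records": [vars(r) for r in self.records],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        records = []
        for row in df.itertuples(index=False):
            mag = row.magnification
            try:
                mag = int(mag)
            except (TypeError, ValueError):
                mag = UNKNOWN
            records.append(
                DatasetRecord(
                    path=str(row.path),
                    tumor_class=str(row.tumor_class),
                    subtype=str(row.subtype),
                    magnification=mag,
                    split=str(row.split) if str(row.split) else "unassigned",
                    provenance=str(getattr(row, "provenance", "")),
                )
            )
        return cls(records)

    def class_counts(self, key: str = "tumor_class") -> dict:
        counts: dict = {}
        for r in self.records:
            counts[getattr(r, key)] = counts.get(getattr(r, key), 0) + 1
        return counts


def _parse_magnification(name: str) -> int | str:
    name = name.strip().lower()
    if name.endswith("x"):
        try:
            mag = int(name[:-1])
        except ValueError:
            return UNKNOWN
        if mag in MAGNIFICATIONS:
            return mag
    return UNKNOWN


def scan_dataset(root_dir: str | Path, layout: str = "breakhis") -> DatasetManifest:
    """Walk an image directory tree and build a manifest.

    ``layout="breakhis"`` expects ``class/subtype/NNX/image``; directory
    components that fail to parse leave the corresponding field ``unknown``
    (with a logged warning) rather than dropping the file.
    ``layout="flat_by_class"`` expects one directory of images per class.

    Record order is lexicographic by path, so repeated scans are
    byte-identical.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root does not exist: {root}")
    if layout not in ("breakhis", "flat_by_class"):
        raise ValueError(f"unknown layout: {layout!r}")

    files = sorted(
        p for p in root.rglob("*") if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES
    )
    records: list[DatasetRecord] = []
    for p in files:
        rel = p.relative_to(root).parts
        tumor_class: str = UNKNOWN
        subtype: str = UNKNOWN
        mag: int | str = UNKNOWN
        if layout == "breakhis":
            if len(rel) >= 1 and rel[0].lower() in TUMOR_CLASSES:
                tumor_class = rel[0].lower()
            if len(rel) >= 2 and rel[1].lower() in SUBTYPES:
                subtype = rel[1].lower()
            if len(rel) >= 3:
                mag = _parse_magnification(rel[2])
            if UNKNOWN in (tumor_class, subtype) or mag == UNKNOWN:
                logger.warning("unparseable path components for %s; kept with unknown fields", p)
        else:  # flat_by_class
            if len(rel) >= 2:
                label = rel[0].lower()
                if label in TUMOR_CLASSES:
                    tumor_class = label
                elif label in SUBTYPES:
                    subtype = label
                    for tc, subs in SUBTYPES_BY_CLASS.items():
                        if label in subs:
                            tumor_class = tc
                else:
                    logger.warning("unrecognized class directory %r for %s", rel[0], p)
        records.append(
            DatasetRecord(path=str(p), tumor_class=tumor_class, subtype=subtype, magnification=mag)
        )
    return DatasetManifest(records, provenance=f"scan:{root}:{layout}")


def sample_subset(
    manifest: DatasetManifest, task: str, per_class: int, seed: int
) -> DatasetManifest:
    """Draw a balanced subset: ``per_class`` records per tumor class
    (``task="binary"``) or per subtype (``task="multiclass"``), uniformly
    without replacement, reproducibly from ``seed``."""
    if task == "binary":
        key, classes = "tumor_class", TUMOR_CLASSES
    elif task == "multiclass":
        key, classes = "subtype", SUBTYPES
    else:
        raise ValueError(f"unknown task: {task!r}")

    by_class: dict[str, list[DatasetRecord]] = {c: [] for c in classes}
    for r in manifest.records:
        label = getattr(r, key)
        if label in by_class:
            by_class[label].append(r)

    rng = np.random.default_rng(seed)
    chosen: list[DatasetRecord] = []
    for c in classes:  # fixed class order keeps the draw reproducible
        pool = by_class[c]
        if len(pool) < per_class:
            raise ValueError(
                f"class {c!r} has only {len(pool)} records, need {per_class}"
            )
        idx = rng.choice(len(pool), size=per_class, replace=False)
        chosen.extend(pool[i] for i in idx)
    chosen.sort(key=lambda r: r.path)
    return DatasetManifest(
        chosen, seed=seed, provenance=f"{manifest.provenance}|sample:{task}:{per_class}:{seed}"
    )


def _largest_remainder_counts(n: int, ratios: Sequence[float]) -> list[int]:
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def make_splits(
    manifest: DatasetManifest,
    ratios: Sequence[float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    stratify_by: str = "tumor_class",
) -> DatasetManifest:
    """Assign train/val/test splits stratified within each class label.

    Per-class split sizes follow the largest-remainder rule so the requested
    ratios are met exactly whenever they divide the class size, and to within
    one record otherwise.
    """
    if len(manifest) == 0:
        raise ValueError("cannot split an empty manifest")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {tuple(ratios)}")
    if len(ratios) != 3:
        raise ValueError("expected exactly three ratios (train, val, test)")

    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(manifest.records):
        by_class.setdefault(getattr(r, stratify_by), []).append(i)

    rng = np.random.default_rng(seed)
    new_records = list(manifest.records)
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        if len(idx) < sum(1 for r in ratios if r > 0):
            raise ValueError(f"class {label!r} has fewer records than nonzero splits")
        counts = _largest_remainder_counts(len(idx), ratios)
        perm = rng.permutation(len(idx))
        start = 0
        for split_name, c in zip(SPLITS, counts):
            for j in perm[start : start + c]:
                new_records[idx[j]] = replace(new_records[idx[j]], split=split_name)
            start += c
    return DatasetManifest(
        new_records,
        seed=seed,
        provenance=f"{manifest.provenance}|split:{tuple(ratios)}:{seed}",
    )
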