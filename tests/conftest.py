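"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from PIL import Image

from mfscnet.manifest import MAGNIFICATIONS, SUBTYPES_BY_CLASS
from mfscnet.synthetic import SynthParams, generate_dataset, generate_patch


@pytest.fixture(scope="session")
def breakhis_tree(tmp_path_factory):
    """A full BreakHis-layout tree: 8 subtypes x 4 magnifications x 5 files."""
    root = tmp_path_factory.mktemp("breakhis")
    img = Image.fromarray(np.full((4, 4, 3), 200, dtype=np.uint8))
    for tumor, subtypes in SUBTYPES_BY_CLASS.items():
        for sub in subtypes:
            for mag in MAGNIFICATIONS:
                d = root / tumor / sub / f"{mag}X"
                d.mkdir(parents=True)
                for i in range(5):
                    img.save(d / f"img_{i}.png")
    return root


@pytest.fixture(scope="session")
def small_params():
    return SynthParams(image_size=96, n_classes=2, seed=3)


@pytest.fixture(scope="session")
def sample_patch(small_params):
    """One synthetic malignant-like patch with its ground truth."""
    return generate_patch(small_params, 1, seed=42)


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    """A written 2-class synthetic dataset (10 patches per class, 48 px)."""
    out = tmp_path_factory.mktemp("synthdata")
    params = SynthParams(image_size=48, n_classes=2, seed=5)
    manifest = generate_dataset(params, per_class=10, out_dir=out)
    return params, manifest, out
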