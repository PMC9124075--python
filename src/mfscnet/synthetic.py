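"""Seeded generator of H&E-like synthetic histopathology patches.

Patches follow the same two-stain Beer-Lambert physics the stain module
inverts: nucleus-like disks carry a high hematoxylin-like concentration, a
diffuse eosin-like background fills the tissue, Gaussian concentration noise
is clipped at zero, and pixel intensities are rendered as the exact inverse
of the OD transform so that stain-matrix recovery is testable to rounding
error.  Classes differ only in nucleus density and radius — the smallest
signal sufficient for a classifier to learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .manifest import (
    MAGNIFICATIONS,
    SUBTYPES,
    SUBTYPES_BY_CLASS,
    DatasetManifest,
    DatasetRecord,
)
from .stain import RUIFROK_HE


def _default_densities(n_classes: int) -> list[float]:
    if n_classes == 2:
        return [8.0, 20.0]
    return list(np.linspace(6.0, 24.0, n_classes))


@dataclass
class SynthParams:
    """Generation conditions for synthetic H&E patches.

    nuclei_density_per_class is in nuclei per 10^4 px^2; densities must be
    strictly positive and distinct so classes are separable.
    """

    image_size: int = 224
    n_classes: int = 2
    nuclei_density_per_class: list[float] = None
    nucleus_radius_range: tuple[float, float] = (3.0, 6.0)
    stain_matrix: np.ndarray = field(default_factory=lambda: RUIFROK_HE.copy())
    concentration_noise_sd: float = 0.02
    background_intensity: int = 255
    seed: int = 0

    def __post_init__(self):
        if self.nuclei_density_per_class is None:
            self.nuclei_density_per_class = _default_densities(self.n_classes)
        if len(self.nuclei_density_per_class) != self.n_classes:
            raise ValueError("need one nucleus density per class")
        d = np.asarray(self.nuclei_density_per_class, dtype=float)
        if np.any(d <= 0) or len(set(d.tolist())) != len(d):
            raise ValueError("nucleus densities must be strictly positive and distinct")
        W = np.asarray(self.stain_matrix, dtype=float)
        if W.shape != (3, 2) or np.any(W < 0):
            raise ValueError("stain matrix must be 3x2 nonnegative")
        if not np.allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-6):
            raise ValueError("stain matrix columns must be unit-norm")
        self.stain_matrix = W


#: Diffuse eosin-like concentration outside nuclei (cytoplasm/stroma).
DIFFUSE_EOSIN = 0.30
#: Hematoxylin-like concentration amplitude inside a nucleus.
NUCLEUS_HEMATOXYLIN = (0.8, 1.2)
#: Fraction of the diffuse eosin displaced inside a nucleus.  Nuclei exclude
#: cytoplasm, so eosin is depleted where hematoxylin is high; this also keeps
#: near-pure pixels of each stain present, without which the stain matrix
#: would not be identifiable from the image.
NUCLEUS_EOSIN_EXCLUSION = 0.8


def _class_radius_range(params: SynthParams, class_index: int) -> tuple[float, float]:
    # later classes (denser) also get modestly larger nuclei
    lo, hi = params.nucleus_radius_range
    bump = 1.0 + 0.35 * class_index / max(params.n_classes - 1, 1)
    return lo * bump, hi * bump


def generate_patch(
    params: SynthParams, class_index: int, seed: int
) -> tuple[np.ndarray, dict]:
    """Render one synthetic RGB patch plus its ground truth.

    Nucleus centers follow a homogeneous Poisson process at the class
    density; stain-1 concentration is high inside nuclei, stain-2 diffuse;
    Gaussian noise (clipped at 0) is added to both concentration maps; the
    image is the exact Beer-Lambert inverse of the OD transform, rounded to
    8 bits.  Fully reproducible from ``seed``.
    """
    if not 0 <= class_index < params.n_classes:
        raise ValueError(f"class_index {class_index} out of range [0, {params.n_classes})")
    rng = np.random.default_rng(seed)
    n = params.image_size
    density = params.nuclei_density_per_class[class_index]
    n_nuclei = rng.poisson(density * n * n / 1e4)

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c_hema = np.zeros((n, n))
    centers = rng.uniform(0, n, size=(n_nuclei, 2))
    r_lo, r_hi = _class_radius_range(params, class_index)
    radii = rng.uniform(r_lo, r_hi, size=n_nuclei)
    amps = rng.uniform(*NUCLEUS_HEMATOXYLIN, size=n_nuclei)
    for (cy, cx), r, a in zip(centers, radii, amps):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        # soft-edged disk: full amplitude in the core, smooth falloff at rim
        c_hema += a * np.clip(1.3 - d2 / r**2, 0.0, 1.0)
    c_eosin = DIFFUSE_EOSIN * (1.0 - NUCLEUS_EOSIN_EXCLUSION * np.clip(c_hema, 0.0, 1.0))

    conc = np.stack([c_hema, c_eosin], axis=-1)
    if params.concentration_noise_sd > 0:
        conc = conc + rng.normal(0.0, params.concentration_noise_sd, size=conc.shape)
    conc = np.clip(conc, 0.0, None)

    od = conc @ params.stain_matrix.T
    bg = float(params.background_intensity)
    intensity = (bg + 1.0) * np.power(10.0, -od) - 1.0
    image = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    truth = {
        "centers": centers,
        "radii": radii,
        "concentrations": conc,
        "stain_matrix": params.stain_matrix.copy(),
        "n_nuclei": int(n_nuclei),
    }
    return image, truth


def _class_dirs(params: SynthParams, class_index: int) -> tuple[str, str]:
    """(tumor_class, subtype) directory names for a synthetic class."""
    if params.n_classes == 2:
        return ("benign", "adenosis") if class_index == 0 else ("malignant", "ductal")
    if params.n_classes == 8:
        subtype = SUBTYPES[class_index]
        tumor = "benign" if subtype in SUBTYPES_BY_CLASS["benign"] else "malignant"
        return tumor, subtype
    # other class counts: synthetic labels under alternating parents
    tumor = "benign" if class_index < params.n_classes / 2 else "malignant"
    return tumor, f"class{class_index}"


def generate_dataset(
    params: SynthParams, per_class: int, out_dir: str | Path
) -> DatasetManifest:
    """Write a BreakHis-style tree of synthetic patches and return its manifest.

    Images are distributed round-robin over the four pseudo-magnification
    directories; content does not vary with magnification.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: list[DatasetRecord] = []
    for k in range(params.n_classes):
        tumor, subtype = _class_dirs(params, k)
        for i in range(per_class):
            mag = MAGNIFICATIONS[i % len(MAGNIFICATIONS)]
            d = out / tumor / subtype / f"{mag}X"
            d.mkdir(parents=True, exist_ok=True)
            img, _ = generate_patch(params, k, seed=params.seed * 1_000_003 + k * 100_000 + i)
            path = d / f"synth_c{k}_{i:05d}.png"
            Image.fromarray(img).save(path)
            records.append(
                DatasetRecord(
                    path=str(path),
                    tumor_class=tumor,
                    subtype=subtype,
                    magnification=mag,
                    provenance=f"synthetic:class{k}:seed{params.seed}",
                )
            )
    records.sort(key=lambda r: r.path)
    return DatasetManifest(records, seed=params.seed, provenance=f"synthetic:{out}")


def generate_arrays(
    params: SynthParams, per_class: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """In-memory dataset: stacked patches (N, H, W, 3) uint8 and labels (N,)."""
    base = params.seed if seed is None else seed
    X, y = [], []
    for k in range(params.n_classes):
        for i in range(per_class):
            img, _ = generate_patch(params, k, seed=base * 1_000_003 + k * 100_000 + i)
            X.append(img)
            y.append(k)
    return np.stack(X), np.asarray(y)
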