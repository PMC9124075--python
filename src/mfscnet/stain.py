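"""H&E stain separation and color normalization.

Stained tissue transmits light according to the Beer-Lambert law: the optical
density (OD) of a pixel is linear in the local dye concentrations,
``OD ≈ W @ c`` with ``W`` the 3x2 stain matrix (columns: hematoxylin-like and
eosin-like RGB absorption directions) and ``c`` the two nonnegative
concentrations.  Color normalization estimates ``W`` and ``c`` for a source
and a target image by sparse non-negative matrix factorization in OD space,
then re-renders the source with the target's stain matrix and per-stain
concentration scale.  Tissue structure — encoded in the concentration maps —
is untouched; only the color basis changes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF

logger = logging.getLogger(__name__)

#: Classic H&E reference absorption directions (hematoxylin, eosin) used to
#: initialize the factorization; columns are unit-norm RGB-OD vectors.
RUIFROK_HE = np.array(
    [[0.650, 0.072], [0.704, 0.990], [0.286, 0.105]], dtype=float
)
RUIFROK_HE /= np.linalg.norm(RUIFROK_HE, axis=0, keepdims=True)

DEFAULT_OD_THRESHOLD = 0.15
DEFAULT_SPARSITY = 0.1


@dataclass
class StainModel:
    """Estimated stain basis for one image.

    stain_matrix : (3, 2) nonnegative, unit-norm columns; column 0 is the
        more blue-absorbing (hematoxylin-like) stain.
    concentration_scale : per-stain 99th percentile of the fitted
        concentrations, used to match stain intensity between images.
    """

    stain_matrix: np.ndarray
    concentration_scale: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "stain_matrix": self.stain_matrix.tolist(),
                    "concentration_scale": self.concentration_scale.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StainModel":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["stain_matrix"]), np.asarray(d["concentration_scale"]))


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to optical density.

    ``OD = -log10((I + 1) / 256)``: zero at full transmission (I=255),
    strictly decreasing in intensity, and exactly invertible by
    :func:`od_to_rgb` on integer input.
    """
    image = np.asarray(image)
    return -np.log10((image.astype(float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded and clipped to 8 bits."""
    intensity = 256.0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def _nnls_2col(W: np.ndarray, od_pixels: np.ndarray) -> np.ndarray:
    """Exact nonnegative least squares for the 2-column system ``W c ≈ od``.

    Vectorized over pixels: solve the unconstrained 2x2 normal equations,
    then for any pixel with a negative coefficient clamp it to zero and
    re-solve the remaining single-variable problem in closed form.
    """
    od_pixels = np.asarray(od_pixels, dtype=float)  # (n, 3)
    G = W.T @ W  # (2, 2)
    b = od_pixels @ W  # (n, 2)
    det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
    c0 = (G[1, 1] * b[:, 0] - G[0, 1] * b[:, 1]) / det
    c1 = (G[0, 0] * b[:, 1] - G[1, 0] * b[:, 0]) / det
    C = np.stack([c0, c1], axis=1)
    neg0 = C[:, 0] < 0
    neg1 = C[:, 1] < 0
    # one active constraint: best single-stain fit, itself clipped at zero
    C[neg0, 0] = 0.0
    C[neg0, 1] = np.maximum(b[neg0, 1] / G[1, 1], 0.0)
    C[neg1 & ~neg0, 1] = 0.0
    C[neg1 & ~neg0, 0] = np.maximum(b[neg1 & ~neg0, 0] / G[0, 0], 0.0)
    return C


def stain_concentrations(image_or_od: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Per-pixel nonnegative concentrations for a fixed stain matrix.

    Accepts either an 8-bit RGB image (H, W, 3) or an OD array of the same
    shape; returns (H, W, 2).
    """
    arr = np.asarray(image_or_od)
    od = rgb_to_od(arr) if arr.dtype == np.uint8 else arr.astype(float)
    flat = od.reshape(-1, 3)
    C = _nnls_2col(np.asarray(stain_matrix, dtype=float), flat)
    return C.reshape(od.shape[:-1] + (2,))


def _order_columns(W: np.ndarray) -> np.ndarray:
    # hematoxylin (blue) absorbs red light more strongly than eosin does
    if W[0, 0] < W[0, 1]:
        W = W[:, ::-1]
    return np.ascontiguousarray(W)


def estimate_stain_model(
    image: np.ndarray,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    sparsity: float = DEFAULT_SPARSITY,
    seed: int = 0,
    max_iter: int = 400,
) -> StainModel:
    """Estimate a two-stain model by sparse NMF on foreground OD pixels.

    Foreground = pixels whose maximum-channel OD exceeds ``od_threshold``
    (background glass carries no stain information).  The factorization
    ``OD ≈ C @ W.T`` is fit with multiplicative updates and an L1 penalty
    (weight ``sparsity``) on the concentrations; it is initialized from the
    canonical H&E absorption directions, which makes the result independent
    of pixel order.  Columns are unit-normalized and ordered
    hematoxylin-first.  The concentration scale is each stain's 99th
    percentile concentration over *all* pixels (not just the foreground):
    normalization maps this percentile onto the target's, so computing it
    on the full image makes renormalizing an already-normalized image a
    near-fixpoint regardless of how much background the image contains.
    """
    od = rgb_to_od(image).reshape(-1, 3)
    fg = od[od.max(axis=1) > od_threshold]
    if fg.shape[0] < 100:
        raise ValueError(
            f"only {fg.shape[0]} foreground pixels above OD {od_threshold}; "
            "lower od_threshold or supply a tissue-bearing image"
        )

    W0 = RUIFROK_HE.copy()
    C0 = np.maximum(_nnls_2col(W0, fg), 1e-8)
    # objective: 0.5*||OD - C W^T||^2 + sparsity*||C||_1; sklearn scales its
    # concentration penalty by n_features, hence alpha_W = sparsity / 3
    nmf = NMF(
        n_components=2,
        init="custom",
        solver="mu",
        beta_loss="frobenius",
        alpha_W=sparsity / 3.0,
        alpha_H=0.0,
        l1_ratio=1.0,
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    )
    # sklearn convention: X (n_pixels, 3) ≈ W_sk (concentrations) @ H_sk (stains)
    C = nmf.fit_transform(fg, W=C0, H=np.ascontiguousarray(W0.T))
    W = nmf.components_.T  # (3, 2)
    norms = np.linalg.norm(W, axis=0)
    if np.any(norms <= 0):
        raise ValueError("degenerate stain estimate: a stain vector collapsed to zero")
    W = _order_columns(W / norms)

    C = _nnls_2col(W, od)  # concentrations of every pixel, unit-norm basis
    scale = np.percentile(C, 99, axis=0)
    return StainModel(stain_matrix=W, concentration_scale=np.asarray(scale, dtype=float))


def normalize_image(
    source: np.ndarray, source_model: StainModel, target_model: StainModel
) -> np.ndarray:
    """Map a source image into the target image's stain basis.

    Source concentrations are rescaled per stain by
    ``target_scale / source_scale`` and re-rendered through the target stain
    matrix via Beer-Lambert.  Zero-OD (background) pixels have zero
    concentration and stay background.
    """
    if np.any(source_model.concentration_scale <= 0):
        raise ValueError("degenerate source stain model: zero concentration scale")
    C = stain_concentrations(np.asarray(source, dtype=np.uint8), source_model.stain_matrix)
    C = C * (target_model.concentration_scale / source_model.concentration_scale)
    od = C @ target_model.stain_matrix.T
    return od_to_rgb(od)


class StainNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn style stain-normalization transformer.

    ``fit`` estimates the stain model of a target image; ``transform`` maps
    source images (each with its own estimated model) into that basis.

    Parameters
    ----------
    od_threshold : float, default 0.15
        Foreground threshold on maximum-channel optical density.
    sparsity : float, default 0.1
        L1 weight on the concentration factor of the NMF.
    seed : int, default 0
        Seed forwarded to the factorization.
    """

    def __init__(
        self,
        od_threshold: float = DEFAULT_OD_THRESHOLD,
        sparsity: float = DEFAULT_SPARSITY,
        seed: int = 0,
    ):
        self.od_threshold = od_threshold
        self.sparsity = sparsity
        self.seed = seed

    def fit(self, X, y=None):
        """Estimate the target stain model from one RGB image (H, W, 3)."""
        X = np.asarray(X)
        if X.ndim == 4:
            if X.shape[0] != 1:
                raise ValueError("fit expects a single target image")
            X = X[0]
        self.target_model_ = estimate_stain_model(
            X, od_threshold=self.od_threshold, sparsity=self.sparsity, seed=self.seed
        )
        return self

    def transform(self, X):
        """Normalize one image (H, W, 3) or a batch (N, H, W, 3)."""
        if not hasattr(self, "target_model_"):
            raise ValueError("StainNormalizer is not fitted; call fit(target_image) first")
        X = np.asarray(X)
        single = X.ndim == 3
        batch = X[None] if single else X
        out = np.empty_like(batch, dtype=np.uint8)
        for i, img in enumerate(batch):
            model = estimate_stain_model(
                img, od_threshold=self.od_threshold, sparsity=self.sparsity, seed=self.seed
            )
            out[i] = normalize_image(img, model, self.target_model_)
        return out[0] if single else out
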