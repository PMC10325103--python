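"""Learnable embedding of images for diversity plots and privacy attacks.

A UMAP reduction is fitted on real data only — by default 3000 train, 1000
validation and 1000 test images — and then applied as a frozen transform to
unseen real and synthetic samples. Two separate models are used: a
64-feature embedding for distance-based attacks and a 2-D embedding for
visual overlap inspection.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import LabeledImageSet

DEFAULT_FIT_COUNTS = {"train": 3000, "validation": 1000, "test": 1000}
ATTACK_DIM = 64
PLOT_DIM = 2


@dataclass
class EmbeddingModel:
    """A fitted reduction from flattened images to ``out_dim`` features."""

    reducer: object
    out_dim: int
    image_shape: tuple[int, int, int]
    fit_counts: dict[str, int]
    _cache: dict = None  # transform outputs cached for purity

    def __post_init__(self):
        self._cache = {}

    @property
    def n_fit(self) -> int:
        return sum(self.fit_counts.values())

    def transform(self, images: np.ndarray) -> np.ndarray:
        """Map an (n, slices, h, w) stack to (n, out_dim) features.

        The mapping is a pure function of the pixels: results are cached by
        content hash so repeated calls return bit-identical features even if
        the underlying reducer were to use an internal random state.
        """
        images = np.asarray(images, dtype=np.float32)
        if images.ndim != 4 or tuple(images.shape[1:]) != self.image_shape:
            raise ValueError(
                f"images must have shape (n, {', '.join(map(str, self.image_shape))})")
        flat = images.reshape(len(images), -1)
        key = hash(flat.tobytes())
        if key not in self._cache:
            self._cache[key] = np.asarray(self.reducer.transform(flat),
                                          dtype=np.float64)
        return self._cache[key].copy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as f:
            pickle.dump(self, f)

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with open(path, "rb") as f:
            return pickle.load(f)


def fit_embedding(data: LabeledImageSet,
                  sample_spec: dict[str, int] | None = None,
                  out_dim: int = ATTACK_DIM, seed: int = 0,
                  n_neighbors: int = 15, min_dist: float = 0.1) -> EmbeddingModel:
    """Fit a UMAP embedding on a per-split sample of real data.

    ``sample_spec`` maps split tag to the number of images drawn (without
    replacement) from that split; a split requesting more images than it
    holds is an error. Deterministic for a fixed seed.
    """
    import umap

    spec = dict(DEFAULT_FIT_COUNTS if sample_spec is None else sample_spec)
    rng = np.random.default_rng(seed)
    parts = []
    for tag, count in spec.items():
        if count == 0:
            continue
        view = data.split_view(tag)
        if len(view) < count:
            raise ValueError(
                f"split {tag!r} has {len(view)} samples, {count} requested")
        idx = rng.choice(len(view), size=count, replace=False)
        parts.append(view.images[np.sort(idx)])
    if not parts:
        raise ValueError("empty sample specification")
    fit_images = np.concatenate(parts, axis=0)
    flat = fit_images.reshape(len(fit_images), -1).astype(np.float32)
    n_neighbors = min(n_neighbors, len(flat) - 1)
    reducer = umap.UMAP(n_components=out_dim, n_neighbors=n_neighbors,
                        min_dist=min_dist, metric="euclidean",
                        random_state=seed, transform_seed=seed)
    reducer.fit(flat)
    return EmbeddingModel(reducer=reducer, out_dim=out_dim,
                          image_shape=tuple(data.image_shape),
                          fit_counts={k: int(v) for k, v in spec.items()})
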