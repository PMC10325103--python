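"""Build a shareable synthetic dataset from a fitted generator.

Region labels are simulated i.i.d. from a stated categorical distribution
(by default the empirical distribution of the training split), each sampled
label conditions the generator through its one-hot vector with a fresh
noise draw, and the provenance (checkpoint id, seed, label distribution) is
recorded alongside the images. Synthetic samples carry no patient id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .acgan import ACGANResults
from .conditioning import sample_labels
from .datasets import LabeledImageSet


@dataclass
class SyntheticDataset:
    """A finite synthetic dataset plus the provenance needed to recreate it."""

    images: np.ndarray
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.images.shape[0]

    def as_image_set(self) -> LabeledImageSet:
        return LabeledImageSet(images=self.images, labels=self.labels,
                               patient_ids=None,
                               split=np.full(len(self), "synthetic", dtype=object))

    def save_hdf5(self, path: str | Path) -> None:
        self.as_image_set().save_hdf5(path, config_json=self.provenance)

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "SyntheticDataset":
        import h5py

        data = LabeledImageSet.load_hdf5(path)
        with h5py.File(path, "r") as f:
            prov = json.loads(f.attrs["config"]) if "config" in f.attrs else {}
        return cls(images=data.images, labels=data.labels, provenance=prov)


def build_synthetic_dataset(model: ACGANResults, n: int, label_probs,
                            seed: int, checkpoint_id: str = "in-memory",
                            batch_size: int = 256) -> SyntheticDataset:
    """Generate ``n`` labelled synthetic images; bit-deterministic in ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = sample_labels(label_probs, n, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    cond = np.zeros((n, 3))
    cond[np.arange(n), labels.astype(int) - 1] = 1.0
    z = rng.standard_normal((n, model.gen_spec.noise_dim))
    chunks = [model.generate(cond[i:i + batch_size], z=z[i:i + batch_size])
              for i in range(0, n, batch_size)]
    images = np.concatenate(chunks, axis=0)
    provenance = {
        "checkpoint": checkpoint_id,
        "seed": int(seed),
        "label_probs": [float(p) for p in np.asarray(label_probs, dtype=float)],
        "n": int(n),
    }
    return SyntheticDataset(images=images, labels=labels, provenance=provenance)


def default_synthetic_size(n_train: int) -> int:
    """Synthetic set sized at 1.25x the training split (~10k for ~8k train)."""
    return int(round(1.25 * n_train))


def contact_sheet(dataset: SyntheticDataset, path: str | Path,
                  n_rows: int = 6, n_slices_shown: int = 4) -> Path:
    """PNG grid of consecutive central slices per sample, for eyeballing."""
    from PIL import Image

    n_rows = min(n_rows, len(dataset))
    _, s, h, w = dataset.images.shape
    first = max(0, s // 2 - n_slices_shown // 2)
    grid = np.full((n_rows * h, n_slices_shown * w), -1.0, dtype=np.float32)
    for r in range(n_rows):
        for c in range(n_slices_shown):
            grid[r * h:(r + 1) * h, c * w:(c + 1) * w] = \
                dataset.images[r, min(first + c, s - 1)]
    arr = ((grid + 1.0) * 127.5).clip(0, 255).astype(np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr, mode="L").save(path)
    return path
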