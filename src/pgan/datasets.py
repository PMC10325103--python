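"""Labelled multi-slice image containers and their HDF5/PNG interfaces.

``LabeledImageSet`` is the common currency of the whole workflow: real
(phantom) data and synthetic data share the layout — an (n, n_slices, h, w)
float32 image stack in [-1, 1], an anatomical-region label per sample
(1=cervical, 2=thoracic, 3=lumbar), a patient/group id (absent for
synthetic data) and a split tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

CLASS_NAMES = {1: "cervical", 2: "thoracic", 3: "lumbar"}
CLASS_INDEX = {name: k for k, name in CLASS_NAMES.items()}
SPLIT_CODES = {"train": 0, "validation": 1, "test": 2, "synthetic": 3}
SPLIT_NAMES = {v: k for k, v in SPLIT_CODES.items()}


class DataValidationError(ValueError):
    """A container violates one of its structural invariants."""


@dataclass
class LabeledImageSet:
    """Images + region labels + patient ids + split tags.

    Invariants (checked by :meth:`validate`): pixel values in [-1, 1],
    labels in {1, 2, 3}, and no patient id appearing in more than one split.
    """

    images: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray | None = None
    split: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.patient_ids is not None:
            self.patient_ids = np.asarray(self.patient_ids, dtype=np.int32)
        if self.split is None:
            self.split = np.full(len(self.labels), "train", dtype=object)
        self.split = np.asarray(self.split, dtype=object)

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return tuple(self.images.shape[1:])  # type: ignore[return-value]

    def validate(self) -> None:
        n = len(self)
        if self.images.ndim != 4:
            raise DataValidationError("images must have shape (n, slices, h, w)")
        if len(self.labels) != n or len(self.split) != n:
            raise DataValidationError("labels/split length mismatch with images")
        if self.patient_ids is not None and len(self.patient_ids) != n:
            raise DataValidationError("patient_ids length mismatch with images")
        if n and (self.images.min() < -1.0 - 1e-6 or self.images.max() > 1.0 + 1e-6):
            raise DataValidationError("pixel values outside [-1, 1]")
        if n and not np.isin(self.labels, (1, 2, 3)).all():
            raise DataValidationError("labels must be in {1, 2, 3}")
        bad = set(np.unique(self.split).tolist()) - set(SPLIT_CODES)
        if bad:
            raise DataValidationError(f"unknown split tags: {sorted(bad)}")
        if self.patient_ids is not None:
            seen: dict[int, str] = {}
            for pid, tag in zip(self.patient_ids.tolist(), self.split):
                if seen.setdefault(pid, tag) != tag:
                    raise DataValidationError(
                        f"patient {pid} appears in splits '{seen[pid]}' and '{tag}'")

    # -- views ------------------------------------------------------------

    def subset(self, mask: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(
            images=self.images[mask],
            labels=self.labels[mask],
            patient_ids=None if self.patient_ids is None else self.patient_ids[mask],
            split=self.split[mask],
        )

    def split_view(self, tag: str) -> "LabeledImageSet":
        if tag not in SPLIT_CODES:
            raise ValueError(f"unknown split tag {tag!r}")
        return self.subset(self.split == tag)

    def split_counts(self) -> dict[str, int]:
        return {tag: int((self.split == tag).sum()) for tag in SPLIT_CODES
                if (self.split == tag).any()}

    # -- persistence -------------------------------------------------------

    def save_hdf5(self, path: str | Path, config_json: dict | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images.astype(np.float32))
            f.create_dataset("labels", data=self.labels.astype(np.int8))
            if self.patient_ids is not None:
                f.create_dataset("patient_ids", data=self.patient_ids.astype(np.int32))
            codes = np.array([SPLIT_CODES[t] for t in self.split], dtype=np.int8)
            f.create_dataset("split", data=codes)
            if config_json is not None:
                f.attrs["config"] = json.dumps(config_json)

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "LabeledImageSet":
        with h5py.File(path, "r") as f:
            images = f["images"][()]
            labels = f["labels"][()]
            patient_ids = f["patient_ids"][()] if "patient_ids" in f else None
            split = np.array([SPLIT_NAMES[int(c)] for c in f["split"][()]],
                             dtype=object)
        return cls(images=images, labels=labels, patient_ids=patient_ids, split=split)

    def export_png(self, directory: str | Path, indices: list[int] | None = None,
                   slices: list[int] | None = None) -> list[Path]:
        """Write individual slices as 8-bit grayscale PNGs for inspection."""
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        indices = list(range(min(len(self), 8))) if indices is None else indices
        slices = [self.images.shape[1] // 2] if slices is None else slices
        written = []
        for i in indices:
            for s in slices:
                arr = ((self.images[i, s] + 1.0) * 127.5).clip(0, 255).astype(np.uint8)
                name = CLASS_NAMES[int(self.labels[i])]
                out = directory / f"sample{i:05d}_slice{s}_{name}.png"
                Image.fromarray(arr, mode="L").save(out)
                written.append(out)
        return written


def concatenate(sets: list[LabeledImageSet]) -> LabeledImageSet:
    has_pids = all(s.patient_ids is not None for s in sets)
    return LabeledImageSet(
        images=np.concatenate([s.images for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        patient_ids=(np.concatenate([s.patient_ids for s in sets])
                     if has_pids else None),
        split=np.concatenate([s.split for s in sets]),
    )
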