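"""Phantom vertebra-like image generator.

The restricted clinical dataset behind this workflow (sagittal T1 vertebral
units from two ankylosing-spondylitis trials) cannot be shipped, so this
module generates a phantom dataset with the same statistical structure:

* three anatomical classes (cervical, thoracic, lumbar) with
  class-dependent morphology — the "vertebral body" is a superellipse whose
  aspect ratio, corner curvature and internal texture frequency all depend
  on the class, so the class signal rests on several independent geometric
  factors and is learnable by a small CNN without being a single-pixel cue;
* per-patient correlated samples — every sample of a patient shares a
  random intensity offset and size factor, so patient-disjoint splits are
  genuinely harder than random splits;
* multiple scans per patient pooled without a longitudinal trend, matching
  how acquisition timepoints are pooled in the source data;
* patient-disjoint train/validation/test splits.

All pixels lie in [-1, 1]; every stochastic choice flows from a single seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import expit

from .datasets import LabeledImageSet

# per-class morphology, expressed as fractions of the canvas so any
# resolution renders the same shapes: (half_width, half_height,
# superellipse exponent, texture frequency)
_CLASS_GEOMETRY = {
    1: (0.22, 0.34, 2.0, 2.0),   # cervical: narrow, tall, rounded, coarse texture
    2: (0.30, 0.25, 3.0, 5.0),   # thoracic: intermediate
    3: (0.40, 0.32, 5.0, 8.0),   # lumbar: wide, boxy, fine texture
}


class PhantomGeometryError(ValueError):
    """The requested shape does not fit on the canvas."""


@dataclass
class PhantomConfig:
    """Generation parameters for a phantom labelled-image dataset.

    ``scans_per_patient`` pools acquisition timepoints; ``vus_per_scan`` is
    the number of vertebral units extracted per scan. ``patient_effect_sd``
    scales the shared per-patient intensity/size offset and ``noise_sd`` the
    per-pixel Gaussian noise (both dimensionless, on the [-1, 1] scale).
    """

    n_patients: int = 27
    scans_per_patient: int = 3
    vus_per_scan: int = 10
    n_slices: int = 9
    height: int = 64
    width: int = 64
    class_probs: tuple[float, float, float] = (0.25, 0.55, 0.20)
    patient_effect_sd: float = 0.15
    noise_sd: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients", "scans_per_patient", "vus_per_scan",
                     "n_slices", "height", "width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any():
            raise ValueError("class_probs must be 3 non-negative numbers")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("class_probs must sum to 1 within 1e-12")
        if self.patient_effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")

    def to_json(self) -> dict:
        d = asdict(self)
        d["class_probs"] = list(self.class_probs)
        return d


def _render_vu(class_label: int, n_slices: int, h: int, w: int,
               size_factor: float, intensity_offset: float,
               shift_y: float, shift_x: float) -> np.ndarray:
    """Render one noise-free multi-slice vertebral-unit phantom."""
    half_w, half_h, exponent, freq = _CLASS_GEOMETRY[class_label]
    a = half_w * size_factor
    b = half_h * size_factor
    if a >= 0.49 or b >= 0.49:
        raise PhantomGeometryError(
            f"class {class_label} body (half extents {a:.2f}, {b:.2f} of the "
            f"canvas) does not fit inside the {h}x{w} canvas; reduce "
            "patient_effect_sd or the body size")
    yy = (np.arange(h) + 0.5) / h - 0.5 - shift_y
    xx = (np.arange(w) + 0.5) / w - 0.5 - shift_x
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    stack = np.empty((n_slices, h, w), dtype=np.float64)
    center = (n_slices - 1) / 2.0
    for s in range(n_slices):
        # through-slice elliptical profile: the body narrows away from the
        # central slice, vanishing just beyond the outermost slice
        d = abs(s - center) / (center + 1.0) if n_slices > 1 else 0.0
        prof = np.sqrt(max(1.0 - d * d, 0.0))
        if prof <= 0.05:
            stack[s] = -1.0
            continue
        r = (np.abs(X / (a * prof)) ** exponent
             + np.abs(Y / b) ** exponent)
        body = expit((1.0 - r) * 40.0)  # soft boundary
        texture = 0.25 * np.sin(2.0 * np.pi * freq * (Y + 0.5))
        intensity = 0.45 + intensity_offset + texture
        stack[s] = -1.0 + body * (1.0 + intensity)
    return stack


def generate_phantom(config: PhantomConfig) -> LabeledImageSet:
    """Generate a phantom dataset; deterministic for a fixed seed.

    Patient effects and pixel noise are always drawn (so the stream of
    random numbers does not depend on the standard deviations) and scaled by
    their respective SDs: with both SDs at zero, two samples of the same
    class are pixel-identical regardless of patient.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_per_patient = config.scans_per_patient * config.vus_per_scan
    n = config.n_patients * n_per_patient

    labels = rng.choice([1, 2, 3], size=n, p=np.asarray(config.class_probs))
    patient_ids = np.repeat(np.arange(config.n_patients, dtype=np.int32),
                            n_per_patient)

    # shared per-patient effects: intensity offset and log-size factor
    pat_intensity = config.patient_effect_sd * rng.standard_normal(config.n_patients)
    pat_logsize = 0.5 * config.patient_effect_sd * rng.standard_normal(config.n_patients)

    images = np.empty((n, config.n_slices, config.height, config.width),
                      dtype=np.float32)
    for i in range(n):
        pid = patient_ids[i]
        # per-sample sub-canvas jitter, amplitude tied to noise_sd
        shift = 2.0 * config.noise_sd * rng.uniform(-1.0, 1.0, size=2) \
            / max(config.height, config.width) * 4.0
        clean = _render_vu(int(labels[i]), config.n_slices, config.height,
                           config.width, float(np.exp(pat_logsize[pid])),
                           float(pat_intensity[pid]), shift[0], shift[1])
        noise = config.noise_sd * rng.standard_normal(clean.shape)
        images[i] = np.clip(clean + noise, -1.0, 1.0)

    data = LabeledImageSet(images=images, labels=labels,
                           patient_ids=patient_ids,
                           split=np.full(n, "train", dtype=object))
    data = split_by_patient(data, (0.67, 0.19, 0.14), seed=config.seed)
    data.validate()
    return data


def split_by_patient(data: LabeledImageSet,
                     fractions: tuple[float, float, float],
                     seed: int) -> LabeledImageSet:
    """Assign train/validation/test tags at the patient level.

    Patients are shuffled and partitioned so the patient counts match the
    requested fractions as closely as possible (largest-remainder rounding);
    no patient ever spans two splits.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 non-negative numbers summing to 1")
    if data.patient_ids is None:
        raise ValueError("split_by_patient requires patient ids")
    patients = np.unique(data.patient_ids)
    n_nonempty = int((fr > 0).sum())
    if len(patients) < n_nonempty:
        raise ValueError(
            f"{len(patients)} patients cannot fill {n_nonempty} non-empty splits")
    rng = np.random.default_rng(seed)
    order = rng.permutation(patients)

    ideal = fr * len(patients)
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for k in np.argsort(-remainder)[: len(patients) - counts.sum()]:
        counts[k] += 1
    # every non-empty split gets at least one patient
    for k in range(3):
        if fr[k] > 0 and counts[k] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[k] += 1

    tags = np.empty(len(patients), dtype=object)
    tags[: counts[0]] = "train"
    tags[counts[0]: counts[0] + counts[1]] = "validation"
    tags[counts[0] + counts[1]:] = "test"
    patient_tag = dict(zip(order.tolist(), tags))

    split = np.array([patient_tag[int(p)] for p in data.patient_ids], dtype=object)
    out = LabeledImageSet(images=data.images, labels=data.labels,
                          patient_ids=data.patient_ids, split=split)
    out.validate()
    return out
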