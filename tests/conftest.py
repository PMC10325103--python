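import numpy as np
import pytest

from pgan import LabeledImageSet, SyntheticDataset
from pgan.phantom import PhantomConfig, generate_phantom, split_by_patient


@pytest.fixture(scope="session")
def micro_phantom() -> LabeledImageSet:
    """Small 16x16 phantom dataset with all three splits populated."""
    cfg = PhantomConfig(n_patients=18, scans_per_patient=2, vus_per_scan=4,
                        n_slices=9, height=16, width=16, seed=11)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def desk_phantom() -> LabeledImageSet:
    """Desk-scale 32x32 phantom dataset used by classifier/GAN tests."""
    cfg = PhantomConfig(n_patients=24, scans_per_patient=2, vus_per_scan=8,
                        n_slices=9, height=32, width=32, seed=1)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def privacy_phantom() -> LabeledImageSet:
    """Many small single-scan patients, balanced splits: attack AUCs on
    this dataset have low patient-clustering noise."""
    cfg = PhantomConfig(n_patients=90, scans_per_patient=1, vus_per_scan=2,
                        n_slices=9, height=16, width=16, seed=21)
    return split_by_patient(generate_phantom(cfg), (0.34, 0.33, 0.33), seed=21)


def memorization_synthetic(real: LabeledImageSet, n: int = 200,
                           noise: float = 0.02, seed: int = 0) -> SyntheticDataset:
    """Leaky synthetic set: near-copies of training images."""
    rng = np.random.default_rng(seed)
    train = real.split_view("train")
    idx = rng.integers(0, len(train), size=n)
    images = np.clip(train.images[idx]
                     + noise * rng.standard_normal(train.images[idx].shape),
                     -1, 1).astype(np.float32)
    return SyntheticDataset(images=images, labels=train.labels[idx],
                            provenance={"fixture": "memorization"})


def independent_synthetic(real: LabeledImageSet, n: int = 200,
                          seed: int = 77) -> SyntheticDataset:
    """No-leak synthetic set: fresh draws from the same phantom distribution
    with disjoint patients."""
    base_cfg = PhantomConfig(
        n_patients=max(8, int(np.ceil(n / 8))), scans_per_patient=1,
        vus_per_scan=8, n_slices=real.image_shape[0],
        height=real.image_shape[1], width=real.image_shape[2], seed=seed)
    fresh = generate_phantom(base_cfg)
    return SyntheticDataset(images=fresh.images[:n], labels=fresh.labels[:n],
                            provenance={"fixture": "independent"})


@pytest.fixture(scope="session")
def privacy_independent() -> SyntheticDataset:
    """No-leak synthetic set for the privacy phantom: fresh single-scan
    patients from the same distribution."""
    cfg = PhantomConfig(n_patients=100, scans_per_patient=1, vus_per_scan=2,
                        n_slices=9, height=16, width=16, seed=77)
    fresh = generate_phantom(cfg)
    return SyntheticDataset(images=fresh.images, labels=fresh.labels,
                            provenance={"fixture": "independent"})


@pytest.fixture(scope="session")
def micro_memorization(micro_phantom) -> SyntheticDataset:
    return memorization_synthetic(micro_phantom)


@pytest.fixture(scope="session")
def micro_independent(micro_phantom) -> SyntheticDataset:
    return independent_synthetic(micro_phantom)
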