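"""End-to-end orchestration: phantom data -> ac-GAN -> synthetic dataset ->
fidelity / diversity / privacy certification -> shareability verdict.

Every stage persists its artifact under the output directory and is
individually resumable: a stage whose artifact already exists is loaded
instead of recomputed (pass ``force=True`` to recompute). All stage seeds
are derived deterministically from the single global seed, so rerunning a
pipeline with the same config reproduces every number in the report.

The three certification axes are operationalized as:

* **fidelity** — the synthetic dataset must be a functional substitute:
  the classifier trained solely on synthetic data must beat chance on the
  real held-out test set (macro AUC > 0.5); the real-vs-synthetic AUC gap
  is reported with a BCa bootstrap interval. Morph grids are produced for
  visual inspection of the conditioning.
* **diversity** — in a 2-D embedding fitted on real data only, synthetic
  samples must cover the real distribution (median real-to-nearest-
  synthetic distance within a factor of the real-to-real spacing) without
  mode collapse (synthetic spacing not degenerate), and all three region
  labels must be present.
* **privacy** — the pairwise and distribution membership attacks must not
  separate training members from validation members (train-vs-validation
  AUC below the leak threshold) in pixel or embedding space.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .acgan import (ACGAN, ACGANResults, DiscriminatorSpec, GanTrainingConfig,
                    GeneratorSpec)
from .datasets import LabeledImageSet
from .embedding import EmbeddingModel, fit_embedding
from .phantom import PhantomConfig, generate_phantom
from .privacy import DEFAULT_CUTOFFS, DEFAULT_LEAK_THRESHOLD, PrivacyAudit
from .synthesis import (SyntheticDataset, build_synthetic_dataset,
                        contact_sheet, default_synthetic_size)
from .utility import ClassifierConfig, ImageClassifier, compare_arms

log = logging.getLogger("pgan")


class ConfigError(ValueError):
    """The pipeline configuration is invalid or incomplete."""


REQUIRED_SECTIONS = ("phantom", "gan", "synthesis", "evaluation")


@dataclass
class PipelineConfig:
    """Fully serializable configuration of the whole workflow."""

    seed: int = 0
    out_dir: str = "pgan_out"
    scale: str = "desk"                     # "desk" or "reference"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    gan: GanTrainingConfig = field(default_factory=GanTrainingConfig)
    gan_base_channels: int = 32
    synthesis_n: int | None = None          # None -> 1.25 x train size
    synthesis_label_probs: tuple | None = None  # None -> empirical train dist
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_resamples: int = 2000
    embedding_fit_counts: dict = field(default_factory=lambda: {
        "train": 300, "validation": 100, "test": 100})
    embedding_attack_dim: int = 64
    privacy_n_per_origin: int = 30
    privacy_total: int | None = None
    privacy_percentile: float = 1.0
    leak_threshold: float = DEFAULT_LEAK_THRESHOLD
    cutoffs: tuple = DEFAULT_CUTOFFS
    diversity_coverage_factor: float = 3.0
    diversity_collapse_ratio: float = 0.1

    def validate(self) -> None:
        if self.scale not in ("desk", "reference"):
            raise ConfigError("scale must be 'desk' or 'reference'")
        self.phantom.validate()
        self.gan.validate()
        self.classifier.validate()
        if self.phantom.height != self.phantom.width:
            raise ConfigError("the generator requires square images")
        if self.scale == "reference" and (self.phantom.height != 64
                                          or self.phantom.n_slices != 9):
            raise ConfigError("reference scale requires 9-slice 64x64 images")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "scale": self.scale,
            "phantom": self.phantom.to_json(),
            "gan": dataclasses.asdict(self.gan),
            "synthesis": {"n": self.synthesis_n,
                          "label_probs": (None if self.synthesis_label_probs is None
                                          else list(self.synthesis_label_probs))},
            "evaluation": {
                "classifier": dataclasses.asdict(self.classifier),
                "n_resamples": self.n_resamples,
                "embedding": {"fit_counts": dict(self.embedding_fit_counts),
                              "attack_dim": self.embedding_attack_dim},
                "privacy": {"n_per_origin": self.privacy_n_per_origin,
                            "total": self.privacy_total,
                            "percentile": self.privacy_percentile,
                            "leak_threshold": self.leak_threshold,
                            "cutoffs": list(self.cutoffs)},
                "diversity": {"coverage_factor": self.diversity_coverage_factor,
                              "collapse_ratio": self.diversity_collapse_ratio},
            },
            "gan_base_channels": self.gan_base_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        missing = [s for s in REQUIRED_SECTIONS if s not in d]
        if missing:
            raise ConfigError(f"config missing stage section(s): {missing}")
        ph = d["phantom"]
        ph = PhantomConfig(**{**ph, "class_probs": tuple(ph.get(
            "class_probs", PhantomConfig.class_probs))})
        ev = d["evaluation"]
        cfg = cls(
            seed=d.get("seed", 0),
            out_dir=d.get("out_dir", "pgan_out"),
            scale=d.get("scale", "desk"),
            phantom=ph,
            gan=GanTrainingConfig(**d["gan"]),
            gan_base_channels=d.get("gan_base_channels", 32),
            synthesis_n=d["synthesis"].get("n"),
            synthesis_label_probs=(None if d["synthesis"].get("label_probs") is None
                                   else tuple(d["synthesis"]["label_probs"])),
            classifier=ClassifierConfig(**ev.get("classifier", {})),
            n_resamples=ev.get("n_resamples", 2000),
            embedding_fit_counts=ev.get("embedding", {}).get(
                "fit_counts", {"train": 300, "validation": 100, "test": 100}),
            embedding_attack_dim=ev.get("embedding", {}).get("attack_dim", 64),
            privacy_n_per_origin=ev.get("privacy", {}).get("n_per_origin", 30),
            privacy_total=ev.get("privacy", {}).get("total"),
            privacy_percentile=ev.get("privacy", {}).get("percentile", 1.0),
            leak_threshold=ev.get("privacy", {}).get("leak_threshold",
                                                     DEFAULT_LEAK_THRESHOLD),
            cutoffs=tuple(ev.get("privacy", {}).get("cutoffs", DEFAULT_CUTOFFS)),
            diversity_coverage_factor=ev.get("diversity", {}).get(
                "coverage_factor", 3.0),
            diversity_collapse_ratio=ev.get("diversity", {}).get(
                "collapse_ratio", 0.1),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigError("config file does not contain a mapping")
        return cls.from_dict(d)


def desk_config(out_dir: str = "pgan_out", seed: int = 0,
                image_size: int = 32, n_slices: int = 9,
                gan_epochs: int = 12) -> PipelineConfig:
    """A configuration the full pipeline can run on one CPU in minutes."""
    return PipelineConfig(
        seed=seed, out_dir=out_dir, scale="desk",
        phantom=PhantomConfig(n_patients=24, scans_per_patient=2,
                              vus_per_scan=8, n_slices=n_slices,
                              height=image_size, width=image_size, seed=seed),
        gan=GanTrainingConfig(epochs=gan_epochs, batch_size=32, seed=seed),
        gan_base_channels=16,
        classifier=ClassifierConfig(lr=0.02, epochs=8, base_channels=8,
                                    seed=seed),
        n_resamples=2000,
        embedding_fit_counts={"train": 150, "validation": 40, "test": 40},
        privacy_n_per_origin=30,
    )


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


class Pipeline:
    """Stage runner over a :class:`PipelineConfig` with resumable artifacts."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.timings: dict[str, float] = {}

    # -- helpers -----------------------------------------------------------

    def _specs(self) -> tuple[GeneratorSpec, DiscriminatorSpec]:
        if self.config.scale == "reference":
            return GeneratorSpec(), DiscriminatorSpec()
        size = self.config.phantom.height
        base = self.config.gan_base_channels
        return (GeneratorSpec.desk(size=size, n_slices=self.config.phantom.n_slices,
                                   base_channels=base),
                DiscriminatorSpec.desk(size=size, base_channels=base))

    def _timed(self, name: str, fn):
        t0 = time.perf_counter()
        out = fn()
        self.timings[name] = time.perf_counter() - t0
        log.info("stage %-12s done in %6.1f s (seed %d)", name,
                 self.timings[name], self.config.seed)
        return out

    # -- stages ------------------------------------------------------------

    def stage_phantom(self, force: bool = False) -> LabeledImageSet:
        path = self.out / "phantom.h5"
        if path.exists() and not force:
            return LabeledImageSet.load_hdf5(path)

        def run():
            data = generate_phantom(self.config.phantom)
            data.save_hdf5(path, config_json=self.config.phantom.to_json())
            return data

        return self._timed("phantom", run)

    def stage_train(self, force: bool = False) -> ACGANResults:
        path = self.out / "checkpoint.pgan"
        if path.exists() and not force:
            return ACGANResults.load(path)
        data = self.stage_phantom()
        gspec, dspec = self._specs()

        def run():
            model = ACGAN(data, gspec, dspec, self.config.gan)
            results = model.fit()
            results.save(path)
            results.export_history_csv(self.out / "training_history.csv")
            return results

        return self._timed("train", run)

    def stage_synthesize(self, force: bool = False) -> SyntheticDataset:
        path = self.out / "synthetic.h5"
        if path.exists() and not force:
            return SyntheticDataset.load_hdf5(path)
        data = self.stage_phantom()
        model = self.stage_train()

        def run():
            from .conditioning import empirical_distribution

            probs = (self.config.synthesis_label_probs
                     or empirical_distribution(data, "train"))
            n = self.config.synthesis_n or default_synthetic_size(
                len(data.split_view("train")))
            synth = build_synthetic_dataset(
                model, n, probs, seed=_stage_seed(self.config.seed, "synthesize"),
                checkpoint_id=str(self.out / "checkpoint.pgan"))
            synth.save_hdf5(path)
            contact_sheet(synth, self.out / "synthetic_contact_sheet.png")
            return synth

        return self._timed("synthesize", run)

    def stage_morph(self, force: bool = False) -> dict:
        path = self.out / "morph.json"
        if path.exists() and not force:
            return json.loads(path.read_text())
        model = self.stage_train()

        def run():
            from .plots import plot_morph_grid

            seed = _stage_seed(self.config.seed, "morph")
            out = {}
            for (src, dst) in ((1, 3), (1, 2), (2, 3)):
                images = model.morph(src, dst, n_steps=2, seed=seed)
                plot_morph_grid(images, self.out / f"morph_{src}_to_{dst}.png")
                # endpoint consistency with one-hot generations (same z)
                from .conditioning import one_hot

                rng = np.random.default_rng(seed)
                z = rng.standard_normal((1, model.gen_spec.noise_dim))
                ends = model.generate([one_hot(src), one_hot(dst)],
                                      z=np.repeat(z, 2, axis=0))
                dev = max(float(np.abs(images[0] - ends[0]).max()),
                          float(np.abs(images[-1] - ends[1]).max()))
                out[f"{src}->{dst}"] = {"endpoint_deviation": dev}
            path.write_text(json.dumps(out, indent=1))
            return out

        return self._timed("morph", run)

    def stage_embeddings(self, force: bool = False) -> dict[str, EmbeddingModel]:
        paths = {"attack": self.out / "embedding_attack.pkl",
                 "plot": self.out / "embedding_plot.pkl"}
        if all(p.exists() for p in paths.values()) and not force:
            return {k: EmbeddingModel.load(p) for k, p in paths.items()}
        data = self.stage_phantom()

        def run():
            seed = _stage_seed(self.config.seed, "embedding")
            counts = self.config.embedding_fit_counts
            models = {
                "attack": fit_embedding(data, counts,
                                        out_dim=self.config.embedding_attack_dim,
                                        seed=seed),
                "plot": fit_embedding(data, counts, out_dim=2, seed=seed),
            }
            for k, m in models.items():
                m.save(paths[k])
            return models

        return self._timed("embeddings", run)

    def stage_utility(self, force: bool = False) -> dict:
        path = self.out / "utility.json"
        if path.exists() and not force:
            return json.loads(path.read_text())
        data = self.stage_phantom()
        synth = self.stage_synthesize()

        def run():
            from .plots import plot_macro_roc

            test = data.split_view("test")
            seed = _stage_seed(self.config.seed, "utility")
            cfg_r = dataclasses.replace(self.config.classifier, seed=seed)
            cfg_s = dataclasses.replace(self.config.classifier, seed=seed)
            f_real = ImageClassifier(data.split_view("train"), cfg_r).fit()
            f_synth = ImageClassifier(synth, cfg_s).fit()
            rep_r = f_real.evaluate(test, arm="F_real",
                                    n_resamples=self.config.n_resamples, seed=seed)
            rep_s = f_synth.evaluate(test, arm="F_synthetic",
                                     n_resamples=self.config.n_resamples, seed=seed)
            gap = compare_arms(rep_r, rep_s, n_resamples=self.config.n_resamples,
                               seed=seed)
            gap.save_json(path)
            rep_r.roc_points().to_csv(self.out / "roc_real.csv", index=False)
            rep_s.roc_points().to_csv(self.out / "roc_synthetic.csv", index=False)
            plot_macro_roc([rep_r, rep_s], self.out / "roc_curves.png")
            (self.out / "utility_summary.txt").write_text(gap.summary())
            return json.loads(path.read_text())

        return self._timed("utility", run)

    def stage_diversity(self, force: bool = False) -> dict:
        path = self.out / "diversity.json"
        if path.exists() and not force:
            return json.loads(path.read_text())
        data = self.stage_phantom()
        synth = self.stage_synthesize()
        emb = self.stage_embeddings()["plot"]

        def run():
            from sklearn.neighbors import NearestNeighbors

            from .plots import plot_embedding_overlay

            rng = np.random.default_rng(_stage_seed(self.config.seed, "diversity"))
            test = data.split_view("test")
            n_syn = min(len(synth), 4 * len(test))
            pick = np.sort(rng.choice(len(synth), size=n_syn, replace=False))
            real_xy = emb.transform(test.images)
            syn_xy = emb.transform(synth.images[pick])
            plot_embedding_overlay(real_xy, test.labels, syn_xy,
                                   self.out / "embedding_overlay.png")

            def median_nn(a, b, exclude_self=False):
                nn = NearestNeighbors(n_neighbors=2 if exclude_self else 1).fit(b)
                d, _ = nn.kneighbors(a)
                return float(np.median(d[:, 1] if exclude_self else d[:, 0]))

            real_spacing = median_nn(real_xy, real_xy, exclude_self=True)
            coverage = median_nn(real_xy, syn_xy) / max(real_spacing, 1e-12)
            syn_spacing = median_nn(syn_xy, syn_xy, exclude_self=True)
            collapse = syn_spacing / max(real_spacing, 1e-12)
            classes_present = sorted(int(k) for k in np.unique(synth.labels))
            ok = (coverage <= self.config.diversity_coverage_factor
                  and collapse >= self.config.diversity_collapse_ratio
                  and classes_present == [1, 2, 3])
            out = {"coverage_ratio": coverage,
                   "collapse_ratio": collapse,
                   "classes_present": classes_present,
                   "coverage_factor_max": self.config.diversity_coverage_factor,
                   "collapse_ratio_min": self.config.diversity_collapse_ratio,
                   "verdict": "PASS" if ok else "FAIL"}
            path.write_text(json.dumps(out, indent=1))
            return out

        return self._timed("diversity", run)

    def stage_privacy(self, force: bool = False) -> dict:
        path = self.out / "privacy.json"
        if path.exists() and not force:
            return json.loads(path.read_text())
        data = self.stage_phantom()
        synth = self.stage_synthesize()
        emb = self.stage_embeddings()["attack"]

        def run():
            from .plots import plot_score_histograms

            audit = PrivacyAudit(
                data, synth, embedding=emb,
                n_per_origin=self.config.privacy_n_per_origin,
                total=self.config.privacy_total,
                percentile=self.config.privacy_percentile,
                leak_threshold=self.config.leak_threshold,
                cutoffs=self.config.cutoffs,
                seed=_stage_seed(self.config.seed, "privacy"))
            report = audit.run()
            report.save_json(path)
            report.save_score_tables(self.out / "attack_scores")
            for key, table in report.tables.items():
                plot_score_histograms(
                    table, self.out / f"scores_{key[0]}_{key[1]}.png")
            (self.out / "privacy_summary.txt").write_text(report.summary())
            return json.loads(path.read_text())

        return self._timed("privacy", run)

    # -- the whole workflow ------------------------------------------------

    def run_all(self) -> dict:
        stages = [
            ("phantom", self.stage_phantom),
            ("train", self.stage_train),
            ("synthesize", self.stage_synthesize),
            ("morph", self.stage_morph),
            ("embeddings", self.stage_embeddings),
            ("utility", self.stage_utility),
            ("diversity", self.stage_diversity),
            ("privacy", self.stage_privacy),
        ]
        results: dict = {}
        for name, fn in stages:
            try:
                results[name] = fn()
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage '{name}' failed: {exc}; partial state kept "
                    f"under {self.out}") from exc

        utility = results["utility"]
        fidelity_ok = utility["synthetic"]["macro_auc"]["estimate"] > 0.5
        fidelity = {
            "synthetic_arm_macro_auc": utility["synthetic"]["macro_auc"],
            "real_arm_macro_auc": utility["real"]["macro_auc"],
            "macro_auc_gap": utility["macro_gap"],
            "morph": results["morph"],
            "verdict": "PASS" if fidelity_ok else "FAIL",
        }
        report = {
            "seed": self.config.seed,
            "scale": self.config.scale,
            "stage_seconds": {k: round(v, 2) for k, v in self.timings.items()},
            "fidelity": fidelity,
            "diversity": results["diversity"],
            "privacy": results["privacy"],
        }
        axes = [report[a]["verdict"] for a in ("fidelity", "diversity", "privacy")]
        report["overall"] = "SHAREABLE" if all(v == "PASS" for v in axes) \
            else "NOT SHAREABLE"
        self.config.to_yaml(self.out / "config.yaml")
        (self.out / "report.json").write_text(json.dumps(report, indent=1))
        return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the bundled three-axis report."""
    return Pipeline(config).run_all()
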