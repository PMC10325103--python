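"""Utility-transfer experiment: matched classifiers on real vs synthetic data.

Two region classifiers are trained with byte-identical configuration — one
on the real training split (F_real), one solely on synthetic data
(F_synthetic) — and both are evaluated on the same independent real test
set via confusion matrices, macro-averaged one-vs-rest ROC curves and BCa
bootstrap AUC intervals. The gap between the arms measures how well the
synthetic dataset substitutes for the real one in a downstream task.

The classifier at desk scale is a compact 4-block CNN (conv-batchnorm-ReLU
blocks halving the spatial size, then a softmax head) trained with SGD
(momentum 0.9, lr 1e-4, 20 epochs, batch 32, cross-entropy) — the reference
protocol's optimizer and loss, at a width a CPU can train.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from . import nn
from .datasets import LabeledImageSet
from .metrics import AucWithCi, MacroRocResult, bca_interval, macro_auc_ci, macro_roc
from .nn import functional as F
from .synthesis import SyntheticDataset

CLASSES = (1, 2, 3)


@dataclass
class ClassifierConfig:
    """Shared training configuration for both arms of the experiment."""

    architecture: str = "cnn"
    lr: float = 1e-4
    momentum: float = 0.9
    epochs: int = 20
    batch_size: int = 32
    base_channels: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.architecture != "cnn":
            raise ValueError(
                f"unknown architecture {self.architecture!r}; available: 'cnn'")
        if self.lr <= 0 or not (0 <= self.momentum < 1):
            raise ValueError("invalid optimizer settings")
        if self.epochs < 1 or self.batch_size < 1 or self.base_channels < 1:
            raise ValueError("epochs, batch_size and base_channels must be >= 1")


def _build_cnn(image_shape: tuple[int, int, int], base: int,
               rng: np.random.Generator) -> nn.Sequential:
    c, h, _ = image_shape
    layers: list[nn.Layer] = []
    width = base
    size = h
    while size > 4:
        layers += [nn.Conv2d(c, width, 4, 2, 1, rng), nn.BatchNorm2d(width),
                   nn.ReLU()]
        c, size, width = width, size // 2, min(width * 2, 8 * base)
    layers += [nn.Flatten(), nn.Linear(c * size * size, len(CLASSES), rng)]
    return nn.Sequential(*layers)


class ImageClassifier:
    """3-class region classifier bound to a training dataset."""

    def __init__(self, train_data: LabeledImageSet | SyntheticDataset,
                 config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.config.validate()
        if isinstance(train_data, SyntheticDataset):
            train_data = train_data.as_image_set()
        view = train_data.split_view("train")
        if len(view) == 0:
            view = train_data
        if len(view) == 0:
            raise ValueError("empty training set")
        self.train_data = view
        if len(np.unique(view.labels)) < 2:
            warnings.warn("single-class training set: the classifier will be "
                          "degenerate", stacklevel=2)

    def fit(self, verbose: bool = False) -> "ClassifierResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net = _build_cnn(self.train_data.image_shape, cfg.base_channels, rng)
        opt = nn.SGD(net.parameters(), lr=cfg.lr, momentum=cfg.momentum)
        n = len(self.train_data)
        bs = min(cfg.batch_size, n)
        history = []
        it = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n - bs + 1, bs):
                idx = order[start:start + bs]
                x = self.train_data.images[idx].astype(np.float64)
                y = self.train_data.labels[idx].astype(int) - 1
                net.zero_grad()
                logits = net.forward(x, train=True)
                loss, dlogits = F.cross_entropy_with_logits(logits, y)
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite loss at iteration {it}")
                net.backward(dlogits)
                opt.step()
                history.append({"iteration": it, "epoch": epoch, "loss": loss})
                it += 1
            if verbose:
                print(f"epoch {epoch}: loss {history[-1]['loss']:.4f}")
        return ClassifierResults(net, cfg, pd.DataFrame(history))


class ClassifierResults:
    """A fitted classifier with prediction and evaluation methods."""

    def __init__(self, net: nn.Sequential, config: ClassifierConfig,
                 history: pd.DataFrame):
        self.net = net
        self.config = config
        self.history = history

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        out = [F.softmax(self.net.forward(images[i:i + batch_size], train=False))
               for i in range(0, len(images), batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(images), axis=1).astype(np.int8) + 1

    def evaluate(self, test: LabeledImageSet, arm: str = "classifier",
                 n_resamples: int = 2000, seed: int = 0) -> "EvalReport":
        post = self.predict_proba(test.images)
        return EvalReport.from_posteriors(post, test.labels, arm=arm,
                                          n_resamples=n_resamples, seed=seed)


@dataclass
class EvalReport:
    """Confusion matrix + macro ROC + BCa AUC interval for one arm."""

    arm: str
    confusion: np.ndarray
    roc: MacroRocResult
    macro_auc: AucWithCi
    posteriors: np.ndarray
    labels: np.ndarray

    @classmethod
    def from_posteriors(cls, posteriors: np.ndarray, labels: np.ndarray,
                        arm: str = "classifier", n_resamples: int = 2000,
                        seed: int = 0) -> "EvalReport":
        post = np.asarray(posteriors, dtype=float)
        y = np.asarray(labels).astype(int)
        pred = np.argmax(post, axis=1) + 1
        cm = confusion_matrix(y, pred, labels=list(CLASSES))
        roc = macro_roc(post, y)
        ci = macro_auc_ci(post, y, n_resamples=n_resamples, seed=seed)
        return cls(arm=arm, confusion=cm, roc=roc, macro_auc=ci,
                   posteriors=post, labels=y)

    def summary(self) -> str:
        names = ("cervical", "thoracic", "lumbar")
        lines = [f"Arm: {self.arm}",
                 f"macro AUC: {self.macro_auc}",
                 "confusion matrix (rows = truth, cols = prediction):",
                 "            " + "".join(f"{n:>10}" for n in names)]
        for i, n in enumerate(names):
            lines.append(f"{n:>10}  " + "".join(
                f"{self.confusion[i, j]:>10d}" for j in range(3)))
        for k, d in self.roc.per_class.items():
            lines.append(f"class {k} ({names[k - 1]}) AUC: {d['auc']:.3f}")
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "arm": self.arm,
            "confusion": self.confusion.tolist(),
            "macro_auc": {"estimate": self.macro_auc.estimate,
                          "lower": self.macro_auc.lower,
                          "upper": self.macro_auc.upper,
                          "n_resamples": self.macro_auc.n_resamples,
                          "method": self.macro_auc.method},
            "per_class_auc": {str(k): d["auc"] for k, d in self.roc.per_class.items()},
        }

    def roc_points(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"curve": "macro", "fpr": self.roc.fpr_grid,
                              "tpr": self.roc.macro_tpr})]
        for k, d in self.roc.per_class.items():
            rows.append(pd.DataFrame({"curve": f"class{k}", "fpr": d["fpr"],
                                      "tpr": d["tpr"]}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class UtilityGap:
    """Real-minus-synthetic performance differences on a shared test set."""

    macro_gap: AucWithCi
    per_class_gap: dict[int, float]
    real: EvalReport
    synthetic: EvalReport

    def summary(self) -> str:
        lines = ["Utility transfer: F_real vs F_synthetic",
                 "=" * 48,
                 f"macro AUC (real):      {self.real.macro_auc}",
                 f"macro AUC (synthetic): {self.synthetic.macro_auc}",
                 f"macro AUC gap (real - synthetic): {self.macro_gap}"]
        for k, g in self.per_class_gap.items():
            lines.append(f"class {k} AUC gap: {g:+.3f}")
        lines.append("")
        lines.append(self.real.summary())
        lines.append("")
        lines.append(self.synthetic.summary())
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "macro_gap": {"estimate": self.macro_gap.estimate,
                          "lower": self.macro_gap.lower,
                          "upper": self.macro_gap.upper},
            "per_class_gap": {str(k): v for k, v in self.per_class_gap.items()},
            "real": self.real.to_json(),
            "synthetic": self.synthetic.to_json(),
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_json(), indent=1))


def compare_arms(real_report: EvalReport, synthetic_report: EvalReport,
                 n_resamples: int = 2000, seed: int = 0) -> UtilityGap:
    """Joint-bootstrap comparison of the two arms on the same test set."""
    if not np.array_equal(real_report.labels, synthetic_report.labels):
        raise ValueError("the two arms must be evaluated on the same test set")

    def gap(post_r, post_s, lab):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return macro_roc(post_r, lab).macro_auc - macro_roc(post_s, lab).macro_auc

    ci = bca_interval(gap, (real_report.posteriors, synthetic_report.posteriors,
                            real_report.labels),
                      n_resamples=n_resamples, seed=seed)
    per_class = {}
    for k in real_report.roc.per_class:
        if k in synthetic_report.roc.per_class:
            per_class[k] = (real_report.roc.per_class[k]["auc"]
                            - synthetic_report.roc.per_class[k]["auc"])
    return UtilityGap(macro_gap=ci, per_class_gap=per_class,
                      real=real_report, synthetic=synthetic_report)
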