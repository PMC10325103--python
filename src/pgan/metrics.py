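"""ROC/AUC machinery: macro-averaged one-vs-rest ROC and BCa bootstrap CIs.

The macro ROC treats each class against the other two as a binary problem,
computes the per-class ROC curves, interpolates them on a common 512-point
false-positive-rate grid and averages with equal weights; the macro AUC is
the area under the averaged curve.

Confidence intervals use the bias-corrected and accelerated (BCa)
bootstrap: the bias term z0 comes from the fraction of bootstrap statistics
below the observed value, the acceleration a from the jackknife skewness,
and the interval endpoints are bootstrap quantiles at the adjusted levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

FPR_GRID_POINTS = 512


@dataclass
class AucWithCi:
    """AUC (or any statistic) point estimate with a BCa bootstrap interval."""

    estimate: float
    lower: float
    upper: float
    coverage: float = 0.95
    n_resamples: int = 2000
    method: str = "BCa"

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate + 1e-12
                and self.estimate <= self.upper + 1e-12):
            raise ValueError("interval must bracket the point estimate")

    def __str__(self) -> str:
        return (f"{self.estimate:.3f} "
                f"[{self.lower:.3f}, {self.upper:.3f}] ({self.method} "
                f"{100 * self.coverage:.0f}%)")


@dataclass
class MacroRocResult:
    """Per-class one-vs-rest ROC curves and their equal-weight average."""

    per_class: dict[int, dict]          # k -> {"fpr", "tpr", "auc"}
    fpr_grid: np.ndarray
    macro_tpr: np.ndarray
    macro_auc: float
    excluded_classes: list[int] = field(default_factory=list)


def macro_roc(posteriors: np.ndarray, labels: np.ndarray,
              classes: tuple[int, ...] = (1, 2, 3)) -> MacroRocResult:
    """Macro-average one-vs-rest ROC from class posteriors.

    ``posteriors`` rows are probability triples; ``labels`` are 1-based.
    A class absent from the truth is excluded with a warning.
    """
    post = np.asarray(posteriors, dtype=float)
    y = np.asarray(labels).astype(int)
    if post.ndim != 2 or post.shape[1] != len(classes):
        raise ValueError(f"posteriors must be (n, {len(classes)})")
    if not np.allclose(post.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    present = [k for k in classes if (y == k).any()]
    if len(present) < 2:
        raise ValueError("at least two classes must be present in the truth")
    excluded = [k for k in classes if k not in present]
    if excluded:
        warnings.warn(f"classes absent from truth excluded from macro ROC: "
                      f"{excluded}", stacklevel=2)
    grid = np.linspace(0.0, 1.0, FPR_GRID_POINTS)
    per_class: dict[int, dict] = {}
    tprs = []
    for k in present:
        fpr, tpr, _ = _roc_curve(y == k, post[:, classes.index(k)])
        per_class[k] = {"fpr": fpr, "tpr": tpr, "auc": float(_auc(fpr, tpr))}
        tprs.append(np.interp(grid, fpr, tpr))
    macro_tpr = np.mean(tprs, axis=0)
    macro_auc = float(np.trapezoid(macro_tpr, grid))
    return MacroRocResult(per_class=per_class, fpr_grid=grid,
                          macro_tpr=macro_tpr, macro_auc=macro_auc,
                          excluded_classes=excluded)


def bca_interval(statistic, sample, n_resamples: int = 2000,
                 coverage: float = 0.95, seed: int = 0) -> AucWithCi:
    """BCa bootstrap interval for ``statistic`` over paired sample arrays.

    ``sample`` is one array or a tuple of equal-length arrays resampled
    jointly (paired resampling — the unit is the sample index, e.g. a
    (posterior row, label) pair); ``statistic`` receives the resampled
    array(s) and returns a scalar.
    """
    arrays = sample if isinstance(sample, (tuple, list)) else (sample,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all sample arrays must have equal length")
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")

    def stat_at(idx: np.ndarray) -> float:
        return float(statistic(*(a[idx] for a in arrays)))

    theta_hat = stat_at(np.arange(n))
    rng = np.random.default_rng(seed)
    boot = np.empty(n_resamples)
    for b in range(n_resamples):
        boot[b] = stat_at(rng.integers(0, n, size=n))

    if np.ptp(boot) == 0.0:
        warnings.warn("degenerate bootstrap distribution; interval collapses "
                      "to a point", stacklevel=2)
        return AucWithCi(theta_hat, float(boot[0]) if boot[0] < theta_hat else theta_hat,
                         max(theta_hat, float(boot[0])), coverage, n_resamples)

    # bias correction from the fraction of bootstrap statistics below the
    # observed value (ties counted half)
    frac = (np.sum(boot < theta_hat) + 0.5 * np.sum(boot == theta_hat)) / n_resamples
    frac = np.clip(frac, 1.0 / (2 * n_resamples), 1.0 - 1.0 / (2 * n_resamples))
    z0 = norm.ppf(frac)

    # acceleration from jackknife skewness
    jack = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        jack[i] = stat_at(np.delete(all_idx, i))
    diff = jack.mean() - jack
    denom = (diff ** 2).sum() ** 1.5
    a = (diff ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0

    alpha = 1.0 - coverage
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        zq = norm.ppf(q)
        adj = norm.cdf(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
        out.append(float(np.quantile(boot, np.clip(adj, 0.0, 1.0))))
    lo, hi = min(out), max(out)
    lo, hi = min(lo, theta_hat), max(hi, theta_hat)
    return AucWithCi(theta_hat, lo, hi, coverage, n_resamples)


def macro_auc_ci(posteriors: np.ndarray, labels: np.ndarray,
                 n_resamples: int = 2000, coverage: float = 0.95,
                 seed: int = 0) -> AucWithCi:
    """BCa interval for the macro AUC, resampling (posterior, label) pairs."""

    def stat(post, lab):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return macro_roc(post, lab).macro_auc

    return bca_interval(stat, (np.asarray(posteriors), np.asarray(labels)),
                        n_resamples=n_resamples, coverage=coverage, seed=seed)


def binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC of ``scores`` ranking ``positive`` above negative (ties half)."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if positive.all() or not positive.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _roc_curve(positive, scores)
    return float(_auc(fpr, tpr))
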