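"""Classifier evaluation: resubstitution accuracy, LOOCV and signal-detection d'.

Older adults are the signal class throughout (their target coding is +1),
so a *hit* is an older adult classified as old and a *false alarm* a
younger adult classified as old.  Sensitivity is the signal-detection
measure d' = PhiInv(hit rate) - PhiInv(false-alarm rate), which is
criterion-free and well suited to the unequal group sizes here.

Leave-one-out cross-validation retrains the network once per participant
on the remaining n - 1, with the held-out row standardized using the
training fold's statistics only (no leakage), and aggregates the held-out
predictions into one d'.  The item-vs-associate ablation runs the same
LOOCV on each 9-column feature half under matched fold seeds, so the
reported difference is a paired comparison.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from metamem.datamodel import FeatureMatrix, select_features
from metamem.perceptron import NetworkParams, TrainingConfig, forward, predict_targets, train

__all__ = [
    "DPrimeResult",
    "LoocvResult",
    "AblationResult",
    "dprime",
    "resubstitution_accuracy",
    "loocv",
    "ablation_compare",
    "fold_seed",
]


@dataclass(frozen=True)
class DPrimeResult:
    """Counts, corrected rates and the resulting sensitivity."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    hit_rate: float
    fa_rate: float
    dprime: float
    correction: str

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


def _corrected_rate(successes: int, n: int, correction: str) -> float:
    if correction == "loglinear":
        return (successes + 0.5) / (n + 1.0)
    rate = successes / n
    if correction == "half_count":
        if rate == 0.0:
            return 1.0 / (2.0 * n)
        if rate == 1.0:
            return 1.0 - 1.0 / (2.0 * n)
        return rate
    if correction == "none":
        if rate in (0.0, 1.0):
            raise ValueError(
                "extreme proportion with correction='none'; d' is undefined"
            )
        return rate
    raise ValueError(f"unknown correction {correction!r}")


def dprime(
    hits: int,
    misses: int,
    false_alarms: int,
    correct_rejections: int,
    correction: str = "half_count",
) -> DPrimeResult:
    """d' from a 2 x 2 classification table.

    ``correction`` handles proportions of exactly 0 or 1, for which the
    normal quantile is infinite: ``"half_count"`` (default) replaces 0
    with 1/(2N) and 1 with 1 - 1/(2N); ``"loglinear"`` adds 0.5 to every
    count; ``"none"`` raises on extreme rates.
    """
    for name, c in (
        ("hits", hits),
        ("misses", misses),
        ("false_alarms", false_alarms),
        ("correct_rejections", correct_rejections),
    ):
        if c < 0:
            raise ValueError(f"{name} must be non-negative")
    n_signal = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_signal < 1 or n_noise < 1:
        raise ValueError("both the signal and noise class must be non-empty")
    hr = _corrected_rate(hits, n_signal, correction)
    far = _corrected_rate(false_alarms, n_noise, correction)
    return DPrimeResult(
        hits=hits,
        misses=misses,
        false_alarms=false_alarms,
        correct_rejections=correct_rejections,
        hit_rate=hr,
        fa_rate=far,
        dprime=float(norm.ppf(hr) - norm.ppf(far)),
        correction=correction,
    )


def resubstitution_accuracy(params: NetworkParams, features, targets) -> float:
    """Fraction of training rows whose classification matches the true label."""
    predictions = predict_targets(params, features)
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape:
        raise ValueError("features and targets disagree on n")
    return float(np.mean(predictions == np.sign(targets)))


@dataclass(frozen=True)
class LoocvResult:
    """Per-individual held-out predictions and the aggregate sensitivity."""

    row_ids: tuple[str, ...]
    predictions: np.ndarray  # +/-1, +1 = old
    outputs: np.ndarray      # raw output activations of each held-out row
    fold_seeds: tuple[int, ...]
    dprime_result: DPrimeResult
    accuracy: float
    subset: str


@dataclass(frozen=True)
class AblationResult:
    """Paired item-vs-associate LOOCV comparison."""

    item: LoocvResult
    associate: LoocvResult

    @property
    def dprime_item(self) -> float:
        return self.item.dprime_result.dprime

    @property
    def dprime_associate(self) -> float:
        return self.associate.dprime_result.dprime

    @property
    def difference(self) -> float:
        return self.dprime_associate - self.dprime_item


def fold_seed(base_seed: int, row_id: str) -> int:
    """Stable per-fold seed: base seed combined with a CRC of the held-out id.

    Hashing the participant id rather than the row index makes LOOCV
    predictions invariant to the row order of the cohort.
    """
    return int((base_seed + zlib.crc32(row_id.encode("utf-8"))) % (2**31))


def _standardize_fold(train_X: np.ndarray, test_x: np.ndarray):
    means = train_X.mean(axis=0)
    sds = train_X.std(axis=0, ddof=1)
    if np.any(sds == 0.0):
        raise ValueError("constant column in a training fold; cannot standardize")
    return (train_X - means) / sds, (test_x - means) / sds


def _train_folds_batched(
    X_folds: np.ndarray,  # f x m x p, one standardized training set per fold
    T_folds: np.ndarray,  # f x m
    test_X: np.ndarray,   # f x p, the standardized held-out row per fold
    seeds: list[int],
    config: TrainingConfig,
    h: int,
) -> np.ndarray:
    """Train all LOOCV folds simultaneously; return each held-out output.

    Each fold's network is independent (its own seeded initialization and
    its own gradient), so running them as stacked tensors performs the
    identical per-fold updates as a sequential loop, just without the
    per-fold Python overhead.  A fold whose error change drops below the
    convergence tolerance is frozen; training stops when every fold has
    converged or at ``max_epochs``.
    """
    f, m, p = X_folds.shape
    r = config.init_range
    W1 = np.empty((f, h, p))
    b1 = np.empty((f, h))
    w2 = np.empty((f, h))
    b2 = np.empty(f)
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        W1[i] = rng.uniform(-r, r, size=(h, p))
        b1[i] = rng.uniform(-r, r, size=h)
        w2[i] = rng.uniform(-r, r, size=h)
        b2[i] = rng.uniform(-r, r)

    lr = config.learning_rate / m
    prev_error = np.full(f, np.inf)
    active = np.ones(f, dtype=bool)
    for epoch in range(config.max_epochs):
        hidden = np.tanh((X_folds @ W1.transpose(0, 2, 1) + b1[:, None, :]) / 2.0)
        output = np.tanh(
            (np.einsum("fmh,fh->fm", hidden, w2) + b2[:, None]) / 2.0
        )
        residual = T_folds - output
        error = np.einsum("fm,fm->f", residual, residual)
        if not np.all(np.isfinite(error[active])):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        newly_done = np.abs(prev_error - error) < config.convergence_tol
        active &= ~newly_done
        if not active.any():
            break
        prev_error = error

        delta2 = -residual * (1.0 - output * output)
        delta2[~active] = 0.0  # frozen folds receive no further updates
        dw2 = np.einsum("fmh,fm->fh", hidden, delta2)
        db2 = delta2.sum(axis=1)
        delta1 = (delta2[:, :, None] * w2[:, None, :]) * ((1.0 - hidden * hidden) / 2.0)
        W1 -= lr * np.einsum("fmh,fmp->fhp", delta1, X_folds)
        b1 -= lr * delta1.sum(axis=1)
        w2 -= lr * dw2
        b2 -= lr * db2

    hidden_t = np.tanh(
        (np.einsum("fhp,fp->fh", W1, test_X) + b1) / 2.0
    )
    return np.tanh((np.einsum("fh,fh->f", w2, hidden_t) + b2) / 2.0)


def loocv(
    features: FeatureMatrix,
    targets,
    config: TrainingConfig | None = None,
    subset: str = "all",
    h: int = 2,
    correction: str = "half_count",
) -> LoocvResult:
    """Leave-one-out cross-validation of the age classifier.

    For each participant: select the feature subset, z-score the n - 1
    training rows, standardize the held-out row with the training fold's
    statistics, train a freshly initialized network (fold seed derived
    from the held-out id) and classify the held-out row.  Held-out
    predictions aggregate into a :class:`DPrimeResult` with old as the
    signal class.
    """
    if config is None:
        config = TrainingConfig()
    sub = select_features(features, subset) if subset != "all" else features
    X = sub.values
    T = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 participants")
    if T.shape != (n,):
        raise ValueError("targets do not match features")

    X_folds = np.empty((n, n - 1, X.shape[1]))
    T_folds = np.empty((n, n - 1))
    test_X = np.empty((n, X.shape[1]))
    seeds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_T = T[mask]
        if np.all(train_T > 0) or np.all(train_T < 0):
            raise ValueError(
                f"fold holding out {sub.row_ids[i]!r} loses an entire class"
            )
        seeds.append(fold_seed(config.seed, sub.row_ids[i]))
        X_folds[i], test_X[i] = _standardize_fold(X[mask], X[i])
        T_folds[i] = train_T
    outputs = _train_folds_batched(X_folds, T_folds, test_X, seeds, config, h)
    predictions = np.where(outputs > 0.0, 1.0, -1.0)

    old = T > 0
    pred_old = predictions > 0
    result = dprime(
        hits=int(np.sum(old & pred_old)),
        misses=int(np.sum(old & ~pred_old)),
        false_alarms=int(np.sum(~old & pred_old)),
        correct_rejections=int(np.sum(~old & ~pred_old)),
        correction=correction,
    )
    return LoocvResult(
        row_ids=sub.row_ids,
        predictions=predictions,
        outputs=outputs,
        fold_seeds=tuple(seeds),
        dprime_result=result,
        accuracy=float(np.mean(predictions == np.sign(T))),
        subset=subset,
    )


def ablation_compare(
    features: FeatureMatrix,
    targets,
    config: TrainingConfig | None = None,
    h: int = 2,
    correction: str = "half_count",
) -> AblationResult:
    """LOOCV on the item-only and associate-only feature halves.

    Fold partitions and fold seeds are identical for both subsets (they
    derive from participant ids), so the d' difference is a paired
    comparison unaffected by fold-level Monte-Carlo noise.
    """
    item = loocv(features, targets, config, subset="item", h=h, correction=correction)
    associate = loocv(
        features, targets, config, subset="associate", h=h, correction=correction
    )
    return AblationResult(item=item, associate=associate)
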