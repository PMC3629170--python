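"""Patient-grouped Monte-Carlo double cross-validation and permutation tests.

Performance of the PLS-DA classifier is estimated with two nested
leave-20%-out loops: the outer loop (default 80 repetitions) holds out
whole patients and measures accuracy/sensitivity/specificity; the inner
loop (default 20 repetitions, run on the outer-training data only)
selects the number of latent variables.  All splits operate on
patients, never on samples, so data from one patient are always
confined to a single set — training, test, or validation — and VAST
scaling is refitted inside every loop on its training portion only.

Splits are Monte-Carlo: each repetition draws a fresh random
leave-group-out split rather than cycling a fixed partition.

Significance is assessed by permutation: class labels are shuffled
(sample-level by default, patient-block optional), the whole double CV
is re-run per permutation, and the p-value uses the add-one rule
``p = (1 + #{null >= observed}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemometrics import classify, fit_plsda, pls_predict

__all__ = [
    "DCVConfig",
    "DCVResult",
    "PermutationResult",
    "grouped_split",
    "select_lv",
    "double_cv",
    "performance",
    "permutation_test",
]


@dataclass(frozen=True)
class DCVConfig:
    """Double cross-validation settings (study defaults)."""

    outer_fraction: float = 0.20
    n_outer: int = 80
    inner_fraction: float = 0.20
    n_inner: int = 20
    max_lv: int = 15
    threshold: float = 0.5
    retry_limit: int = 100  # resamples allowed when a split loses a class
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.outer_fraction, self.inner_fraction):
            if not 0.0 < frac < 1.0:
                raise ValueError("fractions must be in (0, 1)")
        if self.n_outer < 1 or self.n_inner < 1 or self.max_lv < 1:
            raise ValueError("repetition counts and max_lv must be >= 1")


@dataclass
class DCVResult:
    """Outcome of one double-CV run."""

    chosen_A: np.ndarray  # (n_outer,) selected latent-variable count
    accuracy: np.ndarray  # (n_outer,)
    sensitivity: np.ndarray  # (n_outer,) NaN when no tumor sample held out
    specificity: np.ndarray  # (n_outer,)
    held_indices: list[np.ndarray]
    predictions: list[np.ndarray]  # continuous scores per repetition
    mean_accuracy: float = 0.0
    mean_sensitivity: float = 0.0
    mean_specificity: float = 0.0
    pooled_accuracy: float = 0.0
    pooled_sensitivity: float = 0.0
    pooled_specificity: float = 0.0


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float


def grouped_split(
    groups: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly hold out whole groups until >= ``fraction`` of samples is out.

    Groups (patients) are drawn in random order and added to the
    held-out side until its sample count first reaches
    ``fraction * n``; no group ever spans both sides.
    """
    groups = np.asarray(groups)
    n = groups.size
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups to split")
    if counts.max() > (1.0 - fraction) * n:
        big = uniq[np.argmax(counts)]
        raise ValueError(
            f"group {big!r} owns {counts.max()} of {n} samples; "
            f"no valid {fraction:.0%} grouped split exists"
        )
    target = fraction * n
    order = rng.permutation(uniq.size)
    held_groups = []
    total = 0
    for k in order:
        held_groups.append(uniq[k])
        total += counts[k]
        if total >= target:
            break
    held_mask = np.isin(groups, held_groups)
    return np.flatnonzero(~held_mask), np.flatnonzero(held_mask)


def performance(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from hard 0/1 labels.

    Sensitivity is tumor-class (1) recall, specificity non-involved (0)
    recall; a metric whose class is absent from ``y_true`` is NaN.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    acc = float(np.mean(y_true == y_pred))
    pos, neg = y_true == 1, y_true == 0
    sens = float(np.mean(y_pred[pos] == 1)) if pos.any() else float("nan")
    spec = float(np.mean(y_pred[neg] == 0)) if neg.any() else float("nan")
    return acc, sens, spec


def _class_split(
    y: np.ndarray,
    groups: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
    retry_limit: int,
    need_both_held: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Grouped split whose training side keeps both classes (bounded retries)."""
    for _ in range(retry_limit):
        tr, he = grouped_split(groups, fraction, rng)
        if np.unique(y[tr]).size == 2 and (
            not need_both_held or np.unique(y[he]).size == 2
        ):
            return tr, he
    raise RuntimeError(
        f"could not draw a class-preserving grouped split in {retry_limit} tries"
    )


def select_lv(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: DCVConfig,
    rng: np.random.Generator,
) -> int:
    """Choose the latent-variable count by inner grouped cross-validation.

    For A = 1..max_lv the mean validation accuracy over ``n_inner``
    grouped leave-``inner_fraction``-out splits is computed (VAST
    refitted on each inner-training set); the smallest A attaining the
    maximum is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    a_cap = min(config.max_lv, X.shape[0] - 1, X.shape[1])
    correct = np.zeros(a_cap)
    counted = np.zeros(a_cap)
    for _ in range(config.n_inner):
        tr, val = _class_split(
            y, groups, config.inner_fraction, rng, config.retry_limit
        )
        a_max = min(a_cap, tr.size - 1)
        model = fit_plsda(X[tr], y[tr], a_max, threshold=config.threshold)
        for a in range(1, model.A + 1):
            yhat = classify(
                pls_predict(model, X[val], A=a), threshold=config.threshold
            )
            correct[a - 1] += np.sum(yhat == y[val])
            counted[a - 1] += val.size
    usable = counted > 0
    acc = np.full(a_cap, -np.inf)
    acc[usable] = correct[usable] / counted[usable]
    return int(np.argmax(acc)) + 1  # argmax returns the first (smallest A) max


def double_cv(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: DCVConfig | None = None,
    rng: np.random.Generator | int | None = None,
    train_mask: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> DCVResult:
    """Patient-grouped Monte-Carlo double cross-validation.

    Each outer repetition holds out whole patients (~``outer_fraction``
    of samples), selects A by the inner loop on the remaining samples,
    fits the final VAST + PLS-DA model on them, and scores the held-out
    samples.  ``train_mask`` restricts which samples may ever be used
    for fitting (their patients still rotate through the held-out side
    and the masked samples are then scored); ``y_test`` supplies the
    labels used for evaluation when they differ from the training code.
    """
    config = config or DCVConfig()
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(config.seed if rng is None else rng)
    )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    n = X.shape[0]
    train_mask = (
        np.ones(n, dtype=bool) if train_mask is None else np.asarray(train_mask, bool)
    )
    y_eval = y if y_test is None else np.asarray(y_test, dtype=int)

    chosen = np.zeros(config.n_outer, dtype=int)
    acc = np.zeros(config.n_outer)
    sens = np.zeros(config.n_outer)
    spec = np.zeros(config.n_outer)
    held_list: list[np.ndarray] = []
    pred_list: list[np.ndarray] = []
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []

    for rep in range(config.n_outer):
        for _ in range(config.retry_limit):
            tr_all, held = grouped_split(groups, config.outer_fraction, rng)
            tr = tr_all[train_mask[tr_all]]
            if np.unique(y[tr]).size == 2:
                break
        else:
            raise RuntimeError("outer split kept losing a training class")
        assert not set(groups[tr]) & set(groups[held]), "patient leakage"
        a_star = select_lv(X[tr], y[tr], groups[tr], config, rng)
        model = fit_plsda(X[tr], y[tr], a_star, threshold=config.threshold)
        scores = pls_predict(model, X[held])
        labels = classify(scores, threshold=config.threshold)
        chosen[rep] = model.A
        acc[rep], sens[rep], spec[rep] = performance(y_eval[held], labels)
        held_list.append(held)
        pred_list.append(scores)
        pooled_true.append(y_eval[held])
        pooled_pred.append(labels)

    pa, ps, pc = performance(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    return DCVResult(
        chosen_A=chosen,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        held_indices=held_list,
        predictions=pred_list,
        mean_accuracy=float(np.nanmean(acc)),
        mean_sensitivity=float(np.nanmean(sens)),
        mean_specificity=float(np.nanmean(spec)),
        pooled_accuracy=pa,
        pooled_sensitivity=ps,
        pooled_specificity=pc,
    )


def _permute_labels(
    y: np.ndarray,
    groups: np.ndarray,
    rng: np.random.Generator,
    mode: str,
) -> np.ndarray:
    if mode == "samples":
        return rng.permutation(y)
    if mode != "patients":
        raise ValueError("permutation mode must be 'samples' or 'patients'")
    # patient-block shuffle: label blocks swap between patients with the
    # same sample count, preserving the within-patient label structure
    y_perm = y.copy()
    uniq, counts = np.unique(groups, return_counts=True)
    for size in np.unique(counts):
        members = uniq[counts == size]
        idx_blocks = [np.flatnonzero(groups == g) for g in members]
        order = rng.permutation(len(idx_blocks))
        for src, dst in zip(order, range(len(idx_blocks))):
            y_perm[idx_blocks[dst]] = y[idx_blocks[src]]
    return y_perm


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: DCVConfig | None = None,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
    mode: str = "samples",
    train_mask: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> PermutationResult:
    """Permutation test of the double-CV mean accuracy.

    Labels are shuffled ``n_perm`` times (patients still group the CV
    splits) and the full double CV — typically with reduced repetition
    counts in ``config`` — is re-run per permutation; the p-value uses
    the add-one rule, so the smallest attainable p is 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    config = config or DCVConfig()
    rng = (
        rng
        if isinstance(rng, np.random.Generator)
        else np.random.default_rng(config.seed if rng is None else rng)
    )
    observed = double_cv(
        X, y, groups, config, rng, train_mask=train_mask, y_test=y_test
    ).mean_accuracy
    null = np.empty(n_perm)
    for k in range(n_perm):
        y_perm = _permute_labels(np.asarray(y, int), np.asarray(groups), rng, mode)
        y_test_perm = y_perm if y_test is None else y_perm
        null[k] = double_cv(
            X, y_perm, groups, config, rng, train_mask=train_mask,
            y_test=y_test_perm,
        ).mean_accuracy
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return PermutationResult(observed=observed, null=null, p_value=p)
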