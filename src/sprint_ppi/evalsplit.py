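"""Park-Marcotte style C1/C2/C3 evaluation splits and metrics.

Performance measured on test pairs whose proteins were seen in training
does not generalize to the population, so held-out pairs are stratified by
how many of their proteins occur in the training positives: both (C1),
exactly one (C2), or none (C3).  Negatives are sampled uniformly from
pairs not known to interact (homo-pairs excluded), optionally under the
same class constraint, at a configurable negative:positive ratio
(default 1:1).  Metrics are ROC/PR curves and areas plus sensitivity,
precision and F1 at requested high specificity values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skmetrics

from .seqio import PPIList, Proteome

CLASS_LABELS = ("C1", "C2", "C3")


@dataclass
class EvalSplit:
    """One labelled train/test partition with sampled negatives."""

    train_pos: PPIList
    train_neg: PPIList
    test_pos: PPIList
    test_neg: PPIList
    label: str
    rng_seed: int

    def __post_init__(self) -> None:
        if self.label not in ("CV",) + CLASS_LABELS:
            raise ValueError(f"unknown split label {self.label!r}")


def classify_pair(pair: tuple[str, str], train_proteins: set[str]) -> str:
    """C1 if both proteins occur in training pairs, C2 if one, C3 if none."""
    hits = (pair[0] in train_proteins) + (pair[1] in train_proteins)
    return CLASS_LABELS[2 - hits]


def make_c123_split(ppis: PPIList, train_fraction: float = 10 / 11,
                    rng_seed: int = 0) -> tuple[PPIList, dict[str, PPIList]]:
    """Random train/test partition of positives, test pairs classed C1/C2/C3.

    The default train fraction 10/11 gives a 10:1 train:test ratio.  The
    split is deterministic given the seed.
    """
    if len(ppis) == 0:
        raise ValueError("cannot split an empty PPI list")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    pairs = list(ppis)  # sorted canonical order
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(pairs))
    n_train = int(round(train_fraction * len(pairs)))
    train = PPIList(pairs[i] for i in perm[:n_train])
    train_proteins = train.proteins()
    classes: dict[str, list] = {c: [] for c in CLASS_LABELS}
    for i in perm[n_train:]:
        pair = pairs[i]
        classes[classify_pair(pair, train_proteins)].append(pair)
    return train, {c: PPIList(v) for c, v in classes.items()}


def _available_negatives(n_in: int, n_out: int, known: PPIList,
                         train_proteins: set[str],
                         class_constraint: str | None) -> int:
    """Exact count of sampleable negative pairs under the constraint."""
    known_c1 = known_c2 = known_c3 = 0
    for a, b in known:
        if a == b:
            continue
        hits = (a in train_proteins) + (b in train_proteins)
        if hits == 2:
            known_c1 += 1
        elif hits == 1:
            known_c2 += 1
        else:
            known_c3 += 1
    if class_constraint == "C1":
        return n_in * (n_in - 1) // 2 - known_c1
    if class_constraint == "C2":
        return n_in * n_out - known_c2
    if class_constraint == "C3":
        return n_out * (n_out - 1) // 2 - known_c3
    total = n_in + n_out
    return total * (total - 1) // 2 - (known_c1 + known_c2 + known_c3)


def sample_negatives(proteome: Proteome | list[str], known: PPIList, n: int,
                     rng_seed: int = 0, class_constraint: str | None = None,
                     train_proteins: set[str] | None = None) -> PPIList:
    """Sample n unordered non-interacting pairs, disjoint from ``known``.

    Homo-pairs are excluded.  Under a C1/C2/C3 ``class_constraint`` the
    sampled pairs satisfy the same train-protein membership rule as
    positives of that class (``train_proteins`` required).  Raises when n
    exceeds the number of available pairs.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    ids = sorted(p.id for p in proteome) if isinstance(proteome, Proteome) \
        else sorted(proteome)
    if class_constraint is not None:
        if class_constraint not in CLASS_LABELS:
            raise ValueError(f"unknown class constraint {class_constraint!r}")
        if train_proteins is None:
            raise ValueError("class_constraint requires train_proteins")
    tp = train_proteins or set()
    in_pool = [p for p in ids if p in tp]
    out_pool = [p for p in ids if p not in tp]
    avail = _available_negatives(len(in_pool), len(out_pool), known, tp,
                                 class_constraint)
    if n > avail:
        raise ValueError(f"requested {n} negative pairs but only {avail} "
                         f"are available")
    rng = np.random.default_rng(rng_seed)

    def draw() -> tuple[str, str] | None:
        if class_constraint == "C1":
            pool_a = pool_b = in_pool
        elif class_constraint == "C3":
            pool_a = pool_b = out_pool
        elif class_constraint == "C2":
            pool_a, pool_b = in_pool, out_pool
        else:
            pool_a = pool_b = ids
        a = pool_a[rng.integers(len(pool_a))]
        b = pool_b[rng.integers(len(pool_b))]
        return None if a == b else (a, b)

    out = PPIList()
    attempts = 0
    max_attempts = 1000 * max(n, 1) + 10_000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:  # pragma: no cover - safety valve
            raise RuntimeError("negative sampling did not converge")
        pair = draw()
        if pair is None or pair in known or pair in out:
            continue
        out.add(*pair)
    return out


@dataclass
class RocPrResult:
    fpr: np.ndarray
    tpr: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    auroc: float
    aupr: float


def _check_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    return s, y


def roc_pr(scores, labels) -> RocPrResult:
    """ROC and PR curves with areas.

    Thresholds sweep the distinct scores descending; equal scores are
    grouped at one threshold.  AUROC is the trapezoid area over
    (FPR, TPR); AUPR uses step interpolation (average precision).
    """
    s, y = _check_labels(scores, labels)
    fpr, tpr, _ = skmetrics.roc_curve(y, s, drop_intermediate=False)
    precision, recall, _ = skmetrics.precision_recall_curve(y, s)
    auroc = float(skmetrics.auc(fpr, tpr))
    aupr = float(skmetrics.average_precision_score(y, s))
    return RocPrResult(fpr, tpr, recall[::-1], precision[::-1], auroc, aupr)


def metrics_at_specificity(scores, labels, spec_values) -> list[dict]:
    """Sensitivity, precision and F1 at each requested specificity.

    For each requested specificity s the smallest score threshold whose
    specificity is still >= s is chosen (prediction rule: score >=
    threshold), maximizing sensitivity subject to the constraint.
    """
    s, y = _check_labels(scores, labels)
    for v in spec_values:
        if not 0.0 < v <= 1.0:
            raise ValueError(f"specificity {v} outside (0, 1]")
    fpr, tpr, thresholds = skmetrics.roc_curve(y, s, drop_intermediate=False)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    rows = []
    for v in spec_values:
        ok = np.flatnonzero(fpr <= (1.0 - v) + 1e-12)
        i = int(ok[-1])  # smallest qualifying threshold: max sensitivity
        tp = tpr[i] * n_pos
        fp = fpr[i] * n_neg
        sens = float(tpr[i])
        prec = float(tp / (tp + fp)) if tp + fp > 0 else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
        rows.append({
            "specificity": float(v),
            "achieved_specificity": float(1.0 - fpr[i]),
            "threshold": float(thresholds[i]),
            "sensitivity": sens,
            "precision": prec,
            "f1": f1,
        })
    return rows


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic child seed, kept below 2**31."""
    return (master_seed * 1_000_003 + index * 7919 + 1) % (2**31 - 1)


def make_eval_splits(ppis: PPIList, proteome: Proteome | list[str],
                     train_fraction: float = 10 / 11, neg_ratio: float = 1.0,
                     rng_seed: int = 0) -> dict[str, EvalSplit]:
    """One C1/C2/C3 split set with class-matched sampled negatives."""
    train_pos, classes = make_c123_split(ppis, train_fraction, rng_seed)
    train_proteins = train_pos.proteins()
    splits = {}
    for i, label in enumerate(CLASS_LABELS):
        test_pos = classes[label]
        n_neg = int(round(neg_ratio * len(test_pos)))
        seed = derive_seed(rng_seed, i)
        test_neg = sample_negatives(proteome, ppis, n_neg, rng_seed=seed,
                                    class_constraint=label,
                                    train_proteins=train_proteins) \
            if n_neg else PPIList()
        splits[label] = EvalSplit(train_pos, PPIList(), test_pos, test_neg,
                                  label, seed)
    return splits


def repeated_eval_splits(ppis: PPIList, proteome: Proteome | list[str],
                         n_repeats: int = 40, train_fraction: float = 10 / 11,
                         neg_ratio: float = 1.0,
                         master_seed: int = 0) -> list[dict[str, EvalSplit]]:
    """Independent repeated splits (e.g. 40) with per-repeat derived seeds."""
    return [make_eval_splits(ppis, proteome, train_fraction, neg_ratio,
                             derive_seed(master_seed, 100 + r))
            for r in range(n_repeats)]
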