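"""Evaluation datasets and metrics for target-identification benchmarks.

Two compilation rules build evaluation sets from an annotation database:

- DS-I-like (similar-compound retrieval): keep proteins with at least 20
  associated compounds;
- DS-II-like (target identification): keep compounds with at least 5
  associated targets.

Metrics: recall / precision / F-score over predicted-vs-true target sets,
ROC AUC (Mann-Whitney formulation: the probability that a random positive
outscores a random negative, ties counted half), and Pearson correlation
for affinity regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from drift.targetpipe import InteractionRecord


@dataclass
class EvalDataset:
    records: list[InteractionRecord]
    kind: str  # "DS-I-like", "DS-II-like", "affinity"
    compiled_params: dict = field(default_factory=dict)
    n_kept: int = 0
    n_dropped: int = 0


@dataclass
class MetricReport:
    recall: float
    precision: float
    f_score: float
    auc: float | None = None
    pearson_r: float | None = None
    n: int = 0


def dataset_summary(n_molecules: int, n_proteins: int, n_interactions: int) -> dict:
    """Average interaction counts of an affinity dataset.

    Returns per-molecule and per-protein averages rounded to one decimal,
    as benchmark datasets are conventionally summarized.
    """
    if n_molecules <= 0 or n_proteins <= 0:
        raise ValueError("dataset must have molecules and proteins")
    return {
        "per_molecule": round(n_interactions / n_molecules, 1),
        "per_protein": round(n_interactions / n_proteins, 1),
    }


def compile_ds1(records: list[InteractionRecord], min_compounds: int = 20) -> EvalDataset:
    """Keep proteins that have at least ``min_compounds`` associated compounds."""
    by_target: dict[str, set[str]] = {}
    for r in records:
        by_target.setdefault(r.target_id, set()).add(r.compound_id)
    keep = {t for t, comps in by_target.items() if len(comps) >= min_compounds}
    kept = [r for r in records if r.target_id in keep]
    return EvalDataset(
        records=kept,
        kind="DS-I-like",
        compiled_params={"min_compounds": min_compounds},
        n_kept=len(keep),
        n_dropped=len(by_target) - len(keep),
    )


def compile_ds2(records: list[InteractionRecord], min_targets: int = 5) -> EvalDataset:
    """Keep compounds that have at least ``min_targets`` associated targets."""
    by_compound: dict[str, set[str]] = {}
    for r in records:
        by_compound.setdefault(r.compound_id, set()).add(r.target_id)
    keep = {c for c, targs in by_compound.items() if len(targs) >= min_targets}
    kept = [r for r in records if r.compound_id in keep]
    return EvalDataset(
        records=kept,
        kind="DS-II-like",
        compiled_params={"min_targets": min_targets},
        n_kept=len(keep),
        n_dropped=len(by_compound) - len(keep),
    )


def split(dataset: list, ratio: float = 0.8, seed: int = 0) -> tuple[list, list]:
    """Seeded shuffle split into train/test of sizes floor(n*ratio)/rest."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 examples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(n * ratio))
    train = [dataset[i] for i in order[:n_train]]
    test = [dataset[i] for i in order[n_train:]]
    return train, test


def score_retrieval(predicted: set[str], truth: set[str]) -> MetricReport:
    """Recall, precision and F-score of a predicted id set against the truth."""
    if not truth:
        raise ValueError("truth set must be nonempty")
    tp = len(set(predicted) & set(truth))
    recall = tp / len(truth)
    precision = tp / len(predicted) if predicted else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MetricReport(recall=recall, precision=precision, f_score=f, n=len(truth))


def roc_auc(scores: list[float], labels: list[int]) -> float:
    """ROC AUC via the Mann-Whitney rank statistic (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both positive and negative labels")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pearson(x: list[float], y: list[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("pearson needs matched vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
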