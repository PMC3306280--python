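"""Prognosis prediction from the overlap of top-module gene unions.

A training cohort is randomly split into two class-balanced halves.  Each
half, run through the full pipeline (networks -> modules -> ranking), yields
a top-N module gene union; the two unions' overlap percentage
(intersection over union) is the baseline OP_old(N).  A test tumour X is
then assumed recurrent and inserted into both halves; re-running the
pipeline gives OP_new(N).  The normalised overlap OP_new/OP_old, averaged
over a grid of N and over repeated random splits, is the prediction score
<OP>: a genuinely recurrent tumour reinforces the shared recurrence signal
and keeps the overlap high, while a non-recurrent tumour dilutes it.

``mode="full"`` recomputes networks and modules whenever X is added (the
faithful, expensive default); ``mode="rank_only"`` freezes each half's
modules and only recomputes t scores and the ranking — an approximation
that is orders of magnitude faster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .community import DEFAULT_MAX_SIZE, ModulePartition, discover_all
from .io import NON_RECURRENT, RECURRENT, ExpressionDataset, GeneSetCollection, InteractionNetwork
from .networks import build_networks
from .ranking import RankedModules, rank_modules, top_n_gene_union

logger = logging.getLogger(__name__)

DEFAULT_N_GRID = (100, 200, 300, 400, 500)
DEFAULT_N_SPLITS = 10


@dataclass(frozen=True)
class SplitPair:
    """One random class-balanced bisection of the training samples."""

    half_1: tuple[str, ...]
    half_2: tuple[str, ...]
    seed: int


@dataclass
class PredictionScore:
    """<OP> for one test tumour plus its per-(split, N) components."""

    sample_id: str
    components: dict[tuple[int, int], float]
    score: float


@dataclass
class EvaluationReport:
    """ROC evaluation of a batch of prediction scores (recurrent = positive)."""

    roc_points: pd.DataFrame
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    protocol: str
    scores: pd.Series


def overlap_percentage(genes_a: set, genes_b: set) -> float:
    """|a & b| / |a | b|; two empty sets give 0 with a warning."""
    a, b = set(genes_a), set(genes_b)
    union = a | b
    if not union:
        warnings.warn("overlap of two empty gene sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


def random_split(training_samples, labels: pd.Series, seed: int) -> SplitPair:
    """Split each class as evenly as possible between two halves.

    Odd class counts put the extra sample in half_1.  Fully determined by
    ``seed``; requires at least 4 samples of each class so every half keeps
    at least 2 per class.
    """
    samples = list(training_samples)
    by_class = {
        RECURRENT: [s for s in samples if labels.get(s) == RECURRENT],
        NON_RECURRENT: [s for s in samples if labels.get(s) == NON_RECURRENT],
    }
    for cls, members in by_class.items():
        if len(members) < 4:
            raise ValueError(
                f"class {cls!r} has {len(members)} training samples; need >= 4 to split"
            )
    rng = np.random.default_rng(seed)
    h1: list[str] = []
    h2: list[str] = []
    for cls in (NON_RECURRENT, RECURRENT):
        members = by_class[cls]
        order = [members[i] for i in rng.permutation(len(members))]
        cut = (len(order) + 1) // 2
        h1.extend(order[:cut])
        h2.extend(order[cut:])
    return SplitPair(half_1=tuple(h1), half_2=tuple(h2), seed=seed)


@dataclass
class PipelineParams:
    """Everything the per-half pipeline needs besides the data."""

    n_splits: int = DEFAULT_N_SPLITS
    n_grid: tuple[int, ...] = DEFAULT_N_GRID
    max_module_size: int = DEFAULT_MAX_SIZE
    mode: str = "full"
    equal_var: bool = False
    weighted_paths: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("full", "rank_only"):
            raise ValueError(f"mode must be 'full' or 'rank_only', got {self.mode!r}")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


def _rank_for(
    ds: ExpressionDataset,
    partition: ModulePartition,
    samples: list[str],
    extra_recurrent: str | None,
    params: PipelineParams,
) -> RankedModules:
    group_a = [s for s in samples if ds.labels.get(s) == RECURRENT]
    group_b = [s for s in samples if ds.labels.get(s) == NON_RECURRENT]
    if extra_recurrent is not None:
        group_a = group_a + [extra_recurrent]
    return rank_modules(partition, ds, group_a, group_b, equal_var=params.equal_var)


def _discover(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    ppi: InteractionNetwork,
    samples: list[str],
    params: PipelineParams,
    cache: dict | None,
) -> ModulePartition:
    nets = build_networks(ds, sets, ppi, samples, cache=cache)
    return discover_all(
        nets, max_size=params.max_module_size, weighted_paths=params.weighted_paths
    )


@dataclass
class _HalfContext:
    samples: list[str]
    partition: ModulePartition
    unions: dict[int, set]


@dataclass
class _SplitContext:
    split: SplitPair
    halves: list[_HalfContext]
    op_old: dict[int, float]


def build_split_contexts(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    ppi: InteractionNetwork,
    training_samples,
    params: PipelineParams,
    base_seed: int,
    cache: dict | None = None,
) -> list[_SplitContext]:
    """Precompute baseline halves, modules and OP_old for every random split."""
    contexts = []
    for i in range(params.n_splits):
        split = random_split(training_samples, ds.labels, seed=base_seed + i)
        halves = []
        for half in (split.half_1, split.half_2):
            samples = list(half)
            partition = _discover(ds, sets, ppi, samples, params, cache)
            ranked = _rank_for(ds, partition, samples, None, params)
            unions = {n: top_n_gene_union(ranked, n) for n in params.n_grid}
            halves.append(_HalfContext(samples=samples, partition=partition, unions=unions))
        op_old = {
            n: overlap_percentage(halves[0].unions[n], halves[1].unions[n])
            for n in params.n_grid
        }
        contexts.append(_SplitContext(split=split, halves=halves, op_old=op_old))
    return contexts


def _score_against_contexts(
    test_sample: str,
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    ppi: InteractionNetwork,
    contexts: list[_SplitContext],
    params: PipelineParams,
    cache: dict | None = None,
) -> PredictionScore:
    components: dict[tuple[int, int], float] = {}
    for ctx in contexts:
        new_unions = []
        for half in ctx.halves:
            samples_x = half.samples + [test_sample]
            if params.mode == "full":
                partition = _discover(ds, sets, ppi, samples_x, params, cache)
            else:
                partition = half.partition
            ranked = _rank_for(ds, partition, half.samples, test_sample, params)
            new_unions.append({n: top_n_gene_union(ranked, n) for n in params.n_grid})
        for n in params.n_grid:
            old = ctx.op_old[n]
            if old == 0.0:
                warnings.warn(
                    f"OP_old=0 for split seed {ctx.split.seed}, N={n}; component dropped"
                )
                continue
            new = overlap_percentage(new_unions[0][n], new_unions[1][n])
            components[(ctx.split.seed, n)] = new / old
    score = float(np.mean(list(components.values()))) if components else float("nan")
    return PredictionScore(sample_id=test_sample, components=components, score=score)


def predict_score(
    test_sample: str,
    ds: ExpressionDataset,
    training_samples,
    sets: GeneSetCollection,
    ppi: InteractionNetwork,
    params: PipelineParams | None = None,
    base_seed: int = 0,
    cache: dict | None = None,
) -> PredictionScore:
    """<OP> for one test tumour against the given training samples."""
    params = params or PipelineParams()
    if test_sample not in ds.values.columns:
        raise KeyError(f"test sample {test_sample!r} not in expression matrix")
    if test_sample in set(training_samples):
        raise ValueError(f"test sample {test_sample!r} overlaps the training set")
    contexts = build_split_contexts(
        ds, sets, ppi, training_samples, params, base_seed, cache
    )
    return _score_against_contexts(test_sample, ds, sets, ppi, contexts, params, cache)


def score_samples(
    test_samples,
    ds: ExpressionDataset,
    training_samples,
    sets: GeneSetCollection,
    ppi: InteractionNetwork,
    params: PipelineParams | None = None,
    base_seed: int = 0,
    cache: dict | None = None,
) -> list[PredictionScore]:
    """Score many test tumours against one training set, sharing the baselines."""
    params = params or PipelineParams()
    train = set(training_samples)
    overlap = [s for s in test_samples if s in train]
    if overlap:
        raise ValueError(f"test samples overlap the training set: {overlap}")
    contexts = build_split_contexts(
        ds, sets, ppi, training_samples, params, base_seed, cache
    )
    return [
        _score_against_contexts(s, ds, sets, ppi, contexts, params, cache)
        for s in test_samples
    ]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def roc_and_metrics(
    scores: list[PredictionScore],
    true_labels: pd.Series,
    protocol: str = "LOO",
) -> EvaluationReport:
    """ROC/AUC over all thresholds; operating point nearest (0, 1).

    Recurrent is the positive class.  Accuracy, sensitivity and specificity
    are read off at the ROC point minimising Euclidean distance to (0, 1)
    (ties resolved toward higher sensitivity).
    """
    ser = pd.Series({s.sample_id: s.score for s in scores})
    y_true = np.array([1 if true_labels[sid] == RECURRENT else 0 for sid in ser.index])
    if y_true.min() == y_true.max():
        raise ValueError("both classes must be present in true_labels")
    y_score = ser.to_numpy()
    fpr, tpr, thr = skmetrics.roc_curve(y_true, y_score, drop_intermediate=False)
    auc = float(skmetrics.auc(fpr, tpr))
    d2 = fpr**2 + (1.0 - tpr) ** 2
    best = np.lexsort((-tpr, d2))[0]
    n_pos = int(y_true.sum())
    n_neg = int(len(y_true) - n_pos)
    sens = float(tpr[best])
    spec = float(1.0 - fpr[best])
    acc = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return EvaluationReport(
        roc_points=roc_points,
        auc=auc,
        accuracy=float(acc),
        sensitivity=sens,
        specificity=spec,
        protocol=protocol,
        scores=ser,
    )


def evaluate_holdout(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    ppi: InteractionNetwork,
    training_samples,
    test_samples,
    params: PipelineParams | None = None,
    base_seed: int = 0,
    protocol: str = "holdout",
    cache: dict | None = None,
) -> EvaluationReport:
    """Score held-out labeled samples against a fixed training set."""
    scores = score_samples(
        test_samples, ds, training_samples, sets, ppi, params, base_seed, cache
    )
    return roc_and_metrics(scores, ds.labels, protocol=protocol)


def leave_one_out(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    ppi: InteractionNetwork,
    params: PipelineParams | None = None,
    base_seed: int = 0,
    cache: dict | None = None,
) -> EvaluationReport:
    """Each labeled sample scored with every other labeled sample as training."""
    params = params or PipelineParams()
    labeled = [s for s in ds.sample_ids if ds.labels[s] in (RECURRENT, NON_RECURRENT)]
    for cls in (RECURRENT, NON_RECURRENT):
        n = sum(1 for s in labeled if ds.labels[s] == cls)
        if n < 5:
            raise ValueError(f"class {cls!r} has {n} labeled samples; need >= 5 for LOO")
    scores = []
    for s in labeled:
        training = [t for t in labeled if t != s]
        scores.append(
            predict_score(s, ds, training, sets, ppi, params, base_seed, cache)
        )
    return roc_and_metrics(scores, ds.labels, protocol="LOO")


def fixed_train_validation(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    ppi: InteractionNetwork,
    train_size: int,
    n_repeats: int = 5,
    params: PipelineParams | None = None,
    base_seed: int = 0,
    cache: dict | None = None,
) -> tuple[list[EvaluationReport], dict]:
    """Repeatedly draw a fixed-size training set and score all remaining samples.

    Returns the per-repeat reports and a summary of mean/min/max for every
    metric.  A draw lacking 4 samples of either class (the split minimum) is
    redrawn, up to 100 times.
    """
    params = params or PipelineParams()
    labeled = [s for s in ds.sample_ids if ds.labels[s] in (RECURRENT, NON_RECURRENT)]
    if train_size >= len(labeled):
        raise ValueError(
            f"train_size {train_size} must be smaller than the {len(labeled)} labeled samples"
        )
    rng = np.random.default_rng(base_seed)
    reports: list[EvaluationReport] = []
    for rep in range(n_repeats):
        training = None
        for attempt in range(100):
            draw = [labeled[i] for i in rng.permutation(len(labeled))[:train_size]]
            counts = {
                cls: sum(1 for s in draw if ds.labels[s] == cls)
                for cls in (RECURRENT, NON_RECURRENT)
            }
            if min(counts.values()) >= 4:
                training = draw
                break
            logger.info("repeat %d: redraw (class counts %s)", rep, counts)
        if training is None:
            raise ValueError("could not draw a training set with >= 4 samples per class")
        test = [s for s in labeled if s not in set(training)]
        reports.append(
            evaluate_holdout(
                ds, sets, ppi, training, test, params,
                base_seed=base_seed + 1000 * (rep + 1),
                protocol=f"train_{train_size}",
                cache=cache,
            )
        )
    summary = {}
    for metric in ("auc", "accuracy", "sensitivity", "specificity"):
        vals = [getattr(r, metric) for r in reports]
        summary[metric] = {
            "mean": float(np.mean(vals)),
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
        }
    return reports, summary
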