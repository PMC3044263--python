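"""Leave-one-out validation, SE/SP/PPV metrics, CV selection, robustness.

The leave-one-out protocol removes each known gene of a pathway in turn,
ranks the whole target genome against the remaining seeds, and counts the
removed gene as recovered when it appears in the top-gamma output. Per
pathway: TP + FN = |G(P)|; FP is the number of distinct non-pathway genes
appearing in any of the pathway's top-gamma outputs (pooled over the
pathway's LOO runs); TN is every other target-genome gene. Averages over
pathways are unweighted arithmetic means, with pathways whose metric is
undefined excluded from that metric's mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import Params, Pathway, RankedCandidate, ValidationError

logger = logging.getLogger(__name__)

#: rank_fn(seed_set, params) -> ranked candidates over the whole target genome
RankFn = Callable[[frozenset, Params], Sequence[RankedCandidate]]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP,
            self.TN + other.TN, self.FN + other.FN,
        )

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class PathwayResult:
    counts: ConfusionCounts
    SE: Optional[float]
    SP: Optional[float]
    PPV: Optional[float]


@dataclass(frozen=True)
class EvalReport:
    per_pathway: Mapping[str, PathwayResult]
    SE_avg: Optional[float]
    SP_avg: Optional[float]
    PPV_avg: Optional[float]

    @property
    def N(self) -> int:
        return len(self.per_pathway)


@dataclass(frozen=True)
class SweepPoint:
    param_name: str
    change_rate: float
    value: float
    ppv: float
    ppv_change_rate: float


def confusion_metrics(
    c: ConfusionCounts,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(SE, SP, PPV); a metric with a zero denominator is None, never 0."""
    se = c.TP / (c.TP + c.FN) if c.TP + c.FN > 0 else None
    sp = c.TN / (c.TN + c.FP) if c.TN + c.FP > 0 else None
    ppv = c.TP / (c.TP + c.FP) if c.TP + c.FP > 0 else None
    return se, sp, ppv


def leave_one_out(
    pathway: Pathway,
    rank_fn: RankFn,
    params: Params,
    n_target_genes: int,
) -> ConfusionCounts:
    """Confusion counts of the leave-one-out protocol for one pathway.

    Requires |G(P)| >= 2 (a singleton leaves no seeds when held out).
    """
    if pathway.size < 2:
        raise ValidationError(
            f"pathway {pathway.pathway_id}: leave-one-out needs >= 2 genes"
        )
    if n_target_genes < pathway.size:
        raise ValidationError("n_target_genes smaller than the pathway")
    tp = 0
    false_hits: set = set()
    for held_out in sorted(pathway.genes):
        seeds = frozenset(pathway.genes - {held_out})
        ranked = rank_fn(seeds, params)
        top = {c.gene for c in ranked}
        if held_out in top:
            tp += 1
        false_hits.update(top - pathway.genes)
    fn = pathway.size - tp
    fp = len(false_hits)
    tn = n_target_genes - pathway.size - fp
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _mean_defined(values: Iterable[Optional[float]]) -> Optional[float]:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def evaluate_pathways(
    pathways: Sequence[Pathway],
    rank_fn: RankFn,
    params: Params,
    n_target_genes: int,
) -> EvalReport:
    """Per-pathway metrics plus unweighted means over evaluable pathways.

    Singleton pathways are skipped with a logged reason; a metric undefined
    for some pathway is excluded from that metric's mean (N adjusted).
    """
    per: dict[str, PathwayResult] = {}
    for pw in pathways:
        if pw.size < 2:
            logger.info(
                "pathway %s skipped: %d gene(s), leave-one-out needs >= 2",
                pw.pathway_id, pw.size,
            )
            continue
        counts = leave_one_out(pw, rank_fn, params, n_target_genes)
        se, sp, ppv = confusion_metrics(counts)
        per[pw.pathway_id] = PathwayResult(counts, se, sp, ppv)
    if not per:
        raise ValidationError("no evaluable pathway (all singletons?)")
    return EvalReport(
        per_pathway=per,
        SE_avg=_mean_defined(r.SE for r in per.values()),
        SP_avg=_mean_defined(r.SP for r in per.values()),
        PPV_avg=_mean_defined(r.PPV for r in per.values()),
    )


def _grid_sort_key(params: Params) -> tuple:
    return (params.alpha, params.beta, params.system_error, params.K,
            params.K_phylo, params.gamma)


def ten_fold_cv(
    pathways: Sequence[Pathway],
    grid: Sequence[Params],
    rank_fn: RankFn,
    n_target_genes: int,
    seed: int,
    n_folds: int = 10,
) -> Params:
    """Select the grid point with the best mean test-fold PPV.

    Pathways are shuffled by a generator seeded with `seed` and split into
    `n_folds` near-equal folds; each grid point is scored by the average of
    its test-fold PPV means. Ties go to the smaller parameter values.
    """
    if not grid:
        raise ValidationError("empty parameter grid")
    pathways = [p for p in pathways if p.size >= 2]
    if not pathways:
        raise ValidationError("no evaluable pathway")
    if len(pathways) < n_folds:
        logger.warning(
            "only %d evaluable pathways; reducing fold count from %d",
            len(pathways), n_folds,
        )
        n_folds = len(pathways)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pathways))
    folds = [
        [pathways[i] for i in order[f::n_folds]] for f in range(n_folds)
    ]

    best: Optional[tuple] = None
    for point in grid:
        # per-pathway PPV is fold-independent, so compute each pathway once
        ppv_by_id: dict[str, Optional[float]] = {}
        for pw in pathways:
            counts = leave_one_out(pw, rank_fn, point, n_target_genes)
            _, _, ppv = confusion_metrics(counts)
            ppv_by_id[pw.pathway_id] = ppv
        fold_means = [
            _mean_defined(ppv_by_id[p.pathway_id] for p in fold)
            for fold in folds
        ]
        score = _mean_defined(fold_means)
        score = -math.inf if score is None else score
        key = (-score, _grid_sort_key(point))
        if best is None or key < best[0]:
            best = (key, point)
    return best[1]


def robustness_sweep(
    pathways: Sequence[Pathway],
    rank_fn: RankFn,
    base: Params,
    param_name: str,
    rates: Sequence[float],
    n_target_genes: int,
) -> list[SweepPoint]:
    """PPV change rate when one parameter is scaled by (1 + r), r in [-1, 1].

    A change rate of 0 reproduces the baseline exactly (the baseline report
    is reused, not recomputed).
    """
    if param_name not in ("alpha", "beta", "system_error"):
        raise ValidationError(f"cannot sweep parameter {param_name!r}")
    for r in rates:
        if not -1.0 <= r <= 1.0:
            raise ValidationError(f"change rate {r} outside [-1, 1]")
    x0 = getattr(base, param_name)
    baseline = evaluate_pathways(pathways, rank_fn, base, n_target_genes)
    if baseline.PPV_avg is None or baseline.PPV_avg == 0:
        raise ValidationError("baseline PPV undefined or zero; cannot sweep")
    out = []
    for r in rates:
        if r == 0:
            ppv = baseline.PPV_avg
            x = x0
        else:
            x = x0 * (1.0 + r)
            report = evaluate_pathways(
                pathways, rank_fn, base.with_(**{param_name: x}), n_target_genes
            )
            ppv = report.PPV_avg
            if ppv is None:
                raise ValidationError(
                    f"PPV undefined at {param_name}={x} (rate {r})"
                )
        out.append(
            SweepPoint(
                param_name, r, x, ppv,
                (ppv - baseline.PPV_avg) / baseline.PPV_avg,
            )
        )
    return out
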