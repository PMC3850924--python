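"""Validation protocol: site evaluation, site combination, subset selection.

The protocol tunes the model on the validation set V only:

1. *Site evaluation* — each of the ten stimulation sites is evaluated
   separately across a grid of training sizes (10 random balanced subsets
   per size, one when the size equals the full training set); a site's
   "best performance" is its maximum mean rate over sizes.  Sites below a
   75% threshold are discarded.
2. *Site combination* — all non-empty subsets of the retained sites are
   evaluated on the same grid; signals from all sites in a set pool into
   one vote.  The winning set maximizes best performance, with ties broken
   by the higher mean rate across the grid, then by the smaller set.
3. *Training-subset selection* — for the winning site set, the subset with
   the highest r wins; ties prefer the smaller gap |r_h - r_p|, then the
   smaller draw index t, then the smaller training size.

The test set TE must never enter any of these stages; every evaluation
verifies training/evaluation disjointness and can record itself in an
audit log so a full run can prove TE was touched exactly once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classifier import DEFAULT_K, predict_subject, train_model
from .data_preparation import TrainingSubset, sample_training_subsets
from .errors import ProtocolError
from .evaluation import RateTriple, prediction_rates
from .features import DEFAULT_N_BINS
from .signal_model import ReflexWindow, Subject

__all__ = [
    "SITE_RATE_THRESHOLD",
    "DEFAULT_TRAINING_SIZES",
    "AuditLog",
    "GridCell",
    "ValidationReport",
    "evaluate_configuration",
    "evaluate_size_grid",
    "rank_sites",
    "enumerate_site_combinations",
    "select_best_site_set",
    "select_best_subset",
    "site_evaluation",
    "combination_evaluation",
    "subset_search",
]

#: Retention threshold (percent) for single-site best performance.
SITE_RATE_THRESHOLD = 75.0

#: Per-group training sizes explored by the validation grid.
DEFAULT_TRAINING_SIZES = (12, 24, 32, 48, 60, 80, 100)

DEFAULT_N_SUBSETS = 10


@dataclass
class AuditLog:
    """Record of every model evaluation, for protocol-hygiene checks."""

    entries: list[dict] = field(default_factory=list)

    def record(self, stage: str, partition: str, n_train: int, n_eval: int) -> None:
        self.entries.append(
            {
                "stage": stage,
                "partition": partition,
                "n_train": n_train,
                "n_eval": n_eval,
            }
        )

    def accesses(self, partition: str) -> int:
        return sum(1 for e in self.entries if e["partition"] == partition)


@dataclass(frozen=True)
class GridCell:
    """One evaluated configuration of the validation grid."""

    site_ids: tuple[int, ...]
    size_per_group: int
    subset_index: int
    rates: RateTriple


@dataclass
class ValidationReport:
    """All grid cells plus the selections made from them."""

    cells: list[GridCell] = field(default_factory=list)
    site_best_rates: dict[int, float] = field(default_factory=dict)
    retained_sites: list[int] = field(default_factory=list)
    selected_sites: tuple[int, ...] = ()
    selected_subset: TrainingSubset | None = None
    selected_subset_rates: RateTriple | None = None
    imbalance_flags: list[dict] = field(default_factory=list)

    def mean_rate(self, site_ids: tuple[int, ...], size: int) -> float:
        """Mean r over the subsets evaluated at (site set, size)."""
        rates = [
            c.rates.r
            for c in self.cells
            if c.site_ids == site_ids and c.size_per_group == size
        ]
        if not rates:
            raise KeyError(f"no cells for sites {site_ids}, size {size}")
        return float(np.mean(rates))

    def table(self, site_sets: Sequence[tuple[int, ...]], sizes: Sequence[int]):
        """Mean-rate table (site set x size) plus the best-performance column."""
        import pandas as pd

        rows = []
        for ss in site_sets:
            row: dict = {"sites": "{" + ",".join(map(str, ss)) + "}"}
            means = []
            for size in sizes:
                m = self.mean_rate(ss, size)
                row[f"({size},{size})"] = m
                means.append(m)
            row["best"] = max(means)
            rows.append(row)
        return pd.DataFrame(rows).sort_values("best", ascending=False, ignore_index=True)


def evaluate_configuration(
    training_subjects: Sequence[Subject],
    eval_subjects: Sequence[Subject],
    site_ids: Sequence[int],
    k: int = DEFAULT_K,
    n_bins: int = DEFAULT_N_BINS,
    window: ReflexWindow | None = None,
    rectify: bool = False,
    audit: AuditLog | None = None,
    stage: str = "validation",
    partition: str = "V",
    predictions_out: list | None = None,
) -> RateTriple:
    """Train on one subject set, predict another, return prediction rates.

    Fits the amplitude range and subject profiles on ``training_subjects``
    only, classifies every subject in ``eval_subjects``, and computes
    (r, r_h, r_p).  Training and evaluation subjects must be disjoint;
    an overlap raises :class:`ProtocolError`.
    """
    train_ids = {s.subject_id for s in training_subjects}
    overlap = train_ids & {s.subject_id for s in eval_subjects}
    if overlap:
        raise ProtocolError(
            f"training and evaluation subjects overlap: {sorted(overlap)[:5]}"
        )
    if window is None:
        window = ReflexWindow()
    model = train_model(
        training_subjects, site_ids=site_ids, window=window, k=k, n_bins=n_bins,
        rectify=rectify,
    )
    pairs = []
    for s in eval_subjects:
        pred = predict_subject(s, model, window)
        if predictions_out is not None:
            predictions_out.append(pred)
        pairs.append((s.group, pred.predicted_label))
    if audit is not None:
        audit.record(stage, partition, len(training_subjects), len(eval_subjects))
    return prediction_rates(pairs)


def evaluate_size_grid(
    training_pool: Sequence[Subject],
    eval_subjects: Sequence[Subject],
    site_sets: Sequence[Sequence[int]],
    sizes: Sequence[int] = DEFAULT_TRAINING_SIZES,
    n_subsets: int = DEFAULT_N_SUBSETS,
    seed: int = 0,
    k: int = DEFAULT_K,
    n_bins: int = DEFAULT_N_BINS,
    window: ReflexWindow | None = None,
    rectify: bool = False,
    audit: AuditLog | None = None,
    stage: str = "site-evaluation",
    partition: str = "V",
) -> list[GridCell]:
    """Evaluate site sets over the size x subset grid on one eval set.

    For every training size, balanced subsets are drawn once from the pool
    and reused across all site sets, so sites are compared on identical
    training material.  Subset draws are seeded per size (derived from
    ``seed``) and independent of the site sets evaluated.
    """
    pool_by_id = {s.subject_id: s for s in training_pool}
    cells: list[GridCell] = []
    for size_i, size in enumerate(sizes):
        subsets = sample_training_subsets(
            training_pool, size_per_group=size, n_subsets=n_subsets,
            seed=seed + 1009 * size_i,
        )
        for site_set in site_sets:
            ss = tuple(sorted(site_set))
            for subset in subsets:
                tr = [pool_by_id[sid] for sid in subset.subject_ids]
                rates = evaluate_configuration(
                    tr, eval_subjects, ss, k=k, n_bins=n_bins, window=window,
                    rectify=rectify, audit=audit, stage=stage,
                    partition=partition,
                )
                cells.append(
                    GridCell(
                        site_ids=ss,
                        size_per_group=size,
                        subset_index=subset.index,
                        rates=rates,
                    )
                )
    return cells


def rank_sites(
    per_site_best_rates: Mapping[int, float],
    threshold: float = SITE_RATE_THRESHOLD,
) -> list[int]:
    """Sites whose best prediction rate reaches the threshold, best first."""
    if not per_site_best_rates:
        raise ValueError("no site rates supplied")
    for site, rate in per_site_best_rates.items():
        if not 0 <= rate <= 100:
            raise ValueError(f"site {site}: rate {rate} outside [0, 100]")
    retained = [
        site for site, rate in per_site_best_rates.items() if rate >= threshold
    ]
    return sorted(retained, key=lambda s: (-per_site_best_rates[s], s))


def enumerate_site_combinations(
    retained_sites: Sequence[int],
) -> list[tuple[int, ...]]:
    """All non-empty subsets of the retained sites, singletons included."""
    sites = sorted(set(retained_sites))
    if not sites:
        raise ValueError("no retained sites to combine")
    combos: list[tuple[int, ...]] = []
    for size in range(1, len(sites) + 1):
        combos.extend(itertools.combinations(sites, size))
    return combos


def select_best_site_set(
    best_performance: Mapping[tuple[int, ...], float],
    mean_across_sizes: Mapping[tuple[int, ...], float],
) -> tuple[int, ...]:
    """Winning site set: max best performance, then max grid-wide mean,
    then fewer sites, then lexicographic."""
    if not best_performance:
        raise ValueError("no candidate site sets")
    return min(
        best_performance,
        key=lambda ss: (
            -best_performance[ss],
            -mean_across_sizes[ss],
            len(ss),
            ss,
        ),
    )


def select_best_subset(
    candidates: Sequence[tuple[TrainingSubset, RateTriple]],
) -> TrainingSubset:
    """Best training subset: max r, then min |r_h - r_p|, then min t,
    then the smaller training size."""
    if not candidates:
        raise ValueError("no candidate subsets")
    best, _ = min(
        candidates,
        key=lambda c: (
            -c[1].r,
            c[1].rate_gap,
            c[0].index,
            c[0].size_per_group,
        ),
    )
    return best


# ---------------------------------------------------------------------------
# Protocol stages
# ---------------------------------------------------------------------------

def site_evaluation(
    training_pool: Sequence[Subject],
    val_subjects: Sequence[Subject],
    sites: Sequence[int] = tuple(range(1, 11)),
    sizes: Sequence[int] = DEFAULT_TRAINING_SIZES,
    n_subsets: int = DEFAULT_N_SUBSETS,
    seed: int = 0,
    threshold: float = SITE_RATE_THRESHOLD,
    k: int = DEFAULT_K,
    n_bins: int = DEFAULT_N_BINS,
    window: ReflexWindow | None = None,
    rectify: bool = False,
    audit: AuditLog | None = None,
    report: ValidationReport | None = None,
) -> list[int]:
    """Stage 1: evaluate each site separately; retain those above threshold.

    A site's best performance is the maximum over training sizes of its
    mean rate across the random subsets at that size.
    """
    if report is None:
        report = ValidationReport()
    cells = evaluate_size_grid(
        training_pool, val_subjects, [(s,) for s in sites], sizes=sizes,
        n_subsets=n_subsets, seed=seed, k=k, n_bins=n_bins, window=window,
        rectify=rectify, audit=audit, stage="site-evaluation",
    )
    report.cells.extend(cells)
    best: dict[int, float] = {}
    for site in sites:
        best[site] = max(report.mean_rate((site,), size) for size in sizes)
    report.site_best_rates = best
    report.retained_sites = rank_sites(best, threshold)
    return report.retained_sites


def combination_evaluation(
    training_pool: Sequence[Subject],
    val_subjects: Sequence[Subject],
    retained_sites: Sequence[int],
    sizes: Sequence[int] = DEFAULT_TRAINING_SIZES,
    n_subsets: int = DEFAULT_N_SUBSETS,
    seed: int = 0,
    k: int = DEFAULT_K,
    n_bins: int = DEFAULT_N_BINS,
    window: ReflexWindow | None = None,
    rectify: bool = False,
    audit: AuditLog | None = None,
    report: ValidationReport | None = None,
) -> tuple[int, ...]:
    """Stage 2: evaluate all combinations of retained sites; pick the winner.

    Singleton results from stage 1 are reused when available in the report
    rather than recomputed.
    """
    if report is None:
        report = ValidationReport()
    combos = enumerate_site_combinations(retained_sites)
    have = {c.site_ids for c in report.cells}
    todo = [ss for ss in combos if ss not in have]
    cells = evaluate_size_grid(
        training_pool, val_subjects, todo, sizes=sizes, n_subsets=n_subsets,
        seed=seed, k=k, n_bins=n_bins, window=window, rectify=rectify,
        audit=audit, stage="site-combination",
    )
    report.cells.extend(cells)
    best_perf = {
        ss: max(report.mean_rate(ss, size) for size in sizes) for ss in combos
    }
    grid_mean = {
        ss: float(np.mean([report.mean_rate(ss, size) for size in sizes]))
        for ss in combos
    }
    report.selected_sites = select_best_site_set(best_perf, grid_mean)
    return report.selected_sites


def subset_search(
    training_pool: Sequence[Subject],
    val_subjects: Sequence[Subject],
    site_ids: Sequence[int],
    sizes: Sequence[int] = DEFAULT_TRAINING_SIZES,
    n_subsets: int = DEFAULT_N_SUBSETS,
    seed: int = 0,
    k: int = DEFAULT_K,
    n_bins: int = DEFAULT_N_BINS,
    window: ReflexWindow | None = None,
    rectify: bool = False,
    audit: AuditLog | None = None,
    report: ValidationReport | None = None,
) -> tuple[TrainingSubset, RateTriple]:
    """Stage 3: pick the best training subset for the selected site set.

    Re-draws the same seeded subsets used by the grid, evaluates each on V,
    applies the lexicographic selection rule, and flags candidates whose
    healthy/patient rate gap exceeds 30 percentage points for human review.
    """
    if report is None:
        report = ValidationReport()
    pool_by_id = {s.subject_id: s for s in training_pool}
    ss = tuple(sorted(site_ids))
    candidates: list[tuple[TrainingSubset, RateTriple]] = []
    for size_i, size in enumerate(sizes):
        subsets = sample_training_subsets(
            training_pool, size_per_group=size, n_subsets=n_subsets,
            seed=seed + 1009 * size_i,
        )
        for subset in subsets:
            cached = next(
                (
                    c.rates
                    for c in report.cells
                    if c.site_ids == ss
                    and c.size_per_group == size
                    and c.subset_index == subset.index
                ),
                None,
            )
            if cached is None:
                tr = [pool_by_id[sid] for sid in subset.subject_ids]
                cached = evaluate_configuration(
                    tr, val_subjects, ss, k=k, n_bins=n_bins, window=window,
                    rectify=rectify, audit=audit, stage="subset-search",
                )
                report.cells.append(
                    GridCell(ss, size, subset.index, cached)
                )
            candidates.append((subset, cached))
            if cached.rate_gap > 30.0:
                report.imbalance_flags.append(
                    {
                        "size_per_group": size,
                        "subset_index": subset.index,
                        "r": cached.r,
                        "r_h": cached.r_h,
                        "r_p": cached.r_p,
                    }
                )
    best = select_best_subset(candidates)
    rates = next(r for s, r in candidates if s is best)
    report.selected_subset = best
    report.selected_subset_rates = rates
    return best, rates
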