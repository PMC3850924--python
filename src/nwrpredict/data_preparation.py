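"""Demographically balanced data splitting.

The model-building protocol divides a cohort into three disjoint sets —
training (TR), validation (V) and test (TE) — under two restrictions:
healthy subjects and patients are balanced in every set, and within each
group the subjects are evenly distributed over gender (G1 male / G2 female)
and age class (A1: age < 50 y, A2: age >= 50 y).  The four age x gender
strata S1..S4 therefore each contribute exactly n/4 of any selected set of
n subjects per group.

Training subsets of prescribed sizes (12, 24, 32, 48, 60, 80, 100 per
group) are then drawn from TR, each obeying the same n/4-per-stratum rule,
to study how the number of training subjects affects prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import json

import numpy as np

from .errors import CapacityError, ConfigurationError, IntegrityError
from .signal_model import Cohort, Subject

__all__ = [
    "PARTITIONS",
    "AGE_CUT_YEARS",
    "StratumKey",
    "SplitAssignment",
    "TrainingSubset",
    "stratum_key",
    "stratified_split",
    "sample_training_subsets",
    "write_split",
    "read_split",
]

PARTITIONS = ("TR", "V", "TE")

#: Age boundary between the young (A1) and elder (A2) classes; exactly-50
#: subjects fall in A2.
AGE_CUT_YEARS = 50.0


@dataclass(frozen=True, order=True)
class StratumKey:
    """One cell of the group x age-class x gender stratification."""

    group: str  # "h" | "p"
    age_class: str  # "A1" | "A2"
    gender: str  # "G1" | "G2"


def stratum_key(subject: Subject) -> StratumKey:
    age_class = "A1" if subject.age < AGE_CUT_YEARS else "A2"
    return StratumKey(group=subject.group, age_class=age_class, gender=subject.gender)


@dataclass
class SplitAssignment:
    """Mapping subject_id -> partition label in {TR, V, TE}."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        bad = {p for p in self.assignment.values() if p not in PARTITIONS}
        if bad:
            raise ValueError(f"unknown partition labels: {sorted(bad)}")

    def ids(self, partition: str) -> list[str]:
        if partition not in PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return [sid for sid, p in self.assignment.items() if p == partition]

    def __getitem__(self, subject_id: str) -> str:
        return self.assignment[subject_id]

    def __len__(self) -> int:
        return len(self.assignment)


@dataclass(frozen=True)
class TrainingSubset:
    """One balanced draw of training subjects.

    ``size_per_group`` subjects are taken from each of the healthy and
    patient groups, a quarter of them from every age x gender stratum.
    ``index`` is the 1-based draw number t.
    """

    index: int
    size_per_group: int
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.size_per_group % 4 != 0:
            raise ConfigurationError(
                f"size_per_group must be divisible by 4, got {self.size_per_group}"
            )
        if len(self.subject_ids) != 2 * self.size_per_group:
            raise ValueError(
                f"subset holds {len(self.subject_ids)} ids, expected "
                f"{2 * self.size_per_group}"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise IntegrityError("subset contains duplicate subject ids")


def _cells(subjects: Iterable[Subject]) -> dict[StratumKey, list[Subject]]:
    cells: dict[StratumKey, list[Subject]] = {}
    for s in subjects:
        cells.setdefault(stratum_key(s), []).append(s)
    return cells


def _largest_remainder_allocation(
    cell_size: int, ratios: Sequence[float], cell: StratumKey
) -> list[int]:
    """Integer partition counts for one stratum cell.

    Rounds ratio x cell_size by the largest-remainder method.  Raises a
    ConfigurationError when a partition with a positive ratio would end up
    empty in this cell — the split cannot honour the stratification.
    """
    raw = [r * cell_size for r in ratios]
    counts = [int(np.floor(x)) for x in raw]
    remainder = cell_size - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    for i, (r, c) in enumerate(zip(ratios, counts)):
        if r > 0 and c == 0:
            raise ConfigurationError(
                f"stratum {cell}: ratio {r:g} of {cell_size} subjects allocates "
                f"zero to partition {PARTITIONS[i]}"
            )
    return counts


def stratified_split(
    cohort: Cohort,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Split a balanced cohort into TR / V / TE.

    Every group x age-class x gender cell is allocated independently, so the
    partitions inherit exact group balance and even demographic coverage.
    The assignment is a deterministic function of the cohort order and the
    seed: within each cell, subjects are shuffled with a seeded generator
    and contiguous blocks go to TR, V and TE.

    A 280-subject balanced cohort at ratios (0.70, 0.15, 0.15) yields
    |TR| = 200, |V| = 40, |TE| = 40 with 25/5/5 subjects per cell.

    Raises
    ------
    ConfigurationError
        If ratios do not sum to 1, the cohort's stratum cells are not all
        the same size (unbalanced cohort), or the allocation would leave a
        requested partition empty in some cell.
    """
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ConfigurationError(f"need three non-negative ratios, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError(f"ratios must sum to 1, got {sum(ratios)}")

    cells = _cells(cohort)
    if len(cohort) == 0:
        return SplitAssignment({})
    sizes = {key: len(v) for key, v in cells.items()}
    if len(set(sizes.values())) > 1 or len(cells) != 8:
        raise ConfigurationError(
            "cohort is not balanced over group x age-class x gender: "
            f"cell sizes {dict(sorted((str(k), v) for k, v in sizes.items()))}"
        )

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for key in sorted(cells):
        members = cells[key]
        counts = _largest_remainder_allocation(len(members), ratios, key)
        perm = rng.permutation(len(members))
        shuffled = [members[i] for i in perm]
        cursor = 0
        for partition, n in zip(PARTITIONS, counts):
            for s in shuffled[cursor : cursor + n]:
                assignment[s.subject_id] = partition
            cursor += n
    # report in cohort order
    return SplitAssignment(
        {s.subject_id: assignment[s.subject_id] for s in cohort}
    )


def sample_training_subsets(
    training_subjects: Sequence[Subject],
    size_per_group: int,
    n_subsets: int = 10,
    seed: int = 0,
) -> list[TrainingSubset]:
    """Draw balanced training subsets of ``size_per_group`` subjects per group.

    Each draw takes exactly ``size_per_group / 4`` subjects from every
    age x gender stratum of each group, sampled without replacement within
    the draw and independently across draws.  When ``size_per_group``
    equals the full per-group training size there is only one possible
    subset, and a single draw (the full set) is returned.

    Raises
    ------
    ConfigurationError
        If ``size_per_group`` is not divisible by 4.
    CapacityError
        If some stratum holds fewer subjects than required.
    """
    if size_per_group % 4 != 0:
        raise ConfigurationError(
            f"size_per_group must be divisible by 4 "
            f"(one quarter per stratum), got {size_per_group}"
        )
    if n_subsets < 1:
        raise ConfigurationError(f"n_subsets must be >= 1, got {n_subsets}")

    cells = _cells(training_subjects)
    per_cell = size_per_group // 4
    keys = sorted(cells)
    for key in keys:
        if len(cells[key]) < per_cell:
            raise CapacityError(
                f"stratum {key}: requested {per_cell} subjects but only "
                f"{len(cells[key])} available"
            )
    group_sizes = {
        g: sum(len(cells[k]) for k in keys if k.group == g) for g in ("h", "p")
    }
    if set(group_sizes.values()) == {size_per_group}:
        full = tuple(s.subject_id for s in training_subjects)
        return [
            TrainingSubset(index=1, size_per_group=size_per_group, subject_ids=full)
        ]

    rng = np.random.default_rng(seed)
    subsets: list[TrainingSubset] = []
    for t in range(1, n_subsets + 1):
        ids: list[str] = []
        for key in keys:
            members = cells[key]
            chosen = rng.choice(len(members), size=per_cell, replace=False)
            ids.extend(members[i].subject_id for i in sorted(chosen))
        subsets.append(
            TrainingSubset(
                index=t, size_per_group=size_per_group, subject_ids=tuple(ids)
            )
        )
    return subsets


# ---------------------------------------------------------------------------
# Plain-text persistence
# ---------------------------------------------------------------------------

def write_split(split: SplitAssignment, path: str | Path) -> None:
    """Two-column TSV: subject_id <tab> partition."""
    with open(path, "w") as fh:
        fh.write("subject_id\tpartition\n")
        for sid, part in split.assignment.items():
            fh.write(f"{sid}\t{part}\n")


def read_split(path: str | Path) -> SplitAssignment:
    assignment: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip().split("\t") != ["subject_id", "partition"]:
            raise ValueError(f"{path}: unexpected split-file header {header!r}")
        for line in fh:
            if not line.strip():
                continue
            sid, part = line.rstrip("\n").split("\t")
            assignment[sid] = part
    return SplitAssignment(assignment)


def write_subsets(
    subsets: Sequence[TrainingSubset], path: str | Path, seed: int | None = None
) -> None:
    """JSON document {size_per_group, seed, subsets: [[ids...], ...]}."""
    if not subsets:
        raise ValueError("no subsets to write")
    doc = {
        "size_per_group": subsets[0].size_per_group,
        "seed": seed,
        "subsets": [list(s.subject_ids) for s in subsets],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
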