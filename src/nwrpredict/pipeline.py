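"""End-to-end orchestration of the prediction protocol.

A full run executes, in order: stratified split -> per-site evaluation on
the validation set -> site combination -> training-subset search -> one
final evaluation on the test set.  The test set is read exactly once, and
the audit log proves it.  All artifacts (effective config, split, report
tables, model bundle, per-subject predictions, metrics) are written as
plain text (TSV/JSON) into a run directory so runs are reproducible and
diffable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .classifier import (
    DEFAULT_K,
    SubjectPrediction,
    TrainedModel,
    predict_subject,
    train_model,
)
from .data_preparation import stratified_split, write_split
from .errors import ProtocolError, SchemaVersionError
from .evaluation import (
    DemographicRates,
    RateTriple,
    misclassification_demographics,
    prediction_rates,
)
from .features import DEFAULT_N_BINS, Histogram, RangeSpec
from .model_selection import (
    DEFAULT_TRAINING_SIZES,
    SITE_RATE_THRESHOLD,
    AuditLog,
    ValidationReport,
    combination_evaluation,
    site_evaluation,
    subset_search,
)
from .signal_model import Cohort, ReflexWindow, Subject, load_cohort

__all__ = [
    "PipelineConfig",
    "ProtocolResult",
    "run_full_protocol",
    "exclude_noisy_traces",
    "save_model_bundle",
    "load_model_bundle",
    "predict_one",
]

logger = logging.getLogger("nwrpredict")

MODEL_SCHEMA_VERSION = 1


def exclude_noisy_traces(cohort: Cohort, rms_limit: float) -> Cohort:
    """Drop traces whose pre-stimulation RMS exceeds the limit.

    Returns a new cohort; subjects losing all traces are kept (they will
    fail loudly if a required site has no usable trace).
    """
    from .signal_model import QualityFlag, Subject, check_prestim_activity

    subjects = []
    dropped = 0
    for s in cohort:
        kept = [
            tr
            for tr in s.traces
            if check_prestim_activity(tr, rms_limit) is QualityFlag.PASS
        ]
        dropped += len(s.traces) - len(kept)
        subjects.append(
            Subject(
                subject_id=s.subject_id, group=s.group, gender=s.gender,
                age=s.age, traces=kept,
            )
        )
    if dropped:
        logger.info("excluded %d traces failing the pre-stimulation check", dropped)
    return Cohort(subjects=subjects)


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of one protocol run.

    Every seed and option is explicit; the full config is echoed into the
    run directory so no hidden defaults influence an archived result.
    """

    trace_table: str | None = None
    metadata: str | None = None
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    split_seed: int = 0
    subset_seed: int = 0
    k: int = DEFAULT_K
    n_bins: int = DEFAULT_N_BINS
    window_ms: tuple[float, float] = (60.0, 180.0)
    site_threshold: float = SITE_RATE_THRESHOLD
    sites: tuple[int, ...] = tuple(range(1, 11))
    training_sizes: tuple[int, ...] = DEFAULT_TRAINING_SIZES
    n_subsets: int = 10
    #: histogram rectified amplitudes instead of signed ones
    rectify: bool = False
    #: when set, traces whose pre-stimulation RMS exceeds this limit are
    #: excluded before the protocol runs (the quality check itself never
    #: auto-excludes)
    prestim_rms_limit: float | None = None

    @property
    def window(self) -> ReflexWindow:
        return ReflexWindow(*self.window_ms)


@dataclass
class ProtocolResult:
    """Everything a full run produced."""

    config: PipelineConfig
    split: dict[str, str]
    report: ValidationReport
    model: TrainedModel
    test_rates: RateTriple
    demographics: DemographicRates
    predictions: list[SubjectPrediction]
    audit: AuditLog


def run_full_protocol(
    config: PipelineConfig,
    cohort: Cohort | None = None,
    run_dir: str | Path | None = None,
) -> ProtocolResult:
    """Execute the complete protocol on a cohort.

    The cohort is either passed directly or loaded from the paths in the
    config.  When ``run_dir`` is given, all artifacts are written there.

    Raises :class:`ProtocolError` if the audit shows the test set was
    evaluated more than once (which would indicate parameter tuning on TE).
    """
    if cohort is None:
        if config.trace_table is None or config.metadata is None:
            raise FileNotFoundError(
                "no cohort given and config has no trace_table/metadata paths"
            )
        cohort = load_cohort(config.trace_table, config.metadata)

    audit = AuditLog()
    report = ValidationReport()
    window = config.window

    if config.prestim_rms_limit is not None:
        cohort = exclude_noisy_traces(cohort, config.prestim_rms_limit)

    logger.info("stage: split (%d subjects)", len(cohort))
    split = stratified_split(cohort, config.split_ratios, seed=config.split_seed)
    tr = cohort.subset(split.ids("TR"))
    val = cohort.subset(split.ids("V"))
    te = cohort.subset(split.ids("TE"))
    logger.info("split sizes: TR=%d V=%d TE=%d", len(tr), len(val), len(te))

    logger.info("stage: site evaluation (%d sites)", len(config.sites))
    retained = site_evaluation(
        tr, val, sites=config.sites, sizes=config.training_sizes,
        n_subsets=config.n_subsets, seed=config.subset_seed,
        threshold=config.site_threshold, k=config.k, n_bins=config.n_bins,
        window=window, rectify=config.rectify, audit=audit, report=report,
    )
    logger.info("retained sites: %s", retained)
    if not retained:
        raise ProtocolError(
            "no stimulation site reached the retention threshold "
            f"({config.site_threshold}%); cannot proceed to combination"
        )

    logger.info("stage: site combination")
    selected_sites = combination_evaluation(
        tr, val, retained, sizes=config.training_sizes,
        n_subsets=config.n_subsets, seed=config.subset_seed, k=config.k,
        n_bins=config.n_bins, window=window, rectify=config.rectify,
        audit=audit, report=report,
    )
    logger.info("selected site set: %s", selected_sites)

    logger.info("stage: training-subset search")
    best_subset, val_rates = subset_search(
        tr, val, selected_sites, sizes=config.training_sizes,
        n_subsets=config.n_subsets, seed=config.subset_seed, k=config.k,
        n_bins=config.n_bins, window=window, rectify=config.rectify,
        audit=audit, report=report,
    )
    logger.info(
        "selected subset: size %d per group, t=%d (validation %s)",
        best_subset.size_per_group, best_subset.index, val_rates,
    )

    logger.info("stage: final test evaluation (TE accessed now, once)")
    pool_by_id = {s.subject_id: s for s in tr}
    final_training = [pool_by_id[sid] for sid in best_subset.subject_ids]
    model = train_model(
        final_training, site_ids=selected_sites, window=window,
        k=config.k, n_bins=config.n_bins, rectify=config.rectify,
    )
    overlap = set(model.training_ids) & {s.subject_id for s in te}
    if overlap:
        raise ProtocolError(f"test subjects leaked into training: {sorted(overlap)}")
    predictions = [predict_subject(s, model, window) for s in te]
    audit.record("final-test", "TE", len(final_training), len(te))
    pred_by_id = {p.subject_id: p for p in predictions}
    test_rates = prediction_rates(
        (s.group, pred_by_id[s.subject_id].predicted_label) for s in te
    )
    misclassified = [
        s for s in te if pred_by_id[s.subject_id].predicted_label != s.group
    ]
    demographics = misclassification_demographics(misclassified)
    logger.info("final test result: %s", test_rates)

    te_accesses = audit.accesses("TE")
    if te_accesses != 1:
        raise ProtocolError(
            f"protocol hygiene violation: TE was evaluated {te_accesses} times"
        )

    result = ProtocolResult(
        config=config, split=dict(split.assignment), report=report, model=model,
        test_rates=test_rates, demographics=demographics,
        predictions=predictions, audit=audit,
    )
    if run_dir is not None:
        _write_artifacts(result, Path(run_dir))
    return result


def _write_artifacts(result: ProtocolResult, run_dir: Path) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "config.json", "w") as fh:
        json.dump(asdict(result.config), fh, indent=1)
        fh.write("\n")
    from .data_preparation import SplitAssignment

    write_split(SplitAssignment(result.split), run_dir / "split.tsv")
    cells = [
        {
            "sites": list(c.site_ids),
            "size_per_group": c.size_per_group,
            "subset_index": c.subset_index,
            **c.rates.to_dict(),
        }
        for c in result.report.cells
    ]
    with open(run_dir / "validation_report.json", "w") as fh:
        json.dump(
            {
                "cells": cells,
                "site_best_rates": result.report.site_best_rates,
                "retained_sites": result.report.retained_sites,
                "selected_sites": list(result.report.selected_sites),
                "selected_subset": {
                    "index": result.report.selected_subset.index,
                    "size_per_group": result.report.selected_subset.size_per_group,
                    "subject_ids": list(result.report.selected_subset.subject_ids),
                }
                if result.report.selected_subset
                else None,
                "imbalance_flags": result.report.imbalance_flags,
            },
            fh,
            indent=1,
        )
        fh.write("\n")
    save_model_bundle(result.model, run_dir / "model.json")
    with open(run_dir / "predictions.json", "w") as fh:
        json.dump([p.to_dict() for p in result.predictions], fh, indent=1)
        fh.write("\n")
    with open(run_dir / "metrics.json", "w") as fh:
        json.dump(
            {
                "test": result.test_rates.to_dict(),
                "demographics": result.demographics.to_dict(),
            },
            fh,
            indent=1,
        )
        fh.write("\n")
    with open(run_dir / "audit.json", "w") as fh:
        json.dump(result.audit.entries, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Model bundle serialization
# ---------------------------------------------------------------------------

def save_model_bundle(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model to a versioned JSON bundle."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "package_version": __version__,
        "k": model.k,
        "n_bins": model.n_bins,
        "rectify": model.rectify,
        "site_ids": list(model.site_ids),
        "window_ms": [model.window.start_ms, model.window.end_ms],
        "range_spec": {
            "full_range": list(model.range_spec.full_range),
            "mu": model.range_spec.mu,
            "sigma": model.range_spec.sigma,
        },
        "bin_edges": model.profiles[0][2].bin_edges.tolist(),
        "profiles": [
            {"subject_id": sid, "label": lab, "probs": h.probabilities.tolist()}
            for sid, lab, h in model.profiles
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_model_bundle(path: str | Path) -> TrainedModel:
    """Load a model bundle, refusing incompatible schema versions."""
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"model bundle schema version {version!r} is not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    edges = np.asarray(doc["bin_edges"], dtype=float)
    profiles = tuple(
        (
            rec["subject_id"],
            rec["label"],
            Histogram(bin_edges=edges, probabilities=np.asarray(rec["probs"], float)),
        )
        for rec in doc["profiles"]
    )
    rs = doc["range_spec"]
    return TrainedModel(
        profiles=profiles,
        range_spec=RangeSpec(
            full_range=tuple(rs["full_range"]), mu=rs["mu"], sigma=rs["sigma"]
        ),
        k=doc["k"],
        n_bins=doc["n_bins"],
        site_ids=tuple(doc["site_ids"]),
        window=ReflexWindow(*doc["window_ms"]),
        rectify=doc.get("rectify", False),
    )


def predict_one(
    model: TrainedModel | str | Path, query: Subject
) -> SubjectPrediction:
    """Individual assessment of a single query subject.

    ``model`` may be a live :class:`TrainedModel` or the path of a saved
    bundle.  Returns the per-signal breakdown and the final l_q^p.
    """
    if not isinstance(model, TrainedModel):
        model = load_model_bundle(model)
    return predict_subject(query, model, model.window)
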