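"""Synthetic NWR cohort generator.

Real reflex recordings of chronic-pain patients and healthy controls are
not publicly deposited, so the package ships a generator that reproduces
the statistical structure the classifier consumes:

* traces are baseline Gaussian noise with an EMG-like reflex burst —
  noise shaped by a smooth (Hann) envelope — confined to the 60-180 ms
  post-stimulation window;
* each subject carries a per-site reflex gain drawn around a class mean;
  at the *informative* sites the patient mean is shifted upward by
  ``effect_size`` between-subject standard deviations (chronic-pain
  hyperexcitability produces larger reflexes), so the classes differ in
  the dispersion of their reflex-window amplitudes while all other sites
  carry no class signal;
* cohorts are demographically balanced over gender and the two age
  classes, mirroring the 280-subject geometry (35 subjects per
  group x gender x age-class cell) at the default cell size.

An alternative "dispersion" mode widens the patient gain distribution
instead of shifting it, for sensitivity analyses where the class
difference lives in between-subject variability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .signal_model import Cohort, EMGTrace, ReflexWindow, Subject, window_sample_indices

__all__ = [
    "ClassSignalParams",
    "CohortSpec",
    "generate_trace",
    "generate_cohort",
    "biomarker_scalar",
    "write_ground_truth",
]


@dataclass(frozen=True)
class ClassSignalParams:
    """Class- and site-dependent signal structure.

    ``effect_size`` is the separation between the patient and healthy
    per-subject reflex-gain means at informative sites, in units of the
    between-subject gain SD ``gain_sd`` — i.e. the standardized mean
    difference the generator is asked to realise.  ``baseline_noise_sd``
    is deliberately small relative to the reflex gain so that a subject's
    measured reflex-window RMS is, to first order, proportional to its
    gain and the knob stays faithful.
    """

    informative_sites: tuple[int, ...] = (3, 9, 10)
    effect_size: float = 2.0
    gain_mean: float = 1.0
    gain_sd: float = 0.15
    baseline_noise_sd: float = 0.05
    burst_probability: float = 1.0
    mode: str = "scale"  # "scale": shifted patient mean; "dispersion": wider patient spread
    biomarker_log_separation: float = 0.3
    biomarker_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.effect_size < 0 or self.gain_sd < 0 or self.baseline_noise_sd < 0:
            raise ValueError("scales and effect size must be non-negative")
        if not 0 <= self.burst_probability <= 1:
            raise ValueError(
                f"burst_probability must be in [0, 1], got {self.burst_probability}"
            )
        if self.mode not in ("scale", "dispersion"):
            raise ValueError(f"mode must be 'scale' or 'dispersion', got {self.mode!r}")

    def gain_distribution(self, group: str, site: int) -> tuple[float, float]:
        """(mean, sd) of the per-subject reflex gain for a class at a site."""
        if group not in ("h", "p"):
            raise ValueError(f"group must be 'h'/'p', got {group!r}")
        mean, sd = self.gain_mean, self.gain_sd
        if group == "p" and site in self.informative_sites:
            if self.mode == "scale":
                mean = mean + self.effect_size * sd
            else:
                sd = sd * (1.0 + self.effect_size)
        return mean, sd


@dataclass(frozen=True)
class CohortSpec:
    """Cohort geometry: the default reproduces the 280-subject layout
    (n_per_cell = 35 over 8 group x gender x age-class cells), ten sites
    stimulated four times each, 1000 ms traces at 2000 Hz with 200 ms of
    pre-stimulation activity."""

    n_per_cell: int = 35
    sites: tuple[int, ...] = tuple(range(1, 11))
    repetitions: int = 4
    sampling_rate: float = 2000.0
    prestim_ms: float = 200.0
    trace_ms: float = 1000.0
    window: ReflexWindow = field(default_factory=ReflexWindow)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if not 1 <= self.repetitions <= 4:
            raise ValueError("repetitions must be in 1..4")
        if self.trace_ms < self.prestim_ms + 180.0:
            raise ValueError("trace must cover 180 ms post-stimulation")

    @property
    def n_samples(self) -> int:
        return int(round(self.trace_ms * self.sampling_rate / 1000))

    @property
    def stim_onset_index(self) -> int:
        return math.ceil(self.prestim_ms * self.sampling_rate / 1000)


def _burst_envelope(n: int) -> np.ndarray:
    """Smooth Hann envelope shaping the reflex burst."""
    return np.hanning(n)


def generate_trace(
    params: ClassSignalParams,
    group: str,
    site: int,
    rng: np.random.Generator,
    spec: CohortSpec | None = None,
    subject_id: str = "synthetic",
    repetition: int = 1,
    gain: float | None = None,
) -> EMGTrace:
    """Simulate one EMG trace for a stimulation of ``site``.

    The trace is zero-mean Gaussian baseline noise everywhere; with
    probability ``burst_probability`` a reflex burst — white noise scaled
    by the subject's reflex gain and a Hann envelope — is added inside the
    post-stimulation reflex window.  The pre-stimulation segment therefore
    contains baseline noise only.

    ``gain`` fixes the subject's reflex gain; when omitted, a fresh gain
    is drawn from the class/site distribution (floored just above zero).
    """
    if spec is None:
        spec = CohortSpec()
    samples = rng.normal(0.0, params.baseline_noise_sd, size=spec.n_samples)
    if gain is None:
        mean, sd = params.gain_distribution(group, site)
        gain = max(float(rng.normal(mean, sd)), 0.01)
    if rng.random() < params.burst_probability:
        start, stop = window_sample_indices(
            spec.window, spec.sampling_rate, spec.stim_onset_index
        )
        burst = gain * _burst_envelope(stop - start) * rng.standard_normal(stop - start)
        samples[start:stop] += burst
    return EMGTrace(
        subject_id=subject_id,
        site_id=site,
        repetition=repetition,
        samples=samples,
        sampling_rate=spec.sampling_rate,
        stim_onset_index=spec.stim_onset_index,
    )


def generate_cohort(
    spec: CohortSpec | None = None, params: ClassSignalParams | None = None
) -> Cohort:
    """Simulate a balanced cohort.

    Subjects are laid out over the 8 group x gender x age-class cells with
    ``n_per_cell`` subjects each; ages are drawn uniformly within the cell's
    age class (20-49 for A1, 50-80 for A2).  Each subject's reflex gain is
    drawn once per site and shared by that site's repetitions, making the
    four signals of a site correlated realisations of the same subject —
    the structure the subject-profile averaging relies on.  All randomness
    flows from ``spec.seed``, so equal specs produce identical cohorts.
    """
    if spec is None:
        spec = CohortSpec()
    if params is None:
        params = ClassSignalParams()
    rng = np.random.default_rng(spec.seed)
    subjects: list[Subject] = []
    counter = 0
    for group in ("h", "p"):
        for gender in ("G1", "G2"):
            for age_class in ("A1", "A2"):
                for _ in range(spec.n_per_cell):
                    counter += 1
                    sid = f"S{counter:04d}"
                    age = (
                        int(rng.integers(20, 50))
                        if age_class == "A1"
                        else int(rng.integers(50, 81))
                    )
                    traces: list[EMGTrace] = []
                    for site in spec.sites:
                        mean, sd = params.gain_distribution(group, site)
                        gain = max(float(rng.normal(mean, sd)), 0.01)
                        for rep in range(1, spec.repetitions + 1):
                            traces.append(
                                generate_trace(
                                    params,
                                    group,
                                    site,
                                    rng,
                                    spec=spec,
                                    subject_id=sid,
                                    repetition=rep,
                                    gain=gain,
                                )
                            )
                    subjects.append(
                        Subject(
                            subject_id=sid,
                            group=group,
                            gender=gender,
                            age=float(age),
                            traces=traces,
                        )
                    )
    return Cohort(subjects=subjects)


def biomarker_scalar(
    subject: Subject,
    params: ClassSignalParams,
    rng: np.random.Generator,
) -> float:
    """One scalar biomarker value per subject, for the percentile baseline.

    Values are log-normal with a class-dependent log-mean: healthy subjects
    around exp(0), patients shifted by ``biomarker_log_separation`` log
    units.  The default separation keeps the class distributions heavily
    overlapping, emulating a high-variance receptive-field-area-like
    biomarker on which extreme-percentile cutoffs detect few patients.
    """
    shift = params.biomarker_log_separation if subject.group == "p" else 0.0
    return float(np.exp(rng.normal(shift, params.biomarker_log_sd)))


def write_ground_truth(
    params: ClassSignalParams, spec: CohortSpec, path: str | Path
) -> None:
    """Record the generator's ground truth for test harnesses."""
    doc = {
        "informative_sites": list(params.informative_sites),
        "effect_size": params.effect_size,
        "mode": params.mode,
        "gain_mean": params.gain_mean,
        "gain_sd": params.gain_sd,
        "baseline_noise_sd": params.baseline_noise_sd,
        "burst_probability": params.burst_probability,
        "seed": spec.seed,
        "n_per_cell": spec.n_per_cell,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
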