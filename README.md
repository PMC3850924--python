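# nwrpredict

Probabilistic classification of chronic-pain patients from EMG recordings
of the nociceptive withdrawal reflex (NWR).

Chronic low back and neck pain are associated with *central
hyperexcitability*: spinal nociceptive circuits respond more strongly to a
given stimulus. The NWR — the reflex a painful electrical stimulus to the
sole of the foot evokes in the tibialis anterior, measured by surface EMG
60–180 ms after the stimulus — makes this excitability objectively
measurable. Most reference data, however, only separates patient and
healthy *populations*. This package implements a prediction model that
classifies an *individual* as patient or healthy, with a confidence value,
from the statistical shape of their reflex EMG.

It is intended for researchers in pain electrophysiology and
biostatistics who want to apply the model to their own recordings, study
its behaviour on simulated cohorts, or extend the validation protocol.

## The model

Each subject *i* is stimulated 4 times at each of up to ten electrode
sites. For every recorded signal *F<sub>ij</sub>* the amplitudes inside
the 60–180 ms reflex window are binned into a 30-bin probability histogram
over the restricted range *rg* = [*μ−σ*, *μ+σ*], where *μ*, *σ* are the
mean and standard deviation of all pooled training amplitudes (the full
range *Rg* carries ≈1/1000 of the mass at its extremes, so *rg* suffices).
A training subject is represented by the average of its signal histograms,

&nbsp;&nbsp;&nbsp;&nbsp;*P<sub>i</sub>* = ¼ Σ<sub>j</sub> *P<sub>ij</sub>*,

with label *L<sub>i</sub>* ∈ {h, p}. A query signal *P<sub>qj</sub>* is
compared to every training profile by Euclidean distance
*d<sub>ij</sub>* = √Σ<sub>x</sub> (*P<sub>i</sub>*(x) − *P<sub>qj</sub>*(x))²
and the k = 5 nearest training subjects vote:

&nbsp;&nbsp;&nbsp;&nbsp;*l<sub>qj</sub><sup>p</sup>* = (#patient neighbours)/k · 100%.

The individual assessment averages the signal votes,
*l<sub>q</sub><sup>p</sup>* = Σ<sub>j</sub> *l<sub>qj</sub><sup>p</sup>* / J,
and the subject is classified as a patient iff
*l<sub>q</sub><sup>p</sup>* ≥ 50% — an exactly split vote goes to the
patient class, to minimise missed patients.

Model selection follows a strict protocol on a demographically stratified
70/15/15 split (training TR / validation V / test TE, balanced over group,
gender G1/G2 and age class A1 < 50 y ≤ A2): each stimulation site is
evaluated on V across training sizes (12…100 subjects per group, 10 random
balanced subsets each), sites below a 75% prediction rate are discarded,
combinations of the rest are compared, the best balanced training subset
is chosen, and only then is TE evaluated — exactly once, which the audit
log proves. Performance is reported as prediction rates *r*, *r<sub>h</sub>*,
*r<sub>p</sub>* (overall / healthy / patients) plus the gender and
age composition of the misclassified subjects.

Because no recording dataset is distributed, the package ships a synthetic
cohort generator (`nwrpredict.synthetic_data`) that reproduces the
statistical structure the classifier consumes: Hann-enveloped EMG bursts
confined to the reflex window, per-subject reflex gains whose class
difference at chosen "informative" sites is a calibrated standardized
effect size, demographic balance, and a scalar biomarker for the
percentile-cutoff baseline.

## Worked example

`examples/02_individual_assessment.py` trains on 40 synthetic subjects
(sites 9 and 10) and assesses a held-out patient:

```
trained on 40 subjects, sites (9, 10), k=5, 30 bins over rg=(-0.728, 0.734)

query S0045 (true group: p):
  site 9 rep 1: l_qj^p = 100.0%  -> p
  ...
  site 10 rep 4: l_qj^p = 100.0%  -> p
individual assessment l_q^p = 100.0% -> classified patient
```

Every one of the eight signals found 5/5 patient neighbours, so the
assessment is patient with 100% confidence. `examples/03_full_protocol.py`
runs the whole selection protocol on a 96-subject cohort whose class
signal sits at sites 9 and 10:

```
per-site best validation rates:
  site  1:  41.7%
  site  3:  47.9%
  site  9: 100.0%
  site 10: 100.0%
retained (>= 75%): [9, 10]
final test result: r = 93.8%  (r_h = 87.5%, r_p = 100.0%; 15/16 correct)
test-set evaluations in audit log: 1 (the protocol guarantees exactly one)
```

The informative sites are recovered, the noise sites discarded, and the
held-out test set is touched once. `examples/04_percentile_baseline.py`
shows why a scalar-biomarker percentile cutoff is a weak alternative when
class distributions overlap (p95: r_h = 100%, r_p = 14%).

There is also a thin CLI mirroring the pipeline stages:

```bash
nwrpredict simulate --n-per-cell 4 --sites 9,10 --out-dir /tmp/sim
nwrpredict split --traces /tmp/sim/traces.tsv --metadata /tmp/sim/metadata.json \
    --ratios 0.5,0.25,0.25 --out /tmp/split.tsv
nwrpredict train --traces /tmp/sim/traces.tsv --metadata /tmp/sim/metadata.json \
    --sites 9,10 --out /tmp/model.json
nwrpredict predict --model /tmp/model.json --traces /tmp/sim/traces.tsv \
    --metadata /tmp/sim/metadata.json --subject S0001
```

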