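# arcsync

Analysis pipeline for studying **narrative engagement with multi-subject
EEG**: does the audience's moment-to-moment engagement with a story that
follows the six-phase dramatic arc (exposition → rising action → crisis →
climax → falling action → denouement) leave a measurable trace in how
*similar* viewers' brain signals are — and can engagement be decoded from
EEG-derived features?

The package is aimed at cognitive/neuro researchers working with
naturalistic stimuli who need a tested, reusable implementation of:

* **dynamic intersubject correlation (dISC)** — a tapered 15-sample window
  slides over preprocessed EEG; at each position the weighted Pearson
  correlation between homologous channels of every subject pair is Fisher
  z-transformed and pair-averaged,
* **spectral ISC bands** — magnitude-squared coherence of homologous
  channels, ISC(f) = |Gxy(f)|² / (Gxx(f)·Gyy(f)), averaged within δ/θ/α/β,
* **dynamic functional connectivity** and weighted graph features (node
  strength, Onnela clustering coefficient, betweenness centrality),
* **leave-one-subject-out SVR decoding** of continuous engagement ratings
  with fold-wise t-test feature selection,
* **phase-randomised surrogate inference** — p = (1 + #{null ≥ r}) /
  (1 + n_perm) with Benjamini–Hochberg FDR,
* **behavioral statistics** — rating synchrony, an event-segmentation
  coincidence test with a shuffle null, and LSA recall similarity,
* a **synthetic-data generator** producing EEG cohorts, engagement raters,
  segmentation raters and recall corpora with known ground truth, so every
  stage has a recoverable target.

## Worked example

Generate a synthetic cohort in which two channels (Cz, Pz) carry a shared
component whose across-subject coupling follows the dramatic-arc
engagement curve, then test whether dISC recovers that coupling:

```python
import numpy as np
from arcsync.synthetic import CohortConfig, make_arc_engagement, make_eeg_cohort, scaled_template
from arcsync.isc import disc, permutation_test_correlation
from arcsync.prediction import engagement_at_windows

template = scaled_template(120.0)                      # arc compressed to 120 s
_, truth = make_arc_engagement(template, 200.0, 2, 0.0, seed=0)
cohort, gt = make_eeg_cohort(CohortConfig(seed=3), truth)

stack = disc(cohort.data, cohort.fs_hz)                # channels x windows Fisher z
eng = engagement_at_windows(gt["gain_curve"], cohort.fs_hz, stack.window_centers_s)

ch = cohort.channel_names.index("Cz")
res = permutation_test_correlation(stack.values[ch], eng, n_perm=199, seed=0)
print(f"Cz dISC vs engagement: r={res.empirical_r:.3f}  p={res.p:.4f}")

ch0 = cohort.channel_names.index("Oz")                 # uncoupled control channel
res0 = permutation_test_correlation(stack.values[ch0], eng, n_perm=199, seed=0)
print(f"Oz dISC vs engagement: r={res0.empirical_r:.3f}  p={res0.p:.4f}")
```

Output:

```
Cz dISC vs engagement: r=0.771  p=0.0050
Oz dISC vs engagement: r=-0.008  p=0.7400
```

The engagement-coupled channel's intersubject correlation tracks the
generating engagement curve (r = 0.77, the smallest attainable p at 199
permutations), while the uncoupled control channel shows no relationship —
exactly the ground truth planted by the generator.

The same flow is available from the shell:

```bash
arcsync simulate --out sim/ --seed 1
arcsync disc --cohort sim/cohort.h5 --engagement sim/ratings.csv \
             --n-perm 1000 --tails two --seed 1 --out disc/
arcsync segment --stamps sim/stamps.csv --duration 506 --out seg/
arcsync recall --docs sim/recall --k 20 --out recall/
```

See `docs/methods.md` for the estimators, their assumptions, and all
numerical choices.

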