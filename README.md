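# icmspsych

Psychophysical analysis of intracortical microstimulation (ICMS) of human
somatosensory cortex. When current pulse trains are delivered through
penetrating microelectrodes, the evoked tactile percept's intensity depends
on the pulse frequency in an electrode-specific way: some electrodes evoke
their most intense percepts at low frequencies (20–100 Hz), others at the
highest tested frequency (300 Hz). This package implements the full analysis
pipeline for such experiments, plus a synthetic-participant generator so
every stage can be exercised and tested without human data:

* **Magnitude estimation** — free numeric intensity ratings per stimulus
  train, organised in randomised blocks. The pipeline excludes each
  session's first (calibration) block, builds per-electrode
  frequency–intensity profiles (mean ± SEM), screens each electrode for a
  frequency effect with Friedman's test, and corrects across electrodes
  with Benjamini–Hochberg (critical-p convention). Amplitude series are fit
  with a line, duration series with a 3-parameter logistic.
* **Categorization** — k-means on the rated intensity at 20, 100 and 300 Hz
  divides electrodes into low- / intermediate- / high-frequency-preferring
  (LFP / IFP / HFP) categories, named by the frequency at which each
  centroid peaks; k is validated by silhouette and elbow curves. An
  independent clustering on normalized percept-quality report vectors is
  compared with the intensity-based partition via the adjusted Rand index,
  and quality–category associations are tested with pairwise two-sided
  Fisher exact tests (+ BH).
* **Spatial statistics** — the *adjacency fraction*: among tested
  electrodes with at least one tested lattice neighbour (rook 4-adjacency
  by default, queen optional), the proportion having a neighbour of the
  same category. Significance comes from a Monte-Carlo permutation null
  that redistributes the observed labels uniformly over the same tested
  sites of both arrays (category counts fixed), summarised as a pseudo
  p-value `p = #(null ≥ observed) / n_sims`. An exact-enumeration null is
  included for small problems and doubles as the Monte-Carlo oracle.
* **Detection** — a transformed up-down (1-up-3-down) staircase: 2 dB steps,
  start 10 µA, stop at the fifth direction change, threshold = mean of the
  last 10 tested amplitudes. The rule converges on the amplitude where
  P(correct) = 0.5^(1/3) ≈ 79.4% in a 2AFC task. A fixed-amplitude task
  (1.2× the 100 Hz threshold) compares detection accuracy across pulse
  frequencies (one-sample t vs 50% chance; ANOVA + Tukey HSD).

## Worked example

The `icmspsych` CLI chains the stages on a synthetic participant
(30 electrodes, 10 per category, multiplicative log-normal rating noise
σ = 0.2, first-block bias 0.5):

```sh
icmspsych simulate --seed 3 --out demo/sim
icmspsych magnitude --input demo/sim/magnitude.csv --out demo/mag
icmspsych cluster   --profiles demo/mag/profiles.csv --seed 0 --out demo/clu
icmspsych spatial   --grid demo/sim/grid_map.csv --n-sims 100000 --seed 1 --out demo/spa
icmspsych detect    --mode staircase --seed 2 --out demo/det
icmspsych quality   --counts demo/sim/quality_counts --frequency 20 --out demo/qua
```

prints

```
synthetic dataset written to demo/sim (seed=3)
30 of 30 electrodes significant (critical p = 0.000916)
k=3; categories: {'LFP': 10, 'IFP': 10, 'HFP': 10} (seed=0)
observed fraction 1.0000, pseudo-p 0.00000 (rook, 100000 sims, seed=1)
threshold 16.02 µA in 20 trials (seed=2)
3 of 30 pairwise tests significant (critical p = 0.0022)
```

Reading the numbers: every synthetic electrode's rated intensity varies
significantly with pulse frequency (Friedman + BH at the 0.000916 critical
p); silhouette selection recovers k = 3 and the k-means labels match the
10/10/10 ground truth; the generated category map is strongly clustered on
the arrays (every tested electrode has a same-category neighbour — none of
100 000 random redistributions matched it, pseudo-p < 1/100 000); one
simulated staircase run estimates a 16.02 µA threshold against an observer
whose true 79.4%-correct point is 15 µA; and at 20 Hz the qualities that
separate electrode categories (e.g. pressure, reported by LFP/IFP but never
HFP electrodes) are flagged by the pairwise Fisher tests.

The same operations are available as a library, e.g.:

```python
from icmspsych import (SyntheticConfig, gen_magnitude_dataset,
                       trials_to_frame, exclude_first_block,
                       compute_profiles, friedman_screen)

trials, truth = gen_magnitude_dataset(SyntheticConfig(), seed=3)
screen = friedman_screen(exclude_first_block(trials_to_frame(trials)))
print(screen.table.head())
```

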