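# parbkymo

Analysis of single-molecule fluorescence kymographs of ParB proteins on
supercoiled DNA — plus a synthetic data generator so the whole pipeline can
be exercised, validated and benchmarked without experimental data.

## The problem

In the bacterial ParABS chromosome-segregation system, ParB dimers load at
the centromeric *parS* site, clamp around the DNA upon CTP binding, diffuse
along it, and bridge with each other to build the partition complex.
Bacterial DNA is also supercoiled: torsional strain stores DNA in
plectonemes, which appear on a stretched, doubly-tethered molecule as
mobile high-intensity spots. This package implements the quantitative
analyses used to study how the two phenomena interact on ~38 kb tethered
DNA imaged at 10 Hz in two channels (intercalator-stained DNA and labeled
ParB):

- **Preprocessing** — per-frame median smoothing (10 px), white top-hat
  background subtraction, kymograph extraction by summing 11 pixels across
  the DNA axis, single-frame alignment of alternately excited channels.
- **Tracking** — per-frame local-maxima detection, greedy nearest-neighbour
  linking (7 px / 5 frames), and sizing each feature as the fraction of the
  molecule's fluorescence inside a ±2 px window: `size_kb = fraction × 38`.
- **Dynamics** — time-averaged MSD over lag times of 2–20 frames fit to
  `MSD = 2Dτ` (1-D diffusion), and an 11-frame moving window that yields an
  apparent D per frame for arrest detection.
- **Kinetics** — the delayed-dissociation residence-time model: a dimer
  releases after both CTPs hydrolyse (rate `k_CTP` each) and the open clamp
  dissociates (rate `k_off`), giving a hypoexponential dwell-time
  distribution `T = max(E₁,E₂) + E₃` (or the sequential variant
  `E₁+E₂+E₃`), with maximum-likelihood fitting, censoring/truncation
  support, and nonparametric condition comparisons (Mann–Whitney, KS).
- **Condensation** — classification of "supercoiled condensates" (ParB–DNA
  clusters that absorb all plectonemic writhe): apparent D < 10 kb²/s
  sustained over ≥ 200 frames with colocalized ParB and a high local DNA
  fraction; condensed fractions carry exact Clopper–Pearson 95% CIs.
- **Synthetic generator** — ground-truth plectoneme/ParB/condensate tracks
  (reflected Brownian motion, Poisson loading at *parS*, hypoexponential
  dwells, 74% per-monomer labeling → 93% visible dimers) rendered into
  kymographs with a Gaussian PSF and a Poisson + Gaussian camera model.

## Worked example

```python
import numpy as np
from parbkymo import (SimConfig, detect_peaks_kymo, link_tracks,
                      measure_fractions, simulate_kymographs, summarize_tracks)

cfg = SimConfig(n_frames=600, rng_seed=4)      # 38 kb DNA, 12 kb plectonemic
truth, dna, parb = simulate_kymographs(cfg)    # two rendered kymographs

tracks = link_tracks(detect_peaks_kymo(dna))   # detect + link peaks
measure_fractions(dna, tracks, cfg.dna_length_kb)
per_frame, per_track = summarize_tracks(tracks, cfg.n_frames)
print(f"{per_frame.total_kb.mean():.1f} kb")   # -> 11.9 kb
```

The tracked time-averaged plectonemic DNA (11.9 kb) recovers the
configured 12 kb: the intensity-fraction sizing conserves DNA content
through detection and linking. `examples/` contains three narrative
scripts (`simulate_and_track.py`, `residence_kinetics.py`,
`condensation_screen.py`); for instance `residence_kinetics.py` prints the
residence-model summaries per supercoiling condition,

```
  non-coiled             mean  143.8 s   median  126.6 s   mode  92.3 s
  positive supercoiled   mean  109.5 s   median   94.6 s   mode  66.4 s
```

showing the shorter residence of ParB on supercoiled DNA, and
`condensation_screen.py` classifies a 12-molecule cohort (3 pinned) as

```
condensed fraction: 25% (95% CI 5-57%, n=12)
```

A thin CLI mirrors the library: `parbkymo simulate|track|kinetics-fit|all`.

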