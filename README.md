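# hyphachrom

Quantitative analysis of chromosome dynamics in filamentous bacteria
(*Streptomyces* and relatives), built around four measurement problems
that arise when studying nucleoid-associated proteins (HU homologues)
and topoisomerase-dependent chromosome organisation:

1. **Single-molecule diffusion states** (`hyphachrom.spt`).  PALM
   localizations are linked into tracks (nearest-neighbour rule, 0.6 µm
   radius, one missing frame allowed for blinking) and the pooled lag-1
   squared displacements are fit with a K-component exponential mixture
   by EM.  For 2D Brownian motion observed at interval Δt with
   localization error σ_loc, r² | state k ~ Exp(4·D_k·Δt + 4·σ_loc²),
   so the fit yields per-state apparent diffusion coefficients D_k and
   state weights — the immobile (DNA-bound) versus mobile partition.
   Tracks are then classified *confined* / *free* / *mixed* from
   per-step posterior states over sliding 3-step (90 ms) windows.
2. **Hyphal focus quantification** (`hyphachrom.hyphal`).  Fluorescent
   chromosome markers (e.g. ParB·*parS* foci) along 1D hyphal axes:
   SNIP-style background subtraction, MAD-based peak detection with
   sub-pixel refinement, focus tracking with duplication-event
   detection, tip-to-focus distance series, inter-focus spacings,
   loess trends, and germination/stall phenotype rules (16 h
   observation; inhibited if no extension for >1 h; a branch is stalled
   after ≥120 min without extension and no re-initiation).
3. **Sliding-window differential ChIP binding** (`hyphachrom.chip`).
   Fragments counted in 69-bp windows every 23 bp; windows enriched
   log2 > 2 over their local 2-kb background are tested with a
   negative-binomial GLM (common Cox–Reid dispersion, likelihood-ratio
   test); windows <100 bp apart merge into regions; Simes-combined
   p-values are FDR-controlled (Benjamini–Hochberg, 0.05); regions are
   annotated with AT content.
4. **Growth-curve statistics** (`hyphachrom.growth`).  Three-parameter
   log-logistic fits OD(t) = d/(1+exp(b·(log t − log e))) giving the
   plateau d, ED50 e and relative slope b (negative for an increasing
   curve), plus Wilcoxon rank-sum tests and comparative ΔΔCt.

`hyphachrom.simulate` generates all four input classes with known
ground truth (two-state Brownian motion with blinking/bleaching,
extending/branching hyphae with duplicating foci, NB-distributed
windowed fragment counts over AT-rich sites, noisy log-logistic OD
curves), so every stage is testable end to end without external data.

## Worked example

```python
import numpy as np
from hyphachrom import simulate as S, spt

cfg = S.SPTSimConfig(n_molecules=2700, n_frames=2200, D_slow=0.015,
                     D_fast=0.400, f_slow=0.75, switch_prob=0.02,
                     dt=0.03, loc_sigma=0.02, p_bleach=0.05,
                     p_blink=0.02, stagger=True, seed=1)
locs, truth = S.simulate_spt(cfg)
tracks = spt.link_tracks(locs, spt.TrackingConfig(dt=0.03))
fit = spt.fit_diffusion_mixture(tracks, K=2, dt=0.03, loc_sigma=0.02)
print(np.round(fit.D_app, 4), np.round(fit.weights, 3))
```

prints

```
[0.0149 0.4024] [0.735 0.265]
```

i.e. from ~52 000 tracked steps the mixture recovers the immobile state
at D ≈ 0.015 µm²/s carrying ~74% of steps and the mobile state at
D ≈ 0.40 µm²/s — the generating parameters of the simulation, and the
magnitudes typical of a DNA-bound versus freely diffusing partition of
a bacterial nucleoid-associated protein.

The same estimators run from the shell:

```sh
hyphachrom simulate spt --seed 1 --out data/
hyphachrom spt data/localizations.csv --dt 0.03 --out results/
hyphachrom chip sheet.tsv genome.fasta --width 69 --slide 23 --out regions.tsv
hyphachrom growth od.csv --out fit.json
hyphachrom run --seed 1 --out runs/demo     # full pipeline + manifest
```

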