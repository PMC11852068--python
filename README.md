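# nclnet

Functional-connectivity network analysis of multichannel local field
potential (LFP) recordings around a behavioural detection event — built for
the kind of study where an animal (here modelled on pigeon
nidopallium-caudolaterale recordings) triggers a sensor on detecting a
target, and the question is how the brain's functional network reorganizes
in the second after the event compared with the second before.

## What it computes

For each frequency band (delta 1–4, theta 5–12, beta 13–30, slow gamma
31–45, fast gamma 55–80 Hz):

1. **Preprocessing** — zero-phase Butterworth band-pass 1–250 Hz, 50 Hz
   notch, downsampling 30 kHz → 1 kHz, band decomposition, and 2 s
   event-centred epochs (1 s pre + 1 s post).
2. **Coherence networks** — sliding-window (256 samples, step 128)
   multitaper coherence `C_xy(f) = |⟨S_xy⟩|² / (⟨S_xx⟩⟨S_yy⟩)` between all
   channel pairs, averaged over in-band frequency bins, giving one 16 × 16
   adjacency matrix per window per trial (14 windows per epoch, 7 per
   condition).
3. **Threshold selection** — a 100-tier sweep over (0, 1); at each
   threshold every matrix is binarized and its community structure scored
   by hypergeometric Surprise
   `S = −log10 Σ_j C(M_int, j) C(M−M_int, m−j) / C(M, m)`;
   the band's optimal threshold maximizes mean S across all trials and
   subjects, with the largest-connected-component fraction tracked as a
   percolation diagnostic.
4. **Graph features** — average node degree `k̄ = 2m/N` and Newman
   modularity `Q = (1/2m) Σ_ij [A_ij − k_i k_j/(2m)] δ(c_i, c_j)` (with a
   modularity-maximizing partition) for every trial × window network.
5. **Statistics** — two-group one-way ANOVA per (subject, band, feature)
   comparing pre vs post, with `*`/`**` significance marks and a
   mean ± SD summary table.
6. **Decoding** — 120 × 7 per-feature matrices (60 trials × 2 conditions,
   7 windows) and the 120 × 14 combination, classified by a linear
   max-margin decoder, a recurrent sequence decoder and a decision tree
   under stratified ten-fold cross-validation, with pooled ROC curves and
   AUC.

Because such recordings are typically not public, the package ships a
first-class synthetic cohort generator: channels are mixtures of shared
band-limited latent oscillators whose mixing gain switches at the event
(default: beta coupling 0.3 → 0.8), plus private noise and a common 50 Hz
mains component. The generator plants exactly the effect the pipeline is
meant to detect, so every stage can be validated end to end.

## Worked example

```python
import dataclasses
from nclnet import CohortConfig
from nclnet.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(cohort=CohortConfig(n_subjects=1, n_trials=12, seed=3)).fast()
cfg = dataclasses.replace(cfg, bands=("beta",), decode_band="beta")
manifest = run_pipeline(cfg, "run/")
```

or from the shell (`--fast` generates at 1 kHz; without a config file the
full default 4 × 60 cohort is used): `nclnet run-all --out run/ --fast --band beta`.

The run directory then contains `comparisons.csv`:

```
subject_id,band,feature,n_pre,n_post,F,p,mark
bird0,beta,k_bar,84,84,759.8,7.59e-64,**
bird0,beta,Q,84,84,154.6,1.66e-25,**
```

— the planted beta coupling increase raises the average node degree
(pre 1.65 ± 1.64 → post 12.35 ± 3.16) and lowers modularity
(0.32 ± 0.19 → 0.04 ± 0.07), both highly significant: after the event the
network densifies and its modular structure dissolves. `decode_results.json`
reports the nine (feature set × decoder) cross-validated accuracies, e.g.
`degree/margin 1.00`, `modularity/tree 0.90`, `combined/recurrent 1.00` —
all well above the 0.5 chance baseline.

Individual stages (`simulate`, `preprocess`, `coherence`, `threshold`,
`features`, `stats`, `decode`) can be run separately on the persisted
artifacts; see `nclnet --help`.

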