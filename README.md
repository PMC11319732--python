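# epibind

Modeling monoclonal-antibody (mAb) binding landscapes from combinatorial
peptide microarrays, and ranking candidate epitopes among random
sequence space.

## The problem

A mAb raised against a linear epitope binds its cognate sequence with
high affinity and almost nothing else. A combinatorial peptide array —
~10⁵ near-random peptides of 5–11 residues over a 16-letter amino-acid
alphabet (`ADEFGHKLNPQRSVWY`), assayed at four antibody concentrations
(0.125/0.5/2/8 nM) in quadruplicate — samples that landscape extremely
sparsely: nearly every probe sits at the scanner background (~850
counts, log₁₀ ≈ 2.9) and a handful carry the signal, with the strongest
pinned at the 16-bit detector ceiling (65,536 counts). The question this
package operationalizes: can a model trained only on such a sparse,
unbiased sample recognize the antibody's specific epitope?

## The method

For each antibody, a fully connected network (2 hidden layers × 250
ReLU units) maps a one-hot encoded, terminus-marked, `X`-padded peptide
frame — e.g. `(LPGVQG)XXXXX` — to log₁₀ binding at all four
concentrations jointly. Three dataset transformations are applied
cumulatively on top of replicate-averaged, saturation-corrected binding
tables (cognate sequences excluded from training):

1. **high-binder weighting** — peptides binned by 8 nM log₁₀ binding
   (width 0.2); bins under 300 members are grown to 300 by copying, max
   100 copies per pair, rebalancing the loss toward the scarce signal;
2. **register-shift augmentation** — every training pair appears in 6
   shifted frames of an 18-wide window (`(PWRGPWARV)XXXXXXX` …
   `XXXXX(PWRGPWARV)XX`); prediction submits queries the same way and
   keeps the per-concentration frame maximum, forcing
   position-independent recognition;
3. **composition subtraction** — an OLS fit of log₁₀ binding on the
   16-element residue-count vector (per concentration) is subtracted so
   the network learns only order-dependent binding; predictions add it
   back.

Evaluation: an ensemble of independently seeded networks predicts the
cognate and N random sequences of the same length; each concentration is
ranked separately, each sequence takes its best rank, and best ranks are
re-ranked into unique final positions. The headline statistic is the
cognate's **percent rank** = 100·rank/(N+1). Substitution scans
(relative 2 nM binding of every single-residue variant) and antigen
tiling (overlapping 7-mers, I→V/T→S/M→L/C→S mapped) localize and
dissect the epitope. Synthetic landscapes with a planted motif and known
ground truth make every stage testable; see `docs/methods.md`.

## Worked example

```python
from epibind import pipeline
from epibind.model import train_ensemble
from epibind.ranking import RankConfig, random_library, rank_cognate

preset = pipeline.ABUNDANT                     # planted motif PLEEVLN
table = pipeline.prepare_table(preset, seed=1) # simulate + preprocess
cfg = pipeline.preset_config(preset, "+composition", seed=1)
ens = train_ensemble(table, cfg, n_models=3)
randoms = random_library(50_000, 7, seed=500_010)
res = rank_cognate(ens, preset.cognate, randoms,
                   RankConfig(cognate=preset.cognate, n_random=50_000))
print(res.rank, f"{res.percent_rank:.4f}%")
```

prints

```
1 0.0020%
```

— the planted cognate, never seen in training, outranks all 50,000
random 7-mers (percent rank 0.002%, i.e. rank 1 of 50,001). The full
ablation ladder on the scarce-signal preset
(`python analysis/04_ablation_ladder.py --seed 1`) shows why each
transformation exists:

```
scarce-signal (cognate SDLWKLL, n_random 50000):
    ablation  rank  percent_rank
    baseline   412      0.823984
  +weighting    32      0.063999
   +shifting     1      0.002000
+composition     1      0.002000
```

The baseline model, which sees the dozen informative probes only in
their original registers, leaves the cognate near rank 400; weighting
the scarce high binders recovers an order of magnitude; register-shift
augmentation takes it to rank 1. The numbered drivers under `analysis/`
run the complete narrative (simulation → QC → preprocessing → training
→ ablation ladder → substitution scans → antigen tiling → robustness
grids) and write their tables under `results/`.

There is also a CLI:

```bash
epibind simulate --preset abundant-signal --seed 1
epibind rank --preset abundant-signal --seed 1
epibind accept --preset scarce-signal --seed 1
```

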