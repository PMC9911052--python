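# ghatpy — a test for selection on polygenic traits

Breeding and natural selection on a complex trait move allele frequencies
at many loci, each by an amount far too small for per-locus selection
scans. `ghatpy` implements the **Ghat** test, which detects such polygenic
selection by combining every genotyped marker into one composite statistic:

```
Ghat = Σ_j  Δ_j · α_j
```

where `Δ_j` is the allele-frequency change of marker *j* between an early
and a late sample of a population and `α_j` is the marker's estimated
allele-substitution effect. Under pure drift the two are unrelated and
Ghat hovers near zero; directional selection drives it away from zero in
the direction of the trait change. Significance comes from permuting the
effect vector against the change vector, with the permutation null widened
by `sqrt(m / M_eff)` — `M_eff` being the effective number of independent
genome segments — because markers in linkage disequilibrium are not
independent observations.

The package is aimed at quantitative geneticists and breeders who have
genotypes from two (or more) time points — historical seed or tissue DNA
plus modern samples is enough — and phenotypes from at least a modern
subset. It covers the full workflow: genotype/map/phenotype input (CSV,
VCF, PLINK `.raw`), marker-effect estimation by RR-BLUP (REML) or BayesC,
allele-frequency contrasts, LD-decay and simpleM estimates of `M_eff`, the
permutation test with scale/trim/naive LD handling, and a forward-in-time
Wright–Fisher simulator of divergently selected populations used for
validation throughout.

## Worked example

Simulate a pair of cattle-like populations that share founders — one mates
at random for 20 generations, the other undergoes truncation selection
(top 20% by phenotype) — then run the complete scan (RR-BLUP effects from
all generations, frequency change between generations 15 and 20, simpleM,
scale-method permutation test):

```python
import ghatpy as gp

cfg = gp.desk_scale(n=200, n_markers=600, n_qtl=60, seed=1)
neutral, selected = gp.simulate_pair(cfg)
for study in (neutral, selected):
    res = gp.scan_study(study, seed=1)
    print(f"{study.tag:12s} Ghat = {res.ghat:+.3f}  p = {res.p_value:.3g}  "
          f"direction = {res.direction}  M_eff = {res.num_eff}/{res.m}")
```

prints

```
A_unselected Ghat = -0.012  p = 0.812  direction = none  M_eff = 495/600
B_selected   Ghat = +0.423  p = 0.00489  direction = positive  M_eff = 311/600
```

The unselected population shows no relation between frequency changes and
effects (p = 0.81). In the selected population trait-increasing alleles
rose in frequency: Ghat is positive and significant (p < 0.01), and the
direction call reports positive selection. Note the smaller `M_eff` in the
selected population — selection itself builds linkage disequilibrium, which
the scale correction absorbs.

The same analysis runs from files:

```sh
ghat simulate --preset desk --n 200 --n-markers 600 --n-qtl 60 \
    --selection truncation --seed 1 --out sim_out
ghat run --genotypes sim_out/genotypes.csv --map sim_out/map.csv \
    --phenotypes sim_out/phenotypes.csv --trait sim_trait \
    --method scale --seed 1 --out ghat_out
```

which writes a one-row result table, a JSON sidecar with the full test
record (including the permutation-null summary and a provenance block),
and the intermediate effects/change tables. `ghat test` accepts
precomputed two-column effect and change files for the minimal two-vector
entry point; `ghat ld-decay`, `ghat effects`, `ghat sweep` expose the
individual stages. When phenotypes exist only for recent samples, pass
`mode = "modern_phenotypes"` (with `modern_groups`) to fit effects on that
subset while still contrasting frequencies across the full time span.

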