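# bcrep — B cell receptor repertoire variability analysis

High-throughput sequencing of the B cell receptor (BCR) heavy chain gives a
snapshot of the circulating B cell repertoire, but its interpretation hinges
on questions this package quantifies: how much of the repertoire does a
sample of B cells and a fixed sequencing depth actually capture, how
repeatable is that measurement across PCR and biological replicates, how
much does a healthy repertoire fluctuate over time, and how much is shared
between individuals (the public repertoire)?

`bcrep` is a tested, reusable implementation of the full analysis chain for
isotype-resolved heavy-chain repertoire data, together with a synthetic
repertoire simulator that provides ground truth for every stage, so every
estimator in the pipeline is validated by parameter recovery.

## The methods at the core

* **Clonal clustering.** Sequences are grouped into clusters (clonotypes)
  when they share V gene, J gene and CDR3 amino-acid length and their CDR3s
  differ by at most one substitution per *k* amino acids (default *k* = 12,
  i.e. ≥ 92% similarity), taking single-linkage connected components within
  each (V, J, length) partition. All samples are clustered jointly, so a
  cluster's presence can be compared across replicates, visits and
  participants. Nearest-neighbour CDR3 distance distributions (bimodal:
  clonal variants at 0–2 substitutions, unrelated clones at ≥ 3) justify
  the threshold; a threshold scan shows the cluster count is insensitive
  for *k* between 8 and 12.
* **Depth estimation.** Rarefaction curves of cluster richness *S* versus
  depth; the Chao estimator `S_chao = S_obs + f1²/(2 f2)` from singleton and
  doubleton cluster counts, with the standard extrapolation
  `S(n+m) = S_obs + f̂0·[1 − (1 − f1/(n·f̂0 + f1))^m]`; and the Chapman
  capture–recapture estimator `N̂ = (n1+1)(n2+1)/(m+1) − 1` applied to the
  cluster overlap between replicate samples. Replicate overlap is reported
  as `|A∩B| / min(|A|,|B|) × 100`.
* **Diversity.** Shannon entropy `H = −Σ p_i ln p_i`, Simpson concentration
  `C = Σ p_i²`, a cross-replicate clonality index `Σ_c f1(c) f2(c)`, and
  Hill diversity profiles `D_α = (Σ p_i^α)^{1/(1−α)}` over α = 0…10 (step
  0.5, with `D_1 = exp H`), clustered across samples by Euclidean distance
  and complete linkage. Cluster frequencies are the species abundances.
* **Repertoire metrics.** VJ usage vectors, Pearson correlation of usage
  between samples, centered (unscaled) PCA of usage across samples, mean
  CDR3 length / V-gene mutation load / subclass mix, and temporal
  persistence of clusters.
* **Public repertoire.** With joint clustering, a cluster seen in ≥ 2
  participants is public; sharing spectra, paired public-vs-private
  comparisons (Wilcoxon signed-rank over per-participant means), and
  antigen-specificity annotation: a cluster is labelled when a published
  antigen-specific CDR3 of the same length lies within the clustering
  allowance of its center.

The simulator (`bcrep.simulate`, `bcrep.study`) generates all of this from
ground truth: power-law clone abundances, junctional CDR3 diversity with
mutually distant clones, per-isotype error and hypermutation levels,
lognormal per-cell template abundance with per-PCR amplification noise, and
PCR / biological / temporal replicate designs with planted public clones.

## Worked example

The analysis drivers under `analysis/` replay the whole study on a
simulated cohort (ten participants, one sampled at five weekly visits with
IgG biological and PCR replicate pairs; 3,000 reads per sample):

```bash
python analysis/01_simulate_cohort.py
python analysis/04_depth_and_size.py
```

prints, among other tables,

```
mean replicate overlap (% of smaller replicate's clusters):
            total_overlap_pct  abundant_overlap_pct
design
biological               42.4                  56.6
pcr                      69.3                  77.8
```

— PCR replicates of the same aliquot agree far better than biological
replicates (they share cells and templates, not just the donor), and in
both designs the abundant clusters (≥ 10 sequences) are recovered much more
reliably than the full cluster list. `analysis/06_repertoire_metrics.py`
shows VJ usage correlating at r ≈ 0.99 between replicates but r ≈ 0 between
participants, and `analysis/07_public_repertoire.py` recovers the planted
public clones as a ~0.3–0.4% public repertoire that is larger, differently
mutated, and strongly enriched for the planted antigen specificities.
Summary tables land in `results/`; full simulated read tables in
`scratch/`.

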