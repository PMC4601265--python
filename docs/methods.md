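# Methods

This note documents the generative model behind the simulator, the
statistical procedures the package implements, the numerical and design
choices that were genuinely open, and what the synthetic validation does
and does not establish about real repertoire data.

## Generative model

A study is simulated in three layers.

**Latent repertoire.** Each (participant, isotype) carries a repertoire of
`n_clones` clones. Clone frequencies follow a Zipf law `p_r ∝ r^−s` over
abundance ranks: a one-parameter family that reproduces the observed shape
of cluster-size distributions (a small abundant head, a long rare tail).
The library default is `s = 1.5`; the cohort driver uses `s = 1.1`, which
puts the top clone at ≈ 18% of reads — the regime real 100,000-read
samples show, where the largest cluster reaches roughly a fifth of the
repertoire. CDR3s are amino-acid strings with the conserved C…W flanks
around a random core whose length is Poisson-distributed (mean 13, total
length ≈ 15, matching typical mean heavy-chain CDR3 lengths); a candidate
is rejected until it is ≥ 3 substitutions from every same-length clone
already drawn, making distinct clones mutually distant. V and J segments
are drawn with participant-specific lognormal usage tilts (σ = 1.0 for V,
0.7 for J), giving each simulated individual a stable, unique VJ usage
signature. Per-clone hypermutation levels are gamma-distributed with
isotype-specific means (IgA 18, IgG 16, IgM 2 V-gene nucleotide
mutations): class-switched isotypes are heavily mutated, IgM is dominated
by naive cells. Subclasses are a per-clone categorical draw
(IgG1/2/3/4 = 0.50/0.35/0.10/0.05, IgA1/2 = 0.8/0.2).

**Cell aliquot.** Cells are a multinomial draw from the clone
frequencies. Each cell also receives a lognormal template abundance
(σ = 1.0), modelling cell-to-cell differences in immunoglobulin RNA
content; this is a property of the aliquot, not of a PCR run.

**Sequencing.** Reads are drawn from cells in proportion to template
abundance times a fresh lognormal amplification factor (σ = 0.3, redrawn
per PCR). Constant-region mismatches are binomial at the per-isotype assay
error rate (IgA 0.0021, IgG 0.0079, IgM 0.0019 errors per nucleotide over
a 300-nt constant segment); CDR3s pick up substitutions at 0.01 per
residue (`within_clone_diversification`), so intra-clone nearest-neighbour
distances fall in 0–2 while inter-clone distances stay ≥ 3 — the bimodal
distance distribution the clustering threshold exploits.

**Replicate designs.** PCR replicates share the cell draw and template
abundances and differ only in amplification and error noise; biological
replicates are independent aliquots from the same latent repertoire;
temporal replicates perturb clone frequencies by multiplicative lognormal
noise (`drift`, cohort default 0.5 per visit) and replace a `turnover`
fraction of clones (cohort default 0.25) with newborn clones before each
draw. Planted public clones persist through turnover. The split of
amplification noise into a shared template component and a smaller
per-PCR component is what makes PCR replicates reproducibly better than
biological replicates at the cluster level, as observed in real assays.

**Public clones.** A per-isotype pool of clones is inserted verbatim into
every participant's repertoire, taking over the frequency of the private
clone displaced. The cohort plants them at "expanded" ranks — upper but
not top abundance — so the public repertoire is enriched for expanded
clusters while each participant's dominant clones remain private. (Planting
at the extreme head instead makes all participants' top clones identical
and erases inter-individual VJ variation; the option remains for targeted
recovery tests.) A subset of the pool's CDR3s seeds the antigen reference
lists, emulating specificities all participants have historically
encountered; decoy reference CDR3s matching nothing are added so that
annotation is not trivially exhaustive.

## Statistical procedures

* **Clustering rule.** Same V call, same J call, same CDR3 length, Hamming
  distance ≤ ⌊L/k⌋ (k = 12 by default), single-linkage connected
  components within each (V, J, length) partition, computed jointly over
  all samples. Single linkage is the minimal rule consistent with "a
  sequence this similar would have fallen into the cluster"; the floor
  means CDR3s shorter than k require identity (a `min_allowed` option
  raises the floor to 1 for users who prefer the lenient reading). The
  cluster center is the modal member CDR3, ties broken lexicographically;
  clusters with identical centers but different V/J are distinct. Cluster
  ids are assigned in canonical (V, J, length, center) order, so the
  partition is invariant to record and sample order.
* **Chao richness.** `S_obs + f1²/(2 f2)`, falling back to the
  bias-corrected `S_obs + f1(f1−1)/2` when there are no doubletons.
  Extrapolation uses `f̂0 = S_chao − S_obs` and approaches the Chao
  asymptote monotonically; values beyond about twice the observed depth
  are rough. The depth to reach a fraction of the asymptote is read off
  the curve by grid scan; fraction 1.0 with singletons present is
  unreachable and reported as infinity.
* **Rarefaction** subsamples without replacement at a configurable step
  (Monte-Carlo mean over `repeats` draws); an exact mode evaluates the
  hypergeometric expectation `Σ_i [1 − C(N−n_i, d)/C(N, d)]` and serves as
  the oracle for the Monte-Carlo path.
* **Chapman estimator.** `(n1+1)(n2+1)/(m+1) − 1` on the cluster counts of
  two replicates and their overlap. Equal catchability is assumed;
  power-law abundances violate it and deflate the estimate, so it is a
  lower bound on effective repertoire size (the validation below
  quantifies this).
* **Diversity.** Hill numbers over α = 0…10 step 0.5, with the α = 1 limit
  `exp(H)` (α within 1e-9 of 1 is routed to the limit). Frequencies are
  cluster frequencies, not unique-sequence frequencies. The clonality
  index is the cross-replicate coincidence probability `Σ_c f1(c) f2(c)`
  — the published description of the quantity is verbal, and this
  coincidence-probability form (which reduces to Simpson's index for
  identical replicates) is our documented interpretation.
* **Paired public-vs-private tests.** Per participant, the mean metric
  over public clusters and over private clusters forms one pair; pairs are
  compared with the Wilcoxon signed-rank test. The motivating description
  ("paired Mann-Whitney U") names an unpaired test; the signed-rank test
  is the standard paired analogue and is what we run. Participants lacking
  either class are excluded with a warning. A calibration utility draws
  both classes from one distribution and confirms the nominal type-I
  error (≈ 0.049 exactly at n = 10, within 0.05 ± 0.02 over 500 runs).
* **PCA of VJ usage** centers but does not scale columns (usage fractions
  share a scale already); component signs are fixed by making each
  component's largest-magnitude loading positive. Usage vectors are
  aligned on the union of VJ keys with zeros for absent combinations, for
  PCA and for Pearson correlations alike.
* **Percent-sampled values** are rounded half-up to one decimal, matching
  the presentation convention of published capture–recapture summaries;
  `bcrep.reference_tables` carries one such published-style IgG table whose
  percent columns, summary row and fluctuation ratios the suite re-derives
  exactly from the printed counts.

## Validation by parameter recovery, and its limits

The calibration experiments run at desk scale and are seeded; sizes were
chosen so the whole suite runs in well under a minute:

* Chapman on two biological replicates (1,000 cells, 2,500 reads each) of
  a uniform-abundance 500-clone repertoire, through the full clustering
  path: mean estimate 499.8 over 20 repeats (SE ≈ 1.2).
* Chao extrapolation on a uniform 5,000-clone repertoire sequenced to
  20,000 reads: plateau ≈ 4,650, about 7% below truth — the lognormal
  amplification overdisperses read counts, and Chao is a lower bound.
* Both calibrations switch within-clone diversification off so that
  clusters coincide with clones and the estimator is tested in isolation;
  with it on, occasional two-substitution variants fragment into spurious
  singleton clusters and add a small upward richness bias.
* Monte-Carlo rarefaction agrees with the hypergeometric closed form
  within 2% at every depth; Hill identities (D₀ = S, D₁ = e^H,
  D₂ = 1/Simpson) hold to 1e-9; the clustering partition is identical to a
  brute-force pairwise connected-components oracle on 1,000-sequence
  instances.

What passing these tests shows — and does not. The simulator reproduces
the statistical structure the analyses rely on: bimodal CDR3 distances,
heavy-tailed cluster sizes, per-isotype error and mutation levels,
replicate hierarchies, stable participant-specific VJ biases, a small
expanded public repertoire. It does not emulate nucleotide-level VDJ
junctions, SHM hotspot targeting, allele-level genotype variation, light
chains, or real germline segment sequences; clone CDR3s are mutually
distant by construction, so chance near-neighbour pairs between unrelated
clones are rarer than in real data. Two visible consequences: the
threshold scan shows the plateau at k = 8–12 and the sharp cluster-count
rise above k = 12, but not the additional sharp drop below k = 8 that real
data show when unrelated near-neighbours start to merge; and sharing
spectra can contain a few non-planted "public" singletons that are
identical one-substitution variants of abundant planted clones arising
independently in two participants — chance sequence convergence, which
real repertoires also exhibit. Absolute numbers from the desk-scale cohort
(e.g. ~40% of a sample's clusters captured per visit, ~25% of clusters
detected on more than one visit) sit in realistic ranges but are not
calibrated to any particular dataset; the directional contrasts (PCR >
biological overlap, abundant > total, public larger/enriched, within- >
between-participant usage similarity) are the validated claims.

## Degenerate inputs and tie-breaks

Empty CDR3s are skipped with a warning during clustering; sequences with
no same-length comparator are excluded from nearest-neighbour histograms
and counted separately. Zero-variance usage vectors make the Pearson
correlation undefined (NaN with a warning). Identical diversity profiles
merge at distance zero, with profiles sorted by label before linkage so
ties resolve deterministically. All-zero paired differences short-circuit
the signed-rank test to p = 1. Every stochastic operation takes an
explicit seed; pipeline-level seeds derive per-stage seeds via a seeded
generator, and fixed seeds reproduce results bit for bit.
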