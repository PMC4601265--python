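"""Synthetic heavy-chain repertoire simulator with ground truth.

The generative model mirrors what an isotype-specific repertoire sequencing
assay observes:

1.  A latent repertoire of B cell clones per (participant, isotype).  Each
    clone has a V gene, J gene, CDR3 amino-acid sequence, a true circulating
    frequency drawn from a power law (a small abundant head, a long rare
    tail), a somatic-hypermutation level and an isotype subclass.
2.  A cell aliquot drawn multinomially from the clone frequencies.
3.  Reads drawn from cells with lognormal per-cell amplification noise
    (PCR efficiency differences), per-read CDR3 diversification (clonal
    variants plus residual sequencing error on the junction) and binomial
    constant-region mismatches at a per-isotype error rate.

Distinct clones get CDR3s that are mutually distant (>= 3 substitutions for
same-length pairs), while reads within a clone stay within 0-2 substitutions
of the clone sequence, so nearest-neighbour distance distributions of the
simulated reads are bimodal, as observed in real repertoires.

Every operation takes an explicit integer seed and is reproducible bit for
bit; pipeline-level helpers derive per-stage seeds deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from bcrep.records import ISOTYPES, RepertoireSample, SequenceRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

#: constant-region PCR+sequencing error rates (errors per nucleotide) used
#: as per-isotype defaults; IgG amplicons are the noisiest in this assay.
DEFAULT_ERROR_RATES = {"IgA": 0.0021, "IgG": 0.0079, "IgM": 0.0019}

#: mean V-gene nucleotide mutation counts per isotype: class-switched IgA/IgG
#: sequences are heavily hypermutated, IgM is dominated by naive cells.
DEFAULT_SHM_MEANS = {"IgA": 18.0, "IgG": 16.0, "IgM": 2.0}

DEFAULT_SUBCLASS_PROBS = {
    "IgA": {"IgA1": 0.8, "IgA2": 0.2},
    "IgG": {"IgG1": 0.5, "IgG2": 0.35, "IgG3": 0.1, "IgG4": 0.05},
    "IgM": {"IgM": 1.0},
}


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-stage seeds (< 2**31) from one seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# germline universe


@dataclass(slots=True)
class GermlineDB:
    """The germline segment universe a simulated assay draws from."""

    v_genes: list[tuple[str, str]]
    j_genes: list[tuple[str, str]]
    constant_regions: dict[str, str]
    subclass_sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        v_names = [n for n, _ in self.v_genes]
        j_names = [n for n, _ in self.j_genes]
        if len(set(v_names)) != len(v_names) or len(set(j_names)) != len(j_names):
            raise ValueError("V and J gene names must be unique")
        for iso, subs in self.subclass_sets.items():
            if not subs:
                raise ValueError(f"isotype {iso} has no subclasses")
        for iso, seq in self.constant_regions.items():
            if not seq:
                raise ValueError(f"empty constant region for {iso}")


def make_germline_db(n_v: int, n_j: int, seed: int, c_region_length: int = 300) -> GermlineDB:
    """Build a germline database with IGHV/IGHJ-style segment names."""
    if n_v < 1 or n_j < 1:
        raise ValueError("n_v and n_j must be >= 1")
    rng = np.random.default_rng(seed)
    v_genes = [(f"IGHV{1 + i % 7}-{1 + i // 7}", "*01") for i in range(n_v)]
    j_genes = [(f"IGHJ{i + 1}", "*01") for i in range(n_j)]
    constant = {
        iso: "".join(rng.choice(list(_NT), size=c_region_length)) for iso in ISOTYPES
    }
    return GermlineDB(
        v_genes=v_genes,
        j_genes=j_genes,
        constant_regions=constant,
        subclass_sets={k: list(v) for k, v in DEFAULT_SUBCLASS_PROBS.items()},
    )


# ---------------------------------------------------------------------------
# latent repertoire


@dataclass(slots=True)
class Clone:
    """A latent B cell clone: the ground-truth unit the pipeline estimates."""

    v_gene: str
    j_gene: str
    cdr3_aa: str
    true_frequency: float
    mean_mutations: float
    isotype: str
    subclass: str
    is_public: bool = False

    def __post_init__(self) -> None:
        if len(self.cdr3_aa) < 4:
            raise ValueError("CDR3 must be at least 4 amino acids")


@dataclass(slots=True)
class TrueRepertoire:
    participant: str
    timepoint: int
    isotype: str
    clones: list[Clone]
    seed: int

    def __post_init__(self) -> None:
        triples = {(c.v_gene, c.j_gene, c.cdr3_aa) for c in self.clones}
        if len(triples) != len(self.clones):
            raise ValueError("clone (V, J, CDR3) triples must be unique")
        total = sum(c.true_frequency for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone frequencies sum to {total}, not 1")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c.true_frequency for c in self.clones])


def _random_cdr3(rng: np.random.Generator, core_mean: float) -> str:
    """Junctional-diversity CDR3: random core flanked by the conserved C...W."""
    core_len = max(2, int(rng.poisson(core_mean)))
    core = "".join(rng.choice(list(AA_ALPHABET), size=core_len))
    return "C" + core + "W"


def _min_same_length_distance(cdr3: str, by_length: dict[int, list[np.ndarray]]) -> int:
    arrs = by_length.get(len(cdr3))
    if not arrs:
        return len(cdr3)
    cand = np.frombuffer(cdr3.encode(), dtype=np.uint8)
    mat = np.stack(arrs)
    return int((mat != cand).sum(axis=1).min())


def simulate_repertoire(
    db: GermlineDB,
    n_clones: int,
    abundance_shape: float = 1.5,
    shm_mean: float | None = None,
    public_pool: list[Clone] | None = None,
    seed: int = 0,
    *,
    isotype: str = "IgG",
    participant: str = "P01",
    timepoint: int = 0,
    cdr3_core_mean: float = 13.0,
    min_clone_distance: int = 3,
    public_slots: str = "random",
    subclass_probs: dict[str, float] | None = None,
) -> TrueRepertoire:
    """Draw a latent repertoire with power-law clone abundances.

    Clone frequencies follow a Zipf law ``p_r ∝ r**-abundance_shape`` over
    abundance ranks, reproducing the small abundant head and the large rare
    tail of sequenced repertoires with a single parameter.  CDR3s are
    rejected until they are at least ``min_clone_distance`` substitutions
    from every same-length clone already drawn, so distinct clones are
    mutually distant.  ``public_pool`` clones are inserted verbatim, taking
    over the frequency of the private clone they displace (``public_slots``:
    "random" slots; "head" plants them as the most abundant clones;
    "expanded" plants them at upper-but-not-top abundance ranks, so they
    are larger than typical private clones while each participant's
    dominant clones stay private).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if abundance_shape <= 0:
        raise ValueError("abundance_shape must be > 0")
    rng = np.random.default_rng(seed)
    shm = DEFAULT_SHM_MEANS[isotype] if shm_mean is None else shm_mean
    sub_probs = subclass_probs or DEFAULT_SUBCLASS_PROBS[isotype]
    sub_names = list(sub_probs)
    sub_p = np.array([sub_probs[s] for s in sub_names], dtype=float)
    sub_p = sub_p / sub_p.sum()

    ranks = np.arange(1, n_clones + 1, dtype=float)
    freqs = ranks**-abundance_shape
    freqs /= freqs.sum()

    v_names = [n for n, _ in db.v_genes]
    j_names = [n for n, _ in db.j_genes]
    # V/J usage biases: participant-specific lognormal tilt over segments
    v_w = rng.lognormal(0.0, 1.0, size=len(v_names))
    j_w = rng.lognormal(0.0, 0.7, size=len(j_names))
    v_w /= v_w.sum()
    j_w /= j_w.sum()

    by_length: dict[int, list[np.ndarray]] = {}
    seen: set[tuple[str, str, str]] = set()
    clones: list[Clone] = []
    for i in range(n_clones):
        while True:
            cdr3 = _random_cdr3(rng, cdr3_core_mean)
            if _min_same_length_distance(cdr3, by_length) < min_clone_distance:
                continue
            v = v_names[rng.choice(len(v_names), p=v_w)]
            j = j_names[rng.choice(len(j_names), p=j_w)]
            if (v, j, cdr3) not in seen:
                break
        seen.add((v, j, cdr3))
        by_length.setdefault(len(cdr3), []).append(
            np.frombuffer(cdr3.encode(), dtype=np.uint8)
        )
        clones.append(
            Clone(
                v_gene=v,
                j_gene=j,
                cdr3_aa=cdr3,
                true_frequency=float(freqs[i]),
                mean_mutations=float(rng.gamma(2.0, shm / 2.0)) if shm > 0 else 0.0,
                isotype=isotype,
                subclass=sub_names[rng.choice(len(sub_names), p=sub_p)],
            )
        )

    if public_pool:
        if len(public_pool) > n_clones:
            raise ValueError("public_pool larger than repertoire")
        existing = {(c.v_gene, c.j_gene, c.cdr3_aa): i for i, c in enumerate(clones)}
        if public_slots == "head":
            slots = list(range(len(public_pool)))
        elif public_slots == "expanded":
            lo = min(4, n_clones - len(public_pool))
            hi = max(lo + len(public_pool), min(n_clones, max(16, n_clones // 10)))
            slots = list(rng.choice(np.arange(lo, hi), size=len(public_pool), replace=False))
        elif public_slots == "random":
            slots = list(rng.choice(n_clones, size=len(public_pool), replace=False))
        else:
            raise ValueError(f"unknown public_slots mode: {public_slots!r}")
        for pub, slot in zip(public_pool, slots):
            key = (pub.v_gene, pub.j_gene, pub.cdr3_aa)
            if key in existing:
                warnings.warn(f"public clone {key} collides with a private clone; replacing it")
                slot = existing[key]
            clones[slot] = Clone(
                v_gene=pub.v_gene,
                j_gene=pub.j_gene,
                cdr3_aa=pub.cdr3_aa,
                true_frequency=clones[slot].true_frequency,
                mean_mutations=pub.mean_mutations,
                isotype=isotype,
                subclass=pub.subclass,
                is_public=True,
            )
            existing[key] = slot

    return TrueRepertoire(
        participant=participant, timepoint=timepoint, isotype=isotype,
        clones=clones, seed=seed,
    )


def uniform_repertoire(
    db: GermlineDB, n_clones: int, seed: int, **kwargs
) -> TrueRepertoire:
    """A repertoire whose clones all share the same true frequency.

    The equal-abundance setting in which capture-recapture and richness
    estimators are exactly calibrated; used to validate them before applying
    them to skewed repertoires."""
    rep = simulate_repertoire(db, n_clones, abundance_shape=1.0, seed=seed, **kwargs)
    for clone in rep.clones:
        clone.true_frequency = 1.0 / n_clones
    return TrueRepertoire(
        participant=rep.participant, timepoint=rep.timepoint,
        isotype=rep.isotype, clones=rep.clones, seed=seed,
    )


def make_public_pool(
    db: GermlineDB,
    n_public: int,
    seed: int,
    cdr3_core_mean: float = 13.0,
    isotype: str = "IgG",
) -> list[Clone]:
    """Draw a pool of clones to share verbatim across simulated participants."""
    rng = np.random.default_rng(seed)
    pool: list[Clone] = []
    seen: set[str] = set()
    while len(pool) < n_public:
        cdr3 = _random_cdr3(rng, cdr3_core_mean)
        if cdr3 in seen:
            continue
        seen.add(cdr3)
        v = db.v_genes[rng.integers(len(db.v_genes))][0]
        j = db.j_genes[rng.integers(len(db.j_genes))][0]
        subs = DEFAULT_SUBCLASS_PROBS[isotype]
        pool.append(
            Clone(
                v_gene=v, j_gene=j, cdr3_aa=cdr3, true_frequency=0.0,
                mean_mutations=float(rng.gamma(2.0, DEFAULT_SHM_MEANS[isotype] / 2.0)),
                isotype=isotype, subclass=list(subs)[0], is_public=True,
            )
        )
    return pool


# ---------------------------------------------------------------------------
# sequencing


@dataclass(slots=True)
class ReadSet:
    """Sampled annotated reads plus the ground truth behind them."""

    records: list[SequenceRecord]
    truth_map: dict[str, int]
    design: str
    participant: str
    day: int
    isotype: str
    replicate: str
    raw_reads: list | None = None

    def to_sample(self) -> RepertoireSample:
        return RepertoireSample(
            participant=self.participant, day=self.day, isotype=self.isotype,
            replicate=self.replicate, records=list(self.records),
        )


def _draw_cells(
    rep: TrueRepertoire,
    n_cells: int,
    rng: np.random.Generator,
    template_sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a cell aliquot and its per-cell template abundances.

    Template (RNA) content varies lognormally from cell to cell and is a
    property of the aliquot: PCR replicates re-amplify the same templates,
    so these weights are shared across them."""
    counts = rng.multinomial(n_cells, rep.frequencies)
    cell_clones = np.repeat(np.arange(len(counts)), counts)
    templates = rng.lognormal(0.0, template_sigma, size=len(cell_clones))
    return cell_clones, templates


def _mutate_cdr3(cdr3: str, rng: np.random.Generator, p_sub: float) -> str:
    if p_sub <= 0:
        return cdr3
    n_sub = rng.binomial(len(cdr3), p_sub)
    if n_sub == 0:
        return cdr3
    pos = rng.choice(len(cdr3), size=min(n_sub, len(cdr3)), replace=False)
    chars = list(cdr3)
    for p in pos:
        chars[p] = AA_ALPHABET[rng.integers(len(AA_ALPHABET))]
    return "".join(chars)


def _reads_from_cells(
    rep: TrueRepertoire,
    cell_clones: np.ndarray,
    templates: np.ndarray,
    n_reads: int,
    error_rate: float,
    within_clone_diversification: float,
    rng: np.random.Generator,
    amplification_sigma: float,
    c_region_length: int,
    replicate: str,
    design: str,
) -> ReadSet:
    weights = templates * rng.lognormal(0.0, amplification_sigma, size=len(cell_clones))
    weights = weights / weights.sum()
    read_cells = rng.choice(len(cell_clones), size=n_reads, p=weights)
    prefix = f"{rep.participant}_d{rep.timepoint}_{rep.isotype}_{replicate}"
    records: list[SequenceRecord] = []
    truth: dict[str, int] = {}
    for i, cell in enumerate(read_cells):
        clone = rep.clones[int(cell_clones[cell])]
        rid = f"{prefix}_{i:06d}"
        records.append(
            SequenceRecord(
                id=rid,
                v_gene=clone.v_gene,
                j_gene=clone.j_gene,
                cdr3_aa=_mutate_cdr3(clone.cdr3_aa, rng, within_clone_diversification),
                v_mutation_count=int(rng.poisson(clone.mean_mutations)),
                isotype=rep.isotype,
                subclass=clone.subclass,
                c_region_mismatches=int(rng.binomial(c_region_length, error_rate)),
                c_region_length=c_region_length,
            )
        )
        truth[rid] = int(cell_clones[cell])
    return ReadSet(
        records=records, truth_map=truth, design=design,
        participant=rep.participant, day=rep.timepoint, isotype=rep.isotype,
        replicate=replicate,
    )


def sample_reads(
    rep: TrueRepertoire,
    n_cells: int,
    n_reads: int,
    error_rate: float | None = None,
    within_clone_diversification: float = 0.01,
    seed: int = 0,
    *,
    template_sigma: float = 1.0,
    amplification_sigma: float = 0.3,
    c_region_length: int = 300,
    replicate: str = "rep1",
    design: str = "single",
) -> ReadSet:
    """Sequence a cell aliquot from a latent repertoire.

    Cells are a multinomial draw from the true clone frequencies; reads are
    drawn from cells in proportion to lognormal per-cell template abundance
    (``template_sigma``, a property of the aliquot) times lognormal
    per-amplification noise (``amplification_sigma``, redrawn per PCR);
    constant-region mismatches are binomial at ``error_rate`` (per-isotype
    default if None); CDR3s pick up substitutions at
    ``within_clone_diversification`` per residue, keeping intra-clone
    nearest-neighbour distances in 0-2.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rate = DEFAULT_ERROR_RATES[rep.isotype] if error_rate is None else error_rate
    if not 0 <= rate < 1:
        raise ValueError("error_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    cell_clones, templates = _draw_cells(rep, n_cells, rng, template_sigma)
    return _reads_from_cells(
        rep, cell_clones, templates, n_reads, rate, within_clone_diversification,
        rng, amplification_sigma, c_region_length, replicate, design,
    )


def drift_repertoire(
    rep: TrueRepertoire,
    drift: float,
    turnover: float,
    seed: int,
    timepoint: int,
) -> TrueRepertoire:
    """A later visit to the same repertoire: multiplicative lognormal
    frequency drift of magnitude ``drift``, and a ``turnover`` fraction of
    clones dying and being replaced by newborn clones."""
    rng = np.random.default_rng(seed)
    freqs = rep.frequencies.copy()
    if drift > 0:
        freqs = freqs * rng.lognormal(0.0, drift, size=len(freqs))
    clones = [
        Clone(
            v_gene=c.v_gene, j_gene=c.j_gene, cdr3_aa=c.cdr3_aa,
            true_frequency=0.0, mean_mutations=c.mean_mutations,
            isotype=c.isotype, subclass=c.subclass, is_public=c.is_public,
        )
        for c in rep.clones
    ]
    if turnover > 0:
        dead = np.nonzero(rng.random(len(clones)) < turnover)[0]
        taken = {(c.v_gene, c.j_gene, c.cdr3_aa) for c in clones}
        for idx in dead:
            old = clones[idx]
            if old.is_public:
                continue  # planted public clones persist across visits
            while True:
                cdr3 = _random_cdr3(rng, 13.0)
                key = (old.v_gene, old.j_gene, cdr3)
                if key not in taken:
                    break
            taken.add(key)
            clones[idx] = Clone(
                v_gene=old.v_gene, j_gene=old.j_gene, cdr3_aa=cdr3,
                true_frequency=0.0, mean_mutations=old.mean_mutations,
                isotype=old.isotype, subclass=old.subclass,
            )
    freqs = freqs / freqs.sum()
    for c, f in zip(clones, freqs):
        c.true_frequency = float(f)
    return TrueRepertoire(
        participant=rep.participant, timepoint=timepoint, isotype=rep.isotype,
        clones=clones, seed=seed,
    )


def make_replicates(
    rep: TrueRepertoire,
    design: str,
    n_replicates: int = 2,
    drift: float = 0.3,
    seed: int = 0,
    *,
    turnover: float = 0.0,
    n_cells: int = 2000,
    n_reads: int = 5000,
    error_rate: float | None = None,
    within_clone_diversification: float = 0.01,
    template_sigma: float = 1.0,
    amplification_sigma: float = 0.3,
    c_region_length: int = 300,
    timepoints: list[int] | None = None,
) -> list[ReadSet]:
    """Sequence a repertoire under a replicate design.

    ``pcr``        — one cell draw (shared cells and per-cell template
                     abundances), independent amplification and error noise
                     per replicate (re-running the PCR on the same aliquot).
    ``biological`` — independent cell aliquots from the same latent repertoire.
    ``temporal``   — clone frequencies perturbed by multiplicative lognormal
                     noise of magnitude ``drift`` before each draw, and a
                     ``turnover`` fraction of clones replaced by fresh ones
                     (clone death and birth between visits).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if design not in ("pcr", "biological", "temporal"):
        raise ValueError(f"unknown replicate design: {design!r}")
    rate = DEFAULT_ERROR_RATES[rep.isotype] if error_rate is None else error_rate
    seeds = spawn_seeds(seed, n_replicates + 1)
    out: list[ReadSet] = []

    if design == "pcr":
        cell_rng = np.random.default_rng(seeds[-1])
        cell_clones, templates = _draw_cells(rep, n_cells, cell_rng, template_sigma)
        for r in range(n_replicates):
            rng = np.random.default_rng(seeds[r])
            out.append(
                _reads_from_cells(
                    rep, cell_clones, templates, n_reads, rate,
                    within_clone_diversification, rng, amplification_sigma,
                    c_region_length, replicate=f"pcr{r + 1}", design="pcr_replicate",
                )
            )
        return out

    if design == "biological":
        for r in range(n_replicates):
            out.append(
                sample_reads(
                    rep, n_cells, n_reads, rate, within_clone_diversification,
                    seed=seeds[r], template_sigma=template_sigma,
                    amplification_sigma=amplification_sigma,
                    c_region_length=c_region_length, replicate=f"bio{r + 1}",
                    design="biological_replicate",
                )
            )
        return out

    # temporal
    days = timepoints if timepoints is not None else list(range(n_replicates))
    if len(days) != n_replicates:
        raise ValueError("timepoints must match n_replicates")
    for r in range(n_replicates):
        drifted = drift_repertoire(rep, drift, turnover, seeds[r], timepoint=days[r])
        out.append(
            sample_reads(
                drifted, n_cells, n_reads, rate, within_clone_diversification,
                seed=spawn_seeds(seeds[r], 1)[0],
                amplification_sigma=amplification_sigma,
                c_region_length=c_region_length, replicate="rep1",
                design="temporal",
            )
        )
    return out


# ---------------------------------------------------------------------------
# raw reads (for the FASTQ quality filter)


def synthesize_raw_reads(
    n_reads: int,
    seed: int,
    read_length: int = 350,
    ambiguous_read_fraction: float = 0.02,
    low_quality_read_fraction: float = 0.2,
    q_high: int = 38,
    q_low: int = 20,
):
    """Emit Biopython SeqRecords with Phred qualities for filter testing.

    A configurable fraction of reads carry an ambiguous base (N) and another
    fraction carry a >15% tail of low-quality bases, so the standard quality
    filter has work to do.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        seq = list(rng.choice(list(_NT), size=read_length))
        quals = [int(q_high)] * read_length
        roll = rng.random()
        if roll < ambiguous_read_fraction:
            seq[int(rng.integers(read_length))] = "N"
        elif roll < ambiguous_read_fraction + low_quality_read_fraction:
            n_low = int(read_length * rng.uniform(0.16, 0.5))
            for p in rng.choice(read_length, size=n_low, replace=False):
                quals[int(p)] = int(q_low)
        rec = SeqRecord(Seq("".join(seq)), id=f"raw_{i:06d}", description="")
        rec.letter_annotations["phred_quality"] = quals
        reads.append(rec)
    return reads
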