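"""Study-level cohort simulation.

Builds a full synthetic study at desk scale, mirroring the sampling design
the downstream analyses expect:

* one highly sampled participant (``P01``) with five weekly visits
  (days 0, 7, 14, 21, 28); at each visit an IgG sample plus, for IgG,
  a pair of biological replicates (independent cell aliquots) and a pair of
  PCR replicates (same aliquot, independent amplification);
* nine further participants sampled once, each with IgA, IgG and IgM
  samples;
* a small pool of public clones planted verbatim in every participant's
  repertoire, a subset of which match the antigen reference lists
  (historically encountered antigens), the rest of the repertoire private.

All sample sizes are configurable; the defaults are sized so the whole
cohort simulates in well under a minute while preserving the statistical
structure (power-law clone sizes, bimodal CDR3 distances, per-isotype error
and mutation levels, replicate hierarchy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from bcrep.public import AntigenReference
from bcrep.records import RepertoireSample
from bcrep.simulate import (
    Clone,
    GermlineDB,
    TrueRepertoire,
    drift_repertoire,
    make_germline_db,
    make_public_pool,
    make_replicates,
    sample_reads,
    simulate_repertoire,
    spawn_seeds,
)

DEFAULT_N_CLONES = {"IgA": 800, "IgG": 800, "IgM": 2000}


@dataclass(slots=True)
class Cohort:
    db: GermlineDB
    samples: list[RepertoireSample]
    truths: dict[tuple[str, str], TrueRepertoire]  # (participant, isotype) -> base repertoire
    public_pools: dict[str, list[Clone]]  # isotype -> planted public clones
    references: list[AntigenReference]
    seed: int

    def select(
        self,
        isotype: str | None = None,
        participant: str | None = None,
        day: int | None = None,
        replicate: str | None = None,
    ) -> list[RepertoireSample]:
        out = []
        for s in self.samples:
            if isotype is not None and s.isotype != isotype:
                continue
            if participant is not None and s.participant != participant:
                continue
            if day is not None and s.day != day:
                continue
            if replicate is not None and s.replicate != replicate:
                continue
            out.append(s)
        return out

    @property
    def participants(self) -> list[str]:
        return sorted({s.participant for s in self.samples})


def simulate_cohort(
    seed: int,
    n_participants: int = 10,
    days: tuple[int, ...] = (0, 7, 14, 21, 28),
    isotypes: tuple[str, ...] = ("IgA", "IgG", "IgM"),
    n_clones: dict[str, int] | None = None,
    n_public: int = 12,
    n_antigen_public: int = 6,
    n_cells: int = 1500,
    n_reads: int = 3000,
    drift: float = 0.5,
    turnover: float = 0.25,
    abundance_shape: float = 1.1,
    with_replicates: bool = True,
) -> Cohort:
    """Simulate the full study.

    ``n_public`` clones per isotype are planted verbatim in every
    participant at expanded (upper but not dominant) abundance ranks —
    the public repertoire is enriched for expanded clusters while each
    participant's top clones stay private; ``n_antigen_public`` of them
    are also written into the antigen reference lists, emulating
    specificities every participant has historically encountered.
    """
    n_clones = dict(DEFAULT_N_CLONES, **(n_clones or {}))
    seeds = iter(spawn_seeds(seed, 4 + n_participants * len(isotypes) * 16))
    db = make_germline_db(n_v=24, n_j=5, seed=next(seeds))

    public_pools: dict[str, list[Clone]] = {}
    references: list[AntigenReference] = []
    for iso in isotypes:
        public_pools[iso] = make_public_pool(db, n_public, seed=next(seeds), isotype=iso)
    # antigen references: CDR3s of a subset of the IgG+IgM public pools,
    # lightly split between two antigens, plus unmatched published sequences
    ref_cdr3s = {"TT": [], "influenza": []}
    for iso in isotypes:
        for i, clone in enumerate(public_pools[iso][:n_antigen_public]):
            ref_cdr3s["TT" if i % 2 == 0 else "influenza"].append(clone.cdr3_aa)
    decoys = make_public_pool(db, 10, seed=next(seeds))
    for i, clone in enumerate(decoys):
        ref_cdr3s["TT" if i % 2 == 0 else "influenza"].append(clone.cdr3_aa)
    references = [AntigenReference(antigen=a, cdr3s=c) for a, c in ref_cdr3s.items()]

    participants = [f"P{i + 1:02d}" for i in range(n_participants)]
    samples: list[RepertoireSample] = []
    truths: dict[tuple[str, str], TrueRepertoire] = {}

    for p_idx, participant in enumerate(participants):
        highly_sampled = p_idx == 0
        for iso in isotypes:
            base = simulate_repertoire(
                db, n_clones[iso], abundance_shape=abundance_shape,
                public_pool=public_pools[iso], seed=next(seeds),
                isotype=iso, participant=participant, public_slots="expanded",
            )
            truths[(participant, iso)] = base
            if not highly_sampled:
                rs = sample_reads(
                    base, n_cells, n_reads, seed=next(seeds), replicate="rep1",
                )
                samples.append(rs.to_sample())
                continue
            for day in days:
                visit = (
                    base if day == days[0]
                    else drift_repertoire(base, drift, turnover, next(seeds), timepoint=day)
                )
                if iso == "IgG" and with_replicates:
                    for rs in make_replicates(
                        visit, "biological", 2, seed=next(seeds),
                        n_cells=n_cells, n_reads=n_reads,
                    ):
                        samples.append(rs.to_sample())
                    for rs in make_replicates(
                        visit, "pcr", 2, seed=next(seeds),
                        n_cells=n_cells, n_reads=n_reads,
                    ):
                        samples.append(rs.to_sample())
                else:
                    rs = sample_reads(
                        visit, n_cells, n_reads, seed=next(seeds), replicate="rep1",
                    )
                    samples.append(rs.to_sample())

    return Cohort(
        db=db, samples=samples, truths=truths, public_pools=public_pools,
        references=references, seed=seed,
    )
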