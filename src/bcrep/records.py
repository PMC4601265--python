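"""Core sequence-level containers shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

_AA = set("ACDEFGHIKLMNPQRSTVWY")

ISOTYPES = ("IgA", "IgG", "IgM")


@dataclass(slots=True)
class SequenceRecord:
    """One annotated heavy-chain sequence.

    ``v_mutation_count`` counts nucleotide mutations in the V gene relative
    to germline (somatic hypermutation); ``c_region_mismatches`` counts
    nucleotide mismatches against the germline constant region, which is not
    hypermutated and therefore reflects PCR/sequencing error only.
    """

    id: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    v_mutation_count: int
    isotype: str
    subclass: str
    c_region_mismatches: int = 0
    c_region_length: int = 300

    def __post_init__(self) -> None:
        if self.cdr3_aa and not set(self.cdr3_aa) <= _AA:
            raise ValueError(f"CDR3 contains non-amino-acid letters: {self.cdr3_aa!r}")
        if self.v_mutation_count < 0:
            raise ValueError("v_mutation_count must be >= 0")
        if not 0 <= self.c_region_mismatches <= self.c_region_length:
            raise ValueError("c_region_mismatches must lie in [0, c_region_length]")


@dataclass(slots=True)
class RepertoireSample:
    """A set of sequences from one (participant, day, isotype, replicate)."""

    participant: str
    day: int
    isotype: str
    replicate: str
    records: list[SequenceRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.participant, self.day, self.isotype, self.replicate)

    @property
    def label(self) -> str:
        return f"{self.participant}_d{self.day}_{self.isotype}_{self.replicate}"

    def __len__(self) -> int:
        return len(self.records)
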