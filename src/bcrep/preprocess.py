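"""Quality filtering, fixed-depth subsampling, and error-rate estimation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from bcrep.records import RepertoireSample, SequenceRecord


@dataclass(slots=True)
class FilterSummary:
    n_input: int
    n_passed: int
    n_ambiguous: int
    n_low_quality: int


def quality_filter(
    reads,
    max_low_q_fraction: float = 0.15,
    q_threshold: int = 30,
):
    """Drop reads with ambiguous bases or too many low-quality bases.

    A read passes iff it contains no N and the fraction of bases with Phred
    quality below ``q_threshold`` is at most ``max_low_q_fraction`` (exactly
    15% low-quality bases still passes; the rule rejects *more than* 15%).
    ``reads`` may be Biopython SeqRecords with ``phred_quality`` annotations
    or a path to a FASTQ file (Sanger Phred+33).

    Returns ``(passing_reads, FilterSummary)``.  The filter is idempotent:
    re-filtering its output changes nothing.
    """
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        reads = list(SeqIO.parse(str(reads), "fastq"))
    passing = []
    n_ambig = n_lowq = 0
    for idx, rec in enumerate(reads):
        try:
            quals = rec.letter_annotations["phred_quality"]
        except (AttributeError, KeyError) as exc:
            raise ValueError(f"record {idx} carries no per-base qualities") from exc
        seq = str(rec.seq).upper()
        if "N" in seq:
            n_ambig += 1
            continue
        n_low = sum(q < q_threshold for q in quals)
        if n_low > max_low_q_fraction * len(quals):
            n_lowq += 1
            continue
        passing.append(rec)
    summary = FilterSummary(
        n_input=n_ambig + n_lowq + len(passing),
        n_passed=len(passing),
        n_ambiguous=n_ambig,
        n_low_quality=n_lowq,
    )
    return passing, summary


def subsample(
    records: RepertoireSample | Sequence[SequenceRecord],
    depth: int = 100_000,
    seed: int = 0,
):
    """Uniform fixed-depth subsample without replacement.

    Normalizes samples to a common sequencing depth so that richness and
    diversity are comparable across samples.  Applied per sample, never to
    pooled data.  Returns the same container type it was given.
    """
    if isinstance(records, RepertoireSample):
        picked = subsample(records.records, depth, seed)
        return RepertoireSample(
            participant=records.participant, day=records.day,
            isotype=records.isotype, replicate=records.replicate,
            records=picked,
        )
    n = len(records)
    if n < depth:
        raise ValueError(f"cannot subsample {depth} from {n} records (short by {depth - n})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=depth, replace=False)
    return [records[i] for i in idx]


def estimate_error_rate(
    records: Iterable[SequenceRecord] | RepertoireSample,
    by: str = "isotype",
) -> dict[str, float]:
    """Errors per nucleotide from constant-region mismatches.

    The constant region is germline-encoded and not somatically hypermutated,
    so mismatches against the germline constant sequence measure PCR and
    sequencing error directly.  The rate is the ratio of nucleotide totals,
    Σ mismatches / Σ aligned length, per group (default: per isotype).
    """
    if isinstance(records, RepertoireSample):
        records = records.records
    mism: dict[str, int] = {}
    length: dict[str, int] = {}
    for rec in records:
        key = getattr(rec, by)
        mism[key] = mism.get(key, 0) + rec.c_region_mismatches
        length[key] = length.get(key, 0) + rec.c_region_length
    if not length or any(v == 0 for v in length.values()):
        raise ValueError("zero total constant-region length")
    return {k: mism[k] / length[k] for k in sorted(length)}
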