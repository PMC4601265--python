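"""Tab-delimited I/O in AIRR-style rearrangement format.

Annotated reads travel as one row per sequence with AIRR-like column names
(``sequence_id``, ``v_call``, ``j_call``, ``cdr3_aa``, ...) plus the sample
labels, so tables round-trip through pandas and interoperate with other
repertoire tooling.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from bcrep.records import RepertoireSample, SequenceRecord
from bcrep.public import AntigenReference

REARRANGEMENT_COLUMNS = [
    "sequence_id", "v_call", "j_call", "cdr3_aa", "v_mutation_count",
    "isotype", "subclass", "c_region_mismatches", "c_region_length",
    "participant", "day", "replicate",
]


def sample_to_frame(sample: RepertoireSample) -> pd.DataFrame:
    rows = [
        {
            "sequence_id": r.id, "v_call": r.v_gene, "j_call": r.j_gene,
            "cdr3_aa": r.cdr3_aa, "v_mutation_count": r.v_mutation_count,
            "isotype": r.isotype, "subclass": r.subclass,
            "c_region_mismatches": r.c_region_mismatches,
            "c_region_length": r.c_region_length,
            "participant": sample.participant, "day": sample.day,
            "replicate": sample.replicate,
        }
        for r in sample.records
    ]
    return pd.DataFrame(rows, columns=REARRANGEMENT_COLUMNS)


def write_rearrangements(samples: Sequence[RepertoireSample] | RepertoireSample, path) -> None:
    if isinstance(samples, RepertoireSample):
        samples = [samples]
    frame = pd.concat([sample_to_frame(s) for s in samples], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False)


def read_rearrangements(path) -> list[RepertoireSample]:
    """Read a rearrangement TSV back into per-sample containers."""
    frame = pd.read_csv(path, sep="\t", dtype={"cdr3_aa": str, "subclass": str})
    missing = set(REARRANGEMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"rearrangement table is missing columns: {sorted(missing)}")
    samples = []
    group_cols = ["participant", "day", "isotype", "replicate"]
    for (participant, day, isotype, replicate), grp in frame.groupby(group_cols, sort=True):
        records = [
            SequenceRecord(
                id=row.sequence_id, v_gene=row.v_call, j_gene=row.j_call,
                cdr3_aa=row.cdr3_aa, v_mutation_count=int(row.v_mutation_count),
                isotype=row.isotype, subclass=row.subclass,
                c_region_mismatches=int(row.c_region_mismatches),
                c_region_length=int(row.c_region_length),
            )
            for row in grp.itertuples(index=False)
        ]
        samples.append(
            RepertoireSample(
                participant=str(participant), day=int(day), isotype=str(isotype),
                replicate=str(replicate), records=records,
            )
        )
    return samples


def write_truth_map(truth_map: dict[str, int], path) -> None:
    pd.DataFrame(
        {"sequence_id": list(truth_map), "clone_index": list(truth_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_antigen_references(path) -> list[AntigenReference]:
    """Two-column TSV (antigen, cdr3_aa) -> one reference per antigen."""
    frame = pd.read_csv(path, sep="\t")
    if not {"antigen", "cdr3_aa"} <= set(frame.columns):
        raise ValueError("reference table needs 'antigen' and 'cdr3_aa' columns")
    return [
        AntigenReference(antigen=str(a), cdr3s=[str(s) for s in grp["cdr3_aa"]])
        for a, grp in frame.groupby("antigen", sort=True)
    ]


def write_antigen_references(references: Sequence[AntigenReference], path) -> None:
    rows = [
        {"antigen": ref.antigen, "cdr3_aa": cdr3}
        for ref in references
        for cdr3 in ref.cdr3s
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fastq(reads, path) -> None:
    from Bio import SeqIO

    with open(path, "w") as handle:
        SeqIO.write(reads, handle, "fastq")
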