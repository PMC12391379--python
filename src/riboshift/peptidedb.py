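"""Immunopeptidomics search-database construction from scored ORF tables.

The chain mirrors the standard genomics route: filter the ORF table at
p ≤ 0.05, project transcript-space ORFs to genomic BED12 (splice-aware),
extract and translate the nucleotide sequence, keep products longer than
seven amino acids, deduplicate, and append to a reference proteome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .genome import TranscriptModel, extract_spliced_sequence

__all__ = [
    "PeptideRecord",
    "orfs_to_bed12",
    "translate_orf",
    "build_database",
    "write_fasta",
    "read_fasta",
]


@dataclass
class PeptideRecord:
    """A database entry: one unique peptide and every ORF that encodes it."""

    sequence: str
    source_orf_ids: list[str] = field(default_factory=list)

    @property
    def header(self) -> str:
        return ";".join(self.source_orf_ids)


def _orf_header(row) -> str:
    return (
        f"{row.gene_id}|{row.transcript_id}|{row.category}|"
        f"{row.start}-{row.end}|{row.start_codon}"
    )


def orfs_to_bed12(
    orf_table: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    pmax: Optional[float] = 0.05,
) -> pd.DataFrame:
    """Project ORFs (transcript space) to genomic BED12 records.

    Only ORFs with p ≤ ``pmax`` are emitted.  blockCount/blockSizes/
    blockStarts encode exon-split ORFs; thickStart/thickEnd span the whole
    ORF; strand comes from the transcript.
    """
    rows = []
    table = orf_table if pmax is None else orf_table[orf_table.p_value <= pmax]
    for row in table.itertuples(index=False):
        model = models[row.transcript_id]
        blocks = model.tx_interval_to_blocks(int(row.start), int(row.end))
        chrom_start = blocks[0][0]
        chrom_end = blocks[-1][1]
        sizes = ",".join(str(e - s) for s, e in blocks)
        starts = ",".join(str(s - chrom_start) for s, e in blocks)
        rows.append(
            dict(
                chrom=model.chrom,
                chromStart=chrom_start,
                chromEnd=chrom_end,
                name=_orf_header(row),
                score=0,
                strand=model.strand,
                thickStart=chrom_start,
                thickEnd=chrom_end,
                itemRgb="0",
                blockCount=len(blocks),
                blockSizes=sizes,
                blockStarts=starts,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "chromStart", "chromEnd", "name", "score", "strand",
            "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
            "blockStarts",
        ],
    )


def write_bed12(bed: pd.DataFrame, path: str | Path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


def translate_orf(nt: str, initiator_met: bool = True) -> str:
    """Translate an ORF nucleotide sequence to its peptide product.

    Standard nuclear codon table.  By default the initiator codon is decoded
    as methionine regardless of identity (initiator-tRNA convention for
    near-cognate starts; ``initiator_met=False`` decodes it literally).  The
    terminal stop codon is removed; an internal stop truncates the product
    (with a warning); a codon containing N decodes as X.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"ORF length {len(nt)} not divisible by 3")
    if len(nt) < 6:
        raise ValueError("ORF must be at least 6 nt (start + stop)")
    aa = str(Seq(nt).translate(table=1))
    if initiator_met:
        aa = "M" + aa[1:]
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        warnings.warn("internal stop codon; product truncated", stacklevel=2)
        aa = aa.split("*", 1)[0]
    return aa


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def build_database(
    orf_table: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    genome: Mapping[str, object],
    proteome: Sequence[tuple[str, str]],
    min_aa: int = 8,
    pmax: Optional[float] = 0.05,
    initiator_met: bool = True,
    tx_sequences: Optional[Mapping[str, str]] = None,
) -> tuple[list[tuple[str, str]], dict]:
    """Assemble the combined search database (proteome + ORF products).

    Translated ORF products strictly longer than seven amino acids (i.e.
    ≥ ``min_aa``) are kept; exact duplicate sequences are collapsed with
    their headers concatenated by ';'.  Output order is deterministic:
    proteome records first (input order), then ORF entries sorted by header.
    Returns (records, stats).
    """
    table = orf_table if pmax is None else orf_table[orf_table.p_value <= pmax]
    peptides: dict[str, PeptideRecord] = {}
    n_truncated = 0
    for row in table.itertuples(index=False):
        model = models[row.transcript_id]
        if tx_sequences is not None and row.transcript_id in tx_sequences:
            tx_seq = tx_sequences[row.transcript_id]
        else:
            tx_seq = extract_spliced_sequence(model, genome)
        nt = tx_seq[int(row.start) : int(row.end)]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            aa = translate_orf(nt, initiator_met=initiator_met)
        n_truncated += sum("truncated" in str(w.message) for w in caught)
        if len(aa) < min_aa:
            continue
        rec = peptides.setdefault(aa, PeptideRecord(aa))
        rec.source_orf_ids.append(_orf_header(row))
    if not peptides:
        warnings.warn(
            "no ORF product passed the filters; emitting proteome-only database",
            stacklevel=2,
        )
    orf_records = sorted(
        ((rec.header, seq) for seq, rec in peptides.items()), key=lambda r: r[0]
    )
    records = list(proteome) + orf_records
    stats = {
        "n_orf_entries": len(orf_records),
        "n_proteome_entries": len(proteome),
        "n_truncated": n_truncated,
    }
    return records, stats
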