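"""Transcript models, annotation parsing and coordinate algebra.

Everything downstream (P-site tracks, ORF calling, BED12 export) works in
transcript space; this module owns the conversion between genomic and
transcript coordinates and the extraction of spliced transcript sequence.

Conventions
-----------
* Internal coordinates are 0-based, half-open.  GTF (1-based, inclusive) is
  converted at the parsing boundary; BED is native.
* Exons are stored in transcript orientation (5'→3'), i.e. descending genomic
  start on the minus strand, which makes transcript-space arithmetic
  strand-free.
* ``cds_tx`` spans the start codon through the stop codon inclusive, so its
  length is divisible by three.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "read_annotation",
    "select_representative_isoform",
    "extract_spliced_sequence",
    "write_bed6",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """An exon-structured transcript with an optional CDS.

    Parameters
    ----------
    exons
        Genomic ``(start, end)`` pairs, 0-based half-open, ordered 5'→3' in
        transcript orientation (descending start on the minus strand).
    cds_tx
        Transcript-space ``(start, end)`` of the coding region (start codon
        through stop codon), or ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_tx: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
        by_start = sorted(self.exons)
        for (_, prev_end), (next_start, _) in zip(by_start, by_start[1:]):
            if next_start < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expected = sorted(self.exons, reverse=self.strand == "-")
        if list(self.exons) != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcript orientation"
            )
        if self.cds_tx is not None:
            s, e = self.cds_tx
            if not (0 <= s < e <= self.length):
                raise ValueError(f"{self.transcript_id}: CDS outside transcript")
            if (e - s) % 3 != 0:
                raise ValueError(
                    f"{self.transcript_id}: CDS length {e - s} not divisible by 3"
                )

    # -- derived geometry ---------------------------------------------------

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def utr5_len(self) -> int:
        return self.cds_tx[0] if self.cds_tx else 0

    @property
    def cds_len(self) -> int:
        return self.cds_tx[1] - self.cds_tx[0] if self.cds_tx else 0

    @property
    def utr3_len(self) -> int:
        return self.length - self.cds_tx[1] if self.cds_tx else self.length

    @property
    def lengths(self) -> tuple[int, int, int]:
        """(5'UTR, CDS, 3'UTR) lengths in nt; they sum to the transcript length."""
        return (self.utr5_len, self.cds_len, self.utr3_len)

    # -- coordinate algebra -------------------------------------------------

    def tx_to_genomic(self, pos: int) -> tuple[str, int, str]:
        """Map a transcript coordinate to (chrom, genomic position, strand).

        Transcript position 0 is the 5'-most base, which on the minus strand
        is the highest genomic coordinate.
        """
        if not 0 <= pos < self.length:
            raise ValueError(
                f"{self.transcript_id}: position {pos} outside [0,{self.length})"
            )
        off = pos
        for s, e in self.exons:
            n = e - s
            if off < n:
                g = s + off if self.strand == "+" else e - 1 - off
                return self.chrom, g, self.strand
            off -= n
        raise AssertionError("unreachable")

    def genomic_to_tx(self, gpos: int) -> int:
        """Inverse of :meth:`tx_to_genomic`; raises if ``gpos`` is intronic."""
        off = 0
        for s, e in self.exons:
            if s <= gpos < e:
                return off + (gpos - s if self.strand == "+" else e - 1 - gpos)
            off += e - s
        raise ValueError(
            f"{self.transcript_id}: genomic position {gpos} not exonic"
        )

    def tx_interval_to_blocks(self, start: int, end: int) -> list[tuple[int, int]]:
        """Project a transcript-space interval onto genomic exon blocks.

        Returns genomic ``(start, end)`` blocks sorted by genomic start
        (BED block order), covering exactly ``end - start`` bases.
        """
        if not 0 <= start < end <= self.length:
            raise ValueError(
                f"{self.transcript_id}: interval [{start},{end}) outside transcript"
            )
        blocks: list[tuple[int, int]] = []
        off = 0
        for s, e in self.exons:
            n = e - s
            lo = max(start, off)
            hi = min(end, off + n)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((s + (lo - off), s + (hi - off)))
                else:
                    blocks.append((e - (hi - off), e - (lo - off)))
            off += n
        return sorted(blocks)


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> dict[str, TranscriptModel]:
    """Parse a GTF (exon + CDS features) into :class:`TranscriptModel` objects.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open;
    CDS intervals are projected into transcript space and must be contained in
    the transcript's exons.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for f in db.features_of_type(ftype):
            if "transcript_id" not in f.attributes:
                raise ValueError(
                    f"{ftype} feature at {f.seqid}:{f.start}-{f.end} lacks transcript_id"
                )
            tid = f.attributes["transcript_id"][0]
            gid = f.attributes.get("gene_id", [tid])[0]
            store.setdefault(tid, []).append((f.start - 1, f.end))
            meta.setdefault(tid, (gid, f.seqid, f.strand))

    models: dict[str, TranscriptModel] = {}
    for tid, ex in exons.items():
        gid, chrom, strand = meta[tid]
        ex = sorted(ex, reverse=strand == "-")
        model = TranscriptModel(tid, gid, chrom, strand, ex, None)
        if tid in cds:
            try:
                tx_pos = []
                for s, e in cds[tid]:
                    tx_pos.append(model.genomic_to_tx(s))
                    tx_pos.append(model.genomic_to_tx(e - 1))
            except ValueError as exc:
                raise ValueError(
                    f"transcript {tid}: CDS not contained in exons ({exc})"
                ) from None
            model.cds_tx = (min(tx_pos), max(tx_pos) + 1)
            model.__post_init__()  # re-validate with CDS attached
        models[tid] = model
    return models


def select_representative_isoform(
    transcripts: Iterable[TranscriptModel],
) -> TranscriptModel:
    """Pick one transcript per gene by a fixed deterministic hierarchy.

    1. has a CDS with both UTRs annotated (non-empty 5' and 3' UTR);
    2. longest CDS;
    3. longest transcript;
    4. lexicographically smallest transcript_id.
    """
    txs = list(transcripts)
    if not txs:
        raise ValueError("no transcripts supplied")
    genes = {t.gene_id for t in txs}
    if len(genes) > 1:
        raise ValueError(f"transcripts span multiple genes: {sorted(genes)}")

    def key(t: TranscriptModel):
        complete = t.cds_tx is not None and t.utr5_len > 0 and t.utr3_len > 0
        return (-int(complete), -t.cds_len, -t.length, t.transcript_id)

    return min(txs, key=key)


def extract_spliced_sequence(model: TranscriptModel, genome: Mapping[str, object]) -> str:
    """Concatenate exon sequences in transcript order (revcomp on minus).

    ``genome`` may be a ``pyfaidx.Fasta`` or any mapping of chromosome name to
    a sliceable sequence.  Behavioural equivalent of ``bedtools getfasta -s
    -split`` on a BED12 transcript record.
    """
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} absent from genome")
    ref = genome[model.chrom]
    ref_len = len(ref)
    parts = []
    for s, e in sorted(model.exons):
        if e > ref_len:
            raise ValueError(
                f"{model.transcript_id}: exon [{s},{e}) beyond {model.chrom} length {ref_len}"
            )
        parts.append(str(ref[s:e]).upper())
    seq = "".join(parts)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq


def write_bed6(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript spans as BED6 (one line per transcript)."""
    with open(path, "w") as fh:
        for m in models:
            start = min(s for s, _ in m.exons)
            end = max(e for _, e in m.exons)
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{m.transcript_id}\t0\t{m.strand}\n"
            )
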