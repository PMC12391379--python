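"""Synthetic data with the statistical structure the pipeline assumes.

The generator produces, from a single seeded configuration:

* a transcriptome (genomic FASTA + GTF + per-transcript sequence) in which a
  configurable subset of genes carries a planted uORF (entirely inside the
  5'UTR) or uoORF (start in the 5'UTR, stop inside the CDS, frame shifted
  relative to the CDS), recorded in a truth table;
* ribosome-footprint libraries under three regimes — *proliferating*
  (uniform CDS occupancy with baseline UTR leakage), *arrested* (5'UTR and
  5'-CDS density boosted so the expected library-level 5'UTR:3'UTR occupancy
  ratio is ``front_load_ratio`` times the proliferating ratio, plus periodic
  occupancy on planted upstream ORFs), and *harringtonine(t)* (run-off:
  elongating ribosomes within ``rate × t`` codons of their start have left
  the transcript; initiation piles of ±1 codon remain at active starts);
* negative-binomial RNA-seq counts with abundances shared across conditions;
* log-normal peptide intensity matrices with planted log2 fold changes.

Footprints carry transcript-space coordinates (BED6 on transcript
"chromosomes"); alignment is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import TranscriptModel

__all__ = [
    "SimConfig",
    "Transcriptome",
    "simulate_transcriptome",
    "simulate_footprints",
    "simulate_rnaseq_counts",
    "simulate_intensity_matrix",
    "write_footprint_bed",
    "NEAR_COGNATE_STARTS",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
#: ATG plus every single-mismatch codon, the default initiator repertoire.
NEAR_COGNATE_STARTS = (
    "CTG", "GTG", "TTG", "ACG", "AGG", "AAG", "ATA", "ATT", "ATC",
)
START_SET = ("ATG",) + NEAR_COGNATE_STARTS

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
# codons that are neither starts (ATG + near-cognates) nor stops: safe filler
SAFE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in START_SET and a + b + c not in STOP_CODONS
)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults encode the conditions the analysis is designed around: 20–34 nt
    size-selected footprints concentrated at 28–32 nt, a two-fold arrested vs
    proliferating 5'UTR:3'UTR occupancy ratio, 90% in-frame P-sites within
    translated ORFs, and mostly non-ATG upstream initiation.
    """

    n_genes: int = 200
    utr5_mean: float = 180.0
    cds_mean: float = 900.0
    utr3_mean: float = 240.0
    library_size: int = 200_000
    #: footprint length → probability; lengths must lie in [20, 34]
    length_probs: dict = field(
        default_factory=lambda: {28: 0.15, 29: 0.35, 30: 0.30, 31: 0.15, 32: 0.05}
    )
    front_load_ratio: float = 2.0
    #: fraction of the library assigned to planted uORF/uoORFs (arrested regime)
    uorf_occupancy: float = 0.03
    #: probability that a P-site inside an ORF falls in frame 0 of that ORF
    periodicity: float = 0.9
    #: library fraction leaking uniformly into the 5'UTR / 3'UTR
    utr5_leak: float = 0.03
    utr3_leak: float = 0.03
    #: exponential decay scale (nt from the cap) of the arrested front-load component
    frontload_decay_nt: float = 120.0
    #: nt of 5'-CDS included in the front-load support
    frontload_cds_nt: int = 150
    #: per-gene planting probabilities
    p_uorf: float = 0.35
    p_uoorf: float = 0.20
    #: fraction of planted upstream ORFs initiating at ATG (rest near-cognate)
    atg_start_fraction: float = 0.30
    #: log-sd of log-normal transcript abundances
    abundance_sigma: float = 0.75
    rnaseq_dispersion: float = 0.1
    runoff_elongation_rate: float = 3.0  # codons / s
    runoff_time: float = 30.0  # s
    #: initiation-pile share of a harringtonine library
    pile_fraction: float = 0.3
    #: share of initiation-pile reads at upstream (planted) starts
    utis_share_proliferating: float = 0.08
    utis_share_arrested: float = 0.50
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "uorf_occupancy": self.uorf_occupancy,
            "periodicity": self.periodicity,
            "utr5_leak": self.utr5_leak,
            "utr3_leak": self.utr3_leak,
            "p_uorf": self.p_uorf,
            "p_uoorf": self.p_uoorf,
            "atg_start_fraction": self.atg_start_fraction,
            "pile_fraction": self.pile_fraction,
            "utis_share_proliferating": self.utis_share_proliferating,
            "utis_share_arrested": self.utis_share_arrested,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.front_load_ratio <= 0:
            raise ValueError("front_load_ratio must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.length_probs:
            raise ValueError("length_probs empty")
        for ln in self.length_probs:
            if not 20 <= int(ln) <= 34:
                raise ValueError(f"footprint length {ln} outside [20,34]")
        if abs(sum(self.length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("length_probs must sum to 1")
        if self.p_uorf + self.p_uoorf > 1.0:
            raise ValueError("p_uorf + p_uoorf exceeds 1")
        if (self.p_uorf > 0 or self.p_uoorf > 0) and self.utr5_mean < 90:
            raise ValueError(
                "5'UTR mean length too short to host planted upstream ORFs"
            )


@dataclass
class Transcriptome:
    """In-memory simulated transcriptome plus planted-ORF ground truth."""

    models: dict[str, TranscriptModel]
    tx_seq: dict[str, str]
    genome: dict[str, str]
    abundance: dict[str, float]
    truth: pd.DataFrame  # orf_id, transcript_id, gene_id, start, end, start_codon, category

    # ---- writers (all plain text) ----------------------------------------

    def write_genome_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self.models):
                m = self.models[tid]
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{tid}";'
                for s, e in sorted(m.exons):
                    fh.write(
                        f"{m.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                    )
                if m.cds_tx is not None:
                    for s, e in m.tx_interval_to_blocks(*m.cds_tx):
                        fh.write(
                            f"{m.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t{attrs}\n"
                        )

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transcriptome construction
# ---------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _set_codon(seq: np.ndarray, pos: int, codon: str) -> None:
    seq[pos : pos + 3] = list(codon)


def _codon(seq: np.ndarray, pos: int) -> str:
    return "".join(seq[pos : pos + 3])


def _clean_upstream_frame(
    seq: np.ndarray, start: int, lower: int, rng: np.random.Generator
) -> None:
    """Walk upstream in-frame from ``start``; replace start-set codons with
    safe filler until a stop codon (which insulates) or ``lower`` is reached."""
    p = start - 3
    while p >= lower:
        c = _codon(seq, p)
        if c in STOP_CODONS:
            break
        if c in START_SET:
            _set_codon(seq, p, SAFE_CODONS[rng.integers(len(SAFE_CODONS))])
        p -= 3


def _fix_codon_in_place(
    seq: np.ndarray,
    p: int,
    protected: range,
    rng: np.random.Generator,
) -> bool:
    """Mutate one non-protected base of the codon at ``p`` so it is neither a
    start-set nor a stop codon.  Mutations use 'C' first (a 'C' anywhere in a
    codon rules out stop codons in any register containing it at position 0)
    and fall back to random letters.  Returns True on success."""
    for off in (0, 1, 2):
        idx = p + off
        if idx in protected:
            continue
        original = seq[idx]
        for letter in ["C"] + list(rng.permutation(["A", "G", "T"])):
            seq[idx] = letter
            if _codon(seq, p) not in START_SET and _codon(seq, p) not in STOP_CODONS:
                return True
        seq[idx] = original
    return False


def _plant_upstream_orf(
    seq: np.ndarray,
    cds_start: int,
    kind: str,
    rng: np.random.Generator,
    atg_fraction: float,
) -> Optional[tuple[int, int, str]]:
    """Plant a uORF or uoORF into ``seq``; returns (start, end, start_codon).

    The planted ORF's reading frame is scrubbed of competing start-set codons
    (both upstream of the start up to the nearest insulating stop, and inside
    the ORF body), so the planted start is the 5'-most initiator that shares
    the planted stop — the configuration the candidate scanner reports.
    """
    if rng.random() < atg_fraction:
        start_codon = "ATG"
    else:
        start_codon = NEAR_COGNATE_STARTS[rng.integers(len(NEAR_COGNATE_STARTS))]

    if kind == "uORF":
        n_codons = int(rng.integers(8, 21))
        span = 3 * n_codons
        lo, hi = 15, cds_start - span
        if hi <= lo:
            return None
        start = int(rng.integers(lo, hi + 1))
        end = start + span
        _set_codon(seq, start, start_codon)
        for p in range(start + 3, end - 3, 3):
            _set_codon(seq, p, SAFE_CODONS[rng.integers(len(SAFE_CODONS))])
        _set_codon(seq, end - 3, STOP_CODONS[rng.integers(3)])
        _clean_upstream_frame(seq, start, start % 3, rng)
        return start, end, start_codon

    # uoORF: start in 5'UTR, stop inside the CDS, frame != CDS frame.
    n_codons = int(rng.integers(8, 26))
    for _ in range(20):
        frame_shift = int(rng.integers(1, 3))
        in_cds = int(rng.integers(9, 31))
        end = cds_start + in_cds - ((in_cds - frame_shift) % 3)
        if end <= cds_start + 3:
            end += 3
        start = end - 3 * n_codons
        if start >= 15 and end - 3 >= cds_start + 1 and (cds_start - start) % 3 != 0:
            break
    else:
        return None
    protected = range(cds_start, cds_start + 3)  # keep the annotated ATG intact
    _set_codon(seq, start, start_codon)
    for p in range(start + 3, end - 3, 3):
        if any(idx in protected for idx in range(p, p + 3)):
            continue
        _set_codon(seq, p, SAFE_CODONS[rng.integers(len(SAFE_CODONS))])
    _set_codon(seq, end - 3, STOP_CODONS[rng.integers(3)])
    # resolve codons overlapping the protected ATG or otherwise unsafe
    ok = True
    for p in range(start + 3, end - 3, 3):
        c = _codon(seq, p)
        if c in START_SET or c in STOP_CODONS:
            if not _fix_codon_in_place(seq, p, protected, rng):
                ok = False
    if not ok:
        return None
    _clean_upstream_frame(seq, start, start % 3, rng)
    return start, end, start_codon


def simulate_transcriptome(config: SimConfig, seed: Optional[int] = None) -> Transcriptome:
    """Build a seeded synthetic transcriptome with planted upstream ORFs.

    Each gene gets a single transcript (1–3 exons on a shared chromosome,
    random strand) with 5'UTR/CDS/3'UTR structure; at most one uORF or uoORF
    is planted per gene.  Identical ``(config, seed)`` give byte-identical
    outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    models: dict[str, TranscriptModel] = {}
    tx_seq: dict[str, str] = {}
    abundance: dict[str, float] = {}
    truth_rows: list[dict] = []
    chrom_parts: dict[str, list[str]] = {}
    chrom_cursor: dict[str, int] = {}
    genes_per_chrom = 25

    for g in range(config.n_genes):
        gid = f"G{g:04d}"
        tid = f"T{g:04d}"
        chrom = f"chr{g // genes_per_chrom + 1}"

        utr5 = max(90, int(round(rng.normal(config.utr5_mean, 0.2 * config.utr5_mean))))
        n_cds_codons = max(
            100, int(round(rng.normal(config.cds_mean, 0.2 * config.cds_mean) / 3))
        )
        cds_len = 3 * n_cds_codons
        utr3 = max(60, int(round(rng.normal(config.utr3_mean, 0.2 * config.utr3_mean))))
        L = utr5 + cds_len + utr3
        cds_start, cds_end = utr5, utr5 + cds_len

        seq = _rand_seq(rng, L)
        _set_codon(seq, cds_start, "ATG")
        for p in range(cds_start + 3, cds_end - 3, 3):
            if _codon(seq, p) in STOP_CODONS:
                _set_codon(seq, p, SAFE_CODONS[rng.integers(len(SAFE_CODONS))])
        _set_codon(seq, cds_end - 3, STOP_CODONS[rng.integers(3)])

        planted = None
        u = rng.random()
        if u < config.p_uorf:
            planted = ("uORF", _plant_upstream_orf(seq, cds_start, "uORF", rng, config.atg_start_fraction))
        elif u < config.p_uorf + config.p_uoorf:
            planted = ("uoORF", _plant_upstream_orf(seq, cds_start, "uoORF", rng, config.atg_start_fraction))
        if planted is not None and planted[1] is not None:
            kind, (s, e, codon) = planted
            truth_rows.append(
                dict(
                    orf_id=f"{tid}:{s}-{e}",
                    transcript_id=tid,
                    gene_id=gid,
                    start=s,
                    end=e,
                    start_codon=codon,
                    category=kind,
                )
            )

        # place on the genome: 1-3 exons, random strand, introns 60-300 nt
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(50, L - 50), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        bounds = [0, *map(int, cuts), L]
        tx_sequence = "".join(seq)
        pieces = [tx_sequence[a:b] for a, b in zip(bounds, bounds[1:])]
        if strand == "-":
            from .genome import reverse_complement

            genomic_pieces = [reverse_complement(p) for p in reversed(pieces)]
        else:
            genomic_pieces = pieces
        parts = chrom_parts.setdefault(chrom, [])
        cursor = chrom_cursor.get(chrom, 0)
        exon_genomic: list[tuple[int, int]] = []
        gap = int(rng.integers(100, 301))
        parts.append("".join(_rand_seq(rng, gap)))
        cursor += gap
        for i, piece in enumerate(genomic_pieces):
            if i > 0:
                intron = int(rng.integers(60, 301))
                parts.append("".join(_rand_seq(rng, intron)))
                cursor += intron
            exon_genomic.append((cursor, cursor + len(piece)))
            parts.append(piece)
            cursor += len(piece)
        chrom_cursor[chrom] = cursor
        exons = sorted(exon_genomic, reverse=strand == "-")

        model = TranscriptModel(tid, gid, chrom, strand, exons, (cds_start, cds_end))
        models[tid] = model
        tx_seq[tid] = tx_sequence
        abundance[tid] = float(rng.lognormal(0.0, config.abundance_sigma))

    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}
    truth = pd.DataFrame(
        truth_rows,
        columns=["orf_id", "transcript_id", "gene_id", "start", "end", "start_codon", "category"],
    )
    return Transcriptome(models, tx_seq, genome, abundance, truth)


# ---------------------------------------------------------------------------
# footprint libraries
# ---------------------------------------------------------------------------


def _tx_arrays(txome: Transcriptome):
    tids = sorted(txome.models)
    L = np.array([txome.models[t].length for t in tids])
    cs = np.array([txome.models[t].cds_tx[0] for t in tids])
    ce = np.array([txome.models[t].cds_tx[1] for t in tids])
    ab = np.array([txome.abundance[t] for t in tids], dtype=float)
    ab /= ab.sum()
    return tids, L, cs, ce, ab


def _orf_arrays(txome: Transcriptome, tids: Sequence[str], ab: np.ndarray):
    idx_of = {t: i for i, t in enumerate(tids)}
    if len(txome.truth) == 0:
        return None
    tx_idx = np.array([idx_of[t] for t in txome.truth.transcript_id])
    starts = txome.truth.start.to_numpy()
    ends = txome.truth.end.to_numpy()
    w = ab[tx_idx]
    w = w / w.sum()
    return tx_idx, starts, ends, w


def _frame_offsets(rng: np.random.Generator, n: int, periodicity: float) -> np.ndarray:
    """Within-codon P-site offset: 0 with probability `periodicity`, else 1 or 2."""
    off = np.zeros(n, dtype=np.int64)
    shifted = rng.random(n) >= periodicity
    off[shifted] = rng.integers(1, 3, size=int(shifted.sum()))
    return off


def _solve_frontload_weight(config, cs, ce, L, ab, q5_uorf, u):
    """Solve the front-load mixture weight so that the expected library-level
    5'UTR:3'UTR ratio equals front_load_ratio × (proliferating ratio)."""
    lam = config.frontload_decay_nt
    support = cs + np.minimum(config.frontload_cds_nt, ce - cs)
    m5 = (1.0 - np.exp(-cs / lam)) / (1.0 - np.exp(-support / lam))
    M5 = float(np.sum(ab * m5))
    prolif_ratio = config.utr5_leak / config.utr3_leak
    target_f5 = config.front_load_ratio * prolif_ratio * config.utr3_leak
    alpha = (target_f5 - config.utr5_leak - u * q5_uorf) / M5
    if alpha < 0:
        raise ValueError(
            "front_load_ratio unreachable: uORF occupancy plus baseline 5'UTR "
            "leakage already exceeds the target 5'UTR fraction"
        )
    return alpha, support


def simulate_footprints(
    txome: Transcriptome,
    regime: str,
    config: SimConfig,
    seed: Optional[int] = None,
    time: Optional[float] = None,
    arrested: bool = True,
) -> pd.DataFrame:
    """Sample a footprint library (transcript-space BED-style records).

    Returns a DataFrame with columns ``transcript_id``, ``start`` (footprint
    5' end), ``length``; exactly ``config.library_size`` rows.  ``regime`` is
    one of ``proliferating``, ``arrested`` or ``harringtonine`` (the latter
    takes ``time`` in seconds, default ``config.runoff_time``, and
    ``arrested`` selecting the underlying cell state).
    """
    config.validate()
    if regime not in ("proliferating", "arrested", "harringtonine"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tids, L, cs, ce, ab = _tx_arrays(txome)
    orfs = _orf_arrays(txome, tids, ab)
    n = config.library_size
    offset = 12  # matches the default P-site offset table

    if regime == "harringtonine":
        psite_tx, psite_pos = _harringtonine_positions(
            rng, config, tids, L, cs, ce, ab, orfs,
            n, config.runoff_time if time is None else time, arrested,
        )
    else:
        psite_tx, psite_pos = _steady_state_positions(
            rng, config, L, cs, ce, ab, orfs, n, regime
        )

    # footprint geometry: 5' end = P-site − offset; resample reads that would
    # run off either transcript end (cap-proximal edge effect)
    lengths_all = np.array(sorted(config.length_probs), dtype=int)
    lprob = np.array([config.length_probs[int(l)] for l in lengths_all])
    flen = lengths_all[rng.choice(len(lengths_all), size=n, p=lprob)]
    fstart = psite_pos - offset
    for _ in range(50):
        bad = (fstart < 0) | (fstart + flen > L[psite_tx])
        if not bad.any():
            break
        nb = int(bad.sum())
        if regime == "harringtonine":
            t2, p2 = _harringtonine_positions(
                rng, config, tids, L, cs, ce, ab, orfs, nb,
                config.runoff_time if time is None else time, arrested,
            )
        else:
            t2, p2 = _steady_state_positions(
                rng, config, L, cs, ce, ab, orfs, nb, regime
            )
        psite_tx[bad] = t2
        psite_pos[bad] = p2
        flen[bad] = lengths_all[rng.choice(len(lengths_all), size=nb, p=lprob)]
        fstart = psite_pos - offset
    else:
        # clamp the stragglers rather than loop forever
        fstart = np.clip(fstart, 0, L[psite_tx] - flen)

    tid_arr = np.asarray(tids, dtype=object)[psite_tx]
    return pd.DataFrame(
        {"transcript_id": tid_arr, "start": fstart.astype(int), "length": flen.astype(int)}
    )


def _steady_state_positions(rng, config, L, cs, ce, ab, orfs, n, regime):
    per = config.periodicity
    if regime == "proliferating" or orfs is None:
        u = 0.0
        q5 = 0.0
    else:
        u = config.uorf_occupancy
        tx_idx_o, s_o, e_o, w_o = orfs
        frac5 = np.clip(cs[tx_idx_o] - s_o, 0, e_o - s_o) / (e_o - s_o)
        q5 = float(np.sum(w_o * frac5))
    if regime == "arrested":
        alpha, support = _solve_frontload_weight(config, cs, ce, L, ab, q5, u)
    else:
        alpha, support = 0.0, cs  # unused
    w5, w3 = config.utr5_leak, config.utr3_leak
    w_cds = 1.0 - w5 - w3 - alpha - u
    if w_cds <= 0:
        raise ValueError("component weights exceed 1; lower leak/occupancy settings")

    comp = rng.choice(5, size=n, p=[w_cds, w5, w3, alpha, u])
    tx = rng.choice(len(L), size=n, p=ab)
    pos = np.zeros(n, dtype=np.int64)

    m = comp == 0  # CDS-uniform, periodic
    ncod = (ce[tx[m]] - cs[tx[m]]) // 3
    codon = (rng.random(m.sum()) * ncod).astype(np.int64)
    pos[m] = cs[tx[m]] + 3 * codon + _frame_offsets(rng, int(m.sum()), per)

    m = comp == 1  # 5'UTR leakage, frame-random
    pos[m] = (rng.random(m.sum()) * cs[tx[m]]).astype(np.int64)

    m = comp == 2  # 3'UTR leakage
    pos[m] = ce[tx[m]] + (rng.random(m.sum()) * (L[tx[m]] - ce[tx[m]])).astype(np.int64)

    m = comp == 3  # front-load: truncated exponential from the cap
    lam = config.frontload_decay_nt
    S = support[tx[m]]
    x = -lam * np.log1p(-rng.random(m.sum()) * (1.0 - np.exp(-S / lam)))
    pos[m] = np.minimum(x.astype(np.int64), S - 1)

    m = comp == 4  # planted upstream ORFs, periodic
    if m.any():
        tx_idx_o, s_o, e_o, w_o = orfs
        k = rng.choice(len(s_o), size=int(m.sum()), p=w_o)
        tx[m] = tx_idx_o[k]
        ncod = (e_o[k] - s_o[k]) // 3
        codon = (rng.random(m.sum()) * ncod).astype(np.int64)
        pos[m] = s_o[k] + 3 * codon + _frame_offsets(rng, int(m.sum()), per)

    return tx, pos


def _harringtonine_positions(rng, config, tids, L, cs, ce, ab, orfs, n, time, arrested):
    """Run-off regime: initiation piles (±1 codon) persist at active starts;
    elongating ribosomes sit ``rate × t`` codons downstream of where they
    initiated, so the 5' part of each CDS is depleted and ribosomes that
    reach the stop have left the library (resampled)."""
    per = config.periodicity
    shift = int(round(config.runoff_elongation_rate * max(time, 0.0)))
    utis = (
        config.utis_share_arrested if arrested else config.utis_share_proliferating
    )
    tx = np.zeros(n, dtype=np.int64)
    pos = np.zeros(n, dtype=np.int64)
    todo = np.arange(n)
    for _ in range(200):
        k = len(todo)
        if k == 0:
            break
        is_pile = rng.random(k) < config.pile_fraction
        t_i = rng.choice(len(L), size=k, p=ab)
        p_i = np.zeros(k, dtype=np.int64)

        # piles
        mp = is_pile
        n_p = int(mp.sum())
        if n_p:
            at_utis = (rng.random(n_p) < utis) if orfs is not None else np.zeros(n_p, bool)
            site = cs[t_i[mp]].copy()
            if at_utis.any():
                tx_idx_o, s_o, e_o, w_o = orfs
                j = rng.choice(len(s_o), size=int(at_utis.sum()), p=w_o)
                site[at_utis] = s_o[j]
                tmp = t_i[mp]
                tmp[at_utis] = tx_idx_o[j]
                t_i[mp] = tmp
            jitter = rng.choice([-1, 0, 1], size=n_p, p=[0.2, 0.6, 0.2])
            p_i[mp] = site + 3 * jitter + _frame_offsets(rng, n_p, per)

        # elongating: initiated uniformly, advanced by `shift` codons
        me = ~is_pile
        n_e = int(me.sum())
        if n_e:
            ncod = (ce[t_i[me]] - cs[t_i[me]]) // 3
            c0 = (rng.random(n_e) * ncod).astype(np.int64)
            c = c0 + shift
            p_i[me] = cs[t_i[me]] + 3 * c + _frame_offsets(rng, n_e, per)

        ok = (p_i >= 0) & (p_i < L[t_i])
        good = todo[ok]
        tx[good] = t_i[ok]
        pos[good] = p_i[ok]
        todo = todo[~ok]
    if len(todo):
        # long run-off limit: everything that could not elongate is a pile read
        t_i = rng.choice(len(L), size=len(todo), p=ab)
        tx[todo] = t_i
        pos[todo] = cs[t_i] + _frame_offsets(rng, len(todo), per)
    return tx, pos


def write_footprint_bed(footprints: pd.DataFrame, path: str | Path) -> None:
    """BED6 on transcript 'chromosomes': start = footprint 5' end."""
    with open(path, "w") as fh:
        for row in footprints.itertuples(index=False):
            fh.write(
                f"{row.transcript_id}\t{row.start}\t{row.start + row.length}\t.\t0\t+\n"
            )


def read_footprint_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["transcript_id", "start", "end", "name", "score", "strand"],
    )
    df["length"] = df["end"] - df["start"]
    return df[["transcript_id", "start", "length"]]


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


def simulate_rnaseq_counts(
    txome: Transcriptome,
    config: SimConfig,
    features: Optional[pd.DataFrame] = None,
    n_samples: int = 2,
    library_size: int = 2_000_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Negative-binomial counts over features, abundances shared across samples.

    ``features`` needs columns ``feature_id``, ``transcript_id``, ``start``,
    ``end`` (transcript space); by default the planted-ORF truth table plus
    one whole-CDS feature per transcript.  Expected count is proportional to
    transcript abundance × feature length (uniform read coverage along the
    transcript); ``rnaseq_dispersion`` = 0 gives Poisson counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if features is None:
        rows = [
            dict(feature_id=r.orf_id, transcript_id=r.transcript_id, start=r.start, end=r.end)
            for r in txome.truth.itertuples(index=False)
        ]
        for tid in sorted(txome.models):
            m = txome.models[tid]
            rows.append(
                dict(feature_id=f"{tid}:CDS", transcript_id=tid, start=m.cds_tx[0], end=m.cds_tx[1])
            )
        features = pd.DataFrame(rows)
    ab = pd.Series(txome.abundance)
    lens = pd.Series({t: txome.models[t].length for t in txome.models})
    total_mass = float((ab * lens).sum())
    feat_len = (features.end - features.start).to_numpy(dtype=float)
    mu = library_size * ab[features.transcript_id].to_numpy() * feat_len / total_mass

    phi = config.rnaseq_dispersion
    out = {"feature_id": features.feature_id.to_numpy()}
    for s in range(n_samples):
        if phi <= 0:
            counts = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
            counts = rng.poisson(lam)
        out[f"sample_{s + 1}"] = counts
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# peptide intensity matrices
# ---------------------------------------------------------------------------


def simulate_intensity_matrix(
    n_peptides: int,
    n_per_group: int,
    planted_log2fc: Optional[np.ndarray] = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    baseline_mean: float = 23.0,
    baseline_sd: float = 2.0,
    prior_df: float = 4.0,
    prior_var: float = 0.09,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 intensities ~ Normal(baseline ± effect/2, peptide variance).

    Peptide variances are drawn from a scaled inverse-chi-square
    (``prior_df``, ``prior_var``) — the generating model the moderated
    t-test assumes.  Missing values are injected completely at random at
    ``missing_rate``.  Returns (matrix, truth) with sample columns
    ``A_1..A_n`` and ``B_1..B_n``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if planted_log2fc is None:
        planted_log2fc = np.zeros(n_peptides)
    planted_log2fc = np.asarray(planted_log2fc, dtype=float)
    if len(planted_log2fc) != n_peptides:
        raise ValueError("planted_log2fc length mismatch")

    base = rng.normal(baseline_mean, baseline_sd, size=n_peptides)
    s2 = prior_df * prior_var / rng.chisquare(prior_df, size=n_peptides)
    sd = np.sqrt(s2)
    cols = {}
    for g, sign in (("A", -0.5), ("B", +0.5)):
        for i in range(n_per_group):
            mean = base + sign * planted_log2fc
            vals = rng.normal(mean, sd)
            cols[f"{g}_{i + 1}"] = vals
    mat = pd.DataFrame(cols, index=[f"pep{i:05d}" for i in range(n_peptides)])
    if missing_rate > 0:
        mask = rng.random(mat.shape) < missing_rate
        mat = mat.mask(mask)
    truth = pd.DataFrame(
        {"peptide_id": mat.index, "log2fc": planted_log2fc, "variance": s2}
    )
    return mat, truth
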