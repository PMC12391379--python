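"""Candidate ORF scanning, a periodicity-based translation test, the ORF
category taxonomy, start-codon composition and harringtonine run-off scoring.

The detection statistic is a transparent one-sided binomial test on triplet
periodicity of P-sites within the candidate (null: a P-site is equally likely
in each of the three frames).  It deliberately replaces EM-based codon-
activity inference while keeping the same downstream contract: a scored,
categorized ORF table filtered at p ≤ 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import TranscriptModel
from .profiles import PSiteTrack
from .simulate import NEAR_COGNATE_STARTS, STOP_CODONS

__all__ = [
    "OrfCandidate",
    "DEFAULT_START_CODONS",
    "scan_candidates",
    "score_orf",
    "classify_orf",
    "call_orfs",
    "start_codon_composition",
    "tis_runoff_score",
    "fisher_one_sided",
    "CATEGORIES",
]

DEFAULT_START_CODONS: tuple[str, ...] = ("ATG",) + NEAR_COGNATE_STARTS
CATEGORIES = (
    "CDS", "truncation", "uORF", "uoORF", "dORF", "iORF", "ncRNA", "variant", "orphan",
)


@dataclass
class OrfCandidate:
    """A candidate ORF in transcript coordinates (half-open; ``end`` is one
    past the last nt of the stop codon)."""

    transcript_id: str
    start: int
    end: int
    start_codon: str
    frame_vs_cds: str = "na"  # same / different / na
    category: Optional[str] = None
    p_value: Optional[float] = None
    n_psites: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0 or self.end - self.start < 6:
            raise ValueError(
                f"ORF [{self.start},{self.end}) must be ≥6 nt and divisible by 3"
            )


def scan_candidates(
    model: TranscriptModel,
    sequence: str,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[OrfCandidate]:
    """All in-frame (start, first stop) pairs; starts without a downstream
    in-frame stop are discarded.  Among nested candidates sharing a stop,
    only the 5'-most start per start-codon class (ATG vs near-cognate) is
    kept."""
    if len(sequence) != model.length:
        raise ValueError(
            f"{model.transcript_id}: sequence length {len(sequence)} != "
            f"transcript length {model.length}"
        )
    sequence = sequence.upper()
    start_codons = tuple(c.upper() for c in start_codons)
    # per frame, sorted positions of stop codons
    stops_by_frame: list[np.ndarray] = []
    for f in range(3):
        pos = np.arange(f, len(sequence) - 2, 3)
        is_stop = [sequence[p : p + 3] in STOP_CODONS for p in pos]
        stops_by_frame.append(pos[np.fromiter(is_stop, bool, len(pos))])

    best: dict[tuple[int, bool], OrfCandidate] = {}
    for p in range(len(sequence) - 2):
        codon = sequence[p : p + 3]
        if codon not in start_codons:
            continue
        stops = stops_by_frame[p % 3]
        i = np.searchsorted(stops, p + 3)
        if i >= len(stops):
            continue  # no in-frame stop downstream
        stop = int(stops[i])
        key = (stop, codon == "ATG")
        if key not in best:  # scanning 5'→3': first seen is 5'-most
            cand = OrfCandidate(model.transcript_id, p, stop + 3, codon)
            if model.cds_tx is not None:
                cand.frame_vs_cds = (
                    "same" if (p - model.cds_tx[0]) % 3 == 0 else "different"
                )
            best[key] = cand
    return sorted(best.values(), key=lambda c: (c.start, c.end))


def score_orf(
    candidate: OrfCandidate, track: PSiteTrack, min_psites: int = 10
) -> float:
    """One-sided binomial periodicity p-value.

    k = P-sites in frame 0 of the candidate, n = all P-sites within
    [start, end); p = P(X ≥ k | Binomial(n, 1/3)).  Candidates with fewer
    than ``min_psites`` P-sites are uninformative and get p = 1.
    """
    window = track.counts[candidate.start : candidate.end]
    n = int(window.sum())
    candidate.n_psites = n
    if n < min_psites:
        candidate.p_value = 1.0
        return 1.0
    k = int(window[::3].sum())
    p = float(stats.binom.sf(k - 1, n, 1.0 / 3.0))
    candidate.p_value = p
    return p


def classify_orf(candidate: OrfCandidate, model: TranscriptModel) -> str:
    """Assign exactly one category.

    Decision order: ncRNA (no CDS) → CDS (identical) → truncation (same frame
    and stop, start inside the CDS) → uORF (entirely before the CDS) → uoORF
    (start upstream, overlaps the CDS start, different frame) → dORF (entirely
    after the CDS) → iORF (inside the CDS, different frame) → variant
    (same-frame overlap with the CDS, e.g. an N-terminal extension sharing the
    CDS stop) → orphan (anything else).
    """
    s, e = candidate.start, candidate.end
    if model.cds_tx is None:
        cat = "ncRNA"
    else:
        cs, ce = model.cds_tx
        same_frame = (s - cs) % 3 == 0
        if (s, e) == (cs, ce):
            cat = "CDS"
        elif same_frame and e == ce and cs < s < ce:
            cat = "truncation"
        elif e <= cs:
            cat = "uORF"
        elif s < cs < e and not same_frame:
            cat = "uoORF"
        elif s >= ce:
            cat = "dORF"
        elif s >= cs and e <= ce and not same_frame:
            cat = "iORF"
        elif same_frame and s < ce and e > cs:
            cat = "variant"
        else:
            cat = "orphan"
    candidate.category = cat
    return cat


def call_orfs(
    model: TranscriptModel,
    sequence: str,
    track: PSiteTrack,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    min_psites: int = 10,
    pmax: Optional[float] = None,
) -> pd.DataFrame:
    """Scan, score and classify all candidates on one transcript.

    Returns the ORF table (one row per candidate) optionally filtered at
    ``p ≤ pmax``; no multiple-testing correction is applied, mirroring the
    raw p ≤ 0.05 convention of the downstream pipeline.
    """
    rows = []
    for cand in scan_candidates(model, sequence, start_codons):
        score_orf(cand, track, min_psites)
        classify_orf(cand, model)
        rows.append(
            dict(
                transcript_id=cand.transcript_id,
                gene_id=model.gene_id,
                start=cand.start,
                end=cand.end,
                start_codon=cand.start_codon,
                frame_vs_cds=cand.frame_vs_cds,
                category=cand.category,
                n_psites=cand.n_psites,
                p_value=cand.p_value,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_id", "start", "end", "start_codon",
            "frame_vs_cds", "category", "n_psites", "p_value",
        ],
    )
    if pmax is not None and len(df):
        df = df[df.p_value <= pmax].reset_index(drop=True)
    return df


def start_codon_composition(
    orf_table: pd.DataFrame,
    categories: Iterable[str] = ("uORF", "uoORF"),
) -> tuple[pd.Series, float, float]:
    """Start-codon counts plus (ATG fraction, non-ATG fraction) for the
    selected categories."""
    sub = orf_table[orf_table.category.isin(set(categories))]
    if len(sub) == 0:
        raise ValueError("no ORFs in the selected categories")
    counts = sub.start_codon.value_counts()
    atg = counts.get("ATG", 0) / counts.sum()
    return counts, float(atg), float(1.0 - atg)


def tis_runoff_score(
    tracks_by_time: Mapping[float, PSiteTrack],
    sites: Sequence[int],
    window_codons: int = 1,
) -> pd.DataFrame:
    """Per-site accumulation score across a harringtonine time course.

    score(site, t) = P-sites within ±``window_codons`` codons of the site
    (i.e. the window [site − 3w, site + 3w + 3)) divided by the track total
    at time t.  An empty track yields NaN for that time point.
    """
    if len(tracks_by_time) < 2:
        raise ValueError("a run-off time course needs at least two time points")
    w = 3 * window_codons
    rows = []
    for t in sorted(tracks_by_time):
        track = tracks_by_time[t]
        total = track.total
        for site in sites:
            lo = max(0, site - w)
            hi = min(len(track.counts), site + w + 3)
            score = np.nan if total == 0 else float(track.counts[lo:hi].sum()) / total
            rows.append(dict(time=t, site=site, score=score, undefined=total == 0))
    return pd.DataFrame(rows)


def utis_vs_annotated_ratio(
    scores: pd.DataFrame, utis_sites: Sequence[int], annotated_site: int
) -> pd.Series:
    """uTIS:annotated-TIS score ratio at each time point of a run-off course."""
    out = {}
    for t, grp in scores.groupby("time"):
        u = grp[grp.site.isin(set(utis_sites))].score.sum()
        a = grp[grp.site == annotated_site].score.sum()
        out[t] = u / a if a > 0 else np.nan
    return pd.Series(out).sort_index()


def fisher_one_sided(table: Sequence[Sequence[int]]) -> float:
    """One-sided (greater-association) Fisher exact p: the hypergeometric
    upper-tail probability of the observed 2×2 table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2×2")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == arr.astype(int)):
            raise ValueError("table entries must be integers")
        arr = arr.astype(int)
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact(arr, alternative="greater")[1])
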