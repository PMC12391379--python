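"""P-site tracks, region occupancy, metagene profiles and the 5'UTR:3'UTR
redistribution statistic.

The metagene procedure follows the per-transcript recipe: select one isoform
per gene, drop transcripts with fewer than 50 P-sites, interpolate the per-nt
occupancy of each region (5'UTR, CDS, 3'UTR) onto fixed sub-grids summing to
2000 points, normalize each transcript profile to unit mean so deep libraries
do not dominate, average with equal weight and Gaussian-smooth the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .genome import TranscriptModel

__all__ = [
    "DEFAULT_OFFSETS",
    "PSiteTrack",
    "RegionOccupancy",
    "MetageneProfile",
    "compute_psite_track",
    "tracks_from_footprints",
    "region_occupancy",
    "metagene_profile",
    "utr_ratio_statistic",
    "UtrRatioResult",
]

#: default P-site offset (+12 nt from the 5' end) for footprint lengths 28-32;
#: other lengths are dropped unless an explicit table is supplied.
DEFAULT_OFFSETS: dict[int, int] = {28: 12, 29: 12, 30: 12, 31: 12, 32: 12}

MIN_READS_DEFAULT = 50  # transcripts below this total are excluded


@dataclass
class PSiteTrack:
    """Codon-resolution ribosome occupancy: one count per transcript nt."""

    transcript_id: str
    counts: np.ndarray
    n_dropped_no_offset: int = 0
    n_dropped_out_of_range: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class RegionOccupancy:
    transcript_id: str
    counts_5utr: int
    counts_cds: int
    counts_3utr: int
    passes_min_reads: bool

    @property
    def total(self) -> int:
        return self.counts_5utr + self.counts_cds + self.counts_3utr

    @property
    def fractions(self) -> tuple[float, float, float]:
        t = self.total
        if t == 0:
            return (float("nan"),) * 3
        return (self.counts_5utr / t, self.counts_cds / t, self.counts_3utr / t)


@dataclass
class MetageneProfile:
    grid: np.ndarray  # length exactly 2000
    boundaries: tuple[int, int]  # grid indices of 5'UTR|CDS and CDS|3'UTR
    n_transcripts_used: int

    def to_frame(self) -> pd.DataFrame:
        region = np.empty(len(self.grid), dtype=object)
        b1, b2 = self.boundaries
        region[:b1] = "5UTR"
        region[b1:b2] = "CDS"
        region[b2:] = "3UTR"
        return pd.DataFrame(
            {"grid_index": np.arange(len(self.grid)), "value": self.grid, "region": region}
        )


def compute_psite_track(
    footprints: pd.DataFrame | Iterable[tuple[int, int]],
    model: TranscriptModel | int,
    offsets: Optional[Mapping[int, int]] = None,
) -> PSiteTrack:
    """Assign each footprint's P-site at ``5'end + offset(length)``.

    Footprints whose length has no offset, or whose P-site falls outside the
    transcript, are dropped and counted (never fatal).  ``model`` may be a
    :class:`TranscriptModel` or a bare transcript length.
    """
    offsets = DEFAULT_OFFSETS if offsets is None else dict(offsets)
    if isinstance(model, TranscriptModel):
        tid, L = model.transcript_id, model.length
    else:
        tid, L = "?", int(model)
    if isinstance(footprints, pd.DataFrame):
        starts = footprints["start"].to_numpy()
        lengths = footprints["length"].to_numpy()
    else:
        pairs = list(footprints)
        starts = np.array([p[0] for p in pairs], dtype=int)
        lengths = np.array([p[1] for p in pairs], dtype=int)

    off = np.full(len(starts), -1, dtype=int)
    for ln, o in offsets.items():
        off[lengths == ln] = o
    has_offset = off >= 0
    psites = starts + off
    in_range = (psites >= 0) & (psites < L)
    keep = has_offset & in_range
    counts = np.bincount(psites[keep], minlength=L)[:L]
    return PSiteTrack(
        tid,
        counts.astype(np.int64),
        n_dropped_no_offset=int((~has_offset).sum()),
        n_dropped_out_of_range=int((has_offset & ~in_range).sum()),
    )


def tracks_from_footprints(
    footprints: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    offsets: Optional[Mapping[int, int]] = None,
) -> dict[str, PSiteTrack]:
    """Per-transcript tracks from a whole footprint library (BED-style frame)."""
    out: dict[str, PSiteTrack] = {}
    for tid, grp in footprints.groupby("transcript_id", sort=True):
        if tid not in models:
            continue
        out[tid] = compute_psite_track(grp, models[tid], offsets)
    return out


def region_occupancy(
    track: PSiteTrack,
    model: TranscriptModel,
    min_reads: int = MIN_READS_DEFAULT,
) -> RegionOccupancy:
    """Partition P-sites into 5'UTR / CDS / 3'UTR and apply the ≥min_reads flag."""
    if model.cds_tx is None:
        raise ValueError(
            f"{model.transcript_id}: region occupancy undefined without a CDS"
        )
    cs, ce = model.cds_tx
    c = track.counts
    c5 = int(c[:cs].sum())
    cc = int(c[cs:ce].sum())
    c3 = int(c[ce:].sum())
    return RegionOccupancy(
        model.transcript_id, c5, cc, c3, passes_min_reads=(c5 + cc + c3) >= min_reads
    )


def _region_interp(counts: np.ndarray, npts: int) -> np.ndarray:
    L = len(counts)
    if L == 0:
        return np.zeros(npts)
    if L == 1:
        return np.full(npts, float(counts[0]))
    x = np.linspace(0.0, L - 1, npts)
    return np.interp(x, np.arange(L), counts.astype(float))


def metagene_profile(
    tracks: Mapping[str, PSiteTrack],
    models: Mapping[str, TranscriptModel],
    smoothing_sigma: float = 5.0,
    min_reads: int = MIN_READS_DEFAULT,
    grid_split: tuple[int, int, int] = (250, 1500, 250),
) -> MetageneProfile:
    """Boundary-anchored average occupancy over a fixed 2000-point grid.

    Each qualifying transcript's per-nt occupancy is linearly interpolated
    region by region onto ``grid_split`` sub-grids, normalized to unit mean,
    and averaged with equal weight; the average is smoothed with a Gaussian
    kernel (sd ``smoothing_sigma`` grid points, truncated at 4 sd, nearest-
    value boundary handling).
    """
    n5, nc, n3 = grid_split
    total_pts = n5 + nc + n3
    profiles = []
    for tid, track in sorted(tracks.items()):
        model = models[tid]
        if model.cds_tx is None or track.total < min_reads:
            continue
        cs, ce = model.cds_tx
        c = track.counts.astype(float)
        prof = np.concatenate(
            [
                _region_interp(c[:cs], n5),
                _region_interp(c[cs:ce], nc),
                _region_interp(c[ce:], n3),
            ]
        )
        mean = prof.mean()
        if mean > 0:
            profiles.append(prof / mean)
    if not profiles:
        raise ValueError(f"no transcript passed the ≥{min_reads}-read filter")
    avg = np.mean(profiles, axis=0)
    if smoothing_sigma > 0:
        avg = gaussian_filter1d(avg, smoothing_sigma, mode="nearest", truncate=4.0)
    assert len(avg) == total_pts
    return MetageneProfile(avg, (n5, n5 + nc), len(profiles))


@dataclass
class UtrRatioResult:
    """Library-level 5'UTR/3'UTR fractions per replicate and the A:B contrast."""

    frac5_a: np.ndarray
    frac3_a: np.ndarray
    frac5_b: np.ndarray
    frac3_b: np.ndarray
    ratio_a: float  # mean per-replicate 5'UTR:3'UTR ratio, condition A
    ratio_b: float
    ratio_b_over_a: float
    t_stat: Optional[float] = None
    p_value: Optional[float] = None


def _library_fractions(
    occupancies: Sequence[RegionOccupancy], pooled: bool = True
) -> tuple[float, float]:
    """Pooled (sum-of-counts) 5'UTR and 3'UTR fractions over qualifying
    transcripts; ``pooled=False`` averages per-transcript fractions instead."""
    qual = [o for o in occupancies if o.passes_min_reads]
    if not qual:
        raise ValueError("no transcript passes the min-read filter in a replicate")
    if pooled:
        tot = sum(o.total for o in qual)
        return (
            sum(o.counts_5utr for o in qual) / tot,
            sum(o.counts_3utr for o in qual) / tot,
        )
    f5 = float(np.mean([o.fractions[0] for o in qual]))
    f3 = float(np.mean([o.fractions[2] for o in qual]))
    return f5, f3


def utr_ratio_statistic(
    condition_a: Sequence[Sequence[RegionOccupancy]],
    condition_b: Sequence[Sequence[RegionOccupancy]],
    test: bool = True,
    pooled: bool = True,
) -> UtrRatioResult:
    """Per-replicate library 5'UTR and 3'UTR fractions, the B:A ratio of
    5'UTR:3'UTR ratios, and a classic two-tailed unpaired t-test on the
    per-replicate 5'UTR fractions.

    Each element of ``condition_a``/``condition_b`` is the list of per-
    transcript :class:`RegionOccupancy` for one replicate library.
    """
    if not condition_a or not condition_b:
        raise ValueError("each condition needs at least one replicate")
    fa = np.array([_library_fractions(rep, pooled) for rep in condition_a])
    fb = np.array([_library_fractions(rep, pooled) for rep in condition_b])
    ratio_a = float(np.mean(fa[:, 0] / fa[:, 1]))
    ratio_b = float(np.mean(fb[:, 0] / fb[:, 1]))
    res = UtrRatioResult(
        frac5_a=fa[:, 0],
        frac3_a=fa[:, 1],
        frac5_b=fb[:, 0],
        frac3_b=fb[:, 1],
        ratio_a=ratio_a,
        ratio_b=ratio_b,
        ratio_b_over_a=ratio_b / ratio_a,
    )
    if test:
        if len(condition_a) < 2 or len(condition_b) < 2:
            raise ValueError("the t-test needs at least two replicates per condition")
        t, p = stats.ttest_ind(fb[:, 0], fa[:, 0], equal_var=True)
        res.t_stat, res.p_value = float(t), float(p)
    return res
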