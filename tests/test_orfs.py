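"""Candidate scanning, the periodicity test, the category taxonomy,
start-codon composition and run-off scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riboshift.genome import TranscriptModel
from riboshift.orfs import (
    OrfCandidate,
    classify_orf,
    fisher_one_sided,
    scan_candidates,
    score_orf,
    start_codon_composition,
    tis_runoff_score,
    utis_vs_annotated_ratio,
)
from riboshift.profiles import PSiteTrack, tracks_from_footprints
from riboshift.simulate import SimConfig, simulate_footprints, simulate_transcriptome

from _oracles import binomial_tail_onethird, fisher_greater


def _model(length=500, cds=(100, 400)):
    return TranscriptModel("T", "G", "c", "+", [(0, length)], cds)


def _seq_with(insert, at, length=500):
    seq = list("C" * length)
    seq[at : at + len(insert)] = list(insert)
    return "".join(seq)


class TestScan:
    def test_atg_candidate_in_utr(self):
        m = _model()
        seq = _seq_with("ATGAAATAA", 10)
        cands = scan_candidates(m, seq, ["ATG"])
        assert any((c.start, c.end, c.start_codon) == (10, 19, "ATG") for c in cands)

    def test_no_stop_no_candidate(self):
        m = TranscriptModel("T", "G", "c", "+", [(0, 30)])
        seq = _seq_with("ATGAAA", 21, length=30)  # no downstream in-frame stop
        assert scan_candidates(m, seq, ["ATG"]) == []

    def test_near_cognate_requires_configuration(self):
        m = _model()
        seq = _seq_with("CTGAAATAA", 10)
        assert not any(
            c.start == 10 for c in scan_candidates(m, seq, ["ATG"])
        )
        assert any(c.start == 10 for c in scan_candidates(m, seq, ["ATG", "CTG"]))

    def test_five_prime_most_start_per_stop_and_class(self):
        m = _model()
        # two in-frame ATGs sharing a stop: keep the 5'-most; the near-cognate
        # class keeps its own 5'-most representative
        seq = _seq_with("ATGCCCGTGATGAAATAA", 9)
        cands = scan_candidates(m, seq, ["ATG", "GTG"])
        sharing = [c for c in cands if c.end == 27]
        starts = {(c.start_codon, c.start) for c in sharing}
        assert ("ATG", 9) in starts
        assert ("GTG", 15) in starts
        assert not any(c.start == 18 for c in sharing)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            scan_candidates(_model(), "ACGT", ["ATG"])


class TestScore:
    def _candidate(self, start=99, end=399):
        return OrfCandidate("T", start, end, "ATG")

    def test_all_in_frame_closed_form(self):
        cand = OrfCandidate("T", 0, 90, "ATG")
        counts = np.zeros(90, dtype=int)
        counts[::3] = 1  # 30 P-sites, all frame 0
        track = PSiteTrack("T", counts)
        p = score_orf(cand, track)
        assert p == pytest.approx((1 / 3) ** 30, rel=1e-9)
        assert p == pytest.approx(4.857e-15, rel=1e-3)

    def test_brute_force_tail_agreement(self):
        for n, k in [(30, 10), (30, 15), (12, 12), (50, 20), (10, 4)]:
            counts = np.zeros(60, dtype=int)
            counts[0] = k  # frame 0
            counts[1] = n - k
            track = PSiteTrack("T", counts)
            cand = OrfCandidate("T", 0, 60, "ATG")
            assert score_orf(cand, track) == pytest.approx(
                binomial_tail_onethird(n, k), rel=1e-9
            )

    def test_n30_k10_value(self):
        # exact upper tail of Binomial(30, 1/3) at k = 10
        assert binomial_tail_onethird(30, 10) == pytest.approx(0.568256, abs=1e-6)

    def test_below_min_psites_is_one(self):
        counts = np.zeros(60, dtype=int)
        counts[0] = 5
        cand = OrfCandidate("T", 0, 60, "ATG")
        assert score_orf(cand, PSiteTrack("T", counts), min_psites=10) == 1.0

    def test_null_pvalues_super_uniform(self):
        """Frame-uniform occupancy: p-values are uniform or stochastically
        larger (one-sided KS does not reject)."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(400):
            counts = np.bincount(rng.integers(0, 90, size=60), minlength=90)
            cand = OrfCandidate("T", 0, 90, "ATG")
            pvals.append(score_orf(cand, PSiteTrack("T", counts)))
        # empirical CDF must not sit significantly above the uniform CDF
        ks = stats.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01


class TestClassify:
    # CDS spans [100, 400); frames are relative to the CDS start
    FIXTURES = [
        ((10, 40), "uORF"),  # entirely inside the 5'UTR
        ((80, 131), "uoORF"),  # start upstream, stop inside CDS, frame +1
        ((100, 400), "CDS"),  # identical to the annotation
        ((160, 400), "truncation"),  # same frame and stop, start inside CDS
        ((430, 460), "dORF"),  # entirely in the 3'UTR
        ((152, 251), "iORF"),  # inside the CDS, frame +1
        ((70, 400), "variant"),  # same-frame N-terminal extension, shares stop
        ((91, 400), "variant"),  # same-frame extension from inside the 5'UTR
        ((351, 471), "orphan"),  # frame-shifted, starts in CDS, ends in 3'UTR
    ]

    @pytest.mark.parametrize("interval,expected", FIXTURES)
    def test_taxonomy_fixtures(self, interval, expected):
        s, e = interval
        cand = OrfCandidate("T", s, e, "ATG")
        assert classify_orf(cand, _model()) == expected

    def test_ncrna_without_cds(self):
        m = TranscriptModel("T", "G", "c", "+", [(0, 500)])
        cand = OrfCandidate("T", 10, 40, "ATG")
        assert classify_orf(cand, m) == "ncRNA"

    def test_every_candidate_gets_exactly_one_category(self, small_txome):
        tid = small_txome.truth.transcript_id.iloc[0]
        m = small_txome.models[tid]
        cands = scan_candidates(m, small_txome.tx_seq[tid])
        cats = [classify_orf(c, m) for c in cands]
        from riboshift.orfs import CATEGORIES

        assert all(c in CATEGORIES for c in cats)
        assert len(cats) == len(cands)


class TestStartComposition:
    def test_fractions(self):
        df = pd.DataFrame(
            {
                "category": ["uORF"] * 4,
                "start_codon": ["ATG", "ATG", "ATG", "CTG"],
            }
        )
        counts, atg, non_atg = start_codon_composition(df)
        assert atg == 0.75
        assert non_atg == 0.25
        assert counts.sum() == 4

    def test_all_atg(self):
        df = pd.DataFrame({"category": ["uoORF"] * 3, "start_codon": ["ATG"] * 3})
        _, atg, non_atg = start_codon_composition(df)
        assert non_atg == 0.0

    def test_empty_errors(self):
        df = pd.DataFrame({"category": ["CDS"], "start_codon": ["ATG"]})
        with pytest.raises(ValueError):
            start_codon_composition(df)


class TestRunoff:
    def test_single_site_track_scores_one(self):
        counts = np.zeros(900, dtype=int)
        counts[300] = 50
        tracks = {0.0: PSiteTrack("T", counts), 30.0: PSiteTrack("T", counts)}
        scores = tis_runoff_score(tracks, [300])
        assert (scores.score == 1.0).all()

    def test_uniform_track_window_fraction(self):
        counts = np.ones(900, dtype=int)
        tracks = {0.0: PSiteTrack("T", counts), 30.0: PSiteTrack("T", counts)}
        scores = tis_runoff_score(tracks, [450], window_codons=1)
        # window [447, 456) = 9 nt of 900 → 0.01
        assert scores.score.iloc[0] == pytest.approx(9 / 900)

    def test_requires_two_timepoints(self):
        with pytest.raises(ValueError):
            tis_runoff_score({0.0: PSiteTrack("T", np.ones(90, dtype=int))}, [10])

    def test_empty_track_flagged(self):
        tracks = {
            0.0: PSiteTrack("T", np.zeros(90, dtype=int)),
            10.0: PSiteTrack("T", np.ones(90, dtype=int)),
        }
        scores = tis_runoff_score(tracks, [30])
        row = scores[scores.time == 0.0].iloc[0]
        assert row.undefined and np.isnan(row.score)

    def test_utis_score_increases_during_runoff(self):
        """Active uTIS accumulation: the uTIS share of the library grows
        monotonically as elongating ribosomes run off."""
        cfg = SimConfig(n_genes=30, library_size=30_000, seed=17)
        tx = simulate_transcriptome(cfg, seed=17)
        host = tx.truth.iloc[0]
        tid = host.transcript_id
        means = []
        tracks_by_t = {}
        for t in (5.0, 20.0, 60.0):
            fp = simulate_footprints(
                tx, "harringtonine", cfg, seed=int(t), time=t, arrested=True
            )
            tracks = tracks_from_footprints(fp, tx.models)
            tracks_by_t[t] = tracks[tid]
        scores = tis_runoff_score(tracks_by_t, [int(host.start)])
        traj = scores.sort_values("time").score.to_numpy()
        assert traj[0] < traj[1] < traj[2]

    def test_utis_to_annotated_ratio(self):
        counts = np.zeros(900, dtype=int)
        counts[30] = 20  # uTIS
        counts[300] = 40  # annotated TIS
        tracks = {0.0: PSiteTrack("T", counts), 30.0: PSiteTrack("T", counts)}
        scores = tis_runoff_score(tracks, [30, 300])
        ratios = utis_vs_annotated_ratio(scores, [30], 300)
        assert ratios.loc[0.0] == pytest.approx(0.5)


class TestFisher:
    def test_perfect_association_closed_form(self):
        p = fisher_one_sided([[10, 0], [0, 10]])
        import math

        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-12)
        assert p == pytest.approx(5.41e-6, rel=1e-2)

    def test_null_symmetry(self):
        assert fisher_one_sided([[5, 5], [5, 5]]) >= 0.5

    def test_enumeration_oracle_small_margins(self):
        """Exhaustive agreement with the hypergeometric enumeration oracle
        on all tables with total ≤ 12."""
        total_checked = 0
        for a in range(7):
            for b in range(7):
                for c in range(7):
                    for d in range(7):
                        if a + b + c + d == 0 or a + b + c + d > 12:
                            continue
                        table = [[a, b], [c, d]]
                        assert fisher_one_sided(table) == pytest.approx(
                            fisher_greater(table), rel=1e-10, abs=1e-12
                        )
                        total_checked += 1
        assert total_checked > 1000

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            fisher_one_sided([[0, 0], [0, 0]])

    def test_non_integer_errors(self):
        with pytest.raises(ValueError):
            fisher_one_sided([[1.5, 2], [3, 4]])
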