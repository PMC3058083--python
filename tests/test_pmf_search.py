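"""Fingerprint matching, binomial scoring, ranking and peptide collapse."""

import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from tracepmf import (
    DigestIndex,
    ProteinHit,
    SpectrumFingerprint,
    collapse_unique_peptides,
    match_peaks,
    merge_hits,
    rank_entries,
    score_hit,
    search_spot,
    tryptic_peptides,
)
from tracepmf.pmf_search import read_mgf, read_peaks_txt, write_mgf
from tracepmf.simulate import make_fingerprint

from conftest import random_protein


def exhaustive_binomial_tail(k, n, p):
    """Independent oracle: P(X >= k) by direct summation."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


class TestMatchPeaks:
    def _peps(self, protein="MAKRPEPTIDEKSTRLLK"):
        return tryptic_peptides(protein, 1, min_len=1)

    def test_empty_peak_list(self):
        assert match_peaks([], self._peps()) == []

    def test_exact_masses_all_match(self):
        peps = self._peps()[:5]
        pairs = match_peaks([p.mh_mass for p in peps], peps, tolerance=0.2)
        assert len(pairs) == 5

    def test_peak_outside_window_unmatched(self):
        peps = self._peps()
        assert match_peaks([peps[0].mh_mass + 0.5], peps, tolerance=0.2) == []

    def test_one_to_one_no_double_counting(self):
        peps = self._peps()
        # two peaks near one peptide: only one can claim it
        target = peps[0].mh_mass
        pairs = match_peaks([target, target + 0.01], [peps[0]], tolerance=0.2)
        assert len(pairs) == 1
        assert pairs[0][0] == target  # smaller absolute error wins

    def test_tie_break_by_lower_start_offset(self):
        a = self._peps()[0]
        peps = tryptic_peptides("K" + a.sequence + "K" + a.sequence, 0, min_len=1)
        same_mass = [p for p in peps if p.sequence == a.sequence]
        assert len(same_mass) == 2
        pairs = match_peaks([same_mass[0].mh_mass], same_mass, tolerance=0.2)
        assert pairs[0][1].start == min(p.start for p in same_mass)

    def test_non_positive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_peaks([500.0], self._peps(), tolerance=0.0)


class TestScoreHit:
    def test_no_matches_carry_no_evidence(self):
        assert score_hit(0, 10, 0.01) == (1.0, 0.0)

    @pytest.mark.parametrize("k,n,p", [(3, 10, 0.01), (1, 5, 0.3), (7, 20, 0.05),
                                       (15, 30, 0.2), (30, 30, 0.9)])
    def test_matches_exhaustive_summation(self, k, n, p):
        p_value, score = score_hit(k, n, p)
        expected = exhaustive_binomial_tail(k, n, p)
        assert p_value == pytest.approx(expected, rel=1e-9)
        assert score == pytest.approx(-10 * math.log10(expected), rel=1e-9)

    def test_score_strictly_increases_with_matches(self):
        scores = [score_hit(k, 10, 0.01)[1] for k in range(11)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_degenerate_match_probability_clamped(self):
        assert score_hit(5, 10, 1.0) == (1.0, 0.0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            score_hit(11, 10, 0.1)


def _db(rng, n, length=120):
    entries = []
    seen = set()
    while len(entries) < n:
        seq = random_protein(rng, length)
        if seq not in seen:
            seen.add(seq)
            entries.append((f"e{len(entries):04d}", seq))
    return entries


class TestSearchSpot:
    def test_single_entry_is_rank_one(self):
        protein = "MAKRPEPTIDEKSTRLLKAAAK" * 3
        idx = DigestIndex([("only", protein)], 1)
        fp, _ = make_fingerprint(protein, 1.0, 0.0, 0, seed=0, spot_id="s")
        hits = search_spot(fp, {"forward": [idx]}, top_n=10)["forward"]
        assert hits[0].entry_id == "only"
        assert hits[0].matched > 0

    def test_planted_protein_ranks_first_among_500_background(self):
        rng = np.random.default_rng(60)
        entries = _db(rng, 500, 60)
        source = random_protein(rng, 60)
        entries.append(("source", source))
        idx = DigestIndex(entries, 1)
        fp, _ = make_fingerprint(
            source, 1.0, 0.05, 5, seed=61, spot_id="planted", min_pep_len=4
        )
        hits = search_spot(fp, {"forward": [idx]}, tolerance=0.2, top_n=50)
        assert hits["forward"][0].entry_id == "source"

    def test_partition_search_merge_equals_concatenated_search(self):
        rng = np.random.default_rng(70)
        entries = _db(rng, 60, 80)
        full = DigestIndex(entries, 1)
        p1 = DigestIndex(entries[:25], 1)
        p2 = DigestIndex(entries[25:], 1)
        fp, _ = make_fingerprint(entries[3][1], 0.8, 0.05, 8, seed=71, spot_id="s")
        merged = merge_hits(
            [
                rank_entries(fp, p1, "forward", top_n=None),
                rank_entries(fp, p2, "forward", top_n=None),
            ],
            top_n=None,
        )
        whole = rank_entries(fp, full, "forward", top_n=None)
        key = lambda h: (h.entry_id, h.matched, round(h.score, 9))
        assert sorted(map(key, merged)) == sorted(map(key, whole))

    def test_top_n_retained_per_label(self):
        rng = np.random.default_rng(80)
        entries = _db(rng, 40, 80)
        idx = DigestIndex(entries, 1)
        fp, _ = make_fingerprint(entries[0][1], 0.9, 0.05, 5, seed=81, spot_id="s")
        hits = search_spot(fp, {"forward": [idx], "decoy": [idx]}, top_n=10)
        assert len(hits["forward"]) == len(hits["decoy"]) == 10
        total = sum(len(v) for v in hits.values())
        assert total == 10 * len(hits)

    def test_every_entry_materialized_without_truncation(self):
        rng = np.random.default_rng(90)
        entries = _db(rng, 30, 60)
        idx = DigestIndex(entries, 1)
        fp = SpectrumFingerprint("empty-ish", (712.34, 1523.77))
        hits = rank_entries(fp, idx, "forward", top_n=None)
        assert len(hits) == 30
        assert all(h.score >= 0 for h in hits)

    def test_ranking_is_deterministic(self):
        rng = np.random.default_rng(95)
        entries = _db(rng, 50, 70)
        idx = DigestIndex(entries, 1)
        fp, _ = make_fingerprint(entries[5][1], 0.8, 0.05, 6, seed=96, spot_id="s")
        h1 = rank_entries(fp, idx, "forward", top_n=20)
        h2 = rank_entries(fp, idx, "forward", top_n=20)
        assert [(h.entry_id, h.score) for h in h1] == [(h.entry_id, h.score) for h in h2]
        # ordering: score desc, matched desc, entry_id asc
        keys = [h.sort_key() for h in h1]
        assert keys == sorted(keys)

    def test_score_pvalue_relation_on_emitted_hits(self):
        rng = np.random.default_rng(97)
        entries = _db(rng, 50, 70)
        idx = DigestIndex(entries, 1)
        fp, _ = make_fingerprint(entries[7][1], 0.8, 0.05, 6, seed=98, spot_id="s")
        for h in rank_entries(fp, idx, "forward", top_n=None):
            if h.p_value < 1.0:
                assert h.score == pytest.approx(-10 * math.log10(h.p_value), rel=1e-9)
            else:
                assert h.score == 0.0

    def test_empty_database_warns_and_returns_nothing(self, caplog):
        fp = SpectrumFingerprint("s", (800.0,))
        idx = DigestIndex([], 1)
        with caplog.at_level("WARNING"):
            assert rank_entries(fp, idx, "forward") == []
        assert "empty database" in caplog.text

    def test_forward_decoy_null_scores_indistinguishable_on_pure_noise(self):
        """The scorer treats forward and decoy identically: on pure-noise
        fingerprints the two score populations come from the same null."""
        rng = np.random.default_rng(100)
        entries = _db(rng, 200, 100)
        fwd = DigestIndex(entries, 1)
        dec = DigestIndex([(f"DECOY_{e}", s[::-1]) for e, s in entries], 1)
        fwd_scores, dec_scores = [], []
        for i in range(30):
            fp = SpectrumFingerprint(
                f"noise{i}", tuple(rng.uniform(700, 3000, size=15))
            )
            res = search_spot(fp, {"forward": [fwd], "decoy": [dec]}, top_n=50)
            fwd_scores += [h.score for h in res["forward"]]
            dec_scores += [h.score for h in res["decoy"]]
        p = mannwhitneyu(fwd_scores, dec_scores).pvalue
        assert p > 0.01


class TestCollapse:
    def _hit(self, entry, score, peps, label="forward"):
        return ProteinHit("s", label, entry, len(peps), 10, 10 ** (-score / 10),
                          score, tuple(peps))

    def test_single_carrier(self):
        out = collapse_unique_peptides([self._hit("u1", 40.0, ["PEPK"])])
        assert out[0].best_score == 40.0
        assert out[0].entry_ids == ("u1",)

    def test_highest_score_retrieved_across_urfs(self):
        hits = [self._hit("u1", 40.0, ["PEPK"]), self._hit("u2", 55.0, ["PEPK"])]
        out = collapse_unique_peptides(hits)
        assert len(out) == 1
        assert out[0].best_score == 55.0
        assert out[0].entry_ids == ("u1", "u2")

    def test_one_record_per_distinct_peptide_and_label(self):
        hits = [
            self._hit("u1", 30.0, ["AAK", "CCK"]),
            self._hit("u2", 20.0, ["AAK"]),
            self._hit("d1", 25.0, ["AAK"], label="decoy"),
        ]
        out = collapse_unique_peptides(hits)
        assert len(out) == 3  # (forward,AAK), (forward,CCK), (decoy,AAK)
        labels = {(a.db_label, a.peptide_sequence) for a in out}
        assert labels == {("forward", "AAK"), ("forward", "CCK"), ("decoy", "AAK")}


class TestPeakListIO:
    def test_mgf_round_trip(self, tmp_path):
        fps = [
            SpectrumFingerprint("spot_a", (700.12, 1200.5, 2200.9)),
            SpectrumFingerprint("spot_b", (812.3,)),
        ]
        path = tmp_path / "spots.mgf"
        write_mgf(fps, path)
        back = read_mgf(path)
        assert [fp.spot_id for fp in back] == ["spot_a", "spot_b"]
        assert back[0].peaks == pytest.approx(fps[0].peaks, abs=1e-3)

    def test_two_column_text(self, tmp_path):
        path = tmp_path / "spot1.txt"
        path.write_text("# mass intensity\n800.5 12.0\n1200.25\t3.5\n")
        fp = read_peaks_txt(path)
        assert fp.spot_id == "spot1"
        assert fp.peaks == (800.5, 1200.25)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            SpectrumFingerprint("s", (0.0, 800.0))
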