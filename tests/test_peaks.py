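"""Peak windows, purified scores, motif counting, and estimator comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from chipdecon.genome import ChromSizes
from chipdecon.peaks import (
    Peak,
    best_estimator_tally,
    correlate_estimates,
    count_motifs_in_peaks,
    moving_motif_fraction,
    ratio_test,
    read_fimo_tsv,
    sextile_overlap,
    summit_windows,
)

SIZES = ChromSizes({"chr1": 100_000})


class TestSummitWindows:
    def test_symmetric_window_width(self, tmp_path):
        path = tmp_path / "summits.bed"
        path.write_text("chr1\t1000\t1001\tp1\t55.5\n")
        peaks = summit_windows(path, SIZES, h=64)
        p = peaks[0]
        assert (p.start, p.end, p.width) == (936, 1065, 129)
        assert p.score == 55.5

    def test_near_edge_summit_excluded(self, tmp_path):
        path = tmp_path / "summits.bed"
        path.write_text("chr1\t10\t11\tp1\t5\nchr1\t99990\t99991\tp2\t5\n")
        assert summit_windows(path, SIZES, h=64) == []

    def test_narrowpeak_summit_offset_and_score(self, tmp_path):
        path = tmp_path / "peaks.narrowPeak"
        path.write_text(
            "chr1\t900\t1200\tp1\t100\t.\t7.5\t10.0\t8.0\t150\n"
            "chr1\t2000\t2300\tp2\t100\t.\t3.0\t10.0\t8.0\t-1\n"  # unknown summit
        )
        peaks = summit_windows(path, SIZES, h=64)
        assert len(peaks) == 1
        assert peaks[0].summit == 1050
        assert peaks[0].score == 7.5

    def test_random_summits_all_get_width_2h_plus_1(self, tmp_path, rng):
        pos = rng.integers(200, 99_000, 100)
        path = tmp_path / "summits.bed"
        path.write_text("".join(f"chr1\t{p}\t{p + 1}\tp{i}\t1\n" for i, p in enumerate(pos)))
        for h in (10, 64):
            for p in summit_windows(path, SIZES, h=h):
                assert p.width == 2 * h + 1
                assert p.start == p.summit - h


class TestFimo:
    def test_parses_genomic_and_region_relative_coordinates(self, tmp_path):
        path = tmp_path / "fimo.tsv"
        path.write_text(
            "motif_id\tmotif_alt_id\tsequence_name\tstart\tstop\tstrand\tscore\tp-value\tq-value\tmatched_sequence\n"
            "M1\tm\tchr1\t101\t108\t+\t12\t1e-5\t0.01\tACGTACGT\n"
            "M1\tm\tchr1:1000-1129\t5\t12\t-\t12\t1e-5\t0.01\tACGTACGT\n"
        )
        occ = read_fimo_tsv(path)
        assert occ.loc[0, "start"] == 100 and occ.loc[0, "end"] == 108
        assert occ.loc[1, "start"] == 1004 and occ.loc[1, "end"] == 1012

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("motif_id\tsequence_name\tstart\n")
        with pytest.raises(ValueError):
            read_fimo_tsv(path)

    def test_full_containment_rule(self):
        peaks = [Peak("chr1", 1000, 936, 1065, "p0", 1.0)]
        inside = pd.DataFrame({"chrom": ["chr1"], "start": [940], "end": [948]})
        straddle = pd.DataFrame({"chrom": ["chr1"], "start": [930], "end": [940]})
        assert count_motifs_in_peaks(inside, peaks).tolist() == [1]
        assert count_motifs_in_peaks(straddle, peaks).tolist() == [0]

    def test_random_occurrences_match_pairwise_brute_force(self, rng):
        peaks = [
            Peak("chr1", int(s), int(s) - 64, int(s) + 65, f"p{i}", 1.0)
            for i, s in enumerate(rng.integers(100, 90_000, 50))
        ]
        starts = rng.integers(0, 99_000, 300)
        occ = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 8})
        m = count_motifs_in_peaks(occ, peaks)
        for i, p in enumerate(peaks):
            brute = sum(1 for s in starts if p.start <= s and s + 8 <= p.end)
            assert m[i] == brute


class TestCorrelation:
    def make_table(self, B, R, S, M):
        n = len(B)
        return pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * 200, "B": B, "R": R, "S": S,
             "M": M, "has_motif": np.asarray(M) > 0}
        )

    def test_proportional_signals_give_unit_correlation(self):
        M = np.arange(10.0)
        t = self.make_table(3 * M, M + 1, M, M)
        comp = correlate_estimates(t)
        assert np.allclose(comp["pcc"], 1.0)

    def test_constant_signal_flagged_undefined(self):
        t = self.make_table(np.arange(5.0), np.arange(5.0), np.ones(5), np.arange(5))
        comp = correlate_estimates(t).set_index("estimator")
        assert not comp.loc["S", "defined"]
        assert comp.loc["B", "defined"]

    def test_matches_covariance_formula_oracle(self, rng):
        B, R, S = rng.standard_normal((3, 40))
        M = rng.poisson(2.0, 40).astype(float)
        t = self.make_table(B, R, S, M)
        comp = correlate_estimates(t).set_index("estimator")
        for est, x in [("B", B), ("R", R), ("S", S)]:
            num = np.mean((x - x.mean()) * (M - M.mean()))
            r = num / (x.std() * M.std())
            assert comp.loc[est, "pcc"] == pytest.approx(r, abs=1e-12)


class TestRatioTest:
    def test_full_tail_is_one(self):
        assert ratio_test(0, 51, 3) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        n, k, methods = 6, 4, 3
        oracle = sum(
            math.comb(n, j) * (1 / methods) ** j * (1 - 1 / methods) ** (n - j)
            for j in range(k, n + 1)
        )
        assert ratio_test(k, n, methods) == pytest.approx(oracle, rel=1e-12)

    def test_monotone_decreasing_in_successes(self):
        ps = [ratio_test(k, 51, 3) for k in range(52)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_tally_counts_and_tie_break(self):
        def comp(b, r, s):
            return pd.DataFrame(
                {"estimator": ["B", "R", "S"], "pcc": [b, r, s],
                 "p_value": [0.01] * 3, "defined": [True] * 3}
            )

        out = best_estimator_tally([comp(0.5, 0.3, 0.2), comp(0.2, 0.4, 0.4),
                                    comp(0.3, 0.3, 0.3)])
        assert out["tally"] == {"B": 2, "R": 1, "S": 0}  # ties break toward B
        assert out["trials"] == 3
        assert out["best"] == "B"


class TestRankingDiagnostics:
    def test_constant_motif_presence_gives_flat_curve(self):
        t = pd.DataFrame({"chrom": "chr1", "start": np.arange(20) * 200,
                          "B": np.arange(20.0), "has_motif": True})
        assert np.allclose(moving_motif_fraction(t, "B", window=5), 1.0)

    def test_staircase_descends(self):
        n = 20
        t = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * 200,
             "B": np.arange(n, 0, -1, dtype=float),
             "has_motif": np.arange(n) < n // 2}
        )
        curve = moving_motif_fraction(t, "B", window=10)
        assert curve[0] == 1.0 and curve[-1] == 0.0
        assert np.all(np.diff(curve) <= 0)

    def test_matches_sliding_sum_brute_force(self, rng):
        n, w = 200, 50
        t = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * 200,
             "B": rng.standard_normal(n), "has_motif": rng.random(n) < 0.4}
        )
        curve = moving_motif_fraction(t, "B", window=w)
        ranked = t.sort_values("B", ascending=False, kind="stable")["has_motif"].to_numpy()
        for j in range(n - w + 1):
            assert curve[j] == pytest.approx(ranked[j : j + w].mean())

    def test_too_few_peaks_raises(self):
        t = pd.DataFrame({"chrom": "chr1", "start": [0], "B": [1.0],
                          "has_motif": [True]})
        with pytest.raises(ValueError):
            moving_motif_fraction(t, "B", window=1000)

    def test_sextile_overlap_identity_reverse_and_margins(self, rng):
        n = 600
        t = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 200,
                          "A": np.arange(n, 0, -1, dtype=float)})
        t["Arev"] = -t["A"]
        t["Rnd"] = rng.standard_normal(n)
        same = sextile_overlap(t, "A", "A")
        assert np.all(same == np.diag([100] * 6))
        rev = sextile_overlap(t, "A", "Arev")
        assert np.all(rev == np.fliplr(np.diag([100] * 6)))
        rand = sextile_overlap(t, "A", "Rnd")
        assert rand.sum(axis=0).tolist() == [100] * 6
        assert rand.sum(axis=1).tolist() == [100] * 6


class TestScorePeaks:
    def test_b_equals_r_minus_predicted_and_zero_for_exact_model(self, bundle):
        from chipdecon.background import BackgroundModel, decompose_windows
        from chipdecon.peaks import score_peaks
        from chipdecon.reads import deduplicate

        chip = deduplicate(bundle.read_sets["chip"])
        controls = {k: deduplicate(bundle.read_sets[k]) for k in ("dnase", "idna", "igg")}
        tracks = {"mappability": bundle.mappability, "gc": bundle.gc}
        res = decompose_windows(chip, tracks, controls, bundle.sizes,
                                width=129, exclude=())
        peaks = [
            Peak(r["chrom"], int(r["summit"]), int(r["summit"]) - 64,
                 int(r["summit"]) + 65, r["peak_id"], float(r["caller_score"]))
            for _, r in bundle.peaks.iterrows()
        ]
        table = score_peaks(peaks, chip, res, tracks, controls)
        np.testing.assert_allclose(table["B"], table["R"] - table["predicted"],
                                   rtol=0, atol=1e-12)

    def test_zero_coefficient_model_gives_b_equals_r_minus_intercept(self, bundle):
        from chipdecon.background import BackgroundModel
        from chipdecon.peaks import score_peaks
        from chipdecon.reads import deduplicate

        rng = np.random.default_rng(0)
        # fit y = const + noise so all slopes ~ 0, intercept ~ c
        n = 2_000
        names = ["mappability", "gc", "dnase", "idna", "igg"]
        X = {k: np.zeros(n) for k in names}
        y = np.full(n, 7.0) + rng.normal(0, 1e-6, n)
        res = BackgroundModel(y, X).fit()
        chip = deduplicate(bundle.read_sets["chip"])
        controls = {k: deduplicate(bundle.read_sets[k]) for k in ("dnase", "idna", "igg")}
        tracks = {"mappability": bundle.mappability, "gc": bundle.gc}
        peaks = [
            Peak(r["chrom"], int(r["summit"]), int(r["summit"]) - 64,
                 int(r["summit"]) + 65, r["peak_id"], 0.0)
            for _, r in bundle.peaks.head(20).iterrows()
        ]
        table = score_peaks(peaks, chip, res, tracks, controls)
        np.testing.assert_allclose(table["B"], table["R"] - res.params["intercept"],
                                   atol=1e-3)

    def test_width_mismatch_rejected(self, bundle):
        from chipdecon.background import decompose_windows
        from chipdecon.peaks import score_peaks
        from chipdecon.reads import deduplicate

        chip = deduplicate(bundle.read_sets["chip"])
        controls = {k: deduplicate(bundle.read_sets[k]) for k in ("dnase", "idna", "igg")}
        tracks = {"mappability": bundle.mappability, "gc": bundle.gc}
        res = decompose_windows(chip, tracks, controls, bundle.sizes,
                                width=257, exclude=())
        peaks = [Peak("chrS1", 1000, 936, 1065, "p", 1.0)]
        with pytest.raises(ValueError, match="width"):
            score_peaks(peaks, chip, res, tracks, controls)
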