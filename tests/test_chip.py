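"""Window tiling, fragment counting, the local background filter, NB GLM
inference, region merging with Simes combination, and coverage/AT
utilities — each checked against brute-force oracles where one exists."""

import numpy as np
import pandas as pd
import pytest

from hyphachrom import chip as C
from hyphachrom import simulate as S


def brute_counts(windows, fs, fe):
    return [
        int(sum((s < we) & (e > ws) for s, e in zip(fs, fe)))
        for ws, we in zip(windows["start"], windows["end"])
    ]


class TestTiling:
    def test_enumerated_starts_for_200bp_contig(self):
        w = C.tile_windows(200)
        assert w["start"].tolist() == [0, 23, 46, 69, 92, 115, 138, 161, 184]
        assert w["end"].iloc[-1] == 200

    def test_internal_base_in_exactly_three_windows(self):
        w = C.tile_windows(10_000)
        for base in (100, 5000, 9000):
            assert ((w["start"] <= base) & (w["end"] > base)).sum() == 3

    def test_short_contig_single_truncated_window(self):
        w = C.tile_windows(50)
        assert w.values.tolist() == [[0, 50]]

    def test_every_base_covered(self):
        w = C.tile_windows(1000)
        covered = np.zeros(1000, dtype=int)
        for s, e in zip(w["start"], w["end"]):
            covered[s:e] += 1
        assert (covered >= 1).all()


class TestCounting:
    def test_overlap_and_half_open_rules(self):
        w = C.tile_windows(200)
        frags = {"s": pd.DataFrame({"start": [10, 69], "end": [20, 80]})}
        counted = C.count_fragments(w, frags)
        w0 = counted[counted["start"] == 0]["s"].iloc[0]
        assert w0 == 1  # [10,20) overlaps [0,69); [69,80) does not (half-open)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        fs = rng.integers(0, 400, 60)
        fe = fs + rng.integers(1, 60, 60)
        w = C.tile_windows(450)
        counted = C.count_fragments(w, {"s": pd.DataFrame({"start": fs, "end": fe})})
        assert counted["s"].tolist() == brute_counts(w, fs, fe)

    def test_invalid_fragment_rejected(self):
        w = C.tile_windows(100)
        with pytest.raises(ValueError):
            C.count_fragments(w, {"s": pd.DataFrame({"start": [10], "end": [10]})})


class TestLocalFilter:
    def test_worked_arithmetic_example(self):
        # one window holding 40 fragments, its 2 kb surround holding 40
        # more: expected background 40*69/1931, log2fc approx 4.4 -> kept
        cfg = C.WindowConfig()
        L = 5000
        w = C.tile_windows(L, cfg)
        target = w.index[w["start"] == 2300][0]
        ws, we = w.loc[target, ["start", "end"]]
        frag_rows = [(ws + 5, ws + 6)] * 40
        rng = np.random.default_rng(0)
        centre = (ws + we) / 2
        for _ in range(40):
            p = int(rng.uniform(centre - 990, centre + 990))
            while ws - 1 <= p <= we:
                p = int(rng.uniform(centre - 990, centre + 990))
            frag_rows.append((p, p + 1))
        frags = {"s": pd.DataFrame(frag_rows, columns=["start", "end"])}
        counted = C.count_fragments(w, frags, cfg)
        out = C.local_filter(counted, frags, L, cfg, samples=["s"])
        row = out.loc[target]
        assert row["bg_expected"] == pytest.approx(40 * 69 / 1931, rel=0.01)
        assert row["filter_log2fc"] == pytest.approx(4.4, abs=0.15)
        assert bool(row["retained"])

    def test_uniform_coverage_dropped(self):
        cfg = C.WindowConfig()
        L = 20_000
        rng = np.random.default_rng(1)
        fs = rng.integers(0, L - 1, 5000)
        frags = {"s": pd.DataFrame({"start": fs, "end": fs + 1})}
        w = C.tile_windows(L, cfg)
        counted = C.count_fragments(w, frags, cfg)
        out = C.local_filter(counted, frags, L, cfg)
        assert out["retained"].mean() < 0.01

    def test_empty_window_dropped(self):
        cfg = C.WindowConfig()
        frags = {"s": pd.DataFrame({"start": [4000], "end": [4001]})}
        w = C.tile_windows(5000, cfg)
        counted = C.count_fragments(w, frags, cfg)
        out = C.local_filter(counted, frags, 5000, cfg)
        assert not out.loc[out["start"] == 0, "retained"].iloc[0]


class TestDispersion:
    def test_nb_recovery(self):
        rng = np.random.default_rng(5)
        phi, mu = 0.1, 60
        g = rng.gamma(1 / phi, phi, size=(5000, 6))
        Y = rng.poisson(mu * g)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        est = C.estimate_dispersion(Y, groups, np.full(6, 1000.0))
        assert 0.08 <= est <= 0.12

    def test_poisson_counts_give_small_phi(self):
        rng = np.random.default_rng(6)
        Y = rng.poisson(60, size=(4000, 6))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        assert C.estimate_dispersion(Y, groups, np.full(6, 1000.0)) < 0.05

    def test_single_window_warns(self):
        Y = np.array([[5, 6, 7, 8, 9, 10]])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.warns(UserWarning):
            C.estimate_dispersion(Y, groups, np.full(6, 1000.0))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            C.estimate_dispersion(np.zeros((10, 4)), np.array(["a", "a", "b", "b"]))


class TestNBTest:
    def test_identical_groups_null_result(self):
        Y = np.tile([50, 50, 50, 50, 50, 50], (5, 1))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = C.nb_test(Y, groups, 0.1, np.full(6, 1000.0))
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert (res["p"] > 0.99).all()

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(7)
        phi, mu = 0.1, 50
        g = rng.gamma(1 / phi, phi, size=(2000, 6))
        Y = rng.poisson(mu * g)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = C.nb_test(Y, groups, phi, np.full(6, 1000.0))
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.07

    def test_eightfold_enrichment_recovered(self):
        rng = np.random.default_rng(8)
        phi = 0.1
        g = rng.gamma(1 / phi, phi, size=(1000, 6))
        mu = np.where(np.arange(6) < 3, 400, 50)
        Y = rng.poisson(mu * g)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = C.nb_test(Y, groups, phi, np.full(6, 1000.0))
        assert 2.5 <= np.median(-res["log2fc"]) <= 3.5

    def test_qlf_variant_runs(self):
        rng = np.random.default_rng(9)
        Y = rng.poisson(50, size=(200, 6))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = C.nb_test(Y, groups, 0.05, np.full(6, 1000.0), method="qlf")
        assert res["p"].between(0, 1).all()


class TestAgainstReferenceGLM:
    """Frozen cross-check against the reference NB GLM implementation
    (edgeR 4.0: estimateGLMCommonDisp + glmFit/glmLRT run once on this
    exact matrix; its outputs are hard-coded below as the oracle)."""

    def _matrix(self):
        rng = np.random.default_rng(2024)
        phi, mu = 0.08, 40
        g = rng.gamma(1 / phi, phi, size=(60, 6))
        mu_vec = np.where(np.arange(60) % 10 == 0, 4 * mu, mu)[:, None] * np.ones(6)
        mu_vec[:, 3:] = mu
        return rng.poisson(mu_vec * g)

    def test_dispersion_and_lrt_match_reference(self):
        Y = self._matrix()
        assert Y[0].tolist() == [228, 211, 105, 60, 52, 48]  # guard the stream
        groups = np.array(["a"] * 3 + ["b"] * 3)
        libs = Y.sum(axis=0).astype(float)
        phi = C.estimate_dispersion(Y, groups, libs)
        assert phi == pytest.approx(0.087569998, rel=0.02)
        res = C.nb_test(Y, groups, phi, libs)
        ref_p = [0.00032409856, 0.03542652283, 0.35967145085,
                 0.87279239751, 0.46601739915, 0.23363364145]
        ref_lfc = [-1.350489081, 0.849674401, 0.363971770,
                   0.064330254, 0.284089232, 0.474396518]
        for i in range(6):
            assert res["p"].iloc[i] == pytest.approx(ref_p[i], rel=0.05)
            assert res["log2fc"].iloc[i] == pytest.approx(ref_lfc[i], abs=0.15)


class TestMergeAndCombine:
    def _windows(self, intervals, ps):
        return pd.DataFrame({
            "start": [i[0] for i in intervals],
            "end": [i[1] for i in intervals],
            "p": ps,
            "log2fc": 3.0,
        })

    def test_merge_gap_boundary(self):
        merged_99 = C.merge_and_combine(self._windows([(0, 69), (168, 237)], [0.01, 0.01]))
        assert len(merged_99) == 1  # gap 99 < 100 merged
        kept_100 = C.merge_and_combine(self._windows([(0, 69), (169, 238)], [0.01, 0.01]))
        assert len(kept_100) == 2  # gap 100 not merged

    def test_simes_direct_formula(self):
        assert C.simes(np.array([0.01, 0.03, 0.04])) == pytest.approx(0.03)

    def test_single_window_region_keeps_p(self):
        out = C.merge_and_combine(self._windows([(0, 69)], [0.012]))
        assert out["p_combined"].iloc[0] == pytest.approx(0.012)

    def test_simes_at_least_min_p(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            p = rng.uniform(0, 1, rng.integers(1, 8))
            assert C.simes(p) >= p.min() - 1e-12

    def test_idempotent_and_order_invariant(self):
        w = self._windows([(0, 69), (30, 99), (500, 569), (700, 769)],
                          [0.01, 0.2, 0.03, 0.5])
        a = C.merge_and_combine(w)
        b = C.merge_and_combine(w.sample(frac=1.0, random_state=2))
        pd.testing.assert_frame_equal(a, b)
        again = C.merge_and_combine(
            a.rename(columns={"p_combined": "p"})[["start", "end", "p", "log2fc"]]
        )
        assert len(again) == len(a)
        assert again["start"].tolist() == a["start"].tolist()


class TestATFraction:
    @pytest.mark.parametrize("seq, expected", [
        ("ATAT", 1.0),
        ("GCGC", 0.0),
        ("ATGCN", 0.5),   # ambiguous base excluded from both sides
        ("atgc", 0.5),
    ])
    def test_fractions(self, seq, expected):
        assert C.at_fraction(seq) == pytest.approx(expected)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            C.at_fraction("ACGT", 2, 2)

    def test_boosted_sites_above_background(self, chip_enriched):
        cfg, frags, genome, truth = chip_enriched
        site_at = [C.at_fraction(genome, int(s), int(e))
                   for s, e in zip(truth["start"], truth["end"])]
        assert np.median(site_at) > C.at_fraction(genome)


class TestRegionComparison:
    def _df(self, iv):
        return pd.DataFrame(iv, columns=["start", "end"])

    def test_disjoint_and_identical(self):
        a = self._df([(0, 10), (20, 30)])
        b = self._df([(50, 60)])
        ua, ub, shared = C.compare_region_sets(a, b)
        assert (len(ua), len(ub), len(shared)) == (2, 1, 0)
        ua, ub, shared = C.compare_region_sets(a, a)
        assert (len(ua), len(ub), len(shared)) == (0, 0, 2)

    def test_counts_match_bruteforce(self):
        rng = np.random.default_rng(11)
        a = self._df([(s, s + rng.integers(1, 30)) for s in rng.integers(0, 500, 12)])
        b = self._df([(s, s + rng.integers(1, 30)) for s in rng.integers(0, 500, 12)])
        ua, ub, shared = C.compare_region_sets(a, b)
        brute_shared = sum(
            any((bs < ae) and (be > as_) for bs, be in zip(b["start"], b["end"]))
            for as_, ae in zip(a["start"], a["end"])
        )
        assert len(shared) == brute_shared
        assert len(ua) == len(a) - brute_shared


class TestCoverage:
    def test_single_bin_concentration(self):
        frags = {"s": pd.DataFrame({"start": [10, 20, 30], "end": [15, 25, 35]})}
        cov = C.binned_coverage(frags, 1000)
        assert cov["s"].iloc[0] == pytest.approx(1.0)
        assert cov["s"].iloc[1:].sum() == 0

    def test_identical_replicates_average_unchanged(self):
        df = pd.DataFrame({"start": [10, 210], "end": [15, 215]})
        cov = C.binned_coverage({"a": df, "b": df.copy()}, 1000)
        assert np.allclose(cov["coverage"], cov["a"])

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(12)
        fs = rng.integers(0, 900, 40)
        fe = fs + rng.integers(1, 80, 40)
        frags = {"s": pd.DataFrame({"start": fs, "end": fe})}
        cov = C.binned_coverage(frags, 1000, C.CoverageConfig(normalize=False))
        brute = brute_counts(cov, fs, fe)
        assert cov["s"].tolist() == brute

    def test_zero_fragments_rejected(self):
        with pytest.raises(ValueError):
            C.binned_coverage({"s": pd.DataFrame(columns=["start", "end"])}, 1000)


class TestEndToEnd:
    def test_truth_sites_recovered(self, chip_enriched):
        cfg, frags, genome, truth = chip_enriched
        wcfg = C.WindowConfig()
        windows = C.tile_windows(cfg.genome_length, wcfg)
        counted = C.count_fragments(windows, frags, wcfg)
        filtered = C.local_filter(counted, frags, cfg.genome_length, wcfg)
        samples = list(frags)
        groups = np.array([s.rsplit("_rep", 1)[0] for s in samples])
        libs = np.array([len(frags[s]) for s in samples], dtype=float)
        tested = filtered[filtered["retained"]].reset_index(drop=True)
        phi = C.estimate_dispersion(tested[samples].to_numpy(), groups, libs)
        res = C.nb_test(tested[samples].to_numpy(), groups, phi, libs)
        tw = pd.concat([tested[["start", "end"]], res], axis=1)
        regions = C.merge_and_combine(tw, wcfg)
        sig = regions[regions["significant"]]
        hits = sum(
            bool(((sig["start"] < e) & (sig["end"] > s)).any())
            for s, e in zip(truth["start"], truth["end"])
        )
        assert hits >= 0.8 * len(truth)
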