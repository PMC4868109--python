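"""Recovery, dispersion and the global quality descriptors.

Includes two independent oracles: exhaustive enumeration of all subsets
on a tiny library, and the hypergeometric law for a single window's
pass-rate.
"""

from itertools import combinations
from math import comb, floor

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petqc.binning import BinGrid, ContactMatrix, bin_pets
from petqc.errors import ContractError, NothingToScoreError, UndefinedScoreError
from petqc.io import ChromSizes
from petqc.qc import (
    QCConfig,
    denqc,
    dispersion,
    dispersion_map,
    export_dispersion_map,
    qcscore,
    read_dispersion_map,
    recovered_counts,
    run_qc,
    simqc,
)
from petqc.sampling import SamplingPlan, subsample
from petqc.synthetic import SyntheticConfig, generate, saturated_pets

from conftest import make_pets


def matrix(grid, rows):
    df = pd.DataFrame(rows, columns=["chrom", "bin_i", "bin_j", "count"])
    return ContactMatrix(grid=grid, df=df.astype({"bin_i": np.int64, "bin_j": np.int64, "count": np.int64}))


class TestRecoveredCounts:
    def test_recovery_percentages(self, sizes):
        grid = BinGrid(5_000, sizes)
        o = matrix(grid, [("chr1", 0, 4, 10), ("chr1", 0, 6, 4)])
        s = matrix(grid, [("chr1", 0, 4, 5), ("chr1", 0, 6, 4)])
        out = recovered_counts(o, s)
        assert list(out["rec_pct"]) == [50.0, 100.0]

    def test_window_absent_from_subsample_recovers_zero(self, sizes):
        grid = BinGrid(5_000, sizes)
        o = matrix(grid, [("chr1", 0, 4, 3)])
        s = matrix(grid, [])
        out = recovered_counts(o, s)
        assert list(out["rec_pct"]) == [0.0]

    def test_min_window_count_excludes_sparse_windows(self, sizes):
        grid = BinGrid(5_000, sizes)
        o = matrix(grid, [("chr1", 0, 4, 1), ("chr1", 0, 6, 5)])
        out = recovered_counts(o, matrix(grid, []), min_window_count=2)
        assert len(out) == 1 and out["o_count"].iloc[0] == 5

    def test_grid_mismatch_is_contract_error(self, sizes):
        o = matrix(BinGrid(5_000, sizes), [("chr1", 0, 4, 1)])
        s = matrix(BinGrid(25_000, sizes), [])
        with pytest.raises(ContractError):
            recovered_counts(o, s)


class TestIndicatorArithmetic:
    @pytest.mark.parametrize("samd,rec,expected", [(50, 50, 0), (90, 100, -10), (70, 40, 30)])
    def test_dispersion(self, samd, rec, expected):
        assert dispersion(rec, samd) == expected

    def test_denqc_counts_fraction_within_threshold(self, sizes):
        grid = BinGrid(5_000, sizes)

        def dmap_from(dpets):
            df = pd.DataFrame(
                {"chrom": "chr1", "bin_i": 0, "bin_j": range(4, 4 + len(dpets)),
                 "o_count": 10, "s_count": 5, "rec_pct": 50.0, "dpet_pct": dpets}
            )
            from petqc.qc import DispersionMap
            return DispersionMap(50.0, 5_000, 10.0, 0, df)

        assert denqc(dmap_from([0, 0, 0])) == 1.0
        assert denqc(dmap_from([0, 5, 15, 20])) == 0.5
        # absolute value and non-strict boundary
        assert denqc(dmap_from([-10, 10])) == 1.0

    def test_denqc_empty_universe_is_error(self):
        from petqc.qc import DispersionMap
        empty = DispersionMap(50.0, 5_000, 10.0, 0, pd.DataFrame(
            columns=["chrom", "bin_i", "bin_j", "o_count", "s_count", "rec_pct", "dpet_pct"]))
        with pytest.raises(UndefinedScoreError):
            denqc(empty)

    def test_simqc(self):
        assert simqc(0.4, 0.4) == 1.0
        assert simqc(0.8, 0.4) == 2.0
        with pytest.raises(UndefinedScoreError):
            simqc(0.5, 0.0)

    def test_qcscore_values(self):
        raw, logv = qcscore(1.0, 1.0, 1.0)
        assert raw == 1.0 and logv == 0.0
        raw, logv = qcscore(0.01, 2.0, 1.5)
        assert raw == pytest.approx(3.3333e-5, rel=1e-3)
        assert logv == pytest.approx(-44.77, abs=0.01)
        with pytest.raises(UndefinedScoreError):
            qcscore(0.0, 1.0, 1.0)

    def test_qcscore_monotone_in_denqc50(self):
        scores = [qcscore(x, 1.3, 1.1)[1] for x in (0.05, 0.1, 0.2, 0.4, 0.8)]
        assert all(a < b for a, b in zip(scores, scores[1:]))


def toy_three_window_pets(sizes):
    """8 PETs over 3 windows with counts 4/3/1, all spans > 10 kb."""
    rows = (
        [("chr1", 1_000 + k, "+", "chr1", 21_000 + k, "+") for k in range(4)]      # (0,4)
        + [("chr1", 1_000 + k, "+", "chr1", 31_000 + k, "+") for k in range(3)]    # (0,6)
        + [("chr1", 11_000, "+", "chr1", 41_000, "+")]                             # (2,8)
    )
    return make_pets(rows, sizes)


class TestExhaustiveSubsetOracle:
    def test_monte_carlo_denqc_matches_enumeration(self, sizes):
        """Exact expected denQC.50 by enumerating all C(8,4) subsets vs the
        pipeline's Monte-Carlo estimate over 2,000 seeds, within 3 SE."""
        pets = toy_three_window_pets(sizes)
        # windows by construction: indices 0-3 -> A, 4-6 -> B, 7 -> C
        membership = [0] * 4 + [1] * 3 + [2]
        o_counts = [4, 3, 1]
        d, thr = 0.5, 10.0
        k = floor(d * 8)
        vals = []
        for subset in combinations(range(8), k):
            s_counts = [0, 0, 0]
            for idx in subset:
                s_counts[membership[idx]] += 1
            passes = sum(
                abs(50.0 - 100.0 * s / o) <= thr for s, o in zip(s_counts, o_counts)
            )
            vals.append(passes / 3)
        vals = np.array(vals)
        expected, sd = vals.mean(), vals.std(ddof=1)

        grid = BinGrid(5_000, sizes)
        o = bin_pets(pets, grid)
        cfg = QCConfig()
        estimates = []
        for seed in range(2_000):
            s = bin_pets(subsample(pets, d, seed), grid)
            estimates.append(denqc(dispersion_map(o, s, d, cfg, seed)))
        mc = np.mean(estimates)
        assert abs(mc - expected) <= 3 * sd / np.sqrt(len(estimates))


class TestHypergeometricPassRateOracle:
    def test_single_window_pass_rate(self, sizes):
        """P(|dPETcounts| <= 10) for one window from the hypergeometric law
        vs the empirical pass-rate over seeds."""
        o_count, n_total, d, thr = 20, 100, 0.5, 10.0
        rows = [("chr1", 1_000 + k, "+", "chr1", 21_000 + k, "+") for k in range(o_count)]
        rows += [("chr1", 40_000 + 13 * k, "+", "chr1", 90_000 + 13 * k, "+")
                 for k in range(n_total - o_count)]
        pets = make_pets(rows, sizes)
        k_draw = floor(d * n_total)
        # pass iff 100*k/o_count in [40, 60] <=> k in [8, 12]
        law = stats.hypergeom(n_total, o_count, k_draw)
        p_pass = law.cdf(12) - law.cdf(7)
        grid = BinGrid(5_000, sizes)
        o = bin_pets(pets, grid)
        cfg = QCConfig()
        n_seeds = 800
        hits = 0
        for seed in range(n_seeds):
            s = bin_pets(subsample(pets, d, seed), grid)
            dmap = dispersion_map(o, s, d, cfg, seed)
            w = dmap.df.loc[(dmap.df.bin_i == 0) & (dmap.df.bin_j == 4), "dpet_pct"]
            hits += bool(abs(float(w.iloc[0])) <= thr)
        se = np.sqrt(p_pass * (1 - p_pass) / n_seeds)
        assert abs(hits / n_seeds - p_pass) <= 3 * se


class TestRunQC:
    def test_two_pet_single_window_toy(self, sizes):
        """Every size-1 subset of 2 same-window PETs recovers exactly half."""
        pets = make_pets(
            [("chr1", 1_000, "+", "chr1", 21_000, "+"),
             ("chr1", 2_000, "-", "chr1", 22_000, "-")],
            sizes,
        )
        res = run_qc(pets, QCConfig(), SamplingPlan(densities=(0.5,), master_seed=0))
        assert res.summary.denqc[50.0] == 1.0
        dmap = res.dispersion_maps[50.0]
        assert list(dmap.df["rec_pct"]) == [50.0]
        assert list(dmap.df["dpet_pct"]) == [0.0]

    def test_saturated_library_scores_zero(self):
        pets = saturated_pets(n_windows=5, count_per_window=10_000)
        res = run_qc(pets, QCConfig(), SamplingPlan(master_seed=1))
        s = res.summary
        assert all(v == 1.0 for v in s.denqc.values())
        assert all(v == 1.0 for v in s.simqc.values())
        assert s.qcscore == 0.0

    def test_bit_identical_under_same_master_seed(self):
        cfg = SyntheticConfig(n_pets=5_000, seed=3)
        pets = generate(cfg)
        a = run_qc(pets, QCConfig(), SamplingPlan(master_seed=17))
        b = run_qc(pets, QCConfig(), SamplingPlan(master_seed=17))
        assert a.summary.to_dict() == b.summary.to_dict()

    def test_recovery_and_dispersion_bounds(self):
        pets = generate(SyntheticConfig(n_pets=8_000, seed=5))
        res = run_qc(pets, QCConfig(), SamplingPlan(master_seed=2))
        for samd, dmap in res.dispersion_maps.items():
            rec = dmap.df["rec_pct"].to_numpy()
            dpt = dmap.df["dpet_pct"].to_numpy()
            assert (rec >= 0).all() and (rec <= 100).all()
            assert (dpt >= samd - 100).all() and (dpt <= samd).all()

    def test_density_ordering_majority_at_moderate_counts(self):
        """denQC.90 >= denQC.70 >= denQC.50 holds for most seeds when
        per-window counts are moderate (no singleton quantization)."""
        pets = saturated_pets(n_windows=60, count_per_window=30, seed=4)
        ordered = 0
        for seed in range(20):
            s = run_qc(pets, QCConfig(), SamplingPlan(master_seed=seed)).summary
            ordered += s.denqc[90.0] >= s.denqc[70.0] >= s.denqc[50.0]
        assert ordered > 10

    def test_empty_input_is_nothing_to_score(self, sizes):
        with pytest.raises(NothingToScoreError):
            run_qc(make_pets([], sizes), QCConfig(), SamplingPlan())

    def test_all_short_spans_reports_stats(self, sizes):
        pets = make_pets([("chr1", 0, "+", "chr1", 5_000, "+")] * 3, sizes)
        with pytest.raises(NothingToScoreError) as err:
            run_qc(pets, QCConfig(), SamplingPlan())
        assert err.value.stats is not None
        assert err.value.stats.filtered_pets == 0

    def test_singleton_windows_make_score_undefined(self, sizes):
        """All-singleton windows: denQC.50 = 0, so the score must be an
        explicit undefined-score error, not an infinity."""
        rows = [("chr1", 10_000 * k, "+", "chr1", 10_000 * k + 30_000, "+") for k in range(4)]
        with pytest.raises(UndefinedScoreError):
            run_qc(make_pets(rows, sizes), QCConfig(), SamplingPlan(master_seed=0))

    def test_replicates_report_mean_and_cv(self):
        pets = generate(SyntheticConfig(n_pets=20_000, seed=8))
        res = run_qc(pets, QCConfig(), SamplingPlan(replicates=3, master_seed=6))
        assert len(res.replicates) == 3
        scores = np.array([r.qcscore for r in res.replicates])
        assert res.score_mean == pytest.approx(scores.mean())
        assert res.score_cv_pct == pytest.approx(scores.std(ddof=1) / abs(scores.mean()) * 100)
        # adding replicates never changes the first draw
        res1 = run_qc(pets, QCConfig(), SamplingPlan(replicates=1, master_seed=6))
        assert res1.summary.to_dict() == res.replicates[0].to_dict()


class TestDispersionMapExport:
    def test_round_trip_preserves_values(self, tmp_path):
        pets = generate(SyntheticConfig(n_pets=10_000, seed=9))
        res = run_qc(pets, QCConfig(), SamplingPlan(master_seed=4))
        dmap = res.dispersion_maps[50.0]
        out = tmp_path / "dmap.tsv"
        export_dispersion_map(dmap, out)
        df, meta = read_dispersion_map(out)
        assert meta["density_pct"] == "50"
        assert meta["resolution_bp"] == "5000"
        np.testing.assert_allclose(
            df["dpet_pct"].to_numpy(), dmap.df["dpet_pct"].to_numpy()
        )

    def test_region_restriction(self, tmp_path):
        pets = generate(SyntheticConfig(n_pets=10_000, seed=9))
        res = run_qc(pets, QCConfig(), SamplingPlan(master_seed=4))
        dmap = res.dispersion_maps[50.0]
        out = tmp_path / "dmap.tsv"
        export_dispersion_map(dmap, out, region="chrSynA:0-500000", sizes=pets.sizes)
        df, _ = read_dispersion_map(out)
        assert set(df["chrom"]) <= {"chrSynA"}
        assert (df["bin_j"] < 100).all()

    def test_empty_region_gives_header_only(self, tmp_path):
        pets = saturated_pets(n_windows=3, count_per_window=100)
        res = run_qc(pets, QCConfig(), SamplingPlan(master_seed=1))
        out = tmp_path / "dmap.tsv"
        # far end of the chromosome holds no windows
        export_dispersion_map(res.dispersion_maps[50.0], out,
                              region="chrSat:1900000-2000000", sizes=pets.sizes)
        df, meta = read_dispersion_map(out)
        assert len(df) == 0 and "density_pct" in meta

    def test_unknown_region_rejected(self, tmp_path):
        pets = saturated_pets(n_windows=3, count_per_window=100)
        res = run_qc(pets, QCConfig(), SamplingPlan(master_seed=1))
        with pytest.raises(ValueError):
            export_dispersion_map(res.dispersion_maps[50.0], tmp_path / "x.tsv",
                                  region="chrNope", sizes=pets.sizes)
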