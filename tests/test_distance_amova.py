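import itertools

import numpy as np
import pytest

from ystr_popkit.distance_amova import (
    DistanceMatrix,
    DistanceOptions,
    amova_pair,
    haplotype_distance,
    pairwise_differences,
    rst_matrix,
    squared_distance_matrix,
)
from ystr_popkit.haplotype_io import (
    HaplotypeTable,
    LocusPanel,
    STRProfile,
    YFILER_PANEL,
)
from ystr_popkit.synthetic_data import SimulationConfig, simulate_table

from tests.conftest import make_single_locus_table


def pair_panel():
    return LocusPanel(loci=("DYS19", "DYS385"), multi_copy=frozenset({"DYS385"}),
                      derived_encoding={})


class TestHaplotypeDistance:
    def test_identical_profiles_zero(self, study_table):
        table, _ = study_table
        p = table.profiles[0]
        assert haplotype_distance(p, p, table.panel) == 0.0

    def test_single_locus_squared_difference(self, single_locus_panel):
        a = STRProfile.build("a", "p", {"DYS19": 14}, single_locus_panel)
        b = STRProfile.build("b", "p", {"DYS19": 16}, single_locus_panel)
        assert haplotype_distance(a, b, single_locus_panel) == 4.0

    def test_dys385_sorted_positional(self):
        panel = pair_panel()
        a = STRProfile.build("a", "p", {"DYS19": 14, "DYS385": (13, 17)}, panel)
        b = STRProfile.build("b", "p", {"DYS19": 14, "DYS385": (17, 14)}, panel)
        # sorted pairs (13,17) vs (14,17): positional differences 1 + 0
        assert haplotype_distance(a, b, panel) == 1.0

    def test_missing_contributes_zero(self, single_locus_panel):
        panel = pair_panel()
        a = STRProfile.build("a", "p", {"DYS19": 14, "DYS385": (13, 17)}, panel)
        b = STRProfile.build("b", "p", {"DYS19": None, "DYS385": (13, 18)}, panel)
        assert haplotype_distance(a, b, panel) == 1.0

    def test_empty_subset_error(self, single_locus_panel):
        a = STRProfile.build("a", "p", {"DYS19": 14}, single_locus_panel)
        with pytest.raises(ValueError):
            haplotype_distance(a, a, single_locus_panel, locus_subset=[])

    def test_microvariant_face_value_vs_rounded(self):
        panel = LocusPanel(loci=("DYS458",), multi_copy=frozenset(),
                           derived_encoding={})
        a = STRProfile.build("a", "p", {"DYS458": 17.2}, panel)
        b = STRProfile.build("b", "p", {"DYS458": 17}, panel)
        assert haplotype_distance(a, b, panel) == pytest.approx(0.04)
        opts = DistanceOptions(round_microvariants=True)
        assert haplotype_distance(a, b, panel, options=opts) == 0.0


class TestPairwiseDifferences:
    def test_hand_example(self):
        t = make_single_locus_table({"A": [10, 12], "B": [20, 20]})
        res = pairwise_differences(t)
        assert res.pix["A"] == 4.0 and res.pix["B"] == 0.0
        assert res.pixy.loc["A", "B"] == 82.0
        assert res.corrected.loc["A", "B"] == 80.0
        assert res.corrected.loc["A", "A"] == 0.0

    def test_identical_populations_corrected_zero(self):
        t = make_single_locus_table({"A": [10, 12, 14], "B": [10, 12, 14]})
        res = pairwise_differences(t)
        assert res.pixy.loc["A", "B"] == pytest.approx(res.pix["A"], rel=0.5)
        # identical spectra: corrected = PiXY - PiX; cross pairs include
        # self-matches so corrected is exactly 0 only for identical members
        t2 = make_single_locus_table({"A": [10, 10], "B": [10, 10]})
        res2 = pairwise_differences(t2)
        assert res2.corrected.loc["A", "B"] == 0.0

    def test_singleton_population_reported_missing(self):
        t = make_single_locus_table({"A": [10, 12], "B": [20]})
        res = pairwise_differences(t)
        assert np.isnan(res.pix["B"])
        assert np.isnan(res.corrected.loc["A", "B"])

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        vals = {"A": rng.integers(10, 20, 17).tolist(),
                "B": rng.integers(10, 20, 21).tolist(),
                "C": rng.integers(10, 20, 12).tolist()}
        t = make_single_locus_table(vals)
        res = pairwise_differences(t)
        for pop, v in vals.items():
            pairs = [(a - b) ** 2 for a, b in itertools.combinations(v, 2)]
            assert res.pix[pop] == pytest.approx(np.mean(pairs), abs=1e-12)
        for pa, pb in itertools.combinations(vals, 2):
            cross = [(a - b) ** 2 for a in vals[pa] for b in vals[pb]]
            assert res.pixy.loc[pa, pb] == pytest.approx(np.mean(cross), abs=1e-12)


class TestAmova:
    def test_hand_variance_components(self):
        t = make_single_locus_table({"A": [10, 12], "B": [20, 20]})
        res = amova_pair(t, "A", "B")
        # independent hand computation: SSD_total=83, SSD_within=2,
        # MS_among=81, MS_within=1, n_c=2 -> sigma_a=40, R_ST=40/41
        assert res.ssd_total == pytest.approx(83.0)
        assert res.ssd_within == pytest.approx(2.0)
        assert res.sigma2_among == pytest.approx(40.0)
        assert res.sigma2_within == pytest.approx(1.0)
        assert res.rst == pytest.approx(40 / 41)

    def test_no_within_variance_gives_rst_one(self):
        t = make_single_locus_table({"A": [10, 10], "B": [14, 14]})
        assert amova_pair(t, "A", "B").rst == pytest.approx(1.0)

    def test_identical_populations_rst_near_zero(self):
        t = make_single_locus_table({"A": [10, 12, 14], "B": [10, 12, 14]})
        assert amova_pair(t, "A", "B").rst <= 0.0 + 1e-9

    def test_zero_total_variance_flagged(self):
        t = make_single_locus_table({"A": [10, 10], "B": [10, 10]})
        res = amova_pair(t, "A", "B")
        assert res.degenerate and res.rst == 0.0

    def test_ssd_additivity(self, study_table):
        table, _ = study_table
        half = table.n // 2
        relabeled = [("X" if i < half else "Y") for i in range(table.n)]
        t = table.relabel({})  # copy
        from dataclasses import replace
        profs = tuple(replace(p, population=g)
                      for p, g in zip(t.profiles, relabeled))
        t = HaplotypeTable(panel=t.panel, profiles=profs)
        res = amova_pair(t, "X", "Y")
        assert res.ssd_total == pytest.approx(res.ssd_within + res.ssd_among,
                                              abs=1e-9)

    def test_invariant_under_allele_shift_and_scale(self):
        base = {"A": [10, 12, 11], "B": [20, 21, 19]}
        t1 = make_single_locus_table(base)
        t2 = make_single_locus_table({k: [v + 7 for v in vs]
                                      for k, vs in base.items()})
        r1, r2 = amova_pair(t1, "A", "B"), amova_pair(t2, "A", "B")
        assert r1.rst == pytest.approx(r2.rst, abs=1e-12)
        t3 = make_single_locus_table({k: [3 * v for v in vs]
                                      for k, vs in base.items()})
        r3 = amova_pair(t3, "A", "B")
        assert r3.rst == pytest.approx(r1.rst, abs=1e-12)
        assert r3.ssd_total == pytest.approx(9 * r1.ssd_total)

    def test_invariant_under_individual_permutation(self):
        vals = {"A": [10, 12, 11, 13], "B": [20, 21, 19, 18]}
        r1 = amova_pair(make_single_locus_table(vals), "A", "B")
        vals_perm = {"A": [13, 10, 12, 11], "B": [19, 18, 21, 20]}
        r2 = amova_pair(make_single_locus_table(vals_perm), "A", "B")
        assert r1.rst == pytest.approx(r2.rst, abs=1e-12)


class TestRstMatrix:
    def test_single_founder_populations_near_zero(self):
        from ystr_popkit.synthetic_data import DEFAULT_FOUNDERS, LineageSpec

        cfg = SimulationConfig(
            populations=(("A", 25), ("B", 25), ("C", 25)),
            lineages=(LineageSpec("J1a", 1.0, DEFAULT_FOUNDERS["J1a"]),),
            microvariant_rules=(),
            seed=9,
        )
        t, _ = simulate_table(cfg)
        M = rst_matrix(t)
        off = M.values[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.08)

    def test_population_relabelling_permutes_matrix(self):
        t = make_single_locus_table({"A": [10, 12], "B": [20, 20],
                                     "C": [15, 16]})
        M = rst_matrix(t)
        t2 = make_single_locus_table({"C": [15, 16], "A": [10, 12],
                                      "B": [20, 20]})
        M2 = rst_matrix(t2)
        df1, df2 = M.to_dataframe(), M2.to_dataframe()
        assert df2.loc["A", "B"] == pytest.approx(df1.loc["A", "B"])
        assert df2.loc["A", "C"] == pytest.approx(df1.loc["A", "C"])

    def test_requires_two_populations(self, study_table):
        with pytest.raises(ValueError):
            rst_matrix(study_table[0])

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_distance_matrix_brute_force_agreement(study_table):
    """Vectorised matrix equals per-pair haplotype_distance on a subsample."""
    table, _ = study_table
    sub = HaplotypeTable(panel=table.panel, profiles=table.profiles[:12])
    M = squared_distance_matrix(sub)
    for i, j in itertools.combinations(range(12), 2):
        d = haplotype_distance(sub.profiles[i], sub.profiles[j], sub.panel)
        assert M.values[i, j] == pytest.approx(d, abs=1e-9)
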