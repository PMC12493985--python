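"""Neutral-model fitting and the betaNTI / RC_Bray null-model framework."""

import numpy as np
import pandas as pd
import pytest

from eutromics.assembly import (
    OccurrenceStats,
    beta_mntd,
    bnti,
    classify_processes,
    fit_neutral_model,
    ncm_fit,
    ncm_predict,
    occurrence_stats,
    rc_bray,
)
from eutromics.containers import OtuTable, ValidationError
from eutromics.simulate import (
    NeutralSimSpec,
    simulate_neutral_metacommunity,
    yule_tree,
)
from .conftest import random_table


def make_table(rows, otus=None):
    rows = np.atleast_2d(rows)
    return OtuTable(
        pd.DataFrame(
            rows,
            index=[f"s{i}" for i in range(rows.shape[0])],
            columns=otus or [f"o{j}" for j in range(rows.shape[1])],
        )
    )


class TestOccurrenceStats:
    def test_ubiquitous_taxon(self):
        table = make_table([[50, 50], [30, 70], [10, 90]])
        st = occurrence_stats(table)
        assert st.per_otu.loc["o0", "freq"] == 1.0
        assert st.n == pytest.approx(100.0)

    def test_partial_detection(self):
        table = make_table([[10, 90], [0, 100]])
        st = occurrence_stats(table, detection_limit=0.01)
        assert st.per_otu.loc["o0", "freq"] == 0.5
        assert st.per_otu.loc["o0", "p"] == pytest.approx(0.05)

    def test_absent_taxon_excluded(self):
        table = make_table([[10, 0, 5], [3, 0, 2]])
        st = occurrence_stats(table)
        assert "o1" not in st.per_otu.index


class TestNcmFit:
    @staticmethod
    def _exact_stats(m=0.1, n=1000.0, n_taxa=500, seed=0):
        rng = np.random.default_rng(seed)
        p = np.sort(rng.lognormal(-9, 2, n_taxa))
        p = p / p.sum()
        freq = ncm_predict(p, n, m)
        df = pd.DataFrame({"p": p, "freq": freq}, index=[f"o{i}" for i in range(n_taxa)])
        return OccurrenceStats(per_otu=df, n=n, detection_limit=1 / n, n_sites=50)

    def test_self_consistency_on_exact_frequencies(self):
        fit = ncm_fit(self._exact_stats())
        assert fit.m == pytest.approx(0.1, abs=1e-3)
        assert fit.r_squared > 0.999
        assert fit.converged and not fit.at_boundary

    def test_exact_frequencies_partition_within(self):
        fit = ncm_fit(self._exact_stats())
        assert (fit.per_otu["partition"] == "within").all()

    def test_predicted_freq_monotone_in_p(self):
        fit = ncm_fit(self._exact_stats())
        pred = fit.per_otu.sort_values("p")["predicted"].to_numpy()
        assert (np.diff(pred) >= -1e-12).all()

    def test_closed_loop_recovery_from_simulator(self):
        spec = NeutralSimSpec(n_sites=50, n_taxa=500, n_individuals=20000, m=0.5, seed=1)
        fit = fit_neutral_model(simulate_neutral_metacommunity(spec))
        assert fit.nm == pytest.approx(10_000, rel=0.15)

    def test_too_few_otus_rejected(self):
        table = make_table([[5, 3], [2, 6]])
        with pytest.raises(ValidationError):
            fit_neutral_model(table)


def naive_bmntd(d, comm_a, comm_b):
    """Straightforward nested-loop betaMNTD for cross-checking."""
    wa = comm_a / comm_a.sum()
    wb = comm_b / comm_b.sum()
    total = 0.0
    for i in np.flatnonzero(comm_a):
        total += 0.5 * wa[i] * min(d[i, j] for j in np.flatnonzero(comm_b))
    for j in np.flatnonzero(comm_b):
        total += 0.5 * wb[j] * min(d[i, j] for i in np.flatnonzero(comm_a))
    return total


class TestBetaMntd:
    def test_identical_communities_zero(self, two_tip_tree):
        table = make_table([[3, 7], [3, 7]], otus=["A", "B"])
        bm = beta_mntd(table, two_tip_tree)
        assert bm.iloc[0, 1] == pytest.approx(0.0)

    def test_monodominant_pair_equals_patristic_distance(self, two_tip_tree):
        table = make_table([[10, 0], [0, 10]], otus=["A", "B"])
        bm = beta_mntd(table, two_tip_tree)
        assert bm.iloc[0, 1] == pytest.approx(2.0)

    def test_matches_naive_implementation(self):
        rng = np.random.default_rng(4)
        tree = yule_tree(8, seed=2)
        tips = [t.name for t in tree.tips()]
        from eutromics.metrics import patristic_matrix

        d = patristic_matrix(tree).loc[tips, tips].to_numpy()
        for _ in range(10):
            counts = rng.integers(0, 5, size=(2, 8))
            counts[:, rng.integers(8)] += 1
            table = make_table(counts, otus=tips)
            got = beta_mntd(table, tree).iloc[0, 1]
            want = naive_bmntd(d, counts[0].astype(float), counts[1].astype(float))
            assert got == pytest.approx(want)

    def test_shared_taxon_lowers_or_preserves(self):
        rng = np.random.default_rng(9)
        tree = yule_tree(8, seed=5)
        tips = [t.name for t in tree.tips()]
        for _ in range(10):
            counts = np.zeros((2, 8), int)
            counts[0, rng.choice(8, 3, replace=False)] = rng.integers(1, 9, 3)
            counts[1, rng.choice(8, 3, replace=False)] = rng.integers(1, 9, 3)
            before = beta_mntd(make_table(counts, otus=tips), tree).iloc[0, 1]
            shared = rng.integers(8)
            counts[:, shared] += 1
            after = beta_mntd(make_table(counts, otus=tips), tree).iloc[0, 1]
            assert after <= before + 1e-9


class TestBnti:
    @staticmethod
    def _null_data(n_pairs=50, n_taxa=64, richness=12, seed=0):
        """Communities placed on tips at random: data from the shuffle null."""
        rng = np.random.default_rng(seed)
        tree = yule_tree(n_taxa, seed=seed)
        counts = np.zeros((2 * n_pairs, n_taxa), int)
        for s in range(2 * n_pairs):
            present = rng.choice(n_taxa, size=richness, replace=False)
            counts[s, present] = rng.integers(1, 100, size=richness)
        table = make_table(counts, otus=[t.name for t in tree.tips()])
        return table, tree, [(2 * i, 2 * i + 1) for i in range(n_pairs)]

    def test_calibrated_under_own_null(self):
        table, tree, pairs = self._null_data()
        z = bnti(table, tree, reps=199, seed=1, pairs=pairs)
        vals = np.array([z.iat[i, j] for i, j in pairs])
        vals = vals[~np.isnan(vals)]
        assert abs(vals.mean()) < 0.45  # 3 sigma for 50 standard-normal draws
        assert np.mean(np.abs(vals) <= 2) >= 0.85

    def test_deterministic_under_fixed_seed(self):
        table, tree, pairs = self._null_data(n_pairs=3)
        z1 = bnti(table, tree, reps=99, seed=7, pairs=pairs)
        z2 = bnti(table, tree, reps=99, seed=7, pairs=pairs)
        pd.testing.assert_frame_equal(z1, z2)
        z3 = bnti(table, tree, reps=99, seed=8, pairs=pairs)
        assert not z1.equals(z3)

    def test_symmetry_and_nan_diagonal(self):
        table, tree, _ = self._null_data(n_pairs=3)
        z = bnti(table, tree, reps=99, seed=0)
        arr = z.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.isnan(np.diag(arr)).all()


class TestRcBray:
    def test_identical_sites_give_minus_one(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 40, size=(6, 30))
        counts[:, 0] += 1
        counts[1] = counts[0]  # duplicate community: observed BC = 0
        table = make_table(counts)
        rc = rc_bray(table, reps=99, seed=0, pairs=[(0, 1)])
        assert rc.iloc[0, 1] == pytest.approx(-1.0)

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(3)
        table = random_table(rng, n_sites=5, n_otus=25)
        rc = rc_bray(table, reps=99, seed=1)
        arr = rc.to_numpy()
        iu = np.triu_indices(5, 1)
        assert np.all(np.abs(arr[iu]) <= 1.0)
        assert np.allclose(arr, arr.T, equal_nan=True)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        table = random_table(rng, n_sites=4, n_otus=20)
        pd.testing.assert_frame_equal(
            rc_bray(table, reps=49, seed=5), rc_bray(table, reps=49, seed=5)
        )

    def test_zero_reps_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValidationError):
            rc_bray(random_table(rng), reps=0)


class TestClassifyProcesses:
    @staticmethod
    def _matrices(bnti_val, rc_val):
        ids = ["a", "b"]
        b = pd.DataFrame([[np.nan, bnti_val], [bnti_val, np.nan]], index=ids, columns=ids)
        r = pd.DataFrame([[np.nan, rc_val], [rc_val, np.nan]], index=ids, columns=ids)
        return b, r

    @pytest.mark.parametrize(
        "bnti_val, rc_val, expected",
        [
            (3.0, 0.0, "variable_selection"),
            (-3.0, 0.99, "homogeneous_selection"),
            (1.0, 0.99, "dispersal_limitation"),
            (-1.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            (2.0, 0.96, "dispersal_limitation"),  # |bnti| = 2 defers to RC
        ],
    )
    def test_threshold_rules(self, bnti_val, rc_val, expected):
        res = classify_processes(*self._matrices(bnti_val, rc_val))
        assert res.pair_processes.loc[0, "process"] == expected
        assert sum(res.process_fractions.values()) == pytest.approx(1.0)

    def test_undefined_bnti_excluded_and_counted(self):
        ids = ["a", "b", "c"]
        b = pd.DataFrame(np.full((3, 3), np.nan), index=ids, columns=ids)
        b.iloc[0, 1] = b.iloc[1, 0] = 0.0
        r = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
        res = classify_processes(b, r)
        assert res.n_pairs == 1 and res.n_excluded == 2

    def test_raising_threshold_never_increases_selection(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(8)]
        vals = rng.normal(0, 2.5, size=(8, 8))
        b = pd.DataFrame((vals + vals.T) / 2, index=ids, columns=ids)
        r = pd.DataFrame(np.zeros((8, 8)), index=ids, columns=ids)
        frac2 = classify_processes(b, r, bnti_threshold=2.0).process_fractions
        frac3 = classify_processes(b, r, bnti_threshold=3.0).process_fractions
        sel2 = frac2["variable_selection"] + frac2["homogeneous_selection"]
        sel3 = frac3["variable_selection"] + frac3["homogeneous_selection"]
        assert sel3 <= sel2 + 1e-12
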