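"""Wilcoxon DE: exact enumeration oracle, filters, fold-change symmetry,
null behavior and concordance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

import synmac as sm
from synmac.diffexpr import ExclusionList
from synmac.io import NormalizedMatrix

from conftest import toy_cells


def brute_force_ranksum_p(x, y):
    """Independent oracle: enumerate every split of the pooled values."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = scipy.stats.rankdata(pooled)
    e = nx * (n + 1) / 2
    obs = abs(ranks[:nx].sum() - e)
    null = [abs(ranks[list(c)].sum() - e) for c in combinations(range(n), nx)]
    return np.mean(np.array(null) >= obs - 1e-12)


class TestWilcoxonP:
    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=rng.integers(3, 7)).astype(float)
        y = rng.integers(0, 4, size=rng.integers(3, 7)).astype(float)
        assert sm.wilcoxon_p(x, y) == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-12)

    def test_textbook_extreme_case(self):
        assert sm.wilcoxon_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets(self):
        assert sm.wilcoxon_p([1, 2, 2, 5], [1, 2, 2, 5]) == 1.0

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(10):
            x = rng.normal(size=8)
            y = rng.normal(size=9)
            ours = sm.wilcoxon_p(x, y)
            ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                           method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        diffs = []
        for _ in range(50):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            diffs.append(abs(sm.wilcoxon_p(x, y, exact=True)
                             - sm.wilcoxon_p(x, y, exact=False)))
        assert max(diffs) < 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sm.wilcoxon_p([], [1.0])


def norm_from_dense(dense, genes, cells_df):
    return NormalizedMatrix(
        np.array(genes, dtype=object),
        np.array(cells_df.index, dtype=object),
        sp.csr_matrix(np.asarray(dense, dtype=float)),
    )


class TestDETest:
    def test_min_pct_gate(self, rng):
        cells = toy_cells(["S"] * 100, ["S"] * 100)
        dense = np.zeros((2, 200))
        dense[0, :4] = 1.0   # 4% in A, 0% in B -> excluded
        dense[1, :] = rng.random(200) + 0.5
        norm = norm_from_dense(dense, ["rare", "common"], cells)
        res = sm.de_test(norm, cells, "A", "B")
        assert "rare" not in set(res["gene"])
        assert "common" in set(res["gene"])

    def test_identical_groups_flat(self):
        cells = toy_cells(["S"] * 10, ["S"] * 10)
        vals = np.linspace(0.5, 1.5, 10)
        dense = np.tile(np.concatenate([vals, vals]), (3, 1))
        norm = norm_from_dense(dense, ["a", "b", "c"], cells)
        res = sm.de_test(norm, cells, "A", "B")
        # each gene has the same values in both groups
        row = res.set_index("gene").loc["a"]
        assert row["avg_log2fc"] == 0.0 and row["p"] == 1.0 and not row["significant"]

    def test_direction_antisymmetry(self, small_norm):
        _cm, norm, cells = small_norm
        ab = sm.de_test(norm, cells, "old_F", "young_F", subpop="CD163+")
        ba = sm.de_test(norm, cells, "young_F", "old_F", subpop="CD163+")
        m = ab.merge(ba, on="gene", suffixes=("_ab", "_ba"))
        np.testing.assert_allclose(m["avg_log2fc_ab"], -m["avg_log2fc_ba"], atol=1e-10)
        np.testing.assert_allclose(m["p_ab"], m["p_ba"], atol=1e-12)

    def test_exact_path_matches_enumeration(self, rng):
        """With <= 6+6 cells the reported p equals exhaustive enumeration."""
        cells = toy_cells(["S"] * 6, ["S"] * 6)
        dense = rng.integers(0, 5, size=(8, 12)).astype(float)
        dense[:, 0] += 1  # keep pct filter satisfied
        norm = norm_from_dense(dense, [f"g{i}" for i in range(8)], cells)
        res = sm.de_test(norm, cells, "A", "B", min_pct=0.0).set_index("gene")
        for i in range(8):
            expected = brute_force_ranksum_p(dense[i, :6], dense[i, 6:])
            assert res.loc[f"g{i}", "p"] == pytest.approx(expected, abs=1e-12)

    def test_bh_adjustment_properties(self, small_norm):
        _cm, norm, cells = small_norm
        res = sm.de_test(norm, cells, "old_M", "young_M", subpop="CX3CR1+")
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        assert (res["p_adj"] <= 1.0).all()
        # p_adj non-decreasing in p rank
        srt = res.sort_values("p")
        assert (np.diff(srt["p_adj"]) >= -1e-15).all()

    def test_exclusions_applied(self, small_norm):
        _cm, norm, cells = small_norm
        res = sm.de_test(norm, cells, "old_F", "young_F", subpop="CD163+")
        assert not any(g.startswith("mt-") for g in res["gene"])

    def test_explicit_exclusion_rules(self):
        excl = ExclusionList()
        assert excl.matches("mt-Nd1") and excl.matches("Rps4x") and excl.matches("Malat1")
        assert not excl.matches("Cx3cr1")

    def test_planted_effect_recovered(self, small_norm, small_sim):
        cfg, *_ = small_sim
        _cm, norm, cells = small_norm
        res = sm.de_test(norm, cells, "old_F", "young_F", subpop="CD163+")
        planted = f"gene{cfg.de_effects[0].gene + 1:05d}"
        row = res.set_index("gene").loc[planted]
        assert row["significant"] and row["avg_log2fc"] > 0.25

    def test_null_significance_rate_controlled(self):
        cfg = sm.SimConfig(
            n_genes=800, n_cells_per_group=200, groups=("g1", "g2"),
            subpop_names=("A", "B"),
            subpop_props={"g1": np.array([0.5, 0.5]), "g2": np.array([0.5, 0.5])},
            marker_genes_per_subpop=5, pseudotime_spec=None, seed=3,
        )
        cm, cells, _ = sm.simulate_null(cfg)
        norm = sm.lognormalize(cm)
        res = sm.de_test(norm, cells, "g1", "g2", subpop="A")
        assert res["significant"].mean() <= 0.05

    def test_too_few_cells_rejected(self, small_norm):
        _cm, norm, cells = small_norm
        tiny = cells.iloc[:5]
        with pytest.raises(ValueError):
            sm.de_test(norm, tiny, "old_F", "young_F")


class TestConcordance:
    @staticmethod
    def _de(deltas, sig, fc):
        n = len(deltas)
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "pct_a": 0.5 + np.asarray(deltas) / 2,
                "pct_b": 0.5 - np.asarray(deltas) / 2,
                "avg_log2fc": fc,
                "p": 0.01,
                "p_adj": np.where(sig, 0.01, 0.5),
                "significant": sig,
            }
        )

    def test_self_correlation_is_one(self, rng):
        d = rng.normal(0, 0.1, 20)
        de = self._de(d, np.zeros(20, bool), d)
        res = sm.concordance(de, de)
        assert res["r"] == pytest.approx(1.0)

    def test_negated_deltas_give_minus_one(self, rng):
        d = rng.normal(0, 0.1, 20)
        de1 = self._de(d, np.zeros(20, bool), d)
        de2 = self._de(-d, np.zeros(20, bool), -d)
        assert sm.concordance(de1, de2)["r"] == pytest.approx(-1.0)

    def test_classification_partitions_genes(self, rng):
        d = rng.normal(0, 0.1, 30)
        sig1 = rng.random(30) < 0.4
        sig2 = rng.random(30) < 0.4
        de1 = self._de(d, sig1, d)
        de2 = self._de(d * np.where(rng.random(30) < 0.5, 1, -1), sig2, -d)
        res = sm.concordance(de1, de2)
        assert len(res["table"]) == 30
        assert res["table"]["classification"].notna().all()

    def test_planted_discordance_recovered(self):
        """Effects planted in one subpop in males and opposite in females
        yield correlations whose signs match the plant."""
        genes = list(range(100, 180))
        eff_m = [sm.DEEffect(gene=g, group="old_M", log2fc=1.5, subpop="CD163+") for g in genes]
        eff_f_con = [sm.DEEffect(gene=g, group="old_F", log2fc=1.5, subpop="CD163+") for g in genes]
        eff_f_dis = [sm.DEEffect(gene=g, group="old_F", log2fc=-1.5, subpop="MHCII+") for g in genes]
        eff_m2 = [sm.DEEffect(gene=g, group="old_M", log2fc=1.5, subpop="MHCII+") for g in genes]
        cfg = sm.SimConfig(
            # sparse regime (~1 count per gene per cell) so expressing
            # fractions respond to the planted shifts
            n_genes=600, n_cells_per_group=400, marker_genes_per_subpop=5,
            libsize_log_mean=float(np.log(600.0)), umi_floor=100,
            de_effects=eff_m + eff_f_con + eff_f_dis + eff_m2,
            pseudotime_spec=None, seed=9,
        )
        cm, cells, _ = sm.simulate_counts(cfg)
        norm = sm.lognormalize(cm)
        de_m = sm.de_test(norm, cells, "old_M", "young_M", subpop="CD163+")
        de_f = sm.de_test(norm, cells, "old_F", "young_F", subpop="CD163+")
        assert sm.concordance(de_m, de_f)["r"] > 0.2
        de_m2 = sm.de_test(norm, cells, "old_M", "young_M", subpop="MHCII+")
        de_f2 = sm.de_test(norm, cells, "old_F", "young_F", subpop="MHCII+")
        assert sm.concordance(de_m2, de_f2)["r"] < -0.2

    def test_too_few_shared_genes_rejected(self):
        de = self._de([0.1, 0.2], np.zeros(2, bool), [0.1, 0.2])
        with pytest.raises(ValueError):
            sm.concordance(de.iloc[:2], de.iloc[:1])
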