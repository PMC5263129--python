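"""Totals, rank correlations, pair census, Mann-Whitney and Holm control."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_expression
from scqpcr.simulate import GroupSpec, SimulationConfig, generate_dataset
from scqpcr.stats import (
    encode_factor,
    group_compare_mannwhitney,
    mannwhitney_p,
    pairwise_gene_correlations,
    range_ratio,
    spearman_vs_factor,
    total_transcripts,
)


def _ann(phases, sizes=None):
    sizes = sizes or ["small"] * len(phases)
    return pd.DataFrame(
        {"phase": phases, "size": sizes},
        index=pd.Index([f"c{i}" for i in range(len(phases))], name="cell_id"),
    )


class TestTotals:
    def test_row_sum_includes_imputed_values(self):
        expr = make_expression([[1.0, 2.0, 0.5]])
        assert total_transcripts(expr).iloc[0] == 3.5

    def test_all_imputed_93_gene_cell(self):
        expr = make_expression(np.full((1, 93), 0.5))
        assert total_transcripts(expr).iloc[0] == pytest.approx(46.5)

    def test_invariant_under_gene_permutation(self, rng):
        vals = rng.uniform(0.5, 100, size=(5, 10))
        expr = make_expression(vals)
        perm = rng.permutation(10)
        expr_p = make_expression(vals[:, perm])
        np.testing.assert_allclose(
            total_transcripts(expr).to_numpy(), total_transcripts(expr_p).to_numpy()
        )

    def test_additive_under_panel_concatenation(self, rng):
        a, b = rng.uniform(0.5, 50, (4, 3)), rng.uniform(0.5, 50, (4, 5))
        both = make_expression(np.hstack([a, b]))
        ta = total_transcripts(make_expression(a))
        tb = total_transcripts(make_expression(b))
        np.testing.assert_allclose(total_transcripts(both).to_numpy(),
                                   ta.to_numpy() + tb.to_numpy())


class TestSpearman:
    def test_monotone_totals_along_phase_order_give_rho_one(self):
        # one cell per phase so the encoding is tie-free
        ann = _ann(["G1", "S", "G2M"])
        totals = pd.Series([1.0, 2, 3], index=ann.index)
        rep = spearman_vs_factor(totals, ann, "phase")
        assert rep.rho == pytest.approx(1.0)

    def test_tied_encoding_with_monotone_totals_stays_high(self):
        ann = _ann(["G1", "G1", "S", "S", "G2M", "G2M"])
        totals = pd.Series([1.0, 2, 3, 4, 5, 6], index=ann.index)
        assert spearman_vs_factor(totals, ann, "phase").rho > 0.9

    def test_constant_encoding_errors(self):
        ann = _ann(["G1", "G1", "G1"])
        totals = pd.Series([1.0, 2, 3], index=ann.index)
        with pytest.raises(ValueError, match="constant"):
            spearman_vs_factor(totals, ann, "phase")

    def test_combined_encoding_order(self):
        ann = _ann(["G1", "G1", "S", "G2M"], ["small", "large", "small", "large"])
        codes = encode_factor(ann, "phase_x_size")
        assert codes.tolist() == [1.0, 2.0, 3.0, 6.0]

    def test_matches_rank_then_pearson_oracle(self, rng):
        """Spearman rho must equal Pearson correlation of midranks."""
        for _ in range(25):
            n = rng.integers(5, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.5:  # inject ties
                x = np.round(x)
            rho = sps.spearmanr(x, y).statistic
            oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert abs(rho - oracle) < 1e-12

    def test_null_rho_is_small_at_n90(self, rng):
        """Totals independent of the encoding leave |rho| below 0.2 in the
        overwhelming majority of replicates."""
        codes = np.repeat([1, 2, 3], 30)
        hits = 0
        n_reps = 1000
        for _ in range(n_reps):
            totals = rng.normal(size=90)
            rho = sps.spearmanr(totals, codes).statistic
            hits += abs(rho) < 0.2
        # under the null at n=90, sd(rho) ~ 1/sqrt(89) ~ 0.106, so |rho| < 0.2
        # holds for ~94% of draws (permutation oracle estimate)
        assert hits >= 0.92 * n_reps

    def test_phase_coupled_scaling_makes_phase_beat_size(self):
        cfg = SimulationConfig(
            n_genes=20,
            n_informative_phase=0,
            n_informative_size=0,
            phase_scale_coupling=0.5,
            cell_scale_sd=0.5,
            detection_midpoint=None,
            seed=17,
        )
        cq, ann, _ = generate_dataset(cfg)
        from scqpcr.preprocess import cq_to_molecules

        totals = total_transcripts(cq_to_molecules(cq))
        rho_phase = spearman_vs_factor(totals, ann, "phase").rho
        rho_size = spearman_vs_factor(totals, ann, "size").rho
        assert rho_phase > abs(rho_size)


class TestPairwiseCorrelations:
    def test_pair_census_for_93_genes(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 93)))
        res = pairwise_gene_correlations(m)
        assert res.n_pairs == 4278

    def test_two_genes_give_one_pair(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        assert pairwise_gene_correlations(m).n_pairs == 1

    def test_shared_cell_scaling_induces_positive_correlations(self, rng):
        scale = rng.normal(0, 2, size=60)
        m = pd.DataFrame(scale[:, None] + rng.normal(0, 0.5, size=(60, 15)))
        res = pairwise_gene_correlations(m)
        assert res.fraction_positive > 0.9

    def test_zero_variance_pairs_are_excluded_and_counted(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        m["c"] = 1.0
        res = pairwise_gene_correlations(m)
        assert res.n_pairs == 3
        assert res.n_undefined == 2  # (a,c) and (b,c)
        assert res.pairs["rho"].notna().sum() == 1


def _mw_enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        vals = np.array([1.0, 2, 3, 4, 5])
        assert mannwhitney_p(vals, vals.copy()) == pytest.approx(1.0)

    def test_fully_separated_groups_exact_p(self):
        x = np.arange(10, dtype=float)
        y = np.arange(100, 110, dtype=float)
        expected = 2 / math.comb(20, 10)
        assert mannwhitney_p(x, y) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("n1,n2", [(3, 5), (4, 4), (6, 7), (8, 8)])
    def test_matches_full_rank_enumeration(self, n1, n2, rng):
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(0.5, 1, size=n2)
            assert mannwhitney_p(x, y) == pytest.approx(_mw_enumeration_p(x, y), abs=1e-10)


class TestGroupCompare:
    def _totals(self):
        idx = [f"c{i}" for i in range(30)]
        rng = np.random.default_rng(1)
        return pd.Series(rng.uniform(10, 20, 30), index=idx), idx

    def test_identical_groups_not_significant(self):
        totals, idx = self._totals()
        groups = {"A": idx[:10], "B": idx[10:20]}
        totals.loc[idx[10:20]] = totals.loc[idx[:10]].to_numpy()
        out = group_compare_mannwhitney(totals, groups, [("A", "B")])
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert not out.loc[0, "significant"]

    def test_overlapping_groups_error(self):
        totals, idx = self._totals()
        groups = {"A": idx[:10], "B": idx[5:15]}
        with pytest.raises(ValueError, match="overlap"):
            group_compare_mannwhitney(totals, groups, [("A", "B")])

    def test_holm_adjustment_hand_computed_sequence(self, monkeypatch):
        """Raw p = (0.01, 0.02, 0.04) at alpha 0.05: Holm rejects all three
        (0.01*3=0.03, 0.02*2=0.04, 0.04*1=0.04, all <= 0.05)."""
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests([0.01, 0.02, 0.04], alpha=0.05, method="holm")
        assert reject.all()
        np.testing.assert_allclose(p_adj, [0.03, 0.04, 0.04])

    def test_holm_rejections_contain_bonferroni_rejections(self, rng):
        for _ in range(200):
            m = rng.integers(2, 8)
            p = rng.uniform(0, 0.2, size=m)
            from statsmodels.stats.multitest import multipletests

            holm = multipletests(p, alpha=0.05, method="holm")[0]
            bonf = p * m <= 0.05
            assert (holm | ~bonf).all()  # bonf implies holm


class TestRangeRatio:
    def test_example(self):
        assert range_ratio(pd.Series([10.0, 20.0, 170.0])) == pytest.approx(17.0)

    def test_constant(self):
        assert range_ratio(pd.Series([5.0, 5.0])) == pytest.approx(1.0)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            range_ratio(pd.Series([0.0, 1.0]))
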