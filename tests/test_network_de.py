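"""Aggregation, variance moderation, donor blocking, BH, and contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netexpr import (
    BlockingSpec,
    ExpressionMatrix,
    NetworkExpression,
    ValueScale,
    aggregate_to_networks,
    bh_adjust,
    estimate_consensus_correlation,
    estimate_variance_prior,
    fit_network_ovr,
    positive_de_set,
    within_between_contrast,
)


def nexpr_from_records(records, genes):
    """records: (donor, network, values-per-gene) triples."""
    frame = pd.DataFrame(
        [r[2] for r in records],
        index=pd.MultiIndex.from_tuples([(r[0], r[1]) for r in records], names=["donor", "network"]),
        columns=genes,
    )
    counts = pd.DataFrame(1, index=frame.index.get_level_values(0).unique(), columns=frame.index.get_level_values(1).unique())
    return NetworkExpression(frame, counts)


class TestAggregateToNetworks:
    def _inputs(self, values, parcels, networks):
        samples = [f"s{i}" for i in range(len(values))]
        matrix = ExpressionMatrix(
            pd.DataFrame({s: [v] for s, v in zip(samples, values)}, index=["g"]),
            ValueScale.LOG2,
        )
        assignments = pd.DataFrame(
            {"sample_id": samples, "parcel": parcels, "network": networks}
        )
        manifest = pd.DataFrame(
            {
                "sample_id": samples,
                "donor_id": ["d1"] * len(samples),
                "compartment": ["cortex"] * len(samples),
                "mni_x": 0.0,
                "mni_y": 0.0,
                "mni_z": 0.0,
            }
        )
        return matrix, assignments, manifest

    def test_two_stage_average_weights_parcels_equally(self):
        # parcel A samples {2,4}, parcel B sample {6}: network mean 4.5, not 4.0
        matrix, assignments, manifest = self._inputs(
            [2.0, 4.0, 6.0], ["A", "A", "B"], ["limbic"] * 3
        )
        nexpr = aggregate_to_networks(matrix, assignments, manifest)
        assert nexpr.values.loc[("d1", "limbic"), "g"] == pytest.approx(4.5)
        assert nexpr.parcel_counts.loc["d1", "limbic"] == 2

    def test_pass_through_one_sample_per_parcel(self):
        matrix, assignments, manifest = self._inputs(
            [1.0, 9.0], ["A", "B"], ["limbic", "visual"]
        )
        nexpr = aggregate_to_networks(matrix, assignments, manifest)
        assert nexpr.values.loc[("d1", "limbic"), "g"] == 1.0
        assert nexpr.values.loc[("d1", "visual"), "g"] == 9.0

    def test_missing_network_is_absent_not_zero(self):
        matrix, assignments, manifest = self._inputs([1.0], ["A"], ["visual"])
        nexpr = aggregate_to_networks(matrix, assignments, manifest)
        assert ("d1", "limbic") not in nexpr.values.index

    def test_long_format_round_trip(self):
        matrix, assignments, manifest = self._inputs(
            [2.0, 4.0, 6.0], ["A", "A", "B"], ["limbic", "limbic", "visual"]
        )
        nexpr = aggregate_to_networks(matrix, assignments, manifest)
        back = NetworkExpression.from_long(nexpr.to_long())
        pd.testing.assert_frame_equal(back.values, nexpr.values)


class TestVariancePrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = estimate_variance_prior([0.7] * 10, 4)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.7)

    def test_simulation_recovery(self):
        # generative model: sigma_g^2 ~ s0^2 * d0 / chi2_{d0}, s_g^2 ~ sigma_g^2 chi2_d / d
        rng = np.random.default_rng(42)
        d0_true, s0_true, d_resid, n_genes = 4.0, 1.0, 10, 2000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=n_genes)
        s2 = sigma2 * rng.chisquare(d_resid, size=n_genes) / d_resid
        prior = estimate_variance_prior(s2, d_resid)
        assert prior.d0 == pytest.approx(d0_true, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_single_gene_is_error(self):
        with pytest.raises(ValueError, match="2 genes"):
            estimate_variance_prior([0.5], 4)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            estimate_variance_prior([0.0, 0.0], 4)


class TestFitNetworkOvr:
    def _toy(self, rng=None, n_genes=5, effect=0.0):
        rng = rng or np.random.default_rng(0)
        records = []
        for d in ["d1", "d2", "d3", "d4"]:
            for net in ["limbic", "visual"]:
                vals = rng.normal(0, 1, n_genes)
                if net == "limbic":
                    vals = vals + effect
                records.append((d, net, vals))
        return nexpr_from_records(records, [f"g{i}" for i in range(n_genes)])

    def test_flat_gene_gives_zero_stats(self):
        records = [
            (d, net, [1.5]) for d in ["d1", "d2"] for net in ["limbic", "visual", "default"]
        ]
        nexpr = nexpr_from_records(records, ["g0"])
        res = fit_network_ovr(nexpr, "limbic", BlockingSpec(mode="none"), d0=0)
        assert res.loc[0, "log2FC"] == pytest.approx(0.0)
        assert res.loc[0, "t"] == pytest.approx(0.0)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_unmoderated_matches_ols_oracle(self):
        nexpr = self._toy(np.random.default_rng(5), n_genes=8, effect=0.6)
        res = fit_network_ovr(nexpr, "limbic", BlockingSpec(mode="none"), d0=0)
        indicator = (
            nexpr.values.index.get_level_values("network") == "limbic"
        ).astype(float)
        X = np.column_stack([np.ones(len(indicator)), indicator])
        for i, gene in enumerate(nexpr.genes):
            y = nexpr.values[gene].to_numpy()
            beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
            df = len(y) - 2
            s2 = float(res_ss[0]) / df
            v = np.linalg.inv(X.T @ X)[1, 1]
            t_oracle = beta[1] / np.sqrt(s2 * v)
            assert res.loc[i, "t"] == pytest.approx(t_oracle)
            assert res.loc[i, "log2FC"] == pytest.approx(beta[1])
            assert res.loc[i, "df"] == pytest.approx(df)

    def test_infinite_d0_pools_all_variances(self):
        nexpr = self._toy(np.random.default_rng(6), n_genes=6)
        res = fit_network_ovr(nexpr, "limbic", BlockingSpec(mode="none"), d0=np.inf)
        res0 = fit_network_ovr(nexpr, "limbic", BlockingSpec(mode="none"), d0=0)
        # t / log2FC ratio is constant across genes iff the variance is pooled
        ratio = res["t"] / res["log2FC"]
        assert np.allclose(ratio, ratio.iloc[0])
        assert not np.allclose(res0["t"] / res0["log2FC"], (res0["t"] / res0["log2FC"]).iloc[0])

    def test_label_swap_negates_effects(self):
        nexpr = self._toy(np.random.default_rng(7), effect=0.5)
        res_a = fit_network_ovr(nexpr, "limbic", BlockingSpec(mode="none"))
        res_b = fit_network_ovr(nexpr, "visual", BlockingSpec(mode="none"))
        np.testing.assert_allclose(res_a["log2FC"], -res_b["log2FC"])
        np.testing.assert_allclose(res_a["t"], -res_b["t"], rtol=1e-10)
        np.testing.assert_allclose(res_a["p"], res_b["p"], rtol=1e-10)

    def test_sign_consistency_invariant(self):
        nexpr = self._toy(np.random.default_rng(8), n_genes=20, effect=0.3)
        res = fit_network_ovr(nexpr, "limbic")
        ok = res["log2FC"].notna() & (res["log2FC"] != 0)
        assert (np.sign(res.loc[ok, "log2FC"]) == np.sign(res.loc[ok, "t"])).all()
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_missing_target_network_is_error(self):
        nexpr = self._toy()
        with pytest.raises(ValueError, match="absent"):
            fit_network_ovr(nexpr, "nonexistent")

    def test_covariates_adjust_fit(self):
        rng = np.random.default_rng(9)
        donors = ["d1", "d2", "d3", "d4", "d5", "d6"]
        age = pd.DataFrame({"age": [20, 30, 40, 50, 60, 70]}, index=donors)
        records = []
        for i, d in enumerate(donors):
            for net in ["limbic", "visual"]:
                base = 0.05 * age.loc[d, "age"] + rng.normal(0, 0.1, 4)
                records.append((d, net, base))
        nexpr = nexpr_from_records(records, list("abcd"))
        res = fit_network_ovr(
            nexpr, "limbic", BlockingSpec(mode="none"), covariates=age, d0=0
        )
        assert np.abs(res["log2FC"]).max() < 0.2  # age effect absorbed, no network effect

    def test_collinear_covariates_rejected(self):
        nexpr = self._toy()
        donors = nexpr.donors
        cov = pd.DataFrame({"c1": [1.0] * 4}, index=donors)  # duplicates intercept
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_network_ovr(nexpr, "limbic", BlockingSpec(mode="none"), covariates=cov, d0=0)


class TestConsensusCorrelation:
    def _simulate(self, donor_sd, resid_sd, n_donors=6, n_obs_per=5, n_genes=500, seed=0):
        rng = np.random.default_rng(seed)
        donors = np.repeat([f"d{i}" for i in range(n_donors)], n_obs_per)
        donor_fx = rng.normal(0, donor_sd, size=(n_donors, n_genes))
        Y = np.repeat(donor_fx, n_obs_per, axis=0) + rng.normal(
            0, resid_sd, size=(n_donors * n_obs_per, n_genes)
        )
        return Y, donors

    def test_recovers_planted_intra_donor_correlation(self):
        # donor and residual variances 1:1 -> intraclass correlation 0.5
        Y, donors = self._simulate(1.0, 1.0, seed=21)
        rho = estimate_consensus_correlation(Y, donors)
        assert rho == pytest.approx(0.5, abs=0.1)

    def test_null_donor_effect_gives_near_zero(self):
        Y, donors = self._simulate(0.0, 1.0, seed=22)
        rho = estimate_consensus_correlation(Y, donors)
        assert abs(rho) < 0.05

    def test_duplicate_observations_cap(self):
        rng = np.random.default_rng(23)
        base = rng.normal(size=(3, 50))
        Y = np.repeat(base, 2, axis=0)  # identical duplicates per donor
        donors = np.repeat(["d1", "d2", "d3"], 2)
        rho = estimate_consensus_correlation(Y, donors)
        assert rho == pytest.approx(0.99, abs=1e-6)

    def test_single_donor_is_error(self):
        with pytest.raises(ValueError, match="2 donors"):
            estimate_consensus_correlation(np.zeros((3, 5)), ["d1"] * 3)

    def test_blocking_improves_power_under_donor_effects(self):
        # same data, consensus blocking should not be wildly different from none
        rng = np.random.default_rng(24)
        records = []
        for i, d in enumerate([f"d{j}" for j in range(6)]):
            u = rng.normal(0, 0.5, 30)
            for net in ["limbic", "visual", "default"]:
                vals = u + rng.normal(0, 0.3, 30)
                if net == "limbic":
                    vals = vals + 1.0
                records.append((d, net, vals))
        nexpr = nexpr_from_records(records, [f"g{i}" for i in range(30)])
        res_cons = fit_network_ovr(nexpr, "limbic", BlockingSpec(mode="consensus_correlation"))
        res_none = fit_network_ovr(nexpr, "limbic", BlockingSpec(mode="none"))
        assert res_cons["t"].median() > res_none["t"].median()


class TestBHAdjust:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.01]), [0.01])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_oracle_and_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        q = bh_adjust(p)
        # O(m^2) oracle: q_i = min over j with p_j >= p_i of p_j * m / rank_j
        m = len(p)
        order = np.argsort(p)
        oracle = np.empty(m)
        for i in range(m):
            candidates = [
                min(p[order[j]] * m / (j + 1), 1.0) for j in range(m) if p[order[j]] >= p[i] - 1e-15
            ]
            oracle[i] = min(candidates)
        np.testing.assert_allclose(q, oracle, atol=1e-12)
        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)
        assert (q >= p - 1e-15).all()


class TestPositiveDESet:
    def _table(self, genes, log2fc, q):
        return pd.DataFrame({"gene": genes, "log2FC": log2fc, "q": q})

    def test_boundary_q_included(self):
        t = self._table(["a", "b"], [1.0, 1.0], [0.01, 0.0101])
        assert positive_de_set(t) == {"a"}

    def test_negative_fc_excluded(self):
        t = self._table(["a"], [-2.0], [1e-10])
        assert positive_de_set(t) == set()

    def test_set_semantics(self):
        t = self._table(["a", "a"], [1.0, 1.0], [0.001, 0.001])
        assert positive_de_set(t) == {"a"}


class TestWithinBetweenContrast:
    def _nexpr(self, within_vals, between_vals, networks=("visual", "default")):
        records = []
        for i, (w, b) in enumerate(zip(within_vals, between_vals)):
            donor = f"d{i}"
            records.append((donor, "limbic", [w]))
            for net in networks:
                records.append((donor, net, [b]))
        return nexpr_from_records(records, ["g"])

    def test_no_difference_gives_zero_F(self):
        nexpr = self._nexpr([0.2] * 4, [0.2] * 4)
        res = within_between_contrast(nexpr, {"g"}, "limbic")
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_paired_t_oracle(self):
        diffs = [0.1, 0.2, 0.05, 0.15, 0.1, 0.12]
        nexpr = self._nexpr([d + 0.5 for d in diffs], [0.5] * 6)
        res = within_between_contrast(nexpr, {"g"}, "limbic")
        t_oracle = stats.ttest_rel([d + 0.5 for d in diffs], [0.5] * 6)
        assert res.F == pytest.approx(t_oracle.statistic**2)
        assert res.p == pytest.approx(t_oracle.pvalue)
        assert res.df == (1, 5)

    def test_sign_flip_leaves_F_unchanged(self):
        diffs = [0.1, 0.2, 0.05, 0.15]
        up = self._nexpr([d for d in diffs], [0.0] * 4)
        down = self._nexpr([-d for d in diffs], [0.0] * 4)
        res_up = within_between_contrast(up, {"g"}, "limbic")
        res_down = within_between_contrast(down, {"g"}, "limbic")
        assert res_up.F == pytest.approx(res_down.F)

    def test_empty_gene_set_is_error(self):
        nexpr = self._nexpr([0.1], [0.0])
        with pytest.raises(ValueError, match="empty|disjoint"):
            within_between_contrast(nexpr, {"missing"}, "limbic")
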