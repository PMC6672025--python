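"""Subclone model: topology enumeration, expected VAFs, coordinate
ascent, BIC selection, post-hoc placement."""

import numpy as np
import pandas as pd
import pytest

from clonaltrace import subclone_inference as si
from clonaltrace import synthetic_tumor as st
from clonaltrace.errors import ConfigurationError
from clonaltrace.variant_matrix import (CohortVariantMatrix, SomaticVariant,
                                        build_presence_sets)


def _matrix_from_vafs(exp_vaf: pd.DataFrame, depth: int = 200):
    """Noise-free counts: alt = round(depth * expected VAF)."""
    samples = ["normal"] + list(exp_vaf.columns)
    variants = [SomaticVariant("1", 100 + i, "A", "T") for i in range(len(exp_vaf))]
    alt = np.zeros((len(exp_vaf), len(samples)), dtype=np.int64)
    alt[:, 1:] = np.round(depth * exp_vaf.to_numpy()).astype(np.int64)
    ref = np.full_like(alt, depth) - alt
    m = CohortVariantMatrix(variants=variants, samples=samples,
                            normal_sample="normal", alt_counts=alt,
                            ref_counts=ref, variant_ids=list(exp_vaf.index))
    build_presence_sets(m)
    return m


class TestEnumerateTopologies:
    @pytest.mark.parametrize("K,count", [(1, 1), (2, 3), (3, 16), (4, 125)])
    def test_cayley_counts(self, K, count):
        tops = si.enumerate_topologies(K)
        assert len(tops) == count == (K + 1) ** (K - 1)
        assert len({tuple(sorted(t.items())) for t in tops}) == count

    def test_dedup_counts_unlabeled_shapes(self):
        assert [len(si.enumerate_topologies(K, dedup=True)) for K in range(1, 6)] \
            == [1, 2, 4, 9, 20]

    def test_exhaustive_refused_beyond_five(self):
        with pytest.raises(ValueError, match="sampling"):
            si.enumerate_topologies(6)
        assert len(si.enumerate_topologies(6, sample=10, seed=1)) == 10


class TestExpectedVaf:
    def _tree(self):
        parents = {"clone1": "normal", "clone2": "clone1"}
        P = pd.DataFrame({"s1": [0.4, 0.35, 0.25]},
                         index=["normal", "clone1", "clone2"])
        return si.CloneTree(K=2, parents=parents,
                            assignments={"m1": "clone1", "m2": "clone2"}, P=P)

    def test_diploid_carrier_sum(self):
        tree = self._tree()
        m = _matrix_from_vafs(pd.DataFrame({"s1": [0.3, 0.125]}, index=["m1", "m2"]))
        # carriers of clone1 edge: clone1 + clone2 = 0.6 -> VAF 0.30
        assert si.expected_vaf(tree, None, 0, "s1", m) == pytest.approx(0.30)
        assert si.expected_vaf(tree, None, 1, "s1", m) == pytest.approx(0.125)

    def test_absent_carriers_clamped(self):
        tree = self._tree()
        tree.P.loc[:, "s1"] = [1.0, 0.0, 0.0]
        m = _matrix_from_vafs(pd.DataFrame({"s1": [0.0, 0.0]}, index=["m1", "m2"]))
        assert si.expected_vaf(tree, None, 0, "s1", m) == pytest.approx(1e-6)

    def test_cnv_segment_uses_bulk_total(self):
        from clonaltrace import cnv_segments as cs
        tree = self._tree()
        m = _matrix_from_vafs(pd.DataFrame({"s1": [0.2, 0.1]}, index=["m1", "m2"]))
        seg = cs.CnvSegment(chrom="1", start=90, end=105, major={"s1": 2.0},
                            minor={"s1": 1.0}, se_major={"s1": .05}, se_minor={"s1": .05})
        bundle = cs.build_bundle([seg], m, rdep={"s1": 1.0}, samples=["s1"])
        # carriers 0.6 over total CN 3 -> 0.2
        assert si.expected_vaf(tree, bundle, 0, "s1", m) == pytest.approx(0.2)

    def test_unassigned_mutation_is_contract_violation(self):
        from clonaltrace.errors import ContractViolation
        tree = self._tree()
        tree.assignments.pop("m2")
        m = _matrix_from_vafs(pd.DataFrame({"s1": [0.3, 0.1]}, index=["m1", "m2"]))
        with pytest.raises(ContractViolation):
            si.expected_vaf(tree, None, 1, "s1", m)


class TestFit:
    def test_single_clone_single_sample_closed_form(self):
        # alt/depth = 60/200 -> VAF 0.3 -> clone fraction 0.6
        variants = [SomaticVariant("1", 100, "A", "T")]
        m = CohortVariantMatrix(variants=variants, samples=["normal", "s1"],
                                normal_sample="normal",
                                alt_counts=np.array([[0, 60]]),
                                ref_counts=np.array([[200, 140]]))
        build_presence_sets(m)
        fit = si.fit_clone_fractions({"clone1": "normal"}, m, None,
                                     si.FitConfig(restarts=3, seed=1))
        assert fit.P.loc["clone1", "s1"] == pytest.approx(0.6, abs=1e-3)
        assert fit.P.loc["normal", "s1"] == pytest.approx(0.4, abs=1e-3)

    def test_sample_permutation_equivariance(self, small_cohort):
        truth, matrix = small_cohort
        cfg = si.FitConfig(restarts=4, seed=3)
        fit = si.fit_clone_fractions(truth.parents, matrix, None, cfg)
        perm = list(reversed(matrix.samples))
        permuted = CohortVariantMatrix(
            variants=matrix.variants, samples=perm,
            normal_sample=matrix.normal_sample,
            alt_counts=matrix.alt_counts[:, ::-1].copy(),
            ref_counts=matrix.ref_counts[:, ::-1].copy(),
            variant_ids=matrix.variant_ids)
        build_presence_sets(permuted)
        fit_p = si.fit_clone_fractions(truth.parents, permuted, None, cfg)
        a = fit.P[sorted(fit.P.columns)]
        b = fit_p.P[sorted(fit_p.P.columns)]
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=5e-3)

    def test_likelihood_trace_monotone(self, small_cohort):
        truth, matrix = small_cohort
        fit = si.fit_clone_fractions(truth.parents, matrix, None,
                                     si.FitConfig(restarts=2, seed=0))
        trace = np.array(fit.ll_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_true_topology_recovers_fractions(self, small_cohort):
        truth, matrix = small_cohort
        fit = si.fit_clone_fractions(truth.parents, matrix, None,
                                     si.FitConfig(restarts=8, seed=2))
        rmse = si.fraction_rmse(truth.fractions, truth.parents, fit)
        assert rmse <= 0.05

    def test_true_topology_not_beaten_by_wrong_topologies(self, small_cohort):
        # likelihood of the best fit under the true shape dominates other shapes
        truth, matrix = small_cohort
        cfg = si.FitConfig(restarts=6, seed=4)
        ll_true = si.fit_clone_fractions(truth.parents, matrix, None, cfg).log_likelihood
        true_shape = si._shape_hash(truth.parents)
        for parents in si.enumerate_topologies(truth.K, dedup=True):
            if si._shape_hash(parents) == true_shape:
                continue
            ll = si.fit_clone_fractions(parents, matrix, None, cfg).log_likelihood
            assert ll <= ll_true + 1e-6

    def test_normal_row_absorbs_remainder(self, small_cohort):
        truth, matrix = small_cohort
        fit = si.fit_clone_fractions(truth.parents, matrix, None,
                                     si.FitConfig(restarts=2, seed=0))
        cols = fit.P.sum(axis=0)
        assert np.allclose(cols, 1.0, atol=1e-9)
        assert np.allclose(fit.P.loc["normal"],
                           1.0 - fit.P.drop(index="normal").sum(axis=0), atol=1e-9)


class TestSelectModel:
    def _fit(self, K, bic):
        P = pd.DataFrame({"s1": [1.0] + [0.0] * K},
                         index=["normal"] + [f"clone{i+1}" for i in range(K)])
        return si.CloneTree(K=K, parents={f"clone{i+1}": "normal" for i in range(K)},
                            assignments={}, P=P, bic=bic, log_likelihood=bic)

    def test_elbow_selects_before_marginal_step(self):
        fits = {1: self._fit(1, 0.0), 2: self._fit(2, 100.0),
                3: self._fit(3, 200.0), 4: self._fit(4, 202.0)}
        cfg = si.FitConfig(elbow_fraction=0.05)
        assert si.select_model(fits, cfg).K == 3

    def test_equal_likelihoods_smallest_k_wins(self):
        # BIC strictly decreases with K at equal likelihood
        fits = {k: self._fit(k, -10.0 * k) for k in (1, 2, 3)}
        assert si.select_model(fits).K == 1

    def test_no_elbow_takes_bic_max(self):
        fits = {1: self._fit(1, 0.0), 2: self._fit(2, 50.0), 3: self._fit(3, 100.0)}
        assert si.select_model(fits).K == 3

    def test_single_fit_returned_as_is(self):
        f = self._fit(2, 1.0)
        assert si.select_model({2: f}) is f

    def test_bic_penalty_increases_with_k(self, small_cohort):
        truth, matrix = small_cohort
        cfg = si.FitConfig(restarts=2, seed=0)
        fits = {K: si.fit_best_topology(K, matrix, None, cfg) for K in (1, 2)}
        for K, f in fits.items():
            penalty = f.log_likelihood - f.bic
            assert penalty == pytest.approx(
                0.5 * K * len(matrix.tumor_samples)
                * np.log(f.n_modeled * len(matrix.tumor_samples)))

    def test_truncal_only_cohort_selects_one_clone(self):
        truth = st.simulate_clone_tree(1, 40, seed=6)
        st.simulate_clone_fractions(truth, 6, concentration=3.0, seed=7)
        matrix = st.simulate_read_counts(truth, depth_mean=250, seed=8)
        cfg = si.FitConfig(K_range=(1, 3), restarts=4, seed=9)
        selected, _ = si.fit_and_select(matrix, None, cfg)
        assert selected.K == 1


class TestPosthoc:
    def _fitted_tree(self):
        parents = {"clone1": "normal", "clone2": "clone1",
                   "clone3": "clone1", "clone4": "clone1"}
        P = pd.DataFrame(
            {"s1": [0.10, 0.20, 0.30, 0.25, 0.15],
             "s2": [0.20, 0.10, 0.40, 0.10, 0.20],
             "s3": [0.15, 0.25, 0.20, 0.30, 0.10]},
            index=["normal", "clone1", "clone2", "clone3", "clone4"])
        return si.CloneTree(K=4, parents=parents, assignments={}, P=P)

    def test_private_profile_assigned_to_private_edge(self):
        tree = self._fitted_tree()
        exp = 0.5 * tree.P.loc[["clone2"]].sum(axis=0)
        m = _matrix_from_vafs(pd.DataFrame([exp], index=["r1"]))
        out = si.posthoc_assign(tree, m, ["r1"])
        assert out.loc[0, "edge"] == "clone2"
        assert out.loc[0, "margin"] > 0

    def test_sibling_pair_profile_goes_to_hypothetical_ancestor(self):
        # observed only where clones 3 and 4 are, in their summed proportion
        tree = self._fitted_tree()
        exp = 0.5 * tree.P.loc[["clone3", "clone4"]].sum(axis=0)
        m = _matrix_from_vafs(pd.DataFrame([exp], index=["r1"]))
        out = si.posthoc_assign(tree, m, ["r1"])
        assert out.loc[0, "edge"] == "ancestor(clone3+clone4)"
        assert out.loc[0, "margin"] > 0

    def test_zero_depth_everywhere_unassigned(self):
        tree = self._fitted_tree()
        variants = [SomaticVariant("1", 100, "A", "T")]
        m = CohortVariantMatrix(variants=variants,
                                samples=["normal", "s1", "s2", "s3"],
                                normal_sample="normal",
                                alt_counts=np.zeros((1, 4), dtype=np.int64),
                                ref_counts=np.zeros((1, 4), dtype=np.int64),
                                variant_ids=["r1"])
        build_presence_sets(m)
        out = si.posthoc_assign(tree, m, ["r1"])
        assert out.loc[0, "edge"] is None


class TestPrevalence:
    def test_columns_sum_to_hundred_and_round_trip(self, tmp_path, small_cohort):
        import json
        truth, matrix = small_cohort
        fit = si.fit_clone_fractions(truth.parents, matrix, None,
                                     si.FitConfig(restarts=2, seed=0))
        table = si.prevalence_report(fit)
        assert np.allclose(table.loc["total"], 100.0, atol=0.01)
        tsv, js = si.write_prevalence(fit, tmp_path / "comp")
        loaded = json.loads(js.read_text())
        for s in fit.P.columns:
            assert sum(loaded[s].values()) == pytest.approx(100.0, abs=0.01)

    def test_preset_autopsy_only_clone_zero_in_biopsies(self, preset_cohort):
        truth, matrix = preset_cohort
        fit = si.CloneTree(K=4, parents=dict(truth.parents), assignments={},
                           P=truth.fractions)
        table = si.prevalence_report(fit)
        assert table.loc["clone4", "pretreatment"] == 0.0
        assert table.loc["clone4", "postprogression"] == 0.0
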