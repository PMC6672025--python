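"""Generator contracts: topology distribution, simplex fractions,
read-count model, fixture round-trips."""

import json

import numpy as np
import pytest

from clonaltrace import synthetic_tumor as st
from clonaltrace.errors import ConfigurationError


class TestCloneTree:
    def test_single_clone_single_edge_all_mutations(self):
        truth = st.simulate_clone_tree(1, 10, seed=3)
        assert truth.parents == {"clone1": "normal"}
        assert truth.branch_mutations["clone1"] == [f"m{i:04d}" for i in range(1, 11)]

    def test_two_clones_hit_exactly_three_labeled_topologies(self):
        # Cayley: (K+1)^(K-1) = 3 rooted labeled trees for K=2
        seen = {tuple(sorted(st.simulate_clone_tree(2, 4, seed=s).parents.items()))
                for s in range(300)}
        assert len(seen) == 3

    def test_seeded_determinism(self):
        a = st.simulate_clone_tree(4, 40, seed=9)
        b = st.simulate_clone_tree(4, 40, seed=9)
        assert a.parents == b.parents
        assert a.branch_mutations == b.branch_mutations
        assert a.topology_hash() == b.topology_hash()

    @pytest.mark.parametrize("K,n", [(0, 5), (3, 2)])
    def test_invalid_arguments(self, K, n):
        with pytest.raises(ValueError):
            st.simulate_clone_tree(K, n, seed=0)

    def test_every_edge_receives_a_mutation(self):
        for seed in range(20):
            truth = st.simulate_clone_tree(5, 7, seed=seed)
            assert all(len(m) >= 1 for m in truth.branch_mutations.values())
            assert sum(len(m) for m in truth.branch_mutations.values()) == 7

    def test_truncal_reservation_with_single_basal_edge(self):
        truth = st.simulate_clone_tree(4, 100, seed=1, n_truncal=7, require_truncal=True)
        basal = [c for c, p in truth.parents.items() if p == "normal"]
        assert len(basal) == 1
        assert len(truth.branch_mutations[basal[0]]) >= 7


class TestCloneFractions:
    def test_compositions_sum_to_one(self, rng):
        truth = st.simulate_clone_tree(3, 6, seed=2)
        f = st.simulate_clone_fractions(truth, 5, concentration=1.5, seed=4)
        assert np.allclose(f.sum(axis=0), 1.0, atol=1e-12)
        assert ((f >= 0) & (f <= 1)).all().all()

    def test_figure3c_structural_zeros(self):
        truth = st.figure3c_truth()
        f = st.simulate_clone_fractions(truth, 11, concentration=100, seed=1,
                                        preset="figure3c")
        # autopsy-only clone absent from both biopsies
        assert f.loc["clone4", "pretreatment"] == 0.0
        assert f.loc["clone4", "postprogression"] == 0.0
        assert f.loc["clone4", "liver_1"] == 0.0
        # resistance clone private to liver_1 + postprogression
        present = f.loc["clone1"] > 0
        assert set(f.columns[present]) == {"liver_1", "postprogression"}

    def test_large_concentration_approaches_equal_shares(self):
        truth = st.simulate_clone_tree(3, 6, seed=2)
        draws = [st.simulate_clone_fractions(truth, 1, concentration=1e5, seed=s)
                 .iloc[:, 0].to_numpy() for s in range(1000)]
        mean = np.mean(draws, axis=0)
        assert np.abs(mean - 0.25).max() < 0.02  # Dirichlet mean = 1/(K+1)

    def test_invalid_concentration(self):
        truth = st.simulate_clone_tree(2, 4, seed=0)
        with pytest.raises(ValueError):
            st.simulate_clone_fractions(truth, 3, concentration=0.0, seed=0)


class TestReadCounts:
    def test_truncal_expected_vaf_is_half_tumor_fraction(self):
        # total clone fraction 0.6, diploid -> expected VAF 0.30
        truth = st.simulate_clone_tree(1, 3, seed=0)
        import pandas as pd
        truth.fractions = pd.DataFrame({"s1": [0.4, 0.6]}, index=["normal", "clone1"])
        matrix = st.simulate_read_counts(truth, depth_mean=200, seed=1)
        assert np.allclose(matrix.expected_vaf[:, 1], 0.30)
        assert np.all(matrix.expected_vaf[:, 0] == 0.0)  # normal sample

    def test_absent_clone_mutation_has_zero_alt(self):
        import pandas as pd
        truth = st.SimulationTruth(
            parents={"clone1": "normal", "clone2": "clone1"},
            branch_mutations={"clone1": ["m1", "m2"], "clone2": ["m3", "m4"]})
        truth.fractions = pd.DataFrame({"s1": [0.3, 0.7, 0.0]},
                                       index=["normal", "clone1", "clone2"])
        matrix = st.simulate_read_counts(truth, depth_mean=300, seed=2)
        idx = [matrix.variant_ids.index(m) for m in ("m3", "m4")]
        assert matrix.alt_counts[idx, 1].sum() == 0
        assert np.all(matrix.expected_vaf[idx, 1] == 0.0)

    def test_mean_observed_vaf_matches_expectation(self):
        # law of large numbers at depth 250 over 500 truncal sites
        truth = st.simulate_clone_tree(1, 500, seed=7)
        import pandas as pd
        truth.fractions = pd.DataFrame({"s1": [0.2, 0.8]}, index=["normal", "clone1"])
        matrix = st.simulate_read_counts(truth, depth_mean=250, seed=8)
        vaf = matrix.alt_counts[:, 1] / matrix.depth[:, 1]
        assert abs(vaf.mean() - 0.40) < 0.01

    def test_alt_never_exceeds_depth_and_seeds_reproduce(self, preset_cohort):
        truth, matrix = preset_cohort
        assert np.all(matrix.alt_counts <= matrix.depth)
        _, again = st.simulate_figure3c_cohort(seed=5, depth_mean=231.0)
        assert np.array_equal(matrix.alt_counts, again.alt_counts)
        assert np.array_equal(matrix.ref_counts, again.ref_counts)

    def test_expected_vaf_monotone_along_lineage(self, preset_cohort):
        # an edge's expected VAF dominates any descendant edge's in every sample
        truth, matrix = preset_cohort
        ev = st.expected_vaf_matrix(truth)
        edge_first = {e: muts[0] for e, muts in truth.branch_mutations.items()}
        for child, parent in truth.parents.items():
            if parent == "normal":
                continue
            up = ev.loc[edge_first[parent]]
            down = ev.loc[edge_first[child]]
            assert (up >= down - 1e-12).all()

    def test_invalid_depth(self):
        truth = st.simulate_clone_tree(1, 2, seed=0)
        import pandas as pd
        truth.fractions = pd.DataFrame({"s": [0.5, 0.5]}, index=["normal", "clone1"])
        with pytest.raises(ValueError):
            st.simulate_read_counts(truth, depth_mean=0, seed=0)


class TestFixture:
    def test_vcf_round_trip_is_lossless(self, tmp_path, small_cohort):
        from clonaltrace import variant_matrix as vm

        truth, matrix = small_cohort
        paths = st.write_fixture(truth, matrix, tmp_path)
        back = vm.read_cohort(paths["vcf"], paths["manifest"])
        assert back.samples == matrix.samples
        assert [v.key for v in back.variants] == [v.key for v in matrix.variants]
        assert np.array_equal(back.alt_counts, matrix.alt_counts)
        assert np.array_equal(back.ref_counts, matrix.ref_counts)

    def test_truth_json_round_trip(self, tmp_path, small_cohort):
        truth, matrix = small_cohort
        paths = st.write_fixture(truth, matrix, tmp_path)
        loaded = st.SimulationTruth.from_json(paths["truth"].read_text())
        assert loaded.topology_hash() == truth.topology_hash()
        assert json.loads(paths["truth"].read_text())["schema_version"] == "1.0"

    def test_empty_cohort_refused_without_partial_files(self, tmp_path):
        from clonaltrace.variant_matrix import CohortVariantMatrix

        truth = st.simulate_clone_tree(1, 2, seed=0)
        empty = CohortVariantMatrix(
            variants=[], samples=["normal", "t"], normal_sample="normal",
            alt_counts=np.zeros((0, 2), dtype=int), ref_counts=np.zeros((0, 2), dtype=int))
        target = tmp_path / "out"
        with pytest.raises(ValueError):
            st.write_fixture(truth, empty, target)
        assert not (target / "cohort.vcf").exists()


class TestTruthValidation:
    def test_cycle_detected(self):
        bad = st.SimulationTruth(parents={"clone1": "clone2", "clone2": "clone1"},
                                 branch_mutations={"clone1": ["m1"], "clone2": ["m2"]})
        with pytest.raises(ConfigurationError):
            bad.validate()

    def test_mutation_on_two_edges_detected(self):
        bad = st.SimulationTruth(parents={"clone1": "normal", "clone2": "clone1"},
                                 branch_mutations={"clone1": ["m1"], "clone2": ["m1"]})
        with pytest.raises(ConfigurationError):
            bad.validate()
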