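import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ember import chem_io
from ember.chem_io import ActivityParameter, ActivityRecord, Molecule
from ember.curation import (ActivityLabel, ActivityThresholds, PropertyFilterSpec,
                            assemble_dataset, dissimilarity_select,
                            elbow_threshold, label_activity, property_filter,
                            tanimoto, wcss_1d)
from ember.synthdata import make_bimodal_activities


def rec(target, parameter, value_um):
    return ActivityRecord(target=target, parameter=parameter, value_um=value_um)


class TestLabelActivity:
    @pytest.mark.parametrize("value_um,expected", [
        (0.002, ActivityLabel.ACTIVE),       # 2 nM, strongly active
        (50.0, ActivityLabel.INACTIVE),
        (5.0, ActivityLabel.AMBIGUOUS),
        (1.0, ActivityLabel.AMBIGUOUS),      # boundary values are ambiguous
        (10.0, ActivityLabel.AMBIGUOUS),
    ])
    def test_ic50_thresholds(self, value_um, expected):
        labels = label_activity([rec("CDK1", ActivityParameter.IC50, value_um)])
        assert labels["CDK1"] is expected

    @pytest.mark.parametrize("value_um,expected", [
        (7.5, ActivityLabel.INACTIVE),
        (7.0, ActivityLabel.ACTIVE),         # threshold itself counts as active
        (0.5, ActivityLabel.ACTIVE),
    ])
    def test_kd_single_threshold(self, value_um, expected):
        labels = label_activity([rec("ACK", ActivityParameter.KD, value_um)])
        assert labels["ACK"] is expected

    def test_parameter_precedence_ic50_over_kd(self):
        records = [rec("T", ActivityParameter.KD, 50.0),
                   rec("T", ActivityParameter.IC50, 0.01)]
        assert label_activity(records)["T"] is ActivityLabel.ACTIVE

    def test_conflicting_records_combined_by_geometric_mean(self):
        # geometric mean of 0.1 and 10 is 1.0 -> ambiguous
        records = [rec("T", ActivityParameter.IC50, 0.1),
                   rec("T", ActivityParameter.IC50, 10.0)]
        assert label_activity(records)["T"] is ActivityLabel.AMBIGUOUS

    def test_unqueried_target_absent(self):
        assert label_activity([rec("A", ActivityParameter.IC50, 0.5)]).keys() == {"A"}

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ActivityThresholds(ic50_ki_active_below=10, ic50_ki_inactive_above=1)


def brute_force_two_cluster_wcss(values: np.ndarray) -> tuple[float, float]:
    """Best 1-D split into two contiguous clusters by exhaustive scan."""
    x = np.sort(values)
    best = (np.inf, 0.0)
    for cut in range(1, len(x)):
        lo, hi = x[:cut], x[cut:]
        w = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if w < best[0]:
            best = (w, (lo[-1] + hi[0]) / 2.0)
    return best


class TestElbowThreshold:
    def test_recovers_two_well_separated_clusters(self):
        rng = np.random.default_rng(42)
        values = np.concatenate([rng.normal(0.5, 0.1, 100),
                                 rng.normal(20.0, 2.0, 100)])
        res = elbow_threshold(values, k_max=6, seed=0)
        assert res.chosen_k == 2
        assert res.centroids[0] < res.threshold < res.centroids[-1]
        # k-means at k=2 must match the exhaustive 1-D optimum
        best_wcss, best_thr = brute_force_two_cluster_wcss(values)
        assert res.wcss[1] == pytest.approx(best_wcss, rel=1e-9)
        assert res.threshold == pytest.approx(best_thr)

    def test_bimodal_potency_regime(self):
        values = make_bimodal_activities(200, 0.5, 20.0, seed=7)
        res = elbow_threshold(values, seed=0)
        assert res.chosen_k == 2
        assert 0.5 < res.threshold < 20.0

    def test_wcss_non_increasing_in_k(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 100, 80)
        res = elbow_threshold(values, k_max=8, seed=0)
        assert all(a >= b - 1e-9 for a, b in zip(res.wcss, res.wcss[1:]))

    def test_wcss_zero_at_k_equals_distinct_points(self):
        res = elbow_threshold([1.0, 1.0, 5.0, 5.0, 9.0], k_max=5, seed=0)
        assert res.wcss[-1] == pytest.approx(0.0, abs=1e-12)

    def test_identical_values_degenerate(self):
        values = np.full(10, 3.0)
        assert wcss_1d(values, np.array([3.0]), np.zeros(10, dtype=int)) == 0.0
        with pytest.raises(ValueError, match="identical"):
            elbow_threshold(values)


class TestPropertyFilter:
    def test_benzene_rejected(self, benzene):
        assert property_filter([benzene]) == []

    def test_druglike_molecule_kept(self):
        # MW 449, 25 C, 4 N, 3 O, aromatic rings: satisfies every bound
        smi = "COc1ccc2ncc(C(=O)N3CCOCC3)c(Nc3ccc(F)cc3)c2c1"
        mol = Molecule(id="K", smiles=chem_io.canonicalize(smi + "CNC"))
        mol2 = Molecule(id="K2", smiles=chem_io.canonicalize(
            "O=C(Nc1ccc2ncncc2c1)c1cccnc1N1CCN(CCO)CC1"))
        kept = property_filter([mol, mol2])
        assert {m.id for m in kept} <= {"K", "K2"} and kept

    def test_empty_input(self):
        assert property_filter([]) == []

    def test_idempotent(self, druglike_molecules):
        once = property_filter(druglike_molecules)
        assert property_filter(once) == once

    def test_negative_bounds_rejected(self):
        with pytest.raises(ValueError):
            PropertyFilterSpec(min_mw=-1)


class TestTanimoto:
    def test_identical_nonempty(self):
        v = np.array([1, 0, 1, 1, 0])
        assert tanimoto(v, v) == 1.0

    def test_disjoint(self):
        assert tanimoto(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_half_overlap(self):
        a = np.zeros(8, dtype=int); a[[1, 2, 3]] = 1
        b = np.zeros(8, dtype=int); b[[2, 3, 4]] = 1
        assert tanimoto(a, b) == 0.5

    def test_both_empty_convention(self):
        assert tanimoto(np.zeros(4), np.zeros(4)) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(4), np.zeros(5))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=64),
           st.lists(st.booleans(), min_size=1, max_size=64))
    def test_symmetric_and_identity(self, a, b):
        n = max(len(a), len(b))
        a = np.array(a + [False] * (n - len(a)))
        b = np.array(b + [False] * (n - len(b)))
        assert tanimoto(a, b) == tanimoto(b, a)
        if a.any() or b.any():
            assert (tanimoto(a, b) == 1.0) == bool((a == b).all())


class TestDissimilaritySelect:
    def test_identical_to_reference_excluded(self, druglike_molecules):
        ref = druglike_molecules[2]
        clone = Molecule(id="CLONE", smiles=ref.smiles)
        assert dissimilarity_select([clone], [ref]) == []

    def test_dissimilar_molecule_included(self, druglike_molecules):
        ref = druglike_molecules[2]           # a large quinoline amide
        probe = Molecule(id="P", smiles=chem_io.canonicalize("CCSSCC"))
        out = dissimilarity_select([probe], [ref], coeff_range=(0.0, 0.15))
        assert [m.id for m in out] == ["P"]

    def test_output_deduplicated(self, druglike_molecules):
        ref = druglike_molecules[2]
        probe = Molecule(id="P", smiles=chem_io.canonicalize("CCSSCC"))
        dup = Molecule(id="Q", smiles=probe.smiles)
        out = dissimilarity_select([probe, dup], [ref])
        assert [m.id for m in out] == ["P"]

    def test_invalid_range(self, druglike_molecules):
        with pytest.raises(ValueError):
            dissimilarity_select([], druglike_molecules[:1], coeff_range=(0.5, 0.1))

    def test_empty_references(self):
        with pytest.raises(ValueError):
            dissimilarity_select([], [])


def _mols(prefix, n, base="CCO"):
    # distinct ids, same (valid) structure: structure is irrelevant here
    return [Molecule(id=f"{prefix}{i}", smiles=chem_io.canonicalize(base))
            for i in range(n)]


class TestAssembleDataset:
    def test_ratio_relative_to_least_abundant_class(self):
        actives = {"A": _mols("a", 20), "B": _mols("b", 30)}
        inactives = _mols("i", 500)
        ds = assemble_dataset(actives, inactives, ratio=10, seed=0)
        n_inactive = sum((lab.sum() == 0) for part in ds.partitions().values()
                         for _, lab in part)
        assert n_inactive == 10 * 20
        total = sum(len(p) for p in ds.partitions().values())
        assert total == 50 + 200

    def test_split_sizes_and_disjointness(self):
        actives = {"A": _mols("a", 50)}
        ds = assemble_dataset(actives, _mols("i", 1000), ratio=19, seed=1)
        sizes = {k: len(v) for k, v in ds.partitions().items()}
        assert abs(sizes["train"] - 800) <= 2
        assert abs(sizes["validation"] - 100) <= 2
        assert abs(sizes["test"] - 100) <= 2
        ids = [m.id for part in ds.partitions().values() for m, _ in part]
        assert len(ids) == len(set(ids)) == 1000

    def test_stratification_preserves_per_target_counts(self):
        actives = {"A": _mols("a", 100), "B": _mols("b", 100)}
        ds = assemble_dataset(actives, _mols("i", 2000), ratio=10, seed=2)
        for t in range(2):
            counts = {k: int(ds.labels(k)[:, t].sum())
                      for k in ("train", "validation", "test")}
            assert abs(counts["train"] - 80) <= 2
            assert abs(counts["validation"] - 10) <= 2
            assert abs(counts["test"] - 10) <= 2

    def test_multi_target_active_gets_multi_hot_label(self):
        shared = Molecule(id="shared", smiles=chem_io.canonicalize("CCN"))
        actives = {"A": [shared] + _mols("a", 4), "B": [shared] + _mols("b", 4)}
        ds = assemble_dataset(actives, _mols("i", 50), ratio=2, seed=0)
        rows = [lab for part in ds.partitions().values()
                for m, lab in part if m.id == "shared"]
        assert len(rows) == 1
        np.testing.assert_array_equal(rows[0], [1, 1])

    def test_deterministic_under_seed(self):
        actives = {"A": _mols("a", 10)}
        inactives = _mols("i", 100)
        d1 = assemble_dataset(actives, inactives, ratio=5, seed=9)
        d2 = assemble_dataset(actives, inactives, ratio=5, seed=9)
        for part in ("train", "validation", "test"):
            assert [m.id for m, _ in d1.partitions()[part]] == \
                   [m.id for m, _ in d2.partitions()[part]]

    def test_insufficient_inactives_error_states_shortfall(self):
        with pytest.raises(ValueError, match="insufficient"):
            assemble_dataset({"A": _mols("a", 10)}, _mols("i", 5), ratio=100)
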