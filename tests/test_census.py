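import numpy as np
import pytest

from darffc import (
    CircuitCategory,
    classify_autoconfig,
    classify_mode_pair,
    count_autoregulation,
    count_ffcs,
    full_census,
    iter_ffcs,
)

from conftest import make_matrix, make_modes, random_matrix, random_modes
from oracles import brute_force_census


@pytest.mark.parametrize(
    "mode_x,mode_y,expected",
    [
        ("activator", "activator", "coherent_type1"),
        ("repressor", "activator", "coherent_type2"),
        ("activator", "repressor", "incoherent_type1"),
        ("repressor", "repressor", "incoherent_type2"),
        ("activator", "bimodal", "excluded"),
        ("unspecified", "repressor", "excluded"),
        ("bimodal", "bimodal", "excluded"),
    ],
)
def test_classify_mode_pair(mode_x, mode_y, expected):
    """Coherence reduces to the sign rule: coherent iff Y activates,
    type 1 iff X activates; unmoded regulators exclude the circuit."""
    assert classify_mode_pair(mode_x, mode_y) == expected


@pytest.mark.parametrize(
    "auto_x,auto_y,expected",
    [
        (True, True, "double"),
        (False, True, "intermediary_only"),
        (True, False, "originating_only"),
        (False, False, "none"),
    ],
)
def test_classify_autoconfig(auto_x, auto_y, expected):
    assert classify_autoconfig(auto_x, auto_y) == expected


class TestCounting:
    def test_single_triangle_counts_one(self, triangle_matrix):
        assert count_ffcs(triangle_matrix) == 1
        (inst,) = list(iter_ffcs(triangle_matrix))
        assert (inst.x, inst.y, inst.z, inst.target_kind) == (0, 1, 2, "effecter")

    def test_all_ones_3tf_5genes(self):
        # 6 ordered TF pairs x 3 eligible targets (5 genes minus X's and Y's rows)
        m = make_matrix(np.ones((5, 3), dtype=np.uint8))
        assert count_ffcs(m) == 18

    def test_empty_matrix(self):
        m = make_matrix(np.zeros((5, 3), dtype=np.uint8))
        assert count_ffcs(m) == 0
        assert list(iter_ffcs(m)) == []

    def test_mutual_edges_count_both_orders(self):
        entries = np.zeros((3, 2), dtype=np.uint8)
        entries[1, 0] = 1  # TF1 -> TF2
        entries[0, 1] = 1  # TF2 -> TF1
        entries[2, 0] = 1
        entries[2, 1] = 1
        m = make_matrix(entries)
        assert count_ffcs(m) == 2

    def test_autoregulation_counts(self):
        full = np.zeros((6, 5), dtype=np.uint8)
        full[np.arange(5), np.arange(5)] = 1
        assert count_autoregulation(make_matrix(full)) == 5
        assert count_autoregulation(make_matrix(np.zeros((6, 5), dtype=np.uint8))) == 0

    def test_self_target_is_not_an_ffc_target(self):
        # X -> Y plus both targeting X's own gene: no valid Z remains
        entries = np.zeros((2, 2), dtype=np.uint8)
        entries[1, 0] = 1  # X -> Y
        entries[0, 0] = 1  # X -> X (autoregulation)
        entries[0, 1] = 1  # Y -> X
        m = make_matrix(entries)
        assert count_ffcs(m) == 0


class TestFullCensus:
    def test_partition_fully_moded(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 6, 20)
        modes = make_modes(m, ["activator", "repressor"] * 3)
        c = full_census(m, modes)
        assert c.coherent() + c.incoherent() == c.total_ffcs()
        assert c.excluded_unmoded == 0

    def test_autoconfig_partitions_total(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 6, 20)
        c = full_census(m, random_modes(rng, m))
        for tk in ("TF", "effecter"):
            parts = sum(
                c.counts[CircuitCategory("autoconfig", "any", ac, tk)]
                for ac in ("double", "intermediary_only", "originating_only", "none")
            )
            assert parts == c.counts[CircuitCategory("total", target_kind=tk)]

    def test_bimodal_tf_excludes_circuits(self, triangle_matrix):
        modes = make_modes(triangle_matrix, ["bimodal", "activator"])
        c = full_census(triangle_matrix, modes)
        assert c.total_ffcs() == 1
        assert c.coherent() + c.incoherent() == 0
        assert c.excluded_unmoded == 1

    def test_planted_dar_circuit_lands_in_nn_double_effecter(self):
        entries = np.zeros((4, 2), dtype=np.uint8)
        entries[0, 0] = 1  # X autoregulation
        entries[1, 1] = 1  # Y autoregulation
        entries[1, 0] = 1  # X -> Y
        entries[3, 0] = 1  # X -> Z (non-TF gene)
        entries[3, 1] = 1  # Y -> Z
        m = make_matrix(entries)
        modes = make_modes(m, ["repressor", "repressor"])
        c = full_census(m, modes)
        assert c.counts[CircuitCategory("combined", "NN", "double", "effecter")] == 1
        assert c.total_ffcs() == 1

    def test_backbone_at_least_ffc_pairs(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 7, 18)
        modes = random_modes(rng, m)
        c = full_census(m, modes)
        for mp in ("PP", "PN", "NP", "NN"):
            for ac in ("double", "intermediary_only", "originating_only", "none"):
                backbone = c.counts[CircuitCategory("backbone_combined", mp, ac)]
                ffcs = sum(
                    c.counts[CircuitCategory("combined", mp, ac, tk)]
                    for tk in ("TF", "effecter")
                )
                # every FFC pair is a backbone pair; a backbone supports >= 0 FFCs
                assert ffcs == 0 or backbone >= 1

    def test_extended_tf_gene_list_changes_target_kind(self, triangle_matrix):
        modes = make_modes(triangle_matrix, ["activator", "activator"])
        base = full_census(triangle_matrix, modes)
        ext = full_census(triangle_matrix, modes, tf_gene_ids=["G0001"])
        assert base.counts[CircuitCategory("total", target_kind="effecter")] == 1
        assert ext.counts[CircuitCategory("total", target_kind="TF")] == 1
        assert ext.counts[CircuitCategory("total", target_kind="effecter")] == 0

    @pytest.mark.parametrize("trial", range(25))
    def test_algebra_matches_brute_force(self, trial):
        """Vectorized census equals explicit triple enumeration, all keys."""
        rng = np.random.default_rng(100 + trial)
        n_tf = int(rng.integers(2, 9))
        n_genes = int(rng.integers(n_tf, 26))
        m = random_matrix(rng, n_tf, n_genes, density=float(rng.uniform(0.1, 0.6)))
        modes = random_modes(rng, m)
        c = full_census(m, modes)
        expected, excluded = brute_force_census(m, modes)
        assert c.excluded_unmoded == excluded
        assert c.counts == expected

    def test_iterator_matches_algebra(self):
        rng = np.random.default_rng(42)
        m = random_matrix(rng, 8, 25, density=0.4)
        assert sum(1 for _ in iter_ffcs(m)) == count_ffcs(m)
        instances = list(iter_ffcs(m))
        assert len(set(instances)) == len(instances)  # duplicate-free
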