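import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from growssa.engine import Cell, CompiledModel, run_cell
from growssa.model import (
    GeneDef,
    Model,
    ModelError,
    ReactionDef,
    SpeciesDef,
)
from growssa.population import (
    divide,
    lineage_correlation,
    partition_binomial,
    simulate_colony,
    time_weighted_mean,
)

from conftest import make_config


class TestPartitionBinomial:
    def test_zero_counts(self):
        rng = np.random.default_rng(0)
        d1, d2 = partition_binomial(np.array([0, 0]), np.array([True, True]),
                                    rng)
        assert (d1 == 0).all() and (d2 == 0).all()

    @given(st.lists(st.integers(0, 10_000), min_size=1, max_size=6),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_exact_conservation(self, counts, seed):
        rng = np.random.default_rng(seed)
        counts = np.asarray(counts)
        mask = np.ones(len(counts), dtype=bool)
        d1, d2 = partition_binomial(counts, mask, rng)
        assert (d1 + d2 == counts).all()
        assert (d1 >= 0).all() and (d2 >= 0).all()

    def test_binomial_mean(self):
        # 1e5 independent partitions of n=100 against Binomial(100, 1/2)
        rng = np.random.default_rng(42)
        n = 100_000
        counts = np.full(n, 100)
        d1, _ = partition_binomial(counts, np.ones(n, dtype=bool), rng)
        se = math.sqrt(25.0 / n)
        assert abs(d1.mean() - 50.0) < 4 * se

    def test_non_partitionable_copied(self):
        rng = np.random.default_rng(0)
        d1, d2 = partition_binomial(np.array([10, 7]),
                                    np.array([True, False]), rng)
        assert d1[1] == 7 and d2[1] == 7
        assert d1[0] + d2[0] == 10


def _four_copy_cell(autoreg_model):
    config = make_config(T=50.0, C=40.0, D=20.0, t_end=1e9)
    cm = CompiledModel(autoreg_model, config)
    cell = Cell(cm)
    from growssa.engine import apply_replication
    apply_replication(cell, cm, 0)
    cell.t = cell.division_time
    return cell, cm


class TestDivide:
    def test_equal_gene_complement(self, autoreg_model):
        cell, cm = _four_copy_cell(autoreg_model)
        assert len(cell.instances) == 4
        d1, d2 = divide(cell, cm, 1, 2)
        assert len(d1.instances) == 2 and len(d2.instances) == 2

    def test_daughter_volumes_reset(self, autoreg_model):
        cell, cm = _four_copy_cell(autoreg_model)
        d1, d2 = divide(cell, cm, 1, 2)
        assert d1.t_birth == cell.t and d2.t_birth == cell.t
        assert cm.volume(d1.t, d1.t_birth) == pytest.approx(cm.config.v_birth)

    def test_molecule_conservation(self, autoreg_model):
        cell, cm = _four_copy_cell(autoreg_model)
        cell.counts = [5, 113, 7]
        d1, d2 = divide(cell, cm, 1, 2)
        assert [a + b for a, b in zip(d1.counts, d2.counts)] == [5, 113, 7]

    def test_repressed_instance_goes_to_one_daughter(self, autoreg_model):
        cell, cm = _four_copy_cell(autoreg_model)
        # repress one instance of each segregation pair partner
        target = cell.instances[0]
        target.bound[0] = True
        d1, d2 = divide(cell, cm, 1, 2)
        repressed = [sum(any(i.bound) for i in d.instances)
                     for d in (d1, d2)]
        assert sorted(repressed) == [0, 1]

    def test_odd_complement_rejected(self, autoreg_model):
        config = make_config(T=50.0, t_end=1e9)
        cm = CompiledModel(autoreg_model, config)
        cell = Cell(cm)  # two copies, both bit 0: never replicated
        cell.t = cell.division_time
        with pytest.raises(ModelError, match="odd copy complement"):
            divide(cell, cm, 1, 2)

    def test_pending_release_follows_instance(self, autoreg_model):
        cell, cm = _four_copy_cell(autoreg_model)
        from growssa.engine import EV_RELEASE
        inst = cell.instances[0]
        cell.push_event(cell.t + 500.0, EV_RELEASE,
                        (((0, 1),), inst.instance_id))
        d1, d2 = divide(cell, cm, 1, 2)
        holder = d1 if any(i.instance_id == inst.instance_id
                           for i in d1.instances) else d2
        other = d2 if holder is d1 else d1
        releases = [len([ev for ev in d.queue if ev[1] == EV_RELEASE])
                    for d in (holder, other)]
        assert releases == [1, 0]


class TestSimulateColony:
    def test_no_division_before_T(self, autoreg_model):
        config = make_config(T=200.0, t_end=1000.0)
        tree = simulate_colony(autoreg_model, config)
        assert len(tree) == 1
        assert tree.leaves()[0].t_division is None

    def test_full_binary_tree_three_generations(self, autoreg_model):
        config = make_config(T=10.0, t_end=3 * 600.0, grid_dt=60.0)
        tree = simulate_colony(autoreg_model, config)
        assert len(tree) == 15
        assert len(tree.leaves()) == 8

    def test_lineage_consistency(self, autoreg_model):
        config = make_config(T=10.0, t_end=1500.0, grid_dt=60.0)
        tree = simulate_colony(autoreg_model, config)
        for rec in tree.cells():
            if rec.parent_id is not None:
                parent = tree.nodes[rec.parent_id]
                assert rec.t_birth == parent.t_division
            for child in rec.children:
                assert tree.nodes[child].parent_id == rec.cell_id
            assert len(rec.children) in (0, 2)

    def test_max_cells_truncation(self, autoreg_model):
        config = make_config(T=10.0, t_end=1e4, max_cells=5, grid_dt=60.0)
        tree = simulate_colony(autoreg_model, config)
        assert tree.truncated
        assert len(tree) <= 5
        assert tree.warnings

    def test_determinism(self, autoreg_model):
        config = make_config(T=50.0, t_end=6500.0, seed=9, grid_dt=30.0)
        t1 = simulate_colony(autoreg_model, config)
        t2 = simulate_colony(autoreg_model, config)
        assert len(t1) == len(t2)
        for a, b in zip(t1.cells(), t2.cells()):
            assert np.array_equal(a.result.counts, b.result.counts)
            assert np.array_equal(a.result.times, b.result.times)


class TestLineageCorrelation:
    @pytest.fixture
    def constitutive_two_gene_tree(self):
        model = Model(
            name="pair",
            species=[SpeciesDef("mA"), SpeciesDef("mB")],
            reactions=[
                ReactionDef("decA", reactants={"mA": 1}, rate=0.05),
                ReactionDef("decB", reactants={"mB": 1}, rate=0.05),
            ],
            genes=[
                GeneDef("gA", 0.5, 0.2, "mA"),
                GeneDef("gB", 0.5, 0.2, "mB"),
            ],
        ).validate()
        config = make_config(T=20.0, C=40.0, D=20.0, t_end=6 * 1200.0,
                             seed=17, grid_dt=20.0)
        return model, simulate_colony(model, config)

    def test_identical_species(self, constitutive_two_gene_tree):
        model, tree = constitutive_two_gene_tree
        assert lineage_correlation(tree, model, "mA", "mA") == pytest.approx(
            1.0)

    def test_independent_genes_near_zero(self, constitutive_two_gene_tree):
        model, tree = constitutive_two_gene_tree
        r = lineage_correlation(tree, model, "mA", "mB")
        n = len(tree)
        assert abs(r) < 4.0 / math.sqrt(n)  # null CI for 127 cells

    def test_constant_series_is_nan(self, silent_gene_model):
        config = make_config(T=20.0, t_end=5000.0, grid_dt=100.0)
        tree = simulate_colony(silent_gene_model, config)
        assert math.isnan(
            lineage_correlation(tree, silent_gene_model, "x", "x"))

    def test_needs_three_cells(self, autoreg_model):
        config = make_config(T=200.0, t_end=100.0)
        tree = simulate_colony(autoreg_model, config)
        with pytest.raises(ModelError):
            lineage_correlation(tree, autoreg_model, "mRNA", "protein")


def test_time_weighted_mean_step_function():
    t = np.array([0.0, 1.0, 3.0])
    v = np.array([2.0, 8.0, 0.0])
    # piecewise-constant left values: 2 for 1 s, 8 for 2 s
    assert time_weighted_mean(t, v) == pytest.approx((2 + 16) / 3.0)


def test_epigenetic_inheritance_frozen_rates():
    from growssa.acceptance import promoter_inheritance
    out = promoter_inheritance(seed=3, n_generations=5)
    assert out["violations"] == 0
    assert out["n_cells"] == 32
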