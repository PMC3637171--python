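import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from growssa.engine import (
    EV_RELEASE,
    NO_FIRING,
    Cell,
    CompiledModel,
    apply_replication,
    compute_propensities,
    fire_reaction,
    run_cell,
    sample_firing_time,
    select_channel,
    survival_integral,
    _invert_hazard,
    _select_index,
)
from growssa.model import (
    GeneDef,
    Model,
    ModelError,
    ReactionDef,
    RunConfig,
    SpeciesDef,
    counts_per_uM,
)

from conftest import make_config


class TestSurvivalIntegral:
    def test_constant_hazard(self):
        assert survival_integral(1.0, 0.0, 0.5, 3.0) == pytest.approx(3.0)

    def test_growth_free_limit(self):
        assert survival_integral(0.0, 1.0, 1e-14, 3.0) == pytest.approx(
            3.0, rel=1e-9)
        assert survival_integral(0.0, 1.0, 0.0, 3.0) == 3.0

    def test_mixed_case_against_quadrature(self):
        val = survival_integral(1.0, 2.0, 0.01, 10.0)
        oracle, _ = quad(lambda s: 1.0 + 2.0 * math.exp(-0.01 * s), 0.0, 10.0,
                         epsabs=1e-13, epsrel=1e-13)
        assert val == pytest.approx(10.0 + 200.0 * (1 - math.exp(-0.1)))
        assert val == pytest.approx(oracle, rel=1e-12)

    def test_proportional_term(self):
        val = survival_integral(0.5, 0.0, 0.02, 5.0, g=1.5)
        oracle, _ = quad(lambda s: 0.5 + 1.5 * math.exp(0.02 * s), 0.0, 5.0,
                         epsabs=1e-13, epsrel=1e-13)
        assert val == pytest.approx(oracle, rel=1e-12)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            survival_integral(1.0, 0.0, 0.1, -1.0)


def bisect_tau(A, b, g, mu, L):
    hi = max(L / (A + b + g), 1e-12)
    while survival_integral(A, b, mu, hi, g) < L:
        hi *= 2.0
        if hi > 1e280:
            return math.inf
    return brentq(lambda t: survival_integral(A, b, mu, t, g) - L, 0.0, hi,
                  xtol=1e-300, rtol=8.9e-16)


class TestSampleFiringTime:
    def test_reduces_to_gillespie(self):
        assert sample_firing_time(1.0, 0.0, 0.0, 0.3,
                                  math.exp(-1.0)) == pytest.approx(1.0)

    def test_pure_inverse_volume(self):
        r = math.exp(-0.5)
        tau = sample_firing_time(0.0, 1.0, 0.0, 0.01, r)
        assert tau == pytest.approx(-100.0 * math.log(0.995))
        assert tau == pytest.approx(0.50125, abs=5e-5)

    def test_no_firing_when_hazard_bounded(self):
        assert sample_firing_time(0.0, 1.0, 0.0, 1.0,
                                  math.exp(-2.0)) == NO_FIRING

    def test_lambert_agrees_with_bisection(self):
        mu = math.log(2.0) / 12000.0
        tau = sample_firing_time(1.0, 1.0, 0.0, mu, 0.5)
        assert tau == pytest.approx(bisect_tau(1.0, 1.0, 0.0, mu,
                                               -math.log(0.5)), rel=1e-9)

    def test_proportional_branch(self):
        tau = sample_firing_time(0.5, 0.3, 0.8, 0.005, 0.2)
        assert tau == pytest.approx(
            bisect_tau(0.5, 0.3, 0.8, 0.005, -math.log(0.2)), rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sample_firing_time(1.0, 0.0, 0.0, 0.1, 0.0)
        with pytest.raises(ValueError):
            sample_firing_time(-1.0, 0.0, 0.0, 0.1, 0.5)

    @given(
        A=st.one_of(st.just(0.0), st.floats(1e-9, 100.0)),
        b=st.one_of(st.just(0.0), st.floats(1e-9, 100.0)),
        g=st.one_of(st.just(0.0), st.floats(1e-9, 10.0)),
        mu=st.floats(1e-8, 0.1),
        r=st.floats(1e-6, 1.0, exclude_max=True),
    )
    @settings(max_examples=300, deadline=None)
    def test_residual_contract(self, A, b, g, mu, r):
        if A + b + g == 0.0:
            assert sample_firing_time(A, b, g, mu, r) == NO_FIRING
            return
        L = -math.log(r)
        tau = sample_firing_time(A, b, g, mu, r)
        if tau == NO_FIRING:
            assert A == 0.0 and g == 0.0 and mu * L / b >= 1.0
            return
        assert abs(survival_integral(A, b, mu, tau, g) - L) \
            <= 1e-10 * (1.0 + L)


def _compiled(model, **cfg):
    config = make_config(**cfg)
    return CompiledModel(model, config), config


class TestComputePropensities:
    def test_dimerization_scaling(self):
        model = Model(
            species=[SpeciesDef("p", initial_count=100), SpeciesDef("d")],
            reactions=[ReactionDef("dim", reactants={"p": 2},
                                   products={"d": 1}, rate=1.0,
                                   rate_units="per_uM_per_second")],
        ).validate()
        cm, _ = _compiled(model)
        cell = Cell(cm)
        split = compute_propensities(cell, cm)
        omega = counts_per_uM(1.1e-15)  # independent dimensional oracle
        assert split.b == pytest.approx(100 * 99 / omega)
        assert split.b == pytest.approx(14.95, abs=0.01)
        assert split.A == 0.0 and split.g == 0.0

    def test_all_zero(self):
        model = Model(
            species=[SpeciesDef("x")],
            reactions=[ReactionDef("decay", reactants={"x": 1}, rate=1.0)],
        ).validate()
        cm, _ = _compiled(model)
        split = compute_propensities(Cell(cm), cm)
        assert split.total == 0.0

    def test_repressed_instance_halves_one_copy(self, autoreg_model):
        cm, _ = _compiled(autoreg_model)
        cell = Cell(cm)
        assert len(cell.instances) == 2
        cell.counts[cm.idx["dimer"]] = 5
        cell.instances[0].bound[0] = True
        cell._dirty = True
        split = compute_propensities(cell, cm)
        tx = [v for k, v in split.per_channel
              if isinstance(k, tuple) and k[-1] == "tx"]
        assert sum(tx) == pytest.approx(1.0 * (1.0 + 0.1))

    def test_per_channel_sums_to_split(self, autoreg_model):
        cm, _ = _compiled(autoreg_model)
        cell = Cell(cm)
        cell.counts = [3, 50, 4]
        split = compute_propensities(cell, cm)
        assert sum(v for _, v in split.per_channel) == pytest.approx(
            split.total, rel=1e-12)


class TestSelectChannel:
    def test_single_channel(self):
        model = Model(
            species=[SpeciesDef("x", initial_count=1)],
            reactions=[ReactionDef("decay", reactants={"x": 1}, rate=1.0)],
        ).validate()
        cm, _ = _compiled(model)
        cell = Cell(cm)
        assert select_channel(cell, cm, cell.t, 0.7) == "decay"

    def test_threshold_crossing(self):
        assert _select_index([3.0, 1.0], [0, 0], 0.0, 0.0, 0.9) == 1
        assert _select_index([3.0, 1.0], [0, 0], 0.0, 0.0, 0.5) == 0

    def test_monte_carlo_frequencies(self):
        rng = np.random.default_rng(5)
        vals = [3.0, 1.0]
        n = 100_000
        hits = sum(_select_index(vals, [0, 0], 0.0, 0.0, r) == 0
                   for r in rng.random(n))
        p = hits / n
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(p - 0.75) < 4 * se

    def test_zero_total_rejected(self):
        with pytest.raises(ModelError):
            _select_index([0.0], [0], 0.0, 0.0, 0.5)


class TestFireReaction:
    def test_instantaneous_decay(self):
        model = Model(
            species=[SpeciesDef("mRNA", initial_count=5)],
            reactions=[ReactionDef("decay", reactants={"mRNA": 1},
                                   rate=2.0)],
        ).validate()
        cm, _ = _compiled(model)
        cell = Cell(cm)
        compute_propensities(cell, cm)
        fire_reaction(cell, cm, cell._descs[0])
        assert cell.counts[0] == 4

    def test_delayed_translation_consumes_nothing(self, autoreg_model):
        import dataclasses
        rxns = [dataclasses.replace(r, delay=1000.0)
                if r.name == "translation" else r
                for r in autoreg_model.reactions]
        model = dataclasses.replace(autoreg_model, reactions=rxns).validate()
        cm, _ = _compiled(model)
        cell = Cell(cm)
        cell.counts[cm.idx["mRNA"]] = 3
        compute_propensities(cell, cm)
        j = next(i for i, d in enumerate(cell._descs)
                 if d[0] == "rxn" and d[1].name == "translation")
        n_events = len(cell.queue)
        fire_reaction(cell, cm, cell._descs[j])
        assert cell.counts[cm.idx["mRNA"]] == 3       # catalytic template
        assert cell.counts[cm.idx["protein"]] == 0    # not yet released
        release = [ev for ev in cell.queue if ev[1] == EV_RELEASE]
        assert len(cell.queue) == n_events + 1
        assert release[0][0] == pytest.approx(cell.t + 1000.0)

    def test_promoter_binding_moves_tf(self, autoreg_model):
        cm, _ = _compiled(autoreg_model)
        cell = Cell(cm)
        cell.counts[cm.idx["dimer"]] = 2
        compute_propensities(cell, cm)
        j = next(i for i, d in enumerate(cell._descs) if d[0] == "bind")
        inst = cell._descs[j][1]
        fire_reaction(cell, cm, cell._descs[j])
        assert cell.counts[cm.idx["dimer"]] == 1
        assert inst.bound[0] is True

    def test_insufficient_reactants_is_internal_error(self):
        model = Model(
            species=[SpeciesDef("x", initial_count=0)],
            reactions=[ReactionDef("decay", reactants={"x": 1}, rate=1.0)],
        ).validate()
        cm, _ = _compiled(model)
        cell = Cell(cm)
        compute_propensities(cell, cm)
        with pytest.raises(ModelError, match="insufficient"):
            fire_reaction(cell, cm, cell._descs[0])


class TestApplyReplication:
    def test_bound_tf_released(self, autoreg_model):
        import dataclasses
        genes = [dataclasses.replace(autoreg_model.genes[0],
                                     initial_copies=1)]
        model = dataclasses.replace(autoreg_model, genes=genes).validate()
        cm, _ = _compiled(model)
        cell = Cell(cm)
        cell.instances[0].bound[0] = True
        apply_replication(cell, cm, 0)
        assert len(cell.instances) == 2
        assert all(not any(i.bound) for i in cell.instances)
        assert cell.counts[cm.idx["dimer"]] == 1
        assert {i.segregation_bit for i in cell.instances} == {0, 1}

    def test_doubling_unbound(self, autoreg_model):
        cm, _ = _compiled(autoreg_model)
        cell = Cell(cm)
        apply_replication(cell, cm, 0)
        assert len(cell.instances) == 4
        assert cell.copies[0] == 4

    def test_channel_count_grows_per_instance(self, autoreg_model):
        # each live instance contributes one transcription channel plus one
        # channel per binding site (the active binding or unbinding step)
        cm, _ = _compiled(autoreg_model)
        cell = Cell(cm)
        before = len(compute_propensities(cell, cm).per_channel)
        apply_replication(cell, cm, 0)
        after = len(compute_propensities(cell, cm).per_channel)
        assert after - before == 2 * 2  # two new instances, tx + 1 site each


class TestRunCell:
    def test_replication_only_trajectory(self, silent_gene_model):
        config = make_config(T=50.0, C=40.0, D=20.0, t_end=2900.0,
                             grid_dt=10.0)
        cm = CompiledModel(silent_gene_model, config)
        cell = Cell(cm)
        res = run_cell(cell, cm)
        copies = res.copies[:, 0]
        jumps = np.flatnonzero(np.diff(copies))
        assert copies[0] == 2 and copies[-1] == 4
        assert len(jumps) == 1
        assert res.times[jumps[0] + 1] == pytest.approx(2400.0, abs=10.0)

    def test_birth_death_stationary_mean(self, birth_death_model):
        config = make_config(T=1e6, t_end=20000.0, grid_dt=5.0, seed=7)
        cm = CompiledModel(birth_death_model, config)
        res = run_cell(Cell(cm), cm)
        samples = res.counts[res.times > 500.0, 0]
        # stationary mean 2 * a / r1 = 1.0 (Poisson), generous CI for
        # correlated samples
        assert samples.mean() == pytest.approx(1.0, abs=0.1)

    def test_delayed_event_preempts_jump(self, silent_gene_model):
        config = make_config(T=50.0, t_end=12.0, grid_dt=100.0)
        cm = CompiledModel(silent_gene_model, config)
        cell = Cell(cm)
        cell.push_event(10.0, EV_RELEASE, (((0, 3),), None))
        res = run_cell(cell, cm)
        assert cell.counts[0] == 3
        idx = np.searchsorted(res.times, 10.0)
        assert res.counts[idx, 0] == 3
        assert res.counts[idx - 1, 0] == 0

    def test_counts_never_negative(self, autoreg_model):
        config = make_config(T=200.0, t_end=4000.0, grid_dt=5.0, seed=3,
                             record_events=True)
        cm = CompiledModel(autoreg_model, config)
        res = run_cell(Cell(cm), cm)
        assert (res.counts >= 0).all()

    def test_division_time_reached(self, autoreg_model):
        config = make_config(T=10.0, t_end=1e5, grid_dt=60.0, seed=2)
        cm = CompiledModel(autoreg_model, config)
        res = run_cell(Cell(cm), cm)
        assert res.divided
        assert res.t_final == pytest.approx(600.0)

    def test_volume_growth_law(self, autoreg_model):
        config = make_config(T=100.0, t_end=1e5, grid_dt=600.0)
        cm = CompiledModel(autoreg_model, config)
        res = run_cell(Cell(cm), cm)
        vols = res.volumes(cm)
        assert vols[0] == pytest.approx(config.v_birth)
        assert vols[-1] == pytest.approx(2.0 * config.v_birth, rel=1e-9)


class TestHazardInversionGrid:
    def test_engine_path_matches_oracle_everywhere(self):
        # includes the fast Newton path the inner loop uses
        rng = np.random.default_rng(11)
        for _ in range(200):
            A = 10.0 ** rng.uniform(-2, 2)
            b = 10.0 ** rng.uniform(-2, 2)
            mu = 10.0 ** rng.uniform(-8, -1)
            L = -math.log(rng.random())
            tau = _invert_hazard(A, b, 0.0, mu, L)
            assert tau == pytest.approx(bisect_tau(A, b, 0.0, mu, L),
                                        rel=1e-9)
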