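"""Recomputable acceptance metrics.

Each function here recomputes one acceptance quantity from scratch by
running the package; they are shared between the test suite and
``scripts/acceptance.py`` so the reported numbers and the tested numbers are
the same computation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq
from scipy.stats import kstest, ks_2samp

from .dosage import (
    CyclePeriods,
    copies_at_birth,
    max_copies_in_cycle,
    replication_age,
)
from .engine import (
    EV_REPLICATION,
    Cell,
    CompiledModel,
    run_cell,
    sample_firing_time,
    survival_integral,
)
from .model import GeneInstance
from .examples import load_example, oscillation_score, run_example
from .model import Model
from .population import lineage_correlation, simulate_colony
from .reference import (
    FluxParams,
    autoreg_steady_state,
    classic_ssa,
    integrate_delayed_ode,
    integrate_flux_ode,
)

PAPER_PERIODS = CyclePeriods(T=50.0, C=40.0, D=20.0)


# -- t1..t6: dosage arithmetic and growth-rate consistency ------------------

def dosage_targets() -> dict[str, float]:
    """Doubling ages and copy numbers of origin/terminus genes (T=50)."""
    fast = CyclePeriods(T=25.0, C=40.0, D=20.0)
    return {
        "t1": replication_age(0.0, PAPER_PERIODS),
        "t2": replication_age(1.0, PAPER_PERIODS),
        "t3": float(copies_at_birth(0.0, PAPER_PERIODS)),
        "t4": float(copies_at_birth(1.0, PAPER_PERIODS)),
        "t5": float(max_copies_in_cycle(0.0, fast)),
    }


def dilution_rate_per_min(T_minutes: float = 50.0, digits: int = 4) -> float:
    """ln2 / T rounded to the printed precision of the flux parameter set."""
    return round(math.log(2.0) / T_minutes, digits)


# -- criterion 4: firing-time sampler ---------------------------------------

def bisection_firing_time(A: float, b: float, g: float, mu: float,
                          r: float) -> float:
    """Independent inversion of the survival integral by bracketed root
    finding (the oracle for the Lambert-W path)."""
    L = -math.log(r)
    total = A + b + g
    if total <= 0:
        return math.inf
    if mu > 0 and A == 0 and g == 0 and mu * L / b >= 1.0:
        return math.inf
    hi = L / total
    while survival_integral(A, b, mu, hi, g) < L:
        hi *= 2.0
        if hi > 1e300:
            return math.inf
    return brentq(lambda tau: survival_integral(A, b, mu, tau, g) - L,
                  0.0, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)


def lambert_vs_bisection(n_min: int = 1000) -> dict:
    """Max relative disagreement between the closed-form sampler and the
    bisection oracle over a logarithmic parameter grid."""
    As = np.logspace(-2.0, 2.0, 6)
    bs = np.logspace(-2.0, 2.0, 6)
    mus = np.logspace(-6.0, -1.0, 6)
    rs = (0.05, 0.2, 0.4, 0.6, 0.8, 0.95)
    worst = 0.0
    n = 0
    for A in As:
        for b in bs:
            for mu in mus:
                for r in rs:
                    tau = sample_firing_time(A, b, 0.0, mu, r)
                    oracle = bisection_firing_time(A, b, 0.0, mu, r)
                    rel = abs(tau - oracle) / oracle
                    worst = max(worst, rel)
                    n += 1
    assert n >= n_min
    return {"max_rel_error": worst, "n": n}


def firing_time_ks(seed: int, n: int = 10000, A: float = 0.8,
                   b: float = 1.7, mu: float = math.log(2) / 3000.0) -> dict:
    """KS test of sampled waiting times against the analytic CDF."""
    rng = np.random.default_rng(seed)
    samples = np.array([
        sample_firing_time(A, b, 0.0, mu, r) for r in rng.random(n)
    ])

    def cdf(tau):
        tau = np.asarray(tau, dtype=float)
        lam = (A * tau - (b / mu) * np.expm1(-mu * tau))
        return 1.0 - np.exp(-lam)

    stat, pvalue = kstest(samples, cdf)
    return {"ks_stat": float(stat), "pvalue": float(pvalue), "n": n}


# -- criterion 5: zero-growth equivalence and growth-on mean ----------------

def _with_initial_counts(model: Model, counts: dict[str, int]) -> Model:
    species = [
        dataclasses.replace(sp, initial_count=counts.get(sp.name,
                                                         sp.initial_count))
        for sp in model.species
    ]
    return dataclasses.replace(model, species=species).validate()


_NEAR_SS = {"protein": 34, "dimer": 2, "mRNA": 0}


def engine_stationary_protein(seed: int, n_runs: int = 100,
                              samples_per_run: int = 100,
                              spacing: float = 200.0,
                              burnin: float = 1000.0) -> np.ndarray:
    """Stationary protein samples from the growth engine at T = 1e6 min.

    Independent short runs (restarting the volume at birth each time) avoid
    the slow secular volume drift a single long run would accumulate; counts
    start near the deterministic fixed point so the burn-in can be short.
    """
    model, config = load_example("negautoreg")
    model = _with_initial_counts(model, _NEAR_SS)
    config.T = 1e6
    config.t_end = burnin + samples_per_run * spacing
    config.grid_dt = spacing
    config.record_events = False
    ip = model.species_index["protein"]
    out = []
    for run in range(n_runs):
        cfg = dataclasses.replace(config, seed=seed + run)
        cm = CompiledModel(model, cfg)
        cell = Cell(cm, cell_id=0)
        res = run_cell(cell, cm)
        mask = res.times >= burnin - 0.5 * spacing
        out.append(res.counts[mask, ip][:samples_per_run])
    return np.concatenate(out)


def classic_stationary_protein(seed: int, n_runs: int = 100,
                               samples_per_run: int = 100,
                               spacing: float = 200.0,
                               burnin: float = 1000.0) -> np.ndarray:
    """Matching stationary samples from the constant-volume reference SSA."""
    model, _ = load_example("negautoreg")
    model = _with_initial_counts(model, _NEAR_SS)
    t_end = burnin + samples_per_run * spacing
    out = []
    for run in range(n_runs):
        series = classic_ssa(model, t_end=t_end, seed=seed + 7919 * (run + 1),
                             grid_dt=spacing)
        mask = series.t >= burnin - 0.5 * spacing
        out.append(series.column("protein")[mask][:samples_per_run])
    return np.concatenate(out)


def zero_growth_ks(seed: int, n_samples: int = 10000) -> dict:
    """Two-sample KS comparison of engine vs classic SSA protein samples."""
    n_runs = max(1, n_samples // 100)
    eng = engine_stationary_protein(seed, n_runs=n_runs)
    ssa = classic_stationary_protein(seed, n_runs=n_runs)
    stat, pvalue = ks_2samp(eng, ssa)
    return {
        "ks_stat": float(stat),
        "pvalue": float(pvalue),
        "n": int(min(len(eng), len(ssa))),
        "engine_mean": float(eng.mean()),
        "classic_mean": float(ssa.mean()),
    }


def growth_vs_ode(seed: int, t_end: float = 30000.0,
                  burnin: float = 6000.0) -> dict:
    """Mean protein of the growing engine (T = 200 min) vs the ODE fixed
    point; the engine runs with volume growth, dosage doubling and division
    and is expected to sit above the constant-volume deterministic value."""
    model, config = load_example("negautoreg")
    config.seed = seed
    config.t_end = t_end
    config.grid_dt = 5.0
    config.record_events = False
    cm = CompiledModel(model, config)
    tree = simulate_colony(model, config, cm=cm)
    ip = model.species_index["protein"]
    counts = []
    concs = []
    for rec in tree.cells():
        res = rec.result
        mask = res.times >= burnin
        counts.append(res.counts[mask, ip])
        vols = res.volumes(cm)[mask]
        concs.append(res.counts[mask, ip] / (vols * 6.02214076e23 * 1e-6))
    counts = np.concatenate(counts)
    concs = np.concatenate(concs)
    ss = autoreg_steady_state()
    return {
        "engine_mean_protein": float(counts.mean()),
        "engine_mean_protein_uM": float(concs.mean()),
        "ode_ss_protein_uM": ss["protein"],
        "ode_ss_protein_counts": ss["protein"] * cm.omega0,
        "n": int(len(counts)),
    }


# -- criterion 6: delay-induced oscillation ---------------------------------

def delay_oscillation(seed: int) -> dict:
    """Oscillation scores (autocorrelation minima after a 2000 s transient)
    for the delayed ODE and the stochastic engine, with and without the
    1000 s translation delay, over 400 min."""
    dde = integrate_delayed_ode(delay=1000.0, t_end=24000.0)
    ode = integrate_delayed_ode(delay=0.0, t_end=24000.0)
    score_kw = dict(transient=2000.0, max_lag_s=5000.0)
    out = {
        "dde_delay": oscillation_score(dde.t, dde.column("protein"),
                                       **score_kw),
        "dde_nodelay": oscillation_score(ode.t, ode.column("protein"),
                                         **score_kw),
    }
    eng_d = run_example("negautoreg_delay", seed=seed)
    eng_0 = run_example("negautoreg", seed=seed)
    out["engine_delay"] = eng_d["oscillation_score"]
    out["engine_nodelay"] = eng_0["oscillation_score"]
    return out


# -- criterion 7: division ---------------------------------------------------

def division_conservation(seed: int, n: int = 10000) -> dict:
    """Exact conservation over random binomial partitions."""
    from .population import partition_binomial

    rng = np.random.default_rng(seed)
    worst = 0
    for _ in range(n):
        k = rng.integers(1, 8)
        counts = rng.integers(0, 1000, size=k)
        mask = rng.random(k) < 0.8
        d1, d2 = partition_binomial(counts, mask, rng)
        worst = max(worst, int(np.abs(
            np.where(mask, d1 + d2 - counts, 0)).max()))
    return {"max_violation": worst, "n": n}


def _manual_double(cell: Cell, cm: CompiledModel) -> None:
    """Duplicate every gene instance, copying its occupancy state.

    Stands in for replication in division-mechanics tests: the real
    replication step deliberately resets promoter occupancy (fork passage
    dissociates bound TFs), so isolating division inheritance requires a
    state-preserving doubling.
    """
    twins = []
    for inst in cell.instances:
        inst.segregation_bit = 0
        twin = GeneInstance(gene=inst.gene, instance_id=cell._next_iid,
                            segregation_bit=1, bound=list(inst.bound))
        cell._next_iid += 1
        twins.append(twin)
        cell.copies[cm.gene_index[inst.gene.name]] += 1
    cell.instances.extend(twins)
    cell._dirty = True


def promoter_inheritance(seed: int, n_generations: int = 6) -> dict:
    """Promoter states must persist through divisions when binding is frozen.

    Hand-sets occupancy on every instance, chains divisions (with
    state-preserving doubling in between, see :func:`_manual_double`) and
    counts occupancy-state changes; with no binding/unbinding dynamics the
    count must be zero and each generation's states must split one-per-pair
    between the daughters.
    """
    from .population import divide

    model, config = load_example("toggle")
    config.seed = seed
    cm = CompiledModel(model, config)
    rng = np.random.default_rng(seed)
    cell = Cell(cm, cell_id=0)
    cells = [cell]
    next_id = 1
    violations = 0
    for _ in range(n_generations):
        marked: dict[tuple[int, int], tuple[bool, ...]] = {}
        for c in cells:
            for inst in c.instances:
                inst.bound = [bool(rng.random() < 0.5)
                              for _ in inst.bound]
            _manual_double(c, cm)
            for inst in c.instances:
                marked[(c.cell_id, inst.instance_id)] = tuple(inst.bound)
        new_cells = []
        for c in cells:
            c.queue = [ev for ev in c.queue if ev[1] != EV_REPLICATION]
            c.t = c.division_time
            mother_ids = sorted(i.instance_id for i in c.instances)
            d1, d2 = divide(c, cm, next_id, next_id + 1)
            next_id += 2
            seen = []
            for d in (d1, d2):
                for inst in d.instances:
                    key = (c.cell_id, inst.instance_id)
                    if marked[key] != tuple(inst.bound):
                        violations += 1
                    seen.append(inst.instance_id)
            if sorted(seen) != mother_ids:
                violations += 1
            new_cells += [d1, d2]
        cells = new_cells
    return {"violations": violations, "n_cells": len(cells)}


# -- criterion 8: toggle lineage anticorrelation ----------------------------

def toggle_anticorrelation(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of colony seeds whose protein A/B lineage correlation is
    negative (16-leaf colonies)."""
    negatives = 0
    values = []
    model, base = load_example("toggle")
    for k in range(n_seeds):
        config = dataclasses.replace(base, seed=seed + k, grid_dt=5.0,
                                     record_events=False)
        tree = simulate_colony(model, config)
        r = lineage_correlation(tree, model, "protein_A", "protein_B")
        values.append(r)
        if r < 0:
            negatives += 1
    return {
        "fraction_negative": negatives / n_seeds,
        "n_seeds": n_seeds,
        "correlations": values,
    }


# -- criterion 9: flux example ----------------------------------------------

def flux_comparison(seed: int, t_end: float = 12000.0,
                    engine_t_end: float = 9000.0) -> dict:
    """Cycle-averaged M2 level and fluctuation amplitude for symmetric vs
    origin/terminus gene placement, in both the (runtime-scaled) stochastic
    engine and the published-parameter flux ODE."""
    out: dict = {}
    for name in ("flux_balanced", "flux_unbalanced"):
        s = run_example(name, seed=seed, t_end=engine_t_end)
        out[f"engine_{name}_m2_mean"] = s["m2_mean_uM"]
        out[f"engine_{name}_m2_std"] = s["m2_std_uM"]
    for tag, positions in (("balanced", (0.5, 0.5)),
                           ("unbalanced", (0.0, 1.0))):
        series = integrate_flux_ode(FluxParams(), positions=positions,
                                    t_end=t_end)
        m2 = series.column("M2")
        mask = series.t >= 3000.0
        out[f"ode_{tag}_m2_mean"] = float(np.mean(m2[mask]))
        out[f"ode_{tag}_m2_std"] = float(np.std(m2[mask]))
    return out
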