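"""Independent reference solvers used to validate the stochastic engine.

* a deterministic ODE for the negative-autoregulation circuit,
* a delayed-ODE variant (fixed-step RK4 with dense history interpolation),
* a classic constant-volume direct-method SSA, and
* the deterministic dynamic flux-balance ODEs for the metabolic example.

The autoregulation ODE works in uM concentrations:

    d[mRNA]/dt    = a*(G_free + f*G_bound) - r1*[mRNA]
    d[protein]/dt = b*[mRNA](t - delay) - r2*[protein]
                    - 2c*[protein]^2 + 2d*[dm]
    d[dm]/dt      = c*[protein]^2 - d*[dm] - K1*[dm]*G_free + K2*G_bound
    dG_bound/dt   = K1*[dm]*G_free - K2*G_bound

with G_free + G_bound equal to the fixed gene dosage and f the repressed
transcription factor (0.1).  Promoter-bound dimer is counted separately from
the free dimer pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .dosage import CyclePeriods, copies_at_age, replication_age
from .model import (
    DEFAULT_V_BIRTH,
    MICHAELIS_MENTEN,
    Model,
    ModelError,
    counts_per_uM,
)


@dataclass
class TimeSeries:
    """A labelled multivariate time series."""

    t: np.ndarray
    data: dict[str, np.ndarray]
    solver: str = "ode"

    def column(self, name: str) -> np.ndarray:
        return self.data[name]


@dataclass
class AutoregParams:
    """Rates of the negative-autoregulation circuit (defaults as published).

    The dimer production rate ``c`` and promoter binding rate ``K1`` are
    interpreted as per-uM-per-second (bimolecular); see the unit notes in
    the package docs.
    """

    a: float = 1.0          # transcription, per gene per second
    b: float = 1.0          # translation, per mRNA per second
    r1: float = 2.0         # mRNA degradation, 1/s
    r2: float = 0.01        # protein decay, 1/s
    c: float = 1.0          # dimer production, per uM per second
    d: float = 1.0          # dimer dissociation, 1/s
    K1: float = 100.0       # dimer-promoter binding, per uM per second
    K2: float = 0.1         # dimer-promoter unbinding, 1/s
    repressed_factor: float = 0.1
    gene_dosage: float = 0.003  # uM (about two gene copies per cell)


def _autoreg_rhs(y, p: AutoregParams, m_delayed: float):
    m, prot, dm, gb = y
    gf = p.gene_dosage - gb
    bind = p.K1 * dm * gf
    unbind = p.K2 * gb
    dm_dt = p.a * (gf + p.repressed_factor * gb) - p.r1 * m
    dp_dt = (p.b * m_delayed - p.r2 * prot
             - 2.0 * p.c * prot * prot + 2.0 * p.d * dm)
    dd_dt = p.c * prot * prot - p.d * dm - bind + unbind
    dgb_dt = bind - unbind
    return (dm_dt, dp_dt, dd_dt, dgb_dt)


_AUTOREG_NAMES = ("mRNA", "protein", "dimer", "promoter_bound")


def integrate_autoreg_ode(params: Optional[AutoregParams] = None,
                          t_end: float = 12000.0,
                          grid_dt: float = 1.0,
                          y0=(0.0, 0.0, 0.0, 0.0)) -> TimeSeries:
    """Integrate the autoregulation ODE from zero initial conditions."""
    p = params or AutoregParams()

    def rhs(t, y):
        return _autoreg_rhs(y, p, y[0])

    t_eval = np.arange(0.0, t_end + grid_dt / 2, grid_dt)
    sol = solve_ivp(rhs, (0.0, t_end), list(y0), method="LSODA",
                    t_eval=t_eval, rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise ModelError(f"ODE integration failed: {sol.message}")
    data = {n: sol.y[i] for i, n in enumerate(_AUTOREG_NAMES)}
    return TimeSeries(t=sol.t, data=data, solver="ode")


def autoreg_steady_state(params: Optional[AutoregParams] = None) -> dict[str, float]:
    """Steady state of the autoregulation ODE via root finding on the RHS."""
    p = params or AutoregParams()
    tail = integrate_autoreg_ode(p, t_end=5000.0, grid_dt=50.0)
    guess = [tail.data[n][-1] for n in _AUTOREG_NAMES]
    root = fsolve(lambda y: _autoreg_rhs(y, p, y[0]), guess, full_output=False)
    res = _autoreg_rhs(root, p, root[0])
    if max(abs(v) for v in res) > 1e-9:
        raise ModelError("steady-state root finding did not converge")
    return dict(zip(_AUTOREG_NAMES, (float(v) for v in root)))


def integrate_delayed_ode(params: Optional[AutoregParams] = None,
                          delay: float = 1000.0,
                          t_end: float = 24000.0,
                          h: Optional[float] = None,
                          record_every: int = 10) -> TimeSeries:
    """Fixed-step RK4 integration of the autoregulation DDE.

    The translation term uses mRNA(t - delay); history on [-delay, 0] equals
    the (zero) initial condition.  The step must not exceed ``delay/20``;
    mid-step history values use 4-point Lagrange interpolation on the
    solution grid.
    """
    p = params or AutoregParams()
    if delay < 0:
        raise ModelError("delay must be >= 0")
    if delay == 0.0:
        return integrate_autoreg_ode(p, t_end=t_end, grid_dt=1.0)
    if h is None:
        h = min(0.1, delay / 20.0)
    if h > delay / 20.0:
        raise ModelError("step larger than delay/20 rejected")
    n_steps = int(round(t_end / h))
    m_hist = np.zeros(n_steps + 1)
    y = [0.0, 0.0, 0.0, 0.0]
    m_hist[0] = y[0]

    def m_at(t_query: float, upto: int) -> float:
        if t_query <= 0.0:
            return 0.0
        x = t_query / h
        k = int(math.floor(x))
        if k >= upto:
            return m_hist[upto]
        # 4-point Lagrange around the bracketing interval
        k0 = min(max(k - 1, 0), max(upto - 3, 0))
        xs = (k0, k0 + 1, k0 + 2, k0 + 3)
        out = 0.0
        for i in xs:
            li = 1.0
            for j in xs:
                if j != i:
                    li *= (x - j) / (i - j)
            out += li * m_hist[min(i, upto)]
        return out

    rec_t = [0.0]
    rec_y = [tuple(y)]
    for n in range(n_steps):
        t = n * h

        def f(ti, yi):
            return _autoreg_rhs(yi, p, m_at(ti - delay, n))

        k1 = f(t, y)
        y2 = [y[i] + 0.5 * h * k1[i] for i in range(4)]
        k2 = f(t + 0.5 * h, y2)
        y3 = [y[i] + 0.5 * h * k2[i] for i in range(4)]
        k3 = f(t + 0.5 * h, y3)
        y4 = [y[i] + h * k3[i] for i in range(4)]
        k4 = f(t + h, y4)
        y = [y[i] + (h / 6.0) * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i])
             for i in range(4)]
        m_hist[n + 1] = y[0]
        if (n + 1) % record_every == 0:
            rec_t.append((n + 1) * h)
            rec_y.append(tuple(y))

    arr = np.asarray(rec_y)
    data = {n: arr[:, i] for i, n in enumerate(_AUTOREG_NAMES)}
    return TimeSeries(t=np.asarray(rec_t), data=data, solver="dde")


# ---------------------------------------------------------------------------
# classic constant-volume SSA
# ---------------------------------------------------------------------------

def classic_ssa(model: Model, t_end: float, seed: int,
                volume: float = DEFAULT_V_BIRTH,
                gene_copies: Optional[dict[str, int]] = None,
                grid_dt: float = 1.0) -> TimeSeries:
    """Direct-method Gillespie SSA at constant volume.

    Genes are flattened into a fixed number of copies (``gene_copies`` or the
    gene's ``initial_copies`` or 1), each with its own promoter occupancy.
    Delayed reactions, growth and division are outside this solver's scope.

    This is an intentionally independent implementation used as an oracle
    for the growth engine in the zero-growth limit; it shares only the model
    data structures and the count-based propensity convention.
    """
    model.validate()
    omega = counts_per_uM(volume)
    rng = np.random.default_rng(seed)
    idx = model.species_index
    counts = [sp.initial_count for sp in model.species]

    # flatten reactions: (order_code, rate-ish, i1, i2, mods, dr, dp, km)
    rxns = []
    for r in model.reactions:
        if r.delay > 0:
            raise ModelError("classic_ssa does not support delayed reactions")
        dr = tuple((idx[s], n) for s, n in r.reactants.items())
        dp = tuple((idx[s], n) for s, n in r.products.items())
        mods = tuple(idx[s] for s, n in r.modifiers.items() for _ in range(n))
        if r.rate_law == MICHAELIS_MENTEN:
            rxns.append(("mm", r.rate, dr[0][0], mods[0], (), dr, dp,
                         r.km * omega))
        elif r.order == 0:
            base = (r.rate * omega if r.rate_units == "uM_per_second"
                    else r.rate)
            rxns.append(("c", base, -1, -1, mods, dr, dp, 0.0))
        elif r.order == 1:
            rxns.append(("1", r.rate, dr[0][0], -1, mods, dr, dp, 0.0))
        elif len(dr) == 1:
            rxns.append(("2s", r.rate / omega, dr[0][0], -1, mods, dr, dp,
                         0.0))
        else:
            rxns.append(("2", r.rate / omega, dr[0][0], dr[1][0], mods, dr,
                         dp, 0.0))

    copies = []
    for g in model.genes:
        n = 1
        if gene_copies and g.name in gene_copies:
            n = gene_copies[g.name]
        elif g.initial_copies is not None:
            n = g.initial_copies
        for _ in range(n):
            copies.append((g, [False] * g.promoter.n_sites))

    def propensities():
        props = []
        actions = []
        for code, base, i1, i2, mods, dr, dp, km in rxns:
            if code == "1":
                v = base * counts[i1]
            elif code == "2s":
                n = counts[i1]
                v = base * n * (n - 1)
            elif code == "2":
                v = base * counts[i1] * counts[i2]
            elif code == "c":
                v = base
            else:
                xs = counts[i1]
                v = base * counts[i2] * xs / (km + xs) if xs else 0.0
            for m in mods:
                v *= counts[m]
            props.append(v)
            actions.append(("rxn", dr, dp))
        for g, bound in copies:
            occ = tuple(bound)
            props.append(g.transcription_rate * g.promoter.factor(occ))
            actions.append(("tx", idx[g.mrna]))
            coop = g.promoter.binding_multiplier(occ)
            for si, site in enumerate(g.promoter.sites):
                tfi = idx[site.tf]
                if bound[si]:
                    props.append(site.k_off)
                    actions.append(("unbind", bound, si, tfi))
                else:
                    props.append(site.k_on * counts[tfi] / omega * coop)
                    actions.append(("bind", bound, si, tfi))
        return props, actions

    t = 0.0
    rec_t = [0.0]
    rec_c = [list(counts)]
    next_grid = grid_dt
    ubuf = rng.random(8192).tolist()
    ui = 0

    def next_u():
        nonlocal ui, ubuf
        if ui >= len(ubuf):
            ubuf = rng.random(8192).tolist()
            ui = 0
        u = ubuf[ui]
        ui += 1
        return u

    while True:
        props, actions = propensities()
        total = sum(props)
        if total <= 0.0:
            break
        u = next_u()
        while u <= 0.0:
            u = next_u()
        t -= math.log(u) / total
        if t >= t_end:
            break
        while next_grid < t:
            rec_t.append(next_grid)
            rec_c.append(list(counts))
            next_grid += grid_dt
        thresh = next_u() * total
        acc = 0.0
        for j, v in enumerate(props):
            acc += v
            if acc >= thresh:
                break
        act = actions[j]
        if act[0] == "rxn":
            for i, n in act[1]:
                counts[i] -= n
            for i, n in act[2]:
                counts[i] += n
        elif act[0] == "tx":
            counts[act[1]] += 1
        elif act[0] == "bind":
            counts[act[3]] -= 1
            act[1][act[2]] = True
        else:
            counts[act[3]] += 1
            act[1][act[2]] = False
    while next_grid < t_end:
        rec_t.append(next_grid)
        rec_c.append(list(counts))
        next_grid += grid_dt
    arr = np.asarray(rec_c, dtype=np.int64)
    data = {sp.name: arr[:, i] for i, sp in enumerate(model.species)}
    return TimeSeries(t=np.asarray(rec_t), data=data, solver="ssa")


# ---------------------------------------------------------------------------
# dynamic flux-balance ODEs
# ---------------------------------------------------------------------------

@dataclass
class FluxParams:
    """Parameters of the metabolic flux model (defaults as published)."""

    influx_m1: float = 100.0   # uM/s, medium uptake of M1
    r3: float = 1.0            # 1/s, utilization of M1 and M3
    r1: float = 1.0            # 1/s, mRNA degradation
    r2: float = 0.01           # 1/s, enzyme decay
    kc: float = 10.0           # 1/s, enzyme kcat
    km: float = 1.0            # uM, enzyme Km
    a: float = 1.0             # per gene per second, mRNA synthesis
    b: float = 1.0             # per mRNA per second, enzyme synthesis
    mu_per_min: float = 0.0139  # 1/min, dilution rate
    v_birth: float = DEFAULT_V_BIRTH
    init_metabolite: float = 50.0   # molecules
    init_enzyme: float = 100.0      # molecules
    init_mrna: float = 10.0         # molecules
    # optional gene-b overrides (None = same as gene a); a_b = 0 with
    # init_enzyme_b = 0 knocks the output branch out entirely
    a_b: Optional[float] = None
    init_enzyme_b: Optional[float] = None


_FLUX_NAMES = ("mRNA_a", "enzyme_a", "mRNA_b", "enzyme_b", "M1", "M2", "M3")


def integrate_flux_ode(params: Optional[FluxParams] = None,
                       positions: tuple[float, float] = (0.5, 0.5),
                       periods: Optional[CyclePeriods] = None,
                       t_end: float = 12000.0,
                       grid_dt: float = 5.0) -> TimeSeries:
    """Deterministic flux-balance dynamics with dosage-driven enzymes.

    Gene dosage enters as a piecewise-constant copy number over the cell
    cycle (doubling when the fork passes the locus); concentrations carry an
    explicit dilution term, so they are continuous across divisions.
    Integration proceeds segment by segment between dosage discontinuities.
    """
    p = params or FluxParams()
    periods = periods or CyclePeriods(T=50.0, C=40.0, D=20.0)
    omega0 = counts_per_uM(p.v_birth)
    T_s = periods.T * 60.0
    mu_s = p.mu_per_min / 60.0
    p_a, p_b = positions

    def gene_conc(pos: float, t: float) -> float:
        age_min = math.fmod(t, T_s) / 60.0
        n = copies_at_age(pos, periods, age_min)
        return n / (omega0 * 2.0 ** (age_min / periods.T))

    a_b = p.a if p.a_b is None else p.a_b

    def rhs(t, y):
        m_a, e_a, m_b, e_b, m1, m2, m3 = y
        flux_in = p.kc * e_a * m1 / (p.km + m1)
        flux_out = p.kc * e_b * m2 / (p.km + m2)
        return [
            p.a * gene_conc(p_a, t) - (p.r1 + mu_s) * m_a,
            p.b * m_a - (p.r2 + mu_s) * e_a,
            a_b * gene_conc(p_b, t) - (p.r1 + mu_s) * m_b,
            p.b * m_b - (p.r2 + mu_s) * e_b,
            p.influx_m1 - flux_in - (p.r3 + mu_s) * m1,
            flux_in - flux_out - mu_s * m2,
            flux_out - (p.r3 + mu_s) * m3,
        ]

    # breakpoints: divisions and each gene's doubling within every cycle
    breaks = {0.0, t_end}
    n_cycles = int(math.ceil(t_end / T_s))
    for k in range(n_cycles + 1):
        breaks.add(min(k * T_s, t_end))
        for pos in positions:
            tb = k * T_s + replication_age(pos, periods) * 60.0
            if tb < t_end:
                breaks.add(tb)
    edges = sorted(breaks)

    init_e_b = (p.init_enzyme if p.init_enzyme_b is None
                else p.init_enzyme_b)
    y = [p.init_mrna / omega0, p.init_enzyme / omega0,
         p.init_mrna / omega0, init_e_b / omega0,
         p.init_metabolite / omega0, p.init_metabolite / omega0,
         p.init_metabolite / omega0]
    ts = [0.0]
    ys = [list(y)]
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo <= 0:
            continue
        t_eval = np.append(np.arange(lo, hi, grid_dt), hi)
        sol = solve_ivp(rhs, (lo, hi), y, method="LSODA", t_eval=t_eval,
                        rtol=1e-8, atol=1e-12)
        if not sol.success:
            raise ModelError(f"flux ODE failed on [{lo}, {hi}]: {sol.message}")
        for i, ti in enumerate(sol.t):
            if ti <= ts[-1]:
                continue
            ts.append(float(ti))
            ys.append(list(sol.y[:, i]))
        y = list(sol.y[:, -1])

    arr = np.asarray(ys)
    data = {n: arr[:, i] for i, n in enumerate(_FLUX_NAMES)}
    return TimeSeries(t=np.asarray(ts), data=data, solver="ode")
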