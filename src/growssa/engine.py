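"""Stochastic simulation engine for growing cells.

The direct-method SSA is modified for exponential cell-volume growth: between
events the molecule counts are constant, so the total propensity is
``A + b*exp(-mu*s) + g*exp(mu*s)`` where ``A`` collects volume-independent
channels, ``b`` the inverse-volume (bimolecular) channels evaluated at the
current time, ``g`` the proportional-volume channels, and ``mu = ln2/T`` is
the volume growth rate.  Waiting times are sampled by inverting the
cumulative hazard; the ``A, b > 0, g = 0`` case has a closed form through the
principal branch of the Lambert W function, and every sampled time is
polished to a residual ``|Lambda(tau) - L| <= 1e-12 * (1 + L)``, which keeps
delayed-queue preemption honest (an imprecise inverse would starve
non-delayed channels).

Scheduled events (delayed product releases, gene replications) preempt the
sampled reaction: if an event falls inside the sampled waiting interval the
engine advances to it, executes it and resamples.  When a delayed release
and a replication share a timestamp the release is processed first.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import lambertw

from .model import (
    MICHAELIS_MENTEN,
    VOL_PROPORTIONAL,
    GeneInstance,
    Model,
    ModelError,
    RunConfig,
    counts_per_uM,
)
from .dosage import CyclePeriods, copies_at_birth, replication_age
from .noise import ou_step

#: Sentinel returned when the total hazard is bounded below the drawn level.
NO_FIRING = math.inf

# scheduled-event kinds, in tie-break priority order
EV_RELEASE = 0
EV_REPLICATION = 1

# compiled channel kinds
_K_CONST = 0      # base
_K_FIRST = 1      # base * X
_K_BI = 2         # base * X1 * X2 / volume factor
_K_BI_SAME = 3    # base * X * (X - 1) / volume factor
_K_PROP = 4       # base * volume factor
_K_MM = 5         # base * X_enz * X_sub / (km_counts * volfac + X_sub)
_K_BIND = 6       # base * X_tf / volume factor (promoter binding)

# propensity buckets
_B_A = 0
_B_INV = 1
_B_PROP = 2


def survival_integral(A: float, b: float, mu: float, tau: float,
                      g: float = 0.0) -> float:
    """Cumulative hazard Lambda(tau) over a waiting interval of length tau.

    ``Lambda(tau) = A*tau + (b/mu)*(1 - exp(-mu*tau)) + (g/mu)*(exp(mu*tau) - 1)``
    with the obvious ``mu -> 0`` limit; the no-reaction probability over tau
    is ``exp(-Lambda(tau))``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if mu == 0.0:
        return (A + b + g) * tau
    out = A * tau - (b / mu) * math.expm1(-mu * tau)
    if g:
        out += (g / mu) * math.expm1(mu * tau)
    return out


def _polish_root(A: float, b: float, g: float, mu: float, L: float,
                 tau: float) -> float:
    """Safeguarded Newton refinement of Lambda(tau) = L from a guess."""
    tol = 1e-12 * (1.0 + L)
    if tau <= 0.0 or not math.isfinite(tau):
        tau = L / (A + b + g)
    lo = 0.0
    hi = math.inf
    for _ in range(200):
        if g and mu * tau > 709.0:
            # hazard astronomically above L: bisect down without overflowing
            hi = tau
            tau = 0.5 * (lo + hi)
            continue
        f = A * tau - (b / mu) * math.expm1(-mu * tau) - L
        if g:
            f += (g / mu) * math.expm1(mu * tau)
        if abs(f) <= tol:
            return tau
        if f < 0.0:
            lo = tau
        else:
            hi = tau
        if g and f > 10.0 * (1.0 + L) and hi < math.inf:
            # on the exponential cliff Newton only creeps by ~1/mu per step
            tau = 0.5 * (lo + hi)
            continue
        fp = A + b * math.exp(-mu * tau) + (g * math.exp(mu * tau) if g else 0.0)
        cand = tau - f / fp if fp > 0.0 else math.inf
        if not (lo < cand < hi):
            cand = tau * 2.0 + 1.0 if hi == math.inf else 0.5 * (lo + hi)
        tau = cand
    return tau


def _invert_hazard(A: float, b: float, g: float, mu: float, L: float) -> float:
    """Solve Lambda(tau) = L for tau; returns NO_FIRING when unreachable."""
    total = A + b + g
    if total <= 0.0:
        return NO_FIRING
    if L <= 0.0:
        return 0.0
    if mu == 0.0:
        return L / total
    tau0 = L / total
    if mu * tau0 < 1e-4 and A > 0.0:
        # growth over one waiting interval is negligible: Newton from the
        # constant-hazard guess converges in one or two steps
        return _polish_root(A, b, g, mu, L, tau0)
    if g == 0.0:
        if b == 0.0:
            return L / A
        if A == 0.0:
            x = mu * L / b
            if x >= 1.0:
                return NO_FIRING
            return -math.log1p(-x) / mu
        # closed form: tau = c + W0((b/A) * exp(-mu*c)) / mu, c = (L - b/mu)/A
        c = (L - b / mu) / A
        z = math.log(b / A) - mu * c
        if z < 650.0:
            w = float(lambertw(math.exp(z)).real)
        else:
            # asymptotic W0(exp(z)) for arguments beyond float range
            w = z - math.log(z)
            for _ in range(4):
                w = z - math.log(w)
        tau = c + w / mu
        return _polish_root(A, b, g, mu, L, tau)
    # g > 0: the proportional term alone reaches L at log1p(mu*L/g)/mu,
    # which bounds the root from above
    tau0 = min(tau0, math.log1p(mu * L / g) / mu)
    return _polish_root(A, b, g, mu, L, tau0)


def sample_firing_time(A: float, b: float, g: float, mu: float,
                       r: float) -> float:
    """Sample the next-reaction waiting time from a uniform draw ``r``.

    Solves ``Lambda(tau) = -ln(r)``.  Returns :data:`NO_FIRING` (infinity)
    when the total hazard is bounded below ``-ln(r)`` (possible only when the
    surviving channels are all inverse-volume).
    """
    if not (0.0 < r < 1.0):
        raise ValueError("r must lie strictly in (0, 1)")
    if min(A, b, g) < 0 or mu < 0:
        raise ValueError("propensities and growth rate must be >= 0")
    return _invert_hazard(A, b, g, mu, -math.log(r))


@dataclass
class PropensitySplit:
    """Total propensity split by volume-scaling class at the current time."""

    A: float
    b: float
    g: float
    per_channel: list = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.A + self.b + self.g


class _Chan:
    """A compiled static reaction channel."""

    __slots__ = ("kind", "base", "i1", "i2", "mods", "delay", "dr", "dp",
                 "km_counts", "name", "noisy", "bucket")

    def __init__(self, kind, base, i1, i2, mods, delay, dr, dp, km_counts,
                 name, noisy):
        self.kind = kind
        self.base = base
        self.i1 = i1
        self.i2 = i2
        self.mods = mods
        self.delay = delay
        self.dr = dr
        self.dp = dp
        self.km_counts = km_counts
        self.name = name
        self.noisy = noisy
        self.bucket = (_B_INV if kind in (_K_BI, _K_BI_SAME)
                       else _B_PROP if kind == _K_PROP else _B_A)


class CompiledModel:
    """A model compiled against a run configuration.

    Rate constants are converted to molecule-count units exactly once, using
    the conversion factor at birth volume; time-dependent volume factors are
    applied analytically in the event loop.
    """

    def __init__(self, model: Model, config: RunConfig):
        model.validate()
        config.validate()
        self.model = model
        self.config = config
        self.periods = CyclePeriods(T=config.T, C=config.C, D=config.D)
        self.T_s = config.T_seconds
        self.mu = config.growth_rate
        self.omega0 = counts_per_uM(config.v_birth)
        self.idx = {sp.name: i for i, sp in enumerate(model.species)}
        self.n_species = len(model.species)
        self.partition_mask = np.array(
            [sp.partition_at_division for sp in model.species], dtype=bool
        )
        self.initial_counts = [sp.initial_count for sp in model.species]
        noisy_names = (set(config.noise.applied_to)
                       if config.noise is not None else set())
        self.noise = config.noise
        self.channels: list[_Chan] = [
            self._compile_reaction(r, noisy_names) for r in model.reactions
        ]
        self.genes = model.genes
        self.gene_index = {g.name: i for i, g in enumerate(model.genes)}
        self.gene_noisy = [g.name in noisy_names for g in model.genes]
        self.gene_tf_idx = [
            [self.idx[s.tf] for s in g.promoter.sites] for g in model.genes
        ]
        self.gene_mrna_idx = [self.idx[g.mrna] for g in model.genes]
        self.rep_age_s = [
            replication_age(g.position, self.periods) * 60.0
            for g in model.genes
        ]

    def _compile_reaction(self, r, noisy_names) -> _Chan:
        idx = self.idx
        dr = tuple((idx[s], n) for s, n in r.reactants.items())
        dp = tuple((idx[s], n) for s, n in r.products.items())
        mods = tuple(idx[s] for s, n in r.modifiers.items() for _ in range(n))
        vclass = r.resolved_volume_class()
        i1 = i2 = -1
        km_counts = 0.0
        if r.rate_law == MICHAELIS_MENTEN:
            kind = _K_MM
            base = r.rate
            i1 = idx[next(iter(r.reactants))]          # substrate
            i2 = mods[0]                               # enzyme
            mods = ()
            km_counts = r.km * self.omega0
        elif r.order == 2:
            ra = [(idx[s], n) for s, n in r.reactants.items()]
            base = r.rate / self.omega0
            if len(ra) == 1:
                kind = _K_BI_SAME
                i1 = ra[0][0]
            else:
                kind = _K_BI
                i1, i2 = ra[0][0], ra[1][0]
        elif r.order == 1:
            kind = _K_FIRST
            base = r.rate
            i1 = dr[0][0]
        else:  # order 0
            kind = _K_PROP if vclass == VOL_PROPORTIONAL else _K_CONST
            base = (r.rate * self.omega0 if r.rate_units == "uM_per_second"
                    else r.rate)
        return _Chan(kind, base, i1, i2, mods, r.delay, dr, dp, km_counts,
                     r.name, r.name in noisy_names)

    def volume(self, t: float, t_birth: float) -> float:
        return self.config.v_birth * math.exp(self.mu * (t - t_birth))


class Cell:
    """State of one simulated cell.

    ``counts`` is a plain list of integers for speed in the event loop; the
    propensity table (``_table``) caches one row per live channel and is
    rebuilt lazily whenever the channel structure changes (promoter state
    flips, gene replication).
    """

    __slots__ = ("cell_id", "parent_id", "t_birth", "t", "counts",
                 "instances", "queue", "rng", "noise_rng", "eta", "_seq",
                 "_next_iid", "traj_t", "traj_counts", "traj_copies",
                 "division_time", "copies", "_table", "_descs", "_buckets",
                 "_dirty")

    def __init__(self, cm: CompiledModel, cell_id: int = 0,
                 parent_id: Optional[int] = None, t_birth: float = 0.0,
                 counts: Optional[list] = None,
                 instances: Optional[list[GeneInstance]] = None,
                 queue: Optional[list] = None):
        self.cell_id = cell_id
        self.parent_id = parent_id
        self.t_birth = t_birth
        self.t = t_birth
        self.counts = (list(int(c) for c in counts) if counts is not None
                       else list(cm.initial_counts))
        self.rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cm.config.seed,
                                   spawn_key=(cell_id,)))
        self.noise_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cm.config.seed,
                                   spawn_key=(cell_id, 1)))
        self.eta = 0.0
        self._seq = 0
        self.queue = list(queue) if queue is not None else []
        heapq.heapify(self.queue)
        if instances is None:
            instances = []
            iid = 0
            for g in cm.genes:
                n = (g.initial_copies if g.initial_copies is not None
                     else copies_at_birth(g.position, cm.periods))
                for _ in range(n):
                    instances.append(GeneInstance(gene=g, instance_id=iid))
                    iid += 1
            self._next_iid = iid
        else:
            self._next_iid = 1 + max(
                (i.instance_id for i in instances), default=-1)
        self.instances = instances
        self.copies = [0] * len(cm.genes)
        for inst in self.instances:
            self.copies[cm.gene_index[inst.gene.name]] += 1
        self.division_time = t_birth + cm.T_s
        self.traj_t: list[float] = []
        self.traj_counts: list = []
        self.traj_copies: list = []
        self._table: list = []
        self._descs: list = []
        self._buckets: list = []
        self._dirty = True
        # schedule this cell's replication events
        for gi, age_s in enumerate(cm.rep_age_s):
            self.push_event(t_birth + age_s, EV_REPLICATION, gi)

    def push_event(self, time: float, kind: int, payload) -> None:
        if time < self.t:
            raise ModelError("scheduled event lies in the past")
        heapq.heappush(self.queue, (time, kind, self._seq, payload))
        self._seq += 1

    def record(self, t: float) -> None:
        self.traj_t.append(t)
        self.traj_counts.append(list(self.counts))
        self.traj_copies.append(list(self.copies))


def _rebuild_table(cell: Cell, cm: CompiledModel) -> None:
    """Rebuild the flat channel table after a structural change."""
    table = []
    descs = []
    buckets = []
    for ch in cm.channels:
        table.append((ch.kind, ch.base, ch.i1, ch.i2, ch.mods, ch.noisy,
                      ch.km_counts))
        descs.append(("rxn", ch))
        buckets.append(ch.bucket)
    for inst in cell.instances:
        gene = inst.gene
        gi = cm.gene_index[gene.name]
        prom = gene.promoter
        occ = inst.occupancy
        noisy = cm.gene_noisy[gi]
        table.append((_K_CONST,
                      gene.transcription_rate * prom.factor(occ),
                      -1, -1, (), noisy, 0.0))
        descs.append(("tx", inst, cm.gene_mrna_idx[gi], gene.delay))
        buckets.append(_B_A)
        if prom.sites:
            coop = prom.binding_multiplier(occ)
            tf_idx = cm.gene_tf_idx[gi]
            for si, site in enumerate(prom.sites):
                if inst.bound[si]:
                    table.append((_K_CONST, site.k_off, -1, -1, (), noisy,
                                  0.0))
                    descs.append(("unbind", inst, si, tf_idx[si]))
                    buckets.append(_B_A)
                else:
                    table.append((_K_BIND, site.k_on * coop / cm.omega0,
                                  tf_idx[si], -1, (), noisy, 0.0))
                    descs.append(("bind", inst, si, tf_idx[si]))
                    buckets.append(_B_INV)
    cell._table = table
    cell._descs = descs
    cell._buckets = buckets
    cell._dirty = False


def _scan_values(cell: Cell, cm: CompiledModel):
    """Evaluate every channel at the cell's current time.

    Returns (values, A, b, g): current per-channel propensities and their
    bucket totals.  Michaelis-Menten channels are evaluated at the current
    volume and treated as frozen over the waiting interval (the fractional
    volume change between successive events is negligible at the event rates
    such channels imply).
    """
    if cell._dirty:
        _rebuild_table(cell, cm)
    counts = cell.counts
    e = math.exp(cm.mu * (cell.t - cell.t_birth))
    inv = 1.0 / e
    nf = math.exp(cell.eta) if cm.noise is not None else 1.0
    vals = []
    append = vals.append
    A = b = g = 0.0
    for (kind, base, i1, i2, mods, noisy, km_counts) in cell._table:
        if kind == _K_FIRST:
            v = base * counts[i1]
        elif kind == _K_BI:
            v = base * counts[i1] * counts[i2] * inv
        elif kind == _K_BI_SAME:
            n = counts[i1]
            v = base * n * (n - 1) * inv
        elif kind == _K_CONST:
            v = base
        elif kind == _K_BIND:
            v = base * counts[i1] * inv
        elif kind == _K_PROP:
            v = base * e
        else:  # Michaelis-Menten
            xs = counts[i1]
            v = (base * counts[i2] * xs / (km_counts * e + xs)
                 if xs > 0 else 0.0)
        if mods:
            for m in mods:
                v *= counts[m]
        if noisy:
            v *= nf
        if v < 0.0:
            raise ModelError("negative propensity: internal consistency "
                             "failure (negative molecule count?)")
        append(v)
        if kind == _K_BI or kind == _K_BI_SAME or kind == _K_BIND:
            b += v
        elif kind == _K_PROP:
            g += v
        else:
            A += v
    return vals, A, b, g


def _channel_key(desc) -> object:
    if desc[0] == "rxn":
        return desc[1].name
    if desc[0] == "tx":
        return (desc[1].gene.name, desc[1].instance_id, "tx")
    return (desc[1].gene.name, desc[1].instance_id, desc[0], desc[2])


def compute_propensities(cell: Cell, cm: CompiledModel) -> PropensitySplit:
    """Split propensities by volume class at the cell's current time."""
    vals, A, b, g = _scan_values(cell, cm)
    keys = [_channel_key(d) for d in cell._descs]
    return PropensitySplit(A=A, b=b, g=g, per_channel=list(zip(keys, vals)))


def _select_index(vals, buckets, tau, mu, r2) -> int:
    """Pick the firing channel at time t + tau by cumulative propensity."""
    fb = math.exp(-mu * tau)
    fg = 1.0 / fb
    total = 0.0
    for v, bk in zip(vals, buckets):
        total += v * (fb if bk == _B_INV else fg if bk == _B_PROP else 1.0)
    if total <= 0.0:
        raise ModelError("select_channel called with zero total propensity")
    thresh = r2 * total
    acc = 0.0
    j = 0
    for j, (v, bk) in enumerate(zip(vals, buckets)):
        acc += v * (fb if bk == _B_INV else fg if bk == _B_PROP else 1.0)
        if acc >= thresh:
            return j
    return j


def select_channel(cell: Cell, cm: CompiledModel, t_fire: float, r2: float):
    """Channel key selected at ``t_fire`` given a uniform draw ``r2``."""
    vals, A, b, g = _scan_values(cell, cm)
    j = _select_index(vals, cell._buckets, t_fire - cell.t, cm.mu, r2)
    return _channel_key(cell._descs[j])


def _apply_products(cell: Cell, dp) -> None:
    counts = cell.counts
    for i, n in dp:
        counts[i] += n


def fire_reaction(cell: Cell, cm: CompiledModel, desc) -> None:
    """Apply the state change for a firing channel (descriptor form).

    Instantaneous channels apply their full stoichiometry now.  Delayed
    channels consume reactants now and enqueue the product release at
    ``t + delay``.  Promoter binding and unbinding update the specific gene
    instance and move the TF between the free pool and the bound site.
    """
    tag = desc[0]
    counts = cell.counts
    if tag == "rxn":
        ch = desc[1]
        for i, n in ch.dr:
            counts[i] -= n
            if counts[i] < 0:
                raise ModelError(
                    f"insufficient reactants firing {ch.name!r}: "
                    f"internal consistency failure")
        if ch.delay > 0.0:
            cell.push_event(cell.t + ch.delay, EV_RELEASE, (ch.dp, None))
        else:
            _apply_products(cell, ch.dp)
    elif tag == "tx":
        _, inst, mi, delay = desc
        if delay > 0.0:
            cell.push_event(cell.t + delay, EV_RELEASE,
                            (((mi, 1),), inst.instance_id))
        else:
            counts[mi] += 1
    elif tag == "bind":
        _, inst, si, tfi = desc
        counts[tfi] -= 1
        if counts[tfi] < 0:
            raise ModelError("TF binding without free TF: internal failure")
        inst.bound[si] = True
        cell._dirty = True
    elif tag == "unbind":
        _, inst, si, tfi = desc
        counts[tfi] += 1
        inst.bound[si] = False
        cell._dirty = True
    else:  # pragma: no cover
        raise ModelError(f"unknown channel descriptor {tag!r}")


def apply_replication(cell: Cell, cm: CompiledModel, gene_index: int) -> None:
    """Double the copy number of one gene.

    Every existing instance spawns an unbound twin; TFs bound to replicated
    instances dissociate into the free pool.  Segregation bits are reassigned
    (original 0, twin 1) so division hands each daughter one copy per pair.
    """
    gene = cm.genes[gene_index]
    tf_idx = cm.gene_tf_idx[gene_index]
    new_instances = []
    for inst in cell.instances:
        if inst.gene is not gene:
            continue
        for si, bound in enumerate(inst.bound):
            if bound:
                cell.counts[tf_idx[si]] += 1
                inst.bound[si] = False
        inst.segregation_bit = 0
        twin = GeneInstance(gene=gene, instance_id=cell._next_iid,
                            segregation_bit=1)
        cell._next_iid += 1
        new_instances.append(twin)
    cell.instances.extend(new_instances)
    cell.copies[gene_index] += len(new_instances)
    cell._dirty = True


def _execute_event(cell: Cell, cm: CompiledModel, kind: int, payload) -> None:
    if kind == EV_RELEASE:
        dp, _origin = payload
        _apply_products(cell, dp)
    else:
        apply_replication(cell, cm, payload)


@dataclass
class CellResult:
    """Trajectory of one cell between birth and division (or t_end)."""

    cell_id: int
    parent_id: Optional[int]
    t_birth: float
    t_final: float
    divided: bool
    times: np.ndarray
    counts: np.ndarray
    copies: np.ndarray

    def volumes(self, cm: CompiledModel) -> np.ndarray:
        return cm.config.v_birth * np.exp(cm.mu * (self.times - self.t_birth))


def run_cell(cell: Cell, cm: CompiledModel,
             t_end: Optional[float] = None) -> CellResult:
    """Simulate one cell until its division time or ``t_end``.

    Scheduled events falling exactly on the division time (a gene whose
    doubling coincides with division) are executed before the cell is handed
    to the division step.
    """
    config = cm.config
    if t_end is None:
        t_end = config.t_end
    t_stop = min(cell.division_time, t_end)
    mu = cm.mu
    grid_dt = config.grid_dt
    record_events = config.record_events
    noise = cm.noise
    rng = cell.rng
    if not math.isfinite(cell.t):
        raise ModelError("non-finite cell time")
    cell.record(cell.t)
    next_grid = cell.t + grid_dt
    ubuf = rng.random(4096).tolist()
    ui = 0
    queue = cell.queue

    def next_u() -> float:
        nonlocal ui, ubuf
        if ui >= len(ubuf):
            ubuf = rng.random(4096).tolist()
            ui = 0
        u = ubuf[ui]
        ui += 1
        return u

    def advance_to(t_new: float) -> None:
        nonlocal next_grid
        while next_grid < t_new:
            cell.record(next_grid)
            next_grid += grid_dt
        if noise is not None:
            cell.eta = ou_step(cell.eta, t_new - cell.t, noise, cell.noise_rng)
        cell.t = t_new

    while True:
        vals, A, b, g = _scan_values(cell, cm)
        total = A + b + g
        if total > 0.0:
            u = next_u()
            while u <= 0.0:
                u = next_u()
            tau = _invert_hazard(A, b, g, mu, -math.log(u))
        else:
            tau = NO_FIRING
        t_fire = cell.t + tau
        t_event = queue[0][0] if queue else math.inf
        if t_event <= t_fire and t_event <= t_stop:
            _, kind, _, payload = heapq.heappop(queue)
            advance_to(t_event)
            _execute_event(cell, cm, kind, payload)
            if record_events:
                cell.record(cell.t)
            continue
        if t_stop <= t_fire:
            advance_to(t_stop)
            cell.record(cell.t)
            break
        advance_to(t_fire)
        # channel values were evaluated before the jump; _select_index
        # rescales the volume-dependent buckets to t_fire
        j = _select_index(vals, cell._buckets, tau, mu, next_u())
        fire_reaction(cell, cm, cell._descs[j])
        if record_events:
            cell.record(cell.t)

    divided = (t_stop == cell.division_time and cell.division_time <= t_end)
    return CellResult(
        cell_id=cell.cell_id,
        parent_id=cell.parent_id,
        t_birth=cell.t_birth,
        t_final=cell.t,
        divided=divided,
        times=np.asarray(cell.traj_t),
        counts=np.asarray(cell.traj_counts, dtype=np.int64),
        copies=np.asarray(cell.traj_copies, dtype=np.int64),
    )
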