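"""Cell division, binomial partitioning and colony-level simulation.

Division is symmetric: at age T the mother's volume has doubled and each
daughter starts at the birth volume.  Free molecules are partitioned
binomially (p = 1/2, exactly conserving totals); gene instances are split by
segregation bit so each daughter receives an equal complement of gene copies
with their promoter occupancy states intact; pending delayed product releases
follow the originating gene instance when there is one and a fair coin
otherwise.  Both daughters are simulated onward, producing a full binary
lineage tree (truncated at t_end or max_cells).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import EV_RELEASE, Cell, CellResult, CompiledModel, run_cell
from .model import Model, ModelError, RunConfig


def partition_binomial(counts: np.ndarray, partition_mask: np.ndarray,
                       rng) -> tuple[np.ndarray, np.ndarray]:
    """Split molecule counts between two daughters.

    Partitionable species get ``d1 ~ Binomial(n, 1/2)`` and ``d2 = n - d1``
    (exact conservation); non-partitionable species are chromosome-associated
    bookkeeping entities and are copied to both daughters.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ModelError("negative counts at division")
    d1 = counts.copy()
    d2 = counts.copy()
    part = np.asarray(partition_mask, dtype=bool)
    drawn = rng.binomial(counts[part], 0.5)
    d1[part] = drawn
    d2[part] = counts[part] - drawn
    return d1, d2


def divide(cell: Cell, cm: CompiledModel, d1_id: int,
           d2_id: int) -> tuple[Cell, Cell]:
    """Divide a cell at its current time into two daughters."""
    rng = cell.rng
    c1, c2 = partition_binomial(cell.counts, cm.partition_mask, rng)

    groups: dict[str, list] = {}
    for inst in cell.instances:
        groups.setdefault(inst.gene.name, []).append(inst)
    inst1: list = []
    inst2: list = []
    # one flip per division so copies replicated in the same round
    # co-segregate; orientation is otherwise symmetric
    flip = bool(rng.random() < 0.5)
    for gname, insts in groups.items():
        g0 = [i for i in insts if i.segregation_bit == 0]
        g1 = [i for i in insts if i.segregation_bit == 1]
        if len(g0) != len(g1):
            raise ModelError(
                f"gene {gname!r}: odd copy complement at division "
                f"({len(g0)} vs {len(g1)}): internal scheduling error")
        a, bgrp = (g1, g0) if flip else (g0, g1)
        inst1.extend(a)
        inst2.extend(bgrp)
    for inst in inst1 + inst2:
        inst.segregation_bit = 0
    iids1 = {i.instance_id for i in inst1}

    q1: list = []
    q2: list = []
    for time, kind, seq, payload in cell.queue:
        if kind != EV_RELEASE:
            continue
        dp, origin = payload
        if origin is not None:
            to_first = origin in iids1
        else:
            to_first = bool(rng.random() < 0.5)
        (q1 if to_first else q2).append((time, kind, seq, payload))

    t_div = cell.t
    d1 = Cell(cm, cell_id=d1_id, parent_id=cell.cell_id, t_birth=t_div,
              counts=c1, instances=inst1, queue=q1)
    d2 = Cell(cm, cell_id=d2_id, parent_id=cell.cell_id, t_birth=t_div,
              counts=c2, instances=inst2, queue=q2)
    return d1, d2


@dataclass
class CellRecord:
    """One node of the lineage tree."""

    result: CellResult
    children: tuple[int, ...] = ()

    @property
    def cell_id(self) -> int:
        return self.result.cell_id

    @property
    def parent_id(self) -> Optional[int]:
        return self.result.parent_id

    @property
    def t_birth(self) -> float:
        return self.result.t_birth

    @property
    def t_division(self) -> Optional[float]:
        return self.result.t_final if self.result.divided else None


@dataclass
class LineageTree:
    """Binary tree of cell records with per-cell trajectories."""

    nodes: dict[int, CellRecord] = field(default_factory=dict)
    root_id: int = 0
    truncated: bool = False
    warnings: list[str] = field(default_factory=list)

    def cells(self) -> list[CellRecord]:
        return [self.nodes[k] for k in sorted(self.nodes)]

    def leaves(self) -> list[CellRecord]:
        return [rec for rec in self.cells() if not rec.children]

    def __len__(self) -> int:
        return len(self.nodes)


def time_weighted_mean(times: np.ndarray, values: np.ndarray) -> float:
    """Mean of a piecewise-constant (left value) series over its span."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2:
        return float(values[0]) if len(values) else math.nan
    dt = np.diff(times)
    span = times[-1] - times[0]
    if span <= 0:
        return float(values[0])
    return float(np.dot(values[:-1], dt) / span)


def cycle_mean(record: CellRecord, species_index: int) -> float:
    """Time-weighted mean count of one species over a cell's lifetime."""
    return time_weighted_mean(record.result.times,
                              record.result.counts[:, species_index])


def simulate_colony(model: Model, config: RunConfig,
                    cm: Optional[CompiledModel] = None) -> LineageTree:
    """Breadth-first simulation of a micro-colony from a single ancestor.

    Deterministic for a given seed: every cell draws from a substream keyed
    by (seed, cell_id) and cell ids are assigned in breadth-first order.
    """
    if cm is None:
        cm = CompiledModel(model, config)
    tree = LineageTree()
    pending: deque[Cell] = deque([Cell(cm, cell_id=0)])
    next_id = 1
    while pending:
        cell = pending.popleft()
        result = run_cell(cell, cm)
        children: tuple[int, ...] = ()
        # a division landing exactly on t_end still spawns daughters (with
        # empty trajectories), so a horizon of k*T yields 2**k leaves
        if result.divided and result.t_final <= config.t_end:
            if next_id + 2 > config.max_cells:
                tree.truncated = True
                tree.warnings.append(
                    f"max_cells={config.max_cells} reached; cell "
                    f"{cell.cell_id} not divided")
            else:
                d1, d2 = divide(cell, cm, next_id, next_id + 1)
                children = (next_id, next_id + 1)
                next_id += 2
                pending.append(d1)
                pending.append(d2)
        tree.nodes[cell.cell_id] = CellRecord(result=result, children=children)
    return tree


def lineage_correlation(tree: LineageTree, model: Model, species_a: str,
                        species_b: str) -> float:
    """Pearson correlation of cycle-averaged levels of two species across
    all cells of a lineage tree.  Returns NaN when either series is constant.
    """
    # cells with a zero-length lifetime (spawned exactly at t_end) have no
    # meaningful cycle average and are excluded
    recs = [rec for rec in tree.cells()
            if len(rec.result.times) >= 2
            and rec.result.times[-1] > rec.result.times[0]]
    if len(recs) < 3:
        raise ModelError("lineage_correlation needs at least 3 cells")
    idx = model.species_index
    ia, ib = idx[species_a], idx[species_b]
    a = np.array([cycle_mean(rec, ia) for rec in recs])
    b = np.array([cycle_mean(rec, ib) for rec in recs])
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def lineage_path(tree: LineageTree, which: int = 0) -> list[CellRecord]:
    """Follow one line of descent from the root (``which`` picks the child
    branch at every division)."""
    path = [tree.nodes[tree.root_id]]
    while path[-1].children:
        path.append(tree.nodes[path[-1].children[which]])
    return path


def concatenate_path(tree: LineageTree, species_index: int,
                     which: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated (times, counts) series along one line of descent."""
    ts, vs = [], []
    for rec in lineage_path(tree, which):
        ts.append(rec.result.times)
        vs.append(rec.result.counts[:, species_index])
    return np.concatenate(ts), np.concatenate(vs)
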