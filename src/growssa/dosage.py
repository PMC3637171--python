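"""Deterministic replication scheduling of chromosomal genes.

The chromosome is replicated by forks travelling at constant speed from the
origin (position 0) to the terminus (position 1) over the C-period, and the
cell divides a fixed D-period after termination.  Replication rounds initiate
once per generation; when C + D exceeds the generation time T, rounds overlap
and a locus is present in 2, 4 or 8 copies.

All scheduler arithmetic is in minutes; conversion to seconds happens at the
engine boundary.  A gene whose doubling falls exactly on division time is
counted as doubling *at* division: daughters inherit the pre-doubling count
(``replication_age`` returns T in that case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import GeneDef, ModelError


@dataclass(frozen=True)
class CyclePeriods:
    """Cell-cycle periods in minutes: generation time T, replication time C,
    post-termination division delay D."""

    T: float
    C: float = 40.0
    D: float = 20.0

    def __post_init__(self) -> None:
        if not (self.T > 0 and self.C > 0 and self.D > 0):
            raise ModelError("cycle periods T, C, D must all be > 0")
        if not all(math.isfinite(x) for x in (self.T, self.C, self.D)):
            raise ModelError("cycle periods must be finite")


@dataclass(frozen=True)
class ReplicationEvent:
    """A scheduled gene-doubling event at absolute time ``time`` seconds."""

    time: float
    gene: GeneDef
    kind: str = "replication"


def _check_position(p: float) -> None:
    if not (math.isfinite(p) and 0.0 <= p <= 1.0):
        raise ModelError(f"gene position must be finite and in [0, 1], got {p}")


def replication_age(p: float, periods: CyclePeriods) -> float:
    """Cell age (minutes) at which a locus at position ``p`` doubles.

    A fork passing position p at division-minus-(C*(1-p)+D) before a division
    corresponds, within a cycle of length T, to age T - ((C*(1-p)+D) mod T).
    Returns T when the doubling coincides with division.
    """
    _check_position(p)
    lead = periods.C * (1.0 - p) + periods.D
    rem = math.fmod(lead, periods.T)
    if rem == 0.0:
        return periods.T
    return periods.T - rem


def copies_at_birth(p: float, periods: CyclePeriods) -> int:
    """Copy number of the locus at cell birth (a power of two)."""
    _check_position(p)
    lead = periods.C * (1.0 - p) + periods.D
    return 2 ** int(math.floor(lead / periods.T))


def copies_at_age(p: float, periods: CyclePeriods, age: float) -> int:
    """Copy number of the locus at cell age ``age`` minutes (0 <= age < T)."""
    _check_position(p)
    if not (0.0 <= age < periods.T):
        raise ModelError(f"age must lie in [0, T), got {age}")
    birth = copies_at_birth(p, periods)
    return birth if age < replication_age(p, periods) else 2 * birth


def population_mean_dosage(p: float, periods: CyclePeriods) -> float:
    """Expected copy number under the exponential cell-age distribution.

    Equals 2**((C*(1-p)+D)/T), the expectation of :func:`copies_at_age`
    against the age density (2 ln2 / T) * 2**(-age/T).
    """
    _check_position(p)
    return 2.0 ** ((periods.C * (1.0 - p) + periods.D) / periods.T)


def max_copies_in_cycle(p: float, periods: CyclePeriods) -> int:
    """Maximum instantaneous copy number attained during one cell cycle."""
    birth = copies_at_birth(p, periods)
    if replication_age(p, periods) == periods.T:
        return birth
    return 2 * birth


def replication_schedule(
    genes: list[GeneDef],
    periods: CyclePeriods,
    t_birth: float,
    t_end: float,
) -> list[ReplicationEvent]:
    """Doubling events for every gene on [t_birth, t_end), in seconds.

    For each gene, events occur at ``t_birth + (replication_age + k*T) * 60``
    for all k >= 0 with event time < t_end.  Sorted ascending; ties broken by
    gene declaration order.
    """
    if not (t_end > t_birth):
        raise ModelError("replication_schedule requires t_end > t_birth")
    events: list[tuple[float, int]] = []
    T_s = periods.T * 60.0
    for gi, gene in enumerate(genes):
        age_s = replication_age(gene.position, periods) * 60.0
        t = t_birth + age_s
        while t < t_end:
            events.append((t, gi))
            t += T_s
    events.sort()
    return [ReplicationEvent(time=t, gene=genes[gi]) for t, gi in events]
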