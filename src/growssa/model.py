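"""Domain types and validation for species, reactions, genes and whole models.

Unit conventions
----------------
Internal simulation state is always integer molecule counts.  Concentrations
are expressed in micromolar (uM); the conversion factor for a cell of volume
``V`` litres is ``Omega = N_A * V * 1e-6`` molecules per uM.  Rate constants
are stored in the units they were declared with and converted exactly once
when a model is compiled against a birth volume.

Volume-scaling classes
----------------------
Each reaction channel belongs to one of three classes that determine how its
propensity depends on the (exponentially growing) cell volume:

* ``independent`` -- propensity does not depend on volume (zeroth- and
  first-order channels, per-gene transcription).
* ``inverse`` -- propensity scales as 1/V (bimolecular channels).
* ``proportional`` -- propensity scales as V (concentration-defined influxes,
  e.g. a medium uptake flux given in uM/sec).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

AVOGADRO = 6.02214076e23
#: Default birth volume in litres (typical E. coli).
DEFAULT_V_BIRTH = 1.1e-15


def counts_per_uM(volume_litres: float) -> float:
    """Conversion factor Omega: molecules per uM for a cell of given volume."""
    return AVOGADRO * volume_litres * 1e-6


VOL_INDEPENDENT = "independent"
VOL_INVERSE = "inverse"
VOL_PROPORTIONAL = "proportional"
VOLUME_CLASSES = frozenset({VOL_INDEPENDENT, VOL_INVERSE, VOL_PROPORTIONAL})

RATE_UNITS = frozenset(
    {
        "per_second",
        "per_uM_per_second",
        "uM_per_second",
        "per_gene_per_second",
        "per_mRNA_per_second",
    }
)

MASS_ACTION = "mass_action"
MICHAELIS_MENTEN = "michaelis_menten"
RATE_LAWS = frozenset({MASS_ACTION, MICHAELIS_MENTEN})


class ModelError(ValueError):
    """Raised when a model definition fails validation."""


@dataclass(frozen=True)
class SpeciesDef:
    """A molecular species.

    ``partition_at_division`` is True for freely diffusing molecules, which
    are split binomially between daughters; chromosome-bound entities are
    handled through gene instances instead and should set it to False.
    """

    name: str
    initial_count: int = 0
    partition_at_division: bool = True

    def validate(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ModelError("species name must be a non-empty string")
        if self.initial_count < 0:
            raise ModelError(f"species {self.name!r}: initial_count must be >= 0")


@dataclass
class ReactionDef:
    """One reaction channel.

    ``reactants`` are consumed when the reaction initiates; ``products`` are
    released (immediately, or after ``delay`` seconds for delayed channels).
    ``modifiers`` are catalytic templates: their counts multiply the
    propensity but they are never consumed (e.g. mRNA in translation).

    ``rate_law`` is ``mass_action`` by default; ``michaelis_menten`` channels
    use propensity ``rate * X_enzyme * X_substrate / (km * Omega(t) + X_substrate)``
    where the enzyme is the (single) modifier and km is in uM.
    """

    name: str
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    rate: float = 0.0
    rate_units: str = "per_second"
    volume_class: Optional[str] = None
    delay: float = 0.0
    modifiers: Mapping[str, int] = field(default_factory=dict)
    rate_law: str = MASS_ACTION
    km: Optional[float] = None

    @property
    def order(self) -> int:
        return sum(self.reactants.values())

    def resolved_volume_class(self) -> str:
        """Volume class after applying defaults (order-2 -> inverse)."""
        if self.volume_class is not None:
            return self.volume_class
        if self.rate_law == MASS_ACTION and self.order == 2:
            return VOL_INVERSE
        return VOL_INDEPENDENT

    def validate(self, species_names: Iterable[str]) -> None:
        names = set(species_names)
        if not self.name:
            raise ModelError("reaction name must be non-empty")
        for role, mapping in (
            ("reactant", self.reactants),
            ("product", self.products),
            ("modifier", self.modifiers),
        ):
            for sp, st in mapping.items():
                if sp not in names:
                    raise ModelError(
                        f"reaction {self.name!r}: unknown {role} species {sp!r}"
                    )
                if st <= 0 or int(st) != st:
                    raise ModelError(
                        f"reaction {self.name!r}: {role} stoichiometry must be a "
                        f"positive integer, got {st!r}"
                    )
        if not math.isfinite(self.rate) or self.rate < 0:
            raise ModelError(f"reaction {self.name!r}: negative or non-finite rate")
        if self.rate_units not in RATE_UNITS:
            raise ModelError(
                f"reaction {self.name!r}: unknown rate units {self.rate_units!r}"
            )
        if self.delay < 0:
            raise ModelError(f"reaction {self.name!r}: delay must be >= 0")
        if self.rate_law not in RATE_LAWS:
            raise ModelError(f"reaction {self.name!r}: unknown rate law {self.rate_law!r}")
        vclass = self.resolved_volume_class()
        if vclass not in VOLUME_CLASSES:
            raise ModelError(
                f"reaction {self.name!r}: unknown volume class {self.volume_class!r}"
            )
        if self.rate_law == MASS_ACTION:
            order = self.order
            if order > 2:
                raise ModelError(
                    f"reaction {self.name!r}: order {order} > 2 not supported"
                )
            if vclass == VOL_INVERSE and order != 2:
                raise ModelError(
                    f"reaction {self.name!r}: inverse-volume class is only valid "
                    f"for order-2 channels (order is {order})"
                )
            if order == 2 and self.rate_units != "per_uM_per_second":
                raise ModelError(
                    f"reaction {self.name!r}: order-2 channels must carry "
                    f"per_uM_per_second rate units, got {self.rate_units!r}"
                )
        else:  # Michaelis-Menten
            if len(self.modifiers) != 1:
                raise ModelError(
                    f"reaction {self.name!r}: michaelis_menten needs exactly one "
                    f"modifier (the enzyme)"
                )
            if len(self.reactants) != 1 or self.order != 1:
                raise ModelError(
                    f"reaction {self.name!r}: michaelis_menten needs exactly one "
                    f"substrate with stoichiometry 1"
                )
            if self.km is None or self.km <= 0:
                raise ModelError(f"reaction {self.name!r}: km must be positive")


def stoichiometric_order(reaction: ReactionDef) -> int:
    """Total reactant stoichiometry of a reaction channel (0, 1 or 2)."""
    return reaction.order


@dataclass
class BindingSite:
    """A transcription-factor binding site on a promoter.

    ``k_on`` is the binding rate constant (per-uM-per-second, mass action
    against the free TF pool); ``k_off`` the unbinding rate (per second).
    ``bound_factor`` multiplies the transcription rate while the site is
    occupied (e.g. 0.1 for a 10-fold repressor).
    """

    tf: str
    k_on: float
    k_off: float
    bound_factor: float = 1.0


@dataclass
class PromoterLogic:
    """Occupancy-dependent transcription and binding modulation.

    The transcription-rate factor for an occupancy state defaults to the
    product of ``bound_factor`` over occupied sites (1 for the unoccupied
    state); ``state_factors`` may override specific states.  ``cooperativity``
    maps an occupancy state to a multiplier on the binding rates of the
    still-free sites while the promoter is in that state.
    """

    sites: list[BindingSite] = field(default_factory=list)
    state_factors: dict[tuple[bool, ...], float] = field(default_factory=dict)
    cooperativity: dict[tuple[bool, ...], float] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def factor(self, occupancy: tuple[bool, ...]) -> float:
        if occupancy in self.state_factors:
            return self.state_factors[occupancy]
        f = 1.0
        for site, bound in zip(self.sites, occupancy):
            if bound:
                f *= site.bound_factor
        return f

    def binding_multiplier(self, occupancy: tuple[bool, ...]) -> float:
        return self.cooperativity.get(occupancy, 1.0)

    def validate(self, species_names: Iterable[str], gene_name: str) -> None:
        names = set(species_names)
        for site in self.sites:
            if site.tf not in names:
                raise ModelError(
                    f"gene {gene_name!r}: binding site references unknown "
                    f"species {site.tf!r}"
                )
            if site.k_on < 0 or site.k_off < 0:
                raise ModelError(f"gene {gene_name!r}: negative binding rate")
            if site.bound_factor <= 0:
                raise ModelError(f"gene {gene_name!r}: bound factor must be > 0")
        unocc = tuple(False for _ in self.sites)
        if unocc in self.state_factors and self.state_factors[unocc] != 1.0:
            raise ModelError(
                f"gene {gene_name!r}: unoccupied promoter state must have factor 1"
            )
        for state, f in self.state_factors.items():
            if len(state) != self.n_sites:
                raise ModelError(f"gene {gene_name!r}: state/site length mismatch")
            if f <= 0:
                raise ModelError(f"gene {gene_name!r}: state factor must be > 0")


@dataclass
class GeneDef:
    """A chromosomal gene.

    ``position`` is the fractional distance of the locus from the replication
    origin (0) to the terminus (1) along the fork path; it sets when in the
    cell cycle the gene's copy number doubles.  ``transcription_rate`` is in
    transcripts per gene copy per second; ``delay`` optionally postpones mRNA
    release.  ``initial_copies`` overrides the scheduler-derived copy number
    at birth (used for constant-dosage comparisons).
    """

    name: str
    position: float
    transcription_rate: float
    mrna: str
    promoter: PromoterLogic = field(default_factory=PromoterLogic)
    delay: float = 0.0
    initial_copies: Optional[int] = None

    def validate(self, species_names: Iterable[str]) -> None:
        if not (0.0 <= self.position <= 1.0):
            raise ModelError(
                f"gene {self.name!r}: position must lie in [0, 1], "
                f"got {self.position}"
            )
        if self.transcription_rate < 0:
            raise ModelError(f"gene {self.name!r}: negative transcription rate")
        if self.mrna not in set(species_names):
            raise ModelError(
                f"gene {self.name!r}: unknown mRNA species {self.mrna!r}"
            )
        if self.delay < 0:
            raise ModelError(f"gene {self.name!r}: delay must be >= 0")
        if self.initial_copies is not None and self.initial_copies < 1:
            raise ModelError(f"gene {self.name!r}: initial_copies must be >= 1")
        self.promoter.validate(species_names, self.name)


@dataclass
class GeneInstance:
    """One live copy of a gene, with an independently regulated promoter.

    ``segregation_bit`` tags which daughter chromosome complement the copy
    belongs to after its last replication; it drives the split at division.
    ``bound`` holds the current occupancy of each promoter site.
    """

    gene: GeneDef
    instance_id: int
    segregation_bit: int = 0
    bound: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bound:
            self.bound = [False] * self.gene.promoter.n_sites

    @property
    def occupancy(self) -> tuple[bool, ...]:
        return tuple(self.bound)


@dataclass
class OUParams:
    """Parameters of the shared multiplicative Ornstein-Uhlenbeck noise."""

    tau_c: float
    sigma: float
    applied_to: frozenset[str] = frozenset()
    shared: bool = True

    def validate(self) -> None:
        if self.tau_c <= 0:
            raise ModelError("extrinsic noise: tau_c must be > 0")
        if self.sigma < 0:
            raise ModelError("extrinsic noise: sigma must be >= 0")


@dataclass
class RunConfig:
    """Simulation configuration.

    Periods ``T`` (generation time), ``C`` (replication) and ``D``
    (post-termination delay) are in minutes; all other times in seconds.
    """

    T: float = 50.0
    C: float = 40.0
    D: float = 20.0
    v_birth: float = DEFAULT_V_BIRTH
    t_end: float = 3000.0
    seed: int = 0
    grid_dt: float = 1.0
    max_cells: int = 4096
    record_events: bool = True
    noise: Optional[OUParams] = None

    def validate(self) -> None:
        for attr in ("T", "C", "D", "v_birth", "t_end", "grid_dt"):
            if getattr(self, attr) <= 0:
                raise ModelError(f"config: {attr} must be > 0")
        if self.max_cells < 1:
            raise ModelError("config: max_cells must be >= 1")
        if self.noise is not None:
            self.noise.validate()

    @property
    def T_seconds(self) -> float:
        return self.T * 60.0

    @property
    def growth_rate(self) -> float:
        """Exponential volume growth rate mu = ln2 / T in 1/s."""
        return math.log(2.0) / self.T_seconds


@dataclass
class Model:
    """A validated gene-circuit model.

    Gene-derived channels (transcription, TF binding/unbinding) are generated
    per live gene instance at simulation time and are not listed statically
    in ``reactions``.
    """

    species: list[SpeciesDef] = field(default_factory=list)
    reactions: list[ReactionDef] = field(default_factory=list)
    genes: list[GeneDef] = field(default_factory=list)
    name: str = "model"

    def validate(self) -> "Model":
        seen: set[str] = set()
        for sp in self.species:
            sp.validate()
            if sp.name in seen:
                raise ModelError(f"duplicate species name {sp.name!r}")
            seen.add(sp.name)
        rnames: set[str] = set()
        for r in self.reactions:
            r.validate(seen)
            if r.name in rnames:
                raise ModelError(f"duplicate reaction name {r.name!r}")
            rnames.add(r.name)
        gnames: set[str] = set()
        for g in self.genes:
            g.validate(seen)
            if g.name in gnames or g.name in rnames:
                raise ModelError(f"duplicate gene name {g.name!r}")
            gnames.add(g.name)
        return self

    @property
    def species_index(self) -> dict[str, int]:
        return {sp.name: i for i, sp in enumerate(self.species)}

    def species_def(self, name: str) -> SpeciesDef:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)


def _parse_state_key(key) -> tuple[bool, ...]:
    """Occupancy-state key: '01'-style string or sequence of truthy values."""
    if isinstance(key, str):
        return tuple(ch == "1" for ch in key)
    return tuple(bool(b) for b in key)


def _state_key_str(state: tuple[bool, ...]) -> str:
    return "".join("1" if b else "0" for b in state)


def _parse_promoter(entry: Mapping, gene_name: str) -> PromoterLogic:
    sites = [
        BindingSite(
            tf=s["tf"],
            k_on=float(s["k_on"]),
            k_off=float(s["k_off"]),
            bound_factor=float(s.get("bound_factor", 1.0)),
        )
        for s in entry.get("sites", [])
    ]
    state_factors = {
        _parse_state_key(k): float(v)
        for k, v in (entry.get("state_factors") or {}).items()
    }
    cooperativity = {
        _parse_state_key(k): float(v)
        for k, v in (entry.get("cooperativity") or {}).items()
    }
    return PromoterLogic(sites=sites, state_factors=state_factors,
                         cooperativity=cooperativity)


_SPECIES_KEYS = {"name", "initial_count", "partition_at_division"}
_REACTION_KEYS = {"name", "reactants", "products", "rate", "rate_units",
                  "volume_class", "delay", "modifiers", "rate_law", "km"}
_GENE_KEYS = {"name", "position", "transcription_rate", "mrna", "promoter",
              "delay", "initial_copies"}


def _check_keys(entry: Mapping, allowed: set[str], what: str) -> None:
    for key in entry:
        if key not in allowed:
            raise ModelError(f"unknown key {key!r} in {what}")


def build_model(definition) -> Model:
    """Build and validate a :class:`Model` from a structured description.

    ``definition`` is either an already-assembled :class:`Model` (validated
    and returned) or a mapping with ``species`` / ``reactions`` / ``genes``
    sections as produced by :func:`growssa.io.read_model`.
    """
    if isinstance(definition, Model):
        return definition.validate()
    if not isinstance(definition, Mapping):
        raise ModelError("model definition must be a mapping or a Model")

    species = []
    for entry in definition.get("species", []):
        _check_keys(entry, _SPECIES_KEYS, "species entry")
        species.append(
            SpeciesDef(
                name=entry["name"],
                initial_count=int(entry.get("initial_count", 0)),
                partition_at_division=bool(entry.get("partition_at_division", True)),
            )
        )
    reactions = []
    for entry in definition.get("reactions", []):
        _check_keys(entry, _REACTION_KEYS, "reaction entry")
        reactions.append(
            ReactionDef(
                name=entry["name"],
                reactants={k: int(v) for k, v in (entry.get("reactants") or {}).items()},
                products={k: int(v) for k, v in (entry.get("products") or {}).items()},
                rate=float(entry["rate"]),
                rate_units=entry.get("rate_units", "per_second"),
                volume_class=entry.get("volume_class"),
                delay=float(entry.get("delay", 0.0)),
                modifiers={k: int(v) for k, v in (entry.get("modifiers") or {}).items()},
                rate_law=entry.get("rate_law", MASS_ACTION),
                km=(float(entry["km"]) if entry.get("km") is not None else None),
            )
        )
    genes = []
    for entry in definition.get("genes", []):
        _check_keys(entry, _GENE_KEYS, "gene entry")
        genes.append(
            GeneDef(
                name=entry["name"],
                position=float(entry["position"]),
                transcription_rate=float(entry["transcription_rate"]),
                mrna=entry["mrna"],
                promoter=_parse_promoter(entry.get("promoter") or {}, entry["name"]),
                delay=float(entry.get("delay", 0.0)),
                initial_copies=(int(entry["initial_copies"])
                                if entry.get("initial_copies") is not None else None),
            )
        )
    model = Model(species=species, reactions=reactions, genes=genes,
                  name=definition.get("name", "model"))
    return model.validate()


def model_to_dict(model: Model) -> dict:
    """Inverse of :func:`build_model` for mapping input (round-trip safe)."""
    out: dict = {"name": model.name, "species": [], "reactions": [], "genes": []}
    for sp in model.species:
        out["species"].append(
            {"name": sp.name, "initial_count": sp.initial_count,
             "partition_at_division": sp.partition_at_division}
        )
    for r in model.reactions:
        entry = {
            "name": r.name,
            "reactants": dict(r.reactants),
            "products": dict(r.products),
            "rate": r.rate,
            "rate_units": r.rate_units,
            "delay": r.delay,
        }
        if r.volume_class is not None:
            entry["volume_class"] = r.volume_class
        if r.modifiers:
            entry["modifiers"] = dict(r.modifiers)
        if r.rate_law != MASS_ACTION:
            entry["rate_law"] = r.rate_law
            entry["km"] = r.km
        out["reactions"].append(entry)
    for g in model.genes:
        entry = {
            "name": g.name,
            "position": g.position,
            "transcription_rate": g.transcription_rate,
            "mrna": g.mrna,
            "delay": g.delay,
        }
        if g.initial_copies is not None:
            entry["initial_copies"] = g.initial_copies
        prom: dict = {}
        if g.promoter.sites:
            prom["sites"] = [
                {"tf": s.tf, "k_on": s.k_on, "k_off": s.k_off,
                 "bound_factor": s.bound_factor}
                for s in g.promoter.sites
            ]
        if g.promoter.state_factors:
            prom["state_factors"] = {
                _state_key_str(k): v for k, v in g.promoter.state_factors.items()
            }
        if g.promoter.cooperativity:
            prom["cooperativity"] = {
                _state_key_str(k): v for k, v in g.promoter.cooperativity.items()
            }
        if prom:
            entry["promoter"] = prom
        out["genes"].append(entry)
    return out
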