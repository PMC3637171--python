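import dataclasses

import pytest

from growssa.model import (
    BindingSite,
    GeneDef,
    Model,
    PromoterLogic,
    ReactionDef,
    RunConfig,
    SpeciesDef,
)


@pytest.fixture
def autoreg_model():
    """The negative-autoregulation circuit assembled in code."""
    return Model(
        name="autoreg",
        species=[SpeciesDef("mRNA"), SpeciesDef("protein"),
                 SpeciesDef("dimer")],
        reactions=[
            ReactionDef("translation", modifiers={"mRNA": 1},
                        products={"protein": 1}, rate=1.0,
                        rate_units="per_mRNA_per_second"),
            ReactionDef("mrna_decay", reactants={"mRNA": 1}, rate=2.0),
            ReactionDef("protein_decay", reactants={"protein": 1}, rate=0.01),
            ReactionDef("dimerization", reactants={"protein": 2},
                        products={"dimer": 1}, rate=1.0,
                        rate_units="per_uM_per_second"),
            ReactionDef("dimer_dissociation", reactants={"dimer": 1},
                        products={"protein": 2}, rate=1.0),
        ],
        genes=[
            GeneDef("gene", position=0.05, transcription_rate=1.0,
                    mrna="mRNA", initial_copies=2,
                    promoter=PromoterLogic(sites=[
                        BindingSite("dimer", k_on=100.0, k_off=0.1,
                                    bound_factor=0.1)])),
        ],
    ).validate()


@pytest.fixture
def base_config():
    return RunConfig(T=200.0, C=40.0, D=20.0, t_end=3000.0, seed=1,
                     grid_dt=10.0, record_events=False)


@pytest.fixture
def birth_death_model():
    """Constitutive two-copy gene with first-order mRNA decay."""
    return Model(
        name="bd",
        species=[SpeciesDef("mRNA")],
        reactions=[ReactionDef("decay", reactants={"mRNA": 1}, rate=2.0)],
        genes=[GeneDef("g", position=0.0, transcription_rate=1.0,
                       mrna="mRNA", initial_copies=2)],
    ).validate()


@pytest.fixture
def silent_gene_model():
    """One gene, no transcription, no reactions: dosage dynamics only."""
    return Model(
        name="silent",
        species=[SpeciesDef("x")],
        reactions=[],
        genes=[GeneDef("g", position=0.0, transcription_rate=0.0, mrna="x")],
    ).validate()


def make_config(**kw):
    base = dict(T=200.0, C=40.0, D=20.0, t_end=3000.0, seed=1,
                grid_dt=10.0, record_events=False)
    base.update(kw)
    return RunConfig(**base)


@pytest.fixture
def config_factory():
    return make_config
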