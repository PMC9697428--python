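import numpy as np
import pytest

import dgdose as dg


@pytest.fixture
def table1_particle():
    """GSH-coated AgNP as characterised in EMEM + 10% FBS."""
    return dg.ParticleSpec(
        material="Ag",
        density=10.49,
        effective_density=8.58,
        distribution=dg.monodisperse(4.5),
        diameter_sd_nm=1.7,
    )


def small_scenario(
    c0=0.01,
    n=20,
    dt=10.0,
    total_h=0.5,
    interval_min=6.0,
    diameters_nm=(50.0,),
    fractions=None,
    effective_density=2.0,
    k_s=0.0,
    k_d=0.0,
    dissolution=None,
    stickiness=False,
    K_D=None,
    viscosity=0.0081,
    name="small",
):
    """A fast, fully-specified scenario on a 1 mm column with 0.05 mm
    compartments — small enough for property tests, large enough to exercise
    every mechanism."""
    fractions = fractions if fractions is not None else (1.0,) * len(diameters_nm)
    particle = dg.ParticleSpec(
        material="user_defined",
        density=4.0,
        effective_density=effective_density,
        distribution=dg.SizeDistribution(tuple(diameters_nm), tuple(fractions), "volume"),
    )
    solvent = dg.SolventSpec(density=1.0, viscosity=viscosity, temperature=37.0)
    sim = dg.SimulationConfig(
        column_height=1.0,
        compartment_height=1.0 / n,
        initial_concentration=c0,
        total_time=total_h,
        time_step=dt,
    )
    adv = dg.AdvancedConfig(
        k_s=k_s,
        k_d=k_d,
        dissolution=dissolution if dissolution is not None else dg.DissolutionSpec(),
        stickiness_enabled=stickiness,
        adsorption_dissociation_constant=K_D,
    )
    out = dg.OutputSpec(output_interval=interval_min, output_layer_height=1.0 / n)
    return dg.validate_scenario(particle, solvent, sim, adv, out, name=name)


@pytest.fixture
def small_scenario_factory():
    return small_scenario
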