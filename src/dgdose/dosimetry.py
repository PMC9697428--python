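"""Distorted-grid (DG) particokinetics for in vitro nanoparticle dosimetry.

Adherent cells at the bottom of a culture well are exposed to the
nanoparticle concentration in the liquid layer directly above them, not to
the nominal (as-dispersed) concentration.  This module simulates the fate
and transport of a nanoparticle dispersion in the quiescent liquid column of
a culture well — Stokes sedimentation and Stokes–Einstein diffusion per size
bin on a 1-D compartment grid, optional dissolution and an optional Langmuir
"stickiness" attachment condition at the well floor — and converts the
simulated concentration field into the delivered-dose metrics used in
nanotoxicology: mass, particle number and particle surface area, per volume
of the bottom layer or per unit area of the well floor.

The file is organised in the order a simulation runs:

1.  physical constants, material densities, logging;
2.  scenario model — input types, validation, unit conversion, and the six
    bundled Ag/Au case-study fixtures;
3.  particokinetics — pointwise coefficient formulas (settling velocity,
    diffusion coefficient, concentration-dependence corrections, Langmuir
    coverage, molar particle concentration, weighting conversions);
4.  transport solver — compartment grid, implicit finite-volume step,
    bottom attachment, dissolution bookkeeping, the simulation driver, and
    the Mason–Weaver closed-form equilibrium used as its analytic oracle;
5.  dose metrics — layer aggregation, mass→number/surface-area conversion,
    bottom-layer time series, median summaries, dose–response re-keying;
6.  file I/O — JSON scenario configs, size-distribution CSVs, result CSVs
    and run metadata.

Internally everything is CGS (cm, g, s, poise, K) with mass concentrations
in mg/cm³; user-facing inputs keep the units of the lab bench (mm, nm, °C,
hours, minutes) and are converted exactly once at validation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

__all__ = [
    "GRAVITY",
    "BOLTZMANN",
    "AVOGADRO",
    "MATERIAL_DENSITIES",
    "ScenarioError",
    "ConfigError",
    "SizeDistribution",
    "monodisperse",
    "ParticleSpec",
    "SolventSpec",
    "SimulationConfig",
    "DissolutionSpec",
    "AdvancedConfig",
    "OutputSpec",
    "Scenario",
    "validate_scenario",
    "CASE_STUDY_SOLVENT",
    "case_study_names",
    "case_study_concentrations",
    "case_study_scenario",
    "case_study_scenarios",
    "settling_velocity",
    "diffusion_coefficient",
    "correct_sedimentation",
    "correct_diffusion",
    "molar_particle_concentration",
    "langmuir_coverage",
    "convert_weighting",
    "CoefficientTable",
    "build_coefficients",
    "GridSpec",
    "build_grid",
    "graded_grid",
    "SimState",
    "BottomBoundaryState",
    "initialize",
    "step",
    "attach_at_bottom",
    "apply_dissolution",
    "Snapshot",
    "SimulationResult",
    "simulate",
    "mason_weaver_profile",
    "mason_weaver_layer_means",
    "aggregate_layers",
    "number_concentration",
    "surface_area_concentration",
    "bottom_series",
    "median_summary",
    "DoseMetricsRow",
    "summary_table",
    "join_dose_response",
    "scenario_to_dict",
    "scenario_from_dict",
    "read_config",
    "read_distribution_csv",
    "timeseries_table",
    "RunManifest",
    "write_outputs",
]

logger = logging.getLogger("dgdose")

# ---------------------------------------------------------------------------
# Physical constants (CGS; fixed, never user-settable)
# ---------------------------------------------------------------------------

GRAVITY = 980.665  # cm/s², standard gravity
BOLTZMANN = 1.380649e-16  # erg/K
AVOGADRO = 6.02214076e23  # /mol

#: Bulk densities (g/cm³) of the selectable core materials; handbook values.
#: "user_defined" particles must supply their own density.
MATERIAL_DENSITIES: dict[str, float] = {
    "CeO2": 7.22,
    "SiO2": 2.65,
    "Fe2O3": 5.24,
    "TiO2": 4.23,
    "CuO": 6.31,
    "ZnO": 5.61,
    "Au": 19.30,
    "Ag": 10.49,
    "FePO4": 3.06,
}

_MM = 0.1  # mm -> cm
_NM = 1e-7  # nm -> cm
_HOUR = 3600.0  # h -> s
_MINUTE = 60.0  # min -> s

ALL_METRICS = ("mass", "number", "surface_area")


class ScenarioError(ValueError):
    """A scenario field violates an invariant; the message names the field."""


class ConfigError(ValueError):
    """A config file is malformed; the message names the offending key path."""


def _require(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ScenarioError(f"{fieldname}: {message}")


# ---------------------------------------------------------------------------
# Scenario model: input types, validation, case-study fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeDistribution:
    """Discrete hydrodynamic size distribution.

    ``bins`` maps diameter (nm) to fraction; ``weighting`` declares whether
    fractions are volume-weighted (relative mass) or number-weighted
    (relative particle count).  Validation sorts by diameter and normalises
    fractions to sum to one.
    """

    diameters_nm: tuple[float, ...]
    fractions: tuple[float, ...]
    weighting: str = "volume"  # "volume" | "number"

    def validated(self) -> "SizeDistribution":
        _require(self.weighting in ("volume", "number"), "distribution.weighting",
                 f"must be 'volume' or 'number', got {self.weighting!r}")
        d = np.asarray(self.diameters_nm, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        _require(d.size > 0, "distribution", "needs at least one bin")
        _require(d.size == f.size, "distribution", "diameters and fractions differ in length")
        _require(bool(np.all(d > 0)), "distribution.diameters", "all diameters must be > 0")
        _require(bool(np.all(f >= 0)), "distribution.fractions", "fractions must be >= 0")
        order = np.argsort(d)
        d, f = d[order], f[order]
        _require(bool(np.all(np.diff(d) > 0)), "distribution.diameters",
                 "diameters must be distinct (strictly increasing after sorting)")
        total = float(f.sum())
        _require(total > 0, "distribution.fractions", "fractions sum to zero")
        if abs(total - 1.0) > 1e-9:
            logger.warning("size distribution fractions sum to %.6g; renormalising", total)
            f = f / total
        return SizeDistribution(tuple(d.tolist()), tuple(f.tolist()), self.weighting)

    @property
    def diameters_cm(self) -> np.ndarray:
        return np.asarray(self.diameters_nm, dtype=float) * _NM


def monodisperse(diameter_nm: float, weighting: str = "volume") -> SizeDistribution:
    """Single-bin distribution (weighting is immaterial for one bin)."""
    return SizeDistribution((float(diameter_nm),), (1.0,), weighting)


@dataclass(frozen=True)
class ParticleSpec:
    """Nanoparticle material and agglomerate properties.

    ``effective_density`` is the density of the particle–medium agglomerate
    unit (ρ_EV); for porous agglomerates it is below the material density,
    and it may also sit below the solvent density (buoyant particles), which
    is legal.  ``diameter_sd_nm`` is metadata only (measurement spread); the
    transport model uses the distribution bins.
    """

    material: str
    density: float  # g/cm³, bulk material
    effective_density: float  # g/cm³, agglomerate (ρ_EV)
    distribution: SizeDistribution
    diameter_sd_nm: float | None = None

    def validated(self) -> "ParticleSpec":
        _require(self.density > 0, "particle.density", "must be > 0 g/cm³")
        _require(self.effective_density > 0, "particle.effective_density", "must be > 0 g/cm³")
        return dataclasses.replace(self, distribution=self.distribution.validated())


@dataclass(frozen=True)
class SolventSpec:
    """Culture-medium properties: density (g/cm³), viscosity (poise), T (°C)."""

    density: float
    viscosity: float
    temperature: float  # °C

    def validated(self) -> "SolventSpec":
        _require(self.density > 0, "solvent.density", "must be > 0 g/cm³")
        _require(self.viscosity > 0, "solvent.viscosity", "must be > 0 poise")
        _require(self.temperature > -273.15, "solvent.temperature", "must exceed absolute zero")
        return self

    @property
    def temperature_k(self) -> float:
        return self.temperature + 273.15


@dataclass(frozen=True)
class SimulationConfig:
    """Column geometry and time stepping.

    column_height / compartment_height in mm, initial_concentration in
    mg/cm³, total_time in hours, time_step in seconds.  The column must
    divide evenly into compartments.
    """

    column_height: float
    compartment_height: float
    initial_concentration: float
    total_time: float
    time_step: float

    def validated(self) -> "SimulationConfig":
        _require(self.column_height > 0, "simulation.column_height", "must be > 0 mm")
        _require(0 < self.compartment_height <= self.column_height,
                 "simulation.compartment_height", "must satisfy 0 < h <= column height")
        ratio = self.column_height / self.compartment_height
        _require(abs(ratio - round(ratio)) <= 1e-9 * ratio + 1e-12,
                 "simulation.compartment_height",
                 f"column height / compartment height = {ratio:.6g} is not an integer")
        _require(self.initial_concentration >= 0,
                 "simulation.initial_concentration", "must be >= 0 mg/cm³")
        _require(self.total_time > 0, "simulation.total_time", "must be > 0 h")
        _require(self.time_step > 0, "simulation.time_step", "must be > 0 s")
        return self


@dataclass(frozen=True)
class DissolutionSpec:
    """Dissolution bookkeeping: an initial dissolved fraction plus either no
    further dissolution, a constant fraction of the original particulate
    mass per hour, or a tabulated cumulative dissolved fraction vs time (h).
    """

    initial_dissolved_fraction: float = 0.0
    rate_type: str = "none"  # "none" | "constant_per_hour" | "tabulated"
    rate: float = 0.0  # fraction of original mass per hour
    table: tuple[tuple[float, float], ...] = ()

    def validated(self) -> "DissolutionSpec":
        f0 = self.initial_dissolved_fraction
        _require(0.0 <= f0 <= 1.0, "dissolution.initial_dissolved_fraction", "must lie in [0, 1]")
        _require(self.rate_type in ("none", "constant_per_hour", "tabulated"),
                 "dissolution.rate_type", f"unknown rate type {self.rate_type!r}")
        if self.rate_type == "constant_per_hour":
            _require(self.rate >= 0, "dissolution.rate", "must be >= 0 per hour")
        if self.rate_type == "tabulated":
            _require(len(self.table) >= 1, "dissolution.table", "must have at least one row")
            times = [t for t, _ in self.table]
            fracs = [f for _, f in self.table]
            _require(all(b > a for a, b in zip(times, times[1:])),
                     "dissolution.table", "times must be strictly increasing")
            _require(all(b >= a for a, b in zip(fracs, fracs[1:])),
                     "dissolution.table", "cumulative fractions must be non-decreasing")
            _require(all(0.0 <= f <= 1.0 for f in fracs),
                     "dissolution.table", "fractions must lie in [0, 1]")
        return self


@dataclass(frozen=True)
class AdvancedConfig:
    """Concentration-dependence constants, dissolution and stickiness.

    k_s and k_d are the dimensionless sedimentation- and diffusion-
    concentration dependence constants (typical range 0 to 0.1; 0 disables
    the correction).  When ``stickiness_enabled`` the bottom boundary
    adsorbs arriving particles with Langmuir-limited efficiency governed by
    the adsorption dissociation constant K_D (mol/cm³).
    """

    k_s: float = 0.0
    k_d: float = 0.0
    dissolution: DissolutionSpec = field(default_factory=DissolutionSpec)
    stickiness_enabled: bool = False
    adsorption_dissociation_constant: float | None = None

    def validated(self) -> "AdvancedConfig":
        _require(self.k_s >= 0, "advanced.k_s", "must be >= 0")
        _require(self.k_d >= 0, "advanced.k_d", "must be >= 0")
        if self.stickiness_enabled:
            kd = self.adsorption_dissociation_constant
            _require(kd is not None and kd > 0,
                     "advanced.adsorption_dissociation_constant",
                     "must be > 0 mol/cm³ when stickiness is enabled")
        return dataclasses.replace(self, dissolution=self.dissolution.validated())


@dataclass(frozen=True)
class OutputSpec:
    """What to record: snapshot interval (min), output layer height (mm,
    a multiple of the compartment height), dose metrics, bottom-only flag.
    Mass is always computed; number/surface_area are optional extras.
    """

    output_interval: float = 60.0
    output_layer_height: float | None = None  # defaults to compartment height
    metrics: tuple[str, ...] = ALL_METRICS
    bottom_only: bool = False

    def validated(self) -> "OutputSpec":
        _require(self.output_interval > 0, "output.output_interval", "must be > 0 min")
        for m in self.metrics:
            _require(m in ALL_METRICS, "output.metrics", f"unknown metric {m!r}")
        metrics = tuple(dict.fromkeys(("mass",) + tuple(self.metrics)))  # mass always on
        return dataclasses.replace(self, metrics=metrics)


@dataclass(frozen=True)
class Scenario:
    """A fully validated simulation scenario (sections in bench units;
    CGS-converted values exposed as properties)."""

    particle: ParticleSpec
    solvent: SolventSpec
    simulation: SimulationConfig
    advanced: AdvancedConfig
    output: OutputSpec
    name: str = "scenario"

    # -- CGS views ----------------------------------------------------------
    @property
    def column_height_cm(self) -> float:
        return self.simulation.column_height * _MM

    @property
    def compartment_height_cm(self) -> float:
        return self.simulation.compartment_height * _MM

    @property
    def output_layer_height_cm(self) -> float:
        h_out = self.output.output_layer_height
        if h_out is None:
            return self.compartment_height_cm
        return h_out * _MM

    @property
    def total_time_s(self) -> float:
        return self.simulation.total_time * _HOUR

    @property
    def time_step_s(self) -> float:
        return self.simulation.time_step

    @property
    def output_interval_s(self) -> float:
        return self.output.output_interval * _MINUTE

    @property
    def temperature_k(self) -> float:
        return self.solvent.temperature_k

    @property
    def volume_fractions(self) -> np.ndarray:
        """Distribution as volume (mass) fractions — C is mass-based."""
        return np.asarray(
            convert_weighting(self.particle.distribution, "volume").fractions, dtype=float
        )

    @property
    def diameters_cm(self) -> np.ndarray:
        return self.particle.distribution.diameters_cm


def validate_scenario(
    particle: ParticleSpec,
    solvent: SolventSpec,
    simulation: SimulationConfig,
    advanced: AdvancedConfig | None = None,
    output: OutputSpec | None = None,
    name: str = "scenario",
) -> Scenario:
    """Check every invariant, normalise the distribution and cross-check the
    time grid; returns an immutable :class:`Scenario`.

    Raises :class:`ScenarioError` naming the offending field on any
    violation.
    """
    advanced = advanced if advanced is not None else AdvancedConfig()
    output = output if output is not None else OutputSpec()
    scn = Scenario(
        particle=particle.validated(),
        solvent=solvent.validated(),
        simulation=simulation.validated(),
        advanced=advanced.validated(),
        output=output.validated(),
        name=name,
    )
    # cross-field time/geometry consistency
    interval_s = scn.output_interval_s
    dt = scn.time_step_s
    _require(_is_multiple(interval_s, dt), "output.output_interval",
             f"{interval_s} s is not a multiple of the time step {dt} s")
    _require(_is_multiple(scn.total_time_s, interval_s), "simulation.total_time",
             f"{scn.total_time_s} s is not a multiple of the output interval {interval_s} s")
    h_out = scn.output_layer_height_cm
    h = scn.compartment_height_cm
    _require(h_out >= h - 1e-12 * h, "output.output_layer_height",
             "must be at least the compartment height")
    _require(_is_multiple(h_out, h), "output.output_layer_height",
             f"{h_out} cm is not a multiple of the compartment height {h} cm")
    return scn


def _is_multiple(a: float, b: float) -> bool:
    ratio = a / b
    return abs(ratio - round(ratio)) <= 1e-9 * max(ratio, 1.0)


# -- bundled case studies ----------------------------------------------------
# Six coated Ag/Au nanoparticles characterised in EMEM + 10% FBS: material,
# bulk density (g/cm³), effective density (g/cm³), hydrodynamic diameter
# mean ± sd (nm, 100% volume fraction), and the solver time step (s) used
# for each in the case studies.

_CASE_STUDY_PARTICLES: dict[str, tuple[str, float, float, float, float, float]] = {
    "AOT-AgNP": ("Ag", 10.49, 8.58, 48.1, 2.0, 0.5),
    "PLL-AgNP": ("Ag", 10.49, 8.58, 24.2, 2.6, 0.5),
    "CYS-AgNP": ("Ag", 10.49, 8.58, 6.6, 1.5, 2.0),
    "GSH-AgNP": ("Ag", 10.49, 8.58, 4.5, 1.7, 2.0),
    "CYS-AuNP": ("Au", 19.30, 17.73, 18.7, 11.1, 2.0),
    "GSH-AuNP": ("Au", 19.30, 17.73, 3.9, 1.2, 2.0),
}

#: Nominal exposure concentrations (mg/cm³) per particle family.
_CONC_AOT_PLL = (0.00125, 0.0025, 0.005, 0.01, 0.02, 0.04, 0.08, 0.16)
_CONC_CYS_GSH = (0.001, 0.005, 0.01, 0.05, 0.1, 0.3)

#: Cell-culture medium (EMEM + 10% FBS) at 37 °C as characterised for the
#: case studies.
CASE_STUDY_SOLVENT = SolventSpec(density=0.9995, viscosity=0.00081, temperature=37.0)


def case_study_names() -> tuple[str, ...]:
    """Names of the six bundled case-study nanoparticles."""
    return tuple(_CASE_STUDY_PARTICLES)


def case_study_concentrations(name: str) -> tuple[float, ...]:
    """Nominal concentrations (mg/cm³) screened for a case-study particle."""
    _lookup_case_study(name)
    return _CONC_AOT_PLL if name in ("AOT-AgNP", "PLL-AgNP") else _CONC_CYS_GSH


def _lookup_case_study(name: str) -> tuple[str, float, float, float, float, float]:
    try:
        return _CASE_STUDY_PARTICLES[name]
    except KeyError:
        raise ScenarioError(
            f"fixture: unknown case-study particle {name!r}; "
            f"choose from {', '.join(_CASE_STUDY_PARTICLES)}"
        ) from None


def case_study_scenario(name: str, concentration: float) -> Scenario:
    """One bundled case-study scenario: 96-well plate geometry (3 mm column,
    0.005 mm compartments), 24 h exposure, hourly output on 0.01 mm layers,
    no dissolution, no stickiness, k_s = k_d = 0."""
    material, density, eff_density, d_nm, sd_nm, dt = _lookup_case_study(name)
    particle = ParticleSpec(
        material=material,
        density=density,
        effective_density=eff_density,
        distribution=monodisperse(d_nm),
        diameter_sd_nm=sd_nm,
    )
    sim = SimulationConfig(
        column_height=3.0,
        compartment_height=0.005,
        initial_concentration=concentration,
        total_time=24.0,
        time_step=dt,
    )
    out = OutputSpec(output_interval=60.0, output_layer_height=0.01)
    return validate_scenario(particle, CASE_STUDY_SOLVENT, sim, AdvancedConfig(), out,
                             name=f"{name}@{concentration:g}")


def case_study_scenarios() -> list[Scenario]:
    """All bundled scenarios: each particle crossed with its concentration
    series (8 for AOT-/PLL-AgNP, 6 for the CYS/GSH particles)."""
    return [
        case_study_scenario(name, c)
        for name in case_study_names()
        for c in case_study_concentrations(name)
    ]


# ---------------------------------------------------------------------------
# Particokinetics: pointwise coefficient formulas
# ---------------------------------------------------------------------------


def settling_velocity(
    diameter: float, effective_density: float, solvent_density: float, viscosity: float
) -> float:
    """Stokes terminal settling velocity (cm/s), positive toward the well
    bottom:  V = g (ρ_EV − ρ_f) d² / (18 μ).

    The agglomerate effective density ρ_EV drives settling; buoyant
    agglomerates (ρ_EV < ρ_f) rise (negative V).  diameter in cm,
    densities in g/cm³, viscosity in poise.
    """
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0 cm, got {diameter}")
    if viscosity <= 0:
        raise ValueError(f"viscosity must be > 0 poise, got {viscosity}")
    return GRAVITY * (effective_density - solvent_density) * diameter**2 / (18.0 * viscosity)


def diffusion_coefficient(diameter: float, temperature: float, viscosity: float) -> float:
    """Stokes–Einstein diffusion coefficient (cm²/s) for a sphere of
    hydrodynamic diameter d (cm):  D = k_B T / (3 π μ d)."""
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0 cm, got {diameter}")
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    if viscosity <= 0:
        raise ValueError(f"viscosity must be > 0 poise, got {viscosity}")
    return BOLTZMANN * temperature / (3.0 * math.pi * viscosity * diameter)


def correct_sedimentation(S, k_s: float, C):
    """Hindered-settling correction  S′ = S / (1 + k_s C).

    Transport slows as the local concentration C (mg/cm³) rises; k_s = 0
    leaves S unchanged.  Accepts scalars or arrays.
    """
    if not np.isscalar(C):
        C = np.asarray(C, dtype=float)
    return S / (1.0 + k_s * C)


def correct_diffusion(D, k_d: float, C):
    """Hindered-diffusion correction  D′ = D / (1 + k_d C); k_d = 0 is the
    identity."""
    if not np.isscalar(C):
        C = np.asarray(C, dtype=float)
    return D / (1.0 + k_d * C)


def molar_particle_concentration(
    C_p: float, effective_density: float, radius: float
) -> float:
    """Particle molar concentration [P] (mol/cm³) from the mass
    concentration C_p (mg/cm³):

        [P] = C_p / (N_A · ρ_EV · (4/3) π r³)

    with ρ_EV converted to mg/cm³ so the per-particle mass is in mg.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0 cm, got {radius}")
    particle_mass_mg = (effective_density * 1e3) * (4.0 / 3.0) * math.pi * radius**3
    return C_p / particle_mass_mg / AVOGADRO


def langmuir_coverage(P: float, K_D: float) -> float:
    """Langmuir surface coverage  θ = [P] / (K_D + [P]) ∈ [0, 1)."""
    if K_D <= 0:
        raise ValueError(f"K_D must be > 0 mol/cm³, got {K_D}")
    if P < 0:
        raise ValueError(f"[P] must be >= 0 mol/cm³, got {P}")
    return P / (K_D + P)


def convert_weighting(dist: SizeDistribution, target: str) -> SizeDistribution:
    """Convert between volume- and number-weighted fractions.

    A particle of diameter d carries mass ∝ d³, so
    number→volume multiplies fractions by d³ and volume→number divides,
    renormalising either way.  Same-weighting requests are the identity.
    """
    if target not in ("volume", "number"):
        raise ValueError(f"target weighting must be 'volume' or 'number', got {target!r}")
    if target == dist.weighting:
        return dist
    d = np.asarray(dist.diameters_nm, dtype=float)
    f = np.asarray(dist.fractions, dtype=float)
    w = f * d**3 if target == "volume" else f / d**3
    w = w / w.sum()
    return SizeDistribution(dist.diameters_nm, tuple(w.tolist()), target)


@dataclass(frozen=True)
class CoefficientTable:
    """Per-size-bin transport coefficients: Stokes settling velocity S_i
    (cm/s, positive downward) and Stokes–Einstein diffusion coefficient D_i
    (cm²/s).  ``corrected`` applies the concentration-dependence
    corrections per compartment."""

    sedimentation: np.ndarray  # (n_bins,)
    diffusion: np.ndarray  # (n_bins,)

    def corrected(self, C_bin: np.ndarray, k_s: float, k_d: float, i: int):
        """Corrected per-compartment S′_{i,j}, D′_{i,j} for bin ``i`` given
        that bin's compartment concentrations ``C_bin`` (mg/cm³)."""
        S = correct_sedimentation(self.sedimentation[i], k_s, C_bin)
        D = correct_diffusion(self.diffusion[i], k_d, C_bin)
        return S, D


def build_coefficients(scenario: Scenario) -> CoefficientTable:
    """Uncorrected S_i and D_i for every bin of a scenario."""
    solv = scenario.solvent
    d = scenario.diameters_cm
    S = np.array([
        settling_velocity(di, scenario.particle.effective_density, solv.density, solv.viscosity)
        for di in d
    ])
    D = np.array([
        diffusion_coefficient(di, scenario.temperature_k, solv.viscosity) for di in d
    ])
    return CoefficientTable(S, D)


# ---------------------------------------------------------------------------
# Transport solver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Vertical compartment grid.  Index 0 is the bottom compartment (cell
    surface side), increasing upward.  Heights (cm) are uniform by default;
    graded spacing (refinement toward the bottom) is supported through an
    explicit heights array."""

    heights: np.ndarray  # (N,) cm, bottom first

    @property
    def n(self) -> int:
        return int(self.heights.size)

    @property
    def total_height(self) -> float:
        return float(self.heights.sum())

    @property
    def edges(self) -> np.ndarray:
        """Compartment edge z-coordinates (cm), bottom face first (z=0)."""
        return np.concatenate(([0.0], np.cumsum(self.heights)))

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])


def build_grid(column_height: float, compartment_height: float) -> GridSpec:
    """Uniform grid of N = H/h compartments (heights in cm); H/h must be an
    integer within 1e-9 relative."""
    if column_height <= 0 or compartment_height <= 0:
        raise ScenarioError("grid: column and compartment heights must be > 0")
    ratio = column_height / compartment_height
    n = round(ratio)
    if abs(ratio - n) > 1e-9 * max(ratio, 1.0):
        raise ScenarioError(
            f"grid: column height {column_height} cm is not an integer multiple "
            f"of compartment height {compartment_height} cm (ratio {ratio:.9g})"
        )
    return GridSpec(np.full(n, column_height / n))


def graded_grid(column_height: float, n: int, ratio: float = 1.0) -> GridSpec:
    """Geometrically graded grid with ``n`` compartments whose heights grow
    by ``ratio`` upward from the bottom (ratio 1 is uniform); total height is
    exactly ``column_height``."""
    if n < 1 or column_height <= 0 or ratio <= 0:
        raise ScenarioError("grid: need n >= 1, column_height > 0 and ratio > 0")
    weights = ratio ** np.arange(n)
    return GridSpec(column_height * weights / weights.sum())


@dataclass
class SimState:
    """Mutable simulation state.

    C[i, j]: particulate mass concentration (mg/cm³) of size bin i in
    compartment j (j = 0 bottom).  ``adsorbed`` (mg/cm²) is the irreversible
    bottom-surface pool per bin; ``dissolved_fraction`` is the cumulative
    dissolved share of the original total mass.  ``clamped_mass`` audits any
    negativity clamping (mg/cm², cumulative).
    """

    time: float
    C: np.ndarray  # (n_bins, N)
    adsorbed: np.ndarray  # (n_bins,)
    dissolved_fraction: float
    initial_total_mass_per_area: float  # mg/cm²
    clamped_mass: float = 0.0

    def particulate_mass_per_area(self, grid: GridSpec) -> float:
        return float(self.C.sum(axis=0) @ grid.heights)

    def total_mass_per_area(self, grid: GridSpec) -> float:
        return (
            self.particulate_mass_per_area(grid)
            + float(self.adsorbed.sum())
            + self.dissolved_fraction * self.initial_total_mass_per_area
        )

    def copy(self) -> "SimState":
        return SimState(self.time, self.C.copy(), self.adsorbed.copy(),
                        self.dissolved_fraction, self.initial_total_mass_per_area,
                        self.clamped_mass)


@dataclass
class BottomBoundaryState:
    """Langmuir boundary bookkeeping: coverage θ ∈ [0,1], per-bin adsorbed
    mass per area (mg/cm²), and the bottom-compartment particle molar
    concentration [P] (mol/cm³)."""

    coverage: float = 0.0
    adsorbed_mass_per_area: np.ndarray | None = None
    molar_concentration: float = 0.0


def initialize(scenario: Scenario, grid: GridSpec | None = None) -> SimState:
    """Uniform initial state: C_{i,j} = C₀ (1 − f_diss,0) f_vol,i everywhere
    (fractions converted to volume weighting, since C is mass-based)."""
    grid = grid if grid is not None else build_grid(
        scenario.column_height_cm, scenario.compartment_height_cm)
    f0 = scenario.advanced.dissolution.initial_dissolved_fraction
    c0 = scenario.simulation.initial_concentration
    fractions = scenario.volume_fractions
    C = np.outer(fractions, np.full(grid.n, c0 * (1.0 - f0)))
    return SimState(
        time=0.0,
        C=C,
        adsorbed=np.zeros(fractions.size),
        dissolved_fraction=f0,
        initial_total_mass_per_area=c0 * grid.total_height,
    )


def _banded_system(
    grid: GridSpec, s_cells: np.ndarray, d_cells: np.ndarray, dt: float
) -> np.ndarray:
    """Backward-Euler finite-volume matrix for one bin, in LAPACK banded
    (3, N) layout.

    First-order upwind advection (velocity positive downward, i.e. toward
    compartment 0) and central diffusion on possibly non-uniform heights;
    zero-flux boundaries at both the floor and the free surface.  Column
    sums equal h_j/Δt, which is what makes the step exactly conservative.
    """
    h = grid.heights
    n = h.size
    s_cells = np.broadcast_to(s_cells, (n,))
    d_cells = np.broadcast_to(d_cells, (n,))
    delta = 0.5 * (h[:-1] + h[1:])  # centre-to-centre distance across interface
    s_int = 0.5 * (s_cells[:-1] + s_cells[1:])
    d_int = 0.5 * (d_cells[:-1] + d_cells[1:])
    a = d_int / delta
    sp = np.maximum(s_int, 0.0)  # downward advection: donor is the upper cell
    sm = np.maximum(-s_int, 0.0)  # upward advection (buoyant): donor is the lower cell
    diag = h / dt
    diag[: n - 1] = diag[: n - 1] + sm + a
    diag[1:] = diag[1:] + sp + a
    ab = np.zeros((3, n))
    ab[1] = diag
    ab[0, 1:] = -(sp + a)  # super-diagonal: coupling to the cell above
    ab[2, : n - 1] = -(sm + a)  # sub-diagonal: coupling to the cell below
    return ab


def step(
    state: SimState,
    grid: GridSpec,
    coefficients: CoefficientTable,
    dt: float,
    k_s: float = 0.0,
    k_d: float = 0.0,
    _cache: list[np.ndarray] | None = None,
) -> SimState:
    """Advance the particulate field by one implicit transport step.

    Per bin, solves backward-Euler ∂C/∂t = ∂/∂z(D′ ∂C/∂z) − ∂(S′C)/∂z with
    zero-flux (reflective) boundaries; coefficient corrections are evaluated
    from the current per-bin compartment concentrations.  Mass is conserved
    to round-off; any negative round-off is clamped to zero and audited in
    ``state.clamped_mass``.  Mutates and returns ``state``.
    """
    hc = grid.heights / dt
    for i in range(state.C.shape[0]):
        c = state.C[i]
        if _cache is not None:
            ab = _cache[i]
        else:
            S, D = coefficients.corrected(c, k_s, k_d, i)
            ab = _banded_system(grid, S, D, dt)
        try:
            c_new = solve_banded((1, 1), ab, hc * c, check_finite=False)
        except Exception as exc:  # singular system
            raise RuntimeError(
                f"transport solve failed for size bin {i} at t = {state.time:.6g} s: {exc}"
            ) from exc
        neg = c_new < 0.0
        if neg.any():
            state.clamped_mass += float(-(c_new[neg] @ grid.heights[neg]))
            c_new[neg] = 0.0
        state.C[i] = c_new
    state.time += dt
    return state


def attach_at_bottom(
    state: SimState,
    grid: GridSpec,
    coefficients: CoefficientTable,
    advanced: AdvancedConfig,
    effective_density: float,
    diameters_cm: np.ndarray,
    dt: float,
) -> BottomBoundaryState:
    """Langmuir attachment at the well floor.

    Computes the bottom-compartment particle molar concentration [P]
    (per bin, summed) and the coverage θ, then irreversibly transfers the
    settling mass flux arriving at the floor during Δt into the adsorbed
    pool, scaled by the free-surface fraction (1 − θ); the remainder is
    reflected.  Mutates ``state`` and returns the boundary bookkeeping.
    """
    if not advanced.stickiness_enabled:
        return BottomBoundaryState(adsorbed_mass_per_area=state.adsorbed)
    c_bottom = state.C[:, 0]
    P = sum(
        molar_particle_concentration(float(c_bottom[i]), effective_density,
                                     0.5 * float(diameters_cm[i]))
        for i in range(c_bottom.size)
    )
    theta = langmuir_coverage(P, advanced.adsorption_dissociation_constant)
    h0 = grid.heights[0]
    for i in range(c_bottom.size):
        s_eff = correct_sedimentation(
            float(coefficients.sedimentation[i]), advanced.k_s, float(c_bottom[i]))
        if s_eff <= 0.0:
            continue  # buoyant/neutral bins deliver no settling flux to the floor
        transfer = min((1.0 - theta) * s_eff * dt, h0) * float(c_bottom[i])
        state.C[i, 0] -= transfer / h0
        state.adsorbed[i] += transfer
    return BottomBoundaryState(coverage=theta, adsorbed_mass_per_area=state.adsorbed,
                               molar_concentration=P)


def _tabulated_fraction(table: Sequence[tuple[float, float]], t_s: float) -> float:
    times = np.array([row[0] * _HOUR for row in table])
    fracs = np.array([row[1] for row in table])
    return float(np.interp(t_s, times, fracs))


def apply_dissolution(state: SimState, spec: DissolutionSpec, dt: float) -> SimState:
    """Remove dissolved mass for one step, proportionally across bins and
    compartments (diameters are not shrunk; the bookkeeping is a fraction of
    the original total mass).  Mutates and returns ``state``."""
    if spec.rate_type == "none":
        return state
    m0 = state.initial_total_mass_per_area
    if m0 <= 0.0:
        return state
    if spec.rate_type == "constant_per_hour":
        df = spec.rate * dt / _HOUR
    else:  # tabulated cumulative fraction vs time
        df = _tabulated_fraction(spec.table, state.time + dt) - _tabulated_fraction(
            spec.table, state.time)
    df = min(df, 1.0 - state.dissolved_fraction)
    if df <= 0.0:
        return state
    # grid-independent particulate total: C is uniform-height agnostic only
    # through the caller; use mass fractions, so scale C directly.
    m_part_frac = 1.0 - state.dissolved_fraction - float(state.adsorbed.sum()) / m0
    if m_part_frac <= 0.0:
        return state
    df = min(df, m_part_frac)
    state.C *= 1.0 - df / m_part_frac
    state.dissolved_fraction += df
    return state


@dataclass(frozen=True)
class Snapshot:
    """State recorded at one output time: per-bin concentrations aggregated
    to output layers (mg/cm³; layer 0 at the bottom), the adsorbed pool, the
    dissolved fraction, and conservation/clamping audits."""

    time_s: float
    layer_concentrations: np.ndarray  # (n_bins, n_layers)
    adsorbed: np.ndarray  # (n_bins,)
    dissolved_fraction: float
    mass_balance_drift: float  # relative deviation from the initial total
    clamped_mass: float


@dataclass(frozen=True)
class SimulationResult:
    scenario: Scenario
    grid: GridSpec
    layer_height_cm: float
    snapshots: tuple[Snapshot, ...]

    @property
    def n_layers(self) -> int:
        return int(self.snapshots[0].layer_concentrations.shape[1])


def simulate(scenario: Scenario, grid: GridSpec | None = None) -> SimulationResult:
    """Run a scenario to completion.

    Each step applies dissolution, recomputes the concentration-corrected
    coefficients, advances one implicit transport step, then applies the
    Langmuir bottom attachment if enabled.  Snapshots are recorded at every
    output interval (the initial state is not a snapshot).  Deterministic:
    identical inputs give identical outputs.
    """
    grid = grid if grid is not None else build_grid(
        scenario.column_height_cm, scenario.compartment_height_cm)
    adv = scenario.advanced
    dt = scenario.time_step_s
    coeffs = build_coefficients(scenario)
    state = initialize(scenario, grid)

    steps_per_snapshot = round(scenario.output_interval_s / dt)
    n_snapshots = round(scenario.total_time_s / scenario.output_interval_s)

    # With k_s = k_d = 0 the transport matrix never changes (attachment is
    # operator-split), so factor the banded systems once.
    cache = None
    if adv.k_s == 0.0 and adv.k_d == 0.0:
        cache = [
            _banded_system(grid, coeffs.sedimentation[i], coeffs.diffusion[i], dt)
            for i in range(state.C.shape[0])
        ]

    dissolving = adv.dissolution.rate_type != "none"
    sticky = adv.stickiness_enabled
    rho_ev = scenario.particle.effective_density
    diam = scenario.diameters_cm
    m0 = state.initial_total_mass_per_area

    snapshots: list[Snapshot] = []
    for _ in range(n_snapshots):
        for _ in range(steps_per_snapshot):
            if dissolving:
                apply_dissolution(state, adv.dissolution, dt)
            step(state, grid, coeffs, dt, adv.k_s, adv.k_d, _cache=cache)
            if sticky:
                attach_at_bottom(state, grid, coeffs, adv, rho_ev, diam, dt)
        drift = 0.0
        if m0 > 0.0:
            drift = (state.total_mass_per_area(grid) - m0) / m0
        layers = aggregate_layers(state.C, grid, scenario.output_layer_height_cm)
        logger.debug(
            "t = %.1f s: mass drift %.3e, clamped %.3e mg/cm²",
            state.time, drift, state.clamped_mass,
        )
        snapshots.append(Snapshot(
            time_s=state.time,
            layer_concentrations=layers,
            adsorbed=state.adsorbed.copy(),
            dissolved_fraction=state.dissolved_fraction,
            mass_balance_drift=drift,
            clamped_mass=state.clamped_mass,
        ))
    return SimulationResult(scenario, grid, scenario.output_layer_height_cm,
                            tuple(snapshots))


def mason_weaver_profile(z: np.ndarray, S: float, D: float, column_height: float,
                         mean_concentration: float) -> np.ndarray:
    """Closed-form sedimentation–diffusion equilibrium in a closed column
    (the Mason–Weaver profile), used as the solver's analytic oracle:

        C(z) = C̄ · βH · e^{−βz} / (1 − e^{−βH}),   β = S/D

    with z measured upward from the floor.  β depends on viscosity only
    through S/D, so the equilibrium is viscosity-invariant.
    """
    beta = S / D
    bh = beta * column_height
    return mean_concentration * bh * np.exp(-beta * np.asarray(z)) / (1.0 - math.exp(-bh))


def mason_weaver_layer_means(edges: np.ndarray, S: float, D: float,
                             column_height: float, mean_concentration: float) -> np.ndarray:
    """Exact layer averages of the Mason–Weaver profile between ``edges``."""
    beta = S / D
    bh = beta * column_height
    e = np.exp(-beta * np.asarray(edges))
    return mean_concentration * column_height * (e[:-1] - e[1:]) / (
        np.diff(edges) * (1.0 - math.exp(-bh)))


# ---------------------------------------------------------------------------
# Dose metrics
# ---------------------------------------------------------------------------


def aggregate_layers(profile: np.ndarray, grid: GridSpec, h_out: float) -> np.ndarray:
    """Height-weighted mean of compartment concentrations over output layers
    of height ``h_out`` (cm); layer 0 is the bottom layer.  Layer edges must
    coincide with compartment edges.  Mass per area is preserved exactly.

    ``profile`` has compartments on its last axis.
    """
    total = grid.total_height
    ratio = total / h_out
    n_layers = round(ratio)
    if abs(ratio - n_layers) > 1e-9 * max(ratio, 1.0):
        raise ScenarioError(
            f"aggregate: output layer height {h_out} cm does not divide the "
            f"column height {total} cm")
    if n_layers == grid.n:  # layers coincide with compartments: exact identity
        return np.array(profile, dtype=float)
    cum = np.cumsum(grid.heights)
    bounds = np.arange(1, n_layers + 1) * h_out
    tol = 1e-9 * total
    idx = np.searchsorted(cum, bounds - tol)  # compartment whose top is the layer boundary
    if idx.max() >= grid.n or not np.allclose(cum[idx], bounds, rtol=0, atol=tol):
        raise ScenarioError(
            "aggregate: output layer edges do not align with compartment edges")
    mass = np.asarray(profile, dtype=float) * grid.heights  # broadcasts over leading axes
    starts = np.concatenate(([0], idx[:-1] + 1))
    layer_mass = np.add.reduceat(mass, starts, axis=-1)
    widths = np.diff(np.concatenate(([0.0], cum[idx])))
    return layer_mass / widths


def number_concentration(C_bins: np.ndarray, diameters_cm: np.ndarray,
                         effective_density: float) -> np.ndarray | float:
    """Particle number concentration (/cm³) from per-bin mass concentrations
    (mg/cm³):  n = Σ_i C_i / (ρ_EV (π/6) d_i³)  with ρ_EV in mg/cm³.

    Bins are on the first axis of ``C_bins``; any trailing axes (layers,
    times) broadcast.
    """
    mass_per_particle = (effective_density * 1e3) * (math.pi / 6.0) * np.asarray(
        diameters_cm) ** 3
    C = np.asarray(C_bins, dtype=float)
    per_bin = C / mass_per_particle.reshape((-1,) + (1,) * (C.ndim - 1))
    total = per_bin.sum(axis=0)
    return float(total) if np.ndim(total) == 0 else total


def surface_area_concentration(C_bins: np.ndarray, diameters_cm: np.ndarray,
                               effective_density: float) -> np.ndarray | float:
    """Particle surface-area concentration (cm²/cm³):
    SA = Σ_i [C_i / (ρ_EV (π/6) d_i³)] π d_i² = Σ_i 6 C_i / (ρ_EV d_i)."""
    C = np.asarray(C_bins, dtype=float)
    d = np.asarray(diameters_cm).reshape((-1,) + (1,) * (C.ndim - 1))
    total = (6.0 * C / (effective_density * 1e3 * d)).sum(axis=0)
    return float(total) if np.ndim(total) == 0 else total


def bottom_series(result: SimulationResult) -> pd.DataFrame:
    """Bottom-layer dose-metric time series, one row per snapshot.

    Columns: time_h, mass_mg_cm3, mass_per_area_mg_cm2, number_per_cm3,
    number_per_cm2, sa_cm2_per_cm3, sa_cm2_per_cm2.  Per-area values are the
    per-volume values times the output layer height (cm).
    """
    scn = result.scenario
    d = scn.diameters_cm
    rho = scn.particle.effective_density
    h_out = result.layer_height_cm
    rows = []
    for snap in result.snapshots:
        c_bins = snap.layer_concentrations[:, 0]
        mass = float(c_bins.sum())
        num = number_concentration(c_bins, d, rho)
        sa = surface_area_concentration(c_bins, d, rho)
        rows.append({
            "time_h": snap.time_s / _HOUR,
            "mass_mg_cm3": mass,
            "mass_per_area_mg_cm2": mass * h_out,
            "number_per_cm3": num,
            "number_per_cm2": num * h_out,
            "sa_cm2_per_cm3": sa,
            "sa_cm2_per_cm2": sa * h_out,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DoseMetricsRow:
    """Median bottom-layer dose metrics for one scenario: mass, particle
    number and surface area, each per volume of the bottom layer and per
    unit area of the well floor."""

    scenario: str
    nominal_mg_cm3: float
    bottom_mass_mg_cm3: float
    mass_per_area_mg_cm2: float
    number_per_cm3: float
    number_per_cm2: float
    sa_cm2_per_cm3: float
    sa_cm2_per_cm2: float


def median_summary(series: pd.DataFrame, scenario: Scenario) -> DoseMetricsRow:
    """Medians of the bottom-layer metrics over the snapshot series (the
    uniform t = 0 state is not part of the series; even-length medians are
    the mean of the two central values)."""
    if len(series) == 0:
        raise ValueError("median_summary: empty time series")
    med = series.drop(columns="time_h").median()
    return DoseMetricsRow(
        scenario=scenario.name,
        nominal_mg_cm3=scenario.simulation.initial_concentration,
        bottom_mass_mg_cm3=float(med["mass_mg_cm3"]),
        mass_per_area_mg_cm2=float(med["mass_per_area_mg_cm2"]),
        number_per_cm3=float(med["number_per_cm3"]),
        number_per_cm2=float(med["number_per_cm2"]),
        sa_cm2_per_cm3=float(med["sa_cm2_per_cm3"]),
        sa_cm2_per_cm2=float(med["sa_cm2_per_cm2"]),
    )


_SUMMARY_COLUMNS = [
    "scenario", "nominal_mg_cm3", "bottom_mass_mg_cm3", "mass_per_area_mg_cm2",
    "number_per_cm3", "number_per_cm2", "sa_cm2_per_cm3", "sa_cm2_per_cm2",
]


def summary_table(rows: Iterable[DoseMetricsRow], metrics: Sequence[str] = ALL_METRICS,
                  ) -> pd.DataFrame:
    """Summary DataFrame, one row per scenario × nominal concentration.
    Mass columns are always present; number/surface-area columns only when
    those metrics are selected."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=_SUMMARY_COLUMNS)
    keep = ["scenario", "nominal_mg_cm3", "bottom_mass_mg_cm3", "mass_per_area_mg_cm2"]
    if "number" in metrics:
        keep += ["number_per_cm3", "number_per_cm2"]
    if "surface_area" in metrics:
        keep += ["sa_cm2_per_cm3", "sa_cm2_per_cm2"]
    return df[keep]


def join_dose_response(viability: pd.DataFrame,
                       summaries: Mapping[float, DoseMetricsRow]) -> pd.DataFrame:
    """Re-express a viability table on the delivered-dose axis.

    ``viability`` must carry a ``nominal_mg_cm3`` column plus response (and
    optional error) columns.  Each nominal concentration is replaced by the
    simulated particle number per unit area; responses and error bars pass
    through unchanged (pure re-keying, no interpolation).
    """
    missing = [c for c in viability["nominal_mg_cm3"] if float(c) not in summaries]
    if missing:
        raise KeyError(
            f"no simulated summary for nominal concentration(s): "
            f"{', '.join(f'{c:g}' for c in missing)}")
    out = viability.copy()
    out.insert(0, "number_per_cm2",
               [summaries[float(c)].number_per_cm2 for c in viability["nominal_mg_cm3"]])
    return out.drop(columns="nominal_mg_cm3")


# ---------------------------------------------------------------------------
# File I/O: JSON configs, CSV distributions, result files
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "": {"name", "particle", "solvent", "simulation", "advanced", "output"},
    "particle": {"material", "density", "effective_density", "distribution",
                 "diameter_sd_nm"},
    "particle.distribution": {"weighting", "bins", "csv"},
    "solvent": {"density", "viscosity", "temperature"},
    "simulation": {"column_height", "compartment_height", "initial_concentration",
                   "total_time", "time_step"},
    "advanced": {"k_s", "k_d", "dissolution", "stickiness_enabled",
                 "adsorption_dissociation_constant"},
    "advanced.dissolution": {"initial_dissolved_fraction", "rate_type", "rate", "table"},
    "output": {"output_interval", "output_layer_height", "metrics", "bottom_only"},
}


def _warn_unknown(section: Mapping, path: str) -> None:
    for key in set(section) - _KNOWN_KEYS[path]:
        logger.warning("config: ignoring unknown key %r", f"{path}.{key}".lstrip("."))


_MISSING = object()


def _get(section: Mapping, path: str, key: str, default=_MISSING):
    if key in section:
        return section[key]
    if default is not _MISSING:
        return default
    raise ConfigError(f"missing required key {f'{path}.{key}'.lstrip('.')!r}")


def scenario_from_dict(doc: Mapping, base_dir: Path | None = None) -> Scenario:
    """Build and validate a scenario from a JSON-style mapping with sections
    ``particle``, ``solvent``, ``simulation`` and optional ``advanced`` /
    ``output``.  The particle density is auto-filled from the built-in
    material table unless the material is ``user_defined``."""
    if not isinstance(doc, Mapping):
        raise ConfigError("config root must be a JSON object")
    _warn_unknown(doc, "")
    for section in ("particle", "solvent", "simulation"):
        if section not in doc:
            raise ConfigError(f"missing required section {section!r}")

    p = doc["particle"]
    _warn_unknown(p, "particle")
    material = _get(p, "particle", "material")
    density = p.get("density")
    if density is None:
        if material in MATERIAL_DENSITIES:
            density = MATERIAL_DENSITIES[material]
        else:
            raise ConfigError(
                "particle.density is required for user-defined materials "
                f"(material {material!r} has no built-in density)")
    dist_doc = _get(p, "particle", "distribution")
    _warn_unknown(dist_doc, "particle.distribution")
    weighting = dist_doc.get("weighting", "volume")
    if "csv" in dist_doc:
        csv_path = Path(dist_doc["csv"])
        if base_dir is not None and not csv_path.is_absolute():
            csv_path = base_dir / csv_path
        dist = read_distribution_csv(csv_path, weighting)
    elif "bins" in dist_doc:
        bins = dist_doc["bins"]
        dist = SizeDistribution(tuple(float(b[0]) for b in bins),
                                tuple(float(b[1]) for b in bins), weighting)
    else:
        raise ConfigError("particle.distribution needs either 'bins' or 'csv'")
    particle = ParticleSpec(material=material, density=float(density),
                            effective_density=float(_get(p, "particle", "effective_density")),
                            distribution=dist,
                            diameter_sd_nm=p.get("diameter_sd_nm"))

    s = doc["solvent"]
    _warn_unknown(s, "solvent")
    solvent = SolventSpec(density=float(_get(s, "solvent", "density")),
                          viscosity=float(_get(s, "solvent", "viscosity")),
                          temperature=float(_get(s, "solvent", "temperature")))

    m = doc["simulation"]
    _warn_unknown(m, "simulation")
    sim = SimulationConfig(
        column_height=float(_get(m, "simulation", "column_height")),
        compartment_height=float(_get(m, "simulation", "compartment_height")),
        initial_concentration=float(_get(m, "simulation", "initial_concentration")),
        total_time=float(_get(m, "simulation", "total_time")),
        time_step=float(_get(m, "simulation", "time_step")),
    )

    adv_doc = doc.get("advanced", {})
    _warn_unknown(adv_doc, "advanced")
    diss_doc = adv_doc.get("dissolution", {})
    _warn_unknown(diss_doc, "advanced.dissolution")
    dissolution = DissolutionSpec(
        initial_dissolved_fraction=float(diss_doc.get("initial_dissolved_fraction", 0.0)),
        rate_type=diss_doc.get("rate_type", "none"),
        rate=float(diss_doc.get("rate", 0.0)),
        table=tuple((float(t), float(f)) for t, f in diss_doc.get("table", ())),
    )
    kd_raw = adv_doc.get("adsorption_dissociation_constant")
    advanced = AdvancedConfig(
        k_s=float(adv_doc.get("k_s", 0.0)),
        k_d=float(adv_doc.get("k_d", 0.0)),
        dissolution=dissolution,
        stickiness_enabled=bool(adv_doc.get("stickiness_enabled", False)),
        adsorption_dissociation_constant=None if kd_raw is None else float(kd_raw),
    )

    out_doc = doc.get("output", {})
    _warn_unknown(out_doc, "output")
    h_out = out_doc.get("output_layer_height")
    output = OutputSpec(
        output_interval=float(out_doc.get("output_interval", 60.0)),
        output_layer_height=None if h_out is None else float(h_out),
        metrics=tuple(out_doc.get("metrics", ALL_METRICS)),
        bottom_only=bool(out_doc.get("bottom_only", False)),
    )
    return validate_scenario(particle, solvent, sim, advanced, output,
                             name=doc.get("name", "scenario"))


def scenario_to_dict(scenario: Scenario) -> dict:
    """Serialise a scenario to the JSON config layout (exact round trip
    through :func:`scenario_from_dict`)."""
    p = scenario.particle
    diss = scenario.advanced.dissolution
    return {
        "name": scenario.name,
        "particle": {
            "material": p.material,
            "density": p.density,
            "effective_density": p.effective_density,
            "diameter_sd_nm": p.diameter_sd_nm,
            "distribution": {
                "weighting": p.distribution.weighting,
                "bins": [[d, f] for d, f in
                         zip(p.distribution.diameters_nm, p.distribution.fractions)],
            },
        },
        "solvent": {
            "density": scenario.solvent.density,
            "viscosity": scenario.solvent.viscosity,
            "temperature": scenario.solvent.temperature,
        },
        "simulation": {
            "column_height": scenario.simulation.column_height,
            "compartment_height": scenario.simulation.compartment_height,
            "initial_concentration": scenario.simulation.initial_concentration,
            "total_time": scenario.simulation.total_time,
            "time_step": scenario.simulation.time_step,
        },
        "advanced": {
            "k_s": scenario.advanced.k_s,
            "k_d": scenario.advanced.k_d,
            "stickiness_enabled": scenario.advanced.stickiness_enabled,
            "adsorption_dissociation_constant":
                scenario.advanced.adsorption_dissociation_constant,
            "dissolution": {
                "initial_dissolved_fraction": diss.initial_dissolved_fraction,
                "rate_type": diss.rate_type,
                "rate": diss.rate,
                "table": [[t, f] for t, f in diss.table],
            },
        },
        "output": {
            "output_interval": scenario.output.output_interval,
            "output_layer_height": scenario.output.output_layer_height,
            "metrics": list(scenario.output.metrics),
            "bottom_only": scenario.output.bottom_only,
        },
    }


def read_config(path: str | Path) -> Scenario:
    """Parse, unit-check and validate a JSON scenario config.  Unknown keys
    log a warning; missing keys and invariant violations raise with the
    offending key path."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed JSON in {path}: {exc}") from None
    return scenario_from_dict(doc, base_dir=path.parent)


def read_distribution_csv(path: str | Path, weighting: str = "volume") -> SizeDistribution:
    """Read a size distribution from a CSV with header ``diameter_nm,fraction``.
    Rows are sorted by diameter and fractions normalised (percent-style
    tables summing to 100 are accepted with a warning)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise ConfigError(f"distribution CSV not found: {path}") from None
    expected = ["diameter_nm", "fraction"]
    if list(df.columns) != expected:
        raise ConfigError(
            f"{path}: expected header 'diameter_nm,fraction', got {','.join(df.columns)}")
    bad = df.index[(df["diameter_nm"] <= 0) | (df["fraction"] < 0)]
    if len(bad):
        raise ConfigError(
            f"{path}: non-positive diameter or negative fraction at data row(s) "
            f"{', '.join(str(i + 2) for i in bad)}")  # +2: header + 1-based
    dup = df.index[df["diameter_nm"].duplicated()]
    if len(dup):
        raise ConfigError(
            f"{path}: duplicate diameter at data row(s) "
            f"{', '.join(str(i + 2) for i in dup)}")
    return SizeDistribution(tuple(df["diameter_nm"].astype(float)),
                            tuple(df["fraction"].astype(float)), weighting).validated()


def timeseries_table(result: SimulationResult, bottom_only: bool = False) -> pd.DataFrame:
    """Long-format snapshot table: time_h, layer_index (1 = bottom),
    z_lower_mm, z_upper_mm, then one column per selected metric (per-volume
    concentrations of the layer)."""
    scn = result.scenario
    d = scn.diameters_cm
    rho = scn.particle.effective_density
    metrics = scn.output.metrics
    h_out = result.layer_height_cm
    n_layers = 1 if bottom_only else result.n_layers
    z = np.arange(result.n_layers) * h_out
    frames = []
    for snap in result.snapshots:
        c = snap.layer_concentrations[:, :n_layers]
        row = {
            "time_h": snap.time_s / _HOUR,
            "layer_index": np.arange(1, n_layers + 1),
            "z_lower_mm": z[:n_layers] / _MM,
            "z_upper_mm": (z[:n_layers] + h_out) / _MM,
            "mass_mg_cm3": c.sum(axis=0),
        }
        if "number" in metrics:
            row["number_per_cm3"] = number_concentration(c, d, rho)
        if "surface_area" in metrics:
            row["sa_cm2_per_cm3"] = surface_area_concentration(c, d, rho)
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class RunManifest:
    """What to write where for one run."""

    output_dir: Path
    bottom_only: bool = False
    write_timeseries: bool = True
    write_summary: bool = True


def write_outputs(result: SimulationResult, summaries: Sequence[DoseMetricsRow],
                  manifest: RunManifest) -> dict[str, Path]:
    """Write the time-series CSV (all layers or bottom-only), the summary
    CSV and a run-metadata JSON (config echo + package version + timestamp).
    Returns the paths written.  Apart from the timestamp the outputs are
    byte-identical across reruns of the same manifest."""
    from . import __version__

    out = Path(manifest.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    scn = result.scenario
    bottom_only = manifest.bottom_only or scn.output.bottom_only
    try:
        if manifest.write_timeseries:
            ts_path = out / f"{scn.name}_timeseries.csv"
            timeseries_table(result, bottom_only=bottom_only).to_csv(ts_path, index=False)
            written["timeseries"] = ts_path
        if manifest.write_summary:
            sm_path = out / f"{scn.name}_summary.csv"
            summary_table(summaries, scn.output.metrics).to_csv(sm_path, index=False)
            written["summary"] = sm_path
        meta_path = out / f"{scn.name}_run.json"
        meta = {
            "scenario": scenario_to_dict(scn),
            "package_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "n_compartments": result.grid.n,
            "final_mass_balance_drift": result.snapshots[-1].mass_balance_drift,
            "final_clamped_mass_mg_cm2": result.snapshots[-1].clamped_mass,
        }
        meta_path.write_text(json.dumps(meta, indent=2) + "\n")
        written["metadata"] = meta_path
    except OSError as exc:
        raise OSError(f"failed writing outputs under {out}: {exc}") from exc
    return written
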