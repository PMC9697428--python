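# Methods

## Model and assumptions

`dgdose` treats a nanoparticle dispersion in a culture well as a dilute,
quiescent 1-D column: no flow, no meniscus, no lateral gradients, no
particle–particle agglomeration kinetics during the run. The measured
hydrodynamic size distribution (DLS) and the effective (agglomerate)
density ρ_EV are taken as fixed inputs that already encode the
agglomeration state of the dispersion in the exposure medium. Each size bin
moves independently under Stokes settling and Stokes–Einstein diffusion;
bins couple only through the optional concentration corrections, the shared
dissolution bookkeeping and the shared Langmuir boundary.

Transport coefficients use the agglomerate quantities: S = g(ρ_EV − ρ_f)d²/(18μ)
and D = k_BT/(3πμd) with the hydrodynamic diameter d. Buoyant agglomerates
(ρ_EV < ρ_f) get a negative settling velocity and rise; that sign is
preserved by the hindered-transport corrections S′ = S/(1 + k_sC),
D′ = D/(1 + k_dC). Both corrections are written as divisions: transport
slows as local concentration rises, which is the physical content of the
concentration-dependence constants (typical range 0–0.1; 0, the default,
disables them).

Dose metrics likewise use ρ_EV and the bin diameter: the per-particle mass
is ρ_EV(π/6)d³ (consistent with the particle molar concentration
[P] = C_p/(N_A ρ_EV (4/3)πr³) used by the Langmuir boundary), so number and
surface-area concentrations describe agglomerate units, not primary
particles.

## Discretisation

The column is split into N = H/h finite-volume compartments, compartment 1
at the floor. Each time step solves, per bin, a backward-Euler step of the
advection–diffusion equation with first-order upwind advection and central
diffusion as one tridiagonal system (LAPACK banded solve; with k_s = k_d = 0
the matrix is constant and assembled once per run). The implicit scheme is
the deliberate choice here: at the bundled case-study settings the explicit
diffusion number D·Δt/h² reaches ≈10, far beyond the explicit stability
limit of 0.5, so honouring the case studies' printed Δt (0.5 s and 2 s)
requires unconditional stability. The matrix columns sum to h_j/Δt, making
every step conservative to round-off; because the system is an M-matrix the
solution is non-negative in exact arithmetic, and any rounding-level
negativity is clamped to zero and accumulated in an audit counter
(`SimState.clamped_mass`, logged with the mass-balance drift at every
snapshot).

Boundaries: zero flux at the free surface; reflective at the floor by
default. With stickiness enabled, attachment is operator-split after the
transport step: the settling flux into the floor during Δt, S⁺C₁Δt per bin,
is moved irreversibly into an adsorbed surface pool scaled by (1 − θ) with θ
from the Langmuir isotherm evaluated on the current bottom-compartment
concentration; the transfer is capped at the compartment's mass so the
state can never go negative. Dissolution is applied before each transport
step, removing the prescribed fraction of the *original* total mass per
step, proportionally across bins and compartments, capped when the
particulate pool (or the cumulative fraction) is exhausted. Dissolved mass
is inert — not transported and not counted in any dose metric — and
diameters are not shrunk, matching the fraction-of-original
parameterisation. The per-step order is dissolution → coefficient
correction → transport → attachment.

The "distorted grid" grading (geometrically refined compartments toward the
floor, `graded_grid`) is available but unused by the bundled scenarios:
uniform 0.005 mm compartments already resolve the 0.01 mm output layer, and
the solver is validated against closed forms rather than a particular
grading recipe.

## Numerical validation

The analytic oracle is the Mason–Weaver equilibrium
C(z) = C̄·βH·e^(−βz)/(1 − e^(−βH)), β = S/D, the steady state of
sedimentation–diffusion in a closed column. The acceptance suite runs a
200 nm, ρ_EV = 1.7 g/cm³ particle (βH ≈ 2.0) on grids of 150/300/600
compartments with Δt = 60/30/15 s over 24 h and requires every compartment
of the finest profile to sit within 1% of the exact layer averages with
monotonically decreasing error — the first-order upwind scheme has a
per-cell equilibrium error of ≈(βh)²/2, i.e. a cumulative bound of
βH·βh/2 ≈ 0.3% at the finest grid. Since β = S/D cancels viscosity, the
same test is run at μ = 0.00081 P and 0.0081 P and must give identical
equilibria; this also covers the ambiguity in the case studies' printed
medium viscosity (0.00081 P, an order of magnitude below aqueous media at
37 °C — used verbatim in the fixtures, and immaterial for equilibrium
quantities and for the diffusion-dominated small particles, though it does
scale the transient approach to equilibrium, which is faster at lower
viscosity).

Further invariants under test: exact mass balance (particulate + adsorbed +
dissolved within 1e-9 relative at every snapshot, including randomized
mechanism mixes), non-negativity, exact linearity of all outputs in the
nominal concentration when k_s = k_d = 0 and stickiness is off, and the
per-area = per-volume × layer-height identity for every metric.

## Case-study fixtures and what they show

The six bundled Ag/Au particles are encoded with monodisperse,
volume-weighted distributions at their mean hydrodynamic diameters (the
measurement spread is stored as metadata only), in medium at
0.9995 g/cm³ / 0.00081 P / 37 °C, in 96-well geometry (H = 3 mm,
h = 0.005 mm), 24 h, Δt = 0.5 s for AOT-/PLL-AgNP and 2 s for the CYS/GSH
particles, no dissolution, no stickiness, hourly output on 0.01 mm layers.
Medians are taken over the 24 hourly snapshots (the uniform t = 0 state is
excluded: including it would bias every median toward the nominal value).

For the small GSH-/CYS-AgNP particles (4.5 / 6.6 nm) diffusion dominates
(βH ≲ 0.01) and the bottom-layer median equals the nominal concentration to
a fraction of a percent — this is the regime the acceptance targets check,
and it is insensitive to both the monodisperse simplification and the
viscosity value. For the larger particles the monodisperse fixtures are a
*lower bound*, not a reproduction: a single 24.2 nm bin cannot exceed its
Mason–Weaver equilibrium enhancement of ≈1.2×, whereas measured DLS
distributions of agglomerating dispersions contain large-diameter mass that
settles strongly and can raise the bottom-layer concentration by an order
of magnitude. The acceptance suite asserts exactly this bound instead of
pretending to reproduce distribution-dependent values whose input
distributions are not part of the fixture set. Passing tests therefore
demonstrate correct transport physics and bookkeeping; they do not
demonstrate agreement with any particular polydisperse experiment unless
the measured distribution is supplied.

## Parameters that matter

| parameter | units | default | notes |
|---|---|---|---|
| ρ_EV (effective density) | g/cm³ | — (required) | agglomerate density; controls settling direction and rate |
| d (hydrodynamic diameter) | nm | — (required) | per bin; S ∝ d², D ∝ 1/d |
| μ (viscosity) | poise | — (required) | cancels out of equilibrium profiles (β = S/D) |
| H, h | mm | — / — | H/h must be integer; h = 0.005 mm resolves the 0.01 mm output layer |
| Δt | s | — | implicit scheme: accuracy-limited, not stability-limited |
| k_s, k_d | – | 0 | hindered-transport constants, typical 0–0.1 |
| K_D | mol/cm³ | – | Langmuir dissociation constant; only with stickiness |
| output interval / layer | min / mm | 60 / h | medians are over the snapshot series |

Fixed constants: g = 980.665 cm/s², k_B = 1.380649e-16 erg/K,
N_A = 6.02214076e23 /mol. Internal unit system is CGS with mass
concentrations in mg/cm³; all conversions happen once at validation.

## Degenerate inputs and tie-breaks

H = h gives a single well-mixed compartment. C₀ = 0 runs and yields zero
everywhere (mass-balance drift is reported as 0 rather than 0/0). Neutral
buoyancy gives S = 0 exactly. A dissolution table shorter than the run
holds its last cumulative value (flat extrapolation). Distribution bins are
sorted by diameter at validation and fractions renormalised with a logged
warning when they do not sum to 1 (percent-style tables are accepted).
Equal-magnitude floating-point caps in dissolution are resolved so that the
particulate pool reaches exactly zero when the cumulative fraction saturates.

## Known limitations

- No agglomeration/deagglomeration kinetics during the run; the size
  distribution is frozen at its t = 0 measurement.
- Dissolution does not shrink diameters, so it does not feed back on
  transport coefficients.
- 1-D column only: no wall effects, meniscus curvature or convection.
- Monodisperse fixtures understate delivered dose for agglomerating
  dispersions (see above); supply measured DLS distributions for
  quantitative work.
- The Langmuir boundary uses the bottom-compartment concentration explicitly
  (lagged one step); at the bundled step sizes this splitting error is far
  below the transport discretisation error.
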