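# Methods

## Model

The simulator treats a growing multicellular tumor spheroid (MTS) and the
surrounding hydrogel as a two-constituent composite on a spherically
symmetric domain. The constituents are (i) a visco-elastic, compressible,
mutually adhesive cell aggregate described by the total concentration
C_tot = C_p + C_m + C_n of proliferative, hypoxic (motile) and necrotic
cells, and (ii) an isotropic, compressible, linear-elastic porous ECM
scaffold. Interstitial fluid is assumed to move freely through both phases
and carries no stress of its own. Their volume fractions sum to one; the
cell fraction is Φ_c = C_tot/C_max with C_max = 1/V_cell the dense-packing
limit.

Mechanics is quasi-static: growth is slow compared with visco-elastic
relaxation, so at every instant the stress field is in equilibrium with the
current concentration profile. Each transport step therefore re-solves, in
order:

1. the intercellular stress σ_C(C_tot) (adhesion/repulsion law);
2. the ECM displacement BVP driven by δ_v = (1/K_ECM) dσ_C/dr, giving
   strains, the dilatation ε_v and the ECM stress components;
3. the iso-strain composite stress σ_tot = (1−Φ_c) σ_ECM + Φ_c σ_C;
4. the shared Darcy drift v_D = −M_eff ∂σ_tot/∂r.

Biology follows the go-or-grow dichotomy with oxygen as the only
metabolite. Proliferation is logistic with carrying capacity C_q = C_max,
scaled by oxygen availability n_ox/n_max; transitions
proliferative↔hypoxic and hypoxic→necrotic are first-order processes with
characteristic times, gated by smooth tanh switches of width λ centred on
the hypoxia and necrosis thresholds. Necrotic material is inert and never
removed. Two switch variants exist: the strict variant (stiff) makes
proliferative cells immotile and hypoxic cells non-dividing; the
overlapping variant (default) gives proliferative cells a tenth of the
hypoxic motility and hypoxic cells half the proliferative division rate.

## Parameters

All values are stored in mm / day / Pa / (mg/L) / (cells/mm³) units and are
derived, where possible, from single-cell measurements by closed forms that
the `params` module exposes:

| parameter | default | origin |
|---|---|---|
| V_cell | 1200 μm³ | measured glioma cell volume; fixes C_max = 8.33e5 mm⁻³ |
| C_eq | 3.5e5 mm⁻³ | quasi-stationary core density of growing spheroids |
| C_inf | 2.8e4 mm⁻³ | 33-μm interaction cut-off spacing, 1/r³ |
| C_att | 2.35e5 mm⁻³ | 16.2-μm maximal-attraction spacing |
| σ_att | 10 Pa | 12 neighbours × 430 pN over 550 μm² ≈ 9.4 Pa, rounded |
| K_C0 | 500 Pa | cell aggregate: E = 300 Pa, ν = 0.4 |
| E_ECM, ν_ECM | 1000 Pa, 0.13 | acellular collagen range 0.5–2.5 kPa |
| k₀, μ | 1e-12 m², 300 Pa·s | collagen permeability / cell viscosity |
| M₀ = k₀/μ | 2.88e-4 mm²/(Pa·day) | Darcy mobility |
| D_m, D_p | 2e-2, 2e-3 mm²/day | hypoxic motility; D_p = D_m/10 (overlap) |
| D_ox | 86.4 mm²/day | oxygen diffusivity in tissue/gel |
| α_p, α_m | 1.38e-2, α_p/5 (mm³/cell)·mg/(L·day) | uptake rates |
| ξ_h, ξ_n, λ | 1.0, 0.8, 1.0 mg/L | switch thresholds and width |
| τ_p, τ_m | 1, 2 day | doubling times |
| τ_pm, τ_mp, τ_n | 1 h, 96 h, 32 h | transition times |
| R₀, C_init, n₀ | 0.25 mm, 7e4 mm⁻³ (= C_eq/5), 4 mg/L | initial state |
| R_dom | 1.5 mm | domain radius (see below) |

Choices made where the source material was ambiguous or self-inconsistent:

- **τ_n = 32 h.** The transition-rate arithmetic (3.1e-2 h⁻¹) and the
  tabulated "death time" of 48 h disagree; the rate conversion is adopted
  and 48 h remains selectable in the configuration.
- **C_eq = 3.5e5**, with the alternative 4e5 appearing in some derived
  figure annotations exposed as an override, not the default.
- **C_att.** The spacing-derived 2.35e5 differs from the minimiser implied
  by the 27/4 normalisation, (2C_eq + C_inf)/3 = 2.43e5. The stress law
  uses the 27/4 form as written; C_att is retained as a descriptive
  parameter only.
- **R_dom = 1.5 mm.** The source text reuses one symbol for the spheroid
  and the domain radius. 1.5 mm accommodates the ~0.9 mm extent of the
  reported isoline maps. The closed-domain oxygen reservoir scales with
  R_dom³, so this choice strongly conditions the reflection-boundary
  scenarios (see Known limitations).
- **h_m = 1** in overlap mode: the reduced hypoxic proliferation is already
  encoded in τ_m = 2τ_p.
- **Baseline E_ECM = 1.0 kPa**, an assumption inside the stated
  0.5–2.5 kPa range; the stiff scenarios use 2.5 kPa.
- **tanh switches** use the single expression h = (1 ∓ tanh((n−ξ)/λ))/2 for
  all oxygen levels.
- Oxygen uptake is not modulated by the local oxygen level; negativity is
  prevented by clamping at zero and the clamped mass is logged.
- The logistic factor is clamped at zero on transient overshoot of the
  carrying capacity (crowding stops division but does not kill).
- The pore-stretch factor (1 − ε_v/3) is clamped at zero from below
  (a fully collapsed pore cannot have negative length).

## Numerics

- **Grid.** Uniform node-centred radial mesh, node 0 at the centre, default
  spacing 5 μm (301 nodes at R_dom = 1.5 mm) — ≥10 nodes across the ~50 μm
  transition layer. Conservative volume weights from mid-face shell volumes
  sum exactly to the domain volume.
- **Diffusion.** Crank–Nicolson on the conservative finite-volume form of
  (1/r²)∂_r(D r² ∂_r f); no-flux or Dirichlet outer boundary; tridiagonal
  solves via `scipy.linalg.solve_banded` with cached operator assembly.
  Verified against the 3D heat kernel (<1% L² error) and a Dirichlet
  eigenmode decay.
- **Advection.** Flux-corrected transport in the SHASTA family: donor-cell
  low-order fluxes, a Lax–Wendroff high-order flux, Boris–Book prelimiting
  and a Zalesak limiter on the antidiffusive residual. Mass is conserved to
  round-off, non-negative input stays non-negative, and no new extrema
  beyond the low-order transported bounds are created. The enforced Courant
  bound uses the spherical face-area/volume ratio (stricter than |v|Δt/Δr
  near the origin); the engine sub-cycles automatically. Observed
  convergence on smooth profiles is second order against the exact
  spherical-translation solution.
- **Elasticity.** The displacement BVP is discretised with the symmetric
  second-order stencil of u'' + 2u'/r − 2u/r²; regularity u(0) = 0 and
  u(R_dom) = 0 as the outer condition. A well-posed second-order BVP admits
  exactly two conditions, so the additional border condition ε_rr = 0
  sometimes quoted for this problem is reported as a diagnostic rather than
  imposed. The constant-source closed form u = A(r² − R r)/4 is reproduced
  to 1e-8 and the observed order on a manufactured sinusoidal solution
  is 2.
- **Splitting.** Per step of Δt = 2e-4 day (≈17 s; resolves the fastest
  transition, τ_pm = 1 h, with ~200 steps): mechanics solve → FCT advection
  of all phenotypes → Crank–Nicolson phenotype diffusion → explicit Euler
  sources → oxygen step (diffusion + explicit uptake). The order is fixed;
  halving Δt changes short-horizon profiles by <1% in L².
- The δ_v source is computed by direct differencing of the σ_C profile
  (second-order one-sided stencils at the boundaries), not by the
  chain-rule approximation with γ outside the derivative; a config toggle
  exposes the alternative for sensitivity work.
- The model contains no randomness; trajectories are bit-reproducible.

## Scenarios

`baseline` (E_ECM = 1 kPa, closed oxygen domain, overlap switch, constant
permeability), `variable_permeability` (baseline + pore-stretch mobility),
`stiff_switch` (baseline + strict go-or-grow), `subtumor` (E_ECM = 2.5 kPa,
permanent oxygen supply) and `rigid_rbc` (E_ECM = 2.5 kPa, closed domain),
all to 5 simulated days by default with snapshots at a 0.1-day cadence plus
exact hits at 0.2/0.3/0.5/1/2/3/5 days.

Observables (`metrics`): outermost total-density isoline radii (operational
invasive-zone borders at 4e2 and 4e3 cells/mm³), isoline speeds, the
central density fold change, proliferative-rim detection
(`scipy.signal.find_peaks` with a 1e3 cells/mm³ prominence floor), and the
volume-weighted hypoxic fraction of a rim band frozen at an early time
(necrotic cells excluded from the denominator by default; both conventions
are available).

## What the scenarios do and do not demonstrate

The synthetic scenarios are the study conditions themselves — there is no
external data. Everything the kernel-level tests establish (conservation,
positivity, convergence orders, the stress-law extremum, parameter
derivations) holds for real use of the library. The scenario-level
*emergent* observables, however, characterise this parameter set, not
glioma biology at large, and several reference behaviours are **not**
reproduced at the default parameters:

- **Drift is too weak to densify the core.** With M₀ = 2.88e-4
  mm²/(Pa·day) and intercellular stresses capped near |σ_C| ≤ 10 Pa while
  C_tot < C_eq, drift speeds are O(5e-3) mm/day. Against the hypoxic
  motility D_m = 2e-2 mm²/day over the 0.25-mm core (Péclet ≈ 0.06),
  adhesion-driven contraction loses to dispersal: the centre density
  *falls* (≈0.4× by day 3) instead of rising several-fold. A sensitivity
  run with M₀ × 10 flips the regime — the centre then densifies to C_eq
  and a ~5-fold rise appears by day 3 — so the qualitative behaviour
  switches on a mobility scale about one order above the value the
  permeability/viscosity derivation yields. The package keeps the derived
  value as the default and treats the densified regime as unreached under
  these conditions.
- **Closed-domain oxygen budget.** At R_dom = 1.5 mm the reservoir holds
  n₀·V ≈ 57 (mg/L)·mm³ against an initial consumption of ≈63/day, so a
  reflection-boundary run exhausts its oxygen near day 1 and the entire
  population necroses well before day 3; central hypoxia onsets at ≈19 h
  rather than within 8 h. Larger domains delay exhaustion but weaken
  central hypoxia further. No domain radius reconciles both an early
  hypoxic centre and a day-3 proliferative rim without the densified core
  described above.
- **Subtumor formation** (stiff matrix + permanent supply) likewise
  requires core stresses of order 100 Pa to push a detached rim ~0.1
  mm/day; at the default mobility the aggregate never crosses C_eq, total
  stresses stay O(5 Pa), and only the single main rim forms (moving ~0.03
  mm/day). The strain-permeability invasion-speed gain is accordingly tiny
  (+0.002%) though positive.

These gaps are asserted honestly by the scenario-level acceptance tests
(which therefore fail at the default parameters) and quantified by
`scripts/acceptance.py`; they delimit where this parameter set stops
matching the reported phenomenology.

## Known limitations

Beyond the parameter-regime caveats above: no ECM plasticity or yield (core
tension is retained even where a real hydrogel would flow), no fibre
orientation or remodeling beyond the isotropic pore-stretch factor, no
necrotic-cell removal, no interstitial-fluid dynamics, and strictly 1D
spherical symmetry — azimuthal instabilities that fragment rims into
discrete islands in 3D cannot occur here.
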