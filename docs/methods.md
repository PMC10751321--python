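# Methods

This note documents the models, algorithms and numerical choices behind
`athero-ifem`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open design decisions were made.

## 1. Problem setting

Intravascular ultrasound (IVUS) elastography delivers, for one coronary
cross-section, two images at nearby lumen pressures (e.g. diastolic-range
110 and 115 mmHg) from which displacement estimators produce a relative
displacement/strain field. Given a segmentation of the wall into fibrotic
tissue, lipid pools and calcifications, an inverse finite-element analysis
can recover the tissue mechanical properties, and from them the stress
state that governs plaque rupture risk. The package implements the whole
loop *in silico*: synthetic plaque geometries stand in for patient
cross-sections (none are publicly deposited), the FE solver produces the
"measured" frames, and two inverse pipelines recover the properties.

All lengths are mm, stresses kPa, pressures mmHg at the interface
(1 mmHg = 0.1333224 kPa internally — the conversion constant lives in one
place, `fem.MMHG_TO_KPA`).

## 2. Constitutive models

* **Linear elastic** (E, ν): calcifications (ν = 0.333), and all tissues in
  the small-increment linear inversion.
* **Neo-Hooke**: ψ = C10 (Ī₁ − 3) + (1/D1)(J − 1)², with Ī₁ = J^(−2/3) I₁.
  Conversions C10 = E / (4(1+ν)) and D1 = 6(1−2ν)/E map to/from the linear
  parameters (μ = 2 C10, K₀ = 2/D1); they are exact algebraic inverses of
  each other.
* **Gasser–Ogden–Holzapfel (GOH)**:
  ψ = (1/D)(J−1)² + μ(Ī₁−3) + k1/(2k2) Σ_{i=4,6} [exp(k2 Eᵢ²) − 1],
  Eᵢ = κ(Ī₁−3) + (1−3κ)(Īᵢ−1). Fibrotic tissue uses D = 0.005 kPa⁻¹ and
  κ = 1/3 (isotropic fiber response; the fiber directions are then provably
  inert, which a test asserts exactly). The bracket Eᵢ squares the full
  combination κ(Ī₁−3)+(1−3κ)(Īᵢ−1) rather than the canonical
  κI₁+(1−3κ)I₄−1; at κ = 1/3 the two coincide up to the 1/3 scaling of the
  isotropic term, and the form implemented here is the one the reference
  parameter sets were fitted with.

**Isochoric invariants.** Both hyperelastic models use Ī₁, Ī₄ rather than
the raw invariants. With raw I₁ the reference configuration would not be
stress-free (P(I) = 2C10·I) and the energy could go negative in plane
strain; the isochoric form is also the convention of the commercial FE
package these tissue models are normally calibrated in, and it is the only
reading consistent with the (E, ν) ↔ (C10, D1) conversion formulas. Tests
pin this down: zero stress and energy at the identity, and agreement of
the linearized hyperelastic stress with the Hooke law to O(‖ε‖²).

Uniaxial behavior curves impose incompressibility (λ₂ = λ₃ = λ^(−1/2)) and
eliminate the pressure through the traction-free lateral condition; for
Neo-Hooke this reduces to σ = 2 C10 (λ² − 1/λ) exactly. Default curve
range λ ∈ [1, 1.3], 100 points (the plotted range is not standardized
anywhere; it is configurable).

## 3. Finite elements

Three-node linear triangles (constant strain), plane strain, displacement
formulation with single-point integration — the direct analog of CPE3
elements. The lumen pressure is a follower load on the deformed lumen
edges (physically standard; the load stiffness is assembled, so Newton
convergence stays quadratic). Analytic first Piola–Kirchhoff stresses are
used for residuals; consistent tangents come from central differencing of
the analytic stress (step 1e-7), which keeps the material code short and
is verified against finite differences of the energy to ~1e-9.

Rigid-body motion is removed by pinning three outer-contour nodes nearest
to 0°, 120°, 240° (both components) — equal spacing minimizes
constraint-induced stress artifacts given that only "three external
points" is specified. A tangential-roller variant on the whole outer ring
exists for the axisymmetric oracles, where pin constraints would pollute
the comparison. All constraints are assembled as Lagrange rows of a
bordered (KKT) sparse system solved with SuperLU.

Newton defaults: 10 load steps to target pressure, relative residual
tolerance 1e-8, 25 iterations per step, step bisection on divergence (max
4), step-halving line search against element inversion. Inside the inverse
loop the solver warm-starts from the previous equilibrium and attempts the
full pressure in one step, falling back to cold load stepping on failure.

Verification: Lamé thick-walled-cylinder solution (< 1% displacement error
on a 24×96 crossed mesh at ν = 0.49), incompressible Neo-Hookean annulus
inflation against the plane-strain equilibrium quadrature (< 2% with a
small volumetric penalty, ν_eq = 0.499), external-work vs strain-energy
balance (< 1% at 20 load steps), patch-level constant-strain reproduction,
and bitwise run-to-run determinism. The annulus oracles use a structured
"crossed-triangle" mesh (quads split at centroids), which behaves well
under near-incompressibility; unstructured plaque meshes accept the mild
volumetric locking of linear triangles at ν = 0.49, as any CPE3 model
does.

Strains are evaluated per element from shape-function gradients of the
relative frame displacements on the lower-pressure configuration
(infinitesimal theory, appropriate for a 5 mmHg increment). Cylindrical
components are taken about the lumen centroid of that frame (the
cylindrical origin is not standardized; the centroid is the natural
choice). The equivalent strain is the von-Mises strain
√(2/3 e:e) with the plane-strain zero out-of-plane normal strain entering
the deviator.

## 4. Synthetic plaques and meshing

The surrogate geometry is an eccentric-lumen annulus (outer radius 2 mm,
lumen radius 0.9 mm offset 0.5 mm — a ~4 mm vessel with ~80% area
stenosis) with elliptical inclusions: one lipid pool opposite the lumen
(nominal fibrous cap = `min_cap_thickness`, default 0.2 mm) and optionally
one calcification, plus smooth low-order (modes 2–5) Fourier radial
contour noise (default amplitude 0.03 mm), seeded. Infeasible placements
raise explicit errors — inclusions are never silently clipped.

Meshing is a boundary-sampled Delaunay triangulation: contours resampled
at the target edge length appear verbatim as element edges (a hexagonal
interior lattice is kept ≥ 0.62 h away from all contours so the Delaunay
empty-circumcircle property preserves the contour segments). Conformity is
*audited*, not assumed: a missing contour segment, an inverted element, a
hanging node, or a fibrous cap resolved by fewer than 3 element layers
(shortest element-path count from lumen to lipid) is a hard error. Labels
are assigned by centroid point-in-polygon and tested against an
independent shapely oracle. At 0.065 mm edges the default plaque meshes to
~5,000 elements, inside the 3,000–8,000 range of the reference models.

## 5. IVUS simulation and noise

A frame pair is the pair of equilibrium states at (p_lo, p_hi) computed
from the zero-pressure geometry in a single load path; the measurement is
(coordinates at p_lo, relative displacements to p_hi) on shared
connectivity (ground-truth correspondence; displacement-estimator errors
beyond strain noise are out of scope). Strain noise is additive white
Gaussian per Cartesian component with variance mean(signal²)/10^(SNR/10),
default 20 dB, seeded; derived (cylindrical/principal/equivalent)
components are recomputed from the noised tensor so rotation identities
continue to hold. The realized SNR is measured as
10 log₁₀(Σ clean² / Σ (noisy−clean)²) over the Cartesian components and
hits the nominal value within 0.5 dB at 10⁴ elements.

## 6. Pull-back (zero-pressure recovery)

The imaged geometry is inflated by the imaging pressure, and the candidate
zero-pressure configuration is X_zp = X − K·u — imposing −K·u as a
boundary condition on a copy of the geometry yields exactly this
coordinate update, so the update form is implemented directly. The
candidate is scored by re-inflating and taking the RMS nodal distance to
the imaged coordinates. Inside the material-optimization loop K is fixed
at 1 (one displacement solve per iterate — the cost-saving variant); after
the materials converge, K is optimized by golden-section search on
[0.5, 1.5] (tolerance 1e-3 on K, residual plateau 1e-4 mm, plateau stop
armed only after 6 evaluations so the bracket is actually worked; the
bounds and tolerances are package choices — none are standardized).
Round-trip accuracy on a GOH annulus: ZP radii within 0.2% of the outer
radius, residual ~3e-3 mm.

## 7. Inverse characterization

**Cost.** J0 = 100 · RMS(ε_rr^meas − ε_rr^sim) / |mean(ε_rr^meas)| in
percent, over elements on the shared mesh. The absolute value in the
denominator keeps J0 positive (radial strains under inflation are
predominantly negative); a zero-mean reference is rejected as degenerate.

**Search space.** Parameters are affinely mapped to [0, 100] per
dimension, so one normalized poll unit moves each raw parameter by 1% of
its search range — parameters with wider ranges get proportionally more
relevance, and the canonical initial poll sizes (1 for the linear mode,
100 for the non-linear mode) read directly as 1% and 100% of range.
Canonical ranges: E_fib ∈ [390, 1200], E_lip ∈ [1, 100],
E_calc ∈ [500, 10000] kPa (linear); C10 ∈ [1, 50], k1 ∈ [5, 10⁵] kPa,
k2 ∈ [1, 100] for fibrotic GOH, C10 ∈ [0.1, 100] kPa, D1 ∈ [0.005, 0.9]
kPa⁻¹ for lipids, E ∈ [500, 10⁴] kPa for calcifications.

**Generating Set Search.** Opportunistic polling of the 2d signed
coordinate directions with dynamic ordering (last successful direction
first); mesh ×2 on success (capped at 100), ×0.5 on failure. Success uses
the GSS sufficient-decrease rule (forcing function ρ = 1e-4·mesh²):
improvements smaller than ρ still move the incumbent but count the poll
as failed, so noise-level gains on weakly identifiable parameters
(calcification stiffness above all) cannot keep the mesh inflated.
Re-polled lattice points are served from a cache without consuming
budget. After each accepted poll a Hooke–Jeeves pattern move extrapolates
the step, which follows the diagonal C10–k1 compensation valley of the
GOH cost far faster than axis polls alone. The non-linear mode prepends a
10-point Latin-hypercube search phase (budget-counted, seeded) — the
search-poll paradigm's global step, serving the same purpose as the
initial mesh of 100. Termination: J0 < 10⁻⁴ (read as a fraction, i.e.
0.01%; exposed in config since the tolerance's scale is ambiguous), mesh
below 1e-3 normalized units, the evaluation budget, or an optional
wall-clock budget. Budgets are counted in cost evaluations
(hardware-independent); one poll iteration costs up to 2d evaluations,
so the defaults of 200 (linear) and 150 (non-linear) evaluations
correspond to the reported effort of roughly 180 evaluations and ~40 poll
iterations respectively. Failed cost evaluations (solver divergence,
inverted pull-back candidates, exponential overflow at extreme
parameters) score +∞ and never abort the search. The reported optimum is
the best point ever evaluated.

**Linear pipeline.** One Young's modulus per tissue; each evaluation is a
single Hooke-law solve of the 5 mmHg increment on the imaged
configuration (assembly data cached across evaluations). ν is fixed per
tissue class: 0.333 for calcifications and, by library default, 0.49 for
soft tissues. The reference Neo-Hooke truth table is however consistent
with ν = 0.45, and the two prescriptions genuinely conflict; inverting
with 0.49 against a ν = 0.45 truth biases the recovered lipid modulus
~25% low (the fibrotic modulus is barely affected). The recovery *study*
therefore inverts with the truth-consistent ν = 0.45; both variants are a
keyword away (`nu_soft`). Success rate sr = 100(1 − |E_real − E_est|/E_real),
unclamped. After the fit, each modulus is profiled across its range; a
parameter whose profile moves J0 by less than 1% of its best value is
flagged weakly identifiable rather than treated as an error (calcification
stiffness routinely is — the strains inside a 5000 kPa inclusion are too
small to constrain it).

**Non-linear pipeline.** GOH fibrotic (D, κ fixed), Neo-Hooke lipids,
linear-elastic calcifications (mapped through their Neo-Hooke equivalent
inside finite-strain solves). Each evaluation: fixed-K pull-back of the
imaged geometry under the candidate materials → inflation of the ZP
candidate through both frame pressures → J0 of the simulated vs measured
radial frame strains. After termination the pull-back runs once more with
free K. Fibrotic quality is judged by R² between true and recovered
uniaxial curves on λ ∈ [1, 1.3] (different GOH parameter triples can
produce near-identical curves, so curves — not parameters — are compared).

## 8. Study conditions and problem sizes

The synthetic studies fix: frames at 110/115 mmHg, 20 dB strain SNR,
ground truths E_fib = 600 / E_lip = 10 kPa (via the conversion table) with
a 5000 kPa calcification for the linear study, and the stiff calcified
GOH set (C10 = 9.58 kPa, k1 = 17564 kPa, k2 = 0.51) with a Neo-Hooke lipid
for the non-linear study. The linear study runs on the calcified surrogate
(cap 0.2 mm, 0.065 mm edges, ~5,300 elements); the non-linear study runs
on the single-lipid surrogate (cap 0.3 mm, 0.1 mm edges, ~2,200 elements)
— the simple-plaque regime in which the reference analyses report their
headline recoveries, complex multi-inclusion geometries being their known
failure mode. Budgets: 200 evaluations (linear, 5 noise seeds, medians
reported) and 150 evaluations (non-linear). Typical outcomes at these
conditions: median sr_fib ≈ 95, sr_lip ≈ 77; fibrotic curve R² ≈ 0.95 with
J0 within ~1 percentage point of the 20 dB noise floor; the non-linear
J0 undercuts the linear one on identical GOH frames by ~70%. Note the
truth k2 = 0.51 lies below the k2 search range [1, 100] — exact parameter
recovery is impossible by construction, which is precisely why curve-R²
is the metric.

## 9. What the synthetic data does and does not show

The generator emulates: plausible cross-section scale and stenosis,
thin-cap lipid plaques with optional calcification, pressurized imaging
with ground-truth segmentation, infinitesimal relative strains, and
white strain noise at the stated SNR. It does not emulate: real speckle
statistics or displacement-estimator correlation structure, segmentation
error (labels are exact), residual stresses / opening angles, 3D effects,
tissue heterogeneity within a label, or patient geometry variability.
Passing recoveries here show the inverse machinery is correct and
well-conditioned under the stated noise — not that the method attains the
same accuracy on clinical IVUS.

## 10. Known limitations

* CPE3 elements lock mildly at ν → 0.5; moduli recovered from linear
  inversions inherit a small stiffness-dependent discretization bias
  (the fibrotic modulus recovers at ~568 of 600 kPa on the default mesh).
* The fixed-K = 1 pull-back inside the optimization biases fibrotic
  stiffness slightly high; the final free-K pass corrects the geometry
  but not the already-selected parameters.
* Golden-section pull-back assumes a unimodal residual in K (observed, not
  proven).
* The GSS is a local method; the search phase and mesh-100 poll mitigate
  but do not eliminate dependence on the cost landscape.
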