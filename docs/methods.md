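# Methods

## Degradation kinetics

The model tracks one scalar per material point, the degradation degree
`D ∈ [0, 1]`, defined as the fractional loss of fracture strain relative to
virgin material: `D = (ε₀ − ε_t)/ε₀`.  Its evolution under a sustained
maximum principal strain `ε` follows the power law

    D(ε, t) = a (b + c εⁿ) tᵐ,   t in days,   capped at 1,

with fracture strain `ε_t = ε₀(1 − D)`.  The underlying physics is
strain-accelerated hydrolysis of the semi-crystalline PLLA network; the law
is phenomenological — fitted to coupon experiments, not derived from
hydrolysis chemistry.  Molecular-weight kinetics, autocatalysis and
hyperelastic softening of the polymer during degradation are deliberately
out of scope (the coupon data the constants come from show stiffness and
yield changing little while the fracture strain collapses).

Parameters, all dimensionless (defaults = the published coupon fit):

| symbol | default | role |
|---|---|---|
| a | 0.385 | overall rate amplitude |
| b | 0.152 | strain-independent (hydrolytic) floor |
| c | 0.616 | strain-acceleration amplitude |
| m | 0.342 | time exponent (sub-diffusive, <1) |
| n | 0.236 | strain exponent |
| ε₀ | 1.22 | virgin fracture strain |

ε₀ is a coefficient, not a hard-coded constant, so other PLLA batches can be
modelled.  Whether `ε` is engineering or logarithmic strain is left to the
caller: the law uses whatever measure the supplied strain field uses, and
the constants were fitted on engineering pre-stretch.

**Time to fracture.**  Death occurs when `ε_t ≤ ε`, i.e. `D ≥ 1 − ε/ε₀`;
inverting the law gives

    t*(ε) = [ (1 − ε/ε₀) / (a (b + c εⁿ)) ]^(1/m),

0 for `ε ≥ ε₀`.  `t*` is strictly decreasing in ε and is unit-tested against
an independent bisection on the forward law.  Months are 30 days throughout.

**Accumulation under time-varying strain.**  The coupon data constrain only
constant-strain histories, so the stepping rule is a design choice.  The
default is an equivalent-time (strain-hardening) scheme: given the current
degree, find the pseudo-time `t_eq` that would have produced it at the
*current* strain, then evaluate the law at `t_eq + dt`.  It is chosen
because it composes exactly — any partition of `[0, T]` at constant strain
reproduces the closed form at `T` to floating point — and because damage
stays irreversible when strain drops.  The naive alternative (re-evaluating
the law at global time with the current strain) is available as
`mode="global_time"` for comparison; with a frozen strain field the two
coincide up to roundoff.  Damage is monotone non-decreasing and `D = 1` is
absorbing under both modes.

**Coefficient fitting.**  Bounded trust-region least squares
(`scipy.optimize.least_squares`, `a,b,c ∈ [0,10]`, `m,n ∈ [0.01,3]`),
initialised at the published constants by default; deterministic for a
fixed initialisation.  The design demands ≥5 records spanning ≥2 distinct
strains and ≥2 distinct positive times, else the fit aborts with an
identifiability error.  Note the exact scale degeneracy
`a(b + cεⁿ) = (ab) + (ac)εⁿ`: only the products `ab`, `ac` and the
exponents are identified, so individual values of `a, b, c` returned from a
distant initialisation can differ while fitting the data equally well.
Measurement noise therefore inflates the spread of the reported
coefficients — mostly of the weakly identified exponent `n` — well beyond
what the residual norm alone would suggest.

## Scaffold model and simulator

The scaffold is a set of elements with volume (mm³; mass at unit density),
a maximum principal strain, and shared-face adjacency.  The strain field is
**frozen** during degradation — the core simplification that removes the
finite-element dependency, justified by the observation that deployment
strains change little while the device degrades.  Users with FE output can
still supply updated fields per run.  Negative principal strains are clamped
to zero on input (with a logged count): compression does not drive the
tensile law.  CSV input requires explicit neighbor lists (no geometric
inference); legacy-ASCII VTK hexahedral meshes are also read, with volumes
from a 5-tetrahedron decomposition and adjacency from shared faces.  The
VTK I/O is a purpose-built minimal reader/writer for this one format.

The engine steps all alive elements, updates fracture strains, then applies
deaths **simultaneously at the end of the step**, making results independent
of element ordering.  Each element's death time matches `t*(ε)` within one
step; halving `dt` moves any death time by at most the coarser step.
Defaults: `dt = 0.5` days, horizon 180 days, snapshots every 30 days
(whole months).  Reported per step: mass-loss ratio (dead volume over total
volume — exact mass conservation holds by construction), connected
components of the alive-element graph (a discontinuity event is any
increase over the intact count), and the capacity surrogate.

**Capacity surrogate.**  Alive mass fraction, zeroed once the alive graph
has lost every cycle it initially had.  Rationale: the scaffold's hoop
stiffness needs a closed circumferential load path; when the rings are all
severed the device no longer pushes on the wall regardless of how much mass
remains.  This is a connectivity surrogate for the stent–artery contact
force — computing the force itself needs the FE contact solution, which is
out of scope — and it is deliberately conservative: breaking every ring of
the coarse synthetic topology happens as soon as all crowns (which are its
cut vertices) fail.  For structures that are acyclic to begin with the
cycle condition is skipped and the surrogate is the alive mass fraction.

**Strain histogram.**  Mass-weighted fractions over strain intervals, with
the default edges (0.036 … 0.29) taken from the representative material
points conventionally used for this device; open end bins guarantee the
fractions sum to 1.

## Artery surrogate

Incompressible isotropic reduced-polynomial hyperelasticity,
`U = Σᵢ₌₁..₆ Ci0 (Ī₁ − 3)ⁱ` with the published coronary-wall constants
(C10 = 6.52e-3 … C60 = 8.69e-2; units MPa by convention for coronary
tissue — the source tabulates no units).  No volumetric term is published,
so incompressibility is assumed and the uniaxial Cauchy stress uses the
standard reduction `σ = 2(λ² − 1/λ) ∂U/∂Ī₁` at `Ī₁ = λ² + 2/λ`.  Because
C50 < 0 the polynomial is not globally convex; positivity of U is asserted
on the physiological range `Ī₁ ∈ [3, 4.5]` only.  The small-strain uniaxial
modulus is `6·C10`, verified against a central finite difference.  The
lumen-diameter trend interpolates monotonically between the deployed
diameter (capacity 1) and the unloaded diameter (capacity 0) — linear by
default, smoothstep behind a mode flag — because no constitutive coupling
between capacity and diameter is published; it is a reduced-order trend,
not an FE prediction.  Recoil is plain bookkeeping,
`100 (D_exp − D_rec)/D_exp`, reported to one decimal.

## Synthetic data

`generate_stent_field` builds a coarse ring-and-link graph (default: two
rings of six peaks, four elements per strut, three link chains — the device
topology at coarse resolution) and assigns strain by structural role:
crowns 0.3, links 0.12, bodies 0.03, each with multiplicative lognormal
scatter (σ_log = 0.15) so strains stay positive.  The levels reproduce the
qualitative ordering seen in deployed devices — crowns fracture first
(t* < 30 d at the nominal crown level), bodies persist past six months
(t*(0.03) ≈ 190 d) — not any particular FE field; with scatter, individual
body elements can stray above the 180-day line, which is physical
heterogeneity, not an error.  The element volume default (2.7e-5 mm³) is a
0.03 mm cube, the brick-element scale of the real mesh.
`generate_degradation_dataset` emulates the coupon experiments: the forward
law on the 3-strain × 4-time design plus seeded Gaussian noise clipped to
[0, 1].  Both generators are byte-reproducible for a fixed seed.

What passing tests on these fixtures show: the kinetics, bookkeeping and
stepping machinery are correct and internally consistent.  What they do not
show: agreement with any specific deployed device, whose mass-loss
percentages and discontinuity dates depend on the unpublished FE strain
field and contact solution.  Relatedly, experimental "degradation" is often
reported as molecular-weight decrease, a different physical quantity from
the mass-loss ratio this model reports; the two should not be compared
numerically.

## Numerical choices and limitations

- Simulation sizes in tests are kept small (≤ ~1,000 elements, dt ≥ 0.25 d);
  the engine is vectorised and scales linearly in elements × steps.
- Graph work (components, cycle test) is recomputed only on steps where
  deaths occur.
- Death events are logged at the end-of-step time, so simulated death times
  carry a +dt/−0 bias bounded by one step.
- The fracture criterion is evaluated per element, not per integration
  point, and stress is never redistributed after a death (no FE re-solve);
  fatigue and pulsatile loading are out of scope.
- Arterial remodeling and PLLA softening during degradation are not
  modelled (insufficient supporting data).
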