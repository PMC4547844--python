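# Methods

`limbgrn` reverse-engineers the gene regulatory network that interprets the
opposing FGF and retinoic-acid (RA) gradients to position the proximodistal
(PD) segment markers Meis (stylopod), Hoxa11 (zeugopod) and Hoxa13 (autopod)
in a growing 2D limb-bud domain.  This note records the models, the numerical
choices, what the synthetic data generator does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Reaction–diffusion model

Six species are tracked per mesh element: FGF signalling (F, one variable
standing for the combined AER ligands), RA (R), the RA-degrading enzyme
Cyp26b1 (C), and the markers M, H11, H13.  Each obeys

    dc/dt = P(c, x, t) + D ∇²c − λ c,

with the bilinear sink −c₁·C·R added for RA.  Regulatory production terms are
Hill functions — activation x^μ/(k^μ+x^μ), inhibition k^μ/(k^μ+x^μ) — with
multiple regulators combining multiplicatively.  One shared steepness μ
governs every interaction except the Hoxa13⊣Hoxa11 repression, which has its
own coefficient μ̃ because that repression is experimentally very fast (the
two expression domains become mutually exclusive almost immediately).

The upstream circuit common to all topologies is F→C (threshold k₁), linear
degradation of R by C (strength c₁), and R→M (k₂), plus H13⊣H11 (k₇, μ̃).
The candidate topologies differ in how the gradients feed the Hox genes:

| model | wiring                              |
|-------|-------------------------------------|
| A     | R⊣H11, R⊣H13 (RA-dominant)          |
| B     | F→H11, F→H13 (FGF-dominant)         |
| C     | F→H11, R⊣H13 (**crossover**)        |
| D     | R⊣H11, F→H13 (anti-crossover)       |
| E     | C plus M⊣H13                        |
| F     | C plus M⊣C                          |
| X0    | all four RA/FGF→Hox links           |
| X1–X4 | X0 minus one link each              |

Fixed values: production and decay of C/M/H11/H13 at 0.05/min (unit maximal
steady state), D_R = 600 µm²/min, D_F = 100 µm²/min (literature estimates),
source strengths P_R = 0.3/min and P_FGF8 = 0.015/min (these set the
dimensionless concentration scale of the gradients so regulatory thresholds
fall inside their search bounds).  Free: P_FGF4, λ_F, λ_R, μ, μ̃, c₁ and all
thresholds k.  The threshold names follow the links (k_FH11, k_RH13, …)
because the generic numbering k₃–k₆ does not identify which link each
belongs to; the correspondence is configuration, not fact.

## Growth domain

The published limb growth map is not distributed, so the domain is a
parametric stand-in that preserves the two geometric facts the analysis
turns on: a straight proximal RA source line (the flank) and a curved distal
FGF source arc (the AER).  The outline at hour h is a half-ellipse with PD
semi-axis growing 350 → 1100 µm over 36 h and a half-width of 300 µm + 2
µm/h, so elongation is strongly PD-biased (anisotropic growth).  The AER
occupies the distal 75% of the arc (the ridge is the distal rim, not the
whole margin; letting the sources wrap to the flank corners floods the
proximal tissue with FGF).  The FGF4 sub-source starts on the posterior 30%
of the AER and expands linearly to the whole arc by hour 18.

Meshes are rebuilt every hour (boundary points at the target spacing,
hexagonal interior lattice, Delaunay, quality floor 0.08 on the radius
ratio; default target edge 65 µm ≈ 130–300 elements over the 27-h window).
Between consecutive meshes a transfer map is built from exact polygon
overlaps of the displaced old elements with the new elements (shapely
clipping); columns are normalized so every old element's amount is fully
redistributed, which makes remapping conserve total amount to round-off by
construction.  Growth is the affine map that scales material points with
the domain semi-axes.

Morphogen sources are areal fluxes, not per-element labels: a source element
produces at P × (boundary edge length × 28 µm)/element area, so total source
strength is independent of mesh resolution (28 µm is the effective
boundary-element depth of the default mesh; with per-element rates the RA
profile changed ~30% under grid refinement, with the flux form < 1%).

## Time integration

The default scheme is IMEX at dt = 2 min: reaction and decay are advanced
by exact exponential integration (exact for the single-species linear
problems, and unconditionally stable for the RA sink even when c₁·C is
large), diffusion by backward Euler through a sparse LU factorization
precomputed once per mesh.  Both parts conserve total amount to solver
precision, and the scheme is ~5–10× faster than the explicit alternative
at equal accuracy on these smooth dynamics.  A plain explicit Euler scheme
(dt ≤ 0.25·A_min/D_max) is retained as the reference integrator and
cross-checked against the IMEX results in the tests.  Simulations start
from a 3-h presimulation of the gradients on the static initial mesh
(upstream circuit active by default; a diffusion-only mode is provided),
with the three markers starting at zero.

## Synthetic expression data

Real inputs were whole-mount in situ stains mapped onto the growth model;
neither is distributed.  The generator replaces them: the curated Model-C
truth parameter set is simulated over mE10:09 → mE11:12 (27 h), and staged
observations are drawn at 4/26/32 time-points for M/H11/H13 (evenly spaced
in each gene's active window), with truncated-Gaussian noise (sd 0.05) on
the raw concentrations, a steep sigmoid rescaling x^μ/(k^μ+x^μ) with
k = 0.5, μ = 8 (so the information carried is domain *shape*, not level),
and unit weights except the last Hoxa11 time-point (weight 20 — its complex
late shape matters most).

The truth set (P_FGF4 = 0.01, λ_F = 0.0016, λ_R = 0.006, μ = 6, μ̃ = 8,
c₁ = 0.5, k₁ = 1.1, k₂ = 0.7, k₇ = 0.3, k_FH11 = 0.45, k_RH13 = 0.1; plus
k_MC = 1.0 / k_MH13 = 1.1 for Models F/E) was selected by a staged numerical
screen over ~600 candidates for the canonical phenomenology: broad early
Meis retreating proximally, Hoxa11 switching on distally and resolving into
a medial band whose proximal boundary is more curved than its distal one
(the "dumbbell"), Hoxa13 onset distal-posterior with proximally expanding
domain and mutual exclusion against Hoxa11 — and the classical perturbation
responses (see below).  Relative to the real limb the synthetic timeline is
compressed (Hoxa13 turns on around hour 5 rather than hour 12 of the
window): the long-range FGF persistence required for Hoxa11 survival after
AER removal also advances RA clearance.  Passing tests therefore demonstrate
method recovery under a self-consistent forward model, not quantitative
agreement with mouse data: observation counts, staging density, noise and
rescaling emulate the WMISH pipeline, but image artefacts, staging error and
biological variability between limbs do not appear.

Display parameter sets for Models A/B/D (same upstream circuit, thresholds
chosen so a late Hoxa11 band exists) are shipped for the boundary-geometry
comparisons; the anti-crossover Model D reverses the curvature relation, as
its wiring dictates.

## Objective and optimization

The score of a simulation against a dataset is the weighted sum over genes
and staged time-points of the per-element mean squared difference between
the sigmoid-rescaled simulated field and the observation.  Normalizing by
element count makes scores comparable across resolutions — the trade-off is
that raw-sum scores from other mesh sizes are not directly comparable, so
published absolute score values cannot be reproduced, only orderings.  An
area-weighted variant exists for refinement studies.

Free parameters are searched in a unit box: log₁₀ for rates and thresholds
(they span orders of magnitude), linear for μ, μ̃ and P_FGF4; bounds are
k ∈ [10⁻³, 2], λ ∈ [10⁻³, 1]/min, c₁ ∈ [10⁻², 10²], μ ∈ [1, 12],
P_FGF4 ∈ [0, 1]/min.  The multi-start protocol runs 27 local descents per
topology: a 3×3×3 grid over three upstream parameters that affect every
gene (λ_F, λ_R ∈ {10⁻³, 10⁻², 10⁻¹}, c₁ ∈ {0.03, 0.3, 3} — three values
spanning two orders of magnitude each), remaining parameters drawn at
random within bounds.  The local method is trust-region-reflective
least squares on the weighted residual vector (the objective is a sum of
squares, and Gauss–Newton steps follow its narrow curved valleys far better
than simplex descent; `x_scale='jac'` makes steps scale-invariant along
sloppy directions).  Coarse multistarts use a finite-difference step of
10⁻³ in the unit box; the top starts are refined with step 10⁻⁴, which is
what resolves the bottom of the valley (on noiseless data the refit reaches
numerical zero with exact parameter recovery).  Nelder–Mead and L-BFGS-B
remain available.  A run counts as converged when its best-so-far score
plateaus (relative improvement < 10⁻³ over the trailing window) after
having actually descended; immediate stalls on flat regions count as
failures.  Budgets (27 starts × 36 evaluations, refinement 300 for
selection; 27 × 80 plus two refinements of 1200 for recovery) are desk-scale
configuration.

Model ranking uses best score over starts with convergence count as the
tie-breaker.  The super-model X0 is fitted once and each RA/FGF→Hox link
removed singly, scored with and without refitting.  Robustness checks: every
second Hoxa11/Hoxa13 time-point dropped (26→13, 32→16, keeping the weighted
last Hoxa11 point) followed by a refit from the full-data optimum, and an
altered sigmoid rescaling (k = 0.35, μ = 5 — "under-developing the stain")
under which the selection is repeated.

## Perturbation experiments

*RA bead*: one distal element, tracked through each remesh as the element
receiving the largest mass fraction of its predecessor, secretes RA at
P₀·e^(−ρ(t−t_b)) with P₀ = 20 and a 2-h release half-life (ρ is not
constrained by the source experiments; it is exposed in config together
with a P₀ sweep utility).  Inserted at hour 3, read out at mE10:22: the
RA-controlled boundaries (Meis distal, Hoxa11 distal via Hoxa13) shift
distally while Hoxa11's FGF-controlled proximal boundary stays put — the
crossover signature.

*AER removal*: FGF production zeroed from mE10:16, readout +6 h.  The
perturbed arm additionally reduces the Hoxa11 decay rate by 60% (factor
0.4) from the removal time — the one modification needed for the observed
differential response.  Applying the reduced decay to both arms instead
(a supported option) inflates the control's Hoxa11 steady state 2.5× and
makes the retention comparison meaningless, so the default applies it to
the perturbed arm only, leaving the two arms identical before removal.
Hoxa13 collapses because RA re-invades the distal tip once Cyp26b1 decays;
Hoxa11 survives on residual FGF (λ_F is small and the gradient outlives its
source) plus the slower decay.

*Meis overexpression*: +P_M added to Meis production everywhere, contrasted
between Model E (direct M⊣H13: Hoxa13 levels drop, boundaries stay — no
spatial gradient links the two genes) and Model F (M⊣C: the RA gradient
itself moves, so the Hoxa11–Hoxa13 boundary shifts distally with the
proximal Hoxa11 boundary fixed).  At normal Meis levels both extra links are
inert and the controls reproduce Model C (RMS ≤ 0.03).

Boundary geometry is quantified on three AP transects (anterior, central,
posterior at ±55% of the half-width): supra-threshold (0.5 on rescaled
fields) domain limits with sub-element precision by interpolating the
threshold crossing, a curvature index per boundary (deviation of the
central position from the anterior–posterior chord midpoint), and central
band thickness.  An absent domain is flagged, never scored as zero.

## Single-cell analyses

Evaluating the equations without diffusion (one element, no neighbours)
probes which classical concept the fitted circuit implements.  In the
levels test R and F are clamped and the cell integrated to equilibrium
(3000 min; residual drift < 10⁻⁴/60 min): high RA alone → Meis,
intermediate RA and FGF → Hoxa11, FGF alone → Hoxa13 (two-signal
behaviour).  With both inputs zero the repression-only wiring of Hoxa13
leaves it fully derepressed — the (0,0) corner of the phase map is Hoxa13,
a structural property of the equations.  In the duration test the cell is
pre-equilibrated under high RA, then exposed to an FGF pulse of fixed
amplitude and varying duration with RA as a cell state degraded by the
cell's own Cyp26b1; the dominant marker at pulse offset climbs
M → H11 → H13 with duration (progress-zone behaviour).  Clamping RA to zero
during the pulse instead derepresses Hoxa13 immediately and no Hoxa11
window exists, and any readout long after offset sees only decayed
FGF-dependent expression (0.05/min = 14-min half-life) — hence the dynamic-R
mode and offset readout are the defaults; the clamped mode remains
available.  For the shipped truth circuit the Hoxa11 window is ~25–45 min,
so the representative durations are 0/35/480 min.

## Known limitations

- The growth domain is a stylized half-ellipse: no realistic strain fields,
  no paddle-shaped late bud, no fate-map anchoring; stage labels (mE10:09…)
  index hours, not measured shapes.
- The synthetic timeline compresses marker onset relative to the embryo
  (see above); absolute times and absolute scores are not comparable with
  experimental values, only orderings and signatures.
- Convergence counts depend on the local optimizer and are not comparable
  across optimizers; ranking uses best scores.
- The bead release constant, the single-cell input courses and the altered
  rescaling parameters are reconstructions, exposed as configuration.
- Parameter identifiability is only probed by the per-parameter sensitivity
  scans; no formal identifiability or posterior analysis is attempted.
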