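# Methods

`tdcsphere` models how transcranial direct-current stimulation (tDCS)
montages deposit electric field in the cortex of atrophic versus normal
heads, and how group differences in that field are detected statistically.
Everything runs on synthetic, seeded inputs: the package trades anatomical
realism (tetrahedral FEM meshes of individual MRIs) for an analytic
volume conductor in which every claim is cheap to recompute and every
assumption is explicit.

## Volume conductor

The head is five concentric spherical shells — white matter, gray matter,
CSF, skull, scalp — with default outer radii 70 / 78 / 81 / 86 / 92 mm and
conductivities 0.126 / 0.275 / 1.654 / 0.010 / 0.465 S/m (the values
commonly used for DC stimulation modelling; all configurable). At tDCS
frequencies the quasi-static approximation holds, so within each shell the
potential obeys Laplace's equation and, for a point current source on the
scalp, separates into a Legendre series

V_j(r, γ) = Σ_n [ A_{j,n} (r/R)^n + B_{j,n} (R/r)^{n+1} ] P_n(cos γ),

with γ the angle from the source axis and R the scalp radius. Coefficients
follow from regularity at the origin (B = 0 innermost), continuity of V
and of σ ∂V/∂r across interfaces (a 2×2 solve per interface and order),
and the injected current at the outer boundary, whose angular delta
expands as I(2n+1)/(4πR²). The n = 0 term is excluded: montages conserve
current, and fields are superposed from zero-sum point-source sets.
Electrode pads become equivalent-area spherical caps covered by ≥32-point
Fibonacci lattices (preserving the area dependence of current density);
1.2-cm HD electrodes are single points. Pad sponge/gel thickness is not
modelled — an analytic conductor has no electrode volume.

Numerics: default truncation n_max = 80 (region means change by <0.5 %
against n_max = 120 on the default geometry); radii in mm with currents in
mA give potentials in volts directly, and fields are reported in V/m. The
series is evaluated by upward Legendre recurrences (values and
derivatives), with the tangential field written as
(1/r) Σ R_n P_n′(x) (x p̂ − d̂), which is finite on the source axis. The
solver is validated to machine precision against the closed-form
homogeneous-sphere potential obtained by summing the series analytically
(generating functions of P_n and P_n/n).

Fields are sampled on the mid-gray-matter sphere, the standard reporting
surface for cortical field strength; a single surface keeps the four
indices well defined.

## Montages

Five fixed montages at 2 mA total anodal current: four bipolar protocols
from the dementia-tDCS literature — dual-anode F3+F4 (1 mA each) against an
inion cathode (35 cm² pads); F3 anode vs F4 cathode (36 cm²); F3 anode
(24 cm²) vs right supraorbital cathode (100 cm²); F3 anode vs right
supraorbital cathode (35 cm² each) — plus the uniform 4×1 HD ring (anode
F3, cathodes F7/C3/Fz/Fp1 at −0.5 mA). The right supraorbital area is
taken at Fp2. The sixth montage is chosen per subject by the two-rule
optimizer over eight candidate rings with anodes at F3, F5, F1, FC3, AF3,
FC5, F7, C3 and, as cathodes, each anode's four nearest classic
10-20 electrodes — a rule that reproduces the published F3 ring exactly.
Rule 1 requires the strongest anodal region (area-weighted mean of positive
normal components; a regional-peak variant is available) to be the left
dlPFC among the twenty frontal regions; rule 2 maximizes the anodal minus
|cathodal| mean in the target among survivors, with ties broken by
candidate order. An empty admissible set is reported, not raised.

Sensor positions follow the proportional 10-20 scheme on the sphere
(vertex Cz; nasion–inion meridian at 10 % steps; outer circle at 72° polar
angle; interior rows by great-circle interpolation), with the head frame
x toward the nasion, z through Cz, left hemisphere y > 0.

## Atlas

The frontal parcellation is a spherical-patch stand-in for a
ten-regions-per-hemisphere frontal atlas: polar/azimuth bands on the
anterior half-sphere, mirror-symmetric in |azimuth|, with the dlPFC cell
centred on F3's radial projection and ilPFC wrapping it laterally and
inferiorly; everything outside the bands is non-frontal. Only the relative
geometry of the regions matters for the package's claims; the bands are
config-replaceable. Sampling nodes are a Fibonacci lattice (≥2,000 nodes)
with equal area weights.

## Field indices

Per region × hemisphere, area-weighted: mean and SD of |E| ("normfield")
and of the inward normal component E·n̂ (positive = current entering the
cortex, the anodal convention). The coefficient of variation is
100 × SD(normal component) / mean(normfield), computed within subject and
region, then analyzed across subjects. The focality index is the percent
of the ⌈1 %⌉ highest (anodal) or lowest (cathodal) normal-component nodes
— over all mesh nodes, counted not area-weighted, ties broken by node
index — that fall in the left dlPFC. Raw field values throughout; no
normalization.

## Synthetic cohorts

Per subject, cortical thickness is drawn from the group law (atrophic
2.26 ± 0.12 mm, control 2.41 ± 0.10 mm; redraws below 0.5 mm) and mapped
onto the GM shell by the ratio to the 2.41 mm ↔ 8 mm reference; the CSF
outer radius is fixed, so cortical thinning is CSF expansion. Skull and
scalp are identical across subjects (matched groups; isolates the GM/CSF
mechanism); the WM radius carries a 0.35 mm jitter.

A smooth sphere has none of the local irregularity of folded cortex, and
thinning alone slightly *lowers* within-region CV, so the generator models
atrophy-linked irregularity explicitly, with every amplitude ×1.5 in the
atrophic group:

- **sampling-depth roughness** — a smooth random field (9° correlation
  length ≈ sulcal spacing) perturbs each node's sampling radius within the
  GM shell (SD 0.30 mm control);
- **normal orientation dispersion** — inward normals tilt by |N(0, 14°)|
  about random tangent axes, emulating the orientation variability of the
  cortical sheet; this is the dominant CV mechanism;
- **parcellation displacement** — a rigid rotation of the atlas relative
  to the scalp electrodes (8° SD control), matching the ~1–2 cm
  scalp-landmark-to-DLPFC targeting variability reported for 10-20
  positioning; this drives between-subject differences in which candidate
  ring the optimizer selects (24+24 cohort, seed 0: six distinct rings in
  the atrophic group, two in controls).

What passing tests show, and don't: the cohort reproduces the *directions*
— lower field strength in the atrophic group under every montage, higher
CV in every region × montage cell, HD rings more focal than left-anode
pads with the dual-anode montage least focal — at realistic magnitudes
(≈6 % field reduction; group effect ≈ −0.013 V/m). They do not certify
any individual-head field prediction; gyral geometry, tissue anisotropy
and real skull variation are out of scope.

A second generator draws long-format metric tables directly from a known
hierarchical linear model (named design coefficients, subject-intercept
and residual SDs) for validating the inference engine against ground
truth.

## Inference

Each analysis fits Gaussian hierarchical linear models to one response
(mean normal component, mean normfield, or CV) over the factors region
(10 frontal levels), hemisphere, montage and group, always with a subject
random intercept. The ensemble enumerates the 16 factor subsets with full
interactions among included factors (null, 4 singles, 6 pairs, 4 triplets,
full), optionally adding a 17th model: group as a main effect on top of
the full region × hemisphere × montage structure.

Sampling is by a collapsed conjugate Gibbs sampler: because the model is
jointly Gaussian given the two variances, β is drawn exactly from its
conditional with the subject intercepts marginalized out (Woodbury
identity), then the intercepts, then the variances from their
inverse-gamma conditionals. Collapsing matters: an uncollapsed β/b
alternation mixes arbitrarily slowly for between-subject predictors such
as group. Defaults mirror standard practice: 4 chains × 2000 iterations,
first 1000 discarded; priors are weakly informative on the standardized
response (coefficients N(0, 5²), variances InvGamma(0.01, 0.01)).
Convergence requires split-R̂ < 1.05 on all parameters; non-converged fits
are excluded from ranking with a warning (an optional retry doubles the
iteration budget once). R̂ and PSIS-LOO come from ArviZ; HDIs are computed
directly as the narrowest interval of sorted draws and cross-checked
against ArviZ in tests.

Model selection uses LOOIC = −2·elpd_loo, lower better. The pointwise
likelihood defaults to the **marginal** scope — each row's density with
the subject intercept integrated out analytically, N(xβ, σ² + τ²) —
because the scientific question (does diagnosis predict field strength?)
concerns generalization across subjects. Under the conditional scope
(available via `SamplerConfig.loo_scope`), a between-subject predictor is
predictively invisible whenever each subject contributes many rows: the
intercept is pinned by the subject's own data with or without the
predictor, so group-bearing models can never separate from their
group-free twins except by Monte-Carlo noise. The reported group effect
is the marginal contrast (atrophic minus control, averaged over the
observed design), which is well defined for any winning model.

The summary-statistics utility implements the pooled-variance two-sample
t-test (equal group sizes make pooled and unpooled identical), two-sided p
from the t distribution with n₁+n₂−2 df.

## Problem sizes and determinism

Default study: 24+24 subjects, 2,000 cortical nodes, n_max 80, 4×2000
chains. Tests and the acceptance script use 12+12 subjects and 2 chains
of 1000 (500 warm-up) — sizes at which every qualitative finding above is
stable — and complete in a few minutes on one core. All randomness flows
from explicit integer seeds (cohort draws, per-subject mesh seeds, chain
seed sequences); reruns are bit-identical.

## Known limitations

Concentric spheres cannot express gyral folding, so focality indices are
systematically higher than FEM values on real cortex (the orderings, not
the absolute percentages, are the reproducible content). Tissue
conductivity is isotropic. The electrode–skin interface and pad sponge
geometry are ignored. The CV and ring-selection mechanisms are explicit
stand-ins for anatomical variability, parameterized from targeting
literature rather than fitted to data. LOOIC values depend on the chosen
likelihood scope; only within-scope comparisons are meaningful.
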