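# Methods

## The measurement this package models

During the stance phase of gait the plantar heel pad is compressed
between the calcaneus and the ground. Two synchronized instruments can
observe this in vivo: biplane fluoroscopy tracks the perpendicular
distance from the base of the calcaneus to the ground (the pad
thickness, mm, at 50 Hz), while a pressure plate under the foot records
the heel–ground contact force (N) and contact area (cm²) frame by
frame. From these channels one stress–strain cycle per step is
constructed and six clinical material properties are derived per heel:

| property | symbol | unit |
|---|---|---|
| primary thickness | h₀ | mm |
| peak strain | — | % |
| peak stress | — | kPa |
| Young's (elastic) modulus | E | kPa |
| viscous modulus | η | kPa·s |
| energy dissipation ratio | EDR | % |

Definitions follow the in-vivo convention, with compression positive:

- **primary thickness** h₀ — thickness at the frame where the heel first
  carries measurable force; the strain reference length;
- **strain** ε = (h₀ − thickness)/h₀ (dimensionless, reported as %);
- **stress** σ = force/area, in kPa (10 × N/cm²);
- **peak strain / peak stress** — both read at the maximum-strain
  ("rightmost") sample of the cycle, even when the stress maximum falls
  on another frame;
- **EDR** — area enclosed between the loading and unloading branches of
  the σ(ε) loop, divided by the area under the loading branch, × 100.

## Constitutive model

The pad is modelled as a modified Kelvin–Voigt element: a linear spring
in parallel with a nonlinear dashpot whose drag scales with
compression,

    σ(t) = E·ε(t) + η·ε(t)·ε̇(t).

Note on the source literature: the printed form of this equation in the
originating article is typographically corrupted (a flipped sign and a
missing ε on the elastic term); the form above follows the article's
own description of its model figure — a parallel linear elastic and
nonlinear viscous element — and is the only reading under which the
reported parameter signs and loop shapes are coherent.

Because the model is linear in (E, η), fitting is ordinary least
squares of σ on the two regressors ε and ε·ε̇, **without intercept**
(σ = 0 at ε = 0 by construction). The fit uses the full
loading + unloading cycle by default: η is identified chiefly by the
asymmetry between the branches, which a loading-only fit mostly
discards (a `loading_only` flag exists for sensitivity checks). A
rank-deficient regressor matrix — e.g. a static compression with
ε̇ ≡ 0 — raises an unidentifiable-model error; a negative η estimate is
returned as-is but flagged non-physical.

### Loop energetics

The loading-branch energy density is the trapezoidal integral ∫σ dε
over the loading branch. The dissipated energy density is the area of
the closed loop polygon, computed by the shoelace formula with a
clockwise-positive orientation so a physical loop (loading above
unloading) is positive; the unloading integral is closed with the
chord back to the cycle's start point, which makes the identity

    loading_area − unloading_area = signed shoelace area

exact on the discrete polygon (this dual-route identity is tested to
1e-9). The reported `dissipated` value is the magnitude of the signed
area, with an `inverted` flag for the non-physical case of an unloading
branch above the loading branch. For a closed strain cycle the elastic
term integrates to zero, so the loop area equals the viscous work
η∮ε·ε̇ dε — a second independent oracle checked by quadrature against
the analytic trajectory.

EDR is invariant to uniform rescaling of stress (both areas scale
alike) and, for a fixed trajectory, non-decreasing in η.

## From recording to curve

- **Contact detection.** The detector finds the first frame whose force
  reaches a threshold — by default 1% of the recording's peak force,
  which is robust to plate noise around heel strike — and then refines
  it backwards to the onset of sustained force: it walks toward earlier
  frames while the force stays above a floor of 10% of the threshold,
  or is positive and strictly decreasing toward touch-down. In clean
  recordings this lands within one frame of true contact. The
  refinement matters because the thickness at this frame becomes the
  strain reference: stopping at the 1% crossing itself would read the
  reference ~1–3% into compression and bias every downstream property.
  End of contact mirrors the rule at toe-off; frames outside the
  contact window are dropped.
- **Strain** is not clamped at zero: measurement noise can push frames
  slightly negative, and clamping would bias the least-squares fit.
- **Strain rate** is obtained by central differences (one-sided at the
  endpoints), second-order accurate in the frame interval; no further
  smoothing or filtering is applied.
- **Cycle split.** Loading runs from the contact frame to the
  maximum-strain sample, unloading from there to the last in-contact
  frame, sharing the peak sample; ties at the maximum break to the
  first occurrence. A strain history with no unloading branch is a
  split error.
- Frames are 0-based; the time of frame i is i/frame_rate.

## The forward simulator

The synthetic generator plays the chain backwards so every stage can be
validated against known ground truth.

**Strain trajectory.** The default stance-phase strain pulse is a
raised-cosine (Hann) shape, piecewise around an off-centre peak:

    ε(t) = a·sin²(π t / (2 t_p))             t ≤ t_p
    ε(t) = a·sin²(π (T − t) / (2 (T − t_p)))  t > t_p

with peak strain a, stance duration T and peak position
t_p = loading_fraction · T (default 0.4, i.e. faster loading than
unloading, as in-vivo loops are). The shape is zero with zero slope at
touch-down and toe-off, has a single interior maximum and an analytic
derivative. The quadratic lift-off is deliberate: at 50 Hz, a shape
that jumps a full frame's worth of sine slope at touch-down puts ~5% of
the peak strain into the first frame, so no force-based contact
detector could recover the strain reference to 1%; the Hann pulse keeps
the first-frame strain near 1% of the peak.

**Channels.** Thickness is h₀(1 − ε) plus additive Gaussian noise;
stress follows the model with the analytic strain rate; force is
0.1·σ·area (kPa·cm² → N) plus additive Gaussian noise, clipped at zero
as a real plate reports no tension. The contact area grows with
compression as area_peak·√(ε/a) with a floor of 5% of area_peak so
in-contact frames always report a positive area; the fit never uses
area directly, only through σ. If a parameter/trajectory pair drives
the model stress negative (a very viscous pad unloaded faster than
E/η), the negative part is clipped to zero in the force channel only
and the recording carries a warning record.

**Defaults** (chosen once as the study conditions): stance 0.7 s —
typical for ~1.0 m/s walking — at 50 Hz; peak strain 0.52; peak contact
area 40 cm² (≈580 N peak force at healthy central moduli, i.e. the
~140 kPa peak-stress scale); thickness noise 0.1 mm; force noise 2 N.

**Recovery-study conditions.** The noise-free parameter-recovery grid
and the loop-area oracles span E 150–310 kPa, η 20–140 kPa·s,
h₀ 10–18 mm. At the most compliant/viscous corner the physicality
constraint σ ≥ 0 requires max unloading |ε̇| < E/η ≈ 1.07 1/s, so these
studies use a slower stance (1.4 s, loading fraction 0.4; max
unloading rate 0.97 1/s) — a condition derived analytically from the
grid, not fitted to it. Under the default 0.7 s stance the extreme
corner would clip, which is exactly what the clipping warning reports.

**Cohorts.** A cohort draws per-leg material parameters from
group × status truncated-Gaussian distributions parameterized from the
published summary table (healthy vs type-2-diabetes, time-zero vs
post-loading). Where the source reports a median and range instead of
mean ± SD (non-normal rows), the median stands in for the mean and a
quarter of the range for the SD. Correlation structure is a latent
cascade: per subject and property a latent factor; each leg mixes it
with its own factor at `leg_correlation` (default 0.7); each loading
status mixes the leg factor with a fresh one at a per-property
`status_correlation` anchored in the printed SDs of the
between-status differences (h₀ 0.97 — a leg's thickness barely changes
between sessions — E 0.8, η 0.8, peak strain 0.9). Truncation at
physical bounds is by latent re-draw, erroring after 1000 rejections.
Subject covariates (age, BMI, diabetes course) are drawn from the
baseline-table distributions; a `subgroups=True` design splits the
diabetes group by disease course into the two published subgroup
parameterizations. Everything is deterministic for a fixed seed.

## Statistical framework

Every comparison first runs distribution diagnostics at α = 0.05:
Shapiro–Wilk normality per group and Bartlett's test (with its standard
small-sample correction factor; Levene's mean-centred test is available
behind a flag) for homoscedasticity. The diagnostics then route:

| data | diagnostics | test | post hoc |
|---|---|---|---|
| 2 groups | both normal, homoscedastic | Student t | — |
| 2 groups | both normal, heteroscedastic | Welch t | — |
| 2 groups | any non-normal | Wilcoxon rank-sum | — |
| paired | differences normal | paired t | — |
| paired | differences non-normal | Wilcoxon signed-rank | — |
| 3 groups | all normal, homoscedastic | one-way ANOVA | SNK-q |
| 3 groups | all normal, heteroscedastic | Brown–Forsythe F* | Tamhane T2 |
| 3 groups | any non-normal | Kruskal–Wallis | Dunn |

All tests are two-sided at α = 0.05. Rank tests use exact p-values for
n ≤ 25 without ties and the normal approximation with continuity
correction otherwise (matching common statistical-package behaviour).
Post-hoc pairs are computed only when the omnibus test rejects:

- **SNK-q** uses the studentized range on the ANOVA residual variance
  with the span of each pair in the means ordering, harmonic-mean n for
  unequal groups, and the stepwise rule that blocks a pair when a wider
  non-significant span contains it;
- **Tamhane T2** is pairwise Welch tests with Šidák adjustment;
- **Dunn** is pairwise z tests on the pooled Kruskal–Wallis ranks with
  the tie correction, unadjusted.

The Brown–Forsythe test here is the F* statistic for equality of
*means* under unequal variances with Satterthwaite denominator degrees
of freedom (it reduces exactly to the ANOVA F for balanced groups with
a common pooled variance, which is how it is cross-checked).

Summaries are "mean ± SD" when Shapiro–Wilk does not reject and
"median (range: min~max)" otherwise; constant samples are degenerate
and reported in median/range form. Correlation matrices report pairwise
Pearson R with two-sided p and tiered annotations
(. p<0.10, * p<0.05, ** p<0.01, *** p<0.001); constant columns yield
NaN entries and a flag rather than an error. `t_from_summary` computes
the pooled-variance two-sample t directly from printed group summaries
(n, mean, SD) — the only statistic of the original cohort that can be
recomputed exactly from its published numbers.

**Conventions mirrored from the study design, and their cost.** Legs
are treated as independent observations (n = 20 legs from 10 subjects
per group), and no multiple-testing correction is applied across the
six properties. Both choices mirror the study design and are
limitations: with within-subject leg correlation 0.7 the nominal 5%
level is exceeded on clustered nulls and the effective power for
between-group effects is below the independent-n value (a
subject-level clustering option is available but off by default). The
type-I calibration in the acceptance suite therefore uses independent
null samples — it calibrates the routed procedure itself, not the
clustering convention.

## What the generator does and does not emulate

The simulator reproduces: the measurement chain (noise on the measured
channels only, not on derived quantities), the group/status/leg/course
design, realistic thickness, force, peak-stress and strain magnitudes,
and between-status coupling. It does not reproduce: multi-step gait
(one stance per recording), foot placement or area-sensor geometry
(the area trajectory is a plausible monotone shape; fitting never uses
it directly), subject-level biomechanical couplings beyond the latent
correlation cascade (e.g. the strong in-vivo thickness–strain
anticorrelation is not built in), or closed-loop dynamics — the strain
trajectory is imposed, not computed from the force. One visible
consequence: with the published moduli and any realistic ~0.7 s
open-loop strain pulse, the emergent energy dissipation ratio
(~50–60%) is far above the ~19% reported in vivo; the published
(E, η, EDR) triple is mutually consistent only with much slower strain
histories than a smooth stance-time pulse. Passing tests therefore
validate the pipeline's correctness and the statistical framework's
calibration, not the physiological fidelity of every emergent quantity.

## Numerical choices

- Contact threshold 1% of peak force, refinement floor 10% of the
  threshold; both configurable.
- Trapezoidal integration on the measured polyline; no resampling or
  spline smoothing.
- Least squares via SVD-backed `lstsq`; regressors declared collinear
  below a relative condition of 1e-10.
- Strain-maximum ties break to the first frame.
- Identical paired samples short-circuit to (statistic 0, p 1) rather
  than a 0/0 t statistic.
- Moduli are reported in kPa and kPa·s and strain in %, matching the
  clinical table convention.
- File writes are atomic (temp + rename) and byte-stable: floats are
  serialized with `repr` and parsed in round-trip mode, so a re-run
  with the same seed reproduces identical files.
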