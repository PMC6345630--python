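# Methods

## The scientific setting

Rod-shaped fission yeast cells commit to division on reaching a critical
size. Because length, surface area and volume co-vary within one strain,
the analysis relies on strain families of different radius: a geometric
quantity is identified as the sensed one when (i) each strain's
size-homeostasis plot (increment from birth to division against birth
size) has slope −1 in that quantity, and (ii) the three strains' binned
regression lines collapse onto each other in that quantity and not in the
others. `rodsizer` implements this comparison machinery plus the
steady-state model that explains *how* a cortical protein can read out
area or length, and a synthetic-data generator that produces populations
with the statistical structure the analysis assumes.

## Cell geometry

Cells are treated as spherocylinders: radius R, length L, area
A = 2πRL, volume V = πR²(L − 2R/3). From a segmented contour the
symmetry axis is the principal axis of the uniform lamina bounded by the
polygon (closed-form second moments; equivalent to PCA of interior points
without rasterising). Contours whose two principal variances agree within
5% are rejected as axis-undefined. The radius profile R(x) averages
vertex-to-axis distances in axial bins of width max(0.1 μm, L/100) and is
pinned to zero at the poles.

Area and volume are computed three ways: (1) surface of revolution of
R(x) — trapezoidal quadrature of 2πR√(1+R′²) and πR² with
central-difference derivatives (agrees with the closed forms to <0.5% at
≥64 profile samples, the oracle test); (2) per-cell mean radius (taken
over the cylindrical mid-zone, poles excluded) in the closed forms;
(3) population-mean radius in the closed forms. Methodology 3 is the
default for population tables, methodology 2 for radius-binned
division-geometry fits. Vertex density and profile bin width are exposed
as configuration because segmentation pipelines differ in both.

## Synthetic populations

The generator is the study-condition definition, not a tuning dial. A
strain draws a per-cell radius (normal, CV 2% by default) held constant
within the cycle, grows length linearly in time, and divides when its
rule's threshold — perturbed by mean-one lognormal noise — is crossed;
the daughter inherits half the division length times a Gaussian
asymmetry factor (sd 2%). Defaults: area threshold 165 μm² (the division
area of normal-width cells, which at L_div = 14 μm implies
R = 1.876 μm), volume threshold 180 μm³ for the volume-sizer condition,
threshold CV 7.5% (the observed division-size CV), growth rates
0.059–0.061 μm/min across presets (within 5%; the rate only sets the
time axis and does not enter size-vs-size analyses). The thin (1.5 μm)
and fat (2.2 μm) preset radii bracket the normal value the way the
radius mutants do; no published radii exist for them, so they are
configurable stand-ins. Division rules: length, area, exact or cylinder
volume, R^γL, an adder increment in a chosen measure, a timer, or
competing thresholds (first reached wins) — the last producing the
flat-then-slope(−2) crossover in log L_div vs log R with handover radius
R* = √(V*/(πL*)) in the cylinder form.

Lineages are simulated as a single chain (five burn-in cycles discarded)
so birth-size variation arises from the noise propagation itself. Every
stage is seeded; identical seeds give bit-identical output.

What the generator does *not* emulate: cell-to-cell growth-rate
variation, septum placement errors beyond the symmetric-split noise,
radius drift within a cycle, and any photophysics beyond the rendering
described below. Passing tests therefore demonstrate correctness of the
measurement and inference machinery under the assumed statistical
structure, not robustness to every artefact of real microscopy.

## Rendered images and nodal quantification

A rendered cell is a z-sum image: constant cytoplasmic background
(proportional to the cytoplasmic concentration) plus constant membrane
background inside the spherocylinder mask, plus a medial band with
Gaussian axial profile (sd σ_band = W/4, W = 2 μm by default) whose
integrated intensity is the model's steady-state nodal amount times
lognormal noise. A midplane image carries the cytoplasmic concentration
with a dimmer nuclear disc occupying a fixed 10% of the midplane area
(protein exclusion); no point-spread function or photon noise is
modelled. Pixel size must resolve the band (error if larger than
σ_band).

Quantification mirrors the band construction in reverse: masked pixel
intensities are summed onto the axis (one bin per pixel column; the
profile conserves total intensity exactly), the peak is fitted as
baseline + a·exp(−(x−m)²/2σ²), the nodal intensity N sums the profile
over m ± 2σ (baseline-subtracted by default; both modes exposed since a
constant background adds a term proportional to the constant W and does
not change any scaling), and the density is ρ = N/(2πRW) with W = 4σ.
N is a plain sum of samples, so its absolute value depends on the axial
sampling step; ratios and scaling exponents do not.

Numerical choices in the peak fit: the fit is restricted to a window of
half the profile support centred on the smoothed argmax, because the
projected background of a whole cell is flat only in the mid-zone and
tapers toward the poles — a global constant-baseline fit would chase
that taper. σ is capped at a quarter of the window width for the same
reason, and the background is initialised from the window flanks. A fit
whose amplitude is below twice the residual sd raises a no-peak error.
Known limitation: near-spherical cells (L ≲ 4R) have almost no flat
mid-zone and band quantification degrades; the read-back tests use
proper rods. The cytoplasmic concentration is the midplane mean over
cytoplasm excluding the nucleus and (by default, unlike the
nucleus-only exclusion one might use on real data) the nodal zone.

## Steady-state scaling model

Unphosphorylated cytoplasmic protein (copy number N_u) is consumed by a
cytoplasmic phosphorylation route (rate k_p[Ssp1][Cdr2_u]·V) and a
direct membrane-binding route (k_b[Cdr2_u]·A) and replenished by nodal
dissociation (λN_nodal). Steady state (justified by nodal turnover
half-time of minutes, far below the cycle period) gives
k_p[Ssp1][Cdr2_u]V + k_b[Cdr2_u]A = λN. In the wild-type limit the
membrane term is negligible and constant concentrations lump into
K = k_p[Ssp1][Cdr2], so N = K·V/λ ∝ volume; removing phosphorylation
(k_p = 0, the T166A limit) leaves N = k_b[Cdr2]·A/λ ∝ area. Dividing by
the nodal area 2πRW (constant W) gives densities scaling with area
(∝ RL) and length respectively. The model's algebra uses the cylinder
volume V ≈ πR²L — that approximation is what makes the density
predictions exact identities — and the implementation follows it by
default (the exact spherocylinder volume is switchable). A constant
immobile fraction f (N_mobile = (1−f)N) and a constant accessible-volume
fraction c (V_accessible = cV, nucleus and vacuoles excluded) rescale
amounts without touching any exponent; both are implemented and tested
as such. Units are effective fluorescence units throughout: only
scalings are meaningful, never absolute amounts. The steady state is
closed-form; the relaxation ODE exists only as a test oracle.

## Statistics

**Binned regression.** Homeostasis points are binned into 10 equal-width
bins over the central 95% of birth sizes; bins under 5 points merge into
their neighbour; the line is ordinary least squares on bin means
(weighting by SE is exposed but off by default).

**Normalized RMSD.** The three strain lines are evaluated at N = 20
equally spaced points on the intersection of their x-ranges; the three
pairwise root-mean-square deviations are summed and divided by the mean
of all 3×20 line values — making the statistic invariant to common
rescaling of y and to strain order. "Mean of all the y values" is taken
as the mean over the evaluation points of the lines themselves, which
keeps the statistic self-contained. p-values for two RMSDs differing are
Monte-Carlo: slope/intercept pairs are drawn per strain from the
bivariate normal with the regression's estimated covariance (10,000
draws, seeded) and the two RMSD samples compared by Welch's t-test; no
multiple-testing correction is applied.

**Exponent scans.** The γ scan recomputes the three-strain collapse for
S = R^γL over γ ∈ [0, 3] (step 0.01) and reports the argmin. At extreme
γ the strains can fail to share any birth-size range (that separation is
itself the discriminating signal); such grid points score an infinite
objective rather than aborting. The α/β scan fits Q = a·R^αL^β + b by
least squares with β fixed at 1 and α ∈ [−1, 3] (step 0.05), objective =
residual RMS divided by mean Q; only the ratio α/β is identifiable from
the location of the minimum, so the β = 1 gauge is a convention. A
length sizer reads γ = 0, an area sizer γ = 1, an exact-volume sizer an
effective γ ≈ 1.75–1.8 over the preset radius range; volume-scaled
quantities read α/β ≈ 2, area-scaled ≈ 1, length-scaled ≈ 0.

**Division-geometry fits.** Records pooled across radii are binned by
single-cell radius; mean ± SE of log₁₀ L_div per bin is fitted by
weighted χ² against: a flat line (length sizer), slope −1 with free
intercept log(A_div/2π) (area), slope −2 with intercept log(V_div/π)
(cylinder volume), a free-slope line, or the continuous
flat-then-slope(−2) crossover (grid search over R*, continuity
L* = V*/(πR*²) enforced). Goodness of fit is the upper-tail χ²
probability at bins − k dof; χ² of the generating model calibrates to
mean ≈ dof over replicates. Zero-SE degenerate bins get the smallest
positive SE as a floor.

**Segmented homeostasis.** Two independent OLS lines split either at a
fixed fraction (default 60%) of the mean division size or at the
SSE-minimising grid breakpoint; continuity is deliberately not enforced
(both regimes are separate sizers), and at least 10 points are required
per side.

## Problem sizes and precision

The acceptance computations use: 150 replicate populations of 1,000
cells for the sizer slope (a single population's binned-slope estimate
has sampling sd ≈ 0.09 under 7.5% threshold noise, so the replicate mean
with SE ≈ 0.006 is reported); 3 × 500 cells for γ scans; 3 × 400 cells
pushed through contour generation (128 vertices, 0.02 μm jitter) and the
methodology-3 pipeline for threshold recovery; 10 radii × 100 cells for
the log-log slopes; and 3 × 200 model-generated cells at 10% lognormal
noise for the α/β exponents. All computations finish in a few seconds on
one CPU and are fully determined by the command-line seed.

## Known limitations

- Contours are the input boundary: no segmentation of real images is
  provided, and no septum detection or time-lapse tracking.
- The band fit assumes a single medial peak; multi-node substructure,
  node counting and 3D deconvolution are out of scope.
- The flux-balance model is the minimal two-route version; node-formation
  dynamics, the non-nodal membrane pool, and downstream signalling are
  deliberately absent.
- Rendered images are idealised (no PSF, no photon statistics), so image
  quantification accuracy on real data will be lower than the near-exact
  recovery seen here.
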