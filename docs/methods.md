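# Methods

## The lever model

The ankle extensors (m. gastrocnemius, m. soleus, m. flexor digitorum
superficialis) form the Achilles tendon, which inserts on the distal
tip of the calcaneal tuber (point C). Dissection evidence across
mammalian orders shows the tendon running nearly parallel to the tibial
shaft, so the net muscle force line is taken parallel to the tibia.
Treating the tarsus and metatarsus as a single rigid body hinging about
the ankle rotation centre O, the extensor torque is τ = l·F with moment
arm l = OC·sin α, where α is the angle between the force line and OC.
The model's two assumptions — rigid intratarsal articulations and a
hinge (not helical) joint axis — are simplifications that allow
cross-species comparison; neither holds exactly in any real foot.

Because the force line is tied to the tibia while OC rotates with the
foot, dα/dθ = 1, giving α = 90° + (θ_obs − θ_est) and therefore

    mechanical advantage  sin α = cos(θ_obs − θ_est).

θ_est is the joint angle at which the moment arm is maximal (α = 90°).
The advantage is reported unclamped: |θ_obs − θ_est| > 90° yields a
negative value, which the model itself permits. All public angle APIs
use degrees; trigonometry converts internally.

## θ_est from skeletal landmarks

The construction mirrors measurement on a photographed, reassembled
foot skeleton in lateral view:

1. **Circle fit.** A circle is fitted to ≥ 3 points digitized along the
   talar trochlea ridge. The algebraic Kåsa solution (a linear least
   squares problem) seeds a Gauss–Newton iteration on the orthogonal
   point-to-circle distances, run to a relative step tolerance of
   1e-10 (cap 100 iterations). Geometric refinement matters because the
   trochlea is an arc, not a full circle, and the algebraic fit is
   biased toward small radii on short arcs. Three non-collinear points
   return the exact circumcircle; collinear input raises a
   degenerate-geometry error naming the specimen.
2. **Point C** is the calcaneal outline point farthest from the fitted
   centre O (the contact point of the largest concentric circle). Ties
   break by input order. If every calcaneal point falls inside the
   fitted circle the function warns — that configuration is
   anatomically impossible and almost certainly a digitization mix-up —
   but still returns a value.
3. **Angle.** Two undirected lines (the perpendicular to OC through O,
   and the dorsal metatarsal margin) meet at two supplementary angles,
   so an orientation rule is needed: the metatarsal ray runs proximal →
   distal, and the tibia ray takes the side of line OC containing the
   metatarsal midpoint (the dorsal side). This makes extended ungulate
   ankles read above 90° and flexed rodent ankles below, and the result
   is invariant under rotation, translation, uniform scaling and
   reflection of the landmark set (mirrored medial-view digitizations
   give the same angle). If the metatarsal midpoint falls exactly on
   line OC the positive perpendicular is kept; the case has measure
   zero and never arises from real digitizations.

Species-level θ_est is the arithmetic mean over specimens. Adhesive
thickness and re-articulation error in real specimens are not modeled
explicitly; they enter the synthetic tests only as isotropic landmark
noise.

## θ_obs from stance-phase video

One step is one stance phase, touch-down to take-off. Each step is
reduced to six frames at relative times 0, 0.2, …, 1.0 (the five
equal intervals of the video protocol); when supplied sample times do
not hit that grid, angles are linearly interpolated. Species θ_obs is
the mean over the pooled 6 × n_steps frame angles. Pooling and
per-step averaging coincide when every step contributes six frames,
which is the designed case; pooling is the documented choice for
ragged input. The max-deviation statistic — the largest distance from
θ_obs to any pooled frame angle — quantifies how representative a
single mean is of the whole stance. Literature-cited species enter as
pre-aggregated records with the deviation marked unavailable (NaN).
No speed normalization (Froude number, duty factor) is applied; walking
speed variation is an acknowledged limitation of cross-species θ_obs
comparison, not something the package corrects for.

## Phylogenetic comparative statistics

**Covariance.** For tips i, j of a rooted tree with branch lengths,
C[i,j] is the root-to-MRCA shared path length and C[i,i] the tip depth;
Pagel's λ multiplies the off-diagonal. Any stem edge above the root is
excluded — pre-root history is common to all tips and carries no
contrast. Ultrametricity is checked to 1e-6 relative tolerance and
violations warn rather than fail, since published time-calibrated trees
are often slightly off after rounding.

**PGLS.** For the regression θ_obs = β₀ + β₁·θ_est + β₂·ln(mass in g),
the model is y ~ N(Xβ, σ²C_λ). At each λ the GLS β̂ and the ML σ̂² are
analytic (computed via Cholesky whitening), leaving a one-dimensional
profile likelihood in λ maximized by bounded scalar search on [0, 1]
(tolerance 1e-8), with the endpoints checked explicitly because the
bounded optimizer never evaluates them. The Wald table uses the
unbiased σ̂² (denominator n − p) with t reference on n − p df; R² is
taken against the GLS intercept-only model at the same λ̂, and the
overall model p from the corresponding F statistic. A rank-deficient
design raises a singular-design error; a non-positive-definite
covariance raises a numerical error reporting λ and the condition
number.

**Phylogenetic ANOVA.** The observed one-way F is referred to a null
distribution built by simulating Brownian-motion trait sets on the tree
with root state and rate fitted to the data by ML, recomputing F on
each; p = (1 + #{F_sim ≥ F_obs}) / (1 + n_sim). Pairwise
pooled-variance t statistics get simulation p-values the same way
(two-sided on |t|) and are Holm-adjusted. F is location/scale
invariant, so the p-value does not depend on the estimated rate; the
rate is still estimated faithfully. Groups smaller than a configurable
minimum (default 2 in the pipeline, matching the exclusion of
single-species orders) are dropped with a warning. Default n_sim is
1,000; a seed is mandatory in the CLI.

**Spearman.** ρ is the Pearson correlation of midranks; p from the t
approximation on n − 2 df, appropriate at n = 27. An exact-permutation
mode exists for n ≤ 10, mainly to validate the approximation.

**Horse breeds.** The Kiso horse and thoroughbred are two operational
taxa within Equus caballus. Analyses that need one tip per species
select a dataset variant (`kiso_as_horse`, `thoroughbred_as_horse`,
`exclude_horse`) rather than duplicating tree tips.

## Packaged data and known discrepancies

The two fixture tables are transcribed cell-for-cell from the published
study, including their mutual inconsistencies, each analysed rather
than silently corrected:

- The gerbil's printed advantage is 0.88 in the main table and 0.87 in
  the recomputation table; cos(66° − 95°) = 0.8746, so 0.87 is the
  consistent value and the 0.88 cell is presumably rounded from
  unrounded angles. The tapir (θ_est 102 vs 103), macaque (109 vs 111)
  and reindeer (angles transposed) differ similarly between tables.
- Recomputing the count of taxa with advantage above 0.95 from the
  printed angles gives 19 (so does counting the printed advantage
  column directly); the source text reports 18, in a passage whose
  adjacent count ("24 species" above 0.9) also disagrees with its own
  table and discussion (23 of 27). The package reports the computed 19.
- Recomputed Spearman ρ over the 27 printed angle pairs is 0.6966; the
  source reports 0.70 in one place and 0.75/0.74 elsewhere. The
  package reports the computed value; 0.75 is not reproducible from the
  printed data and may reflect unrounded angles or a 26-species subset.
- The printed θ_r-obs column is reproduced by the thoroughbred-dataset
  coefficient set (β₀ = 8.42, β₁ = 0.43, β₂ = 4.87), which also yields
  the reported 3.8° sub-10-kg mean difference, although the text calls
  the Kiso dataset representative. Both published coefficient sets
  (plus the horse-excluded set) are exposed; none is hard-coded as
  canonical.
- "Below 10 kg" is strict (<), confirmed by the seven sub-10-kg rows.

The published PGLS and phyANOVA p-values depend on the TimeTree
topology, which is an external input, so those numbers are validated
structurally (parameter recovery, calibration) rather than
reproduced; any Newick tree covering the taxa can be supplied to run
them.

## Synthetic data

Generators are pure functions of their seed (bit-identical reruns).

- **Trees** are pure-birth (Yule), the simplest ultrametric generator
  adequate for testing, rescaled to unit depth so trait rates are
  per-total-depth. The underlying simulator stops at the n-th split;
  the generator appends the exponential waiting time to the next,
  unrealized split so that terminal branches are positive and the
  covariance is nonsingular.
- **BM traits** are multivariate normal draws with covariance
  σ²C_λ via Cholesky.
- **Feet** place O at the origin, C at a seeded direction and distance,
  trochlea points on the arc facing away from C, and the metatarsal
  tips so the construction returns the requested angle exactly at zero
  noise; isotropic Gaussian noise is then added to every landmark.
- **Stance traces** use a two-harmonic waveform
  sin(2πt) + 0.15·sin(4πt), normalized so the six-frame grid has mean
  exactly θ_mean and extremes ±amplitude — matching the gradual,
  roughly unimodal transitions seen in real stance profiles. The
  normalization is exact when n_frames = 5k + 1.
- **Cohorts** default to the empirical study conditions: 27 taxa, ln
  body mass uniform on (4.1, 15.0) ln-grams (0.06–3,400 kg), θ_est ~
  N(120°, 12°) clipped to (60°, 175°), λ = 0.94, the fitted
  coefficients (4.90, 0.48, 4.87), residual SD 8° (chosen to give an
  adjusted R² near the reported ≈ 0.74; the source does not print a
  residual scale), and locomotor modes drawn at the empirical
  frequencies 12:8:5:2.

What the generators deliberately do not emulate: real bone outlines
(the synthetic calcaneus is three points, not a curve), correlated
digitization error, gait-event detection noise, non-Brownian trait
evolution, and measured (rather than drawn) predictor distributions.
Passing synthetic tests therefore demonstrates correctness of the
computations and calibration of the statistics under the stated model,
not robustness to every failure mode of real photographs and video.

## Validation problem sizes

The simulation studies use sizes chosen to give stable Monte-Carlo
estimates: PGLS recovery over 200 cohorts of 100 taxa (coefficient bias
resolved to ~2 Monte-Carlo SEs; λ̂ median absolute error comes out
near 0.03 against a 0.1 acceptance bound); phylogenetic-ANOVA type-I
calibration over 500 null runs of a 32-tip, four-group design with 200
simulations per test (rejection-rate SE ≈ 0.01 at the nominal 0.05);
θ_est recovery over 200 synthetic feet spanning 70°–150° with landmark
noise of 1 % of the trochlea radius (median error ≈ 0.3°, bound 2°).
The simulation p-value's +1 correction makes the phyANOVA very
slightly conservative at finite n_sim, which the calibration band
absorbs.

## Limitations

Planar hinge kinematics only; no muscle-force estimation from
physiological cross-sections; no 3-D trochlea surface models; no
automatic landmark detection; tree inference and ancestral state
reconstruction are out of scope. The comparative conclusions inherit
the usual caveats of species means: single or few individuals per
species, zoo-kept animals, and unstandardized walking speeds.
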