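# Methods

## Scope and data model

`equiposture` quantifies the posture of a horse's dorsal outline from
2D landmark configurations and tests whether posture relates to
welfare indicators. A configuration is 30 ordered points digitized on a
lateral photograph, running from the first coccygeal vertebra (point 1)
over the withers (the tenth thoracic vertebra, point 15) to the medial
canthus of the eye (point 30). Two analysis schemes are supported:

* **mixed** — eight fixed anatomical landmarks (the clay-marked skeletal
  cues plus the eye), with the 22 remaining outline points treated as
  sliding semilandmarks. Only points 1, 15 and 30 have certain outline
  indices; the other five fixed positions are configurable, with a
  documented default spacing (1, 6, 11, 15, 24, 27, 29, 30) placing two
  marks between croup and withers and three on the neck and head.
* **ssl** — only the eye (point 30) is fixed; all 29 other points slide.

Either scheme can be restricted to the back-and-croup window (points
1–15) or the neck-and-head window (points 15–30; the withers point
belongs to both). Public point indices are 1-based throughout, matching
the anatomical numbering; coordinates use a y-up convention and the TPS
reader offers an image-origin flip for digitizers with y growing
downward.

## Geometric core

**Superimposition.** Generalized Procrustes Analysis in the partial
variant: every configuration is centered and scaled to unit centroid
size, then iteratively rotated (closed-form 2D least-squares rotation,
always proper — orientation is normalized upstream by the horizontal
flip) onto the running consensus, which is the renormalized mean.
Convergence is declared when the consensus moves less than 1e-8
(relative), with a 100-iteration cap; non-convergence is flagged in the
result rather than raised. The final solution is put in a canonical
frame — the consensus chord from point 1 to point 30 horizontal, head
to the right — so aligned coordinates are strictly invariant to
similarity transforms of the inputs. The reported consensus is the
plain coordinate-wise mean of the aligned shapes.

**Thin-plate spline.** Kernel `U(r) = r² log r` with `U(0) = 0` (the
`r² log r²` convention differs only by a positive factor; one is fixed
so printed energies are reproducible). The bending-energy matrix is the
upper-left k×k block of the inverted TPS system; it is symmetrized
exactly and annihilates affine configurations. Degenerate references
(collinear or coincident points) raise errors; nothing is silently
regularized.

**Semilandmark sliding.** Bending-energy sliding: each sliding point
moves only along its local tangent (central difference of its curve
neighbours, one-sided at the endpoints), with displacement magnitudes
solving the closed-form quadratic minimization of the bending energy
toward the reference. The reference is the current GPA consensus,
recomputed each outer iteration (at most 5, stopping when the total
energy drop falls below 1e-6). Points are not re-projected onto the
original digitized curve, which the landmark file does not carry
(tangent-plane variant). The minimum-norm solution of the sliding
system is used, so the energy never increases even when the system is
rank-deficient (near-affine tangential moves).

**Articulation-angle stabilization.** Balance movements of the neck are
cancelled by rigidly rotating the neck-and-head chain (points 16–30)
about the withers so the angle formed by points 1, 15 and 30 is the
same in every photograph. The common reference angle defaults to the
circular mean over the sample. The operation is exactly rigid within
the moved and unmoved subsets. In the full-dorsum analysis it runs
before superimposition; region-restricted analyses do not use it.

## Ordination

PCA is computed on the covariance of the flattened Procrustes-aligned
coordinates (all variables share units, so covariance rather than
correlation). Signs follow a deterministic convention (largest-magnitude
loading entry positive). Deformation grids warp a regular lattice (10%
margin beyond the consensus bounding box, default 24×12 nodes — purely
presentational) from the consensus to the shape at a component's
observed extreme score; figures show the consensus in grey, the axis
minimum in red and the maximum in blue.

## Welfare indicators

Three per-horse indicators are scored from stall observations at a 5%
study-wide significance convention downstream:

* **SB/ARB** (binary): some behaviour shows at least 5 bouts, each of
  at least 3 successive repeats. The bout threshold is read as "≥5
  qualifying events", independent of the observation period. Bouts of
  different behaviours are not pooled.
* **Depressed-like posture** (binary): seen at least once.
* **Ear category**: the favourite posture over exactly 10 foraging
  scans, requiring ≥60%; a 5/5 split is neutral because 60% is not
  reached; asymmetric/lateral positions count as neutral.

Prevalence is reported both raw and half-up rounded to whole percent,
matching the printed style of prevalence tables.

## Statistical linkage

Per-photo PC scores are modelled with a random intercept per horse
(photographs are repeated measures) fit by REML; the horse-level factor
is tested with a Wald F. Denominator degrees of freedom use the
containment rule for between-subject factors, `df_den = n_individuals −
n_levels` (the simplest defensible choice when every tested factor is
constant within individuals; no df method is prescribed by the source
analyses). Quantitative covariates enter as a single continuous fixed
effect (`df_num = 1`, `df_den = n_individuals − 2`). When the estimated
between-individual variance is zero and the design is balanced, the
test collapses to the classical one-way ANOVA F — a property the suite
checks.

Auxiliary tests wrap scipy: Kruskal–Wallis with tie correction
(all-constant input returns a flagged degenerate result), Pearson
correlation, and the Pearson chi-square with a fixed-margins Monte
Carlo option (Patefield sampling, default 2000 tables, seed required)
used when any observed or expected count falls below 5; the Monte Carlo
p-value is `(1 + #{X²* ≥ X²}) / (reps + 1)`. No multiplicity correction
is applied across the PC × indicator grid by default, mirroring the
reporting convention of the source tables; a Holm adjustment is
available but off.

## Synthetic populations

The generator replaces the study's photographs, which are not
deposited. The dorsal template is a fixed smooth curve — a gentle
sinusoid in height over arc length plus localized Gaussian bumps —
parameterized by withers prominence, neck and croup roundness,
head/neck angle, relative head size and baseline (croup-to-eye) length.
The head/neck angle is realized by rigidly rotating the chain beyond
the withers; outlines are validated to keep x strictly increasing, and
individual parameter draws are rejection-sampled into the valid
envelope.

Study-design defaults: 40 individuals, 10 standing and 20 walking
photographs each, a binary group label (balanced) shifting withers
prominence up and neck roundness and head size down by 1.5
between-individual SD (the posture signature associated with
stereotypic/abnormal repetitive behaviour), isotropic landmark jitter
of 2 units (2% of the 100-unit baseline), and a random rigid neck swing
per photograph with 5° SD about the withers. Between-individual SDs
(withers 2.0, neck 2.5, croup 2.0 units; angle 6°; head size 0.12;
baseline 5 units) are chosen so that between-horse posture variation
realistically dominates per-photo jitter — repeated photographs of one
standing horse scatter far less than postures differ between horses.
All randomness flows from one seed through `SeedSequence` spawning, so
stages are independently reproducible.

What the generator does *not* emulate: gait (walking photographs use
the same noise model as standing ones), perspective and lens
distortion, digitizer bias, correlated landmark errors, breed-specific
conformation, and any coupling between posture and the management
covariates (which are drawn independently). Passing recovery tests
therefore show that the pipeline detects a group posture signature of
the stated size under this noise structure — not that real photographs
carry such a signature.

Behaviour streams are constructed to agree with each record's labels:
SB/ARB-positive horses receive rule-satisfying event streams (5–8 bouts
of 3–6 repeats), negative horses receive rule-violating ones; ear scans
realize the recorded favourite category; depressed sightings respect
the binary flag.

## Validation design and problem sizes

`equiposture.validation` quantifies the statistical behaviour of the
pipeline; the same functions back the test suite and
`scripts/acceptance.py`:

* **Type-I error**: 500 null datasets (40 individuals × 10 photos,
  permuted labels); the mixed-ANOVA rejection rate at α = 0.05 should
  fall in a binomial band around the nominal level.
* **Power**: 200 datasets with a 1.5 between-individual-SD shift; the
  rejection rate should reach 0.8.
* **End-to-end recovery**: 100 replicate populations through the full
  pipeline (stabilize → GPA → slide → PCA → mixed ANOVA on PC1–PC3);
  detection means p < 0.05 on at least one component. The paired
  comparison with the unstabilized analysis quantifies the cost of the
  neck-swing nuisance; at the default effect size both arms are near
  ceiling, so the strict paired property is additionally exercised at a
  non-saturating effect size (δ = 1.0, 20 individuals) where the
  difference is informative. Replicates use 3 sliding outer iterations,
  where the energy decrease has long levelled off, to keep the
  replication affordable.

## Known limitations

* The exact outline indices of five of the eight mixed-scheme fixed
  landmarks are conventions, not published facts; conclusions that
  depend on them should vary the scheme definition.
* Sliding does not re-project onto the digitized curve; for strongly
  curved outlines the tangent-plane approximation can move points off
  the anatomical outline.
* The containment denominator df is conservative for unbalanced photo
  counts; Satterthwaite/Kenward–Roger approximations are not
  implemented.
* The chi-square Monte Carlo conditions on both margins; exact
  unconditional tests are out of scope.
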