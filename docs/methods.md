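# Methods

## Scope and data model

The package analyses three kinds of input: (1) genes × cells transcript
count matrices from single-cell libraries of NSC lines (exchanged as
MatrixMarket + TSV sidecars or wide TSV); (2) bulk expression tables,
genes × sample-replicate columns (TSV); (3) planar cell-tracking tables
with one row per labeled cell per frame (CSV with
`cell_id,group,frame,t_min,x_um,y_um`). Each has a matching simulator so
every statistical claim the package makes can be exercised against data
whose ground truth is known.

## Single-cell count model and detection

Expression is modelled as binary per cell and gene: cell *c* transcribes
gene *g* with probability `p_g`, independently across genes and cells.
Conditional on expression, the captured count is Poisson with mean
`d_c · m_g`, where `m_g` is the gene's expected capture at unit depth and
`d_c` a per-cell depth multiplier. Detection is count ≥ 1 (configurable
threshold; presence/absence is the analysis currency, so no normalization
or scaling of counts is applied anywhere). The closed-form detection
fraction is

    P(detect g) = p_g · E_d[1 − exp(−d · m_g)],

evaluated by trapezoid integration over the depth law; the simulator is
validated against it to Monte-Carlo precision.

The Poisson capture choice is the minimal model that reproduces the
depth-inflation mechanism (detection of every gene is an increasing
function of the shared `d_c`); no claim is made that real library counts
are Poisson. The default depth law is log-normal, `d = exp(σZ)` with
σ = 0.8 — read depths in real libraries are highly variable but no
empirical depth distribution is available for the deposited data, so σ is
an explicitly free parameter (σ = 0 or the `constant` family gives the
independence null). Graded expression levels, gene–gene correlation
structure, ambient RNA and doublets are deliberately absent: passing
tests show the estimators are calibrated under the stated model, not that
real libraries satisfy it. Cell-cycle structure is emulated only as an
optional binary G2–M label that scales the capture mean of Hmgb2 / Mki67 /
Top2a; no cell-cycle inference exists in the package.

## Independence prediction and through-origin fit

For genes detected in marginal fractions *p* and *q*, independent
stochastic expression predicts coexpression *p·q* (products extend to
trios). Observed and predicted fractions over a pair set are compared by
least squares constrained through the origin: slope `b = Σxy/Σx²` with
x = predicted, y = observed. Fit quality uses the uncentered convention
`R² = 1 − SS_res/Σy²`, the natural definition for a no-intercept model;
the squared-correlation alternative is available (`r2="corr"`) because
published no-intercept R² values rarely state their convention. Reported
percentages are rounded to one decimal; all internal arithmetic is double
precision.

The default pair set for a headline fit is all within-panel pairs of the
three analysis panels — the A/P trio (Otx2, En2, Hoxa5), a dorsoventral
trio (default Pax6, Irx3, Nkx2-2; a reconstruction, configurable) and the
mixed trio (En2, Hoxa5, Pax6) — de-duplicated (8 pairs). For cross-line
comparisons, mitochondrial (`mt-`) and ribosomal-protein (`Rps`/`Rpl`)
genes are removed by case-insensitive prefix match (the filter names a
gene family, not a casing), and 4000 cells are drawn per line without
replacement under a fixed seed.

## Depth-inflation diagnostic

Cells are ranked by depth (recorded simulator multiplier when present,
otherwise total counts — the observable proxy) and split into equal-size
rank strata (default quartiles; `np.array_split` puts remainders in the
earlier strata). Within each stratum the observed-vs-predicted slope is
refit from stratum-local marginals. Under independent on/off expression,
within-stratum slopes are ≈ 1 for any depth law, while the pooled slope
exceeds 1 whenever depth varies, because detection events of different
genes are increasing functions of the shared depth (a positive-association
argument, so the inflation is an artifact signature, not co-regulation).
Per-pair observed coexpression rises from the shallowest to the deepest
stratum in expectation; at finite n, inversions between adjacent strata
are common for rare pairs, so the summary reports nondecreasing-pair
fractions and the top-vs-bottom contrast rather than demanding strict
per-pair monotonicity.

## Bulk normalization, tiers and the A/P classifier

Replicate columns (`<sample>_<k>`) are averaged before scaling — plots of
replicate ranges suggest no other aggregation — and each gene is divided
by its maximum over a reference sample set: all samples by default, or an
embryo-portion subset, in which case cell-line values may exceed 1.
Genes whose reference maximum is 0 are flagged not-expressed and left
undivided. Normalized values are binned off / low / high with boundaries
0.1 and 0.5, inclusive upward (0.1 → low, 0.5 → high). The thresholds
mimic color-bin figures rather than any stated cutoffs; they are
configurable, and the shipped worked examples use noise-free tier-coded
profiles precisely so that conclusions do not hinge on them.

The classifier assigns every marker an (anterior boundary, posterior
extent) pair on the axis FB < MB < HB < CSC < TSC < LSC < caudal, each
domain split into anterior/posterior halves:

* Brain markers resolve by anteriority: Foxg1 supports a forebrain start;
  Otx2 (spanning FB–MB) a midbrain start when Foxg1 is absent; En2
  (posterior MB–anterior HB) a hindbrain start on its own. Their extents
  end at posterior FB, posterior MB and anterior HB respectively.
* Hox genes default to the posterior half of their class's boundary
  domain for both positions — a brain-marker-free profile expressing a
  class lacks the anterior part of that domain's identity.
* Three anterior-boundary staggerings refine the defaults: Hoxa5 reaches
  only the anterior CSC (its boundary is anterior to Hoxb5's); Hoxa6/a7
  and the CSC/TSC-junction genes Hoxb7–b9 only the anterior TSC, with
  Hoxa9/a10 required for the posterior TSC; Hoxc9 stays within the TSC
  while Hoxc10/c11 extend to the lumbar cord and Hoxa13/b13 to the caudal
  cord.

The sample's interval is then min(anterior boundaries) to max(posterior
extents) over expressed markers; high-tier genes give the core interval
and ≥ low-tier genes the extended one, so core ⊆ extended structurally.
This min/max formulation was chosen over special-case posterior-limit
rules because it makes the classifier provably monotone — raising any
gene's tier can only widen the interval — which a rule list keyed on gene
*absences* cannot guarantee on degenerate profiles; on the six shipped
line profiles both formulations agree. Genes missing from a profile are
treated as off and logged; an all-off profile yields an undetermined
call. The code tables (Hox classes, brain markers, overrides,
dorsoventral sets) ship as plain data and can be replaced from YAML.

The dorsoventral check calls a class (dorsal {Pax3, Pax7, Olig3},
intermediate {Irx3, Irx5, Dbx1, Dbx2, Pax6}, ventral {Nkx6-1, Nkx2-2,
Olig2}; a standard neural-tube progenitor code, configurable) only when
its full marker set is ≥ low tier and no violation exists. Violations:
any partially expressed class (e.g. Nkx2-2 without concurrent Nkx6-1
rules out ventral), and intermediate markers unaccompanied by any dorsal
marker. Anything else is reported `ambiguous` with the violated rules.

## Migration fields

Per-cell velocity at a center frame is the displacement between the
flanking frames divided by twice the frame interval — the mean velocity
over three consecutive frames (−10, 0, +10 min at the default 10-min
cadence), in µm/h. The field averages one velocity per cell (not one per
frame appearance) over all cells whose *center-frame* position lies
within an inclusive 150 µm radius of each 150 µm-grid point; the grid is
anchored at the bounding-box minimum rounded down to a multiple of the
spacing (grid registration is otherwise arbitrary). Cells lacking a
complete frame triple are skipped and counted in the log; empty circles
carry n = 0 and NaN vectors. Axis convention: +y = posterior, so
"posterior-dominant" means |v_y| > |v_x| with v_y > 0; input data may be
re-oriented before loading if recorded differently. Speed summaries
average per-frame velocity magnitudes per cell over the requested center
frames, then report mean and sample SD (ddof = 1) across cells. The
estimator is exact on noise-free constant fields and unbiased under
isotropic positional noise; both properties are tested against a
brute-force per-grid-point loop.

Track simulation seeds cells uniformly in per-group boxes and integrates
`x += v(x)·Δt + ε` with isotropic Gaussian ε per frame; velocity may be a
constant vector or a position-dependent function.

## Numerical and reproducibility choices

* All randomness flows from `numpy.random.default_rng` seeded per run;
  identical seeds give bit-identical outputs, including file round-trips.
* Venn partitions are computed from integer pattern counts divided by the
  cell count, so region fractions are exact ratios and sum to 1 to within
  accumulated rounding (< 1e-12).
* Through-origin fitting rejects an all-zero predictor (undefined slope);
  degenerate inputs elsewhere raise informative `ValueError`s rather than
  propagating NaNs (zero cells, fewer cells than strata, empty groups,
  non-uniform frame spacing).
* Duplicate gene symbols on input are disambiguated with `.1`, `.2`
  suffixes and logged.

## Validation problem sizes

The shipped validation suite calibrates the independence null at 50,000
cells × 20 genes (190 pairs), the depth-inflation property at 20,000
cells over 100 seeds, detection closed forms at 50,000 cells, field
recovery at 60 (noise-free) and 10,000 (noisy) cells plus 100 randomized
brute-force comparisons, and the regional classifier on the six line
profiles; these sizes give Monte-Carlo standard errors comfortably below
the tested tolerances while keeping a full run to a couple of minutes.

## Known limitations

* The coexpression machinery tests a *null*; it cannot distinguish true
  co-regulation from depth inflation when strata are too coarse, and the
  depth proxy (total counts) is itself noisy at low depth.
* The A/P classifier consumes tier codes; with real intensities its calls
  inherit the tier thresholds, which are not biologically derived.
* The migration estimator assumes uniformly spaced frames and does not
  handle track gaps beyond skipping incomplete triples.
* Simulators emulate statistical structure, not biology: no lineage
  dynamics, no spatial expression gradients, no sequencing-read level
  effects.
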