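# Methods

## Coverage model and why ratios work

The observable is the mean on-target read depth of each chromosome,
modelled as

    m[s, c] = D_s · e_c · (cn[s, c] / 2) · ε[s, c]

with a per-sample global depth `D_s`, a per-chromosome capture efficiency
`e_c` fixed by the kit, the chromosomal copy number `cn` (2 for a normal
autosome), and multiplicative noise `ε ~ N(1, σ_c)`. Dividing two
chromosomes of the *same* sample cancels `D_s` exactly, and comparing the
ratio against a cohort sequenced with the same kit cancels `e_c`, leaving
copy number times noise. Everything downstream — normalization selection,
PCA outlier flagging, karyotype grids — operates on such ratios, which is
why every call is invariant to a global rescaling of a sample's coverage
vector (library size, loading differences).

At the depths the pipeline accepts (≥ 50× autosomal mean over
10⁵–10⁷ targeted bases per chromosome) counting noise on a chromosome
*mean* is tiny and the residual variation — capture chemistry, GC effects,
mapping — is well described as multiplicative. This is the reason the
cohort synthesizer draws truncated-Gaussian multiplicative noise rather
than simulating reads.

## Quality control and batching

Samples below 50× autosomal mean depth are excluded ("lower than" is
strict: exactly 50× passes). At that depth a full-aneuploidy coverage
shift clears the chromosome-mean noise floor by more than three standard
deviations. The autosomal mean is target-base weighted when per-chromosome
targeted-base counts are available, with an unweighted fallback otherwise;
the weighted form matches how a pooled mean over the union of targets
would behave.

Capture kit (CES/WES) and indexing mode (single/dual) define batches.
Efficiencies differ across kits and do not cancel between a query and a
mismatched cohort, so cohorts are built per batch; `batch_significance`
runs a Kruskal–Wallis test per autosome on depth-normalized coverage
(`m[s,c] / autosomal mean`) across batches and flags p < .01. Note a
genuine efficiency shift on one chromosome also perturbs every other
chromosome slightly through the shared denominator; the shifted chromosome
carries by far the largest test statistic, which is how the warning names
it.

## Normalization selection

For an autosomal target the candidates are each other single autosome
except 13, 18 and 21, plus the pooled (target-base-weighted) mean of the
other 21 autosomes. Chromosomes 13/18/21 are excluded only as *single*
normalizers — a viable trisomy in a control or query would corrupt any
ratio they anchor — but they still contribute to the pooled denominator,
where their influence is diluted 21-fold, and they remain eligible as
normalizers for the sex chromosomes. Candidates are ranked by the sample
SD (n−1 denominator) of the ratio across the cohort; ties break
deterministically (pooled scheme first, then chromosome number). Under
i.i.d. equal-σ noise the pooled scheme has the smallest denominator
variance and wins for every target; real cohorts have correlated
per-chromosome noise, which is exactly what the ranking discovers (a
chromosome co-varying with the target cancels shared noise in the ratio).

For X and Y a single shared ranking scores each candidate by the mean
beta-dispersion of the XX and XY control clusters in the
(X ratio, Y ratio) plane — a tighter cluster pair separates aneuploid
outliers better. Beta-dispersion is the mean Euclidean distance of members
to their group centroid; the centroid is used because it is closed-form
testable (four corners of a side-2 square → dispersion exactly √2), and a
spatial-median variant (Weiszfeld) is available behind the `center`
argument for users who prefer the robust convention.

## Autosomal outlier rule

Per autosome, the three best ratios form a 3-feature matrix. PCA is
fitted on the control cohort only — centred, unscaled, matching the
convention of the statistical environment this analysis style comes from —
and queries are projected with the control centering, so an aberrant query
cannot move its own threshold (a joint-fit mode exists for the fully
unsupervised variant; on spiked data the two agree). The three ratios are
strongly collinear in copy number, so PC1 carries the signal; its sign is
fixed by positive correlation with the per-sample mean ratio so that gains
always project positive.

Flagging uses the interquartile rule on control PC1: strictly outside
`[Q1 − 5.5·IQR, Q3 + 5.5·IQR]`. Quartiles interpolate linearly at rank
`1 + q(n−1)` (numpy's default, R type 7); the convention is a visible
constant because it sets the bounds. The 5.5 multiplier is far beyond the
0.7413·IQR ≈ σ equivalence of Gaussian data — deliberately conservative, so
that a cohort of hundreds of controls yields essentially no false flags
and anything flagged deserves orthogonal follow-up. Degenerate edge cases:
IQR = 0 flags any query off the median with a warning, and fully
zero-variance control ratios collapse PC1 to the mean-ratio axis so the
same warning path still operates (this only arises in noiseless synthetic
data).

Direction and apparent mosaic fraction come from the mean relative ratio
`r` over the three schemes against the control median: an f-fraction
trisomy multiplies coverage by `(2+f)/2` and a monosomy by `(2−f)/2`, so
`f̂ = 2·|r − 1|` (exact in the noiseless limit, and the estimator the
threshold sweep uses). When a flagged chromosome serves as a single
normalizer in another chromosome's top-3 schemes, that other chromosome's
result carries a cross-contamination note — a true aneuploidy distorts
every ratio it anchors, and users should re-read those calls with the
per-scheme ratios that every result exposes.

## Mosaic threshold calibration

Synthetic mosaics are made by deterministically rescaling a control
individual's chromosome mean — equivalent in expectation to read-level
subsampling and exactly reproducible. Two fraction conventions exist
because "percent mosaicism" is ambiguous: `cell_fraction` (the default; a
fraction f of cells carries the extra/missing chromosome, coverage factor
1 ± f/2) and `coverage_change` (f is the relative coverage change, factor
1 ± f). Every report records the convention used.

`sweep_thresholds` spikes `n_base = 25` distinct, seeded control
individuals per grid fraction (default grid 0.1…1.0) and kind, projects
them through the fitted caller, and defines the minimal detectable
fraction as the smallest grid value whose flagged rate reaches the
detection quorum (default 0.9 — "reliably detected" means ≥ 90% of
replicates flag). A probe fraction (default 0.2) classifies each
chromosome as `both` / `gain_only` / `loss_only` / `none`. Thresholds are
monotone in cohort noise: a chromosome with σ = 0.10 needs a strictly
larger fraction than one with σ = 0.02, reproducing the qualitative
ordering seen on real capture data where gene-dense, GC-extreme
chromosomes are hardest.

## Sex-chromosome karyotyping

Control XX/XY membership is inferred, not declared: per scheme, 2-means on
the (x, y) ratio plane initialised at the extreme-Y and minimal-Y points,
then one trimming pass removing points farther than 6 cluster-dispersions
from *both* centroids (a control-set XXY would otherwise drag a centroid)
and a refit. The cluster with the lower mean Y ratio is XX; a cohort whose
clusters collapse (single-sex input) raises an error asking for explicit
labels rather than guessing.

Copy numbers are referenced to the cluster centres — `x_copy = 2·x/x̄_XX`,
`y_copy = y/ȳ_XY` — because Y capture efficiency varies enormously between
kits (clinical panels target a small, deep Y region; whole-exome kits tile
a much wider one), so absolute Y ratios are not portable but the XY
centroid always means one copy. Estimates are averaged over the three best
schemes and matched to the nearest point of the integer grid
{X0, XX, XY, XXX, XXY, XYY}; anything else is `ambiguous`. A copy estimate
at least 0.25 copy-units from every integer marks a mosaic; the fraction
estimate is the deviation from the nearest normal baseline (XX or XY,
chosen by the coordinate that stays on-grid), which recovers spiked
fractions exactly in the noiseless limit and within ±0.01 on σ = 0.02
cohorts. Deviations *below* 0.25 still report their magnitude and a
`deviation_toward` label, so a 13% XXY mosaic — too small to flag — is
visible as a stable sub-threshold deviation toward XXY across all three
schemes. Intermediate Y copy numbers (0.25–0.75 or 1.25–1.75) with an
integer X copy are labelled `partial_Y_loss`/`partial_Y_gain` by an
optional heuristic (on by default): coverage alone cannot distinguish a
partial Y deletion/duplication from a Y mosaic, so these labels are
explicitly flags for orthogonal confirmation, not definitive karyotypes.

Outlier significance uses one-factor PERMANOVA on the Euclidean distance
matrix of the candidate (or a pooled candidate group) against the nearest
reference cluster. The F statistic partitions the total of squared
pairwise distances by the Gower identity; when the number of distinct
label vectors is ≤ 10,000 the permutation distribution is enumerated
exhaustively (p = #(F ≥ F_obs)/#all), otherwise 999 seeded permutations
are drawn with the identity counted in numerator and denominator so p is
never 0. A single candidate against an n-member cluster has an attainable
floor of 1/(n+1): with a few hundred controls p < .01 is reachable, with
~100 the floor sits just above .01 — such calls grade "suggestive"
(p < .05), mirroring how single mosaic outliers behave against moderate
cohorts. The implementation's F agrees with scikit-bio's PERMANOVA to
machine precision and its exhaustive p with a full-enumeration oracle
exactly; its sampled mode is calibrated (type-I rate 0.049–0.055 at
α = 0.05 over 2,000 null simulations).

## Cohort synthesizer

The generator draws `D_s` log-normal (default median 100×, log-sd 0.25),
applies a kit-specific efficiency profile, per-chromosome truncated
Gaussian noise (floor 0.2), and copy-number factors from the karyotype and
spike list. Residual Y signal in samples without a Y (default 1% of
autosomal-equivalent coverage) models reads mismapping to X-homologous Y
targets, so XX samples sit near — not at — zero Y ratio. Sex-chromosome
mosaic factors scale relative to the baseline copy count (XY gaining an X
in fraction f of cells: 1 → 2 copies, factor 1 + f), unlike the autosomal
2 → 3 gain (factor 1 + f/2); both follow from copy arithmetic.

Three presets (CES-like, WES-single-like, WES-dual-like) put the XY
cluster near (0.5, 1.0), (0.8, 0.8) and (0.5, 0.6) respectively in the
(X, Y) ratio plane, echoing the capture-dependent cluster centres real
kits produce, with per-chromosome noise defaults ordered so chromosomes
13, 16, 17, 19, 20 and 22 are the noisy ones. What the generator does
*not* model: GC-tracking within chromosomes, exon-level variability,
correlated noise between chromosomes sharing chemistry, sub-chromosomal
CNVs, or contamination between samples. Tests passing on synthetic cohorts
therefore demonstrate the statistical machinery under the stated noise
model, not performance on any particular real capture design — on real
data the normalization ranking exists precisely to exploit the correlated
noise the generator omits.

## Problem sizes and determinism

Simulated studies use cohorts of 150–400 controls (real deployments would
use 10× that), 20–50 queries, 20–25 spike replicates per condition, and
999 permutations for sampled PERMANOVA; the permutation kernel is
vectorised so 2,000 null simulations run in seconds. Every stochastic
entry point takes an explicit seed, simulation output is bit-reproducible
given the config, and reports embed the configuration that produced them.

## Known limitations

- Whole-chromosome resolution only: large segmental CNVs (> a few Mb) can
  shift a chromosome mean enough to flag; the per-scheme ratios and the
  contamination notes help, but a general CNV caller is the right tool for
  sub-chromosomal events.
- Queries must match a control cohort's capture and indexing batch; there
  is no cross-kit harmonisation.
- QC gates on absolute depth, so the scale-invariance of calls holds only
  above the 50× floor.
- The partial-Y labels are heuristics over an ambiguous signal.
- Tumour-derived samples violate the model (chromosomal instability) and
  should not enter control cohorts.
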