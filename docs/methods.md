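# Methods

## The statistical model

The quantity of interest is the spatial similarity between two maps over
the brain: a gene's expression profile, observed at each donor's sampling
sites, and a term's meta-analytic activation likelihood, observed
everywhere on a voxel grid. The package treats donors as the unit of
replication ("approximate random effects"): the similarity is estimated
*within* each donor as the OLS slope of standardized activation on
standardized expression (equal to the Pearson r), and the donor-level
slopes are pooled with a one-sample t-test, t = m̄/(s/√n) on n − 1 df.
With six donors this test has little power but a clear interpretation:
it asks whether the correlation would persist in new donors, not merely
whether it is nonzero in these six.

A complementary robustness statistic is the *inter-donor repetition
count*: how many donors are individually significant (two-tailed,
uncorrected, α = 0.05). Its reference distribution cannot be analytic —
activation maps are spatially structured and donors share the map — so it
is built empirically: B random study sets of the same size as the term's
set are drawn without replacement from the database *excluding* the
term's studies (exclusion by study identity), each is turned into a map,
and each yields a repetition count. The empirical p is
#{null counts ≥ observed}/B (plain proportion; an add-one estimator
(1 + #)/(B + 1), which can never return 0, is available behind a flag).
Ties count as extreme, which is conservative.

## Map construction

Studies carry term labels and activation foci in MNI mm. A voxel is
active for a study iff its center lies within a sphere radius of at least
one focus; overlapping foci never double-count. The likelihood map value
is the fraction of active studies, exactly (active count)/n, so values
are rational numbers in [0, 1] and independent of study order. The
sphere radius defaults to 10 mm — the platform convention the source
database popularized; nothing in the analysis depends qualitatively on it
and it is a logged config key. The default grid is 4 mm isotropic over
an MNI-like box (x −90..90, y −126..90, z −72..108; 46×55×46 voxels),
chosen for desk-scale speed; 2 mm reproduces the standard 91×109×91 box.

Whether "activation likelihood" should be a raw frequency or an
association-test statistic is genuinely ambiguous in this literature;
both are implemented (`build_activation_map` and `build_association_map`,
a pooled two-proportion z of term vs. non-term activation rates), the
frequency map is the default, and every output records which mode
produced it.

Sites are read off maps by nearest-voxel lookup (round through the
inverse affine). Interpolation would smuggle in smoothing the donor data
do not justify; synthetic sites sit exactly at voxel centers, where the
lookup is exact.

## The resampling null, efficiently

A donor's correlation depends on a resampled map only through the map's
values at that donor's sites. `study_site_activation_matrix` therefore
precomputes, once per database, a boolean studies × site-voxels matrix;
a resample's map values at the sites are column means over the sampled
rows. This is *exactly* equivalent to building each full map and sampling
it (asserted by a test, not assumed) and makes B = 1000 iterations cost
milliseconds after a one-off precomputation. Per-iteration RNG streams
are spawned from the master seed (`numpy` SeedSequence), so results do
not depend on iteration order and runs are reproducible bit for bit.
Donor-level failures inside an iteration (a map constant at a donor's
sites) are recorded, not dropped; more than 1% of failed donor
evaluations aborts the run.

## Stepwise regression

The two-gene analysis regresses activation at the sites on gene 1,
gene 2 (both standardized within donor) and their elementwise product.
The selection flavor is bidirectional stepwise on partial t-test
p-values, enter at p < 0.05 and remove at p > 0.10 — standard defaults,
exposed as config keys since the procedure is under-specified in the
literature it mirrors; entry ties break lexicographically and an
oscillation guard stops enter/remove cycles. The dependent variable is
standardized too, so reported betas are standardized coefficients and a
single-candidate fit reduces exactly to the simple-regression slope
(asserted to 1e−10). Donors that do not select a term contribute a beta
of exactly zero to the across-donor pooling — a deliberate shrinkage
convention inherited from the analysis this package reimplements: it
biases the pooled mean toward zero and makes the subsequent t-test
conservative for weakly-selected terms. A term selected by no donor has
zero variance and is reported "not testable" rather than tested.

## Screening and domains

Gene screens apply Benjamini–Hochberg (step-up, via statsmodels) across
the random-effects p-values of the screened set at q = 0.05; the
hand-coded step-up serves as an exhaustive test oracle. Robustness is
labeled from the repetition count alone (all donors = robust, one short
= marginal, thresholds configurable) — the full resampling null per
screened gene is available but not the default, for cost. Domain
profiles (nine domains × three sub-domains; two-word sub-domains resolve
as label conjunctions) are reported uncorrected: they are an exploratory
map of where a gene's expression tracks activation, not a test battery.

## Behavior

The sense-of-direction score sums 16 five-point items after mapping
reverse-keyed items v → 6 − v (default reverse set: items 1, 3, 4, 5, 7,
9, 14, the scale's positively-worded items; overridable, since only the
sum convention matters here). The circadian item is a single 1–9 rating.
The sex-adjusted association is the Pearson correlation of the two
variables' least-squares residuals on [1, sex], with
t = r√df/√(1 − r²), df = n − k − 2 (k = 1 covariate), two-tailed. Sex
coding cannot affect the result (residualization is affine-invariant;
tested). The residual method equals the inverse-correlation-matrix
formula to 1e−10 and matches pingouin on random instances.

## The synthetic world

Defaults state the scale of the emulated resources: 400 studies of which
61 carry the target term with ~49 foci each (Poisson truncated at ≥ 1,
so ~3,000 term foci), term foci Gaussian (SD 8 mm) around three
medial-temporal/retrosplenial-like hotspots, background foci uniform over
the bounding box (giving the null real spatial heterogeneity); six donors
× 500 sites, half drawn from the map's nonzero-support voxels and half
uniformly (donors are treated symmetrically; per-donor site counts are
configurable for asymmetric-coverage scenarios); a behavioral sample of
292 (155 female).

Planted effects are exact by construction. For a gene with planted ρ the
latent site signal is ρ·z + √(1 − ρ²)·ε with z the donor's standardized
map profile, so the population site-level correlation is ρ; each probe
adds i.i.d. Gaussian noise (SD 0.3, three probes for the focal gene), and
the probe-averaged correlation attenuates to ρ(1 + σ²/k)^(−1/2) —
verified by Monte Carlo. Default planted values: CRY2 0.3, S100B −0.2,
CLOCK 0.15, ISCA1 0 (a clear focal signal, a negative co-regressor, a
marginal screen survivor, a null comparator); all other panel genes are
pure noise. The behavioral generator draws latent scores bivariate
normal with the planted sex-adjusted ρ = 0.15, adds 0.8-SD sex effects
to both variables (so the marginal correlation is visibly confounded),
and discretizes by equal-width binning of the standardized score onto
1–5 (items, with 0.7-SD item noise) and 1–9 (circadian) — simple,
monotone, and nearly attenuation-free for the 16-item sum.

What the generator does **not** emulate: cortical geometry and
gray-matter restriction, hemispheric coverage asymmetries, gene–gene
co-expression beyond the shared planted map component, spatial
autocorrelation of expression noise, and term co-occurrence structure.
A green recovery test therefore establishes estimator correctness and
calibration under the stated world, not robustness to spatially
autocorrelated noise — the known weakness of this family of analyses
(spin tests and variogram-matched surrogates are deliberately out of
scope).

## Numerical conventions

Standardization uses the n − 1 denominator and rejects constant vectors.
Correlations are clipped to [−1, 1] before p computation; |r| = 1 returns
the smallest positive double rather than 0. Collinear stepwise
candidates (|r| > 0.9999 or design condition number > 1e8) raise, naming
the pair. The interaction constructor enforces its standardization
precondition (|mean| ≤ 1e−6, |SD − 1| ≤ 1e−3). All pipeline randomness
derives from one master seed via named SeedSequence substreams; reports
serialize with sorted keys so identical configurations give byte-identical
JSON, and every report embeds a SHA-256 hash of its config.

## Known limitations

Six donors give the random-effects t-test 5 df; the repetition-count
null is coarse (seven possible counts), so empirical p-values are
discrete and a plain estimator can return 0. The stepwise thresholds
and the likelihood-vs-association map choice are conventions, not
derived quantities; both are logged in every output. The pipeline's
default null uses the likelihood map regardless of the main map mode.
Real-data loaders expect precomputed MNI site coordinates; donor-to-MNI
registration is out of scope.
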