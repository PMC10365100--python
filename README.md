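# imgx

Imaging transcriptomics: does the spatial expression pattern of a gene in
the human brain track where the brain activates during a cognitive
process?

`imgx` implements the full inference chain used to ask that question with
donor microarray atlases (AHBA-style: ~500 sampling sites per donor, six
donors, probe-level normalized expression in MNI space) and coordinate-based
meta-analytic activation maps (Neurosynth-style: studies tagged with term
labels, each contributing activation foci in MNI mm):

1. **Meta-analytic map** — a term's activation-likelihood map assigns each
   voxel the fraction of that term's studies reporting a focus within a
   sphere radius (default 10 mm); a two-proportion association-test z-map
   is available behind a flag.
2. **Per-donor correlation** — within each donor, map values at the
   donor's sampling sites are regressed on the donor's standardized,
   probe-averaged gene expression; on standardized variables the OLS slope
   equals the Pearson r, with a two-tailed p on *n* − 2 df.
3. **Random effects across donors** — a one-sample t-test of the donor
   slopes against zero, t = m̄/(s/√n) with n − 1 df, estimating whether
   the correlation generalizes beyond the sampled donors.
4. **Repeatability null** — the number of individually significant donors
   (uncorrected, two-tailed α = 0.05) is compared with a null built by
   resampling, B = 1000 times, an equal-sized study set from the database
   excluding the term's own studies; the empirical p is the fraction of
   resamples with an equal-or-higher repetition count.
5. **Two-gene stepwise regression** — per donor, activation is regressed
   on two genes' standardized expression and their product (bidirectional
   stepwise, enter p < 0.05 / remove p > 0.10); unselected betas are
   imputed as exactly zero and pooled with the same random-effects t-test.
6. **Gene screening** — the chain is run over a gene panel (e.g. core
   circadian clock genes) with Benjamini–Hochberg FDR at q = 0.05 and a
   repetition-count robustness label (all donors = robust, one short =
   marginal).
7. **Cognitive-domain profile** — one gene against nine domains × three
   sub-domain term maps (two-word terms resolved as label conjunctions),
   reported uncorrected as an exploratory profile.
8. **Behavior** — a 16-item Likert sense-of-direction sum score (reverse-
   keyed items mapped v → 6 − v) is correlated with a single circadian-
   regularity rating, partialling out sex by residualization.

Because the real corpora are large and access-restricted, the package
ships a first-class synthetic-data module that generates study databases,
donor atlases and behavioral tables with *planted, known* effect sizes, so
every stage has a ground-truth recovery test.

## Worked example

```bash
imgx run-all --seed 1 --out results/run1
```

prints (and writes to `results/run1/report.json`):

```
# Synthetic study report

- config hash: `a85f1c113ad8bca1` (seed 1)
- CRY2 vs term map (likelihood): mean slope 0.291 (SD 0.024), t(5) = 29.26, p = 8.735e-07; 6/6 donors significant at alpha = 0.05
- resampling null (B = 1000): observed repetitions 6, null mean 0.47 (SD 0.61), empirical p = 0.000 (plain estimator)
- stepwise random effects — CRY2: mean beta 0.265 (p = 4.94e-06); S100B: mean beta -0.181 (p = 1.33e-05); interaction: mean beta -0.114 (p = 0.00591)
- gene screen: FDR-significant genes: ['CLOCK']
- behavior: partial r = 0.204 (p = 0.0004699, n = 292), marginal r = 0.298
```

Reading it: the default synthetic world plants a spatial correlation of
0.3 between CRY2 expression and the navigation map (recovered as mean
slope 0.29 across the six donors), all six donors are individually
significant while random study sets almost never are (null mean 0.47 of
6), the planted CRY2 (+) / S100B (−) structure survives the stepwise
decomposition, the planted CLOCK signal (ρ = 0.15) is the only screen
survivor at q = 0.05, and the planted sex-adjusted behavioral correlation
of 0.15 is recovered (0.20 here; the confounded marginal, 0.30, is larger
until sex is partialled out).

The same stages are available piecewise (`imgx simulate`, `imgx metamap`,
`imgx correlate`, `imgx nulltest`, `imgx stepwise`, `imgx screen`,
`imgx domains`, `imgx behavior`), reading/writing plain CSV, JSON and
NIfTI, or as library calls (see `imgx/__init__.py` for the public API).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete synthetic study from scratch at the given master
seed — generation, map construction, donor correlations, the B = 1000
resampling null, stepwise, screen, domain and behavioral stages — and
prints the run summary.

## Layout

- `src/imgx/synthetic.py` — generators with planted effects
- `src/imgx/meta_map.py` — voxel grid, study database, activation maps
- `src/imgx/expression.py` — atlases, probe averaging, standardization
- `src/imgx/similarity.py` — donor correlation, random effects, repetitions
- `src/imgx/null_model.py` — study-resampling repeatability null
- `src/imgx/stepwise.py` — two-gene + interaction stepwise regression
- `src/imgx/screening.py` — gene screens, BH-FDR, domain profiles
- `src/imgx/behavior.py` — questionnaire scoring, partial correlation
- `src/imgx/pipeline.py`, `src/imgx/cli.py` — orchestration and CLI
- `docs/methods.md` — modeling assumptions and numerical choices
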