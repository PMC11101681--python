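# Methods

## Scope and data model

The pipeline analyses label-free BioID screens in which each bait cell line
is measured against three negative controls (parental line, GFP–ligase,
nuclear GFP–ligase) in two conditions (untreated, hydroxyurea) with three
biological and two technical replicates. Quantities live in a `QuantMatrix`:
a protein-group × sample table with two aligned layers. Spectral counts are
always observed (a zero is a real zero); an LFQ intensity of 0 or blank in a
MaxQuant-style table means the protein was not quantified and is stored as
missing. Technical replicates are arithmetically averaged into biological
replicates immediately after loading — all statistics downstream operate at
the biological-replicate level, and an averaged intensity is missing only
when every technical replicate was missing.

Row-level quality control removes reverse-database hits, contaminants,
site-only identifications, and groups with fewer than three unique peptides
(boundary inclusive). The protein identity key is the first accession of the
group; gene symbols are used only for reporting.

## Missing-value treatment

Within each (bait-or-control, condition) group of three biological
replicates, every protein is in exactly one regime:

* **FULL** — fully observed; untouched.
* **POV** — partially observed (≥ 1 observed, ≤ `max_missing_pov` = 2
  missing). Imputed by a structured least-squares rule: the predictor for a
  missing entry in column *c* is the protein's mean over its observed
  sibling columns, passed through an affine OLS regression of *c* on the
  same sibling mean fitted on the group's fully observed proteins
  (fallback to the sibling mean itself when fewer than three complete
  proteins exist). Imputations never cascade: predictions are always taken
  from the pre-imputation matrix.
* **MEC** — missing the entire condition. In control groups every MEC entry
  of column *c* is set to `factor × Q_q(observed values of c)` with
  q = 1 % and factor = 0.2 on the log2 scale (deterministic "below
  detection" floor, linear-interpolation quantile). In a bait's own group,
  MEC removes the protein from that bait's NT/HU comparison in **both**
  conditions; without this split, bait-specific preys never seen in the
  nuclear-GFP control would have no computable enrichment ratio, while
  preys absent from a bait would receive fabricated bait signal.

A group with more missing values than the POV bound but not fully missing
cannot occur with three replicates and a bound of two; for other designs it
is treated as MEC (conservative).

Normalization is additive on log2 intensities: per-sample median
normalization to the grand median, then mean centering of each sample to its
condition-group's grand mean. Both preserve within-column differences
exactly, and centering within groups leaves between-group contrasts intact.
The presence rule (observed in ≥ 2 of 3 biological replicates, evaluated on
pre-imputation masks so imputation can never rescue a protein) gates which
proteins enter each bait × condition's downstream results. Whether centering
should act per sample or per protein within conditions is genuinely open;
per sample is implemented as the default reading, and the alternative is a
config choice rather than a silent behavior.

## Interaction scoring

Scoring is a transparent SAINT-style two-component posterior on spectral
counts. For each prey, the background rate is the mean parental-control
count floored at a pseudocount (0.1); per bait column it is scaled by a
total-count library-size factor (bait column sum / mean control column sum).
The interaction rate is the bait's mean count, never below background. Each
biological replicate contributes p_r = L(x_r|λ₁)/(L(x_r|λ₁)+L(x_r|λ₀)) with
equal priors; the score is the replicate mean, exactly 0.5 when the rates
coincide. Replicate counts are fractional after technical averaging, so both
count models (Poisson default; negative binomial with method-of-moments size
from the controls) are evaluated continuously through the gamma function.

Decision gates: a proximal association requires score ≥ 0.95 (parental
control) and AvgSpec ≥ 5. Fold changes over the GFP and GFP-NLS controls
(≥ 1.5, inclusive, conjunctive by default and configurable to disjunctive)
are kept as a separate flag rather than folded into the primary gate — in
the source screens they describe what passing preys usually look like
rather than a hard filter, so the pipeline records both.

Two properties of this estimator are worth knowing. Because λ₁ is
re-estimated from the replicate mean, the score is *not* monotone in a
single replicate's count: raising one replicate raises λ₁ and can lower the
other replicates' posteriors. It is monotone in the level of a consistent
(constant) replicate vector and under uniform count shifts at or above
background, and those are the properties the tests pin. Second, averaging
replicate posteriors means a single background-level replicate caps the
score near 2/3: the gate at 0.95 effectively demands consistent enrichment
across all three biological replicates, which is the intended stringency.

## Differential (hydroxyurea) analysis

The baseline for both conditions is the **untreated** nuclear-GFP control —
treatment leaves nonspecific nuclear labeling essentially unchanged (the
pipeline's `control_concordance` measures this directly; the generator's
no-effect controls reproduce r ≈ 0.99) — so per bait and prey:
ratio_c = log2(linear-scale mean bait intensity in condition c / linear mean
untreated GFP-NLS intensity), enrichment at ratio ≥ 1 (inclusive).

The classified statistic is Δ = ratio_HU − ratio_NT. Per bait, Tukey fences
(Q1 − k·IQR, Q3 + k·IQR; k = 1.5; linear-interpolation quartiles) are
computed on the bait's own Δ distribution over its admissible preys
(presence-passed in both conditions, bait-MEC removed). *Gained* requires
Δ above the upper fence **and** enrichment under HU; *depleted* mirrors it;
any prey that passed no scoring gate in either condition is
*not_interactor* regardless of Δ — this is what prevents treatment-independent
background from being reported as regulated. Tukey fences are the standard
two-threshold interquartile rule for a single distribution; computing
fences per ratio distribution instead of on Δ is exposed as `delta_mode`
but not endorsed as a default. With a constant Δ distribution the fences
collapse and nothing is classified (strict inequalities), which is the
correct degenerate behavior.

## Synthetic data generator

The generator is first-class code: it defines the conditions under which the
pipeline's recovery guarantees are stated.

* **Design**: `n_baits` baits (default 2) and the three controls, each in
  NT and HU, 3 biological × 2 technical replicates (60 samples at default).
* **Classes**: 500 background preys, 30 constitutive interactors
  (8-fold over background in bait samples, both conditions), 10 gained
  (additionally ×4 under HU) and 10 depleted (×1/4 under HU). Controls
  never carry treatment effects; the GFP controls share the parental
  background up to scalars (0.9, 1.1).
* **Counts**: every sample draws a nonspecific background component
  NB(baseline, dispersion) with var = μ + 0.5·μ² (size = 1/dispersion = 2) —
  background binding varies strongly across biological preparations. Bait
  samples add a specific-labeling component with Poisson counting
  statistics, Pois(baseline × (mult − 1)), reflecting that specific
  proximity labeling of an engaged complex is far more reproducible than
  nonspecific sticking. Control and background-prey counts are therefore
  exactly NB(mean, dispersion); interactor bait counts are
  NB + Poisson with the stated marginal mean.
* **Baselines**: background preys draw lognormal baselines with mean
  `background_mean` = 2 and σ = 1.5 (ln units), giving the order-of-magnitude
  dynamic range real proteomes show (and without which a control
  concordance near 1 would be unobtainable); planted interactors sit at the
  typical scale exactly, so recovery measures the method rather than a
  baseline lottery.
* **Intensities**: intensity = `intensity_per_count` × per-sample expected
  abundance × lognormal(0, 0.25 ln). Intensities and counts are coherent
  through the shared rate; intensity noise models LFQ measurement error
  rather than re-importing count shot noise, matching the empirical fact
  that LFQ CVs at low spectral counts are far below count CVs.
* **Missingness**: intensities only. Logistic intensity-dependent dropout
  (midpoint log2 intensity 17.6, slope 1 — about 3 % loss at the background
  median and > 50 % two octaves below it) plus 2 % MCAR. Monotonicity of
  the dropout curve is asserted in tests.
* **Decoys**: six flagged/low-evidence rows (reverse, contaminant,
  site-only, < 3 peptides) exercise the row filters and the manifest's
  row accounting.

What the generator does **not** emulate: peptide-level identity and rollup,
shared-peptide ambiguity, ratio compression, correlated technical replicates
(tech reps are independent redraws, so technical averaging halves count
variance — slightly optimistic), batch effects, and interactor-specific
baseline variation. Passing recovery tests therefore demonstrate the
statistical chain is implemented correctly and calibrated under realistic
noise, not that any particular real screen will reach the same sensitivity.

## Numerical choices

* Quantiles and quartiles: linear interpolation between order statistics
  everywhere (declared in config).
* Likelihoods on fractional counts: gamma-function continuation of the
  Poisson/NB pmf.
* Ties in SLSA column ordering: stable by column index.
* Mean centering idempotent to 1e-12; additive shifts preserve differences
  exactly in floating point (a single addition per entry).
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; every simulation output is bitwise
  reproducible for a fixed config.
* Default problem sizes (2 baits × 556 rows × 60 samples) keep the full
  pipeline under ~2 s, chosen so the whole validation suite can run
  routinely; all sizes scale through the config.

## Known limitations

* The scoring model is a deliberately transparent reimplementation of the
  SAINT decision behavior at its gates; it does not reproduce SAINTexpress
  internals (count truncation, informative priors, topology boosting), so
  scores agree at the decision level rather than numerically.
* The library-size scaling of the background rate uses total column counts;
  in screens where true interactors dominate a bait's total signal this is
  anti-conservative (it inflates the background estimate for strong baits).
  It can be disabled per config.
* Tukey-fence classification is distribution-relative: a bait whose
  interactome is globally remodeled shifts its own fences and will
  under-report changes. Formal moderated statistics are out of scope by
  design.
* GO/pathway enrichment, external network retrieval, and raw-spectra
  processing are out of scope; the pipeline starts at `proteinGroups`-style
  tables.
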