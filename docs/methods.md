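# Methods

This note documents the statistical models, the defaults and the design
choices behind `rxagsp`, and what the synthetic studies do and do not
establish about real data.

## Differential-expression meta-analysis (`meta_de`)

**Model.** Within a platform, cohorts are pooled after per-sample
quantile normalisation to the mean sorted profile (configurable off);
the source cohort becomes the batch label. Gene content is intersected
within a platform only — a gene absent from one platform can still be
called on the other.

**Batch shrinkage.** The adjustment is the parametric empirical-Bayes
location/scale model: per gene, expression is standardised under a
least-squares fit with batch indicators and the MYCN group as
covariates; per-batch additive effects get a normal prior and
multiplicative effects an inverse-gamma prior, both moments-matched
across genes, and the posterior means are solved by the standard fixed
point iteration (relative tolerance 1e-4). Keeping MYCN status in the
design protects the group contrast from being absorbed into the batch
terms. A batch with fewer than two samples is an error (its scale is
unidentifiable); genes constant everywhere are passed through with a
warning. A single batch returns the input unchanged.

**Testing and combination.** Welch's *t* per gene (MA − MN), mapped to a
signed normal quantile through the t tail, then combined across
platforms with weighted Stouffer: z = Σ wᵢzᵢ/√Σwᵢ², wᵢ = √nᵢ (platform
sample count) — the standard convention for unequal study sizes. The
two-sided combined p enters Benjamini–Hochberg; the signature call at
FDR < 0.001 requires the fold-change sign to agree on every covering
platform, drops sign conflicts, and retains single-platform genes.
Genes with fewer than two finite values in a group are untestable and
excluded. Moderated-variance models (limma-style) and exon-level
statistics are deliberately out of scope; Welch on ~100 samples per
group is amply powered and assumption-light.

## Variant integration (`variant_integration`)

"Recurrent" means records from ≥ 2 distinct cases; germline GWAS hits
pass regardless of case count, since they carry population-level
recurrence by construction. Overlap statistics use the one-sided
hypergeometric tail with a default universe of 21,000 protein-coding
genes; the universe is a parameter because the sample odds ratio
(reported as the plain a·d/(b·c)) moves visibly between a 20k and a 21k
universe at these marginals. Depletion can be requested with
`alternative="less"` or `"auto"`; the default tail is
over-representation, so zero overlap gives p = 1. Gene symbols are used
as-is — alias resolution is the caller's responsibility.

## Gene-set-pair search (`gsp_prognosis`)

**Index.** I = median(poor set) − median(good set) over the genes
measured in the sample; positive means I > 0, a tie is negative (the
positive class is defined by a strict "higher than"). Medians over
measured genes only; a sample with an entirely unmeasured set is
unscorable for that pair. Because platform gene content is constant
within a cohort, testability is a per-(pair, cohort) property.

**Enumeration.** All subset pairs with both sides ≥ `min_set_size`
(default 2, the value consistent with the published pair count
2,062,468 = (2¹⁰−11)(2¹¹−12) for pools of 10 and 11), in deterministic
(size, lexicographic) order.

**Screening.** Each cohort precomputes a risk table (sorted times, tie
blocks, at-risk counts); for any indicator matrix the log-rank score
U and its hypergeometric variance V are suffix-sum expressions, so
thousands of pairs are scored per cohort in one vectorised pass. The
one-sided cohort p (direction: positive indicator = adverse outcome)
is Φ̄(U/√V); Liptak combines cohorts with weights √n; BH over all
enumerated pairs gives the joint q. Full Cox fits — Newton–Raphson on
the Breslow partial likelihood for the binary indicator, |β| capped at
15 under separation — run only for pairs surviving the screen
(q < 0.05, U > 0 and two-sided log-rank p < α in every cohort).
Selection additionally requires HR > 1 and Cox Wald p < α per cohort.
For a binary covariate without ties the log-rank χ² *is* the Cox score
statistic, so screening with the log-rank score loses nothing. Event-free
survival is the training endpoint; overall survival is for validation.

**Empirical p.** (time, event) pairs are permuted jointly with the
indicator fixed; the add-one estimator (1 + #{χ²_perm ≥ χ²_obs})/(1 +
n_perm) is reported. The permutation scheme is a package convention —
alternatives (permuting indicators) are equivalent here because only the
pairing is broken.

**Orientation diagnostic.** The sign of the cohort-stratified Cox
coefficient equals the sign of the stratified score at β = 0 (the
partial likelihood is concave), so the pool-orientation check reports
the fraction of pairs with a positive stratified score plus a two-sided
sign test — no per-pair stratified fits needed.

**Kaplan–Meier.** Product-limit with tied times grouped; one row per
distinct time with the at-risk count just before it.

## Enrichment and concurrence (`enrichment_concurrence`)

Per-set Fisher's exact tests share the overlap machinery above; BH runs
across the tested sets in deterministic name order; sets above 2000
genes are skipped. A set is enriched when OR > 2 and q < 0.01. Pathway
concurrence applies the same test to enriched-set *names* within a
finite pathway universe (default 185, the KEGG collection size) with the
automatic tail, so both concurrence and avoidance are reported.

## Network bottlenecks (`network_bottleneck`)

Edges are unweighted and undirected regardless of type (interaction
confidence scores and regulator→target directionality are not modeled;
the edge type is kept as metadata). Betweenness is the exact Brandes
accumulation, unnormalised, endpoints excluded; ranking ties break
alphabetically so results are stable under relabeling. "Bottleneck" is
simply the top-k of this ranking; k is a parameter because no principled
cutoff exists.

## RA differentiation (`ra_differentiation`)

Static contrasts: up means q < 0.05 and linear fold change > 1.5 (down
mirrors with < 1/1.5); each experiment may carry its own thresholds
(e.g. a stricter FC > 2 arm). Time courses: per-gene least-squares fit
of expression on categorical time, treatment and their interaction,
F-tested against the time-only model, so the p-value covers every
treatment-involving term; direction comes from the latest-time fold
change. Count-based inputs are accepted as precomputed stats tables —
negative-binomial modeling is not reimplemented. The core set keeps
genes induced in ≥ 2 experiments ("repeatedly") and repressed in none
("without conflicts"); a gene up in two experiments but down in a third
is excluded — the conflict rule dominates support. ΔΔCt: fold =
2^−[(Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_calibrator];
swapping treated and calibrator inverts the fold exactly.

## Synthetic studies (`synthetic_data`)

**What is emulated.** Four cohorts (default 100 patients each) on two
platforms with partial, forced-overlap gene coverage; log2 expression
N(μ_g, σ_g) with μ_g ~ N(7, 1), σ_g ~ U(0.4, 1.2); planted MA_hi genes
shifted +`de_effect` in MA samples and MN_hi genes in MN samples
(`frac_ma_samples` = 0.4 by default); per-batch additive N(0, 0.5) and
multiplicative exp N(0, 0.1) distortions on the noise term, matching the
location/scale model the adjustment assumes; survival exponential with
log-hazard = `planted_log_hr` × indicator and independent exponential
censoring calibrated so a baseline patient is censored with probability
`censoring_rate` (0.2 by default; exact at log HR = 0, slightly lower
for positive-indicator patients otherwise). The planted hazard is tied
to the indicator evaluated on the *observed* expression — the
relative-expression rule is by definition a function of the measured
profile. Pool genes share a common baseline mean so the planted index
partitions patients by the MYCN-driven shifts rather than by arbitrary
baseline offsets between the two sets (which would concentrate nearly
all patients in one class — a degenerate truth). Variants concentrate
≥ 2 distinct cases on each planted pool gene, put background mutations
outside the signature, and include one germline GWAS record; gene sets
plant one MA_hi-enriched and one MN_hi-enriched set among random ones;
the network joins two dense clusters through a two-hub articulation
bridge so the designated bottlenecks are the top-betweenness nodes by
construction. The RA generator plants induced genes with a 2-log2-unit
(4-fold) effect — the strength of a clearly induced differentiation
marker — in ≥ 2 of 3 experiments (4 replicates per arm, residual sd
0.3) and never in the repressed direction.

**What is not emulated.** Probe-level physics, copy-number segments,
sequencing reads, gene–gene correlation beyond the planted structure,
non-proportional hazards, informative censoring, cohort-specific
follow-up horizons (the real cohorts' censoring rates are unknown; the
default is configurable, not calibrated). Recovery results on these
fixtures therefore demonstrate the correctness and calibration of the
machinery under its own assumptions, not clinical performance.

**Problem sizes.** The bundled recovery studies use 300–2000 genes,
4 × 100 patients, pools of 6 + 6 (3249 pairs) and 20 seeds — sizes
chosen so the full suite exercises every stage end to end while staying
comfortably within a single-CPU run; the search machinery itself streams
arbitrarily large enumerations in fixed-size chunks of work per cohort.

## Numerical conventions

Ties in the prognostic index go to the negative class; p-values of
exactly 0 or 1 are clipped before normal quantile mapping (with a
warning); Cox separation is capped at |β| = 15; betweenness ties break
alphabetically; BH is the plain step-up; all randomness flows through
one `numpy` Generator per entry point, seeds are explicit everywhere,
and identical seeds give byte-identical pipeline outputs (checksummed in
the run manifest).

## Known limitations

- The Cox model is univariate by design (the published selection rule);
  clinical covariates and penalised multigene models are out of scope.
- The Liptak weights (√n) and the permutation scheme for empirical p are
  conventions the source analysis leaves unspecified; both are
  parameters of the implementation and documented above.
- Enrichment universes are counts, not membership lists; callers must
  ensure queries live inside the universe they quote.
- The exhaustive search is O(pairs × samples) per cohort; the full
  2 × 10⁶-pair search is tractable on one CPU but the bundled tests and
  demos use the 6 + 6 pools for speed.
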