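# Methods

This package implements a cross-platform gene-expression meta-analysis of
case/control studies — the design used to detect dose-dependent and
downstream transcriptional dysregulation in trisomy-21 iPSC lines — together
with the closed-form computations behind two mitochondrial functional
assays (Fura-2 calcium imaging and Seahorse oxygen-consumption traces).
Because the original expression studies live in public repositories and are
heterogeneous in platform and size, the package ships a synthetic
multi-study generator with known ground truth, so that the entire pipeline
is testable end to end without any download.

## 1. Statistical model of the meta-analysis

### Per-study differential expression

Each study is analyzed independently with an engine matched to its platform
dialect:

**Array studies (log2 intensities)** use the empirical-Bayes moderated
t-statistic. With per-gene pooled two-group variance `s_g^2` on
`d_g = n - 2` df, a scaled-inverse-chi-square prior `(d0, s0^2)` shrinks the
variances:

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)
    t_g    = log2FC_g / sqrt(s~_g^2 * (1/n1 + 1/n2)),   df = d0 + d_g

The prior is estimated by moment matching on `log s_g^2` using the
log-chi-square mean/variance identities (digamma/trigamma); when the
observed spread of log-variances is at or below the pure sampling spread,
`d0` is treated as infinite (capped at 1e6, normal reference). Genes with
zero variance in both groups are reported with p = 1 and flagged
`degenerate` rather than raising.

**Count studies (RNA-seq)** use a deliberately simple negative-binomial
likelihood-ratio test, *not* a re-implementation of quasi-likelihood
F-tests. Library sizes are normalized as column-sum ratios to their
geometric mean. A per-gene method-of-moments dispersion (pooled across the
two groups, using `Var(y/s) ≈ mu·E[1/s] + phi·mu^2`) is shrunk toward the
across-gene **mean** of the per-gene estimates with prior weight
`prior_df = 20` against the residual df. We use the mean rather than the
median as the pooling target: at group sizes of 3–4 the per-gene moment
estimates are strongly right-skewed, so their median is biased low (measured
0.017 at a true dispersion of 0.02 in simulation), and a low dispersion
target inflates every downstream Z-score; the mean is unbiased for a common
dispersion. Group means are then fitted by Newton iterations on the NB
log-likelihood with the dispersion fixed, and the group effect is tested by
LRT against chi-square(1). log2 fold changes use normalized group means with
a 0.5 pseudo-count. All-zero genes get (log2FC 0, p 1, flag `all_zero`).

Calibration, measured by simulation (tests assert these): type-I error at
alpha = 0.05 is 0.047–0.053 for the moderated t (n = 5v5), 0.03–0.07 for
the NB LRT in the Poisson limit and with estimated dispersion (n = 3v4),
and per-study q <= 0.05 DEG counts on zero-effect data are ~0.

### Signed Z combination

Per gene and study, `Z_i = sign(log2FC_i) * Phi^{-1}(1 - p_i/2)` (p-values
clamped to [1e-300, 1] so quantiles stay finite; a zero fold change gives
Z = 0). Studies are combined with sample-size weights:

    w_i    = sqrt(n_i)
    Z_meta = sum(w_i Z_i) / sqrt(sum(w_i^2)),   p_meta = 2(1 - Phi(|Z_meta|))

`w_i = sqrt(4/(1/n_case + 1/n_control))` (effective sample size) is
available as `weight_scheme="effective_n"`; the default keeps the classical
total-n scheme. Weights are relative: rescaling all `n_i` leaves `Z_meta`
unchanged.

### Heterogeneity

The inclusion filter requires cross-study consistency. The model underlying
the sample-size-weighted combination is `Z_i ~ N(lambda * w_i, 1)` for a
shared standardized effect `lambda`; the corresponding Cochran statistic is
the residual sum of squares around the weighted fit:

    lambda^ = sum(w_i Z_i) / sum(w_i^2)
    Q       = sum((Z_i - w_i * lambda^)^2)  ~  chi^2_{k-1} under homogeneity

`HetP` is its upper tail. With equal weights this reduces exactly to the
textbook `Q = sum((Z_i - Zbar)^2)`, which is what the public
`heterogeneity_test` computes when no weights are given. We fit around the
weighted projection rather than the plain mean deliberately: with study
sizes as unequal as 6v3 and 12v15, a true common effect produces expected
Z's proportional to study size, and a plain-mean Q would be noncentral for
*every* true positive — the filter would then systematically discard
exactly the genes the meta-analysis exists to find. Genes measured in a
single study return (Q = 0, HetP = 1) by convention and are excluded by the
k >= 2 criterion instead.

### Inclusion criteria and FDR

A gene is reported as dysregulated when all three hold: (1) BH q-value of
`p_meta` <= 0.01; (2) measured in >= 2 studies; (3) HetP > 0.05. Ties are
resolved exactly as written (<= and >). By default BH runs over every gene
that entered the meta-analysis (k >= 1), with the k >= 2 criterion applied
afterwards; `fdr_scope="min_studies"` restricts the BH universe first. Both
orders are defensible; the default keeps single-study genes visible in the
output with an explicit exclusion reason rather than silently dropping them.

### Over-representation analysis

Dysregulated lists (up, down, combined) are tested against GMT gene-set
collections with the one-sided hypergeometric tail
`p = P(X >= observed), X ~ HG(N, size, n_deg)`, plus the bookkeeping columns
`expected = size * n_deg / N` and `ratio = observed / expected`, BH-adjusted
across the collection. The background `N` defaults to genes that entered the
meta-analysis intersected with genes annotated anywhere in the collection
(`universe_policy="annotated"`); web enrichment tools behave the same way,
which is why their printed "Expected" columns imply a background smaller
than the full measured gene list. `all_measured` switches to the full list.
No permutation-based combined scores are computed: the hypergeometric
arithmetic is the reproducible core.

## 2. The synthetic data generator

The generator emulates the statistical structure of a four-study
meta-analysis: two microarray studies (6v3 and 12v15 samples, panels of
20,534 and 21,037 genes) and two RNA-seq studies (3v4 and 3v3, panels of
16,214 and 17,251 genes), drawn as random subsets of a 28,675-symbol
universe.

All studies share one latent truth per gene: a baseline
`b_g ~ N(7, 1.5^2)` (log2) and an effect. A `cis` block
(`cis_fraction = 0.008`, ~229 genes, labelled chr21) carries the
gene-dosage effect: a linear x1.5 fold in cases, i.e. +log2(1.5) ≈ 0.585 on
the log2 scale — the three-copies-over-two expectation. A `trans` set (5% of
the remainder) carries `N(0, 0.5)` log2 effects, truncated away from exact
zero; everything else is null. Arrays observe
`b_g + effect*group + N(0, 0.2)`; RNA-seq studies observe NB counts with
mean `1000 * 2^(b_g - 7) * 2^(effect*group) * depth_j`, per-sample depth
factors `lognormal(0, 0.15)`, and constant dispersion 0.02.

Noise levels are design choices (the emulated studies publish no simulation
parameters) and were set by power analysis to reproduce the *qualitative*
behavior the real studies showed — hundreds to thousands of per-study DEGs
even at n = 3v4, which is only possible for isogenic-clone comparisons on
deep libraries. Residual array SD 0.2 (log2) is typical of moderated-t fits
on cell-line replicate arrays; dispersion 0.02 is a biological CV of ~14%,
between the conventional figures for technical replicates (~0.01) and
genetically identical model organisms (~0.1); median count 1000
corresponds to ~30M-read libraries. A deliberately shallow or noisy
configuration is one `SimulationConfig` away, but it is not the default,
because the default encodes the emulated study conditions.

Identifier mess is simulated on top: each gene gets >= 1 probe, a
`duplicate_probe_rate = 0.15` fraction gets a second (perturbed replicate
row for arrays, independent NB redraw for counts), and
`unmapped_probe_rate = 0.02` of probes map to no symbol (junk rows).
Harmonization collapses duplicates with `max_mean` (keep the
highest-average probe; `median` and `first` available) and drops unmapped
probes with a logged count. Symbols are opaque case-sensitive strings; no
alias resolution is attempted.

What the generator does **not** model — and therefore what passing tests do
not demonstrate about real data: batch and lab effects, platform-specific
probe biases (cross-hybridization, GC content), mean–variance trends
(dispersion is constant), paired designs and covariates, correlated genes
(all genes are independent given the truth), and annotation ambiguity beyond
random unmapped probes. Recovery numbers on synthetic data are a check of
the machinery, not a forecast of sensitivity on any particular real dataset.

## 3. Bioenergetics computations

**Grynkiewicz calibration.** `[Ca2+] = Kd * beta * (R - Rmin)/(Rmax - R)`
with `Kd = 224 nM` (Fura-2). `beta = Sf2/Sb2` defaults to 1 with a logged
warning when not supplied, since it is rarely reported; concentrations then
scale linearly in the true beta. R below Rmin or at/above Rmax raises
(saturation has no finite concentration). FCCP-induced mitochondrial
calcium release is summarized as `100 * (peak - basal)/basal`.

**Mito Stress indices.** From an OCR trace with oligomycin, FCCP and
antimycin-A/rotenone injection marks: non-mitochondrial OCR is the mean of
the post-antimycin segment; basal = last pre-oligomycin reading −
non-mito; ATP-linked = last pre-oligomycin − minimum post-oligomycin;
maximal = maximum post-FCCP − non-mito; spare = maximal − basal. Whether
the original analyses used last-before-injection readings or segment means
is not documented; `reading="last"` (the plate-reader convention) is the
default and `reading="mean"` is provided — the two agree on noiseless
traces. Group summaries are normalized as percent of the control-group
mean (`percent_of_control`), which maps the control mean to exactly 100.

## 4. Numerical choices and degenerate inputs

- p-values clamped to [1e-300, 1] before quantile transforms; `d0` capped at
  1e6 (normal reference beyond).
- Trigamma inversion by Newton iterations (50 max, relative tolerance 1e-10).
- NB mean fits: Newton on log-mean, 40 iterations, steps clipped to ±5 on
  the log scale; all-zero genes short-circuit.
- `max_mean` collapse ties break by input order; meta records sort by
  (p_meta, gene) for deterministic output.
- LRT statistics floored at 0 (profiling error can produce -1e-12).
- Dispersion moment estimates clipped to [0, 10].

## 5. Problem sizes used in checks

The packaged checks run the full four-study design (28,675-gene universe) once
for recovery and enrichment — a few seconds of compute — and a scaled-down
twin (2,000-gene universe, same four study shapes) for replicated null
calibration (20 seeds) and distributional tests, which keeps the whole suite
fast while preserving every structural feature of the design.

## 6. Known limitations

- The NB engine is a simplification; it matches quasi-likelihood F-test
  results in calibration, not in exact p-values.
- The heterogeneity statistic assumes unit-variance Z's; with very small
  studies the t-to-normal conversion makes this approximate.
- The FDR-before-k>=2 ordering is one of two defensible readings of the
  inclusion criteria (the alternative is a flag away).
- ORA treats gene sets independently; no ontology-graph redundancy
  reduction is attempted.
- The effective background behind any published "Expected" column must be
  back-calculated by the user; the package exposes the universe policy but
  cannot recover an unstated background.
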