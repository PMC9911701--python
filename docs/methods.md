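# Methods

## The generative model

`spikequant.simulate` implements a deliberately minimal kinetic model of
RNA Pol II transcription with CGI-proximal premature termination. Its
purpose is to generate sequencing-like data in which every downstream
quantity — survival, flux, abundance, coverage, counts — has a known
closed form, so the analysis stack can be validated end-to-end.

**Termination hazard.** A polymerase initiating at a gene with initiation
rate `k_init` (arbitrary units) traverses an attenuation zone of length
`L_zone` downstream of the TSS. The per-bp effective hazard is

    H_g = h0 * z * (1 - alpha * o_g * s) / (1 + k_init / K)

with `z`, `s` in [0, 1] the remaining levels of the terminator (ZC3H4-like)
and protector (SET1-like) after degron treatment, `o_g` in [0, 1] the
gene's protector occupancy, `alpha` the maximal protection and `K` the
initiation-rate saturation constant. Survival is `S_g = exp(-H_g L_zone)`,
productive flux `F_g = k_init * S_g`. The multiplicative structure makes
two facts exact rather than approximate:

* *Epistasis*: `z = 0` gives `H = 0` regardless of `s`, so double
  depletion is field-for-field identical to terminator depletion — the
  phenotype the epistasis analysis must recover with zero residual.
* *Refractoriness*: the `1/(1 + k_init/K)` factor makes highly transcribed
  genes insensitive to the hazard. The saturation form is a design choice;
  only the phenomenon (expression-dependent sensitivity), not this
  functional form, is empirically motivated.

**Hazard shape and attenuation localisation.** Within the zone the hazard
density follows the gene's CpG-density profile, normalised so the total
zone hazard is exactly `H_g * L_zone`. The density is `sin^2(pi x / c)` on
support `[0, c]` with `c = 0.8 * L_zone`, i.e. it peaks mid-island and
falls to zero before the island's 3' edge. This has a consequence worth
stating explicitly: the *expected* log2 fold-change profile after
protector depletion decreases through the CpG-dense region and reaches an
exact plateau at its minimum where the density support ends — strictly
inside the CGI. The TSS-proximal tie-break of `attenuation_summary`
therefore localises the minimum inside the zone deterministically on
expected coverage. On *sampled* coverage the plateau means the argmin is
distributed over the entire downstream plateau whatever the depth; this is
a property of a survival model with a finite hazard support, not of the
estimator, so localisation claims are made on expected (noise-free)
profiles.

**Genome construction.** `build_genome` draws gene lengths uniform
4–16 kb, intergenic gaps 6–15 kb, strands at random, and `k_init`
log-uniform over `[0.1, 100]` (three orders of magnitude, so every
expression decile is populated). A configurable fraction (default 0.7,
matching the CGI share of vertebrate promoters) of genes carries a CGI
reaching ~200 bp upstream and 1–2 kb downstream of the TSS, and only
those genes have protector occupancy, drawn from Beta(8, 2). Genes without
a CGI have `k_init` scaled by 0.05: CGI promoters are the broadly active
promoter class in mammalian cells, non-CGI promoters mostly weak or
tissue-specific; without this, the lowest expression decile is dominated
by unprotected genes and the decile response pattern of the protector
contrast is diluted. Non-CGI genes use a uniform-hazard zone of 1500 bp.
All coordinates are snapped to the coverage bin width (50 bp) so binned
coverage aligns exactly with gene boundaries. `tss`/`tes` store the
biological 5'/3' positions, so for minus-strand genes `tss > tes`; gene
length is `|tes - tss|`.

**Decay kinetics.** Transcript half-lives are log-normal (median 4 h,
sigma 0.6); `k_deg = ln 2 / half-life`. Total-RNA abundance after an
acute flux change is
`R(t) = F_new/k_deg + (F_old - F_new)/k_deg * exp(-k_deg t)`, with
`F_old` always the untreated (`s = z = 1`) steady state. Nascent
labelling is treated as instantaneous relative to decay (a 15-min label
versus multi-hour half-lives), so cTT-like signal is flux-proportional
with no decay term. It follows analytically that
`|log2FC_cRNA(t)| <= |log2FC_cTT|` for every gene and every `t >= 0`,
with equality only as `k_deg * t -> inf` — and that among genes with
equal nascent responses, short-lived transcripts respond more in total
RNA, reproducing the half-life bias of total-RNA-seq calls.

**Assays.** Expected per-bin coverage per strand is computed with exact
bin-averaged piecewise exponentials, so each unit's coverage integral
equals its analytic read mass to machine precision (verified at
construction, tolerance 1e-6). Pol II ChIP adds a promoter-proximal pause
peak — a Gaussian (centre TSS+100 bp, sd 150 bp) with amplitude
`pause_height * k_init / elongation_rate` — to a body term
`flux / elongation_rate`; the peak scales with initiation, the body with
flux, so protector depletion moves bodies but not promoters. Antisense
units (3 kb, opposite strand, initiating at the TSS away from the gene)
and enhancer units (1 kb arms both strands from the midpoint) are
extragenic: they use occupancy 0 and therefore gain signal when the
terminator is depleted. SET1 ChIP signal is CpG-density-shaped and
proportional to `o_g * s`; H3K4me3 ChIP is uniform over the zone.

**Sequencing.** A library of depth `D` from a mixture with
`mixing_ratio = m` spike cells per target cell allocates expected reads
`D * mass_i / (target mass + m * spike mass)`; spike features have
condition-invariant abundances. Counts (and sampled coverage bins) are
negative-binomial, `var = mu + phi mu^2`, `phi = 0.05` by default
(typical bulk RNA-seq overdispersion). ChIP libraries come with matched
inputs that sample the chromatin mixture uniformly — per-feature masses
proportional to length, spike input mass proportional to `m` — so inputs
measure mixing, not enrichment. All randomness flows through named
substreams of one master seed (`SeedSequence([seed, crc32(label)])`), so
adding or removing samples never perturbs other samples' draws.

**Free parameters.** The protection strength and hazard scale are not
measurable from published figures; they were calibrated once so that the
qualitative patterns the model must exhibit (large, detectable reductions
at protected low-expression genes; realistic untreated survival) hold:
`h0 = 1.5e-3 /bp`, `alpha = 0.85`, `K = 5` (a.u.), occupancy Beta(8, 2).
Untreated survival then has median ≈ 0.63 across genes; protector
depletion produces survival drops up to ~4-fold at strongly protected,
lowly transcribed genes.

## Calibration

Raw downsampling factors are `g_s = 1 / spike_s` for RNA/TT libraries and
`g_s = (input_spike_s / input_target_s) / spike_s` for ChIP (the input
ratio is proportional to the realised cell-mixing ratio, so this cancels
mixing variation; the adjustment is applied multiplicatively *before*
reference selection). Retentions are `r_s = g_s / max g_s`: the sample
with the largest factor is the reference and everything else is thinned
down to it — downsample-only, never upsample. Thinning is per-feature
binomial, equivalent in distribution to read-level downsampling.
Size factors for count testing are spike-only median-of-ratios
(per-feature geometric-mean reference; features with zero reference
excluded; rescaled to geometric mean 1 for identifiability), with an
optional input-ratio pre-normalisation of the spike counts for the
H3K4me3-style variant. `total_count_size_factors` is provided as the
deliberately wrong baseline: under a uniform global change it reports
no change at all.

## Differential testing

The test consumes external (spike-derived) size factors. Effects are
log2 ratios of condition means of normalised counts with pseudocount 1/2;
the standard error comes from the NB variance by the delta method,
`Var(mean_c) = q * sum(1/sf) / n^2 + phi * q^2 / n` evaluated at the
condition mean; the Wald statistic is referred to a normal. Features with
normalised baseMean below 1 are not tested (p_adj undefined, class
NotExpressed); BH adjustment runs over tested features only. Calls
require both `p_adj < 0.05` and fold change > 1.5; fold changes are raw
(no shrinkage), which is sufficient for threshold classification and
keeps the effect estimate interpretable.

Dispersions are method-of-moments per condition,
`(v - m)/m^2`, pooled across conditions by degrees of freedom. The trend
is the *mean* of the unclipped estimates within 20 baseMean quantile
bins, and the final dispersion is `max(0.5*genewise + 0.5*trend, trend)`,
floored at 1e-8. Two deliberate choices here: the trend uses the
unclipped mean because the median of zero-clipped moment estimates is
systematically low at 2–3 replicates, and per-gene dispersions are never
taken *below* the trend because at that replication level a gene-wise
estimate far under the trend is noise, and honouring it makes the Wald
test anticonservative (measured null p<0.05 fraction ≈ 0.082 with
plain 50:50 median shrinkage versus ≈ 0.047 with the trend floor).
The cost is conservatism for genuinely low-dispersion genes.

"Expressed" defaults to untreated mean RPKM > 0.5 (configurable). RPKM
uses a common denominator — the mean across samples of normalised library
totals — so a sample's size factor rescales its RPKM rather than
cancelling out.

## Annotation and profiles

All interval logic is 0-based half-open. TSS-to-island distance is
measured between the TSS base and the nearest island base and compared
inclusively (≤ window); "divergent TSS" means opposite-strand only;
antisense windows are `[TSS-5000, TSS)` strand-flipped (for minus-strand
genes, the exact coordinate mirror `[end, end+5000)` on the plus strand);
enhancer windows are midpoint ± 5 kb, clipped to chromosome bounds.
Deciles are balanced to within one gene with stable (input-order)
tie-breaking, labelled 1 (lowest) to 10.

Profile matrices anchor on the TSS with configurable extents (default
±5 kb, 50 bp bins), orient rows 5'→3', read sense signal from the
strand-matched track, and mask out-of-chromosome bins. Metaprofiles are
masked means with per-bin contributor counts; bins with no contributors
are NaN. Fold-change profiles use `(t + pc)/(u + pc)` with the
pseudocount defaulting to 1% of the genome-wide mean per-bin signal.
Promoter/body partitioning uses TSS ± 250 bp and TSS+500→TES (the
windows are conventions, exposed as parameters). The attenuation summary
scans TSS..TSS+3 kb, takes the minimum log2 ratio, resolves ties to the
most TSS-proximal bin, and flags whether the minimum lies inside the
gene's CGI zone.

Metaplots computed on calibrated data use merged (calibrated) signal
first and average across regions second.

## Pipeline and reproducibility

`run_pipeline` chains simulate → calibrate → test → classify → deciles →
attenuation → summary, writing TSV/BED/JSON only; two runs with the same
configuration produce byte-identical output trees (checksum-tested). A
run aborts with a stage-named error and leaves an `INCOMPLETE` marker if
any stage fails. Default run shape: 4 conditions (untreated, protector-,
terminator-, double-depleted) × 3 replicates, 1000 genes, depth 2e6,
mixing ratio 0.25, thresholds alpha = 0.05 and fold change 1.5.

## Problem sizes

The validation battery runs at desk scale by design: 500–2000 genes,
depths 3e6–3e7, 2–3 replicates, 20 sampling repeats for the decile
trends. At these sizes the discriminating quantities (median log2
recovery error, type-I rate over 5000 null genes, sensitivity over ~900
truly changed genes) have sampling noise well inside the decision margins
they are compared against.

## What the synthetic data does and does not show

The simulator reproduces the *structure* of calibrated depletion
experiments: dual-genome counts with mixing distortion, matched inputs,
condition-dependent global shifts, expression-dependent effect sizes,
extragenic transcription, and nascent/total kinetic decoupling. It omits,
among other things: mappability and GC bias, fragment-length effects,
splicing and 3'-end processing, partial depletion kinetics (depletion is
a step function), secondary/indirect transcriptional responses, and any
correlation between occupancy and expression beyond the model's
saturation term. Passing tests therefore demonstrate correctness of the
computations under the model's assumptions, not robustness of the
biology to violations of them.

## Known limitations

* The Wald test's trend-floored dispersions are conservative for genes
  whose true dispersion is far below the trend.
* `estimate_dispersions` requires ≥ 2 replicates per condition; a
  common-dispersion fallback must be supplied explicitly.
* Attenuation localisation is exact only on expected profiles (see the
  hazard-shape note above).
* bigWig is not written; coverage I/O is bedGraph only.
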