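# spikequant

Spike-in-calibrated quantitative sequencing analysis, with a mechanistic
simulator of RNA polymerase II premature termination.

## The problem

Rapid-degron depletion experiments ask what a chromatin factor does in the
first hours after it is removed. Answering that question quantitatively
requires sequencing assays that can detect *global* shifts in signal —
exactly the shifts that conventional library-size normalisation erases,
because it forces every sample to the same total. Calibrated assays
(cChIP-seq, cRNA-seq, cTT-seq) solve this by mixing each sample of target
cells with a fixed aliquot of cells from another species before library
preparation: reads mapping to the exogenous ("spike-in") genome report the
per-cell sequencing yield of each library, anchoring target-genome counts
on an absolute, per-cell scale.

`spikequant` implements the full analysis stack for such experiments, for
people who analyse (or teach, or stress-test) calibrated sequencing data:

* **calibration** — spike-anchored downsampling factors (with matched-input
  correction for cell-mixing variation in ChIP), binomial thinning, and
  spike-derived median-of-ratios size factors;
* **diffexpr** — a negative-binomial Wald test taking *external* size
  factors, BH adjustment, the significance rule `p-adj < 0.05` and
  `fold change > 1.5`, gene classification and RPKM;
* **annotation** — CpG-island/TSS interval logic (island association within
  1.5 kb, TSS-overlapping peaks, divergent-TSS filtering, 5 kb antisense
  and 10 kb enhancer quantification windows, expression deciles);
* **profiles** — strand-aware TSS-anchored coverage matrices, metaprofiles,
  fold-change profiles, promoter/body partitioning of Pol II signal and an
  attenuation summary;
* **simulate** — a generative model of transcription with premature
  termination, so every stage is testable end-to-end on data with known
  ground truth.

## The model behind the simulator

Each gene initiates polymerases at rate $k_{\mathrm{init}}$. In an
*attenuation zone* spanning the CpG island (CGI) downstream of the TSS, a
termination activity (level $z$; ZC3H4-like) imposes a per-bp termination
hazard that SET1 complexes (level $s$) bound over the CpG-rich region
antagonise:

$$H_g = h_0 \, z \, \frac{1 - \alpha\, o_g\, s}{1 + k_{\mathrm{init}}/K},
\qquad
S_g = e^{-H_g L_{\mathrm{zone}}}, \qquad
F_g = k_{\mathrm{init}} S_g ,$$

where $o_g$ is the gene's SET1 occupancy (non-zero only at CGI genes),
$\alpha$ the protection strength, and $K$ a saturation constant making
highly transcribed genes refractory to termination. $S_g$ is the
probability a polymerase survives into productive elongation and $F_g$ the
productive flux measured by nascent (cTT-seq-like) assays. Total RNA
follows first-order decay, so after an acute flux change at $t=0$

$$R_g(t) = \frac{F_{\mathrm{new}}}{k_{\mathrm{deg}}}
  + \frac{F_{\mathrm{old}} - F_{\mathrm{new}}}{k_{\mathrm{deg}}}
    e^{-k_{\mathrm{deg}} t},$$

which makes total-RNA responses lag nascent ones, most for long-lived
transcripts. Setting $z=0$ removes the hazard entirely — depleting the
terminator epistatically erases the protector's phenotype, the signature
the analysis stack is designed to detect.

## Worked example

```python
from spikequant import RunConfig, run_pipeline

cfg = RunConfig(seed=1, n_genes=400, n_spike=100, replicates=3, depth=2e6)
summary = run_pipeline(cfg, "demo_run")
print("expressed genes:", summary["n_expressed"])
for contrast, counts in summary["class_counts"].items():
    print(contrast, counts)
print("epistasis:", summary["epistasis"])
print("attenuation inside CGI zone:",
      round(summary["profiles"]["attenuation_in_cgi_fraction"], 3))
```

prints

```
expressed genes: 341
dSET1_vs_UNT {'Reduced': 179, 'Increased': 2, 'Unchanged': 160, 'NotExpressed': 59}
dZC3H4_vs_UNT {'Reduced': 1, 'Increased': 186, 'Unchanged': 154, 'NotExpressed': 59}
dBOTH_vs_UNT {'Reduced': 0, 'Increased': 178, 'Unchanged': 163, 'NotExpressed': 59}
epistasis: {'pearson_r': 0.9999999999999999, 'mean_abs_delta': 0.0}
attenuation inside CGI zone: 1.0
```

Reading this: depleting the SET1-like protector reduces expression of about
half of the expressed genes (179 Reduced), depleting the ZC3H4-like
terminator increases a comparable set (186 Increased), and the double
depletion phenocopies terminator depletion exactly (Pearson r = 1, mean
absolute difference 0 at expectation level; 0 genes Reduced). The
fold-change-profile minimum after protector depletion falls inside the CGI
attenuation zone for every protected gene. The run directory holds the
count table, calibration factors, per-contrast differential tables,
attenuation summary and a `summary.json` with these numbers.

The same pipeline is available from the shell:

```
spikequant run --config cfg.yaml --outdir demo_run --seed 1
spikequant report --rundir demo_run
```

where `cfg.yaml` holds any subset of the `RunConfig` fields
(`seed`, `n_genes`, `replicates`, `depth`, `conditions`, `contrasts`,
`alpha`, `min_fc`, `kinetics`, ...). Subcommands `simulate`, `calibrate`,
`diffexp`, `annotate` and `profile` expose the individual stages on
BED/bedGraph/TSV files.

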