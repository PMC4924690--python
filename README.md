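# seroarray

Analysis pipeline for **cancer-antigen microarray seromics**: profiling
serum autoantibody responses against a printed panel of 123
tumour-associated antigens (TAAs), most of them cancer/testis antigens
(CTAs) plus a set of mutant-p53 variants, to discover candidate
serological cancer biomarkers. The package targets the prostate-cancer
setting — comparing PCa sera against benign prostatic hyperplasia (BPH)
and non-malignant disease controls (DC) — but every stage is generic
over panel and cohort.

It is written for researchers analysing spot-extraction tables exported
from array scanners (one table per serum sample), and for anyone who
needs a fully testable stand-in for such data: a synthetic-cohort
generator reproduces the slide geometry, log-normal titre structure,
per-array gain bias and the classical print/scan artifacts.

## What it computes

Each slide is a 4-plex; each 1-plex holds 8 subarrays of 64 spots
(512 spots), with every antigen printed in staggered triplicate and
triplicate Cy5-BSA anchors at 5/10/15 ng/mL in every subarray.

1. **Spot QC and collapse.** Net intensity `S = raw − background`;
   gates on signal-to-noise (`raw/bg ≥ 2`), pixel homogeneity, saturation
   and the 200–65,550 RFU validity window. A noisy triplicate drops the
   replicate farthest from the median; the surviving pair must satisfy
   `|S₁ − S₂| / (S₁ + S₂) ≤ v_max` or the antigen is excluded for that
   array.
2. **Composite normalization.** Quantile normalization of each array's
   Cy5-BSA anchor distribution onto the across-array baseline, extended
   to antigen signals by a monotone piecewise-linear map anchored at the
   origin, then a per-array rescale equalizing the anchor sums ("total
   intensity" component). Rank-preserving within arrays, idempotent,
   and removes per-array gain bias.
3. **Linear analyses.** Fold-over-cutoff seropositivity (per-array upper
   quartile cutoff, positive at ≥ 2-fold), per-group top-N rankings by
   mean intensity, the three-way Venn partition of per-group top-50
   sets, and ethnicity-stratified mean profiles.
4. **Differential statistics.** Welch *t*-test per antigen on
   log(x+1) intensities with Bonferroni correction at α = 0.01, gated
   jointly on a ±2-pooled-SD standardized difference; contrasts
   PCa vs BPH, PCa vs DC and PCa vs BPH+DC.
5. **Biomarker union and signatures.** Union of candidates across the
   linear, top-20, Venn-unique, differential and cross-platform
   (shotgun-proteomics gene-symbol overlap) analyses with per-antigen
   provenance; hierarchical clustering, correlation k-means and PCA,
   including the top-10 cancer-signature re-analysis.

## Worked example

```python
from seroarray import (build_default_panel, build_slide_layout, SimConfig,
                       simulate_cohort, process_array, normalize_cohort,
                       top_n_by_group, differential_contrast, pca_signature)
from seroarray.differential import cluster_purity

panel = build_default_panel()                       # 123 antigens
layout = build_slide_layout(panel, seed=0)          # 4 x 512 spots
spiked = panel.antigen_ids[40:50]                   # 10 cancer-reactive antigens
cfg = SimConfig(effect_map={a: {"PCa": 5.0} for a in spiked}, seed=1,
                artifact_rates={k: 0.0 for k in
                                ("high_background", "speckle",
                                 "doughnut", "saturated")})
meta, scans = simulate_cohort(layout, cfg)          # 20 PCa / 32 BPH / 15 DC

collapsed, summaries = {}, []
for scan in scans:
    sigs, summ = process_array(scan, layout)
    collapsed[scan.sample_id] = sigs
    summaries.append(summ)
matrix = normalize_cohort(collapsed, summaries, meta)

tops = top_n_by_group(matrix, meta, n=5)
results, _ = differential_contrast(matrix, meta, "PCa", "BPH+DC")
sig = pca_signature(matrix, meta, top_k=10, n_clusters=3)
print("top PCa antigens:", list(tops["PCa"]["antigen_id"]))
print("recovered spiked:", len(set(sig.top_antigens) & set(spiked)))
print("PCa cluster purity:", cluster_purity(sig.labels, meta, "PCa"))
```

prints

```
top PCa antigens: ['SYN_CTA_045', 'MAGEB1', 'SYN_CTA_046', 'SYN_CTA_048', 'SYN_CTA_043']
recovered spiked: 10
PCa cluster purity: 0.85
```

i.e. the five brightest PCa group means are all spiked antigens, the
top-10 signature recovers all ten injected cancer-reactive antigens,
and clustering the cohort on that signature keeps 17 of the 20 cancer
samples together (purity 0.85).

The same chain is available from the shell:

```bash
seroarray simulate --seed 1 --outdir out/sim      # layout + scan tables + roster
seroarray run --seed 1 --outdir out/run           # full pipeline -> 11 TSV artifacts + manifest
seroarray report                                  # packaged 67-patient cohort summary
```

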