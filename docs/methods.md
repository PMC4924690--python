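# Methods

This note documents the models, parameter choices and numerical details
behind `seroarray`, and what the synthetic-data experiments do and do
not demonstrate about real antigen-array data.

## Slide model and layout generation

A slide is a 4-plex of identical 1-plex arrays; one serum is hybridized
per isolated plex. Each plex has 8 subarrays on an 8×8 raster
(512 spots, 562 µm pitch recorded as metadata). Per plex, the 123-antigen
panel occupies 369 spots (triplicate), Cy5-BSA anchors at 5/10/15 ng/mL
occupy 9 spots per subarray (72 total), and the remaining 71 spots carry
triplicate positive (biotinylated IgG, pooled serum) and negative
(tag-only lysate) assay controls plus empties.

The true spot-to-coordinate map of a physical slide is proprietary to
the print run, and no analysis below depends on coordinates — only on
spot role and antigen identity. `build_slide_layout` therefore generates
a map pseudo-randomly from a seed under the one geometric constraint that
matters for QC semantics: replicates of one antigen are never 8-neighbour
adjacent within a subarray ("staggering"), so a local defect cannot
silently destroy a whole triplicate. Placement is greedy over a seeded
permutation with whole-plex retry; at the panel's 72% occupancy the
retry path is effectively never taken. The map is then serialized and
treated as an input artifact.

Only 41 of the 123 panel members are publicly named; the remainder are
deterministic placeholders (`SYN_CTA_042`…`SYN_CTA_123`) with no gene
symbol, which keeps name-dependent outputs checkable without inventing
identities. Placeholders consequently can never match an external
protein list.

## Synthetic cohorts

The generator's defaults emulate the study cohort: 20 PCa / 32 BPH /
15 DC samples with the study's ethnicity mix per group (PCa exactly
3 B / 6 W / 11 MA; other group sizes are apportioned by largest
remainder).

Per sample, antigen titres are log-normal
(`baseline_log_mean = 6.0`, `baseline_log_sd = 1.0` in log-RFU), i.e.
median ≈ 400 RFU with a heavy right tail — chosen so that group-mean
rankings have their interesting regime in the hundreds of RFU and a
minority of antigens sit below the detection gates, as in real seromics
where most sera are seronegative for most antigens. Group- and
ethnicity-specific effects are multiplicative folds on the titre
(`effect_map`, keyed by group or `group:ethnicity`); the real effect
sizes are unknown, so they are exposed rather than hard-coded.

Spot signal = titre × log-normal replicate noise (sd 0.1); local
background is truncated-normal (100 ± 25 RFU, ≥ 0); a log-normal
per-array gain (sd 0.5) multiplies **all** intensities of an array,
creating exactly the inter-array bias the composite normalizer must
remove (and making its removal verifiable via the returned ground
truth). Cy5-BSA anchors scale 1:2:3 with concentration from a base net
of 2000 RFU. Raw intensities clamp at the 16-bit ceiling (65,535).
Artifacts are injected per spot with configurable rates (default 0.005
each): doughnuts inflate pixel CV, speckles multiply the raw signal,
high background inflates the local background, saturation pins the spot
at the ceiling.

Not modelled: pixel-level images, spatial artifact correlation (dust
usually hits neighbouring spots), grid misalignment, and scanner PMT
nonlinearity beyond the scalar gain. Passing tests therefore show the
pipeline's logic is correct under the assumed noise model, not that the
QC thresholds are optimal for any particular scanner.

## Spot QC and triplicate collapse

Gates (all configurable in `QcThresholds`): SNR = raw/background ≥ 2
(background floored at 1 RFU to avoid division blow-up), raw intensity
inside 200–65,550 RFU, pixel CV ≤ 0.25, saturated fraction < 0.5. SNR
uses raw rather than net in the numerator because the comparison being
made is foreground against its surrounding background. The 65,550
upper bound is kept as published even though the 16-bit ceiling is
65,535. The pixel-CV, triplicate-CV (0.15) and pair-variability (0.10)
bounds have no published values; the defaults are conservative choices
exposed in configuration.

Collapse: screen each replicate; if all three survive and the net CV
(sample SD / mean) exceeds 0.15, drop the replicate with the largest
|net − median|, breaking ties toward the brighter spot — the classical
rule discards the *high* spot, but a median-distance criterion also
catches low outliers such as doughnuts; the pair left behind must agree
within `|S₁−S₂|/(S₁+S₂) ≤ 0.10` or the antigen is excluded for that
array. Negative collapsed nets are floored to 0 and flagged `NEG_NET`
rather than excluded: a sub-background spot is evidence of
seronegativity, not of assay failure. Arrays with > 20% excluded
antigens are flagged for re-assay, mirroring wet-lab practice for dim
or defective slides.

## Composite normalization

Assumption: the Cy5-BSA anchors share one distribution across arrays.
Per array and concentration, anchors beyond 5 scaled MADs from the
median are dropped and reported. (A 3-MAD cut is a popular default, but
with only 24 anchors per concentration the MAD estimate is noisy enough
that 3-MAD trims legitimate spots at a per-cohort rate near one; genuine
artifacts sit orders of magnitude out, so k = 5 loses nothing.) The
surviving values are then *reorganized* onto a common quantile grid (one
level per nominal anchor), so every array contributes an equal-count
control profile.

Step 1 (quantile component): the baseline is the across-array mean of
control order statistics; each array gets the monotone piecewise-linear
map from its own control quantiles to the baseline. The map is anchored
at the origin — zero net signal must normalize to zero — so the
sub-anchor region, where most antigen signals live, is a pure scaling
rather than an affine extrapolation. Above the anchor range the map
extends along the chord from the origin (proportional scaling): the top
empirical segment is governed by two extreme order statistics and is far
too noisy to extrapolate the decade of signal that can sit beyond the
brightest anchor.

Step 2 (total-intensity component): each array is rescaled so its
post-map control sum equals the across-array mean, making the
constant-control-sum postcondition exact. With the equal-count
reorganization of step 0 this factor is 1 up to float error, but it is
computed unconditionally so the postcondition is guaranteed under any
profile-construction variant.

Consequences, verified by tests: within-array ranks are never reordered
(monotone map × positive scalar); post-normalization control sums agree
to ≈ 1e-16 relative; the composite map is idempotent to machine
precision; per-array log-normal gains (sd 0.5) are removed so that
between-array intensity spread collapses to the replicate-noise scale,
and gain-free group means are recovered within 1% (max over group ×
antigen cells). Normalization fixes only the *relative* scale — the
absolute scale is set by the cohort's own anchors — so parameter-recovery
comparisons align the single global factor first.

Normalization operates on collapsed antigen nets, not raw spots, so QC
flags stay meaningful; a quantile normalization over all spots jointly
was rejected because the design explicitly anchors on positive controls.
The order (quantile first, then sum rescale) is fixed because the
reverse order cannot guarantee the constant-sum postcondition exactly.

## Linear analyses

Fold-over-cutoff: cutoff = the array's 75th percentile of non-excluded
antigen values (the "interquartile" reading of an adaptive per-array
threshold), floored at 1 RFU; seropositive at fold ≥ 2. Both knobs are
configuration; the 2-fold call is an assumption, not a published value.
Top-N tables carry group means so intensity-based rationales (e.g.
"means around 500 RFU and higher") remain auditable. The Venn partition
of top-50 sets is pure set algebra and is property-tested against a
brute-force membership oracle. Ethnicity profiles report stratum sizes
alongside the argmax because a 3/6/11 split cannot support strong
per-stratum claims. Cross-platform overlap matches case-insensitively
on gene symbols and never matches antigens without one (splice-variant
resolution is out of scope).

## Differential statistics and signatures

Welch's unequal-variance t-test per antigen on log(x+1) intensities
(groups are unbalanced, intensities right-skewed; the log choice is an
interpretation — the source procedure says only "independent sample
t-test" — and is flagged for sensitivity analysis). Bonferroni over the
antigens actually tested (≥ 2 non-excluded values per side); the
family-wise α = 0.01 gate is applied jointly with |standardized mean
difference| ≥ 2 pooled SDs. A procedure labelled "FDR = 0.01" but
described as Bonferroni is implemented as Bonferroni — the named
procedure over the loose label. Degenerate zero-variance-in-both-groups
antigens report t = 0, p = 1.

The candidate-biomarker union merges the per-analysis lists with
provenance tags {Linear, Top20, Venn, Differential, Shotgun}; direction
is dictated by a differential call when present, else cancer-group
evidence reads High and control-only evidence Low, with dual-support
conflicts reported explicitly.

Clustering imputes missing cells by the antigen mean for distance
computations only; inference never sees imputed values. Hierarchical
clustering is deterministic scipy average linkage (Euclidean or
correlation); the k-means variant standardizes sample rows so squared
Euclidean distance is proportional to 1 − Pearson correlation, with 25
seeded restarts (seed 1234). The top-10 signature ranks antigens
lexicographically by (seropositive presence fraction among cancer
samples, mean cancer titre, antigen id) — the exact composite used in
the source analysis is unspecified, so presence-first is our choice —
and the restricted matrix is re-clustered with **Euclidean** hierarchical
clustering: correlation distance is deliberately avoided there because
row re-centring cancels a signature whose members are coherently
elevated in one group, making the class structure invisible by
construction.

## Problem sizes in the shipped experiments

The test suite and acceptance script use cohorts of the study's size
(67 arrays) or smaller (18–30 arrays) for normalization properties,
1000 replicates for the null family-wise error rate, 100 replicates for
spike power, and 1000 random triples for the Venn oracle; these sizes
give the binomial envelopes quoted in the tests while keeping a full
run in tens of seconds. All experiments are seeded and deterministic.

## Known limitations

- QC gates interact with the per-array gain: a very dim array excludes
  more low-titre antigens, which is flagged for re-assay rather than
  corrected. Parameter-recovery tests isolate the normalizer from this
  censoring effect by construction.
- Occasional legitimate anchors in the far tail are trimmed by the
  robust outlier rule; the equal-count reorganization makes the
  normalizer indifferent to this.
- Direction inference in the union is heuristic for antigens supported
  only by rank-based analyses.
- The placeholder panel members make shotgun overlap conservative: only
  named antigens can ever match.
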