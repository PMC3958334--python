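# Methods

## Screening model

The package analyzes arrayed RNAi screens in which each well of a 96-well
plate receives one dsRNA reagent, the pathway is driven from an inducible
(metallothionein, "pMet") construct, and active (dually phosphorylated)
MAPK is read out by quantitative immunofluorescence. Every plate carries
GFP-dsRNA negative-control wells — the normalization reference — and two
positive-control reagents: mek dsRNA, which abolishes the induced signal,
and PTP-ER dsRNA (a MAPK phosphatase), which raises it.

Well intensities are modeled as multiplicative: per-plate bias (staining,
exposure, dilution) and per-well error act as factors on the raw signal,
i.e. additively on the log scale. Sample values are expressed as the log
ratio to the center of the in-plate negative controls, which cancels the
plate factor exactly. The control center is the **median** of the
negative-control signals by default (robust to a single contaminated
control well); the geometric mean is available by configuration and makes
the mean normalized control value exactly zero. Log bases follow the
assay families: log₁₀ for the pMAPK epistasis screens and hemocyte-style
ratios, log₂ for expression-type summaries.

Assay quality is summarized by the Z′-factor,
Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|, computed with sample (n−1) standard
deviations; Z′ > 0.5 flags a robust assay, and coincident means yield an
explicit "undefined" flag rather than −∞.

## Synthetic screens and what they do (not) emulate

`SimConfig`/`generate_screen` produce the full well table plus per-gene
ground truth. The log₁₀ well model is

    log10(signal) = baseline + plate_effect + s · effect · y_c[assay] + ε

with `plate_effect ~ N(0, plate_effect_sd)` per (assay, plate),
`ε ~ N(0, noise_sd)` per well, `y_c` the idealized interval profile of
the gene's class, and `s = ∓1` for positive/negative regulators. Gene
classes: the three interval-regulator classes; neutral genes (`none`,
zero effect everywhere); `promoter-artifact` genes, which perturb every
pMet-driven assay *and* the two promoter-reporter assays in proportion
(coupling 1.0 by default), giving the promoter filter something to catch;
and `jnk-nonspecific` genes, which perturb the JNK assays as strongly as
pMAPK. Gene-to-plate assignment is round-robin in gene order, with an
optional linear plate-order drift term (off by default).

Defaults are the study conditions used throughout the tests: effect size
1.0 log₁₀ (tenfold), well noise sd 0.06, plate-effect sd 0.05, 4 negative
and 2+2 positive control wells per plate, 2 replicates. Noise and control
effects (−1.0 for mek-like, +0.45 for PTP-ER-like) were chosen once so
that the control separations land in the Z′ range characteristic of this
assay format (≈0.64 strong, ≈0.18 weak); the weak control is
deliberately *not* a robust assay, as is typical for the
phosphatase-depletion control.

What the generator does **not** emulate: spatial (row/column/edge) plate
effects, reagent off-target effects at the sequence level, cell-count
coupling to signal, heavy-tailed well failures, or correlated noise
between assays. Passing recovery tests therefore demonstrate correctness
of the analysis chain under the stated error model, not robustness to
every real-screen pathology.

## Hit calling and the promoter filter

A reagent is a primary hit when its normalized pMAPK value exceeds the
cutoff margin in the same direction in both the primary and the
confirmation screen (default margins ±0.3 log₁₀, i.e. 3× the benchmark
well noise of 0.1; the second screen also stands in for the independent
non-overlapping-dsRNA confirmation). Because the pathway is driven from
the pMet promoter, a reagent can score by perturbing the expression
system itself; the filter fails a hit when its reporter-screen effect
satisfies |reporter| ≥ intercept + slope·|pMAPK| (defaults 0.3 and 0.5).
The signal-dependent form is a linear reconstruction of a cutoff that
grows with the primary-screen effect; both parameters are exposed.

## Epistasis-interval assignment

The weighted uncentered correlation, the assignment rule (argmax |r|
outside the [−0.5, 0.5] grey band), the sign convention (negative r =
positive regulator), and the ambiguity flag (confidence
|r_best| − |r_second| < 0.2) are described in the README. Design points:

- "Highest distance" is read as the largest **absolute** correlation;
  the sign is a direction label, not part of the ranking.
- The confidence score is defined as the gap between the top two
  absolute correlations — a monotone surrogate for however the original
  score was computed, used with the published 0.2 threshold. Exact ties
  report confidence 0 and the ambiguity flag, with the tie resolved in
  fixed interval order.
- Assay order is validated by name so the weight vector can never be
  silently permuted.
- An identically zero profile has no defined correlation; the primitive
  raises a dedicated error (distinct from r = 0), and the classifier
  reports such genes unassigned with NaN correlations.

A structural consequence worth knowing: the MEK–MAPK and RAF–MEK ideal
profiles correlate at √(6/9) ≈ 0.816 under the default weights, so a
perfect uniform suppressor has confidence ≈ 0.18 — below the 0.2
threshold. Clean MEK–MAPK regulators are therefore systematically
*ambiguous-but-correctly-placed*; recovery statistics count the reported
interval, as the ambiguity flag qualifies rather than withholds the call.

Because r is scale-invariant, a pure-noise profile is a random direction
in six dimensions and lands outside the grey band ~40% of the time.
Noise genes are kept out of interval assignments not by the band alone
but by the screen's two-stage design: only reagents that pass
reproducible hit calling (and the promoter filter) are classified.
Recovery benchmarks therefore run the full chain; a neutral gene counts
as correctly silent when it either never becomes a validated candidate
or classifies unassigned/ambiguous. Under the benchmark conditions
(300 genes, effect 1.0, noise 0.1, 20 screens) planted regulators are
recovered with the correct interval and sign in ≥95% of cases (measured:
100%) and neutral genes are essentially never assigned.

## Specificity score

Evidence that a hit is *not* a dedicated RAS/MAPK regulator — pJNK
effects, pMet reporter effects, recurrence in previously published RNAi
screens, non-specific Western-blot changes, global mRNA-export defects,
cell-count loss — is aggregated as a weighted mean of per-component
cleanliness scores in [0, 1] (1 = clean), with genes binned
high/medium/low by score thresholds (0.75/0.5). The off-pathway
penalties (JNK, pMet) are scaled by the gene's own pMAPK effect: an
off-pathway effect as large as the on-pathway one scores zero for that
component. This is why the inputs carry a `pmapk_effect` reference
column. The aggregation is an additive penalty model with every weight
exposed (JNK counts double by default, reflecting its role as the
primary specificity axis); missing components are skipped with
renormalized weights and the per-gene component count is reported.
Prior-screen occurrence is consumed as a supplied count column, never
fetched from a live resource. The score is monotone: worsening any
single component can never raise it.

## Functional-profile clustering

Secondary-screen profiles are clustered agglomeratively with distance
1 − uncentered correlation and average linkage (scipy). The uncentered
metric groups genes that perturb every assay in the same *proportions*
regardless of effect magnitude — the behavior expected of subunits of
one complex. Genes are sorted by identifier before linkage, making the
tree invariant to input order with deterministic tie-breaking; constant
(zero-norm) profiles are rejected by name. Trees export to Newick with
branch lengths.

## Expression calls

qPCR replicate quantities on the log₂ scale are compared by an unpaired
two-tailed Student (pooled-variance) t-test; a knockdown-like call
requires both mean log₂ ratio < −0.75 and p < 1×10⁻⁴. Raw p-values are
reported (the decision rule is a joint threshold, not a
multiplicity-corrected inference); Benjamini–Hochberg adjustment is
available behind a flag, off by default. At the benchmark conditions
(n = 3, replicate sd 0.15), a power analysis shows the joint rule
detects a 4-fold depletion (log₂fc −2) in only ~65% of trials — the
median p sits just under the cutoff — while the exemplar strong
knockdown depth of −2.86 log₂ is detected ~93% of the time with
essentially no false calls on unchanged transcripts. The simulated
"depleted" condition is therefore fixed at −2.86.

## Splice-product classification

An observed exon inclusion/skipping pattern (plus optionally retained
introns) is classified by ORF consequence: `no_start` if the exon
carrying the start codon is skipped; `F` if the stop-carrying exon is
skipped (read-through) or the net frame shift
(inserted − removed CDS nucleotides) mod 3 is nonzero; `T` if CDS
content changed in frame; `N` if the CDS is untouched (UTR-only changes,
including a retained intron upstream of the start codon, are silent).
Note the signed arithmetic: removals shift downstream phase by −S and
retained-intron insertions by +I, so a 1-nt loss plus a 1-nt gain is in
frame. A retained CDS intron with length ≡ 0 mod 3 is grouped with `T`
(altered but in-frame product). Retained introns flanked by a skipped
exon are rejected as inconsistent patterns.

The shipped eight-exon model (`mapk_like_model`) is **synthetic**: its
exon lengths are not the real transcript's, but reproduce the qualitative
architecture the classifier is exercised against — untranslated exon I, a
long first intron, the start codon in exon II, exons IV and VII in frame
(lengths divisible by 3), exons III and V out of frame, the stop in exon
VIII. Correctness is established against an independent
translation oracle: random toy transcripts are built over a {C, G}
alphabet (so the single placed TAA is the only stop codon reachable in
any reading frame), spliced by string concatenation, translated codon by
codon, and compared — 1,000 random model/pattern checks agree exactly.

## Numerical and engineering choices

- All estimators follow scikit-learn conventions (`get_params`/
  `set_params`, fitted attributes with trailing underscores, validation
  in `fit`), so they compose with sklearn tooling; module-level
  functions are thin wrappers.
- Correlations are clipped to [−1, 1] only to absorb floating-point
  overshoot; band/threshold comparisons are otherwise exact.
- TSV output uses a fixed `%.10g` float format and sorted group keys, so
  a fixed seed reproduces byte-identical pipelines (verified by the
  determinism check); the run manifest records config, seed, and SHA-256
  digests without timestamps.
- Wells with nonpositive signal are dropped with a logged count by
  default; a pseudocount is available by configuration.
- Benchmark problem sizes (300-gene screens, 20 seeds; 1,000-trial
  oracles) were chosen as the smallest sizes at which the Monte-Carlo
  error is far from each decision boundary.

## Known limitations

- The promoter-filter cutoff and the specificity aggregation are
  parameterized reconstructions of procedures whose exact published
  forms are not available; defaults are documented above and every
  parameter is exposed.
- The confidence score is a surrogate; only its threshold behavior (0.2)
  is anchored.
- The splice classifier reasons arithmetically about annotated exon
  structures; it does not scan sequence for cryptic start/stop codons
  created by novel junctions.
- Interval recovery statistics are conditional on the generator's error
  model (independent log-normal noise); correlated assay noise would
  lower the effective confidence margins.
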