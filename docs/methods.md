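# Methods

This note documents the models, defaults and numerical choices behind
`selintro`, and what the synthetic-data generator does and does not emulate.

## Pedigree and meiosis model

A population is produced by the crossing scheme F1 → b backcrosses to the
recurrent parent → s generations of selfing with no selection, each line an
independent single-seed descent (defaults b = 2, s = 3, i.e. BC₂F₄). Meiosis
uses the Haldane map function — recombination fraction
c = (1 − e^(−2d/100))/2 for adjacent markers d cM apart, no crossover
interference — and chromosomes assort independently. Haldane is the standard
choice at SSR marker densities, where interference has little practical
effect. Phase is tracked internally through the pedigree, so gametes are
drawn exactly; a line's genotype is a single plant's genotype (no within-line
pooling of residual heterozygosity).

Closed forms under this model: heterozygosity (1/2)^(b+s), donor allele
frequency (1/2)^(b+1) (invariant under selfing), donor-homozygote frequency
their difference — 0.03125 and 0.109375 for BC₂F₄. These are the oracles for
the simulator tests and the null background for the scan.

The default synthetic map has 210 evenly spaced markers on 12 chromosomes
over 1530 cM, the scale of a typical rice SSR framework map.

## Phenotype model

Plot value = baseline(treatment) + Σ_q a_q · k_q(treatment) · dosage_q +
line effect + plot residual, with dosage the donor-allele count (0/1/2),
k_q a treatment-specific multiplier (k = 0 under "normal" makes a
stress-specific QTL), Gaussian line effects and residuals. Spikelet
fertility is clamped to [0, 100]; all other traits are floored at zero.
Filled grain number is derived as FGN = SF·SNP/100 by default so simulated
records satisfy the identity that defines spikelet fertility (set
`derive_fgn=False` to simulate it independently).

Baselines are the check variety's replicated progeny-test means under the
two treatments (e.g. GYP 22.6 g normal / 3.5 g salt, an 84.5% reduction; PN
7.2 / 3.6; PH 124.3 / 85.5 cm; HD 105.3 / 117.0 days — heading is *delayed*
by stress, so its response is reported salt − normal while all other traits
are reported normal − salt). Residual and line-effect standard deviations
(per trait, trait units; e.g. GYP 1.5 / 2.5 g) were chosen once as realistic
plot-level noise for replicated single-row rice plots and are not derived
from published data, which report means only.

What the generator does **not** emulate: field spatial structure, the harsher
initial-screening season (the real screen's check values were lower than the
progeny-test baselines used here, so the default SF/GYP gates select a larger
fraction of simulated lines than the ~5% selected in a real screen),
genotype-by-year effects, residual heterozygosity within a named line, and
gametophytic or viability selection. Passing tests therefore demonstrate the
statistical machinery under a clean additive G + G×S model, not robustness to
those field realities.

## Over-introgression scan

A line *carries* introgression at a marker when its genotype is heterozygous
or donor-homozygous (default); the expected carrier proportion p̄ is the
background donor-homozygote frequency plus heterozygosity, computed from the
full genotyped line set of the same population. At BC₂F₄ heterozygosity is
~3%, so the carrier statistic closely tracks donor-homozygote frequency
without discarding hets. A 3-class variant (genotype trio vs background trio,
2 df) and an exact-binomial p-value are available behind `ScanConfig`
switches. No continuity correction is applied, and no multiple-testing
adjustment beyond the stringent α = 0.001 (an optional Bonferroni mode
exists); these mirror the method as practised.

Bins are fixed 10-cM windows indexed from the chromosome start — a documented
convention, since published bin labels never define their windows. Adjacent
significant markers in one bin collapse to a single QTL at the smallest-p
marker. Only markers enriched *above* background are reported: selection for
a trait enriches carriers at its loci in the selected set regardless of the
direction of selection, because the tested set is always the trait-extreme
set itself.

Calibration: the χ² approximation at n ≈ 78 selected lines and p̄ ≈ 0.14 has
a mildly inflated upper tail; the marginal type-I rate at nominal 0.001 is
~0.0012, within three binomial standard errors of nominal over 10⁵ pooled
tests. Estimates from a single population scatter around that value because
all selections share one realised background; the acceptance script
therefore pools selections across ten independent populations.

## Trait-extreme selection and progeny statistics

Lines significantly above (positive selection, P) or below (negative
selection, N) the check are found by Welch's unequal-variance t-test on plot
values (default α = 0.01), matching the design of few plots per line against
more check plots. The two-way ANOVA is fixed-effects with sequential
(type-I) sums of squares via an OLS fit, so the decomposition
SS_line + SS_treatment + SS_interaction + SS_error = SS_total is exact on
balanced data; a constant response reports zero SS and NaN F rather than an
error. Percent changes keep full precision internally and are rounded only
at reporting. The spikelet-fertility identity SF = FGN/SNP·100 is
cross-checked on input; violating rows (which occur in published tables) are
flagged with a warning and retained.

## Association groups

Candidate loci are those over-introgressed among the selected lines at
χ² p < 0.05. Loci are grouped by their exact carrier pattern across the
selected lines ("perfect association" is taken literally); lines missing a
genotype at any candidate locus are excluded from the pattern comparison.
Within a pattern class, loci on the same chromosome closer than 50 cM
(configurable) collapse transitively to the smallest-p representative;
if at least two pairwise-unlinked representatives remain, the group is
scored with

    p_AG = prod_i p_i^m * prod_i (1 - p_i)^(n - m)

computed in log space, where p_i is the *expected* (null) introgression
frequency — the genome-wide background carrier frequency, by default the
same for every locus; an observed per-locus background is available behind a
switch. No binomial coefficient is included, matching the pattern-probability
definition; `with_binomial_coefficient=True` multiplies in C(n, m) per locus
for users who want the probability of some m/n−m split rather than a fixed
one. A group is emitted only under the double criteria (every locus p < 0.05
and p_AG < 10⁻⁴).

## Gene-CDS haplotypes

A gcHap is an exact uppercased string identity of an aligned CDS; sequences
with ambiguous bases or gaps are dropped before collapsing (a
column-masking policy is intentionally out of scope). Haplotype ids are
assigned by descending pooled count, ties by first occurrence. E_H is Nei
gene diversity 1 − Σf² (the standard haplotype-diversity statistic, bounded
in [0, 1) as the usage implies); Shannon entropy is provided as an
alternative. "Major" haplotypes require pooled frequency ≥ 0.05 and count
≥ 10 (both configurable). Differentiation uses strict >70% predominance per
subspecies. Candidate-gene windows are closed intervals of ±5 cM around the
QTL peak marker, so a gene at exactly 5.0 cM is included. Substitutions are
classified codon-by-codon with the standard genetic code; a codon hit by
several differing sites is translated as a whole codon. The haplotype
network is a minimum spanning tree over pairwise Hamming distances with
deterministic tie-breaking by (distance, haplotype rank) — a deliberate
simplification of median-joining networks that preserves topology for the
predominant-haplotype structures generated here.

The synthetic CDS generator emits five subpopulations (Xian, Geng, Aus, Bas,
Adm) of 50 accessions each with a design predominance of 0.85 for the major
haplotype; "differentiated" genes give Xian and Geng different majors
separated by a few codon substitutions, "conserved" genes share one major,
and "other" genes draw haplotypes near-uniformly. Internal stop codons are
avoided so every haplotype translates cleanly. It does not emulate
recombination within genes, indel variation, or realistic site-frequency
spectra.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed or generator; the CLI
derives one seed per stage from the master seed by SHA-256 of
"seed:stage-name" (below 2³¹), so stages rerun independently with identical
results, and report files are byte-deterministic (stable sort order, fixed
float format, LF endings, "NA" missing token).

Problem sizes used by the test and acceptance suites are the package's
standard working scales: 126-line and 2000-line unselected BC₂F₄ populations
on the 210-marker map for Mendelian recovery; 500 random 78-line selections
(105,000 pooled marker tests) for scan calibration; 100 replicates of a
500-line population with a 3 g·allele⁻¹ salt-specific QTL and top-4%
truncation (20 lines) for power; 2–3 × 10⁵ Monte-Carlo draws per parameter
setting for the p_AG oracle.

## Known limitations

- Marker-wise statistics only: no segment reconstruction between markers and
  no interval mapping; fold-enrichment is the only effect summary, by design.
- The χ² scan's small-sample behaviour is approximate (see calibration
  above); the exact-binomial option is conservative instead.
- ANOVA is restricted to complete line × treatment cells (type-I SS scope);
  mixed-model/BLUP estimation is out of scope.
- gcHap inputs must be pre-aligned; no alignment, no Fst-style selection
  statistics.
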