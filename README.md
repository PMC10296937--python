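# selintro

Selective-introgression analysis for backcross breeding populations.

`selintro` implements the statistical toolkit behind *selective
introgression*: a strategy for simultaneously improving a complex trait and
mapping the loci that control it. Donor genome segments are introgressed at
random into an elite recipient background by backcrossing (e.g. *Xian*/indica
donors into a *Geng*/japonica rice variety), strong phenotypic selection is
applied (e.g. for grain yield under sustained ~0.8% NaCl salt stress), and
QTLs are then detected as marker loci where the selected progeny carry donor
alleles far more often than Mendelian segregation predicts. The package is
aimed at plant-breeding researchers who want to design, simulate, or analyse
such screens.

## What it computes

**Mendelian baseline.** In a BC<sub>b</sub>F<sub>s+1</sub> population without
selection, the expected donor allele frequency is (1/2)<sup>b+1</sup> and the
expected heterozygosity (1/2)<sup>b+s</sup>; for a BC₂F₄ this gives a donor-
homozygote frequency of 1/8 − 1/64 = 0.109375 and heterozygosity 1/32. The
simulator (`simpop`) reproduces this pedigree with Haldane-map meiosis and a
linear QTL + G×S phenotype model; `introstat` measures per-locus and
genome-wide introgression.

**Over-introgression scan.** For a set of n phenotypically selected lines and
a marker where m of them carry donor introgression, `qtlscan` tests

&nbsp;&nbsp;&nbsp;&nbsp;χ² = (m − np̄)²/np̄ + ((n−m) − n(1−p̄))²/n(1−p̄),&nbsp;&nbsp;1 df,

against the genome-wide background p̄ of the population; markers with
p &lt; 0.001 and frequency above background are QTLs, collapsed to one hit
per 10-cM bin and named in the field's convention (`qST3.4`, `qGY12.2^P`).

**Association groups.** `assocgroups` finds sets of r ≥ 2 *unlinked* loci
perfectly co-introgressed across selected lines and computes the multi-locus
independence probability

&nbsp;&nbsp;&nbsp;&nbsp;p<sub>AG</sub> = ∏<sub>i</sub> p<sub>i</sub><sup>m</sup> · ∏<sub>i</sub> (1 − p<sub>i</sub>)<sup>n−m</sup>,

declaring a group under double criteria (every locus over-introgressed at
p &lt; 0.05 and p<sub>AG</sub> &lt; 10⁻⁴).

**Progeny-test statistics.** `progeny` provides the two-way fixed-effects
ANOVA (line, treatment, line×treatment), stress-response summaries, Welch
line-vs-check comparisons, selection-efficiency arithmetic and trait
correlations for replicated salt/normal trials of the eight yield traits
(GYP, SF, FGN, SNP, TGW, PN, PH, HD).

**Gene-CDS haplotypes.** `gchap` collapses aligned CDS sequences into gcHaps,
computes Nei diversity E<sub>H</sub> = 1 − Σf², classifies genes as
*Xian–Geng differentiated* (each subspecies with its own &gt;70% predominant
haplotype) vs *conserved*, locates candidate genes within 5 cM of QTL peaks,
classifies synonymous/nonsynonymous substitutions and builds
minimum-spanning-tree haplotype networks.

## Worked example

Simulate a 500-line BC₂F₄ screen with a planted salt-tolerance QTL at marker
`M03_09`, select the top 4% of lines by yield under salt, and scan:

```python
import selintro as si
from selintro.simpop import (PedigreeConfig, QtlEffect, TraitModel,
                             simulate_bc_population, simulate_phenotypes)
from selintro.qtlscan import ScanConfig, scan_selected_lines, hits_to_dataframe

gmap = si.GeneticMap.default()                      # 210 markers, 12 chromosomes
pop = simulate_bc_population(PedigreeConfig(n_lines=500, seed=1), gmap)
bg = si.genome_background(pop)
print(f"introgression {bg.mean_introgression:.3f}, het {bg.mean_het:.3f}")

model = TraitModel(qtl_effects=[
    QtlEffect("GYP", "M03_09", 2.5, {"normal": 0.2}),   # salt-specific yield QTL
    QtlEffect("SF",  "M03_09", 8.0, {"normal": 0.1}),
])
phenos = simulate_phenotypes(pop, model, n_reps=2, rng=2, check_id="CY1")
means = phenos[phenos.treatment == "salt"].groupby("line_id")["GYP"].mean()
st_lines = means.drop("CY1").nlargest(20).index.tolist()
hits = scan_selected_lines(pop, st_lines, bg, ScanConfig())
print(hits_to_dataframe(hits).to_string(index=False))
```

Output (abridged):

```
introgression 0.108, het 0.032
  name peak_marker  n_selected  carrier_freq  fold_enrichment      chi2      p_value
qST3.4      M03_06          20          0.40         2.855201 11.214625 8.115522e-04
qST3.5      M03_07          20          0.50         3.569001 21.504604 3.529802e-06
qST3.6      M03_08          20          0.65         4.639701 43.165264 5.030590e-11
qST3.7      M03_09          20          0.75         5.353501 61.756165 3.887326e-15
qST3.8      M03_11          20          0.40         2.855201 11.214625 8.115522e-04
```

The unselected population sits at the Mendelian background (0.108 vs the
expected 0.109375). The scan peaks exactly at the planted marker `M03_09`:
75% of the selected lines carry donor introgression there — a 5.4-fold
enrichment over background — with the signal decaying along the linked
flanking markers of chromosome 3.

The same workflow runs from the shell:

```bash
selintro all --seed 7 --out run/       # simulate → screen → progeny → scan → AGs → gcHap
```

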