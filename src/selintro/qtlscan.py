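"""Selection-based QTL detection: chi-square over-introgression scans.

Phenotypic selection on a trait enriches donor alleles at the loci that
control it.  A QTL is therefore declared at a marker where the selected lines
carry donor introgression significantly more often than expected from the
genome-wide background of the population (the null: at most segregating loci
the donor allele is unrelated to the trait, so the background frequency is
the random expectation).

Two carrier conventions are supported for the test:

* 2-class (default): a line "carries" introgression when its genotype is het
  or donor-hom; the expected carrier proportion is the background
  donor-homozygote frequency plus heterozygosity.  At BC2F4 heterozygosity is
  ~3%, so this closely tracks the donor-homozygote frequency while not
  discarding hets.
* 3-class: the full genotype trio (0/1/2) is tested against the background
  trio of class frequencies.

Detected markers falling in the same map bin (fixed windows of
``bin_width_cM`` from the chromosome start) are collapsed to a single QTL
whose peak is the smallest-p marker, and named in the field's style, e.g.
``qGY12.2^P`` (trait GYP, chromosome 12, bin 2, positive selection); scans on
the salt-tolerance target trait use names like ``qST3.4`` with no direction
superscript.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .introstat import GenomeBackground, locus_genotype_freqs
from .simpop import MISSING, GeneticMap, Population

__all__ = [
    "ScanConfig",
    "QtlHit",
    "chi2_overintrogression_test",
    "chi2_threeclass_test",
    "carrier_matrix",
    "scan_selected_lines",
    "select_trait_extremes",
    "assign_bin",
    "assign_bin_and_name",
    "hits_to_dataframe",
]

#: QTL-name trait codes (grain yield GY, 1000-grain weight GW as used in the
#: rice QTL-naming convention; others keep their trait abbreviation).
TRAIT_CODES = {
    "GYP": "GY", "TGW": "GW", "SF": "SF", "SNP": "SNP",
    "PN": "PN", "PH": "PH", "HD": "HD", "ST": "ST",
}


@dataclass(frozen=True)
class ScanConfig:
    alpha_scan: float = 0.001
    alpha_trait_extreme: float = 0.01
    bin_width_cM: float = 10.0
    het_as_carrier: bool = True      # 2-class carrier definition
    three_class: bool = False        # 3-class genotype-trio chi-square
    exact_binomial: bool = False     # exact binomial p instead of chi-square
    bonferroni: bool = False         # divide alpha_scan by the marker count
    collapse_bins: bool = True

    def __post_init__(self):
        for a in (self.alpha_scan, self.alpha_trait_extreme):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha must be in (0, 1)")
        if self.bin_width_cM <= 0:
            raise ValueError("bin width must be positive")


@dataclass(frozen=True)
class QtlHit:
    marker_id: str
    chrom: int
    bin: int
    name: str
    trait: str
    direction: str  # 'P', 'N' or 'ST'
    n_selected: int
    n_carriers: int
    carrier_freq: float
    background_freq: float
    chi2: float
    p_value: float

    @property
    def fold_enrichment(self) -> float:
        return self.carrier_freq / self.background_freq

    @property
    def bin_label(self) -> str:
        return f"{self.chrom}.{self.bin}"


def chi2_overintrogression_test(
    m: int, n: int, p_bar: float, exact: bool = False
) -> tuple[float, float]:
    """1-df chi-square of observed carrier counts (m, n-m) against the
    background expectation (n*p_bar, n*(1-p_bar)); two-sided p.

    With ``exact`` the p-value is the two-sided exact binomial instead (the
    chi-square statistic is still returned).
    """
    if not 0 <= m <= n:
        raise ValueError("need 0 <= m <= n")
    if not 0.0 < p_bar < 1.0:
        raise ValueError("degenerate background frequency (p_bar must be in (0,1))")
    e1 = n * p_bar
    e0 = n * (1.0 - p_bar)
    chi2 = (m - e1) ** 2 / e1 + ((n - m) - e0) ** 2 / e0
    if exact:
        p = stats.binomtest(m, n, p_bar).pvalue
    else:
        p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return float(chi2), float(p)


def chi2_threeclass_test(
    counts: Sequence[int], expected_props: Sequence[float]
) -> tuple[float, float]:
    """2-df chi-square of the genotype trio (recip-hom, het, donor-hom) counts
    against background class proportions."""
    counts = np.asarray(counts, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if counts.shape != (3,) or props.shape != (3,):
        raise ValueError("need three genotype classes")
    if np.any(props <= 0):
        raise ValueError("degenerate background class proportion")
    n = counts.sum()
    expected = n * props / props.sum()
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=2)) if chi2 > 0 else 1.0
    return chi2, p


def carrier_matrix(pop: Population, het_as_carrier: bool = True) -> np.ndarray:
    """Boolean (n_lines, n_markers) carrier matrix; missing stays False but is
    tracked separately by callers via ``pop.genotypes == MISSING``."""
    g = pop.genotypes
    return (g >= 1) if het_as_carrier else (g == 2)


def assign_bin(marker_id: str, gmap: GeneticMap, bin_width: float = 10.0) -> int:
    """1-based fixed-window bin index from the chromosome start."""
    j = gmap.index_of(marker_id)
    return int(gmap.pos_cM[j] // bin_width) + 1


def assign_bin_and_name(
    marker_id: str,
    gmap: GeneticMap,
    trait: str,
    direction: str,
    bin_width: float = 10.0,
) -> str:
    """QTL name: 'q' + trait code + chrom + '.' + bin (+ '^P'/'^N' for
    positive/negative selection; salt-tolerance scans carry no superscript)."""
    j = gmap.index_of(marker_id)
    b = assign_bin(marker_id, gmap, bin_width)
    code = TRAIT_CODES.get(trait, trait)
    suffix = "" if direction == "ST" else f"^{direction}"
    return f"q{code}{gmap.chrom[j]}.{b}{suffix}"


def scan_selected_lines(
    pop: Population,
    selected_ids: Sequence[str],
    background: GenomeBackground,
    config: ScanConfig = ScanConfig(),
    trait: str = "ST",
    direction: str = "ST",
) -> list[QtlHit]:
    """Genome scan for over-introgressed loci in a selected line subset.

    One test per marker against the genome-wide background of the population;
    markers significant at ``alpha_scan`` *and* enriched above background are
    reported, collapsed to one QTL per (chromosome, bin) at the peak marker.
    """
    if len(selected_ids) == 0:
        raise ValueError("empty selection")
    sub = pop.subset(selected_ids)
    gmap = pop.map
    alpha = config.alpha_scan
    if config.bonferroni:
        alpha = alpha / gmap.n_markers

    if config.three_class:
        bg_full = np.array(
            [
                [lf.f_recip_hom, lf.f_het, lf.f_donor_hom]
                for lf in (
                    locus_genotype_freqs(pop.genotypes[:, j], mid)
                    for j, mid in enumerate(gmap.marker_ids)
                )
            ]
        ).mean(axis=0)
        if np.any(bg_full <= 0):
            raise ValueError("degenerate background genotype-class frequencies")
    p_bar = (
        background.carrier_freq if config.het_as_carrier else background.mean_introgression
    )

    hits: list[QtlHit] = []
    carriers = carrier_matrix(sub, config.het_as_carrier)
    missing = sub.genotypes == MISSING
    for j, mid in enumerate(gmap.marker_ids):
        typed = ~missing[:, j]
        n = int(typed.sum())
        if n == 0:
            continue
        m = int(carriers[typed, j].sum())
        if config.three_class:
            g = sub.genotypes[typed, j]
            counts = [int((g == c).sum()) for c in (0, 1, 2)]
            chi2, p = chi2_threeclass_test(counts, bg_full)
            freq = (counts[1] + counts[2]) / n if config.het_as_carrier else counts[2] / n
        else:
            chi2, p = chi2_overintrogression_test(m, n, p_bar, config.exact_binomial)
            freq = m / n
        if p < alpha and freq > p_bar:
            hits.append(
                QtlHit(
                    marker_id=mid,
                    chrom=int(gmap.chrom[j]),
                    bin=assign_bin(mid, gmap, config.bin_width_cM),
                    name=assign_bin_and_name(
                        mid, gmap, trait, direction, config.bin_width_cM
                    ),
                    trait=trait,
                    direction=direction,
                    n_selected=n,
                    n_carriers=m,
                    carrier_freq=float(freq),
                    background_freq=float(p_bar),
                    chi2=chi2,
                    p_value=p,
                )
            )
    hits.sort(key=lambda h: (h.chrom, gmap.pos_cM[gmap.index_of(h.marker_id)]))
    if config.collapse_bins:
        best: dict[tuple[int, int], QtlHit] = {}
        order: list[tuple[int, int]] = []
        for h in hits:
            key = (h.chrom, h.bin)
            if key not in best:
                best[key] = h
                order.append(key)
            elif h.p_value < best[key].p_value:
                best[key] = h
        hits = [best[k] for k in order]
    return hits


def select_trait_extremes(
    phenos: pd.DataFrame,
    check_id: str,
    trait: str,
    direction: str,
    alpha: float = 0.01,
    treatment: str = "normal",
) -> list[str]:
    """Lines whose plot values differ significantly from the check in the
    stated direction (Welch two-sample t-test, p < alpha).

    direction 'P' keeps lines significantly *above* the check (positive
    selection), 'N' significantly below (negative selection).
    """
    if trait not in phenos.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    if direction not in ("P", "N"):
        raise ValueError("direction must be 'P' or 'N'")
    sub = phenos[phenos["treatment"] == treatment]
    check = sub.loc[sub["line_id"] == check_id, trait].dropna().to_numpy()
    if check.size < 2:
        raise ValueError(f"check {check_id!r} needs >= 2 plots under {treatment!r}")
    out = []
    for lid, grp in sub.groupby("line_id", sort=False):
        if lid == check_id:
            continue
        vals = grp[trait].dropna().to_numpy()
        if vals.size < 2:
            raise ValueError(f"line {lid!r} has fewer than 2 plots")
        t, p = stats.ttest_ind(vals, check, equal_var=False)
        sign_ok = t > 0 if direction == "P" else t < 0
        if p < alpha and sign_ok:
            out.append(lid)
    return out


def hits_to_dataframe(hits: Sequence[QtlHit], population: str = "") -> pd.DataFrame:
    """QTL report table (one row per QTL)."""
    cols = [
        "name", "trait", "direction", "population", "chrom", "bin_label",
        "peak_marker", "n_selected", "n_carriers", "carrier_freq",
        "background_freq", "fold_enrichment", "chi2", "p_value",
    ]
    rows = [
        {
            "name": h.name,
            "trait": h.trait,
            "direction": h.direction,
            "population": population,
            "chrom": h.chrom,
            "bin_label": h.bin_label,
            "peak_marker": h.marker_id,
            "n_selected": h.n_selected,
            "n_carriers": h.n_carriers,
            "carrier_freq": h.carrier_freq,
            "background_freq": h.background_freq,
            "fold_enrichment": h.fold_enrichment,
            "chi2": h.chi2,
            "p_value": h.p_value,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=cols)
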