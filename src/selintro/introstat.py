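"""Per-locus and genome-wide introgression statistics.

"Introgression" is reported as the donor-homozygote frequency and
heterozygosity separately; under a BC_b F_{s+1} pedigree without selection the
Mendelian expectations are

    het        = (1/2)^(b+s)
    allele frq = (1/2)^(b+1)          (invariant under selfing)
    donor-hom  = allele frq - het/2

e.g. 0.03125 and 0.109375 for BC2F4.  Missing genotypes are excluded per
locus (complete-case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simpop import MISSING, Population

__all__ = [
    "LocusFreqs",
    "GenomeBackground",
    "locus_genotype_freqs",
    "locus_freq_table",
    "genome_background",
    "mendelian_expectation",
]


@dataclass(frozen=True)
class LocusFreqs:
    marker_id: str
    n_typed: int
    f_recip_hom: float
    f_het: float
    f_donor_hom: float

    @property
    def donor_allele_freq(self) -> float:
        return self.f_donor_hom + self.f_het / 2.0

    @property
    def carrier_freq(self) -> float:
        """Frequency of lines carrying any donor allele (het or donor-hom)."""
        return self.f_donor_hom + self.f_het


@dataclass(frozen=True)
class GenomeBackground:
    """Genome-wide background: unweighted means over markers of the
    donor-homozygote frequency and the heterozygote frequency."""

    mean_introgression: float
    mean_het: float

    @property
    def carrier_freq(self) -> float:
        return self.mean_introgression + self.mean_het


def locus_genotype_freqs(column: np.ndarray, marker_id: str = "") -> LocusFreqs:
    """Genotype-class proportions at one marker over non-missing lines."""
    col = np.asarray(column)
    typed = col[col != MISSING]
    if typed.size == 0:
        raise ValueError(f"all genotypes missing at marker {marker_id!r}")
    n = typed.size
    return LocusFreqs(
        marker_id=marker_id,
        n_typed=int(n),
        f_recip_hom=float(np.count_nonzero(typed == 0)) / n,
        f_het=float(np.count_nonzero(typed == 1)) / n,
        f_donor_hom=float(np.count_nonzero(typed == 2)) / n,
    )


def locus_freq_table(pop: Population) -> pd.DataFrame:
    """Per-marker LocusFreqs as a tidy table."""
    rows = []
    for j, mid in enumerate(pop.map.marker_ids):
        lf = locus_genotype_freqs(pop.genotypes[:, j], mid)
        rows.append(
            {
                "marker_id": mid,
                "chrom": int(pop.map.chrom[j]),
                "pos_cM": float(pop.map.pos_cM[j]),
                "n_typed": lf.n_typed,
                "f_recip_hom": lf.f_recip_hom,
                "f_het": lf.f_het,
                "f_donor_hom": lf.f_donor_hom,
                "donor_allele_freq": lf.donor_allele_freq,
            }
        )
    return pd.DataFrame(rows)


def genome_background(pop: Population) -> GenomeBackground:
    """Marker-wise mean donor-homozygote frequency and heterozygosity."""
    if pop.n_lines < 1 or pop.map.n_markers < 1:
        raise ValueError("empty population")
    hom = np.empty(pop.map.n_markers)
    het = np.empty(pop.map.n_markers)
    for j in range(pop.map.n_markers):
        lf = locus_genotype_freqs(pop.genotypes[:, j], pop.map.marker_ids[j])
        hom[j] = lf.f_donor_hom
        het[j] = lf.f_het
    return GenomeBackground(float(hom.mean()), float(het.mean()))


def mendelian_expectation(n_backcrosses: int, n_selfings: int) -> tuple[float, float]:
    """Expected (donor-homozygote frequency, heterozygosity) under the pedigree
    with no selection."""
    if n_backcrosses < 0 or n_selfings < 0:
        raise ValueError("generation counts must be non-negative")
    het = 0.5 ** (n_backcrosses + n_selfings)
    allele = 0.5 ** (n_backcrosses + 1)
    return allele - het / 2.0, het
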