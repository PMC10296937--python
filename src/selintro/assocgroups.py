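"""Association groups: unlinked loci perfectly co-introgressed under selection.

Selection on a polygenic trait produces non-random multi-locus associations:
sets of unlinked loci whose donor alleles are jointly required end up
*perfectly associated* in the selected lines — the same m lines carry donor
introgression at every locus of the set and the remaining n - m lines carry
it at none.  Under independence (no selection) the probability of such a
pattern for r unlinked loci with expected per-locus introgression
frequencies p_i is

    p_AG = prod_i p_i^m * prod_i (1 - p_i)^(n - m)

which reduces to p^(r m) (1 - p)^(r (n - m)) when all p_i = p.  A small p_AG
is evidence that the co-introgression pattern was produced by selection
rather than chance.

A group is declared only under double criteria: every member locus is itself
over-introgressed (chi-square p < alpha_locus) and p_AG < pag_threshold.
"Unlinked" means different chromosomes or at least ``unlinked_cM`` apart on
the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, exp, log
from typing import Sequence

import numpy as np
import pandas as pd

from .introstat import GenomeBackground, locus_genotype_freqs
from .qtlscan import chi2_overintrogression_test
from .simpop import MISSING, Population

__all__ = ["AgConfig", "AssociationGroup", "p_ag", "find_association_groups",
           "groups_to_dataframe"]


@dataclass(frozen=True)
class AgConfig:
    alpha_locus: float = 0.05
    pag_threshold: float = 1e-4
    unlinked_cM: float = 50.0
    het_as_carrier: bool = True
    with_binomial_coefficient: bool = False  # multiply by C(n, m) per locus
    # p_i = observed per-locus background frequency instead of the genome-wide
    # background (the null expectation; default)
    per_locus_background: bool = False

    def __post_init__(self):
        if not 0 < self.alpha_locus < 1:
            raise ValueError("alpha_locus must be in (0, 1)")
        if self.unlinked_cM <= 0:
            raise ValueError("unlinked_cM must be positive")


@dataclass(frozen=True)
class AssociationGroup:
    loci: tuple[str, ...]
    chroms: tuple[int, ...]
    n: int
    m: int
    p_i: tuple[float, ...]
    p_ag: float
    locus_p_values: tuple[float, ...]

    @property
    def r(self) -> int:
        return len(self.loci)


def p_ag(
    p_list: Sequence[float], n: int, m: int, with_binomial_coefficient: bool = False
) -> float:
    """Multi-locus independence probability of a perfect co-introgression
    pattern: m of n lines carry donor alleles at all r loci, the rest at none.

    Computed in log space.  ``with_binomial_coefficient`` multiplies in
    C(n, m) per locus, turning the pattern probability into the probability
    of *some* m-line perfect split at each locus.
    """
    p = np.asarray(p_list, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need r >= 2 expected frequencies")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("each expected frequency must be in (0, 1)")
    if not 0 <= m <= n:
        raise ValueError("need 0 <= m <= n")
    logp = float(m * np.log(p).sum() + (n - m) * np.log1p(-p).sum())
    if with_binomial_coefficient:
        logp += p.size * log(comb(n, m))
    return exp(logp)


def _linkage_clusters(
    loci_idx: Sequence[int], pop: Population, unlinked_cM: float
) -> list[list[int]]:
    """Cluster map-ordered marker indices transitively: same chromosome and
    consecutive gap < unlinked_cM puts two loci in one cluster."""
    idx = sorted(loci_idx, key=lambda j: (pop.map.chrom[j], pop.map.pos_cM[j]))
    clusters: list[list[int]] = []
    for j in idx:
        if clusters:
            k = clusters[-1][-1]
            same = pop.map.chrom[j] == pop.map.chrom[k]
            if same and pop.map.pos_cM[j] - pop.map.pos_cM[k] < unlinked_cM:
                clusters[-1].append(j)
                continue
        clusters.append([j])
    return clusters


def find_association_groups(
    pop: Population,
    selected_ids: Sequence[str],
    background: GenomeBackground,
    config: AgConfig = AgConfig(),
) -> list[AssociationGroup]:
    """Enumerate association groups among selected lines.

    Candidate loci are those over-introgressed in the selection (chi-square
    p < alpha_locus and carrier frequency above background).  Candidates are
    partitioned by their exact carrier pattern across the selected lines;
    within a pattern class, linked loci (same chromosome, closer than
    ``unlinked_cM``) collapse to their smallest-p representative, and the
    remaining pairwise-unlinked representatives form a group if r >= 2 and
    p_AG < pag_threshold.  Lines with a missing genotype at any candidate
    locus are excluded from the pattern comparison.  Output order follows the
    map position of each group's first locus.
    """
    if len(selected_ids) < 2:
        raise ValueError("need at least 2 selected lines")
    sub = pop.subset(selected_ids)
    gmap = pop.map
    p_bar = (
        background.carrier_freq if config.het_as_carrier else background.mean_introgression
    )

    if config.per_locus_background:
        full_freqs = []
        for j in range(gmap.n_markers):
            lf = locus_genotype_freqs(pop.genotypes[:, j], gmap.marker_ids[j])
            f = lf.carrier_freq if config.het_as_carrier else lf.f_donor_hom
            full_freqs.append(f)
    else:
        full_freqs = [p_bar] * gmap.n_markers

    geno = sub.genotypes
    carrier = (geno >= 1) if config.het_as_carrier else (geno == 2)

    candidates: list[int] = []
    locus_p: dict[int, float] = {}
    for j in range(gmap.n_markers):
        typed = geno[:, j] != MISSING
        n_j = int(typed.sum())
        if n_j == 0:
            continue
        m_j = int(carrier[typed, j].sum())
        chi2, p = chi2_overintrogression_test(m_j, n_j, p_bar)
        if p < config.alpha_locus and m_j / n_j > p_bar:
            candidates.append(j)
            locus_p[j] = p
    if not candidates:
        return []

    complete = np.all(geno[:, candidates] != MISSING, axis=1)
    n = int(complete.sum())
    if n < 2:
        return []
    patt = carrier[complete][:, candidates]

    classes: dict[tuple, list[int]] = {}
    for k, j in enumerate(candidates):
        classes.setdefault(tuple(patt[:, k].tolist()), []).append(j)

    groups: list[AssociationGroup] = []
    for pattern, members in classes.items():
        if len(members) < 2:
            continue
        clusters = _linkage_clusters(members, pop, config.unlinked_cM)
        reps = [min(cl, key=lambda j: (locus_p[j], j)) for cl in clusters]
        if len(reps) < 2:
            continue
        m = int(sum(pattern))
        p_i = []
        for j in reps:
            f = full_freqs[j]
            # clamp degenerate background frequencies away from {0,1}
            p_i.append(min(max(f, 1.0 / (2 * pop.n_lines)), 1.0 - 1.0 / (2 * pop.n_lines)))
        pag = p_ag(p_i, n, m, config.with_binomial_coefficient)
        if pag < config.pag_threshold:
            groups.append(
                AssociationGroup(
                    loci=tuple(gmap.marker_ids[j] for j in reps),
                    chroms=tuple(int(gmap.chrom[j]) for j in reps),
                    n=n,
                    m=m,
                    p_i=tuple(p_i),
                    p_ag=pag,
                    locus_p_values=tuple(locus_p[j] for j in reps),
                )
            )
    groups.sort(
        key=lambda g: (
            gmap.chrom[gmap.index_of(g.loci[0])],
            gmap.pos_cM[gmap.index_of(g.loci[0])],
        )
    )
    return groups


def groups_to_dataframe(groups: Sequence[AssociationGroup]) -> pd.DataFrame:
    cols = ["group_id", "r", "loci", "chroms", "n", "m", "p_ag",
            "min_locus_p", "max_locus_p"]
    rows = [
        {
            "group_id": f"AG{i + 1}",
            "r": g.r,
            "loci": ",".join(g.loci),
            "chroms": ",".join(str(c) for c in g.chroms),
            "n": g.n,
            "m": g.m,
            "p_ag": g.p_ag,
            "min_locus_p": min(g.locus_p_values),
            "max_locus_p": max(g.locus_p_values),
        }
        for i, g in enumerate(groups)
    ]
    return pd.DataFrame(rows, columns=cols)
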