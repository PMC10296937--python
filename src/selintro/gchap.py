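"""Gene-CDS-haplotype (gcHap) analysis.

A gcHap is a distinct coding sequence of a gene across accessions: exact
string identity of the (aligned, uppercased) CDS defines the haplotype.
Haplotypes are ranked Hap1, Hap2, ... by descending pooled count (ties by
first occurrence).  Diversity is Nei gene diversity E_H = 1 - sum f_k^2; the
number of "major" haplotypes (gcHapN) counts those above a pooled frequency
and count floor.

Subspecies differentiation between Xian (indica) and Geng (japonica) rice is
classified from per-subspecies predominance: a gene is *differentiated* when
each subspecies has its own predominant (> 70%) but different haplotype, and
*conserved* when the same haplotype predominates in both.

Coding mutations between two haplotypes are classified codon-by-codon as
synonymous or nonsynonymous with the standard genetic code, and haplotype
relationships are summarised as a minimum-spanning-tree network over pairwise
nucleotide (Hamming) distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

from .simpop import GeneticMap

__all__ = [
    "SUBPOPULATIONS",
    "CdsSet",
    "GcHapTable",
    "Mutation",
    "collapse_gchaps",
    "gchap_diversity",
    "shannon_diversity",
    "classify_differentiation",
    "candidate_gene_window",
    "classify_mutations",
    "haplotype_network",
    "simulate_cds_set",
]

SUBPOPULATIONS = ("Xian", "Geng", "Aus", "Bas", "Adm")
_AMBIGUOUS = set("RYSWKMBDHVN")


@dataclass
class CdsSet:
    """Aligned CDS sequences of one gene across accessions, each labelled with
    a subpopulation; optional parent labels (recipient / donor accessions)."""

    gene: str
    sequences: dict  # accession -> CDS string over {A,C,G,T,N,-}
    subpop: dict     # accession -> subpopulation label
    parents: dict = field(default_factory=dict)  # role -> accession

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"gene {self.gene!r}: aligned CDS lengths differ ({sorted(lengths)})"
            )
        missing = set(self.sequences) - set(self.subpop)
        if missing:
            raise ValueError(f"accessions without subpopulation label: {sorted(missing)}")

    @classmethod
    def from_fasta(cls, path, gene: str, parents: dict | None = None) -> "CdsSet":
        """Read a FASTA whose headers are 'accession|subpop'."""
        sequences, subpop = {}, {}
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: header {rec.id!r} is not 'accession|subpop'"
                )
            acc, sp = parts
            sequences[acc] = str(rec.seq).upper()
            subpop[acc] = sp
        return cls(gene, sequences, subpop, parents or {})


@dataclass
class GcHapTable:
    """Distinct haplotypes of one gene with per-subpopulation counts.

    ``hap_seqs`` maps 'Hap1', 'Hap2', ... (descending pooled count) to the
    haplotype sequence; ``counts`` is a (haplotype x subpopulation) table.
    """

    gene: str
    hap_seqs: dict                 # hap id -> sequence
    counts: pd.DataFrame           # index hap id, columns subpopulations
    n_dropped: int = 0             # sequences removed by the missing-data policy
    parent_haps: dict = field(default_factory=dict)  # role -> hap id or "unassigned"

    @property
    def hap_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def global_freqs(self) -> pd.Series:
        tot = self.total_counts
        return tot / tot.sum()

    def subpop_freqs(self, subpop: str) -> pd.Series:
        col = self.counts[subpop]
        n = col.sum()
        if n == 0:
            raise ValueError(f"no sequences from subpopulation {subpop!r}")
        return col / n

    @property
    def e_h(self) -> float:
        """Pooled Nei gene diversity."""
        return gchap_diversity(self.global_freqs.to_numpy())

    def gchapn(self, min_freq: float = 0.05, min_count: int = 10) -> int:
        """Number of major gcHaps: pooled frequency >= min_freq and pooled
        count >= min_count."""
        tot = self.total_counts
        freq = self.global_freqs
        return int(((freq >= min_freq) & (tot >= min_count)).sum())


def collapse_gchaps(cds: CdsSet, drop_ambiguous: bool = True) -> GcHapTable:
    """Collapse a CDS set into its gcHap table.

    Sequences containing ambiguous bases or gaps are dropped under the default
    policy.  Haplotype ids are assigned by descending pooled count with ties
    broken by first occurrence in the input.
    """
    if not cds.sequences:
        raise ValueError("empty CDS set")
    kept: dict[str, list[str]] = {}
    order: list[str] = []
    n_dropped = 0
    for acc, seq in cds.sequences.items():
        s = seq.upper()
        if drop_ambiguous and (set(s) & _AMBIGUOUS or "-" in s):
            n_dropped += 1
            continue
        if s not in kept:
            kept[s] = []
            order.append(s)
        kept[s].append(acc)
    if not kept:
        raise ValueError("all sequences dropped by the missing-data policy")
    ranked = sorted(order, key=lambda s: (-len(kept[s]), order.index(s)))
    hap_seqs = {f"Hap{i + 1}": s for i, s in enumerate(ranked)}
    subpops = list(dict.fromkeys(cds.subpop.values()))
    counts = pd.DataFrame(0, index=list(hap_seqs), columns=subpops)
    for hap, s in hap_seqs.items():
        for acc in kept[s]:
            counts.loc[hap, cds.subpop[acc]] += 1
    parent_haps = {}
    seq_to_hap = {s: h for h, s in hap_seqs.items()}
    for role, acc in cds.parents.items():
        s = cds.sequences.get(acc, "").upper()
        parent_haps[role] = seq_to_hap.get(s, "unassigned")
    return GcHapTable(cds.gene, hap_seqs, counts, n_dropped, parent_haps)


def gchap_diversity(freqs: Sequence[float]) -> float:
    """Nei gene diversity E_H = 1 - sum f_k^2 over haplotype frequencies."""
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency vector")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    return float(1.0 - np.sum(f**2))


def shannon_diversity(freqs: Sequence[float]) -> float:
    """Shannon entropy (nats) of the haplotype frequency spectrum (alternative
    diversity measure)."""
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency vector")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    f = f[f > 0]
    return float(-np.sum(f * np.log(f)))


def classify_differentiation(
    table: GcHapTable, predominance: float = 0.7
) -> str:
    """Xian-Geng differentiation class of a gene.

    'differentiated': each subspecies has a predominant (> predominance)
    haplotype and they differ; 'conserved': the same haplotype predominates in
    both; 'other' otherwise.
    """
    for sp in ("Xian", "Geng"):
        if sp not in table.counts.columns or table.counts[sp].sum() == 0:
            raise ValueError(f"subpopulation {sp!r} missing from the gcHap table")
    tops = {}
    for sp in ("Xian", "Geng"):
        freqs = table.subpop_freqs(sp)
        top = freqs.idxmax()
        if freqs[top] > predominance:
            tops[sp] = top
    if len(tops) == 2:
        return "conserved" if tops["Xian"] == tops["Geng"] else "differentiated"
    return "other"


def candidate_gene_window(
    peak_marker: str,
    gmap: GeneticMap,
    annotations: pd.DataFrame,
    flank_cM: float = 5.0,
) -> list[str]:
    """Genes within ``flank_cM`` (closed interval) of a QTL peak marker on the
    same chromosome.  ``annotations`` needs columns gene, chrom, pos_cM."""
    required = {"gene", "chrom", "pos_cM"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotations missing columns: {sorted(required - set(annotations.columns))}")
    if annotations["pos_cM"].isna().any():
        bad = annotations.loc[annotations["pos_cM"].isna(), "gene"].tolist()
        raise ValueError(f"gene annotations missing positions: {bad}")
    j = gmap.index_of(peak_marker)
    chrom, pos = gmap.chrom[j], gmap.pos_cM[j]
    hit = annotations[
        (annotations["chrom"] == chrom)
        & ((annotations["pos_cM"] - pos).abs() <= flank_cM)
    ]
    return hit["gene"].tolist()


@dataclass(frozen=True)
class Mutation:
    position: int        # 0-based nucleotide position
    codon_index: int     # 0-based codon
    kind: str            # 'synonymous' or 'nonsynonymous'
    aa_from: str
    aa_to: str


def classify_mutations(hap_a: str, hap_b: str) -> list[Mutation]:
    """Classify the differing sites between two gap-free CDS haplotypes.

    Codons with multiple differing sites are translated as whole codons, so
    each differing site within such a codon reports the same amino-acid
    change.  Requires equal lengths divisible by 3 and unambiguous bases at
    differing codons.
    """
    a, b = hap_a.upper(), hap_b.upper()
    if len(a) != len(b):
        raise ValueError("haplotypes must have equal length")
    if len(a) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    out: list[Mutation] = []
    for pos in range(len(a)):
        if a[pos] == b[pos]:
            continue
        ci = pos // 3
        cod_a, cod_b = a[3 * ci: 3 * ci + 3], b[3 * ci: 3 * ci + 3]
        if set(cod_a + cod_b) - set("ACGT"):
            raise ValueError(
                f"ambiguous base in differing codon {ci + 1} ({cod_a}/{cod_b})"
            )
        aa_a = str(Seq(cod_a).translate())
        aa_b = str(Seq(cod_b).translate())
        kind = "synonymous" if aa_a == aa_b else "nonsynonymous"
        out.append(Mutation(pos, ci, kind, aa_a, aa_b))
    return out


_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


def simulate_cds_set(
    gene: str,
    rng: np.random.Generator | int | None = None,
    n_codons: int = 100,
    n_per_subpop: int = 50,
    structure: str = "differentiated",
    predominance: float = 0.85,
    n_diff_sites: int = 3,
    minor_haps: int = 2,
) -> CdsSet:
    """Generate an aligned CDS set with predominant-haplotype structure.

    Each of the five rice subpopulations contributes ``n_per_subpop``
    accessions.  With structure 'differentiated' Xian and Geng each carry a
    different predominant haplotype (frequency ``predominance``, differing at
    ``n_diff_sites`` sites); with 'conserved' the same haplotype predominates
    everywhere; with 'other' haplotypes are drawn near-uniformly.  The
    remaining probability mass is spread over ``minor_haps`` low-frequency
    haplotypes one extra mutation away.  Internal stop codons are avoided so
    every haplotype translates cleanly.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if structure not in ("differentiated", "conserved", "other"):
        raise ValueError(f"unknown structure {structure!r}")
    base = "ATG" + "".join(
        rng.choice(_NONSTOP_CODONS) for _ in range(n_codons - 1)
    )

    def mutate(seq: str, k: int) -> str:
        s = list(seq)
        codons = rng.choice(np.arange(1, n_codons), size=k, replace=False)
        for ci in codons:
            current = seq[3 * ci: 3 * ci + 3]
            choices = [c for c in _NONSTOP_CODONS if c != current]
            s[3 * ci: 3 * ci + 3] = rng.choice(choices)
        return "".join(s)

    hap_xian = base
    hap_geng = mutate(base, n_diff_sites) if structure == "differentiated" else base
    minors = [mutate(base, n_diff_sites + 1) for _ in range(minor_haps)]

    sequences: dict[str, str] = {}
    subpop: dict[str, str] = {}
    for sp in SUBPOPULATIONS:
        major = hap_geng if sp == "Geng" else hap_xian
        pool = [major] + minors
        if structure == "other":
            probs = np.full(len(pool), 1.0 / len(pool))
        else:
            probs = np.array(
                [predominance] + [(1 - predominance) / minor_haps] * minor_haps
            )
        picks = rng.choice(len(pool), size=n_per_subpop, p=probs)
        for i, k in enumerate(picks):
            acc = f"{sp}_{i + 1:03d}"
            sequences[acc] = pool[k]
            subpop[acc] = sp
    parents = {"recipient": "Geng_001", "donor": "Xian_001"}
    return CdsSet(gene, sequences, subpop, parents)


def haplotype_network(table: GcHapTable) -> list[tuple[str, str, int]]:
    """Minimum-spanning-tree haplotype network.

    Edges (hapA, hapB, nucleotide differences) of an MST over pairwise Hamming
    distances; ties broken deterministically by (distance, hap id pair).
    Haplotype ids are compared by rank (Hap2 before Hap10).
    """
    haps = table.hap_ids
    if len(haps) < 2:
        return []
    rank = {h: i for i, h in enumerate(haps)}
    g = nx.Graph()
    g.add_nodes_from(haps)
    edges = []
    for i, ha in enumerate(haps):
        sa = table.hap_seqs[ha]
        for hb in haps[i + 1:]:
            sb = table.hap_seqs[hb]
            d = sum(1 for x, y in zip(sa, sb) if x != y)
            edges.append((d, rank[ha], rank[hb], ha, hb))
    edges.sort()
    for d, _, _, ha, hb in edges:
        g.add_edge(ha, hb, weight=d)
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    out = sorted(
        ((min(a, b, key=rank.get), max(a, b, key=rank.get), int(mst[a][b]["weight"]))
         for a, b in mst.edges),
        key=lambda e: (rank[e[0]], rank[e[1]]),
    )
    return out
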