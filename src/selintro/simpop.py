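"""Simulation of backcross introgression-line populations and their phenotypes.

The generative model mirrors a classical inter-subspecific backcross breeding
scheme in rice: an F1 between a recurrent (recipient) parent and a donor is
backcrossed to the recipient, and the backcross progeny are selfed without
selection for several generations.  Meiosis uses the Haldane map function (no
crossover interference), so the recombination fraction between adjacent
markers at distance d cM is c = (1 - exp(-2d/100)) / 2 and chromosomes assort
independently.

Genotypes are coded as the donor-allele count per marker:

    0 = recipient homozygote, 1 = heterozygote, 2 = donor homozygote,
    -1 = missing.

Under this pedigree the closed-form Mendelian expectations are: donor allele
frequency (1/2)^(b+1) after b backcrosses (invariant under selfing), and
heterozygosity (1/2)^(b+s) after s additional selfing generations, e.g. 1/8
and 1/32 for a BC2F4 (b=2, s=3), giving an expected donor-homozygote
frequency of 0.109375.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "GeneticMap",
    "PedigreeConfig",
    "Population",
    "QtlEffect",
    "TraitModel",
    "SelectionCriterion",
    "haldane",
    "simulate_gamete",
    "simulate_bc_population",
    "simulate_bc2f4_population",
    "simulate_phenotypes",
    "select_lines",
]

#: Trait order used everywhere: grain yield per plant (g), spikelet fertility
#: (%), filled grains per panicle, spikelets per panicle, 1000-grain weight
#: (g), panicles per plant, plant height (cm), heading date (days).
TRAITS = ("GYP", "SF", "FGN", "SNP", "TGW", "PN", "PH", "HD")

MISSING = -1


def haldane(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: ids, chromosome numbers and positions in cM.

    Markers must be sorted by (chromosome, position), ids unique and positions
    strictly increasing within a chromosome.
    """

    marker_ids: tuple[str, ...]
    chrom: np.ndarray  # int, shape (n_markers,)
    pos_cM: np.ndarray  # float, shape (n_markers,)

    def __post_init__(self):
        chrom = np.asarray(self.chrom, dtype=int)
        pos = np.asarray(self.pos_cM, dtype=float)
        object.__setattr__(self, "marker_ids", tuple(str(m) for m in self.marker_ids))
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_cM", pos)
        n = len(self.marker_ids)
        if not (len(chrom) == len(pos) == n):
            raise ValueError("marker_ids, chrom and pos_cM must have equal length")
        if n == 0:
            raise ValueError("empty genetic map")
        if len(set(self.marker_ids)) != n:
            raise ValueError("marker ids are not unique")
        if np.any(pos < 0):
            raise ValueError("negative cM position")
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("markers must be sorted by (chrom, pos_cM)")
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (np.diff(pos) <= 0)):
            raise ValueError("positions within a chromosome must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def index_of(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not on map") from None

    def transition_probs(self) -> np.ndarray:
        """Per-marker probability that a gamete switches parental haplotype.

        Entry 0 is 0.5 (random initial strand); within-chromosome entries use
        the Haldane function; chromosome boundaries use 0.5, which makes
        chromosomes assort independently.
        """
        c = np.empty(self.n_markers)
        c[0] = 0.5
        if self.n_markers > 1:
            d = np.diff(self.pos_cM)
            within = self.chrom[1:] == self.chrom[:-1]
            c[1:] = np.where(within, haldane(d), 0.5)
        return c

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneticMap":
        required = {"marker_id", "chrom", "pos_cM"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        df = df.sort_values(["chrom", "pos_cM"], kind="stable")
        return cls(tuple(df["marker_id"]), df["chrom"].to_numpy(), df["pos_cM"].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "chrom": self.chrom, "pos_cM": self.pos_cM}
        )

    @classmethod
    def default(
        cls, n_markers: int = 210, n_chromosomes: int = 12, total_cM: float = 1530.0
    ) -> "GeneticMap":
        """Evenly spaced synthetic SSR-scale map (defaults: 210 markers on 12
        chromosomes, ~1530 cM genome, the scale of a typical rice map)."""
        per = [n_markers // n_chromosomes] * n_chromosomes
        for i in range(n_markers % n_chromosomes):
            per[i] += 1
        chrom_len = total_cM / n_chromosomes
        ids, chroms, pos = [], [], []
        for ch in range(1, n_chromosomes + 1):
            k = per[ch - 1]
            step = chrom_len / k
            for j in range(k):
                ids.append(f"M{ch:02d}_{j + 1:02d}")
                chroms.append(ch)
                pos.append(round(step / 2 + step * j, 3))
        return cls(tuple(ids), np.array(chroms), np.array(pos))


@dataclass(frozen=True)
class PedigreeConfig:
    """Crossing-scheme parameters: b backcrosses then s selfing generations,
    no selection, each line an independent single-seed descent."""

    n_backcrosses: int = 2
    n_selfings: int = 3
    n_lines: int = 126
    seed: int = 0

    def __post_init__(self):
        if self.n_backcrosses < 0 or self.n_selfings < 0:
            raise ValueError("generation counts must be non-negative")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")

    @property
    def generation(self) -> str:
        bc = f"BC{self.n_backcrosses}" if self.n_backcrosses else ""
        return f"{bc}F{self.n_selfings + 1}"


@dataclass
class Population:
    """Genotyped line collection: an (n_lines, n_markers) matrix of donor-allele
    counts in {0, 1, 2} (-1 missing), tied to a genetic map."""

    genotypes: np.ndarray
    map: GeneticMap
    line_ids: tuple[str, ...]
    generation: str = "BC2F4"

    def __post_init__(self):
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if g.shape[1] != self.map.n_markers:
            raise ValueError(
                f"genotype matrix has {g.shape[1]} columns but map has "
                f"{self.map.n_markers} markers"
            )
        if g.shape[0] != len(self.line_ids):
            raise ValueError("line_ids length must match genotype rows")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {g[i, j]} at line {self.line_ids[i]!r}, "
                f"marker {self.map.marker_ids[j]!r}"
            )
        self.genotypes = g
        self.line_ids = tuple(str(x) for x in self.line_ids)

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    def subset(self, line_ids: Sequence[str]) -> "Population":
        index = {lid: i for i, lid in enumerate(self.line_ids)}
        unknown = [lid for lid in line_ids if lid not in index]
        if unknown:
            raise KeyError(f"unknown line ids: {unknown}")
        rows = [index[lid] for lid in line_ids]
        return Population(
            self.genotypes[rows], self.map, tuple(line_ids), self.generation
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=list(self.map.marker_ids))
        df.insert(0, "line_id", list(self.line_ids))
        return df


def _gametes(parents: np.ndarray, c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete per parent.  parents: (k, 2, n_markers) phased diplotypes."""
    k, _, n = parents.shape
    switch = rng.random((k, n)) < c
    strand = np.bitwise_and(np.cumsum(switch, axis=1), 1)
    return np.take_along_axis(parents, strand[:, None, :], axis=1)[:, 0, :]


def simulate_gamete(
    parent: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One meiotic gamete from a phased diplotype (2, n_markers) of 0/1 alleles."""
    parent = np.asarray(parent, dtype=np.int8)
    if parent.shape != (2, gmap.n_markers):
        raise ValueError(
            f"parent diplotype shape {parent.shape} does not match map with "
            f"{gmap.n_markers} markers"
        )
    return _gametes(parent[None], gmap.transition_probs(), rng)[0]


def simulate_bc_population(config: PedigreeConfig, gmap: GeneticMap) -> Population:
    """Simulate independent lines through F1 -> b backcrosses -> s selfings.

    The recurrent parent is fixed for allele 0 and the donor for allele 1 at
    every marker.  No selection is applied at any generation; each line is an
    independent single-seed descent.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    c = gmap.transition_probs()
    k, n = config.n_lines, gmap.n_markers
    recip = np.zeros((k, n), dtype=np.int8)
    donor = np.ones((k, n), dtype=np.int8)
    plants = np.stack([recip, donor], axis=1)  # every line starts as the F1
    for _ in range(config.n_backcrosses):
        g = _gametes(plants, c, rng)
        plants = np.stack([g, np.zeros_like(g)], axis=1)
    for _ in range(config.n_selfings):
        g1 = _gametes(plants, c, rng)
        g2 = _gametes(plants, c, rng)
        plants = np.stack([g1, g2], axis=1)
    genotypes = plants.sum(axis=1, dtype=np.int8)
    width = max(4, len(str(k)))
    line_ids = tuple(f"L{i + 1:0{width}d}" for i in range(k))
    return Population(genotypes, gmap, line_ids, config.generation)


def simulate_bc2f4_population(
    n_lines: int = 126, gmap: GeneticMap | None = None, seed: int = 0
) -> Population:
    """Convenience wrapper: BC2F4 (two backcrosses, three selfings)."""
    gmap = gmap or GeneticMap.default()
    cfg = PedigreeConfig(n_backcrosses=2, n_selfings=3, n_lines=n_lines, seed=seed)
    return simulate_bc_population(cfg, gmap)


@dataclass(frozen=True)
class QtlEffect:
    """Additive effect of a donor allele on one trait, optionally scaled per
    treatment (multiplier 0 under 'normal' makes a stress-specific QTL)."""

    trait: str
    marker_id: str
    effect: float
    multipliers: dict = field(default_factory=dict)  # treatment -> multiplier

    def multiplier(self, treatment: str) -> float:
        return self.multipliers.get(treatment, 1.0)


# Check-variety trait means from the replicated progeny test, used as the
# synthetic baselines (normal / salt): the recipient suffers an 84.5% GYP
# reduction, 50% PN reduction, 31.2% height reduction and an 11.7-day heading
# delay under sustained ~0.8% NaCl irrigation.
CHECK_BASELINES = {
    "GYP": {"normal": 22.6, "salt": 3.5},
    "SF": {"normal": 87.5, "salt": 54.0},
    "FGN": {"normal": 124.0, "salt": 48.8},
    "SNP": {"normal": 134.2, "salt": 99.4},
    "TGW": {"normal": 24.2, "salt": 20.3},
    "PN": {"normal": 7.2, "salt": 3.6},
    "PH": {"normal": 124.3, "salt": 85.5},
    "HD": {"normal": 105.3, "salt": 117.0},
}

# Plot-level residual standard deviations (per trait, trait units); chosen as
# realistic field-plot noise for replicated single-row rice plots.
DEFAULT_RESIDUAL_SD = {
    "GYP": 1.5, "SF": 4.0, "FGN": 8.0, "SNP": 10.0,
    "TGW": 0.8, "PN": 0.8, "PH": 4.0, "HD": 1.5,
}

# Between-line polygenic standard deviations (donor segments outside the
# modelled QTLs plus residual heterozygosity).
DEFAULT_LINE_SD = {
    "GYP": 2.5, "SF": 6.0, "FGN": 12.0, "SNP": 15.0,
    "TGW": 1.2, "PN": 1.0, "PH": 8.0, "HD": 3.0,
}


@dataclass
class TraitModel:
    """Linear phenotype model: plot value = baseline(treatment)
    + sum_q effect_q * multiplier_q(treatment) * donor-allele dosage
    + line random effect + plot residual.

    SF is clamped to [0, 100]; all other traits are clamped at zero (counts,
    weights, heights and dates cannot be negative).  With ``derive_fgn`` (the
    default) FGN is computed as SF * SNP / 100 so that the simulated records
    satisfy the defining identity of spikelet fertility.
    """

    baselines: dict = field(default_factory=lambda: {
        t: dict(v) for t, v in CHECK_BASELINES.items()
    })
    qtl_effects: list = field(default_factory=list)
    residual_sd: dict = field(default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    line_sd: dict = field(default_factory=lambda: dict(DEFAULT_LINE_SD))
    derive_fgn: bool = True

    def with_effects(self, effects: Iterable[QtlEffect]) -> "TraitModel":
        return replace(self, qtl_effects=list(effects))


def simulate_phenotypes(
    pop: Population,
    model: TraitModel,
    treatments: Sequence[str] = ("normal", "salt"),
    n_reps: int = 2,
    rng: np.random.Generator | int | None = None,
    check_id: str | None = "CY1",
    n_check_reps: int = 4,
) -> pd.DataFrame:
    """Simulate a replicated two-treatment progeny test.

    Returns a long table with columns line_id, treatment, rep and the eight
    traits.  The check (recurrent parent, all-recipient genotype, no line
    effect) is appended with ``n_check_reps`` plots per treatment when
    ``check_id`` is given.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    for t in treatments:
        if t not in ("normal", "salt"):
            raise ValueError(f"unknown treatment label {t!r}")
    for q in model.qtl_effects:
        if q.marker_id not in pop.map.marker_ids:
            raise KeyError(f"QTL effect marker {q.marker_id!r} not on map")
        if q.trait not in TRAITS:
            raise ValueError(f"unknown trait {q.trait!r} in QTL effects")

    geno = pop.genotypes.astype(float)
    geno[geno == MISSING] = 0.0

    entities = list(pop.line_ids)
    dosages = {q.marker_id: geno[:, pop.map.index_of(q.marker_id)] for q in model.qtl_effects}
    if check_id is not None:
        entities.append(check_id)
        for mid in dosages:
            dosages[mid] = np.append(dosages[mid], 0.0)
    n_ent = len(entities)

    sim_traits = [t for t in TRAITS if not (model.derive_fgn and t == "FGN")]
    # one line effect per entity x trait; the check is the baseline genotype
    line_eff = {
        t: rng.normal(0.0, model.line_sd.get(t, 0.0), size=n_ent) for t in sim_traits
    }
    if check_id is not None:
        for t in sim_traits:
            line_eff[t][-1] = 0.0

    records = []
    for treatment in treatments:
        genetic = {t: np.zeros(n_ent) for t in sim_traits}
        for q in model.qtl_effects:
            if q.trait in genetic:
                genetic[q.trait] += q.effect * q.multiplier(treatment) * dosages[q.marker_id]
        reps = np.array(
            [n_reps] * pop.n_lines + ([n_check_reps] if check_id is not None else [])
        )
        for i, entity in enumerate(entities):
            for rep in range(1, reps[i] + 1):
                row = {"line_id": entity, "treatment": treatment, "rep": rep}
                for t in sim_traits:
                    base = model.baselines[t][treatment]
                    val = (
                        base
                        + genetic[t][i]
                        + line_eff[t][i]
                        + rng.normal(0.0, model.residual_sd.get(t, 0.0))
                    )
                    row[t] = val
                records.append(row)
    df = pd.DataFrame.from_records(records)
    df["SF"] = df["SF"].clip(0.0, 100.0)
    for t in sim_traits:
        if t != "SF":
            df[t] = df[t].clip(lower=0.0)
    if model.derive_fgn:
        df["FGN"] = df["SF"] * df["SNP"] / 100.0
    return df[["line_id", "treatment", "rep", *TRAITS]]


@dataclass(frozen=True)
class SelectionCriterion:
    """Truncation rule on a per-line trait mean: keep lines with mean > threshold
    (op '>') or < threshold (op '<') under the given treatment."""

    trait: str
    treatment: str
    op: str  # ">" or "<"
    threshold: float

    def __post_init__(self):
        if self.op not in (">", "<"):
            raise ValueError("op must be '>' or '<'")


def select_lines(
    pop: Population, phenos: pd.DataFrame, criteria: Sequence[SelectionCriterion]
) -> list[str]:
    """Lines whose per-line means (over reps) satisfy every criterion, in
    population order."""
    for c in criteria:
        if c.trait not in phenos.columns:
            raise KeyError(f"trait {c.trait!r} not in phenotype table")
    means = phenos.groupby(["line_id", "treatment"], sort=False)[list(TRAITS)].mean()
    keep = []
    for lid in pop.line_ids:
        ok = True
        for c in criteria:
            try:
                val = means.loc[(lid, c.treatment), c.trait]
            except KeyError:
                ok = False
                break
            ok = val > c.threshold if c.op == ">" else val < c.threshold
            if not ok:
                break
        if ok:
            keep.append(lid)
    return keep
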