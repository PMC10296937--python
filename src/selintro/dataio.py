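"""Readers and writers for the pipeline's text formats, with validation.

All tabular formats are UTF-8 TSV with a header row; genetic positions are in
cM.  Genotypes are coded 0 (recipient-hom), 1 (het), 2 (donor-hom), with
"NA", "-" or an empty cell for missing (written back as "NA").  CDS sets are
FASTA with 'accession|subpop' headers.  Validation failures raise
:class:`DataValidationError` naming the file, line and column; recoverable
oddities (e.g. FGN > SNP in a phenotype row) are warnings and the row is
retained.

Report writing is byte-deterministic: stable row order, fixed float
formatting and LF line endings, so identical results always produce
identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gchap import CdsSet
from .progeny import check_spikelet_fertility
from .simpop import MISSING, GeneticMap, Population, TRAITS

__all__ = [
    "DataValidationError",
    "Dataset",
    "read_genetic_map",
    "write_genetic_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_gene_annotations",
    "read_config",
    "write_config",
    "read_dataset",
    "write_reports",
]

_MISSING_TOKENS = {"NA", "-", ""}
FLOAT_FORMAT = "%.6f"


class DataValidationError(ValueError):
    """A fatal schema or content violation, located by file/line/column."""

    def __init__(self, path, message, line=None, column=None):
        loc = str(path)
        if line is not None:
            loc += f", line {line}"
        if column is not None:
            loc += f", column {column!r}"
        super().__init__(f"{loc}: {message}")


def read_genetic_map(path) -> GeneticMap:
    """Map TSV with columns marker_id, chrom, pos_cM."""
    df = pd.read_csv(path, sep="\t")
    for col in ("marker_id", "chrom", "pos_cM"):
        if col not in df.columns:
            raise DataValidationError(path, f"missing required column {col!r}")
    try:
        return GeneticMap.from_dataframe(df)
    except ValueError as e:
        raise DataValidationError(path, str(e)) from e


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.to_dataframe().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_genotypes(path, gmap: GeneticMap, generation: str = "BC2F4") -> Population:
    """Genotype TSV: first column line_id, then one column per map marker with
    codes 0/1/2 or a missing token."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "line_id":
        raise DataValidationError(path, "first column must be 'line_id'")
    markers = list(df.columns[1:])
    unknown = [m for m in markers if m not in gmap.marker_ids]
    if unknown:
        raise DataValidationError(path, f"markers not on map: {unknown}")
    absent = [m for m in gmap.marker_ids if m not in markers]
    if absent:
        raise DataValidationError(path, f"map markers missing from genotypes: {absent}")
    n = len(df)
    geno = np.full((n, gmap.n_markers), MISSING, dtype=np.int8)
    for j, mid in enumerate(gmap.marker_ids):
        col = df[mid]
        for i, tok in enumerate(col):
            tok = tok.strip()
            if tok in _MISSING_TOKENS:
                continue
            if tok not in ("0", "1", "2"):
                raise DataValidationError(
                    path, f"invalid genotype code {tok!r}", line=i + 2, column=mid
                )
            geno[i, j] = int(tok)
    line_ids = tuple(df["line_id"])
    if len(set(line_ids)) != len(line_ids):
        raise DataValidationError(path, "duplicate line ids")
    return Population(geno, gmap, line_ids, generation)


def write_genotypes(pop: Population, path) -> None:
    df = pop.to_dataframe().astype({m: object for m in pop.map.marker_ids})
    for m in pop.map.marker_ids:
        df[m] = df[m].map(lambda v: "NA" if v == MISSING else str(int(v)))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Long phenotype TSV: line_id, treatment, rep, then the eight traits.

    Rows with SF inconsistent with FGN/SNP (or FGN > SNP) trigger a warning
    but are retained.
    """
    df = pd.read_csv(path, sep="\t", na_values=sorted(_MISSING_TOKENS))
    required = ["line_id", "treatment", "rep", *TRAITS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(path, f"missing required columns: {missing}")
    bad_treat = set(df["treatment"]) - {"salt", "normal"}
    if bad_treat:
        raise DataValidationError(path, f"unknown treatment labels: {sorted(bad_treat)}")
    dup = df.duplicated(["line_id", "treatment", "rep"])
    if dup.any():
        raise DataValidationError(
            path, "duplicate (line, treatment, rep) records", line=int(dup.idxmax()) + 2
        )
    sf_bad = (df["SF"] < 0) | (df["SF"] > 100)
    if sf_bad.any():
        raise DataValidationError(
            path, "SF outside [0, 100]", line=int(sf_bad.idxmax()) + 2, column="SF"
        )
    check_spikelet_fertility(df)
    return df[required]


def write_phenotypes(phenos: pd.DataFrame, path) -> None:
    phenos.to_csv(
        path, sep="\t", index=False, na_rep="NA",
        float_format=FLOAT_FORMAT, lineterminator="\n",
    )


def read_gene_annotations(path) -> pd.DataFrame:
    """Gene annotation TSV: gene, chrom, pos_cM."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "pos_cM"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(path, f"missing required columns: {sorted(missing)}")
    if df["pos_cM"].isna().any():
        row = int(df["pos_cM"].isna().idxmax())
        raise DataValidationError(path, "missing gene position", line=row + 2, column="pos_cM")
    return df


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DataValidationError(path, "config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


@dataclass
class Dataset:
    """A validated bundle of the pipeline's inputs."""

    map: GeneticMap
    genotypes: Population
    phenotypes: pd.DataFrame | None = None
    cds_sets: dict = field(default_factory=dict)   # gene -> CdsSet
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        if self.phenotypes is not None:
            known = set(self.genotypes.line_ids)
            pheno_ids = set(self.phenotypes["line_id"])
            orphans = pheno_ids - known
            # at most one unknown id is tolerated as the check variety
            if len(orphans) > 1:
                raise ValueError(
                    f"phenotype line ids absent from genotypes: {sorted(orphans)}"
                )


def read_dataset(
    map_path,
    genotype_path,
    phenotype_path=None,
    annotation_path=None,
    cds_paths: dict | None = None,
) -> Dataset:
    gmap = read_genetic_map(map_path)
    pop = read_genotypes(genotype_path, gmap)
    phenos = read_phenotypes(phenotype_path) if phenotype_path else None
    annot = read_gene_annotations(annotation_path) if annotation_path else None
    cds = {
        gene: CdsSet.from_fasta(p, gene) for gene, p in (cds_paths or {}).items()
    }
    try:
        return Dataset(gmap, pop, phenos, cds, annot)
    except ValueError as e:
        raise DataValidationError(phenotype_path or genotype_path, str(e)) from e


def write_reports(results: dict, out_dir) -> pd.DataFrame:
    """Write each named DataFrame as <name>.tsv under out_dir.

    Returns the manifest (file name, row count).  Output is deterministic for
    deterministic inputs: fixed float format, LF endings, "NA" for missing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sorted(results):
        df = results[name]
        dest = out / f"{name}.tsv"
        df.to_csv(
            dest, sep="\t", index=False, na_rep="NA",
            float_format=FLOAT_FORMAT, lineterminator="\n",
        )
        rows.append({"file": dest.name, "n_rows": len(df)})
    return pd.DataFrame(rows, columns=["file", "n_rows"])
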