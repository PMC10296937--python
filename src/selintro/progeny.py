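"""Replicated progeny-test statistics.

Summaries of a two-treatment (salt / normal) replicated yield trial of
introgression lines against a recurrent-parent check: two-way fixed-effects
ANOVA (genotype, stress treatment and their interaction), stress-response
summaries (absolute and percent change per trait), line-vs-check comparisons,
selection-efficiency arithmetic, and trait correlations on line means.

All traits are reduction-signed under stress (normal - salt) except heading
date, which is delay-signed (salt - normal): salt stress delays heading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .simpop import TRAITS

__all__ = [
    "StressResponse",
    "two_way_anova",
    "stress_response_summary",
    "compare_to_check",
    "selection_efficiency",
    "efficiency_ratio",
    "trait_correlations",
    "check_spikelet_fertility",
    "load_promising_lines",
]

#: traits whose stress response is a delay (salt - normal) rather than a
#: reduction (normal - salt)
DELAY_TRAITS = frozenset({"HD"})


@dataclass(frozen=True)
class StressResponse:
    entity: str
    trait: str
    mean_normal: float
    mean_salt: float

    @property
    def abs_change(self) -> float:
        if self.trait in DELAY_TRAITS:
            return self.mean_salt - self.mean_normal
        return self.mean_normal - self.mean_salt

    @property
    def pct_change(self) -> float:
        if self.mean_normal == 0:
            return float("nan")
        return self.abs_change / self.mean_normal * 100.0


def two_way_anova(
    table: pd.DataFrame, trait: str, nest_populations: bool = False
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA of a trait: Line, Treatment and their
    interaction, by sequential (type-I) sums of squares.

    Requires >= 2 lines, both treatments and >= 2 reps per cell.  With
    ``nest_populations`` a population main effect is fitted before lines
    (lines nested within populations; the table must carry a ``population``
    column).  Returns the ANOVA table with sum_sq, df, F and PR(>F); for a
    constant response all SS are 0 and F is reported as NaN.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table")
    df = table[["line_id", "treatment", trait]].dropna().copy()
    df.columns = ["line_id", "treatment", "y"]
    if df["line_id"].nunique() < 2 or df["treatment"].nunique() < 2:
        raise ValueError("need >= 2 lines and 2 treatments")
    cell_sizes = df.groupby(["line_id", "treatment"]).size()
    expected_cells = df["line_id"].nunique() * df["treatment"].nunique()
    if len(cell_sizes) < expected_cells:
        raise ValueError("a line x treatment cell has zero replicates")
    if nest_populations:
        if "population" not in table.columns:
            raise KeyError("nest_populations requires a 'population' column")
        df["population"] = table.loc[df.index, "population"]
        formula = "y ~ C(population) + C(line_id) + C(treatment) + C(line_id):C(treatment)"
    else:
        formula = "y ~ C(line_id) + C(treatment) + C(line_id):C(treatment)"
    if np.ptp(df["y"].to_numpy()) == 0:
        # constant response: all SS zero, F undefined
        terms = (["C(population)"] if nest_populations else []) + [
            "C(line_id)", "C(treatment)", "C(line_id):C(treatment)", "Residual"
        ]
        k_line = df["line_id"].nunique()
        dfs = {
            "C(population)": (df["population"].nunique() - 1) if nest_populations else 0,
            "C(line_id)": k_line - 1,
            "C(treatment)": 1,
            "C(line_id):C(treatment)": k_line - 1,
        }
        if nest_populations:
            dfs["C(line_id)"] -= dfs["C(population)"]
        used = sum(dfs.get(t, 0) for t in terms[:-1]) + 1
        out = pd.DataFrame(
            {
                "sum_sq": [0.0] * len(terms),
                "df": [float(dfs.get(t, len(df) - used)) for t in terms[:-1]]
                + [float(len(df) - used)],
                "F": [np.nan] * len(terms),
                "PR(>F)": [np.nan] * len(terms),
            },
            index=terms,
        )
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ols(formula, data=df).fit()
        aov = sm.stats.anova_lm(model, typ=1)
    return aov


def stress_response_summary(table: pd.DataFrame, entity: str) -> pd.DataFrame:
    """Per-trait stress response of one line or check: treatment means,
    absolute change and percent change (of the normal-condition mean)."""
    sub = table[table["line_id"] == entity]
    if sub.empty:
        raise KeyError(f"entity {entity!r} not in table")
    present = set(sub["treatment"])
    if not {"normal", "salt"} <= present:
        missing = {"normal", "salt"} - present
        raise ValueError(f"entity {entity!r} missing treatment arm(s): {sorted(missing)}")
    means = sub.groupby("treatment")[list(TRAITS)].mean()
    rows = []
    for t in TRAITS:
        sr = StressResponse(entity, t, float(means.loc["normal", t]),
                            float(means.loc["salt", t]))
        rows.append(
            {
                "entity": entity,
                "trait": t,
                "mean_normal": sr.mean_normal,
                "mean_salt": sr.mean_salt,
                "abs_change": sr.abs_change,
                "pct_change": sr.pct_change,
            }
        )
    return pd.DataFrame(rows)


def compare_to_check(
    table: pd.DataFrame, line: str, check: str, trait: str, treatment: str
) -> tuple[float, float, float]:
    """(mean difference, percent change vs check, Welch p) for one trait under
    one treatment.

    The p-value needs >= 2 plots per entity; with means only (single record)
    it is returned as NaN while the percent change is still computed.
    """
    sub = table[table["treatment"] == treatment]
    x = sub.loc[sub["line_id"] == line, trait].dropna().to_numpy(dtype=float)
    c = sub.loc[sub["line_id"] == check, trait].dropna().to_numpy(dtype=float)
    if c.size == 0:
        raise KeyError(f"check {check!r} absent under treatment {treatment!r}")
    if x.size == 0:
        raise KeyError(f"line {line!r} absent under treatment {treatment!r}")
    diff = float(x.mean() - c.mean())
    pct = diff / float(c.mean()) * 100.0
    if x.size >= 2 and c.size >= 2:
        _, p = stats.ttest_ind(x, c, equal_var=False)
        p = float(p)
    else:
        p = float("nan")
    return diff, pct, p


def selection_efficiency(n_confirmed: int, n_screened: int) -> float:
    """Fraction of screened plants confirmed by progeny testing."""
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    return n_confirmed / n_screened


def efficiency_ratio(
    n_confirmed_a: int, n_screened_a: int, n_confirmed_b: int, n_screened_b: int
) -> float:
    """Ratio of two groups' selection efficiencies (group A / group B)."""
    eff_b = selection_efficiency(n_confirmed_b, n_screened_b)
    if eff_b == 0:
        raise ValueError("reference group has zero efficiency")
    return selection_efficiency(n_confirmed_a, n_screened_a) / eff_b


def trait_correlations(
    table: pd.DataFrame, treatment: str, exclude: tuple[str, ...] = ()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of line means under one treatment.

    Returns (r matrix, two-sided p matrix); a constant trait yields NaN off
    the diagonal.  Needs >= 3 lines.
    """
    sub = table[table["treatment"] == treatment]
    means = sub.groupby("line_id")[[t for t in TRAITS if t not in exclude]].mean()
    if len(means) < 3:
        raise ValueError("need >= 3 lines for correlations")
    cols = means.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            x, y = means[a].to_numpy(), means[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def check_spikelet_fertility(table: pd.DataFrame, tolerance: float = 0.5) -> pd.DataFrame:
    """Cross-check the SF column against FGN / SNP * 100.

    Returns the rows whose recomputed SF differs from the recorded SF by more
    than ``tolerance`` percentage points (and warns); rows with FGN > SNP are
    included, a physically impossible combination occasionally seen in
    published tables.
    """
    recomputed = table["FGN"] / table["SNP"] * 100.0
    bad = (recomputed - table["SF"]).abs() > tolerance
    flagged = table[bad | (table["FGN"] > table["SNP"])]
    if not flagged.empty:
        warnings.warn(
            f"{len(flagged)} phenotype rows have SF inconsistent with FGN/SNP "
            "or FGN > SNP",
            stacklevel=2,
        )
    return flagged


def load_promising_lines() -> pd.DataFrame:
    """Published trait means of nine promising introgression lines and the
    recurrent-parent check (CY1) under both treatments of the replicated
    progeny test.  One record per line x treatment (means only, rep = 1)."""
    with resources.files("selintro.data").joinpath("promising_lines.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
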