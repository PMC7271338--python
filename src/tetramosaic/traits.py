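"""Field-trial and knockout statistics.

Trait tables hold replicate measurements per line (pollen fertility %,
seed setting %, yield per plant g, ...). On top of them this module
computes per-line summaries (mean ± SE), Pearson correlation matrices
between traits across lines, mid-parent and over-parent heterosis, and
wild-type vs knockout-mutant contrasts with the conventional significance
stars (* for 0.01 < p <= 0.05, ** for p <= 0.01, Welch two-sided t-test).

All reported percentages and gram values are rounded half-up to 2
decimals, matching how such trials are conventionally reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tetramosaic._util import round_half_up

__all__ = [
    "TraitTable",
    "ContrastResult",
    "star_code",
    "summarize",
    "corr_matrix",
    "heterosis",
    "knockout_contrasts",
    "fertility_decrease_range",
]


class TraitTable:
    """Replicate trait measurements keyed by (line, replicate).

    Wraps a DataFrame with columns ``line``, ``replicate`` and one column
    per trait. Trait values must be finite.
    """

    ID_COLUMNS = ("line", "replicate")

    def __init__(self, data: pd.DataFrame):
        for col in self.ID_COLUMNS:
            if col not in data.columns:
                raise ValueError(f"trait table needs a {col!r} column")
        self.data = data.reset_index(drop=True)
        values = self.data[self.traits]
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            raise ValueError("trait values must be finite")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.ID_COLUMNS]

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.data["line"]))

    def replicates(self, line: str, trait: str) -> np.ndarray:
        sel = self.data.loc[self.data["line"] == line, trait]
        if sel.empty:
            raise KeyError(f"line {line!r} not in trait table")
        return sel.to_numpy(dtype=float)

    def line_means(self) -> pd.DataFrame:
        """Per-line trait means (lines x traits)."""
        return self.data.groupby("line", sort=False)[self.traits].mean()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ContrastResult:
    """Wild-type vs mutant contrast for one trait."""

    trait: str
    reference: str
    test: str
    reference_mean: float
    test_mean: float
    difference: float  # reference − test, rounded to 2 decimals
    p_value: float
    stars: str


def star_code(p: float) -> str:
    """Significance stars: ** for p <= 0.01, * for 0.01 < p <= 0.05."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def summarize(table: TraitTable) -> pd.DataFrame:
    """Per-line mean and standard error (sd/sqrt(n)) for every trait.

    Returns a DataFrame indexed by line with a two-level column index
    (trait, {mean, se}). Raises on any line with a single replicate.
    """
    counts = table.data.groupby("line")["replicate"].count()
    single = counts[counts < 2]
    if not single.empty:
        raise ValueError(
            f"lines with <2 replicates (SE undefined): {list(single.index)}"
        )
    g = table.data.groupby("line", sort=False)[table.traits]
    mean = g.mean()
    se = g.sem(ddof=1)
    out = pd.concat({"mean": mean, "se": se}, axis=1)
    return out.swaplevel(axis=1).sort_index(axis=1)


def corr_matrix(table: TraitTable, traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson correlation between traits across per-line means.

    A zero-variance trait yields NaN cells and a warning rather than a
    silent 0. Requires at least 3 lines.
    """
    traits = list(traits) if traits is not None else table.traits
    means = table.line_means()[traits]
    if len(means) < 3:
        raise ValueError("need >= 3 lines for a correlation matrix")
    zero_var = [t for t in traits if np.isclose(means[t].std(ddof=1), 0.0)]
    if zero_var:
        warnings.warn(
            f"zero-variance traits, correlations undefined: {zero_var}",
            stacklevel=2,
        )
    r = means.corr(method="pearson")
    # pandas leaves the diagonal of a zero-variance trait at 1; flag it
    for t in zero_var:
        r.loc[t, :] = np.nan
        r.loc[:, t] = np.nan
    return r


def heterosis(p1_mean: float, p2_mean: float, f1_mean: float) -> tuple[float, float]:
    """Mid-parent and over-parent heterosis of an F1, in percent.

    MPH = 100·(F1 − MP)/MP with MP = (P1+P2)/2; OPH = 100·(F1 − BP)/BP
    with BP = max(P1, P2). Both rounded half-up to 2 decimals. Parent
    means must be positive for the ratios to be defined.
    """
    if p1_mean <= 0 or p2_mean <= 0:
        raise ValueError("parent means must be positive")
    mp = (p1_mean + p2_mean) / 2.0
    bp = max(p1_mean, p2_mean)
    mph = 100.0 * (f1_mean - mp) / mp
    oph = 100.0 * (f1_mean - bp) / bp
    return round_half_up(mph, 2), round_half_up(oph, 2)


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value, defined also for degenerate
    zero-variance groups (p=0 when the means differ, p=1 when equal)."""
    if (a == a[0]).all() and (b == b[0]).all():
        return 0.0 if a[0] != b[0] else 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def knockout_contrasts(
    table: TraitTable,
    wild_type: str,
    mutants: Sequence[str],
    traits: Sequence[str] | None = None,
) -> tuple[list[ContrastResult], dict[str, float]]:
    """Wild-type vs each mutant per trait, plus cross-mutant mean decrease.

    The per-mutant difference is WT mean − mutant mean; the cross-mutant
    average decrease per trait is WT mean − mean of the mutant means. Both
    rounded half-up to 2 decimals. P-values are Welch two-sided t-tests on
    the replicate values; stars follow :func:`star_code`.
    """
    traits = list(traits) if traits is not None else table.traits
    known = set(table.lines)
    missing = [ln for ln in [wild_type, *mutants] if ln not in known]
    if missing:
        raise KeyError(f"lines absent from trait table: {missing}")
    results: list[ContrastResult] = []
    avg_decrease: dict[str, float] = {}
    for trait in traits:
        wt = table.replicates(wild_type, trait)
        mutant_means = []
        for mut in mutants:
            mu = table.replicates(mut, trait)
            p = _welch_p(wt, mu)
            results.append(
                ContrastResult(
                    trait=trait,
                    reference=wild_type,
                    test=mut,
                    reference_mean=round_half_up(wt.mean(), 2),
                    test_mean=round_half_up(mu.mean(), 2),
                    difference=round_half_up(wt.mean() - mu.mean(), 2),
                    p_value=p,
                    stars=star_code(p),
                )
            )
            mutant_means.append(mu.mean())
        avg_decrease[trait] = round_half_up(
            wt.mean() - float(np.mean(mutant_means)), 2
        )
    return results, avg_decrease


def fertility_decrease_range(
    wt_mean: float, mutant_means: Sequence[float]
) -> tuple[float, float, float]:
    """(min, max, mean) of element-wise WT − mutant decreases, 2 decimals."""
    if len(mutant_means) == 0:
        raise ValueError("need at least one mutant mean")
    decreases = [wt_mean - m for m in mutant_means]
    return (
        round_half_up(min(decreases), 2),
        round_half_up(max(decreases), 2),
        round_half_up(float(np.mean(decreases)), 2),
    )


def contrasts_to_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Contrast results as a flat DataFrame (one row per trait x mutant)."""
    return pd.DataFrame([r.__dict__ for r in results])
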