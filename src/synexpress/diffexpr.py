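"""Four-condition differential-expression procedure and regulation categories.

The design is a 2x2 factorial on log2-scale arrays: wild-type and knockout
cells, each cultured with or without the stimulus (conditions WT, WT_IL4, KO,
KO_IL4, in replicate).  The procedure floors low intensities at one global
standard deviation, excludes genes below that floor in every condition, tests
each two-group contrast with an F-test-gated t test (pooled-variance Student
when the variances are compatible, Welch otherwise), adjusts p values by
Benjamini-Hochberg, and zeroes the log2 fold changes of non-significant
contrasts.  Genes are then assigned to regulation categories from the sign
pattern of the two zeroed stimulus contrasts:

* category I   — induced by the stimulus only when the factor is present
  (WT contrast positive, KO contrast null);
* category II  — suppressed by the stimulus in knockout cells while induced
  or unchanged in wild-type cells (KO contrast negative, WT non-negative);
* category III — suppressed by the stimulus regardless of the factor (both
  contrasts negative);
* unchanged    — every other pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("WT", "WT_IL4", "KO", "KO_IL4")


@dataclass
class FourConditionExperiment:
    """Genes x replicate-columns log2 matrix plus the condition -> columns design."""

    values: pd.DataFrame
    design: dict[str, list[str]]

    def __post_init__(self) -> None:
        if set(self.design) != set(CONDITIONS):
            raise ValueError(f"design must name exactly the conditions {CONDITIONS}")
        for cond, cols in self.design.items():
            if len(cols) < 2:
                raise ValueError(f"condition {cond}: need >= 2 replicates")
            missing = set(cols) - set(self.values.columns)
            if missing:
                raise ValueError(f"condition {cond}: columns {missing} not in matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    def condition_values(self, cond: str) -> pd.DataFrame:
        return self.values[self.design[cond]]


def default_design(replicates: int = 3) -> dict[str, list[str]]:
    return {c: [f"{c}_{i + 1}" for i in range(replicates)] for c in CONDITIONS}


def preprocess_expression(
    experiment: FourConditionExperiment,
) -> tuple[FourConditionExperiment, pd.Series, float]:
    """Global-SD floor and expression mask.

    ``sd_unit`` is the standard deviation of every value in the matrix.  Genes
    whose replicate means are below ``sd_unit`` in all four conditions are
    masked as not expressed; in the remaining matrix, values below ``sd_unit``
    are raised to ``sd_unit``.
    Returns ``(floored experiment, expressed mask, sd_unit)``.
    """
    vals = experiment.values
    sd_unit = float(vals.to_numpy(dtype=float).std(ddof=1))
    if sd_unit == 0.0:
        raise ValueError("zero-variance expression matrix")
    cond_means = pd.DataFrame(
        {c: experiment.condition_values(c).mean(axis=1) for c in CONDITIONS}
    )
    expressed = (cond_means >= sd_unit).any(axis=1)
    floored = vals.loc[expressed].clip(lower=sd_unit)
    return (
        FourConditionExperiment(floored, experiment.design),
        expressed.rename("expressed"),
        sd_unit,
    )


def contrast(
    group_a: Sequence[float], group_b: Sequence[float], gate_alpha: float = 0.05
) -> tuple[float, float, str]:
    """log2 fold change and p value of one two-group comparison (b vs a).

    A two-sided variance-ratio F test gates the choice of t test: when its p
    exceeds ``gate_alpha`` the variances are treated as equal (pooled Student
    t), otherwise Welch's unequal-variance t is used.  Inputs are already on
    the log2 scale, so the fold change is mean(b) - mean(a).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    log2fc = float(b.mean() - a.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        # degenerate replicates: identical means are maximally unsurprising,
        # different means are treated as certain
        return log2fc, (1.0 if log2fc == 0.0 else 0.0), "student"
    if va == 0.0 or vb == 0.0:
        p_f = 0.0  # infinite variance ratio
    else:
        hi, lo = (vb, va) if vb >= va else (va, vb)
        df_hi = (b.size if vb >= va else a.size) - 1
        df_lo = (a.size if vb >= va else b.size) - 1
        p_f = min(1.0, 2.0 * float(stats.f.sf(hi / lo, df_hi, df_lo)))
    if p_f > gate_alpha:
        t_res = stats.ttest_ind(b, a, equal_var=True)
        test_used = "student"
    else:
        t_res = stats.ttest_ind(b, a, equal_var=False)
        test_used = "welch"
    return log2fc, float(t_res.pvalue), test_used


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def zero_nonsignificant(contrasts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Set log2fc to zero wherever the adjusted p is strictly greater than alpha."""
    out = contrasts.copy()
    out["log2fc_zeroed"] = np.where(out["p_adj"] > alpha, 0.0, out["log2fc"])
    return out


def contrast_table(
    experiment: FourConditionExperiment,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene contrast of two conditions with BH adjustment and fold-change zeroing.

    Columns: ``log2fc``, ``p_raw``, ``p_adj``, ``log2fc_zeroed``, ``test_used``
    (indexed by gene).
    """
    a = experiment.condition_values(cond_a).to_numpy(dtype=float)
    b = experiment.condition_values(cond_b).to_numpy(dtype=float)
    rows = [contrast(a[i], b[i]) for i in range(a.shape[0])]
    df = pd.DataFrame(
        rows, index=experiment.values.index, columns=["log2fc", "p_raw", "test_used"]
    )
    df["p_adj"] = adjust_fdr(df["p_raw"].to_numpy())
    df = zero_nonsignificant(df, alpha)
    return df[["log2fc", "p_raw", "p_adj", "log2fc_zeroed", "test_used"]]


def classify_categories(
    experiment: FourConditionExperiment, alpha: float = 0.05
) -> pd.Series:
    """Assign expressed genes to regulation categories I/II/III/unchanged.

    Runs the full preprocessing + contrast pipeline on the stimulus response in
    wild-type (WT_IL4 vs WT) and knockout (KO_IL4 vs KO) cells and applies the
    sign-pattern predicate to the zeroed fold changes.
    """
    floored, expressed, _ = preprocess_expression(experiment)
    wt = contrast_table(floored, "WT", "WT_IL4", alpha)["log2fc_zeroed"]
    ko = contrast_table(floored, "KO", "KO_IL4", alpha)["log2fc_zeroed"]
    labels = pd.Series("unchanged", index=floored.values.index, name="category")
    labels[(wt > 0) & (ko == 0)] = "I"
    labels[(wt >= 0) & (ko < 0)] = "II"
    labels[(wt < 0) & (ko < 0)] = "III"
    return labels


def venn_counts(sets: Mapping[str, Iterable[str]]) -> dict[frozenset, int]:
    """Exact element counts of every region of a Venn diagram over named sets.

    Keys are frozensets of set names; the count for key ``{A, B}`` is the
    number of elements in A and B but in no other set.  The empty frozenset is
    omitted (the complement region is unbounded).
    """
    named = {name: set(v) for name, v in sets.items()}
    all_elements = set().union(*named.values()) if named else set()
    regions: dict[frozenset, int] = {}
    for el in all_elements:
        key = frozenset(name for name, s in named.items() if el in s)
        regions[key] = regions.get(key, 0) + 1
    return regions
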