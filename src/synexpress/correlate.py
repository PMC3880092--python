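"""Pearson-correlation meta-analysis across expression-dataset collections.

Candidate regulators are scored against a reference gene module by averaging
the candidate-vs-reference Pearson correlations first over reference genes
within each dataset, then (unweighted) over datasets, so that no single large
series dominates the meta-analytic score.  Datasets where a vector is
constant contribute nothing to that average — the correlation is undefined
there, not zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import DatasetCollection, ExpressionDataset

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Raised when Pearson correlation is requested for a constant vector."""


@dataclass
class CorrelationProfile:
    """Per-candidate correlation evidence: one mean r per dataset plus the meta-score."""

    candidate: str
    per_dataset_r: dict[str, float] = field(default_factory=dict)

    @property
    def n_datasets(self) -> int:
        return len(self.per_dataset_r)

    @property
    def score(self) -> float:
        if not self.per_dataset_r:
            return float("nan")
        return float(np.mean(list(self.per_dataset_r.values())))


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene matrix of dataset-averaged Pearson r (unit diagonal)."""

    values: pd.DataFrame
    n_datasets_per_cell: pd.DataFrame | None = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (length >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def _row_standardize(mat: np.ndarray) -> np.ndarray:
    """Center and scale rows to unit sum-of-squares; constant rows become NaN."""
    centered = mat - mat.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / norm
    z[np.repeat(norm == 0.0, mat.shape[1], axis=1)] = np.nan
    return z


def _cross_correlation(ds: ExpressionDataset, rows_a: list[str], rows_b: list[str]) -> pd.DataFrame:
    """Within-dataset Pearson r between two gene lists (NaN where undefined)."""
    za = _row_standardize(ds.values.loc[rows_a].to_numpy(dtype=float))
    zb = _row_standardize(ds.values.loc[rows_b].to_numpy(dtype=float))
    r = np.clip(za @ zb.T, -1.0, 1.0)
    return pd.DataFrame(r, index=rows_a, columns=rows_b)


def correlation_profiles(
    collection: DatasetCollection,
    reference: list[str],
    candidates: list[str],
) -> list[CorrelationProfile]:
    """Per-dataset mean correlation of each candidate against the reference module.

    A candidate that is itself a reference gene is correlated only against the
    *other* reference genes.  Candidates measured in zero datasets are omitted
    with a warning.
    """
    reference = list(dict.fromkeys(reference))
    candidates = list(dict.fromkeys(candidates))
    if not reference:
        raise ValueError("empty reference gene set")
    profiles = {c: CorrelationProfile(c) for c in candidates}
    for ds in collection:
        cand_here = [c for c in candidates if c in ds.genes]
        ref_here = [g for g in reference if g in ds.genes]
        if not cand_here or not ref_here:
            continue
        r = _cross_correlation(ds, cand_here, ref_here)
        for c in cand_here:
            if c in r.columns:  # candidate inside the reference: drop self-correlation
                vals = r.loc[c].drop(labels=c)
            else:
                vals = r.loc[c]
            vals = vals.dropna()
            if len(vals):
                profiles[c].per_dataset_r[ds.id] = float(vals.mean())
    out = []
    for c in candidates:
        if profiles[c].n_datasets == 0:
            logger.warning("candidate %s measured in zero datasets; omitted", c)
        else:
            out.append(profiles[c])
    return out


def rank_regulators(
    collection: DatasetCollection,
    reference: list[str],
    candidates: list[str],
) -> pd.DataFrame:
    """Rank candidates by dataset-averaged mean correlation with the reference set.

    Returns a DataFrame with columns ``candidate``, ``score``, ``n_datasets``
    sorted by descending score (ties broken lexicographically by symbol).
    """
    profiles = correlation_profiles(collection, reference, candidates)
    df = pd.DataFrame(
        {
            "candidate": [p.candidate for p in profiles],
            "score": [p.score for p in profiles],
            "n_datasets": [p.n_datasets for p in profiles],
        }
    )
    return (
        df.sort_values(["score", "candidate"], ascending=[False, True])
        .reset_index(drop=True)
    )


def gene_gene_matrix(collection: DatasetCollection, genes: list[str]) -> CorrelationMatrix:
    """Average the within-dataset gene-gene Pearson matrix over datasets.

    Cell (i, j) is the mean over datasets in which both genes are measured and
    non-constant; cells with zero usable datasets are NaN.  The diagonal is 1.
    """
    genes = list(dict.fromkeys(genes))
    missing = set(genes) - set(collection.namespace)
    if missing:
        raise ValueError(f"genes outside namespace: {sorted(missing)}")
    n = len(genes)
    total = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    idx = {g: i for i, g in enumerate(genes)}
    for ds in collection:
        here = [g for g in genes if g in ds.genes]
        if len(here) < 2:
            continue
        r = _cross_correlation(ds, here, here).to_numpy()
        ok = ~np.isnan(r)
        loc = np.array([idx[g] for g in here])
        sub = np.ix_(loc, loc)
        total[sub] += np.where(ok, r, 0.0)
        counts[sub] += ok
    with np.errstate(invalid="ignore"):
        avg = total / counts
    avg[counts == 0] = np.nan
    np.fill_diagonal(avg, 1.0)
    avg = (avg + avg.T) / 2.0  # guard symmetry against float noise
    values = pd.DataFrame(avg, index=genes, columns=genes)
    return CorrelationMatrix(values, pd.DataFrame(counts, index=genes, columns=genes))


def genomewide_correlation(collection: DatasetCollection, reference_gene: str) -> pd.Series:
    """Average correlation of every other gene with one reference gene.

    Returns a Series (gene -> averaged r) sorted descending, excluding the
    reference gene itself.  Apply :func:`~synexpress.expression.filter_by_gene_cv`
    first so only datasets where the reference gene varies are used.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    seen = False
    for ds in collection:
        if reference_gene not in ds.genes:
            continue
        seen = True
        others = [g for g in ds.genes if g != reference_gene]
        if not others:
            continue
        r = _cross_correlation(ds, [reference_gene], others).iloc[0]
        for g, v in r.dropna().items():
            sums[g] = sums.get(g, 0.0) + v
            counts[g] = counts.get(g, 0) + 1
    if not seen:
        raise ValueError(f"reference gene {reference_gene!r} absent from every dataset")
    scores = pd.Series({g: sums[g] / counts[g] for g in sums}, name=reference_gene)
    # descending score, ties broken lexicographically by symbol
    scores = scores.sort_index().sort_values(ascending=False, kind="mergesort")
    return scores
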