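"""Loading and preparation of per-study expression matrices.

Each study is a genes x samples matrix of log2 intensities.  Probe-level
matrices are collapsed to gene symbols by averaging the grade-A probes of
each gene.  Two coefficient-of-variation filters select, from a collection
of studies, those in which a reference module (or a single gene) actually
varies — studies where the genes of interest are flat carry no correlation
signal and would only dilute the meta-analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: minimum number of samples a study must have to enter a collection
MIN_SAMPLES = 6


class DatasetTooSmallError(ValueError):
    """Raised when an expression table has fewer samples than required."""


class UndefinedCVError(ValueError):
    """Raised when the coefficient of variation is requested for a zero-mean vector."""


class EmptyDatasetError(ValueError):
    """Raised when probe collapsing leaves no usable genes."""


@dataclass
class ExpressionDataset:
    """One study's log2 expression matrix (rows = genes or probes, columns = samples)."""

    id: str
    values: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError(f"{self.id}: expression values must be finite")
        if self.values.columns.has_duplicates:
            raise ValueError(f"{self.id}: duplicate sample ids")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class DatasetCollection:
    """Studies sharing one gene namespace."""

    datasets: list[ExpressionDataset]
    namespace: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.namespace:
            seen: dict[str, None] = {}
            for ds in self.datasets:
                for g in ds.genes:
                    seen.setdefault(g, None)
            self.namespace = list(seen)
        ns = set(self.namespace)
        for ds in self.datasets:
            extra = set(ds.genes) - ns
            if extra:
                raise ValueError(
                    f"dataset {ds.id} has genes outside the namespace: {sorted(extra)[:5]}..."
                )

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    @property
    def ids(self) -> list[str]:
        return [ds.id for ds in self.datasets]


def read_expression_table(
    path: str | Path,
    dataset_id: str | None = None,
    platform: str = "",
    min_samples: int = MIN_SAMPLES,
) -> ExpressionDataset:
    """Parse a tab-separated expression table (first column row ids, header sample ids).

    Studies with fewer than ``min_samples`` samples are rejected: short series
    give unstable correlation estimates.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unparseable expression table") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        raise ValueError(f"{path}: non-numeric values in columns {list(non_numeric)}")
    if df.shape[1] < min_samples:
        raise DatasetTooSmallError(
            f"{path}: {df.shape[1]} samples < required minimum of {min_samples}"
        )
    return ExpressionDataset(
        id=dataset_id or path.stem, values=df.astype(float), platform=platform
    )


def collapse_probes(
    dataset: ExpressionDataset,
    annotation: pd.DataFrame,
    grade: str = "A",
) -> ExpressionDataset:
    """Collapse a probe-level matrix to unique gene symbols.

    Only probes of the requested annotation grade that map to a single named
    gene are kept; when several probes report on one gene their values are
    averaged per sample.  ``annotation`` needs columns ``probe_id``,
    ``symbol`` and ``grade``.
    """
    ann = annotation.drop_duplicates(subset="probe_id").set_index("probe_id")
    keep = ann[ann["grade"] == grade]
    # multi-symbol probes (e.g. "Abc /// Def") or blank symbols are ambiguous
    sym = keep["symbol"].astype(str)
    keep = keep[(sym != "") & ~sym.str.contains("///") & sym.notna() & (sym != "nan")]
    probes = dataset.values.index.intersection(keep.index)
    if len(probes) == 0:
        raise EmptyDatasetError(f"{dataset.id}: no grade-{grade} probes with a unique symbol")
    collapsed = (
        dataset.values.loc[probes]
        .groupby(keep.loc[probes, "symbol"])
        .mean()
        .sort_index()
        .rename_axis(index=None)
    )
    return ExpressionDataset(id=dataset.id, values=collapsed, platform=dataset.platform)


def coefficient_of_variation(values: Sequence[float] | np.ndarray) -> float:
    """sd/mean with the sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise UndefinedCVError("empty vector")
    mean = arr.mean()
    if mean == 0.0:
        raise UndefinedCVError("zero-mean vector has no coefficient of variation")
    return float(arr.std(ddof=1) / mean)


def _per_gene_cv(ds: ExpressionDataset, genes: Iterable[str]) -> pd.Series:
    """CV across samples for each listed gene present in the dataset (NaN if zero mean)."""
    present = [g for g in genes if g in ds.genes]
    sub = ds.values.loc[present]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    cv = sd / mean
    cv[mean == 0.0] = np.nan
    return cv


def filter_by_reference_cv(
    collection: DatasetCollection,
    reference: Iterable[str],
    min_cv: float = 0.30,
) -> DatasetCollection:
    """Keep datasets whose mean CV over the reference genes is >= ``min_cv``."""
    reference = list(dict.fromkeys(reference))
    if not reference:
        raise ValueError("empty reference gene set")
    missing = set(reference) - set(collection.namespace)
    if missing:
        raise ValueError(f"reference genes outside namespace: {sorted(missing)}")
    kept = []
    for ds in collection:
        cv = _per_gene_cv(ds, reference)
        usable = cv.dropna()
        if len(usable) == 0:
            logger.info("dataset %s: no usable reference genes; excluded", ds.id)
            continue
        if usable.mean() >= min_cv:
            kept.append(ds)
    return DatasetCollection(kept, namespace=collection.namespace)


def filter_by_gene_cv(
    collection: DatasetCollection,
    gene: str,
    min_cv: float = 0.05,
) -> DatasetCollection:
    """Keep datasets where the CV of one gene is >= ``min_cv``.

    Datasets in which the gene is not measured are excluded (logged).
    """
    if gene not in collection.namespace:
        raise ValueError(f"gene {gene!r} not in collection namespace")
    kept = []
    for ds in collection:
        if gene not in ds.genes:
            logger.info("dataset %s lacks gene %s; excluded", ds.id, gene)
            continue
        cv = _per_gene_cv(ds, [gene]).iloc[0]
        if np.isnan(cv):
            logger.info("dataset %s: CV of %s undefined; excluded", ds.id, gene)
            continue
        if cv >= min_cv:
            kept.append(ds)
    return DatasetCollection(kept, namespace=collection.namespace)


def write_collection(collection: DatasetCollection, out_dir: str | Path) -> None:
    """Write each matrix as TSV plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ds in collection:
        fname = f"{ds.id}.tsv"
        ds.values.to_csv(out / fname, sep="\t")
        manifest.append(
            {"id": ds.id, "platform": ds.platform, "file": fname,
             "n_genes": len(ds.genes), "n_samples": ds.n_samples}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_collection(in_dir: str | Path, min_samples: int = MIN_SAMPLES) -> DatasetCollection:
    """Load a collection written by :func:`write_collection`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    datasets = [
        read_expression_table(
            in_dir / rec["file"], dataset_id=rec["id"],
            platform=rec.get("platform", ""), min_samples=min_samples,
        )
        for rec in manifest
    ]
    return DatasetCollection(datasets)
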