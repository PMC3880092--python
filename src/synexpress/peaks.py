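"""ChIP-seq peak integration: consistency merging, TSS annotation, chromatin states.

Peaks are genomic intervals in 0-based half-open coordinates (BED
convention).  Peaks observed reproducibly across time points are merged where
all replicate sets share at least one common base; merged peaks are assigned
to genes whose transcription start site lies within a +/- 5 kb window of the
peak center; bound-gene sets are tested for over-representation of a target
annotation; and overlap with histone-mark / pioneer-factor peaks in each
condition classifies each region as an active, poised or latent enhancer,
optionally recording whether a stimulus-induced mark gain requires the factor
under study (absent in knockout cells).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .enrichment import hypergeometric_p

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "name", "source"]

#: universe of unique annotated gene symbols used for bound-gene enrichment
DEFAULT_UNIVERSE_SIZE = 23_563


def _empty_peaks() -> pd.DataFrame:
    return pd.DataFrame(columns=PEAK_COLUMNS)


def read_bed(path: str | Path, source: str = "") -> pd.DataFrame:
    """Read a BED3+ file into a peak table (0-based, half-open intervals).

    Malformed records (too few fields, non-numeric or inverted coordinates)
    are logged and skipped.
    """
    rows = []
    n_bad = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except (IndexError, ValueError):
            n_bad += 1
            logger.warning("%s line %d: malformed BED record skipped", path, ln)
            continue
        if start >= end or not chrom:
            n_bad += 1
            logger.warning("%s line %d: invalid interval [%s, %s) skipped", path, ln, fields[1], fields[2])
            continue
        name = fields[3] if len(fields) > 3 else f"peak_{ln}"
        rows.append((chrom, start, end, name, source or Path(path).stem))
    if n_bad:
        logger.info("%s: skipped %d malformed records", path, n_bad)
    if not rows:
        return _empty_peaks()
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read gene models from GFF3 (or BED6) into (symbol, chrom, strand, tss).

    The TSS is strand-aware and 0-based: for a GFF3 gene at 1-based
    ``start..end`` it is ``start - 1`` on "+" and ``end - 1`` on "-"; for a
    BED record it is ``start`` on "+" and ``end - 1`` on "-".
    """
    path = Path(path)
    rows = []
    if path.suffix.lower() in {".gff", ".gff3"}:
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            start, end, strand = int(f[3]), int(f[4]), f[6]
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            symbol = attrs.get("Name") or attrs.get("ID") or f"{f[0]}:{start}"
            tss = start - 1 if strand == "+" else end - 1
            rows.append((symbol, f[0], strand, tss))
    else:
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            start, end, strand = int(f[1]), int(f[2]), f[5] if len(f) > 5 else "+"
            symbol = f[3] if len(f) > 3 else f"{f[0]}:{start}"
            tss = start if strand == "+" else end - 1
            rows.append((symbol, f[0], strand, tss))
    models = pd.DataFrame(rows, columns=["symbol", "chrom", "strand", "tss"])
    if models["symbol"].duplicated().any():
        dups = models.loc[models["symbol"].duplicated(), "symbol"].tolist()
        raise ValueError(f"duplicate gene symbols in {path}: {dups[:5]}")
    return models


def _coverage(peaks: pd.DataFrame, chrom: str) -> list[tuple[int, int]]:
    """Merged (union) intervals covered by any peak of one chromosome."""
    sub = peaks[peaks["chrom"] == chrom].sort_values("start")
    merged: list[tuple[int, int]] = []
    for start, end in zip(sub["start"], sub["end"]):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def consistent_peaks(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge peaks observed consistently in every input set.

    A region is retained where one peak from *each* input set covers a common
    base (mutual overlap, not pairwise chaining); the output interval is the
    union span of all contributing peaks, so touching consistent regions
    coalesce into the "merged coordinates" of the reproducible peak.
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least 2 peak sets")
    if any(len(p) == 0 for p in peak_sets):
        return _empty_peaks()
    chroms = set.intersection(*(set(p["chrom"]) for p in peak_sets))
    rows = []
    for chrom in sorted(chroms):
        common = _coverage(peak_sets[0], chrom)
        for peaks in peak_sets[1:]:
            common = _intersect(common, _coverage(peaks, chrom))
            if not common:
                break
        if not common:
            continue
        # expand each common-base region to the union span of contributing peaks
        all_peaks = pd.concat(
            [p[p["chrom"] == chrom] for p in peak_sets], ignore_index=True
        )
        spans = []
        for lo, hi in common:
            touching = all_peaks[(all_peaks["start"] < hi) & (all_peaks["end"] > lo)]
            spans.append((int(touching["start"].min()), int(touching["end"].max())))
        # union spans may themselves overlap after expansion: merge them
        spans.sort()
        merged: list[list[int]] = []
        for lo, hi in spans:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for i, (lo, hi) in enumerate(merged, 1):
            rows.append((chrom, lo, hi, f"{chrom}_consistent_{i}", "consistent"))
    if not rows:
        return _empty_peaks()
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def annotate_peaks_to_tss(
    peaks: pd.DataFrame,
    models: pd.DataFrame,
    window: int = 5000,
) -> pd.DataFrame:
    """Assign peaks to genes whose TSS lies within ``window`` bp of the peak center.

    The peak center is ``floor((start + end) / 2)`` and the window predicate is
    inclusive (``|center - tss| <= window``).  Peaks may hit several genes and
    genes may collect several peaks; the signed distance is reported 5'->3' on
    the gene's strand.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    rows = []
    by_chrom = {c: g for c, g in models.groupby("chrom")}
    for _, peak in peaks.iterrows():
        genes = by_chrom.get(peak["chrom"])
        if genes is None:
            continue
        center = (int(peak["start"]) + int(peak["end"])) // 2
        delta = center - genes["tss"].to_numpy()
        within = np.abs(delta) <= window
        for sym, strand, d in zip(
            genes.loc[within, "symbol"], genes.loc[within, "strand"], delta[within]
        ):
            signed = int(d) if strand == "+" else -int(d)
            rows.append((peak["name"], peak["chrom"], center, sym, signed))
    return pd.DataFrame(rows, columns=["peak", "chrom", "center", "gene", "distance"])


def bound_genes(annotation: pd.DataFrame) -> set[str]:
    """Unique genes with at least one assigned peak."""
    return set(annotation["gene"])


def bound_gene_enrichment(
    bound: Iterable[str],
    target_set: Iterable[str],
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> dict[str, float]:
    """Hypergeometric over-representation of a target annotation among bound genes."""
    bound = set(bound)
    target = set(target_set)
    k = len(bound & target)
    n, K, N = len(bound), len(target), universe_size
    return {"k": k, "n": n, "K": K, "N": N, "p": hypergeometric_p(k, n, K, N)}


def overlap_flags(
    regions: pd.DataFrame,
    mark_peak_sets: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Boolean overlap flag of each region with each mark/condition peak set.

    A flag is true iff the region shares >= 1 base with any peak of that set
    (half-open intervals: touching endpoints do not overlap).
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    for key, peaks in mark_peak_sets.items():
        per_chrom: dict[str, IntervalTree] = {}
        for chrom, grp in peaks.groupby("chrom"):
            per_chrom[chrom] = IntervalTree.from_tuples(
                zip(grp["start"], grp["end"])
            )
        trees[key] = per_chrom
    flags = pd.DataFrame(
        False, index=regions["name"], columns=list(mark_peak_sets)
    )
    for _, region in regions.iterrows():
        for key in mark_peak_sets:
            tree = trees[key].get(region["chrom"])
            if tree is not None and tree.overlap(region["start"], region["end"]):
                flags.loc[region["name"], key] = True
    return flags


def classify_chromatin_state(
    wt_pre: Mapping[str, bool],
    wt_post: Mapping[str, bool],
    ko_pre: Mapping[str, bool] | None = None,
    ko_post: Mapping[str, bool] | None = None,
    marks: tuple[str, str, str] = ("H3K4me1", "H3K27ac", "Pu1"),
) -> tuple[str, bool | None]:
    """Enhancer-state call for one region from its mark flags.

    Flag dicts map mark names to overlap booleans before (``pre``) and after
    (``post``) stimulation.  Rule order (mutually exclusive): a region with
    pre-existing H3K27ac is ``active``; otherwise pre-existing H3K4me1 makes
    it ``poised`` (``poised_activated`` when H3K27ac appears post-stimulus);
    otherwise a region devoid of all three marks pre-stimulus that gains
    H3K4me1 is ``latent``; anything else is ``other``.

    ``stat6_dependent_gain`` is true when some mark is gained post-stimulus in
    wild-type cells but absent post-stimulus in knockout cells; it is None
    when knockout flags are not supplied.
    """
    me1, ac, pioneer = marks
    for flags, which in ((wt_pre, "wt_pre"), (wt_post, "wt_post")):
        missing = {me1, ac, pioneer} - set(flags)
        if missing:
            raise ValueError(f"{which} flags missing marks: {sorted(missing)}")
    if wt_pre[ac]:
        state = "active"
    elif wt_pre[me1]:
        state = "poised_activated" if wt_post[ac] else "poised"
    elif not (wt_pre[me1] or wt_pre[ac] or wt_pre[pioneer]) and wt_post[me1]:
        state = "latent"
    else:
        state = "other"
    dependent: bool | None = None
    if ko_post is not None:
        dependent = any(
            (not wt_pre[m]) and wt_post[m] and not ko_post[m]
            for m in (me1, ac, pioneer)
        )
    return state, dependent


def classify_regions(
    flags: pd.DataFrame,
    marks: tuple[str, str, str] = ("H3K4me1", "H3K27ac", "Pu1"),
    wt_pre: str = "WT",
    wt_post: str = "WT_IL4",
    ko_pre: str = "KO",
    ko_post: str = "KO_IL4",
) -> pd.DataFrame:
    """Vector wrapper over :func:`classify_chromatin_state`.

    ``flags`` columns are "<mark>:<condition>" as produced by
    :func:`overlap_flags` over a mark x condition design.
    """
    def cond_flags(row: pd.Series, cond: str) -> dict[str, bool]:
        return {m: bool(row.get(f"{m}:{cond}", False)) for m in marks}

    out = []
    have_ko = any(col.endswith(f":{ko_post}") for col in flags.columns)
    for name, row in flags.iterrows():
        state, dep = classify_chromatin_state(
            cond_flags(row, wt_pre),
            cond_flags(row, wt_post),
            cond_flags(row, ko_pre) if have_ko else None,
            cond_flags(row, ko_post) if have_ko else None,
            marks=marks,
        )
        out.append((name, state, dep))
    return pd.DataFrame(out, columns=["region", "state", "stat6_dependent_gain"]).set_index(
        "region"
    )
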