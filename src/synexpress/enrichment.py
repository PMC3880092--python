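"""Gene-set statistics: hypergeometric over-representation and pre-ranked GSEA.

Two complementary set statistics are provided.  The hypergeometric test asks
whether a fixed study list (e.g. a candidate regulator's 500 strongest
correlators) contains more members of an annotation term than expected from
drawing the list at random from the universe.  The pre-ranked GSEA running
sum is the cutoff-free counterpart: it walks down a ranked gene list,
stepping up at members of the set (weighted by |score|^w) and down at
non-members, and reports the signed extreme of this walk as the enrichment
score together with the "leading edge" of set members up to the extreme.
Significance of the running-sum statistic is assessed by a gene-set
permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe of measurable symbols."""

    sets: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("duplicate set names")
        self.sets = {name: set(m) & self.universe for name, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GseaResult:
    """Outcome of a pre-ranked running-sum enrichment test for one gene set."""

    set_name: str
    es: float
    peak_position: int  # 1-based rank of the running-sum extreme
    leading_edge: list[str]
    weight_exponent: float
    nominal_p: float | None = None
    n_permutations: int = 0


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, members...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        sets[name] = set(members)
        descriptions[name] = desc
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets, set(universe), descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in collection.sets:
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(collection.sets[name])]))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_p(count: int, study_size: int, set_size: int, universe_size: int) -> float:
    """Upper-tail probability P(X >= count) for X ~ Hypergeom(N, K, n).

    ``count`` successes observed in a study list of ``study_size`` drawn from a
    universe of ``universe_size`` containing ``set_size`` marked genes.
    """
    k, n, K, N = count, study_size, set_size, universe_size
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts (k={k}, n={n}, K={K}, N={N})")
    if k == 0:
        return 1.0
    # survival function in log space for numerical stability at extreme tails
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def enrich_terms(study: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of every term in a study gene list.

    Returns one row per term with at least one study member, sorted by p
    ascending (ties by term name), with columns ``term``, ``ExpCount``,
    ``Count``, ``Size``, ``p``.
    """
    study_set = set(study)
    dropped = study_set - collection.universe
    if dropped:
        logger.info("dropping %d study genes outside the universe", len(dropped))
    study_set &= collection.universe
    if not study_set:
        raise ValueError("study list is empty after restriction to the universe")
    n, N = len(study_set), len(collection.universe)
    rows = []
    for term, members in collection.sets.items():
        K = len(members)
        k = len(study_set & members)
        if k == 0:
            continue
        rows.append(
            {
                "term": term,
                "ExpCount": n * K / N,
                "Count": k,
                "Size": K,
                "p": hypergeometric_p(k, n, K, N),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "ExpCount", "Count", "Size", "p"])
    return df.sort_values(["p", "term"]).reset_index(drop=True)


def screen_regulators_for_term(
    profiles: Mapping[str, pd.Series],
    collection: GeneSetCollection,
    keywords: Iterable[str],
    top_n: int = 500,
    p_cut: float = 0.001,
) -> dict[str, pd.DataFrame]:
    """Keep candidates whose strongest correlators are enriched for keyword terms.

    For each candidate's ranked correlation profile, the ``top_n`` most
    correlated genes are tested for term over-representation; the candidate is
    retained when any term whose name contains a keyword (case-insensitive
    substring) reaches ``p <= p_cut``.  Returns candidate -> matching rows.
    """
    kws = [k.lower() for k in keywords]
    hits: dict[str, pd.DataFrame] = {}
    for candidate, ranked in profiles.items():
        if len(ranked) < top_n:
            raise ValueError(f"profile for {candidate} has fewer than {top_n} genes")
        study = list(ranked.index[:top_n])
        table = enrich_terms(study, collection)
        mask = table["term"].str.lower().apply(lambda t: any(k in t for k in kws))
        matching = table[mask & (table["p"] <= p_cut)]
        if len(matching):
            hits[candidate] = matching.reset_index(drop=True)
    return hits


def cross_species_intersect(
    hits_a: Iterable[str],
    hits_b: Iterable[str],
    symbol_map: Mapping[str, str] | None = None,
) -> list[str]:
    """Candidates scoring positive in both species' screens.

    Default mapping is case-insensitive symbol identity (mouse Stat6 vs human
    STAT6); an explicit a->b ``symbol_map`` overrides it.  Output preserves
    the order and casing of ``hits_a``.
    """
    if symbol_map is not None:
        b_keys = set(hits_b)
        return [a for a in hits_a if symbol_map.get(a) in b_keys]
    b_fold = {b.lower() for b in hits_b}
    return [a for a in hits_a if a.lower() in b_fold]


def _running_sum(
    scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float
) -> np.ndarray:
    n = len(scores)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a proper subset of the ranked list")
    weights = np.abs(scores) ** weight_exponent
    increments = np.where(hit_mask, weights, 0.0)
    total = increments.sum()
    if total == 0.0:
        # all hit scores are exactly zero: fall back to equal weights
        increments = hit_mask.astype(float)
        total = increments.sum()
    steps = increments / total - (~hit_mask) / (n - n_hits)
    return np.cumsum(steps)


def gsea_preranked(
    ranked: pd.Series,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
    set_name: str = "",
) -> GseaResult:
    """Signed running-sum enrichment score of a gene set along a ranked list.

    ``ranked`` maps genes to scores in descending order.  The walk steps up by
    |score|^w (normalized over the set's hits) at set members and down by
    1/(N - Nh) at non-members; ES is the value at the position of maximum
    absolute deviation.  The leading edge contains the set members at or
    before a positive peak (at or after a negative one).
    """
    scores = ranked.to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("ranked scores must be finite")
    if np.any(np.diff(scores) > 0):
        raise ValueError("ranked list must be sorted in descending score order")
    members = set(gene_set)
    hit_mask = ranked.index.isin(members)
    if not hit_mask.any():
        raise ValueError("gene set shares no genes with the ranked list")
    walk = _running_sum(scores, hit_mask, weight_exponent)
    peak = int(np.argmax(np.abs(walk)))
    es = float(walk[peak])
    genes = np.asarray(ranked.index)
    if es >= 0:
        leading = list(genes[: peak + 1][hit_mask[: peak + 1]])
    else:
        leading = list(genes[peak:][hit_mask[peak:]])
    return GseaResult(
        set_name=set_name,
        es=es,
        peak_position=peak + 1,
        leading_edge=leading,
        weight_exponent=weight_exponent,
    )


def gsea_null(
    ranked: pd.Series,
    set_size: int,
    observed_es: float,
    n_permutations: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> float:
    """Gene-set permutation nominal p for an observed enrichment score.

    Random sets of ``set_size`` genes are drawn from the ranked list; the
    nominal p is the fraction of same-signed null scores whose magnitude
    reaches the observed one, among the same-signed null scores (the standard
    pre-ranked convention; 0.0 when the observed ES exceeds every null).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    scores = ranked.to_numpy(dtype=float)
    n = len(scores)
    rng = np.random.default_rng(seed)
    null_es = np.empty(n_permutations)
    hit_mask = np.zeros(n, dtype=bool)
    for i in range(n_permutations):
        hit_mask[:] = False
        hit_mask[rng.choice(n, size=set_size, replace=False)] = True
        walk = _running_sum(scores, hit_mask, weight_exponent)
        null_es[i] = walk[np.argmax(np.abs(walk))]
    same_sign = null_es >= 0 if observed_es >= 0 else null_es < 0
    denom = int(same_sign.sum())
    if denom == 0:
        return 0.0
    extreme = same_sign & (np.abs(null_es) >= abs(observed_es))
    return float(extreme.sum() / denom)


def gsea(
    ranked: pd.Series,
    gene_set: Iterable[str],
    set_name: str = "",
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Run :func:`gsea_preranked` and attach a permutation nominal p."""
    result = gsea_preranked(ranked, gene_set, weight_exponent, set_name)
    set_size = int(ranked.index.isin(set(gene_set)).sum())
    result.nominal_p = gsea_null(
        ranked, set_size, result.es, n_permutations, seed, weight_exponent
    )
    result.n_permutations = n_permutations
    return result
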