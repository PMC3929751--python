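"""Empirical TFBS enrichment and co-occurrence clustering.

The statistical core of the pipeline: the observed number of binding
sites for each factor in a gene list is compared with the numbers found
in many randomly resampled gene lists of the same size drawn from the
promoter universe, giving a one-sided empirical p-value with the +1
finite-sample correction.  Separately, promoters are searched for
heterotypic clusters: two or three motif hits whose pairwise start
distances all fall within a fixed window (50 bp by default).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .motif_scan import MotifHit

DEFAULT_WINDOW = 50
DEFAULT_RESAMPLES = 100_000


@dataclasses.dataclass
class EnrichmentParams:
    n_resamples: int = DEFAULT_RESAMPLES
    statistic: str = "total_hits"  # or "genes_with_hit"
    seed: int = 0

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.statistic not in ("total_hits", "genes_with_hit"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclasses.dataclass
class EnrichmentResult:
    factor_name: str
    observed: int
    p_emp: float
    n_resamples: int
    null_mean: float
    rank: Optional[int] = None


@dataclasses.dataclass(frozen=True)
class CooccurrenceCluster:
    gene: str
    members: tuple  # 2 or 3 MotifHits, ordered by start
    kind: str       # "triple_distinct" or "pair"

    @property
    def factors(self) -> tuple:
        return tuple(h.factor_name for h in self.members)

    @property
    def span(self) -> int:
        starts = [h.start for h in self.members]
        ends = [h.start + len(h.matched_word) for h in self.members]
        return max(ends) - min(starts)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _null_statistics(
    counts: np.ndarray, list_size: int, n_resamples: int, rng: np.random.Generator,
    genes_with_hit: bool, chunk: int = 2000,
) -> np.ndarray:
    """Statistic per resampled list; lists are drawn uniformly without
    replacement, independently across resamples.

    Sampling is vectorised: within a chunk, each resample ranks a row of
    iid uniforms and the ``list_size`` smallest keys form the list.
    """
    universe = counts.shape[0]
    per_gene = (counts > 0).astype(counts.dtype) if genes_with_hit else counts
    out = np.empty((n_resamples, counts.shape[1]))
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        keys = rng.random((m, universe))
        idx = np.argpartition(keys, list_size - 1, axis=1)[:, :list_size]
        out[done : done + m] = per_gene[idx].sum(axis=1)
        done += m
    return out


def empirical_enrichment(
    gene_list: Sequence[str],
    universe_hits: pd.DataFrame,
    params: EnrichmentParams,
) -> dict[str, EnrichmentResult]:
    """Empirical enrichment p per factor for ``gene_list``.

    ``universe_hits`` is a genes x factors hit-count table covering the
    whole resampling universe (every gene with a promoter record).
    p_emp = (1 + #{null >= observed}) / (R + 1), one-sided.
    """
    gene_list = list(gene_list)
    if not set(gene_list) <= set(universe_hits.index):
        missing = sorted(set(gene_list) - set(universe_hits.index))
        raise ValueError(f"gene list members outside the universe: {missing[:5]}")
    if len(gene_list) > len(universe_hits):
        raise ValueError("list_size exceeds the universe size")
    if len(set(gene_list)) != len(gene_list):
        raise ValueError("gene list contains duplicates")

    counts = universe_hits.to_numpy(dtype=float)
    genes_with_hit = params.statistic == "genes_with_hit"
    obs_tab = universe_hits.loc[gene_list].to_numpy(dtype=float)
    observed = ((obs_tab > 0).sum(axis=0) if genes_with_hit else obs_tab.sum(axis=0))

    rng = np.random.default_rng(params.seed)
    null = _null_statistics(
        counts, len(gene_list), params.n_resamples, rng, genes_with_hit
    )
    exceed = (null >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (params.n_resamples + 1.0)
    results = {}
    for j, factor in enumerate(universe_hits.columns):
        results[factor] = EnrichmentResult(
            factor_name=str(factor),
            observed=int(observed[j]),
            p_emp=float(p[j]),
            n_resamples=params.n_resamples,
            null_mean=float(null[:, j].mean()),
        )
    return results


def rank_enriched(
    results: dict[str, EnrichmentResult], top_k: int = 100
) -> pd.DataFrame:
    """Rank factors by ascending p_emp, breaking ties by descending
    observed count then factor name; truncate to ``top_k``."""
    ordered = sorted(
        results.values(), key=lambda r: (r.p_emp, -r.observed, r.factor_name)
    )
    rows = []
    for rank, r in enumerate(ordered[:top_k], start=1):
        r.rank = rank
        rows.append(
            {
                "rank": rank,
                "factor": r.factor_name,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "p_emp": r.p_emp,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------

def _within(hits: Sequence[MotifHit], window: int) -> bool:
    starts = [h.start for h in hits]
    return max(starts) - min(starts) <= window


def find_cooccurrence(
    hits_by_gene: dict[str, list[MotifHit]],
    factor_trio: Sequence[str],
    window: int = DEFAULT_WINDOW,
    known_factors: Optional[Sequence[str]] = None,
) -> list[CooccurrenceCluster]:
    """Enumerate all qualifying clusters of the trio's hits per gene.

    Triples need three hits of three distinct trio factors with all
    pairwise start distances <= ``window``; pairs are any two trio hits
    (same or different factor) within the window.  Strand is ignored for
    distance (starts are forward-orientation).  Reporting is maximal:
    every qualifying combination is returned, ordered by gene then
    member starts.  When the panel of scanned factors is supplied via
    ``known_factors``, a trio member outside it raises ``KeyError``.
    """
    trio = list(factor_trio)
    if len(trio) != 3:
        raise ValueError("factor_trio must name exactly 3 factors")
    if known_factors is not None:
        unknown = set(trio) - set(known_factors)
        if unknown:
            raise KeyError(f"unknown factors in trio: {sorted(unknown)}")

    clusters: list[CooccurrenceCluster] = []
    for gene in sorted(hits_by_gene):
        hits = sorted(
            (h for h in hits_by_gene[gene] if h.factor_name in trio),
            key=lambda h: (h.start, h.strand, h.factor_name),
        )
        for a, b in itertools.combinations(hits, 2):
            if _within((a, b), window):
                clusters.append(CooccurrenceCluster(gene, (a, b), "pair"))
        for a, b, c in itertools.combinations(hits, 3):
            if len({a.factor_name, b.factor_name, c.factor_name}) == 3 and _within(
                (a, b, c), window
            ):
                clusters.append(CooccurrenceCluster(gene, (a, b, c), "triple_distinct"))
    return clusters


def presence_summary(
    clusters: Sequence[CooccurrenceCluster], gene_list: Sequence[str]
) -> tuple[pd.DataFrame, float]:
    """Per-gene cluster summary over ``gene_list`` and the headline
    fraction of listed genes carrying at least one distinct-factor triple."""
    by_gene: dict[str, list[CooccurrenceCluster]] = {}
    for c in clusters:
        by_gene.setdefault(c.gene, []).append(c)
    rows = []
    for gene in gene_list:
        cs = by_gene.get(gene, [])
        triples = [c for c in cs if c.kind == "triple_distinct"]
        rows.append(
            {
                "gene": gene,
                "has_triple": bool(triples),
                "n_triples": len(triples),
                "n_pairs": sum(1 for c in cs if c.kind == "pair"),
                "triple_starts": ";".join(
                    ",".join(str(h.start) for h in c.members) for c in triples
                ),
            }
        )
    table = pd.DataFrame(rows)
    fraction = float(table["has_triple"].mean()) if len(table) else 0.0
    return table, fraction
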