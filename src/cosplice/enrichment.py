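"""Hypergeometric enrichment validation of mined clusters.

A cluster's exons are collapsed to their distinct host genes and tested
against named gene-set collections (GO terms, splicing-factor targets,
ChIP-seq target sets, protein complexes) with one-sided hypergeometric
tests at a per-collection p-value threshold.  Biological signal is
quantified as a fold ratio: the percentage of real clusters enriched in at
least one term divided by the same percentage for random size-matched gene
sets drawn from the collection's universe.  A co-expression comparison
(mean pairwise expression correlation of the host genes) and a
multi-cluster exon membership summary complete the validation layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .miner import FrequentCoSplicingCluster

__all__ = [
    "AnnotationCollection",
    "EnrichmentResult",
    "hypergeometric_pvalue",
    "enrich_clusters",
    "fold_ratio",
    "baseline_fold_ratio",
    "mean_pairwise_profile_correlation",
    "multi_membership_fraction",
    "read_gmt",
    "read_gene_list",
]

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCollection:
    """Named gene sets over a stated gene universe.

    ``p_threshold`` is the collection's raw significance cut (e.g. 1e-4
    for GO, 0.05 for splicing-factor targets); ``max_term_size`` drops
    overly general terms (e.g. GO terms annotating > 300 genes) before
    testing.
    """

    name: str
    terms: dict[str, frozenset[str]]
    universe: frozenset[str]
    p_threshold: float = 0.05
    max_term_size: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        self.universe = frozenset(self.universe)
        for term, genes in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} has genes outside the universe")

    def testable_terms(self) -> dict[str, frozenset[str]]:
        if self.max_term_size is None:
            return dict(self.terms)
        return {
            t: g for t, g in self.terms.items() if len(g) <= self.max_term_size
        }


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_id: str
    term_id: str
    overlap: int
    cluster_size: int
    term_size: int
    p_value: float
    enriched: bool


def hypergeometric_pvalue(
    overlap: int, term_size: int, cluster_size: int, universe_size: int
) -> float:
    """P(X >= overlap) drawing ``cluster_size`` genes without replacement
    from a universe containing ``term_size`` term genes."""
    if not (
        0 <= overlap <= min(term_size, cluster_size)
        and max(term_size, cluster_size) <= universe_size
    ):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, term={term_size}, "
            f"cluster={cluster_size}, universe={universe_size}"
        )
    return float(hypergeom.sf(overlap - 1, universe_size, term_size, cluster_size))


def _cluster_genes(
    cluster: FrequentCoSplicingCluster,
    exon_to_gene: Mapping[str, str],
    universe: frozenset[str],
) -> frozenset[str]:
    genes = set()
    for exon in cluster.exon_ids:
        gene = exon_to_gene.get(exon)
        if gene is None:
            logger.warning("exon %s has no host-gene mapping; skipped", exon)
            continue
        genes.add(gene)
    return frozenset(genes) & universe


def enrich_clusters(
    clusters: Sequence[FrequentCoSplicingCluster],
    exon_to_gene: Mapping[str, str],
    collection: AnnotationCollection,
    cluster_ids: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """Test every cluster's host-gene set against every testable term.

    Duplicate host genes within a cluster count once, and genes outside
    the collection's universe are ignored (the hypergeometric draw is from
    that universe).  A cluster is "homogeneous" for the collection when
    any of its terms passes the threshold.
    """
    terms = collection.testable_terms()
    universe_size = len(collection.universe)
    if cluster_ids is None:
        cluster_ids = [f"cluster{j:04d}" for j in range(len(clusters))]
    results: list[EnrichmentResult] = []
    for cid, cluster in zip(cluster_ids, clusters):
        genes = _cluster_genes(cluster, exon_to_gene, collection.universe)
        if not genes:
            continue
        for term_id, term_genes in terms.items():
            overlap = len(genes & term_genes)
            p = hypergeometric_pvalue(
                overlap, len(term_genes), len(genes), universe_size
            )
            results.append(
                EnrichmentResult(
                    cluster_id=cid,
                    term_id=term_id,
                    overlap=overlap,
                    cluster_size=len(genes),
                    term_size=len(term_genes),
                    p_value=p,
                    enriched=p < collection.p_threshold,
                )
            )
    return results


def _gene_set_homogeneous(
    genes: frozenset[str],
    terms: Mapping[str, frozenset[str]],
    universe_size: int,
    p_threshold: float,
) -> bool:
    for term_genes in terms.values():
        overlap = len(genes & term_genes)
        if overlap == 0:
            continue
        p = hypergeometric_pvalue(overlap, len(term_genes), len(genes), universe_size)
        if p < p_threshold:
            return True
    return False


def fold_ratio(pct_real: float, pct_random: float) -> float:
    """Percentage of enriched real clusters over percentage of enriched
    random clusters; raises on a zero random rate (undefined ratio)."""
    if pct_random == 0:
        raise ZeroDivisionError("fold ratio undefined: no random cluster enriched")
    return pct_real / pct_random


def baseline_fold_ratio(
    clusters: Sequence[FrequentCoSplicingCluster],
    exon_to_gene: Mapping[str, str],
    collection: AnnotationCollection,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float | None]:
    """(pct_real, pct_random, fold) against size-matched random gene sets.

    For every real cluster, ``reps`` random gene sets of the same size are
    drawn uniformly without replacement from the collection's universe;
    the random percentage is the homogeneity rate over all draws.  Fold is
    None when no random set is enriched.  Percentages are on the 0-100
    scale.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not collection.universe:
        raise ValueError("empty annotation universe")
    terms = collection.testable_terms()
    universe = sorted(collection.universe)
    universe_size = len(universe)
    rng = np.random.default_rng(seed)

    sizes = []
    n_real_enriched = 0
    for cluster in clusters:
        genes = _cluster_genes(cluster, exon_to_gene, collection.universe)
        if not genes:
            continue
        sizes.append(len(genes))
        n_real_enriched += int(
            _gene_set_homogeneous(genes, terms, universe_size, collection.p_threshold)
        )
    if not sizes:
        raise ValueError("no cluster maps any gene into the universe")
    pct_real = 100.0 * n_real_enriched / len(sizes)

    n_random_enriched = 0
    n_random = 0
    for size in sizes:
        for _ in range(reps):
            draw = frozenset(
                universe[i] for i in rng.choice(universe_size, size=size, replace=False)
            )
            n_random += 1
            n_random_enriched += int(
                _gene_set_homogeneous(
                    draw, terms, universe_size, collection.p_threshold
                )
            )
    pct_random = 100.0 * n_random_enriched / n_random
    fold = None if pct_random == 0 else pct_real / pct_random
    return pct_real, pct_random, fold


def mean_pairwise_profile_correlation(
    gene_ids: Iterable[str], expression: pd.DataFrame
) -> float:
    """Mean pairwise-complete Pearson correlation between the expression
    profiles (rows of ``expression``) of the given genes.

    Clusters whose host genes average <= 0.2 are the ones invisible to
    co-expression analysis.
    """
    genes = [g for g in gene_ids if g in expression.index]
    if len(genes) < 2:
        raise ValueError("need >= 2 genes with expression profiles")
    corr = expression.loc[genes].T.corr().to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    vals = corr[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined pairwise correlations")
    return float(vals.mean())


def multi_membership_fraction(
    clusters: Sequence[FrequentCoSplicingCluster],
    enrichments: Sequence[EnrichmentResult],
    min_recurrence: int = 3,
    cluster_ids: Sequence[str] | None = None,
) -> float:
    """Fraction of exons belonging to >= 2 clusters with different
    enriched-term sets.

    Clusters are first filtered to the given minimum recurrence; the
    denominator is the number of distinct exons appearing in any
    qualifying cluster.  Two clusters count as functionally different when
    their sets of enriched terms are not identical (an exon shared only by
    clusters enriched in exactly the same terms does not count).
    """
    if cluster_ids is None:
        cluster_ids = [f"cluster{j:04d}" for j in range(len(clusters))]
    keep = [
        (cid, c)
        for cid, c in zip(cluster_ids, clusters)
        if c.recurrence >= min_recurrence
    ]
    if not keep:
        return 0.0
    enriched_terms: dict[str, set[str]] = {cid: set() for cid, _ in keep}
    for res in enrichments:
        if res.enriched and res.cluster_id in enriched_terms:
            enriched_terms[res.cluster_id].add(res.term_id)
    exon_clusters: dict[str, list[str]] = {}
    for cid, cluster in keep:
        for exon in cluster.exon_ids:
            exon_clusters.setdefault(exon, []).append(cid)
    n_multi = 0
    for exon, cids in exon_clusters.items():
        term_sets = [frozenset(enriched_terms[c]) for c in cids]
        if len(cids) >= 2 and len(set(term_sets)) >= 2:
            n_multi += 1
    return n_multi / len(exon_clusters)


# ---------------------------------------------------------------------------
# GMT and universe files


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file: term_id <TAB> description <TAB> gene ids..."""
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = frozenset(g for g in parts[2:] if g)
    return terms


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a universe file: one gene id per line."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
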