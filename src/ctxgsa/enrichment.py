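"""Per-cluster pathway over-representation analysis.

Each gene cluster is tested against every pathway in a library with the
one-sided hypergeometric tail (the classical over-representation test):
the probability of drawing at least the observed overlap when
``cluster_size`` genes are sampled without replacement from a background
universe containing ``pathway_size`` pathway members.  Raw p-values are
thresholded at a strict significance cutoff (default alpha = 0.001);
Benjamini-Hochberg adjusted values are reported alongside for
transparency but are not used for filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

from scipy.stats import hypergeom

from .core_io import PathwayLibrary

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001


@dataclass
class EnrichedTerm:
    """One significantly over-represented pathway for a cluster."""

    term: str
    overlap_genes: list[str]
    p_value: float
    overlap_count: int
    pathway_size: int
    cluster_size: int
    background_size: int
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")
        if self.overlap_count > min(self.pathway_size, self.cluster_size):
            raise ValueError("overlap exceeds pathway or cluster size")


def hypergeom_tail(
    overlap: int,
    cluster_size: int,
    pathway_size: int,
    background: int,
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(background, pathway_size, cluster_size).

    The upper tail of the hypergeometric distribution: the chance that a
    random draw of ``cluster_size`` genes from ``background`` genes, of
    which ``pathway_size`` belong to the pathway, shares at least
    ``overlap`` genes with the pathway.
    """
    if min(overlap, cluster_size, pathway_size) < 0 or background <= 0:
        raise ValueError("counts must be non-negative with positive background")
    if cluster_size > background or pathway_size > background:
        raise ValueError("cluster and pathway must fit inside the background")
    if overlap > min(cluster_size, pathway_size):
        raise ValueError(
            f"overlap {overlap} exceeds min(cluster {cluster_size}, pathway {pathway_size})"
        )
    # sf(k) = P(X > k), so P(X >= overlap) = sf(overlap - 1)
    return float(hypergeom.sf(overlap - 1, background, pathway_size, cluster_size))


def _bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, pvals[idx] * m / rank)
        adj[idx] = running
    return adj


def enrich_cluster(
    cluster: Iterable[str],
    library: PathwayLibrary,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichedTerm]:
    """Test a gene cluster against every library pathway.

    Returns the pathways with raw ``p < alpha``, sorted ascending by
    p-value with ties broken by term name.  The background defaults to the
    library's gene union (overridable via ``library.background_size``).
    Genes outside the background universe do not count toward the cluster
    size, so the test is conditioned on the annotated universe.
    """
    cluster_set = {g.strip().upper() for g in cluster if g.strip()}
    if not cluster_set:
        raise ValueError("cluster is empty")
    if len(library) == 0:
        raise ValueError("pathway library is empty")
    universe = library.gene_union()
    background = library.background_size or len(universe)
    in_universe = cluster_set & universe
    if not in_universe:
        logger.warning("cluster shares no genes with the library universe")
        return []
    cluster_size = len(in_universe)

    raw: list[tuple[str, list[str], float, int, int]] = []
    for term, genes in library.sets.items():
        members = set(genes)
        overlap = sorted(in_universe & members)
        p = hypergeom_tail(len(overlap), cluster_size, len(members), background)
        raw.append((term, overlap, p, len(overlap), len(members)))

    adjusted = _bh_adjust([r[2] for r in raw])
    results = [
        EnrichedTerm(
            term=term,
            overlap_genes=overlap,
            p_value=p,
            overlap_count=k,
            pathway_size=ps,
            cluster_size=cluster_size,
            background_size=background,
            adjusted_p=adj,
        )
        for (term, overlap, p, k, ps), adj in zip(raw, adjusted)
        if p < alpha
    ]
    results.sort(key=lambda t: (t.p_value, t.term))
    return results


class EnrichmentSource(Protocol):
    """Contract for remote enrichment services (Enrichr-like) or fixtures."""

    def enrich(self, genes: Sequence[str], db_name: str) -> list[dict]:
        """Return records with at least keys: term, p_value, overlap_genes."""
        ...


def fetch_enrichr(
    cluster: Iterable[str],
    db_name: str,
    adapter: EnrichmentSource,
    alpha: float = DEFAULT_ALPHA,
    background_size: int = 20_000,
) -> list[EnrichedTerm]:
    """Map adapter records into :class:`EnrichedTerm`, applying the same
    local alpha filter used for the built-in test."""
    genes = sorted({g.strip().upper() for g in cluster if g.strip()})
    if not genes:
        raise ValueError("cluster is empty")
    try:
        records = adapter.enrich(genes, db_name)
    except Exception as err:
        raise RuntimeError(
            f"enrichment source failed for db {db_name!r} on a {len(genes)}-gene cluster"
        ) from err
    results = []
    for rec in records:
        p = float(rec["p_value"])
        if p >= alpha:
            continue
        overlap = [g.strip().upper() for g in rec.get("overlap_genes", [])]
        results.append(
            EnrichedTerm(
                term=str(rec["term"]),
                overlap_genes=overlap,
                p_value=p,
                overlap_count=len(overlap),
                pathway_size=int(rec.get("pathway_size", max(len(overlap), 1))),
                cluster_size=len(genes),
                background_size=int(rec.get("background_size", background_size)),
                adjusted_p=rec.get("adjusted_p"),
            )
        )
    results.sort(key=lambda t: (t.p_value, t.term))
    return results
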