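"""End-to-end orchestration: network -> clusters -> enrichment -> LLM stages.

The pipeline is a pure function of its inputs and configuration when run
with the deterministic mock backends: re-running from the resolved config
reproduces the report bit-exactly.  Per-stage accounting (genes mapped,
clusters found, terms enriched, terms retained) is carried in the report,
since the method's point is producing fewer, contextually relevant outputs
rather than a long enrichment list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .core_io import ContextPair, GeneSet, PathwayLibrary, read_gene_list, read_gmt
from .enrichment import DEFAULT_ALPHA, EnrichedTerm, enrich_cluster
from .evaluation import (
    DEFAULT_THRESHOLDS,
    StubEncoder,
    harmonic_mean,
    similarity_matrix,
    threshold_sweep,
    topk_evaluate,
)
from .llm import LLMBackend, MockLLMBackend, screen_and_summarize
from .network import build_graph, edmot_partition

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run.

    The resolved config is serialized alongside every report so a run can
    be reproduced exactly.
    """

    genes_path: str
    gmt_path: str
    edges_path: str
    experimental_conditions: str
    research_objectives: str
    min_confidence: float = 0.05
    alpha: float = DEFAULT_ALPHA
    n_components: int = 2
    min_cluster_size: int = 5
    llm_backend: str = "mock"
    encoder: str = "stub"
    thresholds: list[float] = Field(default_factory=lambda: list(DEFAULT_THRESHOLDS))
    seed: int = 0
    output_dir: str = "."

    @field_validator("alpha")
    @classmethod
    def _alpha_in_range(cls, v: float) -> float:
        if not 0.0 < v <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {v}")
        return v

    @field_validator("min_confidence")
    @classmethod
    def _conf_in_range(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError(f"min_confidence must lie in [0, 1), got {v}")
        return v

    @field_validator("min_cluster_size", "n_components")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be >= 1")
        return v


@dataclass
class PipelineReport:
    """Structured result of a pipeline run."""

    config: dict
    counts: dict
    summaries: list[dict]
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "counts": self.counts,
            "summaries": self.summaries,
            "status": self.status,
        }


def make_backend(name: str) -> LLMBackend:
    if name == "mock":
        return MockLLMBackend()
    raise ValueError(f"unknown LLM backend {name!r}; configure a remote adapter explicitly")


def analyze(
    genes: GeneSet,
    library: PathwayLibrary,
    edges: pd.DataFrame,
    contexts: ContextPair,
    min_confidence: float = 0.05,
    alpha: float = DEFAULT_ALPHA,
    n_components: int = 2,
    min_cluster_size: int = 5,
    backend: LLMBackend | None = None,
    config: dict | None = None,
) -> PipelineReport:
    """Run the full analysis on in-memory objects.

    Stages: PPI graph construction, motif-aware clustering, per-cluster
    over-representation, then LLM screening and summarization per cluster.
    Clusters with no significant pathway, or whose pathways are all
    screened away, appear in the accounting but yield no summary row.
    """
    backend = backend or MockLLMBackend()
    net = build_graph(genes, edges, min_confidence=min_confidence)
    clustering = edmot_partition(
        net, n_components=n_components, min_cluster_size=min_cluster_size
    )
    counts = {
        "input_genes": len(genes),
        "network_nodes": len(net),
        "network_edges": net.n_edges,
        "clusters": clustering.n_clusters,
        "dropped_genes": len(clustering.dropped),
        "enriched_terms": 0,
        "retained_terms": 0,
        "removed_terms": 0,
        "summarized_clusters": 0,
    }
    summaries: list[dict] = []
    for cid, cluster in enumerate(clustering.clusters):
        terms = enrich_cluster(cluster, library, alpha=alpha)
        counts["enriched_terms"] += len(terms)
        if not terms:
            logger.info("cluster %d: no pathway passed alpha=%g", cid, alpha)
            continue
        summary = screen_and_summarize(terms, contexts, backend, cluster_id=cid)
        term_by_name: dict[str, EnrichedTerm] = {t.term: t for t in terms}
        if summary.pathway is None:
            counts["removed_terms"] += len(terms)
            logger.info("cluster %d: every pathway screened out", cid)
            continue
        counts["summarized_clusters"] += 1
        counts["retained_terms"] += len(terms)
        chosen = term_by_name.get(summary.pathway)
        summaries.append(
            {
                "cluster_id": cid,
                "cluster_size": len(cluster),
                "pathway": summary.pathway,
                "relevance_score": summary.relevance_score,
                "relevance_band": summary.relevance_band,
                "rationale": summary.rationale,
                "enriched_genes": chosen.overlap_genes if chosen else [],
                "p_value": chosen.p_value if chosen else None,
            }
        )
    summaries.sort(key=lambda s: (-s["relevance_score"], str(s["pathway"])))
    status = "ok" if summaries else "no cluster passed screening"
    return PipelineReport(
        config=config or {}, counts=counts, summaries=summaries, status=status
    )


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Load inputs named in the config, run :func:`analyze`, and write the
    report (JSON + TSV) plus the resolved config into the output directory."""
    from .core_io import write_report

    genes = read_gene_list(config.genes_path)
    library = read_gmt(config.gmt_path)
    edges = pd.read_csv(config.edges_path, sep="\t")
    contexts = ContextPair(
        experimental_conditions=config.experimental_conditions,
        research_objectives=config.research_objectives,
    )
    resolved = config.model_dump()
    report = analyze(
        genes,
        library,
        edges,
        contexts,
        min_confidence=config.min_confidence,
        alpha=config.alpha,
        n_components=config.n_components,
        min_cluster_size=config.min_cluster_size,
        backend=make_backend(config.llm_backend),
        config=resolved,
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(report, outdir / "report.json")
    (outdir / "config.json").write_text(json.dumps(resolved, indent=2, sort_keys=True) + "\n")
    return report


def evaluate_predictions(
    preds: Sequence[str],
    truths: Sequence[str],
    encoder=None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    topk: Sequence[int] = (),
) -> pd.DataFrame:
    """Threshold-sweep (and optional top-K) metric table for a prediction list."""
    encoder = encoder or StubEncoder()
    sim = similarity_matrix(list(preds), list(truths), encoder)
    rows = [
        {
            "threshold": m.threshold,
            "k": None,
            "hit": m.hit,
            "acc": m.acc,
            "harmonic": m.harmonic,
        }
        for m in threshold_sweep(sim, thresholds)
    ]
    for k in topk:
        m = topk_evaluate(list(preds), list(truths), encoder, k=k, threshold=thresholds[0])
        rows.append(
            {"threshold": m.threshold, "k": k, "hit": m.hit, "acc": m.acc, "harmonic": m.harmonic}
        )
    return pd.DataFrame(rows)
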