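"""Synthetic scenario generation: planted modules and contamination benchmarks.

Two generators make every pipeline stage testable offline:

* :func:`make_scenario` plants functional modules.  It samples a gene
  universe, a library of disjoint two-word pathways, and a DEG list that is
  the union of a few planted modules (each drawn, up to a stated noise
  fraction, from a distinct pathway) plus background noise genes.  PPI edges
  are Bernoulli: dense within modules (``p_in``) and sparse elsewhere
  (``p_out``), so motif-aware clustering can recover the planted structure.
  Context strings embed the planted pathway names verbatim — a test
  convenience that lets the deterministic mock language model succeed by
  construction, not a claim about real experimental contexts.

* :func:`contaminate` and :func:`make_contamination_benchmark` build the
  calibration negative control: curated gene sets with 0%, 50% and 100% of
  members replaced by random background genes.  Relevance scores assigned
  by the pipeline should fall as contamination rises, because enrichment
  overlap and contextual coherence both degrade.

All randomness flows through a single integer seed; regeneration with the
same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ContextPair, GeneSet, PathwayLibrary, write_gene_list, write_gmt
from .enrichment import DEFAULT_ALPHA, enrich_cluster
from .llm import LLMBackend, MockLLMBackend, NO_RELEVANT_PATHWAY, screen_and_summarize

# enough two-word combinations for the default library sizes; names built
# from disjoint token pairs so no pathway name shares tokens with another
_VOCAB = [
    "oxidative", "phosphorylation", "axon", "guidance", "apoptosis", "glycolysis",
    "adhesion", "migration", "angiogenesis", "inflammation", "proliferation",
    "autophagy", "chemotaxis", "differentiation", "senescence", "cytokine",
    "kinase", "receptor", "transcription", "translation", "splicing", "repair",
    "replication", "metabolism", "lipid", "sterol", "glutamine", "transport",
    "secretion", "endocytosis", "exocytosis", "ubiquitin", "proteasome",
    "mitotic", "spindle", "checkpoint", "complement", "coagulation",
    "interferon", "hypoxia", "folding", "ribosome", "biogenesis", "telomere",
    "maintenance", "chromatin", "remodeling", "methylation", "acetylation",
    "synapse", "myelination", "ossification", "fibrosis", "keratinization",
    "gluconeogenesis", "lipolysis", "fission", "fusion", "efferocytosis",
    "pyroptosis", "ferroptosis", "necroptosis", "mitophagy", "glycosylation",
    "sumoylation", "neddylation", "palmitoylation", "desaturation",
    "elongation", "termination", "decapping", "polyadenylation",
]


@dataclass
class PlantedScenario:
    """A fully specified synthetic study: inputs plus hidden ground truth."""

    universe: list[str]
    library: PathwayLibrary
    deg_set: GeneSet
    planted_truths: list[str]
    planted_modules: list[set[str]]
    ppi_edges: pd.DataFrame
    contexts: ContextPair
    seed: int


def _pathway_names(n: int) -> list[str]:
    if 2 * n > len(_VOCAB):
        raise ValueError(f"at most {len(_VOCAB) // 2} pathways supported, got {n}")
    return [f"{_VOCAB[2 * i]} {_VOCAB[2 * i + 1]}" for i in range(n)]


def make_scenario(
    n_universe: int = 1500,
    n_pathways: int = 20,
    pathway_size: tuple[int, int] = (20, 40),
    n_modules: int = 3,
    module_size: int = 20,
    noise_frac: float = 0.1,
    p_in: float = 0.6,
    p_out: float = 0.01,
    n_deg_noise: int = 15,
    seed: int = 0,
) -> PlantedScenario:
    """Generate a planted-module scenario.

    ``n_modules`` distinct pathways are chosen as ground truths; each
    planted module draws ``round((1-noise_frac)*module_size)`` genes from
    its pathway and the rest from outside it.  The DEG set is the union of
    the modules plus ``n_deg_noise`` unrelated genes.  PPI edges appear
    with probability ``p_in`` inside modules and ``p_out`` between any
    other DEG pair; confidences are drawn above the ingest cutoff so edge
    filtering does not silently erase the planted structure.
    """
    lo, hi = pathway_size
    if module_size > lo:
        raise ValueError(f"module_size {module_size} exceeds the minimum pathway size {lo}")
    if not p_in > p_out:
        raise ValueError("p_in must exceed p_out")
    if n_modules > n_pathways:
        raise ValueError("cannot plant more modules than pathways")
    if n_pathways * hi > n_universe:
        raise ValueError("universe too small for disjoint pathways of the requested size")

    rng = np.random.default_rng(seed)
    universe = [f"G{i:05d}" for i in range(n_universe)]
    names = _pathway_names(n_pathways)

    # disjoint pathway memberships carved from a permutation of the universe
    perm = list(rng.permutation(n_universe))
    sets: dict[str, list[str]] = {}
    cursor = 0
    for name in names:
        size = int(rng.integers(lo, hi + 1))
        sets[name] = [universe[j] for j in perm[cursor : cursor + size]]
        cursor += size
    library = PathwayLibrary(name="synthetic", sets=sets)

    planted_idx = sorted(rng.choice(n_pathways, size=n_modules, replace=False))
    planted_truths = [names[i] for i in planted_idx]

    pathway_union = {g for genes in sets.values() for g in genes}
    background = [g for g in universe if g not in pathway_union]

    n_pure = round((1.0 - noise_frac) * module_size)
    modules: list[set[str]] = []
    used: set[str] = set()
    for name in planted_truths:
        members = [g.upper() for g in sets[name]]
        pure = list(rng.choice(members, size=n_pure, replace=False))
        pool = [g.upper() for g in background if g.upper() not in used]
        noisy = list(rng.choice(pool, size=module_size - n_pure, replace=False))
        module = set(pure) | set(noisy)
        modules.append(module)
        used |= module

    noise_pool = [g.upper() for g in background if g.upper() not in used]
    deg_noise = list(rng.choice(noise_pool, size=n_deg_noise, replace=False))
    deg_genes = sorted(set().union(*modules)) + sorted(deg_noise)
    deg_set = GeneSet(name=f"planted-scenario-{seed}", genes=deg_genes)

    rows: list[tuple[str, str, float]] = []
    module_of = {g: i for i, m in enumerate(modules) for g in m}
    ordered = deg_set.genes
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            u, v = ordered[i], ordered[j]
            same = module_of.get(u) is not None and module_of.get(u) == module_of.get(v)
            p = p_in if same else p_out
            if rng.random() < p:
                conf = rng.uniform(0.4, 0.99) if same else rng.uniform(0.06, 0.9)
                rows.append((u, v, round(float(conf), 3)))
    ppi_edges = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])

    contexts = ContextPair(
        experimental_conditions=(
            "differential expression observed under perturbation of "
            + " and ".join(planted_truths)
        ),
        research_objectives=(
            "characterize the roles of " + ", ".join(planted_truths) + " in the model system"
        ),
    )
    return PlantedScenario(
        universe=universe,
        library=library,
        deg_set=deg_set,
        planted_truths=planted_truths,
        planted_modules=modules,
        ppi_edges=ppi_edges,
        contexts=contexts,
        seed=seed,
    )


def write_scenario(scenario: PlantedScenario, outdir: str | Path) -> dict[str, Path]:
    """Emit the scenario in the same file formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "deg_list.txt",
        "gmt": outdir / "library.gmt",
        "edges": outdir / "ppi_edges.tsv",
        "truths": outdir / "ground_truths.txt",
        "context_experimental": outdir / "context_experimental.txt",
        "context_objectives": outdir / "context_objectives.txt",
    }
    write_gene_list(scenario.deg_set, paths["genes"])
    write_gmt(scenario.library, paths["gmt"])
    scenario.ppi_edges.to_csv(paths["edges"], sep="\t", index=False)
    paths["truths"].write_text("\n".join(scenario.planted_truths) + "\n")
    paths["context_experimental"].write_text(scenario.contexts.experimental_conditions + "\n")
    paths["context_objectives"].write_text(scenario.contexts.research_objectives + "\n")
    return paths


def contaminate(
    curated: GeneSet,
    fraction: float,
    background: Sequence[str],
    seed: int = 0,
) -> GeneSet:
    """Replace a fraction of a curated gene set with random background genes.

    The output has the same size as the input: ``round(fraction * size)``
    members (round-half-up) are swapped for draws without replacement from
    the background pool.  The pool is filtered to exclude the curated
    genes themselves, so the nominal contamination fraction equals the
    realized fraction exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = curated.genes
    n = len(genes)
    k = floor(fraction * n + 0.5)
    pool = sorted({g.strip().upper() for g in background} - set(genes))
    if len(pool) < k:
        raise ValueError(f"background pool ({len(pool)}) too small for {k} replacements")
    if k == 0:
        return GeneSet(name=curated.name, genes=list(genes), species=curated.species)
    drop_idx = set(rng.choice(n, size=k, replace=False).tolist())
    kept = [g for i, g in enumerate(genes) if i not in drop_idx]
    drawn = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
    return GeneSet(
        name=f"{curated.name}|contaminated-{fraction:g}",
        genes=kept + drawn,
        species=curated.species,
    )


DEFAULT_FRACTIONS = (0.0, 0.5, 1.0)


def make_contamination_benchmark(
    curated_sets: Sequence[tuple[str, GeneSet]],
    background: Sequence[str],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the curated-vs-contaminated benchmark table.

    One row per (curated set, fraction): the contaminated gene list plus a
    context string derived from the set's term (standing in for a curated
    term definition).  Row seeds are drawn from ``seed`` so the whole
    table regenerates bit-identically.
    """
    if not curated_sets:
        raise ValueError("no curated sets supplied")
    rng = np.random.default_rng(seed)
    rows = []
    for term, gene_set in curated_sets:
        for frac in fractions:
            row_seed = int(rng.integers(0, 2**31 - 1))
            contaminated = contaminate(gene_set, frac, background, seed=row_seed)
            rows.append(
                {
                    "term": term,
                    "fraction": float(frac),
                    "genes": list(contaminated.genes),
                    "context": f"genes involved in {term.lower()}",
                    "row_seed": row_seed,
                }
            )
    return pd.DataFrame(rows)


def score_contamination_benchmark(
    benchmark: pd.DataFrame,
    library: PathwayLibrary,
    backend: LLMBackend | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Run each benchmark row through enrichment + screening/summarization
    and record the assigned relevance score.

    A row whose gene set yields no significant pathway, or whose pathways
    are all screened out, scores 0 — the pipeline found nothing
    context-relevant, the intended behaviour for fully randomized sets.
    """
    backend = backend or MockLLMBackend()
    out = []
    for row in benchmark.itertuples(index=False):
        gene_set = GeneSet(name=row.term, genes=list(row.genes))
        terms = enrich_cluster(gene_set.genes, library, alpha=alpha)
        if not terms:
            score, pathway, status = 0.0, None, "no significant pathway"
        else:
            contexts = ContextPair(
                experimental_conditions=row.context, research_objectives=row.context
            )
            summary = screen_and_summarize(terms, contexts, backend)
            score = summary.relevance_score
            pathway = summary.pathway
            status = summary.status
        out.append(
            {
                "term": row.term,
                "fraction": row.fraction,
                "pathway": pathway,
                "relevance_score": score,
                "status": status,
            }
        )
    return pd.DataFrame(out)


def rand_index(labels_a: dict[str, int], labels_b: dict[str, int]) -> float:
    """Rand index between two labelings over their common keys.

    Pair-counting agreement: the fraction of item pairs on which the two
    partitions agree (together in both, or apart in both).
    """
    keys = sorted(set(labels_a) & set(labels_b))
    if len(keys) < 2:
        raise ValueError("need at least two co-labeled items")
    agree = 0
    total = 0
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            same_a = labels_a[keys[i]] == labels_a[keys[j]]
            same_b = labels_b[keys[i]] == labels_b[keys[j]]
            agree += same_a == same_b
            total += 1
    return agree / total


def planted_recovery_rand(scenario: PlantedScenario, clustering) -> float:
    """Rand index between recovered clusters and planted modules, computed
    over the planted-module genes; genes the clustering dropped each get a
    unique singleton label."""
    truth = {g: i for i, m in enumerate(scenario.planted_modules) for g in m}
    pred: dict[str, int] = clustering.labels()
    next_label = len(clustering.clusters)
    for g in truth:
        if g not in pred:
            pred[g] = next_label
            next_label += 1
    return rand_index({g: truth[g] for g in truth}, {g: pred[g] for g in truth})
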