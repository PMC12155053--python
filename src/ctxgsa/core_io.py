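"""Readers, writers and domain containers for gene lists, GMT libraries and reports.

Gene symbols are normalized to an NCBI-style convention: trimmed,
uppercased, and optionally mapped through an alias table.  All containers
de-duplicate on the normalized symbol while preserving first-occurrence
order, so downstream set arithmetic is stable and reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


class GeneListError(ValueError):
    """Raised for empty or unusable gene-list inputs."""


class GMTParseError(ValueError):
    """Raised for malformed GMT lines."""


def normalize_symbols(
    raw: Iterable[str],
    alias_map: Mapping[str, str] | None = None,
) -> list[str]:
    """Trim, uppercase and alias-map gene tokens, preserving order.

    ``alias_map`` maps uppercase alias to uppercase official symbol
    (e.g. ``{"P53": "TP53"}``).  Unmapped tokens are kept as-is; the count
    of unmapped tokens is logged, never raised.
    """
    out: list[str] = []
    unmapped = 0
    for tok in raw:
        sym = tok.strip().upper()
        if not sym:
            continue
        if alias_map:
            if sym in alias_map:
                sym = alias_map[sym].strip().upper()
            else:
                unmapped += 1
        out.append(sym)
    if alias_map and unmapped:
        logger.debug("normalize_symbols: %d tokens had no alias entry", unmapped)
    return out


def _dedupe(symbols: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for s in symbols:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


@dataclass
class GeneSet:
    """An ordered, de-duplicated collection of normalized gene symbols."""

    name: str
    genes: list[str]
    species: str = "human"

    def __post_init__(self) -> None:
        self.genes = _dedupe(normalize_symbols(self.genes))
        for g in self.genes:
            if not g or any(c.isspace() for c in g):
                raise GeneListError(f"invalid gene symbol after normalization: {g!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, item: str) -> bool:
        return item in set(self.genes)


@dataclass
class PathwayLibrary:
    """A named collection of pathway -> gene-membership sets (a GMT library).

    ``background_size`` defaults to the number of distinct genes across the
    library; it can be overridden when the true assay universe is known.
    """

    name: str
    sets: dict[str, list[str]]
    background_size: int | None = None

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for term, genes in self.sets.items():
            norm = _dedupe(normalize_symbols(genes))
            if not norm:
                raise GMTParseError(f"pathway {term!r} has no genes")
            cleaned[term] = norm
        self.sets = cleaned
        union = self.gene_union()
        if self.background_size is None:
            self.background_size = len(union)
        largest = max((len(g) for g in self.sets.values()), default=0)
        if self.background_size < largest:
            raise ValueError(
                f"background_size {self.background_size} smaller than the "
                f"largest pathway ({largest} genes)"
            )

    def gene_union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ContextPair:
    """The two free-text contexts conditioning the language-model stages.

    ``experimental_conditions`` describes how the input genes were produced
    (used for pathway screening); ``research_objectives`` states what the
    study is after (used for pathway summarization).
    """

    experimental_conditions: str
    research_objectives: str

    def __post_init__(self) -> None:
        self.experimental_conditions = self.experimental_conditions.strip()
        self.research_objectives = self.research_objectives.strip()
        if not self.experimental_conditions or not self.research_objectives:
            raise ValueError("both context strings must be non-empty")


def read_gene_list(
    path: str | Path,
    column: str | None = None,
    alias_map: Mapping[str, str] | None = None,
    name: str | None = None,
) -> GeneSet:
    """Read a gene list from a plain text file (one symbol per line) or a
    named TSV column.

    Blank lines are ignored; duplicates (after normalization) are dropped
    keeping first occurrence.  Raises :class:`GeneListError` on an empty
    result.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if column is not None:
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        if column not in df.columns:
            raise GeneListError(f"column {column!r} not found in {path}")
        tokens = [str(t) for t in df[column].dropna()]
    else:
        tokens = [line for line in text.splitlines()]
    symbols = _dedupe(normalize_symbols(tokens, alias_map))
    if not symbols:
        raise GeneListError(f"no genes found in {path}")
    return GeneSet(name=name or path.stem, genes=symbols)


def write_gene_list(genes: GeneSet, path: str | Path) -> None:
    """Write one symbol per line."""
    Path(path).write_text("\n".join(genes.genes) + "\n")


def read_gmt(path: str | Path, background_size: int | None = None) -> PathwayLibrary:
    """Read a Broad-dialect GMT file: term TAB description TAB gene [TAB gene ...].

    Raises :class:`GMTParseError` for an empty file or a line with fewer
    than three tab-separated fields, naming the offending line.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise GMTParseError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GMTParseError(
                f"{path}: line {lineno}: expected term, description and at "
                f"least one gene, got {len(fields)} fields"
            )
        term = fields[0].strip()
        genes = [f for f in fields[2:] if f.strip()]
        sets[term] = genes
    return PathwayLibrary(name=path.stem, sets=sets, background_size=background_size)


def write_gmt(library: PathwayLibrary, path: str | Path) -> None:
    """Write the library in Broad GMT dialect (description column left blank)."""
    with open(path, "w") as fh:
        for term, genes in library.sets.items():
            fh.write("\t".join([term, ""] + list(genes)) + "\n")


def write_report(report, path: str | Path) -> None:
    """Write a pipeline or evaluation report as JSON plus a flat TSV.

    ``path`` is the JSON destination; a sibling ``.tsv`` holds one row per
    summarized cluster — (cluster id, pathway, relevance score, enriched
    genes, p-value) — ordered by relevance score descending.  An empty
    result still produces a valid report with zero rows and a status note.
    """
    path = Path(path)
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    rows = payload.get("summaries", [])
    if not rows:
        payload.setdefault("status", "no cluster passed screening")
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    tsv_path = path.with_suffix(".tsv")
    header = ["cluster_id", "pathway", "relevance_score", "enriched_genes", "p_value"]
    ordered = sorted(
        rows, key=lambda r: (-(r.get("relevance_score") or 0.0), str(r.get("pathway")))
    )
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in ordered:
            fh.write(
                "\t".join(
                    [
                        str(r.get("cluster_id")),
                        str(r.get("pathway")),
                        repr(float(r.get("relevance_score") or 0.0)),
                        ",".join(r.get("enriched_genes", [])),
                        repr(float(r["p_value"])) if r.get("p_value") is not None else "",
                    ]
                )
                + "\n"
            )


def read_report(path: str | Path) -> dict:
    """Round-trip reader for the JSON report (scores reproduce bit-exactly)."""
    return json.loads(Path(path).read_text())
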