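"""Language-model stages: context screening and pathway summarization.

Two prompted stages sit after enrichment.  Screening judges each enriched
pathway against the experimental conditions and removes contextually
irrelevant ones.  Summarization selects the single most representative
pathway for a cluster given the research objectives and assigns a 0-10
contextual relevance score justified by three criteria: contextual
relevance, pathway function analysis, and gene co-expression analysis.
Scores are banded at 5.5 (moderate) and 7.0 (high).

Backends are pluggable behind a one-method contract (``complete``).  The
shipped :class:`MockLLMBackend` is a deterministic rule-based stand-in
driven by token overlap between pathway names and the embedded context,
blended with the fraction of cluster genes the pathway explains, so the
whole pipeline runs offline and reproducibly.  Remote chat-completion
backends must be run at temperature 0.0 to preserve the pipeline's
determinism contract.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Protocol, Sequence

from .core_io import ContextPair
from .enrichment import EnrichedTerm

logger = logging.getLogger(__name__)

MODERATE_CUTOFF = 5.5
HIGH_CUTOFF = 7.0

#: minimum mock screening score (0-10 scale) a pathway must exceed to be retained
MOCK_SCREEN_FLOOR = 0.0

NO_RELEVANT_PATHWAY = "no context-relevant pathway"


class ResponseParseError(ValueError):
    """Raised when a backend response lacks the expected structured block.

    Carries the raw response text for logging/audit.
    """

    def __init__(self, message: str, raw: str):
        super().__init__(message)
        self.raw = raw


class LLMBackend(Protocol):
    """Chat-completion contract: one prompt in, one response text out."""

    deterministic: bool

    def complete(self, prompt: str) -> str: ...


@dataclass
class ScreenedPathways:
    """Outcome of the screening stage for one cluster."""

    cluster_id: int
    retained: list[tuple[str, str]]  # (term, relevance judgment)
    removed: list[str]


@dataclass
class SummarizedPathway:
    """The representative pathway chosen for one cluster, with its score."""

    cluster_id: int
    pathway: str | None
    relevance_score: float
    rationale: str = ""
    status: str = "ok"

    @property
    def relevance_band(self) -> str:
        if self.pathway is None:
            return "low"
        return classify_relevance(self.relevance_score)


def classify_relevance(score: float) -> str:
    """Band a 0-10 relevance score: >= 7.0 high, >= 5.5 moderate, else low.

    Both cutoffs are inclusive."""
    if not 0.0 <= score <= 10.0:
        raise ValueError(f"relevance score out of [0, 10]: {score}")
    if score >= HIGH_CUTOFF:
        return "high"
    if score >= MODERATE_CUTOFF:
        return "moderate"
    return "low"


def _term_lines(terms: Sequence[EnrichedTerm]) -> str:
    lines = []
    for t in terms:
        lines.append(
            f"PATHWAY: {t.term} | P_VALUE: {t.p_value:.3e} | "
            f"OVERLAP: {t.overlap_count}/{t.cluster_size} | "
            f"GENES: {', '.join(t.overlap_genes)}"
        )
    return "\n".join(lines)


SCREEN_TEMPLATE = """\
You are a biomedical expert reviewing pathway enrichment results for a gene
cluster.  Judge each candidate pathway's relevance to the experimental
conditions under which the genes were identified.

EXPERIMENTAL CONDITIONS: {context}

CANDIDATE PATHWAYS:
{terms}

For every candidate above, decide whether it is relevant to the
experimental conditions, considering the pathway's known function and its
enriched genes.  Answer with one block per pathway, exactly:
PATHWAY: <name>
VERDICT: <RETAIN or REMOVE>
"""


SUMMARIZE_TEMPLATE = """\
You are a biomedical expert summarizing pathway enrichment results for a
gene cluster.  From the context-relevant pathways below, select the ONE
most representative pathway for the stated research objectives.

RESEARCH OBJECTIVES: {context}

RETAINED PATHWAYS:
{terms}

Assign the selected pathway a relevance score from 0 to 10, justified by
three criteria: contextual relevance to the research objectives, pathway
function analysis, and gene co-expression analysis.  Answer exactly:
PATHWAY: <name>
SCORE: <number between 0 and 10>
RATIONALE: <one short paragraph>
"""


def render_screen_prompt(terms: Sequence[EnrichedTerm], context: str) -> str:
    """Render the screening prompt: embeds the experimental-conditions text
    and every candidate pathway with its enriched genes, in stable order."""
    if not terms:
        raise ValueError("need at least one enriched term to screen")
    return SCREEN_TEMPLATE.format(context=context, terms=_term_lines(terms))


def render_summarize_prompt(
    screened: ScreenedPathways,
    terms: Sequence[EnrichedTerm],
    context: str,
) -> str:
    """Render the summarization prompt over the retained pathways only."""
    if not screened.retained:
        raise ValueError("no retained pathways to summarize")
    retained_names = {name for name, _ in screened.retained}
    kept = [t for t in terms if t.term in retained_names]
    return SUMMARIZE_TEMPLATE.format(context=context, terms=_term_lines(kept))


_PATHWAY_RE = re.compile(r"^\s*PATHWAY\s*:\s*(.+?)\s*$", re.MULTILINE)
_SCORE_RE = re.compile(r"^\s*SCORE\s*:\s*([-+]?\d+(?:\.\d+)?)\s*$", re.MULTILINE)
_RATIONALE_RE = re.compile(r"^\s*RATIONALE\s*:\s*(.*)\s*$", re.MULTILINE | re.DOTALL)
_VERDICT_RE = re.compile(
    r"^\s*PATHWAY\s*:\s*(.+?)\s*\n\s*(?:SCORE\s*:\s*[^\n]*\n\s*)?VERDICT\s*:\s*(RETAIN|REMOVE)\s*$",
    re.MULTILINE | re.IGNORECASE,
)


def parse_summary_response(text: str, cluster_id: int = 0) -> SummarizedPathway:
    """Extract pathway name and numeric score from a structured response.

    Tolerant of surrounding prose; the score is clamped into [0, 10] with a
    warning.  Raises :class:`ResponseParseError` (carrying the raw text)
    when no pathway or score line is present.
    """
    pm = _PATHWAY_RE.search(text)
    sm = _SCORE_RE.search(text)
    if pm is None or sm is None:
        raise ResponseParseError("response lacks PATHWAY/SCORE block", raw=text)
    score = float(sm.group(1))
    if not 0.0 <= score <= 10.0:
        logger.warning("relevance score %.2f outside [0, 10]; clamping", score)
        score = min(max(score, 0.0), 10.0)
    rm = _RATIONALE_RE.search(text)
    return SummarizedPathway(
        cluster_id=cluster_id,
        pathway=pm.group(1),
        relevance_score=score,
        rationale=rm.group(1).strip() if rm else "",
    )


def parse_screen_response(
    text: str, terms: Sequence[EnrichedTerm], cluster_id: int = 0
) -> ScreenedPathways:
    """Map backend verdicts onto the cluster's terms.

    A term with no verdict in the response is conservatively retained."""
    verdicts = {name.strip(): v.upper() for name, v in _VERDICT_RE.findall(text)}
    retained: list[tuple[str, str]] = []
    removed: list[str] = []
    for t in terms:
        verdict = verdicts.get(t.term, "RETAIN")
        if verdict == "RETAIN":
            retained.append((t.term, verdict))
        else:
            removed.append(t.term)
    return ScreenedPathways(cluster_id=cluster_id, retained=retained, removed=removed)


def screen_and_summarize(
    cluster_terms: Sequence[EnrichedTerm],
    contexts: ContextPair,
    backend: LLMBackend,
    cluster_id: int = 0,
    retries: int = 1,
) -> SummarizedPathway:
    """Run screening then summarization for one cluster.

    If screening removes every pathway, returns a null summary flagged
    ``"no context-relevant pathway"`` instead of forcing a choice.  A
    transient backend failure is retried once (deterministic backends make
    further retries pointless).
    """
    if not cluster_terms:
        raise ValueError("cluster has no enriched terms")

    def _complete(prompt: str) -> str:
        last: Exception | None = None
        for _ in range(retries + 1):
            try:
                return backend.complete(prompt)
            except Exception as err:  # pragma: no cover - fixture-driven
                last = err
        raise RuntimeError("LLM backend failed after retry") from last

    screen_prompt = render_screen_prompt(cluster_terms, contexts.experimental_conditions)
    screened = parse_screen_response(_complete(screen_prompt), cluster_terms, cluster_id)
    if not screened.retained:
        return SummarizedPathway(
            cluster_id=cluster_id,
            pathway=None,
            relevance_score=0.0,
            status=NO_RELEVANT_PATHWAY,
        )
    summarize_prompt = render_summarize_prompt(
        screened, cluster_terms, contexts.research_objectives
    )
    summary = parse_summary_response(_complete(summarize_prompt), cluster_id)
    return summary


# ---------------------------------------------------------------------------
# deterministic mock backend


_TOKEN_RE = re.compile(r"[a-z0-9]+")
_CANDIDATE_RE = re.compile(
    r"^PATHWAY:\s*(.+?)\s*\|\s*P_VALUE:\s*\S+\s*\|\s*OVERLAP:\s*(\d+)/(\d+)\s*\|",
    re.MULTILINE,
)
_CTX_SCREEN_RE = re.compile(r"^EXPERIMENTAL CONDITIONS:\s*(.+)$", re.MULTILINE)
_CTX_SUMM_RE = re.compile(r"^RESEARCH OBJECTIVES:\s*(.+)$", re.MULTILINE)


def _tokens(text: str) -> set[str]:
    return set(_TOKEN_RE.findall(text.lower()))


def _context_overlap(name: str, ctx_tokens: set[str]) -> float:
    name_tokens = _tokens(name)
    if not name_tokens:
        return 0.0
    return len(name_tokens & ctx_tokens) / len(name_tokens)


class MockLLMBackend:
    """Deterministic rule-based stand-in for a chat-completion model.

    Screening: a candidate's screen score is 10x the fraction of its name
    tokens that appear in the embedded context; candidates scoring above a
    fixed floor are retained.  Summarization: each candidate scores a blend
    of context-name overlap (weight 0.6) and the fraction of cluster genes
    it explains (weight 0.4), scaled to 0-10; the argmax is returned, ties
    broken lexicographically on the pathway name.  Responses use the same
    structured blocks the parsers expect, so mock and parser compose
    without error on renderer-produced prompts.
    """

    deterministic = True

    def __init__(
        self,
        screen_floor: float = MOCK_SCREEN_FLOOR,
        context_weight: float = 0.6,
        gene_weight: float = 0.4,
    ):
        self.screen_floor = screen_floor
        self.context_weight = context_weight
        self.gene_weight = gene_weight

    def complete(self, prompt: str) -> str:
        candidates = [
            (name.strip(), int(k), int(n))
            for name, k, n in _CANDIDATE_RE.findall(prompt)
        ]
        screen_ctx = _CTX_SCREEN_RE.search(prompt)
        summ_ctx = _CTX_SUMM_RE.search(prompt)
        if screen_ctx is not None:
            return self._screen(candidates, _tokens(screen_ctx.group(1)))
        if summ_ctx is not None:
            return self._summarize(candidates, _tokens(summ_ctx.group(1)))
        raise ValueError("prompt does not carry a recognized context marker")

    def _screen(self, candidates, ctx_tokens: set[str]) -> str:
        blocks = []
        for name, _k, _n in candidates:
            score = 10.0 * _context_overlap(name, ctx_tokens)
            verdict = "RETAIN" if score > self.screen_floor else "REMOVE"
            blocks.append(f"PATHWAY: {name}\nSCORE: {score:.2f}\nVERDICT: {verdict}")
        return "\n".join(blocks)

    def _summarize(self, candidates, ctx_tokens: set[str]) -> str:
        scored = []
        for name, k, n in candidates:
            ctx_frac = _context_overlap(name, ctx_tokens)
            gene_frac = k / n if n else 0.0
            score = 10.0 * (self.context_weight * ctx_frac + self.gene_weight * gene_frac)
            scored.append((name, score))
        best_name, best_score = min(scored, key=lambda x: (-x[1], x[0]))
        return (
            f"PATHWAY: {best_name}\n"
            f"SCORE: {best_score:.2f}\n"
            f"RATIONALE: token overlap with the stated context and the "
            f"fraction of cluster genes explained make this the most "
            f"representative candidate."
        )


class HTTPChatBackend:
    """Thin adapter for an OpenAI-style chat-completion HTTP endpoint.

    Temperature is pinned to 0.0 so remote runs honor the pipeline's
    determinism contract.  Uses only the standard library; not exercised by
    the offline test suite.
    """

    deterministic = True

    def __init__(self, url: str, model: str, api_key: str = "", timeout: float = 60.0):
        self.url = url
        self.model = model
        self.api_key = api_key
        self.timeout = timeout

    def complete(self, prompt: str) -> str:  # pragma: no cover - network
        import json
        import urllib.request

        payload = json.dumps(
            {
                "model": self.model,
                "temperature": 0.0,
                "messages": [{"role": "user", "content": prompt}],
            }
        ).encode()
        req = urllib.request.Request(
            self.url,
            data=payload,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {self.api_key}",
            },
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            body = json.loads(resp.read())
        return body["choices"][0]["message"]["content"]
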