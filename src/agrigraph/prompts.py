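"""Prompt templates and the delimiter grammar for structured extraction.

Every provider call in the pipeline goes through one of the template ids
below.  Templates carry machine-readable section markers so that the
deterministic stub providers (and tests inspecting provider calls) can
recover exactly what context a stage supplied — this is what makes the
input-purity contracts (e.g. parent summaries see only child summaries)
assertable.

Delimiter grammar for extraction output::

    ("entity"<|>NAME<|>TYPE<|>DESCRIPTION)##
    ("relationship"<|>HEAD<|>TAIL<|>RELATION<|>DESCRIPTION)##
    <|COMPLETE|>

``<|>`` separates tuple fields, ``##`` separates records, and
``<|COMPLETE|>`` terminates the payload; its absence signals truncation.
"""

from __future__ import annotations

from dataclasses import dataclass

from agrigraph.errors import MalformedPromptError

TUPLE_DELIM = "<|>"
RECORD_DELIM = "##"
COMPLETION_DELIM = "<|COMPLETE|>"

CONTEXT_OPEN = "<<CONTEXT>>"
CONTEXT_CLOSE = "<<END CONTEXT>>"
QUERY_OPEN = "<<QUERY>>"
QUERY_CLOSE = "<<END QUERY>>"

# Template ids (one per provider-backed stage).
EXTRACT = "extract_elements"
ELEMENT_SUMMARY = "element_summary"
LEAF_SUMMARY = "leaf_community_summary"
PARENT_SUMMARY = "parent_community_summary"
SCORE = "community_relevance_score"
LOCAL_ANSWER = "local_answer"
MAP_ANSWER = "global_map_answer"
REDUCE_ANSWER = "global_reduce_answer"

#: Default closed set of entity types for extraction.
DEFAULT_ENTITY_TYPES: tuple[str, ...] = (
    "Crops",
    "Diseases",
    "Insect pests",
    "Symptoms",
    "Control measures",
    "Pathogen",
)


@dataclass(frozen=True)
class CompletionRequest:
    """One text-completion call: template id + fully filled prompt."""

    prompt_template_id: str
    filled_prompt: str
    max_output: int = 2048

    def __post_init__(self) -> None:
        if not self.filled_prompt.strip():
            raise MalformedPromptError("filled_prompt must be non-empty")


def _wrap(template_id: str, instructions: str, context: str, query: str | None = None) -> CompletionRequest:
    parts = [f"[{template_id}]", instructions]
    if query is not None:
        parts += [QUERY_OPEN, query, QUERY_CLOSE]
    parts += [CONTEXT_OPEN, context, CONTEXT_CLOSE]
    return CompletionRequest(template_id, "\n".join(parts))


def extract_context(filled_prompt: str) -> str:
    """Recover the context block a prompt was packed with."""
    try:
        after = filled_prompt.split(CONTEXT_OPEN, 1)[1]
        return after.rsplit(CONTEXT_CLOSE, 1)[0].strip("\n")
    except IndexError as exc:  # pragma: no cover - defensive
        raise MalformedPromptError("prompt has no context block") from exc


def extract_query(filled_prompt: str) -> str:
    try:
        after = filled_prompt.split(QUERY_OPEN, 1)[1]
        return after.rsplit(QUERY_CLOSE, 1)[0].strip("\n")
    except IndexError as exc:
        raise MalformedPromptError("prompt has no query block") from exc


def extraction_prompt(chunk_text: str, entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES) -> CompletionRequest:
    instructions = (
        "Given a text document and a list of entity types related to crop "
        "pest and disease activities, identify all entities of the specified "
        f"types ({', '.join(entity_types)}) and all explicitly related "
        "(source entity, target entity) pairs. Return one list of entity and "
        f"relationship records using the {TUPLE_DELIM} / {RECORD_DELIM} "
        f"delimiters. When complete, output {COMPLETION_DELIM}."
    )
    return _wrap(EXTRACT, instructions, chunk_text)


def element_summary_prompt(truncated_descriptions: str) -> CompletionRequest:
    instructions = (
        "Merge the following description fragments of one entity or relation "
        "into a single concise, comprehensive summary."
    )
    return _wrap(ELEMENT_SUMMARY, instructions, truncated_descriptions)


def leaf_summary_prompt(packed_context: str) -> CompletionRequest:
    instructions = (
        "Write a report on this graph community: core theme, principal "
        "entities, the relations among them, and other salient information. "
        "The context packs member text chunks, element summaries, and the "
        "community's entities, attributes, and relations."
    )
    return _wrap(LEAF_SUMMARY, instructions, packed_context)


def parent_summary_prompt(child_summaries: str) -> CompletionRequest:
    instructions = (
        "Aggregate the following child community summaries into one "
        "higher-level community summary. Use only these summaries."
    )
    return _wrap(PARENT_SUMMARY, instructions, child_summaries)


def score_prompt(community_summary: str, query: str) -> CompletionRequest:
    instructions = (
        "Rate the relevance of this community summary to the user query on "
        "an integer scale from 0 (irrelevant) to 5 (directly on topic). "
        "Reply with the integer only."
    )
    return _wrap(SCORE, instructions, community_summary, query=query)


def local_answer_prompt(table: str, query: str) -> CompletionRequest:
    instructions = (
        "Answer the user question about crop pests and diseases using ONLY "
        "the structured data table below (center entity, relations, "
        "neighbor entities, sources)."
    )
    return _wrap(LOCAL_ANSWER, instructions, table, query=query)


def map_answer_prompt(community_summary: str, query: str) -> CompletionRequest:
    instructions = (
        "Produce a partial answer to the user question from this single "
        "community summary; list the supporting facts."
    )
    return _wrap(MAP_ANSWER, instructions, community_summary, query=query)


def reduce_answer_prompt(partials: str, query: str) -> CompletionRequest:
    instructions = (
        "Integrate, refine and synthesize the partial answers below into a "
        "single final response to the user question."
    )
    return _wrap(REDUCE_ANSWER, instructions, partials, query=query)
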