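"""Shared answer container for the local and global query pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Answer:
    """Generated answer text plus its evidence trail.

    ``citations`` lists the ids (chunk, community) the answer was grounded
    in; ``metadata`` carries pipeline-specific diagnostics (entity match,
    score trace, conflict report, ...).
    """

    text: str
    citations: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
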