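"""Ordinal ranking of detected HSEs by predicted functionality.

Matches are ordered by how close they are to the canonical element and
how close they sit to the transcription start site: fewer core
substitutions first, then fewer substitutions at core position 1 (the G
of GAA / first T of TTC, the most disruptive position to perturb), then
fewer inter-unit insertions, then smaller absolute TSS distance, with the
start coordinate as a deterministic final tie-break.  The key composition
is configurable because no single substitution-type hierarchy is
established; the default encodes position-1 hits as more disruptive.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, List, Sequence, Tuple

from .model import HSEMatch

#: Named key components, in the default priority order.
KEY_COMPONENTS: Dict[str, Callable[[HSEMatch], int]] = {
    "substitutions_total": lambda m: m.substitutions_total,
    "subs_at_core_position1": lambda m: m.subs_at_core_position1,
    "insertions_total": lambda m: m.insertions_total,
    "tss_distance_abs": lambda m: abs(m.distance_to_tss),
}

DEFAULT_KEY = (
    "substitutions_total",
    "subs_at_core_position1",
    "insertions_total",
    "tss_distance_abs",
)


def rank_key(match: HSEMatch, components: Sequence[str] = DEFAULT_KEY) -> Tuple[int, ...]:
    """The sort key of one match; smaller ranks first. Start breaks ties."""
    if match.distance_to_tss is None:
        raise ValueError(
            f"match at [{match.start}, {match.end}) has unresolved TSS distance"
        )
    unknown = set(components) - set(KEY_COMPONENTS)
    if unknown:
        raise ValueError(f"unknown rank key components: {sorted(unknown)}")
    return tuple(KEY_COMPONENTS[name](match) for name in components) + (match.start,)


def rank_matches(
    matches: Sequence[HSEMatch], components: Sequence[str] = DEFAULT_KEY
) -> List[HSEMatch]:
    """Assign 1-based ranks by ascending rank key; the input is not mutated.

    Returns copies of the matches in rank order; ranks are exactly 1..n.
    Matches with identical key components receive distinct ranks by start
    order (the key's final component).
    """
    ordered = sorted(matches, key=lambda m: rank_key(m, components))
    return [
        dataclasses.replace(m, rank=i) for i, m in enumerate(ordered, start=1)
    ]
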