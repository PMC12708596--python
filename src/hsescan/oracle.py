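"""Brute-force HSE finder by exhaustive degenerate-template expansion.

This module is the independent reference for the scanner: it realizes
the same search as explicit pattern matching.  Every admissible
combination of first-unit orientation, core-substitution plan and
inter-unit insertion vector is expanded into one fixed-length template
(a string of literal bases and ``n`` wildcards), and every template is
slid over every position of the sequence with direct base comparison.
It deliberately shares no matching code with :mod:`hsescan.scanner` —
the scanner accumulates Hamming distances, the oracle compares literal
substrings — so agreement between the two is meaningful evidence.

Substituted core positions carry an explicit replacement base drawn from
{A,C,G,T,N} minus the canonical base; literal positions match by exact
equality, so an N in the sequence fails every canonical-core literal
(N counts as a substitution) and wildcards accept any base including N.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .io import PromoterRecord
from .model import (
    UNIT_LENGTH,
    HSEMatch,
    Orientation,
    PentamerUnit,
    ScanParams,
    classify,
    orientation_sequence,
)
from .scanner import MatchSet

WILDCARD = "n"
BASES_WITH_N = "ACGTN"

DEFAULT_TEMPLATE_CAP = 10**6


@dataclass(frozen=True)
class Template:
    """One concrete degenerate pattern with its accounting descriptor."""

    pattern: str  # literal bases and 'n' wildcards
    n_units: int
    first_orientation: Orientation
    substitution_plan: Tuple[Tuple[int, int, str], ...]  # (unit idx, core pos, base)
    gap_insertions: Tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class TemplateSet:
    params: ScanParams
    templates: Tuple[Template, ...]

    def __len__(self) -> int:
        return len(self.templates)


def _build_pattern(
    first: Orientation,
    n_units: int,
    plan: Tuple[Tuple[int, int, str], ...],
    gaps: Tuple[int, ...],
) -> str:
    orients = orientation_sequence(first, n_units)
    replacements = {(u, p): b for u, p, b in plan}
    parts = []
    for k in range(n_units):
        core = list(orients[k].core)
        for p in (1, 2, 3):
            if (k, p) in replacements:
                core[p - 1] = replacements[(k, p)]
        parts.append(WILDCARD + "".join(core) + WILDCARD)
        if k < n_units - 1:
            parts.append(WILDCARD * gaps[k])
    return "".join(parts)


def enumerate_templates(
    params: ScanParams, max_templates: int = DEFAULT_TEMPLATE_CAP
) -> TemplateSet:
    """Exhaustively list every concrete degenerate template for `params`.

    The expansion is (2 orientations) × (substitution position and base
    choices within the total and per-unit budgets) × (admissible insertion
    vectors).  A configurable cap guards combinatorial blow-up.
    """
    n = params.n_units
    core_slots = [(u, p) for u in range(n) for p in (1, 2, 3)]
    templates: List[Template] = []
    for first in (Orientation.GAA_type, Orientation.TTC_type):
        orients = orientation_sequence(first, n)
        for gaps in params.gap_vectors():
            for n_subs in range(params.max_subs_total + 1):
                for slots in itertools.combinations(core_slots, n_subs):
                    per_unit: Dict[int, int] = {}
                    for u, _ in slots:
                        per_unit[u] = per_unit.get(u, 0) + 1
                    if any(c > params.max_subs_per_unit for c in per_unit.values()):
                        continue
                    base_choices = [
                        [
                            b
                            for b in BASES_WITH_N
                            if b != orients[u].core[p - 1]
                        ]
                        for u, p in slots
                    ]
                    for bases in itertools.product(*base_choices):
                        plan = tuple(
                            (u, p, b) for (u, p), b in zip(slots, bases)
                        )
                        templates.append(
                            Template(
                                pattern=_build_pattern(first, n, plan, gaps),
                                n_units=n,
                                first_orientation=first,
                                substitution_plan=plan,
                                gap_insertions=gaps,
                            )
                        )
                        if len(templates) > max_templates:
                            raise ValueError(
                                f"template expansion exceeds cap of {max_templates}"
                            )
    return TemplateSet(params=params, templates=tuple(templates))


def oracle_scan(
    record: PromoterRecord,
    params: ScanParams,
    max_templates: int = DEFAULT_TEMPLATE_CAP,
) -> MatchSet:
    """Slide every template over the record and collect matching alignments.

    Hits are converted to matches with the accounting carried by the
    matching template and canonicalized with the same rule as the
    scanner: per (start, end, orientation sequence), keep minimal total
    substitutions, then minimal total insertions, then the smallest
    insertion vector.
    """
    ts = enumerate_templates(params, max_templates=max_templates)
    seq = record.sequence
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    windows_by_len: Dict[int, np.ndarray] = {}

    best: Dict[Tuple[int, int, Orientation], Tuple[Tuple[int, int, Tuple[int, ...]], Template]] = {}
    for t in ts.templates:
        tlen = t.length
        if tlen > codes.size:
            continue
        if tlen not in windows_by_len:
            windows_by_len[tlen] = np.lib.stride_tricks.sliding_window_view(codes, tlen)
        windows = windows_by_len[tlen]
        literal_idx = np.array(
            [i for i, c in enumerate(t.pattern) if c != WILDCARD], dtype=np.intp
        )
        literal_vals = np.array(
            [ord(t.pattern[i]) for i in literal_idx], dtype=np.uint8
        )
        hits = np.nonzero((windows[:, literal_idx] == literal_vals).all(axis=1))[0]
        for s in hits:
            start = int(s)
            key = (start, start + tlen, t.first_orientation)
            ins_total = sum(t.gap_insertions)
            cand = (len(t.substitution_plan), ins_total, t.gap_insertions)
            cur = best.get(key)
            if cur is None or cand < cur[0]:
                best[key] = (cand, t)

    matches: List[HSEMatch] = []
    for (start, end, first), ((subs_total, ins_total, gaps), t) in sorted(
        best.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
    ):
        orients = orientation_sequence(first, t.n_units)
        per_unit: Dict[int, set] = {u: set() for u in range(t.n_units)}
        for u, p, _ in t.substitution_plan:
            per_unit[u].add(p)
        units = []
        offset = start
        for k in range(t.n_units):
            units.append(
                PentamerUnit(
                    start=offset,
                    orientation=orients[k],
                    core_substitutions=len(per_unit[k]),
                    substituted_core_positions=frozenset(per_unit[k]),
                )
            )
            offset += UNIT_LENGTH + (gaps[k] if k < t.n_units - 1 else 0)
        matches.append(
            HSEMatch(
                record_id=record.record_id,
                start=start,
                end=end,
                units=tuple(units),
                gap_insertions=gaps,
                substitutions_total=subs_total,
                insertions_total=ins_total,
                class_label=classify(t.n_units, subs_total, ins_total),
                matched_sequence=seq[start:end],
            )
        )
    return MatchSet(record_id=record.record_id, params=params, matches=tuple(matches))
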