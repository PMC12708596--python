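"""Enumerate HSE matches of a promoter under a tolerance envelope.

The scanner works on the sense strand only: the alternating-pentamer
pattern family is closed under reverse complement (the reverse complement
of ``nGAAnnTTCnnGAAn`` is ``nTTCnnGAAnnTTCn``), so a single-strand scan
finds every element and double-scanning would double count.

Every candidate alignment is a triple (start position, first-unit
orientation, inter-unit insertion vector).  Units tile as adjacent 5-bp
blocks separated by exactly the inserted bases; core substitutions are
Hamming mismatches of the observed trinucleotide against GAA/TTC, with N
always counting as a mismatch in a core and matching freely at wildcard
positions.  Alignments that share (start, end, orientation sequence) but
differ in where the gap insertions sit are collapsed to one canonical
alignment: minimal total substitutions, then minimal total insertions,
then lexicographically smallest insertion vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .io import PromoterRecord
from .model import (
    CLASS_LABELS,
    UNIT_LENGTH,
    ClassSummary,
    HSEMatch,
    Orientation,
    PentamerUnit,
    ScanParams,
    classify,
    orientation_sequence,
)


@dataclass(frozen=True)
class MatchSet:
    """All matches of one record under one parameter envelope."""

    record_id: str
    params: ScanParams
    matches: Tuple[HSEMatch, ...]

    def __len__(self) -> int:
        return len(self.matches)


def match_unit(sequence: str, pos: int, orientation: Orientation) -> PentamerUnit:
    """Align one pentamer unit at `pos` and account its core mismatches.

    The unit occupies sequence[pos:pos+5]; only the central trinucleotide
    is constrained.  Returns the unit regardless of distance (the caller
    applies budget caps).
    """
    if pos < 0 or pos + UNIT_LENGTH > len(sequence):
        raise ValueError(f"unit at {pos} out of range for sequence of length {len(sequence)}")
    core = sequence[pos + 1 : pos + 4]
    subs = frozenset(i + 1 for i in range(3) if core[i] != orientation.core[i])
    return PentamerUnit(
        start=pos,
        orientation=orientation,
        core_substitutions=len(subs),
        substituted_core_positions=subs,
    )


def _core_distance_table(seq_codes: np.ndarray, orientation: Orientation) -> np.ndarray:
    """Hamming distance of the core at each unit start (length L-4 array)."""
    L = seq_codes.size
    n_pos = L - UNIT_LENGTH + 1
    if n_pos <= 0:
        return np.zeros(0, dtype=np.int8)
    dist = np.zeros(n_pos, dtype=np.int8)
    for i, base in enumerate(orientation.core, start=1):
        dist += seq_codes[i : i + n_pos] != ord(base)
    return dist


def scan_record(record: PromoterRecord, params: ScanParams) -> MatchSet:
    """Find every distinct HSE alignment of `record` under `params`.

    Both starting orientations are searched at every position; the
    returned matches are canonicalized per (start, end, orientation
    sequence) and sorted by (start, end, first-unit orientation).
    """
    seq = record.sequence
    L = len(seq)
    n = params.n_units
    seq_codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    tables = {
        o: _core_distance_table(seq_codes, o)
        for o in (Orientation.GAA_type, Orientation.TTC_type)
    }
    n_pos = max(L - UNIT_LENGTH + 1, 0)

    # best alignment per (start, end, first orientation):
    # value = (subs_total, ins_total, gap vector)
    best: Dict[Tuple[int, int, Orientation], Tuple[int, int, Tuple[int, ...]]] = {}
    for first in (Orientation.GAA_type, Orientation.TTC_type):
        orients = orientation_sequence(first, n)
        for gaps in params.gap_vectors():
            ins_total = sum(gaps)
            span = UNIT_LENGTH * n + ins_total
            max_start = L - span
            if max_start < 0:
                continue
            starts = np.arange(max_start + 1)
            offset = 0
            total = np.zeros(starts.size, dtype=np.int16)
            ok = np.ones(starts.size, dtype=bool)
            for k in range(n):
                d = tables[orients[k]][offset : offset + starts.size]
                total += d
                if params.max_subs_per_unit < 3:
                    ok &= d <= params.max_subs_per_unit
                offset += UNIT_LENGTH + (gaps[k] if k < n - 1 else 0)
            ok &= total <= params.max_subs_total
            for s in np.nonzero(ok)[0]:
                key = (int(s), int(s) + span, first)
                cand = (int(total[s]), ins_total, gaps)
                cur = best.get(key)
                if cur is None or cand < cur:
                    best[key] = cand

    matches: List[HSEMatch] = []
    for (start, end, first), (subs_total, ins_total, gaps) in sorted(
        best.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
    ):
        orients = orientation_sequence(first, n)
        units = []
        offset = start
        for k in range(n):
            units.append(match_unit(seq, offset, orients[k]))
            offset += UNIT_LENGTH + (gaps[k] if k < n - 1 else 0)
        matches.append(
            HSEMatch(
                record_id=record.record_id,
                start=start,
                end=end,
                units=tuple(units),
                gap_insertions=gaps,
                substitutions_total=subs_total,
                insertions_total=ins_total,
                class_label=classify(n, subs_total, ins_total),
                matched_sequence=seq[start:end],
            )
        )
    return MatchSet(record_id=record.record_id, params=params, matches=tuple(matches))


def distance_to_tss(match: HSEMatch, record: PromoterRecord) -> int:
    """Resolve the match's TSS distance and 100-bp-window flag (in place).

    Distance is ``tss − end``: 0 means the match abuts the TSS, negative
    means it crosses or lies past it.  ``within_100bp`` is true only when
    the entire match lies inside the 100-bp window upstream of the TSS.
    """
    if match.record_id != record.record_id:
        raise ValueError(
            f"match belongs to {match.record_id!r}, not {record.record_id!r}"
        )
    dist = record.tss - match.end
    match.distance_to_tss = dist
    match.within_100bp = match.start >= record.tss - 100 and match.end <= record.tss
    return dist


def annotate_tss(matchset: MatchSet, record: PromoterRecord) -> MatchSet:
    """Resolve TSS distance for every match in the set."""
    for m in matchset.matches:
        distance_to_tss(m, record)
    return matchset


def _within_window(match: HSEMatch, record: PromoterRecord) -> bool:
    return match.start >= record.tss - 100 and match.end <= record.tss


def summarize(
    matchsets: Mapping[str, MatchSet], record: PromoterRecord
) -> ClassSummary:
    """Count matches by class across the four preset scans of one record.

    Each class preset contributes only the matches it labels with its own
    class: perfect hits found under a widened (imperfect) envelope keep
    their perfect label and are not double-counted as imperfect.  The
    union total is the plain sum of the four class counts; the distinct
    span count deduplicates overlapping class memberships by (start, end).
    """
    for ms in matchsets.values():
        if ms.record_id != record.record_id:
            raise ValueError(
                f"matchset for {ms.record_id!r} does not belong to record "
                f"{record.record_id!r}"
            )
    counts = {label: 0 for label in CLASS_LABELS}
    within = 0
    spans = set()
    for label in CLASS_LABELS:
        ms = matchsets.get(label)
        if ms is None:
            continue
        for m in ms.matches:
            if m.class_label != label:
                continue
            counts[label] += 1
            spans.add((m.start, m.end))
            if _within_window(m, record):
                within += 1
    return ClassSummary(
        record_id=record.record_id,
        count_canonical=counts["canonical"],
        count_minimal_perfect=counts["minimal_perfect"],
        count_imperfect_triple=counts["imperfect_triple"],
        count_imperfect_minimal=counts["imperfect_minimal"],
        count_within_100bp=within,
        union_total=sum(counts.values()),
        distinct_span_count=len(spans),
    )


def filter_nonoverlapping(matches: Sequence[HSEMatch]) -> List[HSEMatch]:
    """Keep a maximal non-overlapping subset chosen left-to-right per record."""
    kept: List[HSEMatch] = []
    last_end: Dict[str, int] = {}
    for m in sorted(matches, key=lambda m: (m.record_id, m.start, m.end)):
        if m.start >= last_end.get(m.record_id, 0):
            kept.append(m)
            last_end[m.record_id] = m.end
    return kept
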