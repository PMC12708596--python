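"""Motif taxonomy and scan-parameter envelope for heat-shock elements.

A heat-shock element (HSE) is the binding site of heat shock factor (HSF)
in heat-responsive promoters.  Its building block is the pentamer unit
``nGAAn`` — a 5-bp block whose first and fifth bases are unconstrained
wildcards and whose 3-bp core is ``GAA`` on one strand or its reverse
complement ``TTC`` on the other.  A functional element is a run of two or
three such units with strictly alternating orientation, tiled head-to-head:
the canonical element is the 15-mer ``nGAAnnTTCnnGAAn`` (or the
``nTTCn``-first phase), and the minimal, partially functional element is
the 10-mer ``nGAAnnTTCn`` / ``nTTCnnGAAn``.

Degenerate ("imperfect") elements tolerate a bounded number of
substitutions inside the unit cores and a bounded number of extra bases
inserted between adjacent units.  :class:`ScanParams` captures one such
tolerance envelope; :func:`classify` maps a match's unit count and
substitution/insertion load onto the four class labels used throughout
the package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

UNIT_LENGTH = 5
CORE_LENGTH = 3

#: Class labels; these exact strings appear in CLI options and reports.
CLASS_CANONICAL = "canonical"
CLASS_MINIMAL_PERFECT = "minimal_perfect"
CLASS_IMPERFECT_TRIPLE = "imperfect_triple"
CLASS_IMPERFECT_MINIMAL = "imperfect_minimal"
CLASS_LABELS = (
    CLASS_CANONICAL,
    CLASS_MINIMAL_PERFECT,
    CLASS_IMPERFECT_TRIPLE,
    CLASS_IMPERFECT_MINIMAL,
)


class Orientation(str, Enum):
    """Orientation of one pentamer unit on the scanned (sense) strand.

    ``GAA_type`` units carry the core ``GAA`` on the given strand;
    ``TTC_type`` units carry ``TTC`` (i.e. the HSF contact on the
    opposite strand).  Units within one element strictly alternate.
    """

    GAA_type = "GAA_type"
    TTC_type = "TTC_type"

    @property
    def core(self) -> str:
        return "GAA" if self is Orientation.GAA_type else "TTC"

    @property
    def flipped(self) -> "Orientation":
        return (
            Orientation.TTC_type
            if self is Orientation.GAA_type
            else Orientation.GAA_type
        )


def classify(n_units: int, substitutions_total: int, insertions_total: int) -> str:
    """Assign the HSE class label for a match's unit count and degeneracy.

    Three perfect units are *canonical*; two perfect units are
    *minimal_perfect*; any substitution or insertion makes the match
    *imperfect_triple* / *imperfect_minimal* according to its unit count.
    """
    if n_units not in (2, 3):
        raise ValueError(f"n_units must be 2 or 3, got {n_units}")
    if substitutions_total < 0 or insertions_total < 0:
        raise ValueError("substitution/insertion totals must be non-negative")
    if substitutions_total == 0 and insertions_total == 0:
        return CLASS_CANONICAL if n_units == 3 else CLASS_MINIMAL_PERFECT
    return CLASS_IMPERFECT_TRIPLE if n_units == 3 else CLASS_IMPERFECT_MINIMAL


@dataclass(frozen=True)
class PentamerUnit:
    """One aligned ``nGAAn``/``nTTCn`` unit within a match.

    ``substituted_core_positions`` uses 1-based positions within the
    3-bp core (1 = the G of GAA / the first T of TTC).  Wildcard
    positions (the flanking n's) never contribute substitutions.
    """

    start: int
    orientation: Orientation
    core_substitutions: int
    substituted_core_positions: frozenset

    def __post_init__(self) -> None:
        if self.core_substitutions != len(self.substituted_core_positions):
            raise ValueError("core_substitutions must equal the number of substituted positions")
        if not self.substituted_core_positions <= {1, 2, 3}:
            raise ValueError("substituted core positions must be within {1, 2, 3}")


@dataclass(frozen=True)
class ScanParams:
    """Tolerance envelope for one scan.

    Parameters
    ----------
    n_units:
        Number of alternating pentamer units (2 or 3).
    max_subs_total:
        Cap on core substitutions summed across all units of a match.
    max_ins_per_gap:
        Extra bases allowed in each inter-unit gap beyond adjacent tiling.
    max_ins_total:
        Cap on inserted bases summed across all gaps.
    max_subs_per_unit:
        Optional per-unit substitution cap (default 3 = unconstrained).
    """

    n_units: int
    max_subs_total: int
    max_ins_per_gap: int
    max_ins_total: int
    max_subs_per_unit: int = 3

    def __post_init__(self) -> None:
        if self.n_units not in (2, 3):
            raise ValueError(f"n_units must be 2 or 3, got {self.n_units}")
        if self.max_subs_total < 0 or self.max_ins_per_gap < 0 or self.max_ins_total < 0:
            raise ValueError("tolerance caps must be non-negative")
        if self.max_ins_per_gap > self.max_ins_total:
            raise ValueError("max_ins_per_gap must not exceed max_ins_total")
        if not 0 <= self.max_subs_per_unit <= CORE_LENGTH:
            raise ValueError("max_subs_per_unit must be within [0, 3]")

    @property
    def n_gaps(self) -> int:
        return self.n_units - 1

    def gap_vectors(self) -> Tuple[Tuple[int, ...], ...]:
        """All admissible inter-unit insertion vectors, lexicographic order."""
        return tuple(
            v
            for v in itertools.product(range(self.max_ins_per_gap + 1), repeat=self.n_gaps)
            if sum(v) <= self.max_ins_total
        )

    def span_length(self, insertions_total: int) -> int:
        return UNIT_LENGTH * self.n_units + insertions_total


#: Named parameter envelopes corresponding to the four HSE classes.
PRESETS = {
    CLASS_CANONICAL: ScanParams(3, 0, 0, 0),
    CLASS_MINIMAL_PERFECT: ScanParams(2, 0, 0, 0),
    CLASS_IMPERFECT_TRIPLE: ScanParams(3, 2, 2, 2),
    CLASS_IMPERFECT_MINIMAL: ScanParams(2, 1, 2, 2),
}


def orientation_sequence(first: Orientation, n_units: int) -> Tuple[Orientation, ...]:
    """The strictly alternating orientation assignment starting at `first`."""
    out = []
    cur = first
    for _ in range(n_units):
        out.append(cur)
        cur = cur.flipped
    return tuple(out)


@dataclass
class HSEMatch:
    """One detected element: span, unit layout and degeneracy accounting.

    Coordinates are 0-based half-open on the sense strand.  TSS-derived
    fields (``distance_to_tss``, ``within_100bp``) and ``rank`` start
    unset and are filled by :func:`hsescan.scanner.distance_to_tss` and
    :func:`hsescan.ranking.rank_matches`.
    """

    record_id: str
    start: int
    end: int
    units: Tuple[PentamerUnit, ...]
    gap_insertions: Tuple[int, ...]
    substitutions_total: int
    insertions_total: int
    class_label: str
    matched_sequence: str
    distance_to_tss: Optional[int] = None
    within_100bp: Optional[bool] = None
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.units)
        if n not in (2, 3):
            raise ValueError("a match must have 2 or 3 units")
        if len(self.gap_insertions) != n - 1:
            raise ValueError("gap_insertions must have n_units - 1 entries")
        if self.end - self.start != UNIT_LENGTH * n + self.insertions_total:
            raise ValueError("span length must equal 5*n_units + insertions_total")
        for a, b in zip(self.units, self.units[1:]):
            if b.orientation is not a.orientation.flipped:
                raise ValueError("unit orientations must strictly alternate")
        if self.substitutions_total != sum(u.core_substitutions for u in self.units):
            raise ValueError("substitutions_total must equal the sum over units")
        if self.insertions_total != sum(self.gap_insertions):
            raise ValueError("insertions_total must equal the sum of gap insertions")
        expected = classify(n, self.substitutions_total, self.insertions_total)
        if self.class_label != expected:
            raise ValueError(
                f"class_label {self.class_label!r} inconsistent with accounting ({expected!r})"
            )

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def first_orientation(self) -> Orientation:
        return self.units[0].orientation

    @property
    def subs_at_core_position1(self) -> int:
        """Substitutions hitting core position 1 (the G of GAA / first T of TTC)."""
        return sum(1 for u in self.units if 1 in u.substituted_core_positions)


@dataclass(frozen=True)
class ClassSummary:
    """Per-promoter match counts by class, TSS proximity and union total.

    ``union_total`` is the plain sum of the four class counts (overlapping
    spans counted in more than one class are not deduplicated);
    ``distinct_span_count`` additionally reports the number of distinct
    genomic spans for users who want a deduplicated view.
    """

    record_id: str
    count_canonical: int
    count_minimal_perfect: int
    count_imperfect_triple: int
    count_imperfect_minimal: int
    count_within_100bp: int
    union_total: int
    distinct_span_count: int

    def __post_init__(self) -> None:
        total = (
            self.count_canonical
            + self.count_minimal_perfect
            + self.count_imperfect_triple
            + self.count_imperfect_minimal
        )
        if self.union_total != total:
            raise ValueError("union_total must equal the sum of the four class counts")
        if self.count_within_100bp > self.union_total:
            raise ValueError("count_within_100bp cannot exceed union_total")
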