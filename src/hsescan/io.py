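"""Promoter FASTA / TSS-sidecar input and match-report output.

Coordinate conventions: 0-based half-open internally; the TSV report uses
1-based inclusive spans; BED6 output uses the standard 0-based half-open
convention.  The TSV is a faithful serialization — :func:`read_matches_tsv`
reconstructs every field of every match bit-exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

from Bio import SeqIO

from .model import (
    UNIT_LENGTH,
    HSEMatch,
    Orientation,
    PentamerUnit,
    classify,
    orientation_sequence,
)

VALID_BASES = frozenset("ACGTN")

TSV_COLUMNS = [
    "record_id",
    "start_1based",
    "end_1based_inclusive",
    "n_units",
    "first_unit_orientation",
    "substitutions_total",
    "substitution_positions",
    "insertions_per_gap",
    "insertions_total",
    "class",
    "distance_to_tss",
    "within_100bp_of_tss",
    "rank",
    "matched_sequence",
]


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter sequence with its TSS annotation.

    ``sequence`` is uppercase over {A,C,G,T,N}, written 5'→3' on the
    promoter sense strand.  ``tss`` is the 0-based position of the first
    transcribed base; for a pure upstream fragment this is one past the
    last promoter base (the default when no sidecar entry exists).
    """

    record_id: str
    sequence: str
    tss: int

    def __post_init__(self) -> None:
        bad = next(
            ((i, c) for i, c in enumerate(self.sequence) if c not in VALID_BASES), None
        )
        if bad is not None:
            raise ValueError(
                f"record {self.record_id!r}: invalid base {bad[1]!r} at offset {bad[0]}"
            )
        if not 0 <= self.tss <= len(self.sequence):
            raise ValueError(
                f"record {self.record_id!r}: tss {self.tss} outside [0, {len(self.sequence)}]"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_tss_table(path: Union[str, Path]) -> Dict[str, Union[int, str]]:
    """Parse the TSS sidecar: two tab-separated columns, '#' comments ignored.

    Values are 1-based TSS positions or the literal token ``end``.
    """
    table: Dict[str, Union[int, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            rid, value = parts[0].strip(), parts[1].strip()
            if rid in table:
                raise ValueError(f"{path}: duplicate TSS entry for record {rid!r}")
            table[rid] = value if value == "end" else int(value)
    return table


def read_promoters(
    fasta_path: Union[str, Path],
    tss_table_path: Optional[Union[str, Path]] = None,
) -> List[PromoterRecord]:
    """Read promoter records from FASTA, resolving TSS from an optional sidecar.

    Sidecar positions are 1-based and converted to the internal 0-based
    convention; the token ``end`` (and a missing entry) resolve to the
    sequence end.  Duplicate FASTA IDs, sidecar IDs absent from the FASTA,
    out-of-range TSS values and non-ACGTN characters are hard errors.
    """
    tss_table = read_tss_table(tss_table_path) if tss_table_path is not None else {}
    records: List[PromoterRecord] = []
    seen = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"{fasta_path}: duplicate record ID {rid!r}")
        seen.add(rid)
        seq = str(entry.seq).upper()
        length = len(seq)
        if rid in tss_table:
            raw = tss_table[rid]
            if raw == "end":
                tss = length
            else:
                if not 1 <= int(raw) <= length:
                    raise ValueError(
                        f"record {rid!r}: sidecar TSS {raw} outside [1, {length}]"
                    )
                tss = int(raw) - 1
        else:
            tss = length
        records.append(PromoterRecord(record_id=rid, sequence=seq, tss=tss))
    missing = set(tss_table) - seen
    if missing:
        raise ValueError(
            f"TSS sidecar IDs absent from FASTA: {', '.join(sorted(missing))}"
        )
    return records


def _encode_substitution_positions(match: HSEMatch) -> str:
    parts = []
    for i, unit in enumerate(match.units, start=1):
        if unit.substituted_core_positions:
            pos = "".join(str(p) for p in sorted(unit.substituted_core_positions))
            parts.append(f"u{i}p{pos}")
    return ";".join(parts) if parts else "-"


def _decode_substitution_positions(text: str, n_units: int) -> List[frozenset]:
    per_unit = [frozenset() for _ in range(n_units)]
    if text != "-":
        for token in text.split(";"):
            if not token.startswith("u") or "p" not in token:
                raise ValueError(f"malformed substitution token {token!r}")
            u_text, p_text = token[1:].split("p", 1)
            per_unit[int(u_text) - 1] = frozenset(int(c) for c in p_text)
    return per_unit


def _record_order(matches: Sequence[HSEMatch]) -> Dict[str, int]:
    order: Dict[str, int] = {}
    for m in matches:
        order.setdefault(m.record_id, len(order))
    return order


def sorted_for_report(matches: Sequence[HSEMatch]) -> List[HSEMatch]:
    """Sort rows grouped by record (input record order), then by span."""
    order = _record_order(matches)
    return sorted(matches, key=lambda m: (order[m.record_id], m.start, m.end))


def write_matches_tsv(matches: Sequence[HSEMatch], out_path: Union[str, Path]) -> None:
    """Write the tabular match report (tab-separated, with header)."""
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for m in sorted_for_report(matches):
            writer.writerow(
                [
                    m.record_id,
                    m.start + 1,
                    m.end,
                    m.n_units,
                    m.first_orientation.value,
                    m.substitutions_total,
                    _encode_substitution_positions(m),
                    ",".join(str(g) for g in m.gap_insertions),
                    m.insertions_total,
                    m.class_label,
                    "." if m.distance_to_tss is None else m.distance_to_tss,
                    "." if m.within_100bp is None else str(m.within_100bp).lower(),
                    "." if m.rank is None else m.rank,
                    m.matched_sequence,
                ]
            )


def read_matches_tsv(path: Union[str, Path]) -> List[HSEMatch]:
    """Re-parse a TSV match report into fully populated matches."""
    matches: List[HSEMatch] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected TSV header")
        for row in reader:
            rec = dict(zip(TSV_COLUMNS, row))
            n_units = int(rec["n_units"])
            start = int(rec["start_1based"]) - 1
            end = int(rec["end_1based_inclusive"])
            first = Orientation(rec["first_unit_orientation"])
            orients = orientation_sequence(first, n_units)
            gaps = tuple(int(g) for g in rec["insertions_per_gap"].split(","))
            sub_sets = _decode_substitution_positions(
                rec["substitution_positions"], n_units
            )
            units = []
            offset = start
            for k in range(n_units):
                units.append(
                    PentamerUnit(
                        start=offset,
                        orientation=orients[k],
                        core_substitutions=len(sub_sets[k]),
                        substituted_core_positions=sub_sets[k],
                    )
                )
                offset += UNIT_LENGTH + (gaps[k] if k < n_units - 1 else 0)
            matches.append(
                HSEMatch(
                    record_id=rec["record_id"],
                    start=start,
                    end=end,
                    units=tuple(units),
                    gap_insertions=gaps,
                    substitutions_total=int(rec["substitutions_total"]),
                    insertions_total=int(rec["insertions_total"]),
                    class_label=rec["class"],
                    matched_sequence=rec["matched_sequence"],
                    distance_to_tss=(
                        None if rec["distance_to_tss"] == "." else int(rec["distance_to_tss"])
                    ),
                    within_100bp=(
                        None
                        if rec["within_100bp_of_tss"] == "."
                        else rec["within_100bp_of_tss"] == "true"
                    ),
                    rank=None if rec["rank"] == "." else int(rec["rank"]),
                )
            )
    return matches


def bed_score(rank: Optional[int], n_ranked: int) -> int:
    """Scale a 1-based rank linearly to [0, 1000]; best rank maps to 1000."""
    if rank is None or n_ranked <= 0:
        return 0
    return round(1000 * (n_ranked - rank + 1) / n_ranked)


def write_matches_bed(matches: Sequence[HSEMatch], out_path: Union[str, Path]) -> None:
    """Write BED6: chrom=record_id, 0-based half-open span, name=class label.

    The score column is the match's rank position scaled to [0, 1000]
    within its record's rank pool.  Strand is always '+' because scanning
    is sense-strand only (the motif family is closed under reverse
    complement, so one strand covers both phases).
    """
    rows = sorted_for_report(matches)
    pool: Dict[str, int] = {}
    for m in rows:
        if m.rank is not None:
            pool[m.record_id] = max(pool.get(m.record_id, 0), m.rank)
    with open(out_path, "w") as fh:
        for m in rows:
            score = bed_score(m.rank, pool.get(m.record_id, 0))
            fh.write(
                f"{m.record_id}\t{m.start}\t{m.end}\t{m.class_label}\t{score}\t+\n"
            )


def write_fasta(records: Iterable[PromoterRecord], out_path: Union[str, Path], width: int = 60) -> None:
    """Write records as wrapped multi-FASTA (deterministic byte layout)."""
    with open(out_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
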