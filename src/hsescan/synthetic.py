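"""Seeded synthetic promoters with HSE motifs planted at known positions.

The generator emulates the simplest adequate null for a promoter scan:
an i.i.d. background with controllable GC content, into which concrete
elements of a requested class and degeneracy are spliced by overwriting
(wildcard positions keep the background base, so the planted element's
flanks look like background).  A truth table records every planted
element so detection can be audited for recall with exact span and
substitution/insertion accounting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .io import PromoterRecord, write_fasta
from .model import (
    CLASS_LABELS,
    UNIT_LENGTH,
    Orientation,
    PRESETS,
    ScanParams,
    classify,
    orientation_sequence,
)
from .oracle import oracle_scan
from .scanner import scan_record

BASE_ORDER = "ACGT"

TRUTH_COLUMNS = [
    "record_id",
    "position",
    "n_units",
    "first_orientation",
    "substitutions",
    "insertions",
    "expected_class",
]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted element.

    ``substitutions`` holds (unit index, core position 1-3, replacement
    base) triples; ``insertions`` holds the concrete inserted bases for
    each inter-unit gap ('' for an adjacent gap).
    """

    record_id: str
    position: int
    n_units: int
    first_orientation: Orientation
    substitutions: Tuple[Tuple[int, int, str], ...]
    insertions: Tuple[str, ...]
    expected_class: str

    def __post_init__(self) -> None:
        if self.n_units not in (2, 3):
            raise ValueError("n_units must be 2 or 3")
        if len(self.insertions) != self.n_units - 1:
            raise ValueError("insertions must have one entry per inter-unit gap")
        orients = orientation_sequence(self.first_orientation, self.n_units)
        seen = set()
        for u, p, b in self.substitutions:
            if not (0 <= u < self.n_units and p in (1, 2, 3)):
                raise ValueError(f"substitution ({u}, {p}) out of range")
            if (u, p) in seen:
                raise ValueError(f"duplicate substitution slot ({u}, {p})")
            seen.add((u, p))
            if b == orients[u].core[p - 1]:
                raise ValueError("replacement base must differ from the canonical base")
        params = PRESETS[self.expected_class]
        subs = len(self.substitutions)
        ins = sum(len(g) for g in self.insertions)
        if self.n_units != params.n_units or subs > params.max_subs_total:
            raise ValueError("substitution plan exceeds the class envelope")
        if ins > params.max_ins_total or any(
            len(g) > params.max_ins_per_gap for g in self.insertions
        ):
            raise ValueError("insertion plan exceeds the class envelope")
        if classify(self.n_units, subs, ins) != self.expected_class:
            raise ValueError("plan degeneracy inconsistent with expected_class")

    @property
    def insertions_total(self) -> int:
        return sum(len(g) for g in self.insertions)

    @property
    def span_length(self) -> int:
        return UNIT_LENGTH * self.n_units + self.insertions_total

    @property
    def end(self) -> int:
        return self.position + self.span_length


def sample_background(
    length: int,
    gc_fraction: float,
    seed: int,
    forbid_matches_under: Optional[ScanParams] = None,
    max_attempts: int = 200,
) -> str:
    """Draw an i.i.d. background with P(G)=P(C)=gc/2 and P(A)=P(T)=(1−gc)/2.

    With ``forbid_matches_under``, rejection-sample (checked by the
    brute-force oracle) until the sequence is free of matches under those
    parameters; exceeding the attempt cap is a hard error.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    for _ in range(max_attempts):
        idx = rng.choice(4, size=length, p=p)
        seq = "".join(BASE_ORDER[i] for i in idx)
        if forbid_matches_under is None:
            return seq
        probe = PromoterRecord(record_id="_bg", sequence=seq, tss=length)
        if len(oracle_scan(probe, forbid_matches_under)) == 0:
            return seq
    raise RuntimeError(
        f"no motif-free background found in {max_attempts} attempts; "
        "loosen the forbidden envelope or shorten the sequence"
    )


def render_motif(truth: PlantedTruth, background: str) -> str:
    """The concrete planted span, with wildcards taken from the background."""
    orients = orientation_sequence(truth.first_orientation, truth.n_units)
    replacements = {(u, p): b for u, p, b in truth.substitutions}
    chars: List[str] = []
    offset = truth.position
    for k in range(truth.n_units):
        core = list(orients[k].core)
        for p in (1, 2, 3):
            if (k, p) in replacements:
                core[p - 1] = replacements[(k, p)]
        chars.append(background[offset])  # 5' wildcard kept from background
        chars.extend(core)
        chars.append(background[offset + 4])  # 3' wildcard kept from background
        offset += UNIT_LENGTH
        if k < truth.n_units - 1:
            chars.append(truth.insertions[k])
            offset += len(truth.insertions[k])
    return "".join(chars)


def embed_hse(background: str, truth: PlantedTruth) -> str:
    """Splice the concrete motif into the background by overwriting.

    The background length is unchanged; only the motif's internal
    insertions lengthen the planted span itself.
    """
    if truth.end > len(background):
        raise ValueError(
            f"planted span [{truth.position}, {truth.end}) overflows "
            f"background of length {len(background)}"
        )
    motif = render_motif(truth, background)
    return background[: truth.position] + motif + background[truth.end :]


def _draw_truth_plan(
    rng: np.random.Generator, record_id: str, position: int, expected_class: str
) -> PlantedTruth:
    """Random degeneracy plan within the class envelope (s + i ≥ 1 if imperfect)."""
    params = PRESETS[expected_class]
    n = params.n_units
    first = (Orientation.GAA_type, Orientation.TTC_type)[rng.integers(2)]
    orients = orientation_sequence(first, n)
    while True:
        n_subs = int(rng.integers(0, params.max_subs_total + 1))
        gaps = tuple(
            int(rng.integers(0, params.max_ins_per_gap + 1)) for _ in range(n - 1)
        )
        if sum(gaps) > params.max_ins_total:
            continue
        if params.max_subs_total + params.max_ins_total > 0 and n_subs + sum(gaps) == 0:
            continue  # imperfect classes require at least one deviation
        break
    slots = [(u, p) for u in range(n) for p in (1, 2, 3)]
    chosen = [slots[i] for i in rng.choice(len(slots), size=n_subs, replace=False)]
    subs = tuple(
        (u, p, str(rng.choice([b for b in BASE_ORDER if b != orients[u].core[p - 1]])))
        for u, p in sorted(chosen)
    )
    insertions = tuple(
        "".join(str(b) for b in rng.choice(list(BASE_ORDER), size=g)) for g in gaps
    )
    return PlantedTruth(
        record_id=record_id,
        position=position,
        n_units=n,
        first_orientation=first,
        substitutions=subs,
        insertions=insertions,
        expected_class=expected_class,
    )


def _truth_recovered(truth: PlantedTruth, record: PromoterRecord) -> bool:
    """Exact-recovery check: span, orientation and accounting all equal."""
    ms = scan_record(record, PRESETS[truth.expected_class])
    want_subs: Dict[int, frozenset] = {u: frozenset() for u in range(truth.n_units)}
    grouped: Dict[int, set] = {}
    for u, p, _ in truth.substitutions:
        grouped.setdefault(u, set()).add(p)
    for u, ps in grouped.items():
        want_subs[u] = frozenset(ps)
    for m in ms.matches:
        if (
            m.start == truth.position
            and m.end == truth.end
            and m.first_orientation is truth.first_orientation
            and m.class_label == truth.expected_class
            and m.gap_insertions == tuple(len(g) for g in truth.insertions)
            and all(
                u.substituted_core_positions == want_subs[k]
                for k, u in enumerate(m.units)
            )
        ):
            return True
    return False


def _place_spans(
    rng: np.random.Generator, record_length: int, span_lengths: Sequence[int], margin: int = 5
) -> List[int]:
    """Non-overlapping random placements (with a small separating margin)."""
    for _ in range(500):
        placed: List[Tuple[int, int]] = []
        positions: List[int] = []
        ok = True
        for span in span_lengths:
            if record_length < span:
                ok = False
                break
            for _ in range(200):
                pos = int(rng.integers(0, record_length - span + 1))
                if all(
                    pos + span + margin <= a or b + margin <= pos for a, b in placed
                ):
                    placed.append((pos, pos + span))
                    positions.append(pos)
                    break
            else:
                ok = False
            if not ok:
                break
        if ok:
            return positions
    raise ValueError(
        "cannot place the requested planted spans without overlap; "
        "use fewer/shorter truths or longer records"
    )


def encode_truth_row(truth: PlantedTruth) -> List[str]:
    subs = (
        ";".join(f"u{u}p{p}>{b}" for u, p, b in truth.substitutions)
        if truth.substitutions
        else "-"
    )
    ins = ";".join(g if g else "." for g in truth.insertions)
    return [
        truth.record_id,
        str(truth.position),
        str(truth.n_units),
        truth.first_orientation.value,
        subs,
        ins,
        truth.expected_class,
    ]


def read_truth_table(path: Union[str, Path]) -> List[PlantedTruth]:
    truths: List[PlantedTruth] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth-table header")
        for line in fh:
            rec = dict(zip(TRUTH_COLUMNS, line.rstrip("\n").split("\t")))
            subs: List[Tuple[int, int, str]] = []
            if rec["substitutions"] != "-":
                for token in rec["substitutions"].split(";"):
                    head, base = token.split(">")
                    u_text, p_text = head[1:].split("p")
                    subs.append((int(u_text), int(p_text), base))
            insertions = tuple(
                "" if g == "." else g for g in rec["insertions"].split(";")
            )
            truths.append(
                PlantedTruth(
                    record_id=rec["record_id"],
                    position=int(rec["position"]),
                    n_units=int(rec["n_units"]),
                    first_orientation=Orientation(rec["first_orientation"]),
                    substitutions=tuple(subs),
                    insertions=insertions,
                    expected_class=rec["expected_class"],
                )
            )
    return truths


def generate_benchmark(
    n_records: int,
    record_length: int,
    truths_per_record: int,
    class_mix: Dict[str, float],
    seed: int,
    out_dir: Union[str, Path],
    gc_fraction: float = 0.5,
) -> Tuple[Path, Path]:
    """Write a planted-motif benchmark: multi-FASTA plus a truth table.

    Outputs are pure functions of the arguments.  Each record is verified
    after embedding: every planted truth must be recovered by the scanner
    under its class preset with exact span and accounting; a record whose
    context spoils a plant (e.g. an alternative gap placement with fewer
    substitutions over the same span) is redrawn.
    """
    if n_records < 1 or truths_per_record < 0 or record_length < 1:
        raise ValueError("n_records, record_length must be >= 1; truths_per_record >= 0")
    bad = set(class_mix) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class labels in mix: {sorted(bad)}")
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class-mix proportions must sum to 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    labels = [c for c in CLASS_LABELS if class_mix.get(c, 0) > 0]
    probs = np.array([class_mix[c] for c in labels])

    records: List[PromoterRecord] = []
    truths: List[PlantedTruth] = []
    for r in range(n_records):
        record_id = f"synth_{r + 1:03d}"
        for attempt in range(50):
            classes = [
                labels[i]
                for i in rng.choice(len(labels), size=truths_per_record, p=probs)
            ]
            bg_seed = int(rng.integers(0, 2**31))
            background = sample_background(record_length, gc_fraction, bg_seed)
            # draw plans first so span lengths are known for placement
            plans = [
                _draw_truth_plan(rng, record_id, 0, cls) for cls in classes
            ]
            positions = _place_spans(
                rng, record_length, [t.span_length for t in plans]
            )
            rec_truths = [
                PlantedTruth(
                    record_id=t.record_id,
                    position=pos,
                    n_units=t.n_units,
                    first_orientation=t.first_orientation,
                    substitutions=t.substitutions,
                    insertions=t.insertions,
                    expected_class=t.expected_class,
                )
                for t, pos in zip(plans, positions)
            ]
            seq = background
            for t in rec_truths:
                seq = embed_hse(seq, t)
            record = PromoterRecord(record_id=record_id, sequence=seq, tss=len(seq))
            if all(_truth_recovered(t, record) for t in rec_truths):
                records.append(record)
                truths.extend(sorted(rec_truths, key=lambda t: t.position))
                break
        else:
            raise RuntimeError(
                f"could not build a verifiable record for {record_id} in 50 attempts"
            )

    fasta_path = out_dir / "benchmark.fasta"
    truth_path = out_dir / "benchmark_truth.tsv"
    write_fasta(records, fasta_path)
    with open(truth_path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write("\t".join(encode_truth_row(t)) + "\n")
    return fasta_path, truth_path
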