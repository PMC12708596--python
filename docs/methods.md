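# Methods

## The search model

A heat-shock element is modelled as a run of `n_units ∈ {2, 3}` pentamer
units tiled head-to-head on the sense strand.  Each unit occupies exactly
5 bp — wildcard, 3-bp core, wildcard — with the core equal to `GAA`
(GAA_type) or `TTC` (TTC_type), and orientations strictly alternate along
the run.  Head-to-head alternation is the only repeat geometry searched;
same-orientation tandem variants are out of scope.  An alignment is the
triple (start position, first-unit orientation, insertion vector): units
are adjacent by default, and the insertion vector allows up to
`max_ins_per_gap` extra bases in each inter-unit gap, with the sum capped
by `max_ins_total`.  Core degeneracy is Hamming distance: each unit's
observed trinucleotide is compared with its canonical core, wildcard
positions never count, and the summed distance must not exceed
`max_subs_total` (optionally also a per-unit cap, default unconstrained).
An `N` in a core position always counts as a substitution (conservative
calling); `N` at wildcard positions is free.

The substitution budget is interpreted as a **total across all unit
cores**, not per unit: this reading reproduces the four class envelopes
most parsimoniously, and the per-unit cap remains available for users
who want the stricter reading.  The insertion budget is capped both per
gap (2) and in total (2) by default, so default match lengths never
exceed `5·n_units + 2`.

Classes partition the envelope: `(3, 0 subs, 0 ins)` → `canonical`;
`(2, 0, 0)` → `minimal_perfect`; any deviation → `imperfect_triple` /
`imperfect_minimal` by unit count.  The four presets are
canonical = (3 units, 0 subs, 0/0 ins), minimal_perfect = (2, 0, 0/0),
imperfect_triple = (3, ≤2, ≤2/≤2), imperfect_minimal = (2, ≤1, ≤2/≤2).
The triple envelope tolerates two substitutions while the minimal
envelope tolerates one: a shorter site carries less redundancy, so the
same absolute degeneracy is a proportionally larger perturbation.

### Sense-strand-only scanning

The reverse complement of `nGAAnnTTCnnGAAn` is `nTTCnnGAAnnTTCn`: the
pattern family is closed under reverse complement.  Scanning one strand
therefore finds every element; users should not scan both strands, which
would report every site twice.  The test suite verifies the mirror
property explicitly (spans map to `(L − end, L − start)`).

### Canonicalization and counting

Two alignments can share (start, end, orientation sequence) and differ
only in where the inserted bases sit between units.  Only one canonical
alignment is kept per such span: minimal total substitutions, then
minimal total insertions, then the lexicographically smallest insertion
vector.  Across *different* spans no merging occurs — overlapping and
nested matches are all reported, because per-promoter element tallies in
this field count overlapping degenerate sites individually.  An optional
post-filter (`--no-overlap`) keeps a maximal non-overlapping subset
chosen left-to-right for users who want disjoint sites.

Per-promoter summaries count, for each class preset, the matches that
preset labels with its own class; a perfect hit rediscovered under a
widened envelope keeps its perfect label and is never double-counted as
imperfect.  The union total is the plain sum of the four class counts —
overlapping spans counted in more than one class are deliberately not
deduplicated, matching how combined per-promoter totals are convention-
ally reported as sums of per-class tallies; a `distinct_span_count`
column provides the deduplicated view.  A consequence worth knowing:
every canonical 15-mer nests two perfect minimal 10-mers, so a promoter
with one canonical element summarizes to union_total 3, not 1.

### TSS annotation and ranking

TSS positions are caller-supplied (sidecar table, 1-based, `end`
allowed); the default is the sequence end, i.e. the record is assumed to
be a pure upstream fragment.  How a promoter's TSS was annotated is
deliberately externalized — the method itself does not locate TSSs.
Distance is `tss − end` (0 = abutting; negative = crossing or past the
TSS), and the 100-bp-proximal flag requires **full containment** of the
match in the window `[tss − 100, tss]`; partial overlap does not count.
Matches may extend past the TSS when the record contains transcribed
sequence; they simply get negative distances and `within_100bp = false`.

Ranking is ordinal, ascending by the key (total core substitutions,
substitutions at core position 1, total insertions, |TSS distance|,
start).  Position-1 substitutions (the G of GAA / first T of TTC) are
treated as the most disruptive substitution type; because no definitive
substitution-type hierarchy is established, the key composition is a
user-facing knob (`--rank-key`), not ground truth.  |distance| is used
so that proximity ranks higher regardless of sign.  The start tie-break
makes ranking a deterministic permutation 1..n.

## The brute-force oracle

`hsescan.oracle` re-realizes the search as exhaustive pattern expansion:
every combination of first orientation × substitution plan (position and
replacement base, within the budgets) × insertion vector becomes one
fixed-length degenerate template, and each template is slid over every
position with direct literal comparison (wildcards match any base).
Replacement bases are drawn from {A, C, G, T, N} minus the canonical
base; literal positions match by exact equality, which reproduces the
scanner's N semantics (an N in a core never matches the canonical
literal, i.e. it costs a substitution).  The oracle shares no matching
code with the scanner — the scanner sums precomputed per-position core
Hamming distances, the oracle compares explicit substrings — and applies
the same canonicalization, so the two outputs are comparable
match-for-match.  A template cap (default 10⁶) guards combinatorial
blow-up; the widest preset expands to a few thousand templates.  The
oracle is test-facing (and reachable via a hidden `--use-oracle` scan
flag); it is transparent rather than fast.

## The synthetic generator

`sample_background` draws i.i.d. bases with P(G) = P(C) = gc/2 — the
simplest null adequate for recall and false-positive characterization.
It deliberately does **not** model dinucleotide composition, repeat
structure, chromatin or any promoter grammar of real plant sequences, so
passing recall/specificity tests demonstrates algorithmic correctness of
the search, not performance on genomic backgrounds.  An optional
rejection-sampling mode (verified by the oracle) yields backgrounds free
of matches under a given envelope, with a hard error when the attempt
cap is exhausted (e.g. a GC-balanced 500-mer essentially always contains
imperfect-minimal hits, so forbidding them is infeasible).

`embed_hse` splices a concrete element into the background by
**overwriting** (wildcards and flanks keep the background base), so
record length is unchanged and all planted coordinates remain valid;
only the element's own internal insertions lengthen its span.
`generate_benchmark` places the requested spans non-overlapping (5-bp
margin), embeds them, and then verifies each plant by scanning: with
inter-unit insertions, the surrounding context can occasionally admit an
alternative gap placement with fewer substitutions over the same span,
which canonicalization would prefer, changing the accounting.  Records
where any plant fails exact recovery are redrawn (bounded retries), so
100% recall with exact accounting holds by construction, deterministically
per seed.  Default benchmark conditions used by the acceptance checks:
300-bp records, GC 0.5, equal mixture of the four classes.

## Numerical and interface choices

- Coordinates: 0-based half-open internally; 1-based inclusive in the
  TSV; BED6 is 0-based half-open.  The TSV is a lossless serialization
  (bit-exact round trip), which is why it is written/parsed with the csv
  module rather than a dataframe layer.
- BED score: rank scaled linearly to [0, 1000] within each record's rank
  pool (best rank → 1000); unranked matches score 0.  Strand is always
  `+` (see sense-strand scanning above).
- Match sorting: (record input order, start, end) in reports;
  (start, end, first orientation) within a match set.
- Determinism: all generator outputs are pure functions of their
  arguments; the CLI pipeline simulate → scan → summarize is bytewise
  reproducible per seed.
- Exit codes: 0 success, 2 usage/configuration error, 1 runtime error;
  stdout carries only data/paths.
- Problem sizes for the property checks (chosen as comfortably
  informative for a 300-bp promoter scale): oracle equivalence on 100
  seeded sequences × 36 parameter combinations; recall on 50 records ×
  4 plants; symmetry on 50 and monotonicity on 20 sequences.

## Known limitations

- No position-weight-matrix or HSF-affinity scoring; ranking is ordinal
  and its substitution-type component is a modelling choice, not a
  measured hierarchy.
- IUPAC ambiguity codes beyond N are rejected rather than expanded.
- Per-promoter counts on real promoters depend on the exact fragment
  boundaries and TSS annotation supplied by the caller; the package does
  not attempt to reconstruct either.
- The scan enumerates all alignments within the envelope; distinct
  orientation phases over the same locus are distinct matches by design,
  which inflates counts relative to tools that merge per locus.
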