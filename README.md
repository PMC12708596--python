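# hsescan

Detection, classification and ranking of heat-shock elements (HSEs) in
promoter sequences.

HSEs are the binding sites of heat shock factor (HSF) in heat-responsive
promoters — for example the small heat shock protein (*sHSP*) promoters
used as heat-inducible expression tools in plant biotechnology.  The
element is built from the pentamer unit `nGAAn` (n = any base); a
functional site is a run of two or three such units with strictly
alternating orientation:

- **canonical** — three alternating units, `nGAAnnTTCnnGAAn` or
  `nTTCnnGAAnnTTCn` (15 bp), no core mismatches, no insertions;
- **minimal_perfect** — two alternating units, `nGAAnnTTCn` or
  `nTTCnnGAAn` (10 bp), a partially functional site;
- **imperfect_triple** / **imperfect_minimal** — 3- or 2-unit matches
  carrying 1–2 substitutions in the GAA/TTC cores and/or 1–2 bp inserted
  between adjacent units.

Because HSEs tolerate considerable degeneracy, generic plant
*cis*-element databases under-report them.  `hsescan` performs the
explicit degenerate search: every alignment
(start, first-unit orientation, insertion vector) whose total core
substitutions and insertions stay within a configurable envelope is
reported, annotated with its distance to the transcription start site
(TSS), classified, and ranked by predicted functionality — fewer core
substitutions first (position-1 hits, the G of GAA, counted as most
disruptive), then fewer insertions, then TSS proximity.

Scanning is sense-strand only: the pattern family is closed under
reverse complement, so one strand finds every element and double-scanning
would double count.

The package also ships

- a seeded **synthetic generator** (`hsescan simulate` /
  `hsescan.synthetic`) producing GC-controlled random promoters with
  elements of known class and degeneracy planted at known positions,
  plus a truth table for recall audits, and
- an independent **brute-force oracle** (`hsescan.oracle`) that expands
  the search into explicit degenerate templates and slides each one over
  the sequence — sharing no matching code with the scanner, so exact
  agreement between the two is meaningful evidence of correctness.

## Worked example

A 59-bp demo promoter containing a perfect canonical element and a
separate downstream minimal element, with the TSS annotated at base 55
(1-based) via the sidecar:

```sh
printf '>pHSP_demo\nGCGTCCTGAGATCAGAACATTCGAGAATCGTACGGATCCTTTCTAGAACTGGCATCCGT\n' > promoter.fa
printf 'pHSP_demo\t55\n' > tss.tsv
hsescan scan --fasta promoter.fa --tss tss.tsv --out . --preset canonical --preset minimal_perfect
```

`promoter.hse.tsv` (tab-separated; spans are 1-based inclusive):

```
record_id  start_1based  end_1based_inclusive  n_units  first_unit_orientation  substitutions_total  substitution_positions  insertions_per_gap  insertions_total  class            distance_to_tss  within_100bp_of_tss  rank  matched_sequence
pHSP_demo  14            23                    2        GAA_type                0                    -                       0                   0                 minimal_perfect  31               true                 4     AGAACATTCG
pHSP_demo  14            28                    3        GAA_type                0                    -                       0,0                 0                 canonical        26               true                 2     AGAACATTCGAGAAT
pHSP_demo  19            28                    2        TTC_type                0                    -                       0                   0                 minimal_perfect  26               true                 3     ATTCGAGAAT
pHSP_demo  40            49                    2        TTC_type                0                    -                       0                   0                 minimal_perfect  5                true                 1     TTTCTAGAAC
```

The canonical 15-mer at bases 14–28 is found once, together with the two
perfect minimal 10-mers it necessarily nests (nested hits are reported,
not collapsed), and the separate minimal element at 40–49.
`distance_to_tss` counts the bases between the last matched base and the
TSS; `rank` orders matches by (substitutions, position-1 substitutions,
insertions, |TSS distance|), so the TSS-proximal minimal element ranks
first among the perfect hits.  `hsescan summarize` aggregates the same
scans into per-promoter class counts, the count of matches lying wholly
within 100 bp upstream of the TSS, a union total (the plain sum of the
four class counts) and a deduplicated distinct-span count:

```
record_id  count_canonical  count_minimal_perfect  count_imperfect_triple  count_imperfect_minimal  count_within_100bp  union_total  distinct_span_count
pHSP_demo  1                3                      8                       4                        16                  16           16
```

Other entry points: `hsescan simulate --out DIR --seed N` writes a
planted-motif benchmark (FASTA + truth table), `hsescan rank` re-ranks an
existing report with a different key, and `--bed` adds BED6 output whose
score column scales rank to [0, 1000].

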