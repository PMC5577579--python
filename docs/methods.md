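# Methods

This note records the modelling choices, defaults and known limitations
of `venomhmm`. Everything stated here is implemented and exercised by the
test suite; no empirical claim is made beyond what the tests and
`scripts/acceptance.py` compute.

## Profile HMM construction

A model with `M` match states stores match emissions (`M × 20`), insert
emissions (`(M+1) × 20`, node 0 = the flanking insert before match 1) and
per-node transition groups `M→{M,I,D}`, `I→{M,I}`, `D→{M,D}` (seven
probabilities per node, constants `T_MM … T_DD`).

* **Match-column rule.** An alignment column becomes a match state when
  its gap fraction is strictly below 0.5; other columns contribute insert
  emissions and insert transitions.
* **Pseudocounts.** Emissions: `P(a) = (c_a + w·q_a) / (n + w)` with
  weight `w = 1` and background `q` (uniform 1/20 by default, a
  Swiss-Prot-style composition table is available as an option). So a
  column of three identical cysteines gives
  `(3 + 0.05) / 4 = 0.7625` for C. Transitions use the same mix with the
  uniform prior over the legal options in each group:
  `(c + w/g) / (total + w)`, `g` = group size (3 for `M→`, 2 for `I→`
  and `D→`).
* **Boundary conventions.** Node 0's `M→` row models the begin state;
  the final node's `M→M` entry stores `M→End`; `D→M` at the last node is
  fixed to 1. Delete state 1 is unreachable and insert states exist only
  between matches (`I_1 … I_{M-1}`), matching the enumerated path space
  used as the oracle.

## Scoring

Scores are **log2-odds (bits)** against an i.i.d. background. The main
statistic is a *local best-domain Viterbi* score: the maximum over all
contiguous query segments, all model entry/exit match states, and all
state paths, of `log2 P(segment, path | model) − log2 P(segment | bg)`.
Local entry and exit at any match state are **free** (probability 1), so
a query equal to a near-deterministic consensus of length `L` scores
close to `L·log2 20` bits. Ambiguous residues (X, B, Z, U) contribute 0
bits. A model *matches* a sequence iff its best-domain score is strictly
positive; otherwise no hit is reported.

A Forward variant (log2-sum over the same local path space, via
`logaddexp2`) is provided as a diagnostic and is always ≥ the Viterbi
score. Both algorithms are validated against an independent brute-force
path enumerator (`tests/oracle.py`) exhaustively over all sequences of
length ≤ 4 on a reduced 3-letter alphabet against models with ≤ 3 match
states; agreement is required to 1e-9 bits (observed ≈ 1e-14).

## Competition

`compete` scores every model against every query and keeps, per query,
the model with the **highest bit score**; ties break to the
lexicographically smallest model name, which also makes the output
invariant under permutation of the model database (tested). Unmatched
queries are omitted unless `--allseq` is given. Alternative matches are
encoded `(from-to#name#score)` with one decimal, sorted by descending
score then name. The `--hsout` table is a domtblout-style whitespace
table carrying the bit score in column 14.

## Profile database format

Models are serialized in a HMMER3-flavoured ASCII dialect: header line
`HMMER3/f [venomhmm profile format]`, `NAME`/`DESC`/`LENG`/`ALPH amino`
fields, a nonstandard `BACKG` line recording the 20 background
frequencies, then per-node blocks of negative natural logs with 5
decimals (`*` = probability 0), terminated by `//`. Because probabilities
are stored as rounded negative logs, the format is **canonical**: writing
a re-read database reproduces it byte for byte, and a write/read
round-trip agrees with the original within 1e-3 in natural-log space
(observed ≈ 5e-6). The dialect is self-contained; it is not guaranteed to
be consumed by other HMMER3 readers (the `BACKG` line is an extension).

## Structural grouping

* **Framework.** Adjacent cysteines merge into one token, e.g. six
  cysteines with a fused pair render as `C-C-CC-C-C`.
* **Spacing signature.** Exact inter-cysteine gap lengths, rendered
  `C-X(6)-C-X(5)-C-C-X(4)-C-X(8)-C`.
* **ICK range pattern.** `X(6)-C-X(4,6)-C-X(4,9)-C-C-X(2,10)-C-X(3,14)-
  C-X(1,16)` — fixed leading length, bounded internal gaps, bounded
  trailing tail.
* **Grouping key.** Framework rendering plus the exact gap tuple;
  cysteine-free sequences form a single `no-framework` group. With
  `split_on_properties` the residue-property class of the ±3 window
  around each fused `CC` token joins the key. Property classes:
  charged `DEKRH`, polar-uncharged `STNQYC`, hydrophobic `AVLIMFW`,
  small `GP`.
* **Core trimming.** `trim_msa_to_core` keeps the column span from the
  first to the last column whose cysteine fraction exceeds 0.5, drops
  fragment rows that are > 50% gaps inside that span, and deduplicates
  identical ungapped peptides. If no column qualifies it raises an error
  advising the caller to skip trimming.

Grouping on exact gap tuples deliberately errs on the side of
over-splitting: two family members that differ by a single loop-length
indel land in different groups. That is the intended behaviour for
building tight classifiers; merging such groups is an upstream curation
decision, not something the partition guesses at.

## Synthetic benchmark

The generator produces toxin-like families for end-to-end testing, not
realistic venom data.

* Each family has a fixed consensus: a scaffold (an exact spacing tuple
  with fixed leading/trailing flank lengths) filled from a loop-class
  palette, or a 25-residue linear cationic peptide. Palettes contain no
  cysteine, so the framework is invariant under mutation.
* Members are consensus copies with i.i.d. substitutions at
  `mutation_rate = 0.1`, always to a non-cysteine residue;
  `mutation_rate = 0` yields identical members. Family seeds derive
  deterministically from the benchmark seed.
* The default benchmark has 10 families × 30 members: three fixed
  huwentoxin-like spacings (`[6,5,0,4,8]`, `[6,6,0,4,6]`, `[6,5,0,4,7]`),
  six distinct tuples drawn (seeded) from inside the ICK gap ranges with
  fixed per-family flanks, and one linear family. Exact tuples are used
  so that exact-gap grouping recovers precisely 10 groups and members
  align trivially (equal lengths) — the benchmark isolates the
  group → build → compete pipeline from alignment construction, which
  the package does not perform.
* `run_benchmark` groups the 200 training sequences, builds one profile
  per group, competes on the 100 held-out sequences and reports
  sensitivity (fraction classified into their true family). The
  acceptance threshold is ≥ 0.95; the observed value at the default
  settings is 1.0. Generator parameters are study conditions fixed in
  advance, not tuned.

What the generator does **not** emulate: real mutation processes (no
indels, no position-specific rates, no phylogenetic correlation between
members), signal/propeptide regions, or overlapping families with shared
loops. Reported sensitivities therefore characterise the pipeline's
internal consistency, not expected performance on natural sequences.

## Nomenclature registry

Classifier names follow `^(SC|SN|VP)_\d{2}_\d{2}$` (toxin type, family,
subgroup; subgroup `00` marks the family-wide model). The packaged
registry table stores name ranges (`A to B`) with legacy family
annotations and InterPro/Pfam identifiers; expansion yields 21 SC, 170 SN
and 28 VP classifiers (219 total). A second packaged table records the
legacy signature-based annotation inventory (1036 sequences across 23
distinct Pfam models). Both fixtures are integrity-checked by SHA-256 at
load time. `hierarchy_check` inspects competition output: a win by an
`xx_nn_00` model with no level-3 sibling among the alternatives flags a
new-subgroup candidate.

## Tolerances and problem sizes

| check | size | tolerance | observed |
| --- | --- | --- | --- |
| Viterbi/Forward vs enumeration | M ≤ 3, L ≤ 4, 3-letter alphabet | 1e-9 bits | ~1e-14 |
| profile DB round trip | 10 random models, M ∈ [2,10) | 1e-3 (ln space) | ~5e-6 |
| benchmark sensitivity | 10 families, 200 train / 100 test | ≥ 0.95 | 1.0 |

## Limitations

* No alignment construction: multi-sequence input to `build` must
  already be aligned (the benchmark sidesteps this by equal-length
  families).
* Single best domain per model-query pair; multi-domain architectures
  are out of scope.
* No E-values or extreme-value calibration; the match criterion is the
  raw `bit score > 0` rule, and scores are comparable across models only
  through the competition's shared background.
* The profile file dialect is self-describing but not interchange-tested
  against external HMMER3 consumers.
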