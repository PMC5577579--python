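# venomhmm

Competition-based profile HMM classification of spider venom peptides and
proteins.

Spider venoms contain hundreds of peptides whose structural organisation —
above all the arrangement of cysteines forming disulfide scaffolds such as
the inhibitor cystine knot (ICK) — defines natural families. Profile HMMs
built for tight structural groups are sensitive classifiers, but closely
related models inevitably all match the same peptide, so a plain database
search drowns the user in overlapping hits. `venomhmm` addresses both
sides of the problem, for toxinologists and transcriptome annotators:

* **Classifier construction** — partition sequences into structural
  conservation groups by cysteine framework (`C-C-CC-C-C`),
  inter-cysteine spacing (`C-X(6)-C-X(5)-C-C-X(4)-C-X(8)-C`) and residue
  properties, trim alignments to the core cysteine motif, and estimate a
  profile HMM per group.
* **Competition classification** — score every profile against every
  query with a local best-domain Viterbi algorithm and report, per
  sequence, only the winning classifier (the `hmmcompete` report format),
  with optional alternatives, matched regions and description lines.
* **Nomenclature** — the packaged three-level SC/SN/VP registry
  (21 + 170 + 28 = 219 classifier names with their legacy ToxProt family
  annotations) with parsing, range expansion and hierarchy advice
  (a win by a family-wide `xx_nn_00` model with no specific sibling
  flags a candidate for a new level-3 group).

## The model

A profile HMM with `M` match states carries match emissions `e_k(a)`,
insert emissions, and per-node transitions `M→M, M→I, M→D, I→M, I→I,
D→M, D→D`. Parameters are estimated from an alignment by background-mixed
pseudocounts,

```
P(a | state) = (c_a + w · q_a) / (n + w)
```

with counts `c_a`, background `q_a` (uniform 1/20 by default) and weight
`w = 1`. Columns with gap fraction < 0.5 become match states. A query
segment's **bit score** is

```
S = log2  P(segment, best path | model) / P(segment | background)
```

maximised over all contiguous segments and model sub-paths (free uniform
local entry/exit over match states). A model *matches* a sequence when
`S > 0`; the competition winner is the model with the highest best-domain
bit score (ties break to the lexicographically smallest name). A Forward
variant (log-sum over all paths) is provided as a diagnostic. Both
algorithms are validated against exhaustive path enumeration.

## Worked example

Build two profiles from huwentoxin-1-group-like alignments (spacings
`[6,5,0,4,8]` vs `[6,6,0,4,6]` on the shared `C-C-CC-C-C` framework) and
classify held-out members:

```sh
hmmcompete --hmm demo.hmm -i demo.fas -d --pepreg --altpred
```

```
sequence_id	classifier_name	ali_from	ali_to	target_region	classifier_desc	matches_count	matches_position
huw01|006	SN_10_01	1	35	SMQCNNQQSNCSNYNSCCNWQYCDQYTSNNQCYTY	Huwentoxin-1 family	2	(1-35#SN_10_01#112.6)(17-18#SN_10_04#8.1)
huw01|007	SN_10_01	1	35	SSQCNNWQSECGNYNFCCQSQYCYQYTSNNLCYTY	Huwentoxin-1 family	2	(1-35#SN_10_01#92.9)(17-18#SN_10_04#8.1)
huw04|006	SN_10_04	1	34	MVWCWAVVVMCLIVWMMCCAVDLCWFAIIICAYV	Huwentoxin-1 family	2	(1-34#SN_10_04#116.1)(18-20#SN_10_01#9.5)
huw04|007	SN_10_04	1	34	MVWCWAVVVMCLIVWMMCCASWLCKFAIWICAFV	Huwentoxin-1 family	2	(1-34#SN_10_04#113.7)(18-21#SN_10_01#13.5)
```

Every held-out sequence wins with its own group's model by a wide margin
(e.g. 112.6 vs 8.1 bits); the trailing columns show the matched region,
the winner's legacy annotation, and the encoded alternative matches. Both
models match both sequence sets — exactly the ambiguity the competition
resolves.

Subcommands `venomhmm build / group / registry / benchmark` cover profile
construction, structural grouping reports, the SC/SN/VP registry, and the
synthetic held-out benchmark; `venomhmm registry --counts` prints

```
SC	21
SN	170
VP	28
total	219
```

## Layout

| module | contents |
| --- | --- |
| `venomhmm.io_formats` | FASTA / aligned-FASTA / Stockholm readers, HMMER3-style profile database subset, domtblout-style winner table, packaged reference tables |
| `venomhmm.profile_hmm` | the profile HMM container, alignment-based construction, local Viterbi best-domain and Forward scoring |
| `venomhmm.competition` | the best-classifier competition and its TSV/HTML reports |
| `venomhmm.grouping` | cysteine frameworks, spacing signatures, ICK range pattern, structural grouping, core-motif trimming |
| `venomhmm.naming` | SC/SN/VP classifier names, registry, hierarchy advice |
| `venomhmm.synthetic` | seeded toxin-like family generator and the held-out benchmark |
| `venomhmm.cli` | `hmmcompete` and `venomhmm` console scripts |

See `docs/methods.md` for the modelling choices, defaults and limitations.
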