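# Methods

## Problem and model

Human clinical variant databases and model-organism mutation collections
describe the same molecular events in different coordinate systems. Given
orthologous proteins from two species, this package identifies *matching
variants* (MatchVars): amino-acid substitutions occupying the same column
of a global protein alignment with identical reference and identical
alternate residues. The underlying assumption is that a substitution at a
conserved residue perturbs the same structural/functional context in both
proteins, so a phenotype observed for the model-organism allele is evidence
about the human allele.

Only substitutions (missense and nonsense) are modelled. Frameshifts,
indels and synonymous changes are rejected at parse time: their
cross-species correspondence is not well defined at a single residue, and
silently coercing them would fabricate matches. `*` (stop) is a first-class
alternate allele and matches only `*`. Selenocysteine (U) is accepted in
sequences but not as a variant allele.

All residue positions are 1-based over the ungapped sequence (HGVS
convention); alignment columns are 1-based; the gap character is `-`.

## Orthology

Ortholog pairs are inferred by reciprocal best hits (RBH) over exact
Smith–Waterman local alignment scores with BLOSUM62, gap open 11 / extend 1
(a gap of length L costs 11 + L). At curated-set scale, exact scoring makes
heuristic seeding and E-value statistics unnecessary: only the within-set
ranking matters for RBH. Score ties for "best hit" are broken by longer
partner sequence, then lexicographic accession, and flagged in the output.
A user-supplied pair list can always override the inference.

## Alignment and position maps

Ortholog pairs are aligned globally by Needleman–Wunsch with affine gaps
(BLOSUM62, gap open 10 / extend 0.5 — approximating classic protein
aligner defaults), implemented on Biopython's `PairwiseAligner`. Externally
computed alignments (aligned FASTA or CLUSTAL) can be imported instead, so
any preferred aligner's output drops into the same pipeline; alignments
with three or more rows are supported via this import path only.

Among co-optimal trace-backs the first alignment the enumerator yields is
taken — a fixed operator order, hence byte-identical outputs for identical
inputs (verified by the determinism tests). Near a repeat adjacent to an
indel, different optimal aligners may legitimately slide a gap by a residue
or two; positions inside such context have no unique correspondence from
the sequences alone (see the generator notes below).

The position map stores, per row, the residue-index→column array (strictly
increasing) and its column→residue inverse (0 at gaps). Mapping a position
across rows returns `mapped` (with target position and residue),
`gap-in-target`, or `out-of-range`; the map inverts exactly on non-gap
columns, a property the suite checks on a thousand random alignments.

The per-column similarity index is the fraction of row pairs carrying an
identical non-gap residue in that column; a pair with a gap counts as a
mismatch. An optional centered sliding-window mean smooths it. This
pairwise-identity-fraction definition is this package's own convention for
a quantity that is displayed, but not defined, in the literature it
follows.

## Matching

Validated variants (reference residue confirmed against the sequence;
failures excluded and reported) are matched under the three-condition rule
in the README. The strict alternate-allele condition is the default: every
published worked example pairs identical substitutions. `ref-only` mode is
available because prose descriptions of the rule ("the residue must be
matched") admit the looser reading; conserved-position /
different-substitution pairs are then promoted, with both alternates
recorded. Output is deduplicated on the two protein-level variant keys
(accession, ref, position, alt) and sorted for reproducible diffs.

Database-overlap counting uses the same protein-level key. Counts are per
membership pattern (Venn cells) and sum to the union size. Note the
semantic difference from genomic-coordinate Venns: distinct nucleotide
changes yielding the same protein substitution collapse here.

## Annotation transfer and statistics

PTM point annotations transfer through the position map; entries landing in
gaps are reported unmappable. Domain intervals map endpoint-wise, with an
endpoint in a gap truncated inward to the nearest mapped residue; intervals
entirely inside a gap are reported. Transferred positions never exceed the
target length.

Proportion comparisons build a 2×2 table — model-organism side phenotypic
vs not, against two chosen human significance classes — and apply the
Pearson chi-square test (df = 1) without continuity correction; Yates'
correction is behind a flag. The statistic is cross-checked in the suite
against the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) to 1e-10.
Significance labels normalize through an editable mapping table
(pathogenic, likely_pathogenic, benign, likely_benign, vus, phenotypic,
unknown, conflicting); unmapped labels go to `other` and are logged.

## Synthetic ortholog generator

`fixtures.evolve` derives a child protein by per-site substitution
(probability `sub_rate`, uniform over the 19 other residues) and indel
events (probability `indel_rate` per site; insertion or deletion with equal
odds; geometric lengths, mean 2 by default; boundary indels allowed),
recording the exact residue correspondence and an event log whose replay
reproduces the child. Uniform substitution is deliberate: the generator
tests alignment/mapping/matching plumbing with exact expected answers, not
evolutionary realism — no rate heterogeneity, no BLOSUM-weighted exchange,
no domain structure. Passing its suites therefore demonstrates coordinate
bookkeeping and matching-rule correctness, not aligner accuracy on deeply
diverged real proteins.

`fixtures.plant_matchvars` places known identical substitutions on
conserved correspondences and adds three labelled distractor classes:
alt-mismatch pairs (must surface as conserved-different, never MatchVars),
ref-mismatch pairs at diverged sites (must not match), and gap-adjacent
variants with no counterpart. MatchVar and alt-mismatch sites are drawn
only from conserved positions at least `ambiguity_buffer` (default 5)
residues from any indel: within that shadow, gap placement at repeats is a
pure aligner convention, so an exact expectation list would be ill-defined;
near-gap behaviour is probed by the dedicated gap-adjacent class instead.

Verification sizes used by the test suite and `scripts/acceptance.py`:
pairs of length 300 at 5% substitutions / 1% indels (20 seeds) for
end-to-end recovery; 1,000 random ≤8-mer pairs for the DP-oracle score
comparison; 1,000 random alignments for map inversion; 200 replicates of
500 MatchVars per arm for chi-square power at a planted odds ratio of 3
(baseline phenotypic fraction 0.2 in the benign arm — a deliberately
moderate baseline so the planted ratio-3 enrichment is realistic rather
than saturated). These sizes give stable, fast checks at full statistical
strength for the properties asserted.

## Numerical and degenerate-input conventions

- Empty sequences, ragged alignments, duplicate accessions, gap characters
  in unaligned FASTA, and zero contingency marginals raise typed
  `DataError`s.
- Variant table reading is skip-and-report by default (rows_in is always
  reconciled); `strict` makes malformed rows fatal.
- Trailing `*` on a FASTA sequence is stripped and flagged, matching common
  RefSeq export styles; internal stops are errors.
- U scores as X during alignment; sequence content is never rewritten.
- All randomness in the generator and the verification scripts flows from
  explicit integer seeds.

## Known limitations

- Pairwise (one human protein vs one ortholog) is the primary mode;
  multi-species alignments are import-only.
- Orthology is sequence-similarity RBH: no synteny, trees, or
  many-to-many groups.
- Variant identity is protein-level; genomic liftover and codon-level
  comparison are out of scope.
- The worked-example test against the published RefSeq ortholog pairs
  requires a small network download (sequences are not redistributed);
  synthetic stand-ins with the same coordinate geometry cover the code
  path offline.
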