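# matchvar

Cross-species matching of protein variants between orthologous genes.

Model organisms carry decades of phenotype-annotated mutations; human
clinical databases are dominated by variants of uncertain significance
(VUS). When a human substitution and a model-organism substitution hit the
*same residue* of an orthologous protein — same reference amino acid, same
alternate amino acid at the corresponding alignment position — the
model-organism phenotype becomes direct functional evidence about the human
variant. `matchvar` finds these **matching variants (MatchVars)**: it pairs
orthologs by reciprocal best alignment hits, aligns each pair globally,
builds a gap-aware residue↔column position map, and compares per-species
variant tables on it, carrying clinical/phenotypic annotations along.

## The matching rule

Given orthologous proteins $H$ and $O$ with a global alignment, variants
$h = \mathrm{p.}r_h\,i\,a_h$ on $H$ and $o = \mathrm{p.}r_o\,j\,a_o$ on $O$
form a MatchVar iff

1. residues $i$ of $H$ and $j$ of $O$ occupy the same alignment column,
2. $r_h = r_o$ (the position is conserved), and
3. $a_h = a_o$ (the identical substitution; `*`, a nonsense change, matches
   only `*`).

Pairs meeting (1)–(2) but not (3) are reported separately as
conserved-position/different-substitution pairs (or promoted to MatchVars
under `--mode ref-only`). Variants whose stated reference residue
contradicts the sequence are excluded and reported, never matched.

Supporting machinery: HGVS p. substitution parsing (one- and three-letter),
Needleman–Wunsch global and Smith–Waterman local alignment (BLOSUM62, affine
gaps, via Biopython), reciprocal-best-hit orthology, a per-column similarity
index, PTM/domain annotation transfer across alignments, cross-database
Venn counting on protein-level variant keys, two-proportion Pearson
chi-square comparisons, lollipop-track export, and a seeded synthetic
ortholog-pair generator with exact ground truth.

## Worked example

```python
from matchvar import (align_global, build_position_map, map_position,
                      call_matchvars, ProteinVariant, ProteinChange)

human = "MSKLVANDWQRTPGAFECIKHM"   # P at position 13
worm  = "MSKLVNDWQRTPGAFECIKHM"    # one residue deleted upstream: P at 12
aln = align_global(human, worm, "HUM_P1", "WRM_P1")
for acc, row in aln.rows:
    print(f"{acc:8s} {row}")

pmap = build_position_map(aln)
print(map_position(pmap, "HUM_P1", 13, "WRM_P1"))

res = call_matchvars(
    [ProteinVariant("HUM_P1", ProteinChange("P", 13, "S"), "ClinVar",
                    significance="Pathogenic")],
    [ProteinVariant("WRM_P1", ProteinChange("P", 12, "S"), "WormBase",
                    significance="phenotypic")],
    aln,
)
m = res.matchvars[0]
print(f"MatchVar: p.P{m.position_a}S <-> p.P{m.position_b}S (column {m.column})")
```

prints

```
HUM_P1   MSKLVANDWQRTPGAFECIKHM
WRM_P1   MSKLV-NDWQRTPGAFECIKHM
MappedPosition(status='mapped', column=13, target_position=12, target_residue='P')
MatchVar: p.P13S <-> p.P12S (column 13)
```

The deletion shifts the worm's coordinates by one, so human position 13 and
worm position 12 share a column; both species carry P→S there, so the pair
is a MatchVar — the human pathogenic annotation and the worm phenotype now
describe the same molecular lesion.

The same pipeline from the shell:

```sh
matchvar fixtures --length 300 --n-variants 10 --seed 7 --out-dir fx/
matchvar align --fasta-a fx/parent.fa --fasta-b fx/child.fa --out aln.fa
matchvar match --human-variants fx/variants_parent.tsv \
               --ortho-variants fx/variants_child.tsv \
               --alignment aln.fa --out matchvars.tsv
```

Other subcommands: `orthologs` (RBH pairing), `annotate` (PTM/domain
transfer), `stats` (two-proportion chi-square on a MatchVar table),
`overlap` (cross-database Venn counts). Every run writes its resolved
configuration next to its output and is byte-for-byte reproducible.

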