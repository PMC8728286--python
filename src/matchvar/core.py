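"""The MatchVar caller: cross-species matching of amino-acid substitutions.

Two variants — one per species in an orthologous protein pair — form a
*matching variant* (MatchVar) when

1. their residue positions occupy the same alignment column,
2. the reference residues are identical (the position is conserved), and
3. the alternate residues are identical (the same substitution).

Pairs satisfying (1) and (2) but not (3) are real biological signal too
(a conserved position hit by different substitutions in the two species);
they are emitted under a separate label, never as MatchVars.  Variants whose
stated reference residue disagrees with the actual sequence are excluded
from matching and reported — silently including them would fabricate
matches on the wrong isoform.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, NamedTuple

from . import hgvs
from .alignment import Alignment, PositionMap, build_position_map, map_position, ungap_rows
from .errors import DataError
from .hgvs import ProteinChange


class VariantKey(NamedTuple):
    """Protein-level variant identity: same key ⇒ same variant, whatever the source."""

    accession: str
    ref: str
    position: int
    alt: str


@dataclass(frozen=True)
class ProteinVariant:
    """One amino-acid substitution with its provenance and annotations."""

    accession: str
    change: ProteinChange
    source_db: str
    variant_id: str | None = None
    significance: str = "unknown"
    phenotype: str | None = None
    allele_freq: float | None = None

    @property
    def key(self) -> VariantKey:
        return VariantKey(
            self.accession, self.change.ref_aa, self.change.position, self.change.alt_aa
        )

    @property
    def hgvs_p(self) -> str:
        return hgvs.format(self.change)


@dataclass(frozen=True)
class MatchVar:
    """A matched cross-species variant pair with its alignment evidence."""

    variant_a: ProteinVariant
    variant_b: ProteinVariant
    column: int
    position_a: int
    position_b: int
    shared_ref: str
    shared_alt: str


@dataclass(frozen=True)
class ConservedDifferentSub:
    """Conserved position carrying different substitutions in the two species."""

    variant_a: ProteinVariant
    variant_b: ProteinVariant
    column: int
    shared_ref: str
    alt_a: str
    alt_b: str


@dataclass
class MatchResult:
    """Everything the caller produced, including the exclusion report."""

    matchvars: list[MatchVar]
    conserved_different: list[ConservedDifferentSub]
    invalid_a: list[tuple[ProteinVariant, str]] = field(default_factory=list)
    invalid_b: list[tuple[ProteinVariant, str]] = field(default_factory=list)


MatchMode = Literal["strict-alt", "ref-only"]


def _validated(
    variants: Iterable[ProteinVariant], sequences: Mapping[str, str]
) -> tuple[list[ProteinVariant], list[tuple[ProteinVariant, str]]]:
    kept: list[ProteinVariant] = []
    rejected: list[tuple[ProteinVariant, str]] = []
    seen: set[tuple[VariantKey, str]] = set()
    for v in variants:
        if v.accession not in sequences:
            raise DataError(f"variant accession {v.accession!r} absent from alignment")
        verdict = hgvs.validate_against(v.change, sequences[v.accession])
        if not verdict:
            rejected.append((v, verdict.reason))
            continue
        dedup = (v.key, v.source_db)
        if dedup in seen:
            continue
        seen.add(dedup)
        kept.append(v)
    return kept, rejected


def call_matchvars(
    variants_a: Iterable[ProteinVariant],
    variants_b: Iterable[ProteinVariant],
    alignment: Alignment,
    pmap: PositionMap | None = None,
    mode: MatchMode = "strict-alt",
) -> MatchResult:
    """Find all cross-species variant pairs satisfying the matching rule.

    ``mode='strict-alt'`` (default) requires identical alternates (condition 3);
    ``mode='ref-only'`` promotes conserved-position/different-substitution
    pairs to MatchVars as well, reflecting the looser reading of the rule.
    Output is deduplicated on (key_a, key_b) and symmetric under swapping
    the two species' roles.
    """
    if pmap is None:
        pmap = build_position_map(alignment)
    sequences = ungap_rows(alignment)
    valid_a, invalid_a = _validated(variants_a, sequences)
    valid_b, invalid_b = _validated(variants_b, sequences)

    # index species-b variants by (accession, residue position)
    b_by_pos: dict[tuple[str, int], list[ProteinVariant]] = {}
    for vb in valid_b:
        b_by_pos.setdefault((vb.accession, vb.change.position), []).append(vb)

    matchvars: list[MatchVar] = []
    conserved_diff: list[ConservedDifferentSub] = []
    seen_pairs: set[tuple[VariantKey, VariantKey]] = set()
    for va in valid_a:
        for acc_b in sequences:
            if acc_b == va.accession:
                continue
            mapped = map_position(pmap, va.accession, va.change.position, acc_b)
            if mapped.status != "mapped":
                continue
            if mapped.target_residue != va.change.ref_aa:
                continue  # position not conserved: condition 2 fails for any vb
            for vb in b_by_pos.get((acc_b, mapped.target_position), ()):
                pair_key = (va.key, vb.key)
                if pair_key in seen_pairs:
                    continue
                seen_pairs.add(pair_key)
                # vb passed validation, so vb.ref equals the target residue
                if va.change.alt_aa == vb.change.alt_aa or mode == "ref-only":
                    matchvars.append(
                        MatchVar(
                            variant_a=va,
                            variant_b=vb,
                            column=mapped.column,
                            position_a=va.change.position,
                            position_b=vb.change.position,
                            shared_ref=va.change.ref_aa,
                            shared_alt=va.change.alt_aa
                            if va.change.alt_aa == vb.change.alt_aa
                            else f"{va.change.alt_aa}/{vb.change.alt_aa}",
                        )
                    )
                else:
                    conserved_diff.append(
                        ConservedDifferentSub(
                            variant_a=va,
                            variant_b=vb,
                            column=mapped.column,
                            shared_ref=va.change.ref_aa,
                            alt_a=va.change.alt_aa,
                            alt_b=vb.change.alt_aa,
                        )
                    )
    matchvars.sort(
        key=lambda m: (m.variant_a.accession, m.position_a, m.shared_alt,
                       m.variant_b.accession, m.position_b)
    )
    conserved_diff.sort(
        key=lambda m: (m.variant_a.accession, m.variant_a.change.position,
                       m.alt_a, m.variant_b.accession, m.alt_b)
    )
    return MatchResult(matchvars, conserved_diff, invalid_a, invalid_b)


def swap_roles(result: MatchResult) -> MatchResult:
    """Mirror a MatchResult, exchanging the two species' roles."""
    return MatchResult(
        matchvars=sorted(
            (
                MatchVar(
                    variant_a=m.variant_b,
                    variant_b=m.variant_a,
                    column=m.column,
                    position_a=m.position_b,
                    position_b=m.position_a,
                    shared_ref=m.shared_ref,
                    shared_alt="/".join(reversed(m.shared_alt.split("/")))
                    if "/" in m.shared_alt
                    else m.shared_alt,
                )
                for m in result.matchvars
            ),
            key=lambda m: (m.variant_a.accession, m.position_a, m.shared_alt,
                           m.variant_b.accession, m.position_b),
        ),
        conserved_different=[
            replace(m, variant_a=m.variant_b, variant_b=m.variant_a,
                    alt_a=m.alt_b, alt_b=m.alt_a)
            for m in result.conserved_different
        ],
        invalid_a=result.invalid_b,
        invalid_b=result.invalid_a,
    )


def conservation_status(
    position: int,
    accession: str,
    alignments: Mapping[str, Alignment],
) -> dict[str, bool]:
    """Is the residue at ``position`` conserved in each counterpart alignment?

    ``alignments`` maps a species/counterpart label to a pairwise alignment
    containing ``accession``.  The verdict is True iff the counterpart row
    carries the identical residue at the corresponding column; a gap or a
    different residue is "not conserved".
    """
    verdicts: dict[str, bool] = {}
    for label, aln in alignments.items():
        pmap = build_position_map(aln)
        others = [acc for acc in aln.accessions if acc != accession]
        if accession not in aln.accessions or not others:
            raise DataError(f"alignment {label!r} does not pair {accession!r}")
        source_seq = aln.ungapped(accession)
        if not 1 <= position <= len(source_seq):
            raise DataError(f"position {position} out of range for {accession}")
        source_res = source_seq[position - 1]
        mapped = map_position(pmap, accession, position, others[0])
        verdicts[label] = (
            mapped.status == "mapped" and mapped.target_residue == source_res
        )
    return verdicts


def count_db_overlaps(
    tables: Mapping[str, Iterable[ProteinVariant]],
) -> dict[frozenset[str], int]:
    """Counts of variant keys per source-membership pattern (Venn cells).

    Returns every non-empty powerset cell as ``frozenset(sources) -> count``;
    the cell counts sum to the size of the union of all key sets.
    """
    if len(tables) < 2:
        raise DataError("overlap counting needs at least 2 variant tables")
    membership: dict[VariantKey, set[str]] = {}
    for label, variants in tables.items():
        for v in variants:
            membership.setdefault(v.key, set()).add(label)
    cells: Counter[frozenset[str]] = Counter(
        frozenset(sources) for sources in membership.values()
    )
    return dict(cells)


def matchvar_counts(
    matchvars: Iterable[MatchVar],
    species_of: Mapping[str, str] | None = None,
) -> dict[tuple[str, str], int]:
    """Counts per (species-b label, significance class of the species-b variant).

    ``species_of`` maps accession → species tag; when omitted, the species-b
    accession itself is used as the stratum label.  The counts sum to the
    number of MatchVars.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for m in matchvars:
        acc = m.variant_b.accession
        species = species_of.get(acc, acc) if species_of else acc
        counts[(species, m.variant_b.significance)] += 1
    return dict(counts)
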