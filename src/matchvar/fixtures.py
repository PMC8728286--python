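"""Synthetic ortholog families with ground truth, for pipeline testing.

:func:`evolve` derives a "child" protein from a parent under a transparent
mutation model — per-site uniform substitutions plus geometric-length
insertions and deletions — while recording the exact residue-level
correspondence (the true position map) and the full event log.  Uniform
(rather than BLOSUM-weighted) substitution is deliberate: the generator
exists to exercise alignment/mapping/matching plumbing with known answers,
not to emulate evolutionary realism.

:func:`plant_matchvars` then drops known substitutions on conserved
correspondences of such a pair — plus labelled distractors that must *not*
match — so the full align → map → match pipeline can be scored for exact
recall and precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import ProteinVariant, VariantKey
from .errors import DataError
from .hgvs import AA1, ProteinChange
from .seq_io import ProteinRecord


@dataclass
class EvolvedPair:
    """Parent/child proteins with their exact residue correspondence."""

    parent: ProteinRecord
    child: ProteinRecord
    true_map: list[tuple[int, int]]  # (parent_pos, child_pos), both 1-based
    events: list[tuple]  # ("sub", parent_pos, new_aa) | ("del", start, len) | ("ins", before_pos, seq)
    seed: int

    @property
    def conserved(self) -> list[tuple[int, int]]:
        """Correspondences where parent and child carry the same residue."""
        return [
            (pp, cp)
            for pp, cp in self.true_map
            if self.parent.sequence[pp - 1] == self.child.sequence[cp - 1]
        ]


def random_protein(length: int, seed: int, accession: str = "SYN_P1") -> ProteinRecord:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AA1), size=length))
    return ProteinRecord(accession, seq, species="synthetic")


def evolve(
    parent: ProteinRecord,
    sub_rate: float,
    indel_rate: float,
    mean_indel_len: float = 2.0,
    seed: int = 0,
    child_accession: str | None = None,
) -> EvolvedPair:
    """Mutate ``parent`` into a child, recording ground truth exactly.

    Per parent site: with probability ``indel_rate`` an indel event starts
    (insertion or deletion, equal odds, geometric length with the given
    mean); otherwise the residue is copied, substituted with probability
    ``sub_rate`` (uniform over the 19 other residues).  A terminal insertion
    is drawn with the same per-site rate.  Deterministic per seed.
    """
    for name, rate in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not 0 <= rate < 1:
            raise DataError(f"{name} must be in [0, 1), got {rate}")
    if mean_indel_len < 1:
        raise DataError("mean_indel_len must be >= 1")
    rng = np.random.default_rng(seed)
    aa = list(AA1)
    geom_p = 1.0 / mean_indel_len

    child: list[str] = []
    true_map: list[tuple[int, int]] = []
    events: list[tuple] = []
    i = 1  # 1-based parent position
    L = len(parent)
    while i <= L:
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.geometric(geom_p))
            if rng.random() < 0.5:  # deletion of parent residues i..i+length-1
                length = min(length, L - i + 1)
                events.append(("del", i, length))
                i += length
                continue
            inserted = "".join(rng.choice(aa, size=length))
            events.append(("ins", i, inserted))
            child.extend(inserted)
        res = parent.sequence[i - 1]
        if sub_rate > 0 and rng.random() < sub_rate:
            res = rng.choice([x for x in aa if x != parent.sequence[i - 1]])
            events.append(("sub", i, res))
        child.append(res)
        true_map.append((i, len(child)))
        i += 1
    if indel_rate > 0 and rng.random() < indel_rate:
        inserted = "".join(rng.choice(aa, size=int(rng.geometric(geom_p))))
        events.append(("ins", L + 1, inserted))
        child.extend(inserted)
    if not child:
        # pathological rates can delete everything; keep the invariant simple
        raise DataError("evolution deleted the entire sequence; lower indel_rate")
    acc = child_accession or f"{parent.accession}_child"
    return EvolvedPair(
        parent=parent,
        child=ProteinRecord(acc, "".join(child), species="synthetic"),
        true_map=true_map,
        events=events,
        seed=seed,
    )


def apply_events(parent: ProteinRecord, events: list[tuple]) -> str:
    """Replay an event log against the parent; must reproduce the child."""
    subs = {pos: aa for kind, pos, aa in events if kind == "sub"}
    dels: set[int] = set()
    for kind, start, length in (e for e in events if e[0] == "del"):
        dels.update(range(start, start + length))
    ins = {pos: seq for kind, pos, seq in events if kind == "ins"}
    out: list[str] = []
    for i in range(1, len(parent) + 2):
        if i in ins:
            out.append(ins[i])
        if i > len(parent) or i in dels:
            continue
        out.append(subs.get(i, parent.sequence[i - 1]))
    return "".join(out)


@dataclass
class PlantResult:
    """Planted variant tables plus the exact expectation lists."""

    variants_parent: list[ProteinVariant]
    variants_child: list[ProteinVariant]
    expected_matchvars: set[tuple[VariantKey, VariantKey]]
    expected_conserved_diff: set[tuple[VariantKey, VariantKey]]
    unmatched_keys: set[VariantKey] = field(default_factory=set)


def _indel_shadow(pair: EvolvedPair, buffer: int) -> set[int]:
    """Parent positions within ``buffer`` residues of any indel event."""
    shadow: set[int] = set()
    for event in pair.events:
        if event[0] == "del":
            _, start, length = event
            shadow.update(range(start - buffer, start + length + buffer))
        elif event[0] == "ins":
            _, before, seq = event
            shadow.update(range(before - buffer, before + len(seq) + buffer))
    return shadow


def plant_matchvars(
    pair: EvolvedPair,
    n: int,
    seed: int = 0,
    n_alt_mismatch: int = 0,
    n_ref_mismatch: int = 0,
    n_gap_adjacent: int = 0,
    ambiguity_buffer: int = 5,
) -> PlantResult:
    """Plant ``n`` true MatchVars on conserved correspondences, plus distractors.

    MatchVars and alt-mismatch distractors are planted on conserved sites at
    least ``ambiguity_buffer`` residues away from any indel: gap placement at
    repeats next to an indel is a pure aligner convention, so correspondences
    inside that shadow are not uniquely recoverable from the sequences alone
    and would make exact expectation lists ill-defined.  Near-gap behaviour
    is probed explicitly by the gap-adjacent distractor class instead.

    Distractor classes (all recorded in the expectation lists, none of which
    may surface as a MatchVar):

    * alt-mismatch — same conserved position, different alternates in the two
      species (expected as conserved-position/different-substitution pairs);
    * ref-mismatch — variants at a diverged correspondence, each valid on its
      own sequence (reference residues differ, so no match);
    * gap-adjacent — variants at positions with no counterpart (deleted from
      or inserted into the child), present in one species only.
    """
    rng = np.random.default_rng(seed)
    aa = list(AA1)
    shadow = _indel_shadow(pair, ambiguity_buffer)
    conserved = [(pp, cp) for pp, cp in pair.conserved if pp not in shadow]
    if n + n_alt_mismatch > len(conserved):
        raise DataError(
            f"need {n + n_alt_mismatch} unambiguous conserved sites, "
            f"pair has {len(conserved)}"
        )
    order = rng.permutation(len(conserved))
    picks = [conserved[int(k)] for k in order[: n + n_alt_mismatch]]

    parent_acc, child_acc = pair.parent.accession, pair.child.accession
    var_p: list[ProteinVariant] = []
    var_c: list[ProteinVariant] = []
    expected: set[tuple[VariantKey, VariantKey]] = set()
    expected_diff: set[tuple[VariantKey, VariantKey]] = set()
    unmatched: set[VariantKey] = set()

    def _variant(acc: str, ref: str, pos: int, alt: str, source: str,
                 significance: str) -> ProteinVariant:
        return ProteinVariant(
            accession=acc,
            change=ProteinChange(ref, pos, alt),
            source_db=source,
            significance=significance,
        )

    for pp, cp in picks[:n]:
        ref = pair.parent.sequence[pp - 1]
        alt = str(rng.choice([x for x in aa if x != ref]))
        vp = _variant(parent_acc, ref, pp, alt, "humanDB", "vus")
        vc = _variant(child_acc, ref, cp, alt, "modelDB", "phenotypic")
        var_p.append(vp)
        var_c.append(vc)
        expected.add((vp.key, vc.key))

    for pp, cp in picks[n:]:
        ref = pair.parent.sequence[pp - 1]
        alt_a, alt_b = rng.choice([x for x in aa if x != ref], size=2, replace=False)
        vp = _variant(parent_acc, ref, pp, str(alt_a), "humanDB", "vus")
        vc = _variant(child_acc, ref, cp, str(alt_b), "modelDB", "phenotypic")
        var_p.append(vp)
        var_c.append(vc)
        expected_diff.add((vp.key, vc.key))

    diverged = [
        (pp, cp)
        for pp, cp in pair.true_map
        if pair.parent.sequence[pp - 1] != pair.child.sequence[cp - 1]
    ]
    if n_ref_mismatch > len(diverged):
        raise DataError(f"need {n_ref_mismatch} diverged sites, pair has {len(diverged)}")
    for k in rng.permutation(len(diverged))[:n_ref_mismatch]:
        pp, cp = diverged[int(k)]
        ref_p, ref_c = pair.parent.sequence[pp - 1], pair.child.sequence[cp - 1]
        alt = str(rng.choice([x for x in aa if x not in (ref_p, ref_c)]))
        vp = _variant(parent_acc, ref_p, pp, alt, "humanDB", "vus")
        vc = _variant(child_acc, ref_c, cp, alt, "modelDB", "phenotypic")
        var_p.append(vp)
        var_c.append(vc)
        unmatched.update((vp.key, vc.key))

    mapped_parent = {pp for pp, _ in pair.true_map}
    mapped_child = {cp for _, cp in pair.true_map}
    orphans_p = sorted(set(range(1, len(pair.parent) + 1)) - mapped_parent)
    orphans_c = sorted(set(range(1, len(pair.child) + 1)) - mapped_child)
    orphans = [("p", p) for p in orphans_p] + [("c", c) for c in orphans_c]
    if n_gap_adjacent > len(orphans):
        raise DataError(
            f"need {n_gap_adjacent} gap-adjacent sites, pair has {len(orphans)}"
        )
    for k in rng.permutation(len(orphans))[:n_gap_adjacent]:
        side, pos = orphans[int(k)]
        record = pair.parent if side == "p" else pair.child
        ref = record.sequence[pos - 1]
        alt = str(rng.choice([x for x in aa if x != ref]))
        v = _variant(
            record.accession, ref, pos, alt,
            "humanDB" if side == "p" else "modelDB",
            "vus" if side == "p" else "phenotypic",
        )
        (var_p if side == "p" else var_c).append(v)
        unmatched.add(v.key)

    return PlantResult(var_p, var_c, expected, expected_diff, unmatched)


def write_fixture_set(
    out_dir: str | Path,
    length: int,
    sub_rate: float,
    indel_rate: float,
    n_variants: int,
    seed: int,
    n_alt_mismatch: int = 0,
    n_ref_mismatch: int = 0,
    n_gap_adjacent: int = 0,
) -> dict:
    """Generate a full fixture set on disk: FASTA, variant TSVs, expectation JSON."""
    from .seq_io import write_fasta, write_variant_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parent = random_protein(length, seed=seed)
    pair = evolve(parent, sub_rate, indel_rate, seed=seed + 1)
    planted = plant_matchvars(
        pair, n_variants, seed=seed + 2,
        n_alt_mismatch=n_alt_mismatch,
        n_ref_mismatch=n_ref_mismatch,
        n_gap_adjacent=n_gap_adjacent,
    )
    write_fasta([pair.parent], out / "parent.fa")
    write_fasta([pair.child], out / "child.fa")
    write_variant_tsv(planted.variants_parent, out / "variants_parent.tsv")
    write_variant_tsv(planted.variants_child, out / "variants_child.tsv")
    expectation = {
        "seed": seed,
        "true_map": pair.true_map,
        "expected_matchvars": sorted(
            [list(ka), list(kb)] for ka, kb in planted.expected_matchvars
        ),
        "expected_conserved_diff": sorted(
            [list(ka), list(kb)] for ka, kb in planted.expected_conserved_diff
        ),
    }
    (out / "expectation.json").write_text(json.dumps(expectation, indent=1))
    return expectation
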