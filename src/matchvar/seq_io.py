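"""Readers and writers for the package's file dialects.

Sequences travel as FASTA, alignments as aligned FASTA or CLUSTAL (both via
Biopython), and variant / annotation tables as tab-separated text with a
header row, UTF-8, ``.`` for missing values.  The variant dialect is this
package's own simplified contract — the upstream clinical and model-organism
databases each dump in a different native format, all out of scope here:

======== ===========================================================
column    meaning
======== ===========================================================
accession protein accession the variant is expressed on
hgvs_p    protein substitution, e.g. ``p.P375S`` (or ref/pos/alt cols)
source    originating database label (gnomAD, ClinVar, WormBase, ...)
variant_id, significance, phenotype, allele_freq   optional
======== ===========================================================
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import hgvs
from .alignment import GAP, Alignment
from .core import ProteinVariant
from .errors import DataError, HgvsError

SEQUENCE_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXU")
MISSING = "."


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence for one species."""

    accession: str
    sequence: str
    species: str = ""
    had_stop: bool = False  # a trailing '*' was stripped during normalization

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise DataError(
                f"{self.accession}: illegal residue character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_sequence(raw: str, accession: str) -> tuple[str, bool]:
    seq = raw.upper()
    if GAP in seq:
        raise DataError(f"{accession}: gap character in unaligned sequence")
    had_stop = seq.endswith("*")
    if had_stop:
        seq = seq[:-1]
    if "*" in seq:
        raise DataError(f"{accession}: internal stop character")
    return seq, had_stop


def read_fasta(
    path: str | Path, species: str = "", species_key: str | None = None
) -> list[ProteinRecord]:
    """Read protein FASTA; the header's first token is the accession.

    ``species_key`` names a ``key=value`` field in the description to parse the
    species tag from (e.g. ``organism``); otherwise ``species`` applies to all.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        if accession in seen:
            raise DataError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        tag = species
        if species_key:
            for token in rec.description.split():
                if token.startswith(f"{species_key}="):
                    tag = token.split("=", 1)[1]
        seq, had_stop = _normalize_sequence(str(rec.seq), accession)
        records.append(ProteinRecord(accession, seq, tag, had_stop))
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=r.accession,
            description=f"species={r.species}" if r.species else "",
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_alignment(
    path: str | Path, format: Literal["fasta", "clustal"] = "fasta"
) -> Alignment:
    """Import an externally computed alignment (aligned FASTA or CLUSTAL)."""
    if format not in ("fasta", "clustal"):
        raise DataError(f"unknown alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise DataError(f"cannot read {format} alignment from {path}: {exc}") from exc
    rows = tuple((rec.id, str(rec.seq).upper()) for rec in msa)
    for acc, gapped in rows:
        _normalize_sequence(gapped.replace(GAP, ""), acc)
    return Alignment(rows=rows)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(gapped), id=acc, description="")
        for acc, gapped in alignment.rows
    ]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class VariantTable:
    """Parsed variant rows plus the per-row rejection report.

    ``rows_in == len(variants) + len(skipped) + duplicates_collapsed`` — the
    reader never silently drops a row.
    """

    variants: list[ProteinVariant]
    skipped: list[tuple[int, str, str]] = field(default_factory=list)  # (line, cell, why)
    duplicates_collapsed: int = 0

    @property
    def rows_in(self) -> int:
        return len(self.variants) + len(self.skipped) + self.duplicates_collapsed


def _get(row: pd.Series, col: str) -> str | None:
    val = row.get(col)
    if val is None or (isinstance(val, float) and pd.isna(val)):
        return None
    text = str(val).strip()
    return None if text in ("", MISSING) else text


def read_variant_tsv(
    path: str | Path | io.TextIOBase, strict: bool = False
) -> VariantTable:
    """Read the variant TSV dialect; unparsable rows are skipped-and-reported
    (default) or fatal (``strict=True``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "accession" not in df.columns or "source" not in df.columns:
        raise DataError("variant table must have 'accession' and 'source' columns")
    triplet = {"ref", "pos", "alt"}.issubset(df.columns)
    if "hgvs_p" not in df.columns and not triplet:
        raise DataError("variant table needs 'hgvs_p' or 'ref'/'pos'/'alt' columns")

    variants: list[ProteinVariant] = []
    skipped: list[tuple[int, str, str]] = []
    seen: set[tuple] = set()
    dup = 0
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        accession, source = _get(row, "accession"), _get(row, "source")
        cell = _get(row, "hgvs_p") or ""
        try:
            if not accession or not source:
                raise DataError("missing accession or source")
            if cell:
                change = hgvs.parse(cell)
            elif triplet:
                change = hgvs.ProteinChange(
                    ref_aa=_get(row, "ref") or "",
                    position=int(_get(row, "pos") or 0),
                    alt_aa=_get(row, "alt") or "",
                )
            else:
                raise DataError("no substitution given")
        except (HgvsError, DataError, ValueError) as exc:
            if strict:
                raise DataError(f"line {line_no}: {exc}") from exc
            skipped.append((line_no, cell, str(exc)))
            continue
        freq_text = _get(row, "allele_freq")
        variant = ProteinVariant(
            accession=accession,
            change=change,
            source_db=source,
            variant_id=_get(row, "variant_id"),
            significance=_get(row, "significance") or "unknown",
            phenotype=_get(row, "phenotype"),
            allele_freq=float(freq_text) if freq_text else None,
        )
        dedup_key = (variant.key, variant.source_db)
        if dedup_key in seen:
            dup += 1
            continue
        seen.add(dedup_key)
        variants.append(variant)
    if not variants:
        raise DataError("no parsable variant rows")
    return VariantTable(variants, skipped, dup)


def write_variant_tsv(variants: Iterable[ProteinVariant], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "accession": v.accession,
            "hgvs_p": v.hgvs_p,
            "source": v.source_db,
            "variant_id": v.variant_id or MISSING,
            "significance": v.significance,
            "phenotype": v.phenotype or MISSING,
            "allele_freq": v.allele_freq if v.allele_freq is not None else MISSING,
        }
        for v in variants
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PtmAnnotation:
    accession: str
    position: int
    label: str


@dataclass(frozen=True)
class DomainAnnotation:
    accession: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise DataError(f"bad domain interval [{self.start}, {self.end}]")


def read_ptm_tsv(path: str | Path) -> list[PtmAnnotation]:
    """PTM point annotations: columns accession, position, label."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require(df, {"accession", "position", "label"}, "PTM table")
    return [
        PtmAnnotation(r["accession"], int(r["position"]), r["label"])
        for _, r in df.iterrows()
    ]


def read_domain_tsv(path: str | Path) -> list[DomainAnnotation]:
    """Domain intervals: columns accession, start, end, name (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require(df, {"accession", "start", "end", "name"}, "domain table")
    return [
        DomainAnnotation(r["accession"], int(r["start"]), int(r["end"]), r["name"])
        for _, r in df.iterrows()
    ]


def _require(df: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise DataError(f"{what} missing column(s): {sorted(missing)}")
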