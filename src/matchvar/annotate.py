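"""Significance normalization, annotation transfer, and proportion statistics.

Clinical databases spell the same concept many ways ("Pathogenic",
"pathogenic/likely pathogenic", "Uncertain significance", ...); model
organisms annotate phenotypes instead of pathogenicity.  Everything is
funnelled into one small :class:`SignificanceClass` vocabulary so that
cross-species contingency tables are well defined.  The label → class table
ships as an editable key-value mapping; unmapped labels fall into ``other``
and are logged, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .alignment import PositionMap, map_position
from .core import MatchVar, ProteinVariant
from .errors import DataError
from .seq_io import DomainAnnotation, PtmAnnotation, ProteinRecord

logger = logging.getLogger(__name__)


class SignificanceClass(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "vus"
    PHENOTYPIC = "phenotypic"
    UNKNOWN = "unknown"
    CONFLICTING = "conflicting"
    OTHER = "other"


#: Default label → class mapping (case-insensitive, surrounding space ignored).
#: Editable/overridable via the ``table`` argument of normalize_significance.
DEFAULT_SIGNIFICANCE_MAP: dict[str, SignificanceClass] = {
    "pathogenic": SignificanceClass.PATHOGENIC,
    "likely pathogenic": SignificanceClass.LIKELY_PATHOGENIC,
    "pathogenic/likely pathogenic": SignificanceClass.LIKELY_PATHOGENIC,
    "benign": SignificanceClass.BENIGN,
    "likely benign": SignificanceClass.LIKELY_BENIGN,
    "benign/likely benign": SignificanceClass.LIKELY_BENIGN,
    "uncertain significance": SignificanceClass.VUS,
    "vus": SignificanceClass.VUS,
    "uncertain": SignificanceClass.VUS,
    "phenotypic": SignificanceClass.PHENOTYPIC,
    "phenotype": SignificanceClass.PHENOTYPIC,
    "has phenotype": SignificanceClass.PHENOTYPIC,
    "unknown": SignificanceClass.UNKNOWN,
    "not provided": SignificanceClass.UNKNOWN,
    "unknown significance": SignificanceClass.UNKNOWN,
    "conflicting interpretations of pathogenicity": SignificanceClass.CONFLICTING,
    "conflicting": SignificanceClass.CONFLICTING,
}


def normalize_significance(
    label: str,
    table: Mapping[str, SignificanceClass] | None = None,
) -> SignificanceClass:
    """Map a raw significance/phenotype label to its normalized class.

    Deterministic table lookup; unmapped labels return ``OTHER`` and emit a
    log entry so bulk runs can audit their label universe.
    """
    if not label or not label.strip():
        raise DataError("empty significance label")
    mapping = DEFAULT_SIGNIFICANCE_MAP if table is None else table
    key = label.strip().lower()
    cls = mapping.get(key)
    if cls is None:
        logger.warning("unmapped significance label %r -> other", label)
        return SignificanceClass.OTHER
    return cls


def load_significance_map(path) -> dict[str, SignificanceClass]:
    """Read a two-column (label<TAB>class) mapping file."""
    table: dict[str, SignificanceClass] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            label, _, cls = line.partition("\t")
            table[label.strip().lower()] = SignificanceClass(cls.strip())
    return table


# ---------------------------------------------------------------------------
# annotation transfer

@dataclass
class TransferReport:
    transferred_ptms: list[PtmAnnotation]
    transferred_domains: list[DomainAnnotation]
    unmappable: list[tuple[object, str]]  # (annotation, reason)


def transfer_annotations(
    ptms: Sequence[PtmAnnotation],
    domains: Sequence[DomainAnnotation],
    pmap: PositionMap,
    from_row: str,
    to_row: str,
) -> TransferReport:
    """Carry PTM points and domain intervals across an alignment.

    Points map through :func:`map_position`; intervals map endpoint-wise,
    with endpoints falling into gaps truncated inward to the nearest mapped
    residue.  Entries that cannot be placed at all are reported, never
    silently dropped, and no output position exceeds the target length.
    """
    out_ptms: list[PtmAnnotation] = []
    out_domains: list[DomainAnnotation] = []
    unmappable: list[tuple[object, str]] = []

    for ptm in ptms:
        mapped = map_position(pmap, from_row, ptm.position, to_row)
        if mapped.status == "mapped":
            out_ptms.append(
                PtmAnnotation(to_row, mapped.target_position, ptm.label)
            )
        else:
            unmappable.append((ptm, mapped.status))

    src_len = len(pmap.res_to_col[from_row])
    for dom in domains:
        if dom.end > src_len:
            unmappable.append((dom, "out-of-range"))
            continue
        start = _map_inward(pmap, from_row, to_row, dom.start, dom.end, step=+1)
        end = _map_inward(pmap, from_row, to_row, dom.end, dom.start, step=-1)
        if start is None or end is None or start > end:
            unmappable.append((dom, "interval-entirely-in-gap"))
            continue
        out_domains.append(DomainAnnotation(to_row, start, end, dom.name))
    return TransferReport(out_ptms, out_domains, unmappable)


def _map_inward(
    pmap: PositionMap, from_row: str, to_row: str, pos: int, limit: int, step: int
) -> int | None:
    # walk from an interval endpoint toward the other end until a residue maps
    p = pos
    while (step > 0 and p <= limit) or (step < 0 and p >= limit):
        mapped = map_position(pmap, from_row, p, to_row)
        if mapped.status == "mapped":
            return mapped.target_position
        p += step
    return None


# ---------------------------------------------------------------------------
# two-proportion chi-square

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Successes/failures × group1/group2: rows are groups, columns outcome."""

    a: int  # group 1, success
    b: int  # group 1, failure
    c: int  # group 2, success
    d: int  # group 2, failure

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("negative cell count")
        if self.n == 0:
            raise DataError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    proportions: tuple[float, float]


def chi_square_2x2(
    table: ContingencyTable2x2, yates: bool = False
) -> ChiSquareResult:
    """Pearson chi-square on a 2×2 table (df=1), no continuity correction by
    default; Yates' correction available behind the flag."""
    arr = table.as_array()
    if np.any(arr.sum(axis=1) == 0) or np.any(arr.sum(axis=0) == 0):
        raise DataError("zero marginal in contingency table")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=yates)
    p1 = table.a / (table.a + table.b)
    p2 = table.c / (table.c + table.d)
    return ChiSquareResult(float(stat), int(df), float(p), (p1, p2))


def proportion_comparison(
    matchvars: Iterable[MatchVar],
    human_class_1: SignificanceClass,
    human_class_2: SignificanceClass,
    yates: bool = False,
) -> tuple[ContingencyTable2x2, ChiSquareResult]:
    """Compare the phenotypic fraction of model-organism MatchVars between two
    human significance classes.

    Rows: human variant in ``human_class_1`` vs ``human_class_2`` (MatchVars
    in neither class are ignored); columns: model-organism side phenotypic vs
    not.  Significance strings on both sides are normalized here.
    """
    cells = [0, 0, 0, 0]  # a, b, c, d
    for m in matchvars:
        human_cls = normalize_significance(m.variant_a.significance)
        if human_cls not in (human_class_1, human_class_2):
            continue
        phenotypic = (
            normalize_significance(m.variant_b.significance)
            is SignificanceClass.PHENOTYPIC
        )
        row = 0 if human_cls is human_class_1 else 2
        cells[row + (0 if phenotypic else 1)] += 1
    table = ContingencyTable2x2(*cells)
    return table, chi_square_2x2(table, yates=yates)


# ---------------------------------------------------------------------------
# lollipop track export

def export_lollipop(
    variants: Sequence[ProteinVariant],
    domains: Sequence[DomainAnnotation],
    protein: ProteinRecord,
) -> tuple[list[dict], list[ProteinVariant]]:
    """Plot-ready per-protein track: one row per variant, one per domain, one
    carrying the protein length.  Out-of-range variants are excluded and
    returned separately instead of corrupting the track."""
    rows: list[dict] = [
        {
            "track": "protein",
            "accession": protein.accession,
            "position": ".",
            "start": 1,
            "end": len(protein),
            "alt": ".",
            "class": ".",
            "source": ".",
            "name": protein.accession,
        }
    ]
    excluded: list[ProteinVariant] = []
    for dom in domains:
        if dom.end > len(protein):
            raise DataError(
                f"domain {dom.name} [{dom.start},{dom.end}] exceeds protein length"
            )
        rows.append(
            {
                "track": "domain",
                "accession": protein.accession,
                "position": ".",
                "start": dom.start,
                "end": dom.end,
                "alt": ".",
                "class": ".",
                "source": ".",
                "name": dom.name,
            }
        )
    for v in sorted(variants, key=lambda v: (v.change.position, v.change.alt_aa)):
        if v.change.position > len(protein):
            excluded.append(v)
            continue
        rows.append(
            {
                "track": "variant",
                "accession": v.accession,
                "position": v.change.position,
                "start": ".",
                "end": ".",
                "alt": v.change.alt_aa,
                "class": normalize_significance(v.significance).value,
                "source": v.source_db,
                "name": v.hgvs_p,
            }
        )
    return rows, excluded
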