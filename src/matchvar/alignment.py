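"""Global ortholog alignment, gap-aware position maps, per-column similarity.

The coordinate contract used everywhere downstream:

* residue positions are 1-based over the *ungapped* sequence (HGVS style);
* alignment columns are 1-based over the gapped rows;
* the gap character is ``-``.

A :class:`PositionMap` materialises the bijection between residue indices and
non-gap columns for every row, so that a variant position in one species can
be carried across to the orthologous residue in another (or be reported as
falling into a gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import DataError

GAP = "-"

#: Needleman–Wunsch defaults approximating ClustalW protein settings.
DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GLOBAL_GAP_OPEN = 10.0
DEFAULT_GLOBAL_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class Alignment:
    """A gapped alignment: ordered (accession, gapped sequence) rows of equal width."""

    rows: tuple[tuple[str, str], ...]
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise DataError("alignment has no rows")
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) != 1:
            raise DataError(f"ragged alignment rows: widths {sorted(widths)}")
        seen: set[str] = set()
        for acc, _ in self.rows:
            if acc in seen:
                raise DataError(f"duplicate accession in alignment: {acc}")
            seen.add(acc)

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(acc for acc, _ in self.rows)

    def gapped(self, accession: str) -> str:
        for acc, seq in self.rows:
            if acc == accession:
                return seq
        raise KeyError(f"accession {accession!r} not in alignment")

    def ungapped(self, accession: str) -> str:
        return self.gapped(accession).replace(GAP, "")


def _make_aligner(
    mode: Literal["global", "local"],
    matrix: str,
    gap_open: float,
    gap_extend: float,
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # affine cost: a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _scoring_view(seq: str) -> str:
    # U (selenocysteine) is legal sequence content but absent from BLOSUM62;
    # score it as X without touching the stored sequence.
    return seq.replace("U", "X")


def align_global(
    seq_a: str,
    seq_b: str,
    accession_a: str = "a",
    accession_b: str = "b",
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GLOBAL_GAP_OPEN,
    gap_extend: float = DEFAULT_GLOBAL_GAP_EXTEND,
) -> Alignment:
    """Optimal Needleman–Wunsch global alignment with affine gap costs.

    Trace-back ties are broken by taking the first optimal alignment the
    underlying enumerator yields — a fixed operator order, hence fully
    deterministic for identical inputs.
    """
    if not seq_a or not seq_b:
        raise DataError("cannot align an empty sequence")
    aligner = _make_aligner("global", matrix, gap_open, gap_extend)
    result = aligner.align(_scoring_view(seq_a), _scoring_view(seq_b))
    best = result[0]
    gapped_a, gapped_b = _regap(str(best[0]), seq_a), _regap(str(best[1]), seq_b)
    return Alignment(
        rows=((accession_a, gapped_a), (accession_b, gapped_b)),
        score=float(result.score),
    )


def _regap(gapped_view: str, original: str) -> str:
    # restore original letters (e.g. U) under the gap pattern of the scored view
    out = []
    it = iter(original)
    for ch in gapped_view:
        out.append(GAP if ch == GAP else next(it))
    return "".join(out)


@dataclass
class MappedPosition:
    """Result of carrying a residue position across an alignment."""

    status: Literal["mapped", "gap-in-target", "out-of-range"]
    column: int | None = None
    target_position: int | None = None
    target_residue: str | None = None


@dataclass
class PositionMap:
    """Bidirectional residue-index ↔ alignment-column maps for every row.

    ``res_to_col[acc][i-1]`` is the 1-based column of residue ``i``;
    ``col_to_res[acc][c-1]`` is the 1-based residue index at column ``c``,
    or 0 where the row has a gap.
    """

    alignment: Alignment
    res_to_col: dict[str, np.ndarray] = field(init=False)
    col_to_res: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.res_to_col = {}
        self.col_to_res = {}
        for acc, gapped in self.alignment.rows:
            chars = np.frombuffer(gapped.encode("ascii"), dtype=np.uint8)
            is_res = chars != ord(GAP)
            col_to_res = np.where(is_res, np.cumsum(is_res), 0)
            self.col_to_res[acc] = col_to_res
            self.res_to_col[acc] = np.flatnonzero(is_res) + 1

    def column_of(self, accession: str, position: int) -> int | None:
        """1-based alignment column of residue ``position``, or None if out of range."""
        arr = self.res_to_col[accession]
        if not 1 <= position <= len(arr):
            return None
        return int(arr[position - 1])

    def residue_at(self, accession: str, column: int) -> int:
        """1-based residue index at ``column`` (0 when the row has a gap there)."""
        return int(self.col_to_res[accession][column - 1])


def build_position_map(alignment: Alignment) -> PositionMap:
    return PositionMap(alignment)


def map_position(
    pmap: PositionMap, from_row: str, position: int, to_row: str
) -> MappedPosition:
    """Carry a 1-based residue position from one row to another via its column."""
    if from_row not in pmap.res_to_col:
        raise KeyError(f"unknown row accession {from_row!r}")
    if to_row not in pmap.res_to_col:
        raise KeyError(f"unknown row accession {to_row!r}")
    column = pmap.column_of(from_row, position)
    if column is None:
        return MappedPosition(status="out-of-range")
    target_idx = pmap.residue_at(to_row, column)
    if target_idx == 0:
        return MappedPosition(status="gap-in-target", column=column)
    residue = pmap.alignment.gapped(to_row)[column - 1]
    return MappedPosition(
        status="mapped",
        column=column,
        target_position=target_idx,
        target_residue=residue,
    )


def similarity_index(alignment: Alignment, window: int = 1) -> np.ndarray:
    """Per-column fraction of identical non-gap residue pairs among the rows.

    For each column the fraction of row pairs carrying the same (non-gap)
    residue is reported; any pair involving a gap counts as a mismatch.
    ``window`` > 1 applies a centered sliding-window mean (edges use the
    available columns).
    """
    if len(alignment.rows) < 2:
        raise DataError("similarity index needs at least 2 rows")
    if window < 1 or window > alignment.width:
        raise DataError(f"window {window} out of range for width {alignment.width}")
    rows = [seq for _, seq in alignment.rows]
    n_pairs = len(rows) * (len(rows) - 1) // 2
    values = np.empty(alignment.width, dtype=float)
    for c in range(alignment.width):
        identical = sum(
            1
            for r1, r2 in combinations(rows, 2)
            if r1[c] != GAP and r1[c] == r2[c]
        )
        values[c] = identical / n_pairs
    if window > 1:
        kernel = np.ones(window) / window
        padded = np.convolve(values, kernel, mode="same")
        # renormalise the edges where the kernel overhangs
        counts = np.convolve(np.ones_like(values), kernel, mode="same")
        values = padded / counts
    return values


def ungap_rows(alignment: Alignment) -> dict[str, str]:
    """Accession → ungapped sequence for every row."""
    return {acc: seq.replace(GAP, "") for acc, seq in alignment.rows}
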