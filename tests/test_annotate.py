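"""Significance normalization, annotation transfer, chi-square comparisons."""

import numpy as np
import pytest

from matchvar import (
    Alignment,
    ContingencyTable2x2,
    ProteinChange,
    ProteinVariant,
    SignificanceClass,
    build_position_map,
    chi_square_2x2,
    normalize_significance,
    proportion_comparison,
    transfer_annotations,
)
from matchvar.annotate import export_lollipop, load_significance_map
from matchvar.core import MatchVar
from matchvar.errors import DataError
from matchvar.seq_io import DomainAnnotation, PtmAnnotation, ProteinRecord
from oracles import pearson_chi2_2x2


class TestNormalizeSignificance:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("Pathogenic", SignificanceClass.PATHOGENIC),
            ("Pathogenic/Likely pathogenic", SignificanceClass.LIKELY_PATHOGENIC),
            ("Uncertain significance", SignificanceClass.VUS),
            ("Benign", SignificanceClass.BENIGN),
            ("phenotype", SignificanceClass.PHENOTYPIC),
            ("not provided", SignificanceClass.UNKNOWN),
        ],
    )
    def test_known_labels(self, label, expected):
        assert normalize_significance(label) is expected

    def test_unmapped_label_goes_to_other_and_logs(self, caplog):
        with caplog.at_level("WARNING"):
            assert normalize_significance("frobnitz") is SignificanceClass.OTHER
        assert "frobnitz" in caplog.text

    def test_empty_label_rejected(self):
        with pytest.raises(DataError):
            normalize_significance("  ")

    def test_mapping_file_round_trip(self, tmp_path):
        path = tmp_path / "sig.tsv"
        path.write_text("# custom map\nDisease causing\tpathogenic\n")
        table = load_significance_map(path)
        assert normalize_significance("disease causing", table) is (
            SignificanceClass.PATHOGENIC
        )


class TestTransferAnnotations:
    def _pmap(self, row_a, row_b):
        return build_position_map(Alignment(rows=(("A", row_a), ("B", row_b))))

    def test_ptm_on_self_alignment_keeps_position(self):
        pmap = self._pmap("ACDEF", "ACDEF")
        report = transfer_annotations(
            [PtmAnnotation("A", 3, "phospho")], [], pmap, "A", "B"
        )
        assert report.transferred_ptms == [PtmAnnotation("B", 3, "phospho")]

    def test_ptm_into_gap_reported_unmappable(self):
        pmap = self._pmap("ACDEF", "AC-EF")
        report = transfer_annotations(
            [PtmAnnotation("A", 3, "phospho")], [], pmap, "A", "B"
        )
        assert report.transferred_ptms == []
        assert report.unmappable == [(PtmAnnotation("A", 3, "phospho"), "gap-in-target")]

    def test_domain_endpoints_truncate_into_gaps(self):
        # columns:      1234567
        # A residues:   ABCDEFG -> [3,7]
        # B row:        AB CDEF-  (gap under G): endpoint 7 truncates to residue 6
        pmap = self._pmap("ACDEFWG", "ACDEFW-")
        report = transfer_annotations(
            [], [DomainAnnotation("A", 3, 7, "dom")], pmap, "A", "B"
        )
        assert report.transferred_domains == [DomainAnnotation("B", 3, 6, "dom")]

    def test_transferred_positions_never_exceed_target_length(self):
        from matchvar import align_global
        from matchvar.fixtures import evolve, random_protein

        parent = random_protein(120, seed=31, accession="A")
        pair = evolve(parent, 0.1, 0.05, seed=32, child_accession="B")
        aln = align_global(pair.parent.sequence, pair.child.sequence, "A", "B")
        pmap = build_position_map(aln)
        ptms = [PtmAnnotation("A", p, "x") for p in range(1, len(parent) + 1, 7)]
        domains = [DomainAnnotation("A", 10, 100, "d")]
        report = transfer_annotations(ptms, domains, pmap, "A", "B")
        limit = len(pair.child)
        assert all(1 <= p.position <= limit for p in report.transferred_ptms)
        assert all(1 <= d.start <= d.end <= limit for d in report.transferred_domains)


class TestChiSquare:
    def test_equal_proportions_zero_statistic(self):
        table = ContingencyTable2x2(10, 90, 10, 90)
        res = chi_square_2x2(table)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_known_table_closed_form(self):
        # N(ad-bc)^2/((a+b)(c+d)(a+c)(b+d)) = 200*2000^2/(100*100*40*160) = 12.5
        res = chi_square_2x2(ContingencyTable2x2(30, 70, 10, 90))
        assert res.statistic == pytest.approx(12.5)
        assert res.df == 1

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            a, b, c, d = rng.integers(1, 200, size=4)
            res = chi_square_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert res.statistic == pytest.approx(
                pearson_chi2_2x2(int(a), int(b), int(c), int(d)), abs=1e-10
            )

    def test_row_swap_invariance(self):
        r1 = chi_square_2x2(ContingencyTable2x2(30, 70, 10, 90))
        r2 = chi_square_2x2(ContingencyTable2x2(10, 90, 30, 70))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.proportions == tuple(reversed(r2.proportions))

    def test_zero_marginal_rejected(self):
        with pytest.raises(DataError, match="marginal"):
            chi_square_2x2(ContingencyTable2x2(0, 0, 10, 90))

    def test_yates_correction_shrinks_statistic(self):
        table = ContingencyTable2x2(30, 70, 10, 90)
        assert chi_square_2x2(table, yates=True).statistic < chi_square_2x2(table).statistic


def _mv(human_sig, model_sig):
    va = ProteinVariant("H", ProteinChange("P", 3, "S"), "ClinVar",
                        significance=human_sig)
    vb = ProteinVariant("W", ProteinChange("P", 3, "S"), "WormBase",
                        significance=model_sig)
    return MatchVar(va, vb, column=3, position_a=3, position_b=3,
                    shared_ref="P", shared_alt="S")


class TestProportionComparison:
    def test_table_construction_and_classes(self):
        mvs = (
            [_mv("Pathogenic", "phenotypic")] * 6
            + [_mv("Pathogenic", "unknown")] * 4
            + [_mv("Benign", "phenotypic")] * 2
            + [_mv("Benign", "unknown")] * 8
            + [_mv("Uncertain significance", "phenotypic")] * 5  # ignored
        )
        table, res = proportion_comparison(
            mvs, SignificanceClass.PATHOGENIC, SignificanceClass.BENIGN
        )
        assert (table.a, table.b, table.c, table.d) == (6, 4, 2, 8)
        assert res.proportions == (0.6, 0.2)

    def test_planted_enrichment_detected(self):
        """Phenotypic fraction enriched among pathogenic humans at odds ratio
        3 with 500 MatchVars per arm: the chi-square test rejects."""
        rng = np.random.default_rng(41)
        p_benign = 0.2
        odds = 3 * p_benign / (1 - p_benign)
        p_path = odds / (1 + odds)
        mvs = []
        for _ in range(500):
            mvs.append(_mv("Pathogenic",
                           "phenotypic" if rng.random() < p_path else "unknown"))
            mvs.append(_mv("Benign",
                           "phenotypic" if rng.random() < p_benign else "unknown"))
        _, res = proportion_comparison(
            mvs, SignificanceClass.PATHOGENIC, SignificanceClass.BENIGN
        )
        assert res.p_value < 0.05


class TestLollipopExport:
    PROTEIN = ProteinRecord("P1", "ACDEFGHIKL")

    def test_empty_variant_set_gives_length_row_only(self):
        rows, excluded = export_lollipop([], [], self.PROTEIN)
        assert [r["track"] for r in rows] == ["protein"]
        assert rows[0]["end"] == 10 and excluded == []

    def test_variant_classes_labelled(self):
        variants = [
            ProteinVariant("P1", ProteinChange("C", 2, "S"), "ClinVar",
                           significance="Pathogenic"),
            ProteinVariant("P1", ProteinChange("F", 5, "L"), "ClinVar",
                           significance="Uncertain significance"),
        ]
        rows, _ = export_lollipop(variants, [DomainAnnotation("P1", 2, 6, "dom")],
                                  self.PROTEIN)
        classes = [r["class"] for r in rows if r["track"] == "variant"]
        assert classes == ["pathogenic", "vus"]
        assert any(r["track"] == "domain" and r["name"] == "dom" for r in rows)

    def test_out_of_range_variant_excluded_and_reported(self):
        far = ProteinVariant("P1", ProteinChange("A", 99, "T"), "db")
        rows, excluded = export_lollipop([far], [], self.PROTEIN)
        assert excluded == [far]
        assert all(r["track"] != "variant" for r in rows)
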