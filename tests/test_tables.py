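"""Contingency tables, HWE derivation, and the allelic chi-square."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.stats import chi2_contingency

from dpgwas import (
    DomainError,
    GenotypeTable,
    SnpPanel,
    allelic_chi2,
    allelic_from_genotype,
    chi2_of_x,
    chi2_profile,
    chi2_threshold,
    hwe_control_genotypes,
    read_panel,
    write_panel,
)
from dpgwas.tables import round_preserving_sum


class TestHweControlGenotypes:
    @pytest.mark.parametrize(
        "maf,S,expected",
        [
            (0.5, 100, (25, 50, 25)),
            (0.0, 50, (50, 0, 0)),
            (1.0, 50, (0, 0, 50)),
            (0.1, 174, (174 * 0.81, 2 * 174 * 0.1 * 0.9, 174 * 0.01)),
        ],
    )
    def test_closed_forms(self, maf, S, expected):
        assert hwe_control_genotypes(maf, S) == pytest.approx(expected, abs=1e-12)

    @given(maf=st.floats(0, 1), S=st.integers(1, 10_000))
    @settings(deadline=None, max_examples=200)
    def test_conserves_sample_size(self, maf, S):
        s = hwe_control_genotypes(maf, S)
        assert sum(s) == pytest.approx(S, abs=1e-12 * S)
        assert min(s) >= 0

    @pytest.mark.parametrize("maf,S", [(-0.1, 10), (1.1, 10), (0.2, 0), (0.2, -5)])
    def test_domain_errors(self, maf, S):
        with pytest.raises(DomainError):
            hwe_control_genotypes(maf, S)

    def test_largest_remainder_rounding(self):
        s = hwe_control_genotypes(0.31, 174)
        rounded = round_preserving_sum(s)
        assert sum(rounded) == 174
        assert all(abs(a - b) < 1 for a, b in zip(rounded, s))


class TestAllelicTable:
    @pytest.mark.parametrize(
        "r,s,case_cells,control_cells",
        [
            ((10, 0, 0), (10, 0, 0), (0, 20), (0, 20)),
            ((0, 0, 10), (5, 5, 0), (20, 0), (5, 15)),
            ((5, 3, 2), (6, 2, 2), (7, 13), (6, 14)),
        ],
    )
    def test_cell_formulas(self, r, s, case_cells, control_cells):
        a = allelic_from_genotype(GenotypeTable(*r, *s))
        assert (a.case_minor, a.case_major) == case_cells
        assert (a.control_minor, a.control_major) == control_cells

    def test_row_totals_are_allele_counts(self):
        t = GenotypeTable(5, 3, 2, 6.5, 2.2, 2.3)
        a = allelic_from_genotype(t)
        assert a.case_total == 2 * t.R
        assert a.control_total == pytest.approx(2 * t.S)


class TestAllelicChi2:
    def test_proportional_rows_give_zero(self):
        t = GenotypeTable(4, 4, 2, 8, 8, 4)
        assert allelic_chi2(t) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_zero_convention(self, caplog):
        t = GenotypeTable(10, 0, 0, 20, 0, 0)
        with caplog.at_level("WARNING", logger="dpgwas"):
            assert allelic_chi2(t) == 0.0
        assert "monomorphic" in caplog.text

    def test_matches_independent_pearson(self):
        t = GenotypeTable(5, 3, 2, 10, 8, 2)
        ours = allelic_chi2(t)
        ref = chi2_contingency(
            allelic_from_genotype(t).as_array(), correction=False
        ).statistic
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_pearson_equivalence_many_tables(self, random_tables):
        """Tabular formula equals Pearson chi-square on the 2x2 allelic table."""
        for t in random_tables:
            ref = chi2_contingency(
                allelic_from_genotype(t).as_array(), correction=False
            ).statistic
            assert allelic_chi2(t) == pytest.approx(ref, rel=1e-9, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            allelic_chi2(GenotypeTable(0, 0, 0, 5, 5, 5))


class TestChi2OfX:
    def test_zero_at_vertex(self):
        # x = n10 R / S attainable: n10=20, R=10, S=20 -> x=10
        assert chi2_of_x(10, 20, 10, 20, 30) == pytest.approx(0.0, abs=1e-12)

    def test_consistent_with_tabular_form(self, random_tables):
        """All tables on one x-line share one statistic."""
        for t in random_tables:
            x = 2 * t.r0 + t.r1
            n10 = 2 * t.s0 + t.s1
            assert chi2_of_x(x, n10, t.R, t.S, t.N) == pytest.approx(
                allelic_chi2(t), rel=1e-9, abs=1e-9
            )

    def test_boundary_max_formula(self):
        """Endpoint values match max{2NRn10/(S(2N-n10)), 2NR(2S-n10)/(S(2R+n10))}."""
        n10, R, S = 28.0, 10, 20.0
        N = R + S
        y0 = chi2_of_x(0, n10, R, S, N)
        y2r = chi2_of_x(2 * R, n10, R, S, N)
        assert y0 == pytest.approx(2 * N * R * n10 / (S * (2 * N - n10)), rel=1e-12)
        assert y2r == pytest.approx(
            2 * N * R * (2 * S - n10) / (S * (2 * R + n10)), rel=1e-12
        )
        assert max(chi2_of_x(x, n10, R, S, N) for x in range(2 * R + 1)) <= max(y0, y2r)

    def test_unimodality_about_vertex(self, rng):
        """Decreasing left of x = n10 R/S, increasing right of it (trend lemma)."""
        for _ in range(100):
            R = int(rng.integers(2, 80))
            S = float(rng.integers(2, 80))
            n10 = float(rng.uniform(0.5, 2 * S - 0.5))
            ys = chi2_profile(n10, R, S)
            vertex = n10 * R / S
            x = np.arange(2 * R + 1)
            left = ys[x < vertex]
            right = ys[x > vertex]
            assert np.all(np.diff(left) <= 1e-12)
            assert np.all(np.diff(right) >= -1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            chi2_of_x(-1, 10, 5, 10, 15)
        with pytest.raises(DomainError):
            chi2_of_x(0, 0, 5, 10, 15)  # zero margin


class TestChi2Threshold:
    def test_classic_critical_value(self):
        assert chi2_threshold(0.05).c == pytest.approx(3.8415, abs=5e-5)

    def test_limit_small_c(self):
        assert chi2_threshold(1 - 1e-9).c == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("p_star", [0.1 / 5000, 0.01 / 5000, 0.05, 0.5])
    def test_survival_round_trip(self, p_star):
        thr = chi2_threshold(p_star)
        assert stats.chi2.sf(thr.c, df=1) == pytest.approx(p_star, rel=1e-10)

    def test_monotone_in_p_star(self):
        cs = [chi2_threshold(p).c for p in (0.5, 0.05, 1e-3, 1e-8)]
        assert cs == sorted(cs)

    @pytest.mark.parametrize("p_star", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, p_star):
        with pytest.raises(DomainError):
            chi2_threshold(p_star)


class TestGenotypeTableInvariants:
    def test_rejects_negative_and_fractional_case_counts(self):
        with pytest.raises(DomainError):
            GenotypeTable(-1, 0, 1, 1, 1, 1)
        with pytest.raises(DomainError):
            GenotypeTable(1.5, 0, 1, 1, 1, 1)
        with pytest.raises(DomainError):
            GenotypeTable(1, 0, 1, -0.5, 1, 1)

    def test_totals(self):
        t = GenotypeTable(5, 3, 2, 6.5, 2.2, 2.3)
        assert t.R == 10
        assert t.S == pytest.approx(11.0)
        assert t.N == pytest.approx(21.0)


class TestPanelIO:
    def make_panel(self):
        tables = [
            GenotypeTable(5, 3, 2, 10, 8, 2),
            GenotypeTable(0, 4, 6, 7, 9, 4),
            GenotypeTable(9, 1, 0, 12, 6, 2),
        ]
        return SnpPanel(snp_ids=["rs1", "rs2", "rs3"], tables=tables)

    def test_round_trip_byte_identical(self, tmp_path):
        panel = self.make_panel()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_panel(panel, p1)
        write_panel(read_panel(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_control_maf_form_derives_hwe(self, tmp_path):
        path = tmp_path / "maf.tsv"
        path.write_text("snp_id\tr0\tr1\tr2\tcontrol_maf\nrs1\t5\t3\t2\t0.25\n")
        panel = read_panel(path, n_controls=100)
        t = panel.tables[0]
        assert t.control_row == pytest.approx(hwe_control_genotypes(0.25, 100))
        assert panel.control_maf["rs1"] == 0.25

    def test_control_maf_requires_n_controls(self, tmp_path):
        path = tmp_path / "maf.tsv"
        path.write_text("snp_id\tr0\tr1\tr2\tcontrol_maf\nrs1\t5\t3\t2\t0.25\n")
        with pytest.raises(DomainError, match="n_controls"):
            read_panel(path)

    def test_invalid_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "snp_id\tr0\tr1\tr2\ts0\ts1\ts2\n"
            "rs1\t5\t3\t2\t10\t8\t2\n"
            "rs2\t-1\t3\t2\t10\t8\t2\n"
        )
        with pytest.raises(DomainError, match=r":3:"):
            read_panel(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DomainError):
            SnpPanel(
                snp_ids=["rs1", "rs1"],
                tables=[GenotypeTable(1, 0, 0, 1, 1, 1)] * 2,
            )

    def test_comment_lines_skipped(self, tmp_path):
        panel = self.make_panel()
        path = tmp_path / "prov.tsv"
        write_panel(panel, path, provenance="dpgwas-config-sha256:deadbeef")
        assert path.read_text().startswith("# dpgwas")
        back = read_panel(path)
        assert back.snp_ids == panel.snp_ids
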