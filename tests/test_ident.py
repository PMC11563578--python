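"""Identification parsing, merging, fragment ladders and spectrum validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xlquant import masschem as mc
from xlquant.ident import (
    CrosslinkID,
    MonolinkID,
    ParseIssue,
    PeptideForm,
    QLINKER_CROSSLINK,
    QLINKER_MONOLINK,
    SiteKey,
    ambiguous_scans,
    link_class,
    merge_engines,
    parse_ids,
    site_key,
    theoretical_fragments,
    validate_spectrum,
    write_interchange,
)
from xlquant.spectra import Spectrum

INTERCHANGE_TEXT = """\
run\tscan\ttype\tpepA\tlinkA\tprotA\tresA\tpepB\tlinkB\tprotB\tresB\tscore\tengine\tdecoy
runA\t10\txl\tAKR\t2\tRpb7\t23\tMKE\t2\tRpb4\t80\t12.5\tNexus\t0
runA\t11\txl\tSYKDE\t3\tRpb1\t332\tLLKQ\t3\tRpb2\t507\t8.1\tpLink2;Nexus\t0
runA\t12\tmono\tSYEEELAKDPR\t8\tMBP\t313\t\t\t\t\t20\tComet\t0
"""


@pytest.fixture()
def interchange_file(tmp_path):
    p = tmp_path / "ids.tsv"
    p.write_text(INTERCHANGE_TEXT)
    return p


class TestParsing:
    def test_interchange_roundtrip(self, interchange_file, tmp_path):
        ids = parse_ids(interchange_file)
        assert len(ids) == 3
        assert isinstance(ids[0], CrosslinkID) and isinstance(ids[2], MonolinkID)
        assert site_key(ids[0]) == SiteKey((("Rpb4", 80), ("Rpb7", 23)))
        assert ids[1].engines == frozenset({"pLink2", "Nexus"})
        out = tmp_path / "echo.tsv"
        write_interchange(ids, out)
        again = parse_ids(out)
        assert [site_key(i) for i in again] == [site_key(i) for i in ids]

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(INTERCHANGE_TEXT.splitlines()[0] + "\n")
        assert parse_ids(p) == []

    def test_bad_link_position_collected_not_fatal(self, tmp_path):
        bad = INTERCHANGE_TEXT + "runA\t13\tmono\tAK\t9\tX\t1\t\t\t\t\t1\tN\t0\n"
        p = tmp_path / "bad.tsv"
        p.write_text(bad)
        issues: list[ParseIssue] = []
        ids = parse_ids(p, issues=issues)
        assert len(ids) == 3
        assert len(issues) == 1 and issues[0].row == 5

    def test_unknown_dialect(self, interchange_file):
        with pytest.raises(ValueError):
            parse_ids(interchange_file, dialect="pepxml")

    def test_plink2_csv(self, tmp_path):
        p = tmp_path / "plink.csv"
        p.write_text(
            "Title,Peptide,Proteins,Score\n"
            "runB.101.101.3,AKR(2)-MKE(2),Rpb7 (23)-Rpb4 (80),0.001\n"
            "runB.102.102.2,SYEEELAKDPR(8),MBP (313),0.01\n"
        )
        ids = parse_ids(p, dialect="plink2_csv")
        assert len(ids) == 2
        assert ids[0].run_id == "runB" and ids[0].scan == 101
        assert site_key(ids[0]) == SiteKey((("Rpb4", 80), ("Rpb7", 23)))
        assert site_key(ids[1]) == SiteKey((("MBP", 313),))

    def test_decoy_rows_flagged_not_dropped(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            INTERCHANGE_TEXT.splitlines()[0] + "\n"
            "runA\t20\tmono\tAKR\t2\tX\t5\t\t\t\t\t1\tN\t1\n"
        )
        ids = parse_ids(p)
        assert len(ids) == 1 and ids[0].decoy


class TestSiteKeys:
    def test_canonical_order(self):
        key = SiteKey((("Rpb7", 23), ("Rpb4", 80)))
        assert key.sites == (("Rpb4", 80), ("Rpb7", 23))

    def test_symmetry_under_peptide_swap(self):
        a = CrosslinkID(run_id="r", scan=1, alpha=PeptideForm("AKR", 2),
                        beta=PeptideForm("MKE", 2), site_alpha=("Rpb7", 23),
                        site_beta=("Rpb4", 80))
        b = CrosslinkID(run_id="r", scan=1, alpha=PeptideForm("MKE", 2),
                        beta=PeptideForm("AKR", 2), site_alpha=("Rpb4", 80),
                        site_beta=("Rpb7", 23))
        assert site_key(a) == site_key(b)

    def test_link_classes(self):
        assert link_class(SiteKey((("MBP", 313),))) == "monolink"
        assert link_class(SiteKey((("TBP", 47), ("TBP", 83)))) == "intralink"
        assert link_class(SiteKey((("Rpb4", 80), ("Rpb7", 23)))) == "interlink"

    def test_string_round_trip(self):
        key = SiteKey((("Rpb4", 80), ("Rpb7", 23)))
        assert SiteKey.from_string(str(key)) == key


class TestMerging:
    def _mk(self, scan, sites, engine, score=1.0):
        return CrosslinkID(
            run_id="r", scan=scan, engines=frozenset({engine}), score=score,
            alpha=PeptideForm("AKR", 2), beta=PeptideForm("MKE", 2),
            site_alpha=sites[0], site_beta=sites[1],
        )

    def test_same_scan_same_sites_union_engines(self):
        a = self._mk(5, (("P1", 10), ("P2", 20)), "Nexus")
        b = self._mk(5, (("P2", 20), ("P1", 10)), "pLink2")
        merged = merge_engines([a], [b])
        assert len(merged) == 1
        assert merged[0].engines == frozenset({"Nexus", "pLink2"})

    def test_disjoint_scans_concatenate(self):
        a = self._mk(1, (("P1", 1), ("P2", 2)), "Nexus")
        b = self._mk(2, (("P1", 1), ("P2", 2)), "pLink2")
        assert len(merge_engines([a], [b])) == 2

    def test_conflicting_sites_kept_and_flagged(self):
        a = self._mk(5, (("P1", 10), ("P2", 20)), "Nexus")
        b = self._mk(5, (("P1", 10), ("P3", 30)), "pLink2")
        merged = merge_engines([a], [b])
        assert len(merged) == 2
        amb = ambiguous_scans(merged)
        assert ("r", 5) in amb and len(amb[("r", 5)]) == 2

    def test_merge_is_idempotent(self):
        ids = [
            self._mk(1, (("P1", 1), ("P2", 2)), "Nexus"),
            self._mk(1, (("P1", 1), ("P2", 2)), "pLink2"),
            self._mk(2, (("P1", 3), ("P2", 4)), "Nexus"),
        ]
        once = merge_engines(ids)
        twice = merge_engines(once)
        assert once == twice


def _brute_force_ladder(seq, extra=None):
    """Independent b/y ladder: cumulative residue sums, charge 1."""
    extra = extra or {}
    masses = [mc.AMINO_ACID_MASSES[a] + extra.get(i + 1, 0.0)
              for i, a in enumerate(seq)]
    water = mc.monoisotopic_mass("H2O")
    b = [sum(masses[:i]) + mc.PROTON_MASS for i in range(1, len(seq))]
    y = [sum(masses[-i:]) + water + mc.PROTON_MASS for i in range(1, len(seq))]
    return b, y


class TestFragments:
    def test_fragment_count(self):
        ident = MonolinkID(run_id="r", scan=1,
                           peptide=PeptideForm("SYEEELAKDPR", 8),
                           site=("MBP", 313))
        frags = theoretical_fragments(ident, charges=(1,))
        n = 11
        assert len(frags) == 2 * (n - 1)

    def test_monolink_y1_hand_summed(self):
        # K residue + monolink delta + water + proton, summed by hand
        ident = MonolinkID(run_id="r", scan=1, peptide=PeptideForm("AK", 2),
                           site=("MBP", 313))
        frags = dict(theoretical_fragments(ident, charges=(1,)))
        expected = (mc.AMINO_ACID_MASSES["K"] + QLINKER_MONOLINK.delta_mass
                    + mc.monoisotopic_mass("H2O") + mc.PROTON_MASS)
        assert frags["y1+1"] == pytest.approx(expected, abs=1e-6)
        assert round(frags["y1+1"], 2) == 444.29

    def test_unmodified_ladder_matches_brute_force(self):
        ident = MonolinkID(run_id="r", scan=1, peptide=PeptideForm("PEPTIDEK", 8),
                           site=("X", 8))
        frags = dict(theoretical_fragments(ident, charges=(1,), include_linker=False))
        b, y = _brute_force_ladder("PEPTIDEK")
        for i, (bm, ym) in enumerate(zip(b, y), start=1):
            assert frags[f"b{i}+1"] == pytest.approx(bm, abs=1e-9)
            assert frags[f"y{i}+1"] == pytest.approx(ym, abs=1e-9)

    def test_crosslink_partner_is_fixed_mass(self):
        ident = CrosslinkID(
            run_id="r", scan=1, alpha=PeptideForm("AKR", 2),
            beta=PeptideForm("MKE", 2), site_alpha=("P1", 2), site_beta=("P2", 2),
        )
        frags = dict(theoretical_fragments(ident, charges=(1,)))
        partner = PeptideForm("MKE", 2).mass + QLINKER_CROSSLINK.delta_mass
        b, y = _brute_force_ladder("AKR", extra={2: partner})
        assert frags["bA2+1"] == pytest.approx(b[1], abs=1e-9)
        assert frags["yA2+1"] == pytest.approx(y[1], abs=1e-9)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=12))
    @settings(max_examples=40, derandomize=True)
    def test_by_complementarity(self, seq):
        """b_i + y_(n-i) = MH+ + proton for every cleavage position."""
        pep = PeptideForm(seq + "K", len(seq) + 1)
        ident = MonolinkID(run_id="r", scan=1, peptide=pep, site=("X", 1))
        frags = dict(theoretical_fragments(ident, charges=(1,)))
        n = len(pep.sequence)
        mh = pep.mass + QLINKER_MONOLINK.delta_mass + mc.PROTON_MASS
        for i in range(1, n):
            total = frags[f"b{i}+1"] + frags[f"y{n - i}+1"]
            assert total == pytest.approx(mh + mc.PROTON_MASS, abs=1e-6)


def _spectrum_from(mzs, intensities):
    return Spectrum("r", 1, mz=mzs, intensity=intensities)


class TestValidation:
    @pytest.fixture()
    def monolink(self):
        return MonolinkID(run_id="r", scan=1,
                          peptide=PeptideForm("SYEEELAKDPR", 8),
                          site=("MBP", 313))

    def test_complete_ladder_passes(self, monolink):
        frags = theoretical_fragments(monolink, charges=(1,))
        s = _spectrum_from([m for _, m in frags], [1000.0] * len(frags))
        report = validate_spectrum(monolink, s)
        n = len(monolink.peptide.sequence)
        assert report.passed
        assert report.b_runs[0] == n - 1 and report.y_runs[0] == n - 1
        assert report.annotated_fraction == pytest.approx(1.0)

    def test_short_runs_fail(self, monolink):
        frags = theoretical_fragments(monolink, charges=(1,))
        keep = [(lbl, m) for lbl, m in frags
                if lbl in ("b1+1", "b2+1", "b3+1", "y1+1", "y2+1", "y3+1")]
        s = _spectrum_from([m for _, m in keep], [1000.0] * len(keep))
        report = validate_spectrum(monolink, s)
        assert max(report.b_runs[0], report.y_runs[0]) == 3
        assert not report.passed

    def test_dominant_noise_fails_majority(self, monolink):
        frags = theoretical_fragments(monolink, charges=(1,))
        mzs = [m for _, m in frags] + [900.0]
        ints = [100.0] * len(frags) + [1.1 * 100.0 * len(frags)]
        report = validate_spectrum(monolink, _spectrum_from(mzs, ints))
        assert report.annotated_fraction < 0.5
        assert not report.passed

    def test_both_peptides_must_have_runs(self):
        xl = CrosslinkID(
            run_id="r", scan=1, alpha=PeptideForm("PEPTIDEKR", 8),
            beta=PeptideForm("MKESTLNK", 2), site_alpha=("P1", 8),
            site_beta=("P2", 2),
        )
        frags = theoretical_fragments(xl, charges=(1,))
        only_a = [(lbl, m) for lbl, m in frags if "A" in lbl]
        s = _spectrum_from([m for _, m in only_a], [1000.0] * len(only_a))
        report = validate_spectrum(xl, s)
        assert max(report.b_runs[0], report.y_runs[0]) >= 4
        assert max(report.b_runs[1], report.y_runs[1]) == 0
        assert not report.passed
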