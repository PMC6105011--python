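import numpy as np
import pandas as pd
import pytest

from ptm_evoscan.conservation import (
    CLASS,
    STRICT,
    apply_column_mask,
    build_call_table,
    call_conservation,
    column_conserved,
    conserved_site_table,
    residue_class_for,
    residue_conservation_map,
    table1_summary,
)
from ptm_evoscan.datamodel_io import (
    METHYL_CLASS,
    CladeHierarchy,
    FamilyAlignment,
    PtmSite,
    ValidationError,
)
from ptm_evoscan.region_annotation import ORDERED, ResidueAnnotation

HS = "homo_sapiens"


def aln(human, **rows):
    return FamilyAlignment("p1", human, rows)


class TestPositionToColumn:
    def test_gap_offset(self):
        a = aln("M-KR", sp1="MQKR")
        assert a.position_to_column(2) == 3

    def test_first_position(self):
        a = aln("--MK", sp1="QQMK")
        assert a.position_to_column(1) == 3

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            aln("MK", sp1="MK").position_to_column(3)


class TestColumnConserved:
    def test_strict_all_equal(self):
        a = aln("K", pan="K", mus="K")
        ok, n = column_conserved(a, 1, {"pan", "mus"}, mode=STRICT)
        assert ok and n == 2

    def test_class_mode_allows_substitution(self):
        a = aln("K", pan="K", mus="R")
        strict_ok, _ = column_conserved(a, 1, {"pan", "mus"}, mode=STRICT)
        class_ok, _ = column_conserved(
            a, 1, {"pan", "mus"}, METHYL_CLASS, mode=CLASS
        )
        assert not strict_ok and class_ok

    def test_gap_kills_conservation_both_modes(self):
        a = aln("K", pan="K", mus="-")
        assert not column_conserved(a, 1, {"pan", "mus"}, mode=STRICT)[0]
        assert not column_conserved(a, 1, {"pan", "mus"}, METHYL_CLASS, mode=CLASS)[0]

    def test_absent_species_ignored(self):
        a = aln("K", pan="K")
        ok, n = column_conserved(a, 1, {"pan", "mus"}, mode=STRICT)
        assert ok and n == 1

    def test_no_rows_is_not_conserved(self):
        a = aln("K", pan="K")
        ok, n = column_conserved(a, 1, {"mus"}, mode=STRICT)
        assert not ok and n == 0

    def test_strict_implies_class_when_human_in_class(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            chars = rng.choice(list("KRAG-"), size=3)
            a = aln("K", pan=chars[0], mus=chars[1], rat=chars[2])
            strict_ok, _ = column_conserved(a, 1, {"pan", "mus", "rat"}, mode=STRICT)
            class_ok, _ = column_conserved(
                a, 1, {"pan", "mus", "rat"}, METHYL_CLASS, mode=CLASS
            )
            if strict_ok:
                assert class_ok


class TestResidueClassFor:
    def test_strict_is_singleton(self):
        rc = residue_class_for("methylation", "K", STRICT)
        assert rc.members == frozenset("K")

    def test_class_methylation(self):
        assert residue_class_for("methylation", "K", CLASS).members == frozenset("KR")

    def test_class_acetylation(self):
        assert residue_class_for("acetylation", "K", CLASS).members == frozenset("KAGMST")

    def test_class_ubiquitination_stays_strict(self):
        assert residue_class_for("ubiquitination", "K", CLASS).members == frozenset("K")


class TestApplyColumnMask:
    def test_recommended_range(self):
        mask = apply_column_mask([2, 5, 10])
        assert mask.retained == (False, True, True)

    def test_vacuous_mask(self):
        mask = apply_column_mask([0, 3, 7], min_score=0, max_score=10)
        assert all(mask.retained)

    def test_score_out_of_range(self):
        with pytest.raises(ValidationError):
            apply_column_mask([11])


class TestCallConservation:
    @pytest.fixture
    def hierarchy(self, tiny_hierarchy):
        return tiny_hierarchy

    def test_newly_emerged_truth_table(self, hierarchy):
        # conserved in Apes and Primates, broken from Mammals outward
        a = aln("K", pan="K", macaca="K", mus="Q", yeast="Q")
        site = PtmSite("p1", 1, "K", "methylation")
        calls = {c.level: c for c in call_conservation(site, a, hierarchy)}
        assert [calls[lv].conserved for lv in hierarchy.names] == [
            True, True, False, False,
        ]
        assert calls["Primates"].newly_emerged
        assert not calls["Apes"].newly_emerged
        assert not calls["Mammals"].newly_emerged

    def test_conserved_everywhere_never_new(self, hierarchy):
        a = aln("K", pan="K", macaca="K", mus="K", yeast="K")
        site = PtmSite("p1", 1, "K", "methylation")
        calls = call_conservation(site, a, hierarchy)
        assert all(c.conserved for c in calls)
        assert not any(c.newly_emerged for c in calls)

    def test_conserved_nowhere(self, hierarchy):
        a = aln("K", pan="Q", macaca="Q", mus="Q", yeast="Q")
        site = PtmSite("p1", 1, "K", "methylation")
        calls = call_conservation(site, a, hierarchy)
        assert not any(c.conserved for c in calls)

    def test_outermost_never_newly_emerged(self, hierarchy):
        a = aln("K", yeast="K")
        site = PtmSite("p1", 1, "K", "methylation")
        calls = call_conservation(site, a, hierarchy)
        euk = [c for c in calls if c.level == "Eukaryotes"]
        assert euk[0].conserved and not euk[0].newly_emerged

    def test_levels_without_inclusion_skipped(self, hierarchy):
        a = aln("K", mus="K")  # no ape/primate ortholog
        site = PtmSite("p1", 1, "K", "methylation")
        levels = [c.level for c in call_conservation(site, a, hierarchy)]
        assert levels == ["Mammals", "Eukaryotes"]

    def test_mask_forces_not_conserved(self, hierarchy):
        a = aln("K", pan="K", macaca="K", mus="K", yeast="K")
        site = PtmSite("p1", 1, "K", "methylation")
        mask = apply_column_mask([2.0])  # below retained range
        calls = call_conservation(site, a, hierarchy, mask=mask)
        assert all(c.masked and not c.conserved for c in calls)

    def test_masking_only_removes_conservation(self, hierarchy):
        rng = np.random.default_rng(4)
        for _ in range(50):
            human = "".join(rng.choice(list("KRQ"), 5))
            rows = {
                sp: "".join(rng.choice(list("KRQ-"), 5))
                for sp in ("pan", "macaca", "mus", "yeast")
            }
            a = FamilyAlignment("p1", human, rows)
            pos = int(rng.integers(1, 6))
            site = PtmSite("p1", pos, human[pos - 1], "methylation")
            mask = apply_column_mask(rng.uniform(0, 10, 5))
            unmasked = {c.level: c for c in call_conservation(site, a, hierarchy)}
            masked = {
                c.level: c for c in call_conservation(site, a, hierarchy, mask=mask)
            }
            for level, call in masked.items():
                assert not (call.conserved and not unmasked[level].conserved)

    def test_nesting_property_random_alignments(self, hierarchy):
        rng = np.random.default_rng(8)
        for _ in range(200):
            human = "".join(rng.choice(list("KRQA"), 8))
            rows = {
                sp: "".join(rng.choice(list("KRQA-"), 8))
                for sp in ("pan", "macaca", "mus", "yeast")
                if rng.random() < 0.8
            }
            if not rows:
                continue
            a = FamilyAlignment("p1", human, rows)
            pos = int(rng.integers(1, 9))
            site = PtmSite("p1", pos, human[pos - 1], "methylation")
            calls = call_conservation(site, a, hierarchy)
            flags = [c.conserved for c in calls]
            # conserved at a wider level implies conserved at any narrower one
            for narrow, wide in zip(flags, flags[1:]):
                assert not (wide and not narrow)


class TestCallTableAndSummaries:
    @pytest.fixture
    def small_calls(self, tiny_hierarchy):
        human = "KKRKK"
        a = FamilyAlignment(
            "p1", human,
            {"pan": "KKRKK", "macaca": "KKRKK", "mus": "KKRKQ", "yeast": "QKRKQ"},
        )
        sites = [
            PtmSite("p1", 1, "K", "methylation"),
            PtmSite("p1", 3, "R", "methylation"),
            PtmSite("p1", 4, "K", "acetylation"),
            PtmSite("p1", 5, "K", "ubiquitination"),
        ]
        labels = np.array(
            [ORDERED, ORDERED, ORDERED, "disordered", "disordered"], dtype=object
        )
        anns = {"p1": ResidueAnnotation("p1", labels)}
        calls = build_call_table(sites, {"p1": a}, tiny_hierarchy, anns)
        return calls

    def test_rows_per_site_per_level(self, small_calls):
        assert len(small_calls) == 4 * 4  # 4 sites x 4 included levels

    def test_aggregation_counts(self, small_calls):
        table = conserved_site_table(small_calls)
        row = table[
            (table.level == "Eukaryotes")
            & (table.ptm_type == "methylation")
            & (table.residue == "R")
        ].iloc[0]
        assert row.n_total == 1 and row.n_conserved == 1

    def test_empty_input(self):
        assert conserved_site_table(pd.DataFrame()).empty

    def test_table1_shape(self, small_calls):
        t1 = table1_summary(small_calls, "Eukaryotes")
        assert set(t1.category) == {
            "all_mau", "methylation_K", "methylation_R",
            "acetylation_K", "ubiquitination_K",
        }
        all_mau_ord = t1[(t1.category == "all_mau") & (t1.region == "ordered")].iloc[0]
        # positions 1 (broken in yeast) and 3 (conserved) are ordered MAU residues
        assert all_mau_ord.total_residues == 2
        assert all_mau_ord.conserved_residues == 1

    def test_one_conserved_site_full_protein_count(self, small_calls):
        t1 = table1_summary(small_calls, "Eukaryotes")
        row = t1[(t1.category == "methylation_R") & (t1.region == "ordered")].iloc[0]
        assert row.proteins_with_conserved == 1 and row.total_proteins == 1


class TestResidueConservationMap:
    def test_matches_column_conserved(self, tiny_hierarchy):
        rng = np.random.default_rng(12)
        human = "".join(rng.choice(list("KRQA"), 20))
        rows = {
            sp: "".join(rng.choice(list("KRQA-"), 20))
            for sp in ("pan", "macaca", "mus", "yeast")
        }
        a = FamilyAlignment("p1", human, rows)
        positions = [i + 1 for i, ch in enumerate(human) if ch in "KR"]
        cmap = residue_conservation_map(a, tiny_hierarchy, positions)
        for pos in positions:
            for name, spp in tiny_hierarchy.levels:
                expected, _ = column_conserved(
                    a, a.position_to_column(pos), spp - {HS}, mode=STRICT
                )
                assert cmap[(pos, name)] == expected
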