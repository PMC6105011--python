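import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptm_evoscan.datamodel_io import ProteinSequence, PtmSite, ValidationError
from ptm_evoscan.enrichment_stats import (
    ResidueUniverse,
    TestSpec,
    bonferroni_threshold,
    conserved_mau_enrichment,
    format_percentage,
    hypergeom_tail,
    hypergeom_tail_log10,
    multi_mau,
    percentage_summary,
    run_test,
)
from ptm_evoscan.region_annotation import ResidueAnnotation


def oracle_tail(k, n, K, N, direction):
    """Exact tail by enumeration of all C(N, n) draws (tiny N only)."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in combinations(range(N), n):
        total += 1
        successes = sum(population[i] for i in draw)
        if direction == "enrich" and successes >= k:
            hits += 1
        if direction == "deplete" and successes <= k:
            hits += 1
    return Fraction(hits, total)


class TestHypergeomTail:
    def test_k_zero_enrich_is_one(self):
        assert hypergeom_tail(0, 4, 5, 10, "enrich") == pytest.approx(1.0)

    def test_worked_example(self):
        # C(5,4) C(5,0) / C(10,4) = 5/210
        assert hypergeom_tail(4, 4, 5, 10, "enrich") == pytest.approx(
            5 / 210, rel=1e-12
        )

    def test_degenerate_population(self):
        assert hypergeom_tail(3, 3, 3, 3, "enrich") == pytest.approx(1.0)

    def test_exhaustive_enumeration_oracle_tiny(self):
        for (k, n, K, N) in [(2, 3, 4, 8), (1, 4, 2, 7), (0, 2, 5, 9), (3, 5, 3, 9)]:
            for direction in ("enrich", "deplete"):
                expected = float(oracle_tail(k, n, K, N, direction))
                assert hypergeom_tail(k, n, K, N, direction) == pytest.approx(
                    expected, rel=1e-12
                )

    def test_bounds_violation_raises(self):
        with pytest.raises(ValidationError):
            hypergeom_tail(5, 4, 5, 10, "enrich")
        with pytest.raises(ValidationError):
            hypergeom_tail(1, 11, 5, 10, "enrich")

    def test_log10_survives_extreme_magnitudes(self):
        lg = hypergeom_tail_log10(400, 400, 400, 4000, "enrich")
        assert lg < -300  # far below double underflow as a plain probability
        assert math.isfinite(lg)

    @given(
        st.integers(1, 25).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(0, N),
                st.integers(0, N),
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_tails_share_observed_term(self, nkn):
        N, K, n = nkn
        lo, hi = max(0, n + K - N), min(n, K)
        for k in range(lo, hi + 1):
            p_e = hypergeom_tail(k, n, K, N, "enrich")
            p_d = hypergeom_tail(k, n, K, N, "deplete")
            assert p_e + p_d >= 1.0 - 1e-9


class TestBonferroni:
    def test_simple(self):
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)

    def test_identity(self):
        assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)

    def test_family_of_seven_matches_printed_threshold(self):
        assert bonferroni_threshold(0.05, 7) == pytest.approx(0.0071, abs=5e-5)

    def test_zero_family_error(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)


def _universe_10K():
    """10 K residues, 5 ordered, 4 MAU sites all ordered."""
    rows = []
    for i in range(10):
        rows.append(
            {
                "protein_id": "p1",
                "position": i + 1,
                "residue": "K",
                "region": "ordered" if i < 5 else "disordered",
                "fb": False,
                "homopeptide": False,
                "prion_like": False,
                "histone": False,
                "acetylation": i < 4,
                "any_mau": i < 4,
                "multi_mau": False,
            }
        )
    return ResidueUniverse(pd.DataFrame(rows))


class TestRunTest:
    def test_region_preference_enumeration_oracle(self):
        universe = _universe_10K()
        spec = TestSpec(
            name="acetyl-ordered",
            population={"residue": "K"},
            sample={"region": "ordered"},
            marker={"acetylation": True},
            direction="enrich",
        )
        res = run_test(spec, universe, alpha_corrected=0.05)
        assert (res.k, res.n, res.K, res.N) == (4, 5, 4, 10)
        expected = float(oracle_tail(4, 5, 4, 10, "enrich"))  # 6/252
        assert res.p_enrich == pytest.approx(expected, rel=1e-12)
        assert res.call == "enriched"  # 0.0238 <= 0.05

    def test_sample_equals_population(self):
        universe = _universe_10K()
        spec = TestSpec(
            name="trivial",
            population={"residue": "K"},
            sample={"residue": "K"},
            marker={"acetylation": True},
        )
        res = run_test(spec, universe)
        assert res.n == res.N and res.p_enrich == pytest.approx(1.0)

    def test_empty_population_is_error(self):
        universe = _universe_10K()
        spec = TestSpec(
            name="fb", population={"fb": True}, sample={}, marker={"acetylation": True}
        )
        with pytest.raises(ValidationError, match="empty population"):
            run_test(spec, universe)

    def test_empty_sample_warns_not_errors(self):
        universe = _universe_10K()
        spec = TestSpec(
            name="hp",
            population={"residue": "K"},
            sample={"homopeptide": True},
            marker={"acetylation": True},
        )
        res = run_test(spec, universe)
        assert res.n == 0 and res.warning

    def test_count_invariants(self):
        universe = _universe_10K()
        spec = TestSpec(
            name="x",
            population={},
            sample={"region": "disordered"},
            marker={"any_mau": True},
        )
        res = run_test(spec, universe)
        assert res.k <= res.K and res.k <= res.n and res.n <= res.N and res.K <= res.N


class TestMultiMau:
    @pytest.fixture
    def annotated(self):
        labels = np.array(["ordered"] * 3 + ["disordered"] * 3, dtype=object)
        return {"p1": ResidueAnnotation("p1", labels)}

    def test_two_types_counted_once(self, annotated):
        sites = [
            PtmSite("p1", 1, "K", "acetylation"),
            PtmSite("p1", 1, "K", "ubiquitination"),
        ]
        venn, multi = multi_mau(sites, annotated)
        cell = frozenset({"acetylation", "ubiquitination"})
        assert venn["ordered"].counts[cell] == 1
        assert venn["ordered"].counts[frozenset({"acetylation"})] == 0
        assert multi == [("p1", 1)]

    def test_single_type_not_multi(self, annotated):
        sites = [PtmSite("p1", 2, "K", "methylation")]
        venn, multi = multi_mau(sites, annotated)
        assert venn["ordered"].counts[frozenset({"methylation"})] == 1
        assert multi == []

    def test_three_types_only_triple_cell(self, annotated):
        sites = [
            PtmSite("p1", 4, "K", "methylation"),
            PtmSite("p1", 4, "K", "acetylation"),
            PtmSite("p1", 4, "K", "ubiquitination"),
        ]
        venn, _ = multi_mau(sites, annotated)
        counts = venn["disordered"].counts
        triple = frozenset({"methylation", "acetylation", "ubiquitination"})
        assert counts[triple] == 1
        assert sum(counts.values()) == 1

    def test_cells_sum_to_distinct_residues(self, annotated):
        rng = np.random.default_rng(3)
        sites = []
        for pos in range(1, 7):
            for t in ("methylation", "acetylation", "ubiquitination"):
                if rng.random() < 0.5:
                    sites.append(PtmSite("p1", pos, "K", t))
        venn, _ = multi_mau(sites, annotated)
        n_residues = len({(s.protein_id, s.position) for s in sites})
        assert sum(v.total() for v in venn.values()) == n_residues


class TestPercentageSummary:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (393, 91535, "0.43%"),
            (18, 356, "5.06%"),
            (0, 100, "0.00%"),
            (0, 0, "NA"),
        ],
    )
    def test_format(self, num, den, expected):
        assert format_percentage(num, den) == expected

    def test_summary_frame(self):
        table = pd.DataFrame(
            [
                {
                    "category": "all_mau",
                    "region": "ordered",
                    "conserved_residues": 393,
                    "total_residues": 91535,
                    "proteins_with_conserved": 270,
                    "total_proteins": 3719,
                }
            ]
        )
        out = percentage_summary(table)
        assert out.residues_pct.iloc[0] == "0.43%"
        assert out.proteins_pct.iloc[0] == "7.26%"
        assert out.conserved_residues.iloc[0] == 393  # raw counts retained


class TestConservedMauEnrichment:
    def test_signal_recovered(self):
        # 40 K residues: 10 sites conserved, 30 background mostly unconserved
        rows = []
        conserved_map = {}
        for i in range(40):
            is_site = i < 10
            rows.append(
                {
                    "protein_id": "p1",
                    "position": i + 1,
                    "residue": "K",
                    "region": "ordered",
                    "fb": False,
                    "homopeptide": False,
                    "prion_like": False,
                    "histone": False,
                    "acetylation": is_site,
                    "any_mau": is_site,
                    "multi_mau": False,
                }
            )
            if not is_site:
                conserved_map[("p1", i + 1)] = i < 12  # 2 of 30 background
        universe = ResidueUniverse(pd.DataFrame(rows))
        calls = pd.DataFrame(
            [
                {
                    "protein_id": "p1",
                    "position": i + 1,
                    "residue": "K",
                    "ptm_type": "acetylation",
                    "level": "Mammals",
                    "region": "ordered",
                    "conserved": True,
                    "newly_emerged": False,
                }
                for i in range(10)
            ]
        )
        res = conserved_mau_enrichment(
            "Mammals", "ordered", "acetylation", calls, universe,
            included_proteins=frozenset({"p1"}),
            conserved_map=conserved_map,
            alpha_corrected=0.05 / 11,
        )
        assert (res.k, res.n, res.K, res.N) == (10, 12, 10, 40)
        assert res.call == "enriched"

    def test_no_conserved_residues_warns(self):
        universe = _universe_10K()
        calls = pd.DataFrame(
            columns=["protein_id", "position", "residue", "ptm_type", "level",
                     "region", "conserved", "newly_emerged"]
        )
        res = conserved_mau_enrichment(
            "Mammals", "ordered", "acetylation", calls, universe,
            included_proteins=frozenset({"p1"}), conserved_map={},
        )
        assert res.n == 0 and res.call == "not_significant" and res.warning
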