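"""Tests for marker-site selection, parental screening and validation."""

import numpy as np
import pandas as pd
import pytest

from frostmas import markers as mk
from frostmas.scan import CandidateRegion


def _stats(positions, deltas, chrom="chr05"):
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "position": positions,
            "delta_snp_index": deltas,
        }
    )


class TestSelectTargetSites:
    def test_threshold_is_strict(self):
        region = CandidateRegion("chr05", 0, 10_000, 1.0, 1)
        stats = _stats([100, 200, 300], [0.25, 0.26, 0.24])
        with pytest.warns(UserWarning, match="qualify"):
            sites = mk.select_target_sites(stats, [region], n_per_region=3)
        assert [s.position for s in sites] == [200]

    def test_all_returned_when_exactly_enough(self):
        region = CandidateRegion("chr05", 0, 1_000_000, 1.0, 1)
        pos = list(range(1000, 41_000, 1000))
        sites = mk.select_target_sites(
            _stats(pos, [0.4] * 40), [region], n_per_region=40
        )
        assert len(sites) == 40
        assert [s.position for s in sites] == pos  # named by ascending position

    def test_farthest_point_spacing(self):
        """Choosing 10 of 100 uniformly spaced sites keeps the largest gap
        within twice the ideal spacing."""
        region = CandidateRegion("chr05", 0, 2_000_000, 1.0, 1)
        pos = list(range(10_000, 1_010_000, 10_000))  # 100 sites over 1 Mb
        sites = mk.select_target_sites(
            _stats(pos, [0.5] * 100), [region], n_per_region=10
        )
        chosen = sorted(s.position for s in sites)
        ideal = (chosen[-1] - chosen[0]) / (len(chosen) - 1)
        gaps = np.diff(chosen)
        assert gaps.max() <= 2 * ideal

    def test_names_follow_chromosome_rank(self):
        region = CandidateRegion("chr09", 0, 10_000, 1.0, 1)
        sites = mk.select_target_sites(
            _stats([500, 1500], [0.5, 0.5], chrom="chr09"), [region], 2
        )
        assert [s.name for s in sites] == ["chr09V1", "chr09V2"]

    def test_no_regions_rejected(self):
        with pytest.raises(ValueError):
            mk.select_target_sites(_stats([1], [0.5]), [])


class TestExtractFlanks:
    @pytest.fixture()
    def reference(self, tmp_path):
        import pyfaidx

        fasta = tmp_path / "ref.fa"
        fasta.write_text(">chr05\n" + "acgt" * 50 + "\n>tiny\nG\n")
        return pyfaidx.Fasta(str(fasta))

    def test_full_flank(self, reference):
        site = mk.MarkerSite("chr05V1", "chr05", 100, 0.5)
        seq = mk.extract_flanks(site, reference, flank=75)
        assert len(seq) == 151
        assert seq == seq.upper()

    def test_left_truncation(self, reference):
        site = mk.MarkerSite("chr05V1", "chr05", 10, 0.5)
        with pytest.warns(UserWarning, match="truncated"):
            seq = mk.extract_flanks(site, reference, flank=75)
        assert len(seq) == 85  # positions 1..85

    def test_single_base_contig(self, reference):
        site = mk.MarkerSite("t", "tiny", 1, 0.5)
        assert mk.extract_flanks(site, reference, flank=0) == "G"

    def test_missing_chromosome(self, reference):
        site = mk.MarkerSite("x", "chr99", 5, 0.5)
        with pytest.raises(ValueError, match="absent"):
            mk.extract_flanks(site, reference)


def _parent_table(rows):
    return pd.DataFrame(rows, columns=["marker", "individual_id", "genotype"])


TOL = [f"FT{i}" for i in range(1, 9)]
SEN = [f"CV{i}" for i in range(1, 9)]


class TestParentScreen:
    def test_diagnostic_heterozygote(self):
        rows = [("m1", p, "G/T") for p in TOL] + [("m1", p, "G/G") for p in SEN]
        res = mk.screen_parent_polymorphism(_parent_table(rows), TOL, SEN)
        assert res.coding["m1"] == {"G/T": 1, "G/G": 0}
        assert res.rejected == {}

    def test_shared_genotype_codes_zero(self):
        # het seen in both classes -> 0; only the tolerant-unique form codes 1
        rows = (
            [("m1", p, "A/A") for p in TOL[:4]]
            + [("m1", p, "A/G") for p in TOL[4:]]
            + [("m1", p, "A/G") for p in SEN[:2]]
            + [("m1", p, "G/G") for p in SEN[2:]]
        )
        res = mk.screen_parent_polymorphism(_parent_table(rows), TOL, SEN)
        assert res.coding["m1"] == {"A/A": 1, "A/G": 0, "G/G": 0}

    def test_monomorphic_rejected(self):
        rows = [("m1", p, "A/A") for p in TOL + SEN]
        res = mk.screen_parent_polymorphism(_parent_table(rows), TOL, SEN)
        assert res.rejected["m1"] == "monomorphic"

    def test_not_detected_rejected(self):
        rows = [("m1", p, None) for p in TOL + SEN]
        res = mk.screen_parent_polymorphism(_parent_table(rows), TOL, SEN)
        assert res.rejected["m1"] == "not detected"

    def test_attrition_rates_on_structured_panel(self):
        """80 candidate markers, 67 detected, 42 polymorphic reproduce the
        detection (83.75%) and polymorphism (62.69%) rates."""
        rows = []
        for i in range(42):  # polymorphic
            m = f"p{i:02d}"
            rows += [(m, p, "G/T") for p in TOL] + [(m, p, "G/G") for p in SEN]
        for i in range(25):  # detected but monomorphic
            m = f"m{i:02d}"
            rows += [(m, p, "A/A") for p in TOL + SEN]
        for i in range(13):  # never detected
            m = f"n{i:02d}"
            rows += [(m, p, None) for p in TOL + SEN]
        res = mk.screen_parent_polymorphism(_parent_table(rows), TOL, SEN)
        assert res.summary["n_markers"] == 80
        assert res.summary["n_detected"] == 67
        assert res.summary["n_polymorphic"] == 42
        assert round(res.summary["detection_rate_pct"], 2) == 83.75
        assert round(res.summary["polymorphism_rate_pct"], 2) == 62.69

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            mk.screen_parent_polymorphism(_parent_table([]), [], SEN)


class TestBinarize:
    def test_unseen_genotype_is_missing(self):
        table = _parent_table([("m1", "x", "G/T"), ("m1", "y", "T/T"),
                               ("m1", "z", None)])
        codes = mk.binarize_genotypes(table, {"m1": {"G/T": 1, "G/G": 0}})
        by_ind = codes.set_index("individual_id")["code"]
        assert by_ind["x"] == 1
        assert np.isnan(by_ind["y"])
        assert np.isnan(by_ind["z"])


class TestSpearmanValidate:
    def test_perfect_anticorrelation(self):
        codes = {f"g{i}": 1.0 if i < 5 else 0.0 for i in range(10)}
        as_env = pd.DataFrame(
            {"EnvI": np.arange(10, dtype=float)}, index=[f"g{i}" for i in range(10)]
        )
        v = mk.spearman_validate(codes, as_env)
        assert v.rho_by_environment["EnvI"] == pytest.approx(-0.8703883, abs=1e-5)
        assert v.passed
        assert v.sign_consistent

    def test_constant_codes_fail(self):
        codes = {f"g{i}": 1.0 for i in range(10)}
        as_env = pd.DataFrame(
            {"EnvI": np.arange(10, dtype=float)}, index=list(codes)
        )
        v = mk.spearman_validate(codes, as_env)
        assert not v.passed
        assert "zero variance" in v.reason

    def test_constant_phenotype_fails(self):
        codes = {f"g{i}": float(i % 2) for i in range(10)}
        as_env = pd.DataFrame({"EnvI": [2.0] * 10}, index=list(codes))
        v = mk.spearman_validate(codes, as_env)
        assert not v.passed

    def test_requires_overlap(self):
        codes = {"a": 1.0, "b": 0.0}
        as_env = pd.DataFrame({"EnvI": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match=">= 5"):
            mk.spearman_validate(codes, as_env)

    def test_requires_all_environments_by_default(self, rng):
        n = 60
        ids = [f"g{i}" for i in range(n)]
        codes = dict(zip(ids, (np.arange(n) % 2).astype(float)))
        strong = -np.array(list(codes.values())) + rng.normal(0, 0.1, n)
        noise = rng.normal(0, 1, n)
        as_env = pd.DataFrame({"EnvI": strong, "EnvIV": noise}, index=ids)
        assert not mk.spearman_validate(codes, as_env).passed
        assert mk.spearman_validate(
            codes, as_env, require_all_environments=False
        ).passed


class TestGoodnessOfFit:
    def test_perfect_marker(self):
        pool_of = {"a": "RP", "b": "SP"}
        assert mk.goodness_of_fit(pool_of, {"a": 1, "b": 0}) == 100.0

    def test_missing_codes_excluded(self):
        pool_of = {"a": "RP", "b": "RP", "c": "SP"}
        out = mk.goodness_of_fit(pool_of, {"a": 1, "b": np.nan, "c": 0})
        assert out == 100.0

    def test_pool_code_swap_symmetry(self):
        pool_of = {"a": "RP", "b": "RP", "c": "SP", "d": "SP"}
        codes = {"a": 1, "b": 0, "c": 0, "d": 1}
        swapped_pool = {k: ("SP" if v == "RP" else "RP") for k, v in pool_of.items()}
        swapped_codes = {k: 1 - v for k, v in codes.items()}
        assert mk.goodness_of_fit(pool_of, codes) == mk.goodness_of_fit(
            swapped_pool, swapped_codes
        )

    def test_no_genotyped_members_rejected(self):
        with pytest.raises(ValueError):
            mk.goodness_of_fit({"a": "RP"}, {"a": np.nan})

    def test_unknown_pool_rejected(self):
        with pytest.raises(ValueError):
            mk.goodness_of_fit({"a": "XX"}, {"a": 1})
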