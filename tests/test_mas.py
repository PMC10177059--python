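"""Tests for genotype strings, combination classes and the selection rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from frostmas import mas

ORDER = mas.DEFAULT_MARKER_ORDER
CHROM_OF = {m: m.split("V")[0] for m in ORDER}

# Published genotype-type table of the chr05(1)+chr09(1) class: the twelve
# six-marker strings with their progeny counts.
TYPE_COUNTS = {
    "001011": 11, "100111": 3, "100011": 4, "110011": 18, "101011": 15,
    "111011": 29, "011011": 9, "001111": 14, "110111": 16, "011111": 16,
    "101111": 9, "111111": 99,
}
STRONG = {"001111", "011111", "101111", "111111"}
POOR = {"001011", "100011", "100111"}


def _codes(strings_by_individual):
    rows = []
    for ind, s in strings_by_individual.items():
        for m, c in zip(ORDER, s):
            rows.append({"marker": m, "individual_id": ind,
                         "code": np.nan if c == "." else float(c)})
    return pd.DataFrame(rows)


class TestGenotypeStrings:
    def test_complete_and_missing(self):
        codes = _codes({"a": "111111", "b": "000000", "c": "1.1111"})
        strings, excluded = mas.build_genotype_strings(codes, ORDER)
        by_id = {g.individual_id: g.code_string for g in strings}
        assert by_id == {"a": "111111", "b": "000000"}
        assert excluded == ["c"]

    def test_unknown_marker_rejected(self):
        codes = _codes({"a": "111111"})
        with pytest.raises(ValueError, match="absent"):
            mas.build_genotype_strings(codes, ORDER + ("chr01V9",))

    def test_empty_order_rejected(self):
        with pytest.raises(ValueError):
            mas.build_genotype_strings(_codes({"a": "111111"}), ())

    def test_string_invariants(self):
        with pytest.raises(ValueError):
            mas.GenotypeString("a", ORDER, "11")
        with pytest.raises(ValueError):
            mas.GenotypeString("a", ORDER, "11211x")


class TestCombinationClass:
    @pytest.mark.parametrize(
        "string, label",
        [
            ("000000", "chr05(0)+chr09(0)"),
            ("001000", "chr05(1)+chr09(0)"),
            ("000100", "chr05(0)+chr09(1)"),
            ("111111", "chr05(1)+chr09(1)"),
        ],
    )
    def test_labels(self, string, label):
        gs = mas.GenotypeString("x", ORDER, string)
        assert mas.combination_class(gs, CHROM_OF) == label

    def test_monotone_in_codes(self):
        """Flipping any code 0->1 never clears a chromosome-group indicator."""
        def indicators(label):
            return label.count("(1)")

        for bits in itertools.product("01", repeat=6):
            s = "".join(bits)
            base = indicators(
                mas.combination_class(mas.GenotypeString("x", ORDER, s), CHROM_OF)
            )
            for i, b in enumerate(bits):
                if b == "0":
                    flipped = s[:i] + "1" + s[i + 1 :]
                    up = indicators(
                        mas.combination_class(
                            mas.GenotypeString("x", ORDER, flipped), CHROM_OF
                        )
                    )
                    assert up >= base

    def test_classes_partition_population(self):
        strings, _ = mas.build_genotype_strings(
            _codes({f"g{i}": f"{i % 2}{(i // 2) % 2}1011" for i in range(20)}), ORDER
        )
        frame = mas.classify_population(strings, CHROM_OF)
        assert len(frame) == 20
        assert frame["combination_class"].notna().all()

    def test_missing_group_rejected(self):
        gs = mas.GenotypeString("x", ("m1",), "1")
        with pytest.raises(ValueError):
            mas.combination_class(gs, {})


class TestSelectionRule:
    def test_published_types_split_into_strong_and_poor(self):
        """On the twelve published genotype strings the default rule keeps
        exactly the four strong types and rejects the three poor ones."""
        selected = {
            s for s in TYPE_COUNTS
            if mas.apply_selection_rule(mas.GenotypeString("x", ORDER, s))
        }
        assert selected == STRONG
        assert selected & POOR == set()

    def test_empty_rule_selects_everything(self):
        rule = mas.SelectionRule(frozenset())
        gs = mas.GenotypeString("x", ORDER, "000000")
        assert mas.apply_selection_rule(gs, rule)

    def test_rule_marker_must_exist(self):
        gs = mas.GenotypeString("x", ("m1",), "1")
        with pytest.raises(ValueError):
            mas.apply_selection_rule(gs, mas.SelectionRule(frozenset({"m9"})))

    def test_select_individuals_counts(self):
        strings = [
            mas.GenotypeString(f"i{k}", ORDER, s)
            for k, s in enumerate(TYPE_COUNTS)
        ]
        out = mas.select_individuals(strings)
        assert int(out["selected"].sum()) == len(STRONG)


class TestClassComparison:
    def test_identical_classes_share_a_letter(self, rng):
        ids = [f"g{i}" for i in range(40)]
        class_of = {g: ("A" if i < 20 else "B") for i, g in enumerate(ids)}
        as_env = pd.DataFrame({"EnvI": rng.normal(3, 1, 40)}, index=ids)
        out = mas.class_phenotype_comparison(class_of, as_env)
        letters = dict(zip(out["combination_class"], out["letters"]))
        assert set(letters["A"]) & set(letters["B"])

    def test_extreme_separation_gets_distinct_letters(self, rng):
        ids = [f"g{i}" for i in range(40)]
        class_of = {g: ("A" if i < 20 else "B") for i, g in enumerate(ids)}
        vals = np.r_[rng.normal(0, 0.1, 20), rng.normal(6, 0.1, 20)]
        as_env = pd.DataFrame({"EnvI": vals}, index=ids)
        out = mas.class_phenotype_comparison(class_of, as_env)
        letters = dict(zip(out["combination_class"], out["letters"]))
        assert not set(letters["A"]) & set(letters["B"])

    def test_small_class_reported_without_letters(self, rng):
        ids = [f"g{i}" for i in range(41)]
        class_of = {g: ("A" if i < 20 else "B") for i, g in enumerate(ids[:-1])}
        class_of[ids[-1]] = "C"  # singleton
        as_env = pd.DataFrame({"EnvI": rng.normal(3, 1, 41)}, index=ids)
        out = mas.class_phenotype_comparison(class_of, as_env, min_n=3)
        c_row = out[out["combination_class"] == "C"].iloc[0]
        assert c_row["n"] == 1
        assert c_row["letters"] == ""
        assert np.isnan(c_row["sd"])

    def test_shifted_class_detected_in_monte_carlo(self, rng):
        """A class shifted by two SDs earns its own letter in >= 95% of
        simulated trials (three classes, n = 30 each)."""
        hits = 0
        reps = 200
        ids = [f"g{i}" for i in range(90)]
        class_of = {g: "ABC"[i // 30] for i, g in enumerate(ids)}
        for _ in range(reps):
            vals = np.r_[
                rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(2, 1, 30)
            ]
            as_env = pd.DataFrame({"EnvI": vals}, index=ids)
            out = mas.class_phenotype_comparison(class_of, as_env)
            letters = dict(zip(out["combination_class"], out["letters"]))
            if not (set(letters["C"]) & (set(letters["A"]) | set(letters["B"]))):
                hits += 1
        assert hits / reps >= 0.95


class TestAlleleEffectReport:
    def _table(self, codes, phenos):
        code_df = pd.DataFrame(
            {"marker": "m1", "individual_id": list(codes), "code": list(codes.values())}
        )
        as_env = pd.DataFrame({"EnvI": pd.Series(phenos)})
        return code_df, as_env

    def test_identical_groups_zero_difference(self):
        codes = {"a": 1.0, "b": 1.0, "c": 0.0, "d": 0.0}
        phenos = {"a": 2.0, "b": 4.0, "c": 2.0, "d": 4.0}
        out = mas.allele_effect_report(*self._table(codes, phenos))
        assert out["mean_diff"].iloc[0] == pytest.approx(0.0)

    def test_swapped_coding_flips_sign(self, rng):
        ids = [f"g{i}" for i in range(20)]
        codes = {g: float(i % 2) for i, g in enumerate(ids)}
        phenos = dict(zip(ids, rng.normal(3, 1, 20)))
        a = mas.allele_effect_report(*self._table(codes, phenos))
        swapped = {k: 1 - v for k, v in codes.items()}
        b = mas.allele_effect_report(*self._table(swapped, phenos))
        assert a["mean_diff"].iloc[0] == pytest.approx(-b["mean_diff"].iloc[0])
        assert abs(a["t"].iloc[0]) == pytest.approx(abs(b["t"].iloc[0]))

    def test_one_sided_group_skipped(self):
        codes = {"a": 1.0, "b": 1.0}
        phenos = {"a": 1.0, "b": 2.0}
        out = mas.allele_effect_report(*self._table(codes, phenos))
        assert out["note"].iloc[0] == "one-sided group empty"

    def test_power_for_moderate_effect(self, rng):
        """Effect 1.5 injury units, n = 150 per group, SD 1: significant at
        p < 0.01 in at least 99% of simulations."""
        hits = 0
        reps = 300
        ids = [f"g{i}" for i in range(300)]
        codes = {g: float(i < 150) for i, g in enumerate(ids)}
        for _ in range(reps):
            vals = np.r_[rng.normal(2, 1, 150), rng.normal(3.5, 1, 150)]
            out = mas.allele_effect_report(
                *self._table(codes, dict(zip(ids, vals)))
            )
            if out["p_value"].iloc[0] < 0.01:
                hits += 1
        assert hits / reps >= 0.99


def test_published_share_of_best_type():
    """The all-ones type accounts for 99/243 = 40.74% of the printed class."""
    total = sum(TYPE_COUNTS.values())
    assert total == 243
    share = 100.0 * TYPE_COUNTS["111111"] / total
    assert round(share, 2) == 40.74
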