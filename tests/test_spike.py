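"""Two-tier spike normalization: arithmetic, chain, filters and tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from regennorm import (
    ConfigurationError,
    UndefinedReferenceError,
    batch_average,
    bsa_equivalents,
    correction_factor,
    correction_sets,
    extraction_efficiency,
    filter_min_replicates,
    group_test,
    ideal_correction_factor,
    normalize_protein,
    normalize_proteins,
    protein_multiplier,
    recovery_fraction,
    regen_v_default,
    tier_summary,
)
from regennorm.types import SpikeConfig, SpikeStandard, Tier

from conftest import abundance_table, design_table

positive = st.floats(min_value=1e-6, max_value=1e9, allow_nan=False)


class TestScalarOps:
    @pytest.mark.parametrize(
        "raw, bsa_amount, bsa_raw, expected",
        [
            (1.0e6, 6.65, 2.0e6, 3.325),
            (2.0e6, 6.65, 2.0e6, 6.65),  # raw equal to BSA raw -> BSA amount
            (0.0, 6.65, 2.0e6, 0.0),
        ],
    )
    def test_bsa_equivalents(self, raw, bsa_amount, bsa_raw, expected):
        assert bsa_equivalents(raw, bsa_amount, bsa_raw) == pytest.approx(expected)

    def test_bsa_equivalents_zero_reference(self):
        with pytest.raises(UndefinedReferenceError):
            bsa_equivalents(1.0, 6.65, 0.0)

    @pytest.mark.parametrize(
        "raw, bsa_amount, spiked, bsa_raw, expected",
        [
            (1.0e6, 6.65, 3.325, 2.0e6, 1.0),
            (1.0e6, 6.65, 6.65, 2.0e6, 0.5),
            (0.0, 6.65, 3.0, 2.0e6, 0.0),
        ],
    )
    def test_recovery_fraction(self, raw, bsa_amount, spiked, bsa_raw, expected):
        assert recovery_fraction(raw, bsa_amount, spiked, bsa_raw) == pytest.approx(expected)

    def test_recovery_requires_positive_spike(self):
        with pytest.raises(ConfigurationError):
            recovery_fraction(1.0, 6.65, 0.0, 2.0e6)

    @pytest.mark.parametrize(
        "values, expected",
        [([2, 4, 6], 4.0), ([2, math.nan, 6], 4.0)],
    )
    def test_tier_summary_mean_excludes_missing(self, values, expected):
        assert tier_summary(values) == pytest.approx(expected)

    def test_tier_summary_all_missing_is_nan(self):
        assert math.isnan(tier_summary([math.nan, math.nan]))

    @pytest.mark.parametrize(
        "pre, post, expected",
        [(0.5, 1.0, 0.5), (3.7, 3.7, 1.0), (0.667 * 0.757, 1.0, 0.505)],
    )
    def test_correction_factor(self, pre, post, expected):
        assert correction_factor(pre, post) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "cf, ideal, expected",
        [(0.5, 0.66, 0.7576), (0.66, 0.66, 1.0), (0.33, 0.66, 0.5)],
    )
    def test_extraction_efficiency(self, cf, ideal, expected):
        assert extraction_efficiency(cf, ideal) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "raw, mult, expected",
        [(1.0e6, 1.0, 3.325), (1.0e6, 1 / 0.757, 4.392), (0.0, 2.0, 0.0)],
    )
    def test_normalize_protein(self, raw, mult, expected):
        assert normalize_protein(raw, 6.65, 2.0e6, mult) == pytest.approx(expected, abs=5e-4)

    def test_literal_multiplier_differs_by_ideal_constant(self):
        # post/pre convention = (ideal/cf) / ideal
        cf, ideal = 0.505, 2 / 3
        assert protein_multiplier(cf, ideal, "literal") == pytest.approx(
            protein_multiplier(cf, ideal, "efficiency") / ideal
        )


class TestIdealFactor:
    def test_regen_v_configuration(self, spike_config):
        # 36 µM pre vs 54 µM post tiers at equal volumes
        assert ideal_correction_factor(spike_config) == pytest.approx(0.667, abs=1e-3)

    def test_equal_tiers_give_unity(self):
        config = SpikeConfig.validate(
            [
                SpikeStandard("a", Tier.PRE_EXTRACTION, 5.0),
                SpikeStandard("b", Tier.POST_EXTRACTION, 5.0),
                SpikeStandard("BSA", Tier.CARRIER_DIGEST, 6.65),
            ]
        )
        assert ideal_correction_factor(config) == 1.0

    def test_arbitrary_ratio(self):
        config = SpikeConfig.validate(
            [
                SpikeStandard("a", Tier.PRE_EXTRACTION, 10.0),
                SpikeStandard("b", Tier.POST_EXTRACTION, 40.0),
                SpikeStandard("BSA", Tier.CARRIER_DIGEST, 6.65),
            ]
        )
        assert ideal_correction_factor(config) == pytest.approx(0.25)


class TestProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(scale=positive, raw=positive, bsa_raw=positive)
    def test_instrument_scale_invariance_scalar(self, scale, raw, bsa_raw):
        """Multiplying every abundance of a sample by c > 0 changes nothing."""
        base = bsa_equivalents(raw, 6.65, bsa_raw)
        scaled = bsa_equivalents(raw * scale, 6.65, bsa_raw * scale)
        assert scaled == pytest.approx(base, rel=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(cf=positive, ideal=positive)
    def test_multiplier_times_efficiency_is_one(self, cf, ideal):
        eff = extraction_efficiency(cf, ideal)
        mult = protein_multiplier(cf, ideal, "efficiency")
        assert mult * eff == pytest.approx(1.0, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(pre=positive, post=positive, ideal=positive)
    def test_efficiency_consistency(self, pre, post, ideal):
        assert extraction_efficiency(correction_factor(pre, post), ideal) == (
            (pre / post) / ideal
        )

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(raw_lo=positive, delta=positive)
    def test_monotone_in_raw_abundance(self, raw_lo, delta):
        lo = normalize_protein(raw_lo, 6.65, 2.0e6, 1.3)
        hi = normalize_protein(raw_lo + delta, 6.65, 2.0e6, 1.3)
        assert hi > lo

    def test_table_scale_invariance(self, simple_config):
        rows = [
            ("pre1", "spike_peptide", "s1", 1.0e6),
            ("post1", "spike_peptide", "s1", 3.0e6),
            ("BSA", "carrier_peptide", "s1", 2.0e6),
            ("prot", "protein", "s1", 5.0e5),
        ]
        base = correction_sets(abundance_table(rows), simple_config)
        scaled_rows = [(f, k, s, v * 137.0) for f, k, s, v in rows]
        scaled = correction_sets(abundance_table(scaled_rows), simple_config)
        for col in ("pre_summary", "post_summary", "correction_factor",
                    "extraction_efficiency", "protein_multiplier"):
            assert scaled[col].iloc[0] == pytest.approx(base[col].iloc[0], rel=1e-9)


class TestChainAgainstBruteForce:
    def test_three_batch_toy_matches_spreadsheet_recomputation(self, simple_config):
        """Full chain vs an independent plain-dict recomputation, 1e-9 rel."""
        rng = np.random.default_rng(42)
        samples = [(f"s{i}", f"b{(i - 1) % 3 + 1}", "control", i) for i in range(1, 7)]
        rows = []
        raw = {}
        for s, _, _, _ in samples:
            for feat, kind in [("pre1", "spike_peptide"), ("post1", "spike_peptide"),
                               ("BSA", "carrier_peptide"), ("protA", "protein"),
                               ("protB", "protein")]:
                v = float(rng.uniform(1e5, 1e7))
                raw[(feat, s)] = v
                rows.append((feat, kind, s, v))
        abund = abundance_table(rows)

        corrections = correction_sets(abund, simple_config)
        normalized = normalize_proteins(abund, corrections, simple_config)

        # independent spreadsheet-style recomputation
        for s, _, _, _ in samples:
            bsa = raw[("BSA", s)]
            pre = raw[("pre1", s)] * 6.65 / bsa
            post = raw[("post1", s)] * 6.65 / bsa
            cf = pre / post
            ideal = 2.0 / 4.0
            mult = ideal / cf
            row = corrections[corrections["sample_id"] == s].iloc[0]
            assert row["correction_factor"] == pytest.approx(cf, rel=1e-9)
            assert row["extraction_efficiency"] == pytest.approx(cf / ideal, rel=1e-9)
            for prot in ("protA", "protB"):
                expected = raw[(prot, s)] * 6.65 / bsa * mult
                got = normalized[
                    (normalized["protein_id"] == prot) & (normalized["sample_id"] == s)
                ]["normalized_amount"].iloc[0]
                assert got == pytest.approx(expected, rel=1e-9)

    def test_missing_bsa_excludes_sample_with_nan(self, simple_config, caplog):
        rows = [
            ("pre1", "spike_peptide", "s1", 1.0e6),
            ("post1", "spike_peptide", "s1", 3.0e6),
            ("BSA", "carrier_peptide", "s1", None),
        ]
        corrections = correction_sets(abundance_table(rows), simple_config)
        assert math.isnan(corrections["correction_factor"].iloc[0])
        assert any("carrier" in r.message for r in caplog.records)


class TestReplicateFilter:
    def test_counting_oracle(self):
        """5 proteins observed in {1,2,2,3,6} replicates, k=2 -> 4 retained."""
        samples = [(f"s{i}", "b1", "control", i) for i in range(1, 7)]
        design = design_table(samples)
        counts = {"p1": 1, "p2": 2, "p3": 2, "p4": 3, "p5": 6}
        rows = [
            {"protein_id": p, "sample_id": f"s{i}", "normalized_amount": 1.0}
            for p, n in counts.items()
            for i in range(1, n + 1)
        ]
        filtered, retained = filter_min_replicates(pd.DataFrame(rows), design, k=2)
        assert retained == 4
        assert set(filtered["protein_id"]) == {"p2", "p3", "p4", "p5"}

    def test_counts_within_single_condition(self):
        # one observation in each of two conditions does not pass k=2
        design = design_table(
            [("s1", "b1", "control", 1), ("s2", "b1", "crush", 1)]
        )
        rows = pd.DataFrame(
            [
                {"protein_id": "p1", "sample_id": "s1", "normalized_amount": 1.0},
                {"protein_id": "p1", "sample_id": "s2", "normalized_amount": 1.0},
            ]
        )
        _, retained = filter_min_replicates(rows, design, k=2)
        assert retained == 0

    def test_missing_values_do_not_count(self):
        design = design_table(
            [("s1", "b1", "control", 1), ("s2", "b1", "control", 2)]
        )
        rows = pd.DataFrame(
            [
                {"protein_id": "p1", "sample_id": "s1", "normalized_amount": 1.0},
                {"protein_id": "p1", "sample_id": "s2", "normalized_amount": np.nan},
            ]
        )
        _, retained = filter_min_replicates(rows, design, k=2)
        assert retained == 0


class TestBatchAverage:
    def test_mean_and_missing_exclusion(self):
        rows = pd.DataFrame(
            [
                {"protein_id": "p1", "sample_id": "s1", "normalized_amount": 2.0},
                {"protein_id": "p1", "sample_id": "s1", "normalized_amount": 4.0},
                {"protein_id": "p2", "sample_id": "s1", "normalized_amount": 2.0},
                {"protein_id": "p2", "sample_id": "s1", "normalized_amount": np.nan},
            ]
        )
        out = batch_average(rows)
        by = out.set_index("protein_id")["normalized_amount"]
        assert by["p1"] == pytest.approx(3.0)
        assert by["p2"] == pytest.approx(2.0)

    def test_single_batch_identity(self):
        rows = pd.DataFrame(
            [{"protein_id": "p1", "sample_id": "s1", "normalized_amount": 5.0}]
        )
        out = batch_average(rows)
        assert out["normalized_amount"].tolist() == [5.0]


class TestGroupTest:
    @staticmethod
    def consensus(values: dict) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"protein_id": p, "sample_id": s, "normalized_amount": v}
                for p, sv in values.items()
                for s, v in sv.items()
            ]
        )

    def test_identical_groups_null(self):
        data = self.consensus(
            {"p1": {"a1": 1.0, "a2": 2.0, "a3": 3.0, "b1": 1.0, "b2": 2.0, "b3": 3.0}}
        )
        out = group_test(data, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        row = out.iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_separated_groups_against_welch_oracle(self):
        """{10,11,12} vs {20,21,22}: closed-form Welch t and p."""
        data = self.consensus(
            {"p1": {"a1": 10.0, "a2": 11.0, "a3": 12.0,
                    "b1": 20.0, "b2": 21.0, "b3": 22.0}}
        )
        out = group_test(data, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        # independent closed form: equal variances s^2 = 1, n = 3 each
        t_expected = (11.0 - 21.0) / math.sqrt(1.0 / 3 + 1.0 / 3)
        df = 4.0  # Welch-Satterthwaite with equal variances and sizes
        p_expected = 2 * stats.t.sf(abs(t_expected), df)
        row = out.iloc[0]
        assert row["t"] == pytest.approx(t_expected, rel=1e-9)
        assert row["p"] == pytest.approx(p_expected, rel=1e-9)
        assert row["significant"] and row["p"] < 0.05

    def test_underpowered_protein_flagged_untested(self):
        data = self.consensus({"p1": {"a1": 1.0, "b1": 2.0, "b2": 3.0}})
        out = group_test(data, ["a1", "a2"], ["b1", "b2"])
        assert not out.iloc[0]["tested"]
        assert not out.iloc[0]["significant"]

    def test_fdr_is_no_less_conservative(self):
        rng = np.random.default_rng(3)
        values = {}
        for i in range(20):
            a = rng.normal(10, 1, 3)
            b = rng.normal(10 + (2 if i < 3 else 0), 1, 3)
            values[f"p{i}"] = {f"a{j}": a[j] for j in range(3)} | {
                f"b{j}": b[j] for j in range(3)
            }
        data = self.consensus(values)
        groups = ([f"a{j}" for j in range(3)], [f"b{j}" for j in range(3)])
        raw = group_test(data, *groups, fdr=False)
        adj = group_test(data, *groups, fdr=True)
        assert adj["significant"].sum() <= raw["significant"].sum()
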