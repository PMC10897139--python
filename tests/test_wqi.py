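"""Band-table scoring, the weighted index, seasonal aggregation and
guideline flagging."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riverwq.wqi import (
    CI_LEVELS,
    PARAMETER_IDS,
    WEIGHTS,
    Guideline,
    GuidelineSet,
    NormalizationTable,
    SeasonCalendar,
    aggregate_seasonal,
    compute_wqi,
    default_guidelines,
    flag_exceedances,
    normalize_parameter,
)

from conftest import make_record, random_record
from oracle_table import DOMAINS, oracle_ci, oracle_wqi


class TestNormalizationTable:
    def test_weights(self, table):
        assert table.weight("dissolved_oxygen") == 4
        assert table.weight("ammonium") == 3
        assert sum(table.weight(p) for p in PARAMETER_IDS) == 24
        assert dict(WEIGHTS) == {p: table.weight(p) for p in PARAMETER_IDS}

    def test_structure(self, table):
        assert set(table.parameters) == set(PARAMETER_IDS)
        for p in PARAMETER_IDS:
            assert tuple(ci for ci, _ in table[p].bands) == CI_LEVELS

    @pytest.mark.parametrize(
        "param,value,expected",
        [
            ("conductivity", 500, 100),
            ("conductivity", 800, 90),
            ("dissolved_oxygen", 0.5, 0),
            ("dissolved_oxygen", 7.5, 100),
            ("dissolved_oxygen", 7.0, 80),  # strict "> 7" fails at 7.0
            ("nitrite", 0.85, 10),
            ("ph", 6.8, 70),  # first matching interval scanning down
            ("ph", 7.5, 100),
            ("temperature", 18, 100),
            ("temperature", 50, 0),
            ("turbidity", 5, 90),  # boundary: "< 5" fails at exactly 5
            ("total_coliforms", 14000, 10),
            ("total_coliforms", 14000.1, 0),
        ],
    )
    def test_banded_scores(self, table, param, value, expected):
        assert normalize_parameter(table, param, value) == expected

    def test_unknown_parameter_and_nonfinite_value(self, table):
        with pytest.raises(KeyError, match="phosphorus"):
            table.normalize("phosphorus", 1.0)
        with pytest.raises(ValueError, match="finite"):
            table.normalize("nitrite", float("nan"))

    def test_dense_grid_matches_independent_oracle(self, table):
        """Every value in a dense domain scan maps to the hand-read score."""
        for param, (lo, hi) in DOMAINS.items():
            grid = np.linspace(lo, hi, 2000)
            for v in grid:
                assert table.normalize(param, float(v)) == oracle_ci(param, float(v)), (
                    param, v,
                )

    def test_monotone_degradation_smaller_is_better(self, table):
        rng = np.random.default_rng(42)
        monotone_down = [p for p in PARAMETER_IDS
                         if p not in ("dissolved_oxygen", "temperature", "ph")]
        for param in monotone_down:
            vals = np.sort(rng.uniform(*DOMAINS[param], size=200))
            scores = [table.normalize(param, float(v)) for v in vals]
            assert all(a >= b for a, b in zip(scores, scores[1:]))
        do = np.sort(rng.uniform(*DOMAINS["dissolved_oxygen"], size=200))
        scores = [table.normalize("dissolved_oxygen", float(v)) for v in do]
        assert all(a <= b for a, b in zip(scores, scores[1:]))

    @settings(max_examples=300, derandomize=True)
    @given(
        param=st.sampled_from(sorted(DOMAINS)),
        frac=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_every_domain_value_scores_a_valid_band(self, table, param, frac):
        """Band predicates jointly cover each parameter's domain: any value
        gets a score in {0, 10, ..., 100} that agrees with the hand-read
        table."""
        lo, hi = DOMAINS[param]
        value = lo + frac * (hi - lo)
        ci = table.normalize(param, value)
        assert ci in set(range(0, 101, 10))
        assert ci == oracle_ci(param, value)

    def test_yaml_round_trip(self, table, tmp_path):
        path = tmp_path / "table.yaml"
        table.to_yaml(path)
        restored = NormalizationTable.from_yaml(path)
        rng = np.random.default_rng(1)
        for param, (lo, hi) in DOMAINS.items():
            for v in rng.uniform(lo, hi, size=50):
                assert restored.normalize(param, float(v)) == table.normalize(param, float(v))


def _record_all_at(table, ci_level):
    """Build a record whose every parameter scores exactly ci_level=100 or 0."""
    if ci_level == 100:
        values = {
            "conductivity": 100, "dissolved_oxygen": 9, "turbidity": 1,
            "nitrite": 0.001, "nitrate": 0.1, "ammonium": 0.005, "hardness": 10,
            "chloride": 10, "sulfate": 10, "total_coliforms": 10,
            "temperature": 18, "ph": 7.5,
        }
    else:
        values = {
            "conductivity": 15000, "dissolved_oxygen": 0.5, "turbidity": 200,
            "nitrite": 1.5, "nitrate": 120, "ammonium": 1.5, "hardness": 1800,
            "chloride": 1800, "sulfate": 1800, "total_coliforms": 15000,
            "temperature": 48, "ph": 0.5,
        }
    return make_record(values)


class TestComputeWqi:
    def test_all_best_scores_100_all_worst_scores_0(self, table):
        assert compute_wqi(_record_all_at(table, 100), table).wqi == 100.0
        assert compute_wqi(_record_all_at(table, 0), table).wqi == 0.0

    def test_single_degraded_parameter_worked_example(self, table):
        rec = _record_all_at(table, 100)
        rec.values["conductivity"] = 800  # scores 90, weight 2
        res = compute_wqi(rec, table)
        assert res.wqi == pytest.approx((2400 - 20) / 24, abs=1e-12)
        by_param = {b["parameter"]: b for b in res.breakdown}
        assert by_param["conductivity"]["ci"] == 90
        assert sum(b["weight"] for b in res.breakdown) == 24

    def test_matches_bruteforce_oracle_on_random_records(self, table):
        rng = np.random.default_rng(7)
        for _ in range(300):
            rec = random_record(rng)
            assert compute_wqi(rec, table).wqi == oracle_wqi(rec.values)

    def test_order_independence(self, table, rng):
        rec = random_record(rng)
        shuffled = make_record(dict(reversed(list(rec.values.items()))))
        assert compute_wqi(rec, table).wqi == compute_wqi(shuffled, table).wqi

    def test_missing_policy(self, table, rng):
        rec = random_record(rng)
        full_strict = compute_wqi(rec, table, "strict").wqi
        assert compute_wqi(rec, table, "renormalize").wqi == full_strict

        del rec.values["ph"]
        with pytest.raises(ValueError, match="ph"):
            compute_wqi(rec, table, "strict")
        res = compute_wqi(rec, table, "renormalize")
        assert res.missing == ["ph"]
        assert res.wqi == oracle_wqi(rec.values)

        empty = make_record({"color": 5.0})
        with pytest.raises(ValueError, match="no index parameters"):
            compute_wqi(empty, table, "renormalize")

    def test_wqi_bounds(self, table, rng):
        for _ in range(100):
            w = compute_wqi(random_record(rng), table).wqi
            assert 0 <= w <= 100


class TestAggregateSeasonal:
    def test_single_summer_record(self, table, rng):
        rec = random_record(rng)
        out = aggregate_seasonal([rec], table)
        w = compute_wqi(rec, table).wqi
        assert out["overall"].wqi == out["summer"].wqi == w
        assert "winter" not in out

    def test_balanced_seasonal_means(self, table, rng):
        recs = [random_record(rng) for _ in range(4)]
        recs[2].season = recs[3].season = "winter"
        out = aggregate_seasonal(recs, table)
        wqis = [compute_wqi(r, table).wqi for r in recs]
        assert out["summer"].wqi == pytest.approx(np.mean(wqis[:2]))
        assert out["winter"].wqi == pytest.approx(np.mean(wqis[2:]))
        assert out["overall"].wqi == pytest.approx(np.mean(wqis))
        assert out["overall"].n_records == 4

    def test_rejects_multi_site_batches_and_empty(self, table, rng):
        with pytest.raises(ValueError, match="at least one"):
            aggregate_seasonal([], table)
        recs = [random_record(rng, "SS1"), random_record(rng, "SS2")]
        with pytest.raises(ValueError, match="multiple sites"):
            aggregate_seasonal(recs, table)


class TestGuidelines:
    def test_printed_limits(self):
        g = default_guidelines()
        rec = make_record({"nitrite": 0.8, "dissolved_oxygen": 2.0, "ammonium": 0.03})
        violated = {v.parameter for v in flag_exceedances(rec, g)}
        assert violated == {"nitrite", "dissolved_oxygen"}  # ammonium 0.03 is safe

    def test_compliant_record_and_absent_parameter(self):
        g = default_guidelines()
        rec = make_record({"nitrite": 0.1, "dissolved_oxygen": 8.0})
        assert flag_exceedances(rec, g) == []  # ammonium guideline skipped

    def test_yaml_round_trip(self, tmp_path):
        g = GuidelineSet([Guideline("nitrate", "max", high=50.0, source="WHO")])
        path = tmp_path / "g.yaml"
        g.to_yaml(path)
        g2 = GuidelineSet.from_yaml(path)
        assert g2.by_parameter["nitrate"].high == 50.0


def test_season_calendar_wet_dry_split():
    cal = SeasonCalendar()
    assert cal.season_for(date(2018, 1, 10)) == "summer"
    assert cal.season_for(date(2018, 4, 30)) == "summer"
    assert cal.season_for(date(2018, 5, 1)) == "winter"
    assert cal.season_for(date(2018, 11, 30)) == "winter"
    assert cal.season_for(date(2018, 12, 1)) == "summer"
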