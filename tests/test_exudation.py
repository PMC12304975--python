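"""Blank correction, specific rates, and areal scaling of net exudation."""

import numpy as np
import pandas as pd
import pytest

from rhizoface.exudation import areal_rate, blank_correct, exudation_rates, specific_rates


def _incubation(sample_id="s1", box="b1", array="A1", tp="Aug2020", is_blank=False,
                C=60.0, N=6.0, mass=2.5, area=500.0, dur=1.0):
    return {
        "sample_id": sample_id, "array_id": array, "treatment": "ambient",
        "timepoint": tp, "collection_date": "2020-08-10", "box_id": box,
        "is_blank": is_blank, "solution_C_ug": C, "solution_N_ug": N,
        "root_dry_mass_g": np.nan if is_blank else mass,
        "root_surface_area_mm2": np.nan if is_blank else area,
        "duration_d": dur,
    }


class TestBlankCorrect:
    def test_box_blank_subtracted(self):
        df = pd.DataFrame([
            _incubation(C=60.0),
            _incubation("blank1", is_blank=True, C=10.0, N=1.0),
        ])
        out = blank_correct(df)
        assert out.iloc[0]["corrected_C_ug"] == pytest.approx(50.0)
        assert out.iloc[0]["blank_level"] == "box"
        assert not out.iloc[0]["negative_after_blank"]

    def test_net_reuptake_flagged_not_floored(self):
        df = pd.DataFrame([
            _incubation(C=8.0),
            _incubation("blank1", is_blank=True, C=10.0, N=1.0),
        ])
        out = blank_correct(df)
        assert out.iloc[0]["corrected_C_ug"] == pytest.approx(-2.0)
        assert bool(out.iloc[0]["negative_after_blank"])

    def test_fallback_to_array_mean_blank(self):
        df = pd.DataFrame([
            _incubation(C=60.0, box="b1"),
            _incubation("blank-other", box="b2", is_blank=True, C=12.0, N=1.0),
        ])
        out = blank_correct(df)
        assert out.iloc[0]["corrected_C_ug"] == pytest.approx(48.0)
        assert out.iloc[0]["blank_level"] == "array"

    def test_fallback_to_global_timepoint_blank(self):
        df = pd.DataFrame([
            _incubation(C=60.0, array="A1", box="b1"),
            _incubation("blank-a2", array="A2", box="b9", is_blank=True, C=20.0, N=2.0),
        ])
        out = blank_correct(df)
        assert out.iloc[0]["blank_level"] == "global"
        assert out.iloc[0]["corrected_C_ug"] == pytest.approx(40.0)

    def test_orphan_sample_named_in_error(self):
        df = pd.DataFrame([
            _incubation(sample_id="lost", tp="Jun2021"),
            _incubation("blank1", is_blank=True, tp="Aug2020", C=10.0),
        ])
        with pytest.raises(ValueError, match="lost"):
            blank_correct(df)

    def test_duplicate_blank_leaves_correction_unchanged(self):
        base = [_incubation(C=60.0), _incubation("blank1", is_blank=True, C=10.0, N=1.0)]
        dup = base + [_incubation("blank2", is_blank=True, C=10.0, N=1.0)]
        a = blank_correct(pd.DataFrame(base)).iloc[0]["corrected_C_ug"]
        b = blank_correct(pd.DataFrame(dup)).iloc[0]["corrected_C_ug"]
        assert a == b

    def test_doubling_masses_doubles_correction(self):
        rows = [_incubation(C=60.0, N=6.0), _incubation("blank1", is_blank=True, C=10.0, N=1.0)]
        once = blank_correct(pd.DataFrame(rows))
        doubled_rows = [dict(rows[0], solution_C_ug=120.0, solution_N_ug=12.0,
                             sample_id="s1"), dict(rows[1], solution_C_ug=20.0, solution_N_ug=2.0)]
        twice = blank_correct(pd.DataFrame(doubled_rows))
        assert twice.iloc[0]["corrected_C_ug"] == pytest.approx(2 * once.iloc[0]["corrected_C_ug"])
        assert twice.iloc[0]["corrected_N_ug"] == pytest.approx(2 * once.iloc[0]["corrected_N_ug"])


class TestSpecificRates:
    def test_mass_specific_rate(self):
        df = pd.DataFrame([_incubation()])
        df["corrected_C_ug"], df["corrected_N_ug"] = 50.0, 5.0
        out = specific_rates(df)
        assert out.iloc[0]["C_rate_ug_g_d"] == pytest.approx(50.0 / 2.5)  # 20

    def test_cn_ratio_identity_and_undefined(self):
        df = pd.DataFrame([_incubation(), _incubation("s2")])
        df["corrected_C_ug"] = [3.37, 3.37]
        df["corrected_N_ug"] = [3.37, -0.5]
        out = specific_rates(df)
        assert out.iloc[0]["CN_ratio"] == pytest.approx(1.0)
        assert np.isnan(out.iloc[1]["CN_ratio"])  # undefined when N rate <= 0

    def test_zero_root_mass_rejected(self):
        df = pd.DataFrame([_incubation(mass=0.0)])
        df["corrected_C_ug"], df["corrected_N_ug"] = 50.0, 5.0
        with pytest.raises(ValueError, match="root dry mass"):
            specific_rates(df)

    def test_mass_area_rate_consistency(self):
        rng = np.random.default_rng(2)
        rows = [_incubation(f"s{i}", C=float(rng.uniform(20, 80)),
                            mass=float(rng.uniform(0.5, 3)), area=float(rng.uniform(100, 900)))
                for i in range(10)]
        df = pd.DataFrame(rows)
        df["corrected_C_ug"] = df["solution_C_ug"] - 5
        df["corrected_N_ug"] = df["solution_N_ug"]
        out = specific_rates(df)
        ratio = out["C_rate_ug_g_d"] / out["C_rate_ug_mm2_d"]
        expected = out["root_surface_area_mm2"] / out["root_dry_mass_g"]
        np.testing.assert_allclose(ratio, expected)


def _biomass_row(array="A1", date="2020-08-10", lt1=60.0, one2=40.0):
    return {"array_id": array, "treatment": "ambient", "census_date": date,
            "biomass_lt1mm_g_m2": lt1, "biomass_1to2mm_g_m2": one2}


class TestArealRate:
    def _rates(self, date="2020-08-10"):
        df = pd.DataFrame([_incubation()])
        df["collection_date"] = date
        df["corrected_C_ug"], df["corrected_N_ug"] = 12.5, 2.5
        return specific_rates(df)

    def test_product_of_rate_and_stock(self):
        out = areal_rate(self._rates(), pd.DataFrame([_biomass_row()]))
        # rate 5 ug/g/d x (60+40) g/m2 = 500
        assert out.iloc[0]["C_rate_ug_m2_d"] == pytest.approx(500.0)

    def test_zero_rate_gives_zero(self):
        rates = self._rates()
        rates["C_rate_ug_g_d"] = 0.0
        out = areal_rate(rates, pd.DataFrame([_biomass_row(lt1=999.0)]))
        assert out.iloc[0]["C_rate_ug_m2_d"] == 0.0

    def test_equidistant_censuses_pick_later(self):
        bio = pd.DataFrame([
            _biomass_row(date="2020-08-05", lt1=10.0, one2=0.0),
            _biomass_row(date="2020-08-15", lt1=90.0, one2=0.0),
        ])
        out = areal_rate(self._rates(date="2020-08-10"), bio)
        assert out.iloc[0]["standing_root_g_m2"] == pytest.approx(90.0)

    def test_missing_array_record_is_an_error(self):
        bio = pd.DataFrame([_biomass_row(array="A2")])
        with pytest.raises(ValueError, match="A1"):
            areal_rate(self._rates(), bio)


def test_end_to_end_rates_pipeline():
    df = pd.DataFrame([
        _incubation(C=60.0, N=6.0),
        _incubation("blank1", is_blank=True, C=10.0, N=1.0),
    ])
    out = exudation_rates(df, pd.DataFrame([_biomass_row()]))
    assert out.iloc[0]["C_rate_ug_g_d"] == pytest.approx(20.0)
    assert out.iloc[0]["C_rate_ug_m2_d"] == pytest.approx(2000.0)
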