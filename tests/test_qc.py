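"""Ingest, quality filtering, PFT merging, LAI scaling, the humidity/rain LE
correction and Bowen-ratio closure."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from eiflux.core import SERIES_COLUMNS, SiteSeries
from eiflux.qc import (aggregate_to_hourly, apply_qc_filters, bowen_closure,
                       correct_le_humidity_rain, fit_ler_model, merge_pft,
                       read_site_csv, scale_site_lai)


def make_series(n=24, freq="h", **cols):
    idx = pd.date_range("2001-06-01", periods=n, freq=freq)
    df = pd.DataFrame({c: np.zeros(n) for c in SERIES_COLUMNS}, index=idx)
    df["Ta"] = 20.0
    df["RH"] = 60.0
    df["LE"] = 100.0
    df["H"] = 50.0
    df["Rn"] = 200.0
    for k, v in cols.items():
        df[k] = v
    return SiteSeries(data=df)


class TestReadCsv:
    CSV = textwrap.dedent("""\
        TIMESTAMP_START,TA_F,RH,VPD_F,NETRAD,G_F_MDS,H_F_MDS,LE_F_MDS,WS_F,P_F
        200106010000,20,60,9.35,400,40,100,200,2,0
        200106010030,21,55,11.1,420,42,110,210,2.2,0.3
        200106010100,22,50,13.2,430,43,120,220,2.4,0
        """)

    def test_reads_and_converts_units(self):
        s = read_site_csv(io.StringIO(self.CSV))
        assert len(s) == 3
        assert s.half_hourly
        assert s.data["VPD"].iloc[0] == pytest.approx(0.935)  # hPa -> kPa

    def test_missing_required_column_named(self):
        bad = self.CSV.replace("LE_F_MDS,", "X,")
        with pytest.raises(KeyError, match="LE"):
            read_site_csv(io.StringIO(bad))

    def test_hourly_spacing_not_flagged(self):
        csv = self.CSV.replace("200106010030", "200106010100").replace(
            "200106010100,22", "200106010200,22")
        s = read_site_csv(io.StringIO(csv))
        assert not s.half_hourly


class TestAggregate:
    def _half_hourly(self, le=(100.0, 200.0), p=(0.3, 0.2)):
        idx = pd.date_range("2001-06-01", periods=2, freq="30min")
        df = pd.DataFrame({c: np.zeros(2) for c in SERIES_COLUMNS}, index=idx)
        df["LE"] = le
        df["P"] = p
        return SiteSeries(data=df, half_hourly=True)

    def test_states_average_and_rain_sums(self):
        out = aggregate_to_hourly(self._half_hourly())
        assert out.data["LE"].iloc[0] == 150.0
        assert out.data["P"].iloc[0] == pytest.approx(0.5)

    def test_missing_half_poisons_hour(self):
        out = aggregate_to_hourly(self._half_hourly(le=(100.0, np.nan)))
        assert np.isnan(out.data["LE"].iloc[0])

    def test_odd_trailing_half_hour_dropped(self):
        idx = pd.date_range("2001-06-01", periods=3, freq="30min")
        df = pd.DataFrame({c: np.ones(3) for c in SERIES_COLUMNS}, index=idx)
        s = SiteSeries(data=df, half_hourly=True)
        with pytest.warns(UserWarning, match="odd trailing"):
            out = aggregate_to_hourly(s)
        assert len(out) == 1


class TestQCFilters:
    def test_rules_and_accounting(self):
        s = make_series(n=10)
        s.data.loc[s.data.index[1], "LE"] = -5.0
        s.data.loc[s.data.index[2], "Ta"] = -1.0
        s.data.loc[s.data.index[3], "qc"] = 3
        out, report = apply_qc_filters(s)
        assert report.removed["negative_LE"] == 1
        assert report.removed["freezing"] == 1
        assert report.removed["poor_quality"] == 1
        assert report.retained == 7
        assert sum(report.removed.values()) + report.retained == 10
        assert out.data["qc_rule"].iloc[1] == "negative_LE"
        assert out.data["qc_rule"].iloc[2] == "freezing"

    def test_clean_series_untouched(self):
        _, report = apply_qc_filters(make_series(n=8))
        assert report.retained == 8
        assert sum(report.removed.values()) == 0

    def test_masking_preserves_time_axis(self):
        s = make_series(n=10)
        s.data.loc[s.data.index[4], "LE"] = -1.0
        out, _ = apply_qc_filters(s)
        assert len(out) == 10  # masked, not deleted


class TestMergePft:
    @pytest.mark.parametrize("raw,expected", [
        ("WSA", "SAV"), ("OSH", "SHU"), ("CSH", "SHU"),
        ("EBF", "EBF"), ("GRA", "GRA"),
    ])
    def test_mapping(self, raw, expected):
        assert merge_pft(raw) == expected

    def test_unsupported_code(self):
        with pytest.raises(ValueError, match="WET"):
            merge_pft("WET")


class TestScaleLai:
    def test_ratio_arithmetic(self):
        grid = np.array([1.0, 2.0, 4.0])
        assert np.allclose(scale_site_lai(grid, 2.0, 4.0), grid / 2)
        assert np.allclose(scale_site_lai(grid, 4.0, 4.0), grid)

    def test_zero_grid_max_guard(self):
        with pytest.raises(ValueError):
            scale_site_lai([1.0], 2.0, 0.0)


class TestLECorrection:
    def _site(self, n=600, seed=0, rh_effect=0.0):
        """LER = 0.5 + rh_effect*(RH-50)/50, built exactly into LE."""
        rng = np.random.default_rng(seed)
        rh = rng.uniform(30, 95, n)
        p = np.where(rng.random(n) < 0.2, rng.gamma(1.0, 1.0, n), 0.0)
        avail = rng.uniform(50, 400, n)
        ler = 0.5 + rh_effect * (rh - 50.0) / 50.0
        s = make_series(n=n, RH=rh, P=p)
        s.data["Rn"] = avail
        s.data["G"] = 0.0
        s.data["H"] = 0.0
        s.data["LE"] = ler * avail
        return s

    def test_reference_conditions_leave_le_unchanged(self):
        s = self._site()
        s.data.loc[s.data.index[0], ["RH", "P"]] = [50.0, 0.0]
        model = fit_ler_model(s, seed=0)
        out = correct_le_humidity_rain(s, model)
        le0, raw0 = out.data["LE"].iloc[0], out.data["LE_raw"].iloc[0]
        assert le0 == pytest.approx(raw0, rel=1e-9)

    def test_constant_ler_site_statistically_unchanged(self):
        s = self._site(rh_effect=0.0)
        out = correct_le_humidity_rain(s, fit_ler_model(s, seed=1))
        rel = np.abs(out.data["LE"] - out.data["LE_raw"]) / out.data["LE_raw"]
        assert rel.mean() < 0.01

    def test_halved_ler_doubles_le(self):
        # direct substitution: LER_pred = 0.5 * reference -> factor 2
        s = self._site(rh_effect=0.25)
        model = fit_ler_model(s, seed=2)
        ref = float(model.predict([50.0], [0.0])[0])
        # find an hour whose predicted LER is below reference; factor = ref/pred
        pred = model.predict(s.data["RH"].to_numpy(), s.data["P"].to_numpy())
        out = correct_le_humidity_rain(s, model)
        factor = out.data["LE"] / out.data["LE_raw"]
        assert np.allclose(factor, ref / pred, rtol=1e-9)


class TestBowenClosure:
    def test_arithmetic(self):
        s = make_series(n=1, LE=60.0, H=40.0, Rn=120.0, G=0.0)
        out = bowen_closure(s)
        assert out.data["LE"].iloc[0] == pytest.approx(72.0)
        assert out.data["H"].iloc[0] == pytest.approx(48.0)

    def test_already_closed_unchanged(self):
        s = make_series(n=1, LE=80.0, H=40.0, Rn=120.0, G=0.0)
        out = bowen_closure(s)
        assert out.data["LE"].iloc[0] == pytest.approx(80.0)

    def test_closure_exact_everywhere_unflagged(self):
        rng = np.random.default_rng(3)
        n = 500
        s = make_series(n=n, LE=rng.uniform(-20, 300, n), H=rng.uniform(-50, 200, n),
                        Rn=rng.uniform(0, 600, n), G=rng.uniform(-20, 60, n))
        out = bowen_closure(s)
        ok = ~out.data["bowen_flagged"]
        resid = (out.data["LE"] + out.data["H"] - (out.data["Rn"] - out.data["G"]))[ok]
        assert np.abs(resid).max() < 1e-9

    def test_nonpositive_turbulent_flux_flagged(self):
        s = make_series(n=1, LE=-10.0, H=5.0)
        out = bowen_closure(s)
        assert bool(out.data["bowen_flagged"].iloc[0])
        assert out.data["LE"].iloc[0] == -10.0
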