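"""Flux accounting: litterfall, production, gross/net fluxes, identities."""

import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from herbflux.data_model import UnsupportedElementError
from herbflux.fluxes import (
    CoverageError,
    compute_fluxes,
    counterfactual_litter_flux,
    foliar_production,
    gross_flux,
    hc_to_litter_ratio,
    litter_element_flux,
    mass_loss_correction,
    net_flux,
    plot_litterfall,
    resorption_efficiency,
    trap_annual_litterfall,
)


def _series(trap_id, masses, area, start=dt.date(2020, 1, 1), days=30):
    rows = []
    d0 = start
    for m in masses:
        d1 = d0 + dt.timedelta(days=days)
        rows.append({"trap_id": trap_id, "plot_id": "p", "date_start": d0,
                     "date_end": d1, "leaf_dry_mass_g": m, "trap_area_m2": area})
        d0 = d1
    return pd.DataFrame(rows)


class TestTrapAnnualLitterfall:
    def test_single_full_year_collection(self):
        frame = _series("t", [50.0], 0.25, days=365)
        assert trap_annual_litterfall(frame) == pytest.approx(200.0)

    def test_monthly_series(self):
        frame = _series("t", [10.0] * 12, 0.5)
        assert trap_annual_litterfall(frame) == pytest.approx(240.0)

    def test_short_series_needs_complete_season_flag(self):
        frame = _series("t", [10.0] * 3, 0.5)  # 90 days spanned
        with pytest.raises(CoverageError):
            trap_annual_litterfall(frame)
        assert trap_annual_litterfall(frame, complete_season=True) == pytest.approx(60.0)

    def test_overlapping_intervals_rejected(self):
        frame = _series("t", [10.0, 10.0], 0.5, days=40)
        frame.loc[1, "date_start"] = frame.loc[0, "date_start"] + dt.timedelta(days=10)
        frame.loc[1, "date_end"] = frame.loc[1, "date_start"] + dt.timedelta(days=360)
        with pytest.raises(ValueError, match="overlap"):
            trap_annual_litterfall(frame)


class TestPlotLitterfall:
    def test_mean_and_se_across_traps(self):
        l_h, se = plot_litterfall({2020: [200.0, 240.0, 280.0]})
        assert l_h == pytest.approx(240.0)
        assert se == pytest.approx(23.09, abs=0.01)  # sd/sqrt(3)

    def test_single_trap_has_no_se(self):
        l_h, se = plot_litterfall({2020: [200.0]})
        assert l_h == 200.0
        assert np.isnan(se)

    def test_years_averaged_unweighted(self):
        l_h, _ = plot_litterfall({2020: [230.0, 250.0], 2021: [250.0, 270.0]})
        assert l_h == pytest.approx(250.0)


class TestFoliarProduction:
    def test_no_herbivory_identity(self):
        assert foliar_production(200.0, 0.0) == 200.0

    def test_moderate_herbivory(self):
        assert foliar_production(200.0, 0.05) == pytest.approx(210.526, abs=1e-3)

    def test_maximum_observed_herbivory(self):
        assert foliar_production(300.0, 0.136) == pytest.approx(347.222, abs=1e-3)

    def test_h_of_one_rejected_and_large_h_warns(self):
        with pytest.raises(ValueError):
            foliar_production(100.0, 1.0)
        with pytest.warns(UserWarning, match="0.5"):
            foliar_production(100.0, 0.6)


class TestGrossFlux:
    def test_zero_herbivory(self):
        assert gross_flux(500.0, 0.02, 0.0) == 0.0

    def test_nitrogen_example(self):
        assert gross_flux(500.0, 0.02, 0.05) == pytest.approx(0.50)

    def test_carbon_example(self):
        assert gross_flux(500.0, 0.48, 0.05) == pytest.approx(12.0)


class TestMassLossCorrection:
    @pytest.mark.parametrize("phenology,expected",
                             [("evergreen", 0.78), ("deciduous", 0.784)])
    def test_angiosperm_factors(self, phenology, expected):
        assert mass_loss_correction(phenology) == expected

    def test_unknown_phenology(self):
        with pytest.raises(ValueError, match="mixed"):
            mass_loss_correction("mixed")


class TestResorptionEfficiency:
    def test_no_withdrawal(self):
        assert resorption_efficiency(0.02, 0.02, 1.0) == pytest.approx(0.0)

    def test_deciduous_example(self):
        assert resorption_efficiency(0.02, 0.01, 0.784) == pytest.approx(0.608)

    def test_evergreen_example(self):
        # 1 - (0.0107/0.02)*0.78 = 1 - 0.4173
        assert resorption_efficiency(0.02, 0.0107, 0.78) == pytest.approx(0.5827)

    def test_silicon_unsupported(self):
        with pytest.raises(UnsupportedElementError):
            resorption_efficiency(0.01, 0.005, 0.78, element="Si")

    def test_out_of_range_flagged_not_clamped(self):
        with pytest.warns(UserWarning, match="outside"):
            re = resorption_efficiency(0.01, 0.02, 0.784)
        assert re < 0


class TestNetFlux:
    def test_zero_resorption(self):
        assert net_flux(1.0, 0.0) == 0.0

    def test_boreal_nitrogen_example(self):
        assert net_flux(0.082, 0.618) == pytest.approx(0.0507, abs=1e-4)

    def test_temperate_phosphorus_example(self):
        assert net_flux(0.016, 0.579) == pytest.approx(0.009264)

    def test_silicon_unsupported(self):
        with pytest.raises(UnsupportedElementError):
            net_flux(1.0, 0.5, element="Si")


class TestLitterFluxes:
    def test_litter_element_flux(self):
        assert litter_element_flux(0.0, 0.01) == 0.0
        assert litter_element_flux(300.0, 0.01) == pytest.approx(3.0)
        assert litter_element_flux(240.0, 0.005) == pytest.approx(1.2)

    def test_counterfactual_reduces_to_observed_without_herbivory(self):
        assert counterfactual_litter_flux(3.0, 500.0, 0.0, 0.01, 0.784) == 3.0

    def test_counterfactual_example(self):
        assert counterfactual_litter_flux(4.75, 500.0, 0.05, 0.01, 0.784) == (
            pytest.approx(4.946))

    def test_hc_to_litter_ratio(self):
        assert hc_to_litter_ratio(1.5, 1.5) == 1.0
        assert hc_to_litter_ratio(0.03, 1.5) == pytest.approx(0.02)
        assert np.isnan(hc_to_litter_ratio(0.03, 0.0))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    l_h=hst.floats(min_value=1.0, max_value=2000.0),
    h=hst.floats(min_value=0.0, max_value=0.49),
    f_green=hst.floats(min_value=1e-4, max_value=0.6),
    litter_ratio=hst.floats(min_value=0.05, max_value=1.5),
    mlcf=hst.sampled_from([0.78, 0.784]),
)
def test_three_term_identity(l_h, h, f_green, litter_ratio, mlcf):
    """L_EH + H_c - L_E == H_c * RE for any inputs, to machine precision."""
    c_litter = f_green * litter_ratio
    fp = foliar_production(l_h, h)
    h_c = gross_flux(fp, f_green, h)
    l_eh = litter_element_flux(l_h, c_litter)
    l_e = counterfactual_litter_flux(l_eh, fp, h, c_litter, mlcf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        re = resorption_efficiency(f_green, c_litter, mlcf)
    lhs = l_eh + h_c - l_e
    rhs = net_flux(h_c, re)
    assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)
    assert fp >= l_h
    assert l_e >= l_eh


def test_compute_fluxes_recovers_generator_truth(small_dataset, small_truth,
                                                 small_fluxes):
    table = small_fluxes.table
    assert not small_fluxes.errors
    truth = small_truth.plots.set_index("plot_id")
    base = table.drop_duplicates("plot_id").set_index("plot_id")
    # H within multinomial sampling error of the configured truth
    mae = (base["h"] - truth["h_true"]).abs().mean()
    assert mae < 0.01
    # row-wise identities
    cnp = table[table["element"].isin(("C", "N", "P"))]
    np.testing.assert_allclose(cnp["h_i"], cnp["h_c"] * cnp["re"], rtol=1e-12)
    assert (table["fp"] >= table["l_h"]).all()
    assert np.isnan(table.loc[table["element"] == "Si", "h_i"]).all()
    # net flux never exceeds gross where resorption is a proportion
    ok = cnp[cnp["re"] <= 1]
    assert (ok["h_i"] <= ok["h_c"] + 1e-12).all()


def test_doubling_trap_masses_scales_fluxes(small_dataset):
    import copy

    doubled = copy.copy(small_dataset)
    doubled.traps = small_dataset.traps.copy()
    doubled.traps["leaf_dry_mass_g"] *= 2.0
    a = compute_fluxes(small_dataset).table.set_index(["plot_id", "element"])
    b = compute_fluxes(doubled).table.set_index(["plot_id", "element"])
    for col in ("l_h", "fp", "h_c"):
        np.testing.assert_allclose(b[col], 2.0 * a[col], rtol=1e-12)
    cnp = a.index[a.index.get_level_values("element") != "Si"]
    np.testing.assert_allclose(b.loc[cnp, "h_i"], 2.0 * a.loc[cnp, "h_i"],
                               rtol=1e-12)
    for col in ("h", "re"):
        np.testing.assert_allclose(b[col].dropna(), a[col].dropna(), rtol=1e-12)


def test_missing_chemistry_recorded_not_fatal(small_dataset):
    import copy

    ds = copy.copy(small_dataset)
    drop_plot = ds.chemistry["plot_id"].iloc[0]
    ds.chemistry = small_dataset.chemistry.query(
        "~(plot_id == @drop_plot and element == 'P')").copy()
    flux = compute_fluxes(ds)
    assert any("missing chemistry" in e and drop_plot in e for e in flux.errors)
    assert not flux.table.query(
        "plot_id == @drop_plot and element == 'P'").shape[0]
    assert flux.table.query("plot_id == @drop_plot").shape[0] == 3
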