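"""Dose reconstruction: unit conversions, decay, dose rates, cumulation."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birddose import dosimetry as dm


class TestArealConversion:
    def test_default_divisor_is_65(self):
        assert dm.areal_to_specific_activity(65000.0) == pytest.approx(1000.0)
        assert 0.05 * 1300.0 == pytest.approx(65.0)

    def test_zero_activity(self):
        assert dm.areal_to_specific_activity(0.0) == 0.0

    @pytest.mark.parametrize("depth,density", [(0.0, 1300.0), (0.05, -1.0)])
    def test_invalid_parameters(self, depth, density):
        with pytest.raises(ValueError):
            dm.areal_to_specific_activity(100.0, depth, density)


class TestDecay:
    def test_no_elapsed_time(self):
        assert dm.decay_factor(0.0, dm.DEFAULT_NUCLIDES["Cs-137"]) == 1.0

    def test_one_half_life(self):
        assert dm.decay_factor(8.02, dm.DEFAULT_NUCLIDES["I-131"]) == pytest.approx(0.5)

    def test_iodine_negligible_at_first_census(self):
        # closed form 2^(-112/8.02); far below 1e-4 four months post-accident
        f = dm.decay_factor(112.0, dm.DEFAULT_NUCLIDES["I-131"])
        assert f == pytest.approx(2.0 ** (-112.0 / 8.02), rel=1e-12)
        assert f < 1e-4

    def test_cesium137_slow_over_four_years(self):
        assert dm.decay_factor(4 * 365.25, dm.DEFAULT_NUCLIDES["Cs-137"]) > 0.9

    @given(st.floats(0.0, 1e4), st.floats(0.1, 1e4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing(self, t, dt):
        nuc = dm.DEFAULT_NUCLIDES["Cs-134"]
        assert dm.decay_factor(t + dt, nuc) < dm.decay_factor(t, nuc)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            dm.decay_factor(-1.0, dm.DEFAULT_NUCLIDES["Cs-137"])


class TestDoseRates:
    def test_internal_unit_chasing(self):
        assert dm.internal_dose_rate(5e-4, 2.0, 1000.0) == pytest.approx(1.0)
        assert dm.internal_dose_rate(1.0, 1.0, 0.0) == 0.0
        assert dm.internal_dose_rate(1.3e-4, 0.8, 4615.4) == pytest.approx(0.480, rel=1e-3)

    def test_external_limits_and_weighting(self):
        assert dm.external_dose_rate(2e-4, 1e-4, 1.0, 1000.0) == pytest.approx(0.2)
        assert dm.external_dose_rate(2e-4, 1e-4, 0.0, 1000.0) == pytest.approx(0.1)
        assert dm.external_dose_rate(2e-4, 1e-4, 0.5, 1000.0) == pytest.approx(0.15)

    def test_external_time_budget_bounds(self):
        with pytest.raises(ValueError):
            dm.external_dose_rate(2e-4, 1e-4, 1.5, 1000.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            dm.internal_dose_rate(-1e-4, 0.8, 10.0)

    def test_total_is_sum_and_order_free(self):
        comp = {"Cs-137": (0.3, 0.5), "Cs-134": (0.2, 0.4), "I-131": (0.01, 0.02)}
        expected = 0.3 + 0.5 + 0.2 + 0.4 + 0.01 + 0.02
        assert dm.total_dose_rate(comp) == pytest.approx(expected)
        reordered = dict(reversed(list(comp.items())))
        assert dm.total_dose_rate(reordered) == dm.total_dose_rate(comp)

    def test_total_empty_rejected(self):
        with pytest.raises(ValueError):
            dm.total_dose_rate({})


class TestExposureBookkeeping:
    def test_calendar_exact_durations(self):
        censuses = [date(y, 7, 1) for y in (2011, 2012, 2013, 2014)]
        out = dm.exposure_durations(date(2011, 3, 11), censuses)
        assert out.tolist() == [112, 478, 843, 1208]

    def test_accident_date_itself(self):
        assert dm.exposure_durations(date(2011, 3, 11), [date(2011, 3, 11)]).tolist() == [0]

    def test_census_before_accident_rejected(self):
        with pytest.raises(ValueError):
            dm.exposure_durations(date(2011, 3, 11), [date(2011, 1, 1)])

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            dm.exposure_durations(date(2011, 3, 11), [date(2011, 7, 1), date(2011, 7, 1)])


class TestCumulativeDose:
    def test_benchmark_rate_conversion(self):
        # 2 uGy/h sustained: 5.4 mGy by the 2011 census, 58 mGy by 2014
        td = dm.cumulate_total_dose([2.0] * 4, [112, 478, 843, 1208])
        mgy = dm.round_sig(td * 1000.0, 2)
        assert mgy[0] == pytest.approx(5.4)
        assert mgy[-1] == pytest.approx(58.0)

    def test_zero_rate(self):
        assert dm.cumulate_total_dose([0.0, 0.0], [112, 478]).tolist() == [0.0, 0.0]

    def test_non_decreasing(self):
        td = dm.cumulate_total_dose([5.0, 1.0, 0.5, 0.1], [112, 478, 843, 1208])
        assert np.all(np.diff(td) >= 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dm.cumulate_total_dose([1.0, 2.0], [112])


class TestConcentrationRatioFallback:
    @pytest.fixture()
    def cr_table(self):
        return pd.DataFrame(
            {
                "species": ["A", "B", "C"],
                "genus": ["ga", "gb", "gc"],
                "diet": ["omnivorous", "herbivorous", "omnivorous"],
                "taxon_class": ["bird", "bird", "mammal"],
                "nuclide": ["Cs-137"] * 3,
                "cr": [1.0, 2.0, 3.0],
            }
        )

    def test_exact_species(self, cr_table):
        assert dm.select_concentration_ratio("B", "Cs-137", cr_table) == (2.0, "species")

    def test_congener_then_diet_then_class(self, cr_table):
        cr, tag = dm.select_concentration_ratio(
            "X", "Cs-137", cr_table, genus="gb", diet="omnivorous", taxon_class="mammal"
        )
        assert (cr, tag) == (2.0, "genus")
        cr, tag = dm.select_concentration_ratio(
            "X", "Cs-137", cr_table, genus="gz", diet="herbivorous", taxon_class="mammal"
        )
        assert (cr, tag) == (2.0, "diet")
        cr, tag = dm.select_concentration_ratio(
            "X", "Cs-137", cr_table, genus="gz", diet="carnivorous", taxon_class="mammal"
        )
        assert (cr, tag) == (3.0, "class")

    def test_no_match_raises(self, cr_table):
        with pytest.raises(KeyError):
            dm.select_concentration_ratio("X", "I-131", cr_table)
        with pytest.raises(KeyError):
            dm.select_concentration_ratio("X", "Cs-137", cr_table.iloc[:0])


class TestIcrpBands:
    @pytest.mark.parametrize(
        "rate,label",
        [
            (1.0, "below-DCRL"),
            (4.0, "DCRL"),
            (100.0, "reduced-reproductive-success"),
            (1000.0, "increased-morbidity"),
            (10000.0, "embryo-long-term-effects"),
            (50000.0, "adult-mortality"),
        ],
    )
    def test_band_labels(self, rate, label):
        assert dm.classify_icrp_band(rate) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dm.classify_icrp_band(-0.1)


def _toy_inputs():
    """3 species x 2 nuclides x 2 sites toy configuration."""
    species = [
        dm.SpeciesDoseProfile(
            species=f"s{i}", genus="g", diet="omnivorous", t_on_soil=t,
            cr={"Cs-134": c, "Cs-137": 2 * c},
            dcc_int={"Cs-134": 1e-4, "Cs-137": 1.5e-4},
            dcc_on_soil={"Cs-134": 3e-4, "Cs-137": 2e-4},
            dcc_off_soil={"Cs-134": 2e-4, "Cs-137": 1e-4},
        )
        for i, (t, c) in enumerate([(0.2, 0.5), (0.9, 4.0), (0.5, 0.05)])
    ]
    site_activity = pd.DataFrame(
        [
            {"site": 1, "nuclide": "Cs-134", "activity_Bq_m2": 2.0e5, "sampling_date": "2011-03-11"},
            {"site": 1, "nuclide": "Cs-137", "activity_Bq_m2": 2.0e5, "sampling_date": "2011-03-11"},
            {"site": 2, "nuclide": "Cs-134", "activity_Bq_m2": 5.0e4, "sampling_date": "2011-03-11"},
            {"site": 2, "nuclide": "Cs-137", "activity_Bq_m2": 5.0e4, "sampling_date": "2011-03-11"},
        ]
    )
    censuses = [date(y, 7, 1) for y in (2011, 2012, 2013, 2014)]
    return species, site_activity, censuses


class TestDosePipelineOracle:
    def test_matches_spreadsheet_recomputation(self):
        """Pipeline TD equals a straight-line per-cell recomputation to 1e-12."""
        species, site_activity, censuses = _toy_inputs()
        out = dm.compute_dose_table(site_activity, species, censuses)
        durations = [112, 478, 843, 1208]
        for site in (1, 2):
            areal = site_activity[site_activity["site"] == site].set_index("nuclide")[
                "activity_Bq_m2"
            ]
            for sp in species:
                tdrs = []
                for dur in durations:
                    tdr = 0.0
                    for nuc in ("Cs-134", "Cs-137"):
                        a = (areal[nuc] / 65.0) * 2.0 ** (
                            -dur / dm.DEFAULT_NUCLIDES[nuc].half_life_days
                        )
                        idr = sp.dcc_int[nuc] * sp.cr[nuc] * a
                        edr = (
                            sp.dcc_on_soil[nuc] * sp.t_on_soil
                            + sp.dcc_off_soil[nuc] * (1 - sp.t_on_soil)
                        ) * a
                        tdr += idr + edr
                    tdrs.append(tdr)
                td = 0.0
                prev = 0
                for k, dur in enumerate(durations):
                    td += tdrs[k] * (dur - prev) * 24.0 * 1e-6
                    prev = dur
                    row = out[
                        (out["site"] == site)
                        & (out["species"] == sp.species)
                        & (out["duration_days"] == dur)
                    ].iloc[0]
                    assert row["TDR_uGy_h"] == pytest.approx(tdrs[k], rel=1e-12)
                    assert row["TD_Gy"] == pytest.approx(td, rel=1e-12)

    def test_cumulative_dose_non_decreasing(self):
        species, site_activity, censuses = _toy_inputs()
        out = dm.compute_dose_table(site_activity, species, censuses)
        for _, g in out.groupby(["site", "species"]):
            assert np.all(np.diff(g.sort_values("duration_days")["TD_Gy"]) >= 0)

    def test_radionuclide_additivity(self):
        """TDR over a nuclide set equals the sum over disjoint subsets."""
        species, site_activity, censuses = _toy_inputs()
        both = dm.compute_dose_table(site_activity, species, censuses)
        parts = [
            dm.compute_dose_table(
                site_activity[site_activity["nuclide"] == nuc], species, censuses
            )
            for nuc in ("Cs-134", "Cs-137")
        ]
        key = ["site", "species", "duration_days"]
        merged = parts[0].set_index(key)["TDR_uGy_h"] + parts[1].set_index(key)["TDR_uGy_h"]
        np.testing.assert_allclose(
            both.set_index(key)["TDR_uGy_h"].sort_index(), merged.sort_index(), rtol=1e-12
        )

    def test_sampling_date_decay_reference(self):
        species, site_activity, censuses = _toy_inputs()
        sampled = site_activity.assign(sampling_date="2011-06-15")
        out = dm.compute_dose_table(
            sampled, species, censuses, decay_reference="sampling"
        )
        ref = dm.compute_dose_table(site_activity, species, censuses)
        # less decay time from mid-June than from the accident -> higher TDR
        assert (out["TDR_uGy_h"] > ref["TDR_uGy_h"]).all()
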