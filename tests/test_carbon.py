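"""Carbon-pool aggregation: areas, worked examples, conservation,
summaries and composition percentages."""
import math

import numpy as np
import pandas as pd
import pytest

from fallowcarbon import (AnalysisConfig, Inventory, category_summary,
                          composition_percentages, horizontal_area_ha,
                          pools_frame, site_pools)


def _one_site(slope=0.0, category="SA0_5", age=3.0):
    return pd.DataFrame([{
        "site_id": "s0", "category": category, "fallow_age_yr": age,
        "slope_deg": slope, "patch_size_ha": 2.0, "distance_m": 500.0,
        "soc_pct": 4.0, "elevation_m": 300.0, "lai": 2.0,
        "n_transects": 4, "transect_length_m": 50.0, "transect_width_m": 5.0,
    }])


@pytest.mark.parametrize("slope,expected", [
    (0.0, 0.1),
    (60.0, 0.05),
    (30.0, 0.1 * math.cos(math.pi / 6)),
])
def test_horizontal_area_slope_correction(slope, expected):
    assert horizontal_area_ha(_one_site(slope).iloc[0]) == pytest.approx(
        expected, rel=1e-9)


def test_horizontal_area_rejects_vertical_site():
    with pytest.raises(ValueError):
        horizontal_area_ha(_one_site(90.0).iloc[0])


def test_empty_site_has_zero_pools():
    p = site_pools(Inventory(sites=_one_site()), "s0")
    assert p.agtbc == 0.0
    assert all(v == 0.0 for fam in p.breakdowns.values() for v in fam.values())


def test_single_cwd_piece_worked_example():
    """One fresh piece (D=100 cm, L=1 m) on a flat 0.1 ha site:
    376.99 kg dry mass, x0.5 carbon, /0.1 ha = 1.88496 Mg C/ha."""
    inv = Inventory(sites=_one_site())
    inv.dead_wood = pd.DataFrame([{
        "site_id": "s0", "transect_id": "T1", "diameter_cm": 100.0,
        "length_in_transect_m": 1.0, "stand_form": "downed",
        "decay_class": "fresh",
    }])
    p = site_pools(inv, "s0")
    want = math.pi / 4 * 0.48 * 1000 * 0.5 / 1000 / 0.1
    assert p.cdwbc == pytest.approx(want, rel=1e-9)
    assert p.cdwbc == pytest.approx(1.88496, abs=1e-4)
    assert p.agtbc == pytest.approx(p.cdwbc, rel=1e-12)
    assert p.breakdowns["decay_class"]["fresh"] == pytest.approx(p.cdwbc)
    assert p.breakdowns["stand_form"]["downed"] == pytest.approx(p.cdwbc)


def test_conservation_on_all_synthetic_sites(pools):
    for p in pools:
        total = p.lwbc + p.olbc + p.cdwbc + p.ubc + p.lbc
        assert p.agtbc == pytest.approx(total, rel=1e-9)
        parents = {
            "guild": p.lwbc, "origin": p.lwbc, "dbh_class": p.lwbc,
            "height_class": p.lwbc, "olbc_kind": p.olbc,
            "stand_form": p.cdwbc, "decay_class": p.cdwbc,
        }
        for family, cells in p.breakdowns.items():
            assert sum(cells.values()) == pytest.approx(
                parents[family], rel=1e-9, abs=1e-12), family


def test_slope_increases_per_ha_pools():
    """Same records on a steeper site occupy less horizontal area,
    hence larger per-ha stocks."""
    flat, steep = Inventory(sites=_one_site(0.0)), Inventory(sites=_one_site(40.0))
    stem = pd.DataFrame([{
        "site_id": "s0", "transect_id": "T1", "species_name": "x",
        "genus": "X", "dbh_cm": 30.0, "height_m": 20.0,
        "wood_density_g_cm3": 0.5, "guild": "climax", "origin": "native",
    }])
    flat.live_stems = stem.copy()
    steep.live_stems = stem.copy()
    assert site_pools(steep, "s0").lwbc > site_pools(flat, "s0").lwbc


def test_category_summary_hand_values():
    sites = pd.concat([_one_site() for _ in range(5)], ignore_index=True)
    sites["site_id"] = [f"s{i}" for i in range(5)]
    from fallowcarbon.carbon import CarbonPools
    pools = [CarbonPools(site_id=f"s{i}", lwbc=float(i + 1)) for i in range(5)]
    summ = category_summary(pools, sites)
    row = summ.loc[summ["metric"] == "lwbc"].iloc[0]
    assert row["mean"] == pytest.approx(3.0)
    assert row["se"] == pytest.approx(math.sqrt(2.5 / 5), rel=1e-9)
    # identical sites -> SE 0
    pools_same = [CarbonPools(site_id=f"s{i}", lwbc=7.0) for i in range(5)]
    row = category_summary(pools_same, sites).query("metric == 'lwbc'").iloc[0]
    assert row["mean"] == 7.0 and row["se"] == 0.0


def test_category_summary_single_site_se_absent():
    sites = _one_site()
    from fallowcarbon.carbon import CarbonPools
    summ = category_summary([CarbonPools(site_id="s0", lwbc=1.0)], sites)
    assert np.isnan(summ.query("metric == 'lwbc'").iloc[0]["se"])


def test_composition_families_sum_to_100(pools):
    for p in pools:
        comp = composition_percentages(p)
        for family, cells in comp.items():
            assert sum(cells.values()) == pytest.approx(100.0, abs=1e-6), family


def test_single_component_site_is_100_percent():
    inv = Inventory(sites=_one_site())
    inv.dead_wood = pd.DataFrame([{
        "site_id": "s0", "transect_id": "T1", "diameter_cm": 20.0,
        "length_in_transect_m": 2.0, "stand_form": "standing",
        "decay_class": "moderate",
    }])
    comp = composition_percentages(site_pools(inv, "s0"))
    assert comp["pool"]["CDWBC"] == pytest.approx(100.0)
    assert "guild" not in comp  # zero LWBC denominator -> family absent


def test_quadrat_scaling_uses_quadrat_area():
    """20 g litter per 1 m2 quadrat at 50% C on flat ground is
    4*20g*0.5 = 40 g C on 4e-4 ha -> 0.1 Mg C/ha."""
    inv = Inventory(sites=_one_site())
    inv.quadrats = pd.DataFrame([
        {"site_id": "s0", "transect_id": f"T{t}", "component": "litter",
         "dry_mass_g": 20.0, "carbon_fraction": 0.5}
        for t in range(1, 5)
    ])
    p = site_pools(inv, "s0")
    assert p.lbc == pytest.approx(0.1, rel=1e-9)
    assert p.ubc == 0.0
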