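"""Generator determinism, schema validity, design arithmetic and the
ground-truth recovery scenario."""
import numpy as np
import pandas as pd
import pytest

from fallowcarbon import (GeneratorConfig, all_site_pools,
                          collinearity_screen, generate_inventory,
                          generate_recovery_scenario, lmm_frame,
                          recovery_table, reference_pool_means,
                          write_inventory)
from fallowcarbon.inventory import CATEGORIES


def test_same_seed_gives_identical_csv_bytes(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    write_inventory(generate_inventory(GeneratorConfig(seed=21)), a)
    write_inventory(generate_inventory(GeneratorConfig(seed=21)), b)
    for f in ("sites.csv", "live_stems.csv", "other_living.csv",
              "dead_wood.csv", "quadrats.csv"):
        assert (a / f).read_bytes() == (b / f).read_bytes()
    # and a different seed differs
    c = tmp_path / "c"
    write_inventory(generate_inventory(GeneratorConfig(seed=22)), c)
    assert (a / "live_stems.csv").read_bytes() != (c / "live_stems.csv").read_bytes()


def test_design_structure(inventory):
    assert len(inventory.sites) == 25
    counts = inventory.sites["category"].value_counts()
    assert all(counts[c] == 5 for c in CATEGORIES)
    assert (inventory.live_stems["dbh_cm"] >= 5).all()
    assert inventory.dead_wood["decay_class"].isin(
        ["fresh", "moderate", "high", "burnt"]).all()
    # one quadrat record per component per transect
    assert len(inventory.quadrats) == 25 * 4 * 2


def test_reference_table_consistency():
    """Component means sum to the total within printed rounding."""
    m = reference_pool_means()
    comp = m[["LWBC", "OLBC", "CDWBC", "UBC", "LBC"]].sum(axis=1)
    assert (comp - m["AGTBC"]).abs().max() <= 0.02
    assert m.loc["OG", "LWBC"] == 316.96
    assert m.loc["SA0_5", "AGTBC"] == 160.3


def test_builtin_collinearity_detected(inventory):
    fal = inventory.sites[inventory.sites["category"] != "OG"].copy()
    fal = fal.rename(columns={
        "fallow_age_yr": "FA", "distance_m": "DIS", "slope_deg": "SL",
        "patch_size_ha": "PS", "soc_pct": "SOC",
        "elevation_m": "E", "lai": "LAI",
    })
    retained, excluded = collinearity_screen(
        fal[["FA", "DIS", "SL", "PS", "SOC", "E", "LAI"]])
    assert set(excluded) == {"E", "LAI"}
    assert retained == ["FA", "DIS", "SL", "PS", "SOC"]


def test_scenario_zero_effects_zero_noise_uniform_recovery():
    inv, truth = generate_recovery_scenario(
        GeneratorConfig(seed=31), effects={}, intercept=40.0, noise_sd=0.0)
    table = recovery_table(all_site_pools(inv), inv.sites)
    lw = table.query("pool == 'LWBC'")["recovery_pct"]
    assert np.allclose(lw, 40.0, atol=1e-8)
    assert truth["control_mean"] > 0


def test_scenario_hits_target_recoveries_exactly():
    inv, truth = generate_recovery_scenario(
        GeneratorConfig(seed=33), effects={"PS": 10, "SOC": 8}, noise_sd=3.0)
    table = recovery_table(all_site_pools(inv), inv.sites)
    lw = table.query("pool == 'LWBC'").set_index("site_id")["recovery_pct"]
    for sid, target in truth["target_recovery_pct"].items():
        assert lw[sid] == pytest.approx(target, abs=1e-8)


def test_scenario_rejects_unknown_covariate():
    with pytest.raises(ValueError):
        generate_recovery_scenario(GeneratorConfig(seed=1), effects={"LAI": 5})


def test_lmm_frame_shape(inventory, pools):
    table = recovery_table(pools, inventory.sites)
    df = lmm_frame(table, inventory.sites, "LWBC")
    assert len(df) == 20
    assert {"recovery_pct", "FA", "DIS", "SL", "PS", "SOC",
            "category"} <= set(df.columns)
    assert df["FA"].notna().all()


def test_parashorea_leads_lwbc_contribution(inventory, pools):
    """The dominant dipterocarp should rank first in living woody
    carbon on default seeds."""
    stems = inventory.live_stems.copy()
    from fallowcarbon import agb_tree
    stems["agb"] = agb_tree(stems["dbh_cm"].to_numpy(float),
                            stems["height_m"].to_numpy(float),
                            stems["wood_density_g_cm3"].to_numpy(float))
    top = stems.groupby("species_name")["agb"].sum().idxmax()
    assert top == "Parashorea malaanonan"
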