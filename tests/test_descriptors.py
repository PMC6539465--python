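"""Grids, σ/ESP histogram profiles, region classification, table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iltox.descriptors import (
    DegenerateProfileError,
    DescriptorAssemblyError,
    TARGET_COLUMN,
    assemble_descriptor_row,
    build_descriptor_table,
    classify_sigma_region,
    compute_profile,
    descriptor_names,
    esp_grid,
    feature_columns,
    sigma_grid,
)
from iltox.surfaces import ESPSurfacePoints, SurfaceSegmentSet


def brute_force_bin(value, grid):
    """Linear scan over half-open bins; top edge goes to the last bin."""
    if value == grid.high:
        return grid.n_bins - 1
    for i in range(grid.n_bins):
        left = grid.low + i * grid.step
        if left <= value < left + grid.step:
            return i
    return -1


class TestGrids:
    def test_sigma_grid_shape(self):
        g = sigma_grid()
        assert g.n_bins == 60
        assert g.low == -0.03 and g.high == 0.03 and g.step == 0.001
        # leftmost bin covers [-0.030, -0.029)
        assert g.bin_index(np.array([-0.030]))[0] == 0
        assert g.bin_index(np.array([-0.0291]))[0] == 0
        assert g.bin_index(np.array([-0.029]))[0] == 1
        centers = g.centers
        assert np.allclose(np.diff(centers), 0.001)
        assert centers[0] == pytest.approx(-0.0295)
        assert centers[-1] == pytest.approx(0.0295)

    def test_esp_grids(self):
        gc = esp_grid("cation")
        ga = esp_grid("anion")
        assert gc.n_bins == 300 and ga.n_bins == 300
        # the bin labeled 88.75 covers [88.5, 89.0)
        i = gc.labels.index("88.75")
        assert gc.left_edges[i] == pytest.approx(88.5)
        assert gc.bin_index(np.array([88.5, 88.99, 89.0])).tolist() == [i, i, i + 1]
        assert ga.labels[0] == "-149.75"
        with pytest.raises(ValueError):
            esp_grid("zwitterion")

    def test_top_edge_assigned_to_last_bin(self):
        g = sigma_grid()
        assert g.bin_index(np.array([0.03]))[0] == g.n_bins - 1
        assert g.bin_index(np.array([0.0301, -0.0301])).tolist() == [-1, -1]


class TestProfiles:
    def test_single_segment_lands_in_its_bin(self):
        s = SurfaceSegmentSet("i", np.array([5.0]), np.array([0.0]))
        prof = compute_profile(s, sigma_grid())
        idx = sigma_grid().bin_index(np.array([0.0]))[0]
        assert prof.bin_areas[idx] == pytest.approx(5.0)
        assert prof.bin_areas.sum() == pytest.approx(5.0)
        assert prof.spill_count == 0

    def test_same_bin_accumulates(self):
        s = SurfaceSegmentSet("i", np.array([2.0, 3.0]),
                              np.array([0.0130, 0.0131]))
        prof = compute_profile(s, sigma_grid())
        assert (prof.bin_areas > 0).sum() == 1
        assert prof.bin_areas.max() == pytest.approx(5.0)

    def test_area_conservation_large_random(self, random_surface):
        prof = compute_profile(random_surface, sigma_grid())
        assert prof.bin_areas.sum() == pytest.approx(
            random_surface.total_area, rel=1e-9)

    def test_bin_assignment_matches_linear_scan_oracle(self, rng):
        g = esp_grid("cation")
        areas = rng.uniform(0.1, 1.0, 300)
        esps = rng.uniform(-5.0, 155.0, 300)  # some out of grid
        pts = ESPSurfacePoints("i", "cation", areas, esps)
        prof = compute_profile(pts, g)
        expected = np.zeros(g.n_bins)
        spill = 0.0
        for a, v in zip(areas, esps):
            j = brute_force_bin(v, g)
            if j < 0:
                spill += a
            else:
                expected[j] += a
        np.testing.assert_allclose(prof.bin_areas, expected, rtol=1e-12)
        assert prof.spill_area == pytest.approx(spill)
        assert prof.bin_areas.sum() + prof.spill_area == pytest.approx(
            pts.total_area, rel=1e-12)

    def test_profile_permutation_invariant(self, rng, random_surface):
        perm = rng.permutation(len(random_surface))
        shuffled = SurfaceSegmentSet("ionX", random_surface.areas[perm],
                                     random_surface.sigmas[perm])
        p1 = compute_profile(random_surface, sigma_grid())
        p2 = compute_profile(shuffled, sigma_grid())
        np.testing.assert_allclose(p1.bin_areas, p2.bin_areas, rtol=1e-12)

    def test_degenerate_profile_raises_or_warns(self, caplog):
        pts = ESPSurfacePoints("a", "anion", np.array([1.0, 1.0]),
                               np.array([10.0, 20.0]))  # positive ESP, anion grid
        with pytest.raises(DegenerateProfileError):
            compute_profile(pts, esp_grid("anion"))
        with caplog.at_level("WARNING"):
            prof = compute_profile(pts, esp_grid("anion"), on_degenerate="warn")
        assert prof.spill_area == pytest.approx(2.0)
        assert prof.bin_areas.sum() == 0.0


class TestSigmaRegions:
    @pytest.mark.parametrize("sigma,region", [
        (-0.01, "HB_donor"),
        (-0.0082, "non_polar"),   # inclusive bounds
        (0.0082, "non_polar"),
        (0.013, "HB_acceptor"),
        (0.0, "non_polar"),
        (-0.00821, "HB_donor"),
    ])
    def test_region_boundaries(self, sigma, region):
        assert classify_sigma_region(sigma) == region

    @given(st.floats(min_value=-0.05, max_value=0.05,
                     allow_nan=False, allow_subnormal=False))
    @settings(derandomize=True, max_examples=200)
    def test_exactly_one_region_per_sigma(self, sigma):
        labels = {"HB_donor", "non_polar", "HB_acceptor"}
        assert classify_sigma_region(sigma) in labels


def _profiles_for(ion_id, role, rng):
    seg = SurfaceSegmentSet(ion_id, rng.uniform(0.1, 1.0, 50),
                            rng.uniform(-0.03, 0.03, 50))
    lo, hi = (0.0, 150.0) if role == "cation" else (-150.0, 0.0)
    esp = ESPSurfacePoints(ion_id, role, rng.uniform(0.1, 1.0, 50),
                           rng.uniform(lo, hi, 50))
    return {"sigma": compute_profile(seg, sigma_grid()),
            "esp": compute_profile(esp, esp_grid(role))}


class TestAssembly:
    def test_row_has_720_named_features_in_order(self, rng):
        cat = _profiles_for("cat1", "cation", rng)
        an = _profiles_for("an1", "anion", rng)
        row = assemble_descriptor_row(cat, an)
        assert len(row) == 720
        assert list(row.index) == descriptor_names()
        assert row.index[0].startswith("S_EP-C")
        assert "S_EP-C88.75" in row.index
        assert "S_σ-C0.013" in row.index
        assert "S_σ-A-0.012" in row.index

    def test_missing_profile_named_in_error(self, rng):
        cat = _profiles_for("cat1", "cation", rng)
        an = _profiles_for("an1", "anion", rng)
        with pytest.raises(DescriptorAssemblyError, match="sigma.*anion"):
            assemble_descriptor_row(cat, {"esp": an["esp"]})

    def test_shared_cation_gives_identical_block(self, rng):
        cat = _profiles_for("cat1", "cation", rng)
        an1 = _profiles_for("an1", "anion", rng)
        an2 = _profiles_for("an2", "anion", rng)
        r1 = assemble_descriptor_row(cat, an1)
        r2 = assemble_descriptor_row(cat, an2)
        cat_cols = [c for c in r1.index if c.startswith(("S_EP-C", "S_σ-C"))]
        assert (r1[cat_cols] == r2[cat_cols]).all()

    def test_build_table_rows_and_errors(self, rng):
        profiles = {
            "cat1": _profiles_for("cat1", "cation", rng),
            "cat2": _profiles_for("cat2", "cation", rng),
            "an1": _profiles_for("an1", "anion", rng),
        }
        samples = pd.DataFrame({
            "il_id": ["il1", "il2", "il3"],
            "cation_id": ["cat1", "cat2", "cat1"],
            "anion_id": ["an1", "an1", "an1"],
            TARGET_COLUMN: [2.0, 3.0, 4.0],
        })
        table = build_descriptor_table(samples, profiles)
        assert len(table) == 3
        assert table.shape[1] == 721
        assert feature_columns(table) == descriptor_names()
        assert table[TARGET_COLUMN].tolist() == [2.0, 3.0, 4.0]

        bad = samples.assign(cation_id=["cat1", "ghost", "cat1"])
        with pytest.raises(DescriptorAssemblyError, match="il2.*ghost"):
            build_descriptor_table(bad, profiles)
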