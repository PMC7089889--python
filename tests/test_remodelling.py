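"""SED thresholds, slice classification, stiffness sweep, trends."""

import numpy as np
import pandas as pd
import pytest

from boneplug import fe
from boneplug.geometry import SliceSpec
from boneplug.materials import default_cards
from boneplug.loads import lc2
from boneplug.remodelling import (SliceReport, Thresholds, classify,
                                  sed_bounds, stiffness_sweep, trend)


class TestBounds:
    def test_default_band_in_joules_per_cubic_metre(self):
        assert sed_bounds(Thresholds()) == pytest.approx((6480.0, 7920.0))

    def test_linearity_in_density(self):
        lo1, hi1 = sed_bounds(Thresholds(density=1.8))
        lo2, hi2 = sed_bounds(Thresholds(density=3.6))
        assert (lo2, hi2) == pytest.approx((2 * lo1, 2 * hi1))

    def test_vanishing_band_width(self):
        t = Thresholds(lower=0.0044 - 1e-9, upper=0.0044)
        lo, hi = sed_bounds(t)
        assert hi - lo == pytest.approx(1e-9 * 1.8e6, rel=1e-6)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(lower=0.005, upper=0.004)


def synthetic_sed(mesh, values_fn):
    """SEDField with per-element U prescribed by values_fn(element index)."""
    U = np.array([values_fn(i) for i in range(mesh.n_elements)], dtype=float)
    return fe.SEDField(U=U, volume=mesh.element_volumes())


class TestClassify:
    def test_uniform_sed_inside_band(self, sliced_mesh):
        rep = classify(synthetic_sed(sliced_mesh, lambda i: 7000.0),
                       sliced_mesh, Thresholds())
        assert np.allclose(rep.fractions("within"), 1.0)
        assert np.allclose(rep.fractions("below"), 0.0)
        assert np.allclose(rep.fractions("above"), 0.0)

    def test_two_bin_split_by_area(self, sliced_mesh):
        """Elements covering a known area fraction above the band give that
        fraction exactly (area-weighted counting)."""
        coords = sliced_mesh.element_coords()
        height = coords[:, :, 1].max(axis=1) - coords[:, :, 1].min(axis=1)
        area = sliced_mesh.element_volumes() / height
        sel1 = np.flatnonzero(sliced_mesh.slice_index == 1)
        high = sel1[: len(sel1) // 2]
        U = np.full(sliced_mesh.n_elements, 5000.0)
        U[high] = 9000.0
        rep = classify(fe.SEDField(U=U, volume=sliced_mesh.element_volumes()),
                       sliced_mesh, Thresholds())
        expected_above = area[high].sum() / area[sel1].sum()
        row = rep.table[rep.table["slice"] == 1].iloc[0]
        assert row["fraction_above"] == pytest.approx(expected_above, rel=1e-12)
        assert row["fraction_below"] == pytest.approx(1 - expected_above, rel=1e-12)
        assert row["fraction_within"] == pytest.approx(0.0, abs=1e-12)

    def test_fractions_sum_to_one(self, solved_lc2):
        mesh, _, _, _, sed_field = solved_lc2
        rep = classify(sed_field, mesh, Thresholds())
        total = (rep.fractions("below") + rep.fractions("within")
                 + rep.fractions("above"))
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_unsliced_mesh_rejected(self, uniform_composite):
        with pytest.raises(ValueError, match="slice"):
            classify(synthetic_sed(uniform_composite, lambda i: 7000.0),
                     uniform_composite, Thresholds())


def report_from_fractions(above, below):
    n = len(above)
    return SliceReport(table=pd.DataFrame({
        "slice": np.arange(1, n + 1),
        "area": np.ones(n),
        "fraction_below": below,
        "fraction_within": 1 - np.asarray(above) - np.asarray(below),
        "fraction_above": above,
    }), thresholds=Thresholds())


class TestTrend:
    def test_constant_fractions_zero_change(self):
        rep = report_from_fractions([0.4] * 5, [0.1] * 5)
        t = trend(rep, slice_range=(1, 5))
        assert t["apposition_mean_change_pct"] == pytest.approx(0.0)
        assert t["resorption_mean_change_pct"] == pytest.approx(0.0)

    def test_doubling_gives_plus_hundred_percent(self):
        rep = report_from_fractions([0.05, 0.1, 0.2, 0.4], [0.01] * 4)
        assert trend(rep, (1, 4))["apposition_mean_change_pct"] \
            == pytest.approx(100.0)

    def test_hand_computed_mean_change(self):
        """(0.4, 0.3, 0.2): mean of (-25%, -33.33%) = -29.2%."""
        rep = report_from_fractions([0.4, 0.3, 0.2], [0.0] * 3)
        assert trend(rep, (1, 3))["apposition_mean_change_pct"] \
            == pytest.approx(-29.1666, abs=0.01)

    def test_zero_baseline_steps_skipped(self):
        rep = report_from_fractions([0.2] * 3, [0.0, 0.0, 0.1])
        assert np.isnan(trend(rep, (1, 3))["resorption_mean_change_pct"])

    def test_single_slice_rejected(self):
        rep = report_from_fractions([0.5], [0.1])
        with pytest.raises(ValueError):
            trend(rep, (1, 1))


@pytest.fixture(scope="module")
def sweep(coarse_spec, materials, sliced_mesh):
    return stiffness_sweep(coarse_spec, materials, lc2(),
                           [20e9, 115e9, 210e9], mesh=sliced_mesh)


class TestSweep:
    def test_bone_layer_sed_decreases_with_stem_stiffness(self, sweep):
        """Load sharing by stiffness: a stiffer stem shields the bone layer,
        lowering its mean and peak SED."""
        s = sweep.summary.sort_values("stem_modulus")
        assert np.all(np.diff(s["mean_sed_bone_layer"]) < 0)
        assert np.all(np.diff(s["peak_sed_bone_layer"]) < 0)

    def test_apposition_non_increasing_with_stem_stiffness(self, sweep):
        """Per-slice apposition (above-band) fraction does not grow as the
        stem stiffens, and falls strictly in aggregate."""
        above = np.array([sweep.reports[E].fractions("above")
                          for E in (20e9, 115e9, 210e9)])
        assert np.all(np.diff(above, axis=0) <= 1e-12)
        assert above[0].sum() > above[2].sum()

    def test_fractions_conserved_for_every_modulus(self, sweep):
        for rep in sweep.reports.values():
            total = (rep.fractions("below") + rep.fractions("within")
                     + rep.fractions("above"))
            assert np.allclose(total, 1.0, atol=1e-12)

    def test_repeated_run_is_identical(self, coarse_spec, materials, sliced_mesh):
        a = stiffness_sweep(coarse_spec, materials, lc2(), [115e9], mesh=sliced_mesh)
        b = stiffness_sweep(coarse_spec, materials, lc2(), [115e9], mesh=sliced_mesh)
        pd.testing.assert_frame_equal(a.reports[115e9].table,
                                      b.reports[115e9].table)

    def test_duplicate_or_invalid_moduli_rejected(self, coarse_spec, materials):
        with pytest.raises(ValueError):
            stiffness_sweep(coarse_spec, materials, lc2(), [115e9, 115e9])
        with pytest.raises(ValueError):
            stiffness_sweep(coarse_spec, materials, lc2(), [-1e9])
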