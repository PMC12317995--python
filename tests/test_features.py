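"""Penalty functions, frame features, trajectory statistics and the table."""

import numpy as np
import pytest
from scipy.special import erf

from curvmap.curvature import PatchField
from curvmap.errors import ParameterError
from curvmap.features import (
    FeatureConfig,
    FeatureSpec,
    build_feature_table,
    default_grid,
    frame_feature,
    penalty,
    trajectory_statistic,
)
from curvmap.synthetic import make_jittered_trajectory, make_toy_protein, toy_annotation


class TestPenalty:
    @pytest.mark.parametrize(
        "kind, s, c, expected",
        [
            ("P1", 1.0, 0.5, 0.5),
            ("P1", -1.0, 7.3, 0.0),
            ("P2", 1.0, 0.0, 1.0),
            ("P2", 0.0, 1.0, 0.5 * np.exp(-1.0)),  # 0.18394...
            ("P3", 0.0, 5.0, 0.0),
            ("P3", 1.0, 2.0, erf(2.0)),  # 0.99532...
        ],
    )
    def test_closed_form_values(self, kind, s, c, expected):
        assert penalty(s, c, kind) == pytest.approx(expected, abs=1e-12)

    def test_ranges_on_grid(self):
        s, c = np.meshgrid(np.linspace(-1, 1, 41), np.linspace(0, 5, 41))
        p1 = penalty(s, c, "P1")
        p2 = penalty(s, c, "P2")
        p3 = penalty(s, c, "P3")
        assert (p1 >= 0).all() and (p1 <= c + 1e-15).all()
        assert (p2 >= 0).all() and (p2 <= 1).all()
        assert (p3 > -1).all() and (p3 < 1).all()
        pos = c > 0
        assert np.all(np.sign(p3[pos]) == np.sign(s[pos]))

    def test_monotonicity_sweeps(self):
        s = np.linspace(-1, 1, 101)
        c = np.linspace(0, 4, 101)
        # increasing in s at fixed c
        for cv in (0.2, 1.0, 3.0):
            assert (np.diff(penalty(s, cv, "P1")) >= 0).all()
            assert (np.diff(penalty(s, cv, "P2")) >= 0).all()
            assert (np.diff(penalty(s, cv, "P3")) >= 0).all()
        # P1 increasing / P2 decreasing in c at fixed s > -1
        assert (np.diff(penalty(0.5, c, "P1")) >= 0).all()
        assert (np.diff(penalty(0.5, c, "P2")) <= 0).all()
        # P3 increasing in the product s·c
        sc = np.linspace(-3, 3, 101)
        assert (np.diff(erf(sc)) >= 0).all()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            penalty(0.0, 0.0, "P9")


def _patch(n, s=1.0, c=0.0):
    return PatchField(
        cutoff=5.0,
        s_bar=np.full(n, s),
        c_bar=np.full(n, c),
        valid=np.ones(n, dtype=bool),
    )


class TestFrameFeature:
    def test_sum_of_ones(self):
        # P2(s=1, c=0) = 1, so uniform φ⁺ = 1 over 100 points sums to 100
        patch = _patch(100)
        val = frame_feature(np.ones(100), patch, np.ones(100, bool), "P2")
        assert val == pytest.approx(100.0)

    def test_zero_property_zero_feature(self):
        patch = _patch(50, s=0.3, c=1.2)
        for kind in ("P1", "P2", "P3"):
            assert frame_feature(np.zeros(50), patch, np.ones(50, bool), kind) == 0.0

    def test_empty_region_is_zero(self):
        patch = _patch(10)
        assert frame_feature(np.ones(10), patch, np.zeros(10, bool), "P1") == 0.0

    def test_linearity_in_property(self):
        rng = np.random.default_rng(5)
        patch = PatchField(
            cutoff=5.0,
            s_bar=rng.uniform(-1, 1, 30),
            c_bar=rng.uniform(0, 2, 30),
            valid=np.ones(30, dtype=bool),
        )
        phi = rng.normal(size=30)
        mask = rng.random(30) > 0.3
        f1 = frame_feature(phi, patch, mask, "P3")
        f3 = frame_feature(3.0 * phi, patch, mask, "P3")
        assert f3 == pytest.approx(3.0 * f1, rel=1e-12)

    def test_invalid_points_excluded(self):
        patch = _patch(4)
        patch.valid[2] = False
        val = frame_feature(np.ones(4), patch, np.ones(4, bool), "P2")
        assert val == pytest.approx(3.0)


class TestTrajectoryStatistic:
    def test_constant_series(self):
        for stat, expected in [("MIN", 5), ("MAX", 5), ("AVG", 5), ("VAR", 0)]:
            assert trajectory_statistic([5, 5, 5], stat) == expected

    def test_population_variance(self):
        assert trajectory_statistic([1, 2, 3], "AVG") == 2
        assert trajectory_statistic([1, 2, 3], "VAR") == pytest.approx(2 / 3)

    def test_single_frame(self):
        for stat, expected in [("MIN", 4.2), ("MAX", 4.2), ("AVG", 4.2), ("VAR", 0.0)]:
            assert trajectory_statistic([4.2], stat) == pytest.approx(expected)

    def test_empty_series_rejected(self):
        with pytest.raises(ParameterError):
            trajectory_statistic([], "AVG")

    def test_min_max_compose_over_concatenation(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=7), rng.normal(size=5)
        both = np.concatenate([a, b])
        assert trajectory_statistic(both, "MIN") == min(
            trajectory_statistic(a, "MIN"), trajectory_statistic(b, "MIN")
        )
        avg = (7 * trajectory_statistic(a, "AVG") + 5 * trajectory_statistic(b, "AVG")) / 12
        assert trajectory_statistic(both, "AVG") == pytest.approx(avg)


class TestFeatureSpec:
    def test_name_grammar(self):
        spec = FeatureSpec("HCM (logP)", "+", "P3", 10.0, "AVG", "CDRH1")
        assert spec.name == "HCM (logP) +, P3, 10 Å, AVG, CDRH1"

    def test_name_roundtrip(self):
        for spec in default_grid()[::97]:
            assert FeatureSpec.from_name(spec.name) == spec

    def test_default_grid_size_and_uniqueness(self):
        grid = default_grid()
        assert len(grid) == 3 * 2 * 3 * 3 * 4 * 8 == 1728
        assert len({sp.name for sp in grid}) == 1728

    def test_invalid_fields_rejected(self):
        with pytest.raises(ParameterError):
            FeatureSpec("HCM (ww)", "+", "P4", 1.0, "AVG", "Fv")
        with pytest.raises(ParameterError):
            FeatureSpec("HCM (ww)", "+", "P1", 1.0, "MED", "Fv")


@pytest.fixture(scope="module")
def toy_table_inputs():
    toy = make_toy_protein(n_atoms=10, motif="globule", seed=11)
    traj = make_jittered_trajectory(toy.structure, n_frames=2, seed=12)
    ann = toy_annotation(toy.structure)
    cfg = FeatureConfig(grid_spacing=0.8, hydrophobicity_mode="stored")
    return traj, ann, cfg


class TestBuildFeatureTable:
    def test_identical_trajectories_identical_rows(self, toy_table_inputs):
        traj, ann, cfg = toy_table_inputs
        specs = default_grid()[::144]  # small, spread across the grid
        ft = build_feature_table({"a": traj, "b": traj}, ann, specs=specs, config=cfg)
        np.testing.assert_array_equal(
            ft.table.loc["a"].to_numpy(), ft.table.loc["b"].to_numpy()
        )
        assert list(ft.table.columns) == [sp.name for sp in specs]

    def test_stride_on_constant_trajectory(self, toy_table_inputs):
        traj, ann, cfg = toy_table_inputs
        from curvmap.structures import Trajectory

        const = Trajectory(frames=[traj.frames[0]] * 4)
        specs = default_grid()[::432]
        full = build_feature_table({"m": const}, ann, specs=specs, config=cfg)
        cfg2 = FeatureConfig(grid_spacing=0.8, hydrophobicity_mode="stored", stride=2)
        strided = build_feature_table({"m": const}, ann, specs=specs, config=cfg2)
        np.testing.assert_allclose(
            full.table.to_numpy(), strided.table.to_numpy(), atol=1e-12
        )

    def test_csv_roundtrip(self, toy_table_inputs, tmp_path):
        traj, ann, cfg = toy_table_inputs
        from curvmap.features import FeatureTable

        specs = default_grid()[::432]
        ft = build_feature_table({"m": traj}, ann, specs=specs, config=cfg)
        path = tmp_path / "features.csv"
        ft.to_csv(path)
        back = FeatureTable.from_csv(path)
        np.testing.assert_allclose(back.table.to_numpy(), ft.table.to_numpy())
        assert [sp.name for sp in back.specs] == [sp.name for sp in specs]
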