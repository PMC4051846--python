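import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleomorph.curvature import (
    baseline_register,
    curve_distance,
    estimate_kappa,
    flatten_to_plane,
    mean_curve,
    rank_taxa,
    register,
)
from paleomorph.morphodata import Clade, CurveLandmarks, CurveState, ValidationError
from paleomorph.synthetic_data import CurveSimSpec, gen_curve, random_rotation


def planar_chain(y_values, specimen_id="c", taxon="t"):
    """A planar2d 10-point chain with given interior y at x = 0..9."""
    x = np.arange(10, dtype=float)
    y = np.zeros(10)
    y[1:-1] = y_values
    return CurveLandmarks(specimen_id, taxon, Clade.SMALL_APES,
                         np.column_stack([x, y]), CurveState.PLANAR2D)


def bookstein_chain(free_y, specimen_id="c", taxon="t", clade=Clade.SMALL_APES):
    x = np.linspace(0, 1, 10)
    y = np.zeros(10)
    y[1:-1] = free_y
    return CurveLandmarks(specimen_id, taxon, clade,
                         np.column_stack([x, y]), CurveState.BOOKSTEIN2D)


coords3d = st.floats(min_value=-100, max_value=100, allow_nan=False)


class TestFlatten:
    def test_planar_data_in_3d_pose_preserves_pairwise_distances(self, rng):
        arc = gen_curve(CurveSimSpec(kappa=0.1, noise_sd=0.0,
                                     pose=(np.eye(3), np.zeros(3))), seed=0)
        posed = arc.points @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
        posed_curve = CurveLandmarks("p", "t", Clade.SMALL_APES, posed, CurveState.RAW3D)
        flat = flatten_to_plane(posed_curve)
        orig = np.linalg.norm(arc.points[:, None] - arc.points[None], axis=-1)
        new = np.linalg.norm(flat.points[:, None] - flat.points[None], axis=-1)
        np.testing.assert_allclose(new, orig, atol=1e-9)

    def test_collinear_points_map_to_x_axis(self):
        t = np.linspace(0, 9, 10)
        pts = np.column_stack([t, 2 * t, -t])
        flat = flatten_to_plane(CurveLandmarks("l", "t", Clade.SMALL_APES, pts,
                                               CurveState.RAW3D))
        np.testing.assert_allclose(flat.points[:, 1], 0.0, atol=1e-10)
        assert flat.points[-1, 0] > flat.points[0, 0]  # proximal -> distal

    def test_degenerate_chain_is_error(self):
        pts = np.ones((10, 3))
        with pytest.raises(ValidationError, match="degenerate"):
            flatten_to_plane(CurveLandmarks("d", "t", Clade.SMALL_APES, pts,
                                            CurveState.RAW3D))

    def test_orientation_normalized_bow_is_positive(self, rng):
        # an arc reflected in 3D still comes out with positive summed bow
        arc = gen_curve(CurveSimSpec(kappa=0.08, noise_sd=0.0,
                                     pose=(np.eye(3), np.zeros(3))), seed=0)
        mirrored = arc.points * np.array([1.0, -1.0, 1.0])
        flat = flatten_to_plane(CurveLandmarks("m", "t", Clade.SMALL_APES,
                                               mirrored, CurveState.RAW3D))
        reg = baseline_register(flat)
        assert reg.points[1:-1, 1].sum() > 0


class TestBaselineRegister:
    def test_hand_computed_triangle_midpoint(self):
        # chain (0,0) .. (1,1) at the middle .. (2,0): midpoint -> (0.5, 0.5)
        x = np.linspace(0, 2, 10)
        y = 1.0 - np.abs(x - 1.0)
        c = CurveLandmarks("tri", "t", Clade.SMALL_APES,
                          np.column_stack([x, y]), CurveState.PLANAR2D)
        reg = baseline_register(c)
        # every point maps to half its planar coordinates (baseline length 2)
        idx = int(np.argmin(np.abs(x - 1.0)))
        np.testing.assert_allclose(reg.points[idx], [x[idx] / 2, y[idx] / 2], atol=1e-12)
        np.testing.assert_array_equal(reg.points[0], [0, 0])
        np.testing.assert_array_equal(reg.points[-1], [1, 0])

    def test_idempotent_on_canonical_input(self):
        c = bookstein_chain(np.full(8, 0.05))
        planar = CurveLandmarks(c.specimen_id, c.taxon, c.clade, c.points,
                                CurveState.PLANAR2D)
        reg = baseline_register(planar)
        np.testing.assert_allclose(reg.points, c.points, atol=1e-14)

    def test_similarity_invariance_rotation_and_scale(self):
        base = planar_chain(np.linspace(0.1, 0.4, 8))
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        transformed = CurveLandmarks(
            "t2", "t", Clade.SMALL_APES, (base.points @ R.T) * 3.0 + [5.0, -2.0],
            CurveState.PLANAR2D,
        )
        np.testing.assert_allclose(
            baseline_register(base).points, baseline_register(transformed).points,
            atol=1e-12,
        )

    def test_coincident_endpoints_error(self):
        pts = np.zeros((10, 2))
        pts[1:-1, 0] = np.arange(8) + 1
        with pytest.raises(ValidationError, match="coincide"):
            baseline_register(CurveLandmarks("e", "t", Clade.SMALL_APES, pts,
                                             CurveState.PLANAR2D))


class TestEndToEnd:
    @settings(max_examples=25)
    @given(st.integers(0, 10_000))
    def test_similarity_invariance_of_full_pipeline(self, seed):
        """Rotating/translating/scaling the raw 3-D landmarks leaves the
        registered shape unchanged to 1e-8."""
        rng = np.random.default_rng(seed)
        arc = gen_curve(CurveSimSpec(kappa=0.07, noise_sd=1.0), seed=seed)
        scale = rng.uniform(0.2, 5.0)
        moved = scale * (arc.points @ random_rotation(rng).T) + rng.uniform(-40, 40, 3)
        a = register(arc)
        b = register(CurveLandmarks("m", "t", Clade.SMALL_APES, moved,
                                    CurveState.RAW3D))
        np.testing.assert_allclose(a.points, b.points, atol=1e-8)

    @pytest.mark.parametrize("kappa", [0.0, 0.02, 0.1, 0.3])
    def test_noiseless_arc_recovers_kappa_exactly(self, kappa):
        shape = register(gen_curve(CurveSimSpec(kappa=kappa, noise_sd=0.0), seed=3))
        assert estimate_kappa(shape) == pytest.approx(kappa, abs=1e-9)


class TestMeanCurve:
    def test_single_shape_is_itself(self):
        c = bookstein_chain(np.linspace(0, 0.1, 8))
        np.testing.assert_allclose(mean_curve([c]).points, c.points, atol=1e-15)

    def test_mirror_symmetric_arcs_average_to_flat(self):
        up = bookstein_chain(np.full(8, 0.08))
        down = bookstein_chain(np.full(8, -0.08))
        m = mean_curve([up, down])
        np.testing.assert_allclose(m.points[:, 1], 0.0, atol=1e-15)

    def test_mean_of_arcs_recovers_mean_kappa(self):
        shapes = [register(gen_curve(CurveSimSpec(kappa=k, noise_sd=0.0), seed=1))
                  for k in (0.05, 0.10, 0.15)]
        m = mean_curve(shapes)
        assert estimate_kappa(m) == pytest.approx(0.10, abs=1e-9)

    def test_empty_list_is_error(self):
        with pytest.raises(ValidationError):
            mean_curve([])


class TestCurveDistance:
    def test_identical_shapes_distance_zero(self):
        c = bookstein_chain(np.linspace(0, 0.1, 8))
        assert curve_distance(c, c).d == 0.0

    def test_constant_offset_gives_that_offset(self):
        a = bookstein_chain(np.zeros(8))
        b = bookstein_chain(np.full(8, 0.02))
        assert curve_distance(a, b).d == pytest.approx(0.02, abs=1e-15)
        # including the (zero-distance) endpoints rescales by 8/10
        assert curve_distance(a, b, include_endpoints=True).d == pytest.approx(
            0.016, abs=1e-15)

    def test_unregistered_input_is_error(self):
        a = bookstein_chain(np.zeros(8))
        with pytest.raises(ValidationError):
            curve_distance(a, planar_chain(np.zeros(8)))

    @settings(max_examples=30)
    @given(
        st.lists(st.floats(-0.5, 0.5), min_size=8, max_size=8),
        st.lists(st.floats(-0.5, 0.5), min_size=8, max_size=8),
        st.lists(st.floats(-0.5, 0.5), min_size=8, max_size=8),
    )
    def test_metric_axioms(self, ya, yb, yc):
        a, b, c = (bookstein_chain(np.array(v)) for v in (ya, yb, yc))
        dab, dba = curve_distance(a, b).d, curve_distance(b, a).d
        assert dab >= 0
        assert dab == pytest.approx(dba, abs=1e-15)
        if ya == yb:
            assert dab == 0
        dac = curve_distance(a, c).d
        dcb = curve_distance(c, b).d
        assert dab <= dac + dcb + 1e-12


class TestRankTaxa:
    def test_synthetic_taxa_rank_by_kappa_proximity(self):
        taxa = {}
        for k in (0.05, 0.10, 0.20):
            taxa[f"taxon_{k}"] = [
                register(gen_curve(CurveSimSpec(kappa=k, noise_sd=0.0), seed=s))
                for s in range(3)
            ]
        fossil = register(gen_curve(CurveSimSpec(kappa=0.11, noise_sd=0.0), seed=9))
        ranking = rank_taxa(fossil, taxa)
        assert ranking[0].taxon == "taxon_0.1"
        assert [cd.d for cd in ranking] == sorted(cd.d for cd in ranking)

    def test_fossil_equal_to_taxon_mean_ranks_first_with_zero(self):
        shapes = [bookstein_chain(np.full(8, 0.05)), bookstein_chain(np.full(8, 0.07))]
        fossil = mean_curve(shapes)
        ranking = rank_taxa(fossil, {"target": shapes,
                                     "other": [bookstein_chain(np.full(8, 0.3))]})
        assert ranking[0].taxon == "target"
        assert ranking[0].d == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_mode_differs_but_preserves_obvious_order(self):
        near = [bookstein_chain(np.full(8, 0.05)), bookstein_chain(np.full(8, 0.06))]
        far = [bookstein_chain(np.full(8, 0.4))]
        fossil = bookstein_chain(np.full(8, 0.055))
        for mode in ("mean", "pairwise"):
            ranking = rank_taxa(fossil, {"near": near, "far": far}, mode=mode)
            assert ranking[0].taxon == "near"

    def test_empty_taxa_error(self):
        with pytest.raises(ValidationError):
            rank_taxa(bookstein_chain(np.zeros(8)), {})
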