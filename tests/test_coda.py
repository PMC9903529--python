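"""Compositional geometry: closure, ILR map, descriptives, reallocation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movecoda import coda
from movecoda.coda import (
    Composition,
    ZeroPartError,
    aitchison_distance,
    amalgamate,
    closure,
    geometric_mean_composition,
    ilr_basis,
    ilr_inverse,
    ilr_transform,
    reallocate_proportional,
    replace_zeros,
    ternary_coordinates,
    variation_matrix,
)

CENTRE = np.array([10.0, 55.0, 346.0, 512.0, 518.0])  # sums to 1441
#: ILR coordinates of CENTRE, frozen from an independent formula-by-formula
#: evaluation with a hand calculator / standalone script.
CENTRE_ILR = np.array([-2.936344419702294, -1.82233080550331,
                       -0.32472980118698574, -0.008238230441253262])

positive_parts = st.lists(
    st.floats(min_value=0.1, max_value=1200.0, allow_nan=False), min_size=5, max_size=5
)


class TestClosure:
    def test_rescales_to_total(self):
        closed = closure(CENTRE, 1440.0)
        assert np.allclose(closed, CENTRE * 1440.0 / 1441.0)
        assert abs(closed.sum() - 1440.0) < 1e-9

    def test_already_closed_is_unchanged(self):
        parts = np.full(5, 288.0)
        assert np.allclose(closure(parts), parts)

    def test_hand_multiplication(self):
        assert np.allclose(closure([1, 2, 3, 4, 5]), [96, 192, 288, 384, 480])

    def test_rejects_nonpositive_parts(self):
        with pytest.raises(ZeroPartError):
            closure([0.0, 1, 1, 1, 1])
        with pytest.raises(ValueError):
            closure([1, 1, 1, 1, 1], total=0.0)

    def test_composition_type_enforces_invariants(self):
        c = Composition.from_array(CENTRE)
        assert abs(c.to_array().sum() - 1440.0) < 1e-9
        with pytest.raises(ValueError):
            Composition(100, 100, 100, 100, 100)  # does not sum to 1440


class TestZeroReplacement:
    def test_floor_and_total_preserved(self):
        parts = np.array([0.0, 55, 346, 512, 527])
        out = replace_zeros(parts, floor=1.0)
        assert out[0] == 1.0
        assert abs(out.sum() - parts.sum()) < 1e-9
        assert np.all(out > 0)

    def test_no_zeros_is_identity(self):
        assert np.allclose(replace_zeros(CENTRE), CENTRE)


class TestIlr:
    def test_equal_parts_map_to_origin(self):
        assert np.allclose(ilr_transform(np.full(5, 288.0)), 0.0, atol=1e-12)

    def test_last_coordinate_closed_form(self):
        # sqrt(1/2) * ln(512/518), other parts arbitrary
        z = ilr_transform([100, 100, 100, 512, 518])
        assert np.isclose(z[3], np.sqrt(0.5) * np.log(512 / 518))
        assert np.isclose(z[3], -0.008238230441253262)

    def test_reference_centre_frozen_vector(self):
        assert np.allclose(ilr_transform(CENTRE), CENTRE_ILR, atol=1e-12)

    def test_matches_scikit_bio_sbp_basis(self):
        """Independent oracle: scikit-bio's ILR with the same sequential
        binary partition must agree coordinate by coordinate."""
        import skbio.stats.composition as sc

        x = CENTRE / CENTRE.sum()
        ours = ilr_transform(x)
        theirs = sc.ilr(x, basis=ilr_basis().T)
        assert np.allclose(ours, theirs, atol=1e-12)
        # and the basis itself matches the one built from the partition
        sbp = np.array(
            [
                [1, -1, -1, -1, -1],
                [0, 1, -1, -1, -1],
                [0, 0, 1, -1, -1],
                [0, 0, 0, 1, -1],
            ]
        )
        basis_from_sbp = sc.sbp_basis(sbp)
        assert np.allclose(np.abs(basis_from_sbp), np.abs(ilr_basis().T), atol=1e-12)

    def test_rejects_zero_part(self):
        with pytest.raises(ZeroPartError):
            ilr_transform([0, 1, 1, 1, 1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(parts=positive_parts, k=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, parts, k):
        parts = np.asarray(parts)
        assert np.allclose(
            ilr_transform(parts), ilr_transform(k * parts), atol=1e-9
        )


class TestIlrInverse:
    def test_origin_maps_to_barycentre(self):
        assert np.allclose(ilr_inverse(np.zeros(4)), np.full(5, 288.0))

    def test_round_trip_of_reference_centre(self):
        back = ilr_inverse(ilr_transform(CENTRE))
        assert np.allclose(back, closure(CENTRE), atol=1e-9)

    def test_random_coordinates_close_to_day_total(self, rng):
        z = rng.normal(0, 2, size=(50, 4))
        comps = ilr_inverse(z)
        assert np.allclose(comps.sum(axis=1), 1440.0, atol=1e-9)

    def test_round_trip_over_many_random_compositions(self, rng):
        parts = rng.uniform(0.5, 800.0, size=(1000, 5))
        back = ilr_inverse(ilr_transform(parts))
        assert np.max(np.abs(back - closure(parts))) < 1e-9


class TestDescriptives:
    def test_single_sample_geometric_mean_is_closure(self):
        assert np.allclose(geometric_mean_composition(CENTRE), closure(CENTRE))

    def test_two_sample_hand_computation(self):
        p = np.array([100, 200, 300, 400, 440.0])
        q = np.array([90, 210, 310, 390, 450.0])
        expected = closure(np.sqrt(p * q))
        got = geometric_mean_composition(np.stack([p, q]))
        assert np.allclose(got, expected)
        # frozen from a separate hand computation
        assert np.allclose(
            got,
            [94.55926409, 204.27135706, 303.96550636, 393.68160997, 443.52226252],
            atol=1e-6,
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_composition(np.empty((0, 5)))

    def test_variation_matrix_zero_for_identical_samples(self):
        samples = np.tile(CENTRE, (4, 1))
        assert np.allclose(variation_matrix(samples), 0.0)

    def test_variation_matrix_zero_entry_for_proportional_parts(self, rng):
        samples = rng.uniform(10, 500, size=(20, 5))
        samples[:, 1] = 3.0 * samples[:, 0]  # constant ratio
        V = variation_matrix(samples)
        assert abs(V[0, 1]) < 1e-12
        assert V[0, 1] == V[1, 0]

    def test_variation_matrix_against_spreadsheet_oracle(self):
        X = np.array(
            [[10, 55, 346, 512, 518], [15, 50, 300, 540, 535], [8, 60, 380, 480, 512.0]]
        )
        V = variation_matrix(X)
        # frozen from an element-by-element spreadsheet-style computation
        assert np.isclose(V[0, 1], 0.16742996, atol=1e-7)
        assert np.isclose(V[3, 4], 0.00144811, atol=1e-7)
        assert np.allclose(np.diag(V), 0.0)
        assert np.allclose(V, V.T)
        # invariant to rescaling one sample by a positive constant
        X2 = X.copy()
        X2[1] *= 7.3
        assert np.allclose(variation_matrix(X2), V, atol=1e-12)

    def test_variation_matrix_needs_two_samples(self):
        with pytest.raises(ValueError):
            variation_matrix(CENTRE.reshape(1, 5))


class TestAitchisonDistance:
    def test_zero_on_identical_and_symmetric(self, rng):
        a = rng.uniform(1, 500, 5)
        b = rng.uniform(1, 500, 5)
        assert aitchison_distance(a, a) == 0.0
        assert np.isclose(aitchison_distance(a, b), aitchison_distance(b, a))

    def test_isometry_with_clr_oracle(self, rng):
        """Distance equals the clr-space Euclidean distance (independent
        route avoiding the ILR basis entirely)."""
        for _ in range(20):
            a = rng.uniform(1, 500, 5)
            b = rng.uniform(1, 500, 5)
            clr = lambda x: np.log(x) - np.log(x).mean()
            d_clr = np.linalg.norm(clr(a) - clr(b))
            assert abs(aitchison_distance(a, b) - d_clr) < 1e-10
            d_ilr = np.linalg.norm(ilr_transform(a) - ilr_transform(b))
            assert abs(aitchison_distance(a, b) - d_ilr) < 1e-10


class TestAmalgamationAndTernary:
    def test_default_grouping_on_reference_centre(self):
        got = amalgamate(CENTRE)
        assert np.allclose(got, np.array([518, 512, 411.0]) / 1441.0)

    def test_equal_parts_one_one_three_split(self):
        got = amalgamate(np.full(5, 288.0))
        assert np.allclose(got, [0.2, 0.2, 0.6])

    def test_groups_always_sum_to_one(self, rng):
        parts = rng.uniform(1, 500, size=(10, 5))
        assert np.allclose(amalgamate(parts).sum(axis=1), 1.0)

    def test_malformed_grouping_rejected(self):
        with pytest.raises(ValueError):
            amalgamate(CENTRE, {"a": ["sleep"], "b": ["sedentary"]})
        with pytest.raises(ValueError):
            amalgamate(
                CENTRE,
                {"a": ["sleep"], "b": ["sleep"], "c": ["vigorous", "moderate", "light"]},
            )

    def test_ternary_vertices_and_centroid(self):
        assert np.allclose(ternary_coordinates([1, 0, 0]), [0, 0])
        assert np.allclose(ternary_coordinates([0, 1, 0]), [1, 0])
        assert np.allclose(ternary_coordinates([0, 0, 1]), [0.5, np.sqrt(3) / 2])
        assert np.allclose(
            ternary_coordinates([1 / 3, 1 / 3, 1 / 3]), [0.5, np.sqrt(3) / 6]
        )

    def test_ternary_rejects_unnormalised(self):
        with pytest.raises(ValueError):
            ternary_coordinates([0.5, 0.5, 0.5])


class TestReallocation:
    def test_zero_delta_is_identity(self):
        assert np.allclose(reallocate_proportional(CENTRE, "vigorous", 0.0), CENTRE)

    def test_ten_minutes_to_vpa_hand_arithmetic(self):
        out = reallocate_proportional(CENTRE, "vigorous", 10.0)
        scale = (1441.0 - 20.0) / (1441.0 - 10.0)
        assert np.isclose(out[0], 20.0)
        assert np.allclose(out[1:], CENTRE[1:] * scale)
        assert np.isclose(out.sum(), 1441.0)

    def test_vpa_reallocation_moves_only_first_coordinate(self):
        z0 = ilr_transform(CENTRE)
        z1 = ilr_transform(reallocate_proportional(CENTRE, "vigorous", 10.0))
        assert np.max(np.abs(z1[1:] - z0[1:])) < 1e-10
        assert z1[0] > z0[0]

    def test_forward_backward_round_trip(self):
        out = reallocate_proportional(
            reallocate_proportional(CENTRE, "vigorous", 7.0), "vigorous", -7.0
        )
        assert np.allclose(out, CENTRE, atol=1e-10)

    def test_exhausting_a_part_rejected(self):
        with pytest.raises(ValueError):
            reallocate_proportional(CENTRE, "vigorous", -10.0)  # VPA -> 0
        with pytest.raises(ValueError):
            reallocate_proportional(CENTRE, "sleep", 1000.0)
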