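"""Construction and surgical modification of periodic torsional potentials."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from torsplit import (
    PeriodicPotential,
    RotorParams,
    find_stationary_points,
    fit_fourier,
    insert_rectangular_barrier,
    rescale_to_anchors,
    solve,
    splitting,
    symmetrize,
    synth_double_well,
    excited_state_potential,
)
from torsplit.analysis import localize_and_decompose

from conftest import low_ts_angle

GRID = np.arange(0.0, 360.0, 0.1)


class TestFitFourier:
    def test_exact_threefold_cosine(self):
        samples = [(a, 100.0 * (1 - np.cos(3 * np.radians(a))) / 2) for a in np.arange(0, 360, 1.0)]
        pot = fit_fourier(samples, order=5)
        assert pot.a0 == pytest.approx(50.0, abs=1e-9)
        assert pot.a[2] == pytest.approx(-50.0, abs=1e-9)
        mask = np.ones(5, dtype=bool)
        mask[2] = False
        assert np.max(np.abs(pot.a[mask])) < 1e-9
        assert np.max(np.abs(pot.b)) < 1e-9
        assert pot.fit_rms < 1e-9

    def test_constant_rezeros_to_zero(self):
        samples = [(a, 7.0) for a in np.arange(0, 360, 5.0)]
        pot = fit_fourier(samples, order=2)
        assert np.max(np.abs(pot(GRID))) < 1e-10

    def test_round_trip_against_generator(self, asymmetric_well):
        samples = list(zip(GRID, asymmetric_well(GRID)))
        refit = fit_fourier(samples, order=8)
        assert np.max(np.abs(refit(GRID) - asymmetric_well(GRID))) < 1e-8

    def test_underdetermined_raises(self):
        samples = [(a, 1.0 + np.cos(np.radians(a))) for a in (0.0, 90.0, 180.0)]
        with pytest.raises(ValueError, match="underdetermined"):
            fit_fourier(samples, order=3)

    def test_nonfinite_raises(self):
        samples = [(a, np.nan if a == 10 else 1.0) for a in np.arange(0, 360, 5.0)]
        with pytest.raises(ValueError, match="non-finite"):
            fit_fourier(samples, order=2)

    def test_duplicate_angles_mod_360_raise(self):
        samples = [(a, 1.0) for a in np.arange(0, 360, 10.0)] + [(370.0, 1.0)]
        with pytest.raises(ValueError, match="duplicate"):
            fit_fourier(samples, order=2)


class TestStationaryPoints:
    def test_threefold_symmetry(self, cos3_potential):
        pts = find_stationary_points(cos3_potential)
        mins = [p.angle for p in pts if p.kind == "minimum"]
        maxs = [p.angle for p in pts if p.kind == "maximum"]
        assert np.allclose(mins, [0, 120, 240], atol=1e-4)
        assert np.allclose(maxs, [60, 180, 300], atol=1e-4)

    def test_plain_cosine(self):
        pot = PeriodicPotential(a0=0.0, a=np.array([1.0]), b=np.zeros(1))
        pts = find_stationary_points(pot)
        kinds = {p.kind: p.angle for p in pts}
        assert kinds["minimum"] == pytest.approx(180.0, abs=1e-4)
        assert kinds["maximum"] == pytest.approx(0.0, abs=1e-4)

    def test_alternating_kinds_on_circle(self, asymmetric_well):
        pts = find_stationary_points(asymmetric_well)
        kinds = [p.kind for p in pts]
        for i, k in enumerate(kinds):
            assert k != kinds[(i + 1) % len(kinds)]

    def test_generator_ground_truth_recovered(self, asymmetric_well):
        pts = find_stationary_points(asymmetric_well)
        truth = asymmetric_well.known_stationary_points
        assert len(pts) == len(truth)
        for found, known in zip(pts, truth):
            assert found.angle == pytest.approx(known.angle, abs=1e-3)
            assert found.kind == known.kind

    def test_flat_potential_raises(self):
        pot = PeriodicPotential(a0=5.0, a=np.zeros(2), b=np.zeros(2))
        with pytest.raises(ValueError, match="no isolated stationary points"):
            find_stationary_points(pot)


class TestSymmetrize:
    def test_idempotent_on_symmetric_input(self, symmetric_well):
        ts = low_ts_angle(symmetric_well)
        out = symmetrize(symmetric_well, ts)
        assert np.max(np.abs(out(GRID) - symmetric_well(GRID))) < 1e-8

    def test_mirror_symmetry_produced(self):
        pot = PeriodicPotential(a0=0.0, a=np.array([1.0]), b=np.array([0.3])).rezeroed()
        ts = [p.angle for p in find_stationary_points(pot) if p.kind == "maximum"][0]
        out = symmetrize(pot, ts)
        x = np.arange(0.0, 180.0, 0.1)
        assert np.max(np.abs(out(ts + x) - out(ts - x))) < 1e-10

    def test_symmetrize_twice_equals_once(self, asymmetric_well):
        ts = low_ts_angle(asymmetric_well)
        once = symmetrize(asymmetric_well, ts)
        twice = symmetrize(once, ts)
        assert np.max(np.abs(twice(GRID) - once(GRID))) < 1e-8

    def test_non_maximum_angle_rejected(self, symmetric_well):
        with pytest.raises(ValueError, match="not a stationary maximum"):
            symmetrize(symmetric_well, low_ts_angle(symmetric_well) + 25.0)


class TestRescaleToAnchors:
    def test_identity_corrections(self, asymmetric_well):
        pts = find_stationary_points(asymmetric_well)
        anchors = [(p, p.energy) for p in pts]
        out = rescale_to_anchors(asymmetric_well, anchors)
        assert np.max(np.abs(out(GRID) - asymmetric_well(GRID))) < 1e-12

    def test_uniform_shift_is_identity_after_rezero(self, asymmetric_well):
        pts = find_stationary_points(asymmetric_well)
        anchors = [(p, p.energy + 37.5) for p in pts]
        out = rescale_to_anchors(asymmetric_well, anchors)
        assert np.max(np.abs(out(GRID) - asymmetric_well(GRID))) < 1e-10

    def test_passes_exactly_through_corrected_energies(self, asymmetric_well):
        rng = np.random.default_rng(7)
        pts = find_stationary_points(asymmetric_well)
        corr = rng.uniform(-5.0, 5.0, size=len(pts))
        anchors = [(p, p.energy + c) for p, c in zip(pts, corr)]
        out = rescale_to_anchors(asymmetric_well, anchors)
        # re-zeroing shifts all values by the same constant
        vals = np.array([float(out(np.array([p.angle]))[0]) for p, _ in anchors])
        target = np.array([e for _, e in anchors])
        shift = vals - target
        assert np.max(np.abs(shift - shift[0])) < 1e-9

    def test_incomplete_anchor_set_rejected(self, asymmetric_well):
        pts = find_stationary_points(asymmetric_well)
        with pytest.raises(ValueError, match="full stationary set"):
            rescale_to_anchors(asymmetric_well, [(pts[0], 0.0)])

    def test_non_stationary_anchor_rejected(self, asymmetric_well):
        from torsplit import StationaryPoint

        pts = find_stationary_points(asymmetric_well)
        bad = [(StationaryPoint(p.angle + 7.0, p.energy, p.kind), p.energy) for p in pts]
        with pytest.raises(ValueError, match="not a stationary point"):
            rescale_to_anchors(asymmetric_well, bad)


class TestRectangularBarrier:
    def test_changes_energy_only_inside_support(self, symmetric_well):
        ts = low_ts_angle(symmetric_well)
        out = insert_rectangular_barrier(symmetric_well, ts, width=1.0, height=1e6)
        assert float(out(np.array([ts + 2.0]))[0]) == pytest.approx(
            float(symmetric_well(np.array([ts + 2.0]))[0]), abs=1e-12
        )
        assert float(out(np.array([ts]))[0]) == pytest.approx(
            float(symmetric_well(np.array([ts]))[0]) + 1e6, abs=1e-6
        )

    def test_fourier_part_untouched(self, symmetric_well):
        out = insert_rectangular_barrier(symmetric_well, 0.0)
        assert np.array_equal(out.a, symmetric_well.a)
        assert np.array_equal(out.b, symmetric_well.b)
        assert out.a0 == symmetric_well.a0

    def test_invalid_geometry_rejected(self, symmetric_well):
        with pytest.raises(ValueError):
            insert_rectangular_barrier(symmetric_well, 0.0, width=-1.0)
        with pytest.raises(ValueError):
            insert_rectangular_barrier(symmetric_well, 0.0, height=0.0)


class TestExcitedStatePotential:
    def test_equal_offsets_leave_potential_unchanged(self, asymmetric_well):
        pts = find_stationary_points(asymmetric_well)
        out = excited_state_potential(asymmetric_well, [(p, 3700.0) for p in pts])
        assert np.max(np.abs(out(GRID) - asymmetric_well(GRID))) < 1e-9

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_raising_barrier_decreases_splitting(self, symmetric_well, methyl_rotor):
        pts = find_stationary_points(symmetric_well)
        ts = low_ts_angle(symmetric_well)
        offsets = [(p, 40.0 if abs((p.angle - ts + 180) % 360 - 180) < 1 else 0.0) for p in pts]
        raised = excited_state_potential(symmetric_well, offsets)
        s0 = splitting(solve(symmetric_well, methyl_rotor, n_states=2, basis_size=60))
        s1 = splitting(solve(raised, methyl_rotor, n_states=2, basis_size=60))
        assert s1 < s0

    def test_reducing_well_offset_decreases_localized_delta(self, asymmetric_well, methyl_rotor):
        pts = find_stationary_points(asymmetric_well)
        ts = low_ts_angle(asymmetric_well)
        mins = sorted(
            [p for p in pts if p.kind == "minimum"], key=lambda p: p.energy
        )[:2]
        upper = max(mins, key=lambda p: p.energy)
        # lower the higher well by 5 cm^-1: asymmetry shrinks
        offsets = [(p, -5.0 if p.angle == upper.angle else 0.0) for p in pts]
        evened = excited_state_potential(asymmetric_well, offsets)
        d0 = localize_and_decompose(asymmetric_well, methyl_rotor, ts, basis_size=60)
        d1 = localize_and_decompose(evened, methyl_rotor, ts, basis_size=60)
        assert abs(d1.delta) < abs(d0.delta)


class TestSynthDoubleWell:
    def test_zero_asymmetry_is_mirror_symmetric(self, symmetric_well):
        ts = low_ts_angle(symmetric_well)
        x = np.arange(0.0, 180.0, 0.1)
        assert np.max(np.abs(symmetric_well(ts + x) - symmetric_well(ts - x))) < 1e-8

    def test_recorded_minima_differ_by_requested_asymmetry(self, asymmetric_well):
        mins = sorted(
            [p for p in asymmetric_well.known_stationary_points if p.kind == "minimum"],
            key=lambda p: p.energy,
        )[:2]
        assert mins[1].energy - mins[0].energy == pytest.approx(9.0, abs=1e-6)

    def test_infeasible_parameters_raise(self):
        with pytest.raises(ValueError):
            synth_double_well(barrier=100.0, asymmetry=100.0, well_separation=104.0)
        with pytest.raises(ValueError):
            synth_double_well(barrier=-5.0, asymmetry=0.0, well_separation=104.0)
        with pytest.raises(ValueError):
            synth_double_well(barrier=100.0, asymmetry=0.0, well_separation=200.0)

    @pytest.mark.parametrize("asym", [0.0, 4.0, 20.0])
    def test_barrier_height_near_request(self, asym):
        pot = synth_double_well(barrier=250.0, asymmetry=asym, well_separation=100.0)
        maxima = [p for p in pot.known_stationary_points if p.kind == "maximum"]
        low_top = min(maxima, key=lambda p: p.energy)
        assert low_top.energy == pytest.approx(250.0, rel=0.2)


@given(
    a=st.lists(st.floats(-100, 100), min_size=2, max_size=5),
    b=st.lists(st.floats(-100, 100), min_size=2, max_size=5),
    tau=st.floats(0, 360),
)
def test_evaluation_is_exactly_periodic(a, b, tau):
    k = min(len(a), len(b))
    pot = PeriodicPotential(a0=0.0, a=np.array(a[:k]), b=np.array(b[:k]))
    v0 = float(pot(np.array([tau]))[0])
    v1 = float(pot(np.array([tau + 360.0]))[0])
    assert v1 == pytest.approx(v0, abs=1e-9 * max(1.0, abs(v0)))
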