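import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slaml.gating import (
    ChannelError,
    EventMatrix,
    GateParams,
    MarkerProfile,
    cutoff_from_negative_control,
    gate_blasts,
    lsc_fraction,
    marker_profile_from_events,
    percent_positive,
    profiles_from_frame,
    profiles_to_frame,
)
from slaml.synthetic import simulate_events


def matrix_from_columns(**cols):
    names = list(cols)
    mat = np.column_stack([np.asarray(cols[c], dtype=float) for c in names])
    return EventMatrix(mat, names)


class TestEventMatrix:
    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            EventMatrix(np.array([[1.0, np.nan]]), ["CD45", "CD34"])

    def test_channel_map_resolution(self):
        em = EventMatrix(np.array([[1.0, 2.0]]), ["FL1", "FL2"],
                         channel_map={"FL1": "CD34", "FL2": "CD45"})
        assert em.marker_values("CD34")[0] == 1.0
        assert em.marker_values("CD45")[0] == 2.0

    def test_unknown_marker_raises(self):
        em = matrix_from_columns(CD45=[1.0])
        with pytest.raises(ChannelError):
            em.marker_values("CD34")

    def test_roundtrip_frame(self):
        em = matrix_from_columns(CD45=[1, 2], CD34=[3, 4])
        em2 = EventMatrix.from_frame(em.to_frame())
        np.testing.assert_array_equal(em.intensities, em2.intensities)


class TestGate:
    def test_pure_blasts_fully_retained(self, archetypes):
        ev = simulate_events(archetypes["MPP-L"], 5000, seed=1,
                             lymphocyte_fraction=0.0)
        res = gate_blasts(ev)
        assert res.fraction_retained == pytest.approx(1.0, abs=0.005)

    def test_70_30_mixture(self, archetypes):
        ev = simulate_events(archetypes["CMP-L"], 20_000, seed=2,
                             lymphocyte_fraction=0.30)
        res = gate_blasts(ev)
        # binomial 3-sigma bound around 0.70
        sd = np.sqrt(0.7 * 0.3 / 20_000)
        assert abs(res.fraction_retained - 0.70) < 3 * sd + 0.005

    def test_low_count_warning(self, archetypes):
        ev = simulate_events(archetypes["MPP-L"], 5000, seed=3,
                             lymphocyte_fraction=0.0)
        assert gate_blasts(ev).low_count_warning
        big = simulate_events(archetypes["MPP-L"], 15_000, seed=3,
                              lymphocyte_fraction=0.0)
        assert not gate_blasts(big).low_count_warning

    def test_missing_cd45_raises(self):
        em = matrix_from_columns(CD34=[1.0, 2.0])
        with pytest.raises(ChannelError):
            gate_blasts(em)

    def test_invalid_gate_params(self):
        with pytest.raises(ValueError):
            GateParams(cd45_low=100, cd45_high=10)

    def test_indices_unique_and_in_range(self, mpp_events):
        res = gate_blasts(mpp_events)
        assert len(np.unique(res.indices)) == len(res.indices)
        assert res.indices.max() < mpp_events.n_events


class TestPercentPositive:
    def test_all_above(self):
        em = matrix_from_columns(CD34=[50, 60, 70])
        assert percent_positive(em, "CD34", 10) == 100.0

    def test_none_above(self):
        em = matrix_from_columns(CD34=[1, 2, 3])
        assert percent_positive(em, "CD34", 10) == 0.0

    def test_three_of_ten(self):
        em = matrix_from_columns(CD34=[1] * 7 + [100] * 3)
        assert percent_positive(em, "CD34", 10) == 30.0

    def test_at_cutoff_counts_negative(self):
        em = matrix_from_columns(CD34=[10.0, 20.0])
        assert percent_positive(em, "CD34", 10.0) == 50.0

    def test_empty_gate_is_nan(self):
        em = matrix_from_columns(CD45=[1e6], CD34=[5.0])
        gate = gate_blasts(em)  # CD45 outside gate
        assert gate.n_retained == 0
        assert np.isnan(percent_positive(em, "CD34", 10, gate))

    def test_negative_cutoff_rejected(self):
        em = matrix_from_columns(CD34=[1.0])
        with pytest.raises(ValueError):
            percent_positive(em, "CD34", -1)

    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=50),
           st.floats(0, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_permutation_and_duplication_invariance(self, values, cutoff):
        em = matrix_from_columns(CD34=values)
        base = percent_positive(em, "CD34", cutoff)
        perm = percent_positive(
            matrix_from_columns(CD34=list(reversed(values))), "CD34", cutoff)
        dup = percent_positive(matrix_from_columns(CD34=values * 2), "CD34", cutoff)
        assert base == perm
        assert base == pytest.approx(dup)

    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_cutoff(self, values):
        em = matrix_from_columns(CD34=values)
        pcts = [percent_positive(em, "CD34", c) for c in (0, 10, 100, 1000)]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))


class TestMarkerProfile:
    def test_mpp_archetype_profile(self, mpp_events, cutoffs):
        prof = marker_profile_from_events(mpp_events, cutoffs)
        assert prof.percentages["CD34"] >= 20
        assert prof.percentages["MPO"] < 10

    def test_empty_matrix(self, cutoffs):
        em = EventMatrix(np.empty((0, 2)), ["CD45", "CD34"])
        prof = marker_profile_from_events(em, {"CD34": 100.0})
        assert prof.n_blasts == 0
        assert np.isnan(prof.percentages["CD34"])

    def test_event_order_irrelevant(self, mpp_events, cutoffs):
        perm = np.random.default_rng(0).permutation(mpp_events.n_events)
        shuffled = EventMatrix(mpp_events.intensities[perm], mpp_events.channels)
        p1 = marker_profile_from_events(mpp_events, cutoffs)
        p2 = marker_profile_from_events(shuffled, cutoffs)
        assert p1.percentages == p2.percentages

    def test_percentage_bounds_enforced(self):
        with pytest.raises(ValueError):
            MarkerProfile(patient_id="x", percentages={"CD34": 150.0})

    def test_roundtrip_frame(self):
        profs = [MarkerProfile("a", {"CD34": 10.0, "MPO": 5.0}, n_blasts=100)]
        back = profiles_from_frame(profiles_to_frame(profs))
        assert back[0].percentages["CD34"] == 10.0
        assert back[0].n_blasts == 100


class TestLSC:
    def test_constructed_18_percent(self, archetypes, cutoffs):
        ev = simulate_events(archetypes["HSC-L"], 20_000, seed=11)
        gate = gate_blasts(ev)
        assert lsc_fraction(ev, cutoffs, gate) == pytest.approx(18.03, abs=1.5)

    def test_all_cd38_positive_is_zero(self):
        em = matrix_from_columns(CD34=[1000] * 5, CD38=[1000] * 5, CD123=[1000] * 5)
        assert lsc_fraction(em, {"CD34": 100, "CD38": 100, "CD123": 100}) == 0.0

    def test_all_lsc_is_100(self):
        em = matrix_from_columns(CD34=[1000] * 5, CD38=[1] * 5, CD123=[1000] * 5)
        assert lsc_fraction(em, {"CD34": 100, "CD38": 100, "CD123": 100}) == 100.0

    def test_missing_channel_raises(self):
        em = matrix_from_columns(CD34=[1.0], CD38=[1.0])
        with pytest.raises(ChannelError):
            lsc_fraction(em, {"CD34": 100, "CD38": 100, "CD123": 100})

    def test_lsc_bounded_by_cd34_positive(self, archetypes, cutoffs):
        for lab in ("HSC-L", "CMP-L", "GMP-L", "MP-L"):
            ev = simulate_events(archetypes[lab], 5000, seed=13)
            gate = gate_blasts(ev)
            lsc = lsc_fraction(ev, cutoffs, gate)
            cd34 = percent_positive(ev, "CD34", cutoffs["CD34"], gate)
            assert lsc <= cd34 + 1e-9


class TestCutoffFromControl:
    def test_percentile(self):
        control = np.arange(1000, dtype=float)
        cut = cutoff_from_negative_control(control, q=99.5)
        assert cut == pytest.approx(994.0, abs=1.0)

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            cutoff_from_negative_control(np.array([]))
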