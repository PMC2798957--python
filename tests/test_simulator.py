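"""Integrator correctness against the matrix-exponential solution, entry
actions, and protocol chaining."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from b2arsim import (
    AGONISTS,
    LigandEnvironment,
    Protocol,
    ProtocolSegment,
    RateSet,
    apply_instantaneous_dissociation,
    effective_rates,
    integrate_segment,
    linear_oracle,
    naive_state,
    rate_matrix,
    run_protocol,
    state,
)
from conftest import random_rate_table, random_state


class TestRateMatrix:
    def test_columns_sum_to_zero(self, rates, iso_1uM):
        A = rate_matrix(effective_rates(rates, iso_1uM))
        np.testing.assert_allclose(A.sum(axis=0), 0.0, atol=1e-12)

    def test_matches_handwritten_derivatives(self, rates, iso_1uM):
        """The declarative reaction table and the written-out mass-action
        right-hand side are two routes to the same linear operator."""
        from b2arsim import derivatives

        r = effective_rates(rates, iso_1uM)
        A = rate_matrix(r)
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = random_state(rng)
            np.testing.assert_allclose(A @ y, derivatives(y, r), atol=1e-12)


class TestLinearOracle:
    def test_identity_at_t_zero(self, rates, iso_1uM, y0):
        r = effective_rates(rates, iso_1uM)
        np.testing.assert_allclose(linear_oracle(y0, r, 0.0), y0, atol=1e-14)

    def test_all_rates_zero_is_identity(self, y0):
        r = {key: 0.0 for _, _, key in __import__("b2arsim").REACTIONS}
        np.testing.assert_allclose(linear_oracle(y0, r, 50.0), y0, atol=1e-14)


class TestIntegrateSegment:
    def test_two_state_binding_equilibrium(self, y0):
        """With only ligand binding enabled the bound fraction approaches
        k1f/(k1f + k1b) = 500/504."""
        zeros = {f: 0.0 for f in RateSet().to_dict()}
        zeros.update(k1f=500.0, k1b=4.0)
        rates = RateSet(**zeros)
        env = LigandEnvironment(AGONISTS["ISO"], 1000.0)
        _, ys = integrate_segment(
            y0, ProtocolSegment(5.0, env), rates, rate_scales={"k2f": 0.0}
        )
        assert ys[-1][1] == pytest.approx(500.0 / 504.0, abs=1e-9)

    def test_final_state_matches_oracle(self, rates, iso_1uM, y0):
        seg = ProtocolSegment(5.0, iso_1uM)
        _, ys = integrate_segment(y0, seg, rates)
        expected = linear_oracle(y0, effective_rates(rates, iso_1uM), 5.0)
        np.testing.assert_allclose(ys[-1], expected, atol=1e-8)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_oracle_agreement_random_rates_and_states(self, seed):
        rng = np.random.default_rng(seed)
        r = random_rate_table(rng)
        y0 = random_state(rng)
        duration = float(rng.uniform(0.1, 10.0))
        rates = RateSet().replace(**{k: v for k, v in r.items() if k != "k2f"})
        env = LigandEnvironment(AGONISTS["ISO"], 1000.0)
        seg = ProtocolSegment(duration, env)
        scale = {"k2f": r["k2f"] / effective_rates(RateSet(), env)["k2f"]}
        _, ys = integrate_segment(y0, seg, rates, rate_scales=scale)
        expected = linear_oracle(y0, effective_rates(rates, env, scale), duration)
        np.testing.assert_allclose(ys[-1], expected, atol=1e-8)


class TestInstantaneousDissociation:
    def test_mapping(self):
        y = state(RstarLs=0.4, Rs=0.1)
        out = apply_instantaneous_dissociation(y)
        np.testing.assert_allclose(out, state(Rs=0.5), atol=1e-15)

    def test_identity_when_no_ligand_bound(self):
        y = state(Rs=0.3, Rgs=0.2, Ri=0.5)
        np.testing.assert_allclose(apply_instantaneous_dissociation(y), y)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_mass_preserved_exactly(self, seed):
        y = random_state(np.random.default_rng(seed))
        assert apply_instantaneous_dissociation(y).sum() == pytest.approx(
            y.sum(), abs=1e-15
        )


class TestRunProtocol:
    def test_single_segment_equals_integrate_segment(self, rates, iso_1uM, y0):
        seg = ProtocolSegment(5.0, iso_1uM)
        traj = run_protocol(y0, Protocol([seg], 0.01), rates)
        _, ys = integrate_segment(y0, seg, rates)
        np.testing.assert_allclose(traj.final_state, ys[-1], atol=1e-12)

    def test_semigroup_property(self, rates, iso_1uM, y0):
        """Two consecutive segments with the same environment are equivalent
        to one segment of the summed duration."""
        one = run_protocol(y0, Protocol([ProtocolSegment(10.0, iso_1uM)], 0.01), rates)
        two = run_protocol(
            y0,
            Protocol(
                [ProtocolSegment(4.0, iso_1uM), ProtocolSegment(6.0, iso_1uM)], 0.01
            ),
            rates,
        )
        np.testing.assert_allclose(two.final_state, one.final_state, atol=1e-9)

    def test_times_strictly_increasing_with_boundaries(self, rates, iso_1uM, y0):
        protocol = Protocol(
            [
                ProtocolSegment(1.0, iso_1uM),
                ProtocolSegment(1.0, LigandEnvironment(), "instantaneous_dissociation"),
                ProtocolSegment(1.0, iso_1uM),
            ],
            0.01,
        )
        traj = run_protocol(y0, protocol, rates)
        assert np.all(np.diff(traj.times) > 0)
        assert traj.segment_boundaries == (1.0, 2.0)

    def test_antagonist_switch_decays_phosphorylation(self, rates, iso_1uM, y0):
        from b2arsim import phosphorylated_fraction

        blocked = LigandEnvironment(iso_1uM.agonist, iso_1uM.concentration, True)
        traj = run_protocol(
            y0,
            Protocol(
                [ProtocolSegment(5.0, iso_1uM), ProtocolSegment(25.0, blocked)], 0.01
            ),
            rates,
        )
        ph = np.asarray(phosphorylated_fraction(traj.states))
        i_switch = np.argmin(np.abs(traj.times - 5.0))
        assert ph[-1] < 0.8 * ph[i_switch]
        # oracle composition across the two segments
        r1 = effective_rates(rates, iso_1uM)
        r2 = effective_rates(rates, blocked)
        expected = linear_oracle(linear_oracle(y0, r1, 5.0), r2, 25.0)
        np.testing.assert_allclose(traj.final_state, expected, atol=1e-8)

    def test_washout_modes_converge_when_downstream_frozen(self, y0):
        """Instantaneous dissociation and plain washout (off-rates 4/min)
        reach the same state once bound ligand has fully dissociated, when
        all non-ligand reactions are disabled."""
        zeros = {f: 0.0 for f in RateSet().to_dict()}
        zeros.update(k1f=500.0, k1b=4.0, k4f=4.0, k4b=500.0, k5f=4.0, k5b=500.0)
        rates = RateSet(**zeros)
        env = LigandEnvironment(AGONISTS["ISO"], 1000.0)
        load = ProtocolSegment(5.0, env)
        plain = run_protocol(
            y0,
            Protocol([load, ProtocolSegment(10.0, LigandEnvironment())], 0.01),
            rates,
        )
        instant = run_protocol(
            y0,
            Protocol(
                [
                    load,
                    ProtocolSegment(
                        10.0, LigandEnvironment(), "instantaneous_dissociation"
                    ),
                ],
                0.01,
            ),
            rates,
        )
        np.testing.assert_allclose(plain.final_state, instant.final_state, atol=1e-9)

    def test_trajectory_csv_roundtrip(self, rates, iso_1uM, y0, tmp_path):
        import pandas as pd

        traj = run_protocol(y0, Protocol([ProtocolSegment(2.0, iso_1uM)], 0.05), rates)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time_min"] + list(__import__("b2arsim").SPECIES) + [
            "segment"
        ]
        np.testing.assert_allclose(df.iloc[-1, 1:-1].to_numpy(float), traj.final_state)


class TestProtocolValidation:
    def test_sampling_interval_must_fit_shortest_segment(self, iso_1uM):
        with pytest.raises(ValueError):
            Protocol([ProtocolSegment(0.5, iso_1uM)], sample_interval=1.0)

    def test_dissociation_entry_requires_agonist_free_segment(self, iso_1uM):
        with pytest.raises(ValueError):
            ProtocolSegment(1.0, iso_1uM, "instantaneous_dissociation")

    def test_nonpositive_duration_rejected(self, iso_1uM):
        with pytest.raises(ValueError):
            ProtocolSegment(0.0, iso_1uM)
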