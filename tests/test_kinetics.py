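import numpy as np
import pytest

from presteady.constants import ELEMENTARY_CHARGE_C, PhysicalConstants
from presteady.kinetics import (
    ASCT2_DEFAULTS,
    KineticScheme,
    Transition,
    asct2_default_scheme,
    check_microscopic_reversibility,
    compute_currents,
    equilibrium_occupancy,
    generator_matrix,
    integrate_protocol,
    voltage_rate,
)
from presteady.protocols import SolutionProtocol


def step_protocol(ligand="L", conc=1.0, pre_ms=0.0, on_ms=200.0, tau=0.0):
    segments = []
    if pre_ms > 0:
        segments.append((0.0, pre_ms, {ligand: 0.0}))
    segments.append((pre_ms, pre_ms + on_ms, {ligand: conc}))
    return SolutionProtocol(segments=tuple(segments), exchange_tau_ms=tau)


class TestVoltageRate:
    def test_zero_voltage_returns_k0(self):
        assert voltage_rate(123.4, -0.7, 0.0) == 123.4

    def test_printed_slope_at_room_temperature(self):
        """d ln k / dV = zQ / (2 RT/F) = -0.0037 per mV for zQ = -0.19."""
        c = PhysicalConstants(297.0)
        slope = -0.19 / (2.0 * c.RT_over_F_mV)
        assert slope == pytest.approx(-0.0037, abs=1e-4)

    def test_direct_evaluation(self):
        c = PhysicalConstants(298.15)
        # 10 * exp(0.19 * 100 / 51.386)
        assert voltage_rate(10.0, -0.19, -100.0, c) == pytest.approx(14.48, abs=0.01)

    def test_overflow_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            r = voltage_rate(1.0, 100.0, 1e5)
        assert np.isfinite(r)

    def test_forward_backward_symmetry(self):
        """Opposite valences at opposite voltages give the same factor."""
        for z, v in [(0.4, -80.0), (-0.08, 60.0), (1.0, 25.0)]:
            assert voltage_rate(1.0, z, v) == pytest.approx(
                voltage_rate(1.0, -z, -v), rel=1e-12)


class TestEquilibrium:
    def test_single_state(self):
        scheme = KineticScheme(states=("A",), transitions=())
        p = equilibrium_occupancy(scheme, {}, 0.0)
        assert p == pytest.approx([1.0])

    def test_two_state_binding_printed_affinity(self):
        """Kd 0.83 uM at 1 uM ligand: bound fraction 1.2048/2.2048 = 0.546."""
        scheme = KineticScheme(
            states=("free", "bound"),
            transitions=(
                Transition("free", "bound", 10.0, ligand="L"),  # 1/(s*mM)
                Transition("bound", "free", 10.0 * 0.00083),
            ),
        )
        p = equilibrium_occupancy(scheme, {"L": 0.001})
        assert p[1] == pytest.approx(1.0 / (1.0 + 0.83), abs=1e-3)

    def test_three_state_detailed_balance_cycle(self):
        """Stationary distribution equals the product of rate ratios."""
        # rates chosen to satisfy the cycle condition exactly
        k = {"ab": 2.0, "ba": 4.0, "bc": 6.0, "cb": 3.0, "ca": 1.0}
        k["ac"] = k["ba"] * k["cb"] * k["ca"] / (k["ab"] * k["bc"])  # closure
        scheme = KineticScheme(
            states=("a", "b", "c"),
            transitions=(
                Transition("a", "b", k["ab"]), Transition("b", "a", k["ba"]),
                Transition("b", "c", k["bc"]), Transition("c", "b", k["cb"]),
                Transition("c", "a", k["ca"]), Transition("a", "c", k["ac"]),
            ),
        )
        assert check_microscopic_reversibility(scheme, {}) == []
        p = equilibrium_occupancy(scheme, {})
        # detailed balance: p_b / p_a = k_ab / k_ba etc.
        assert p[1] / p[0] == pytest.approx(k["ab"] / k["ba"], rel=1e-10)
        assert p[2] / p[1] == pytest.approx(k["bc"] / k["cb"], rel=1e-10)

    def test_reducible_graph_errors(self):
        scheme = KineticScheme(
            states=("a", "b", "c", "d"),
            transitions=(
                Transition("a", "b", 1.0), Transition("b", "a", 1.0),
                Transition("c", "d", 1.0), Transition("d", "c", 1.0),
            ),
        )
        with pytest.raises(ValueError, match="reducible"):
            equilibrium_occupancy(scheme, {})

    def test_dissipative_cycle_flagged(self):
        scheme = KineticScheme(
            states=("a", "b", "c"),
            transitions=(
                Transition("a", "b", 2.0), Transition("b", "a", 1.0),
                Transition("b", "c", 2.0), Transition("c", "b", 1.0),
                Transition("c", "a", 2.0), Transition("a", "c", 1.0),
            ),
        )
        flagged = check_microscopic_reversibility(scheme, {})
        assert len(flagged) == 1


class TestIntegration:
    def test_constant_inputs_keep_equilibrium(self):
        scheme = KineticScheme(
            states=("u", "b"),
            transitions=(Transition("u", "b", 50.0, ligand="L"),
                         Transition("b", "u", 20.0)),
        )
        proto = step_protocol(conc=2.0, on_ms=100.0)
        traj = integrate_protocol(scheme, proto, initial="equilibrate")
        assert np.allclose(traj.occupancy, traj.occupancy[0], atol=1e-9)

    def test_irreversible_two_state_closed_form(self):
        """A -> B at 100 1/s switched on at t=0: p_B = 1 - exp(-t / 10 ms)."""
        scheme = KineticScheme(
            states=("A", "B"),
            transitions=(Transition("A", "B", 100.0, ligand="L"),),
        )
        proto = step_protocol(conc=1.0, on_ms=50.0)
        traj = integrate_protocol(scheme, proto, initial=np.array([1.0, 0.0]))
        expected = 1.0 - np.exp(-traj.times_ms / 10.0)
        assert np.allclose(traj.state_series("B"), expected, atol=1e-9)

    def test_conservation_at_every_sample(self, default_scheme):
        proto = SolutionProtocol(
            segments=((0.0, 50.0, {"Na": 140.0, "S": 0.0, "I": 0.0}),
                      (50.0, 250.0, {"Na": 140.0, "S": 2.0, "I": 0.0})),
            exchange_tau_ms=5.0)
        traj = integrate_protocol(default_scheme, proto)
        sums = traj.occupancy.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) <= 1e-9
        assert traj.occupancy.min() >= 0.0

    def test_matches_eigendecomposition_oracle(self):
        """Step response of a 3-state scheme vs the spectral closed form."""
        scheme = KineticScheme(
            states=("a", "b", "c"),
            transitions=(
                Transition("a", "b", 80.0, ligand="L"), Transition("b", "a", 30.0),
                Transition("b", "c", 55.0), Transition("c", "b", 12.0),
            ),
        )
        p0 = np.array([1.0, 0.0, 0.0])
        proto = step_protocol(conc=1.5, on_ms=80.0)
        traj = integrate_protocol(scheme, proto, initial=p0, dt_ms=0.5)
        # independent oracle: eigendecomposition of the generator
        Q = generator_matrix(scheme, {"L": 1.5}, 0.0) / 1000.0  # per ms
        lam, V = np.linalg.eig(Q.T)
        Vinv = np.linalg.inv(V)
        for i, t in enumerate(traj.times_ms):
            p_exact = (V @ np.diag(np.exp(lam * t)) @ Vinv @ p0).real
            assert np.allclose(traj.occupancy[i], p_exact, atol=1e-8)

    def test_paired_pulse_returns_to_rest(self, default_scheme):
        proto = SolutionProtocol(
            segments=((0.0, 50.0, {"Na": 140.0, "S": 0.0, "I": 0.0}),
                      (50.0, 250.0, {"Na": 140.0, "S": 2.0, "I": 0.0}),
                      (250.0, 1500.0, {"Na": 140.0, "S": 0.0, "I": 0.0})),
            exchange_tau_ms=0.0)
        traj = integrate_protocol(default_scheme, proto)
        assert np.allclose(traj.occupancy[-1], traj.occupancy[0], atol=1e-5)


class TestCurrents:
    def test_equilibrium_transport_current_is_zero(self, default_scheme):
        proto = SolutionProtocol(
            segments=((0.0, 100.0, {"Na": 140.0, "S": 0.0, "I": 0.0}),),
            exchange_tau_ms=0.0)
        traj = integrate_protocol(default_scheme, proto, initial="equilibrate")
        trace = compute_currents(traj, default_scheme)
        assert np.max(np.abs(trace.transport_pA)) < 1e-9

    @pytest.mark.parametrize("zq, expected_peak", [(1.0, -16.02), (-0.08, 1.28)])
    def test_binding_step_peak_current_closed_form(self, zq, expected_peak):
        """Peak transport current at t=0+ is -e N zQ k; charge = -e N zQ dp."""
        scheme = KineticScheme(
            states=("A", "B"),
            transitions=(Transition("A", "B", 100.0, zQ=zq, ligand="L"),),
            N_transporters=1e6,
        )
        proto = step_protocol(conc=1.0, on_ms=100.0)
        traj = integrate_protocol(scheme, proto, initial=np.array([1.0, 0.0]),
                                  dt_ms=0.01)
        trace = compute_currents(traj, scheme)
        assert trace.transport_pA[0] == pytest.approx(expected_peak, abs=0.005)
        # decay time constant 10 ms
        ratio = trace.transport_pA[1000] / trace.transport_pA[0]
        assert ratio == pytest.approx(np.exp(-1.0), rel=1e-6)
        # integrated charge equals -e N zQ * (occupancy change), to 0.1%
        q_num = np.trapezoid(trace.transport_pA, traj.times_ms) * 1e-3  # pC
        dp = traj.state_series("B")[-1] - traj.state_series("B")[0]
        q_exact = -ELEMENTARY_CHARGE_C * 1e6 * zq * dp * 1e12  # pC
        assert q_num == pytest.approx(q_exact, rel=1e-3)

    def test_mismatched_scheme_rejected(self, default_scheme):
        proto = SolutionProtocol(
            segments=((0.0, 10.0, {"Na": 140.0, "S": 0.0, "I": 0.0}),),
            exchange_tau_ms=0.0)
        traj = integrate_protocol(default_scheme, proto)
        other = KineticScheme(states=("x", "y"),
                              transitions=(Transition("x", "y", 1.0),))
        with pytest.raises(ValueError, match="different scheme"):
            compute_currents(traj, other)


class TestDefaultScheme:
    def test_leak_state_occupied_and_conducting_without_ligands(self, default_scheme):
        p = equilibrium_occupancy(default_scheme, {"Na": 140.0, "S": 0.0, "I": 0.0})
        idx = default_scheme.index("TNa")
        assert p[idx] > 0.99
        g = sum(default_scheme.anion_conductance_pS.get(s, 0.0) *
                p[default_scheme.index(s)] for s in default_scheme.conducting)
        assert g > 0

    def test_na1_half_saturation_is_printed_km(self, default_scheme):
        km = ASCT2_DEFAULTS["Km_Na1_mM"]
        p = equilibrium_occupancy(default_scheme, {"Na": km, "S": 0.0, "I": 0.0})
        bound = p[default_scheme.index("TNa")]
        free = p[default_scheme.index("T")]
        assert bound == pytest.approx(free, rel=1e-6)

    def test_inhibitor_residency_default(self):
        assert 1000.0 / ASCT2_DEFAULTS["k_off_I"] == pytest.approx(120.0, abs=0.5)

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            asct2_default_scheme(bogus_rate=1.0)

    def test_calibrated_relaxations(self, default_scheme):
        """The shipped defaults reproduce the designed observables exactly."""
        from presteady.kinetics import _slowest_relaxation_ms

        sub = ("T", "TNa", "TNaS", "TNa2S", "TSocc")
        wash = _slowest_relaxation_ms(default_scheme,
                                      {"Na": 140.0, "S": 0.0, "I": 0.0}, states=sub)
        act = _slowest_relaxation_ms(default_scheme,
                                     {"Na": 140.0, "S": 2.0, "I": 0.0}, states=sub)
        assert wash == pytest.approx(ASCT2_DEFAULTS["turnover_tau_ms"], rel=1e-6)
        assert act == pytest.approx(ASCT2_DEFAULTS["activation_tau_ms"], rel=1e-6)
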