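import numpy as np
import pytest

from swdnet import (
    CouplingMatrix,
    IntegrationBlowupError,
    NetworkLayout,
    NodeParams,
    SimulationConfig,
    coupling_function,
    renormalized_sampling_frequency,
    simulate,
)
from swdnet.dynamics import euler_step
from swdnet.layout import Population, Region

from conftest import make_matrix
from reference import reference_trajectory


class TestCouplingFunction:
    def test_midpoint(self):
        assert coupling_function(0.0) == 0.5

    @pytest.mark.parametrize("x", [-3.0, -0.7, 0.01, 1.9, 5.0])
    def test_odd_symmetry_and_range(self, x):
        assert coupling_function(x) + coupling_function(-x) == pytest.approx(1.0)
        assert 0.0 < coupling_function(x) < 1.0

    def test_reference_value(self):
        # (1 + tanh 2) / 2
        assert coupling_function(2.0) == pytest.approx(0.98201379, abs=1e-6)

    def test_monotone(self):
        xs = np.linspace(-4, 4, 100)
        assert np.all(np.diff(coupling_function(xs)) > 0)


class TestTimeBase:
    def test_default_sampling_frequency(self):
        fs = renormalized_sampling_frequency(SimulationConfig(duration_s=1))
        assert fs == pytest.approx(3400.0, rel=1e-12)

    def test_halved_rate(self):
        cfg = SimulationConfig(duration_s=1, dt_model=1.0)
        assert renormalized_sampling_frequency(cfg) == pytest.approx(1700.0, rel=1e-12)

    @pytest.mark.parametrize(
        "tau,delay_ms", [(9, 2.6470588), (13, 3.8235294)]
    )
    def test_delay_in_renormalized_time(self, tau, delay_ms):
        fs = renormalized_sampling_frequency(SimulationConfig(duration_s=1))
        assert tau / fs * 1000 == pytest.approx(delay_ms, abs=1e-4)


class TestEulerStep:
    def test_origin_is_fixed_point(self):
        x = np.zeros(1)
        y = np.zeros(1)
        C = np.zeros((1, 1))
        xn, yn = euler_step(x, y, x, C, NodeParams(), 0.5)
        assert xn[0] == 0.0 and yn[0] == 0.0

    def test_hand_computed_step(self):
        # isolated node at (0.5, 0): dx = 0.5*0.3*(-0.5) = -0.075
        x = np.array([0.5])
        y = np.array([0.0])
        C = np.zeros((1, 1))
        xn, yn = euler_step(x, y, x, C, NodeParams(), 0.5)
        assert xn[0] == pytest.approx(0.4625, abs=1e-15)
        assert yn[0] == pytest.approx(0.002, abs=1e-15)

    def test_clamped_source_gives_constant_drive(self):
        # node 1 sees node 0 through +0.1 edge; source history clamped at 0
        C = np.array([[0.0, 0.0], [0.1, 0.0]])
        x = np.zeros(2)
        y = np.zeros(2)
        xn, _ = euler_step(x, y, np.zeros(2), C, NodeParams(), 0.5)
        assert xn[1] == pytest.approx(0.5 * 0.1 * 0.5)  # dt * C * h(0)
        assert xn[0] == 0.0


class TestSimulate:
    def test_equilibrium_network_stays_flat(self, tiny_layout):
        m = make_matrix(np.zeros((3, 3)), layout=tiny_layout)
        cfg = SimulationConfig(
            duration_s=0.5, initial_state=np.zeros((2, 3))
        )
        res = simulate(m, cfg)
        assert res.n_steps == round(0.5 * 3400)
        assert np.all(res.x == 0.0)

    def test_determinism(self, tiny_layout):
        C = np.array([[0, 0.1, 0], [-0.1, 0, 0.1], [0.1, 0, 0]])
        m = make_matrix(C, layout=tiny_layout)
        cfg = SimulationConfig(duration_s=0.5, seed=3)
        r1 = simulate(m, cfg)
        r2 = simulate(m, cfg)
        np.testing.assert_array_equal(r1.x, r2.x)

    def test_time_axis(self, tiny_layout):
        m = make_matrix(np.zeros((3, 3)), layout=tiny_layout)
        res = simulate(m, SimulationConfig(duration_s=1.0, seed=0))
        t = res.time()
        assert len(t) == 3400
        assert np.allclose(np.diff(t), 1 / 3400.0)

    @pytest.mark.parametrize("n_nodes,tau", [(1, 9), (2, 10), (3, 13)])
    def test_matches_bruteforce_reference(self, n_nodes, tau):
        """Vectorized integrator equals the naive loop oracle to 1e-12."""
        rng = np.random.default_rng(n_nodes)
        C = rng.choice([0.0, 0.1, -0.1], size=(n_nodes, n_nodes))
        np.fill_diagonal(C, 0.0)
        m = make_matrix(
            C,
            tau_steps=tau,
            layout=NetworkLayout({(Population.PY, Region.FOCAL): n_nodes}),
        )
        x0 = rng.uniform(-0.1, 0.9, n_nodes)
        y0 = rng.uniform(-0.05, 0.05, n_nodes)
        n_steps = 1000
        cfg = SimulationConfig(
            duration_s=n_steps / 3400.0,
            initial_state=np.vstack([x0, y0]),
        )
        res = simulate(m, cfg)
        ref = reference_trajectory(C.tolist(), tau, x0.tolist(), y0.tolist(), n_steps)
        ref = np.asarray(ref)
        scale = np.maximum(np.abs(ref), 1.0)
        assert np.max(np.abs(res.x - ref) / scale) < 1e-12

    def test_delay_shift_in_feedforward_chain(self):
        """A source pulse reaches the target exactly tau steps later.

        The target starts at its constant-input equilibrium, so its
        trajectory is flat until the delayed pulse arrives; runs with
        different tau are exact shifted copies of each other.
        """
        from scipy.optimize import brentq

        from swdnet.protocols import ProtocolEvent

        lay = NetworkLayout(
            {(Population.PY, Region.FOCAL): 1, (Population.TC, Region.FOCAL): 1}
        )
        # node 0 = PY target, node 1 = TC source (stays at origin unless driven)
        C = np.array([[0.0, 0.1], [0.0, 0.0]])
        p = NodeParams()
        # PY equilibrium under the constant h(0)-mediated input 0.1 * 0.5
        g = lambda x: x * (p.a - x) * (x - 1.0) - (p.b / p.gamma) * x + 0.05
        x_eq = brentq(g, 0.0, 0.5, xtol=1e-15)
        y_eq = (p.b / p.gamma) * x_eq
        pulse = ProtocolEvent(
            kind="additive_pulse_train",
            t_start=0.05,
            t_end=0.06,
            nodes=((Population.TC, None),),
            amplitude=0.5,
            pulse_width_s=0.005,
            pulse_period_s=1.0,
        )
        outs = {}
        for tau in (9, 13):
            m = make_matrix(C, tau_steps=tau, layout=lay)
            init = np.array([[x_eq, 0.0], [y_eq, 0.0]])
            res = simulate(
                m, SimulationConfig(duration_s=0.3, initial_state=init), [pulse]
            )
            outs[tau] = res.x[:, 0]
        a, b = outs[9], outs[13]
        k0 = int(0.05 * 3400)  # pulse onset sample
        # flat before the delayed pulse arrives
        assert np.allclose(a[: k0 + 9], a[0], atol=1e-12)
        assert np.allclose(b[: k0 + 13], b[0], atol=1e-12)
        # thereafter: identical trajectories, shifted by the delay difference
        np.testing.assert_array_equal(a[k0 + 9 : -4], b[k0 + 13 :])

    def test_blowup_reported_with_step(self, tiny_layout):
        # strong positive self-reinforcing loop with huge weights blows up
        C = np.full((3, 3), 50.0)
        np.fill_diagonal(C, 0.0)
        m = make_matrix(C, layout=tiny_layout)
        init = np.full((2, 3), 5.0)
        with pytest.raises(IntegrationBlowupError) as ei:
            with np.errstate(all="ignore"):
                simulate(m, SimulationConfig(duration_s=1.0, initial_state=init))
        assert ei.value.step > 0

    def test_compartment_recording_matches_full(self, tiny_layout):
        C = np.array([[0, 0.1, 0], [-0.1, 0, 0.1], [0.1, 0, 0]])
        m = make_matrix(C, layout=tiny_layout)
        cfg_full = SimulationConfig(duration_s=0.3, seed=1, record="full")
        cfg_comp = SimulationConfig(duration_s=0.3, seed=1, record="compartments")
        rf = simulate(m, cfg_full)
        rc = simulate(m, cfg_comp)
        np.testing.assert_allclose(
            rf.population_sum(Population.PY),
            rc.population_sum(Population.PY),
            atol=1e-12,
        )
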