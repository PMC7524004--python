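import io

import numpy as np
import pytest

from swdnet import (
    CouplingMatrix,
    NetworkLayout,
    ProbabilityTable,
    apply_collaterals,
    compose_network,
    load_matrix,
    sample_matrix,
    save_matrix,
)
from swdnet.connectivity import DEFAULT_PROBABILITIES
from swdnet.layout import Population as P, Region as R


class TestLayout:
    def test_default_totals(self):
        lay = NetworkLayout.default()
        assert lay.n_total == 500
        counts = lay.counts
        assert counts[(P.PY, R.FOCAL)] == 40
        assert counts[(P.PY, R.SURROUND)] == 160
        # population totals: 200 PY + 50 IN + 120 TC + 120 RE + 10 NT
        assert len(lay.indices(P.PY)) == 200
        assert len(lay.indices(P.IN)) == 50
        assert len(lay.indices(P.TC)) == 120
        assert len(lay.indices(P.RE)) == 120
        assert len(lay.indices(P.NT)) == 10

    def test_ranges_partition(self):
        lay = NetworkLayout.default()
        seen = sorted(i for rng in lay.ranges().values() for i in rng)
        assert seen == list(range(500))

    def test_nt_must_be_external(self):
        with pytest.raises(ValueError):
            NetworkLayout({(P.NT, R.FOCAL): 5})


class TestProbabilityTable:
    def test_focal_at_least_surrounding(self):
        """Focal targets are wired at least as densely as surrounding ones."""
        tab = ProbabilityTable.default()
        for (tpop, spop, region), p in DEFAULT_PROBABILITIES.items():
            if region is R.FOCAL and spop is not P.NT:
                assert p >= tab.get(tpop, spop, R.SURROUND)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ProbabilityTable({(P.PY, P.PY, R.FOCAL): 1.5})

    def test_nt_target_rejected(self):
        with pytest.raises(ValueError):
            ProbabilityTable({(P.NT, P.PY, R.FOCAL): 0.1})


class TestSampleMatrix:
    def test_zero_probabilities_give_zero_matrix(self):
        lay = NetworkLayout.focal_only()
        m = sample_matrix(lay, ProbabilityTable({}), seed=0)
        assert m.n_edges() == 0

    def test_saturated_block(self):
        """Probability 1 on focal PY<-PY wires every ordered pair once."""
        lay = NetworkLayout.focal_only()
        tab = ProbabilityTable({(P.PY, P.PY, R.FOCAL): 1.0})
        m = sample_matrix(lay, tab, seed=0, collaterals=False)
        py = lay.indices(P.PY, R.FOCAL)
        block = m.C[np.ix_(py, py)]
        assert np.all(block[~np.eye(len(py), dtype=bool)] == 0.1)
        assert np.all(np.diag(block) == 0.0)
        assert m.n_edges() == len(py) * (len(py) - 1)

    def test_edge_density_matches_probability(self):
        """Empirical density concentrates on the table probability.

        Binomial oracle: over many seeds the pooled density of the focal
        PY<-PY block (p = 0.036) stays within 3 binomial standard errors.
        """
        lay = NetworkLayout({(P.PY, R.FOCAL): 40})
        tab = ProbabilityTable({(P.PY, P.PY, R.FOCAL): 0.036})
        trials_per_seed = 40 * 39
        n_seeds = 400
        hits = 0
        for seed in range(n_seeds):
            m = sample_matrix(lay, tab, seed=seed, collaterals=False)
            hits += m.n_edges()
        n = n_seeds * trials_per_seed
        se = np.sqrt(0.036 * (1 - 0.036) / n)
        assert abs(hits / n - 0.036) < 3 * se

    def test_determinism(self):
        lay = NetworkLayout.focal_only()
        m1 = sample_matrix(lay, seed=11)
        m2 = sample_matrix(lay, seed=11)
        np.testing.assert_array_equal(m1.C, m2.C)

    def test_dale_sign_rule(self):
        """Nonzero entries of each column share the source population's sign
        (exact before collateral completion / under the Dale variant)."""
        lay = NetworkLayout.default()
        for seed in (0, 1):
            m = sample_matrix(lay, seed=seed, collateral_rule="dale")
            m.validate_signs()
            pops = lay.population_of()
            for j in range(0, 500, 17):
                col = m.C[:, j]
                nz = col[col != 0]
                if nz.size:
                    expected = 0.1 if pops[j] in (P.PY, P.TC, P.NT) else -0.1
                    assert np.all(nz == expected)

    def test_structural_zeros(self):
        """Blocks absent from the probability table stay empty (pre-collateral)."""
        lay = NetworkLayout.default()
        m = sample_matrix(lay, seed=4, collaterals=False)
        ranges = lay.ranges()
        tab = ProbabilityTable.default()
        for (tpop, tr), trng in ranges.items():
            for (spop, sr), srng in ranges.items():
                if tab.get(tpop, spop, tr) == 0.0:
                    block = m.C[np.ix_(list(trng), list(srng))]
                    assert not block.any()

    def test_nt_receives_nothing_even_after_collaterals(self):
        lay = NetworkLayout.default()
        m = sample_matrix(lay, seed=4, collaterals=True)
        nt = lay.indices(P.NT)
        assert not m.C[nt, :].any()


class TestCollaterals:
    def _single_edge(self, tpop, spop):
        lay = NetworkLayout.focal_only()
        C = np.zeros((lay.n_total, lay.n_total))
        i = lay.indices(tpop, R.FOCAL)[0]
        j = lay.indices(spop, R.FOCAL)[0]
        C[i, j] = 0.1
        return CouplingMatrix(C, 10, lay, meta={"w_exc": 0.1, "w_inh": 0.1}), i, j

    def test_excitatory_reciprocal(self):
        # PY -> TC edge acquires TC -> PY back-edge (TC is excitatory):
        # both completion rules agree here
        m, i, j = self._single_edge(P.TC, P.PY)
        assert apply_collaterals(m, rule="copy").C[j, i] == 0.1
        assert apply_collaterals(m, rule="dale").C[j, i] == 0.1

    def test_reciprocal_of_edge_onto_inhibitory_population(self):
        # PY -> RE edge: the value-copy rule duplicates the +0.1 weight,
        # the Dale variant signs the back-edge by its RE source instead
        m, i, j = self._single_edge(P.RE, P.PY)
        assert apply_collaterals(m, rule="copy").C[j, i] == 0.1
        assert apply_collaterals(m, rule="dale").C[j, i] == -0.1

    @pytest.mark.parametrize("rule", ["copy", "dale"])
    def test_idempotent(self, rule):
        lay = NetworkLayout.focal_only()
        m = sample_matrix(lay, seed=9, collaterals=False)
        once = apply_collaterals(m, rule=rule)
        twice = apply_collaterals(once, rule=rule)
        np.testing.assert_array_equal(once.C, twice.C)

    def test_symmetric_support_after_completion(self):
        """Every edge has a reciprocal partner (except into NT nodes)."""
        lay = NetworkLayout.focal_only()
        m = sample_matrix(lay, seed=9)
        nt = set(lay.indices(P.NT))
        keep = np.array([i not in nt for i in range(lay.n_total)])
        sub = (m.C != 0)[np.ix_(keep, keep)]
        assert np.array_equal(sub, sub.T)


class TestCompose:
    def test_zero_cross_probabilities_block_diagonal(self):
        mf = sample_matrix(NetworkLayout.focal_only(), seed=0)
        ms = sample_matrix(NetworkLayout.surround_only(), seed=1)
        empty = ProbabilityTable({})
        full = compose_network(mf, ms, empty, seed=2)
        lay = full.layout
        focal = [i for (p, r), rng in lay.ranges().items() if r is R.FOCAL for i in rng]
        surr = [i for (p, r), rng in lay.ranges().items() if r is R.SURROUND for i in rng]
        assert not full.C[np.ix_(focal, surr)].any()
        assert not full.C[np.ix_(surr, focal)].any()

    def test_diagonal_blocks_preserved(self):
        mf = sample_matrix(NetworkLayout.focal_only(), seed=0)
        ms = sample_matrix(NetworkLayout.surround_only(), seed=1)
        full = compose_network(mf, ms, ProbabilityTable({}), seed=2)
        lay = full.layout
        for key, rng in mf.layout.ranges().items():
            frng = lay.ranges()[key]
            sub = full.C[np.ix_(list(frng), list(frng))]
            orig = mf.C[np.ix_(list(rng), list(rng))]
            np.testing.assert_array_equal(sub, orig)

    def test_mismatched_tau_rejected(self):
        mf = sample_matrix(NetworkLayout.focal_only(), seed=0, tau_steps=9)
        ms = sample_matrix(NetworkLayout.surround_only(), seed=1, tau_steps=10)
        with pytest.raises(ValueError, match="tau"):
            compose_network(mf, ms, seed=2)

    def test_default_cross_blocks_follow_allowed_pathways(self):
        """Cross-block edges appear only for pathways present in the table
        (or their collaterals) and a focal->surrounding PY bridge exists."""
        mf = sample_matrix(NetworkLayout.focal_only(), seed=0)
        ms = sample_matrix(NetworkLayout.surround_only(), seed=1)
        full = compose_network(mf, ms, seed=3)
        lay = full.layout
        tab = ProbabilityTable.default()
        ranges = lay.ranges()
        pys = ranges[(P.PY, R.SURROUND)]
        pyf = ranges[(P.PY, R.FOCAL)]
        bridge = full.C[np.ix_(list(pys), list(pyf))]
        assert bridge.any()  # the focal-to-surrounding "bridge"
        # a pathway with zero probability whose reverse is also zero stays
        # empty even after collaterals, e.g. RE <- IN
        ref = ranges[(P.RE, R.SURROUND)]
        inf = ranges[(P.IN, R.FOCAL)]
        assert not full.C[np.ix_(list(ref), list(inf))].any()


class TestRoundTrip:
    def test_save_load_identity(self, tmp_path):
        m = sample_matrix(NetworkLayout.focal_only(), seed=5, tau_steps=12)
        path = tmp_path / "m.tsv"
        save_matrix(m, path)
        back = load_matrix(path)
        np.testing.assert_array_equal(m.C, back.C)
        assert back.tau_steps == 12
        assert back.layout.counts == m.layout.counts
        assert back.meta["seed"] == 5

    def test_self_edge_rejected(self):
        text = (
            "# swdnet coupling matrix v1\n"
            "# layout PY:focal=3\n"
            "# tau_steps 10\n"
            "1\t1\t0.1\n"
        )
        with pytest.raises(ValueError, match="line 4"):
            load_matrix(io.StringIO(text))

    def test_empty_edge_list(self):
        text = "# swdnet coupling matrix v1\n# layout PY:focal=4\n# tau_steps 9\n"
        m = load_matrix(io.StringIO(text))
        assert m.C.shape == (4, 4)
        assert m.n_edges() == 0

    def test_malformed_line_names_line(self):
        text = (
            "# swdnet coupling matrix v1\n"
            "# layout PY:focal=3\n"
            "# tau_steps 10\n"
            "0\t1\n"
        )
        with pytest.raises(ValueError, match="line 4"):
            load_matrix(io.StringIO(text))
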