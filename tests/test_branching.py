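"""Birth-death simulators, lineage networks, snapshots and export."""

import math

import networkx as nx
import numpy as np
import pytest

import oubranch as ob


class TestPhenotypeRates:
    def test_at_reference_trait(self):
        cfg = ob.BranchingConfig(lambda0=0.05, delta0=0.04, alpha=1.0, beta=2.0,
                                 mu_ref=-5.0)
        lam, dlt = ob.phenotype_rates(-5.0, cfg)
        assert lam == pytest.approx(0.05)
        assert dlt == pytest.approx(0.04)

    def test_uncoupled_rates_constant(self):
        cfg = ob.BranchingConfig(alpha=0.0, beta=0.0)
        for y in (-10.0, 0.0, 10.0):
            lam, dlt = ob.phenotype_rates(y, cfg)
            assert (lam, dlt) == (pytest.approx(0.05), pytest.approx(0.04))

    def test_clipping(self):
        cfg = ob.BranchingConfig(lambda0=0.05, alpha=1.0, mu_ref=0.0, rate_cap=10.0)
        lam, _ = ob.phenotype_rates(20.0, cfg)
        assert lam == 10.0


class TestConstantBirthDeath:
    def test_critical_process_is_martingale(self):
        out = ob.constant_bd_ensemble(b=0.05, d=0.05, n0=40, n_runs=2000,
                                      seed=0, t_max=20.0)
        mean = out["final_size"].mean()
        se = out["final_size"].std(ddof=1) / math.sqrt(2000)
        assert abs(mean - 40.0) < 3 * se

    def test_single_founder_extinction_probability(self):
        """Linear birth-death from one founder goes extinct w.p. d/b = 0.8."""
        out = ob.constant_bd_ensemble(b=0.05, d=0.04, n0=1, n_runs=4000,
                                      seed=1, size_cap=1000)
        frac = out["extinct"].mean()
        assert abs(frac - 0.8) < 0.02

    def test_mean_growth_matches_closed_form(self):
        out = ob.constant_bd_ensemble(b=0.05, d=0.04, n0=40, n_runs=2000,
                                      seed=2, t_max=10.0)
        expected = 40.0 * math.exp(0.01 * 10.0)
        mean = out["final_size"].mean()
        se = out["final_size"].std(ddof=1) / math.sqrt(2000)
        assert abs(mean - expected) < 3 * se

    def test_single_run_event_bookkeeping(self):
        times, sizes = ob.simulate_constant_bd(0.05, 0.04, n0=10, t_max=50.0, seed=3)
        assert sizes[0] == 10
        assert np.all(np.abs(np.diff(sizes)) == 1)
        assert np.all(np.diff(times) > 0)
        # conservation: size = n0 + births - deaths at every event
        steps = np.diff(sizes)
        births = (steps == 1).cumsum()
        deaths = (steps == -1).cumsum()
        np.testing.assert_array_equal(sizes[1:], 10 + births - deaths)

    def test_seed_reproducibility(self):
        a = ob.simulate_constant_bd(0.05, 0.04, 5, 30.0, seed=7)
        b = ob.simulate_constant_bd(0.05, 0.04, 5, 30.0, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestLineageNetwork:
    def test_lethal_config_all_founders_extinct(self, wt_params):
        cfg = ob.BranchingConfig(lambda0=1e-9, delta0=8.0, n0=12, t_max=10.0,
                                 rate_cap=10.0)
        net = ob.simulate_lineage_network(wt_params, cfg, seed=0,
                                          snapshot_time=10.0, record_paths=False)
        assert net.n_nodes == 12
        assert np.all(~np.isnan(net.death))
        extant, extinct = ob.snapshot_classification(net, 10.0)
        assert extant.size == 0 and extinct.size == 12

    def test_seed_determinism_bitwise(self, wt_params):
        cfg = ob.BranchingConfig(n0=20, t_max=15.0, alpha=0.5, beta=0.5,
                                 mu_ref=wt_params.mu)
        a = ob.simulate_lineage_network(wt_params, cfg, seed=5, snapshot_time=10.0)
        b = ob.simulate_lineage_network(wt_params, cfg, seed=5, snapshot_time=10.0)
        c = ob.simulate_lineage_network(wt_params, cfg, seed=6, snapshot_time=10.0)
        np.testing.assert_array_equal(a.birth, b.birth)
        np.testing.assert_array_equal(a.death, b.death)
        np.testing.assert_array_equal(a.y_final, b.y_final)
        assert not (a.n_nodes == c.n_nodes and np.array_equal(a.birth, c.birth))

    def test_population_conservation(self, wt_params):
        cfg = ob.BranchingConfig(n0=30, t_max=20.0, lambda0=0.08, delta0=0.05)
        net = ob.simulate_lineage_network(wt_params, cfg, seed=2,
                                          record_paths=False)
        for t in (0.0, 5.0, 10.0, 20.0):
            born = int((net.birth <= t).sum())
            dead = int((~np.isnan(net.death) & (net.death <= t)).sum())
            assert net.population_size(t) == born - dead
        # every non-founder has a valid parent born earlier
        child = net.parent >= 0
        assert np.all(net.birth[child] >= net.birth[net.parent[child]])

    def test_matches_constant_rate_extinction(self, wt_params):
        """With zero coupling the per-step scheme reproduces the Gillespie
        linear birth-death extinction fraction from a single founder."""
        b, d = 0.5, 0.4
        n_runs = 1500
        cfg = ob.BranchingConfig(lambda0=b, delta0=d, alpha=0.0, beta=0.0,
                                 n0=1, t_max=40.0, dt=0.02)
        ext = 0
        for k in range(n_runs):
            net = ob.simulate_lineage_network(wt_params, cfg, seed=k,
                                              snapshot_time=40.0,
                                              record_paths=False)
            ext += net.population_size(40.0) == 0
        frac = ext / n_runs
        oracle = ob.constant_bd_ensemble(b, d, 1, 4000, seed=99, t_max=40.0)
        se = math.sqrt(frac * (1 - frac) / n_runs + oracle["extinct"].var() / 4000)
        assert abs(frac - oracle["extinct"].mean()) < max(3 * se, 0.04)

    def test_selection_differential_sign(self):
        """With positive couplings, extant clones at the snapshot carry higher
        phenotypes than extinct ones (sign test over seeded runs)."""
        ou = ob.OUParams(0.0, 0.3, 0.8)
        cfg = ob.BranchingConfig(lambda0=0.25, delta0=0.2, alpha=1.0, beta=1.0,
                                 mu_ref=0.0, n0=30, t_max=20.0, dt=0.05)
        wins = trials = 0
        for k in range(60):
            net = ob.simulate_lineage_network(ou, cfg, seed=k, snapshot_time=20.0,
                                              record_paths=False)
            extant, extinct = ob.snapshot_classification(net, 20.0)
            if extant.size and extinct.size:
                trials += 1
                wins += (net.y_final[extant].mean()
                         > net.y_final[extinct].mean())
        assert trials >= 30
        # binomial sign test against p=0.5, normal approximation p < 0.01
        z = (wins - trials / 2) / math.sqrt(trials / 4)
        assert z > 2.33, (wins, trials)

    def test_step_size_robustness(self):
        """Halving dt leaves the ensemble extinction fraction unchanged
        within Monte Carlo error."""
        ou = ob.OUParams(0.0, 1.0, 0.3)
        fracs = {}
        for dt in (0.1, 0.05):
            cfg = ob.BranchingConfig(lambda0=0.3, delta0=0.35, alpha=0.0,
                                     beta=0.0, n0=3, t_max=25.0, dt=dt)
            ext = sum(
                ob.simulate_lineage_network(ou, cfg, seed=k, snapshot_time=25.0,
                                            record_paths=False)
                .population_size(25.0) == 0
                for k in range(600)
            )
            fracs[dt] = ext / 600
        se = math.sqrt(2 * 0.5 * 0.5 / 600)
        assert abs(fracs[0.1] - fracs[0.05]) < 2 * se + 0.02


class TestSnapshotAndDownsample:
    @pytest.fixture()
    def small_net(self, wt_params):
        cfg = ob.BranchingConfig(lambda0=0.15, delta0=0.05, n0=10, t_max=30.0)
        return ob.simulate_lineage_network(wt_params, cfg, seed=8,
                                           record_paths=False)

    def test_founders_extant_at_time_zero(self, small_net):
        extant, extinct = ob.snapshot_classification(small_net, 0.0)
        assert extant.size == 10 and extinct.size == 0

    def test_snapshot_beyond_horizon_rejected(self, small_net):
        with pytest.raises(ValueError):
            ob.snapshot_classification(small_net, 100.0)

    def test_hand_built_classification(self):
        net = ob.LineageNetwork(
            parent=np.array([-1, 0, 0]),
            birth=np.array([0.0, 2.0, 3.0]),
            death=np.array([np.nan, 5.0, 25.0]),
            y_birth=np.zeros(3), y_final=np.zeros(3),
            lam_at_birth=np.array([np.nan, 0.1, 0.1]),
            snapshot_time=20.0, seed=0, t_end=40.0, t_max=40.0,
        )
        extant, extinct = ob.snapshot_classification(net, 20.0)
        assert set(extant) == {0, 2} and set(extinct) == {1}

    def test_downsample_identity_when_small(self, small_net):
        assert ob.downsample_extant(small_net, max_nodes=100000) is small_net

    def test_downsample_single_node_keeps_root_path(self, small_net):
        view = ob.downsample_extant(small_net, max_nodes=1, seed=0)
        # the view is a chain from one extant node up to its founder
        roots = (view.parent == -1).sum()
        assert roots == 1
        g = view.to_networkx()
        assert nx.is_forest(g.to_undirected()) or g.number_of_nodes() == 1

    def test_downsample_deterministic(self, wt_params):
        cfg = ob.BranchingConfig(lambda0=0.3, delta0=0.02, n0=20, t_max=20.0,
                                 dt=0.05)
        net = ob.simulate_lineage_network(wt_params, cfg, seed=1,
                                          record_paths=False)
        extant, _ = ob.snapshot_classification(net, 20.0)
        cap = max(1, extant.size // 2)
        a = ob.downsample_extant(net, max_nodes=cap, seed=3)
        b = ob.downsample_extant(net, max_nodes=cap, seed=3)
        np.testing.assert_array_equal(a.node_ids, b.node_ids)


class TestExport:
    def test_edge_list(self, tmp_path):
        net = ob.LineageNetwork(
            parent=np.array([-1, 0, 0]),
            birth=np.array([0.0, 2.0, 3.0]),
            death=np.array([np.nan, 5.0, np.nan]),
            y_birth=np.zeros(3), y_final=np.array([0.1, -0.2, 0.4]),
            lam_at_birth=np.array([np.nan, 0.11, 0.07]),
            snapshot_time=20.0, seed=0, t_end=40.0, t_max=40.0,
        )
        p = ob.export_network(net, tmp_path / "net.csv", format="edgelist")
        import pandas as pd

        df = pd.read_csv(p)
        assert len(df) == 2
        assert set(df["child"]) == {1, 2}

    def test_graphml_round_trip(self, tmp_path, wt_params):
        cfg = ob.BranchingConfig(lambda0=0.1, delta0=0.05, n0=5, t_max=15.0)
        net = ob.simulate_lineage_network(wt_params, cfg, seed=4,
                                          snapshot_time=15.0, record_paths=False)
        p = ob.export_network(net, tmp_path / "net.graphml", format="graphml")
        g = nx.read_graphml(p)
        orig = net.to_networkx()
        assert g.number_of_nodes() == orig.number_of_nodes()
        assert g.number_of_edges() == orig.number_of_edges()
        assert nx.is_isomorphic(g, nx.relabel_nodes(orig, str))
        # node attributes survive
        some = next(iter(g.nodes))
        assert "phenotype" in g.nodes[some] and "status" in g.nodes[some]

    def test_empty_forest_exports(self, tmp_path):
        net = ob.LineageNetwork(
            parent=np.array([], dtype=np.int64), birth=np.array([]),
            death=np.array([]), y_birth=np.array([]), y_final=np.array([]),
            lam_at_birth=np.array([]), snapshot_time=0.0, seed=0,
            t_end=0.0, t_max=0.0,
        )
        p = ob.export_network(net, tmp_path / "empty.json", format="json")
        import json

        assert json.loads(p.read_text())["nodes"] == []

    def test_unknown_format_rejected(self, tmp_path, wt_params):
        cfg = ob.BranchingConfig(n0=2, t_max=1.0)
        net = ob.simulate_lineage_network(wt_params, cfg, seed=0,
                                          snapshot_time=1.0, record_paths=False)
        with pytest.raises(ValueError):
            ob.export_network(net, tmp_path / "x.bin", format="pickle")
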