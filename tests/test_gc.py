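import numpy as np
import pandas as pd
import pytest

from latticegc.antigens import build_antigen_set
from latticegc.gc import (divisions_from_antigen, draw_cycle_times,
                          initialize, run, run_replicates, step)


class TestDivisionNumber:
    def test_zero_antigen_gives_nmin(self):
        assert divisions_from_antigen(0) == 1

    def test_saturates_to_nmax(self):
        assert divisions_from_antigen(10_000) == 6

    def test_monotone_nondecreasing_and_bounded(self):
        vals = [divisions_from_antigen(a, 1, 6, 9.0, 2.0) for a in range(0, 200)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(1 <= v <= 6 for v in vals)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            divisions_from_antigen(-1)


def test_cycle_time_sampler_truncated_positive(bundle):
    rng = np.random.default_rng(0)
    t = draw_cycle_times(bundle.config, rng, 10_000)
    assert (t > 0).all()
    assert t.mean() == pytest.approx(7.5, abs=0.1)


class TestInitialize:
    def test_agents_placed_and_antigen_split(self, bundle, micro_cfg):
        agset = build_antigen_set([bundle.hi, bundle.lo],
                                  total_dose=micro_cfg.antigen_total)
        st = initialize(micro_cfg, agset, bundle.pool, docker=bundle.docker, seed=0)
        assert len(st.tfh_pos) == micro_cfg.n_tfh
        assert (st.occ == -2).sum() == micro_cfg.n_fdc + micro_cfg.n_stromal
        # per-domain equal split summing exactly to the total
        assert st.node_antigen.sum() == micro_cfg.antigen_total
        per_domain = st.node_antigen.sum(axis=0)
        assert per_domain[0] == per_domain[1] == micro_cfg.antigen_total // 2
        # Tfh all in the LZ, inside the sphere
        for p in st.tfh_pos:
            assert st.inside[tuple(p)] and st.is_lz[tuple(p)]

    def test_empty_gc_steps_without_bcells(self, bundle, micro_cfg):
        cfg = micro_cfg.replace(founder_influx_per_h=1e-12)
        agset = build_antigen_set([bundle.hi, bundle.lo],
                                  total_dose=cfg.antigen_total)
        st = initialize(cfg, agset, bundle.pool, docker=bundle.docker, seed=1)
        before = st.tfh_pos.copy()
        for _ in range(20):
            step(st)
        assert st.bcells.n_alive == 0
        assert (st.tfh_pos != before).any()   # Tfh keep moving


def test_founder_influx_is_poisson_with_expected_mean(bundle, micro_cfg):
    """Mean founders after 10 simulated hours of influx-only stepping is
    rate x time (= 20 at 2 cells/h), across replicates."""
    from latticegc.gc import _influx
    cfg = micro_cfg.replace(founder_influx_per_h=2.0)
    agset = build_antigen_set([bundle.hi, bundle.lo],
                              total_dose=cfg.antigen_total)
    counts = []
    for seed in range(40):
        st = initialize(cfg, agset, bundle.pool, docker=bundle.docker, seed=seed)
        for _ in range(int(10.0 / cfg.dt_h)):
            st.time_h += cfg.dt_h   # advance clock; influx only
            _influx(st)
        counts.append(st.bcells.n_alive)
    mean = np.mean(counts)
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(mean - 20.0) < 3 * max(se, 0.5)


class TestRunInvariants:
    def test_same_seed_identical_results(self, bundle, micro_cfg):
        agset = build_antigen_set([bundle.hi, bundle.lo],
                                  total_dose=micro_cfg.antigen_total)
        r1 = run(micro_cfg, agset, bundle.pool, docker=bundle.docker, seed=5)
        r2 = run(micro_cfg, agset, bundle.pool, docker=bundle.docker, seed=5)
        pd.testing.assert_frame_equal(r1.timeseries, r2.timeseries)
        pd.testing.assert_frame_equal(r1.outputs, r2.outputs)

    def test_antigen_ledger_balances_at_end(self, micro_run, micro_cfg):
        bal = micro_run.state.ledger_balance()
        assert bal["total"] == micro_cfg.antigen_total

    def test_occupancy_one_cell_per_node(self, micro_run):
        st = micro_run.state
        alive = st.bcells.indices()
        nodes = {tuple(p) for p in st.bcells.pos[alive]}
        assert len(nodes) == len(alive)          # no two B cells share a node
        for b in alive:
            assert st.occ[tuple(st.bcells.pos[b])] == b
        tfh_nodes = {tuple(p) for p in st.tfh_pos}
        assert len(tfh_nodes) == len(st.tfh_pos)
        assert not (nodes & tfh_nodes)

    def test_states_on_documented_arcs_only(self, micro_run):
        st = micro_run.state
        alive = st.bcells.indices()
        assert set(np.unique(st.bcells.state[alive])) <= {0, 1, 2}
        assert (st.bcells.a[alive] >= 0).all()

    def test_outputs_cumulative_nondecreasing(self, micro_run):
        out = micro_run.timeseries["cumulative_outputs"].to_numpy()
        assert (np.diff(out) >= 0).all()


class TestReplicates:
    def test_single_replicate_sd_zero(self, bundle, micro_cfg):
        agset = build_antigen_set([bundle.hi, bundle.lo],
                                  total_dose=micro_cfg.antigen_total)
        summary, results = run_replicates(micro_cfg, agset, bundle.pool, n=1,
                                          base_seed=3, docker=bundle.docker)
        assert len(results) == 1
        assert (summary["n_bcells_sd"] == 0).all()

    def test_mean_lies_between_replicate_extremes(self, bundle, micro_cfg):
        agset = build_antigen_set([bundle.hi, bundle.lo],
                                  total_dose=micro_cfg.antigen_total)
        summary, results = run_replicates(micro_cfg, agset, bundle.pool, n=3,
                                          base_seed=7, docker=bundle.docker)
        stacked = np.stack([r.timeseries["n_bcells"].to_numpy() for r in results])
        assert (summary["n_bcells_mean"].to_numpy() >= stacked.min(0)).all()
        assert (summary["n_bcells_mean"].to_numpy() <= stacked.max(0)).all()


def test_trajectories_robust_to_time_step(bundle, micro_cfg):
    """Halving dt (event rates fixed) leaves summary statistics in the same
    regime at micro scale."""
    agset = build_antigen_set([bundle.hi, bundle.lo],
                              total_dose=micro_cfg.antigen_total)

    def total_cell_hours(cfg):
        acc = 0.0
        for seed in (1, 2, 3):
            ts = run(cfg, agset, bundle.pool, docker=bundle.docker,
                     seed=seed).timeseries
            acc += ts["n_bcells"].sum() * cfg.snapshot_interval_h
        return acc / 3

    coarse = total_cell_hours(micro_cfg)
    fine = total_cell_hours(micro_cfg.replace(dt_h=0.005))
    assert 0.5 < fine / coarse < 2.0
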