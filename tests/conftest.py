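"""Shared fixtures: the seeded toy bundle and the (expensive) GC runs that
several trend tests read from. Everything is generated at session start
from fixed seeds; no data files are stored."""

from __future__ import annotations

import numpy as np
import pytest

from latticegc.antigens import Antigen, build_antigen_set, randomize_residues
from latticegc.fixtures import make_fixtures, screen_antigens
from latticegc.gc import run
from latticegc.potential import load_potential
from latticegc.repertoire import generate_founder_pool

TREND_SEEDS = (1, 2, 3, 4, 5)
VALENCY_SEEDS = (1, 2, 3, 4, 5, 6)


@pytest.fixture(scope="session")
def bundle():
    return make_fixtures(0)


@pytest.fixture(scope="session")
def potential():
    return load_potential()


def _pool(agset, docker, cfg, seed=13):
    return generate_founder_pool(agset, docker, pool_total=cfg.founder_pool_total,
                                 min_affinity=cfg.founder_min_affinity, seed=seed)


@pytest.fixture(scope="session")
def micro_cfg(bundle):
    """A sub-minute two-domain configuration for functional tests."""
    return bundle.config.replace(gc_radius_um=50.0, n_tfh=12, n_fdc=8,
                                 n_stromal=12, arm_length_um=15.0,
                                 sim_days=1.5, founder_influx_per_h=6.0)


@pytest.fixture(scope="session")
def micro_run(bundle, micro_cfg):
    agset = build_antigen_set([bundle.hi, bundle.lo],
                              total_dose=micro_cfg.antigen_total)
    return run(micro_cfg, agset, bundle.pool, docker=bundle.docker, seed=5)


@pytest.fixture(scope="session")
def single_and_pair_runs(bundle):
    """hi-alone, lo-alone and {hi,lo} two-domain runs, TREND_SEEDS each."""
    cfg, d = bundle.config, bundle.docker
    sets = {
        "hi": build_antigen_set([bundle.hi], total_dose=cfg.antigen_total),
        "lo": build_antigen_set([bundle.lo], total_dose=cfg.antigen_total),
        "both": build_antigen_set([bundle.hi, bundle.lo], total_dose=cfg.antigen_total),
    }
    pools = {k: _pool(s, d, cfg) for k, s in sets.items()}
    return {k: [run(cfg, sets[k], pools[k], docker=d, seed=s).timeseries
                for s in TREND_SEEDS]
            for k in sets}


@pytest.fixture(scope="session")
def dose_runs(bundle):
    """mid-immunogenicity antigen at full (3000) and half (1500) dose."""
    cfg, d = bundle.config, bundle.docker
    agset = build_antigen_set([bundle.mid], total_dose=cfg.antigen_total)
    pool = _pool(agset, d, cfg)
    half_cfg = cfg.replace(antigen_total=cfg.antigen_total // 2)
    return {
        "full": [run(cfg, agset, pool, docker=d, seed=s).timeseries
                 for s in TREND_SEEDS],
        "half": [run(half_cfg, agset, pool, docker=d, seed=s).timeseries
                 for s in TREND_SEEDS],
    }


@pytest.fixture(scope="session")
def valency_runs(bundle):
    """mid + 1 low domain vs mid + 3 low domains (distinct structures),
    constant total dose."""
    cfg, d = bundle.config, bundle.docker
    _, _, lo_b = screen_antigens(31, d)
    _, _, lo_c = screen_antigens(47, d)
    lo_b = Antigen(lo_b.structure, "LOB")
    lo_c = Antigen(lo_c.structure, "LOC")
    set_v2 = build_antigen_set([bundle.mid, bundle.lo], total_dose=cfg.antigen_total)
    set_v4 = build_antigen_set([bundle.mid, bundle.lo, lo_b, lo_c],
                               total_dose=cfg.antigen_total)
    return {
        "v2": [run(cfg, set_v2, _pool(set_v2, d, cfg), docker=d, seed=s).timeseries
               for s in VALENCY_SEEDS],
        "v4": [run(cfg, set_v4, _pool(set_v4, d, cfg), docker=d, seed=s).timeseries
               for s in VALENCY_SEEDS],
    }
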