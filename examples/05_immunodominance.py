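"""Immunodominance between antigen domains of unequal immunogenicity.

Compares three conditions with the same total antigen dose: the
high-immunogenicity domain alone, the low-immunogenicity domain alone, and
both displayed together. The two-domain GC tracks the dominant domain's
dynamics, and the response to the weak domain is suppressed but not
abolished — the hallmark immunodominance phenomenology.
"""

import numpy as np

from latticegc.antigens import build_antigen_set
from latticegc.fixtures import make_fixtures
from latticegc.gc import run
from latticegc.repertoire import generate_founder_pool

bundle = make_fixtures(seed=0)
cfg, d = bundle.config, bundle.docker

conditions = {
    "HI alone": [bundle.hi],
    "LO alone": [bundle.lo],
    "HI + LO": [bundle.hi, bundle.lo],
}
for name, domains in conditions.items():
    agset = build_antigen_set(domains, total_dose=cfg.antigen_total)
    pool = generate_founder_pool(agset, d, pool_total=cfg.founder_pool_total,
                                 min_affinity=cfg.founder_min_affinity, seed=13)
    ts = run(cfg, agset, pool, docker=d, seed=1).timeseries
    peak = ts["n_bcells"].max()
    end = {ag.identity: ts[f"mean_affinity_{ag.identity}"].tail(24).mean()
           for ag in agset.domains}
    end_str = ", ".join(f"{k}: {v:.3f}" for k, v in end.items())
    print(f"{name:9s} | peak GC {peak:5d} cells | end-run mean affinity {end_str}")

print("\nThe HI+LO volume trajectory resembles HI-alone (the dominant domain")
print("drives GC dynamics), while affinity maturation to LO stays near its")
print("LO-alone level: dominance inhibits but does not abolish the weak response.")
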