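"""Founder-pool construction with affinity filtering.

For N antigens the naive pool holds pool_total/N sequences per antigen,
rejection-sampled uniformly and kept only above the affinity floor to the
assigned antigen. Cross-reactivity to the other antigen is left untouched
and is visible in the summary below.
"""

import numpy as np

from latticegc.antigens import build_antigen_set
from latticegc.docking import energy_to_affinity
from latticegc.fixtures import make_fixtures
from latticegc.repertoire import generate_founder_pool

bundle = make_fixtures(seed=0)
cfg, docker = bundle.config, bundle.docker
agset = build_antigen_set([bundle.hi, bundle.lo], total_dose=cfg.antigen_total)
pool = generate_founder_pool(agset, docker,
                             pool_total=cfg.founder_pool_total,
                             min_affinity=cfg.founder_min_affinity, seed=13)

print(f"pool: {pool.total} founders, floor affinity {pool.min_affinity}")
for agid, seqs in pool.sequences.items():
    own = energy_to_affinity(docker.batch_energies(list(seqs),
                             {a.identity: a for a in agset.domains}[agid]),
                             docker.affinity_params)
    other_ag = [a for a in agset.domains if a.identity != agid][0]
    cross = energy_to_affinity(docker.batch_energies(list(seqs), other_ag),
                               docker.affinity_params)
    print(f"  {agid}: {len(seqs)} founders | affinity to own antigen "
          f"median {np.median(own):.3g} (min {own.min():.3g}) | "
          f"cross-reactive affinity to {other_ag.identity} "
          f"median {np.median(cross):.3g}")
print("\nEvery founder meets the floor to its own antigen. Cross-affinities")
print("are unconstrained: here LO-assigned founders bind the intrinsically")
print("sticky HI domain more strongly than their own, an immunodominance")
print("ingredient that emerges from the structural model rather than being")
print("imposed.")
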