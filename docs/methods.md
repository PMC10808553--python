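# Methods

`latticegc` simulates germinal-center (GC) reactions in which B-cell
receptor (BCR) affinity is not an abstract fitness value but the outcome of
a structural model: exhaustive docking of a short peptide on a cubic
lattice against a rigid lattice antigen under an empirical amino-acid
contact potential. This note records the model, its assumptions, the
parameters that matter, the numerical choices, and what the reduced-scale
test conditions do and do not demonstrate.

## The affinity model

Antigens and BCR peptides are lattice proteins: one residue per node of a
cubic lattice (5.25 Å spacing in molecular units), covalent neighbors
adjacent, chains self-avoiding. A *pose* of a length-L BCR is any
self-avoiding walk of L nodes that does not overlap the antigen and makes
at least `min_contacts` non-covalent adjacencies to antigen nodes. The
energy of a pose for a sequence is

    E = Σ_inter U(seq[i], antigen_res) + s · Σ_intra U(seq[i], seq[j]),

where U is the 20×20 contact potential, the inter sum runs over
BCR-antigen adjacencies, and the intra sum runs over non-covalent BCR
self-contacts (|i−j| ≥ 2) weighted by the stabilization factor `s`
(default 1.0). The binding energy of a sequence is the minimum of E over
all poses; ties resolve to the smallest pose index in the fixed enumeration
order (starts lexicographic, directions +x,−x,+y,−y,+z,−z), so results are
bit-reproducible.

Energies (kT) convert to unitless affinities by `Aff = exp((Emax − E)/C)`
with Emax = −100 and C = 2.8: affinity 1 at E = Emax, below 1 for weaker
binders, above 1 for stronger. A `mode="literal"` option implements the
opposite sign convention for comparison; the default orientation is the one
consistent with affinities "typically between 0 and 1" and with stronger
binding meaning higher capture probability.

**Contact potential.** The packaged default transcribes the
Miyazawa–Jernigan (1996) inter-residue contact energies (Table 5 e_ij, kT
units), the standard empirical potential for lattice-protein work. The
resource file documents its origin and residue order; any table in the
same text format (including an all-zero table used by tests) can be
swapped in. Symmetry and finiteness are enforced on load. The published
source offers several table variants; the e_ij upper-half values were
chosen, and no result in this package depends on individual entries.

**Two-phase evaluation.** A GC run scores 10³–10⁵ mutant sequences against
the same antigen, so enumeration and scoring are separated. Poses are
enumerated once per (antigen structure, L, min_contacts) by a depth-first
search with an admissible pruning bound (taxicab distance to the contact
shell bounds the contacts still reachable). Each pose is reduced to its
*contact profile* — the sorted list of (BCR index, antigen node) and
(i, j) intra pairs — and profiles are deduplicated in-flight through an
open-addressing hash table (128-bit FNV hashes; dangling-tail poses
collapse onto one profile, typically a 3–20× reduction). Scoring a
sequence is then a table-lookup sum per profile, compiled with numba.
Because profiles store antigen *node indices* rather than residue letters,
one enumeration serves every residue reassignment of the same structure;
a memory guard fails enumeration beyond `max_poses` (default 5×10⁷) with
an instructive message.

## Antigens and immunogenicity

Synthetic antigen structures are compactness-biased self-avoiding walks:
each growth step weights candidate nodes by exp(compactness × k), k being
the number of occupied non-head neighbors; compactness 0 recovers the
uniform self-avoiding walk and values ≥ 1.5 give globular shapes.
Externally discretized structures can be imported from a plain one-line-
per-residue text format. Residues are assigned uniformly at random to all
nodes; burial is emergent (a buried residue simply cannot be contacted).

Immunogenicity of an antigen is its mean optimal binding energy against a
panel of random naive BCR sequences (200 by default). Classes partition
the mean-energy axis: A below −75 kT, then 2.5-kT steps through G, H above
−60 kT; a boundary value belongs to the less immunogenic (right) class —
an arbitrary but documented convention. Antigen sets split a constant
total dose (default 3000 units) equally across domains.

## The agent-based GC

Cells occupy single nodes of a second cubic lattice (5 µm nodes) inside a
sphere (default radius 160 µm) whose lower/upper hemispheres are dark and
light zone (DZ/LZ). At initialization 250 Tfh cells and 200 FDCs (six
40-µm dendrite arms along the axes) are placed randomly in the LZ, 300
stromal cells in the DZ; B and T cells may overlap dendrite nodes but not
each other. Antigen is spread uniformly over dendrite nodes, equally per
domain, with integer units (remainders go to the first nodes so the ledger
stays exact). Two static guidance fields (Jacobi relaxation to steady
state with dendrite and stromal nodes as sources) stand in for the
pre-calculated CXCL13/CXCL12 chemokine maps.

Movement is a persistent random walk: an agent steps with probability
speed·dt/node (7.5 µm/min default), redraws its direction with probability
dt/persistence (1.5 min) from a softmax over the neighbor gains of its
guidance field (centroblasts home to the DZ, all other mobile states and
Tfh to the LZ). Updates are synchronous; contested target nodes go to a
random contender and losers turn.

Per time step (dt = 1e−4 h default) the event order is fixed: founder
influx → movement → DZ cycling/division → capture (on its own 0.001 h
cadence) and search resolution → Tfh contacts and selection → output/ASC
bookkeeping. Founders enter as Poisson arrivals (2 cells/h for 96 h) at
free nodes with BCRs drawn from the founder pool and proliferate 6 times
(cycle ~ Normal(7.5, 1.25) h truncated positive; the SD is not printed in
the protocol and is configurable). Each division mutates both daughter
sequences independently (per-residue replacement probability 0.055, a
guaranteed change to one of the 19 other residues, so a 9-mer averages
0.495 ≈ 0.5 replacements per division); affinities of new sequences to
all domains are computed once and cached by sequence.

In the LZ, an unselected cell standing on a stocked dendrite node attempts
capture every 0.001 h: the target is the highest-affinity domain still
stocked at that node, and success probability is min(1, capture_rate·Aff)
(capture_rate default 1.0, the plain "proportional to affinity" clamp)
with a hard floor of Aff ≥ 1e−8. Cells that capture nothing within the
0.7 h search time die. Survivors enter a 3 h Tfh window: a free Tfh
engages the adjacent window-phase B cell with the most internalized
antigen for a 0.6 h contact during which both partners are immobile and
polarization time accrues (at most one Tfh per B cell at a time);
0.5 h of accrued polarization selects the cell, window expiry kills it.
Selected cells recycle to the DZ with a division number
Nmin + round((Nmax−Nmin)·aʰ/(aʰ+Kʰ)) in captured units a (defaults
Nmin 1, Nmax 6, K 9, h 2 — the functional form is a documented stand-in
for the unpublished pMHC→divisions map). Internalized antigen passes to
one daughter in 72% of divisions and is split evenly (odd unit by fair
coin) otherwise. A cell finishing its divisions with antigen leaves as an
output cell; with none, it re-enters LZ competition. The output pool
differentiates into antibody-secreting cells as a deterministic
compartment with 24 h half-life; each ASC secretes 3e−8 mol/h.

**Bookkeeping invariants.** Antigen is integer-conserved at all times:
units on FDC nodes + units inside living B cells + units removed with
apoptotic and output cells = total dose, checkable per step
(`audit_ledger=True`). Occupancy holds one cell per node (dendrites
excepted). A single seed expands into per-subsystem RNG streams
(placement, influx, movement, SHM, capture, cycle, Tfh), so a
(config, antigen set, founder pool, seed) tuple fully determines every
output artifact.

## Reduced-scale study conditions

Full-protocol runs (9-mer BCRs on 100+-residue antigens, 5×10⁶ steps,
21 days) cost CPU-hours per antigen. The packaged toy conditions
(`fixtures.toy_config`) shrink every axis while keeping each mechanism in
its operating regime:

| knob | full | toy | why |
|---|---|---|---|
| BCR length L | 9 | 5 | pose count; energies shrink accordingly |
| min_contacts | 1 | 2 | prunes dangling poses at tiny antigen size |
| Emax | −100 | −44 | anchors affinity 1 to the 5-mer energy range |
| founder floor | 1e−4 | 1e−2 | floor founders keep a ~5–10% chance of one capture per LZ sojourn |
| capture_rate | 1.0 | 0.15 | toy affinities are compressed upward; keeps antigen scarce rather than exhausted |
| Hill K (divisions) | 9 | 1.5 | per-sojourn captures are ~5× smaller at the 0.01 h check cadence |
| radius / agents | 160 µm, 250/200/300 | 80 µm, 40/30/40 | tenth-scale cell population |
| dt / capture cadence | 1e−4 / 1e−3 h | 0.01 / 0.01 h | trajectories are robust to coarsening (tested) |
| horizon | 21 d | 8 d | the toy GC's full rise-and-contraction arc |

Each scaled value keeps a dimensionless ratio from the full protocol
(expected floor-founder captures per sojourn, captured units at
half-saturation of the division map, antigen scarcity during the
selection phase). With these conditions the package reproduces,
directionally and with seed replication, the headline phenomenology:
higher-immunogenicity antigens yield larger GCs and higher matured
affinity; a two-domain GC's volume trajectory tracks the dominant domain
(compared over the 96 h influx/growth phase, since the toy GC's post-peak
phase is dominated by exhaustion timing); halving a single antigen's dose
raises end-run affinity; and adding low-immunogenicity domains at constant
total dose shrinks the peak GC.

**What the toy conditions do not show.** Absolute energies, affinities,
pose counts and class labels at L = 5 are not comparable to the 9-mer
protocol (classes A–H are defined on the full scale only). Synthetic
compact antigens lack the surface topology of discretized real proteins,
so topological effects (cryptic epitopes, structure-specific
immunogenicity differences between scaffolds) are out of reach of the
tests. Cross-reactivity at L = 5 is much stronger than at L = 9 — the
valency experiments therefore place extra domains on distinct structures.
Trend checks are directional, not quantitative, reproductions.

## Numerical choices and degenerate inputs

- Pose enumeration is exact (no sampling); the pruning bound is
  admissible, so no valid pose is lost.
- Equal-energy poses resolve to the smallest enumeration index; profile
  representatives carry the smallest member pose index, which preserves
  that rule under deduplication.
- The truncated-normal cycle sampler redraws non-positive values
  (truncation shifts the mean by ~1e−8 of an SD at the defaults).
- Empty GC snapshots report NaN affinity means and zero counts; the
  empty founder pool, an unbindable antigen (no pose at min_contacts), a
  non-divisible pool total (floor division with a logged warning), and a
  non-positive rate in a config file all fail fast with named errors.
- Division waits when no free neighbor node exists (space-limited
  growth); founders bounce if the GC is completely full.
- ASC differentiation and antibody accrual are deterministic compartments
  (expected-value updates), not per-cell stochastic events.

## Known limitations

Antibody feedback / epitope masking, per-domain Tfh specificity,
affinity-dependent mutation rates, chemokine receptor desensitization,
glycan effects, and memory re-entry beyond injected founder sequences are
all outside scope. The division-number map and the chemokine-field
construction are documented stand-ins where the underlying protocol is
unpublished. PDB discretization is delegated to external tools; the
text importer accepts their output.
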