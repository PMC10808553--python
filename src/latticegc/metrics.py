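"""Observables of a GC run: volume, affinities, diversity, SHM load,
per-cell cross-domain affinity scatters, and the binding-conformation census.

All metrics are pure functions of a simulation state (or of recorded
outputs) and are deterministic given that state. Affinity means are taken
over living GC B cells only.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .docking import energy_to_affinity

__all__ = ["record_snapshot", "affinity_scatter", "conformation_census",
           "shm_histogram", "normalize_affinity_to_reference"]


def record_snapshot(state) -> dict:
    """One metrics row: GC size, per-domain and max-over-domain mean
    affinity, sequence diversity, cumulative outputs and antibody pools.
    Means over an empty GC are reported as NaN."""
    bc = state.bcells
    alive = bc.indices()
    row = {"time_h": state.time_h, "n_bcells": int(len(alive))}
    ids = bc.seq_id[alive]
    if len(alive):
        affs = state.registry.affinities(ids)
        for k, ag in enumerate(state.antigens.domains):
            row[f"mean_affinity_{ag.identity}"] = float(affs[:, k].mean())
        row["mean_affinity_max_domain"] = float(affs.max(axis=1).mean())
        row["diversity"] = int(len(np.unique(ids)))
    else:
        for ag in state.antigens.domains:
            row[f"mean_affinity_{ag.identity}"] = np.nan
        row["mean_affinity_max_domain"] = np.nan
        row["diversity"] = 0
    row["cumulative_outputs"] = int(state.n_outputs)
    if state.outputs:
        out_ids = np.array([o[1] for o in state.outputs])
        out_aff = state.registry.affinities(out_ids)
        row["mean_output_affinity"] = float(out_aff.max(axis=1).mean())
    else:
        row["mean_output_affinity"] = np.nan
    row["asc"] = float(state.asc)
    row["antibody_mol"] = float(state.antibody_mol)
    # per-domain antigen remaining on FDCs
    for k, ag in enumerate(state.antigens.domains):
        row[f"antigen_on_fdc_{ag.identity}"] = int(state.node_antigen[:, k].sum())
    return row


def affinity_scatter(state, domain_pair: tuple = None,
                     extra_antigens: Sequence = ()) -> pd.DataFrame:
    """Per-cell affinities to a pair of domains at a snapshot (one row per
    living GC B cell). Domains may be named by identity; an antigen absent
    from the simulation can be passed in ``extra_antigens`` and is docked
    on the fly (the cross-reactivity readout for single-antigen runs)."""
    bc = state.bcells
    alive = bc.indices()
    lookup = {ag.identity: ("sim", k) for k, ag in enumerate(state.antigens.domains)}
    for ag in extra_antigens:
        lookup.setdefault(ag.identity, ("extra", ag))
    if domain_pair is None:
        ids = state.antigens.identities[:2]
        if len(ids) < 2:
            raise ValueError("domain_pair required for single-domain runs")
        domain_pair = tuple(ids)
    cols = {}
    seqs = [state.registry.seqs[i] for i in bc.seq_id[alive]]
    params = state.docker.affinity_params
    for name in domain_pair:
        kind, ref = lookup[name]
        if kind == "sim":
            e = state.registry.energies[bc.seq_id[alive], ref]
        else:
            e = state.docker.batch_energies(seqs, ref) if seqs else np.zeros(0)
        cols[f"affinity_{name}"] = energy_to_affinity(e, params) if len(alive) else np.zeros(0)
    df = pd.DataFrame(cols)
    df.insert(0, "cell_id", alive)
    df.insert(1, "time_h", state.time_h)
    return df


def conformation_census(state, domain: int = 0) -> pd.DataFrame:
    """Number of distinct living BCR sequences whose optimal binding pose on
    the given domain is each conformation; counts partition the distinct
    sequences. Returns pose id with its lattice geometry for rendering."""
    bc = state.bcells
    alive = bc.indices()
    uniq_ids = np.unique(bc.seq_id[alive])
    antigen = state.antigens.domains[domain]
    ps = state.docker.pose_set(antigen)
    seqs = [state.registry.seqs[i] for i in uniq_ids]
    if not seqs:
        return pd.DataFrame(columns=["pose_id", "n_sequences", "positions"])
    _, prof = state.docker.batch_binding(seqs, antigen)
    rows = []
    for p, count in zip(*np.unique(prof, return_counts=True)):
        rows.append({"pose_id": int(ps.rep_pose[p]),
                     "n_sequences": int(count),
                     "positions": ps.profile_positions(int(p)).tolist()})
    return pd.DataFrame(rows)


def shm_histogram(outputs: pd.DataFrame, cumulative: bool = False) -> pd.Series:
    """Distribution of mutation counts over output cells, indexed by the
    number of mutations; optionally the cumulative (integral) form."""
    if len(outputs) == 0:
        return pd.Series(dtype=np.int64, name="n_cells")
    counts = outputs["mutations"].value_counts().sort_index()
    counts.name = "n_cells"
    return counts.cumsum() if cumulative else counts


def normalize_affinity_to_reference(series, reference_series) -> np.ndarray:
    """Element-wise ratio of an affinity series to the mean of a reference
    condition (e.g. affinities to domain D in a combination run, normalized
    to the D-alone run)."""
    ref = np.asarray(reference_series, dtype=np.float64)
    ref_mean = np.nanmean(ref)
    if not np.isfinite(ref_mean) or ref_mean == 0:
        raise ValueError("reference series has zero or undefined mean")
    return np.asarray(series, dtype=np.float64) / ref_mean
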