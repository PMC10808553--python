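"""Simulation configuration: defaults, validation, and the flat key=value
config-file format.

Defaults are the reference protocol values: a 5 um cellular lattice, 250 Tfh
cells, 200 FDCs with six 40-um dendrite arms, 300 stromal cells, 1e-4 h time
steps, founder influx of 2 cells/h proliferating 6 times, 7.5 h mean cell
cycle, per-residue SHM probability 0.055 on 9-mer BCRs, 3000 antigen units,
0.7 h antigen search, 3 h Tfh selection window with 0.5 h polarization
requirement, 72% asymmetric antigen division, 24 h output-to-ASC half-life,
3e-8 mol/h antibody secretion, capture floor affinity 1e-8, and the
energy-affinity map Emax = -100 kT, C = 2.8.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO, Union

from .docking import AffinityParams


@dataclass
class GCConfig:
    # --- space ---
    node_size_um: float = 5.0
    gc_radius_um: float = 160.0
    # --- fixed stroma ---
    n_tfh: int = 250
    n_fdc: int = 200
    fdc_arms: int = 6
    arm_length_um: float = 40.0
    n_stromal: int = 300
    # --- time ---
    dt_h: float = 1e-4
    capture_interval_h: float = 0.001
    sim_days: float = 21.0
    snapshot_interval_h: float = 1.0
    # --- founder influx ---
    founder_influx_per_h: float = 2.0
    inflow_duration_h: float = 96.0
    founder_divisions: int = 6
    founder_pool_total: int = 1000
    founder_min_affinity: float = 1e-4
    # --- proliferation & SHM ---
    cycle_mean_h: float = 7.5
    cycle_sd_h: float = 1.25
    shm_p: float = 0.055
    asym_prob: float = 0.72
    div_nmin: int = 1
    div_nmax: int = 6
    div_k: float = 9.0
    div_h: float = 2.0
    # --- antigen & capture ---
    antigen_total: int = 3000
    search_time_h: float = 0.7
    capture_min_affinity: float = 1e-8
    capture_rate: float = 1.0   # capture probability = min(1, capture_rate * Aff)
    # --- Tfh selection ---
    tfh_window_h: float = 3.0
    polarization_required_h: float = 0.5
    contact_duration_h: float = 0.6
    # --- output / antibodies ---
    output_asc_halflife_h: float = 24.0
    ab_rate_mol_per_h: float = 3e-8
    # --- movement ---
    speed_um_min: float = 7.5
    persistence_min: float = 1.5
    chemo_weight: float = 2.0
    # --- affinity model ---
    bcr_length: int = 9
    min_contacts: int = 1
    stabilization: float = 1.0
    emax: float = -100.0
    aff_c: float = 2.8
    aff_mode: str = "strength"
    max_poses: int = 50_000_000
    # --- bookkeeping ---
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ["node_size_um", "gc_radius_um", "dt_h", "capture_interval_h",
                    "sim_days", "snapshot_interval_h", "founder_influx_per_h",
                    "inflow_duration_h", "cycle_mean_h", "cycle_sd_h",
                    "search_time_h", "tfh_window_h", "polarization_required_h",
                    "contact_duration_h", "output_asc_halflife_h",
                    "speed_um_min", "persistence_min", "aff_c", "arm_length_um"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config key {name!r} must be positive, "
                                 f"got {getattr(self, name)}")
        for name in ["n_tfh", "n_fdc", "n_stromal", "fdc_arms",
                     "founder_divisions", "antigen_total", "founder_pool_total"]:
            if getattr(self, name) < 1:
                raise ValueError(f"config key {name!r} must be >= 1")
        if not 0 <= self.asym_prob <= 1:
            raise ValueError("asym_prob must be in [0, 1]")
        if not 0 <= self.shm_p <= 1:
            raise ValueError("shm_p must be in [0, 1]")
        ratio = self.capture_interval_h / self.dt_h
        if abs(ratio - round(ratio)) > 1e-6 or round(ratio) < 1:
            raise ValueError(
                f"dt_h={self.dt_h} must divide capture_interval_h="
                f"{self.capture_interval_h}")

    @property
    def affinity_params(self) -> AffinityParams:
        return AffinityParams(emax=self.emax, c=self.aff_c, mode=self.aff_mode)

    @property
    def radius_nodes(self) -> int:
        return int(round(self.gc_radius_um / self.node_size_um))

    @property
    def capture_every_steps(self) -> int:
        return int(round(self.capture_interval_h / self.dt_h))

    def replace(self, **kwargs) -> "GCConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(GCConfig)}


def _coerce(name: str, raw: str):
    kind = _FIELD_TYPES[name]
    if kind == "int":
        return int(float(raw))
    if kind == "float":
        return float(raw)
    return raw


def load_config(source: Union[str, Path, TextIO]) -> GCConfig:
    """Parse a flat ``key = value`` config file ('#' comments, blank lines
    ignored). Unknown keys are rejected by name; missing keys take the
    reference defaults. An empty file yields the full default config."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    overrides = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        elif ":" in line:
            key, _, val = line.partition(":")
        else:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key = key.strip()
        val = val.strip()
        if key not in _FIELD_TYPES:
            raise ValueError(f"line {lineno}: unknown config key {key!r}")
        try:
            overrides[key] = _coerce(key, val)
        except ValueError:
            raise ValueError(f"line {lineno}: bad value {val!r} for key {key!r}") from None
    return GCConfig(**overrides)


def save_config(config: GCConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write("# latticegc simulation parameters (flat key = value)\n")
        for f in dataclasses.fields(GCConfig):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")
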