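"""Run configuration: one YAML file overriding every tunable default.

The file has one section per stage; any key left out keeps its default.
``default_config_yaml`` emits a fully commented template with the shipped
values, and ``load_config`` merges a user file over the defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .dynamics import DynamicsParams
from .errors import WnsError
from .shaker import FilterParams, ShakerConfig
from .wrapper import WrapperConfig


@dataclasses.dataclass
class WnsConfig:
    wrapper: WrapperConfig = dataclasses.field(default_factory=WrapperConfig)
    shaker: ShakerConfig = dataclasses.field(default_factory=ShakerConfig)


def _update_dataclass(obj, data: dict, path: str) -> None:
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise WnsError(f"unknown config key {path}{key}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value, f"{path}{key}.")
        else:
            setattr(obj, key, type(current)(value) if current is not None else value)


def load_config(path: str | Path | None = None) -> WnsConfig:
    """Defaults, optionally overridden by a YAML file."""
    cfg = WnsConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise WnsError("config file must be a mapping of sections")
    for section, value in data.items():
        if section == "wrapper":
            _update_dataclass(cfg.wrapper, value, "wrapper.")
        elif section == "shaker":
            _update_dataclass(cfg.shaker, value, "shaker.")
        else:
            raise WnsError(f"unknown config section {section!r}")
    return cfg


def default_config_yaml() -> str:
    """A fully commented config template carrying the shipped defaults."""
    w = WrapperConfig()
    s = ShakerConfig()
    f = FilterParams()
    d = DynamicsParams()
    return f"""\
# Monolayer wrapping and shaking configuration.
# Distances in Angstrom, energies in kcal/mol unless noted.

wrapper:
  n_runs: {w.n_runs}                  # docked copies per blind-docking cycle
  mc_steps: {w.mc_steps}              # Monte-Carlo steps per docking run
  translation_step: {w.translation_step}        # Gaussian translation proposal scale
  rotation_step: {w.rotation_step}           # Gaussian rotation proposal scale, degrees
  mc_temperature: {w.mc_temperature}           # Metropolis kT
  dielectric: {w.dielectric}
  cluster_rmsd_tol: {w.cluster_rmsd_tol}         # per-cycle pose clustering tolerance
  interface_tolerance: {w.interface_tolerance}      # target atoms this close to a copy are excluded
  asa_exit_fraction: {w.asa_exit_fraction}       # stop when uncovered surface drops below this
  trim_distance: {w.trim_distance}            # drop copies farther than this from the target
  max_cycles: {w.max_cycles}
  retain: {w.retain}        # "representatives" or "all" poses per cycle
  exclusion_enabled: {str(w.exclusion_enabled).lower()}        # false = control mode without repulsion
  clash_distance: {w.clash_distance}           # candidate vs excluded-zone screen
  overlap_distance: {w.overlap_distance}         # candidate vs retained-copy screen
  r_x: {w.r_x}                      # excluded-type pair distance (see calibrate)
  eps_x: {w.eps_x}                 # excluded-type well depth
  asa_n_points: {w.asa_n_points}              # Shrake-Rupley sphere points
  asa_probe: {w.asa_probe}

shaker:
  ec_s_threshold: {s.ec_s_threshold}          # stop once this fraction of copies is eliminated
  max_bsa_cycles: {s.max_bsa_cycles}
  cluster_dist_limit: {s.cluster_dist_limit}        # final clustering distance limit (6.0 = wide variant)
  cluster_metric: {s.cluster_metric}       # "centroid" or "rmsd"
  final_rank_key: {s.final_rank_key}         # "e_lj" or "e_lj+e_coulomb"
  skip_md_b: {str(s.skip_md_b).lower()}
  skip_md_bsa: {str(s.skip_md_bsa).lower()}
  run_md_f: {str(s.run_md_f).lower()}
  steps_per_ns: {s.steps_per_ns}           # toy-step equivalent of 1 ns
  mw_cutoff: {s.mw_cutoff}             # annealing ceiling switches at this ligand MW
  high_temp_at_boundary: {str(s.high_temp_at_boundary).lower()}   # MW exactly at the cutoff: take 80 C
  filters:
    d_diss: {f.d_diss}                # final-frame dissociation distance
    d_drift: {f.d_drift}               # sustained centroid-drift threshold
    e_mean_cap: {f.e_mean_cap}           # windowed mean E_LJ must stay below this
    window_frac: {f.window_frac}           # trailing window for the drift/energy screens
  dynamics:
    dt: {d.dt}
    gamma: {d.gamma}
    gamma_rot: {d.gamma_rot}
    tether_k: {d.tether_k}
    noise: {str(d.noise).lower()}
    dielectric: {d.dielectric}
    max_step_displacement: {d.max_step_displacement}
    cc_force_clamp: {d.cc_force_clamp}
"""
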