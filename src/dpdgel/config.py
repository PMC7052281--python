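"""Run configuration: one flat, YAML-serialisable record of every knob.

Defaults are the study conditions: 80% water, precursor mass ratio
AAm:MBAA = 1:0.002, crosslinking at kT = 9 with the soft bond (C = 4),
tension at kT = 1 with the stiff bond (C = 116,000, dt = 0.001).
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    # mixture
    total_beads: int = 125_000
    water_fraction: float = 0.80
    mass_ratio: float = 0.002
    box_density: float = float(np.sqrt(2.0))
    chi: float = 0.57
    rho_for_a: float = 2.0
    # thermostat / integration
    sigma: float = 3.0
    dt: float = 0.01
    seed: int = 0
    # crosslinking schedule
    cross_temperature: float = 9.0
    relax_steps: int = 10_000
    bond_attempt_interval: int = 10
    crosslink_steps: int = 500_000
    bond_cutoff: float = 1.0
    cool_steps: int = 100_000
    final_relax_steps: int = 100_000
    soft_bond_C: float = 4.0
    # tension
    tension_bond_C: float = 116_000.0
    tension_dt: float = 0.001
    loading_rate: float = 0.001
    max_stretch: float = 4.0
    sample_every: int = 200
    # transport mapping
    n_m: int = 8
    r_cut_real_m: float = 6.98e-10
    d_water_real_m2_s: float = 2.43e-9
    # output
    out_dir: str = "."
    thin_every: int = 100

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        """Load from a YAML path or string; unknown keys are rejected."""
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        if data is None:
            data = {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Short stable digest embedded in output files for provenance."""
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]

    def replace(self, **changes) -> "RunConfig":
        import dataclasses

        return dataclasses.replace(self, **changes)
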