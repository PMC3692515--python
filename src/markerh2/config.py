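"""Simulation and experiment configuration.

The default values reproduce the study conditions of the simulation
experiment: constant-size populations of N = 500 hermaphroditic diploids,
non-overlapping generations, 10 generations of either random mating (S = 0)
or 90% selfing (S = 0.9), a purely additive trait controlled by 500 unlinked
QTLs with five alleles each, SNP panels of 384-5000 unlinked biallelic
markers, target heritabilities 0.15 / 0.3 / 0.6, and 20 replicates per
parameter combination.
"""

from __future__ import annotations

import dataclasses
import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "SimulationConfig",
    "ExperimentGrid",
    "load_config",
    "save_config",
    "cell_seed",
]


class ConfigError(ValueError):
    """Raised when a configuration file violates a parameter invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one forward-in-time simulation replicate set.

    Attributes
    ----------
    N : population size, constant across generations.
    S : per-offspring selfing probability in [0, 1].
    n_generations : generations simulated after the founders (analyses are
        run on the final generation).
    L_M : number of biallelic marker (SNP) loci.
    L_QTL : number of causal loci.
    n_qtl_alleles : alleles segregating per causal locus in the founders.
    target_h2 : narrow-sense heritability calibrated in the founder
        generation, in (0, 1).
    theta : Dirichlet/Beta concentration for founder allele frequencies
        (mutation-drift equilibrium shape).
    seed : base RNG seed; replicate r uses seed + r.
    n_replicates : replicates per parameter combination.
    """

    N: int = 500
    S: float = 0.0
    n_generations: int = 10
    L_M: int = 1500
    L_QTL: int = 500
    n_qtl_alleles: int = 5
    target_h2: float = 0.3
    theta: float = 0.2
    seed: int = 0
    n_replicates: int = 20

    def __post_init__(self) -> None:
        problems = []
        if self.N <= 0:
            problems.append(f"N must be positive (got {self.N})")
        if not 0.0 <= self.S <= 1.0:
            problems.append(f"S must be in [0, 1] (got {self.S})")
        if self.n_generations < 0:
            problems.append("n_generations must be >= 0")
        if self.L_M < 1 or self.L_QTL < 1:
            problems.append("L_M and L_QTL must be >= 1")
        if self.n_qtl_alleles < 2:
            problems.append("n_qtl_alleles must be >= 2")
        if not 0.0 < self.target_h2 < 1.0:
            problems.append(f"target_h2 must be in (0, 1) (got {self.target_h2})")
        if self.theta <= 0:
            problems.append(f"theta must be positive (got {self.theta})")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if problems:
            raise ConfigError("; ".join(problems))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = repr(sorted(self.to_dict().items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class ExperimentGrid:
    """Grid of simulation cells for the replicated experiments."""

    selfing_rates: tuple = (0.0, 0.9)
    heritabilities: tuple = (0.15, 0.3, 0.6)
    panel_sizes: tuple = (384, 1500, 3000, 5000)
    population_sizes: tuple = (500,)
    n_replicates: int = 20
    base: SimulationConfig = field(default_factory=SimulationConfig)

    def cells(self):
        """Yield one SimulationConfig per (N, S, h2, L_M) combination."""
        for N in self.population_sizes:
            for S in self.selfing_rates:
                for h2 in self.heritabilities:
                    for L_M in self.panel_sizes:
                        yield self.base.replace(
                            N=N,
                            S=S,
                            target_h2=h2,
                            L_M=L_M,
                            n_replicates=self.n_replicates,
                        )


_GRID_KEYS = {
    "selfing_rates",
    "heritabilities",
    "panel_sizes",
    "population_sizes",
    "n_replicates",
}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path: str | Path) -> tuple[SimulationConfig, ExperimentGrid]:
    """Read a YAML config; missing keys fall back to the study defaults.

    An empty file yields the full default grid. Unknown keys raise
    ConfigError listing the offending fields.
    """
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(data) - _SIM_KEYS - _GRID_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    sim_kwargs = {k: v for k, v in data.items() if k in _SIM_KEYS}
    try:
        sim = SimulationConfig(**sim_kwargs)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    grid_kwargs = {
        k: (tuple(v) if isinstance(v, Sequence) else v)
        for k, v in data.items()
        if k in _GRID_KEYS
    }
    if "n_replicates" in data:
        grid_kwargs["n_replicates"] = int(data["n_replicates"])
    grid = ExperimentGrid(base=sim, **grid_kwargs)
    return sim, grid


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def cell_seed(experiment_seed: int, **coords) -> int:
    """Deterministic per-cell seed from the experiment seed and coordinates.

    Hashes the canonical string of the sorted coordinates with CRC32 so that
    every grid cell receives an independent, reproducible stream. Kept below
    2**31 for portability.
    """
    label = ";".join(f"{k}={coords[k]!r}" for k in sorted(coords))
    crc = zlib.crc32(label.encode())
    return (int(experiment_seed) * 2654435761 + crc) % (2**31 - 1)
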