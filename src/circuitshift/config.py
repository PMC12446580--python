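"""Experiment plans: configuration, validation and seed bookkeeping.

An :class:`ExperimentPlan` enumerates every solver run the pipeline will
perform — one per species x climate scenario (15 species x 3 scenarios =
45 runs in the full design) — together with the solver settings (number
of perimeter nodes, buffer fraction) and SDM settings (pseudo-absence
ratio, fold count, ROC retention threshold, decile cut).

A single master seed expands deterministically into per-stage,
per-species sub-seeds via ``numpy.random.SeedSequence`` spawning keyed on
(stage name, species index), so any stage can be rerun in isolation and
reproduce its part of a full run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .resistance import ALLOWED_EXPONENTS, SpeciesMovementProfile

__all__ = ["ExperimentPlan", "SpeciesSpec", "load_config", "subseed"]

DEFAULTS = {
    "n_nodes": 25,
    "buffer_fraction": 0.20,
    "decile": 0.9,
    "pa_ratio": 3,
    "roc_retention": 0.70,
    "n_blocks": 40,
    "n_folds": 5,
}

STAGES = ("sdm", "resistance", "circuit", "network", "zonal")


def subseed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic sub-seed for a stage (and optional species index).

    Always below 2**31 so it is safe for every RNG consumer.
    """
    import zlib

    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode()) % (2**31), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SpeciesSpec:
    """One species: identifier plus movement profile (resistance exponent)."""

    species_id: str
    exponent: float

    def profile(self) -> SpeciesMovementProfile:
        return SpeciesMovementProfile(species_id=self.species_id, c=self.exponent)


@dataclass
class ExperimentPlan:
    """Fully validated run plan for the connectivity pipeline."""

    species: list[SpeciesSpec]
    scenarios: list[str]
    reference_scenario: str = "current"
    n_nodes: int = DEFAULTS["n_nodes"]
    buffer_fraction: float = DEFAULTS["buffer_fraction"]
    decile: float = DEFAULTS["decile"]
    pa_ratio: int = DEFAULTS["pa_ratio"]
    roc_retention: float = DEFAULTS["roc_retention"]
    n_blocks: int = DEFAULTS["n_blocks"]
    n_folds: int = DEFAULTS["n_folds"]
    seed: int = 0
    out_dir: Path = field(default_factory=lambda: Path("runs"))

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("plan needs at least one species")
        if not self.scenarios:
            raise ValueError("plan needs at least one scenario")
        if self.reference_scenario not in self.scenarios:
            raise ValueError(
                f"reference scenario {self.reference_scenario!r} not in scenarios {self.scenarios}"
            )
        if self.scenarios[0] != self.reference_scenario:
            raise ValueError("the reference scenario must be listed first")
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids")
        for sp in self.species:
            if sp.exponent not in ALLOWED_EXPONENTS:
                raise ValueError(
                    f"species {sp.species_id!r}: exponent {sp.exponent} not in allowed set {ALLOWED_EXPONENTS}"
                )
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")

    @property
    def n_runs(self) -> int:
        """Solver runs: one per species x scenario."""
        return len(self.species) * len(self.scenarios)

    @property
    def n_pairs_per_run(self) -> int:
        """Pairwise solves per run: C(n_nodes, 2)."""
        return self.n_nodes * (self.n_nodes - 1) // 2

    def runs(self) -> list[tuple[str, str]]:
        """All (species_id, scenario) run labels, species-major order."""
        return [(sp.species_id, sc) for sp in self.species for sc in self.scenarios]

    def stage_seed(self, stage: str, index: int = 0) -> int:
        return subseed(self.seed, stage, index)


def load_config(path: str | Path) -> ExperimentPlan:
    """Load and validate a YAML experiment plan.

    Minimal schema::

        species:
          - id: hedgehog
            exponent: 4
        scenarios: [current, y2050, y2090]
        reference_scenario: current   # optional; default 'current'
        n_nodes: 25                   # optional; defaults as documented
        seed: 0
        out_dir: runs

    Unknown solver settings fall back to the documented defaults.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if "species" not in raw or not raw["species"]:
        raise ValueError("config must list at least one species")
    if "scenarios" not in raw or not raw["scenarios"]:
        raise ValueError("config must list at least one scenario")
    species = [
        SpeciesSpec(species_id=str(item["id"]), exponent=float(item["exponent"]))
        for item in raw["species"]
    ]
    kwargs = {k: raw[k] for k in DEFAULTS if k in raw}
    return ExperimentPlan(
        species=species,
        scenarios=[str(s) for s in raw["scenarios"]],
        reference_scenario=str(raw.get("reference_scenario", raw["scenarios"][0])),
        seed=int(raw.get("seed", 0)),
        out_dir=Path(raw.get("out_dir", "runs")),
        **kwargs,
    )
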