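"""End-to-end orchestration: synthetic inputs -> SDM -> resistance -> circuit -> network -> zonal.

:func:`run_pipeline` executes the five analysis stages of an
:class:`~circuitshift.config.ExperimentPlan` on a generated landscape and
writes every declared artefact (ASCII-grid rasters, CSV tables, a JSON
manifest with seeds and per-file checksums) under the plan's output
directory.  Rerunning with the same seeds reproduces every output
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circuit as ct
from . import network as net
from . import sdm, synthetic, zonal
from .config import ExperimentPlan
from .occurrences import OccurrenceSet
from .raster import Raster, RasterStack, write_ascii
from .resistance import suitability_to_resistance

__all__ = ["run_pipeline", "simulate_inputs", "PipelineError", "SimulatedInputs"]

#: additive climate shift per scenario position (reference first); emulates
#: progressive warming between the reference period and the two futures
SCENARIO_SHIFT_STEP = 1.5


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class SimulatedInputs:
    """Everything the analysis stages consume, generated from one seed."""

    scenario_stacks: dict[str, RasterStack]
    occurrences: dict[str, OccurrenceSet]
    true_models: dict[str, synthetic.TrueModel]
    landcover: Raster
    zones: Raster
    protected: Raster
    grid: Raster


def simulate_inputs(
    plan: ExperimentPlan,
    n_rows: int = 48,
    n_cols: int = 48,
    n_climate: int = 3,
    n_presence: int = 150,
    cell_size: float = 1000.0,
) -> SimulatedInputs:
    """Generate co-registered synthetic inputs for every species and scenario.

    Climate layers get an additive shift of ``SCENARIO_SHIFT_STEP`` per
    scenario step beyond the reference; static layers (distance to linear
    features, topographic position) are shared across scenarios.  Each
    species' occurrences are sampled from its own random ground-truth
    logistic model evaluated on the reference-scenario predictors.
    """
    seed = plan.stage_seed("simulate")
    rng = np.random.default_rng(seed)

    # static layers
    dem_field = synthetic.smooth_field(n_rows, n_cols, rng) * 100.0
    dem = Raster(dem_field, cell_size=cell_size)
    lines = synthetic.gen_linear_features(n_rows, n_cols, 3, seed=seed + 1, cell_size=cell_size)
    from .predictors import grid_distance, tpi

    static_layers = [grid_distance(lines), tpi(dem, 2)]
    static_names = ["dist_linear", "tpi"]

    scenario_stacks: dict[str, RasterStack] = {}
    for k, scen in enumerate(plan.scenarios):
        climate = synthetic.gen_climate_stack(
            n_rows, n_cols, n_climate, scenario_shift=k * SCENARIO_SHIFT_STEP, seed=seed + 2, cell_size=cell_size
        )
        scenario_stacks[scen] = RasterStack(
            list(climate.layers) + static_layers, list(climate.names) + static_names
        )

    ref_stack = scenario_stacks[plan.reference_scenario]
    n_layers = len(ref_stack)
    occurrences: dict[str, OccurrenceSet] = {}
    true_models: dict[str, synthetic.TrueModel] = {}
    for i, sp in enumerate(plan.species):
        coefs = np.zeros(n_layers + 1)
        coefs[0] = -1.0
        coefs[1 : n_climate + 1] = rng.normal(0, 1.5, size=n_climate)
        coefs[n_climate + 1 :] = rng.normal(0, 0.02, size=n_layers - n_climate)
        model = synthetic.TrueModel(coefs)
        true_models[sp.species_id] = model
        occurrences[sp.species_id] = synthetic.gen_occurrences(
            model, ref_stack, n_presence, seed=seed + 100 + i
        )

    landcover = synthetic.gen_landcover(n_rows, n_cols, 6, seed=seed + 3, cell_size=cell_size)
    zones = synthetic.gen_zones(n_rows, n_cols, 8, seed=seed + 4, cell_size=cell_size)
    protected = synthetic.gen_protected_mask(n_rows, n_cols, 0.13, seed=seed + 5, cell_size=cell_size)
    return SimulatedInputs(
        scenario_stacks=scenario_stacks,
        occurrences=occurrences,
        true_models=true_models,
        landcover=landcover,
        zones=zones,
        protected=protected,
        grid=ref_stack.geometry,
    )


# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class _Manifest:
    seed: int
    stages: list[str] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)

    def record(self, out_dir: Path, path: Path) -> None:
        self.files[str(path.relative_to(out_dir))] = _sha256(path)

    def write(self, out_dir: Path) -> None:
        payload = {"seed": self.seed, "stages_completed": self.stages, "checksums": self.files}
        (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _fit_species_ensemble(
    plan: ExperimentPlan, occ: OccurrenceSet, stack: RasterStack, species_seed: int
) -> tuple[sdm.EnsembleModel, pd.DataFrame, dict[str, tuple[float, float]]]:
    grid = stack.geometry
    pres = sdm.grid_records(occ, grid)
    absn = sdm.sample_pseudo_absences(pres, grid, ratio=plan.pa_ratio, seed=species_seed)
    records = pres.concat(absn)
    folds = sdm.assign_spatial_blocks(
        records, grid.extent, n_blocks=plan.n_blocks, n_folds=plan.n_folds, seed=species_seed + 1
    )
    records = records.with_fold(folds.fold_id)

    members: list[tuple[sdm.FittedLearner, sdm.EvaluationScores]] = []
    report_rows = []
    for fold in sorted(set(folds.fold_id)):
        train = OccurrenceSet(records.frame[records.fold != fold])
        test = OccurrenceSet(records.frame[records.fold == fold])
        if len(np.unique(train.presence)) < 2 or len(np.unique(test.presence)) < 2:
            continue
        learner = sdm.fit_logistic(train, stack, quadratic=True)
        X, ok = sdm.extract_predictors(test, stack)
        scores = sdm.evaluate(learner.predict(X[ok]), test.presence[ok])
        members.append((learner, scores))
        report_rows.append(
            {"learner": "glm", "fold": int(fold), "tss": scores.tss, "roc_auc": scores.roc_auc, "threshold": scores.best_threshold}
        )
    if not members:
        raise ValueError("no fold produced a usable train/test split")
    ensemble = sdm.EnsembleModel(members=members, retention_rule=plan.roc_retention, mode="committee")
    if not ensemble.retained():
        # no member cleared the ROC bar: keep the best one so projection stays defined
        best = max(members, key=lambda m: m[1].roc_auc)
        ensemble = sdm.EnsembleModel(members=[best], retention_rule=0.0, mode="committee")

    X_all, ok_all = sdm.extract_predictors(records, stack)
    ranges = {
        name: (float(np.min(X_all[ok_all, k])), float(np.max(X_all[ok_all, k])))
        for k, name in enumerate(stack.names)
    }
    return ensemble, pd.DataFrame(report_rows), ranges


def run_pipeline(
    plan: ExperimentPlan,
    *,
    n_rows: int = 48,
    n_cols: int = 48,
    n_climate: int = 3,
    n_presence: int = 150,
    inputs: SimulatedInputs | None = None,
) -> Path:
    """Run the full analysis and return the artefact directory.

    ``inputs`` may be supplied to run on pre-generated (or user) data;
    otherwise the landscape is simulated from the plan's seed.
    """
    out_dir = Path(plan.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(seed=plan.seed)

    if inputs is None:
        inputs = simulate_inputs(plan, n_rows=n_rows, n_cols=n_cols, n_climate=n_climate, n_presence=n_presence)

    # -- stage 1: sdm ------------------------------------------------------
    stage = "sdm"
    suitability: dict[tuple[str, str], Raster] = {}
    try:
        reports = []
        for i, sp in enumerate(plan.species):
            seed_i = plan.stage_seed("sdm", i)
            ref_stack = inputs.scenario_stacks[plan.reference_scenario]
            ensemble, report, ranges = _fit_species_ensemble(
                plan, inputs.occurrences[sp.species_id], ref_stack, seed_i
            )
            report.insert(0, "species", sp.species_id)
            reports.append(report)
            climate_ranges = {n: ranges[n] for n in ranges if n.startswith("bio")}
            for scen in plan.scenarios:
                stack = inputs.scenario_stacks[scen]
                surf = sdm.project(ensemble, stack)
                suitability[(sp.species_id, scen)] = surf
                write_ascii(surf, out_dir / f"{sp.species_id}_{scen}_suitability.asc")
                mess = sdm.mess_count(climate_ranges, stack)
                write_ascii(mess, out_dir / f"{sp.species_id}_{scen}_mess.asc")
        pd.concat(reports, ignore_index=True).to_csv(out_dir / "sdm_evaluation.csv", index=False)
        for f in out_dir.glob("*.asc"):
            manifest.record(out_dir, f)
        manifest.record(out_dir, out_dir / "sdm_evaluation.csv")
        manifest.stages.append(stage)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        manifest.write(out_dir)
        raise PipelineError(stage, str(exc)) from exc

    # -- stage 2: resistance ----------------------------------------------
    stage = "resistance"
    resist: dict[tuple[str, str], Raster] = {}
    try:
        for sp in plan.species:
            profile = sp.profile()
            for scen in plan.scenarios:
                r = suitability_to_resistance(suitability[(sp.species_id, scen)], profile)
                resist[(sp.species_id, scen)] = r
                path = out_dir / f"{sp.species_id}_{scen}_resistance.asc"
                write_ascii(r, path)
                manifest.record(out_dir, path)
        manifest.stages.append(stage)
    except Exception as exc:  # noqa: BLE001
        manifest.write(out_dir)
        raise PipelineError(stage, str(exc)) from exc

    # -- stage 3: circuit --------------------------------------------------
    stage = "circuit"
    norm_maps: dict[tuple[str, str], ct.CurrentMap] = {}
    try:
        node_seed = plan.stage_seed("circuit")
        width = None
        nodes = None
        null_map = None
        log_rows = []
        for i, sp in enumerate(plan.species):
            fill_seed = plan.stage_seed("circuit", i + 1)
            for scen in plan.scenarios:
                buffered = ct.add_buffer(resist[(sp.species_id, scen)], plan.buffer_fraction, seed=fill_seed)
                if nodes is None:
                    width = ct.buffer_width(resist[(sp.species_id, scen)], plan.buffer_fraction)
                    nodes = ct.place_nodes(buffered, plan.n_nodes, seed=node_seed)
                    null_map = ct.null_current(buffered.shape, buffered, nodes)
                graph = ct.build_lattice(buffered)
                cur = ct.cumulative_current(graph, nodes)
                norm = ct.null_normalise(cur, buffered.shape, nodes, null=null_map)
                core = ct.crop_buffer(norm, width)
                norm_maps[(sp.species_id, scen)] = core
                raw_core = ct.crop_buffer(cur, width)
                for suffix, cm in (("current", raw_core), ("norm", core)):
                    path = out_dir / f"{sp.species_id}_{scen}_{suffix}.asc"
                    write_ascii(cm.raster, path)
                    manifest.record(out_dir, path)
                log_rows.append(
                    {"species": sp.species_id, "scenario": scen, "n_nodes": len(nodes), "n_pairs": cur.n_pairs}
                )
        pd.DataFrame(log_rows).to_csv(out_dir / "circuit_runs.csv", index=False)
        manifest.record(out_dir, out_dir / "circuit_runs.csv")
        manifest.stages.append(stage)
    except Exception as exc:  # noqa: BLE001
        manifest.write(out_dir)
        raise PipelineError(stage, str(exc)) from exc

    # -- stage 4: network --------------------------------------------------
    stage = "network"
    try:
        if len(plan.scenarios) != 3:
            raise ValueError("network classification requires three scenarios (reference, mid, late)")
        stacked = {
            scen: net.stack_species([norm_maps[(sp.species_id, scen)] for sp in plan.species])
            for scen in plan.scenarios
        }
        reference = stacked[plan.reference_scenario]
        z = {scen: net.relative_standardise(stacked[scen], reference, scenario=scen) for scen in plan.scenarios}
        stats = pd.DataFrame({scen: net.summary_stats(z[scen]).as_series() for scen in plan.scenarios})
        stats.to_csv(out_dir / "scenario_summary_stats.csv")
        corr_rows = []
        for a in range(len(plan.scenarios)):
            for b in range(a + 1, len(plan.scenarios)):
                sa, sb = plan.scenarios[a], plan.scenarios[b]
                corr_rows.append({"a": sa, "b": sb, "pearson_r": net.surface_correlation(z[sa].z, z[sb].z)})
        pd.DataFrame(corr_rows).to_csv(out_dir / "scenario_correlations.csv", index=False)
        masks = {scen: net.top_decile_mask(z[scen], decile=plan.decile) for scen in plan.scenarios}
        classmap = net.classify_network(*(masks[s] for s in plan.scenarios))
        write_ascii(classmap.raster, out_dir / "network_classes.asc")
        (out_dir / "network_legend.json").write_text(json.dumps(classmap.legend(), indent=2))
        for scen in plan.scenarios:
            write_ascii(z[scen].z, out_dir / f"allspecies_{scen}_z.asc")
        for name in ("scenario_summary_stats.csv", "scenario_correlations.csv", "network_classes.asc", "network_legend.json"):
            manifest.record(out_dir, out_dir / name)
        manifest.stages.append(stage)
    except Exception as exc:  # noqa: BLE001
        manifest.write(out_dir)
        raise PipelineError(stage, str(exc)) from exc

    # -- stage 5: zonal ----------------------------------------------------
    stage = "zonal"
    try:
        zone_table = zonal.rank_zones(classmap, inputs.zones)
        zone_table.to_csv(out_dir / "zone_ranking.csv", index=False)
        inside, outside, frac = zonal.protected_overlap(classmap, inputs.protected)
        pd.DataFrame(
            [{"inside_ha": inside, "outside_ha": outside, "inside_fraction": frac}]
        ).to_csv(out_dir / "protected_overlap.csv", index=False)
        tally = zonal.landcover_tally(classmap, inputs.landcover, inputs.protected)
        tally.to_csv(out_dir / "landcover_tally.csv", index=False)
        for name in ("zone_ranking.csv", "protected_overlap.csv", "landcover_tally.csv"):
            manifest.record(out_dir, out_dir / name)
        manifest.stages.append(stage)
    except Exception as exc:  # noqa: BLE001
        manifest.write(out_dir)
        raise PipelineError(stage, str(exc)) from exc

    manifest.write(out_dir)
    return out_dir
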