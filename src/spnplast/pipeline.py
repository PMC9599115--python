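"""End-to-end experiment orchestration.

Four experiment kinds mirror the study designs: ``single_trial`` (one trial
of correlated trains on one mapping), ``variability_sweep`` (10 repeated
trials at several jitter widths, or spike-moving probabilities),
``cluster_sweep`` (single trial repeated over mappings with different
spines-per-cluster and cluster lengths) and ``shuffle_control`` (the cluster
sweep driven by ISI-shuffled trains).  Each run writes tidy CSV tables
(per-trial weight changes, weight-change triggered averages, random-forest
scores) plus a JSON manifest recording the config hash and every derived
seed.

Desk-scale defaults (50 trains for the variability sweep, 100 trains on
2 spines/µm for the cluster sweeps, 5 configs x 5 mapping seeds) keep a full
experiment within minutes on one CPU; the full-scale settings of the study
are plain config values away.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, analysis as an
from .calcium import CalciumParams
from .morphology import ClusterConfig, assign_clusters, build_default_morphology, place_spines
from .neuron import SynapseParams
from .plasticity import PlasticityParams
from .simulation import SimulationConfig, SimResult, SPNSimulation
from .spiketrains import (
    VariabilitySpec,
    build_experiment,
    default_ensemble_spec,
    generate_correlated_trains,
    shuffle_isis,
    write_trains,
)

__all__ = ["ExperimentConfig", "run_experiment", "generate_inputs"]

_KINDS = ("single_trial", "variability_sweep", "cluster_sweep", "shuffle_control")


@dataclass
class ExperimentConfig:
    """Structured configuration of one experiment (YAML round-trippable)."""

    experiment: str = "single_trial"
    seed: int = 1
    out_dir: str = "results"
    # synthetic input ensemble
    n_trains: int = 50
    trial_duration: float = 1.0
    median_rate: float = 4.0
    rate_sigma: float = 0.8
    ramp: bool = True
    ramp_amplitude: float = 2.0
    # trial layout
    n_trials: int = 10
    intertrial_interval: float = 1.0
    lead_in: float = 1.0
    # variability sweep
    variability_kind: str = "jitter"
    sigmas_ms: list = field(default_factory=lambda: [0.0, 10.0, 100.0])
    p_moves: list = field(default_factory=lambda: [0.1, 0.5, 1.0])
    # morphology / spines / clusters
    spine_density: float = 1.0
    cluster_spines: int = 5
    cluster_length: float = 20.0
    cluster_configs: list = field(
        default_factory=lambda: [[1, 0.0], [5, 10.0], [5, 40.0], [10, 20.0], [20, 40.0]]
    )
    n_mapping_seeds: int = 5
    # module parameter overrides (flat dicts applied onto the defaults)
    plasticity: dict = field(default_factory=dict)
    synapse: dict = field(default_factory=dict)
    calcium: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    # analysis
    wcta_bins: int = 7
    time_samples: int = 5
    rf_estimators: int = 500
    neighbor_k: int = 19

    def __post_init__(self):
        if self.experiment not in _KINDS:
            raise ValueError(
                f"unknown experiment kind {self.experiment!r}; expected one of {_KINDS}"
            )

    # -- serialisation --------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _child_seed(root: int, *path: int) -> int:
    return int(np.random.SeedSequence([root, *path]).generate_state(1)[0] % (2**31))


def _build_cell(cfg: ExperimentConfig, seed: int):
    morph = build_default_morphology()
    density = cfg.spine_density
    if cfg.experiment in ("cluster_sweep", "shuffle_control"):
        density = max(density, 2.0)  # clustered input needs dense spines
    spines = place_spines(morph, density, 25.0, seed=_child_seed(seed, 1))
    return morph, spines


def generate_inputs(cfg: ExperimentConfig, seed: int | None = None):
    """The initial trial of correlated excitatory trains."""
    seed = cfg.seed if seed is None else seed
    spec = default_ensemble_spec(
        n_trains=cfg.n_trains,
        trial_duration=cfg.trial_duration,
        seed=_child_seed(seed, 0),
        median_rate=cfg.median_rate,
        rate_sigma=cfg.rate_sigma,
        ramp=cfg.ramp,
        ramp_amplitude=cfg.ramp_amplitude,
    )
    return generate_correlated_trains(spec)


def _sim_for(cfg, morph, spines, mapping, trial_set, seed):
    return SPNSimulation(
        morph,
        spines,
        mapping,
        trial_set,
        synapse=SynapseParams(**cfg.synapse),
        ca_params=CalciumParams(**cfg.calcium) if cfg.calcium else None,
        plasticity=PlasticityParams(**cfg.plasticity),
        config=SimulationConfig(**cfg.simulation),
        seed=seed,
    )


def _weights_table(res: SimResult, extra: dict) -> pd.DataFrame:
    dw = res.per_trial_dw()
    rows = []
    for k, (t0, t1) in enumerate(res.trial_windows):
        w0 = res.weight_at(t0)
        w1 = res.weight_at(t1)
        for j in range(dw.shape[1]):
            rows.append(
                {
                    "spine_id": int(res.spine_index[j]),
                    "train_id": int(res.train_ids[j]),
                    "trial": k,
                    "w_start": w0[j],
                    "w_end": w1[j],
                    "dw": dw[k, j],
                    **extra,
                }
            )
    return pd.DataFrame(rows)


def _trial_series(res: SimResult, trial: int):
    """Calcium rows (synapses x time) restricted to one trial window (µM)."""
    t0, t1 = res.trial_windows[trial]
    sel = (res.t_ms > t0 * 1e3) & (res.t_ms <= t1 * 1e3)
    return res.ca_spine[sel].T, res.t_ms[sel]


def _rate_series(trains, window, grid_step=0.01):
    grid = None
    rows = []
    for tr in trains:
        grid, rate = an.instantaneous_rate(tr.times, window, grid_step=grid_step)
        rows.append(rate)
    return np.asarray(rows), grid


def build_feature_table(
    cfg: ExperimentConfig,
    sim_results: list,
) -> pd.DataFrame:
    """Per-synapse-per-trial feature rows for the weight-change regression.

    Each entry of ``sim_results`` is ``(res, mapping, trial_trains, meta)``;
    rows hold the response dw, five 200 ms time samples of the direct
    presynaptic rate and of spine calcium, five samples of the combined rate
    of the nearest neighbours, cluster length, spines per cluster and the
    synapse's distance to the soma.
    """
    frames = []
    for res, mapping, trial_trains, meta in sim_results:
        dw_trials = res.per_trial_dw()
        dist = mapping.spines.path_distance
        lengths = mapping.realized_cluster_lengths()
        train_lookup = {int(t.train_id): t for t in trial_trains}
        for trial_idx in range(dw_trials.shape[0]):
            window = res.trial_windows[trial_idx]
            ca_rows, _ = _trial_series(res, trial_idx)
            times_by_spine = {}
            for j, sp in enumerate(mapping.spine_ids):
                tr = train_lookup[int(res.train_ids[j])]
                times_by_spine[int(sp)] = tr.times + (
                    window[0] - tr.t_start
                )
            rows = []
            for j, sp in enumerate(mapping.spine_ids):
                _, rate = an.instantaneous_rate(
                    times_by_spine[int(sp)], window
                )
                rate_s = an.time_sample_features(rate, 5)
                ca_s = an.time_sample_features(ca_rows[j], 5)
                _, nrate, _, _ = an.neighbor_combined_rate(
                    int(sp), mapping, times_by_spine, window, k=cfg.neighbor_k
                )
                nbr_s = an.time_sample_features(nrate, 5)
                cid = int(mapping.cluster_ids[j])
                row = {
                    "spine_id": int(sp),
                    "trial": trial_idx,
                    "dw": dw_trials[trial_idx, j],
                    "cluster_length": lengths[cid],
                    "spines_per_cluster": int(
                        np.sum(mapping.cluster_ids == cid)
                    ),
                    "distance_to_soma": dist[int(sp)],
                    **meta,
                }
                for i in range(5):
                    row[f"rate_{i+1}"] = rate_s[i]
                    row[f"ca_{i+1}"] = ca_s[i]
                    row[f"nbr_{i+1}"] = nbr_s[i]
                rows.append(row)
            frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def _wcta_tables(table: pd.DataFrame, n_bins: int):
    """WCTA of the five-sample rate and calcium features (tidy CSV form)."""
    out = {}
    dw = table["dw"].to_numpy()
    for name, cols in (
        ("rate", [f"rate_{i+1}" for i in range(5)]),
        ("calcium", [f"ca_{i+1}" for i in range(5)]),
    ):
        series = table[cols].to_numpy()
        res = an.weight_change_triggered_average(
            dw, series, t=np.arange(5) * 0.2 + 0.1, n_bins=n_bins
        )
        rows = []
        for b in range(res.n_bins):
            for ti, tv in enumerate(res.t):
                rows.append(
                    {
                        "bin": b,
                        "lo": res.edges[b],
                        "hi": res.edges[b + 1],
                        "t_s": tv,
                        "mean": res.means[b, ti],
                        "n": int(res.counts[b]),
                    }
                )
        out[name] = pd.DataFrame(rows)
    return out


def _rf_tables(cfg: ExperimentConfig, table: pd.DataFrame, seed: int):
    """The regression panel: calcium samples, rate samples, rate + spatial."""
    specs = {
        "ca_1": ["ca_1"],
        "ca_3": ["ca_2", "ca_4", "ca_5"],
        "ca_5": [f"ca_{i+1}" for i in range(5)],
        "rate_1": ["rate_1"],
        "rate_5": [f"rate_{i+1}" for i in range(5)],
        "rate_1+cluster_length": ["rate_1", "cluster_length"],
        "rate_5+cluster_length": [f"rate_{i+1}" for i in range(5)] + ["cluster_length"],
        "rate_1+spines_per_cluster": ["rate_1", "spines_per_cluster"],
        "rate_1+distance": ["rate_1", "distance_to_soma"],
    }
    rows = []
    for si, (name, feats) in enumerate(specs.items()):
        rf = an.rf_predict(
            table,
            feats,
            seed=_child_seed(seed, 7, si),
            n_estimators=cfg.rf_estimators,
        )
        for i, (r2, r2t) in enumerate(zip(rf.r2, rf.r2_train)):
            rows.append(
                {"feature_set": name, "split": i, "r2_test": r2, "r2_train": r2t}
            )
    return pd.DataFrame(rows)


def run_experiment(
    cfg: ExperimentConfig,
    seed: int | None = None,
    out_dir=None,
    initial_trains: list | None = None,
) -> dict:
    """Execute one configured experiment and write its result bundle.

    Returns a dict of the output DataFrames plus the manifest.  Stage
    failures raise with the stage name in the message.
    """
    seed = cfg.seed if seed is None else seed
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    def stage(name, fn, *a, **k):
        try:
            return fn(*a, **k)
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"stage '{name}' failed: {e}") from e

    morph, spines = stage("build_cell", _build_cell, cfg, seed)
    trains = (
        initial_trains
        if initial_trains is not None
        else stage("generate_inputs", generate_inputs, cfg, seed)
    )
    write_trains(out / "initial_trial.tsv", trains)

    results = {}
    sim_bundles = []
    weights_frames = []

    if cfg.experiment in ("single_trial", "variability_sweep"):
        train_ids = np.arange(cfg.n_trains)
        mapping = stage(
            "assign_clusters",
            assign_clusters,
            spines,
            train_ids,
            ClusterConfig(cfg.cluster_spines, cfg.cluster_length),
            seed=_child_seed(seed, 2),
        )
        if cfg.experiment == "single_trial":
            levels = [("none", 0.0)]
        elif cfg.variability_kind == "move":
            levels = [("move", p) for p in cfg.p_moves]
        else:
            levels = [("jitter", s / 1e3) for s in cfg.sigmas_ms]
        n_trials = 1 if cfg.experiment == "single_trial" else cfg.n_trials
        for li, (kind, level) in enumerate(levels):
            if kind == "none" or level == 0.0:
                var = None
            elif kind == "jitter":
                var = VariabilitySpec("jitter", sigma=level, seed=0)
            else:
                var = VariabilitySpec("move", p_move=level, seed=0)
            ts = stage(
                "build_experiment",
                build_experiment,
                trains,
                n_trials,
                cfg.intertrial_interval,
                var,
                seed=_child_seed(seed, 3, li),
                lead_in=cfg.lead_in,
            )
            sim = _sim_for(cfg, morph, spines, mapping, ts, _child_seed(seed, 4, li))
            res = stage("simulate", sim.run)
            meta = {"variability_kind": kind, "level": level, "mapping_id": 0}
            weights_frames.append(_weights_table(res, meta))
            sim_bundles.append((res, mapping, trains, meta))

    else:  # cluster_sweep / shuffle_control
        work_trains = trains
        if cfg.experiment == "shuffle_control":
            ss = np.random.SeedSequence([seed, 5]).spawn(len(trains))
            work_trains = [
                shuffle_isis(tr, int(s.generate_state(1)[0] % (2**31)))
                for tr, s in zip(trains, ss)
            ]
            write_trains(out / "shuffled_trial.tsv", work_trains)
        ts = stage(
            "build_experiment",
            build_experiment,
            work_trains,
            1,
            cfg.intertrial_interval,
            None,
            seed=_child_seed(seed, 3),
            lead_in=cfg.lead_in,
        )
        train_ids = np.arange(cfg.n_trains)
        mid = 0
        for ci, (spc, clen) in enumerate(cfg.cluster_configs):
            for mi in range(cfg.n_mapping_seeds):
                mapping = stage(
                    "assign_clusters",
                    assign_clusters,
                    spines,
                    train_ids,
                    ClusterConfig(int(spc), float(clen)),
                    seed=_child_seed(seed, 2, ci, mi),
                )
                sim = _sim_for(
                    cfg, morph, spines, mapping, ts, _child_seed(seed, 4, ci, mi)
                )
                res = stage("simulate", sim.run)
                meta = {
                    "mapping_id": mid,
                    "spc_config": int(spc),
                    "cluster_length_config": float(clen),
                }
                weights_frames.append(_weights_table(res, meta))
                sim_bundles.append((res, mapping, work_trains, meta))
                mid += 1

    weights = pd.concat(weights_frames, ignore_index=True)
    weights.to_csv(out / "weights.csv", index=False)
    results["weights"] = weights

    table = stage("build_feature_table", build_feature_table, cfg, sim_bundles)
    table.to_csv(out / "features.csv", index=False)
    results["features"] = table

    wcta = stage("wcta", _wcta_tables, table, cfg.wcta_bins)
    for name, df in wcta.items():
        df.to_csv(out / f"wcta_{name}.csv", index=False)
        results[f"wcta_{name}"] = df

    if len(table) >= 50 and table["dw"].nunique() > 1:
        rf = stage("rf_predict", _rf_tables, cfg, table, seed)
        rf.to_csv(out / "rf_scores.csv", index=False)
        results["rf_scores"] = rf

    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "root_seed": seed,
        "experiment": cfg.experiment,
        "n_simulations": len(sim_bundles),
        "elapsed_s": round(time.time() - t_start, 2),
        "config": asdict(cfg),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
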