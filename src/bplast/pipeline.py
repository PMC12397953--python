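"""End-to-end orchestration: tracks -> metrics -> features -> clusters -> arcs.

Each stage writes its tabular outputs and a provenance record into the
output directory; ``resume`` re-runs from a named stage when the
configuration of the upstream stages is unchanged (verified by per-stage
config hashes).  All randomness fans out deterministically from a single
master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior_space as bs
from . import entropy_arcs as ea
from . import wavelets as wv
from .io_tracks import TankPolygon, Trajectory, check_inside, equilateral_tank, fill_gaps, read_tracks
from .metrics import IntervalSpec, METRICS, coefficient_of_variation, compute_metrics, metrics_frame

log = logging.getLogger(__name__)

STAGES = ("metrics", "features", "cluster", "entropy", "arcs")


@dataclass
class PipelineConfig:
    """Everything needed to run the analysis once, reproducibly."""

    out_dir: str
    tracks_path: str | None = None
    tank: TankPolygon = field(default_factory=equilateral_tank)
    interval_kind: str = "hour"
    seconds_per_hour: float = 3600.0
    hours_per_day: int = 8
    k: int = 20
    method: str = "watershed"          # or "kmeans"
    n_wavelets: int = 25
    f_min: float = 0.01
    f_max: float = 2.5
    omega0: float = 5.0
    sample_fraction: float = bs.DEFAULT_SAMPLE_FRACTION
    n_neighbors: int = bs.DEFAULT_N_NEIGHBORS
    min_dist: float = bs.DEFAULT_MIN_DIST
    grid: int = bs.DEFAULT_GRID
    max_gap_frames: int = 5
    qc_tol_cm: float = 0.5
    abs_turn: bool = True
    use_covariates: bool = True
    n_boot: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.method not in ("watershed", "kmeans"):
            raise ValueError("method must be 'watershed' or 'kmeans'")

    @property
    def interval(self) -> IntervalSpec:
        return IntervalSpec(self.interval_kind, self.seconds_per_hour, self.hours_per_day)

    def stage_hash(self, stage: str) -> str:
        """Hash of the config fields a stage (and its inputs) depends on."""
        dep: dict[str, list[str]] = {
            "metrics": ["tracks_path", "max_gap_frames", "qc_tol_cm", "abs_turn",
                        "interval_kind", "seconds_per_hour", "hours_per_day"],
            "features": ["n_wavelets", "f_min", "f_max", "omega0", "abs_turn"],
            "cluster": ["k", "method", "sample_fraction", "n_neighbors", "min_dist",
                        "grid", "seed"],
            "entropy": ["interval_kind", "seconds_per_hour", "hours_per_day", "k"],
            "arcs": ["use_covariates", "n_boot", "seed"],
        }
        tank_v = np.asarray(self.tank.vertices).tolist()
        payload = {"tank": tank_v}
        chain = []
        for s in STAGES:
            chain.extend(dep[s])
            if s == stage:
                break
        payload.update({f: getattr(self, f) for f in chain})
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


def load_and_qc(cfg: PipelineConfig, trajectories: list[Trajectory] | None = None):
    """Read (or accept) trajectories, regularize, gap-fill and QC them."""
    if trajectories is None:
        if cfg.tracks_path is None:
            raise ValueError("either tracks_path or in-memory trajectories required")
        trajectories = read_tracks(cfg.tracks_path)
    out = []
    reports = []
    for tr in trajectories:
        tr = fill_gaps(tr, cfg.max_gap_frames)
        tr, rep = check_inside(tr, cfg.tank, cfg.qc_tol_cm)
        out.append(tr)
        reports.append(rep.to_dict())
    return out, reports


def covariate_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = {
        tr.individual_id: {
            "individual_id": tr.individual_id,
            "mother_id": tr.mother_id,
            "tank_position": tr.tank_position,
            "tank_system": tr.tank_system,
        }
        for tr in trajectories
    }
    return pd.DataFrame(rows.values())


def stage_metrics(cfg: PipelineConfig, trajectories: list[Trajectory]):
    series = [compute_metrics(tr, cfg.tank) for tr in trajectories]
    mdf = metrics_frame(series)
    cov = coefficient_of_variation(mdf, cfg.interval, abs_turn=cfg.abs_turn)
    return series, mdf, cov


def stage_features(cfg: PipelineConfig, series) -> wv.FeatureMatrix:
    freqs = wv.make_frequency_ladder(cfg.n_wavelets, cfg.f_min, cfg.f_max)
    by_ind: dict[str, list] = {}
    for ms in series:
        by_ind.setdefault(ms.individual_id, []).append(ms)
    parts = [
        wv.features_for_individual(ms_list, freqs, omega0=cfg.omega0, abs_turn=cfg.abs_turn)
        for _, ms_list in sorted(by_ind.items())
    ]
    return wv.FeatureMatrix.concat(parts)


def stage_cluster(cfg: PipelineConfig, features: wv.FeatureMatrix):
    """Assign every feature row a cluster label 1..k; returns (labels_df, artifacts)."""
    seed = _stage_seed(cfg.seed, "cluster")
    artifacts: dict = {"method": cfg.method, "seed": seed}
    if cfg.method == "watershed":
        model = bs.fit_embedding(
            features,
            sample_fraction=cfg.sample_fraction,
            seed=seed,
            n_neighbors=cfg.n_neighbors,
            min_dist=cfg.min_dist,
        )
        emb = bs.embed_points(model, features)
        field_ = bs.cluster_field_from_points(emb, cfg.k, grid=cfg.grid)
        labels = bs.assign_clusters(emb, field_)
        artifacts.update(model=model, embedded=emb, field=field_)
    else:
        labels = bs.kmeans_clusters(features, cfg.k, seed=seed)
    labels_df = features.index.copy()
    labels_df["cluster"] = labels
    return labels_df, artifacts

def stage_entropy(cfg: PipelineConfig, labels_df: pd.DataFrame, covariates: pd.DataFrame):
    return ea.entropy_table(labels_df, cfg.interval, cfg.k, covariates=covariates)


def stage_arcs(cfg: PipelineConfig, entropy: pd.DataFrame, cov: pd.DataFrame):
    """Linear-vs-quadratic arc selection + peak estimate per response."""
    seed = _stage_seed(cfg.seed, "arcs")
    results = {}
    responses = [("entropy", entropy, "entropy_nats")]
    for metric in METRICS:
        sub = cov[cov["metric"] == metric].rename(columns={"cov": "cov_value"})
        responses.append((f"cov_{metric}", sub, "cov_value"))
    for name, df, col in responses:
        lin = ea.fit_arc_models(df, col, "linear", cfg.interval, covariates=cfg.use_covariates)
        quad = ea.fit_arc_models(df, col, "quadratic", cfg.interval, covariates=cfg.use_covariates)
        sel = ea.select_model(lin, quad)
        peak = ea.peak_time(quad, df, cfg.interval, n_boot=cfg.n_boot, seed=seed)
        results[name] = {
            "linear": lin.to_dict(),
            "quadratic": quad.to_dict(),
            "selection": sel.to_dict(),
            "peak": peak.to_dict(),
        }
    return results


def _write_provenance(cfg: PipelineConfig, out: Path, timings: dict, qc: list):
    import bplast

    prov = {
        "package_version": bplast.__version__,
        "config": {
            k: (np.asarray(v.vertices).tolist() if isinstance(v, TankPolygon) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stage_hashes": {s: cfg.stage_hash(s) for s in STAGES},
        "seed": cfg.seed,
        "stage_seconds": timings,
        "qc_reports": qc,
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))


def run_all(
    cfg: PipelineConfig,
    trajectories: list[Trajectory] | None = None,
) -> dict:
    """Run every stage and persist per-stage outputs under ``cfg.out_dir``.

    Returns a results bundle with the in-memory tables: metrics, cov,
    features, labels, entropy and the arc-fit summary.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.time()
    trajs, qc = load_and_qc(cfg, trajectories)
    covariates = covariate_table(trajs)
    covariates.to_csv(out / "covariates.csv", index=False)
    timings["load"] = time.time() - t0

    t0 = time.time()
    series, mdf, cov = stage_metrics(cfg, trajs)
    cov.to_csv(out / "cov.csv", index=False)
    timings["metrics"] = time.time() - t0

    t0 = time.time()
    features = stage_features(cfg, series)
    timings["features"] = time.time() - t0

    t0 = time.time()
    labels_df, artifacts = stage_cluster(cfg, features)
    labels_df.to_csv(out / "clusters.csv", index=False)
    np.save(out / "labels.npy", labels_df["cluster"].to_numpy())
    timings["cluster"] = time.time() - t0

    t0 = time.time()
    entropy = stage_entropy(cfg, labels_df, covariates)
    entropy.to_csv(out / "entropy.csv", index=False)
    timings["entropy"] = time.time() - t0

    t0 = time.time()
    arcs = stage_arcs(cfg, entropy, cov)
    (out / "arcs.json").write_text(json.dumps(arcs, indent=2))
    timings["arcs"] = time.time() - t0

    _write_provenance(cfg, out, timings, qc)
    log.info("pipeline finished: %s", {k: round(v, 1) for k, v in timings.items()})
    return {
        "trajectories": trajs,
        "covariates": covariates,
        "metrics": mdf,
        "cov": cov,
        "features": features,
        "labels": labels_df,
        "cluster_artifacts": artifacts,
        "entropy": entropy,
        "arcs": arcs,
    }


def resume(cfg: PipelineConfig, stage: str, trajectories: list[Trajectory] | None = None) -> dict:
    """Re-run from ``stage`` onward, verifying upstream config is unchanged.

    Upstream stage hashes recorded in ``provenance.json`` must match the
    current config; a mismatch means the persisted intermediates were
    produced under different settings and the resume is refused.  Stages
    whose large intermediates are not persisted (features) are recomputed
    transparently.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    out = Path(cfg.out_dir)
    prov_path = out / "provenance.json"
    if not prov_path.exists():
        raise FileNotFoundError("no provenance.json in out_dir; run run_all first")
    prov = json.loads(prov_path.read_text())
    i = STAGES.index(stage)
    for s in STAGES[:i]:
        if prov["stage_hashes"].get(s) != cfg.stage_hash(s):
            raise ValueError(
                f"config affecting upstream stage {s!r} changed since the stored "
                f"run; refusing to resume at {stage!r} (re-run run_all)"
            )
    if stage in ("entropy", "arcs"):
        # small persisted intermediates suffice; no re-simulation needed
        for fname in ("cov.csv", "clusters.csv", "covariates.csv"):
            if not (out / fname).exists():
                raise FileNotFoundError(f"missing intermediate {fname}; cannot resume")
        cov = pd.read_csv(out / "cov.csv")
        covariates = pd.read_csv(out / "covariates.csv").astype(str)
        labels_df = pd.read_csv(out / "clusters.csv")
        if stage == "arcs" and (out / "entropy.csv").exists():
            entropy = pd.read_csv(out / "entropy.csv")
        else:
            entropy = stage_entropy(cfg, labels_df, covariates)
            entropy.to_csv(out / "entropy.csv", index=False)
        arcs = stage_arcs(cfg, entropy, cov)
        (out / "arcs.json").write_text(json.dumps(arcs, indent=2))
        prov["stage_hashes"] = {s: cfg.stage_hash(s) for s in STAGES}
        prov_path.write_text(json.dumps(prov, indent=2, default=str))
        return {"cov": cov, "labels": labels_df, "entropy": entropy, "arcs": arcs}
    # metrics/features/cluster: large intermediates are not persisted; recompute
    return run_all(cfg, trajectories)
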