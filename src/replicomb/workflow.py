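"""End-to-end seeded runs: simulate/generate -> measure -> fit -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import ClusterParams, call_clusters, cluster_statistics
from .generators import (
    ClusteredPlacementParams,
    generate_rdna_array,
    generate_two_regime_molecules,
    generate_uniform_molecules,
)
from .genome import GenomeSpec
from .iodstats import (
    fit_exponential_regimes,
    lilliefors_exponential,
    survival_curve,
)
from .io import write_molecules
from .kinetics import estimate_fork_velocities, classify_replicons, kinetic_point
from .metrics import call_origins, eligible_distances, iods_to_frame, measure_iods
from .noise import CombingNoise, fragment_and_stretch
from .simulate import KineticProfile, label_pulse_chase, simulate_genome_sphase

log = logging.getLogger("replicomb")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``generator`` is one of ``kinetic`` (whole-genome S-phase simulation with
    pulse/chase labeling), ``clustered``, ``uniform``, or ``rdna``; the
    analysis thresholds default to the study's values.
    """

    generator: str = "clustered"
    seed: int = 0
    outdir: str = "run"
    # generator parameters
    n_molecules: int = 131
    replication_extent: float = 0.15
    n_origins: int = 1200
    sample_time_min: float = 8.0
    chase_min: float = 3.0
    rdna_firing_prob: float = 0.2
    apply_combing_noise: bool = False
    # analysis thresholds
    max_track_kb: float = 20.0
    max_fraction: float = 0.5
    d_max_kb: float = 40.0
    min_n: int = 5
    window_kb: float = 200.0
    step_kb: float = 2.0
    velocity_window_kb: float = 300.0
    lilliefors_null: int = 2000
    regime_bootstrap: int = 200

    def __post_init__(self):
        for name in ("max_track_kb", "d_max_kb", "min_n", "window_kb", "step_kb",
                     "velocity_window_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.generator not in ("kinetic", "clustered", "uniform", "rdna"):
            raise ValueError(f"unknown generator {self.generator!r}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat key-value config (YAML mapping); unknown keys rejected."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _generate(cfg: RunConfig, genome: GenomeSpec):
    if cfg.generator == "clustered":
        mols, _ = generate_two_regime_molecules(
            ClusteredPlacementParams(), genome, cfg.replication_extent,
            seed=cfg.seed, n_molecules=cfg.n_molecules,
        )
    elif cfg.generator == "uniform":
        mols, _ = generate_uniform_molecules(
            cfg.n_origins, genome, cfg.replication_extent,
            seed=cfg.seed, n_molecules=cfg.n_molecules,
        )
    elif cfg.generator == "rdna":
        mols = generate_rdna_array(
            firing_prob=cfg.rdna_firing_prob, seed=cfg.seed,
            n_molecules=cfg.n_molecules,
        )
    else:  # kinetic
        sim = simulate_genome_sphase(genome, KineticProfile(chase_min=cfg.chase_min),
                                     seed=cfg.seed)
        timing = sim.timing_map()
        t0 = min(cfg.sample_time_min, max(0.0, sim.duration_min - cfg.chase_min))
        mols = label_pulse_chase(timing, 0.0, t0, cfg.chase_min)
        mols = fragment_and_stretch(mols, CombingNoise(), seed=cfg.seed + 1)
        return mols
    if cfg.apply_combing_noise:
        mols = fragment_and_stretch(mols, CombingNoise(), seed=cfg.seed + 1)
    return mols


def run_pipeline(cfg: RunConfig, genome: Optional[GenomeSpec] = None) -> Path:
    """Run generate -> measure -> fit, writing tables and a manifest.

    Deterministic for a fixed seed: two runs with the same config produce
    byte-identical tables.  Returns the run directory.
    """
    genome = genome or GenomeSpec()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: Dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "files": [],
    }

    def emit(name: str, df: pd.DataFrame):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["files"].append(name)

    try:
        log.info("run start: generator=%s seed=%d", cfg.generator, cfg.seed)
        mols = _generate(cfg, genome)
        write_molecules(mols, outdir / "molecules.tsv")
        manifest["files"].append("molecules.tsv")

        records = measure_iods(mols, cfg.max_track_kb, cfg.max_fraction)
        emit("iods.tsv", iods_to_frame(records))
        dist = eligible_distances(records)
        if len(dist) >= 2:
            emit("survival.tsv", survival_curve(dist).to_frame())
        else:
            log.warning("no eligible IODs; survival/fit tables skipped")

        if len(dist) >= 50:
            cmp_ = fit_exponential_regimes(
                dist, n_bootstrap=cfg.regime_bootstrap, seed=cfg.seed
            )
            lil = lilliefors_exponential(dist, n_null=cfg.lilliefors_null,
                                         seed=cfg.seed)
            emit("fits.tsv", pd.DataFrame([{
                "n_iods": len(dist),
                "single_rate_per_kb": cmp_.single.rate_per_kb,
                "single_median_kb": cmp_.single.median_kb,
                "steep_median_kb": cmp_.two_regime.median_steep_kb,
                "shallow_median_kb": cmp_.two_regime.median_shallow_kb,
                "weight_steep": cmp_.two_regime.weight_steep,
                "breakpoint_kb": cmp_.two_regime.breakpoint_kb,
                "lrt": cmp_.lrt_statistic,
                "p_bootstrap": cmp_.p_bootstrap,
                "preferred": cmp_.preferred,
                "lilliefors_D": lil.statistic,
                "lilliefors_p": lil.p_value,
            }]))

        origins = [o for m in mols for o in call_origins(m)]
        calls = call_clusters(origins, ClusterParams(cfg.d_max_kb, cfg.min_n))
        emit("clusters.tsv", pd.DataFrame(
            [
                {
                    "molecule_id": c.molecule_id, "start_kb": c.start_kb,
                    "end_kb": c.end_kb, "n_origins": c.n_origins,
                    "size_kb": c.size_kb,
                    "mean_internal_iod_kb": c.mean_internal_iod_kb,
                }
                for c in calls
            ],
            columns=["molecule_id", "start_kb", "end_kb", "n_origins",
                     "size_kb", "mean_internal_iod_kb"],
        ))
        stats = cluster_statistics(calls, origins, mols, genome.total_kb)
        emit("cluster_summary.tsv", pd.DataFrame([{
            "n_clusters": stats.n_clusters,
            "clusters_per_genome": stats.clusters_per_genome,
            "mean_within_iod_kb": stats.mean_within_iod_kb,
            "origins_per_cluster": stats.origins_per_cluster_mean,
            "fraction_origins_in_clusters": stats.fraction_origins_in_clusters,
        }]))

        if cfg.generator == "kinetic":
            points = [kinetic_point(m, genome.total_kb, cfg.chase_min) for m in mols]
            emit("kinetics.tsv", pd.DataFrame([p.__dict__ for p in points]))
            records_k = [r for m in mols for r in classify_replicons(m)]
            vel = estimate_fork_velocities(records_k, cfg.chase_min)
            emit("velocities.tsv", pd.DataFrame(
                {"velocity_kb_min": vel.velocities_kb_min}
            ))

        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("run complete: %d files", len(manifest["files"]))
    finally:
        log.removeHandler(fh)
        fh.close()
    return outdir


def generate_report(run_dir) -> List[Path]:
    """Render figures from a run directory's tables (no computation here).

    Every figure is backed by a TSV written by :func:`run_pipeline`; missing
    tables produce a placeholder panel, and re-rendering from the same TSVs
    is deterministic.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    out = []

    def placeholder(ax, text):
        ax.text(0.5, 0.5, text, ha="center", va="center")
        ax.set_axis_off()

    fig, ax = plt.subplots(figsize=(5, 4))
    surv = run_dir / "survival.tsv"
    if surv.exists():
        df = pd.read_csv(surv, sep="\t")
        pos = df[df["exceedance"] > 0]
        ax.semilogy(pos["distance_kb"], pos["exceedance"], "k-")
        ax.set_xlabel("IOD (kb)")
        ax.set_ylabel("fraction of IODs larger")
    else:
        placeholder(ax, "no data")
    fig.savefig(run_dir / "survival_semilog.png", dpi=120)
    plt.close(fig)
    out.append(run_dir / "survival_semilog.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    cl = run_dir / "clusters.tsv"
    if cl.exists() and len(df := pd.read_csv(cl, sep="\t")):
        ax.hist(df["size_kb"], bins=np.arange(0, df["size_kb"].max() + 50, 25))
        ax.set_xlabel("cluster size (kb)")
        ax.set_ylabel("count")
    else:
        placeholder(ax, "no data")
    fig.savefig(run_dir / "cluster_sizes.png", dpi=120)
    plt.close(fig)
    out.append(run_dir / "cluster_sizes.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    velp = run_dir / "velocities.tsv"
    if velp.exists() and len(df := pd.read_csv(velp, sep="\t")):
        ax.hist(df["velocity_kb_min"], bins=np.arange(0, 8, 0.5))
        ax.set_xlabel("fork velocity (kb/min)")
        ax.set_ylabel("forks")
    else:
        placeholder(ax, "no data")
    fig.savefig(run_dir / "velocity_hist.png", dpi=120)
    plt.close(fig)
    out.append(run_dir / "velocity_hist.png")

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    kin = run_dir / "kinetics.tsv"
    if kin.exists() and len(df := pd.read_csv(kin, sep="\t")):
        axes[0].plot(df["fraction"] * 100, df["rate_per_min_mb"], "k.")
        axes[0].set_xlabel("% DNA synthesis")
        axes[0].set_ylabel("origins / min / Mb unreplicated")
        axes[1].plot(df["fraction"] * 100, df["density_per_100kb"], "k.")
        axes[1].set_xlabel("% DNA synthesis")
        axes[1].set_ylabel("active replicons / 100 kb unreplicated")
    else:
        for ax in axes:
            placeholder(ax, "no data")
    fig.tight_layout()
    fig.savefig(run_dir / "kinetic_profiles.png", dpi=120)
    plt.close(fig)
    out.append(run_dir / "kinetic_profiles.png")
    return out
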