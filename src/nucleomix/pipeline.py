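"""Experiment orchestration: configuration, logging and the mu-sweep driver.

``run_experiment`` ties the stages together for every (mu, seed) cell:
simulate -> distance maps -> temporal network -> community detection ->
mixing and cluster statistics -> simulated microscope images -> image
statistics, writing one tidy TSV per statistic keyed by (mu, seed) plus a
field-for-field echo of the configuration.  All randomness in a cell is
funneled through the cell's own seed, so any cell replays bit-identically
from the same configuration.
"""

from __future__ import annotations

import configparser
import io
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import communities, distance_maps, imaging, mixing, networks, polymer

__all__ = ["RunConfig", "run_experiment", "DEFAULT_MU_GRID"]

log = logging.getLogger("nucleomix")

# log-spaced kinetic timescales spanning the rigid -> non-clustering range
DEFAULT_MU_GRID = tuple(np.round(np.geomspace(0.09, 90.0, 10), 4))


@dataclass
class RunConfig:
    """Parameters of a full sweep experiment."""

    preset: str = "nucleolus"          # "nucleolus" | "genome"
    n_beads: int = 120
    total_time: float = 60.0
    burn_in: float = 10.0
    mu_grid: tuple = DEFAULT_MU_GRID
    seeds: tuple = (1,)
    delta_frames: int = 10
    d_star_mixing: float = 100.0
    d_star_network: float = 325.0
    gamma: float = 10.0
    omega: float = 1.0
    image_timepoints: int = 11
    out_dir: str = "nucleomix_out"

    def __post_init__(self):
        if any(m <= 0 for m in self.mu_grid):
            raise ValueError("mu grid values must be positive")
        if self.preset not in ("nucleolus", "genome"):
            raise ValueError("preset must be 'nucleolus' or 'genome'")

    # -- plain-text round trip -------------------------------------------
    def to_text(self) -> str:
        cp = configparser.ConfigParser()
        cp["simulation"] = {
            "preset": self.preset, "n_beads": str(self.n_beads),
            "total_time": str(self.total_time), "burn_in": str(self.burn_in),
            "mu_grid": ",".join(str(m) for m in self.mu_grid),
            "seeds": ",".join(str(s) for s in self.seeds),
        }
        cp["network"] = {
            "delta_frames": str(self.delta_frames),
            "d_star_mixing": str(self.d_star_mixing),
            "d_star_network": str(self.d_star_network),
        }
        cp["communities"] = {"gamma": str(self.gamma),
                             "omega": str(self.omega)}
        cp["imaging"] = {"image_timepoints": str(self.image_timepoints)}
        cp["output"] = {"out_dir": str(self.out_dir)}
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read_string(text)
        sim = cp["simulation"]
        net = cp["network"]
        com = cp["communities"]
        img = cp["imaging"]
        return cls(
            preset=sim.get("preset", "nucleolus"),
            n_beads=sim.getint("n_beads"),
            total_time=sim.getfloat("total_time"),
            burn_in=sim.getfloat("burn_in"),
            mu_grid=tuple(float(x) for x in sim["mu_grid"].split(",")),
            seeds=tuple(int(x) for x in sim["seeds"].split(",")),
            delta_frames=net.getint("delta_frames"),
            d_star_mixing=net.getfloat("d_star_mixing"),
            d_star_network=net.getfloat("d_star_network"),
            gamma=com.getfloat("gamma"),
            omega=com.getfloat("omega"),
            image_timepoints=img.getint("image_timepoints"),
            out_dir=cp["output"].get("out_dir", "nucleomix_out"),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())


def _topology(config: RunConfig, seed: int | None = None):
    if config.preset == "genome":
        return polymer.genome_preset()
    return polymer.nucleolus_preset(config.n_beads, orientation_seed=seed)


def run_cell(config: RunConfig, mu: float, seed: int) -> dict:
    """Run every stage for one (mu, seed) cell and return its records."""
    topo = _topology(config, seed)
    radius = (polymer.scaled_nucleus_radius(config.n_beads)
              if config.preset == "nucleolus" else 1000.0)
    params = polymer.SimParams(mu=mu, total_time=config.total_time, seed=seed,
                               nucleus_radius=radius)
    t0 = time.perf_counter()
    traj = polymer.simulate(topo, params)
    t_sim = time.perf_counter() - t0

    start = int(round(config.burn_in / params.save_interval))
    key = {"mu": mu, "seed": seed}

    # bead-level mixing on the post-burn-in frames
    bead = mixing.mixing_summary(traj, "bead", d_star=config.d_star_mixing,
                                 start_frame=start)

    # temporal network + communities + community-level statistics
    net = networks.build_temporal_network(
        traj, delta=config.delta_frames, d_star=config.d_star_network,
        start_frame=start)
    part = communities.optimize_louvain(
        net, communities.ModularityParams(config.gamma, config.omega),
        seed=seed)
    comm = mixing.mixing_summary(part, "community")
    clusters = mixing.cluster_lifetimes(part)
    persistence = mixing.persistence_probability(part)

    # distance-map snapshot statistics
    snap = distance_maps.instantaneous_map(
        traj, traj.times[-1], nucleolar_only=True)
    try:
        low_mode = distance_maps.lowest_distance_mode(snap.condensed())
    except ValueError:
        low_mode = float("nan")

    # simulated microscopy
    frames = np.linspace(start, traj.n_frames - 1,
                         config.image_timepoints).astype(int)
    img_rows = []
    for fidx in frames:
        stack = imaging.render_microscope_stack(traj, traj.times[fidx])
        rep = imaging.analyze_mip(stack.mip)
        rep.update(key, time=traj.times[fidx])
        img_rows.append(rep)

    t_total = time.perf_counter() - t0
    log.info("cell mu=%g seed=%d: sim %.1fs, total %.1fs, Q=%.3f, "
             "%d communities", mu, seed, t_sim, t_total, part.Q,
             part.n_communities)
    return {
        "mixing_bead": {**key, "level": "bead",
                        **_summary_dict(bead)},
        "mixing_community": {**key, "level": "community",
                             **_summary_dict(comm)},
        "clusters": clusters.table.assign(**key),
        "persistence": persistence.assign(**key),
        "snapshot": {**key, "lowest_mode_nm": low_mode, "Q": part.Q,
                     "n_communities": part.n_communities},
        "imaging": pd.DataFrame(img_rows),
    }


def _summary_dict(s: mixing.MixingSummary) -> dict:
    return {
        "interaction_fraction": s.interaction_fraction,
        "mean_interaction_number": s.mean_interaction_number,
        "mean_waiting_time_s": s.mean_waiting_time,
        "mean_interaction_duration_s": s.mean_interaction_duration,
    }


def run_experiment(config: RunConfig) -> dict:
    """Drive the full mu-sweep and write tidy TSV outputs.

    A failing cell is recorded in ``errors.tsv`` and the sweep continues.
    Returns the collected tables keyed by statistic name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.ini").write_text(config.to_text())

    tables: dict = {"mixing": [], "clusters": [], "persistence": [],
                    "snapshot": [], "imaging": [], "errors": []}
    for mu in config.mu_grid:
        for seed in config.seeds:
            try:
                cell = run_cell(config, mu, seed)
            except Exception as exc:  # keep sweeping on per-cell failure
                log.error("cell mu=%g seed=%d failed: %s", mu, seed, exc)
                tables["errors"].append(
                    {"mu": mu, "seed": seed, "error": repr(exc)})
                continue
            tables["mixing"].append(cell["mixing_bead"])
            tables["mixing"].append(cell["mixing_community"])
            tables["clusters"].append(cell["clusters"])
            tables["persistence"].append(cell["persistence"])
            tables["snapshot"].append(cell["snapshot"])
            tables["imaging"].append(cell["imaging"])

    result = {}
    for name, rows in tables.items():
        if not rows:
            continue
        if isinstance(rows[0], pd.DataFrame):
            df = pd.concat(rows, ignore_index=True)
        else:
            df = pd.DataFrame(rows)
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        result[name] = df
    return result
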