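"""Run orchestration and I/O: the macro-step loop wired end to end.

A run directory is self-describing: it contains the fully resolved config,
the seed, the per-step trace table, periodic field/lattice snapshots and
the experience dataset, so a run can be reproduced bit-for-bit from its
outputs alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, write_config
from .decision import (FEATURE_LAYOUT, LAYOUT_VERSION, Experience,
                       ExperienceWindow, QLearner, _make_learners, macro_step)
from .agents import initialize_world, World
from .signaling import SignalingEngine
from .validation import fit_growth_law

__all__ = ["run", "export_timeseries", "import_timeseries", "export_dataset",
           "import_dataset", "export_snapshot", "validate_trace"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def run(config: SimulationConfig, mode: str = "train",
        out_dir: str | Path | None = None,
        learners: dict[str, QLearner] | None = None) -> Path:
    """Execute a full simulation run and write all outputs.

    The loop stops at the configured horizon or as soon as no empty site
    remains for tissue cells, whichever comes first.  ``mode="test"``
    requires trained learners (pass the ones returned by a train run).
    Any module error aborts the run with a partial-output manifest.
    """
    if mode not in ("train", "test"):
        raise ValueError("mode must be 'train' or 'test'")
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_config(config, out / "resolved_config.yaml")
    (out / "seed.txt").write_text(f"{int(config.seed)}\n")

    manifest = {"schema_version": SCHEMA_VERSION, "mode": mode,
                "status": "running", "outputs": ["resolved_config.yaml",
                                                 "seed.txt"]}
    world = initialize_world(config)
    if learners is None:
        learners = _make_learners(config)
    engine = SignalingEngine()
    rng = config.rng(f"{mode}-loop")
    trace: list[dict] = []
    try:
        export_snapshot(world, 0, out)
        manifest["outputs"].append("snapshot_000000")
        for step in range(config.horizon):
            trace.append(macro_step(world, learners, engine, mode, rng))
            if (step + 1) % config.snapshot_interval == 0:
                export_snapshot(world, step + 1, out)
                manifest["outputs"].append(f"snapshot_{step + 1:06d}")
            if _lattice_full(world):
                log.info("stopping at step %d: no empty tissue site remains",
                         step + 1)
                break
        manifest["status"] = "complete"
    except Exception as err:  # partial-output manifest, then re-raise
        manifest["status"] = f"aborted: {err}"
        raise
    finally:
        if trace:
            export_timeseries(trace, out / "trace.csv")
            manifest["outputs"].append("trace.csv")
        for cat, learner in learners.items():
            if len(learner.window):
                export_dataset(learner.window, out / f"dataset_{cat}.csv", cat)
                manifest["outputs"].append(f"dataset_{cat}.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _lattice_full(world: World) -> bool:
    lat = world.lattice
    return not ((lat.occupant == 0) & (lat.endo_count == 0)).any()


# ---------------------------------------------------------------------------
# Tabular exports (all re-importable losslessly)


def export_timeseries(trace: list[dict] | pd.DataFrame, path: str | Path) -> Path:
    df = trace if isinstance(trace, pd.DataFrame) else pd.DataFrame(trace)
    if df.empty:
        raise ValueError("cannot export an empty trace")
    path = Path(path)
    try:
        df.to_csv(path, index=False)
    except OSError as err:
        raise OSError(f"failed writing trace to {path}: {err}") from err
    return path


def import_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_dataset(window: ExperienceWindow, path: str | Path,
                   category: str) -> Path:
    """The self-generated dataset: named state columns, action, Q, reward."""
    cols = list(FEATURE_LAYOUT[category])
    rows = []
    for exp in window:
        rows.append({**dict(zip(cols, exp.state)), "action": exp.action,
                     "q": exp.q, "reward": exp.reward, "step": exp.step,
                     "celltype": exp.celltype})
    df = pd.DataFrame(rows, columns=[*cols, "action", "q", "reward", "step",
                                     "celltype"])
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# oncolattice dataset category={category} "
                 f"layout_version={LAYOUT_VERSION}\n")
        df.to_csv(fh, index=False)
    return path


def import_dataset(path: str | Path) -> tuple[ExperienceWindow, str]:
    """Read a dataset export back into a window (for offline training)."""
    path = Path(path)
    header = path.read_text().splitlines()[0]
    if not header.startswith("# oncolattice dataset"):
        raise ValueError(f"{path} is not an oncolattice dataset export")
    category = header.split("category=")[1].split()[0]
    df = pd.read_csv(path, comment="#")
    cols = list(FEATURE_LAYOUT[category])
    window = ExperienceWindow(max(len(df), 1))
    for _, r in df.iterrows():
        window.append(Experience(r[cols].to_numpy(dtype=float), r["action"],
                                 float(r["q"]), float(r["reward"]),
                                 int(r["step"]), str(r["celltype"])))
    return window, category


def export_snapshot(world: World, step: int, out_dir: str | Path) -> Path:
    """Per-step world state: field arrays (compressed npz) + site table."""
    out = Path(out_dir) / f"snapshot_{step:06d}"
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / "fields.npz",
                        **{sp: f.C for sp, f in world.fields.items()})
    world.lattice.snapshot(world.phenotype_grid).to_csv(
        out / "sites.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# Trace-level growth-law validation


def validate_trace(trace: pd.DataFrame, drop_initial: int = 0) -> dict:
    """Fit the growth laws to a run trace.

    Gompertz goes on the total cancerous population (live + necrotic),
    the sigmoid law on total vessel length, and the branching law on the
    cumulative branch-event count.  Returns a report dict of
    :class:`~oncolattice.validation.FitResult`.
    """
    t = trace["step"].to_numpy(dtype=float)[drop_initial:]
    report: dict[str, object] = {}
    n = trace["n_cancer_total"].to_numpy(dtype=float)[drop_initial:]
    if (n > 0).all() and len(n) >= 4:
        report["gompertz"] = fit_growth_law(t, n, "gompertz")
    g = trace["vessel_length_um"].to_numpy(dtype=float)[drop_initial:]
    if len(g) >= 4 and g.max() > g.min():
        try:
            report["sigmoid"] = fit_growth_law(t, g, "sigmoid")
        except RuntimeError as err:
            report["sigmoid"] = str(err)
    b = np.cumsum(trace["branch_events"].to_numpy(dtype=float))[drop_initial:]
    if len(b) >= 4 and b.max() > b.min():
        try:
            report["branching"] = fit_growth_law(t, b, "branching")
        except RuntimeError as err:
            report["branching"] = str(err)
    return report
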