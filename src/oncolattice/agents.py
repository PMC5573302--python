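"""Cell agents and the simulated world: state vectors, phenotype semantics,
nutrient-guided site selection and angiogenesis.

Tissue cells (healthy, cancerous) live one per site and act through the
phenotypes of the shared action vocabulary; endothelial cells (tip, stalk)
build vascular sprouts rooted on the eight parent vessels, up to four per
site.  Site selection for migration, daughter placement and sprouting uses
the two-stage nutrient rule: a candidate neighbourhood is "interesting"
when its maximum exceeds its mean by more than three standard deviations
for any relevant nutrient, and among candidates one is drawn with
probability proportional to the summed neighbourhood-mean concentrations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import actions as A
from .actions import ALLOWED_ACTIONS, allowed_actions
from .config import SimulationConfig, resolve_substep
from .fields import ConcentrationField
from .lattice import (ARTERIOLE, CANCEROUS, HEALTHY, PARENT_ARTERY,
                      PARENT_VEIN, VENULE, Claim, Lattice, moore_neighbors,
                      resolve_competition)

__all__ = ["CellAgent", "VesselTree", "World", "initialize_world",
           "candidate_condition", "selection_probabilities",
           "neighborhood_stats", "apply_phenotype", "update_perfusion",
           "allowed_actions"]

log = logging.getLogger(__name__)

_FOOTPRINT = np.ones((3, 3, 3), dtype=bool)
_FOOTPRINT[1, 1, 1] = False
_KERNEL = _FOOTPRINT.astype(np.float64)

TISSUE_TYPES = ("healthy", "cancerous")
VESSEL_TYPES = ("tip", "stalk")
RELEVANT_NUTRIENTS = {
    "healthy": ("oxygen", "glucose"), "cancerous": ("oxygen", "glucose"),
    "tip": ("vegf",), "stalk": ("vegf",),
}
_OCC_CODE = {"healthy": HEALTHY, "cancerous": CANCEROUS}


@dataclass
class CellAgent:
    """One agent; tissue- or vessel-specific state variables as applicable."""

    id: int
    ctype: str
    site: tuple[int, int, int]
    phenotype: str = "quiescence"   # current action label; default phenotype
    frozen: bool = False            # quiescence chosen -> absorbing
    # tissue-cell state variables
    division_counter: int = 0       # healthy only
    prolif_delay: float = 0.0       # hours a division has been postponed
    hypoxia_counter: float = 0.0    # hours spent hypoxic
    plcg: float = 0.0
    egfr_bound: float = 0.0
    death_signal: float = 0.0
    tnfr_bound: float = 0.0
    # vessel-cell state variables
    tip_age: float = 0.0
    vclass: int = 0                 # vessel annotation code of its segment
    parent: int | None = None       # lineage: parent endothelial agent id
    side: str | None = None         # "artery" | "vein" sprout rooting side

    def __post_init__(self) -> None:
        if self.ctype not in ALLOWED_ACTIONS:
            raise ValueError(f"unknown cell type {self.ctype!r}")


class VesselTree:
    """Sprout lineage forest over endothelial agents.

    Roots attach to a parent-vessel site; every segment inherits the class
    of its parent sprout.  Perfusion is a derived property recomputed from
    connectivity by :func:`update_perfusion`.
    """

    def __init__(self) -> None:
        self.parent: dict[int, int | None] = {}
        self.side: dict[int, str] = {}
        self.perfused_ids: set[int] = set()

    def add(self, cid: int, parent: int | None, side: str) -> None:
        self.parent[cid] = parent
        self.side[cid] = side

    def remove(self, cid: int) -> None:
        self.parent.pop(cid, None)
        self.side.pop(cid, None)
        self.perfused_ids.discard(cid)

    def path_to_root(self, cid: int) -> list[int]:
        chain = [cid]
        seen = {cid}
        while True:
            p = self.parent.get(chain[-1])
            if p is None or p in seen:
                return chain
            chain.append(p)
            seen.add(p)


class World:
    """Mutable simulation state shared by the field, signalling and
    decision layers."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        g = config.geometry
        self.lattice = Lattice(g.nx, g.ny, g.nz)
        self.fields: dict[str, ConcentrationField] = {}
        self.agents: dict[int, CellAgent] = {}
        self.vessel_tree = VesselTree()
        #: per-site phenotype code of the resident tissue cell (or debris)
        self.phenotype_grid = np.full(self.lattice.dims, A.QUIESCENCE, dtype=np.int8)
        self.t = 0
        self._next_id = 0
        self.rng = config.rng("world")
        self.stats: dict[str, dict[str, np.ndarray]] = {}
        self.nb_counts: dict[str, np.ndarray] = {}
        self.substeps = {sp: resolve_substep(fp, g.ds_um, 1.0)
                         for sp, fp in config.fields.items()}
        self.action_log: list[tuple] = []   # (t, id, type, action)

    # -- bookkeeping ---------------------------------------------------------

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    def spawn_tissue(self, ctype: str, site: tuple[int, int, int]) -> CellAgent:
        cid = self.new_id()
        agent = CellAgent(cid, ctype, site)
        self.lattice.place_tissue(cid, _OCC_CODE[ctype], site)
        self.phenotype_grid[site] = A.QUIESCENCE
        self.agents[cid] = agent
        return agent

    def spawn_endothelial(self, ctype: str, site: tuple[int, int, int],
                          parent: int | None, side: str,
                          vclass: int) -> CellAgent:
        cid = self.new_id()
        agent = CellAgent(cid, ctype, site, vclass=vclass, parent=parent,
                          side=side)
        self.lattice.add_endothelial(site)
        if self.lattice.vessel[site] == 0:
            self.lattice.vessel[site] = vclass
        self.vessel_tree.add(cid, parent, side)
        self.agents[cid] = agent
        return agent

    def remove_agent(self, cid: int) -> None:
        agent = self.agents.pop(cid)
        if agent.ctype in TISSUE_TYPES:
            self.lattice.remove_tissue(agent.site)
            self.phenotype_grid[agent.site] = A.QUIESCENCE
        else:
            self.lattice.remove_endothelial(agent.site)
            self.vessel_tree.remove(cid)

    def live_tissue(self) -> list[CellAgent]:
        return [a for a in self.agents.values() if a.ctype in TISSUE_TYPES]

    def counts(self) -> dict[str, int]:
        out = {ct: 0 for ct in (*TISSUE_TYPES, *VESSEL_TYPES)}
        for a in self.agents.values():
            out[a.ctype] += 1
        out["necrotic"] = int((self.lattice.occupant == 3).sum())
        return out

    # -- per-step cached neighbourhood statistics -----------------------------

    def refresh_neighbor_stats(self) -> None:
        """Moore-neighbourhood max / mean / std per species, plus tissue
        neighbour counts and derived site-selection grids, recomputed once
        per macro step."""
        for sp in ("oxygen", "glucose", "vegf"):
            C = self.fields[sp].C
            n = ndimage.correlate(np.ones(C.shape), _KERNEL, mode="constant",
                                  cval=0.0)
            s1 = ndimage.correlate(C, _KERNEL, mode="constant", cval=0.0)
            s2 = ndimage.correlate(C * C, _KERNEL, mode="constant", cval=0.0)
            mean = s1 / n
            var = np.maximum(s2 / n - mean**2, 0.0)
            mx = ndimage.maximum_filter(C, footprint=_FOOTPRINT,
                                        mode="constant", cval=-np.inf)
            self.stats[sp] = {"max": mx, "mean": mean, "std": np.sqrt(var)}
        for name, code in (("healthy", HEALTHY), ("cancerous", CANCEROUS)):
            occ = (self.lattice.occupant == code).astype(np.float64)
            self.nb_counts[name] = ndimage.correlate(
                occ, _KERNEL, mode="constant", cval=0.0)
        # derived grids for fast site selection (field-based, so they only
        # go stale with physics updates, never with occupancy changes)
        lat = self.lattice
        self._pass3 = {}
        self._selweight = {}
        for cat, species in (("tissue", ("oxygen", "glucose")),
                             ("vessel", ("vegf",))):
            p = np.zeros(lat.dims, dtype=bool)
            w = np.zeros(lat.dims)
            for sp in species:
                st = self.stats[sp]
                p |= st["max"] - st["mean"] > 3.0 * st["std"]
                w += st["mean"]
            self._pass3[cat] = p
            self._selweight[cat] = w


# ---------------------------------------------------------------------------
# Site selection (two-stage nutrient rule)


def _site_stats(world: World, species: str, p: tuple[int, int, int]
                ) -> tuple[float, float, float]:
    if species in world.stats:
        st = world.stats[species]
        return float(st["max"][p]), float(st["mean"][p]), float(st["std"][p])
    C = world.fields[species].C
    nbs = moore_neighbors(p, world.lattice)
    vals = np.array([C[q] for q in nbs])
    return float(vals.max()), float(vals.mean()), float(vals.std())


def candidate_condition(site: tuple[int, int, int], world: World,
                        celltype: str) -> bool:
    """True when any relevant nutrient shows max - mean > 3*std over the
    candidate's Moore neighbourhood (OR across nutrients)."""
    for sp in RELEVANT_NUTRIENTS[celltype]:
        mx, mean, std = _site_stats(world, sp, site)
        if mx - mean > 3.0 * std:
            return True
    return False


def selection_probabilities(candidates: list[tuple[int, int, int]],
                            world: World, celltype: str) -> np.ndarray:
    """Probability per candidate, proportional to the summed neighbourhood-
    mean concentrations of the relevant nutrients.  All-zero weights fall
    back to a uniform draw (logged)."""
    if not candidates:
        raise ValueError("selection_probabilities requires >= 1 candidate")
    weights = np.zeros(len(candidates))
    for i, p in enumerate(candidates):
        for sp in RELEVANT_NUTRIENTS[celltype]:
            weights[i] += _site_stats(world, sp, p)[1]
    total = weights.sum()
    if total <= 0.0:
        log.debug("all candidate weights zero; uniform fallback")
        return np.full(len(candidates), 1.0 / len(candidates))
    return weights / total


def neighborhood_stats(C: np.ndarray) -> dict[str, np.ndarray]:
    """Standalone Moore-neighbourhood max/mean/std arrays for one field."""
    n = ndimage.correlate(np.ones(C.shape), _KERNEL, mode="constant", cval=0.0)
    s1 = ndimage.correlate(C, _KERNEL, mode="constant", cval=0.0)
    s2 = ndimage.correlate(C * C, _KERNEL, mode="constant", cval=0.0)
    mean = s1 / n
    var = np.maximum(s2 / n - mean**2, 0.0)
    mx = ndimage.maximum_filter(C, footprint=_FOOTPRINT, mode="constant",
                                cval=-np.inf)
    return {"max": mx, "mean": mean, "std": np.sqrt(var)}


_OFFSETS26 = np.array([(dx, dy, dz)
                       for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                       for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)],
                      dtype=np.int64)


def _draw(weights: np.ndarray, rng: np.random.Generator) -> int:
    """Index drawn proportionally to non-negative weights (uniform if all 0)."""
    total = weights.sum()
    if total <= 0.0:
        return int(rng.integers(len(weights)))
    cum = np.cumsum(weights)
    return int(np.searchsorted(cum, rng.random() * total, side="right"))


def select_target_site(world: World, agent: CellAgent,
                       rng: np.random.Generator) -> tuple[int, int, int] | None:
    """Pick a free Moore site by the two-stage rule; None when boxed in.

    Candidates passing the max-mean condition are preferred; whether zero,
    one or many pass, the final draw is by the normalised nutrient weights
    over the preferred pool (the ranking rule applied uniformly).  Uses the
    per-step cached grids; necrotic sites are never free.
    """
    cat = "tissue" if agent.ctype in TISSUE_TYPES else "vessel"
    coords = _OFFSETS26 + np.asarray(agent.site)
    ok = np.all((coords >= 0) & (coords < np.asarray(world.lattice.dims)), axis=1)
    coords = coords[ok]
    idx = (coords[:, 0], coords[:, 1], coords[:, 2])
    occ = world.lattice.occupant[idx]
    endo = world.lattice.endo_count[idx]
    free = (occ == 0) & (endo == 0) if cat == "tissue" \
        else (occ == 0) & (endo < 4)
    if not free.any():
        return None
    passing = free & world._pass3[cat][idx]
    pool = passing if passing.any() else free
    weights = np.where(pool, world._selweight[cat][idx], 0.0)
    k = _draw(weights[pool], rng)
    chosen = coords[pool][k]
    return (int(chosen[0]), int(chosen[1]), int(chosen[2]))


# ---------------------------------------------------------------------------
# Phenotype application


#: sentinel: let apply_phenotype pick the target site itself
AUTO = "auto"


def apply_phenotype(world: World, agent: CellAgent, action: str,
                    rng: np.random.Generator | None = None,
                    target=AUTO) -> str:
    """Execute one action for one agent; returns the realised phenotype.

    The realised phenotype can differ from the requested action when the
    world forbids it: a proliferation or branch with no free Moore site
    falls back to quiescence (resting phase, absorbing); a cell that lost
    a site competition simply stays put this step.  ``target`` lets the
    synchronous batch update pass a conflict-resolved destination
    (``None`` marks a competition loser); by default the two-stage
    site-selection rule picks one.
    """
    if action not in allowed_actions(agent.ctype):
        raise ValueError(f"action {action!r} not allowed for {agent.ctype}")
    rng = rng if rng is not None else world.rng
    realised, effect = action, action

    if agent.ctype in VESSEL_TYPES:
        agent.tip_age += 1.0
        realised, effect = _apply_vessel(world, agent, action, rng)
    elif action == "apoptosis":
        world.remove_agent(agent.id)
        effect = "removed"
    elif action == "necrosis":
        site = agent.site
        world.agents.pop(agent.id)
        world.lattice.mark_necrotic(site)
        world.phenotype_grid[site] = A.NECROSIS
        effect = "necrotic"
    elif action == "quiescence":
        agent.frozen = True
        world.phenotype_grid[agent.site] = A.QUIESCENCE
        effect = "frozen"
    elif action == "hypoxia":
        agent.hypoxia_counter += 1.0
        world.phenotype_grid[agent.site] = A.HYPOXIA
        effect = "hypoxic"
    elif action == "migration":
        dest = select_target_site(world, agent, rng) if target is AUTO else target
        if dest is None:
            world.phenotype_grid[agent.site] = A.MIGRATION
            effect = "stationary"
        else:
            world.lattice.move_tissue(agent.site, dest)
            world.phenotype_grid[agent.site] = A.QUIESCENCE
            agent.site = dest
            world.phenotype_grid[dest] = A.MIGRATION
            effect = "moved"
    elif action == "proliferation":
        o2 = float(world.fields["oxygen"].C[agent.site])
        if o2 < world.config.agents.prolif_o2_min:
            # rule 4: postpone division until oxygen suffices
            agent.prolif_delay += 1.0
            world.phenotype_grid[agent.site] = A.PROLIFERATION
            effect = "postponed"
        else:
            dest = select_target_site(world, agent, rng) if target is AUTO else target
            if dest is None and not any(
                    world.lattice.can_occupy(q, agent.ctype)
                    for q in moore_neighbors(agent.site, world.lattice)):
                # neighbourhood full: resting phase, absorbing
                agent.frozen = True
                realised, effect = "quiescence", "frozen"
                world.phenotype_grid[agent.site] = A.QUIESCENCE
            elif dest is None:
                effect = "stationary"  # lost the site competition this step
                world.phenotype_grid[agent.site] = A.PROLIFERATION
            else:
                daughter = world.spawn_tissue(agent.ctype, dest)
                daughter.plcg = agent.plcg
                world.phenotype_grid[agent.site] = A.PROLIFERATION
                agent.prolif_delay = 0.0
                effect = "divided"
                if agent.ctype == "healthy":
                    agent.division_counter += 1
                    daughter.division_counter = agent.division_counter
    else:  # pragma: no cover - exhaustive over tissue actions
        raise AssertionError(action)

    agent.phenotype = realised
    if effect != "rested":   # no-op rests would dominate the log
        world.action_log.append((world.t, agent.id, agent.ctype, realised,
                                 effect))
    return realised


def _free_endo_sites(world: World, agent: CellAgent) -> list[tuple[int, int, int]]:
    coords = _OFFSETS26 + np.asarray(agent.site)
    ok = np.all((coords >= 0) & (coords < np.asarray(world.lattice.dims)), axis=1)
    coords = coords[ok]
    idx = (coords[:, 0], coords[:, 1], coords[:, 2])
    free = (world.lattice.occupant[idx] == 0) & (world.lattice.endo_count[idx] < 4)
    return [tuple(map(int, c)) for c in coords[free]]


def _sprout_class(agent: CellAgent) -> int:
    if agent.vclass in (PARENT_ARTERY, ARTERIOLE):
        return ARTERIOLE
    return VENULE


def _apply_vessel(world: World, agent: CellAgent, action: str,
                  rng: np.random.Generator) -> tuple[str, str]:
    if action == "quiescence":
        # endothelial quiescence is a per-step rest, not the absorbing
        # G0 exit of the tissue cell cycle
        return "quiescence", "rested"
    free = _free_endo_sites(world, agent)
    if action == "branch":
        if len(free) < 2:
            log.debug("agent %d: branch blocked, resting this step", agent.id)
            return "quiescence", "rested"
        picks = []
        pool = list(free)
        for _ in range(2):
            probs = selection_probabilities(pool, world, agent.ctype)
            k = int(rng.choice(len(pool), p=probs))
            picks.append(pool.pop(k))
        for q in picks:
            world.spawn_endothelial(agent.ctype, q, agent.id,
                                    agent.side or "artery", _sprout_class(agent))
        return "branch", "branched"
    if action == "expansion":
        if not free:
            return "quiescence", "rested"
        probs = selection_probabilities(free, world, agent.ctype)
        dest = free[int(rng.choice(len(free), p=probs))]
        old = agent.site
        world.lattice.remove_endothelial(old)
        world.lattice.add_endothelial(dest)
        if world.lattice.vessel[dest] == 0:
            world.lattice.vessel[dest] = _sprout_class(agent)
        # a fresh stalk takes the vacated site, spliced into the lineage
        stalk = world.spawn_endothelial("stalk", old, agent.parent,
                                        agent.side or "artery", agent.vclass)
        agent.parent = stalk.id
        agent.site = dest
        agent.vclass = _sprout_class(agent)
        return "expansion", "expanded"
    if action == "sprout":
        if not free:
            return "quiescence", "rested"
        probs = selection_probabilities(free, world, agent.ctype)
        dest = free[int(rng.choice(len(free), p=probs))]
        world.spawn_endothelial("tip", dest, agent.id,
                                agent.side or "artery", _sprout_class(agent))
        return "sprout", "sprouted"
    raise AssertionError(action)


def environmental_transitions(world: World,
                              skip_increment: set[int] | None = None) -> dict:
    """Starvation and TNF-driven deaths, applied to every live tissue cell.

    The hypoxia counter tracks hours of nutrient deprivation: it rises
    while the local oxygen sits below the hypoxia threshold or the local
    glucose below its dead threshold, and resets on recovery (cells that
    took the hypoxia action this step already incremented it there).  A cell deprived for longer than the duration
    limit dies -- necrosis for a cancerous cell, apoptosis for a healthy
    one -- and a cell whose TNF death signal has crossed its threshold dies
    the same way.  These transitions are forced by the environment and
    therefore also reach quiescent cells: resting cells are not immune to
    starvation or death-receptor signalling.
    """
    from .signaling import DEATH_SIGNAL_THRESHOLD
    skip = skip_increment or set()
    cfgA = world.config.agents
    thr = cfgA.hypoxia_o2_threshold
    limits = {"cancerous": cfgA.hypoxia_duration_limit,
              "healthy": cfgA.hypoxia_duration_limit_healthy}
    o2 = world.fields["oxygen"].C
    glu = world.fields["glucose"].C
    glu_dead = cfgA.glucose_dead
    doomed: list[CellAgent] = []
    for a in world.agents.values():
        if a.ctype not in TISSUE_TYPES:
            continue
        if o2[a.site] < thr or glu[a.site] < glu_dead:
            if a.id not in skip:
                a.hypoxia_counter += 1.0
        else:
            a.hypoxia_counter = 0.0
        if a.hypoxia_counter > limits[a.ctype] or \
                a.death_signal > DEATH_SIGNAL_THRESHOLD:
            doomed.append(a)
    n_starved = n_killed = 0
    for a in doomed:
        cause = "starved" if a.hypoxia_counter > limits[a.ctype] \
            else "tnf_killed"
        if a.ctype == "cancerous":
            site = a.site
            world.agents.pop(a.id)
            world.lattice.mark_necrotic(site)
            world.phenotype_grid[site] = A.NECROSIS
            world.action_log.append((world.t, a.id, a.ctype, "necrosis", cause))
        else:
            world.remove_agent(a.id)
            world.action_log.append((world.t, a.id, a.ctype, "apoptosis", cause))
        if cause == "starved":
            n_starved += 1
        else:
            n_killed += 1
    return {"starved": n_starved, "tnf_killed": n_killed}


# ---------------------------------------------------------------------------
# Perfusion


def update_perfusion(world: World) -> int:
    """Recompute perfusion from sprout connectivity; returns the number of
    perfused sprout segments.

    An artery-rooted sprout becomes perfused along its whole root-to-tip
    path once its tip touches (enters the Moore neighbourhood of) any
    vein-side vessel site.  Perfusion is derived state: it is recomputed
    from scratch, so removing a connecting segment reverts its path.
    """
    lat = world.lattice
    lat.perfused[:] = np.isin(lat.vessel, (PARENT_ARTERY, PARENT_VEIN))
    world.vessel_tree.perfused_ids.clear()

    vein_side = np.isin(lat.vessel, (PARENT_VEIN, VENULE))
    n_perfused = 0
    for agent in world.agents.values():
        if agent.ctype != "tip" or agent.side != "artery":
            continue
        touches = any(vein_side[q] for q in moore_neighbors(agent.site, lat))
        if not touches:
            continue
        for cid in world.vessel_tree.path_to_root(agent.id):
            seg = world.agents.get(cid)
            if seg is None:
                continue
            if cid not in world.vessel_tree.perfused_ids:
                n_perfused += 1
            world.vessel_tree.perfused_ids.add(cid)
            lat.perfused[seg.site] = True
    return n_perfused


# ---------------------------------------------------------------------------
# Initialisation


def _parent_vessel_lines(config: SimulationConfig
                         ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    g = config.geometry
    mid = [(g.nx // 2, 0), (g.nx // 2, g.ny - 1),
           (0, g.ny // 2), (g.nx - 1, g.ny // 2)]
    edges = [(0, 0), (0, g.ny - 1), (g.nx - 1, 0), (g.nx - 1, g.ny - 1)]
    if g.artery_layout == "midfaces":
        return mid, edges          # arteries on mid-faces, veins on edges
    return edges, mid


def initialize_world(config: SimulationConfig) -> World:
    """Build the initial world: vessels, tissue, nutrient landscape.

    Cancer cells seed a sphere of the configured radius (60 um = 3 sites at
    the default spacing) at the lattice centre with the configured per-site
    probability; healthy cells fill the rest at the same probability.
    Oxygen and glucose start as Gaussian-decay profiles peaking at the
    eight parent-vessel lines; VEGF, TGFα and TNFα start at zero.
    """
    config.validate()
    world = World(config)
    g = config.geometry
    lat = world.lattice
    arteries, veins = _parent_vessel_lines(config)
    if any(not (0 <= x < g.nx and 0 <= y < g.ny) for x, y in arteries + veins):
        raise ValueError("geometry incompatible with parent-vessel layout")

    for (x, y), vclass, side in (
            *(((x, y), PARENT_ARTERY, "artery") for x, y in arteries),
            *(((x, y), PARENT_VEIN, "vein") for x, y in veins)):
        for z in range(g.nz):
            site = (x, y, z)
            lat.vessel[site] = vclass
            lat.perfused[site] = True
            world.spawn_endothelial("stalk", site, None, side, vclass)

    # nutrient landscape: Gaussian decay from the nearest parent-vessel line
    xs, ys = np.meshgrid(np.arange(g.nx), np.arange(g.ny), indexing="ij")
    d2 = np.full((g.nx, g.ny), np.inf)
    for lx, ly in arteries + veins:
        d2 = np.minimum(d2, ((xs - lx) ** 2 + (ys - ly) ** 2) * g.ds_um**2)
    profile = config.agents.init_field_amplitude * np.exp(
        -d2 / (2.0 * config.agents.init_field_width_um**2))
    profile3d = np.repeat(profile[:, :, None], g.nz, axis=2)

    for sp, fp in config.fields.items():
        init = profile3d if sp in ("oxygen", "glucose") else 0.0
        world.fields[sp] = ConcentrationField(fp, lat.dims, g.ds_um, init)

    # tissue: cancer seed sphere at the centre, healthy elsewhere
    rng = config.rng("init")
    center = np.array([(d - 1) / 2.0 for d in lat.dims])
    seed_r = config.agents.seed_radius_um / g.ds_um
    p_occ = config.agents.init_prob
    for x in range(g.nx):
        for y in range(g.ny):
            for z in range(g.nz):
                site = (x, y, z)
                if not lat.can_occupy(site, "healthy"):
                    continue
                dist = math.dist((x, y, z), center)
                ctype = "cancerous" if dist <= seed_r else "healthy"
                if rng.random() < p_occ:
                    agent = world.spawn_tissue(ctype, site)
                    if ctype == "healthy":
                        # mature tissue: the division budget is spent, so
                        # normal cells are homeostatic rather than expansive
                        agent.division_counter = \
                            config.agents.division_limit + 2

    world.refresh_neighbor_stats()
    update_perfusion(world)
    return world


# ---------------------------------------------------------------------------
# Synchronous movement/birth batch


def resolve_moves(world: World, proposals: list[tuple[CellAgent, str]],
                  rng: np.random.Generator) -> dict[int, tuple[int, int, int]]:
    """Resolve simultaneous migration/proliferation targets.

    Each proposing agent picks its preferred free site; contested sites go
    to a cancerous claimant over a healthy one, then to a uniform draw.
    Returns agent id -> granted target for the winners; losers stay put.
    """
    claims = []
    for agent, action in proposals:
        dest = select_target_site(world, agent, rng)
        if dest is not None:
            claims.append(Claim(agent.id, agent.ctype, dest))
    winners = resolve_competition(claims, rng)
    return {c.cell_key: t for t, c in winners.items()}
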