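"""The 3D site grid: Moore neighbourhoods, occupancy rules and claim competition.

One lattice site holds either a single tissue cell (healthy or cancerous),
a permanent necrotic-debris marker, or up to four endothelial (vessel)
cells; the two occupancy kinds are mutually exclusive.  Vessel annotations
(parent artery/vein, arteriole, venule, capillary) and the perfused flag
live on the site as well, since nutrient exchange happens through the
vessel wall at the site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EMPTY", "HEALTHY", "CANCEROUS", "NECROTIC",
    "VESSEL_NONE", "PARENT_ARTERY", "PARENT_VEIN", "ARTERIOLE", "VENULE",
    "CAPILLARY", "VESSEL_NAMES", "OCCUPANT_NAMES",
    "Site", "Lattice", "Claim",
    "moore_offsets", "moore_neighbors", "resolve_competition",
]

# occupant codes
EMPTY, HEALTHY, CANCEROUS, NECROTIC = 0, 1, 2, 3
OCCUPANT_NAMES = {EMPTY: "empty", HEALTHY: "healthy", CANCEROUS: "cancerous",
                  NECROTIC: "necrotic"}

# vessel annotation codes
VESSEL_NONE, PARENT_ARTERY, PARENT_VEIN, ARTERIOLE, VENULE, CAPILLARY = range(6)
VESSEL_NAMES = {VESSEL_NONE: "none", PARENT_ARTERY: "parent_artery",
                PARENT_VEIN: "parent_vein", ARTERIOLE: "arteriole",
                VENULE: "venule", CAPILLARY: "capillary"}

MAX_ENDOTHELIAL_PER_SITE = 4

_OFFSETS = np.array([(dx, dy, dz)
                     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                     if (dx, dy, dz) != (0, 0, 0)], dtype=np.int64)


def moore_offsets() -> np.ndarray:
    """The 26 Chebyshev-distance-1 offsets, shape (26, 3)."""
    return _OFFSETS.copy()


@dataclass(frozen=True)
class Site:
    """Read-only view of one lattice site."""

    p: tuple[int, int, int]
    occupant: int
    cell_id: int
    endothelial_count: int
    vessel: int
    perfused: bool


class Lattice:
    """Array-backed 3D grid with an occupancy index for tissue cells."""

    def __init__(self, nx: int, ny: int, nz: int):
        if min(nx, ny, nz) < 1:
            raise ValueError("lattice dimensions must be >= 1")
        self.dims = (nx, ny, nz)
        shape = (nx, ny, nz)
        self.occupant = np.zeros(shape, dtype=np.int8)
        self.cell_id = np.full(shape, -1, dtype=np.int64)
        self.endo_count = np.zeros(shape, dtype=np.int8)
        self.vessel = np.zeros(shape, dtype=np.int8)
        self.perfused = np.zeros(shape, dtype=bool)
        #: tissue-cell id -> (x, y, z)
        self.index: dict[int, tuple[int, int, int]] = {}

    # -- geometry ------------------------------------------------------------

    def in_bounds(self, p: Sequence[int]) -> bool:
        return all(0 <= p[i] < self.dims[i] for i in range(3))

    def site(self, p: Sequence[int]) -> Site:
        p = tuple(int(v) for v in p)
        if not self.in_bounds(p):
            raise IndexError(f"site {p} outside lattice dims {self.dims}")
        return Site(p, int(self.occupant[p]), int(self.cell_id[p]),
                    int(self.endo_count[p]), int(self.vessel[p]),
                    bool(self.perfused[p]))

    # -- occupancy -----------------------------------------------------------

    def can_occupy(self, p: Sequence[int], celltype: str) -> bool:
        """Occupancy admission per the one-tissue-or-four-endothelial rule."""
        p = tuple(int(v) for v in p)
        occ = self.occupant[p]
        if occ == NECROTIC:
            return False
        if celltype in ("healthy", "cancerous"):
            return occ == EMPTY and self.endo_count[p] == 0
        if celltype in ("tip", "stalk"):
            return occ == EMPTY and self.endo_count[p] < MAX_ENDOTHELIAL_PER_SITE
        raise ValueError(f"unknown cell type {celltype!r}")

    def place_tissue(self, cid: int, ctype: int, p: Sequence[int]) -> None:
        p = tuple(int(v) for v in p)
        assert self.occupant[p] == EMPTY and self.endo_count[p] == 0, \
            f"site {p} cannot admit a tissue cell"
        self.occupant[p] = ctype
        self.cell_id[p] = cid
        self.index[cid] = p

    def remove_tissue(self, p: Sequence[int]) -> int:
        """Free the site; returns the removed cell id."""
        p = tuple(int(v) for v in p)
        cid = int(self.cell_id[p])
        assert cid >= 0, f"no tissue cell at {p}"
        self.occupant[p] = EMPTY
        self.cell_id[p] = -1
        del self.index[cid]
        return cid

    def move_tissue(self, src: Sequence[int], dst: Sequence[int]) -> None:
        src = tuple(int(v) for v in src)
        dst = tuple(int(v) for v in dst)
        ctype = int(self.occupant[src])
        cid = self.remove_tissue(src)
        # re-register under the same id
        self.place_tissue(cid, ctype, dst)

    def mark_necrotic(self, p: Sequence[int]) -> None:
        """Permanent debris marker; the site blocks all future occupancy."""
        p = tuple(int(v) for v in p)
        cid = int(self.cell_id[p])
        if cid >= 0:
            del self.index[cid]
        self.cell_id[p] = -1
        self.occupant[p] = NECROTIC

    def add_endothelial(self, p: Sequence[int]) -> None:
        p = tuple(int(v) for v in p)
        assert self.can_occupy(p, "tip"), f"site {p} cannot admit an endothelial cell"
        self.endo_count[p] += 1

    def remove_endothelial(self, p: Sequence[int]) -> None:
        p = tuple(int(v) for v in p)
        assert self.endo_count[p] > 0
        self.endo_count[p] -= 1

    def check_invariants(self) -> None:
        both = (self.occupant > 0) & (self.endo_count > 0)
        assert not both.any(), "site holds both tissue and endothelial occupants"
        assert (self.endo_count <= MAX_ENDOTHELIAL_PER_SITE).all()
        live = np.argwhere((self.occupant == HEALTHY) | (self.occupant == CANCEROUS))
        assert len(live) == len(self.index)
        for p in map(tuple, live):
            cid = int(self.cell_id[p])
            assert self.index.get(cid) == p, "occupancy index out of sync"

    # -- export ---------------------------------------------------------------

    def snapshot(self, phenotype: np.ndarray | None = None) -> pd.DataFrame:
        """Tabular per-site state (only non-trivial sites are listed)."""
        mask = (self.occupant != EMPTY) | (self.endo_count > 0) | (self.vessel != 0)
        coords = np.argwhere(mask)
        rows = {
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
            "occupant": [OCCUPANT_NAMES[int(self.occupant[tuple(c)])] for c in coords],
            "endothelial": self.endo_count[mask],
            "vessel": [VESSEL_NAMES[int(self.vessel[tuple(c)])] for c in coords],
            "perfused": self.perfused[mask],
        }
        if phenotype is not None:
            rows["phenotype"] = phenotype[mask]
        return pd.DataFrame(rows)


def moore_neighbors(p: Sequence[int], lattice: Lattice) -> list[tuple[int, int, int]]:
    """In-bounds sites at Chebyshev distance 1 (up to 26 of them)."""
    p = tuple(int(v) for v in p)
    if not lattice.in_bounds(p):
        raise IndexError(f"site {p} outside lattice dims {lattice.dims}")
    cand = _OFFSETS + np.asarray(p)
    ok = np.all((cand >= 0) & (cand < np.asarray(lattice.dims)), axis=1)
    return [tuple(map(int, c)) for c in cand[ok]]


@dataclass(frozen=True)
class Claim:
    """One cell's claim on a target site during the synchronous update."""

    cell_key: object            # opaque identifier of the claimant
    celltype: str               # "healthy" | "cancerous" | "tip" | "stalk"
    target: tuple[int, int, int]


def resolve_competition(claims: Iterable[Claim],
                        rng: np.random.Generator) -> dict[tuple[int, int, int], Claim]:
    """Resolve simultaneous claims on sites; returns target -> winning claim.

    A cancerous claimant beats a healthy one on the same site; ties between
    same-precedence claimants are broken uniformly at random.  Losing cells
    simply stay where they are (handled by the caller).  Claims are grouped
    by target in sorted order so the outcome does not depend on the
    iteration order of the input.
    """
    by_target: dict[tuple[int, int, int], list[Claim]] = {}
    for c in claims:
        by_target.setdefault(tuple(c.target), []).append(c)
    winners: dict[tuple[int, int, int], Claim] = {}
    for target in sorted(by_target):
        group = by_target[target]
        if len(group) == 1:
            winners[target] = group[0]
            continue
        cancerous = [c for c in group if c.celltype == "cancerous"]
        pool = cancerous if cancerous else group
        pool = sorted(pool, key=lambda c: repr(c.cell_key))
        winners[target] = pool[int(rng.integers(len(pool)))]
    return winners
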