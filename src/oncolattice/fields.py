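"""Continuum species on the lattice: explicit reaction-diffusion stepping.

Each of the five species (oxygen, glucose, TGFα, TNFα, VEGF) evolves by an
explicit finite-difference update over the 26-neighbour Moore stencil:

    C(t+dt) = C(t) + D*(dt/dS^2)*Lap26(C) - U + S [- W]

with per-site uptake U, source S and (VEGF only) first-order waste W.
Boundaries are no-flux: a missing neighbour mirrors the centre value and
contributes zero to the Laplacian.  Oxygen/glucose enter through perfused
vessel walls and are consumed by tissue cells at a phenotype-dependent rate;
TGFα/TNFα are secreted by tissue cells and consumed by the signalling
module; VEGF is secreted by stressed cancer cells, taken up by perfused
vessels and decays globally.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import actions as A
from .config import STABILITY_LIMIT, FieldParams, GeometryParams
from .lattice import (ARTERIOLE, CANCEROUS, CAPILLARY, HEALTHY, NECROTIC,
                      PARENT_ARTERY, PARENT_VEIN, VENULE, Lattice)

__all__ = ["ConcentrationField", "laplacian26", "laplacian26_array",
           "step_nutrient", "step_vegf", "uptake_coefficients",
           "vessel_radius_map"]

log = logging.getLogger(__name__)

_FOOTPRINT = np.ones((3, 3, 3), dtype=bool)
_FOOTPRINT[1, 1, 1] = False
_KERNEL = _FOOTPRINT.astype(np.float64)

# Eq.-3 uptake schedule: fraction of beta_c consumed per cancer phenotype,
# monotone decreasing with metabolic activity.
NUTRIENT_SCHEDULE = {
    A.PROLIFERATION: 1.0, A.MIGRATION: 1 / 2, A.QUIESCENCE: 1 / 4,
    A.HYPOXIA: 1 / 6, A.NECROSIS: 1 / 8,
}
# Eq.-4 VEGF production schedule: the reverse ordering -- the more stressed
# the cancer cell, the more VEGF it secretes.
VEGF_SCHEDULE = {
    A.NECROSIS: 1.0, A.HYPOXIA: 1 / 2, A.QUIESCENCE: 1 / 4,
    A.MIGRATION: 1 / 6, A.PROLIFERATION: 1 / 8,
}


class ConcentrationField:
    """One species' scalar concentration over the lattice.

    Values are clamped to be non-negative after every update; clamping
    events are counted and logged.
    """

    def __init__(self, params: FieldParams, dims: Sequence[int], ds: float,
                 initial: float | np.ndarray = 0.0):
        self.params = params
        self.ds = float(ds)
        self.C = np.full(tuple(dims), 0.0, dtype=np.float64)
        self.C += initial
        if not np.isfinite(self.C).all() or (self.C < 0).any():
            raise ValueError(f"{params.species}: initial field must be finite and >= 0")
        self.clamp_events = 0
        # in-bounds neighbour count per site (8..26), fixed by geometry
        self._n_nb = ndimage.correlate(np.ones(self.C.shape), _KERNEL,
                                       mode="constant", cval=0.0)

    @property
    def species(self) -> str:
        return self.params.species

    def total(self) -> float:
        return float(self.C.sum())

    def laplacian(self) -> np.ndarray:
        """26-neighbour Laplacian of the current field (cached counts)."""
        s = ndimage.correlate(self.C, _KERNEL, mode="constant", cval=0.0)
        return s - self._n_nb * self.C

    def _clamp(self) -> None:
        neg = self.C < 0.0
        n = int(neg.sum())
        if n:
            self.clamp_events += n
            log.debug("%s: clamped %d negative sites to 0", self.species, n)
            self.C[neg] = 0.0
        if not np.isfinite(self.C).all():
            raise FloatingPointError(f"{self.species}: non-finite concentration")


def laplacian26_array(C: np.ndarray) -> np.ndarray:
    """Discrete 26-neighbour Laplacian with no-flux boundaries.

    Interior: sum of the 26 neighbours minus 26*C.  At boundaries the
    missing neighbours mirror the centre, i.e. contribute zero.
    """
    n_nb = ndimage.correlate(np.ones(C.shape), _KERNEL, mode="constant", cval=0.0)
    s = ndimage.correlate(C, _KERNEL, mode="constant", cval=0.0)
    return s - n_nb * C


def laplacian26(field: ConcentrationField, site: Sequence[int]) -> float:
    """Laplacian stencil value at one site (scalar convenience form)."""
    p = tuple(int(v) for v in site)
    if not all(0 <= p[i] < field.C.shape[i] for i in range(3)):
        raise IndexError(f"site {p} outside field of shape {field.C.shape}")
    lo = [max(0, p[i] - 1) for i in range(3)]
    hi = [min(field.C.shape[i], p[i] + 2) for i in range(3)]
    block = field.C[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    n_nb = block.size - 1
    return float(block.sum() - field.C[p] - n_nb * field.C[p])


def vessel_radius_map(lattice: Lattice, geometry: GeometryParams
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site vessel radius R and intravascular class (1=artery-side,
    2=vein-side, 0=no perfused vessel).

    Only perfused vessels exchange material: unperfused sprouts have R = 0.
    Artery-side segments (parent arteries, arterioles) carry the arteriole
    radius; vein-side and capillary segments carry the capillary radius.
    """
    R = np.zeros(lattice.dims, dtype=np.float64)
    side = np.zeros(lattice.dims, dtype=np.int8)
    art = np.isin(lattice.vessel, (PARENT_ARTERY, ARTERIOLE)) & lattice.perfused
    ven = np.isin(lattice.vessel, (PARENT_VEIN, VENULE, CAPILLARY)) & lattice.perfused
    R[art] = geometry.r_art_um
    R[ven] = geometry.r_cap_um
    side[art] = 1
    side[ven] = 2
    return R, side


def uptake_coefficients(lattice: Lattice, phenotype: np.ndarray,
                        params: FieldParams, necrotic_uptake: bool = True
                        ) -> np.ndarray:
    """Per-site uptake rate ζ [1/h] for oxygen/glucose.

    Cancer cells consume at beta_c scaled by the Eq.-3 phenotype schedule;
    healthy cells at alpha_n; empty sites not at all.  Necrotic debris
    consuming at beta_c/8 follows the schedule literally; it can be switched
    off with ``necrotic_uptake=False``.
    """
    zeta = np.zeros(lattice.dims, dtype=np.float64)
    cancer = lattice.occupant == CANCEROUS
    for phen, frac in NUTRIENT_SCHEDULE.items():
        if phen == A.NECROSIS:
            continue
        zeta[cancer & (phenotype == phen)] = params.beta_c * frac
    if necrotic_uptake:
        zeta[lattice.occupant == NECROTIC] = params.beta_c * NUTRIENT_SCHEDULE[A.NECROSIS]
    zeta[lattice.occupant == HEALTHY] = params.alpha_n
    return zeta


def _check_stability(field: ConcentrationField, dt: float) -> None:
    number = field.params.D * dt / field.ds**2
    if number > STABILITY_LIMIT * (1 + 1e-12):
        raise ValueError(
            f"{field.species}: D*dt/dS^2 = {number:.4g} exceeds the stability "
            f"bound 1/26; reduce dt via resolve_substep")


def step_nutrient(field: ConcentrationField, lattice: Lattice, dt: float,
                  phenotype: np.ndarray | None = None,
                  geometry: GeometryParams | None = None,
                  necrotic_uptake: bool = True) -> ConcentrationField:
    """One explicit sub-step for oxygen, glucose, TGFα or TNFα.

    Oxygen/glucose: diffusion + cellular uptake + transmural vessel source
    2π R Pe (ρ - C) at perfused vessel sites.  TGFα/TNFα: diffusion +
    constant secretion by live tissue cells; their consumption happens in
    the signalling module, not here.
    """
    _check_stability(field, dt)
    p = field.params
    C = field.C
    newC = C + p.D * (dt / field.ds**2) * field.laplacian()

    if p.species in ("oxygen", "glucose"):
        if phenotype is None:
            phenotype = np.full(lattice.dims, A.QUIESCENCE, dtype=np.int8)
        zeta = uptake_coefficients(lattice, phenotype, p, necrotic_uptake)
        newC -= dt * zeta * C
        if geometry is not None:
            R, side = vessel_radius_map(lattice, geometry)
            rho = np.where(side == 1, p.rho_art,
                           np.where(side == 2, p.rho_cap, 0.0))
            newC += (dt / field.ds**2) * (2.0 * np.pi * R * p.Pe * (rho - C))
    elif p.species in ("tgf_alpha", "tnf_alpha"):
        tissue = (lattice.occupant == HEALTHY) | (lattice.occupant == CANCEROUS)
        newC += dt * p.SO * tissue
    else:
        raise ValueError(f"step_nutrient does not handle species {p.species!r}")

    field.C = newC
    field._clamp()
    return field


def step_vegf(field: ConcentrationField, lattice: Lattice, dt: float,
              phenotype: np.ndarray | None = None,
              geometry: GeometryParams | None = None) -> ConcentrationField:
    """One explicit sub-step for VEGF (diffusion, vessel uptake, cancer
    source on the stress schedule, global first-order decay)."""
    if field.params.species != "vegf":
        raise ValueError("step_vegf requires the VEGF field")
    _check_stability(field, dt)
    p = field.params
    C = field.C
    newC = C + p.D * (dt / field.ds**2) * field.laplacian()

    if geometry is not None:
        R, _ = vessel_radius_map(lattice, geometry)
        newC -= (dt / field.ds**2) * (2.0 * np.pi * R * p.Pe * C)

    if phenotype is None:
        phenotype = np.full(lattice.dims, A.QUIESCENCE, dtype=np.int8)
    # only live cancer cells secrete; necrotic debris does not (the
    # schedule's necrosis entry covers a cell in the act of dying)
    source = np.zeros(lattice.dims, dtype=np.float64)
    cancer = lattice.occupant == CANCEROUS
    for phen, frac in VEGF_SCHEDULE.items():
        source[cancer & (phenotype == phen)] = p.phi_c * frac
    newC += dt * source

    newC -= dt * p.omega * C
    field.C = newC
    field._clamp()
    return field
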