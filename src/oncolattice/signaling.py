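"""Subcellular signalling: EGFR (TGFα -> PLCγ) and TNF (TNFα -> death signal).

The pathway contract is an input/output one: the EGFR cascade
turns local TGFα concentration into a PLCγ level that arbitrates the
migrate-versus-proliferate choice, and the TNF cascade turns local TNFα
into a death signal.  The exact ODE systems behind those cascades are not
part of this package; instead a documented surrogate -- mass-action
receptor binding followed by a saturating Hill-type activation stage --
sits behind a pluggable :class:`PathwayModel` interface so a different
system can be registered without touching any other module.

Integration runs once per macro step (one hour) at the sub-second internal
resolution of an adaptive Runge-Kutta method, for all cells at once.  Both
surrogates are monotone in their ligand by construction: a larger sustained
TGFα dose never lowers PLCγ, and a larger TNFα dose never lowers the death
signal (which, like an integrated damage variable, never decreases at all).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["SignalingState", "PathwayModel", "ReceptorHillPathway",
           "default_egfr_pathway", "default_tnf_pathway", "SignalingEngine",
           "plc_gamma_decision"]


@dataclass
class SignalingState:
    """Per-cell pathway state, stored as parallel arrays.

    ``tgf_consumed``/``tnf_consumed`` report the ligand amount each cell
    removed from its local field during the last macro step, so the field
    coupling conserves mass.
    """

    plcg: np.ndarray           # PLCγ output level [conc]
    egfr_bound: np.ndarray     # bound EGFR fraction, in [0, 1]
    death_signal: np.ndarray   # accumulated TNF death signal [dimensionless]
    tnfr_bound: np.ndarray     # bound TNFR fraction, in [0, 1]
    tgf_consumed: np.ndarray
    tnf_consumed: np.ndarray

    @classmethod
    def basal(cls, n: int) -> "SignalingState":
        z = lambda: np.zeros(n, dtype=np.float64)  # noqa: E731
        return cls(z(), z(), z(), z(), z(), z())

    def validate(self) -> None:
        for name in ("plcg", "egfr_bound", "death_signal", "tnfr_bound",
                     "tgf_consumed", "tnf_consumed"):
            arr = getattr(self, name)
            assert np.isfinite(arr).all() and (arr >= 0).all(), \
                f"signalling state {name} must be finite and >= 0"


class PathwayModel(Protocol):
    """Plug-in contract: advance (bound, output) under a constant ligand."""

    #: fraction of the local ligand concentration consumed per hour of exposure
    consumption_rate: float

    def integrate(self, ligand: np.ndarray, bound: np.ndarray,
                  output: np.ndarray, dt: float
                  ) -> tuple[np.ndarray, np.ndarray]:
        ...


class ReceptorHillPathway:
    """Mass-action receptor binding feeding a Hill-type activation stage.

    dB/dt = kon * L * (1 - B) - koff * B
    dY/dt = kact * B^h / (K^h + B^h) * (y_max - Y) - kdeg * Y

    With ``kdeg = 0`` and ``y_max = inf``-like behaviour disabled, the output
    accumulates monotonically (used for the TNF death signal); with
    ``kdeg > 0`` the output settles to a dose-dependent steady state (used
    for PLCγ).  Integration uses an adaptive RK method on the stacked state
    of all cells; on integrator failure the previous state is kept and the
    failure is reported by raising only when nothing was integrated.
    """

    def __init__(self, kon: float, koff: float, kact: float, K: float,
                 h: float, kdeg: float, y_max: float,
                 consumption_rate: float):
        self.kon, self.koff = float(kon), float(koff)
        self.kact, self.K, self.h = float(kact), float(K), float(h)
        self.kdeg, self.y_max = float(kdeg), float(y_max)
        self.consumption_rate = float(consumption_rate)

    def _rhs(self, t: float, y: np.ndarray, L: np.ndarray) -> np.ndarray:
        n = L.size
        B, Y = y[:n], y[n:]
        B = np.clip(B, 0.0, 1.0)
        act = B**self.h / (self.K**self.h + B**self.h)
        dB = self.kon * L * (1.0 - B) - self.koff * B
        if np.isfinite(self.y_max):
            dY = self.kact * act * (self.y_max - Y) - self.kdeg * Y
        else:
            dY = self.kact * act - self.kdeg * Y
        return np.concatenate([dB, dY])

    def integrate(self, ligand: np.ndarray, bound: np.ndarray,
                  output: np.ndarray, dt: float
                  ) -> tuple[np.ndarray, np.ndarray]:
        ligand = np.atleast_1d(np.asarray(ligand, dtype=np.float64))
        bound = np.atleast_1d(np.asarray(bound, dtype=np.float64)).copy()
        output = np.atleast_1d(np.asarray(output, dtype=np.float64)).copy()
        if (ligand < 0).any():
            raise ValueError("ligand concentrations must be >= 0")
        if ligand.size == 0 or dt <= 0:
            return bound, output
        y0 = np.concatenate([bound, output])
        sol = solve_ivp(self._rhs, (0.0, dt), y0, args=(ligand,),
                        method="RK45", rtol=1e-6, atol=1e-9)
        if not sol.success:
            raise RuntimeError(f"pathway integration failed: {sol.message}")
        y = sol.y[:, -1]
        n = ligand.size
        return np.clip(y[:n], 0.0, 1.0), np.maximum(y[n:], 0.0)

    def steady_state(self, ligand: float) -> float:
        """Analytic fixed point of the output for a sustained ligand level."""
        B = self.kon * ligand / (self.kon * ligand + self.koff)
        act = B**self.h / (self.K**self.h + B**self.h)
        if self.kdeg == 0.0:
            return float("inf") if act > 0 else 0.0
        if np.isfinite(self.y_max):
            return self.kact * act * self.y_max / (self.kact * act + self.kdeg)
        return self.kact * act / self.kdeg


def default_egfr_pathway() -> ReceptorHillPathway:
    """PLCγ output saturating at 1.0 with a ~10-minute binding timescale."""
    return ReceptorHillPathway(kon=20.0, koff=2.0, kact=5.0, K=0.5, h=2.0,
                               kdeg=1.0, y_max=1.0, consumption_rate=0.2)


def default_tnf_pathway() -> ReceptorHillPathway:
    """Accumulating death signal with a steep dose response.

    Calibrated so one hour above the rule-8 TNFα threshold (0.3) pushes the
    signal past the death threshold 1.0, while the ambient TNFα level that
    dense tissue settles at (secretion/consumption ~ 0.02) accumulates so
    slowly that unexposed cells outlive any simulated horizon.
    """
    return ReceptorHillPathway(kon=20.0, koff=5.0, kact=2.5, K=0.6, h=4.0,
                               kdeg=0.0, y_max=float("inf"),
                               consumption_rate=0.1)


#: Death-signal level past which rule-8 death biases apply at full strength.
DEATH_SIGNAL_THRESHOLD = 1.0


class SignalingEngine:
    """Drives both pathways for a batch of cells and reports consumption."""

    def __init__(self, egfr: PathwayModel | None = None,
                 tnf: PathwayModel | None = None):
        self.egfr = egfr or default_egfr_pathway()
        self.tnf = tnf or default_tnf_pathway()

    def integrate_egfr(self, local_tgf: np.ndarray, state: SignalingState,
                       dt: float) -> SignalingState:
        """Advance PLCγ under the local TGFα level; records consumption."""
        local_tgf = np.atleast_1d(np.asarray(local_tgf, dtype=np.float64))
        try:
            state.egfr_bound, state.plcg = self.egfr.integrate(
                local_tgf, state.egfr_bound, state.plcg, dt)
        except RuntimeError:
            pass  # keep previous PLCγ on integrator failure
        state.tgf_consumed = np.minimum(
            self.egfr.consumption_rate * local_tgf * dt, local_tgf)
        return state

    def integrate_tnf(self, local_tnf: np.ndarray, state: SignalingState,
                      dt: float) -> SignalingState:
        """Advance the death signal under the local TNFα level."""
        local_tnf = np.atleast_1d(np.asarray(local_tnf, dtype=np.float64))
        try:
            state.tnfr_bound, state.death_signal = self.tnf.integrate(
                local_tnf, state.tnfr_bound, state.death_signal, dt)
        except RuntimeError:
            pass
        state.tnf_consumed = np.minimum(
            self.tnf.consumption_rate * local_tnf * dt, local_tnf)
        return state


def plc_gamma_decision(cell_plcg: float, others_plcg: np.ndarray) -> str:
    """Migrate-versus-proliferate preference from relative PLCγ.

    A cell whose PLCγ strictly exceeds the mean over all *other* tissue
    cells prefers proliferation, otherwise migration.  A singleton
    population compares against a mean of 0, so any positive PLCγ yields
    the proliferate preference (documented edge case of the strict ">").
    """
    others_plcg = np.asarray(others_plcg, dtype=np.float64)
    mean_others = float(others_plcg.mean()) if others_plcg.size else 0.0
    return "proliferation" if cell_plcg > mean_others else "migration"
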