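"""The phenotype-decision engine.

Each live agent reads its state (the per-type state variables), obtains a
Q value for every allowed action from the kernel-ensemble regressor,
samples an action (train phase: proportional to shifted-non-negative Q,
modulated by the policy-rule selection biases; test phase: greedy), and
after the world advances receives a reward equal to the mean of the
per-policy reward terms

    RF_p(x) = direction_p * tanh((x - threshold_p) / gradient_p),

updating Q by the standard one-step rule

    Q <- (1 - eta) Q + eta (r + gamma_disc * max_a' Q(s', a')).

Experiences with reward strictly above the admission threshold enter a
FIFO sliding window that serves as the regressor's training set.  Before
the first ensemble is fitted (cold start) actions are sampled from the
policy-bias distribution directly.

The same loop primitives drive both the tumour world (multi-agent, via
:func:`run_train_phase` / :func:`run_test_phase`) and any single-agent
:class:`Environment` such as a toy Markov decision process (via
:func:`train_loop`), which is how the learning plumbing is validated
against dynamic programming.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Hashable, Iterable, Protocol, Sequence

import numpy as np
from scipy import ndimage

from .actions import allowed_actions
from .agents import (TISSUE_TYPES, VESSEL_TYPES, CellAgent, World,
                     apply_phenotype, environmental_transitions,
                     initialize_world, resolve_moves, update_perfusion)
from .config import LearningParams, PolicyRule, SimulationConfig
from .fields import step_nutrient, step_vegf
from .regressor import RegressorEnsemble, fit_ensemble
from .signaling import SignalingEngine, SignalingState

__all__ = [
    "Experience", "ExperienceWindow", "reward_fn", "total_reward",
    "policy_bias", "q_update", "select_action_train", "select_action_test",
    "admit_experience", "Environment", "QFunction", "TabularQ", "train_loop",
    "QLearner", "run_train_phase", "run_test_phase", "macro_step",
    "state_variables", "feature_vector", "TISSUE_ACTIONS", "VESSEL_ACTIONS",
    "advance_fields_and_signaling",
]

log = logging.getLogger(__name__)

TISSUE_ACTIONS = ("quiescence", "proliferation", "migration", "hypoxia",
                  "necrosis", "apoptosis")
VESSEL_ACTIONS = ("quiescence", "branch", "expansion", "sprout")

#: feature layout per learner category, versioned for dataset exports
FEATURE_LAYOUT = {
    "tissue": ("oxygen", "glucose", "division_counter", "prolif_delay",
               "hypoxia_counter", "plcg", "n_healthy_nb", "n_cancerous_nb",
               "tnf_alpha", "is_cancerous"),
    "vessel": ("vegf", "tip_age", "is_tip"),
}
LAYOUT_VERSION = 1


# ---------------------------------------------------------------------------
# Experiences


@dataclass
class Experience:
    """One learning sample: state features, action, updated Q, reward."""

    state: np.ndarray
    action: str
    q: float
    reward: float
    step: int
    celltype: str = "cancerous"

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=float)
        if not np.isfinite(self.q):
            raise ValueError("Q value must be finite")
        if self.action not in allowed_actions(self.celltype):
            raise ValueError(
                f"action {self.action!r} not allowed for {self.celltype}")


class ExperienceWindow:
    """FIFO sliding window of capacity ``d`` (oldest evicted first)."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("window capacity must be >= 1")
        self.capacity = capacity
        self._buf: deque[Experience] = deque(maxlen=capacity)

    def append(self, exp: Experience) -> None:
        self._buf.append(exp)

    def __len__(self) -> int:
        return len(self._buf)

    def __iter__(self):
        return iter(self._buf)

    def __getitem__(self, i):
        return self._buf[i]

    def to_arrays(self, action_space: Sequence[str]
                  ) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) with the action appended one-hot to the state features."""
        X = np.array([_with_action(e.state, e.action, action_space)
                      for e in self._buf])
        y = np.array([e.q for e in self._buf])
        return X, y


def admit_experience(exp: Experience, theta: float,
                     window: ExperienceWindow) -> ExperienceWindow:
    """Append iff reward strictly exceeds the admission threshold."""
    if exp.reward > theta:
        window.append(exp)
    return window


def _with_action(state: np.ndarray, action: str,
                 action_space: Sequence[str]) -> np.ndarray:
    onehot = np.zeros(len(action_space))
    onehot[action_space.index(action)] = 1.0
    return np.concatenate([state, onehot])


# ---------------------------------------------------------------------------
# Rewards and policy biases


def reward_fn(x: float, rule: PolicyRule) -> float:
    """Per-policy reward term; 0 at the threshold, bounded in (-1, 1)."""
    if rule.gradient <= 0:
        raise ValueError("rule gradient must be > 0")
    return rule.direction * float(np.tanh((x - rule.threshold) / rule.gradient))


def _applicable(rules: Iterable[PolicyRule], celltype: str,
                state: dict[str, float]) -> list[PolicyRule]:
    return [r for r in rules if celltype in r.cell_types and r.variable in state]


def total_reward(state: dict[str, float], rules: Sequence[PolicyRule],
                 celltype: str) -> float:
    """Arithmetic mean of the applicable per-policy reward terms."""
    app = _applicable(rules, celltype, state)
    if not app:
        raise ValueError(f"no applicable policy rules for {celltype}")
    return float(np.mean([reward_fn(state[r.variable], r) for r in app]))


def policy_bias(state: dict[str, float], rules: Sequence[PolicyRule],
                celltype: str, strength: float = 1.5) -> dict[str, float]:
    """Multiplicative per-action selection weights from the policy rules.

    Every applicable rule multiplies its favoured actions by
    ``exp(strength * RF)`` and its disfavoured ones by ``exp(-strength * RF)``
    -- mass moved toward some phenotypes is mass moved away from the others
    once the weights are normalised.  A rule's hard gate zeroes its action
    outright while the raw state value is at or below the threshold
    (the neighbour-count rule makes migration impossible with two or fewer
    neighbours).
    """
    weights = {a: 1.0 for a in sorted(allowed_actions(celltype))}
    for rule in _applicable(rules, celltype, state):
        rf = reward_fn(state[rule.variable], rule)
        for a in rule.favors:
            if a in weights:
                weights[a] *= float(np.exp(strength * rf))
        for a in rule.disfavors:
            if a in weights:
                weights[a] *= float(np.exp(-strength * rf))
        if rule.hard_gates and state[rule.variable] <= rule.threshold:
            for a in rule.hard_gates:
                if a in weights:
                    weights[a] = 0.0
    return weights


def q_update(q: float, r: float, max_next_q: float, eta: float,
             gamma_disc: float) -> float:
    """One-step Q-learning update (exact formula value)."""
    return (1.0 - eta) * q + eta * (r + gamma_disc * max_next_q)


# ---------------------------------------------------------------------------
# Action selection


#: exploration floor added to every shifted Q weight; keeps all actions
#: reachable (plain Q/sum(Q) starves unexplored zero-Q actions forever)
Q_FLOOR = 0.05


def _shifted(qs: np.ndarray, floor: float = Q_FLOOR) -> np.ndarray:
    """Non-negative weights proportional to Q, valid for negative Q too.

    Negative sets are shifted up by |min|; the floor is added throughout so
    the distribution stays proper and every action keeps a small chance.
    """
    qs = np.asarray(qs, dtype=float)
    w = qs - min(qs.min(), 0.0) + floor
    if w.sum() <= 0.0:
        return np.full(qs.size, 1.0 / qs.size)
    return w / w.sum()


def _draw_index(weights: np.ndarray, rng: np.random.Generator) -> int:
    total = weights.sum()
    if total <= 0.0:
        return int(rng.integers(len(weights)))
    cum = np.cumsum(weights)
    return int(np.searchsorted(cum, rng.random() * total, side="right"))


def select_action_train(q_values: dict[str, float],
                        rng: np.random.Generator) -> str:
    """Sample an action with probability proportional to shifted Q."""
    if not q_values:
        raise ValueError("need at least one allowed action")
    names = sorted(q_values)
    probs = _shifted(np.array([q_values[a] for a in names]))
    return names[_draw_index(probs, rng)]


def select_action_test(q_values: dict[str, float],
                       rng: np.random.Generator) -> str:
    """Greedy action; exact ties broken uniformly at random."""
    if not q_values:
        raise ValueError("need at least one allowed action")
    names = sorted(q_values)
    qs = np.array([q_values[a] for a in names])
    best = np.flatnonzero(qs == qs.max())
    return names[int(best[rng.integers(len(best))])]


def _sample_weighted(weights: dict[str, float],
                     rng: np.random.Generator) -> str:
    names = sorted(weights)
    w = np.array([max(weights[a], 0.0) for a in names])
    return names[_draw_index(w, rng)]


# ---------------------------------------------------------------------------
# Generic single-agent loop (used to validate the plumbing on toy MDPs)


class Environment(Protocol):
    """Minimal environment contract for the generic learning loop."""

    def reset(self, rng: np.random.Generator) -> Hashable: ...
    def actions(self, state: Hashable) -> Sequence[str]: ...
    def step(self, state: Hashable, action: str,
             rng: np.random.Generator) -> tuple[Hashable, float]: ...


class QFunction(Protocol):
    @property
    def ready(self) -> bool: ...
    def predict(self, state: Hashable, action: str) -> float: ...
    def fit(self, window: ExperienceWindow) -> None: ...


class TabularQ:
    """Lookup-table Q function; the tabular-equivalent regressor.

    ``fit`` replays the window in insertion order so the newest value per
    (state, action) pair wins.
    """

    def __init__(self) -> None:
        self.table: dict[tuple[Hashable, str], float] = {}
        self._fitted = False

    @property
    def ready(self) -> bool:
        return self._fitted

    def predict(self, state: Hashable, action: str) -> float:
        return self.table.get((state, action), 0.0)

    def fit(self, window: ExperienceWindow) -> None:
        for exp in window:
            self.table[(_hashable(exp.state), exp.action)] = exp.q
        self._fitted = True


def _hashable(state) -> Hashable:
    if isinstance(state, np.ndarray):
        return tuple(state.tolist())
    return state


class _GenericExperience(Experience):
    """Experience carrying an arbitrary hashable state (toy environments)."""

    def __init__(self, state, action, q, reward, step):
        self.state = state
        self.action = action
        self.q = float(q)
        self.reward = float(reward)
        self.step = step
        self.celltype = "generic"
        if not np.isfinite(self.q):
            raise ValueError("Q value must be finite")


def train_loop(env: Environment, qfunc: QFunction, params: LearningParams,
               rng: np.random.Generator, n_steps: int,
               refit_interval: int = 1) -> list[tuple]:
    """Drive the enumerated train-phase steps on a single-agent environment.

    Per step: read the state, probe Q for every allowed action, sample an
    action proportionally to shifted Q (uniform during cold start), advance
    the environment, update Q from the reward and the successor state's
    best Q, and admit the experience when the reward clears the threshold.
    Returns the (state, action, reward) trace.
    """
    window = ExperienceWindow(params.window)
    state = env.reset(rng)
    trace = []
    for t in range(n_steps):
        acts = list(env.actions(state))
        qs = {a: (qfunc.predict(state, a) if qfunc.ready else 0.0)
              for a in acts}
        action = select_action_train(qs, rng)
        nxt, r = env.step(state, action, rng)
        nacts = list(env.actions(nxt))
        max_next = max((qfunc.predict(nxt, a) for a in nacts), default=0.0) \
            if qfunc.ready else 0.0
        qnew = q_update(qs[action], r, max_next, params.eta, params.gamma_disc)
        admit_experience(_GenericExperience(state, action, qnew, r, t),
                         params.theta, window)
        if (t + 1) % refit_interval == 0 and len(window):
            qfunc.fit(window)
        trace.append((state, action, r))
        state = nxt
    return trace


# ---------------------------------------------------------------------------
# Tumour-world state vectors


def state_variables(world: World, agent: CellAgent,
                    plcg_sum: float, plcg_n: int) -> dict[str, float]:
    """The per-type state variables, plus derived policy inputs."""
    p = agent.site
    if agent.ctype in TISSUE_TYPES:
        n_h = float(world.nb_counts["healthy"][p])
        n_c = float(world.nb_counts["cancerous"][p])
        others = plcg_n - 1
        mean_others = (plcg_sum - agent.plcg) / others if others > 0 else 0.0
        return {
            "oxygen": float(world.fields["oxygen"].C[p]),
            "glucose": float(world.fields["glucose"].C[p]),
            "division_counter": float(agent.division_counter),
            "prolif_delay": float(agent.prolif_delay),
            "hypoxia_counter": float(agent.hypoxia_counter),
            "plcg": float(agent.plcg),
            "plcg_excess": float(agent.plcg - mean_others),
            "n_healthy_nb": n_h,
            "n_cancerous_nb": n_c,
            "n_neighbors": n_h + n_c,
            "tnf_alpha": float(world.fields["tnf_alpha"].C[p]),
            "is_cancerous": 1.0 if agent.ctype == "cancerous" else 0.0,
        }
    return {
        "vegf": float(world.fields["vegf"].C[p]),
        "tip_age": float(agent.tip_age),
        "is_tip": 1.0 if agent.ctype == "tip" else 0.0,
    }


def feature_vector(state: dict[str, float], category: str) -> np.ndarray:
    return np.array([state[k] for k in FEATURE_LAYOUT[category]])


def _category(ctype: str) -> str:
    return "tissue" if ctype in TISSUE_TYPES else "vessel"


# ---------------------------------------------------------------------------
# Ensemble-backed learner


class QLearner:
    """Sliding window + SVR ensemble for one agent category."""

    def __init__(self, category: str, params: LearningParams,
                 rng: np.random.Generator):
        self.category = category
        self.params = params
        self.rng = rng
        self.window = ExperienceWindow(params.window)
        self.ensemble: RegressorEnsemble | None = None
        self.action_space = (TISSUE_ACTIONS if category == "tissue"
                             else VESSEL_ACTIONS)

    @property
    def ready(self) -> bool:
        return self.ensemble is not None

    def predict_batch(self, probes: list[tuple[np.ndarray, str]]) -> np.ndarray:
        if not probes:
            return np.zeros(0)
        if self.ensemble is None:
            return np.zeros(len(probes))
        X = np.array([_with_action(s, a, self.action_space) for s, a in probes])
        return self.ensemble.predict(X)

    def refit(self) -> None:
        p = self.params
        X, y = self.window.to_arrays(self.action_space)
        try:
            self.ensemble = fit_ensemble(
                X, y, p.c_range, p.eps_range, p.gamma_range,
                p.nsga_pop, p.nsga_gens, self.rng,
                min_samples=p.min_fit_samples,
                fingerprint=f"{self.category}/v{LAYOUT_VERSION}/n{len(y)}")
        except ValueError as err:
            log.debug("%s learner refit skipped: %s", self.category, err)

    def maybe_refit(self, step: int) -> None:
        if len(self.window) >= self.params.min_fit_samples and \
                (step + 1) % self.params.refit_interval == 0:
            self.refit()


# ---------------------------------------------------------------------------
# Tumour-world physics advance and macro step


def advance_fields_and_signaling(world: World, engine: SignalingEngine) -> None:
    """One hour of diffusion (stability-resolved sub-steps) and signalling."""
    cfg = world.config
    geom = cfg.geometry
    for sp, f in world.fields.items():
        n_sub, dt = world.substeps[sp]
        for _ in range(n_sub):
            if sp == "vegf":
                step_vegf(f, world.lattice, dt, world.phenotype_grid, geom)
            else:
                step_nutrient(f, world.lattice, dt, world.phenotype_grid,
                              geom, cfg.agents.necrotic_uptake)

    cells = sorted(world.live_tissue(), key=lambda a: a.id)
    if cells:
        sites = tuple(np.array([a.site[i] for a in cells]) for i in range(3))
        state = SignalingState(
            plcg=np.array([a.plcg for a in cells]),
            egfr_bound=np.array([a.egfr_bound for a in cells]),
            death_signal=np.array([a.death_signal for a in cells]),
            tnfr_bound=np.array([a.tnfr_bound for a in cells]),
            tgf_consumed=np.zeros(len(cells)),
            tnf_consumed=np.zeros(len(cells)))
        tgf = world.fields["tgf_alpha"].C[sites]
        tnf = world.fields["tnf_alpha"].C[sites]
        engine.integrate_egfr(tgf, state, 1.0)
        engine.integrate_tnf(tnf, state, 1.0)
        # conservative field coupling: remove exactly what was consumed
        world.fields["tgf_alpha"].C[sites] = tgf - state.tgf_consumed
        world.fields["tnf_alpha"].C[sites] = tnf - state.tnf_consumed
        for i, a in enumerate(cells):
            a.plcg = float(state.plcg[i])
            a.egfr_bound = float(state.egfr_bound[i])
            a.death_signal = float(state.death_signal[i])
            a.tnfr_bound = float(state.tnfr_bound[i])


# -- vectorised per-category batch helpers (the scalar operations above are
#    the reference semantics; a unit test pins the equivalence) --------------


def _gather_vars(world: World, agents: list[CellAgent], category: str,
                 plcg_sum: float, plcg_n: int) -> dict[str, np.ndarray]:
    n = len(agents)
    if category == "tissue":
        sites = tuple(np.array([a.site[i] for a in agents], dtype=np.int64)
                      for i in range(3))
        plcg = np.array([a.plcg for a in agents])
        others = plcg_n - 1
        mean_others = (plcg_sum - plcg) / others if others > 0 \
            else np.zeros(n)
        n_h = world.nb_counts["healthy"][sites]
        n_c = world.nb_counts["cancerous"][sites]
        return {
            "oxygen": world.fields["oxygen"].C[sites],
            "glucose": world.fields["glucose"].C[sites],
            "division_counter": np.array([float(a.division_counter)
                                          for a in agents]),
            "prolif_delay": np.array([a.prolif_delay for a in agents]),
            "hypoxia_counter": np.array([a.hypoxia_counter for a in agents]),
            "plcg": plcg,
            "plcg_excess": plcg - mean_others,
            "n_healthy_nb": n_h,
            "n_cancerous_nb": n_c,
            "n_neighbors": n_h + n_c,
            "tnf_alpha": world.fields["tnf_alpha"].C[sites],
            "is_cancerous": np.array([1.0 if a.ctype == "cancerous" else 0.0
                                      for a in agents]),
        }
    sites = tuple(np.array([a.site[i] for a in agents], dtype=np.int64)
                  for i in range(3))
    return {
        "vegf": world.fields["vegf"].C[sites],
        "tip_age": np.array([a.tip_age for a in agents]),
        "is_tip": np.array([1.0 if a.ctype == "tip" else 0.0
                            for a in agents]),
    }


_CAT_TYPES = {"tissue": TISSUE_TYPES, "vessel": VESSEL_TYPES}


def _allowed_matrix(ctypes: np.ndarray, category: str) -> np.ndarray:
    space = TISSUE_ACTIONS if category == "tissue" else VESSEL_ACTIONS
    out = np.zeros((len(ctypes), len(space)), dtype=bool)
    for ct in set(ctypes.tolist()):
        acts = allowed_actions(ct)
        row = np.array([a in acts for a in space])
        out[ctypes == ct] = row
    return out


def _batch_bias(varr: dict[str, np.ndarray], ctypes: np.ndarray,
                rules, category: str, strength: float) -> np.ndarray:
    """(N, A) policy-bias weights; zero for disallowed/hard-gated actions."""
    space = TISSUE_ACTIONS if category == "tissue" else VESSEL_ACTIONS
    col = {a: i for i, a in enumerate(space)}
    W = _allowed_matrix(ctypes, category).astype(float)
    for rule in rules:
        if rule.variable not in varr:
            continue
        rows = np.isin(ctypes, rule.cell_types)
        if not rows.any():
            continue
        rf = rule.direction * np.tanh(
            (varr[rule.variable][rows] - rule.threshold) / rule.gradient)
        for a in rule.favors:
            if a in col:
                W[rows, col[a]] *= np.exp(strength * rf)
        for a in rule.disfavors:
            if a in col:
                W[rows, col[a]] *= np.exp(-strength * rf)
        if rule.hard_gates:
            gated = np.flatnonzero(rows)[varr[rule.variable][rows]
                                         <= rule.threshold]
            for a in rule.hard_gates:
                if a in col:
                    W[gated, col[a]] = 0.0
    return W


def _batch_reward(varr: dict[str, np.ndarray], ctypes: np.ndarray,
                  rules) -> np.ndarray:
    """Mean applicable per-policy reward term per agent."""
    tot = np.zeros(len(ctypes))
    cnt = np.zeros(len(ctypes))
    for rule in rules:
        if rule.variable not in varr:
            continue
        rows = np.isin(ctypes, rule.cell_types)
        if not rows.any():
            continue
        rf = rule.direction * np.tanh(
            (varr[rule.variable][rows] - rule.threshold) / rule.gradient)
        tot[rows] += rf
        cnt[rows] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)


def _batch_draw(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One weighted draw per row; uniform over columns when a row is all 0."""
    W = np.where(W > 0.0, W, 0.0)
    totals = W.sum(axis=1)
    bad = totals <= 0.0
    if bad.any():
        W = W.copy()
        W[bad] = 1.0
        totals = W.sum(axis=1)
    cum = np.cumsum(W, axis=1)
    r = rng.random(len(W)) * totals
    return (cum < r[:, None]).sum(axis=1)


def _batch_select(Q: np.ndarray, mask: np.ndarray, mode: str,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-row action choice from Q restricted to mask.

    Train: proportional to shifted-non-negative Q (the scalar
    :func:`select_action_train` semantics, row-wise).  Test: greedy with
    uniform tie-breaks.
    """
    masked = np.where(mask, Q, np.nan)
    if mode == "test":
        mx = np.nanmax(masked, axis=1)
        choice = np.empty(len(Q), dtype=np.int64)
        for i in range(len(Q)):
            best = np.flatnonzero(masked[i] == mx[i])
            choice[i] = best[rng.integers(len(best))]
        return choice
    lo = np.nanmin(masked, axis=1)
    shift = -np.minimum(lo, 0.0) + Q_FLOOR
    W = np.where(mask, Q + shift[:, None], 0.0)
    return _batch_draw(W, rng)


def _feature_matrix(varr: dict[str, np.ndarray], category: str) -> np.ndarray:
    return np.stack([varr[k] for k in FEATURE_LAYOUT[category]], axis=1)


def macro_step(world: World, learners: dict[str, QLearner],
               engine: SignalingEngine, mode: str,
               rng: np.random.Generator) -> dict:
    """One full macro step: decide, advance, act, reward, learn.

    Returns a bookkeeping row (counts, field totals, vessel metrics,
    birth/removal tallies) for the run trace.
    """
    cfg = world.config
    rules = cfg.policies
    strength = cfg.agents.bias_strength

    # vessel cells below the angiogenic VEGF gate, or with no free
    # neighbouring slot, can only rest this step: skip their decision
    # entirely (they still mature) -- saturated or unstimulated vascular
    # beds would otherwise dominate the step cost
    vegf_grid = world.fields["vegf"].C
    gate = cfg.agents.vegf_sprout_threshold
    cap = ((world.lattice.occupant == 0)
           & (world.lattice.endo_count < 4)).astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0   # daughters go to neighbouring sites only
    free_nb = ndimage.correlate(cap, kernel, mode="constant", cval=0.0)
    actives = []
    for a in sorted(world.agents.values(), key=lambda x: x.id):
        if a.frozen:
            continue
        if a.ctype in VESSEL_TYPES and (vegf_grid[a.site] <= gate
                                        or free_nb[a.site] < 1.0):
            a.tip_age += 1.0
            continue
        actives.append(a)
    tissue_live = world.live_tissue()
    plcg_sum = float(sum(a.plcg for a in tissue_live))
    plcg_n = len(tissue_live)

    # -- step 1-5: read states, predict Q per (state, action), select
    by_cat = {cat: [a for a in actives if _category(a.ctype) == cat]
              for cat in ("tissue", "vessel")}
    chosen: dict[int, str] = {}
    feats: dict[int, np.ndarray] = {}
    qrow: dict[int, np.ndarray] = {}
    pre_reward: dict[int, float] = {}
    for cat, agents_c in by_cat.items():
        if not agents_c:
            continue
        space = TISSUE_ACTIONS if cat == "tissue" else VESSEL_ACTIONS
        varr = _gather_vars(world, agents_c, cat, plcg_sum, plcg_n)
        ctypes = np.array([a.ctype for a in agents_c])
        S = _feature_matrix(varr, cat)
        W = _batch_bias(varr, ctypes, rules, cat, strength)
        for a, r in zip(agents_c, _batch_reward(varr, ctypes, rules)):
            pre_reward[a.id] = float(r)
        learner = learners[cat]
        if learner.ready:
            n, A = len(agents_c), len(space)
            X = np.concatenate([np.repeat(S, A, axis=0),
                                np.tile(np.eye(A), (n, 1))], axis=1)
            Q = learner.ensemble.predict(X).reshape(n, A)
            mask = W > 0.0
            mask[~mask.any(axis=1)] = _allowed_matrix(ctypes, cat)[
                ~mask.any(axis=1)]
            if mode == "test":
                picks = _batch_select(Q, mask, mode, rng)
            else:
                # train: proportional to shifted Q, modulated by the
                # policy biases (the rules shift selection probability
                # directly, and they keep one immature fit from drowning
                # out the biology)
                masked = np.where(mask, Q, np.nan)
                lo = np.nanmin(masked, axis=1)
                shift = -np.minimum(lo, 0.0) + Q_FLOOR
                Wsel = np.where(mask, (Q + shift[:, None]) * np.maximum(W, 0.0),
                                0.0)
                picks = _batch_draw(Wsel, rng)
        else:
            Q = np.zeros((len(agents_c), len(space)))
            picks = _batch_draw(W, rng)
        for i, a in enumerate(agents_c):
            chosen[a.id] = space[picks[i]]
            feats[a.id] = S[i]
            qrow[a.id] = Q[i]

    # -- step 6: advance the world, then perform the actions
    advance_fields_and_signaling(world, engine)
    world.refresh_neighbor_stats()   # site selection reads fresh fields

    log_start = len(world.action_log)
    mover_ids = {a.id for a in actives
                 if a.ctype in TISSUE_TYPES
                 and chosen[a.id] in ("migration", "proliferation")}
    movers = [(a, chosen[a.id]) for a in actives if a.id in mover_ids]
    granted = resolve_moves(world, movers, rng)
    realised: dict[int, str] = {}
    for a in actives:
        if a.id not in world.agents:
            continue
        act = chosen[a.id]
        if a.ctype in VESSEL_TYPES and act == "quiescence":
            # endothelial rest is a no-op; cells still mature while resting
            a.tip_age += 1.0
            a.phenotype = "quiescence"
            realised[a.id] = "quiescence"
        elif a.id in mover_ids:
            dest = granted.get(a.id)
            if dest is not None and not world.lattice.can_occupy(dest, a.ctype):
                dest = None  # target taken meanwhile (e.g. by a new sprout)
            realised[a.id] = apply_phenotype(world, a, act, rng, target=dest)
        else:
            realised[a.id] = apply_phenotype(world, a, act, rng)
    env = environmental_transitions(
        world, {cid for cid, act in realised.items() if act == "hypoxia"})
    n_perfused = update_perfusion(world)
    world.refresh_neighbor_stats()
    after = world.counts()
    effects = [rec[4] for rec in world.action_log[log_start:]]

    # -- step 7: rewards, Q updates, admission (train phase only)
    if mode == "train":
        tissue_live = world.live_tissue()
        plcg_sum = float(sum(x.plcg for x in tissue_live))
        plcg_n = len(tissue_live)
        for cat, agents_c in by_cat.items():
            space = TISSUE_ACTIONS if cat == "tissue" else VESSEL_ACTIONS
            learner = learners[cat]
            # a cell that died of its own chosen phenotype is a terminal
            # transition: no successor, no future term
            for a in agents_c:
                if a.id in world.agents or a.id not in chosen:
                    continue
                r = pre_reward[a.id]
                qold = float(qrow[a.id][space.index(chosen[a.id])])
                qnew = q_update(qold, r, 0.0, cfg.learning.eta,
                                cfg.learning.gamma_disc)
                admit_experience(
                    Experience(feats[a.id], chosen[a.id],
                               float(np.clip(qnew, -1, 1)), r, world.t,
                               a.ctype),
                    cfg.learning.theta, learner.window)
            survivors = [a for a in agents_c if a.id in world.agents]
            if not survivors:
                continue
            varr2 = _gather_vars(world, survivors, cat, plcg_sum, plcg_n)
            ctypes2 = np.array([a.ctype for a in survivors])
            rewards = _batch_reward(varr2, ctypes2, rules)
            allowed2 = _allowed_matrix(ctypes2, cat)
            if learner.ready:
                S2 = _feature_matrix(varr2, cat)
                n, A = len(survivors), len(space)
                X2 = np.concatenate([np.repeat(S2, A, axis=0),
                                     np.tile(np.eye(A), (n, 1))], axis=1)
                Q2 = learner.ensemble.predict(X2).reshape(n, A)
            else:
                Q2 = np.zeros((len(survivors), len(space)))
            max_next = np.where(allowed2, Q2, -np.inf).max(axis=1)
            qui = space.index("quiescence")
            for i, a in enumerate(survivors):
                act = chosen[a.id]
                qold = float(qrow[a.id][space.index(act)])
                # an absorbed (quiescent) cell's only future is quiescence
                nxt = float(Q2[i, qui]) if a.frozen else float(max_next[i])
                qnew = q_update(qold, float(rewards[i]), nxt,
                                cfg.learning.eta, cfg.learning.gamma_disc)
                admit_experience(
                    Experience(feats[a.id], act, float(np.clip(qnew, -1, 1)),
                               float(rewards[i]), world.t, a.ctype),
                    cfg.learning.theta, learner.window)
        for learner in learners.values():
            learner.maybe_refit(world.t)

    # -- bookkeeping row (births/removals tallied from the effect log so the
    #    conservation identity cells(t+1) = cells(t) + births - removals holds)
    phen_counts: dict[str, int] = {}
    for act in realised.values():
        phen_counts[act] = phen_counts.get(act, 0) + 1
    eff = {e: effects.count(e) for e in set(effects)}
    row = {
        "step": world.t,
        **{f"n_{k}": v for k, v in after.items()},
        "n_cancer_total": after["cancerous"] + after["necrotic"],
        **{f"phen_{a}": phen_counts.get(a, 0)
           for a in (*TISSUE_ACTIONS, "branch", "expansion", "sprout")},
        **{f"total_{sp}": world.fields[sp].total() for sp in world.fields},
        "vessel_sites": int((world.lattice.vessel > 0).sum()),
        "vessel_length_um": float((world.lattice.vessel > 0).sum()
                                  * cfg.geometry.ds_um),
        "branch_events": eff.get("branched", 0),
        "perfused_segments": n_perfused,
        "n_active": len(actives),
        "births": eff.get("divided", 0),
        "removals": (eff.get("removed", 0) + eff.get("necrotic", 0)
                     + env["starved"] + env["tnf_killed"]),
        "starved": env["starved"],
        "tnf_killed": env["tnf_killed"],
        "vessel_births": (2 * eff.get("branched", 0) + eff.get("sprouted", 0)
                          + eff.get("expanded", 0)),
    }
    world.t += 1
    return row


def _make_learners(cfg: SimulationConfig) -> dict[str, QLearner]:
    return {cat: QLearner(cat, cfg.learning, cfg.rng("learner", cat))
            for cat in ("tissue", "vessel")}


def run_train_phase(config: SimulationConfig, n_steps: int | None = None,
                    world: World | None = None,
                    learners: dict[str, QLearner] | None = None,
                    engine: SignalingEngine | None = None
                    ) -> tuple[dict[str, QLearner], list[dict], World]:
    """Run the train phase: build the dataset while simulating.

    Returns the learners (windows + fitted ensembles), the per-step trace
    rows and the final world.
    """
    world = world if world is not None else initialize_world(config)
    learners = learners if learners is not None else _make_learners(config)
    engine = engine or SignalingEngine()
    rng = config.rng("train-loop")
    n = config.horizon if n_steps is None else n_steps
    trace = [macro_step(world, learners, engine, "train", rng)
             for _ in range(n)]
    return learners, trace, world


def run_test_phase(config: SimulationConfig,
                   learners: dict[str, QLearner],
                   n_steps: int | None = None,
                   world: World | None = None,
                   engine: SignalingEngine | None = None
                   ) -> tuple[list[dict], World]:
    """Run the test phase: greedy action selection with a trained ensemble."""
    world = world if world is not None else initialize_world(config)
    engine = engine or SignalingEngine()
    rng = config.rng("test-loop")
    n = config.horizon if n_steps is None else n_steps
    trace = [macro_step(world, learners, engine, "test", rng)
             for _ in range(n)]
    return trace, world
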