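"""Q-value function approximation: a three-kernel SVR ensemble.

One support-vector regressor per kernel family (RBF, polynomial, sigmoid),
each with its (C, epsilon, gamma) chosen by an NSGA-II multi-objective
search maximising cross-validated recall, precision and F-measure; the
fitted kernels vote with weights equal to their training F-measure.  The
F-measure of a regressor is defined through a sign-agreement binarisation
of the Q labels (a prediction is "positive" when it is > 0), with an
optional k-bin agreement variant.

NSGA-II here is the standard elitist algorithm: fast non-dominated
sorting, crowding distance, binary tournament selection, simulated binary
crossover and polynomial mutation.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "ClassificationCounts", "KernelSpec", "RegressorEnsemble",
    "f_measure", "discretize_for_metrics", "classification_counts",
    "nsga2", "nsga2_search", "fit_ensemble", "predict_q",
    "KERNEL_FAMILIES",
]

log = logging.getLogger(__name__)

KERNEL_FAMILIES = ("rbf", "poly", "sigmoid")


@dataclass
class ClassificationCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("classification counts must be >= 0")

    def __add__(self, other: "ClassificationCounts") -> "ClassificationCounts":
        return ClassificationCounts(self.tp + other.tp, self.fp + other.fp,
                                    self.fn + other.fn, self.tn + other.tn)

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0


def f_measure(counts: ClassificationCounts) -> float:
    """Harmonic mean of precision and recall; 0 when undefined (logged)."""
    r, p = counts.recall, counts.precision
    if r + p == 0.0:
        if counts.tp + counts.fn == 0 or counts.tp + counts.fp == 0:
            log.debug("F-measure undefined (no positives); defined as 0")
        return 0.0
    return 2.0 * r * p / (r + p)


def discretize_for_metrics(q_pred: float, q_true: float,
                           bins: int | None = None) -> ClassificationCounts:
    """One regression pair's contribution to the classification counts.

    Default sign rule: the true class is positive iff q_true > 0 and the
    prediction agrees by its own sign.  With ``bins`` set, prediction and
    truth are mapped onto ``bins`` equal-width bins over [-1, 1] and a
    same-bin pair counts as correct for its true class.
    """
    true_pos = q_true > 0.0
    if bins is None:
        correct = (q_pred > 0.0) == true_pos
    else:
        edges = np.linspace(-1.0, 1.0, bins + 1)
        b = lambda v: int(np.clip(np.digitize(v, edges[1:-1]), 0, bins - 1))  # noqa: E731
        correct = b(q_pred) == b(q_true)
    if true_pos:
        return ClassificationCounts(tp=int(correct), fn=int(not correct))
    return ClassificationCounts(tn=int(correct), fp=int(not correct))


def classification_counts(q_pred: np.ndarray, q_true: np.ndarray,
                          bins: int | None = None) -> ClassificationCounts:
    """Vectorised sum of :func:`discretize_for_metrics` over paired arrays."""
    q_pred = np.asarray(q_pred, dtype=float)
    q_true = np.asarray(q_true, dtype=float)
    if q_pred.shape != q_true.shape:
        raise ValueError("prediction/truth arrays must have equal shape")
    true_pos = q_true > 0.0
    if bins is None:
        correct = (q_pred > 0.0) == true_pos
    else:
        edges = np.linspace(-1.0, 1.0, bins + 1)
        bp = np.clip(np.digitize(q_pred, edges[1:-1]), 0, bins - 1)
        bt = np.clip(np.digitize(q_true, edges[1:-1]), 0, bins - 1)
        correct = bp == bt
    return ClassificationCounts(
        tp=int((correct & true_pos).sum()), fp=int((~correct & ~true_pos).sum()),
        fn=int((~correct & true_pos).sum()), tn=int((correct & ~true_pos).sum()))


@dataclass(frozen=True)
class KernelSpec:
    """One SVR configuration."""

    kernel: str
    C: float
    epsilon: float
    gamma: float

    def __post_init__(self) -> None:
        if self.kernel not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.kernel!r}")
        if not (self.C > 0 and self.epsilon >= 0 and self.gamma > 0):
            raise ValueError("require C > 0, epsilon >= 0, gamma > 0")

    def build(self) -> Pipeline:
        return Pipeline([
            ("scale", StandardScaler()),
            ("svr", SVR(kernel=self.kernel, C=self.C, epsilon=self.epsilon,
                        gamma=self.gamma, max_iter=20_000)),
        ])


# ---------------------------------------------------------------------------
# NSGA-II (maximisation)


def _non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Fast non-dominated sorting of objective rows (all maximised)."""
    n = len(F)
    dominates = (F[:, None, :] >= F[None, :, :]).all(-1) & \
                (F[:, None, :] > F[None, :, :]).any(-1)
    n_dom = dominates.sum(axis=0)          # how many dominate i
    fronts = []
    remaining = np.arange(n)
    counts = n_dom.copy()
    while remaining.size:
        mask = counts[remaining] == 0
        front = remaining[mask]
        if front.size == 0:  # numerical guard; cannot happen with finite F
            front = remaining
        fronts.append(front)
        remaining = remaining[~mask]
        if remaining.size:
            counts[remaining] -= dominates[np.ix_(front, remaining)].sum(axis=0)
    return fronts


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j])
        span = F[order[-1], j] - F[order[0], j]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            d[order[1:-1]] += (F[order[2:], j] - F[order[:-2], j]) / span
    return d


def _sbx(p1: np.ndarray, p2: np.ndarray, lo: np.ndarray, hi: np.ndarray,
         rng: np.random.Generator, eta: float = 15.0) -> tuple[np.ndarray, np.ndarray]:
    u = rng.random(p1.size)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutation(x: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                   rng: np.random.Generator, eta: float = 20.0,
                   prob: float | None = None) -> np.ndarray:
    prob = 1.0 / x.size if prob is None else prob
    y = x.copy()
    for i in range(x.size):
        if rng.random() < prob:
            u = rng.random()
            delta = (2 * u) ** (1 / (eta + 1)) - 1 if u < 0.5 \
                else 1 - (2 * (1 - u)) ** (1 / (eta + 1))
            y[i] = np.clip(x[i] + delta * (hi[i] - lo[i]), lo[i], hi[i])
    return y


def nsga2(evaluate, bounds: np.ndarray, pop_size: int, generations: int,
          rng: np.random.Generator,
          on_generation=None) -> tuple[np.ndarray, np.ndarray]:
    """Generic NSGA-II maximising ``evaluate(x) -> objective tuple``.

    ``bounds`` is ``(n_var, 2)``.  Returns the final non-dominated set as
    ``(X_front, F_front)``.  ``on_generation(X, F)`` is called after each
    generation (used by property tests to watch the front evolve).
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    X = lo + rng.random((pop_size, len(bounds))) * (hi - lo)
    F = np.array([evaluate(x) for x in X], dtype=float)

    def rank_and_crowd(F_):
        fronts = _non_dominated_sort(F_)
        rank = np.empty(len(F_), dtype=int)
        crowd = np.empty(len(F_))
        for r, fr in enumerate(fronts):
            rank[fr] = r
            crowd[fr] = _crowding_distance(F_[fr])
        return fronts, rank, crowd

    fronts, rank, crowd = rank_and_crowd(F)
    if on_generation is not None:
        on_generation(X[fronts[0]], F[fronts[0]])

    for _ in range(generations):
        def tournament():
            i, j = rng.integers(pop_size, size=2)
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            return i if crowd[i] >= crowd[j] else j

        children = []
        while len(children) < pop_size:
            c1, c2 = _sbx(X[tournament()], X[tournament()], lo, hi, rng)
            children.append(_poly_mutation(c1, lo, hi, rng))
            if len(children) < pop_size:
                children.append(_poly_mutation(c2, lo, hi, rng))
        CX = np.array(children)
        CF = np.array([evaluate(x) for x in CX], dtype=float)

        AX, AF = np.vstack([X, CX]), np.vstack([F, CF])
        fronts_all = _non_dominated_sort(AF)
        keep: list[int] = []
        for fr in fronts_all:
            if len(keep) + len(fr) <= pop_size:
                keep.extend(fr.tolist())
            else:
                cd = _crowding_distance(AF[fr])
                order = fr[np.argsort(-cd)]
                keep.extend(order[: pop_size - len(keep)].tolist())
                break
        X, F = AX[keep], AF[keep]
        fronts, rank, crowd = rank_and_crowd(F)
        if on_generation is not None:
            on_generation(X[fronts[0]], F[fronts[0]])

    first = fronts[0]
    return X[first], F[first]


# ---------------------------------------------------------------------------
# SVR hyper-parameter search and the ensemble


def _cv_objectives(spec: KernelSpec, X: np.ndarray, y: np.ndarray,
                   n_folds: int, bins: int | None) -> tuple[float, float, float]:
    """(recall, precision, F-measure) of out-of-fold predictions."""
    n = len(X)
    n_folds = min(n_folds, n)
    idx = np.arange(n)
    counts = ClassificationCounts()
    for k in range(n_folds):
        test = idx[k::n_folds]
        train = np.setdiff1d(idx, test)
        if train.size < 2:
            continue
        model = spec.build()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X[train], y[train])
            pred = model.predict(X[test])
        except Exception:  # degenerate fold (e.g. constant features)
            continue
        counts = counts + classification_counts(pred, y[test], bins)
    return counts.recall, counts.precision, f_measure(counts)


def nsga2_search(X: np.ndarray, y: np.ndarray, kernel: str,
                 c_range=(0.1, 100.0), eps_range=(1e-3, 0.5),
                 gamma_range=(1e-3, 10.0), pop_size: int = 12,
                 generations: int = 6,
                 rng: np.random.Generator | None = None,
                 n_folds: int = 3, bins: int | None = None
                 ) -> tuple[list[KernelSpec], np.ndarray, KernelSpec]:
    """NSGA-II over (C, epsilon, gamma) for one kernel family.

    C and gamma are searched on a log scale.  Returns the non-dominated
    front (specs and objective rows) and the single spec selected from it
    by highest F-measure, ties broken by crowding distance.
    """
    if len(X) == 0:
        raise ValueError("empty training window")
    rng = rng if rng is not None else np.random.default_rng()
    bounds = np.array([
        [np.log10(c_range[0]), np.log10(c_range[1])],
        [eps_range[0], eps_range[1]],
        [np.log10(gamma_range[0]), np.log10(gamma_range[1])],
    ])

    def decode(x: np.ndarray) -> KernelSpec:
        return KernelSpec(kernel, 10.0 ** x[0], float(x[1]), 10.0 ** x[2])

    cache: dict[tuple, tuple[float, float, float]] = {}

    def evaluate(x: np.ndarray) -> tuple[float, float, float]:
        key = tuple(np.round(x, 10))
        if key not in cache:
            cache[key] = _cv_objectives(decode(x), X, y, n_folds, bins)
        return cache[key]

    Xf, Ff = nsga2(evaluate, bounds, pop_size, generations, rng)
    specs = [decode(x) for x in Xf]
    crowd = _crowding_distance(Ff)
    crowd_rank = np.where(np.isinf(crowd), np.finfo(float).max, crowd)
    order = sorted(range(len(specs)),
                   key=lambda i: (-Ff[i, 2], -crowd_rank[i]))
    return specs, Ff, specs[order[0]]


@dataclass
class RegressorEnsemble:
    """Fitted per-kernel SVRs with F-measure voting weights."""

    models: dict[str, Pipeline]
    weights: dict[str, float]
    specs: dict[str, KernelSpec]
    objectives: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    fingerprint: str = ""

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("ensemble weights must be >= 0")

    @property
    def usable(self) -> bool:
        return sum(self.weights.values()) > 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weight-normalised vote of the kernels, clipped to [-1, 1]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        wsum = sum(self.weights.values())
        if wsum <= 0.0:
            raise ValueError("ensemble has all-zero weights")
        out = np.zeros(len(X))
        for fam, model in self.models.items():
            w = self.weights[fam]
            if w > 0.0:
                out += w * model.predict(X)
        return np.clip(out / wsum, -1.0, 1.0)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "RegressorEnsemble":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError("file does not contain a RegressorEnsemble")
        return obj

    def report(self) -> str:
        lines = ["kernel    C        epsilon  gamma    recall  precision  "
                 "F-meas  weight"]
        for fam, spec in self.specs.items():
            r, p, f = self.objectives.get(fam, (float("nan"),) * 3)
            lines.append(
                f"{fam:<9s}{spec.C:<9.3g}{spec.epsilon:<9.3g}{spec.gamma:<9.3g}"
                f"{r:<8.3f}{p:<11.3f}{f:<8.3f}{self.weights[fam]:.3f}")
        return "\n".join(lines)


def fit_ensemble(X: np.ndarray, y: np.ndarray,
                 c_range=(0.1, 100.0), eps_range=(1e-3, 0.5),
                 gamma_range=(1e-3, 10.0), pop_size: int = 12,
                 generations: int = 6,
                 rng: np.random.Generator | None = None,
                 min_samples: int = 10, bins: int | None = None,
                 fingerprint: str = "") -> RegressorEnsemble:
    """Search, fit and weight all three kernel families on one window."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < min_samples:
        raise ValueError(f"training window has {len(X)} < {min_samples} samples")
    rng = rng if rng is not None else np.random.default_rng()
    models, weights, specs, objectives = {}, {}, {}, {}
    for fam in KERNEL_FAMILIES:
        _, _, best = nsga2_search(
            X, y, fam, c_range, eps_range, gamma_range, pop_size,
            generations, rng, bins=bins)
        model = best.build()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        counts = classification_counts(model.predict(X), y, bins)
        models[fam] = model
        specs[fam] = best
        weights[fam] = f_measure(counts)
        objectives[fam] = (counts.recall, counts.precision, weights[fam])
    if sum(weights.values()) == 0.0:
        # degenerate window (e.g. one-sided labels): fall back to equal votes
        log.debug("all kernel F-measures zero; using equal voting weights")
        weights = {fam: 1.0 for fam in KERNEL_FAMILIES}
    return RegressorEnsemble(models, weights, specs, objectives, fingerprint)


def predict_q(ensemble: RegressorEnsemble, features: np.ndarray) -> float:
    """Scalar convenience wrapper around :meth:`RegressorEnsemble.predict`."""
    return float(ensemble.predict(np.atleast_2d(features))[0])
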