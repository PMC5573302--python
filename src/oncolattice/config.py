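"""Model constants, run configuration, validation and deterministic seeding.

Every physical constant of the model (diffusion coefficients, vessel
permeabilities, uptake/production rates, policy thresholds) lives here as a
documented implementation default and can be overridden from a YAML config
file.  Lengths are micrometres, times are hours, concentrations are
normalised units with intravascular oxygen/glucose at 1.0.

A macro step is one hour; diffusion runs on finer sub-steps chosen by
:func:`resolve_substep` so the explicit 26-neighbour stencil stays stable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "FieldParams",
    "GeometryParams",
    "LearningParams",
    "PolicyRule",
    "AgentParams",
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "write_config",
    "resolve_substep",
    "default_config",
    "SPECIES",
    "STABILITY_LIMIT",
]

#: The five continuum species tracked on the lattice.
SPECIES = ("oxygen", "glucose", "tgf_alpha", "tnf_alpha", "vegf")

#: Explicit-scheme stability bound for the 26-neighbour Laplacian:
#: D * dt / dS^2 must not exceed 1/26.
STABILITY_LIMIT = 1.0 / 26.0


class ConfigError(ValueError):
    """Raised when a configuration key violates its documented constraint."""


def _require(cond: bool, key: str, constraint: str) -> None:
    if not cond:
        raise ConfigError(f"config key {key!r}: {constraint}")


@dataclass
class FieldParams:
    """Per-species transport and reaction constants.

    Only the fields relevant to a species are non-zero: vessels exchange
    oxygen, glucose and VEGF through their walls (``Pe``); tissue cells
    secrete TGFα/TNFα at a constant rate (``SO``); VEGF decays globally
    (``omega``) and is produced by cancer cells (``phi_c``).
    """

    species: str
    D: float = 0.0          # diffusion coefficient [um^2/h]
    Pe: float = 0.0         # vessel wall permeability [um/h]
    rho_art: float = 0.0    # intravascular conc., artery-side vessels [conc]
    rho_cap: float = 0.0    # intravascular conc., vein-side vessels [conc]
    SO: float = 0.0         # constant per-cell production [conc/h]
    omega: float = 0.0      # first-order decay rate [1/h]
    beta_c: float = 0.0     # cancer-cell base uptake rate [1/h]
    alpha_n: float = 0.0    # normal-cell uptake rate [1/h]
    phi_c: float = 0.0      # cancer-cell base VEGF production [conc/h]

    def validate(self) -> None:
        _require(self.species in SPECIES, f"fields.{self.species}.species",
                 f"must be one of {SPECIES}")
        for name in ("D", "Pe", "rho_art", "rho_cap", "SO", "omega",
                     "beta_c", "alpha_n", "phi_c"):
            val = getattr(self, name)
            _require(math.isfinite(val) and val >= 0.0,
                     f"fields.{self.species}.{name}", "must be finite and >= 0")


@dataclass
class GeometryParams:
    """Lattice extent, spacing and parent-vessel layout."""

    nx: int = 40
    ny: int = 40
    nz: int = 40
    ds_um: float = 20.0        # lattice spacing [um]; ~ one cell diameter
    r_art_um: float = 6.0      # arteriole radius [um]
    r_cap_um: float = 3.0      # capillary radius [um]
    #: "midfaces" puts the 4 parent arteries on vertical mid-face lines and
    #: the 4 parent veins on the vertical edges; "edges" swaps them.
    artery_layout: str = "midfaces"

    def validate(self) -> None:
        for name in ("nx", "ny", "nz"):
            _require(int(getattr(self, name)) >= 1, f"geometry.{name}", "must be >= 1")
        _require(self.ds_um > 0, "geometry.ds_um", "must be > 0")
        _require(self.r_art_um >= 0, "geometry.r_art_um", "must be >= 0")
        _require(0 <= self.r_cap_um <= self.r_art_um, "geometry.r_cap_um",
                 "must satisfy 0 <= r_cap_um <= r_art_um")
        _require(self.artery_layout in ("midfaces", "edges"),
                 "geometry.artery_layout", "must be 'midfaces' or 'edges'")

    @property
    def n_sites(self) -> int:
        return self.nx * self.ny * self.nz


@dataclass
class LearningParams:
    """Q-learning and SVR/NSGA-II hyper-parameters."""

    eta: float = 0.3             # learning rate, in (0, 1]
    gamma_disc: float = 0.9      # discount factor, in [0, 1)
    theta: float = 0.0           # reward admission threshold (strict >)
    window: int = 200            # sliding-window capacity d [samples]
    min_fit_samples: int = 30    # smallest window the ensemble will fit on
    refit_interval: int = 50     # macro steps between ensemble refits
    nsga_pop: int = 12           # NSGA-II population size
    nsga_gens: int = 6           # NSGA-II generations
    c_range: tuple[float, float] = (0.1, 100.0)      # SVR C search range
    eps_range: tuple[float, float] = (1e-3, 0.5)     # SVR epsilon range
    gamma_range: tuple[float, float] = (1e-3, 10.0)  # kernel gamma range

    def validate(self) -> None:
        _require(0.0 < self.eta <= 1.0, "learning.eta", "must be in (0, 1]")
        _require(0.0 <= self.gamma_disc < 1.0, "learning.gamma_disc",
                 "must be in [0, 1)")
        _require(self.window >= 1, "learning.window", "must be >= 1")
        _require(self.min_fit_samples >= 2, "learning.min_fit_samples", "must be >= 2")
        _require(self.refit_interval >= 1, "learning.refit_interval", "must be >= 1")
        _require(self.nsga_pop >= 4, "learning.nsga_pop", "must be >= 4")
        _require(self.nsga_gens >= 1, "learning.nsga_gens", "must be >= 1")
        for key, rng in (("c_range", self.c_range), ("eps_range", self.eps_range),
                         ("gamma_range", self.gamma_range)):
            _require(len(rng) == 2 and 0 <= rng[0] <= rng[1],
                     f"learning.{key}", "must be an ordered non-negative pair")


@dataclass
class PolicyRule:
    """One state-variable policy: threshold, steepness and action biases.

    ``direction`` is +1 when larger values of the state variable favour the
    survival side of the reward, -1 otherwise.  ``favors``/``disfavors`` name
    the actions whose selection weight is pushed up/down when the rule's
    reward term is positive (and symmetrically down/up when negative).
    ``hard_gates`` lists actions zeroed outright while the raw state value
    is at or below the threshold (the neighbour-count gate on migration and
    the VEGF gate on vessel growth).
    """

    rule_id: int
    variable: str
    threshold: float
    gradient: float
    direction: int = 1
    cell_types: tuple[str, ...] = ("healthy", "cancerous")
    favors: tuple[str, ...] = ()
    disfavors: tuple[str, ...] = ()
    hard_gates: tuple[str, ...] = ()

    def validate(self, allowed: dict[str, frozenset[str]]) -> None:
        _require(self.gradient > 0, f"policies[{self.rule_id}].gradient", "must be > 0")
        _require(self.direction in (-1, 1), f"policies[{self.rule_id}].direction",
                 "must be +1 or -1")
        for ct in self.cell_types:
            _require(ct in allowed, f"policies[{self.rule_id}].cell_types",
                     f"unknown cell type {ct!r}")
        # an affected action must be legal for at least one targeted type
        # (rules may name type-specific phenotypes, e.g. apoptosis vs necrosis)
        union = frozenset().union(*(allowed[ct] for ct in self.cell_types))
        for a in (*self.favors, *self.disfavors, *self.hard_gates):
            _require(a in union, f"policies[{self.rule_id}]",
                     f"action {a!r} not allowed for any of {self.cell_types}")


@dataclass
class AgentParams:
    """Per-cell thresholds and initialisation constants."""

    hypoxia_o2_threshold: float = 0.08   # rule-1 oxygen threshold [conc]
    hypoxia_duration_limit: float = 72.0  # cancer-cell hours of hypoxia before necrosis
    hypoxia_duration_limit_healthy: float = 24.0  # healthy cells starve sooner
    division_limit: int = 3              # rule-3 healthy-cell division budget
                                         # (normal tissue is homeostatic)
    prolif_o2_min: float = 0.02          # oxygen needed to actually divide [conc]
    prolif_delay_threshold: float = 3.0  # rule-4 delay [h] before death bias rises
    glucose_dead: float = 0.02           # rule-2 dead threshold [conc]
    glucose_active: float = 0.15         # rule-2 active threshold [conc]
    tnf_death_threshold: float = 0.30    # rule-8 TNFα threshold [conc]
    vegf_sprout_threshold: float = 0.005  # rule-9 VEGF threshold [conc]
    tip_maturity_psi: float = 10.0       # rule-10 tip age before branching [h]
    neighbor_migration_min: int = 2      # rule-7: migrate only with > this many neighbours
    init_prob: float = 0.70              # per-site occupancy probability at t=0
    seed_radius_um: float = 60.0         # cancer seed sphere radius [um]
    bias_strength: float = 3.0           # exponent scale of policy bias factors
    necrotic_uptake: bool = True         # Eq.-3 schedule taxes necrotic cells at beta_c/8
    init_field_amplitude: float = 1.0    # peak initial oxygen/glucose at vessels [conc]
    init_field_width_um: float = 120.0   # Gaussian decay width of initial nutrients [um]

    def validate(self) -> None:
        _require(self.hypoxia_o2_threshold >= 0, "agents.hypoxia_o2_threshold", ">= 0")
        _require(self.hypoxia_duration_limit > 0, "agents.hypoxia_duration_limit", "> 0")
        _require(self.hypoxia_duration_limit_healthy > 0,
                 "agents.hypoxia_duration_limit_healthy", "> 0")
        _require(self.division_limit >= 1, "agents.division_limit", ">= 1")
        _require(0 <= self.glucose_dead <= self.glucose_active,
                 "agents.glucose_dead", "must satisfy 0 <= dead <= active")
        _require(self.tip_maturity_psi >= 0, "agents.tip_maturity_psi", ">= 0")
        _require(0.0 <= self.init_prob <= 1.0, "agents.init_prob", "must be in [0, 1]")
        _require(self.seed_radius_um >= 0, "agents.seed_radius_um", ">= 0")
        _require(self.bias_strength >= 0, "agents.bias_strength", ">= 0")
        _require(self.neighbor_migration_min >= 0, "agents.neighbor_migration_min", ">= 0")
        _require(self.init_field_width_um > 0, "agents.init_field_width_um", "> 0")


def _default_fields() -> dict[str, FieldParams]:
    # Implementation defaults, not from the source publication's (unavailable)
    # supplementary tables.  Chosen so vessels sustain a nutrient landscape on
    # the 20 um lattice with O(10) diffusion sub-steps per hour.
    return {
        # D/uptake sets a ~60 um supply length around a vessel: tissue more
        # than a few sites from a perfused vessel cannot be sustained, so
        # distant healthy cells regress and angiogenesis must reach the
        # tumour.  Cancer cells consume at ten times the normal rate.
        "oxygen": FieldParams("oxygen", D=200.0, Pe=20.0, rho_art=1.0,
                              rho_cap=0.8, beta_c=0.5, alpha_n=0.05),
        "glucose": FieldParams("glucose", D=200.0, Pe=20.0, rho_art=1.0,
                               rho_cap=0.8, beta_c=0.5, alpha_n=0.05),
        "tgf_alpha": FieldParams("tgf_alpha", D=80.0, SO=0.01),
        "tnf_alpha": FieldParams("tnf_alpha", D=80.0, SO=0.002),
        "vegf": FieldParams("vegf", D=80.0, Pe=10.0, omega=0.05, phi_c=0.05),
    }


def default_policy_rules(agents: AgentParams) -> list[PolicyRule]:
    """The ten state-variable policies, instantiated from agent thresholds.

    Rule 2 (glucose) has two thresholds and is expressed as two entries
    sharing ``rule_id`` 2.  Rule 5 (hypoxia duration) likewise carries a
    secondary low-threshold entry that favours the hypoxia phenotype while
    the counter is short of the necrosis limit.
    """
    tissue = ("healthy", "cancerous")
    return [
        PolicyRule(1, "oxygen", agents.hypoxia_o2_threshold, 0.05, +1, tissue,
                   favors=("proliferation", "migration"),
                   disfavors=("hypoxia", "necrosis", "apoptosis")),
        PolicyRule(2, "glucose", agents.glucose_dead, 0.02, +1, tissue,
                   favors=(), disfavors=("necrosis", "apoptosis")),
        PolicyRule(2, "glucose", agents.glucose_active, 0.05, +1, tissue,
                   favors=("proliferation", "migration")),
        # the mid-glucose drift into quiescence applies to healthy cells only
        PolicyRule(2, "glucose", agents.glucose_active, 0.05, +1, ("healthy",),
                   disfavors=("quiescence",)),
        PolicyRule(3, "division_counter", float(agents.division_limit), 2.0, -1,
                   ("healthy",), favors=("proliferation",),
                   disfavors=("quiescence",)),
        PolicyRule(4, "prolif_delay", agents.prolif_delay_threshold, 1.0, -1, tissue,
                   favors=(), disfavors=("hypoxia", "necrosis", "apoptosis")),
        # the duration gate appears twice: starvation-driven death should
        # follow *sustained* deprivation, so while the counter is short of
        # the limit its suppression outweighs the instantaneous
        # low-oxygen/low-glucose death drives of rules 1 and 2
        PolicyRule(5, "hypoxia_counter", agents.hypoxia_duration_limit, 4.0, -1,
                   tissue, favors=(), disfavors=("necrosis", "apoptosis")),
        PolicyRule(5, "hypoxia_counter", agents.hypoxia_duration_limit, 4.0, -1,
                   tissue, favors=(), disfavors=("necrosis", "apoptosis")),
        PolicyRule(5, "hypoxia_counter", 1.0, 1.0, -1, tissue,
                   favors=(), disfavors=("hypoxia",)),
        PolicyRule(6, "plcg_excess", 0.0, 0.1, +1, tissue,
                   favors=("proliferation",), disfavors=("migration",)),
        PolicyRule(7, "n_neighbors", float(agents.neighbor_migration_min), 1.0, -1,
                   tissue, favors=(), disfavors=("migration",),
                   hard_gates=("migration",)),
        PolicyRule(8, "tnf_alpha", agents.tnf_death_threshold, 0.1, -1, tissue,
                   favors=(), disfavors=("necrosis", "apoptosis")),
        PolicyRule(9, "vegf", agents.vegf_sprout_threshold, 0.02, +1,
                   ("stalk", "tip"), favors=("sprout", "branch", "expansion"),
                   hard_gates=("sprout", "branch", "expansion")),
        PolicyRule(10, "tip_age", agents.tip_maturity_psi, 2.0, +1, ("tip",),
                   favors=("branch",), disfavors=("expansion", "quiescence")),
    ]


@dataclass
class SimulationConfig:
    """A fully resolved, validated run configuration."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    fields: dict[str, FieldParams] = field(default_factory=_default_fields)
    learning: LearningParams = field(default_factory=LearningParams)
    agents: AgentParams = field(default_factory=AgentParams)
    policies: list[PolicyRule] = field(default_factory=list)
    horizon: int = 504            # macro steps (one hour each)
    snapshot_interval: int = 50   # macro steps between lattice snapshots
    seed: int = 0
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if not self.policies:
            self.policies = default_policy_rules(self.agents)

    def validate(self) -> "SimulationConfig":
        from .actions import ALLOWED_ACTIONS
        self.geometry.validate()
        _require(set(self.fields) == set(SPECIES), "fields",
                 f"must define exactly the species {SPECIES}")
        for fp in self.fields.values():
            fp.validate()
        self.learning.validate()
        self.agents.validate()
        for rule in self.policies:
            rule.validate(ALLOWED_ACTIONS)
        _require(self.horizon >= 0, "horizon", "must be >= 0")
        _require(self.snapshot_interval >= 1, "snapshot_interval", "must be >= 1")
        _require(0 <= int(self.seed) < 2**63, "seed", "must be a non-negative integer")
        return self

    # -- deterministic seeding -------------------------------------------------

    def rng(self, *stream: Any) -> np.random.Generator:
        """A reproducible generator for a named random stream.

        All stochastic choices in a run (initialisation, tie-breaks, action
        sampling, the genetic search) draw from streams derived from the
        single config seed, so runs are bit-reproducible.
        """
        key = [int(self.seed)] + [_stable_hash(s) for s in stream]
        return np.random.default_rng(np.random.SeedSequence(key))


def _stable_hash(obj: Any) -> int:
    """Process-independent 31-bit hash of a stream label."""
    import zlib
    return zlib.crc32(repr(obj).encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Serialisation

_SECTION_TYPES = {
    "geometry": GeometryParams,
    "learning": LearningParams,
    "agents": AgentParams,
}


def _build_section(cls: type, data: dict, prefix: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"config key {prefix}.{key!r}: unknown key")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            val = data[f.name]
            if isinstance(val, list):
                val = tuple(val)
            coerced[f.name] = val
    return cls(**coerced)


def default_config() -> SimulationConfig:
    return SimulationConfig().validate()


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> SimulationConfig:
    """Load and validate a YAML run configuration.

    Missing sections fall back to the documented defaults; unknown keys and
    invariant violations raise :class:`ConfigError` naming the offending key.
    ``path=None`` with no overrides yields the shipped default config.
    """
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        with open(p) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {p} must contain a mapping")
    if overrides:
        data = {**data, **overrides}

    top_known = set(_SECTION_TYPES) | {
        "fields", "policies", "horizon", "snapshot_interval", "seed", "out_dir"}
    for key in data:
        if key not in top_known:
            raise ConfigError(f"config key {key!r}: unknown key")

    kwargs: dict[str, Any] = {}
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            kwargs[section] = _build_section(cls, dict(data[section]), section)
    if "fields" in data:
        merged = _default_fields()
        for sp, fdata in dict(data["fields"]).items():
            if sp not in SPECIES:
                raise ConfigError(f"config key fields.{sp!r}: unknown species")
            base = dataclasses.asdict(merged[sp])
            for k in fdata:
                if k not in base:
                    raise ConfigError(f"config key fields.{sp}.{k!r}: unknown key")
            base.update(fdata)
            merged[sp] = FieldParams(**base)
        kwargs["fields"] = merged
    if "policies" in data:
        kwargs["policies"] = [
            _build_section(PolicyRule, dict(rd), f"policies[{i}]")
            for i, rd in enumerate(data["policies"])
        ]
    for key in ("horizon", "snapshot_interval", "seed", "out_dir"):
        if key in data:
            kwargs[key] = data[key]
    return SimulationConfig(**kwargs).validate()


def write_config(config: SimulationConfig, path: str | Path) -> Path:
    """Write a fully resolved config; round-trips through load_config."""
    doc = {
        "geometry": dataclasses.asdict(config.geometry),
        "fields": {sp: dataclasses.asdict(fp) for sp, fp in config.fields.items()},
        "learning": dataclasses.asdict(config.learning),
        "agents": dataclasses.asdict(config.agents),
        "policies": [dataclasses.asdict(r) for r in config.policies],
        "horizon": config.horizon,
        "snapshot_interval": config.snapshot_interval,
        "seed": int(config.seed),
        "out_dir": config.out_dir,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_tuples_to_lists(doc), fh, sort_keys=False)
    return path


def _tuples_to_lists(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# Diffusion sub-step resolution


def resolve_substep(field_params: FieldParams, ds: float,
                    dt_macro: float = 1.0) -> tuple[int, float]:
    """Smallest number of equal sub-steps keeping the explicit scheme stable.

    Returns ``(n_sub, dt_diff)`` with ``n_sub * dt_diff == dt_macro`` and
    ``D * dt_diff / ds**2 <= 1/26``.  ``D == 0`` needs no subdivision.
    """
    if ds <= 0:
        raise ConfigError("config key geometry.ds_um: must be > 0")
    D = field_params.D
    if D < 0:
        raise ConfigError(f"config key fields.{field_params.species}.D: must be >= 0")
    if D == 0.0:
        return 1, dt_macro
    number = D * dt_macro / ds**2
    n_sub = max(1, math.ceil(number / STABILITY_LIMIT))
    # guard against float round-up error at exact multiples
    while n_sub > 1 and D * (dt_macro / (n_sub - 1)) / ds**2 <= STABILITY_LIMIT:
        n_sub -= 1
    return n_sub, dt_macro / n_sub
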