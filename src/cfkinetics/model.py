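"""Kinetic model core: species, mechanistic rate laws, and ODE assembly.

The package models cell-free NADH assays built around two dehydrogenases:

* FDH (formate dehydrogenase): NAD+ (A) + formate (B) -> NADH (Q) + CO2 (C),
  described by an irreversible ordered bi-bi rate law with competitive NADH
  product inhibition.
* BDH (2,3-butanediol dehydrogenase): acetoin (S) + NADH (Q) <-> 2,3-butanediol
  (P) + NAD+ (A), described by reversible convenience kinetics constrained by
  the Haldane thermodynamic relationship.
* Non-enzymatic first-order NADH decomposition Q -> X (inert sink).

Units: concentrations in mM, time in minutes (canonical). Turnover numbers
(kcat, kcatf, kcatr) are stored in 1/s and converted on evaluation; the
decomposition constant kdq is stored in 1/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np

__all__ = [
    "R_GAS",
    "SECONDS_PER_MINUTE",
    "Species",
    "FDHParams",
    "BDHParams",
    "DecompParams",
    "ThermoInfo",
    "Reaction",
    "KineticModel",
    "fdh_rate",
    "bdh_rate",
    "decomp_rate",
    "haldane_keq",
    "haldane_residual",
    "assemble_rhs",
    "fdh_model",
    "bdh_model",
    "binary_model",
    "model_from_yaml",
    "model_from_dict",
]

#: Gas constant in kJ/(mol K).
R_GAS = 8.314e-3

SECONDS_PER_MINUTE = 60.0

#: Species roles recognised by the built-in rate laws.
ROLES = frozenset({"A", "B", "Q", "S", "P", "C", "X"})


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")


def _check_conc(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"concentration {name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"concentration {name} must be >= 0 mM, got {value!r}")


@dataclass(frozen=True)
class Species:
    """A model species.

    Parameters
    ----------
    id
        Short symbol used in stoichiometries and state vectors.
    name
        Human-readable name.
    role
        One of ``A`` (NAD+), ``B`` (formate), ``Q`` (NADH), ``S`` (acetoin),
        ``P`` (2,3-butanediol), ``C`` (CO2), ``X`` (degraded-NADH sink).
    """

    id: str
    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown species role {self.role!r}; expected one of {sorted(ROLES)}")


@dataclass(frozen=True)
class FDHParams:
    """Parameters of the FDH rate law (kcat in 1/s, constants in mM)."""

    kcat: float
    KIA: float
    KIQ: float
    KMA: float
    KMB: float

    def __post_init__(self) -> None:
        for name in ("kcat", "KIA", "KIQ", "KMA", "KMB"):
            _check_positive(name, getattr(self, name))


@dataclass(frozen=True)
class BDHParams:
    """Parameters of the BDH convenience-kinetics rate law.

    kcatf/kcatr in 1/s; Michaelis constants in mM.
    """

    kcatf: float
    kcatr: float
    KMS: float
    KMQ: float
    KMP: float
    KMA: float

    def __post_init__(self) -> None:
        for name in ("kcatf", "kcatr", "KMS", "KMQ", "KMP", "KMA"):
            _check_positive(name, getattr(self, name))


@dataclass(frozen=True)
class DecompParams:
    """First-order NADH decomposition constant, canonical unit 1/min."""

    kdq: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.kdq) or self.kdq < 0:
            raise ValueError(f"kdq must be finite and >= 0, got {self.kdq!r}")

    @classmethod
    def from_per_hour(cls, kdq_per_hour: float) -> "DecompParams":
        """Build from a rate constant expressed in 1/h."""
        return cls(kdq_per_hour / 60.0)


@dataclass(frozen=True)
class ThermoInfo:
    """Standard Gibbs free energy and temperature defining Keq.

    dG0, dG0_sd in kJ/mol; T in K; R fixed at 8.314e-3 kJ/(mol K).
    """

    dG0: float
    dG0_sd: float = 0.0
    T: float = 310.15
    R: float = R_GAS

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.T!r}")

    def keq(self) -> float:
        return haldane_keq(self)


def fdh_rate(p: FDHParams, A: float, B: float, Q: float, E: float) -> float:
    """FDH reaction rate in mM/min.

    Irreversible ordered bi-bi law with competitive product (NADH) inhibition::

        v = 60 * kcat * A * B * E
            / (KIA*KMB + KMB*A + KMA*B + A*B + (KIA*KMB/KIQ)*Q + (KMA/KIQ)*B*Q)

    The factor 60 converts kcat from 1/s to 1/min. Every denominator term
    carries mM^2, so the expression is dimensionally consistent and the
    denominator is bounded below by KIA*KMB > 0.
    """
    for name, c in (("A", A), ("B", B), ("Q", Q), ("E", E)):
        _check_conc(name, c)
    num = SECONDS_PER_MINUTE * p.kcat * A * B * E
    den = (
        p.KIA * p.KMB
        + p.KMB * A
        + p.KMA * B
        + A * B
        + (p.KIA * p.KMB / p.KIQ) * Q
        + (p.KMA / p.KIQ) * B * Q
    )
    return num / den


def bdh_rate(p: BDHParams, S: float, Q: float, P: float, A: float, E: float) -> float:
    """BDH convenience-kinetics rate in mM/min, positive acetoin -> butanediol.

    ::

        v = 60 * E * [kcatf*(S/KMS)*(Q/KMQ) - kcatr*(P/KMP)*(A/KMA)]
            / [(1+S/KMS)*(1+Q/KMQ) + (1+P/KMP)*(1+A/KMA) - 1]

    The denominator is >= 1 for non-negative concentrations.
    """
    for name, c in (("S", S), ("Q", Q), ("P", P), ("A", A), ("E", E)):
        _check_conc(name, c)
    s, q, pp, a = S / p.KMS, Q / p.KMQ, P / p.KMP, A / p.KMA
    num = SECONDS_PER_MINUTE * E * (p.kcatf * s * q - p.kcatr * pp * a)
    den = (1.0 + s) * (1.0 + q) + (1.0 + pp) * (1.0 + a) - 1.0
    return num / den


def decomp_rate(p: DecompParams, Q: float) -> float:
    """Consumption flux of NADH by first-order decomposition, mM/min.

    The contribution to dQ/dt is ``-decomp_rate(p, Q)``.
    """
    _check_conc("Q", Q)
    return p.kdq * Q


def haldane_keq(thermo: ThermoInfo) -> float:
    """Equilibrium constant from the standard Gibbs free energy.

    Keq = exp(-dG0 / (R*T)), dimensionless.
    """
    if thermo.T <= 0:
        raise ValueError("temperature must be > 0 K")
    return math.exp(-thermo.dG0 / (thermo.R * thermo.T))


def haldane_residual(p: BDHParams, keq: float) -> float:
    """Deviation of the kinetic-parameter ratio from the Haldane equality.

    Returns ``kcatf*KMP*KMA/(kcatr*KMS*KMQ) - Keq``; zero when the rate-law
    parameters are thermodynamically consistent.
    """
    if keq <= 0:
        raise ValueError(f"Keq must be > 0, got {keq!r}")
    return p.kcatf * p.KMP * p.KMA / (p.kcatr * p.KMS * p.KMQ) - keq


# ---------------------------------------------------------------------------
# Rate-law registry and model container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _RateLaw:
    param_names: tuple
    roles: tuple  # species roles read by the law
    needs_enzyme: bool
    stoich_by_role: Mapping[str, float]  # canonical stoichiometry per role


_RATE_LAWS: dict[str, _RateLaw] = {
    "fdh": _RateLaw(
        param_names=("kcat", "KIA", "KIQ", "KMA", "KMB"),
        roles=("A", "B", "Q"),
        needs_enzyme=True,
        stoich_by_role={"A": -1, "B": -1, "Q": +1, "C": +1},
    ),
    "bdh": _RateLaw(
        param_names=("kcatf", "kcatr", "KMS", "KMQ", "KMP", "KMA"),
        roles=("S", "Q", "P", "A"),
        needs_enzyme=True,
        stoich_by_role={"S": -1, "Q": -1, "P": +1, "A": +1},
    ),
    "decomp": _RateLaw(
        param_names=("kdq",),
        roles=("Q",),
        needs_enzyme=False,
        stoich_by_role={"Q": -1, "X": +1},
    ),
}


@dataclass
class Reaction:
    """A reaction with a named rate law.

    ``params`` maps the rate law's parameter names (e.g. ``kcat``) to entries
    of the model's parameter vector (e.g. ``kcat_fdh``); enzymatic laws
    additionally require an ``E`` mapping giving the parameter holding the
    enzyme concentration. ``custom_rate`` supports user-defined laws and is
    called as ``custom_rate(params: dict, conc: dict[species_id, mM]) -> mM/min``.
    """

    id: str
    stoichiometry: Mapping[str, float]
    rate_law: str
    params: Mapping[str, str] = field(default_factory=dict)
    custom_rate: Optional[Callable] = None


@dataclass
class KineticModel:
    """Species, reactions, and a named parameter vector with bounds."""

    species: list
    reactions: list
    params: dict
    bounds: dict = field(default_factory=dict)
    thermo: Optional[ThermoInfo] = None

    def __post_init__(self) -> None:
        roles = [s.role for s in self.species]
        if len(set(roles)) != len(roles):
            raise ValueError("species roles must be unique within a model")
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("species ids must be unique within a model")
        self._validate_reactions()
        for name, (lo, hi) in self.bounds.items():
            if lo < 0:
                raise ValueError(f"bound for {name} must be non-negative, got lo={lo}")
            if hi < lo:
                raise ValueError(f"bound for {name} has hi < lo")

    # -- helpers ----------------------------------------------------------
    @property
    def species_ids(self) -> list:
        return [s.id for s in self.species]

    def species_by_role(self, role: str) -> Species:
        for s in self.species:
            if s.role == role:
                return s
        raise KeyError(f"no species with role {role!r}")

    def index_of(self, species_id: str) -> int:
        return self.species_ids.index(species_id)

    def _validate_reactions(self) -> None:
        role_of = {s.id: s.role for s in self.species}
        for rxn in self.reactions:
            if rxn.rate_law == "user-defined":
                if rxn.custom_rate is None:
                    raise ValueError(f"reaction {rxn.id}: user-defined law needs custom_rate")
                continue
            if rxn.rate_law not in _RATE_LAWS:
                raise ValueError(f"reaction {rxn.id}: unknown rate law {rxn.rate_law!r}")
            law = _RATE_LAWS[rxn.rate_law]
            # stoichiometry must be mass-consistent with the canonical law
            by_role = {role_of[sid]: coef for sid, coef in rxn.stoichiometry.items()}
            for role, coef in law.stoich_by_role.items():
                if by_role.get(role, 0.0) != coef:
                    raise ValueError(
                        f"reaction {rxn.id}: stoichiometry inconsistent with "
                        f"{rxn.rate_law} law for role {role} (expected {coef})"
                    )
            for pname in law.param_names:
                ref = rxn.params.get(pname)
                if ref is None or ref not in self.params:
                    raise ValueError(
                        f"reaction {rxn.id}: parameter {pname!r} must map to an "
                        f"entry of the model parameter vector"
                    )
            if law.needs_enzyme:
                ref = rxn.params.get("E")
                if ref is None or ref not in self.params:
                    raise ValueError(
                        f"reaction {rxn.id}: enzymatic law requires an enzyme "
                        f"concentration parameter mapping 'E'"
                    )

    def rate(self, rxn: Reaction, params: Mapping[str, float], conc: Mapping[str, float]) -> float:
        """Evaluate one reaction rate (mM/min) at given concentrations."""
        if rxn.rate_law == "user-defined":
            return rxn.custom_rate(dict(params), dict(conc))
        law = _RATE_LAWS[rxn.rate_law]
        get = lambda pname: params[rxn.params[pname]]
        by_role = {
            role: conc[self.species_by_role(role).id] for role in law.roles
        }
        if rxn.rate_law == "fdh":
            p = FDHParams(get("kcat"), get("KIA"), get("KIQ"), get("KMA"), get("KMB"))
            return fdh_rate(p, by_role["A"], by_role["B"], by_role["Q"], get("E"))
        if rxn.rate_law == "bdh":
            p = BDHParams(
                get("kcatf"), get("kcatr"), get("KMS"), get("KMQ"), get("KMP"), get("KMA")
            )
            return bdh_rate(p, by_role["S"], by_role["Q"], by_role["P"], by_role["A"], get("E"))
        if rxn.rate_law == "decomp":
            return decomp_rate(DecompParams(get("kdq")), by_role["Q"])
        raise ValueError(f"unknown rate law {rxn.rate_law!r}")  # pragma: no cover


def assemble_rhs(
    model: KineticModel,
    params: Mapping[str, float],
    feed=None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the ODE right-hand side ``f(t, x) -> dx/dt`` for the model.

    The state vector follows ``model.species_ids``. Each species derivative is
    the stoichiometry-weighted sum of reaction rates plus, if ``feed`` is
    given, the feed rate for fed species at time ``t``. Concentrations are
    floored at zero before rate evaluation so that small negative integrator
    excursions cannot produce spurious fluxes. Rate laws are compiled to
    index-based closures once, so the returned function is cheap enough for
    Newton iterations inside the fitting loop.
    """
    ids = model.species_ids
    index = {sid: i for i, sid in enumerate(ids)}
    n = len(ids)
    params = dict(params)

    compiled = []  # (stoich_vector, rate_fn(x) -> mM/min)
    for rxn in model.reactions:
        sv = np.zeros(n)
        for sid, coef in rxn.stoichiometry.items():
            sv[index[sid]] = coef
        compiled.append((sv, _compile_rate(model, rxn, params, index)))

    if feed is not None:
        fed_ids = sorted({seg[2] for seg in getattr(feed, "segments", [])}
                         & set(ids)) or [sid for sid in ids]

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        xc = np.maximum(x, 0.0)
        dx = np.zeros(n)
        for sv, rate_fn in compiled:
            dx += sv * rate_fn(xc)
        if feed is not None:
            for sid in fed_ids:
                dx[index[sid]] += feed.rate_at(t, sid)
        return dx

    return rhs


def _compile_rate(model: KineticModel, rxn: Reaction, params: Mapping[str, float],
                  index: Mapping[str, int]) -> Callable[[np.ndarray], float]:
    """Bind one reaction's parameters and species indices into a closure."""
    if rxn.rate_law == "user-defined":
        p = dict(params)
        ids = list(index)

        def user_rate(x: np.ndarray) -> float:
            return rxn.custom_rate(p, {sid: x[index[sid]] for sid in ids})

        return user_rate

    get = lambda pname: float(params[rxn.params[pname]])
    at = lambda role: index[model.species_by_role(role).id]

    if rxn.rate_law == "fdh":
        kcat60 = SECONDS_PER_MINUTE * get("kcat")
        KIA, KIQ, KMA, KMB = get("KIA"), get("KIQ"), get("KMA"), get("KMB")
        E = get("E")
        iA, iB, iQ = at("A"), at("B"), at("Q")
        c0 = KIA * KMB
        cQ = KIA * KMB / KIQ
        cBQ = KMA / KIQ

        def fdh(x: np.ndarray) -> float:
            A, B, Q = x[iA], x[iB], x[iQ]
            return (kcat60 * A * B * E) / (
                c0 + KMB * A + KMA * B + A * B + cQ * Q + cBQ * B * Q
            )

        return fdh

    if rxn.rate_law == "bdh":
        kf60 = SECONDS_PER_MINUTE * get("kcatf")
        kr60 = SECONDS_PER_MINUTE * get("kcatr")
        KMS, KMQ, KMP, KMA = get("KMS"), get("KMQ"), get("KMP"), get("KMA")
        E = get("E")
        iS, iQ, iP, iA = at("S"), at("Q"), at("P"), at("A")

        def bdh(x: np.ndarray) -> float:
            s, q = x[iS] / KMS, x[iQ] / KMQ
            pp, a = x[iP] / KMP, x[iA] / KMA
            num = E * (kf60 * s * q - kr60 * pp * a)
            den = (1.0 + s) * (1.0 + q) + (1.0 + pp) * (1.0 + a) - 1.0
            return num / den

        return bdh

    if rxn.rate_law == "decomp":
        kdq = get("kdq")
        iQ = at("Q")

        def decomp(x: np.ndarray) -> float:
            return kdq * x[iQ]

        return decomp

    raise ValueError(f"unknown rate law {rxn.rate_law!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Built-in model factories
# ---------------------------------------------------------------------------

DEFAULT_BOUNDS = (1e-4, 1e4)

#: Standard Gibbs free energy of the acetoin + NADH -> 2,3-butanediol + NAD+
#: reaction (kJ/mol) and its uncertainty, at assay temperature 37 C.
BDH_THERMO = ThermoInfo(dG0=-22.5, dG0_sd=4.1, T=310.15)


def fdh_model(
    params: Optional[Mapping[str, float]] = None,
    bounds: Optional[Mapping[str, tuple]] = None,
) -> KineticModel:
    """FDH assay model: A + B -> Q + C plus NADH decomposition Q -> X."""
    species = [
        Species("A", "NAD+", "A"),
        Species("B", "formate", "B"),
        Species("Q", "NADH", "Q"),
        Species("C", "CO2", "C"),
        Species("X", "degraded NADH", "X"),
    ]
    default = {
        "kcat": 0.18,
        "KIA": 78.14,
        "KIQ": 0.118,
        "KMA": 0.0384,
        "KMB": 0.472,
        "kdq": 3.45e-2 / 60.0,  # 1/min
        "E_fdh": 1.0,
    }
    if params:
        default.update(params)
    b = {k: DEFAULT_BOUNDS for k in ("kcat", "KIA", "KIQ", "KMA", "KMB")}
    b["kdq"] = (0.0, 1.0)
    if bounds:
        b.update(bounds)
    reactions = [
        Reaction(
            id="FDH",
            stoichiometry={"A": -1, "B": -1, "Q": +1, "C": +1},
            rate_law="fdh",
            params={"kcat": "kcat", "KIA": "KIA", "KIQ": "KIQ", "KMA": "KMA",
                    "KMB": "KMB", "E": "E_fdh"},
        ),
        Reaction(
            id="NADH_decomp",
            stoichiometry={"Q": -1, "X": +1},
            rate_law="decomp",
            params={"kdq": "kdq"},
        ),
    ]
    return KineticModel(species=species, reactions=reactions, params=default, bounds=b)


def bdh_model(
    params: Optional[Mapping[str, float]] = None,
    bounds: Optional[Mapping[str, tuple]] = None,
    thermo: ThermoInfo = BDH_THERMO,
) -> KineticModel:
    """BDH assay model: S + Q <-> P + A plus NADH decomposition Q -> X."""
    species = [
        Species("S", "acetoin", "S"),
        Species("Q", "NADH", "Q"),
        Species("P", "2,3-butanediol", "P"),
        Species("A", "NAD+", "A"),
        Species("X", "degraded NADH", "X"),
    ]
    default = {
        "kcatf": 10.0,
        "kcatr": 0.01,
        "KMS": 1.0,
        "KMQ": 0.1,
        "KMP": 10.0,
        "KMA": 1.0,
        "kdq": 1.286e-3,  # 1/min
        "E_bdh": 1.0,
    }
    if params:
        default.update(params)
    b = {k: DEFAULT_BOUNDS for k in ("kcatf", "kcatr", "KMS", "KMQ", "KMP", "KMA")}
    b["kdq"] = (0.0, 1.0)
    if bounds:
        b.update(bounds)
    reactions = [
        Reaction(
            id="BDH",
            stoichiometry={"S": -1, "Q": -1, "P": +1, "A": +1},
            rate_law="bdh",
            params={"kcatf": "kcatf", "kcatr": "kcatr", "KMS": "KMS", "KMQ": "KMQ",
                    "KMP": "KMP", "KMA": "KMA", "E": "E_bdh"},
        ),
        Reaction(
            id="NADH_decomp",
            stoichiometry={"Q": -1, "X": +1},
            rate_law="decomp",
            params={"kdq": "kdq"},
        ),
    ]
    return KineticModel(
        species=species, reactions=reactions, params=default, bounds=b, thermo=thermo
    )


def binary_model(
    fdh_params: Mapping[str, float],
    bdh_params: Mapping[str, float],
    kdq: float = 0.0,
    thermo: ThermoInfo = BDH_THERMO,
) -> KineticModel:
    """Combined FDH + BDH cascade sharing the NAD+/NADH pool.

    Parameter names from the single-enzyme fits are suffixed ``_fdh`` /
    ``_bdh`` where they collide (KMA, kcat variants keep their own names).
    """
    species = [
        Species("A", "NAD+", "A"),
        Species("B", "formate", "B"),
        Species("Q", "NADH", "Q"),
        Species("S", "acetoin", "S"),
        Species("P", "2,3-butanediol", "P"),
        Species("C", "CO2", "C"),
        Species("X", "degraded NADH", "X"),
    ]
    params = {
        "kcat": fdh_params["kcat"],
        "KIA": fdh_params["KIA"],
        "KIQ": fdh_params["KIQ"],
        "KMA_fdh": fdh_params["KMA"],
        "KMB": fdh_params["KMB"],
        "E_fdh": fdh_params.get("E_fdh", 1.0),
        "kcatf": bdh_params["kcatf"],
        "kcatr": bdh_params["kcatr"],
        "KMS": bdh_params["KMS"],
        "KMQ": bdh_params["KMQ"],
        "KMP": bdh_params["KMP"],
        "KMA_bdh": bdh_params["KMA"],
        "E_bdh": bdh_params.get("E_bdh", 1.0),
        "kdq": kdq,
    }
    reactions = [
        Reaction(
            id="FDH",
            stoichiometry={"A": -1, "B": -1, "Q": +1, "C": +1},
            rate_law="fdh",
            params={"kcat": "kcat", "KIA": "KIA", "KIQ": "KIQ", "KMA": "KMA_fdh",
                    "KMB": "KMB", "E": "E_fdh"},
        ),
        Reaction(
            id="BDH",
            stoichiometry={"S": -1, "Q": -1, "P": +1, "A": +1},
            rate_law="bdh",
            params={"kcatf": "kcatf", "kcatr": "kcatr", "KMS": "KMS", "KMQ": "KMQ",
                    "KMP": "KMP", "KMA": "KMA_bdh", "E": "E_bdh"},
        ),
        Reaction(
            id="NADH_decomp",
            stoichiometry={"Q": -1, "X": +1},
            rate_law="decomp",
            params={"kdq": "kdq"},
        ),
    ]
    return KineticModel(species=species, reactions=reactions, params=params, thermo=thermo)


def model_from_dict(cfg: Mapping) -> KineticModel:
    """Build a model from a plain configuration mapping (YAML-friendly)."""
    species = [Species(**s) for s in cfg["species"]]
    reactions = [
        Reaction(
            id=r["id"],
            stoichiometry=dict(r["stoichiometry"]),
            rate_law=r["rate_law"],
            params=dict(r.get("params", {})),
        )
        for r in cfg["reactions"]
    ]
    thermo = None
    if "thermo" in cfg and cfg["thermo"] is not None:
        thermo = ThermoInfo(**cfg["thermo"])
    bounds = {k: tuple(v) for k, v in cfg.get("bounds", {}).items()}
    return KineticModel(
        species=species,
        reactions=reactions,
        params=dict(cfg["params"]),
        bounds=bounds,
        thermo=thermo,
    )


def model_from_yaml(path) -> KineticModel:
    """Load a model definition from a YAML file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return model_from_dict(cfg)
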