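"""Kinetic model of E. coli central carbon metabolism with enzyme levels.

The network couples glycolysis, the pentose phosphate pathway and two
gluconeogenic reactions (PPS, FBP) into 18 balanced metabolites and 32
enzyme-catalysed reactions.  Metabolite dynamics follow

    dC/dt = S · (e(t) ∘ r(C; P)) − μ C

where ``S`` is the stoichiometric matrix, ``r`` the vector of kinetic rate
laws evaluated at constant co-metabolite concentrations, ``e`` the vector of
dimensionless enzyme levels (1.0 = nominal expression) and ``μ`` the
specific growth rate supplying a first-order dilution of every pool into
biomass.

Concentrations are mM, time is seconds, rates are mM/s throughout.

The shipped parameter file (``data/ecoli_ccm.yaml``) carries the transcribed
rate-law parameters, the constant co-metabolite pools, the calibrated
maximal rates and the refined nominal steady state.  Calibration
(`calibrate_network`) fixes the maximal rates of the glucose import step and
of the two gluconeogenic enzymes "top down", i.e. so that every node of the
network balances exactly at the nominal concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import _kinetics as K

__all__ = [
    "ConfigError", "DomainError", "ConvergenceError",
    "MetabolicNetwork", "load_network", "save_network", "load_builtin",
    "enzyme_vector", "rate_vector", "rhs", "find_steady_state",
    "calibrate_network",
]


class ConfigError(ValueError):
    """Malformed network / scenario configuration."""


class DomainError(ValueError):
    """Physically invalid input (e.g. negative concentration)."""


class ConvergenceError(RuntimeError):
    """A numerical routine failed to reach its tolerance."""


# negative concentrations beyond this magnitude abort; smaller ones are
# treated as solver noise and clipped to zero inside rate evaluation
NEG_CLIP = 1e-9


@dataclass
class MetabolicNetwork:
    """Stoichiometry, rate laws, parameters and nominal operating point."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray                      # n_met x n_rxn
    kinds: list[str]                   # rate-law kind per reaction
    rxn_metabolites: list[list[str]]   # state metabolites each law reads
    params: dict[str, dict[str, float]]
    cometabolites: dict[str, float]
    mu: float
    steady_state: np.ndarray
    essential: list[str] = field(default_factory=list)
    inflow: dict[str, float] = field(default_factory=dict)
    name: str = "network"

    # ---- derived packed arrays (built lazily, invalidated on edit) ----
    def __post_init__(self) -> None:
        self._packed: tuple | None = None
        self.validate()

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def metabolite_index(self, name: str) -> int:
        try:
            return self.metabolite_ids.index(name)
        except ValueError:
            raise ConfigError(f"unknown metabolite {name!r}") from None

    def reaction_index(self, name: str) -> int:
        try:
            return self.reaction_ids.index(name)
        except ValueError:
            raise ConfigError(f"unknown reaction {name!r}") from None

    def validate(self) -> None:
        n, m = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (n, m):
            raise ConfigError(
                f"stoichiometric matrix is {self.S.shape}, expected {(n, m)}")
        if len(self.kinds) != m or len(self.rxn_metabolites) != m:
            raise ConfigError("per-reaction metadata length mismatch")
        for rid, kind, mets in zip(self.reaction_ids, self.kinds,
                                   self.rxn_metabolites):
            if kind not in K.KIND_NAMES:
                raise ConfigError(f"reaction {rid}: unknown rate law {kind!r}")
            want = K.PARAM_ORDER[K.KIND_NAMES[kind]]
            have = self.params.get(rid)
            if have is None:
                raise ConfigError(f"reaction {rid}: no parameters")
            missing = [p for p in want if p not in have]
            if missing:
                raise ConfigError(f"reaction {rid}: missing parameters "
                                  f"{missing}")
            if "rmax" in want and not have["rmax"] >= 0:
                raise ConfigError(f"reaction {rid}: rmax must be >= 0")
            for name in mets:
                if name not in self.metabolite_ids:
                    raise ConfigError(
                        f"reaction {rid} references unknown metabolite "
                        f"{name!r}")
        for co in K.CO_ORDER:
            if co not in self.cometabolites:
                raise ConfigError(f"missing co-metabolite {co!r}")
        for met in self.inflow:
            if met not in self.metabolite_ids:
                raise ConfigError(f"inflow on unknown metabolite {met!r}")
        if len(self.steady_state) != n:
            raise ConfigError("steady_state has wrong length")
        self._packed = None

    def packed(self):
        """Arrays for the compiled kernels (kinds, met indices, params, co)."""
        if self._packed is None:
            m = self.n_reactions
            kinds = np.array([K.KIND_NAMES[k] for k in self.kinds],
                             dtype=np.int32)
            midx = np.full((m, 4), -1, dtype=np.int32)
            for j, mets in enumerate(self.rxn_metabolites):
                for slot, name in enumerate(mets):
                    midx[j, slot] = self.metabolite_index(name)
            P = np.zeros((m, K.N_PMAX))
            for j, rid in enumerate(self.reaction_ids):
                order = K.PARAM_ORDER[K.KIND_NAMES[self.kinds[j]]]
                for slot, pname in enumerate(order):
                    P[j, slot] = float(self.params[rid][pname])
            co = np.array([float(self.cometabolites[c]) for c in K.CO_ORDER])
            b = np.zeros(self.n_metabolites)
            for met, v in self.inflow.items():
                b[self.metabolite_index(met)] = float(v)
            self._packed = (kinds, midx, P, co,
                            np.ascontiguousarray(self.S, dtype=float), b)
        return self._packed

    def set_param(self, reaction: str, name: str, value: float) -> None:
        self.reaction_index(reaction)
        self.params[reaction][name] = float(value)
        self._packed = None

    # ---- serialization ----
    def to_dict(self) -> dict:
        triplets = []
        for i, met in enumerate(self.metabolite_ids):
            for j, rid in enumerate(self.reaction_ids):
                if self.S[i, j] != 0.0:
                    triplets.append([met, rid, float(self.S[i, j])])
        return {
            "name": self.name,
            "mu": float(self.mu),
            "metabolites": list(self.metabolite_ids),
            "cometabolites": {k: float(v)
                              for k, v in self.cometabolites.items()},
            "reactions": [
                {"id": rid, "kind": kind, "metabolites": list(mets),
                 "params": {k: float(v)
                            for k, v in self.params[rid].items()}}
                for rid, kind, mets in zip(self.reaction_ids, self.kinds,
                                           self.rxn_metabolites)
            ],
            "stoichiometry": triplets,
            "steady_state": {met: float(c) for met, c in
                             zip(self.metabolite_ids, self.steady_state)},
            "essential": list(self.essential),
            "inflow": {k: float(v) for k, v in self.inflow.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetabolicNetwork":
        try:
            mets = list(d["metabolites"])
            rxns = d["reactions"]
            n, m = len(mets), len(rxns)
            S = np.zeros((n, m))
            rids = [r["id"] for r in rxns]
            for met, rid, coef in d["stoichiometry"]:
                S[mets.index(met), rids.index(rid)] = float(coef)
            return cls(
                metabolite_ids=mets,
                reaction_ids=rids,
                S=S,
                kinds=[r["kind"] for r in rxns],
                rxn_metabolites=[list(r.get("metabolites", [])) for r in rxns],
                params={r["id"]: dict(r["params"]) for r in rxns},
                cometabolites=dict(d["cometabolites"]),
                mu=float(d["mu"]),
                steady_state=np.array([float(d["steady_state"][met])
                                       for met in mets]),
                essential=list(d.get("essential", [])),
                inflow=dict(d.get("inflow", {})),
                name=d.get("name", "network"),
            )
        except (KeyError, ValueError, TypeError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"bad network definition: {exc}") from exc


def load_network(path) -> MetabolicNetwork:
    """Read a network parameter file (YAML)."""
    with open(path) as fh:
        return MetabolicNetwork.from_dict(yaml.safe_load(fh))


def save_network(net: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(net.to_dict(), fh, sort_keys=False)


def load_builtin() -> MetabolicNetwork:
    """The shipped, calibrated E. coli central-carbon-metabolism network."""
    ref = resources.files("pepwave.data") / "ecoli_ccm.yaml"
    return MetabolicNetwork.from_dict(yaml.safe_load(ref.read_text()))


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def _check_state(state: np.ndarray, net: MetabolicNetwork) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (net.n_metabolites,):
        raise DomainError(f"state has shape {state.shape}, expected "
                          f"({net.n_metabolites},)")
    if not np.all(np.isfinite(state)):
        raise DomainError("non-finite concentration in state")
    bad = np.where(state < -NEG_CLIP)[0]
    if bad.size:
        raise DomainError(
            "negative concentration for "
            + ", ".join(net.metabolite_ids[i] for i in bad))
    return np.maximum(state, 0.0)


def enzyme_vector(net: MetabolicNetwork,
                  levels: Mapping[str, float] | None = None) -> np.ndarray:
    """Dense enzyme-level vector, 1.0 everywhere except the given overrides."""
    e = np.ones(net.n_reactions)
    for name, lvl in (levels or {}).items():
        j = net.reaction_index(name)
        if lvl < 0:
            raise DomainError(f"enzyme level for {name} must be >= 0")
        e[j] = float(lvl)
    return e


def rate_vector(state: np.ndarray, enzymes: np.ndarray,
                net: MetabolicNetwork) -> np.ndarray:
    """All 32 reaction rates (mM/s): e_j · r_j(C)."""
    state = _check_state(state, net)
    enzymes = np.asarray(enzymes, dtype=float)
    if enzymes.shape != (net.n_reactions,):
        raise ConfigError("enzyme vector has wrong length")
    if np.any(enzymes < 0):
        raise DomainError("enzyme levels must be >= 0")
    kinds, midx, P, co, _, _ = net.packed()
    return enzymes * K.rates_core(state, co, kinds, midx, P)


def rhs(t: float, state: np.ndarray,
        enzyme_fn: Callable[[float], np.ndarray] | np.ndarray | None,
        net: MetabolicNetwork) -> np.ndarray:
    """Mass-balance derivative S·r − μC at time ``t``.

    ``enzyme_fn`` may be a callable t → levels, a fixed vector, or None
    (all levels 1).
    """
    if enzyme_fn is None:
        e = np.ones(net.n_reactions)
    elif callable(enzyme_fn):
        e = np.asarray(enzyme_fn(t), dtype=float)
    else:
        e = np.asarray(enzyme_fn, dtype=float)
    r = rate_vector(state, e, net)
    _, _, _, _, S, b = net.packed()
    return S @ r + b - net.mu * np.asarray(state, dtype=float)


def _constant_forcing(net: MetabolicNetwork, enzymes: np.ndarray):
    m = net.n_reactions
    z = np.zeros(m)
    return (np.zeros(m, dtype=np.int32), z, z, z,
            np.asarray(enzymes, dtype=float), np.ones(m),
            np.zeros(m), np.full(m, np.inf))


def _rhs_closure(net: MetabolicNetwork, forcing):
    kinds, midx, P, co, S, b = net.packed()
    mu = net.mu
    wkind, A, om, ph, h, sgn, emin, emax = forcing

    def f(t, C):
        # the solver's trial points may dip below zero; rate laws clip
        # those themselves and dilution pushes them back, so only a
        # non-finite state aborts the run (accepted output is checked by
        # the caller)
        if not np.all(np.isfinite(C)):
            raise ConvergenceError(
                f"state became non-finite at t={t:.3f} s")
        return K.rhs_core(t, np.maximum(C, 0.0), S, mu, co, b, kinds, midx,
                          P, wkind, A, om, ph, h, sgn, emin, emax)
    return f


def find_steady_state(net: MetabolicNetwork,
                      enzymes: np.ndarray | None = None,
                      guess: np.ndarray | None = None,
                      tol: float = 1e-8,
                      max_hours: float = 100.0) -> np.ndarray:
    """Steady state of the network at fixed enzyme levels.

    Long-horizon relaxation integration with a Newton (hybr) root refinement
    fallback; raises :class:`ConvergenceError` instead of returning a point
    that misses the tolerance.  ``tol`` bounds the max-norm of dC/dt in mM/s.
    """
    if enzymes is None:
        enzymes = np.ones(net.n_reactions)
    enzymes = np.asarray(enzymes, dtype=float)
    guess = np.array(net.steady_state if guess is None else guess,
                     dtype=float)
    if np.any(guess <= 0):
        raise DomainError("steady-state guess must be strictly positive")
    f = _rhs_closure(net, _constant_forcing(net, enzymes))

    def resid(C):
        return float(np.max(np.abs(f(0.0, C))))

    if resid(guess) < tol:
        return guess

    C = guess
    t_leg, t_total = 2.0e3, 0.0
    max_seconds = max_hours * 3600.0
    while t_total < max_seconds:
        sol = solve_ivp(f, (0.0, t_leg), C, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise ConvergenceError(
                f"relaxation integration failed: {sol.message}")
        C = np.maximum(sol.y[:, -1], 0.0)
        t_total += t_leg
        t_leg = min(t_leg * 4.0, max_seconds - t_total + 1.0)
        if resid(C) < tol:
            return C
        if not np.all(np.isfinite(C)) or np.max(C) > 1e6:
            raise ConvergenceError(
                f"trajectory diverged (|C|max={np.max(C):.3g} mM)")
        # try a Newton polish once the relaxation is in the basin
        if resid(C) < 1e-4:
            sol_r = root(lambda x: f(0.0, x), C, method="hybr",
                         options={"xtol": 1e-13})
            Cr = sol_r.x
            if (sol_r.success and np.all(Cr > -NEG_CLIP)
                    and resid(np.maximum(Cr, 0.0)) < tol):
                return np.maximum(Cr, 0.0)
    raise ConvergenceError(
        f"no steady state within {max_hours} h; final ||dC/dt||inf = "
        f"{resid(C):.3e} mM/s")


# --------------------------------------------------------------------------
# top-down calibration
# --------------------------------------------------------------------------

def calibrate_network(net: MetabolicNetwork,
                      gluconeogenic_fraction: float = 0.05,
                      tol: float = 1e-10) -> MetabolicNetwork:
    """Fix maximal rates so every node balances exactly at the nominal state.

    Three maximal rates are determined "top down" from the nominal
    concentrations rather than taken from in vitro data:

    * ``PTS``: with extracellular glucose held constant the glucose import
      scale is unobservable, so r_max,PTS is set to make the g6p node
      balance (import = consumption by PGI + G6PDH + PGM + dilution).
    * ``PPS`` and ``FBP``: the gluconeogenic reactions run a small futile
      cycle against PK and PFK; their nominal flux is
      ``gluconeogenic_fraction`` of the opposing glycolytic flux, and
      r_max,PK / r_max,PFK are scaled up so the pep/pyr and f6p/fdp nodes
      still balance.

    The nominal steady state is then refined by Newton iteration and stored
    on the returned network, so ``rhs`` vanishes there to ``tol``.
    """
    net = MetabolicNetwork.from_dict(net.to_dict())   # work on a copy
    C = np.array(net.steady_state, dtype=float)
    e1 = np.ones(net.n_reactions)

    def unit_rate(rid: str) -> float:
        """Rate of one reaction at C with its rmax set to 1."""
        saved = net.params[rid]["rmax"]
        net.set_param(rid, "rmax", 1.0)
        v = rate_vector(C, e1, net)[net.reaction_index(rid)]
        net.set_param(rid, "rmax", saved)
        return float(v)

    def flux(rid: str) -> float:
        return float(rate_vector(C, e1, net)[net.reaction_index(rid)])

    # PTS import balances the g6p node
    demand = (flux("PGI") + flux("G6PDH") + flux("PGM")
              + net.mu * C[net.metabolite_index("g6p")])
    net.set_param("PTS", "rmax", demand / unit_rate("PTS"))

    # chemostat glucose pool: the biomass-to-reactor volume conversion
    # (stoichiometric coefficient of PTS on extracellular glucose) is set so
    # the feed exactly balances uptake plus washout at the nominal point
    if "glcex" in net.metabolite_ids:
        ig = net.metabolite_index("glcex")
        feed = float(net.inflow.get("glcex", 0.0))
        supply = feed - net.mu * C[ig]
        if supply <= 0:
            raise ConfigError("glcex feed does not cover washout")
        net.S[ig, net.reaction_index("PTS")] = -supply / flux("PTS")

    # gluconeogenic futile cycles
    a = float(gluconeogenic_fraction)
    if not 0.0 <= a < 1.0:
        raise ConfigError("gluconeogenic_fraction must be in [0, 1)")
    v_pk, v_pfk = flux("PK"), flux("PFK")
    net.set_param("PPS", "rmax", a * v_pk / unit_rate("PPS"))
    net.set_param("PK", "rmax", net.params["PK"]["rmax"] * (1.0 + a))
    net.set_param("FBP", "rmax", a * v_pfk / unit_rate("FBP"))
    net.set_param("PFK", "rmax", net.params["PFK"]["rmax"] * (1.0 + a))

    # decoupled pools (fed by reactions, drained only by dilution) balance
    # analytically at inflow / mu
    r_now = rate_vector(C, e1, net)
    for i in range(net.n_metabolites):
        row = net.S[i]
        if np.all(row >= 0) and np.any(row > 0):
            C[i] = float(row @ r_now) / net.mu

    # Newton refinement of the full state
    f = _rhs_closure(net, _constant_forcing(net, e1))
    sol = root(lambda x: f(0.0, x), C, method="hybr",
               options={"xtol": 1e-13})
    Cr = np.maximum(sol.x, 0.0)
    res = float(np.max(np.abs(f(0.0, Cr))))
    if not (sol.success and res < tol and np.all(sol.x > 0)):
        raise ConvergenceError(
            f"calibration refinement failed (residual {res:.3e} mM/s)")
    net.steady_state = Cr
    net._packed = None
    return net


def steady_state_residual(net: MetabolicNetwork) -> float:
    """max |dC/dt| at the stored nominal state with all enzyme levels 1."""
    d = rhs(0.0, net.steady_state, None, net)
    return float(np.max(np.abs(d)))
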