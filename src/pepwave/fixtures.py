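"""Toy-network generator with a closed-form steady state.

The toy network is a linear chain of irreversible Michaelis–Menten steps
fed by a constant influx, with first-order dilution on every pool and an
optional first-order branch drain at the second node:

    feed →(v0) X1 →(MM) X2 →(MM) ... →(MM) Xn →(MM) out
                         ↘(k·X2, optional branch)

Each node's balance  F = rmax·x/(K + x) + β·x  (β = μ plus any branch rate)
is a quadratic in x with exactly one positive root, so the steady state is
available in closed form node by node — the fixture's stored
``steady_state`` is that analytic solution, making the toy an independent
oracle for the numerical steady-state and RHS machinery.
"""

from __future__ import annotations

import numpy as np

from .network_model import ConfigError, MetabolicNetwork

__all__ = ["make_toy_network", "toy_chain_steady_state"]

# co-metabolite slots are required by the engine's fixed layout but unused
# by the toy rate laws
_CO_DUMMY = dict(atp=4.27, adp=0.595, amp=0.955, nad=1.47, nadh=0.1,
                 nadp=0.195, nadph=0.062, glcex=0.0556)


def _positive_root(F: float, rmax: float, Km: float, beta: float) -> float:
    """Positive solution of beta*x^2 + (rmax + beta*Km - F)*x - F*Km = 0."""
    b = rmax + beta * Km - F
    disc = b * b + 4.0 * beta * F * Km
    return (-b + np.sqrt(disc)) / (2.0 * beta)


def toy_chain_steady_state(v0: float, rmax: np.ndarray, Km: np.ndarray,
                           mu: float, k_branch: float = 0.0,
                           branch_node: int = 1) -> np.ndarray:
    """Closed-form steady state of the chain, solved node by node."""
    n = len(rmax)
    x = np.empty(n)
    F = v0
    for j in range(n):
        beta = mu + (k_branch if j == branch_node else 0.0)
        x[j] = _positive_root(F, rmax[j], Km[j], beta)
        F = rmax[j] * x[j] / (Km[j] + x[j])     # outflow feeds the next node
    return x


def make_toy_network(n_chain: int = 3, branch: bool = False,
                     seed: int = 0) -> MetabolicNetwork:
    """Build a seeded toy chain network with its analytic steady state.

    The same seed always yields the same network.  Parameters are drawn so
    concentrations stay O(0.1–1 mM) and every Michaelis–Menten step runs
    below saturation at the nominal point.
    """
    if n_chain < 2:
        raise ConfigError("n_chain must be >= 2")
    rng = np.random.default_rng(int(seed))
    v0 = 0.01                                        # feed, mM/s
    mu = 1.0e-4                                      # dilution, 1/s
    rmax = v0 * (1.5 + rng.uniform(0.5, 1.5, n_chain))
    Km = rng.uniform(0.2, 2.0, n_chain)
    k_branch = 2.0e-3 if branch else 0.0

    mets = [f"X{i + 1}" for i in range(n_chain)]
    rids = ["FEED"] + [f"M{i + 1}" for i in range(n_chain)]
    kinds = ["constant"] + ["mm1"] * n_chain
    rxn_mets: list[list[str]] = [[]] + [[m] for m in mets]
    params = {"FEED": {"rmax": v0}}
    for i in range(n_chain):
        params[f"M{i + 1}"] = {"rmax": float(rmax[i]), "Km": float(Km[i])}

    S = np.zeros((n_chain, n_chain + 1))
    S[0, 0] = 1.0                                    # feed into X1
    for i in range(n_chain):
        S[i, i + 1] = -1.0                           # Mi drains Xi
        if i + 1 < n_chain:
            S[i + 1, i + 1] = 1.0                    # ... into Xi+1
    if branch:
        rids.append("BRANCH")
        kinds.append("linear")
        rxn_mets.append(["X2"])
        params["BRANCH"] = {"k": k_branch}
        S = np.hstack([S, np.zeros((n_chain, 1))])
        S[1, -1] = -1.0

    ss = toy_chain_steady_state(v0, rmax, Km, mu, k_branch, branch_node=1)
    return MetabolicNetwork(
        metabolite_ids=mets, reaction_ids=rids, S=S, kinds=kinds,
        rxn_metabolites=rxn_mets, params=params,
        cometabolites=dict(_CO_DUMMY), mu=mu,
        steady_state=ss, essential=[], name=f"toy_chain_{n_chain}_{seed}")
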