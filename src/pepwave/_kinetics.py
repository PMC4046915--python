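"""Compiled kinetic rate-law engine.

Every reaction in a network carries a rate-law *kind* (an integer code), up
to four state-metabolite indices and a packed parameter row.  The engine
evaluates all reaction rates, the forced enzyme levels e(t) and the full
right-hand side S·r(C)·e − μC inside numba-compiled kernels so that a single
8 h integration stays in the low tens of milliseconds.

Co-metabolites (ATP, ADP, AMP, NAD(H), NADP(H), extracellular glucose) are
held constant and passed as a fixed-layout vector, see ``CO_ORDER``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- fixed co-metabolite vector layout -------------------------------------
CO_ORDER = ("atp", "adp", "amp", "nad", "nadh", "nadp", "nadph", "glcex")
I_ATP, I_ADP, I_AMP, I_NAD, I_NADH, I_NADP, I_NADPH, I_GLCEX = range(8)

# --- rate-law kind codes ----------------------------------------------------
CONSTANT = 0      # zero-order drain/source
MM1 = 1           # irreversible Michaelis-Menten, one substrate
HILL1 = 2         # irreversible Hill, one substrate
REV_UNI_MM = 3    # reversible uni-uni MM with product inhibition
REV_UNI_MA = 4    # reversible uni-uni mass action
REV_BI_MA = 5     # reversible bi-bi mass action
LINEAR = 6        # first order
PTS = 7
PGI = 8
G6PDH = 9
PFK = 10
ALDO = 11
GAPDH = 12
PGK = 13
PK = 14
PEPC = 15
DAHPS = 16
PGDH = 17
G1PAT = 18
PPS = 19
FBP = 20

#: ordered parameter names per kind; YAML stores parameters by name, the
#: packer lays them out in this order.
PARAM_ORDER: dict[int, tuple[str, ...]] = {
    CONSTANT: ("rmax",),
    MM1: ("rmax", "Km"),
    HILL1: ("rmax", "K", "n"),
    REV_UNI_MM: ("rmax", "Keq", "Ka", "Kb"),
    REV_UNI_MA: ("rmax", "Keq"),
    REV_BI_MA: ("rmax", "Keq"),
    LINEAR: ("k",),
    PTS: ("rmax", "Ka1", "Ka2", "Ka3", "Kg6p", "ng6p"),
    PGI: ("rmax", "Keq", "Kg6p", "Kf6p", "Kf6p_6pg", "Kg6p_6pg"),
    G6PDH: ("rmax", "Kg6p", "Knadp", "Knadph_g6p", "Knadph_nadp"),
    PFK: ("rmax", "Katp", "Kadp_c", "Kf6p", "Kpep", "Kadp_b", "Kamp_b",
          "Kadp_a", "Kamp_a", "L", "n"),
    ALDO: ("rmax", "Keq", "Kfdp", "Kgap", "Kdhap", "blf", "Kgap_inh"),
    GAPDH: ("rmax", "Keq", "Kgap", "Kpgp", "Knad", "Knadh"),
    PGK: ("rmax", "Keq", "Kadp", "Katp", "Kpgp", "Kpg3"),
    PK: ("rmax", "Kpep", "n", "L", "Katp", "Kfdp", "Kamp", "Kadp"),
    PEPC: ("rmax", "Kpep", "Kfdp", "nfdp"),
    DAHPS: ("rmax", "Ke4p", "ne4p", "Kpep", "npep"),
    PGDH: ("rmax", "K6pg", "Knadp", "Knadph", "Katp"),
    G1PAT: ("rmax", "Kg1p", "Katp", "Kfdp", "nfdp"),
    PPS: ("rmax", "Kpyr", "Kipep"),
    FBP: ("rmax", "Kfdp", "Kiamp"),
}

KIND_NAMES = {
    "constant": CONSTANT, "mm1": MM1, "hill1": HILL1,
    "rev_uni_mm": REV_UNI_MM, "rev_uni_ma": REV_UNI_MA,
    "rev_bi_ma": REV_BI_MA, "linear": LINEAR, "pts": PTS, "pgi": PGI,
    "g6pdh": G6PDH, "pfk": PFK, "aldo": ALDO, "gapdh": GAPDH, "pgk": PGK,
    "pk": PK, "pepc": PEPC, "dahps": DAHPS, "pgdh": PGDH, "g1pat": G1PAT,
    "pps": PPS, "fbp": FBP,
}
KIND_CODES = {v: k for k, v in KIND_NAMES.items()}

N_PMAX = max(len(v) for v in PARAM_ORDER.values())

# waveform codes for the forcing kernel
W_CONSTANT = 0
W_COSINE = 1
W_SQUARE = 2


@njit(cache=True)
def rates_core(C, co, kinds, midx, P):
    """Unscaled reaction rates r(C) in mM/s (enzyme levels applied outside)."""
    m = kinds.shape[0]
    r = np.empty(m)
    atp = co[0]; adp = co[1]; amp = co[2]
    nad = co[3]; nadh = co[4]; nadp = co[5]; nadph = co[6]; glcex = co[7]
    for j in range(m):
        k = kinds[j]
        p = P[j]
        a = 0.0; b = 0.0; c = 0.0; d = 0.0
        if midx[j, 0] >= 0:
            a = C[midx[j, 0]]
            if a < 0.0:
                a = 0.0
        if midx[j, 1] >= 0:
            b = C[midx[j, 1]]
            if b < 0.0:
                b = 0.0
        if midx[j, 2] >= 0:
            c = C[midx[j, 2]]
            if c < 0.0:
                c = 0.0
        if midx[j, 3] >= 0:
            d = C[midx[j, 3]]
            if d < 0.0:
                d = 0.0

        if k == CONSTANT:
            r[j] = p[0]
        elif k == MM1:
            r[j] = p[0] * a / (p[1] + a)
        elif k == HILL1:
            an = a ** p[2]
            r[j] = p[0] * an / (p[1] + an)
        elif k == REV_UNI_MM:
            r[j] = p[0] * (a - b / p[1]) / (p[2] * (1.0 + b / p[3]) + a)
        elif k == REV_UNI_MA:
            r[j] = p[0] * (a - b / p[1])
        elif k == REV_BI_MA:
            r[j] = p[0] * (a * b - c * d / p[1])
        elif k == LINEAR:
            r[j] = p[0] * a
        elif k == PTS:
            # a=pep, b=pyr, c=g6p, d=extracellular glucose (falls back to
            # the constant co-metabolite pool when not a state variable)
            g = d if midx[j, 3] >= 0 else glcex
            rat = a / b if b > 1e-12 else 0.0
            den1 = p[1] + p[2] * rat + p[3] * g + g * rat
            den2 = 1.0 + c ** p[5] / p[4]
            r[j] = p[0] * g * rat / (den1 * den2)
        elif k == PGI:
            # a=g6p, b=f6p, c=6pg
            den = p[2] * (1.0 + b / (p[3] * (1.0 + c / p[4])) + c / p[5]) + a
            r[j] = p[0] * (a - b / p[1]) / den
        elif k == G6PDH:
            r[j] = (p[0] * a * nadp
                    / ((a + p[1]) * (1.0 + nadph / p[3])
                       * (p[2] * (1.0 + nadph / p[4]) + nadp)))
        elif k == PFK:
            # a=f6p, b=pep
            A1 = 1.0 + b / p[4] + adp / p[5] + amp / p[6]
            A2 = 1.0 + adp / p[7] + amp / p[8]
            den = ((atp + p[1] * (1.0 + adp / p[2]))
                   * (a + p[3] * A1 / A2)
                   * (1.0 + p[9] / (1.0 + a * A2 / (p[3] * A1)) ** p[10]))
            r[j] = p[0] * atp * a / den
        elif k == ALDO:
            # a=fdp, b=gap, c=dhap
            den = (p[2] + a + p[3] * c / (p[1] * p[5])
                   + p[4] * b / (p[1] * p[5]) + a * b / p[6]
                   + b * c / (p[1] * p[5]))
            r[j] = p[0] * (a - b * c / p[1]) / den
        elif k == GAPDH:
            # a=gap, b=pgp
            r[j] = (p[0] * (a * nad - b * nadh / p[1])
                    / ((p[2] * (1.0 + b / p[3]) + a)
                       * (p[4] * (1.0 + nadh / p[5]) + nad)))
        elif k == PGK:
            # a=pgp, b=pg3
            r[j] = (p[0] * (adp * a - atp * b / p[1])
                    / ((p[2] * (1.0 + atp / p[3]) + adp)
                       * (p[4] * (1.0 + b / p[5]) + a)))
        elif k == PK:
            # a=pep, b=fdp
            t1 = a / p[1] + 1.0
            Lterm = ((1.0 + atp / p[4]) / (b / p[5] + amp / p[6] + 1.0)) ** p[2]
            r[j] = (p[0] * a * t1 ** (p[2] - 1.0) * adp
                    / (p[1] * (p[3] * Lterm + t1 ** p[2]) * (adp + p[7])))
        elif k == PEPC:
            # a=pep, b=fdp
            r[j] = p[0] * a * (1.0 + (b / p[2]) ** p[3]) / (p[1] + a)
        elif k == DAHPS:
            # a=e4p, b=pep
            an = a ** p[2]
            bn = b ** p[4]
            r[j] = p[0] * an * bn / ((p[1] + an) * (p[3] + bn))
        elif k == PGDH:
            # a=6pg
            r[j] = (p[0] * a * nadp
                    / ((a + p[1])
                       * (nadp + p[2] * (1.0 + nadph / p[3])
                          * (1.0 + atp / p[4]))))
        elif k == G1PAT:
            # a=g1p, b=fdp
            r[j] = (p[0] * a * atp * (1.0 + (b / p[3]) ** p[4])
                    / ((p[2] + atp) * (p[1] + a)))
        elif k == PPS:
            # a=pyr, b=pep (product inhibition)
            r[j] = p[0] * a / (p[1] * (1.0 + b / p[2]) + a)
        elif k == FBP:
            # a=fdp
            r[j] = p[0] * a / ((p[1] + a) * (1.0 + amp / p[2]))
        else:
            r[j] = np.nan
    return r


@njit(cache=True)
def levels_core(t, wkind, A, omega, phi, h, sgn, emin, emax):
    """Enzyme levels e(t)/ê for all reactions, clamped to [emin, emax]."""
    m = wkind.shape[0]
    e = np.empty(m)
    for j in range(m):
        if wkind[j] == W_CONSTANT:
            v = h[j]
        else:
            cw = np.cos(omega[j] * t + phi[j])
            if wkind[j] == W_SQUARE:
                cw = 1.0 if cw >= 0.0 else -1.0
            v = h[j] + sgn[j] * A[j] * cw
        if v < emin[j]:
            v = emin[j]
        elif v > emax[j]:
            v = emax[j]
        e[j] = v
    return e


@njit(cache=True)
def rhs_core(t, C, S, mu, co, inflow, kinds, midx, P,
             wkind, A, omega, phi, h, sgn, emin, emax):
    """dC/dt = S·(e(t) ∘ r(C)) + b − μ·C.

    ``inflow`` b holds non-catalysed sources, e.g. the chemostat glucose
    feed D·c_feed on the extracellular pool.
    """
    r = rates_core(C, co, kinds, midx, P)
    e = levels_core(t, wkind, A, omega, phi, h, sgn, emin, emax)
    n = C.shape[0]
    dC = np.empty(n)
    for i in range(n):
        s = inflow[i]
        for j in range(r.shape[0]):
            sij = S[i, j]
            if sij != 0.0:
                s += sij * e[j] * r[j]
        dC[i] = s - mu * C[i]
    return dC
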