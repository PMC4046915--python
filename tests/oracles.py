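"""Independent single-purpose reimplementations used as test oracles.

Each function here evaluates one quantity with straightforward standalone
code (plain Python floats, textbook formulas), sharing nothing with the
package's compiled engine, so agreement is evidence of correctness rather
than repetition.
"""

import numpy as np


def pearson_two_pass(x, y):
    """Textbook two-pass Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def rate_laws(net, C):
    """Evaluate every rate law of the E. coli network independently.

    Formulas are written out reaction by reaction from the network's own
    parameter table; returns {reaction_id: rate} at unit enzyme levels.
    """
    c = {met: C[i] for i, met in enumerate(net.metabolite_ids)}
    co = net.cometabolites
    p = {rid: net.params[rid] for rid in net.reaction_ids}
    atp, adp, amp = co["atp"], co["adp"], co["amp"]
    nad, nadh, nadp, nadph = co["nad"], co["nadh"], co["nadp"], co["nadph"]
    glcex = c.get("glcex", co["glcex"])
    v = {}

    q = p["PTS"]
    rat = c["pep"] / c["pyr"]
    v["PTS"] = (q["rmax"] * glcex * rat
                / ((q["Ka1"] + q["Ka2"] * rat + q["Ka3"] * glcex
                    + glcex * rat)
                   * (1 + c["g6p"] ** q["ng6p"] / q["Kg6p"])))
    q = p["PGI"]
    v["PGI"] = (q["rmax"] * (c["g6p"] - c["f6p"] / q["Keq"])
                / (q["Kg6p"] * (1 + c["f6p"] / (q["Kf6p"]
                                * (1 + c["6pg"] / q["Kf6p_6pg"]))
                                + c["6pg"] / q["Kg6p_6pg"]) + c["g6p"]))
    q = p["PGM"]
    v["PGM"] = (q["rmax"] * (c["g6p"] - c["g1p"] / q["Keq"])
                / (q["Ka"] * (1 + c["g1p"] / q["Kb"]) + c["g6p"]))
    q = p["G6PDH"]
    v["G6PDH"] = (q["rmax"] * c["g6p"] * nadp
                  / ((c["g6p"] + q["Kg6p"]) * (1 + nadph / q["Knadph_g6p"])
                     * (q["Knadp"] * (1 + nadph / q["Knadph_nadp"]) + nadp)))
    q = p["PFK"]
    B = 1 + c["pep"] / q["Kpep"] + adp / q["Kadp_b"] + amp / q["Kamp_b"]
    A2 = 1 + adp / q["Kadp_a"] + amp / q["Kamp_a"]
    v["PFK"] = (q["rmax"] * atp * c["f6p"]
                / ((atp + q["Katp"] * (1 + adp / q["Kadp_c"]))
                   * (c["f6p"] + q["Kf6p"] * B / A2)
                   * (1 + q["L"] / (1 + c["f6p"] * A2
                                    / (q["Kf6p"] * B)) ** q["n"])))
    q = p["TA"]
    v["TA"] = q["rmax"] * (c["gap"] * c["sed7p"]
                           - c["e4p"] * c["f6p"] / q["Keq"])
    q = p["TKA"]
    v["TKA"] = q["rmax"] * (c["rib5p"] * c["xyl5p"]
                            - c["sed7p"] * c["gap"] / q["Keq"])
    q = p["TKB"]
    v["TKB"] = q["rmax"] * (c["xyl5p"] * c["e4p"]
                            - c["f6p"] * c["gap"] / q["Keq"])
    v["MURSYNTH"] = p["MURSYNTH"]["rmax"]
    q = p["ALDO"]
    v["ALDO"] = (q["rmax"] * (c["fdp"] - c["gap"] * c["dhap"] / q["Keq"])
                 / (q["Kfdp"] + c["fdp"]
                    + q["Kgap"] * c["dhap"] / (q["Keq"] * q["blf"])
                    + q["Kdhap"] * c["gap"] / (q["Keq"] * q["blf"])
                    + c["fdp"] * c["gap"] / q["Kgap_inh"]
                    + c["gap"] * c["dhap"] / (q["Keq"] * q["blf"])))
    q = p["GAPDH"]
    v["GAPDH"] = (q["rmax"] * (c["gap"] * nad - c["pgp"] * nadh / q["Keq"])
                  / ((q["Kgap"] * (1 + c["pgp"] / q["Kpgp"]) + c["gap"])
                     * (q["Knad"] * (1 + nadh / q["Knadh"]) + nad)))
    q = p["TIS"]
    v["TIS"] = (q["rmax"] * (c["dhap"] - c["gap"] / q["Keq"])
                / (q["Ka"] * (1 + c["gap"] / q["Kb"]) + c["dhap"]))
    q = p["G3PDH"]
    v["G3PDH"] = q["rmax"] * c["dhap"] / (q["Km"] + c["dhap"])
    q = p["PGK"]
    v["PGK"] = (q["rmax"] * (adp * c["pgp"] - atp * c["pg3"] / q["Keq"])
                / ((q["Kadp"] * (1 + atp / q["Katp"]) + adp)
                   * (q["Kpgp"] * (1 + c["pg3"] / q["Kpg3"]) + c["pgp"])))
    q = p["SER"]
    v["SER"] = q["rmax"] * c["pg3"] / (q["Km"] + c["pg3"])
    q = p["PGLUMU"]
    v["PGLUMU"] = (q["rmax"] * (c["pg3"] - c["pg2"] / q["Keq"])
                   / (q["Ka"] * (1 + c["pg2"] / q["Kb"]) + c["pg3"]))
    q = p["ENO"]
    v["ENO"] = (q["rmax"] * (c["pg2"] - c["pep"] / q["Keq"])
                / (q["Ka"] * (1 + c["pep"] / q["Kb"]) + c["pg2"]))
    q = p["PK"]
    t1 = c["pep"] / q["Kpep"] + 1
    v["PK"] = (q["rmax"] * c["pep"] * t1 ** (q["n"] - 1) * adp
               / (q["Kpep"]
                  * (q["L"] * ((1 + atp / q["Katp"])
                               / (c["fdp"] / q["Kfdp"]
                                  + amp / q["Kamp"] + 1)) ** q["n"]
                     + t1 ** q["n"])
                  * (adp + q["Kadp"])))
    q = p["PEPC"]
    v["PEPC"] = (q["rmax"] * c["pep"] * (1 + (c["fdp"] / q["Kfdp"])
                                         ** q["nfdp"])
                 / (q["Kpep"] + c["pep"]))
    q = p["SYN1"]
    v["SYN1"] = q["rmax"] * c["pep"] / (q["Km"] + c["pep"])
    q = p["SYN2"]
    v["SYN2"] = q["rmax"] * c["pyr"] / (q["Km"] + c["pyr"])
    q = p["DAHPS"]
    v["DAHPS"] = (q["rmax"] * c["e4p"] ** q["ne4p"] * c["pep"] ** q["npep"]
                  / ((q["Ke4p"] + c["e4p"] ** q["ne4p"])
                     * (q["Kpep"] + c["pep"] ** q["npep"])))
    q = p["PDH"]
    v["PDH"] = q["rmax"] * c["pyr"] ** q["n"] / (q["K"] + c["pyr"] ** q["n"])
    v["METSYNTH"] = p["METSYNTH"]["rmax"]
    q = p["PGDH"]
    v["PGDH"] = (q["rmax"] * c["6pg"] * nadp
                 / ((c["6pg"] + q["K6pg"])
                    * (nadp + q["Knadp"] * (1 + nadph / q["Knadph"])
                       * (1 + atp / q["Katp"]))))
    q = p["R5PI"]
    v["R5PI"] = q["rmax"] * (c["ribu5p"] - c["rib5p"] / q["Keq"])
    q = p["RU5P"]
    v["RU5P"] = q["rmax"] * (c["ribu5p"] - c["xyl5p"] / q["Keq"])
    q = p["RPPK"]
    v["RPPK"] = q["rmax"] * c["rib5p"] / (q["Km"] + c["rib5p"])
    q = p["G1PAT"]
    v["G1PAT"] = (q["rmax"] * c["g1p"] * atp
                  * (1 + (c["fdp"] / q["Kfdp"]) ** q["nfdp"])
                  / ((q["Katp"] + atp) * (q["Kg1p"] + c["g1p"])))
    v["TRPSYNTH"] = p["TRPSYNTH"]["rmax"]
    q = p["PPS"]
    v["PPS"] = (q["rmax"] * c["pyr"]
                / (q["Kpyr"] * (1 + c["pep"] / q["Kipep"]) + c["pyr"]))
    q = p["FBP"]
    v["FBP"] = (q["rmax"] * c["fdp"]
                / ((q["Kfdp"] + c["fdp"]) * (1 + amp / q["Kiamp"])))
    return v


def dense_rhs(net, C, e):
    """Mass-balance derivative by explicit matrix product, from the oracle
    rates."""
    v = rate_laws(net, C)
    r = np.array([v[rid] for rid in net.reaction_ids]) * np.asarray(e)
    b = np.zeros(len(net.metabolite_ids))
    for met, val in net.inflow.items():
        b[net.metabolite_ids.index(met)] = val
    return np.asarray(net.S) @ r + b - net.mu * np.asarray(C)
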