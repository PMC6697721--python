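"""Independent brute-force oracles used by the tests.

The RK4 integrator below is written directly from the model equations and
shares no code with the package's prediction paths (closed-form cascade,
RK4-on-forcing, or adaptive ODE solve).
"""

from __future__ import annotations

import numpy as np


def rk4_full_model(p: dict, dose_nmol: float, times, dt: float = 1e-4):
    """Fixed-step RK4 of the seven-state system, stepping piecewise between
    the dose-event discontinuities so every sub-interval is smooth.

    Returns dict analyte -> concentrations (nM) at ``times``.
    """
    times = np.asarray(times, dtype=float)
    d1, d2 = p["D1"], p["D2"]
    alag = p["ALAG"]
    ka1, ka2 = p["ka1"], p["ka2"]
    v = p["V_SL_F"]
    ke = p["CL_SLe_F"] / v
    f1, f2 = p["F1"], p["F2"]
    delta = 1e-12
    gam = p["gamma"]

    def rhs(t, y, r1, r2):
        ad1, ad2, asv, csva, ch, cha, cd = y
        csv = asv / v
        chc = max(ch, 0.0)
        phi = (chc + delta) ** gam - delta ** gam
        hill = p["CLEmax_VHSV"] * phi / (p["CLEC50"] ** gam + phi)
        return np.array([
            r1 - ka1 * ad1,
            r2 - ka2 * ad2,
            ka1 * ad1 + ka2 * ad2 - ke * asv,
            p["CLLA_VSVA"] * csv - p["CLSVAe_VSVA"] * csva,
            p["CLLH_VHSV"] * csv - hill,
            p["CLAH_VHSVA"] * csva + p["CLHSVHSVA_VHSVA"] * chc
            - p["CLHSVAe_VHSVA"] * cha,
            p["CLLD_VDHSV"] * csv - p["CLDHSe_VDHSV"] * cd,
        ])

    tmax = float(times.max())
    breaks = sorted({0.0, min(d1, tmax), min(alag, tmax),
                     min(alag + d2, tmax), tmax} | set(times))
    y = np.zeros(7)
    out = {t: None for t in times}
    if 0.0 in out:
        out[0.0] = y.copy()
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi <= lo:
            continue
        mid = 0.5 * (lo + hi)
        r1 = f1 * dose_nmol / d1 if 0.0 <= mid < d1 else 0.0
        r2 = f2 * dose_nmol / d2 if alag <= mid < alag + d2 else 0.0
        n = max(int(np.ceil((hi - lo) / dt)), 1)
        h = (hi - lo) / n
        t = lo
        for _ in range(n):
            k1 = rhs(t, y, r1, r2)
            k2 = rhs(t + h / 2, y + h / 2 * k1, r1, r2)
            k3 = rhs(t + h / 2, y + h / 2 * k2, r1, r2)
            k4 = rhs(t + h, y + h * k3, r1, r2)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        if hi in out:
            out[hi] = y.copy()
    states = np.array([out[t] for t in times])
    return {
        "SV": states[:, 2] / v,
        "SVA": states[:, 3],
        "HMSV": states[:, 4],
        "HMSVA": states[:, 5],
        "DHSV": states[:, 6],
    }
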