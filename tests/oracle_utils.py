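"""Independent oracles for the compartmental model, kept free of the package's
solution path: an analytic upstream + fixed-grid RK4 integrator for the
delayed system, a per-time matrix-exponential solve, and a single-molecule
Monte Carlo jump process for residence/recycling quantities."""

from __future__ import annotations

import numpy as np
from scipy import linalg


def _rates(params, spec):
    a = spec.absorption_efficiency
    g = params.to_dict()
    return {
        "k1": g["L_2_1"] / a,          # total outflow of compartment 1
        "l21": g["L_2_1"],
        "l32": g["L_3_2"],
        "l54": g["L_5_4"],
        "l65": g["L_6_5"],
        "l56": g["L_5_6"],
        "l106": g["L_10_6"],
        "l75": g.get("L_7_5", 0.0),
        "l57": g.get("L_5_7", 0.0),
        "dt3": g["DT_3"],
    }


def upstream_efflux(params, spec, t):
    """Analytic flow rate out of compartment 2 (into the delay) at time t."""
    r = _rates(params, spec)
    t = np.asarray(t, dtype=float)
    k1, l21, l32 = r["k1"], r["l21"], r["l32"]
    if abs(l32 - k1) < 1e-12:
        q2 = l21 * t * np.exp(-k1 * t)
    else:
        q2 = l21 * (np.exp(-k1 * t) - np.exp(-l32 * t)) / (l32 - k1)
    return l32 * np.where(t >= 0, q2, 0.0)


def rk4_fdp(params, spec, times, h=1e-3):
    """Fixed-grid RK4 solve of the downstream subsystem driven by the
    delayed upstream efflux; returns fdp at the requested times."""
    r = _rates(params, spec)
    two_ev = r["l75"] > 0 or r["l57"] > 0
    n = 4 if two_ev else 3  # states 4,5,6[,7]
    A = np.zeros((n, n))
    A[0, 0] = -r["l54"]
    A[1, 0] = r["l54"]
    A[1, 1] = -(r["l65"] + r["l75"])
    A[2, 1] = r["l65"]
    A[1, 2] = r["l56"]
    A[2, 2] = -(r["l56"] + r["l106"])
    if two_ev:
        A[3, 1] = r["l75"]
        A[1, 3] = r["l57"]
        A[3, 3] = -r["l57"]

    dt3 = r["dt3"]
    times = np.asarray(times, dtype=float)
    t_end = times.max()
    out = np.zeros_like(times)
    if t_end <= dt3:
        return out

    def rhs(t, x):
        dx = A @ x
        dx[0] += upstream_efflux(params, spec, t - dt3)
        return dx

    # integrate from dt3 (downstream starts empty; forcing smooth after dt3)
    grid = np.arange(dt3, t_end + h, h)
    x = np.zeros(n)
    want = {}
    for i, t in enumerate(times):
        if t > dt3:
            want.setdefault(int(round((t - dt3) / h)), []).append(i)
    for k in range(len(grid) - 1):
        if k in want:
            for i in want[k]:
                out[i] = x[1]
        t = grid[k]
        k1v = rhs(t, x)
        k2v = rhs(t + h / 2, x + h / 2 * k1v)
        k3v = rhs(t + h / 2, x + h / 2 * k2v)
        k4v = rhs(t + h, x + h * (k3v))
        x = x + h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
    if len(grid) - 1 in want:
        for i in want[len(grid) - 1]:
            out[i] = x[1]
    # exact landing: re-interpolate requested times not on the grid
    for i, t in enumerate(times):
        k = (t - dt3) / h
        if t > dt3 and abs(k - round(k)) > 1e-9:
            raise ValueError("times must be multiples of h past the delay")
    return out


def expm_fdp(params, spec, times):
    """Per-time matrix exponential of the delay-free system, shifted by DT(3)."""
    r = _rates(params, spec)
    two_ev = r["l75"] > 0 or r["l57"] > 0
    comps = [1, 2, 4, 5, 6] + ([7] if two_ev else [])
    idx = {c: k for k, c in enumerate(comps)}
    n = len(comps)
    M = np.zeros((n, n))

    def flow(src, dst, rate):
        M[idx[src], idx[src]] -= rate
        if dst is not None:
            M[idx[dst], idx[src]] += rate

    flow(1, 2, r["l21"])
    flow(1, None, r["k1"] - r["l21"])
    flow(2, 4, r["l32"])
    flow(4, 5, r["l54"])
    flow(5, 6, r["l65"])
    flow(6, 5, r["l56"])
    flow(6, None, r["l106"])
    if two_ev:
        flow(5, 7, r["l75"])
        flow(7, 5, r["l57"])
    x0 = np.zeros(n)
    x0[idx[1]] = 1.0
    out = np.zeros(len(times))
    for i, t in enumerate(np.asarray(times, dtype=float)):
        s = t - r["dt3"]
        if s > 0:
            out[i] = (linalg.expm(M * s) @ x0)[idx[5]]
    return out


def mc_plasma_cycle(params, spec, n_particles, seed):
    """Jump-process simulation of molecules entering plasma (compartment 5).

    Returns mean time in 5, 6, 7 per molecule and the mean number of returns
    to plasma before irreversible loss from compartment 6.
    """
    r = _rates(params, spec)
    rng = np.random.default_rng(seed)
    out5 = r["l65"] + r["l75"]
    out6 = r["l56"] + r["l106"]
    t5 = np.zeros(n_particles)
    t6 = np.zeros(n_particles)
    t7 = np.zeros(n_particles)
    returns = np.zeros(n_particles)

    idx = np.arange(n_particles)
    state = np.full(n_particles, 5, dtype=np.int8)
    while idx.size:
        # one jump for every live particle
        in5 = state == 5
        in6 = state == 6
        in7 = state == 7
        if in5.any():
            ii = idx[in5]
            t5[ii] += rng.exponential(1.0 / out5, ii.size)
            to7 = rng.random(ii.size) < (r["l75"] / out5)
            state[in5] = np.where(to7, 7, 6)
        if in6.any():
            ii = idx[in6]
            t6[ii] += rng.exponential(1.0 / out6, ii.size)
            back = rng.random(ii.size) < (r["l56"] / out6)
            new = np.where(back, 5, 0).astype(np.int8)  # 0 = lost
            returns[ii] += back
            state[in6] = new
        if in7.any():
            ii = idx[in7]
            t7[ii] += rng.exponential(1.0 / r["l57"], ii.size)
            returns[ii] += 1
            state[in7] = 5
        live = state != 0
        idx = idx[live]
        state = state[live]
    return {"time5": t5, "time6": t6, "time7": t7, "returns": returns}


def mc_system_residence(params, spec, n_particles, seed):
    """Mean total time in the system per molecule of dietary input into 1,
    counting the delay transit for absorbed molecules."""
    r = _rates(params, spec)
    rng = np.random.default_rng(seed)
    total = rng.exponential(1.0 / r["k1"], n_particles)  # time in 1
    absorbed = rng.random(n_particles) < spec.absorption_efficiency
    n_abs = int(absorbed.sum())
    cyc = mc_plasma_cycle(params, spec, n_abs, seed + 1)
    total[absorbed] += (
        rng.exponential(1.0 / r["l32"], n_abs)          # compartment 2
        + r["dt3"]                                      # delay transit
        + rng.exponential(1.0 / r["l54"], n_abs)        # compartment 4
        + cyc["time5"] + cyc["time6"] + cyc["time7"]    # plasma cycling
    )
    return total.mean()
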