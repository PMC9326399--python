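"""Independent LP oracle for the dip statistic.

Computes the infimal sup-norm distance from the ECDF of a sample to the
class of unimodal CDFs (convex below the mode, concave above, one jump
allowed at the mode) by direct linear programming over piecewise-linear
candidates with knots at the data points and midpoints, one LP per
candidate mode position.  Boundary tails (decay to 0 on the left, rise to
1 on the right) impose no constraint in the infimum, because any convex
(resp. concave) branch with positive slope can be extended to reach them.

This oracle shares no code or algorithmic structure with
``omicsfuse.cluster.dip_statistic`` (which uses the iterative
modal-interval hull algorithm); agreement between the two is the
correctness evidence.
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp_oracle(v) -> float:
    v = np.asarray(v, float)
    n = v.size
    x, counts = np.unique(v, return_counts=True)
    F = np.cumsum(counts) / n
    nodes = np.array(sorted(set(x) | set((x[:-1] + x[1:]) / 2)))
    M = len(nodes)
    Fn = np.zeros(M)
    for t, xt in enumerate(nodes):
        idx = np.searchsorted(x, xt, side="right") - 1
        Fn[t] = 0.0 if idx < 0 else F[idx]
    best = np.inf
    for mode in range(M):
        nv = M + 2  # g_0..g_{M-1}, h (left limit at the mode), d
        ih, idd = M, M + 1
        A_ub, b_ub = [], []

        def le(coefs, rhs):
            row = np.zeros(nv)
            for i, c in coefs:
                row[i] += c
            A_ub.append(row)
            b_ub.append(rhs)

        for t in range(M):
            le([(t, -1), (idd, -1)], -Fn[t])  # g_t >= F_t - d
            le([(t, 1), (idd, -1)], Fn[t])  # g_t <= F_t + d
        if mode != 0:
            le([(0, 1), (idd, -1)], 0.0)  # band left of the data: G <= d
        for t in range(M - 1):  # left limits bind against the lower F step
            tgt = ih if (t + 1) == mode else t + 1
            le([(tgt, 1), (idd, -1)], Fn[t])
        chain = (
            list(range(0, mode))
            + ([ih, mode] if mode > 0 else [mode])
            + list(range(mode + 1, M))
        )
        for a, b in zip(chain[:-1], chain[1:]):
            le([(a, 1), (b, -1)], 0.0)  # monotone, jump only at the mode
        left_idx = list(range(0, mode)) + ([ih] if mode > 0 else [])
        left_x = list(nodes[:mode]) + ([nodes[mode]] if mode > 0 else [])
        for i in range(len(left_idx) - 2):  # convex below the mode
            i0, i1, i2 = left_idx[i], left_idx[i + 1], left_idx[i + 2]
            x0, x1, x2 = left_x[i], left_x[i + 1], left_x[i + 2]
            le([(i1, x2 - x0), (i0, -(x2 - x1)), (i2, -(x1 - x0))], 0.0)
        right_idx = list(range(mode, M))
        right_x = list(nodes[mode:])
        for i in range(len(right_idx) - 2):  # concave above the mode
            i0, i1, i2 = right_idx[i], right_idx[i + 1], right_idx[i + 2]
            x0, x1, x2 = right_x[i], right_x[i + 1], right_x[i + 2]
            le([(i1, -(x2 - x0)), (i0, (x2 - x1)), (i2, (x1 - x0))], 0.0)
        c = np.zeros(nv)
        c[idd] = 1.0
        bounds = [(0, 1)] * M + [(0, 1), (0, 0.5)]
        res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds,
                      method="highs")
        if res.status == 0:
            best = min(best, res.fun)
    return max(best, 1.0 / (2 * n))
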