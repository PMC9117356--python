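"""Independent reference implementations used only as test oracles.

Everything here is written directly from first principles / textbook
formulas and deliberately shares no code with the package: explicit Python
loops for co-occurrence counting, a hand-written Cox partial likelihood,
and the classic log-rank O-E/V computation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def brute_force_glcm(levels: np.ndarray, offset, distance=1, symmetric=True):
    """Count co-occurring level pairs by an explicit loop over all voxels.

    ``levels`` holds -1 outside the ROI.  Returns the integer count matrix
    for one offset (both orders accumulated when symmetric).
    """
    ng = int(levels.max()) + 1
    counts = np.zeros((ng, ng), dtype=np.int64)
    d = tuple(int(c) * distance for c in offset)
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a < 0:
                    continue
                u, v, w = x + d[0], y + d[1], z + d[2]
                if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                    continue
                b = levels[u, v, w]
                if b < 0:
                    continue
                counts[a, b] += 1
                if symmetric:
                    counts[b, a] += 1
    return counts


def textbook_haralick(p: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics computed with explicit loops.

    Natural log, 0*log0 = 0; sum variance centred on the sum average.
    """
    p = np.asarray(p, dtype=float)
    ng = p.shape[0]

    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(ng))

    p_sum = [0.0] * (2 * ng - 1)
    p_diff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    def xlogx(v):
        return v * np.log(v) if v > 0 else 0.0

    asm = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    contrast = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    if var_x > 0 and var_y > 0:
        corr = (
            sum(i * j * p[i][j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y
        ) / np.sqrt(var_x * var_y)
    else:
        corr = float("nan")
    variance = sum((i - mu_x) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    idm = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    sum_average = sum(k * p_sum[k] for k in range(2 * ng - 1))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(2 * ng - 1))
    sum_entropy = -sum(xlogx(v) for v in p_sum)
    entropy = -sum(xlogx(p[i][j]) for i in range(ng) for j in range(ng))
    diff_mean = sum(k * p_diff[k] for k in range(ng))
    difference_variance = sum((k - diff_mean) ** 2 * p_diff[k] for k in range(ng))
    difference_entropy = -sum(xlogx(v) for v in p_diff)

    hx = -sum(xlogx(v) for v in px)
    hy = -sum(xlogx(v) for v in py)
    hxy1 = -sum(
        p[i][j] * np.log(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        xlogx(px[i] * py[j]) for i in range(ng) for j in range(ng)
    )
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else float("nan")
    imc2 = np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - entropy)), 0.0))

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": corr,
        "variance": variance,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
    }


def cox_partial_loglik(beta: float, time, x, event) -> float:
    """Hand-written Cox partial log-likelihood, one covariate, no ties."""
    time = np.asarray(time, float)
    x = np.asarray(x, float)
    event = np.asarray(event, int)
    ll = 0.0
    for i in np.where(event == 1)[0]:
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_mle_1d(time, x, event, bound=10.0) -> float:
    """Maximize the hand-written partial likelihood over a single beta."""
    res = minimize_scalar(
        lambda b: -cox_partial_loglik(b, time, x, event),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def logrank_two_group(time, event, group) -> float:
    """Classic two-group log-rank chi-square via the O-E/V formula."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == group[np.argsort(group)][0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == group[np.argsort(group)][0])).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)
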