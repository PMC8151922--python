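"""Independent brute-force evaluators used as oracles by the test suite.

Everything here is written with plain Python loops, dicts and ``math`` —
deliberately sharing no code path with the package implementation — so
agreement between the two is meaningful evidence of correctness.
"""

from __future__ import annotations

import math


def brute_glcm(levels, dr: int, dc: int, symmetric: bool) -> dict:
    """Co-occurrence probabilities {(i, j): p} by exhaustive pair enumeration."""
    rows, cols = len(levels), len(levels[0])
    counts: dict[tuple[int, int], float] = {}
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                pair = (int(levels[r][c]), int(levels[r2][c2]))
                counts[pair] = counts.get(pair, 0) + 1
                if symmetric:
                    rev = (pair[1], pair[0])
                    counts[rev] = counts.get(rev, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no pairs")
    return {k: v / total for k, v in counts.items()}


def brute_features(p: dict, n: int, dialect: str = "as_printed", log=math.log) -> dict:
    """All 19 descriptors evaluated by literal double-loop summation.

    ``p`` maps 1-based (i, j) pairs to probabilities; absent cells are zero.
    """
    px = {i: sum(p.get((i, j), 0.0) for j in range(1, n + 1)) for i in range(1, n + 1)}
    py = {j: sum(p.get((i, j), 0.0) for i in range(1, n + 1)) for j in range(1, n + 1)}
    mu_x = sum(i * px[i] for i in px)
    mu_y = sum(j * py[j] for j in py)
    var_x = sum((i - mu_x) ** 2 * px[i] for i in px)
    var_y = sum((j - mu_y) ** 2 * py[j] for j in py)
    p_sum = {k: 0.0 for k in range(2, 2 * n + 1)}
    p_diff = {k: 0.0 for k in range(0, n)}
    for (i, j), v in p.items():
        p_sum[i + j] += v
        p_diff[abs(i - j)] += v
    mu_sum = sum(k * v for k, v in p_sum.items())
    mu_diff = sum(k * v for k, v in p_diff.items())

    def ent(dist) -> float:
        return -sum(v * log(v) for v in dist if v > 0)

    hx = ent(px.values())
    hy = ent(py.values())
    hxy = ent(p.values())
    hxy1 = -sum(v * log(px[i] * py[j]) for (i, j), v in p.items() if v > 0)
    hxy2 = -sum(
        px[i] * py[j] * log(px[i] * py[j])
        for i in px for j in py if px[i] * py[j] > 0
    )

    out = {}
    out["autocorrelation"] = sum(i * j * v for (i, j), v in p.items())
    out["contrast"] = sum((i - j) ** 2 * v for (i, j), v in p.items())
    sigma = math.sqrt(var_x * var_y)
    out["correlation"] = (
        sum((i - mu_x) * (j - mu_y) * v for (i, j), v in p.items()) / sigma if sigma > 0 else 0.0
    )
    prom_exp, shade_exp = (3, 4) if dialect == "as_printed" else (4, 3)
    mu = mu_x
    out["cluster_prominence"] = sum((i + j - 2 * mu) ** prom_exp * v for (i, j), v in p.items())
    out["cluster_shade"] = sum((i + j - 2 * mu) ** shade_exp * v for (i, j), v in p.items())
    out["dissimilarity"] = sum(abs(i - j) * v for (i, j), v in p.items())
    out["energy"] = sum(v * v for v in p.values())
    out["entropy"] = hxy
    out["homogeneity"] = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    out["maximum_probability"] = max(p.values())
    out["sum_of_squares_variance"] = sum((i - mu) ** 2 * v for (i, j), v in p.items())
    out["sum_average"] = sum(k * v for k, v in p_sum.items())
    out["sum_variance"] = sum((k - mu_sum) ** 2 * v for k, v in p_sum.items())
    out["sum_entropy"] = ent(p_sum.values())
    out["difference_variance"] = sum((k - mu_diff) ** 2 * v for k, v in p_diff.items())
    out["difference_entropy"] = ent(p_diff.values())
    if hxy <= 0:
        out["imc1"] = 0.0
        out["imc2"] = 0.0
    else:
        denom = max(hx, hy)
        out["imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
        core = 1.0 - math.exp(-2.0 * (hxy2 - hxy))
        out["imc2"] = core if dialect == "as_printed" else math.sqrt(max(0.0, core))
    j_start = 2 if dialect == "as_printed" else 1
    out["inverse_difference"] = sum(
        v / (1 + abs(i - j)) for (i, j), v in p.items() if j >= j_start
    )
    return out


def brute_auc(scores, labels, positive) -> float:
    """Concordance probability over all positive-negative pairs; ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    if not pos or not neg:
        raise ValueError("need both positive and negative samples")
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
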