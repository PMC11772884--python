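"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by naive enumeration (dictionaries,
explicit loops, quadrature) rather than calling the library code paths
they check.
"""

from __future__ import annotations

import numpy as np


def reference_expand(seeds, classes, thresholds, spots):
    """Naive round-by-round simulation of synchronous cell expansion.

    seeds: {cell_id: (x, y)} integer seed positions (distinct);
    classes/thresholds: {cell_id: class}, {class: max spots};
    spots: {(x, y): count} occupied spots.
    Returns {(x, y): cell_id} for assigned occupied spots.
    """

    def neighbors(pos):
        x, y = pos
        return [(x - 1, y), (x + 1, y), (x, y - 1), (x, y + 1)]

    territory = {c: {pos} for c, pos in seeds.items()}
    assigned = {}
    sizes = {c: 0 for c in seeds}
    for c, pos in seeds.items():
        if pos in spots:
            assigned[pos] = c
            sizes[c] = 1
    thr = {c: thresholds[classes[c]] for c in seeds}

    while True:
        cands = []
        for pos in spots:
            if pos in assigned:
                continue
            adj = sorted(
                c for c, terr in territory.items()
                if any(nb in terr for nb in neighbors(pos))
            )
            if adj:
                cands.append((pos, adj))
        if not cands:
            break
        cands.sort(key=lambda t: (-spots[t[0]], t[0][1], t[0][0]))
        new_terr = []
        for pos, adj in cands:
            eligible = [c for c in adj if sizes[c] < thr[c]]
            if not eligible:
                continue
            winner = min(
                eligible,
                key=lambda c: (
                    (seeds[c][0] - pos[0]) ** 2 + (seeds[c][1] - pos[1]) ** 2,
                    c,
                ),
            )
            assigned[pos] = winner
            sizes[winner] += 1
            new_terr.append((winner, pos))
        if not new_terr:
            break
        for winner, pos in new_terr:
            territory[winner].add(pos)
    return assigned


def exhaustive_otsu(values: np.ndarray) -> float:
    """Between-class-variance maximization by exhaustive search over all
    midpoints between consecutive distinct intensities."""
    v = np.sort(np.unique(values))
    flat = np.asarray(values, dtype=float).ravel()
    best_t, best_var = v[0], -1.0
    for t in (v[:-1] + v[1:]) / 2.0:
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)


def brute_force_signed_distance(labels, pitch_um):
    """All-pairs minimum distance to the boundary bin set.

    labels: int array with 1 tumor, 2 liver, 3 stroma, 0 background.
    Boundary = tumor bins 4-adjacent to liver/stroma bins.
    """
    h, w = labels.shape
    tumor = labels == 1
    nontum = (labels == 2) | (labels == 3)
    bnd = []
    for y in range(h):
        for x in range(w):
            if not tumor[y, x]:
                continue
            for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and nontum[yy, xx]:
                    bnd.append((y, x))
                    break
    # all-pairs minimum, vectorized over the boundary set
    bnd_arr = np.array(bnd, dtype=float)  # (k, 2) as (y, x)
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    d = np.sqrt(((pts[:, None, :] - bnd_arr[None, :, :]) ** 2).sum(-1)).min(1)
    d = d.reshape(h, w) * pitch_um
    out = np.where(tumor, d, -d)
    out[~(tumor | nontum)] = np.nan
    return out


def hd_weights_by_quadrature(n: int, p: float) -> np.ndarray:
    """Harrell-Davis weights via adaptive quadrature of the beta density."""
    from scipy.integrate import quad
    from scipy.special import betaln

    a, b = (n + 1) * p, (n + 1) * (1 - p)
    lognorm = betaln(a, b)

    def dens(t):
        if t <= 0 or t >= 1:
            return 0.0
        return np.exp((a - 1) * np.log(t) + (b - 1) * np.log1p(-t) - lognorm)

    w = np.empty(n)
    for i in range(n):
        w[i], _ = quad(dens, i / n, (i + 1) / n, epsabs=1e-15, epsrel=1e-13, limit=200)
    return w
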