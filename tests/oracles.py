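"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately re-derive every quantity from first principles (explicit
loops, flood fill, closed-form formulas) so they share no code path with the
package implementations they check.
"""

import numpy as np


def rank_oracle(x):
    """Mid-ranks with average-rank ties, built element by element."""
    x = np.asarray(x, float)
    ranks = np.empty(x.size)
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def pearson_oracle(x, y):
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def spearman_oracle(x, y):
    return pearson_oracle(rank_oracle(x), rank_oracle(y))


def partial_spearman_oracle(a, b, controls):
    """Rank, residualize on controls + intercept via lstsq, correlate."""
    ra, rb = rank_oracle(a), rank_oracle(b)
    design = np.column_stack(
        [np.ones(ra.size)] + [rank_oracle(c) for c in controls]
    )
    res_a = ra - design @ np.linalg.lstsq(design, ra, rcond=None)[0]
    res_b = rb - design @ np.linalg.lstsq(design, rb, rcond=None)[0]
    return pearson_oracle(res_a, res_b)


def tfce_oracle(stat_map, extent_power, height_power, dh):
    """Explicit threshold loop with flood-fill connected components."""
    m = np.maximum(np.asarray(stat_map, float), 0.0)
    shape = m.shape
    out = np.zeros_like(m)
    top = m.max()
    n_steps = int(np.floor(top / dh + 1e-12))

    def neighbors(p):
        if len(shape) == 1:
            (i,) = p
            for d in (-1, 1):
                if 0 <= i + d < shape[0]:
                    yield (i + d,)
        else:
            i, j = p
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                if 0 <= i + di < shape[0] and 0 <= j + dj < shape[1]:
                    yield (i + di, j + dj)

    for k in range(1, n_steps + 1):
        h = k * dh
        mask = m >= h
        seen_global = set()
        for p in np.ndindex(*shape):
            if not mask[p] or p in seen_global:
                continue
            component = {p}
            stack = [p]
            while stack:
                q = stack.pop()
                for nb in neighbors(q):
                    if mask[nb] and nb not in component:
                        component.add(nb)
                        stack.append(nb)
            seen_global |= component
            for q in component:
                out[q] += len(component) ** extent_power * h**height_power * dh
    return out
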