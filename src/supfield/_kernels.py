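"""Numba kernels for the lattice agent-based model.

State is a pair of square grids: ``gen`` (genotype id per cell, -1 for
empty) and ``age`` (time steps since birth).  Edges wrap (torus); the
competitive neighbourhood is the 8-cell Moore neighbourhood.  One update
is synchronous: survival of every agent is decided from the pre-update
state, deaths are applied, survivors reproduce into empty cells
(including cells vacated this same step — which is what produces an
emergent replacement rate below one), and finally all agents age by one
step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EMPTY = -1

#: dispersal mode codes
MODE_RANDOM = 0
MODE_LIMITED = 1
MODE_OVERDISPERSED = 2

#: minimum torus Chebyshev distance for over-dispersed offspring
OVERDISPERSAL_RADIUS = 10


@njit(cache=False)
def _age_mult(a: int, maturity: int) -> float:
    m = a / maturity
    return m if m < 1.0 else 1.0


@njit(cache=False)
def local_suppression(gen, age, S, maturity, on_S, x, y):
    """Mean age-effective suppression over the 8 Moore neighbours.

    Empty cells contribute zero, so local density scales the field the
    way rho does in the mean-field model.
    """
    side = gen.shape[0]
    total = 0.0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            if dx == 0 and dy == 0:
                continue
            xx = (x + dx) % side
            yy = (y + dy) % side
            g = gen[xx, yy]
            if g >= 0:
                m = _age_mult(age[xx, yy], maturity) if on_S else 1.0
                total += S[g] * m
    return total / 8.0


@njit(cache=False)
def survival_probabilities(gen, age, T, S, P, maturity, on_T, on_S):
    """Per-cell survival probability (nan for empty cells); no RNG."""
    side = gen.shape[0]
    out = np.full((side, side), np.nan)
    for x in range(side):
        for y in range(side):
            g = gen[x, y]
            if g < 0:
                continue
            s_loc = local_suppression(gen, age, S, maturity, on_S, x, y)
            t_eff = T[g] * (_age_mult(age[x, y], maturity) if on_T else 1.0)
            out[x, y] = P - P * s_loc * (1.0 - t_eff)
    return out


@njit(cache=False)
def neighbour_pair_counts(gen):
    """(same-genotype, both-occupied) counts over unordered Moore pairs.

    Each unordered pair is visited once via the 4 forward directions
    E, S, SE, NE.
    """
    side = gen.shape[0]
    same = 0
    total = 0
    for x in range(side):
        for y in range(side):
            g = gen[x, y]
            if g < 0:
                continue
            for d in range(4):
                if d == 0:
                    xx, yy = x, (y + 1) % side
                elif d == 1:
                    xx, yy = (x + 1) % side, y
                elif d == 2:
                    xx, yy = (x + 1) % side, (y + 1) % side
                else:
                    xx, yy = (x + 1) % side, (y - 1) % side
                h = gen[xx, yy]
                if h >= 0:
                    total += 1
                    if h == g:
                        same += 1
    return same, total


@njit(cache=False)
def _shuffle_pairs(xs, ys, m):
    for i in range(m - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        xs[i], xs[j] = xs[j], xs[i]
        ys[i], ys[j] = ys[j], ys[i]


@njit(cache=False)
def _census(row, gen, age, maturity, counts, occupied, alpha_mean, pairs_same, pairs_total):
    side = gen.shape[0]
    occ = 0
    asum = 0.0
    for x in range(side):
        for y in range(side):
            g = gen[x, y]
            if g >= 0:
                counts[row, g] += 1
                occ += 1
                asum += _age_mult(age[x, y], maturity)
    occupied[row] = occ
    alpha_mean[row] = asum / occ if occ > 0 else 0.0
    s, t = neighbour_pair_counts(gen)
    pairs_same[row] = s
    pairs_total[row] = t
    return occ


@njit(cache=False)
def simulate(gen, age, T, S, P, fecundity, maturity, on_T, on_S, on_F, mode, steps, seed):
    """Run ``steps`` synchronous updates in place; return per-step records.

    Returns (counts, occupied, alpha_mean, pairs_same, pairs_total,
    deaths, refilled, steps_done): genotype abundances and emergent
    statistics per recorded state (steps+1 rows, row 0 = initial state),
    plus per-update death counts and counts of death-vacated cells
    re-occupied by the end of the same update.  ``steps_done < steps``
    flags extinction.
    """
    np.random.seed(seed)
    side = gen.shape[0]
    k = T.size
    ncell = side * side
    counts = np.zeros((steps + 1, k), np.int64)
    occupied = np.zeros(steps + 1, np.int64)
    alpha_mean = np.zeros(steps + 1)
    pairs_same = np.zeros(steps + 1, np.int64)
    pairs_total = np.zeros(steps + 1, np.int64)
    deaths = np.zeros(steps, np.int64)
    refilled = np.zeros(steps, np.int64)

    death_mask = np.zeros((side, side), np.bool_)
    off_x = np.empty(ncell * fecundity, np.int64)
    off_y = np.empty(ncell * fecundity, np.int64)
    emp_x = np.empty(ncell, np.int64)
    emp_y = np.empty(ncell, np.int64)
    nb_x = np.empty(8, np.int64)
    nb_y = np.empty(8, np.int64)

    _census(0, gen, age, maturity, counts, occupied, alpha_mean, pairs_same, pairs_total)
    steps_done = steps
    for t in range(steps):
        # --- survival (synchronous: decisions from the pre-update state)
        ndeath = 0
        for x in range(side):
            for y in range(side):
                death_mask[x, y] = False
                g = gen[x, y]
                if g < 0:
                    continue
                s_loc = local_suppression(gen, age, S, maturity, on_S, x, y)
                t_eff = T[g] * (_age_mult(age[x, y], maturity) if on_T else 1.0)
                p = P - P * s_loc * (1.0 - t_eff)
                if np.random.random() >= p:
                    death_mask[x, y] = True
                    ndeath += 1
        deaths[t] = ndeath
        for x in range(side):
            for y in range(side):
                if death_mask[x, y]:
                    gen[x, y] = EMPTY
        # --- reproduction by survivors
        noff = 0
        for x in range(side):
            for y in range(side):
                g = gen[x, y]
                if g < 0:
                    continue
                fm = _age_mult(age[x, y], maturity) if on_F else 1.0
                for _ in range(fecundity):
                    if np.random.random() < fm:
                        off_x[noff] = x
                        off_y[noff] = y
                        noff += 1
        _shuffle_pairs(off_x, off_y, noff)
        # --- dispersal into empty cells
        if mode == MODE_RANDOM:
            ne = 0
            for x in range(side):
                for y in range(side):
                    if gen[x, y] < 0:
                        emp_x[ne] = x
                        emp_y[ne] = y
                        ne += 1
            _shuffle_pairs(emp_x, emp_y, ne)
            m = noff if noff < ne else ne
            for i in range(m):
                gen[emp_x[i], emp_y[i]] = gen[off_x[i], off_y[i]]
                age[emp_x[i], emp_y[i]] = 0
        elif mode == MODE_LIMITED:
            for i in range(noff):
                px, py = off_x[i], off_y[i]
                cnt = 0
                for dx in range(-1, 2):
                    for dy in range(-1, 2):
                        if dx == 0 and dy == 0:
                            continue
                        xx = (px + dx) % side
                        yy = (py + dy) % side
                        if gen[xx, yy] < 0:
                            nb_x[cnt] = xx
                            nb_y[cnt] = yy
                            cnt += 1
                if cnt > 0:
                    j = np.random.randint(0, cnt)
                    gen[nb_x[j], nb_y[j]] = gen[px, py]
                    age[nb_x[j], nb_y[j]] = 0
        else:  # MODE_OVERDISPERSED: uniform over empties at torus
            # Chebyshev distance >= OVERDISPERSAL_RADIUS, by rejection
            for i in range(noff):
                px, py = off_x[i], off_y[i]
                for _try in range(200):
                    rx = np.random.randint(0, side)
                    ry = np.random.randint(0, side)
                    if gen[rx, ry] >= 0:
                        continue
                    dx = abs(rx - px)
                    if side - dx < dx:
                        dx = side - dx
                    dy = abs(ry - py)
                    if side - dy < dy:
                        dy = side - dy
                    if dx >= OVERDISPERSAL_RADIUS or dy >= OVERDISPERSAL_RADIUS:
                        gen[rx, ry] = gen[px, py]
                        age[rx, ry] = 0
                        break
        # --- replacement accounting
        nref = 0
        for x in range(side):
            for y in range(side):
                if death_mask[x, y] and gen[x, y] >= 0:
                    nref += 1
        refilled[t] = nref
        # --- aging (newborns were placed with age 0 -> age 1 now)
        for x in range(side):
            for y in range(side):
                if gen[x, y] >= 0:
                    age[x, y] += 1
        occ = _census(
            t + 1, gen, age, maturity, counts, occupied, alpha_mean, pairs_same, pairs_total
        )
        if occ == 0:
            steps_done = t + 1
            break
    return counts, occupied, alpha_mean, pairs_same, pairs_total, deaths, refilled, steps_done
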