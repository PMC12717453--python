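"""Compiled inner loop: one night of movement, encounters and trapping.

The engine advances each night as 16 sequential 30-minute steps.  Within a
step stoats act in freshly randomised order; each one (1) re-assesses its
centre of attraction (home-range centre, or a multinomially selected mate /
nest / pheromone decoy within the 2.5 km detection radius), (2) draws a von
Mises bearing and exponential step length and moves, redrawing up to
``max_tries`` times if the step would leave the island, (3) resolves
encounters within 25 m, and (4) is tested against the nearest active trap
within 15 m.

Two encounter semantics are supported (``selected_only``):

* True (default): an interaction happens only when the stoat's *selected*
  COA lies within 25 m at the end of the step; the interaction partner is
  then chosen mate-first among everything in range.  A stoat honing in on
  a decoy walks straight past unselected potential mates — the distraction
  mechanism that makes decoys disruptive.
* False: any non-habituated entity within 25 m triggers an interaction,
  mates taking precedence over decoys (opportunistic encounters).

Everything operates on the flat numpy buffers owned by
:class:`~stoatsim.life_history.Population`, mutating them in place.  All
randomness flows through the single numpy ``Generator`` of the realisation,
so runs are reproducible given the seed.  Static point sets (decoys,
traps) are pre-binned into uniform-grid CSR structures so per-step
neighbourhood scans touch only nearby points.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .movement import _draw_vonmises, _draw_exponential, _point_in_polygon

NEST_CODE_BASE = 1_000_000
STOAT_CODE_BASE = 2_000_000

# selected-COA kinds
K_NONE, K_STOAT, K_NEST, K_DECOY = 0, 1, 2, 3


class GridIndex:
    """Uniform-grid spatial index (CSR layout) over a static point set."""

    __slots__ = ("x", "y", "x0", "y0", "cell", "nx", "ny", "start", "items")

    def __init__(self, xy: np.ndarray, cell: float):
        xy = np.asarray(xy, dtype=np.float64).reshape(-1, 2)
        self.x = np.ascontiguousarray(xy[:, 0])
        self.y = np.ascontiguousarray(xy[:, 1])
        self.cell = float(cell)
        if len(xy):
            self.x0 = float(self.x.min())
            self.y0 = float(self.y.min())
            self.nx = int((self.x.max() - self.x0) // cell) + 1
            self.ny = int((self.y.max() - self.y0) // cell) + 1
        else:
            self.x0 = self.y0 = 0.0
            self.nx = self.ny = 1
        cix = ((self.x - self.x0) // cell).astype(np.int64)
        ciy = ((self.y - self.y0) // cell).astype(np.int64)
        flat = ciy * self.nx + cix
        order = np.argsort(flat, kind="stable")
        self.items = order.astype(np.int64)
        counts = np.bincount(flat, minlength=self.nx * self.ny)
        self.start = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)


_EMPTY_GRID = GridIndex(np.empty((0, 2)), 1.0)


@njit(cache=True)
def _is_habituated(hab_code, hab_exp, i, code, day):
    for s in range(hab_code.shape[1]):
        if hab_code[i, s] == code and hab_exp[i, s] > day:
            return True
    return False


@njit(cache=True)
def _add_habituation(hab_code, hab_exp, i, code, expiry):
    cap = hab_code.shape[1]
    for s in range(cap):
        if hab_code[i, s] == code:
            if expiry > hab_exp[i, s]:
                hab_exp[i, s] = expiry
            return
    best = 0
    for s in range(1, cap):
        if hab_exp[i, s] < hab_exp[i, best]:
            best = s
    hab_code[i, best] = code
    hab_exp[i, best] = expiry


@njit(cache=True)
def _scan_coas(i, threshold, n, male, x, y, alive, attractive,
               hab_code, hab_exp, day,
               nest_x, nest_y, nest_fem, nest_mated, nest_alive,
               dec_on, dec_x, dec_y, dec_w,
               dg_start, dg_items, dg_x0, dg_y0, dg_cell, dg_nx, dg_ny,
               det_r, delta):
    """Walk all COA candidates of stoat i in a fixed order.

    With ``threshold < 0`` returns (K_NONE, -1, 0., 0., total_weight)
    where total_weight sums exp(-delta*dist) [times the decoy age factor
    for decoys].  With a threshold in [0, total) returns
    (kind, index, tx, ty, weight) for the candidate at which the running
    sum first exceeds it, implementing the multinomial selection with
    probability weight/total.
    """
    xi = x[i]
    yi = y[i]
    i_male = male[i]
    acc = 0.0
    # opposite-sex mate-searching / receptive stoats
    for j in range(n):
        if j == i or not alive[j] or male[j] == i_male or not attractive[j]:
            continue
        dx = x[j] - xi
        dy = y[j] - yi
        d = math.sqrt(dx * dx + dy * dy)
        if d > det_r:
            continue
        if _is_habituated(hab_code, hab_exp, i, STOAT_CODE_BASE + j, day):
            continue
        w = math.exp(-delta * d)
        acc += w
        if threshold >= 0.0 and acc > threshold:
            return K_STOAT, j, x[j], y[j], w
    # nests holding unmated female kits attract males
    if i_male:
        for j in range(len(nest_x)):
            if not nest_alive[j] or nest_mated[j] or nest_fem[j] == 0:
                continue
            dx = nest_x[j] - xi
            dy = nest_y[j] - yi
            d = math.sqrt(dx * dx + dy * dy)
            if d > det_r:
                continue
            if _is_habituated(hab_code, hab_exp, i, NEST_CODE_BASE + j, day):
                continue
            w = math.exp(-delta * d)
            acc += w
            if threshold >= 0.0 and acc > threshold:
                return K_NEST, j, nest_x[j], nest_y[j], w
    # active pheromone decoys (shared age factor dec_w)
    if dec_on and dec_w > 0.0:
        cix = int((xi - dg_x0) // dg_cell)
        ciy = int((yi - dg_y0) // dg_cell)
        for cy in range(max(0, ciy - 1), min(dg_ny, ciy + 2)):
            for cx in range(max(0, cix - 1), min(dg_nx, cix + 2)):
                c = cy * dg_nx + cx
                for s in range(dg_start[c], dg_start[c + 1]):
                    j = dg_items[s]
                    dx = dec_x[j] - xi
                    dy = dec_y[j] - yi
                    d = math.sqrt(dx * dx + dy * dy)
                    if d > det_r:
                        continue
                    if _is_habituated(hab_code, hab_exp, i, j, day):
                        continue
                    w = math.exp(-delta * d) * dec_w
                    acc += w
                    if threshold >= 0.0 and acc > threshold:
                        return K_DECOY, j, dec_x[j], dec_y[j], w
    return K_NONE, -1, 0.0, 0.0, acc


@njit(cache=True)
def _nearest_grid_point(xi, yi, gx, gy, g_start, g_items,
                        g_x0, g_y0, g_cell, g_nx, g_ny, radius):
    """Index and distance of the nearest indexed point within ``radius``
    (or (-1, inf))."""
    best = -1
    best_d = 1e30
    cix = int((xi - g_x0) // g_cell)
    ciy = int((yi - g_y0) // g_cell)
    for cy in range(max(0, ciy - 1), min(g_ny, ciy + 2)):
        for cx in range(max(0, cix - 1), min(g_nx, cix + 2)):
            c = cy * g_nx + cx
            for s in range(g_start[c], g_start[c + 1]):
                j = g_items[s]
                dx = gx[j] - xi
                dy = gy[j] - yi
                d = math.sqrt(dx * dx + dy * dy)
                if d <= radius and d < best_d:
                    best = j
                    best_d = d
    return best, best_d


@njit(cache=True)
def run_night(rng, n, male, x, y, hx, hy, alive, ms, attractive, pregnant,
              nursing, hab_code, hab_exp, death_cause,
              nest_x, nest_y, nest_fem, nest_mated, nest_fem_preg, nest_alive,
              dec_on, dec_x, dec_y, dec_w,
              dg_start, dg_items, dg_x0, dg_y0, dg_cell, dg_nx, dg_ny,
              traps_live, trap_x, trap_y,
              tg_start, tg_items, tg_x0, tg_y0, tg_cell, tg_nx, tg_ny,
              poly_x, poly_y,
              alpha, delta, min_k, base_scale, det_r, enc_mate, enc_trap,
              p_capture, p_preg, hab_days, day, steps, oestrus, max_tries,
              selected_only):
    """Advance one night in place; returns (trap_deaths, conceptions)."""
    order = np.empty(n, dtype=np.int64)
    trap_deaths = 0
    conceptions = 0
    for _step in range(steps):
        for i in range(n):
            order[i] = i
        for i in range(n - 1, 0, -1):
            j = rng.integers(0, i + 1)
            t = order[i]
            order[i] = order[j]
            order[j] = t
        for oi in range(n):
            i = order[oi]
            if not alive[i]:
                continue
            # --- (1) centre of attraction ---
            seeking = oestrus and ms[i]
            sel_kind = K_NONE
            sel_idx = -1
            if seeking:
                _, _, _, _, total = _scan_coas(
                    i, -1.0, n, male, x, y, alive, attractive,
                    hab_code, hab_exp, day,
                    nest_x, nest_y, nest_fem, nest_mated, nest_alive,
                    dec_on, dec_x, dec_y, dec_w,
                    dg_start, dg_items, dg_x0, dg_y0, dg_cell, dg_nx, dg_ny,
                    det_r, delta)
                if total > 0.0:
                    thr = rng.random() * total
                    sel_kind, sel_idx, tx, ty, w = _scan_coas(
                        i, thr, n, male, x, y, alive, attractive,
                        hab_code, hab_exp, day,
                        nest_x, nest_y, nest_fem, nest_mated, nest_alive,
                        dec_on, dec_x, dec_y, dec_w,
                        dg_start, dg_items, dg_x0, dg_y0, dg_cell, dg_nx, dg_ny,
                        det_r, delta)
                    dx = tx - x[i]
                    dy = ty - y[i]
                    dist = math.sqrt(dx * dx + dy * dy)
                    mu = math.atan2(dx, dy)
                    kappa = w / min_k
                    scale = dist / 2.0 if dist < base_scale else base_scale
                else:
                    mu = 0.0
                    kappa = 0.0  # no scent within range: unbiased walk
                    scale = base_scale
            else:
                dx = hx[i] - x[i]
                dy = hy[i] - y[i]
                dist = math.sqrt(dx * dx + dy * dy)
                kappa = alpha * math.log(dist) if dist > 1.0 else 0.0
                mu = math.atan2(dx, dy)
                scale = base_scale
            # --- (2) constrained move ---
            for _try in range(max_tries):
                b = _draw_vonmises(rng, mu, kappa)
                ln = _draw_exponential(rng, scale)
                cand_x = x[i] + ln * math.sin(b)
                cand_y = y[i] + ln * math.cos(b)
                if _point_in_polygon(cand_x, cand_y, poly_x, poly_y):
                    x[i] = cand_x
                    y[i] = cand_y
                    break
            # --- (3) encounters (mate-searching stoats only) ---
            if seeking and ms[i] and alive[i]:
                xi = x[i]
                yi = y[i]
                i_male = male[i]
                interact = True
                if selected_only:
                    # only the selected COA, still within 25 m, triggers
                    # an interaction
                    interact = False
                    if sel_kind == K_STOAT:
                        ddx = x[sel_idx] - xi
                        ddy = y[sel_idx] - yi
                        interact = ddx * ddx + ddy * ddy <= enc_mate * enc_mate
                    elif sel_kind == K_NEST:
                        ddx = nest_x[sel_idx] - xi
                        ddy = nest_y[sel_idx] - yi
                        interact = ddx * ddx + ddy * ddy <= enc_mate * enc_mate
                    elif sel_kind == K_DECOY:
                        ddx = dec_x[sel_idx] - xi
                        ddy = dec_y[sel_idx] - yi
                        interact = ddx * ddx + ddy * ddy <= enc_mate * enc_mate
                if interact:
                    # partner: nearest non-habituated mate/nest in range,
                    # mates taking precedence over decoys
                    mate_j = -1
                    mate_d = 1e30
                    nest_j = -1
                    for j in range(n):
                        if j == i or not alive[j] or male[j] == i_male \
                                or not attractive[j]:
                            continue
                        ddx = x[j] - xi
                        ddy = y[j] - yi
                        d = math.sqrt(ddx * ddx + ddy * ddy)
                        if d <= enc_mate and d < mate_d and not _is_habituated(
                                hab_code, hab_exp, i, STOAT_CODE_BASE + j, day):
                            mate_j = j
                            mate_d = d
                    if i_male:
                        for j in range(len(nest_x)):
                            if not nest_alive[j] or nest_mated[j] \
                                    or nest_fem[j] == 0:
                                continue
                            ddx = nest_x[j] - xi
                            ddy = nest_y[j] - yi
                            d = math.sqrt(ddx * ddx + ddy * ddy)
                            if d <= enc_mate and d < mate_d \
                                    and not _is_habituated(
                                        hab_code, hab_exp, i,
                                        NEST_CODE_BASE + j, day):
                                nest_j = j
                                mate_j = -1
                                mate_d = d
                    if nest_j >= 0:
                        # mate every unmated female kit in the nest
                        _add_habituation(hab_code, hab_exp, i,
                                         NEST_CODE_BASE + nest_j,
                                         day + hab_days)
                        got = 0
                        for _k in range(nest_fem[nest_j]):
                            if rng.random() < p_preg:
                                got += 1
                        nest_mated[nest_j] = True
                        nest_fem_preg[nest_j] = got
                        conceptions += got
                    elif mate_j >= 0:
                        # the male habituates to the female he mated,
                        # whichever of the pair moved
                        if i_male:
                            m_idx, f_idx = i, mate_j
                        else:
                            m_idx, f_idx = mate_j, i
                        _add_habituation(hab_code, hab_exp, m_idx,
                                         STOAT_CODE_BASE + f_idx,
                                         day + hab_days)
                        if not pregnant[f_idx] and rng.random() < p_preg:
                            pregnant[f_idx] = True
                            ms[f_idx] = False  # fertilised: back to home range
                            conceptions += 1
                    elif dec_on and dec_w > 0.0:
                        # decoy interaction: habituate
                        if selected_only and sel_kind == K_DECOY:
                            dj = sel_idx
                        else:
                            dj, _dd = _nearest_grid_point(
                                xi, yi, dec_x, dec_y, dg_start, dg_items,
                                dg_x0, dg_y0, dg_cell, dg_nx, dg_ny, enc_mate)
                        if dj >= 0 and not _is_habituated(
                                hab_code, hab_exp, i, dj, day):
                            _add_habituation(hab_code, hab_exp, i, dj,
                                             day + hab_days)
            # --- (4) trap check ---
            if traps_live and alive[i]:
                tj, _td = _nearest_grid_point(
                    x[i], y[i], trap_x, trap_y, tg_start, tg_items,
                    tg_x0, tg_y0, tg_cell, tg_nx, tg_ny, enc_trap)
                if tj >= 0 and rng.random() < p_capture:
                    alive[i] = False
                    ms[i] = False
                    attractive[i] = False
                    death_cause[i] = 1
                    trap_deaths += 1
    return trap_deaths, conceptions
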