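"""Numba-compiled inner loop for independent-learner DQN training.

The per-step work — featurization, epsilon-greedy action selection, the
physics update, prioritized-replay sampling, the double-DQN target, Huber
backprop and the Adam update for every agent — runs inside one compiled
chunk so that desk-scale runs (tens of thousands of episodes) complete in
minutes on one CPU core. Network math runs in float32; p_i^alpha values are
cached so prioritized sampling costs one cumulative sum per draw. The
helpers mirror the float64 numpy implementations in ``env``, ``agents`` and
``learning`` one-to-one; the test suite checks the two paths against each
other step by step.

Event codes: 0 none, 1 capture, 2 prey out, 3 predator out, 4 timeout.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ADAM_B1 = 0.9
ADAM_B2 = 0.999
ADAM_EPS = 1e-8

F0 = np.float32(0.0)
F1 = np.float32(1.0)
FB1 = np.float32(ADAM_B1)
FB2 = np.float32(ADAM_B2)
FC1 = np.float32(1.0 - ADAM_B1)
FC2 = np.float32(1.0 - ADAM_B2)
FEPS = np.float32(ADAM_EPS)


@njit(cache=True)
def featurize(pos, vel, agent, n_pred, out):
    """Fill ``out`` with the agent's state vector (same layout as
    agents.build_state_vector)."""
    n_agents = pos.shape[0]
    prey = n_pred
    if agent != prey:
        ref = prey
    else:
        ref = 0
        best = 1e300
        for j in range(n_pred):
            dx = pos[j, 0] - pos[agent, 0]
            dy = pos[j, 1] - pos[agent, 1]
            d2 = dx * dx + dy * dy
            if d2 < best:
                best = d2
                ref = j
    dx = pos[ref, 0] - pos[agent, 0]
    dy = pos[ref, 1] - pos[agent, 1]
    nrm = np.sqrt(dx * dx + dy * dy)
    if nrm < 1e-12:
        ux, uy = 1.0, 0.0
    else:
        ux, uy = dx / nrm, dy / nrm
    vx_ax, vy_ax = -uy, ux
    out[0] = pos[agent, 0]
    out[1] = pos[agent, 1]
    out[2] = ux * vel[agent, 0] + uy * vel[agent, 1]
    out[3] = vx_ax * vel[agent, 0] + vy_ax * vel[agent, 1]
    k = 4
    for other in range(n_agents):
        if other == agent:
            continue
        px = pos[other, 0] - pos[agent, 0]
        py = pos[other, 1] - pos[agent, 1]
        qx = vel[other, 0] - vel[agent, 0]
        qy = vel[other, 1] - vel[agent, 1]
        out[k] = ux * px + uy * py
        out[k + 1] = vx_ax * px + vy_ax * py
        out[k + 2] = ux * qx + uy * qy
        out[k + 3] = vx_ax * qx + vy_ax * qy
        k += 4


@njit(cache=True, fastmath=True)
def q_forward_one(w1, b1, w2, b2, wa, ba, wa2, ba2, wv, bv, wv2, bv2, s):
    """Q values (13,) for a single state (float32)."""
    h1 = np.maximum(np.dot(s, w1) + b1, F0)
    h2 = np.maximum(np.dot(h1, w2) + b2, F0)
    ha = np.maximum(np.dot(h2, wa) + ba, F0)
    adv = np.dot(ha, wa2) + ba2
    hv = np.maximum(np.dot(h2, wv) + bv, F0)
    val = np.dot(hv, wv2)[0] + bv2[0]
    return val + adv - adv.mean()


@njit(cache=True, fastmath=True)
def q_forward_batch(w1, b1, w2, b2, wa, ba, wa2, ba2, wv, bv, wv2, bv2, x):
    """Q values (B, 13) for a batch of states (float32)."""
    h1 = np.maximum(np.dot(x, w1) + b1, F0)
    h2 = np.maximum(np.dot(h1, w2) + b2, F0)
    ha = np.maximum(np.dot(h2, wa) + ba, F0)
    adv = np.dot(ha, wa2) + ba2
    hv = np.maximum(np.dot(h2, wv) + bv, F0)
    val = np.dot(hv, wv2)
    q = np.empty_like(adv)
    n_act = adv.shape[1]
    for i in range(adv.shape[0]):
        m = F0
        for a in range(n_act):
            m += adv[i, a]
        m /= n_act
        for a in range(n_act):
            q[i, a] = val[i, 0] + bv2[0] + adv[i, a] - m
    return q


@njit(cache=True)
def env_step(pos, vel, actions, n_pred, mobility, prey_accel, damping, dt, diameter, half,
             step_next, max_steps, shared, new_pos, new_vel, rewards):
    """One physics step on raw arrays; returns (event_code, event_agent).

    ``actions`` are 1-based; rewards are written in place. Mirrors
    env.step / env.detect_events / env.compute_rewards (float64).
    """
    n_agents = pos.shape[0]
    prey = n_pred
    for i in range(n_agents):
        a = actions[i]
        if a == 13:
            ax, ay = 0.0, 0.0
        else:
            if i != prey:
                ref = prey
                mag = prey_accel * mobility
            else:
                ref = 0
                best = 1e300
                for j in range(n_pred):
                    ddx = pos[j, 0] - pos[i, 0]
                    ddy = pos[j, 1] - pos[i, 1]
                    d2 = ddx * ddx + ddy * ddy
                    if d2 < best:
                        best = d2
                        ref = j
                mag = prey_accel
            dx = pos[ref, 0] - pos[i, 0]
            dy = pos[ref, 1] - pos[i, 1]
            nrm = np.sqrt(dx * dx + dy * dy)
            if nrm < 1e-12:
                ux, uy = 1.0, 0.0
            else:
                ux, uy = dx / nrm, dy / nrm
            theta = (a - 1) * (np.pi / 6.0)
            c, s_ = np.cos(theta), np.sin(theta)
            ax = mag * (c * ux + s_ * (-uy))
            ay = mag * (c * uy + s_ * ux)
        new_vel[i, 0] = damping * vel[i, 0] + ax * dt
        new_vel[i, 1] = damping * vel[i, 1] + ay * dt
        new_pos[i, 0] = pos[i, 0] + new_vel[i, 0] * dt
        new_pos[i, 1] = pos[i, 1] + new_vel[i, 1] * dt

    event = 0
    event_agent = -1
    best = 1e300
    for j in range(n_pred):
        dx = new_pos[j, 0] - new_pos[prey, 0]
        dy = new_pos[j, 1] - new_pos[prey, 1]
        d = np.sqrt(dx * dx + dy * dy)
        if d < best:
            best = d
            if d <= diameter:
                event = 1
                event_agent = j
    if event != 1:
        if abs(new_pos[prey, 0]) > half or abs(new_pos[prey, 1]) > half:
            event = 2
            event_agent = prey
        else:
            for j in range(n_pred):
                if abs(new_pos[j, 0]) > half or abs(new_pos[j, 1]) > half:
                    event = 3
                    event_agent = j
                    break
            if event == 0 and step_next >= max_steps:
                event = 4

    for i in range(n_agents):
        rewards[i] = 0.0
    if event == 1:
        if shared:
            for j in range(n_pred):
                rewards[j] = 1.0
        else:
            rewards[event_agent] = 1.0
        rewards[prey] = -1.0
    elif event == 2:
        rewards[prey] = -1.0
    elif event == 3:
        rewards[event_agent] = -1.0
    return event, event_agent


@njit(cache=True, fastmath=True)
def _adam2(w, g, m, v, ibc1, ibc2, lr):
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            gij = g[i, j]
            mij = FB1 * m[i, j] + FC1 * gij
            vij = FB2 * v[i, j] + FC2 * gij * gij
            m[i, j] = mij
            v[i, j] = vij
            w[i, j] -= lr * (mij * ibc1) / (np.sqrt(vij * ibc2) + FEPS)


@njit(cache=True, fastmath=True)
def _adam1(w, g, m, v, ibc1, ibc2, lr):
    for j in range(w.shape[0]):
        gj = g[j]
        mj = FB1 * m[j] + FC1 * gj
        vj = FB2 * v[j] + FC2 * gj * gj
        m[j] = mj
        v[j] = vj
        w[j] -= lr * (mj * ibc1) / (np.sqrt(vj * ibc2) + FEPS)


@njit(cache=True, fastmath=True)
def _mm_At_B(a, b, out):
    """out = a.T @ b for C-contiguous float32 a (n, k), b (n, m)."""
    n, k = a.shape
    m = b.shape[1]
    for i in range(k):
        for j in range(m):
            out[i, j] = F0
    for r in range(n):
        for i in range(k):
            ari = a[r, i]
            for j in range(m):
                out[i, j] += ari * b[r, j]


@njit(cache=True, fastmath=True)
def _mm_A_Bt(a, b, out):
    """out = a @ b.T for C-contiguous float32 a (n, k), b (m, k)."""
    n, k = a.shape
    m = b.shape[0]
    for r in range(n):
        for i in range(m):
            acc = F0
            for j in range(k):
                acc += a[r, j] * b[i, j]
            out[r, i] = acc


@njit(cache=True, fastmath=True)
def train_step(online, target, mstate, vstate, t_adam, xs, acts, rs_, x2s, dones, ws,
               gamma, lr, td_out):
    """One gradient step: DDQN targets, IS-weighted Huber loss, Adam.

    ``online``/``target``/``mstate``/``vstate`` are 12-tuples of float32
    arrays (w1,b1,w2,b2,wa,ba,wa2,ba2,wv,bv,wv2,bv2). The online forward
    passes for s and s' share one stacked GEMM chain. TD errors are written
    to ``td_out``; the scalar loss is returned.
    """
    w1, b1, w2, b2, wa, ba, wa2, ba2, wv, bv, wv2, bv2 = online
    tw1, tb1, tw2, tb2, twa, tba, twa2, tba2, twv, tbv, twv2, tbv2 = target
    B = xs.shape[0]
    dim = xs.shape[1]
    n_act = wa2.shape[1]

    xcat = np.empty((2 * B, dim), dtype=np.float32)
    xcat[:B] = xs
    xcat[B:] = x2s
    z1 = np.dot(xcat, w1) + b1
    h1 = np.maximum(z1, F0)
    z2 = np.dot(h1, w2) + b2
    h2 = np.maximum(z2, F0)
    za = np.dot(h2, wa) + ba
    ha = np.maximum(za, F0)
    adv = np.dot(ha, wa2) + ba2
    zv = np.dot(h2, wv) + bv
    hv = np.maximum(zv, F0)
    val = np.dot(hv, wv2)

    # double-DQN targets: online argmax (rows B..2B), target evaluation
    q2t = q_forward_batch(tw1, tb1, tw2, tb2, twa, tba, twa2, tba2, twv, tbv, twv2, tbv2, x2s)
    ys = np.empty(B, dtype=np.float32)
    for i in range(B):
        if dones[i] > 0.5:
            ys[i] = rs_[i]
        else:
            j = B + i
            m = F0
            for a in range(n_act):
                m += adv[j, a]
            m /= n_act
            astar = 0
            best = adv[j, 0]
            for a in range(1, n_act):
                if adv[j, a] > best:  # argmax of Q == argmax of advantages
                    best = adv[j, a]
                    astar = a
            ys[i] = rs_[i] + gamma * q2t[i, astar]

    loss = 0.0
    g = np.empty(B, dtype=np.float32)
    for i in range(B):
        m = F0
        for a in range(n_act):
            m += adv[i, a]
        m /= n_act
        qa = val[i, 0] + bv2[0] + adv[i, acts[i] - 1] - m
        td = ys[i] - qa
        td_out[i] = td
        atd = abs(td)
        if atd <= F1:
            loss += ws[i] * np.float32(0.5) * td * td
            dh = td
        else:
            loss += ws[i] * (atd - np.float32(0.5))
            dh = F1 if td > F0 else -F1
        g[i] = -ws[i] * dh / B
    loss /= B

    # gradients flow only through Q(s, a), not through the target y
    dq = np.zeros((B, n_act), dtype=np.float32)
    dval = np.empty((B, 1), dtype=np.float32)
    for i in range(B):
        dq[i, acts[i] - 1] = g[i]
        dval[i, 0] = g[i]
    dadv = np.empty((B, n_act), dtype=np.float32)
    for i in range(B):
        mean_g = g[i] / n_act
        for a in range(n_act):
            dadv[i, a] = dq[i, a] - mean_g

    # row slices of the fused activations are contiguous views
    hvB, haB, h2B, h1B = hv[:B], ha[:B], h2[:B], h1[:B]
    n_h = w2.shape[1]
    n_s = wa.shape[1]

    dwv2 = np.empty((n_s, 1), dtype=np.float32)
    _mm_At_B(hvB, dval, dwv2)
    dbv2 = np.empty(1, dtype=np.float32)
    dbv2[0] = dval.sum()
    dzv = np.empty((B, n_s), dtype=np.float32)
    _mm_A_Bt(dval, wv2, dzv)  # dhv
    for i in range(B):
        for j in range(n_s):
            if zv[i, j] <= F0:
                dzv[i, j] = F0
    dwa2 = np.empty((n_s, n_act), dtype=np.float32)
    _mm_At_B(haB, dadv, dwa2)
    dba2 = np.empty(n_act, dtype=np.float32)
    for a in range(n_act):
        acc = F0
        for i in range(B):
            acc += dadv[i, a]
        dba2[a] = acc
    dza = np.empty((B, n_s), dtype=np.float32)
    _mm_A_Bt(dadv, wa2, dza)  # dha
    for i in range(B):
        for j in range(n_s):
            if za[i, j] <= F0:
                dza[i, j] = F0
    dwv = np.empty((n_h, n_s), dtype=np.float32)
    _mm_At_B(h2B, dzv, dwv)
    dbv = np.empty(n_s, dtype=np.float32)
    dba = np.empty(n_s, dtype=np.float32)
    for j in range(n_s):
        av = F0
        aa = F0
        for i in range(B):
            av += dzv[i, j]
            aa += dza[i, j]
        dbv[j] = av
        dba[j] = aa
    dwa = np.empty((n_h, n_s), dtype=np.float32)
    _mm_At_B(h2B, dza, dwa)
    dz2 = np.empty((B, n_h), dtype=np.float32)
    dz2b = np.empty((B, n_h), dtype=np.float32)
    _mm_A_Bt(dzv, wv, dz2)
    _mm_A_Bt(dza, wa, dz2b)
    for i in range(B):
        for j in range(n_h):
            dz2[i, j] = dz2[i, j] + dz2b[i, j] if z2[i, j] > F0 else F0
    dw2 = np.empty((n_h, n_h), dtype=np.float32)
    _mm_At_B(h1B, dz2, dw2)
    db2 = np.empty(n_h, dtype=np.float32)
    for j in range(n_h):
        acc = F0
        for i in range(B):
            acc += dz2[i, j]
        db2[j] = acc
    dz1 = np.empty((B, n_h), dtype=np.float32)
    _mm_A_Bt(dz2, w2, dz1)  # dh1
    for i in range(B):
        for j in range(n_h):
            if z1[i, j] <= F0:
                dz1[i, j] = F0
    dw1 = np.empty((dim, n_h), dtype=np.float32)
    _mm_At_B(xs, dz1, dw1)
    db1 = np.empty(n_h, dtype=np.float32)
    for j in range(n_h):
        acc = F0
        for i in range(B):
            acc += dz1[i, j]
        db1[j] = acc

    m1, mb1, m2, mb2, ma, mba_, ma2, mba2_, mv, mbv_, mv2, mbv2_ = mstate
    v1, vb1, v2, vb2, va, vba_, va2, vba2_, vv, vbv_, vv2, vbv2_ = vstate
    ibc1 = np.float32(1.0 / (1.0 - ADAM_B1 ** t_adam))
    ibc2 = np.float32(1.0 / (1.0 - ADAM_B2 ** t_adam))
    _adam2(w1, dw1, m1, v1, ibc1, ibc2, lr)
    _adam1(b1, db1, mb1, vb1, ibc1, ibc2, lr)
    _adam2(w2, dw2, m2, v2, ibc1, ibc2, lr)
    _adam1(b2, db2, mb2, vb2, ibc1, ibc2, lr)
    _adam2(wa, dwa, ma, va, ibc1, ibc2, lr)
    _adam1(ba, dba, mba_, vba_, ibc1, ibc2, lr)
    _adam2(wa2, dwa2, ma2, va2, ibc1, ibc2, lr)
    _adam1(ba2, dba2, mba2_, vba2_, ibc1, ibc2, lr)
    _adam2(wv, dwv, mv, vv, ibc1, ibc2, lr)
    _adam1(bv, dbv, mbv_, vbv_, ibc1, ibc2, lr)
    _adam2(wv2, dwv2, mv2, vv2, ibc1, ibc2, lr)
    _adam1(bv2, dbv2, mbv2_, vbv2_, ibc1, ibc2, lr)
    return loss


@njit(cache=True, fastmath=True)
def _sample_indices(prio_alpha, size, batch, idx_out, w_out, beta):
    """Proportional prioritized sampling + IS weights (normalized by max).

    ``prio_alpha`` caches p_i^alpha so drawing a batch costs one cumulative
    sum; the powers are maintained incrementally where priorities change.
    """
    cum = np.empty(size, dtype=np.float32)
    total = F0
    for k in range(size):
        total += prio_alpha[k]
        cum[k] = total
    wmax = 0.0
    for b in range(batch):
        r = np.float32(np.random.random()) * total
        lo, hi = 0, size - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if cum[mid] < r:
                lo = mid + 1
            else:
                hi = mid
        idx_out[b] = lo
        p = prio_alpha[lo] / total
        w = (1.0 / (size * p)) ** beta
        w_out[b] = w
        if w > wmax:
            wmax = w
    for b in range(batch):
        w_out[b] /= np.float32(wmax)


@njit(cache=True)
def train_chunk(seed, ep_offset, n_episodes,
                n_pred, mobility, prey_accel, damping, dt, diameter, half, max_steps,
                init_range, shared,
                gamma, alpha, beta, lr, batch, target_sync_every,
                eps_start, eps_final, eps_anneal, prio_floor,
                online, target, mstate, vstate, adam_t,
                rep_s, rep_a, rep_r, rep_s2, rep_d, rep_p, rep_pa, rep_meta, rep_max,
                ep_len, ep_event, ep_return, ep_loss):
    """Train every agent for a block of episodes (in-place on all state).

    Stacked float32 arrays carry one leading agent axis. ``rep_meta[i] =
    (ptr, size)`` for agent i's ring buffer. The epsilon schedule and
    target-network syncs use the global episode index ``ep_offset + e``.
    """
    np.random.seed(seed)
    w1, b1, w2, b2, wa, ba, wa2, ba2, wv, bv, wv2, bv2 = online
    tw1, tb1, tw2, tb2, twa, tba, twa2, tba2, twv, tbv, twv2, tbv2 = target
    n_agents = n_pred + 1
    dim = rep_s.shape[2]
    cap = rep_s.shape[1]
    gamma32 = np.float32(gamma)
    lr32 = np.float32(lr)

    S = np.empty((n_agents, dim), dtype=np.float32)
    S2 = np.empty((n_agents, dim), dtype=np.float32)
    actions = np.empty(n_agents, dtype=np.int64)
    rewards = np.empty(n_agents)
    new_pos = np.empty((n_agents, 2))
    new_vel = np.empty((n_agents, 2))
    xs = np.empty((batch, dim), dtype=np.float32)
    x2s = np.empty((batch, dim), dtype=np.float32)
    acts = np.empty(batch, dtype=np.int64)
    rs_ = np.empty(batch, dtype=np.float32)
    dones = np.empty(batch, dtype=np.float32)
    ws = np.empty(batch, dtype=np.float32)
    idx = np.empty(batch, dtype=np.int64)
    td = np.empty(batch, dtype=np.float32)

    for e in range(n_episodes):
        ep_global = ep_offset + e
        if target_sync_every > 0 and ep_global % target_sync_every == 0:
            tw1[:] = w1; tb1[:] = b1; tw2[:] = w2; tb2[:] = b2
            twa[:] = wa; tba[:] = ba; twa2[:] = wa2; tba2[:] = ba2
            twv[:] = wv; tbv[:] = bv; twv2[:] = wv2; tbv2[:] = bv2
        if ep_global >= eps_anneal:
            eps = eps_final
        else:
            eps = eps_start + (eps_final - eps_start) * ep_global / eps_anneal

        pos = (np.random.random((n_agents, 2)) * 2.0 - 1.0) * init_range
        vel = np.zeros((n_agents, 2))
        for i in range(n_agents):
            ep_return[e, i] = 0.0
            ep_loss[e, i] = 0.0
        n_updates = 0
        event = 0
        t = 0
        for t in range(max_steps):
            for i in range(n_agents):
                featurize(pos, vel, i, n_pred, S[i])
            for i in range(n_agents):
                if np.random.random() < eps:
                    actions[i] = 1 + np.int64(np.random.random() * 13.0)
                else:
                    q = q_forward_one(w1[i], b1[i], w2[i], b2[i], wa[i], ba[i], wa2[i],
                                      ba2[i], wv[i], bv[i], wv2[i], bv2[i], S[i])
                    best = q[0]
                    abest = 0
                    for a in range(1, 13):
                        if q[a] > best:
                            best = q[a]
                            abest = a
                    actions[i] = abest + 1
            event, _ = env_step(pos, vel, actions, n_pred, mobility, prey_accel, damping,
                                dt, diameter, half, t + 1, max_steps, shared,
                                new_pos, new_vel, rewards)
            for i in range(n_agents):
                featurize(new_pos, new_vel, i, n_pred, S2[i])
            done = 1.0 if event != 0 else 0.0
            for i in range(n_agents):
                ptr = rep_meta[i, 0]
                for k in range(dim):
                    rep_s[i, ptr, k] = S[i, k]
                    rep_s2[i, ptr, k] = S2[i, k]
                rep_a[i, ptr] = actions[i]
                rep_r[i, ptr] = rewards[i]
                rep_d[i, ptr] = done
                rep_p[i, ptr] = rep_max[i]
                rep_pa[i, ptr] = rep_max[i] ** alpha
                rep_meta[i, 0] = (ptr + 1) % cap
                if rep_meta[i, 1] < cap:
                    rep_meta[i, 1] += 1
                size = rep_meta[i, 1]
                if size >= batch:
                    _sample_indices(rep_pa[i], size, batch, idx, ws, beta)
                    for b in range(batch):
                        j = idx[b]
                        for k in range(dim):
                            xs[b, k] = rep_s[i, j, k]
                            x2s[b, k] = rep_s2[i, j, k]
                        acts[b] = rep_a[i, j]
                        rs_[b] = rep_r[i, j]
                        dones[b] = rep_d[i, j]
                    adam_t[i] += 1
                    loss = train_step(
                        (w1[i], b1[i], w2[i], b2[i], wa[i], ba[i], wa2[i], ba2[i],
                         wv[i], bv[i], wv2[i], bv2[i]),
                        (tw1[i], tb1[i], tw2[i], tb2[i], twa[i], tba[i], twa2[i], tba2[i],
                         twv[i], tbv[i], twv2[i], tbv2[i]),
                        (mstate[0][i], mstate[1][i], mstate[2][i], mstate[3][i],
                         mstate[4][i], mstate[5][i], mstate[6][i], mstate[7][i],
                         mstate[8][i], mstate[9][i], mstate[10][i], mstate[11][i]),
                        (vstate[0][i], vstate[1][i], vstate[2][i], vstate[3][i],
                         vstate[4][i], vstate[5][i], vstate[6][i], vstate[7][i],
                         vstate[8][i], vstate[9][i], vstate[10][i], vstate[11][i]),
                        adam_t[i], xs, acts, rs_, x2s, dones, ws, gamma32, lr32, td)
                    for b in range(batch):
                        p = abs(td[b]) + prio_floor
                        rep_p[i, idx[b]] = p
                        rep_pa[i, idx[b]] = p ** alpha
                        if p > rep_max[i]:
                            rep_max[i] = p
                    ep_loss[e, i] += loss
                    if i == 0:
                        n_updates += 1
                ep_return[e, i] += rewards[i]
            pos[:] = new_pos
            vel[:] = new_vel
            if event != 0:
                break
        ep_len[e] = t + 1
        ep_event[e] = event
        if n_updates > 0:
            for i in range(n_agents):
                ep_loss[e, i] /= n_updates


@njit(cache=True)
def greedy_rollout(online, init_pos, n_pred, mobility, prey_accel, damping, dt,
                   diameter, half, max_steps):
    """Debug/equivalence path: fully greedy episode from a given initial state.

    Returns (positions (T+1, n_agents, 2), actions (T, n_agents), event code).
    """
    w1, b1, w2, b2, wa, ba, wa2, ba2, wv, bv, wv2, bv2 = online
    n_agents = n_pred + 1
    dim = 4 + 4 * (n_agents - 1)
    pos = init_pos.copy()
    vel = np.zeros((n_agents, 2))
    traj = np.empty((max_steps + 1, n_agents, 2))
    acts = np.empty((max_steps, n_agents), dtype=np.int64)
    rewards = np.empty(n_agents)
    new_pos = np.empty((n_agents, 2))
    new_vel = np.empty((n_agents, 2))
    s = np.empty(dim, dtype=np.float32)
    traj[0] = pos
    event = 0
    t_end = 0
    for t in range(max_steps):
        for i in range(n_agents):
            featurize(pos, vel, i, n_pred, s)
            q = q_forward_one(w1[i], b1[i], w2[i], b2[i], wa[i], ba[i], wa2[i], ba2[i],
                              wv[i], bv[i], wv2[i], bv2[i], s)
            best = q[0]
            abest = 0
            for a in range(1, 13):
                if q[a] > best:
                    best = q[a]
                    abest = a
            acts[t, i] = abest + 1
        event, _ = env_step(pos, vel, acts[t], n_pred, mobility, prey_accel, damping,
                            dt, diameter, half, t + 1, max_steps, True,
                            new_pos, new_vel, rewards)
        pos[:] = new_pos
        vel[:] = new_vel
        traj[t + 1] = pos
        t_end = t + 1
        if event != 0:
            break
    return traj[: t_end + 1], acts[:t_end], event
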