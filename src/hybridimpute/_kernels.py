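"""Numba kernels for the Li-Stephens forward-backward recursions.

The transition structure (stay on the current template, or jump and land
uniformly) lets every forward/backward step collapse to scaled sums, so a
haploid pass costs O(M x |H|) and a diploid pass O(T x |H|^2) where T is
the number of informative markers; runs of uninformative markers are
absorbed into an effective stay probability (the product of the per
interval non-crossover probabilities), which is exact because a product
of matrices of the form s*I + j*11' stays in that family.

All sampling uses externally supplied uniforms so that determinism is
owned by the callers' seeded generators.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["haploid_pass", "diploid_obs_pass"]


@njit(cache=True, fastmath=True)
def haploid_pass(At, obs, theta, eps, u_path, u_jump):
    """One haploid forward-backward pass with posterior and path sampling.

    Parameters
    ----------
    At : (M, H) int8 template alleles, marker-major.
    obs : (M,) int8 observed alleles {0, 1, 9}.
    theta : (M-1,) crossover parameters.
    eps : (M,) error parameters.
    u_path, u_jump : uniforms for the stochastic traceback ((M,) and (M-1,)).

    Returns
    -------
    post1 : (M,) posterior probability that the underlying template allele
        is 1 at each marker.
    path : (M,) sampled template indices.
    jumps : (M-1,) sampled crossover indicators (a jump may land on the
        same template).
    loglik : log-likelihood of the observations.
    """
    M, H = At.shape
    F = np.empty((M, H))
    loglik = 0.0

    # forward, renormalised each marker
    tot = 0.0
    for h in range(H):
        o = obs[0]
        e = 1.0 if o == 9 else ((1.0 - eps[0]) if At[0, h] == o else eps[0])
        F[0, h] = e / H
        tot += F[0, h]
    loglik += np.log(tot)
    for h in range(H):
        F[0, h] /= tot
    for t in range(1, M):
        s = 1.0 - theta[t - 1]
        j = theta[t - 1] / H
        o = obs[t]
        tot = 0.0
        for h in range(H):
            pred = s * F[t - 1, h] + j  # row sums to 1 after normalisation
            e = 1.0 if o == 9 else ((1.0 - eps[t]) if At[t, h] == o else eps[t])
            F[t, h] = pred * e
            tot += F[t, h]
        loglik += np.log(tot)
        for h in range(H):
            F[t, h] /= tot

    # backward pass for exact per-marker allele posteriors
    post1 = np.empty(M)
    B = np.ones(H)
    acc = 0.0
    for h in range(H):
        if At[M - 1, h] == 1:
            acc += F[M - 1, h]
    post1[M - 1] = acc
    for t in range(M - 2, -1, -1):
        s = 1.0 - theta[t]
        j = theta[t] / H
        # fold emission at t+1 into B, then collapse the transition
        tot_eb = 0.0
        o = obs[t + 1]
        for h in range(H):
            e = 1.0 if o == 9 else ((1.0 - eps[t + 1]) if At[t + 1, h] == o else eps[t + 1])
            B[h] = e * B[h]
            tot_eb += B[h]
        norm = 0.0
        p1 = 0.0
        for h in range(H):
            B[h] = s * B[h] + j * tot_eb
            w = F[t, h] * B[h]
            norm += w
            if At[t, h] == 1:
                p1 += w
        post1[t] = p1 / norm
        for h in range(H):
            B[h] /= norm  # keep B scaled

    # stochastic traceback
    path = np.empty(M, dtype=np.int64)
    jumps = np.zeros(M - 1, dtype=np.int8)
    r = u_path[M - 1]
    cum = 0.0
    pick = H - 1
    for h in range(H):
        cum += F[M - 1, h]
        if r <= cum:
            pick = h
            break
    path[M - 1] = pick
    for t in range(M - 2, -1, -1):
        s = 1.0 - theta[t]
        j = theta[t] / H
        nxt = path[t + 1]
        norm = 0.0
        for h in range(H):
            w = F[t, h] * (j + (s if h == nxt else 0.0))
            norm += w
        r = u_path[t] * norm
        cum = 0.0
        pick = H - 1
        for h in range(H):
            cum += F[t, h] * (j + (s if h == nxt else 0.0))
            if r <= cum:
                pick = h
                break
        path[t] = pick
        if pick != nxt:
            jumps[t] = 1
        else:
            # a jump can land on the same template
            p_jump = j / (s + j)
            if u_jump[t] <= p_jump:
                jumps[t] = 1
    return post1, path, jumps, loglik


@njit(cache=True, fastmath=True)
def diploid_obs_pass(A_obs, W, s_gap, u_path):
    """Diploid forward pass over informative markers plus pair sampling.

    Parameters
    ----------
    A_obs : (T, H) int8 template alleles at the informative markers.
    W : (T, 2, 2) emission weights indexed by the two template alleles.
    s_gap : (T-1,) effective per-gamete stay probabilities between
        consecutive informative markers (products of 1 - theta_i).
    u_path : (T, 3) uniforms for the traceback (component choice and the
        two gamete draws).

    Returns
    -------
    states : (T, 2) sampled template index pairs.
    loglik : log-likelihood of the informative observations.
    """
    T, H = A_obs.shape
    F = np.empty((T, H, H))
    loglik = 0.0
    tot = 0.0
    for h in range(H):
        ah = A_obs[0, h]
        for k in range(H):
            v = W[0, ah, A_obs[0, k]] / (H * H)
            F[0, h, k] = v
            tot += v
    loglik += np.log(tot)
    inv = 1.0 / tot
    for h in range(H):
        for k in range(H):
            F[0, h, k] *= inv

    rs = np.empty(H)
    cs = np.empty(H)
    for t in range(1, T):
        s = s_gap[t - 1]
        j = (1.0 - s) / H
        for h in range(H):
            r = 0.0
            for k in range(H):
                r += F[t - 1, h, k]
            rs[h] = r
        for k in range(H):
            c = 0.0
            for h in range(H):
                c += F[t - 1, h, k]
            cs[k] = c
        tot = 0.0
        for h in range(H):
            ah = A_obs[t, h]
            for k in range(H):
                pred = (
                    s * s * F[t - 1, h, k]
                    + s * j * (rs[h] + cs[k])
                    + j * j
                )
                v = pred * W[t, ah, A_obs[t, k]]
                F[t, h, k] = v
                tot += v
        loglik += np.log(tot)
        inv = 1.0 / tot
        for h in range(H):
            for k in range(H):
                F[t, h, k] *= inv

    # stochastic traceback using the 4-component decomposition of the
    # factorised transition: (stay, stay), (stay, jump), (jump, stay),
    # (jump, jump)
    states = np.empty((T, 2), dtype=np.int64)
    r = u_path[T - 1, 0]
    cum = 0.0
    ph = H - 1
    pk = H - 1
    done = False
    for h in range(H):
        if done:
            break
        for k in range(H):
            cum += F[T - 1, h, k]
            if r <= cum:
                ph = h
                pk = k
                done = True
                break
    states[T - 1, 0] = ph
    states[T - 1, 1] = pk
    for t in range(T - 2, -1, -1):
        s = s_gap[t]
        j = (1.0 - s) / H
        nh = states[t + 1, 0]
        nk = states[t + 1, 1]
        for h in range(H):
            r_ = 0.0
            for k in range(H):
                r_ += F[t, h, k]
            rs[h] = r_
        for k in range(H):
            c = 0.0
            for h in range(H):
                c += F[t, h, k]
            cs[k] = c
        tot_ = 0.0
        for h in range(H):
            for k in range(H):
                tot_ += F[t, h, k]
        m1 = s * s * F[t, nh, nk]
        m2 = s * j * rs[nh]  # first gamete stays on nh, second jumps
        m3 = s * j * cs[nk]  # second stays on nk, first jumps
        m4 = j * j * tot_
        z = m1 + m2 + m3 + m4
        rc = u_path[t, 0] * z
        if rc <= m1:
            states[t, 0] = nh
            states[t, 1] = nk
        elif rc <= m1 + m2:
            states[t, 0] = nh
            r2 = u_path[t, 1] * rs[nh]
            cum = 0.0
            pick = H - 1
            for k in range(H):
                cum += F[t, nh, k]
                if r2 <= cum:
                    pick = k
                    break
            states[t, 1] = pick
        elif rc <= m1 + m2 + m3:
            states[t, 1] = nk
            r2 = u_path[t, 1] * cs[nk]
            cum = 0.0
            pick = H - 1
            for h in range(H):
                cum += F[t, h, nk]
                if r2 <= cum:
                    pick = h
                    break
            states[t, 0] = pick
        else:
            r2 = u_path[t, 1] * tot_
            cum = 0.0
            ph = H - 1
            pk = H - 1
            done = False
            for h in range(H):
                if done:
                    break
                for k in range(H):
                    cum += F[t, h, k]
                    if r2 <= cum:
                        ph = h
                        pk = k
                        done = True
                        break
            states[t, 0] = ph
            states[t, 1] = pk
    return states, loglik
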