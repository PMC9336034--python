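"""Numba-compiled fused NLL + gradient kernel for the univariate network.

Single pass over observations; identical mathematics to the numpy path in
``network._nll_and_gradient_numpy`` (log-sum-exp likelihood, closed-form
pre-activation gradients, tanh backpropagation), fused to avoid the
per-call temporary-array overhead that dominates full-batch training.
"""

import numpy as np
from numba import njit

_SIGMA_FLOOR = 1e-8
_LOG_2PI = float(np.log(2.0 * np.pi))


@njit(cache=True, fastmath=True)
def fused_nll_grad(
    x, y, hidden_w, hidden_b, alpha_w, alpha_b, mu_w, mu_b, sigma_w, sigma_b,
    alpha_connected, softplus,
):
    n = x.shape[0]
    H = hidden_b.shape[0]
    M = alpha_b.shape[0]

    g_hw = np.zeros(H)
    g_hb = np.zeros(H)
    g_aw = np.zeros((H, M))
    g_ab = np.zeros(M)
    g_mw = np.zeros((H, M))
    g_mb = np.zeros(M)
    g_sw = np.zeros((H, M))
    g_sb = np.zeros(M)

    h = np.empty(H)
    a_alpha = np.empty(M)
    a_mu = np.empty(M)
    a_sigma = np.empty(M)
    sd = np.empty(M)
    log_joint = np.empty(M)
    pi = np.empty(M)
    alpha = np.empty(M)

    nll = 0.0
    for i in range(n):
        xi = x[i]
        yi = y[i]
        for k in range(H):
            h[k] = np.tanh(hidden_w[k] * xi + hidden_b[k])
        for m in range(M):
            aa = alpha_b[m]
            am = mu_b[m]
            asg = sigma_b[m]
            for k in range(H):
                am += h[k] * mu_w[k, m]
                asg += h[k] * sigma_w[k, m]
            if alpha_connected:
                for k in range(H):
                    aa += h[k] * alpha_w[k, m]
            a_alpha[m] = aa
            a_mu[m] = am
            a_sigma[m] = asg

        # log-softmax of the weight pre-activations
        amax = a_alpha[0]
        for m in range(1, M):
            if a_alpha[m] > amax:
                amax = a_alpha[m]
        ssum = 0.0
        for m in range(M):
            ssum += np.exp(a_alpha[m] - amax)
        log_norm = np.log(ssum) + amax
        for m in range(M):
            alpha[m] = np.exp(a_alpha[m] - log_norm)

        for m in range(M):
            if softplus:
                a = a_sigma[m]
                sig = a + np.log1p(np.exp(-a)) if a > 0.0 else np.log1p(np.exp(a))
            else:
                sig = np.exp(a_sigma[m])
            if sig < _SIGMA_FLOOR:
                sig = _SIGMA_FLOOR
            sd[m] = sig
            z = (yi - a_mu[m]) / sig
            log_joint[m] = (
                a_alpha[m] - log_norm - 0.5 * _LOG_2PI - np.log(sig) - 0.5 * z * z
            )

        jmax = log_joint[0]
        for m in range(1, M):
            if log_joint[m] > jmax:
                jmax = log_joint[m]
        jsum = 0.0
        for m in range(M):
            jsum += np.exp(log_joint[m] - jmax)
        log_mix = np.log(jsum) + jmax
        nll -= log_mix
        for m in range(M):
            pi[m] = np.exp(log_joint[m] - log_mix)

        # pre-activation gradients, accumulated into the weight blocks
        for m in range(M):
            d_alpha = alpha[m] - pi[m]
            zm = (yi - a_mu[m]) / sd[m]
            d_mu = pi[m] * (a_mu[m] - yi) / (sd[m] * sd[m])
            if softplus:
                sprime = 1.0 / (1.0 + np.exp(-a_sigma[m]))
                d_sigma = pi[m] * (1.0 / sd[m] - zm * zm / sd[m]) * sprime
            else:
                d_sigma = pi[m] * (1.0 - zm * zm)

            g_ab[m] += d_alpha
            g_mb[m] += d_mu
            g_sb[m] += d_sigma
            for k in range(H):
                back = d_mu * mu_w[k, m] + d_sigma * sigma_w[k, m]
                if alpha_connected:
                    g_aw[k, m] += h[k] * d_alpha
                    back += d_alpha * alpha_w[k, m]
                g_mw[k, m] += h[k] * d_mu
                g_sw[k, m] += h[k] * d_sigma
                d_h = back * (1.0 - h[k] * h[k])
                g_hw[k] += d_h * xi
                g_hb[k] += d_h

    total = H + H + M + H * M + M + H * M + M
    if alpha_connected:
        total += H * M
    grads = np.empty(total)
    pos = 0
    for k in range(H):
        grads[pos] = g_hw[k]
        pos += 1
    for k in range(H):
        grads[pos] = g_hb[k]
        pos += 1
    if alpha_connected:
        for k in range(H):
            for m in range(M):
                grads[pos] = g_aw[k, m]
                pos += 1
    for m in range(M):
        grads[pos] = g_ab[m]
        pos += 1
    for k in range(H):
        for m in range(M):
            grads[pos] = g_mw[k, m]
            pos += 1
    for m in range(M):
        grads[pos] = g_mb[m]
        pos += 1
    for k in range(H):
        for m in range(M):
            grads[pos] = g_sw[k, m]
            pos += 1
    for m in range(M):
        grads[pos] = g_sb[m]
        pos += 1
    return nll, grads
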