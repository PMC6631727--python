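"""Independent closed-form oracles used by the tests.

Everything here is deliberately written against textbook formulas
(Kalman recursions, joint-Gaussian marginals) and scipy distributions,
not against the package's own code paths.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def kalman_filter(ssm, y: np.ndarray):
    """Exact Kalman filter for a diagonal linear-Gaussian SSM instance.

    Returns (filtered means (T+1, d), filtered covariances list,
    log-likelihood of y).
    """
    d = ssm.d
    A = np.diag(ssm.coeffs)
    Q = np.diag(ssm.process_var)
    C = ssm.emission
    R = np.diag(ssm.obs_var)
    m, P = ssm.init_mean.copy(), np.diag(ssm.init_var)
    means, covs, loglik = [], [], 0.0
    for t in range(len(y)):
        if t > 0:
            m = A @ m
            P = A @ P @ A.T + Q
        S = C @ P @ C.T + R
        innov = y[t] - C @ m
        loglik += multivariate_normal.logpdf(innov, mean=np.zeros(len(innov)),
                                             cov=S)
        K = P @ C.T @ np.linalg.inv(S)
        m = m + K @ innov
        P = (np.eye(d) - K @ C) @ P
        means.append(m.copy())
        covs.append(P.copy())
    return np.array(means), covs, float(loglik)


def joint_gaussian_loglik(ssm, y: np.ndarray) -> float:
    """log p(y_0:T) via the stacked joint-Gaussian marginal (no recursion)."""
    T1, d = len(y), ssm.d
    A = np.diag(ssm.coeffs)
    state_covs = [np.diag(ssm.init_var)]
    for _ in range(1, T1):
        state_covs.append(A @ state_covs[-1] @ A.T + np.diag(ssm.process_var))
    Pz = np.zeros((T1 * d, T1 * d))
    for t in range(T1):
        for s in range(T1):
            if t <= s:
                block = state_covs[t] @ np.linalg.matrix_power(A, s - t).T
            else:
                block = np.linalg.matrix_power(A, t - s) @ state_covs[s]
            Pz[t * d:(t + 1) * d, s * d:(s + 1) * d] = block
    Cbig = np.kron(np.eye(T1), ssm.emission)
    Py = Cbig @ Pz @ Cbig.T + np.kron(np.eye(T1), np.diag(ssm.obs_var))
    return float(multivariate_normal.logpdf(
        y.ravel(), mean=np.zeros(y.size), cov=Py))


def diag_gaussian_kl_quadrature(mu_q, var_q, mu_p, var_p,
                                half_width: float = 12.0, n: int = 20001) -> float:
    """KL(q || p) for diagonal Gaussians by per-coordinate quadrature.

    The KL factorizes over coordinates for diagonal covariances, so each
    1-D integral of q log(q/p) is evaluated on a dense grid.
    """
    total = 0.0
    for mq, vq, mp_, vp in zip(np.atleast_1d(mu_q), np.atleast_1d(var_q),
                               np.atleast_1d(mu_p), np.atleast_1d(var_p)):
        sd = np.sqrt(vq)
        xs = np.linspace(mq - half_width * sd, mq + half_width * sd, n)
        logq = -0.5 * (np.log(2 * np.pi * vq) + (xs - mq) ** 2 / vq)
        logp = -0.5 * (np.log(2 * np.pi * vp) + (xs - mp_) ** 2 / vp)
        total += np.trapezoid(np.exp(logq) * (logq - logp), xs)
    return float(total)
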