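"""Exact Polya-Gamma PG(1, c) sampling.

The Gibbs sampler for the Bernoulli-logit likelihood augments each
observation with a Polya-Gamma latent variable, which makes every
Gaussian block of the model conditionally conjugate.  Draws are exact
(Devroye-style alternating-series rejection on the Jacobi J*(1, z)
density), not a truncated series approximation, so the augmented chain
targets the exact posterior.

Compiled with numba; the JIT state is seeded explicitly per call so draw
streams are reproducible.
"""

import math

import numpy as np
from numba import njit

# truncation point of the two-piece proposal (standard choice)
_TRUNC = 0.64


@njit(cache=True)
def _a_coef(n, x):
    # n-th alternating-series coefficient of the J*(1, 0) density,
    # piecewise form: left piece for x <= t, right piece for x > t
    if x > _TRUNC:
        return math.pi * (n + 0.5) * math.exp(
            -((n + 0.5) ** 2) * math.pi ** 2 * x / 2.0
        )
    return (
        math.pi
        * (n + 0.5)
        * (2.0 / (math.pi * x)) ** 1.5
        * math.exp(-2.0 * (n + 0.5) ** 2 / x)
    )


@njit(cache=True)
def _log_norm_cdf(x):
    return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))


@njit(cache=True)
def _rtigauss(z, t):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t]."""
    x = t + 1.0
    if z < 1.0 / t:
        # large-mean regime (incl. z == 0): rejection from the
        # scaled inverse-chi-square tail
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = t / ((1.0 + t * e1) ** 2)
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.standard_normal() ** 2
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _draw_pg1(c):
    """One draw of PG(1, c) via J*(1, |c|/2) / 4."""
    z = abs(c) * 0.5
    t = _TRUNC
    fz = math.pi ** 2 / 8.0 + z * z / 2.0

    # p / (p + q): probability mass of the exponential (right) piece
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_norm_cdf(b)
    xa = x0 + z + _log_norm_cdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    p_right = 1.0 / (1.0 + qdivp)

    while True:
        if np.random.random() < p_right:
            x = t + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z, t)
        # alternating-series accept/reject
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return 0.25 * x


@njit(cache=True)
def _pg_vector(c, seed):
    np.random.seed(seed)
    out = np.empty(c.size)
    for i in range(c.size):
        out[i] = _draw_pg1(c[i])
    return out


def sample_pg(c, seed):
    """Draw omega_i ~ PG(1, c_i) for a vector of tilting parameters.

    Parameters
    ----------
    c : array-like
        Tilting parameters (the linear predictor values); any sign.
    seed : int
        Seed for this batch of draws (0 <= seed < 2**32).

    Returns
    -------
    ndarray of positive draws, same shape as ``c``.
    """
    c = np.ascontiguousarray(np.asarray(c, dtype=np.float64).ravel())
    return _pg_vector(c, np.uint32(seed))


def pg_mean(c):
    """E[PG(1, c)] = tanh(c/2) / (2 c), with the c -> 0 limit 1/4."""
    c = np.asarray(c, dtype=np.float64)
    out = np.full(c.shape, 0.25)
    nz = np.abs(c) > 1e-12
    out[nz] = np.tanh(c[nz] / 2.0) / (2.0 * c[nz])
    return out


def pg_var(c):
    """Var[PG(1, c)] from the infinite-series representation."""
    c = np.atleast_1d(np.asarray(c, dtype=np.float64))
    k = np.arange(1, 20001)[:, None]
    d = (k - 0.5) ** 2 + (c[None, :] / (2.0 * math.pi)) ** 2
    return (d ** -2).sum(axis=0) / (4.0 * math.pi ** 4)
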