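"""Conjugate-update building blocks for the Gibbs samplers.

Every model in this package is linear-Gaussian conditional on its variance
parameters, so posterior simulation reduces to three primitives:

* multivariate-normal draws for regression coefficients,
* inverse-gamma draws for scalar variances with a half-Student-t prior on the
  standard deviation, expressed through the usual inverse-gamma scale mixture,
* inverse-Wishart draws for 2x2 intercept-slope covariance blocks with the
  Huang-Wand (2013) auxiliary parameterisation, which gives marginal half-t
  priors on the standard deviations and (for nu = 2) a marginally uniform
  prior on the correlation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "sample_mvn_regression",
    "HalfTVariance",
    "HuangWandCov2",
    "sample_bivariate_groups",
    "collapsed_bivariate_loglik",
    "collapsed_scalar_loglik",
]


def sample_mvn_regression(
    xtx: np.ndarray,
    xty: np.ndarray,
    noise_var: float,
    prior_prec: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw beta ~ N(m, V) with V^-1 = X'X / s2 + P0 and m = V X'y / s2.

    ``xtx`` and ``xty`` are the accumulated cross-products of the design
    against the (partial) response; ``prior_prec`` is the prior precision
    matrix (typically diagonal and small).
    """
    prec = xtx / noise_var + prior_prec
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, xty / noise_var)
    z = rng.standard_normal(len(mean))
    return mean + np.linalg.solve(chol.T, z)


class HalfTVariance:
    """Scalar variance with a half-t(df, scale) prior on the SD.

    Uses sigma2 | a ~ InvGamma(df/2, df/a), a ~ InvGamma(1/2, 1/scale^2),
    whose marginal on sigma is half-t. Both conditionals are inverse-gamma,
    so the pair is updated by exact Gibbs steps.
    """

    def __init__(self, df: float = 3.0, scale: float = 5.0, init: float = 1.0):
        if df <= 0 or scale <= 0:
            raise ValueError("half-t df and scale must be positive")
        self.df = float(df)
        self.scale = float(scale)
        self.value = float(init)
        self._a = scale**2

    def update(self, sum_sq: float, n: int, rng: np.random.Generator) -> float:
        """One Gibbs sweep given a residual sum of squares over n terms."""
        shape = 0.5 * (self.df + n)
        rate = self.df / self._a + 0.5 * sum_sq
        self.value = rate / rng.gamma(shape)
        # auxiliary
        a_shape = 0.5 * (self.df + 1.0)
        a_rate = self.df / self.value + 1.0 / self.scale**2
        self._a = a_rate / rng.gamma(a_shape)
        return self.value

    def log_prior(self, v: float) -> float:
        """Conditional log prior p(v | a), up to a constant."""
        return -(0.5 * self.df + 1.0) * np.log(v) - self.df / (self._a * v)

    def update_aux(self, rng: np.random.Generator) -> None:
        """Refresh the scale-mixture auxiliary given the current variance."""
        a_shape = 0.5 * (self.df + 1.0)
        a_rate = self.df / self.value + 1.0 / self.scale**2
        self._a = a_rate / rng.gamma(a_shape)

    def mh_update(
        self,
        loglik,
        rng: np.random.Generator,
        steps: int = 3,
        step_scale: float = 1.0,
    ) -> None:
        """Random-walk Metropolis on log(v) against a collapsed likelihood.

        ``loglik(v)`` must be the marginal log likelihood with the group
        deviations integrated out; this step crosses the near-zero funnel
        that the conjugate conditional update cannot.
        """
        t = np.log(self.value)
        lp = loglik(self.value) + self.log_prior(self.value) + t  # + log Jacobian
        for _ in range(steps):
            t_new = t + step_scale * rng.standard_normal()
            v_new = float(np.exp(t_new))
            lp_new = loglik(v_new) + self.log_prior(v_new) + t_new
            if np.log(rng.random()) < lp_new - lp:
                t, lp, self.value = t_new, lp_new, v_new


class HuangWandCov2:
    """2x2 covariance with Huang-Wand hierarchical inverse-Wishart prior.

    Sigma | a ~ IW(nu + 1, 2 nu diag(1/a_k)); a_k ~ InvGamma(1/2, 1/A_k^2).
    Marginally sd_k ~ half-t(nu, A_k); with nu = 2 the correlation is
    uniform on (-1, 1).
    """

    def __init__(self, nu: float = 2.0, scales=(5.0, 5.0), init: np.ndarray | None = None):
        self.nu = float(nu)
        self.scales = np.asarray(scales, dtype=float)
        self.value = np.eye(2) if init is None else np.array(init, dtype=float)
        self._a = self.scales**2

    def update(self, scatter: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        """Gibbs sweep given sum of outer products of n group deviations."""
        df = self.nu + 1.0 + n
        scale_mat = 2.0 * self.nu * np.diag(1.0 / self._a) + scatter
        self.value = stats.invwishart.rvs(df=df, scale=scale_mat, random_state=rng)
        self.value = np.atleast_2d(self.value)
        prec_diag = np.diag(np.linalg.inv(self.value))
        a_shape = 0.5 * (self.nu + 2.0)
        a_rate = self.nu * prec_diag + 1.0 / self.scales**2
        self._a = a_rate / rng.gamma(a_shape, size=2)
        return self.value

    def update_aux(self, rng: np.random.Generator) -> None:
        """Refresh the Huang-Wand auxiliaries given the current covariance."""
        prec_diag = np.diag(np.linalg.inv(self.value))
        a_shape = 0.5 * (self.nu + 2.0)
        a_rate = self.nu * prec_diag + 1.0 / self.scales**2
        self._a = a_rate / rng.gamma(a_shape, size=2)

    def log_prior(self, sigma: np.ndarray) -> float:
        """Conditional log prior p(Sigma | a): IW(nu + 1, 2 nu diag(1/a))."""
        det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
        inv00 = sigma[1, 1] / det
        inv11 = sigma[0, 0] / det
        trace = 2.0 * self.nu * (inv00 / self._a[0] + inv11 / self._a[1])
        df = self.nu + 1.0
        return -0.5 * (df + 3.0) * np.log(det) - 0.5 * trace

    def mh_update(
        self,
        loglik,
        rng: np.random.Generator,
        steps: int = 5,
        step_scale=(1.2, 1.2, 0.5),
    ) -> None:
        """Random-walk Metropolis on (log v0, log v1, atanh rho).

        ``loglik(Sigma)`` is the marginal log likelihood with the group
        deviations integrated out.  The conjugate inverse-Wishart update
        conditions on the current deviations and therefore barely moves when
        a variance sits near zero (the usual funnel); this collapsed step
        restores mixing across scales.
        """
        v0, v1 = self.value[0, 0], self.value[1, 1]
        rho = np.clip(self.value[0, 1] / np.sqrt(v0 * v1), -0.999, 0.999)
        theta = np.array([np.log(v0), np.log(v1), np.arctanh(rho)])
        step = np.asarray(step_scale)

        def log_post(th):
            w0, w1 = np.exp(th[0]), np.exp(th[1])
            r = np.tanh(th[2])
            sig = np.array(
                [[w0, r * np.sqrt(w0 * w1)], [r * np.sqrt(w0 * w1), w1]]
            )
            # Jacobian of (v0, cov, v1) <- (log v0, atanh rho, log v1)
            jac = 1.5 * (th[0] + th[1]) + np.log1p(-r * r)
            return loglik(sig) + self.log_prior(sig) + jac, sig

        lp, _ = log_post(theta)
        for _ in range(steps):
            prop = theta + step * rng.standard_normal(3)
            lp_new, sig_new = log_post(prop)
            if np.log(rng.random()) < lp_new - lp:
                theta, lp, self.value = prop, lp_new, sig_new


def collapsed_bivariate_loglik(
    sigma: np.ndarray,
    s_n: np.ndarray,
    s_x: np.ndarray,
    s_xx: np.ndarray,
    s_r: np.ndarray,
    s_xr: np.ndarray,
    noise_var: float,
) -> float:
    """Marginal log likelihood of Sigma with all group deviations integrated out.

    For each group g with design X_g = [1, x] and partial residuals r_g,
    r_g ~ N(0, Ve I + X_g Sigma X_g'); by the Woodbury/determinant lemmas

        log|Ve I + X Sigma X'| = n log Ve + log|Sigma| + log|M|,
        M = Sigma^-1 + X'X / Ve,

    and the quadratic form reduces to r'r/Ve - b' M^-1 b with b = X'r/Ve.
    Terms constant in Sigma are dropped.  Inputs are per-group sufficient
    statistics; everything is evaluated with closed-form 2x2 algebra.
    """
    det_s = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
    if det_s <= 0:
        return -np.inf
    si00 = sigma[1, 1] / det_s
    si01 = -sigma[0, 1] / det_s
    si11 = sigma[0, 0] / det_s
    m00 = si00 + s_n / noise_var
    m01 = si01 + s_x / noise_var
    m11 = si11 + s_xx / noise_var
    det_m = m00 * m11 - m01 * m01
    b0 = s_r / noise_var
    b1 = s_xr / noise_var
    quad = (m11 * b0 * b0 - 2.0 * m01 * b0 * b1 + m00 * b1 * b1) / det_m
    G = len(s_n)
    return -0.5 * (G * np.log(det_s) + np.log(det_m).sum() - quad.sum())


def collapsed_scalar_loglik(
    v: float,
    s_n: np.ndarray,
    s_r: np.ndarray,
    noise_var,
) -> float:
    """Scalar-intercept version of :func:`collapsed_bivariate_loglik`.

    Groups have r_g ~ N(0, Ve I + v J); ``noise_var`` may be scalar or
    per-group.  Constant terms are dropped.
    """
    if v <= 0:
        return -np.inf
    m = 1.0 / v + s_n / noise_var
    b = s_r / noise_var
    return -0.5 * (len(s_n) * np.log(v) + np.log(m).sum() - (b * b / m).sum())


def sample_bivariate_groups(
    prior_prec: np.ndarray,
    s_n: np.ndarray,
    s_x: np.ndarray,
    s_xx: np.ndarray,
    s_r: np.ndarray,
    s_xr: np.ndarray,
    noise_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised draw of (intercept, slope) pairs for G exchangeable groups.

    Each group g has model r_i = u0 + u1 * x_i + e_i with e ~ N(0, noise_var)
    and prior (u0, u1) ~ N(0, Sigma), prior_prec = Sigma^-1.  Inputs are the
    per-group sufficient statistics (counts, sums of x, x^2, r, x*r).
    Returns an array (G, 2).
    """
    p00 = prior_prec[0, 0] + s_n / noise_var
    p01 = prior_prec[0, 1] + s_x / noise_var
    p11 = prior_prec[1, 1] + s_xx / noise_var
    b0 = s_r / noise_var
    b1 = s_xr / noise_var
    det = p00 * p11 - p01 * p01
    # covariance = inverse of the 2x2 precision, in closed form
    c00 = p11 / det
    c01 = -p01 / det
    c11 = p00 / det
    m0 = c00 * b0 + c01 * b1
    m1 = c01 * b0 + c11 * b1
    # lower Cholesky of the covariance
    l00 = np.sqrt(c00)
    l10 = c01 / l00
    l11 = np.sqrt(np.maximum(c11 - l10 * l10, 1e-300))
    z = rng.standard_normal((2, len(s_n)))
    u0 = m0 + l00 * z[0]
    u1 = m1 + l10 * z[0] + l11 * z[1]
    return np.column_stack([u0, u1])
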