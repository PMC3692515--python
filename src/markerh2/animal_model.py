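"""Single-random-effect animal model fitted by restricted maximum likelihood.

Model: y = mu * 1 + a + e with a ~ N(0, sigma2_A * G) and e ~ N(0,
sigma2_E * I), where G is a positive semi-definite genetic covariance
structure (2 Phi / (1+F) from a pedigree, or 2 K / (1+F) from markers).

The restricted likelihood is evaluated on the contrast space orthogonal to
the intercept. Writing V = sigma2_A G + sigma2_E I and X = 1:

    2 l_R = -(n-1) log(2 pi) - log|V| - log|X' V^-1 X| + log|X' X| - y' P y

with P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1. A one-time symmetric
eigendecomposition G = U D U' turns every evaluation into O(n) work: in the
rotated basis V has eigenvalues sigma2_A d_i + sigma2_E, and the total
variance profiles out in closed form. The fit is a bracketed 1-D search on
the variance ratio lambda = sigma2_A / sigma2_E (heritability
h2 = lambda / (1 + lambda) since G has unit-scale diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["VarianceFit", "RemlProblem", "restricted_loglik", "fit_reml", "heritability"]

_LOG_LAMBDA_RANGE = (-12.0, 12.0)
_N_GRID = 64
_LOGLIK_TOL = 1e-8


class RemlError(RuntimeError):
    pass


@dataclass
class VarianceFit:
    """REML variance components and derived heritability."""

    sigma2_A: float
    sigma2_E: float
    h2: float
    se_h2: float
    loglik_restricted: float
    converged: bool
    boundary: bool  # estimate pinned at sigma2_A = 0 (or the lambda ceiling)
    identifiable: bool = True
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_A < 0 or self.sigma2_E < 0:
            raise ValueError("variance components must be non-negative")
        total = self.sigma2_A + self.sigma2_E
        if total > 0 and abs(self.h2 - self.sigma2_A / total) > 1e-10:
            raise ValueError("h2 inconsistent with variance components")


class RemlProblem:
    """Precomputed eigen-rotation of one (y, G) REML problem.

    Rotating by the eigenvectors of G diagonalizes V for every value of the
    variance components, so each restricted-likelihood evaluation costs
    O(n). The intercept column is rotated along with the data and handled
    by one-dimensional generalized least squares inside each evaluation.
    """

    def __init__(self, y: np.ndarray, G: np.ndarray):
        y = np.asarray(y, dtype=float)
        G = np.asarray(G, dtype=float)
        n = y.shape[0]
        if n < 2:
            raise ValueError("need at least two observations")
        if G.shape != (n, n):
            raise ValueError("G must be n x n")
        if not np.allclose(G, G.T, atol=1e-8):
            raise ValueError("G must be symmetric")
        d, U = np.linalg.eigh(G)
        if d[0] < -1e-8 * max(1.0, d[-1]):
            raise RemlError(f"G is not positive semi-definite (min eigenvalue {d[0]:.3g})")
        self.n = n
        self.d = np.maximum(d, 0.0)
        self.y_rot = U.T @ y
        self.x_rot = U.T @ np.ones(n)
        self.logdet_xx = np.log(float(n))  # log|X'X| for X = 1
        self.n_evaluations = 0

    def _gls_pieces(self, v: np.ndarray):
        """Weighted sums for the intercept GLS fit under Var eigenvalues v."""
        w = 1.0 / v
        xtwx = float(np.sum(w * self.x_rot**2))
        xtwy = float(np.sum(w * self.x_rot * self.y_rot))
        mu = xtwy / xtwx
        rss = float(np.sum(w * (self.y_rot - mu * self.x_rot) ** 2))
        return xtwx, rss

    def loglik(self, sigma2_A: float, sigma2_E: float) -> float:
        """Restricted log-likelihood at the given variance components."""
        v = sigma2_A * self.d + sigma2_E
        if np.any(v <= 0):
            raise RemlError("covariance matrix V is singular at these components")
        self.n_evaluations += 1
        xtwx, rss = self._gls_pieces(v)
        return -0.5 * (
            (self.n - 1) * np.log(2.0 * np.pi)
            + float(np.log(v).sum())
            + np.log(xtwx)
            - self.logdet_xx
            + rss
        )

    def profile_loglik(self, lam: float):
        """Restricted log-likelihood maximized over total variance at fixed
        lambda = sigma2_A / sigma2_E. Returns (loglik, sigma2_E_hat)."""
        v = lam * self.d + 1.0
        if np.any(v <= 0):
            return -np.inf, np.nan
        self.n_evaluations += 1
        xtwx, rss = self._gls_pieces(v)
        s2e = rss / (self.n - 1)
        if s2e <= 0:
            return -np.inf, np.nan
        ll = -0.5 * (
            (self.n - 1) * (np.log(2.0 * np.pi * s2e) + 1.0)
            + float(np.log(v).sum())
            + np.log(xtwx)
            - self.logdet_xx
        )
        return ll, s2e


def restricted_loglik(y, G, sigma2_A: float, sigma2_E: float) -> float:
    """REML log-likelihood of y under N(mu 1, sigma2_A G + sigma2_E I)."""
    return RemlProblem(y, G).loglik(sigma2_A, sigma2_E)


def _profile_curvature(problem: RemlProblem, h2: float, step: float = 1e-4) -> float:
    """Numerical second derivative of the profile restricted log-likelihood
    on the heritability scale (observed information with sign flipped)."""
    lo, hi = 1e-9, 1.0 - 1e-9
    h = min(step, (h2 - lo) / 2, (hi - h2) / 2)
    if h <= 0:
        return np.nan

    def ll_at(h2v):
        lam = h2v / (1.0 - h2v)
        return problem.profile_loglik(lam)[0]

    f0 = ll_at(h2)
    fp = ll_at(h2 + h)
    fm = ll_at(h2 - h)
    return (fp - 2.0 * f0 + fm) / h**2


def fit_reml(y, G) -> VarianceFit:
    """Maximize the restricted likelihood over (sigma2_A, sigma2_E) >= 0.

    Strategy: coarse grid on log(lambda) over [-12, 12] plus the lambda = 0
    boundary, then bracketed scalar refinement (Brent) around the grid
    optimum, with the total variance profiled out in closed form at every
    step. Boundary solutions are flagged rather than discarded; the standard
    error of h2 comes from the numerical observed information of the profile
    likelihood on the h2 scale.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 observations for a variance-component fit")
    if np.allclose(y, y[0]):
        raise ValueError("phenotype vector is constant")
    problem = RemlProblem(y, G)

    lo, hi = _LOG_LAMBDA_RANGE
    grid = np.linspace(lo, hi, _N_GRID)
    lls = np.array([problem.profile_loglik(np.exp(t))[0] for t in grid])
    ll0, _ = problem.profile_loglik(0.0)

    # likelihood flat in lambda <=> sigma2_A not identifiable (e.g. G = I)
    spread = float(np.nanmax(np.append(lls, ll0)) - np.nanmin(np.append(lls, ll0)))
    identifiable = spread > 1e-6 * max(1.0, abs(ll0))

    best = int(np.nanargmax(lls))
    left = grid[max(best - 1, 0)]
    right = grid[min(best + 1, _N_GRID - 1)]
    if best in (0, _N_GRID - 1):
        t_hat, ll_hat = grid[best], lls[best]
    else:
        res = optimize.minimize_scalar(
            lambda t: -problem.profile_loglik(np.exp(t))[0],
            bounds=(left, right),
            method="bounded",
            options={"xatol": 1e-10},
        )
        t_hat, ll_hat = float(res.x), -float(res.fun)
        if ll_hat < lls[best]:  # guard: never worse than the grid
            t_hat, ll_hat = grid[best], lls[best]

    boundary = False
    if ll0 >= ll_hat - _LOGLIK_TOL and ll0 >= ll_hat:
        lam_hat, ll_hat = 0.0, ll0
        boundary = True
    else:
        lam_hat = float(np.exp(t_hat))
        if t_hat <= lo + 1e-9:
            # indistinguishable from the sigma2_A = 0 boundary
            if ll0 >= ll_hat - _LOGLIK_TOL:
                lam_hat, ll_hat, boundary = 0.0, max(ll0, ll_hat), True
        elif t_hat >= hi - 1e-9:
            boundary = True

    _, s2e = problem.profile_loglik(lam_hat)
    s2a = lam_hat * s2e
    h2 = lam_hat / (1.0 + lam_hat)

    se_h2 = np.nan
    if identifiable and not boundary:
        curv = _profile_curvature(problem, h2)
        if np.isfinite(curv) and curv < 0:
            se_h2 = float(np.sqrt(-1.0 / curv))

    return VarianceFit(
        sigma2_A=float(s2a),
        sigma2_E=float(s2e),
        h2=float(h2),
        se_h2=se_h2,
        loglik_restricted=float(ll_hat),
        converged=True,
        boundary=boundary,
        identifiable=identifiable,
        n_evaluations=problem.n_evaluations,
    )


def heritability(fit: VarianceFit) -> float:
    """h2 = sigma2_A / (sigma2_A + sigma2_E); 0 at the sigma2_A = 0 boundary."""
    if not fit.converged:
        raise RemlError("fit did not converge")
    total = fit.sigma2_A + fit.sigma2_E
    if total <= 0:
        raise RemlError("both variance components are zero; heritability undefined")
    return fit.sigma2_A / total
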