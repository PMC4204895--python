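"""Single-output partial least-squares regression with sign-constrained
coefficients and log-penalized component selection.

The variant implemented here is the covariance-direction NIPALS-style
algorithm: each direction vector is proportional to the input–output
covariances of the current residuals, inputs and output are regressed on
the component scores and deflated, and the loop stops when the output
residual is small, a direction degenerates, or the component count reaches
the sample-size cap.  Coefficients over the original inputs are recovered
through the accumulated deflation transform, so a full-component fit on
tall full-rank data reproduces ordinary least squares.  X and y are
mean-centered internally (the intercept is recovered); the field-specific
mean/std feature scaling is applied upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDirectionError, InsufficientDataError

#: covariances with absolute value below this count as zero
_COV_TOL = 1e-12


@dataclass
class PLSComponent:
    p: np.ndarray          # unit direction vector over (current residual) inputs
    ax: np.ndarray         # per-input regression coefficients on the scores
    ay: float              # output regression coefficient on the scores
    scores: np.ndarray     # t = p^T X_residual, one value per sample


@dataclass
class PLSModel:
    """Fitted PLS decomposition plus recovered original-input coefficients."""

    components: list[PLSComponent]
    recovered_coefficients: np.ndarray   # over original inputs
    intercept: float
    residual: np.ndarray                 # final output residual (centered scale)
    residual_norms: np.ndarray           # ||ry|| after 1..m components
    x_mean: np.ndarray
    y_mean: float
    y_variance: float = 1.0
    zero_covariance_stop: bool = False
    transform_basis: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + self.recovered_coefficients @ np.asarray(X, float)

    def coefficients_upto(self, m: int) -> tuple[np.ndarray, float]:
        """Recovered coefficients using only the first ``m`` components."""
        coef = _recover(self.components[:m], self.x_mean.size)
        return coef, self.y_mean - coef @ self.x_mean

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_components": self.n_components,
                "coefficients": self.recovered_coefficients.tolist(),
                "intercept": self.intercept,
                "residual_norms": self.residual_norms.tolist(),
                "directions": [c.p.tolist() for c in self.components],
                "zero_covariance_stop": self.zero_covariance_stop,
            },
            indent=2,
        )


def direction_vector(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Unit vector over features proportional to cov(x_i, y).

    Returns ``(p, degenerate)``; ``degenerate`` is True when every
    covariance is (numerically) zero, in which case p is the zero vector.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if X.shape[1] < 2:
        raise InsufficientDataError("direction vector needs >= 2 samples")
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ yc / (X.shape[1] - 1)
    norm = float(np.linalg.norm(cov))
    if norm < _COV_TOL:
        return np.zeros(X.shape[0]), True
    return cov / norm, False


def deflate(
    X: np.ndarray, y: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Regress inputs and output on the scores t = pᵀX and return residuals.

    Returns ``(rx, ry, ax, ay)`` with rx/ry orthogonal to t.  Raises
    :class:`DegenerateDirectionError` when the scores carry no variation.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    if np.linalg.norm(p) < _COV_TOL:
        raise DegenerateDirectionError("zero-norm direction vector")
    t = p @ X
    tt = float(t @ t)
    if tt < _COV_TOL:
        raise DegenerateDirectionError("direction orthogonal to data variation")
    ax = X @ t / tt
    ay = float(y @ t / tt)
    rx = X - np.outer(ax, t)
    ry = y - ay * t
    return rx, ry, ax, ay


def _recover(components: list[PLSComponent], n_features: int) -> np.ndarray:
    """Map direction vectors back to coefficients over the original inputs.

    Each residual-input matrix is a linear image of the original inputs:
    X_{i+1} = (I − ax_i p_iᵀ) X_i, so the prediction Σ ay_i p_iᵀ X_i is a
    linear form cᵀX with c accumulated through the deflation maps (the
    identity-seeded basis below).
    """
    basis = np.eye(n_features)   # maps original X to current residual X
    coef = np.zeros(n_features)
    for c in components:
        coef += c.ay * (basis.T @ c.p)
        basis = (np.eye(n_features) - np.outer(c.ax, c.p)) @ basis
    return coef


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int | None = None,
    residual_tol: float = 1e-10,
) -> PLSModel:
    """Fit the covariance-direction PLS decomposition.

    Components are added until the output-residual norm drops below
    ``residual_tol``, a zero-covariance direction appears, or the count
    reaches ``min(max_components, n_samples − 1)``.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n_feat, n_samp = X.shape
    if n_samp < 2:
        raise InsufficientDataError("fit_pls needs >= 2 samples")
    if y.shape != (n_samp,):
        raise InsufficientDataError("y length must equal sample count")
    cap = n_samp - 1
    if max_components is not None:
        cap = min(cap, int(max_components))
    x_mean = X.mean(axis=1)
    y_mean = float(y.mean())
    rx = X - x_mean[:, None]
    ry = y - y_mean
    components: list[PLSComponent] = []
    norms: list[float] = []
    zero_stop = False
    basis = np.eye(n_feat)
    while len(components) < cap:
        p, degenerate = direction_vector(rx, ry)
        if degenerate:
            zero_stop = True
            break
        try:
            rx_new, ry_new, ax, ay = deflate(rx, ry, p)
        except DegenerateDirectionError:
            zero_stop = True
            break
        components.append(PLSComponent(p=p, ax=ax, ay=ay, scores=p @ rx))
        basis = (np.eye(n_feat) - np.outer(ax, p)) @ basis
        rx, ry = rx_new, ry_new
        norms.append(float(np.linalg.norm(ry)))
        if norms[-1] <= residual_tol:
            break
    coef = _recover(components, n_feat)
    return PLSModel(
        components=components,
        recovered_coefficients=coef,
        intercept=y_mean - coef @ x_mean,
        residual=ry,
        residual_norms=np.array(norms),
        x_mean=x_mean,
        y_mean=y_mean,
        y_variance=float(np.var(y, ddof=1)),
        zero_covariance_stop=zero_stop,
        transform_basis=basis,
    )


def enforce_sign_constraints(
    coefficients: np.ndarray, signs: np.ndarray, epsilon: float = 1e-3
) -> np.ndarray:
    """Replace coefficients that contradict their regulation sign by sign·ε.

    A declared activator keeps only positive weight; a declared repressor
    only negative.  Conforming (and exactly-zero-sign) entries pass through
    untouched.  Idempotent.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    coef = np.array(coefficients, dtype=float)
    signs = np.asarray(signs)
    wrong = (signs != 0) & (coef * signs < 0)
    coef[wrong] = signs[wrong] * epsilon
    return coef


def penalized_component_count(
    pls: PLSModel, n_samples: int, penalty_weight: float | None = None
) -> int:
    """Select the component count m minimizing RSS(m) + λ·ln(1+m).

    λ defaults to the sample variance of the (centered) output, giving the
    penalty the scale of one output-variance unit per log-component.
    """
    if pls.n_components == 0:
        return 0
    rss = pls.residual_norms**2
    if penalty_weight is None:
        penalty_weight = pls.y_variance
    m_grid = np.arange(1, pls.n_components + 1)
    crit = rss + penalty_weight * np.log1p(m_grid)
    return int(m_grid[int(np.argmin(crit))])
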