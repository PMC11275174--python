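"""Linear Kalman filtering used to smooth acceleration channels.

The predict/update recursion is implemented for general matrix models, but
the pipeline applies it per channel with the simplest model consistent with
"smooth the fused data": an independent scalar random walk per acceleration
axis (A = 1, B = 0, H = 1).  Process noise Q defaults to 0.01·R; R can be
estimated from the first few quiescent samples of a channel.

The covariance update uses the Joseph form
``P = (I - K H) P (I - K H)^T + K R K^T`` which is algebraically equal to
``(I - K H) P`` at the exact gain but stays symmetric positive semi-definite
under round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ValidationError

__all__ = [
    "KalmanModel",
    "KalmanState",
    "kf_predict",
    "kf_update",
    "scalar_random_walk",
    "estimate_observation_noise",
    "smooth_stream",
    "steady_state_gain",
]


def _as_matrix(m, name: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(m, dtype=float))
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be a matrix, got ndim={arr.ndim}")
    return arr


def _check_psd(m: np.ndarray, name: str, strict: bool = False) -> None:
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValidationError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(m)
    lo = eigvals.min(initial=0.0)
    if strict and eigvals.min() <= 0:
        raise ValidationError(f"{name} must be positive definite (min eig {lo:g})")
    if not strict and lo < -1e-10 * max(1.0, abs(eigvals).max()):
        raise ValidationError(f"{name} must be positive semi-definite (min eig {lo:g})")


@dataclass(frozen=True)
class KalmanModel:
    """Time-invariant linear-Gaussian model (A, B, H, Q, R)."""

    A: np.ndarray
    B: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", _as_matrix(self.A, "A"))
        object.__setattr__(self, "B", _as_matrix(self.B, "B"))
        object.__setattr__(self, "H", _as_matrix(self.H, "H"))
        object.__setattr__(self, "Q", _as_matrix(self.Q, "Q"))
        object.__setattr__(self, "R", _as_matrix(self.R, "R"))
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValidationError("A must be square")
        if self.B.shape[0] != n:
            raise ValidationError("B row count must match the state dimension")
        if self.H.shape[1] != n:
            raise ValidationError("H column count must match the state dimension")
        m = self.H.shape[0]
        if self.Q.shape != (n, n):
            raise ValidationError("Q must be n-by-n")
        if self.R.shape != (m, m):
            raise ValidationError("R must be m-by-m")
        _check_psd(self.Q, "Q")
        _check_psd(self.R, "R", strict=True)

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]

    @property
    def obs_dim(self) -> int:
        return self.H.shape[0]


@dataclass(frozen=True)
class KalmanState:
    """State estimate x with covariance P."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, dtype=float)).ravel()
        P = _as_matrix(self.P, "P")
        if P.shape != (x.size, x.size):
            raise ValidationError("P must be n-by-n for an n-dimensional state")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "P", P)


def kf_predict(
    state: KalmanState, model: KalmanModel, u: np.ndarray | float | None = None
) -> KalmanState:
    """Prediction step: x⁻ = A x + B u,  P⁻ = A P Aᵀ + Q.

    The returned covariance is explicitly symmetrised to machine precision.
    """
    if state.x.size != model.state_dim:
        raise ValidationError(
            f"state dimension {state.x.size} does not match model {model.state_dim}"
        )
    if u is None:
        u_vec = np.zeros(model.B.shape[1])
    else:
        u_vec = np.atleast_1d(np.asarray(u, dtype=float)).ravel()
        if u_vec.size != model.B.shape[1]:
            raise ValidationError("control input dimension does not match B")
    x_prior = model.A @ state.x + model.B @ u_vec
    P_prior = model.A @ state.P @ model.A.T + model.Q
    P_prior = 0.5 * (P_prior + P_prior.T)
    return KalmanState(x=x_prior, P=P_prior)


def kf_update(
    state: KalmanState, model: KalmanModel, z: np.ndarray | float
) -> KalmanState:
    """Update step: K = P⁻Hᵀ(HP⁻Hᵀ + R)⁻¹, x = x⁻ + K(z − Hx⁻), P = (I − KH)P⁻.

    Internally the covariance is propagated in Joseph form for robustness;
    the result agrees with (I − KH)P⁻ to symmetrisation tolerance.

    Raises
    ------
    NumericalError
        If the innovation covariance S = HP⁻Hᵀ + R is singular to working
        precision.
    """
    z_vec = np.atleast_1d(np.asarray(z, dtype=float)).ravel()
    if z_vec.size != model.obs_dim:
        raise ValidationError("observation dimension does not match H")
    H, R = model.H, model.R
    S = H @ state.P @ H.T + R
    S = 0.5 * (S + S.T)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e14:
        raise NumericalError(
            f"innovation covariance is singular to working precision (cond={cond:.3g})"
        )
    K = np.linalg.solve(S.T, (state.P @ H.T).T).T
    innovation = z_vec - H @ state.x
    x_post = state.x + K @ innovation
    I_KH = np.eye(state.x.size) - K @ H
    P_post = I_KH @ state.P @ I_KH.T + K @ R @ K.T
    P_post = 0.5 * (P_post + P_post.T)
    return KalmanState(x=x_post, P=P_post)


def scalar_random_walk(q: float, r: float) -> KalmanModel:
    """Scalar random-walk smoother model: A = H = 1, B = 0."""
    if q < 0 or r <= 0:
        raise ValidationError("need q >= 0 and r > 0")
    return KalmanModel(A=[[1.0]], B=[[0.0]], H=[[1.0]], Q=[[q]], R=[[r]])


def estimate_observation_noise(values, n: int = 10, floor: float = 1e-6) -> float:
    """Observation-noise variance from the first ``n`` quiescent samples.

    Intended for streams that begin at rest (standing), where early-sample
    scatter is measurement noise rather than motion.  Falls back to ``floor``
    when fewer than two samples are available or the variance is ~0.
    """
    head = np.asarray(values, dtype=float)[:n]
    if head.size < 2:
        return floor
    return max(float(np.var(head, ddof=1)), floor)


def smooth_stream(values, model: KalmanModel) -> np.ndarray:
    """Filter a scalar series through repeated predict/update cycles.

    The state is initialised at the first observation with P0 = R, so the
    output has the same length as the input and a constant series is a fixed
    point.  An empty series yields an empty output.
    """
    series = np.asarray(values, dtype=float).ravel()
    if series.size == 0:
        return series.copy()
    if not np.all(np.isfinite(series)):
        raise ValidationError("series contains non-finite values")
    if model.state_dim != 1 or model.obs_dim != 1:
        raise ValidationError("smooth_stream expects a scalar model")
    state = KalmanState(x=[series[0]], P=model.R.copy())
    out = np.empty_like(series)
    out[0] = series[0]
    for k in range(1, series.size):
        state = kf_predict(state, model)
        state = kf_update(state, model, series[k])
        out[k] = state.x[0]
    return out


def steady_state_gain(q: float, r: float) -> float:
    """Closed-form steady-state gain of the scalar random-walk filter.

    Solves the Riccati fixed point for A = H = 1:
    P⁻ = (q + sqrt(q² + 4qr)) / 2 and K = P⁻ / (P⁻ + r).
    """
    if q < 0 or r <= 0:
        raise ValidationError("need q >= 0 and r > 0")
    p_prior = 0.5 * (q + np.sqrt(q * q + 4.0 * q * r))
    return float(p_prior / (p_prior + r))
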