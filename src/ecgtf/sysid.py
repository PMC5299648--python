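"""Discrete-time rational transfer-function estimation between SAECGs.

The model is a ratio of polynomials in z with a monic denominator and no
feedthrough (numerator order strictly below denominator order),

    G(z) = (b_n z^n + ... + b_0) / (z^m + a_{m-1} z^{m-1} + ... + a_0),
    n <= m - 1,

so the simulated output at time t depends only on past inputs.  Estimation
follows the classical output-error recipe: an equation-error (ARX) linear
least-squares fit provides the starting point, and a damped Gauss-Newton
(Levenberg-Marquardt) iteration then minimises the *simulation* error
``sum (y - G(x))^2`` with zero initial conditions.  Fit quality is the
normalised-RMS goodness of fit

    GF = 100 * (1 - ||y_m - y_s|| / ||y_m - mean(y_m)||),

which is 100 for a perfect simulation and 0 for the constant-mean predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DegenerateDataError, InstabilityError, ParameterError

__all__ = [
    "DiscreteTransferFunction",
    "FitResult",
    "simulate_tf",
    "goodness_of_fit",
    "estimate_tf",
    "is_stable",
]


@dataclass(frozen=True)
class DiscreteTransferFunction:
    """Rational transfer function in z, descending powers, monic denominator.

    Parameters
    ----------
    num : coefficients ``b_n ... b_0`` (numerator order ``n = len(num) - 1``).
    den : coefficients ``1, a_{m-1} ... a_0`` (denominator order ``m``);
        the leading coefficient must be exactly 1.

    The no-feedthrough constraint ``n <= m - 1`` is enforced at construction.
    """

    num: tuple[float, ...]
    den: tuple[float, ...]

    def __post_init__(self):
        num = tuple(float(c) for c in self.num)
        den = tuple(float(c) for c in self.den)
        if len(den) < 2:
            raise ParameterError("denominator order must be >= 1")
        if den[0] != 1.0:
            raise ParameterError("denominator must be monic (leading coefficient 1)")
        if len(num) < 1:
            raise ParameterError("numerator must have at least one coefficient")
        if len(num) > len(den) - 1:
            raise ParameterError(
                f"no-feedthrough violated: numerator order {len(num) - 1} "
                f">= denominator order {len(den) - 1}"
            )
        if not (np.all(np.isfinite(num)) and np.all(np.isfinite(den))):
            raise ParameterError("coefficients must be finite")
        object.__setattr__(self, "num", num)
        object.__setattr__(self, "den", den)

    @property
    def num_order(self) -> int:
        return len(self.num) - 1

    @property
    def den_order(self) -> int:
        return len(self.den) - 1

    def to_dict(self) -> dict:
        return {"num": list(self.num), "den": list(self.den)}

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteTransferFunction":
        return cls(num=tuple(d["num"]), den=tuple(d["den"]))


@dataclass
class FitResult:
    """An estimated transfer function plus its goodness of fit against y."""

    tf: DiscreteTransferFunction
    gf: float
    converged: bool
    n_iter: int
    subject_id: str | None = None
    pair: str | None = None
    meta: dict = field(default_factory=dict)


def _padded_num(tf: DiscreteTransferFunction) -> np.ndarray:
    """Numerator zero-padded on the left to denominator length.

    Dividing num and den by z^m turns G into a causal filter in z^{-1};
    the pad implements the m - n sample delay of the no-feedthrough model.
    """
    pad = len(tf.den) - len(tf.num)
    return np.concatenate([np.zeros(pad), np.asarray(tf.num, dtype=float)])


def simulate_tf(tf: DiscreteTransferFunction, x: np.ndarray) -> np.ndarray:
    """Simulate the response of ``tf`` to input ``x`` with zero initial conditions.

    Implements the difference equation

        y[t] = -sum_{k=1..m} a_{m-k} y[t-k] + sum_{j=0..n} b_j x[t-(m-j)]

    (terms with negative indices are zero).  Raises
    :class:`~ecgtf.errors.InstabilityError` naming the first non-finite sample
    if the recursion blows up.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("input signal must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ParameterError("input signal contains non-finite samples")
    y = sps.lfilter(_padded_num(tf), np.asarray(tf.den, dtype=float), x)
    bad = ~np.isfinite(y)
    if bad.any():
        first = int(np.argmax(bad))
        raise InstabilityError(
            f"simulation produced a non-finite value at sample {first}", first
        )
    return y


def _simulate_raw(num_pad: np.ndarray, den: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Simulation without finiteness checks, for use inside the optimiser."""
    return sps.lfilter(num_pad, den, x)


def goodness_of_fit(y_measured: np.ndarray, y_simulated: np.ndarray) -> float:
    """Normalised-RMS goodness of fit, in percent.

    ``100 * (1 - ||y_m - y_s||_2 / ||y_m - mean(y_m)||_2)``.  Returns exactly
    100.0 when the vectors are identical; may be negative for fits worse than
    the constant-mean predictor.
    """
    y_m = np.asarray(y_measured, dtype=float)
    y_s = np.asarray(y_simulated, dtype=float)
    if y_m.shape != y_s.shape:
        raise ParameterError(
            f"length mismatch: {y_m.shape} vs {y_s.shape}"
        )
    if y_m.size < 2:
        raise ParameterError("need at least 2 samples")
    denom = np.linalg.norm(y_m - y_m.mean())
    if denom == 0.0:
        raise DegenerateDataError("measured signal is constant (zero reference norm)")
    if np.array_equal(y_m, y_s):
        return 100.0
    return float(100.0 * (1.0 - np.linalg.norm(y_m - y_s) / denom))


def is_stable(tf: DiscreteTransferFunction) -> bool:
    """True iff every pole (denominator root) lies strictly inside the unit circle."""
    roots = np.roots(np.asarray(tf.den, dtype=float))
    if roots.size == 0:
        return True
    return bool(np.max(np.abs(roots)) < 1.0)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def _delayed(v: np.ndarray, k: int) -> np.ndarray:
    """v delayed by k samples, zero-filled at the head (zero initial conditions)."""
    if k == 0:
        return v
    out = np.zeros_like(v)
    out[k:] = v[:-k]
    return out


#: relative Tikhonov floor on the LM step matrix.  Smooth band-limited
#: inputs leave near-flat directions in the output-error cost (the
#: out-of-band response is unconstrained); the floor keeps steps along
#: those directions negligible so the iteration stays anchored near its
#: initialisation instead of drifting along the valley.  It regularises
#: only the trajectory: a converged point still has zero gradient of the
#: unmodified cost.
_STEP_FLOOR_REL = 1e-3


def _arx_init(
    x: np.ndarray, y: np.ndarray, n: int, m: int, ridge: float = 0.0
) -> np.ndarray:
    """Equation-error least squares for the difference-equation coefficients.

    Regressors use zero padding for negative time indices, consistent with the
    zero-initial-condition simulation convention.  Returns the parameter
    vector ``[b_n..b_0, a_{m-1}..a_0]``.
    """
    cols = []
    # b_j multiplies x[t - (m - j)], j = n..0 -> delays m-n .. m
    for j in range(n, -1, -1):
        cols.append(_delayed(x, m - j))
    # a_{m-k} multiplies -y[t - k], k = 1..m
    for k in range(1, m + 1):
        cols.append(-_delayed(y, k))
    phi = np.column_stack(cols)
    if ridge > 0.0:
        gram = phi.T @ phi + ridge * np.eye(phi.shape[1])
        return np.linalg.solve(gram, phi.T @ y)
    theta, *_ = np.linalg.lstsq(phi, y, rcond=None)
    return theta


def _theta_to_tf(theta: np.ndarray, n: int, m: int) -> DiscreteTransferFunction:
    num = tuple(theta[: n + 1])
    den = (1.0, *theta[n + 1 :])
    return DiscreteTransferFunction(num=num, den=den)


def _stabilized_den(den: np.ndarray) -> np.ndarray:
    """Reflect any pole on or outside the unit circle to modulus < 1.

    Reflection (r -> 1/conj(r)) preserves the magnitude response up to gain;
    it turns an exploding initial model into a usable starting point.
    """
    roots = np.roots(den)
    mags = np.abs(roots)
    if roots.size == 0 or np.max(mags) < 1.0:
        return den
    new = roots.copy()
    for i, (r, mag) in enumerate(zip(roots, mags)):
        if mag >= 1.0:
            new_mag = min(1.0 / mag, 0.99) if mag > 0 else 0.0
            new[i] = r / mag * new_mag
    out = np.real(np.poly(new))
    out[0] = 1.0
    return out


def _oe_cost(
    theta: np.ndarray, n: int, m: int, x: np.ndarray, y: np.ndarray, ridge: float = 0.0
) -> tuple[np.ndarray | None, float]:
    """Simulation and (ridge-penalised) output-error cost; (None, inf) on blow-up."""
    den = np.concatenate([[1.0], theta[n + 1 :]])
    pad = np.concatenate([np.zeros(m - n), theta[: n + 1]])
    with np.errstate(all="ignore"):
        sim = _simulate_raw(pad, den, x)
        if not np.all(np.isfinite(sim)):
            return None, np.inf
        cost = float(np.sum((y - sim) ** 2) + ridge * np.sum(theta**2))
    if not np.isfinite(cost):
        return None, np.inf
    return sim, cost


def _initialize(
    x: np.ndarray,
    y: np.ndarray,
    n: int,
    m: int,
    ridge: float = 0.0,
    sm_iterations: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Starting point for the output-error refinement.

    Plain ARX is the first candidate; Steiglitz-McBride-style iterations
    (re-solving the ARX least squares on data prefiltered by 1/A of the
    previous, pole-reflected, denominator estimate) then successively reduce
    the equation-error bias.  A pure-FIR solution (denominator z^m) is kept
    as a guaranteed-finite fallback.  Returns the candidate with the lowest
    simulation cost.
    """
    candidates: list[np.ndarray] = []

    theta_arx = _arx_init(x, y, n, m, ridge)
    candidates.append(theta_arx)
    # pole-reflected variant, in case the raw ARX model explodes
    den_stab = _stabilized_den(np.concatenate([[1.0], theta_arx[n + 1 :]]))
    candidates.append(np.concatenate([theta_arx[: n + 1], den_stab[1:]]))

    # FIR fallback: a = 0, b by least squares on the delayed-input regressors
    cols = [_delayed(x, m - j) for j in range(n, -1, -1)]
    b_fir, *_ = np.linalg.lstsq(np.column_stack(cols), y, rcond=None)
    candidates.append(np.concatenate([b_fir, np.zeros(m)]))

    den_prev = den_stab
    one = np.array([1.0])
    for _ in range(sm_iterations):
        with np.errstate(all="ignore"):
            xf = sps.lfilter(one, den_prev, x)
            yf = sps.lfilter(one, den_prev, y)
        if not (np.all(np.isfinite(xf)) and np.all(np.isfinite(yf))):
            break
        theta_sm = _arx_init(xf, yf, n, m, ridge)
        den_prev = _stabilized_den(np.concatenate([[1.0], theta_sm[n + 1 :]]))
        candidates.append(theta_sm)
        candidates.append(np.concatenate([theta_sm[: n + 1], den_prev[1:]]))

    best_theta, best_sim, best_cost = None, None, np.inf
    for theta in candidates:
        sim, cost = _oe_cost(theta, n, m, x, y, ridge)
        if cost < best_cost:
            best_theta, best_sim, best_cost = theta, sim, cost
    if best_theta is None:  # even the FIR fallback failed: degenerate input
        best_theta = candidates[-1]
        best_sim = np.zeros_like(y)
        best_cost = float(np.sum(y**2))
    return best_theta, best_sim, best_cost


def _oe_jacobian(
    theta: np.ndarray, n: int, m: int, x: np.ndarray, y_sim: np.ndarray
) -> np.ndarray:
    """Analytic Jacobian of the simulated output w.r.t. the parameters.

    With y = (B/A) x:  dy/db_j = (1/A) x delayed by m-j, and
    dy/da_{m-k} = -(1/A) y_sim delayed by k.
    """
    den = np.concatenate([[1.0], theta[n + 1 :]])
    one = np.array([1.0])
    fx = sps.lfilter(one, den, x)
    fy = sps.lfilter(one, den, y_sim)
    cols = [_delayed(fx, m - j) for j in range(n, -1, -1)]
    cols += [-_delayed(fy, k) for k in range(1, m + 1)]
    return np.column_stack(cols)


def estimate_tf(
    x: np.ndarray,
    y: np.ndarray,
    num_order: int,
    den_order: int,
    *,
    max_iter: int = 100,
    rtol: float = 1e-8,
) -> FitResult:
    """Estimate a no-feedthrough transfer function from input x to output y.

    Two stages: an equation-error (ARX) linear least-squares initialisation,
    sharpened by Steiglitz-McBride-style prefiltered re-solves with unstable
    poles reflected inside the unit circle, then Levenberg-Marquardt
    refinement of the output-error cost ``sum (y - simulate(theta, x))^2``
    with zero initial conditions.  Damping is multiplied by 10 on a rejected
    step and by 0.1 on an accepted one; iteration stops on a relative cost
    change below ``rtol`` or after ``max_iter`` iterations.  If no usable
    starting point simulates to finite values, the fallback model is returned
    with ``converged=False`` and ``gf=-inf``.

    The refinement only ever accepts cost-decreasing steps, so the returned
    simulation error is never worse than the initialisation's.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = int(num_order), int(den_order)
    if m < 1:
        raise ParameterError("denominator order must be >= 1")
    if n > m - 1:
        raise ParameterError("no feedthrough: require num_order <= den_order - 1")
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D arrays")
    if x.size <= 10 * m:
        raise ParameterError(
            f"need more than {10 * m} samples for denominator order {m}, got {x.size}"
        )
    if np.ptp(y) == 0.0:
        raise DegenerateDataError("output signal is constant")

    theta, y_sim, cost = _initialize(x, y, n, m)
    if y_sim is None or not np.isfinite(cost):
        tf0 = _theta_to_tf(theta, n, m)
        return FitResult(tf=tf0, gf=float("-inf"), converged=False, n_iter=0)

    lam = 1e-3
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        with np.errstate(all="ignore"):
            jac = _oe_jacobian(theta, n, m, x, y_sim)
            resid = y - y_sim
            jtj = jac.T @ jac
            jtr = jac.T @ resid
        if not (np.all(np.isfinite(jtj)) and np.all(np.isfinite(jtr))):
            break
        diag = np.diag(jtj).copy()
        diag[diag <= 0.0] = 1.0
        floor = _STEP_FLOOR_REL * float(np.mean(diag)) * np.eye(jac.shape[1])
        accepted = False
        while lam <= 1e12:
            with np.errstate(all="ignore"):
                try:
                    step = np.linalg.solve(jtj + lam * np.diag(diag) + floor, jtr)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
            if not np.all(np.isfinite(step)):
                lam *= 10.0
                continue
            cand = theta + step
            cand_sim, cand_cost = _oe_cost(cand, n, m, x, y)
            if cand_cost < cost:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            converged = True  # no descent direction left: at a (local) minimum
            break
        rel_change = (cost - cand_cost) / max(cost, np.finfo(float).tiny)
        theta, y_sim, cost = cand, cand_sim, cand_cost
        lam = max(lam * 0.1, 1e-12)
        if rel_change < rtol:
            converged = True
            break

    tf = _theta_to_tf(theta, n, m)
    gf = goodness_of_fit(y, y_sim)
    return FitResult(tf=tf, gf=gf, converged=converged, n_iter=n_iter)
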