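"""Levenberg-Marquardt least squares with a multiplicative damping schedule.

Both calibration (estimating the 12 model coefficients) and inversion
(estimating the two sources of one observation) minimise a sum of squared
residuals by damped Gauss-Newton steps: at iterate theta_k solve

    (J^T J + lambda_k I) step = J^T residual(theta_k)

and accept theta_{k+1} = theta_k - step when it lowers the cost, shrinking
lambda by a fixed factor; otherwise lambda grows and the step is retried.
An optional projection hook constrains iterates (exponent bounds during
calibration, nonnegative sources during inversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["FitOptions", "LMResult", "levenberg_marquardt", "numeric_jacobian"]


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the damped least-squares solver.

    lambda0 is the initial damping, multiplied/divided by lambda_factor on
    rejected/accepted steps.  tol_step stops on small parameter steps,
    tol_cost on small relative cost decrease.  seed and n_restarts control
    the randomised multi-start used by calibration.
    """

    lambda0: float = 1e-3
    lambda_factor: float = 10.0
    max_iter: int = 500
    tol_step: float = 1e-10
    tol_cost: float = 1e-12
    seed: int = 0
    n_restarts: int = 3

    def __post_init__(self):
        if min(self.lambda0, self.lambda_factor, self.tol_step, self.tol_cost) <= 0:
            raise ValueError("lambda0, lambda_factor and tolerances must be positive")
        if self.lambda_factor <= 1:
            raise ValueError("lambda_factor must exceed 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.n_restarts < 0:
            raise ValueError("n_restarts must be nonnegative")


@dataclass
class LMResult:
    params: np.ndarray
    cost: float
    converged: bool
    n_iter: int
    cost_history: list = field(default_factory=list)
    message: str = ""


def numeric_jacobian(fun: Callable[[np.ndarray], np.ndarray], theta: np.ndarray,
                     rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of a residual function."""
    theta = np.asarray(theta, dtype=float)
    f0 = np.asarray(fun(theta), dtype=float)
    jac = np.empty((f0.size, theta.size))
    for j in range(theta.size):
        h = rel_step * max(abs(theta[j]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        jac[:, j] = (np.asarray(fun(tp)) - np.asarray(fun(tm))) / (2.0 * h)
    return jac


def levenberg_marquardt(
    fun: Callable[[np.ndarray], np.ndarray],
    theta0: Sequence[float],
    jac: Callable[[np.ndarray], np.ndarray] | None = None,
    options: FitOptions | None = None,
    project: Callable[[np.ndarray], np.ndarray] | None = None,
) -> LMResult:
    """Minimise ||fun(theta)||^2 from theta0.

    Parameters
    ----------
    fun : callable
        Residual vector as a function of the parameters.
    jac : callable, optional
        Analytic Jacobian of ``fun``; finite differences when omitted.
    project : callable, optional
        Applied to every trial iterate (and to theta0) before evaluation;
        must be idempotent (e.g. clipping to a box).

    The returned ``cost_history`` holds the cost after every *accepted*
    step (starting with the initial cost), hence is non-increasing.
    """
    opts = options or FitOptions()
    theta = np.asarray(theta0, dtype=float).copy()
    if project is not None:
        theta = project(theta)

    def residual(t):
        r = np.asarray(fun(t), dtype=float)
        if not np.all(np.isfinite(r)):
            raise FloatingPointError("non-finite residual encountered")
        return r

    jac_fun = jac if jac is not None else (lambda t: numeric_jacobian(fun, t))

    r = residual(theta)
    cost = float(r @ r)
    lam = opts.lambda0
    history = [cost]
    converged = False
    message = "max_iter reached"
    n_iter = 0

    for n_iter in range(1, opts.max_iter + 1):
        J = np.asarray(jac_fun(theta), dtype=float)
        g = J.T @ r
        JtJ = J.T @ J
        accepted = False
        # inner loop: inflate damping until a step is accepted (or give up)
        for _ in range(50):
            try:
                step = np.linalg.solve(JtJ + lam * np.eye(theta.size), g)
            except np.linalg.LinAlgError:
                lam *= opts.lambda_factor
                continue
            trial = theta - step
            if project is not None:
                trial = project(trial)
                # active-set refinement: a clipped coordinate can dominate the
                # damped solve and freeze the free ones at the constraint, so
                # re-solve with the clipped coordinates held at their bounds
                clipped = ~np.isclose(trial, theta - step)
                if np.any(clipped) and not np.all(clipped):
                    free = ~clipped
                    step_c = theta[clipped] - trial[clipped]
                    rhs = g[free] - JtJ[np.ix_(free, clipped)] @ step_c
                    sub = JtJ[np.ix_(free, free)] + lam * np.eye(int(free.sum()))
                    try:
                        step_f = np.linalg.solve(sub, rhs)
                        alt = trial.copy()
                        alt[free] = theta[free] - step_f
                        alt = project(alt)
                        if float(residual(alt) @ residual(alt)) < float(
                            residual(trial) @ residual(trial)
                        ):
                            trial = alt
                    except (np.linalg.LinAlgError, FloatingPointError):
                        pass
            try:
                r_trial = residual(trial)
            except FloatingPointError:
                lam *= opts.lambda_factor
                continue
            cost_trial = float(r_trial @ r_trial)
            if cost_trial <= cost:
                accepted = True
                break
            lam *= opts.lambda_factor
        if not accepted:
            converged = cost <= opts.tol_cost or float(g @ g) < opts.tol_step**2
            message = "no acceptable step found (damping exhausted)"
            break

        step_norm = float(np.linalg.norm(theta - trial))
        rel_decrease = (cost - cost_trial) / max(cost, np.finfo(float).tiny)
        theta, r, cost = trial, r_trial, cost_trial
        history.append(cost)
        lam = max(lam / opts.lambda_factor, 1e-15)

        if step_norm < opts.tol_step:
            converged, message = True, "step tolerance reached"
            break
        if rel_decrease < opts.tol_cost:
            converged, message = True, "cost tolerance reached"
            break
    else:
        # loop exhausted: flag convergence only if the cost is essentially zero
        converged = cost <= opts.tol_cost

    return LMResult(
        params=theta,
        cost=cost,
        converged=converged,
        n_iter=n_iter,
        cost_history=history,
        message=message,
    )
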