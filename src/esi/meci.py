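"""Minimum-energy conical intersection (MECI) optimizers.

Both optimizers are driven purely through the interface API (set
coordinates, request energies/gradients/couplings, run) so they work
unchanged over an analytic model, a numerical-differentiation hybrid, or
any other interface tree that can serve the needed requests.

**Penalty method** (gradients only).  Minimize

    F(R) = (E_i + E_j)/2 + sigma * dE^2 / (dE + alpha),    dE = E_i - E_j

with the smoothing parameter alpha keeping F differentiable through the
seam.  The chain rule gives dF = w_i dE_i + w_j dE_j with

    w_i = 1/2 + sigma * (dE^2 + 2*alpha*dE) / (dE + alpha)^2,   w_j = 1 - w_i.

A small gap typically remains at the optimum, set by sigma/alpha and the
intersection topology.

**Projected-gradient method** (needs NAC vectors, e.g. from the numerical
differentiation hybrid).  The branching plane is spanned by the gradient
difference g_d = dE_i - dE_j and the (normalized) NAC vector; the
composite step combines a gap-closing move along g_d with the mean-energy
gradient projected orthogonal to the branching plane (the seam
component), driving the geometry to the true minimum on the degenerate
seam.  Normalizing the NAC before spanning the plane makes the step
scale-invariant to its 1/dE growth near the seam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import Interface
from .containers import RequestSet
from .errors import ConditioningError, NegotiationError

__all__ = [
    "PenaltyConfig",
    "OptState",
    "penalty_objective",
    "penalty_optimize",
    "projected_gradient_step",
    "projected_optimize",
    "optimize_meci",
]


@dataclass
class PenaltyConfig:
    """Penalty weight sigma, smoothing alpha (Hartree) and the state pair.

    ``state_lower``/``state_upper`` are 1-based sublevel indices with the
    upper state directly above the lower one.
    """

    sigma: float = 3.5
    alpha: float = 0.02
    state_lower: int = 1
    state_upper: int = 2

    def __post_init__(self):
        if self.sigma <= 0 or self.alpha <= 0:
            raise ValueError("sigma and alpha must be positive")


@dataclass
class OptState:
    """Optimizer bookkeeping: geometry, energies, gap and convergence flags."""

    geometry: np.ndarray
    energies: np.ndarray
    gap: float
    iterations: int
    converged: bool
    method: str
    gap_converged: bool = False
    step_converged: bool = False
    grad_converged: bool = False
    history: dict = field(default_factory=lambda: {"objective": [], "gap": []})


def penalty_objective(e_i: float, e_j: float, cfg: PenaltyConfig):
    """Penalty value and the chain-rule weights (w_i, w_j), w_i + w_j = 1.

    ``e_i`` is the upper state, ``e_j`` the lower (e_i >= e_j).
    """
    de = e_i - e_j
    value = 0.5 * (e_i + e_j) + cfg.sigma * de**2 / (de + cfg.alpha)
    w_i = 0.5 + cfg.sigma * (de**2 + 2.0 * cfg.alpha * de) / (de + cfg.alpha) ** 2
    return value, w_i, 1.0 - w_i


class _Evaluator:
    """Steps an interface through successive single points for an optimizer."""

    def __init__(self, interface: Interface, pair: tuple[int, int]):
        self.interface = interface
        self.lower, self.upper = pair  # 1-based sublevel indices
        start = interface.save.last_successful_step
        self.step = 0 if start is None else start + 1
        self.n_evals = 0

    def __call__(self, R, need_grad=False, need_nac=False):
        req = RequestSet(hamiltonian=True, step=self.step)
        if need_grad:
            req.gradients = [self.lower, self.upper]
        if need_nac:
            req.nac_vectors = True
        out = self.interface.single_point(np.asarray(R, float).reshape(-1, 3), req)
        self.step += 1
        self.n_evals += 1
        e = out.energies
        res = {"e_lower": e[self.lower - 1], "e_upper": e[self.upper - 1], "energies": e}
        if need_grad:
            res["g_lower"] = out.grad[self.lower - 1].ravel()
            res["g_upper"] = out.grad[self.upper - 1].ravel()
        if need_nac:
            nac = out.nacdr[self.lower - 1, self.upper - 1].ravel()
            flagged = out.metadata.get("nacdr_flagged", [])
            res["nac"] = nac
            res["nac_defined"] = (
                (self.lower - 1, self.upper - 1) not in [tuple(p) for p in flagged]
            )
        return res


def penalty_optimize(
    interface: Interface,
    start_geometry,
    cfg: PenaltyConfig | None = None,
    max_iterations: int = 200,
    grad_tol: float = 1e-6,
    step_tol: float = 1e-5,
) -> OptState:
    """BFGS with backtracking line search on the penalty objective.

    Requires per-state gradients from the interface.  Stops when both the
    projected step norm and the objective gradient norm fall below their
    tolerances; returns the last state on non-convergence.
    """
    cfg = cfg or PenaltyConfig()
    interface.get_features().require({"h", "grad"}, who="penalty optimizer")
    ev = _Evaluator(interface, (cfg.state_lower, cfg.state_upper))
    x = np.asarray(start_geometry, float).ravel().copy()
    n = len(x)

    def fg(xv):
        r = ev(xv, need_grad=True)
        f, w_i, w_j = penalty_objective(r["e_upper"], r["e_lower"], cfg)
        g = w_i * r["g_upper"] + w_j * r["g_lower"]
        return f, g, r

    f, g, r = fg(x)
    hess_inv = np.eye(n)
    history = {"objective": [f], "gap": [r["e_upper"] - r["e_lower"]]}
    it = 0
    step_ok = grad_ok = False
    for it in range(1, max_iterations + 1):
        p = -hess_inv @ g
        if p @ g > 0:  # safeguard against a corrupted quadratic model
            hess_inv = np.eye(n)
            p = -g
        # Armijo backtracking
        t = 1.0
        f_new = g_new = r_new = None
        for _ in range(40):
            f_try, g_try, r_try = fg(x + t * p)
            if f_try <= f + 1e-4 * t * (g @ p):
                f_new, g_new, r_new = f_try, g_try, r_try
                break
            t *= 0.5
        if f_new is None:
            break  # line search failed: converged to numerical precision
        s = t * p
        y = g_new - g
        sy = s @ y
        if sy > 1e-14:
            rho = 1.0 / sy
            eye = np.eye(n)
            hess_inv = (eye - rho * np.outer(s, y)) @ hess_inv @ (
                eye - rho * np.outer(y, s)
            ) + rho * np.outer(s, s)
        x, f, g, r = x + s, f_new, g_new, r_new
        history["objective"].append(f)
        history["gap"].append(r["e_upper"] - r["e_lower"])
        step_ok = np.linalg.norm(s) < step_tol
        grad_ok = np.linalg.norm(g) < grad_tol
        if step_ok and grad_ok:
            break
    gap = r["e_upper"] - r["e_lower"]
    return OptState(
        geometry=x.reshape(-1, 3),
        energies=r["energies"],
        gap=gap,
        iterations=it,
        converged=step_ok and grad_ok,
        method="penalty",
        step_converged=step_ok,
        grad_converged=grad_ok,
        history=history,
    )


@dataclass
class CompositeStep:
    """Decomposed projected-gradient step (all vectors over 3N coordinates)."""

    gap_component: np.ndarray   # Newton move along the gradient difference
    seam_component: np.ndarray  # mean-energy gradient, branching plane projected out
    direction: np.ndarray       # composite downhill direction (their sum)
    b1: np.ndarray              # normalized gradient difference
    b2: np.ndarray              # normalized NAC, orthogonalized against b1


def projected_gradient_step(
    delta_e: float, g_lower, g_upper, nac, parallel_tol: float = 1e-8
) -> CompositeStep:
    """Composite MECI step from the branching-plane construction.

    The gap component is the first-order Newton move that closes the gap
    along the normalized gradient difference; the seam component is the
    mean-energy gradient with both branching-plane directions projected
    out (zero overlap with either, to machine precision).  Raises
    :class:`ConditioningError` when the gradient difference and the NAC
    are (anti)parallel and the plane degenerates.
    """
    g_lower = np.asarray(g_lower, float).ravel()
    g_upper = np.asarray(g_upper, float).ravel()
    nac = np.asarray(nac, float).ravel()
    gd = g_upper - g_lower
    gd_norm = np.linalg.norm(gd)
    if gd_norm < 1e-14:
        raise ConditioningError("gradient difference vanishes; branching plane undefined")
    b1 = gd / gd_norm
    nac_norm = np.linalg.norm(nac)
    if nac_norm < 1e-14:
        raise ConditioningError("NAC vector vanishes; branching plane undefined")
    n_hat = nac / nac_norm
    n_perp = n_hat - (n_hat @ b1) * b1
    if np.linalg.norm(n_perp) < parallel_tol:
        raise ConditioningError(
            "gradient difference and NAC vector are parallel; branching plane "
            "is degenerate"
        )
    b2 = n_perp / np.linalg.norm(n_perp)
    g_mean = 0.5 * (g_lower + g_upper)
    seam = g_mean - (g_mean @ b1) * b1 - (g_mean @ b2) * b2
    gap_component = (delta_e / gd_norm) * b1
    return CompositeStep(gap_component, seam, gap_component + seam, b1, b2)


def projected_optimize(
    interface: Interface,
    start_geometry,
    pair: tuple[int, int] = (1, 2),
    max_iterations: int = 200,
    gap_tol: float = 1e-6,
    grad_tol: float = 1e-6,
    step_tol: float = 1e-5,
) -> OptState:
    """Branching-plane MECI optimization using gradients and NAC vectors.

    Each iteration closes the gap with Newton moves along the gradient
    difference, then takes a backtracking descent step along the negative
    seam component.  When the gap falls below the near-degeneracy threshold
    of the NAC provider, the last well-defined branching-plane direction is
    reused.  Converged when gap <= gap_tol and |seam gradient| <= grad_tol.
    """
    interface.get_features().require({"h", "grad", "nacdr"}, who="projected optimizer")
    ev = _Evaluator(interface, pair)
    x = np.asarray(start_geometry, float).ravel().copy()
    history = {"objective": [], "gap": []}
    # drive the gap to gap_target (not exactly zero): backends legitimately
    # refuse analytic derivatives at numerically exact degeneracy
    gap_target = 0.5 * gap_tol
    last_b2: np.ndarray | None = None
    seam_scale = 1.0
    it = 0
    gap_ok = grad_ok = step_ok = False
    for it in range(1, max_iterations + 1):
        r = ev(x, need_grad=True, need_nac=True)
        gap = r["e_upper"] - r["e_lower"]
        mean = 0.5 * (r["e_upper"] + r["e_lower"])
        history["objective"].append(mean)
        history["gap"].append(gap)
        try:
            if r["nac_defined"] and np.linalg.norm(r["nac"]) > 1e-12:
                step = projected_gradient_step(gap, r["g_lower"], r["g_upper"], r["nac"])
                last_b2 = step.b2
            else:
                raise ConditioningError("NAC unavailable")
        except ConditioningError:
            if last_b2 is None:
                raise NegotiationError(
                    "projected optimizer has no usable NAC direction; start "
                    "farther from the seam or use the penalty method first"
                )
            gd = r["g_upper"] - r["g_lower"]
            b1 = gd / np.linalg.norm(gd)
            b2 = last_b2 - (last_b2 @ b1) * b1
            b2 /= np.linalg.norm(b2)
            g_mean = 0.5 * (r["g_lower"] + r["g_upper"])
            seam = g_mean - (g_mean @ b1) * b1 - (g_mean @ b2) * b2
            step = CompositeStep(
                (gap / np.linalg.norm(gd)) * b1, seam, None, b1, b2
            )
        gap_ok = abs(gap) <= gap_tol
        grad_ok = np.linalg.norm(step.seam_component) <= grad_tol
        if gap_ok and grad_ok:
            break
        # gap-closing Newton move(s)
        if not gap_ok:
            gd_norm = np.linalg.norm(r["g_upper"] - r["g_lower"])
            x = x - ((gap - gap_target) / gd_norm) * step.b1
            if np.linalg.norm(step.gap_component) > 10 * step_tol:
                continue  # re-evaluate before attempting a seam move
            r = ev(x, need_grad=True, need_nac=False)
            gap = r["e_upper"] - r["e_lower"]
            mean = 0.5 * (r["e_upper"] + r["e_lower"])
            gd = r["g_upper"] - r["g_lower"]
            b1 = gd / np.linalg.norm(gd)
            b2 = step.b2 - (step.b2 @ b1) * b1
            b2 /= np.linalg.norm(b2)
            g_mean = 0.5 * (r["g_lower"] + r["g_upper"])
            seam = g_mean - (g_mean @ b1) * b1 - (g_mean @ b2) * b2
        else:
            seam = step.seam_component
        # backtracking seam descent on the mean energy
        d = -seam
        d_norm = np.linalg.norm(d)
        if d_norm < 1e-14:
            continue
        t = seam_scale
        accepted = False
        for _ in range(30):
            r_try = ev(x + t * d)
            mean_try = 0.5 * (r_try["e_upper"] + r_try["e_lower"])
            if mean_try <= mean - 1e-4 * t * d_norm**2:
                x = x + t * d
                accepted = True
                seam_scale = min(t * 2.0, 4.0)
                break
            t *= 0.5
        if not accepted:
            seam_scale = max(seam_scale * 0.5, 1e-6)
            step_ok = True  # seam step stalled at numerical precision
    r = ev(x, need_grad=False, need_nac=False)
    gap = r["e_upper"] - r["e_lower"]
    return OptState(
        geometry=x.reshape(-1, 3),
        energies=r["energies"],
        gap=gap,
        iterations=it,
        converged=gap_ok and grad_ok,
        method="projected",
        gap_converged=gap_ok,
        grad_converged=grad_ok,
        step_converged=step_ok,
        history=history,
    )


def optimize_meci(
    interface: Interface,
    method: str,
    start_geometry,
    cfg: PenaltyConfig | None = None,
    **kwargs,
) -> OptState:
    """Run a MECI optimization: ``penalty``, ``projected`` or ``two-stage``.

    ``two-stage`` follows the standard protocol: an approximate penalty
    optimization first, then the projected-gradient method from its final
    geometry to close the residual gap.  The returned state carries the
    stage states in ``history['stages']``.
    """
    cfg = cfg or PenaltyConfig()
    pair = (cfg.state_lower, cfg.state_upper)
    if method == "penalty":
        return penalty_optimize(interface, start_geometry, cfg, **kwargs)
    if method == "projected":
        return projected_optimize(interface, start_geometry, pair, **kwargs)
    if method == "two-stage":
        stage1 = penalty_optimize(interface, start_geometry, cfg)
        stage2 = projected_optimize(interface, stage1.geometry, pair, **kwargs)
        stage2.history["stages"] = [stage1, stage2]
        stage2.method = "two-stage"
        return stage2
    raise ValueError(f"unknown method {method!r}")
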