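"""Economic real-time optimization by modifier adaptation (MAWQA).

The plant is driven to its economically optimal feed flows although the
available process model is wrong (structural and parametric mismatch).
Instead of re-identifying model parameters, the *optimization problem*
is corrected: a zeroth-order bias and first-order gradient modifiers
are added to the model profit so that, at convergence, the first-order
optimality conditions of the true plant are satisfied.  Plant gradients
are never measured directly — finite differences would amplify noise —
but estimated from a quadratic surrogate regressed over the history of
operating points (the "quadratic approximation" in MAWQA), with
poisedness screening and probing moves when the geometry is degenerate.

The profit of the lithiation reactor is

    Profit = w4 * M_LiNDPA * c_LiNDPA / rho_mix * sum(u) - sum(w_i u_i)

with u = (aniline, LiHMDS, o-FNB) feed flows in kg/h, c_LiNDPA the
measured product concentration in mol/m^3, and cost weights
w = (10000, 25000, 12000, 450000) per kg.  The stoichiometric
constraint n_LiHMDS >= 2 n_aniline (molar feed ratio) is enforced
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from . import plant_simulator as ps

__all__ = [
    "ProfitParams",
    "OperatingPoint",
    "ModifierState",
    "MAWQAConfig",
    "GradientEstimate",
    "profit",
    "feed_molar_ratio",
    "nominal_optimize",
    "estimate_gradient_quadratic",
    "run_mawqa",
    "grid_optimum",
    "simulated_plant",
    "nominal_model",
]


@dataclass
class ProfitParams:
    """Economic weights of the profit function (cost units per kg)."""

    w: tuple[float, float, float, float] = (10000.0, 25000.0, 12000.0, 450000.0)
    M_LiNDPA: float = 0.2202      # kg/mol, C12H9LiN2O2
    rho_mixture: float = 900.0    # kg/m^3
    #: assumed feed concentrations (mol/L) for the molar-ratio constraint
    feed_conc: dict[str, float] = field(default_factory=lambda: {
        "aniline": 0.96, "LiHMDS": 1.10, "oFNB": 0.63})

    def __post_init__(self) -> None:
        if any(wi <= 0 for wi in self.w) or self.rho_mixture <= 0:
            raise ValueError("weights and rho_mixture must be positive")


@dataclass
class OperatingPoint:
    """One visited operating point of the iterative optimization."""

    u: np.ndarray                 # (aniline, LiHMDS, oFNB) kg/h
    c_LiNDPA: float               # mol/m^3, measured
    profit_plant: float
    profit_model: float
    iteration: int
    phase: str = "iterate"        # "probe" | "iterate"


@dataclass
class ModifierState:
    """Bias and gradient correction terms of the modified problem."""

    epsilon: float = 0.0
    lam: np.ndarray = field(default_factory=lambda: np.zeros(3))
    history: list[OperatingPoint] = field(default_factory=list)


def profit(u: np.ndarray, c_LiNDPA: float, pp: ProfitParams | None = None
           ) -> float:
    """Profit in cost units per hour; homogeneous of degree 1 in u."""
    pp = pp or ProfitParams()
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("feed flows must be non-negative")
    revenue = pp.w[3] * pp.M_LiNDPA * c_LiNDPA / pp.rho_mixture * float(u.sum())
    cost = float(pp.w[0] * u[0] + pp.w[1] * u[1] + pp.w[2] * u[2])
    return revenue - cost


def feed_molar_ratio(u: np.ndarray, pp: ProfitParams | None = None,
                     densities: dict[str, float] | None = None) -> float:
    """Molar LiHMDS:aniline feed ratio from mass flows and the
    configured feed concentrations/densities."""
    pp = pp or ProfitParams()
    d = densities or {"aniline": 0.90, "LiHMDS": 0.90}
    n_an = u[0] / d["aniline"] * pp.feed_conc["aniline"]
    n_li = u[1] / d["LiHMDS"] * pp.feed_conc["LiHMDS"]
    return float(n_li / n_an) if n_an > 0 else np.inf


@dataclass
class MAWQAConfig:
    """Algorithmic defaults of the MAWQA loop.

    Probe step 5% of u0 per axis, initial trust radius 10% of ||u0||,
    halved whenever a move loses measured profit; convergence when the
    input move falls below ``tol`` kg/h.
    """

    max_iter: int = 30
    tol: float = 1e-3                       # kg/h
    probe_step_frac: float = 0.05
    trust_radius_frac: float = 0.10
    trust_shrink: float = 0.5
    trust_grow: float = 1.3
    trust_max_frac: float = 0.5
    trust_radius_min: float = 0.02
    bounds: tuple[float, float] = (0.5, 9.0)  # kg/h per feed
    regression_radius_factor: float = 3.0     # x trust radius
    max_history: int = 30
    surprise_frac: float = 0.15               # surrogate-misfit trigger
    disturbance_frac: float = 0.08            # incumbent-profit-shift trigger
    cond_max: float = 1e8
    min_spacing: float = 1e-4


@dataclass
class GradientEstimate:
    """Outcome of the quadratic-surrogate gradient estimation."""

    ok: bool
    gradient: np.ndarray | None = None
    probes: list[np.ndarray] | None = None
    condition: float = np.nan


def _quad_design(U: np.ndarray) -> np.ndarray:
    """Full quadratic design matrix in 3 inputs: 10 columns."""
    u1, u2, u3 = U[:, 0], U[:, 1], U[:, 2]
    return np.column_stack([
        np.ones(len(U)), u1, u2, u3,
        u1 * u1, u2 * u2, u3 * u3, u1 * u2, u1 * u3, u2 * u3])


def estimate_gradient_quadratic(history: list[OperatingPoint],
                                u_current: np.ndarray,
                                regression_radius: float,
                                config: MAWQAConfig | None = None
                                ) -> GradientEstimate:
    """Gradient of the measured profit at ``u_current`` from a full
    quadratic surrogate over nearby history points.

    Requires at least (n+1)(n+2)/2 = 10 well-poised points within the
    regression radius; otherwise returns a need-probe signal with
    suggested axis probing moves.
    """
    config = config or MAWQAConfig()
    u_current = np.asarray(u_current, float)
    pts = [p for p in history
           if np.linalg.norm(p.u - u_current) <= regression_radius]
    pts = pts[-config.max_history:]

    def probes() -> list[np.ndarray]:
        step = max(0.25 * regression_radius, 1e-3)
        out = []
        for k in range(3):
            e = np.zeros(3)
            e[k] = step
            out += [u_current + e, u_current - e]
        out += [u_current + step * np.array(v) / np.sqrt(2)
                for v in ([1, 1, 0], [0, 1, 1], [1, 0, 1])]
        return out

    if len(pts) < 10:
        return GradientEstimate(ok=False, probes=probes())
    U = np.array([p.u for p in pts])
    # minimum pairwise spacing guard against duplicated points
    diff = U[:, None, :] - U[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    if np.min(dist.min(axis=1)) < config.min_spacing:
        U_unique, keep = np.unique(np.round(U, 6), axis=0, return_index=True)
        if len(U_unique) < 10:
            return GradientEstimate(ok=False, probes=probes())
        pts = [pts[i] for i in sorted(keep)]
        U = np.array([p.u for p in pts])
    y = np.array([p.profit_plant for p in pts])
    # scale to the unit ball for conditioning
    scale = max(regression_radius, 1e-9)
    Z = (U - u_current) / scale
    A = _quad_design(Z)
    cond = float(np.linalg.cond(A))
    if cond > config.cond_max:
        return GradientEstimate(ok=False, probes=probes(), condition=cond)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    # gradient at z = 0: the linear coefficients, unscaled
    grad = coef[1:4] / scale
    return GradientEstimate(ok=True, gradient=grad, condition=cond)


def _ratio_constraint(pp: ProfitParams) -> dict:
    """n_LiHMDS - 2 n_aniline >= 0, linear in u (equal feed densities)."""
    c_an = pp.feed_conc["aniline"]
    c_li = pp.feed_conc["LiHMDS"]
    return {"type": "ineq",
            "fun": lambda u: c_li * u[1] - 2.0 * c_an * u[0],
            "jac": lambda u: np.array([-2.0 * c_an, c_li, 0.0])}


def nominal_optimize(model: Callable[[np.ndarray], float],
                     modifiers: ModifierState,
                     u_ref: np.ndarray,
                     pp: ProfitParams | None = None,
                     trust_radius: float = 1.0,
                     bounds: tuple[float, float] = (0.5, 9.0)) -> np.ndarray:
    """Maximize the modifier-corrected model profit inside the trust
    region.

    Objective: profit_model(u) + epsilon + lam . (u - u_ref), subject to
    the molar-ratio constraint, box bounds, and ||u - u_ref|| <=
    trust_radius.  ``model`` maps u -> predicted c_LiNDPA (mol/m^3).
    """
    pp = pp or ProfitParams()
    u_ref = np.asarray(u_ref, float)

    def neg_obj(u: np.ndarray) -> float:
        j = profit(u, model(u), pp)
        return -(j + modifiers.epsilon + float(modifiers.lam @ (u - u_ref)))

    cons = [
        _ratio_constraint(pp),
        {"type": "ineq",
         "fun": lambda u: trust_radius ** 2 - float(((u - u_ref) ** 2).sum()),
         "jac": lambda u: -2.0 * (u - u_ref)},
    ]
    box = [(bounds[0], bounds[1])] * 3
    starts = [u_ref]
    for d in np.eye(3):
        starts.append(np.clip(u_ref + 0.5 * trust_radius * d, *bounds))
        starts.append(np.clip(u_ref - 0.5 * trust_radius * d, *bounds))
    def feasible(u: np.ndarray, tol: float = 1e-6) -> bool:
        return (np.all(u >= bounds[0] - tol) and np.all(u <= bounds[1] + tol)
                and cons[0]["fun"](u) >= -tol
                and cons[1]["fun"](u) >= -tol * max(trust_radius, 1.0))

    best_u, best_v = None, np.inf
    for s in starts:
        res = minimize(neg_obj, s, method="SLSQP", bounds=box,
                       constraints=cons,
                       options={"maxiter": 200, "ftol": 1e-10})
        # SLSQP's soft failures (e.g. linesearch status 8) still carry a
        # usable iterate; judge candidates by value and feasibility
        for cand in (res.x, s):
            if feasible(cand):
                v = neg_obj(cand)
                if v < best_v:
                    best_u, best_v = cand.copy(), v
    if best_u is None:
        # the stoichiometric set may not intersect the trust ball when
        # the loop starts sub-stoichiometric (the plant is commissioned
        # "far from the optimum"); restore: step toward the closest
        # feasible point instead of optimizing
        proj = minimize(lambda u: float(((u - u_ref) ** 2).sum()),
                        np.clip(u_ref, *bounds), method="SLSQP", bounds=box,
                        constraints=[_ratio_constraint(pp)],
                        options={"maxiter": 200, "ftol": 1e-12})
        if not proj.success:
            raise RuntimeError(
                "modified optimization infeasible and restoration failed; "
                f"active constraints: ratio>=2 within bounds {bounds}, "
                f"trust radius {trust_radius}")
        direction = proj.x - u_ref
        dist = float(np.linalg.norm(direction))
        if dist <= trust_radius or dist == 0.0:
            best_u = proj.x
        else:
            best_u = u_ref + direction * (trust_radius / dist)
    # snap into the feasible set against round-off
    u = np.clip(best_u, *bounds)
    return u


def run_mawqa(plant: Callable[[np.ndarray], float],
              model: Callable[[np.ndarray], float],
              u0: np.ndarray,
              pp: ProfitParams | None = None,
              config: MAWQAConfig | None = None,
              disturbance_iteration: int | None = None,
              on_disturbance: Callable[[], None] | None = None
              ) -> list[OperatingPoint]:
    """Iterate modifier adaptation until the input moves converge.

    ``plant`` maps u -> *measured* c_LiNDPA (mol/m^3); ``model`` is the
    nominal prediction.  The loop: probe (initially, or whenever the
    surrogate geometry degenerates), estimate the plant gradient from
    the quadratic surrogate, set the modifiers (bias from the profit
    mismatch, lambda from the gradient mismatch), solve the modified
    problem in a trust region, and move.  A measured profit far off the
    surrogate's prediction (e.g. after an unannounced feed-batch
    change) flushes the history and triggers re-probing, after which
    the scheme re-converges.  ``on_disturbance`` is invoked before
    iteration ``disturbance_iteration`` to mutate the plant closure.
    """
    pp = pp or ProfitParams()
    config = config or MAWQAConfig()
    u0 = np.asarray(u0, float)

    def measure(u: np.ndarray, it: int, phase: str) -> OperatingPoint:
        c = float(plant(u))
        return OperatingPoint(
            u=u.copy(), c_LiNDPA=c,
            profit_plant=profit(u, c, pp),
            profit_model=profit(u, model(u), pp),
            iteration=it, phase=phase)

    def model_gradient(u: np.ndarray, h: float = 1e-4) -> np.ndarray:
        g = np.zeros(3)
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            g[k] = (profit(u + e, model(u + e), pp)
                    - profit(u - e, model(u - e), pp)) / (2 * h)
        return g

    trust0 = config.trust_radius_frac * float(np.linalg.norm(u0))
    trust_max = config.trust_max_frac * float(np.linalg.norm(u0))
    trust = trust0
    traj: list[OperatingPoint] = []
    mods = ModifierState()

    def probe_around(u: np.ndarray, it: int, step: float) -> None:
        """Axis and diagonal probing moves of the given step size."""
        for k in range(3):
            for sgn in (+1.0, -1.0):
                e = np.zeros(3)
                e[k] = sgn * step
                up = np.clip(u + e, *config.bounds)
                traj.append(measure(up, it, "probe"))
                mods.history.append(traj[-1])
        for v in ([1, 1, 0], [0, 1, 1], [1, 0, 1]):
            up = np.clip(u + step * np.array(v, float) / np.sqrt(2),
                         *config.bounds)
            traj.append(measure(up, it, "probe"))
            mods.history.append(traj[-1])

    def local_gradient(u: np.ndarray, radius: float, it: int
                       ) -> GradientEstimate:
        """Surrogate gradient near u; probes locally if the geometry of
        the available history cannot support a quadratic."""
        est = estimate_gradient_quadratic(mods.history, u, radius, config)
        if not est.ok:
            probe_around(u, it, step=0.35 * radius)
            est = estimate_gradient_quadratic(mods.history, u, radius, config)
        return est

    u_k = u0.copy()
    current = measure(u_k, 0, "iterate")
    traj.append(current)
    mods.history.append(current)
    probe_around(u_k, 0,
                 step=config.probe_step_frac * float(np.linalg.norm(u0)))

    for it in range(1, config.max_iter + 1):
        if disturbance_iteration is not None and it == disturbance_iteration \
                and on_disturbance is not None:
            on_disturbance()

        radius = config.regression_radius_factor * max(trust,
                                                       config.trust_radius_min)
        est = local_gradient(u_k, radius, it)
        g_plant = est.gradient if est.ok else np.zeros(3)
        mods.epsilon = current.profit_plant - current.profit_model
        mods.lam = g_plant - model_gradient(u_k)

        u_next = nominal_optimize(model, mods, u_k, pp,
                                  trust_radius=max(trust, config.trust_radius_min),
                                  bounds=config.bounds)
        step_len = float(np.linalg.norm(u_next - u_k))
        if step_len < config.tol and est.ok:
            # stationary within the trust region: converged only once
            # the region has been refined, else keep shrinking
            if trust <= 2.0 * config.trust_radius_min:
                break
            trust = max(trust * config.trust_shrink, config.trust_radius_min)
            continue
        nxt = measure(u_next, it, "iterate")
        traj.append(nxt)
        mods.history.append(nxt)
        if len(mods.history) > 4 * config.max_history:
            del mods.history[: len(mods.history) - 4 * config.max_history]

        # a measurement far off the modifier-corrected prediction is
        # either surrogate error (far step) or an unannounced plant
        # disturbance; re-measuring the incumbent discriminates: only a
        # disturbance changes the profit at an unchanged operating point
        expected = (nxt.profit_model + mods.epsilon
                    + float(mods.lam @ (u_next - u_k)))
        scale = max(abs(nxt.profit_plant), abs(current.profit_plant), 1.0)
        if abs(nxt.profit_plant - expected) > config.surprise_frac * scale:
            recheck = measure(u_k, it, "probe")
            traj.append(recheck)
            if abs(recheck.profit_plant - current.profit_plant) \
                    > config.disturbance_frac * scale:
                # plant moved under us: restart the surrogate surface
                current = recheck
                mods.history = [recheck, nxt]
                trust = trust0
                probe_around(u_k, it,
                             step=config.probe_step_frac
                             * float(np.linalg.norm(u_k)))
                continue
            mods.history.append(recheck)
            if nxt.profit_plant <= current.profit_plant:
                trust = max(trust * config.trust_shrink,
                            config.trust_radius_min)
                continue  # surrogate error on a losing move: reject

        improvement = nxt.profit_plant - current.profit_plant
        if improvement > 1e-6 * scale:
            trust = min(trust * config.trust_grow, trust_max)
            current, u_k = nxt, u_next
        else:
            # failed or null move: stay, refine locally
            trust = max(trust * config.trust_shrink, config.trust_radius_min)
            if abs(improvement) <= 1e-6 * scale:
                current, u_k = nxt, u_next  # flat: accept without growing

    # the plant is left running at the incumbent: if the last evaluated
    # move was rejected, move back before handing over
    if not np.allclose(traj[-1].u, u_k):
        traj.append(measure(u_k, traj[-1].iteration, "iterate"))
    return traj


# ---------------------------------------------------------------------------
# simulator glue and the brute-force oracle


def simulated_plant(params: ps.PlantParams | None = None,
                    noise_sd: float = 0.0,
                    seed: int | None = None,
                    feed_concs: dict[str, float] | None = None
                    ) -> Callable[[np.ndarray], float]:
    """Plant closure: u -> measured c_LiNDPA in mol/m^3.

    ``noise_sd`` (mol/m^3) emulates NMR quantification noise; 0 gives
    the noiseless oracle mode.  ``feed_concs`` overrides the true feed
    concentrations (e.g. after a batch change) without telling the
    optimizer.
    """
    params = params or ps.TRUE_PLANT_PARAMS
    rng = np.random.default_rng(seed)
    state = {"concs": dict(feed_concs or {})}

    def fun(u: np.ndarray) -> float:
        feeds = ps.default_feeds((u[0], u[1], u[2]), state["concs"])
        c = ps.true_plant(feeds, params).concentrations["LiNDPA"]
        if noise_sd > 0:
            c = max(c + rng.normal(0.0, noise_sd), 0.0)
        return float(c)

    fun.set_feed_concs = lambda concs: state["concs"].update(concs)  # type: ignore[attr-defined]
    return fun


def nominal_model(params: ps.PlantParams | None = None
                  ) -> Callable[[np.ndarray], float]:
    """Nominal (mismatched) model closure: u -> predicted c_LiNDPA."""
    params = params or ps.PlantParams()

    def fun(u: np.ndarray) -> float:
        feeds = ps.default_feeds((u[0], u[1], u[2]))
        return float(ps.reactor_steady_state(feeds, params)
                     .concentrations["LiNDPA"])

    return fun


def grid_optimum(plant: Callable[[np.ndarray], float],
                 pp: ProfitParams | None = None,
                 bounds: tuple[float, float] = (0.5, 9.0),
                 n: int = 51) -> tuple[np.ndarray, float]:
    """Brute-force oracle: best feasible profit on an n^3 grid over u."""
    pp = pp or ProfitParams()
    grid = np.linspace(bounds[0], bounds[1], n)
    c_an = pp.feed_conc["aniline"]
    c_li = pp.feed_conc["LiHMDS"]
    best_u, best_p = None, -np.inf
    for u1 in grid:
        for u2 in grid:
            if c_li * u2 < 2.0 * c_an * u1:
                continue  # stoichiometric constraint
            for u3 in grid:
                u = np.array([u1, u2, u3])
                p = profit(u, plant(u), pp)
                if p > best_p:
                    best_u, best_p = u, p
    return best_u, float(best_p)
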