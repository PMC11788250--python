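"""Joint weighted least-squares estimation of all five organs at once.

A single parameter vector couples the organs through the shared arterial
corrections (partial-volume scale gamma, dispersion tau) while each organ
contributes its own delay, fractional blood volume and rate constants.
The default free-parameter enumeration has 22 entries:

    gamma, tau,
    delay x5, vb x5,
    K1 (heart, lungs, liver; their k2 is tied to K1 via the fixed Vd),
    K1, k2, k3, k4 (kidneys),
    K1, k2, k3 (femur).

Fitting minimizes counting-statistics-weighted residuals with a bounded
trust-region least-squares solver, restarted from a centered Latin
hypercube over the bounds.  The restart ensemble is kept in full: the
minimum-chi2 member is the point estimate, a kernel-density mode summarizes
the most probable region, parameter error bars are read off where the
reduced chi-square rises by 1, and the near-optimal subset feeds the
correlation/identifiability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .expsum import ExpSum
from .input_function import (
    AIFCorrections,
    IDIFFit,
    InputFunctionModel,
    counting_weights,
    corrected_input,
)
from .organs import ORGANS, ORGAN_IDS, KineticParams, solve_tissue, tissue_curve
from .schedule import FrameSchedule

__all__ = [
    "ParamSpec",
    "JointParams",
    "FitResult",
    "MultistartEnsemble",
    "ErrorBar",
    "MultiOrganKineticModel",
    "build_param_spec",
    "objective",
    "fit_once",
    "lhs_starts",
    "multistart",
    "score_fit",
    "error_bars",
    "noise_sigma_from_data",
    "DEFAULT_BOUNDS",
    "DEFAULT_NOISE_SC",
]

#: Default per-organ noise scaling factors Sc: residual weights in the fit
#: and, via :mod:`mokin.synthetic`, the noise level of simulated data.
DEFAULT_NOISE_SC: dict[str, float] = {
    "heart": 0.5,
    "lungs": 0.5,
    "liver": 0.5,
    "kidneys": 0.5,
    "femur": 0.5,
    "idif": 1.5,
}

#: Bounds informed by the fitted ranges and physiology.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "gamma": (0.1, 3.0),
    "tau": (1e-3, 2.0),
    "delay": (-0.5, 1.0),
    "vb": (0.0, 1.0),
    "K1": (0.0, 10.0),
    "k": (0.0, 10.0),
}


@dataclass(frozen=True)
class ParamSpec:
    """Ordered table of free parameters with bounds."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    @property
    def n_free(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


def build_param_spec(
    bounds: dict[str, tuple[float, float]] | None = None,
    free_heart_k2: bool = False,
) -> ParamSpec:
    """Enumerate the free parameters (22 by default).

    ``free_heart_k2=True`` releases the heart's efflux rate from the Vd tie,
    adding a 23rd free parameter.
    """
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    names: list[str] = ["gamma", "tau"]
    los: list[float] = [b["gamma"][0], b["tau"][0]]
    his: list[float] = [b["gamma"][1], b["tau"][1]]

    def add(name: str, kind: str) -> None:
        names.append(name)
        los.append(b[kind][0])
        his.append(b[kind][1])

    for organ in ORGAN_IDS:
        add(f"delay_{organ}", "delay")
    for organ in ORGAN_IDS:
        add(f"vb_{organ}", "vb")
    for organ in ("heart", "lungs", "liver"):
        add(f"K1_{organ}", "K1")
    if free_heart_k2:
        add("k2_heart", "k")
    for name in ("K1_kidneys", "k2_kidneys", "k3_kidneys", "k4_kidneys"):
        add(name, "K1" if name.startswith("K1") else "k")
    for name in ("K1_femur", "k2_femur", "k3_femur"):
        add(name, "K1" if name.startswith("K1") else "k")
    return ParamSpec(tuple(names), np.array(los), np.array(his))


@dataclass
class JointParams:
    """A complete named free-parameter assignment for the joint model."""

    spec: ParamSpec
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(self.spec.names) - set(self.values)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")

    @classmethod
    def from_vector(cls, spec: ParamSpec, x: np.ndarray) -> "JointParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (spec.n_free,):
            raise ValueError("vector length does not match the parameter spec")
        return cls(spec, dict(zip(spec.names, x)))

    def to_vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in self.spec.names])

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def corrections(self) -> AIFCorrections:
        return AIFCorrections(
            gamma=self.values["gamma"],
            tau=self.values["tau"],
            delays={o: self.values[f"delay_{o}"] for o in ORGAN_IDS},
        )

    def kinetics(self, organ: str) -> KineticParams:
        v = self.values
        model = ORGANS[organ]
        k1 = v[f"K1_{organ}"]
        if model.vd_constraint is not None:
            k2 = v.get(f"k2_{organ}", k1 / model.vd_constraint)
        else:
            k2 = v[f"k2_{organ}"]
        return KineticParams(
            K1=k1,
            k2=k2,
            k3=v.get(f"k3_{organ}", 0.0),
            k4=v.get(f"k4_{organ}", 0.0),
            vb=v[f"vb_{organ}"],
            delay=v[f"delay_{organ}"],
        )


@dataclass
class FitResult:
    params: JointParams
    chi2_nu: float
    per_organ_chi2: dict[str, float]
    converged: bool
    n_obs: int
    n_free: int
    cost: float = np.nan
    nfev: int = 0

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_free


@dataclass
class MultistartEnsemble:
    results: list[FitResult]
    best: FitResult
    mode: JointParams
    mode_index: int

    @property
    def chi2_nu(self) -> np.ndarray:
        return np.array([r.chi2_nu for r in self.results])

    def param_matrix(self, converged_only: bool = False) -> np.ndarray:
        rows = [
            r.params.to_vector()
            for r in self.results
            if r.converged or not converged_only
        ]
        return np.array(rows)


@dataclass(frozen=True)
class ErrorBar:
    minus: float
    plus: float
    censored_minus: bool = False
    censored_plus: bool = False

    @property
    def half_width(self) -> float:
        return 0.5 * (self.minus + self.plus)

    @property
    def censored(self) -> bool:
        return self.censored_minus or self.censored_plus


# ----------------------------------------------------------------------
# forward model and objective


def model_frame_averages(
    params: JointParams,
    idif_curve: ExpSum,
    schedule: FrameSchedule,
    gamma_mode: str = "divide",
) -> dict[str, np.ndarray]:
    """Frame-averaged model TAC for each organ at the given parameters."""
    corr = params.corrections()
    # gamma scale and dispersion are shared; only the delay differs per organ
    base = corrected_input(idif_curve, replace(corr, delays={}), "", gamma_mode)
    out: dict[str, np.ndarray] = {}
    for organ in ORGAN_IDS:
        ca = base.shift(corr.delays[organ])
        ct = tissue_curve(ORGANS[organ], params.kinetics(organ), ca)
        out[organ] = ct.frame_averages(schedule.starts_min, schedule.durations_min)
    return out


class ObjectiveContext:
    """Weighted-residual evaluation with a structured Jacobian.

    Only gamma and tau couple all organs; every other free parameter touches
    a single organ's residual block, so the Jacobian is assembled from
    per-organ forward evaluations instead of full-model differences.  Three
    parameter families have exact columns at no extra model cost: gamma
    (the whole model is proportional to 1/gamma, or gamma), the blood
    fractions vb (the model is affine in vb) and the K1 of organs without a
    Vd tie (their parenchymal response is linear in K1).  The forward state
    at the current iterate is cached, since the solver evaluates residual
    and Jacobian at the same point.
    """

    def __init__(
        self,
        data: dict[str, np.ndarray],
        idif_curve: ExpSum,
        schedule: FrameSchedule,
        sigma: dict[str, np.ndarray],
        spec: ParamSpec,
        gamma_mode: str = "divide",
    ) -> None:
        for o in ORGAN_IDS:
            if np.any(np.asarray(sigma[o]) <= 0):
                raise ValueError(f"non-positive noise sigma for {o}")
        self.data = data
        self.idif_curve = idif_curve
        self.schedule = schedule
        self.sigma = sigma
        self.spec = spec
        self.gamma_mode = gamma_mode
        self.n_frames = schedule.n_frames
        self._bounds_min = np.concatenate(
            [schedule.starts_min, [schedule.total_s / 60.0]]
        )
        self._durs_min = schedule.durations_min
        # which organ block each parameter touches (None = all organs)
        self._scope: list[str | None] = []
        for name in spec.names:
            if name in ("gamma", "tau"):
                self._scope.append(None)
            else:
                self._scope.append(name.rsplit("_", 1)[1])
        self._cache_key: bytes | None = None
        self._cache: dict | None = None

    # -- forward pieces -------------------------------------------------
    def _base(self, params: JointParams) -> ExpSum:
        corr = params.corrections()
        return corrected_input(
            self.idif_curve, replace(corr, delays={}), "", self.gamma_mode
        )

    def _avg(self, curve: ExpSum) -> np.ndarray:
        return curve._averages_contiguous(self._bounds_min, self._durs_min)

    def _organ_pieces(
        self, params: JointParams, organ: str, base: ExpSum
    ) -> tuple[np.ndarray, np.ndarray]:
        """(parenchyma average, vascular average) for one organ."""
        kin = params.kinetics(organ)
        ca = base.shift(kin.delay)
        c1, c2 = solve_tissue(ORGANS[organ], kin, ca)
        paren = c1 if c2 is None else c1 + c2
        return self._avg(paren), self._avg(ca)

    def _organ_model(self, params: JointParams, organ: str, base: ExpSum) -> np.ndarray:
        paren, vasc = self._organ_pieces(params, organ, base)
        vb = params[f"vb_{organ}"]
        return (1.0 - vb) * paren + vb * vasc

    def _state(self, x: np.ndarray) -> dict:
        key = x.tobytes()
        if key != self._cache_key:
            params = JointParams.from_vector(self.spec, x)
            base = self._base(params)
            pieces = {
                o: self._organ_pieces(params, o, base) for o in ORGAN_IDS
            }
            model = {
                o: (1.0 - params[f"vb_{o}"]) * pieces[o][0]
                + params[f"vb_{o}"] * pieces[o][1]
                for o in ORGAN_IDS
            }
            resid = {
                o: (self.data[o] - model[o]) / self.sigma[o] for o in ORGAN_IDS
            }
            self._cache_key = key
            self._cache = {
                "params": params,
                "base": base,
                "pieces": pieces,
                "model": model,
                "resid": resid,
            }
        return self._cache

    def residual(self, x: np.ndarray, *_args) -> np.ndarray:
        resid = self._state(x)["resid"]
        return np.concatenate([resid[o] for o in ORGAN_IDS])

    # -- jacobian ---------------------------------------------------------
    def jacobian(self, x: np.ndarray, *_args) -> np.ndarray:
        spec = self.spec
        state = self._state(x)
        params, base = state["params"], state["base"]
        pieces, model = state["pieces"], state["model"]
        m = self.n_frames
        jac = np.zeros((m * len(ORGAN_IDS), spec.n_free))
        rows = {o: slice(i * m, (i + 1) * m) for i, o in enumerate(ORGAN_IDS)}
        rel = np.sqrt(np.finfo(float).eps)
        gamma_sign = -1.0 if self.gamma_mode == "divide" else 1.0
        for j, name in enumerate(spec.names):
            # exact columns: residual = (O - C)/sigma, so d(res) = -dC/sigma
            if name == "gamma":
                g = x[j]
                for o in ORGAN_IDS:
                    jac[rows[o], j] = -gamma_sign * model[o] / (g * self.sigma[o])
                continue
            if name.startswith("vb_"):
                o = self._scope[j]
                paren, vasc = pieces[o]
                jac[rows[o], j] = -(vasc - paren) / self.sigma[o]
                continue
            if name in ("K1_kidneys", "K1_femur") and x[j] > 1e-12:
                o = self._scope[j]
                paren, _ = pieces[o]
                vb = params[f"vb_{o}"]
                jac[rows[o], j] = -(1.0 - vb) * paren / (x[j] * self.sigma[o])
                continue
            # finite differences for the rest
            h = rel * max(abs(x[j]), 1e-3 * (spec.upper[j] - spec.lower[j]))
            if x[j] + h > spec.upper[j]:
                h = -h
            xj = x.copy()
            xj[j] += h
            pj = JointParams.from_vector(spec, xj)
            scope = self._scope[j]
            if scope is None:
                base_j = self._base(pj)
                for o in ORGAN_IDS:
                    dm = self._organ_model(pj, o, base_j) - model[o]
                    jac[rows[o], j] = -dm / (h * self.sigma[o])
            else:
                dm = self._organ_model(pj, scope, base) - model[scope]
                jac[rows[scope], j] = -dm / (h * self.sigma[scope])
        return jac


def noise_sigma_from_data(
    data: dict[str, np.ndarray],
    schedule: FrameSchedule,
    sc: dict[str, float],
) -> dict[str, np.ndarray]:
    """Per-frame noise scale from the observed activities (clipped positive)."""
    return {o: sc[o] * counting_weights(data[o], schedule) for o in data}


def objective(
    x: np.ndarray | JointParams,
    data: dict[str, np.ndarray],
    idif_curve: ExpSum,
    schedule: FrameSchedule,
    sigma: dict[str, np.ndarray],
    spec: ParamSpec | None = None,
    gamma_mode: str = "divide",
) -> np.ndarray:
    """Stacked weighted residuals ``(O - C) / sigma`` over organs and frames."""
    params = (
        x if isinstance(x, JointParams) else JointParams.from_vector(spec, x)
    )
    for o in ORGAN_IDS:
        if np.any(sigma[o] <= 0):
            raise ValueError(f"non-positive noise sigma for {o}")
    model = model_frame_averages(params, idif_curve, schedule, gamma_mode)
    return np.concatenate(
        [(data[o] - model[o]) / sigma[o] for o in ORGAN_IDS]
    )


def score_fit(
    params: JointParams,
    data: dict[str, np.ndarray],
    idif_curve: ExpSum,
    schedule: FrameSchedule,
    sigma: dict[str, np.ndarray],
    n_free: int | None = None,
    gamma_mode: str = "divide",
) -> tuple[float, dict[str, float]]:
    """Reduced chi-square and per-organ contributions (summing to the total).

    ``nu = N_obs - n_free``; each organ's contribution is its weighted sum of
    squares divided by the same ``nu``, so the contributions add up to the
    total reduced chi-square.
    """
    n_free = params.spec.n_free if n_free is None else n_free
    n_obs = schedule.n_frames * len(ORGAN_IDS)
    nu = n_obs - n_free
    if nu <= 0:
        raise ValueError(
            f"non-positive degrees of freedom (N={n_obs}, free={n_free})"
        )
    model = model_frame_averages(params, idif_curve, schedule, gamma_mode)
    per_organ = {
        o: float(np.sum(((data[o] - model[o]) / sigma[o]) ** 2)) / nu
        for o in ORGAN_IDS
    }
    return sum(per_organ.values()), per_organ


def fit_once(
    start: JointParams | np.ndarray,
    data: dict[str, np.ndarray],
    idif_curve: ExpSum,
    schedule: FrameSchedule,
    sigma: dict[str, np.ndarray],
    spec: ParamSpec | None = None,
    gamma_mode: str = "divide",
    max_nfev: int | None = 2000,
    xtol: float = 1e-10,
) -> FitResult:
    """One bounded least-squares descent from ``start``; never raises on a
    poor start — non-convergence is flagged and the best iterate kept."""
    if isinstance(start, JointParams):
        spec = start.spec
        x0 = start.to_vector()
    else:
        if spec is None:
            raise ValueError("spec required when start is a bare vector")
        x0 = np.asarray(start, dtype=float)
    x0 = spec.clip(x0)
    ctx = ObjectiveContext(data, idif_curve, schedule, sigma, spec, gamma_mode)
    res = least_squares(
        ctx.residual,
        x0,
        jac=ctx.jacobian,
        bounds=(spec.lower, spec.upper),
        method="trf",
        x_scale="jac",
        xtol=xtol,
        ftol=xtol,
        gtol=None,
        max_nfev=max_nfev,
    )
    params = JointParams.from_vector(spec, res.x)
    chi2_nu, per_organ = score_fit(
        params, data, idif_curve, schedule, sigma, gamma_mode=gamma_mode
    )
    return FitResult(
        params=params,
        chi2_nu=chi2_nu,
        per_organ_chi2=per_organ,
        converged=bool(res.status > 0),
        n_obs=schedule.n_frames * len(ORGAN_IDS),
        n_free=spec.n_free,
        cost=float(res.cost),
        nfev=int(res.nfev),
    )


def lhs_starts(spec: ParamSpec, n_starts: int, seed: int) -> np.ndarray:
    """Centered Latin-hypercube start points over the bounded box."""
    sampler = qmc.LatinHypercube(d=spec.n_free, scramble=False, seed=seed)
    unit = sampler.random(n_starts)
    return spec.lower + unit * (spec.upper - spec.lower)


def multistart(
    data: dict[str, np.ndarray],
    idif_curve: ExpSum,
    schedule: FrameSchedule,
    sigma: dict[str, np.ndarray],
    spec: ParamSpec,
    n_starts: int = 5000,
    seed: int = 0,
    gamma_mode: str = "divide",
    max_nfev: int = 150,
    polish: bool = True,
    polish_max_nfev: int = 4000,
) -> MultistartEnsemble:
    """Restarted joint fit with KDE mode selection.

    Every restart's result is retained (including non-converged ones); the
    KDE mode is chosen among converged fits, and the reported best fit is
    the minimum-chi2 member, optionally re-polished with a generous
    evaluation budget.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    starts = lhs_starts(spec, n_starts, seed)
    results = [
        fit_once(
            x0, data, idif_curve, schedule, sigma,
            spec=spec, gamma_mode=gamma_mode, max_nfev=max_nfev, xtol=1e-8,
        )
        for x0 in starts
    ]
    converged = [r for r in results if r.converged and np.isfinite(r.chi2_nu)]
    if not converged:
        raise RuntimeError("no restart converged; increase max_nfev or n_starts")
    best = min(results, key=lambda r: r.chi2_nu)
    if polish:
        polished = fit_once(
            best.params, data, idif_curve, schedule, sigma,
            gamma_mode=gamma_mode, max_nfev=polish_max_nfev, xtol=1e-12,
        )
        if polished.chi2_nu <= best.chi2_nu:
            best = polished
    mode_idx = kde_mode_index(np.array([r.params.to_vector() for r in converged]))
    mode = converged[mode_idx].params
    global_mode_index = next(
        i for i, r in enumerate(results) if r is converged[mode_idx]
    )
    return MultistartEnsemble(results, best, mode, global_mode_index)


def kde_mode_index(matrix: np.ndarray) -> int:
    """Index of the highest-density member under a Gaussian product KDE.

    Parameters are standardized per dimension (zero-variance dimensions are
    dropped); the bandwidth follows Scott's rule.  The mode is the ensemble
    member with the highest estimated density — an actual fit result, not an
    off-grid argmax — for reproducibility.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n == 1:
        return 0
    sd = matrix.std(axis=0)
    keep = sd > 0
    if not np.any(keep):
        return 0
    z = (matrix[:, keep] - matrix[:, keep].mean(axis=0)) / sd[keep]
    d = z.shape[1]
    h = n ** (-1.0 / (d + 4))  # Scott's rule on standardized coordinates
    sq = np.sum((z[:, None, :] - z[None, :, :]) ** 2, axis=-1)
    dens = np.exp(-sq / (2.0 * h * h)).sum(axis=1)
    return int(np.argmax(dens))


# ----------------------------------------------------------------------
# Delta-chi2 error bars


def error_bars(
    best: FitResult,
    data: dict[str, np.ndarray],
    idif_curve: ExpSum,
    schedule: FrameSchedule,
    sigma: dict[str, np.ndarray],
    gamma_mode: str = "divide",
    delta: float = 1.0,
    profile: bool = False,
    profile_max_nfev: int = 60,
) -> dict[str, ErrorBar]:
    """Per-parameter excursion until the reduced chi-square rises by ``delta``.

    Each parameter is scanned away from the optimum in both directions;
    by default the other parameters stay fixed (``profile=True`` re-optimizes
    them at every trial point).  If a bound is reached before the chi-square
    target, the excursion is bound-censored.
    """
    spec = best.params.spec
    x_hat = best.params.to_vector()
    target = best.chi2_nu + delta

    def chi2_at(i: int, theta: float) -> float:
        x = x_hat.copy()
        x[i] = theta
        if profile:
            free = [j for j in range(spec.n_free) if j != i]
            sub_res = least_squares(
                lambda xf: objective(
                    _insert(x, free, xf), data, idif_curve, schedule, sigma,
                    spec=spec, gamma_mode=gamma_mode,
                ),
                x[free],
                bounds=(spec.lower[free], spec.upper[free]),
                method="trf",
                max_nfev=profile_max_nfev,
            )
            x = _insert(x, free, sub_res.x)
        chi2_nu, _ = score_fit(
            JointParams.from_vector(spec, x), data, idif_curve, schedule,
            sigma, gamma_mode=gamma_mode,
        )
        return chi2_nu

    out: dict[str, ErrorBar] = {}
    for i, name in enumerate(spec.names):
        scale = max(abs(x_hat[i]), 1e-3 * (spec.upper[i] - spec.lower[i]))
        excursions: list[float] = []
        censored: list[bool] = []
        for bound in (spec.lower[i], spec.upper[i]):
            if bound == x_hat[i]:
                excursions.append(0.0)
                censored.append(True)
                continue
            if chi2_at(i, bound) < target:
                excursions.append(abs(bound - x_hat[i]))
                censored.append(True)
                continue
            theta = brentq(
                lambda th: chi2_at(i, th) - target,
                min(x_hat[i], bound),
                max(x_hat[i], bound),
                xtol=1e-6 * scale,
            )
            excursions.append(abs(theta - x_hat[i]))
            censored.append(False)
        out[name] = ErrorBar(
            minus=excursions[0],
            plus=excursions[1],
            censored_minus=censored[0],
            censored_plus=censored[1],
        )
    return out


def _insert(x: np.ndarray, idx: list[int], vals: np.ndarray) -> np.ndarray:
    out = x.copy()
    out[idx] = vals
    return out


# ----------------------------------------------------------------------
# estimator facade


class MultiOrganKineticModel(BaseEstimator):
    """Joint five-organ kinetic model fitted to one subject's framed TACs.

    ``fit`` expects a tidy dataset — a DataFrame with columns
    ``frame_start_s, frame_duration_s, heart, lungs, liver, kidneys, femur,
    idif`` (activities in kBq/mL) — smooths the IDIF, then runs the
    restarted joint fit on the selected time scale.

    Parameters
    ----------
    scale : 'short' (first 3 min) or 'long' (full schedule).
    n_starts : number of Latin-hypercube restarts.
    noise_sc : per-organ noise scaling factors Sc for the residual weights
        (defaults to 1 everywhere).
    sigma : optional exact per-organ noise curves, overriding the
        data-derived weights (useful when the noise level is known).
    free_heart_k2 : release the heart k2 from the Vd tie (23rd parameter).
    """

    def __init__(
        self,
        scale: str = "long",
        n_starts: int = 200,
        seed: int = 0,
        bounds: dict[str, tuple[float, float]] | None = None,
        gamma_mode: str = "divide",
        noise_sc: dict[str, float] | None = None,
        idif_n_terms: int = 3,
        idif_n_starts: int = 30,
        max_nfev: int = 150,
        polish: bool = True,
        polish_max_nfev: int = 4000,
        free_heart_k2: bool = False,
    ) -> None:
        self.scale = scale
        self.n_starts = n_starts
        self.seed = seed
        self.bounds = bounds
        self.gamma_mode = gamma_mode
        self.noise_sc = noise_sc
        self.idif_n_terms = idif_n_terms
        self.idif_n_starts = idif_n_starts
        self.max_nfev = max_nfev
        self.polish = polish
        self.polish_max_nfev = polish_max_nfev
        self.free_heart_k2 = free_heart_k2

    # ------------------------------------------------------------------
    def fit(
        self,
        X: pd.DataFrame,
        y: None = None,
        sigma: dict[str, np.ndarray] | None = None,
    ) -> "MultiOrganKineticModel":
        full_schedule, data_full, idif_samples = split_dataset(X)
        schedule = full_schedule.for_scale(self.scale)
        n = schedule.n_frames
        data = {o: data_full[o][:n] for o in ORGAN_IDS}

        idif_est = InputFunctionModel(
            n_terms=self.idif_n_terms,
            n_starts=self.idif_n_starts,
            seed=self.seed,
        ).fit(schedule, idif_samples[:n])
        self.idif_ = idif_est.to_idif_fit()

        sc = self.noise_sc or {o: DEFAULT_NOISE_SC[o] for o in ORGAN_IDS}
        if sigma is None:
            sigma = noise_sigma_from_data(data, schedule, sc)
        else:
            sigma = {o: np.asarray(sigma[o], dtype=float)[:n] for o in ORGAN_IDS}
        self.spec_ = build_param_spec(self.bounds, self.free_heart_k2)
        self.ensemble_ = multistart(
            data,
            self.idif_.model,
            schedule,
            sigma,
            self.spec_,
            n_starts=self.n_starts,
            seed=self.seed,
            gamma_mode=self.gamma_mode,
            max_nfev=self.max_nfev,
            polish=self.polish,
            polish_max_nfev=self.polish_max_nfev,
        )
        self.best_ = self.ensemble_.best
        self.mode_ = self.ensemble_.mode
        self.params_ = self.best_.params
        self.chi2_nu_ = self.best_.chi2_nu
        self.per_organ_chi2_ = self.best_.per_organ_chi2
        self.schedule_ = schedule
        self.data_ = data
        self.sigma_ = sigma
        return self

    def predict(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Model TACs at the fitted parameters on the fit (or given) frames."""
        if X is None:
            schedule = self.schedule_
        else:
            schedule, _, _ = split_dataset(X, require_organs=False)
        model = model_frame_averages(
            self.params_, self.idif_.model, schedule, self.gamma_mode
        )
        out = pd.DataFrame(
            {
                "frame_start_s": schedule.starts_s,
                "frame_duration_s": schedule.durations_s,
            }
        )
        for organ in ORGAN_IDS:
            out[organ] = model[organ]
        return out

    def compute_error_bars(
        self, profile: bool = False
    ) -> dict[str, ErrorBar]:
        self.error_bars_ = error_bars(
            self.best_,
            self.data_,
            self.idif_.model,
            self.schedule_,
            self.sigma_,
            gamma_mode=self.gamma_mode,
            profile=profile,
        )
        return self.error_bars_

    def parameter_table(self) -> pd.DataFrame:
        """One row per free parameter: estimate, error bar, censoring flag."""
        bars = getattr(self, "error_bars_", None) or self.compute_error_bars()
        rows = []
        for name in self.spec_.names:
            bar = bars[name]
            rows.append(
                {
                    "parameter": name,
                    "estimate": self.params_[name],
                    "error_bar": bar.half_width,
                    "bound_censored": bar.censored,
                }
            )
        return pd.DataFrame(rows)


def split_dataset(
    df: pd.DataFrame, require_organs: bool = True
) -> tuple[FrameSchedule, dict[str, np.ndarray], np.ndarray | None]:
    """Split a tidy TAC table into schedule, per-organ arrays and IDIF."""
    for col in ("frame_start_s", "frame_duration_s"):
        if col not in df.columns:
            raise ValueError(f"dataset missing column {col!r}")
    schedule = FrameSchedule(
        df["frame_start_s"].to_numpy(dtype=float),
        df["frame_duration_s"].to_numpy(dtype=float),
    )
    data: dict[str, np.ndarray] = {}
    for organ in ORGAN_IDS:
        if organ in df.columns:
            data[organ] = df[organ].to_numpy(dtype=float)
        elif require_organs:
            raise ValueError(f"dataset missing organ column {organ!r}")
    idif = df["idif"].to_numpy(dtype=float) if "idif" in df.columns else None
    return schedule, data, idif
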