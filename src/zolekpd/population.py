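"""Population (nonlinear mixed-effects) layer for the K-PD model.

Each literature study arm is treated as one "individual": the fitted series
are digitised arm-level mean BMD trajectories, so the exchangeable unit is
the arm, and the random effect captures inter-arm variability.

Model
-----
* Typical structural parameters (KDE, KD, EDK50, K); baseline BMD is supplied
  per arm, not estimated globally.
* One log-normal random effect on EDK50: ``edk50_i = edk50 * exp(eta_i)``,
  ``eta_i ~ N(0, omega2)``.  Random effects on KDE, KD and K are fixed to 0.
* Additive Gaussian residual on absolute BMD with variance ``sigma2``
  (a proportional alternative is available via ``residual="proportional"``).

Estimation maximises a Laplace approximation to the marginal likelihood:
for each arm the conditional -2 log-likelihood is minimised over eta (the
empirical-Bayes mode) and the Gaussian curvature correction is added from a
finite-difference second derivative at the mode.  The outer search runs on
log-transformed parameters with a Nelder-Mead simplex; standard errors come
from a finite-difference Hessian of the objective at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model import KPDParams, Regimen, ResponseKernel

__all__ = [
    "PopulationModel",
    "EventDataset",
    "Arm",
    "FitResult",
    "ShrinkageResult",
    "individual_params",
    "conditional_minus2ll",
    "laplace_marginal_minus2ll",
    "fit",
    "shrinkage",
    "stepwise_covariate_search",
]

_LOG2PI = math.log(2.0 * math.pi)

#: parameter names the outer optimiser can estimate, in packing order
FIT_PARAMS = ("kde", "kd", "edk50", "k_tol", "omega2", "sigma2")


@dataclass(frozen=True)
class PopulationModel:
    """Typical values plus variability for the population K-PD model.

    ``theta.base`` is a nominal placeholder; every prediction substitutes the
    arm's own baseline (see :func:`individual_params`).
    """

    theta: KPDParams
    omega2_edk50: float
    sigma2: float
    residual: str = "additive"

    def __post_init__(self) -> None:
        if self.omega2_edk50 < 0:
            raise ValueError("omega2_edk50 must be >= 0")
        # sigma2 = 0 is allowed for noise-free simulation; likelihoods need > 0
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.residual not in ("additive", "proportional"):
            raise ValueError("residual must be 'additive' or 'proportional'")

    def replace(self, **kw) -> "PopulationModel":
        return replace(self, **kw)


def individual_params(pop: PopulationModel, eta: float, base: float) -> KPDParams:
    """Arm-level parameters: EDK50 scaled by exp(eta), baseline set per arm."""
    if base <= 0:
        raise ValueError("base must be > 0")
    return pop.theta.replace(edk50=pop.theta.edk50 * math.exp(eta), base=base)


@dataclass
class Arm:
    """Observation and dosing records of one study arm (one NONMEM ID)."""

    id: str
    regimen: Regimen
    obs_times: np.ndarray
    dv: np.ndarray
    base: float
    n_subjects: int = 1
    _kernel: ResponseKernel | None = field(default=None, repr=False, compare=False)

    @property
    def kernel(self) -> ResponseKernel:
        if self._kernel is None:
            self._kernel = ResponseKernel(self.regimen, self.obs_times)
        return self._kernel

    def predict(self, params: KPDParams) -> np.ndarray:
        return self.kernel.response(params)


class EventDataset:
    """Long-format NONMEM-flavoured event records for fitting and VPC.

    Columns: ``ID, TIME, EVID, AMT, DV, MDV, N`` — dose rows have EVID=1 and
    AMT in ng; observation rows have EVID=0, DV in g/cm^2 and MDV=0.  ``N``
    carries the arm size as metadata (predictions are unweighted by default).
    """

    COLUMNS = ("ID", "TIME", "EVID", "AMT", "DV", "MDV", "N")

    def __init__(self, df: pd.DataFrame):
        self.df = self._validate(df)

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in EventDataset.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.loc[:, list(EventDataset.COLUMNS)].copy()
        df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("empty dataset")
        for arm_id, g in df.groupby("ID", sort=False):
            doses = g[g.EVID == 1]
            obs = g[(g.EVID == 0) & (g.MDV == 0)]
            if doses.empty:
                raise ValueError(f"id {arm_id!r}: no dose record")
            if obs.empty:
                raise ValueError(f"id {arm_id!r}: no observation record")
            if not (obs.TIME <= doses.TIME.min()).any():
                raise ValueError(
                    f"id {arm_id!r}: no baseline observation at or before first dose")
            if (obs.DV <= 0).any() or obs.DV.isna().any():
                raise ValueError(f"id {arm_id!r}: observations must have DV > 0")
            if doses.DV.notna().any():
                raise ValueError(f"id {arm_id!r}: DV present on a dose row")
            if (doses.AMT <= 0).any() or doses.AMT.isna().any():
                raise ValueError(f"id {arm_id!r}: dose rows must have AMT > 0")
        return df

    @property
    def ids(self) -> list:
        return list(dict.fromkeys(self.df["ID"]))

    def __len__(self) -> int:
        return int(((self.df.EVID == 0) & (self.df.MDV == 0)).sum())

    def arms(self) -> list[Arm]:
        out = []
        for arm_id, g in self.df.groupby("ID", sort=False):
            doses = g[g.EVID == 1]
            obs = g[(g.EVID == 0) & (g.MDV == 0)]
            regimen = Regimen.from_doses(zip(doses.TIME, doses.AMT))
            base = float(obs.sort_values("TIME").DV.iloc[0])
            out.append(Arm(
                id=arm_id,
                regimen=regimen,
                obs_times=obs.TIME.to_numpy(float),
                dv=obs.DV.to_numpy(float),
                base=base,
                n_subjects=int(g.N.iloc[0]),
            ))
        return out

    def subset(self, ids: Sequence, relabel: bool = False) -> "EventDataset":
        """Rows of the given ids, with replacement allowed when ``relabel``."""
        frames = []
        for k, arm_id in enumerate(ids):
            g = self.df[self.df.ID == arm_id].copy()
            if g.empty:
                raise KeyError(arm_id)
            if relabel:
                g["ID"] = f"bs{k:03d}_{arm_id}"
            frames.append(g)
        return EventDataset(pd.concat(frames, ignore_index=True))


def _residual_sd(pop: PopulationModel, pred: np.ndarray) -> np.ndarray:
    if pop.residual == "additive":
        return np.full_like(pred, math.sqrt(pop.sigma2))
    return np.sqrt(pop.sigma2) * pred


def _conditional_m2ll_arm(pop: PopulationModel, arm: Arm, eta: float,
                          weight: float = 1.0) -> float:
    if pop.sigma2 == 0:
        raise ValueError("likelihood undefined with sigma2 = 0")
    params = individual_params(pop, eta, arm.base)
    pred = arm.predict(params)
    sd = _residual_sd(pop, pred)
    resid = (arm.dv - pred) / sd
    m2ll = float(weight * np.sum(resid**2 + 2.0 * np.log(sd) + _LOG2PI))
    if pop.omega2_edk50 > 0:
        m2ll += eta**2 / pop.omega2_edk50 + math.log(2.0 * math.pi * pop.omega2_edk50)
    elif eta != 0.0:
        raise ValueError("eta must be 0 when omega2 is 0")
    return m2ll


def conditional_minus2ll(pop: PopulationModel, arm: Arm | EventDataset, eta: float) -> float:
    """Conditional -2 log-likelihood of one arm's data given its eta.

    Gaussian residual term around the arm's predicted trajectory plus the
    normal prior term ``eta^2/omega2 + ln(2*pi*omega2)``.
    """
    if isinstance(arm, EventDataset):
        arms = arm.arms()
        if len(arms) != 1:
            raise ValueError("expected records of exactly one id")
        arm = arms[0]
    return _conditional_m2ll_arm(pop, arm, eta)


def _eta_mode(pop: PopulationModel, arm: Arm, weight: float = 1.0,
              guess: float = 0.0) -> tuple[float, float, float]:
    """Empirical-Bayes mode of eta: (mode, objective, second derivative).

    Safeguarded Newton iteration with finite-difference derivatives, warm-
    startable from a previous mode (the outer optimiser moves in small steps,
    so the mode barely moves between objective evaluations); falls back to a
    bounded Brent search if the iteration misbehaves.
    """
    g = lambda e: _conditional_m2ll_arm(pop, arm, e, weight)
    # central differences: step balances truncation against cancellation in
    # the curvature used for the Laplace correction
    h = 1e-3
    eta = float(np.clip(guess, -11.0, 11.0))
    for _ in range(60):
        g0, gp, gm = g(eta), g(eta + h), g(eta - h)
        d1 = (gp - gm) / (2.0 * h)
        d2 = (gp - 2.0 * g0 + gm) / h**2
        if not np.isfinite(d2) or d2 <= 0:
            break
        step = float(np.clip(-d1 / d2, -1.0, 1.0))
        eta += step
        if abs(eta) > 12.0:
            break
        if abs(step) < 1e-10:
            return eta, g(eta), d2
    res = optimize.minimize_scalar(g, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"eta mode search failed for id {arm.id!r}: {res.message}")
    eta = float(res.x)
    d2 = (g(eta + h) - 2.0 * res.fun + g(eta - h)) / h**2
    return eta, float(res.fun), float(d2)


def _laplace_arm(pop: PopulationModel, arm: Arm, weight: float = 1.0,
                 guess: float = 0.0) -> tuple[float, float]:
    """(marginal -2LL contribution, eta mode) of one arm."""
    if pop.omega2_edk50 == 0.0:
        return _conditional_m2ll_arm(pop, arm, 0.0, weight), 0.0
    eta_hat, g_hat, d2 = _eta_mode(pop, arm, weight, guess)
    if not np.isfinite(d2) or d2 <= 0:
        # at a bound or flat spot: fall back to the prior curvature
        d2 = 2.0 / pop.omega2_edk50
    return g_hat + math.log(0.5 * d2) - _LOG2PI, eta_hat


def laplace_marginal_minus2ll(pop: PopulationModel, data: EventDataset | Iterable[Arm],
                              weights: Mapping | None = None,
                              eta_guesses: dict | None = None) -> float:
    """Laplace-approximate marginal -2 log-likelihood, summed over arms.

    ``eta_guesses`` (id -> eta) warm-starts each arm's mode search and is
    updated in place with the modes found.
    """
    arms = data.arms() if isinstance(data, EventDataset) else list(data)
    total = 0.0
    for arm in arms:
        w = 1.0 if weights is None else float(weights.get(arm.id, 1.0))
        guess = eta_guesses.get(arm.id, 0.0) if eta_guesses is not None else 0.0
        contrib, eta_hat = _laplace_arm(pop, arm, w, guess)
        if eta_guesses is not None:
            eta_guesses[arm.id] = eta_hat
        total += contrib
    return total


@dataclass
class FitResult:
    """Estimates, uncertainty, and empirical-Bayes etas from one fit."""

    estimates: PopulationModel
    se: dict[str, float]
    cv_pct: dict[str, float]
    minus2ll: float
    etas: dict
    cov: pd.DataFrame
    corr: pd.DataFrame
    condition_number: float
    converged: bool
    n_evals: int
    hessian_pd: bool
    data: EventDataset = field(repr=False, default=None)
    fixed: frozenset = frozenset()

    def summary(self) -> pd.DataFrame:
        est = _pop_to_dict(self.estimates)
        rows = []
        for name in FIT_PARAMS:
            rows.append({
                "parameter": name,
                "estimate": est[name],
                "fixed": name in self.fixed,
                "se": self.se.get(name, np.nan),
                "cv_pct": self.cv_pct.get(name, np.nan),
            })
        return pd.DataFrame(rows)


def _pop_to_dict(pop: PopulationModel) -> dict[str, float]:
    return {
        "kde": pop.theta.kde, "kd": pop.theta.kd, "edk50": pop.theta.edk50,
        "k_tol": pop.theta.k_tol, "omega2": pop.omega2_edk50, "sigma2": pop.sigma2,
    }


def _dict_to_pop(d: Mapping[str, float], template: PopulationModel) -> PopulationModel:
    theta = template.theta.replace(kde=d["kde"], kd=d["kd"], edk50=d["edk50"],
                                   k_tol=d["k_tol"])
    return template.replace(theta=theta, omega2_edk50=d["omega2"], sigma2=d["sigma2"])


def fit(data: EventDataset, init: PopulationModel,
        fixed: Iterable[str] = (), *,
        weights: Mapping | None = None,
        maxfev: int = 800,
        compute_se: bool = True) -> FitResult:
    """Estimate population parameters by Laplace marginal likelihood.

    Parameters
    ----------
    data
        Event dataset; each ID is one arm.
    init
        Starting values (and the residual-model choice).
    fixed
        Names from ``FIT_PARAMS`` to hold at their ``init`` values.  With all
        names fixed the objective is evaluated once and returned.
    weights
        Optional per-id likelihood weights (e.g. arm sizes); default
        unweighted, mirroring an aggregate-data fit of arm means.
    """
    fixed = frozenset(fixed)
    unknown = fixed - set(FIT_PARAMS)
    if unknown:
        raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")
    arms = data.arms()
    free = [p for p in FIT_PARAMS if p not in fixed]
    init_d = _pop_to_dict(init)
    if init_d["omega2"] == 0 and "omega2" not in fixed:
        raise ValueError("omega2 init must be > 0 unless fixed")

    n_evals = 0
    eta_guesses: dict = {}  # warm starts for the inner mode searches

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        d = dict(init_d)
        for name, xi in zip(free, x):
            d[name] = math.exp(xi)
        try:
            pop = _dict_to_pop(d, init)
            return laplace_marginal_minus2ll(pop, arms, weights, eta_guesses)
        except (ValueError, ArithmeticError, RuntimeError, OverflowError):
            return 1e12

    if not free:
        m2ll = laplace_marginal_minus2ll(init, arms, weights)
        etas = {a.id: _laplace_arm(init, a)[1] for a in arms}
        empty = pd.DataFrame()
        return FitResult(init, {}, {}, m2ll, etas, empty, empty, 1.0, True, 1,
                         True, data, fixed)

    x0 = np.array([math.log(init_d[p]) for p in free])
    # fatol 1e-5 on a -2LL of magnitude ~1e3 is ~1e-8 relative; xatol 1e-3 on
    # log-parameters is 0.1%, far below the statistical uncertainty here
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"maxfev": maxfev, "xatol": 1e-3,
                                     "fatol": 1e-5, "adaptive": True})
    x_hat = res.x
    d_hat = dict(init_d)
    for name, xi in zip(free, x_hat):
        d_hat[name] = math.exp(xi)
    pop_hat = _dict_to_pop(d_hat, init)

    se: dict[str, float] = {}
    cv: dict[str, float] = {}
    cov_df = corr_df = pd.DataFrame()
    cond = 1.0
    hess_pd = True
    if compute_se:
        H = _fd_hessian(objective, x_hat)
        try:
            cov_log = 2.0 * np.linalg.inv(H)
            if np.any(np.diag(cov_log) <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
        except np.linalg.LinAlgError:
            hess_pd = False
            cov_log = np.full((len(free), len(free)), np.nan)
        # delta method from log scale: se_nat = estimate * se_log
        est_vec = np.array([d_hat[p] for p in free])
        cov_nat = cov_log * np.outer(est_vec, est_vec)
        cov_df = pd.DataFrame(cov_nat, index=free, columns=free)
        with np.errstate(invalid="ignore"):
            dinv = np.diag(1.0 / np.sqrt(np.diag(cov_nat)))
            corr = dinv @ cov_nat @ dinv
        corr_df = pd.DataFrame(corr, index=free, columns=free)
        for i, p in enumerate(free):
            se[p] = float(np.sqrt(cov_nat[i, i]))
            cv[p] = 100.0 * se[p] / est_vec[i]
        if hess_pd:
            eig = np.linalg.eigvalsh(corr)
            cond = float(eig.max() / eig.min()) if eig.min() > 0 else math.inf
            hess_pd = bool(eig.min() > 0)

    etas = {a.id: _laplace_arm(pop_hat, a,
                               1.0 if weights is None else float(weights.get(a.id, 1.0)))[1]
            for a in arms}
    return FitResult(pop_hat, se, cv, float(res.fun), etas, cov_df, corr_df,
                     cond, bool(res.success), n_evals, hess_pd, data, fixed)


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian on the (log-)parameter scale."""
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i]**2
        for j in range(i):
            ej = np.zeros(n); ej[j] = h[j]
            fpj = f(x + ei + ej); fmj = f(x - ei - ej)
            fpm = f(x + ei - ej); fmp = f(x - ei + ej)
            H[i, j] = H[j, i] = (fpj + fmj - fpm - fmp) / (4 * h[i] * h[j])
    return H


@dataclass(frozen=True)
class ShrinkageResult:
    eta_pct: float
    eps_pct: float


def shrinkage(fit_result: FitResult) -> ShrinkageResult:
    """Eta- and epsilon-shrinkage of a converged fit.

    eta-shrinkage = 100*(1 - SD(EBE eta)/sqrt(omega2));
    eps-shrinkage = 100*(1 - SD(IWRES)).  Undefined when omega2 = 0 or the
    dataset has fewer than two arms.
    """
    pop = fit_result.estimates
    if pop.omega2_edk50 <= 0:
        raise ValueError("shrinkage undefined when omega2 = 0")
    etas = np.array(list(fit_result.etas.values()), dtype=float)
    if etas.size < 2:
        raise ValueError("shrinkage needs >= 2 arms")
    eta_pct = 100.0 * (1.0 - etas.std(ddof=1) / math.sqrt(pop.omega2_edk50))
    iwres = []
    for arm in fit_result.data.arms():
        params = individual_params(pop, fit_result.etas[arm.id], arm.base)
        pred = arm.predict(params)
        # the baseline observation anchors BASE and has no residual
        m = arm.obs_times > arm.obs_times.min()
        iwres.append(((arm.dv - pred) / _residual_sd(pop, pred))[m])
    iwres = np.concatenate(iwres)
    eps_pct = 100.0 * (1.0 - iwres.std(ddof=1))
    return ShrinkageResult(eta_pct=float(eta_pct), eps_pct=float(eps_pct))


def stepwise_covariate_search(base_minus2ll: float,
                              forward_candidates: Mapping[str, float],
                              backward_candidates: Mapping[str, float] | None = None,
                              forward_cutoff: float = 6.63,
                              backward_cutoff: float = 10.83) -> dict:
    """Generic likelihood-ratio stepwise screen over candidate model fits.

    A scaffold for covariate selection: callers supply the -2LL of the base
    model and of each candidate extension (forward) or reduction (backward);
    candidates are retained when the objective drops by more than
    ``forward_cutoff`` (default 6.63, alpha=0.01, df=1) and survive backward
    elimination when removal raises it by more than ``backward_cutoff``
    (10.83, alpha=0.001).  Disabled by default in the analysis pipeline: the
    final model carries no covariates.
    """
    selected = {k: v for k, v in forward_candidates.items()
                if base_minus2ll - v > forward_cutoff}
    retained = dict(selected)
    if backward_candidates:
        for k, v in backward_candidates.items():
            if k in retained and v - retained[k] <= backward_cutoff:
                retained.pop(k)
    return {"selected_forward": sorted(selected),
            "retained": sorted(retained),
            "base_minus2ll": base_minus2ll}
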