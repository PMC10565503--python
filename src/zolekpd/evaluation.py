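"""Model-evaluation diagnostics: GOF residuals, VPC, and bootstrap.

Goodness of fit reports population predictions (PRED, at eta = 0),
individual predictions (IPRED, at each arm's empirical-Bayes eta), and two
residual scalings.  IWRES divides the individual residual by the residual
SD.  WRES decorrelates the population residual with the first-order
approximate marginal covariance, so that it is approximately standard normal
when the model is right; an additive-sigma scaling alone would be
overdispersed whenever omega2 > 0.  Because each arm's baseline BMD is
anchored to its earliest observation, that observation has a structurally
zero residual (flagged ``anchor`` in the table and excluded from the
whitening), and its measurement noise propagates multiplicatively into every
later prediction — the marginal covariance therefore carries both terms:
sigma2*(I + rho*rho') + omega2*G*G', with rho the prediction relative to
baseline and G the sensitivity of the prediction to eta.

The visual predictive check simulates replicate datasets under the design of
the observed one and compares observed percentiles per time bin with the
spread of the same percentiles across simulations.  The bootstrap resamples
whole study arms with replacement — the only exchangeable unit in this
aggregate-data setting — and refits each resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import (EventDataset, FitResult, PopulationModel, Arm,
                         _residual_sd, fit, individual_params)

__all__ = ["gof", "vpc", "bootstrap", "VPCSummary", "BootstrapResult",
           "DEFAULT_PERCENTILES", "CI_PERCENTILES"]

#: plotting default percentile set
DEFAULT_PERCENTILES = (5.0, 50.0, 95.0)
#: outer band used for confidence-interval style summaries
CI_PERCENTILES = (2.5, 50.0, 97.5)


def _eta_sensitivity(pop: PopulationModel, arm: Arm, h: float = 1e-3) -> np.ndarray:
    p_plus = individual_params(pop, h, arm.base)
    p_minus = individual_params(pop, -h, arm.base)
    return (arm.predict(p_plus) - arm.predict(p_minus)) / (2.0 * h)


def gof(fit_result: FitResult, data: EventDataset | None = None) -> pd.DataFrame:
    """Per-observation GOF table: PRED, IPRED, WRES, IWRES.

    ``data`` defaults to the dataset the fit was run on; passing a different
    dataset with the same ids evaluates the fitted model against it.  The
    ``anchor`` column marks each arm's baseline observation, whose residual
    is zero by construction (it defines the arm's BASE); distributional
    checks should use ``table[~table.anchor]``.
    """
    if data is None:
        data = fit_result.data
    pop = fit_result.estimates
    rows = []
    for arm in data.arms():
        if arm.id not in fit_result.etas:
            raise KeyError(f"no empirical-Bayes eta for id {arm.id!r}")
        eta = fit_result.etas[arm.id]
        pred = arm.predict(individual_params(pop, 0.0, arm.base))
        ipred = arm.predict(individual_params(pop, eta, arm.base))
        iwres = (arm.dv - ipred) / _residual_sd(pop, ipred)
        anchor = arm.obs_times == arm.obs_times.min()
        # first-order marginal covariance of the non-anchor observations:
        # residual noise, propagated baseline noise, and the eta term
        m = ~anchor
        g_eta = _eta_sensitivity(pop, arm)[m]
        rho = (pred / arm.base)[m]
        sd = _residual_sd(pop, pred)[m]
        base_var = pop.sigma2 if pop.residual == "additive" \
            else pop.sigma2 * arm.base**2
        cov = pop.omega2_edk50 * np.outer(g_eta, g_eta)
        cov += base_var * np.outer(rho, rho)
        cov[np.diag_indices_from(cov)] += sd**2
        chol = np.linalg.cholesky(cov)
        wres = np.zeros(arm.dv.size)
        wres[m] = np.linalg.solve(chol, (arm.dv - pred)[m])
        for k in range(arm.dv.size):
            rows.append({"id": arm.id, "time": arm.obs_times[k], "dv": arm.dv[k],
                         "pred": pred[k], "ipred": ipred[k],
                         "wres": wres[k], "iwres": iwres[k],
                         "anchor": bool(anchor[k])})
    return pd.DataFrame(rows)


@dataclass
class VPCSummary:
    """Observed vs simulated percentile bands per time bin."""

    table: pd.DataFrame  # bin, percentile, observed, sim_median, sim_lo, sim_hi
    n_sims: int
    percentiles: tuple[float, ...]

    def coverage(self, percentile: float = 50.0) -> float:
        """Fraction of bins whose observed percentile lies inside the
        simulated band's 95% CI."""
        sub = self.table[self.table.percentile == percentile]
        inside = (sub.observed >= sub.sim_lo) & (sub.observed <= sub.sim_hi)
        return float(inside.mean())


def vpc(pop: PopulationModel, data: EventDataset, n_sims: int = 1000,
        seed: int = 0, percentiles: tuple[float, ...] = DEFAULT_PERCENTILES) -> VPCSummary:
    """Visual predictive check of ``pop`` against ``data``.

    Replicate datasets are simulated under the observed design (same arms,
    regimens and sampling times, fresh eta and residual draws); per time bin
    the observed percentiles of DV are compared with the median and 2.5/97.5
    envelope of the same percentile across simulations.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for stable bands")
    arms = data.arms()
    bins = np.unique(np.concatenate([a.obs_times for a in arms]))
    obs_by_bin = {t: [] for t in bins}
    for a in arms:
        for t, v in zip(a.obs_times, a.dv):
            obs_by_bin[t].append(v)
    keep = [t for t in bins if len(obs_by_bin[t]) > 0]
    dropped = set(bins) - set(keep)
    if dropped:
        warnings.warn(f"dropping empty VPC bins: {sorted(dropped)}")

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(pop.sigma2)
    omega = np.sqrt(pop.omega2_edk50)
    # per-sim, per-bin percentiles of simulated DVs
    sim_pct = np.empty((n_sims, len(keep), len(percentiles)))
    typ_pred = {a.id: a.predict(individual_params(pop, 0.0, a.base)) for a in arms}
    for s in range(n_sims):
        sim_by_bin = {t: [] for t in keep}
        for a in arms:
            eta = rng.normal(0.0, omega) if omega > 0 else 0.0
            if eta == 0.0:
                resp = typ_pred[a.id]
            else:
                resp = a.predict(individual_params(pop, eta, a.base))
            dv = resp + (rng.normal(0.0, sigma, size=resp.size) if sigma > 0 else 0.0)
            for t, v in zip(a.obs_times, dv):
                sim_by_bin[t].append(v)
        for b, t in enumerate(keep):
            sim_pct[s, b, :] = np.percentile(sim_by_bin[t], percentiles)

    rows = []
    for b, t in enumerate(keep):
        obs_p = np.percentile(obs_by_bin[t], percentiles)
        for j, p in enumerate(percentiles):
            lo, med, hi = np.percentile(sim_pct[:, b, j], [2.5, 50.0, 97.5])
            rows.append({"bin": t, "percentile": p, "observed": obs_p[j],
                         "sim_median": med, "sim_lo": lo, "sim_hi": hi,
                         "n_obs": len(obs_by_bin[t])})
    return VPCSummary(table=pd.DataFrame(rows), n_sims=n_sims,
                      percentiles=tuple(percentiles))


@dataclass
class BootstrapResult:
    """Percentile summary of parameter estimates across resampled refits."""

    table: pd.DataFrame  # parameter, median, ci_low, ci_high
    n_boot: int          # successful replicates
    n_failed: int
    unreliable: bool     # >20% of replicates failed

    def median(self, parameter: str) -> float:
        return float(self.table.set_index("parameter").loc[parameter, "median"])


def bootstrap(data: EventDataset, init: PopulationModel, n_boot: int = 500,
              seed: int = 0, fixed=(), maxfev: int = 600) -> BootstrapResult:
    """Nonparametric bootstrap: resample arms with replacement and refit."""
    ids = data.ids
    if len(ids) < 2:
        raise ValueError("bootstrap needs >= 2 arms")
    rng = np.random.default_rng(seed)
    draws: list[dict[str, float]] = []
    n_failed = 0
    from .population import _pop_to_dict
    for _ in range(n_boot):
        sample = [ids[k] for k in rng.integers(0, len(ids), size=len(ids))]
        try:
            sub = data.subset(sample, relabel=True)
            res = fit(sub, init, fixed=fixed, compute_se=False, maxfev=maxfev)
            draws.append(_pop_to_dict(res.estimates))
        except Exception:
            n_failed += 1
    if not draws:
        raise RuntimeError("all bootstrap replicates failed")
    frame = pd.DataFrame(draws)
    rows = [{"parameter": p,
             "median": float(np.median(frame[p])),
             "ci_low": float(np.percentile(frame[p], 2.5)),
             "ci_high": float(np.percentile(frame[p], 97.5))}
            for p in frame.columns]
    return BootstrapResult(table=pd.DataFrame(rows), n_boot=len(draws),
                           n_failed=n_failed,
                           unreliable=n_failed > 0.2 * n_boot)
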