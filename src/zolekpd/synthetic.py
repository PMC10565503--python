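"""Synthetic event datasets emulating the pooled zoledronic-acid trials.

The generator reproduces the statistical structure the population analysis
assumes: arm-level mean BMD trajectories from the K-PD model, a log-normal
inter-arm random effect on EDK50, and additive Gaussian residual noise on
each scheduled observation.  The bundled default designs transcribe the ten
pooled osteoporosis trials (regimen, arm size, baseline vertebral BMD,
follow-up length); observations fall on a regular 6-month grid, which real
digitised data do not — see the methods note for what that idealisation
implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import NG_PER_MG, Regimen, simulate
from .population import EventDataset, PopulationModel, individual_params

__all__ = ["ArmDesign", "GeneratorConfig", "default_designs",
           "replicate_designs", "generate"]

OBS_INTERVAL_MONTHS = 6.0


@dataclass(frozen=True)
class ArmDesign:
    """Design of one study arm: size, baseline BMD, regimen, follow-up."""

    label: str
    n_subjects: int
    baseline_bmd: float
    regimen: Regimen
    observation_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.4 <= self.baseline_bmd <= 1.4:
            raise ValueError(
                f"baseline {self.baseline_bmd} outside plausible 0.4-1.4 g/cm^2")
        if len(self.observation_times) < 1:
            raise ValueError("need at least one observation time")


@dataclass(frozen=True)
class GeneratorConfig:
    pop: PopulationModel
    designs: tuple[ArmDesign, ...]
    seed: int = 0


def _obs_grid(followup_months: float) -> tuple[float, ...]:
    return tuple(np.arange(0.0, followup_months + 1e-9, OBS_INTERVAL_MONTHS))


def default_designs() -> list[ArmDesign]:
    """The ten pooled trial arms (6,014 subjects in total).

    Three trials randomised subjects to single doses of 1, 2.5 or 5 mg; one
    representative dose per trial is used here (1, 2.5 and 5 mg respectively)
    so the defaults span the studied dose range.  Annual regimens dose every
    12 months for the stated treatment duration.
    """
    from .io import load_design_table  # deferred: io depends on this module's types

    designs = []
    for row in load_design_table().itertuples():
        amount = row.dose_mg * NG_PER_MG
        regimen = Regimen.repeated(amount, int(row.n_doses), row.interval_months) \
            if row.n_doses > 1 else Regimen.single(amount)
        designs.append(ArmDesign(
            label=str(row.label),
            n_subjects=int(row.n_subjects),
            baseline_bmd=float(row.baseline_bmd),
            regimen=regimen,
            observation_times=_obs_grid(float(row.followup_months)),
        ))
    return designs


def replicate_designs(designs: Sequence[ArmDesign], n_copies: int) -> list[ArmDesign]:
    """``n_copies`` relabelled copies of the designs (e.g. 10 -> 40 arms)."""
    out = []
    for c in range(n_copies):
        for d in designs:
            out.append(replace(d, label=f"{d.label}_r{c + 1}"))
    return out


def generate(config: GeneratorConfig) -> EventDataset:
    """Draw one synthetic EventDataset under the configured designs.

    Per arm: eta ~ N(0, omega2) scales EDK50; the arm trajectory is simulated
    at those individual parameters; each scheduled observation gets i.i.d.
    N(0, sigma2) additive noise, redrawing the rare non-positive value.  Arms
    use independent child streams spawned from the root seed, so adding an
    arm never perturbs the draws of existing arms.
    """
    pop = config.pop
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.designs))
    rows = []
    for design, child in zip(config.designs, children):
        rng = np.random.default_rng(child)
        eta = rng.normal(0.0, np.sqrt(pop.omega2_edk50)) if pop.omega2_edk50 > 0 else 0.0
        params = individual_params(pop, eta, design.baseline_bmd)
        traj = simulate(params, design.regimen, np.asarray(design.observation_times))
        sd = np.sqrt(pop.sigma2)
        for t, r in zip(traj.times, traj.response):
            dv = r + rng.normal(0.0, sd)
            while dv <= 0:  # total contract; practically never triggers
                dv = r + rng.normal(0.0, sd)
            rows.append((design.label, float(t), 0, np.nan, float(dv), 0,
                         design.n_subjects))
        for ev in design.regimen.events:
            rows.append((design.label, float(ev.time), 1, float(ev.amount),
                         np.nan, 1, design.n_subjects))
    df = pd.DataFrame(rows, columns=list(EventDataset.COLUMNS))
    return EventDataset(df)
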