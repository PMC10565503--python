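"""File I/O: bundled fixtures, event-record CSVs, and run configuration.

All interchange is plain CSV.  Event records use a NONMEM-flavoured dialect
(``ID,TIME,EVID,AMT,DV,MDV,N``) with doses stored in ng; the command line
converts mg at the boundary.  The bundled fixture tables (study designs,
population parameter estimates, APR incidence counts) are checksummed so a
corrupted installation fails loudly instead of silently shifting results.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import KPDParams
from .population import EventDataset, PopulationModel

__all__ = [
    "load_fixtures",
    "load_design_table",
    "load_population_parameters",
    "load_parameter_table",
    "read_event_dataset",
    "write_event_dataset",
    "RunConfig",
]

_FIXTURE_SHA256 = {
    "study_designs.csv":
        "e9133b4129558810846d85cd3329e4ab4d93e1798eb5976d2f7269f94b1b627b",
    "population_parameters.csv":
        "b1179b6990133b94b56094b8f5cb78eee043eff1b575cb06cee1c2eb83356dc9",
    "apr_incidence.csv":
        "f0c66767505022f8e93e1934bb1586cc0bcf9320bb039a159f4955d019ef5ac4",
}


def _fixture_bytes(name: str) -> bytes:
    data = resources.files("zolekpd.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(
            f"fixture {name} checksum mismatch (got {digest}); "
            "the installed package data is corrupted")
    return data


def _fixture_frame(name: str) -> pd.DataFrame:
    import io as _io
    return pd.read_csv(_io.BytesIO(_fixture_bytes(name)))


def load_design_table() -> pd.DataFrame:
    """Raw study-design fixture (one row per pooled trial arm)."""
    return _fixture_frame("study_designs.csv")


def load_parameter_table() -> pd.DataFrame:
    """Published population estimates with RSE%, bootstrap medians and 95% CIs."""
    return _fixture_frame("population_parameters.csv").set_index("parameter")


def load_population_parameters(base: float = 0.79) -> PopulationModel:
    """Final population model estimates as a :class:`PopulationModel`.

    ``base`` only seeds ``theta.base`` as a nominal placeholder (the largest
    trial's baseline); predictions always substitute an arm-specific baseline.
    """
    tab = load_parameter_table()["estimate"]
    theta = KPDParams(kde=float(tab["kde"]), kd=float(tab["kd"]),
                      edk50=float(tab["edk50"]), k_tol=float(tab["k_tol"]),
                      base=base)
    return PopulationModel(theta=theta, omega2_edk50=float(tab["omega2_edk50"]),
                           sigma2=float(tab["sigma2"]))


def load_fixtures():
    """(designs, PopulationModel, APRTable) from the bundled fixture tables."""
    from .apr import APRTable
    from .synthetic import default_designs

    return default_designs(), load_population_parameters(), APRTable.bundled()


def read_event_dataset(path) -> EventDataset:
    """Read and validate an event-record CSV, with row-addressed errors."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty event-record file") from None
    missing = [c for c in EventDataset.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("TIME", "AMT", "DV"):
        bad = df[~df[col].map(lambda v: _is_number_or_blank(v))]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col} at data line(s) "
                f"{[i + 2 for i in bad.index[:5]]}")
    df = df.astype({"TIME": float, "EVID": int, "AMT": float, "DV": float,
                    "MDV": int, "N": int}, errors="raise")
    try:
        return EventDataset(df)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def _is_number_or_blank(v) -> bool:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return True
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_event_dataset(data: EventDataset, path) -> None:
    """Write the canonical (sorted, column-ordered) event-record CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data.df.to_csv(path, index=False, float_format="%.10g")


@dataclass
class RunConfig:
    """Run-level configuration shared by the CLI subcommands.

    Stored as plain ``key = value`` text; unknown keys are rejected so typos
    surface instead of silently taking defaults.
    """

    seed: int = 1
    n_sims: int = 1000
    n_boot: int = 500
    threshold_pct: float = 3.0
    residual: str = "additive"
    weight_by_arm_size: bool = False
    covariate_screen: bool = False
    dataset: str = ""
    out_dir: str = "zolekpd_out"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = cls()
        casts = {"seed": int, "n_sims": int, "n_boot": int,
                 "threshold_pct": float, "residual": str,
                 "weight_by_arm_size": _parse_bool, "covariate_screen": _parse_bool,
                 "dataset": str, "out_dir": str}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in casts:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            setattr(cfg, key, casts[key](value))
        return cfg


def _parse_bool(s: str) -> bool:
    s = s.strip().lower()
    if s in ("1", "true", "yes", "on"):
        return True
    if s in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {s!r}")
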