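"""House-level ammonia-emission scaling.

Plate-level coverage scales to the whole house as
``A_T = CP_i/100 * A_plate * N_cage`` (one collection plate spans one cage),
and hourly ammonia emission follows ``M_NH3 = ER * A_s`` with the projected
manure area used as the emitting surface area.  The emission rate ER
(mg m^-2 h^-1) comes from an upstream mechanistic model and is taken here as
an input series, never computed.

The projected-area approximation ``A_s ~= A_p`` rests on the field
observation that manure buried under overlaps contributes little to release;
it is recorded in the output metadata rather than silently assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import QuarticModel

__all__ = [
    "HouseSpec",
    "total_house_area",
    "ammonia_emission",
    "hourly_emission_series",
    "read_er_series",
]

EMISSION_COLUMNS = ["hour", "cp_pct", "a_t_m2", "m_nh3_mg_h", "in_domain"]


@dataclass(frozen=True)
class HouseSpec:
    """Belt geometry of one layer house.

    ``n_cage`` is mandatory configuration: it cannot be derived reliably from
    a bird count because occupancy per cage varies between houses.
    """

    n_cage: int
    a_plate_m2: float = 0.5848
    description: str = ""

    def __post_init__(self) -> None:
        if self.a_plate_m2 <= 0:
            raise ValueError("a_plate_m2 must be positive")
        if self.n_cage < 1:
            raise ValueError("n_cage must be >= 1")


def total_house_area(cp_pct: float, house: HouseSpec) -> float:
    """Total manure-covered belt area in the house, m^2."""
    if not 0.0 <= cp_pct <= 100.0:
        raise ValueError(f"coverage percent {cp_pct} outside [0, 100]")
    return cp_pct / 100.0 * house.a_plate_m2 * house.n_cage


def ammonia_emission(er_mg_m2_h: float, a_s_m2: float) -> float:
    """Hourly ammonia emission ``ER * A_s`` in mg/h."""
    if er_mg_m2_h < 0 or a_s_m2 < 0:
        raise ValueError("emission rate and surface area must be non-negative")
    return er_mg_m2_h * a_s_m2


def read_er_series(path) -> pd.DataFrame:
    """Read an hourly emission-rate CSV with header ``hour,er_mg_m2_h``."""
    df = pd.read_csv(path)
    missing = [c for c in ("hour", "er_mg_m2_h") if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed ER CSV {path!r}: missing columns {missing}; "
            "expected header hour,er_mg_m2_h"
        )
    if (df["er_mg_m2_h"] < 0).any():
        raise ValueError("ER series contains negative emission rates")
    return df


def hourly_emission_series(
    model: QuarticModel,
    house: HouseSpec,
    er: pd.DataFrame | float,
    hours=None,
) -> pd.DataFrame:
    """Per-hour coverage, house manure area and ammonia emission.

    ``er`` is either a DataFrame (``hour, er_mg_m2_h``) covering the hour
    grid or a constant rate.  Hours outside the model's fitted domain are
    computed but flagged ``in_domain = False``.  The returned frame carries
    ``attrs['surface_area_approximation'] = 'A_s ~= A_p (projected area)'``.
    """
    if hours is None:
        if isinstance(er, pd.DataFrame):
            hours = er["hour"].to_numpy()
        else:
            lo, hi = model.domain_hours
            hours = np.arange(int(lo), int(hi) + 1)
    hours = np.asarray(hours)
    if isinstance(er, pd.DataFrame):
        er_map = er.set_index("hour")["er_mg_m2_h"]
        missing = [int(h) for h in hours if h not in er_map.index]
        if missing:
            raise ValueError(f"ER series does not cover hours: {missing}")
        er_vals = er_map.loc[hours].to_numpy(dtype=float)
    else:
        if er < 0:
            raise ValueError("constant ER must be non-negative")
        er_vals = np.full(len(hours), float(er))
    cp = np.array([model.predict(h, warn_out_of_domain=False) for h in hours], dtype=float)
    a_t = np.array([total_house_area(c, house) for c in cp])
    out = pd.DataFrame(
        {
            "hour": hours,
            "cp_pct": cp,
            "a_t_m2": a_t,
            "m_nh3_mg_h": er_vals * a_t,
            "in_domain": model.in_domain(hours),
        }
    )
    out.attrs["surface_area_approximation"] = "A_s ~= A_p (projected area)"
    out.attrs["model"] = model.name
    return out
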