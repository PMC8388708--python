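"""Manure-coverage-proportion (MCP) growth-curve models.

Three model families live here:

* :class:`QuarticModel` — the published degree-4 polynomials MCP48 (belt
  cleared every 48 h) and MCP24 (every 24 h) in hours since the last manure
  removal, with packaged default coefficients.
* :class:`MCPCurveModel` / :class:`MCPCurveResults` — an OLS quartic
  growth-curve fit to an hourly mean-coverage series, in the Model/Results
  idiom: construct from data, call :meth:`MCPCurveModel.fit`, inspect
  coefficients, residuals, R^2 and ``summary()``.
* :func:`baseline_daily_mcp` — the literature daily rule ``min(d/3, 1)``, and
  :func:`boolean_expected_coverage` — the germ-grain closed form
  ``1 - exp(-S/A)`` used as the simulator's analytic oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "QuarticModel",
    "MCPCurveModel",
    "MCPCurveResults",
    "load_default_models",
    "eval_mcp",
    "baseline_daily_mcp",
    "boolean_expected_coverage",
    "compare_models",
]


@dataclass(frozen=True)
class QuarticModel:
    """A quartic MCP curve ``c4 h^4 + c3 h^3 + c2 h^2 + c1 h + c0`` (percent).

    ``domain_hours`` is the fitted validity interval; evaluation outside it is
    permitted but flagged with a warning because the polynomial extrapolates
    poorly (the published 48-h curve is negative at h = 0).  With ``clamp``
    set (the default) predictions are restricted to the physical range
    [0, 100] %.
    """

    coefficients: tuple[float, ...]  # highest degree first
    domain_hours: tuple[float, float] = (1.0, 48.0)
    clamp: bool = True
    name: str = "quartic"

    def __post_init__(self) -> None:
        if len(self.coefficients) != 5:
            raise ValueError("a quartic model needs exactly five coefficients")
        if self.domain_hours[0] < 0:
            raise ValueError("domain lower bound must be >= 0")

    def in_domain(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return (h >= self.domain_hours[0]) & (h <= self.domain_hours[1])

    def predict(self, h, warn_out_of_domain: bool = True):
        """Evaluate the quartic at hour(s) ``h`` (Horner form via polyval)."""
        h_arr = np.asarray(h, dtype=float)
        if not np.all(np.isfinite(h_arr)):
            raise ValueError("hour values must be finite")
        if warn_out_of_domain and not np.all(self.in_domain(h_arr)):
            warnings.warn(
                f"evaluating {self.name} outside its fitted domain "
                f"{self.domain_hours}; extrapolation is unreliable",
                stacklevel=2,
            )
        out = np.polyval(self.coefficients, h_arr)
        if self.clamp:
            out = np.clip(out, 0.0, 100.0)
        return float(out) if np.isscalar(h) else out


def eval_mcp(model: QuarticModel, h, clamp: bool | None = None):
    """Evaluate an MCP model at hour(s) ``h``; percent.

    ``clamp`` overrides the model's own clamping flag when given.
    """
    if clamp is not None and clamp != model.clamp:
        model = QuarticModel(model.coefficients, model.domain_hours, clamp, model.name)
    return model.predict(h)


def load_default_models() -> dict[str, QuarticModel]:
    """Load the packaged published MCP48/MCP24 coefficient sets."""
    text = resources.files("beltcover.data").joinpath("mcp_coefficients.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: QuarticModel(
            coefficients=tuple(entry["coefficients"]),
            domain_hours=tuple(entry["domain_hours"]),
            name=name,
        )
        for name, entry in raw.items()
    }


def baseline_daily_mcp(d: int) -> float:
    """Literature daily coverage rule: ``min(d/3, 1) * 100`` percent.

    ``d`` is the whole number of days since the most recent manure removal.
    """
    if d != int(d) or d < 0:
        raise ValueError("d must be a non-negative integer number of days")
    return min(d / 3.0, 1.0) * 100.0


def boolean_expected_coverage(cumulative_fresh_area_m2: float, plate_area_m2: float):
    """Expected boolean-model coverage percent, ``(1 - exp(-S/A)) * 100``.

    ``S`` is the cumulative un-overlapped (fresh) grain area deposited so
    far; under uniform independent placement the covered fraction of a plate
    of area ``A`` is ``1 - exp(-S/A)``.  Accepts scalars or arrays in S.
    """
    if plate_area_m2 <= 0:
        raise ValueError("plate_area_m2 must be positive")
    s = np.asarray(cumulative_fresh_area_m2, dtype=float)
    if np.any(s < 0):
        raise ValueError("cumulative fresh area must be non-negative")
    out = (1.0 - np.exp(-s / plate_area_m2)) * 100.0
    return float(out) if np.isscalar(cumulative_fresh_area_m2) else out


class MCPCurveModel:
    """OLS quartic growth-curve model for an hourly coverage series.

    Parameters
    ----------
    endog : array-like
        Mean coverage percent per hour (the fit target; the field protocol
        averages six plates per hour before fitting).
    hours : array-like
        Hours since last manure removal, 1-based.
    """

    degree = 4

    def __init__(self, endog, hours):
        self.endog = np.asarray(endog, dtype=float)
        self.hours = np.asarray(hours, dtype=float)
        if self.endog.shape != self.hours.shape or self.endog.ndim != 1:
            raise ValueError("endog and hours must be 1-D arrays of equal length")
        if len(np.unique(self.hours)) < self.degree + 2:
            raise ValueError(
                f"need at least {self.degree + 2} distinct hours to fit a quartic"
            )
        if np.ptp(self.endog) == 0:
            raise ValueError("constant coverage series: zero total variance")

    @classmethod
    def from_series(cls, series: pd.DataFrame, value_col: str = "gamma_pct") -> "MCPCurveModel":
        """Build from a coverage series DataFrame with ``hour`` and a value column."""
        if value_col not in series.columns:
            raise ValueError(f"series has no column {value_col!r}")
        grouped = series.groupby("hour", as_index=False)[value_col].mean()
        return cls(grouped[value_col].to_numpy(), grouped["hour"].to_numpy())

    def fit(self) -> "MCPCurveResults":
        coeffs, cov = np.polyfit(self.hours, self.endog, self.degree, cov=True)
        fitted = np.polyval(coeffs, self.hours)
        resid = self.endog - fitted
        ss_res = float(resid @ resid)
        ss_tot = float(((self.endog - self.endog.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        return MCPCurveResults(
            model=self,
            params=coeffs,
            bse=np.sqrt(np.diag(cov)),
            fittedvalues=fitted,
            resid=resid,
            r_squared=r2,
        )


@dataclass
class MCPCurveResults:
    """Results of an OLS quartic MCP fit."""

    model: MCPCurveModel
    params: np.ndarray  # c4..c0, highest degree first
    bse: np.ndarray
    fittedvalues: np.ndarray
    resid: np.ndarray
    r_squared: float
    domain_hours: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.domain_hours = (float(self.model.hours.min()), float(self.model.hours.max()))

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    def as_quartic(self, clamp: bool = True, name: str = "fitted") -> QuarticModel:
        """Freeze the fit into a :class:`QuarticModel` for downstream use."""
        return QuarticModel(tuple(self.params), self.domain_hours, clamp, name)

    def predict(self, h, clamp: bool = True):
        return self.as_quartic(clamp=clamp).predict(h, warn_out_of_domain=False)

    def summary(self) -> str:
        lines = [
            "Quartic MCP growth-curve fit (OLS)",
            "=" * 46,
            f"{'observations':<20}{self.nobs:>10d}",
            f"{'hour domain':<20}{self.domain_hours[0]:>5.0f} - {self.domain_hours[1]:.0f}",
            f"{'R-squared':<20}{self.r_squared:>10.4f}",
            "-" * 46,
            f"{'term':<8}{'coef':>16}{'std err':>14}",
        ]
        for p, (c, se) in enumerate(zip(self.params, self.bse)):
            deg = self.model.degree - p
            lines.append(f"{'h^' + str(deg):<8}{c:>16.6g}{se:>14.3g}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot data, fitted curve and residual band on an hourly grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.model.hours
        grid = np.linspace(h.min(), h.max(), 200)
        ax.plot(h, self.model.endog, "ko", ms=4, label="mean MCP")
        ax.plot(grid, self.predict(grid), "r-", label=f"quartic fit (R$^2$={self.r_squared:.3f})")
        ax.set_xlabel("hours since manure removal")
        ax.set_ylabel("coverage proportion (%)")
        ax.legend()
        return ax


def compare_models(h_grid, models: dict[str, QuarticModel | float | object]) -> pd.DataFrame:
    """Tabulate MCP percent per hour for several models.

    ``models`` maps a column name to a :class:`QuarticModel`, a callable of
    hour, or a constant.  Returns one row per hour, one column per model.
    """
    h_grid = list(h_grid)
    out = pd.DataFrame({"hour": h_grid})
    for name, m in models.items():
        if isinstance(m, QuarticModel):
            vals = [m.predict(h, warn_out_of_domain=False) for h in h_grid]
        elif callable(m):
            vals = [m(h) for h in h_grid]
        else:
            vals = [float(m)] * len(h_grid)
        out[name] = vals
    return out
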