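"""Dose-response analysis of influx constants against a competitor.

Carrier-mediated uptake is saturable: increasing the concentration c_K of an
unlabelled competitor displaces the tracer from membrane carriers and lowers
the fitted influx constant.  The dependence is modelled as

    I(c_K) = v_lim / (IC50 + c_K) + D

where v_lim (nM * s^-1 under this parameterisation) scales the saturable
component, IC50 (nM) is the competitor concentration of half-saturation, and
D (s^-1) is the residual influx that persists when the carrier system is
fully saturated (e.g. passive diffusion).  A competitor that produces no
inhibition drives the fitted IC50 towards infinity; this is detected and
reported as "no saturation observed" rather than as a numeric estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import UnderdeterminedError, ValidationError

__all__ = [
    "SaturationParams",
    "DoseResponseSeries",
    "SaturationFit",
    "eval_saturation",
    "fit_saturation",
    "fold_change_matrix",
    "FoldChangeResult",
]

#: fitted IC50 above this multiple of the largest tested concentration is
#: treated as divergent (no saturation within the observable range)
_DIVERGENCE_FACTOR = 1e6


@dataclass(frozen=True)
class SaturationParams:
    """Parameters of the saturable-influx model."""

    v_lim: float  # nM * s^-1
    ic50: float  # nM
    D: float  # s^-1

    def __post_init__(self) -> None:
        for name in ("v_lim", "ic50", "D"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass
class DoseResponseSeries:
    """Fitted influx constants at a ladder of competitor concentrations."""

    competitor_conc: np.ndarray  # nM
    I_values: np.ndarray  # s^-1
    tracer: str = ""
    competitor: str = ""

    def __post_init__(self) -> None:
        self.competitor_conc = np.asarray(self.competitor_conc, dtype=float)
        self.I_values = np.asarray(self.I_values, dtype=float)
        if self.competitor_conc.shape != self.I_values.shape:
            raise ValidationError("competitor_conc and I_values must have equal length")
        if np.any(self.competitor_conc < 0):
            raise ValidationError("competitor concentrations must be >= 0")
        if 0.0 not in self.competitor_conc:
            warnings.warn("series has no zero-concentration (uninhibited) point")


@dataclass
class SaturationFit:
    """Fit outcome: parameters, diagnostics and the no-saturation flag."""

    params: SaturationParams
    residual_norm: float
    converged: bool
    no_saturation: bool
    notes: List[str] = field(default_factory=list)


def eval_saturation(cK, p: SaturationParams) -> np.ndarray:
    """Influx constant at competitor concentration cK (vectorized)."""
    cK = np.asarray(cK, dtype=float)
    if np.any(cK < 0):
        raise ValidationError("cK must be >= 0")
    if np.any(p.ic50 + cK == 0):
        raise ValidationError("IC50 + cK = 0: saturation model undefined")
    return p.v_lim / (p.ic50 + cK) + p.D


def fit_saturation(
    series: DoseResponseSeries,
    ftol: float = 1e-15,
    xtol: float = 1e-15,
    gtol: float = 1e-15,
    max_nfev: int = 100_000,
) -> SaturationFit:
    """Bounded least-squares fit of (v_lim, IC50, D) to a dose-response series.

    Initial guesses are 1 for all three parameters with lower bounds of zero.
    """
    cK, I = series.competitor_conc, series.I_values
    if len(cK) < 4:
        raise UnderdeterminedError(f"{len(cK)} points for 3 free parameters")

    def residual(x):
        return x[0] / (x[1] + cK) + x[2] - I

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(
            residual,
            [1.0, 1.0, 1.0],
            bounds=(0.0, np.inf),
            method="trf",
            ftol=ftol,
            xtol=xtol,
            gtol=gtol,
            max_nfev=max_nfev,
        )
    v_lim, ic50, D = sol.x
    notes: List[str] = []
    scale = float(np.max(np.abs(I))) or 1.0
    # saturable drop the fitted curve predicts across the tested range
    drop = v_lim / (ic50 + cK.min()) - v_lim / (ic50 + cK.max())
    diverged = ic50 > _DIVERGENCE_FACTOR * max(cK.max(), 1.0)
    flat_fit = drop < 1e-9 * scale
    data_constant = np.allclose(I, I[0], rtol=1e-12, atol=1e-15 * scale)
    no_saturation = bool(diverged or (flat_fit and not data_constant))
    if no_saturation:
        notes.append("no saturation observed: IC50 not identifiable from this series")
    if not sol.success:
        notes.append(f"solver did not converge: {sol.message}")
    return SaturationFit(
        params=SaturationParams(float(v_lim), float(ic50), float(D)),
        residual_norm=float(2.0 * sol.cost),
        converged=bool(sol.success),
        no_saturation=no_saturation,
        notes=notes,
    )


class FoldChangeResult(NamedTuple):
    """Fold-change heat-map data: tracer rows x competitor columns."""

    matrix: pd.DataFrame  # NaN marks non-tested combinations
    undefined: List[Tuple[str, str]]  # cells with a zero control median


def fold_change_matrix(
    control_medians: Mapping[str, float],
    treated_medians: Mapping[Tuple[str, str], float],
) -> FoldChangeResult:
    """Ratios of treated to control median influx constants.

    ``fold = median I(tracer with competitor) / median I(tracer alone)``;
    values below 1 indicate inhibition.  Combinations absent from
    ``treated_medians`` stay NaN (non-tested); cells whose control median is
    zero are NaN and listed in ``undefined``.
    """
    tracers = sorted({t for t, _ in treated_medians})
    competitors = sorted({c for _, c in treated_medians})
    missing = [t for t in tracers if t not in control_medians]
    if missing:
        raise ValidationError(f"no control median for tracer(s) {missing}")
    mat = pd.DataFrame(np.nan, index=tracers, columns=competitors, dtype=float)
    undefined: List[Tuple[str, str]] = []
    for (tracer, comp), value in treated_medians.items():
        control = control_medians[tracer]
        if control == 0:
            undefined.append((tracer, comp))
            continue
        mat.loc[tracer, comp] = value / control
    return FoldChangeResult(matrix=mat, undefined=undefined)
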