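"""Nonlinear least-squares estimation of transport kinetic parameters.

Three fitting modes are provided:

* per-assay fits of (I, E, K) to a single accumulation curve;
* a joint dataset fit in which every assay keeps its own influx constant I
  while the efflux constant E and the adsorption factor K are shared across
  assays (used when comparing conditions measured on the same cell culture);
* piecewise fits of (I, I', E, K) for assays with a mid-assay treatment.

All fits use bounded trust-region least squares with lower bounds of zero on
every parameter, initial guesses of 1e-3 s^-1 for I and E and 0 for K, and
function/step tolerances of 1e-15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigurationError, UnderdeterminedError, ValidationError
from .model import (
    AccumulationAssay,
    KineticParams,
    eval_accumulation,
    eval_accumulation_with_treatment,
)

__all__ = [
    "SolverConfig",
    "FitResult",
    "AssayDataset",
    "fit_single_assay",
    "fit_dataset_shared",
    "fit_treatment_assay",
    "summarize_I",
]

#: a parameter closer than this to a bound is reported in ``bound_hits``
_BOUND_TOL = 1e-12


@dataclass(frozen=True)
class SolverConfig:
    """Settings for the bounded least-squares solver."""

    ftol: float = 1e-15
    xtol: float = 1e-15
    gtol: float = 1e-15
    max_nfev: int = 100_000
    guess_I: float = 1e-3
    guess_E: float = 1e-3
    guess_K: float = 0.0


@dataclass
class FitResult:
    """Optimised kinetic parameters with solver diagnostics."""

    params: Dict[str, KineticParams]
    shared_params: Optional[Tuple[float, float]] = None  # (E, K)
    residual_norm: float = 0.0
    converged: bool = False
    bound_hits: List[str] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)
    nfev: int = 0

    def single(self) -> KineticParams:
        """The parameters of the only assay in a single-assay fit."""
        if len(self.params) != 1:
            raise ValueError(f"fit holds {len(self.params)} assays, not one")
        return next(iter(self.params.values()))


@dataclass
class AssayDataset:
    """A collection of accumulation assays sharing one volume-correction factor."""

    assays: List[AccumulationAssay]
    f: float
    grouping: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.assays:
            raise ValidationError("dataset must contain at least one assay")
        if not (np.isfinite(self.f) and self.f > 0):
            raise ValidationError(f"f must be > 0, got {self.f!r}")
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate assay_id in dataset")
        for a in self.assays:
            if not np.isclose(a.f, self.f):
                raise ValidationError(
                    f"assay {a.assay_id!r} has f={a.f}, dataset f={self.f}"
                )


def _solve(residual_fn, x0, bounds, cfg: SolverConfig):
    x0 = np.maximum(np.asarray(x0, dtype=float), 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sub-eps tolerance notices from scipy
        sol = least_squares(
            residual_fn,
            x0,
            bounds=bounds,
            method="trf",
            ftol=cfg.ftol,
            xtol=cfg.xtol,
            gtol=cfg.gtol,
            max_nfev=cfg.max_nfev,
        )
    return sol


def _bound_hits(names: Sequence[str], x: np.ndarray) -> List[str]:
    return [n for n, v in zip(names, x) if v <= _BOUND_TOL]


def fit_single_assay(
    assay: AccumulationAssay, f: float, solver_cfg: Optional[SolverConfig] = None
) -> FitResult:
    """Fit (I, E, K) of the accumulation model to one assay."""
    cfg = solver_cfg or SolverConfig()
    if assay.n_points < 4:
        raise UnderdeterminedError(
            f"assay {assay.assay_id!r}: {assay.n_points} points for 3 free parameters"
        )
    t, c = assay.time_points, assay.concentrations

    def residual(x):
        return eval_accumulation(t, KineticParams(*x), assay.c0, f) - c

    sol = _solve(
        residual, [cfg.guess_I, cfg.guess_E, cfg.guess_K], (0.0, np.inf), cfg
    )
    I, E, K = sol.x
    hits = _bound_hits(["I", "E", "K"], sol.x)
    notes: List[str] = []
    # a fitted curve with negligible dynamic range carries no flux
    # information: I is effectively zero and E cannot be identified
    fitted = KineticParams(I, E, K)
    dyn_range = float(
        eval_accumulation(t[-1], fitted, assay.c0, f)
        - eval_accumulation(t[0], fitted, assay.c0, f)
    )
    scale = max(float(np.max(np.abs(c))), assay.c0 * 1e-12)
    if dyn_range < 1e-6 * scale:
        notes.append("flat trace carries no flux information: E unidentifiable")
    if not sol.success:
        notes.append(f"solver did not converge: {sol.message}")
    return FitResult(
        params={assay.assay_id: KineticParams(I, E, K)},
        residual_norm=float(2.0 * sol.cost),
        converged=bool(sol.success),
        bound_hits=hits,
        notes=notes,
        nfev=sol.nfev,
    )


def fit_dataset_shared(
    dataset: AssayDataset, solver_cfg: Optional[SolverConfig] = None
) -> FitResult:
    """Joint fit of all assays with per-assay I and shared (E, K).

    The parameter vector is (I_1, ..., I_n, E, K); residuals of all assays
    are stacked into one objective so that E and K are constrained to common
    values across the dataset.
    """
    cfg = solver_cfg or SolverConfig()
    assays = dataset.assays
    n = len(assays)
    n_points = sum(a.n_points for a in assays)
    if n_points < n + 2:
        raise UnderdeterminedError(
            f"{n_points} points for {n + 2} free parameters"
        )

    def residual(x):
        E, K = x[n], x[n + 1]
        res = [
            eval_accumulation(a.time_points, KineticParams(x[i], E, K), a.c0, dataset.f)
            - a.concentrations
            for i, a in enumerate(assays)
        ]
        return np.concatenate(res)

    x0 = [cfg.guess_I] * n + [cfg.guess_E, cfg.guess_K]
    sol = _solve(residual, x0, (0.0, np.inf), cfg)
    E, K = sol.x[n], sol.x[n + 1]
    names = [f"I[{a.assay_id}]" for a in assays] + ["E", "K"]
    params = {
        a.assay_id: KineticParams(sol.x[i], E, K) for i, a in enumerate(assays)
    }
    notes = [] if sol.success else [f"solver did not converge: {sol.message}"]
    return FitResult(
        params=params,
        shared_params=(float(E), float(K)),
        residual_norm=float(2.0 * sol.cost),
        converged=bool(sol.success),
        bound_hits=_bound_hits(names, sol.x),
        notes=notes,
        nfev=sol.nfev,
    )


def fit_treatment_assay(
    assay: AccumulationAssay, f: float, solver_cfg: Optional[SolverConfig] = None
) -> FitResult:
    """Fit (I, I', E, K) of the piecewise model to a mid-assay treatment trace.

    Falls back to the plain model (with a warning note) when the assay has no
    points after the treatment time.
    """
    cfg = solver_cfg or SolverConfig()
    if assay.t_prime is None:
        raise ConfigurationError(f"assay {assay.assay_id!r} has no t_prime")
    n_post = int(np.sum(assay.time_points > assay.t_prime))
    if n_post == 0:
        warnings.warn(
            f"assay {assay.assay_id!r}: no points after t_prime={assay.t_prime}; "
            "falling back to the untreated model"
        )
        res = fit_single_assay(assay, f, cfg)
        res.notes.append("no post-treatment points: I_prime not estimated")
        return res
    if assay.n_points < 5:
        raise UnderdeterminedError(
            f"assay {assay.assay_id!r}: {assay.n_points} points for 4 free parameters"
        )
    t, c = assay.time_points, assay.concentrations
    tp = assay.t_prime

    def residual(x):
        I, Ip, E, K = x
        p = KineticParams(I, E, K, I_prime=Ip)
        return eval_accumulation_with_treatment(t, p, tp, assay.c0, f) - c

    x0 = [cfg.guess_I, cfg.guess_I, cfg.guess_E, cfg.guess_K]
    sol = _solve(residual, x0, (0.0, np.inf), cfg)
    I, Ip, E, K = sol.x
    notes = [] if sol.success else [f"solver did not converge: {sol.message}"]
    return FitResult(
        params={assay.assay_id: KineticParams(I, E, K, I_prime=Ip)},
        residual_norm=float(2.0 * sol.cost),
        converged=bool(sol.success),
        bound_hits=_bound_hits(["I", "I_prime", "E", "K"], sol.x),
        notes=notes,
        nfev=sol.nfev,
    )


def summarize_I(
    fits: Iterable[FitResult], grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Median influx constant per condition group.

    Parameters
    ----------
    fits : iterable of FitResult
        Any mix of single-assay and joint fits; per-assay I values are pooled.
    grouping : mapping assay_id -> group label
        Assays without a group entry are ignored with a warning.

    Returns
    -------
    DataFrame with one row per group: ``group``, ``n_assays``, ``median_I``
    and the per-assay values in ``I_values``.  Medians use the standard
    midpoint convention for even counts.
    """
    per_group: Dict[str, List[float]] = {}
    for fit in fits:
        for assay_id, p in fit.params.items():
            if assay_id not in grouping:
                warnings.warn(f"assay {assay_id!r} has no group assignment; skipped")
                continue
            per_group.setdefault(grouping[assay_id], []).append(p.I)
    for g in set(grouping.values()) - set(per_group):
        warnings.warn(f"group {g!r} has no fitted assays; omitted")
    rows = [
        {
            "group": g,
            "n_assays": len(vals),
            "median_I": float(np.median(vals)),
            "I_values": sorted(vals),
        }
        for g, vals in sorted(per_group.items())
    ]
    return pd.DataFrame(rows, columns=["group", "n_assays", "median_I", "I_values"])
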