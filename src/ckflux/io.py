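"""Table and image readers/writers plus configuration handling.

All tables are comma-separated UTF-8 with a mandatory header row and ``.``
as the decimal mark.

Assay schema (long format, one row per sampled time point)::

    assay_id,time_s,conc_nM,c0_nM,f,t_prime_s,tracer,competitor,
    competitor_conc_nM,treatment,replicate

An empty ``t_prime_s`` means no mid-assay treatment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .dose_response import DoseResponseSeries, SaturationFit
from .errors import ConfigurationError, SchemaError
from .fitting import AssayDataset, FitResult
from .model import AccumulationAssay
from .segmentation import SegmentationConfig

__all__ = [
    "ASSAY_COLUMNS",
    "read_assays",
    "write_assays",
    "write_fit_results",
    "read_dose_response_series",
    "write_saturation_fits",
    "read_qpcr",
    "read_image",
    "write_label_mask",
    "PipelineConfig",
]

ASSAY_COLUMNS = [
    "assay_id",
    "time_s",
    "conc_nM",
    "c0_nM",
    "f",
    "t_prime_s",
    "tracer",
    "competitor",
    "competitor_conc_nM",
    "treatment",
    "replicate",
]

_META_COLUMNS = ["tracer", "competitor", "competitor_conc_nM", "treatment", "replicate"]


def read_assays(path: Union[str, Path]) -> AssayDataset:
    """Read a long-format assay table into a validated dataset."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"assay_id": str}, float_precision="round_trip")
    missing = [c for c in ("assay_id", "time_s", "conc_nM", "c0_nM", "f") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    assays = []
    f_values = []
    for assay_id, rows in df.groupby("assay_id", sort=False):
        rows = rows.reset_index()  # keep original row numbers for messages
        t = rows["time_s"].to_numpy(dtype=float)
        order = np.argsort(t, kind="stable")
        rows = rows.iloc[order]
        t = t[order]
        dup = np.flatnonzero(np.diff(t) <= 0)
        if dup.size:
            bad = rows.iloc[dup[0] + 1]
            raise SchemaError(
                f"{path}: assay {assay_id!r} has repeated/non-increasing time "
                f"{bad['time_s']} (file row {int(bad['index']) + 2})"
            )
        c = rows["conc_nM"].to_numpy(dtype=float)
        neg = np.flatnonzero(c < 0)
        if neg.size:
            bad = rows.iloc[neg[0]]
            raise SchemaError(
                f"{path}: assay {assay_id!r} has negative concentration "
                f"{bad['conc_nM']} (file row {int(bad['index']) + 2})"
            )
        c0 = rows["c0_nM"].iloc[0]
        f_val = rows["f"].iloc[0]
        if rows["c0_nM"].nunique() > 1 or rows["f"].nunique() > 1:
            raise SchemaError(f"{path}: assay {assay_id!r} has inconsistent c0/f values")
        t_prime = None
        if "t_prime_s" in rows.columns:
            tp = rows["t_prime_s"].iloc[0]
            if pd.notna(tp):
                t_prime = float(tp)
        condition = {}
        for col in _META_COLUMNS:
            if col in rows.columns and pd.notna(rows[col].iloc[0]):
                condition[col] = rows[col].iloc[0]
        try:
            assays.append(
                AccumulationAssay(
                    assay_id=str(assay_id),
                    time_points=t,
                    concentrations=c,
                    c0=float(c0),
                    f=float(f_val),
                    t_prime=t_prime,
                    condition=condition,
                )
            )
        except Exception as exc:
            raise SchemaError(f"{path}: assay {assay_id!r}: {exc}") from exc
        f_values.append(float(f_val))
    if not assays:
        raise SchemaError(f"{path}: no assays found")
    if len(set(f_values)) > 1:
        raise SchemaError(f"{path}: inconsistent f across assays: {sorted(set(f_values))}")
    grouping = {
        a.assay_id: str(a.condition.get("tracer", "")) for a in assays
    }
    return AssayDataset(assays=assays, f=f_values[0], grouping=grouping)


def write_assays(dataset: AssayDataset, path: Union[str, Path]) -> None:
    """Write a dataset back to the long-format schema (lossless round-trip)."""
    rows = []
    for a in dataset.assays:
        for t, c in zip(a.time_points, a.concentrations):
            rows.append(
                {
                    "assay_id": a.assay_id,
                    "time_s": repr(float(t)),
                    "conc_nM": repr(float(c)),
                    "c0_nM": repr(float(a.c0)),
                    "f": repr(float(a.f)),
                    "t_prime_s": "" if a.t_prime is None else repr(float(a.t_prime)),
                    **{col: a.condition.get(col, "") for col in _META_COLUMNS},
                }
            )
    pd.DataFrame(rows, columns=ASSAY_COLUMNS).to_csv(path, index=False)


def write_fit_results(
    fits: List[FitResult], path: Union[str, Path], shared: bool = False
) -> None:
    """Write fitted parameters: one row per assay."""
    rows = []
    for fit in fits:
        for assay_id, p in fit.params.items():
            rows.append(
                {
                    "assay_id": assay_id,
                    "I_per_s": p.I,
                    "I_prime_per_s": "" if p.I_prime is None else p.I_prime,
                    "E_per_s": p.E,
                    "K": p.K,
                    "shared_fit": fit.shared_params is not None,
                    "residual_norm": fit.residual_norm,
                    "converged": fit.converged,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dose_response_series(path: Union[str, Path]) -> List[DoseResponseSeries]:
    """Read ``tracer,competitor,competitor_conc_nM,I_per_s`` into series."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"tracer", "competitor", "competitor_conc_nM", "I_per_s"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    out = []
    for (tracer, competitor), rows in df.groupby(["tracer", "competitor"], sort=False):
        rows = rows.sort_values("competitor_conc_nM")
        out.append(
            DoseResponseSeries(
                competitor_conc=rows["competitor_conc_nM"].to_numpy(dtype=float),
                I_values=rows["I_per_s"].to_numpy(dtype=float),
                tracer=str(tracer),
                competitor=str(competitor),
            )
        )
    return out


def write_saturation_fits(
    fits: Dict[tuple, SaturationFit], path: Union[str, Path]
) -> None:
    """Write saturation fits: ``tracer,competitor,v_lim,IC50_nM,D_per_s,no_saturation_flag``."""
    rows = [
        {
            "tracer": tracer,
            "competitor": competitor,
            "v_lim": fit.params.v_lim,
            "IC50_nM": fit.params.ic50,
            "D_per_s": fit.params.D,
            "no_saturation_flag": fit.no_saturation,
        }
        for (tracer, competitor), fit in fits.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_qpcr(path: Union[str, Path]) -> pd.DataFrame:
    """Read a crossing-point table ``sample_id,genotype,cp_target,cp_ref1,cp_ref2``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    required = {"sample_id", "cp_target", "cp_ref1", "cp_ref2"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read a PNG/TIFF scan as an RGB array (alpha channel dropped)."""
    import imageio.v3 as iio

    img = iio.imread(Path(path))
    if img.ndim == 3 and img.shape[-1] == 4:
        img = img[..., :3]
    return img


def write_label_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    """Write an integer label mask as 16-bit PNG."""
    import imageio.v3 as iio

    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    iio.imwrite(Path(path), mask.astype(np.uint16))


@dataclass
class PipelineConfig:
    """Serializable configuration of a full pipeline run."""

    f: float = 0.05
    seed: int = 0
    out_dir: str = "ckflux_out"
    log_level: str = "INFO"
    # solver
    ftol: float = 1e-15
    xtol: float = 1e-15
    max_nfev: int = 100_000
    shared_ek: bool = True
    group_by: str = "tracer"
    # simulation
    sim_n_assays: int = 6
    sim_noise_sd: float = 0.04
    sim_c0: float = 2.0
    sim_t_end: float = 900.0
    sim_n_points: int = 12
    # segmentation
    a_max: float = -9.5
    b_min: float = -9.5
    L_min: float = 18.5
    min_size_pre: int = 2048
    closing_radius: int = 8
    min_size_post: int = 8192
    # stage inputs (optional; simulate writes them when absent)
    assays_csv: Optional[str] = None
    image_path: Optional[str] = None
    qpcr_csv: Optional[str] = None
    dpi: Optional[float] = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run logs."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            a_max=self.a_max,
            b_min=self.b_min,
            L_min=self.L_min,
            min_size_pre=self.min_size_pre,
            closing_radius=self.closing_radius,
            min_size_post=self.min_size_post,
        )
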