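"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions of a BY-2 radio-accumulation
campaign: regularly sampled accumulation curves over 0-900 s at an initial
extracellular tracer concentration of 2 nM, dose-response ladders at
competitor concentrations of 0/2/20/200/2000/20000 nM, top-view scans of
green rosette blobs on a light background with sub-threshold distractor
objects, and qPCR plates with two reference genes.  Every generator is
deterministic given its seed and returns a machine-readable truth record
alongside the data so that recovery tests never rely on hard-coded numbers.

Measurement noise on accumulation curves is additive Gaussian truncated at
zero with a default standard deviation of 2% of c0 (0.04 nM at the default
c0 = 2 nM); the underlying counting noise of the original scintillation
measurements is not modelled in more detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .dose_response import SaturationParams, eval_saturation
from .errors import ValidationError
from .fitting import AssayDataset
from .model import (
    AccumulationAssay,
    KineticParams,
    eval_accumulation,
    eval_accumulation_with_treatment,
)

__all__ = [
    "SimulationDesign",
    "COMPETITOR_LADDER_NM",
    "ROSETTE_GREEN",
    "simulate_assay",
    "simulate_competition_experiment",
    "render_shoot_scene",
    "ShootScene",
    "simulate_qpcr_plate",
]

#: competitor concentration ladder of the dose-response design, nM
COMPETITOR_LADDER_NM: Tuple[float, ...] = (0.0, 2.0, 20.0, 200.0, 2000.0, 20000.0)

#: sRGB foreground colour of rendered rosettes; its L*a*b* coordinates
#: (L* 61.8, a* -51.7, b* 41.8) pass the default segmentation thresholds
ROSETTE_GREEN: Tuple[int, int, int] = (60, 170, 70)

#: near-white scan background (fails the a* threshold)
SCAN_BACKGROUND: Tuple[int, int, int] = (245, 245, 245)


@dataclass(frozen=True)
class SimulationDesign:
    """Sampling design of a simulated radio-accumulation assay.

    Defaults mirror the experimental design: 12 regular samples over
    0-900 s, c0 = 2 nM, volume-correction factor f = 0.05, measurement
    noise of 2% of c0, and (for mid-assay treatment designs) a treatment
    7 min after tracer addition.
    """

    time_grid: Tuple[float, ...] = tuple(np.linspace(0.0, 900.0, 12))
    c0: float = 2.0
    f: float = 0.05
    noise_sd: float = 0.04  # nM
    seed: Optional[int] = None
    t_prime: Optional[float] = None  # seconds; 420 for treatment designs

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if len(self.time_grid) < 2 or np.any(np.diff(self.time_grid) <= 0):
            raise ValidationError("time_grid must be strictly increasing")

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValidationError("a seed must be set explicitly for stochastic simulation")
        return np.random.default_rng(self.seed)


def simulate_assay(
    truth: KineticParams,
    design: SimulationDesign,
    assay_id: str = "sim",
    condition: Optional[dict] = None,
) -> Tuple[AccumulationAssay, Dict]:
    """Sample one accumulation curve from known parameters.

    Uses the mid-assay treatment model when both ``design.t_prime`` and
    ``truth.I_prime`` are set.  Gaussian noise (sd ``design.noise_sd``) is
    added and truncated at zero.  Returns the assay and a truth record.
    """
    t = np.asarray(design.time_grid, dtype=float)
    if design.t_prime is not None and truth.I_prime is not None:
        clean = eval_accumulation_with_treatment(
            t, truth, design.t_prime, design.c0, design.f
        )
    else:
        clean = eval_accumulation(t, truth, design.c0, design.f)
    if design.noise_sd > 0:
        noisy = np.maximum(0.0, clean + design.rng().normal(0.0, design.noise_sd, t.shape))
    else:
        noisy = clean
    assay = AccumulationAssay(
        assay_id=assay_id,
        time_points=t,
        concentrations=noisy,
        c0=design.c0,
        f=design.f,
        t_prime=design.t_prime if truth.I_prime is not None else None,
        condition=dict(condition or {}),
    )
    truth_record = {
        "assay_id": assay_id,
        "I": truth.I,
        "E": truth.E,
        "K": truth.K,
        "I_prime": truth.I_prime,
        "t_prime": design.t_prime,
        "c0": design.c0,
        "f": design.f,
        "noise_sd": design.noise_sd,
        "seed": design.seed,
    }
    return assay, truth_record


def simulate_competition_experiment(
    truth_sat: SaturationParams,
    shared_E: float,
    shared_K: float,
    design: SimulationDesign,
    ladder: Sequence[float] = COMPETITOR_LADDER_NM,
    tracer: str = "tracer",
    competitor: str = "competitor",
) -> Tuple[AssayDataset, Dict]:
    """Simulate a full dose-response campaign on a competitor ladder.

    For each competitor concentration c_K the true influx constant is set to
    the saturation model value I(c_K); one assay is simulated per rung with
    the shared efflux and adsorption parameters.  Pushing the result through
    the joint fit and the saturation fit recovers ``truth_sat``.
    """
    if len(ladder) == 0:
        raise ValidationError("ladder must be non-empty")
    seeds = (
        np.random.SeedSequence(design.seed).generate_state(len(ladder)) % (2**31)
        if design.seed is not None
        else [None] * len(ladder)
    )
    assays: List[AccumulationAssay] = []
    truths: List[Dict] = []
    for i, cK in enumerate(ladder):
        I_true = float(eval_saturation(cK, truth_sat))
        sub = replace(design, seed=None if seeds[i] is None else int(seeds[i]))
        assay, rec = simulate_assay(
            KineticParams(I=I_true, E=shared_E, K=shared_K),
            sub,
            assay_id=f"{tracer}_cK{cK:g}",
            condition={
                "tracer": tracer,
                "competitor": competitor,
                "competitor_conc_nM": float(cK),
            },
        )
        assays.append(assay)
        truths.append(rec)
    dataset = AssayDataset(
        assays=assays,
        f=design.f,
        grouping={a.assay_id: tracer for a in assays},
    )
    truth = {
        "v_lim": truth_sat.v_lim,
        "ic50": truth_sat.ic50,
        "D": truth_sat.D,
        "shared_E": shared_E,
        "shared_K": shared_K,
        "ladder_nM": [float(c) for c in ladder],
        "assays": truths,
    }
    return dataset, truth


@dataclass
class ShootScene:
    """Rendered scan with its exact ground truth."""

    image: np.ndarray  # uint8 RGB
    truth_mask: np.ndarray  # int labels of foreground blobs (merged if touching)
    truth_areas: np.ndarray  # pixel counts per label
    distractor_mask: np.ndarray  # bool, sub-threshold foreground-coloured objects


def _paint(mask: np.ndarray, shape) -> None:
    if len(shape) == 2 and np.isscalar(shape[1]):  # (center, radius) disk
        rr, cc = draw_disk(shape[0], shape[1], shape=mask.shape)
    else:  # polygon vertices (rows, cols)
        rows, cols = np.asarray(shape[0]), np.asarray(shape[1])
        rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True


def render_shoot_scene(
    blobs: Sequence,
    distractors: Sequence = (),
    canvas: Tuple[int, int] = (600, 800),
    seed: int = 0,
    blob_color: Tuple[int, int, int] = ROSETTE_GREEN,
    background: Tuple[int, int, int] = SCAN_BACKGROUND,
) -> ShootScene:
    """Render solid rosette blobs plus sub-2048-px distractors on a scan.

    ``blobs`` and ``distractors`` are sequences of either ``(center, radius)``
    disks or ``(rows, cols)`` polygons (image coordinates).  Blobs are painted
    in a green whose L*a*b* values pass the default segmentation thresholds;
    distractors use the same colour but must each stay below the 2048-px
    pre-filter.  Overlapping blobs merge in the ground truth.  The seed only
    controls the faint background texture; rendering is bit-reproducible.
    """
    from skimage.measure import label as _label

    h, w = canvas
    rng = np.random.default_rng(seed)
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[...] = np.asarray(background, dtype=np.uint8)
    # faint grey paper texture; stays far from the a* threshold
    texture = rng.integers(-4, 5, size=(h, w, 1))
    image = np.clip(image.astype(int) + texture, 0, 255).astype(np.uint8)

    blob_mask = np.zeros((h, w), dtype=bool)
    for shape in blobs:
        _paint(blob_mask, shape)
    distractor_mask = np.zeros((h, w), dtype=bool)
    for shape in distractors:
        single = np.zeros((h, w), dtype=bool)
        _paint(single, shape)
        if single.sum() >= 2048:
            raise ValidationError(
                f"distractor of {single.sum()} px is not below the 2048-px pre-filter"
            )
        distractor_mask |= single

    image[blob_mask | distractor_mask] = np.asarray(blob_color, dtype=np.uint8)
    labels = _label(blob_mask, connectivity=1)
    n = int(labels.max())
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(np.int64)
    return ShootScene(
        image=image,
        truth_mask=labels,
        truth_areas=areas,
        distractor_mask=distractor_mask,
    )


def simulate_qpcr_plate(
    true_rel: Dict[str, float],
    ref_cp: Union[float, Tuple[float, float]] = (20.0, 22.0),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    genotypes: Optional[Dict[str, str]] = None,
) -> Tuple[pd.DataFrame, Dict]:
    """Generate a crossing-point table realising known relative expressions.

    The target crossing point of each sample is placed log2(REL) cycles below
    the mean of the two reference crossing points, plus optional Gaussian
    noise (in cycles).  With ``noise_sd = 0`` the computed REL of every row
    equals its true value exactly.
    """
    if isinstance(ref_cp, (int, float)):
        ref1 = ref2 = float(ref_cp)
    else:
        ref1, ref2 = (float(ref_cp[0]), float(ref_cp[1]))
    mean_ref = (ref1 + ref2) / 2.0
    for sample, rel in true_rel.items():
        if not (np.isfinite(rel) and rel > 0):
            raise ValidationError(f"true_rel for {sample!r} must be > 0, got {rel!r}")
    if noise_sd > 0 and seed is None:
        raise ValidationError("a seed must be set explicitly for stochastic simulation")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, rel in true_rel.items():
        cp = mean_ref - np.log2(rel)
        if noise_sd > 0:
            cp += rng.normal(0.0, noise_sd)
        rows.append(
            {
                "sample_id": sample,
                "genotype": (genotypes or {}).get(sample, ""),
                "cp_target": float(cp),
                "cp_ref1": ref1,
                "cp_ref2": ref2,
            }
        )
    truth = {"true_rel": dict(true_rel), "ref_cp": (ref1, ref2), "noise_sd": noise_sd, "seed": seed}
    return pd.DataFrame(rows), truth
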