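"""Top-view shoot-area measurement from RGB scans.

Rosettes scanned on a light background are segmented in the CIELAB colour
space: green tissue is selected by fixed thresholds (a* <= -9.5,
b* >= -9.5, L* >= 18.5, chosen from multi-Otsu estimates), small debris is
removed before and after a morphological closing with a disk footprint, and
the pixel areas of the remaining connected objects are reported.

Input images are assumed to be sRGB (D65 white point) with L* in [0, 100]
and signed a*/b*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from skimage.color import rgb2lab
from skimage.measure import label
from skimage.morphology import closing, disk, remove_small_objects

from .errors import ValidationError

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "estimate_thresholds",
    "segment_shoots",
    "areas_report",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and morphological settings of the segmentation recipe."""

    a_max: float = -9.5  # keep pixels with a* <= a_max
    b_min: float = -9.5  # keep pixels with b* >= b_min
    L_min: float = 18.5  # keep pixels with L* >= L_min
    min_size_pre: int = 2048  # px, removed before closing
    closing_radius: int = 8  # px, disk footprint radius
    min_size_post: int = 8192  # px, removed after closing
    connectivity: int = 1  # 1 = faces only (4-connectivity)

    def __post_init__(self) -> None:
        for name in ("min_size_pre", "closing_radius", "min_size_post"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        if self.connectivity not in (1, 2):
            raise ValidationError("connectivity must be 1 or 2")
        for name in ("a_max", "b_min", "L_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


@dataclass
class SegmentationResult:
    """Labeled shoot mask and per-object pixel areas."""

    label_mask: np.ndarray  # int labels, 0 = background, objects 1..n
    areas: np.ndarray  # pixel counts, indexed by label - 1
    object_count: int


def _require_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValidationError(
            f"expected a 3-channel RGB image, got shape {image.shape}"
        )
    return image


def estimate_thresholds(
    rgb_image: np.ndarray, classes: int = 3
) -> Dict[str, Dict[str, object]]:
    """Multi-Otsu class boundaries of each L*a*b* channel.

    Advisory only: the segmentation default uses fixed thresholds, which were
    themselves chosen from such estimates.  Returns, per channel, the sorted
    boundary values and a ``degenerate`` flag for channels whose histogram
    cannot support the requested number of classes (e.g. a uniform image).
    """
    from skimage.filters import threshold_multiotsu

    lab = rgb2lab(_require_rgb(rgb_image))
    out: Dict[str, Dict[str, object]] = {}
    for i, name in enumerate(("L", "a", "b")):
        channel = lab[..., i]
        entry: Dict[str, object] = {"thresholds": np.array([]), "classes_used": 0, "degenerate": True}
        # a channel with few distinct values (e.g. a two-tone scan) cannot be
        # split into the requested number of classes; fall back gracefully
        for k in range(classes, 1, -1):
            try:
                thr = threshold_multiotsu(channel, classes=k)
            except ValueError:
                continue
            entry = {
                "thresholds": np.asarray(thr, dtype=float),
                "classes_used": k,
                "degenerate": False,
            }
            break
        out[name] = entry
    return out


def segment_shoots(
    rgb_image: np.ndarray, cfg: Optional[SegmentationConfig] = None
) -> SegmentationResult:
    """Segment green shoots and measure their pixel areas.

    Pipeline order: RGB -> L*a*b*; threshold mask; remove components smaller
    than ``min_size_pre``; morphological closing with a disk of
    ``closing_radius``; remove components smaller than ``min_size_post``;
    label and count.  An image with no passing objects yields a valid result
    with ``object_count == 0``.
    """
    cfg = cfg or SegmentationConfig()
    lab = rgb2lab(_require_rgb(rgb_image))
    mask = (
        (lab[..., 1] <= cfg.a_max)
        & (lab[..., 2] >= cfg.b_min)
        & (lab[..., 0] >= cfg.L_min)
    )
    # "smaller than N px" is strict: an object of exactly N px survives
    mask = remove_small_objects(
        mask, max_size=cfg.min_size_pre - 1, connectivity=cfg.connectivity
    )
    mask = closing(mask, disk(cfg.closing_radius))
    mask = remove_small_objects(
        mask, max_size=cfg.min_size_post - 1, connectivity=cfg.connectivity
    )
    labels = label(mask, connectivity=cfg.connectivity)
    n = int(labels.max())
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(np.int64)
    return SegmentationResult(label_mask=labels, areas=areas, object_count=n)


def areas_report(
    result: SegmentationResult, dpi: Optional[float] = None
) -> pd.DataFrame:
    """Tabulate object areas in pixels and, if a scan resolution is given, mm^2.

    ``mm^2 = px * (25.4 / dpi)^2``.  Rows are sorted by descending area.
    """
    if dpi is not None and dpi <= 0:
        raise ValidationError(f"dpi must be positive, got {dpi!r}")
    rows: List[dict] = []
    order = np.argsort(result.areas)[::-1]
    for rank, idx in enumerate(order, start=1):
        row = {"label": int(idx + 1), "area_px": int(result.areas[idx])}
        if dpi is not None:
            row["area_mm2"] = float(result.areas[idx]) * (25.4 / dpi) ** 2
        rows.append(row)
    columns = ["label", "area_px"] + (["area_mm2"] if dpi is not None else [])
    return pd.DataFrame(rows, columns=columns)
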