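"""Nuclear-fraction quantification from segmented immunofluorescence records.

Works on per-cell nuclear intensity records (NF-kB and DAPI channels) plus
per-frame totals and background means, as produced by confocal image
segmentation.  The nuclear NF-kB fraction of cell *i* is

    frac_i = (In_i^NFkB / I*^NFkB) * (I*^DAPI / In_i^DAPI)

on background-corrected intensities (each raw sum minus area times the mean
background pixel intensity of its frame and channel).  The DAPI ratio
corrects for out-of-focus displacement, which attenuates a cell equally in
both channels.

The module also inverts the cytoplasmic-interference (CI) bias of confocal
readouts: a fraction ``ci`` (population default 0.24) of cytoplasmic
fluorescence located above and below the nucleus registers as nuclear, so an
observed nuclear fraction relates to the true one by
``x_obs = x + ci * (1 - x)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellIntensityRecord",
    "FrameRecord",
    "TranslocationHistogram",
    "nuclear_fraction",
    "quantify_table",
    "ci_apply",
    "ci_invert",
    "build_histogram",
    "DEFAULT_CI",
    "DEFAULT_BIN_WIDTH",
]

logger = logging.getLogger(__name__)

DEFAULT_CI = 0.24
DEFAULT_BIN_WIDTH = 0.05

CELL_COLUMNS = [
    "cell_id",
    "frame_id",
    "nuc_intensity_nfkb",
    "nuc_intensity_dapi",
    "nuc_area_nfkb",
    "nuc_area_dapi",
]
FRAME_COLUMNS = [
    "frame_id",
    "total_intensity_nfkb",
    "total_intensity_dapi",
    "area_nfkb",
    "area_dapi",
    "bg_mean_nfkb",
    "bg_mean_dapi",
]


@dataclass(frozen=True)
class CellIntensityRecord:
    """Summed nuclear pixel intensities and areas for one segmented cell."""

    nuc_intensity_nfkb: float
    nuc_intensity_dapi: float
    nuc_area_nfkb: float
    nuc_area_dapi: float
    frame_id: object = None

    def __post_init__(self):
        if self.nuc_intensity_nfkb < 0 or self.nuc_intensity_dapi < 0:
            raise ValueError("intensities must be non-negative")
        if self.nuc_area_nfkb <= 0 or self.nuc_area_dapi <= 0:
            raise ValueError("areas must be positive")


@dataclass(frozen=True)
class FrameRecord:
    """Whole-frame totals and background means (>= 3 cell-free regions)."""

    total_intensity_nfkb: float
    total_intensity_dapi: float
    area_nfkb: float
    area_dapi: float
    bg_mean_nfkb: float = 0.0
    bg_mean_dapi: float = 0.0
    frame_id: object = None

    def __post_init__(self):
        if self.total_intensity_nfkb < 0 or self.total_intensity_dapi < 0:
            raise ValueError("totals must be non-negative")
        if self.area_nfkb <= 0 or self.area_dapi <= 0:
            raise ValueError("areas must be positive")
        if self.bg_mean_nfkb < 0 or self.bg_mean_dapi < 0:
            raise ValueError("background means must be non-negative")


@dataclass(frozen=True)
class TranslocationHistogram:
    """Fixed-width histogram of normalized nuclear translocation values."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_cells: int
    mean: float


class ExcludedRecordError(ValueError):
    """Raised for a record whose corrected DAPI nuclear intensity is <= 0."""


def _corrected(intensity: float, area: float, bg_mean: float) -> float:
    return intensity - area * bg_mean


def nuclear_fraction(cell: CellIntensityRecord, frame: FrameRecord) -> float:
    """Background-corrected, DAPI-normalized nuclear NF-kB fraction of one cell.

    Raises :class:`ExcludedRecordError` when the background-corrected DAPI
    nuclear intensity is non-positive (malformed nucleus); such records are
    excluded from population statistics and counted in the run log.
    """
    in_nfkb = _corrected(cell.nuc_intensity_nfkb, cell.nuc_area_nfkb, frame.bg_mean_nfkb)
    in_dapi = _corrected(cell.nuc_intensity_dapi, cell.nuc_area_dapi, frame.bg_mean_dapi)
    tot_nfkb = _corrected(frame.total_intensity_nfkb, frame.area_nfkb, frame.bg_mean_nfkb)
    tot_dapi = _corrected(frame.total_intensity_dapi, frame.area_dapi, frame.bg_mean_dapi)
    if in_dapi <= 0:
        raise ExcludedRecordError(
            "non-positive corrected DAPI nuclear intensity; record excluded"
        )
    if tot_nfkb <= 0 or tot_dapi <= 0:
        raise ExcludedRecordError(
            "non-positive corrected frame intensity; record excluded"
        )
    return (in_nfkb / tot_nfkb) * (tot_dapi / in_dapi)


def quantify_table(cells: pd.DataFrame, frames: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Nuclear fractions for a per-cell table joined with its per-frame table.

    Returns ``(fractions, n_excluded)`` where ``fractions`` has columns
    ``cell_id, frame_id, nuclear_fraction`` (excluded records dropped) and
    ``n_excluded`` counts records with non-positive corrected DAPI signal.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    missing = [c for c in FRAME_COLUMNS if c not in frames.columns]
    if missing:
        raise ValueError(f"frame table missing columns: {missing}")
    df = cells.merge(frames, on="frame_id", how="left", validate="many_to_one")
    if df["total_intensity_nfkb"].isna().any():
        raise ValueError("some cells reference unknown frame_id")
    in_nfkb = df["nuc_intensity_nfkb"] - df["nuc_area_nfkb"] * df["bg_mean_nfkb"]
    in_dapi = df["nuc_intensity_dapi"] - df["nuc_area_dapi"] * df["bg_mean_dapi"]
    tot_nfkb = df["total_intensity_nfkb"] - df["area_nfkb"] * df["bg_mean_nfkb"]
    tot_dapi = df["total_intensity_dapi"] - df["area_dapi"] * df["bg_mean_dapi"]
    ok = (in_dapi > 0) & (tot_nfkb > 0) & (tot_dapi > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("excluded %d record(s) with non-positive corrected signal", n_excluded)
    frac = (in_nfkb / tot_nfkb) * (tot_dapi / in_dapi)
    out = pd.DataFrame(
        {
            "cell_id": df.loc[ok, "cell_id"],
            "frame_id": df.loc[ok, "frame_id"],
            "nuclear_fraction": frac[ok],
        }
    ).reset_index(drop=True)
    return out, n_excluded


def ci_apply(x: float, ci: float = DEFAULT_CI):
    """Observed nuclear fraction under cytoplasmic interference: x + ci*(1-x)."""
    if not 0.0 <= ci < 1.0:
        raise ValueError("ci must lie in [0, 1)")
    return x + ci * (1.0 - np.asarray(x, dtype=float))


def ci_invert(x_obs: float, ci: float = DEFAULT_CI):
    """True nuclear fraction from an observed one: (x_obs - ci) / (1 - ci)."""
    if not 0.0 <= ci < 1.0:
        raise ValueError("ci must lie in [0, 1)")
    arr = np.asarray(x_obs, dtype=float)
    if np.any(arr < ci):
        raise ValueError(
            "observed fraction below the interference level would imply "
            "negative nuclear content"
        )
    return (arr - ci) / (1.0 - ci)


def build_histogram(fractions, bin_width: float = DEFAULT_BIN_WIDTH) -> TranslocationHistogram:
    """Fixed-width histogram (bins anchored at 0) of translocation values."""
    arr = np.asarray(fractions, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("fractions must be non-empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(arr.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(arr, bins=edges)
    return TranslocationHistogram(
        bin_edges=edges, counts=counts, n_cells=arr.size, mean=float(arr.mean())
    )
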