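"""Signal transforms from raw imaging/counting channels to model observables.

Live-cell imaging yields, per frame: a coverage (confluence) mask, a
dead-cell marker channel (nuclear dye that only enters dead cells), and the
oxidized and reduced channels of a ratiometric lipid-peroxidation reporter.
The transforms here reproduce the normalisations used downstream by the
fitting module:

* dead-cell counts normalised to confluence (accounts for seeding density),
* the oxidized/reduced reporter ratio (lipid ROS readout),
* exclusion of dead-cell signal by thresholding the dead marker, dilating
  the resulting mask, and intersecting with the coverage mask,
* cellular lipid ROS = live-cell ROS signal divided by live confluence,
* flow-cytometry MFI normalisation to a per-replicate reference group,
* population doublings from seeded and counted cell numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

__all__ = [
    "ChannelFrame",
    "LiveCellMeasurement",
    "UndefinedRatioError",
    "oxred_ratio",
    "dead_to_confluence",
    "population_doublings",
    "mfi_normalize",
    "dead_mask",
    "live_cell_measurement",
]


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a ratio's denominator is zero (never returns infinity)."""


@dataclass(frozen=True)
class ChannelFrame:
    """One multi-channel imaging frame.

    All images must share a shape; intensities are non-negative.
    ``pixel_size_um`` is optional metadata.
    """

    coverage: np.ndarray  # boolean cell-coverage mask
    dead: np.ndarray  # dead-marker intensity image
    oxidized: np.ndarray  # oxidized reporter channel
    reduced: np.ndarray  # reduced reporter channel
    time_h: float = 0.0
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        cov = np.asarray(self.coverage, dtype=bool)
        object.__setattr__(self, "coverage", cov)
        for name in ("dead", "oxidized", "reduced"):
            img = np.asarray(getattr(self, name), dtype=float)
            if img.shape != cov.shape:
                raise ValueError(f"channel {name!r} shape {img.shape} != coverage {cov.shape}")
            if np.any(img < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            object.__setattr__(self, name, img)


@dataclass(frozen=True)
class LiveCellMeasurement:
    """Per-frame summary after dead-cell exclusion.

    ``live_lipid_ros`` and ``cellular_lipid_ros`` are NaN (flagged
    undefined) when the live mask is empty.
    """

    live_confluence: float
    live_lipid_ros: float
    cellular_lipid_ros: float
    dead_area_fraction: float
    time_h: float = 0.0

    @property
    def defined(self) -> bool:
        return not np.isnan(self.live_lipid_ros)


def oxred_ratio(ox_signal: float, red_signal: float) -> float:
    """Oxidized/reduced reporter ratio, the lipid ROS readout."""
    if ox_signal < 0 or red_signal < 0:
        raise ValueError("signals must be >= 0")
    if red_signal == 0:
        raise UndefinedRatioError("reduced-channel signal is zero; ratio undefined")
    return ox_signal / red_signal


def dead_to_confluence(dead_count: float, confluence_pct: float) -> float:
    """Dead-cell count normalised to confluence (density-corrected death)."""
    if dead_count < 0 or confluence_pct < 0:
        raise ValueError("inputs must be >= 0")
    if confluence_pct == 0:
        raise UndefinedRatioError("confluence is zero; normalised death undefined")
    return dead_count / confluence_pct


def population_doublings(cells_seeded: float, cells_counted: float) -> float:
    """log2(cells counted) - log2(cells seeded); negative if the population shrank."""
    if cells_seeded <= 0 or cells_counted <= 0:
        raise ValueError("cell counts must be > 0")
    return float(np.log2(cells_counted) - np.log2(cells_seeded))


def mfi_normalize(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Normalise fluorescence intensities to a per-replicate reference.

    ``values`` has one row per replicate (or is 1-D with one entry per
    replicate); ``reference`` gives each replicate's reference-group value
    (e.g. the low-density reading at 24 h).  Each row is divided by its
    replicate's reference, so the reference entries map to 1.0.
    """
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference values must be > 0")
    if values.ndim == 1:
        if reference.shape not in ((), values.shape):
            raise ValueError("reference must be scalar or match values")
        return values / reference
    if reference.shape != (values.shape[0],):
        raise ValueError("need one reference value per replicate row")
    return values / reference[:, None]


def dead_mask(frame: ChannelFrame, threshold: float | None = None, dilation_radius: int = 3) -> np.ndarray:
    """Boolean dead-cell mask: threshold the dead marker, then dilate.

    With ``threshold=None`` an Otsu threshold is computed from the dead
    channel (an all-background channel yields an empty mask).  Dilation
    uses a discrete disk of the given radius, so the result is always a
    superset of the plain threshold mask.
    """
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    img = frame.dead
    if threshold is None:
        if img.max() == img.min():
            return np.zeros(img.shape, dtype=bool)
        threshold = threshold_otsu(img)
    mask = img > threshold
    if dilation_radius > 0 and mask.any():
        mask = dilation(mask, disk(dilation_radius))
    return mask


def live_cell_measurement(
    frame: ChannelFrame, threshold: float | None = None, dilation_radius: int = 3
) -> LiveCellMeasurement:
    """Summarise a frame with dead-cell signal excluded.

    The live mask is coverage minus the (dilated) dead mask.  The lipid ROS
    ratio over live pixels is computed sum-then-divide — total oxidized
    over total reduced signal within the mask — which is robust to
    zero-intensity pixels.  Cellular lipid ROS divides that ratio by the
    live confluence, giving a per-cell-normalised burden.
    """
    dmask = dead_mask(frame, threshold=threshold, dilation_radius=dilation_radius)
    live = frame.coverage & ~dmask
    n_pix = frame.coverage.size
    live_conf = float(live.sum()) / n_pix
    dead_frac = float((frame.coverage & dmask).sum()) / n_pix
    if live.any():
        red_sum = float(frame.reduced[live].sum())
        if red_sum > 0:
            ratio = float(frame.oxidized[live].sum()) / red_sum
        else:
            ratio = float("nan")
    else:
        ratio = float("nan")
    cellular = ratio / live_conf if (live_conf > 0 and not np.isnan(ratio)) else float("nan")
    return LiveCellMeasurement(
        live_confluence=live_conf,
        live_lipid_ros=ratio,
        cellular_lipid_ros=cellular,
        dead_area_fraction=dead_frac,
        time_h=frame.time_h,
    )
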