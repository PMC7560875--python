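"""Droplet statistics from fluorescence micrographs.

Segmentation follows the classic particle-analysis recipe: global threshold,
connected components, small-object rejection, per-object measurements under
the assumption that droplets are perfect spheres (volumes from the 2-D
equivalent diameter).  Partition coefficients are intensity ratios between
droplet interiors and the surrounding dilute phase.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

__all__ = [
    "MicrographFrame",
    "DropletRecord",
    "DropletStats",
    "PartitionEstimate",
    "segment",
    "segment_labels",
    "timelapse_stats",
    "partition_coefficient",
]


@dataclass(frozen=True)
class MicrographFrame:
    """A single grayscale frame with physical metadata.

    ``pixel_size_um`` converts pixel lengths to micrometres; ``time_min`` is
    the acquisition time since fuel addition.
    """

    pixels: np.ndarray
    pixel_size_um: float
    time_min: float = 0.0
    channel: str = "570-620nm"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if np.any(px < 0):
            raise ValueError("intensities must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "pixels", px)

    def to_tiff(self, path) -> None:
        """16-bit TIFF plus a JSON metadata sidecar."""
        import tifffile

        arr = np.round(np.clip(self.pixels, 0, 65535)).astype(np.uint16)
        tifffile.imwrite(path, arr)
        with open(f"{path}.json", "w") as fh:
            json.dump(
                {"pixel_size_um": self.pixel_size_um, "time_min": self.time_min, "channel": self.channel},
                fh,
            )

    @classmethod
    def from_tiff(cls, path) -> "MicrographFrame":
        import tifffile

        arr = tifffile.imread(path).astype(float)
        try:
            with open(f"{path}.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"pixel_size_um": 1.0, "time_min": 0.0, "channel": ""}
        return cls(pixels=arr, **meta)


@dataclass(frozen=True)
class DropletRecord:
    """Measurements of one segmented droplet."""

    centroid_xy: tuple[float, float]
    area_px: float
    eq_diameter_um: float
    volume_um3: float
    mean_intensity: float
    label: int = 0
    has_vacuole: bool | None = None

    def __post_init__(self) -> None:
        expected = np.pi / 6 * self.eq_diameter_um**3
        if abs(self.volume_um3 - expected) > 1e-6 * max(expected, 1e-12):
            raise ValueError("volume must equal (pi/6) d^3")


@dataclass(frozen=True)
class PartitionEstimate:
    """Intensity-ratio partition coefficient for one frame.

    ``K`` is the median interior intensity over the median background
    intensity; ``unbounded`` flags a zero background median.
    """

    K: float
    interior_median: float
    background_median: float
    n_droplets: int
    unbounded: bool = False


class DropletStats:
    """Time-binned droplet summaries (default 5-minute bins).

    Each row aggregates all frames whose acquisition time falls in
    ``[bin_start, bin_start + width)``: droplet count per frame, mean volume
    and mean intensity with their standard deviations.  Bins containing no
    frames are absent, not zero.
    """

    def __init__(self, table: pd.DataFrame, bin_width: float):
        self.table = table
        self.bin_width = bin_width

    def __repr__(self) -> str:
        return f"DropletStats(bins={len(self.table)}, width={self.bin_width} min)\n{self.table}"


def _threshold_value(pixels: np.ndarray, method) -> float | None:
    """Resolve the threshold; ``None`` means "nothing to segment"."""
    if isinstance(method, (int, float)):
        return float(method)
    if method != "otsu":
        raise ValueError("threshold method must be 'otsu' or a fixed number")
    if np.ptp(pixels) == 0:
        return None
    thr = float(filters.threshold_otsu(pixels))
    # Otsu always splits the histogram; on a droplet-free noisy frame the
    # split sits inside the noise band.  Require the threshold to clear the
    # background by a robust margin before accepting any object.
    med = float(np.median(pixels))
    mad_sigma = 1.4826 * float(np.median(np.abs(pixels - med)))
    if thr < med + 4 * mad_sigma:
        return None
    return thr


def segment_labels(
    frame: MicrographFrame,
    threshold="otsu",
    min_area_px: int = 4,
) -> tuple[list[DropletRecord], np.ndarray]:
    """Segment a frame, returning droplet records plus the label image.

    ``threshold`` is ``"otsu"`` (default) or a fixed intensity for
    deterministic pipelines.  Connected components smaller than
    ``min_area_px`` are discarded.  A blank frame yields an empty list.
    """
    px = frame.pixels
    thr = _threshold_value(px, threshold)
    labels = np.zeros(px.shape, dtype=int)
    if thr is None:
        return [], labels
    mask = px > thr
    labels = measure.label(mask)
    records = []
    kept = np.zeros(labels.max() + 1, dtype=bool)
    for rp in measure.regionprops(labels, intensity_image=px):
        if rp.area < min_area_px:
            continue
        kept[rp.label] = True
        d_um = rp.equivalent_diameter_area * frame.pixel_size_um
        records.append(
            DropletRecord(
                centroid_xy=(float(rp.centroid[1]), float(rp.centroid[0])),
                area_px=float(rp.area),
                eq_diameter_um=float(d_um),
                volume_um3=float(np.pi / 6 * d_um**3),
                mean_intensity=float(rp.intensity_mean),
                label=int(rp.label),
            )
        )
    labels = np.where(kept[labels], labels, 0)
    return records, labels


def segment(frame: MicrographFrame, threshold="otsu", min_area_px: int = 4) -> list[DropletRecord]:
    """Per-droplet records of one frame (see :func:`segment_labels`)."""
    return segment_labels(frame, threshold, min_area_px)[0]


def annotate_vacuoles(
    frame: MicrographFrame,
    records: list[DropletRecord],
    labels: np.ndarray,
    rim_fraction: float = 0.5,
) -> list[DropletRecord]:
    """Optional vacuole annotation: flag droplets whose interior contains a
    dark region below ``rim_fraction`` of the rim intensity.  The droplet is
    still counted once; this is an annotation, not a headline statistic."""
    import dataclasses

    from scipy.ndimage import binary_fill_holes

    out = []
    px = frame.pixels
    for rec in records:
        # vacuoles fall below the threshold, leaving holes in the mask
        region = binary_fill_holes(labels == rec.label)
        interior = morphology.erosion(region, morphology.disk(2))
        rim = region & ~interior
        if interior.sum() < 4 or rim.sum() == 0:
            out.append(dataclasses.replace(rec, has_vacuole=False))
            continue
        rim_med = np.median(px[rim])
        has = bool(np.any(px[interior] < rim_fraction * rim_med))
        out.append(dataclasses.replace(rec, has_vacuole=has))
    return out


def timelapse_stats(
    frames: list[tuple[MicrographFrame, list[DropletRecord]]],
    bin_width: float = 5.0,
) -> DropletStats:
    """Aggregate per-frame segmentations into time bins.

    Mirrors the particle-analysis workflow of binning per-frame counts,
    volumes and intensities into 5-minute bins; each bin reports how many
    frames fed it.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    rows = []
    for frame, records in frames:
        rows.append(
            {
                "time_min": frame.time_min,
                "count": len(records),
                "mean_volume_um3": np.mean([r.volume_um3 for r in records]) if records else np.nan,
                "mean_intensity": np.mean([r.mean_intensity for r in records]) if records else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    # right-closed bins: minute 5 belongs to the 1-5 bin, not the 5-10 one
    idx = np.maximum(np.ceil(df["time_min"] / bin_width).astype(int) - 1, 0)
    df["bin_start"] = idx * bin_width
    agg = (
        df.groupby("bin_start")
        .agg(
            n_frames=("time_min", "size"),
            count_mean=("count", "mean"),
            count_sd=("count", "std"),
            volume_mean=("mean_volume_um3", "mean"),
            volume_sd=("mean_volume_um3", "std"),
            intensity_mean=("mean_intensity", "mean"),
            intensity_sd=("mean_intensity", "std"),
        )
        .reset_index()
        .sort_values("bin_start", ignore_index=True)
    )
    return DropletStats(agg, bin_width)


def partition_coefficient(
    frame: MicrographFrame,
    records: list[DropletRecord] | None = None,
    labels: np.ndarray | None = None,
    interior_erosion_px: int = 2,
    background_dilation_px: int = 2,
    threshold="otsu",
    min_area_px: int = 4,
) -> PartitionEstimate:
    """Median-based partition coefficient of one frame.

    The interior mask is the union of droplet footprints eroded by
    ``interior_erosion_px`` (discarding blurred rims); the background is the
    complement of the droplet mask dilated by ``background_dilation_px``
    (discarding halos).  ``K`` is the ratio of the two medians.
    """
    if records is None or labels is None:
        records, labels = segment_labels(frame, threshold, min_area_px)
    if not records:
        raise ValueError("no droplets to estimate a partition coefficient from")
    px = frame.pixels
    mask = labels > 0
    interior = morphology.erosion(mask, morphology.disk(interior_erosion_px)) if interior_erosion_px else mask
    if not interior.any():
        interior = mask  # droplets too small to erode; fall back to full mask
    background = ~morphology.dilation(mask, morphology.disk(background_dilation_px))
    if not background.any():
        raise ValueError("background region empty after dilation")
    med_in = float(np.median(px[interior]))
    med_bg = float(np.median(px[background]))
    if med_bg == 0:
        warnings.warn("zero background median; partition coefficient unbounded", stacklevel=2)
        return PartitionEstimate(
            K=np.inf,
            interior_median=med_in,
            background_median=0.0,
            n_droplets=len(records),
            unbounded=True,
        )
    return PartitionEstimate(
        K=med_in / med_bg,
        interior_median=med_in,
        background_median=med_bg,
        n_droplets=len(records),
    )


def records_dataframe(frames: list[tuple[MicrographFrame, list[DropletRecord]]]) -> pd.DataFrame:
    """Flat per-droplet table across frames, matching the CLI CSV layout."""
    rows = []
    for i, (frame, records) in enumerate(frames):
        for r in records:
            rows.append(
                {
                    "frame": i,
                    "time_min": frame.time_min,
                    "centroid_x": r.centroid_xy[0],
                    "centroid_y": r.centroid_xy[1],
                    "area_px": r.area_px,
                    "eq_diam_um": r.eq_diameter_um,
                    "volume_um3": r.volume_um3,
                    "mean_intensity": r.mean_intensity,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame",
            "time_min",
            "centroid_x",
            "centroid_y",
            "area_px",
            "eq_diam_um",
            "volume_um3",
            "mean_intensity",
        ],
    )
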