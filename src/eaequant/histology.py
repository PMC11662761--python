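"""Histological quantification: eYFP transection, NR white-matter loss, g-ratios.

Three image-based readouts of spinal-cord pathology:

* **Axonal transection** from punctate eYFP fluorescence.  Because grey-matter
  fluorescence is unaffected by disease or treatment, each image is
  thresholded relative to its own grey-matter mean: a cohort-wide
  standardized ratio (mean healthy-white-matter / grey-matter intensity) is
  multiplied by the per-image grey-matter mean and a factor (default 1.5) to
  give a per-image threshold; the percent area of white matter with strictly
  suprathreshold intensity measures transection.

* **White-matter loss** from Eriochrome-Cyanine / Neutral-Red stained
  sections: percent of the white-matter mask whose red/blue channel ratio
  marks it NR-positive (demyelinated).

* **Remyelination** from axon/myelin label masks produced by an external
  segmentation tool.  The area-equivalent g-ratio g = sqrt(A_axon /
  (A_axon + A_myelin)) is computed per axon; myelinated axons with g
  strictly above the cutoff (default 0.8) count as remyelinating (thin,
  newly formed sheaths).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageWithMasks",
    "EyfpImageResult",
    "AxonRecord",
    "RemyelinationSummary",
    "eyfp_standardized_ratio",
    "eyfp_percent_transection",
    "nr_percent_wm_loss",
    "gratio_records",
    "remyelination_summary",
]

EYFP_FACTOR_DEFAULT = 1.5
G_CUTOFF_DEFAULT = 0.8
NR_RED_BLUE_MIN_DEFAULT = 1.2
MIN_AXON_AREA_PX_DEFAULT = 10


@dataclass
class ImageWithMasks:
    """Greyscale fluorescence image with white/grey-matter region masks.

    ``healthy_wm_mask`` delineates visually healthy white matter and must be
    a subset of ``wm_mask``; white and grey matter must not overlap.
    """

    intensity: np.ndarray
    wm_mask: np.ndarray
    gm_mask: np.ndarray
    healthy_wm_mask: np.ndarray | None = None
    pixel_size_um: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError(f"image {self.name!r}: intensity must be 2-D greyscale")
        for label in ("wm_mask", "gm_mask", "healthy_wm_mask"):
            m = getattr(self, label)
            if m is None:
                continue
            m = np.asarray(m).astype(bool)
            if m.shape != self.intensity.shape:
                raise ValueError(f"image {self.name!r}: {label} shape mismatch")
            setattr(self, label, m)
        if np.logical_and(self.wm_mask, self.gm_mask).any():
            raise ValueError(f"image {self.name!r}: wm_mask and gm_mask overlap")
        if self.healthy_wm_mask is not None and np.any(
            self.healthy_wm_mask & ~self.wm_mask
        ):
            raise ValueError(
                f"image {self.name!r}: healthy_wm_mask is not a subset of wm_mask"
            )


@dataclass
class EyfpImageResult:
    """Per-image eYFP transection quantification."""

    name: str
    gm_mean: float
    threshold: float
    percent_transection: float
    standardized_ratio: float
    factor: float


@dataclass
class AxonRecord:
    """One segmented axon: areas, area-equivalent g-ratio, class flags."""

    label: int
    axon_area_um2: float
    myelin_area_um2: float
    g: float
    myelinated: bool
    remyelinating: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.g <= 1.0):
            raise ValueError(f"axon {self.label}: g={self.g} outside (0, 1]")
        if (self.g == 1.0) != (self.myelin_area_um2 == 0.0):
            raise ValueError(f"axon {self.label}: g=1 must coincide with zero myelin")


@dataclass
class RemyelinationSummary:
    """Field-level remyelination counts and densities."""

    n_axons: int
    n_myelinated: int
    n_remyelinating: int
    density_remyelinating: float  # axons / um^2
    percent_remyelinating: float  # of all retained axons
    percent_of_myelinated: float  # alternative denominator
    g_cutoff: float = G_CUTOFF_DEFAULT
    field_area_um2: float = 0.0


def _masked_mean(image: ImageWithMasks, mask: np.ndarray, label: str) -> float:
    if mask is None or not mask.any():
        raise ValueError(f"image {image.name!r}: empty {label}")
    return float(image.intensity[mask].mean())


def eyfp_standardized_ratio(images: list[ImageWithMasks]) -> float:
    """Cohort standardized ratio of healthy-WM to GM fluorescence.

    Per image, mean intensity over the healthy white-matter mask divided by
    mean intensity over the grey-matter mask; the arithmetic mean of these
    per-image ratios over the cohort is returned.
    """
    if not images:
        raise ValueError("at least one image is required")
    ratios = []
    for img in images:
        hwm = _masked_mean(img, img.healthy_wm_mask, "healthy_wm_mask")
        gm = _masked_mean(img, img.gm_mask, "gm_mask")
        if gm == 0:
            raise ValueError(f"image {img.name!r}: zero grey-matter mean intensity")
        ratios.append(hwm / gm)
    return float(np.mean(ratios))


def eyfp_percent_transection(
    image: ImageWithMasks,
    ratio: float,
    factor: float = EYFP_FACTOR_DEFAULT,
) -> EyfpImageResult:
    """Percent white-matter area with strictly suprathreshold eYFP signal.

    threshold = ratio x (per-image GM mean) x factor; the comparison is
    strict (> threshold), so an image whose white matter sits exactly at
    the healthy level contributes 0%.  The result is invariant under
    multiplying all pixel intensities by a positive constant, since the
    threshold scales with the GM mean.
    """
    if ratio <= 0 or factor <= 0:
        raise ValueError("ratio and factor must be positive")
    gm_mean = _masked_mean(image, image.gm_mask, "gm_mask")
    if not image.wm_mask.any():
        raise ValueError(f"image {image.name!r}: empty wm_mask")
    threshold = ratio * gm_mean * factor
    wm = image.intensity[image.wm_mask]
    percent = 100.0 * float((wm > threshold).sum()) / wm.size
    return EyfpImageResult(
        name=image.name,
        gm_mean=gm_mean,
        threshold=threshold,
        percent_transection=percent,
        standardized_ratio=ratio,
        factor=factor,
    )


def nr_percent_wm_loss(
    rgb: np.ndarray,
    wm_mask: np.ndarray,
    red_blue_ratio_min: float = NR_RED_BLUE_MIN_DEFAULT,
) -> float:
    """Percent of white matter that is Neutral-Red positive (demyelinated).

    EC-stained myelin is blue; NR counterstain marks demyelinated tissue
    red.  A pixel is NR-positive when red / (blue + eps) exceeds
    ``red_blue_ratio_min`` (default 1.2).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb must be an H x W x 3 image")
    wm_mask = np.asarray(wm_mask).astype(bool)
    if wm_mask.shape != rgb.shape[:2]:
        raise ValueError("wm_mask shape does not match image")
    if not wm_mask.any():
        raise ValueError("empty wm_mask")
    red = rgb[..., 0][wm_mask]
    blue = rgb[..., 2][wm_mask]
    nr_pos = red / (blue + 1e-6) > red_blue_ratio_min
    return 100.0 * float(nr_pos.sum()) / nr_pos.size


def gratio_records(
    axon_mask: np.ndarray,
    myelin_mask: np.ndarray,
    pixel_size_um: float,
    min_axon_area_px: int = MIN_AXON_AREA_PX_DEFAULT,
    g_cutoff: float = G_CUTOFF_DEFAULT,
) -> list[AxonRecord]:
    """Per-axon areas and area-equivalent g-ratios from label masks.

    Axon and myelin masks share integer labels (myelin pixels of axon *i*
    carry value *i*).  For each axon, A_axon and A_myelin are pixel counts
    scaled by pixel_size^2 and g = sqrt(A_axon / (A_axon + A_myelin)).
    Axons touching the image border (their area is underestimated) or
    smaller than ``min_axon_area_px`` (segmentation specks) are excluded;
    myelin labels without a matching axon are skipped with a warning.
    """
    axon_mask = np.asarray(axon_mask)
    myelin_mask = np.asarray(myelin_mask)
    if axon_mask.shape != myelin_mask.shape:
        raise ValueError("axon and myelin masks must have the same shape")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")

    axon_ids, axon_counts = np.unique(axon_mask[axon_mask > 0], return_counts=True)
    myelin_counts = dict(
        zip(*np.unique(myelin_mask[myelin_mask > 0], return_counts=True))
    )
    orphan = sorted(set(myelin_counts) - set(axon_ids.tolist()))
    if orphan:
        warnings.warn(
            f"myelin labels with no matching axon skipped: {orphan}", stacklevel=2
        )

    border = np.zeros_like(axon_mask, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_ids = set(np.unique(axon_mask[border & (axon_mask > 0)]).tolist())
    border_ids |= set(np.unique(myelin_mask[border & (myelin_mask > 0)]).tolist())

    px2 = pixel_size_um**2
    records: list[AxonRecord] = []
    for lab, n_ax in zip(axon_ids.tolist(), axon_counts.tolist()):
        if lab in border_ids or n_ax < min_axon_area_px:
            continue
        n_my = int(myelin_counts.get(lab, 0))
        a_axon = n_ax * px2
        a_myelin = n_my * px2
        g = float(np.sqrt(a_axon / (a_axon + a_myelin)))
        myelinated = a_myelin > 0
        records.append(
            AxonRecord(
                label=int(lab),
                axon_area_um2=a_axon,
                myelin_area_um2=a_myelin,
                g=g,
                myelinated=myelinated,
                remyelinating=bool(myelinated and g > g_cutoff),
            )
        )
    return records


def remyelination_summary(
    records: list[AxonRecord],
    field_area_um2: float,
    g_cutoff: float = G_CUTOFF_DEFAULT,
) -> RemyelinationSummary:
    """Counts, density and percentage of remyelinating axons in one field.

    Remyelinating = myelinated and g strictly above ``g_cutoff`` ("above
    0.8"): an axon at exactly the cutoff is not counted.  The headline
    percentage uses all retained axons as denominator; the
    myelinated-only denominator is also reported.
    """
    if field_area_um2 <= 0:
        raise ValueError("field_area_um2 must be positive")
    if not (0.0 < g_cutoff < 1.0):
        raise ValueError("g_cutoff must be in (0, 1)")
    if not records:
        warnings.warn("empty axon record list: summary of zeros", stacklevel=2)
        return RemyelinationSummary(0, 0, 0, 0.0, 0.0, 0.0, g_cutoff, field_area_um2)
    n_axons = len(records)
    n_myel = sum(r.myelinated for r in records)
    n_rem = sum(bool(r.myelinated and r.g > g_cutoff) for r in records)
    return RemyelinationSummary(
        n_axons=n_axons,
        n_myelinated=n_myel,
        n_remyelinating=n_rem,
        density_remyelinating=n_rem / field_area_um2,
        percent_remyelinating=100.0 * n_rem / n_axons,
        percent_of_myelinated=(100.0 * n_rem / n_myel) if n_myel else 0.0,
        g_cutoff=g_cutoff,
        field_area_um2=field_area_um2,
    )
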