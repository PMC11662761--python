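"""Pose-track ingestion and pixel-to-centimetre calibration.

Markerless pose-estimation software (DeepLabCut-style) exports per-frame
pixel coordinates of tracked hindlimb landmarks as CSV with three header
rows (scorer / bodyparts / coords) and x, y, likelihood columns per
landmark.  A calibration frame showing four markers at the corners of a
rectangle of known physical size (4 cm high by 7 cm wide in the treadmill
setup) yields a scalar conversion coefficient from pixels to centimetres.
Calibrated tracks are expressed in a y-up centimetre frame so joint heights
are positive upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LANDMARKS",
    "PoseTrack",
    "Calibration",
    "CalibratedTrack",
    "read_pose_track",
    "write_pose_track",
    "compute_calibration",
    "read_calibration_yaml",
    "calibrate_track",
]

#: Canonical hindlimb landmark names, proximal to distal.
LANDMARKS = ("iliac_crest", "hip", "knee", "ankle", "mtp", "toe")

#: Aliases accepted (case-insensitively) when mapping CSV bodypart names.
_LANDMARK_ALIASES = {
    "iliac_crest": {"iliac_crest", "iliaccrest", "iliac crest", "crest"},
    "hip": {"hip"},
    "knee": {"knee"},
    "ankle": {"ankle"},
    "mtp": {"mtp", "metatarsophalangeal", "metatarsophalangeal_joint", "mtp_joint"},
    "toe": {"toe"},
}

DEFAULT_FPS = 250.0
LIKELIHOOD_MIN_DEFAULT = 0.9
ANISOTROPY_TOL_DEFAULT = 0.05


@dataclass
class PoseTrack:
    """Raw per-frame pixel coordinates of the six hindlimb landmarks.

    Arrays are dicts keyed by landmark name; ``likelihood`` may be None
    when the exporting software provides no confidence column.
    """

    fps: float
    x_px: dict
    y_px: dict
    likelihood: dict | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name in LANDMARKS:
            if name not in self.x_px or name not in self.y_px:
                raise ValueError(f"landmark {name!r} not found")
        lengths = {len(self.x_px[n]) for n in LANDMARKS}
        lengths |= {len(self.y_px[n]) for n in LANDMARKS}
        if len(lengths) != 1:
            raise ValueError("all landmark coordinate arrays must have equal length")
        self.x_px = {n: np.asarray(self.x_px[n], dtype=float) for n in LANDMARKS}
        self.y_px = {n: np.asarray(self.y_px[n], dtype=float) for n in LANDMARKS}
        if self.likelihood is not None:
            self.likelihood = {
                n: np.asarray(self.likelihood[n], dtype=float) for n in LANDMARKS
            }

    @property
    def frames(self) -> int:
        return len(self.x_px[LANDMARKS[0]])


@dataclass
class Calibration:
    """Scalar pixel-to-centimetre conversion from the marker rectangle."""

    coefficient: float  # cm per pixel
    anisotropy: float
    rect_width_cm: float
    rect_height_cm: float

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("conversion coefficient must be positive")
        if self.anisotropy < 0:
            raise ValueError("anisotropy must be non-negative")


@dataclass
class CalibratedTrack:
    """Per-frame centimetre coordinates, y increasing upward, gaps filled."""

    fps: float
    x_cm: dict
    y_cm: dict

    def __post_init__(self) -> None:
        for n in LANDMARKS:
            x = np.asarray(self.x_cm[n], dtype=float)
            y = np.asarray(self.y_cm[n], dtype=float)
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
                raise ValueError(f"non-finite coordinates for landmark {n!r}")
            self.x_cm[n], self.y_cm[n] = x, y

    @property
    def frames(self) -> int:
        return len(self.x_cm[LANDMARKS[0]])


def _canonical_landmark(raw: str) -> str | None:
    key = raw.strip().lower().replace("-", "_").replace(" ", "_")
    for canon, aliases in _LANDMARK_ALIASES.items():
        if key == canon or key in {a.replace(" ", "_") for a in aliases}:
            return canon
    return None


def read_pose_track(path, fps: float = DEFAULT_FPS) -> PoseTrack:
    """Read a three-header-row pose-estimation CSV into a :class:`PoseTrack`.

    Header rows are scorer / bodyparts / coords; bodypart names are mapped
    case-insensitively onto the six canonical landmarks.  Row order is
    preserved.  Raises ``ValueError`` for an empty file, a missing
    landmark, or non-numeric coordinate cells (reported with row index).
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty pose CSV: {path}") from None
    if df.empty:
        raise ValueError(f"pose CSV has no data rows: {path}")

    cols: dict[tuple[str, str], pd.Series] = {}
    for scorer, bodypart, coord in df.columns:
        canon = _canonical_landmark(str(bodypart))
        coord = str(coord).strip().lower()
        if canon is not None and coord in ("x", "y", "likelihood"):
            cols[(canon, coord)] = df[(scorer, bodypart, coord)]

    x_px, y_px, likelihood = {}, {}, {}
    for name in LANDMARKS:
        for coord, store in (("x", x_px), ("y", y_px)):
            if (name, coord) not in cols:
                raise ValueError(f"landmark {name!r} not found (missing {coord} column)")
            series = pd.to_numeric(cols[(name, coord)], errors="coerce")
            bad = series.index[series.isna() & cols[(name, coord)].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric value for {name}/{coord} at row {bad[0]}"
                )
            if series.isna().any():
                row = series.index[series.isna()][0]
                raise ValueError(f"missing value for {name}/{coord} at row {row}")
            store[name] = series.to_numpy(dtype=float)
        if (name, "likelihood") in cols:
            likelihood[name] = pd.to_numeric(
                cols[(name, "likelihood")], errors="coerce"
            ).to_numpy(dtype=float)
    if len(likelihood) != len(LANDMARKS):
        likelihood = None
    return PoseTrack(fps=fps, x_px=x_px, y_px=y_px, likelihood=likelihood)


def write_pose_track(track: PoseTrack, path, scorer: str = "synthetic") -> None:
    """Write a :class:`PoseTrack` in the three-header-row CSV dialect."""
    data = {}
    for name in LANDMARKS:
        data[(scorer, name, "x")] = track.x_px[name]
        data[(scorer, name, "y")] = track.y_px[name]
        lk = (
            track.likelihood[name]
            if track.likelihood is not None
            else np.ones(track.frames)
        )
        data[(scorer, name, "likelihood")] = lk
    df = pd.DataFrame(data)
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["scorer", "bodyparts", "coords"]
    )
    df.to_csv(path, index_label=None)


def compute_calibration(
    marker_px,
    rect_width_cm: float = 7.0,
    rect_height_cm: float = 4.0,
    anisotropy_tol: float = ANISOTROPY_TOL_DEFAULT,
) -> Calibration:
    """Conversion coefficient from four marker pixel coordinates.

    The four markers sit at the corners of an axis-aligned rectangle of
    known physical size (defaults: the 7 cm wide by 4 cm high treadmill
    marker rectangle).  Corners are matched by lexicographic sort, the two
    axis scales computed, and their mean returned as the scalar
    coefficient.  Axis scales differing by more than ``anisotropy_tol``
    (fractional) indicate a tilted camera or mis-clicked markers and raise.
    """
    pts = np.asarray(marker_px, dtype=float)
    if pts.shape != (4, 2):
        raise ValueError("marker_px must be four (x, y) points")
    if rect_width_cm <= 0 or rect_height_cm <= 0:
        raise ValueError("rectangle dimensions must be positive")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    # after sort: [left-bottom, left-top, right-bottom, right-top] in pixel axes
    left, right = pts[:2], pts[2:]
    width_px = float(np.mean(right[:, 0]) - np.mean(left[:, 0]))
    height_px = float(abs(pts[1, 1] - pts[0, 1]) + abs(pts[3, 1] - pts[2, 1])) / 2.0
    if width_px <= 0 or height_px <= 0:
        raise ValueError("degenerate marker rectangle (zero width or height)")
    if not (
        np.isclose(pts[0, 0], pts[1, 0])
        and np.isclose(pts[2, 0], pts[3, 0])
        and np.isclose(min(pts[0, 1], pts[1, 1]), min(pts[2, 1], pts[3, 1]))
    ):
        raise ValueError("markers do not form an axis-aligned rectangle")
    scale_x = rect_width_cm / width_px
    scale_y = rect_height_cm / height_px
    mean_scale = (scale_x + scale_y) / 2.0
    anisotropy = abs(scale_x - scale_y) / mean_scale
    if anisotropy > anisotropy_tol:
        raise ValueError(
            f"calibration anisotropy {anisotropy:.3f} exceeds tolerance "
            f"{anisotropy_tol:.3f} (scale_x={scale_x:.5g}, scale_y={scale_y:.5g})"
        )
    return Calibration(
        coefficient=mean_scale,
        anisotropy=anisotropy,
        rect_width_cm=rect_width_cm,
        rect_height_cm=rect_height_cm,
    )


def read_calibration_yaml(path) -> Calibration:
    """Load a calibration YAML (marker pixel coords + true rectangle size)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return compute_calibration(
        doc["marker_px"],
        rect_width_cm=float(doc.get("rect_width_cm", 7.0)),
        rect_height_cm=float(doc.get("rect_height_cm", 4.0)),
        anisotropy_tol=float(doc.get("anisotropy_tol", ANISOTROPY_TOL_DEFAULT)),
    )


def _fill_gaps(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation across invalid frames; edges take nearest value."""
    if valid.all():
        return values
    idx = np.arange(values.size, dtype=float)
    return np.interp(idx, idx[valid], values[valid])


def calibrate_track(
    track: PoseTrack,
    cal: Calibration,
    likelihood_min: float = LIKELIHOOD_MIN_DEFAULT,
    image_height_px: float = 600.0,
) -> CalibratedTrack:
    """Convert a pixel track to the y-up centimetre treadmill frame.

    Frames where a landmark's likelihood falls below ``likelihood_min``
    are treated as tracking dropouts and replaced by linear interpolation
    between the nearest confidently tracked frames (edge gaps extend the
    nearest valid value).  The y axis is flipped so heights increase
    upward: y_cm = (image_height_px - y_px) * coefficient.

    Raises if any landmark is confidently tracked in fewer than half the
    frames ("tracking quality insufficient").
    """
    if not (0.0 <= likelihood_min < 1.0):
        raise ValueError("likelihood_min must be in [0, 1)")
    n = track.frames
    x_cm, y_cm = {}, {}
    for name in LANDMARKS:
        if track.likelihood is not None:
            valid = track.likelihood[name] >= likelihood_min
        else:
            valid = np.ones(n, dtype=bool)
        if valid.sum() < 0.5 * n:
            raise ValueError(
                f"tracking quality insufficient: landmark {name!r} valid in "
                f"{valid.sum()}/{n} frames"
            )
        x = _fill_gaps(track.x_px[name], valid)
        y = _fill_gaps(track.y_px[name], valid)
        x_cm[name] = x * cal.coefficient
        y_cm[name] = (image_height_px - y) * cal.coefficient
    return CalibratedTrack(fps=track.fps, x_cm=x_cm, y_cm=y_cm)
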