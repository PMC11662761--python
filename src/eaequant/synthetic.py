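"""Seeded synthetic datasets with exported ground truth for every pipeline input.

Each generator is a pure function of its parameters and seed and returns,
alongside the data in exactly the form the analysis modules consume, the
ground truth needed to predict the pipeline's output without re-deriving it:

* :func:`gen_gait_recording` — treadmill pose tracks built by forward
  kinematics from prescribed joint-angle waveforms, so true phase
  boundaries, duty factor and per-frame joint angles are known in closed
  form.  During stance all limb-segment angles are the thigh sweep plus
  constants, so the leg rotates rigidly about the hip and the toe moves
  strictly rearward — the property the phase detector keys on.
* :func:`gen_eyfp_image` — fluorescence images with grey-matter,
  white-matter and healthy-white-matter regions and a painted set of
  suprathreshold pixels of exactly known area fraction.
* :func:`gen_axon_field` — label masks of non-overlapping elliptical
  axon/myelin annuli whose true g-ratios are computed from the very pixel
  counts used to rasterize them, making the truth exact under the
  area-equivalent definition.
* :func:`gen_clinical_cohort` — ordinal disease-score trajectories (onset,
  peak at DPI 16, group-specific recovery) on the 0.5 grid.
* :func:`gen_qpcr_plate` — technical-triplicate Cq tables with known true
  fold changes and reference-gene stability.

Realism is secondary to verifiability: ground truth is defined at the level
the pipeline measures (angle waveforms, phase boundaries, painted areas),
not at the level of muscle dynamics or microscope optics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pose_io import LANDMARKS, PoseTrack, Calibration, compute_calibration
from .histology import ImageWithMasks
from .qpcr import CqTable
from .stats import ClinicalTrajectory

__all__ = [
    "GaitSimParams",
    "GaitGroundTruth",
    "EyfpSimParams",
    "AxonSimParams",
    "gen_gait_recording",
    "gen_eyfp_image",
    "gen_axon_field",
    "gen_clinical_cohort",
    "gen_qpcr_plate",
]


# --------------------------------------------------------------------------
# gait


@dataclass
class GaitSimParams:
    """Treadmill gait simulation parameters.

    The hindlimb is a five-segment chain (iliac crest - hip - knee - ankle -
    MTP - toe).  The thigh sweeps between +/- ``hip_sweep_deg`` about the
    vertical with zero angular velocity exactly at touch-down and lift-off;
    knee and ankle hold constant interior angles during stance and flex by a
    smooth bump during swing.  ``knee_offset_deg`` shifts the knee waveform
    rigidly (the EAE-like deficit the study measures); ``cycle_noise_sd_deg``
    adds an independent constant angle offset per joint per cycle
    (step-to-step variability); ``tracking_noise_sd_cm`` adds white noise to
    every landmark coordinate (pose-estimation jitter).
    """

    fps: float = 250.0
    duration_s: float = 4.0
    cadence_hz: float = 1.5
    duty_factor: float = 0.6
    # segment lengths, cm (adult mouse hindlimb scale)
    pelvis_cm: float = 0.8
    thigh_cm: float = 1.6
    shank_cm: float = 1.8
    foot_cm: float = 1.0
    mtp_toe_cm: float = 0.5
    # waveform shape, degrees
    hip_sweep_deg: float = 25.0
    pelvis_tilt_deg: float = -40.0  # fixed crest->hip direction from vertical-down
    knee_base_deg: float = 130.0
    knee_flex_deg: float = 35.0
    ankle_base_deg: float = 105.0
    ankle_flex_deg: float = 25.0
    crest_osc_cm: float = 0.05
    # perturbations
    knee_offset_deg: float = 0.0
    cycle_noise_sd_deg: float = 0.0
    tracking_noise_sd_cm: float = 0.0
    # camera / calibration
    px_per_cm: float = 100.0
    image_height_px: int = 600
    crest_x_cm: float = 4.0
    crest_y_cm: float = 5.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.duty_factor < 1.0):
            raise ValueError("duty_factor must be in (0, 1)")
        if self.fps <= 0 or self.cadence_hz <= 0 or self.duration_s <= 0:
            raise ValueError("fps, cadence and duration must be positive")
        for name in ("pelvis_cm", "thigh_cm", "shank_cm", "foot_cm", "mtp_toe_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GaitGroundTruth:
    """Everything needed to predict the gait pipeline's output."""

    params: GaitSimParams
    calibration: Calibration
    marker_px: np.ndarray  # the four calibration marker pixel positions
    duty_factor: float
    cadence_hz: float
    # float frame indices of each complete cycle's boundaries
    boundaries: list  # (stance_start, stance_end=swing_start, swing_end)
    # realized noiseless-tracking per-frame true angles, degrees
    hip_deg: np.ndarray
    knee_deg: np.ndarray
    ankle_deg: np.ndarray
    # noiseless landmark cm coordinates
    x_cm: dict = field(default_factory=dict)
    y_cm: dict = field(default_factory=dict)

    def true_average_angles(self) -> dict:
        """Phase-balanced true average angles, matching the pipeline's
        equal stance/swing weighting in the representative cycle."""
        out = {}
        for joint, arr in (
            ("hip", self.hip_deg),
            ("knee", self.knee_deg),
            ("ankle", self.ankle_deg),
        ):
            st_means, sw_means = [], []
            for s0, s1, s2 in self.boundaries:
                i0, i1, i2 = (int(math.ceil(v)) for v in (s0, s1, s2))
                st_means.append(float(np.mean(arr[i0:i1])))
                sw_means.append(float(np.mean(arr[i1:i2])))
            out[joint] = 0.5 * float(np.mean(st_means)) + 0.5 * float(np.mean(sw_means))
        return out


def _swing_bump(phase: np.ndarray, duty: float) -> np.ndarray:
    """Smooth 0->1->0 bump over the swing fraction; zero value and slope at
    both phase boundaries."""
    b = np.zeros_like(phase)
    sw = phase >= duty
    u = (phase[sw] - duty) / (1.0 - duty)
    b[sw] = np.sin(np.pi * u) ** 2
    return b


def _thigh_sweep(phase: np.ndarray, duty: float, amp: float) -> np.ndarray:
    """Thigh down-angle (deg from vertical, +forward): cosine-eased sweep
    from +amp at touch-down to -amp at lift-off and back, with zero angular
    velocity exactly at the phase boundaries."""
    psi = np.empty_like(phase)
    st = phase < duty
    psi[st] = amp * np.cos(np.pi * phase[st] / duty)
    u = (phase[~st] - duty) / (1.0 - duty)
    psi[~st] = -amp * np.cos(np.pi * u)
    return psi


def _forward_kinematics(
    p: GaitSimParams,
    psi: np.ndarray,
    knee: np.ndarray,
    ankle: np.ndarray,
    crest_y: np.ndarray,
) -> tuple[dict, dict]:
    """Landmark cm coordinates from segment angles (degrees)."""
    d2r = math.pi / 180.0
    x, y = {}, {}
    x["iliac_crest"] = np.full_like(psi, p.crest_x_cm)
    y["iliac_crest"] = crest_y
    gam = p.pelvis_tilt_deg * d2r
    x["hip"] = x["iliac_crest"] + p.pelvis_cm * math.sin(gam)
    y["hip"] = y["iliac_crest"] - p.pelvis_cm * math.cos(gam)
    psi_r = psi * d2r
    x["knee"] = x["hip"] + p.thigh_cm * np.sin(psi_r)
    y["knee"] = y["hip"] - p.thigh_cm * np.cos(psi_r)
    # shank direction from +x axis: thigh direction (-90 + psi) folded back
    # by the knee interior angle
    phi_s = (psi + knee - 270.0) * d2r
    x["ankle"] = x["knee"] + p.shank_cm * np.cos(phi_s)
    y["ankle"] = y["knee"] + p.shank_cm * np.sin(phi_s)
    # foot folds forward at the ankle
    phi_f = phi_s + (180.0 - ankle) * d2r
    x["mtp"] = x["ankle"] + p.foot_cm * np.cos(phi_f)
    y["mtp"] = y["ankle"] + p.foot_cm * np.sin(phi_f)
    x["toe"] = x["mtp"] + p.mtp_toe_cm * np.cos(phi_f)
    y["toe"] = y["mtp"] + p.mtp_toe_cm * np.sin(phi_f)
    return x, y


def _check_velocity_signs(
    toe_x: np.ndarray, phase: np.ndarray, duty: float, fps: float
) -> bool:
    """True if toe x-velocity is negative through the interior of every
    stance and positive through the interior of every swing."""
    v = np.gradient(toe_x) * fps
    frac = np.mod(phase, 1.0)
    st = (frac > 0.05 * duty) & (frac < 0.95 * duty)
    sw = (frac > duty + 0.05 * (1 - duty)) & (frac < duty + 0.95 * (1 - duty))
    return bool(np.all(v[st] < 0) and np.all(v[sw] > 0))


def gen_gait_recording(
    params: GaitSimParams | None = None,
) -> tuple[PoseTrack, GaitGroundTruth]:
    """Simulate one treadmill recording and its ground truth.

    Joint-angle waveforms (baseline shape + knee offset + per-cycle constant
    noise) drive a forward-kinematic limb whose toe moves rearward during
    stance and forward during swing; the noiseless construction is checked
    for that velocity-sign property and a violation raises.  Landmark cm
    coordinates are converted to pixels through a known calibration (y axis
    image-down) and tracking noise is added last.
    """
    p = params or GaitSimParams()
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fps))
    t = np.arange(n) / p.fps
    phase = t * p.cadence_hz
    frac = np.mod(phase, 1.0)
    cyc = np.floor(phase).astype(int)
    n_cycles_total = cyc.max() + 1

    # per-cycle constant angle offsets, one per joint
    noise = rng.normal(0.0, p.cycle_noise_sd_deg, size=(n_cycles_total, 3))
    if p.cycle_noise_sd_deg == 0:
        noise[:] = 0.0

    psi = _thigh_sweep(frac, p.duty_factor, p.hip_sweep_deg)
    bump = _swing_bump(frac, p.duty_factor)
    knee = p.knee_base_deg - p.knee_flex_deg * bump + p.knee_offset_deg + noise[cyc, 1]
    ankle = p.ankle_base_deg - p.ankle_flex_deg * bump + noise[cyc, 2]
    psi = psi + noise[cyc, 0]
    crest_y = p.crest_y_cm + p.crest_osc_cm * np.sin(2 * math.pi * frac)

    x_cm, y_cm = _forward_kinematics(p, psi, knee, ankle, crest_y)
    if not _check_velocity_signs(x_cm["toe"], phase, p.duty_factor, p.fps):
        raise ValueError(
            "waveform/duty-factor combination violates the stance-velocity "
            "constraint; adjust hip_sweep_deg or flexion amplitudes"
        )

    # true interior angles of the construction (hip derived from the fixed
    # pelvis direction; knee/ankle are set directly)
    hip_true = 180.0 - np.abs(psi - p.pelvis_tilt_deg)
    boundaries = []
    fpc = p.fps / p.cadence_hz  # frames per cycle
    for k in range(n_cycles_total):
        s0, s1, s2 = k * fpc, (k + p.duty_factor) * fpc, (k + 1) * fpc
        if s2 <= n - 1:
            boundaries.append((s0, s1, s2))

    # camera: cm -> px through a known calibration rectangle
    coeff = 1.0 / p.px_per_cm
    marker_px = np.array(
        [[100.0, 100.0], [100.0 + 7.0 * p.px_per_cm, 100.0],
         [100.0 + 7.0 * p.px_per_cm, 100.0 + 4.0 * p.px_per_cm],
         [100.0, 100.0 + 4.0 * p.px_per_cm]]
    )
    cal = compute_calibration(marker_px, 7.0, 4.0)

    x_px, y_px, lik = {}, {}, {}
    for name in LANDMARKS:
        xn = x_cm[name] + rng.normal(0.0, p.tracking_noise_sd_cm, n) \
            if p.tracking_noise_sd_cm > 0 else x_cm[name]
        yn = y_cm[name] + rng.normal(0.0, p.tracking_noise_sd_cm, n) \
            if p.tracking_noise_sd_cm > 0 else y_cm[name]
        x_px[name] = xn / coeff
        y_px[name] = p.image_height_px - yn / coeff
        lik[name] = np.ones(n)

    track = PoseTrack(fps=p.fps, x_px=x_px, y_px=y_px, likelihood=lik)
    truth = GaitGroundTruth(
        params=p,
        calibration=cal,
        marker_px=marker_px,
        duty_factor=p.duty_factor,
        cadence_hz=p.cadence_hz,
        boundaries=boundaries,
        hip_deg=hip_true,
        knee_deg=knee,
        ankle_deg=ankle,
        x_cm=x_cm,
        y_cm=y_cm,
    )
    return track, truth


# --------------------------------------------------------------------------
# eYFP fluorescence


@dataclass
class EyfpSimParams:
    """Synthetic eYFP section: GM slab, WM slab, healthy-WM sub-region,
    and puncta painted at a known multiple of the analytic threshold."""

    shape: tuple = (256, 256)
    gm_mean: float = 100.0
    wm_healthy_ratio: float = 1.25
    factor: float = 1.5  # threshold multiplier the analysis will use
    puncta_fraction: float = 0.10  # target fraction of WM area painted
    puncta_radius_px: int = 3
    puncta_intensity_factor: float = 2.0  # multiple of the analytic threshold
    noise_sd_frac: float = 0.0  # Gaussian noise SD as a fraction of gm_mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gm_mean <= 0 or self.wm_healthy_ratio <= 0:
            raise ValueError("intensities must be positive")
        if not (0.0 <= self.puncta_fraction < 0.5):
            raise ValueError("puncta_fraction must be in [0, 0.5)")
        if self.puncta_intensity_factor <= 1.0:
            raise ValueError("puncta must be painted above the threshold")


def gen_eyfp_image(
    params: EyfpSimParams | None = None,
) -> tuple[ImageWithMasks, float]:
    """One synthetic fluorescence section and its true suprathreshold percent.

    Grey matter fills the left 40% of columns at ``gm_mean``; white matter
    fills the right 55% at ``gm_mean * wm_healthy_ratio``; the healthy-WM
    reference ROI is a box inside the white matter kept free of puncta so the
    cohort standardized ratio stays exact.  Puncta disks are painted in the
    remaining white matter at ``puncta_intensity_factor`` times the analytic
    threshold, trimmed to exactly the requested pixel count, so
    ``true_percent`` is exact by construction at zero noise.
    """
    p = params or EyfpSimParams()
    rng = np.random.default_rng(p.seed)
    h, w = p.shape
    img = np.zeros((h, w), dtype=float)
    gm = np.zeros((h, w), dtype=bool)
    wm = np.zeros((h, w), dtype=bool)
    gm[:, : int(0.40 * w)] = True
    wm[:, int(0.45 * w) :] = True
    healthy = np.zeros((h, w), dtype=bool)
    hw0, hw1 = int(0.80 * w), w
    healthy[int(0.1 * h) : int(0.9 * h), hw0:hw1] = True
    healthy &= wm

    wm_level = p.gm_mean * p.wm_healthy_ratio
    img[gm] = p.gm_mean
    img[wm] = wm_level
    threshold = p.wm_healthy_ratio * p.gm_mean * p.factor

    target_px = int(round(p.puncta_fraction * wm.sum()))
    paint = np.zeros((h, w), dtype=bool)
    paintable = wm & ~healthy
    r = p.puncta_radius_px
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = yy**2 + xx**2 <= r**2
    cand_rows, cand_cols = np.nonzero(paintable)
    if target_px > 0 and cand_rows.size == 0:
        raise ValueError("no paintable white matter for puncta")
    attempts = 0
    while paint.sum() < target_px:
        attempts += 1
        if attempts > 100_000:
            raise ValueError("puncta exceed white-matter capacity")
        i = rng.integers(cand_rows.size)
        cy, cx = int(cand_rows[i]), int(cand_cols[i])
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        sub = disk[(y0 - cy + r) : (y1 - cy + r), (x0 - cx + r) : (x1 - cx + r)]
        region = paintable[y0:y1, x0:x1] & sub
        paint[y0:y1, x0:x1] |= region
    # trim overshoot to hit the target pixel count exactly
    excess = int(paint.sum()) - target_px
    if excess > 0:
        pr, pc = np.nonzero(paint)
        drop = rng.choice(pr.size, size=excess, replace=False)
        paint[pr[drop], pc[drop]] = False

    img[paint] = threshold * p.puncta_intensity_factor
    if p.noise_sd_frac > 0:
        img = img + rng.normal(0.0, p.noise_sd_frac * p.gm_mean, img.shape)
        img = np.clip(img, 0.0, None)

    true_percent = 100.0 * float(paint.sum()) / float(wm.sum())
    image = ImageWithMasks(
        intensity=img, wm_mask=wm, gm_mask=gm, healthy_wm_mask=healthy,
        name=f"synthetic_eyfp_seed{p.seed}",
    )
    return image, true_percent


# --------------------------------------------------------------------------
# axon / myelin annuli


@dataclass
class AxonSimParams:
    """Synthetic TEM-style segmentation field of elliptical axon annuli."""

    field_size_px: int = 512
    pixel_size_um: float = 0.02
    n_axons: int = 30
    radius_px_range: tuple = (8.0, 20.0)
    #: explicit target g-ratios; if None, drawn from a two-component
    #: mixture around 0.7 (mature myelin) and 0.85 (thin remyelinated)
    g_values: Sequence[float] | None = None
    mix_high_fraction: float = 0.5
    g_low: float = 0.70
    g_high: float = 0.85
    g_sd: float = 0.02
    ellipticity_range: tuple = (1.0, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_px_range[0] < 5:
            raise ValueError("axon radii must be at least 5 px")
        if self.n_axons < 1:
            raise ValueError("n_axons must be >= 1")


def gen_axon_field(
    params: AxonSimParams | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, float]:
    """Rasterize non-overlapping axon/myelin annuli with exact area truth.

    Returns ``(axon_mask, myelin_mask, truth, field_area_um2)``.  Truth has
    one row per placed axon with pixel counts and the true area-equivalent
    g-ratio computed from those same counts, so it is exact under the
    pipeline's definition.  Axons that cannot be placed without overlap
    after bounded retries are dropped with fewer axons in the field.
    """
    p = params or AxonSimParams()
    rng = np.random.default_rng(p.seed)
    size = p.field_size_px
    axon_mask = np.zeros((size, size), dtype=np.uint16)
    myelin_mask = np.zeros((size, size), dtype=np.uint16)

    if p.g_values is not None:
        gs = list(p.g_values)[: p.n_axons]
        if len(gs) < p.n_axons:
            raise ValueError("g_values shorter than n_axons")
    else:
        high = rng.random(p.n_axons) < p.mix_high_fraction
        gs = np.where(
            high,
            rng.normal(p.g_high, p.g_sd, p.n_axons),
            rng.normal(p.g_low, p.g_sd, p.n_axons),
        )
        gs = np.clip(gs, 0.55, 0.97).tolist()

    placed = []  # (cx, cy, outer_radius)
    rows = []
    yy, xx = np.mgrid[0:size, 0:size]
    label = 0
    for g_target in gs:
        r_ax = rng.uniform(*p.radius_px_range)
        ell = rng.uniform(*p.ellipticity_range)
        a_ax, b_ax = r_ax * math.sqrt(ell), r_ax / math.sqrt(ell)
        scale = 1.0 / g_target if g_target < 1.0 else 1.0
        a_f, b_f = a_ax * scale, b_ax * scale
        r_out = max(a_f, b_f)
        ok = False
        for _ in range(200):
            cx = rng.uniform(r_out + 2, size - r_out - 3)
            cy = rng.uniform(r_out + 2, size - r_out - 3)
            if all(
                math.hypot(cx - px, cy - py) > r_out + pr + 2 for px, py, pr in placed
            ):
                ok = True
                break
        if not ok:
            continue  # field too crowded; fewer axons with a shorter truth table
        placed.append((cx, cy, r_out))
        theta = rng.uniform(0, math.pi)
        ct, st = math.cos(theta), math.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        in_axon = (xr / a_ax) ** 2 + (yr / b_ax) ** 2 <= 1.0
        in_fiber = (xr / a_f) ** 2 + (yr / b_f) ** 2 <= 1.0
        label += 1
        axon_mask[in_axon] = label
        myelin_mask[in_fiber & ~in_axon] = label
        n_ax = int(in_axon.sum())
        n_my = int((in_fiber & ~in_axon).sum())
        g_true = math.sqrt(n_ax / (n_ax + n_my)) if (n_ax + n_my) else 1.0
        rows.append(
            {
                "label": label,
                "g_target": float(g_target),
                "n_axon_px": n_ax,
                "n_myelin_px": n_my,
                "g_true": g_true,
                "myelinated": n_my > 0,
            }
        )
    truth = pd.DataFrame(rows)
    field_area_um2 = (size * p.pixel_size_um) ** 2
    return axon_mask, myelin_mask, truth, field_area_um2


# --------------------------------------------------------------------------
# clinical scores


def gen_clinical_cohort(
    n_per_group: int = 10,
    *,
    groups: Mapping[str, float] | None = None,
    onset_dpi_range: tuple = (9, 12),
    peak_range: tuple = (2.5, 4.0),
    peak_dpi: int = 16,
    end_dpi: int = 44,
    daily_jitter_sd: float = 0.3,
    seed: int = 0,
) -> list[ClinicalTrajectory]:
    """Simulate ordinal clinical-score trajectories for treatment groups.

    ``groups`` maps group label to recovery rate in score points per week
    after ``peak_dpi`` (default: vehicle 0.35, treated 0.9 — the treated
    group declines faster after dosing onset at peak disease).  Scores are
    zero before a per-animal onset day, ramp linearly to a per-animal peak
    at ``peak_dpi``, decline at the group rate afterwards, get daily
    Gaussian jitter, and are rounded to the 0.5 grid and clipped to [0, 5].
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    groups = dict(groups) if groups is not None else {"vehicle": 0.35, "treated": 0.9}
    rng = np.random.default_rng(seed)
    days = np.arange(0, end_dpi + 1)
    cohort = []
    for group, rate_per_week in groups.items():
        for i in range(n_per_group):
            onset = rng.integers(onset_dpi_range[0], onset_dpi_range[1] + 1)
            peak = rng.uniform(*peak_range)
            traj = np.zeros(days.size)
            ramp = (days >= onset) & (days <= peak_dpi)
            traj[ramp] = peak * (days[ramp] - onset) / max(peak_dpi - onset, 1)
            post = days > peak_dpi
            traj[post] = peak - rate_per_week / 7.0 * (days[post] - peak_dpi)
            traj += rng.normal(0.0, daily_jitter_sd, days.size)
            traj = np.clip(np.round(traj * 2.0) / 2.0, 0.0, 5.0)
            cohort.append(
                ClinicalTrajectory(
                    animal_id=f"{group}_{i + 1:02d}",
                    group=group,
                    scores={int(d): float(s) for d, s in zip(days, traj)},
                )
            )
    return cohort


# --------------------------------------------------------------------------
# qPCR plates


def gen_qpcr_plate(
    true_folds: Mapping[str, float] | None = None,
    references: Sequence[str] = ("hprt1", "gapdh"),
    *,
    n_per_group: int = 7,
    control_group: str = "vehicle",
    treated_group: str = "treated",
    n_replicates: int = 3,
    ref_stability_sd: float = 0.05,
    target_bio_sd: float = 0.1,
    replicate_sd: float = 0.05,
    sample_shift_sd: float = 0.3,
    seed: int = 0,
) -> tuple[CqTable, dict]:
    """Simulate a technical-triplicate Cq table with known fold changes.

    ``true_folds`` maps target gene to the treated-vs-control expression
    fold (default {"mbp": 2.0, "il17": 0.5, "gfap": 1.0}).  Per sample,
    every gene shares a global Cq shift (RNA loading); reference genes get
    ``ref_stability_sd`` biological jitter, targets ``target_bio_sd``; each
    technical replicate adds ``replicate_sd`` noise.  With all SDs zero the
    ddCq pipeline recovers the true folds exactly.

    Returns the table and a truth dict {target: fold}.
    """
    true_folds = dict(true_folds) if true_folds is not None else {
        "mbp": 2.0, "il17": 0.5, "gfap": 1.0,
    }
    references = list(references)
    if len(references) < 2:
        raise ValueError("at least two reference genes required")
    overlap = set(true_folds) & set(references)
    if overlap:
        raise ValueError(f"genes both target and reference: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    genes = list(true_folds) + references
    base_cq = {g: rng.uniform(20.0, 26.0) for g in genes}
    rows = []
    for group in (control_group, treated_group):
        for i in range(n_per_group):
            sid = f"{group}_{i + 1:02d}"
            shift = rng.normal(0.0, sample_shift_sd) if sample_shift_sd > 0 else 0.0
            for g in genes:
                cq = base_cq[g] + shift
                if g in true_folds:
                    if group == treated_group:
                        cq -= math.log2(true_folds[g])
                    if target_bio_sd > 0:
                        cq += rng.normal(0.0, target_bio_sd)
                else:
                    if ref_stability_sd > 0:
                        cq += rng.normal(0.0, ref_stability_sd)
                for rep in range(1, n_replicates + 1):
                    cq_rep = cq + (
                        rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0
                    )
                    rows.append(
                        {
                            "sample_id": sid,
                            "group": group,
                            "gene": g,
                            "replicate": rep,
                            "cq": cq_rep,
                        }
                    )
    return CqTable(pd.DataFrame(rows)), dict(true_folds)
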