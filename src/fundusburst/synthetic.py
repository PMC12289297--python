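"""Synthetic fundus phantoms, burst acquisitions and two-camera study sessions.

Everything downstream of the camera — burst fusion, quality control, grader
statistics — is exercised against data generated here, with full ground truth
(per-frame gaze shifts, per-class artifact masks, latent image quality), so no
external dataset is required.

The phantom is a stylized macula-centered 45-degree fundus: a bright optic
disc, a darker macula, and branching curvilinear vessels radiating from the
disc over a textured background, all inside a circular field-of-view (FOV)
mask.  It is not photorealistic; downstream operators are contrast/geometry
based and only need plausible structure.

Coordinates are 0-based, row-major, origin top-left; shifts are (dy, dx) with
positive down/right.  All operations are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .utils import inscribed_circle_mask, integer_shift

__all__ = [
    "FundusPhantom",
    "LashSpec",
    "HazeSpec",
    "BlurSpec",
    "SaturationSpec",
    "ArtifactSpec",
    "HEAVY_ARTIFACTS",
    "IlluminationSchedule",
    "BurstConfig",
    "BurstStack",
    "SessionTable",
    "generate_phantom",
    "simulate_burst",
    "simulate_session",
    "default_quality_model",
    "default_grader_model",
    "majority_prob",
    "expected_proportion",
    "p_good_for_marginal",
    "SINGLE_FLASH_BUDGET_MS",
]

SINGLE_FLASH_BUDGET_MS = 200.0  # a burst must fit in one perceived flash
MAX_BURST_FRAMES = 30

ARTIFACT_CLASSES = ("lash", "haze", "blur", "darkness", "saturation")


# ---------------------------------------------------------------------------
# phantom


@dataclass(frozen=True)
class FundusPhantom:
    """Stylized fundus image with ground-truth geometry.

    ``image`` is a 2-D float array in [0, 1]; pixels outside ``fov_mask`` are 0.
    """

    image: np.ndarray
    fov_mask: np.ndarray
    vessel_mask: np.ndarray
    disc_center: tuple[int, int]
    disc_radius: float
    macula_center: tuple[int, int]
    seed: int

    @property
    def side(self) -> int:
        return self.image.shape[0]


def _grow_vessels(
    rng: np.random.Generator,
    side: int,
    disc_center: tuple[int, int],
    disc_radius: float,
    density: float,
    fov: np.ndarray,
) -> np.ndarray:
    """Random branching walks from the disc rim; stamped with tapering width."""
    mask = np.zeros((side, side), dtype=bool)
    n_major = max(2, int(round(60 * density)))
    # (y, x, heading, remaining steps, half-width)
    queue: list[tuple[float, float, float, int, float]] = []
    for k in range(n_major):
        ang = 2.0 * np.pi * (k + rng.uniform(-0.2, 0.2)) / n_major
        y0 = disc_center[0] + disc_radius * np.sin(ang)
        x0 = disc_center[1] + disc_radius * np.cos(ang)
        queue.append((y0, x0, ang, int(0.65 * side), 0.012 * side))
    max_segments = 6 * n_major
    n_segments = 0
    while queue and n_segments < max_segments:
        y, x, heading, steps, hw = queue.pop()
        n_segments += 1
        for t in range(steps):
            y += np.sin(heading)
            x += np.cos(heading)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < side and 0 <= ix < side) or not fov[iy, ix]:
                break
            r = max(1, int(round(hw * (1.0 - 0.6 * t / steps))))
            mask[max(0, iy - r) : iy + r + 1, max(0, ix - r) : ix + r + 1] = True
            heading += rng.normal(0.0, 0.06)
            if rng.random() < 0.015 and steps - t > 20:
                branch = heading + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 0.8)
                queue.append((y, x, branch, int(0.6 * (steps - t)), hw * 0.75))
    return mask & fov


def generate_phantom(
    seed: int,
    side_px: int = 256,
    vessel_density: float = 0.1,
    disc_params: dict | None = None,
) -> FundusPhantom:
    """Render a deterministic fundus phantom.

    Parameters
    ----------
    seed : int
        Seeds every random element; equal seed and parameters give
        bit-identical output.
    side_px : int
        Image side in pixels, at least 128.
    vessel_density : float
        In (0, 1]; controls the number of major vessel trees.
    disc_params : dict, optional
        Overrides for ``radius_frac``, ``center_frac`` (row, col fractions)
        and ``brightness`` of the optic disc.
    """
    if side_px < 128:
        raise ValueError(f"side_px must be >= 128, got {side_px}")
    if not (0.0 < vessel_density <= 1.0):
        raise ValueError(f"vessel_density must be in (0, 1], got {vessel_density}")
    params = {"radius_frac": 0.075, "center_frac": (0.5, 0.70), "brightness": 0.30}
    if disc_params:
        unknown = set(disc_params) - set(params)
        if unknown:
            raise ValueError(f"unknown disc_params {sorted(unknown)}")
        params.update(disc_params)

    rng = np.random.default_rng(seed)
    n = side_px
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    fov = inscribed_circle_mask((n, n))

    # textured background with a gentle vertical illumination gradient
    img = 0.45 + 0.04 * (yy - n / 2) / n
    tex = ndimage.gaussian_filter(rng.standard_normal((n, n)), n / 48.0)
    img += tex * (0.06 / (tex.std() + 1e-12))

    # bright, slightly elliptical optic disc
    dc = (
        int(round(params["center_frac"][0] * (n - 1))),
        int(round(params["center_frac"][1] * (n - 1))),
    )
    dr = params["radius_frac"] * n
    d_dist = np.hypot(yy - dc[0], (xx - dc[1]) / 1.15)
    img += params["brightness"] * (0.5 * (1.0 + np.tanh((dr - d_dist) / (0.2 * dr))))

    # darker macula, nasal of center in this layout
    mc = (int(round(0.5 * (n - 1))), int(round(0.40 * (n - 1))))
    img -= 0.12 * np.exp(-(((yy - mc[0]) ** 2 + (xx - mc[1]) ** 2) / (0.10 * n) ** 2))

    vessel_mask = _grow_vessels(rng, n, dc, dr, vessel_density, fov)
    soft = ndimage.gaussian_filter(vessel_mask.astype(float), 0.8)
    img -= 0.18 * np.clip(soft / max(soft.max(), 1e-9), 0.0, 1.0)

    img = np.clip(img, 0.0, 1.0)
    img[~fov] = 0.0
    return FundusPhantom(
        image=img,
        fov_mask=fov,
        vessel_mask=vessel_mask,
        disc_center=dc,
        disc_radius=dr,
        macula_center=mc,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# artifact and burst specification


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class LashSpec:
    """Eyelash occlusions: dark thick arcs entering from the top of the FOV."""

    count: int = 0
    thickness_px: float = 6.0
    opacity: float = 0.8

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("lash count must be >= 0")
        _check_unit("lash opacity", self.opacity)


@dataclass(frozen=True)
class HazeSpec:
    """Low-frequency scatter veil (cataract / media opacity stand-in)."""

    amplitude: float = 0.0
    spatial_scale_px: float = 64.0

    def __post_init__(self) -> None:
        _check_unit("haze amplitude", self.amplitude)
        if self.spatial_scale_px <= 0:
            raise ValueError("haze spatial scale must be positive")


@dataclass(frozen=True)
class BlurSpec:
    """Defocus blur applied to a fraction of the frames."""

    kernel_radius_px: float = 0.0
    frame_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel_radius_px < 0:
            raise ValueError("blur kernel radius must be >= 0")
        _check_unit("blur frame fraction", self.frame_fraction)


@dataclass(frozen=True)
class SaturationSpec:
    """Specular bright spots (corneal / lens reflections)."""

    spot_count: int = 0
    radius_px: float = 12.0

    def __post_init__(self) -> None:
        if self.spot_count < 0:
            raise ValueError("saturation spot count must be >= 0")
        if self.radius_px <= 0:
            raise ValueError("saturation radius must be positive")


@dataclass(frozen=True)
class ArtifactSpec:
    """Per-stack degradation recipe; all amplitudes 0 means artifact-free."""

    lash_occlusion: LashSpec = field(default_factory=LashSpec)
    haze: HazeSpec = field(default_factory=HazeSpec)
    blur: BlurSpec = field(default_factory=BlurSpec)
    darkness_gain: float = 1.0
    saturation: SaturationSpec = field(default_factory=SaturationSpec)

    def __post_init__(self) -> None:
        if not (0.0 < self.darkness_gain <= 1.0):
            raise ValueError(f"darkness_gain must be in (0, 1], got {self.darkness_gain}")

    @property
    def is_null(self) -> bool:
        return (
            self.lash_occlusion.count == 0
            and self.haze.amplitude == 0.0
            and (self.blur.kernel_radius_px == 0.0 or self.blur.frame_fraction == 0.0)
            and self.darkness_gain == 1.0
            and self.saturation.spot_count == 0
        )


#: Heavy degradation recipe used for the artifact arm of cutoff calibration.
HEAVY_ARTIFACTS = ArtifactSpec(
    lash_occlusion=LashSpec(count=3, thickness_px=9.0, opacity=0.9),
    haze=HazeSpec(amplitude=0.5, spatial_scale_px=64.0),
    blur=BlurSpec(kernel_radius_px=4.0, frame_fraction=1.0),
    darkness_gain=0.45,
    saturation=SaturationSpec(spot_count=4, radius_px=20.0),
)


@dataclass(frozen=True)
class IlluminationSchedule:
    """Per-frame spatially varying gain: a radial vignette whose center is
    jittered from frame to frame, abstracting the camera's sweep of
    illumination configurations across the pupil."""

    vignette_strength: float = 0.25
    center_jitter_px: float = 0.0

    def __post_init__(self) -> None:
        _check_unit("vignette_strength", self.vignette_strength)
        if self.center_jitter_px < 0:
            raise ValueError("center_jitter_px must be >= 0")


@dataclass(frozen=True)
class BurstConfig:
    """Acquisition parameters for one burst.

    ``gaze_model`` is either an explicit list of per-frame integer (dy, dx)
    shifts, or ``{"kind": "random_walk", "step_px": s}`` for a bounded-step
    integer random walk starting at (0, 0).
    """

    n_frames: int = 20
    frame_interval_ms: float = 6.0
    gaze_model: object = None
    illumination: IlluminationSchedule = field(default_factory=IlluminationSchedule)
    noise_sd: float = 0.01
    single_flash: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_frames <= MAX_BURST_FRAMES):
            raise ValueError(f"n_frames must be in 1..{MAX_BURST_FRAMES}, got {self.n_frames}")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.single_flash and self.duration_ms >= SINGLE_FLASH_BUDGET_MS:
            raise ValueError(
                f"single-flash burst must complete in under {SINGLE_FLASH_BUDGET_MS:.0f} ms; "
                f"{self.n_frames} x {self.frame_interval_ms} ms = {self.duration_ms} ms"
            )

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms

    def resolve_shifts(self, rng: np.random.Generator) -> list[tuple[int, int]]:
        gm = self.gaze_model
        if gm is None:
            gm = {"kind": "random_walk", "step_px": 1}
        if isinstance(gm, dict):
            if gm.get("kind") != "random_walk":
                raise ValueError(f"unknown gaze model {gm!r}")
            s = int(gm.get("step_px", 1))
            steps = rng.integers(-s, s + 1, size=(self.n_frames, 2))
            steps[0] = 0
            cum = np.cumsum(steps, axis=0)
            return [(int(dy), int(dx)) for dy, dx in cum]
        shifts = [(int(dy), int(dx)) for dy, dx in gm]
        if len(shifts) != self.n_frames:
            raise ValueError(
                f"gaze model lists {len(shifts)} shifts for {self.n_frames} frames"
            )
        return shifts


@dataclass
class BurstStack:
    """Ordered burst frames plus acquisition metadata and (for synthetic
    stacks) ground truth: true per-frame shifts and per-class artifact masks."""

    frames: list[np.ndarray]
    metadata: BurstConfig
    truth: dict | None = None
    source_id: str = ""
    fov_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a BurstStack needs at least one frame")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames in a stack must share one shape")
        if self.truth is not None and len(self.truth["shifts"]) != len(self.frames):
            raise ValueError("truth shifts length must equal the frame count")
        if self.fov_mask is None:
            self.fov_mask = inscribed_circle_mask(shape)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.frames[0].shape


# ---------------------------------------------------------------------------
# burst simulation


def _vignette(shape: tuple[int, int], center: tuple[float, float], strength: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r = np.hypot(yy - center[0], xx - center[1]) / (min(h, w) / 2.0)
    return 1.0 - strength * np.clip(r, 0.0, 1.2) ** 2


def _apply_lashes(img: np.ndarray, fov: np.ndarray, spec: LashSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = img.shape
    occ = np.zeros((h, w), dtype=float)
    r = max(1, int(round(spec.thickness_px / 2)))
    for _ in range(spec.count):
        x = rng.uniform(0.25 * w, 0.75 * w)
        y = rng.uniform(0.0, 0.15 * h)
        heading = np.pi / 2 + rng.uniform(-0.5, 0.5)
        for _step in range(int(0.5 * h)):
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < h and 0 <= ix < w):
                break
            occ[max(0, iy - r) : iy + r + 1, max(0, ix - r) : ix + r + 1] = 1.0
            heading += rng.normal(0.0, 0.05) + 0.004  # gentle curl
            y += np.sin(heading)
            x += np.cos(heading)
    occ = ndimage.gaussian_filter(occ, 1.0)
    return img * (1.0 - spec.opacity * np.clip(occ, 0.0, 1.0) * fov)


def _apply_haze(img: np.ndarray, fov: np.ndarray, spec: HazeSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = img.shape
    f = ndimage.gaussian_filter(rng.standard_normal((h, w)), spec.spatial_scale_px / 2.0)
    f = f - f.min()
    f = spec.amplitude * f / max(f.max(), 1e-12)
    # veil: convex pull toward a bright gray scatter level
    return np.where(fov, img * (1.0 - f) + 0.75 * f, img)


def _apply_saturation(img: np.ndarray, fov: np.ndarray, spec: SaturationSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    c = ((h - 1) / 2.0, (w - 1) / 2.0)
    out = img
    for _ in range(spec.spot_count):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rad = rng.uniform(0.0, 0.6) * (min(h, w) / 2.0)
        cy, cx = c[0] + rad * np.sin(ang), c[1] + rad * np.cos(ang)
        d = np.hypot(yy - cy, xx - cx)
        p = np.clip((spec.radius_px - d) / (0.4 * spec.radius_px), 0.0, 1.0)
        out = np.where(fov, out * (1.0 - p) + 1.0 * p, out)
    return out


def simulate_burst(
    phantom: FundusPhantom,
    config: BurstConfig,
    artifacts: ArtifactSpec | None = None,
    source_id: str = "",
) -> BurstStack:
    """Simulate one burst acquisition of ``phantom``.

    Each frame is the phantom shifted by that frame's true gaze shift,
    multiplied by a per-frame illumination vignette, composited with the
    artifact layers of ``artifacts`` (lash arcs, haze veil, defocus on a
    subset of frames, global darkness gain, specular spots — positions drawn
    per frame), plus additive Gaussian noise, clipped to [0, 1].

    Ground truth recorded in ``stack.truth``: the exact shifts and, for each
    artifact class and frame, the boolean mask of pixels that class modified.
    """
    if artifacts is None:
        artifacts = ArtifactSpec()
    rng = np.random.default_rng(config.seed)
    shifts = config.resolve_shifts(rng)
    n = config.n_frames
    fov = phantom.fov_mask
    h, w = phantom.image.shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    n_blur = int(round(artifacts.blur.frame_fraction * n))
    blur_frames = set(rng.choice(n, size=n_blur, replace=False).tolist()) if n_blur else set()

    frames: list[np.ndarray] = []
    masks: dict[str, list[np.ndarray]] = {c: [] for c in ARTIFACT_CLASSES}
    for i in range(n):
        dy, dx = shifts[i]
        frame = integer_shift(phantom.image, dy, dx)
        jit = config.illumination.center_jitter_px
        off = rng.uniform(-jit, jit, size=2) if jit > 0 else np.zeros(2)
        frame = frame * _vignette((h, w), (center[0] + off[0], center[1] + off[1]),
                                  config.illumination.vignette_strength)

        def _tracked(fun, cls: str, cur: np.ndarray) -> np.ndarray:
            new = fun(cur)
            masks[cls].append(new != cur)
            return new

        frame = _tracked(
            lambda f: f * artifacts.darkness_gain if artifacts.darkness_gain < 1.0 else f,
            "darkness", frame)
        frame = _tracked(
            lambda f: _apply_haze(f, fov, artifacts.haze, rng)
            if artifacts.haze.amplitude > 0 else f,
            "haze", frame)
        frame = _tracked(
            lambda f: _apply_lashes(f, fov, artifacts.lash_occlusion, rng)
            if artifacts.lash_occlusion.count > 0 else f,
            "lash", frame)
        frame = _tracked(
            lambda f: _apply_saturation(f, fov, artifacts.saturation, rng)
            if artifacts.saturation.spot_count > 0 else f,
            "saturation", frame)
        frame = _tracked(
            lambda f: np.where(fov, ndimage.gaussian_filter(f, artifacts.blur.kernel_radius_px), f)
            if i in blur_frames and artifacts.blur.kernel_radius_px > 0 else f,
            "blur", frame)

        if config.noise_sd > 0:
            frame = frame + rng.normal(0.0, config.noise_sd, size=frame.shape) * fov
        frame = np.clip(frame, 0.0, 1.0)
        frame[~fov] = 0.0
        frames.append(frame)

    truth = {"shifts": shifts, "artifact_masks": masks}
    return BurstStack(frames=frames, metadata=config, truth=truth,
                      source_id=source_id or f"phantom-{phantom.seed}", fov_mask=fov)


# ---------------------------------------------------------------------------
# session simulation (two-camera paired study)


def majority_prob(p: float) -> float:
    """P(at least 2 of 3 independent Bernoulli(p) graders say yes)."""
    return 3.0 * p * p * (1.0 - p) + p ** 3


def default_grader_model() -> dict:
    """Grader behaviour given the latent good/bad state of an image.

    'Sufficient for clinical interpretation' and 'gradable' are distinct
    judgments with separate probabilities; graders are conditionally
    independent given the image state (shared latent quality + per-grader
    Bernoulli noise).
    """
    return {
        "p_sufficient": {"good": 0.995, "bad": 0.05},
        "p_gradable": {"good": 0.997, "bad": 0.45},
    }


def expected_proportion(p_good: float, p_label: dict) -> float:
    """Closed-form marginal P(majority label yes) under the session model."""
    return p_good * majority_prob(p_label["good"]) + (1.0 - p_good) * majority_prob(p_label["bad"])


def p_good_for_marginal(target: float, p_label: dict) -> float:
    """Invert :func:`expected_proportion` for the good-image probability."""
    lo, hi = majority_prob(p_label["bad"]), majority_prob(p_label["good"])
    if not (lo < target < hi):
        raise ValueError(f"target {target} not attainable with grader probs {p_label}")
    return (target - lo) / (hi - lo)


def default_quality_model(
    marginal_investigational: float = 0.985,
    marginal_reference: float = 0.971,
    grader_model: dict | None = None,
) -> dict:
    """Study conditions for the paired two-camera session.

    The good-image probabilities are set so that the closed-form marginal
    majority-sufficient proportions equal the requested targets (defaults
    match the comparative study's observed 98.5% / 97.1%).  The reference
    camera fails to capture more often (small pupils), mirroring the study's
    imbalance in uncaptured images.
    """
    gm = grader_model or default_grader_model()
    p_suff = gm["p_sufficient"]
    return {
        "p_good": {
            "investigational": p_good_for_marginal(marginal_investigational, p_suff),
            "reference": p_good_for_marginal(marginal_reference, p_suff),
        },
        "within_participant_corr": 0.3,
        "p_capture_fail": {"investigational": 3 / 209, "reference": 42 / 248},
        "p_both_eyes": 98 / 108,
        "p_qc_pass": {"good": 0.95, "bad": 0.08},
        "quality_beta": {"good": (12.0, 3.0), "bad": (2.5, 5.0)},
    }


SESSION_COLUMNS = [
    "participant_id", "eye", "camera", "acquisition_index", "capture_success",
    "qc_pass", "latent_quality", "true_good",
    "grader1_sufficient", "grader2_sufficient", "grader3_sufficient",
    "grader1_gradable", "grader2_gradable", "grader3_gradable",
]


@dataclass
class SessionTable:
    """Acquisition-level rows of a simulated two-camera session.

    One row per acquisition (up to 3 per participant-eye-camera); an
    eye-camera whose capture failed entirely contributes a single row with
    ``capture_success = False`` and missing labels, preserving the paired
    structure.  Columns are :data:`SESSION_COLUMNS`.
    """

    df: pd.DataFrame
    quality_model: dict
    grader_model: dict
    seed: int

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _validate_probs(model: dict, keys: Sequence[tuple]) -> None:
    for path in keys:
        v = model
        for k in path:
            v = v[k]
        if not (0.0 <= float(v) <= 1.0):
            raise ValueError(f"probability {'.'.join(map(str, path))}={v} outside [0, 1]")


def simulate_session(
    n_participants: int,
    quality_model: dict | None = None,
    grader_model: dict | None = None,
    seed: int = 0,
) -> SessionTable:
    """Simulate a paired two-camera acquisition session with known structure.

    Each participant contributes one or two eyes; each eye is imaged on both
    cameras (reference first, then investigational), with up to 3 acquisitions
    per eye-camera.  A latent good/bad image state drives QC decisions and
    all six grader labels; within-participant correlation is induced by a
    shared participant-level uniform reused (with probability
    ``within_participant_corr``) when thresholding the good-state draw, which
    leaves the marginal P(good) exact so expected proportions have a closed
    form (:func:`expected_proportion`).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    qm = quality_model or default_quality_model()
    gm = grader_model or default_grader_model()
    _validate_probs(qm, [("p_good", "investigational"), ("p_good", "reference"),
                         ("within_participant_corr",),
                         ("p_capture_fail", "investigational"), ("p_capture_fail", "reference"),
                         ("p_both_eyes",), ("p_qc_pass", "good"), ("p_qc_pass", "bad")])
    _validate_probs(gm, [("p_sufficient", "good"), ("p_sufficient", "bad"),
                         ("p_gradable", "good"), ("p_gradable", "bad")])

    rng = np.random.default_rng(seed)
    rho = float(qm["within_participant_corr"])

    both = rng.random(n_participants) < qm["p_both_eyes"]
    pidx = np.repeat(np.arange(n_participants), np.where(both, 2, 1))
    n_eyes = pidx.size
    eye = np.empty(n_eyes, dtype=object)
    first_of_p = np.r_[True, np.diff(pidx) != 0]
    eye[first_of_p] = "R"
    eye[~first_of_p] = "L"
    u_part = rng.random(n_participants)

    pieces = []
    for camera in ("reference", "investigational"):
        p_good = float(qm["p_good"][camera])
        fail = rng.random(n_eyes) < qm["p_capture_fail"][camera]
        use_shared = rng.random(n_eyes) < rho
        v = np.where(use_shared, u_part[pidx], rng.random(n_eyes))
        good = v < p_good
        a_good = qm["quality_beta"]["good"]
        a_bad = qm["quality_beta"]["bad"]
        q = np.where(good,
                     rng.beta(a_good[0], a_good[1], n_eyes),
                     rng.beta(a_bad[0], a_bad[1], n_eyes))
        p_qc = np.where(good, qm["p_qc_pass"]["good"], qm["p_qc_pass"]["bad"])
        qc_draws = rng.random((n_eyes, 3)) < p_qc[:, None]
        if camera == "investigational":
            # stop after the first QC pass, else after 3 attempts
            any_pass = qc_draws.any(axis=1)
            n_acq = np.where(any_pass, qc_draws.argmax(axis=1) + 1, 3)
        else:
            n_acq = rng.integers(1, 4, size=n_eyes)  # operator discretion
        n_acq = np.where(fail, 1, n_acq)

        p_suff = np.where(good, gm["p_sufficient"]["good"], gm["p_sufficient"]["bad"])
        p_grad = np.where(good, gm["p_gradable"]["good"], gm["p_gradable"]["bad"])
        suff = rng.random((n_eyes, 3)) < p_suff[:, None]
        grad = rng.random((n_eyes, 3)) < p_grad[:, None]

        rep = np.repeat(np.arange(n_eyes), n_acq)
        acq_index = np.concatenate([np.arange(1, k + 1) for k in n_acq])
        row_fail = fail[rep]
        qc = qc_draws[rep, acq_index - 1]
        df = pd.DataFrame({
            "participant_id": [f"P{j:04d}" for j in pidx[rep]],
            "eye": eye[rep],
            "camera": camera,
            "acquisition_index": acq_index,
            "capture_success": ~row_fail,
            "qc_pass": np.where(row_fail, np.nan, qc.astype(float)),
            "latent_quality": np.where(row_fail, np.nan, q[rep]),
            "true_good": np.where(row_fail, np.nan, good[rep].astype(float)),
        })
        for g in range(3):
            df[f"grader{g + 1}_sufficient"] = np.where(row_fail, np.nan, suff[rep, g].astype(float))
            df[f"grader{g + 1}_gradable"] = np.where(row_fail, np.nan, grad[rep, g].astype(float))
        pieces.append(df)

    out = pd.concat(pieces, ignore_index=True)[SESSION_COLUMNS]
    out = out.sort_values(["participant_id", "eye", "camera", "acquisition_index"],
                          kind="stable").reset_index(drop=True)
    return SessionTable(df=out, quality_model=qm, grader_model=gm, seed=int(seed))
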