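"""Synthetic layered B-scan generator with frame averaging and media opacity.

The generator emulates the statistical structure the quality analysis
assumes: a piecewise-layered retina with distinct per-layer mean
reflectivities, per-frame uncorrelated noise, an optional frame-correlated
noise floor (one spatial field shared by every frame of a stack — the
mechanism that caps achievable SNR however many frames are averaged),
optional multiplicative speckle, optional per-frame axial jitter, and a
media-opacity (cataract-like) condition that attenuates signal and inflates
the uncorrelated noise.

A study dataset mirrors a two-visit averaging protocol: for each eye, seven
averaged scans per visit at 2, 4, 8, 16, 32, 48 and 96 frames, acquired in
randomized order on identical geometry (the follow-up alignment means pre-
and postoperative scans of one eye share a single boundary annotation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .annotations import (
    BoundarySet,
    N_BOUNDARIES,
    rasterize,
    read_boundaries,
    write_boundaries,
)
from .errors import ConfigurationError, FormatError
from .image import BScan, read_scan_tiff, round_half_up, write_scan_tiff

logger = logging.getLogger(__name__)

__all__ = [
    "BoundaryCurve", "SceneConfig", "NoiseConfig", "StudyDesign",
    "FrameStack", "EyeData", "StudyDataset",
    "generate_clean_scan", "generate_frames", "average_frames",
    "simulate_study", "write_dataset", "load_dataset",
]

CONDITIONS = ("pre", "post")
DEFAULT_SETTINGS = (2, 4, 8, 16, 32, 48, 96)


@dataclass
class BoundaryCurve:
    """Smooth boundary geometry for one boundary: a low-order polynomial in
    normalized column position x in [-1, 1] plus an optional Gaussian
    foveal-dip bump (positive amplitude pushes the boundary deeper).
    """

    offset: float                 # c0, rows
    tilt: float = 0.0             # c1, rows per unit x
    curvature: float = 0.0        # c2, rows per unit x^2
    dip_amplitude: float = 0.0    # rows, at dip center
    dip_center: float = 0.0       # normalized x of the dip
    dip_width: float = 0.12       # normalized x std of the dip

    def evaluate(self, width: int) -> np.ndarray:
        x = np.linspace(-1.0, 1.0, width)
        y = self.offset + self.tilt * x + self.curvature * x**2
        if self.dip_amplitude != 0.0:
            y = y + self.dip_amplitude * np.exp(
                -0.5 * ((x - self.dip_center) / self.dip_width) ** 2
            )
        return y


# Default boundary geometry as fractions of image depth, so scenes scale to
# small test images.  Offsets place ~5 layers in the middle of the scan with
# a gentle bowl and a foveal dip that fades with depth.
_BASE_OFFSET_FRAC = (0.282, 0.319, 0.434, 0.500, 0.554, 0.706)
_BASE_DIP_FRAC = (0.060, 0.048, 0.032, 0.016, 0.008, 0.0)
_BASE_CURVATURE_FRAC = 0.016


@dataclass
class SceneConfig:
    """Geometry and clean reflectivity of one synthetic retina.

    ``layer_means`` are the five annotated layers' clean intensities (NFL,
    GCL+IPL, INL, OPL, ONL); the flanking vitreous, sub-ELM band and
    background get their own means.  All intensities live in [0, 1].
    """

    width: int = 512
    depth: int = 496
    layer_means: tuple[float, ...] = (0.72, 0.40, 0.26, 0.48, 0.14)
    vitreous_mean: float = 0.05
    sub_elm_mean: float = 0.42
    background_mean: float = 0.08
    boundary_params: list[BoundaryCurve] = field(default_factory=list)
    band: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_means) != 5:
            raise ConfigurationError("exactly 5 layer means required")
        means = (*self.layer_means, self.vitreous_mean, self.sub_elm_mean,
                 self.background_mean)
        if any(not (0.0 <= m <= 1.0) for m in means):
            raise ConfigurationError("region means must lie in [0, 1]")
        if not self.boundary_params:
            self.boundary_params = _default_boundaries(self.depth)
        if len(self.boundary_params) != N_BOUNDARIES:
            raise ConfigurationError(
                f"exactly {N_BOUNDARIES} boundary curves required"
            )

    @property
    def region_means(self) -> np.ndarray:
        """Means indexed by label code VITREOUS..BELOW."""
        return np.array(
            [self.vitreous_mean, *self.layer_means, self.sub_elm_mean,
             self.background_mean]
        )


def _default_boundaries(depth: int) -> list[BoundaryCurve]:
    return [
        BoundaryCurve(
            offset=f * depth,
            curvature=_BASE_CURVATURE_FRAC * depth,
            dip_amplitude=d * depth,
        )
        for f, d in zip(_BASE_OFFSET_FRAC, _BASE_DIP_FRAC)
    ]


@dataclass
class NoiseConfig:
    """Acquisition noise model for one media condition.

    sigma_u
        Per-frame uncorrelated Gaussian noise scale (grey value units).
    sigma_c
        Scale of the frame-correlated noise floor: one spatial Gaussian field
        drawn per stack and added to every frame, so it survives averaging.
    speckle_shape
        Gamma shape of unit-mean multiplicative speckle, or None to disable.
    opacity
        Signal attenuation in (0, 1]; 1 means clear media.
    noise_inflation
        Multiplier on sigma_u applied when opacity < 1 (scattering media
        inflate speckle noise more than they dim the mean signal).
    jitter_px
        Std of a per-frame random axial sub-pixel shift; models imperfect
        tracking and produces the smoothing cost of heavy averaging.
    """

    sigma_u: float = 0.06
    sigma_c: float = 0.0
    speckle_shape: float | None = None
    opacity: float = 1.0
    noise_inflation: float = 1.0
    jitter_px: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_u <= 0:
            raise ConfigurationError("sigma_u must be > 0")
        if self.sigma_c < 0:
            raise ConfigurationError("sigma_c must be >= 0")
        if not (0.0 < self.opacity <= 1.0):
            raise ConfigurationError("opacity must lie in (0, 1]")
        if self.jitter_px < 0:
            raise ConfigurationError("jitter_px must be >= 0")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ConfigurationError("speckle_shape must be > 0 or None")

    @property
    def effective_sigma_u(self) -> float:
        return self.sigma_u * (self.noise_inflation if self.opacity < 1 else 1.0)

    @classmethod
    def clear_media(cls) -> "NoiseConfig":
        """Postoperative defaults: the correlated floor dominates beyond
        ~16 averaged frames, producing the quality plateau."""
        return cls(sigma_u=0.06, sigma_c=0.035, opacity=1.0)

    @classmethod
    def opaque_media(cls) -> "NoiseConfig":
        """Preoperative (cataract) defaults: attenuated signal with strongly
        inflated uncorrelated noise that dominates the (small) correlated
        floor, so quality keeps rising through 96 frames."""
        return cls(sigma_u=0.06, sigma_c=0.012, opacity=0.85,
                   noise_inflation=4.0)


@dataclass
class StudyDesign:
    """The averaging-protocol grid: eyes x settings x two conditions."""

    n_eyes: int = 13
    settings: tuple[int, ...] = DEFAULT_SETTINGS
    conditions: tuple[str, str] = CONDITIONS
    n_boundaries: int = 6
    n_layers: int = 5

    def __post_init__(self) -> None:
        s = tuple(int(m) for m in self.settings)
        if any(m <= 0 for m in s) or not all(b > a for a, b in zip(s, s[1:])):
            raise ConfigurationError(
                "settings must be strictly increasing positive ints"
            )
        self.settings = s
        if len(self.conditions) != 2:
            raise ConfigurationError("exactly two conditions required")
        if self.n_eyes < 1:
            raise ConfigurationError("n_eyes must be >= 1")


@dataclass
class FrameStack:
    """A stack of repeated frames of one scan location."""

    frames: np.ndarray  # (M, depth, width)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] < 1:
            raise ConfigurationError("frame stack must be (M>=1, depth, width)")
        self.frames = f

    @classmethod
    def from_frames(cls, frames: list[np.ndarray]) -> "FrameStack":
        if not frames:
            raise ConfigurationError("empty frame stack")
        shape = frames[0].shape
        if any(f.shape != shape for f in frames):
            raise ConfigurationError("all frames must share one shape")
        return cls(np.stack(frames))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def generate_clean_scan(cfg: SceneConfig) -> tuple[BScan, BoundarySet]:
    """Render the noise-free scene: each pixel takes the mean intensity of
    the region containing it; the returned boundaries are the exact
    generating geometry (real-valued curves rounded half-up to pixel rows).
    """
    curves = np.stack([c.evaluate(cfg.width) for c in cfg.boundary_params])
    rows = round_half_up(curves)
    if np.any(rows < 0) or np.any(rows >= cfg.depth):
        raise ConfigurationError("boundary curves leave the image depth range")
    if (np.diff(rows, axis=0) < 0).any():
        col = int(np.argmax((np.diff(rows, axis=0) < 0).any(axis=0)))
        raise ConfigurationError(f"boundary curves cross at column {col}")
    bset = BoundarySet(rows)
    mask = rasterize(bset, depth=cfg.depth, band=cfg.band)
    image = cfg.region_means[mask.labels]
    return BScan(image=image), bset


def generate_frames(
    clean: BScan,
    n_frames: int,
    noise: NoiseConfig,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> FrameStack:
    """Simulate a stack of repeated acquisitions of one clean scene.

    frame_i = jitter_shift(clean * opacity * speckle_i + u_i) + c, clipped to
    [0, 1]; u_i is per-frame iid Gaussian noise (inflated under opacity),
    speckle_i per-frame multiplicative gamma noise, and c one frame-correlated
    Gaussian field drawn once per stack.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    shape = clean.image.shape
    correlated = (
        rng.normal(0.0, noise.sigma_c, size=shape) if noise.sigma_c > 0 else 0.0
    )
    signal = clean.image * noise.opacity
    if noise.speckle_shape is not None:
        k = noise.speckle_shape
        speckle = rng.gamma(k, 1.0 / k, size=(n_frames, *shape))
        frames = signal[None] * speckle
    else:
        frames = np.broadcast_to(signal, (n_frames, *shape)).copy()
    frames += rng.normal(0.0, noise.effective_sigma_u, size=(n_frames, *shape))
    if noise.jitter_px > 0:
        shifts = rng.normal(0.0, noise.jitter_px, size=n_frames)
        for i in range(n_frames):
            frames[i] = ndimage.shift(
                frames[i], (shifts[i], 0.0), order=1, mode="nearest"
            )
    frames += correlated
    np.clip(frames, 0.0, 1.0, out=frames)
    return FrameStack(frames)


def average_frames(stack: FrameStack) -> BScan:
    """Pixel-wise arithmetic mean of a frame stack."""
    return BScan(image=stack.frames.mean(axis=0), n_averaged=stack.n_frames)


@dataclass
class EyeData:
    """All scans of one eye plus the shared ground-truth annotation."""

    eye_id: str
    boundaries: BoundarySet
    scans: dict[tuple[str, int], BScan]
    acquisition_order: dict[str, tuple[int, ...]]
    scene: SceneConfig | None = None


@dataclass
class StudyDataset:
    """A full simulated (or loaded) two-visit averaging study."""

    design: StudyDesign
    eyes: list[EyeData]
    seed: int | None = None
    band: int = 20
    gaps: list[dict] = field(default_factory=list)


def _perturbed_scene(scene: SceneConfig, rng: np.random.Generator) -> SceneConfig:
    """Seeded per-eye random effect on reflectivities and geometry, giving
    the between-eye heterogeneity a per-eye matching analysis needs."""
    scale = rng.normal(1.0, 0.04, size=8)
    means = np.clip(scene.region_means * scale, 0.02, 0.95)
    global_shift = rng.normal(0.0, 0.012) * scene.depth
    local = rng.normal(0.0, 0.003, size=N_BOUNDARIES) * scene.depth
    offsets = [
        c.offset + global_shift + local[k]
        for k, c in enumerate(scene.boundary_params)
    ]
    # enforce a minimum boundary spacing so perturbed curves cannot cross
    min_gap = 0.02 * scene.depth
    for k in range(1, N_BOUNDARIES):
        offsets[k] = max(offsets[k], offsets[k - 1] + min_gap)
    params = [
        replace(c, offset=offsets[k]) for k, c in enumerate(scene.boundary_params)
    ]
    return replace(
        scene,
        layer_means=tuple(means[1:6]),
        vitreous_mean=float(means[0]),
        sub_elm_mean=float(means[6]),
        background_mean=float(means[7]),
        boundary_params=params,
    )


def simulate_study(
    design: StudyDesign,
    scene: SceneConfig,
    noise_pre: NoiseConfig,
    noise_post: NoiseConfig,
    seed: int,
) -> StudyDataset:
    """Simulate the full eyes x settings x {pre, post} acquisition grid.

    Each eye gets one seeded scene perturbation and one boundary set shared
    by all its scans (the follow-up alignment); acquisition order per visit
    is randomized and recorded, though it does not influence synthesis.
    """
    if noise_pre.opacity >= 1.0:
        raise ConfigurationError("preoperative noise must have opacity < 1")
    if noise_post.opacity != 1.0:
        raise ConfigurationError("postoperative noise must have opacity = 1")
    root = np.random.SeedSequence(seed)
    eye_seeds = root.spawn(design.n_eyes)
    eyes: list[EyeData] = []
    for i in range(design.n_eyes):
        children = eye_seeds[i].spawn(2 + 2 * len(design.settings))
        rng_eye = np.random.default_rng(children[0])
        eye_scene = _perturbed_scene(scene, rng_eye)
        clean, bset = generate_clean_scan(eye_scene)
        order_rng = np.random.default_rng(children[1])
        acquisition_order = {
            cond: tuple(
                int(m) for m in order_rng.permutation(list(design.settings))
            )
            for cond in design.conditions
        }
        scans: dict[tuple[str, int], BScan] = {}
        eye_id = f"eye{i + 1:02d}"
        child_idx = 2
        for cond, noise in zip(design.conditions, (noise_pre, noise_post)):
            for m in design.settings:
                stack = generate_frames(clean, m, noise, children[child_idx])
                child_idx += 1
                scan = average_frames(stack)
                scan.eye, scan.condition = eye_id, cond
                scans[(cond, m)] = scan
        eyes.append(
            EyeData(
                eye_id=eye_id,
                boundaries=bset,
                scans=scans,
                acquisition_order=acquisition_order,
                scene=eye_scene,
            )
        )
        logger.info("simulated %s (%d scans)", eye_id, len(scans))
    return StudyDataset(
        design=design, eyes=eyes, seed=seed, band=scene.band
    )


# ---------------------------------------------------------------------------
# Dataset persistence: 8-bit TIFF scans, boundary CSVs, JSON manifest.

def write_dataset(
    dataset: StudyDataset, outdir: str | Path, overwrite: bool = False
) -> Path:
    """Write scans (8-bit TIFF), boundary CSVs and a JSON manifest."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise ConfigurationError(
            f"{manifest_path} exists; pass overwrite=True to replace it"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for eye in dataset.eyes:
        eye_dir = outdir / eye.eye_id
        eye_dir.mkdir(exist_ok=True)
        write_boundaries(eye.boundaries, eye_dir / "boundaries.csv")
        for (cond, m), scan in sorted(eye.scans.items()):
            name = f"{cond}_m{m:03d}.tif"
            write_scan_tiff(scan, eye_dir / name)
            records.append(
                {
                    "eye": eye.eye_id,
                    "condition": cond,
                    "n_averaged": m,
                    "path": f"{eye.eye_id}/{name}",
                    "boundaries": f"{eye.eye_id}/boundaries.csv",
                }
            )
    manifest = {
        "seed": dataset.seed,
        "band": dataset.band,
        "design": {
            "n_eyes": dataset.design.n_eyes,
            "settings": list(dataset.design.settings),
            "conditions": list(dataset.design.conditions),
        },
        "acquisition_order": {
            eye.eye_id: {c: list(o) for c, o in eye.acquisition_order.items()}
            for eye in dataset.eyes
        },
        "scans": records,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_dataset(datadir: str | Path) -> StudyDataset:
    """Load a written dataset; unreadable scans become recorded gaps."""
    datadir = Path(datadir)
    manifest_path = datadir / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    design = StudyDesign(
        n_eyes=manifest["design"]["n_eyes"],
        settings=tuple(manifest["design"]["settings"]),
        conditions=tuple(manifest["design"]["conditions"]),
    )
    eyes: dict[str, EyeData] = {}
    gaps: list[dict] = []
    for rec in manifest["scans"]:
        eye_id = rec["eye"]
        if eye_id not in eyes:
            order = manifest.get("acquisition_order", {}).get(eye_id, {})
            eyes[eye_id] = EyeData(
                eye_id=eye_id,
                boundaries=read_boundaries(datadir / rec["boundaries"]),
                scans={},
                acquisition_order={c: tuple(o) for c, o in order.items()},
            )
        key = (rec["condition"], int(rec["n_averaged"]))
        try:
            eyes[eye_id].scans[key] = read_scan_tiff(
                datadir / rec["path"],
                eye=eye_id,
                condition=rec["condition"],
                n_averaged=int(rec["n_averaged"]),
            )
        except (OSError, ValueError) as exc:
            logger.warning("unreadable scan %s: %s", rec["path"], exc)
            gaps.append({**rec, "reason": str(exc)})
    return StudyDataset(
        design=design,
        eyes=[eyes[k] for k in sorted(eyes)],
        seed=manifest.get("seed"),
        band=int(manifest.get("band", 20)),
        gaps=gaps,
    )
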