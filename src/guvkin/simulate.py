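"""Forward model: synthetic two-channel GUV time-lapse movies.

The generator emulates the confocal kinase assay: immobilized giant
unilamellar vesicles appear as bright rings (equatorial cross-sections)
in a membrane-dye channel, while a fluorescent PI(3)P reporter
accumulates on each ring as the lipid kinase produces PI(3)P.  The
reporter progress curve is piecewise lag -> linear -> plateau, the rate
optionally increasing with membrane curvature (1/R).  A diffuse haze
from unbound reporter rises with saturating-exponential kinetics and,
because its time constant is shorter than the enzymatic lag, appears
*before* any on-membrane signal — the source of the negative
baseline-corrected values in the lag phase.  Optics and detection are
modelled as a Gaussian PSF, scaled Poisson photon noise and additive
Gaussian read noise.

Every movie carries a ground-truth record (exact membrane masks and
per-GUV rates) so the downstream segmentation, quantification and
kinetics stages can be tested without any real acquisition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import ImageStack

log = logging.getLogger("guvkin")

CHANNELS = ("membrane", "reporter")


@dataclass
class KineticParams:
    """Ground-truth kinetics of reporter recruitment.

    The on-membrane signal of a GUV of radius ``R`` (um) is::

        S(t) = 0                        for t < lag
             = r_eff * (t - lag)        while below the plateau
             = plateau_au               afterwards

    with ``r_eff = rate_au_per_min + curvature_coupling_b / R``.  The
    haze is ``B(t) = baseline_max_au * (1 - exp(-t / baseline_tau_min))``.
    """

    lag_min: float = 10.0
    rate_au_per_min: float = 1.0
    plateau_au: float = 120.0
    baseline_max_au: float = 20.0
    baseline_tau_min: float = 4.0
    curvature_coupling_b: float = 0.0  # AU*um/min

    def __post_init__(self) -> None:
        if self.lag_min < 0:
            raise ValueError("lag_min must be >= 0")
        if self.rate_au_per_min < 0:
            raise ValueError("rate_au_per_min must be >= 0")
        if not self.plateau_au > 0:
            raise ValueError("plateau_au must be > 0")
        if self.baseline_max_au < 0:
            raise ValueError("baseline_max_au must be >= 0")
        if not self.baseline_tau_min > 0:
            raise ValueError("baseline_tau_min must be > 0")
        if self.curvature_coupling_b < 0:
            raise ValueError("curvature_coupling_b must be >= 0")

    def effective_rate(self, radius_um: float) -> float:
        return self.rate_au_per_min + self.curvature_coupling_b / radius_um


def membrane_signal(t, p: KineticParams, radius_um: float):
    """On-membrane reporter signal (AU) at time ``t`` minutes.

    Continuous, non-decreasing, clipped at ``plateau_au``.  Accepts a
    scalar or array ``t``; ``t`` must be >= 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    r_eff = p.effective_rate(radius_um)
    out = np.clip(r_eff * (t - p.lag_min), 0.0, p.plateau_au)
    return float(out) if out.ndim == 0 else out


def baseline_signal(t, p: KineticParams):
    """Diffuse haze (AU): saturating exponential, uniform in space."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = p.baseline_max_au * (1.0 - np.exp(-t / p.baseline_tau_min))
    return float(out) if out.ndim == 0 else out


@dataclass
class SimulationScene:
    """Geometry, kinetics, optics and noise of one simulated movie."""

    image_shape: Tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.25
    #: list of ((cy_um, cx_um), radius_um); radii within [1, 30] um.
    guvs: List[Tuple[Tuple[float, float], float]] = field(default_factory=list)
    membrane_thickness_um: float = 0.5
    psf_sigma_um: float = 0.2
    membrane_dye_au: float = 100.0
    kinetics: KineticParams = field(default_factory=KineticParams)
    photon_gain: float = 20.0  # detected photons per AU
    read_noise_sd: float = 1.0  # AU
    time_grid_min: Sequence[float] = field(
        default_factory=lambda: tuple(np.arange(0.0, 60.1, 2.5))
    )
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.membrane_thickness_um > 0:
            raise ValueError("membrane_thickness_um must be > 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")
        if not self.membrane_dye_au > 0:
            raise ValueError("membrane_dye_au must be > 0")
        if not self.photon_gain > 0:
            raise ValueError("photon_gain must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        self.time_grid_min = tuple(float(t) for t in self.time_grid_min)
        if len(self.time_grid_min) == 0:
            raise ValueError("time grid must not be empty")
        diffs = np.diff(self.time_grid_min)
        if np.any(diffs <= 0):
            raise ValueError("time grid must be strictly increasing")
        if len(diffs) and (diffs.min() < 2.0 or diffs.max() > 3.0):
            log.warning("frame interval outside the usual 2-3 min range")
        h_um = self.image_shape[0] * self.pixel_size_um
        w_um = self.image_shape[1] * self.pixel_size_um
        half_th = self.membrane_thickness_um / 2.0
        for (cy, cx), r in self.guvs:
            if not (1.0 <= r <= 30.0):
                raise ValueError(f"GUV radius {r} um outside [1, 30]")
            if not (
                r + half_th <= cy <= h_um - r - half_th
                and r + half_th <= cx <= w_um - r - half_th
            ):
                raise ValueError(f"GUV at ({cy}, {cx}) um does not fit the field of view")
        for i, ((cy, cx), r) in enumerate(self.guvs):
            for (cy2, cx2), r2 in self.guvs[i + 1:]:
                if math.hypot(cy - cy2, cx - cx2) < r + r2:
                    log.warning("overlapping GUVs in scene %r", self.label)


@dataclass
class GroundTruth:
    """Exact per-GUV membrane masks, rates and haze of one movie.

    GUVs are immobilized, so one mask per GUV is valid for all frames.
    """

    masks: List[np.ndarray]
    radii_um: List[float]
    centers_px: List[Tuple[float, float]]
    true_rates: List[float]  # AU/min, rate + b/R
    time_grid_min: Tuple[float, ...]
    baseline: np.ndarray  # haze AU per frame

    def mask(self, guv: int, frame: int = 0) -> np.ndarray:
        return self.masks[guv]


def rasterize_annulus(
    shape: Tuple[int, int],
    center_px: Tuple[float, float],
    radius_px: float,
    thickness_px: float,
) -> np.ndarray:
    """Boolean mask of pixels whose center lies within the annulus."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    d = np.hypot(yy - center_px[0], xx - center_px[1])
    return np.abs(d - radius_px) <= thickness_px / 2.0


def _scene_masks(scene: SimulationScene) -> List[np.ndarray]:
    px = scene.pixel_size_um
    return [
        rasterize_annulus(
            scene.image_shape,
            (cy / px, cx / px),
            r / px,
            scene.membrane_thickness_um / px,
        )
        for (cy, cx), r in scene.guvs
    ]


def apply_noise(
    clean: np.ndarray, photon_gain: float, read_noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Scaled-Poisson shot noise plus Gaussian read noise, clipped at 0.

    The expected value of the noisy pixel equals the noiseless pixel
    (before clipping).
    """
    noisy = rng.poisson(photon_gain * clean).astype(float) / photon_gain
    if read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, read_noise_sd, size=clean.shape)
    return np.clip(noisy, 0.0, None)


def render_frame(
    scene: SimulationScene,
    t: float,
    rng: Optional[np.random.Generator] = None,
    masks: Optional[List[np.ndarray]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render one (2, Y, X) frame at time ``t`` minutes.

    Returns ``(noisy, noiseless)``; with ``rng=None`` the two are equal.
    Channel 0 is the membrane dye (constant rings, no haze), channel 1
    the reporter (rings at ``membrane_signal`` plus uniform haze).
    """
    if masks is None:
        masks = _scene_masks(scene)
    p = scene.kinetics
    haze = baseline_signal(t, p)
    mem = np.zeros(scene.image_shape, float)
    rep_sig = np.zeros(scene.image_shape, float)
    for m, (_, r) in zip(masks, scene.guvs):
        mem[m] = scene.membrane_dye_au
        np.maximum(rep_sig, m * membrane_signal(t, p, r), out=rep_sig)
    rep = rep_sig + haze
    clean = np.stack([mem, rep])
    if scene.psf_sigma_um > 0:
        sigma_px = scene.psf_sigma_um / scene.pixel_size_um
        clean = np.stack([gaussian_filter(c, sigma_px, mode="mirror") for c in clean])
    if rng is None:
        return clean, clean
    noisy = apply_noise(clean, scene.photon_gain, scene.read_noise_sd, rng)
    return noisy, clean


def simulate_timelapse(
    scene: SimulationScene, noiseless: bool = False
) -> Tuple[ImageStack, GroundTruth]:
    """Simulate the full movie; deterministic given ``scene.seed``."""
    if len(scene.time_grid_min) == 0:
        raise ValueError("time grid must not be empty")
    masks = _scene_masks(scene)
    rng = None if noiseless else np.random.default_rng(scene.seed)
    frames = []
    for t in scene.time_grid_min:
        noisy, _ = render_frame(scene, t, rng=rng, masks=masks)
        frames.append(noisy)
    stack = ImageStack(
        np.stack(frames),
        list(scene.time_grid_min),
        list(CHANNELS),
        scene.pixel_size_um,
    )
    px = scene.pixel_size_um
    gt = GroundTruth(
        masks=masks,
        radii_um=[r for _, r in scene.guvs],
        centers_px=[(cy / px, cx / px) for (cy, cx), _ in scene.guvs],
        true_rates=[scene.kinetics.effective_rate(r) for _, r in scene.guvs],
        time_grid_min=tuple(scene.time_grid_min),
        baseline=np.asarray(
            [baseline_signal(t, scene.kinetics) for t in scene.time_grid_min]
        ),
    )
    log.info(
        "simulated %r: %d GUVs, %d frames, seed %d",
        scene.label, len(scene.guvs), stack.n_frames, scene.seed,
    )
    return stack, gt


def place_guvs(
    n: int,
    rng: np.random.Generator,
    image_shape: Tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.25,
    radius_range_um: Tuple[float, float] = (2.5, 5.5),
    min_separation_um: float = 0.5,
    max_attempts: int = 20000,
) -> List[Tuple[Tuple[float, float], float]]:
    """Rejection-sample ``n`` non-overlapping GUVs inside the field."""
    h_um = image_shape[0] * pixel_size_um
    w_um = image_shape[1] * pixel_size_um
    placed: List[Tuple[Tuple[float, float], float]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} GUVs of radius {radius_range_um} um "
                f"in a {h_um:g}x{w_um:g} um field"
            )
        r = rng.uniform(*radius_range_um)
        margin = r + 1.0  # keep the ring and its blur inside the field
        cy = rng.uniform(margin, h_um - margin)
        cx = rng.uniform(margin, w_um - margin)
        if all(
            math.hypot(cy - cy2, cx - cx2) >= r + r2 + min_separation_um
            for (cy2, cx2), r2 in placed
        ):
            placed.append(((cy, cx), r))
    return placed


# ---------------------------------------------------------------------------
# Fixture registry: condition sets whose ground-truth rate ratios encode the
# fold-changes of the GUV assay figures.  Absolute AU scales are arbitrary;
# only the ratios (and, for the curvature fixture, slope signs) are anchored.

FIXTURES: Dict[str, Dict[str, Dict[str, float]]] = {
    "FIG1C": {"CI": {"rate": 1.0}, "CII": {"rate": 1.0 / 7.0}},
    "FIG7D": {
        "CII_WT": {"rate": 0.1},
        "U_BATS": {"rate": 0.7},
        "UdC_BATS": {"rate": 1.1},
    },
    "FIG9_CI": {
        "base": {"rate": 1.0},
        "PI4P": {"rate": 1.8},
        "PI45P2": {"rate": 1.2},
    },
    "FIG9_CII": {
        "base": {"rate": 1.0},
        "PI4P": {"rate": 1.7},
        "PI45P2": {"rate": 1.0},
    },
    "FIG2GH": {
        "SO55_DO27": {"rate": 0.0, "b": 0.5},
        "SO82": {"rate": 0.0, "b": 0.0},
        "DO82": {"rate": 1.0, "b": 0.0},
    },
    "FIG4": {
        "VPS34_10PS": {"rate": 0.0},
        "VPS34_25PS": {"rate": 0.5},
        "CI_25PS": {"rate": 1.0},
        "CII_25PS": {"rate": 1.0},
    },
}


def fixture(
    name: str,
    seed: int = 0,
    n_guvs: int = 15,
    low_noise: bool = False,
) -> Dict[str, SimulationScene]:
    """Build one :class:`SimulationScene` per condition of a registry entry.

    Conditions share geometry defaults (256x256 px at 0.25 um/px,
    2.5-min frames for 60 min, >=15 GUVs of radius 2.5-5.5 um) and
    kinetics defaults; only the ground-truth rate (and curvature
    coupling ``b`` for the packing/curvature fixture) differ.  The
    ``low_noise`` profile halves the read noise and doubles the GUV
    count, for conditions whose printed fold-change is close to 1.
    """
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    conditions = FIXTURES[name]
    if low_noise and n_guvs == 15:
        n_guvs = 30
    children = np.random.SeedSequence(seed).spawn(len(conditions))
    scenes: Dict[str, SimulationScene] = {}
    for (cond, params), child in zip(conditions.items(), children):
        cond_seed = int(child.generate_state(1)[0] % (2**31))
        placement_rng = np.random.default_rng([cond_seed, 0x90D5])
        guvs = place_guvs(n_guvs, placement_rng)
        scenes[cond] = SimulationScene(
            guvs=guvs,
            kinetics=KineticParams(
                rate_au_per_min=params["rate"],
                curvature_coupling_b=params.get("b", 0.0),
            ),
            read_noise_sd=0.5 if low_noise else 1.0,
            seed=cond_seed,
            label=f"{name}:{cond}",
        )
    return scenes


def true_ratio(name: str, num: str, den: str) -> float:
    """Ground-truth rate ratio encoded in a fixture registry entry."""
    entry = FIXTURES[name]
    return entry[num]["rate"] / entry[den]["rate"]
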