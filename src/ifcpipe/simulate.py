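"""Synthetic multi-subject BOLD cohorts with planted group effects.

The generator emulates the study design the pipeline is built for: two
balanced groups (18 patients, 18 controls by default) scanned for 300
volumes at TR = 2 s, with slow (< 0.1 Hz) latent network fluctuations,
spherical seed regions whose signals are coupled to the networks, global /
white-matter / CSF nuisance processes, spatially white thermal noise, and
random-walk head-motion traces.

The group difference is planted exactly where the pipeline looks for it:
patients' target correlations between a system's seed signals and that
system's "home" networks are shifted by a configurable amount per system.
The default scenario plants large shifts for cerebellum and MTL seeds and
small shifts for striatum and amygdala seeds, i.e. a cohort in which
cerebello-cortical and MTL-cortical coupling changes are highly consistent
across patients while striatal and amygdalar changes are weak.

Seed signals are built generatively: seed j's course is
``sum_k b_jk * network_k + sqrt(1 - ||b_j||^2) * innovation_j`` with unit
variance network courses, so the planted coupling matrix ``b`` *is* the
population seed-network correlation. Validity of a coupling row therefore
reduces to ``||b_j|| <= 1`` (the implied joint covariance is positive
semi-definite exactly then); rows violating it by more than a rounding
margin are rejected with a diagnostic naming the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import Grid
from .preprocess import MotionTrace, VolumeSeries, bandpass
from .rois import SYSTEMS, RoiMask, RoiSpec, default_roi_specs, make_roi_masks

# Default planted correlation shifts (patient minus control, correlation
# scale) per subcortical-cerebellar system: the differential-consistency
# scenario with strong cerebellum/MTL and weak striatum/amygdala effects.
DEFAULT_EFFECT_SIZES = {
    "cerebellum": 0.50,
    "mtl": 0.45,
    "striatum": 0.10,
    "amygdala": 0.10,
}

PSD_MARGIN = 1e-6  # tolerated row-norm excess, repaired with a warning


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    ``n_per_group``, ``n_volumes`` and ``tr_seconds`` default to the study
    design (18 + 18 subjects, 300 volumes, TR 2 s). The grid is a
    desk-scale MNI-like box (20 x 27 x 16 voxels of 4 mm, ~10^4 voxels)
    chosen so that all default seed centres fall inside it; 8 latent
    networks stand in for the 22 cortical networks of a full-scale
    analysis (both are plain config choices, not hard limits).
    """

    n_per_group: int = 18
    n_volumes: int = 300
    tr_seconds: float = 2.0
    grid_dims: tuple[int, int, int] = (20, 27, 16)
    voxel_size_mm: float = 4.0
    grid_origin_mm: tuple[float, float, float] = (-38.0, -92.0, -48.0)
    n_latent_networks: int = 8
    roi_specs: list[RoiSpec] = field(default_factory=default_roi_specs)
    effect_size_per_system: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    baseline_coupling: float = 0.35
    within_group_sd: float = 0.08
    network_amplitude: float = 3.0
    roi_amplitude: float = 2.0
    noise_sd: float = 1.0
    baseline_intensity: float = 100.0
    nuisance_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"global": 0.5, "wm": 0.5, "csf": 0.5}
    )
    motion_step_mm: float = 0.02
    motion_step_rad: float = 2e-4
    band_hz: tuple[float, float] = (0.009, 0.08)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_volumes < 8:
            raise ValueError("n_volumes must be >= 8")
        for sysname, eff in self.effect_size_per_system.items():
            if sysname not in SYSTEMS:
                raise ValueError(f"unknown system {sysname!r} in effect sizes")
            if not abs(eff) < 1:
                raise ValueError(f"|effect size| must be < 1 (got {eff} for {sysname})")
        if self.n_latent_networks < 2:
            raise ValueError("need at least 2 latent networks")

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_per_group

    def make_grid(self) -> Grid:
        return Grid.from_spacing(self.grid_dims, self.voxel_size_mm, self.grid_origin_mm)


@dataclass
class GroundTruth:
    """Everything the generator knows and downstream stages must recover."""

    grid: Grid
    latent_network_maps: np.ndarray  # (n_networks, n_voxels), peak-normalized
    latent_network_timecourses: list[np.ndarray]  # per subject (n_volumes, n_networks)
    planted_coupling: list[np.ndarray]  # per subject (n_rois, n_networks)
    group_labels: list[str]  # "control" / "patient"
    roi_masks: list[RoiMask]
    gm_mask: np.ndarray  # flat voxel indices
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    home_networks: dict[str, list[int]]  # system -> network indices carrying its effect

    @property
    def roi_names(self) -> list[str]:
        return [m.name for m in self.roi_masks]


def make_roi_masks_from_config(config: SimConfig) -> list[RoiMask]:
    return make_roi_masks(config.roi_specs, config.make_grid())


def validate_coupling(B: np.ndarray, roi_names: list[str]) -> np.ndarray:
    """Check that each seed's coupling row is a valid correlation target.

    The implied joint (networks + seed) covariance is positive
    semi-definite iff every row norm is <= 1. Rows exceeding 1 by at most
    ``PSD_MARGIN`` are rescaled onto the unit sphere (nearest valid
    target) with a warning; larger violations are an error naming the
    offending seed.
    """
    B = np.array(B, dtype=float)
    norms2 = (B**2).sum(axis=1)
    for j, n2 in enumerate(norms2):
        if n2 > 1.0 + PSD_MARGIN:
            raise ValueError(
                f"planted coupling for seed {roi_names[j]!r} is not a valid "
                f"correlation target: row norm {np.sqrt(n2):.6f} > 1 "
                "(implied covariance not positive semi-definite)"
            )
        if n2 > 1.0:
            warnings.warn(
                f"coupling row for {roi_names[j]!r} projected onto the unit sphere "
                f"(excess {n2 - 1.0:.2e})",
                RuntimeWarning,
            )
            B[j] /= np.sqrt(n2)
    return B


def _network_centers(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Spread network centres through the upper ('cortical') part of the box.

    Centres are drawn with a minimum mutual distance so that every map has
    a dominant, well-separated peak and template matching is well-posed.
    """
    grid = config.make_grid()
    centers_world = grid.voxel_centers()
    lo = centers_world.min(axis=0) + 8.0
    hi = centers_world.max(axis=0) - 8.0
    lo[2] = max(lo[2], -12.0)  # stay above the subcortical seeds
    chosen: list[np.ndarray] = []
    min_dist = 28.0
    attempts = 0
    while len(chosen) < config.n_latent_networks:
        c = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm(c - p) >= min_dist for p in chosen):
            chosen.append(c)
        attempts += 1
        if attempts > 20000:
            min_dist *= 0.9  # box too crowded for the requested count
            attempts = 0
    return np.asarray(chosen)


def _network_maps(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    grid = config.make_grid()
    centers_world = grid.voxel_centers()
    centers = _network_centers(config, rng)
    sd = 8.0  # mm; compact blobs
    maps = np.empty((config.n_latent_networks, grid.n_voxels))
    for k, c in enumerate(centers):
        d2 = ((centers_world - c) ** 2).sum(axis=1)
        m = np.exp(-d2 / (2 * sd**2))
        m[m < 0.05] = 0.0  # sparse support -> super-Gaussian sources
        maps[k] = m
    return maps


def _bandlimited(
    rng: np.random.Generator, n: int, t: int, config: SimConfig
) -> np.ndarray:
    """(n, t) unit-variance signals with power confined below 0.1 Hz."""
    x = rng.standard_normal((n, t))
    x = bandpass(x, config.band_hz[0], config.band_hz[1], config.tr_seconds)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _home_networks(config: SimConfig) -> dict[str, list[int]]:
    """Round-robin assignment of networks carrying each system's effect."""
    systems = sorted({s.system for s in config.roi_specs}, key=SYSTEMS.index)
    k = config.n_latent_networks
    per = max(1, k // len(systems)) if k >= len(systems) else 1
    per = min(per, 2)
    homes: dict[str, list[int]] = {}
    nxt = 0
    for s in systems:
        homes[s] = [(nxt + i) % k for i in range(per)]
        nxt += per
    return homes


def _subject_coupling(
    config: SimConfig,
    group: str,
    roi_specs: list[RoiSpec],
    homes: dict[str, list[int]],
    rng: np.random.Generator,
) -> np.ndarray:
    n_roi = len(roi_specs)
    B = np.zeros((n_roi, config.n_latent_networks))
    for j, spec in enumerate(roi_specs):
        for k in homes[spec.system]:
            b = config.baseline_coupling
            if group == "patient":
                b -= config.effect_size_per_system.get(spec.system, 0.0)
            b += rng.normal(0.0, config.within_group_sd)
            B[j, k] = float(np.clip(b, -0.9, 0.9))
    return validate_coupling(B, [s.name for s in roi_specs])


def _box_mask(grid: Grid, lo: tuple, hi: tuple, exclude: np.ndarray) -> np.ndarray:
    c = grid.voxel_centers()
    inside = np.all((c >= lo) & (c <= hi), axis=1)
    inside[exclude] = False
    return np.flatnonzero(inside)


def generate_cohort(
    config: SimConfig,
) -> tuple[list[VolumeSeries], list[MotionTrace], GroundTruth]:
    """Generate one seeded cohort.

    Subjects are ordered controls first, patients second
    (``sub-01 … sub-{2n}``). Each subject's voxel x time data is

    ``baseline + A_net * maps.T @ nw + A_roi * roi_indicators.T @ seed
    + nuisance fields + noise``

    with all temporal signals band-limited except the i.i.d. Gaussian
    noise. Identical config (including seed) yields a bit-identical
    cohort.
    """
    grid = config.make_grid()
    root = np.random.SeedSequence(config.seed)
    ss_maps, ss_subj = root.spawn(2)
    rng_maps = np.random.default_rng(ss_maps)

    maps = _network_maps(config, rng_maps)
    roi_masks = make_roi_masks(config.roi_specs, grid)
    homes = _home_networks(config)

    # tissue masks: GM = network support plus seeds; WM/CSF = boxes outside GM
    gm = maps.max(axis=0) > 0.05
    for m in roi_masks:
        gm[m.indices] = True
    gm_idx = np.flatnonzero(gm)
    # deep boxes the cortical blobs (z >= -12, ~20 mm reach) cannot touch
    wm_idx = _box_mask(grid, (-14, -60, -46), (14, -30, -34), np.flatnonzero(gm))
    csf_idx = _box_mask(grid, (-14, -20, -46), (14, 0, -34), np.flatnonzero(gm))
    if wm_idx.size == 0 or csf_idx.size == 0:
        raise ValueError("WM/CSF stand-in boxes are empty on this grid")

    n_roi = len(roi_masks)
    labels = ["control"] * config.n_per_group + ["patient"] * config.n_per_group
    subj_seeds = ss_subj.spawn(config.n_subjects)

    series_list: list[VolumeSeries] = []
    motion_list: list[MotionTrace] = []
    nw_tcs: list[np.ndarray] = []
    couplings: list[np.ndarray] = []

    T = config.n_volumes
    maps32 = maps.astype(np.float32)
    for s, (group, sseed) in enumerate(zip(labels, subj_seeds)):
        rng = np.random.default_rng(sseed)
        nw = _bandlimited(rng, config.n_latent_networks, T, config)  # (K, T)
        B = _subject_coupling(config, group, config.roi_specs, homes, rng)
        innov = _bandlimited(rng, n_roi, T, config)
        resid_sd = np.sqrt(np.clip(1.0 - (B**2).sum(axis=1), 0.0, None))
        roi_sig = B @ nw + resid_sd[:, None] * innov  # (n_roi, T)

        g_tc, wm_tc, csf_tc = _bandlimited(rng, 3, T, config)
        amps = config.nuisance_amplitudes

        data = rng.standard_normal((grid.n_voxels, T), dtype=np.float32)
        data *= np.float32(config.noise_sd)
        data += np.float32(config.baseline_intensity)
        data += np.float32(config.network_amplitude) * (maps32.T @ nw.astype(np.float32))
        roi_sig32 = roi_sig.astype(np.float32)
        for j, m in enumerate(roi_masks):
            data[m.indices] += np.float32(config.roi_amplitude) * roi_sig32[j]
        data[gm_idx] += np.float32(amps.get("global", 0.0)) * g_tc.astype(np.float32)
        data[wm_idx] += np.float32(amps.get("wm", 0.0)) * wm_tc.astype(np.float32)
        data[csf_idx] += np.float32(amps.get("csf", 0.0)) * csf_tc.astype(np.float32)

        series_list.append(
            VolumeSeries(
                data=data,
                grid=grid,
                tr_seconds=config.tr_seconds,
                subject_id=f"sub-{s + 1:02d}",
            )
        )
        trans = np.cumsum(rng.normal(0.0, config.motion_step_mm, size=(3, T)), axis=1)
        trans -= trans[:, :1]
        rots = np.cumsum(rng.normal(0.0, config.motion_step_rad, size=(3, T)), axis=1)
        rots -= rots[:, :1]
        motion_list.append(
            MotionTrace(translations_mm=trans, rotations_deg=np.degrees(rots))
        )
        nw_tcs.append(nw.T)  # (T, K)
        couplings.append(B)

    truth = GroundTruth(
        grid=grid,
        latent_network_maps=maps,
        latent_network_timecourses=nw_tcs,
        planted_coupling=couplings,
        group_labels=labels,
        roi_masks=roi_masks,
        gm_mask=gm_idx,
        wm_mask=wm_idx,
        csf_mask=csf_idx,
        home_networks=homes,
    )
    return series_list, motion_list, truth
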