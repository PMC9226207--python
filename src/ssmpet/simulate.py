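"""Synthetic phantom cohorts with known ground truth.

Every downstream stage (kinetic fitting, SSM/PCA pattern derivation, scoring,
score statistics) is testable by *recovery*: the generator embeds a known
disease topography and known kinetic parameters, and the pipeline must get
them back.

A phantom study consists of:

* an ellipsoidal brain mask partitioned into contiguous atlas regions, one of
  which plays the cerebellar grey-matter reference region;
* a unit-norm spatial *pattern template* — the ground-truth analogue of the
  disease pattern, negative in affected lobes;
* a static cohort in which subject ``s`` expresses the template with strength
  ``z_s`` on top of a shared baseline anatomy, with lognormal global scaling
  and smoothed additive noise;
* a dynamic cohort whose voxel time-activity curves follow the SRTM forward
  model per region, driven by a gamma-variate reference curve.

Group expression means default to HC = 0, MCI- = 0.3, MCI+ = 1.0, AD = 2.0
(unitless multiples of the unit-norm template), mirroring the ordering of
clinical score distributions.  All generators are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .kinetics import (
    KineticParameters,
    ReferenceCurve,
    frame_average,
    log_theta_grid,
    srtm_forward,
)
from .types import AtlasDefinition, Cohort, DynamicImage, FrameSchedule, ImageVolume, Subject

REFERENCE_REGION = "cerebellum GM"
CORTICAL_LOBES = ("frontal", "parietal", "temporal", "occipital")


def _fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size) -> list[float]:
    factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    return [fwhm_mm / factor / v for v in voxel_size]


def smooth(volume: np.ndarray, fwhm_mm: float, voxel_size) -> np.ndarray:
    """Separable Gaussian smoothing specified in mm FWHM."""
    if fwhm_mm <= 0:
        return volume
    return gaussian_filter(volume, _fwhm_to_sigma_voxels(fwhm_mm, voxel_size))


@dataclass
class PatternTemplate:
    """Ground-truth disease topography: unit-norm weights, zero outside mask."""

    weights: ImageVolume
    mask: np.ndarray
    affected_lobes: list[str]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def values(self) -> np.ndarray:
        """Template weights restricted to the mask (1D)."""
        return self.weights.data[self.mask]


@dataclass
class SimulationConfig:
    """Study conditions for the static phantom cohort.

    The default group sizes (15 AD, 11 MCI+, 10 MCI-, 16 HC) match the
    clinical cohort composition this pipeline is designed around; expression
    means/SD, global-scale SD, noise SD and smoothing are phantom choices.
    """

    n_AD: int = 15
    n_HC: int = 16
    n_MCIplus: int = 11
    n_MCIminus: int = 10
    expression_mean: dict = field(
        default_factory=lambda: {"HC": 0.0, "MCI-": 0.3, "MCI+": 1.0, "AD": 2.0}
    )
    expression_sd: float = 0.5
    global_scale_sd: float = 0.05
    noise_sd: float = 0.01
    smoothing_fwhm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_AD, self.n_HC, self.n_MCIplus, self.n_MCIminus):
            if n < 0:
                raise ValueError("group counts must be >= 0")
        for sd in (self.expression_sd, self.global_scale_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")

    def group_counts(self) -> dict[str, int]:
        return {
            "AD": self.n_AD,
            "MCI+": self.n_MCIplus,
            "MCI-": self.n_MCIminus,
            "HC": self.n_HC,
        }


def make_phantom_atlas(
    grid_shape=(16, 16, 16),
    n_regions: int = 6,
    seed: int = 0,
    voxel_size=(2.0, 2.0, 2.0),
) -> tuple[AtlasDefinition, np.ndarray]:
    """Partition an ellipsoidal mask into contiguous regions.

    Seeded Voronoi partition: region seed points are drawn inside the
    ellipsoid and every mask voxel joins its nearest seed, so each cell is
    the intersection of a convex cell with the ellipsoid (contiguous).  The
    seed with the lowest z-centroid becomes the cerebellar grey-matter
    reference region; the rest are assigned cyclically to the four cortical
    lobes.
    """
    if n_regions < 2:
        raise ValueError("need >= 2 regions (one reference plus cortex)")
    grid_shape = tuple(int(g) for g in grid_shape)
    centre = (np.array(grid_shape) - 1) / 2.0
    semi = np.maximum(np.array(grid_shape) / 2.0 - 1.0, 0.5)
    idx = np.indices(grid_shape).reshape(3, -1).T
    r2 = (((idx - centre) / semi) ** 2).sum(axis=1)
    mask_flat = r2 <= 1.0
    mask = mask_flat.reshape(grid_shape)
    n_in = int(mask.sum())
    if n_in < n_regions:
        raise ValueError(
            f"grid {grid_shape} has only {n_in} mask voxels for {n_regions} regions"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(np.flatnonzero(mask_flat), size=n_regions, replace=False)
    seeds = idx[pick].astype(float)
    d2 = ((idx[mask_flat, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)

    labels = np.zeros(grid_shape, dtype=np.int32)
    labels.reshape(-1)[np.flatnonzero(mask_flat)] = assign + 1

    ref_region = int(np.argmin(seeds[:, 2])) + 1  # lowest z: plays the cerebellum
    region_names: dict[int, str] = {}
    lobe_map: dict[str, str] = {}
    cortical_i = 0
    for lab in range(1, n_regions + 1):
        if lab == ref_region:
            region_names[lab] = REFERENCE_REGION
            lobe_map[REFERENCE_REGION] = "cerebellum"
        else:
            lobe = CORTICAL_LOBES[cortical_i % len(CORTICAL_LOBES)]
            name = f"{lobe} region {cortical_i // len(CORTICAL_LOBES) + 1}"
            region_names[lab] = name
            lobe_map[name] = lobe
            cortical_i += 1
    atlas = AtlasDefinition(labels, region_names, lobe_map, voxel_size)
    return atlas, mask


def reference_mask(atlas: AtlasDefinition) -> np.ndarray:
    """Voxels of the cerebellar grey-matter reference region."""
    labels = [lab for lab, name in atlas.region_names.items() if name == REFERENCE_REGION]
    if not labels:
        raise ValueError("atlas has no reference region")
    return np.isin(atlas.labels, labels)


def make_baseline(
    mask: np.ndarray,
    voxel_size=(2.0, 2.0, 2.0),
    mean_level: float = 1.0,
    variation: float = 0.1,
    smoothing_fwhm: float = 8.0,
    seed: int = 0,
) -> ImageVolume:
    """Smooth strictly-positive shared anatomy for the static cohort.

    A unit-level field plus a smoothed random modulation of relative
    amplitude ``variation``, clipped well away from zero.
    """
    rng = np.random.default_rng(seed)
    field_ = rng.standard_normal(mask.shape)
    field_ = smooth(field_, smoothing_fwhm, voxel_size)
    sd = field_[mask].std()
    if sd > 0:
        field_ = field_ / sd * variation
    data = mean_level * np.clip(1.0 + field_, 0.2, None) * mask
    return ImageVolume(data, voxel_size)


def make_pattern_template(
    atlas: AtlasDefinition,
    mask: np.ndarray,
    effects_by_lobe: dict[str, float],
    smoothing_fwhm: float = 6.0,
) -> PatternTemplate:
    """Piecewise-constant-per-lobe effect map, smoothed, masked, unit-normalised.

    Sign convention: affected lobes carry negative weights (relative
    reduction in patients).
    """
    unknown = set(effects_by_lobe) - set(atlas.lobe_map.values())
    if unknown:
        raise ValueError(f"unknown lobes: {sorted(unknown)}")
    vol = np.zeros(mask.shape)
    for lobe, effect in effects_by_lobe.items():
        vol[atlas.lobe_mask(lobe)] = effect
    vol = smooth(vol, smoothing_fwhm, atlas.voxel_size)
    vol = np.where(mask, vol, 0.0)
    norm = np.linalg.norm(vol[mask])
    if norm == 0:
        raise ValueError("null template: all effects are zero, cannot normalise")
    vol /= norm
    affected = sorted(lobe for lobe, e in effects_by_lobe.items() if e < 0)
    return PatternTemplate(ImageVolume(vol, atlas.voxel_size), mask, affected)


def simulate_static_cohort(
    template: PatternTemplate,
    baseline: ImageVolume,
    cfg: SimulationConfig,
    z_table: pd.DataFrame | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Static phantom cohort with known per-subject pattern expression.

    Each subject's image is

        g_s * baseline * (1 + z_s * template) + noise

    with ``g_s ~ lognormal(0, global_scale_sd)``, ``z_s ~ Normal(mean[group],
    expression_sd)`` and smoothed iid Gaussian noise.  Returns the cohort and
    a ground-truth table of ``(subject_id, group, z, g)``.

    ``z_table`` (columns ``subject_id``, ``z``) pins each subject's expression
    instead of drawing it — this is how one disease process is imaged through
    several modalities: re-simulate with the same z values (scaled by the
    modality's expression gain) and a different noise seed.
    """
    mask = template.mask
    if np.any(baseline.data[mask] <= 0):
        raise ValueError("baseline must be strictly positive inside the mask")
    z_fixed = None
    if z_table is not None:
        z_fixed = dict(zip(z_table["subject_id"], z_table["z"]))
    rng = np.random.default_rng(cfg.seed)
    tdata = template.weights.data
    subjects: list[Subject] = []
    rows = []
    for group, count in cfg.group_counts().items():
        mu = cfg.expression_mean.get(group, 0.0)
        for i in range(count):
            z = rng.normal(mu, cfg.expression_sd)
            if z_fixed is not None:
                z = float(z_fixed[f"{group}{i + 1:02d}"])
            g = rng.lognormal(0.0, cfg.global_scale_sd)
            modulation = 1.0 + z * tdata
            if np.any(modulation[mask] <= 0):
                raise ValueError(
                    f"expression z={z:.3g} drives the image non-positive; "
                    "reduce expression means/SD or template contrast"
                )
            noise = rng.standard_normal(mask.shape) * cfg.noise_sd
            noise = smooth(noise, cfg.smoothing_fwhm, baseline.voxel_size)
            data = g * baseline.data * modulation + noise
            data = np.where(mask, data, 0.0)
            sid = f"{group}{i + 1:02d}"
            subjects.append(Subject(sid, group, ImageVolume(data, baseline.voxel_size)))
            rows.append({"subject_id": sid, "group": group, "z": z, "g": g})
    cohort = Cohort(subjects, mask, baseline.voxel_size)
    return cohort, pd.DataFrame(rows)


def simulate_reference_curve(
    duration_s: float = 3600.0,
    A: float = 10.0,
    alpha: float = 2.0,
    tau_s: float = 80.0,
) -> ReferenceCurve:
    """Gamma-variate reference-tissue curve ``A * (t/tau)^alpha * exp(-t/tau)``.

    Sampled at 1 s; zero at t = 0; peaks at ``t = alpha * tau`` (within the
    first third of the scan for the defaults).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if A <= 0 or alpha <= 0 or tau_s <= 0:
        raise ValueError("A, alpha and tau must all be positive")
    t = np.arange(0.0, np.floor(duration_s) + 1.0)
    values = A * (t / tau_s) ** alpha * np.exp(-t / tau_s)
    return ReferenceCurve(values, 1.0, {"A": A, "alpha": alpha, "tau_s": tau_s})


def default_frame_schedule(total_s: float = 3600.0) -> FrameSchedule:
    """A dynamic-scan-like schedule: short early frames, lengthening later.

    The 5 s frames cover the reference curve's rise and peak, which is what
    the convolution basis (and hence voxelwise R1) is most sensitive to.
    """
    pattern = [(5.0, 24), (10.0, 12), (30.0, 8), (60.0, 6), (120.0, 5), (300.0, 1000)]
    starts, ends = [], []
    t = 0.0
    for dur, count in pattern:
        for _ in range(count):
            if t + dur > total_s + 1e-9:
                break
            starts.append(t)
            ends.append(t + dur)
            t += dur
    return FrameSchedule(np.array(starts), np.array(ends))


def default_region_kinetics(
    atlas: AtlasDefinition,
    k2_prime: float | None = None,
    seed: int = 0,
    k2a_min: float = 0.01,
    k2a_max: float = 0.3,
    n_basis: int = 80,
) -> tuple[dict[int, KineticParameters], float]:
    """Plausible per-region SRTM ground truth with on-grid apparent efflux.

    The reference region gets ``R1 = 1, BPND = 0, k2 = k2'``; each cortical
    region gets a target delivery ratio and binding potential whose implied
    ``k2a`` is snapped to the SRTM2 basis grid (keeping ``k2/R1 = k2'``
    consistent across tissue, as the reference-tissue model assumes).
    Returns the kinetics and the generating ``k2'`` (1/min).
    """
    grid = log_theta_grid(k2a_min, k2a_max, n_basis)
    if k2_prime is None:
        k2_prime = float(grid[np.searchsorted(grid, 0.15)])  # on-grid by construction
    rng = np.random.default_rng(seed)
    kinetics: dict[int, KineticParameters] = {}
    for lab, name in sorted(atlas.region_names.items()):
        if name == REFERENCE_REGION:
            kinetics[lab] = KineticParameters(R1=1.0, k2=k2_prime, BPND=0.0)
            continue
        r1_target = rng.uniform(0.6, 1.3)
        bp = rng.uniform(0.2, 1.5)
        k2a = grid[np.argmin(np.abs(grid - r1_target * k2_prime / (1.0 + bp)))]
        r1 = float(k2a * (1.0 + bp) / k2_prime)
        kinetics[lab] = KineticParameters(R1=r1, k2=r1 * k2_prime, BPND=bp)
    return kinetics, k2_prime


def simulate_dynamic_cohort(
    atlas: AtlasDefinition,
    kinetics_by_region: dict[int, KineticParameters],
    ref_curve: ReferenceCurve,
    schedule: FrameSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_subjects: int = 1,
) -> tuple[list[DynamicImage], ImageVolume]:
    """Dynamic phantom scans from the SRTM forward model, plus true R1 map.

    Every voxel of a region shares that region's noiseless frame-averaged
    SRTM solution; iid Gaussian noise of SD ``noise_sd`` is added per frame.
    """
    if schedule.total_end > ref_curve.duration_s + 1e-9:
        raise ValueError(
            f"schedule ends at {schedule.total_end} s, beyond the reference "
            f"curve duration {ref_curve.duration_s} s"
        )
    labels = atlas.labels
    present = sorted(set(np.unique(labels)) - {0})
    missing = [lab for lab in present if lab not in kinetics_by_region]
    if missing:
        raise ValueError(f"no kinetics for regions {missing}")
    for lab, name in atlas.region_names.items():
        if name == REFERENCE_REGION:
            p = kinetics_by_region[lab]
            if not (np.isclose(p.R1, 1.0) and np.isclose(p.BPND, 0.0)):
                raise ValueError(
                    "reference region must have R1 = 1 and BPND = 0 by definition"
                )
    tacs = {lab: srtm_forward(ref_curve, schedule, kinetics_by_region[lab]) for lab in present}
    truth = np.zeros(labels.shape)
    noiseless = np.zeros(labels.shape + (len(schedule),))
    for lab in present:
        sel = labels == lab
        truth[sel] = kinetics_by_region[lab].R1
        noiseless[sel] = tacs[lab]
    rng = np.random.default_rng(seed)
    scans = []
    for _ in range(n_subjects):
        noise = rng.standard_normal(noiseless.shape) * noise_sd if noise_sd > 0 else 0.0
        data = noiseless + noise
        data[labels == 0] = 0.0
        scans.append(DynamicImage(data, schedule, atlas.voxel_size))
    return scans, ImageVolume(truth, atlas.voxel_size)


def frame_averaged_reference(ref_curve: ReferenceCurve, schedule: FrameSchedule) -> np.ndarray:
    """Frame-averaged reference curve (ground truth for reference-voxel TACs)."""
    return frame_average(ref_curve.values, ref_curve.dt_s, schedule)
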