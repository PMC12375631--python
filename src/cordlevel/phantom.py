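"""Synthetic cervical-cord cohorts with fully known ground truth.

The phantom emulates a study's *preprocessed* outputs: co-registered masks at
0.5 mm isotropic atlas resolution, a continuous vertebral-level map spanning
C2-C6, and a 15-direction b=750 s/mm^2 single-shell DWI series with three
averages and Rician noise. Geometry is a straight elliptical cord along the
slice axis with a smooth cervical enlargement toward C5, a butterfly-shaped
gray-matter core, six white-matter pathway sectors and six gray-matter horn
sectors. Group effects (e.g. an FA deficit in the patient group), per-subject
random intercepts, focal lesions, and a clinical model linking gray-matter
cross-sectional area at C2-C3 to walking measures are all generated from an
explicit configuration, so every downstream estimate can be checked against
recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    ContinuousLevelMap,
    GradientTable,
    LabelVolume,
    PATHWAY_NAMES,
    RegionSet,
    SUBREGION_NAMES,
    SubjectRecord,
    VoxelGrid,
)
from .dti import DiffusionTensorField, ScalarMapSet, scalar_indices
from .levels import build_profiles, discretize_levels

LEVEL_TOP = 2.0
LEVEL_BOTTOM = 6.0  # exclusive

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions on the upper hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n
    theta = i * _GOLDEN_ANGLE
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass(frozen=True)
class AcquisitionSpec:
    """Single-shell diffusion acquisition: 15 directions at b=750 s/mm^2,
    one b=0, three averages, Rician noise at S0/snr."""

    n_directions: int = 15
    b_value: float = 750.0
    n_b0: int = 1
    n_averages: int = 3
    s0: float = 1000.0
    snr: float | None = 20.0  # None = noiseless

    def __post_init__(self) -> None:
        if self.n_directions < 6:
            raise ValueError("need at least 6 diffusion directions")
        if self.b_value <= 0:
            raise ValueError("b-value must be positive")
        if self.n_b0 < 1 or self.n_averages < 1:
            raise ValueError("n_b0 and n_averages must be >= 1")
        if self.snr is not None and not self.snr > 0:
            raise ValueError("snr must be positive (or None for noiseless)")

    def gradient_table(self) -> GradientTable:
        bvals = np.concatenate([
            np.zeros(self.n_b0), np.full(self.n_directions, self.b_value)])
        bvecs = np.vstack([
            np.zeros((self.n_b0, 3)), fibonacci_hemisphere(self.n_directions)])
        return GradientTable(bvals, bvecs)


def axisymmetric_eigenvalues(fa: float | np.ndarray,
                             md: float | np.ndarray) -> np.ndarray:
    """Eigenvalue triples (l1, l2, l2) with the requested FA and MD.

    Solves the quadratic implied by FA^2 = 9 (md - l2)^2 / (l1^2 + 2 l2^2)
    with l1 = 3 md - 2 l2, taking the prolate root (l2 <= md).
    """
    f = np.asarray(fa, dtype=float)
    m = np.asarray(md, dtype=float)
    if np.any((f < 0) | (f >= 1)):
        raise ValueError("FA must lie in [0, 1)")
    if np.any(m <= 0):
        raise ValueError("MD must be positive")
    f2 = f**2
    a = 6 * f2 - 9.0
    b = (18.0 - 12 * f2) * m
    c = 9 * m**2 * (f2 - 1.0)
    disc = b**2 - 4 * a * c
    # conjugate root form: stable at FA -> 0, where the prolate root -> md;
    # the min() guards float jitter so l1 >= l2 holds exactly
    lam2 = np.minimum(2 * c / (-b - np.sqrt(np.maximum(disc, 0.0))), m)
    lam1 = np.maximum(3 * m - 2 * lam2, lam2)
    out = np.stack([lam1, lam2, lam2], axis=-1)
    if np.any(out <= 0):
        raise ValueError("requested (FA, MD) implies non-positive eigenvalues")
    return out


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth tensor eigenvalues per tissue class (mm^2/s).

    Defaults are chosen so that cohort-mean FA lands at the healthy-control
    anchor (~0.63 whole cord) before group effects: WM (FA 0.63, MD
    1.17e-3) and GM (FA 0.62, MD 0.95e-3) both oriented superior-inferior,
    lesions prolate but much less anisotropic (FA ~ 0.24) with elevated
    radial diffusivity, CSF isotropic and fast.
    """

    wm: tuple[float, float, float] = tuple(
        axisymmetric_eigenvalues(0.63, 1.17e-3))
    gm: tuple[float, float, float] = tuple(
        axisymmetric_eigenvalues(0.62, 0.95e-3))
    lesion: tuple[float, float, float] = (1.2e-3, 0.8e-3, 0.8e-3)
    csf: tuple[float, float, float] = (3.0e-3, 3.0e-3, 3.0e-3)

    def __post_init__(self) -> None:
        for name in ("wm", "gm", "lesion", "csf"):
            lam = getattr(self, name)
            if not (lam[0] >= lam[1] >= lam[2] > 0):
                raise ValueError(f"{name} eigenvalues must satisfy l1>=l2>=l3>0: {lam}")

    def fa_md(self, name: str) -> tuple[float, float]:
        fa, md, _, _ = scalar_indices(np.asarray(getattr(self, name)))
        return float(fa), float(md)


@dataclass(frozen=True)
class EffectSpec:
    """Additive group effect on one tissue's FA or MD, optionally limited to
    a vertebral band [lo, hi] (inclusive, in continuous level units)."""

    tissue: str  # "WM" | "GM" | "lesion"
    metric: str  # "FA" | "MD"
    delta: float
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.tissue not in ("WM", "GM", "lesion"):
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.metric not in ("FA", "MD"):
            raise ValueError(f"effects act on FA or MD, got {self.metric!r}")


@dataclass(frozen=True)
class ClinicalModel:
    """Standardized linear model generating TUG / T25 / EDSS.

    Each latent score is b1 * (standardized ground-truth GM CSA averaged
    over the generative band) + age/sex/diagnosis terms + Gaussian noise,
    then mapped to seconds via the healthy-control anchor mean and a scale.
    EDSS exists only for patients and is snapped to the 0-3.5 half-point grid.
    """

    band: tuple[float, float] = (2.0, 3.8)   # C2-C3 sub-levels drive disability
    b1_tug: float = -0.28
    b1_t25: float = -0.15
    b1_edss: float = -0.12
    age_beta: float = 0.15
    sex_beta: float = 0.10
    dx_beta_tug: float = 1.0
    dx_beta_t25: float = 0.8
    noise_sd: float = 0.6
    tug_anchor: tuple[float, float] = (6.10, 1.2)   # (HC mean s, scale s)
    t25_anchor: tuple[float, float] = (4.25, 0.75)
    edss_anchor: tuple[float, float] = (1.5, 1.0)
    edss_max: float = 3.5


@dataclass(frozen=True)
class CohortConfig:
    """Everything that defines a synthetic cohort, plus the master seed.

    Geometry radii are in mm at the top of C2; the cervical enlargement
    grows them smoothly by ``enlargement`` toward C5. Subject-to-subject
    size variation has a global component and, for GM, an independent
    per-vertebral-band component so that gray-matter area at C2-C3 carries
    information the C4-C5 levels do not share.
    """

    n_hc: int = 46
    n_ms: int = 54
    age_hc: tuple[float, float] = (31.86, 6.78)
    age_ms: tuple[float, float] = (36.70, 7.51)
    female_frac_hc: float = 29 / 46
    female_frac_ms: float = 36 / 54
    grid_dims: tuple[int, int, int] = (24, 24, 40)
    voxel_size_mm: float = 0.5
    cord_rx_mm: float = 3.4
    cord_ry_mm: float = 2.7
    enlargement: float = 0.25
    cord_scale_sd: float = 0.04
    gm_scale_global_sd: float = 0.01
    gm_scale_band_sd: float = 0.05
    gm_bands: tuple[tuple[float, float], ...] = ((2.0, 4.0), (4.0, 6.0))
    tissue: TissueParams = field(default_factory=TissueParams)
    effects: tuple[EffectSpec, ...] = (
        EffectSpec("WM", "FA", -0.02),
        EffectSpec("GM", "FA", -0.04),
    )
    between_subject_sd: dict = field(
        default_factory=lambda: {"FA": 0.025, "MD": 3e-5})
    lesion_count_range: tuple[int, int] = (1, 4)
    lesion_radius_range_mm: tuple[float, float] = (1.0, 3.0)
    clinical: ClinicalModel = field(default_factory=ClinicalModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc <= 0 or self.n_ms <= 0:
            raise ValueError("group sizes must be positive")
        if self.cord_scale_sd < 0 or self.gm_scale_band_sd < 0:
            raise ValueError("scale sds must be >= 0")
        if self.lesion_radius_range_mm[0] <= 0:
            raise ValueError("lesion radii must be positive")

    @property
    def grid(self) -> VoxelGrid:
        s = self.voxel_size_mm
        return VoxelGrid(self.grid_dims, (s, s, s))


@dataclass
class PhantomSubject:
    """One generated subject: anatomy, truth, and (optionally) its DWI."""

    record: SubjectRecord
    grid: VoxelGrid
    regions: RegionSet
    levels: ContinuousLevelMap
    truth_tensors: DiffusionTensorField
    truth_scalars: ScalarMapSet
    truth_profile: pd.DataFrame
    dwi: object | None = None  # DWIVolume when simulated


def _smoothstep(x: np.ndarray) -> np.ndarray:
    s = np.clip(x, 0.0, 1.0)
    return 3 * s**2 - 2 * s**3


def build_anatomy(grid: VoxelGrid, config: CohortConfig,
                  rng: np.random.Generator | None = None,
                  group: str = "HC") -> tuple[RegionSet, ContinuousLevelMap]:
    """Straight elliptical cord with butterfly GM, sector parcellations,
    and (for patients) focal white-matter lesions.

    ``rng`` drives subject-specific geometry (global cord scale, per-band GM
    scale, lesion placement); pass ``None`` for the noiseless template.
    """
    if not grid.is_isotropic:
        raise ValueError(f"phantom requires an isotropic grid, got {grid.voxel_size}")
    nx, ny, nz = grid.dims
    dx = grid.voxel_size[0]

    cord_mult = 1.0
    gm_global = 0.0
    gm_band_mult = np.ones(len(config.gm_bands))
    if rng is not None:
        cord_mult = 1.0 + rng.normal(0.0, config.cord_scale_sd)
        gm_global = rng.normal(0.0, config.gm_scale_global_sd)
        gm_band_mult = 1.0 + gm_global + rng.normal(
            0.0, config.gm_scale_band_sd, size=len(config.gm_bands))
        cord_mult = max(cord_mult, 0.6)
        gm_band_mult = np.clip(gm_band_mult, 0.6, 1.4)

    # level is linear in slice index: exactly 2.0 at the top slice, < 6.0 at
    # the bottom; C6 content (v >= 6 would only occur off-grid) is the tail
    # of the last slices and is excluded later by the C5.8 cut.
    k = np.arange(nz)
    slice_level = LEVEL_TOP + (LEVEL_BOTTOM - LEVEL_TOP) * k / nz

    cx, cy = nx * dx / 2.0, ny * dx / 2.0
    x = (np.arange(nx) + 0.5) * dx - cx
    y = (np.arange(ny) + 0.5) * dx - cy
    X, Y = np.meshgrid(x, y, indexing="ij")

    enlarge = 1.0 + config.enlargement * _smoothstep((slice_level - 2.0) / 3.0)
    rx = config.cord_rx_mm * enlarge * cord_mult
    ry = config.cord_ry_mm * enlarge * cord_mult
    if rx.max() >= cx or ry.max() >= cy:
        raise ValueError(
            f"grid too small to contain the cord: radii up to "
            f"({rx.max():.1f}, {ry.max():.1f}) mm vs half-extent ({cx}, {cy}) mm")

    def band_index(level: float) -> int:
        for i, (lo, hi) in enumerate(config.gm_bands):
            if lo <= level < hi:
                return i
        return len(config.gm_bands) - 1

    cord = np.zeros(grid.dims, dtype=np.uint8)
    gm = np.zeros(grid.dims, dtype=np.uint8)
    U = np.zeros(grid.dims, dtype=float)  # cord-normalized coords (sectors)
    V = np.zeros(grid.dims, dtype=float)
    Vg = np.zeros(grid.dims, dtype=float)  # GM-normalized dorsoventral coord

    # butterfly: union of four ellipses (+v = dorsal). GM is sized in
    # template coordinates (cervical enlargement but NOT the subject's cord
    # scale), so gray-matter area varies independently of cord caliber.
    horn_spec = [  # (u0, v0, au, av)
        (-0.28, -0.32, 0.30, 0.34),  # left ventral
        (+0.28, -0.32, 0.30, 0.34),  # right ventral
        (-0.20, +0.40, 0.20, 0.42),  # left dorsal
        (+0.20, +0.40, 0.20, 0.42),  # right dorsal
    ]
    rx_t = config.cord_rx_mm * enlarge  # template (subject-scale-free) radii
    ry_t = config.cord_ry_mm * enlarge
    for kk in range(nz):
        u = X / rx[kk]
        v = Y / ry[kk]
        inside = (u**2 + v**2) <= 1.0
        cord[:, :, kk] = inside
        U[:, :, kk] = u
        V[:, :, kk] = v
        ug = X / rx_t[kk]
        vg = Y / ry_t[kk]
        Vg[:, :, kk] = vg
        gmul = gm_band_mult[band_index(slice_level[kk])]
        g = np.zeros_like(inside)
        for u0, v0, au, av in horn_spec:
            g |= ((ug - u0) / (au * gmul)) ** 2 + ((vg - v0) / (av * gmul)) ** 2 <= 1.0
        gm[:, :, kk] = g & inside

    wm = (cord.astype(bool) & ~gm.astype(bool)).astype(np.uint8)

    # six WM pathway sectors: side by u sign, dorsal/lateral/ventral by the
    # angle from the dorsal (+v) axis
    phi = np.arctan2(np.abs(U), V)  # 0 = dorsal pole, pi = ventral pole
    left = U < 0
    wmb = wm.astype(bool)
    sectors = {
        "Do": phi < np.pi / 3,
        "L": (phi >= np.pi / 3) & (phi < 2 * np.pi / 3),
        "V": phi >= 2 * np.pi / 3,
    }
    pathways = {}
    for side, smask in (("L", left), ("R", ~left)):
        for part, pmask in sectors.items():
            name = side + part if part != "L" else side + "L"
            pathways[name] = LabelVolume(
                grid, (wmb & smask & pmask).astype(np.uint8))
    assert set(pathways) == set(PATHWAY_NAMES)

    # six GM horn subregions: side by u sign, dorsal/intermediate/ventral by
    # the GM-intrinsic dorsoventral coordinate
    gmb = gm.astype(bool)
    horns = {
        "DH": Vg >= 0.15,
        "IH": (Vg > -0.05) & (Vg < 0.15),
        "VH": Vg <= -0.05,
    }
    subregions = {}
    for side, smask in (("L", left), ("R", ~left)):
        for part, pmask in horns.items():
            subregions[side + part] = LabelVolume(
                grid, (gmb & smask & pmask).astype(np.uint8))
    assert set(subregions) == set(SUBREGION_NAMES)

    lesion_vol = None
    if group == "pwRRMS" and rng is not None:
        lesion = np.zeros(grid.dims, dtype=bool)
        lo, hi = config.lesion_count_range
        n_lesions = int(rng.integers(lo, hi + 1))
        wm_idx = np.argwhere(wmb)
        xs = (np.arange(nx) + 0.5) * dx
        ys = (np.arange(ny) + 0.5) * dx
        zs = (np.arange(nz) + 0.5) * dx
        for _ in range(n_lesions):
            ci = wm_idx[rng.integers(len(wm_idx))]
            r = rng.uniform(*config.lesion_radius_range_mm)
            c = np.array([xs[ci[0]], ys[ci[1]], zs[ci[2]]])
            d2 = ((xs[:, None, None] - c[0]) ** 2
                  + (ys[None, :, None] - c[1]) ** 2
                  + (zs[None, None, :] - c[2]) ** 2)
            lesion |= d2 <= r**2
        lesion &= cord.astype(bool)
        lesion_vol = LabelVolume(grid, lesion.astype(np.uint8))

    level_data = np.where(cord.astype(bool),
                          slice_level[None, None, :], 0.0)
    levels = ContinuousLevelMap(grid, level_data)
    regions = RegionSet(grid, LabelVolume(grid, cord), LabelVolume(grid, wm),
                        LabelVolume(grid, gm), pathways, subregions,
                        lesion=lesion_vol)
    return regions, levels


def build_tensor_field(regions: RegionSet, levels: ContinuousLevelMap,
                       config: CohortConfig, group: str,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[DiffusionTensorField, ScalarMapSet]:
    """Ground-truth tensors: tissue-class eigenvalues modulated by the
    subject random intercept and (for patients) the configured group
    effects; lesion voxels overwrite their WM tensor."""
    grid = regions.grid
    b_fa = b_md = 0.0
    if rng is not None:
        b_fa = rng.normal(0.0, config.between_subject_sd.get("FA", 0.0))
        b_md = rng.normal(0.0, config.between_subject_sd.get("MD", 0.0))

    fa_map = np.zeros(grid.dims)
    md_map = np.zeros(grid.dims)
    classes = [("WM", regions.wm), ("GM", regions.gm)]
    if regions.lesion is not None:
        classes.append(("lesion", regions.lesion))
    tissue_attr = {"WM": "wm", "GM": "gm", "lesion": "lesion"}
    cord = regions.cord.data.astype(bool)
    for tissue, vol in classes:
        m = vol.data.astype(bool)
        fa0, md0 = config.tissue.fa_md(tissue_attr[tissue])
        fa_map[m] = fa0 + b_fa
        md_map[m] = md0 + b_md
        if group == "pwRRMS":
            for eff in config.effects:
                if eff.tissue != tissue:
                    continue
                in_band = m
                if eff.band is not None:
                    lo, hi = eff.band
                    in_band = m & (levels.data >= lo) & (levels.data <= hi)
                if eff.metric == "FA":
                    fa_map[in_band] += eff.delta
                else:
                    md_map[in_band] += eff.delta

    if np.any(md_map[cord] <= 0) or np.any(fa_map[cord] >= 1) or np.any(
            fa_map[cord] < 0):
        bad_fa = (float(fa_map[cord].min()), float(fa_map[cord].max()))
        bad_md = float(md_map[cord].min())
        raise ValueError(
            "configured effects produce an invalid tensor: FA range "
            f"{bad_fa}, min MD {bad_md:g} — reduce |delta| or the "
            "between-subject sd")

    lam = np.zeros(grid.dims + (3,))
    lam[cord] = axisymmetric_eigenvalues(fa_map[cord], md_map[cord])

    comp = np.zeros(grid.dims + (6,))
    comp[..., 0] = lam[..., 1]  # Dxx
    comp[..., 3] = lam[..., 2]  # Dyy
    comp[..., 5] = lam[..., 0]  # Dzz: principal axis superior-inferior
    comp[~cord] = 0.0

    s0 = np.where(cord, 1.0, 0.0)
    field_ = DiffusionTensorField(grid, comp, s0, lam, mask=cord)

    fa_t, md_t, ad_t, rd_t = (np.full(grid.dims, np.nan) for _ in range(4))
    f, m_, a, r = scalar_indices(lam[cord])
    fa_t[cord], md_t[cord], ad_t[cord], rd_t[cord] = f, m_, a, r
    truth = ScalarMapSet(grid, fa_t, md_t, ad_t, rd_t, valid=cord.copy())
    return field_, truth


def simulate_dwi(tensors: DiffusionTensorField, acq: AcquisitionSpec,
                 rng: np.random.Generator | None = None,
                 gradients: GradientTable | None = None):
    """Forward single-shell signal S = S0 exp(-b g^T D g) with Rician noise.

    Each of ``n_averages`` repeats gets independent Gaussian noise of sd
    S0/snr in both quadrature channels; magnitudes are averaged. Background
    voxels carry noise-only signal. ``acq.snr = None`` disables noise;
    ``gradients`` overrides the acquisition's deterministic direction set.
    """
    from .core_io import DWIVolume

    gt = gradients if gradients is not None else acq.gradient_table()
    lam = tensors.eigenvalues[tensors.mask]
    if lam.size and lam.min() <= 0:
        raise ValueError("tensor field must be positive-definite")
    c = tensors.components
    g = gt.bvecs
    quad = (np.einsum("...c,vc->...v", c[..., [0, 3, 5]], g**2)
            + 2 * np.einsum("...c,vc->...v", c[..., [1, 2, 4]],
                            np.stack([g[:, 0] * g[:, 1], g[:, 0] * g[:, 2],
                                      g[:, 1] * g[:, 2]], axis=1)))
    S = acq.s0 * tensors.mask[..., None] * np.exp(-gt.bvals * quad)
    if acq.snr is None or np.isinf(acq.snr):
        return DWIVolume(tensors.grid, S, gt)
    if rng is None:
        raise ValueError("noisy simulation requires an rng")
    sigma = acq.s0 / acq.snr
    out = np.zeros_like(S)
    for _ in range(acq.n_averages):
        e1 = rng.normal(0.0, sigma, size=S.shape)
        e2 = rng.normal(0.0, sigma, size=S.shape)
        out += np.sqrt((S + e1) ** 2 + e2**2)
    out /= acq.n_averages
    return DWIVolume(tensors.grid, out, gt)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def build_subject(config: CohortConfig, acq: AcquisitionSpec,
                  subject_id: str, group: str,
                  seed_seq: np.random.SeedSequence,
                  age: float, sex: str,
                  with_dwi: bool = True) -> PhantomSubject:
    """Deterministically build one subject from its spawned seed sequence."""
    anat_ss, tens_ss, dwi_ss = seed_seq.spawn(3)
    grid = config.grid
    regions, levels = build_anatomy(grid, config,
                                    rng=np.random.default_rng(anat_ss),
                                    group=group)
    tensors, truth = build_tensor_field(regions, levels, config, group,
                                        rng=np.random.default_rng(tens_ss))
    sub = discretize_levels(levels)
    record = SubjectRecord(id=subject_id, group=group, age=age, sex=sex)
    truth_profile = build_profiles(subject_id, truth, regions, sub)
    dwi = None
    if with_dwi:
        dwi = simulate_dwi(tensors, acq, rng=np.random.default_rng(dwi_ss))
    return PhantomSubject(record, grid, regions, levels, tensors, truth,
                          truth_profile, dwi=dwi)


def _truth_band_mean(profile: pd.DataFrame, region: str, metric: str,
                     band: tuple[float, float]) -> float:
    from .levels import SUBLEVELS, SUBLEVEL_VALUES
    lo, hi = band
    labels = [s for s, v in zip(SUBLEVELS, SUBLEVEL_VALUES) if lo <= v <= hi]
    sel = profile[(profile.region == region) & (profile.metric == metric)
                  & (profile.sublevel.isin(labels))]
    return float(sel.value.mean())


@dataclass
class CohortPlan:
    """Deterministic per-subject assignments spawned from the master seed."""

    ids: list[str]
    groups: list[str]
    ages: np.ndarray
    sexes: np.ndarray
    subject_seeds: list[np.random.SeedSequence]
    clinical_rng: np.random.Generator

    def __len__(self) -> int:
        return len(self.ids)


def plan_cohort(config: CohortConfig) -> CohortPlan:
    """Draw ids, groups, ages and sexes; spawn one seed per subject."""
    n_total = config.n_hc + config.n_ms
    root = np.random.SeedSequence(config.seed)
    cohort_ss, *subject_ss = root.spawn(n_total + 1)
    crng = np.random.default_rng(cohort_ss)
    groups = ["HC"] * config.n_hc + ["pwRRMS"] * config.n_ms
    ids = [f"HC{i+1:03d}" for i in range(config.n_hc)] + \
          [f"MS{i+1:03d}" for i in range(config.n_ms)]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    ages = np.concatenate([
        crng.normal(*config.age_hc, size=config.n_hc),
        crng.normal(*config.age_ms, size=config.n_ms)])
    ages = np.clip(ages, 18.0, 80.0)
    female = np.concatenate([
        crng.random(config.n_hc) < config.female_frac_hc,
        crng.random(config.n_ms) < config.female_frac_ms])
    sexes = np.where(female, "F", "M")
    return CohortPlan(ids, groups, ages, sexes, subject_ss, crng)


def clinical_records(config: CohortConfig, plan: CohortPlan,
                     gm_csa_band: np.ndarray) -> pd.DataFrame:
    """Generate TUG/T25/EDSS from each subject's ground-truth GM CSA in the
    configured band and assemble the subject table."""
    cm = config.clinical
    n_total = len(plan)
    crng = plan.clinical_rng
    z_csa = _standardize(np.asarray(gm_csa_band, dtype=float))
    z_age = _standardize(plan.ages)
    male = (plan.sexes == "M").astype(float)
    dx = np.array([g == "pwRRMS" for g in plan.groups], dtype=float)

    def latent(b1: float, dx_beta: float) -> np.ndarray:
        return (b1 * z_csa + cm.age_beta * z_age + cm.sex_beta * male
                + dx_beta * dx + crng.normal(0.0, cm.noise_sd, n_total))

    tug = cm.tug_anchor[0] + cm.tug_anchor[1] * latent(cm.b1_tug, cm.dx_beta_tug)
    t25 = cm.t25_anchor[0] + cm.t25_anchor[1] * latent(cm.b1_t25, cm.dx_beta_t25)
    edss_latent = (cm.edss_anchor[0] + cm.edss_anchor[1]
                   * (cm.b1_edss * z_csa + crng.normal(0.0, cm.noise_sd, n_total)))
    edss = np.clip(np.round(edss_latent * 2) / 2, 0.0, cm.edss_max)

    rows = []
    for i in range(n_total):
        is_ms = plan.groups[i] == "pwRRMS"
        rows.append(dict(id=plan.ids[i], group=plan.groups[i],
                         age=float(plan.ages[i]), sex=str(plan.sexes[i]),
                         edss=float(edss[i]) if is_ms else None,
                         tug_s=float(max(tug[i], 0.5)),
                         t25_s=float(max(t25[i], 0.5))))
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig, acq: AcquisitionSpec | None = None,
                    with_dwi: bool = True,
                    ) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Generate the full cohort and its subject table.

    Per-subject seeds are spawned deterministically from the master seed, so
    identical (config, seed) yields bit-identical volumes and tables. The
    clinical scores are generated after anatomy from each subject's
    ground-truth GM CSA in the configured vertebral band.
    """
    acq = acq or AcquisitionSpec()
    plan = plan_cohort(config)
    subjects = [
        build_subject(config, acq, plan.ids[i], plan.groups[i],
                      plan.subject_seeds[i], float(plan.ages[i]),
                      str(plan.sexes[i]), with_dwi=with_dwi)
        for i in range(len(plan))
    ]
    gm_csa = np.array([
        _truth_band_mean(s.truth_profile, "GM", "CSA", config.clinical.band)
        for s in subjects])
    records = clinical_records(config, plan, gm_csa)
    for s, row in zip(subjects, records.itertuples()):
        s.record.tug_s = row.tug_s
        s.record.t25_s = row.t25_s
        s.record.edss = None if pd.isna(row.edss) else float(row.edss)
    return subjects, records
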