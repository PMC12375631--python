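"""Vertebral sub-level discretization and per-(region, sub-level) extraction.

The continuous vertebral coordinate (2.0 = top of C2) is discretized into 20
half-open 0.2-wide bins C2.0, C2.2, ..., C5.8; a voxel with level value v is
assigned to bin floor(v / 0.2) * 0.2. Content at v >= 6.0 (below C5.8) is
generated but not analyzed. Per sub-level the pipeline extracts:

* CSA — per-axial-slice mask area (voxel count x in-plane voxel area, mm^2),
  each slice assigned to the bin of the median cord-voxel level in that
  slice, averaged over the bin's slices;
* mean FA/MD/AD/RD over region ∩ sub-level voxels (lesion voxels included,
  fit-flagged voxels excluded);
* lesion load — |lesion ∩ region ∩ sub-level| / |region ∩ sub-level|.

Missing (region, sub-level) combinations are absent rows, never zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ContinuousLevelMap, LabelVolume, RegionSet
from .dti import ScalarMapSet

BIN_WIDTH = 0.2
N_SUBLEVELS = 20
UNASSIGNED = -1

METRICS = ("CSA", "FA", "MD", "AD", "RD", "lesion_load")


def sublevel_value(code: int) -> float:
    """Numeric lower edge of sub-level bin ``code`` (0 -> 2.0, 19 -> 5.8)."""
    return 2.0 + BIN_WIDTH * code


def sublevel_label(code: int) -> str:
    v = sublevel_value(code)
    return f"C{int(v)}.{int(round(v * 10)) % 10}"


SUBLEVELS = tuple(sublevel_label(c) for c in range(N_SUBLEVELS))
SUBLEVEL_VALUES = tuple(sublevel_value(c) for c in range(N_SUBLEVELS))


@dataclass(frozen=True)
class SublevelIndex:
    """One of the 20 analyzed sub-levels, C2.0 ... C5.8."""

    code: int

    def __post_init__(self) -> None:
        if not 0 <= self.code < N_SUBLEVELS:
            raise ValueError(f"sub-level code out of range: {self.code}")

    @property
    def label(self) -> str:
        return sublevel_label(self.code)

    @property
    def value(self) -> float:
        return sublevel_value(self.code)


def discretize_levels(levels: ContinuousLevelMap) -> LabelVolume:
    """Per-voxel sub-level code; -1 where outside the cord or beyond C5.8."""
    v = levels.data
    # bin-edge tolerance of 1e-5 bins (2e-6 in level units) so edges survive
    # float32 storage of the level map; C2.0/C2.4 examples are unaffected
    codes = np.floor(v / BIN_WIDTH + 1e-5).astype(np.int32) - 10
    codes[(v <= 0) | (codes < 0) | (codes >= N_SUBLEVELS)] = UNASSIGNED
    return LabelVolume(levels.grid, codes, kind="label")


def _slice_sublevels(sublevels: LabelVolume) -> np.ndarray:
    """Sub-level code per axial slice: median assigned-voxel code (lower
    median for even counts); UNASSIGNED for slices with no cord voxels."""
    codes = sublevels.data
    nz = codes.shape[2]
    out = np.full(nz, UNASSIGNED, dtype=np.int32)
    for k in range(nz):
        vals = codes[:, :, k]
        vals = vals[vals != UNASSIGNED]
        if vals.size:
            out[k] = int(np.sort(vals)[(vals.size - 1) // 2])
    return out


def compute_csa(mask: LabelVolume, sublevels: LabelVolume) -> pd.DataFrame:
    """Per-sub-level cross-sectional area of ``mask`` in mm^2.

    Returns columns (sublevel, value, n_voxels); n_voxels is the total voxel
    count pooled over the bin's slices. Empty masks yield an empty frame.
    """
    mask.grid.check_same(sublevels.grid, what="compute_csa")
    area = mask.grid.slice_area_mm2
    per_slice = mask.data.reshape(-1, mask.grid.dims[2]).sum(axis=0)
    slice_bins = _slice_sublevels(sublevels)
    rows = []
    for code in range(N_SUBLEVELS):
        sel = (slice_bins == code) & (per_slice > 0)
        if not sel.any():
            continue
        counts = per_slice[sel]
        rows.append((sublevel_label(code), float(counts.mean() * area), int(counts.sum())))
    return pd.DataFrame(rows, columns=["sublevel", "value", "n_voxels"])


def compute_mean_metric(map_data: np.ndarray, region: LabelVolume,
                        sublevels: LabelVolume, min_voxels: int = 1,
                        valid: np.ndarray | None = None) -> pd.DataFrame:
    """Unweighted mean of ``map_data`` over region ∩ sub-level voxels.

    ``valid`` (optional bool array) excludes fit-flagged voxels. Combinations
    with fewer than ``min_voxels`` contributing voxels are absent rows.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    region.grid.check_same(sublevels.grid, what="compute_mean_metric")
    use = region.data.astype(bool)
    if valid is not None:
        use = use & valid
    codes = sublevels.data[use]
    vals = np.asarray(map_data, dtype=float)[use]
    ok = (codes != UNASSIGNED) & np.isfinite(vals)
    codes, vals = codes[ok], vals[ok]
    rows = []
    for code in range(N_SUBLEVELS):
        sel = codes == code
        n = int(sel.sum())
        if n >= min_voxels:
            rows.append((sublevel_label(code), float(vals[sel].mean()), n))
    return pd.DataFrame(rows, columns=["sublevel", "value", "n_voxels"])


def compute_lesion_load(lesion: LabelVolume, region: LabelVolume,
                        sublevels: LabelVolume) -> pd.DataFrame:
    """Lesion volume fraction of ``region`` per sub-level.

    The pooled whole-region load (all analyzed sub-levels together) is
    appended with sublevel = "all". Sub-levels where the region is empty are
    absent rows.
    """
    lesion.grid.check_same(region.grid, what="compute_lesion_load")
    codes = sublevels.data
    reg = region.data.astype(bool)
    les = lesion.data.astype(bool)
    rows = []
    tot_reg = tot_les = 0
    for code in range(N_SUBLEVELS):
        in_bin = codes == code
        n_reg = int(np.count_nonzero(reg & in_bin))
        if n_reg == 0:
            continue
        n_les = int(np.count_nonzero(les & reg & in_bin))
        tot_reg += n_reg
        tot_les += n_les
        rows.append((sublevel_label(code), n_les / n_reg, n_reg))
    if tot_reg:
        rows.append(("all", tot_les / tot_reg, tot_reg))
    return pd.DataFrame(rows, columns=["sublevel", "value", "n_voxels"])


def build_profiles(subject_id: str, scalars: ScalarMapSet | None,
                   regions: RegionSet, sublevels: LabelVolume,
                   min_voxels: int = 1) -> pd.DataFrame:
    """Tidy long profile for one subject.

    Columns: subject_id, region, sublevel, metric, value, n_voxels. CSA and
    the four diffusion indices cover all 15 analysis regions; lesion load is
    emitted for cord/WM/GM only when a lesion mask is present. Rows are
    deterministically ordered (region, sublevel, metric).

    Aggregation is a single pass per region via code-indexed bincounts; the
    per-operation functions (:func:`compute_csa` etc.) define the semantics
    and agree with this path exactly.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    codes = sublevels.data
    nz = codes.shape[2]
    area = regions.grid.slice_area_mm2
    slice_bins = _slice_sublevels(sublevels)
    flat_codes = codes.reshape(-1)
    assigned = flat_codes != UNASSIGNED
    if scalars is not None:
        metric_maps = {m: scalars[m].reshape(-1) for m in ("FA", "MD", "AD", "RD")}
        valid = scalars.valid.reshape(-1)
    lesion_flat = (regions.lesion.data.reshape(-1).astype(bool)
                   if regions.lesion is not None else None)

    rows: list[tuple] = []
    for name, mask in regions.analysis_regions().items():
        mflat = mask.data.reshape(-1).astype(bool)
        # CSA: per-slice voxel counts grouped by the slice's sub-level bin
        per_slice = mask.data.reshape(-1, nz).sum(axis=0)
        sel = (slice_bins != UNASSIGNED) & (per_slice > 0)
        if sel.any():
            vox = np.bincount(slice_bins[sel], weights=per_slice[sel],
                              minlength=N_SUBLEVELS)
            nsl = np.bincount(slice_bins[sel], minlength=N_SUBLEVELS)
            for code in np.nonzero(nsl)[0]:
                rows.append((name, "CSA", sublevel_label(code),
                             vox[code] / nsl[code] * area, int(vox[code])))
        # diffusion indices: unweighted voxel means per bin
        if scalars is not None:
            use = mflat & assigned & valid
            idx = flat_codes[use]
            counts = np.bincount(idx, minlength=N_SUBLEVELS)
            for metric in ("FA", "MD", "AD", "RD"):
                vals = metric_maps[metric][use]
                fin = np.isfinite(vals)
                s = np.bincount(idx[fin], weights=vals[fin],
                                minlength=N_SUBLEVELS)
                c = np.bincount(idx[fin], minlength=N_SUBLEVELS)
                for code in np.nonzero(c >= min_voxels)[0]:
                    rows.append((name, metric, sublevel_label(code),
                                 s[code] / c[code], int(c[code])))
        # lesion load for cord/WM/GM, plus the pooled whole-region row
        if lesion_flat is not None and name in ("cord", "WM", "GM"):
            use = mflat & assigned
            idx = flat_codes[use]
            n_reg = np.bincount(idx, minlength=N_SUBLEVELS)
            n_les = np.bincount(idx[lesion_flat[use]], minlength=N_SUBLEVELS)
            for code in np.nonzero(n_reg)[0]:
                rows.append((name, "lesion_load", sublevel_label(code),
                             n_les[code] / n_reg[code], int(n_reg[code])))
            if n_reg.sum():
                rows.append((name, "lesion_load", "all",
                             n_les.sum() / n_reg.sum(), int(n_reg.sum())))

    order = {s: i for i, s in enumerate(SUBLEVELS)}
    order["all"] = N_SUBLEVELS
    rows.sort(key=lambda r: (r[0], order[r[2]], r[1]))
    out = pd.DataFrame(rows, columns=["region", "metric", "sublevel",
                                      "value", "n_voxels"])
    out.insert(0, "subject_id", subject_id)
    return out
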