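"""Diffusion tensor estimation and scalar indices (FA, MD, AD, RD).

The fit is weighted linear least squares on the log-signal model

    ln S(g, b) = ln S0 - b * g^T D g

with one reweighting iteration (weights = squared predicted signal) from an
unweighted first pass — the standard WLLS estimator, deterministic and exact
on noiseless data. Eigenvalues are sorted descending and clamped below at
``EPS_EIG`` so FA stays defined at noisy voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import DWIVolume, LabelVolume, VoxelGrid

EPS_EIG = 1e-7  # mm^2/s eigenvalue clamp

# symmetric tensor component ordering used on disk and in memory
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")


@dataclass
class DiffusionTensorField:
    """Per-voxel symmetric diffusion tensor with eigenvalues and S0."""

    grid: VoxelGrid
    components: np.ndarray   # (nx, ny, nz, 6) ordered as TENSOR_COMPONENTS
    s0: np.ndarray           # (nx, ny, nz)
    eigenvalues: np.ndarray  # (nx, ny, nz, 3) sorted descending
    mask: np.ndarray         # bool: voxels with a fitted tensor
    excluded: np.ndarray | None = None  # bool: flagged (non-positive signal)
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if self.excluded is None:
            self.excluded = np.zeros(self.grid.dims, dtype=bool)
        ev = self.eigenvalues[self.mask]
        if ev.size and np.any(np.diff(ev, axis=-1) > 1e-15):
            raise ValueError("eigenvalues must be sorted descending")

    def as_matrices(self) -> np.ndarray:
        """Full (..., 3, 3) symmetric matrices."""
        c = self.components
        out = np.empty(c.shape[:-1] + (3, 3), dtype=float)
        out[..., 0, 0] = c[..., 0]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 1]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 2]
        out[..., 1, 1] = c[..., 3]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 4]
        out[..., 2, 2] = c[..., 5]
        return out


@dataclass
class ScalarMapSet:
    """FA (unitless), MD/AD/RD (mm^2/s) maps; background is NaN."""

    grid: VoxelGrid
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    valid: np.ndarray = field(default=None)  # bool: voxels usable in profiles

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.fa)

    def __getitem__(self, metric: str) -> np.ndarray:
        return {"FA": self.fa, "MD": self.md, "AD": self.ad, "RD": self.rd}[metric]


def scalar_indices(eigenvalues: np.ndarray) -> tuple[np.ndarray, ...]:
    """FA, MD, AD, RD from eigenvalue triples (last axis).

    MD = (l1+l2+l3)/3, AD = l1, RD = (l2+l3)/2,
    FA = sqrt(3/2) * ||l - MD|| / ||l||  (0 where ||l|| = 0).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = (lam[..., 1] + lam[..., 2]) / 2.0
    num = np.linalg.norm(lam - md[..., None], axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return fa, md, ad, rd


def design_matrix(gradients) -> np.ndarray:
    """(nvol, 7) log-linear design: [1, -b gx^2, -b gy^2, -b gz^2,
    -2b gx gy, -2b gx gz, -2b gy gz]; coefficients are
    [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    b = gradients.bvals
    g = gradients.bvecs
    X = np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])
    return X


def fit_tensor(dwi: DWIVolume, mask: LabelVolume) -> DiffusionTensorField:
    """Weighted linear least-squares tensor fit inside ``mask``.

    Voxels with any non-positive signal are flagged and excluded from the
    fit (and later from profiles). Requires at least one b=0 volume and six
    non-collinear diffusion directions.
    """
    dwi.grid.check_same(mask.grid, what="fit_tensor mask")
    gt = dwi.gradients
    if gt.n_b0 < 1:
        raise ValueError("tensor fit requires at least one b=0 volume")
    dirs = gt.bvecs[~gt.is_b0]
    if len(dirs) < 6 or np.linalg.matrix_rank(design_matrix(gt)) < 7:
        raise ValueError(
            "tensor fit requires >= 6 non-collinear nonzero-b directions "
            f"(got {len(dirs)} directions)"
        )

    X = design_matrix(gt)
    m = mask.data.astype(bool)
    signals = dwi.data[m]  # (N, nvol)
    positive = np.all(signals > 0, axis=1)
    excluded = np.zeros(dwi.grid.dims, dtype=bool)
    idx = np.argwhere(m)
    excluded[tuple(idx[~positive].T)] = True

    S = signals[positive]
    y = np.log(S)
    # unweighted pass (shared design -> one pinv)
    beta = y @ np.linalg.pinv(X).T  # (N, 7)
    # one reweighting iteration, weights = predicted signal squared
    w = np.exp(beta @ X.T) ** 2  # (N, nvol)
    XtW = X.T[None, :, :] * w[:, None, :]            # (N, 7, nvol)
    A = XtW @ X                                      # (N, 7, 7)
    rhs = np.einsum("nkv,nv->nk", XtW, y)            # (N, 7)
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]

    comp = np.zeros(dwi.grid.dims + (6,), dtype=float)
    s0 = np.zeros(dwi.grid.dims, dtype=float)
    evals = np.zeros(dwi.grid.dims + (3,), dtype=float)
    fitted = np.zeros(dwi.grid.dims, dtype=bool)
    good = tuple(idx[positive].T)
    fitted[good] = True
    s0[good] = np.exp(beta[:, 0])
    # reorder [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)
    comp[good] = beta[:, [1, 4, 5, 2, 6, 3]]

    D = np.empty((len(beta), 3, 3))
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]
    lam = np.linalg.eigvalsh(D)[:, ::-1]  # descending
    n_clamped = int(np.count_nonzero(lam < EPS_EIG))
    lam = np.maximum(lam, EPS_EIG)
    evals[good] = lam

    return DiffusionTensorField(
        grid=dwi.grid, components=comp, s0=s0, eigenvalues=evals,
        mask=fitted, excluded=excluded, n_clamped=n_clamped,
    )


def tensor_scalars(tensors: DiffusionTensorField) -> ScalarMapSet:
    """Derive the four scalar maps from a fitted tensor field."""
    shape = tensors.grid.dims
    fa = np.full(shape, np.nan)
    md = np.full(shape, np.nan)
    ad = np.full(shape, np.nan)
    rd = np.full(shape, np.nan)
    m = tensors.mask
    f, mm, aa, rr = scalar_indices(tensors.eigenvalues[m])
    fa[m], md[m], ad[m], rd[m] = f, mm, aa, rr
    valid = m & ~tensors.excluded
    return ScalarMapSet(tensors.grid, fa, md, ad, rd, valid=valid)
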