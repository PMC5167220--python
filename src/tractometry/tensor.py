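"""Diffusion tensor fitting and scalar metrics.

The diffusion tensor model represents water diffusion in a voxel as a
symmetric positive 3x3 matrix D (units mm^2/s).  For a diffusion-weighted
acquisition with b-value ``b`` and unit gradient direction ``g`` the
noise-free signal obeys the Stejskal-Tanner equation::

    S(b, g) = S0 * exp(-b * g^T D g)

so ``log(S/S0)`` is linear in the six unique tensor elements, and the
tensor can be recovered by ordinary least squares over the weighted
volumes.  The fitted tensor's eigenvalues (sorted lambda1 >= lambda2 >=
lambda3) yield the four scalar metrics used throughout the package:

* axial diffusivity        AX = lambda1
* mean diffusivity         MD = (lambda1 + lambda2 + lambda3) / 3
* radial diffusivity       RD = (lambda2 + lambda3) / 2
* fractional anisotropy    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||

RD is the average of the two minor eigenvalues; a variant with a /3
denominator, which appears in some published formula listings, is
available through ``rd_denominator=3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DiffusionScheme",
    "Tensor",
    "ScalarSet",
    "METRICS",
    "fit_tensor_loglinear",
    "compute_scalars",
    "scalars_from_tensor",
    "forward_signals",
    "fit_tensor_volume",
    "save_scalar_maps",
    "make_scheme",
]

#: Canonical metric order used everywhere in the package.
METRICS = ("FA", "MD", "RD", "AX")


@dataclass(frozen=True)
class DiffusionScheme:
    """Acquisition scheme: one b-value and one gradient direction per volume.

    b=0 volumes carry no diffusion weighting; their gradient rows are
    ignored.  At least one b=0 volume and six independent weighted
    directions are required for a tensor fit.
    """

    bvalues: np.ndarray  # (n,) s/mm^2
    bvectors: np.ndarray  # (n, 3) unit vectors for weighted volumes

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvalues, dtype=float)
        bvecs = np.asarray(self.bvectors, dtype=float)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"shape mismatch: bvalues {bvals.shape}, bvectors {bvecs.shape}"
            )
        weighted = bvals > 0
        norms = np.linalg.norm(bvecs[weighted], axis=1)
        if weighted.any() and not np.allclose(norms, 1.0, atol=1e-6):
            bad = np.flatnonzero(weighted)[np.abs(norms - 1.0) > 1e-6]
            raise ValueError(f"non-unit bvectors at weighted volumes {bad.tolist()}")
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "bvectors", bvecs)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvalues == 0))

    @property
    def n_weighted(self) -> int:
        return int(np.sum(self.bvalues > 0))

    def validate_for_fit(self) -> None:
        if self.n_b0 < 1:
            raise ValueError("tensor fit requires at least one b=0 volume")
        if self.n_weighted < 6:
            raise ValueError(
                f"tensor fit requires >= 6 weighted volumes, got {self.n_weighted}"
            )

    @classmethod
    def from_bval_bvec(cls, bval_path: str | Path, bvec_path: str | Path) -> "DiffusionScheme":
        """Read FSL-style text files: bvals on one row, bvecs on three rows."""
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        return cls(bvals, bvecs)

    def to_bval_bvec(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        np.savetxt(bval_path, self.bvalues[None, :], fmt="%.1f")
        np.savetxt(bvec_path, self.bvectors.T, fmt="%.8f")


@dataclass(frozen=True)
class Tensor:
    """A fitted diffusion tensor with its eigendecomposition attached."""

    matrix: np.ndarray  # (3, 3) symmetric, mm^2/s
    eigenvalues: np.ndarray  # (3,) sorted descending
    eigenvectors: np.ndarray  # (3, 3) columns matching eigenvalues

    @classmethod
    def from_matrix(cls, d: np.ndarray) -> "Tensor":
        d = np.asarray(d, dtype=float)
        d = 0.5 * (d + d.T)  # enforce exact symmetry
        evals, evecs = np.linalg.eigh(d)
        order = np.argsort(evals)[::-1]
        return cls(matrix=d, eigenvalues=evals[order], eigenvectors=evecs[:, order])


@dataclass(frozen=True)
class ScalarSet:
    """The four DTI scalar metrics at one location."""

    fa: float
    md: float
    rd: float
    ax: float

    def as_array(self) -> np.ndarray:
        """Values in canonical :data:`METRICS` order (FA, MD, RD, AX)."""
        return np.array([self.fa, self.md, self.rd, self.ax])


def _design_matrix(scheme: DiffusionScheme, weighted: np.ndarray) -> np.ndarray:
    """Rows of -b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]."""
    b = scheme.bvalues[weighted][:, None]
    g = scheme.bvectors[weighted]
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    cols = np.stack(
        [gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=1
    )
    return -b * cols


def _tensor_from_coeffs(coef: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def fit_tensor_loglinear(signals: np.ndarray, scheme: DiffusionScheme) -> Tensor:
    """Fit a single tensor by unweighted log-linear least squares.

    S0 is estimated as the mean over b=0 volumes.  Signals must be
    strictly positive for every volume entering the fit.
    """
    scheme.validate_for_fit()
    s = np.asarray(signals, dtype=float).ravel()
    if s.size != scheme.bvalues.size:
        raise ValueError(
            f"expected {scheme.bvalues.size} signal values, got {s.size}"
        )
    nonpos = np.flatnonzero(s <= 0)
    if nonpos.size:
        raise ValueError(f"non-positive signal at volume(s) {nonpos.tolist()}")
    weighted = scheme.bvalues > 0
    s0 = s[~weighted].mean()
    y = np.log(s[weighted] / s0)
    b_mat = _design_matrix(scheme, weighted)
    if np.linalg.matrix_rank(b_mat) < 6:
        raise ValueError("gradient directions are rank-deficient (< 6 independent)")
    coef, *_ = np.linalg.lstsq(b_mat, y, rcond=None)
    return Tensor.from_matrix(_tensor_from_coeffs(coef))


def compute_scalars(eigenvalues: np.ndarray, rd_denominator: int = 2) -> ScalarSet:
    """Scalar metrics from eigenvalues sorted descending.

    ``rd_denominator=2`` gives the conventional RD (mean of the two minor
    eigenvalues); ``rd_denominator=3`` reproduces the variant sometimes
    printed with a /3 denominator.  A degenerate all-zero tensor has
    FA defined as 0.  Negative lambda3 (possible in noisy fits) is kept
    as-is but reported through the warnings channel.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape != (3,) or not np.all(np.isfinite(lam)):
        raise ValueError("eigenvalues must be three finite values")
    if not (lam[0] >= lam[1] >= lam[2]):
        raise ValueError("eigenvalues must be sorted descending")
    if rd_denominator not in (2, 3):
        raise ValueError("rd_denominator must be 2 or 3")
    if lam[2] < 0:
        warnings.warn(
            f"negative minor eigenvalue {lam[2]:.3e}; scalars computed as-is",
            RuntimeWarning,
            stacklevel=2,
        )
    md = lam.sum() / 3.0
    rd = (lam[1] + lam[2]) / rd_denominator
    ax = lam[0]
    norm_sq = float(np.dot(lam, lam))
    if norm_sq == 0.0:
        fa = 0.0
    else:
        fa = float(np.sqrt(1.5) * np.sqrt(np.sum((lam - md) ** 2) / norm_sq))
    return ScalarSet(fa=fa, md=float(md), rd=float(rd), ax=float(ax))


def scalars_from_tensor(tensor: Tensor, rd_denominator: int = 2) -> ScalarSet:
    return compute_scalars(tensor.eigenvalues, rd_denominator=rd_denominator)


def forward_signals(d: np.ndarray, scheme: DiffusionScheme, s0: float = 1.0) -> np.ndarray:
    """Noise-free signals from tensor ``d`` under ``scheme`` (all volumes)."""
    d = np.asarray(d, dtype=float)
    b = scheme.bvalues
    g = scheme.bvectors
    adc = np.einsum("ni,ij,nj->n", g, d, g)
    out = s0 * np.exp(-b * adc)
    out[b == 0] = s0
    return out


def fit_tensor_volume(
    data: np.ndarray, scheme: DiffusionScheme, mask: np.ndarray | None = None,
    rd_denominator: int = 2,
) -> dict[str, np.ndarray]:
    """Voxel-wise log-linear tensor fit over a 4D array (x, y, z, volume).

    Returns float32 scalar maps keyed by metric name; voxels outside the
    mask (or with non-positive signal) are zero.  The per-voxel fits share
    one pseudo-inverse of the design matrix, so the whole volume is a
    single matrix product.
    """
    scheme.validate_for_fit()
    data = np.asarray(data, dtype=float)
    if data.ndim != 4 or data.shape[3] != scheme.bvalues.size:
        raise ValueError("data must be 4D with one volume per scheme entry")
    shape = data.shape[:3]
    flat = data.reshape(-1, data.shape[3])
    valid = np.all(flat > 0, axis=1)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool).ravel()
    weighted = scheme.bvalues > 0
    s0 = flat[valid][:, ~weighted].mean(axis=1)
    y = np.log(flat[valid][:, weighted] / s0[:, None])
    b_mat = _design_matrix(scheme, weighted)
    coefs = y @ np.linalg.pinv(b_mat).T  # (n_valid, 6)
    # Eigenvalues of many symmetric 3x3 tensors at once.
    dxx, dyy, dzz, dxy, dxz, dyz = coefs.T
    tensors = np.empty((coefs.shape[0], 3, 3))
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    lam = np.linalg.eigvalsh(tensors)[:, ::-1]  # descending
    md = lam.mean(axis=1)
    rd = (lam[:, 1] + lam[:, 2]) / rd_denominator
    ax = lam[:, 0]
    norm_sq = np.sum(lam**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.sum((lam - md[:, None]) ** 2, axis=1) / norm_sq)
    fa = np.where(norm_sq == 0, 0.0, fa)
    maps = {}
    for name, values in zip(METRICS, (fa, md, rd, ax)):
        vol = np.zeros(np.prod(shape))
        vol[valid] = values
        maps[name] = vol.reshape(shape).astype(np.float32)
    return maps


def save_scalar_maps(
    maps: dict[str, np.ndarray], affine: np.ndarray, out_dir: str | Path,
    prefix: str = "",
) -> dict[str, Path]:
    """Write one float32 NIfTI-1 file per metric, carrying the affine."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in maps.items():
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine)
        path = out_dir / f"{prefix}{name.lower()}.nii"
        nib.save(img, path)
        paths[name] = path
    return paths


def make_scheme(n_directions: int = 30, bvalue: float = 1000.0, n_b0: int = 1) -> DiffusionScheme:
    """A well-spread acquisition scheme: b=0 volumes plus a Fibonacci-sphere
    set of ``n_directions`` unit gradients at the given b-value.

    The defaults mirror a common clinical protocol (1 b0 + 30 directions
    at b = 1000 s/mm^2).
    """
    i = np.arange(n_directions)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_directions
    rho = np.sqrt(1.0 - z**2)
    dirs = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionScheme(bvals, bvecs)
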