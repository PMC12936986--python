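"""Statistical shape model construction.

A shape model is a linear point-distribution model over corresponded
surfaces: any shape is expressed as S = S̄ + P·α, where S̄ is the mean of
the Procrustes-aligned training cohort, the columns of P are the unit
eigenvectors of the shape covariance C = 1/(N−1) Σ (Sᵢ−S̄)(Sᵢ−S̄)ᵀ, and α
weights the retained modes. Modes are kept up to a cumulative-variance
threshold (default 98%).

Numerically the eigenpairs come from an SVD of the centred N×3V data
matrix, never from the 3V×3V covariance. Generalised Procrustes Analysis
removes translation and rotation before PCA; scale is kept by default
because absolute size carries clinical meaning for mm-valued outputs.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AlignmentError, MeshValidationError
from .geometry import kabsch
from .meshdata import TemplateDefinition

GPA_TOL = 1e-9
GPA_MAX_ITER = 100
VARIANCE_THRESHOLD = 0.98


@dataclass
class CorrespondedCohort:
    """N shapes sharing one vertex ordering; shapes stored as (N, V, 3)."""

    shapes: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.shapes = np.asarray(self.shapes, dtype=float)
        if self.shapes.ndim != 3 or self.shapes.shape[2] != 3:
            raise MeshValidationError("cohort shapes must be (N, V, 3)")
        if self.shapes.shape[0] < 2:
            raise MeshValidationError("cohort needs N >= 2 shapes")

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def vertex_count(self) -> int:
        return self.shapes.shape[1]

    def subset(self, vertex_indices) -> "CorrespondedCohort":
        return CorrespondedCohort(self.shapes[:, np.asarray(vertex_indices)], list(self.provenance))


@dataclass
class ShapeModel:
    """Mean shape + orthonormal variation modes of a corresponded cohort.

    ``mean`` is the stacked 3V vector of the consensus shape; ``modes`` is
    3V×t with orthonormal columns sorted by descending eigenvalue (mm²);
    ``spectrum`` keeps the full positive eigenvalue list for variance
    accounting. ``region_indices`` is set for local (sub-surface) models.
    """

    mean: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: float
    spectrum: np.ndarray
    region_scope: str = "global"
    region_indices: np.ndarray | None = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.modes = np.asarray(self.modes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.spectrum = np.asarray(self.spectrum, dtype=float)

    @property
    def t(self) -> int:
        return self.modes.shape[1]

    @property
    def vertex_count(self) -> int:
        return self.mean.size // 3

    @property
    def mean_points(self) -> np.ndarray:
        return self.mean.reshape(-1, 3)

    # ------------------------------------------------------------------
    def synthesize(self, alpha: np.ndarray) -> np.ndarray:
        """Return the 3V shape vector S̄ + P·α."""
        alpha = np.asarray(alpha, dtype=float).ravel()
        if alpha.size != self.t:
            raise ValueError(f"alpha has length {alpha.size}, model has t={self.t}")
        return self.mean + self.modes @ alpha

    def synthesize_points(self, alpha) -> np.ndarray:
        return self.synthesize(alpha).reshape(-1, 3)

    def project(self, shape: np.ndarray) -> np.ndarray:
        """Mode coefficients Pᵀ(S − S̄) of a (3V,) or (V, 3) shape."""
        s = np.asarray(shape, dtype=float).ravel()
        if s.size != self.mean.size:
            raise ValueError("shape size mismatch")
        return self.modes.T @ (s - self.mean)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive serialization: a zip of .npy arrays + JSON header."""
        meta = {
            "format": "limbmark-ssm-1",
            "t": int(self.t),
            "vertex_count": int(self.vertex_count),
            "variance_fraction": float(self.variance_fraction),
            "region_scope": self.region_scope,
        }
        with zipfile.ZipFile(str(path), "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            for name, arr in [
                ("mean", self.mean),
                ("modes", self.modes),
                ("eigenvalues", self.eigenvalues),
                ("spectrum", self.spectrum),
            ]:
                buf = io.BytesIO()
                np.save(buf, arr)
                zf.writestr(name + ".npy", buf.getvalue())
            if self.region_indices is not None:
                buf = io.BytesIO()
                np.save(buf, np.asarray(self.region_indices, dtype=np.int64))
                zf.writestr("region_indices.npy", buf.getvalue())

    @classmethod
    def load(cls, path) -> "ShapeModel":
        with zipfile.ZipFile(str(path)) as zf:
            meta = json.loads(zf.read("meta.json"))
            arrays = {}
            for name in ("mean", "modes", "eigenvalues", "spectrum"):
                arrays[name] = np.load(io.BytesIO(zf.read(name + ".npy")))
            region = None
            if "region_indices.npy" in zf.namelist():
                region = np.load(io.BytesIO(zf.read("region_indices.npy")))
        return cls(
            arrays["mean"],
            arrays["modes"],
            arrays["eigenvalues"],
            meta["variance_fraction"],
            arrays["spectrum"],
            meta.get("region_scope", "global"),
            region,
        )


# ---------------------------------------------------------------------------
# Generalised Procrustes Analysis
# ---------------------------------------------------------------------------


def generalized_procrustes(
    cohort: CorrespondedCohort,
    with_scaling: bool = False,
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
):
    """Iteratively align a cohort to its consensus (translation + rotation).

    Each shape is centred and rotated (optionally scaled) onto the current
    consensus via Kabsch; the consensus is the vertex-wise mean of the
    aligned shapes; iteration stops when the relative consensus change
    drops below ``tol``.

    Returns ``(aligned CorrespondedCohort, consensus (V, 3))``.
    """
    X = cohort.shapes.copy()
    if not np.isfinite(X).all():
        raise AlignmentError("non-finite coordinates in cohort")
    X -= X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=(1, 2))
    if (norms < 1e-12).any():
        raise AlignmentError("degenerate shape: all points coincident")
    if with_scaling:
        X /= norms[:, None, None]

    consensus = X[0].copy()
    scale_ref = np.linalg.norm(consensus)
    for _ in range(max_iter):
        for i in range(len(X)):
            R, t, s = kabsch(X[i], consensus, scale=with_scaling)
            X[i] = s * X[i] @ R.T + t
        new = X.mean(axis=0)
        new -= new.mean(axis=0)
        if with_scaling:
            new *= scale_ref / np.linalg.norm(new)
        change = np.linalg.norm(new - consensus) / max(np.linalg.norm(consensus), 1e-300)
        consensus = new
        if change < tol:
            break
    return CorrespondedCohort(X, list(cohort.provenance)), consensus


# ---------------------------------------------------------------------------
# PCA model construction
# ---------------------------------------------------------------------------


def build_ssm(
    cohort: CorrespondedCohort,
    variance_threshold: float = VARIANCE_THRESHOLD,
    region_scope: str = "global",
    region_indices=None,
) -> ShapeModel:
    """PCA of an aligned cohort; retain modes up to the variance threshold.

    The eigendecomposition is done by SVD of the centred N×3V data matrix;
    eigenvalues are singular values squared over (N−1). The retained count
    t is the smallest number of leading modes whose cumulative variance
    reaches ``variance_threshold`` of the total.
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    N = cohort.n
    flat = cohort.shapes.reshape(N, -1)
    mean = flat.mean(axis=0)
    centred = flat - mean
    # SVD of the (small) data matrix; rank <= N-1 after centring
    U, S, Vt = np.linalg.svd(centred, full_matrices=False)
    k = min(N - 1, Vt.shape[0])
    eigvals = (S[:k] ** 2) / (N - 1)
    modes = Vt[:k].T  # (3V, k), orthonormal columns

    total = eigvals.sum()
    if total <= 0:
        t = 1
        variance_fraction = 1.0
    else:
        frac = np.cumsum(eigvals) / total
        t = int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)
        t = min(t, k)
        variance_fraction = float(frac[t - 1])

    modes = modes[:, :t]
    # sign convention: each mode's largest-magnitude component is positive
    arg = np.abs(modes).argmax(axis=0)
    signs = np.sign(modes[arg, np.arange(t)])
    signs[signs == 0] = 1.0
    modes = modes * signs

    return ShapeModel(
        mean,
        modes,
        eigvals[:t],
        variance_fraction,
        eigvals,
        region_scope,
        None if region_indices is None else np.asarray(region_indices, dtype=np.int64),
    )


def synthesize(model: ShapeModel, alpha) -> np.ndarray:
    """Module-level alias for :meth:`ShapeModel.synthesize`."""
    return model.synthesize(alpha)


# ---------------------------------------------------------------------------
# Local (regional) models
# ---------------------------------------------------------------------------


def extract_local_region(
    template: TemplateDefinition,
    bone_axis_fraction: float = 0.20,
    end: str = "proximal",
) -> np.ndarray:
    """Vertex indices of one terminal slab along the bone's long axis.

    The longitudinal axis is the first principal axis of the template
    vertices, sign-oriented so the declared proximal marker vertex sits at
    the high end; the region is the requested terminal fraction of the
    axial extent.
    """
    if not 0.0 < bone_axis_fraction <= 0.5:
        raise ValueError("bone_axis_fraction must be in (0, 0.5]")
    if end not in ("proximal", "distal"):
        raise ValueError("end must be 'proximal' or 'distal'")
    v = template.mesh.vertices
    centred = v - v.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    axis = Vt[0]
    coord = centred @ axis
    marker = template.proximal_marker
    if marker is None:
        raise MeshValidationError("template lacks a proximal marker vertex")
    if coord[marker] < 0:
        coord = -coord
    lo, hi = coord.min(), coord.max()
    extent = hi - lo
    if end == "proximal":
        sel = coord >= hi - bone_axis_fraction * extent
    else:
        sel = coord <= lo + bone_axis_fraction * extent
    return np.nonzero(sel)[0]


def build_local_ssm(
    cohort: CorrespondedCohort,
    region_indices,
    variance_threshold: float = VARIANCE_THRESHOLD,
    with_scaling: bool = False,
) -> ShapeModel:
    """GPA + PCA on a vertex subset; the model remembers its region indices."""
    region_indices = np.asarray(region_indices, dtype=np.int64)
    if region_indices.size == 0:
        raise MeshValidationError("empty region")
    if region_indices.min() < 0 or region_indices.max() >= cohort.vertex_count:
        raise MeshValidationError("region index out of range for cohort")
    sub = cohort.subset(region_indices)
    aligned, _ = generalized_procrustes(sub, with_scaling=with_scaling)
    return build_ssm(
        aligned,
        variance_threshold,
        region_scope=f"local({region_indices.size} vertices)",
        region_indices=region_indices,
    )
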