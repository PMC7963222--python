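"""Tensor-valued diffusion encoding: b-tensors, acquisition protocols, Voigt algebra.

A diffusion measurement is described by a symmetric positive-semidefinite 3x3
b-tensor B (units ms/um^2).  Conventional single-direction encoding gives a
rank-1 ("linear") b-tensor b*(n n^T); isotropic encoding gives a "spherical"
b-tensor (b/3)*I.  Acquiring both shapes is what makes the microscopic
anisotropy identifiable in the cumulant model of :mod:`qtimcd.qti`.

The Voigt convention used throughout the package maps a symmetric 3x3 matrix
to a 6-vector ``[xx, yy, zz, sqrt(2)*yz, sqrt(2)*xz, sqrt(2)*xy]`` so that the
double contraction A:B of two symmetric matrices equals the plain dot product
of their 6-vectors.  The analogous scaled mapping of a symmetric 6x6 matrix to
a 21-vector makes fourth-order double contractions plain dot products as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BTensor",
    "AcquisitionProtocol",
    "make_btensor",
    "btensor_from_matrix",
    "build_protocol",
    "uniform_directions",
    "voigt6",
    "unvoigt6",
    "voigt21",
    "unvoigt21",
    "read_sidecar",
    "write_sidecar",
    "read_bval_bvec",
    "write_bval_bvec",
    "DEFAULT_SHELLS",
    "DEFAULT_N_B0",
]

_SQRT2 = float(np.sqrt(2.0))

# Default multi-shell protocol: linear + spherical shapes up to b = 2.0 ms/um^2.
# 2 b=0 volumes + 38 linear + 18 spherical = 58 measurements; gives a
# full-rank (28-column) cumulant design matrix.
DEFAULT_SHELLS: tuple[dict, ...] = (
    {"shape": "linear", "b": 0.1, "n": 6},
    {"shape": "linear", "b": 0.7, "n": 6},
    {"shape": "linear", "b": 1.4, "n": 10},
    {"shape": "linear", "b": 2.0, "n": 16},
    {"shape": "spherical", "b": 0.1, "n": 3},
    {"shape": "spherical", "b": 0.7, "n": 3},
    {"shape": "spherical", "b": 1.4, "n": 6},
    {"shape": "spherical", "b": 2.0, "n": 6},
)
DEFAULT_N_B0 = 2


# ---------------------------------------------------------------------------
# Voigt algebra
# ---------------------------------------------------------------------------

def _require_symmetric(a: np.ndarray, tol: float, what: str) -> None:
    if a.shape != (a.shape[0], a.shape[0]):
        raise ValueError(f"{what} must be square, got shape {a.shape}")
    scale = max(float(np.abs(a).max()), 1.0)
    if float(np.abs(a - a.T).max()) > tol * scale:
        raise ValueError(f"{what} is not symmetric to tolerance {tol}")


def voigt6(matrix: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Map a symmetric 3x3 matrix to its scaled 6-vector.

    The scaling by sqrt(2) on the off-diagonal entries preserves inner
    products: ``voigt6(A) @ voigt6(B) == A:B``.
    """
    a = np.asarray(matrix, dtype=float)
    if a.shape != (3, 3):
        raise ValueError(f"expected 3x3 matrix, got shape {a.shape}")
    _require_symmetric(a, tol, "matrix")
    return np.array(
        [a[0, 0], a[1, 1], a[2, 2], _SQRT2 * a[1, 2], _SQRT2 * a[0, 2], _SQRT2 * a[0, 1]]
    )


def unvoigt6(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voigt6` (exact round trip)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (6,):
        raise ValueError(f"expected 6-vector, got shape {v.shape}")
    yz, xz, xy = v[3] / _SQRT2, v[4] / _SQRT2, v[5] / _SQRT2
    return np.array([[v[0], xy, xz], [xy, v[1], yz], [xz, yz, v[2]]])


# index pairs of the 6x6 upper triangle: 6 diagonal entries first, then the
# 15 off-diagonal entries in row-major order
_TRIU21: tuple[tuple[int, int], ...] = tuple((i, i) for i in range(6)) + tuple(
    (i, j) for i in range(6) for j in range(i + 1, 6)
)


def voigt21(m6: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Map a symmetric 6x6 matrix (in the scaled Voigt basis) to a 21-vector.

    Diagonal entries are kept as-is and off-diagonals are scaled by sqrt(2),
    so fourth-order double contractions become 21-vector dot products.
    """
    m = np.asarray(m6, dtype=float)
    if m.shape != (6, 6):
        raise ValueError(f"expected 6x6 matrix, got shape {m.shape}")
    _require_symmetric(m, tol, "matrix")
    out = np.empty(21)
    for k, (i, j) in enumerate(_TRIU21):
        out[k] = m[i, j] if i == j else _SQRT2 * m[i, j]
    return out


def unvoigt21(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voigt21` (exact round trip)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (21,):
        raise ValueError(f"expected 21-vector, got shape {v.shape}")
    m = np.zeros((6, 6))
    for k, (i, j) in enumerate(_TRIU21):
        if i == j:
            m[i, i] = v[k]
        else:
            m[i, j] = m[j, i] = v[k] / _SQRT2
    return m


# ---------------------------------------------------------------------------
# B-tensors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BTensor:
    """A single diffusion-encoding b-tensor.

    Attributes
    ----------
    matrix : (3, 3) ndarray
        Symmetric positive-semidefinite encoding tensor, ms/um^2.
    shape_tag : {"linear", "spherical"}
        Encoding shape; linear tensors are rank 1, spherical tensors are
        isotropic.
    b : float
        Total diffusion weighting, trace of ``matrix`` (ms/um^2).
    orientation : (3,) ndarray or None
        Unit encoding direction; defined for linear tensors only.
    """

    matrix: np.ndarray
    shape_tag: str
    b: float
    orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if self.shape_tag not in ("linear", "spherical"):
            raise ValueError(f"unknown shape_tag {self.shape_tag!r}")
        _require_symmetric(m, 1e-10, "b-tensor matrix")
        tr = float(np.trace(m))
        scale = max(abs(self.b), 1.0)
        if abs(tr - self.b) > 1e-12 * scale:
            raise ValueError(f"trace {tr} does not match b {self.b}")
        if self.b < 0:
            raise ValueError("b must be non-negative")
        w = np.linalg.eigvalsh(m)
        if w[0] < -1e-12 * scale:
            raise ValueError("b-tensor must be positive semidefinite")
        if self.orientation is not None:
            object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))


def make_btensor(
    shape_tag: str, b: float, orientation: Sequence[float] | None = None
) -> BTensor:
    """Construct a linear (rank-1) or spherical (isotropic) b-tensor.

    Parameters
    ----------
    shape_tag : {"linear", "spherical"}
    b : float
        Diffusion weighting in ms/um^2 (trace of the tensor).
    orientation : length-3 sequence, optional
        Unit direction; required for linear encoding, ignored for spherical.
    """
    if b < 0:
        raise ValueError(f"b must be non-negative, got {b}")
    if shape_tag == "linear":
        if orientation is None:
            raise ValueError("linear b-tensor requires an orientation")
        n = np.asarray(orientation, dtype=float)
        nn = float(np.linalg.norm(n))
        if nn < 1e-12:
            raise ValueError("orientation must have nonzero norm")
        if abs(nn - 1.0) > 1e-8:
            raise ValueError(f"orientation must be a unit vector, norm {nn}")
        n = n / nn
        return BTensor(matrix=b * np.outer(n, n), shape_tag="linear", b=float(b), orientation=n)
    if shape_tag == "spherical":
        return BTensor(matrix=(b / 3.0) * np.eye(3), shape_tag="spherical", b=float(b))
    raise ValueError(f"unknown shape_tag {shape_tag!r}")


def btensor_from_matrix(matrix: np.ndarray, tol: float = 1e-6) -> BTensor:
    """Classify a raw 3x3 encoding matrix as a linear or spherical b-tensor.

    A zero matrix (b = 0) is tagged spherical by convention.  Matrices that
    are neither rank 1 nor isotropic to within ``tol`` (relative to b) are
    rejected.
    """
    m = np.asarray(matrix, dtype=float)
    _require_symmetric(m, 1e-8, "b-tensor matrix")
    m = 0.5 * (m + m.T)
    b = float(np.trace(m))
    if b < tol:
        return BTensor(matrix=np.zeros((3, 3)), shape_tag="spherical", b=0.0)
    w, v = np.linalg.eigh(m)
    if w[2] / b > 1.0 - tol:
        n = v[:, 2]
        return BTensor(matrix=b * np.outer(n, n), shape_tag="linear", b=b, orientation=n)
    if float(np.abs(m - (b / 3.0) * np.eye(3)).max()) < tol * b:
        return BTensor(matrix=(b / 3.0) * np.eye(3), shape_tag="spherical", b=b)
    raise ValueError("b-tensor is neither linear (rank 1) nor spherical (isotropic)")


# ---------------------------------------------------------------------------
# Direction sets and protocols
# ---------------------------------------------------------------------------

def uniform_directions(n: int, seed: int = 0, n_iter: int = 200, step: float = 0.1) -> np.ndarray:
    """Approximately uniform unit directions by seeded electrostatic repulsion.

    Points repel each other and their antipodes (charges on a projective
    sphere), which suits diffusion encoding where +n and -n are equivalent.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    for _ in range(n_iter):
        f = np.zeros_like(x)
        for sgn in (1.0, -1.0):
            d = x[:, None, :] - sgn * x[None, :, :]
            r2 = np.einsum("ijk,ijk->ij", d, d)
            if sgn == 1.0:
                np.fill_diagonal(r2, np.inf)
            f += np.einsum("ijk,ij->ik", d, r2**-1.5)
        f -= np.einsum("ik,ik->i", f, x)[:, None] * x  # tangent projection
        x = x + step * f / n
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    # canonical hemisphere (z >= 0) for reproducible sign conventions
    flip = (x[:, 2] < 0) | ((x[:, 2] == 0) & (x[:, 0] < 0))
    x[flip] *= -1.0
    return x


@dataclass(frozen=True)
class AcquisitionProtocol:
    """An ordered list of b-tensors, one per acquired 4-D volume."""

    btensors: tuple[BTensor, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "btensors", tuple(self.btensors))
        if not self.btensors:
            raise ValueError("protocol must contain at least one b-tensor")

    def __len__(self) -> int:
        return len(self.btensors)

    @property
    def bvals(self) -> np.ndarray:
        return np.array([bt.b for bt in self.btensors])

    @property
    def b_max(self) -> float:
        return float(self.bvals.max())

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals < 1e-9))

    def matrices(self) -> np.ndarray:
        """Stack of encoding matrices, shape (n, 3, 3)."""
        return np.stack([bt.matrix for bt in self.btensors])

    def scaled(self, factor: float) -> "AcquisitionProtocol":
        """Protocol with every b-value multiplied by ``factor`` (same shapes
        and directions); used for b_max sweeps."""
        out = []
        for bt in self.btensors:
            if bt.shape_tag == "linear" and bt.b > 0:
                out.append(make_btensor("linear", bt.b * factor, bt.orientation))
            else:
                out.append(make_btensor(bt.shape_tag, bt.b * factor, bt.orientation))
        return AcquisitionProtocol(tuple(out))


def build_protocol(
    shells: Iterable[dict] = DEFAULT_SHELLS,
    n_b0: int = DEFAULT_N_B0,
    seed: int = 0,
    for_fitting: bool = True,
) -> AcquisitionProtocol:
    """Build a multi-shell protocol from per-shell specs.

    Parameters
    ----------
    shells : iterable of dict
        Each entry has keys ``shape`` ("linear"/"spherical"), ``b`` (ms/um^2)
        and ``n`` (number of directions for linear shells, repeats for
        spherical shells).
    n_b0 : int
        Number of b=0 volumes, placed first.
    seed : int
        Seed for the per-shell direction sets (deterministic).
    for_fitting : bool
        When True, require at least one linear and one spherical nonzero-b
        shell so the cumulant model is identifiable.
    """
    shells = list(shells)
    if not shells and n_b0 == 0:
        raise ValueError("empty protocol specification")
    shapes_nonzero = {s["shape"] for s in shells if s["b"] > 0}
    if for_fitting and not {"linear", "spherical"} <= shapes_nonzero:
        raise ValueError(
            "QTI fitting requires both linear and spherical nonzero-b shells; "
            f"got shapes {sorted(shapes_nonzero)}"
        )
    bts: list[BTensor] = [make_btensor("spherical", 0.0) for _ in range(n_b0)]
    for k, shell in enumerate(shells):
        shape, b, n = shell["shape"], float(shell["b"]), int(shell["n"])
        if shape == "linear":
            dirs = uniform_directions(n, seed=seed + 1000 * k)
            bts.extend(make_btensor("linear", b, d) for d in dirs)
        elif shape == "spherical":
            bts.extend(make_btensor("spherical", b) for _ in range(n))
        else:
            raise ValueError(f"unknown shell shape {shape!r}")
    return AcquisitionProtocol(tuple(bts))


# ---------------------------------------------------------------------------
# Sidecar I/O
# ---------------------------------------------------------------------------

def write_sidecar(protocol: AcquisitionProtocol, path: str | Path) -> None:
    """Write the per-volume b-tensor sidecar: one line of 9 row-major matrix
    entries (ms/um^2) per volume; '#' lines are comments."""
    lines = ["# b-tensor sidecar: one volume per line, 9 row-major entries, ms/um^2"]
    for bt in protocol.btensors:
        lines.append(" ".join(f"{x:.12g}" for x in bt.matrix.ravel()))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path: str | Path) -> AcquisitionProtocol:
    """Read a b-tensor sidecar written by :func:`write_sidecar`."""
    bts = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals = line.split()
        if len(vals) != 9:
            raise ValueError(f"{path}:{ln}: expected 9 entries, got {len(vals)}")
        m = np.array([float(v) for v in vals]).reshape(3, 3)
        bts.append(btensor_from_matrix(m))
    if not bts:
        raise ValueError(f"{path}: no b-tensors found")
    return AcquisitionProtocol(tuple(bts))


def write_bval_bvec(protocol: AcquisitionProtocol, prefix: str | Path) -> None:
    """Write legacy bval/bvec files plus a shape column (``.shape``).

    bvals are in ms/um^2; spherical and b=0 volumes get a zero bvec.
    """
    prefix = Path(prefix)
    bvals, bvecs, shapes = [], [], []
    for bt in protocol.btensors:
        bvals.append(bt.b)
        shapes.append(bt.shape_tag)
        if bt.shape_tag == "linear" and bt.orientation is not None and bt.b > 0:
            bvecs.append(bt.orientation)
        else:
            bvecs.append(np.zeros(3))
    bvecs_arr = np.array(bvecs).T
    prefix.with_suffix(".bval").write_text(" ".join(f"{b:.12g}" for b in bvals) + "\n")
    prefix.with_suffix(".bvec").write_text(
        "\n".join(" ".join(f"{x:.12g}" for x in row) for row in bvecs_arr) + "\n"
    )
    prefix.with_suffix(".shape").write_text("\n".join(shapes) + "\n")


def read_bval_bvec(prefix: str | Path) -> AcquisitionProtocol:
    """Read a bval/bvec pair plus shape column written by
    :func:`write_bval_bvec`."""
    prefix = Path(prefix)
    bvals = [float(v) for v in prefix.with_suffix(".bval").read_text().split()]
    rows = [
        [float(v) for v in line.split()]
        for line in prefix.with_suffix(".bvec").read_text().splitlines()
        if line.strip()
    ]
    bvecs = np.array(rows).T
    shapes = [s.strip() for s in prefix.with_suffix(".shape").read_text().split()]
    if not (len(bvals) == len(bvecs) == len(shapes)):
        raise ValueError("bval/bvec/shape files disagree on volume count")
    bts = []
    for b, vec, shape in zip(bvals, bvecs, shapes):
        if b <= 0:
            bts.append(make_btensor("spherical", 0.0))
        elif shape == "spherical":
            bts.append(make_btensor("spherical", b))
        else:
            bts.append(make_btensor("linear", b, np.asarray(vec) / np.linalg.norm(vec)))
    return AcquisitionProtocol(tuple(bts))
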