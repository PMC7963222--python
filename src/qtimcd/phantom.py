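"""Digital phantom of malformations of cortical development (MCD).

The phantom emulates aligned multi-contrast data from a patient with a
gray-matter malformation: a coarse brain geometry (cortex shell, white
matter, deep gray nuclei, ventricular CSF) with procedural lesions of the
four classic MCD types --

* PH  : periventricular heterotopia, a nodule on the ventricular border
* SH  : subcortical heterotopia, a blob embedded in deep white matter
* FCD : focal cortical dysplasia, a patch straddling the gray-white boundary
* PMG : polymicrogyria, a ribbon of cortex along the brain surface

Each voxel carries a ground-truth *diffusion tensor distribution* (a discrete
mixture of Gaussian tensors).  White matter uses high-anisotropy axisymmetric
components (coherent or 90-degree crossing); cortex and deep gray use
low-anisotropy components with uniform orientation dispersion; CSF is fast
and isotropic.  Lesion voxels always receive cortex-level structural
(myelin-surrogate) intensity, while a designed fraction ``wm_fraction`` of
them -- the deepest part, farthest from the cortical surface -- receives
white-matter-like microstructure.  This encodes the dissociation the package
exists to study: tissue that looks like cortex on structural contrasts but
carries axon-like microscopic anisotropy.

Diffusion signals are simulated from the exact tensor mixture (not the
cumulant expansion) with Rician noise; pseudo-T1w/FLAIR volumes are monotone
functions of the myelin surrogate with Gaussian noise.  Everything is
reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy import ndimage

from .btensor import AcquisitionProtocol
from .qti import QTIMetrics, metrics_from_moments, moments_of_mixture

__all__ = [
    "TensorDistribution",
    "TissueParams",
    "LesionSpec",
    "PhantomSpec",
    "Phantom",
    "LABELS",
    "default_tissue_table",
    "default_phantom_spec",
    "axisymmetric_tensor",
    "build_labelmap",
    "assign_microstructure",
    "generate_dwi",
    "generate_structural",
    "build_phantom",
]

LABELS = {"background": 0, "csf": 1, "cortex": 2, "wm": 3, "deep_gm": 4}
LESION_LABEL_START = 10

# six icosahedral directions (antipodally unique); their outer-product mean
# is exactly I/3, so uniformly dispersed mixtures have an isotropic mean tensor
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICOSA6 = np.array(
    [
        [0.0, 1.0, _PHI],
        [0.0, 1.0, -_PHI],
        [1.0, _PHI, 0.0],
        [1.0, -_PHI, 0.0],
        [_PHI, 0.0, 1.0],
        [-_PHI, 0.0, 1.0],
    ]
)
_ICOSA6 /= np.linalg.norm(_ICOSA6, axis=1, keepdims=True)


def axisymmetric_tensor(axial: float, radial: float, direction: np.ndarray) -> np.ndarray:
    """Axially symmetric diffusion tensor with given principal direction."""
    n = np.asarray(direction, dtype=float)
    n = n / np.linalg.norm(n)
    return radial * np.eye(3) + (axial - radial) * np.outer(n, n)


@dataclass(frozen=True)
class TensorDistribution:
    """Discrete mixture of Gaussian diffusion tensors within one voxel."""

    weights: np.ndarray  # (k,)
    tensors: np.ndarray  # (k, 3, 3), um^2/ms

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        t = np.asarray(self.tensors, dtype=float)
        if w.ndim != 1 or t.shape != (len(w), 3, 3):
            raise ValueError("weights must be (k,) and tensors (k, 3, 3)")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")
        for d in t:
            if np.abs(d - d.T).max() > 1e-10:
                raise ValueError("component tensors must be symmetric")
            if np.linalg.eigvalsh(d)[0] < -1e-12:
                raise ValueError("component tensors must be positive semidefinite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "tensors", t)

    def moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact Voigt moments (mean 6-vector, covariance 6x6)."""
        return moments_of_mixture(self.weights, self.tensors)

    def metrics(self) -> QTIMetrics:
        """Ground-truth scalar metrics from the exact moments."""
        return metrics_from_moments(*self.moments())

    def signal(self, protocol: AcquisitionProtocol, s0: float = 1.0) -> np.ndarray:
        """Exact multi-Gaussian signal (no cumulant truncation)."""
        B = protocol.matrices()  # (n, 3, 3)
        atten = np.einsum("nij,kij->nk", B, self.tensors)
        return s0 * (np.exp(-atten) @ self.weights)


def _dispersed(axial: float, radial: float, mode: str) -> TensorDistribution:
    """Mixture of identical axisymmetric components at a given orientation
    dispersion mode."""
    if mode == "coherent":
        dirs = np.array([[0.0, 0.0, 1.0]])
    elif mode == "crossing":
        dirs = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    elif mode == "uniform":
        dirs = _ICOSA6
    else:
        raise ValueError(f"unknown dispersion mode {mode!r}")
    tensors = np.stack([axisymmetric_tensor(axial, radial, d) for d in dirs])
    w = np.full(len(dirs), 1.0 / len(dirs))
    return TensorDistribution(w, tensors)


@dataclass(frozen=True)
class TissueParams:
    """Per-label microstructure and pseudo-structural parameters.

    ``axial``/``radial`` are component diffusivities in um^2/ms; ``myelin``
    is a dimensionless myelin surrogate in [0, 1] that drives the
    pseudo-structural contrasts; ``t1w_mean``/``flair_mean`` are the noise-free
    pseudo-structural intensities (arbitrary units).
    """

    axial: float
    radial: float
    dispersion: str  # coherent | crossing | uniform
    myelin: float
    t1w_mean: float
    flair_mean: float

    def distribution(self) -> TensorDistribution:
        return _dispersed(self.axial, self.radial, self.dispersion)


def default_tissue_table() -> dict[str, TissueParams]:
    """Plausible adult-brain defaults.

    White matter is highly anisotropic (2.2/0.2 um^2/ms); cortex and deep
    gray are mildly anisotropic (1.2/0.7, 1.3/0.75) with uniform dispersion,
    so their FA is ~0 while their microscopic anisotropy is small but
    nonzero; CSF is fast isotropic (3.0).  Pseudo-T1w increases and
    pseudo-FLAIR decreases with the myelin surrogate across parenchyma; CSF
    is dark in both (fluid attenuation).
    """
    return {
        "csf": TissueParams(3.0, 3.0, "coherent", 0.0, 0.10, 0.08),
        "cortex": TissueParams(1.2, 0.7, "uniform", 0.25, 0.55, 0.75),
        "deep_gm": TissueParams(1.3, 0.75, "uniform", 0.30, 0.60, 0.72),
        "wm": TissueParams(2.2, 0.2, "coherent", 0.85, 0.95, 0.45),
    }


@dataclass(frozen=True)
class LesionSpec:
    """One procedural lesion.

    ``center`` is in voxel coordinates, ``radius`` the per-axis semi-size in
    voxels, and ``wm_fraction`` the designed
    fraction of lesion voxels carrying white-matter-like microstructure.
    """

    kind: str  # PH | SH | FCD | PMG
    center: tuple[int, int, int]
    radius: tuple[float, float, float]
    wm_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("PH", "SH", "FCD", "PMG"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if not 0.0 <= self.wm_fraction <= 1.0:
            raise ValueError("wm_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; (spec, seed) fixes every output byte."""

    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 4.0)  # mm
    tissue: dict[str, TissueParams] = field(default_factory=default_tissue_table)
    lesions: tuple[LesionSpec, ...] = ()
    snr: float = 30.0  # at b=0, relative to the white-matter S0
    structural_noise_sd: float = 0.03
    seed: int = 0


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Default study phantom: one lesion of each MCD type on a 32x32x16 grid.

    The SH lesion carries the designed white-matter-like fraction 0.40 used
    in the end-to-end dissociation analysis.
    """
    return PhantomSpec(
        lesions=(
            LesionSpec("PH", center=(21, 15, 8), radius=(2.5, 2.5, 2.0), wm_fraction=0.0),
            LesionSpec("SH", center=(8, 20, 8), radius=(4.0, 3.5, 2.5), wm_fraction=0.40),
            LesionSpec("FCD", center=(15, 4, 8), radius=(3.0, 3.0, 2.5), wm_fraction=0.30),
            LesionSpec("PMG", center=(27, 20, 8), radius=(4.0, 5.0, 3.0), wm_fraction=0.50),
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, semi) -> np.ndarray:
    g = np.indices(shape).astype(float)
    r2 = sum(((g[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def build_labelmap(spec: PhantomSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Construct the integer label volume and the ROI masks.

    Returns ``(labels, rois)`` where lesion i gets label ``10 + i`` and
    ``rois`` holds, per lesion, the lesion mask, a contralateral
    normal-cortex mask and an adjacent normal-white-matter mask, plus one
    shared deep-white-matter reference mask (a stand-in for the homogeneous
    anterior corona radiata used to normalize FLAIR intensities).
    """
    nx, ny, nz = spec.shape
    c = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    brain = _ellipsoid(spec.shape, c, (0.44 * nx, 0.47 * ny, 0.44 * nz))
    interior = ndimage.binary_erosion(brain, iterations=2)
    cortex = brain & ~interior
    ventricle = _ellipsoid(spec.shape, c, (3.0, 5.0, 2.5)) & interior
    deep_gm = np.zeros(spec.shape, dtype=bool)
    for dx in (-6.0, 6.0):
        deep_gm |= _ellipsoid(spec.shape, (c[0] + dx, c[1] - 1, c[2]), (1.8, 2.8, 1.5))
    deep_gm &= interior & ~ventricle
    wm = interior & ~ventricle & ~deep_gm

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[cortex] = LABELS["cortex"]
    labels[wm] = LABELS["wm"]
    labels[deep_gm] = LABELS["deep_gm"]
    labels[ventricle] = LABELS["csf"]

    lesion_masks: list[np.ndarray] = []
    for les in spec.lesions:
        region = _ellipsoid(spec.shape, les.center, les.radius)
        if les.kind == "PH":
            # nodule on the ventricular border: carve from tissue, keep
            # contact with CSF by including voxels bordering the ventricle
            m = region & (wm | deep_gm)
        elif les.kind == "SH":
            m = region & wm
        elif les.kind == "FCD":
            # patch straddling the gray-white boundary
            m = region & (cortex | wm)
        elif les.kind == "PMG":
            # ribbon following the cortical shell, one voxel into WM
            rim = cortex | (wm & ndimage.binary_dilation(cortex))
            m = region & rim
        if not m.any():
            raise ValueError(f"lesion {les.kind} at {les.center} is empty")
        lesion_masks.append(m)

    for i, mi in enumerate(lesion_masks):
        for j in range(i):
            if (mi & lesion_masks[j]).any():
                raise ValueError(
                    f"lesion specs {j} ({spec.lesions[j].kind}) and {i} "
                    f"({spec.lesions[i].kind}) overlap"
                )

    for i, m in enumerate(lesion_masks):
        labels[m] = LESION_LABEL_START + i

    rois: dict[str, np.ndarray] = {}
    cortex_now = labels == LABELS["cortex"]
    wm_now = labels == LABELS["wm"]
    grid = np.indices(spec.shape).reshape(3, -1).T.astype(float)
    for i, (les, m) in enumerate(zip(spec.lesions, lesion_masks)):
        rois[f"lesion_{i}_{les.kind}"] = m
        centroid = np.array(np.nonzero(m)).mean(axis=1)
        mirrored = centroid.copy()
        mirrored[0] = (nx - 1) - mirrored[0]
        # contralateral normal cortex: nearest cortex voxels to the mirror point
        cidx = np.flatnonzero(cortex_now.ravel())
        dist = np.linalg.norm(grid[cidx] - mirrored, axis=1)
        keep = cidx[np.argsort(dist, kind="stable")[:40]]
        cmask = np.zeros(spec.shape, dtype=bool)
        cmask.ravel()[keep] = True
        rois[f"cortex_{i}"] = cmask
        # adjacent normal white matter: WM voxels within 3 voxels of the lesion
        d_les = ndimage.distance_transform_edt(~m)
        adj = wm_now & (d_les > 0) & (d_les <= 3.0)
        if adj.sum() < 10:
            adj = wm_now & (d_les > 0) & (d_les <= 5.0)
        rois[f"wm_adj_{i}"] = adj
    # homogeneous deep-WM reference region (anterior corona radiata stand-in)
    ref_box = np.zeros(spec.shape, dtype=bool)
    ref_box[nx // 2 - 3 : nx // 2 + 3, ny // 4 - 2 : ny // 4 + 3, nz // 2 - 1 : nz // 2 + 2] = True
    rois["reference"] = ref_box & wm_now
    if not rois["reference"].any():
        raise ValueError("reference ROI is empty; enlarge the grid")
    return labels, rois


# ---------------------------------------------------------------------------
# Microstructure
# ---------------------------------------------------------------------------

def assign_microstructure(
    labels: np.ndarray, spec: PhantomSpec
) -> tuple[np.ndarray, list[TensorDistribution], dict[str, np.ndarray]]:
    """Assign a ground-truth tensor distribution to every non-background voxel.

    White matter is coherent except an anterior strip that carries a
    90-degree crossing (same components, hence same microscopic anisotropy
    but reduced FA).  For each lesion, the ``round(wm_fraction * n)`` voxels
    deepest below the cortical surface receive the coherent white-matter
    distribution; the rest stay cortex-like.

    Returns ``(dist_id, distributions, ground_truth)`` where ``dist_id`` is
    -1 for background and indexes ``distributions`` elsewhere, and
    ``ground_truth`` holds exact-moment MD/FA/MK_A volumes plus the
    ``wm_like`` lesion mask.
    """
    tissue = spec.tissue
    for name in ("csf", "cortex", "deep_gm", "wm"):
        if name not in tissue:
            raise ValueError(f"tissue table missing entry for {name!r}")
    dists = [
        tissue["csf"].distribution(),  # 0
        tissue["cortex"].distribution(),  # 1
        tissue["deep_gm"].distribution(),  # 2
        tissue["wm"].distribution(),  # 3: coherent WM
        _dispersed(tissue["wm"].axial, tissue["wm"].radial, "crossing"),  # 4
    ]
    CSF_D, CTX_D, DGM_D, WM_D, WMX_D = range(5)

    present = set(int(v) for v in np.unique(labels))
    known = set(LABELS.values()) | {
        LESION_LABEL_START + i for i in range(len(spec.lesions))
    }
    unknown = present - known
    if unknown:
        raise ValueError(f"unknown labels in volume: {sorted(unknown)}")

    dist_id = np.full(labels.shape, -1, dtype=np.int16)
    dist_id[labels == LABELS["csf"]] = CSF_D
    dist_id[labels == LABELS["cortex"]] = CTX_D
    dist_id[labels == LABELS["deep_gm"]] = DGM_D
    wm_mask = labels == LABELS["wm"]
    dist_id[wm_mask] = WM_D
    # anterior strip of WM carries crossing fibers
    ny = labels.shape[1]
    strip = np.zeros(labels.shape, dtype=bool)
    strip[:, : ny // 4, :] = True
    dist_id[wm_mask & strip] = WMX_D

    # depth below the cortical surface (distance to the nearest cortex voxel)
    cortex_mask = labels == LABELS["cortex"]
    depth = ndimage.distance_transform_edt(~cortex_mask)

    wm_like = np.zeros(labels.shape, dtype=bool)
    for i, les in enumerate(spec.lesions):
        m = labels == LESION_LABEL_START + i
        n = int(m.sum())
        dist_id[m] = CTX_D
        k = int(round(les.wm_fraction * n))
        if k > 0:
            flat = np.flatnonzero(m.ravel())
            order = np.argsort(-depth.ravel()[flat], kind="stable")
            chosen = flat[order[:k]]
            sel = np.zeros(labels.shape, dtype=bool)
            sel.ravel()[chosen] = True
            dist_id[sel] = WM_D
            wm_like |= sel

    gt: dict[str, np.ndarray] = {}
    per_dist = [d.metrics() for d in dists]
    for key in ("md", "fa", "mk_a"):
        vol = np.full(labels.shape, np.nan)
        for k, met in enumerate(per_dist):
            vol[dist_id == k] = getattr(met, key)
        gt[key] = vol
    gt["wm_like"] = wm_like
    return dist_id, dists, gt


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def generate_dwi(
    dist_id: np.ndarray,
    dists: list[TensorDistribution],
    protocol: AcquisitionProtocol,
    snr: float | None,
    seed: int,
    s0: float = 1.0,
) -> np.ndarray:
    """Simulate 4-D diffusion-weighted data from per-voxel distributions.

    Signals are the exact multi-Gaussian mixture attenuations (no cumulant
    truncation).  Rician noise: the magnitude of (s + e1, e2) with e1, e2
    drawn from N(0, sigma), sigma = s0 / SNR (SNR defined at b=0 in white
    matter, which shares ``s0`` with all tissue here).  ``snr=None`` (or
    inf) yields noiseless data.  Deterministic given ``seed``.
    """
    if snr is not None and not np.isinf(snr) and snr <= 0:
        raise ValueError("snr must be positive")
    dist_id = np.asarray(dist_id)
    n = len(protocol)
    library = np.zeros((len(dists) + 1, n))
    for k, d in enumerate(dists):
        library[k] = d.signal(protocol, s0=s0)
    # background (-1) maps to the all-zero last row
    signals = library[dist_id]
    if snr is None or np.isinf(snr):
        return signals
    sigma = s0 / float(snr)
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, signals.shape)
    e2 = rng.normal(0.0, sigma, signals.shape)
    return np.hypot(signals + e1, e2)


def generate_structural(
    labels: np.ndarray, spec: PhantomSpec, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate pseudo-T1w and pseudo-FLAIR volumes.

    Intensity is a per-label mean (monotone increasing in the myelin
    surrogate for T1w and decreasing for FLAIR across parenchyma) plus
    Gaussian noise.  Lesion voxels always receive the cortex means -- the
    structural appearance of misplaced cortical tissue does not depend on
    its axonal content.
    """
    tissue = spec.tissue
    t1w = np.zeros(labels.shape)
    flair = np.zeros(labels.shape)
    by_label = {
        LABELS["csf"]: tissue["csf"],
        LABELS["cortex"]: tissue["cortex"],
        LABELS["deep_gm"]: tissue["deep_gm"],
        LABELS["wm"]: tissue["wm"],
    }
    for i in range(len(spec.lesions)):
        by_label[LESION_LABEL_START + i] = tissue["cortex"]
    for lab, par in by_label.items():
        m = labels == lab
        t1w[m] = par.t1w_mean
        flair[m] = par.flair_mean
    rng = np.random.default_rng(seed)
    brain = labels > 0
    t1w[brain] += rng.normal(0.0, spec.structural_noise_sd, int(brain.sum()))
    flair[brain] += rng.normal(0.0, spec.structural_noise_sd, int(brain.sum()))
    return t1w, flair


@dataclass
class Phantom:
    """All phantom arrays for one (spec, seed) realization."""

    spec: PhantomSpec
    labels: np.ndarray
    rois: dict[str, np.ndarray]
    dist_id: np.ndarray
    distributions: list[TensorDistribution]
    ground_truth: dict[str, np.ndarray]
    dwi: np.ndarray
    t1w: np.ndarray
    flair: np.ndarray

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


def build_phantom(
    spec: PhantomSpec, protocol: AcquisitionProtocol, noiseless: bool = False
) -> Phantom:
    """Run the full synthesis chain for one phantom realization."""
    labels, rois = build_labelmap(spec)
    dist_id, dists, gt = assign_microstructure(labels, spec)
    snr = None if noiseless else spec.snr
    dwi = generate_dwi(dist_id, dists, protocol, snr, seed=spec.seed)
    t1w, flair = generate_structural(labels, spec, seed=spec.seed + 1)
    return Phantom(spec, labels, rois, dist_id, dists, gt, dwi, t1w, flair)
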