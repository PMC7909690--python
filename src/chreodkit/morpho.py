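"""Geometric-morphometric preprocessing of 2-D landmark configurations.

Centroid size, generalized Procrustes superimposition (translation, scale
and rotation removed; reflections forbidden), and sliding of semilandmarks
along their outline curves to minimize thin-plate-spline bending energy
against the Procrustes mean.  The aligned shape coordinates (2k per
specimen) feed directly into the uni- and multivariate canalization
estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkSet",
    "ProcrustesResult",
    "centroid_size",
    "gpa",
    "slide_semilandmarks",
    "bending_energy_matrix",
    "bending_energy",
]


@dataclass
class LandmarkSet:
    """Specimens x landmarks x 2 coordinate array with metadata.

    ``curves`` declares sliding semilandmarks: each entry is an ordered list
    of landmark indices tracing one outline; interior points of a curve
    slide, the first and last act as fixed anchors.
    """

    coords: np.ndarray                       # (n, k, 2)
    landmark_names: list[str] | None = None
    specimen_ids: list[str] | None = None
    curves: list[list[int]] = field(default_factory=list)
    metadata: "object | None" = None         # e.g. DataFrame of individual/age/group

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must be (specimens, landmarks, 2)")
        if self.coords.shape[1] < 3:
            raise ValueError("need at least 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        k = self.coords.shape[1]
        for curve in self.curves:
            if len(curve) < 3:
                raise ValueError("each sliding curve needs at least 3 points")
            if any(not 0 <= i < k for i in curve):
                raise ValueError("curve index out of range")
        if self.specimen_ids is None:
            self.specimen_ids = [f"spec{i:04d}" for i in range(self.coords.shape[0])]

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def sliding_indices(self) -> list[int]:
        out: list[int] = []
        for curve in self.curves:
            out.extend(curve[1:-1])
        return out


@dataclass
class ProcrustesResult:
    """Output of generalized Procrustes superimposition."""

    aligned: np.ndarray          # (n, k, 2), centred, unit centroid size
    mean_shape: np.ndarray       # (k, 2)
    centroid_sizes: np.ndarray   # (n,), input units
    iterations: int
    convergence_gap: float

    def shape_coordinates(self) -> np.ndarray:
        """Flattened (n, 2k) shape-coordinate matrix (x1, y1, x2, y2, ...)."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of the summed squared landmark distances to the centroid.

    Invariant to translation and rotation, scales linearly with uniform
    scaling.  A value of zero (all landmarks coincident) is flagged.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 2:
        raise ValueError("config must be (k >= 2, dim)")
    centred = config - config.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs == 0:
        warnings.warn("degenerate configuration: all landmarks coincide", stacklevel=2)
    return cs


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det +1, no reflection) minimizing ||source @ R - target||."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def _canonical_orientation(X: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Rotation aligning the mean's principal axes with the coordinate axes.

    Removes the arbitrary overall orientation of a Procrustes solution so the
    output is invariant to how the input specimens were oriented.  The
    remaining 180-degree ambiguity is resolved by requiring the mean landmark
    farthest from the centroid along the major axis to have a positive
    coordinate.
    """
    _, _, Vt = np.linalg.svd(mean - mean.mean(axis=0), full_matrices=False)
    R = Vt.T
    if np.linalg.det(R) < 0:  # never reflect
        R[:, 1] = -R[:, 1]
    rotated_mean = mean @ R
    j = int(np.argmax(np.abs(rotated_mean[:, 0])))
    if rotated_mean[j, 0] < 0:
        R = -R  # 180-degree turn, det still +1
    return R


def gpa(
    landmark_set: LandmarkSet | np.ndarray,
    scale: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes analysis.

    Each specimen is centred, (optionally) scaled to unit centroid size and
    rotated to the current mean shape; the mean is re-estimated and
    re-normalized until it changes by less than ``tol`` (root summed squared
    coordinate change).  The first specimen seeds the mean.  Reflections are
    never used, and the converged solution is put into a canonical
    orientation (principal axes of the mean shape), making the output
    invariant to arbitrary similarity transforms of the input.
    """
    coords = landmark_set.coords if isinstance(landmark_set, LandmarkSet) else np.asarray(landmark_set, dtype=float)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("need at least 2 specimens of (k, 2) landmarks")
    n = coords.shape[0]

    centred0 = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(centred0**2, axis=(1, 2)))
    if np.any(sizes == 0):
        raise ValueError("zero-size (degenerate) configuration present")
    X = coords - coords.mean(axis=1, keepdims=True)
    if scale:
        X = X / sizes[:, None, None]

    mean = X[0].copy()
    gap = np.inf
    for it in range(1, max_iter + 1):
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        if scale:
            new_mean = new_mean / centroid_size(new_mean)
        gap = float(np.sqrt(np.sum((new_mean - mean) ** 2)))
        mean = new_mean
        if gap < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last gap {gap:.3g})"
        )
    R = _canonical_orientation(X.mean(axis=0), X.mean(axis=0))
    X = X @ R
    # the reported mean is the plain arithmetic mean of the aligned specimens
    # (the normalized mean above only steers the iteration)
    return ProcrustesResult(
        aligned=X, mean_shape=X.mean(axis=0), centroid_sizes=sizes,
        iterations=it, convergence_gap=gap,
    )


# ---------------------------------------------------------------------------
# thin-plate-spline bending energy and sliding


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of the thin-plate spline anchored at ``reference``.

    The k x k matrix B such that a TPS deformation mapping the reference
    configuration onto target coordinates (x, y) has bending energy
    x' B x + y' B y.  B is the upper-left block of the inverse of the
    bordered TPS system and annihilates affine transforms of the reference.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    diff = ref[:, None, :] - ref[None, :, :]
    r2 = np.sum(diff**2, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(r2 > 0, r2 * np.log(r2) / 2, 0.0)  # U(r) = r^2 log r
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        L_inv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular bending-energy system (degenerate reference)") from exc
    B = L_inv[:k, :k]
    return (B + B.T) / 2


def bending_energy(reference: np.ndarray, target: np.ndarray) -> float:
    """Bending energy of the TPS deformation from ``reference`` to ``target``."""
    B = bending_energy_matrix(reference)
    tgt = np.asarray(target, dtype=float)
    return float(np.einsum("id,ij,jd->", tgt, B, tgt))


def _tangents(config: np.ndarray, curve: list[int]) -> dict[int, np.ndarray]:
    """Unit chord tangents (next minus previous neighbour) for interior curve points."""
    out = {}
    for pos in range(1, len(curve) - 1):
        i_prev, i, i_next = curve[pos - 1], curve[pos], curve[pos + 1]
        t = config[i_next] - config[i_prev]
        norm = np.linalg.norm(t)
        if norm == 0:
            raise ValueError(f"degenerate curve around landmark {i}")
        out[i] = t / norm
    return out


def _project_to_polyline(point: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Closest point on a piecewise-linear curve."""
    best, best_d = polyline[0], np.inf
    for a, b in zip(polyline[:-1], polyline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        s = 0.0 if denom == 0 else float(np.clip((point - a) @ ab / denom, 0.0, 1.0))
        cand = a + s * ab
        dist = float(np.sum((point - cand) ** 2))
        if dist < best_d:
            best, best_d = cand, dist
    return best


def _slide_one(
    config: np.ndarray,
    mean: np.ndarray,
    B: np.ndarray,
    curves: list[list[int]],
    original: np.ndarray,
) -> np.ndarray:
    """One linearized sliding step for a single specimen.

    Semilandmarks move along finite-difference tangents to minimize the
    bending energy relative to the mean (a quadratic program solved
    exactly), then are projected back onto the specimen's original outline
    polyline so they never drift off the curve.
    """
    sliders: list[int] = []
    tangents: list[np.ndarray] = []
    for curve in curves:
        tans = _tangents(config, curve)
        for i, u in tans.items():
            sliders.append(i)
            tangents.append(u)
    if not sliders:
        return config

    k = config.shape[0]
    m = len(sliders)
    # y = vec(config - mean) stacked per coordinate dim; Q = blockdiag(B, B)
    y0 = (config - mean).T.reshape(-1)           # (2k,): all x then all y
    M = np.zeros((2 * k, m))
    for j, (i, u) in enumerate(zip(sliders, tangents)):
        M[i, j] = u[0]
        M[k + i, j] = u[1]
    Q = np.zeros((2 * k, 2 * k))
    Q[:k, :k] = B
    Q[k:, k:] = B
    A = M.T @ Q @ M
    b = -M.T @ Q @ y0
    try:
        t = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        t = np.linalg.lstsq(A, b, rcond=None)[0]

    slid = config.copy()
    for j, i in enumerate(sliders):
        slid[i] = config[i] + t[j] * tangents[j]
    # re-interpolate onto the original outline
    for curve in curves:
        polyline = original[curve]
        for pos in range(1, len(curve) - 1):
            i = curve[pos]
            slid[i] = _project_to_polyline(slid[i], polyline)
    return slid


def slide_semilandmarks(
    landmark_set: LandmarkSet,
    tol: float = 1e-8,
    max_iter: int = 100,
    scale: bool = True,
) -> tuple[LandmarkSet, ProcrustesResult]:
    """Slide semilandmarks to minimize bending energy around the Procrustes mean.

    Alternates (a) a linearized sliding step of every specimen's
    semilandmarks along their outline tangents against the current mean and
    (b) re-superimposition by GPA, until the mean shape stabilizes.  Total
    bending energy against the mean is monitored and never allowed to
    increase across outer iterations: if a step would raise it (e.g. through
    the projection back onto the outline), the previous state is kept and
    iteration stops.

    Returns the slid landmark set (aligned coordinates) together with the
    final Procrustes result.  With no declared curves this reduces to plain
    GPA.
    """
    proc = gpa(landmark_set, scale=scale, tol=tol, max_iter=max_iter)
    if not landmark_set.curves:
        slid_set = LandmarkSet(
            coords=proc.aligned,
            landmark_names=landmark_set.landmark_names,
            specimen_ids=landmark_set.specimen_ids,
            curves=[],
            metadata=landmark_set.metadata,
        )
        return slid_set, proc

    sizes = proc.centroid_sizes          # original-unit sizes, kept through sliding
    X = proc.aligned.copy()
    originals = X.copy()                 # outlines to re-interpolate along
    mean = proc.mean_shape
    B = bending_energy_matrix(mean)
    energy = sum(float(np.einsum("id,ij,jd->", x - mean, B, x - mean)) for x in X)

    for _ in range(max_iter):
        candidate = np.array(
            [_slide_one(x, mean, B, landmark_set.curves, orig)
             for x, orig in zip(X, originals)]
        )
        cand_proc = gpa(candidate, scale=scale, tol=tol, max_iter=max_iter)
        cand_mean = cand_proc.mean_shape
        cand_B = bending_energy_matrix(cand_mean)
        cand_energy = sum(
            float(np.einsum("id,ij,jd->", x - cand_mean, cand_B, x - cand_mean))
            for x in cand_proc.aligned
        )
        if cand_energy > energy - tol:
            if cand_energy <= energy:
                X, mean, proc, energy = cand_proc.aligned, cand_mean, cand_proc, cand_energy
            break
        X, mean, B, proc, energy = (
            cand_proc.aligned, cand_mean, cand_B, cand_proc, cand_energy
        )

    slid_set = LandmarkSet(
        coords=X,
        landmark_names=landmark_set.landmark_names,
        specimen_ids=landmark_set.specimen_ids,
        curves=landmark_set.curves,
        metadata=landmark_set.metadata,
    )
    final = ProcrustesResult(
        aligned=X, mean_shape=mean, centroid_sizes=sizes,
        iterations=proc.iterations, convergence_gap=proc.convergence_gap,
    )
    return slid_set, final
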