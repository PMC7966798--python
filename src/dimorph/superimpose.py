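"""Generalized Procrustes superimposition and related shape operations.

Implements partial Procrustes superimposition (translation, unit-centroid-size
scaling, optimal rotation to an iterated consensus), thin-plate-spline
bending-energy semilandmark sliding, bilateral symmetrization by
reflect-relabel-align-average, outlier screening, and digitization
repeatability from Procrustes ANOVA.

Shape vectors are stored flat as ``(x1, y1, x2, y2, ...)`` in Procrustes
units (dimensionless, unit centroid size after the scaling step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import LandmarkTemplate, RawDataset, ValidationError

__all__ = [
    "AlignedDataset",
    "RepeatabilityResult",
    "centroid_size",
    "center_configuration",
    "optimal_rotation",
    "gpa",
    "bending_energy_matrix",
    "bending_energy",
    "slide_semilandmarks",
    "symmetrize",
    "procrustes_distance",
    "detect_outliers",
    "repeatability",
]


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid.

    The size measure removed by the Procrustes scaling step.  A single point,
    or coincident points, give 0; downstream scaling rejects 0.
    """
    pts = np.asarray(points, dtype=float)
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def center_configuration(points: np.ndarray) -> np.ndarray:
    """Translate a k x 2 configuration so its centroid is at the origin."""
    pts = np.asarray(points, dtype=float)
    return pts - pts.mean(axis=0)


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper 2x2 rotation R minimizing ||A @ R - B||_F (reflections barred).

    Both configurations must be centered and have the same number of
    landmarks.  A degenerate (rank-0) input yields the identity with a
    warning.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    H = A.T @ B
    if not np.any(H):
        warnings.warn("degenerate configuration: identity rotation returned")
        return np.eye(2)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, d]) @ Vt


@dataclass
class AlignedDataset:
    """Superimposed shape data in a common Procrustes frame.

    Attributes
    ----------
    shapes : (n, 2k) ndarray
        Flattened aligned coordinates, order ``x1, y1, x2, y2, ...``.
    centroid_sizes : (n,) ndarray
        Original centroid sizes removed by scaling.
    consensus : (2k,) ndarray
        Mean shape of the aligned rows.
    meta : DataFrame
        Per-row metadata (id, sex, population, covariates).
    template : LandmarkTemplate
    slid, symmetrized : bool
        Provenance flags.
    residualized_on : tuple of str
        Covariates partialled out of the shapes, in order of application.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    meta: pd.DataFrame
    template: LandmarkTemplate
    slid: bool = False
    symmetrized: bool = False
    residualized_on: tuple[str, ...] = ()
    gpa_iterations: int = 0
    energy_history: tuple[float, ...] = field(default=(), repr=False)

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1] // 2

    def points(self) -> np.ndarray:
        """Aligned coordinates as an (n, k, 2) array (a view-copy)."""
        return self.shapes.reshape(self.n, self.k, 2)

    def consensus_points(self) -> np.ndarray:
        return self.consensus.reshape(self.k, 2)

    def provenance(self) -> dict:
        return {
            "slid": self.slid,
            "symmetrized": self.symmetrized,
            "residualized_on": list(self.residualized_on),
            "gpa_iterations": self.gpa_iterations,
        }

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV layout: id + 2k coordinate columns + centroid size."""
        cols = {}
        for j in range(self.k):
            cols[f"x{j + 1}"] = self.shapes[:, 2 * j]
            cols[f"y{j + 1}"] = self.shapes[:, 2 * j + 1]
        df = pd.DataFrame(cols)
        df.insert(0, "id", self.meta["id"].to_numpy())
        df["centroid_size"] = self.centroid_sizes
        return df


def _project_to_tangent(flat: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent plane at the consensus.

    Removes the component of each deviation from the consensus that lies
    along the consensus direction, linearizing shape space locally.
    """
    c_hat = consensus / np.linalg.norm(consensus)
    dev = flat - consensus
    return flat - np.outer(dev @ c_hat, c_hat)


def gpa(
    dataset: RawDataset | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    project_to_tangent: bool = True,
    template: LandmarkTemplate | None = None,
    meta: pd.DataFrame | None = None,
) -> AlignedDataset:
    """Generalized Procrustes superimposition.

    Each configuration is centred, scaled to unit centroid size, and
    iteratively rotated to the running consensus until the root-mean-square
    change of the consensus falls below ``tol``.  With
    ``project_to_tangent=True`` (the dominant morphometrics convention) the
    aligned rows are orthogonally projected onto the tangent plane at the
    consensus after convergence, so downstream linear operations act in an
    approximately linear space.

    Parameters
    ----------
    dataset
        A :class:`~dimorph.io.RawDataset`, or an (n, k, 2) array (then
        ``template`` and optionally ``meta`` must be given).
    """
    if isinstance(dataset, RawDataset):
        pts = dataset.points_array()
        template = dataset.template
        meta = dataset.meta_frame()
    else:
        pts = np.asarray(dataset, dtype=float)
        if template is None:
            template = LandmarkTemplate(n_landmarks=pts.shape[1])
        if meta is None:
            meta = pd.DataFrame({"id": [str(i) for i in range(pts.shape[0])]})
    n, k, _ = pts.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if k < 3:
        raise ValueError("GPA needs k >= 3 landmarks")

    sizes = np.array([centroid_size(p) for p in pts])
    if np.any(sizes == 0):
        bad = meta["id"].to_numpy()[sizes == 0].tolist()
        raise ValueError(f"zero centroid size for ids: {bad}")
    aligned = (pts - pts.mean(axis=1, keepdims=True)) / sizes[:, None, None]

    consensus = aligned[0].copy()
    consensus /= np.linalg.norm(consensus)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus /= np.linalg.norm(new_consensus)
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus RMS change {change:.3e})"
        )

    flat = aligned.reshape(n, 2 * k)
    consensus_flat = aligned.mean(axis=0).reshape(2 * k)
    if project_to_tangent:
        flat = _project_to_tangent(flat, consensus_flat)
        consensus_flat = flat.mean(axis=0)
    return AlignedDataset(
        shapes=flat,
        centroid_sizes=sizes,
        consensus=consensus_flat,
        meta=meta.reset_index(drop=True),
        template=template,
        gpa_iterations=iterations,
    )


# ---------------------------------------------------------------------------
# Thin-plate-spline bending energy and semilandmark sliding
# ---------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """2D TPS radial kernel U(r) = r^2 log r^2, with U(0) = 0."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy quadratic form of the thin-plate spline at ``reference``.

    Returns the upper-left k x k block of the inverse of the TPS system
    matrix L = [[K, Q], [Q^T, 0]], where K holds the radial-kernel values and
    Q = [1 | x | y].  The result is symmetric positive semi-definite and
    annihilates affine displacement fields; x- and y-displacements d satisfy
    energy = d_x^T B d_x + d_y^T B d_y.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    diff = ref[:, None, :] - ref[None, :, :]
    r2 = np.sum(diff**2, axis=-1)
    dup = np.argwhere((r2 == 0) & ~np.eye(k, dtype=bool))
    if dup.size:
        i, j = dup[0]
        raise ValueError(
            f"duplicate landmarks {i} and {j}: TPS kernel is singular"
        )
    K = _tps_kernel(r2)
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.inv(L)
    B = Linv[:k, :k]
    return (B + B.T) / 2


def bending_energy(B: np.ndarray, displacement: np.ndarray) -> float:
    """Energy of a k x 2 displacement field under the quadratic form ``B``."""
    d = np.asarray(displacement, dtype=float)
    return float(d[:, 0] @ B @ d[:, 0] + d[:, 1] @ B @ d[:, 1])


def _slide_pass(
    pts: np.ndarray,
    consensus_pts: np.ndarray,
    template: LandmarkTemplate,
    B: np.ndarray,
) -> np.ndarray:
    """One sliding pass: jointly optimal tangent displacements per specimen."""
    slm = list(template.semilandmark_indices)
    m = len(slm)
    out = pts.copy()
    for i in range(pts.shape[0]):
        p = pts[i]
        # unit tangent at each semilandmark from its flanking curve points
        T = np.empty((m, 2))
        for j, s in enumerate(slm):
            a, b = template.neighbours_of(s)
            t = p[b] - p[a]
            norm = np.linalg.norm(t)
            if norm == 0:
                raise ValueError(
                    f"coincident flanking points for semilandmark {s}"
                )
            T[j] = t / norm
        dev = p - consensus_pts
        # minimize (dx + Sx u)' B (dx + Sx u) + (dy + Sy u)' B (dy + Sy u)
        Sx = np.zeros((pts.shape[1], m))
        Sy = np.zeros((pts.shape[1], m))
        Sx[slm, np.arange(m)] = T[:, 0]
        Sy[slm, np.arange(m)] = T[:, 1]
        A = Sx.T @ B @ Sx + Sy.T @ B @ Sy
        rhs = -(Sx.T @ B @ dev[:, 0] + Sy.T @ B @ dev[:, 1])
        u = np.linalg.lstsq(A, rhs, rcond=None)[0]
        out[i, slm, 0] += T[:, 0] * u
        out[i, slm, 1] += T[:, 1] * u
    return out


def slide_semilandmarks(
    aligned: AlignedDataset,
    template: LandmarkTemplate | None = None,
    iterations: int = 3,
) -> AlignedDataset:
    """Slide semilandmarks along their curve tangents to minimize bending energy.

    For each specimen, all semilandmarks are displaced jointly along tangent
    directions (estimated from the flanking curve points) by the amounts
    minimizing the thin-plate-spline bending energy of the displacement from
    the consensus.  GPA is re-run after every pass and the consensus updated.
    The recorded ``energy_history`` holds the total bending energy at the
    start of each pass and after the final pass, measured against the
    consensus current at that moment.
    """
    template = template or aligned.template
    if not template.semilandmark_indices:
        raise ValidationError("template declares no semilandmarks")
    for s in template.semilandmark_indices:
        template.neighbours_of(s)  # raises if a semilandmark lacks neighbours

    current = aligned
    history: list[float] = []
    for it in range(iterations):
        cons = current.consensus_points()
        B = bending_energy_matrix(cons)
        pts = current.points()
        history.append(
            sum(bending_energy(B, p - cons) for p in pts)
        )
        slid_pts = _slide_pass(pts, cons, current.template, B)
        if it == iterations - 1:
            # final energy against the consensus the pass minimized toward
            history.append(
                sum(bending_energy(B, p - cons) for p in slid_pts)
            )
        refit = gpa(
            slid_pts,
            template=current.template,
            meta=current.meta,
            project_to_tangent=False,
        )
        current = replace(
            current,
            shapes=refit.shapes,
            consensus=refit.consensus,
            gpa_iterations=refit.gpa_iterations,
        )
    return replace(current, slid=True, energy_history=tuple(history))


# ---------------------------------------------------------------------------
# Bilateral symmetrization
# ---------------------------------------------------------------------------

def _mirror_relabel(pts: np.ndarray, template: LandmarkTemplate) -> np.ndarray:
    """Negate x and swap each bilateral pair's labels (the operator M)."""
    out = pts.copy()
    out[:, 0] *= -1
    for a, b in template.bilateral_pairs:
        out[[a, b]] = out[[b, a]]
    return out


def _rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def symmetrize(
    aligned: AlignedDataset,
    template: LandmarkTemplate | None = None,
) -> AlignedDataset:
    """Average each configuration with its aligned mirror image.

    For each specimen A (centred): build M(A) by negating x and relabelling
    bilateral pairs, rotate it optimally onto A, and average.  The average B
    satisfies M(B) = R(-gamma) B exactly (gamma the alignment angle), i.e. B
    is exactly symmetric about an axis at angle gamma/2; rotating B by
    -gamma/2 places that axis on the y-axis, so the output is an exact fixed
    point of M.  Rows are re-scaled to unit centroid size (averaging shrinks
    size slightly) and the consensus is recomputed.

    Idempotent: symmetrizing an already-symmetric dataset returns it
    unchanged to machine precision.
    """
    template = template or aligned.template
    if not template.bilateral_pairs:
        raise ValidationError(
            "template declares no bilateral pairs: cannot symmetrize"
        )
    # validation: bilateral_pairs + midline must cover everything
    covered = {i for p in template.bilateral_pairs for i in p}
    covered |= set(template.midline_indices)
    if covered != set(range(template.n_landmarks)):
        raise ValidationError(
            "unpaired non-midline landmarks: "
            f"{sorted(set(range(template.n_landmarks)) - covered)}"
        )
    pts = aligned.points()
    out = np.empty_like(pts)
    for i in range(pts.shape[0]):
        A = pts[i] - pts[i].mean(axis=0)
        MA = _mirror_relabel(A, template)
        R = optimal_rotation(MA, A)
        gamma = np.arctan2(R[1, 0], R[0, 0])
        B = (A + MA @ R) / 2
        # M(B) = B R^{-1} exactly; right-multiplying by the half-angle
        # inverse rotation makes B an exact fixed point of M.
        B = B @ _rotation_matrix(-gamma / 2)
        cs = centroid_size(B)
        if cs == 0:
            raise ValueError(f"degenerate symmetrized shape at row {i}")
        out[i] = B / cs
    flat = out.reshape(aligned.n, -1)
    return replace(
        aligned,
        shapes=flat,
        consensus=flat.mean(axis=0),
        symmetrized=True,
    )


# ---------------------------------------------------------------------------
# Distances, outliers, repeatability
# ---------------------------------------------------------------------------

def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two flat shape vectors in a common frame."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def detect_outliers(aligned: AlignedDataset, multiplier: float = 1.5) -> list[str]:
    """Flag specimens unusually far from the consensus.

    A specimen is flagged when its Procrustes distance to the consensus
    exceeds Q3 + multiplier * IQR of the distance distribution — the
    screening step for digitizing errors.
    """
    d = np.linalg.norm(aligned.shapes - aligned.consensus, axis=1)
    q1, q3 = np.percentile(d, [25, 75])
    cutoff = q3 + multiplier * (q3 - q1)
    ids = aligned.meta["id"].to_numpy()
    return [str(i) for i in ids[d > cutoff]]


@dataclass
class RepeatabilityResult:
    """Digitization repeatability from Procrustes ANOVA.

    ``repeatability`` is the intraclass correlation of the individual effect:
    sigma2_between / (sigma2_between + sigma2_within), with
    sigma2_between = (MS_between - MS_within) / r clipped at 0.
    ``measurement_error`` = 1 - repeatability.
    """

    repeatability: float
    measurement_error: float
    variance_components: tuple[float, float]
    ms_between: float
    ms_within: float
    n_individuals: int
    n_replicates: int


def repeatability(
    aligned: AlignedDataset,
    individual: str | np.ndarray = "individual",
) -> RepeatabilityResult:
    """Measurement repeatability of replicate digitizations.

    The jointly superimposed dataset must contain >= 2 replicate rows for
    each of >= 2 individuals (grouping given by the ``individual`` metadata
    column or an explicit label array).  The total Procrustes sum of squares
    is partitioned into between- and within-individual components summed
    over all coordinates; repeatability is the classical ICC from the ANOVA
    mean squares.  Identical replicates give exactly 1.
    """
    if isinstance(individual, str):
        labels = aligned.meta[individual].to_numpy()
    else:
        labels = np.asarray(individual)
    X = aligned.shapes
    uniq, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("repeatability needs >= 2 individuals")
    if np.any(counts < 2):
        bad = uniq[counts < 2].tolist()
        raise ValueError(f"individuals with < 2 replicates: {bad}")
    grand = X.mean(axis=0)
    group_means = np.zeros((len(uniq), X.shape[1]))
    np.add.at(group_means, inv, X)
    group_means /= counts[:, None]
    ss_between = float(np.sum(counts[:, None] * (group_means - grand) ** 2))
    ss_within = float(np.sum((X - group_means[inv]) ** 2))
    n = len(uniq)
    N = X.shape[0]
    r = N / n  # replicates per individual (mean if unbalanced)
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (N - n)
    sigma2_b = max((ms_between - ms_within) / r, 0.0)
    sigma2_w = ms_within
    if sigma2_b + sigma2_w == 0:
        rep = 1.0  # replicates bit-identical and individuals identical
    else:
        rep = sigma2_b / (sigma2_b + sigma2_w)
    return RepeatabilityResult(
        repeatability=rep,
        measurement_error=1.0 - rep,
        variance_components=(sigma2_b, sigma2_w),
        ms_between=ms_between,
        ms_within=ms_within,
        n_individuals=n,
        n_replicates=int(round(r)),
    )
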