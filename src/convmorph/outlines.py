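"""Elliptical Fourier analysis (EFA) of closed 2-D outlines.

A closed outline (pronotum or elytron silhouette, given as an ordered list of
coordinates) is decomposed into harmonic ellipse coefficients
``(a_n, b_n, c_n, d_n)`` following the Kuhl & Giardina closed-contour
formulas, using a piecewise-linear parameterization by cumulative chord
length.  Normalized coefficients are invariant to rotation, scale,
translation and starting point — but *not* to reflection, which carries
biological sidedness and must be handled upstream.  Flattened coefficient
vectors are projected to principal-component "shape scores" for downstream
comparative analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Outline",
    "EFACoefficients",
    "ShapeScores",
    "efa_decompose",
    "efa_normalize",
    "efa_reconstruct",
    "choose_harmonics",
    "shape_pca",
    "outline_from_mask",
]


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class Outline:
    """Closed polygonal outline, normalized to counter-clockwise orientation.

    Consecutive duplicate points are dropped on ingest; at least 3
    non-collinear points are required.
    """

    points: np.ndarray
    label: str = ""
    structure: str = "pronotum"
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        # drop consecutive duplicates (including a repeated closing point)
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-300, axis=1)
        pts = pts[keep]
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("outline needs >= 3 distinct points")
        area = _signed_area(pts)
        if abs(area) < 1e-300:
            raise ValueError("degenerate (collinear) outline")
        if area < 0:  # enforce CCW
            pts = pts[::-1]
        self.points = pts

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class EFACoefficients:
    """Harmonic coefficients; ``harmonics[n-1] = (a_n, b_n, c_n, d_n)``.

    ``A0, C0`` are the arclength centroid of the curve.  After
    normalization the first-harmonic semi-major axis is 1, ``a_1 > 0`` and
    ``b_1 = 0``.
    """

    A0: float
    C0: float
    harmonics: np.ndarray
    normalized: bool = False
    label: str = ""
    structure: str = ""

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    def power(self) -> np.ndarray:
        """Per-harmonic power (a^2 + b^2 + c^2 + d^2) / 2."""
        return 0.5 * np.sum(self.harmonics**2, axis=1)

    def flatten(self) -> np.ndarray:
        return self.harmonics.ravel()


@dataclass
class ShapeScores:
    labels: list
    scores: np.ndarray
    explained_variance: np.ndarray
    components: np.ndarray = field(default=None)  # type: ignore[assignment]
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Decomposition / reconstruction
# ---------------------------------------------------------------------------

def efa_decompose(outline: Outline, n_harmonics: int) -> EFACoefficients:
    """Kuhl–Giardina elliptical Fourier coefficients of a closed outline.

    The outline is parameterized piecewise-linearly by cumulative chord
    length.  ``n_harmonics`` must lie in ``[1, n_points // 2]`` (the Nyquist
    bound for the polygon's vertices).
    """
    pts = outline.points
    K = len(pts)
    if not 1 <= n_harmonics <= K // 2:
        raise ValueError(f"n_harmonics must be in [1, {K // 2}]")
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)  # (K, 2) segment steps
    dt = np.hypot(d[:, 0], d[:, 1])
    if not np.all(dt > 0):  # pragma: no cover - duplicates dropped on ingest
        raise ValueError("zero-length segment")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise ValueError("zero perimeter")
    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    phi = 2.0 * np.pi * t / T  # (K+1,)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (N, K)
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * (n.ravel() ** 2) * np.pi**2)  # (N,)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    dd = const * (dsin @ vy)
    # centroid of the piecewise-linear curve under arclength measure
    mid = 0.5 * (pts + np.vstack([pts[1:], pts[:1]]))
    A0 = float(np.dot(mid[:, 0], dt) / T)
    C0 = float(np.dot(mid[:, 1], dt) / T)
    return EFACoefficients(
        A0=A0,
        C0=C0,
        harmonics=np.column_stack([a, b, c, dd]),
        normalized=False,
        label=outline.label,
        structure=outline.structure,
    )


def efa_reconstruct(coef: EFACoefficients, n_points: int) -> Outline:
    """Sample the truncated Fourier curve back into a closed outline."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, coef.n_harmonics + 1)[:, None]
    ang = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(ang), np.sin(ang)
    a, b, c, d = coef.harmonics.T
    x = coef.A0 + a @ cos + b @ sin
    y = coef.C0 + c @ cos + d @ sin
    return Outline(
        np.column_stack([x, y]),
        label=coef.label,
        structure=coef.structure or "pronotum",
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _rotate_startpoint(h: np.ndarray, theta: float) -> np.ndarray:
    """Shift the curve's starting point: harmonic n rotates by n*theta."""
    out = np.empty_like(h)
    for i in range(len(h)):
        ang = (i + 1) * theta
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        m = h[i].reshape(2, 2) @ rot
        out[i] = m.ravel()
    return out


def _candidate(h: np.ndarray, theta: float) -> tuple[np.ndarray, float]:
    hs = _rotate_startpoint(h, theta)
    a1, b1, c1, d1 = hs[0]
    psi = np.arctan2(c1, a1)
    E = float(np.hypot(a1, c1))
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    out = np.array([(rot @ m.reshape(2, 2)).ravel() for m in hs])
    return out / E, E


def efa_normalize(coef: EFACoefficients) -> EFACoefficients:
    """Normalize coefficients for rotation, scale, translation and start point.

    The starting point is moved to the first-harmonic semi-major axis, the
    shape is rotated so that axis is horizontal, and scale is fixed so the
    semi-major axis is 1; translation terms are zeroed.  Among the residual
    axis/endpoint candidates the lexicographically largest coefficient vector
    is chosen, which makes the result a deterministic canonical form.
    Reflection is deliberately *not* removed.
    """
    h = coef.harmonics
    a1, b1, c1, d1 = h[0]
    if abs(a1 * d1 - b1 * c1) < 1e-14:
        raise ValueError("degenerate first harmonic (a1*d1 - b1*c1 = 0)")
    theta0 = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
    )
    cands = [_candidate(h, theta0 + k * np.pi / 2.0) for k in range(4)]
    Emax = max(E for _, E in cands)
    best = None
    for out, E in cands:
        if E < Emax * (1.0 - 1e-9):
            continue  # started on the minor axis
        key = np.round(out.ravel(), 9)
        if best is None or tuple(key) > tuple(np.round(best.ravel(), 9)):
            best = out
    return replace(coef, A0=0.0, C0=0.0, harmonics=best, normalized=True)


# ---------------------------------------------------------------------------
# Harmonic selection, PCA
# ---------------------------------------------------------------------------

def choose_harmonics(outlines: list[Outline], power_threshold: float = 0.99) -> int:
    """Smallest harmonic count whose mean cumulative power fraction reaches
    ``power_threshold`` across the given outlines."""
    if not outlines:
        raise ValueError("empty outline list")
    if not 0.0 < power_threshold <= 1.0:
        raise ValueError("power_threshold must be in (0, 1]")
    n_max = min(len(o.points) // 2 for o in outlines)
    if power_threshold >= 1.0:
        return n_max
    powers = np.zeros(n_max)
    for o in outlines:
        powers += efa_decompose(o, n_max).power()
    powers /= len(outlines)
    frac = np.cumsum(powers) / powers.sum()
    idx = np.nonzero(frac >= power_threshold - 1e-12)[0]
    return int(idx[0]) + 1 if len(idx) else n_max


def shape_pca(coefs: list[EFACoefficients], center: bool = True) -> ShapeScores:
    """PCA of flattened coefficient vectors -> orthogonal shape scores."""
    if len(coefs) < 2:
        raise ValueError("need >= 2 specimens for shape PCA")
    lengths = {c.n_harmonics for c in coefs}
    if len(lengths) != 1:
        raise ValueError("coefficient vectors differ in harmonic count")
    X = np.array([c.flatten() for c in coefs])
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / max(len(X) - 1, 1)
    total = eig.sum()
    frac = eig / total if total > 0 else eig
    return ShapeScores(
        labels=[c.label for c in coefs],
        scores=U * s,
        explained_variance=frac,
        components=Vt,
        mean=mean,
    )


def outline_from_mask(mask: np.ndarray, label: str = "", structure: str = "pronotum") -> Outline:
    """Convenience: trace a binary mask's longest iso-contour into an Outline
    (CCW-normalized).  Coordinate lists, not rasters, are the primary input."""
    from skimage import measure

    contours = measure.find_contours(np.asarray(mask, dtype=float), 0.5)
    if not contours:
        raise ValueError("no contour found in mask")
    c = max(contours, key=len)
    return Outline(c[:, ::-1], label=label, structure=structure)  # (row,col)->(x,y)
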