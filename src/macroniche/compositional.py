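"""Aitchison-geometry engine for D-part compositions.

A composition is a vector of non-negative parts carrying only relative
information, constrained by closure to sum to one. All statistics here live
in log-ratio space: the centred log-ratio (clr) maps the simplex to the
hyperplane of zero-sum vectors, the isometric log-ratio (ilr) to an
unconstrained (D-1)-dimensional Euclidean space in which ordinary
multivariate statistics are valid. Descriptive summaries follow the
compositional canon: closed geometric mean as the centre, the variation
matrix (variances of pairwise log-ratios) as the dispersion summary, and
principal components computed on clr coordinates (acomp PCA).

The study motivating this package works with D=3 (protein, carbohydrate,
lipid energy fractions of omnivore diets), but every operation is written
for general D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "PCL",
    "Composition",
    "CompositionSet",
    "CompositionSummary",
    "PcaResult",
    "SimplexRegion",
    "closure",
    "replace_zeros",
    "clr",
    "clr_inv",
    "ilr",
    "ilr_inv",
    "helmert_basis",
    "aitchison_distance",
    "close_rows",
    "ilr_rows",
    "ilr_inv_rows",
    "summarize",
    "geometric_mean_composition",
    "mean_ratio_matrix",
    "variation_matrix",
    "metric_variance",
    "acomp_pca",
    "sigma_region",
    "confidence_region",
]

#: Part labels of the study's macronutrient simplex: protein, carbohydrate,
#: lipid, as fractions of metabolizable energy.
PCL = ("P", "C", "L")

_ATOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """A point on the unit simplex with ordered, named parts."""

    parts: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "parts", tuple(self.parts))
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(self.parts) != v.shape[-1]:
            raise ValueError("parts and values length mismatch")
        if v.ndim != 1:
            raise ValueError("Composition holds a single vector")
        if np.any(v < 0):
            raise ValueError("negative part in composition")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"composition does not sum to 1 (sum={v.sum()!r}); apply closure()"
            )

    @property
    def D(self) -> int:
        return len(self.parts)

    def __getitem__(self, part: str) -> float:
        return float(self.values[self.parts.index(part)])

    def asdict(self) -> dict[str, float]:
        return dict(zip(self.parts, map(float, self.values)))

    def __eq__(self, other) -> bool:  # value equality, used heavily in tests
        return (
            isinstance(other, Composition)
            and self.parts == other.parts
            and np.allclose(self.values, other.values, atol=_ATOL)
        )


@dataclass
class CompositionSet:
    """N compositions sharing one label set, with optional row metadata.

    Metadata columns used by the pipeline: ``population_id``, ``season``
    (spring|summer|autumn|winter) and ``subsidy`` (natural|anthropogenic).
    """

    parts: tuple[str, ...]
    values: np.ndarray  # N x D
    metadata: dict[str, list] = field(default_factory=dict)

    def __post_init__(self):
        self.parts = tuple(self.parts)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 1:
            raise ValueError("CompositionSet requires N >= 1 rows")
        if self.values.shape[1] != len(self.parts):
            raise ValueError("row width does not match part labels")
        sums = self.values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9) or np.any(self.values < 0):
            raise ValueError("rows must be closed compositions; apply closure()")
        for key, col in self.metadata.items():
            if len(col) != len(self):
                raise ValueError(f"metadata column {key!r} has wrong length")

    def __len__(self) -> int:
        return self.values.shape[0]

    def __iter__(self):
        for row in self.values:
            yield Composition(self.parts, row)

    def row(self, i: int) -> Composition:
        return Composition(self.parts, self.values[i])

    def select(self, mask) -> "CompositionSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        meta = {k: [v[i] for i in idx] for k, v in self.metadata.items()}
        return CompositionSet(self.parts, self.values[idx], meta)

    @classmethod
    def from_compositions(
        cls, rows: Sequence[Composition], metadata: dict | None = None
    ) -> "CompositionSet":
        if not rows:
            raise ValueError("empty composition set")
        parts = rows[0].parts
        if any(r.parts != parts for r in rows):
            raise ValueError("all rows must share identical part labels")
        return cls(parts, np.vstack([r.values for r in rows]), metadata or {})


@dataclass(frozen=True)
class CompositionSummary:
    """Descriptive statistics of a composition set in Aitchison geometry."""

    geometric_mean: Composition
    mean_ratio_matrix: np.ndarray
    variation_matrix: np.ndarray
    metric_variance: float
    n: int


@dataclass(frozen=True)
class PcaResult:
    """Principal components of clr coordinates (acomp geometry).

    ``components`` are (D-1) orthonormal zero-sum clr directions, rows sorted
    by decreasing explained variance; ``biplot_rays`` are the clr loadings
    ``sqrt(lambda_k) * v_k`` arranged per part (D x (D-1)), whose pairwise
    link length equals the SD of the corresponding pairwise log-ratio when
    all D-1 components are retained.
    """

    center: Composition
    components: np.ndarray
    explained_variance: np.ndarray
    scores: np.ndarray
    biplot_rays: np.ndarray

    @property
    def explained_shares(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


@dataclass(frozen=True)
class SimplexRegion:
    """A closed elliptical region on the simplex.

    ``kind`` is ``"sigma"`` (spread of individual compositions, level = the
    Mahalanobis multiplier k) or ``"confidence"`` (region for the mean,
    level = coverage). The boundary is a closed polyline of compositions;
    the generating ellipse (ilr centre, shape matrix, squared radius) is kept
    so that membership can be tested exactly.
    """

    kind: str
    level: float
    boundary: CompositionSet
    ilr_center: np.ndarray
    ilr_shape: np.ndarray
    radius2: float
    basis: np.ndarray

    def contains(self, c: Composition) -> bool:
        d = ilr(c, self.basis) - self.ilr_center
        return float(d @ np.linalg.solve(self.ilr_shape, d)) <= self.radius2


# ---------------------------------------------------------------------------
# transforms


def closure(raw, parts: Sequence[str] = PCL) -> Composition:
    """Normalize a non-negative vector to unit sum, preserving labels."""
    v = np.asarray(raw, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative entry; compositions are non-negative")
    s = v.sum()
    if s <= 0:
        raise ValueError("degenerate composition: all parts zero")
    return Composition(tuple(parts), v / s)


def close_rows(raw: np.ndarray) -> np.ndarray:
    """Row-wise closure of a matrix of non-negative vectors."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    s = raw.sum(axis=1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("degenerate composition: all parts zero")
    return raw / s


def replace_zeros(c: Composition, delta: float = 1e-3) -> Composition:
    """Multiplicative zero replacement.

    Zero parts are set to ``delta`` and the non-zero parts are shrunk by the
    factor ``1 - z*delta`` (z = number of zeros), so their ratios are
    untouched — the defining property of multiplicative replacement.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    v = c.values
    zero = v == 0
    z = int(zero.sum())
    if z == 0:
        return c
    nz_min = v[~zero].min()
    if delta >= nz_min / c.D:
        raise ValueError(
            f"delta={delta} too large for smallest nonzero part {nz_min}"
        )
    out = np.where(zero, delta, v * (1.0 - z * delta))
    warnings.warn(
        f"replaced {z} zero part(s) with delta={delta}", stacklevel=2
    )
    return closure(out, c.parts)


def _clr_rows(x: np.ndarray) -> np.ndarray:
    if np.any(x <= 0):
        raise ValueError(
            "zero or negative part; log-ratios need strictly positive parts "
            "(use replace_zeros)"
        )
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def clr(c: Composition) -> np.ndarray:
    """Centred log-ratio: ln(x_i / g(x)); coordinates sum to zero."""
    return _clr_rows(c.values)


def clr_inv(v, parts: Sequence[str] = PCL) -> Composition:
    """Inverse clr: closure of the componentwise exponential."""
    return closure(np.exp(np.asarray(v, dtype=float)), parts)


def helmert_basis(D: int) -> np.ndarray:
    """Helmert-type orthonormal contrast basis, (D-1) x D.

    Row k contrasts the geometric mean of the first k+1 parts against part
    k+2, in the fixed part order; rows are orthonormal and sum to zero, so
    ilr built on them is an isometry between the simplex and R^(D-1).
    """
    V = np.zeros((D - 1, D))
    for k in range(1, D):
        V[k - 1, :k] = 1.0 / k
        V[k - 1, k] = -1.0
        V[k - 1] *= np.sqrt(k / (k + 1.0))
    return V


def _check_basis(basis: np.ndarray, D: int) -> np.ndarray:
    basis = np.asarray(basis, dtype=float)
    if basis.shape != (D - 1, D):
        raise ValueError(f"ilr basis must be {(D - 1, D)}, got {basis.shape}")
    if not np.allclose(basis @ basis.T, np.eye(D - 1), atol=1e-8):
        raise ValueError("ilr basis rows must be orthonormal")
    if not np.allclose(basis.sum(axis=1), 0, atol=1e-8):
        raise ValueError("ilr basis rows must sum to zero (clr subspace)")
    return basis


def ilr(c: Composition, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates: basis @ clr(c)."""
    basis = helmert_basis(c.D) if basis is None else _check_basis(basis, c.D)
    return basis @ clr(c)


def ilr_inv(
    y, basis: np.ndarray | None = None, parts: Sequence[str] = PCL
) -> Composition:
    y = np.asarray(y, dtype=float)
    D = len(parts)
    basis = helmert_basis(D) if basis is None else _check_basis(basis, D)
    return clr_inv(basis.T @ y, parts)


def ilr_rows(s: CompositionSet, basis: np.ndarray | None = None) -> np.ndarray:
    """ilr coordinates of every row of a set, N x (D-1)."""
    D = len(s.parts)
    basis = helmert_basis(D) if basis is None else _check_basis(basis, D)
    return _clr_rows(s.values) @ basis.T


def ilr_inv_rows(
    y: np.ndarray, parts: Sequence[str] = PCL, basis: np.ndarray | None = None
) -> np.ndarray:
    D = len(parts)
    basis = helmert_basis(D) if basis is None else _check_basis(basis, D)
    return close_rows(np.exp(np.atleast_2d(y) @ basis))


def aitchison_distance(x: Composition, y: Composition) -> float:
    """Euclidean distance between clr vectors (= ilr distance)."""
    return float(np.linalg.norm(clr(x) - clr(y)))


# ---------------------------------------------------------------------------
# descriptive statistics


def geometric_mean_composition(s: CompositionSet) -> Composition:
    """Closed geometric mean: per-part geometric means, re-closed.

    Identical to clr_inv of the arithmetic mean of the clr rows.
    """
    if len(s) < 1:
        raise ValueError("empty composition set")
    logmean = np.log(_strict(s.values)).mean(axis=0)
    return closure(np.exp(logmean), s.parts)


def _strict(x: np.ndarray) -> np.ndarray:
    if np.any(x <= 0):
        raise ValueError(
            "zero part in set; log-ratio statistics need strictly positive "
            "parts (use replace_zeros)"
        )
    return x


def mean_ratio_matrix(s: CompositionSet) -> np.ndarray:
    """Geometric mean pairwise ratio matrix: entry (i,j) = g_i / g_j.

    Equals exp(mean of ln(x_i/x_j)) over rows; obeys reciprocal symmetry
    M[i,j] * M[j,i] = 1 with unit diagonal.
    """
    g = geometric_mean_composition(s).values
    return g[:, None] / g[None, :]


def variation_matrix(s: CompositionSet) -> np.ndarray:
    """Variances of all pairwise log-ratios (unbiased, N-1 denominator)."""
    x = _strict(s.values)
    n, D = x.shape
    if n < 2:
        warnings.warn("variation matrix of a single row is zero", stacklevel=2)
        return np.zeros((D, D))
    lx = np.log(x)
    T = np.empty((D, D))
    for i in range(D):
        for j in range(D):
            T[i, j] = 0.0 if i == j else np.var(lx[:, i] - lx[:, j], ddof=1)
    return T


def metric_variance(s: CompositionSet) -> float:
    """Total Aitchison variance: (1/2D) * sum of the variation matrix.

    Equals the trace of the clr covariance matrix and hence the sum of the
    acomp PCA eigenvalues.
    """
    T = variation_matrix(s)
    return float(T.sum() / (2 * len(s.parts)))


def summarize(s: CompositionSet) -> CompositionSummary:
    return CompositionSummary(
        geometric_mean=geometric_mean_composition(s),
        mean_ratio_matrix=mean_ratio_matrix(s),
        variation_matrix=variation_matrix(s),
        metric_variance=metric_variance(s),
        n=len(s),
    )


# ---------------------------------------------------------------------------
# PCA


def acomp_pca(s: CompositionSet) -> PcaResult:
    """Principal component analysis in Aitchison (acomp) geometry.

    Eigen-decomposition of the clr covariance matrix, centred at the clr of
    the geometric mean. One eigenvalue is structurally zero (clr vectors sum
    to zero); the remaining D-1 components are returned sorted by decreasing
    variance. Biplot rays are covariance-scaled loadings per part.
    """
    if len(s) < 3:
        raise ValueError("acomp PCA needs N >= 3 rows")
    Z = _clr_rows(_strict(s.values))
    center_clr = Z.mean(axis=0)
    Zc = Z - center_clr
    cov = Zc.T @ Zc / (len(s) - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][: len(s.parts) - 1]
    eigval = np.clip(eigval[order], 0.0, None)
    comps = eigvec[:, order].T  # (D-1) x D, rows orthonormal, sum ~ 0
    # fix sign convention: make the largest-magnitude loading positive
    for k in range(comps.shape[0]):
        if comps[k, np.argmax(np.abs(comps[k]))] < 0:
            comps[k] = -comps[k]
    rays = comps.T * np.sqrt(eigval)  # D x (D-1)
    return PcaResult(
        center=clr_inv(center_clr, s.parts),
        components=comps,
        explained_variance=eigval,
        scores=Zc @ comps.T,
        biplot_rays=rays,
    )


# ---------------------------------------------------------------------------
# simplex regions


def _ellipse_boundary(
    center: np.ndarray, shape: np.ndarray, radius2: float, n_points: int
) -> np.ndarray:
    """Closed polyline (n_points+1 x 2) of the ellipse x'S^-1x = r^2."""
    try:
        L = np.linalg.cholesky(shape)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular ilr covariance; jitter the data or drop a collinear "
            "part before requesting a region"
        ) from e
    t = np.linspace(0.0, 2 * np.pi, n_points + 1)
    circle = np.stack([np.cos(t), np.sin(t)])
    return (center[:, None] + np.sqrt(radius2) * (L @ circle)).T


def _ilr_mean_cov(s: CompositionSet, basis: np.ndarray):
    Y = ilr_rows(s, basis)
    return Y.mean(axis=0), np.cov(Y, rowvar=False, ddof=1)


def sigma_region(
    s: CompositionSet,
    k: float = 2,
    n_points: int = 256,
    basis: np.ndarray | None = None,
) -> SimplexRegion:
    """k-sigma ellipse of individual compositions around the geometric mean.

    Mahalanobis radius k under the ilr sample covariance. For 3-part data
    the ilr space is bivariate, so the k=2 ellipse is predicted to contain
    1 - exp(-k^2/2) ≈ 86.5% of logistic-normal draws (the univariate
    68-95-99.7 rule does not carry over).
    """
    if len(s) < 3:
        raise ValueError("sigma region needs N >= 3")
    D = len(s.parts)
    basis = helmert_basis(D) if basis is None else _check_basis(basis, D)
    mean, cov = _ilr_mean_cov(s, basis)
    bnd = _ellipse_boundary(mean, cov, float(k) ** 2, n_points)
    return SimplexRegion(
        kind="sigma",
        level=float(k),
        boundary=CompositionSet(s.parts, ilr_inv_rows(bnd, s.parts, basis)),
        ilr_center=mean,
        ilr_shape=cov,
        radius2=float(k) ** 2,
        basis=basis,
    )


def confidence_region(
    s: CompositionSet,
    coverage: float = 0.90,
    n_points: int = 256,
    basis: np.ndarray | None = None,
) -> SimplexRegion:
    """Hotelling-T² confidence ellipse for the mean composition.

    In ilr coordinates (p = D-1): centre = sample mean, shape = S/N,
    squared radius = p(N-1)/(N-p) * F_{p, N-p}(coverage).
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0,1)")
    N, D = len(s), len(s.parts)
    p = D - 1
    if N <= p:
        raise ValueError(f"confidence region needs N > D-1 (= {p})")
    basis = helmert_basis(D) if basis is None else _check_basis(basis, D)
    mean, cov = _ilr_mean_cov(s, basis)
    radius2 = p * (N - 1) / (N - p) * _sstats.f.ppf(coverage, p, N - p)
    bnd = _ellipse_boundary(mean, cov / N, radius2, n_points)
    return SimplexRegion(
        kind="confidence",
        level=float(coverage),
        boundary=CompositionSet(s.parts, ilr_inv_rows(bnd, s.parts, basis)),
        ilr_center=mean,
        ilr_shape=cov / N,
        radius2=float(radius2),
        basis=basis,
    )
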