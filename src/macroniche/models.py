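"""Inference on diet compositions: ilr linear models, MANOVA, diagnostics.

Compositions are mapped to ilr coordinates, where ordinary least squares is
valid, and a shared design matrix is fitted to each of the D-1 coordinates.
Factor effects are tested jointly across coordinates with a multivariate
ANOVA (Wilks' lambda with the Rao F approximation, exact for D=3; Pillai's
trace available). Group means back-transform to closed geometric means on
the simplex. Univariate logit-linear models per macronutrient provide a
conventional cross-check, and Cook's distance in stacked ilr coordinates
flags influential populations for sensitivity refits.

Winter diets are excluded from seasonal inference (too few observations);
exclusion happens here, not in the estimation layer, so the estimates
themselves remain complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sstats

from .compositional import (
    Composition,
    CompositionSet,
    clr_inv,
    helmert_basis,
    ilr_inv,
    ilr_rows,
    _check_basis,
)

__all__ = [
    "DesignSpec",
    "CompositionalFit",
    "GlobalTest",
    "IntakeTarget",
    "LogitFit",
    "fit_compositional_lm",
    "anova_global",
    "fit_logit_lm",
    "cooks_influence",
    "compare_to_target",
    "group_geometric_means",
]

SEASON_LEVELS = ("spring", "summer", "autumn")  # ordered; spring = reference
SUBSIDY_LEVELS = ("natural", "anthropogenic")  # natural = reference


@dataclass(frozen=True)
class IntakeTarget:
    """Self-selected optimal protein share of captive bears: 17% +/- 4."""

    protein_fraction: float = 0.17
    band_halfwidth: float = 0.04

    def __post_init__(self):
        lo = self.protein_fraction - self.band_halfwidth
        hi = self.protein_fraction + self.band_halfwidth
        if not (0 < lo and hi < 1):
            raise ValueError("target band must lie inside (0,1)")


@dataclass
class DesignSpec:
    """Model specification: a composition set plus named factors.

    ``factors`` draws on the set's metadata columns; ``season`` is an
    ordered 3-level factor (spring < summer < autumn, spring reference) and
    ``subsidy`` a binary natural/anthropogenic factor. Winter rows are
    dropped when season is modelled.
    """

    response: CompositionSet
    factors: tuple[str, ...] = ("season",)
    interaction: bool = False

    def __post_init__(self):
        self.factors = tuple(self.factors)
        for f in self.factors:
            if f not in ("season", "subsidy"):
                raise ValueError(f"unknown factor {f!r}")
            if f not in self.response.metadata:
                raise ValueError(f"response metadata lacks column {f!r}")
        if self.interaction and len(self.factors) != 2:
            raise ValueError("interaction requires both factors")

    def drop_winter(self) -> "DesignSpec":
        if "season" not in self.factors:
            return self
        keep = [s != "winter" for s in self.response.metadata["season"]]
        return DesignSpec(self.response.select(np.array(keep)), self.factors,
                          self.interaction)


def _design_matrix(spec: DesignSpec) -> tuple[np.ndarray, dict[str, list[int]], list[str]]:
    """Treatment-coded design matrix and term -> column-index map."""
    n = len(spec.response)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["Intercept"]
    terms: dict[str, list[int]] = {"Intercept": [0]}
    blocks: dict[str, np.ndarray] = {}
    for f in spec.factors:
        levels = SEASON_LEVELS if f == "season" else SUBSIDY_LEVELS
        vals = spec.response.metadata[f]
        bad = sorted(set(vals) - set(levels))
        if bad:
            raise ValueError(f"factor {f!r} has unexpected levels {bad}")
        dummies = np.stack(
            [np.array([v == lev for v in vals], dtype=float) for lev in levels[1:]],
            axis=1,
        )
        blocks[f] = dummies
        terms[f] = list(range(len(cols), len(cols) + dummies.shape[1]))
        cols.extend(dummies.T)
        names.extend(f"{f}[{lev}]" for lev in levels[1:])
    if spec.interaction:
        a, b = (blocks[f] for f in spec.factors)
        inter = np.stack(
            [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])],
            axis=1,
        )
        terms[":".join(spec.factors)] = list(range(len(cols), len(cols) + inter.shape[1]))
        cols.extend(inter.T)
        names.extend(
            f"{spec.factors[0]}:{spec.factors[1]}[{i},{j}]"
            for i in range(a.shape[1])
            for j in range(b.shape[1])
        )
    X = np.stack(cols, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design; aliased terms among " + ", ".join(names)
        )
    return X, terms, names


@dataclass
class GlobalTest:
    statistic_name: str
    statistic: float
    f_value: float
    df_num: float
    df_den: float
    p_value: float


@dataclass
class CompositionalFit:
    """An OLS fit of ilr coordinates on a shared design matrix."""

    spec: DesignSpec
    basis: np.ndarray
    X: np.ndarray
    Y: np.ndarray  # N x (D-1) ilr responses
    coefficients: np.ndarray  # q x (D-1)
    terms: dict[str, list[int]]
    term_names: list[str]

    @property
    def fitted_ilr(self) -> np.ndarray:
        return self.X @ self.coefficients

    @property
    def residuals_ilr(self) -> np.ndarray:
        return self.Y - self.fitted_ilr

    @property
    def df_resid(self) -> int:
        return self.X.shape[0] - self.X.shape[1]

    def fitted_compositions(self) -> CompositionSet:
        from .compositional import ilr_inv_rows

        vals = ilr_inv_rows(self.fitted_ilr, self.spec.response.parts, self.basis)
        return CompositionSet(self.spec.response.parts, vals,
                              dict(self.spec.response.metadata))


def fit_compositional_lm(
    spec: DesignSpec, basis: np.ndarray | None = None
) -> CompositionalFit:
    """OLS per ilr coordinate with a shared treatment-coded design matrix."""
    spec = spec.drop_winter()
    D = len(spec.response.parts)
    basis = helmert_basis(D) if basis is None else _check_basis(basis, D)
    X, terms, names = _design_matrix(spec)
    if X.shape[0] <= X.shape[1] + (D - 1) - 1:
        raise ValueError("too few observations for the requested model")
    Y = ilr_rows(spec.response, basis)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return CompositionalFit(spec, basis, X, Y, B, terms, names)


def _wilks_rao_f(lam: float, p: int, q: int, v: int) -> tuple[float, float, float]:
    """Rao's F approximation for Wilks' lambda (exact when min(p,q) <= 2).

    p responses, q hypothesis df, v error df.
    """
    r = v - (p - q + 1) / 2.0
    u = (p * q - 2) / 4.0
    denom = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    df1 = p * q
    df2 = r * t - 2 * u
    lam_t = lam ** (1.0 / t)
    f = (1 - lam_t) / lam_t * df2 / df1
    return float(f), float(df1), float(df2)


def anova_global(
    fit: CompositionalFit, term: str, statistic: str = "wilks"
) -> GlobalTest:
    """Multivariate test of one model term across all ilr coordinates.

    Compares the full fit against the fit with the term's columns removed:
    E = full-model residual cross-product, H = extra cross-product of the
    reduced model. Both Wilks' lambda (likelihood ratio, Rao F) and
    Pillai's trace are invariant to the choice of orthonormal ilr basis.
    """
    if term not in fit.terms or term == "Intercept":
        raise ValueError(
            f"term {term!r} not in model (terms: {sorted(fit.terms)})"
        )
    drop = fit.terms[term]
    keep = [j for j in range(fit.X.shape[1]) if j not in drop]
    E = fit.residuals_ilr.T @ fit.residuals_ilr
    Xr = fit.X[:, keep]
    Br, *_ = np.linalg.lstsq(Xr, fit.Y, rcond=None)
    Rr = fit.Y - Xr @ Br
    H = Rr.T @ Rr - E
    p = fit.Y.shape[1]
    q = len(drop)
    v = fit.df_resid
    if statistic == "wilks":
        lam = float(np.linalg.det(E) / np.linalg.det(E + H))
        f, df1, df2 = _wilks_rao_f(lam, p, q, v)
        pval = float(_sstats.f.sf(f, df1, df2))
        return GlobalTest("Wilks' lambda", lam, f, df1, df2, pval)
    if statistic == "pillai":
        V = float(np.trace(H @ np.linalg.inv(H + E)))
        s = min(p, q)
        m = (abs(p - q) - 1) / 2.0
        nn = (v - p - 1) / 2.0
        df1 = s * (2 * m + s + 1)
        df2 = s * (2 * nn + s + 1)
        f = (df2 / df1) * V / (s - V)
        pval = float(_sstats.f.sf(f, df1, df2))
        return GlobalTest("Pillai trace", V, f, df1, df2, pval)
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass
class LogitFit:
    """Univariate OLS of a logit-transformed part on an ordered factor."""

    part: str
    coefficients: dict[str, float]
    linear_contrast: float
    linear_se: float
    linear_t: float
    linear_p: float


def fit_logit_lm(
    s: CompositionSet, part_order: Sequence[str] | None = None
) -> dict[str, LogitFit]:
    """Per-macronutrient logit LMs of season as an ordered factor.

    Seasons are coded with orthogonal polynomial contrasts (linear and
    quadratic over spring < summer < autumn); the linear-trend contrast is
    reported with its t test. Winter rows are dropped.
    """
    keep = np.array([x != "winter" for x in s.metadata["season"]])
    s = s.select(keep)
    seasons = s.metadata["season"]
    if np.any(s.values <= 0) or np.any(s.values >= 1):
        raise ValueError(
            "logit needs fractions strictly inside (0,1); use replace_zeros"
        )
    idx = np.array([SEASON_LEVELS.index(x) for x in seasons])
    lin_c = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2)
    quad_c = np.array([1.0, -2.0, 1.0]) / np.sqrt(6)
    X = np.stack([np.ones(len(s)), lin_c[idx], quad_c[idx]], axis=1)
    names = ["Intercept", "season.L", "season.Q"]
    out: dict[str, LogitFit] = {}
    XtXinv = np.linalg.inv(X.T @ X)
    for j, part in enumerate(s.parts):
        y = np.log(s.values[:, j] / (1 - s.values[:, j]))
        b = XtXinv @ X.T @ y
        resid = y - X @ b
        dof = len(s) - X.shape[1]
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * np.diag(XtXinv))
        # perfect fits have zero residual variance; report t=0 for a zero slope
        t = b[1] / se[1] if se[1] > 0 else (0.0 if b[1] == 0 else np.inf)
        out[part] = LogitFit(
            part=part,
            coefficients=dict(zip(names, map(float, b))),
            linear_contrast=float(b[1]),
            linear_se=float(se[1]),
            linear_t=float(t),
            linear_p=float(2 * _sstats.t.sf(abs(t), dof)),
        )
    return out


def cooks_influence(fit: CompositionalFit) -> np.ndarray:
    """Cook's distance per observation in stacked ilr coordinates.

    The D-1 coordinate models share one design matrix, so observation i has
    one leverage h_ii; its squared residuals are pooled across coordinates
    and scaled by p_total = q*(D-1) parameters and the pooled residual
    variance, the stacked-regression analogue of the univariate formula.
    """
    X, R = fit.X, fit.residuals_ilr
    n, q = X.shape
    k = R.shape[1]
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    h = np.diag(H)
    p_total = q * k
    s2 = float((R * R).sum()) / (n * k - p_total)
    e2 = (R * R).sum(axis=1)
    return e2 * h / (p_total * s2 * (1 - h) ** 2)


def compare_to_target(
    c: Composition, target: IntakeTarget = IntakeTarget()
) -> tuple[str, float]:
    """Classify a diet against the intake-target protein band.

    Returns (classification, gap) where classification is below|within|above
    the band [target - halfwidth, target + halfwidth] on the protein part
    and gap is protein - target (signed).
    """
    p = c["P"]
    gap = p - target.protein_fraction
    lo = target.protein_fraction - target.band_halfwidth
    hi = target.protein_fraction + target.band_halfwidth
    if p < lo:
        cls = "below"
    elif p > hi:
        cls = "above"
    else:
        cls = "within"
    return cls, gap


def group_geometric_means(
    s: CompositionSet, factor: str
) -> dict[str, Composition]:
    """Closed geometric mean per factor level, in level order of appearance."""
    from .compositional import geometric_mean_composition

    levels = list(dict.fromkeys(s.metadata[factor]))
    out = {}
    for lev in levels:
        mask = np.array([v == lev for v in s.metadata[factor]])
        out[lev] = geometric_mean_composition(s.select(mask))
    return out
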