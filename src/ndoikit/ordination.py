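"""Linear constrained ordination: rare-disease filtering, PCA, RDA, and a
Monte Carlo permutation test.

Redundancy analysis (RDA) regresses a response ("species": diseases ×
months) matrix on an explanatory ("environment": covariates) matrix by
multivariate least squares and then performs a PCA of the fitted values;
the constrained fraction — the share of total response variance captured
by the fitted values — measures how much of the disease signal the
covariates explain jointly.  A linear method is appropriate here because
the underlying compositional gradient is short (detrended correspondence
analysis on the source data gave a first-axis gradient length of 0.5,
well inside the linear regime); the unimodal alternative is deliberately
not implemented.

Months enter as exchangeable sites: significance comes from a Monte Carlo
test permuting the explanatory rows, with p = (1 + exceedances) /
(1 + permutations).

Scaling conventions: the species matrix is centered and standardized
(correlation-scale RDA) because disease counts span orders of magnitude;
the environment matrix is always standardized.  Axis signs are fixed by
making the largest-magnitude species loading on each axis positive, so
results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .tables import MonthlyCaseTable

_RANK_TOL = 1e-9


class OrdinationError(ValueError):
    """Input cannot be ordinated (empty, degenerate, or rank-deficient)."""


def rare_filter(table: MonthlyCaseTable, threshold: float = 0.05) -> MonthlyCaseTable:
    """Drop diseases present (count ≥ 1) in fewer than ``threshold`` of months.

    Mirrors the rare-species screen customary before ordination; survivors
    keep their original order.  ``threshold`` is a fraction of months, and
    removal is strict (< threshold).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be a fraction in [0, 1]")
    freq = (table.counts >= 1).mean(axis=0)
    keep = [d for d in table.diseases if freq[d] >= threshold]
    if not keep:
        raise OrdinationError("rare-disease filter removed every disease")
    return MonthlyCaseTable(table.counts[keep], table.catalog.subset(keep))


@dataclass
class OrdinationResult:
    """Eigen-structure of a PCA or RDA.

    Eigenvalues are variances along axes (descending, ≥ 0); explained
    fractions are relative to the total variance of the (scaled) response.
    For RDA, ``eigenvalues`` are the constrained axes, ``residual_eigenvalues``
    the unconstrained remainder, and ``constrained_fraction`` their ratio of
    the total.
    """

    method: str
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    total_variance: float
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame | None = None
    constrained_fraction: float | None = None
    residual_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    marginal_fraction: dict[str, float] | None = None
    permutation_p: dict[str, float] | None = None


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic axis orientation: largest-|loading| positive per axis
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
            scores[:, k] = -scores[:, k]
    return loadings, scores


def _eigen_axes(M: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based axes of an n × p matrix: eigenvalues (variances), site
    coordinates and loadings, truncated to numerical rank."""
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    lam = s ** 2 / (n - 1)
    rank = int(np.sum(s > s[0] * _RANK_TOL)) if s.size and s[0] > 0 else 0
    lam, U, s, Vt = lam[:rank], U[:, :rank], s[:rank], Vt[:rank]
    sites = U * s           # principal coordinates
    loadings = Vt.T
    loadings, sites = _fix_signs(loadings, sites)
    return lam, sites, loadings


def _standardize(X: np.ndarray, names, what: str, strict: bool = True) -> np.ndarray:
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        bad = [str(names[i]) for i in np.flatnonzero(zero)]
        if strict:
            raise OrdinationError(f"zero-variance {what} column(s) {bad} cannot be standardized")
        warnings.warn(f"constant {what} column(s) {bad} left at zero", UserWarning, stacklevel=3)
        sd = np.where(zero, 1.0, sd)
    return X / sd


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"v{j}" for j in range(X.shape[1])])


def pca(matrix, center: bool = True, standardize: bool = False) -> OrdinationResult:
    """Principal component analysis of a sites × variables matrix.

    Eigenvalues are axis variances summing to the total variance of the
    (centered/standardized) data; with standardization their sum equals the
    number of non-constant variables.
    """
    df = _as_frame(matrix)
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 1:
        raise OrdinationError("PCA needs at least 2 sites and 1 variable")
    if standardize:
        X = _standardize(X, df.columns, "variable", strict=True)
    elif center:
        X = X - X.mean(axis=0)
    lam, sites, loadings = _eigen_axes(X, n)
    total = float(X.var(axis=0, ddof=1).sum())
    axes = [f"PC{k + 1}" for k in range(len(lam))]
    return OrdinationResult(
        method="PCA",
        eigenvalues=lam,
        explained_fraction=lam / total if total > 0 else np.zeros_like(lam),
        total_variance=total,
        site_scores=pd.DataFrame(sites, index=df.index, columns=axes),
        species_scores=pd.DataFrame(loadings * np.sqrt(lam), index=df.columns, columns=axes),
    )


def _drop_collinear(E: pd.DataFrame) -> pd.DataFrame:
    """Greedily keep env columns left-to-right, dropping any column linearly
    dependent (after centering) on the ones already kept."""
    C = E.to_numpy(dtype=float)
    C = C - C.mean(axis=0)
    kept: list[int] = []
    rank = 0
    for j in range(C.shape[1]):
        cand_rank = np.linalg.matrix_rank(C[:, kept + [j]])
        if cand_rank > rank:
            kept.append(j)
            rank = cand_rank
        else:
            warnings.warn(f"dropping collinear covariate {E.columns[j]!r}", UserWarning, stacklevel=3)
    return E.iloc[:, kept]


class RDA(BaseEstimator):
    """Redundancy analysis: PCA of the least-squares fit of species on environment.

    Follows the cross-decomposition convention ``fit(X, Y)`` with ``X`` the
    explanatory (environment) matrix and ``Y`` the response (species)
    matrix; the module-level :func:`rda` wrapper takes ``(species, env)`` in
    the ecological argument order.

    Parameters
    ----------
    scale_species : bool, default True
        Standardize species columns (correlation-scale RDA); disease counts
        span orders of magnitude, so the default puts them on a common
        scale.  Constant columns are left at zero with a warning.
    n_permutations, random_state
        Monte Carlo test of the constrained fraction run at fit time when
        ``n_permutations`` > 0.

    Attributes
    ----------
    eigenvalues_ : constrained-axis variances, descending.
    residual_eigenvalues_ : unconstrained-axis variances.
    constrained_fraction_ : share of total species variance explained.
    site_scores_, species_scores_, biplot_scores_ : score matrices.
    marginal_fraction_ : per-covariate constrained fraction (fit alone).
    permutation_p_ : overall and per-covariate Monte Carlo p-values.
    env_columns_ : covariates retained after collinearity pruning.
    """

    def __init__(self, scale_species: bool = True, n_permutations: int = 0,
                 random_state: int | None = None):
        self.scale_species = scale_species
        self.n_permutations = n_permutations
        self.random_state = random_state

    # -- core computation -------------------------------------------------
    def _prepare(self, X, Y):
        E, S = _as_frame(X), _as_frame(Y)
        if len(E) != len(S):
            raise OrdinationError("species and environment must have aligned sites")
        n = len(S)
        if n < 3:
            raise OrdinationError("RDA needs at least 3 sites")
        if E.shape[1] > n - 1:
            raise OrdinationError(f"{E.shape[1]} covariates exceed sites-1 = {n - 1}")
        E = _drop_collinear(E)
        Z = _standardize(E.to_numpy(dtype=float), E.columns, "covariate", strict=True)
        Ymat = S.to_numpy(dtype=float)
        if self.scale_species:
            Ymat = _standardize(Ymat, S.columns, "species", strict=False)
        else:
            Ymat = Ymat - Ymat.mean(axis=0)
        return E, S, Z, Ymat, n

    @staticmethod
    def _constrained_fraction(Z: np.ndarray, Y: np.ndarray) -> float:
        total = float((Y ** 2).sum())
        if total == 0:
            return 0.0
        B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        fitted = Z @ B
        return float((fitted ** 2).sum()) / total

    def fit(self, X, Y=None):
        if Y is None:
            raise ValueError("RDA.fit requires both an environment matrix X and a species matrix Y")
        E, S, Z, Ymat, n = self._prepare(X, Y)
        B, *_ = np.linalg.lstsq(Z, Ymat, rcond=None)
        fitted = Z @ B
        resid = Ymat - fitted

        lam_c, sites, loadings = _eigen_axes(fitted, n)
        lam_r, _, _ = _eigen_axes(resid, n)
        total = float(Ymat.var(axis=0, ddof=1).sum())
        axes = [f"RDA{k + 1}" for k in range(len(lam_c))]

        self.n_sites_ = n
        self.env_columns_ = tuple(E.columns)
        self.eigenvalues_ = lam_c
        self.residual_eigenvalues_ = lam_r
        self.total_variance_ = total
        self.explained_fraction_ = lam_c / total if total > 0 else np.zeros_like(lam_c)
        self.constrained_fraction_ = float(lam_c.sum() / total) if total > 0 else 0.0
        self.site_scores_ = pd.DataFrame(sites, index=S.index, columns=axes)
        self.species_scores_ = pd.DataFrame(loadings * np.sqrt(lam_c), index=S.columns, columns=axes)
        # biplot scores: correlation of (standardized) covariates with site axes
        bip = np.zeros((Z.shape[1], len(axes)))
        for j in range(Z.shape[1]):
            for k in range(len(axes)):
                sc = sites[:, k]
                bip[j, k] = 0.0 if sc.std() == 0 else float(np.corrcoef(Z[:, j], sc)[0, 1])
        self.biplot_scores_ = pd.DataFrame(bip, index=E.columns, columns=axes)
        self.marginal_fraction_ = {
            col: self._constrained_fraction(Z[:, [j]], Ymat)
            for j, col in enumerate(E.columns)
        }
        if self.n_permutations:
            rng = np.random.default_rng(self.random_state)
            self.permutation_p_ = {
                "overall": _permute_fraction(Z, Ymat, self.n_permutations, rng),
                **{col: _permute_fraction(Z[:, [j]], Ymat, self.n_permutations, rng)
                   for j, col in enumerate(E.columns)},
            }
        else:
            self.permutation_p_ = None
        return self

    def result(self) -> OrdinationResult:
        return OrdinationResult(
            method="RDA",
            eigenvalues=self.eigenvalues_,
            explained_fraction=self.explained_fraction_,
            total_variance=self.total_variance_,
            site_scores=self.site_scores_,
            species_scores=self.species_scores_,
            biplot_scores=self.biplot_scores_,
            constrained_fraction=self.constrained_fraction_,
            residual_eigenvalues=self.residual_eigenvalues_,
            marginal_fraction=self.marginal_fraction_,
            permutation_p=self.permutation_p_,
        )


def _permute_fraction(Z: np.ndarray, Y: np.ndarray, permutations: int,
                      rng: np.random.Generator) -> float:
    obs = RDA._constrained_fraction(Z, Y)
    n = Z.shape[0]
    exceed = 0
    for _ in range(int(permutations)):
        perm = rng.permutation(n)
        if RDA._constrained_fraction(Z[perm], Y) >= obs - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + permutations)


def rda(species, env, scale_species: bool = True, n_permutations: int = 0,
        random_state: int | None = None) -> OrdinationResult:
    """Functional wrapper: ``rda(species, env)`` in the ecological argument order."""
    model = RDA(scale_species=scale_species, n_permutations=n_permutations,
                random_state=random_state).fit(env, species)
    return model.result()


def permutation_test(species, env, subset=None, permutations: int = 499,
                     seed: int | None = None, scale_species: bool = True) -> float:
    """Monte Carlo p-value for the constrained fraction of an RDA.

    Rows of the (optionally column-subset) environment matrix are permuted
    jointly; p = (1 + #{permuted ≥ observed}) / (1 + permutations), so the
    smallest attainable p is 1/(permutations+1).
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    E, S = _as_frame(env), _as_frame(species)
    if subset is not None:
        E = E[list(subset)]
    model = RDA(scale_species=scale_species)
    E2, S2, Z, Ymat, n = model._prepare(E, S)
    rng = np.random.default_rng(seed)
    return _permute_fraction(Z, Ymat, permutations, rng)


def variable_ranking(species, env, subset=None,
                     scale_species: bool = True) -> tuple[pd.Series, float | None]:
    """Covariates ranked by marginal constrained fraction, descending.

    Returns the ranking and, when ``subset`` names covariates, the joint
    constrained fraction of that subset.
    """
    model = RDA(scale_species=scale_species).fit(env, species)
    ranking = pd.Series(model.marginal_fraction_).sort_values(ascending=False, kind="stable")
    joint = None
    if subset is not None:
        E = _as_frame(env)[list(subset)]
        joint = rda(species, E, scale_species=scale_species).constrained_fraction
    return ranking, joint
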