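"""Ordination: Hellinger transform, block preprocessing, 2B-PLS, PCA.

Two-block partial least squares (2B-PLS, a.k.a. PLS-SVD / co-inertia
analysis) relates two matrices measured on the same samples — here a
geochemical block and a community or pathway-completeness block. The
paired axes (u_k, v_k) are the left/right singular vectors of the
cross-covariance matrix C = X'Y/(n-1) of the column-centered blocks;
the singular value d_k is the covariance of the paired scores Xu_k and
Yv_k, and r_k their Pearson correlation. Significance of an axis is
assessed by permuting the rows of one block.

Sign conventions (for byte-stable output across backends): singular
values are non-negative, and each (u_k, v_k) pair is jointly flipped so
the largest-magnitude entry of u_k is positive. Because d_k >= 0 and
cov(Xu_k, Yv_k) = d_k for centered blocks, the score correlations r_k
are automatically non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.decomposition import PCA as _SkPCA

from .errors import DegenerateInputError, ValidationError
from .io import OtuTable, to_relative


@dataclass
class Block:
    """Samples x variables real matrix with a preprocessing tag."""

    data: pd.DataFrame
    preprocessing: str = "raw"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def hellinger_transform(table: OtuTable) -> Block:
    """Square root of relative abundances.

    Down-weights dominant OTUs so Euclidean-geometry methods (PCA, PLS)
    behave sensibly on community data; a complete row has unit
    Euclidean norm after the transform.
    """
    rel = to_relative(table) if table.unit == "counts" else table
    sums = rel.data.sum(axis=1)
    if (sums <= 0).any():
        bad = sums.index[int(np.argmax((sums <= 0).to_numpy()))]
        raise DegenerateInputError(f"sample {bad!r} has zero total abundance")
    return Block(data=np.sqrt(rel.data), preprocessing="hellinger")


class BlockScaler:
    """Column-wise block preprocessing: log10, imputation, center, scale.

    sklearn-style transformer. ``log10_vars`` names concentration
    variables to be mapped through log10(x + eps) (eps is the smallest
    positive value of the column divided by 2, or machine tiny if the
    column is all zero) before centering — concentrations span orders
    of magnitude and are roughly log-normal. Missing cells are imputed
    with the column median (policy ``column_median``) or rejected
    (policy ``fail``). With ``scale`` zero-variance columns are dropped
    with a warning, since they carry no association signal and would
    divide by zero.
    """

    def __init__(
        self,
        center: bool = True,
        scale: bool = False,
        log10_vars: list[str] | None = None,
        impute: str = "column_median",
    ):
        self.center = center
        self.scale = scale
        self.log10_vars = log10_vars
        self.impute = impute

    def get_params(self, deep: bool = True) -> dict:
        return {
            "center": self.center,
            "scale": self.scale,
            "log10_vars": self.log10_vars,
            "impute": self.impute,
        }

    def set_params(self, **params) -> "BlockScaler":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _log10(self, df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        for var in self.log10_vars or []:
            if var not in df.columns:
                continue
            col = df[var]
            pos = col[col > 0]
            # pseudocount only when zeros are present (e.g. censored cells)
            if len(pos) and (col.dropna() > 0).all():
                eps = 0.0
            elif len(pos):
                eps = pos.min() / 2.0
            else:
                eps = np.finfo(float).tiny
            df[var] = np.log10(col + eps)
        return df

    def fit(self, X: Block | pd.DataFrame, y=None) -> "BlockScaler":
        df = X.data if isinstance(X, Block) else pd.DataFrame(X)
        if df.shape[0] < 3:
            raise ValidationError("block preprocessing requires at least 3 samples")
        if self.impute not in ("column_median", "fail"):
            raise ValidationError(f"unknown imputation policy {self.impute!r}")
        df = self._log10(df)
        if df.isna().any().any():
            if self.impute == "fail":
                col = df.columns[df.isna().any()][0]
                row = df.index[df[col].isna()][0]
                raise ValidationError(
                    f"missing cell at sample {row!r}, variable {col!r} (policy=fail)"
                )
            self.medians_ = df.median(axis=0, skipna=True)
        else:
            self.medians_ = None
        filled = df.fillna(self.medians_) if self.medians_ is not None else df
        self.means_ = filled.mean(axis=0)
        sds = filled.std(axis=0, ddof=1)
        self.dropped_ = []
        if self.scale:
            self.dropped_ = list(sds.index[(sds == 0) | sds.isna()])
            if self.dropped_:
                warnings.warn(
                    f"dropping zero-variance variables: {self.dropped_}", UserWarning
                )
        self.sds_ = sds.drop(self.dropped_)
        self.means_ = self.means_.drop(self.dropped_)
        return self

    def transform(self, X: Block | pd.DataFrame) -> Block:
        df = X.data if isinstance(X, Block) else pd.DataFrame(X)
        tag = X.preprocessing if isinstance(X, Block) else "raw"
        df = self._log10(df).drop(columns=self.dropped_, errors="ignore")
        if self.medians_ is not None:
            df = df.fillna(self.medians_.drop(self.dropped_, errors="ignore"))
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            raise ValidationError(f"variable {col!r} still has missing cells")
        if self.center:
            df = df - self.means_
            tag = "z_scored" if self.scale else "centered"
        if self.scale:
            df = df / self.sds_
        return Block(data=df, preprocessing=tag)

    def fit_transform(self, X: Block | pd.DataFrame, y=None) -> Block:
        return self.fit(X).transform(X)


def prepare_block(
    raw: Block,
    center: bool = True,
    scale: bool = False,
    log10_vars: list[str] | None = None,
    impute: str = "column_median",
) -> Block:
    """Functional form of :class:`BlockScaler` (fit and transform in one)."""
    return BlockScaler(center, scale, log10_vars, impute).fit_transform(raw)


# ---------------------------------------------------------------------------
# 2B-PLS
# ---------------------------------------------------------------------------

def _as_matrix(X) -> tuple[np.ndarray, list | None, list | None]:
    if isinstance(X, Block):
        return X.values(), list(X.data.index), list(X.data.columns)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, None, None


def _pls_core(Xc: np.ndarray, Yc: np.ndarray, n_axes: int):
    """SVD of the cross-covariance of pre-centered blocks; sign-fixed."""
    n = Xc.shape[0]
    C = Xc.T @ Yc / (n - 1)
    U, d, Vt = scipy.linalg.svd(C, full_matrices=False)
    k = min(n_axes, len(d))
    U, d, V = U[:, :k], d[:k], Vt[:k].T
    for j in range(k):  # joint flip keeps d_j >= 0
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    return U, V, d, C


def _score_correlations(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    rs = []
    for j in range(xs.shape[1]):
        sx, sy = xs[:, j].std(), ys[:, j].std()
        rs.append(np.corrcoef(xs[:, j], ys[:, j])[0, 1] if sx > 0 and sy > 0 else 0.0)
    return np.asarray(rs)


@dataclass
class TwoBlockResult:
    """Paired axes of a fitted 2B-PLS: weights, scores, d, r, permutation p."""

    x_weights: np.ndarray
    y_weights: np.ndarray
    singular_values: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    score_correlations: np.ndarray
    sample_ids: list | None = None
    p_values: dict[int, float] | None = None
    n_permutations: int | None = None
    seed: int | None = None


class TwoBlockPLS:
    """Two-block PLS estimator (SVD of the between-block cross-covariance).

    Parameters
    ----------
    n_axes : int
        Number of paired axes to retain.
    center : bool
        Column-center both blocks inside ``fit``. Already-centered
        blocks are unchanged by this, so leaving it on is safe.

    Fitted attributes (trailing underscore): ``x_weights_`` (p x k),
    ``y_weights_`` (q x k), ``singular_values_`` (k,), ``x_scores_`` /
    ``y_scores_`` (n x k), ``score_correlations_`` (k,), and
    ``cross_covariance_``.
    """

    def __init__(self, n_axes: int = 2, center: bool = True):
        self.n_axes = n_axes
        self.center = center

    def get_params(self, deep: bool = True) -> dict:
        return {"n_axes": self.n_axes, "center": self.center}

    def set_params(self, **params) -> "TwoBlockPLS":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _validated(self, X, Y) -> tuple[np.ndarray, np.ndarray, list | None]:
        Xm, x_samples, x_vars = _as_matrix(X)
        Ym, y_samples, y_vars = _as_matrix(Y)
        if Xm.shape[0] != Ym.shape[0]:
            raise ValidationError(
                f"blocks have {Xm.shape[0]} vs {Ym.shape[0]} samples"
            )
        if Xm.shape[0] < 3:
            raise ValidationError("2B-PLS requires at least 3 samples")
        if x_samples is not None and y_samples is not None and x_samples != y_samples:
            only_x = sorted(set(x_samples) - set(y_samples))
            only_y = sorted(set(y_samples) - set(x_samples))
            if only_x or only_y:
                raise ValidationError(
                    f"sample sets differ: only in X {only_x}, only in Y {only_y}"
                )
            raise ValidationError("blocks list the same samples in different orders")
        if np.isnan(Xm).any() or np.isnan(Ym).any():
            raise ValidationError("blocks contain missing values; prepare them first")
        self._x_vars, self._y_vars = x_vars, y_vars
        return Xm, Ym, x_samples

    def fit(self, X, Y) -> "TwoBlockPLS":
        Xm, Ym, samples = self._validated(X, Y)
        if self.center:
            Xm = Xm - Xm.mean(axis=0)
            Ym = Ym - Ym.mean(axis=0)
        U, V, d, C = _pls_core(Xm, Ym, self.n_axes)
        self.x_weights_, self.y_weights_ = U, V
        self.singular_values_ = d
        self.cross_covariance_ = C
        self.x_scores_ = Xm @ U
        self.y_scores_ = Ym @ V
        self.score_correlations_ = _score_correlations(self.x_scores_, self.y_scores_)
        self.sample_ids_ = samples
        self.n_samples_ = Xm.shape[0]
        self._Xc, self._Yc = Xm, Ym
        return self

    def result(self) -> TwoBlockResult:
        return TwoBlockResult(
            x_weights=self.x_weights_,
            y_weights=self.y_weights_,
            singular_values=self.singular_values_,
            x_scores=self.x_scores_,
            y_scores=self.y_scores_,
            score_correlations=self.score_correlations_,
            sample_ids=self.sample_ids_,
        )

    def permutation_test(
        self,
        axis: int = 1,
        n_perm: int = 999,
        seed: int | None = None,
        statistic: str = "axis_correlation",
    ) -> float:
        """Permutation p-value for one axis (1-based).

        Rows of the Y block are permuted uniformly; the statistic (axis
        score correlation or singular value) is recomputed on a fresh
        decomposition each time. Add-one estimator,
        p = (1 + #{perm >= observed}) / (1 + n_perm), with ties counted
        as exceeding (conservative). Resolving p below 1e-4 therefore
        needs at least 10^4 permutations.
        """
        if not hasattr(self, "x_weights_"):
            raise ValidationError("fit the model before testing")
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if not (1 <= axis <= len(self.singular_values_)):
            raise ValidationError(
                f"axis {axis} out of range 1..{len(self.singular_values_)}"
            )
        if statistic not in ("axis_correlation", "singular_value"):
            raise ValidationError(f"unknown statistic {statistic!r}")
        j = axis - 1
        observed = (
            self.score_correlations_[j]
            if statistic == "axis_correlation"
            else self.singular_values_[j]
        )
        rng = np.random.default_rng(seed)
        Xc, Yc = self._Xc, self._Yc
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(Yc.shape[0])
            Yp = Yc[perm]
            U, V, d, _ = _pls_core(Xc, Yp, axis)
            if statistic == "singular_value":
                stat = d[j]
            else:
                stat = _score_correlations((Xc @ U)[:, [j]], (Yp @ V)[:, [j]])[0]
            if stat >= observed:
                exceed += 1
        return (1 + exceed) / (1 + n_perm)


def two_block_pls(X, Y, n_axes: int = 2, center: bool = True) -> TwoBlockResult:
    """Fit a :class:`TwoBlockPLS` and return its result container."""
    return TwoBlockPLS(n_axes=n_axes, center=center).fit(X, Y).result()


def permutation_test(
    X,
    Y,
    axis: int = 1,
    n_perm: int = 999,
    seed: int | None = None,
    statistic: str = "axis_correlation",
    n_axes: int | None = None,
) -> float:
    """Fit 2B-PLS on (X, Y) and permutation-test one axis (1-based)."""
    model = TwoBlockPLS(n_axes=n_axes or max(axis, 2)).fit(X, Y)
    return model.permutation_test(axis=axis, n_perm=n_perm, seed=seed, statistic=statistic)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # variables x components
    explained_variance_ratio: np.ndarray


def pca(block: Block | pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Principal component analysis of a (centered) block.

    Thin wrapper over a standard SVD-based PCA with a deterministic
    sign convention: each component is flipped so its largest-magnitude
    loading is positive. Requesting more components than the rank
    supports truncates with a warning.
    """
    X, _, _ = _as_matrix(block)
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating", UserWarning
        )
        n_components = rank
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T.copy()
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=np.asarray(model.explained_variance_ratio_),
    )
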