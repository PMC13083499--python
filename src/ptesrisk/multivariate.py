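"""Source-apportionment statistics.

The element-association battery used to argue common origin of trace
elements across stations:

* Pearson correlation matrix (pairwise deletion for missing values),
* the KMO measure of sampling adequacy and Bartlett's test of
  sphericity as the gate for PCA (adequate when KMO > 0.5 and
  p < 0.001),
* PCA on the correlation matrix of z-scored concentrations with Kaiser
  retention (eigenvalue > 1),
* two-way agglomerative clustering with Ward linkage on Euclidean
  distances of z-scored data, for elements and for stations.

All statistics are invariant to per-element positive affine rescaling
of the concentrations, so unit choices cannot change the conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import ConcentrationTable

RIDGE_DEFAULT = 1e-8


def _frame(table) -> pd.DataFrame:
    if isinstance(table, ConcentrationTable):
        return table.values
    return pd.DataFrame(table)


def pearson_matrix(table) -> pd.DataFrame:
    """Element × element Pearson correlations with pairwise deletion.

    Zero-variance elements get NaN correlations (undefined, never 0).
    Requires at least 3 complete observations per pair.
    """
    df = _frame(table)
    if len(df) < 3:
        raise ValueError("Pearson correlation needs at least 3 stations")
    both = df.notna().astype(int)
    pair_n = both.T @ both
    if (pair_n.to_numpy()[~np.eye(len(pair_n), dtype=bool)] < 3).any():
        raise ValueError("some element pairs have < 3 complete observations")
    corr = df.corr(method="pearson", min_periods=3)
    return corr


def kmo(corr: pd.DataFrame | np.ndarray, ridge: float = 0.0) -> float:
    """Kaiser–Meyer–Olkin measure of sampling adequacy in [0, 1].

    KMO = Σr²ᵢⱼ / (Σr²ᵢⱼ + Σa²ᵢⱼ) over i≠j, where the anti-image
    partial correlations are aᵢⱼ = −sᵢⱼ/√(sᵢᵢsⱼⱼ) from S = R⁻¹.
    A ridge (e.g. 1e-8) can be added to the diagonal when R is singular.
    """
    R = np.asarray(corr, dtype=float)
    if np.isnan(R).any():
        raise ValueError("correlation matrix contains undefined entries")
    if ridge:
        R = R + ridge * np.eye(len(R))
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; retry with ridge=1e-8"
        ) from err
    d = np.sqrt(np.diag(S))
    partial = -S / np.outer(d, d)
    off = ~np.eye(len(R), dtype=bool)
    r2 = (R[off] ** 2).sum()
    a2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + a2))


def bartlett_sphericity(corr: pd.DataFrame | np.ndarray,
                        n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    χ² = −[(n−1) − (2p+5)/6]·ln det(R) with df = p(p−1)/2; small p
    justifies PCA. ``n`` is the number of observations (stations).
    """
    R = np.asarray(corr, dtype=float)
    p = len(R)
    if n <= p:
        raise ValueError(f"need n > p observations (n={n}, p={p})")
    det = np.linalg.det(R)
    if det <= 0:
        raise ValueError("non-positive determinant: correlation matrix singular")
    chi2 = -((n - 1) - (2 * p + 5) / 6.0) * np.log(det)
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, pval


@dataclass
class PcaResult:
    """Correlation-matrix PCA output with Kaiser retention."""

    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    cum_explained_pct: np.ndarray
    loadings: pd.DataFrame          # element × PC, scaled by sqrt(eigenvalue)
    components: pd.DataFrame        # element × PC, orthonormal eigenvectors
    n_retained: int
    dropped_zero_variance: list[str] = field(default_factory=list)


class CorrelationPCA(BaseEstimator, TransformerMixin):
    """PCA on the correlation matrix of station × element data.

    Columns are z-scored, the correlation matrix eigendecomposed, and
    components sorted by descending eigenvalue. Eigenvalues sum to the
    number of variables; the Kaiser rule retains components with
    eigenvalue > 1. Sign convention: in every component the
    largest-magnitude loading is positive, so outputs are reproducible.
    Zero-variance columns are dropped with a notice.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, table, y=None):
        df = _frame(table)
        if len(df) < 3:
            raise ValueError("PCA needs at least 3 stations")
        variances = df.var(axis=0, ddof=1)
        dropped = variances.index[variances == 0].tolist()
        if dropped:
            import warnings
            warnings.warn(f"dropping zero-variance elements: {dropped}")
            df = df.drop(columns=dropped)
        if df.shape[1] < 2:
            raise ValueError("PCA needs at least 2 elements with variance")
        corr = df.corr().to_numpy()
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        # sign convention: largest |entry| of each component positive
        for j in range(eigvec.shape[1]):
            k = np.argmax(np.abs(eigvec[:, j]))
            if eigvec[k, j] < 0:
                eigvec[:, j] = -eigvec[:, j]
        ncomp = self.n_components or len(eigval)
        pcs = [f"PC{j + 1}" for j in range(len(eigval))]
        self.eigenvalues_ = eigval
        self.explained_pct_ = 100.0 * eigval / eigval.sum()
        self.cum_explained_pct_ = np.cumsum(self.explained_pct_)
        self.components_ = pd.DataFrame(eigvec, index=df.columns, columns=pcs)
        self.loadings_ = self.components_ * np.sqrt(np.clip(eigval, 0, None))
        self.n_retained_ = int((eigval > 1.0).sum())
        self.feature_names_in_ = df.columns.to_numpy()
        self.dropped_zero_variance_ = dropped
        self.mean_ = df.mean(axis=0)
        self.scale_ = df.std(axis=0, ddof=1)
        self._ncomp = min(ncomp, len(eigval))
        return self

    def transform(self, table) -> pd.DataFrame:
        df = _frame(table)[list(self.feature_names_in_)]
        z = (df - self.mean_) / self.scale_
        scores = z.to_numpy() @ self.components_.to_numpy()[:, : self._ncomp]
        return pd.DataFrame(scores, index=df.index,
                            columns=self.components_.columns[: self._ncomp])

    def result(self) -> PcaResult:
        return PcaResult(
            eigenvalues=self.eigenvalues_,
            explained_pct=self.explained_pct_,
            cum_explained_pct=self.cum_explained_pct_,
            loadings=self.loadings_,
            components=self.components_,
            n_retained=self.n_retained_,
            dropped_zero_variance=self.dropped_zero_variance_,
        )


def pca(table, n_components: int | None = None) -> PcaResult:
    """Functional wrapper over :class:`CorrelationPCA`."""
    return CorrelationPCA(n_components=n_components).fit(table).result()


@dataclass
class ClusterResult:
    """Ward/Euclidean agglomerative clustering of one axis."""

    axis: str                   # "elements" | "stations"
    linkage: np.ndarray         # scipy linkage matrix
    labels: pd.Series           # item → cluster id (1..k)
    k: int
    heat_matrix: pd.DataFrame   # z-scored station × element values

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for item, lab in self.labels.items():
            out.setdefault(int(lab), []).append(item)
        return out


class WardClusterer(BaseEstimator):
    """Ward-linkage hierarchical clustering on z-scored concentrations.

    ``axis="elements"`` clusters the element profiles across stations
    (the source-apportionment view); ``axis="stations"`` clusters the
    stations. Merge heights are non-decreasing (Ward linkage on
    Euclidean distance is monotone).
    """

    def __init__(self, axis: str = "elements", k: int = 2):
        self.axis = axis
        self.k = k

    def fit(self, table, y=None):
        if self.axis not in ("elements", "stations"):
            raise ValueError("axis must be elements|stations")
        df = _frame(table)
        z = (df - df.mean(axis=0)) / df.std(axis=0, ddof=1)
        z = z.fillna(0.0)  # zero-variance columns contribute nothing
        mat = z.T if self.axis == "elements" else z
        items = list(mat.index)
        if len(items) < 2:
            raise ValueError("clustering needs at least 2 items")
        if not 1 <= self.k <= len(items):
            raise ValueError(f"k={self.k} outside 1..{len(items)}")
        self.linkage_ = hierarchy.linkage(mat.to_numpy(), method="ward",
                                          metric="euclidean")
        raw = hierarchy.fcluster(self.linkage_, t=self.k, criterion="maxclust")
        self.labels_ = pd.Series(raw, index=items, name="cluster")
        self.heat_matrix_ = z
        return self

    def result(self) -> ClusterResult:
        return ClusterResult(axis=self.axis, linkage=self.linkage_,
                             labels=self.labels_, k=self.k,
                             heat_matrix=self.heat_matrix_)


def ward_cluster(table, axis: str = "elements", k: int = 2) -> ClusterResult:
    """Functional wrapper over :class:`WardClusterer`."""
    return WardClusterer(axis=axis, k=k).fit(table).result()


@dataclass
class GateDecision:
    """KMO + Bartlett gate for PCA adequacy."""

    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    passed: bool
    kmo_threshold: float = 0.5
    p_threshold: float = 0.001


def gate_for_pca(table, kmo_threshold: float = 0.5,
                 p_threshold: float = 0.001,
                 ridge: float = 0.0) -> GateDecision:
    """Decide whether the data are adequate for PCA.

    Passes iff KMO > ``kmo_threshold`` and Bartlett p < ``p_threshold``.
    An identity correlation matrix fails (KMO degenerates to 0/0, which
    is reported as 0 — there is nothing to factor).
    """
    df = _frame(table)
    corr = pearson_matrix(df)
    R = corr.to_numpy()
    off = ~np.eye(len(R), dtype=bool)
    if np.allclose(R[off], 0.0):
        kmo_val = 0.0  # no shared variance at all
    else:
        kmo_val = kmo(R, ridge=ridge)
    chi2, dof, pval = bartlett_sphericity(R, n=len(df))
    return GateDecision(
        kmo=kmo_val, bartlett_chi2=chi2, bartlett_df=dof, bartlett_p=pval,
        passed=bool(kmo_val > kmo_threshold and pval < p_threshold),
        kmo_threshold=kmo_threshold, p_threshold=p_threshold,
    )
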