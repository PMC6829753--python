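"""Sample clustering on methylation feature matrices: raw, PCA- and ICA-based.

Raw clustering is Ward hierarchical clustering on Euclidean distances between
samples' feature vectors (features missing in any sample are dropped
listwise). The decomposition workflows model the centered feature matrix X
(features x samples) as X ~ S.A with S the source/loading matrix (features x
components, scaled to unit variance so loadings are in SD units) and A the
mixing matrix (components x samples); the columns of A are the sample
vectors used for clustering. The "common component" - the component whose
mixing weights are nearly constant across samples, i.e. the shared baseline -
is removed before clustering. Group discrimination per component uses the
exact two-sided Wilcoxon rank-sum test on mixing weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu

from .features import FeatureMatrix


@dataclass
class Decomposition:
    """Sources S (features x components) and mixing A (components x samples)."""

    sources: pd.DataFrame
    mixing: pd.DataFrame
    method: str
    seed: int | None = None
    converged: bool = True
    n_iter: int | None = None

    @property
    def components(self) -> list:
        return list(self.mixing.index)

    @property
    def samples(self) -> list:
        return list(self.mixing.columns)


def _sample_matrix(matrix: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Features x samples frame with listwise-complete features."""
    vals = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    complete = vals.dropna()
    if len(complete) < len(vals):
        warnings.warn(f"dropped {len(vals) - len(complete)} features with "
                      "missing values (listwise deletion)")
    return complete


def cluster_raw(matrix: FeatureMatrix | pd.DataFrame) -> tuple[np.ndarray, list]:
    """Ward linkage on Euclidean distances between samples' raw feature vectors."""
    X = _sample_matrix(matrix)
    Z = linkage(X.T.to_numpy(), method="ward", metric="euclidean")
    return Z, list(X.columns)


def _normalize(S: np.ndarray, A: np.ndarray):
    """Unit-variance sources (loadings in SD units); sign fixed per component."""
    sd = S.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    S = S / sd
    A = A * sd[:, None]
    for k in range(A.shape[0]):
        j = int(np.argmax(np.abs(A[k])))
        if A[k, j] < 0:
            A[k] = -A[k]
            S[:, k] = -S[:, k]
    return S, A


def run_ica(matrix: FeatureMatrix | pd.DataFrame, n_components: int | None = None,
            seed: int = 0, max_iter: int = 2_000, tol: float = 1e-5) -> Decomposition:
    """FastICA decomposition of the feature matrix; seed-reproducible."""
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning
    X = _sample_matrix(matrix)
    n_samples = X.shape[1]
    if n_components is None:
        n_components = n_samples - 1
    if n_components > n_samples:
        raise ValueError(f"n_components ({n_components}) exceeds the number "
                         f"of samples ({n_samples})")
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=max_iter, tol=tol)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        S = ica.fit_transform(X.to_numpy())
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(f"FastICA did not converge (seed={seed}, "
                          f"n_iter={ica.n_iter_}); results may vary", stacklevel=2)
    A = ica.mixing_.T  # components x samples
    S, A = _normalize(S, A)
    ids = [f"IC{k + 1}" for k in range(n_components)]
    return Decomposition(pd.DataFrame(S, index=X.index, columns=ids),
                         pd.DataFrame(A, index=ids, columns=X.columns),
                         "ica", seed=seed, converged=converged,
                         n_iter=getattr(ica, "n_iter_", None))


def run_pca(matrix: FeatureMatrix | pd.DataFrame,
            n_components: int | None = None) -> Decomposition:
    """PCA in the same orientation as ICA: scores are loadings, components_
    rows are per-sample weights; components are variance-sorted/orthogonal."""
    from sklearn.decomposition import PCA
    X = _sample_matrix(matrix)
    n_samples = X.shape[1]
    if n_components is None:
        n_components = n_samples - 1
    pca = PCA(n_components=n_components)
    S = pca.fit_transform(X.to_numpy())
    A = pca.components_
    S, A = _normalize(S, A.copy())
    ids = [f"PC{k + 1}" for k in range(A.shape[0])]
    return Decomposition(pd.DataFrame(S, index=X.index, columns=ids),
                         pd.DataFrame(A, index=ids, columns=X.columns), "pca")


def common_component(dec: Decomposition) -> tuple[str, float]:
    """The component with the lowest coefficient of variation of its mixing
    weights across samples - a near-constant weight marks the shared baseline.
    Returns (component id, its CV)."""
    A = dec.mixing.to_numpy()
    cv = A.std(axis=1, ddof=1) / np.maximum(np.abs(A.mean(axis=1)), 1e-12)
    k = int(np.argmin(cv))
    return dec.components[k], float(cv[k])


def cluster_components(dec: Decomposition, remove_common: bool = True,
                       common_cv_max: float = 0.5) -> tuple[np.ndarray, list]:
    """Ward clustering of samples in component-weight space.

    The common component is removed only when it is clearly identifiable as a
    shared baseline (mixing-weight CV below ``common_cv_max``); when no
    component has near-constant weights, nothing is dropped - distances in
    the full component space then coincide with the raw-feature distances up
    to the decomposition's rotation.
    """
    A = dec.mixing
    if remove_common and len(A) > 1:
        comp, cv = common_component(dec)
        if cv <= common_cv_max:
            A = A.drop(index=comp)
    Z = linkage(A.T.to_numpy(), method="ward", metric="euclidean")
    return Z, list(A.columns)


def cut_clusters(Z: np.ndarray, labels: list, n_clusters: int) -> dict:
    """Flat cluster assignment label -> cluster id."""
    assign = fcluster(Z, t=n_clusters, criterion="maxclust")
    return dict(zip(labels, (int(a) for a in assign)))


def top_contributors(dec: Decomposition, component: str, threshold: float = 5.0,
                     top_n: int | None = None,
                     positive_only: bool = False) -> pd.DataFrame:
    """Features contributing to a component.

    Threshold mode keeps features with |loading| >= threshold (loadings are in
    SD units). ``top_n`` mode instead returns the N strongest features ranked
    by descending loading (descending signed loading when positive_only).
    """
    if component not in dec.sources.columns:
        raise KeyError(f"unknown component {component!r}")
    load = dec.sources[component]
    if top_n is not None:
        ranked = load.sort_values(ascending=False) if positive_only \
            else load.reindex(load.abs().sort_values(ascending=False).index)
        sel = ranked.head(top_n)
    else:
        sel = load[load >= threshold] if positive_only \
            else load[load.abs() >= threshold]
        sel = sel.reindex(sel.abs().sort_values(ascending=False).index)
    return pd.DataFrame({"feature_id": sel.index, "loading": sel.to_numpy()})


def discriminating_components(dec: Decomposition, group_a: list,
                              group_b: list) -> pd.DataFrame:
    """Exact two-sided rank-sum p-value per component for group separation,
    sorted most-discriminating first."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    rows = []
    for comp in dec.components:
        wa = dec.mixing.loc[comp, group_a].to_numpy(float)
        wb = dec.mixing.loc[comp, group_b].to_numpy(float)
        res = mannwhitneyu(wa, wb, alternative="two-sided", method="exact")
        rows.append((comp, float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["component", "p_value"])
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    n = len(labels)
    node = {i: (labels[i], 0.0) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        la, ha = node[int(a)]
        lb, hb = node[int(b)]
        node[n + k] = (f"({la}:{h - ha:.6g},{lb}:{h - hb:.6g})", h)
    return node[n + len(Z) - 1][0] + ";"
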