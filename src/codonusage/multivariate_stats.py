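"""PCA of the gene × 59-codon RSCU matrix and correlation reports.

The RSCU PCA is covariance (column-mean-centred, unscaled) PCA: the 59
RSCU values already share one scale, so no per-column standardisation is
applied. Axis signs are fixed by forcing the largest-magnitude loading
on each axis positive, which makes scores and biplots reproducible
across SVD implementations. Missing RSCU entries (amino acid absent from
a gene) are imputed as 0 before decomposition.

Correlation reports give Pearson r with the two-tailed p-value from the
t distribution on n−2 degrees of freedom, plus the conventional
significance stars (p < 0.05/0.01/0.001/0.0001). An optional
Benjamini–Hochberg q-value column can be added; the stars are always
computed from raw p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = ["PcaResult", "RscuPCA", "pca_rscu", "correlate"]


@dataclass(frozen=True)
class PcaResult:
    variance_fraction: np.ndarray  # percent per axis, non-increasing
    scores: pd.DataFrame  # genes × axes
    loadings: pd.DataFrame  # codons × axes


class RscuPCA(TransformerMixin, BaseEstimator):
    """Covariance PCA of an RSCU matrix with deterministic axis signs.

    Parameters
    ----------
    n_components
        Number of axes to keep; None keeps all.

    Fitted attributes: ``variance_fraction_`` (percent per axis),
    ``loadings_`` (codons × axes DataFrame), ``mean_``. ``transform``
    returns gene scores; ``fit_transform`` also stores them as
    ``scores_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def _clean(self, X) -> pd.DataFrame:
        df = pd.DataFrame(X).astype(float)
        if df.shape[0] < 3:
            raise ValueError("PCA needs at least 3 genes")
        return df.fillna(0.0)

    def fit(self, X, y=None):
        df = self._clean(X)
        pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(df.to_numpy())
        components = pca.components_  # axes × codons
        # fix axis orientation: largest-|loading| entry positive
        for i, row in enumerate(components):
            if row[np.argmax(np.abs(row))] < 0:
                components[i] = -row
        self._pca = pca
        self.mean_ = pca.mean_
        self.components_ = components
        self.variance_fraction_ = 100.0 * pca.explained_variance_ratio_
        axes = [f"PC{i + 1}" for i in range(components.shape[0])]
        self.loadings_ = pd.DataFrame(
            components.T, index=df.columns, columns=axes
        )
        self.feature_names_in_ = np.asarray(df.columns)
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        df = pd.DataFrame(X).astype(float).fillna(0.0)
        scores = (df.to_numpy() - self.mean_) @ self.components_.T
        return pd.DataFrame(
            scores, index=df.index, columns=self.loadings_.columns
        )

    def fit_transform(self, X, y=None):
        self.fit(X)
        self.scores_ = self.transform(X)
        return self.scores_


def pca_rscu(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """Functional wrapper around :class:`RscuPCA`."""
    est = RscuPCA(n_components=n_components)
    scores = est.fit_transform(matrix)
    return PcaResult(est.variance_fraction_, scores, est.loadings_)


_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cut, label in _STAR_LEVELS:
        if p < cut:
            return label
    return "NS"


def correlate(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | str = "all",
    bh_column: bool = False,
) -> pd.DataFrame:
    """Pearson correlation report over column pairs of a numeric table.

    Parameters
    ----------
    table
        Numeric columns, one row per gene. Rows with a missing value in
        either member of a pair are dropped pairwise.
    pairs
        Explicit (column_a, column_b) pairs, or ``"all"`` for every
        unordered pair.
    bh_column
        Add a Benjamini–Hochberg adjusted q-value column (the stars stay
        based on raw p, matching conventional reporting).

    Returns
    -------
    DataFrame with columns variable_a, variable_b, n, pearson_r,
    p_value, significance; pairs with a zero-variance column get NaN r
    and significance "NS".
    """
    if pairs == "all":
        pair_list = list(itertools.combinations(table.columns, 2))
    else:
        pair_list = list(pairs)

    rows = []
    for a, b in pair_list:
        sub = table[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"fewer than 3 complete observations for ({a}, {b})")
        x = sub[a].to_numpy(dtype=float)
        y = sub[b].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            rows.append((a, b, n, np.nan, np.nan, "NS"))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((a, b, n, float(r), float(p), _stars(float(p))))

    out = pd.DataFrame(
        rows,
        columns=["variable_a", "variable_b", "n", "pearson_r", "p_value", "significance"],
    )
    if bh_column:
        q = np.full(len(out), np.nan)
        mask = out["p_value"].notna().to_numpy()
        if mask.any():
            q[mask] = stats.false_discovery_control(
                out.loc[mask, "p_value"].to_numpy()
            )
        out["bh_q_value"] = q
    return out
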