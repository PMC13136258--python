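"""PCA-based comprehensive evaluation and elite-accession screening.

All traits (qualitative ones as their numeric codes) are Z-score
standardized; PCA is the eigendecomposition of the trait correlation
matrix.  Components with eigenvalue > 1 are retained, each retained
component i receives the weight

    W_i = c_i / sum_{j <= k} c_j

where c_i is its variance contribution rate (%), and every accession
gets the composite score F = W_1 F_1 + ... + W_k F_k over its
standardized (unit-variance) component scores.  Accessions with
F > 1.00 (or the top N by rank) are flagged elite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from germdiv.phenotype import correlation_matrix


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # all p, non-increasing
    contributions: np.ndarray  # percent of total variance, sums to 100
    cumulative: np.ndarray
    loadings: pd.DataFrame  # trait x component, loading = eigvec * sqrt(lambda)
    scores: pd.DataFrame  # accession x retained component, unit variance
    retained: int  # count(lambda > 1)
    communalities: pd.Series  # per trait, over retained components

    @property
    def retained_contributions(self) -> np.ndarray:
        return self.contributions[: self.retained]


@dataclass
class CompositeScore:
    weights: np.ndarray  # W1..Wk, sums to 1
    f: pd.Series  # per-accession composite score
    rank: pd.Series  # 1 = best; ties broken by accession id
    elite: pd.Series  # boolean flag


def zscore(table, *, ddof: int = 1) -> pd.DataFrame:
    """Z-score standardize every column (mean 0, sample SD 1).

    Accepts a TraitTable or a numeric DataFrame.  Zero-variance columns
    are dropped with a warning; missing cells are preserved.
    """
    df = table.values if hasattr(table, "trait_names") else table
    df = df.astype(float)
    sd = df.std(ddof=ddof)
    dead = sd.index[sd == 0].tolist()
    if dead:
        warnings.warn(f"dropping zero-variance columns: {dead}")
        df = df.drop(columns=dead)
        sd = sd.drop(dead)
    return (df - df.mean()) / sd


def pca(ztable: pd.DataFrame, *, eigen_threshold: float = 1.0) -> PCAResult:
    """Eigenvalue-threshold PCA on the trait correlation matrix.

    Missing cells are mean-imputed (i.e. zero after standardization)
    with a warning.  Component scores are standardized to unit sample
    variance.  Each component is oriented so its largest-|loading| trait
    loads positively (the sign of a component is otherwise arbitrary).
    """
    z = ztable.astype(float)
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("need >= 2 accessions and >= 2 traits")
    if z.isna().any().any():
        warnings.warn("missing cells mean-imputed before PCA")
        z = z.fillna(0.0)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("correlation matrix contains non-finite entries")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # orient: largest-|loading| trait positive per component
    for j in range(eigvecs.shape[1]):
        i_max = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i_max, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    total = eigvals.sum()
    contributions = eigvals / total * 100.0
    retained = int(np.sum(eigvals > eigen_threshold))
    retained = max(retained, 1)
    comp_names = [f"PC{i + 1}" for i in range(len(eigvals))]
    loadings = pd.DataFrame(
        eigvecs * np.sqrt(eigvals), index=z.columns, columns=comp_names
    )
    raw_scores = z.to_numpy() @ eigvecs[:, :retained]
    sds = raw_scores.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    scores = pd.DataFrame(
        raw_scores / sds, index=z.index, columns=comp_names[:retained]
    )
    communalities = (loadings.iloc[:, :retained] ** 2).sum(axis=1)
    return PCAResult(
        eigenvalues=eigvals,
        contributions=contributions,
        cumulative=np.cumsum(contributions),
        loadings=loadings,
        scores=scores,
        retained=retained,
        communalities=communalities,
    )


def component_weights(contributions, k: int | None = None) -> np.ndarray:
    """Weight coefficients W_i = c_i / cumulative contribution of the
    retained set; returns an array summing to 1."""
    c = np.asarray(contributions, dtype=float)
    if k is None:
        k = len(c)
    if k < 1:
        raise ValueError("need at least one retained component")
    c = c[:k]
    cum = c.sum()
    if cum <= 0:
        raise ValueError("cumulative contribution is zero")
    return c / cum


def composite_scores(
    scores: pd.DataFrame,
    weights,
    *,
    elite_threshold: float = 1.0,
) -> CompositeScore:
    """Composite score F = sum_i W_i F_i per accession, with descending
    rank (ties broken lexicographically by accession id) and the default
    F > 1.00 elite flag."""
    w = np.asarray(weights, dtype=float)
    if scores.shape[1] != len(w):
        raise ValueError(
            f"score matrix has {scores.shape[1]} components but {len(w)} weights"
        )
    f = pd.Series(scores.to_numpy() @ w, index=scores.index, name="F")
    order = sorted(f.index, key=lambda a: (-f[a], str(a)))
    rank = pd.Series({a: i + 1 for i, a in enumerate(order)}, name="rank").reindex(f.index)
    elite = f > elite_threshold
    return CompositeScore(weights=w, f=f, rank=rank, elite=elite)


def screen_elite(
    cs: CompositeScore,
    *,
    mode: str = "threshold",
    threshold: float = 1.0,
    n: int | None = None,
) -> pd.Index:
    """Select elite accessions either by F > threshold (default 1.00) or
    as the top N ranked accessions; returns their ids best-first."""
    order = cs.rank.sort_values().index
    if mode == "threshold":
        return pd.Index([a for a in order if cs.f[a] > threshold])
    if mode == "top_n":
        if n is None:
            raise ValueError("top_n mode needs n")
        if n > len(order):
            warnings.warn(f"requested top {n} of {len(order)} accessions; clipping")
            n = len(order)
        return pd.Index(order[:n])
    raise ValueError(f"unknown mode {mode!r}")


def score_trait_correlations(f: pd.Series, table) -> pd.DataFrame:
    """Correlate the composite score F with every trait.

    Returns per-trait (r, p, stars) plus columns are ordered as in the
    table; also useful to count traits significant at 0.05 and 0.01.
    """
    df = table.values if hasattr(table, "trait_names") else table
    joint = df.copy()
    joint.insert(0, "__F__", f.reindex(df.index))
    cm = correlation_matrix(joint)
    out = pd.DataFrame(
        {
            "r": cm.r["__F__"].drop("__F__"),
            "p": cm.p["__F__"].drop("__F__"),
            "n": cm.n["__F__"].drop("__F__"),
            "stars": cm.stars()["__F__"].drop("__F__"),
        }
    )
    out.index.name = "trait"
    return out


def evaluate(table, *, eigen_threshold: float = 1.0,
             elite_threshold: float = 1.0) -> tuple[PCAResult, CompositeScore]:
    """One-call pipeline: standardize, PCA, weights, composite F."""
    z = zscore(table)
    res = pca(z, eigen_threshold=eigen_threshold)
    w = component_weights(res.contributions, res.retained)
    cs = composite_scores(res.scores, w, elite_threshold=elite_threshold)
    return res, cs
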