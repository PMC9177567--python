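"""Individual-fingerprint statistics.

SV profiles (and prophage/CRISPR-spacer repertoires) are highly distinct
between individuals and stable within one individual over time.  This module
quantifies that: per-Mb SV-rate comparisons between inter- and
intra-individual sample pairs (two-sided Wilcoxon rank-sum), Jaccard
distances on presence/absence feature matrices, classical-scaling PCoA, and
Procrustes superimposition with a permutation test (protest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


def pairwise_sv_rates(
    presence: pd.DataFrame,
    genome_size_bp: int,
    species: str = "sp",
) -> pd.DataFrame:
    """Per-Mb SV rate for every sample pair from a binary SV-presence matrix:
    the number of differing pool SVs, normalised per 1 Mb of genome."""
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    x = presence.to_numpy(dtype=int)
    diff = (x[:, None, :] != x[None, :, :]).sum(axis=2)
    samples = list(presence.index)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            rows.append(
                {
                    "species": species,
                    "sample_a": samples[i],
                    "sample_b": samples[j],
                    "rate_per_mb": diff[i, j] * 1e6 / genome_size_bp,
                }
            )
    return pd.DataFrame(rows, columns=["species", "sample_a", "sample_b", "rate_per_mb"])


def classify_pairs(
    sv_rates: pd.DataFrame,
    sample_to_individual: dict[str, str],
) -> pd.DataFrame:
    """Label each same-species sample pair inter- or intra-individual."""
    out = sv_rates.copy()
    for col in ("sample_a", "sample_b"):
        unknown = set(out[col]) - set(sample_to_individual)
        if unknown:
            raise ValueError(f"samples without an individual label: {sorted(unknown)}")
    ind_a = out["sample_a"].map(sample_to_individual)
    ind_b = out["sample_b"].map(sample_to_individual)
    out["comparison_class"] = np.where(
        ind_a == ind_b, "intra_individual", "inter_individual"
    )
    return out


def wilcoxon_rank_sum(
    x,
    y,
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U with midranks).

    Exact enumeration when the combined n is <= ``exact_max_n`` and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U statistic of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return (x.size * y.size / 2.0, 1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return (float(res.statistic), float(res.pvalue))


def jaccard_distance_matrix(
    presence: pd.DataFrame,
    empty_pair: str = "zero",
) -> pd.DataFrame:
    """Pairwise Jaccard distances d = 1 - |A&B| / |A|B| between sample rows.

    Two samples with empty feature sets are at distance 0 by default
    (identical emptiness); ``empty_pair='na'`` reports NaN instead.
    """
    x = presence.to_numpy()
    if not np.isin(x, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    b = x.astype(bool)
    if len(presence) < 2:
        d = np.zeros((len(presence), len(presence)))
    else:
        d = squareform(pdist(b, metric="jaccard"))
    if empty_pair == "na":
        empty = ~b.any(axis=1)
        pair_empty = np.outer(empty, empty)
        np.fill_diagonal(pair_empty, False)
        d[pair_empty] = np.nan
    elif empty_pair != "zero":
        raise ValueError("empty_pair must be 'zero' or 'na'")
    return pd.DataFrame(d, index=presence.index, columns=presence.index)


@dataclass
class Ordination:
    """Sample coordinates from classical scaling plus retained eigenvalues."""

    coordinates: np.ndarray  # samples x k, column means ~ 0
    eigenvalues: np.ndarray  # non-increasing
    sample_ids: list[str]


def pcoa(distances: pd.DataFrame | np.ndarray, k: int = 2) -> Ordination:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centres the squared-distance Gram matrix and keeps the top-k
    positive eigenpairs; negative eigenvalues (non-Euclidean input) are
    dropped with a warning, and k is reduced if fewer positive eigenvalues
    exist.
    """
    if isinstance(distances, pd.DataFrame):
        ids = [str(i) for i in distances.index]
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        ids = [f"s{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distances must be a symmetric square matrix")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if k < 1:
        raise ValueError("k must be >= 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(evals[0]), 1.0))
    if (evals < -tol).any():
        warnings.warn("negative eigenvalues dropped (distances not Euclidean)")
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        warnings.warn("no positive eigenvalues; returning zero coordinates")
        return Ordination(np.zeros((n, k)), np.zeros(k), ids)
    if k > n_pos:
        warnings.warn(f"k reduced from {k} to {n_pos} positive eigenvalues")
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    return Ordination(coords, evals[:k], ids)


@dataclass
class ProtestResult:
    m2: float
    correlation: float
    p: float
    n_perm: int


def _as_config(x) -> np.ndarray:
    if isinstance(x, Ordination):
        return np.asarray(x.coordinates, dtype=float)
    return np.asarray(x, dtype=float)


def _normalize_config(z: np.ndarray) -> np.ndarray:
    zc = z - z.mean(axis=0)
    norm = np.sqrt((zc**2).sum())
    if norm == 0:
        raise ValueError("degenerate configuration (all points identical)")
    return zc / norm


def protest(
    x,
    y,
    n_perm: int = 999,
    seed: int = 0,
) -> ProtestResult:
    """Procrustes superimposition with a permutation test.

    Both configurations are centred and scaled to unit trace; the optimal
    rotation gives the residual m2 = 1 - (sum of singular values of X'Y)^2
    and correlation sqrt(1 - m2).  Significance permutes the row order of
    the second configuration: p = (1 + #{m2_perm <= m2_obs}) / (n_perm + 1),
    so the smallest attainable p at 999 permutations is exactly 0.001.
    """
    xa, ya = _as_config(x), _as_config(y)
    if xa.ndim == 1:
        xa = xa[:, None]
    if ya.ndim == 1:
        ya = ya[:, None]
    if xa.shape[0] != ya.shape[0]:
        raise ValueError("configurations must have the same samples")
    n = xa.shape[0]
    if n < 3:
        raise ValueError("protest needs at least 3 samples")
    k = max(xa.shape[1], ya.shape[1])
    if xa.shape[1] < k:
        xa = np.hstack([xa, np.zeros((n, k - xa.shape[1]))])
    if ya.shape[1] < k:
        ya = np.hstack([ya, np.zeros((n, k - ya.shape[1]))])
    xn, yn = _normalize_config(xa), _normalize_config(ya)

    def m2_of(yperm: np.ndarray) -> float:
        t = np.linalg.svd(xn.T @ yperm, compute_uv=False).sum()
        return max(0.0, 1.0 - t * t)

    m2 = m2_of(yn)
    corr = float(min(1.0, np.sqrt(max(0.0, 1.0 - m2))))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if m2_of(yn[rng.permutation(n)]) <= m2 + 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return ProtestResult(m2=float(m2), correlation=corr, p=float(p), n_perm=n_perm)
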