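"""Abundance-table preprocessing and community-level diversity analysis.

Preprocessing follows the 16S workflow for the multibreed herd: rarefaction
to a fixed depth, a prevalence-based "core taxa" filter (nonzero in at
least half the animals of a growth stage), and a log10 transform in which
half of the detection limit (0.00004613) is added to every value of any
taxon that contains zeros.  Community analysis uses the Shannon index,
Bray-Curtis dissimilarity, classical PCoA, and a permutation PERMANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sympy.utilities.iterables import multiset_permutations

HALF_DETECTION_LIMIT = 0.00004613
RAREFACTION_DEPTH = 10840


def core_taxa_filter(
    table: pd.DataFrame, min_prevalence: float = 0.5
) -> pd.DataFrame:
    """Keep taxa with nonzero abundance in >= ``min_prevalence`` of samples.

    The threshold is inclusive: a taxon present in exactly half the samples
    is core at the default 0.5.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    if table.empty:
        raise ValueError("abundance table is empty")
    prevalence = (table > 0).mean(axis=0)
    return table.loc[:, prevalence >= min_prevalence].copy()


def log10_floor_transform(
    table: pd.DataFrame, half_floor: float = HALF_DETECTION_LIMIT
) -> pd.DataFrame:
    """Log10-transform relative abundances with a per-taxon detection floor.

    For each taxon that contains at least one zero, ``half_floor`` (half of
    the 16S detection limit) is added to all of that taxon's values before
    the log; taxa observed in every sample are transformed unchanged.
    """
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundances are not valid")
    has_zero = (values == 0).any(axis=0)
    shifted = values + np.where(has_zero, half_floor, 0.0)
    return pd.DataFrame(
        np.log10(shifted), index=table.index, columns=table.columns
    )


def rarefy(
    counts: pd.DataFrame, depth: int = RAREFACTION_DEPTH, seed: int | None = None
) -> pd.DataFrame:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below the depth are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("rarefaction requires integer counts")
        values = np.round(values).astype(np.int64)
    rng = np.random.default_rng(seed)
    totals = values.sum(axis=1)
    keep = totals >= depth
    dropped = list(counts.index[~keep])
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} sample(s) below depth {depth}: {dropped}"
        )
    rows = []
    for i in np.flatnonzero(keep):
        if totals[i] == depth:
            rows.append(values[i])
        else:
            rows.append(rng.multivariate_hypergeometric(values[i], depth))
    return pd.DataFrame(
        np.array(rows, dtype=np.int64),
        index=counts.index[keep],
        columns=counts.columns,
    )


def shannon_index(abundances, base: float = 2.0) -> float:
    """Shannon diversity ``H = -sum p log p`` (log base 2 by default)."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero sample has undefined diversity")
    p = p[p > 0] / total
    return float(-(p * np.log(p) / np.log(base)).sum())


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)``."""
    if len(table) < 2:
        raise ValueError("need at least two samples")
    values = table.to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).sum() >= 2:
        raise ValueError(
            "Bray-Curtis is undefined between two all-zero samples"
        )
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in table.index])


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues


def pcoa(dm: DistanceMatrix, k_axes: int | None = None) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower-centers ``-D**2 / 2``, eigendecomposes, and returns coordinates on
    the top-k positive eigenvalues; negative eigenvalues are reported but
    their axes are never returned.
    """
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > 1e-12 * max(1.0, abs(eigval[0]))
    n_pos = int(positive.sum())
    if k_axes is None:
        k = n_pos
    else:
        if k_axes > n_pos:
            warnings.warn(
                f"only {n_pos} positive eigenvalues; truncating to {n_pos}"
            )
        k = min(k_axes, n_pos)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k]) if k else np.zeros((n, 0))
    prop = (
        eigval[:n_pos] / eigval[:n_pos].sum() if n_pos else np.array([])
    )
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords,
            index=list(dm.ids),
            columns=[f"PCo{i+1}" for i in range(k)],
        ),
        eigenvalues=eigval,
        proportion_explained=prop,
    )


@dataclass
class PermanovaResult:
    statistic: float  # pseudo-F
    p_value: float
    n_permutations: int
    method: str  # "sampled" or "exhaustive"


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F of the distance partition for a label vector."""
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g_val, cnt in zip(groups, counts):
        idx = np.flatnonzero(labels == g_val)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(cnt, k=1)].sum() / cnt
    ss_between = ss_total - ss_within
    g = len(groups)
    denom = ss_within / (n - g)
    num = ss_between / (g - 1)
    if denom == 0:
        return np.inf if num > 0 else 0.0
    return num / denom


def _n_distinct_assignments(counts: np.ndarray) -> float:
    from math import factorial

    total = factorial(int(counts.sum()))
    for c in counts:
        total //= factorial(int(c))
    return total


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA by raw label permutation.

    When the number of distinct label assignments does not exceed
    ``n_perm`` the test enumerates them exhaustively; otherwise ``n_perm``
    random shuffles are drawn and ``p = (#{F_perm >= F_obs} + 1)/(n_perm + 1)``
    (ties count toward the numerator).
    """
    labels = np.asarray(pd.factorize(np.asarray(grouping))[0])
    if len(labels) != dm.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, labels)

    n_distinct = _n_distinct_assignments(counts)
    if n_distinct <= n_perm:
        hits = 0
        total = 0
        for perm in multiset_permutations(list(labels)):
            total += 1
            if _pseudo_f(d2, np.asarray(perm)) >= f_obs:
                hits += 1
        return PermanovaResult(
            statistic=float(f_obs),
            p_value=hits / total,
            n_permutations=total,
            method="exhaustive",
        )

    rng = np.random.default_rng(seed)
    hits = 0
    work = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if _pseudo_f(d2, work) >= f_obs:
            hits += 1
    return PermanovaResult(
        statistic=float(f_obs),
        p_value=(hits + 1) / (n_perm + 1),
        n_permutations=n_perm,
        method="sampled",
    )
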