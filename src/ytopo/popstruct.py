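"""Between-population structure statistics from Y-STR haplotypes.

PhiST is the two-level AMOVA fixation index computed from squared
inter-haplotype distances: with N individuals in K groups,

    SS_total  = (1/2N) * sum_xy d2_xy
    SS_within = sum_k (1/2n_k) * sum_{xy in k} d2_xy
    SS_among  = SS_total - SS_within
    MS_among  = SS_among / (K - 1),  MS_within = SS_within / (N - K)
    n_prime   = (N - sum_k n_k^2 / N) / (K - 1)
    sigma2_a  = (MS_among - MS_within) / n_prime
    PhiST     = sigma2_a / (sigma2_a + MS_within)

Significance comes from permuting individuals across groups; P uses the
(b+1)/(m+1) convention.  Shannon mutual information between group label
and haplotype identity (natural log) serves as an alternative
differentiation measure, and principal coordinates analysis embeds a
distance matrix through eigendecomposition of its Gower-centered form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .strprofiles import NumericHaplotype

__all__ = [
    "haplotype_distance_matrix", "amova_phist", "phist_from_distances",
    "pairwise_phist", "shannon_mutual_information", "pcoa",
    "PcoaResult", "PairwiseDistanceResult",
]


def haplotype_distance_matrix(haplotypes: Sequence[NumericHaplotype],
                              metric: str = "sum-squared-repeat") -> np.ndarray:
    """Squared inter-individual distance matrix.

    ``sum-squared-repeat``: sum over jointly non-missing loci of squared
    repeat-length differences.  ``count-different-loci``: number of
    differing loci.  A pair with no jointly typed locus is an error.
    """
    if metric not in ("sum-squared-repeat", "count-different-loci"):
        raise ValueError(f"unknown metric {metric!r}")
    X = np.array([h.as_array() for h in haplotypes], dtype=float)
    n = len(X)
    present = ~np.isnan(X)
    Xz = np.where(present, X, 0.0)
    overlap = present.astype(float) @ present.astype(float).T
    if n and np.any(overlap[~np.eye(n, dtype=bool)] == 0):
        i, j = np.argwhere((overlap == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(f"haplotypes {i} and {j} share no typed locus")
    D = np.zeros((n, n))
    for i in range(n):
        ok = present[i] & present
        diff = np.where(ok, Xz - Xz[i], 0.0)
        if metric == "sum-squared-repeat":
            D[i] = np.sum(diff ** 2, axis=1)
        else:
            D[i] = np.sum(np.abs(diff) > 1e-9, axis=1)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _ss_decomposition(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_among, SS_within) from a squared-distance matrix and labels."""
    N = len(groups)
    ss_total = d2.sum() / (2.0 * N)
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total - ss_within, ss_within


def phist_from_distances(d2: np.ndarray, groups: Sequence) -> float:
    """PhiST point estimate from a squared-distance matrix and group labels.

    Negative estimates are reported as computed, not clamped.
    """
    groups = np.asarray(groups)
    labels, sizes = np.unique(groups, return_counts=True)
    K, N = len(labels), len(groups)
    if K < 2:
        raise ValueError("need at least 2 groups")
    if np.any(sizes < 2):
        small = labels[sizes < 2]
        raise ValueError(f"groups need n >= 2, too small: {list(small)}")
    ss_among, ss_within = _ss_decomposition(d2, groups)
    ms_among = ss_among / (K - 1)
    ms_within = ss_within / (N - K)
    n_prime = (N - np.sum(sizes ** 2) / N) / (K - 1)
    sigma2_a = (ms_among - ms_within) / n_prime
    denom = sigma2_a + ms_within
    if denom == 0:
        return 0.0
    return float(sigma2_a / denom)


def amova_phist(samples: Mapping[str, Sequence[NumericHaplotype]],
                metric: str = "sum-squared-repeat",
                n_perm: int = 5000, seed: int | None = None,
                ) -> tuple[float, float]:
    """PhiST between >= 2 groups with a permutation P value.

    Individuals are shuffled across groups; P is the proportion of
    permutations with PhiST >= observed, with +1 in numerator and
    denominator.
    """
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    haps = [h for g in labels for h in samples[g]]
    groups = np.array([g for g in labels for _ in samples[g]], dtype=object)
    d2 = haplotype_distance_matrix(haps, metric)
    observed = phist_from_distances(d2, groups)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if phist_from_distances(d2, perm) >= observed - 1e-12:
            hits += 1
    return observed, (hits + 1) / (n_perm + 1)


@dataclass(frozen=True)
class PairwiseDistanceResult:
    """Pairwise population distances with permutation P values."""

    labels: tuple[str, ...]
    estimates: np.ndarray       # symmetric, zero diagonal
    pvalues: np.ndarray         # symmetric; NaN on the diagonal
    n_permutations: int
    metric: str

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = list(self.labels)
        return (pd.DataFrame(self.estimates, index=idx, columns=idx),
                pd.DataFrame(self.pvalues, index=idx, columns=idx))


def pairwise_phist(samples: Mapping[str, Sequence[NumericHaplotype]],
                   metric: str = "sum-squared-repeat",
                   n_perm: int = 5000, seed: int | None = None,
                   ) -> PairwiseDistanceResult:
    """PhiST and permutation P for every pair of population samples."""
    labels = [g for g in samples if len(samples[g]) >= 2]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    k = len(labels)
    est = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=k * k)
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        phi, p = amova_phist({a: samples[a], b: samples[b]}, metric,
                             n_perm, int(seeds[i * k + j]))
        est[i, j] = est[j, i] = phi
        pvals[i, j] = pvals[j, i] = p
    return PairwiseDistanceResult(tuple(labels), est, pvals, n_perm, metric)


# ---------------------------------------------------------------------------
# Shannon mutual information

def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def shannon_mutual_information(samples: Mapping[str, Sequence],
                               mode: str = "haplotype") -> float:
    """Mutual information between population label and haplotype identity.

    I = H_pooled - sum_k (n_k / N) H_k with plug-in entropies in nats.
    ``mode='haplotype'`` treats the whole haplotype as one allele;
    ``mode='per-locus'`` averages the same quantity over loci.
    """
    from .strprofiles import _hashable

    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for g, haps in samples.items():
        if len(haps) == 0:
            raise ValueError(f"group {g!r} is empty")
    if mode == "haplotype":
        keys = {g: [_hashable(h) for h in haps] for g, haps in samples.items()}
        return _label_information(keys)
    if mode != "per-locus":
        raise ValueError("mode must be 'haplotype' or 'per-locus'")
    some = next(iter(samples.values()))[0]
    n_loci = len(some.loci)
    vals = []
    for locus_i in range(n_loci):
        keys = {}
        for g, haps in samples.items():
            keys[g] = [(h.values[locus_i] if not h.missing[locus_i] else None)
                       for h in haps]
        vals.append(_label_information(keys))
    return float(np.mean(vals))


def _label_information(keys_by_group: Mapping[str, Sequence]) -> float:
    alphabet = sorted({k for ks in keys_by_group.values() for k in ks},
                      key=repr)
    index = {k: i for i, k in enumerate(alphabet)}
    N = sum(len(ks) for ks in keys_by_group.values())
    pooled = np.zeros(len(alphabet))
    within = 0.0
    for ks in keys_by_group.values():
        counts = np.zeros(len(alphabet))
        for k in ks:
            counts[index[k]] += 1
        pooled += counts
        within += (len(ks) / N) * _entropy(counts)
    return max(0.0, _entropy(pooled) - within)


# ---------------------------------------------------------------------------
# principal coordinates analysis

@dataclass(frozen=True)
class PcoaResult:
    coordinates: np.ndarray       # n x n_positive_axes
    eigenvalues: np.ndarray       # all eigenvalues, decreasing
    variance_fraction: np.ndarray  # per positive axis, of positive total

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(distance_matrix: np.ndarray, atol: float = 1e-8) -> PcoaResult:
    """Classical metric MDS of a distance matrix.

    Gower-centers -0.5 * D^2, eigendecomposes, and scales eigenvectors by
    the square roots of their (positive) eigenvalues.  Negative
    eigenvalues are reported but excluded from variance fractions.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=atol):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(atol, atol * abs(eigval[0]) if n else 0)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    total = eigval[pos].sum()
    frac = eigval[pos] / total if total > 0 else np.array([])
    return PcoaResult(coordinates=coords, eigenvalues=eigval,
                      variance_fraction=frac)
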