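"""Multivariate spatial autocorrelation of haplotypes against geography.

The autocorrelation coefficient r follows the multivariate approach of
Smouse & Peakall: squared genetic distances between individuals are
Gower-centered into a covariance-analog matrix C, geographic
(road-distance) pairs are binned into distance classes, and per class h

    r(h) = sum_{x != y, (x,y) in h} c_xy / sum_x m_x(h) * c_xx

with m_x(h) the number of class-h pairs involving individual x.  The null
distribution comes from random shuffling of individuals across locations
(permutation envelope, one-sided P per class); bootstrap resampling of
pairs within a class yields confidence intervals; the overall correlogram
significance uses omega = sum_h r(h)^2 against the joint permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "gower_center", "build_distance_classes", "autocorrelogram",
    "omega_overall_test", "Correlogram", "DistanceClasses",
]


def gower_center(d2: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Gower-center a squared distance matrix.

    c_xy = -0.5 * (d2_xy - rowmean_x - colmean_y + grandmean).  For
    Euclidean squared distances of centered points this is the Gram
    matrix of the configuration.
    """
    d2 = np.asarray(d2, dtype=float)
    if d2.ndim != 2 or d2.shape[0] != d2.shape[1]:
        raise ValueError("squared distance matrix must be square")
    if not np.allclose(d2, d2.T, atol=atol):
        raise ValueError("squared distance matrix must be symmetric")
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    grand = d2.mean()
    return -0.5 * (d2 - row - col + grand)


@dataclass(frozen=True)
class DistanceClasses:
    """Assignment of individual pairs to geographic distance classes."""

    class_of_pair: np.ndarray    # n x n int; -1 on the diagonal
    edges: np.ndarray            # (k, 2) km range [min, max] per class
    n_classes: int

    @property
    def pair_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_classes, dtype=int)
        iu = np.triu_indices_from(self.class_of_pair, k=1)
        for h in range(self.n_classes):
            counts[h] = int(np.sum(self.class_of_pair[iu] == h))
        return counts


def build_distance_classes(geo_dist: np.ndarray, scheme: str = "even-pair-counts",
                           k: int | None = None,
                           edges: Sequence[float] | None = None,
                           ) -> DistanceClasses:
    """Bin individual pairs by geographic distance.

    ``even-pair-counts`` sorts the C(n,2) pairs by distance (stable pair
    order breaking ties) and splits them into k classes of near-equal
    size, larger classes first.  ``fixed-edges`` bins by supplied km
    edges, the last bin closed.  An empty class is an error.
    """
    D = np.asarray(geo_dist, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("geographic distance matrix must be square")
    iu = np.triu_indices(n, k=1)
    dists = D[iu]
    npairs = len(dists)
    if npairs == 0:
        raise ValueError("need at least one pair")
    assign = np.full((n, n), -1, dtype=int)

    if scheme == "even-pair-counts":
        if not k or k < 1:
            raise ValueError("even-pair-counts scheme needs k >= 1")
        if k > npairs:
            raise ValueError(f"k={k} classes but only {npairs} pairs")
        order = np.argsort(dists, kind="stable")
        base, rem = divmod(npairs, k)
        sizes = [base + 1] * rem + [base] * (k - rem)
        edge_list, pos = [], 0
        for h, size in enumerate(sizes):
            sel = order[pos:pos + size]
            pos += size
            edge_list.append((float(dists[sel].min()), float(dists[sel].max())))
            assign[iu[0][sel], iu[1][sel]] = h
        edges_arr = np.array(edge_list)
        n_classes = k
    elif scheme == "fixed-edges":
        if edges is None or len(edges) < 2:
            raise ValueError("fixed-edges scheme needs >= 2 edge values")
        e = np.asarray(edges, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing")
        n_classes = len(e) - 1
        cls = np.digitize(dists, e[1:-1], right=False)
        out = (dists < e[0]) | (dists > e[-1])
        if np.any(out):
            raise ValueError("some pair distances fall outside the supplied edges")
        assign[iu] = cls
        edges_arr = np.column_stack([e[:-1], e[1:]])
        for h in range(n_classes):
            if not np.any(cls == h):
                raise ValueError(f"distance class {h} ({e[h]}-{e[h+1]} km) is empty")
    else:
        raise ValueError("scheme must be 'even-pair-counts' or 'fixed-edges'")

    assign = np.maximum(assign, assign.T)
    np.fill_diagonal(assign, -1)
    return DistanceClasses(class_of_pair=assign, edges=edges_arr,
                           n_classes=n_classes)


@dataclass(frozen=True)
class Correlogram:
    """Per-distance-class autocorrelation with resampling uncertainty."""

    edges: np.ndarray            # (k, 2) km
    r: np.ndarray                # observed r per class
    n_pairs: np.ndarray
    perm_low: np.ndarray         # 95% permutation envelope
    perm_high: np.ndarray
    boot_low: np.ndarray         # 95% bootstrap CI
    boot_high: np.ndarray
    pvalues: np.ndarray          # one-sided per class
    omega: float
    omega_p: float
    n_permutations: int
    n_bootstraps: int
    seed: int | None
    perm_r: np.ndarray           # (n_permutations, k) replicate matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class_min_km": self.edges[:, 0], "class_max_km": self.edges[:, 1],
            "r": self.r, "n_pairs": self.n_pairs,
            "perm_low": self.perm_low, "perm_high": self.perm_high,
            "boot_low": self.boot_low, "boot_high": self.boot_high,
            "p_one_sided": self.pvalues,
        })


def _class_r(C: np.ndarray, masks: list[np.ndarray], diag: np.ndarray,
             perm: np.ndarray | None = None) -> np.ndarray:
    """Observed (or permuted) r per class; permutation relocates individuals."""
    if perm is not None:
        Cp = C[np.ix_(perm, perm)]
        dp = diag[perm]
    else:
        Cp, dp = C, diag
    out = np.empty(len(masks))
    for h, mask in enumerate(masks):
        num = float(np.sum(Cp[mask]))
        m_x = mask.sum(axis=1)
        den = float(np.sum(m_x * dp))
        out[h] = num / den if den != 0 else np.nan
    return out


def autocorrelogram(C: np.ndarray, classes: DistanceClasses,
                    n_perm: int = 9999, n_boot: int = 9999,
                    seed: int | None = None) -> Correlogram:
    """Spatial autocorrelogram from a Gower-centered genetic matrix.

    Returns per-class r, the 95% permutation envelope (2.5/97.5
    percentiles under random relocation of individuals), per-class
    bootstrap CIs (resampling pairs within class), one-sided P values and
    the overall omega test.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if classes.class_of_pair.shape != (n, n):
        raise ValueError("class assignment does not match C's size")
    counts = classes.pair_counts
    if np.any(counts == 0):
        raise ValueError(f"distance class without pairs: {np.flatnonzero(counts == 0)}")
    masks = [classes.class_of_pair == h for h in range(classes.n_classes)]
    diag = np.diag(C).copy()
    observed = _class_r(C, masks, diag)

    rng = np.random.default_rng(seed)
    perm_r = np.empty((n_perm, classes.n_classes))
    idx = np.arange(n)
    for b in range(n_perm):
        perm = rng.permutation(idx)
        perm_r[b] = _class_r(C, masks, diag, perm)
    perm_low, perm_high = np.percentile(perm_r, [2.5, 97.5], axis=0)

    pvals = np.empty(classes.n_classes)
    for h in range(classes.n_classes):
        if observed[h] >= 0:
            b = np.sum(perm_r[:, h] >= observed[h] - 1e-12)
        else:
            b = np.sum(perm_r[:, h] <= observed[h] + 1e-12)
        pvals[h] = (b + 1) / (n_perm + 1)

    # bootstrap: resample pairs with replacement within each class
    iu = np.triu_indices(n, k=1)
    boot_low = np.empty(classes.n_classes)
    boot_high = np.empty(classes.n_classes)
    for h in range(classes.n_classes):
        sel = classes.class_of_pair[iu] == h
        xs, ys = iu[0][sel], iu[1][sel]
        cvals = C[xs, ys]
        npair = len(xs)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            take = rng.integers(0, npair, size=npair)
            m_x = np.bincount(np.concatenate([xs[take], ys[take]]), minlength=n)
            den = float(np.sum(m_x * diag))
            reps[b] = 2.0 * float(cvals[take].sum()) / den if den != 0 else np.nan
        boot_low[h], boot_high[h] = np.nanpercentile(reps, [2.5, 97.5])

    omega = float(np.sum(observed ** 2))
    omega_p = omega_overall_test(observed, perm_r)
    return Correlogram(
        edges=classes.edges, r=observed, n_pairs=counts,
        perm_low=perm_low, perm_high=perm_high,
        boot_low=boot_low, boot_high=boot_high, pvalues=pvals,
        omega=omega, omega_p=omega_p,
        n_permutations=n_perm, n_bootstraps=n_boot, seed=seed, perm_r=perm_r,
    )


def omega_overall_test(observed_r: np.ndarray, perm_r: np.ndarray) -> float:
    """Overall correlogram significance: omega = sum_h r(h)^2.

    P is the proportion of permutation replicates whose omega reaches the
    observed one, with the +1 correction.
    """
    if perm_r is None or len(perm_r) == 0:
        raise ValueError("permutation replicate matrix is required")
    perm_r = np.asarray(perm_r, dtype=float)
    observed = float(np.sum(np.asarray(observed_r) ** 2))
    omegas = np.sum(perm_r ** 2, axis=1)
    b = int(np.sum(omegas >= observed - 1e-12))
    return (b + 1) / (len(omegas) + 1)
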