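"""Y-STR haplotype preprocessing and diversity statistics.

The Yfiler panel types 17 alleles at 16 loci: 15 singleton microsatellites
plus the duplicated locus DYS385 (an unordered allele pair).  DYS389II is a
concatenated read that contains DYS389I, so the non-overlapping repeat
block DYS389b = DYS389II - DYS389I is derived before any computation.

For numeric work the raw repeat designations are converted to inferred
repeat-block lengths: a partial-repeat allele ``x.y`` at a locus with
repeat unit length ``u`` becomes ``x + y/u`` (e.g. DYS458 17.2 -> 17.5 on
a tetranucleotide).  DYS385 is dropped from numeric haplotypes by default
and loci observed in a duplicated state are treated as missing throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusPanel", "YfilerProfile", "NumericHaplotype", "DiversityStats",
    "load_default_panel", "derive_dys389b", "to_numeric",
    "pairwise_allele_differences", "multistep_neighbor_count",
    "diversity_stats", "compare_dispersion", "NUMERIC_LOCI",
]

#: locus order of numeric 15-locus haplotypes (DYS385 removed, DYS389b derived)
NUMERIC_LOCI = (
    "DYS19", "DYS389I", "DYS389b", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458", "DYS635",
    "Y-GATA-H4",
)

MULTISTEP_THRESHOLD = 2.0  # repeat units; >= this counts as a multi-step neighbor


@dataclass(frozen=True)
class LocusPanel:
    """Locus names and repeat-unit lengths of an STR panel."""

    loci: tuple[str, ...]
    repeat_unit: dict[str, int]
    duplicated_loci: frozenset[str]

    def __post_init__(self):
        for locus in self.loci:
            if locus not in self.repeat_unit:
                raise ValueError(f"no repeat unit length for locus {locus}")
            if self.repeat_unit[locus] < 1:
                raise ValueError(f"repeat unit at {locus} must be >= 1")

    @property
    def singleton_loci(self) -> tuple[str, ...]:
        return tuple(l for l in self.loci if l not in self.duplicated_loci)

    @classmethod
    def from_table(cls, path) -> "LocusPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(
            loci=tuple(df["locus"]),
            repeat_unit={r.locus: int(r.repeat_unit) for r in df.itertuples()},
            duplicated_loci=frozenset(df.loc[df["duplicated"] == 1, "locus"]),
        )


def load_default_panel() -> LocusPanel:
    """The 17-allele Yfiler panel shipped with the package."""
    ref = resources.files("ytopo.data").joinpath("yfiler_panel.tsv")
    with resources.as_file(ref) as path:
        panel = LocusPanel.from_table(path)
    return panel


@dataclass(frozen=True)
class YfilerProfile:
    """A raw 17-allele profile.

    ``alleles`` maps singleton locus name to repeat designation (float to
    carry partial repeats like 17.2, ``None`` when missing).  ``dys385`` is
    the unordered allele pair, ``None`` when missing.  ``duplicated`` flags
    singleton loci observed in a duplicated state; those are treated as
    missing in every computation.
    """

    alleles: dict[str, float | None]
    dys385: frozenset[float] | None = None
    duplicated: frozenset[str] = frozenset()

    def __post_init__(self):
        for locus, a in self.alleles.items():
            if a is not None and a <= 0:
                raise ValueError(f"allele designation at {locus} must be positive")

    def allele(self, locus: str) -> float | None:
        if locus in self.duplicated:
            return None
        return self.alleles.get(locus)


@dataclass(frozen=True)
class NumericHaplotype:
    """Repeat-block-length vector over the 15-locus numeric panel."""

    values: tuple[float, ...]
    missing: tuple[bool, ...]
    loci: tuple[str, ...] = NUMERIC_LOCI

    def __post_init__(self):
        if not (len(self.values) == len(self.missing) == len(self.loci)):
            raise ValueError("values, missing mask and loci must have equal length")

    def as_array(self) -> np.ndarray:
        arr = np.asarray(self.values, dtype=float)
        arr[np.asarray(self.missing)] = np.nan
        return arr


def derive_dys389b(profile: YfilerProfile) -> YfilerProfile:
    """Replace DYS389II by the non-overlapping block DYS389b = DYS389II - DYS389I.

    DYS389I is retained.  If either source locus is missing (or flagged
    duplicated) DYS389b is missing.  A non-positive difference is a
    biologically impossible profile and raises ``ValueError``.
    """
    a1 = profile.allele("DYS389I")
    a2 = profile.allele("DYS389II")
    alleles = dict(profile.alleles)
    alleles.pop("DYS389II", None)
    if a1 is None or a2 is None:
        alleles["DYS389b"] = None
    else:
        b = a2 - a1
        if b <= 0:
            raise ValueError(
                f"DYS389II ({a2}) must exceed DYS389I ({a1}); profile impossible"
            )
        alleles["DYS389b"] = b
    duplicated = set(profile.duplicated)
    if "DYS389II" in duplicated:
        duplicated.discard("DYS389II")
        duplicated.add("DYS389b")
    return replace(profile, alleles=alleles, duplicated=frozenset(duplicated))


def _to_block_length(designation: float, unit: int) -> float:
    """Convert a repeat designation, allowing incomplete repeat units.

    ``x.y`` means x full repeats plus y bases of a partial repeat; the
    numeric value is x + y/u.  Integer designations are unchanged.
    """
    whole = math.floor(designation + 1e-9)
    frac_bases = round((designation - whole) * 10)
    if frac_bases == 0:
        return float(whole)
    if frac_bases >= unit:
        raise ValueError(
            f"partial repeat .{frac_bases} not smaller than unit length {unit}"
        )
    return whole + frac_bases / unit


def to_numeric(profile: YfilerProfile, panel: LocusPanel | None = None,
               drop_dys385: bool = True) -> NumericHaplotype:
    """Clean a raw profile into a numeric 15-locus haplotype.

    Requires DYS389b to be derived already (see :func:`derive_dys389b`).
    Duplicated singleton loci become missing; DYS385 is dropped when
    ``drop_dys385`` (the default, matching all numeric analyses here).
    """
    if not drop_dys385:
        raise NotImplementedError(
            "numeric haplotypes are defined on the 15-locus panel; DYS385 is "
            "compared only through the raw-profile pairwise statistics"
        )
    panel = panel or load_default_panel()
    if "DYS389b" not in profile.alleles:
        raise ValueError("derive DYS389b before numeric conversion")
    units = dict(panel.repeat_unit)
    units.setdefault("DYS389b", panel.repeat_unit["DYS389II"])
    values, missing = [], []
    for locus in NUMERIC_LOCI:
        a = profile.allele(locus)
        if a is None:
            values.append(np.nan)
            missing.append(True)
        else:
            values.append(_to_block_length(a, units[locus]))
            missing.append(False)
    return NumericHaplotype(values=tuple(values), missing=tuple(missing))


# ---------------------------------------------------------------------------
# pairwise statistics

def _compared_diffs(a, b, panel: str) -> list[float]:
    """Absolute differences at jointly non-missing loci (DYS385 handled apart)."""
    if panel not in ("15", "17"):
        raise ValueError("panel must be '15' or '17'")
    if panel == "15":
        if not (isinstance(a, NumericHaplotype) and isinstance(b, NumericHaplotype)):
            raise ValueError("15-locus comparisons need NumericHaplotype inputs")
        if a.loci != b.loci:
            raise ValueError("panel mismatch between haplotypes")
        va, vb = a.as_array(), b.as_array()
        ok = ~np.isnan(va) & ~np.isnan(vb)
        return list(np.abs(va[ok] - vb[ok]))
    # 17-locus: raw profiles including DYS385 as a multiset
    if not (isinstance(a, YfilerProfile) and isinstance(b, YfilerProfile)):
        raise ValueError("17-locus comparisons need YfilerProfile inputs")
    loci = sorted(set(a.alleles) & set(b.alleles))
    diffs: list[float] = []
    for locus in loci:
        xa, xb = a.allele(locus), b.allele(locus)
        if xa is None or xb is None:
            continue
        diffs.append(abs(xa - xb))
    if a.dys385 is not None and b.dys385 is not None:
        diffs.extend(_dys385_diffs(a.dys385, b.dys385))
    return diffs


def _dys385_diffs(pa: frozenset, pb: frozenset) -> list[float]:
    """Multiset comparison of the duplicated locus: best pairing of the two
    allele pairs; each non-shared element contributes one difference."""
    la, lb = sorted(pa), sorted(pb)
    if len(la) == 1:
        la = la * 2
    if len(lb) == 1:
        lb = lb * 2
    pairings = [
        [abs(la[0] - lb[0]), abs(la[1] - lb[1])],
        [abs(la[0] - lb[1]), abs(la[1] - lb[0])],
    ]
    # minimal number of differing positions, then minimal total step distance
    return min(pairings, key=lambda d: (sum(x > 0 for x in d), sum(d)))


def pairwise_allele_differences(a, b, panel: str = "15") -> int:
    """Number of compared loci at which two haplotypes differ.

    ``panel='15'`` compares numeric haplotypes; ``panel='17'`` compares raw
    profiles with DYS385 as an unordered pair ({11,14} vs {11,15} counts one
    difference).  Loci missing in either haplotype are excluded.
    """
    return int(sum(d > 1e-9 for d in _compared_diffs(a, b, panel)))


def multistep_neighbor_count(a, b, panel: str = "15") -> int:
    """Number of compared loci differing by >= 2 repeat units."""
    return int(sum(d >= MULTISTEP_THRESHOLD - 1e-9
                   for d in _compared_diffs(a, b, panel)))


# ---------------------------------------------------------------------------
# sample-level statistics

@dataclass(frozen=True)
class DiversityStats:
    n: int
    k: int                       # distinct haplotypes
    haplotype_diversity: float   # H, Nei's unbiased gene diversity
    discrimination_capacity: float  # D = k / n
    mean_pairwise_diff: float
    sd_pairwise_diff: float
    mean_multistep: float
    n_pairs: int


def _hashable(h) -> tuple:
    if isinstance(h, NumericHaplotype):
        return tuple(None if m else v for v, m in zip(h.values, h.missing))
    if isinstance(h, YfilerProfile):
        return (tuple(sorted((k, v) for k, v in h.alleles.items()
                             if k not in h.duplicated)),
                tuple(sorted(h.dys385)) if h.dys385 is not None else None)
    return tuple(h)


def diversity_stats(sample: Sequence, panel: str = "15") -> DiversityStats:
    """Haplotype diversity H, discrimination capacity D and pairwise means.

    H = n(1 - sum p_i^2)/(n - 1) over haplotype frequencies; D = k/n.
    Pairwise means run over all C(n, 2) haplotype pairs.
    """
    n = len(sample)
    if n < 2:
        raise ValueError("diversity statistics need at least 2 haplotypes")
    counts: dict[tuple, int] = {}
    for h in sample:
        key = _hashable(h)
        counts[key] = counts.get(key, 0) + 1
    k = len(counts)
    freqs = np.array(list(counts.values())) / n
    H = n * (1.0 - float(np.sum(freqs ** 2))) / (n - 1)
    diffs, multi = [], []
    for a, b in itertools.combinations(sample, 2):
        diffs.append(pairwise_allele_differences(a, b, panel))
        multi.append(multistep_neighbor_count(a, b, panel))
    diffs = np.asarray(diffs, dtype=float)
    return DiversityStats(
        n=n, k=k,
        haplotype_diversity=H,
        discrimination_capacity=k / n,
        mean_pairwise_diff=float(diffs.mean()),
        sd_pairwise_diff=float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
        mean_multistep=float(np.mean(multi)),
        n_pairs=len(diffs),
    )


def _group_mean(sample: Sequence, statistic: str, panel: str) -> float:
    fn = (pairwise_allele_differences if statistic == "pairwise-diff"
          else multistep_neighbor_count)
    vals = [fn(a, b, panel) for a, b in itertools.combinations(sample, 2)]
    return float(np.mean(vals))


def compare_dispersion(group_a: Sequence, group_b: Sequence,
                       statistic: str = "pairwise-diff", panel: str = "15",
                       n_perm: int = 999, seed: int | None = None,
                       method: str = "permutation") -> float:
    """Two-sided test for a difference in mean pairwise dispersion.

    The default is a label permutation test: individuals are shuffled
    between the two groups and the absolute difference of group mean
    pairwise statistics is recomputed; P = (b+1)/(m+1).  ``method='t'``
    gives a Welch two-sample t-test on the per-pair values for comparison.
    """
    if statistic not in ("pairwise-diff", "multistep"):
        raise ValueError("statistic must be 'pairwise-diff' or 'multistep'")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 haplotypes")
    if method == "t":
        from scipy import stats as sps
        fn = (pairwise_allele_differences if statistic == "pairwise-diff"
              else multistep_neighbor_count)
        va = [fn(a, b, panel) for a, b in itertools.combinations(group_a, 2)]
        vb = [fn(a, b, panel) for a, b in itertools.combinations(group_b, 2)]
        return float(sps.ttest_ind(va, vb, equal_var=False).pvalue)
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 't'")
    rng = np.random.default_rng(seed)
    pooled = list(group_a) + list(group_b)
    na = len(group_a)
    observed = abs(_group_mean(group_a, statistic, panel)
                   - _group_mean(group_b, statistic, panel))
    hits = 0
    idx = np.arange(len(pooled))
    for _ in range(n_perm):
        rng.shuffle(idx)
        ga = [pooled[i] for i in idx[:na]]
        gb = [pooled[i] for i in idx[na:]]
        stat = abs(_group_mean(ga, statistic, panel)
                   - _group_mean(gb, statistic, panel))
        if stat >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
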