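"""Y-SNP haplogroup phylogeny, calling and frequency comparison.

A panel of binary Y-chromosome markers defines a rooted tree of
haplogroups.  A sample's genotype (ancestral/derived/missing state per
marker) is resolved to the deepest marker whose whole ancestor path is
derived; the label is the major haplogroup letter plus the most derived
marker (e.g. ``R-U152/S28``).  A trailing asterisk marks paragroups:
chromosomes derived at a marker but ancestral at every typed sub-marker
(e.g. ``R-S116*``).  Chromosomes ancestral at every typed marker fall into
the root paragroup ``Y*``.

The recurrent marker SRY_10831_ is encoded at a single position (the R1a
branch, where its second mutation event places it jointly with M173/M17);
profiles contradicting this placement are reported as inconsistent rather
than resolved through back-mutation logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerTree", "SnpGenotype", "HaplogroupCall", "InconsistentProfileError",
    "load_default_tree", "assign_haplogroup", "enumerate_haplogroups",
    "canonical_profile", "dedup_paternal_relatives", "modified_wald_ci",
    "haplogroup_frequencies", "frequency_table_from_counts",
    "fisher_exact_2x2", "adjust_pvalues", "round_half_away",
]

ROOT = "ROOT"
ROOT_LABEL = "Y*"

ANCESTRAL, DERIVED, MISSING = "ancestral", "derived", "missing"

#: genotype: marker name -> state
SnpGenotype = Mapping[str, str]


class InconsistentProfileError(ValueError):
    """A derived marker sits under a typed-ancestral parent (or two derived
    markers lie on incompatible branches)."""

    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs = pairs
        super().__init__(f"inconsistent SNP profile; conflicting marker pairs: {pairs}")


@dataclass(frozen=True)
class HaplogroupCall:
    label: str
    path: tuple[str, ...]      # derived markers, ROOT-side first; () for Y*
    star: bool

    @property
    def terminal(self) -> str | None:
        return self.path[-1] if self.path else None


@dataclass(frozen=True)
class MarkerTree:
    """Rooted tree of binary markers with major-haplogroup letters.

    ROOT is virtual: a profile ancestral at every typed marker belongs to
    the root paragroup.
    """

    parent: dict[str, str]             # marker -> parent marker or ROOT
    major: dict[str, str]              # marker -> major haplogroup letter

    def __post_init__(self):
        markers = set(self.parent)
        if len(markers) != len(self.parent):
            raise ValueError("duplicate marker in tree")
        for m, p in self.parent.items():
            if p != ROOT and p not in markers:
                raise ValueError(f"parent {p!r} of marker {m!r} is not in the tree")
        # acyclicity / single rooted tree: every marker must reach ROOT
        for m in markers:
            seen = set()
            cur = m
            while cur != ROOT:
                if cur in seen:
                    raise ValueError(f"cycle involving marker {m!r}")
                seen.add(cur)
                cur = self.parent[cur]
        # major letters form contiguous runs along every root-to-marker path
        for m in markers:
            letters = [self.major[x] for x in self.path_to(m)]
            seen_done: set[str] = set()
            prev = None
            for letter in letters:
                if letter != prev:
                    if letter in seen_done:
                        raise ValueError(
                            f"major letter {letter!r} reappears along path to {m!r}")
                    if prev is not None:
                        seen_done.add(prev)
                    prev = letter

    @property
    def markers(self) -> set[str]:
        return set(self.parent)

    @property
    def children(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {ROOT: []}
        for m in self.parent:
            out.setdefault(m, [])
        for m, p in sorted(self.parent.items()):
            out.setdefault(p, []).append(m)
        return {k: tuple(v) for k, v in out.items()}

    def path_to(self, marker: str) -> tuple[str, ...]:
        """Markers from the ROOT side down to ``marker`` inclusive."""
        path = []
        cur = marker
        while cur != ROOT:
            path.append(cur)
            cur = self.parent[cur]
        return tuple(reversed(path))

    def label_for(self, marker: str | None, star: bool) -> str:
        if marker is None:
            return ROOT_LABEL
        return f"{self.major[marker]}-{marker}" + ("*" if star else "")

    @classmethod
    def from_table(cls, path) -> "MarkerTree":
        df = pd.read_csv(path, sep="\t")
        return cls(
            parent={r.marker: r.parent for r in df.itertuples()},
            major={r.marker: r.major for r in df.itertuples()},
        )


def load_default_tree() -> MarkerTree:
    """The canonical 27-marker tree shipped with the package."""
    ref = resources.files("ytopo.data").joinpath("marker_tree.tsv")
    with resources.as_file(ref) as path:
        return MarkerTree.from_table(path)


def _state(genotype: SnpGenotype, marker: str) -> str:
    return genotype.get(marker, MISSING)


def assign_haplogroup(genotype: SnpGenotype, tree: MarkerTree) -> HaplogroupCall:
    """Resolve a SNP profile to its haplogroup.

    The call is the deepest marker whose full ancestor path is derived;
    missing markers on the path are tolerated because the deeper derived
    marker confirms the lineage.  A derived marker under a typed-ancestral
    ancestor, or derived markers on incompatible branches, raise
    :class:`InconsistentProfileError`.
    """
    if not genotype:
        raise ValueError("empty genotype")
    unknown = set(genotype) - tree.markers
    if unknown:
        raise ValueError(f"genotype has markers absent from the tree: {sorted(unknown)}")
    bad = {ANCESTRAL, DERIVED, MISSING}
    for m, s in genotype.items():
        if s not in bad:
            raise ValueError(f"invalid state {s!r} at marker {m}")

    derived = [m for m in genotype if genotype[m] == DERIVED]
    conflicts: list[tuple[str, str]] = []
    for m in derived:
        for anc in tree.path_to(m)[:-1]:
            if _state(genotype, anc) == ANCESTRAL:
                conflicts.append((anc, m))
    if conflicts:
        raise InconsistentProfileError(sorted(conflicts))

    if not derived:
        return HaplogroupCall(label=ROOT_LABEL, path=(), star=True)

    terminal = max(derived, key=lambda m: (len(tree.path_to(m)), m))
    on_path = set(tree.path_to(terminal))
    off_path = sorted(m for m in derived if m not in on_path)
    if off_path:
        raise InconsistentProfileError([(terminal, m) for m in off_path])

    kids = tree.children.get(terminal, ())
    typed_kids = [k for k in kids if _state(genotype, k) != MISSING]
    star = bool(typed_kids) and all(_state(genotype, k) == ANCESTRAL
                                    for k in typed_kids)
    return HaplogroupCall(label=tree.label_for(terminal, star),
                          path=tree.path_to(terminal), star=star)


def canonical_profile(tree: MarkerTree, marker: str | None) -> dict[str, str]:
    """The fully typed profile whose call terminates at ``marker``
    (``None`` for the root paragroup): derived along the path, ancestral
    everywhere else."""
    on_path = set(tree.path_to(marker)) if marker is not None else set()
    return {m: (DERIVED if m in on_path else ANCESTRAL) for m in tree.markers}


def enumerate_haplogroups(tree: MarkerTree) -> list[str]:
    """All theoretically distinguishable haplo/paragroup labels.

    One label per marker (a star paragroup when the marker has typed
    children in the canonical fully typed profile, a terminal clade
    otherwise) plus the root paragroup.
    """
    children = tree.children
    labels = [ROOT_LABEL]
    for m in sorted(tree.markers, key=lambda m: (len(tree.path_to(m)), m)):
        labels.append(tree.label_for(m, star=bool(children.get(m))))
    return labels


# ---------------------------------------------------------------------------
# sample handling

def dedup_paternal_relatives(records: Sequence) -> tuple[list, list]:
    """Collapse likely close paternal relatives to one specimen per group.

    Records sharing an identical haplogroup call, an identical full STR
    profile and the same declared descent group are treated as paternal
    relatives; the record with the lexicographically smallest id is kept.
    Records without a descent group are never collapsed.
    """
    from .strprofiles import _hashable  # profile fingerprint

    keyed: dict[tuple, list] = {}
    singles: list = []
    for rec in records:
        if getattr(rec, "descent_group", None) is None:
            singles.append(rec)
            continue
        key = (rec.haplogroup, _hashable(rec.str_profile), rec.descent_group)
        keyed.setdefault(key, []).append(rec)
    kept, removed = list(singles), []
    for group in keyed.values():
        group = sorted(group, key=lambda r: r.id)
        kept.append(group[0])
        removed.extend(group[1:])
    kept.sort(key=lambda r: r.id)
    removed.sort(key=lambda r: r.id)
    return kept, removed


# ---------------------------------------------------------------------------
# frequencies and tests

def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (report-table convention)."""
    factor = 10 ** ndigits
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


def modified_wald_ci(x: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Modified Wald (add-2-successes/add-2-failures) binomial CI,
    clamped to [0, 1]."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n, n > 0")
    p = (x + 2) / (n + 4)
    half = z * np.sqrt(p * (1 - p) / (n + 4))
    return max(0.0, p - half), min(1.0, p + half)


def frequency_table_from_counts(counts: Mapping[str, Mapping[str, int]],
                                informative_threshold: float = 0.05,
                                z: float = 1.96) -> pd.DataFrame:
    """Frequency table (counts, relative frequencies, modified-Wald 95% CIs,
    informative flags) from per-group haplogroup counts."""
    rows = []
    for group, hg_counts in counts.items():
        n = sum(hg_counts.values())
        if n == 0:
            raise ValueError(f"group {group!r} is empty")
        for hg, c in sorted(hg_counts.items()):
            f = c / n
            lo, hi = modified_wald_ci(c, n, z)
            rows.append({
                "group": group, "haplogroup": hg, "count": c, "n": n,
                "frequency": f, "ci_low": lo, "ci_high": hi,
                "informative": f >= informative_threshold,
            })
    return pd.DataFrame(rows)


def haplogroup_frequencies(records: Sequence, grouping,
                           informative_threshold: float = 0.05,
                           z: float = 1.96) -> pd.DataFrame:
    """Frequency table for records grouped by ``grouping``.

    ``grouping`` is a callable mapping a record to a group key, or ``None``
    to exclude the record.  Every haplogroup observed anywhere is tabulated
    in every group (zero counts included) so groups are comparable.
    """
    by_group: dict[str, list] = {}
    for rec in records:
        g = grouping(rec)
        if g is None:
            continue
        by_group.setdefault(g, []).append(rec)
    if not by_group:
        raise ValueError("grouping excluded every record")
    all_hgs = sorted({rec.haplogroup for recs in by_group.values() for rec in recs})
    counts = {
        g: {hg: sum(r.haplogroup == hg for r in recs) for hg in all_hgs}
        for g, recs in sorted(by_group.items())
    }
    return frequency_table_from_counts(counts, informative_threshold, z)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 count table.

    Returns (odds ratio, two-sided P); the two-sided P sums hypergeometric
    probabilities not exceeding that of the observed table.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def adjust_pvalues(pvalues: Sequence[float], method: str = "BY",
                   alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-testing adjustment.

    ``method``: ``"BH"`` (step-up FDR), ``"BY"`` (FDR valid under arbitrary
    dependence, = BH with harmonic-sum inflation) or ``"bonferroni"``.
    Returns (adjusted p-values clamped at 1, significance flags at alpha).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"BH": "fdr_bh", "BY": "fdr_by", "bonferroni": "bonferroni"}
    if method not in sm_method:
        raise ValueError(f"unknown method {method!r}")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, adj, _, _ = multipletests(p, alpha=alpha, method=sm_method[method])
    return adj, reject
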