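"""Readers and writers for the tabular inputs and outputs.

Input tables are delimited text (comma or tab, auto-detected).  Missing
values are empty cells or ``NA`` — never 0, since an allele designation of
0 would parse but is not meaningful.  The duplicated Yfiler locus DYS385
is accepted either as one column holding an unordered pair (``11-14`` or
``11,14``) or as separate ``DYS385a``/``DYS385b`` columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .strprofiles import LocusPanel, YfilerProfile, load_default_panel

__all__ = [
    "IndividualRecord", "GeoTable", "RoadDistanceMatrix",
    "read_population_table", "write_population_table",
    "read_geo_and_distances", "write_labelled_matrix", "read_labelled_matrix",
]

_MISSING = {"", "na", "nan", "none"}

SNP_STATE_MAP = {
    "a": "ancestral", "ancestral": "ancestral", "0": "ancestral",
    "d": "derived", "derived": "derived", "1": "derived",
}


@dataclass
class IndividualRecord:
    """One sampled man: genealogy, SNP genotype and STR profile."""

    id: str
    snp_profile: dict[str, str]
    str_profile: YfilerProfile
    municipality_proband: str | None = None
    municipality_father: str | None = None
    municipality_grandfather: str | None = None
    birth_year_proband: int | None = None
    birth_year_father: int | None = None
    birth_year_grandfather: int | None = None
    surname_etymon_class: str = "unknown"
    descent_group: str | None = None
    haplogroup: str | None = None   # filled in by the calling stage

    def municipality(self, generation_level: str) -> str | None:
        return getattr(self, f"municipality_{generation_level}")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip().lower() in _MISSING


def _parse_allele(value, column: str, row: int) -> float | None:
    if _is_missing(value):
        return None
    try:
        a = float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"row {row}: non-numeric allele {value!r} in column {column!r}")
    if a == 0:
        raise ValueError(
            f"row {row}: allele 0 in column {column!r}; missing values must "
            "be empty or NA, never 0")
    return a


def _parse_dys385(value, row: int) -> frozenset | None:
    if _is_missing(value):
        return None
    parts = re.split(r"[-,/;]", str(value))
    alleles = [_parse_allele(p.strip(), "DYS385", row) for p in parts if p.strip()]
    if not alleles or any(a is None for a in alleles) or len(alleles) > 2:
        raise ValueError(f"row {row}: cannot parse DYS385 value {value!r}")
    return frozenset(alleles)


def read_population_table(path, panel: LocusPanel | None = None,
                          column_map: Mapping[str, str] | None = None,
                          ) -> list[IndividualRecord]:
    """Read per-individual records from a delimited table.

    The header must carry the Yfiler locus columns; SNP marker columns are
    every remaining column matching a known marker naming pattern (states
    ``A``/``D``/``ancestral``/``derived``; empty = untyped).  ``column_map``
    renames logical names (e.g. ``{"id": "sample"}``) to actual columns.
    An unrecognized STR-locus-like column is a format error.
    """
    panel = panel or load_default_panel()
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if "id" not in df.columns:
        raise ValueError("population table needs an 'id' column")

    singleton_loci = set(panel.singleton_loci)
    known_meta = {
        "id", "municipality_proband", "municipality_father",
        "municipality_grandfather", "birth_year_proband", "birth_year_father",
        "birth_year_grandfather", "surname_etymon_class", "descent_group",
        "duplicated_loci", "region", "haplogroup",
    }
    str_like = re.compile(r"^(DYS\d+.*|Y-?GATA.*)$", re.IGNORECASE)
    locus_cols, snp_cols = [], []
    for col in df.columns:
        if col in known_meta:
            continue
        if col in singleton_loci or col in ("DYS385", "DYS385a", "DYS385b"):
            locus_cols.append(col)
        elif str_like.match(col):
            raise ValueError(f"unknown STR locus column {col!r}")
        else:
            snp_cols.append(col)

    records = []
    for i, row in enumerate(df.to_dict("records")):
        alleles = {loc: _parse_allele(row[loc], loc, i)
                   for loc in locus_cols if loc in singleton_loci}
        if "DYS385" in df.columns:
            dys385 = _parse_dys385(row["DYS385"], i)
        elif "DYS385a" in df.columns and "DYS385b" in df.columns:
            a = _parse_allele(row["DYS385a"], "DYS385a", i)
            b = _parse_allele(row["DYS385b"], "DYS385b", i)
            dys385 = frozenset(x for x in (a, b) if x is not None) or None
        else:
            dys385 = None
        dup_raw = row.get("duplicated_loci", "")
        duplicated = frozenset(
            x.strip() for x in re.split(r"[;,]", dup_raw) if x.strip()
        ) if not _is_missing(dup_raw) else frozenset()
        snp = {}
        for col in snp_cols:
            v = row[col]
            if _is_missing(v):
                continue
            state = SNP_STATE_MAP.get(str(v).strip().lower())
            if state is None:
                raise ValueError(
                    f"row {i}: invalid SNP state {v!r} in column {col!r}")
            snp[col] = state

        def _opt(key):
            v = row.get(key, "")
            return None if _is_missing(v) else str(v).strip()

        def _opt_int(key):
            v = _opt(key)
            if v is None:
                return None
            try:
                return int(v)
            except ValueError:
                raise ValueError(f"row {i}: non-integer year {v!r} in {key!r}")

        records.append(IndividualRecord(
            id=str(row["id"]).strip(),
            snp_profile=snp,
            str_profile=YfilerProfile(alleles=alleles, dys385=dys385,
                                      duplicated=duplicated),
            municipality_proband=_opt("municipality_proband"),
            municipality_father=_opt("municipality_father"),
            municipality_grandfather=_opt("municipality_grandfather"),
            birth_year_proband=_opt_int("birth_year_proband"),
            birth_year_father=_opt_int("birth_year_father"),
            birth_year_grandfather=_opt_int("birth_year_grandfather"),
            surname_etymon_class=_opt("surname_etymon_class") or "unknown",
            descent_group=_opt("descent_group"),
            haplogroup=_opt("haplogroup"),
        ))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate record ids: {dupes}")
    return records


def _fmt_allele(a: float | None) -> str:
    if a is None:
        return ""
    return f"{a:g}"


def write_population_table(records: Sequence[IndividualRecord], path,
                           panel: LocusPanel | None = None) -> None:
    """Inverse of :func:`read_population_table` (tab-delimited)."""
    panel = panel or load_default_panel()
    snp_markers = sorted({m for r in records for m in r.snp_profile})
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "municipality_proband": r.municipality_proband or "",
            "municipality_father": r.municipality_father or "",
            "municipality_grandfather": r.municipality_grandfather or "",
            "birth_year_proband": r.birth_year_proband or "",
            "birth_year_father": r.birth_year_father or "",
            "birth_year_grandfather": r.birth_year_grandfather or "",
            "surname_etymon_class": r.surname_etymon_class,
            "descent_group": r.descent_group or "",
            "haplogroup": r.haplogroup or "",
            "duplicated_loci": ";".join(sorted(r.str_profile.duplicated)),
        }
        for locus in panel.singleton_loci:
            row[locus] = _fmt_allele(r.str_profile.alleles.get(locus))
        row["DYS385"] = ("-".join(_fmt_allele(a)
                                  for a in sorted(r.str_profile.dys385))
                         if r.str_profile.dys385 is not None else "")
        for m in snp_markers:
            state = r.snp_profile.get(m)
            row[m] = {"ancestral": "A", "derived": "D"}.get(state, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# geography

@dataclass(frozen=True)
class GeoTable:
    """Planar (pre-projected, km) municipality coordinates."""

    coords: dict[str, tuple[float, float]]
    valley: dict[str, str] = field(default_factory=dict)
    region: dict[str, str] = field(default_factory=dict)  # optional fixed A/B

    def __post_init__(self):
        for key, (x, y) in self.coords.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite coordinates for {key!r}")

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(sorted(self.coords))


@dataclass(frozen=True)
class RoadDistanceMatrix:
    """Symmetric nonnegative km distances between municipalities.

    The triangle inequality is not assumed: road networks need not embed
    in a metric space.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if np.any(m < 0) or np.any(np.diag(m) != 0):
            raise ValueError("distances must be nonnegative with zero diagonal")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")

    def distance(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[ia, ib])

    def submatrix(self, keys: Sequence[str]) -> np.ndarray:
        idx = [self.labels.index(k) for k in keys]
        return self.matrix[np.ix_(idx, idx)]


def read_geo_and_distances(geo_path, dist_path, symmetry_tol_km: float = 0.1,
                           ) -> tuple[GeoTable, RoadDistanceMatrix]:
    """Read municipality coordinates and the road-distance matrix.

    Distance matrix labels must match the geography keys.  An asymmetric
    input is symmetrized by averaging when upper and lower triangles agree
    within ``symmetry_tol_km``; larger discrepancies are an error.
    """
    geo_df = pd.read_csv(geo_path, sep=None, engine="python")
    required = {"municipality", "x_km", "y_km"}
    if not required <= set(geo_df.columns):
        raise ValueError(f"geo table needs columns {sorted(required)}")
    if geo_df["municipality"].duplicated().any():
        raise ValueError("duplicate municipality keys in geo table")
    coords = {str(r.municipality): (float(r.x_km), float(r.y_km))
              for r in geo_df.itertuples()}
    valley = ({str(r.municipality): str(r.valley) for r in geo_df.itertuples()}
              if "valley" in geo_df.columns else {})
    region = ({str(r.municipality): str(r.region) for r in geo_df.itertuples()
               if not _is_missing(r.region)}
              if "region" in geo_df.columns else {})
    geo = GeoTable(coords=coords, valley=valley, region=region)

    labels, m = read_labelled_matrix(dist_path)
    missing = sorted(set(labels) ^ set(coords))
    if missing:
        raise ValueError(
            f"distance-matrix labels do not match geography; mismatched keys: {missing}")
    gap = np.abs(m - m.T)
    if np.max(gap) > symmetry_tol_km:
        i, j = np.unravel_index(np.argmax(gap), gap.shape)
        raise ValueError(
            f"asymmetric road distances beyond tolerance at "
            f"({labels[i]}, {labels[j]}): {m[i, j]} vs {m[j, i]}")
    m = (m + m.T) / 2.0
    return geo, RoadDistanceMatrix(labels=tuple(labels), matrix=m)


def read_labelled_matrix(path) -> tuple[list[str], np.ndarray]:
    """Square matrix with a labelled header row and first column."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    labels = [str(x) for x in df.index]
    if labels != [str(x) for x in df.columns]:
        raise ValueError("matrix row and column labels differ")
    return labels, df.to_numpy(dtype=float)


def write_labelled_matrix(labels: Sequence[str], matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t")
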