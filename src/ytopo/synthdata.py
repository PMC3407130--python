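"""Synthetic data generator with the structure the analysis assumes.

The generator emulates the study design: ~270 men sampled across ~29
municipalities of a small alpine district split into a former-Romance
region A (35 samples) and a former-Slavic region B (235 samples).  Each
individual draws a haplogroup from his region's founder frequencies
(including region-restricted clades — one lineage at 16% in region B and
absent from region A), and a 15-locus Y-STR haplotype descending from the
haplogroup founder under the symmetric single-step stepwise mutation
model (per-locus per-generation rate 2e-3, 50 generations by default —
roughly the time depth of the settlement history being emulated).
Three-generation municipality histories follow a simple migration kernel,
pasture-name points come as spatially clustered Gaussian mixtures per
etymon class (Germanic uniform in high density, 853 points at 71/17/12%),
and a configurable number of close paternal relatives is planted for the
deduplication stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .haplogroups import MarkerTree, canonical_profile, load_default_tree
from .io import GeoTable, IndividualRecord, RoadDistanceMatrix
from .strprofiles import NUMERIC_LOCI, YfilerProfile
from .toponyms import PastureNamePoint

__all__ = ["SimConfig", "SimTruth", "default_sim_config",
           "simulate_population", "simulate_pasture_points",
           "make_geography", "label_to_marker"]

# modal-like base haplotype over the numeric panel order
_BASE_HAPLOTYPE = {
    "DYS19": 14, "DYS389I": 13, "DYS389b": 16, "DYS390": 24, "DYS391": 10,
    "DYS392": 13, "DYS393": 13, "DYS437": 15, "DYS438": 12, "DYS439": 12,
    "DYS448": 19, "DYS456": 15, "DYS458": 16, "DYS635": 23, "Y-GATA-H4": 12,
}

_DEFAULT_FREQS = {
    # region A: former Romance settlement — R1b-heavy, no R-M17
    "A": {
        "R-U152/S28": 0.22, "R-U106/S21": 0.20, "R-M412/S167*": 0.14,
        "R-M343*": 0.10, "I-M253": 0.14, "G-P15": 0.08, "J-M304": 0.09,
        "E-M96*": 0.03, "R-M17": 0.0, "R-S116*": 0.0,
    },
    # region B: former Slavic settlement — R-M17 at 16%, R-S116* present
    "B": {
        "R-M17": 0.16, "R-U106/S21": 0.17, "R-U152/S28": 0.11,
        "R-M412/S167*": 0.03, "R-M343*": 0.06, "R-S116*": 0.03,
        "I-M253": 0.17, "J-M304": 0.09, "G-P15": 0.07, "E-M78": 0.03,
        "K-M9*": 0.04, "T-M70": 0.04, "E-M96*": 0.0,
    },
}


def _default_municipalities() -> tuple[dict, dict, dict]:
    """Hand-laid two-cluster geography ~50 km across (coords in km)."""
    coords, region, sizes = {}, {}, {}
    sizes_a = [10, 5, 4, 4, 3, 3, 3, 3]
    for i, n in enumerate(sizes_a):
        key = f"A{i + 1:02d}"
        coords[key] = (8.0 + 3.0 * (i % 3), 8.0 + 3.0 * (i // 3))
        region[key] = "A"
        sizes[key] = n
    sizes_b = [99, 19, 14, 9, 8, 8, 7, 7, 7, 6, 6, 6, 6, 5, 5, 5, 4, 4, 4, 3, 3]
    for j, n in enumerate(sizes_b):
        key = f"B{j + 1:02d}"
        coords[key] = (35.0 + 4.0 * (j % 5), 15.0 + 4.0 * (j // 5))
        region[key] = "B"
        sizes[key] = n
    return coords, region, sizes


@dataclass
class SimConfig:
    """Ground-truth parameters of a simulated study."""

    seed: int = 0
    municipal_coords: dict[str, tuple[float, float]] = None
    region_of: dict[str, str] = None
    sample_sizes: dict[str, int] = None
    road_inflation: float = 1.4
    founder_freqs: dict[str, dict[str, float]] = None
    founder_haplotypes: dict[str, tuple] = None  # label -> 15-locus override
    generations: int = 50
    mutation_rate: float = 2e-3
    multistep_prob: float = 0.0   # probability a mutation jumps 2 steps
    migration_prob: float = 0.3   # per generation step
    migration_scale_km: float = 10.0  # exponential distance decay of moves
    missing_father_prob: float = 0.0
    n_duplicates: int = 17
    n_pasture: dict[str, int] = None
    pasture_spread_km: float = 6.0
    study_box: tuple[float, float, float, float] = (0.0, 0.0, 60.0, 40.0)

    def __post_init__(self):
        coords, region, sizes = _default_municipalities()
        if self.municipal_coords is None:
            self.municipal_coords = coords
        if self.region_of is None:
            self.region_of = {k: region[k] for k in self.municipal_coords}
        if self.sample_sizes is None:
            self.sample_sizes = {k: sizes.get(k, 5) for k in self.municipal_coords}
        if self.founder_freqs is None:
            self.founder_freqs = {r: dict(f) for r, f in _DEFAULT_FREQS.items()}
        if self.n_pasture is None:
            self.n_pasture = {"Germanic": 606, "Slavic": 145, "Romance": 102}
        for r, freqs in self.founder_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"founder frequencies for region {r!r} sum to {total}")
        if not 0.0 <= self.mutation_rate < 0.1:
            raise ValueError("mutation rate must lie in [0, 0.1)")
        if any(n <= 0 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be positive")
        if self.generations < 0 or self.n_duplicates < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class SimTruth:
    """Everything the generator knows that the analysis must recover."""

    region_of: dict[str, str]                   # municipality -> A/B
    haplogroup_of: dict[str, str]               # individual id -> label
    founder_haplotypes: dict[str, tuple]        # label -> 15-locus vector
    lineage_paths: dict[str, tuple[str, str, str]]  # id -> (gf, f, proband) muns
    duplicates: tuple[tuple[str, str], ...]     # (original id, planted copy id)


def default_sim_config(seed: int = 0, **overrides) -> SimConfig:
    return SimConfig(seed=seed, **overrides)


def label_to_marker(label: str) -> str | None:
    """Terminal marker of a haplogroup label (None for the root paragroup)."""
    if label == "Y*":
        return None
    _, _, marker = label.partition("-")
    return marker.rstrip("*")


def make_geography(cfg: SimConfig) -> tuple[GeoTable, RoadDistanceMatrix]:
    """Geo table and road distances (Euclidean x inflation factor)."""
    keys = sorted(cfg.municipal_coords)
    xy = np.array([cfg.municipal_coords[k] for k in keys])
    diff = xy[:, None, :] - xy[None, :, :]
    eu = np.sqrt(np.sum(diff ** 2, axis=-1))
    geo = GeoTable(coords={k: cfg.municipal_coords[k] for k in keys},
                   region=dict(cfg.region_of))
    return geo, RoadDistanceMatrix(labels=tuple(keys),
                                   matrix=eu * cfg.road_inflation)


def _founder_haplotypes(cfg: SimConfig, labels: Sequence[str]) -> dict[str, tuple]:
    """Deterministic founder haplotype per haplogroup: the base modal
    haplotype plus a label-seeded repeat offset of up to 3 units per locus,
    so distinct founders are several mutational steps apart."""
    founders = dict(cfg.founder_haplotypes or {})
    for label in sorted(labels):
        if label in founders:
            founders[label] = tuple(float(v) for v in founders[label])
            continue
        rng = np.random.default_rng([zlib.crc32(label.encode()), cfg.seed])
        offsets = rng.integers(-3, 4, size=len(NUMERIC_LOCI))
        founders[label] = tuple(
            float(_BASE_HAPLOTYPE[locus] + off)
            for locus, off in zip(NUMERIC_LOCI, offsets)
        )
    return founders


def _mutate(haplotype: np.ndarray, cfg: SimConfig, rng: np.random.Generator,
            ) -> np.ndarray:
    """Evolve one haplotype ``cfg.generations`` generations under the
    symmetric stepwise model (optional 2-step jumps)."""
    h = haplotype.copy()
    if cfg.generations == 0 or cfg.mutation_rate == 0.0:
        return h
    hits = rng.random((cfg.generations, len(h))) < cfg.mutation_rate
    n_hits = hits.sum()
    if n_hits:
        signs = rng.choice([-1.0, 1.0], size=n_hits)
        steps = np.where(rng.random(n_hits) < cfg.multistep_prob, 2.0, 1.0)
        np.add.at(h, np.nonzero(hits)[1], signs * steps)
    return h


def _migration_weights(cfg: SimConfig, keys: Sequence[str]) -> np.ndarray:
    """Destination probabilities per origin: exponentially
    distance-decaying moves (migration is mostly local in valley
    networks); zero weight on staying put."""
    xy = np.array([cfg.municipal_coords[k] for k in keys])
    d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1)) * cfg.road_inflation
    w = np.exp(-d / cfg.migration_scale_km)
    np.fill_diagonal(w, 0.0)
    if len(keys) > 1:
        w /= w.sum(axis=1, keepdims=True)
    return w


def _migrate(start_idx: int, weights: np.ndarray, cfg: SimConfig,
             rng: np.random.Generator) -> int:
    if len(weights) < 2 or rng.random() >= cfg.migration_prob:
        return start_idx
    return int(rng.choice(len(weights), p=weights[start_idx]))


def simulate_population(cfg: SimConfig, tree: MarkerTree | None = None,
                        ) -> tuple[list[IndividualRecord], SimTruth]:
    """Generate individual records plus the generating truth.

    Haplogroups are drawn per region, haplotypes evolve from haplogroup
    founders, SNP profiles are the noiseless canonical profiles of the
    drawn haplogroup, municipality histories follow the migration kernel,
    and ``cfg.n_duplicates`` close paternal relatives (same genotypes,
    shared descent group) are planted.
    """
    tree = tree or load_default_tree()
    rng = np.random.default_rng(cfg.seed)
    keys = sorted(cfg.municipal_coords)
    labels = sorted({l for f in cfg.founder_freqs.values() for l in f})
    founders = _founder_haplotypes(cfg, labels)
    valid = {m for m in tree.markers}
    for label in labels:
        marker = label_to_marker(label)
        if marker is not None and marker not in valid:
            raise ValueError(f"founder haplogroup {label!r} not in the marker tree")

    records: list[IndividualRecord] = []
    haplogroup_of: dict[str, str] = {}
    lineage: dict[str, tuple[str, str, str]] = {}
    weights = _migration_weights(cfg, keys)
    key_index = {k: i for i, k in enumerate(keys)}
    i = 0
    for mun in keys:
        region = cfg.region_of[mun]
        freqs = cfg.founder_freqs[region]
        hg_labels = sorted(freqs)
        probs = np.array([freqs[l] for l in hg_labels])
        for _ in range(cfg.sample_sizes[mun]):
            i += 1
            rid = f"I{i:04d}"
            label = hg_labels[rng.choice(len(hg_labels), p=probs)]
            hap = _mutate(np.array(founders[label]), cfg, rng)
            gf = mun
            fa = keys[_migrate(key_index[gf], weights, cfg, rng)]
            pr = keys[_migrate(key_index[fa], weights, cfg, rng)]
            fa_out = None if rng.random() < cfg.missing_father_prob else fa
            alleles = {locus: float(v) for locus, v in zip(NUMERIC_LOCI, hap)}
            # present the raw profile with the concatenated DYS389 read
            alleles["DYS389II"] = alleles["DYS389I"] + alleles.pop("DYS389b")
            profile = YfilerProfile(
                alleles=alleles,
                dys385=frozenset({11.0, 14.0 + (zlib.crc32(label.encode()) % 3)}),
            )
            snp = canonical_profile(tree, label_to_marker(label))
            records.append(IndividualRecord(
                id=rid, snp_profile=snp, str_profile=profile,
                municipality_proband=pr, municipality_father=fa_out,
                municipality_grandfather=gf,
                birth_year_proband=int(rng.integers(1950, 1990)),
                descent_group=f"D{i:04d}",
            ))
            haplogroup_of[rid] = label
            lineage[rid] = (gf, fa, pr)

    # plant close paternal relatives: same genotypes, shared descent group
    dup_pairs = []
    if cfg.n_duplicates:
        origin_idx = rng.choice(len(records), size=cfg.n_duplicates, replace=False)
        for j, oi in enumerate(sorted(origin_idx), start=1):
            orig = records[oi]
            rid = f"R{j:04d}"
            records.append(IndividualRecord(
                id=rid, snp_profile=dict(orig.snp_profile),
                str_profile=orig.str_profile,
                municipality_proband=orig.municipality_proband,
                municipality_father=orig.municipality_father,
                municipality_grandfather=orig.municipality_grandfather,
                birth_year_proband=orig.birth_year_proband,
                descent_group=orig.descent_group,
            ))
            haplogroup_of[rid] = haplogroup_of[orig.id]
            lineage[rid] = lineage[orig.id]
            dup_pairs.append((orig.id, rid))

    truth = SimTruth(
        region_of=dict(cfg.region_of),
        haplogroup_of=haplogroup_of,
        founder_haplotypes=founders,
        lineage_paths=lineage,
        duplicates=tuple(dup_pairs),
    )
    return records, truth


def simulate_pasture_points(cfg: SimConfig) -> list[PastureNamePoint]:
    """Etymon-labelled point clouds.

    Germanic names are uniform over the study box; Slavic points cluster
    around region-B municipalities, Romance points around region-A
    municipalities (Gaussian spread ``pasture_spread_km``).  Class counts
    are honored exactly.
    """
    rng = np.random.default_rng([cfg.seed, 7])
    xmin, ymin, xmax, ymax = cfg.study_box
    points: list[PastureNamePoint] = []
    n_g = cfg.n_pasture.get("Germanic", 0)
    xs = rng.uniform(xmin, xmax, size=n_g)
    ys = rng.uniform(ymin, ymax, size=n_g)
    points += [PastureNamePoint(float(x), float(y), "Germanic")
               for x, y in zip(xs, ys)]
    centers = {
        "Slavic": [cfg.municipal_coords[k] for k in sorted(cfg.municipal_coords)
                   if cfg.region_of[k] == "B"],
        "Romance": [cfg.municipal_coords[k] for k in sorted(cfg.municipal_coords)
                    if cfg.region_of[k] == "A"],
    }
    for cls in ("Slavic", "Romance"):
        n = cfg.n_pasture.get(cls, 0)
        ctrs = centers[cls]
        picks = rng.integers(0, len(ctrs), size=n)
        for p in picks:
            cx, cy = ctrs[p]
            x = cx + rng.normal(0, cfg.pasture_spread_km)
            y = cy + rng.normal(0, cfg.pasture_spread_km)
            points.append(PastureNamePoint(float(x), float(y), cls))
    return points
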