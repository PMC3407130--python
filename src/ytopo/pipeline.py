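"""End-to-end analysis driver.

Orchestrates the full workflow: read inputs, call haplogroups, collapse
paternal relatives, build toponym density surfaces and the A/B region
map, tabulate and contrast haplogroup frequencies, prepare numeric
haplotypes, compute diversity statistics, pairwise PhiST and Shannon
mutual information, the spatial autocorrelogram, and a PCoA of the
municipality PhiST matrix.  Every stage logs record counts in and out;
any failure aborts with the stage name and cause.  All artifacts are
delimited text plus one machine-readable ``summary.json``; output is
deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import haplogroups as hg
from . import popstruct, spatial, strprofiles, toponyms
from .config import AnalysisConfig
from .io import (read_geo_and_distances, read_population_table,
                 write_population_table)

__all__ = ["PipelineInputs", "StageError", "run_pipeline"]

_log = logging.getLogger("ytopo.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineInputs:
    population: Path
    geo: Path
    distances: Path
    pasture: Path
    fixed_regions: Path | None = None  # optional municipality,region table


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


def _region_lookup(records, region_map, level):
    """record -> region label via its municipality at the generation level."""
    def lookup(rec):
        mun = rec.municipality(level)
        if mun is None:
            return None
        return region_map.region.get(mun)
    return lookup


def run_pipeline(config: AnalysisConfig, inputs: PipelineInputs,
                 outdir: str | Path) -> dict:
    """Run the whole analysis; returns the summary dict (also written as
    ``summary.json`` in ``outdir``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {k: v for k, v in vars(config).items()}}
    tree = hg.load_default_tree()
    panel = strprofiles.load_default_panel()

    records, geo, roads, points = _read_inputs(inputs)
    summary["counts"] = {"records_read": len(records),
                         "municipalities": len(geo.coords),
                         "pasture_points": len(points)}
    _log.info("read %d records, %d municipalities, %d pasture points",
              len(records), len(geo.coords), len(points))

    records = _call_haplogroups(records, tree)
    records, removed = _dedup(records)
    summary["counts"]["paternal_relatives_removed"] = len(removed)
    summary["counts"]["records_after_dedup"] = len(records)
    _log.info("dedup: %d -> %d records (%d removed)",
              len(records) + len(removed), len(records), len(removed))

    region_map, composition = _toponym_stage(config, geo, points, outdir)
    summary["etymon_composition"] = {
        cls: {"count": c, "proportion": p} for cls, (c, p) in composition.items()}
    summary["counts"]["municipalities_unresolved_region"] = len(region_map.unresolved)

    lookup = _region_lookup(records, region_map, config.generation_level)
    placed = [r for r in records if lookup(r) is not None]
    summary["counts"]["records_with_region"] = len(placed)
    summary["counts"]["records_excluded_no_region"] = len(records) - len(placed)
    _log.info("generation level %s: %d records placed, %d excluded",
              config.generation_level, len(placed), len(records) - len(placed))

    freq_summary = _frequency_stage(config, records, lookup, outdir)
    summary["haplogroup_contrasts"] = freq_summary

    numeric = _numeric_stage(records, panel)
    summary["diversity"] = _diversity_stage(records, numeric, lookup, outdir)

    phist_summary = _structure_stage(config, placed, numeric, lookup, outdir)
    summary.update(phist_summary)

    autocorr_summary = _spatial_stage(config, placed, numeric, roads, outdir)
    summary["spatial_autocorrelation"] = autocorr_summary

    write_population_table(records, outdir / "records_dedup.tsv", panel)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


@_stage("read-inputs")
def _read_inputs(inputs: PipelineInputs):
    records = read_population_table(inputs.population)
    geo, roads = read_geo_and_distances(inputs.geo, inputs.distances)
    points = toponyms.read_pasture_points(inputs.pasture)
    for rec in records:
        for level in ("proband", "father", "grandfather"):
            mun = rec.municipality(level)
            if mun is not None and mun not in geo.coords:
                raise ValueError(
                    f"record {rec.id}: unknown municipality {mun!r} at {level} level")
    return records, geo, roads, points


@_stage("call-haplogroups")
def _call_haplogroups(records, tree):
    for rec in records:
        rec.haplogroup = hg.assign_haplogroup(rec.snp_profile, tree).label
    return records


@_stage("dedup-relatives")
def _dedup(records):
    return hg.dedup_paternal_relatives(records)


@_stage("toponym-density")
def _toponym_stage(config, geo, points, outdir):
    R = config.density_radius_km
    px = np.array([p.x for p in points])
    py = np.array([p.y for p in points])
    bounds = (px.min() - R, py.min() - R, px.max() + R, py.max() + R)
    grids = {}
    for cls in toponyms.ETYMON_CLASSES:
        grid = toponyms.point_density(
            points, cell_km=config.density_cell_km, radius_km=R,
            bounds=bounds, etymon_class=cls)
        grids[cls] = grid
        np.savetxt(outdir / f"density_{cls.lower()}.tsv", grid.density,
                   delimiter="\t")
    region_map = toponyms.classify_regions(
        grids["Romance"], grids["Slavic"], geo.coords,
        fallback=geo.region or None)
    pd.DataFrame({
        "municipality": list(region_map.region),
        "region": [region_map.region[k] for k in region_map.region],
        "provenance": [region_map.provenance[k] for k in region_map.region],
    }).to_csv(outdir / "regions.tsv", sep="\t", index=False)
    composition = toponyms.etymon_composition(points)
    return region_map, composition


@_stage("haplogroup-frequencies")
def _frequency_stage(config, records, lookup, outdir):
    table = hg.haplogroup_frequencies(
        records, lookup, informative_threshold=config.informative_threshold)
    overall = hg.haplogroup_frequencies(
        records, lambda r: "all" if r.haplogroup else None,
        informative_threshold=config.informative_threshold)
    pd.concat([overall, table]).to_csv(
        outdir / "haplogroup_frequencies.tsv", sep="\t", index=False)
    groups = sorted(table["group"].unique())
    contrasts = {}
    if len(groups) == 2:
        a, b = groups
        ta = table[table["group"] == a].set_index("haplogroup")
        tb = table[table["group"] == b].set_index("haplogroup")
        hgs = sorted(set(ta.index) | set(tb.index))
        pvals = []
        for h in hgs:
            xa = int(ta.loc[h, "count"]) if h in ta.index else 0
            xb = int(tb.loc[h, "count"]) if h in tb.index else 0
            na = int(ta["n"].iloc[0])
            nb = int(tb["n"].iloc[0])
            _, p = hg.fisher_exact_2x2([[xa, na - xa], [xb, nb - xb]])
            pvals.append(p)
        adj, sig = hg.adjust_pvalues(pvals, method=config.mt_method)
        contrasts = {
            h: {"p": p, "p_adjusted": float(q), "significant": bool(s)}
            for h, p, q, s in zip(hgs, pvals, adj, sig)}
        pd.DataFrame({"haplogroup": hgs, "p": pvals, "p_adjusted": adj,
                      "significant": sig}).to_csv(
            outdir / "haplogroup_contrasts.tsv", sep="\t", index=False)
    return contrasts


@_stage("prepare-haplotypes")
def _numeric_stage(records, panel):
    numeric = {}
    for rec in records:
        prof = strprofiles.derive_dys389b(rec.str_profile)
        numeric[rec.id] = strprofiles.to_numeric(prof, panel)
    return numeric


@_stage("diversity")
def _diversity_stage(records, numeric, lookup, outdir):
    groups = {"all": [numeric[r.id] for r in records]}
    for rec in records:
        g = lookup(rec)
        if g is not None:
            groups.setdefault(g, []).append(numeric[rec.id])
    rows, out = [], {}
    for g, haps in sorted(groups.items()):
        if len(haps) < 2:
            continue
        d = strprofiles.diversity_stats(haps)
        rows.append({"group": g, "n": d.n, "k": d.k,
                     "H": d.haplotype_diversity,
                     "D": d.discrimination_capacity,
                     "mean_pairwise_diff": d.mean_pairwise_diff,
                     "sd_pairwise_diff": d.sd_pairwise_diff,
                     "mean_multistep": d.mean_multistep,
                     "n_pairs": d.n_pairs})
        out[g] = rows[-1]
    pd.DataFrame(rows).to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    return out


@_stage("population-structure")
def _structure_stage(config, placed, numeric, lookup, outdir):
    by_region: dict[str, list] = {}
    by_mun: dict[str, list] = {}
    for rec in placed:
        by_region.setdefault(lookup(rec), []).append(numeric[rec.id])
        mun = rec.municipality(config.generation_level)
        by_mun.setdefault(mun, []).append(numeric[rec.id])
    summary: dict = {}
    if len(by_region) >= 2 and all(len(v) >= 2 for v in by_region.values()):
        res = popstruct.pairwise_phist(by_region, n_perm=config.permutations_fst,
                                       seed=config.seed)
        est, pv = res.to_frames()
        est.to_csv(outdir / "phist_regions.tsv", sep="\t")
        pv.to_csv(outdir / "phist_regions_pvalues.tsv", sep="\t")
        labels = list(res.labels)
        summary["phist_regions"] = {
            f"{a}|{b}": {"phist": float(res.estimates[i, j]),
                         "p": float(res.pvalues[i, j])}
            for i, a in enumerate(labels) for j, b in enumerate(labels) if i < j}
        summary["shannon_mutual_information"] = {
            "haplotype": popstruct.shannon_mutual_information(by_region),
            "per_locus": popstruct.shannon_mutual_information(
                by_region, mode="per-locus"),
        }
    mun_ok = {m: h for m, h in by_mun.items() if len(h) >= 2}
    if len(mun_ok) >= 3:
        res = popstruct.pairwise_phist(mun_ok, n_perm=config.permutations_fst,
                                       seed=config.seed + 1)
        est, pv = res.to_frames()
        est.to_csv(outdir / "phist_municipal.tsv", sep="\t")
        pv.to_csv(outdir / "phist_municipal_pvalues.tsv", sep="\t")
        emb = popstruct.pcoa(np.maximum(res.estimates, 0.0))
        coords = pd.DataFrame(
            emb.coordinates, index=list(res.labels),
            columns=[f"PCo{i+1}" for i in range(emb.n_axes)])
        with open(outdir / "pcoa_municipal.tsv", "w") as fh:
            fh.write("# eigenvalues\t" + "\t".join(
                f"{v:.10g}" for v in emb.eigenvalues) + "\n")
            fh.write("# variance_fraction\t" + "\t".join(
                f"{v:.10g}" for v in emb.variance_fraction) + "\n")
            coords.to_csv(fh, sep="\t")
        summary["pcoa"] = {
            "variance_fraction": [float(v) for v in emb.variance_fraction[:2]]}
    return summary


@_stage("spatial-autocorrelation")
def _spatial_stage(config, placed, numeric, roads, outdir):
    level = config.generation_level
    usable = [r for r in placed if r.municipality(level) is not None]
    if len(usable) < 4:
        return {"skipped": f"only {len(usable)} usable records"}
    haps = [numeric[r.id] for r in usable]
    muns = [r.municipality(level) for r in usable]
    d2 = popstruct.haplotype_distance_matrix(haps)
    C = spatial.gower_center(d2)
    geo = np.zeros((len(usable), len(usable)))
    for i, a in enumerate(muns):
        for j, b in enumerate(muns):
            if i < j and a != b:
                geo[i, j] = geo[j, i] = roads.distance(a, b)
    classes = spatial.build_distance_classes(
        geo, "even-pair-counts", k=config.n_distance_classes)
    corr = spatial.autocorrelogram(
        C, classes, n_perm=config.permutations_autocorr,
        n_boot=config.bootstraps, seed=config.seed)
    corr.to_frame().to_csv(outdir / "correlogram.tsv", sep="\t", index=False)
    with open(outdir / "correlogram_overall.tsv", "w") as fh:
        fh.write(f"omega\t{corr.omega:.10g}\nomega_p\t{corr.omega_p:.10g}\n")
    return {"n_individuals": len(usable), "omega": corr.omega,
            "omega_p": corr.omega_p,
            "r": [float(v) for v in corr.r],
            "p_per_class": [float(v) for v in corr.pvalues]}
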