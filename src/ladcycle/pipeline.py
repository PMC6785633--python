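"""Stage-wise orchestration of the LAD periodicity analysis.

Each stage reads and writes only declared files under one output directory
(one subdirectory per stage, TSV outputs plus a machine-readable manifest),
so stages can be re-run individually:

  simulate   -> toy genome, LAD BEDs per (CT, replicate), genes, FPKM, truth
  lads       -> cov_max, border series, replicate intersects, stats, gain/loss
  rhythm     -> rhythm fits of variable LAD borders
  randomize  -> CT-order randomization verdicts for fitted borders
  expression -> per-gene rhythm classification from FPKM
  genedist   -> strand-aware gene-to-nearest-LAD distances and variation
  report     -> joined summary (periodic LADs with verdicts, gene context)

Identical config and seeds produce byte-identical outputs; no stage mutates
its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import dynamics, expression, genes, randomization, rhythm, simulate
from .grid import TimeGrid
from .intervals import GenomicInterval, IntervalSet, intersect_all, read_bed, write_bed

log = logging.getLogger("ladcycle")

FLOAT_FMT = "%.10g"


def default_config() -> dict[str, Any]:
    return {
        "seed": 0,
        "grid": {
            "times_h": [0, 6, 12, 18, 24, 30],
            "ct_labels": ["CT0", "CT6", "CT12", "CT18", "CT24", "CT30"],
            "replicates": ["r1", "r2"],
        },
        "paths": {},  # lad_dir, genes, fpkm; default to the simulate stage outputs
        "thresholds": {"strong_p": 0.005, "relaxed_p": 0.05},
        "rhythm": {
            "ls_period_range": [12.0, 48.0],
            "ls_oversample": 10.0,
            "ls_tail": "beta",
            "ls_n_effective": "scanned",
            "strategy": "replicates",
            "min_border_sd": 0.0,
        },
        "randomization": {"n_shuffles": 3, "alpha": 0.05, "min_discordant": 2},
        "genedist": {"window_bp": 2_500_000, "variation_cts": ["CT0", "CT12", "CT24"]},
        "expression": {"replicates": ["r1", "r2", "r3"], "expressed_threshold": 0.0},
        "simulate": {
            "n_chroms": 2,
            "chrom_length": 60_000_000,
            "n_lads": 40,
            "n_genes": 120,
            "emit_ns": True,
        },
    }


def load_config(path: str | Path | None) -> dict[str, Any]:
    cfg = default_config()
    if path is not None:
        with Path(path).open() as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, extra: Mapping) -> None:
    for key, value in extra.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def _grid(cfg: Mapping, replicates: list[str] | None = None) -> TimeGrid:
    g = cfg["grid"]
    return TimeGrid(
        tuple(g["ct_labels"]),
        tuple(float(t) for t in g["times_h"]),
        tuple(replicates if replicates is not None else g["replicates"]),
    )


def _engine_kwargs(cfg: Mapping) -> dict[str, Any]:
    r = cfg["rhythm"]
    return {
        "ls_period_range": tuple(r["ls_period_range"]),
        "ls_oversample": r["ls_oversample"],
        "ls_tail": r["ls_tail"],
        "ls_n_effective": r["ls_n_effective"],
        "strategy": r["strategy"],
    }


def _stage_dir(outdir: Path, stage: str) -> Path:
    d = Path(outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_manifest(stage_dir: Path, cfg: Mapping, extra: Mapping | None = None) -> None:
    dump = yaml.safe_dump(_jsonable(cfg), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(dump.encode()).hexdigest(),
        "seed": cfg.get("seed"),
    }
    if extra:
        manifest.update(_jsonable(extra))
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input does not exist: {path}")
    return path


def _paths(cfg: Mapping, outdir: Path) -> dict[str, Path]:
    paths = cfg.get("paths") or {}
    sim = Path(outdir) / "simulate"
    return {
        "lad_dir": Path(paths.get("lad_dir", sim / "lads")),
        "genes": Path(paths.get("genes", sim / "genes.bed")),
        "fpkm": Path(paths.get("fpkm", sim / "fpkm.tsv")),
    }


def setup_logging(outdir: Path, level: int = logging.INFO) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    handlers.append(logging.FileHandler(outdir / "pipeline.log"))
    logging.basicConfig(
        level=level,
        handlers=handlers,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )


# -- stages ----------------------------------------------------------------


def run_simulate(cfg: Mapping, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    stage = _stage_dir(outdir, "simulate")
    (outdir / "config_used.yaml").write_text(yaml.safe_dump(_jsonable(cfg), sort_keys=True))
    seed = int(cfg["seed"])
    sim_cfg = cfg["simulate"]
    lad_grid = _grid(cfg)
    expr_grid = _grid(cfg, replicates=list(cfg["expression"]["replicates"]))

    genome = simulate.generate_genome(
        n_chroms=int(sim_cfg["n_chroms"]),
        chrom_length=int(sim_cfg["chrom_length"]),
        n_lads=int(sim_cfg["n_lads"]),
        n_genes=int(sim_cfg["n_genes"]),
        seed=seed,
    )
    specs = simulate.default_lad_specs(genome.base_lads, seed=seed + 1)
    course = simulate.generate_lad_timecourse(
        genome.base_lads, specs, lad_grid, seed=seed + 2, emit_ns=bool(sim_cfg.get("emit_ns"))
    )
    lad_dir = stage / "lads"
    lad_dir.mkdir(exist_ok=True)
    for (ct, rep), iset in course.samples.items():
        write_bed(iset, lad_dir / f"{ct}_{rep}.bed")
    for rep, iset in course.ns_samples.items():
        write_bed(iset, lad_dir / f"NS_{rep}.bed")
    genes.write_genes_bed(genome.genes, stage / "genes.bed")
    expr_specs = simulate.default_expression_specs(genome.genes, seed=seed + 3)
    fpkm, expr_truth, n_trunc = simulate.generate_expression_timecourse(
        expr_specs, expr_grid, seed=seed + 4
    )
    fpkm.to_csv(stage / "fpkm.tsv", sep="\t", float_format=FLOAT_FMT)
    _write_tsv(course.truth, stage / "lad_truth.tsv")
    _write_tsv(course.spec_table, stage / "lad_specs.tsv")
    _write_tsv(expr_truth, stage / "expression_truth.tsv")
    _write_tsv(genome.gene_truth, stage / "gene_truth.tsv")
    _write_manifest(stage, cfg, {"n_clamped": course.n_clamped, "n_truncated_fpkm": n_trunc})
    log.info("simulate: %d LADs, %d genes, %d clamp events", len(genome.base_lads),
             len(genome.genes), course.n_clamped)
    return stage


def _load_lad_samples(cfg: Mapping, outdir: Path) -> tuple[dict[tuple[str, str], IntervalSet], dict[str, IntervalSet]]:
    grid = _grid(cfg)
    lad_dir = _require(_paths(cfg, outdir)["lad_dir"])
    samples: dict[tuple[str, str], IntervalSet] = {}
    for ct, rep in grid.samples():
        path = _require(lad_dir / f"{ct}_{rep}.bed")
        samples[(ct, rep)] = read_bed(path).normalize()
    ns: dict[str, IntervalSet] = {}
    for rep in grid.replicates:
        path = lad_dir / f"NS_{rep}.bed"
        if path.exists():
            ns[rep] = read_bed(path).normalize()
    return samples, ns


def run_lads(cfg: Mapping, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    stage = _stage_dir(outdir, "lads")
    grid = _grid(cfg)
    samples, ns = _load_lad_samples(cfg, outdir)

    records = dynamics.compute_covmax(samples.values())
    cov = dynamics.covmax_frame(records)
    cov_set = IntervalSet(
        tuple(GenomicInterval(r.chrom, r.start, r.end) for r in records),
        label="cov_max", normalized=True,
    )
    write_bed(cov_set, stage / "covmax.bed", names=[r.lad_id for r in records])
    _write_tsv(cov, stage / "covmax.tsv")

    borders = dynamics.border_series_table(records, samples)
    _write_tsv(borders, stage / "border_series.tsv")

    # replicate intersects per CT (used for descriptive stats and distances)
    intersects: dict[str, IntervalSet] = {}
    for ct in grid.ct_labels:
        intersects[ct] = intersect_all(
            [samples[(ct, rep)] for rep in grid.replicates], label=ct
        )
        write_bed(intersects[ct], stage / f"intersect_{ct}.bed")
    stats = dynamics.lad_stats(intersects)
    _write_tsv(stats, stage / "lad_stats.tsv")

    jac_rows = []
    for ct in grid.ct_labels:
        reps = grid.replicates
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                jac_rows.append(
                    (ct, reps[i], reps[j], samples[(ct, reps[i])].jaccard(samples[(ct, reps[j])]))
                )
    _write_tsv(pd.DataFrame(jac_rows, columns=["ct", "rep_a", "rep_b", "jaccard"]),
               stage / "replicate_jaccard.tsv")

    if ns:
        ns_intersect = intersect_all(list(ns.values()), label="NS")
        write_bed(ns_intersect, stage / "intersect_NS.bed")
        first_ct = grid.ct_labels[0]
        gl = dynamics.classify_gain_loss(ns_intersect, intersects[first_ct])
        _write_tsv(gl, stage / f"gain_loss_{first_ct}_vs_NS.tsv")
        _write_tsv(dynamics.gain_loss_totals(gl), stage / f"gain_loss_totals_{first_ct}_vs_NS.tsv")
    _write_manifest(stage, cfg, {"n_covmax": len(records)})
    log.info("lads: %d cov_max regions", len(records))
    return stage


def _border_matrix(borders: pd.DataFrame, grid: TimeGrid) -> dict[tuple[str, str], np.ndarray]:
    """(lad_id, side) -> (n_replicates, n_ct) value array."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for (lad_id, side), sub in borders.groupby(["lad_id", "side"], sort=True):
        arr = np.full((grid.n_replicates, grid.n_ct), np.nan)
        for _, row in sub.iterrows():
            i = grid.replicates.index(row["replicate"])
            j = grid.ct_labels.index(row["ct"])
            arr[i, j] = row["value"]
        if np.isnan(arr).any():
            raise ValueError(f"border series {lad_id}/{side} does not cover the full grid")
        out[(lad_id, side)] = arr
    return out


def run_rhythm(cfg: Mapping, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    stage = _stage_dir(outdir, "rhythm")
    grid = _grid(cfg)
    borders = pd.read_csv(_require(Path(outdir) / "lads" / "border_series.tsv"), sep="\t")
    matrices = _border_matrix(borders, grid)
    min_sd = float(cfg["rhythm"]["min_border_sd"])
    engine = _engine_kwargs(cfg)
    times = np.asarray(grid.times_h)
    rows = []
    n_skipped = 0
    for (lad_id, side), arr in matrices.items():
        if arr.std(ddof=0) <= min_sd:
            n_skipped += 1
            continue
        fit = rhythm.meta_fit(arr, times, series_id=f"{lad_id}:{side}", **engine)
        rows.append(
            (
                lad_id,
                side,
                fit.p_jtk,
                fit.p_ls,
                fit.p_combined,
                fit.period_jtk,
                fit.period_ls,
                fit.period_mean,
                fit.phase_h,
                fit.amplitude,
                fit.base,
                fit.period_group if fit.period_group is not None else "none",
                fit.phase_group if fit.phase_group is not None else "none",
            )
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "lad_id", "side", "p_jtk", "p_ls", "p_combined", "period_jtk", "period_ls",
            "period_mean", "phase_h", "amplitude", "base", "period_group", "phase_group",
        ],
    )
    _write_tsv(result, stage / "lad_rhythm.tsv")
    _write_manifest(stage, cfg, {"n_fitted": len(result), "n_skipped_low_variance": n_skipped})
    log.info("rhythm: fitted %d variable borders (skipped %d)", len(result), n_skipped)
    return stage


def run_randomize(cfg: Mapping, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    stage = _stage_dir(outdir, "randomize")
    grid = _grid(cfg)
    rnd = cfg["randomization"]
    borders = pd.read_csv(_require(Path(outdir) / "lads" / "border_series.tsv"), sep="\t")
    fits = pd.read_csv(_require(Path(outdir) / "rhythm" / "lad_rhythm.tsv"), sep="\t")
    matrices = _border_matrix(borders, grid)
    perms = randomization.shuffle_ct_orders(
        grid.n_ct, n=int(rnd["n_shuffles"]), seed=int(cfg["seed"]) + 10
    )
    engine = _engine_kwargs(cfg)
    times = np.asarray(grid.times_h)
    rows = []
    for _, fit_row in fits.iterrows():
        key = (fit_row["lad_id"], fit_row["side"])
        verdict = randomization.randomization_verdict(
            matrices[key],
            times,
            perms,
            series_id=f"{key[0]}:{key[1]}",
            alpha=float(rnd["alpha"]),
            min_discordant=int(rnd["min_discordant"]),
            **engine,
        )
        rows.append(
            (
                key[0],
                key[1],
                verdict.experimental_group if verdict.experimental_group is not None else "none",
                verdict.p_experimental,
                ",".join("none" if g is None else str(g) for g in verdict.shuffle_groups),
                verdict.n_shuffles,
                verdict.n_discordant,
                verdict.passes,
            )
        )
    result = pd.DataFrame(
        rows,
        columns=["lad_id", "side", "experimental_group", "p_experimental",
                 "shuffle_groups", "n_shuffles", "n_discordant", "passes"],
    )
    _write_tsv(result, stage / "verdicts.tsv")
    _write_manifest(stage, cfg, {"n_series": len(result),
                                 "permutations": [list(p) for p in perms]})
    log.info("randomize: %d verdicts", len(result))
    return stage


def run_expression(cfg: Mapping, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    stage = _stage_dir(outdir, "expression")
    expr_grid = _grid(cfg, replicates=list(cfg["expression"]["replicates"]))
    fpkm_path = _require(_paths(cfg, outdir)["fpkm"])
    matrix = expression.ExpressionMatrix.read_tsv(fpkm_path, expr_grid)
    results, excluded = expression.classify_periodic(
        matrix,
        strong_p=float(cfg["thresholds"]["strong_p"]),
        expressed_threshold=float(cfg["expression"]["expressed_threshold"]),
        **_engine_kwargs(cfg),
    )
    out = results.copy()
    out["period_group"] = out["period_group"].map(lambda g: "none" if pd.isna(g) else int(g))
    out["phase_group"] = out["phase_group"].fillna("none")
    nonperiodic = expression.classify_nonperiodic(results)
    out["nonperiodic_reference"] = out["gene_id"].isin(nonperiodic)
    _write_tsv(out, stage / "gene_rhythm.tsv")
    pd.DataFrame({"gene_id": excluded}).to_csv(
        stage / "excluded_unexpressed.tsv", sep="\t", index=False
    )
    _write_manifest(stage, cfg, {"n_classified": len(out), "n_excluded": len(excluded)})
    log.info("expression: %d genes classified, %d excluded", len(out), len(excluded))
    return stage


def run_genedist(cfg: Mapping, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    stage = _stage_dir(outdir, "genedist")
    grid = _grid(cfg)
    gene_list = genes.read_genes_bed(_require(_paths(cfg, outdir)["genes"]))
    intersects = {
        ct: read_bed(_require(Path(outdir) / "lads" / f"intersect_{ct}.bed")).normalize()
        for ct in grid.ct_labels
    }
    table = genes.distance_table(gene_list, intersects)
    _write_tsv(table, stage / "distances.tsv")

    cts = cfg["genedist"]["variation_cts"]
    pivots = {
        ct: dict(zip(table.loc[table["ct"] == ct, "gene_id"],
                     table.loc[table["ct"] == ct, "nearest"]))
        for ct in cts
    }
    variation = genes.distance_variation(pivots[cts[0]], pivots[cts[1]], pivots[cts[2]])
    _write_tsv(variation, stage / "distance_variation.tsv")
    excluded = pd.DataFrame(variation.attrs.get("excluded", []), columns=["gene_id", "reason"])
    _write_tsv(excluded, stage / "distance_variation_excluded.tsv")
    _write_manifest(stage, cfg, {"n_genes": len(gene_list)})
    log.info("genedist: %d genes over %d CTs", len(gene_list), len(intersects))
    return stage


def run_report(cfg: Mapping, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    stage = _stage_dir(outdir, "report")
    strong = float(cfg["thresholds"]["strong_p"])
    relaxed = float(cfg["thresholds"]["relaxed_p"])

    fits = pd.read_csv(_require(outdir / "rhythm" / "lad_rhythm.tsv"), sep="\t")
    verdicts = pd.read_csv(_require(outdir / "randomize" / "verdicts.tsv"), sep="\t")
    gene_fits = pd.read_csv(_require(outdir / "expression" / "gene_rhythm.tsv"), sep="\t")

    lad_summary = fits.merge(verdicts[["lad_id", "side", "n_discordant", "passes"]],
                             on=["lad_id", "side"], how="left")
    periodic = lad_summary[
        (lad_summary["p_combined"] < relaxed) & (lad_summary["period_group"] != "none")
    ].copy()
    _write_tsv(periodic.sort_values(["p_combined", "lad_id", "side"]),
               stage / "periodic_lads.tsv")

    summary: dict[str, Any] = {
        "n_borders_fitted": int(len(fits)),
        "n_borders_periodic_strong": int(
            ((fits["p_combined"] < strong) & (fits["period_group"] != "none")).sum()
        ),
        "n_borders_periodic_relaxed": int(
            ((fits["p_combined"] < relaxed) & (fits["period_group"] != "none")).sum()
        ),
        "n_lads_periodic_strong": int(
            fits.loc[(fits["p_combined"] < strong) & (fits["period_group"] != "none"),
                     "lad_id"].nunique()
        ),
        "n_lads_periodic_relaxed": int(
            fits.loc[(fits["p_combined"] < relaxed) & (fits["period_group"] != "none"),
                     "lad_id"].nunique()
        ),
        "n_verdict_passes": int(verdicts["passes"].sum()),
        "n_genes_classified": int(len(gene_fits)),
        "n_genes_periodic_strong": int(gene_fits["cls"].str.startswith("periodic").sum()),
        "n_genes_nonperiodic_reference": int(gene_fits["nonperiodic_reference"].sum()),
    }

    truth_path = outdir / "simulate" / "lad_specs.tsv"
    if truth_path.exists():
        specs = pd.read_csv(truth_path, sep="\t")
        merged = fits.merge(specs, on=["lad_id", "side"], how="left")
        cosine = merged[merged["mode"] == "cosine"]
        if len(cosine):
            correct = (
                cosine["period_group"].astype(str)
                == cosine["period_h"].map(lambda p: str(int(p)))
            ) & (cosine["p_combined"] < relaxed)
            summary["border_period_recovery_rate"] = float(correct.mean())
        expr_truth_path = outdir / "simulate" / "expression_truth.tsv"
        if expr_truth_path.exists():
            etruth = pd.read_csv(expr_truth_path, sep="\t")
            gm = gene_fits.merge(etruth, on="gene_id", how="left")
            per = gm[gm["label"] == "periodic"]
            if len(per):
                target = per["period_h"].astype(int).astype(str)
                ok_strong = per["cls"] == "periodic-" + target
                ok_relaxed = (per["p_combined"] < relaxed) & (
                    per["period_group"].astype(str) == target
                )
                summary["gene_period_recovery_rate_strong"] = float(ok_strong.mean())
                summary["gene_period_recovery_rate_relaxed"] = float(ok_relaxed.mean())
    (stage / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")
    _write_manifest(stage, cfg)
    log.info("report: %s", summary)
    return stage


STAGES = {
    "simulate": run_simulate,
    "lads": run_lads,
    "rhythm": run_rhythm,
    "randomize": run_randomize,
    "expression": run_expression,
    "genedist": run_genedist,
    "report": run_report,
}

STAGE_ORDER = ["simulate", "lads", "rhythm", "randomize", "expression", "genedist", "report"]


def run_all(cfg: Mapping, outdir: str | Path) -> None:
    for name in STAGE_ORDER:
        STAGES[name](cfg, outdir)
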