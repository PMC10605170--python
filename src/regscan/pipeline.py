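"""End-to-end orchestration of the regulatory survey.

A single declarative config drives the stages in dependency order:

    coexpression ∥ chromatin scan → overlap enrichment → distance/GSEA →
    GSEA–signal integration

Every stage reads and writes plain-text files (TSV/BED/BEDPE/GMT/JSON), is
seeded from the global seed through named substreams, and records its
outputs in a run manifest with content hashes, so identical configs and
seeds give byte-identical results.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .chromatin import (
    BinCountMatrix,
    DEFAULT_ALPHA,
    RELAXED_ALPHA,
    correlate_bins,
    select_significant,
)
from .coexpression import CohortExpression, pan_cancer_median, spearman_to_focal, z_transform
from .enrichment import PeakExperiment, factor_enrichment, loop_intersect, overlap_survey
from .intervals import BinGrid, GenomicInterval, make_bins
from .seeding import stage_rng, stage_seed
from .similarity import (
    TargetGeneSet,
    build_regulatory_matrix,
    build_target_sets,
    gene_distance,
    gsea_batch,
    gsea_signal_integration,
    pca_project,
)
from .chromatin import quantile_normalize

__version__ = "0.1.0"

logger = logging.getLogger("regscan")

__all__ = ["RunConfig", "StageError", "run_pipeline", "validate_inputs", "write_simulation"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration for a full survey run.

    Thresholds follow the survey's constants: window-scoped BH cutoffs 1e-4
    (strict) and 5e-3 (relaxed), 100 permutations for expected overlap,
    10,000 draws for the factor-level permutation test and for GSEA.
    """

    focal_gene: str
    cohorts_dir: str
    atac_counts: str
    atac_expression: str
    peak_manifest: str
    outdir: str
    loops: str | None = None
    target_sets: str | None = None  # GMT; alternative to tss-based construction
    tss: str | None = None
    focal_promoter: str | None = None  # region string; default window center ±1 kb
    alpha: float = DEFAULT_ALPHA
    alpha_relaxed: float = RELAXED_ALPHA
    n_perm: int = 100
    n_null: int = 10_000
    gsea_n_perm: int = 10_000
    min_cohorts: int = 3
    min_peak_score: float | None = None  # upstream peak-inclusion score filter
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for threshold in (self.alpha, self.alpha_relaxed):
            if not 0 < threshold < 1:
                raise ValueError(f"alpha thresholds must lie in (0, 1), got {threshold}")
        if self.n_perm < 1 or self.n_null < 100 or self.gsea_n_perm < 100:
            raise ValueError("permutation counts too small")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        required = [self.cohorts_dir, self.atac_counts, self.atac_expression, self.peak_manifest]
        optional = [self.loops, self.target_sets, self.tss]
        for p in required + [p for p in optional if p]:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        if self.target_sets is None and self.tss is None:
            raise ValueError("need either a target-set GMT or a TSS table")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohorts(cohorts_dir: str) -> list[CohortExpression]:
    paths = sorted(Path(cohorts_dir).glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no cohort TSVs in {cohorts_dir}")
    return [CohortExpression(p.stem, io.read_expression_tsv(p)) for p in paths]


def _load_peaks(manifest_path: str, min_score: float | None) -> list[PeakExperiment]:
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = Path(manifest_path).parent
    experiments = []
    for row in manifest.itertuples():
        bed = io.read_bed(base / row.path, n_cols=5)
        if min_score is not None:
            bed = bed[bed["score"] >= min_score]
        experiments.append(
            PeakExperiment(
                experiment_id=str(row.experiment_id),
                factor=str(row.factor),
                context=str(getattr(row, "context", "")),
                starts=bed["start"].to_numpy(),
                ends=bed["end"].to_numpy(),
                scores=bed["score"].to_numpy(float),
            )
        )
    return experiments


def run_pipeline(config: RunConfig) -> dict:
    """Execute all survey stages; returns the run manifest (also written).

    Stage order: co-expression and chromatin scans feed the enrichment
    stage, whose inputs (significant bins) and the co-expression ranking
    feed distance/GSEA, then integration. Any stage failure aborts the run
    with the failing stage named; outputs of completed stages remain on
    disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {k: v for k, v in vars(config).items()},
        "stage_seeds": {},
        "outputs": {},
    }

    def record(stage: str, path: Path) -> None:
        manifest["outputs"][path.name] = {"stage": stage, "sha256": _sha256(path)}

    def run_stage(stage: str, fn):
        t0 = time.monotonic()
        seed_state = stage_seed(config.seed, stage).entropy
        manifest["stage_seeds"][stage] = seed_state
        logger.info("stage=%s seed=%s start", stage, seed_state)
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - named-stage abort contract
            raise StageError(stage, exc) from exc
        logger.info("stage=%s wall_time=%.2fs done", stage, time.monotonic() - t0)
        return result

    # --- stage: co-expression survey -------------------------------------
    def coexpr():
        cohorts = _load_cohorts(config.cohorts_dir)
        zs = [z_transform(spearman_to_focal(c, config.focal_gene)) for c in cohorts]
        score = pan_cancer_median(zs, min_cohorts=config.min_cohorts)
        path = outdir / "coexpression.tsv"
        score.table.to_csv(path, sep="\t", index_label="gene", float_format=io.FLOAT_FORMAT)
        record("coexpr", path)
        return score

    score = run_stage("coexpr", coexpr)

    # --- stage: chromatin scan --------------------------------------------
    def chromatin():
        chrom, starts, ends, counts = io.read_bin_counts_tsv(config.atac_counts)
        window = GenomicInterval(chrom, int(starts.min()), int(ends.max()))
        bin_size = int(ends[0] - starts[0])
        grid = make_bins(window, bin_size)
        expr = pd.read_csv(config.atac_expression, sep="\t", index_col=0).iloc[:, 0]
        normalized = quantile_normalize(counts)
        track = correlate_bins(BinCountMatrix(grid, normalized), expr)
        path = outdir / "bin_track.tsv"
        track.table.to_csv(path, sep="\t", index=False, float_format=io.FLOAT_FORMAT)
        record("chromatin", path)
        pos, neg = select_significant(track, config.alpha)
        for name, sub in (("positive_bins.bed", pos), ("negative_bins.bed", neg)):
            p = outdir / name
            io.write_bed(p, sub[["chrom", "start", "end", "rho", "padj"]])
            record("chromatin", p)
        return track, pos, neg

    track, pos_bins, neg_bins = run_stage("chromatin", chromatin)

    # --- stage: overlap enrichment -----------------------------------------
    def enrich():
        experiments = _load_peaks(config.peak_manifest, config.min_peak_score)
        sig = pd.concat([pos_bins, neg_bins])
        background = track.grid.window
        rng = stage_rng(config.seed, "enrich")
        results = overlap_survey(
            experiments,
            sig["start"].to_numpy(),
            sig["end"].to_numpy(),
            background,
            n_perm=config.n_perm,
            rng=rng,
        )
        table = factor_enrichment(results, n_null=config.n_null, rng=rng)
        path = outdir / "enrichment.tsv"
        table.to_csv(path, sep="\t", index_label="factor", float_format=io.FLOAT_FORMAT)
        record("enrich", path)
        if config.loops and len(neg_bins):
            loops = io.read_bedpe(config.loops)
            flags = loop_intersect(
                neg_bins["start"].to_numpy(), neg_bins["end"].to_numpy(),
                track.grid.window.chrom, loops,
            )
            flagged = neg_bins.copy()
            flagged["loop_anchor"] = flags.astype(int)
            p = outdir / "negative_bins_loops.tsv"
            flagged.to_csv(p, sep="\t", index=False, float_format=io.FLOAT_FORMAT)
            record("enrich", p)
        return experiments, table

    experiments, enrichment_table = run_stage("enrich", enrich)

    # --- stage: regulatory distance + GSEA ---------------------------------
    def distance_gsea():
        if config.target_sets:
            gmt = io.read_gmt(config.target_sets)
            sets = [
                TargetGeneSet(name, genes, pd.Series(np.nan, index=genes))
                for name, genes in gmt.items()
            ]
        else:
            tss = pd.read_csv(config.tss, sep="\t")
            sets = build_target_sets(experiments, tss)
        # the focal gene is excluded from its own co-expression ranking but
        # must carry an occupancy row for the distance computation
        universe = [config.focal_gene] + list(score.table.index)
        matrix = build_regulatory_matrix(sets, universe)
        dist = gene_distance(matrix, config.focal_gene)
        dist = dist.join(score.table["median_z"], how="left")
        path = outdir / "distances.tsv"
        dist.to_csv(path, sep="\t", index_label="gene", float_format=io.FLOAT_FORMAT)
        record("distance", path)
        proj, _ = pca_project(matrix)
        p = outdir / "pca.tsv"
        proj.to_csv(p, sep="\t", index_label="gene", float_format=io.FLOAT_FORMAT)
        record("distance", p)
        ranking = score.median_z.dropna()
        usable = {
            s.factor: [g for g in s.genes if g in ranking.index]
            for s in sets
        }
        usable = {k: v for k, v in usable.items() if v}
        gsea = gsea_batch(
            ranking, usable, n_perm=config.gsea_n_perm,
            rng=stage_rng(config.seed, "gsea"),
        )
        p = outdir / "gsea.tsv"
        gsea.to_csv(p, sep="\t", index_label="set", float_format=io.FLOAT_FORMAT)
        record("gsea", p)
        return gsea

    gsea = run_stage("distance_gsea", distance_gsea)

    # --- stage: GSEA–promoter-signal integration ----------------------------
    def integrate():
        if config.focal_promoter:
            promoter = GenomicInterval.parse(config.focal_promoter)
        else:
            center = (track.grid.window.start + track.grid.window.end) // 2
            promoter = GenomicInterval(track.grid.window.chrom, center - 1000, center + 1000)
        signal: dict[str, list[float]] = {}
        for exp in experiments:
            m = (exp.starts < promoter.end) & (exp.ends > promoter.start)
            if m.any():
                signal.setdefault(exp.factor, []).extend(exp.scores[m].tolist())
        promoter_signal = pd.Series(
            {f: float(np.mean(v)) for f, v in signal.items()}, name="promoter_signal"
        )
        rho, p_value, table = gsea_signal_integration(gsea, promoter_signal)
        path = outdir / "integration.tsv"
        table.to_csv(path, sep="\t", index_label="factor", float_format=io.FLOAT_FORMAT)
        record("integrate", path)
        io.write_json(
            outdir / "integration_summary.json",
            {"spearman_rho": rho, "p": p_value, "n_factors": int(len(table))},
        )
        record("integrate", outdir / "integration_summary.json")
        return rho, p_value

    run_stage("integrate", integrate)

    io.write_json(outdir / "run_manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(config: RunConfig) -> dict:
    """Machine-readable format report for every configured input file.

    Never raises for content problems: each failed check appends
    ``{"file", "check", "message"}`` to the report's error list. Sample-ID
    mismatches between the accessibility matrix and its expression table are
    reported as join warnings.
    """
    errors: list[dict] = []
    warnings_: list[dict] = []

    def err(file: str, check: str, message: str) -> None:
        errors.append({"file": str(file), "check": check, "message": message})

    try:
        cohorts = _load_cohorts(config.cohorts_dir)
        for c in cohorts:
            if config.focal_gene not in c.matrix.index:
                err(config.cohorts_dir, "focal_gene", f"{config.focal_gene} missing from {c.cohort}")
    except Exception as exc:  # noqa: BLE001
        err(config.cohorts_dir, "cohorts", str(exc))

    atac_samples: set[str] = set()
    try:
        _, starts, ends, counts = io.read_bin_counts_tsv(config.atac_counts)
        atac_samples = set(counts.columns)
        if (starts >= ends).any():
            err(config.atac_counts, "coordinates", "bin start >= end")
    except Exception as exc:  # noqa: BLE001
        err(config.atac_counts, "bin_counts", str(exc))

    try:
        expr = pd.read_csv(config.atac_expression, sep="\t", index_col=0).iloc[:, 0]
        shared = atac_samples & set(expr.index)
        if atac_samples and len(shared) < 4:
            warnings_.append(
                {
                    "file": str(config.atac_expression),
                    "check": "sample_join",
                    "message": f"only {len(shared)} sample IDs match the accessibility matrix",
                }
            )
    except Exception as exc:  # noqa: BLE001
        err(config.atac_expression, "expression", str(exc))

    try:
        manifest = pd.read_csv(config.peak_manifest, sep="\t")
        base = Path(config.peak_manifest).parent
        for row in manifest.itertuples():
            try:
                io.read_bed(base / row.path, n_cols=5)
            except Exception as exc:  # noqa: BLE001
                err(row.path, "bed", str(exc))
    except Exception as exc:  # noqa: BLE001
        err(config.peak_manifest, "manifest", str(exc))

    if config.loops:
        try:
            io.read_bedpe(config.loops)
        except Exception as exc:  # noqa: BLE001
            err(config.loops, "bedpe", str(exc))
    if config.target_sets:
        try:
            io.read_gmt(config.target_sets)
        except Exception as exc:  # noqa: BLE001
            err(config.target_sets, "gmt", str(exc))

    return {"errors": errors, "warnings": warnings_, "valid": not errors}


# ---------------------------------------------------------------------------
# simulation writer: emits a complete input fixture + ready-to-run config


def write_simulation(sim_config, outdir: str | Path) -> Path:
    """Write a full synthetic input set and a matching run config YAML.

    Returns the path of the written run config. The directory is laid out as
    the pipeline expects: ``cohorts/*.tsv``, ``atac_counts.tsv``,
    ``atac_expression.tsv``, ``peaks/*.bed`` + ``peak_manifest.tsv``,
    ``target_sets.gmt``, ``loops.bedpe``, ``tss.tsv`` and ``truth.json``.
    """
    from .synthetic import (
        simulate_atac,
        simulate_cohorts,
        simulate_peak_experiments,
        simulate_target_sets,
        simulate_tss_table,
    )

    outdir = Path(outdir)
    (outdir / "cohorts").mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)

    cohorts, truth = simulate_cohorts(sim_config)
    for c in cohorts:
        io.write_expression_tsv(outdir / "cohorts" / f"{c.cohort}.tsv", c.matrix)

    rng = stage_rng(sim_config.seed, "atac_expression")
    expr = pd.Series(
        np.exp(rng.normal(3.0, 1.0, size=sim_config.atac_samples)),
        index=[f"ATAC{i:04d}" for i in range(sim_config.atac_samples)],
        name="expression",
    )
    expr.to_frame().to_csv(
        outdir / "atac_expression.tsv", sep="\t", index_label="sample",
        float_format=io.FLOAT_FORMAT,
    )
    atac = simulate_atac(sim_config, expr)
    io.write_bin_counts_tsv(
        outdir / "atac_counts.tsv", atac.grid.window.chrom,
        atac.grid.starts, atac.grid.ends, atac.counts,
    )

    grid = sim_config.grid()
    planted_bins = [grid.bin(i) for i, _ in sim_config.planted_bins]
    if not planted_bins:  # null configs still need a target for peak placement
        planted_bins = [grid.bin(grid.n_bins // 2)]
    experiments = simulate_peak_experiments(sim_config, planted_bins)
    manifest_rows = []
    for exp in experiments:
        bed_name = f"peaks/{exp.experiment_id}.bed"
        io.write_bed(
            outdir / bed_name,
            pd.DataFrame(
                {
                    "chrom": sim_config.window.chrom,
                    "start": exp.starts,
                    "end": exp.ends,
                    "name": exp.experiment_id,
                    "score": exp.scores,
                }
            ),
        )
        manifest_rows.append(
            {
                "experiment_id": exp.experiment_id,
                "factor": exp.factor,
                "context": exp.context,
                "path": bed_name,
            }
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "peak_manifest.tsv", sep="\t", index=False)

    sets, universe, loops = simulate_target_sets(sim_config)
    io.write_gmt(outdir / "target_sets.gmt", {s.factor: s.genes for s in sets})
    io.write_bedpe(outdir / "loops.bedpe", loops)
    simulate_tss_table(sim_config).to_csv(outdir / "tss.tsv", sep="\t", index=False)
    io.write_json(outdir / "truth.json", truth.to_dict())

    run_cfg = {
        "focal_gene": sim_config.focal_gene,
        "cohorts_dir": str(outdir / "cohorts"),
        "atac_counts": str(outdir / "atac_counts.tsv"),
        "atac_expression": str(outdir / "atac_expression.tsv"),
        "peak_manifest": str(outdir / "peak_manifest.tsv"),
        "target_sets": str(outdir / "target_sets.gmt"),
        "loops": str(outdir / "loops.bedpe"),
        "outdir": str(outdir / "results"),
        "seed": sim_config.seed,
    }
    cfg_path = outdir / "run_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return cfg_path
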