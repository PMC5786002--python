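"""End-to-end orchestration of the analysis stages from one YAML config.

The pipeline runs, in order and as requested by the config: per-stage
segmentation of pooled CpG tables, consensus merging across stages, gene
annotation (gUMRs, FMRs, demethylation flags, gene proximity),
replicate-aware differential methylation, and SNP enrichment. Every
artifact is written under the output directory and recorded in a
manifest with its SHA-256 checksum, so identical (config, inputs) yield
identical manifests.

Config layout (YAML)::

    seed: 1
    output_dir: out
    chrom_sizes: sizes.tsv
    stages:
      fetal:    [fetal_r1.tsv, fetal_r2.tsv]
      adult_NF: [nf_r1.tsv, nf_r2.tsv]
    segmentation: {min_cpgs: 3, max_meth: 0.5}   # optional overrides
    calibration_grid: [[3, 0.5], [4, 0.5]]       # optional
    annotation: {genes: genes.tsv, cgis: cgi.bed}
    dmr:
      comparisons:
        - name: NF_vs_F
          group_a: [nf_r1.tsv, nf_r2.tsv]
          group_b: [f_r1.tsv, f_r2.tsv]
    enrichment: {snps: snps.bed, n_iter: 100}
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import fields as dataclass_fields
from pathlib import Path

import yaml

from . import annotation as ann
from . import differential as diff
from . import enrichment as enr
from . import io as mio
from . import segmentation as seg

log = logging.getLogger("segmeth.pipeline")


class PipelineValidationError(ValueError):
    """Config invalid; message lists every problem found."""


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineValidationError("config must be a YAML mapping")
    cfg.setdefault("_config_dir", str(Path(path).parent))
    return cfg


def _resolve(cfg: dict, p) -> Path:
    p = Path(p)
    if not p.is_absolute():
        p = Path(cfg.get("_config_dir", ".")) / p
    return p


def validate_config(cfg: dict) -> list[str]:
    """Return a list of problems (empty means the config validates)."""
    problems: list[str] = []
    if "seed" not in cfg:
        problems.append("missing mandatory 'seed' (stochastic stages need it)")
    if "chrom_sizes" not in cfg:
        problems.append("missing 'chrom_sizes'")
    elif not _resolve(cfg, cfg["chrom_sizes"]).exists():
        problems.append(f"chrom_sizes file not found: {cfg['chrom_sizes']}")
    stages = cfg.get("stages", {})
    if not stages:
        problems.append("no 'stages' with CpG tables configured")
    for stage, paths in stages.items():
        for p in paths:
            if not _resolve(cfg, p).exists():
                problems.append(f"stage {stage}: missing input {p}")
    seg_cfg = cfg.get("segmentation", {})
    valid_keys = {f.name for f in dataclass_fields(seg.SegmentationParams)}
    for key in seg_cfg:
        if key not in valid_keys:
            problems.append(f"segmentation: unknown parameter {key!r}")
    if "annotation" in cfg:
        for key in ("genes",):
            if key not in cfg["annotation"]:
                problems.append(f"annotation: missing {key!r}")
            elif not _resolve(cfg, cfg["annotation"][key]).exists():
                problems.append(f"annotation: missing file {cfg['annotation'][key]}")
        cgis = cfg["annotation"].get("cgis")
        if cgis and not _resolve(cfg, cgis).exists():
            problems.append(f"annotation: missing file {cgis}")
    for comp in cfg.get("dmr", {}).get("comparisons", []):
        for side in ("group_a", "group_b"):
            for p in comp.get(side, []):
                if not _resolve(cfg, p).exists():
                    problems.append(f"dmr {comp.get('name')}: missing input {p}")
    if "enrichment" in cfg:
        snps = cfg["enrichment"].get("snps")
        if not snps:
            problems.append("enrichment: missing 'snps'")
        elif not _resolve(cfg, snps).exists():
            problems.append(f"enrichment: missing file {snps}")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: dict, output_dir=None) -> dict:
    """Run all configured stages; return the output manifest.

    The manifest maps artifact name -> {path, sha256}. A stage failure
    raises StageFailure naming the stage; artifacts written before the
    failure remain on disk.
    """
    problems = validate_config(cfg)
    if problems:
        raise PipelineValidationError("; ".join(problems))
    outdir = Path(output_dir or _resolve(cfg, cfg.get("output_dir", "segmeth_out")))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict[str, dict] = {}
    t_start = time.time()

    def record(name: str, path: Path):
        manifest[name] = {"path": str(path), "sha256": _sha256(path)}

    chrom_sizes = mio.read_chrom_sizes(_resolve(cfg, cfg["chrom_sizes"]))
    params = seg.SegmentationParams(**cfg.get("segmentation", {}))
    grid = [tuple(g) for g in cfg.get("calibration_grid", [])] or None
    log.info("segmentation parameters: %s (seed %d)", params, seed)

    # --- per-stage segmentation -------------------------------------------
    stage_sets: list[list[mio.GenomicRegion]] = []
    stage_methylomes: list[mio.Methylome] = []
    try:
        for stage, paths in cfg["stages"].items():
            reps = [
                mio.read_cpg_table(_resolve(cfg, p), f"{stage}_r{i}", chrom_sizes)
                for i, p in enumerate(paths, 1)
            ]
            pooled = seg.pool_replicates(reps, sample_id=stage)
            stage_methylomes.append(pooled)
            pmrs, hypo, calibration = seg.segment_methylome(
                pooled, params, seed=seed, calibration_grid=grid
            )
            stage_sets.append(pmrs + hypo)
            for cls in ("PMR", "LMR", "UMR"):
                path = outdir / f"{stage}.{cls}.bed"
                mio.write_regions_bed(
                    [r for r in pmrs + hypo if r.region_class == cls], path
                )
                record(f"{stage}.{cls}", path)
            if calibration is not None:
                path = outdir / f"{stage}.calibration.tsv"
                _write_calibration(calibration, path)
                record(f"{stage}.calibration", path)
            log.info(
                "stage %s: %d PMRs, %d LMR/UMR regions", stage, len(pmrs), len(hypo)
            )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageFailure("segment", exc) from exc

    # --- consensus merge ---------------------------------------------------
    try:
        union = seg.pool_replicates(stage_methylomes, sample_id="union")
        consensus = seg.merge_stage_segmentations(
            stage_sets, union, params.lmr_umr_cutoff
        )
        for cls in ("PMR", "LMR", "UMR"):
            path = outdir / f"consensus.{cls}.bed"
            mio.write_regions_bed(
                [r for r in consensus if r.region_class == cls], path
            )
            record(f"consensus.{cls}", path)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("merge", exc) from exc

    pmrs = [r for r in consensus if r.region_class == "PMR"]
    lmrs = [r for r in consensus if r.region_class == "LMR"]
    umrs = [r for r in consensus if r.region_class == "UMR"]

    # --- annotation --------------------------------------------------------
    genes = None
    if "annotation" in cfg:
        try:
            acfg = cfg["annotation"]
            genes = mio.read_gene_models(_resolve(cfg, acfg["genes"]))
            cgis = (
                mio.read_regions_bed(_resolve(cfg, acfg["cgis"]))
                if acfg.get("cgis")
                else []
            )
            gumrs = ann.assign_gumrs(umrs, genes, cgis, union)
            path = outdir / "gumrs.bed"
            with open(path, "wt") as fh:
                for g in gumrs:
                    for frag in g.fragments:
                        fh.write(
                            f"{frag.chrom}\t{frag.start}\t{frag.end}\t{g.gene_id}\n"
                        )
            record("gumrs", path)
            gene_map = {g.gene_id: g for g in genes}
            path = outdir / "demethylation_flags.tsv"
            with open(path, "wt") as fh:
                fh.write("gene_id\tflagged\treason\ttotal_length\tgene_fraction\n")
                for g in gumrs:
                    flag = ann.flag_extended_demethylation(g, gene_map[g.gene_id])
                    fh.write(
                        f"{g.gene_id}\t{int(flag.flagged)}\t{flag.reason or '.'}"
                        f"\t{g.total_length}\t{g.gene_fraction:.4f}\n"
                    )
            record("demethylation_flags", path)
            fmrs = ann.compute_fmrs(chrom_sizes, cgis, lmrs, umrs, pmrs)
            path = outdir / "consensus.FMR.bed"
            mio.write_regions_bed(fmrs, path)
            record("consensus.FMR", path)
            proximity = ann.nearest_gene_within(lmrs, genes)
            path = outdir / "lmr_gene_proximity.tsv"
            with open(path, "wt") as fh:
                fh.write("chrom\tstart\tend\tgene_id\n")
                for (chrom, s, e), gid in sorted(proximity.items()):
                    fh.write(f"{chrom}\t{s}\t{e}\t{gid or '.'}\n")
            record("lmr_gene_proximity", path)
        except Exception as exc:  # noqa: BLE001
            raise StageFailure("annotate", exc) from exc

    # --- differential methylation -----------------------------------------
    for comp in cfg.get("dmr", {}).get("comparisons", []):
        name = comp.get("name", "comparison")
        try:
            dparams = diff.DmrTestParams(**comp.get("params", {}))
            group_a = [
                mio.read_cpg_table(_resolve(cfg, p), f"a{i}", chrom_sizes)
                for i, p in enumerate(comp["group_a"], 1)
            ]
            group_b = [
                mio.read_cpg_table(_resolve(cfg, p), f"b{i}", chrom_sizes)
                for i, p in enumerate(comp["group_b"], 1)
            ]
            test_pmrs = pmrs
            if genes is not None:
                test_pmrs, _ = diff.exclude_gene_spanning_pmrs(pmrs, genes)
            regions = lmrs + umrs + test_pmrs
            results = diff.region_dmr_test(regions, group_a, group_b, dparams)
            path = outdir / f"dmr.{name}.tsv"
            _write_dmr(results, path)
            record(f"dmr.{name}", path)
            log.info(
                "dmr %s: %d/%d significant",
                name,
                sum(r.significant for r in results),
                len(results),
            )
        except Exception as exc:  # noqa: BLE001
            raise StageFailure(f"dmr:{name}", exc) from exc

    # --- SNP enrichment ----------------------------------------------------
    if "enrichment" in cfg:
        try:
            ecfg = cfg["enrichment"]
            snp_sets = read_snp_bed(_resolve(cfg, ecfg["snps"]))
            n_iter = int(ecfg.get("n_iter", 100))
            nulls = enr.sample_matched_regions(
                lmrs, chrom_sizes, n_iter=n_iter, seed=seed
            )
            path = outdir / "enrichment.tsv"
            with open(path, "wt") as fh:
                fh.write(
                    "trait\tn_snps\tobserved_in\texpected_in\tfold\tchi2\tp\t"
                    "p_empirical\tneg_log10_p\n"
                )
                for snps in snp_sets:
                    r = enr.snp_region_enrichment(snps, lmrs, nulls)
                    fold = f"{r.fold:.4f}" if r.fold is not None else "."
                    chi2 = f"{r.chi2:.4f}" if r.chi2 is not None else "."
                    fh.write(
                        f"{r.trait}\t{r.n_snps}\t{r.observed_in}\t{r.expected_in:.3f}"
                        f"\t{fold}\t{chi2}\t{r.p_value:.3e}\t{r.p_empirical:.3e}"
                        f"\t{r.neg_log10_p:.3f}\n"
                    )
            record("enrichment", path)
        except Exception as exc:  # noqa: BLE001
            raise StageFailure("enrich", exc) from exc

    path = outdir / "manifest.json"
    with open(path, "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline finished in %.1fs, %d artifacts", time.time() - t_start, len(manifest))
    return manifest


def read_snp_bed(path) -> list[enr.SnpSet]:
    """BED3+ SNP file with trait (col 4) and provenance (col 5) columns."""
    by_trait: dict[str, list] = {}
    prov: dict[str, list] = {}
    with mio._open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise mio.ParseError(f"{path}:{lineno}: need chrom,start,end,trait")
            trait = parts[3]
            by_trait.setdefault(trait, []).append((parts[0], int(parts[1])))
            prov.setdefault(trait, []).append(parts[4] if len(parts) > 4 else "lead")
    out = []
    for trait, positions in by_trait.items():
        uniq: dict[tuple[str, int], str] = {}
        for pos, pv in zip(positions, prov[trait]):
            uniq.setdefault(pos, pv)
        out.append(
            enr.SnpSet(
                trait=trait,
                positions=list(uniq),
                provenance=list(uniq.values()),
            )
        )
    return out


def _write_calibration(cal: seg.FdrCalibration, path: Path) -> None:
    with open(path, "wt") as fh:
        fh.write("min_cpgs\tmax_meth\tn_original\tn_randomized\tfdr\tchosen\n")
        for row in cal.as_rows():
            fh.write(
                f"{row['min_cpgs']}\t{row['max_meth']}\t{row['n_original']}"
                f"\t{row['n_randomized']}\t{row['fdr']:.6f}\t{int(row['chosen'])}\n"
            )


def _write_dmr(results: list[diff.DmrResult], path: Path) -> None:
    with open(path, "wt") as fh:
        fh.write(
            "chrom\tstart\tend\tclass\tn_cpg_tested\tmean_a\tmean_b\tdiff\tp\tq"
            "\tsignificant\tuntestable\n"
        )
        for r in results:
            q = f"{r.q_value:.4e}" if r.q_value is not None else "."
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}"
                f"\t{r.region.region_class}\t{r.n_cpg_tested}\t{r.mean_a:.4f}"
                f"\t{r.mean_b:.4f}\t{r.diff:.4f}\t{r.p_value:.4e}\t{q}"
                f"\t{int(r.significant)}\t{int(r.untestable)}\n"
            )
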