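"""End-to-end orchestration: simulate -> count -> diff -> annotate -> GO -> rescue.

A run is configured by one flat YAML file, executes its stages in
dependency order into a fixed run-directory layout, and leaves a
machine-readable ``report.json`` recording parameters, input checksums and
per-stage row counts. Outputs are deterministic: the same config and seed
produce byte-identical TSV/JSON outputs (``run.log`` carries wall-clock
timestamps and is the one exception).

Run directory layout::

    <outdir>/
      inputs/    simulated or copied input files
      counts/    per-library locus counts
      diff/      differential calls + summary
      genes/     locus-to-gene assignment of the selected locus set
      go/        GO enrichment results
      rescue/    expression screen results
      report.json, run.log
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import annotation, counting, differential, enrichment, genomeio, rescue as rescue_mod
from .counting import OverlapRule
from .differential import Direction, LIBRARY_ROLES
from .rescue import RescueCriteria
from .simulate import SimConfig, TruthManifest, config_from_dict, generate_dataset

__all__ = ["RunConfig", "ConfigError", "StageError", "validate_config", "run_all"]

logger = logging.getLogger("repeathet")


class ConfigError(ValueError):
    """Invalid run configuration; carries every violation found."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid run config:\n  - " + "\n  - ".join(errors))
        self.errors = errors


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "repeathet_run"
    seed: int = 17
    # either simulate a dataset ...
    simulate: SimConfig | None = None
    # ... or point at existing inputs
    reads: dict[str, str] = field(default_factory=dict)   # role -> BED path
    repeats: str | None = None                            # rmsk-style TSV
    genes: str | None = None
    association: str | None = None
    expression: str | None = None
    chrom_sizes: str | None = None
    manifest: str | None = None                           # optional truth for scoring
    # parameters
    min_fraction: float = 0.90
    unique_best: bool = False
    fold_threshold: float = 100.0
    rpm_floor: float | None = None
    min_input_reads: int = 0
    min_cond_fold: float = 1.0
    reversal_margin: float = 0.0
    flank: int = 10_000
    which: str = "hfup-reversed"  # locus set fed to the gene/GO stages
    universe_n: int | None = None
    term_k: dict[str, int] = field(default_factory=dict)
    max_ratio_hf: float = 0.5
    min_ratio_treat: float = 1.4
    min_hf_expression: float = 100.0
    rounding_tolerance: float = 0.0
    log_level: str = "INFO"


_WHICH_CHOICES = ("hfup-reversed", "hfup", "hfdown-reversed", "hfdown", "all-called")


def validate_config(source: str | Path | Mapping) -> RunConfig:
    """Parse and validate a run config, reporting every violation at once."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])

    errors: list[str] = []
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        errors.append(f"unknown option(s): {sorted(unknown)}")
        data = {k: v for k, v in data.items() if k in known}

    sim_cfg = None
    if data.get("simulate") is not None:
        try:
            sim_raw = dict(data["simulate"])
            if "seed" not in sim_raw and "seed" in data:
                sim_raw["seed"] = data["seed"]
            sim_cfg = config_from_dict(sim_raw)
            sim_cfg.validate()
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate: {exc}")
    data = {k: v for k, v in data.items() if k != "simulate"}

    try:
        cfg = RunConfig(simulate=sim_cfg, **data)
    except TypeError as exc:
        raise ConfigError(errors + [str(exc)])

    if not (0.0 < cfg.min_fraction <= 1.0):
        errors.append(f"min_fraction must be in (0, 1], got {cfg.min_fraction}")
    if cfg.fold_threshold <= 0:
        errors.append(f"fold_threshold must be positive, got {cfg.fold_threshold}")
    if cfg.rpm_floor is not None and cfg.rpm_floor <= 0:
        errors.append(f"rpm_floor must be positive, got {cfg.rpm_floor}")
    if cfg.min_input_reads < 0:
        errors.append("min_input_reads must be >= 0")
    if cfg.min_cond_fold < 1.0:
        errors.append("min_cond_fold must be >= 1")
    if cfg.reversal_margin < 0:
        errors.append("reversal_margin must be >= 0")
    if cfg.flank < 0:
        errors.append("flank must be >= 0")
    if cfg.which not in _WHICH_CHOICES:
        errors.append(f"which must be one of {_WHICH_CHOICES}, got {cfg.which!r}")
    if cfg.max_ratio_hf <= 0 or cfg.min_ratio_treat <= 0 or cfg.min_hf_expression <= 0:
        errors.append("rescue thresholds must be positive")
    if cfg.rounding_tolerance < 0:
        errors.append("rounding_tolerance must be >= 0")
    if cfg.seed < 0:
        errors.append("seed must be >= 0")

    if cfg.simulate is None:
        required = {
            "repeats": cfg.repeats,
            "genes": cfg.genes,
            "association": cfg.association,
            "expression": cfg.expression,
        }
        if set(cfg.reads) != set(LIBRARY_ROLES):
            errors.append(f"reads must map exactly the roles {LIBRARY_ROLES}")
        for role, path in sorted(cfg.reads.items()):
            if not Path(path).is_file():
                errors.append(f"reads[{role}]: missing file {path}")
        for name, path in required.items():
            if path is None:
                errors.append(f"{name} path required when no simulation block is given")
            elif not Path(path).is_file():
                errors.append(f"{name}: missing file {path}")
        for name, path in (("chrom_sizes", cfg.chrom_sizes), ("manifest", cfg.manifest)):
            if path is not None and not Path(path).is_file():
                errors.append(f"{name}: missing file {path}")

    if errors:
        raise ConfigError(errors)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _select_loci(diff_df, which: str) -> list[str]:
    up = diff_df["direction"] == Direction.HF_UP
    down = diff_df["direction"] == Direction.HF_DOWN
    rev = diff_df["reversed"]
    mask = {
        "hfup-reversed": up & rev,
        "hfup": up,
        "hfdown-reversed": down & rev,
        "hfdown": down,
        "all-called": up | down,
    }[which]
    return list(diff_df.loc[mask, "locus_id"])


def run_all(config: RunConfig, force: bool = False) -> dict:
    """Execute every stage; return the report dict (also written as JSON)."""
    outdir = Path(config.outdir)
    report_path = outdir / "report.json"
    if report_path.exists() and not force:
        raise StageError("setup", RuntimeError(
            f"{report_path} already exists; pass force=True (--force) to overwrite"
        ))
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "FAILED").unlink(missing_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())

    stage = "setup"
    try:
        report: dict = {"parameters": _parameters_dict(config), "stages": {}}

        # --- inputs --------------------------------------------------------
        stage = "inputs"
        logger.info("stage %s", stage)
        inputs_dir = outdir / "inputs"
        if config.simulate is not None:
            dataset = generate_dataset(config.simulate)
            paths = dataset.write(inputs_dir)
            repeats = dataset.repeats
            genes = dataset.genes
            association, term_names = dataset.association, dataset.term_names
            expression = dataset.expression
            chrom_sizes = dataset.chrom_sizes
            manifest = dataset.manifest
            reads = dataset.reads
            library_sizes = {r: len(dataset.reads[r]) for r in LIBRARY_ROLES}
        else:
            paths = {name: Path(p) for name, p in (
                [("repeats_rmsk", config.repeats), ("genes", config.genes),
                 ("association", config.association), ("expression", config.expression)]
                + [(f"reads_{r}", config.reads[r]) for r in LIBRARY_ROLES]
                + ([("chrom_sizes", config.chrom_sizes)] if config.chrom_sizes else [])
                + ([("manifest", config.manifest)] if config.manifest else [])
            )}
            repeats = genomeio.read_rmsk(paths["repeats_rmsk"])
            genes = genomeio.read_gene_table(paths["genes"])
            association, term_names = genomeio.read_go_association(paths["association"])
            expression = genomeio.read_expression(paths["expression"])
            chrom_sizes = genomeio.read_chrom_sizes(paths["chrom_sizes"]) if config.chrom_sizes else None
            manifest = TruthManifest.read(paths["manifest"]) if config.manifest else None
            reads = {r: genomeio.read_reads(paths[f"reads_{r}"], r) for r in LIBRARY_ROLES}
            library_sizes = {r: len(reads[r]) for r in LIBRARY_ROLES}
        def _relpath(p: Path) -> str:
            try:
                return str(Path(p).resolve().relative_to(outdir.resolve()))
            except ValueError:
                return str(p)

        report["inputs"] = {name: {"path": _relpath(Path(p)), "sha256": _sha256(Path(p))}
                            for name, p in sorted(paths.items())}
        report["stages"]["inputs"] = {
            "n_repeats": len(repeats), "n_genes": len(genes),
            "library_sizes": dict(sorted(library_sizes.items())),
        }

        # --- counting ------------------------------------------------------
        stage = "count"
        logger.info("stage %s (min_fraction=%s)", stage, config.min_fraction)
        counts_dir = outdir / "counts"
        counts_dir.mkdir(exist_ok=True)
        rule = OverlapRule(config.min_fraction)
        counts = {}
        for role in LIBRARY_ROLES:
            counts[role] = counting.count_reads(
                reads[role], repeats, rule,
                library=role, library_size=library_sizes[role],
                unique_best=config.unique_best,
            )
            counting.write_counts(counts[role], repeats, counts_dir / f"{role}.tsv")
        report["stages"]["count"] = {
            role: {"reads_on_repeats": int(sum(counts[role].counts.values()))}
            for role in LIBRARY_ROLES
        }

        # --- differential ---------------------------------------------------
        stage = "diff"
        logger.info("stage %s (fold_threshold=%s)", stage, config.fold_threshold)
        diff_dir = outdir / "diff"
        diff_dir.mkdir(exist_ok=True)
        calls = differential.call_enrichment(
            counts, config.fold_threshold, config.rpm_floor, config.min_input_reads
        )
        diffs = differential.classify_differential(
            calls, config.min_cond_fold, config.reversal_margin
        )
        summary = differential.summarize(diffs)
        differential.write_diff(calls, diffs, repeats, diff_dir / "diff.tsv")
        differential.write_summary(summary, diff_dir / "summary.tsv")
        report["stages"]["diff"] = {
            "n_hf_up": summary.n_hf_up, "n_hf_down": summary.n_hf_down,
            "n_hf_up_reversed": summary.n_hf_up_reversed,
            "n_hf_down_reversed": summary.n_hf_down_reversed,
            "pct_hf_up_reversed": summary.pct_hf_up_reversed,
            "pct_hf_down_reversed": summary.pct_hf_down_reversed,
        }
        if manifest is not None:
            agree = sum(
                1 for d in diffs
                if manifest.records[d.locus_id].true_direction is d.direction
                and manifest.records[d.locus_id].true_reversed == d.reversed
            )
            by_class: dict[str, int] = {}
            for rec in manifest.planted():
                key = f"{rec.true_direction.value.lower()}_{'reversed' if rec.true_reversed else 'static'}"
                by_class[key] = by_class.get(key, 0) + 1
            report["stages"]["diff"]["truth_agreement"] = {
                "n_loci": len(diffs), "n_agree": agree,
                "planted_class_counts": dict(sorted(by_class.items())),
            }

        # --- gene annotation -------------------------------------------------
        stage = "annotate"
        logger.info("stage %s (flank=%s, which=%s)", stage, config.flank, config.which)
        genes_dir = outdir / "genes"
        genes_dir.mkdir(exist_ok=True)
        diff_df = differential.read_diff(diff_dir / "diff.tsv")
        selected_ids = set(_select_loci(diff_df, config.which))
        selected = [l for l in repeats if l.locus_id in selected_ids]
        assignment, study_genes = annotation.assign_loci_to_genes(
            selected, genes, config.flank, chrom_sizes
        )
        with open(genes_dir / "locus_genes.tsv", "w", encoding="utf-8") as fh:
            fh.write("locus_id\tgene_ids\n")
            for locus in selected:
                fh.write(f"{locus.locus_id}\t{','.join(assignment[locus.locus_id])}\n")
        with open(genes_dir / "study_genes.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_id\n")
            fh.writelines(f"{g}\n" for g in study_genes)
        territories = annotation.make_territories(genes, config.flank, chrom_sizes)
        rep_fraction = (
            annotation.repetitive_fraction(territories, repeats) if territories else None
        )
        report["stages"]["annotate"] = {
            "n_selected_loci": len(selected),
            "n_study_genes": len(study_genes),
            "repetitive_fraction_pct": None if rep_fraction is None else round(rep_fraction, 3),
        }

        # --- GO enrichment ----------------------------------------------------
        stage = "go"
        logger.info("stage %s", stage)
        go_dir = outdir / "go"
        go_dir.mkdir(exist_ok=True)
        if study_genes:
            go_results = enrichment.go_sea(
                study_genes, association, term_names,
                universe_n=config.universe_n, term_k=config.term_k or None,
            )
        else:
            go_results = []
            logger.warning("no study genes selected; GO stage writes an empty table")
        enrichment.write_go_results(go_results, go_dir / "go.tsv")
        report["stages"]["go"] = {
            "n_terms_tested": len(go_results),
            "top_term": go_results[0].term_id if go_results else None,
        }

        # --- rescue screen ----------------------------------------------------
        stage = "rescue"
        logger.info("stage %s", stage)
        rescue_dir = outdir / "rescue"
        rescue_dir.mkdir(exist_ok=True)
        criteria = RescueCriteria(
            config.max_ratio_hf, config.min_ratio_treat,
            config.min_hf_expression, config.rounding_tolerance,
        )
        passed, skipped = rescue_mod.apply_rescue_filter(expression, criteria)
        rescue_mod.write_rescue(passed, rescue_dir / "rescue.tsv", criteria, skipped)
        report["stages"]["rescue"] = {"n_passed": len(passed), "n_skipped": len(skipped)}

        stage = "report"
        with open(report_path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("run complete: %s", report_path)
        return report
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n", encoding="utf-8")
        logger.error("stage %s failed: %s", stage, exc)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def _parameters_dict(config: RunConfig) -> dict:
    from .simulate import config_to_dict

    d = {k: getattr(config, k) for k in RunConfig.__dataclass_fields__}
    d["simulate"] = config_to_dict(config.simulate) if config.simulate else None
    return d
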