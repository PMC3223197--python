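"""End-to-end orchestration: simulate/load -> call -> classify -> compare.

Every stage writes plain-text outputs (BED/TSV/JSON) into the output
directory, so each stage can also be re-run standalone from the previous
stage's files. The whole run is a pure function of (inputs, config,
seed): reports from identical reruns are byte-identical. Progress and
timing go to stderr and a log file, never into the reports.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import __version__
from .core import ChromSizes, GeneModel, Peak, TagLibrary
from .genome_partition import build_partition, distribution_report
from .io_formats import (
    read_chrom_sizes,
    read_gene_annotation,
    read_peaks,
    read_tags,
    write_chrom_sizes,
    write_gene_annotation,
    write_peaks,
    write_report,
    write_tags,
)
from .metagene_profile import metagene_profile
from .peak_calling import PeakCallerParams, call_peaks
from .peak_comparison import (
    compare_peak_sets,
    cross_mark_comparison,
    enrichment_correlation,
    gene_venn,
    marked_promoters,
    promoter_mark_table,
    records_to_frame,
)
from .synthetic_data import ArchitectureParams, me1_like, me3_like, simulate_mark

logger = logging.getLogger("histmark")

CELLS = ("A", "B")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Either ``simulate`` is true (inputs are generated from the presets
    under ``seed``) or ``annotation``/``chrom_sizes``/``tag_files`` point
    at existing files. ``peak_files`` plus ``skip_calling`` bypass the
    built-in caller with externally called peaks.
    """

    output_dir: str = "histmark_out"
    seed: int = 0
    simulate: bool = True
    marks: List[str] = field(default_factory=lambda: ["H3K4me3", "H3K4me1"])
    n_genes: int = 200
    library_size: int = 200_000
    n_peaks_per_mark: int = 300
    annotation: Optional[str] = None
    chrom_sizes: Optional[str] = None
    tag_files: Dict[str, Dict[str, str]] = field(default_factory=dict)
    peak_files: Dict[str, Dict[str, str]] = field(default_factory=dict)
    skip_calling: bool = False
    promoter_halfwidth: int = 1000
    classification_mode: str = "precedence"
    correlation_method: str = "pearson"
    cpm: bool = False
    combine: str = "sum"
    flank: int = 5000
    n_bins: int = 40
    caller: PeakCallerParams = field(default_factory=PeakCallerParams)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        caller = PeakCallerParams(**raw.pop("caller", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(caller=caller, **raw)

    def echo(self) -> dict:
        d = asdict(self)
        return d


def _preset_for(mark: str, cfg: PipelineConfig) -> ArchitectureParams:
    base = me3_like() if "me3" in mark.lower() else me1_like()
    return replace(
        base,
        mark=mark,
        n_genes=cfg.n_genes,
        library_size=cfg.library_size,
        n_peaks_per_mark=cfg.n_peaks_per_mark,
        promoter_halfwidth=cfg.promoter_halfwidth,
        seed=cfg.seed,
    )


def _validate_inputs(cfg: PipelineConfig) -> None:
    missing: List[str] = []
    if not cfg.simulate:
        for label, path in (("annotation", cfg.annotation),
                            ("chrom_sizes", cfg.chrom_sizes)):
            if path is None:
                missing.append(f"{label}: not set")
            elif not Path(path).exists():
                missing.append(f"{label}: {path} does not exist")
        for mark in cfg.marks:
            for cell in CELLS:
                path = cfg.tag_files.get(mark, {}).get(cell)
                if path is None:
                    missing.append(f"tag_files[{mark}][{cell}]: not set")
                elif not Path(path).exists():
                    missing.append(f"tag_files[{mark}][{cell}]: {path} missing")
    if cfg.skip_calling:
        for mark in cfg.marks:
            for cell in CELLS:
                path = cfg.peak_files.get(mark, {}).get(cell)
                if path is None:
                    missing.append(f"peak_files[{mark}][{cell}]: not set")
                elif not Path(path).exists():
                    missing.append(f"peak_files[{mark}][{cell}]: {path} missing")
    if missing:
        raise PipelineError(
            "input validation failed:\n  " + "\n  ".join(missing)
        )


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Run every stage and write the result bundle under cfg.output_dir.

    Returns a summary dict (also written as summary.json).
    """
    _validate_inputs(cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()

    try:
        return _run(cfg, out, t0)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, out: Path, t0: float) -> Dict[str, object]:
    # --- stage 0: obtain inputs -------------------------------------------
    tag_libs: Dict[str, Dict[str, TagLibrary]] = {}
    if cfg.simulate:
        logger.info("simulating inputs (seed=%d)", cfg.seed)
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        genome = None
        truths = {}
        for mark in cfg.marks:
            params = _preset_for(mark, cfg)
            genome, truth, tags_a, tags_b = simulate_mark(params, genome)
            truths[mark] = truth
            tag_libs[mark] = {"A": tags_a, "B": tags_b}
            for cell, lib in tag_libs[mark].items():
                write_tags(lib, inputs / f"tags_{mark}_{cell}.bed")
            write_peaks(
                [p for p in truth.as_peaks("A")], inputs / f"truth_{mark}_A.bed"
            )
            write_peaks(
                [p for p in truth.as_peaks("B")], inputs / f"truth_{mark}_B.bed"
            )
        sizes, genes = genome
        write_chrom_sizes(sizes, inputs / "genome.chrom.sizes")
        write_gene_annotation(genes, inputs / "genes.refFlat")
        truth_summary = {
            mark: {
                "n_planted": len(truths[mark].peaks),
                "realized_share": truths[mark].realized_share,
            }
            for mark in cfg.marks
        }
        (inputs / "truth.json").write_text(
            json.dumps(truth_summary, indent=2, sort_keys=True) + "\n"
        )
    else:
        sizes = read_chrom_sizes(cfg.chrom_sizes)
        genes = read_gene_annotation(cfg.annotation)
        for mark in cfg.marks:
            tag_libs[mark] = {
                cell: read_tags(
                    cfg.tag_files[mark][cell], mark=mark, cell_type=cell
                )
                for cell in CELLS
            }

    partition = build_partition(genes, sizes, cfg.promoter_halfwidth)
    logger.info("partition built (%.1fs)", time.time() - t0)

    # --- stage 1: peaks ----------------------------------------------------
    peaks: Dict[str, Dict[str, List[Peak]]] = {}
    for mark in cfg.marks:
        peaks[mark] = {}
        for cell in CELLS:
            if cfg.skip_calling:
                peaks[mark][cell] = read_peaks(cfg.peak_files[mark][cell])
            else:
                peaks[mark][cell] = call_peaks(
                    tag_libs[mark][cell], sizes, cfg.caller
                )
            write_peaks(peaks[mark][cell], out / f"peaks_{mark}_{cell}.bed")
            logger.info(
                "%s/%s: %d islands (%.1fs)",
                mark, cell, len(peaks[mark][cell]), time.time() - t0,
            )

    # --- stage 2: per-mark reports ----------------------------------------
    summary: Dict[str, object] = {"seed": cfg.seed, "marks": {}}
    for mark in cfg.marks:
        mark_summary: Dict[str, object] = {}
        for cell in CELLS:
            report = distribution_report(
                partition, peaks[mark][cell], mode=cfg.classification_mode
            )
            write_report(report, out / f"distribution_{mark}_{cell}.tsv", "tsv")
            mark_summary[f"distribution_{cell}"] = report.to_dict()
            profile = metagene_profile(
                genes, tag_libs[mark][cell], flank=cfg.flank, n_bins=cfg.n_bins
            )
            write_report(profile, out / f"metagene_{mark}_{cell}.tsv", "tsv")

        comparison = compare_peak_sets(peaks[mark]["A"], peaks[mark]["B"])
        for label, subset in (
            ("common_A", comparison.common_a),
            ("common_B", comparison.common_b),
            ("specific_A", comparison.specific_a),
            ("specific_B", comparison.specific_b),
        ):
            write_peaks(subset, out / f"{label}_{mark}.bed")
        write_report(comparison, out / f"comparison_{mark}.json", "json")
        mark_summary["comparison"] = comparison.to_dict()

        records = promoter_mark_table(
            partition,
            peaks[mark]["A"],
            peaks[mark]["B"],
            tag_libs[mark]["A"],
            tag_libs[mark]["B"],
            combine=cfg.combine,
            cpm=cfg.cpm,
        )
        records_to_frame(records).to_csv(
            out / f"promoter_table_{mark}.tsv", sep="\t", index=False
        )
        try:
            r, n = enrichment_correlation(records, method=cfg.correlation_method)
            mark_summary["enrichment_correlation"] = {"r": r, "n": n}
        except Exception as exc:  # too few marked promoters on tiny runs
            logger.info("%s: correlation unavailable (%s)", mark, exc)
            mark_summary["enrichment_correlation"] = None

        venn = gene_venn(
            marked_promoters(partition, peaks[mark]["A"]),
            marked_promoters(partition, peaks[mark]["B"]),
            partition,
        )
        write_report(venn, out / f"gene_venn_{mark}.json", "json")
        mark_summary["gene_venn"] = {
            k: v for k, v in venn.to_dict().items() if k.startswith("n_")
        }
        summary["marks"][mark] = mark_summary
        logger.info("%s reports written (%.1fs)", mark, time.time() - t0)

    # --- stage 3: cross-mark comparison per cell type ----------------------
    if len(cfg.marks) == 2:
        m1, m2 = cfg.marks
        summary["cross_mark"] = {}
        for cell in CELLS:
            xm = cross_mark_comparison(peaks[m1][cell], peaks[m2][cell])
            write_report(xm, out / f"cross_mark_{cell}.json", "json")
            summary["cross_mark"][cell] = xm.to_dict()

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.echo(),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return summary
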