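"""End-to-end analysis: QC -> CNVR merge -> segmentation -> genotypes ->
population structure -> selection scan, with a machine-readable manifest.

Every stage writes deterministic, position-sorted TSV outputs; rerunning
with the same configuration and inputs reproduces the files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from . import io as cio
from .cnvr import merge_calls_to_cnvrs, summarize_cnvrs
from .qc import QcThresholds, filter_samples, records_from_table
from .scan import ScanConfig, run_selection_scan
from .segmentation import build_genotype_matrix, encode_matrix, partition_all
from .structure import hierarchical_cluster, pairwise_distance, pca

log = logging.getLogger("cnvpop")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters for one full run.

    ``group_x`` / ``group_y`` are comparison-group labels from the
    population map; leaving them unset skips the selection scan.  The
    structure stage needs >= 2 kept samples and is skipped otherwise.
    """

    calls: str
    popmap: str
    chrom_sizes: str
    outdir: str
    qc_table: Optional[str] = None
    genes: Optional[str] = None
    genes_dialect: str = "bed"
    group_x: Optional[str] = None
    group_y: Optional[str] = None
    autosomes_only: bool = True
    qc_thresholds: QcThresholds = field(default_factory=QcThresholds)
    scan: ScanConfig = field(default_factory=ScanConfig)
    encoding: str = "onehot"
    metric: str = "euclidean"
    linkage: str = "average"
    n_components: int = 2
    do_structure: bool = True

    def config_hash(self) -> str:
        # outdir does not affect the analysis, so it is not part of the hash
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    manifest: dict
    counts: dict


def _header(config: PipelineConfig) -> str:
    return f"# cnvpop {__version__} config={config.config_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every configured stage; returns the manifest and stage counts.

    Any stage failure raises with a stage-named message (the CLI converts
    that into a nonzero exit status).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "cnvpop",
        "version": __version__,
        "config_hash": config.config_hash(),
        "files": {},
    }
    counts: dict = {}

    def stage(name: str):
        log.info("stage %s", name)
        class _Ctx:
            def __enter__(self_inner):
                return None
            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return _Ctx()

    with stage("load"):
        calls = cio.read_penncnv_calls(config.calls, autosomes_only=config.autosomes_only)
        popmap = cio.read_population_map(config.popmap)
        chrom_sizes = cio.read_chrom_sizes(config.chrom_sizes)
        genes = (
            cio.read_gene_annotation(config.genes, dialect=config.genes_dialect)
            if config.genes
            else None
        )

    with stage("qc"):
        if config.qc_table:
            records = records_from_table(cio.read_qc_table(config.qc_table))
            kept, removed = filter_samples(records, config.qc_thresholds)
            kept &= set(popmap.samples)
        else:
            kept, removed = set(popmap.samples), {}
        calls = [c for c in calls if c.sample_id in kept]
        samples = [s for s in popmap.samples if s in kept]
        counts["samples_kept"] = len(samples)
        counts["samples_removed"] = len(removed)
        counts["calls"] = len(calls)
        report = pd.DataFrame(
            sorted((s, ",".join(m)) for s, m in removed.items()),
            columns=["sample_id", "failed_metrics"],
        )
        path = outdir / "qc_removed.tsv"
        _write_tsv(report, path, config)
        manifest["files"]["qc_removed"] = str(path)
        log.info("qc: kept %d samples, removed %d", len(samples), len(removed))

    with stage("merge"):
        if not calls:
            raise ValueError("no calls left after QC")
        cnvrs = merge_calls_to_cnvrs(calls)
        summary = summarize_cnvrs(cnvrs, chrom_sizes)
        counts["cnvrs"] = summary.n_cnvrs
        counts["cnvr_coverage_fraction"] = summary.coverage_fraction
        counts["cnvr_types"] = summary.type_counts
        path = outdir / "cnvrs.tsv"
        cio.write_cnvr_table(cnvrs, path, dialect="tsv")
        manifest["files"]["cnvrs"] = str(path)
        path = outdir / "cnvr_summary.tsv"
        _write_tsv(summary.per_chrom, path, config)
        manifest["files"]["cnvr_summary"] = str(path)
        log.info("merge: %d CNVRs covering %.2f%% of the genome",
                 summary.n_cnvrs, 100 * summary.coverage_fraction)

    with stage("segment"):
        segments = partition_all(cnvrs)
        counts["segments"] = len(segments)
        seg_df = pd.DataFrame(
            {
                "segment_id": [s.id for s in segments],
                "chrom": [s.chrom for s in segments],
                "start": [s.start for s in segments],
                "end": [s.end for s in segments],
                "parent_cnvr_id": [s.parent_cnvr_id for s in segments],
            }
        )
        path = outdir / "segments.tsv"
        _write_tsv(seg_df, path, config)
        manifest["files"]["segments"] = str(path)
        log.info("segment: %d segments", len(segments))

    with stage("genotype"):
        matrix = build_genotype_matrix(samples, segments, calls)
        path = outdir / "genotypes.tsv"
        with open(path, "w") as fh:
            fh.write(_header(config))
            matrix.to_frame().to_csv(fh, sep="\t", index_label="sample_id")
        manifest["files"]["genotypes"] = str(path)

    if config.do_structure and len(samples) >= 2:
        with stage("structure"):
            encoded = encode_matrix(matrix, config.encoding)
            dist = pairwise_distance(encoded, config.metric)
            tree = hierarchical_cluster(dist, config.linkage)
            path = outdir / "tree.nwk"
            with open(path, "w") as fh:
                fh.write(tree.to_newick() + "\n")
            manifest["files"]["tree"] = str(path)
            result = pca(encoded, n_components=config.n_components)
            coords = result.coordinates.copy()
            path = outdir / "pca.tsv"
            with open(path, "w") as fh:
                fh.write(_header(config))
                fh.write(
                    "# explained_fraction="
                    + ",".join(f"{f:.6g}" for f in result.explained_fraction)
                    + "\n"
                )
                coords.to_csv(fh, sep="\t", index_label="sample_id")
            manifest["files"]["pca"] = str(path)
            counts["pc_explained_fraction"] = [
                float(f) for f in result.explained_fraction
            ]

    if config.group_x and config.group_y:
        with stage("scan"):
            gx = [s for s in samples if popmap.group_of(s) == config.group_x]
            gy = [s for s in samples if popmap.group_of(s) == config.group_y]
            if not gx or not gy:
                raise ValueError(
                    f"empty comparison group(s): {config.group_x}={len(gx)}, "
                    f"{config.group_y}={len(gy)}"
                )
            results = run_selection_scan(calls, gx, gy, config.scan, genes)
            counts["scan_segments"] = len(results.table)
            counts["scan_defined"] = int(results.table["defined"].sum())
            counts["scan_threshold"] = results.threshold
            counts["scan_selected"] = len(results.selected)
            counts["scan_joined"] = len(results.joined)
            path = outdir / "fst.tsv"
            _write_tsv(results.table, path, config)
            manifest["files"]["fst"] = str(path)
            path = outdir / "selected.tsv"
            _write_tsv(results.selected, path, config)
            manifest["files"]["selected"] = str(path)
            joined_rows = []
            for iv in results.joined:
                row = {"chrom": iv[0], "start": iv[1], "end": iv[2]}
                if results.genes is not None:
                    row["genes"] = ",".join(results.genes[iv])
                joined_rows.append(row)
            path = outdir / "selected_joined.tsv"
            _write_tsv(pd.DataFrame(joined_rows), path, config)
            manifest["files"]["selected_joined"] = str(path)
            log.info(
                "scan: %d/%d segments defined, threshold %.4f, %d selected -> %d joined",
                counts["scan_defined"], counts["scan_segments"],
                results.threshold, counts["scan_selected"], counts["scan_joined"],
            )

    manifest["counts"] = counts
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["files"]["manifest"] = str(manifest_path)
    return PipelineResult(manifest=manifest, counts=counts)
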