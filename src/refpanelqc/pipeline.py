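"""End-to-end orchestration: QC -> mask -> scan -> strain genetics -> liftover.

One :class:`PipelineConfig` (real input paths or a synthetic generator
config) drives the stages in the analysis order used for auditing a
reference with an inbred panel: variant quality filter, sample QC,
misassembly scan on the reference-strain subset, shared-error-site scan and
masking, then IBS / UPGMA / proxy / mislabel / sharing analyses on the
masked panel, with optional chain-based liftover evaluation.  Every run
writes a manifest recording parameters, seed, and per-stage row counts;
identical config and seed reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

from refpanelqc import genotype_io
from refpanelqc.genotype_io import GenotypePanel, parse_vcf, write_vcf
from refpanelqc.misassembly_scan import (
    ScanParams,
    flagged_regions_bed,
    scan_panel,
    segments_table,
)
from refpanelqc.site_anomaly import (
    SharedScanParams,
    mask_panel,
    records_table,
    shared_site_scan,
)
from refpanelqc.strain_genetics import (
    ibs_matrix,
    match_and_flag,
    sharing_summary,
    upgma_tree,
)
from refpanelqc.synthetic_data import SimConfig, generate_panel

log = logging.getLogger("refpanelqc")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs.  Exactly one of ``vcf_path`` /
    ``synthetic`` must be set."""

    outdir: str = "refpanelqc_out"
    seed: int = 0
    vcf_path: str | None = None
    synthetic: SimConfig | None = None
    chain_path: str | None = None
    min_qual: float = 30.0
    max_missing: float = 0.04
    min_depth: float = 10.0
    scan: ScanParams = field(default_factory=ScanParams)
    shared: SharedScanParams = field(default_factory=SharedScanParams)
    proxy_queries: list[str] = field(default_factory=list)
    proxy_threshold: float = 0.995
    same_low: float = 0.97
    cross_high: float = 0.98
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.vcf_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of vcf_path / synthetic must be set")


def _write(outdir: str, name: str, text: str) -> str:
    path = os.path.join(outdir, name)
    with open(path, "w") as fh:
        fh.write(text)
    return name


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest.

    Any stage failure aborts with :class:`PipelineError` naming the stage;
    the partial manifest is written with a FAILED marker.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "min_qual": config.min_qual,
            "max_missing": config.max_missing,
            "min_depth": config.min_depth,
            "scan": asdict(config.scan),
            "shared_min_share": config.shared.min_share,
            "proxy_threshold": config.proxy_threshold,
            "same_low": config.same_low,
            "cross_high": config.cross_high,
        },
        "stages": {},
    }
    stage = "load"
    try:
        truth = None
        if config.synthetic is not None:
            config.synthetic.seed = config.seed
            panel, truth = generate_panel(config.synthetic)
            log.info("generated synthetic panel: %d samples, %d sites",
                     panel.n_samples, panel.n_sites)
        else:
            panel = parse_vcf(config.vcf_path)
        manifest["stages"]["load"] = {
            "status": "OK", "n_samples": panel.n_samples,
            "n_sites": panel.n_sites}

        stage = "variant_filter"
        n_before = panel.n_sites
        panel = genotype_io.filter_variants(panel, min_qual=config.min_qual)
        manifest["stages"][stage] = {
            "status": "OK", "sites_in": n_before, "sites_kept": panel.n_sites,
            "sites_removed": n_before - panel.n_sites}

        stage = "sample_qc"
        n_before = panel.n_samples
        panel, qc_report = genotype_io.sample_qc(
            panel, max_missing=config.max_missing, min_depth=config.min_depth)
        manifest["stages"][stage] = {
            "status": "OK", "samples_in": n_before,
            "samples_kept": panel.n_samples,
            "failed_samples": qc_report.failed}

        stage = "misassembly_scan"
        ref_ids = panel.reference_sample_ids()
        if not ref_ids:
            raise ValueError("no reference-strain samples in panel; the "
                             "misassembly scan needs the reference strain")
        segments, flagged = scan_panel(panel, subset=ref_ids, params=config.scan)
        manifest["stages"][stage] = {
            "status": "OK", "n_reference_samples": len(ref_ids),
            "n_segments": len(segments), "n_flagged_regions": len(flagged),
            "flagged_bed": _write(config.outdir, "flagged_regions.bed",
                                  flagged_regions_bed(flagged)),
            "segments_table": _write(config.outdir, "segments.tsv",
                                     segments_table(segments))}

        stage = "shared_site_scan"
        records, depth_summary = shared_site_scan(panel, config.shared)
        panel, bed = mask_panel(panel, records)
        manifest["stages"][stage] = {
            "status": "OK", "n_shared_sites": len(records),
            "depth_summary": depth_summary,
            "sites_after_mask": panel.n_sites,
            "records_table": _write(config.outdir, "shared_sites.tsv",
                                    records_table(records)),
            "exclusion_bed": _write(config.outdir, "shared_sites.bed", bed)}

        stage = "strain_genetics"
        ibs = ibs_matrix(panel)
        tree, newick = upgma_tree(ibs)
        labels = {s.id: (s.strain, s.substrain) for s in panel.samples}
        proxies, mislabels = match_and_flag(
            ibs, labels, proxy_queries=config.proxy_queries,
            proxy_threshold=config.proxy_threshold,
            same_low=config.same_low, cross_high=config.cross_high)
        groups: dict[str, list[str]] = {}
        for s in panel.samples:
            groups.setdefault(s.strain, []).append(s.id)
        sharing = sharing_summary(panel, groups)
        manifest["stages"][stage] = {
            "status": "OK",
            "ibs_matrix": _write(config.outdir, "ibs.tsv",
                                 ibs.to_frame().to_csv(sep="\t")),
            "tree_newick": _write(config.outdir, "strains.nwk", newick + "\n"),
            "n_proxy_queries": len(proxies),
            "n_mislabel_flags": len(mislabels),
            "mislabels": [
                {"pair": [f.sample_a, f.sample_b], "ibs": round(f.ibs, 4),
                 "rule": f.rule} for f in mislabels],
            "sharing": {"totals": sharing["totals"],
                        "unique": sharing["unique"],
                        "shared_by_all": sharing["shared_by_all"]}}

        if config.chain_path:
            stage = "liftover_eval"
            from refpanelqc.coordmap import parse_chain, simulate_and_eval_liftover
            chains = parse_chain(config.chain_path)
            sizes = {c.src_chrom: c.src_size for c in chains.chains}
            report = simulate_and_eval_liftover(sizes, chains)
            manifest["stages"][stage] = {
                "status": "OK", "n_sites": report.n_input,
                "n_lifted": report.n_lifted,
                "fraction_lifted": report.fraction_lifted}

        if truth is not None:
            stage = "truth_recovery"
            manifest["stages"][stage] = _truth_recovery(
                truth, flagged, records, mislabels)

        stage = "write_outputs"
        _write(config.outdir, "masked_panel.vcf", write_vcf(panel))
        manifest["status"] = "OK"
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write(config.outdir, "manifest.json", json.dumps(manifest, indent=2))
        raise PipelineError(stage, exc) from exc
    _write(config.outdir, "manifest.json", json.dumps(manifest, indent=2))
    return manifest


def region_jaccard(truth_region, flagged) -> float:
    """Best Jaccard overlap of a truth interval against flagged regions.

    Truth intervals are 1-based inclusive; flagged regions BED half-open.
    """
    ts, te = truth_region.start - 1, truth_region.end
    best = 0.0
    for f in flagged:
        if f.chrom != truth_region.chrom:
            continue
        inter = max(0, min(te, f.end) - max(ts, f.start))
        union = (te - ts) + (f.end - f.start) - inter
        if union > 0:
            best = max(best, inter / union)
    return best


def _truth_recovery(truth, flagged, records, mislabels) -> dict:
    planted = truth.error_site_set()
    found = {(r.chrom, r.pos) for r in records}
    jaccards = [region_jaccard(reg, flagged) for reg in truth.collapsed_regions]
    return {
        "status": "OK",
        "collapsed_region_jaccard": [round(j, 3) for j in jaccards],
        "error_sites_planted": len(planted),
        "error_sites_recovered": len(planted & found),
        "error_sites_spurious": len(found - planted),
        "n_mislabel_flags": len(mislabels),
    }
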