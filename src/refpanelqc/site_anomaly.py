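"""Per-site reference anomalies: shared non-reference sites and masking.

A site where (nearly) every inbred sample carries a non-reference genotype —
including the replicates of the strain the reference was assembled from — is
most parsimoniously a wrong base recorded in the reference.  Shared sites
split into two classes: homozygous-alternate (a simple base error) and
heterozygous (reads from two collapsed repeat copies piling onto one locus,
recognisable by roughly doubled read depth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from refpanelqc.genotype_io import (
    GT_HET,
    GT_HOM_ALT,
    GenotypePanel,
)

HOM_SHARED = "HOM_SHARED"
HET_SHARED = "HET_SHARED"


@dataclass
class SharedScanParams:
    """Scan thresholds.

    ``min_share`` defaults to ceil(0.95 * n samples) — "most of the panel".
    When ``require_reference_strain`` is set, a shared site must additionally
    be non-reference in every reference-strain sample.
    """

    min_share: int | None = None
    require_reference_strain: bool = True

    def resolve_min_share(self, n_samples: int) -> int:
        ms = self.min_share
        if ms is None:
            ms = int(np.ceil(0.95 * n_samples))
        if not 1 <= ms <= n_samples:
            raise ValueError(f"min_share {ms} outside [1, {n_samples}]")
        return ms


@dataclass
class SharedSiteRecord:
    """One site flagged as a shared reference anomaly."""

    chrom: str
    pos: int                  # 1-based
    ref: str
    alts: tuple[str, ...]
    cls: str                  # HOM_SHARED or HET_SHARED
    n_nonref: int
    n_het: int
    mean_depth: float         # over all samples


def shared_site_scan(panel: GenotypePanel,
                     params: SharedScanParams | None = None
                     ) -> tuple[list[SharedSiteRecord], dict]:
    """Find sites non-reference in at least ``min_share`` samples.

    Classification: HET_SHARED when heterozygous calls are at least as many
    as homozygous-alternate calls among the non-reference carriers, else
    HOM_SHARED.  The summary reports mean +/- SD depth per class (depth
    averaged over all samples at each site) and the het/hom depth ratio.
    """
    params = params or SharedScanParams()
    n = panel.n_samples
    min_share = params.resolve_min_share(n)
    ref_cols = panel.sample_index(panel.reference_sample_ids()) \
        if params.require_reference_strain else np.array([], dtype=int)
    if params.require_reference_strain and ref_cols.size == 0:
        raise ValueError("panel has no reference-strain samples; "
                         "disable require_reference_strain or add them")

    records: list[SharedSiteRecord] = []
    for chrom, blk in panel.blocks.items():
        cls = blk.classes()
        nonref = (cls == GT_HET) | (cls == GT_HOM_ALT)
        n_nonref = nonref.sum(axis=1)
        hit = n_nonref >= min_share
        if params.require_reference_strain and ref_cols.size:
            hit &= nonref[:, ref_cols].all(axis=1)
        for i in np.flatnonzero(hit):
            n_het = int((cls[i] == GT_HET).sum())
            n_hom = int((cls[i] == GT_HOM_ALT).sum())
            records.append(SharedSiteRecord(
                chrom=chrom, pos=int(blk.positions[i]), ref=blk.ref[i],
                alts=blk.alts[i],
                cls=HET_SHARED if n_het >= n_hom else HOM_SHARED,
                n_nonref=int(n_nonref[i]), n_het=n_het,
                mean_depth=float(blk.depth[i].mean())))
    summary = _depth_summary(records)
    return records, summary


def _depth_summary(records: list[SharedSiteRecord]) -> dict:
    out: dict = {"n_records": len(records)}
    for label in (HOM_SHARED, HET_SHARED):
        depths = np.array([r.mean_depth for r in records if r.cls == label])
        out[label] = {
            "n": int(depths.size),
            "mean_depth": float(depths.mean()) if depths.size else float("nan"),
            "sd_depth": float(depths.std(ddof=1)) if depths.size > 1 else float("nan"),
        }
    hom, het = out[HOM_SHARED]["mean_depth"], out[HET_SHARED]["mean_depth"]
    out["het_hom_depth_ratio"] = het / hom if out[HOM_SHARED]["n"] else float("nan")
    return out


def mask_panel(panel: GenotypePanel, records: list[SharedSiteRecord]
               ) -> tuple[GenotypePanel, str]:
    """Remove the recorded sites; return the masked panel and an exclusion BED.

    Every record must resolve to a panel site; site counts are conserved:
    input sites = output sites + records.
    """
    wanted: dict[str, set[int]] = {}
    for r in records:
        wanted.setdefault(r.chrom, set()).add(r.pos)
    masks = {}
    bed_rows = []
    for chrom, blk in panel.blocks.items():
        drop = wanted.pop(chrom, set())
        keep = ~np.isin(blk.positions, sorted(drop))
        found = set(blk.positions[~keep].tolist())
        missing = drop - found
        if missing:
            pos = sorted(missing)[0]
            raise KeyError(f"record {chrom}:{pos} not found in panel")
        masks[chrom] = keep
        for p in sorted(found):
            bed_rows.append(f"{chrom}\t{p - 1}\t{p}")
    if wanted:
        chrom = next(iter(wanted))
        raise KeyError(f"record chromosome {chrom!r} not found in panel")
    return panel.subset_sites(masks), "".join(r + "\n" for r in bed_rows)


def records_table(records: list[SharedSiteRecord]) -> str:
    header = "chrom\tpos\tref\talt\tclass\tn_nonref\tn_het\tmean_depth\n"
    rows = [f"{r.chrom}\t{r.pos}\t{r.ref}\t{','.join(r.alts)}\t{r.cls}\t"
            f"{r.n_nonref}\t{r.n_het}\t{r.mean_depth:.2f}" for r in records]
    return header + "\n".join(rows) + ("\n" if rows else "")


def error_fold_reduction(count_ref_a: int, count_ref_b: int) -> float:
    """Fold reduction in shared-anomaly counts between two references (a/b),
    rounded to one decimal."""
    if count_ref_a <= 0 or count_ref_b <= 0:
        raise ValueError("counts must be positive")
    return round(count_ref_a / count_ref_b, 1)
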