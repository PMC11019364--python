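"""Multi-sample genotype panels: VCF parsing/writing, QC filters, site statistics.

The central container is :class:`GenotypePanel`, an array-backed matrix of
per-sample allele indices and read depths over ordered variant sites, grouped
by chromosome.  Everything downstream (misassembly scanning, shared-site
anomaly detection, IBS) consumes this container.

Genotype classes are encoded as small integers:

====================  ====  =========================================
constant              code  meaning
====================  ====  =========================================
``GT_HOM_REF``        0     both alleles reference
``GT_HET``            1     two distinct allele indices
``GT_HOM_ALT``        2     two identical non-reference indices
``GT_MISSING``        3     no call (``./.``)
====================  ====  =========================================

Multi-allelic records are kept with their allele indices; the class of a
genotype derives from the indices alone (two distinct non-missing indices are
heterozygous regardless of which alternates are involved).

Coordinates are 1-based (VCF convention) throughout; conversion to 0-based
half-open happens only where BED is emitted or read.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = 3

GT_CLASS_NAMES = {GT_HOM_REF: "HOM_REF", GT_HET: "HET",
                  GT_HOM_ALT: "HOM_ALT", GT_MISSING: "MISSING"}

#: chromosome names excluded by default (the scans cover autosomes only)
SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY", "MT", "chrM"})


class VcfParseError(ValueError):
    """Raised when a VCF stream cannot be interpreted."""


@dataclass(frozen=True)
class SampleInfo:
    """Identity and strain metadata for one sequenced sample."""

    id: str
    strain: str
    substrain: str
    is_reference: bool = False


@dataclass
class Genotype:
    """One genotype call: class code plus allele indices (missing -> none)."""

    cls: int
    alleles: tuple[int, int] | None

    @classmethod
    def from_indices(cls, a1: int, a2: int) -> "Genotype":
        return cls(classify_alleles(a1, a2),
                   None if a1 < 0 or a2 < 0 else (a1, a2))


def classify_alleles(a1: int, a2: int) -> int:
    """Genotype class from a pair of allele indices (-1 = no call)."""
    if a1 < 0 or a2 < 0:
        return GT_MISSING
    if a1 != a2:
        return GT_HET
    return GT_HOM_REF if a1 == 0 else GT_HOM_ALT


def classify_matrix(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Vectorised genotype classification of allele-index matrices."""
    cls = np.full(a1.shape, GT_MISSING, dtype=np.int8)
    called = (a1 >= 0) & (a2 >= 0)
    het = called & (a1 != a2)
    hom_ref = called & (a1 == 0) & (a2 == 0)
    hom_alt = called & ~het & ~hom_ref
    cls[het] = GT_HET
    cls[hom_ref] = GT_HOM_REF
    cls[hom_alt] = GT_HOM_ALT
    return cls


@dataclass
class VariantSite:
    """A single jointly-called variant record (read-only view of a panel row)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    genotypes: list[Genotype]
    depths: np.ndarray


@dataclass
class ChromBlock:
    """All sites of one chromosome: parallel arrays, rows = sites."""

    positions: np.ndarray          # int64, 1-based, strictly increasing
    ref: list
    alts: list                     # list of tuple[str, ...]
    qual: np.ndarray               # float64
    a1: np.ndarray                 # int16 (n_sites, n_samples); -1 = no call
    a2: np.ndarray
    depth: np.ndarray              # int32 (n_sites, n_samples)

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.ref) == len(self.alts) == len(self.qual)
                == self.a1.shape[0] == self.a2.shape[0] == self.depth.shape[0] == n):
            raise ValueError("chromosome block arrays disagree on site count")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions not strictly increasing within chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def classes(self) -> np.ndarray:
        return classify_matrix(self.a1, self.a2)

    def take(self, mask: np.ndarray) -> "ChromBlock":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return ChromBlock(
            positions=self.positions[idx],
            ref=[self.ref[i] for i in idx],
            alts=[self.alts[i] for i in idx],
            qual=self.qual[idx],
            a1=self.a1[idx], a2=self.a2[idx], depth=self.depth[idx],
        )

    def take_samples(self, cols: np.ndarray) -> "ChromBlock":
        return replace(self, a1=self.a1[:, cols], a2=self.a2[:, cols],
                       depth=self.depth[:, cols])


@dataclass
class GenotypePanel:
    """Samples x ordered variant sites, grouped per chromosome."""

    samples: list[SampleInfo]
    blocks: dict[str, ChromBlock] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in panel")
        n = len(ids)
        for chrom, blk in self.blocks.items():
            if blk.a1.shape[1] != n:
                raise ValueError(f"{chrom}: genotype columns != sample count")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chroms(self) -> list[str]:
        return list(self.blocks)

    @property
    def n_sites(self) -> int:
        return sum(b.n_sites for b in self.blocks.values())

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s.id: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def reference_sample_ids(self) -> list[str]:
        return [s.id for s in self.samples if s.is_reference]

    # -- views ----------------------------------------------------------------

    def sites(self, chrom: str):
        """Iterate :class:`VariantSite` views over one chromosome."""
        blk = self.blocks[chrom]
        for i in range(blk.n_sites):
            gts = [Genotype.from_indices(int(blk.a1[i, j]), int(blk.a2[i, j]))
                   for j in range(self.n_samples)]
            yield VariantSite(chrom, int(blk.positions[i]), blk.ref[i],
                              blk.alts[i], float(blk.qual[i]), gts, blk.depth[i])

    def subset_samples(self, ids) -> "GenotypePanel":
        cols = self.sample_index(ids)
        return GenotypePanel(
            samples=[self.samples[i] for i in cols],
            blocks={c: b.take_samples(cols) for c, b in self.blocks.items()},
        )

    def subset_sites(self, masks: dict[str, np.ndarray]) -> "GenotypePanel":
        """Keep, per chromosome, only sites where the boolean mask is True."""
        blocks = {}
        for chrom, blk in self.blocks.items():
            m = masks.get(chrom)
            if m is None:
                blocks[chrom] = blk
            else:
                sub = blk.take(np.asarray(m))
                if sub.n_sites:
                    blocks[chrom] = sub
        return GenotypePanel(samples=list(self.samples), blocks=blocks)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_META_PREFIX = "##SAMPLE=<"


def _parse_sample_meta(header_text: str) -> dict[str, dict]:
    """Strain metadata from ##SAMPLE=<ID=..,Strain=..,Substrain=..,Reference=..>."""
    meta: dict[str, dict] = {}
    for line in header_text.splitlines():
        if not line.startswith(_META_PREFIX):
            continue
        body = line[len(_META_PREFIX):].rstrip(">")
        kv = dict(item.split("=", 1) for item in body.split(",") if "=" in item)
        if "ID" in kv:
            meta[kv["ID"]] = kv
    return meta


def parse_vcf(source, keep_sex: bool = False) -> GenotypePanel:
    """Read a VCFv4.x file (path or VCF text) into a :class:`GenotypePanel`.

    GT is required; DP is optional (absent depths become 0).  Sites must be
    sorted within each chromosome; unsorted input is rejected.  Strain
    metadata is read from ``##SAMPLE=`` header lines when present, otherwise
    the sample id doubles as strain and substrain.

    Sex chromosomes and the mitochondrion are dropped unless ``keep_sex``.
    """
    from cyvcf2 import VCF

    tmp = None
    path = source
    if hasattr(source, "read"):
        source = source.read()
    if isinstance(source, str) and "\n" in source:
        tmp = tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False)
        tmp.write(source)
        tmp.close()
        path = tmp.name
    try:
        try:
            vcf = VCF(str(path))
        except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
            raise VcfParseError(f"cannot open VCF: {exc}") from exc
        sample_ids = list(vcf.samples)
        if len(set(sample_ids)) != len(sample_ids):
            raise VcfParseError("duplicate sample ids in VCF header")
        meta = _parse_sample_meta(vcf.raw_header)
        samples = [
            SampleInfo(
                id=s,
                strain=meta.get(s, {}).get("Strain", s),
                substrain=meta.get(s, {}).get("Substrain", s),
                is_reference=meta.get(s, {}).get("Reference", "0") in ("1", "true", "True"),
            )
            for s in sample_ids
        ]
        per_chrom: dict[str, dict[str, list]] = {}
        for line_no, rec in enumerate(vcf, start=1):
            chrom = rec.CHROM
            if not keep_sex and chrom in SEX_CHROMS:
                continue
            acc = per_chrom.setdefault(
                chrom, {"pos": [], "ref": [], "alts": [], "qual": [],
                        "a1": [], "a2": [], "dp": []})
            if acc["pos"] and rec.POS <= acc["pos"][-1]:
                raise VcfParseError(
                    f"unsorted VCF: {chrom}:{rec.POS} after {acc['pos'][-1]} "
                    f"(record {line_no})")
            acc["pos"].append(rec.POS)
            acc["ref"].append(rec.REF)
            acc["alts"].append(tuple(rec.ALT) if rec.ALT else ("<NON_REF>",))
            acc["qual"].append(rec.QUAL if rec.QUAL is not None else 0.0)
            g = np.array([gt[:2] for gt in rec.genotypes], dtype=np.int16)
            acc["a1"].append(g[:, 0])
            acc["a2"].append(g[:, 1])
            dp = rec.format("DP")
            if dp is None:
                acc["dp"].append(np.zeros(len(sample_ids), dtype=np.int32))
            else:
                dp = dp.astype(np.int64).ravel()
                dp[dp < 0] = 0
                acc["dp"].append(dp.astype(np.int32))
        blocks = {}
        for chrom, acc in per_chrom.items():
            blocks[chrom] = ChromBlock(
                positions=np.array(acc["pos"], dtype=np.int64),
                ref=acc["ref"],
                alts=acc["alts"],
                qual=np.array(acc["qual"], dtype=float),
                a1=np.vstack(acc["a1"]),
                a2=np.vstack(acc["a2"]),
                depth=np.vstack(acc["dp"]),
            )
        return GenotypePanel(samples=samples, blocks=blocks)
    finally:
        if tmp is not None:
            os.unlink(tmp.name)


def write_vcf(panel: GenotypePanel, path=None) -> str:
    """Emit the panel as VCFv4.2 text (GT and DP per sample, QUAL column).

    Returns the text; also writes it to ``path`` when given.  Strain metadata
    is preserved in ``##SAMPLE=`` header lines so that a parse round-trip
    reconstructs the same panel.
    """
    out = io.StringIO()
    out.write("##fileformat=VCFv4.2\n")
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    for chrom, blk in panel.blocks.items():
        end = int(blk.positions[-1]) + 1000 if blk.n_sites else 1000
        out.write(f"##contig=<ID={chrom},length={end}>\n")
    for s in panel.samples:
        out.write(f"##SAMPLE=<ID={s.id},Strain={s.strain},Substrain={s.substrain},"
                  f"Reference={1 if s.is_reference else 0}>\n")
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(panel.sample_ids) + "\n")
    for chrom, blk in panel.blocks.items():
        for i in range(blk.n_sites):
            cols = [chrom, str(int(blk.positions[i])), ".", blk.ref[i],
                    ",".join(blk.alts[i]), f"{blk.qual[i]:g}", "PASS", ".", "GT:DP"]
            for j in range(panel.n_samples):
                a1, a2 = int(blk.a1[i, j]), int(blk.a2[i, j])
                gt = "./." if a1 < 0 or a2 < 0 else f"{a1}/{a2}"
                cols.append(f"{gt}:{int(blk.depth[i, j])}")
            out.write("\t".join(cols) + "\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Filtering and QC
# ---------------------------------------------------------------------------

def _exclusion_masks(panel: GenotypePanel, exclude) -> dict[str, np.ndarray]:
    """Boolean keep-masks per chromosome from an interval/site exclusion list.

    ``exclude`` may be None, an iterable of BED intervals (chrom, start, end)
    in 0-based half-open coordinates, or an iterable of sites (chrom, pos)
    with 1-based positions.
    """
    masks = {c: np.ones(b.n_sites, dtype=bool) for c, b in panel.blocks.items()}
    if exclude is None:
        return masks
    for item in exclude:
        if len(item) == 3 and isinstance(item[2], (int, np.integer)):
            chrom, start, end = item
            blk = panel.blocks.get(chrom)
            if blk is None:
                continue
            hit = (blk.positions > start) & (blk.positions <= end)
            masks[chrom] &= ~hit
        else:
            chrom, pos = item[0], int(item[1])
            blk = panel.blocks.get(chrom)
            if blk is None:
                continue
            masks[chrom] &= blk.positions != pos
    return masks


def filter_variants(panel: GenotypePanel, min_qual: float = 30.0,
                    exclude=None) -> GenotypePanel:
    """Drop sites with QUAL below ``min_qual`` and sites in the exclusion set.

    A site with QUAL exactly equal to the threshold is kept (sites *below*
    the threshold are removed).  Order is preserved; the result may be empty.
    """
    if min_qual < 0:
        raise ValueError("min_qual must be non-negative")
    masks = _exclusion_masks(panel, exclude)
    for chrom, blk in panel.blocks.items():
        masks[chrom] &= blk.qual >= min_qual
    return panel.subset_sites(masks)


@dataclass
class SampleQCReport:
    """Per-sample missingness and depth with pass/fail flags."""

    table: pd.DataFrame  # index sample id; columns missing_rate, mean_depth, pass

    @property
    def failed(self) -> list[str]:
        return list(self.table.index[~self.table["pass"]])


def sample_qc(panel: GenotypePanel, max_missing: float = 0.04,
              min_depth: float = 10.0) -> tuple[GenotypePanel, SampleQCReport]:
    """Remove samples with excess missingness or insufficient mean depth.

    Pass requires missing rate <= ``max_missing`` and mean depth >=
    ``min_depth`` (both boundaries inclusive on the passing side).  The
    report covers all input samples; the returned panel keeps passers only.
    """
    if max_missing <= 0 or min_depth <= 0:
        raise ValueError("QC thresholds must be positive")
    if panel.n_sites == 0:
        raise ValueError("cannot QC an empty panel")
    miss = np.zeros(panel.n_samples)
    depth_sum = np.zeros(panel.n_samples)
    total = 0
    for blk in panel.blocks.values():
        cls = blk.classes()
        miss += (cls == GT_MISSING).sum(axis=0)
        depth_sum += blk.depth.sum(axis=0)
        total += blk.n_sites
    missing_rate = miss / total
    mean_depth = depth_sum / total
    ok = (missing_rate <= max_missing) & (mean_depth >= min_depth)
    report = SampleQCReport(pd.DataFrame(
        {"missing_rate": missing_rate, "mean_depth": mean_depth, "pass": ok},
        index=pd.Index(panel.sample_ids, name="sample")))
    if not ok.any():
        raise ValueError("all samples fail QC; downstream analyses need >= 1 sample")
    kept = [s for s, keep in zip(panel.sample_ids, ok) if keep]
    return panel.subset_samples(kept), report


def site_statistics(panel: GenotypePanel, subset=None,
                    window_bp: int = 1_000_000) -> dict:
    """Per-site genotype-class counts plus per-sample and per-window summaries.

    Returns a dict with

    ``sites``
        DataFrame (chrom, pos, het, missing, nonref, mean_depth) where counts
        are over the selected sample subset; ``nonref`` counts samples with an
        observed alternate allele (HET or HOM_ALT) — MISSING never counts.
    ``homozygosity``
        per-sample HOM_ALT / (HOM_ALT + HET) among non-missing non-reference
        calls.
    ``density``
        variants per kb in fixed windows of ``window_bp``.
    """
    ids = panel.sample_ids if subset is None else list(subset)
    if not ids:
        raise ValueError("sample subset must be non-empty")
    cols = panel.sample_index(ids)

    site_frames = []
    hom_alt = np.zeros(len(cols))
    het_tot = np.zeros(len(cols))
    dens_rows = []
    for chrom, blk in panel.blocks.items():
        cls = blk.classes()[:, cols]
        dp = blk.depth[:, cols]
        het = (cls == GT_HET).sum(axis=1)
        mis = (cls == GT_MISSING).sum(axis=1)
        nonref = ((cls == GT_HET) | (cls == GT_HOM_ALT)).sum(axis=1)
        site_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": blk.positions, "het": het,
            "missing": mis, "nonref": nonref,
            "mean_depth": dp.mean(axis=1) if dp.size else 0.0}))
        hom_alt += (cls == GT_HOM_ALT).sum(axis=0)
        het_tot += (cls == GT_HET).sum(axis=0)
        if blk.n_sites:
            win = (blk.positions - 1) // window_bp
            counts = pd.Series(win).value_counts().sort_index()
            for w, c in counts.items():
                dens_rows.append((chrom, int(w) * window_bp,
                                  (int(w) + 1) * window_bp,
                                  c / (window_bp / 1000.0)))
    denom = hom_alt + het_tot
    homozygosity = pd.Series(
        np.divide(hom_alt, denom, out=np.full(len(cols), np.nan), where=denom > 0),
        index=pd.Index(ids, name="sample"), name="homozygosity")
    sites = (pd.concat(site_frames, ignore_index=True)
             if site_frames else pd.DataFrame(
                 columns=["chrom", "pos", "het", "missing", "nonref", "mean_depth"]))
    density = pd.DataFrame(dens_rows,
                           columns=["chrom", "start", "end", "per_kb"])
    return {"sites": sites, "homozygosity": homozygosity, "density": density}
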