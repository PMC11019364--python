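"""Coordinate lifting between assemblies and its downstream evaluations.

A UCSC chain file describes block-wise alignments from a source assembly to
a target assembly; positions inside aligned blocks translate by offset
(reverse-strand blocks run backwards through the target), positions in
alignment gaps or on absent chromosomes are unmappable.  On top of lifting,
this module implements three evaluation protocols:

* a simulated lift of evenly spaced sites, measuring what fraction of the
  source genome has a one-to-one match in the target;
* a comparison of a lifted variant set against variants called directly on
  the target;
* cis/trans classification of SNP-gene association pairs under two
  coordinate maps, counting reclassifications (a spurious trans association
  caused by a misplaced segment becomes cis once the segment is back where
  it belongs);
* rank concordance between genetic-map (cM) and physical (bp) marker order,
  flagging anti-monotone runs as inversion candidates.
"""

from __future__ import annotations

import io
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CIS = "CIS"
AMBIGUOUS = "AMBIGUOUS"
TRANS = "TRANS"


# ---------------------------------------------------------------------------
# chain parsing
# ---------------------------------------------------------------------------

@dataclass
class ChainBlock:
    """One gapless aligned block (0-based half-open, forward source coords)."""

    src_start: int
    src_end: int
    tgt_start: int   # forward target coordinate of the block start


@dataclass
class Chain:
    """One chain record: colinear blocks from source (t) to target (q)."""

    score: float
    src_chrom: str
    src_size: int
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_size: int
    tgt_strand: str     # '+' or '-'
    tgt_start: int      # strand coordinates as written in the file
    tgt_end: int
    chain_id: str
    blocks: list[ChainBlock] = field(default_factory=list)


@dataclass
class ChainSet:
    chains: list[Chain]

    def __post_init__(self) -> None:
        self._by_src: dict[str, list[Chain]] = {}
        for c in self.chains:
            self._by_src.setdefault(c.src_chrom, []).append(c)
        for lst in self._by_src.values():
            lst.sort(key=lambda c: -c.score)

    def for_chrom(self, chrom: str) -> list[Chain]:
        return self._by_src.get(chrom, [])


class ChainParseError(ValueError):
    pass


def parse_chain(source) -> ChainSet:
    """Parse UCSC chain text (path, text, or open handle) into a ChainSet.

    Header: ``chain score tName tSize tStrand tStart tEnd qName qSize
    qStrand qStart qEnd id``; the t-side is the lift source.  Block lines
    carry ``size dt dq``; the final block is a bare size.  The cumulative
    block arithmetic must reproduce the declared spans, else the chain is
    rejected by id.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    chains: list[Chain] = []
    lines = iter(text.splitlines())
    current: Chain | None = None
    src_cur = tgt_cur = 0
    closed = True
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("chain"):
            if current is not None and not closed:
                raise ChainParseError(
                    f"chain {current.chain_id}: truncated block list")
            f = line.split()
            if len(f) != 13:
                raise ChainParseError(f"malformed chain header: {line!r}")
            if f[4] != "+":
                raise ChainParseError("source strand must be '+'")
            current = Chain(score=float(f[1]), src_chrom=f[2],
                            src_size=int(f[3]), src_start=int(f[5]),
                            src_end=int(f[6]), tgt_chrom=f[7],
                            tgt_size=int(f[8]), tgt_strand=f[9],
                            tgt_start=int(f[10]), tgt_end=int(f[11]),
                            chain_id=f[12])
            if current.tgt_strand not in "+-":
                raise ChainParseError("target strand must be '+' or '-'")
            chains.append(current)
            src_cur, tgt_cur = current.src_start, current.tgt_start
            closed = False
        else:
            if current is None:
                raise ChainParseError(f"block line outside a chain: {line!r}")
            parts = line.split()
            size = int(parts[0])
            if current.tgt_strand == "+":
                tgt_fwd = tgt_cur
            else:
                # strand coordinates count from the reversed target; the
                # block occupies forward interval [size_ - (cur+size), ...)
                tgt_fwd = current.tgt_size - (tgt_cur + size)
            current.blocks.append(ChainBlock(src_cur, src_cur + size, tgt_fwd))
            src_cur += size
            tgt_cur += size
            if len(parts) == 3:
                src_cur += int(parts[1])
                tgt_cur += int(parts[2])
            elif len(parts) == 1:
                if src_cur != current.src_end or tgt_cur != current.tgt_end:
                    raise ChainParseError(
                        f"chain {current.chain_id}: block arithmetic does not "
                        f"match declared spans")
                closed = True
            else:
                raise ChainParseError(f"malformed block line: {line!r}")
    if current is not None and not closed:
        raise ChainParseError(f"chain {current.chain_id}: truncated block list")
    return ChainSet(chains=chains)


# ---------------------------------------------------------------------------
# lifting
# ---------------------------------------------------------------------------

UNMAPPED_GAP = "gap"
UNMAPPED_CHROM_ABSENT = "chrom_absent"


@dataclass
class LiftResult:
    chrom: str | None
    pos: int | None          # 1-based
    strand: str | None
    reason: str | None       # None when mapped

    @property
    def mapped(self) -> bool:
        return self.reason is None


def lift_position(chains: ChainSet, chrom: str, pos: int) -> LiftResult:
    """Lift a 1-based source position through the highest-scoring cover.

    Chains are tried in descending score order; the first chain whose span
    covers the position decides the outcome (inside one of its aligned
    blocks -> mapped, inside one of its gaps -> unmapped "gap").
    """
    cands = chains.for_chrom(chrom)
    if not cands:
        return LiftResult(None, None, None, UNMAPPED_CHROM_ABSENT)
    p0 = pos - 1
    in_any_span = False
    for chain in cands:
        if not chain.src_start <= p0 < chain.src_end:
            continue
        in_any_span = True
        starts = [b.src_start for b in chain.blocks]
        k = bisect_right(starts, p0) - 1
        if k >= 0:
            b = chain.blocks[k]
            if p0 < b.src_end:
                off = p0 - b.src_start
                if chain.tgt_strand == "+":
                    return LiftResult(chain.tgt_chrom, b.tgt_start + off + 1,
                                      "+", None)
                size = b.src_end - b.src_start
                return LiftResult(chain.tgt_chrom,
                                  b.tgt_start + (size - 1 - off) + 1, "-", None)
        # inside this chain's span but in a gap: fall through to lower-score
        # chains that might still align it
    return LiftResult(None, None, None,
                      UNMAPPED_GAP if in_any_span else UNMAPPED_CHROM_ABSENT)


def invert_chains(chains: ChainSet) -> ChainSet:
    """The inverse mapping: target coordinates back to source coordinates.

    Block-wise inversion; a reverse-strand block stays reverse-strand (the
    composition of the two reversals is the identity on every aligned base).
    """
    inv = []
    for c in chains.chains:
        blocks = sorted(
            (ChainBlock(src_start=b.tgt_start,
                        src_end=b.tgt_start + (b.src_end - b.src_start),
                        tgt_start=b.src_start)
             for b in c.blocks), key=lambda b: b.src_start)
        if not blocks:
            continue
        inv.append(Chain(
            score=c.score, src_chrom=c.tgt_chrom, src_size=c.tgt_size,
            src_start=blocks[0].src_start, src_end=blocks[-1].src_end,
            tgt_chrom=c.src_chrom, tgt_size=c.src_size,
            tgt_strand=c.tgt_strand, tgt_start=0, tgt_end=0,
            chain_id=c.chain_id + "_inv", blocks=blocks))
    return ChainSet(chains=inv)


@dataclass
class LiftReport:
    """Bookkeeping of a lift evaluation run."""

    n_input: int = 0
    n_lifted: int = 0
    unmapped_reasons: dict = field(default_factory=dict)
    n_matched: int = 0
    n_lifted_only: int = 0
    n_direct_only: int = 0

    @property
    def fraction_lifted(self) -> float:
        return self.n_lifted / self.n_input if self.n_input else float("nan")


def simulate_and_eval_liftover(chrom_lengths: dict[str, int],
                               chains: ChainSet,
                               spacing: int = 1000) -> LiftReport:
    """Lift evenly spaced simulated sites and report the liftable fraction.

    Sites sit at 1, 1+spacing, 2*spacing+1, ... on every source chromosome.
    """
    if not chrom_lengths:
        raise ValueError("empty chromosome map")
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    report = LiftReport()
    for chrom, length in chrom_lengths.items():
        for pos in range(1, length + 1, spacing):
            report.n_input += 1
            res = lift_position(chains, chrom, pos)
            if res.mapped:
                report.n_lifted += 1
            else:
                report.unmapped_reasons[res.reason] = \
                    report.unmapped_reasons.get(res.reason, 0) + 1
    return report


def compare_lifted_vs_direct(lifted, direct) -> LiftReport:
    """Partition two variant sets (keyed (chrom, pos, alleles)) into
    matched / lifted-only / direct-only."""
    lifted, direct = set(lifted), set(direct)
    report = LiftReport()
    report.n_matched = len(lifted & direct)
    report.n_lifted_only = len(lifted - direct)
    report.n_direct_only = len(direct - lifted)
    return report


# ---------------------------------------------------------------------------
# cis/trans classification
# ---------------------------------------------------------------------------

@dataclass
class FeaturePair:
    """A SNP locus paired with a gene TSS locus under one reference."""

    snp_id: str
    gene_id: str
    pvalue: float = 0.0


def classify_locus_pair(snp: tuple[str, int], tss: tuple[str, int],
                        cis_bp: int = 1_000_000,
                        ambiguous_bp: int = 5_000_000) -> str:
    """CIS when same chromosome and |distance| < cis_bp; TRANS when on
    different chromosomes or |distance| > ambiguous_bp; else AMBIGUOUS
    (distances exactly at either bound are AMBIGUOUS)."""
    if snp[0] != tss[0]:
        return TRANS
    dist = abs(snp[1] - tss[1])
    if dist < cis_bp:
        return CIS
    if dist > ambiguous_bp:
        return TRANS
    return AMBIGUOUS


def classify_pairs(pairs: list[FeaturePair],
                   snp_coords_a: dict, snp_coords_b: dict,
                   tss_coords_a: dict, tss_coords_b: dict,
                   cis_bp: int = 1_000_000,
                   ambiguous_bp: int = 5_000_000) -> dict:
    """Classify SNP-gene pairs under two coordinate maps and count moves.

    Coordinate dicts map snp_id / gene_id -> (chrom, pos).  Returns per-map
    class lists, a conversion table keyed (class_a, class_b), and a per-gene
    rollup of TRANS->CIS and CIS->TRANS conversions.
    """
    classes_a, classes_b = [], []
    conversions: dict[tuple[str, str], int] = {}
    per_gene: dict[str, dict[str, int]] = {}
    for pair in pairs:
        for name, coords in (("snp A", snp_coords_a), ("snp B", snp_coords_b)):
            if pair.snp_id not in coords:
                raise KeyError(f"pair ({pair.snp_id}, {pair.gene_id}): "
                               f"missing {name} coordinate")
        for name, coords in (("TSS A", tss_coords_a), ("TSS B", tss_coords_b)):
            if pair.gene_id not in coords:
                raise KeyError(f"pair ({pair.snp_id}, {pair.gene_id}): "
                               f"missing {name} coordinate")
        ca = classify_locus_pair(snp_coords_a[pair.snp_id],
                                 tss_coords_a[pair.gene_id], cis_bp, ambiguous_bp)
        cb = classify_locus_pair(snp_coords_b[pair.snp_id],
                                 tss_coords_b[pair.gene_id], cis_bp, ambiguous_bp)
        classes_a.append(ca)
        classes_b.append(cb)
        conversions[(ca, cb)] = conversions.get((ca, cb), 0) + 1
        g = per_gene.setdefault(pair.gene_id,
                                {"trans_to_cis": 0, "cis_to_trans": 0})
        if (ca, cb) == (TRANS, CIS):
            g["trans_to_cis"] += 1
        elif (ca, cb) == (CIS, TRANS):
            g["cis_to_trans"] += 1
    return {
        "classes_a": classes_a,
        "classes_b": classes_b,
        "conversions": conversions,
        "trans_to_cis": conversions.get((TRANS, CIS), 0),
        "cis_to_trans": conversions.get((CIS, TRANS), 0),
        "unchanged": sum(v for (a, b), v in conversions.items() if a == b),
        "per_gene": per_gene,
    }


# ---------------------------------------------------------------------------
# genetic-map vs physical-order concordance
# ---------------------------------------------------------------------------

@dataclass
class AntiMonotoneRun:
    """A run of consecutive markers whose genetic position decreases."""

    first_index: int
    last_index: int
    start_bp: int
    end_bp: int
    n_markers: int


def marker_concordance(markers, min_run: int = 5) -> dict:
    """Rank concordance of genetic (cM) vs physical (bp) marker order.

    ``markers`` is a sequence of (cM, bp) sorted by physical position.
    Returns Spearman rho and maximal runs of >= ``min_run`` consecutive
    markers with locally decreasing genetic position (inversion candidates),
    each with its bp extent.
    """
    markers = list(markers)
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    cm = np.array([m[0] for m in markers], dtype=float)
    bp = np.array([m[1] for m in markers], dtype=np.int64)
    if not np.all(np.diff(bp) >= 0):
        raise ValueError("markers must be sorted by physical position")
    rho = float(stats.spearmanr(cm, bp).statistic)
    runs: list[AntiMonotoneRun] = []
    start = None
    for i in range(1, len(cm)):
        if cm[i] < cm[i - 1]:
            if start is None:
                start = i - 1
        else:
            if start is not None:
                _close_run(runs, start, i - 1, bp, min_run)
                start = None
    if start is not None:
        _close_run(runs, start, len(cm) - 1, bp, min_run)
    return {"rho": rho, "runs": runs}


def _close_run(runs: list, first: int, last: int, bp: np.ndarray,
               min_run: int) -> None:
    n = last - first + 1
    if n >= min_run:
        runs.append(AntiMonotoneRun(first, last, int(bp[first]), int(bp[last]),
                                    n))
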