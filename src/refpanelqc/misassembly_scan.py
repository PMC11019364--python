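"""Misassembly-region flagging from inbred-panel heterozygosity.

Inbred samples should be homozygous almost everywhere; a run of sites with
many heterozygous or no-call genotypes in reference-strain samples marks a
region where the reference likely collapsed a repeat (twice the reads, two
haplotypes' worth of alleles piled onto one locus).

The scan works on the per-site het+NA count over a designated sample subset:

1. transform: ``y_i = log2(het_i + na_i + 2)`` — the pseudocount of 2 makes
   the baseline resemble 2 DNA copies, elevated regions up to 14;
2. segment the series with a circular-binary-segmentation style recursive
   changepoint search (best arc by a two-sample t-like statistic, accepted
   by a seeded permutation test);
3. merge the over-segmented result with a sliding-triplet rule set that
   joins same-state neighbours and absorbs sub-5-kb "flickers";
4. flag merged segments whose mean transformed value exceeds 1.5 and emit
   them as BED intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: intervals at most this long are searched exhaustively over all arcs;
#: longer intervals use a strided candidate grid with exact local refinement
EXACT_SEARCH_LIMIT = 256
_GRID_SIZE = 256


@dataclass
class ScanParams:
    """Tuning knobs of the heterozygosity scan.

    ``threshold`` separates HIGH from LOW segment means on the log2(x+2)
    scale; a mean exactly equal to the threshold is LOW.  ``min_width`` and
    the segmentation operate on site index; ``flicker_bp`` operates on
    genomic bp.
    """

    pseudocount: int = 2
    threshold: float = 1.5
    min_width: int = 5
    alpha: float = 0.001
    flicker_bp: int = 5000
    permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount < 1:
            raise ValueError("pseudocount must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.flicker_bp <= 0:
            raise ValueError("flicker_bp must be positive")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


@dataclass
class Segment:
    """A contiguous run of sites with a common mean transformed value."""

    chrom: str
    first: int        # 0-based site index, inclusive
    last: int         # inclusive
    start_bp: int     # 0-based half-open genomic bounds
    end_bp: int
    mean: float
    n_sites: int

    def is_high(self, threshold: float) -> bool:
        return self.mean > threshold

    @property
    def bp_length(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class FlaggedRegion:
    """A candidate misassembly interval (BED coordinates)."""

    chrom: str
    start: int
    end: int
    mean_het_na: float   # back-transformed: 2**mean - pseudocount
    n_sites: int

    def bed_row(self) -> str:
        return (f"{self.chrom}\t{self.start}\t{self.end}\t"
                f"{self.mean_het_na:.3f}\t{self.n_sites}")


def scan_statistic(het_counts, missing_counts,
                   params: ScanParams | None = None) -> np.ndarray:
    """Per-site transformed series ``log2(het + missing + pseudocount)``."""
    params = params or ScanParams()
    het = np.asarray(het_counts, dtype=float)
    na = np.asarray(missing_counts, dtype=float)
    if het.shape != na.shape:
        raise ValueError("het and missing series must be aligned")
    if (het < 0).any() or (na < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log2(het + na + params.pseudocount)


# ---------------------------------------------------------------------------
# changepoint search
# ---------------------------------------------------------------------------

def _arc_t_stats(cs: np.ndarray, css: np.ndarray, i: np.ndarray, j: np.ndarray,
                 n: int) -> np.ndarray:
    """Two-sample t-like statistic for arcs [i, j) against their complement.

    ``cs``/``css`` are 0-prefixed cumulative sums of values and squares over
    the interval of length ``n``.  Degenerate variance with unequal means
    maps to +inf, with equal means to 0.
    """
    d = j - i
    sum_in = cs[j] - cs[i]
    ss_in = css[j] - css[i]
    total, total_sq = cs[n], css[n]
    sum_out = total - sum_in
    n_out = n - d
    mean_in = sum_in / d
    mean_out = sum_out / n_out
    dev_in = ss_in - sum_in ** 2 / d
    dev_out = (total_sq - ss_in) - sum_out ** 2 / n_out
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = (dev_in + dev_out) / max(n - 2, 1)
        se = np.sqrt(s2 * (1.0 / d + 1.0 / n_out))
        t = np.abs(mean_in - mean_out) / se
    diff = np.abs(mean_in - mean_out)
    t = np.where(se > 0, t, np.where(diff > 0, np.inf, 0.0))
    return t


def _prefix_sums(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (np.concatenate([[0.0], np.cumsum(values)]),
            np.concatenate([[0.0], np.cumsum(values ** 2)]))


def _best_arc(cs: np.ndarray, css: np.ndarray, n: int, min_width: int,
              gi: np.ndarray, gj: np.ndarray):
    """Best (statistic, i, j) over the candidate boundary grid gi x gj.

    A split at (i, j) produces pieces [0,i), [i,j), [j,n); it is admissible
    when every non-empty piece holds at least ``min_width`` sites and the
    arc is not the whole interval.  Fully vectorised over the grid.
    """
    i2, j2 = np.meshgrid(gi, gj, indexing="ij")
    i2, j2 = i2.ravel(), j2.ravel()
    ok = ((j2 - i2 >= min_width)
          & ((n - j2 >= min_width) | (j2 == n))
          & ((i2 >= min_width) | (i2 == 0))
          & ~((i2 == 0) & (j2 == n)))
    i2, j2 = i2[ok], j2[ok]
    if i2.size == 0:
        return 0.0, 0, n
    t = _arc_t_stats(cs, css, i2, j2, n)
    k = int(np.argmax(t))
    return float(t[k]), int(i2[k]), int(j2[k])


def _max_arc_exact(values: np.ndarray, min_width: int):
    """Best admissible arc, exhaustively over all boundary pairs."""
    n = len(values)
    cs, css = _prefix_sums(values)
    g = np.arange(0, n + 1)
    return _best_arc(cs, css, n, min_width, g, g)


def _max_arc_strided(values: np.ndarray, min_width: int, stride: int):
    """Best arc restricted to boundaries on a strided grid (plus the ends)."""
    n = len(values)
    cs, css = _prefix_sums(values)
    g = np.unique(np.concatenate([np.arange(0, n + 1, stride), [n]]))
    return _best_arc(cs, css, n, min_width, g, g)


def _refine_arc(values: np.ndarray, min_width: int, i0: int, j0: int,
                stride: int):
    """Exact search of the +/- stride neighbourhood around a strided optimum."""
    n = len(values)
    cs, css = _prefix_sums(values)
    gi = np.arange(max(0, i0 - stride), min(n, i0 + stride) + 1)
    gj = np.arange(max(0, j0 - stride), min(n, j0 + stride) + 1)
    return _best_arc(cs, css, n, min_width, gi, gj)


def _interval_rng(seed: int, lo: int, hi: int) -> np.random.Generator:
    """Seeded generator for one interval's permutation test.

    Derived from (seed, interval bounds) so results are independent of the
    recursion order and reproducible by an external oracle.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(lo), int(hi))))


def _significant_split(values: np.ndarray, lo: int, hi: int,
                       params: ScanParams) -> tuple[int, int] | None:
    """Best arc of values[lo:hi] if its permutation p-value < alpha, else None.

    Returns interval-local (i, j) arc bounds.  The permutation test shuffles
    the interval's values with a generator seeded from (params.seed, lo, hi)
    and stops early once the exceedance count already guarantees p >= alpha.
    """
    seg = values[lo:hi]
    n = len(seg)
    if n < 2 * params.min_width:
        return None
    if np.all(seg == seg[0]):
        return None
    exact = n <= EXACT_SEARCH_LIMIT
    if exact:
        stat, i, j = _max_arc_exact(seg, params.min_width)
        test_stat = stat
    else:
        stride = max(1, int(np.ceil(n / _GRID_SIZE)))
        test_stat, i, j = _max_arc_strided(seg, params.min_width, stride)
        _, i, j = _refine_arc(seg, params.min_width, i, j, stride)
    if test_stat <= 0:
        return None
    rng = _interval_rng(params.seed, lo, hi)
    n_perm = params.permutations
    exceed = 0
    for _ in range(n_perm):
        shuffled = rng.permutation(seg)
        if exact:
            s, _, _ = _max_arc_exact(shuffled, params.min_width)
        else:
            s, _, _ = _max_arc_strided(shuffled, params.min_width, stride)
        if s >= test_stat:
            exceed += 1
            if (exceed + 1) / (n_perm + 1) >= params.alpha:
                return None
    p = (exceed + 1) / (n_perm + 1)
    if p >= params.alpha:
        return None
    return i, j


def cbs_segment(series, positions, params: ScanParams | None = None,
                chrom: str = "chr?") -> list[Segment]:
    """Segment a transformed series into mean-homogeneous runs of sites.

    Recursive changepoint search: in each interval the arc maximising the
    two-sample t-like statistic between inside and outside means is tested
    by permutation; a significant arc splits the interval at its bounds and
    the parts are searched again.  No segment is ever shorter than
    ``min_width`` sites; intervals shorter than twice that return unsplit.
    """
    params = params or ScanParams()
    values = np.asarray(series, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    if values.ndim != 1 or values.shape != pos.shape:
        raise ValueError("series and positions must be aligned 1-D arrays")
    if len(values) == 0:
        return []
    if len(pos) > 1 and not np.all(np.diff(pos) > 0):
        raise ValueError("positions must be strictly increasing")

    final: list[tuple[int, int]] = []
    stack = [(0, len(values))]
    while stack:
        lo, hi = stack.pop()
        split = _significant_split(values, lo, hi, params)
        if split is None:
            final.append((lo, hi))
            continue
        i, j = split
        pieces = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
        for piece in pieces:
            if piece[1] > piece[0]:
                stack.append(piece)
    final.sort()
    segments = []
    for lo, hi in final:
        segments.append(Segment(
            chrom=chrom, first=lo, last=hi - 1,
            start_bp=int(pos[lo]) - 1, end_bp=int(pos[hi - 1]),
            mean=float(values[lo:hi].mean()), n_sites=hi - lo))
    return segments


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _merge_pair(a: Segment, b: Segment) -> Segment:
    n = a.n_sites + b.n_sites
    return Segment(
        chrom=a.chrom, first=a.first, last=b.last,
        start_bp=a.start_bp, end_bp=b.end_bp,
        mean=(a.mean * a.n_sites + b.mean * b.n_sites) / n,
        n_sites=n)


def _merge_pass(segments: list[Segment], params: ScanParams) -> list[Segment]:
    """One sliding-triplet scan over the segment list."""
    T = params.threshold
    segs = list(segments)
    i = 0
    while i + 1 < len(segs):
        a, b = segs[i], segs[i + 1]
        both_high = a.is_high(T) and b.is_high(T)
        both_low = (not a.is_high(T)) and (not b.is_high(T))
        merge = both_high or both_low
        if not merge and i + 2 < len(segs):
            c = segs[i + 2]
            hi_lo_hi = (a.is_high(T) and not b.is_high(T) and c.is_high(T))
            lo_hi_lo = (not a.is_high(T) and b.is_high(T) and not c.is_high(T))
            if (hi_lo_hi or lo_hi_lo) and b.bp_length < params.flicker_bp:
                merge = True
        if merge:
            segs[i:i + 2] = [_merge_pair(a, b)]
            # next triplet: (merged, old third, newly called-up fourth)
        else:
            i += 1
    return segs


def merge_and_flag(segments: list[Segment], params: ScanParams | None = None
                   ) -> tuple[list[Segment], list[FlaggedRegion]]:
    """Merge over-segmented output and flag HIGH regions.

    The sliding-triplet scan merges the first two segments of the current
    triplet when (1) both are HIGH, (2) both are LOW, (3) the triplet is
    high-low-high with a sub-``flicker_bp`` middle ("positive flicker"), or
    (4) low-high-low with a sub-``flicker_bp`` middle ("negative flicker");
    after a merge the next triplet starts from the merged segment, otherwise
    the scan advances one segment.  A trailing pair is merged on conditions
    (1)/(2) only.  The scan is repeated until no merge fires, so the result
    is a fixpoint (a flicker merge can flip the merged segment's state and
    expose a new same-state pair behind the cursor; the extra passes absorb
    those).

    Flagged regions are the final segments with mean above the threshold,
    with the mean het+NA count back-transformed as ``2**mean - pseudocount``.
    """
    params = params or ScanParams()
    if not segments:
        return [], []
    for a, b in zip(segments, segments[1:]):
        if a.chrom == b.chrom and b.first != a.last + 1:
            raise ValueError("segments do not partition the site-index range")
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    merged_all: list[Segment] = []
    for chrom, segs in by_chrom.items():
        prev = segs
        while True:
            nxt = _merge_pass(prev, params)
            if len(nxt) == len(prev):
                break
            prev = nxt
        merged_all.extend(nxt)
    flags = [FlaggedRegion(chrom=s.chrom, start=s.start_bp, end=s.end_bp,
                           mean_het_na=2.0 ** s.mean - params.pseudocount,
                           n_sites=s.n_sites)
             for s in merged_all if s.is_high(params.threshold)]
    return merged_all, flags


# ---------------------------------------------------------------------------
# end-to-end scan over a panel
# ---------------------------------------------------------------------------

def scan_panel(panel, subset=None, params: ScanParams | None = None
               ) -> tuple[list[Segment], list[FlaggedRegion]]:
    """Run the full scan on a genotype panel (reference-strain subset default).

    ``subset`` is a list of sample ids; by default the panel's
    reference-strain samples are used, mirroring an audit of the assembly's
    own strain.
    """
    from refpanelqc.genotype_io import site_statistics

    params = params or ScanParams()
    if subset is None:
        subset = panel.reference_sample_ids()
        if not subset:
            raise ValueError("panel has no reference-strain samples; "
                             "pass an explicit sample subset")
    stats = site_statistics(panel, subset=subset)["sites"]
    segments: list[Segment] = []
    flagged: list[FlaggedRegion] = []
    for chrom, grp in stats.groupby("chrom", sort=False):
        y = scan_statistic(grp["het"].to_numpy(), grp["missing"].to_numpy(),
                           params)
        segs = cbs_segment(y, grp["pos"].to_numpy(), params, chrom=chrom)
        merged, flags = merge_and_flag(segs, params)
        segments.extend(merged)
        flagged.extend(flags)
    return segments, flagged


def flagged_regions_bed(regions: list[FlaggedRegion]) -> str:
    return "".join(r.bed_row() + "\n" for r in regions)


def segments_table(segments: list[Segment]) -> str:
    header = "chrom\tfirst\tlast\tstart\tend\tmean\tn_sites\n"
    rows = [f"{s.chrom}\t{s.first}\t{s.last}\t{s.start_bp}\t{s.end_bp}\t"
            f"{s.mean:.4f}\t{s.n_sites}" for s in segments]
    return header + "\n".join(rows) + ("\n" if rows else "")
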