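"""Synthetic inbred genotype panels, toy assemblies, and chain files.

Every downstream stage of the package is exercisable without any real data:
the generators here emulate the statistical structure of a jointly-called
inbred rat panel — ~6 variants/kb, ~98% homozygous calls per sample, sparse
residual heterozygosity and missingness — and plant three kinds of reference
defects with recorded truth:

* **collapsed regions**: intervals where heterozygous/no-call genotypes are
  drawn at an elevated per-sample rate and read depths are multiplied (the
  signature of a tandem repeat folded into one reference copy);
* **shared error sites**: single sites where every sample, including the
  reference-strain replicates, carries a non-reference genotype (a wrong
  base recorded in the reference); heterozygous-class error sites also get
  doubled depth;
* **label swaps**: sample metadata exchanged after generation, so genotypes
  and labels disagree (mislabel-detection fodder).

All generation is driven by one integer seed; identical configs and seeds
produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from refpanelqc.genotype_io import (
    ChromBlock,
    GenotypePanel,
    SampleInfo,
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollapsedRegionSpec:
    """A planted collapsed-repeat interval (1-based inclusive bp bounds)."""

    chrom: str
    start: int
    end: int
    het_na_rate: float = 0.6
    depth_multiplier: float = 2.0


@dataclass
class SimConfig:
    """Parameters of a synthetic inbred panel.

    Defaults mirror the structure of a laboratory-rat joint call set: about
    6 variant sites per kb, ~0.5% residual heterozygosity and ~0.5%
    missingness per sample, and Poisson read depth around ``base_depth``.
    Strain 0 is the reference strain (its genome is, by construction, the
    reference — all its background calls are homozygous reference); it can
    carry more replicates than the other strains via ``reference_replicates``.
    """

    n_strains: int = 20
    replicates_per_strain: int = 2
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000})
    variant_density: float = 6.0          # sites per kb
    background_het_rate: float = 0.005    # per site per sample
    missing_rate: float = 0.005
    collapsed_regions: list[CollapsedRegionSpec] = field(default_factory=list)
    error_sites: int = 0
    error_het_fraction: float = 0.25      # fraction of error sites in the het class
    base_depth: float = 30.0
    label_swaps: list[tuple[int, int]] = field(default_factory=list)
    reference_replicates: int | None = None  # default: replicates_per_strain
    strain_alt_rate: float = 0.3          # per-strain hom-alt draw probability
    seed: int = 0

    def validate(self) -> None:
        for name, rate in [("variant_density", self.variant_density)]:
            if rate <= 0:
                raise ValueError(f"{name} must be positive")
        for name, rate in [("background_het_rate", self.background_het_rate),
                           ("missing_rate", self.missing_rate),
                           ("error_het_fraction", self.error_het_fraction),
                           ("strain_alt_rate", self.strain_alt_rate)]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_strains < 1 or self.replicates_per_strain < 1:
            raise ValueError("need at least one strain and one replicate")
        regs = sorted(self.collapsed_regions, key=lambda r: (r.chrom, r.start))
        for i, r in enumerate(regs):
            if not 0.0 <= r.het_na_rate <= 1.0:
                raise ValueError("het_na_rate must lie in [0, 1]")
            if r.depth_multiplier < 1:
                raise ValueError("depth_multiplier must be >= 1")
            if r.chrom not in self.chrom_lengths:
                raise ValueError(f"region chromosome {r.chrom!r} unknown")
            if not 1 <= r.start <= r.end <= self.chrom_lengths[r.chrom]:
                raise ValueError(f"region {r} outside chromosome bounds")
            if i and regs[i - 1].chrom == r.chrom and regs[i - 1].end >= r.start:
                raise ValueError("collapsed regions overlap")


@dataclass
class SimTruth:
    """Everything the generator planted, for recovery checks."""

    collapsed_regions: list[CollapsedRegionSpec]
    error_sites: list[tuple[str, int, str]]   # (chrom, 1-based pos, "hom"|"het")
    swapped_samples: list[tuple[int, int]]
    true_labels: list[SampleInfo]             # pre-swap metadata, panel order

    def error_site_set(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _ in self.error_sites}


def _poisson_positions(rng: np.random.Generator, length: int,
                       density_per_kb: float) -> np.ndarray:
    """Strictly increasing 1-based positions from a Poisson process."""
    mean_gap = 1000.0 / density_per_kb
    n_expect = int(length / mean_gap * 1.3) + 20
    gaps = rng.exponential(mean_gap, size=n_expect)
    pos = np.unique(np.ceil(np.cumsum(gaps)).astype(np.int64))
    while pos.size and pos[-1] < length:
        extra = rng.exponential(mean_gap, size=n_expect // 4 + 10)
        more = pos[-1] + np.ceil(np.cumsum(extra)).astype(np.int64)
        pos = np.unique(np.concatenate([pos, more]))
    return pos[(pos >= 1) & (pos <= length)]


def generate_panel(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Simulate a jointly-called inbred panel with planted truth.

    Returns the panel plus a :class:`SimTruth` recording every planted
    collapsed region, error site, and label swap.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    ref_reps = (config.reference_replicates
                if config.reference_replicates is not None
                else config.replicates_per_strain)
    strains = ["REF"] + [f"STR{i:02d}" for i in range(1, config.n_strains)]
    samples: list[SampleInfo] = []
    strain_of_sample: list[int] = []
    for si, strain in enumerate(strains):
        reps = ref_reps if si == 0 else config.replicates_per_strain
        for r in range(1, reps + 1):
            samples.append(SampleInfo(id=f"{strain}_r{r}", strain=strain,
                                      substrain=strain, is_reference=(si == 0)))
            strain_of_sample.append(si)
    n_samples = len(samples)
    strain_col = np.array(strain_of_sample)

    # pre-pick error sites across chromosomes proportionally to length
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    err_per_chrom = rng.multinomial(config.error_sites, lengths / lengths.sum()) \
        if config.error_sites else np.zeros(len(chroms), dtype=int)

    blocks: dict[str, ChromBlock] = {}
    truth_errors: list[tuple[str, int, str]] = []
    for ci, chrom in enumerate(chroms):
        length = config.chrom_lengths[chrom]
        pos = _poisson_positions(rng, length, config.variant_density)
        n = pos.size
        # per-strain hom-alt allele (strain 0 = reference strain, always 0);
        # sites with no carrier get one forced so every site is a variant site
        carrier = rng.random((len(strains), n)) < config.strain_alt_rate
        carrier[0] = False
        none = ~carrier.any(axis=0)
        if none.any() and len(strains) > 1:
            forced = rng.integers(1, len(strains), size=int(none.sum()))
            carrier[forced, np.flatnonzero(none)] = True
        a1 = carrier[strain_col].astype(np.int16).T * 0  # start hom-ref
        a2 = a1.copy()
        strain_gt = carrier[strain_col].T                # (n_sites, n_samples)
        a1[strain_gt] = 1
        a2[strain_gt] = 1

        depth = rng.poisson(config.base_depth, size=(n, n_samples)).astype(np.int32)

        # background residual heterozygosity and missingness (independent per
        # replicate: replicates share the strain genotype, not the noise)
        u = rng.random((n, n_samples))
        het_bg = u < config.background_het_rate
        mis_bg = (u >= config.background_het_rate) & \
                 (u < config.background_het_rate + config.missing_rate)

        # collapsed regions: elevated het+NA on all samples, depth multiplied
        region_mask = np.zeros(n, dtype=bool)
        het_cr = np.zeros((n, n_samples), dtype=bool)
        mis_cr = np.zeros((n, n_samples), dtype=bool)
        for reg in config.collapsed_regions:
            if reg.chrom != chrom:
                continue
            inside = (pos >= reg.start) & (pos <= reg.end)
            region_mask |= inside
            v = rng.random((int(inside.sum()), n_samples))
            hit = v < reg.het_na_rate
            # among elevated calls: 3/4 heterozygous, 1/4 no-call
            as_het = hit & (v < reg.het_na_rate * 0.75)
            as_mis = hit & ~as_het
            het_cr[inside] = as_het
            mis_cr[inside] = as_mis
            depth[inside] = np.round(
                depth[inside] * reg.depth_multiplier).astype(np.int32)

        het = het_cr | (het_bg & ~region_mask[:, None])
        mis = mis_cr | (mis_bg & ~region_mask[:, None] & ~het)
        a1[het] = 0
        a2[het] = 1
        a1[mis] = -1
        a2[mis] = -1

        # planted shared error sites (outside collapsed regions)
        n_err = int(err_per_chrom[ci])
        if n_err:
            eligible = np.flatnonzero(~region_mask)
            if eligible.size < n_err:
                raise ValueError("not enough sites outside collapsed regions "
                                 "to plant the requested error sites")
            chosen = np.sort(rng.choice(eligible, size=n_err, replace=False))
            n_het_err = int(round(n_err * config.error_het_fraction))
            het_err = np.zeros(n_err, dtype=bool)
            if n_het_err:
                het_err[rng.choice(n_err, size=n_het_err, replace=False)] = True
            for k, idx in enumerate(chosen):
                if het_err[k]:
                    a1[idx, :], a2[idx, :] = 0, 1
                    depth[idx, :] = np.round(depth[idx, :] * 2.0).astype(np.int32)
                    truth_errors.append((chrom, int(pos[idx]), "het"))
                else:
                    a1[idx, :], a2[idx, :] = 1, 1
                    truth_errors.append((chrom, int(pos[idx]), "hom"))

        ref_base = rng.choice(_BASES, size=n)
        alt_base = np.array([_BASES[(list(_BASES).index(r) + 1) % 4]
                             for r in ref_base])
        qual = np.clip(rng.normal(70.0, 20.0, size=n), 1.0, None)
        blocks[chrom] = ChromBlock(
            positions=pos, ref=list(ref_base),
            alts=[(b,) for b in alt_base], qual=qual,
            a1=a1, a2=a2, depth=depth)

    true_labels = list(samples)
    for i, j in config.label_swaps:
        if not (0 <= i < n_samples and 0 <= j < n_samples):
            raise ValueError(f"label swap ({i}, {j}) out of sample range")
        si, sj = samples[i], samples[j]
        # exchange metadata, keep genotype columns in place
        samples[i] = SampleInfo(sj.id, sj.strain, sj.substrain, sj.is_reference)
        samples[j] = SampleInfo(si.id, si.strain, si.substrain, si.is_reference)

    panel = GenotypePanel(samples=samples, blocks=blocks)
    truth = SimTruth(collapsed_regions=list(config.collapsed_regions),
                     error_sites=truth_errors,
                     swapped_samples=list(config.label_swaps),
                     true_labels=true_labels)
    return panel, truth


# ---------------------------------------------------------------------------
# Toy assemblies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldSpec:
    """One scaffold as alternating runs: ("seq", n) and ("gap", n) pieces."""

    name: str
    pieces: tuple[tuple[str, int], ...]

    def length(self) -> int:
        return sum(n for _, n in self.pieces)


def generate_assembly(specs: list[ScaffoldSpec], seed: int = 0,
                      min_gap: int = 10) -> tuple[str, dict]:
    """Emit FASTA text for the given scaffold layouts plus contiguity truth.

    Truth lists, per scaffold, the contig lengths produced by splitting at
    N-runs of ``min_gap`` or more (shorter runs stay inside a contig), and
    the scaffold lengths themselves.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xA55)))
    records = []
    scaffold_lengths: dict[str, int] = {}
    contig_lengths: dict[str, list[int]] = {}
    for spec in specs:
        for (k1, _), (k2, _) in zip(spec.pieces, spec.pieces[1:]):
            if k1 == k2 == "gap":
                raise ValueError("adjacent gap pieces must be merged into one")
        total = spec.length()
        parts = []
        contigs: list[int] = []
        cur = 0
        for kind, n in spec.pieces:
            if n < 0:
                raise ValueError("piece lengths must be non-negative")
            if kind == "gap":
                if n >= total:
                    raise ValueError("gap run must be shorter than its scaffold")
                parts.append("N" * n)
                if n >= min_gap:
                    if cur:
                        contigs.append(cur)
                    cur = 0
                else:
                    # sub-threshold N-runs stay inside the contig, wherever
                    # they fall (including scaffold edges)
                    cur += n
            elif kind == "seq":
                parts.append("".join(rng.choice(_BASES, size=n)))
                cur += n
            else:
                raise ValueError(f"unknown piece kind {kind!r}")
        if cur:
            contigs.append(cur)
        scaffold_lengths[spec.name] = total
        contig_lengths[spec.name] = contigs
        records.append((spec.name, "".join(parts)))
    fasta = "".join(f">{name}\n" + "\n".join(
        seq[i:i + 70] for i in range(0, len(seq), 70)) + "\n"
        for name, seq in records)
    truth = {"scaffold_lengths": scaffold_lengths,
             "contig_lengths": contig_lengths}
    return fasta, truth


# ---------------------------------------------------------------------------
# Chain files
# ---------------------------------------------------------------------------

@dataclass
class ChainTruth:
    """Ground-truth map for a synthetic chain: per-chrom mappable segments.

    ``segments`` holds (src_start, src_end, tgt_start, strand) with 0-based
    half-open source coordinates and forward-strand target coordinates; for
    '-' segments the source base at src_start maps to tgt_start + (length-1)
    and positions decrease across the block.
    """

    segments: dict[str, list[tuple[int, int, int, str]]]
    deleted: dict[str, list[tuple[int, int]]]
    src_sizes: dict[str, int]
    tgt_sizes: dict[str, int]

    def expected_target(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Expected lifted position for a 1-based source position, or None."""
        p0 = pos - 1
        for s, e, t, strand in self.segments.get(chrom, []):
            if s <= p0 < e:
                off = p0 - s
                if strand == "+":
                    return chrom, t + off + 1
                return chrom, t + (e - s - 1 - off) + 1
        return None

    def n_unmappable(self, chrom: str) -> int:
        return sum(e - s for s, e in self.deleted.get(chrom, []))


def generate_chain(chrom_lengths: dict[str, int], deleted_fraction: float = 0.0,
                   inverted_blocks: list[tuple[str, int, int]] | None = None,
                   seed: int = 0, n_deletions: int = 10) -> tuple[str, ChainTruth]:
    """Build a UCSC chain from a source genome to a shrunken/rearranged target.

    ``deleted_fraction`` of each source chromosome (exactly
    ``round(fraction * length)`` bases, spread over up to ``n_deletions``
    intervals) is absent from the target; ``inverted_blocks`` are (chrom,
    start, end) 0-based half-open source intervals emitted as reverse-strand
    chains.  Returns the chain text and the exact truth map.
    """
    if not 0.0 <= deleted_fraction < 1.0:
        raise ValueError("deleted_fraction must lie in [0, 1)")
    inverted_blocks = list(inverted_blocks or [])
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in inverted_blocks:
        if chrom not in chrom_lengths or not 0 <= s < e <= chrom_lengths[chrom]:
            raise ValueError(f"inverted block ({chrom},{s},{e}) out of bounds")
        by_chrom.setdefault(chrom, []).append((s, e))
    for blocks in by_chrom.values():
        blocks.sort()
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if e1 > s2:
                raise ValueError("inverted blocks overlap")

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xC4A1)))
    out_lines: list[str] = []
    truth_segments: dict[str, list] = {}
    truth_deleted: dict[str, list] = {}
    tgt_sizes: dict[str, int] = {}
    chain_id = 1

    for chrom, length in chrom_lengths.items():
        inv = by_chrom.get(chrom, [])
        n_del_bases = int(round(deleted_fraction * length))
        deletions: list[tuple[int, int]] = []
        if n_del_bases:
            k = min(n_deletions, n_del_bases)
            sizes = np.full(k, n_del_bases // k, dtype=int)
            sizes[: n_del_bases % k] += 1
            forbidden = list(inv)
            for size in sizes:
                for _ in range(1000):
                    start = int(rng.integers(0, length - size + 1))
                    cand = (start, start + size)
                    busy = forbidden + deletions
                    if all(cand[1] <= s or cand[0] >= e for s, e in busy):
                        deletions.append(cand)
                        break
                else:
                    raise ValueError("could not place deletion intervals; "
                                     "chromosome too crowded")
            deletions.sort()
        truth_deleted[chrom] = deletions
        tgt_sizes[chrom] = length - n_del_bases

        # walk the source, emitting kept segments with target offsets
        breaks = sorted({0, length}
                        | {b for s, e in deletions for b in (s, e)}
                        | {b for s, e in inv for b in (s, e)})
        del_set = deletions
        segs = []  # (src_start, src_end, tgt_start, strand)
        tgt_cursor = 0
        for s, e in zip(breaks, breaks[1:]):
            if any(ds <= s < de for ds, de in del_set):
                continue
            strand = "-" if any(is_ <= s < ie for is_, ie in inv) else "+"
            segs.append((s, e, tgt_cursor, strand))
            tgt_cursor += e - s
        truth_segments[chrom] = segs

        # forward chain: all '+' segments, colinear in both genomes
        fwd = [g for g in segs if g[3] == "+"]
        tsize, qsize = length, tgt_sizes[chrom]
        if fwd:
            t_start, q_start = fwd[0][0], fwd[0][2]
            t_end, q_end = fwd[-1][1], fwd[-1][2] + (fwd[-1][1] - fwd[-1][0])
            score = 100 * sum(e - s for s, e, _, _ in
                              [(s, e, t, st) for s, e, t, st in fwd])
            out_lines.append(
                f"chain {score} {chrom} {tsize} + {t_start} {t_end} "
                f"{chrom} {qsize} + {q_start} {q_end} {chain_id}")
            chain_id += 1
            for i, (s, e, t, _) in enumerate(fwd):
                size = e - s
                if i + 1 < len(fwd):
                    ns, ne, nt, _ = fwd[i + 1]
                    out_lines.append(f"{size} {ns - e} {nt - (t + size)}")
                else:
                    out_lines.append(f"{size}")
            out_lines.append("")
        # one reverse-strand chain per inverted segment
        for s, e, t, strand in segs:
            if strand != "-":
                continue
            size = e - s
            q_start_fwd, q_end_fwd = t, t + size
            q_start_rev = qsize - q_end_fwd
            q_end_rev = qsize - q_start_fwd
            out_lines.append(
                f"chain {50 * size} {chrom} {tsize} + {s} {e} "
                f"{chrom} {qsize} - {q_start_rev} {q_end_rev} {chain_id}")
            chain_id += 1
            out_lines.append(f"{size}")
            out_lines.append("")

    truth = ChainTruth(segments=truth_segments, deleted=truth_deleted,
                       src_sizes=dict(chrom_lengths), tgt_sizes=tgt_sizes)
    return "\n".join(out_lines) + ("\n" if out_lines else ""), truth
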