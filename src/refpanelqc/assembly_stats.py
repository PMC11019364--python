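"""Assembly contiguity statistics: scaffold/contig lengths, N50/L50, fold ratios.

Every FASTA record counts as a scaffold; contigs are obtained by splitting
scaffolds at runs of 10 or more consecutive Ns (shorter N-runs stay inside a
contig and count toward its length).  No minimum-length filtering is applied
anywhere.  Only the letter N (either case) defines a gap; other ambiguity
codes are ordinary sequence.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

from Bio import SeqIO


def contig_lengths_from_sequence(sequence: str, min_gap: int = 10) -> list[int]:
    """Contig lengths after splitting at maximal N-runs of ``min_gap``+ bases.

    N-runs shorter than ``min_gap`` remain inside a contig and count toward
    its length; leading/trailing qualifying runs produce no empty contigs.
    An all-gap or empty scaffold yields an empty list.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    if not sequence:
        return []
    pieces = re.split(f"[nN]{{{min_gap},}}", sequence)
    lengths = []
    for piece in pieces:
        # short N-runs survive the split and count toward the contig, but a
        # piece of nothing-but-short-runs boundaries can still be empty
        if piece:
            lengths.append(len(piece))
    return lengths


def nx_stats(lengths, x: float = 50.0) -> tuple[int, int]:
    """(Nx, Lx): the length at which the descending cumulative sum first
    reaches x% of the total, and the number of sequences in that prefix."""
    lengths = sorted((int(v) for v in lengths), reverse=True)
    if not lengths:
        raise ValueError("cannot compute Nx of an empty length set")
    if not 0 < x < 100:
        raise ValueError("x must lie in (0, 100)")
    half = sum(lengths) * x / 100.0
    acc = 0
    for i, v in enumerate(lengths, start=1):
        acc += v
        if acc >= half:
            return v, i
    raise AssertionError("unreachable: cumulative sum must reach the target")


@dataclass
class AssemblySummary:
    """Contiguity summary of one assembly."""

    name: str
    scaffold_lengths: list[int]
    contig_lengths: list[int]

    @property
    def total_length(self) -> int:
        return sum(self.scaffold_lengths)

    @property
    def ungapped_length(self) -> int:
        return sum(self.contig_lengths)

    @property
    def n_scaffolds(self) -> int:
        return len(self.scaffold_lengths)

    @property
    def n_contigs(self) -> int:
        return len(self.contig_lengths)

    @property
    def scaffold_n50(self) -> int:
        return nx_stats(self.scaffold_lengths)[0]

    @property
    def scaffold_l50(self) -> int:
        return nx_stats(self.scaffold_lengths)[1]

    @property
    def contig_n50(self) -> int:
        return nx_stats(self.contig_lengths)[0]

    @property
    def contig_l50(self) -> int:
        return nx_stats(self.contig_lengths)[1]

    def to_table(self) -> str:
        rows = [
            ("Total sequence length", self.total_length),
            ("Total ungapped length", self.ungapped_length),
            ("No. of scaffolds", self.n_scaffolds),
            ("Scaffold N50", self.scaffold_n50),
            ("Scaffold L50", self.scaffold_l50),
            ("No. of contigs", self.n_contigs),
            ("Contig N50", self.contig_n50),
            ("Contig L50", self.contig_l50),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def summarize_fasta(source, name: str = "assembly",
                    min_gap: int = 10) -> AssemblySummary:
    """Summarize a (multi-record) FASTA file or text into an AssemblySummary."""
    if isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    else:
        handle = open(source)
    try:
        scaffolds, contigs = [], []
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq)
            scaffolds.append(len(seq))
            contigs.extend(contig_lengths_from_sequence(seq, min_gap=min_gap))
    finally:
        handle.close()
    if not scaffolds:
        raise ValueError("no FASTA records found")
    return AssemblySummary(name=name, scaffold_lengths=scaffolds,
                           contig_lengths=contigs)


def _round_fold(value: float, is_n50: bool) -> float:
    """Quoting convention: N50 folds >= 100 round to the nearest 10;
    count folds round to the nearest integer; smaller values keep 1 decimal."""
    if is_n50 and value >= 100:
        return round(value / 10.0) * 10
    if not is_n50:
        return float(round(value))
    return round(value, 1)


def fold_ratio(numerator: float, denominator: float, kind: str = "n50") -> float:
    """A quotable fold ratio: ``kind`` 'n50' rounds to the nearest 10 when
    >= 100 (1 decimal below); 'count' rounds to the nearest integer."""
    if denominator == 0:
        raise ValueError("zero denominator in fold ratio")
    if kind not in ("n50", "count"):
        raise ValueError("kind must be 'n50' or 'count'")
    return _round_fold(numerator / denominator, kind == "n50")


def compare_assemblies(a: AssemblySummary, b: AssemblySummary) -> dict:
    """Fold-ratio comparison of two assemblies (conventionally b over a).

    Reports the contig N50 gain of ``b`` over ``a``, the contig and scaffold
    count reductions of ``a`` over ``b``, and the raw totals.
    """
    for s in (a, b):
        if not s.scaffold_lengths or not s.contig_lengths:
            raise ValueError(f"assembly {s.name!r} is empty")
    if b.contig_n50 == 0 or b.n_contigs == 0 or b.n_scaffolds == 0:
        raise ValueError("zero denominator in fold comparison")
    return {
        "contig_n50_fold": _round_fold(b.contig_n50 / a.contig_n50, True),
        "contig_count_fold": _round_fold(a.n_contigs / b.n_contigs, False),
        "scaffold_count_fold": _round_fold(a.n_scaffolds / b.n_scaffolds, False),
        "total_length": {a.name: a.total_length, b.name: b.total_length},
        "ungapped_length": {a.name: a.ungapped_length, b.name: b.ungapped_length},
    }
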