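"""Strain relationships: IBS matrices, UPGMA trees, proxies, mislabels, sharing.

Identity-by-state (IBS) between two samples is the fraction of alleles they
share at sites where both are called: identical genotypes score 1, a
heterozygote against either homozygote scores 0.5, opposite homozygotes 0,
averaged over co-called sites.  The pairwise matrix drives an ultrametric
UPGMA dendrogram, progenitor-proxy matching (a living substrain over 99.5%
identical to a historical strain can stand in for it), and mislabel flagging
(same-substrain pairs with suspiciously low IBS, cross-strain pairs with
suspiciously high IBS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from refpanelqc.genotype_io import GT_MISSING, GenotypePanel, classify_matrix

SAME_STRAIN_LOW = "SAME_STRAIN_LOW"
CROSS_STRAIN_HIGH = "CROSS_STRAIN_HIGH"


# ---------------------------------------------------------------------------
# IBS
# ---------------------------------------------------------------------------

@dataclass
class IBSMatrix:
    """Symmetric matrix of pairwise IBS proportions."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("matrix shape does not match sample count")
        if not np.allclose(v, v.T):
            raise ValueError("IBS matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def distance(self) -> np.ndarray:
        return 1.0 - self.values


def ibs_matrix(panel: GenotypePanel, biallelic_snps_only: bool = True
               ) -> IBSMatrix:
    """Pairwise IBS over (by default) biallelic SNP sites.

    Sites missing in either member of a pair are excluded for that pair; a
    pair with zero co-called sites is an error.
    """
    if panel.n_samples < 2:
        raise ValueError("IBS needs at least two samples")
    dosage_blocks = []
    for blk in panel.blocks.values():
        use = np.ones(blk.n_sites, dtype=bool)
        if biallelic_snps_only:
            use = np.array([len(a) == 1 and len(a[0]) == 1 and len(r) == 1
                            for r, a in zip(blk.ref, blk.alts)])
        if not use.any():
            continue
        cls = blk.classes()[use]
        dose = (blk.a1[use] + blk.a2[use]).astype(float)
        dose[cls == GT_MISSING] = np.nan
        dosage_blocks.append(dose)
    if not dosage_blocks:
        raise ValueError("no usable sites for IBS")
    dose = np.vstack(dosage_blocks)
    n = panel.n_samples
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(dose[:, i]) & ~np.isnan(dose[:, j])
            if not both.any():
                raise ValueError(
                    f"samples {panel.sample_ids[i]!r} and "
                    f"{panel.sample_ids[j]!r} share no co-called sites")
            ibs = 1.0 - np.abs(dose[both, i] - dose[both, j]).mean() / 2.0
            values[i, j] = values[j, i] = ibs
    return IBSMatrix(sample_ids=list(panel.sample_ids), values=values)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of a rooted ultrametric dendrogram."""

    name: str | None = None           # leaf label, None for internal
    height: float = 0.0               # distance from node to any of its leaves
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk()}:{self.height - c.height:g}"
                         for c in self.children)
        return f"({inner})"


@dataclass
class StrainTree:
    root: TreeNode

    def newick(self) -> str:
        return self.root.newick()

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (all equal for an ultrametric tree)."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            if not node.children:
                depths[node.name] = acc
                return
            for c in node.children:
                walk(c, acc + (node.height - c.height))

        walk(self.root, 0.0)
        return depths


def upgma_tree(matrix: IBSMatrix) -> tuple[StrainTree, str]:
    """UPGMA dendrogram on distance = 1 - IBS.

    Iteratively joins the minimum-distance cluster pair; the distance from a
    new cluster to the others is the size-weighted average of its members'
    distances (i.e. the unweighted average over leaf pairs); node height is
    half the join distance.  Ties are broken by the lexicographically
    smallest (min-label, max-label) pair, so output is deterministic.
    """
    d = matrix.distance().astype(float).copy()
    ids = list(matrix.sample_ids)
    nodes = {i: TreeNode(name=s) for i, s in enumerate(ids)}
    sizes = {i: 1 for i in nodes}
    labels = {i: ids[i] for i in nodes}  # min leaf label, for tie-breaking
    active = set(nodes)
    dist = {}
    for i in active:
        for j in active:
            if i < j:
                dist[(i, j)] = d[i, j]
    next_id = len(ids)
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                la, lb = sorted((labels[i], labels[j]))
                key = (dist[(i, j)], la, lb)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (join_d, _, _), i, j = best
        node = TreeNode(height=join_d / 2.0,
                        children=sorted([nodes[i], nodes[j]],
                                        key=lambda n: min(n.leaves())))
        k = next_id
        next_id += 1
        for m in active:
            if m in (i, j):
                continue
            dmi = dist[(min(m, i), max(m, i))]
            dmj = dist[(min(m, j), max(m, j))]
            dist[(min(m, k), max(m, k))] = (
                sizes[i] * dmi + sizes[j] * dmj) / (sizes[i] + sizes[j])
        nodes[k] = node
        sizes[k] = sizes[i] + sizes[j]
        labels[k] = min(labels[i], labels[j])
        active.discard(i)
        active.discard(j)
        active.add(k)
    tree = StrainTree(root=nodes[next(iter(active))])
    return tree, tree.newick()


# ---------------------------------------------------------------------------
# proxies and mislabels
# ---------------------------------------------------------------------------

@dataclass
class ProxyMatch:
    query_strain: str
    best_sample: str
    ibs: float
    passes: bool


@dataclass
class MislabelFlag:
    sample_a: str
    sample_b: str
    ibs: float
    rule: str       # SAME_STRAIN_LOW or CROSS_STRAIN_HIGH
    severity: float  # distance from the violated threshold


def match_and_flag(matrix: IBSMatrix, labels: dict[str, tuple[str, str]],
                   proxy_queries: list[str] | None = None,
                   proxy_threshold: float = 0.995,
                   same_low: float = 0.97,
                   cross_high: float = 0.98
                   ) -> tuple[list[ProxyMatch], list[MislabelFlag]]:
    """Progenitor-proxy matching and mislabel flagging on one IBS matrix.

    ``labels`` maps sample id -> (strain, substrain) and must cover every
    sample.  For each query strain the best-IBS sample outside the query's
    own substrain(s) is reported against ``proxy_threshold``.  Mislabels:
    same-substrain pairs with IBS < ``same_low``, different-strain pairs
    with IBS >= ``cross_high``; each flag cites exactly one rule, sorted by
    distance from the violated threshold (most severe first).
    """
    ids = matrix.sample_ids
    missing = [s for s in ids if s not in labels]
    if missing:
        raise KeyError(f"labels missing for samples: {missing}")

    proxies: list[ProxyMatch] = []
    for query in proxy_queries or []:
        own = [s for s in ids if labels[s][0] == query]
        if not own:
            raise KeyError(f"query strain {query!r} absent from labels")
        own_subs = {labels[s][1] for s in own}
        best: tuple[float, str] | None = None
        for cand in ids:
            if labels[cand][1] in own_subs:
                continue
            score = max(matrix.get(q, cand) for q in own)
            if best is None or score > best[0]:
                best = (score, cand)
        if best is None:
            raise ValueError(f"no candidates outside substrain of {query!r}")
        proxies.append(ProxyMatch(query, best[1], best[0],
                                  best[0] >= proxy_threshold))

    flags: list[MislabelFlag] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ibs = matrix.get(a, b)
            if labels[a][1] == labels[b][1] and ibs < same_low:
                flags.append(MislabelFlag(a, b, ibs, SAME_STRAIN_LOW,
                                          same_low - ibs))
            elif labels[a][0] != labels[b][0] and ibs >= cross_high:
                flags.append(MislabelFlag(a, b, ibs, CROSS_STRAIN_HIGH,
                                          ibs - cross_high))
    flags.sort(key=lambda f: -f.severity)
    return proxies, flags


# ---------------------------------------------------------------------------
# variant sharing across strains
# ---------------------------------------------------------------------------

def sharing_summary(panel: GenotypePanel, groups: dict[str, list[str]]) -> dict:
    """Per-strain variant carriage: totals, private counts, shared-by-all.

    A strain carries a site iff any of its samples has a non-reference call
    there.  Returns per-strain totals and unique (carried by exactly one
    strain) counts, the shared-by-all count, and a per-chromosome table of
    site counts by the number of carrying strains.
    """
    if not groups:
        raise ValueError("need at least one strain group")
    for strain, members in groups.items():
        if not members:
            raise ValueError(f"group {strain!r} is empty")
    cols = {strain: panel.sample_index(members)
            for strain, members in groups.items()}
    strains = list(groups)
    totals = {s: 0 for s in strains}
    unique = {s: 0 for s in strains}
    shared_all = 0
    chrom_rows = []
    for chrom, blk in panel.blocks.items():
        cls = classify_matrix(blk.a1, blk.a2)
        nonref = (cls == 1) | (cls == 2)  # GT_HET | GT_HOM_ALT
        carrier = np.stack([nonref[:, cols[s]].any(axis=1) for s in strains])
        n_carrying = carrier.sum(axis=0)
        for si, s in enumerate(strains):
            totals[s] += int(carrier[si].sum())
            unique[s] += int((carrier[si] & (n_carrying == 1)).sum())
        shared_all += int((n_carrying == len(strains)).sum())
        counts = {k: int((n_carrying == k).sum())
                  for k in range(1, len(strains) + 1)}
        chrom_rows.append({"chrom": chrom, **counts})
    table = pd.DataFrame(chrom_rows).set_index("chrom") if chrom_rows \
        else pd.DataFrame()
    return {"totals": totals, "unique": unique, "shared_by_all": shared_all,
            "per_chromosome": table}
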