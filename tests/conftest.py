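"""Shared fixtures: small hand-built and generated panels."""

import numpy as np
import pytest

from refpanelqc.genotype_io import ChromBlock, GenotypePanel, SampleInfo


def build_panel(genotypes, positions=None, quals=None, depths=None,
                samples=None, chrom="chr1", ref_flags=None):
    """Construct a panel from a (n_sites, n_samples) list of genotype codes.

    Codes: 0 hom-ref, 1 het (0/1), 2 hom-alt (1/1), 3 missing.
    """
    g = np.asarray(genotypes, dtype=int)
    n_sites, n_samples = g.shape
    a1 = np.zeros_like(g, dtype=np.int16)
    a2 = np.zeros_like(g, dtype=np.int16)
    a1[g == 1] = 0
    a2[g == 1] = 1
    a1[g == 2] = 1
    a2[g == 2] = 1
    a1[g == 3] = -1
    a2[g == 3] = -1
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if quals is None:
        quals = np.full(n_sites, 60.0)
    if depths is None:
        depths = np.full((n_sites, n_samples), 30, dtype=np.int32)
    if samples is None:
        ref_flags = ref_flags or [False] * n_samples
        samples = [SampleInfo(f"S{i}", f"S{i}", f"S{i}", ref_flags[i])
                   for i in range(n_samples)]
    blk = ChromBlock(positions=np.asarray(positions, dtype=np.int64),
                     ref=["A"] * n_sites, alts=[("T",)] * n_sites,
                     qual=np.asarray(quals, dtype=float),
                     a1=a1, a2=a2, depth=np.asarray(depths, dtype=np.int32))
    return GenotypePanel(samples=samples, blocks={chrom: blk})


@pytest.fixture
def tiny_panel():
    """3 samples x 4 sites with a mix of genotype classes."""
    return build_panel([
        [0, 0, 0],
        [1, 3, 2],
        [2, 2, 2],
        [0, 1, 0],
    ])
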