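"""Published summary statistics used as arithmetic inputs.

Contiguity statistics of the public rat reference assemblies (Rnor_6.0 and
mRatBN7.2, as distributed by UCSC/NCBI), shared-variant counts from joint
calls of an inbred rat panel against each assembly, and variant totals for
the laboratory-rat populations.  These are inputs to fold-ratio and
consistency computations, not outputs of this package.
"""

# Contiguity of the two rat reference assemblies (bp / counts)
RNOR6_CONTIG_N50 = 100_511
MRATBN7_CONTIG_N50 = 29_198_295
RNOR6_N_CONTIGS = 75_695
MRATBN7_N_CONTIGS = 757
RNOR6_N_SCAFFOLDS = 953
MRATBN7_N_SCAFFOLDS = 176

# Variants shared by all 36 inbred samples (incl. the reference strain) when
# jointly called against each assembly — the base-level error proxy
SHARED_VARIANTS_RNOR6 = 1_310_902
SHARED_VARIANTS_MRATBN7 = 143_254

# Shared anomalous sites on mRatBN7.2 (non-reference in most of 163 samples)
SHARED_ANOMALY_SNPS = 33_550
SHARED_ANOMALY_INDELS = 95_636

# Joint-call variant decompositions (SNPs, indels, mixed) per population
VARIANT_DECOMPOSITION = {
    "RatCollection": (12_661_110, 7_313_702, 12_461),
    "HS progenitors": (9_947_112, 6_479_485, 11_705),
}
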