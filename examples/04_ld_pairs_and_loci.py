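"""Mine SNP-CNV linkage and build multi-marker CNV loci.

Simulates a block of deletion markers sharing one CNV event (perfect
within-block LD), plus a SNP in LD with that event, then (i) pairs the
SNP with nearby CNV markers under the distance / r^2 / annotation
filters and (ii) chains the block into a gene-spanning CNV locus.
"""

import numpy as np

from duocall import call_dataset, simulate_dataset
from duocall.evaluation import cnv_locus_builder, ld_pair_candidates
from duocall.types import AnnotationIntervals

# 3 deletion markers, 1 kb apart, sharing a single CNV event
intens, manifest, truth, _ = simulate_dataset(
    3, 200, mixture={"deletion": 1.0}, block_size=3, spacing=1000, noise_sd=0.05, seed=5
)
_, cnv, _ = call_dataset(intens)

# a synthetic trait-associated SNP whose B dosage tags the block-1 event
snp_dosage = (truth.copy_number[0] < 2).astype(float)

annotations = AnnotationIntervals(
    kind=np.array(["gene"], dtype=object),
    chrom=np.array(["1"], dtype=object),
    start=np.array([1500]),
    end=np.array([2500]),
    name=np.array(["GENE_X"], dtype=object),
)

pairs = ld_pair_candidates(
    {"mk00001": snp_dosage}, cnv, manifest, annotations  # SNP = marker mk00001's position
)
print("SNP-CNV candidate pairs (distance <= 50 kb, r2 > 0.7, near gene/TF):")
print(pairs[["snp_id", "cnv_id", "snp_pos", "cnv_pos", "best_r2"]].to_string(index=False))

loci = cnv_locus_builder(cnv, manifest, annotations)
print("\nCNV loci (>=3 chained markers <=5 kb apart, all pairwise r2 > 0.7):")
print(loci[["chrom", "start", "end", "n_markers", "mean_r2", "genes"]].to_string(index=False))
# Each locus is a run of probes reporting the same copy-number event over
# a gene; mean_r2 summarizes how consistently its members co-segregate.
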