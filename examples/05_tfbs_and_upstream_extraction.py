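"""TFBS scanning and upstream-sequence extraction for motif discovery.

A gapped PSSM (TAA-N7-TTAAC, spacer columns unscored) scans the direct
strand upstream of every gene; sites ending 22-25 nt upstream of a TSS
overlap the -35 element and are direct-regulation candidates.  Strongly
expressed mRNA TSS without a sigma assignment yield 40-nt upstream windows
for external de novo motif discovery (e.g. MEME).
"""

import numpy as np

from tssmap.synthetic_data import SynthConfig, plant_features, simulate_read_starts
from tssmap.tfbs_analysis import (
    GappedMotifConfig,
    correlate_tfbs_with_tss,
    extract_unassigned_upstream,
    scan_gapped_motif,
)
from tssmap.tss_calling import call_and_merge
from tssmap.tss_classification import build_mtus, classify_tss

config = SynthConfig(n_replicons=1, n_genes=60, n_mtss=12, n_lmtss=4, n_pmtss=5,
                     n_setss=8, n_astss=8, n_stss=5, promoter_fraction=0.3,
                     n_tfbs=6, seed=42)
genome, truth = plant_features(config)
reads = simulate_read_starts(genome, truth, config)
contigs, _, _ = call_and_merge(reads)
classified = classify_tss(contigs, build_mtus(truth.genes, genome=genome), genome)

rng = np.random.default_rng(0)
train = ["TAA" + "".join(rng.choice(list("ACGT"), 7)) + "TTAAC" for _ in range(5)]
motif = GappedMotifConfig(training_sites=train)
hits = scan_gapped_motif(genome, truth.genes, motif)
print(f"TFBS hits (positive score, P<=1e-4, outside ORFs): {len(hits)}; "
      f"planted: {len(truth.tfbs)}")

sites, counts = correlate_tfbs_with_tss(truth.tfbs, classified)
print("positional categories of planted sites:", counts)
# '-35-overlap' sites sit 22-25 nt upstream of a TSS: the bound factor
# would contact the promoter's -35 region, suggesting direct regulation.

seqs = extract_unassigned_upstream(classified, promoter_tss_ids=set(), genome=genome,
                                   min_coverage=30)
print(f"upstream windows for de novo motif discovery: {len(seqs)} x 40 nt")
print("first window:", seqs[0][0], seqs[0][1])
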