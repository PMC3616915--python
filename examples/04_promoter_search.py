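"""Sigma-factor promoter prediction: two-phase profile search + string search.

Five imperfect seed promoters bootstrap the -35/-10 PSSMs; Phase 1 admits
only candidates with element P-values <= 0.005 near a TSS (5-12 nt gap) and
feeds them back into the matrices; Phase 2 rescans at P <= 0.02.  An ECF
sigma factor known only by consensus is searched by string matching with at
most one mismatch.
"""

from collections import Counter

from tssmap.pipeline import anchors_from_classified
from tssmap.promoter_discovery import (
    PromoterSeed,
    SigmaModel,
    genome_background,
    run_two_phase,
    string_promoter_search,
)
from tssmap.synthetic_data import SynthConfig, plant_features, simulate_read_starts
from tssmap.tss_calling import call_and_merge
from tssmap.tss_classification import build_mtus, classify_tss

config = SynthConfig(n_replicons=1, n_genes=60, n_mtss=12, n_lmtss=4, n_pmtss=5,
                     n_setss=8, n_astss=8, n_stss=5, promoter_fraction=0.7, seed=42)
genome, truth = plant_features(config)
reads = simulate_read_starts(genome, truth, config)
contigs, _, _ = call_and_merge(reads)
classified = classify_tss(contigs, build_mtus(truth.genes, genome=genome), genome)
anchors = anchors_from_classified(classified)

seeds = [PromoterSeed(sigma="RpoD", seq35=a, spacer_seq="G" * 17, seq10=b)
         for a, b in [("ATGACA", "TATAAC"), ("TTGACC", "TATACT"), ("TTGATA", "TACAAT"),
                      ("CTGACA", "TATGAT"), ("TTCACA", "CATAAT")]]
sigma = SigmaModel(name="RpoD", w35=6, w10=6)
res = run_two_phase(seeds, sigma, genome, anchors, genome_background(genome))

print(f"planted promoters: {len(truth.promoters)}")
print("hit labels:", dict(Counter(h.label for h in res.phase2)))
found = {(h.replicon, h.strand, h.pos35, h.pos10) for h in res.phase2}
planted = {(p.replicon, p.strand, p.pos35, p.pos10)
           for p in truth.promoters.itertuples(index=False)}
print(f"planted promoters recovered: {len(found & planted)}/{len(planted)}")
h = res.phase2[0]
print(f"example hit: -35 {h.seq35} (P={h.p35:.2e}) .. spacer {h.spacer} .. "
      f"-10 {h.seq10} (P={h.p10:.2e}), {h.gap_to_tss} nt upstream of {h.tss_id}")

ecf = SigmaModel(name="RpoE1", mode="string", consensus="GAAT-N18-GTCT",
                 w35=4, w10=4, spacer_min=17, spacer_max=19)
print(f"RpoE1 string search ({ecf.consensus}, <=1 mismatch):",
      len(string_promoter_search(ecf, genome, anchors)), "hits")
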