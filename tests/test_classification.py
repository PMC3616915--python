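"""MTU construction and the six-class TSS hierarchy.

The rule oracle below evaluates each class definition naively per TSS and
then applies the documented precedence; it shares no code with the
production classifier.
"""

import numpy as np
import pytest

from tssmap.genome_io import Genome, GeneModel
from tssmap.tss_calling import TSSContig
from tssmap.tss_classification import (
    MTUConfig,
    build_mtus,
    classify_tss,
    merge_rna_features,
    summarize_classification,
)


def contig(pos, end, strand="+", rep="chr", count=30, id=None):
    return TSSContig(rep, strand, pos, end, count, id=id)


@pytest.fixture
def genome_one_gene():
    rng = np.random.default_rng(3)
    seq = list(rng.choice(list("ACGT"), size=3000))
    seq[999:1002] = "ATG"  # plus-strand start codon at 1000
    g = Genome({"chr": "".join(seq)})
    gene = GeneModel("g1", "chr", "+", 1000, 1500)
    return g, [gene]


# ---------------------------------------------------------------------------
# MTU arithmetic


def test_mtu_plus_strand_arithmetic():
    gene = GeneModel("g", "chr", "+", 1000, 1500)
    (m,) = build_mtus([gene])
    assert m.span == (986, 1520)
    assert m.promoter == (946, 985)
    assert m.m_window == (946, 999)


def test_mtu_minus_strand_mirrors():
    gene = GeneModel("g", "chr", "-", 1500, 1000)
    (m,) = build_mtus([gene])
    assert m.span == (980, 1514)
    assert m.promoter == (1515, 1554)
    assert m.m_window == (1501, 1554)


def test_mtu_truncated_at_replicon_start():
    gene = GeneModel("g", "chr", "+", 5, 304)
    genome = Genome({"chr": "A" * 1000})
    (m,) = build_mtus([gene], genome=genome)
    assert m.span == (1, 324)
    assert m.promoter is None  # entirely off the replicon
    assert m.truncated


# ---------------------------------------------------------------------------
# classification examples


def test_lmtss_at_atg_start(genome_one_gene):
    g, genes = genome_one_gene
    mtus = build_mtus(genes, genome=g)
    (c,) = classify_tss([contig(1000, 1090)], mtus, g)
    assert (c.tss_class, c.target_feature, c.utr5_len) == ("lmTSS", "g1", 0)


def test_mtss_contig_overlapping_window(genome_one_gene):
    g, genes = genome_one_gene
    mtus = build_mtus(genes, genome=g)
    (c,) = classify_tss([contig(960, 1050)], mtus, g)
    assert (c.tss_class, c.target_feature, c.utr5_len) == ("mTSS", "g1", 40)


def test_setss_inside_mtu(genome_one_gene):
    g, genes = genome_one_gene
    mtus = build_mtus(genes, genome=g)
    (c,) = classify_tss([contig(1200, 1290)], mtus, g)
    assert (c.tss_class, c.target_feature) == ("seTSS", "g1")


def test_astss_antisense_overlap(genome_one_gene):
    g, genes = genome_one_gene
    mtus = build_mtus(genes, genome=g)
    (c,) = classify_tss([contig(1290, 1200, strand="-")], mtus, g)
    assert (c.tss_class, c.target_feature) == ("asTSS", "g1")


def test_pm_vs_s_distance_threshold():
    rng = np.random.default_rng(4)
    seq = list(rng.choice(list("ACGT"), size=3000))
    g = Genome({"chr": "".join(seq)})
    mtus_far = build_mtus([GeneModel("g1", "chr", "+", 700, 1300)], genome=g)
    (c,) = classify_tss([contig(300, 400)], mtus_far, g)
    assert c.tss_class == "sTSS"  # start codon 400 nt downstream
    mtus_near = build_mtus([GeneModel("g1", "chr", "+", 550, 1150)], genome=g)
    (c,) = classify_tss([contig(300, 400)], mtus_near, g)
    assert (c.tss_class, c.target_feature) == ("pmTSS", "g1")  # 250 nt


def test_pm_boundary_at_exactly_300():
    g = Genome({"chr": "A" * 3000})
    mtus = build_mtus([GeneModel("g1", "chr", "+", 1000, 1600)], genome=g)
    (c300,) = classify_tss([contig(700, 790)], mtus, g)
    assert c300.tss_class == "pmTSS"
    (c301,) = classify_tss([contig(699, 789)], mtus, g)
    assert c301.tss_class == "sTSS"


def test_mtss_via_leader_contig():
    import pandas as pd

    g = Genome({"chr": "A" * 3000})
    mtus = build_mtus([GeneModel("g1", "chr", "+", 1000, 1600)], genome=g)
    # contig ends upstream of the promoter region (946..985), 400 nt from start
    t = contig(600, 690)
    leaders = pd.DataFrame(
        {"replicon": ["chr"], "strand": ["+"], "five_prime_pos": [590], "gene_id": ["g1"]}
    )
    (c,) = classify_tss([t], mtus, g, leaders)
    assert (c.tss_class, c.target_feature, c.utr5_len) == ("mTSS", "g1", 400)
    # without the leader the same geometry is sTSS
    (c2,) = classify_tss([t], mtus, g)
    assert c2.tss_class == "sTSS"


def test_tss_outside_genome_rejected():
    g = Genome({"chr": "A" * 100})
    with pytest.raises(ValueError, match="outside replicon"):
        classify_tss([contig(500, 590)], [], g)


# ---------------------------------------------------------------------------
# rule oracle


def oracle_classify(t: TSSContig, genes, genome, config=MTUConfig()):
    """Naive independent evaluation of all six definitions + precedence."""

    def updist(start, strand):
        return start - t.tss_pos if strand == "+" else t.tss_pos - start

    def interval(g):  # MTU span
        if g.strand == "+":
            return (g.start_codon_pos - config.utr5_len, g.stop_codon_pos + config.utr3_len)
        return (g.stop_codon_pos - config.utr3_len, g.start_codon_pos + config.utr5_len)

    def window(g):  # 54-nt m-window
        if g.strand == "+":
            return (g.start_codon_pos - config.m_window, g.start_codon_pos - 1)
        return (g.start_codon_pos + 1, g.start_codon_pos + config.m_window)

    def ov(a, b):
        return a[0] <= b[1] and b[0] <= a[1]

    clo, chi = min(t.tss_pos, t.end_pos), max(t.tss_pos, t.end_pos)
    same = [g for g in genes if g.replicon == t.replicon and g.strand == t.strand]
    anti = [g for g in genes if g.replicon == t.replicon and g.strand != t.strand]
    is_lm = any(
        g.start_codon_pos == t.tss_pos
        and genome.triplet_at(t.replicon, t.tss_pos, t.strand) == "ATG"
        for g in same
    )
    m_genes = [g for g in same if ov((clo, chi), window(g)) and updist(g.start_codon_pos, g.strand) > 0]
    is_se = any(interval(g)[0] <= t.tss_pos <= interval(g)[1] for g in same)
    is_as = any(ov((clo, chi), interval(g)) for g in anti)
    no_mtu = not any(ov((clo, chi), interval(g)) for g in genes if g.replicon == t.replicon)
    is_pm = no_mtu and any(0 < updist(g.start_codon_pos, g.strand) <= config.pm_max_dist for g in same)
    if is_lm:
        return "lmTSS"
    if m_genes:
        return "mTSS"
    if is_se:
        return "seTSS"
    if is_as:
        return "asTSS"
    if is_pm:
        return "pmTSS"
    return "sTSS"


def random_gene_genome(rng, n_genes=50, L=60_000):
    seq = list(rng.choice(list("ACGT"), size=L))
    genes = []
    pos = 200
    for i in range(n_genes):
        length = 3 * int(rng.integers(60, 250))
        if pos + length > L - 200:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            seq[pos - 1 : pos + 2] = "ATG"
            genes.append(GeneModel(f"g{i}", "chr", "+", pos, pos + length - 1))
        else:
            hi = pos + length - 1
            seq[hi - 3 : hi] = list("CAT")
            genes.append(GeneModel(f"g{i}", "chr", "-", hi, pos))
        pos += length + int(rng.integers(50, 600))
    return Genome({"chr": "".join(seq)}), genes


def test_classifier_matches_rule_oracle_on_random_tss():
    rng = np.random.default_rng(2024)
    genome, genes = random_gene_genome(rng)
    mtus = build_mtus(genes, genome=genome)
    L = genome.length("chr")
    tss = []
    for _ in range(1000):
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(rng.integers(200, L - 200))
        length = int(rng.integers(87, 109))
        end = pos + length - 1 if strand == "+" else pos - length + 1
        tss.append(contig(pos, end, strand))
    classified = classify_tss(tss, mtus, genome)
    for c in classified:
        assert c.tss_class == oracle_classify(c.tss, genes, genome)


def test_classification_partition_and_lm_triplet(small_world, small_config):
    from tssmap.tss_calling import call_and_merge

    genome, truth, reads = small_world
    contigs, _, _ = call_and_merge(reads)
    mtus = build_mtus(truth.genes, genome=genome)
    classified = classify_tss(contigs, mtus, genome)
    assert len(classified) == len(contigs)
    for c in classified:
        if c.tss_class == "lmTSS":
            assert genome.triplet_at(c.tss.replicon, c.tss.tss_pos, c.tss.strand) == "ATG"


def test_classification_strand_symmetry(small_world):
    from conftest import mirror_genes, mirror_genome, mirror_reads
    from tssmap.tss_calling import call_and_merge

    genome, truth, reads = small_world
    mg = mirror_genome(genome)
    mreads = mirror_reads(reads, genome)
    mgenes = mirror_genes(truth.genes, genome)
    fwd, _, _ = call_and_merge(reads)
    rev, _, _ = call_and_merge(mreads)
    cf = classify_tss(fwd, build_mtus(truth.genes, genome=genome), genome)
    cr = classify_tss(rev, build_mtus(mgenes, genome=mg), mg)
    L = genome.length("repA")
    key_f = sorted((c.tss.strand, c.tss.tss_pos, c.tss_class) for c in cf)
    key_r = sorted(
        ({"+": "-", "-": "+"}[c.tss.strand], L - c.tss.tss_pos + 1, c.tss_class) for c in cr
    )
    assert key_f == key_r


# ---------------------------------------------------------------------------
# sRNA/asRNA features and summary


def test_astss_merge_into_single_asrna(genome_one_gene):
    g, genes = genome_one_gene
    mtus = build_mtus(genes, genome=g)
    cls = classify_tss(
        [contig(1300, 1210, "-", id="t1"), contig(1290, 1200, "-", id="t2")], mtus, g
    )
    feats = merge_rna_features(cls, genes)
    assert len(feats) == 1
    f = feats[0]
    assert f.kind == "asRNA" and sorted(f.member_tss) == ["t1", "t2"]
    assert f.target == "g1" and f.overlap_region == "CDS"


def test_asrna_3utr_overlap_region(genome_one_gene):
    g, genes = genome_one_gene
    mtus = build_mtus(genes, genome=g)
    # antisense contig entirely within [stop+1, stop+20]
    cls = classify_tss([contig(1515, 1505, "-")], mtus, g)
    assert cls[0].tss_class == "asTSS"
    feats = merge_rna_features(cls, genes)
    assert feats[0].overlap_region == "3'-UTR"


def test_non_overlapping_stss_stay_separate():
    g = Genome({"chr": "A" * 5000})
    cls = classify_tss([contig(1000, 1090, id="a"), contig(1140, 1230, id="b")], [], g)
    assert all(c.tss_class == "sTSS" for c in cls)
    feats = merge_rna_features(cls, [])
    assert [f.kind for f in feats] == ["sRNA", "sRNA"]


def test_summary_histogram_and_composition(genome_one_gene):
    g, genes = genome_one_gene
    mtus = build_mtus(genes, genome=g)
    cls = classify_tss([contig(960, 1050), contig(930, 1020)], mtus, g)
    feats = merge_rna_features(cls, genes)
    s = summarize_classification(cls, feats, genes, g)
    assert s["class_counts"]["mTSS"] == 2
    assert s["gene_tss_histogram"] == {"1": 0, "2": 1, "3": 0, "4": 0, ">4": 0}
    assert s["utr5_mean"] == pytest.approx((40 + 70) / 2)
    comp = s["initiation_composition"]["+1"]
    assert sum(comp.values()) == 2


def test_summary_gene_histogram_counts():
    # genes with [1,1,2,5] TSS -> {1:2, 2:1, >4:1}
    g = Genome({"chr": "A" * 20000})
    genes = [GeneModel(f"g{i}", "chr", "+", 2000 * (i + 1), 2000 * (i + 1) + 300) for i in range(4)]
    mtus = build_mtus(genes, genome=g)
    tss = []
    for i, n in enumerate([1, 1, 2, 5]):
        start = genes[i].start_codon_pos
        for k in range(n):
            tss.append(contig(start - 20 - 10 * k, start - 20 - 10 * k + 90))
    cls = classify_tss(tss, mtus, g)
    assert all(c.tss_class == "mTSS" for c in cls)
    s = summarize_classification(cls, [], genes, g)
    assert s["gene_tss_histogram"] == {"1": 2, "2": 1, "3": 0, "4": 0, ">4": 1}


def test_utr5_mean_on_constructed_pair():
    g = Genome({"chr": "A" * 5000})
    genes = [GeneModel("g1", "chr", "+", 1000, 1300), GeneModel("g2", "chr", "+", 3000, 3300)]
    mtus = build_mtus(genes, genome=g)
    cls = classify_tss([contig(960, 1050), contig(2904, 2995)], mtus, g)
    assert [c.utr5_len for c in cls] == [40, 96]
    s = summarize_classification(cls, [], genes, g)
    assert s["utr5_mean"] == pytest.approx(68.0)
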