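"""PSSM construction, exact P-values, scanning, chaining, the two-phase
search, string search and cross-sigma overlap.

Oracles: full enumeration of all 4^w words for P-values; a character-level
sliding-window matcher for the string search.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tssmap.genome_io import Genome, revcomp
from tssmap.promoter_discovery import (
    PromoterSeed,
    SigmaModel,
    TSSAnchor,
    build_pssm,
    chain_and_associate,
    cross_sigma_overlap,
    extend_seed_exact,
    genome_background,
    parse_consensus,
    run_two_phase,
    scan_elements,
    string_promoter_search,
)


# ---------------------------------------------------------------------------
# PSSM arithmetic


def test_pssm_counts_pseudocount_hand_arithmetic():
    pssm = build_pssm(["AA", "AA"])
    # (2+1)/(2+4) = 0.5 for A at both positions; log-odds ln(0.5/0.25) = ln 2
    assert pssm.freqs[0, 0] == pytest.approx(0.5)
    assert pssm.logodds[0, 0] == pytest.approx(math.log(2))
    assert pssm.score("AA") == pytest.approx(2 * math.log(2))


def test_pssm_single_column_all_G():
    pssm = build_pssm(["G", "G", "G", "G"])
    assert pssm.freqs[0, 2] == pytest.approx(5 / 8)


def test_pssm_background_equal_frequencies_zero_logodds():
    pssm = build_pssm(["A", "C", "G", "T"], background=[0.25] * 4)
    # counts 1 each + pc 1 -> 0.25 everywhere -> log-odds 0
    assert np.allclose(pssm.logodds, 0.0)


def test_pssm_input_validation():
    with pytest.raises(ValueError, match="equal length"):
        build_pssm(["AA", "AAA"])
    with pytest.raises(ValueError, match="at least one"):
        build_pssm([])


# ---------------------------------------------------------------------------
# exact P-values


def enumerate_pvalue(pssm, threshold):
    """Brute force: sum background probabilities of all words scoring >= t."""
    total = 0.0
    for word in itertools.product("ACGT", repeat=pssm.width):
        s = 0.0
        prob = 1.0
        for j, b in enumerate(word):
            s += pssm.logodds[j, "ACGT".index(b)]
            prob *= pssm.background["ACGT".index(b)]
        if s >= threshold:
            total += prob
    return total


def test_width1_single_best_letter():
    pssm = build_pssm(["A", "A", "A", "A"])
    assert pssm.pvalue(pssm.max_score) == pytest.approx(0.25)


def test_pvalue_of_minus_infinity_is_one():
    pssm = build_pssm(["ACGT", "AAGT"])
    assert pssm.pvalue(float("-inf")) == pytest.approx(1.0)


@pytest.mark.parametrize("width", [2, 3, 5, 8])
def test_pvalue_matches_enumeration(width):
    rng = np.random.default_rng(width)
    seqs = ["".join(rng.choice(list("ACGT"), size=width)) for _ in range(6)]
    bg = rng.dirichlet([5, 5, 5, 5])
    pssm = build_pssm(seqs, background=bg)
    scores, _ = pssm.score_distribution()
    probe = list(scores[:: max(1, len(scores) // 25)]) + [pssm.max_score, 0.0]
    for t in probe:
        assert pssm.pvalue(t) == pytest.approx(enumerate_pvalue(pssm, t), abs=1e-10)


def test_pvalue_monotone_in_score():
    rng = np.random.default_rng(17)
    pssm = build_pssm(["".join(rng.choice(list("ACGT"), size=6)) for _ in range(8)])
    scores, _ = pssm.score_distribution()
    pvals = [pssm.pvalue(t) for t in scores]
    assert all(a >= b - 1e-15 for a, b in zip(pvals, pvals[1:]))


# ---------------------------------------------------------------------------
# scanning


def test_scan_counts_all_windows_at_pmax_one():
    genome = Genome({"c": "ACGTACGTACGTACGTACGT"})  # 20 nt, N-free
    pssm = build_pssm(["ACG", "ACG"])
    hits = scan_elements(genome, pssm, p_max=1.0)
    assert len(hits) == 2 * (20 - 3 + 1)


def test_scan_skips_windows_containing_N():
    genome = Genome({"c": "ACGTNACGT"})
    pssm = build_pssm(["ACGT", "ACGT"])
    hits = scan_elements(genome, pssm, p_max=1.0)
    # windows (1-based starts) 1..6 per strand; starts 2..5 contain the N
    assert sorted(hits["start"].unique()) == [1, 6]


def test_scan_finds_planted_word_both_strands():
    word = "TTGACA"
    genome = Genome({"c": "G" * 40 + word + "G" * 40})
    pssm = build_pssm([word, word])
    thr = pssm.score_for_pvalue(0.01)
    hits = scan_elements(genome, pssm, p_max=0.01)
    plus = hits[hits.strand == "+"]
    assert list(plus["start"]) == [41]
    # the same site read on the minus strand is TGTCAA: not a motif match;
    # plant the reverse complement elsewhere and expect a minus-strand hit
    genome2 = Genome({"c": "G" * 40 + revcomp(word) + "G" * 40})
    hits2 = scan_elements(genome2, pssm, p_max=0.01)
    minus = hits2[hits2.strand == "-"]
    assert list(minus["start"]) == [41]


def test_scan_scores_bitwise_consistent_with_pvalues():
    rng = np.random.default_rng(5)
    genome = Genome({"c": "".join(rng.choice(list("ACGT"), size=400))})
    pssm = build_pssm(["TTGACA", "TTGAGA", "CTGACA"], background=genome_background(genome))
    hits = scan_elements(genome, pssm, p_max=1.0)
    for row in hits.sample(30, random_state=0).itertuples(index=False):
        word = genome.fetch("c", row.start, row.start + 5, row.strand)
        assert pssm.score(word) == row.score  # bit-identical accumulation
        assert pssm.pvalue(row.score) == pytest.approx(row.pvalue, abs=1e-12)


# ---------------------------------------------------------------------------
# chaining and association


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["replicon", "strand", "start", "score", "pvalue"])


def sigma66():
    return SigmaModel(name="S", w35=6, w10=6, spacer_min=14, spacer_max=20)


def test_chain_spacer_and_gap_arithmetic():
    # -35 at 100-105, -10 at 120-125 (+): spacer 14; TSS 131 -> gap 5
    sig = sigma66()
    anchors = [TSSAnchor("t1", "c", "+", 131, "mTSS")]
    out = chain_and_associate(
        hits_frame([("c", "+", 100, 1.0, 0.001)]),
        hits_frame([("c", "+", 120, 1.0, 0.001)]),
        sig,
        anchors,
    )
    assert len(out) == 1
    h = out[0]
    assert (h.pos35, h.pos10, h.spacer, h.gap_to_tss, h.tss_id) == (100, 120, 14, 5, "t1")


def test_chain_gap_13_rejected():
    sig = sigma66()
    anchors = [TSSAnchor("t1", "c", "+", 139, "mTSS")]
    out = chain_and_associate(
        hits_frame([("c", "+", 100, 1.0, 0.001)]),
        hits_frame([("c", "+", 120, 1.0, 0.001)]),
        sig,
        anchors,
    )
    assert out == []


def test_chain_requires_collinearity():
    sig = sigma66()
    anchors = [TSSAnchor("t1", "c", "+", 131, "mTSS")]
    # -35 downstream of -10: no chain
    out = chain_and_associate(
        hits_frame([("c", "+", 140, 1.0, 0.001)]),
        hits_frame([("c", "+", 120, 1.0, 0.001)]),
        sig,
        anchors,
    )
    assert out == []


def test_chain_minus_strand_mirrors():
    sig = sigma66()
    # minus strand: -10 leftmost 200, ends (txn) at 200; TSS at 194 -> gap 5
    anchors = [TSSAnchor("t1", "c", "-", 194, "mTSS")]
    out = chain_and_associate(
        hits_frame([("c", "-", 220, 1.0, 0.001)]),
        hits_frame([("c", "-", 200, 1.0, 0.001)]),
        sig,
        anchors,
    )
    assert len(out) == 1
    assert (out[0].spacer, out[0].gap_to_tss) == (14, 5)


# ---------------------------------------------------------------------------
# seed extension


def test_extend_seed_exact_finds_second_occurrence():
    rng = np.random.default_rng(8)
    bg = "".join(rng.choice(list("AC"), size=400))
    s35, s10 = "TTGACA", "TATGAT"
    # occurrence: -35 at 101, spacer 17, -10 at 124 (ends 129), TSS at 138 (gap 8)
    seq = bg[:100] + s35 + bg[100:117] + s10 + bg[117:]
    genome = Genome({"c": seq})
    sig = sigma66()
    anchors = [TSSAnchor("t1", "c", "+", 138, "mTSS")]
    seeds = [PromoterSeed(sigma="S", seq35=s35, spacer_seq="G" * 17, seq10=s10)]
    out = extend_seed_exact(seeds, genome, sig, anchors)
    added = [s for s in out if s.label == "extended_model"]
    assert len(added) == 1
    assert (added[0].pos35, added[0].pos10, added[0].tss_id) == (101, 124, "t1")


def test_extend_without_nearby_tss_adds_nothing():
    genome = Genome({"c": "A" * 100 + "TTGACA" + "C" * 17 + "TATGAT" + "A" * 100})
    sig = sigma66()
    seeds = [PromoterSeed(sigma="S", seq35="TTGACA", spacer_seq="G" * 17, seq10="TATGAT")]
    out = extend_seed_exact(seeds, genome, sig, [])
    assert out == seeds


def test_virtual_seed_with_no_occurrence_leaves_set_unchanged():
    genome = Genome({"c": "A" * 300})
    sig = sigma66()
    seeds = [PromoterSeed(sigma="S", seq35="TTGACA", spacer_seq="G" * 17, seq10="TATGAT",
                          label="virtual")]
    assert extend_seed_exact(seeds, genome, sig, [TSSAnchor("t", "c", "+", 150, "mTSS")]) == seeds


# ---------------------------------------------------------------------------
# two-phase search


def planted_promoter_genome(n_tss=10, seed=0, gc=0.6):
    """A toy replicon with consensus promoters planted 5-12 nt before TSS."""
    rng = np.random.default_rng(seed)
    L = 20_000
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list(rng.choice(list("ACGT"), size=L, p=p))
    anchors, truth = [], []
    cons35, cons10 = "TTGACA", "TATAAT"
    for k in range(n_tss):
        t = 1000 + k * 1800
        gap = 5 + int(rng.integers(0, 8))
        spacer = int(rng.integers(15, 19))
        p10 = t - gap - 6
        p35 = p10 - spacer - 6
        seq[p35 - 1 : p35 + 5] = cons35
        seq[p10 - 1 : p10 + 5] = cons10
        anchors.append(TSSAnchor(f"t{k}", "c", "+", t, "mTSS"))
        truth.append((p35, p10))
    return Genome({"c": "".join(seq)}), anchors, truth


def seed_variants():
    return [
        PromoterSeed(sigma="S", seq35=s35, spacer_seq="G" * 17, seq10=s10)
        for s35, s10 in [
            ("ATGACA", "TATAAC"),
            ("TTGACC", "TATACT"),
            ("TTGATA", "TACAAT"),
            ("CTGACA", "TATGAT"),
            ("TTCACA", "CATAAT"),
        ]
    ]


def test_two_phase_recovers_planted_consensus_as_new_initial():
    genome, anchors, truth = planted_promoter_genome()
    sig = sigma66()
    res = run_two_phase(seed_variants(), sig, genome, anchors, genome_background(genome))
    got = {(h.pos35, h.pos10) for h in res.phase1 if h.label == "new_initial"}
    assert set(truth) <= got
    assert {(h.pos35, h.pos10) for h in res.phase1} <= {(h.pos35, h.pos10) for h in res.phase2}


def test_two_phase_no_matches_is_fixed_point():
    genome = Genome({"c": "A" * 5000})
    sig = sigma66()
    res = run_two_phase(seed_variants(), sig, genome, [], genome_background(genome))
    assert res.phase1 == [] and res.phase2 == []
    labels = [s.label for s in res.seeds_final]
    assert labels == ["model"] * 5  # input seeds preserved, nothing added


def test_two_phase_needs_two_seeds():
    genome = Genome({"c": "A" * 5000})
    with pytest.raises(ValueError, match="at least 2"):
        run_two_phase(seed_variants()[:1], sigma66(), genome, [])


def test_phase1_drops_setss_exclusive_candidates():
    genome, anchors, truth = planted_promoter_genome(n_tss=6)
    # mark half of the anchors as seTSS-only associations
    se = [
        TSSAnchor(a.id, a.replicon, a.strand, a.pos, "seTSS") if i % 2 == 0 else a
        for i, a in enumerate(anchors)
    ]
    sig = sigma66()
    res = run_two_phase(seed_variants(), sig, genome, se, genome_background(genome))
    p1 = {(h.pos35, h.pos10) for h in res.phase1}
    p2 = {(h.pos35, h.pos10) for h in res.phase2}
    dropped = {truth[i] for i in range(6) if i % 2 == 0}
    assert not (dropped & p1)  # excluded from Phase 1
    assert dropped <= p2  # eligible again in Phase 2
    assert (sum(1 for h in res.phase2 if h.label == "second_search") >= 3)


def test_two_phase_recovers_pssm_sampled_plants():
    # plants sampled from a tight PSSM at >= 80% of maximal log-odds score
    rng = np.random.default_rng(42)
    from tssmap.synthetic_data import _sample_motif, _tight_freqs

    L = 20_000
    seq = list(rng.choice(list("ACGT"), size=L, p=[0.2, 0.3, 0.3, 0.2]))
    f35, f10 = _tight_freqs("TTGACA"), _tight_freqs("TATAAT")
    anchors, truth = [], []
    for k in range(10):
        t = 1000 + k * 1800
        gap = 5 + int(rng.integers(0, 8))
        spacer = int(rng.integers(15, 19))
        p10 = t - gap - 6
        p35 = p10 - spacer - 6
        seq[p35 - 1 : p35 + 5] = _sample_motif(rng, f35, 0.8)
        seq[p10 - 1 : p10 + 5] = _sample_motif(rng, f10, 0.8)
        anchors.append(TSSAnchor(f"t{k}", "c", "+", t, "mTSS"))
        truth.append((p35, p10))
    genome = Genome({"c": "".join(seq)})
    res = run_two_phase(seed_variants(), sigma66(), genome, anchors, genome_background(genome))
    got = {(h.pos35, h.pos10) for h in res.phase2}
    assert len(set(truth) & got) >= 9  # >= 90% recovery


# ---------------------------------------------------------------------------
# string search


def oracle_string_search(genome, pattern, spacer_range, max_mm, anchors, gap=(5, 12)):
    """Character-level sliding-window matcher, both strands."""
    b1, _, b2 = parse_consensus(pattern)
    results = set()
    for rep, seq in genome.replicons.items():
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            apos = sorted(
                (a.pos - 1) if strand == "+" else (L - a.pos) for a in anchors
                if a.replicon == rep and a.strand == strand
            )
            for spacer in range(spacer_range[0], spacer_range[1] + 1):
                w = len(b1) + spacer + len(b2)
                for i in range(L - w + 1):
                    mm = sum(x != y for x, y in zip(s[i : i + len(b1)], b1))
                    mm += sum(
                        x != y for x, y in zip(s[i + len(b1) + spacer : i + w], b2)
                    )
                    if mm > max_mm:
                        continue
                    e2 = i + w - 1
                    if any(e2 + gap[0] + 1 <= a <= e2 + gap[1] + 1 for a in apos):
                        if strand == "+":
                            results.add((rep, strand, i + 1, i + len(b1) + spacer + 1, spacer))
                        else:
                            results.add(
                                (rep, strand, L - (i + len(b1) - 1), L - e2, spacer)
                            )
    return results


def rpoe1():
    return SigmaModel(name="RpoE1", mode="string", consensus="GAAT-N18-GTCT",
                      w35=4, w10=4, spacer_min=17, spacer_max=19, max_mismatch=1)


def test_string_search_finds_planted_consensus():
    rng = np.random.default_rng(3)
    seq = list(rng.choice(list("AC"), size=2000))
    # GAAT + N18 + GTCT ending 8 nt upstream of a TSS at 1130
    p = 1096
    seq[p - 1 : p + 3] = "GAAT"
    seq[p + 21 : p + 25] = "GTCT"
    genome = Genome({"c": "".join(seq)})
    anchors = [TSSAnchor("t1", "c", "+", 1130, "mTSS")]
    hits = string_promoter_search(rpoe1(), genome, anchors)
    assert len(hits) == 1
    assert (hits[0].pos35, hits[0].pos10, hits[0].gap_to_tss) == (1096, 1118, 8)


def test_string_search_mismatch_boundary():
    rng = np.random.default_rng(3)
    seq = list(rng.choice(list("AC"), size=2000))
    p = 1096
    seq[p - 1 : p + 3] = "GACT"  # one mismatch in box1
    seq[p + 21 : p + 25] = "GTCT"
    genome = Genome({"c": "".join(seq)})
    anchors = [TSSAnchor("t1", "c", "+", 1130, "mTSS")]
    assert len(string_promoter_search(rpoe1(), genome, anchors)) == 1
    seq[p + 21 : p + 25] = "GTAT"  # second mismatch -> over the limit
    genome2 = Genome({"c": "".join(seq)})
    assert string_promoter_search(rpoe1(), genome2, anchors) == []


def test_string_search_spacer_outside_range_rejected():
    seq = ["A"] * 2000
    p = 1000
    seq[p - 1 : p + 3] = "GAAT"
    seq[p + 28 : p + 32] = "GTCT"  # spacer 25
    genome = Genome({"c": "".join(seq)})
    anchors = [TSSAnchor("t1", "c", "+", p + 40, "mTSS")]
    assert string_promoter_search(rpoe1(), genome, anchors) == []


@pytest.mark.parametrize("pattern,spacer", [("GAAT-N18-GTCT", (17, 19)),
                                            ("TGTCACA-N16-CGTC", (15, 17))])
def test_string_search_matches_sliding_oracle(pattern, spacer):
    rng = np.random.default_rng(abs(hash(pattern)) % 2**31)
    genome = Genome({"c": "".join(rng.choice(list("ACGT"), size=20_000))})
    anchors = [
        TSSAnchor(f"t{k}", "c", "+" if k % 2 else "-", int(pos), "mTSS")
        for k, pos in enumerate(rng.integers(100, 19_900, size=120))
    ]
    b1, k, b2 = parse_consensus(pattern)
    sig = SigmaModel(name="X", mode="string", consensus=pattern, w35=len(b1), w10=len(b2),
                     spacer_min=spacer[0], spacer_max=spacer[1], max_mismatch=1)
    hits = string_promoter_search(sig, genome, anchors)
    got = {(h.replicon, h.strand, h.pos35, h.pos10, h.spacer) for h in hits}
    assert got == oracle_string_search(genome, pattern, spacer, 1, anchors)


def test_parse_consensus_errors():
    with pytest.raises(ValueError, match="malformed"):
        parse_consensus("GAATGTCT")
    with pytest.raises(ValueError, match="malformed"):
        parse_consensus("GAAT-N1x-GTCT")


# ---------------------------------------------------------------------------
# cross-sigma overlap


def hit(sigma, tss_id):
    from tssmap.promoter_discovery import PromoterHit

    return PromoterHit(sigma=sigma, replicon="c", strand="+", pos35=10, pos10=30, w35=6,
                       w10=6, spacer=14, p35=0.001, p10=0.001, seq35="", seq10="",
                       tss_id=tss_id, gap_to_tss=6, label="model")


def test_cross_sigma_overlap_pairs():
    report = cross_sigma_overlap({"RpoD": [hit("RpoD", "t1")], "RpoH1": [hit("RpoH1", "t1")]})
    assert len(report) == 1
    assert report.loc[0, "sigmas"] == "RpoD,RpoH1"


def test_cross_sigma_disjoint_empty():
    report = cross_sigma_overlap({"A": [hit("A", "t1")], "B": [hit("B", "t2")]})
    assert report.empty


def test_cross_sigma_symmetric_in_input_order():
    a = cross_sigma_overlap({"A": [hit("A", "t1")], "B": [hit("B", "t1")]})
    b = cross_sigma_overlap({"B": [hit("B", "t1")], "A": [hit("A", "t1")]})
    pd.testing.assert_frame_equal(a, b)
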