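"""Distance/dN-dS statistics against independent oracles, plus forensics ops."""

import math
from itertools import permutations

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from neosexscan import divergence, gametolog, simdata
from neosexscan.divergence import (DndsEstimate, bootstrap_selection_screen,
                                   delta_dxy_outliers, detect_gap_spans,
                                   dnds_contrast, dxy_table, k80_distance,
                                   local_align_exon, ng86_dnds)

# --------------------------------------------------------------------------
# independent oracles (deliberately written from the definitions, not the
# package internals)
# --------------------------------------------------------------------------

def k80_oracle(a, b):
    """Recount P/Q and evaluate the closed form directly."""
    pur = set("AG")
    ts = sum(1 for x, y in zip(a, b) if x != y and (x in pur) == (y in pur))
    diff = sum(1 for x, y in zip(a, b) if x != y)
    P, Q = ts / len(a), (diff - ts) / len(a)
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon):
    return str(Seq(codon).translate())


def ng86_sites_oracle(codon):
    """Synonymous sites, mutations to stop codons disregarded per position."""
    s = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:] for b in "ACGT" if b != codon[pos]]
        alts = [c for c in alts if c not in STOPS]
        if alts:
            s += sum(_aa(c) == _aa(codon) for c in alts) / len(alts)
    return s


def ng86_diff_oracle(c1, c2):
    """Equal-weight average over stop-free shortest pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    usable = []
    for order in permutations(diff):
        cur, steps, ok = c1, [], True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                ok = False
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            usable.append(steps)
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if _aa(a) == _aa(b):
                sd += 1 / len(usable)
            else:
                nd += 1 / len(usable)
    return sd, nd


def random_pair(rng, n=300, sub_rate=0.05):
    a = rng.choice(list("ACGT"), size=n)
    b = a.copy()
    hit = rng.random(n) < sub_rate
    b[hit] = rng.choice(list("ACGT"), size=int(hit.sum()))
    return "".join(a), "".join(b)


class TestK80:
    def test_identical_sequences_have_zero_distance(self):
        d = k80_distance("ACGTACGT", "ACGTACGT")
        assert d.dxy == 0.0 and d.P == d.Q == 0.0

    def test_worked_example(self):
        # 100 sites, 2 transitions, 1 transversion
        a = "A" * 100
        b = "G" * 2 + "C" + "A" * 97
        d = k80_distance(a, b)
        assert d.dxy == pytest.approx(-0.5 * math.log(0.95) - 0.25 * math.log(0.98), abs=1e-15)

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = random_pair(rng)
            d = k80_distance(a, b)
            if d.dxy is not None:
                assert d.dxy == pytest.approx(k80_oracle(a, b), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = random_pair(rng)
            assert k80_distance(a, b).dxy == k80_distance(b, a).dxy

    def test_estimator_consistency_under_k80_process(self):
        # simulate directly from K80 transition probabilities at d = 0.05
        d, kappa = 0.05, 2.0
        beta = 1.0 / (kappa + 2.0)
        alpha = kappa * beta
        t = d  # rate normalized: d = (alpha + 2 beta) * t with alpha+2beta=1
        e4 = math.exp(-4 * beta * t)
        e2 = math.exp(-2 * (alpha + beta) * t)
        p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
        p_tv = 0.5 - 0.5 * e4  # total over both transversion targets
        rng = np.random.default_rng(3)
        n = 100_000
        a = rng.choice(list("ACGT"), size=n)
        u = rng.random(n)
        ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
        tv_map = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
        b = []
        for x, uu in zip(a, u):
            if uu < p_ts:
                b.append(ts_map[x])
            elif uu < p_ts + p_tv:
                b.append(tv_map[x][0 if uu < p_ts + p_tv / 2 else 1])
            else:
                b.append(x)
        est = k80_distance("".join(a), "".join(b)).dxy
        se = math.sqrt(d / n)  # rough scale of the sampling error
        assert abs(est - d) < 5 * se

    def test_saturated_pair_is_undefined(self):
        d = k80_distance("A" * 10, "G" * 10)
        assert d.dxy is None


class TestNG86:
    def test_identical_sequences(self):
        est = ng86_dnds("TTTAAA", "TTTAAA")
        assert est.dn == 0.0 and est.ds == 0.0 and est.dnds is None

    def test_single_nonsynonymous_difference(self):
        # Phe (TTT) -> Leu (TTA): one nonsynonymous difference
        from neosexscan._codon import CODON_INDEX, ng86_diff_tables
        sd, nd = ng86_diff_tables()
        i, j = CODON_INDEX["TTT"], CODON_INDEX["TTA"]
        assert (sd[i, j], nd[i, j]) == (0.0, 1.0)

    def test_internal_stop_is_an_error_naming_position(self):
        with pytest.raises(ValueError, match="codon index 1"):
            ng86_dnds("AAATAAAAA", "AAAAAAAAA")

    def test_terminal_stop_tolerated(self):
        est = ng86_dnds("AAATAA", "AAATGA")
        assert est.n_codons == 1

    def test_sites_and_diffs_match_enumeration_oracle(self):
        from neosexscan._codon import CODONS, ng86_diff_tables, ng86_site_table
        sites = ng86_site_table()
        for i, c in enumerate(CODONS):
            assert sites[i] == pytest.approx(ng86_sites_oracle(c), abs=1e-12)
        sd, nd = ng86_diff_tables()
        rng = np.random.default_rng(4)
        for _ in range(300):  # random sample; the full grid runs in acceptance
            i, j = rng.integers(0, 61, size=2)
            osd, ond = ng86_diff_oracle(CODONS[i], CODONS[j])
            assert sd[i, j] == pytest.approx(osd, abs=1e-12)
            assert nd[i, j] == pytest.approx(ond, abs=1e-12)


class TestDxyTable:
    def test_only_shared_gametologs_compared(self):
        aln = {"og1": {
            "g1|coastal|W": "ATGAAA", "g1|inland|W": "ATGAAA", "g1|coastal|Z": "ATGAAA",
            "g1|outgroup|A": "ATGAAA",
        }}
        sets = gametolog.sets_from_alignments(aln)
        recs = dxy_table(sets)
        assert [(r.og_id, r.linkage) for r in recs] == [("og1", "W")]

    def test_zero_divergence_simulation_gives_zero_dxy(self):
        cfg = simdata.SimConfig(seed=1, n_genes=4, n_codons=40,
                                branch_lengths={k: 0.0 for k in
                                                ("outgroup", "split", "autosomal", "z", "w")})
        aln, _, fn, _ = simdata.simulate_gametolog_alignments(cfg)
        recs = dxy_table(gametolog.sets_from_alignments(aln, fn))
        assert recs and all(r.dxy == 0.0 for r in recs)

    def test_boosted_nmt_w_divergence_detected_by_wilcoxon(self):
        from scipy.stats import mannwhitneyu
        cfg = simdata.SimConfig(seed=8, n_genes=200, n_codons=300, nmt_fraction=0.5,
                                w_nmt_boost=4.0)
        aln, _, fn, _ = simdata.simulate_gametolog_alignments(cfg)
        recs = dxy_table(gametolog.sets_from_alignments(aln, fn))
        w_nmt = [r.dxy for r in recs if r.linkage == "W" and r.is_nmt and r.dxy is not None]
        w_non = [r.dxy for r in recs if r.linkage == "W" and not r.is_nmt and r.dxy is not None]
        assert np.mean(w_nmt) > np.mean(w_non)
        p = mannwhitneyu(w_nmt, w_non, alternative="greater").pvalue
        assert p < 0.01


class TestDeltaDxy:
    def _dist(self, og, linkage, dxy, nmt=False):
        return divergence.PairwiseDistance(og, linkage, dxy, 100, 0.0, 0.0, is_nmt=nmt)

    def test_constant_deltas_rejected(self):
        recs = [self._dist(f"og{i}", lk, d) for i in range(5)
                for lk, d in (("Z", 0.01), ("W", 0.02))]
        with pytest.raises(ValueError, match="identical"):
            delta_dxy_outliers(recs)

    def test_constructed_outlier_flagged(self):
        rng = np.random.default_rng(5)
        recs = []
        for i in range(100):
            z = 0.001
            w = 0.002 + rng.normal(0, 0.0002)
            recs += [self._dist(f"og{i:03d}", "Z", z), self._dist(f"og{i:03d}", "W", w)]
        recs += [self._dist("og_out", "Z", 0.001), self._dist("og_out", "W", 0.02)]
        out = delta_dxy_outliers(recs)
        flagged = [r.og_id for r in out if r.is_outlier]
        assert "og_out" in flagged

    def test_boosted_subset_recovered_exactly(self):
        # 4 strongly boosted genes among 68: exactly those 4 are z > 1.96
        base = simdata.SimConfig(seed=12, n_genes=64, n_codons=500, nmt_fraction=0.0,
                                 w_nmt_boost=1.0)
        boosted = simdata.SimConfig(seed=13, n_genes=4, n_codons=500, nmt_fraction=1.0,
                                    w_nmt_boost=8.0)
        recs = []
        for tag, cfg in (("null", base), ("boost", boosted)):
            aln, _, fn, _ = simdata.simulate_gametolog_alignments(cfg)
            sets = gametolog.sets_from_alignments(aln, fn)
            for r in dxy_table(sets):
                recs.append(divergence.PairwiseDistance(f"{tag}_{r.og_id}", r.linkage,
                                                        r.dxy, r.n_sites, r.P, r.Q,
                                                        is_nmt=r.is_nmt))
        out = delta_dxy_outliers(recs)
        flagged = sorted(r.og_id for r in out if r.is_outlier)
        assert flagged == [f"boost_og_{i:05d}" for i in range(4)]


class TestDndsContrast:
    def _est(self, og, lineage, linkage, dnds):
        return DndsEstimate(og, lineage, linkage, 0.01, 0.01, dnds, 100)

    def test_equal_estimates_give_zero_unflagged_when_larger_exists(self):
        ests = [self._est("a", "coastal", "Z", 0.2), self._est("a", "inland", "Z", 0.2),
                self._est("b", "coastal", "Z", 0.9), self._est("b", "inland", "Z", 0.1)]
        out = {c.og_id: c for c in dnds_contrast(ests)}
        assert out["a"].value == 0.0 and not out["a"].is_outlier
        assert out["b"].value == pytest.approx(0.8) and out["b"].is_outlier

    def test_ceiling_rule_flags_exactly_two_of_200(self):
        rng = np.random.default_rng(6)
        ests = []
        for i in range(200):
            ests += [self._est(f"og{i:03d}", "coastal", "Z", float(rng.random())),
                     self._est(f"og{i:03d}", "inland", "Z", float(rng.random()))]
        out = dnds_contrast(ests)
        assert sum(c.is_outlier for c in out) == 2

    def test_sign_convention_coastal_elevated_positive(self):
        ests = [self._est("a", "coastal", "W", 0.9), self._est("a", "inland", "W", 0.2)]
        (c,) = dnds_contrast(ests)
        assert c.value > 0

    def test_undefined_side_skipped(self):
        ests = [self._est("a", "coastal", "Z", None), self._est("a", "inland", "Z", 0.2)]
        assert dnds_contrast(ests) == []


class TestBootstrapScreen:
    def test_identical_sequences_undefined(self):
        assert bootstrap_selection_screen("AAATTT" * 20, "AAATTT" * 20, n_boot=100, seed=0) is None

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        root = rng.integers(0, 61, 200).astype(np.int16)
        a = simdata._seq_str(simdata.evolve_codons(root, 0.1, 2.0, 1.0, np.random.default_rng(1)))
        b = simdata._seq_str(root)
        p1 = bootstrap_selection_screen(a, b, n_boot=300, seed=5)
        p2 = bootstrap_selection_screen(a, b, n_boot=300, seed=5)
        assert p1 == p2

    def test_power_under_strong_positive_selection(self):
        # omega = 5, branch length 0.3, 500 codons: reject in > half of genes
        rejected = 0
        n_genes = 40
        for g in range(n_genes):
            rng = np.random.default_rng(100 + g)
            root = rng.integers(0, 61, 500).astype(np.int16)
            a = simdata.evolve_codons(root, 0.3, 2.0, 5.0, rng)
            p = bootstrap_selection_screen(simdata._seq_str(a), simdata._seq_str(root),
                                           n_boot=300, seed=g)
            if p is not None and p < 0.05:
                rejected += 1
        assert rejected / n_genes > 0.5

    def test_n_boot_floor_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_selection_screen("AAA", "AAC", n_boot=10, seed=0)


class TestGapSpans:
    def test_known_exon_loss_fraction(self):
        aln = {"w_inland": "ATG" * 56 + "---" * 91, "z": "ATG" * 147}
        (span,) = detect_gap_spans(aln, og_id="og")
        assert span.length_codons == 91
        assert span.fraction_of_alignment == pytest.approx(273 / 441, abs=1e-12)

    def test_sixteen_codon_gap(self, exon_loss_alignment):
        aln, _ = exon_loss_alignment
        spans = detect_gap_spans(aln, min_len_codons=16)
        z_spans = [s for s in spans if "|Z" in s.sequence_id]
        assert sorted(s.length_codons for s in z_spans) == [16, 16]

    def test_no_gaps_gives_empty_list(self):
        assert detect_gap_spans({"a": "ATGATG"}) == []

    def test_min_len_filter_and_maximality(self):
        aln = {"a": "---" * 2 + "ATG" + "---" * 5}
        spans = detect_gap_spans(aln, min_len_codons=3)
        assert [(s.start_codon, s.length_codons) for s in spans] == [(3, 5)]

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            detect_gap_spans({"a": "ATGA"})


class TestLocalAlignment:
    def test_exact_substring_found_with_full_identity(self):
        rng = np.random.default_rng(8)
        scaffold = "".join(rng.choice(list("ACGT"), 2000))
        query = scaffold[100:373]
        hit = local_align_exon(query, scaffold)
        assert (hit.target_start, hit.target_end) == (100, 373)
        assert hit.identity == 1.0 and hit.strand == "+"

    def test_reverse_complement_found_on_minus_strand(self):
        from Bio.Seq import reverse_complement
        rng = np.random.default_rng(9)
        scaffold = "".join(rng.choice(list("ACGT"), 2000))
        query = reverse_complement(scaffold[100:373])
        hit = local_align_exon(query, scaffold)
        assert (hit.target_start, hit.target_end) == (100, 373)
        assert hit.strand == "-"

    def test_random_query_rarely_hits_at_default_threshold(self):
        misses = 0
        trials = 100
        for t in range(trials):
            rng = np.random.default_rng(1000 + t)
            scaffold = "".join(rng.choice(list("ACGT"), 10_000))
            query = "".join(rng.choice(list("ACGT"), 60))
            if local_align_exon(query, scaffold) is None:
                misses += 1
        assert misses / trials >= 0.95

    def test_empty_scaffold_and_short_query(self):
        assert local_align_exon("A" * 30, "") is None
        with pytest.raises(ValueError):
            local_align_exon("A" * 10, "ACGT" * 100)
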