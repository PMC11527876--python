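"""Between-lineage divergence statistics for Z/W gametologs.

* :func:`k80_distance` -- Kimura two-parameter distance between two aligned,
  gap-free sequences, d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q) with P and Q the
  observed transition and transversion proportions.  Used as the
  between-lineage divergence measure (Dxy) of each gametolog.
* :func:`delta_dxy_outliers` -- per-gene Dxy(W) - Dxy(Z) contrast, flagged
  against the pooled distribution at |z| > 1.96.
* :func:`ng86_dnds` -- Nei-Gojobori (1986) counting estimate of dN/dS with
  Jukes-Cantor correction, relative to an outgroup sequence.
* :func:`dnds_contrast` -- per-gene coastal-minus-inland dN/dS difference
  with the most extreme 1% flagged.
* :func:`bootstrap_selection_screen` -- codon-bootstrap one-sided test for
  dN > dS, a counting-based screen for positive selection.
* :func:`detect_gap_spans` / :func:`local_align_exon` -- exon-loss
  forensics: maximal gap runs in codon alignments and Smith-Waterman local
  search of an exon against a scaffold (both strands).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from ._codon import encode_codons, ng86_diff_tables, ng86_site_table
from .gametolog import GametologSet, delete_gap_sites

log = logging.getLogger(__name__)

OUTLIER_Z = 1.96


# ---------------------------------------------------------------------------
# K80 / Dxy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseDistance:
    og_id: str
    linkage: str
    dxy: float | None
    n_sites: int
    P: float  # transition proportion
    Q: float  # transversion proportion
    is_nmt: bool | None = None


_NT = {c: i for i, c in enumerate("ACGT")}
_TS_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k80_distance(seq_a: str, seq_b: str, og_id: str = "", linkage: str = "") -> PairwiseDistance:
    """Kimura (1980) two-parameter distance between gap-free aligned sequences.

    ``dxy`` is None (undefined) when the log arguments 1-2P-Q or 1-2Q are
    not positive, or when there are no overlapping sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    a = seq_a.upper()
    b = seq_b.upper()
    n = len(a)
    if n == 0:
        return PairwiseDistance(og_id, linkage, None, 0, 0.0, 0.0)
    ts = tv = 0
    for x, y in zip(a, b):
        if x == y:
            continue
        if x not in _NT or y not in _NT:
            raise ValueError(f"non-ACGT character in gap-free input: {x!r}/{y!r}")
        if (x, y) in _TS_PAIRS:
            ts += 1
        else:
            tv += 1
    P = ts / n
    Q = tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        log.warning("K80 distance undefined (P=%.4g, Q=%.4g) for %s/%s", P, Q, og_id, linkage)
        return PairwiseDistance(og_id, linkage, None, n, P, Q)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return PairwiseDistance(og_id, linkage, d, n, P, Q)


def dxy_table(gametolog_sets: list[GametologSet]) -> list[PairwiseDistance]:
    """Coastal-vs-inland K80 distance per (orthogroup, Z/W gametolog).

    Emits one record per orthogroup and linkage class where both lineages
    carry that gametolog; gaps/N columns are deleted pairwise first.  The
    two gametologs of one lineage are never compared with each other.
    """
    out = []
    for gset in gametolog_sets:
        nmt = any(rec.is_nmt for rec in gset.slots.values())
        for linkage in ("Z", "W"):
            c = gset.get("coastal", linkage)
            i = gset.get("inland", linkage)
            if c is None or i is None:
                log.info("%s: %s gametolog missing in one lineage; skipped", gset.og_id, linkage)
                continue
            a, b = delete_gap_sites(c.cds, i.cds)
            rec = k80_distance(a, b, og_id=gset.og_id, linkage=linkage)
            out.append(PairwiseDistance(rec.og_id, rec.linkage, rec.dxy, rec.n_sites,
                                        rec.P, rec.Q, is_nmt=nmt))
    return out


@dataclass(frozen=True)
class DeltaDxyRecord:
    og_id: str
    is_nmt: bool
    delta_dxy: float  # dxy_W - dxy_Z
    zscore: float
    is_outlier: bool


def delta_dxy_outliers(distances: list[PairwiseDistance],
                       z_cut: float = OUTLIER_Z) -> list[DeltaDxyRecord]:
    """Per-gene Dxy(W) - Dxy(Z), z-scored against the pooled distribution.

    Only orthogroups with a defined Dxy for both gametologs contribute; both
    function classes are pooled for the mean/sd.  |z| > ``z_cut`` flags an
    outlier.
    """
    by_og: dict = {}
    for rec in distances:
        if rec.dxy is None or rec.linkage not in ("Z", "W"):
            continue
        by_og.setdefault(rec.og_id, {})[rec.linkage] = rec
    pairs = {og: d for og, d in by_og.items() if "Z" in d and "W" in d}
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 orthogroups with both gametologs, got {len(pairs)}")
    ogs = sorted(pairs)
    deltas = np.array([pairs[og]["W"].dxy - pairs[og]["Z"].dxy for og in ogs])
    sd = deltas.std(ddof=1)
    if sd == 0:
        raise ValueError("all delta-Dxy values identical; z-scores undefined")
    z = (deltas - deltas.mean()) / sd
    return [DeltaDxyRecord(og_id=og, is_nmt=bool(pairs[og]["W"].is_nmt),
                           delta_dxy=float(d), zscore=float(zz),
                           is_outlier=bool(abs(zz) > z_cut))
            for og, d, zz in zip(ogs, deltas, z)]


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DndsEstimate:
    og_id: str
    lineage: str
    linkage: str
    dn: float | None
    ds: float | None
    dnds: float | None
    n_codons: int
    outgroup_id: str = ""


def _jc_rate(p: float) -> float | None:
    """Jukes-Cantor corrected rate d = -3/4 ln(1 - 4p/3); None if p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _ng86_arrays(seq: str, outgroup_seq: str, name: str = "sequence",
                 outgroup_name: str = "outgroup"):
    """Per-codon-column (S, N, Sd, Nd) contributions for a sequence pair."""
    if len(seq) != len(outgroup_seq):
        raise ValueError(f"aligned lengths differ: {len(seq)} vs {len(outgroup_seq)}")
    try:
        c1 = encode_codons(seq)
    except ValueError as e:
        raise ValueError(f"{name}: {e}") from None
    try:
        c2 = encode_codons(outgroup_seq)
    except ValueError as e:
        raise ValueError(f"{outgroup_name}: {e}") from None
    m = min(len(c1), len(c2))  # differ only via a trailing stop
    c1, c2 = c1[:m], c2[:m]
    s_tab = ng86_site_table()
    sd_tab, nd_tab = ng86_diff_tables()
    S = (s_tab[c1] + s_tab[c2]) / 2.0
    N = 3.0 - S
    Sd = sd_tab[c1, c2]
    Nd = nd_tab[c1, c2]
    return np.column_stack([S, N, Sd, Nd])


def _dnds_from_totals(S, N, Sd, Nd):
    ps = Sd / S if S > 0 else math.nan
    pn = Nd / N if N > 0 else math.nan
    ds = _jc_rate(ps) if math.isfinite(ps) else None
    dn = _jc_rate(pn) if math.isfinite(pn) else None
    dnds = (dn / ds) if (dn is not None and ds is not None and ds > 0) else None
    return dn, ds, dnds


def ng86_dnds(seq: str, outgroup_seq: str, og_id: str = "", lineage: str = "",
              linkage: str = "", outgroup_id: str = "") -> DndsEstimate:
    """Nei-Gojobori (1986) dN/dS of ``seq`` relative to ``outgroup_seq``.

    Inputs must be gap-free, in-frame and stop-free (a single terminal stop
    is tolerated).  Synonymous/nonsynonymous sites are counted per codon
    position with mutations to stop codons disregarded; differences are
    averaged over all shortest substitution pathways of equal weight, with
    pathways through stop codons excluded.  Proportions are Jukes-Cantor
    corrected; dnds is None when dS is zero or undefined.
    """
    cols = _ng86_arrays(seq, outgroup_seq,
                        name=f"sequence {og_id or '<query>'}",
                        outgroup_name=f"outgroup {outgroup_id or '<outgroup>'}")
    S, N, Sd, Nd = cols.sum(axis=0)
    dn, ds, dnds = _dnds_from_totals(S, N, Sd, Nd)
    return DndsEstimate(og_id=og_id, lineage=lineage, linkage=linkage,
                        dn=dn, ds=ds, dnds=dnds, n_codons=cols.shape[0],
                        outgroup_id=outgroup_id)


@dataclass(frozen=True)
class DndsContrast:
    og_id: str
    linkage: str
    value: float  # dnds_coastal - dnds_inland
    is_outlier: bool
    is_nmt: bool | None = None


def dnds_contrast(estimates: list[DndsEstimate],
                  outlier_quantile: float = 0.01) -> list[DndsContrast]:
    """Per-(orthogroup, linkage) coastal-minus-inland dN/dS difference.

    Positive values mean faster protein evolution in the coastal lineage.
    The ceil(quantile * n) pairs (at least one, when any exist) most extreme
    by |value| are flagged.  Pairs with an undefined estimate on either side
    are skipped with a log message.
    """
    by_key: dict = {}
    for est in estimates:
        if est.linkage not in ("Z", "W") or est.lineage not in ("coastal", "inland"):
            continue
        by_key.setdefault((est.og_id, est.linkage), {})[est.lineage] = est
    rows = []
    for (og, linkage), d in sorted(by_key.items()):
        if "coastal" not in d or "inland" not in d:
            continue
        c, i = d["coastal"], d["inland"]
        if c.dnds is None or i.dnds is None:
            log.info("%s/%s: undefined dN/dS on one side; contrast skipped", og, linkage)
            continue
        rows.append([og, linkage, c.dnds - i.dnds])
    if not rows:
        return []
    k = max(1, math.ceil(outlier_quantile * len(rows)))
    order = sorted(range(len(rows)), key=lambda r: (-abs(rows[r][2]), rows[r][0]))
    flagged = set(order[:k])
    return [DndsContrast(og_id=og, linkage=linkage, value=v, is_outlier=(r in flagged))
            for r, (og, linkage, v) in enumerate(rows)]


def bootstrap_selection_screen(seq: str, outgroup_seq: str, n_boot: int = 1000,
                               seed: int = 0) -> float | None:
    """Codon-bootstrap one-sided p-value for dN > dS.

    Codon columns are resampled with replacement ``n_boot`` times; the
    p-value is the fraction of replicates (with defined dN and dS) in which
    dN <= dS.  Returns None when the sequences are identical or when dN or
    dS is undefined in more than half of the replicates.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    cols = _ng86_arrays(seq, outgroup_seq)
    n = cols.shape[0]
    if n == 0 or (cols[:, 2].sum() + cols[:, 3].sum()) == 0:
        return None  # no differences: the contrast is empty
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    totals = counts @ cols  # (n_boot, 4): S, N, Sd, Nd
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = totals[:, 2] / totals[:, 0]
        pn = totals[:, 3] / totals[:, 1]
    defined = (ps < 0.75) & (pn < 0.75) & np.isfinite(ps) & np.isfinite(pn)
    if defined.sum() <= n_boot / 2:
        log.warning("dN or dS undefined in %d/%d bootstrap replicates; p undefined",
                    n_boot - int(defined.sum()), n_boot)
        return None
    ds = -0.75 * np.log(1.0 - 4.0 * ps[defined] / 3.0)
    dn = -0.75 * np.log(1.0 - 4.0 * pn[defined] / 3.0)
    return float((dn <= ds).mean())


# ---------------------------------------------------------------------------
# exon-loss forensics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapSpan:
    og_id: str
    sequence_id: str
    start_codon: int     # 0-based
    length_codons: int
    fraction_of_alignment: float


def detect_gap_spans(alignment: dict[str, str], min_len_codons: int = 1,
                     og_id: str = "") -> list[GapSpan]:
    """Maximal runs of fully gapped codons per sequence in a codon alignment.

    ``alignment`` maps sequence id -> aligned sequence; all sequences must
    share a length divisible by 3.  A codon column counts as gapped for a
    sequence when all three of its characters are '-' ('N' is missing data,
    not a deletion, and does not extend a span).  ``fraction_of_alignment``
    is the span length in nt over the aligned length in nt.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError(f"{og_id}: inconsistent aligned lengths {sorted(lengths)}")
    if not alignment:
        return []
    length = lengths.pop()
    if length % 3:
        raise ValueError(f"{og_id}: aligned length {length} not divisible by 3")
    n_codons = length // 3
    spans = []
    for sid in sorted(alignment):
        seq = alignment[sid]
        gap = [seq[3 * k: 3 * k + 3] == "---" for k in range(n_codons)]
        k = 0
        while k < n_codons:
            if gap[k]:
                start = k
                while k < n_codons and gap[k]:
                    k += 1
                run = k - start
                if run >= min_len_codons:
                    spans.append(GapSpan(og_id=og_id, sequence_id=sid, start_codon=start,
                                         length_codons=run,
                                         fraction_of_alignment=3.0 * run / length))
            else:
                k += 1
    return spans


@dataclass(frozen=True)
class LocalAlignmentHit:
    query_id: str
    target_scaffold: str
    target_start: int  # 0-based, half-open, forward strand
    target_end: int
    score: float
    identity: float
    strand: str = "+"


DEFAULT_SCORING = {"match": 2, "mismatch": -3, "gap_open": -5, "gap_extend": -2}
DEFAULT_SCORE_THRESHOLD = 50.0


def _best_local(aligner: PairwiseAligner, target: str, query: str):
    alns = aligner.align(target, query)
    if len(alns) == 0:
        return None
    return alns[0]


def local_align_exon(query_exon: str, scaffold_seq: str, scoring: dict | None = None,
                     score_threshold: float = DEFAULT_SCORE_THRESHOLD,
                     query_id: str = "", target_scaffold: str = "") -> LocalAlignmentHit | None:
    """Best Smith-Waterman local alignment of an exon against a scaffold.

    Searches both strands under affine-gap scoring; returns None for an
    empty scaffold or when the best score falls below ``score_threshold``.
    Coordinates are 0-based half-open on the forward strand of the scaffold.
    """
    if len(query_exon) < 20:
        raise ValueError(f"query too short ({len(query_exon)} nt; need >= 20)")
    if not scaffold_seq:
        return None
    sc = dict(DEFAULT_SCORING)
    sc.update(scoring or {})
    aligner = PairwiseAligner(mode="local", match_score=sc["match"],
                              mismatch_score=sc["mismatch"],
                              open_gap_score=sc["gap_open"],
                              extend_gap_score=sc["gap_extend"])
    target = scaffold_seq.upper()
    best = None
    for strand, q in (("+", query_exon.upper()), ("-", reverse_complement(query_exon.upper()))):
        aln = _best_local(aligner, target, q)
        if aln is None:
            continue
        if best is None or aln.score > best[1].score:
            best = (strand, aln)
    if best is None or best[1].score < score_threshold:
        return None
    strand, aln = best
    tblocks = aln.aligned[0]
    start, end = int(tblocks[0][0]), int(tblocks[-1][1])
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    return LocalAlignmentHit(query_id=query_id, target_scaffold=target_scaffold,
                             target_start=start, target_end=end, score=float(aln.score),
                             identity=float(identity), strand=strand)
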