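"""Shared codon machinery: the standard genetic code, codon neighbourhoods,
and precomputed Nei-Gojobori site/difference tables.

Everything here is derived once from the standard nuclear code (NCBI table 1)
and cached at module import.  All downstream users (the codon simulator and
the dN/dS estimator) index codons by their position in :data:`CODONS`.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUCS)}

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)

#: the 61 sense codons of the standard nuclear code, sorted lexicographically
CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in product(NUCS, repeat=3)) if c not in STOP_CODONS)
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61

#: amino acid encoded by each sense codon
AMINO = tuple(_table.forward_table[c] for c in CODONS)

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True when the nucleotide change a->b is a transition (A<->G, C<->T)."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def codon_neighbors(codon: str):
    """All single-nucleotide mutations of ``codon`` to *sense* codons.

    Returns a list of (neighbor_codon, transition?, nonsynonymous?) triples;
    mutations creating stop codons are not listed.
    """
    out = []
    aa = _table.forward_table[codon]
    for pos in range(3):
        for b in NUCS:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            out.append((mut, is_transition(codon[pos], b), _table.forward_table[mut] != aa))
    return out


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) site and difference tables
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def ng86_site_table() -> np.ndarray:
    """Per-codon synonymous site counts, shape (61,).

    Classic convention: at each codon position the synonymous fraction is
    taken over the mutations that do not create a stop codon, so synonymous
    plus nonsynonymous sites always total 3 per codon.
    """
    s = np.zeros(N_CODONS)
    for ci, codon in enumerate(CODONS):
        aa = _table.forward_table[codon]
        total = 0.0
        for pos in range(3):
            syn = 0
            considered = 0
            for b in NUCS:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if mut in STOP_CODONS:
                    continue
                considered += 1
                if _table.forward_table[mut] == aa:
                    syn += 1
            if considered:
                total += syn / considered
        s[ci] = total
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two
    sense codons over all shortest substitution pathways.

    Pathways passing through a stop codon are dropped; should every pathway
    be blocked (which cannot happen between sense codons of the standard
    code, but is guarded for), all pathways are used.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:  # pragma: no cover - unreachable for the standard code
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    w = 1.0 / len(usable)
    for steps in usable:
        for a, b in steps:
            if _table.forward_table[a] == _table.forward_table[b]:
                sd += w
            else:
                nd += w
    return sd, nd


@lru_cache(maxsize=1)
def ng86_diff_tables() -> tuple[np.ndarray, np.ndarray]:
    """(sd, nd) pathway-averaged difference counts for all 61x61 codon pairs."""
    sd = np.zeros((N_CODONS, N_CODONS))
    nd = np.zeros((N_CODONS, N_CODONS))
    for i, c1 in enumerate(CODONS):
        for j, c2 in enumerate(CODONS):
            if i < j:
                continue
            s, n = _pathway_counts(c1, c2)
            sd[i, j] = sd[j, i] = s
            nd[i, j] = nd[j, i] = n
    return sd, nd


def encode_codons(seq: str) -> np.ndarray:
    """Translate an ungapped in-frame nucleotide string to codon indices.

    Raises ``ValueError`` naming the codon index if an internal stop codon or
    an unknown triplet is encountered.  A single terminal stop is allowed and
    dropped.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    seq = seq.upper()
    n = len(seq) // 3
    out = np.empty(n, dtype=np.int16)
    last = n - 1
    for k in range(n):
        codon = seq[3 * k: 3 * k + 3]
        if codon in STOP_CODONS:
            if k == last:
                return out[:last]
            raise ValueError(f"internal stop codon {codon} at codon index {k}")
        try:
            out[k] = CODON_INDEX[codon]
        except KeyError:
            raise ValueError(f"unrecognized codon {codon!r} at codon index {k}") from None
    return out
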