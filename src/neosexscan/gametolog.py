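"""Gene-level sex-linkage bookkeeping and alignment gap handling.

Genes inherit the linkage call of their parent scaffold, which misassigns
some genuinely sex-linked genes on long, weakly differentiated scaffolds as
autosomal.  The reassignment rule is deliberately asymmetric: within one
lineage, an orthogroup holding an autosomal and a W-linked copy but no
Z-linked one has its autosomal copy promoted to the Z slot (a W copy proves
the gene is on the neo-sex pair, and W scaffolds are rarely misassigned);
an autosomal-plus-Z orthogroup is left alone, its W copy treated as not
sequenced, because W assemblies are fragmented and W calls are reliable.

Gap handling for the distance statistics: pairwise distances drop any
aligned column where either sequence is gapped; codon-model statistics drop
whole codon columns gapped in *any* focal-lineage gametolog (outgroup-only
gaps are kept).  'N' bases count as gaps throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

log = logging.getLogger(__name__)

GAP_CHARS = frozenset("-N")

LINEAGES = ("coastal", "inland")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    og_id: str
    lineage: str   # coastal / inland / outgroup
    linkage: str   # A / Z / W
    cds: str
    is_nmt: bool = False
    reassigned: bool = False


@dataclass
class GametologSet:
    """One orthogroup's sequences, keyed by (lineage, linkage) slot."""

    og_id: str
    slots: dict = field(default_factory=dict)   # (lineage, linkage) -> GeneRecord
    outgroup: list = field(default_factory=list)  # GeneRecord list

    def get(self, lineage: str, linkage: str) -> GeneRecord | None:
        return self.slots.get((lineage, linkage))

    def put(self, rec: GeneRecord) -> None:
        if rec.lineage == "outgroup":
            self.outgroup.append(rec)
            return
        key = (rec.lineage, rec.linkage)
        if key in self.slots:
            raise ValueError(f"{self.og_id}: duplicate sequence for slot {key}")
        self.slots[key] = rec

    def all_records(self) -> list[GeneRecord]:
        return list(self.slots.values()) + list(self.outgroup)

    def aligned_length(self) -> int:
        recs = self.all_records()
        if not recs:
            return 0
        lengths = {len(r.cds) for r in recs}
        if len(lengths) != 1:
            raise ValueError(f"{self.og_id}: inconsistent aligned lengths {sorted(lengths)}")
        return lengths.pop()


def sets_from_alignments(alignments: dict, function_table: pd.DataFrame | None = None) -> list[GametologSet]:
    """Build GametologSets from {og_id: {'<gene>|<lineage>|<linkage>': seq}}."""
    nmt = set()
    if function_table is not None:
        nmt = set(function_table.loc[function_table["is_nmt"].astype(int) == 1, "gene_id"])
    out = []
    for og in sorted(alignments):
        gs = GametologSet(og_id=og)
        for sid in sorted(alignments[og]):
            gene, lineage, linkage = sid.split("|")
            gs.put(GeneRecord(gene_id=gene, og_id=og, lineage=lineage, linkage=linkage,
                              cds=alignments[og][sid], is_nmt=gene in nmt))
        out.append(gs)
    return out


def select_longest_transcript(transcripts: dict[str, str]) -> tuple[str, str]:
    """Pick one transcript per gene: longest ungapped length, then smallest id.

    ``transcripts`` maps transcript id -> nucleotide sequence; returns the
    chosen (id, sequence).
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    def ungapped(seq: str) -> int:
        return sum(1 for c in seq if c not in GAP_CHARS)
    best = min(transcripts, key=lambda t: (-ungapped(transcripts[t]), t))
    return best, transcripts[best]


def reassign_autosomal_gametologs(gset: GametologSet) -> GametologSet:
    """Promote autosomal copies to the Z slot where a W copy proves sex linkage.

    Per lineage: A + W present, Z absent -> the autosomal record becomes the
    Z-linked gametolog (flagged ``reassigned``).  A + Z present, W absent ->
    unchanged (the W copy is treated as unsequenced).  Idempotent.
    """
    new = GametologSet(og_id=gset.og_id, slots=dict(gset.slots), outgroup=list(gset.outgroup))
    for lineage in LINEAGES:
        a = new.slots.get((lineage, "A"))
        w = new.slots.get((lineage, "W"))
        z = new.slots.get((lineage, "Z"))
        if a is not None and w is not None and z is None:
            new.slots[(lineage, "Z")] = replace(a, linkage="Z", reassigned=True)
            del new.slots[(lineage, "A")]
    return new


def label_function(genes: list[GeneRecord], function_table: pd.DataFrame) -> list[GeneRecord]:
    """Set ``is_nmt`` from a two-column table (gene_id, is_nmt 0/1).

    Genes absent from the table default to non-N-mt (count logged); a gene id
    appearing with conflicting flags is an error.
    """
    dup = function_table.groupby("gene_id")["is_nmt"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise ValueError(f"conflicting function flags for gene(s): {list(conflicts.index)}")
    flags = {str(g): bool(int(v)) for g, v in
             zip(function_table["gene_id"], function_table["is_nmt"])}
    missing = sum(1 for g in genes if g.gene_id not in flags)
    if missing:
        log.warning("%d gene(s) absent from function table; labelled non-N-mt", missing)
    return [replace(g, is_nmt=flags.get(g.gene_id, False)) for g in genes]


def delete_gap_sites(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Drop every aligned column where either sequence has a gap or N."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    keep = [(a, b) for a, b in zip(seq_a.upper(), seq_b.upper())
            if a not in GAP_CHARS and b not in GAP_CHARS]
    if not keep:
        return "", ""
    a, b = zip(*keep)
    return "".join(a), "".join(b)


def trim_codon_gaps(gset: GametologSet) -> GametologSet:
    """Remove codon columns gapped in any focal-lineage (non-outgroup) sequence.

    The triplet is removed from *all* sequences in the orthogroup; codon
    columns gapped only in outgroup sequences are retained.
    """
    length = gset.aligned_length()
    if length % 3:
        raise ValueError(f"{gset.og_id}: aligned length {length} not divisible by 3")
    focal = list(gset.slots.values())
    keep = []
    for k in range(length // 3):
        sl = slice(3 * k, 3 * k + 3)
        if all(not (GAP_CHARS & set(rec.cds[sl].upper())) for rec in focal):
            keep.append(k)

    def trim(seq: str) -> str:
        return "".join(seq[3 * k: 3 * k + 3] for k in keep)

    new = GametologSet(og_id=gset.og_id)
    new.slots = {key: replace(rec, cds=trim(rec.cds)) for key, rec in gset.slots.items()}
    new.outgroup = [replace(rec, cds=trim(rec.cds)) for rec in gset.outgroup]
    return new
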