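"""Synthetic cohorts for the neo-sex chromosome analysis.

Two generators are provided, mirroring the two kinds of evidence the
pipeline consumes:

* :func:`simulate_scaffold_tables` -- per-scaffold, per-sex mapping summaries
  (mean mapped depth, horizontal coverage, single-copy-kmer matching) for
  autosomal, Z-linked and W-linked scaffolds, as produced by mapping pooled
  male and female whole-genome resequencing reads to a female assembly.
  In a ZW system males are ZZ and carry no W, so the male:female depth
  expectation is 1:1 for autosomes, 2:1 for Z scaffolds and ~0:1 for W
  scaffolds (plus a small mismapping floor).

* :func:`simulate_gametolog_alignments` -- per-orthogroup codon alignments of
  an outgroup plus, for each of two sister lineages ("coastal", "inland"),
  an autosomal copy and the W and Z gametologs, evolved under a
  continuous-time codon substitution process with per-branch dN/dS.
  W branches of nuclear genes with mitochondrial function (N-mt genes) can
  be stretched by ``w_nmt_boost`` to emulate accelerated neo-W divergence.

Both generators are fully deterministic given ``SimConfig.seed``; every
scaffold/gene draws from its own seed-derived substream, so outputs do not
depend on iteration order.  Ground truth (class labels, true branch dN/dS,
deletion spans) is returned in a :class:`SimTruth` for recovery testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codon import CODONS, N_CODONS, codon_neighbors

LINEAGES = ("coastal", "inland")
LINKAGES = ("A", "Z", "W")

#: branch identifiers used in ``omega_map`` / ``SimTruth.branch_omega``
BRANCH_CLASSES = ("outgroup", "autosomal", "z_coastal", "z_inland", "w_coastal", "w_inland")

_DEFAULT_OMEGA = {b: 0.2 for b in BRANCH_CLASSES}
# expected substitutions per nucleotide site; "split" is the stem branch of
# each lineage (inter-lineage split depth), free of the Z/W onset depth
_DEFAULT_BRANCH_LEN = {"outgroup": 0.10, "split": 0.001, "autosomal": 0.001, "z": 0.0005, "w": 0.002}


class SimConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SimConfig:
    """Study conditions for both generators.

    Defaults emulate the published study design: two pools of nine ~10x
    resequenced birds per sex (~90x pooled depth), a few hundred scaffolds
    with a trimodal male:female depth-ratio structure, ~10% of genes with
    mitochondrial function, and mild purifying selection (dN/dS = 0.2) with
    a transition:transversion ratio typical of passerine nuclear genes.
    """

    seed: int = 0
    # scaffold cohort
    n_autosomal: int = 200
    n_z: int = 60
    n_w: int = 40
    depth_mean: float = 90.0
    depth_dispersion: float = 1.5
    # gene cohort
    n_genes: int = 300
    n_codons: int = 300
    nmt_fraction: float = 0.1
    kappa: float = 4.0
    omega_map: dict = field(default_factory=lambda: dict(_DEFAULT_OMEGA))
    branch_lengths: dict = field(default_factory=lambda: dict(_DEFAULT_BRANCH_LEN))
    w_nmt_boost: float = 4.0
    #: list of (gene_id, "<linkage>-<lineage>", start_codon, length_codons)
    deletion_spec: list = field(default_factory=list)

    def validate(self) -> None:
        counts = dict(n_autosomal=self.n_autosomal, n_z=self.n_z, n_w=self.n_w,
                      n_genes=self.n_genes, n_codons=self.n_codons)
        for name, v in counts.items():
            if v < 0:
                raise SimConfigError(f"{name} must be >= 0, got {v}")
        if not (0.0 <= self.nmt_fraction <= 1.0):
            raise SimConfigError(f"nmt_fraction must be in [0,1], got {self.nmt_fraction}")
        if not np.isfinite(self.depth_mean) or self.depth_mean < 0:
            raise SimConfigError(f"depth_mean must be finite and >= 0, got {self.depth_mean}")
        if not np.isfinite(self.depth_dispersion) or self.depth_dispersion < 1:
            raise SimConfigError("depth_dispersion must be finite and >= 1")
        if not np.isfinite(self.kappa) or self.kappa <= 0:
            raise SimConfigError("kappa must be finite and > 0")
        if not np.isfinite(self.w_nmt_boost) or self.w_nmt_boost < 1:
            raise SimConfigError("w_nmt_boost must be finite and >= 1")
        for b in BRANCH_CLASSES:
            w = self.omega_map.get(b)
            if w is None or not np.isfinite(w) or w <= 0:
                raise SimConfigError(f"omega_map[{b!r}] must be finite and > 0")
        for b in _DEFAULT_BRANCH_LEN:
            t = self.branch_lengths.get(b)
            if t is None or not np.isfinite(t) or t < 0:
                raise SimConfigError(f"branch_lengths[{b!r}] must be finite and >= 0")


@dataclass
class SimTruth:
    """Generator-side ground truth for parameter-recovery tests."""

    scaffold_linkage: dict = field(default_factory=dict)  # scaffold_id -> A/Z/W
    gene_linkage: dict = field(default_factory=dict)      # gene_id -> linkage of parent scaffold
    gene_function: dict = field(default_factory=dict)     # gene_id -> True if N-mt
    branch_omega: dict = field(default_factory=dict)      # (gene_id, branch) -> true dN/dS
    deletion_spans: list = field(default_factory=list)    # (gene_id, slot, start, length)


def _rng_for(config: SimConfig, domain: int, index: int) -> np.random.Generator:
    """Deterministic per-item substream (independent of iteration order)."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(domain, index)))


# ---------------------------------------------------------------------------
# scaffold-level generator
# ---------------------------------------------------------------------------

# depth expectation of the absent sex, as a fraction of the present sex
# (spurious mapping of repetitive/homologous reads)
MISMAP_FLOOR = 0.02

# kmer unmatched-proportion priors per class: W scaffolds are female-specific
# so most of their single-copy kmers are absent from the male pool
_KMER_BETA = {"A": (2.0, 98.0), "Z": (2.0, 98.0), "W": (42.5, 7.5)}


def _nb_total(rng: np.random.Generator, mean: float, dispersion: float) -> float:
    """One draw of a negative-binomial count with Var = dispersion * mean."""
    if mean <= 0:
        return 0.0
    if dispersion <= 1.0:
        return float(rng.poisson(mean))
    p = 1.0 / dispersion
    n = mean * p / (1.0 - p)
    return float(rng.negative_binomial(n, p))


def _scaffold_row(config: SimConfig, rng: np.random.Generator, linkage: str):
    """Per-sex (depth, coverage, kmer) draws for one scaffold."""
    med_len = 50_000 if linkage == "W" else 200_000
    length = int(np.exp(rng.normal(np.log(med_len), 0.5)))
    length = max(length, 5_000)
    n_win = max(1, length // 1000)

    mu = config.depth_mean
    expect = {
        "A": {"male": mu, "female": mu},
        "Z": {"male": 2 * mu, "female": mu},
        "W": {"male": MISMAP_FLOOR * mu, "female": mu},
    }[linkage]

    rows = {}
    for sex in ("male", "female"):
        m = expect[sex]
        # mean depth over ~1 kb windows treated as independent counts
        total = _nb_total(rng, m * n_win, config.depth_dispersion)
        depth = total / n_win
        absent = linkage == "W" and sex == "male"
        if absent:
            # mismapped reads pile up in repetitive tracts, so horizontal
            # coverage sits far below the Poisson expectation for this depth
            cov = float(rng.beta(2.0, 38.0))
        else:
            cov = float(1.0 - np.exp(-max(depth, 0.0)))
        n_kmers = int(rng.poisson(length / 500)) if not absent else int(rng.poisson(MISMAP_FLOOR * length / 500))
        a, b = _KMER_BETA[linkage]
        p_un = rng.beta(a, b) if sex == "female" else rng.beta(2.0, 98.0)
        n_un = int(rng.binomial(n_kmers, p_un)) if n_kmers else 0
        rows[sex] = dict(mean_depth=depth, horiz_cov=cov, n_kmers=n_kmers, n_kmers_unmatched=n_un)
    return length, rows


def simulate_scaffold_tables(config: SimConfig):
    """Simulate the per-scaffold mapping summary tables.

    Returns ``(depth_table, kmer_table, truth)`` where ``depth_table`` has
    one row per scaffold and sex (columns ``scaffold_id, sex, mean_depth,
    horiz_cov, n_kmers, n_kmers_unmatched, length_bp``) and ``kmer_table``
    summarizes the female pool's single-copy kmers against the male pool
    (columns ``scaffold_id, n_kmers, n_kmers_unmatched``).
    """
    config.validate()
    truth = SimTruth()
    classes = ["A"] * config.n_autosomal + ["Z"] * config.n_z + ["W"] * config.n_w
    depth_rows, kmer_rows = [], []
    for i, linkage in enumerate(classes):
        sid = f"scaffold_{i:05d}"
        rng = _rng_for(config, 1, i)
        length, rows = _scaffold_row(config, rng, linkage)
        truth.scaffold_linkage[sid] = linkage
        for sex in ("male", "female"):
            depth_rows.append({"scaffold_id": sid, "sex": sex, **rows[sex], "length_bp": length})
        f = rows["female"]
        kmer_rows.append({"scaffold_id": sid, "n_kmers": f["n_kmers"],
                          "n_kmers_unmatched": f["n_kmers_unmatched"]})
    depth_table = pd.DataFrame(depth_rows, columns=["scaffold_id", "sex", "mean_depth",
                                                    "horiz_cov", "n_kmers", "n_kmers_unmatched",
                                                    "length_bp"])
    kmer_table = pd.DataFrame(kmer_rows, columns=["scaffold_id", "n_kmers", "n_kmers_unmatched"])
    return depth_table, kmer_table, truth


# ---------------------------------------------------------------------------
# codon sequence generator
# ---------------------------------------------------------------------------

_rate_cache: dict = {}


def _rates(kappa: float, omega: float):
    """Total out-rate vector and cumulative target distribution per codon.

    Single-nucleotide changes between sense codons only; rate kappa for
    transitions, 1 for transversions, multiplied by omega when the change is
    nonsynonymous.  Rates are rescaled so that the mean total out-rate over a
    uniform codon distribution is 3, i.e. one unit of branch time equals one
    expected substitution per *nucleotide* site at the root composition.
    """
    key = (round(kappa, 12), round(omega, 12))
    hit = _rate_cache.get(key)
    if hit is not None:
        return hit
    rate = np.zeros((N_CODONS, N_CODONS))
    from ._codon import CODON_INDEX
    for ci, codon in enumerate(CODONS):
        for mut, ts, nonsyn in codon_neighbors(codon):
            r = (kappa if ts else 1.0) * (omega if nonsyn else 1.0)
            rate[ci, CODON_INDEX[mut]] = r
    total = rate.sum(axis=1)
    scale = 3.0 / total.mean()
    total = total * scale
    cum = np.cumsum(rate / rate.sum(axis=1, keepdims=True), axis=1)
    out = (total, cum)
    _rate_cache[key] = out
    return out


def evolve_codons(codons: np.ndarray, t: float, kappa: float, omega: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Evolve codon indices for branch length ``t`` (substitutions/nt site).

    Site-independent Gillespie simulation: each codon site waits an
    exponential time set by its current total substitution rate, then jumps
    to a neighbouring sense codon in proportion to the per-target rates.
    """
    state = codons.copy()
    if t <= 0 or state.size == 0:
        return state
    total, cum = _rates(kappa, omega)
    t_rem = np.full(state.size, float(t))
    idx = np.arange(state.size)
    while idx.size:
        r = total[state[idx]]
        t_rem[idx] -= rng.standard_exponential(idx.size) / r
        idx = idx[t_rem[idx] > 0]
        if not idx.size:
            break
        u = rng.random(idx.size)
        state[idx] = (u[:, None] < cum[state[idx]]).argmax(axis=1)
    return state


def _seq_str(codons: np.ndarray) -> str:
    return "".join(CODONS[c] for c in codons)


#: alignment slots emitted per gene: (lineage, linkage)
GAMETOLOG_SLOTS = tuple(
    [("outgroup", "A")] + [(lin, lk) for lin in LINEAGES for lk in LINKAGES]
)


def seq_id(gene: str, lineage: str, linkage: str) -> str:
    return f"{gene}|{lineage}|{linkage}"


def simulate_gametolog_alignments(config: SimConfig):
    """Simulate per-orthogroup codon alignments for two lineages + outgroup.

    Topology per gene (shared root, one outgroup):
    ``(outgroup, ((A_c, (W_c, Z_c)), (A_i, (W_i, Z_i))))`` where the stem
    branch of each lineage has length ``branch_lengths['split']`` and the
    within-lineage A/W/Z branches hang directly off the lineage ancestor.
    W-branch lengths of N-mt genes are multiplied by ``w_nmt_boost``.

    Returns ``(alignments, og_table, function_table, truth)``;
    ``alignments`` maps og_id -> {sequence id -> aligned codon string}
    (deletions from ``deletion_spec`` appear as ``---`` codons).
    """
    config.validate()
    truth = SimTruth()
    bl = config.branch_lengths
    om = config.omega_map
    n_nmt = int(round(config.nmt_fraction * config.n_genes))

    deletions: dict = {}
    for gene, slot, start, length in config.deletion_spec:
        if start < 0 or length < 0 or start + length > config.n_codons:
            raise SimConfigError(
                f"deletion span ({gene}, {slot}, {start}, {length}) exceeds "
                f"gene length {config.n_codons} codons")
        deletions.setdefault((gene, slot), []).append((start, length))

    alignments: dict = {}
    og_rows, fn_rows = [], []
    for gi in range(config.n_genes):
        gene = f"gene_{gi:05d}"
        og = f"og_{gi:05d}"
        is_nmt = gi < n_nmt
        rng = _rng_for(config, 2, gi)
        root = rng.integers(0, N_CODONS, size=config.n_codons).astype(np.int16)

        seqs: dict = {}
        seqs[("outgroup", "A")] = evolve_codons(root, bl["outgroup"], config.kappa, om["outgroup"], rng)
        truth.branch_omega[(gene, "outgroup")] = om["outgroup"]
        for lin in LINEAGES:
            anc = evolve_codons(root, bl["split"], config.kappa, om["autosomal"], rng)
            truth.branch_omega[(gene, f"split_{lin}")] = om["autosomal"]
            seqs[(lin, "A")] = evolve_codons(anc, bl["autosomal"], config.kappa, om["autosomal"], rng)
            truth.branch_omega[(gene, f"autosomal_{lin}")] = om["autosomal"]
            w_len = bl["w"] * (config.w_nmt_boost if is_nmt else 1.0)
            seqs[(lin, "W")] = evolve_codons(anc, w_len, config.kappa, om[f"w_{lin}"], rng)
            truth.branch_omega[(gene, f"w_{lin}")] = om[f"w_{lin}"]
            seqs[(lin, "Z")] = evolve_codons(anc, bl["z"], config.kappa, om[f"z_{lin}"], rng)
            truth.branch_omega[(gene, f"z_{lin}")] = om[f"z_{lin}"]

        aln: dict = {}
        for (lin, lk) in GAMETOLOG_SLOTS:
            sid = seq_id(gene, lin, lk)
            codons = [CODONS[c] for c in seqs[(lin, lk)]]
            slot = f"{lk}-{lin}"
            for start, length in deletions.get((gene, slot), []):
                codons[start:start + length] = ["---"] * length
                truth.deletion_spans.append((gene, slot, start, length))
            aln[sid] = "".join(codons)
            og_rows.append({"og_id": og, "gene_id": gene, "lineage": lin, "linkage": lk})
        alignments[og] = aln
        fn_rows.append({"gene_id": gene, "is_nmt": int(is_nmt)})
        truth.gene_function[gene] = bool(is_nmt)

    og_table = pd.DataFrame(og_rows, columns=["og_id", "gene_id", "lineage", "linkage"])
    function_table = pd.DataFrame(fn_rows, columns=["gene_id", "is_nmt"])
    return alignments, og_table, function_table, truth


def write_alignments(alignments: dict, outdir: str | Path) -> list[Path]:
    """Write one FASTA per orthogroup; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for og in sorted(alignments):
        path = outdir / f"{og}.fasta"
        with open(path, "w") as fh:
            for sid in sorted(alignments[og]):
                fh.write(f">{sid}\n{alignments[og][sid]}\n")
        paths.append(path)
    return paths


#: reference chromosomes offered as mapping targets; half of the simulated
#: sex-linked scaffolds derive from the fused former autosome ("chr1A"),
#: the rest from the ancestral Z/W
_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 11))


def write_scaffold_paf(config: SimConfig, truth: SimTruth, depth_table: pd.DataFrame,
                       path: str | Path) -> None:
    """Emit a minimal 12-column PAF of scaffold-to-reference top alignments.

    Autosomal scaffolds map to ordinary autosomes; half of the Z (W)
    scaffolds map to the ancestral chrZ (chrW) and half to the neo-sex
    donor autosome chr1A.  One high-quality block per scaffold, plus a
    shorter secondary block to exercise the top-hit selection rule.
    """
    lengths = (depth_table.drop_duplicates("scaffold_id")
               .set_index("scaffold_id")["length_bp"].to_dict())
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, sid in enumerate(sorted(truth.scaffold_linkage)):
            rng = _rng_for(config, 3, i)
            linkage = truth.scaffold_linkage[sid]
            if linkage == "A":
                target = _AUTOSOMES[int(rng.integers(len(_AUTOSOMES)))]
            elif linkage == "Z":
                target = "chr1A" if rng.random() < 0.5 else "chrZ"
            else:
                target = "chr1A" if rng.random() < 0.5 else "chrW"
            qlen = int(lengths.get(sid, 10_000))
            block = max(1000, int(0.8 * qlen))
            rows = [(sid, qlen, 0, block, "+", target, 100_000_000, 0, block,
                     int(0.95 * block), block, 60)]
            decoy = _AUTOSOMES[int(rng.integers(len(_AUTOSOMES)))]
            rows.append((sid, qlen, 0, block // 4, "+", decoy, 100_000_000, 0,
                         block // 4, int(0.6 * block // 4), block // 4,
                         int(rng.integers(0, 30))))
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a (YAML-derived) plain dict, merging defaults."""
    d = dict(d)
    omega = dict(_DEFAULT_OMEGA); omega.update(d.pop("omega_map", {}))
    bl = dict(_DEFAULT_BRANCH_LEN); bl.update(d.pop("branch_lengths", {}))
    dels = [tuple(x) for x in d.pop("deletion_spec", [])]
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise SimConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(omega_map=omega, branch_lengths=bl, deletion_spec=dels, **d)
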