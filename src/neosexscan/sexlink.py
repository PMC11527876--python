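"""Scaffold sex-linkage metrics and Z/W/autosome classification.

Three per-scaffold statistics discriminate inheritance classes when pooled
male and female reads are mapped to a female assembly:

* male:female ratio of mean mapped read depth (A ~1, Z ~2, W ~0),
* male:female ratio of horizontal mapping coverage (W scaffolds are barely
  covered by male reads),
* proportion of the female pool's single-copy kmers unmatched in the male
  pool (near 1 for female-specific W scaffolds, near 0 otherwise).

Scaffolds are classified by PCA on the z-standardized metric matrix followed
by 1-D k-means (k=3) on PC1, with clusters anchored to biology through the
raw depth ratio (ZZ males double Z depth, lack W entirely).  A leave-one-out
cross-validated LDA quantifies how well the raw metrics predict the calls,
and reference-genome top hits (PAF) flag sex-linked scaffolds whose best
target is an autosome as neo-sex derived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

log = logging.getLogger(__name__)

#: pseudocount added to numerator and denominator of the M:F ratios
RATIO_EPS = 0.5


class ClassificationError(ValueError):
    """Raised when the scaffold cohort cannot support a 3-class split."""


@dataclass(frozen=True)
class ScaffoldMetrics:
    scaffold_id: str
    unmatched_kmer_prop: float
    depth_ratio_mf: float
    cov_ratio_mf: float
    length_bp: int

    def __post_init__(self):
        if not (0.0 <= self.unmatched_kmer_prop <= 1.0):
            raise ValueError(f"{self.scaffold_id}: unmatched_kmer_prop outside [0,1]")
        for name in ("depth_ratio_mf", "cov_ratio_mf"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{self.scaffold_id}: {name} must be finite and >= 0")


@dataclass(frozen=True)
class LinkageCall:
    scaffold_id: str
    pc1: float
    pc2: float
    call: str  # A / Z / W
    posterior_note: str = ""


@dataclass(frozen=True)
class ReferenceHit:
    scaffold_id: str
    target_chrom: str
    mapq: int
    block_len: int
    is_neo_sex: bool = False


def compute_metrics(depth_table: pd.DataFrame, kmer_table: pd.DataFrame) -> list[ScaffoldMetrics]:
    """Compute the three sex-linkage metrics per scaffold.

    ``depth_table`` needs one male and one female row per scaffold
    (columns ``scaffold_id, sex, mean_depth, horiz_cov``); ``kmer_table``
    summarizes the female pool's single-copy kmers against the male pool
    (columns ``scaffold_id, n_kmers, n_kmers_unmatched``).
    """
    kmer = kmer_table.set_index("scaffold_id")
    has_len = "length_bp" in depth_table.columns
    out = []
    for sid, grp in depth_table.groupby("scaffold_id", sort=True):
        sexes = set(grp["sex"])
        if sexes != {"male", "female"}:
            raise ValueError(f"scaffold {sid!r} lacks rows for both sexes (has {sorted(sexes)})")
        male = grp[grp["sex"] == "male"].iloc[0]
        female = grp[grp["sex"] == "female"].iloc[0]
        depth_ratio = (male["mean_depth"] + RATIO_EPS) / (female["mean_depth"] + RATIO_EPS)
        cov_ratio = (male["horiz_cov"] + RATIO_EPS) / (female["horiz_cov"] + RATIO_EPS)
        if sid in kmer.index:
            n = int(kmer.loc[sid, "n_kmers"])
            prop = float(kmer.loc[sid, "n_kmers_unmatched"]) / n if n else 0.0
        else:
            prop = 0.0
        out.append(ScaffoldMetrics(
            scaffold_id=str(sid),
            unmatched_kmer_prop=prop,
            depth_ratio_mf=float(depth_ratio),
            cov_ratio_mf=float(cov_ratio),
            length_bp=int(male["length_bp"]) if has_len else 1,
        ))
    return out


def _metric_matrix(metrics: list[ScaffoldMetrics]) -> tuple[list[str], np.ndarray]:
    order = sorted(range(len(metrics)), key=lambda i: metrics[i].scaffold_id)
    ids = [metrics[i].scaffold_id for i in order]
    X = np.array([[metrics[i].unmatched_kmer_prop,
                   metrics[i].depth_ratio_mf,
                   metrics[i].cov_ratio_mf] for i in order])
    return ids, X


def classify_scaffolds(metrics: list[ScaffoldMetrics]):
    """PCA + 1-D k-means classification of scaffolds into A/Z/W.

    Returns ``(calls, variance_explained)`` where ``variance_explained`` is
    the per-PC fraction of variance.  Input order does not matter.
    """
    if len(metrics) < 3:
        raise ClassificationError(f"need >= 3 scaffolds, got {len(metrics)}")
    ids, X = _metric_matrix(metrics)
    sd = X.std(axis=0, ddof=0)
    if not (sd > 0).any():
        raise ClassificationError("all metrics are constant across scaffolds")
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    pca = PCA(n_components=3)
    scores = pca.fit_transform(Z)
    var_frac = pca.explained_variance_ratio_
    pc1 = scores[:, 0]
    if len(np.unique(np.round(pc1, 12))) < 3:
        raise ClassificationError("fewer than 3 distinct PC1 values; cannot form 3 clusters")

    km = KMeans(n_clusters=3, n_init=50, random_state=0)
    labels = km.fit_predict(pc1[:, None])

    # anchor cluster labels to biology via the raw M:F depth ratio: males are
    # ZZ so the Z cluster has the highest ratio, and carry no W so the W
    # cluster has the lowest.  Rank anchoring keeps the classification
    # invariant to affine rescaling of any one metric; whether the called
    # classes are plausible on the physical ratio scale is checked separately
    # (validate_calls).
    depth = X[:, 1]
    medians = {k: float(np.median(depth[labels == k])) for k in range(3)}
    order = sorted(medians, key=medians.get)  # ascending: W, A, Z
    label_map = {order[0]: "W", order[1]: "A", order[2]: "Z"}

    calls = []
    for i, sid in enumerate(ids):
        centre = km.cluster_centers_[labels[i], 0]
        calls.append(LinkageCall(
            scaffold_id=sid, pc1=float(pc1[i]), pc2=float(scores[i, 1]),
            call=label_map[labels[i]],
            posterior_note=f"pc1_dist_to_centroid={abs(pc1[i] - centre):.4g}",
        ))
    return calls, var_frac


def validate_calls(metrics: list[ScaffoldMetrics],
                   calls: list[LinkageCall]) -> tuple[list[LinkageCall], list[str]]:
    """Check called classes against ploidy expectations on the raw ratio scale.

    Males are ZZ (M:F depth ratio ~2) and lack the W (ratio ~0); autosomes
    sit at ~1.  A called Z class whose median raw depth ratio is below 1.5,
    or a called W class above 0.5, indicates the cohort lacks that class and
    k-means split another one: those calls are relabelled to A and a warning
    is returned.
    """
    ratio = {m.scaffold_id: m.depth_ratio_mf for m in metrics}
    warnings = []
    relabel = set()
    for cls, lo, hi in (("W", -math.inf, 0.5), ("Z", 1.5, math.inf)):
        members = [c.scaffold_id for c in calls if c.call == cls]
        if not members:
            warnings.append(f"class {cls} absent from this cohort")
            continue
        med = float(np.median([ratio[s] for s in members]))
        if not (lo < med < hi):
            warnings.append(f"called class {cls} has implausible median depth ratio "
                            f"{med:.3g}; class {cls} treated as absent")
            relabel.add(cls)
    if not relabel:
        return calls, warnings
    out = [LinkageCall(c.scaffold_id, c.pc1, c.pc2,
                       "A" if c.call in relabel else c.call, c.posterior_note)
           for c in calls]
    return out, warnings


def lda_cross_validate(metrics: list[ScaffoldMetrics], calls: list[LinkageCall]) -> float:
    """Leave-one-out cross-validated LDA accuracy of metrics vs. calls.

    Scaffolds whose class has a single member cannot be held out (LDA needs
    every class in training); they are excluded with a warning.
    """
    ids, X = _metric_matrix(metrics)
    call_map = {c.scaffold_id: c.call for c in calls}
    y = np.array([call_map[s] for s in ids])
    classes, counts = np.unique(y, return_counts=True)
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 classes with >= 2 members each for LOOCV")
    singletons = set(classes[counts < 2])
    if singletons:
        log.warning("excluding %d scaffold(s) in singleton classes %s from LOOCV",
                    sum(counts[counts < 2]), sorted(singletons))
        keep = ~np.isin(y, list(singletons))
        X, y = X[keep], y[keep]
    correct = 0
    n = len(y)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        lda = LinearDiscriminantAnalysis()
        lda.fit(X[mask], y[mask])
        correct += int(lda.predict(X[i:i + 1])[0] == y[i])
    return correct / n


# ---------------------------------------------------------------------------
# reference mapping (PAF) rules
# ---------------------------------------------------------------------------

MAPQ_MIN = 40


@dataclass(frozen=True)
class PafRecord:
    query: str
    target: str
    mapq: int
    block_len: int


def parse_paf(path) -> list[PafRecord]:
    """Parse the 12 mandatory minimap2 PAF columns (tags ignored)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line has {len(parts)} columns, expected >= 12")
            try:
                records.append(PafRecord(query=parts[0], target=parts[5],
                                         mapq=int(parts[11]), block_len=int(parts[10])))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed PAF field: {e}") from None
    return records


def assign_reference_target(paf_records, scaffold_id: str,
                            mapq_min: int = MAPQ_MIN) -> ReferenceHit | None:
    """Best reference target of a scaffold from its PAF alignment blocks.

    Blocks with mapq below ``mapq_min`` are dropped; survivors are ranked by
    descending mapq, then descending block length, then ascending target
    name (a deterministic tiebreak).  Returns None if nothing survives.
    """
    cands = [r for r in paf_records if r.query == scaffold_id and r.mapq >= mapq_min]
    if not cands:
        return None
    best = min(cands, key=lambda r: (-r.mapq, -r.block_len, r.target))
    return ReferenceHit(scaffold_id=scaffold_id, target_chrom=best.target,
                        mapq=best.mapq, block_len=best.block_len)


def default_chrom_class(name: str) -> str:
    """Fallback reference-chromosome classification from its name."""
    n = name.lower().removeprefix("chr").strip("_")
    if n in ("z",):
        return "Z"
    if n in ("w",):
        return "W"
    if n in ("m", "mt", "mito"):
        return "mito"
    return "autosome"


def flag_neo_sex(calls: list[LinkageCall], hits: list[ReferenceHit],
                 chrom_classes: dict[str, str] | None = None) -> list[ReferenceHit]:
    """Mark sex-linked scaffolds whose best reference target is an autosome.

    ``chrom_classes`` maps reference chromosome names to
    {autosome, Z, W, mito}; names not in the table (or with no table) fall
    back to name-based detection of Z/W/mito.  Hits for scaffolds without a
    linkage call are dropped with a warning.
    """
    call_map = {c.scaffold_id: c.call for c in calls}
    out = []
    for hit in hits:
        call = call_map.get(hit.scaffold_id)
        if call is None:
            log.warning("scaffold %s has a reference hit but no linkage call; skipping",
                        hit.scaffold_id)
            continue
        cls = (chrom_classes or {}).get(hit.target_chrom) or default_chrom_class(hit.target_chrom)
        neo = call in ("Z", "W") and cls == "autosome"
        out.append(ReferenceHit(scaffold_id=hit.scaffold_id, target_chrom=hit.target_chrom,
                                mapq=hit.mapq, block_len=hit.block_len, is_neo_sex=neo))
    return out
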