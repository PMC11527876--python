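"""End-to-end orchestration: scaffold classification (H1) and gametolog
divergence analysis (H2/H3), with TSV tables and JSON summaries.

Stages are pure functions of their inputs plus the config: rerunning a
stage with the same inputs and seed reproduces its outputs byte for byte.
Every table carries a header row and a trailing provenance comment
(config hash, seed, tool version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, divergence, gametolog, sexlink, simdata, stats

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (bad value or missing input)."""


@dataclass
class PipelineConfig:
    # inputs
    depth_table: str | None = None
    kmer_table: str | None = None
    paf: str | None = None
    og_fasta_dir: str | None = None
    og_table: str | None = None
    function_table: str | None = None
    chrom_classes: str | None = None
    # thresholds
    mapq_min: int = 40
    zscore_cut: float = 1.96
    outlier_quantile: float = 0.01
    n_boot: int = 1000
    gap_min_codons: int = 5
    # run
    seed: int = 0
    outdir: str = "neosexscan_out"
    simulate: dict = field(default_factory=dict)

    def digest(self) -> str:
        # analytic parameters only; file locations do not affect results
        d = dataclasses.asdict(self)
        for key in ("outdir", "depth_table", "kmer_table", "paf", "og_fasta_dir",
                    "og_table", "function_table", "chrom_classes"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def validate_thresholds(self) -> None:
        if self.mapq_min < 0:
            raise ConfigError("mapq_min must be >= 0")
        if self.zscore_cut <= 0:
            raise ConfigError("zscore_cut must be > 0")
        if not (0 < self.outlier_quantile <= 1):
            raise ConfigError("outlier_quantile must be in (0, 1]")
        if self.n_boot < 100:
            raise ConfigError("n_boot must be >= 100")

    def require(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if path is None:
                raise ConfigError(f"input {name!r} is required but not configured")
            if not Path(path).exists():
                raise ConfigError(f"input {name!r} not found: {path}")


def load_config(path: str | Path, seed: int | None = None,
                outdir: str | None = None) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown_sections = set(raw) - {"inputs", "thresholds", "seed", "outdir", "simulate"}
    if unknown_sections:
        raise ConfigError(f"unknown config keys: {sorted(unknown_sections)}")
    flat: dict = {}
    flat.update(raw.get("inputs", {}))
    flat.update(raw.get("thresholds", {}))
    for key in ("seed", "outdir", "simulate"):
        if key in raw:
            flat[key] = raw[key]
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(flat) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**flat)
    if seed is not None:
        cfg.seed = seed
    if outdir is not None:
        cfg.outdir = outdir
    cfg.validate_thresholds()
    return cfg


def _provenance(cfg: PipelineConfig) -> str:
    return f"# provenance: config_sha256={cfg.digest()} seed={cfg.seed} version={__version__}"


def write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write(_provenance(cfg) + "\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _write_json(obj: dict, path: Path, cfg: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    obj = dict(obj)
    obj["provenance"] = {"config_sha256": cfg.digest(), "seed": cfg.seed, "version": __version__}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _fit_to_dict(fit: stats.LmmFit) -> dict:
    d = dataclasses.asdict(fit)
    return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig) -> dict:
    """Generate the synthetic inputs configured under ``simulate:``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simdata.config_from_dict({"seed": cfg.seed, **cfg.simulate})
    t0 = time.perf_counter()
    depth, kmer, truth_s = simdata.simulate_scaffold_tables(sim)
    write_tsv(depth, outdir / "depth_table.tsv", cfg)
    write_tsv(kmer, outdir / "kmer_table.tsv", cfg)
    simdata.write_scaffold_paf(sim, truth_s, depth, outdir / "scaffolds.paf")
    alignments, og_table, fn_table, truth_g = simdata.simulate_gametolog_alignments(sim)
    simdata.write_alignments(alignments, outdir / "og_fasta")
    write_tsv(og_table, outdir / "og_table.tsv", cfg)
    write_tsv(fn_table, outdir / "function_table.tsv", cfg)
    truth = pd.DataFrame(sorted(truth_s.scaffold_linkage.items()),
                         columns=["scaffold_id", "linkage"])
    write_tsv(truth, outdir / "scaffold_truth.tsv", cfg)
    log.info("simulate stage done in %.1fs", time.perf_counter() - t0)
    return {"n_scaffolds": len(truth), "n_genes": len(fn_table),
            "outdir": str(outdir)}


def run_h1(cfg: PipelineConfig) -> dict:
    """Scaffold classification, LDA validation and neo-sex flagging."""
    cfg.require("depth_table", "kmer_table", "paf")
    outdir = Path(cfg.outdir)
    t0 = time.perf_counter()
    warnings: list[str] = []

    depth = read_tsv(cfg.depth_table)
    kmer = read_tsv(cfg.kmer_table)
    metrics = sexlink.compute_metrics(depth, kmer)
    calls, var_frac = sexlink.classify_scaffolds(metrics)
    calls, call_warnings = sexlink.validate_calls(metrics, calls)
    for w in call_warnings:
        warnings.append(w)
        log.warning("%s", w)
    accuracy = sexlink.lda_cross_validate(metrics, calls)

    call_df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
    write_tsv(call_df, outdir / "linkage_calls.tsv", cfg)

    class_counts = call_df["call"].value_counts().to_dict()

    lengths = {m.scaffold_id: m.length_bp for m in metrics}
    neo_len = {"Z": 0, "W": 0}
    hit_rows = []
    records = sexlink.parse_paf(cfg.paf)
    chrom_classes = None
    if cfg.chrom_classes is not None:
        cc = read_tsv(cfg.chrom_classes)
        chrom_classes = dict(zip(cc.iloc[:, 0].astype(str), cc.iloc[:, 1].astype(str)))
    hits = []
    for m in sorted(metrics, key=lambda m: m.scaffold_id):
        hit = sexlink.assign_reference_target(records, m.scaffold_id, mapq_min=cfg.mapq_min)
        if hit is not None:
            hits.append(hit)
    flagged = sexlink.flag_neo_sex(calls, hits, chrom_classes)
    call_map = {c.scaffold_id: c.call for c in calls}
    for h in flagged:
        hit_rows.append(dataclasses.asdict(h))
        if h.is_neo_sex:
            neo_len[call_map[h.scaffold_id]] += lengths.get(h.scaffold_id, 0)
    write_tsv(pd.DataFrame(hit_rows,
                           columns=["scaffold_id", "target_chrom", "mapq",
                                    "block_len", "is_neo_sex"]),
              outdir / "reference_hits.tsv", cfg)

    summary = {
        "n_scaffolds": len(metrics),
        "class_counts": class_counts,
        "pc_variance_fractions": [float(v) for v in var_frac],
        "loocv_lda_accuracy": accuracy,
        "n_reference_hits": len(hit_rows),
        "n_neo_sex": sum(1 for r in hit_rows if r["is_neo_sex"]),
        "neo_sex_total_length_bp": neo_len,
        "warnings": warnings,
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    _write_json(summary, outdir / "h1_summary.json", cfg)
    return summary


def read_og_fastas(fasta_dir: str | Path) -> dict:
    """Load per-orthogroup FASTA files into {og_id: {seq_id: sequence}}."""
    alignments = {}
    for path in sorted(Path(fasta_dir).glob("*.fasta")):
        seqs = {}
        sid = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if sid is not None:
                        seqs[sid] = "".join(chunks)
                    sid = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line)
        if sid is not None:
            seqs[sid] = "".join(chunks)
        alignments[path.stem] = seqs
    return alignments


def run_h2_h3(cfg: PipelineConfig) -> dict:
    """Divergence statistics, selection screens and mixed-model reports."""
    cfg.require("og_fasta_dir", "function_table")
    outdir = Path(cfg.outdir)
    t0 = time.perf_counter()
    warnings: list[str] = []

    alignments = read_og_fastas(cfg.og_fasta_dir)
    fn_table = read_tsv(cfg.function_table)
    sets = gametolog.sets_from_alignments(alignments, fn_table)
    usable = []
    for gset in sets:
        try:
            gset.aligned_length()
        except ValueError as e:
            warnings.append(str(e))
            log.warning("skipping orthogroup: %s", e)
            continue
        usable.append(gametolog.reassign_autosomal_gametologs(gset))

    # --- Dxy ---------------------------------------------------------------
    distances = divergence.dxy_table(usable)
    dist_df = pd.DataFrame([dataclasses.asdict(d) for d in distances])
    write_tsv(dist_df, outdir / "dxy.tsv", cfg)

    delta_records = []
    try:
        delta_records = divergence.delta_dxy_outliers(distances, z_cut=cfg.zscore_cut)
    except ValueError as e:
        warnings.append(f"delta-Dxy outliers skipped: {e}")
    if delta_records:
        write_tsv(pd.DataFrame([dataclasses.asdict(r) for r in delta_records]),
                  outdir / "delta_dxy.tsv", cfg)

    # --- NG86 dN/dS + bootstrap screen --------------------------------------
    estimates = []
    boot_rows = []
    gap_rows = []
    for k, gset in enumerate(sorted(usable, key=lambda g: g.og_id)):
        for span in divergence.detect_gap_spans(
                {f"{r.gene_id}|{r.lineage}|{r.linkage}": r.cds for r in gset.all_records()},
                min_len_codons=cfg.gap_min_codons, og_id=gset.og_id):
            gap_rows.append(dataclasses.asdict(span))
        trimmed = gametolog.trim_codon_gaps(gset)
        if not trimmed.outgroup:
            warnings.append(f"{gset.og_id}: no outgroup sequence; dN/dS skipped")
            continue
        og_rec = trimmed.outgroup[0]
        for j, (lineage, linkage) in enumerate(
                [(lin, lk) for lin in ("coastal", "inland") for lk in ("Z", "W")]):
            rec = trimmed.get(lineage, linkage)
            if rec is None:
                continue
            a, b = gametolog.delete_gap_sites(rec.cds, og_rec.cds)
            est = divergence.ng86_dnds(a, b, og_id=gset.og_id, lineage=lineage,
                                       linkage=linkage, outgroup_id=og_rec.gene_id)
            estimates.append(est)
            seed = _boot_seed(cfg.seed, gset.og_id, lineage, linkage)
            pval = divergence.bootstrap_selection_screen(a, b, n_boot=cfg.n_boot, seed=seed)
            boot_rows.append({"og_id": gset.og_id, "lineage": lineage, "linkage": linkage,
                              "p_dn_gt_ds": pval})

    est_df = pd.DataFrame([dataclasses.asdict(e) for e in estimates])
    write_tsv(est_df, outdir / "dnds.tsv", cfg)
    boot_df = pd.DataFrame(boot_rows)
    if len(boot_df) and boot_df["p_dn_gt_ds"].notna().any():
        boot_df = _with_bh(boot_df)
    write_tsv(boot_df, outdir / "selection_screen.tsv", cfg)
    write_tsv(pd.DataFrame(gap_rows, columns=["og_id", "sequence_id", "start_codon",
                                              "length_codons", "fraction_of_alignment"]),
              outdir / "gap_spans.tsv", cfg)

    contrasts = divergence.dnds_contrast(estimates, outlier_quantile=cfg.outlier_quantile)
    write_tsv(pd.DataFrame([dataclasses.asdict(c) for c in contrasts]),
              outdir / "dnds_contrast.tsv", cfg)

    # --- mixed models --------------------------------------------------------
    nmt_map = {str(g): bool(int(v)) for g, v in zip(fn_table["gene_id"], fn_table["is_nmt"])}
    gene_of_og = {gset.og_id: gset for gset in usable}
    reports: dict = {}

    dxy_rows = [{"gene": d.og_id, "function": int(bool(d.is_nmt)), "linkage": d.linkage,
                 "dxy": d.dxy} for d in distances if d.dxy is not None]
    if len(dxy_rows) >= 8:
        dxy_data = pd.DataFrame(dxy_rows)
        try:
            rep = stats.interaction_and_contrasts(dxy_data, stats.LmmSpec(response="dxy"))
            reports["dxy"] = _report_to_dict(rep)
        except ValueError as e:
            warnings.append(f"Dxy LMM skipped: {e}")

    ci_rows = []
    for c in contrasts:
        gset = gene_of_og.get(c.og_id)
        nmt = any(r.is_nmt for r in gset.slots.values()) if gset is not None else False
        ci_rows.append({"gene": c.og_id, "function": int(nmt), "linkage": c.linkage,
                        "dnds_ci": c.value})
    if len(ci_rows) >= 8:
        ci_data = pd.DataFrame(ci_rows)
        try:
            rep = stats.interaction_and_contrasts(
                ci_data, stats.LmmSpec(response="dnds_ci", fixed=("function", "linkage")))
            reports["dnds_ci"] = _report_to_dict(rep)
        except ValueError as e:
            warnings.append(f"dNdS(C-I) LMM skipped: {e}")

    summary = {
        "n_orthogroups": len(usable),
        "n_dxy_records": len(distances),
        "n_delta_dxy_outliers": sum(r.is_outlier for r in delta_records),
        "delta_dxy_outlier_ogs": sorted(r.og_id for r in delta_records if r.is_outlier),
        "n_dnds_estimates": len(estimates),
        "n_contrast_outliers": sum(c.is_outlier for c in contrasts),
        "n_gap_spans": len(gap_rows),
        "lmm": reports,
        "warnings": warnings,
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    _write_json(summary, outdir / "h2h3_summary.json", cfg)
    return summary


def run_all(cfg: PipelineConfig) -> dict:
    """simulate -> h1 -> h2h3, wiring the simulated outputs into the stages."""
    sim_summary = run_simulate(cfg)
    outdir = Path(cfg.outdir)
    cfg.depth_table = str(outdir / "depth_table.tsv")
    cfg.kmer_table = str(outdir / "kmer_table.tsv")
    cfg.paf = str(outdir / "scaffolds.paf")
    cfg.og_fasta_dir = str(outdir / "og_fasta")
    cfg.og_table = str(outdir / "og_table.tsv")
    cfg.function_table = str(outdir / "function_table.tsv")
    return {"simulate": sim_summary, "h1": run_h1(cfg), "h2h3": run_h2_h3(cfg)}


def _boot_seed(seed: int, *key: str) -> int:
    payload = "|".join(key).encode()
    h = int.from_bytes(hashlib.sha256(payload).digest()[:4], "big")
    return (seed ^ h) % (2**31 - 1)


def _with_bh(boot_df: pd.DataFrame) -> pd.DataFrame:
    """Append a Benjamini-Hochberg adjusted column (uncorrected p retained)."""
    p = boot_df["p_dn_gt_ds"].to_numpy(dtype=float)
    mask = ~pd.isna(p)
    q = p.copy()
    pm = p[mask]
    m = pm.size
    order = pm.argsort()
    ranked = pm[order] * m / (1 + np.arange(m))
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[mask] = adj
    out = boot_df.copy()
    out["p_bh"] = q
    return out


def _report_to_dict(rep: dict) -> dict:
    out = {}
    for key, val in rep.items():
        if isinstance(val, stats.LmmFit):
            out[key] = _fit_to_dict(val)
        elif isinstance(val, dict) and val and isinstance(next(iter(val.values())), stats.LmmFit):
            out[key] = {k: _fit_to_dict(v) for k, v in val.items()}
        else:
            out[key] = val
    return out
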