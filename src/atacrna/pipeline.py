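"""End-to-end orchestration: windows -> differential -> cis score ->
regulatory behaviors -> motif screens, with a reproducible manifest.

`run_pipeline` operates on in-memory tables (the synthetic dataset or
tables loaded from disk); `run_all` is the file-level wrapper used by
the command line: it loads the inputs named in a RunConfig, runs the
stages in order, and writes one TSV/JSON per stage plus a manifest of
input checksums, stage row counts and wall-clock times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from atacrna import behavior as bh
from atacrna import cisscore, differential, motif, windows
from atacrna.intervals import read_bed

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and stage parameters for one pipeline run."""

    outdir: str
    peaks: str = ""
    tss: str = ""
    rna_counts: str = ""
    fragments: dict[str, str] = field(default_factory=dict)
    sample_conditions: dict[str, str] = field(default_factory=dict)
    genome: str = ""
    pwms: str = ""
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    pad_peak: int = 1000
    win_peak: int = 250
    step: int = 50
    pad_promoter: int = 5000
    win_promoter: int = 2000
    span: int = 100_000
    k: int = 4
    alpha: float = 0.05
    motif_alpha: float = 0.1
    n_shuffles: int = 100
    hit_metric: str = "total"
    positive_condition: str = ""
    exclude_promoters: str = "any"
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def validate_inputs(config: RunConfig) -> list[str]:
    """Schema/consistency checks; returns a list of failure messages."""
    failures: list[str] = []
    for label in ("peaks", "tss", "rna_counts"):
        p = getattr(config, label)
        if not p or not Path(p).exists():
            failures.append(f"{label}: file missing ({p!r})")
    for sample, p in config.fragments.items():
        if not Path(p).exists():
            failures.append(f"fragments[{sample}]: file missing ({p!r})")
        if sample not in config.sample_conditions:
            failures.append(f"sample {sample} missing from sample_conditions")
    if config.peaks and Path(config.peaks).exists():
        try:
            peaks = read_bed(config.peaks)
            if config.chrom_sizes:
                bad = peaks[~peaks["chrom"].isin(config.chrom_sizes)]
                if len(bad):
                    failures.append(
                        f"peaks: {len(bad)} rows on unknown chromosomes")
        except ValueError as exc:
            failures.append(f"peaks: {exc}")
    if config.rna_counts and Path(config.rna_counts).exists():
        counts = pd.read_csv(config.rna_counts, sep="\t", index_col=0)
        missing = [s for s in config.fragments if s not in counts.columns]
        if missing:
            failures.append(f"rna_counts: columns missing for samples "
                            f"{missing}")
    if config.pwms and Path(config.pwms).exists():
        try:
            for p in motif.read_jaspar(config.pwms):
                pass
        except ValueError as exc:
            failures.append(f"pwms: {exc}")
    return failures


def assemble_lineage_region_sets(gene_table: pd.DataFrame,
                                 deg: pd.DataFrame,
                                 dar_windows: pd.DataFrame,
                                 dar: pd.DataFrame,
                                 promoter_windows: pd.DataFrame,
                                 prom_da: pd.DataFrame,
                                 conditions: tuple[str, str],
                                 span: int = 100_000
                                 ) -> dict[tuple[str, str], np.ndarray]:
    """Matched-direction region sets per (lineage, regulatory class).

    Enhancer/combo classes: DA peak windows sharing the lineage
    direction within TSS +/- span of same-direction DEGs of that class.
    Promoter class: optimized promoter windows of same-direction DEGs.
    Positive logFC means the second condition; indices point into the
    row order of ``dar_windows`` / ``promoter_windows``.
    """
    neg_lin, pos_lin = conditions
    win = dar_windows.reset_index(drop=True).copy()
    win["midpoint"] = (win["start"] + win["end"]) // 2
    win = win.merge(dar[["log2FC", "significant"]], left_on="name",
                    right_index=True, how="left")
    prom = promoter_windows.reset_index(drop=True)
    sets: dict[tuple[str, str], np.ndarray] = {}
    for lineage, sign in ((neg_lin, -1), (pos_lin, 1)):
        deg_dir = deg[(deg["significant"]) & (np.sign(deg["log2FC"]) == sign)]
        for rclass in ("enhancer_centric", "combo_centric"):
            genes = gene_table[
                (gene_table["behavior_label"] == rclass)
                & gene_table["gene_id"].isin(deg_dir.index)]
            idx: set[int] = set()
            for g in genes.itertuples(index=False):
                sub = win[(win["chrom"] == g.chrom)
                          & (win["midpoint"] >= g.tss - span)
                          & (win["midpoint"] <= g.tss + span)
                          & win["significant"].fillna(False)
                          & (np.sign(win["log2FC"]) == sign)]
                idx.update(sub.index.tolist())
            sets[(lineage, rclass)] = np.array(sorted(idx), dtype=int)
        pc = gene_table[(gene_table["behavior_label"] == "promoter_centric")
                        & gene_table["gene_id"].isin(deg_dir.index)]
        mask = prom["name"].isin(pc["gene_id"])
        sets[(lineage, "promoter_centric")] = np.nonzero(
            mask.to_numpy())[0]
    return sets


def run_pipeline(*, peaks: pd.DataFrame, tss: pd.DataFrame,
                 rna_counts: pd.DataFrame,
                 fragments: dict[str, pd.DataFrame],
                 condition_labels: list[str],
                 chrom_sizes: dict[str, int],
                 genome: dict | None = None,
                 pwm_library: list[motif.PWM] | None = None,
                 config: RunConfig | None = None) -> dict:
    """Run every analysis stage on in-memory inputs.

    Returns a dict with the windowed regions, the three differential
    tables, cis scores, regulatory profiles with cluster tests, and
    (when a genome and PWM library are supplied) the motif screen.
    """
    cfg = config or RunConfig(outdir=".")
    timings: dict[str, float] = {}
    results: dict = {"timings": timings}

    t0 = time.perf_counter()
    peak_regs = windows.peak_regions(peaks, chrom_sizes, cfg.pad_peak,
                                     cfg.win_peak, cfg.step)
    prom_regs = windows.promoter_regions(tss, chrom_sizes, cfg.pad_promoter,
                                         cfg.win_promoter, cfg.step)
    windows.optimize_regions(peak_regs + prom_regs, fragments, chrom_sizes)
    peak_cov = windows.representative_matrix(peak_regs)
    prom_cov = windows.representative_matrix(prom_regs)
    peak_win = windows.selected_windows_frame(peak_regs)
    prom_win = windows.selected_windows_frame(prom_regs)
    results.update(peak_windows=peak_win, promoter_windows=prom_win,
                   peak_coverage=peak_cov, promoter_coverage=prom_cov)
    timings["windows"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rna_counts = rna_counts[peak_cov.columns]
    diff = differential.run_differential(
        rna_counts, peak_cov, prom_cov, condition_labels,
        positive_condition=cfg.positive_condition or None,
        alpha_sig=cfg.alpha)
    results["differential"] = diff
    timings["differential"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    captured = cisscore.capture_regions(tss, peak_win, prom_win,
                                        span=cfg.span,
                                        exclude=cfg.exclude_promoters)
    scores = cisscore.score_genes(captured, diff["peaks"],
                                  gene_ids=tss["gene_id"].tolist(),
                                  span=cfg.span)
    results.update(captured=captured, cis_scores=scores)
    timings["cis_score"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    expr_filtered = differential.low_count_filter(rna_counts)
    expr_sf = differential.size_factors(expr_filtered)
    expr_vst = bh.vst_expression(expr_filtered, expr_sf)
    prom_norm = differential.normalized_counts(prom_cov)
    peak_norm = differential.normalized_counts(peak_cov)
    profiles = bh.profile_genes(tss["gene_id"], expr_vst, prom_norm,
                                peak_norm, captured)
    if len(profiles) >= cfg.k:
        profiles = bh.cluster_behaviors(profiles, k=cfg.k, seed=cfg.seed)
        labels = profiles["behavior_label"]
        deg = diff["expression"]
        common = labels.index.intersection(deg.index)
        effect = bh.cluster_effect_size_summary(
            labels.loc[common], deg.loc[common, "log2FC"],
            deg.loc[common, "significant"])
        is_b = np.asarray(condition_labels) == sorted(set(condition_labels))[1]
        shared = {}
        for cluster, sub in profiles.groupby("behavior_label"):
            gids = sub.index
            cov_rows = []
            for g in gids:
                cov = bh.build_covariates(g, expr_vst, prom_norm, peak_norm,
                                          captured)
                if cov is not None:
                    cov_rows.append(cov)
            if not cov_rows:
                continue
            def bias(key):
                arr = np.vstack([c[key] for c in cov_rows])
                return arr[:, is_b].mean(axis=1) - arr[:, ~is_b].mean(axis=1)
            shared[cluster] = bh.shared_direction_test(
                bias("enhancer_acc"), bias("promoter_acc"),
                bias("expression"))
        results.update(profiles=profiles, cluster_effect_sizes=effect,
                       shared_direction=shared)
    else:
        logger.warning("too few profilable genes for clustering")
        results.update(profiles=profiles, cluster_effect_sizes=None,
                       shared_direction={})
    timings["behavior"] = time.perf_counter() - t0

    if genome is not None and pwm_library:
        t0 = time.perf_counter()
        conds = tuple(sorted(set(condition_labels)))
        padded = windows.pad_peaks(peaks, chrom_sizes, cfg.pad_peak)
        background = motif.estimate_background(
            motif.extract_sequences(genome, padded))
        deg = diff["expression"]
        de_genes = deg.index[deg["significant"]].tolist()
        tf_pwms = motif.select_de_tfs(de_genes, pwm_library)
        if not tf_pwms:  # fall back to screening the whole library
            tf_pwms = {p.name or p.pwm_id: p for p in pwm_library}
        prof = results.get("profiles")
        sets = {}
        if prof is not None and "behavior_label" in getattr(prof, "columns",
                                                            []):
            sets = assemble_lineage_region_sets(
                prof.reset_index().merge(tss, on="gene_id", how="left"),
                deg, peak_win, diff["peaks"], prom_win, diff["promoters"],
                conds, span=cfg.span)
        universes = {
            "enhancer_centric": motif.extract_sequences(genome, peak_win),
            "combo_centric": motif.extract_sequences(genome, peak_win),
            "promoter_centric": motif.extract_sequences(genome, prom_win),
        }
        p_thr = motif.threshold_from_alpha(cfg.motif_alpha, cfg.win_peak)
        screen = motif.specificity_screen(
            tf_pwms, sets, universes, background,
            n_shuffles=cfg.n_shuffles, seed=cfg.seed, alpha=cfg.alpha,
            p_threshold=p_thr, hit_metric=cfg.hit_metric) if sets else None
        results.update(motif_background=background, tf_pwms=tf_pwms,
                       motif_screen=screen)
        timings["motif"] = time.perf_counter() - t0
    return results


def _checksum(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """File-level pipeline: load inputs, run stages, write outputs."""
    failures = validate_inputs(config)
    if failures:
        raise ValueError("input validation failed: " + "; ".join(failures))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    peaks = read_bed(config.peaks)
    tss = pd.read_csv(config.tss, sep="\t")
    rna = pd.read_csv(config.rna_counts, sep="\t", index_col=0)
    fragments = {s: read_bed(p) for s, p in config.fragments.items()}
    labels = [config.sample_conditions[s] for s in fragments]
    chrom_sizes = dict(config.chrom_sizes)
    if not chrom_sizes:
        if config.genome:
            import pyfaidx
            fa = pyfaidx.Fasta(config.genome)
            chrom_sizes = {name: len(fa[name]) for name in fa.keys()}
        else:
            raise ValueError("chrom_sizes (or a genome FASTA) is required")
    genome = None
    if config.genome:
        import pyfaidx
        genome = pyfaidx.Fasta(config.genome)
    pwm_library = motif.read_jaspar(config.pwms) if config.pwms else None

    results = run_pipeline(
        peaks=peaks, tss=tss, rna_counts=rna, fragments=fragments,
        condition_labels=labels, chrom_sizes=chrom_sizes, genome=genome,
        pwm_library=pwm_library, config=config)

    stage_rows: dict[str, int] = {}
    for name in ("peak_windows", "promoter_windows"):
        results[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)
        stage_rows[name] = len(results[name])
    for name, table in results["differential"].items():
        table.to_csv(out / f"differential_{name}.tsv", sep="\t")
        stage_rows[f"differential_{name}"] = len(table)
    results["cis_scores"].to_csv(out / "cis_scores.tsv", sep="\t")
    stage_rows["cis_scores"] = len(results["cis_scores"])
    prof = results.get("profiles")
    if prof is not None and len(prof):
        prof.to_csv(out / "regulatory_profiles.tsv", sep="\t")
        stage_rows["regulatory_profiles"] = len(prof)
    shared = {
        str(k): {"statistic": v["statistic"], "p": v["p"],
                 "table": np.asarray(v["table"]).tolist()}
        for k, v in results.get("shared_direction", {}).items()}
    with open(out / "cluster_tests.json", "w") as fh:
        json.dump(shared, fh, indent=2)
    screen = results.get("motif_screen")
    if screen is not None:
        screen.to_csv(out / "motif_screen.tsv", sep="\t", index=False)
        stage_rows["motif_screen"] = len(screen)

    manifest = {
        "config": asdict(config),
        "input_checksums": {
            k: _checksum(p) for k, p in
            [("peaks", config.peaks), ("tss", config.tss),
             ("rna_counts", config.rna_counts)]
            + [(f"fragments/{s}", p) for s, p in config.fragments.items()]
            if p},
        "stage_rows": stage_rows,
        "stage_seconds": {k: round(v, 3)
                          for k, v in results["timings"].items()},
        "version": "0.1.0",
    }
    tmp = out / "run_manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2)
    tmp.rename(out / "run_manifest.json")  # atomic publish
    results["manifest"] = manifest
    return results
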