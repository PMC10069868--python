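"""Self-contained synthetic dataset with explicit ground truth.

Emulates a paired two-condition (3 vs 3) ATAC + RNA experiment: an
i.i.d. background genome, TSS models, peaks with planted roles
(promoter / enhancer / decoy) and optional condition bias, per-sample
fragment files whose per-peak counts are negative-binomial
(Var = mu + alpha*mu^2), an RNA count matrix whose expression is driven
by promoter accessibility, distance-weighted enhancer accessibility,
both, or neither, and PWM instances planted into chosen regions.

Every quantity downstream stages try to recover is recorded in truth
tables (per-gene behavior class and condition bias, per-peak role and
bias, per-instance motif plants), and a fixed seed makes every emitted
file byte-identical across runs.

Genes are placed on well-separated loci (about 200 kb apart under the
default configuration) so each gene's +/-100 kb capture window contains
only its own planted peaks plus unassigned decoys; real loci are not
this clean, so recovery rates here bound what the method can do when
regulatory landscapes do not overlap, not what it achieves on tissue
data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from atacrna.cisscore import distance_weight
from atacrna.motif import PWM, write_jaspar

BEHAVIOR_CLASSES = ("unexplained", "promoter_centric", "enhancer_centric",
                    "combo_centric")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the paired 3-vs-3 design at strong archetypal
    effect sizes: a 2-fold-per-log-unit condition effect on biased
    peaks (``effect_size_logfc`` in log2), NB overdispersion 0.05,
    regression drivers of ~1.3 log2 expression units per SD of
    accessibility.
    """

    n_chroms: int = 80
    chrom_length: int = 1_000_000
    n_genes: int = 400
    n_peaks: int = 2000  # total: promoters + enhancers + decoys
    n_samples_per_condition: int = 3
    conditions: tuple[str, str] = ("A", "B")  # A ~ TGFB, B ~ BMP
    effect_size_logfc: float = 2.0
    dispersion: float = 0.05
    fragments_per_sample: int = 600_000
    motif_plant_rate: float = 0.25
    seed: int = 0
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    background_fraction: float = 0.1
    n_enhancers_per_gene: int = 2
    enhancer_min_dist: int = 8_000
    enhancer_max_dist: int = 45_000
    peak_width: int = 400
    fragment_length_range: tuple[int, int] = (80, 220)
    acc_noise_sd: float = 0.25  # per-sample lognormal accessibility noise
    depth_noise_sd: float = 0.05  # per-sample depth factor spread
    promoter_weight: float = 2.0  # accessibility boost of promoter peaks
    enhancer_weight: float = 3.0  # accessibility boost of enhancer peaks
    frac_biased_genes: float = 0.5
    decoy_biased_fraction: float = 0.1
    beta_promoter: float = 1.5
    beta_enhancer: float = 1.5
    beta_interaction: float = 2.2
    beta_additive_combo: float = 0.3
    rna_mean: float = 500.0
    rna_baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_samples_per_condition",
                     "n_peaks", "fragments_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.chrom_length < 300_000:
            raise ValueError("chrom_length must be >= 300000 so that "
                             "+/-100 kb gene loci fit")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9 or len(self.base_freqs) != 4:
            raise ValueError("base_freqs must be 4 values summing to 1")
        if not 0.0 <= self.motif_plant_rate <= 1.0:
            raise ValueError("motif_plant_rate must be in [0, 1]")
        if len(set(self.conditions)) != 2:
            raise ValueError("need two distinct condition labels")
        n_assigned = self.n_genes * (1 + self.n_enhancers_per_gene)
        if self.n_peaks < n_assigned:
            raise ValueError(f"n_peaks={self.n_peaks} cannot host "
                             f"{n_assigned} promoter+enhancer peaks")

    @property
    def sample_names(self) -> list[str]:
        a, b = self.conditions
        n = self.n_samples_per_condition
        return [f"{a}{i+1}" for i in range(n)] + \
               [f"{b}{i+1}" for i in range(n)]

    @property
    def sample_conditions(self) -> list[str]:
        n = self.n_samples_per_condition
        return [self.conditions[0]] * n + [self.conditions[1]] * n

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i+1}" for i in range(self.n_chroms)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    @classmethod
    def small(cls, **overrides) -> "SyntheticConfig":
        """A fast smoke-test-sized configuration."""
        base = dict(n_chroms=3, chrom_length=400_000, n_genes=9,
                    n_peaks=45, fragments_per_sample=30_000, seed=0)
        base.update(overrides)
        return cls(**base)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def generate_genome(cfg: SyntheticConfig,
                    rng: np.random.Generator) -> dict[str, str]:
    """I.i.d. background genome at the configured base frequencies."""
    genome = {}
    p = np.asarray(cfg.base_freqs)
    for chrom in cfg.chrom_names:
        codes = rng.choice(4, size=cfg.chrom_length, p=p)
        genome[chrom] = _BASES[codes].tobytes().decode("ascii")
    return genome


def generate_gene_models(cfg: SyntheticConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """TSS table with strand, behavior class and condition bias.

    TSS are evenly spaced (with +/-2 kb jitter) at least 105 kb from
    chromosome ends; behavior classes cycle through the four archetypes
    and biased genes split evenly between conditions.
    """
    margin = 105_000
    span = cfg.chrom_length - 2 * margin
    per_chrom = [cfg.n_genes // cfg.n_chroms
                 + (1 if i < cfg.n_genes % cfg.n_chroms else 0)
                 for i in range(cfg.n_chroms)]
    if max(per_chrom, default=0) > 0 and span / max(per_chrom) < 1000:
        raise ValueError("chromosome too short to host requested genes")
    rows = []
    gid = 0
    for chrom, g in zip(cfg.chrom_names, per_chrom):
        for i in range(g):
            center = margin + (i + 0.5) * span / g
            tss = int(center + rng.integers(-2000, 2001))
            tss = min(max(tss, margin), cfg.chrom_length - margin)
            rows.append({
                "gene_id": f"gene{gid:04d}", "chrom": chrom, "tss": tss,
                "strand": "+" if rng.random() < 0.5 else "-",
            })
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    if len(genes) == 0:
        genes["behavior_class"] = pd.Series(dtype=str)
        genes["condition_bias"] = pd.Series(dtype=str)
        return genes
    classes = np.array([BEHAVIOR_CLASSES[i % 4] for i in range(len(genes))])
    rng.shuffle(classes)
    genes["behavior_class"] = classes
    bias = np.full(len(genes), "none", dtype=object)
    if cfg.effect_size_logfc != 0:
        drawn = rng.random(len(genes)) < cfg.frac_biased_genes
        direction = rng.random(len(genes)) < 0.5
        bias[drawn & direction] = cfg.conditions[0]
        bias[drawn & ~direction] = cfg.conditions[1]
    bias[classes == "unexplained"] = "none"
    genes["condition_bias"] = bias
    return genes


def _peak_table(cfg: SyntheticConfig, genes: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    half = cfg.peak_width // 2
    rows = []
    for g in genes.itertuples(index=False):
        drives_prom = g.behavior_class in ("promoter_centric", "combo_centric")
        drives_enh = g.behavior_class in ("enhancer_centric", "combo_centric")
        center = int(g.tss + rng.integers(-200, 201))
        rows.append({"chrom": g.chrom, "center": center, "role": "promoter",
                     "gene_id": g.gene_id,
                     "bias": g.condition_bias if drives_prom else "none"})
        for _ in range(cfg.n_enhancers_per_gene):
            d = int(rng.integers(cfg.enhancer_min_dist,
                                 cfg.enhancer_max_dist + 1))
            sign = -1 if rng.random() < 0.5 else 1
            rows.append({"chrom": g.chrom, "center": int(g.tss + sign * d),
                         "role": "enhancer", "gene_id": g.gene_id,
                         "bias": g.condition_bias if drives_enh else "none"})
    n_decoys = cfg.n_peaks - len(rows)
    tss_by_chrom: dict[str, np.ndarray] = {
        c: sub["tss"].to_numpy() for c, sub in genes.groupby("chrom")}
    chroms = cfg.chrom_names
    placed = 0
    while placed < n_decoys:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        center = int(rng.integers(half + 1, cfg.chrom_length - half - 1))
        near_tss = tss_by_chrom.get(chrom)
        if near_tss is not None and np.any(np.abs(near_tss - center) < 6000):
            continue  # keep decoys out of promoter windows
        biased = (cfg.effect_size_logfc != 0
                  and rng.random() < cfg.decoy_biased_fraction)
        bias = (cfg.conditions[int(rng.random() < 0.5)]
                if biased else "none")
        rows.append({"chrom": chrom, "center": center, "role": "decoy",
                     "gene_id": "", "bias": bias})
        placed += 1
    peaks = pd.DataFrame(rows)
    peaks["start"] = peaks["center"] - half
    peaks["end"] = peaks["center"] + (cfg.peak_width - half)
    peaks["name"] = [f"peak{i:05d}" for i in range(len(peaks))]
    peaks["logfc"] = 0.0
    peaks.loc[peaks["bias"] == cfg.conditions[1], "logfc"] = \
        cfg.effect_size_logfc
    peaks.loc[peaks["bias"] == cfg.conditions[0], "logfc"] = \
        -cfg.effect_size_logfc
    return peaks[["chrom", "start", "end", "name", "center", "role",
                  "gene_id", "bias", "logfc"]]


def generate_peaks_and_fragments(cfg: SyntheticConfig, genes: pd.DataFrame,
                                 rng: np.random.Generator
                                 ) -> tuple[pd.DataFrame,
                                            dict[str, pd.DataFrame],
                                            pd.DataFrame]:
    """Peaks with roles, per-sample fragment BED frames, and the
    realized per-peak fragment-count matrix (the accessibility truth).

    Per-peak per-sample counts are NB with mean
    scale * w_p * 2^(+/- logfc/2) * exp(N(0, acc_noise_sd)) * depth_s;
    fragment starts are jittered around the peak center and a
    ``background_fraction`` of fragments lands uniformly on the genome.
    """
    peaks = _peak_table(cfg, genes, rng)
    n_peaks, samples = len(peaks), cfg.sample_names
    role_boost = peaks["role"].map({
        "promoter": cfg.promoter_weight, "enhancer": cfg.enhancer_weight,
        "decoy": 1.0}).to_numpy()
    weights = rng.lognormal(0.0, 0.4, size=n_peaks) * role_boost
    scale = (1 - cfg.background_fraction) * cfg.fragments_per_sample \
        / weights.sum()
    depth = rng.lognormal(0.0, cfg.depth_noise_sd, size=len(samples))
    is_b = np.array([c == cfg.conditions[1] for c in cfg.sample_conditions])
    logfc = peaks["logfc"].to_numpy()
    counts = np.zeros((n_peaks, len(samples)), dtype=np.int64)
    for s in range(len(samples)):
        fold = 2.0 ** (logfc / 2.0 if is_b[s] else -logfc / 2.0)
        noise = rng.lognormal(0.0, cfg.acc_noise_sd, size=n_peaks)
        mu = scale * weights * fold * noise * depth[s]
        lam = rng.gamma(1.0 / cfg.dispersion, mu * cfg.dispersion)
        counts[:, s] = rng.poisson(lam)

    lo, hi = cfg.fragment_length_range
    n_bg = int(round(cfg.background_fraction * cfg.fragments_per_sample))
    centers = peaks["center"].to_numpy()
    chrom_codes = pd.Categorical(peaks["chrom"],
                                 categories=cfg.chrom_names).codes
    fragments: dict[str, pd.DataFrame] = {}
    for s, name in enumerate(samples):
        reps = counts[:, s]
        frag_chrom = np.repeat(chrom_codes, reps)
        frag_center = (np.repeat(centers, reps)
                       + rng.normal(0.0, 150.0, size=reps.sum()))
        lengths = rng.integers(lo, hi + 1, size=reps.sum())
        bg_chrom = rng.integers(0, cfg.n_chroms, size=n_bg)
        bg_start = rng.integers(0, cfg.chrom_length - hi, size=n_bg)
        bg_len = rng.integers(lo, hi + 1, size=n_bg)
        chrom_idx = np.concatenate([frag_chrom, bg_chrom])
        starts = np.concatenate([
            np.rint(frag_center - lengths // 2).astype(np.int64),
            bg_start])
        lens = np.concatenate([lengths, bg_len])
        starts = np.clip(starts, 0, cfg.chrom_length - lens)
        df = pd.DataFrame({
            "chrom": np.asarray(cfg.chrom_names)[chrom_idx],
            "start": starts, "end": starts + lens})
        df["name"] = "."
        fragments[name] = df.sort_values(
            ["chrom", "start"], kind="stable").reset_index(drop=True)
    count_df = pd.DataFrame(counts, index=peaks["name"], columns=samples)
    return peaks, fragments, count_df


def simulate_expression(cfg: SyntheticConfig, genes: pd.DataFrame,
                        peaks: pd.DataFrame, peak_counts: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    """NB RNA counts driven by the realized peak accessibility.

    Per gene the log2 mean is baseline plus, depending on the behavior
    class, beta_promoter * z(promoter counts), beta_enhancer *
    z(distance-weighted enhancer count sum), or (combo) a moderate
    additive part plus a dominant promoter x enhancer interaction.
    Combo genes are interaction-driven so that their synergy is visible
    to the variance partition: with independent covariates a purely
    additive mix would leave no variance beyond the two
    single-predictor models.
    """
    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    samples = list(peak_counts.columns)
    mat = np.zeros((len(genes), len(samples)), dtype=np.int64)
    by_gene = peaks.groupby("gene_id")
    for i, g in enumerate(genes.itertuples(index=False)):
        if g.gene_id not in by_gene.groups:
            raise ValueError(f"gene {g.gene_id} has no assigned peaks")
        own = by_gene.get_group(g.gene_id)
        prom = own[own["role"] == "promoter"]
        enh = own[own["role"] == "enhancer"]
        if len(prom) != 1:
            raise ValueError(f"gene {g.gene_id} lacks a unique promoter peak")
        p_vec = peak_counts.loc[prom["name"].iloc[0]].to_numpy(dtype=float)
        d = np.abs(enh["center"].to_numpy() - g.tss)
        e_vec = distance_weight(d) @ \
            peak_counts.loc[enh["name"]].to_numpy(dtype=float)
        zp, ze = zscore(p_vec), zscore(e_vec)
        base = np.log2(cfg.rna_mean) + rng.normal(0.0, cfg.rna_baseline_sd)
        logmean = np.full(len(samples), base)
        if g.behavior_class == "promoter_centric":
            logmean += cfg.beta_promoter * zp
        elif g.behavior_class == "enhancer_centric":
            logmean += cfg.beta_enhancer * ze
        elif g.behavior_class == "combo_centric":
            logmean += cfg.beta_additive_combo * (zp + ze) \
                + cfg.beta_interaction * zscore(zp * ze)
        mu = np.maximum(2.0 ** logmean, 1e-6)
        lam = rng.gamma(1.0 / cfg.dispersion, mu * cfg.dispersion)
        mat[i] = rng.poisson(lam)
    return pd.DataFrame(mat, index=genes["gene_id"].to_numpy(),
                        columns=samples)


def sample_pwm_instance(pwm: PWM, rng: np.random.Generator) -> str:
    """One site sampled letter-by-letter from the PWM columns."""
    return "".join("ACGT"[rng.choice(4, p=pwm.matrix[j] / pwm.matrix[j].sum())]
                   for j in range(pwm.width))


def plant_motifs(pwm: PWM, regions: pd.DataFrame, rate: float,
                 rng: np.random.Generator, genome: dict[str, str]
                 ) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant PWM instances into a Bernoulli(rate) subset of regions.

    Each selected region receives one instance at a uniform position on
    a uniform strand (minus-strand instances are reverse-complemented
    before insertion). Returns the edited genome and a truth table.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    from atacrna.motif import _revcomp

    buffers = {c: bytearray(s, "ascii") for c, s in genome.items()}
    records = []
    for r in regions.itertuples(index=False):
        if (r.end - r.start) < pwm.width:
            raise ValueError(f"region {r.name} shorter than PWM width")
        if rng.random() >= rate:
            continue
        pos = int(rng.integers(r.start, r.end - pwm.width + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site = sample_pwm_instance(pwm, rng)
        inserted = site if strand == "+" else _revcomp(site)
        buffers[r.chrom][pos:pos + pwm.width] = inserted.encode("ascii")
        records.append({"pwm_id": pwm.pwm_id, "region_id": r.name,
                        "chrom": r.chrom, "position": pos,
                        "strand": strand, "site": site})
    edited = {c: b.decode("ascii") for c, b in buffers.items()}
    truth = pd.DataFrame(records, columns=["pwm_id", "region_id", "chrom",
                                           "position", "strand", "site"])
    return edited, truth


def random_pwm(width: int, rng: np.random.Generator, pwm_id: str = "TF1",
               name: str = "TF1", concentration: float = 0.1) -> PWM:
    """A random informative PWM (near-one-hot Dirichlet columns)."""
    mat = rng.dirichlet([concentration] * 4, size=width)
    return PWM(pwm_id, mat, name=name)


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus writers for the on-disk form."""

    config: SyntheticConfig
    genes: pd.DataFrame
    peaks: pd.DataFrame
    fragments: dict[str, pd.DataFrame]
    peak_counts: pd.DataFrame
    rna_counts: pd.DataFrame
    genome: dict[str, str] | None = None
    pwms: list[PWM] = field(default_factory=list)
    motif_truth: pd.DataFrame | None = None

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.config.chrom_sizes

    @property
    def tss_table(self) -> pd.DataFrame:
        return self.genes[["gene_id", "chrom", "tss", "strand"]]

    def write(self, outdir, include_genome: bool = True) -> dict:
        """Write FASTA/BED/TSV/JASPAR files and a manifest JSON."""
        from pathlib import Path

        out = Path(outdir)
        (out / "fragments").mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        if include_genome and self.genome is not None:
            paths["genome"] = out / "genome.fa"
            with open(paths["genome"], "w") as fh:
                for chrom, seq in self.genome.items():
                    fh.write(f">{chrom}\n")
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i:i + 80] + "\n")
        peaks_bed = self.peaks.copy()
        peaks_bed["score"] = 0
        peaks_bed["strand"] = "."
        paths["peaks"] = out / "peaks.bed"
        peaks_bed[["chrom", "start", "end", "name", "score", "strand"]] \
            .to_csv(paths["peaks"], sep="\t", header=False, index=False)
        for sample, df in self.fragments.items():
            p = out / "fragments" / f"{sample}.bed"
            df[["chrom", "start", "end"]].to_csv(p, sep="\t", header=False,
                                                 index=False)
            paths[f"fragments/{sample}"] = p
        paths["tss"] = out / "tss.tsv"
        self.tss_table.to_csv(paths["tss"], sep="\t", index=False)
        paths["rna_counts"] = out / "rna_counts.tsv"
        self.rna_counts.to_csv(paths["rna_counts"], sep="\t")
        paths["gene_truth"] = out / "gene_truth.tsv"
        self.genes.to_csv(paths["gene_truth"], sep="\t", index=False)
        paths["peak_truth"] = out / "peak_truth.tsv"
        self.peaks.to_csv(paths["peak_truth"], sep="\t", index=False)
        if self.pwms:
            paths["pwms"] = out / "pwms.jaspar"
            write_jaspar(self.pwms, paths["pwms"])
        if self.motif_truth is not None:
            paths["motif_truth"] = out / "motif_truth.tsv"
            self.motif_truth.to_csv(paths["motif_truth"], sep="\t",
                                    index=False)
        manifest = {
            "coordinate_system": "0-based half-open (BED)",
            "seed": self.config.seed,
            "config": asdict(self.config),
            "fragment_totals": {s: int(len(df))
                                for s, df in self.fragments.items()},
            "checksums": {k: hashlib.md5(p.read_bytes()).hexdigest()
                          for k, p in paths.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return manifest


def generate_dataset(cfg: SyntheticConfig, include_genome: bool = False,
                     plant_pwm: PWM | None = None,
                     plant_roles: tuple[str, ...] = ("enhancer",),
                     plant_bias: str | None = None) -> SyntheticDataset:
    """Generate the full dataset from a config.

    ``include_genome`` materializes the FASTA-able sequence (needed for
    motif work only). With ``plant_pwm`` given, instances are planted
    at ``cfg.motif_plant_rate`` into peaks matching ``plant_roles`` and
    (optionally) ``plant_bias``.
    """
    rng_genome, rng_genes, rng_peaks, rng_expr, rng_motif = \
        _rngs(cfg.seed, 5)
    genome = generate_genome(cfg, rng_genome) if include_genome else None
    genes = generate_gene_models(cfg, rng_genes)
    peaks, fragments, peak_counts = \
        generate_peaks_and_fragments(cfg, genes, rng_peaks)
    rna = simulate_expression(cfg, genes, peaks, peak_counts, rng_expr)
    ds = SyntheticDataset(cfg, genes, peaks, fragments, peak_counts, rna,
                          genome=genome)
    if plant_pwm is not None:
        if genome is None:
            raise ValueError("planting motifs requires include_genome=True")
        targets = peaks[peaks["role"].isin(plant_roles)]
        if plant_bias is not None:
            targets = targets[targets["bias"] == plant_bias]
        edited, truth = plant_motifs(plant_pwm, targets,
                                     cfg.motif_plant_rate, rng_motif, genome)
        ds.genome = edited
        ds.pwms = [plant_pwm]
        ds.motif_truth = truth
    return ds
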