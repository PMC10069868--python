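"""PWM scanning with exact p-values and shuffled-background enrichment.

Scanning follows the FIMO convention: log-odds scores of a
position-weight matrix against a Markov background, with a hit
threshold defined by the exact null score distribution (computed by
dynamic programming over integer-scaled scores, granularity 1/1000
bit) at a target p-value; the default threshold p = 2e-4 arises from
alpha / (2 strands x 250 bp of sequence) with alpha = 0.1. Both strands
are scanned and all (possibly overlapping) hits are reported.

Enrichment of a motif in a target region set is measured against an
empirical null: the target set is shuffled n times (uniformly across
the genome avoiding an exclusion set, or by resampling from a peak or
promoter universe), each shuffle is scanned identically, and the
observed hit metric is standardized against the shuffle distribution;
significance comes from the standard-normal CDF of the z statistic,
with Benjamini-Hochberg correction across the TF family tested.

Background estimation, exact-p computation, scanning, shuffling and
the enrichment/overlap statistics are implemented here; PWM file
parsing (JASPAR / minimal MEME) is delegated to Bio.motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
GRANULARITY = 1000  # integer score units per bit
PSEUDOCOUNT = 0.01  # times the background, added before log-odds
DEFAULT_P_THRESHOLD = 2e-4
_SENTINEL = -(10 ** 7)  # per-position score for non-ACGT symbols


def threshold_from_alpha(alpha: float = 0.1, region_length: int = 250,
                         strands: int = 2) -> float:
    """Hit p-value threshold alpha / (strands * region_length)."""
    return alpha / (strands * region_length)


# ---------------------------------------------------------------------------
# PWM

@dataclass
class PWM:
    """Position probability matrix with log-odds scoring support."""

    pwm_id: str
    matrix: np.ndarray  # (width, 4) probabilities
    name: str = ""
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (width, 4)")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"PWM {self.pwm_id}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def information_content(self) -> float:
        """Sum over positions/bases of p*log2(p/q), in bits (0*log0=0)."""
        p = self.matrix
        q = self.background
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / q), 0.0)
        return float(terms.sum())

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """log2((p + pc*q)/(1+pc) / q) per position/base."""
        q = self.background if background is None else np.asarray(background)
        p = (self.matrix + PSEUDOCOUNT * q) / (1.0 + PSEUDOCOUNT)
        return np.log2(p / q)

    def int_log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """Log-odds rounded to integer 1/GRANULARITY-bit units."""
        return np.rint(self.log_odds(background) * GRANULARITY).astype(np.int64)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.pwm_id + "_rc", self.matrix[::-1, ::-1],
                   self.name, self.background)


def read_jaspar(path, background=None) -> list[PWM]:
    """Read a JASPAR-format PWM file (counts or probabilities)."""
    from Bio import motifs as bio_motifs
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    return [_from_biomotif(m, background) for m in parsed]


def read_meme(path, background=None) -> list[PWM]:
    """Read a minimal-MEME-format PWM file."""
    from Bio import motifs as bio_motifs
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    return [_from_biomotif(m, background) for m in parsed]


def _from_biomotif(m, background) -> PWM:
    counts = np.array([[m.counts[b][i] for b in BASES]
                       for i in range(m.length)], dtype=float)
    probs = counts / counts.sum(axis=1, keepdims=True)
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    ident = m.matrix_id if getattr(m, "matrix_id", None) else m.name
    return PWM(str(ident), probs, name=str(m.name or ident), background=bg)


def write_jaspar(pwms: list[PWM], path, counts_scale: int = 100) -> None:
    """Write PWMs as JASPAR-style count matrices."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.pwm_id} {pwm.name or pwm.pwm_id}\n")
            counts = np.rint(pwm.matrix * counts_scale).astype(int)
            for bi, base in enumerate(BASES):
                row = " ".join(str(c) for c in counts[:, bi])
                fh.write(f"{base}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# Markov background

@dataclass
class MarkovBackground:
    """Order-0 (or order-1) background frequencies with pseudocounts.

    Estimated from both strands of a sequence set, mirroring the MEME
    `fasta-get-markov` behavior. Scanning p-values always use the
    order-0 marginal.
    """

    order: int
    frequencies: np.ndarray  # (4,) marginal base probabilities
    conditional: np.ndarray | None = None  # (4, 4) P(b | a) for order 1

    def __post_init__(self) -> None:
        if not np.isclose(self.frequencies.sum(), 1.0, atol=1e-9):
            raise ValueError("background frequencies must sum to 1")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def estimate_background(sequences, order: int = 0,
                        pseudocount: float = 1.0) -> MarkovBackground:
    """Estimate base (and optionally dinucleotide) frequencies.

    Counts both the sequences and their reverse complements; non-ACGT
    symbols are skipped (counted, logged). Pseudocount 1 per symbol
    context.
    """
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    counts = np.zeros(4)
    di = np.zeros((4, 4))
    skipped = 0
    for seq in sequences:
        for s in (seq.upper(), _revcomp(seq).upper()):
            idx = np.array([_BASE_INDEX.get(c, -1) for c in s], dtype=int)
            skipped += int(np.sum(idx < 0))
            valid = idx[idx >= 0]
            np.add.at(counts, valid, 1)
            if order == 1 and len(idx) > 1:
                a, b = idx[:-1], idx[1:]
                ok = (a >= 0) & (b >= 0)
                np.add.at(di, (a[ok], b[ok]), 1)
    if skipped:
        logger.warning("estimate_background: skipped %d non-ACGT symbols",
                       skipped)
    if counts.sum() == 0:
        raise ValueError("no ACGT symbols in input sequences")
    freqs = (counts + pseudocount) / (counts.sum() + 4 * pseudocount)
    cond = None
    if order == 1:
        cond = (di + pseudocount) / (di.sum(axis=1, keepdims=True)
                                     + 4 * pseudocount)
    return MarkovBackground(order, freqs, cond)


# ---------------------------------------------------------------------------
# Exact score distribution and scanning

def score_distribution(pwm: PWM, background: MarkovBackground
                       ) -> tuple[int, np.ndarray]:
    """Exact null distribution of integer log-odds scores.

    Dynamic program over positions under the order-0 background;
    returns (min_score, probs) where probs[i] = P(score == min_score+i).
    """
    lom = pwm.int_log_odds(background.frequencies)
    q = background.frequencies
    mins = lom.min(axis=1)
    dist = np.array([1.0])
    offset = 0
    for j in range(pwm.width):
        span = int(lom[j].max() - mins[j])
        new = np.zeros(len(dist) + span)
        for b in range(4):
            shift = int(lom[j, b] - mins[j])
            new[shift:shift + len(dist)] += q[b] * dist
        dist = new
        offset += int(mins[j])
    return offset, dist


def tail_probabilities(offset: int, probs: np.ndarray) -> np.ndarray:
    """tails[i] = P(score >= offset + i)."""
    return np.cumsum(probs[::-1])[::-1]


def pwm_pvalue_threshold_score(pwm: PWM, background: MarkovBackground,
                               p_threshold: float = DEFAULT_P_THRESHOLD
                               ) -> int:
    """Smallest integer score whose exact upper-tail p <= p_threshold.

    Returns max_score + 1 (unattainable) when even the single best
    outcome exceeds the threshold; p_threshold = 1 returns the minimal
    achievable score.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    offset, probs = score_distribution(pwm, background)
    tails = tail_probabilities(offset, probs)
    ok = np.nonzero(tails <= p_threshold)[0]
    if len(ok) == 0:
        return offset + len(probs)  # no achievable score qualifies
    return offset + int(ok[0])


def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def _window_scores(encoded: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Scores of every window of one strand; non-ACGT positions sink
    the window below any threshold."""
    w = lom.shape[0]
    n = len(encoded) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    ext = np.hstack([lom, np.full((w, 1), _SENTINEL, dtype=np.int64)])
    scores = np.zeros(n, dtype=np.int64)
    for j in range(w):
        scores += ext[j, encoded[j:j + n]]
    return scores


class MotifScanner:
    """Scans sequences for hits of one PWM at an exact-p threshold."""

    def __init__(self, pwm: PWM, background: MarkovBackground,
                 p_threshold: float = DEFAULT_P_THRESHOLD):
        self.pwm = pwm
        self.background = background
        self.p_threshold = p_threshold
        self.threshold_score = pwm_pvalue_threshold_score(
            pwm, background, p_threshold)
        self._lom_fwd = pwm.int_log_odds(background.frequencies)
        self._lom_rev = self._lom_fwd[::-1, ::-1]

    def scan(self, seq: str) -> pd.DataFrame:
        """All hits on both strands: (position, strand, score).

        Positions are 0-based starts on the forward strand; sequences
        shorter than the PWM yield an empty table.
        """
        enc = encode_sequence(seq)
        recs = []
        for strand, lom in (("+", self._lom_fwd), ("-", self._lom_rev)):
            scores = _window_scores(enc, lom)
            for pos in np.nonzero(scores >= self.threshold_score)[0]:
                recs.append((int(pos), strand, int(scores[pos])))
        return pd.DataFrame(recs, columns=["position", "strand", "score"])

    def count_hits(self, seqs) -> np.ndarray:
        """Per-sequence total hit count over both strands."""
        out = np.zeros(len(seqs), dtype=np.int64)
        thr = self.threshold_score
        for i, seq in enumerate(seqs):
            enc = encode_sequence(seq)
            n = 0
            for lom in (self._lom_fwd, self._lom_rev):
                scores = _window_scores(enc, lom)
                n += int(np.sum(scores >= thr))
            out[i] = n
        return out


# ---------------------------------------------------------------------------
# Shuffled-background machinery

def extract_sequences(genome, regions: pd.DataFrame) -> list[str]:
    """Fetch region sequences from a dict-like or pyfaidx genome."""
    out = []
    for r in regions.itertuples(index=False):
        seq = genome[r.chrom][int(r.start):int(r.end)]
        out.append(str(seq))
    return out


def shuffle_regions(regions: pd.DataFrame, mode: str, n_sets: int,
                    rng: np.random.Generator,
                    universe: pd.DataFrame | None = None,
                    chrom_sizes: dict[str, int] | None = None,
                    exclusion: pd.DataFrame | None = None,
                    max_tries: int = 1000) -> list[pd.DataFrame]:
    """Randomized stand-ins for a target region set.

    mode "genome": uniform length-preserving placement across the
    genome, rejecting overlaps with the exclusion set (typically the
    true targets). Universe modes ("peak_universe" /
    "promoter_universe"): sample |regions| members without replacement
    from the supplied universe table.
    """
    if mode in ("peak_universe", "promoter_universe"):
        if universe is None or len(universe) == 0:
            raise ValueError("universe required for universe-mode shuffles")
        if len(universe) < len(regions):
            raise ValueError("universe smaller than the target set")
        return [universe.iloc[rng.choice(len(universe), size=len(regions),
                                         replace=False)].reset_index(drop=True)
                for _ in range(n_sets)]
    if mode != "genome":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    if not chrom_sizes:
        raise ValueError("chrom_sizes required for genome-mode shuffles")
    from intervaltree import IntervalTree
    excl: dict[str, IntervalTree] = {}
    if exclusion is not None:
        for r in exclusion.itertuples(index=False):
            excl.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    lengths = (regions["end"] - regions["start"]).to_numpy()
    sets = []
    for _ in range(n_sets):
        recs = []
        for length in lengths:
            for _try in range(max_tries):
                c = chroms[int(rng.choice(len(chroms), p=weights))]
                limit = chrom_sizes[c] - int(length)
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit + 1))
                tree = excl.get(c)
                if tree is not None and tree.overlap(start, start + int(length)):
                    continue
                recs.append((c, start, start + int(length)))
                break
            else:
                raise RuntimeError(
                    f"could not place a {length}-bp interval after "
                    f"{max_tries} tries; exclusion set too dense")
        sets.append(pd.DataFrame(recs, columns=["chrom", "start", "end"]))
    return sets


def _hit_metric(counts: np.ndarray, metric: str) -> float:
    if metric == "total":
        return float(counts.sum())
    if metric == "seqs_with_hit":
        return float(np.sum(counts > 0))
    raise ValueError(f"unknown hit metric {metric!r}")


def standardized_enrichment(observed: float, background_values: np.ndarray,
                            pwm_id: str = "", region_set_id: str = "") -> dict:
    """z and normal-CDF tail p-values of an observed hit metric against
    a shuffle background; sd = 0 yields p_enrich = 1 with a flag."""
    bg = np.asarray(background_values, dtype=float)
    mean_bg, sd_bg = float(bg.mean()), float(bg.std(ddof=1))
    if sd_bg == 0:
        return {"pwm_id": pwm_id, "region_set_id": region_set_id,
                "observed_hits": observed, "mean_bg": mean_bg, "sd_bg": 0.0,
                "z": np.nan, "p_enrich": 1.0, "p_deplete": 1.0,
                "n_shuffles": len(bg), "degenerate": True}
    z = (observed - mean_bg) / sd_bg
    return {"pwm_id": pwm_id, "region_set_id": region_set_id,
            "observed_hits": observed, "mean_bg": mean_bg, "sd_bg": sd_bg,
            "z": float(z), "p_enrich": float(stats.norm.sf(z)),
            "p_deplete": float(stats.norm.cdf(z)),
            "n_shuffles": len(bg), "degenerate": False}


def enrichment_test(target_seqs, shuffle_seq_sets, pwm: PWM,
                    background: MarkovBackground,
                    p_threshold: float = DEFAULT_P_THRESHOLD,
                    hit_metric: str = "total",
                    region_set_id: str = "") -> dict:
    """Shuffle-background enrichment of one motif in one sequence set.

    Observed and per-shuffle hit metrics are computed identically; at
    least 30 shuffle sets are required.
    """
    shuffle_seq_sets = list(shuffle_seq_sets)
    if len(shuffle_seq_sets) < 30:
        raise ValueError("need >= 30 shuffle sets")
    scanner = MotifScanner(pwm, background, p_threshold)
    observed = _hit_metric(scanner.count_hits(target_seqs), hit_metric)
    bg = np.array([_hit_metric(scanner.count_hits(s), hit_metric)
                   for s in shuffle_seq_sets])
    return standardized_enrichment(observed, bg, pwm.pwm_id, region_set_id)


def enrichment_test_universe(target_idx, universe_seqs, pwm: PWM,
                             background: MarkovBackground,
                             n_shuffles: int, rng: np.random.Generator,
                             p_threshold: float = DEFAULT_P_THRESHOLD,
                             hit_metric: str = "total",
                             region_set_id: str = "",
                             per_seq_counts: np.ndarray | None = None) -> dict:
    """Universe-resampling enrichment (fast path).

    Per-sequence hit counts over the universe are computed once (or
    passed in precomputed) and shuffle sets are index resamples without
    replacement, so the null is exactly the universe-shuffle null at a
    fraction of the scanning cost.
    """
    if n_shuffles < 30:
        raise ValueError("need >= 30 shuffle sets")
    target_idx = np.asarray(target_idx, dtype=int)
    if len(target_idx) > len(universe_seqs):
        raise ValueError("universe smaller than the target set")
    if per_seq_counts is None:
        scanner = MotifScanner(pwm, background, p_threshold)
        per_seq_counts = scanner.count_hits(universe_seqs)
    observed = _hit_metric(per_seq_counts[target_idx], hit_metric)
    bg = np.empty(n_shuffles)
    n_univ = len(universe_seqs)
    for i in range(n_shuffles):
        idx = rng.choice(n_univ, size=len(target_idx), replace=False)
        bg[i] = _hit_metric(per_seq_counts[idx], hit_metric)
    return standardized_enrichment(observed, bg, pwm.pwm_id, region_set_id)


def adjust_family(results: pd.DataFrame, p_column: str = "p_enrich",
                  alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust one family of enrichment tests (family size recorded)."""
    out = results.copy()
    out["padj"] = multipletests(out[p_column].to_numpy(),
                                method="fdr_bh")[1]
    out["significant"] = out["padj"] < alpha
    out["family_size"] = len(out)
    return out


# ---------------------------------------------------------------------------
# TF selection, specificity, diagnostics, ChIP overlap

def select_de_tfs(de_genes, motif_library: list[PWM]) -> dict[str, PWM]:
    """Differentially expressed TFs with one PWM each.

    Matches DE gene symbols against PWM names case-insensitively;
    among duplicates the highest-information-content matrix is
    retained (ties: first in library order, logged).
    """
    if not motif_library:
        raise ValueError("empty motif library")
    de_upper = {str(g).upper() for g in de_genes}
    chosen: dict[str, PWM] = {}
    for pwm in motif_library:
        key = (pwm.name or pwm.pwm_id).upper()
        if key not in de_upper:
            continue
        if key in chosen:
            prev = chosen[key]
            if pwm.information_content > prev.information_content:
                chosen[key] = pwm
            elif pwm.information_content == prev.information_content:
                logger.info("IC tie for %s; keeping first matrix %s",
                            key, prev.pwm_id)
        else:
            chosen[key] = pwm
    if not chosen:
        logger.warning("no DE gene has a PWM in the library")
    return chosen


def specificity_screen(tf_pwms: dict[str, PWM],
                       region_sets: dict[tuple[str, str], np.ndarray],
                       universes: dict[str, list],
                       background: MarkovBackground,
                       n_shuffles: int = 100, seed: int = 0,
                       alpha: float = 0.05,
                       p_threshold: float = DEFAULT_P_THRESHOLD,
                       hit_metric: str = "total") -> pd.DataFrame:
    """Matched- vs opposite-direction motif enrichment matrix.

    ``region_sets`` maps (lineage, regulatory_class) to index arrays
    into the class's universe sequence list (``universes[class]``). A
    TF is called specific to a lineage within a class when its
    enrichment is significant (BH-adjusted within the (lineage, class)
    family) in that lineage's set and not significant in the opposite
    lineage's set. Empty sets are marked untestable.
    """
    rng = np.random.default_rng(seed)
    count_cache: dict[tuple[str, str], np.ndarray] = {}
    rows = []
    for (lineage, rclass), idx in sorted(region_sets.items()):
        universe = universes[rclass]
        for tf, pwm in sorted(tf_pwms.items()):
            if len(idx) == 0:
                rows.append({"tf": tf, "lineage": lineage, "class": rclass,
                             "pwm_id": pwm.pwm_id, "untestable": True,
                             "z": np.nan, "p_enrich": np.nan,
                             "p_deplete": np.nan, "observed_hits": np.nan,
                             "mean_bg": np.nan, "sd_bg": np.nan})
                continue
            key = (rclass, tf)
            if key not in count_cache:
                scanner = MotifScanner(pwm, background, p_threshold)
                count_cache[key] = scanner.count_hits(universe)
            res = enrichment_test_universe(
                idx, universe, pwm, background, n_shuffles, rng,
                p_threshold, hit_metric,
                region_set_id=f"{lineage}/{rclass}",
                per_seq_counts=count_cache[key])
            res.update({"tf": tf, "lineage": lineage, "class": rclass,
                        "untestable": False})
            rows.append(res)
    out = pd.DataFrame(rows)
    out["padj"] = np.nan
    out["significant"] = False
    for (lineage, rclass), grp in out.groupby(["lineage", "class"]):
        testable = grp[~grp["untestable"]]
        if len(testable) == 0:
            continue
        padj = multipletests(testable["p_enrich"].to_numpy(),
                             method="fdr_bh")[1]
        out.loc[testable.index, "padj"] = padj
        out.loc[testable.index, "significant"] = padj < alpha
    # lineage-specificity calls per (tf, class)
    out["specific_to"] = None
    lineages = sorted({lin for lin, _ in region_sets})
    if len(lineages) == 2:
        a, b = lineages
        for (tf, rclass), grp in out.groupby(["tf", "class"]):
            by_lin = grp.set_index("lineage")
            if a not in by_lin.index or b not in by_lin.index:
                continue
            sig_a = bool(by_lin.loc[a, "significant"])
            sig_b = bool(by_lin.loc[b, "significant"])
            call = a if (sig_a and not sig_b) else (
                b if (sig_b and not sig_a) else None)
            out.loc[grp.index, "specific_to"] = call
    return out


def ic_hit_fraction_diagnostic(tf_pwms: dict[str, PWM], seqs,
                               background: MarkovBackground,
                               p_threshold: float = DEFAULT_P_THRESHOLD
                               ) -> dict:
    """Per-TF (IC, fraction of sequences with >= 1 hit) + Pearson r.

    Checks whether promiscuous hit rates reflect low matrix
    information content. Requires >= 3 TFs; zero variance on either
    axis reports r as undefined.
    """
    if len(tf_pwms) < 3:
        raise ValueError("need >= 3 TFs for the IC diagnostic")
    rows = []
    for tf, pwm in sorted(tf_pwms.items()):
        scanner = MotifScanner(pwm, background, p_threshold)
        counts = scanner.count_hits(seqs)
        rows.append({"tf": tf, "pwm_id": pwm.pwm_id,
                     "ic": pwm.information_content,
                     "hit_fraction": float(np.mean(counts > 0))})
    table = pd.DataFrame(rows)
    if table["ic"].nunique() < 2 or table["hit_fraction"].nunique() < 2:
        logger.warning("zero variance on an axis; correlation undefined")
        return {"table": table, "pearson_r": np.nan, "p": np.nan}
    r, p = stats.pearsonr(table["ic"], table["hit_fraction"])
    return {"table": table, "pearson_r": float(r), "p": float(p)}


def chip_overlap_test(target: pd.DataFrame, chip_peaks: pd.DataFrame,
                      universe: pd.DataFrame) -> dict:
    """Upper-tail hypergeometric test of ChIP-peak overlap.

    N = |universe|, K = universe regions overlapping >= 1 ChIP peak,
    n = |target|, k = target regions overlapping; p = P(X >= k). The
    target must be a subset of the universe.
    """
    from atacrna.intervals import overlap_mask

    univ_keys = set(zip(universe["chrom"], universe["start"],
                        universe["end"]))
    for r in target.itertuples(index=False):
        if (r.chrom, r.start, r.end) not in univ_keys:
            raise ValueError("target region not contained in the universe")
    N = len(universe)
    K = int(overlap_mask(universe, chip_peaks).sum())
    n = len(target)
    k = int(overlap_mask(target, chip_peaks).sum())
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    return {"N": N, "K": K, "n": n, "k": k, "p": min(p, 1.0)}
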