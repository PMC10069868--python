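"""Sliding-window refinement of peaks and promoters.

Each called peak is padded to a fixed 1000 bp anchor around its center
and tiled with 250 bp windows in 50 bp steps (16 windows); each promoter
span is the TSS +/- 5 kb tiled with 2000 bp windows in 50 bp steps (161
windows). Per-sample window coverage (summed per-base fragment depth) is
smoothed per sample -- windows more than one standard deviation from the
region's mean are replaced by the average of their neighbors' original
values -- and the window with the greatest cross-sample 75th-percentile
smoothed coverage is selected to represent the region. Differential
testing downstream uses the selected window's RAW coverage; smoothing
only influences which window is chosen, so a transiently extreme window
does not define the region.

Numerical conventions (the source methods leave these open): the 75th
percentile interpolates linearly between order statistics; the standard
deviation uses the n-1 denominator (sigma = 0 means no replacement);
edge windows use their single neighbor; replacements read neighbors'
pre-replacement values so the result is order-independent; selection
ties break to the leftmost window; anchors running off a chromosome end
are clipped (and logged), not discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from atacrna.intervals import GenomicInterval

logger = logging.getLogger(__name__)

PEAK_PAD = 1000
PEAK_WINDOW = 250
PROMOTER_PAD = 5000
PROMOTER_WINDOW = 2000
STEP = 50


@dataclass
class WindowedRegion:
    """A padded peak or promoter with its sliding windows and coverage."""

    region_id: str
    source_kind: str  # "peak" or "promoter"
    anchor: GenomicInterval
    window_starts: np.ndarray
    window_length: int
    raw_coverage: np.ndarray | None = None  # (n_windows, n_samples)
    smoothed_coverage: np.ndarray | None = None
    selected_index: int | None = None
    sample_names: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    @property
    def windows(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.anchor.chrom, int(s), int(s) + self.window_length)
            for s in self.window_starts
        ]

    @property
    def selected_window(self) -> GenomicInterval:
        if self.selected_index is None:
            raise ValueError("representative window not selected yet")
        s = int(self.window_starts[self.selected_index])
        return GenomicInterval(self.anchor.chrom, s, s + self.window_length)

    @property
    def representative_raw_coverage(self) -> np.ndarray:
        if self.selected_index is None or self.raw_coverage is None:
            raise ValueError("coverage/selection not computed yet")
        return self.raw_coverage[self.selected_index]


def pad_peaks(peaks: pd.DataFrame, chrom_sizes: dict[str, int],
              size: int = PEAK_PAD) -> pd.DataFrame:
    """Pad each peak to ``size`` bp centered on its midpoint.

    Anchors exceeding chromosome bounds are clipped (logged). Identical
    padded anchors are deduplicated (pooling); each surviving anchor
    keeps the name of its first contributing peak.
    """
    centers = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    half = size // 2
    starts = centers - half
    ends = centers + (size - half)
    out = pd.DataFrame({
        "chrom": peaks["chrom"].to_numpy(),
        "start": starts,
        "end": ends,
        "name": peaks["name"].to_numpy(),
    })
    lengths = out["chrom"].map(chrom_sizes)
    clip_lo = out["start"] < 0
    clip_hi = out["end"] > lengths
    n_clip = int(clip_lo.sum() + clip_hi.sum())
    if n_clip:
        logger.warning("clipped %d padded peak anchors at chromosome bounds",
                       n_clip)
    out.loc[clip_lo, "start"] = 0
    out["end"] = np.minimum(out["end"], lengths)
    out = out.drop_duplicates(subset=["chrom", "start", "end"],
                              keep="first").reset_index(drop=True)
    return out


def slide_windows(anchor: GenomicInterval, window: int,
                  step: int = STEP) -> np.ndarray:
    """Window start offsets tiling the anchor: 0, step, ... while the
    window fits fully inside; count = floor((len-window)/step) + 1."""
    if step <= 0:
        raise ValueError("step must be positive")
    length = len(anchor)
    if window > length:
        raise ValueError(f"window {window} exceeds anchor length {length}")
    n = (length - window) // step + 1
    return anchor.start + step * np.arange(n)


def _coverage_prefix(fragments: pd.DataFrame, chrom: str,
                     chrom_length: int) -> np.ndarray:
    """Prefix sums S such that per-base depth summed over [a,b) is
    S[b]-S[a]; fragments clipped to the chromosome."""
    diff = np.zeros(chrom_length + 1, dtype=np.int64)
    sub = fragments[fragments["chrom"] == chrom]
    if len(sub):
        starts = np.clip(sub["start"].to_numpy(), 0, chrom_length)
        ends = np.clip(sub["end"].to_numpy(), 0, chrom_length)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
    depth = np.cumsum(diff[:-1])
    return np.concatenate([[0], np.cumsum(depth)])


def window_coverage(regions: list[WindowedRegion],
                    fragments: dict[str, pd.DataFrame],
                    chrom_sizes: dict[str, int]) -> None:
    """Fill ``raw_coverage`` (windows x samples, per-base depth sums)
    for every region, in place.

    Chromosomes absent from a fragment file contribute zero coverage
    (logged once per sample).
    """
    sample_names = list(fragments)
    by_chrom: dict[str, list[WindowedRegion]] = {}
    for reg in regions:
        reg.sample_names = sample_names
        reg.raw_coverage = np.zeros((reg.n_windows, len(sample_names)),
                                    dtype=np.int64)
        by_chrom.setdefault(reg.anchor.chrom, []).append(reg)
    for chrom, regs in by_chrom.items():
        if chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        length = chrom_sizes[chrom]
        for s_idx, name in enumerate(sample_names):
            frag = fragments[name]
            if not (frag["chrom"] == chrom).any():
                logger.warning("sample %s has no fragments on %s", name, chrom)
                continue
            prefix = _coverage_prefix(frag, chrom, length)
            for reg in regs:
                starts = reg.window_starts
                ends = np.minimum(starts + reg.window_length, length)
                reg.raw_coverage[:, s_idx] = prefix[ends] - prefix[starts]


def smoothen(raw_coverage: np.ndarray) -> np.ndarray:
    """Replace per-sample outlier windows by their neighbors' average.

    Per sample: windows whose coverage falls strictly outside one sample
    standard deviation of the region mean take the mean of the two
    adjacent windows' original values (edge windows: the single
    neighbor). Fewer than 3 windows: pass-through with a warning.
    """
    raw = np.asarray(raw_coverage, dtype=float)
    n_win = raw.shape[0]
    if n_win < 3:
        logger.warning("smoothen: fewer than 3 windows, passing through")
        return raw.copy()
    mu = raw.mean(axis=0)
    sigma = raw.std(axis=0, ddof=1)
    outlier = np.abs(raw - mu) > sigma  # sigma == 0 -> no replacement
    neighbor_mean = np.empty_like(raw)
    neighbor_mean[1:-1] = (raw[:-2] + raw[2:]) / 2.0
    neighbor_mean[0] = raw[1]
    neighbor_mean[-1] = raw[-2]
    return np.where(outlier, neighbor_mean, raw)


def select_representative(smoothed: np.ndarray,
                          raw: np.ndarray) -> tuple[int, np.ndarray]:
    """Select the window maximizing the cross-sample 75th percentile of
    SMOOTHED coverage; return (index, RAW coverage of that window).

    Ties break to the leftmost window.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    raw = np.asarray(raw)
    if smoothed.shape != raw.shape:
        raise ValueError("smoothed and raw matrices must share shape")
    if smoothed.size == 0:
        raise ValueError("empty coverage matrix")
    q75 = np.percentile(smoothed, 75, axis=1)  # linear interpolation
    idx = int(np.argmax(q75))  # argmax returns the first (leftmost) max
    return idx, raw[idx].copy()


def peak_regions(peaks: pd.DataFrame, chrom_sizes: dict[str, int],
                 pad: int = PEAK_PAD, window: int = PEAK_WINDOW,
                 step: int = STEP) -> list[WindowedRegion]:
    """Padded-peak WindowedRegions (coverage not yet computed)."""
    padded = pad_peaks(peaks, chrom_sizes, size=pad)
    out = []
    for r in padded.itertuples(index=False):
        anchor = GenomicInterval(r.chrom, int(r.start), int(r.end))
        win = min(window, len(anchor))
        out.append(WindowedRegion(
            region_id=str(r.name), source_kind="peak", anchor=anchor,
            window_starts=slide_windows(anchor, win, step),
            window_length=win))
    return out


def promoter_regions(tss: pd.DataFrame, chrom_sizes: dict[str, int],
                     pad: int = PROMOTER_PAD, window: int = PROMOTER_WINDOW,
                     step: int = STEP) -> list[WindowedRegion]:
    """TSS +/- pad promoter WindowedRegions (strand-symmetric anchors).

    ``tss`` columns: gene_id, chrom, tss, strand. Anchors are clipped at
    chromosome ends (logged).
    """
    out = []
    n_clipped = 0
    for r in tss.itertuples(index=False):
        length = chrom_sizes[r.chrom]
        start, end = int(r.tss) - pad, int(r.tss) + pad
        if start < 0 or end > length:
            n_clipped += 1
            start, end = max(0, start), min(end, length)
        anchor = GenomicInterval(r.chrom, start, end)
        win = min(window, len(anchor))
        out.append(WindowedRegion(
            region_id=str(r.gene_id), source_kind="promoter", anchor=anchor,
            window_starts=slide_windows(anchor, win, step),
            window_length=win))
    if n_clipped:
        logger.warning("clipped %d promoter anchors at chromosome ends",
                       n_clipped)
    return out


def optimize_regions(regions: list[WindowedRegion],
                     fragments: dict[str, pd.DataFrame],
                     chrom_sizes: dict[str, int]) -> None:
    """Coverage -> smoothing -> representative selection, in place."""
    window_coverage(regions, fragments, chrom_sizes)
    for reg in regions:
        reg.smoothed_coverage = smoothen(reg.raw_coverage)
        reg.selected_index, _ = select_representative(
            reg.smoothed_coverage, reg.raw_coverage)


def representative_matrix(regions: list[WindowedRegion]) -> pd.DataFrame:
    """Features x samples matrix of selected-window RAW coverages."""
    if not regions:
        return pd.DataFrame()
    data = np.vstack([reg.representative_raw_coverage for reg in regions])
    return pd.DataFrame(data, index=[reg.region_id for reg in regions],
                        columns=regions[0].sample_names)


def selected_windows_frame(regions: list[WindowedRegion]) -> pd.DataFrame:
    """BED-like table of each region's selected window."""
    recs = []
    for reg in regions:
        w = reg.selected_window
        recs.append((w.chrom, w.start, w.end, reg.region_id,
                     reg.source_kind))
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "name",
                                       "source_kind"])
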