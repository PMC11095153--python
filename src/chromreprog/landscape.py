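"""Histone-mark landscape analytics.

Peak dynamics between conditions (presence/absence by interval overlap),
genomic-region annotation, promoter state typing including bivalency
(H3K4me3 + H3K27me3 co-occupancy of the promoter window), active-enhancer
definition (non-promoter H3K27ac peaks), and modification-expression
correlation.  The promoter window is TSS +/- 2.5 kb throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneAnnotation, PeakSet, SignalTrack

PROMOTER_HALFWIDTH = 2500


@dataclass
class PeakDynamics:
    """Conserved / lost / gained peaks between two conditions."""

    conserved: pd.DataFrame
    lost: pd.DataFrame
    gained: pd.DataFrame

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.conserved), len(self.lost), len(self.gained)


@dataclass
class EnhancerSet:
    """Active enhancers: the enhancer mark's peaks outside promoter windows."""

    peaks: PeakSet

    def __len__(self) -> int:
        return len(self.peaks)


def _trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in peaks.df.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def _overlaps(trees: dict[str, IntervalTree], chrom: str, start: int, end: int,
              min_overlap_bp: int = 1) -> bool:
    tree = trees.get(chrom)
    if tree is None:
        return False
    for iv in tree.overlap(start, end):
        if min(iv.end, end) - max(iv.begin, start) >= min_overlap_bp:
            return True
    return False


def classify_peak_dynamics(peaks1: PeakSet, peaks2: PeakSet,
                           min_overlap_bp: int = 1) -> PeakDynamics:
    """Overlap-based peak dynamics.

    A condition-1 peak overlapping any condition-2 peak by at least
    ``min_overlap_bp`` is conserved, otherwise lost; condition-2 peaks with no
    such overlap are gained.  The three categories partition the union of both
    inputs, and swapping conditions swaps lost and gained exactly.
    """
    trees2 = _trees(peaks2)
    trees1 = _trees(peaks1)
    mask1 = np.array([
        _overlaps(trees2, r.chrom, r.start, r.end, min_overlap_bp)
        for r in peaks1.df.itertuples(index=False)], dtype=bool) \
        if len(peaks1) else np.zeros(0, dtype=bool)
    mask2 = np.array([
        _overlaps(trees1, r.chrom, r.start, r.end, min_overlap_bp)
        for r in peaks2.df.itertuples(index=False)], dtype=bool) \
        if len(peaks2) else np.zeros(0, dtype=bool)
    return PeakDynamics(
        conserved=peaks1.df[mask1].reset_index(drop=True),
        lost=peaks1.df[~mask1].reset_index(drop=True),
        gained=peaks2.df[~mask2].reset_index(drop=True),
    )


def annotate_regions(peaks: PeakSet, genes: GeneAnnotation,
                     exons: PeakSet | None = None,
                     promoter_halfwidth: int = PROMOTER_HALFWIDTH,
                     ) -> tuple[pd.Series, dict[str, int]]:
    """One category per peak by midpoint, precedence promoter > exon > intron > distal.

    ``intron`` means the midpoint falls in a gene body (annotation ``start`` /
    ``end`` columns) without hitting an exon.  Returns the per-peak category
    series and the category counts.
    """
    prom = genes.promoter_windows(halfwidth=promoter_halfwidth)
    prom_trees: dict[str, IntervalTree] = {}
    for r in prom.itertuples(index=False):
        prom_trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    exon_trees = _trees(exons) if exons is not None else {}
    body_trees: dict[str, IntervalTree] = {}
    if {"start", "end"} <= set(genes.df.columns):
        for r in genes.df.itertuples(index=False):
            if r.end > r.start:
                body_trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)

    cats = []
    for r in peaks.df.itertuples(index=False):
        mid = (r.start + r.end) // 2
        if _overlaps(prom_trees, r.chrom, mid, mid + 1):
            cats.append("promoter")
        elif _overlaps(exon_trees, r.chrom, mid, mid + 1):
            cats.append("exon")
        elif _overlaps(body_trees, r.chrom, mid, mid + 1):
            cats.append("intron")
        else:
            cats.append("distal")
    series = pd.Series(cats, dtype=str)
    counts = {c: int((series == c).sum())
              for c in ("promoter", "exon", "intron", "distal")}
    return series, counts


def promoter_state(k4: PeakSet, k27: PeakSet, genes: GeneAnnotation,
                   promoter_halfwidth: int = PROMOTER_HALFWIDTH) -> pd.Series:
    """Promoter state per gene from the 2x2 mark-overlap truth table.

    bivalent = both an H3K4me3 and an H3K27me3 peak overlap the promoter
    window [tss - hw, tss + hw).
    """
    k4_trees = _trees(k4)
    k27_trees = _trees(k27)
    prom = genes.promoter_windows(halfwidth=promoter_halfwidth)
    states = {}
    for r in prom.itertuples(index=False):
        has4 = _overlaps(k4_trees, r.chrom, r.start, r.end)
        has27 = _overlaps(k27_trees, r.chrom, r.start, r.end)
        if has4 and has27:
            states[r.gene_id] = "bivalent"
        elif has4:
            states[r.gene_id] = "K4_only"
        elif has27:
            states[r.gene_id] = "K27_only"
        else:
            states[r.gene_id] = "none"
    return pd.Series(states, name="state")


def bivalent_transition_table(states1: pd.Series, states2: pd.Series,
                              diff: pd.DataFrame) -> pd.DataFrame:
    """Mark changes at bivalent promoters of significantly altered genes.

    Restricted to genes bivalent in condition 1 and significant in ``diff``:
    rows {up, down} by log2fc sign, columns {lost_K27, lost_K4, stable} by
    whether the promoter's H3K27me3 or H3K4me3 overlap disappeared in
    condition 2 (a promoter-window change, not genome-wide peak identity).
    """
    table = pd.DataFrame(0, index=["up", "down"],
                         columns=["lost_K27", "lost_K4", "stable"])
    sig = diff[diff.get("significant", pd.Series(False, index=diff.index))]
    for gene in sig.index:
        if states1.get(gene) != "bivalent":
            continue
        direction = "up" if sig.loc[gene, "log2fc"] > 0 else "down"
        s2 = states2.get(gene, "none")
        had_k27 = s2 in ("bivalent", "K27_only")
        had_k4 = s2 in ("bivalent", "K4_only")
        if not had_k27 and had_k4:
            col = "lost_K27"
        elif not had_k4 and had_k27:
            col = "lost_K4"
        elif not had_k4 and not had_k27:
            # both marks gone: count by the direction-relevant loss
            col = "lost_K27" if direction == "up" else "lost_K4"
        else:
            col = "stable"
        table.loc[direction, col] += 1
    return table


def promoter_signal(track: SignalTrack, genes: GeneAnnotation,
                    halfwidth: int = PROMOTER_HALFWIDTH,
                    chrom_lengths: dict[str, int] | None = None) -> pd.Series:
    """Length-weighted mean per-bp signal over each promoter window.

    Windows are clipped at chromosome ends (position 0 and, when lengths are
    supplied, the chromosome length).
    """
    out = {}
    for r in genes.df.itertuples(index=False):
        start = max(r.tss - halfwidth, 0)
        end = r.tss + halfwidth
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[r.chrom])
        if r.chrom not in track.values:
            out[r.gene_id] = np.nan
            continue
        end = min(end, len(track.values[r.chrom]) * track.bin_size)
        out[r.gene_id] = track.mean_over_interval(r.chrom, start, end)
    return pd.Series(out, name="promoter_signal")


def modification_expression_correlation(signal_lfc: pd.Series,
                                        expr_lfc: pd.Series,
                                        restrict: set | None = None,
                                        ) -> tuple[float, float, int]:
    """Pearson correlation of promoter-mark log2FC against expression log2FC.

    Returns (r, two-sided p, n) over the gene intersection, optionally
    restricted to a significant set.
    """
    common = signal_lfc.index.intersection(expr_lfc.index)
    if restrict is not None:
        common = common.intersection(pd.Index(list(restrict)))
    x = signal_lfc.loc[common].astype(float)
    y = expr_lfc.loc[common].astype(float)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 genes for correlation, have {len(x)}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate input: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(x))


def define_enhancers(k27ac: PeakSet, genes: GeneAnnotation,
                     promoter_halfwidth: int = PROMOTER_HALFWIDTH) -> EnhancerSet:
    """Non-promoter H3K27ac peaks are the active enhancers.

    Any peak overlapping any promoter window (by >= 1 bp) is removed; the
    remainder keeps its signal.
    """
    prom = genes.promoter_windows(halfwidth=promoter_halfwidth)
    trees: dict[str, IntervalTree] = {}
    for r in prom.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    keep = [not _overlaps(trees, r.chrom, r.start, r.end)
            for r in k27ac.df.itertuples(index=False)]
    return EnhancerSet(peaks=PeakSet(k27ac.df[keep].reset_index(drop=True)))


def enhancer_dynamics(enh1: EnhancerSet, enh2: EnhancerSet,
                      min_overlap_bp: int = 1) -> dict[str, int]:
    """Shared / silenced / activated enhancer counts (overlap rule)."""
    dyn = classify_peak_dynamics(enh1.peaks, enh2.peaks, min_overlap_bp)
    c, l, g = dyn.counts
    return {"shared": c, "silenced": l, "activated": g}


def signal_at_regions(track: SignalTrack, regions: list[tuple[str, int]],
                      flank_bins: int) -> np.ndarray:
    """Mean signal profile across aligned regions.

    ``regions`` are (chrom, position) anchor points; the profile covers bin
    offsets -flank..+flank around each anchor's bin, averaging across regions
    (anchors whose window runs off the chromosome are clipped per offset).
    """
    width = 2 * flank_bins + 1
    total = np.zeros(width)
    count = np.zeros(width)
    for chrom, pos in regions:
        vec = track.values[chrom]
        center = pos // track.bin_size
        for k, off in enumerate(range(-flank_bins, flank_bins + 1)):
            b = center + off
            if 0 <= b < len(vec):
                total[k] += vec[b]
                count[k] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)
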