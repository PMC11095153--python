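"""Activity-by-contact (ABC) promoter-enhancer scoring and the ABC-P2 variant.

For each gene, candidate enhancers are the active-enhancer intervals whose
midpoint lies within +/- 1 Mb of the TSS.  Each enhancer's activity score A is
its calibrated summed H3K27ac signal; its contact score C is the 5 kb-binned
contact count between the TSS bin and the enhancer-midpoint bin, normalized to
contacts-per-million of that chromosome's cis total (so C is invariant to
sequencing depth).  ABC = sum over enhancers of A * C — a plain sum, with no
denominator over candidate elements.  The promoter score P is the calibrated
mean H3K4me3 signal over TSS +/- 2.5 kb, and ABC-P2 = ABC * P**2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ContactMap, GeneAnnotation, SignalTrack
from .diffstats import NormalizationFactors
from .landscape import EnhancerSet

ABC_WINDOW = 1_000_000
ABC_RESOLUTION = 5_000
PROMOTER_HALFWIDTH = 2500


@dataclass
class ABCRecord:
    """Per-gene ABC decomposition."""

    gene_id: str
    enhancers: list[tuple[tuple[str, int, int], float, float, float]] = field(
        default_factory=list)  # (interval, A, C, A*C)
    abc: float = 0.0
    p_score: float = 0.0

    @property
    def abc_p2(self) -> float:
        return self.abc * self.p_score ** 2


def candidate_enhancers(gene, enhancers: EnhancerSet,
                        window: int = ABC_WINDOW) -> pd.DataFrame:
    """Enhancers whose midpoint lies in [tss - window, tss + window)."""
    df = enhancers.peaks.df
    sub = df[df["chrom"] == gene.chrom]
    mids = (sub["start"] + sub["end"]) // 2
    keep = (mids >= gene.tss - window) & (mids < gene.tss + window)
    return sub[keep]


def activity_A(enhancer, k27ac_track: SignalTrack, factor: float = 1.0) -> float:
    """A = summed per-bp enhancer-mark signal over the interval, calibrated."""
    return k27ac_track.sum_over_interval(
        enhancer.chrom, enhancer.start, enhancer.end) * factor


def contact_C(gene, enhancer, contacts: ContactMap) -> float:
    """C = contacts-per-million between the TSS bin and the enhancer midpoint bin.

    The raw count is divided by (chromosome cis total / 1e6); scaling the whole
    matrix leaves C unchanged.
    """
    if gene.chrom != enhancer.chrom:
        raise ValueError("promoter and enhancer must share a chromosome")
    mat = contacts.cis[gene.chrom]
    bs = contacts.bin_size
    bi = gene.tss // bs
    bj = ((enhancer.start + enhancer.end) // 2) // bs
    if not (0 <= bi < mat.shape[0] and 0 <= bj < mat.shape[0]):
        return 0.0
    total = contacts.cis_total(gene.chrom)
    if total == 0:
        return 0.0
    return float(mat[bi, bj]) / (total / 1e6)


def promoter_p(gene, k4_track: SignalTrack, factor: float = 1.0,
               halfwidth: int = PROMOTER_HALFWIDTH) -> float:
    """P = calibrated mean per-bp promoter-mark signal over TSS +/- halfwidth."""
    start = max(gene.tss - halfwidth, 0)
    end = gene.tss + halfwidth
    vec = k4_track.values.get(gene.chrom)
    if vec is None:
        return 0.0
    end = min(end, len(vec) * k4_track.bin_size)
    if end <= start:
        return 0.0              # window beyond track coverage
    return k4_track.mean_over_interval(gene.chrom, start, end) * factor


def abc_score(gene, enhancers: EnhancerSet, k27ac_track: SignalTrack,
              k4_track: SignalTrack, contacts: ContactMap,
              activity_factor: float = 1.0, promoter_factor: float = 1.0,
              window: int = ABC_WINDOW,
              promoter_halfwidth: int = PROMOTER_HALFWIDTH) -> ABCRecord:
    """Full per-gene record: per-enhancer (A, C, A*C), ABC, P and ABC-P2."""
    record = ABCRecord(gene_id=gene.gene_id)
    for enh in candidate_enhancers(gene, enhancers, window).itertuples(index=False):
        a = activity_A(enh, k27ac_track, activity_factor)
        c = contact_C(gene, enh, contacts)
        record.enhancers.append(((enh.chrom, enh.start, enh.end), a, c, a * c))
    record.abc = float(sum(e[3] for e in record.enhancers))
    record.p_score = promoter_p(gene, k4_track, promoter_factor,
                                promoter_halfwidth)
    return record


def abc_table(genes: GeneAnnotation, enhancers: EnhancerSet,
              k27ac_track: SignalTrack, k4_track: SignalTrack,
              contacts: ContactMap,
              factors: NormalizationFactors | None = None,
              k27ac_sample: str | None = None, k4_sample: str | None = None,
              window: int = ABC_WINDOW,
              promoter_halfwidth: int = PROMOTER_HALFWIDTH) -> pd.DataFrame:
    """ABC / P / ABC-P2 scores for every gene; columns
    (abc, p_score, abc_p2, n_enhancers, top_enhancer)."""
    af = factors[k27ac_sample] if factors and k27ac_sample else 1.0
    pf = factors[k4_sample] if factors and k4_sample else 1.0
    rows = []
    for gene in genes.df.itertuples(index=False):
        rec = abc_score(gene, enhancers, k27ac_track, k4_track, contacts,
                        activity_factor=af, promoter_factor=pf,
                        window=window, promoter_halfwidth=promoter_halfwidth)
        top = max(rec.enhancers, key=lambda e: e[3])[0] if rec.enhancers else None
        rows.append((rec.gene_id, rec.abc, rec.p_score, rec.abc_p2,
                     len(rec.enhancers),
                     f"{top[0]}:{top[1]}-{top[2]}" if top else ""))
    return pd.DataFrame(rows, columns=[
        "gene_id", "abc", "p_score", "abc_p2", "n_enhancers", "top_enhancer",
    ]).set_index("gene_id")


def abc_expression_correlation(table1: pd.DataFrame, table2: pd.DataFrame,
                               expr_lfc: pd.Series, score: str = "abc_p2",
                               mode: str = "difference",
                               ) -> tuple[float, float, int]:
    """Pearson correlation of the score change against expression log2FC.

    ``mode='difference'`` correlates score2 - score1; ``mode='log_ratio'``
    correlates log2((score2 + 1) / (score1 + 1)).
    """
    common = table1.index.intersection(table2.index).intersection(expr_lfc.index)
    s1 = table1.loc[common, score].astype(float)
    s2 = table2.loc[common, score].astype(float)
    if mode == "difference":
        delta = s2 - s1
    elif mode == "log_ratio":
        delta = np.log2((s2 + 1.0) / (s1 + 1.0))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    y = expr_lfc.loc[common].astype(float)
    ok = delta.notna() & y.notna()
    delta, y = delta[ok], y[ok]
    if len(delta) < 3:
        raise ValueError(f"need >= 3 genes, have {len(delta)}")
    if delta.std() == 0 or y.std() == 0:
        raise ValueError("degenerate input: zero variance in scores or expression")
    r, p = stats.pearsonr(delta, y)
    return float(r), float(p), int(len(delta))
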