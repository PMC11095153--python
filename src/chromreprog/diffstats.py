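"""Two-group differential statistics and the significance filter.

Shrinkage-based count-model engines (DESeq2-style dispersion sharing) are
deliberately not reimplemented; this transparent stand-in keeps the same
(log2fc, padj) semantics downstream code needs: a Welch t-test on
log2(x + 1) of normalized counts, or an exact label permutation test,
followed by Benjamini-Hochberg adjustment, with the significance rule
padj <= 0.05 and |log2fc| >= 0.5 (both boundaries inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT = 1.0


@dataclass
class NormalizationFactors:
    """Per-sample positive scale factors; normalized counts = counts / factor."""

    factors: dict[str, float]

    def __post_init__(self) -> None:
        for sample, f in self.factors.items():
            if not np.isfinite(f) or f <= 0:
                raise ValueError(f"non-positive factor for sample {sample}")

    def __getitem__(self, sample: str) -> float:
        return self.factors[sample]


def normalize_library(expr: pd.DataFrame, mode: str = "median_of_ratios",
                      ) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Library-size normalization.

    ``median_of_ratios``: factor_j = median over genes of count_gj / geometric
    mean of gene g (genes positive in all samples only).  ``per_million``:
    factor_j = column sum / 1e6.
    """
    if (expr.sum(axis=0) == 0).any():
        bad = expr.columns[expr.sum(axis=0) == 0]
        raise ValueError(f"all-zero sample(s): {list(bad)}")
    if mode == "median_of_ratios":
        positive = expr[(expr > 0).all(axis=1)]
        if positive.empty:
            raise ValueError("no gene with nonzero counts in all samples")
        log_geomean = np.log(positive).mean(axis=1)
        ratios = np.log(positive).sub(log_geomean, axis=0)
        factors = np.exp(ratios.median(axis=0))
    elif mode == "per_million":
        factors = expr.sum(axis=0) / 1e6
    else:
        raise ValueError(f"unknown mode {mode!r}")
    nf = NormalizationFactors(dict(factors))
    return expr.div(factors, axis=1), nf


def spike_in_factors(spike_counts: dict[str, float]) -> NormalizationFactors:
    """Spike-in scale factors: geometric mean of spike counts / sample count.

    Exogenous spike-in DNA added proportionally to input cells makes spike
    coverage a depth proxy; dividing by it equalizes coverage between samples.
    Scale-invariant: multiplying every count by a constant changes nothing.
    """
    counts = np.array(list(spike_counts.values()), dtype=float)
    if np.any(counts <= 0):
        raise ValueError("spike-in counts must be positive")
    geomean = np.exp(np.mean(np.log(counts)))
    return NormalizationFactors(
        {s: geomean / c for s, c in spike_counts.items()})


def _welch_log(norm: pd.DataFrame, g1: list[str], g2: list[str]) -> np.ndarray:
    x1 = np.log2(norm[g1].to_numpy() + PSEUDOCOUNT)
    x2 = np.log2(norm[g2].to_numpy() + PSEUDOCOUNT)
    with warnings.catch_warnings():
        # near-constant genes trigger a precision warning; their NaN p-values
        # are mapped to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance identical groups yield nan; no evidence of change
    same = np.isnan(p)
    p[same] = 1.0
    return p


def _permutation_p(norm: pd.DataFrame, g1: list[str], g2: list[str],
                   max_perms: int = 200) -> np.ndarray:
    """Exact permutation p-values on the difference of log2(x+1) group means."""
    samples = g1 + g2
    x = np.log2(norm[samples].to_numpy() + PSEUDOCOUNT)
    n1 = len(g1)
    idx_all = list(range(len(samples)))
    splits = list(combinations(idx_all, n1))
    if len(splits) > max_perms:
        raise ValueError(
            f"{len(splits)} label permutations exceed max_perms={max_perms}")
    obs = np.abs(x[:, n1:].mean(axis=1) - x[:, :n1].mean(axis=1))
    count = np.zeros(len(x), dtype=int)
    for split in splits:
        sel = np.zeros(len(samples), dtype=bool)
        sel[list(split)] = True
        stat = np.abs(x[:, ~sel].mean(axis=1) - x[:, sel].mean(axis=1))
        count += stat >= obs - 1e-12
    return count / len(splits)


def two_group_test(norm: pd.DataFrame, design: dict[str, str],
                   cond1: str, cond2: str, test: str = "welch_log",
                   ) -> pd.DataFrame:
    """Per-feature log2 fold change and p-value between two conditions.

    log2fc = log2((mean2 + 1) / (mean1 + 1)) on normalized values.  Returns a
    DataFrame with columns (log2fc, pvalue) indexed by feature.
    """
    g1 = [s for s, c in design.items() if c == cond1]
    g2 = [s for s, c in design.items() if c == cond2]
    if not g1 or not g2:
        raise ValueError("both conditions need samples")
    mean1 = norm[g1].mean(axis=1)
    mean2 = norm[g2].mean(axis=1)
    log2fc = np.log2((mean2 + PSEUDOCOUNT) / (mean1 + PSEUDOCOUNT))
    if test == "welch_log":
        if min(len(g1), len(g2)) < 2:
            raise ValueError(
                "welch_log needs >=2 replicates per group; "
                "use test='exact_permutation' for single replicates")
        pvalues = _welch_log(norm, g1, g2)
    elif test == "exact_permutation":
        pvalues = _permutation_p(norm, g1, g2)
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame({"log2fc": log2fc, "pvalue": pvalues}, index=norm.index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) | np.any(p > 1) | np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def apply_significance(results: pd.DataFrame, padj_max: float = 0.05,
                       lfc_min: float = 0.5) -> pd.DataFrame:
    """Flag features with padj <= padj_max and |log2fc| >= lfc_min.

    Both boundaries are inclusive.  Adds ``padj`` (if absent) and
    ``significant`` columns; attrs carry the up/down counts.
    """
    out = results.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = (out["padj"] <= padj_max) & (out["log2fc"].abs() >= lfc_min)
    sig = out[out["significant"]]
    out.attrs["n_up"] = int((sig["log2fc"] > 0).sum())
    out.attrs["n_down"] = int((sig["log2fc"] < 0).sum())
    return out


def differential(expr: pd.DataFrame, design: dict[str, str], cond1: str,
                 cond2: str, test: str = "welch_log",
                 norm_mode: str = "median_of_ratios", padj_max: float = 0.05,
                 lfc_min: float = 0.5) -> pd.DataFrame:
    """Normalize, test, adjust and flag in one call."""
    norm, _ = normalize_library(expr, mode=norm_mode)
    res = two_group_test(norm, design, cond1, cond2, test=test)
    return apply_significance(res, padj_max=padj_max, lfc_min=lfc_min)


def peak_signal_matrix(peaks, tracks: dict[str, "object"],
                       factors: NormalizationFactors | None = None,
                       ) -> pd.DataFrame:
    """Per-peak summed track coverage per sample, spike-in scaled.

    Rows are peaks (``chrom:start-end``), columns the samples of ``tracks``.
    Feeding this to :func:`two_group_test` mirrors peak-level differential
    analysis under spike-in coverage normalization.
    """
    rows = {}
    for sample, track in tracks.items():
        f = factors[sample] if factors is not None else 1.0
        col = {}
        for r in peaks.df.itertuples(index=False):
            key = f"{r.chrom}:{r.start}-{r.end}"
            col[key] = track.sum_over_interval(r.chrom, r.start, r.end) * f
        rows[sample] = col
    return pd.DataFrame(rows)
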