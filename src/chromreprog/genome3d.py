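"""Contact-map analytics: P(s) curves, chromosome-level interaction changes,
A/B compartment eigenvectors, the 7-way compartment-change classifier, saddle
plots, and insulation/TAD-boundary comparison.

All statistics that compare maps are depth-invariant: counts are normalized
per valid bin-pair and per map total before any ratio is taken, so a globally
scaled copy of a map produces identical curves and zero log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ContactMap, GenomeModel

CHANGE_CATEGORIES = (
    "A_to_strongerA", "B_to_A", "B_to_weakerB", "B_to_strongerB",
    "A_to_B", "A_to_weakerA", "stable",
)


# ---------------------------------------------------------------------------
# Expected / observed-over-expected


def expected_by_distance(cis: np.ndarray) -> np.ndarray:
    """Mean contact count per diagonal offset of a symmetric cis matrix."""
    n = cis.shape[0]
    return np.array([np.mean(np.diagonal(cis, d)) for d in range(n)])


def oe_matrix(cis: np.ndarray, expected: np.ndarray | None = None) -> np.ndarray:
    """Observed / expected matrix; offsets with zero expectation become NaN."""
    if expected is None:
        expected = expected_by_distance(cis)
    n = cis.shape[0]
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    exp = expected[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, cis / np.where(exp > 0, exp, 1.0), np.nan)
    return oe


# ---------------------------------------------------------------------------
# Compartments


@dataclass
class CompartmentTrack:
    """Per-bin leading-eigenvector (PC1) values, GC-oriented, with a mask."""

    values: dict[str, np.ndarray]       # NaN at masked bins
    bin_size: int
    oriented_by: str = "gc"

    def unmasked(self, chrom: str) -> np.ndarray:
        v = self.values[chrom]
        return v[~np.isnan(v)]


def _running_mean(mat: np.ndarray, window: int) -> np.ndarray:
    """Row-and-column running mean with a centered window (NaN-aware)."""
    if window <= 1:
        return mat
    kernel = np.ones(window)

    def smooth_axis(a):
        filled = np.nan_to_num(a, nan=0.0)
        weight = (~np.isnan(a)).astype(float)
        num = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="same"), 1, filled)
        den = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="same"), 1, weight)
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)

    return smooth_axis(smooth_axis(mat).T).T


def compartment_pc1(cis: np.ndarray, gc: np.ndarray, bin_size: int = 25_000,
                    window: int = 100_000, min_unmasked: int = 50,
                    min_explained: float = 0.05) -> np.ndarray:
    """Leading eigenvector of the correlation of the smoothed O/E matrix.

    Bins with zero coverage are masked.  The O/E matrix is smoothed with a
    running window of ``window`` bp (the 100 kb / 25 kb idiom gives 4 bins),
    Pearson-correlated bin-against-bin, and decomposed; the eigenvector sign
    is anchored so that Pearson(PC1, GC) >= 0.  Raises if there is no
    compartment signal (near-constant correlation matrix or a leading
    eigenvalue explaining < ``min_explained`` of total variance).
    """
    n = cis.shape[0]
    cover = cis.sum(axis=1)
    mask = cover > 0
    if mask.sum() < min_unmasked:
        raise ValueError(f"only {int(mask.sum())} unmasked bins (< {min_unmasked})")
    oe = oe_matrix(cis)
    oe_sub = oe[np.ix_(mask, mask)]
    # centered window: an even bin count would shift the signal half a bin
    # and systematically mislabel block edges, so widen to the next odd count
    w = max(int(round(window / bin_size)), 1)
    if w % 2 == 0:
        w += 1
    sm = _running_mean(oe_sub, w)
    sm = np.nan_to_num(sm, nan=1.0)
    sd = sm.std(axis=1)
    if np.all(sd < 1e-12):
        raise ValueError("no compartment signal: constant correlation matrix")
    corr = np.corrcoef(sm)
    corr = np.nan_to_num(corr, nan=0.0)
    eigvals, eigvecs = np.linalg.eigh(corr)
    share = eigvals[-1] / np.sum(np.abs(eigvals))
    if share < min_explained:
        raise ValueError(
            f"no compartment signal: leading eigenvalue explains {share:.3f} "
            f"of variance (< {min_explained})")
    pc1 = eigvecs[:, -1]
    gc_sub = np.asarray(gc, dtype=float)[mask]
    if np.std(gc_sub) > 0 and np.std(pc1) > 0:
        if np.corrcoef(pc1, gc_sub)[0, 1] < 0:
            pc1 = -pc1
    # scale so values are comparable across chromosomes (unit variance)
    pc1 = pc1 / pc1.std() if pc1.std() > 0 else pc1
    out = np.full(n, np.nan)
    out[mask] = pc1
    return out


def compartment_track(cmap: ContactMap, genome: GenomeModel,
                      window: int = 100_000, min_unmasked: int = 50,
                      ) -> CompartmentTrack:
    """Per-chromosome GC-oriented PC1 over a whole contact map."""
    values = {}
    for chrom in genome.chrom_names:
        values[chrom] = compartment_pc1(
            cmap.cis[chrom], genome.gc[chrom], bin_size=cmap.bin_size,
            window=window, min_unmasked=min_unmasked)
    return CompartmentTrack(values=values, bin_size=cmap.bin_size)


def classify_compartment_change(pc1_c1: np.ndarray, pc1_c2: np.ndarray,
                                t: float = 0.2) -> np.ndarray:
    """7-way per-bin compartment-change labels.

    The category definitions overlap; the first matching rule in the listed
    order wins (the order below is the documented precedence):
      1. A_to_strongerA:  c2 - c1 > t  and c1 > t
      2. B_to_A:          c2 > 0      and c1 < 0
      3. B_to_weakerB:    c2 - c1 > t  and c2 < -t
      4. B_to_strongerB:  c2 - c1 < -t and c1 < -t
      5. A_to_B:          c2 < 0      and c1 > 0
      6. A_to_weakerA:    c2 - c1 < -t and c1 > t
      7. stable otherwise.
    Masked (NaN) bins get the empty label ''.
    """
    c1 = np.asarray(pc1_c1, dtype=float)
    c2 = np.asarray(pc1_c2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("PC1 tracks have different lengths")
    out = np.full(c1.shape, "", dtype=object)
    for i in range(c1.size):
        a, b = c1.flat[i], c2.flat[i]
        if np.isnan(a) or np.isnan(b):
            continue
        d = b - a
        if d > t and a > t:
            lab = "A_to_strongerA"
        elif b > 0 and a < 0:
            lab = "B_to_A"
        elif d > t and b < -t:
            lab = "B_to_weakerB"
        elif d < -t and a < -t:
            lab = "B_to_strongerB"
        elif b < 0 and a > 0:
            lab = "A_to_B"
        elif d < -t and a > t:
            lab = "A_to_weakerA"
        else:
            lab = "stable"
        out.flat[i] = lab
    return out


def change_fractions(labels: np.ndarray) -> pd.Series:
    """Genome fraction per category over unmasked bins (sums to 1)."""
    lab = labels[labels != ""]
    n = len(lab)
    return pd.Series({c: float(np.sum(lab == c)) / n if n else np.nan
                      for c in CHANGE_CATEGORIES})


# ---------------------------------------------------------------------------
# Saddle


@dataclass
class SaddleMatrix:
    matrix: np.ndarray                  # n_bins x n_bins mean O/E
    corner_aa: float
    corner_bb: float
    corner_ab: float

    @property
    def strength(self) -> float:
        """Compartmentalization strength AA * BB / AB**2."""
        return self.corner_aa * self.corner_bb / self.corner_ab ** 2


def saddle(oe_by_chrom: dict[str, np.ndarray], pc1: CompartmentTrack,
           n_bins: int = 50, trim: float = 0.025, corner: int = 5) -> SaddleMatrix:
    """O/E contacts aggregated over PC1-ranked bin groups.

    The whole-genome eigenvector is trimmed of its top and bottom ``trim``
    quantiles, the surviving bins are rank-split into ``n_bins`` equal groups
    (ascending PC1: group 0 is strongest B, last group strongest A), and every
    cis bin-pair's O/E value is averaged within its group pair.  Corner means
    are over the ``corner`` x ``corner`` extreme blocks (AA = high-high,
    BB = low-low, AB = mean of the two off-diagonal corners).
    """
    entries = []          # (value, chrom, bin)
    for chrom in pc1.values:
        v = pc1.values[chrom]
        for b in np.where(~np.isnan(v))[0]:
            entries.append((v[b], chrom, int(b)))
    if len(entries) < n_bins:
        raise ValueError(
            f"{len(entries)} usable bins < n_bins={n_bins}; lower n_bins")
    all_vals = np.array([e[0] for e in entries])
    lo, hi = np.quantile(all_vals, [trim, 1 - trim])
    survivors = sorted(e for e in entries if lo <= e[0] <= hi)
    group_of: dict[tuple[str, int], int] = {}
    for rank, (_, chrom, b) in enumerate(survivors):
        group_of[(chrom, b)] = rank * n_bins // len(survivors)
    sums = np.zeros((n_bins, n_bins))
    counts = np.zeros((n_bins, n_bins))
    for chrom, oe in oe_by_chrom.items():
        idx = np.array(sorted(b for c, b in group_of if c == chrom), dtype=int)
        if idx.size == 0:
            continue
        group = np.array([group_of[(chrom, int(b))] for b in idx])
        sub = oe[np.ix_(idx, idx)]
        valid = ~np.isnan(sub)
        gi = np.repeat(group, idx.size).reshape(idx.size, idx.size)
        gj = gi.T
        np.add.at(sums, (gi[valid], gj[valid]), sub[valid])
        np.add.at(counts, (gi[valid], gj[valid]), 1)
    with np.errstate(invalid="ignore"):
        mat = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    aa = float(np.nanmean(mat[-corner:, -corner:]))
    bb = float(np.nanmean(mat[:corner, :corner]))
    ab = float(np.nanmean(np.concatenate(
        [mat[:corner, -corner:].ravel(), mat[-corner:, :corner].ravel()])))
    return SaddleMatrix(matrix=mat, corner_aa=aa, corner_bb=bb, corner_ab=ab)


# ---------------------------------------------------------------------------
# P(s)


@dataclass
class PsCurve:
    """Distance-binned mean contact frequency (log-spaced bins)."""

    edges: np.ndarray                   # bp, length n+1, strictly increasing
    frequency: np.ndarray               # per valid bin-pair, per total cis count

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])


def ps_curve(cmap: ContactMap, n_log_bins: int = 30) -> PsCurve:
    """Contact frequency P as a function of genomic distance s.

    For each log-spaced distance bin: (sum of counts at those diagonal
    offsets over all chromosomes) / (number of contributing bin-pairs) /
    (total cis counts), so two maps identical up to global scale give
    identical curves.
    """
    bs = cmap.bin_size
    max_bins = max(m.shape[0] for m in cmap.cis.values())
    count_by_d = np.zeros(max_bins)
    pairs_by_d = np.zeros(max_bins)
    for mat in cmap.cis.values():
        n = mat.shape[0]
        for d in range(1, n):
            count_by_d[d] += np.diagonal(mat, d).sum()
            pairs_by_d[d] += n - d
    total_cis = sum(float(m.sum()) for m in cmap.cis.values())
    edges = np.unique(np.geomspace(bs, max_bins * bs, n_log_bins + 1).astype(int))
    freq = np.zeros(len(edges) - 1)
    dists = np.arange(max_bins) * bs
    for k in range(len(edges) - 1):
        sel = (dists >= edges[k]) & (dists < edges[k + 1])
        npairs = pairs_by_d[sel].sum()
        if npairs > 0 and total_cis > 0:
            freq[k] = count_by_d[sel].sum() / npairs / total_cis
    return PsCurve(edges=edges.astype(float), frequency=freq)


def ps_slope(curve: PsCurve, s_min: float | None = None,
             s_max: float | None = None) -> float:
    """Log-log regression slope of P(s) over the populated range."""
    c = curve.centers
    f = curve.frequency
    ok = f > 0
    if s_min is not None:
        ok &= c >= s_min
    if s_max is not None:
        ok &= c <= s_max
    if ok.sum() < 2:
        raise ValueError("too few populated bins for a slope")
    coef = np.polyfit(np.log10(c[ok]), np.log10(f[ok]), 1)
    return float(coef[0])


def ps_log2fc(curve1: PsCurve, curve2: PsCurve,
              ) -> tuple[np.ndarray, list[float]]:
    """Per-bin log2(curve2/curve1) plus crossing points.

    Crossings are distances where the ratio changes sign, linearly
    interpolated in log10(s) between adjacent populated bin centers (matching
    how curve intersections are read off a log-x plot).
    """
    if not np.array_equal(curve1.edges, curve2.edges):
        raise ValueError("curves must share distance-bin edges")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((curve1.frequency > 0) & (curve2.frequency > 0),
                         np.log2(curve2.frequency / curve1.frequency), np.nan)
    ok = ~np.isnan(ratio)
    if not ok.any():
        raise ValueError("curves have disjoint support")
    centers = curve1.centers
    xs = np.log10(centers[ok])
    ys = ratio[ok].copy()
    # ratios within float round-off of 0 are 0, not sign changes
    ys[np.abs(ys) < 1e-9] = 0.0
    crossings = []
    for i in range(len(ys) - 1):
        if ys[i] == 0:
            continue
        if ys[i] * ys[i + 1] < 0:
            frac = ys[i] / (ys[i] - ys[i + 1])
            crossings.append(float(10 ** (xs[i] + frac * (xs[i + 1] - xs[i]))))
    return ratio, crossings


# ---------------------------------------------------------------------------
# Chromosome-level fold changes and trans enrichment


def interaction_fold_changes(map1: ContactMap, map2: ContactMap,
                             ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-chromosome cis and per-pair trans log2 fold changes.

    Each class's summed counts are divided by its map's total contacts before
    the ratio, so a global scaling of either map gives all-zero fold changes.
    Classes with zero counts in either map are NaN.
    """
    t1, t2 = map1.total_contacts, map2.total_contacts
    cis = {}
    for chrom in map1.cis:
        a = map1.cis_total(chrom) / t1
        b = map2.cis_total(chrom) / t2
        cis[chrom] = np.log2(b / a) if a > 0 and b > 0 else np.nan
    chroms = sorted({c for pair in map1.trans for c in pair})
    trans = pd.DataFrame(np.nan, index=chroms, columns=chroms)
    for pair, m1 in map1.trans.items():
        m2 = map2.trans.get(pair)
        if m2 is None:
            continue
        a = float(m1.sum()) / t1
        b = float(m2.sum()) / t2
        val = np.log2(b / a) if a > 0 and b > 0 else np.nan
        trans.loc[pair[0], pair[1]] = val
        trans.loc[pair[1], pair[0]] = val
    return pd.Series(cis), trans


def _coarse_bin(mat: np.ndarray, factor: int) -> np.ndarray:
    """Sum-aggregate a matrix into factor x factor blocks."""
    n, m = mat.shape
    cn, cm = -(-n // factor), -(-m // factor)
    out = np.zeros((cn, cm))
    for i in range(cn):
        for j in range(cm):
            out[i, j] = mat[i * factor:(i + 1) * factor,
                            j * factor:(j + 1) * factor].sum()
    return out


def top_trans_regions(map1: ContactMap, map2: ContactMap,
                      chrom_pair: tuple[str, str], fraction: float = 0.005,
                      direction: str = "increased",
                      coarse_bin: int = 2_000_000) -> pd.DataFrame:
    """Most-changed trans contact region pairs between two chromosomes.

    Bin-pair counts are aggregated to ``coarse_bin`` resolution, normalized
    per map total, ranked by signed log2 fold change (pseudocounted), and the
    top ``fraction`` taken ('increased' ranks descending, 'decreased'
    ascending; ties break by coordinate order).  Contiguous selected pairs are
    merged into rectangular region pairs.
    """
    m1, m2 = map1.trans[chrom_pair], map2.trans[chrom_pair]
    factor = max(coarse_bin // map1.bin_size, 1)
    c1 = _coarse_bin(m1, factor) / map1.total_contacts
    c2 = _coarse_bin(m2, factor) / map2.total_contacts
    eps = 0.5 * min(1.0 / map1.total_contacts, 1.0 / map2.total_contacts)
    fc = np.log2((c2 + eps) / (c1 + eps))
    flat = [(fc[i, j], i, j) for i in range(fc.shape[0]) for j in range(fc.shape[1])]
    reverse = direction == "increased"
    flat.sort(key=lambda t: ((-t[0] if reverse else t[0]), t[1], t[2]))
    k = max(int(np.ceil(fraction * len(flat))), 1)
    chosen = {(i, j) for _, i, j in flat[:k]}
    # merge contiguous selected coarse-bin pairs into rectangles (greedy)
    bs = factor * map1.bin_size
    rows = []
    seen = set()
    for _, i, j in flat[:k]:
        if (i, j) in seen:
            continue
        block = {(i, j)}
        frontier = [(i, j)]
        while frontier:
            a, b = frontier.pop()
            for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = (a + da, b + db)
                if nb in chosen and nb not in block:
                    block.add(nb)
                    frontier.append(nb)
        seen |= block
        is_ = [a for a, _ in block]
        js = [b for _, b in block]
        rows.append((
            chrom_pair[0], min(is_) * bs, (max(is_) + 1) * bs,
            chrom_pair[1], min(js) * bs, (max(js) + 1) * bs,
            float(np.mean([fc[a, b] for a, b in block])), len(block)))
    return pd.DataFrame(rows, columns=[
        "chromA", "startA", "endA", "chromB", "startB", "endB",
        "mean_log2fc", "n_pairs"])


# ---------------------------------------------------------------------------
# Insulation and boundaries


@dataclass
class InsulationTrack:
    """log2(diamond mean / chromosome mean diamond) per bin; NaN at edges."""

    scores: dict[str, np.ndarray]
    window_bins: int


def insulation_scores(cis: np.ndarray, window_bins: int = 10) -> np.ndarray:
    """Diamond insulation profile of one chromosome.

    For bin i the diamond is the window_bins x window_bins block of contacts
    between [i-w, i) upstream and (i, i+w] downstream; the score is
    log2(diamond mean / mean diamond over valid bins).  A uniform matrix
    scores 0 everywhere.
    """
    n = cis.shape[0]
    w = window_bins
    means = np.full(n, np.nan)
    for i in range(w, n - w):
        means[i] = cis[i - w:i, i + 1:i + 1 + w].mean()
    valid = ~np.isnan(means)
    if valid.any():
        chrom_mean = np.nanmean(means)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(valid & (means > 0) & (chrom_mean > 0),
                              np.log2(means / chrom_mean), np.nan)
    else:
        scores = means
    return scores


def insulation(cmap: ContactMap, window_bins: int = 10) -> InsulationTrack:
    return InsulationTrack(
        scores={c: insulation_scores(m, window_bins) for c, m in cmap.cis.items()},
        window_bins=window_bins)


def boundaries_and_domains(track: InsulationTrack, prominence: float = 0.1,
                           min_sep: int = 3,
                           ) -> tuple[dict[str, list[int]],
                                      dict[str, list[tuple[int, int]]],
                                      list[int]]:
    """Insulation minima below -prominence -> boundaries; gaps -> domains.

    Local minima are collected deepest-first with a ``min_sep``-bin exclusion
    zone.  Domains are the inter-boundary intervals per chromosome (including
    chromosome ends); the returned size list is in bins.
    """
    boundaries: dict[str, list[int]] = {}
    domains: dict[str, list[tuple[int, int]]] = {}
    sizes: list[int] = []
    for chrom, s in track.scores.items():
        n = len(s)
        cand = []
        for i in range(n):
            if np.isnan(s[i]) or s[i] >= -prominence:
                continue
            left = s[i - 1] if i > 0 else np.nan
            right = s[i + 1] if i < n - 1 else np.nan
            if (np.isnan(left) or s[i] <= left) and (np.isnan(right) or s[i] <= right):
                cand.append((s[i], i))
        cand.sort()
        chosen: list[int] = []
        for _, i in cand:
            if all(abs(i - j) >= min_sep for j in chosen):
                chosen.append(i)
        chosen.sort()
        boundaries[chrom] = chosen
        cuts = [0, *chosen, n]
        doms = [(a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]
        domains[chrom] = doms
        sizes.extend(b - a for a, b in doms)
    return boundaries, domains, sizes


def merge_boundaries(b1: dict[str, list[int]], b2: dict[str, list[int]],
                     tol: int = 1) -> dict[str, list[int]]:
    """Union of boundary sets, collapsing positions within ``tol`` bins."""
    merged: dict[str, list[int]] = {}
    for chrom in sorted(set(b1) | set(b2)):
        pts = sorted(b1.get(chrom, []) + b2.get(chrom, []))
        out: list[int] = []
        for p in pts:
            if out and p - out[-1] <= tol:
                continue
            out.append(p)
        merged[chrom] = out
    return merged


def compare_boundary_insulation(track1: InsulationTrack, track2: InsulationTrack,
                                merged: dict[str, list[int]],
                                ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Paired insulation scores at merged TAD boundaries.

    Returns the per-boundary table (chrom, bin, score1, score2, delta) and a
    summary: mean delta plus counts of boundaries weakening / strengthening.
    """
    rows = []
    for chrom, bins in merged.items():
        s1 = track1.scores.get(chrom)
        s2 = track2.scores.get(chrom)
        if s1 is None or s2 is None:
            continue
        for b in bins:
            v1 = s1[b] if b < len(s1) else np.nan
            v2 = s2[b] if b < len(s2) else np.nan
            rows.append((chrom, b, v1, v2, v2 - v1))
    if not rows:
        raise ValueError("empty merged boundary set")
    table = pd.DataFrame(rows, columns=["chrom", "bin", "score1", "score2", "delta"])
    delta = table["delta"].dropna()
    summary = {
        "mean_delta": float(delta.mean()) if len(delta) else np.nan,
        "n_weaker": int((delta > 0).sum()),
        "n_stronger": int((delta < 0).sum()),
        "n_boundaries": int(len(table)),
    }
    return table, summary


# ---------------------------------------------------------------------------
# Marks over compartment categories


def signal_change_by_category(labels: np.ndarray, mark_lfc: np.ndarray,
                              ) -> pd.DataFrame:
    """Distribution summaries of per-bin mark log2FC per change category.

    Returns one row per category with (n, median, q25, q75); bins lacking
    mark coverage (NaN lfc) are excluded, with the exclusion count reported
    in ``n_excluded``.
    """
    lfc = np.asarray(mark_lfc, dtype=float)
    rows = []
    for cat in CHANGE_CATEGORIES:
        sel = (labels == cat)
        vals = lfc[sel]
        n_excluded = int(np.isnan(vals).sum())
        vals = vals[~np.isnan(vals)]
        if len(vals):
            rows.append((cat, len(vals), float(np.median(vals)),
                         float(np.quantile(vals, 0.25)),
                         float(np.quantile(vals, 0.75)), n_excluded))
        else:
            rows.append((cat, 0, np.nan, np.nan, np.nan, n_excluded))
    return pd.DataFrame(rows, columns=[
        "category", "n", "median", "q25", "q75", "n_excluded"]).set_index("category")
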