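"""Seeded synthetic multi-omic data with planted ground truth.

Every generator draws from its own pseudo-random stream derived from the
master seed, so adding one modality never perturbs another, and every planted
quantity is recorded in :class:`SyntheticTruth` for use as an exact oracle by
the downstream stages.

What is emulated
----------------
* expression: negative-binomial counts, 2 conditions x 3 replicates, a set of
  planted differential genes at a fixed log2 fold change;
* histone marks: three marks (repressive H3K27me3, promoter-active H3K4me3,
  enhancer-active H3K27ac) with planted promoter states
  (none / K4 / K27 / bivalent) per condition and gained/lost peaks;
* contacts: cis maps with power-law distance decay times a same-compartment
  boost (Poisson sampled), trans maps uniform plus planted enriched blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ContactMap, GeneAnnotation, GenomeModel, PeakSet, SignalTrack

MARKS = ("H3K27me3", "H3K4me3", "H3K27ac")
STATES = ("none", "K4_only", "K27_only", "bivalent")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic dataset."""

    seed: int
    de_genes: dict[str, float] = field(default_factory=dict)      # gene -> planted lfc
    promoter_states: dict[str, dict[str, str]] = field(default_factory=dict)
    planted_peaks: dict[str, dict[str, list]] = field(default_factory=dict)
    compartment_labels: dict[str, dict[str, list]] = field(default_factory=dict)
    flipped_bins: dict[str, list] = field(default_factory=dict)
    decay_exponent: float | None = None
    enriched_trans_pairs: list = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("genome", "expression", "marks", "contacts", "misc")
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


# ---------------------------------------------------------------------------
# Genome and compartment labels


def checkerboard_labels(n_bins: int, block: int = 10, start: int = 1) -> np.ndarray:
    """Alternating blocks of +1 (A) and -1 (B)."""
    labels = np.empty(n_bins, dtype=int)
    sign = start
    for lo in range(0, n_bins, block):
        labels[lo:lo + block] = sign
        sign = -sign
    return labels


def flip_labels(labels: dict[str, np.ndarray], n_flip_blocks: int, block: int,
                seed: int) -> tuple[dict[str, np.ndarray], dict[str, list]]:
    """Relabel ``n_flip_blocks`` whole blocks per chromosome (A<->B).

    Flipping relabels existing blocks rather than redrawing the genome, so the
    compartment classifier sees an isolated, known signal.
    """
    rng = np.random.default_rng(seed)
    flipped = {c: v.copy() for c, v in labels.items()}
    flip_bins: dict[str, list] = {}
    for chrom, vec in flipped.items():
        n_blocks = len(vec) // block
        chosen = rng.choice(n_blocks, size=min(n_flip_blocks, n_blocks), replace=False)
        bins: list[int] = []
        for b in sorted(chosen):
            vec[b * block:(b + 1) * block] *= -1
            bins.extend(range(b * block, (b + 1) * block))
        flip_bins[chrom] = bins
    return flipped, flip_bins


def make_genome(n_chrom: int, chrom_length_bp: int, bin_size: int, seed: int,
                compartment_labels: dict[str, np.ndarray] | None = None,
                gc_label_shift: float = 0.05) -> GenomeModel:
    """Genome with a smooth GC track in [0.3, 0.6].

    When ``compartment_labels`` is given, A-labelled bins get ``gc_label_shift``
    added before clipping, so GC correlates positively with compartment A (the
    anchor used to orient eigenvectors).
    """
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    if bin_size > chrom_length_bp:
        raise ValueError("bin_size exceeds chromosome length")
    rng = _streams(seed)["genome"]
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    lengths = {c: chrom_length_bp for c in names}
    gc = {}
    for chrom in names:
        n = int(np.ceil(chrom_length_bp / bin_size))
        # smooth random walk, rescaled into [0.3, 0.6]
        raw = np.cumsum(rng.normal(0, 1, n))
        k = min(9, n)           # convolve('same') returns len(kernel) if longer
        kernel = np.ones(k) / k
        smooth = np.convolve(raw, kernel, mode="same")
        lo, hi = smooth.min(), smooth.max()
        track = 0.3 + 0.3 * (smooth - lo) / (hi - lo) if hi > lo else np.full(n, 0.45)
        if compartment_labels is not None and chrom in compartment_labels:
            track = track + gc_label_shift * (compartment_labels[chrom] > 0)
        gc[chrom] = np.clip(track, 0.0, 1.0)
    return GenomeModel(chrom_names=names, chrom_lengths=lengths,
                       bin_size=bin_size, gc=gc)


def place_genes(genome: GenomeModel, n_genes: int, margin: int = 20_000,
                seed: int = 0) -> GeneAnnotation:
    """Evenly spaced genes over the genome with random strands and 5 kb bodies.

    Genes are distributed across chromosomes proportionally to length, with a
    ``margin`` kept clear at both chromosome ends; spacing must leave at least
    10 kb between adjacent gene bodies so planted promoter peaks never overlap.
    """
    rng = np.random.default_rng(seed)
    total = sum(genome.chrom_lengths.values())
    rows = []
    gid = 0
    counts = {}
    for k, chrom in enumerate(genome.chrom_names):
        share = genome.chrom_lengths[chrom] / total
        counts[chrom] = int(round(share * n_genes))
    # adjust rounding drift on the last chromosome
    drift = n_genes - sum(counts.values())
    counts[genome.chrom_names[-1]] += drift
    for chrom in genome.chrom_names:
        count = counts[chrom]
        if count <= 0:
            continue
        usable = genome.chrom_lengths[chrom] - 2 * margin
        spacing = usable // count
        if spacing < 15_000:
            raise ValueError(
                f"genome too small: {count} genes on {chrom} gives spacing "
                f"{spacing} bp (< 15 kb)")
        for k in range(count):
            pos = margin + k * spacing
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = pos, pos + 5000
            tss = start if strand == "+" else end - 1
            rows.append((f"gene{gid:05d}", chrom, strand, tss, start, end))
            gid += 1
    return GeneAnnotation(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"]))


def make_pathway_db(gene_ids: list[str], n_pathways: int = 40, size: int = 25,
                    seed: int = 0) -> dict[str, set[str]]:
    """Random gene-set catalogue (genes may belong to several pathways)."""
    rng = np.random.default_rng(seed)
    db = {}
    for k in range(n_pathways):
        members = rng.choice(len(gene_ids), size=min(size, len(gene_ids)),
                             replace=False)
        db[f"pathway{k:03d}"] = {gene_ids[i] for i in members}
    return db


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(n_genes: int = 2000, n_de: int = 200, lfc: float = 2.0,
                        dispersion: float = 0.01, depth: float = 500.0,
                        n_reps: int = 3, seed: int = 0,
                        gene_ids: list[str] | None = None,
                        ) -> tuple[pd.DataFrame, dict[str, str], SyntheticTruth]:
    """Negative-binomial counts for 2 conditions x ``n_reps`` replicates.

    Planted differential genes (half up, half down) have expected fold change
    ``2**lfc`` in condition 2; all other genes share means.  ``depth`` is the
    median per-gene base mean; the defaults emulate deeply sequenced replicate
    cultures of a clonal cell line (median count ~500, dispersion 0.01).
    """
    if n_de > n_genes:
        raise ValueError("n_de exceeds n_genes")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if n_de and lfc == 0:
        raise ValueError("planted DE genes need a non-zero lfc")
    rng = _streams(seed)["expression"]
    genes = gene_ids if gene_ids is not None else [f"gene{i:05d}" for i in range(n_genes)]
    if len(genes) != n_genes:
        raise ValueError("gene_ids length mismatch")
    base = depth * np.exp(rng.normal(0, 1, n_genes))
    fc = np.ones(n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = np.resize([1.0, -1.0], n_de)
    fc[de_idx] = 2.0 ** (lfc * signs)
    mean1 = base
    mean2 = base * fc
    size = 1.0 / dispersion

    def draw(mu):
        p = size / (size + mu)
        return rng.negative_binomial(size, p[:, None], size=(n_genes, n_reps))

    counts = np.hstack([draw(mean1), draw(mean2)])
    samples = [f"cond1_rep{r + 1}" for r in range(n_reps)] + \
              [f"cond2_rep{r + 1}" for r in range(n_reps)]
    design = {s: ("cond1" if s.startswith("cond1") else "cond2") for s in samples}
    expr = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    truth = SyntheticTruth(seed=seed, de_genes={
        genes[i]: float(lfc * s) for i, s in zip(de_idx, signs)})
    return expr, design, truth


# ---------------------------------------------------------------------------
# Histone marks


def plant_promoter_states(genes: GeneAnnotation, seed: int,
                          fractions=(0.55, 0.30, 0.10, 0.05),
                          transition_fraction: float = 0.2,
                          ) -> dict[str, dict[str, str]]:
    """Assign each gene a state per condition.

    Condition-1 states are drawn with the given (none, K4, K27, bivalent)
    fractions; in condition 2 a ``transition_fraction`` of bivalent genes lose
    one of the two marks and a matching share of other genes gain/lose a mark,
    producing planted gained/lost promoter peaks.
    """
    rng = np.random.default_rng(seed)
    ids = list(genes.df["gene_id"])
    s1 = rng.choice(STATES, size=len(ids), p=fractions)
    s2 = s1.copy()
    for i, st in enumerate(s1):
        u = rng.random()
        if st == "bivalent" and u < transition_fraction:
            s2[i] = "K4_only" if rng.random() < 0.5 else "K27_only"
        elif st == "K4_only" and u < transition_fraction / 4:
            s2[i] = "none"
        elif st == "none" and u < transition_fraction / 8:
            s2[i] = "K4_only"
    return {"cond1": dict(zip(ids, s1)), "cond2": dict(zip(ids, s2))}


def plant_enhancers(genome: GenomeModel, genes: GeneAnnotation, n_shared: int = 60,
                    n_lost: int = 10, n_gained: int = 5, width: int = 3000,
                    seed: int = 0) -> dict[str, list]:
    """Intergenic enhancer intervals: shared plus condition-specific ones.

    Sites are taken midway between adjacent gene bodies so that no planted
    enhancer can touch a promoter window.
    """
    rng = np.random.default_rng(seed)
    sites = []
    for chrom in genome.chrom_names:
        sub = genes.df[genes.df["chrom"] == chrom].sort_values("tss")
        tss = sub["tss"].to_numpy()
        for a, b in zip(tss[:-1], tss[1:]):
            mid = int((a + b) // 2)
            if min(mid - a, b - mid) > width + 4000:
                sites.append((chrom, mid - width // 2, mid + width // 2))
    need = n_shared + n_lost + n_gained
    if len(sites) < need:
        raise ValueError("not enough intergenic space for requested enhancers")
    chosen = rng.choice(len(sites), size=need, replace=False)
    picked = [sites[i] for i in sorted(chosen)]
    shared = picked[:n_shared]
    lost = picked[n_shared:n_shared + n_lost]
    gained = picked[n_shared + n_lost:]
    return {"cond1": shared + lost, "cond2": shared + gained,
            "shared": shared, "lost": lost, "gained": gained}


def _call_peaks(vec: np.ndarray, bin_size: int, threshold: float,
                min_run: int = 4) -> list[tuple[int, int, float]]:
    """Runs of >= min_run consecutive bins above threshold -> (start, end, mean)."""
    above = vec > threshold
    peaks = []
    i = 0
    n = len(vec)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                peaks.append((i * bin_size, j * bin_size, float(vec[i:j].mean())))
            i = j
        else:
            i += 1
    return peaks


def simulate_marks(genome: GenomeModel, genes: GeneAnnotation,
                   states: dict[str, dict[str, str]],
                   enhancers: dict[str, list] | None = None,
                   snr: float = 10.0, noise_sd: float = 1.0,
                   track_bin: int = 500, peak_halfwidth: int = 2000,
                   seed: int = 0,
                   ) -> tuple[dict[tuple[str, str], tuple[PeakSet, SignalTrack]],
                              SyntheticTruth]:
    """Signal tracks plus called peaks for the three marks in each condition.

    Planted peaks sit at promoter windows (per the planted state) and, for the
    enhancer mark, at the planted enhancer intervals.  The noisy track is
    background + peak plateaux + truncated Gaussian noise; peaks are then
    re-called from the noisy track by thresholding, so finite ``snr`` can
    genuinely lose or invent peaks.  ``snr`` is the plateau height in units of
    ``noise_sd``; ``noise_sd=0`` gives an exact noise-free dataset.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0 and snr <= 3:
        raise ValueError("peak height must exceed the detection threshold (snr > 3)")
    rng = _streams(seed)["marks"]
    height = snr * noise_sd if noise_sd > 0 else 10.0
    background = noise_sd  # mean background level
    threshold = background + 3.0 * noise_sd if noise_sd > 0 else height / 2.0

    promoters = genes.promoter_windows(halfwidth=peak_halfwidth)
    by_gene = {r.gene_id: (r.chrom, r.start, r.end)
               for r in promoters.itertuples(index=False)}

    planted: dict[str, dict[str, list]] = {m: {} for m in MARKS}
    for cond, st_map in states.items():
        for mark in MARKS:
            planted[mark][cond] = []
        for gid, st in st_map.items():
            chrom, start, end = by_gene[gid]
            if st in ("K4_only", "bivalent"):
                planted["H3K4me3"][cond].append((chrom, start, end))
                planted["H3K27ac"][cond].append((chrom, start, end))
            if st in ("K27_only", "bivalent"):
                planted["H3K27me3"][cond].append((chrom, start, end))
        if enhancers is not None:
            planted["H3K27ac"][cond].extend(
                (c, s, e) for c, s, e in enhancers[cond])

    out: dict[tuple[str, str], tuple[PeakSet, SignalTrack]] = {}
    for mark in MARKS:
        for cond in states:
            intervals = sorted(planted[mark][cond])
            for (c1, s1, e1), (c2, s2, e2) in zip(intervals, intervals[1:]):
                if c1 == c2 and s2 < e1:
                    raise ValueError(
                        f"overlapping planted {mark} peaks on {c1} in {cond}")
            values = {}
            for chrom in genome.chrom_names:
                n = int(np.ceil(genome.chrom_lengths[chrom] / track_bin))
                base = np.zeros(n)
                for c, s, e in intervals:
                    if c != chrom:
                        continue
                    for b in range(s // track_bin, (e - 1) // track_bin + 1):
                        lo, hi = max(s, b * track_bin), min(e, (b + 1) * track_bin)
                        if b < n:
                            base[b] += height * (hi - lo) / track_bin
                if noise_sd > 0:
                    base += background + rng.normal(0, noise_sd, n)
                values[chrom] = np.clip(base, 0.0, None)
            track = SignalTrack(values=values, bin_size=track_bin,
                                sample=f"{mark}_{cond}")
            records = []
            for chrom in genome.chrom_names:
                for s, e, sig in _call_peaks(track.values[chrom], track_bin, threshold):
                    records.append((chrom, s, e, sig))
            peaks = PeakSet(pd.DataFrame(
                records, columns=["chrom", "start", "end", "signal"]))
            out[(mark, cond)] = (peaks, track)

    truth = SyntheticTruth(seed=seed, promoter_states=states,
                           planted_peaks=planted)
    return out, truth


# ---------------------------------------------------------------------------
# Contacts


def simulate_contacts(genome: GenomeModel, labels: dict[str, dict[str, np.ndarray]],
                      decay_exponent: float = -1.0, delta: float = 1.0,
                      total_reads: float = 5e6, cis_fraction: float = 0.9,
                      trans_spec: list | None = None, trans_enrichment: float = 4.0,
                      seed: int = 0,
                      ) -> tuple[dict[str, ContactMap], SyntheticTruth]:
    """Poisson-sampled contact maps for each condition.

    Cis expectation over bins i, j: ``(|i-j|+1)**decay_exponent`` times
    ``1 + delta`` when i and j share a compartment label.  Trans expectation is
    uniform except in planted enriched blocks
    ``(chromA, (lo, hi), chromB, (lo, hi))`` which get ``trans_enrichment``-fold
    counts.  Both conditions share the decay law; only labels differ.
    """
    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be negative")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rng = _streams(seed)["contacts"]
    truth = SyntheticTruth(seed=seed, decay_exponent=decay_exponent,
                           compartment_labels={
                               cond: {c: v.tolist() for c, v in lab.items()}
                               for cond, lab in labels.items()},
                           enriched_trans_pairs=list(trans_spec or []))
    chroms = genome.chrom_names
    nbins = {c: genome.n_bins(c) for c in chroms}
    maps: dict[str, ContactMap] = {}
    for cond, lab in labels.items():
        cis_expected = {}
        for chrom in chroms:
            n = nbins[chrom]
            idx = np.arange(n)
            dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
            # pure power law in bin distance; the diagonal (s=0) sits at the
            # s=1 level so short-range coverage stays populated
            base = np.where(dist >= 1, dist, 1.0) ** decay_exponent
            same = lab[chrom][:, None] == lab[chrom][None, :]
            cis_expected[chrom] = base * (1.0 + delta * same)
        upper_sum = sum(float(np.triu(m).sum()) for m in cis_expected.values())
        cis_scale = cis_fraction * total_reads / upper_sum

        trans_expected = {}
        if len(chroms) > 1:
            n_trans_entries = sum(
                nbins[a] * nbins[b]
                for i, a in enumerate(chroms) for b in chroms[i + 1:])
            trans_reads = (1.0 - cis_fraction) * total_reads
            base_rate = trans_reads / n_trans_entries
            for i, a in enumerate(chroms):
                for b in chroms[i + 1:]:
                    exp = np.full((nbins[a], nbins[b]), base_rate)
                    for spec in trans_spec or []:
                        ca, (alo, ahi), cb, (blo, bhi) = spec
                        if (ca, cb) == (a, b):
                            exp[alo:ahi, blo:bhi] *= trans_enrichment
                        elif (cb, ca) == (a, b):
                            exp[blo:bhi, alo:ahi] *= trans_enrichment
                    trans_expected[(a, b)] = exp

        mean_diag1 = cis_scale * np.mean(
            [np.mean(np.diagonal(m, 1)) for m in cis_expected.values()])
        if mean_diag1 < 10:
            truth.warnings.append(
                f"{cond}: mean near-diagonal expectation {mean_diag1:.2f} < 10; "
                "map may be too sparse")

        cis = {}
        for chrom in chroms:
            lam = np.triu(cis_expected[chrom] * cis_scale)
            upper = rng.poisson(lam).astype(float)
            mat = upper + np.triu(upper, 1).T
            cis[chrom] = mat
        trans = {k: rng.poisson(v).astype(float) for k, v in trans_expected.items()}
        maps[cond] = ContactMap(bin_size=genome.bin_size, cis=cis, trans=trans)
    return maps, truth
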