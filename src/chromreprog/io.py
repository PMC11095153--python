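"""Readers and writers for the text formats the pipeline exchanges.

Formats: BED (3-5 columns), bedGraph, GMT gene sets, expression/gene TSV,
and a 5-column bin-pair triple text for binned contact matrices
(chromA, startA, chromB, startB, count).  Everything round-trips:
``read(write(x)) == x`` for canonical inputs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import ContactMap, GeneAnnotation, GenomeModel, PeakSet, SignalTrack


class FormatError(ValueError):
    """Raised for malformed input files, naming the offending line."""


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> PeakSet:
    """Read a 3-5 column BED file into a sorted PeakSet.

    Column 4 (name) is ignored; column 5 is parsed as the signal value.
    Missing signal defaults to 1.0.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            signal = 1.0
            if len(fields) >= 5 and fields[4] != "":
                try:
                    signal = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            records.append((chrom, start, end, signal))
    return PeakSet(pd.DataFrame(records, columns=["chrom", "start", "end", "signal"]))


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as canonical 5-column BED (name column = '.')."""
    with open(path, "w") as fh:
        for row in peaks.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t{row.signal:g}\n")


# ---------------------------------------------------------------------------
# bedGraph / SignalTrack


def read_bedgraph(path, genome: GenomeModel, bin_size: int | None = None,
                  sample: str = "") -> SignalTrack:
    """Bin a bedGraph into a fixed-bin SignalTrack.

    Intervals not aligned to the bin grid contribute length-weighted: a bin's
    value is the mean per-bp signal of the bases it covers (uncovered bases
    count as 0).
    """
    bs = bin_size or genome.bin_size
    sums = {c: np.zeros(math.ceil(genome.chrom_lengths[c] / bs)) for c in genome.chrom_names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            if chrom not in sums:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed record") from exc
            if start >= end or start < 0:
                raise FormatError(f"{path}:{lineno}: bad interval")
            vec = sums[chrom]
            end = min(end, genome.chrom_lengths[chrom])
            for b in range(start // bs, (end - 1) // bs + 1):
                lo, hi = max(start, b * bs), min(end, (b + 1) * bs)
                if hi > lo:
                    vec[b] += value * (hi - lo)
    values = {}
    for chrom, vec in sums.items():
        widths = np.full(len(vec), bs, dtype=float)
        tail = genome.chrom_lengths[chrom] - (len(vec) - 1) * bs
        widths[-1] = tail
        values[chrom] = vec / widths
    return SignalTrack(values=values, bin_size=bs, sample=sample)


def write_signal_bedgraph(track: SignalTrack, genome: GenomeModel, path) -> None:
    """Write one bedGraph line per bin (zero bins included, for round-trips)."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            vec = track.values[chrom]
            length = genome.chrom_lengths[chrom]
            for b, v in enumerate(vec):
                fh.write(f"{chrom}\t{b * bs}\t{min((b + 1) * bs, length)}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# Contact matrices (bin-pair triple text)


def read_contacts(path, genome: GenomeModel, bin_size: int | None = None) -> ContactMap:
    """Read bin-pair triple text into a ContactMap.

    Accepted layouts per line (tab-separated):
      5 columns: chromA  startA  chromB  startB  count
      3 columns: binA_id  binB_id  count  (genome-wide bin ids in chromosome
                 order, row-major)
    Cis counts are added to both (i, j) and (j, i) unless i == j; trans counts
    are stored once under the genome-ordered chromosome pair.
    """
    bs = bin_size or genome.bin_size
    order = {c: k for k, c in enumerate(genome.chrom_names)}
    nbins = {c: math.ceil(genome.chrom_lengths[c] / bs) for c in genome.chrom_names}
    offsets = {}
    cum = 0
    for c in genome.chrom_names:
        offsets[c] = cum
        cum += nbins[c]
    cis = {c: np.zeros((nbins[c], nbins[c])) for c in genome.chrom_names}
    trans: dict[tuple[str, str], np.ndarray] = {}

    def global_to_local(gid: int) -> tuple[str, int]:
        for c in genome.chrom_names:
            if gid < offsets[c] + nbins[c]:
                return c, gid - offsets[c]
        raise FormatError(f"bin id {gid} outside genome")

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 5:
                    ca, cb = fields[0], fields[2]
                    ia, ib = int(fields[1]) // bs, int(fields[3]) // bs
                    count = float(fields[4])
                elif len(fields) == 3:
                    ca, ia = global_to_local(int(fields[0]))
                    cb, ib = global_to_local(int(fields[1]))
                    count = float(fields[2])
                else:
                    raise FormatError(f"{path}:{lineno}: expected 3 or 5 columns")
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed record") from exc
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            for c, i in ((ca, ia), (cb, ib)):
                if c not in nbins:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {c}")
                if not 0 <= i < nbins[c]:
                    raise FormatError(f"{path}:{lineno}: bin outside chromosome {c}")
            if ca == cb:
                cis[ca][ia, ib] += count
                if ia != ib:
                    cis[ca][ib, ia] += count
            else:
                if order[ca] > order[cb]:
                    ca, cb, ia, ib = cb, ca, ib, ia
                key = (ca, cb)
                if key not in trans:
                    trans[key] = np.zeros((nbins[ca], nbins[cb]))
                trans[key][ia, ib] += count
    return ContactMap(bin_size=bs, cis=cis, trans=trans)


def write_contacts(cmap: ContactMap, genome: GenomeModel, path) -> None:
    """Write non-zero entries as 5-column triples (cis upper triangle once)."""
    bs = cmap.bin_size
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            mat = cmap.cis.get(chrom)
            if mat is None:
                continue
            rows, cols = np.nonzero(np.triu(mat))
            for i, j in zip(rows, cols):
                fh.write(f"{chrom}\t{i * bs}\t{chrom}\t{j * bs}\t{mat[i, j]:.10g}\n")
        for (ca, cb), mat in cmap.trans.items():
            rows, cols = np.nonzero(mat)
            for i, j in zip(rows, cols):
                fh.write(f"{ca}\t{i * bs}\t{cb}\t{j * bs}\t{mat[i, j]:.10g}\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file into {pathway -> gene set}; duplicate names error."""
    db: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected name, description, >=1 gene")
            name = fields[0]
            if name in db:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway with no genes")
            db[name] = genes
    return db


def write_gmt(db: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in db.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def gene_membership_counts(db: dict[str, set[str]]) -> dict[str, int]:
    """Number of pathways each gene belongs to."""
    counts: dict[str, int] = {}
    for genes in db.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Genome model


def write_chrom_sizes(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f"{chrom}\t{genome.chrom_lengths[chrom]}\n")


def read_genome(chrom_sizes_path, bin_size: int,
                gc_bedgraph_path=None) -> GenomeModel:
    """GenomeModel from a chrom-sizes TSV plus an optional per-bin GC bedGraph."""
    names, lengths = [], {}
    with open(chrom_sizes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{chrom_sizes_path}:{lineno}: expected 2 columns")
            names.append(fields[0])
            lengths[fields[0]] = int(fields[1])
    genome = GenomeModel(chrom_names=names, chrom_lengths=lengths, bin_size=bin_size)
    if gc_bedgraph_path is not None:
        track = read_bedgraph(gc_bedgraph_path, genome, bin_size=bin_size)
        genome.gc = {c: np.clip(v, 0.0, 1.0) for c, v in track.values.items()}
    return genome


# ---------------------------------------------------------------------------
# Expression / design / gene tables


def read_expression(path) -> pd.DataFrame:
    """Genes x samples count table; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> dict[str, str]:
    """Two-column TSV sample -> condition."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["condition"]))


def write_design(design: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, cond in design.items():
            fh.write(f"{sample}\t{cond}\n")


def read_genes(path) -> GeneAnnotation:
    """Gene annotation TSV with header gene_id, chrom, strand, tss[, start, end]."""
    df = pd.read_csv(path, sep="\t")
    return GeneAnnotation(df)


def write_genes(genes: GeneAnnotation, path) -> None:
    genes.df.to_csv(path, sep="\t", index=False)


def read_genes_gtf(path) -> GeneAnnotation:
    """GTF-lite adapter: 'gene' features only; TSS from strand.

    Converts the GTF 1-based closed interval to 0-based half-open; the TSS of
    a minus-strand gene is the interval's last base.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            chrom, start1, end1, strand, attrs = (
                fields[0], int(fields[3]), int(fields[4]), fields[6], fields[8])
            gene_id = None
            for token in attrs.split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gene_id = token.split(" ", 1)[1].strip().strip('"')
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            start, end = start1 - 1, end1
            tss = start if strand == "+" else end - 1
            rows.append((gene_id, chrom, strand, tss, start, end))
    return GeneAnnotation(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"]))
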