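"""End-to-end orchestration: demo dataset generation and the staged run.

``make_demo`` writes a fully self-contained synthetic dataset (expression,
gene sets, gene annotation, three histone marks in two conditions, cis/trans
contact maps at compartment and ABC resolution) plus the planted-truth JSON
and a ready-to-run YAML config.  ``run_pipeline`` executes the four analysis
stages in dependency order, writes tables under the output directory and
returns a report with per-stage statuses, row counts, the echoed thresholds
and a SHA-256 manifest of every output (reruns with the same config and seed
are byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abcscore, diffstats, genome3d, io, landscape, pathway, synthetic
from .core import GenomeModel
from .synthetic import SyntheticTruth


@dataclass
class Thresholds:
    """Every analysis threshold the pipeline applies, with its default."""

    padj_max: float = 0.05
    lfc_min: float = 0.5
    pathway_diff: float = 0.1
    classifier_t: float = 0.2
    saddle_bins: int = 50
    saddle_trim: float = 0.025
    promoter_halfwidth: int = 2500
    abc_window: int = 1_000_000
    abc_resolution: int = 5_000
    insulation_window_bins: int = 10
    boundary_prominence: float = 0.1


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    chrom_sizes: str | None = None
    gc_bedgraph: str | None = None
    bin_size: int = 25_000
    expression: str | None = None
    design: str | None = None
    gmt: str | None = None
    genes: str | None = None
    # marks[mark][condition] -> {"peaks": path, "track": path}
    marks: dict = field(default_factory=dict)
    # contacts[condition] at compartment resolution; contacts_fine at ABC res.
    contacts: dict = field(default_factory=dict)
    contacts_fine: dict = field(default_factory=dict)
    conditions: tuple[str, str] = ("cond1", "cond2")
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        thr = Thresholds(**data.pop("thresholds", {}))
        cond = tuple(data.pop("conditions", ("cond1", "cond2")))
        return cls(thresholds=thr, conditions=cond, **data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["conditions"] = list(self.conditions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def validate(self) -> None:
        for name in ("padj_max", "lfc_min", "pathway_diff", "classifier_t",
                     "saddle_trim", "boundary_prominence"):
            if getattr(self.thresholds, name) < 0:
                raise ValueError(f"threshold {name} must be non-negative")
        for label, p in self._paths():
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p}")

    def _paths(self):
        yield "chrom_sizes", self.chrom_sizes
        yield "gc_bedgraph", self.gc_bedgraph
        for attr in ("expression", "design", "gmt", "genes"):
            yield attr, getattr(self, attr)
        for mark, conds in self.marks.items():
            for cond, files in conds.items():
                yield f"marks.{mark}.{cond}.peaks", files.get("peaks")
                yield f"marks.{mark}.{cond}.track", files.get("track")
        for cond, p in self.contacts.items():
            yield f"contacts.{cond}", p
        for cond, p in self.contacts_fine.items():
            yield f"contacts_fine.{cond}", p


# ---------------------------------------------------------------------------
# Demo dataset


def make_demo(out_dir, seed: int = 0, n_genes: int = 1200, n_de: int = 200,
              lfc: float = 2.0, dispersion: float = 0.01,
              n_chrom: int = 2, chrom_length: int = 10_000_000,
              bin_size: int = 25_000, block_bins: int = 10,
              delta: float = 1.0, decay_exponent: float = -1.0,
              total_reads: float = 5e6, fine_reads: float = 1.5e6,
              snr: float = 10.0, write_fine: bool = True) -> RunConfig:
    """Generate a self-contained synthetic dataset plus its RunConfig.

    The fine-resolution (5 kb) contact map used for ABC scoring is simulated
    for the first chromosome only; ABC scores cover its genes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]

    # genome, compartment labels, flips
    labels1 = {f"chr{i + 1}": synthetic.checkerboard_labels(
        int(np.ceil(chrom_length / bin_size)), block=block_bins)
        for i in range(n_chrom)}
    labels2, flip_bins = synthetic.flip_labels(
        labels1, n_flip_blocks=4, block=block_bins, seed=seeds[0])
    genome = synthetic.make_genome(n_chrom, chrom_length, bin_size, seeds[1],
                                   compartment_labels=labels1)
    io.write_chrom_sizes(genome, out / "chrom.sizes")
    gc_track = io.SignalTrack(values={c: v.copy() for c, v in genome.gc.items()},
                              bin_size=bin_size, sample="gc")
    io.write_signal_bedgraph(gc_track, genome, out / "gc.bedgraph")

    # genes + expression + pathways
    genes = synthetic.place_genes(genome, n_genes, seed=seeds[2])
    io.write_genes(genes, out / "genes.tsv")
    expr, design, truth_expr = synthetic.simulate_expression(
        n_genes=n_genes, n_de=n_de, lfc=lfc, dispersion=dispersion,
        seed=seeds[3], gene_ids=list(genes.df["gene_id"]))
    io.write_expression(expr, out / "expression.tsv")
    io.write_design(design, out / "design.tsv")
    db = synthetic.make_pathway_db(list(genes.df["gene_id"]), seed=seeds[4])
    io.write_gmt(db, out / "pathways.gmt")

    # histone marks
    states = synthetic.plant_promoter_states(genes, seed=seeds[5])
    enhancers = synthetic.plant_enhancers(genome, genes, seed=seeds[5] + 1)
    marks, truth_marks = synthetic.simulate_marks(
        genome, genes, states, enhancers=enhancers, snr=snr, seed=seeds[6])
    marks_cfg: dict = {}
    for (mark, cond), (peaks, track) in marks.items():
        pb = out / f"{mark}_{cond}_peaks.bed"
        tb = out / f"{mark}_{cond}.bedgraph"
        io.write_bed(peaks, pb)
        io.write_signal_bedgraph(track, genome, tb)
        marks_cfg.setdefault(mark, {})[cond] = {
            "peaks": str(pb), "track": str(tb)}

    # contact maps
    trans_spec = [("chr1", (40, 80), "chr2", (100, 140))] if n_chrom > 1 else []
    cmaps, truth_contacts = synthetic.simulate_contacts(
        genome, {"cond1": labels1, "cond2": labels2},
        decay_exponent=decay_exponent, delta=delta, total_reads=total_reads,
        trans_spec=trans_spec, seed=seeds[7])
    contacts_cfg = {}
    for cond, cmap in cmaps.items():
        p = out / f"contacts_{cond}_{bin_size}.txt"
        io.write_contacts(cmap, genome, p)
        contacts_cfg[cond] = str(p)

    fine_cfg = {}
    if write_fine:
        fine_bin = 5_000
        chr1 = genome.chrom_names[0]
        fine_genome = GenomeModel(
            chrom_names=[chr1],
            chrom_lengths={chr1: genome.chrom_lengths[chr1]},
            bin_size=fine_bin)
        factor = bin_size // fine_bin
        fine_labels = {
            "cond1": {chr1: np.repeat(labels1[chr1], factor)},
            "cond2": {chr1: np.repeat(labels2[chr1], factor)},
        }
        fine_maps, _ = synthetic.simulate_contacts(
            fine_genome, fine_labels, decay_exponent=decay_exponent,
            delta=delta, total_reads=fine_reads, cis_fraction=1.0,
            seed=seeds[7] + 1)
        for cond, cmap in fine_maps.items():
            p = out / f"contacts_{cond}_5000.txt"
            io.write_contacts(cmap, fine_genome, p)
            fine_cfg[cond] = str(p)

    truth = SyntheticTruth(
        seed=seed,
        de_genes=truth_expr.de_genes,
        promoter_states=truth_marks.promoter_states,
        planted_peaks=truth_marks.planted_peaks,
        compartment_labels=truth_contacts.compartment_labels,
        flipped_bins=flip_bins,
        decay_exponent=decay_exponent,
        enriched_trans_pairs=[[t[0], list(t[1]), t[2], list(t[3])]
                              for t in trans_spec],
        warnings=truth_contacts.warnings,
    )
    truth.to_json(out / "truth.json")

    config = RunConfig(
        out_dir=str(out / "results"),
        seed=seed,
        chrom_sizes=str(out / "chrom.sizes"),
        gc_bedgraph=str(out / "gc.bedgraph"),
        bin_size=bin_size,
        expression=str(out / "expression.tsv"),
        design=str(out / "design.tsv"),
        gmt=str(out / "pathways.gmt"),
        genes=str(out / "genes.tsv"),
        marks=marks_cfg,
        contacts=contacts_cfg,
        contacts_fine=fine_cfg,
    )
    config.to_yaml(out / "config.yaml")
    return config


# ---------------------------------------------------------------------------
# Pipeline run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _binned_track_lfc(track1, track2, genome: GenomeModel, bin_size: int,
                      eps: float = 0.1) -> dict[str, np.ndarray]:
    """Per-coarse-bin log2 fold change of mean track signal."""
    out = {}
    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        v1 = np.array([track1.mean_over_interval(
            chrom, b * bin_size, min((b + 1) * bin_size,
                                     genome.chrom_lengths[chrom]))
            for b in range(n)])
        v2 = np.array([track2.mean_over_interval(
            chrom, b * bin_size, min((b + 1) * bin_size,
                                     genome.chrom_lengths[chrom]))
            for b in range(n)])
        out[chrom] = np.log2((v2 + eps) / (v1 + eps))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; returns the run report."""
    config.validate()
    thr = config.thresholds
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    c1, c2 = config.conditions
    report: dict = {"stages": {}, "thresholds": asdict(thr),
                    "seed": config.seed, "outputs": {}}
    t_all = time.time()

    genome = None
    if config.chrom_sizes:
        genome = io.read_genome(config.chrom_sizes, config.bin_size,
                                gc_bedgraph_path=config.gc_bedgraph)
    genes = io.read_genes(config.genes) if config.genes else None

    def stage(name):
        report["stages"][name] = {"status": "running"}
        return time.time()

    def done(name, t0, **info):
        report["stages"][name].update(status="ok",
                                      seconds=round(time.time() - t0, 2), **info)

    def skip(name, reason):
        report["stages"][name] = {"status": "skipped", "reason": reason}

    # ---- stage 1: expression ------------------------------------------------
    diff = None
    if config.expression and config.design:
        t0 = stage("expression")
        expr = io.read_expression(config.expression)
        design = io.read_design(config.design)
        norm, _ = diffstats.normalize_library(expr)
        res = diffstats.two_group_test(norm, design, c1, c2)
        diff = diffstats.apply_significance(res, padj_max=thr.padj_max,
                                            lfc_min=thr.lfc_min)
        diff.to_csv(out / "differential.tsv", sep="\t", index_label="gene_id")
        info = {"n_features": len(diff), "n_up": diff.attrs["n_up"],
                "n_down": diff.attrs["n_down"]}
        if config.gmt:
            db = io.read_gmt(config.gmt)
            rel = pathway.relative_expression(norm, design)
            act = pathway.pathway_activity(rel, db)
            act.scores.assign(difference=act.difference(c1, c2)).to_csv(
                out / "pathway_activity.tsv", sep="\t")
            div = pathway.filter_divergent_pathways(act, c1, c2,
                                                    threshold=thr.pathway_diff)
            div.scores.assign(difference=div.difference(c1, c2)).to_csv(
                out / "pathway_divergent.tsv", sep="\t")
            info["n_pathways"] = len(act.scores)
            info["n_divergent"] = len(div.scores)
        done("expression", t0, **info)
    else:
        skip("expression", "expression/design inputs absent")

    # ---- stage 2: landscape -------------------------------------------------
    enh_sets = {}
    states = {}
    mark_tracks: dict = {}
    if config.marks and genes is not None:
        t0 = stage("landscape")
        data: dict = {}
        for mark, conds in config.marks.items():
            for cond, files in conds.items():
                peaks = io.read_bed(files["peaks"])
                track = io.read_bedgraph(files["track"], genome,
                                         bin_size=None if genome is None else 500) \
                    if genome is not None else None
                data[(mark, cond)] = (peaks, track)
                mark_tracks[(mark, cond)] = track
        dyn_rows = []
        for mark in config.marks:
            dyn = landscape.classify_peak_dynamics(
                data[(mark, c1)][0], data[(mark, c2)][0])
            cons, lost, gained = dyn.counts
            dyn_rows.append((mark, cons, lost, gained))
        pd.DataFrame(dyn_rows, columns=["mark", "conserved", "lost", "gained"]
                     ).to_csv(out / "peak_dynamics.tsv", sep="\t", index=False)

        for cond in (c1, c2):
            states[cond] = landscape.promoter_state(
                data[("H3K4me3", cond)][0], data[("H3K27me3", cond)][0],
                genes, promoter_halfwidth=thr.promoter_halfwidth)
            enh_sets[cond] = landscape.define_enhancers(
                data[("H3K27ac", cond)][0], genes,
                promoter_halfwidth=thr.promoter_halfwidth)
        pd.DataFrame(states).to_csv(out / "promoter_states.tsv", sep="\t",
                                    index_label="gene_id")
        enh_dyn = landscape.enhancer_dynamics(enh_sets[c1], enh_sets[c2])
        info = {"promoter_genes": len(states[c1]),
                "enhancers_" + c1: len(enh_sets[c1]),
                "enhancers_" + c2: len(enh_sets[c2]), **enh_dyn}

        if diff is not None:
            biv = landscape.bivalent_transition_table(states[c1], states[c2], diff)
            biv.to_csv(out / "bivalent_transitions.tsv", sep="\t")
            corr_rows = []
            for mark in ("H3K27me3", "H3K4me3"):
                if (mark, c1) not in data or data[(mark, c1)][1] is None:
                    continue
                s1 = landscape.promoter_signal(
                    data[(mark, c1)][1], genes, halfwidth=thr.promoter_halfwidth)
                s2 = landscape.promoter_signal(
                    data[(mark, c2)][1], genes, halfwidth=thr.promoter_halfwidth)
                sig_lfc = np.log2((s2 + 1.0) / (s1 + 1.0))
                sig_set = set(diff.index[diff["significant"]])
                try:
                    r, p, n = landscape.modification_expression_correlation(
                        sig_lfc, diff["log2fc"], restrict=sig_set)
                    corr_rows.append((mark, r, p, n))
                except ValueError:
                    corr_rows.append((mark, np.nan, np.nan, 0))
            pd.DataFrame(corr_rows, columns=["mark", "pearson_r", "pvalue", "n"]
                         ).to_csv(out / "mark_expression_correlation.tsv",
                                  sep="\t", index=False)
        done("landscape", t0, **info)
    else:
        skip("landscape", "marks/genes inputs absent")

    # ---- stage 3: ABC -------------------------------------------------------
    if config.contacts_fine and enh_sets and genome is not None:
        t0 = stage("abc")
        tables = {}
        for cond in (c1, c2):
            fine_map = io.read_contacts(Path(config.contacts_fine[cond]),
                                        genome, bin_size=thr.abc_resolution)
            covered = [c for c, m in fine_map.cis.items() if m.sum() > 0]
            sub_genes = io.GeneAnnotation(
                genes.df[genes.df["chrom"].isin(covered)])
            tables[cond] = abcscore.abc_table(
                sub_genes, enh_sets[cond],
                mark_tracks[("H3K27ac", cond)], mark_tracks[("H3K4me3", cond)],
                fine_map, window=thr.abc_window,
                promoter_halfwidth=thr.promoter_halfwidth)
            tables[cond].to_csv(out / f"abc_{cond}.tsv", sep="\t")
        info = {"n_genes": len(tables[c1])}
        if diff is not None:
            for score in ("abc", "abc_p2"):
                try:
                    r, p, n = abcscore.abc_expression_correlation(
                        tables[c1], tables[c2], diff["log2fc"], score=score)
                    info[f"{score}_expr_r"] = round(r, 4)
                    info[f"{score}_expr_n"] = n
                except ValueError:
                    info[f"{score}_expr_r"] = None
        done("abc", t0, **info)
    else:
        skip("abc", "fine contacts / enhancers absent")

    # ---- stage 4: 3D genome -------------------------------------------------
    if config.contacts and genome is not None and genome.gc:
        t0 = stage("genome3d")
        cmaps = {cond: io.read_contacts(Path(p), genome, config.bin_size)
                 for cond, p in config.contacts.items()}
        tracks = {cond: genome3d.compartment_track(cmaps[cond], genome)
                  for cond in (c1, c2)}
        for cond in (c1, c2):
            with open(out / f"pc1_{cond}.bedgraph", "w") as fh:
                for chrom in genome.chrom_names:
                    for b, v in enumerate(tracks[cond].values[chrom]):
                        if not np.isnan(v):
                            fh.write(f"{chrom}\t{b * config.bin_size}"
                                     f"\t{(b + 1) * config.bin_size}\t{v:.6g}\n")
        labels = {}
        frac_rows = {}
        for chrom in genome.chrom_names:
            labels[chrom] = genome3d.classify_compartment_change(
                tracks[c1].values[chrom], tracks[c2].values[chrom],
                t=thr.classifier_t)
        all_labels = np.concatenate([labels[c] for c in genome.chrom_names])
        fracs = genome3d.change_fractions(all_labels)
        fracs.to_csv(out / "compartment_change_fractions.tsv", sep="\t",
                     header=["fraction"])
        with open(out / "compartment_changes.bed", "w") as fh:
            for chrom in genome.chrom_names:
                for b, lab in enumerate(labels[chrom]):
                    if lab:
                        fh.write(f"{chrom}\t{b * config.bin_size}"
                                 f"\t{(b + 1) * config.bin_size}\t{lab}\n")

        oe = {cond: {c: genome3d.oe_matrix(cmaps[cond].cis[c])
                     for c in genome.chrom_names} for cond in (c1, c2)}
        saddles = {cond: genome3d.saddle(oe[cond], tracks[cond],
                                         n_bins=thr.saddle_bins,
                                         trim=thr.saddle_trim)
                   for cond in (c1, c2)}
        for cond, sad in saddles.items():
            np.savetxt(out / f"saddle_{cond}.tsv", sad.matrix, delimiter="\t")
        curves = {cond: genome3d.ps_curve(cmaps[cond]) for cond in (c1, c2)}
        ratio, crossings = genome3d.ps_log2fc(curves[c1], curves[c2])
        ps_df = pd.DataFrame({
            "distance_bp": curves[c1].centers,
            f"freq_{c1}": curves[c1].frequency,
            f"freq_{c2}": curves[c2].frequency,
            "log2fc": ratio})
        ps_df.to_csv(out / "ps_curve.tsv", sep="\t", index=False)
        cis_fc, trans_fc = genome3d.interaction_fold_changes(cmaps[c1], cmaps[c2])
        cis_fc.to_csv(out / "cis_log2fc.tsv", sep="\t", header=["log2fc"])
        trans_fc.to_csv(out / "trans_log2fc.tsv", sep="\t")

        ins = {cond: genome3d.insulation(cmaps[cond],
                                         window_bins=thr.insulation_window_bins)
               for cond in (c1, c2)}
        bnd = {}
        for cond in (c1, c2):
            with open(out / f"insulation_{cond}.bedgraph", "w") as fh:
                for chrom in genome.chrom_names:
                    for b, v in enumerate(ins[cond].scores[chrom]):
                        if not np.isnan(v):
                            fh.write(f"{chrom}\t{b * config.bin_size}"
                                     f"\t{(b + 1) * config.bin_size}\t{v:.6g}\n")
            bnd[cond], _, _ = genome3d.boundaries_and_domains(
                ins[cond], prominence=thr.boundary_prominence)
        merged = genome3d.merge_boundaries(bnd[c1], bnd[c2])
        try:
            btab, bsum = genome3d.compare_boundary_insulation(
                ins[c1], ins[c2], merged)
            btab.to_csv(out / "boundary_insulation.tsv", sep="\t", index=False)
        except ValueError:
            bsum = {"n_boundaries": 0}

        info = {"saddle_strength_" + c1: round(saddles[c1].strength, 3),
                "saddle_strength_" + c2: round(saddles[c2].strength, 3),
                "n_ps_crossings": len(crossings),
                "ps_crossings_bp": [round(x) for x in crossings],
                **{f"boundary_{k}": v for k, v in bsum.items()}}

        if cmaps[c1].trans:
            pair = next(iter(cmaps[c1].trans))
            top = genome3d.top_trans_regions(cmaps[c1], cmaps[c2], pair,
                                             fraction=0.005)
            top.to_csv(out / "top_trans_regions.tsv", sep="\t", index=False)
            info["n_top_trans_regions"] = len(top)

        if mark_tracks:
            for mark in config.marks:
                lfc_by_chrom = _binned_track_lfc(
                    mark_tracks[(mark, c1)], mark_tracks[(mark, c2)],
                    genome, config.bin_size)
                lfc_all = np.concatenate(
                    [lfc_by_chrom[c] for c in genome.chrom_names])
                summary = genome3d.signal_change_by_category(all_labels, lfc_all)
                summary.to_csv(out / f"mark_by_category_{mark}.tsv", sep="\t")
        done("genome3d", t0, **info)
    else:
        skip("genome3d", "contacts / genome inputs absent")

    # mark stages after a failure as unreached happens via exception
    report["outputs"] = {p.name: _sha256(p)
                         for p in sorted(out.iterdir())
                         if p.is_file() and p.name != "report.json"}
    report["total_seconds"] = round(time.time() - t_all, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
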