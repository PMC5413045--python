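"""Pipeline orchestration, run reporting and count/percentage bookkeeping.

``run_pipeline`` executes the full chain on synthetic inputs:

    syndata -> readproc -> mirdiscover -> diffexpr -> enrichment -> targetscan

writing every stage artifact plus a manifest (parameters, seed, artifact
hashes, package version) so a rerun with the identical configuration is
byte-reproducible.  The :class:`RunReport` collects the bookkeeping the
study reports: per-stage read counts, per-contrast up/down counts with
percentages of the probe total, Venn overlaps between contrasts, the
cross-contrast Pearson correlation, screened-miRNA counts and enrichment
summaries — every number recomputable from the written artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import (
    call_de,
    cluster_features,
    contrast_correlation,
    ddct,
    linkage_to_newick,
    normalize_trimmed_mean,
    screen_responsive,
    venn,
)
from .enrichment import TermMap, enrich
from .mirdiscover import (
    DiscoveryParams,
    discover_loci,
    quantify,
    rescue_unaligned,
    write_predictions_gff3,
    write_predictions_tsv,
)
from .readproc import align_perfect, mask_genome, preprocess_library, write_hits_tsv, \
    write_processed_fasta
from .syndata import (
    SAMPLES,
    SimConfig,
    discovery_stats,
    make_genome,
    sample_id,
    simulate_ct_table,
    simulate_go_map,
    simulate_microarray_pair,
    simulate_small_rna_libraries,
    simulate_transcripts,
    write_annotations_gff3,
    write_config,
    write_genome_fasta,
    write_reads_fastq,
)
from .targetscan import scan, write_hits_tsv as write_target_hits_tsv

__all__ = ["RunReport", "report_fractions", "run_pipeline"]


def report_fractions(count: int, total: int) -> float:
    """Percentage 100*count/total, rounded half-away-from-zero to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RunReport:
    """Count/percentage bookkeeping for one pipeline run."""

    seed: int = 0
    stage_counts: dict = field(default_factory=dict)       # library -> stage rows
    discovery: dict = field(default_factory=dict)
    quantification: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=dict)          # name -> counts/pcts
    venn_regions: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    targets: dict = field(default_factory=dict)
    qpcr: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            raise TypeError(f"not serializable: {type(o)}")

        Path(path).write_text(json.dumps(asdict(self), indent=2, default=default))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: SimConfig, outdir, *, small_rna: bool = True,
                 microarray: bool = True, params: DiscoveryParams | None = None
                 ) -> RunReport:
    """Run the synthetic study end to end; artifacts land under ``outdir``.

    ``small_rna=False`` or ``microarray=False`` skips the corresponding
    branch (the report then covers only the other one).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or DiscoveryParams()
    report = RunReport(seed=config.seed)
    artifacts: list[Path] = []

    def save(path: Path):
        artifacts.append(path)
        return path

    write_config(config, save(outdir / "config.txt"))

    genome = make_genome(config)
    write_genome_fasta(genome, save(outdir / "genome.fasta"))
    write_annotations_gff3(genome, save(outdir / "annotations.gff3"))
    with open(save(outdir / "catalog.fasta"), "w") as fh:
        for name, seq in genome.catalog.items():
            fh.write(f">{name}\n{seq}\n")

    counts_table = None
    if small_rna:
        libraries, truth_small = simulate_small_rna_libraries(genome, config)
        truth_small.to_csv(save(outdir / "truth_small_rna.tsv"), sep="\t", index=False)
        masked = mask_genome(genome.chromosomes,
                             genome.repeats + [d[:3] for d in genome.decoys])
        hits_by_library = {}
        unaligned = []
        for line, temp in SAMPLES:
            sid = sample_id(line, temp)
            raw = libraries[sid]
            write_reads_fastq(raw, save(outdir / f"reads_{sid}.fastq"))
            reads, log = preprocess_library(
                raw, sid, config.adapter_seq, config.stop_oligo_seq,
                list(genome.decoy_seqs.values()),
                min_len=params.min_mirna_len, max_len=params.max_mirna_len)
            write_processed_fasta(reads, save(outdir / f"processed_{sid}.fasta"))
            lib_hits, lib_unaligned = align_perfect(reads, masked)
            write_hits_tsv(lib_hits, save(outdir / f"hits_{sid}.tsv"))
            aligned_units = sum(h.read.count for h in lib_hits)
            log.add("align", sum(r.count for r in reads), aligned_units)
            log.write(save(outdir / f"stages_{sid}.tsv"))
            report.stage_counts[sid] = log.rows
            hits_by_library[sid] = lib_hits
            unaligned.extend(lib_unaligned)

        pooled = [h for hs in hits_by_library.values() for h in hs]
        predictions, rejections = discover_loci(pooled, masked, genome.catalog, params)
        write_predictions_gff3(predictions, save(outdir / "predictions.gff3"))
        write_predictions_tsv(predictions, save(outdir / "predictions.tsv"))
        pd.DataFrame([r.__dict__ for r in rejections]).to_csv(
            save(outdir / "rejections.tsv"), sep="\t", index=False)
        rescues = rescue_unaligned(unaligned, genome.catalog, params.known_identity)
        counts_table = quantify(predictions, rescues, hits_by_library)
        counts_table.to_csv(save(outdir / "mirna_counts.tsv"), sep="\t")

        stats = discovery_stats(predictions, genome.truth_loci)
        reasons = {}
        for r in rejections:
            reasons[r.reason] = reasons.get(r.reason, 0) + 1
        report.discovery = {
            "n_predictions": len(predictions),
            "n_known": sum(p.status == "known" for p in predictions),
            "n_novel": sum(p.status == "novel" for p in predictions),
            "n_rescued": len(rescues),
            "rejections": reasons,
            **stats,
        }
        libs = [sample_id(l, t) for l, t in SAMPLES]
        n_all = int(counts_table["expressed_in_all"].sum())
        report.quantification = {
            "n_features": len(counts_table),
            "n_expressed_in_all": n_all,
            "pct_expressed_in_all": report_fractions(n_all, len(counts_table)),
            "reads_assigned": {lib: int(counts_table[lib].sum()) for lib in libs},
        }

        # responsiveness screen over miRNAs expressed in all four libraries
        expressed = counts_table[counts_table["expressed_in_all"]]
        screen_table = screen_responsive(expressed, "wt", "net2")
        screen_table.to_csv(save(outdir / "screen.tsv"), sep="\t")
        selected = set(screen_table.index[screen_table["selected"]])
        # map selected features back to planted responsive loci
        truth_resp = set()
        pred_by_id = {p.locus_id: p for p in predictions}
        for locus in genome.truth_loci:
            if not locus.responsive:
                continue
            for fid in selected:
                p = pred_by_id.get(fid)
                if p is not None and p.chromosome == locus.chromosome \
                        and p.strand == locus.strand \
                        and p.mature_interval[0] < locus.mature_interval[1] \
                        and locus.mature_interval[0] < p.mature_interval[1]:
                    truth_resp.add(locus.locus_id)
        n_responsive = sum(l.responsive for l in genome.truth_loci)
        report.screen = {
            "n_screened": len(screen_table),
            "n_selected": len(selected),
            "selected": sorted(selected),
            "n_planted_responsive": n_responsive,
            "n_planted_recovered": len(truth_resp),
            "screen_sensitivity": (len(truth_resp) / n_responsive
                                   if n_responsive else float("nan")),
        }

    if microarray:
        matrix, truth_de = simulate_microarray_pair(config)
        matrix.to_csv(save(outdir / "microarray_raw.tsv"), sep="\t")
        truth_de.to_csv(save(outdir / "truth_microarray.tsv"), sep="\t", index=False)
        norm = normalize_trimmed_mean(matrix)
        norm.to_csv(save(outdir / "microarray_normalized.tsv"), sep="\t")
        reps = config.n_reps
        groups = {g: [f"{g}_{r + 1}" for r in range(reps)] for g in "ABC"}
        contrast_defs = {"B_vs_A": ("A", "B"), "C_vs_A": ("A", "C")}
        results = {}
        total = len(norm)
        for name, (ga, gb) in contrast_defs.items():
            res = call_de(norm, groups[ga], groups[gb])
            res.table.to_csv(save(outdir / f"contrast_{name}.tsv"), sep="\t")
            results[name] = res
            report.contrasts[name] = {
                "total_probes": total,
                "n_up": len(res.up),
                "n_down": len(res.down),
                "pct_up": report_fractions(len(res.up), total),
                "pct_down": report_fractions(len(res.down), total),
            }
        report.venn_regions = {
            "up": venn({"B_vs_A": results["B_vs_A"].up, "C_vs_A": results["C_vs_A"].up}),
            "down": venn({"B_vs_A": results["B_vs_A"].down,
                          "C_vs_A": results["C_vs_A"].down}),
        }
        log = np.log2(norm + 1)
        d1 = (log[groups["B"]].mean(axis=1) - log[groups["A"]].mean(axis=1)).values
        d2 = (log[groups["C"]].mean(axis=1) - log[groups["A"]].mean(axis=1)).values
        r, p = contrast_correlation(d1, d2)
        report.correlations["B_vs_A~C_vs_A"] = {"r": round(r, 3), "p": p}

        # cluster the union of differential probes on per-replicate log2 ratios
        de_union = sorted(results["B_vs_A"].up | results["B_vs_A"].down
                          | results["C_vs_A"].up | results["C_vs_A"].down)
        if len(de_union) >= 6:
            prof = pd.DataFrame({
                f"{g}{r + 1}": log.loc[de_union, f"{g}_{r + 1}"]
                                - log.loc[de_union, groups["A"]].mean(axis=1)
                for g in "BC" for r in range(reps)})
            link, labels, dropped = cluster_features(prof, k=6)
            labels.to_csv(save(outdir / "clusters.tsv"), sep="\t")
            (outdir / "dendrogram.nwk").write_text(
                linkage_to_newick(link, list(labels.index)))
            artifacts.append(outdir / "dendrogram.nwk")
            report.clustering = {
                "n_features": len(labels),
                "n_clusters": int(labels.nunique()),
                "n_dropped_constant": len(dropped),
            }

        # GO enrichment of the B-contrast differential set
        de_set = results["B_vs_A"].up | results["B_vs_A"].down
        go = simulate_go_map(config, genes=list(norm.index),
                             test_set=de_set or None)
        term_map = TermMap(go.gene2term, go.term_levels)
        if de_set:
            table = enrich(de_set, set(norm.index), term_map)
            table.to_csv(save(outdir / "enrichment.tsv"), sep="\t", index=False)
            sig = set(table.loc[table["significant"], "term"])
            report.enrichment = {
                "n_terms_tested": len(table),
                "n_significant": len(sig),
                "planted_terms": go.enriched_terms,
                "planted_recovered": sorted(sig & set(go.enriched_terms)),
            }

    # target prediction for the known-miRNA catalog entries
    known = {k: v for k, v in genome.catalog.items() if k.startswith("kmiR")}
    transcripts, truth_sites = simulate_transcripts(config, known)
    with open(save(outdir / "transcripts.fasta"), "w") as fh:
        for name, seq in transcripts.items():
            fh.write(f">{name}\n{seq}\n")
    truth_sites.to_csv(save(outdir / "truth_targets.tsv"), sep="\t", index=False)
    target_hits = scan(known, transcripts)
    write_target_hits_tsv(target_hits, save(outdir / "target_hits.tsv"))
    recovered = 0
    for row in truth_sites.itertuples():
        if any(h.mirna_id == row.mirna_id and h.transcript_id == row.transcript_id
               and h.start < row.end and row.start < h.end for h in target_hits):
            recovered += 1
    report.targets = {
        "n_hits": len(target_hits),
        "n_planted_sites": len(truth_sites),
        "n_planted_recovered": recovered,
        "max_expectation": max((h.expectation for h in target_hits), default=0.0),
    }

    # qPCR relative quantification
    ct_table, truth_ct = simulate_ct_table(config)
    ct_table.to_csv(save(outdir / "ct_table.tsv"), sep="\t", index=False)
    truth_ct.to_csv(save(outdir / "truth_ct.tsv"), sep="\t")
    calibrator = sample_id(*SAMPLES[0])
    rel = {}
    for gene in truth_ct.index:
        rel[gene] = {s: round(ddct(ct_table, gene, "actin", s, calibrator), 4)
                     for s in truth_ct.columns}
    report.qpcr = {"calibrator": calibrator, "relative_expression": rel}

    report.to_json(outdir / "report.json")
    artifacts.append(outdir / "report.json")
    manifest = {
        "tool": "crownmir",
        "version": __version__,
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
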