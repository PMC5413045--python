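"""Locus discovery: clustering, hairpin gating, classification, quantification."""

import pytest

from crownmir.mirdiscover import (
    DiscoveryParams,
    MirnaPrediction,
    Rejection,
    classify_known,
    cluster_hits,
    discover_loci,
    predict_locus,
    quantify,
    rescue_unaligned,
)
from crownmir.readproc import AlignmentHit, ProcessedRead, align_perfect, preprocess_library
from crownmir.syndata import (
    SimConfig,
    make_genome,
    revcomp,
    simulate_small_rna_libraries,
)


def hit(seq, chrom, start, strand="+", count=1, lib="lib"):
    return AlignmentHit(ProcessedRead(seq, count, lib), chrom, start, start + len(seq), strand)


@pytest.fixture(scope="module")
def mini_config():
    return SimConfig(genome_length=30_000, n_known_loci=6, n_novel_loci=4,
                     n_decoy_ncrna=4, n_repeats=6, library_depth=10_000, seed=11)


@pytest.fixture(scope="module")
def mini_run(mini_config):
    """Reduced-scale end-to-end run: simulate -> preprocess -> align -> discover."""
    from crownmir.readproc import mask_genome

    genome = make_genome(mini_config)
    libraries, truth = simulate_small_rna_libraries(genome, mini_config)
    masked = mask_genome(genome.chromosomes,
                         genome.repeats + [d[:3] for d in genome.decoys])
    hits_by_library = {}
    unaligned = []
    for sid, raw in libraries.items():
        reads, _ = preprocess_library(raw, sid, mini_config.adapter_seq,
                                      mini_config.stop_oligo_seq,
                                      list(genome.decoy_seqs.values()))
        lib_hits, lib_un = align_perfect(reads, masked)
        hits_by_library[sid] = lib_hits
        unaligned.extend(lib_un)
    pooled = [h for hits in hits_by_library.values() for h in hits]
    predictions, rejections = discover_loci(pooled, masked, genome.catalog)
    return dict(genome=genome, truth=truth, hits_by_library=hits_by_library,
                unaligned=unaligned, predictions=predictions, rejections=rejections,
                masked=masked)


class TestClusterHits:
    def test_distant_hits_make_two_clusters(self):
        hits = [hit("A" * 20, "A", 100), hit("C" * 20, "A", 720)]
        assert len(cluster_hits(hits, cluster_gap=50)) == 2

    def test_overlapping_isomirs_make_one_cluster(self):
        hits = [hit("A" * 20, "A", 100, count=5), hit("A" * 21, "A", 101, count=2)]
        clusters = cluster_hits(hits)
        assert len(clusters) == 1
        assert clusters[0].anchor.read.count == 5

    def test_strands_never_mix(self):
        hits = [hit("A" * 20, "A", 100, "+"), hit("C" * 20, "A", 105, "-")]
        assert len(cluster_hits(hits)) == 2

    def test_cluster_count_matches_expressed_truth_loci(self, mini_run):
        # same support floor the discovery entry point applies
        supported = [h for hs in mini_run["hits_by_library"].values()
                     for h in hs if h.read.count >= 2]
        clusters = cluster_hits(supported)
        truth = mini_run["genome"].truth_loci
        # clusters overlapping a truth precursor == expressed loci (all are expressed)
        n_truth_clusters = 0
        for c in clusters:
            s = min(h.start for h in c.hits)
            e = max(h.end for h in c.hits)
            if any(l.chromosome == c.chromosome and l.strand == c.strand
                   and s < l.precursor_interval[1] and l.precursor_interval[0] < e
                   for l in truth):
                n_truth_clusters += 1
        assert n_truth_clusters == len(truth)


class TestPredictLocus:
    def test_planted_locus_accepted_with_true_mature(self, mini_run):
        genome = mini_run["genome"]
        locus = genome.truth_loci[0]
        accepted = [p for p in mini_run["predictions"]
                    if p.chromosome == locus.chromosome and p.strand == locus.strand
                    and p.mature_interval[0] < locus.mature_interval[1]
                    and locus.mature_interval[0] < p.mature_interval[1]]
        assert accepted, "planted locus not recovered"
        assert accepted[0].mature_seq == locus.mature_seq

    def test_random_region_rejected(self):
        # anchor in a complementarity-free region
        genome = {"A": "C" * 200 + "ACAACCACAACCACAACCAC" + "C" * 200}
        cands = cluster_hits([hit("ACAACCACAACCACAACCAC", "A", 200, count=10)])
        result = predict_locus(cands[0], genome)
        assert isinstance(result, Rejection)
        assert result.reason in {"no_hairpin", "energy_gate"}

    def test_weak_hairpin_fails_energy_gate(self):
        # A20/U20 duplex: 19 AU/AU stacks + loop = -13.1 kcal/mol, above -20
        mature = "A" * 20
        core = mature + "CCCCC" + "T" * 20
        genome = {"A": "C" * 100 + core + "C" * 100}
        cands = cluster_hits([hit(mature, "A", 100, count=10)])
        result = predict_locus(cands[0], genome)
        assert isinstance(result, Rejection)
        assert result.reason == "energy_gate"

    def test_anchor_length_gate(self):
        genome = {"A": "C" * 100 + "A" * 30 + "C" * 100}
        cands = cluster_hits([hit("A" * 28, "A", 100, count=10)])
        result = predict_locus(cands[0], genome)
        assert isinstance(result, Rejection) and result.reason == "length_gate"

    def test_accepted_predictions_satisfy_all_gates(self, mini_run):
        params = DiscoveryParams()
        for p in mini_run["predictions"]:
            assert p.energy <= params.max_energy
            assert p.duplex_bulge <= params.max_duplex_bulge
            assert params.min_ref_len <= len(p.mature_seq) <= params.max_ref_len
            ms, me = p.mature_interval
            ss, se = p.star_interval
            assert max(ss - me, ms - se) <= params.max_star_space

    def test_loosening_energy_gate_never_loses_loci(self, mini_run):
        pooled = [h for hs in mini_run["hits_by_library"].values() for h in hs]
        loose, _ = discover_loci(pooled, mini_run["masked"],
                                 mini_run["genome"].catalog,
                                 DiscoveryParams(max_energy=-10.0))
        strict_keys = {(p.chromosome, p.strand, p.mature_interval)
                       for p in mini_run["predictions"]}
        loose_keys = {(p.chromosome, p.strand, p.mature_interval) for p in loose}
        assert strict_keys <= loose_keys


class TestClassifyKnown:
    def make_pred(self, mature):
        return MirnaPrediction("x", "A", "+", (0, 100), "", mature, (10, 10 + len(mature)),
                               "", (50, 70), None, -30.0)

    def test_exact_catalog_match_is_known(self):
        catalog = {"miR-1": "ACGTACGTACGTACGTACGT"}
        status, name = classify_known(self.make_pred("ACGTACGTACGTACGTACGT"), catalog)
        assert (status, name) == ("known", "miR-1")

    def test_ninety_percent_identity_boundary_inclusive(self):
        entry = "ACGTACGTACGTACGTACGT"
        mature = entry[:7] + "T" + entry[8:13] + "A" + entry[14:]  # 2 mismatches / 20
        assert mature != entry
        status, name = classify_known(self.make_pred(mature), {"miR-1": entry})
        assert (status, name) == ("known", "miR-1")

    def test_random_sequence_is_novel(self):
        catalog = {"miR-1": "ACGTACGTACGTACGTACGT"}
        status, name = classify_known(self.make_pred("GGATCCGGTTAACCGGATTGCA"), catalog)
        assert (status, name) == ("novel", None)


class TestRescue:
    def test_exact_catalog_read_rescued(self):
        catalog = {"miR-9": "ACGTACGTACGTACGTACGTA"}
        reads = [ProcessedRead("ACGTACGTACGTACGTACGTA", 7, "wt_24C")]
        assert rescue_unaligned(reads, catalog) == {"miR-9": {"wt_24C": 7}}

    def test_empty_input(self):
        assert rescue_unaligned([], {"miR-9": "ACGTACGTACGTACGTACGTA"}) == {}

    def test_jittered_read_rescued_at_identity_boundary(self):
        catalog = {"miR-9": "ACGTACGTACGTACGTACGTA"}
        reads = [ProcessedRead("CGTACGTACGTACGTACGTA", 2, "net2_4C")]  # 5' trim
        assert rescue_unaligned(reads, catalog) == {"miR-9": {"net2_4C": 2}}

    def test_planted_rescue_mirnas_recovered(self, mini_run):
        rescues = rescue_unaligned(mini_run["unaligned"], mini_run["genome"].catalog)
        for name in mini_run["genome"].rescue_mirnas:
            assert name in rescues


class TestQuantify:
    def test_counts_and_flags(self, mini_run):
        rescues = rescue_unaligned(mini_run["unaligned"], mini_run["genome"].catalog)
        table = quantify(mini_run["predictions"], rescues, mini_run["hits_by_library"])
        libs = sorted(mini_run["hits_by_library"])
        assert list(table.columns[:4]) == libs
        assert (table[libs] >= 0).all().all()
        # planted loci are expressed everywhere
        n_all = int(table["expressed_in_all"].sum())
        assert n_all >= len(mini_run["genome"].truth_loci)

    def test_absent_mirna_counts_zero(self):
        pred = MirnaPrediction("m1", "A", "+", (0, 100), "", "ACGT" * 5, (30, 50),
                               "", (60, 80), None, -30.0)
        table = quantify([pred], {}, {"wt_24C": [], "wt_4C": []})
        assert table.loc["m1", "wt_24C"] == 0
        assert not bool(table.loc["m1", "expressed_in_all"])

    def test_column_sums_conserve_assigned_reads(self, mini_run):
        table = quantify(mini_run["predictions"], {}, mini_run["hits_by_library"])
        libs = sorted(mini_run["hits_by_library"])
        for lib in libs:
            assigned = 0
            for h in mini_run["hits_by_library"][lib]:
                for p in mini_run["predictions"]:
                    ms, me = p.mature_interval
                    if (h.chromosome == p.chromosome and h.strand == p.strand
                            and h.start >= ms - 2 and h.end <= me + 2
                            and h.start < me and h.end > ms):
                        assigned += h.read.count
            assert table[lib].sum() == assigned


class TestRecovery:
    def test_sensitivity_and_precision(self, mini_run):
        from crownmir.syndata import discovery_stats
        stats = discovery_stats(mini_run["predictions"], mini_run["genome"].truth_loci)
        assert stats["sensitivity"] >= 0.9
        assert stats["precision"] >= 0.9

    def test_known_novel_split_matches_truth(self, mini_run):
        truth = {l.locus_id: l for l in mini_run["genome"].truth_loci}
        for p in mini_run["predictions"]:
            match = [l for l in truth.values()
                     if l.chromosome == p.chromosome and l.strand == p.strand
                     and p.mature_interval[0] < l.mature_interval[1]
                     and l.mature_interval[0] < p.mature_interval[1]]
            if match:
                expected = "known" if match[0].is_known else "novel"
                assert p.status == expected, (p.locus_id, match[0].locus_id)
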