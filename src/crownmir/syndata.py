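"""Synthetic study emulator: every input the pipeline consumes, with ground truth.

The generator mirrors the design of the source study: two wheat-hybrid
genotypes (a wild-type line, ``wt``, and a *Net2*-carrying line showing
temperature-dependent growth abnormality, ``net2``) each sampled at normal
temperature (24C) and low temperature (4C), giving four small-RNA libraries;
two-replicate microarray intensity matrices; Ct tables for relative qPCR
quantification; and a GO-style annotation map.  Everything is produced from a
single :class:`SimConfig` and a seed, and is byte-reproducible.

The genome is a desk-scale echo of the repeat-masked A- and D-genome
references: two 100 kb chromosomes carrying planted miRNA hairpin loci
(mature + loop + reverse-complement star, designed fold energy <= -25
kcal/mol, a >=5 kcal/mol margin below the -20 discovery gate), decoy
non-coding RNAs from distinct families (the Rfam stand-in) and tandem-repeat
tracts (the Repbase stand-in).  Reads are mature/star sequences with isomiR
end jitter plus a full 3' adapter, stop-oligo contaminants, and background
from decoys, repeats and random genome fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .rnafold import SecondaryStructure, score_energy

__all__ = [
    "SimConfig",
    "TruthLocus",
    "AnnotatedGenome",
    "SAMPLES",
    "make_genome",
    "simulate_small_rna_libraries",
    "simulate_microarray",
    "simulate_microarray_pair",
    "simulate_transcripts",
    "simulate_ct_table",
    "simulate_go_map",
    "GoSim",
    "discovery_stats",
    "write_genome_fasta",
    "write_annotations_gff3",
    "write_reads_fastq",
    "write_config",
    "read_config",
]

COMP = str.maketrans("ACGT", "TGCA")

#: the four libraries: (genotype, temperature C)
SAMPLES = (("wt", 24), ("wt", 4), ("net2", 24), ("net2", 4))


def sample_id(line: str, temp: int) -> str:
    return f"{line}_{temp}C"


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults are the desk-scale emulation of the study: 2 chromosomes x
    100 kb, 20 hairpin loci, 4 libraries of 50,000 reads, 2-replicate
    2,000-probe arrays with 10% planted 8-fold differential probes.
    """

    # genome
    genome_length: int = 100_000
    chromosome_names: tuple = ("A", "D")
    n_known_loci: int = 12
    n_novel_loci: int = 8
    n_decoy_ncrna: int = 8
    n_repeats: int = 20
    mature_length_range: tuple = (20, 24)
    loop_length_range: tuple = (12, 24)
    stem_mismatches: int = 2          # designed stem mismatches per duplex (1..this)
    design_energy: float = -27.0      # designed fold energy ceiling, kcal/mol
    flank: int = 20
    # small-RNA libraries
    library_depth: int = 50_000
    responsive_fraction: float = 0.3
    responsive_ratio: float = 8.0     # planted R_wt / R_net2 (or its inverse)
    expression_model: dict | None = None   # optional {locus_id: {sample_id: weight}}
    jitter_prob: float = 0.2          # read emitted off truth ends with this prob
    star_fraction: float = 0.1
    stop_fraction: float = 0.05
    decoy_read_fraction: float = 0.12
    repeat_read_fraction: float = 0.12
    random_read_fraction: float = 0.13
    rescue_read_fraction: float = 0.03
    n_rescue_mirnas: int = 2
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"
    stop_oligo_seq: str = "CCTTGGCACCCGAGAATTCCA"
    partial_adapter: bool = False     # reserved: sequencing running past the adapter
    background_length_range: tuple = (16, 32)
    # microarray
    n_probes: int = 2000
    de_fraction: float = 0.10
    planted_fold: float = 8.0
    noise_sd: float = 0.1             # SD of log2 intensity noise per measurement
    n_reps: int = 2
    de_shared_fraction: float = 0.5   # DE probes shared between the two contrasts
    # qPCR
    ct_noise_sd: float = 0.05
    n_ct_genes: int = 4
    # target transcripts
    n_transcripts: int = 10
    transcript_length: int = 1000
    # GO annotation
    n_go_genes: int = 800
    n_go_terms: int = 30
    go_base_prob: float = 0.08
    n_enriched_terms: int = 3
    enrichment_odds: float = 10.0
    go_test_size: int = 100
    seed: int = 0

    def __post_init__(self):
        counts = [self.n_known_loci, self.n_novel_loci, self.n_decoy_ncrna,
                  self.n_repeats, self.n_probes, self.n_reps, self.library_depth]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.planted_fold < 1:
            raise ValueError("planted_fold must be >= 1")
        for name in ("responsive_fraction", "de_fraction", "jitter_prob",
                     "stop_fraction", "star_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.mature_length_range
        if not (18 <= lo <= hi <= 26):
            raise ValueError("mature_length_range must lie within [18, 26]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream keyed on (seed, stream)."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthLocus:
    """Ground truth for one planted miRNA hairpin locus."""

    locus_id: str
    chromosome: str
    strand: str
    precursor_interval: tuple      # 0-based half-open, includes flanks
    mature_interval: tuple
    star_interval: tuple
    mature_seq: str                # read orientation (DNA alphabet)
    star_seq: str
    is_known: bool
    designed_energy: float
    responsive: bool = False
    response_ratio: float = 1.0    # planted S = R_wt / R_net2
    expected_abundance: dict = field(default_factory=dict)  # sample_id -> mature reads


@dataclass
class AnnotatedGenome:
    """Chromosomes plus repeat/decoy annotations, truth loci and catalogs."""

    chromosomes: dict
    repeats: list                  # (chrom, start, end)
    decoys: list                   # (chrom, start, end, ncrna_class)
    truth_loci: list
    decoy_seqs: dict               # name -> sequence (the Rfam stand-in)
    catalog: dict                  # name -> mature sequence (the miRBase stand-in)
    rescue_mirnas: dict            # catalog entries absent from the genome


def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _design_hairpin(rng, cfg: SimConfig) -> tuple[str, str, str, str, float, int]:
    """Design one hairpin: (mature, loop, star, arm, energy, n_mismatch).

    The designed structure pairs mature base k with the opposite star base,
    minus any planted stem mismatches; its energy under the folding model is
    required to sit at or below ``cfg.design_energy`` so every planted
    precursor clears the -20 kcal/mol discovery gate with margin.
    """
    lo, hi = cfg.mature_length_range
    for _ in range(200):
        L = int(rng.integers(lo, hi + 1))
        mature = _random_seq(rng, L)
        loop = _random_seq(rng, int(rng.integers(*cfg.loop_length_range)))
        # at least one stem mismatch: real miRNA/miRNA* duplexes are imperfect,
        # and a perfect inverted repeat would make the arms indistinguishable
        # to an exact-match aligner (the mature read would hit the star site
        # on the opposite strand as well)
        n_mm = int(rng.integers(1, max(1, cfg.stem_mismatches) + 1))
        star = list(revcomp(mature))
        mm_pos = sorted(rng.choice(np.arange(2, L - 2), size=n_mm, replace=False))
        for p in mm_pos:
            # corrupt the star base opposite mature position p
            q = L - 1 - p
            old = star[q]
            choices = [b for b in "ACGT" if b != old]
            star[q] = choices[int(rng.integers(0, 3))]
        star = "".join(star)
        hairpin = mature + loop + star
        # designed pair set: mature p <-> star (reading hairpin coordinates)
        pairs = set()
        for p in range(L):
            if p in mm_pos:
                continue
            j = len(hairpin) - 1 - p
            pairs.add((p, j))
        rna = hairpin.replace("T", "U")
        try:
            energy = score_energy(SecondaryStructure(rna, frozenset(pairs), 0.0))
        except ValueError:
            continue  # a planted mismatch happened to create an invalid pair map
        if energy <= cfg.design_energy:
            arm = "5p" if rng.random() < 0.5 else "3p"
            return mature, loop, star, arm, energy, n_mm
    raise RuntimeError("could not design a hairpin below the energy ceiling")


class _Placer:
    """Non-overlapping interval allocator with a safety margin."""

    def __init__(self, rng, chrom_names, length, margin=100):
        self.rng = rng
        self.names = list(chrom_names)
        self.length = length
        self.margin = margin
        self.placed = {c: [] for c in chrom_names}

    def place(self, size: int) -> tuple[str, int]:
        for _ in range(500):
            chrom = self.names[int(self.rng.integers(0, len(self.names)))]
            if self.length - size - self.margin <= self.margin:
                continue
            start = int(self.rng.integers(self.margin, self.length - size - self.margin))
            lo, hi = start - self.margin, start + size + self.margin
            if all(e <= lo or s >= hi for s, e in self.placed[chrom]):
                self.placed[chrom].append((start, start + size))
                return chrom, start
        raise ValueError("genome too short to place requested features without overlap")


def make_genome(config: SimConfig) -> AnnotatedGenome:
    """Build the annotated genome with planted loci, decoys and repeats."""
    rng = config.rng(1)
    chroms = {c: list(_random_seq(rng, config.genome_length))
              for c in config.chromosome_names}
    placer = _Placer(rng, config.chromosome_names, config.genome_length)

    def write(chrom, start, seq):
        chroms[chrom][start:start + len(seq)] = list(seq)

    # tandem repeats from a few distinct families
    repeat_units = [_random_seq(rng, int(rng.integers(50, 150))) for _ in range(4)]
    repeats = []
    for _ in range(config.n_repeats):
        unit = repeat_units[int(rng.integers(0, len(repeat_units)))]
        tract = unit * int(rng.integers(3, 6))
        chrom, start = placer.place(len(tract))
        write(chrom, start, tract)
        repeats.append((chrom, start, start + len(tract)))

    # decoy non-coding RNAs (distinct families)
    classes = ["rRNA", "tRNA", "snoRNA"]
    decoys, decoy_seqs = [], {}
    for i in range(config.n_decoy_ncrna):
        cls = classes[i % len(classes)]
        seq = _random_seq(rng, int(rng.integers(80, 200)))
        chrom, start = placer.place(len(seq))
        write(chrom, start, seq)
        decoys.append((chrom, start, start + len(seq), cls))
        decoy_seqs[f"{cls}_{i + 1}"] = seq

    # planted miRNA hairpin loci
    truth_loci = []
    catalog = {}
    n_total = config.n_known_loci + config.n_novel_loci
    for i in range(n_total):
        mature, loop, star, arm, energy, _ = _design_hairpin(rng, config)
        if arm == "5p":
            core = mature + loop + star
            m_off, s_off = 0, len(mature) + len(loop)
        else:
            core = star + loop + mature
            s_off, m_off = 0, len(star) + len(loop)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, start = placer.place(len(core))
        genomic = core if strand == "+" else revcomp(core)
        write(chrom, start, genomic)

        def g_interval(off, L):
            if strand == "+":
                return (start + off, start + off + L)
            return (start + len(core) - off - L, start + len(core) - off)

        is_known = i < config.n_known_loci
        locus = TruthLocus(
            locus_id=f"locus_{i + 1:03d}",
            chromosome=chrom,
            strand=strand,
            precursor_interval=(max(0, start - config.flank),
                                min(config.genome_length, start + len(core) + config.flank)),
            mature_interval=g_interval(m_off, len(mature)),
            star_interval=g_interval(s_off, len(star)),
            mature_seq=mature,
            star_seq=star,
            is_known=is_known,
            designed_energy=energy,
        )
        truth_loci.append(locus)
        if is_known:
            catalog[f"kmiR-{i + 1:03d}"] = mature

    chrom_strs = {c: "".join(s) for c, s in chroms.items()}

    # rescue miRNAs: in the catalog, in the reads, absent from the genome
    rescue = {}
    for i in range(config.n_rescue_mirnas):
        while True:
            seq = _random_seq(rng, int(rng.integers(*config.mature_length_range)))
            if all(seq not in ref and revcomp(seq) not in ref
                   for ref in chrom_strs.values()):
                break
        name = f"rescue-miR-{i + 1:02d}"
        rescue[name] = seq
        catalog[name] = seq
    # a few catalog entries that are never expressed anywhere
    for i in range(3):
        catalog[f"silent-miR-{i + 1:02d}"] = _random_seq(rng, 21)

    return AnnotatedGenome(chrom_strs, repeats, decoys, truth_loci,
                           decoy_seqs, catalog, rescue)


# ------------------------------------------------------------------
# small-RNA libraries
# ------------------------------------------------------------------

def _expression_weights(genome: AnnotatedGenome, config: SimConfig, rng
                        ) -> dict[str, dict[str, float]]:
    """Per-locus relative abundance per sample, with planted responsiveness."""
    if config.expression_model is not None:
        return config.expression_model
    weights: dict[str, dict[str, float]] = {}
    n_resp = round(config.responsive_fraction * len(genome.truth_loci))
    resp_idx = set(rng.choice(len(genome.truth_loci), size=n_resp, replace=False).tolist())
    direction = 1
    for i, locus in enumerate(genome.truth_loci):
        mu = float(np.clip(rng.lognormal(0.0, 0.8), 0.3, 8.0))
        temp_ratio = float(rng.lognormal(0.0, 0.6))  # shared 4C/24C response
        if i in resp_idx:
            locus.responsive = True
            locus.response_ratio = (config.responsive_ratio if direction > 0
                                    else 1.0 / config.responsive_ratio)
            direction *= -1
        r_wt = temp_ratio
        r_mut = temp_ratio / locus.response_ratio
        weights[locus.locus_id] = {
            sample_id("wt", 24): mu,
            sample_id("wt", 4): mu * r_wt,
            sample_id("net2", 24): mu,
            sample_id("net2", 4): mu * r_mut,
        }
    return weights


def _emit_interval(rng, config, chrom_seq: str, interval, strand: str) -> str:
    """Read off a genomic interval with isomiR end jitter."""
    s, e = interval
    if rng.random() < config.jitter_prob:
        which = int(rng.integers(0, 4))
        if which == 0:
            s -= 1
        elif which == 1:
            s += 1
        elif which == 2:
            e -= 1
        else:
            e += 1
        s = max(0, s)
        e = min(len(chrom_seq), e)
    frag = chrom_seq[s:e]
    return frag if strand == "+" else revcomp(frag)


def simulate_small_rna_libraries(genome: AnnotatedGenome, config: SimConfig
                                 ) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Four raw small-RNA libraries plus the per-locus expected-count table.

    Returns ``(libraries, truth)`` where ``libraries`` maps sample id to raw
    read list (insert + full 3' adapter) and ``truth`` holds per-locus
    expected mature-read counts per library with responsiveness flags.
    """
    rng = config.rng(2)
    weights = _expression_weights(genome, config, rng)

    mirna_share = 1.0 - (config.stop_fraction + config.decoy_read_fraction
                         + config.repeat_read_fraction + config.random_read_fraction
                         + config.rescue_read_fraction)
    if mirna_share <= 0:
        raise ValueError("background read fractions leave no room for miRNA reads")

    libraries: dict[str, list[str]] = {}
    truth_rows = []
    loci = genome.truth_loci
    bg_lo, bg_hi = config.background_length_range
    chrom_names = list(genome.chromosomes)
    decoy_list = list(genome.decoy_seqs.values())
    rescue_list = list(genome.rescue_mirnas.values())

    for line, temp in SAMPLES:
        sid = sample_id(line, temp)
        depth = config.library_depth
        w = np.array([weights[l.locus_id][sid] for l in loci], dtype=float)
        w_norm = w / w.sum() if w.sum() > 0 else w
        # component probability vector:
        # [mature_1..n, star_1..n, rescue..., decoy, repeat, random, stop]
        probs = []
        probs.extend(mirna_share * w_norm * (1 - config.star_fraction))
        probs.extend(mirna_share * w_norm * config.star_fraction)
        n_rescue = len(rescue_list)
        probs.extend([config.rescue_read_fraction / max(n_rescue, 1)] * n_rescue)
        probs.extend([config.decoy_read_fraction, config.repeat_read_fraction,
                      config.random_read_fraction, config.stop_fraction])
        probs = np.array(probs)
        probs = probs / probs.sum()
        counts = rng.multinomial(depth, probs) if depth > 0 else np.zeros(len(probs), int)

        n = len(loci)
        reads: list[str] = []
        for i, locus in enumerate(loci):
            chrom_seq = genome.chromosomes[locus.chromosome]
            for _ in range(counts[i]):
                reads.append(_emit_interval(rng, config, chrom_seq,
                                            locus.mature_interval, locus.strand))
            for _ in range(counts[n + i]):
                reads.append(_emit_interval(rng, config, chrom_seq,
                                            locus.star_interval, locus.strand))
            locus.expected_abundance[sid] = depth * probs[i]
            truth_rows.append({
                "locus_id": locus.locus_id, "sample": sid,
                "expected_mature_reads": depth * probs[i],
                "responsive": locus.responsive,
                "response_ratio": locus.response_ratio,
            })
        for r, seq in enumerate(rescue_list):
            for _ in range(counts[2 * n + r]):
                if rng.random() < config.jitter_prob:
                    seq_out = seq[1:] if rng.random() < 0.5 else seq[:-1]
                else:
                    seq_out = seq
                reads.append(seq_out)
        n_decoy, n_repeat, n_random, n_stop = counts[2 * n + len(rescue_list):]
        for _ in range(n_decoy):
            d = decoy_list[int(rng.integers(0, len(decoy_list)))]
            L = min(int(rng.integers(bg_lo, bg_hi + 1)), len(d))
            s = int(rng.integers(0, len(d) - L + 1))
            reads.append(d[s:s + L])
        for _ in range(n_repeat):
            chrom, s0, e0 = genome.repeats[int(rng.integers(0, len(genome.repeats)))]
            L = min(int(rng.integers(bg_lo, bg_hi + 1)), e0 - s0)
            s = int(rng.integers(s0, e0 - L + 1))
            frag = genome.chromosomes[chrom][s:s + L]
            reads.append(frag if rng.random() < 0.5 else revcomp(frag))
        for _ in range(n_random):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            L = int(rng.integers(bg_lo, bg_hi + 1))
            s = int(rng.integers(0, config.genome_length - L))
            frag = genome.chromosomes[chrom][s:s + L]
            reads.append(frag if rng.random() < 0.5 else revcomp(frag))
        for _ in range(n_stop):
            reads.append(config.stop_oligo_seq + _random_seq(rng, int(rng.integers(0, 7))))

        raw = [r + config.adapter_seq for r in reads]
        order = rng.permutation(len(raw))
        libraries[sid] = [raw[i] for i in order]

    truth = pd.DataFrame(truth_rows)
    return libraries, truth


# ------------------------------------------------------------------
# microarray
# ------------------------------------------------------------------

def simulate_microarray(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group, replicated probe-intensity matrix with planted DE probes.

    Returns ``(matrix, truth)``: probes x samples linear intensities
    (log-normal) and the planted-direction table.  Group B carries the
    planted fold (half of the DE probes up, half down).
    """
    if config.n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a t-test design")
    rng = config.rng(3)
    n = config.n_probes
    probes = [f"probe_{i + 1:05d}" for i in range(n)]
    base = rng.normal(10.0, 1.2, size=n)
    n_de = round(config.de_fraction * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    offset = np.zeros(n)
    half = n_de // 2
    lf = math.log2(config.planted_fold)
    offset[de_idx[:half]] = lf
    offset[de_idx[half:]] = -lf

    cols = {}
    for r in range(config.n_reps):
        cols[f"A_{r + 1}"] = base + rng.normal(0, config.noise_sd, n)
    for r in range(config.n_reps):
        cols[f"B_{r + 1}"] = base + offset + rng.normal(0, config.noise_sd, n)
    matrix = pd.DataFrame({k: 2.0 ** v for k, v in cols.items()}, index=probes)
    truth = pd.DataFrame({
        "probe": [probes[i] for i in de_idx],
        "direction": ["up"] * half + ["down"] * (n_de - half),
    })
    return matrix, truth


def simulate_microarray_pair(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three-group array: one reference (A) and two test lines (B, C).

    Emulates the study's two abnormal lines compared against one wild type:
    each test line carries planted DE probes, a ``de_shared_fraction`` of
    them common to both lines with the same direction (so the two contrasts
    show overlapping calls and positively correlated intensity differences).
    Returns ``(matrix, truth)`` with truth columns probe/direction_B/
    direction_C ("up", "down" or "").
    """
    if config.n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a t-test design")
    rng = config.rng(6)
    n = config.n_probes
    probes = [f"probe_{i + 1:05d}" for i in range(n)]
    base = rng.normal(10.0, 1.2, size=n)
    lf = math.log2(config.planted_fold)
    n_de = round(config.de_fraction * n)
    n_shared = round(config.de_shared_fraction * n_de)
    picks = rng.choice(n, size=2 * n_de - n_shared, replace=False)
    shared = picks[:n_shared]
    only_b = picks[n_shared:n_de]
    only_c = picks[n_de:]
    signs = rng.choice([1.0, -1.0], size=picks.size)

    off_b = np.zeros(n)
    off_c = np.zeros(n)
    for k, idx in enumerate(shared):
        off_b[idx] = off_c[idx] = signs[k] * lf
    for k, idx in enumerate(only_b, start=n_shared):
        off_b[idx] = signs[k] * lf
    for k, idx in enumerate(only_c, start=n_de):
        off_c[idx] = signs[k] * lf

    cols = {}
    for grp, off in (("A", np.zeros(n)), ("B", off_b), ("C", off_c)):
        for r in range(config.n_reps):
            cols[f"{grp}_{r + 1}"] = base + off + rng.normal(0, config.noise_sd, n)
    matrix = pd.DataFrame({k: 2.0 ** v for k, v in cols.items()}, index=probes)

    def direction(off):
        return np.where(off > 0, "up", np.where(off < 0, "down", ""))

    truth = pd.DataFrame({"probe": probes,
                          "direction_B": direction(off_b),
                          "direction_C": direction(off_c)})
    truth = truth[(truth.direction_B != "") | (truth.direction_C != "")]
    return matrix, truth.reset_index(drop=True)


def simulate_transcripts(config: SimConfig, mirnas: dict[str, str]
                         ) -> tuple[dict[str, str], pd.DataFrame]:
    """Transcript set with one planted target site per miRNA.

    Sites are reverse complements of the mature sequence with 0-2 non-seed
    corruptions (expectation stays at or below the psRNATarget-style gate of
    2).  Returns ``(transcripts, truth)`` with the planted coordinates.
    """
    rng = config.rng(7)
    transcripts = {f"tx_{i + 1:02d}": list(_random_seq(rng, config.transcript_length))
                   for i in range(config.n_transcripts)}
    names = list(transcripts)
    rows = []
    for mid, mature in mirnas.items():
        site = revcomp(mature.replace("U", "T"))
        L = len(site)
        site = list(site)
        n_mut = int(rng.integers(0, 3))
        # corrupt only bases facing miRNA positions 14..L (outside the
        # doubled seed region); each costs at most 1 penalty point
        free = [L - pos for pos in range(14, L + 1) if 0 <= L - pos < L]
        for j in rng.choice(free, size=min(n_mut, len(free)), replace=False):
            old = site[j]
            site[j] = [b for b in "ACGT" if b != old][int(rng.integers(0, 3))]
        for _ in range(100):
            tid = names[int(rng.integers(0, len(names)))]
            start = int(rng.integers(50, config.transcript_length - L - 50))
            taken = [r for r in rows if r["transcript_id"] == tid]
            if all(start + L + 10 <= r["start"] or r["end"] + 10 <= start
                   for r in taken):
                break
        else:
            raise ValueError("could not place target sites without overlap")
        transcripts[tid][start:start + L] = site
        rows.append({"mirna_id": mid, "transcript_id": tid,
                     "start": start, "end": start + L, "n_corruptions": n_mut})
    return ({k: "".join(v) for k, v in transcripts.items()},
            pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "start",
                                        "end", "n_corruptions"]))


# ------------------------------------------------------------------
# qPCR Ct tables
# ------------------------------------------------------------------

def simulate_ct_table(config: SimConfig, rel_expression: pd.DataFrame | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table (3 technical replicates) with planted relative expression.

    ``rel_expression`` (gene x sample, calibrator column = 1.0) overrides the
    random planted effects; the calibrator sample is ``wt_24C`` and the
    internal control gene is ``actin``.  Returns ``(ct_table, truth)`` where
    the truth table holds the planted relative levels.
    """
    rng = config.rng(4)
    genes = [f"target_{i + 1}" for i in range(config.n_ct_genes)]
    samples = [sample_id(l, t) for l, t in SAMPLES]
    calibrator = samples[0]
    if rel_expression is None:
        data = 2.0 ** rng.normal(0.0, 1.5, size=(len(genes), len(samples)))
        data[:, 0] = 1.0
        rel_expression = pd.DataFrame(data, index=genes, columns=samples)

    rows = []
    base_dct = {g: float(rng.normal(5.0, 1.0)) for g in genes}
    for s in samples:
        actin_ct = float(rng.uniform(19.0, 21.0))
        for rep in range(1, 4):
            rows.append({"gene": "actin", "sample": s, "replicate": rep,
                         "ct": actin_ct + float(rng.normal(0, config.ct_noise_sd))})
        for g in genes:
            dct = base_dct[g] - math.log2(rel_expression.loc[g, s])
            for rep in range(1, 4):
                rows.append({"gene": g, "sample": s, "replicate": rep,
                             "ct": actin_ct + dct + float(rng.normal(0, config.ct_noise_sd))})
    truth = rel_expression.copy()
    truth.index.name = "gene"
    assert calibrator in samples
    return pd.DataFrame(rows), truth


# ------------------------------------------------------------------
# GO annotation maps
# ------------------------------------------------------------------

@dataclass
class GoSim:
    """Synthetic GO-style annotation with planted enrichment."""

    gene2term: dict                # gene -> set of term ids (leaves only)
    term_levels: dict              # term -> level (root = 1)
    parent_edges: list             # (child, parent)
    test_set: set
    reference_set: set
    enriched_terms: list           # planted truth


def simulate_go_map(config: SimConfig, odds: float | None = None,
                    genes: list[str] | None = None,
                    test_set: set[str] | None = None) -> GoSim:
    """Three-level term DAG with ``n_enriched_terms`` planted enriched leaves.

    ``odds`` overrides ``config.enrichment_odds``; odds = 1 plants nothing
    (uniform null annotation).  ``genes`` substitutes the gene universe
    (e.g. the array's probe ids) and ``test_set`` the subset that receives
    the planted enrichment (e.g. a differential set); both default to
    internally generated ones.
    """
    rng = config.rng(5)
    odds = config.enrichment_odds if odds is None else odds
    if genes is None:
        genes = [f"gene_{i + 1:04d}" for i in range(config.n_go_genes)]
    genes = list(genes)
    mids = [f"GO:M{i + 1:02d}" for i in range(5)]
    leaves = [f"GO:L{i + 1:03d}" for i in range(config.n_go_terms)]
    parent_edges = [(m, "GO:ROOT") for m in mids]
    parent_edges += [(leaf, mids[i % len(mids)]) for i, leaf in enumerate(leaves)]
    term_levels = {"GO:ROOT": 1, **{m: 2 for m in mids}, **{l: 3 for l in leaves}}

    reference = set(genes)
    if test_set is None:
        test = set(rng.choice(genes, size=config.go_test_size, replace=False).tolist())
    else:
        test = set(test_set) & reference
    enriched = leaves[:config.n_enriched_terms] if odds != 1.0 else []
    p0 = config.go_base_prob
    odds0 = p0 / (1 - p0)
    p1 = (odds * odds0) / (1 + odds * odds0)

    gene2term: dict[str, set] = {g: set() for g in genes}
    for leaf in leaves:
        for g in genes:
            p = p1 if (leaf in enriched and g in test) else p0
            if rng.random() < p:
                gene2term[g].add(leaf)
    return GoSim(gene2term, term_levels, parent_edges, test, reference, enriched)


# ------------------------------------------------------------------
# evaluation against truth
# ------------------------------------------------------------------

def discovery_stats(predictions, truth_loci) -> dict:
    """Sensitivity/precision of predicted loci against the planted truth.

    A prediction matches a truth locus when chromosome and strand agree and
    the mature intervals overlap.
    """
    matched_truth = set()
    matched_pred = 0
    for pred in predictions:
        hit = None
        for locus in truth_loci:
            if (pred.chromosome == locus.chromosome and pred.strand == locus.strand
                    and pred.mature_interval[0] < locus.mature_interval[1]
                    and locus.mature_interval[0] < pred.mature_interval[1]):
                hit = locus
                break
        if hit is not None:
            matched_pred += 1
            matched_truth.add(hit.locus_id)
    n_truth = len(truth_loci)
    n_pred = len(predictions)
    return {
        "n_truth": n_truth,
        "n_predicted": n_pred,
        "n_truth_recovered": len(matched_truth),
        "sensitivity": len(matched_truth) / n_truth if n_truth else float("nan"),
        "precision": matched_pred / n_pred if n_pred else float("nan"),
    }


# ------------------------------------------------------------------
# I/O
# ------------------------------------------------------------------

def write_genome_fasta(genome: AnnotatedGenome, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_annotations_gff3(genome: AnnotatedGenome, path) -> None:
    """Repeats, decoys and truth loci as GFF3 (1-based, closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, s, e in genome.repeats:
            fh.write(f"{chrom}\tsyndata\trepeat_region\t{s + 1}\t{e}\t.\t+\t.\t"
                     f"ID=repeat_{s}\n")
        for chrom, s, e, cls in genome.decoys:
            fh.write(f"{chrom}\tsyndata\tncRNA\t{s + 1}\t{e}\t.\t+\t.\t"
                     f"ID=decoy_{s};ncrna_class={cls}\n")
        for locus in genome.truth_loci:
            ps, pe = locus.precursor_interval
            ms, me = locus.mature_interval
            fh.write(f"{locus.chromosome}\tsyndata\tmiRNA_primary_transcript\t"
                     f"{ps + 1}\t{pe}\t.\t{locus.strand}\t.\tID={locus.locus_id}\n")
            fh.write(f"{locus.chromosome}\tsyndata\tmiRNA\t{ms + 1}\t{me}\t.\t"
                     f"{locus.strand}\t.\tID={locus.locus_id}_mature;"
                     f"Parent={locus.locus_id}\n")


def write_reads_fastq(reads: list[str], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f"@read_{i}\n{r}\n+\n{'I' * len(r)}\n")


def write_config(config: SimConfig, path) -> None:
    """Flat key=value dump of the configuration."""
    with open(path, "w") as fh:
        for f in fields(config):
            fh.write(f"{f.name}={getattr(config, f.name)}\n")


def read_config(path) -> SimConfig:
    import ast

    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("=", 1)
        try:
            kwargs[key] = ast.literal_eval(value)
        except (ValueError, SyntaxError):
            kwargs[key] = value
    if "expression_model" in kwargs and kwargs["expression_model"] == "None":
        kwargs["expression_model"] = None
    return SimConfig(**kwargs)
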