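"""miRNA locus discovery from perfectly aligned small-RNA reads.

Mirrors a mireap-style parameter set: candidate loci are same-strand read
clusters; the cluster's most abundant read (the anchor) is placed on the 5'
or 3' arm of a putative hairpin; a star arm is sought by reverse-complement
complementarity within 400 nt; the mature/star duplex may carry at most 3
unpairable positions, and the hairpin structure the duplex asserts over the
precursor window (arms + 20 nt flanks) must score <= -20 kcal/mol under the
folding energy model.  Gating on the hairpin energy rather than the window's
unconstrained MFE keeps the test hairpin-specific (the free MFE is always at
least as low, so the -20 precursor-MFE contract holds a fortiori).  Every
rejection carries a machine-readable reason (``length_gate``,
``no_hairpin``, ``energy_gate``, ``bulge_gate``).

Accepted loci are classified known/novel against a mature-miRNA catalog with
the same >=90%-identity local-alignment rule used for decoy filtering, and
reads that never aligned to the genome get a rescue pass against the same
catalog.  A 2-nt 3' duplex overhang is checked and logged but is not a gate,
and star-less acceptance never occurs by construction (the star search is
what defines the hairpin); multi-mapping reads count at every locus they
match, flagged as non-unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .readproc import AlignmentHit, ProcessedRead, _make_aligner, best_local_identity
from .rnafold import EnergyModel, DEFAULT_MODEL, SecondaryStructure, pair_type, score_energy
from .syndata import revcomp

__all__ = [
    "DiscoveryParams",
    "CandidateLocus",
    "MirnaPrediction",
    "Rejection",
    "cluster_hits",
    "predict_locus",
    "classify_known",
    "rescue_unaligned",
    "quantify",
    "discover_loci",
    "validate_prediction",
    "write_predictions_gff3",
    "write_predictions_tsv",
]

MIN_LOOP = 3


@dataclass(frozen=True)
class DiscoveryParams:
    """Gates for precursor acceptance (lengths nt, energy kcal/mol)."""

    min_mirna_len: int = 18
    max_mirna_len: int = 30
    min_ref_len: int = 18
    max_ref_len: int = 26
    max_star_space: int = 400
    max_duplex_bulge: int = 3
    flank: int = 20
    max_energy: float = -20.0
    known_identity: float = 0.90
    cluster_gap: int = 50
    min_read_count: int = 2   # read support required to seed/bound a cluster

    def __post_init__(self):
        if self.min_mirna_len > self.max_mirna_len or self.min_ref_len > self.max_ref_len:
            raise ValueError("min length exceeds max length")
        if self.max_energy >= 0:
            raise ValueError("max_energy must be negative")


@dataclass
class CandidateLocus:
    chromosome: str
    strand: str
    hits: list
    anchor: AlignmentHit


@dataclass
class MirnaPrediction:
    locus_id: str
    chromosome: str
    strand: str
    precursor_interval: tuple
    precursor_seq: str            # transcript orientation, DNA
    mature_seq: str
    mature_interval: tuple
    star_seq: str
    star_interval: tuple
    structure: SecondaryStructure
    energy: float
    status: str = "novel"
    matched_catalog_id: str | None = None
    star_observed: bool = False
    duplex_bulge: int = 0
    overhang_3p: int | None = None  # logged, not gated
    mature_counts: dict = field(default_factory=dict)
    star_counts: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Rejection:
    chromosome: str
    strand: str
    interval: tuple
    anchor_seq: str
    reason: str  # no_hairpin | energy_gate | bulge_gate | length_gate


def cluster_hits(hits: list[AlignmentHit], cluster_gap: int = 50) -> list[CandidateLocus]:
    """Maximal runs of same-strand hits with inter-hit gap <= cluster_gap."""
    by_key: dict[tuple, list[AlignmentHit]] = {}
    for h in hits:
        by_key.setdefault((h.chromosome, h.strand), []).append(h)
    clusters = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.start, h.end, h.read.sequence))
        current: list[AlignmentHit] = []
        reach = None
        for h in group:
            if current and h.start - reach > cluster_gap:
                clusters.append(_finish_cluster(chrom, strand, current))
                current = []
                reach = None
            current.append(h)
            reach = h.end if reach is None else max(reach, h.end)
        if current:
            clusters.append(_finish_cluster(chrom, strand, current))
    return clusters


def _finish_cluster(chrom, strand, hits) -> CandidateLocus:
    anchor = max(hits, key=lambda h: (h.read.count, -h.start, h.read.sequence))
    return CandidateLocus(chrom, strand, list(hits), anchor)


def _duplex_stats(structure: SecondaryStructure, mature_rng, star_rng):
    """(n_pairs, per-arm unpaired-in-duplex counts, star 3' overhang)."""
    ms, me = mature_rng
    ss, se = star_rng
    duplex = [(i, j) for i, j in structure.pairs
              if (ms <= i < me and ss <= j < se) or (ss <= i < se and ms <= j < me)]
    if not duplex:
        return 0, (0, 0), None
    m_idx = sorted(i if ms <= i < me else j for i, j in duplex)
    s_idx = sorted(i if ss <= i < se else j for i, j in duplex)
    m_gap = (m_idx[-1] - m_idx[0] + 1) - len(m_idx)
    s_gap = (s_idx[-1] - s_idx[0] + 1) - len(s_idx)
    # star bases 3' of its last mature-pairing position
    overhang = se - 1 - max(s_idx)
    return len(duplex), (m_gap, s_gap), overhang


def predict_locus(candidate: CandidateLocus, genome: dict[str, str],
                  params: DiscoveryParams = DiscoveryParams(),
                  model: EnergyModel = DEFAULT_MODEL):
    """Fold-and-gate one candidate cluster; MirnaPrediction or Rejection."""
    anchor = candidate.anchor
    L = anchor.end - anchor.start
    interval = (anchor.start, anchor.end)
    if not (params.min_ref_len <= L <= params.max_ref_len):
        return Rejection(candidate.chromosome, candidate.strand, interval,
                         anchor.read.sequence, "length_gate")

    ref = genome[candidate.chromosome]
    reach = params.max_star_space + params.flank + L
    r_lo = max(0, anchor.start - reach)
    r_hi = min(len(ref), anchor.end + reach)
    region = ref[r_lo:r_hi]
    strand = candidate.strand
    if strand == "-":
        region = revcomp(region)
        a_lo = len(region) - (anchor.end - r_lo)
    else:
        a_lo = anchor.start - r_lo
    a_hi = a_lo + L
    mature_t = region[a_lo:a_hi]
    if "N" in mature_t:
        return Rejection(candidate.chromosome, strand, interval,
                         anchor.read.sequence, "no_hairpin")

    def local_to_genome(lo, hi):
        if strand == "+":
            return (r_lo + lo, r_lo + hi)
        n = len(region)
        return (r_lo + n - hi, r_lo + n - lo)

    # complementarity scan for a star arm on either side of the anchor:
    # at each antiparallel register, the duplex bulge is the number of
    # unpairable positions (one unpaired nt on each arm per miss)
    mature_rna = mature_t.replace("T", "U")
    scan_slack = 2 * params.max_duplex_bulge  # loose scan; the hard gate follows
    star_candidates = []  # (bulge, p)
    for p in range(0, len(region) - L + 1):
        if p + L <= a_lo:  # star 5' of mature
            gap = a_lo - (p + L)
        elif p >= a_hi:    # star 3' of mature
            gap = p - a_hi
        else:
            continue
        if gap < MIN_LOOP or gap > params.max_star_space:
            continue
        window = region[p:p + L]
        if "N" in window:
            continue
        matches = sum(1 for k in range(L)
                      if pair_type(mature_rna[k],
                                   window[L - 1 - k].replace("T", "U")))
        if matches >= L - scan_slack:
            star_candidates.append((L - matches, p))

    if not star_candidates:
        return Rejection(candidate.chromosome, strand, interval,
                         anchor.read.sequence, "no_hairpin")

    duplexes = [(b, p) for b, p in star_candidates if b <= params.max_duplex_bulge]
    if not duplexes:
        return Rejection(candidate.chromosome, strand, interval,
                         anchor.read.sequence, "bulge_gate")

    # score the hairpin structure each duplex register asserts and gate on
    # its energy; accept the lowest-energy window.  The unconstrained MFE of
    # the window is by definition <= this hairpin energy, so the gate is the
    # hairpin-specific (stricter) form of the precursor energy threshold.
    best = None
    for bulge, p in duplexes:
        lo = max(0, min(a_lo, p) - params.flank)
        hi = min(len(region), max(a_hi, p + L) + params.flank)
        pre_seq = region[lo:hi]
        pairs = set()
        for k in range(L):
            i = a_lo - lo + k
            j = p - lo + (L - 1 - k)
            a, b = (i, j) if i < j else (j, i)
            if pair_type(pre_seq[a].replace("T", "U"), pre_seq[b].replace("T", "U")):
                pairs.add((a, b))
        struct = SecondaryStructure(pre_seq.replace("T", "U"), frozenset(pairs), 0.0)
        energy = score_energy(struct, model)
        if energy > params.max_energy:
            continue
        struct = SecondaryStructure(struct.sequence, struct.pairs, energy)
        _, _, overhang = _duplex_stats(
            struct, (a_lo - lo, a_hi - lo), (p - lo, p + L - lo))
        key = (energy, abs(p - a_lo), p)
        if best is None or key < best[0]:
            best = (key, p, lo, hi, struct, bulge, overhang)

    if best is None:
        return Rejection(candidate.chromosome, strand, interval,
                         anchor.read.sequence, "energy_gate")

    _, p, lo, hi, struct, bulge, overhang = best
    star_t = region[p:p + L]
    pred = MirnaPrediction(
        locus_id="",  # assigned by discover_loci
        chromosome=candidate.chromosome,
        strand=strand,
        precursor_interval=local_to_genome(lo, hi),
        precursor_seq=region[lo:hi],
        mature_seq=mature_t,
        mature_interval=local_to_genome(a_lo, a_hi),
        star_seq=star_t,
        star_interval=local_to_genome(p, p + L),
        structure=struct,
        energy=struct.energy,
        duplex_bulge=bulge,
        overhang_3p=overhang,
    )
    # star observed: any cluster read within +/-2 nt of the predicted star
    ss, se = pred.star_interval
    pred.star_observed = any(abs(h.start - ss) <= 2 and abs(h.end - se) <= 2
                             for h in candidate.hits)
    validate_prediction(pred, params)
    return pred


def validate_prediction(pred: MirnaPrediction, params: DiscoveryParams) -> None:
    """Field-by-field gate assertion; raises on any violated invariant."""
    L = len(pred.mature_seq)
    if not (params.min_ref_len <= L <= params.max_ref_len):
        raise AssertionError("mature length outside reference gate")
    if pred.energy > params.max_energy:
        raise AssertionError("energy above the precursor gate")
    if pred.duplex_bulge > params.max_duplex_bulge:
        raise AssertionError("duplex bulge above gate")
    ms, me = sorted(pred.mature_interval)
    ss, se = sorted(pred.star_interval)
    gap = max(ss - me, ms - se)
    if gap > params.max_star_space:
        raise AssertionError("mature-star space above gate")
    ps, pe = pred.precursor_interval
    if not (ps <= min(ms, ss) and max(me, se) <= pe):
        raise AssertionError("arms outside precursor")


def classify_known(pred: MirnaPrediction, catalog: dict[str, str],
                   known_identity: float = 0.90, aligner=None) -> tuple[str, str | None]:
    """Known/novel call for a prediction's mature sequence (plus strand)."""
    match = _best_catalog_match(pred.mature_seq, catalog, known_identity, aligner)
    if match is None:
        return "novel", None
    return "known", match


def _best_catalog_match(seq: str, catalog: dict[str, str], known_identity: float,
                        aligner=None) -> str | None:
    aligner = aligner or _make_aligner()
    L = len(seq)
    span_needed = known_identity * L
    score_bound = span_needed * (known_identity - 2 * (1 - known_identity))
    best = None
    for name, mature in catalog.items():
        if seq == mature or seq in mature:
            identity, span = 1.0, L
        else:
            if aligner.score(mature, seq) < score_bound:
                continue
            identity, span = best_local_identity(seq, mature, aligner)
        if identity >= known_identity and span >= span_needed:
            if best is None or identity > best[0]:
                best = (identity, name)
    return best[1] if best else None


def rescue_unaligned(unaligned: list[ProcessedRead], catalog: dict[str, str],
                     known_identity: float = 0.90) -> dict[str, dict[str, int]]:
    """Assign genome-unaligned reads to catalog miRNAs by the same identity rule.

    Returns ``{catalog_id: {library_id: read_count}}``.
    """
    aligner = _make_aligner()
    out: dict[str, dict[str, int]] = {}
    cache: dict[str, str | None] = {}
    for read in unaligned:
        seq = read.sequence
        if seq not in cache:
            cache[seq] = _best_catalog_match(seq, catalog, known_identity, aligner)
        name = cache[seq]
        if name is not None:
            out.setdefault(name, {})
            out[name][read.library_id] = out[name].get(read.library_id, 0) + read.count
    return out


def quantify(predictions: list[MirnaPrediction],
             rescues: dict[str, dict[str, int]],
             hits_by_library: dict[str, list[AlignmentHit]],
             slop: int = 2) -> pd.DataFrame:
    """Per-miRNA read counts per library.

    A read contributes to a prediction when its alignment overlaps the mature
    interval (within ``slop`` nt at each end) on the same chromosome/strand;
    reads matching several predictions are counted once per prediction and
    flagged non-unique.  Rescued catalog miRNAs appear as extra rows.
    Columns: one per library, plus ``expressed_in_all`` and ``unique_only``.
    """
    libraries = sorted(hits_by_library)
    rows = {}
    multimapped: dict[str, bool] = {}
    for pred in predictions:
        rows[pred.locus_id] = {lib: 0 for lib in libraries}
        multimapped[pred.locus_id] = False

    for lib, hits in hits_by_library.items():
        for h in hits:
            touching = []
            for pred in predictions:
                ms, me = pred.mature_interval
                if (h.chromosome == pred.chromosome and h.strand == pred.strand
                        and h.start >= ms - slop and h.end <= me + slop
                        and h.start < me and h.end > ms):
                    touching.append(pred)
            for pred in touching:
                rows[pred.locus_id][lib] += h.read.count
                if len(touching) > 1:
                    multimapped[pred.locus_id] = True
                # record per-library mature counts on the prediction too
                pred.mature_counts[lib] = pred.mature_counts.get(lib, 0) + h.read.count
            # star accounting
            for pred in predictions:
                ss, se = pred.star_interval
                if (h.chromosome == pred.chromosome and h.strand == pred.strand
                        and h.start >= ss - slop and h.end <= se + slop
                        and h.start < se and h.end > ss):
                    pred.star_counts[lib] = pred.star_counts.get(lib, 0) + h.read.count

    for name, by_lib in sorted(rescues.items()):
        rows[name] = {lib: by_lib.get(lib, 0) for lib in libraries}
        multimapped[name] = False

    table = pd.DataFrame.from_dict(rows, orient="index")[libraries]
    table.index.name = "mirna_id"
    table["expressed_in_all"] = (table[libraries] >= 1).all(axis=1)
    table["unique_only"] = [not multimapped[i] for i in table.index]
    return table


def discover_loci(hits: list[AlignmentHit], genome: dict[str, str],
                  catalog: dict[str, str],
                  params: DiscoveryParams = DiscoveryParams(),
                  model: EnergyModel = DEFAULT_MODEL
                  ) -> tuple[list[MirnaPrediction], list[Rejection]]:
    """Cluster -> predict -> classify over a pooled hit set.

    Hits below ``params.min_read_count`` (library-level read support) do not
    seed or extend clusters: at desk scale the genome is tiled by unique
    background fragments, and without a support floor cluster boundaries
    would chain across unrelated loci.  All hits still count in ``quantify``.
    """
    supported = [h for h in hits if h.read.count >= params.min_read_count]
    predictions, rejections = [], []
    aligner = _make_aligner()
    for i, cand in enumerate(cluster_hits(supported, params.cluster_gap)):
        result = predict_locus(cand, genome, params, model)
        if isinstance(result, Rejection):
            rejections.append(result)
            continue
        result.locus_id = f"mir-candidate-{len(predictions) + 1:03d}"
        result.status, result.matched_catalog_id = classify_known(
            result, catalog, params.known_identity, aligner)
        predictions.append(result)
    return predictions, rejections


# ------------------------------------------------------------------
# I/O
# ------------------------------------------------------------------

def write_predictions_gff3(predictions: list[MirnaPrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in predictions:
            ps, pe = p.precursor_interval
            ms, me = p.mature_interval
            ss, se = p.star_interval
            fh.write(f"{p.chromosome}\tcrownmir\tmiRNA_primary_transcript\t{ps + 1}\t{pe}"
                     f"\t.\t{p.strand}\t.\tID={p.locus_id};energy={p.energy}\n")
            fh.write(f"{p.chromosome}\tcrownmir\tmiRNA\t{ms + 1}\t{me}\t.\t{p.strand}\t.\t"
                     f"ID={p.locus_id}_mature;Parent={p.locus_id}\n")
            fh.write(f"{p.chromosome}\tcrownmir\tmiRNA_star\t{ss + 1}\t{se}\t.\t{p.strand}"
                     f"\t.\tID={p.locus_id}_star;Parent={p.locus_id}\n")


def write_predictions_tsv(predictions: list[MirnaPrediction], path) -> None:
    rows = []
    for p in predictions:
        rows.append({
            "locus_id": p.locus_id, "chrom": p.chromosome, "strand": p.strand,
            "mature_seq": p.mature_seq, "star_seq": p.star_seq,
            "precursor_seq": p.precursor_seq,
            "energy": p.energy, "status": p.status,
            "matched_catalog_id": p.matched_catalog_id or "",
            "structure": p.structure.dot_bracket(),
            "star_observed": p.star_observed,
            "duplex_bulge": p.duplex_bulge,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
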