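"""Assembly benchmark panel: stringent transcript completeness, in-silico
label maps with DP alignment and label-site coverage, scaffold-retention
filter, gene-confidence classification, and a combined report.

The label-map confidence score is this module's own scale, calibrated so
that self-alignment of a 20-site map scores far above the retention
threshold (20) while a spacing-incompatible map scores below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._align import find_local_hits, make_aligner
from .genome_model import (
    Assembly,
    gap_segments,
    nx_stat,
    reverse_complement,
)

DLE1_MOTIF = "CTTAAG"


# ---------------------------------------------------------------------------
# Transcript completeness
# ---------------------------------------------------------------------------


@dataclass
class TranscriptHit:
    transcript_id: str
    target_seq: str | None
    coverage: float  # percent of transcript aligned
    identity: float  # percent of aligned columns matching
    counted: bool


def transcript_completeness(
    transcripts: list[tuple[str, str]],
    assembly: Assembly,
    min_cov: float,
    min_id: float,
    k: int = 21,
) -> tuple[float, list[TranscriptHit]]:
    """Fraction of transcripts aligning at >= min_cov coverage and
    >= min_id identity (both percent), via seeded local alignment.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    if not (0 < min_cov <= 100 and 0 < min_id <= 100):
        raise ValueError("thresholds must be in (0, 100]")
    aligner = make_aligner(2, -2, -10, -0.5, mode="local")
    hits: list[TranscriptHit] = []
    counted = 0
    for tid, tseq in transcripts:
        best = None
        best_rec = None
        for rec in assembly:
            for h in find_local_hits(tseq, rec.seq, k=k, aligner=aligner):
                if best is None or h.score > best.score:
                    best, best_rec = h, rec.name
        if best is None:
            hits.append(TranscriptHit(tid, None, 0.0, 0.0, False))
            continue
        ok = best.coverage >= min_cov and best.identity >= min_id
        counted += ok
        hits.append(TranscriptHit(tid, best_rec, best.coverage, best.identity, ok))
    return counted / len(transcripts), hits


# ---------------------------------------------------------------------------
# In-silico label maps
# ---------------------------------------------------------------------------


@dataclass
class LabelMap:
    """Ordered motif-site positions per sequence."""

    sites: dict[str, list[int]]
    lengths: dict[str, int]


def insilico_digest(assembly: Assembly, motif: str = DLE1_MOTIF) -> LabelMap:
    """All motif occurrence start positions per sequence.

    A reverse-complement-palindromic motif (like CTTAAG) needs only one
    strand scan; otherwise both strands are scanned and positions
    deduplicated.
    """
    if not motif:
        raise ValueError("empty motif")
    motif = motif.upper()
    palindromic = reverse_complement(motif) == motif
    sites: dict[str, list[int]] = {}
    lengths: dict[str, int] = {}
    for rec in assembly:
        positions = set()
        for m_seq in [motif] if palindromic else [motif, reverse_complement(motif)]:
            start = rec.seq.find(m_seq)
            while start != -1:
                positions.add(start)
                start = rec.seq.find(m_seq, start + 1)
        sites[rec.name] = sorted(positions)
        lengths[rec.name] = rec.length
    return LabelMap(sites=sites, lengths=lengths)


def write_label_map(label_map: LabelMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in label_map.lengths.items():
            fh.write(f"#length\t{name}\t{length}\n")
        fh.write("seq_name\tposition\n")
        for name, positions in label_map.sites.items():
            for p in positions:
                fh.write(f"{name}\t{p}\n")


def read_label_map(path: str | Path) -> LabelMap:
    sites: dict[str, list[int]] = {}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith("#length"):
                _, name, length = line.split("\t")
                lengths[name] = int(length)
                sites.setdefault(name, [])
            elif line and not line.startswith("seq_name"):
                name, pos = line.split("\t")
                sites.setdefault(name, []).append(int(pos))
    for positions in sites.values():
        positions.sort()
    return LabelMap(sites=sites, lengths=lengths)


@dataclass
class MapAlignParams:
    site_match_score: float = 3.0
    spacing_weight: float = 3.0
    tolerance: float = 0.10  # relative spacing discrepancy scale
    skip_penalty: float = 1.0
    max_skip: int = 10  # sites skippable between consecutive matches


@dataclass
class MapAlignmentResult:
    matched_pairs: list[tuple[int, int]]  # (query index, ref index)
    confidence: float

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)


def score_matching(
    query_sites: list[int],
    ref_sites: list[int],
    matching: list[tuple[int, int]],
    params: MapAlignParams | None = None,
) -> float:
    """Score of a monotone matching (shared by DP and the brute-force
    oracle): each matched pair earns site_match_score; each consecutive
    linked pair pays spacing_weight * rel_disc / tolerance plus
    skip_penalty per site skipped on either side between the two pairs.
    """
    if params is None:
        params = MapAlignParams()
    score = params.site_match_score * len(matching)
    for (q0, r0), (q1, r1) in zip(matching, matching[1:]):
        dq = query_sites[q1] - query_sites[q0]
        dr = ref_sites[r1] - ref_sites[r0]
        denom = max(dq, dr)
        rel = abs(dq - dr) / denom if denom > 0 else 0.0
        score -= params.spacing_weight * rel / params.tolerance
        score -= params.skip_penalty * ((q1 - q0 - 1) + (r1 - r0 - 1))
    return score


def align_label_maps(
    query_sites: list[int],
    ref_sites: list[int],
    params: MapAlignParams | None = None,
) -> MapAlignmentResult:
    """Best-scoring monotone matching of two ordered site lists by DP.

    The chain may start and end anywhere (local in both maps); skips inside
    the chain are penalized and bounded by max_skip per step.
    """
    if params is None:
        params = MapAlignParams()
    nq, nr = len(query_sites), len(ref_sites)
    if nq < 2 or nr < 2:
        raise ValueError("need at least 2 labels on each map")
    ms = params.max_skip
    best = [[params.site_match_score] * nr for _ in range(nq)]
    back: list[list[tuple[int, int] | None]] = [[None] * nr for _ in range(nq)]
    for i in range(nq):
        for j in range(nr):
            for pi in range(max(0, i - ms - 1), i):
                for pj in range(max(0, j - ms - 1), j):
                    dq = query_sites[i] - query_sites[pi]
                    dr = ref_sites[j] - ref_sites[pj]
                    denom = max(dq, dr)
                    rel = abs(dq - dr) / denom if denom > 0 else 0.0
                    cand = (
                        best[pi][pj]
                        + params.site_match_score
                        - params.spacing_weight * rel / params.tolerance
                        - params.skip_penalty * ((i - pi - 1) + (j - pj - 1))
                    )
                    if cand > best[i][j]:
                        best[i][j] = cand
                        back[i][j] = (pi, pj)
    end = max(
        ((i, j) for i in range(nq) for j in range(nr)),
        key=lambda ij: best[ij[0]][ij[1]],
    )
    chain: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = end
    while cur is not None:
        chain.append(cur)
        cur = back[cur[0]][cur[1]]
    chain.reverse()
    return MapAlignmentResult(matched_pairs=chain, confidence=best[end[0]][end[1]])


def label_site_coverage(
    assembly: Assembly,
    ref_map: LabelMap,
    motif: str = DLE1_MOTIF,
    min_contig: int = 100_000,
    min_confidence: float = 20.0,
    params: MapAlignParams | None = None,
) -> float:
    """Percent of ref-map label sites aligned to the assembly.

    Only ref-map sequences >= min_contig contribute; each is aligned to its
    best assembly target and retained when the alignment confidence is >=
    min_confidence.
    """
    asm_map = insilico_digest(assembly, motif)
    total = 0
    matched = 0
    for name, ref_sites in ref_map.sites.items():
        if ref_map.lengths.get(name, 0) < min_contig:
            continue
        total += len(ref_sites)
        if len(ref_sites) < 2:
            continue
        best: MapAlignmentResult | None = None
        for asm_sites in asm_map.sites.values():
            if len(asm_sites) < 2:
                continue
            res = align_label_maps(asm_sites, ref_sites, params)
            if best is None or res.confidence > best.confidence:
                best = res
        if best is not None and best.confidence >= min_confidence:
            matched += best.n_matched
    if total == 0:
        return 0.0
    return 100.0 * matched / total


# ---------------------------------------------------------------------------
# Scaffold retention filter
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldMeta:
    name: str
    length: int
    chromosome_assigned: bool
    bubble: bool
    read_coverage: float
    has_unique_genes: bool

    def __post_init__(self) -> None:
        if self.length <= 0 or self.read_coverage < 0:
            raise ValueError(f"invalid metadata for {self.name}")


def scaffold_filter(
    metas: list[ScaffoldMeta],
    min_length: int = 50_000,
    min_coverage: float = 10.0,
) -> tuple[list[ScaffoldMeta], list[tuple[ScaffoldMeta, str]]]:
    """Retention rule for unassigned scaffolds.

    Chromosome-assigned scaffolds are always kept. Unassigned scaffolds are
    kept iff length >= 50 kb AND not a bubble AND (read coverage >= 10x OR
    they carry genes absent from assigned scaffolds).
    """
    kept: list[ScaffoldMeta] = []
    discarded: list[tuple[ScaffoldMeta, str]] = []
    for m in metas:
        if m.chromosome_assigned:
            kept.append(m)
            continue
        if m.length < min_length:
            discarded.append((m, "length"))
        elif m.bubble:
            discarded.append((m, "bubble"))
        elif m.read_coverage < min_coverage and not m.has_unique_genes:
            discarded.append((m, "coverage_and_genes"))
        else:
            kept.append(m)
    return kept, discarded


# ---------------------------------------------------------------------------
# Gene confidence classification
# ---------------------------------------------------------------------------


@dataclass
class DbHit:
    e_value: float
    query_cov: float  # percent
    subject_cov: float  # percent

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("negative e-value")
        if not (0 <= self.query_cov <= 100 and 0 <= self.subject_cov <= 100):
            raise ValueError("coverage out of [0, 100]")


@dataclass
class HitRecord:
    protein_id: str
    complete: bool
    unimag: DbHit | None = None
    unipoa: DbHit | None = None
    ptrep: DbHit | None = None
    ahrd_stars: int = 2


@dataclass
class ConfidenceDecision:
    protein_id: str
    decision: str  # HC | LC | REP | UNCLASSIFIED
    rule: str


E_VALUE_MAX = 1e-10
COVERAGE_MIN = 80.0


def classify_gene_confidence(
    records: list[HitRecord],
    e_value_max: float = E_VALUE_MAX,
    coverage_min: float = COVERAGE_MIN,
) -> list[ConfidenceDecision]:
    """Tiered homology/completeness confidence classes with rule traces.

    Hits at e-value >= the threshold are treated as no-hit. Rules, in
    order: (1) complete + UniMag query&subject coverage >= 80 -> HC;
    (2) complete + no UniMag hit + UniPoa hit + no PTREP hit -> HC;
    (3) incomplete + (UniMag or UniPoa) + no PTREP -> LC; (4) no hits
    anywhere + complete -> LC; (5) no UniMag + complete + PTREP -> REP.
    AHRD refinement then promotes 3-star LC to HC and demotes 1-star HC
    to LC.
    """
    decisions: list[ConfidenceDecision] = []
    for r in records:
        def usable(h: DbHit | None) -> DbHit | None:
            return h if h is not None and h.e_value < e_value_max else None

        mag, poa, rep = usable(r.unimag), usable(r.unipoa), usable(r.ptrep)
        decision, rule = "UNCLASSIFIED", "none"
        if (
            r.complete
            and mag is not None
            and mag.query_cov >= coverage_min
            and mag.subject_cov >= coverage_min
        ):
            decision, rule = "HC", "rule1_complete_unimag"
        elif r.complete and mag is None and poa is not None and rep is None:
            decision, rule = "HC", "rule2_unipoa_no_trep"
        elif not r.complete and (mag is not None or poa is not None) and rep is None:
            decision, rule = "LC", "rule3_incomplete_hit"
        elif mag is None and poa is None and rep is None and r.complete:
            decision, rule = "LC", "rule4_complete_no_hit"
        elif mag is None and r.complete and rep is not None:
            decision, rule = "REP", "rule5_trep"
        # AHRD refinement
        if decision == "LC" and r.ahrd_stars == 3:
            decision, rule = "HC", rule + "+ahrd_promoted"
        elif decision == "HC" and r.ahrd_stars == 1:
            decision, rule = "LC", rule + "+ahrd_demoted"
        decisions.append(ConfidenceDecision(r.protein_id, decision, rule))
    return decisions


# ---------------------------------------------------------------------------
# Combined benchmark panel
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkReport:
    total_size: int
    size_over_1mb: int
    contig_n50: int
    scaffold_n50: int
    gap_bases: int
    completeness_99_100: float
    completeness_90_97: float
    label_site_coverage: float
    fl_ltr_count: int | None = None
    tsd_rate: float | None = None
    extras: dict = field(default_factory=dict)


def benchmark_panel(
    assembly: Assembly,
    transcripts: list[tuple[str, str]],
    ref_map: LabelMap,
    fl_ltr_count: int | None = None,
    tsd_rate: float | None = None,
) -> BenchmarkReport:
    """Table-style benchmark row for one assembly."""
    scaffold_lengths = assembly.lengths()
    gaps = gap_segments(assembly)
    from .genome_model import contig_segments

    contig_lengths = [c.length for c in contig_segments(assembly)] or [1]
    comp_strict, _ = transcript_completeness(transcripts, assembly, 99, 100)
    comp_loose, _ = transcript_completeness(transcripts, assembly, 90, 97)
    return BenchmarkReport(
        total_size=assembly.total_length,
        size_over_1mb=sum(l for l in scaffold_lengths if l > 1_000_000),
        contig_n50=nx_stat(contig_lengths, 50),
        scaffold_n50=nx_stat(scaffold_lengths, 50),
        gap_bases=sum(g.n_count for g in gaps),
        completeness_99_100=comp_strict,
        completeness_90_97=comp_loose,
        label_site_coverage=label_site_coverage(assembly, ref_map),
        fl_ltr_count=fl_ltr_count,
        tsd_rate=tsd_rate,
    )
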