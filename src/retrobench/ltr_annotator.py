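"""Structural detection of full-length LTR retrotransposons and solo-LTRs.

Detection proceeds in the classic structural-hallmark fashion: exact-seed
matching of direct repeats at family-scale separations, x-drop extension,
similarity/length/distance gating, boundary refinement against the TG...CA
terminal motif and a flanking target-site duplication, protein-domain-order
superfamily classification, and a stringent quality filter (no N bases,
bounded tandem-repeat content, no gene domains, no duplicated TE domains,
strand-consistent domains).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._align import find_local_hits, global_alignment, identity_percent, make_aligner
from .genome_model import Assembly, Interval


@dataclass
class DetectionParams:
    seed_len: int = 30
    min_ltr: int = 100
    max_ltr: int = 2000
    min_dist: int = 3000
    max_dist: int = 25000
    min_similarity: float = 85.0
    tsd_min: int = 4
    tsd_max: int = 20
    motif: str = "tgca"
    motif_mismatch_max: int = 1
    vicinity: int = 60
    xdrop: int = 5
    match: int = 2
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -3
    # module extensions (not part of the canonical parameter set)
    seed_chain_gap: int = 500
    solo_min_identity: float = 80.0
    solo_min_coverage: float = 80.0
    tandem_max_inner: float = 30.0
    tandem_max_ltr: float = 35.0

    def __post_init__(self) -> None:
        if self.min_ltr > self.max_ltr or self.min_dist > self.max_dist:
            raise ValueError("inconsistent length/distance bounds")


@dataclass
class Candidate:
    seq_name: str
    element_interval: Interval
    ltr5: Interval
    ltr3: Interval
    similarity: float
    score: float
    tsd: str | None = None
    tsd_intervals: tuple[Interval, Interval] | None = None
    motif_ok: bool = False
    motif_mismatches: int | None = None
    edge_flag: bool = False


@dataclass(frozen=True)
class DomainHit:
    seq_name: str
    start: int
    end: int
    strand: str
    kind: str  # INT | RT | RH | GENE | OTHER_TE


@dataclass
class FullLengthElement:
    candidate: Candidate
    superfamily: str = "RLX"  # RLC | RLG | RLX
    quality_pass: bool = False
    failure_reasons: list[str] = field(default_factory=list)
    family: str | None = None

    @property
    def interval(self) -> Interval:
        return self.candidate.element_interval

    @property
    def length(self) -> int:
        return self.candidate.element_interval.length


@dataclass
class SoloLTR:
    seq_name: str
    interval: Interval
    identity: float
    tsd: str | None = None


def load_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read domain hits from TSV: seq_name, start, end, strand, kind."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip().split("\t")
        if header != ["seq_name", "start", "end", "strand", "kind"]:
            raise ValueError(f"unexpected domain TSV header: {header}")
        for line in fh:
            f = line.rstrip().split("\t")
            hits.append(DomainHit(f[0], int(f[1]), int(f[2]), f[3], f[4]))
    return hits


# ---------------------------------------------------------------------------
# Candidate detection
# ---------------------------------------------------------------------------


def _xdrop_extend_left(seq: str, start: int, d: int, params: DetectionParams) -> int:
    best, cur, best_i = 0.0, 0.0, start
    i = start - 1
    while i >= 0:
        a, b = seq[i], seq[i + d]
        cur += params.match if (a == b and a != "N") else params.mismatch
        if cur > best:
            best, best_i = cur, i
        if cur < best - params.xdrop:
            break
        i -= 1
    return best_i if best > 0 else start


def _xdrop_extend_right(seq: str, end: int, d: int, params: DetectionParams) -> int:
    best, cur, best_j = 0.0, 0.0, end
    j = end
    n = len(seq)
    while j + d < n:
        a, b = seq[j], seq[j + d]
        cur += params.match if (a == b and a != "N") else params.mismatch
        if cur > best:
            best, best_j = cur, j + 1
        if cur < best - params.xdrop:
            break
        j += 1
    return best_j if best > 0 else end


def _seed_pairs_by_diagonal(
    seq: str, params: DetectionParams
) -> dict[int, list[int]]:
    """Exact seed matches grouped by separation (diagonal).

    Only separations within [min_dist - max_ltr, max_dist + max_ltr] are
    kept, per the candidate-generation contract.
    """
    k = params.seed_len
    lo = params.min_dist - params.max_ltr
    hi = params.max_dist + params.max_ltr
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    diagonals: dict[int, list[int]] = defaultdict(list)
    for positions in index.values():
        if len(positions) < 2:
            continue
        m = len(positions)
        for a in range(m):
            for b in range(a + 1, m):
                d = positions[b] - positions[a]
                if d > hi:
                    break
                if d >= lo:
                    diagonals[d].append(positions[a])
    return diagonals


def find_candidates(assembly: Assembly, params: DetectionParams | None = None) -> list[Candidate]:
    """Detect direct-repeat (LTR pair) candidates.

    Seeds of length >= seed_len on the same diagonal are chained (gaps up to
    seed_chain_gap), x-drop extended under the match/mismatch scheme, and
    accepted when both repeats are within [min_ltr, max_ltr], start-to-start
    distance within [min_dist, max_dist] and global similarity >=
    min_similarity. Overlapping candidates are resolved best-score-first.
    """
    if params is None:
        params = DetectionParams()
    k = params.seed_len
    aligner = make_aligner(
        params.match, params.mismatch, params.gap_open, params.gap_extend, "global"
    )
    raw: list[Candidate] = []
    for rec in assembly:
        diagonals = _seed_pairs_by_diagonal(rec.seq, params)
        for d, starts in diagonals.items():
            starts = sorted(set(starts))
            clusters: list[tuple[int, int]] = []
            c_start, c_end = starts[0], starts[0] + k
            for s in starts[1:]:
                if s - c_end <= params.seed_chain_gap:
                    c_end = max(c_end, s + k)
                else:
                    clusters.append((c_start, c_end))
                    c_start, c_end = s, s + k
            clusters.append((c_start, c_end))
            for a, b in clusters:
                s = _xdrop_extend_left(rec.seq, a, d, params)
                e = _xdrop_extend_right(rec.seq, b, d, params)
                e = min(e, s + d)  # repeats must not overlap each other
                rep_len = e - s
                if not params.min_ltr <= rep_len <= params.max_ltr:
                    continue
                if not params.min_dist <= d <= params.max_dist:
                    continue
                ltr5_seq = rec.seq[s:e]
                ltr3_seq = rec.seq[s + d : e + d]
                aln = global_alignment(ltr5_seq, ltr3_seq, aligner)
                sim = identity_percent(str(aln[0]), str(aln[1]))
                if sim < params.min_similarity:
                    continue
                raw.append(
                    Candidate(
                        seq_name=rec.name,
                        element_interval=Interval(rec.name, s, e + d, "+"),
                        ltr5=Interval(rec.name, s, e, "+"),
                        ltr3=Interval(rec.name, s + d, e + d, "+"),
                        similarity=sim,
                        score=float(aln.score),
                    )
                )
    return resolve_overlaps(raw)


def resolve_overlaps(candidates: list[Candidate]) -> list[Candidate]:
    """Keep the best-scoring candidate among overlapping ones.

    Ties broken by leftmost start, then shorter element.
    """
    order = sorted(
        candidates,
        key=lambda c: (-c.score, c.element_interval.start, c.element_interval.length),
    )
    kept: list[Candidate] = []
    for cand in order:
        if not any(cand.element_interval.overlaps(k.element_interval) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: (c.seq_name, c.element_interval.start))
    return kept


# ---------------------------------------------------------------------------
# Boundary refinement: terminal motif + TSD
# ---------------------------------------------------------------------------


def _motif_mismatches(seq: str, s: int, e: int, motif: str) -> int:
    """Mismatches of seq[s:s+2] / seq[e-2:e] against the 4 motif bases."""
    m = motif.upper()
    head, tail = m[:2], m[2:]
    mm = 0
    for i in range(2):
        if seq[s + i] != head[i]:
            mm += 1
        if seq[e - 2 + i] != tail[i]:
            mm += 1
    return mm


def _longest_tsd(seq: str, s: int, e: int, tsd_min: int, tsd_max: int) -> str | None:
    for t in range(tsd_max, tsd_min - 1, -1):
        if s - t < 0 or e + t > len(seq):
            continue
        left = seq[s - t : s]
        if left == seq[e : e + t] and "N" not in left:
            return left
    return None


def refine_boundaries(
    candidate: Candidate, assembly: Assembly, params: DetectionParams | None = None
) -> Candidate | None:
    """Adjust element termini within +/- vicinity for motif and TSD.

    Returns None when no boundary pair within the vicinity satisfies the
    terminal-motif requirement (<= motif_mismatch_max mismatches over the
    four motif bases). The TSD, when found, is the longest flanking direct
    repeat within [tsd_min, tsd_max]; its absence does not reject the
    candidate.
    """
    if params is None:
        params = DetectionParams()
    seq = assembly[candidate.seq_name].seq
    s0, e0 = candidate.element_interval.start, candidate.element_interval.end
    vic = params.vicinity
    best_key = None
    best: tuple[int, int, int, str | None] | None = None
    for ds in range(-vic, vic + 1):
        s = s0 + ds
        if s < 0 or s + 2 > len(seq):
            continue
        for de in range(-vic, vic + 1):
            e = e0 + de
            if e > len(seq) or e - 2 < s:
                continue
            mm = _motif_mismatches(seq, s, e, params.motif)
            if mm > params.motif_mismatch_max:
                continue
            tsd = _longest_tsd(seq, s, e, params.tsd_min, params.tsd_max)
            key = (
                tsd is not None,
                -mm,
                -(abs(ds) + abs(de)),
                len(tsd) if tsd else 0,
            )
            if best_key is None or key > best_key:
                best_key = key
                best = (s, e, mm, tsd)
    if best is None:
        return None
    s, e, mm, tsd = best
    edge = s - params.tsd_min < 0 or e + params.tsd_min > len(seq)
    t = len(tsd) if tsd else 0
    refined = replace(
        candidate,
        element_interval=Interval(candidate.seq_name, s, e, "+"),
        ltr5=Interval(candidate.seq_name, s, max(candidate.ltr5.end, s + 1), "+"),
        ltr3=Interval(candidate.seq_name, min(candidate.ltr3.start, e - 1), e, "+"),
        tsd=tsd,
        tsd_intervals=(
            Interval(candidate.seq_name, s - t, s),
            Interval(candidate.seq_name, e, e + t),
        )
        if tsd
        else None,
        motif_ok=mm == 0,
        motif_mismatches=mm,
        edge_flag=edge and tsd is None,
    )
    return refined


# ---------------------------------------------------------------------------
# Superfamily classification and quality filter
# ---------------------------------------------------------------------------

_TE_KINDS = ("INT", "RT", "RH")


def classify_superfamily(candidate: Candidate, domains: list[DomainHit]) -> str:
    """RLC (INT-RT-RH), RLG (RT-RH-INT) or RLX from internal domain order."""
    inner = [
        h
        for h in domains
        if h.seq_name == candidate.seq_name
        and h.start >= candidate.ltr5.end
        and h.end <= candidate.ltr3.start
        and h.kind in _TE_KINDS
    ]
    inner.sort(key=lambda h: h.start)
    strands = {h.strand for h in inner}
    order = [h.kind for h in inner]
    if len(strands) == 1 and strands == {"-"}:
        order = order[::-1]
    kinds = set(order)
    if kinds != set(_TE_KINDS) or len(order) != 3:
        return "RLX"
    if order == ["INT", "RT", "RH"]:
        return "RLC"
    if order == ["RT", "RH", "INT"]:
        return "RLG"
    return "RLX"


def tandem_fraction(
    seq: str,
    min_period: int = 2,
    max_period: int = 50,
    min_identity: float = 0.8,
) -> float:
    """Fraction of bases covered by tandem arrays of period 2-50.

    A position is covered when a window of max(2p, 12) period-p
    self-comparisons around it matches at >= min_identity. This is the
    module's own definition of tandem-repeat percentage.
    """
    n = len(seq)
    if n == 0:
        return 0.0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    covered = np.zeros(n, dtype=bool)
    for p in range(min_period, max_period + 1):
        w = max(2 * p, 12)
        if n < w + p:
            continue
        m = (arr[:-p] == arr[p:]).astype(np.int32)
        cs = np.concatenate([[0], np.cumsum(m)])
        win = cs[w:] - cs[:-w]  # matches in m[i : i+w]
        hit = np.nonzero(win >= min_identity * w)[0]
        for i in hit:
            covered[i : i + w + p] = True
    return float(covered.mean())


def quality_filter(
    elements: list[FullLengthElement],
    assembly: Assembly,
    domains: list[DomainHit],
    params: DetectionParams | None = None,
) -> tuple[list[FullLengthElement], list[FullLengthElement]]:
    """Stringent gap-free high-quality filter.

    Pass requires: zero N inside the span; tandem-repeat fraction <=
    tandem_max_inner in the internal region and <= tandem_max_ltr in each
    LTR; no GENE domain hits inside; no duplicated TE domain kinds; strand
    consistency among domain hits. Every element carries its failure
    reasons.
    """
    if params is None:
        params = DetectionParams()
    passed: list[FullLengthElement] = []
    failed: list[FullLengthElement] = []
    for el in elements:
        cand = el.candidate
        seq = assembly.fetch(cand.element_interval)
        reasons: list[str] = []
        if "N" in seq:
            reasons.append("gap")
        inner_seq = assembly[cand.seq_name].seq[cand.ltr5.end : cand.ltr3.start]
        if tandem_fraction(inner_seq) > params.tandem_max_inner / 100.0:
            reasons.append("tandem_inner")
        for label, iv in (("ltr5", cand.ltr5), ("ltr3", cand.ltr3)):
            if tandem_fraction(assembly.fetch(iv)) > params.tandem_max_ltr / 100.0:
                reasons.append(f"tandem_{label}")
        inside = [
            h
            for h in domains
            if h.seq_name == cand.seq_name
            and h.start >= cand.element_interval.start
            and h.end <= cand.element_interval.end
        ]
        if any(h.kind == "GENE" for h in inside):
            reasons.append("gene_domain")
        te_kinds = [h.kind for h in inside if h.kind in _TE_KINDS]
        if len(te_kinds) != len(set(te_kinds)):
            reasons.append("duplicated_te_domain")
        strands = {h.strand for h in inside if h.kind in _TE_KINDS}
        if len(strands) > 1:
            reasons.append("strand_inconsistency")
        el.failure_reasons = reasons
        el.quality_pass = not reasons
        (passed if el.quality_pass else failed).append(el)
    return passed, failed


def annotate_assembly(
    assembly: Assembly,
    domains: list[DomainHit] | None = None,
    params: DetectionParams | None = None,
) -> list[FullLengthElement]:
    """Full pipeline: detect, refine, classify, quality-filter.

    Returns all refined elements (passing and failing) with quality flags
    set; superfamily is RLX when no domain information is supplied.
    """
    if params is None:
        params = DetectionParams()
    domains = domains or []
    elements: list[FullLengthElement] = []
    for cand in find_candidates(assembly, params):
        refined = refine_boundaries(cand, assembly, params)
        if refined is None:
            continue
        sf = classify_superfamily(refined, domains)
        elements.append(FullLengthElement(candidate=refined, superfamily=sf))
    quality_filter(elements, assembly, domains, params)
    return elements


# ---------------------------------------------------------------------------
# Solo-LTRs and size selection
# ---------------------------------------------------------------------------


def find_solo_ltrs(
    assembly: Assembly,
    ltr_consensus: str,
    full_length_spans: list[Interval],
    params: DetectionParams | None = None,
) -> list[SoloLTR]:
    """Solo-LTR discovery by local alignment against an LTR consensus.

    Hits need >= solo_min_coverage coverage and >= solo_min_identity
    identity, must not overlap a full-length element span, and must not
    have a second hit within max_dist on the same strand (which would
    indicate an undetected LTR pair).
    """
    if params is None:
        params = DetectionParams()
    if len(ltr_consensus) < params.min_ltr:
        raise ValueError("consensus shorter than min_ltr")
    solos: list[SoloLTR] = []
    for rec in assembly:
        hits = find_local_hits(ltr_consensus, rec.seq, k=16)
        hits = [
            h
            for h in hits
            if h.identity >= params.solo_min_identity
            and h.coverage >= params.solo_min_coverage
        ]
        # deduplicate overlapping hits, best score first
        dedup = []
        for h in hits:
            if all(
                h.target_end <= o.target_start or h.target_start >= o.target_end
                for o in dedup
            ):
                dedup.append(h)
        # exclude hits inside detected full-length elements
        spans = [iv for iv in full_length_spans if iv.seq_name == rec.name]
        free = [
            h
            for h in dedup
            if not any(
                h.target_start < iv.end and iv.start < h.target_end for iv in spans
            )
        ]
        for h in free:
            paired = any(
                o is not h
                and o.strand == h.strand
                and abs(o.target_start - h.target_start) <= params.max_dist
                for o in free
            )
            if paired:
                continue
            tsd = _longest_tsd(
                rec.seq, h.target_start, h.target_end, params.tsd_min, params.tsd_max
            )
            solos.append(
                SoloLTR(
                    seq_name=rec.name,
                    interval=Interval(rec.name, h.target_start, h.target_end, h.strand),
                    identity=h.identity,
                    tsd=tsd,
                )
            )
    solos.sort(key=lambda s: (s.seq_name, s.interval.start))
    return solos


def select_size_class(
    elements: list[FullLengthElement],
    min_len: int = 8500,
    max_len: int = 9000,
    gappy_max_len: int = 9800,
    gappy: bool = False,
) -> list[FullLengthElement]:
    """Family size selection: keep elements in [min_len, max_len].

    In gappy mode (gap-inflated assemblies) the upper bound is relaxed to
    gappy_max_len.
    """
    upper = gappy_max_len if gappy else max_len
    return [el for el in elements if min_len <= el.length <= upper]
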