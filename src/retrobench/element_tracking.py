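"""Junction-anchored tracking of elements between assembly versions and the
normalized SNP/N divergence profile.

Each element is represented by two junction sequences (terminal 100 bp of
the element plus 100 bp of flank on each side). Junctions are located in a
target assembly by seeded local alignment; an element is accepted when both
junctions hit the same sequence in the same orientation at the expected
spacing. Accepted element pairs are locally aligned and their SNP and N
columns are accumulated on a 1,000-bin normalized coordinate, summed into
100 ten-bin windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import aligned_strings, find_local_hits, make_aligner
from .genome_model import Assembly, Interval

JUNCTION_TERMINAL = 100  # bp of element terminus in each junction
JUNCTION_FLANK = 100  # bp of flanking sequence in each junction

N_BINS = 1000
BINS_PER_WINDOW = 10
N_WINDOWS = N_BINS // BINS_PER_WINDOW


@dataclass
class JunctionPair:
    element_id: str
    five_prime: str  # flank + terminal element sequence
    three_prime: str  # terminal element sequence + flank
    element_length: int
    five_truncated: bool = False
    three_truncated: bool = False


@dataclass
class JunctionMatch:
    element_id: str
    target_seq: str | None
    accepted: bool
    reason: str = ""
    observed_span: int | None = None
    expected_span: int | None = None
    five_interval: Interval | None = None
    three_interval: Interval | None = None
    strand: str | None = None


@dataclass
class ElementAlignment:
    element_id: str
    aligned_query: str
    aligned_target: str
    snp_positions: list[int] = field(default_factory=list)  # query-relative
    n_positions: list[int] = field(default_factory=list)
    query_length: int = 0


@dataclass
class DivergenceProfile:
    windows: pd.DataFrame  # columns: window, snp_count, n_count
    n_elements: int


def extract_junctions(
    element_id: str, interval: Interval, assembly: Assembly
) -> JunctionPair:
    """Terminal 100 bp of the element plus 100 bp of flank, on each side.

    Flanks are clipped at sequence edges and flagged as truncated.
    """
    if interval.length < 2 * JUNCTION_TERMINAL:
        raise ValueError(
            f"element {element_id} shorter than {2 * JUNCTION_TERMINAL} bp"
        )
    rec = assembly[interval.seq_name]
    f_lo = max(0, interval.start - JUNCTION_FLANK)
    t_hi = min(rec.length, interval.end + JUNCTION_FLANK)
    five = rec.seq[f_lo : interval.start + JUNCTION_TERMINAL]
    three = rec.seq[interval.end - JUNCTION_TERMINAL : t_hi]
    return JunctionPair(
        element_id=element_id,
        five_prime=five,
        three_prime=three,
        element_length=interval.length,
        five_truncated=f_lo > interval.start - JUNCTION_FLANK
        or interval.start < JUNCTION_FLANK,
        three_truncated=t_hi < interval.end + JUNCTION_FLANK,
    )


def _best_hits(junction_seq: str, rec_seq: str, aligner, min_identity, min_cov_frac):
    hits = find_local_hits(junction_seq, rec_seq, k=16, aligner=aligner)
    return [
        h
        for h in hits
        if h.identity >= min_identity
        and h.coverage >= 100.0 * min_cov_frac
    ]


def match_junctions(
    junctions: JunctionPair,
    target: Assembly,
    tolerance: float = 0.10,
    min_identity: float = 90.0,
    min_coverage: float = 0.80,
) -> JunctionMatch:
    """Locate both junctions in the target assembly.

    Accepted iff the best hits of both junctions land on the same sequence
    in the same orientation with an observed span within ``tolerance`` of
    the expected span. Ambiguous junctions (two equal-scoring best hits)
    are rejected conservatively.
    """
    aligner = make_aligner(2, -2, -10, -0.5, mode="local")
    per_junction = []
    for jseq in (junctions.five_prime, junctions.three_prime):
        all_hits = []
        for rec in target:
            for h in _best_hits(jseq, rec.seq, aligner, min_identity, min_coverage):
                all_hits.append((rec.name, h))
        if not all_hits:
            return JunctionMatch(
                junctions.element_id, None, False, reason="junction_unmatched"
            )
        all_hits.sort(key=lambda x: -x[1].score)
        if (
            len(all_hits) > 1
            and all_hits[0][1].score == all_hits[1][1].score
            and (
                all_hits[0][0] != all_hits[1][0]
                or all_hits[0][1].target_start != all_hits[1][1].target_start
            )
        ):
            return JunctionMatch(
                junctions.element_id, None, False, reason="ambiguous"
            )
        per_junction.append(all_hits[0])
    (seq5, hit5), (seq3, hit3) = per_junction
    if seq5 != seq3:
        return JunctionMatch(
            junctions.element_id, None, False, reason="different_sequences"
        )
    if hit5.strand != hit3.strand:
        return JunctionMatch(
            junctions.element_id, seq5, False, reason="opposite_orientation"
        )
    lo = min(hit5.target_start, hit3.target_start)
    hi = max(hit5.target_end, hit3.target_end)
    observed = hi - lo
    expected = (
        len(junctions.five_prime)
        + len(junctions.three_prime)
        + junctions.element_length
        - 2 * JUNCTION_TERMINAL
    )
    if abs(observed - expected) > tolerance * expected:
        return JunctionMatch(
            junctions.element_id,
            seq5,
            False,
            reason="span_mismatch",
            observed_span=observed,
            expected_span=expected,
        )
    return JunctionMatch(
        junctions.element_id,
        seq5,
        True,
        observed_span=observed,
        expected_span=expected,
        five_interval=Interval(seq5, hit5.target_start, hit5.target_end),
        three_interval=Interval(seq3, hit3.target_start, hit3.target_end),
        strand=hit5.strand,
    )


def align_elements(
    element_id: str,
    query_seq: str,
    target_seq: str,
    match: float = 2.0,
    mismatch: float = -2.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> ElementAlignment:
    """Local (water-style) alignment with SNP and N column classification.

    SNP: aligned column with two determinate, unequal bases. N column:
    target base is N. Positions are query-relative offsets.
    """
    if not query_seq or not target_seq:
        raise ValueError("empty input sequence")
    aligner = make_aligner(
        match, mismatch, gap_open, gap_extend, mode="local", n_neutral=True
    )
    aln = aligner.align(query_seq, target_seq)[0]
    ga, gb = aligned_strings(aln)
    q_pos = int(aln.coordinates[0][0])
    snps: list[int] = []
    ns: list[int] = []
    det = set("ACGT")
    for x, y in zip(ga, gb):
        if y == "N" and x != "-":
            ns.append(q_pos)
        elif x in det and y in det and x != y:
            snps.append(q_pos)
        if x != "-":
            q_pos += 1
    return ElementAlignment(
        element_id=element_id,
        aligned_query=ga,
        aligned_target=gb,
        snp_positions=snps,
        n_positions=ns,
        query_length=len(query_seq),
    )


def divergence_profile(alignments: list[ElementAlignment]) -> DivergenceProfile:
    """Aggregate SNP/N positions into 100 windows of 10 normalized bins.

    Each position is mapped to a relative coordinate on its query element,
    binned into 1,000 bins, aggregated across elements and summed in
    10-bin windows.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    snp_bins = np.zeros(N_BINS, dtype=np.int64)
    n_bins = np.zeros(N_BINS, dtype=np.int64)
    for aln in alignments:
        L = aln.query_length
        if L <= 0:
            raise ValueError("alignment with non-positive query length")
        for pos in aln.snp_positions:
            snp_bins[min(int(pos * N_BINS / L), N_BINS - 1)] += 1
        for pos in aln.n_positions:
            n_bins[min(int(pos * N_BINS / L), N_BINS - 1)] += 1
    snp_windows = snp_bins.reshape(N_WINDOWS, BINS_PER_WINDOW).sum(axis=1)
    n_windows = n_bins.reshape(N_WINDOWS, BINS_PER_WINDOW).sum(axis=1)
    df = pd.DataFrame(
        {
            "window": np.arange(N_WINDOWS),
            "snp_count": snp_windows,
            "n_count": n_windows,
        }
    )
    return DivergenceProfile(windows=df, n_elements=len(alignments))


def track_elements(
    elements: list[tuple[str, Interval]],
    source: Assembly,
    target: Assembly,
    tolerance: float = 0.10,
) -> tuple[list[JunctionMatch], list[ElementAlignment]]:
    """End-to-end tracking: junctions, matching, and element alignment."""
    matches: list[JunctionMatch] = []
    alignments: list[ElementAlignment] = []
    for element_id, iv in elements:
        jp = extract_junctions(element_id, iv, source)
        m = match_junctions(jp, target, tolerance)
        matches.append(m)
        if not m.accepted:
            continue
        query_seq = source.fetch(iv)
        lo = min(m.five_interval.start, m.three_interval.start)
        hi = max(m.five_interval.end, m.three_interval.end)
        target_seq = target[m.target_seq].seq[lo:hi]
        alignments.append(align_elements(element_id, query_seq, target_seq))
    return matches, alignments
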