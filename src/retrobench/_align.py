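"""Shared pairwise-alignment helpers built on Bio.Align.PairwiseAligner.

Wraps global/local affine-gap alignment and a seeded local-hit finder used
by solo-LTR discovery, junction matching and transcript mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_model import reverse_complement


def make_aligner(
    match: float = 2.0,
    mismatch: float = -2.0,
    gap_open: float = -3.0,
    gap_extend: float = -3.0,
    mode: str = "global",
    n_neutral: bool = False,
) -> Align.PairwiseAligner:
    """Affine-gap aligner; with n_neutral, N scores 0 against everything.

    Neutral N keeps gap-masked stretches columnar instead of having them
    gapped out, which matters when classifying N columns.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if n_neutral:
        alphabet = "ACGTN"
        mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                if a == "N" or b == "N":
                    mat[a, b] = 0.0
                else:
                    mat[a, b] = match if a == b else mismatch
        aligner.substitution_matrix = mat
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def aligned_strings(alignment) -> tuple[str, str]:
    """Gapped query/target strings of a Bio.Align.Alignment."""
    return str(alignment[0]), str(alignment[1])


def global_alignment(a: str, b: str, aligner: Align.PairwiseAligner | None = None):
    if aligner is None:
        aligner = make_aligner()
    return aligner.align(a, b)[0]


def identity_percent(gapped_a: str, gapped_b: str) -> float:
    """Percent of alignment columns with equal determinate bases."""
    if len(gapped_a) != len(gapped_b):
        raise ValueError("gapped strings differ in length")
    if not gapped_a:
        return 0.0
    matches = sum(1 for x, y in zip(gapped_a, gapped_b) if x == y and x != "-")
    return 100.0 * matches / len(gapped_a)


def global_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    aln = global_alignment(a, b, aligner)
    return identity_percent(*aligned_strings(aln))


@dataclass
class LocalHit:
    """Best local-alignment hit of a query inside a target sequence."""

    target_start: int
    target_end: int
    query_start: int
    query_end: int
    strand: str
    score: float
    identity: float  # percent over aligned columns
    coverage: float  # percent of query length aligned
    alignment: object = None


def _seed_clusters(query: str, target: str, k: int, max_diag_drift: int = 50):
    """Cluster exact k-mer matches by diagonal; yields (t_lo, t_hi) windows."""
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    hits: list[tuple[int, int]] = []  # (diagonal, target pos)
    for j in range(len(target) - k + 1):
        positions = index.get(target[j : j + k])
        if positions:
            for qpos in positions:
                hits.append((j - qpos, j))
    if not hits:
        return []
    hits.sort()
    clusters: list[list[tuple[int, int]]] = []
    cur = [hits[0]]
    for h in hits[1:]:
        if h[0] - cur[-1][0] <= max_diag_drift:
            cur.append(h)
        else:
            clusters.append(cur)
            cur = [h]
    clusters.append(cur)
    # Window must cover the whole query around the seeded region.
    pad = len(query) + 2 * max_diag_drift
    windows = []
    for cl in clusters:
        t_lo = max(0, min(t for _, t in cl) - pad)
        t_hi = min(len(target), max(t for _, t in cl) + k + pad)
        windows.append((t_lo, t_hi, len(cl)))
    windows.sort(key=lambda w: -w[2])
    return windows


def find_local_hits(
    query: str,
    target: str,
    k: int = 16,
    aligner: Align.PairwiseAligner | None = None,
    both_strands: bool = True,
    max_windows: int = 20,
) -> list[LocalHit]:
    """Seeded local alignment of query against target.

    Exact k-mer seeds are clustered by diagonal; each cluster window is
    realigned with an affine-gap local aligner. Returns hits sorted by
    descending score.
    """
    if aligner is None:
        aligner = make_aligner(2, -2, -10, -0.5, mode="local")
    hits: list[LocalHit] = []
    strands = [("+", query)]
    if both_strands:
        strands.append(("-", reverse_complement(query)))
    for strand, q in strands:
        for t_lo, t_hi, _ in _seed_clusters(q, target, k)[:max_windows]:
            window = target[t_lo:t_hi]
            alns = aligner.align(q, window)
            if len(alns) == 0:
                continue
            aln = alns[0]
            if aln.score <= 0:
                continue
            coords = aln.coordinates
            q_start, q_end = int(coords[0][0]), int(coords[0][-1])
            t_start, t_end = int(coords[1][0]) + t_lo, int(coords[1][-1]) + t_lo
            ga, gb = aligned_strings(aln)
            ident = identity_percent(ga, gb)
            cov = 100.0 * (q_end - q_start) / len(q)
            if strand == "-":
                q_start, q_end = len(q) - q_end, len(q) - q_start
            hits.append(
                LocalHit(
                    target_start=t_start,
                    target_end=t_end,
                    query_start=q_start,
                    query_end=q_end,
                    strand=strand,
                    score=float(aln.score),
                    identity=ident,
                    coverage=cov,
                    alignment=aln,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.target_start))
    return hits
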