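"""Divergence-based insertion dating, TSD decay arithmetic and 20-mer
repetitivity of detected elements.

Insertion age follows from the Kimura 2-parameter distance d between the
two LTRs of an element: age = d / (2 * mu), with mu the per-site per-year
substitution rate (default 1.3e-8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import aligned_strings, global_alignment, make_aligner
from .genome_model import Assembly, reverse_complement
from .ltr_annotator import DetectionParams, FullLengthElement

DEFAULT_MU = 1.3e-8

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_DETERMINATE = frozenset("ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: log argument non-positive."""


@dataclass(frozen=True)
class K2PResult:
    P: float  # transition fraction
    Q: float  # transversion fraction
    d: float  # substitutions per site
    sites_used: int


@dataclass
class AgeEstimate:
    element_id: str
    d: float
    mu: float
    age_years: float
    superfamily: str = "RLX"


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def k2p_distance(aligned_a: str, aligned_b: str) -> K2PResult:
    """Kimura 2-parameter distance from an aligned pair.

    Columns containing a gap or N are excluded (pairwise deletion).
    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    sites = transitions = transversions = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in _DETERMINATE or y not in _DETERMINATE:
            continue
        sites += 1
        if x == y:
            continue
        if is_transition(x, y):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no usable sites (all columns gapped or ambiguous)")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated divergence: P={P:.3f}, Q={Q:.3f}")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, d=d, sites_used=sites)


def insertion_age(d: float, mu: float = DEFAULT_MU) -> float:
    """Years since insertion: d / (2 * mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if d < 0:
        raise ValueError("d must be >= 0")
    return d / (2.0 * mu)


def tsd_decay_fraction(
    age_years: float,
    mu: float = DEFAULT_MU,
    tsd_len: int = 5,
    model: str = "expected_count",
) -> float:
    """Percent of TSDs expected to carry a mutation after ``age_years``.

    expected_count: 100 * tsd_len * mu * age (expected substitution load);
    poisson: 100 * (1 - exp(-tsd_len * mu * age)) (probability of >= 1 hit).
    """
    if age_years < 0:
        raise ValueError("age_years must be >= 0")
    lam = tsd_len * mu * age_years
    if model == "expected_count":
        return 100.0 * lam
    if model == "poisson":
        return 100.0 * (1.0 - math.exp(-lam))
    raise ValueError(f"unknown model {model!r}")


def tsd_perfect(left_tsd: str | None, right_tsd: str | None, tsd_len: int = 5):
    """True iff both copies are present, byte-identical and of tsd_len.

    Returns None (indeterminate) when a side is absent, e.g. at a contig
    edge.
    """
    if left_tsd is None or right_tsd is None:
        return None
    return left_tsd == right_tsd and len(left_tsd) == tsd_len


# ---------------------------------------------------------------------------
# Element dating pipeline
# ---------------------------------------------------------------------------


def date_element(
    element: FullLengthElement,
    assembly: Assembly,
    mu: float = DEFAULT_MU,
    params: DetectionParams | None = None,
) -> AgeEstimate:
    """Globally align the element's LTR pair and convert K2P d to years."""
    if params is None:
        params = DetectionParams()
    aligner = make_aligner(
        params.match, params.mismatch, params.gap_open, params.gap_extend, "global"
    )
    a = assembly.fetch(element.candidate.ltr5)
    b = assembly.fetch(element.candidate.ltr3)
    aln = global_alignment(a, b, aligner)
    res = k2p_distance(*aligned_strings(aln))
    return AgeEstimate(
        element_id=f"{element.interval.seq_name}:{element.interval.start}-{element.interval.end}",
        d=res.d,
        mu=mu,
        age_years=insertion_age(res.d, mu),
        superfamily=element.superfamily,
    )


def date_elements(
    elements: list[FullLengthElement],
    assembly: Assembly,
    mu: float = DEFAULT_MU,
    params: DetectionParams | None = None,
) -> list[AgeEstimate]:
    return [date_element(el, assembly, mu, params) for el in elements]


# ---------------------------------------------------------------------------
# 20-mer repetitivity
# ---------------------------------------------------------------------------


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


class KmerIndex:
    """Frequency table of canonical k-mers of an assembly (N-free only)."""

    def __init__(self, k: int = 20):
        self.k = k
        self.counts: dict[str, int] = {}

    def add_sequence(self, seq: str) -> None:
        k = self.k
        counts = self.counts
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            ckmer = canonical_kmer(kmer)
            counts[ckmer] = counts.get(ckmer, 0) + 1

    def frequency(self, kmer: str) -> int:
        return self.counts.get(canonical_kmer(kmer), 0)


def build_kmer_index(assembly: Assembly, k: int = 20) -> KmerIndex:
    index = KmerIndex(k)
    for rec in assembly:
        index.add_sequence(rec.seq)
    return index


def element_repetitivity(element_seq: str, index: KmerIndex) -> float:
    """Median index frequency over all N-free k-mers of the element."""
    k = index.k
    if len(element_seq) < k:
        raise ValueError(f"element shorter than k={k}")
    freqs = [
        index.frequency(element_seq[i : i + k])
        for i in range(len(element_seq) - k + 1)
        if "N" not in element_seq[i : i + k]
    ]
    if not freqs:
        raise ValueError("no N-free k-mers in element")
    return float(np.median(freqs))


def age_histogram(
    estimates: list[AgeEstimate], bin_width_years: float = 100_000.0
) -> pd.DataFrame:
    """Counts per age bin for all elements and per superfamily subset."""
    if any(not math.isfinite(e.age_years) for e in estimates):
        raise ValueError("non-finite age estimate")
    ages = np.array([e.age_years for e in estimates])
    sfs = np.array([e.superfamily for e in estimates])
    n_bins = int(ages.max() // bin_width_years) + 1 if len(ages) else 1
    edges = np.arange(n_bins + 1) * bin_width_years
    rows = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        in_bin = (ages >= lo) & ((ages < hi) | ((i == n_bins - 1) & (ages == hi)))
        row = {"bin_start": lo, "bin_end": hi, "all": int(in_bin.sum())}
        for sf in ("RLC", "RLG", "RLX"):
            row[sf] = int((in_bin & (sfs == sf)).sum())
        rows.append(row)
    return pd.DataFrame(rows)
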