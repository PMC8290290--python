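"""Synthetic genomes with planted LTR retrotransposons, solo-LTRs and genes.

The simulator provides ground truth for every downstream analysis stage:
element positions, LTR pairs, target-site duplications (TSDs), insertion
ages, solo flags, planted genes, and a record of every degradation edit
(N-run masking inside LTRs, collapse of near-identical copies, random
substitutions, contig fragmentation) so that truth can be tracked through
a degraded assembly.

Insertion semantics: the ``tsd_len`` bases at the insertion site are
duplicated so that identical TSD copies flank the element; deleting the
element plus one TSD copy restores the pre-insertion sequence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_model import (
    Assembly,
    GeneModel,
    Gff3Feature,
    Interval,
    SequenceRecord,
)

DEFAULT_MU = 1.3e-8  # substitutions per site per year
DEFAULT_KAPPA = 2.0  # transition:transversion ratio

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class FamilyModel:
    """Size/structure model of one retrotransposon family."""

    name: str
    ltr_len: int
    internal_len: int
    # (kind, start, end) relative to the internal region
    domain_layout: tuple[tuple[str, int, int], ...] = ()
    tsd_len: int = 5

    def __post_init__(self) -> None:
        if not 4 <= self.tsd_len <= 20:
            raise ValueError("tsd_len must be in [4, 20]")
        for kind, s, e in self.domain_layout:
            if not 0 <= s < e <= self.internal_len:
                raise ValueError(f"domain {kind} outside internal region")

    @property
    def total_len(self) -> int:
        return 2 * self.ltr_len + self.internal_len


def copia_family(
    name: str = "fam_rlc",
    ltr_len: int = 1000,
    total_len: int = 8950,
    tsd_len: int = 5,
) -> FamilyModel:
    """Copia-like family: internal domain order INT-RT-RH."""
    internal = total_len - 2 * ltr_len
    third = internal // 4
    layout = (
        ("INT", third // 2, third // 2 + 600),
        ("RT", third + third // 2, third + third // 2 + 700),
        ("RH", 2 * third + third // 2, 2 * third + third // 2 + 500),
    )
    return FamilyModel(name, ltr_len, internal, layout, tsd_len)


def gypsy_family(
    name: str = "fam_rlg",
    ltr_len: int = 1000,
    total_len: int = 8600,
    tsd_len: int = 5,
) -> FamilyModel:
    """Gypsy-like family: internal domain order RT-RH-INT."""
    internal = total_len - 2 * ltr_len
    third = internal // 4
    layout = (
        ("RT", third // 2, third // 2 + 700),
        ("RH", third + third // 2, third + third // 2 + 500),
        ("INT", 2 * third + third // 2, 2 * third + third // 2 + 600),
    )
    return FamilyModel(name, ltr_len, internal, layout, tsd_len)


@dataclass
class DomainAnnotation:
    kind: str
    interval: Interval
    strand: str = "+"


@dataclass
class PlantedElement:
    id: str
    family: str
    interval: Interval  # element span, TSDs excluded
    age_years: float
    tsd_seq: str
    is_solo: bool = False
    ltr_intervals: tuple[Interval, ...] = ()
    tsd_intervals: tuple[Interval, ...] = ()
    domains: list[DomainAnnotation] = field(default_factory=list)
    collapsed: bool = False
    broken: bool = False
    gapped: bool = False

    @property
    def surviving(self) -> bool:
        return not (self.collapsed or self.broken)


@dataclass
class DegradationProfile:
    ltr_gap_rate: float = 0.0
    gap_len_mean: float = 200.0
    gap_len_max: int = 1000
    collapse_fraction: float = 0.0
    collapse_identity_min: float = 99.0
    fragment_break_rate: float = 0.0  # breaks per Mb
    base_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("ltr_gap_rate", "collapse_fraction", "base_error_rate"):
            if not 0.0 <= getattr(self, attr) <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1]")
        if self.fragment_break_rate < 0 or self.gap_len_mean <= 0:
            raise ValueError("invalid profile")


@dataclass
class Edit:
    kind: str  # gap | collapse | substitution | break
    seq_name: str
    start: int
    end: int
    payload: dict = field(default_factory=dict)


@dataclass
class SimTruth:
    elements: list[PlantedElement] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    edits: list[Edit] = field(default_factory=list)
    # family name -> (ancestral LTR, ancestral internal region)
    consensus: dict[str, tuple[str, str]] = field(default_factory=dict)

    def surviving_elements(self) -> list[PlantedElement]:
        return [e for e in self.elements if e.surviving]


@dataclass
class InsertionPlan:
    family: FamilyModel
    age_years: float
    is_solo: bool = False
    position: int | None = None


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=n, p=p))


def simulate_background(
    length: int, gc: float = 0.44, seed=None, name: str = "chr1"
) -> SequenceRecord:
    """I.i.d. background sequence with P(G)+P(C) = gc."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = _rng(seed)
    return SequenceRecord(name, _random_dna(length, rng, gc))


def _mutate(
    seq: str,
    n_subs: int,
    rng: np.random.Generator,
    kappa: float,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Apply n substitutions at uniform positions (protected sites excluded)."""
    if n_subs == 0:
        return seq
    chars = list(seq)
    candidates = [i for i in range(len(chars)) if i not in protected]
    if not candidates:
        return seq
    p_ts = kappa / (kappa + 1.0)
    for pos in rng.choice(candidates, size=min(n_subs, len(candidates)), replace=True):
        base = chars[pos]
        if base == "N":
            continue
        if rng.random() < p_ts:
            chars[pos] = _TRANSITION[base]
        else:
            chars[pos] = _TRANSVERSIONS[base][rng.integers(2)]
    return "".join(chars)


@dataclass
class SynthesizedElement:
    """Element DNA plus structure in element-relative coordinates."""

    dna: str
    family: FamilyModel
    age_years: float
    ltr_spans: tuple[tuple[int, int], ...]
    domain_spans: tuple[tuple[str, int, int], ...]
    is_solo: bool = False


def make_family_ancestor(
    family: FamilyModel, seed=None
) -> tuple[str, str]:
    """Ancestral (LTR, internal) sequences shared by all family members."""
    rng = _rng(seed)
    ltr = "TG" + _random_dna(family.ltr_len - 4, rng) + "CA"
    internal = _random_dna(family.internal_len, rng)
    return ltr, internal


def synthesize_element(
    family: FamilyModel,
    age_years: float,
    mu: float = DEFAULT_MU,
    kappa: float = DEFAULT_KAPPA,
    seed=None,
    protect_motif: bool = True,
    is_solo: bool = False,
    ancestor: tuple[str, str] | None = None,
) -> SynthesizedElement:
    """Build an element whose two LTRs have diverged for ``age_years``.

    The ancestral LTR starts with TG and ends with CA; each copy
    independently receives Poisson(ltr_len * mu * age) substitutions so the
    expected pairwise LTR divergence is ~ 2 * mu * age. By default the
    terminal TG/CA dinucleotides are protected from mutation. Passing the
    same ``ancestor`` (from make_family_ancestor) makes members of a family
    share descent, so near-identical copy pairs exist at low ages.
    """
    if age_years < 0:
        raise ValueError("age_years must be >= 0")
    rng = _rng(seed)
    L = family.ltr_len
    if ancestor is None:
        ancestor = make_family_ancestor(family, rng)
    ltr, internal = ancestor
    if len(ltr) != L or len(internal) != family.internal_len:
        raise ValueError("ancestor sequences inconsistent with family model")
    protected = frozenset({0, 1, L - 2, L - 1}) if protect_motif else frozenset()
    lam = L * mu * age_years

    def aged_copy() -> str:
        return _mutate(ltr, int(rng.poisson(lam)), rng, kappa, protected)

    if is_solo:
        dna = aged_copy()
        return SynthesizedElement(
            dna, family, age_years, ((0, L),), (), is_solo=True
        )
    left, right = aged_copy(), aged_copy()
    dna = left + internal + right
    domain_spans = tuple(
        (kind, L + s, L + e) for kind, s, e in family.domain_layout
    )
    ltr_spans = ((0, L), (L + family.internal_len, family.total_len))
    return SynthesizedElement(dna, family, age_years, ltr_spans, domain_spans)


def plant_insertions(
    record: SequenceRecord,
    plans: list[InsertionPlan],
    seed=None,
    mu: float = DEFAULT_MU,
    kappa: float = DEFAULT_KAPPA,
    min_spacing: int = 0,
    age_tsds: bool = False,
    id_prefix: str = "elem",
) -> tuple[SequenceRecord, SimTruth]:
    """Insert planned elements, duplicating the target site on both flanks.

    Positions without a fixed value are drawn uniformly, re-drawn until all
    sites are pairwise separated by at least ``min_spacing``. When
    ``age_tsds`` is set, the element-distal TSD copy accumulates
    Poisson(tsd_len * mu * age) substitutions, modelling post-insertion
    TSD decay at the per-site rate ``mu``.
    """
    rng = _rng(seed)
    n = len(record.seq)
    fixed = [p.position for p in plans if p.position is not None]
    for p in fixed:
        if not 0 <= p <= n - max(pl.family.tsd_len for pl in plans):
            raise ValueError(f"insertion position {p} out of bounds")
    positions: list[int] = list(fixed)
    n_free = sum(1 for p in plans if p.position is None)
    max_tsd = max((p.family.tsd_len for p in plans), default=5)
    if n_free:
        # draw sorted positions with a guaranteed minimum gap by sampling
        # in the gap-reduced space, then re-expanding
        gap = max(min_spacing, max_tsd + 1)
        lo, hi = max_tsd, n - max_tsd
        reduced_span = (hi - lo) - (n_free - 1) * gap
        if reduced_span <= 0:
            raise ValueError("could not place insertions with requested spacing")
        tries = 0
        while True:
            draws = np.sort(rng.integers(0, reduced_span, size=n_free))
            cand = [int(d) + lo + i * gap for i, d in enumerate(draws)]
            if all(
                abs(c - f) >= gap for c in cand for f in fixed
            ) and all(b - a >= gap for a, b in zip(cand, cand[1:])):
                positions.extend(cand)
                break
            tries += 1
            if tries > 10_000:
                raise ValueError("could not place insertions with requested spacing")
    # pair plans to positions: fixed keep theirs, the rest in drawn order
    paired: list[tuple[int, InsertionPlan]] = []
    drawn = positions[len(fixed):]
    di = 0
    for plan in plans:
        if plan.position is not None:
            paired.append((plan.position, plan))
        else:
            paired.append((drawn[di], plan))
            di += 1
    paired.sort(key=lambda x: x[0])

    pieces: list[str] = []
    truth = SimTruth()
    ancestors: dict[str, tuple[str, str]] = {}
    prev = 0
    offset = 0
    for idx, (pos, plan) in enumerate(paired):
        fam = plan.family
        if fam.name not in ancestors:
            ancestors[fam.name] = make_family_ancestor(fam, rng)
        synth = synthesize_element(
            fam, plan.age_years, mu, kappa, rng,
            is_solo=plan.is_solo, ancestor=ancestors[fam.name],
        )
        t = plan.family.tsd_len
        tsd = record.seq[pos : pos + t]
        right_tsd = tsd
        if age_tsds:
            right_tsd = _mutate(
                tsd, int(rng.poisson(t * mu * plan.age_years)), rng, kappa
            )
        pieces.append(record.seq[prev:pos])
        pieces.append(tsd)
        pieces.append(synth.dna)
        pieces.append(right_tsd)
        prev = pos + t
        # final coordinates
        elem_start = pos + offset + t
        elem_end = elem_start + len(synth.dna)
        ltrs = tuple(
            Interval(record.name, elem_start + s, elem_start + e, "+")
            for s, e in synth.ltr_spans
        )
        domains = [
            DomainAnnotation(kind, Interval(record.name, elem_start + s, elem_start + e, "+"))
            for kind, s, e in synth.domain_spans
        ]
        truth.elements.append(
            PlantedElement(
                id=f"{id_prefix}{idx:03d}",
                family=plan.family.name,
                interval=Interval(record.name, elem_start, elem_end, "+"),
                age_years=plan.age_years,
                tsd_seq=tsd,
                is_solo=plan.is_solo,
                ltr_intervals=ltrs,
                tsd_intervals=(
                    Interval(record.name, elem_start - t, elem_start),
                    Interval(record.name, elem_end, elem_end + t),
                ),
                domains=domains,
            )
        )
        offset += len(synth.dna) + t
    pieces.append(record.seq[prev:])
    truth.consensus = ancestors
    return SequenceRecord(record.name, "".join(pieces)), truth


def remove_insertion(seq: str, element: PlantedElement) -> str:
    """Delete an element plus one TSD copy; inverse of insertion."""
    t = len(element.tsd_seq)
    return seq[: element.interval.start] + seq[element.interval.end + t :]


def plant_genes(
    record: SequenceRecord,
    truth: SimTruth,
    n: int,
    gene_len: int = 1500,
    seed=None,
    id_prefix: str = "gene",
) -> tuple[SequenceRecord, SimTruth]:
    """Insert random gene sequences outside planted elements.

    Existing truth coordinates are lifted over the gene insertions; gene
    sequences are recorded verbatim.
    """
    if n == 0:
        return record, truth
    rng = _rng(seed)
    blocked: list[tuple[int, int]] = []
    for e in truth.elements:
        lo = min(iv.start for iv in (e.tsd_intervals or (e.interval,)))
        hi = max(iv.end for iv in (e.tsd_intervals or (e.interval,)))
        blocked.append((lo, hi))
    blocked.sort()

    def is_free(pos: int) -> bool:
        return all(not (lo < pos < hi) for lo, hi in blocked)

    points: list[int] = []
    tries = 0
    while len(points) < n:
        cand = int(rng.integers(0, len(record.seq)))
        if is_free(cand) and all(abs(cand - q) > gene_len for q in points):
            points.append(cand)
        tries += 1
        if tries > 200_000:
            raise ValueError("insufficient free space to place genes")
    points.sort()

    pieces: list[str] = []
    prev = 0
    genes: list[GeneModel] = []
    for i, pos in enumerate(points):
        gene_seq = _random_dna(gene_len, rng)
        pieces.append(record.seq[prev:pos])
        pieces.append(gene_seq)
        start = pos + i * gene_len
        genes.append(
            GeneModel(
                id=f"{id_prefix}{i:03d}",
                interval=Interval(record.name, start, start + gene_len, "+"),
                sequence=gene_seq,
            )
        )
        prev = pos

    pieces.append(record.seq[prev:])
    new_seq = "".join(pieces)

    def lift(iv: Interval) -> Interval:
        shift = gene_len * sum(1 for p in points if p <= iv.start)
        return iv.shifted(shift) if shift else iv

    new_elements = []
    for e in truth.elements:
        new_elements.append(
            replace(
                e,
                interval=lift(e.interval),
                ltr_intervals=tuple(lift(iv) for iv in e.ltr_intervals),
                tsd_intervals=tuple(lift(iv) for iv in e.tsd_intervals),
                domains=[
                    DomainAnnotation(d.kind, lift(d.interval), d.strand)
                    for d in e.domains
                ],
            )
        )
    return SequenceRecord(record.name, new_seq), SimTruth(
        new_elements, truth.genes + genes, truth.edits, truth.consensus
    )


def _hamming_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        return 0.0
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def degrade_assembly(
    record: SequenceRecord,
    truth: SimTruth,
    profile: DegradationProfile,
    seed=None,
) -> tuple[Assembly, SimTruth]:
    """Apply short-read-assembly-style degradation.

    Order: (1) N-run masking inside LTRs, (2) collapse of near-identical
    copy pairs (one copy deleted), (3) random substitutions, (4)
    fragmentation into contigs. Truth coordinates are lifted through the
    coordinate-changing steps.
    """
    rng = _rng(seed)
    seq = list(record.seq)
    elements = [replace(e) for e in truth.elements]
    genes = list(truth.genes)
    edits = list(truth.edits)

    # (1) N runs targeted at LTRs; in-place masking keeps coordinates stable
    if profile.ltr_gap_rate > 0:
        for e in elements:
            for ltr in e.ltr_intervals:
                if rng.random() < profile.ltr_gap_rate:
                    glen = 1 + int(rng.exponential(profile.gap_len_mean))
                    glen = min(glen, profile.gap_len_max, ltr.length)
                    gstart = ltr.start + int(rng.integers(0, ltr.length - glen + 1))
                    seq[gstart : gstart + glen] = "N" * glen
                    e.gapped = True
                    edits.append(Edit("gap", record.name, gstart, gstart + glen))

    # (2) collapse near-identical duplicate pairs
    if profile.collapse_fraction > 0:
        by_family: dict[str, list[PlantedElement]] = {}
        for e in elements:
            if not e.is_solo:
                by_family.setdefault(e.family, []).append(e)
        eligible: list[tuple[PlantedElement, PlantedElement]] = []
        for fam_elems in by_family.values():
            for i in range(len(fam_elems)):
                for j in range(i + 1, len(fam_elems)):
                    a, b = fam_elems[i], fam_elems[j]
                    sa = "".join(seq[a.interval.start : a.interval.end])
                    sb = "".join(seq[b.interval.start : b.interval.end])
                    if _hamming_identity(sa, sb) >= profile.collapse_identity_min:
                        eligible.append((a, b))
        k = int(round(profile.collapse_fraction * len(eligible)))
        used: set[str] = set()
        deletions: list[PlantedElement] = []
        for a, b in eligible:
            if len(deletions) >= k:
                break
            if b.id in used or a.id in used:
                continue
            used.add(b.id)
            deletions.append(b)
        deletions.sort(key=lambda e: -e.interval.start)
        for victim in deletions:
            t = len(victim.tsd_seq)
            dstart, dend = victim.interval.start, victim.interval.end + t
            del seq[dstart:dend]
            dlen = dend - dstart
            victim.collapsed = True
            edits.append(Edit("collapse", record.name, dstart, dend, {"id": victim.id}))

            def lift(iv: Interval) -> Interval:
                if iv.start >= dend:
                    return iv.shifted(-dlen)
                return iv

            for e in elements:
                if e is victim or e.collapsed:
                    continue
                e.interval = lift(e.interval)
                e.ltr_intervals = tuple(lift(iv) for iv in e.ltr_intervals)
                e.tsd_intervals = tuple(lift(iv) for iv in e.tsd_intervals)
                e.domains = [
                    DomainAnnotation(d.kind, lift(d.interval), d.strand)
                    for d in e.domains
                ]
            genes = [
                GeneModel(g.id, lift(g.interval), g.sequence) for g in genes
            ]

    # (3) random substitutions
    if profile.base_error_rate > 0:
        n_err = rng.binomial(len(seq), profile.base_error_rate)
        pos_arr = rng.choice(len(seq), size=n_err, replace=False)
        for pos in pos_arr:
            base = seq[pos]
            if base == "N":
                continue
            alts = [b for b in _BASES if b != base]
            seq[pos] = alts[rng.integers(3)]
        edits.append(
            Edit("substitution", record.name, 0, len(seq), {"count": int(n_err)})
        )

    # (4) fragmentation
    full = "".join(seq)
    if profile.fragment_break_rate > 0:
        n_breaks = rng.poisson(profile.fragment_break_rate * len(full) / 1e6)
        breaks = sorted(
            int(b) for b in rng.choice(len(full), size=min(n_breaks, len(full) - 1), replace=False)
        )
    else:
        breaks = []
    bounds = [0] + [b for b in breaks if 0 < b < len(full)] + [len(full)]
    records = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        cname = record.name if len(bounds) == 2 else f"{record.name}_c{i}"
        records.append(SequenceRecord(cname, full[lo:hi]))
        if len(bounds) > 2:
            edits.append(Edit("break", record.name, lo, hi, {"contig": cname}))

    if len(bounds) > 2:
        def remap(iv: Interval) -> tuple[Interval | None, bool]:
            for i in range(len(bounds) - 1):
                lo, hi = bounds[i], bounds[i + 1]
                if lo <= iv.start < hi:
                    cname = f"{record.name}_c{i}"
                    if iv.end <= hi:
                        return Interval(cname, iv.start - lo, iv.end - lo, iv.strand), False
                    return None, True
            return None, True

        for e in elements:
            if e.collapsed:
                continue
            new_iv, broken = remap(e.interval)
            if broken or any(remap(iv)[1] for iv in e.ltr_intervals):
                e.broken = True
                continue
            e.interval = new_iv
            e.ltr_intervals = tuple(remap(iv)[0] for iv in e.ltr_intervals)
            tsds = [remap(iv) for iv in e.tsd_intervals]
            if any(b for _, b in tsds):
                e.broken = True
                continue
            e.tsd_intervals = tuple(iv for iv, _ in tsds)
            e.domains = [
                DomainAnnotation(d.kind, remap(d.interval)[0], d.strand)
                for d in e.domains
                if not remap(d.interval)[1]
            ]
        kept_genes = []
        for g in genes:
            new_iv, broken = remap(g.interval)
            if not broken:
                kept_genes.append(GeneModel(g.id, new_iv, g.sequence))
        genes = kept_genes

    return Assembly(records), SimTruth(elements, genes, edits, truth.consensus)


# ---------------------------------------------------------------------------
# Truth emission
# ---------------------------------------------------------------------------


def truth_to_gff3(truth: SimTruth, source: str = "retrobench-sim") -> list[Gff3Feature]:
    feats: list[Gff3Feature] = []
    for e in truth.elements:
        if e.collapsed:
            continue
        etype = "solo_LTR" if e.is_solo else "LTR_retrotransposon"
        feats.append(
            Gff3Feature(
                e.interval.seq_name,
                source,
                etype,
                e.interval.start,
                e.interval.end,
                strand=e.interval.strand,
                attributes={
                    "ID": e.id,
                    "family": e.family,
                    "age_years": f"{e.age_years:.0f}",
                    "tsd": e.tsd_seq,
                },
            )
        )
        for i, ltr in enumerate(e.ltr_intervals):
            feats.append(
                Gff3Feature(
                    ltr.seq_name, source, "long_terminal_repeat",
                    ltr.start, ltr.end, strand=ltr.strand,
                    attributes={"ID": f"{e.id}_ltr{i}", "Parent": e.id},
                )
            )
        for i, tsd in enumerate(e.tsd_intervals):
            feats.append(
                Gff3Feature(
                    tsd.seq_name, source, "target_site_duplication",
                    tsd.start, tsd.end,
                    attributes={"ID": f"{e.id}_tsd{i}", "Parent": e.id},
                )
            )
    for g in truth.genes:
        feats.append(
            Gff3Feature(
                g.interval.seq_name, source, "gene",
                g.interval.start, g.interval.end, strand=g.interval.strand,
                attributes={"ID": g.id},
            )
        )
    return feats


def domains_to_tsv(truth: SimTruth, path) -> None:
    """Emit planted protein-domain annotations as TSV for the annotator."""
    with open(path, "w") as fh:
        fh.write("seq_name\tstart\tend\tstrand\tkind\n")
        for e in truth.elements:
            if e.collapsed:
                continue
            for d in e.domains:
                fh.write(
                    f"{d.interval.seq_name}\t{d.interval.start}\t{d.interval.end}"
                    f"\t{d.strand}\t{d.kind}\n"
                )
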