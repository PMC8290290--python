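"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately re-derive expected results by enumeration or direct
restatement, never by calling the code paths they check.
"""

from retrobench.assembly_benchmarks import score_matching


def exhaustive_best_matching(query_sites, ref_sites, params):
    """Enumerate all non-empty monotone matchings; return the best score."""
    nq, nr = len(query_sites), len(ref_sites)
    best = None

    def recurse(qi, ri, chain):
        nonlocal best
        if chain:
            s = score_matching(query_sites, ref_sites, chain, params)
            if best is None or s > best:
                best = s
        for i in range(qi, nq):
            for j in range(ri, nr):
                recurse(i + 1, j + 1, chain + [(i, j)])

    recurse(0, 0, [])
    return best


def scaffold_oracle(m):
    """Independent restatement of the scaffold retention rule."""
    if m.chromosome_assigned:
        return True
    return (
        m.length >= 50_000
        and not m.bubble
        and (m.read_coverage >= 10 or m.has_unique_genes)
    )


def gene_oracle(r):
    """Independent restatement of the gene-confidence rules."""

    def ok(h):
        return h is not None and h.e_value < 1e-10

    mag = r.unimag if ok(r.unimag) else None
    poa = r.unipoa if ok(r.unipoa) else None
    rep = r.ptrep if ok(r.ptrep) else None
    if r.complete and mag and mag.query_cov >= 80 and mag.subject_cov >= 80:
        d = "HC"
    elif r.complete and mag is None and poa and rep is None:
        d = "HC"
    elif not r.complete and (mag or poa) and rep is None:
        d = "LC"
    elif mag is None and poa is None and rep is None and r.complete:
        d = "LC"
    elif mag is None and r.complete and rep:
        d = "REP"
    else:
        d = "UNCLASSIFIED"
    if d == "LC" and r.ahrd_stars == 3:
        d = "HC"
    elif d == "HC" and r.ahrd_stars == 1:
        d = "LC"
    return d
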