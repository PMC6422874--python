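"""Independent brute-force oracles used across the test suite.

These deliberately avoid the implementation's algorithms: local alignment
is scored by exhaustive enumeration over monotone matchings, peptide
matching by a per-entry substring scan.
"""

from itertools import combinations


def brute_force_local_score(
    q: str, s: str, match: int = 2, mismatch: int = -3,
    gap_open: int = -5, gap_extend: int = -2,
) -> int:
    """Optimal local alignment score by enumerating all monotone matchings.

    Every local alignment is a non-empty set of aligned position pairs
    (i1<i2<...<ik, j1<...<jk); interior runs of skipped positions are gaps
    costing open + extend*length on each sequence independently; flanks are
    free.  Feasible for sequences up to ~8 nt.
    """
    n, m = len(q), len(s)
    best = 0
    for k in range(1, min(n, m) + 1):
        for qi in combinations(range(n), k):
            for sj in combinations(range(m), k):
                score = 0
                for t in range(k):
                    a, b = q[qi[t]], s[sj[t]]
                    score += match if (a == b and a in "ACGT") else mismatch
                    if t:
                        gq = qi[t] - qi[t - 1] - 1
                        gs = sj[t] - sj[t - 1] - 1
                        if gq:
                            score += gap_open + gap_extend * gq
                        if gs:
                            score += gap_open + gap_extend * gs
                if score > best:
                    best = score
    return best


def naive_peptide_scan(peptide: str, entries) -> set[str]:
    """Match a peptide by scanning every entry with the `in` operator."""
    pep = peptide.upper()
    return {
        e.entry_id for e in entries if pep in e.protein_fragment.upper()
    }
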