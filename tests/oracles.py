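"""Independent brute-force oracles used by the test-suite.

These re-derive expected results by enumeration or exhaustive scanning,
sharing no code path with the implementations they check.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# alignment: exhaustive enumeration of all global alignments
# ---------------------------------------------------------------------------

def score_gapped(aligned_a: str, aligned_b: str, score_fn,
                 gap_open: float, gap_extend: float,
                 free_end_gaps: bool) -> float:
    """Score an explicit alignment: affine gaps (gap of length L costs
    open + L*extend), end gaps free when requested.  Independent of the
    package's scorer."""
    total = 0.0
    for s in (aligned_a, aligned_b):
        runs = []
        start = None
        for i, c in enumerate(s):
            if c == "-" and start is None:
                start = i
            elif c != "-" and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(s)))
        for a, b in runs:
            if free_end_gaps and (a == 0 or b == len(s)):
                continue
            total -= gap_open + (b - a) * gap_extend
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            total += score_fn(x, y)
    return total


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment (as a pair of gapped strings) of two
    short sequences; column count equals len(a)+len(b)-matches."""
    def rec(i, j, col_a, col_b):
        if i == len(a) and j == len(b):
            yield "".join(col_a), "".join(col_b)
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, col_a + [a[i]], col_b + [b[j]])
        if i < len(a):
            yield from rec(i + 1, j, col_a + [a[i]], col_b + ["-"])
        if j < len(b):
            yield from rec(i, j + 1, col_a + ["-"], col_b + [b[j]])
    yield from rec(0, 0, [], [])


def best_alignment_score(a: str, b: str, score_fn, gap_open: float,
                         gap_extend: float, free_end_gaps: bool) -> float:
    return max(
        score_gapped(x, y, score_fn, gap_open, gap_extend, free_end_gaps)
        for x, y in enumerate_alignments(a, b)
    )


# ---------------------------------------------------------------------------
# embedded antisense ORFs: six-frame scan + containment filter
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def sixframe_embedded_orfs(contig: str, features, codon_to_aa,
                           start_codons, min_codons: int):
    """All antisense embedded ORFs by brute force.

    For each host CDS and each of the three frames on the opposite strand,
    enumerate every start->stop span fully contained in the host span and
    keep, per (host, stop), the longest.  Returns a set of
    (start, end, strand, protein) genomic tuples.
    """
    stops = {c for c, aa in codon_to_aa.items() if aa == "*"}
    strands = {"+": contig, "-": _revcomp(contig)}
    n = len(contig)

    def genomic(strand: str, p0: int, p1: int) -> tuple[int, int]:
        """0-based [p0, p1) on the strand sequence -> 1-based genomic."""
        if strand == "+":
            return p0 + 1, p1
        return n - p1 + 1, n - p0

    out = set()
    for host in features:
        if host.kind != "CDS":
            continue
        anti = "-" if host.strand == "+" else "+"
        seq = strands[anti]
        per_stop: dict[int, tuple] = {}
        for frame in range(3):
            for s0 in range(frame, len(seq) - 2, 3):
                if seq[s0:s0 + 3] not in start_codons:
                    continue
                for e0 in range(s0 + 3, len(seq) - 2, 3):
                    codon = seq[e0:e0 + 3]
                    if codon in stops:
                        if (e0 - s0) // 3 >= min_codons:
                            g_start, g_end = genomic(anti, s0, e0 + 3)
                            if host.start <= g_start and g_end <= host.end:
                                prev = per_stop.get(e0)
                                if prev is None or s0 < prev[0]:
                                    per_stop[e0] = (s0, g_start, g_end)
                        break
        for e0, (s0, g_start, g_end) in per_stop.items():
            nt = seq[s0:e0]
            protein = "".join(codon_to_aa[nt[i:i + 3]]
                              for i in range(0, len(nt), 3))
            out.add((g_start, g_end, anti, protein))
    return out
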