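"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive re-derivations — a Gotoh affine-gap DP
written from the recurrences, a frame-scan ORF enumerator, and an
adjacency enumerator for signed permutations — sharing no code with the
package paths they check.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_NEG = float("-inf")


def gotoh_score(
    query: str,
    target: str,
    mode: str = "local",
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal affine-gap alignment score by explicit three-state DP.

    The first residue of a gap costs ``gap_open``, every further residue
    ``gap_extend`` (same convention as the package aligner). ``local``
    gives Smith-Waterman (floor 0), ``global`` Needleman-Wunsch with end
    gaps penalized.
    """
    mat = substitution_matrices.load(matrix_name)
    n, m = len(query), len(target)
    local = mode == "local"
    # M: last column aligns query[i-1] with target[j-1]
    # X: gap in target (query residue consumed), Y: gap in query
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    best = 0.0 if local else _NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(mat[query[i - 1], target[j - 1]])
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = diag + s
            if local:
                M[i][j] = max(M[i][j], s)
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open,
            )
            if local:
                best = max(best, M[i][j])
    if local:
        return best
    return max(M[n][m], X[n][m], Y[n][m])


GENETIC_CODE_11 = None


def _codon_table():
    global GENETIC_CODE_11
    if GENETIC_CODE_11 is None:
        from Bio.Data import CodonTable

        t = CodonTable.unambiguous_dna_by_id[11]
        table = dict(t.forward_table)
        for stop in t.stop_codons:
            table[stop] = "*"
        GENETIC_CODE_11 = table
    return GENETIC_CODE_11


_COMP = str.maketrans("ACGT", "TGCA")


def brute_orfs(seq: str, min_aa: int) -> set[tuple[int, int, int, str]]:
    """Naive frame scan: every stop-free codon run of >= min_aa in all six
    frames, reported as (start, end, frame, protein) on the forward strand."""
    table = _codon_table()
    out = set()
    n = len(seq)
    rc = seq.translate(_COMP)[::-1]
    for sign, s in ((1, seq), (-1, rc)):
        for offset in range(3):
            frame = sign * (offset + 1)
            codons = [
                s[k : k + 3] for k in range(offset, len(s) - 2, 3)
            ]
            run: list[str] = []
            run_start = offset
            pos = offset
            for codon in codons + ["TAA"]:
                aa = table.get(codon, "X") if len(codon) == 3 else "*"
                if aa == "*":
                    if len(run) >= min_aa:
                        a, b = run_start, run_start + 3 * len(run)
                        if sign == 1:
                            out.add((a, b, frame, "".join(run)))
                        else:
                            out.add((n - b, n - a, frame, "".join(run)))
                    run = []
                    run_start = pos + 3
                else:
                    run.append(aa)
                pos += 3
    return out


def brute_breakpoints(order_a: list[int], order_b: list[int]) -> int:
    """Count adjacencies of ``order_a`` not conserved in ``order_b`` by
    scanning every neighboring pair of ``order_b`` in both reading
    directions."""
    count = 0
    pairs_b = list(zip(order_b, order_b[1:]))
    for x, y in zip(order_a, order_a[1:]):
        conserved = False
        for u, v in pairs_b:
            if (u, v) == (x, y) or (u, v) == (-y, -x):
                conserved = True
                break
        if not conserved:
            count += 1
    return count
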