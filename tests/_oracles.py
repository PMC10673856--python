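"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method available
(exhaustive DP, regex, grid scan, naive window enumeration, codon-table
lookup) and share no code with the implementation paths they check.
"""

from __future__ import annotations

import re

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NEG_INF = float("-inf")


def affine_dp_score(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                    gap_open: float = -8.0, gap_extend: float = -1.0) -> float:
    """Exhaustive Gotoh global alignment score.

    A gap of length L costs gap_open + (L-1)*gap_extend; end gaps are
    penalised the same as internal gaps.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


_EXACT4_RE = re.compile(r"[^C]*C[^C]{5}C[^C]+C[^C]{4}C[^C]*\Z")
_ANY_RE = re.compile(r"(?=C.{5}C.+C.{4}C)", re.DOTALL)


def motif_regex_match(peptide: str, require_exact_four_cys: bool = True):
    """(matched, cys_positions or None) by regular expression.

    In exact-four mode the positions are forced to be the four cysteines.
    """
    if require_exact_four_cys:
        if peptide.count("C") != 4:
            return False, None
        if _EXACT4_RE.match(peptide):
            return True, tuple(i + 1 for i, aa in enumerate(peptide) if aa == "C")
        return False, None
    return bool(_ANY_RE.search(peptide)), None


def grid_pI(peptide: str, pka_table: dict, step: float = 1e-4) -> float:
    """pH-grid scan for the isoelectric point (argmin |net charge|)."""
    side = pka_table["side_chains"]
    pH = np.arange(0.0, 14.0 + step, step)
    q = 1.0 / (1.0 + 10.0 ** (pH - pka_table["n_term"]))
    q -= 1.0 / (1.0 + 10.0 ** (pka_table["c_term"] - pH))
    for aa in "KRH":
        n = peptide.count(aa)
        if n and aa in side:
            q += n / (1.0 + 10.0 ** (pH - side[aa]))
    for aa in "DECY":
        n = peptide.count(aa)
        if n and aa in side:
            q -= n / (1.0 + 10.0 ** (side[aa] - pH))
    return float(pH[int(np.argmin(np.abs(q)))])


_RC = str.maketrans("ACGT", "TGCA")


def brute_protospacers(seq: str) -> set[tuple[str, str, str, int]]:
    """All (protospacer, pam, strand, plus-strand start) by naive window scan."""
    out = set()
    rc = seq.translate(_RC)[::-1]
    n = len(seq)
    for s, strand in ((seq, "+"), (rc, "-")):
        for i in range(len(s) - 22):
            window = s[i:i + 23]
            if window[21] == "G" and window[22] == "G":
                if strand == "+":
                    start = i
                else:
                    start = n - (i + 20)
                out.add((window[:20], window[20:], strand, start))
    return out


def brute_offtarget_min(protospacer: str, genome: dict[str, str],
                        exclude: tuple[str, int, str] | None) -> float:
    best = float("inf")
    for name, contig in genome.items():
        for ps, pam, strand, start in brute_protospacers(contig):
            if exclude is not None and (name, start, strand) == exclude:
                continue
            d = sum(x != y for x, y in zip(protospacer, ps))
            best = min(best, d)
    return best


def codon_translate(cds: str) -> str:
    """Translate an in-frame CDS to its first stop using the standard table."""
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    prot = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if codon in stops:
            break
        prot.append(table[codon])
    return "".join(prot)
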