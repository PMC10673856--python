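"""SpCas9 guide-site enumeration, placement constraints and off-target search.

Protospacers are 20-mers adjacent to an NGG PAM on either strand.  The blunt
Cas9 cut falls between protospacer positions 17 and 18 (3 bp 5' of the PAM).
Candidates are ranked by the constraints the construct design imposes:

* the cut must fall strictly upstream of the codon of the fourth conserved
  cysteine, so that the edit disrupts the cysteines essential for peptide
  function (failing candidates are retained but flagged);
* a 5'-G protospacer is preferred over 5'-A over anything else, because the
  U6 promoter driving the sgRNA initiates transcription most efficiently on
  G (a 5'-C was observed to all but abolish editing);
* among equals, cuts closer to the start of the mature peptide rank first.

Off-target safety is a minimum-Hamming-distance scan over every NGG-adjacent
20-mer in a reference genome, with the rule that a guide is acceptable only
when every off-target site differs by at least two mismatches.

Coordinates are 0-based half-open internally; reverse-strand candidates are
reported in plus-strand coordinates.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InputError

DNA = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - DNA
    if bad:
        raise InputError(f"{what} contains ambiguous/invalid bases: {sorted(bad)!r}")


PROTOSPACER_LEN = 20
PAM_LEN = 3
#: offset of the blunt cut from the protospacer start on the protospacer strand
CUT_OFFSET = 17


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer+PAM site.

    ``start`` is the 0-based plus-strand offset of the protospacer's leftmost
    base; ``cut_site`` the 0-based plus-strand position immediately 3' of the
    blunt cut (cut between ``cut_site - 1`` and ``cut_site``).  On the plus
    strand ``cut_site = start + 17``; on the minus strand ``start + 3``.
    """

    protospacer: str
    pam: str
    strand: str
    start: int
    cut_site: int
    five_prime_class: str | None = None
    upstream_of_cys4: bool | None = None
    distance_to_mature: int | None = None
    rank: int | None = None
    min_offtarget_mismatches: float | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise InputError("protospacer must be exactly 20 bases")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise InputError(f"PAM {self.pam!r} does not match NGG")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-level coordinates needed to place a guide.

    ``cys4_codon_start`` is the 0-based offset of the first base of the
    fourth conserved cysteine's codon.  ``mature_start`` (0-based offset of
    the first mature-peptide codon) anchors the distance used for ranking;
    when absent it defaults to the start of the first CDS interval.
    """

    gene_sequence: str
    cds_intervals: tuple[tuple[int, int], ...]
    cys4_codon_start: int
    mature_start: int | None = None

    def __post_init__(self) -> None:
        _check_dna(self.gene_sequence, "gene sequence")
        ivals = sorted(self.cds_intervals)
        for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
            if b1 > a2:
                raise InputError("cds_intervals overlap")
        if not any(a <= self.cys4_codon_start < b for a, b in self.cds_intervals):
            raise InputError("cys4_codon_start not inside any CDS interval")

    @property
    def anchor(self) -> int:
        if self.mature_start is not None:
            return self.mature_start
        return min(a for a, _ in self.cds_intervals)


def enumerate_protospacers(gene_sequence: str) -> list[GuideCandidate]:
    """Enumerate every NGG-adjacent 20-mer on both strands.

    Returns candidates sorted by (start, strand); constraint fields are left
    unevaluated.
    """
    _check_dna(gene_sequence)
    if len(gene_sequence) < PROTOSPACER_LEN + PAM_LEN:
        raise InputError("sequence shorter than protospacer + PAM (23 bases)")
    seq = gene_sequence
    n = len(seq)
    out: list[GuideCandidate] = []
    for i in range(n - 22):
        # plus strand: protospacer [i, i+20), PAM [i+20, i+23) = NGG
        if seq[i + 21] == "G" and seq[i + 22] == "G":
            out.append(GuideCandidate(
                protospacer=seq[i:i + 20], pam=seq[i + 20:i + 23],
                strand="+", start=i, cut_site=i + CUT_OFFSET,
            ))
        # minus strand: plus-strand layout CCN + 20-mer over [i, i+23)
        if seq[i] == "C" and seq[i + 1] == "C":
            out.append(GuideCandidate(
                protospacer=revcomp(seq[i + 3:i + 23]), pam=revcomp(seq[i:i + 3]),
                strand="-", start=i + 3, cut_site=i + 3 + (PROTOSPACER_LEN - CUT_OFFSET),
            ))
    out.sort(key=lambda c: (c.start, c.strand))
    return out


_FIVE_PRIME_RANK = {"G": 0, "A": 1, "other": 2}


def _five_prime_class(protospacer: str) -> str:
    base = protospacer[0]
    return base if base in ("G", "A") else "other"


def apply_constraints(
    candidates: Sequence[GuideCandidate],
    annot: GeneAnnotation,
) -> list[GuideCandidate]:
    """Evaluate placement/5'-base constraints and rank candidates.

    Ranking order: upstream-of-Cys4 first, then 5' base G > A > other, then
    ascending distance of the cut to the mature-peptide start; ties broken by
    ascending start coordinate then strand, making the order total.
    Candidates whose cut is not upstream of the fourth-cysteine codon are
    retained but flagged.  ``upstream_of_cys4`` uses the strict inequality
    ``cut_site < cys4_codon_start``.
    """
    seq = annot.gene_sequence
    evaluated = []
    for c in candidates:
        # verify the candidate actually derives from this gene sequence
        if c.strand == "+":
            site = seq[c.start:c.start + 20]
        else:
            site = revcomp(seq[c.start:c.start + 20])
        if site != c.protospacer:
            raise InputError(
                f"candidate at {c.start}{c.strand} does not match the annotated gene sequence"
            )
        evaluated.append(dataclasses.replace(
            c,
            upstream_of_cys4=c.cut_site < annot.cys4_codon_start,
            five_prime_class=_five_prime_class(c.protospacer),
            distance_to_mature=abs(c.cut_site - annot.anchor),
        ))
    evaluated.sort(key=lambda c: (
        not c.upstream_of_cys4,
        _FIVE_PRIME_RANK[c.five_prime_class],
        c.distance_to_mature,
        c.start,
        c.strand,
    ))
    return [dataclasses.replace(c, rank=i + 1) for i, c in enumerate(evaluated)]


def _pam_sites(contig: str) -> Iterable[tuple[int, str, str]]:
    """Yield (start, strand, protospacer) for every NGG-adjacent 20-mer."""
    n = len(contig)
    for i in range(n - 22):
        if contig[i + 21] == "G" and contig[i + 22] == "G":
            yield i, "+", contig[i:i + 20]
        if contig[i] == "C" and contig[i + 1] == "C":
            yield i + 3, "-", revcomp(contig[i + 3:i + 23])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def min_offtarget_mismatches(
    protospacer: str,
    genome: Mapping[str, str],
    target_locus: tuple[str, int, str] | None = None,
) -> float:
    """Minimum Hamming distance to any PAM-adjacent genomic site.

    ``genome`` maps contig names to plus-strand sequences; ``target_locus``
    is (contig, protospacer start, strand) of the on-target site, which is
    excluded from the scan.  Returns ``math.inf`` when the genome contains no
    other NGG-adjacent site.  Only NGG PAMs are scanned and only mismatches
    (no bulges) are counted.
    """
    if len(protospacer) != PROTOSPACER_LEN:
        raise InputError("protospacer must be exactly 20 bases")
    _check_dna(protospacer, "protospacer")
    best = math.inf
    for name, contig in genome.items():
        _check_dna(contig, f"contig {name!r}")
        if len(contig) < 23:
            continue
        for start, strand, site in _pam_sites(contig):
            if target_locus is not None and (name, start, strand) == target_locus:
                continue
            d = _hamming(protospacer, site)
            if d < best:
                best = d
                if best == 0:
                    return 0
    return best


def meets_offtarget_rule(min_mismatches: float, required: int = 2) -> bool:
    """Acceptance predicate: every off-target site differs by >= ``required``
    mismatches (a site-free genome trivially passes)."""
    return min_mismatches >= required
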