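"""Per-nodule amplicon genotyping: allele calling, classification, consequences.

Hairy-root transformation produces chimeric tissue, so every nodule is
genotyped separately: its ~200 bp amplicon reads are aligned to the
reference, collapsed into edit-signature alleles within a quantification
window around the Cas9 cut site, and the nodule is classified by its
wild-type read fraction:

* ``wild_type`` — mostly WT reads, no mutant allele above the reporting floor
* ``heterozygous_chimeric`` — WT majority plus at least one mutant allele
* ``mutant_majority`` — WT fraction at or below 50%
* ``fully_mutant_indel_only`` / ``fully_mutant_with_mismatch`` — WT fraction
  at or below a small ceiling (default 5%), split by whether every retained
  mutant allele is an indel or some carry only substitutions

Protein consequences (frameshift, chimeric C-terminus, premature stop, loss
of conserved cysteines, in-frame residue deletions) are predicted by
translating the edited CDS.  ``summarize_editing`` emits the per-construct
editing-efficiency table (nodules sequenced, nodules at or below 50% WT,
fully mutant counts, percent of nodules carrying only indel alleles).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .errors import DegenerateInputError, InputError

# ---------------------------------------------------------------------------
# Reference and alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconRef:
    """Amplicon reference with the Cas9 cut site and quantification window.

    ``cut_site`` is the 0-based position immediately 3' of the blunt cut.
    Edits are attributed to an allele only when they intersect
    ``cut_site ± quantification_window`` (positions, inclusive).
    """

    sequence: str
    cut_site: int
    quantification_window: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.cut_site < len(self.sequence):
            raise InputError("cut_site outside the amplicon")
        if (self.cut_site - self.quantification_window < 0
                or self.cut_site + self.quantification_window >= len(self.sequence)):
            raise InputError("quantification window extends beyond the amplicon")


#: Default global affine-gap scoring (a gap of length L costs open+(L-1)*extend).
DEFAULT_SCORING = {"match": 2.0, "mismatch": -3.0, "gap_open": -8.0, "gap_extend": -1.0}

MIN_IDENTITY = 0.60


def _make_aligner(scoring: Mapping[str, float]) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    aligner.open_gap_score = scoring["gap_open"]
    aligner.extend_gap_score = scoring["gap_extend"]
    return aligner


_DEFAULT_ALIGNER = _make_aligner(DEFAULT_SCORING)


@dataclass(frozen=True)
class ReadAlignment:
    """A global alignment of one read to the amplicon reference."""

    ref_aligned: str
    read_aligned: str
    score: float
    identity: float
    discard: bool


def _finish(ref_aln: str, read_aln: str, score: float) -> ReadAlignment:
    matches = sum(a == b for a, b in zip(ref_aln, read_aln) if a != "-")
    identity = matches / len(ref_aln) if ref_aln else 0.0
    return ReadAlignment(ref_aln, read_aln, score, identity, identity < MIN_IDENTITY)


def align_read(
    read: str,
    ref: AmpliconRef,
    scoring: Mapping[str, float] | None = None,
) -> ReadAlignment:
    """Globally align a read to the amplicon (affine gaps).

    Reads with < 60% identity over the alignment are flagged ``discard``.
    For equal-length reads with at most three substitutions the gapless
    alignment is provably optimal under the default scoring (any gapped
    alignment of equal-length sequences opens at least two gap runs, costing
    more than three mismatches), so it is returned directly.
    """
    if not read:
        raise InputError("empty read")
    bad = set(read) - set("ACGTN")
    if bad:
        raise InputError(f"read contains invalid characters: {sorted(bad)!r}")

    if scoring is None:
        scoring = DEFAULT_SCORING
        aligner = _DEFAULT_ALIGNER
        if len(read) == len(ref.sequence):
            mm = sum(a != b for a, b in zip(ref.sequence, read))
            if mm <= 3:
                score = (scoring["match"] * (len(read) - mm)
                         + scoring["mismatch"] * mm)
                return _finish(ref.sequence, read, score)
    else:
        aligner = _make_aligner(scoring)

    result = aligner.align(ref.sequence, read)
    aln = result[0]
    return _finish(str(aln[0]), str(aln[1]), result.score)


# ---------------------------------------------------------------------------
# Edit signatures
# ---------------------------------------------------------------------------

Op = tuple[str, int, int, str]  # (kind, ref_offset from cut, length, bases)


@dataclass(frozen=True)
class EditSignature:
    """The in-window edits of one allele, relative to the cut site.

    ``ops`` are (kind, ref_offset, length, bases) with kind in
    {'del','ins','sub'}; offsets are ref positions minus cut_site (for an
    insertion, the ref position before which the bases are inserted).
    """

    ops: tuple[Op, ...] = ()

    @property
    def is_wt(self) -> bool:
        return not self.ops

    @property
    def net_indel(self) -> int:
        return (sum(o[2] for o in self.ops if o[0] == "ins")
                - sum(o[2] for o in self.ops if o[0] == "del"))

    @property
    def classification(self) -> str:
        if not self.ops:
            return "WT"
        if any(o[0] in ("del", "ins") for o in self.ops):
            return "indel"
        return "mismatch_only"

    def __str__(self) -> str:
        if not self.ops:
            return "WT"
        parts = []
        for kind, off, length, bases in self.ops:
            tag = f"{kind}{length}@{off:+d}"
            if bases:
                tag += f":{bases}"
            parts.append(tag)
        return ";".join(parts)


WT_SIGNATURE = EditSignature()


def call_allele(alignment: ReadAlignment, ref: AmpliconRef) -> EditSignature:
    """Reduce an alignment to its edit signature within the quantification
    window.

    Adjacent same-kind operations are merged; operations wholly outside
    ``cut_site ± quantification_window`` are treated as sequencing noise and
    dropped, so reads differing only far from the cut collapse to the same
    allele.
    """
    raw: list[list] = []  # [kind, ref_start, length, bases]
    r = 0
    for a, b in zip(alignment.ref_aligned, alignment.read_aligned):
        if a == "-":
            if raw and raw[-1][0] == "ins" and raw[-1][1] == r:
                raw[-1][2] += 1
                raw[-1][3] += b
            else:
                raw.append(["ins", r, 1, b])
        elif b == "-":
            if raw and raw[-1][0] == "del" and raw[-1][1] + raw[-1][2] == r:
                raw[-1][2] += 1
            else:
                raw.append(["del", r, 1, ""])
            r += 1
        else:
            if a != b:
                if raw and raw[-1][0] == "sub" and raw[-1][1] + raw[-1][2] == r:
                    raw[-1][2] += 1
                    raw[-1][3] += b
                else:
                    raw.append(["sub", r, 1, b])
            r += 1

    lo = ref.cut_site - ref.quantification_window
    hi = ref.cut_site + ref.quantification_window
    ops: list[Op] = []
    for kind, start, length, bases in raw:
        if kind == "ins":
            inside = lo <= start <= hi
        else:
            inside = start <= hi and start + length - 1 >= lo
        if inside:
            ops.append((kind, start - ref.cut_site, length, bases))
    return EditSignature(tuple(ops))


# ---------------------------------------------------------------------------
# Allele tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationThresholds:
    """Thresholds for nodule classification.

    ``wt_max_for_mutant_majority``: nodules at or below this WT fraction
    count as mutant-majority ("max. 50% WT allele").
    ``wt_max_for_fully_mutant``: ceiling of WT reads still compatible with a
    fully mutant nodule (trace contamination allowance).
    ``min_allele_frequency``: signatures below this raw frequency are pooled
    into an "other" row that never participates in classification.
    """

    wt_max_for_mutant_majority: float = 0.50
    wt_max_for_fully_mutant: float = 0.05
    min_allele_frequency: float = 0.01

    def __post_init__(self) -> None:
        if self.wt_max_for_fully_mutant > self.wt_max_for_mutant_majority:
            raise InputError("fully-mutant ceiling must be <= mutant-majority ceiling")


@dataclass(frozen=True)
class AlleleRow:
    signature: EditSignature
    reads: int
    frequency: float


@dataclass(frozen=True)
class AlleleTable:
    """Collapsed edit signatures of one nodule.

    ``rows`` hold the named alleles (raw frequency >= min_allele_frequency),
    sorted by frequency descending then signature; their ``frequency`` values
    are normalised over named rows and sum to 1.  ``other_reads`` pools
    sub-threshold signatures (counted in ``total_reads``, excluded from
    classification and from the normalisation).
    """

    nodule_id: str
    rows: tuple[AlleleRow, ...]
    total_reads: int
    discarded_reads: int
    other_reads: int = 0

    @property
    def wt_fraction(self) -> float:
        for row in self.rows:
            if row.signature.is_wt:
                return row.frequency
        return 0.0

    def to_frame(self) -> pd.DataFrame:
        recs = [{"allele": str(r.signature), "classification": r.signature.classification,
                 "net_indel": r.signature.net_indel, "reads": r.reads,
                 "frequency": r.frequency} for r in self.rows]
        if self.other_reads:
            recs.append({"allele": "other", "classification": "other",
                         "net_indel": 0, "reads": self.other_reads,
                         "frequency": float("nan")})
        return pd.DataFrame(recs)


def build_allele_table(
    reads: Iterable[str],
    ref: AmpliconRef,
    thresholds: ClassificationThresholds | None = None,
    nodule_id: str = "",
) -> AlleleTable:
    """Align reads, collapse identical signatures, and build the allele table.

    Reads are de-duplicated before alignment (identical sequences share one
    alignment).  Low-identity reads (< 60%) are discarded but counted.
    """
    thresholds = thresholds or ClassificationThresholds()
    counts = Counter(reads)
    n_input = sum(counts.values())
    if n_input == 0:
        raise DegenerateInputError("no reads supplied")

    sig_counts: Counter[EditSignature] = Counter()
    discarded = 0
    for seq, n in counts.items():
        aln = align_read(seq, ref)
        if aln.discard:
            discarded += n
            continue
        sig_counts[call_allele(aln, ref)] += n

    retained = sum(sig_counts.values())
    if retained == 0:
        raise DegenerateInputError("all reads were discarded")

    named = {s: n for s, n in sig_counts.items()
             if n / retained >= thresholds.min_allele_frequency}
    other = retained - sum(named.values())
    if not named:
        raise DegenerateInputError("no allele reaches min_allele_frequency")
    named_total = sum(named.values())
    rows = tuple(sorted(
        (AlleleRow(s, n, n / named_total) for s, n in named.items()),
        key=lambda r: (-r.frequency, str(r.signature)),
    ))
    return AlleleTable(nodule_id=nodule_id, rows=rows, total_reads=retained,
                       discarded_reads=discarded, other_reads=other)


# ---------------------------------------------------------------------------
# Nodule classification
# ---------------------------------------------------------------------------

GENOTYPE_CLASSES = (
    "wild_type",
    "heterozygous_chimeric",
    "mutant_majority",
    "fully_mutant_indel_only",
    "fully_mutant_with_mismatch",
)

PHENOTYPE_LABELS = ("pink_elongated", "white_undeveloped", "unscored")


@dataclass(frozen=True)
class NoduleGenotype:
    nodule_id: str
    genotype_class: str
    wt_fraction: float
    n_alleles: int
    phenotype_label: str = "unscored"
    construct: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def classify_nodule(
    table: AlleleTable,
    thresholds: ClassificationThresholds | None = None,
    phenotype_label: str = "unscored",
    construct: str = "",
) -> NoduleGenotype:
    """Classify one nodule from its allele table.

    Thresholds are applied to the WT fraction over named alleles; the pooled
    "other" row never influences the class.
    """
    thresholds = thresholds or ClassificationThresholds()
    if phenotype_label not in PHENOTYPE_LABELS:
        raise InputError(f"unknown phenotype label {phenotype_label!r}")
    wt = table.wt_fraction
    mutants = [r for r in table.rows if not r.signature.is_wt]
    if wt <= thresholds.wt_max_for_fully_mutant:
        if all(r.signature.classification == "indel" for r in mutants):
            cls = "fully_mutant_indel_only"
        else:
            cls = "fully_mutant_with_mismatch"
    elif wt <= thresholds.wt_max_for_mutant_majority:
        cls = "mutant_majority"
    elif mutants:
        cls = "heterozygous_chimeric"
    else:
        cls = "wild_type"
    return NoduleGenotype(
        nodule_id=table.nodule_id, genotype_class=cls, wt_fraction=wt,
        n_alleles=len(table.rows), phenotype_label=phenotype_label,
        construct=construct,
    )


# ---------------------------------------------------------------------------
# Protein consequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinAnnotation:
    """Maps the amplicon edit coordinates into the protein.

    ``cut_site_in_cds``: 0-based offset of the cut site within the in-frame
    CDS.  ``signal_peptide_length``: number of signal-peptide residues (0 if
    none); mature-peptide positions are reported relative to the residue
    after the signal peptide.  ``conserved_cys``: 1-based residue indices of
    the four motif cysteines in the full peptide.
    """

    cut_site_in_cds: int
    signal_peptide_length: int = 0
    conserved_cys: tuple[int, ...] = ()


@dataclass(frozen=True)
class ConsequenceReport:
    frameshift: bool
    start_lost: bool
    identical_residues_before_divergence: int
    novel_residues_before_stop: int
    stop_position: int | None
    lost_conserved_cys: tuple[int, ...]
    inframe_deleted_residues: tuple[tuple[int, str], ...]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _translate_to_stop(cds: str) -> tuple[str, bool]:
    """Translate an in-frame CDS up to (not including) the first stop.

    Returns (protein, stop_found); trailing partial codons are ignored.
    """
    trimmed = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(trimmed).translate())
    stop = prot.find("*")
    if stop >= 0:
        return prot[:stop], True
    return prot, False


def apply_signature(cds: str, signature: EditSignature, cut_site_in_cds: int) -> str:
    """Apply a cut-site-relative edit signature to a CDS string."""
    ops = sorted(signature.ops, key=lambda o: o[1], reverse=True)
    s = cds
    for kind, off, length, bases in ops:
        p = cut_site_in_cds + off
        if kind == "ins":
            if not 0 <= p <= len(s):
                raise InputError("insertion point outside the CDS")
            s = s[:p] + bases + s[p:]
        else:
            if not (0 <= p and p + length <= len(s)):
                raise InputError(f"{kind} outside the CDS")
            if kind == "del":
                s = s[:p] + s[p + length:]
            else:
                s = s[:p] + bases + s[p + length:]
    return s


def predict_consequence(
    ref_cds: str,
    signature: EditSignature,
    annot: ProteinAnnotation,
) -> ConsequenceReport:
    """Predict the protein-level consequence of one allele.

    The edited CDS is translated to its first stop and compared with the
    wild-type peptide: the identical N-terminal stretch, any novel residues
    before termination, the (1-based) stop position, conserved cysteines no
    longer present at their wild-type positions, and — for in-frame
    deletions — the deleted residues with positions relative to the mature
    peptide.  An edit touching the start codon is flagged ``start_lost`` and
    not translated.
    """
    for kind, off, length, bases in signature.ops:
        p = annot.cut_site_in_cds + off
        if kind == "ins":
            if not 0 <= p <= len(ref_cds):
                raise InputError("edit outside the CDS")
            touches_start = 0 < p < 3  # insertion splitting the start codon
        else:
            if not (0 <= p and p + length <= len(ref_cds)):
                raise InputError("edit outside the CDS")
            touches_start = p < 3  # deletion/substitution overlapping ATG
        if touches_start:
            return ConsequenceReport(
                frameshift=signature.net_indel % 3 != 0, start_lost=True,
                identical_residues_before_divergence=0,
                novel_residues_before_stop=0, stop_position=None,
                lost_conserved_cys=tuple(annot.conserved_cys),
                inframe_deleted_residues=(),
            )

    frameshift = signature.net_indel % 3 != 0
    wt_prot, _ = _translate_to_stop(ref_cds)
    edited = apply_signature(ref_cds, signature, annot.cut_site_in_cds)
    ed_prot, stop_found = _translate_to_stop(edited)

    prefix = 0
    for a, b in zip(wt_prot, ed_prot):
        if a != b:
            break
        prefix += 1
    novel = len(ed_prot) - prefix
    stop_position = len(ed_prot) + 1 if stop_found else None

    lost = tuple(i for i in annot.conserved_cys
                 if i > len(ed_prot) or ed_prot[i - 1] != "C")

    inframe_deleted: tuple[tuple[int, str], ...] = ()
    if not frameshift and not signature.is_wt and len(ed_prot) < len(wt_prot):
        suffix = 0
        while (suffix < min(len(wt_prot), len(ed_prot)) - prefix
               and wt_prot[len(wt_prot) - 1 - suffix] == ed_prot[len(ed_prot) - 1 - suffix]):
            suffix += 1
        mid_ed = ed_prot[prefix:len(ed_prot) - suffix]
        mid_wt = wt_prot[prefix:len(wt_prot) - suffix]
        if not mid_ed and mid_wt:
            inframe_deleted = tuple(
                (prefix + i + 1 - annot.signal_peptide_length, aa)
                for i, aa in enumerate(mid_wt)
            )

    return ConsequenceReport(
        frameshift=frameshift, start_lost=False,
        identical_residues_before_divergence=prefix,
        novel_residues_before_stop=novel,
        stop_position=stop_position,
        lost_conserved_cys=lost,
        inframe_deleted_residues=inframe_deleted,
    )


# ---------------------------------------------------------------------------
# Editing-efficiency summary
# ---------------------------------------------------------------------------

def _round_half_up_percent(fraction: float) -> int:
    return int(math.floor(fraction * 100.0 + 0.5))


def summarize_editing(genotypes: Iterable[NoduleGenotype]) -> pd.DataFrame:
    """Per-construct (and per-phenotype when scored) editing-efficiency table.

    Columns: nodules sequenced; nodules carrying at most 50% WT allele;
    fully mutant nodules (mismatch or indel); fully mutant nodules (only
    indel); percent of nodule samples carrying only indel alleles
    (indel-only / sequenced, rounded half-up to an integer percent).
    """
    genotypes = list(genotypes)
    by_construct: dict[str, list[NoduleGenotype]] = {}
    for g in genotypes:
        by_construct.setdefault(g.construct, []).append(g)

    records = []
    for construct, group in by_construct.items():
        if not group:
            warnings.warn(f"construct {construct!r} has no genotypes; skipped")
            continue
        labels = {g.phenotype_label for g in group}
        if labels - {"unscored"}:
            keys = sorted(labels)
            subgroups = [(lab, [g for g in group if g.phenotype_label == lab])
                         for lab in keys]
        else:
            subgroups = [("all", group)]
        for label, sub in subgroups:
            if not sub:
                continue
            n = len(sub)
            n_max50 = sum(g.wt_fraction <= 0.50 for g in sub)
            n_fully = sum(g.genotype_class in
                          ("fully_mutant_indel_only", "fully_mutant_with_mismatch")
                          for g in sub)
            n_indel_only = sum(g.genotype_class == "fully_mutant_indel_only"
                               for g in sub)
            records.append({
                "construct": construct,
                "phenotype": label,
                "n_sequenced": n,
                "n_max50_wt": n_max50,
                "n_fully_mutant": n_fully,
                "n_fully_mutant_indel_only": n_indel_only,
                "pct_indel_only": _round_half_up_percent(n_indel_only / n),
            })
    return pd.DataFrame(records)
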