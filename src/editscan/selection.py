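"""Candidate selection for nodule-specific cysteine-rich (NCR) peptides.

NCR peptides are short secreted plant peptides that drive the terminal
differentiation of rhizobia inside legume nodules.  The gene family is large
(several hundred members in *Medicago truncatula*), and knockout candidates
are funnelled through a sequence of filters before guide design:

1. the encoded peptide carries a predicted N-terminal signal peptide
   (signal-peptide status is an *input annotation* here, never predicted);
2. the mature peptide contains four cysteines in the conserved spacing
   C-X5-C-Xn-C-X4-C;
3. the gene is expressed in nodules above a read-count threshold
   (strictly more than 10,000 reads by default; zero-read genes are
   flagged as pseudogene-like);
4. candidates are additionally characterised by the isoelectric point (pI)
   of the mature peptide and a derived charge class, so that anionic,
   neutral and cationic family members can all be represented.

The module exposes the motif scanner, a Henderson-Hasselbalch bisection pI
solver, the charge classifier and the funnel itself, plus a per-stage
:class:`FunnelReport`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, InputError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Nodule zones profiled by laser-capture RNAseq: distal/proximal infection
#: zone, interzone and nitrogen-fixation zone.
ZONE_LABELS = ("IID", "IIP", "IZ", "ZIII")


def _check_peptide(peptide: str) -> None:
    bad = set(peptide) - AMINO_ACIDS
    if bad:
        raise InputError(
            f"peptide contains non-amino-acid characters: {sorted(bad)!r}"
        )


# ---------------------------------------------------------------------------
# Cysteine motif
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSpec:
    """Inter-cysteine gap constraints of the conserved C-X5-C-Xn-C-X4-C motif.

    ``gap1`` and ``gap3`` are exact residue counts between cysteines 1-2 and
    3-4; ``min_gap2`` is the lower bound on the unconstrained middle gap.
    With ``require_exact_four_cys`` (the default) a mature peptide whose
    total cysteine count differs from four never matches, regardless of
    spacing; six-cysteine family members are a separate class and out of
    scope here.
    """

    gap1: int = 5
    min_gap2: int = 1
    gap3: int = 4
    require_exact_four_cys: bool = True

    def __post_init__(self) -> None:
        if self.gap1 < 0 or self.gap3 < 0 or self.min_gap2 < 0:
            raise ConfigurationError("motif gap constraints must be >= 0")


@dataclass(frozen=True)
class MotifMatch:
    """Result of a motif scan.

    ``cys_positions`` are 1-based residue indices within the mature peptide
    of the leftmost matching cysteine quadruple; ``n_additional`` counts any
    further downstream quadruples that also satisfy the spacing.
    """

    matched: bool
    cys_positions: tuple[int, int, int, int] | None = None
    n_additional: int = 0

    def __bool__(self) -> bool:  # allows `if scan_cys_motif(...)`
        return self.matched


def scan_cys_motif(mature_peptide: str, motif: MotifSpec | None = None) -> MotifMatch:
    """Scan a mature peptide for the conserved four-cysteine spacing.

    Returns the leftmost matching quadruple (smallest positions in
    lexicographic order); matching is deterministic.
    """
    if motif is None:
        motif = MotifSpec()
    _check_peptide(mature_peptide)
    cys = [i + 1 for i, aa in enumerate(mature_peptide) if aa == "C"]
    if motif.require_exact_four_cys and len(cys) != 4:
        return MotifMatch(False)
    cys_set = set(cys)
    hits: list[tuple[int, int, int, int]] = []
    for c1 in cys:
        c2 = c1 + motif.gap1 + 1
        if c2 not in cys_set:
            continue
        for c3 in cys:
            if c3 - c2 - 1 < motif.min_gap2:
                continue
            c4 = c3 + motif.gap3 + 1
            if c4 in cys_set:
                hits.append((c1, c2, c3, c4))
    if not hits:
        return MotifMatch(False)
    hits.sort()
    return MotifMatch(True, hits[0], len(hits) - 1)


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


def load_pka_table(name: str = "emboss") -> dict:
    """Load a named, versioned pKa table shipped with the package."""
    path = resources.files("editscan.data").joinpath(f"pka_{name}.json")
    try:
        with path.open("r") as fh:
            return json.load(fh)
    except FileNotFoundError:  # pragma: no cover
        raise ConfigurationError(f"unknown pKa table {name!r}") from None


_DEFAULT_PKA = load_pka_table("emboss")


def net_charge(pH: float, peptide: str, pka_table: Mapping | None = None) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH.

    Free N- and C-termini are always included; side chains contribute
    per-residue.  Positive groups contribute ``1/(1+10^(pH-pKa))``,
    negative groups ``-1/(1+10^(pKa-pH))``.
    """
    table = pka_table if pka_table is not None else _DEFAULT_PKA
    side = table["side_chains"]
    q = 1.0 / (1.0 + 10.0 ** (pH - table["n_term"]))
    q -= 1.0 / (1.0 + 10.0 ** (table["c_term"] - pH))
    for aa in _BASIC:
        n = peptide.count(aa)
        if n and aa in side:
            q += n / (1.0 + 10.0 ** (pH - side[aa]))
    for aa in _ACIDIC:
        n = peptide.count(aa)
        if n and aa in side:
            q -= n / (1.0 + 10.0 ** (side[aa] - pH))
    return q


def compute_pI(peptide: str, pka_table: Mapping | None = None, tol: float = 1e-4) -> float:
    """Isoelectric point: the pH in [0, 14] at which the net charge is zero.

    Solved by bisection (charge is strictly decreasing in pH) to ``tol``.
    The returned value is unrounded; reports format it to 2 decimals.
    """
    if not peptide:
        raise InputError("empty peptide")
    _check_peptide(peptide)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(mid, peptide, pka_table) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Charge class
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChargeBoundaries:
    """pI boundaries separating anionic / neutral / cationic peptides.

    The source study never defines numeric boundaries, so these defaults
    (anionic at pI <= 6.5, cationic at pI >= 7.5) are a declared choice and
    fully configurable.
    """

    anionic_max: float = 6.5
    cationic_min: float = 7.5

    def __post_init__(self) -> None:
        if not self.anionic_max < self.cationic_min:
            raise ConfigurationError("anionic_max must be < cationic_min")


def classify_charge(pI: float, boundaries: ChargeBoundaries | None = None) -> str:
    """Map a pI to {'anionic', 'neutral', 'cationic'} (boundaries inclusive)."""
    b = boundaries or ChargeBoundaries()
    if not 0.0 <= pI <= 14.0:
        raise InputError(f"pI {pI} outside [0, 14]")
    if pI <= b.anionic_max:
        return "anionic"
    if pI >= b.cationic_min:
        return "cationic"
    return "neutral"


# ---------------------------------------------------------------------------
# Records and the selection funnel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NCRPeptideRecord:
    """One NCR peptide with its annotation and expression profile.

    ``signal_cleavage_site`` is the 1-based index of the last signal-peptide
    residue; ``mature_peptide`` is the suffix after that residue (the whole
    peptide when no signal peptide is annotated).  ``cys_positions`` are
    1-based indices within the mature peptide.  ``zone_reads`` maps nodule
    zone labels to read counts; ``total_reads`` is their sum.
    """

    gene_id: str
    full_peptide: str
    has_signal_peptide: bool = False
    signal_cleavage_site: int | None = None
    mature_peptide: str | None = None
    cys_positions: tuple[int, ...] | None = None
    pI: float | None = None
    charge_class: str | None = None
    total_reads: int | None = None
    zone_reads: Mapping[str, int] | None = None

    def with_mature(self) -> "NCRPeptideRecord":
        """Return a copy with the mature peptide derived from the annotation."""
        if self.mature_peptide is not None:
            return self
        if self.has_signal_peptide and self.signal_cleavage_site:
            mature = self.full_peptide[self.signal_cleavage_site:]
        else:
            mature = self.full_peptide
        return dataclasses.replace(self, mature_peptide=mature)


def annotate_records(
    records: Iterable[NCRPeptideRecord],
    pka_table: Mapping | None = None,
    boundaries: ChargeBoundaries | None = None,
) -> list[NCRPeptideRecord]:
    """Fill mature peptide, cysteine positions, pI and charge class.

    Pure: returns new records, inputs are untouched.
    """
    out = []
    for rec in records:
        rec = rec.with_mature()
        mature = rec.mature_peptide or ""
        cys = tuple(i + 1 for i, aa in enumerate(mature) if aa == "C")
        pI = compute_pI(mature, pka_table) if mature else None
        cc = classify_charge(pI, boundaries) if pI is not None else None
        out.append(dataclasses.replace(rec, cys_positions=cys, pI=pI, charge_class=cc))
    return out


@dataclass(frozen=True)
class SelectionThresholds:
    """Expression filter: retain genes with total_reads strictly greater than
    ``min_total_reads``; genes at or below ``pseudogene_reads`` are flagged
    pseudogene-like."""

    min_total_reads: int = 10_000
    pseudogene_reads: int = 0

    def __post_init__(self) -> None:
        if self.pseudogene_reads > self.min_total_reads:
            raise ConfigurationError("pseudogene_reads must be <= min_total_reads")


@dataclass(frozen=True)
class FunnelReport:
    """Per-stage survivor counts of the candidate-selection funnel.

    ``stages()`` returns the monotone survivor sequence
    input >= signal_peptide >= motif >= expressed >= retained.
    ``n_pseudogene_like`` and ``n_low_expression`` are the counts removed at
    the two expression sub-stages (zero reads; nonzero but at or below the
    threshold).
    """

    n_input: int
    n_signal_peptide: int
    n_motif: int
    n_expressed: int
    n_retained: int
    n_pseudogene_like: int
    n_low_expression: int
    min_total_reads: int
    pseudogene_reads: int
    pka_table: str

    def stages(self) -> list[int]:
        return [self.n_input, self.n_signal_peptide, self.n_motif,
                self.n_expressed, self.n_retained]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def select_candidates(
    records: Sequence[NCRPeptideRecord],
    thresholds: SelectionThresholds | None = None,
    motif: MotifSpec | None = None,
    pka_table_name: str = "emboss",
) -> tuple[list[NCRPeptideRecord], FunnelReport]:
    """Run the selection funnel and return (retained records, FunnelReport).

    Retained = annotated signal peptide AND conserved-cysteine motif AND
    total_reads strictly above the threshold.  The funnel is a pure filter:
    input records are not mutated and re-running on the output returns the
    same set.
    """
    thresholds = thresholds or SelectionThresholds()
    motif = motif or MotifSpec()
    records = [r.with_mature() for r in records]
    for r in records:
        if r.total_reads is None:
            raise InputError(f"record {r.gene_id!r} has no expression data")

    with_sp = [r for r in records if r.has_signal_peptide]
    with_motif = [r for r in with_sp if scan_cys_motif(r.mature_peptide or "", motif)]
    expressed = [r for r in with_motif if (r.total_reads or 0) > thresholds.pseudogene_reads]
    retained = [r for r in expressed if (r.total_reads or 0) > thresholds.min_total_reads]

    report = FunnelReport(
        n_input=len(records),
        n_signal_peptide=len(with_sp),
        n_motif=len(with_motif),
        n_expressed=len(expressed),
        n_retained=len(retained),
        n_pseudogene_like=len(with_motif) - len(expressed),
        n_low_expression=len(expressed) - len(retained),
        min_total_reads=thresholds.min_total_reads,
        pseudogene_reads=thresholds.pseudogene_reads,
        pka_table=pka_table_name,
    )
    return retained, report
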