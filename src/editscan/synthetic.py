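"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here with known truth,
so that each analytic module has a parameter-recovery oracle:

* NCR-like peptide families (signal peptide, conserved-cysteine motif and
  expression-class labels recorded per gene);
* zone-wise nodule expression tables (negative-binomial counts spanning the
  10,000-read selection threshold);
* genomes with planted guide target sites and decoy off-target sites of
  known Hamming distance;
* per-nodule amplicon read sets drawn from a wild-type allele plus 1-3 edit
  alleles at a Cas9 cut site, with a simple per-base error model and a
  read-id -> allele-id truth table;
* four-channel chromatogram traces whose edited trace is an exact
  fraction-weighted sum of shifted control signals plus truncated Gaussian
  noise.

All generators are pure functions of their spec plus a seed.  The synthetic
"signal peptides" are only a hydrophobic-rich N-terminal stretch — a
generator convenience; the analytic modules treat signal-peptide status
strictly as an input annotation and never infer it from sequence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .genotyping import AlleleTable, EditSignature
from .guides import revcomp
from .selection import NCRPeptideRecord, ZONE_LABELS, scan_cys_motif
from .tide import CHANNELS, ChromatogramTrace

_NON_CYS = "ADEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "ALVIFMW"
_BASES = "ACGT"


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Peptide families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic NCR-like peptide family.

    Fractions are of all genes: ``frac_with_signal_peptide`` get a synthetic
    signal peptide, ``frac_with_motif`` a mature peptide built around the
    conserved C-X5-C-Xn-C-X4-C spacing.  Expression classes (used by
    :func:`gen_expression_table`) are zero / high / low with means 0 /
    ``high_mean`` / ``low_mean`` reads.
    """

    n_genes: int
    frac_with_signal_peptide: float = 0.8
    frac_with_motif: float = 0.5
    mature_length_range: tuple[int, int] = (30, 60)
    frac_high_expression: float = 0.5
    frac_zero_expression: float = 0.05
    high_mean: float = 50_000.0
    low_mean: float = 2_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        for name in ("frac_with_signal_peptide", "frac_with_motif",
                     "frac_high_expression", "frac_zero_expression"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.mature_length_range
        if lo < 15 or hi < lo:
            raise ConfigurationError(
                "mature_length_range must satisfy 15 <= lo <= hi "
                "(the motif needs at least 15 residues)")


def _motif_positive_mature(rng: np.random.Generator, length: int) -> str:
    """Mature peptide containing exactly four Cys in the conserved spacing."""
    rem = length - 13  # 4 Cys + 5 + 4 fixed spacer residues
    m = int(rng.integers(1, rem + 1))          # middle gap >= 1
    a = int(rng.integers(0, rem - m + 1))      # N-terminal flank
    t = rem - m - a
    pick = lambda k: "".join(rng.choice(list(_NON_CYS), size=k))
    return (pick(a) + "C" + pick(5) + "C" + pick(m) + "C" + pick(4) + "C" + pick(t))


def _motif_negative_mature(rng: np.random.Generator, length: int) -> str:
    """Mature peptide that the motif scanner rejects (wrong Cys count or spacing)."""
    for _ in range(200):
        n_cys = int(rng.choice([0, 1, 2, 3, 4, 5, 6]))
        residues = list(rng.choice(list(_NON_CYS), size=length))
        if n_cys:
            pos = rng.choice(length, size=min(n_cys, length), replace=False)
            for p in pos:
                residues[p] = "C"
        pep = "".join(residues)
        if not scan_cys_motif(pep):
            return pep
    raise RuntimeError("could not generate a motif-negative peptide")  # pragma: no cover


def _signal_peptide(rng: np.random.Generator) -> str:
    """N-terminal stretch of 15-25 residues, >= 70% hydrophobic."""
    length = int(rng.integers(15, 26))
    n_hydro = int(np.ceil(0.7 * length))
    pool = (list(rng.choice(list(_HYDROPHOBIC), size=n_hydro))
            + list(rng.choice(list(_NON_CYS), size=length - n_hydro)))
    rng.shuffle(pool)
    return "M" + "".join(pool)[1:]


def gen_ncr_family(spec: FamilySpec) -> tuple[list[NCRPeptideRecord], pd.DataFrame]:
    """Generate a peptide family with ground-truth labels.

    Returns (records, truth) where truth has one row per gene with columns
    gene_id, has_signal_peptide, has_motif, expression_class, mean_reads.
    Deterministic for a fixed spec (byte-identical FASTA on rerun).
    """
    rng = _rng(spec.seed)
    records, truth = [], []
    lo, hi = spec.mature_length_range
    for i in range(spec.n_genes):
        gene_id = f"ncr_{i:04d}"
        has_sp = bool(rng.random() < spec.frac_with_signal_peptide)
        has_motif = bool(rng.random() < spec.frac_with_motif)
        length = int(rng.integers(lo, hi + 1))
        mature = (_motif_positive_mature(rng, length) if has_motif
                  else _motif_negative_mature(rng, length))
        if has_sp:
            signal = _signal_peptide(rng)
            full = signal + mature
            cleavage = len(signal)
        else:
            full, cleavage = mature, None
        u = rng.random()
        if u < spec.frac_zero_expression:
            expr_class, mean = "zero", 0.0
        elif u < spec.frac_zero_expression + spec.frac_high_expression:
            expr_class, mean = "high", spec.high_mean
        else:
            expr_class, mean = "low", spec.low_mean
        records.append(NCRPeptideRecord(
            gene_id=gene_id, full_peptide=full, has_signal_peptide=has_sp,
            signal_cleavage_site=cleavage, mature_peptide=mature,
        ))
        truth.append({"gene_id": gene_id, "has_signal_peptide": has_sp,
                      "has_motif": has_motif, "expression_class": expr_class,
                      "mean_reads": mean})
    return records, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

#: default relative zone weights (distal/proximal infection zone, interzone,
#: nitrogen-fixation zone); they sum to 1 so mean_reads is the total mean.
DEFAULT_ZONE_PROFILE: Mapping[str, float] = {
    "IID": 0.15, "IIP": 0.20, "IZ": 0.40, "ZIII": 0.25,
}


def gen_expression_table(
    truth: pd.DataFrame,
    zone_profiles: Mapping[str, float] | None = None,
    seed: int = 0,
    dispersion: float = 10.0,
) -> pd.DataFrame:
    """Sample zone-wise negative-binomial read counts per gene.

    ``truth`` must carry gene_id and mean_reads (as produced by
    :func:`gen_ncr_family`); ``zone_profiles`` maps each of the four zone
    labels to a non-negative weight multiplying the gene mean.  The
    total_reads column equals the row sum.
    """
    profiles = dict(zone_profiles if zone_profiles is not None else DEFAULT_ZONE_PROFILE)
    unknown = set(profiles) - set(ZONE_LABELS)
    if unknown:
        raise ConfigurationError(f"unknown zone labels: {sorted(unknown)}")
    missing = set(ZONE_LABELS) - set(profiles)
    if missing:
        raise ConfigurationError(f"missing zone profiles: {sorted(missing)}")
    if dispersion <= 0:
        raise ConfigurationError("dispersion must be > 0")
    rng = _rng(seed)
    rows = []
    for rec in truth.itertuples():
        counts = {}
        for zone in ZONE_LABELS:
            mean = float(rec.mean_reads) * float(profiles[zone])
            p = dispersion / (dispersion + mean)
            counts[zone] = int(rng.negative_binomial(dispersion, p)) if mean > 0 else 0
        rows.append({"gene_id": rec.gene_id, **counts,
                     "total_reads": sum(counts.values())})
    return pd.DataFrame(rows)


def attach_expression(
    records: Sequence[NCRPeptideRecord], expression: pd.DataFrame
) -> list[NCRPeptideRecord]:
    """Return records with total_reads / zone_reads filled from a table."""
    by_gene = expression.set_index("gene_id")
    out = []
    for rec in records:
        if rec.gene_id not in by_gene.index:
            raise InputError(f"no expression row for gene {rec.gene_id!r}")
        row = by_gene.loc[rec.gene_id]
        out.append(dataclasses.replace(
            rec,
            total_reads=int(row["total_reads"]),
            zone_reads={z: int(row[z]) for z in ZONE_LABELS},
        ))
    return out


# ---------------------------------------------------------------------------
# Amplicon read simulation
# ---------------------------------------------------------------------------

_KINDS = ("deletion", "insertion", "substitution")
_KIND_TO_OP = {"deletion": "del", "insertion": "ins", "substitution": "sub"}


@dataclass(frozen=True)
class Edit:
    """One edit of an allele: position is the ref offset from the cut site."""

    kind: str
    position: int
    length: int
    inserted: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown edit kind {self.kind!r}")
        if self.length < 1:
            raise ConfigurationError("edit length must be >= 1")
        if self.kind == "insertion" and len(self.inserted) != self.length:
            raise ConfigurationError("insertion length must match inserted bases")
        if self.kind == "substitution" and len(self.inserted) != self.length:
            raise ConfigurationError("substitution length must match alt bases")


@dataclass(frozen=True)
class AlleleSpec:
    """One allele of a nodule: its edits and its mixture fraction."""

    edits: tuple[Edit, ...]
    fraction: float
    allele_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError("allele fraction must be in [0, 1]")

    @property
    def is_wt(self) -> bool:
        return not self.edits

    @property
    def net_indel(self) -> int:
        return (sum(e.length for e in self.edits if e.kind == "insertion")
                - sum(e.length for e in self.edits if e.kind == "deletion"))

    def to_signature(self) -> EditSignature:
        ops = tuple(sorted(
            (_KIND_TO_OP[e.kind], e.position, e.length,
             e.inserted if e.kind != "deletion" else "")
            for e in self.edits
        ))
        return EditSignature(ops)


def _check_fractions(alleles: Sequence[AlleleSpec]) -> None:
    total = sum(a.fraction for a in alleles)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"allele fractions must sum to 1, got {total}")


def apply_allele(ref_amplicon: str, cut_site: int, allele: AlleleSpec) -> str:
    """Apply an allele's edits to the reference amplicon."""
    seq = ref_amplicon
    for e in sorted(allele.edits, key=lambda e: e.position, reverse=True):
        p = cut_site + e.position
        if e.kind == "insertion":
            if not 0 <= p <= len(seq):
                raise InputError("edit outside amplicon bounds")
            seq = seq[:p] + e.inserted + seq[p:]
        else:
            if not (0 <= p and p + e.length <= len(ref_amplicon)):
                raise InputError("edit outside amplicon bounds")
            if e.kind == "deletion":
                seq = seq[:p] + seq[p + e.length:]
            else:
                seq = seq[:p] + e.inserted + seq[p + e.length:]
    return seq


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters.

    ``read_length`` of None means full-amplicon reads (merged ~200 bp
    amplicon sequencing); error rates are per base, substitutions uniform
    over the three alternatives, indel errors 1 bp placed uniformly.
    """

    n_reads: int = 10_000
    read_length: int | None = None
    substitution_error_rate: float = 0.001
    indel_error_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be >= 1")
        for name in ("substitution_error_rate", "indel_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.1:
                raise ConfigurationError(f"{name} must be in [0, 0.1]")


def _mutate_read(seq: str, rng: np.random.Generator, cfg: ReadSimConfig) -> str:
    n_sub = rng.binomial(len(seq), cfg.substitution_error_rate) if cfg.substitution_error_rate else 0
    if n_sub:
        chars = list(seq)
        for p in rng.choice(len(chars), size=min(n_sub, len(chars)), replace=False):
            alts = [b for b in _BASES if b != chars[p]]
            chars[p] = alts[int(rng.integers(3))]
        seq = "".join(chars)
    n_ind = rng.binomial(len(seq), cfg.indel_error_rate) if cfg.indel_error_rate else 0
    for _ in range(n_ind):
        p = int(rng.integers(len(seq) + 1))
        if rng.random() < 0.5:
            seq = seq[:p] + _BASES[int(rng.integers(4))] + seq[p:]
        elif len(seq) > 1:
            p = min(p, len(seq) - 1)
            seq = seq[:p] + seq[p + 1:]
    return seq


def gen_amplicon_reads(
    ref_amplicon: str,
    cut_site: int,
    alleles: Sequence[AlleleSpec],
    cfg: ReadSimConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a nodule's amplicon reads.

    Returns (reads, truth): reads as (read_id, sequence) pairs, truth as a
    read_id -> allele_id sidecar table recording the multinomial draw.
    Deterministic per config seed.
    """
    if not 0 <= cut_site < len(ref_amplicon):
        raise InputError("cut_site outside ref_amplicon")
    _check_fractions(alleles)
    rng = _rng(cfg.seed)
    ids = [a.allele_id or f"allele_{i}" for i, a in enumerate(alleles)]
    seqs = [apply_allele(ref_amplicon, cut_site, a) for a in alleles]
    fracs = np.array([a.fraction for a in alleles], dtype=float)
    fracs = fracs / fracs.sum()
    assignment = rng.choice(len(alleles), size=cfg.n_reads, p=fracs)
    reads, truth = [], []
    for i, a_idx in enumerate(assignment):
        seq = _mutate_read(seqs[a_idx], rng, cfg)
        if cfg.read_length is not None:
            seq = seq[:cfg.read_length]
        read_id = f"read_{i:06d}"
        reads.append((read_id, seq))
        truth.append({"read_id": read_id, "allele_id": ids[a_idx]})
    return reads, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Decoy genomes for off-target search
# ---------------------------------------------------------------------------

def gen_decoy_genome(
    protospacer: str,
    planted_mismatches: Sequence[int] = (2, 3, 4),
    spacer: int = 60,
    seed: int = 0,
) -> tuple[dict[str, str], tuple[str, int, str], pd.DataFrame]:
    """Genome with the on-target site plus decoy sites of known distance.

    Each decoy is the protospacer with exactly d bases changed, followed by
    an AGG PAM; decoys alternate between plus and minus strand embeddings.
    Returns (genome, target_locus, planted) where planted lists each decoy's
    plus-strand start, strand and Hamming distance.
    """
    if len(protospacer) != 20:
        raise InputError("protospacer must be exactly 20 bases")
    rng = _rng(seed)
    bg = lambda k: "".join(rng.choice(list(_BASES), size=k))
    pieces = [bg(spacer)]
    pos = spacer
    # on-target site
    pieces.append(protospacer + "AGG")
    target = ("chr1", pos, "+")
    pos += 23
    planted = []
    for j, d in enumerate(planted_mismatches):
        pieces.append(bg(spacer))
        pos += spacer
        decoy = list(protospacer)
        for p in rng.choice(20, size=d, replace=False):
            alts = [b for b in _BASES if b != decoy[p]]
            decoy[p] = alts[int(rng.integers(3))]
        site = "".join(decoy) + "AGG"
        if j % 2 == 0:
            pieces.append(site)
            planted.append({"start": pos, "strand": "+", "mismatches": d})
        else:
            pieces.append(revcomp(site))
            planted.append({"start": pos + 3, "strand": "-", "mismatches": d})
        pos += 23
    pieces.append(bg(spacer))
    return {"chr1": "".join(pieces)}, target, pd.DataFrame(planted)


# ---------------------------------------------------------------------------
# Chromatogram traces
# ---------------------------------------------------------------------------

def sequence_trace(sequence: str, peak_height: float = 1000.0) -> ChromatogramTrace:
    """Idealised single-peak chromatogram of a sequence (one peak per base)."""
    arr = np.zeros((4, len(sequence)))
    for i, base in enumerate(sequence):
        try:
            arr[CHANNELS.index(base), i] = peak_height
        except ValueError:
            raise InputError(f"invalid base {base!r} in trace sequence") from None
    return ChromatogramTrace(arr)


def gen_trace(
    control_sequence: str,
    mixture: Sequence[tuple[int, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_height: float = 1000.0,
) -> tuple[ChromatogramTrace, ChromatogramTrace]:
    """Generate (control, edited) chromatogram traces.

    The edited trace is the exact fraction-weighted sum of the control trace
    displaced by each mixture shift (positions without shifted coverage
    contribute zero), plus Gaussian noise truncated at zero on the edited
    trace only.  A {(0, 1.0)} mixture at zero noise reproduces the control
    exactly.
    """
    fractions = [f for _, f in mixture]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("mixture fractions must sum to 1")
    control = sequence_trace(control_sequence, peak_height)
    L = control.length
    edited = np.zeros_like(control.channels)
    for shift, frac in mixture:
        src_lo = max(0, -shift)
        src_hi = min(L, L - shift)
        if src_hi <= src_lo:
            raise InputError(f"shift {shift} leaves no overlap with the trace")
        edited[:, src_lo + shift:src_hi + shift] += frac * control.channels[:, src_lo:src_hi]
    if noise_sd > 0:
        rng = _rng(seed)
        edited = np.clip(edited + rng.normal(0.0, noise_sd, edited.shape), 0.0, None)
    return control, ChromatogramTrace(edited)


# ---------------------------------------------------------------------------
# Nodule scenario sampling (for end-to-end recovery experiments)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoduleDesign:
    """A simulated nodule: its allele mixture and the genotype it realises."""

    nodule_id: str
    alleles: tuple[AlleleSpec, ...]
    intended_class: str


def gen_amplicon(length: int = 200, seed: int = 0) -> str:
    """Random amplicon sequence."""
    return "".join(_rng(seed).choice(list(_BASES), size=length))


def _random_indel_edit(rng: np.random.Generator, used_nets: set[int]) -> Edit:
    for _ in range(100):
        if rng.random() < 0.6:
            length = int(rng.integers(1, 9))
            net = -length
            if net in used_nets:
                continue
            used_nets.add(net)
            return Edit("deletion", int(rng.integers(-3, 1)), length)
        length = int(rng.integers(1, 4))
        if length in used_nets:
            continue
        used_nets.add(length)
        ins = "".join(rng.choice(list(_BASES), size=length))
        return Edit("insertion", int(rng.integers(-1, 2)), length, ins)
    raise RuntimeError("could not draw a distinct indel")  # pragma: no cover


def _random_sub_edit(rng: np.random.Generator, ref: str, cut_site: int) -> Edit:
    length = int(rng.integers(1, 3))
    pos = int(rng.integers(-2, 3 - length))
    alt = ""
    for k in range(length):
        base = ref[cut_site + pos + k]
        alts = [b for b in _BASES if b != base]
        alt += alts[int(rng.integers(3))]
    return Edit("substitution", pos, length, alt)


def _split_fractions(rng: np.random.Generator, total: float, n: int) -> list[float]:
    if n == 1:
        return [total]
    for _ in range(100):
        parts = rng.dirichlet(np.ones(n)) * total
        if parts.min() >= 0.06:
            return [float(p) for p in parts]
    return [total / n] * n


def sample_nodule_designs(
    ref_amplicon: str,
    cut_site: int,
    n_nodules: int,
    seed: int = 0,
) -> list[NoduleDesign]:
    """Draw random nodule designs spanning all five genotype classes.

    Wild-type fractions are kept away from the classification thresholds
    (0.05 and 0.50) so each design maps unambiguously to one intended
    class; indel alleles within a nodule have distinct net indel sizes and
    at most one substitution-only allele is used per nodule.
    """
    rng = _rng(seed)
    classes = (
        "wild_type", "heterozygous_chimeric", "mutant_majority",
        "fully_mutant_indel_only", "fully_mutant_with_mismatch",
    )
    designs = []
    for i in range(n_nodules):
        cls = classes[int(rng.integers(len(classes)))]
        alleles: list[AlleleSpec] = []
        used_nets: set[int] = set()
        if cls == "wild_type":
            alleles.append(AlleleSpec((), 1.0, "WT"))
        else:
            if cls == "heterozygous_chimeric":
                wt = float(rng.uniform(0.60, 0.85))
            elif cls == "mutant_majority":
                wt = float(rng.uniform(0.10, 0.45))
            else:
                wt = float(rng.uniform(0.0, 0.03))
            n_mut = int(rng.integers(1, 4))
            fracs = _split_fractions(rng, 1.0 - wt, n_mut)
            if wt > 0:
                alleles.append(AlleleSpec((), wt, "WT"))
            else:
                fracs = _split_fractions(rng, 1.0, n_mut)
            with_sub = cls == "fully_mutant_with_mismatch"
            for j, f in enumerate(fracs):
                if with_sub and j == 0:
                    edit = _random_sub_edit(rng, ref_amplicon, cut_site)
                else:
                    edit = _random_indel_edit(rng, used_nets)
                alleles.append(AlleleSpec((edit,), f, f"mut_{j}"))
        designs.append(NoduleDesign(f"nodule_{i:03d}", tuple(alleles), cls))
    return designs


def recovered_fractions(table: AlleleTable, design: NoduleDesign) -> dict[str, float]:
    """Measured frequency of each designed allele in a recovered table.

    Designed alleles are matched by kind: the WT row, the (single)
    substitution-only row, and indel rows by net indel size.  Alleles absent
    from the table get frequency 0.
    """
    out = {}
    for allele in design.alleles:
        freq = 0.0
        if allele.is_wt:
            freq = table.wt_fraction
        elif all(e.kind == "substitution" for e in allele.edits):
            for row in table.rows:
                if row.signature.classification == "mismatch_only":
                    freq = row.frequency
                    break
        else:
            for row in table.rows:
                if (row.signature.classification == "indel"
                        and row.signature.net_indel == allele.net_indel):
                    freq = row.frequency
                    break
        out[allele.allele_id] = freq
    return out
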