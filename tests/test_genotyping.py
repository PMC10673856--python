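"""Alignment, allele calling, nodule classification, consequences, summary."""

import numpy as np
import pytest

import editscan as es
from editscan.errors import DegenerateInputError, InputError

from _oracles import affine_dp_score, codon_translate


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# align_read
# ---------------------------------------------------------------------------

def test_perfect_read_aligns_gapless(amplicon_ref):
    aln = es.align_read(amplicon_ref.sequence, amplicon_ref)
    assert aln.ref_aligned == aln.read_aligned == amplicon_ref.sequence
    assert aln.identity == 1.0
    assert not aln.discard


def test_seven_bp_deletion_gives_single_gap(amplicon_ref):
    seq, cut = amplicon_ref.sequence, amplicon_ref.cut_site
    read = seq[:cut - 3] + seq[cut + 4:]
    aln = es.align_read(read, amplicon_ref)
    sig = es.call_allele(aln, amplicon_ref)
    assert len(sig.ops) == 1
    kind, off, length, _ = sig.ops[0]
    assert (kind, length) == ("del", 7)
    assert sig.net_indel == -7
    assert abs(off) <= amplicon_ref.quantification_window


def test_alignment_scores_match_dp_oracle(rng):
    ref60 = es.AmpliconRef(_random_dna(rng, 60), 30, quantification_window=5)
    for _ in range(150):
        n = int(rng.integers(5, 31))
        ref = es.AmpliconRef(_random_dna(rng, max(n, 11)), 5, quantification_window=2)
        read = _random_dna(rng, int(rng.integers(1, 31)))
        assert es.align_read(read, ref).score == affine_dp_score(ref.sequence, read)
    # also equal-length reads with few substitutions (gapless fast path)
    for _ in range(50):
        seq = list(ref60.sequence)
        for p in rng.choice(60, size=int(rng.integers(0, 4)), replace=False):
            seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
        read = "".join(seq)
        assert es.align_read(read, ref60).score == affine_dp_score(ref60.sequence, read)


def test_garbage_read_is_flagged_discard(amplicon_ref):
    read = "T" * len(amplicon_ref.sequence)
    if es.align_read(read, amplicon_ref).identity >= 0.6:  # pragma: no cover
        pytest.skip("reference unexpectedly T-rich")
    assert es.align_read(read, amplicon_ref).discard


def test_empty_and_invalid_reads_raise(amplicon_ref):
    with pytest.raises(InputError):
        es.align_read("", amplicon_ref)
    with pytest.raises(InputError):
        es.align_read("ACGU", amplicon_ref)


# ---------------------------------------------------------------------------
# call_allele
# ---------------------------------------------------------------------------

def test_perfect_alignment_is_wild_type(amplicon_ref):
    aln = es.align_read(amplicon_ref.sequence, amplicon_ref)
    assert es.call_allele(aln, amplicon_ref).is_wt


def test_one_base_insertion_at_cut_site(amplicon_ref):
    seq, cut = amplicon_ref.sequence, amplicon_ref.cut_site
    base = "C" if seq[cut] != "C" else "G"
    read = seq[:cut] + base + seq[cut:]
    sig = es.call_allele(es.align_read(read, amplicon_ref), amplicon_ref)
    assert sig.net_indel == 1
    assert sig.classification == "indel"
    (op,) = sig.ops
    assert op[0] == "ins" and op[2] == 1


def test_edit_far_from_cut_is_ignored(amplicon_ref):
    seq, cut = amplicon_ref.sequence, amplicon_ref.cut_site
    p = cut - 30  # well outside the +/-10 window
    read = seq[:p] + ("A" if seq[p] != "A" else "G") + seq[p + 1:]
    sig = es.call_allele(es.align_read(read, amplicon_ref), amplicon_ref)
    assert sig.is_wt


def test_adjacent_substitutions_merge(amplicon_ref):
    seq, cut = amplicon_ref.sequence, amplicon_ref.cut_site
    alt = "".join("A" if b != "A" else "G" for b in seq[cut:cut + 2])
    read = seq[:cut] + alt + seq[cut + 2:]
    sig = es.call_allele(es.align_read(read, amplicon_ref), amplicon_ref)
    (op,) = sig.ops
    assert op == ("sub", 0, 2, alt)
    assert sig.classification == "mismatch_only"


# ---------------------------------------------------------------------------
# build_allele_table
# ---------------------------------------------------------------------------

def test_identical_wt_reads_collapse_to_one_row(amplicon_ref):
    table = es.build_allele_table([amplicon_ref.sequence] * 100, amplicon_ref)
    assert len(table.rows) == 1
    assert table.rows[0].signature.is_wt
    assert table.rows[0].frequency == 1.0
    assert table.total_reads == 100
    assert table.discarded_reads == 0


def test_reads_differing_outside_window_collapse(amplicon_ref):
    seq, cut = amplicon_ref.sequence, amplicon_ref.cut_site
    p = cut + 40
    variant = seq[:p] + ("T" if seq[p] != "T" else "A") + seq[p + 1:]
    table = es.build_allele_table([seq] * 50 + [variant] * 50, amplicon_ref)
    assert len(table.rows) == 1
    assert table.rows[0].reads == 100


def test_rare_signatures_pool_into_other(amplicon_ref):
    seq, cut = amplicon_ref.sequence, amplicon_ref.cut_site
    rare = seq[:cut] + "A" + seq[cut:]  # 1-bp insertion, 1 read of 300
    table = es.build_allele_table([seq] * 299 + [rare], amplicon_ref)
    assert len(table.rows) == 1
    assert table.other_reads == 1
    assert table.rows[0].frequency == 1.0  # renormalised over named rows
    assert table.total_reads == 300


def test_simulated_mixture_frequencies_match_truth(amplicon):
    seq, cut = amplicon
    alleles = (es.AlleleSpec((), 0.3, "WT"),
               es.AlleleSpec((es.Edit("deletion", -3, 7),), 0.4, "del7"),
               es.AlleleSpec((es.Edit("insertion", 0, 1, "A"),), 0.3, "ins1"))
    reads, truth = es.gen_amplicon_reads(
        seq, cut, alleles, es.ReadSimConfig(n_reads=4000, seed=13))
    table = es.build_allele_table([s for _, s in reads], es.AmpliconRef(seq, cut))
    measured = es.recovered_fractions(
        table, es.NoduleDesign("n", alleles, "mutant_majority"))
    observed = truth["allele_id"].value_counts(normalize=True)
    for allele_id, freq in measured.items():
        assert freq == pytest.approx(observed[allele_id], abs=0.02)


def test_read_conservation(amplicon_ref):
    seq = amplicon_ref.sequence
    garbage = "T" * len(seq)
    reads = [seq] * 90 + [garbage] * 10
    table = es.build_allele_table(reads, amplicon_ref)
    assert table.total_reads + table.discarded_reads == 100
    assert sum(r.frequency for r in table.rows) == pytest.approx(1.0, abs=1e-9)


def test_empty_read_set_raises(amplicon_ref):
    with pytest.raises(DegenerateInputError):
        es.build_allele_table([], amplicon_ref)


# ---------------------------------------------------------------------------
# classify_nodule
# ---------------------------------------------------------------------------

def _table(rows, nodule_id="n"):
    named = tuple(es.genotyping.AlleleRow(sig, int(f * 1000), f) for sig, f in rows)
    return es.AlleleTable(nodule_id=nodule_id, rows=named, total_reads=1000,
                          discarded_reads=0)


DEL7 = es.EditSignature((("del", -3, 7, ""),))
DEL4 = es.EditSignature((("del", -2, 4, ""),))
INS1 = es.EditSignature((("ins", 0, 1, "A"),))
SUB2 = es.EditSignature((("sub", 0, 2, "AG"),))


@pytest.mark.parametrize("rows, expected", [
    ([(es.WT_SIGNATURE, 1.0)], "wild_type"),
    ([(es.WT_SIGNATURE, 0.02), (DEL7, 0.49), (INS1, 0.49)], "fully_mutant_indel_only"),
    ([(es.WT_SIGNATURE, 0.45), (DEL4, 0.55)], "mutant_majority"),
    ([(es.WT_SIGNATURE, 0.70), (DEL4, 0.30)], "heterozygous_chimeric"),
    ([(es.WT_SIGNATURE, 0.03), (SUB2, 0.97)], "fully_mutant_with_mismatch"),
    ([(DEL7, 0.6), (INS1, 0.4)], "fully_mutant_indel_only"),
    ([(es.WT_SIGNATURE, 0.50), (DEL4, 0.50)], "mutant_majority"),  # "max. 50%" inclusive
])
def test_classification_thresholds(rows, expected):
    assert es.classify_nodule(_table(rows)).genotype_class == expected


def test_classification_threshold_objects_validate():
    with pytest.raises(InputError):
        es.ClassificationThresholds(wt_max_for_mutant_majority=0.1,
                                    wt_max_for_fully_mutant=0.2)


# ---------------------------------------------------------------------------
# predict_consequence
# ---------------------------------------------------------------------------

CDS = "ATG" + "GATCGTACCTGTAAAGAAGCATGTATTCGT" * 3 + "TGTTTCTGA"
ANNOT = es.ProteinAnnotation(cut_site_in_cds=45, signal_peptide_length=5,
                             conserved_cys=(5, 9, 15, 25))


def test_wt_signature_changes_nothing():
    rep = es.predict_consequence(CDS, es.WT_SIGNATURE, ANNOT)
    assert not rep.frameshift
    assert rep.novel_residues_before_stop == 0
    assert rep.lost_conserved_cys == ()
    assert rep.inframe_deleted_residues == ()


def test_inframe_codon_deletion():
    # delete one full codon at a codon boundary (position 45 = codon 16)
    sig = es.EditSignature((("del", 0, 3, ""),))
    rep = es.predict_consequence(CDS, sig, ANNOT)
    assert not rep.frameshift
    assert len(rep.inframe_deleted_residues) == 1
    pos, aa = rep.inframe_deleted_residues[0]
    assert aa == codon_translate(CDS)[15]
    assert pos == 16 - ANNOT.signal_peptide_length


def test_frameshift_counts_match_translate_and_diff_oracle(rng):
    wt_prot = codon_translate(CDS)
    for _ in range(50):
        if rng.random() < 0.5:
            length = int(rng.integers(1, 6))
            sig = es.EditSignature((("del", int(rng.integers(-6, 3)), length, ""),))
        else:
            length = int(rng.integers(1, 6))
            ins = "".join(rng.choice(list("ACGT"), size=length))
            sig = es.EditSignature((("ins", int(rng.integers(-6, 4)), length, ins),))
        rep = es.predict_consequence(CDS, sig, ANNOT)
        assert rep.frameshift == (sig.net_indel % 3 != 0)
        edited = es.genotyping.apply_signature(CDS, sig, ANNOT.cut_site_in_cds)
        ed_prot = codon_translate(edited)
        prefix = 0
        for a, b in zip(wt_prot, ed_prot):
            if a != b:
                break
            prefix += 1
        assert rep.identical_residues_before_divergence == prefix
        assert rep.novel_residues_before_stop == len(ed_prot) - prefix
        expected_lost = tuple(i for i in ANNOT.conserved_cys
                              if i > len(ed_prot) or ed_prot[i - 1] != "C")
        assert rep.lost_conserved_cys == expected_lost


def test_edit_spanning_start_codon_is_flagged():
    sig = es.EditSignature((("del", -45, 5, ""),))
    rep = es.predict_consequence(CDS, sig, ANNOT)
    assert rep.start_lost
    assert rep.stop_position is None


# ---------------------------------------------------------------------------
# summarize_editing
# ---------------------------------------------------------------------------

def _genotype(cls, wt, construct, phenotype="unscored", i=[0]):
    i[0] += 1
    return es.NoduleGenotype(nodule_id=f"n{i[0]}", genotype_class=cls,
                             wt_fraction=wt, n_alleles=2, construct=construct,
                             phenotype_label=phenotype)


def test_summary_percentage_rounding_half_up():
    # 7 of 15 indel-only nodules must print as 47%
    genotypes = ([_genotype("fully_mutant_indel_only", 0.02, "A") for _ in range(7)]
                 + [_genotype("fully_mutant_with_mismatch", 0.02, "A") for _ in range(7)]
                 + [_genotype("mutant_majority", 0.3, "A")])
    df = es.summarize_editing(genotypes)
    row = df.iloc[0]
    assert (row.n_sequenced, row.n_max50_wt, row.n_fully_mutant,
            row.n_fully_mutant_indel_only, row.pct_indel_only) == (15, 15, 14, 7, 47)


def test_summary_zero_and_hundred_percent():
    zero = [_genotype("mutant_majority", 0.4, "B") for _ in range(3)]
    full = [_genotype("fully_mutant_indel_only", 0.0, "C") for _ in range(13)]
    df = es.summarize_editing(zero + full).set_index("construct")
    assert df.loc["B", "pct_indel_only"] == 0
    assert df.loc["C", "pct_indel_only"] == 100


def test_summary_splits_by_phenotype_when_scored():
    white = [_genotype("fully_mutant_indel_only", 0.0, "D", "white_undeveloped")
             for _ in range(3)]
    pink = [_genotype("wild_type", 0.9, "D", "pink_elongated") for _ in range(3)]
    df = es.summarize_editing(white + pink).set_index("phenotype")
    assert df.loc["white_undeveloped", "pct_indel_only"] == 100
    assert df.loc["pink_elongated", "pct_indel_only"] == 0
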