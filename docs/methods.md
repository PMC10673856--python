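# Methods

This note records the models behind each `editscan` stage, the defaults
that matter, the numerical choices, and what the synthetic generators do
and do not emulate. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Candidate selection

**Motif.** A mature NCR-like peptide matches when four cysteines occur with
inter-cysteine gaps of exactly 5, at least 1, and exactly 4 residues
(C–X₅–C–Xₙ–C–X₄–C). By default a peptide whose mature sequence contains a
cysteine count other than four never matches (`require_exact_four_cys`),
because six-cysteine family members form a separate class that this
pipeline does not handle. The scanner returns the leftmost matching
quadruple (lexicographically smallest position vector) and reports any
further quadruples only as a count, which makes matching deterministic.

**Isoelectric point.** Net charge at a given pH is the Henderson–
Hasselbalch sum over the free termini and the D, E, C, Y (acidic) and
H, K, R (basic) side chains. Charge is strictly decreasing in pH, so the
pI is found by bisection on [0, 14] to a tolerance of 1e-4 pH units;
reports format it to two decimals. The shipped pKa set
(`data/pka_emboss.json`, "emboss" v1.0) is the EMBOSS *iep* default table;
every funnel report records which table was used. Published pI values for
real NCR peptides derive from a precomputed catalog whose pKa model is not
public, so no specific pI range is treated as a reference value here —
only the bisection/grid-scan agreement is.

**Charge classes.** Anionic at pI ≤ 6.5, cationic at pI ≥ 7.5 (both
boundaries inclusive), neutral between. The boundaries are a declared,
configurable choice; the source literature classifies peptides by charge
without stating numeric cutoffs.

**Funnel.** Stages are applied in sequence — signal-peptide annotation,
motif, nonzero expression, expression strictly above `min_total_reads`
(default 10,000, matching the published "more than 10,000 reads" wording,
so a gene at exactly 10,000 reads is excluded) — and the `FunnelReport`
stores the survivor count of each stage, which is monotone by
construction. The removed counts (pseudogene-like zero-read genes,
low-expression genes) are carried as separate fields because they are the
numbers such studies quote. Signal-peptide status is an input annotation
throughout; the package never predicts signal peptides.

## Guide design

Protospacers are 20-mers 5′ of an NGG PAM on either strand; reverse-strand
candidates are reported in plus-strand coordinates. The blunt cut sits
between protospacer positions 17 and 18 (3 bp 5′ of the PAM), standard
SpCas9 biochemistry. Ranking is lexicographic: cut strictly upstream of
the fourth-conserved-cysteine codon first (strict inequality; a cut *at*
the codon start does not disrupt the cysteines upstream of it), then 5′
base G > A > other (U6-type promoters initiate best on G, and a 5′-C
protospacer was observed to nearly abolish editing), then ascending
distance of the cut to the mature-peptide start, with start coordinate and
strand as documented tie-breaks so the order is total. Non-upstream
candidates are flagged, not dropped, since small genes may offer no
compliant site.

Off-target safety is the minimum Hamming distance between the protospacer
and every NGG-adjacent 20-mer in the genome, excluding the on-target
locus; a guide passes when that minimum is at least 2. Only NGG PAMs are
scanned (NAG scanning is a refinement of dedicated off-target tools, not
part of this rule) and gapped ("bulge") off-targets are not considered.
Sites never span FASTA record boundaries, so the count is invariant to
contig order and to splitting a genome into multiple records.

## Amplicon genotyping

**Alignment.** Reads are globally aligned to the amplicon with affine gap
scoring (match +2, mismatch −3, gap open −8, gap extend −1; a gap of
length L costs open + (L−1)·extend). The implementation delegates to
Biopython's `PairwiseAligner`; for equal-length reads with at most three
substitutions the gapless alignment is returned directly, which is
provably optimal under these scores because a gapped alignment of
equal-length sequences must open at least two gap runs (≥ 16 penalty,
more than three mismatches cost). Reads below 60% identity over the
alignment are discarded but counted. When several alignments are optimal
the aligner's first is used, which is deterministic for fixed inputs.

**Allele calling.** Alignment columns are reduced to runs of same-kind
operations; only operations intersecting the quantification window
(cut ± 10 bp, configurable) enter the edit signature — the window mirrors
CRISPResso2-like behaviour with an explicit, recorded choice, and it means
PCR or sequencing noise far from the cut cannot split alleles. A signature
with no in-window operations is wild type; one with any insertion or
deletion is an indel allele; otherwise it is mismatch-only.

**Allele tables.** Reads are de-duplicated before alignment. Signatures
below `min_allele_frequency` (default 1%) are pooled into an `other` row
that is counted in the total but excluded from classification *and from
the frequency normalisation*: named-allele frequencies are renormalised
over named rows. Reads leave their allele's row only through in-window
sequencing errors, which strike all alleles proportionally, so the
renormalised frequencies are unbiased estimates of the mixture — without
renormalisation every named frequency would be biased low by the in-window
error mass (about 2% of reads at the default error rates and window).

**Classification.** With wt = the WT row's (renormalised) frequency:
fully mutant when wt ≤ 0.05 — split into indel-only vs with-mismatch by
whether every retained mutant allele is an indel; else mutant-majority
when wt ≤ 0.50 ("max. 50% WT" is read as inclusive; configurable); else
chimeric if any retained mutant allele exists; else wild type. The 5%
fully-mutant ceiling is a declared stand-in for "very few wild-type
reads / trace contamination", recorded in every report and configurable.

**Consequences.** The edited CDS is built by applying the signature at the
cut-site offset and translated with the standard code to the first stop.
Frameshift is exactly (net indel mod 3 ≠ 0). The report counts the
identical N-terminal residues before divergence and the novel residues
before termination (the "chimeric peptide" description), gives the 1-based
stop position when a stop is reached, lists conserved cysteines that are
no longer cysteine *at their wild-type positions* (positional
conservation is what matters for these peptides, so an in-frame deletion
upstream of a cysteine counts it as lost even though the residue persists
downstream), and, for pure in-frame deletions, the deleted residues with
positions relative to the mature peptide. Edits touching the start codon
are flagged `start_lost` and not translated.

**Summary.** Per construct — and per phenotype label when any nodule is
scored — the table reports nodules sequenced, nodules at ≤ 50% WT, fully
mutant (mismatch/indel), fully mutant (indel only), and the percentage of
nodules carrying only indel alleles, rounded half-up to an integer percent
(7/15 prints as 47%).

## Trace decomposition

A chromatogram is one peak value per channel per position (no peak-shape
convolution — sufficient for shift decomposition). An allele with net
indel k contributes the control signal of position p−k at position p, so
the edited trace over the decomposition window is modelled as
Σₖ wₖ·control(p−k), k ∈ [−max_shift, +max_shift]. The window defaults to
cut+5 … cut+54 (skipping the heterogeneous junction, length 50, both
configurable), clipped so every shifted copy stays inside coverage.
Weights come from active-set non-negative least squares
(`scipy.optimize.nnls`, deterministic pivoting), are rounded to 1e-6, and
normalised to fractions; R² = 1 − SS_resid/SS_total (centered, clipped to
[0, 1]). The spectrum is invariant to a common rescaling of both traces.
An all-zero control window is a degenerate-input error.

## Synthetic generators

All generators are pure functions of spec + seed (`numpy.default_rng`).

* **Families** — signal peptides are 15–25 residues, ≥ 70% drawn from
  {A,L,V,I,F,M,W}, starting with M: a generator convenience only, not a
  model of real signal peptides. Motif-positive mature peptides are built
  around the exact spacing; motif-negative ones are resampled until the
  scanner rejects them, so generator labels agree with the scanner by
  construction. Expression classes (default 50% high / 45% low / 5% zero,
  means 50,000 / 2,000 / 0 reads) are chosen so a family straddles the
  10,000-read threshold with a wide margin on both sides.
* **Expression** — per-zone negative-binomial counts (dispersion 10)
  with default zone weights IID 0.15, IIP 0.20, IZ 0.40, ZIII 0.25
  summing to 1, emulating interzone-skewed nodule expression; the
  total-reads column is the row sum by construction.
* **Reads** — full-amplicon reads (merged ~200 bp amplicon sequencing);
  per-base substitution errors (default 1e-3) uniform over the three
  alternative bases and 1 bp indel errors (default 1e-4) placed uniformly:
  the simplest model that stresses the allele-collapsing logic. No quality
  modelling, no realistic Illumina error profile — qualities are written
  as a fixed Phred 40. The read→allele assignment is recorded in a truth
  sidecar, so recovery tests compare against the realised multinomial
  draw, not the nominal fractions.
* **Nodule designs** — mixtures are sampled with wild-type fractions kept
  ≥ 0.02 away from the 0.05 and 0.50 classification thresholds and mutant
  alleles ≥ 6% with distinct net indel sizes, so each design maps
  unambiguously to one intended genotype at 5,000 reads.
* **Traces** — the edited trace is the exact weighted sum of shifted
  control traces (the shift applied across the whole trace; the
  decomposition window lies downstream of the cut where the pure-shift
  model is the right description either way), plus zero-truncated Gaussian
  noise on the edited trace only, so the zero-noise identity mixture
  reproduces the control byte-for-byte.
* **Decoy genomes** — the on-target site plus decoys at exact Hamming
  distances, alternating strands, embedded in random background; a random
  20-mer is ~15 mismatches from any fixed protospacer, so background sites
  never undercut planted distances in practice.

Because these generators are deliberately simple, passing recovery tests
shows the *logic* of the pipeline is correct at the stated noise levels;
it does not certify performance on real Illumina error profiles, real
chromatogram peak shapes, or real signal peptides.

## Problem sizes and determinism

The shipped tests and the acceptance script use a 200 bp amplicon with
100 simulated nodules × 5,000 reads, 500-gene families, 1,000–10,000-case
oracle comparisons and 100-seed noise sweeps — sizes at which every
stochastic check is far from its threshold (e.g. allele-frequency RMSE
≈ 0.002 against a 0.01 bound) while the whole suite runs in well under a
minute per stage. All randomness flows through explicit seeds; rerunning
any generator or test with the same seed reproduces its output exactly.

## Known limitations

* Signal-peptide prediction, six-cysteine NCRs, orthology screening and
  on-target efficiency scores (Doench/CFD etc.) are out of scope.
* Off-target search counts mismatches only (no bulges, NGG only).
* Genotyping assumes single-end, pre-merged reads; no UMI handling, no
  base-quality-aware calling, no HDR allele classes.
* Trace decomposition reports no per-shift p-values and reads TSV traces,
  not AB1 files.
* The published funnel totals for the real NCR catalog (679 → 248 → 172)
  are not reproducible here because the catalog and the laser-capture
  RNAseq table are not public; the funnel is instead validated against
  generator ground truth.
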