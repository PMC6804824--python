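# Methods

This note documents the models and estimators scentvar implements, the
parameters that matter, the design of the synthetic study conditions, and the
numerical choices a maintainer would want to know about. It states nothing
the test suite or `scripts/acceptance.py` does not itself compute.

## Volatile quantification and aroma classification

Quantification uses the standard internal-standard ratio: for compound *c*
with peak area *A_c*, internal standard of known amount *m_IS* (μg) and peak
area *A_IS*, and fresh sample weight *w* (g),

    content_c = (A_c · m_IS / A_IS) / w      [μg/g]

Relative percentages are computed over the sum of contents; by linearity they
are equally computable from raw areas. Contents are linear in each compound's
area and invariant to rescaling all areas (including the internal
standard's) by a common factor — both are property-tested. Compounds absent
from a sample are peak area 0, not missing. Reported tables round percentages
to 2 decimals; internal math is full precision.

Odor-class aggregation sums compound percentages into five classes (herbal,
fruity, cool, floral, spicy) through an editable CSV map
(`src/scentvar/data/odor_map.csv`). The shipped map covers the sixteen major
lily scent compounds; assignments follow common odor descriptors (eucalyptol
→ cool, linalool → floral, esters and benzoates → fruity, monoterpene
hydrocarbons → herbal, caryophyllene → spicy) and are deliberately
configuration, not code. A compound missing from the map contributes to no
class and is reported in a side list, so class sums plus the unmapped share
always total 100% of a non-empty profile.

Aroma grouping is an ordered decision list over the five class percentages
and the total content (`src/scentvar/data/aroma_rules.yaml`):

1. faint if total < 1.0 μg/g
2. cool if cool ≥ 40 and fruity < 20
3. musky if cool ≥ 20 and cool+fruity ≥ 55
4. lily if herbal ≥ 20 and fruity ≥ 35
5. fruity if fruity ≥ 55 and cool < 5
6. fruity-honey if fruity ≥ 40
7. otherwise unassigned.

Published six-group cultivar classifications are not a pure function of the
five class percentages (cultivars with near-identical cool shares appear in
different groups, because sensory assessment and parentage also informed the
published grouping), so no threshold set can reproduce every published label.
The strict-fruity rule is ordered before fruity-honey so that
ester-dominated, eucalyptol-free profiles (e.g. 87.7% fruity / 2.2% cool)
classify as fruity rather than fruity-honey; profiles with a substantial cool
component fall through to musky or fruity-honey as appropriate. The list is a
best-effort default, meant to be edited, and is not treated as a validated
classifier.

## Variant calling on near-identical cDNA panels

Queries are aligned to a single designated reference ORF by global pairwise
alignment (Biopython `PairwiseAligner`) with match +2, mismatch −3, gap open
−10, gap extend −0.5. The panels this tool targets differ by isolated SNPs
and one or two block InDels, so results are insensitive to the exact scores;
the strong gap-open penalty keeps block InDels contiguous. Ties between
co-optimal alignments resolve to the aligner's deterministic first
traceback; reproducible variant coordinates come not from the tie-break but
from VCF-style left-normalization — every InDel is shifted to its 5′-most
equivalent position, without crossing another variant's position (crossing a
SNP would change the reconstructed sequence). The round-trip law — applying
the called variants to the reference reconstructs the query byte-exactly —
is asserted over 1,000 random mutants in the acceptance checks and in a
property test.

Panels are cataloged pairwise against the reference and merged by normalized
(position, kind, alleles); no consensus multiple alignment is built, which is
exact for panels of this structure and much easier to audit. Panel entries
are treated as ORF clones and aligned as-is — a nonsense SNP in a cultivar
must not truncate its alignment. Sites whose alleles include the ambiguity
code N are excluded from the catalogue and reported separately.

Coding effects compare reference and mutated codons under the standard
genetic code (stop-gain counts as nonsynonymous); InDels are inframe when
their length is divisible by 3, else frameshift. Coordinates are 1-based on
the reference ORF, matching the convention in which the diagnostic insertion
sits at position 230 and the diagnostic deletion at 873; output headers state
the convention.

Isoform grouping is signature-based: a 12-bp insertion marks the long
isoform class (LTPS-2-like), a 114-bp deletion the short class (LTPS-3-like),
neither the reference class; both at once is an error, as no such molecule is
expected.

Motif patterns (configurable): RRX8W = `RR.{8}W` beginning within the first
80 residues; RX8W = `R.{8}W` outside the RRX8W hit (the larger motif nests
the smaller); DDXXD = `DD..D`; NSE/DTE = `[ND]D..[ST]...E`, which should be
treated as provisional since the motif is named in the literature but not
standardized as a regular expression. When RRX8W is found downstream of
residue 1, the upstream region is reported as the candidate plastid transit
peptide.

## Diversity statistics

For a panel of n equal-length haplotypes: π is the mean over all n(n−1)/2
unordered pairs of (pairwise differences / sites compared); Hd is the
unbiased estimator n/(n−1)·(1 − Σ pᵢ²) over distinct sequences (exact string
equality); S counts columns with ≥ 2 distinct non-missing bases. Gaps and N
are missing. The default missing-data policy is pairwise deletion (each pair
compared over its mutually observed sites) because it uses the most data;
complete deletion is available by flag, and the policy used is recorded in
output metadata, since the published tables do not state which their software
used. Summary tables round π to 3 decimals and Hd to 2, mirroring the
published formatting; machine outputs keep full precision.

Within-group statistics are computed on each group's own full-length ORF
alignment. The group-defining block InDels are shared by construction within
a group, so columns are well-defined without masking; this matches counting
SNP sites on each isoform class's own ORF.

With two sequences and no missing data, π = S/L exactly; with two distinct
haplotypes Hd = 1 exactly — both are used as desk checks.

## Splice mapping

The mapper is an exact dynamic program over (genomic position i, cDNA
position j) with two transitions: align the next cDNA base (match +1000,
mismatch −2500) or skip a genomic block of ≥ `min_intron` (default 40) nt
between consecutive cDNA bases, paying an intron penalty (5000) and earning
+100 for a GT donor and +100 for an AG acceptor. The bookkeeping scores are
two orders of magnitude below the match score, so splice-site preference can
never trade away an aligned base, a spurious intron can never substitute for
a single mismatch (5000 > 3500), and among equal-coverage boundary
placements the GT-AG-canonical one wins; remaining ties resolve 5′-most
(earliest donor in the prefix-maximum, diagonal preferred in traceback).
The program is O(n·m) time vectorized per cDNA column and O(n·m) memory for
traceback pointers — for a ~2.7-kb locus and ~1.8-kb cDNA about 5 M cells,
well under a second. An anchor-and-chain heuristic was considered and
rejected: at this problem size the exact DP is faster to verify and
implements the boundary tie-break directly rather than as a post-hoc repair.

Exon coordinates are 1-based inclusive on the forward strand; callers must
reverse-complement reverse-strand input themselves. Mapping tolerates up to
`max_mismatch` (default 2) mismatches per exon and fails beyond that with
the best partial chain attached; when no mismatches were tolerated, the
spliced exon concatenation is asserted byte-equal to the cDNA on every call.

Isoform comparison is coordinate-based on a shared locus: with equal intron
counts, a moved donor is an alternative 5′ site (Δnt = query donor −
canonical donor, i.e. exonic nt gained), a moved acceptor an alternative 3′
site (Δnt = canonical acceptor − query acceptor); with unequal counts the
tool reports intron retention (canonical intron inside a query exon) and
exon skipping (canonical exon inside a query intron). Δnt is antisymmetric
under swapping the two models.

## Gray relational analysis

Orientation follows the association question "which sites co-vary with this
compound": each compound's cultivar series is the reference, each site's 0/1
incidence series a comparison. Min-max normalization is applied per series —
the only preprocessing that makes binary site vectors commensurate with
continuous emissions; mean normalization is available for sensitivity
analysis and recorded in output metadata. Δmin and Δmax are taken over all
comparison series and points for a given reference. ρ defaults to 0.5
(Deng's conventional value; exposed as a flag). GRD(x, x) = 1 exactly; GRD is
non-decreasing in ρ and invariant under positive affine transforms of any
input series — both property-tested. The statistic is undefined in the
degenerate case Δ ≡ 0 up to floating-point noise (handled exactly for true
equality). Constant site columns carry no contrast and are excluded with a
flag; constant compound columns yield NaN. Cultivars missing either a
sequence or an emission record must be dropped listwise before building the
matrices. No significance test is attached to GRD: it is a similarity
ordering, not an inferential statistic.

## Synthetic study conditions

The generator emulates the system under study with recognizable dimensions,
all configurable:

* locus: 7 exons (229, 300, 343, 300, 250, 200, 139 nt; ORF 1761 nt) and six
  150-nt GT-AG introns → 2661-nt locus;
* isoforms: an alternative 5′ donor 12 nt into intron 1 (insertion at ORF
  position 230, ORF 1773 nt → 590 aa) and an alternative 3′ acceptor 114 nt
  into exon 4 (deletion at position 873, ORF 1647 nt → 548 aa); both offsets
  are validated frame-preserving, and the alternative sites are planted as
  canonical GT / AG so both splice forms obey the GT-AG rule;
* motifs: RRX8W at residues 21–31, RX8W at 301–310 — inside the deleted
  block, so the short isoform's translation loses it while keeping RRX8W,
  DDXXD (351–355) and the NSE/DTE-like motif (481–489). Random codons are
  drawn from the 60 sense codons excluding tryptophan, so R-x8-W scans hit
  only where planted (a uniform 548-residue protein would otherwise contain
  ~0.6 chance matches and make absence assertions meaningless);
* panels: default 23 cultivars (the size of an emission-plus-sequence
  panel), independent per-site substitution at 0.005/site with a uniform
  alternative base, plus a 12-bp-insertion carrier genotype at frequency 0.3
  — high enough to keep a binary vector non-degenerate at n = 23;
* emissions: five monoterpene compounds at baseline 2.0 μg/g with Gaussian
  noise (σ = 0.5 μg/g), the causal compound adding effect_size × genotype
  with effect 1.5 μg/g (3σ), truncated at zero; peak tables are
  back-computed so internal-standard quantification recovers the intended
  contents exactly.

Under this substitution model the expected nucleotide diversity is
E[π] = 2p(1−p) + (2/3)p², i.e. ≈ 0.00997 at p = 0.005 — deliberately in the
range of the published panel-level estimate (π ≈ 0.010 for the largest
isoform group). The calibration check simulates 200 panels and requires the
mean π within 3 standard errors of this closed form.

Isoform construction redraws codon content deterministically (bounded
retries off the seeded stream) if either alternative splice junction creates
an in-frame stop. All randomness flows from one `numpy` generator per run;
identical seed and configuration reproduce byte-identical fixture files
(tested).

What the generator does **not** emulate: GC-MS noise structure (co-eluting
peaks, baseline drift), linkage between sites (all substitutions are
independent, so there is no haplotype structure or population
stratification), back-mutation, codon usage bias beyond the no-tryptophan
constraint, and sensory variability in aroma labels. Passing tests therefore
demonstrate correctness of the computations under clean, planted conditions,
not robustness to real instrument or population artifacts.

## Problem sizes in the checks

The acceptance script and heavyweight tests use: 1,000 mutated pairs for the
variant-calling round trip on the 1761-nt reference; 200 replicate panels
(23 × 1761) for the π calibration; 100 replicate studies for the
planted-association ranking; 1,000 random instances for ρ-monotonicity; and
three seeds for exact splice recovery. These sizes give stable statistics
(the 3-SE and ≥90/100 margins) while the whole suite stays in the
couple-of-minutes range.

## Known limitations

* The aroma decision list approximates a partly sensory classification and
  should not be used as ground truth for group labels.
* Pairwise-to-reference variant calling assumes a panel of near-identical
  sequences; it is not a general small-variant caller.
* The splice mapper is a single-gene tool (forward strand, one locus); it is
  not a genome-scale spliced aligner and does not model branch points or
  polypyrimidine tracts.
* GRD magnitudes depend on the normalization and ρ; cross-study comparisons
  of absolute GRD values are only meaningful under identical preprocessing,
  which is why both knobs are recorded in every output.
* Homology percentages between isoform classes are not reported: their
  published definition (gap treatment) is ambiguous.
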