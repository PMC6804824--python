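"""SNP/InDel calling on near-identical monoterpene-synthase cDNA panels.

Queries are globally aligned to a designated reference ORF with affine gap
penalties; mismatch columns become SNPs and contiguous gap runs become single
insertion/deletion records, left-normalized VCF-style so positions are
reproducible.  Applying the called variants to the reference reconstructs the
query byte-exactly.  Coding effects are annotated under the standard genetic
code, cDNAs are binned into isoform groups by their diagnostic block InDels
(a 12-bp insertion marks the long isoform, a 114-bp deletion the short one),
and translated proteins are scanned for terpene-synthase motifs
(RRX8W, RX8W, DDXXD, NSE/DTE).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}


class OrfNotFound(ValueError):
    pass


class VariantError(ValueError):
    pass


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}, uppercase canonical."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: non-nucleotide characters {sorted(bad)}")


@dataclass
class Orf:
    """An ATG-initiated open reading frame ending in a stop codon.

    ``start``/``end`` are 1-based inclusive on the source sequence; ``protein``
    is the translation without the terminal stop.
    """

    start: int
    end: int
    seq: str
    protein: str

    def __post_init__(self) -> None:
        if len(self.seq) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if not self.seq.startswith("ATG"):
            raise ValueError("ORF must begin with ATG")
        if self.seq[-3:] not in STOP_CODONS:
            raise ValueError("ORF must end with a stop codon")


@dataclass
class Variant:
    """One SNP or InDel in 1-based reference-ORF coordinates.

    SNP: single-base ``ref_allele``/``alt_allele`` at ``pos``.
    Insertion: empty ``ref_allele``; ``alt_allele`` inserted so that its first
    base sits at reference position ``pos`` (i.e. before the base currently at
    ``pos``).  Deletion: empty ``alt_allele``; ``ref_allele`` starts at ``pos``.
    """

    ref_id: str
    pos: int
    kind: str  # "SNP" | "insertion" | "deletion"
    ref_allele: str
    alt_allele: str
    effect: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise VariantError("SNP alleles must be single bases")
        elif self.kind == "insertion":
            if self.ref_allele != "" or not self.alt_allele:
                raise VariantError("insertion must have empty ref_allele")
        elif self.kind == "deletion":
            if self.alt_allele != "" or not self.ref_allele:
                raise VariantError("deletion must have empty alt_allele")
        else:
            raise VariantError(f"unknown variant kind {self.kind!r}")

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))

    def key(self) -> tuple:
        return (self.pos, self.kind, self.ref_allele, self.alt_allele)


@dataclass
class IsoformGroupLabel:
    label: str  # "LTPS-1" | "LTPS-2" | "LTPS-3"
    evidence: list[Variant] = field(default_factory=list)


@dataclass
class MotifHit:
    motif_name: str
    start: int  # 1-based residue
    end: int  # 1-based inclusive
    matched: str


def find_orf(record: SequenceRecord) -> Orf:
    """Longest ATG-initiated ORF ending in a stop codon; ties go leftmost."""
    seq = record.seq
    n = len(seq)
    # per-frame sorted stop positions for O(log n) next-stop lookup
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(n - 2):
        if seq[i : i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    best: tuple[int, int] | None = None  # (-length, start) minimised
    import bisect

    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        stops = stops_by_frame[i % 3]
        j = bisect.bisect_left(stops, i + 3)
        if j == len(stops):
            continue
        stop = stops[j]
        length = stop + 3 - i
        cand = (-length, i)
        if best is None or cand < best:
            best = cand
    if best is None:
        raise OrfNotFound(f"{record.id}: no complete ATG-initiated ORF found")
    length, start = -best[0], best[1]
    orf_seq = seq[start : start + length]
    protein = str(Seq(orf_seq[:-3]).translate())
    return Orf(start=start + 1, end=start + length, seq=orf_seq, protein=protein)


def make_aligner(
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair(ref_seq: str, query_seq: str, aligner: PairwiseAligner | None = None):
    """Optimal global alignment; returns (gapped_ref, gapped_query)."""
    if not ref_seq or not query_seq:
        raise ValueError("align_pair requires non-empty sequences")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(ref_seq, query_seq)[0]
    return str(aln[0]), str(aln[1])


def _left_normalize_insertion(ref: str, pos: int, alt: str, blocked: set[int]) -> tuple[int, str]:
    # insertion sits before ref position `pos`; rotate 5'-ward through repeats
    while pos > 1 and alt[-1] == ref[pos - 2] and (pos - 1) not in blocked:
        alt = ref[pos - 2] + alt[:-1]
        pos -= 1
    return pos, alt


def _left_normalize_deletion(ref: str, pos: int, length: int, blocked: set[int]) -> int:
    while pos > 1 and ref[pos - 2] == ref[pos + length - 2] and (pos - 1) not in blocked:
        pos -= 1
    return pos


def call_variants(
    ref: str | Orf,
    query: str | Orf,
    ref_id: str = "ref",
    aligner: PairwiseAligner | None = None,
) -> list[Variant]:
    """Call SNPs and left-normalized InDels from a global pairwise alignment.

    Sites where either allele is the ambiguity code N are excluded from the
    returned catalogue (see :func:`call_variants_with_ambiguous` to retrieve
    them).  Round trip: ``apply_variants(ref, call_variants(ref, q)) == q``.
    """
    variants, _ = call_variants_with_ambiguous(ref, query, ref_id, aligner)
    return variants


def call_variants_with_ambiguous(
    ref: str | Orf,
    query: str | Orf,
    ref_id: str = "ref",
    aligner: PairwiseAligner | None = None,
) -> tuple[list[Variant], list[Variant]]:
    ref_seq = ref.seq if isinstance(ref, Orf) else ref
    query_seq = query.seq if isinstance(query, Orf) else query
    gref, gquery = align_pair(ref_seq, query_seq, aligner)

    raw: list[Variant] = []
    rpos = 0  # reference bases consumed
    i = 0
    ncol = len(gref)
    while i < ncol:
        a, b = gref[i], gquery[i]
        if a != "-" and b != "-":
            rpos += 1
            if a != b:
                raw.append(Variant(ref_id, rpos, "SNP", a, b))
            i += 1
        elif a == "-":  # insertion run in query
            j = i
            while j < ncol and gref[j] == "-":
                j += 1
            alt = gquery[i:j]
            raw.append(Variant(ref_id, rpos + 1, "insertion", "", alt))
            i = j
        else:  # deletion run from reference
            j = i
            while j < ncol and gquery[j] == "-":
                j += 1
            ref_run = gref[i:j]
            raw.append(Variant(ref_id, rpos + 1, "deletion", ref_run, ""))
            rpos += len(ref_run)
            i = j

    # left-normalize indels without crossing other variant positions
    snp_positions = {v.pos for v in raw if v.kind == "SNP"}
    out: list[Variant] = []
    for v in raw:
        if v.kind == "insertion":
            pos, alt = _left_normalize_insertion(ref_seq, v.pos, v.alt_allele, snp_positions)
            out.append(Variant(v.ref_id, pos, "insertion", "", alt))
        elif v.kind == "deletion":
            pos = _left_normalize_deletion(ref_seq, v.pos, len(v.ref_allele), snp_positions)
            ref_run = ref_seq[pos - 1 : pos - 1 + len(v.ref_allele)]
            out.append(Variant(v.ref_id, pos, "deletion", ref_run, ""))
        else:
            out.append(v)
    out.sort(key=lambda v: (v.pos, v.kind))
    is_ambiguous = lambda v: "N" in v.ref_allele or "N" in v.alt_allele
    clean = [v for v in out if not is_ambiguous(v)]
    ambiguous = [v for v in out if is_ambiguous(v)]
    return clean, ambiguous


def apply_variants(ref: str, variants: list[Variant]) -> str:
    """Apply SNPs/InDels (reference coordinates) to rebuild the query."""
    seq = list(ref)
    # right-to-left so earlier coordinates stay valid; at an equal position
    # the insertion goes last (it sits 5' of the base a SNP/deletion edits)
    for v in sorted(variants, key=lambda v: (-v.pos, v.kind == "insertion")):
        idx = v.pos - 1
        if v.kind == "SNP":
            if seq[idx] != v.ref_allele:
                raise VariantError(f"ref mismatch at {v.pos}: {seq[idx]} != {v.ref_allele}")
            seq[idx] = v.alt_allele
        elif v.kind == "insertion":
            seq[idx:idx] = list(v.alt_allele)
        else:
            if "".join(seq[idx : idx + len(v.ref_allele)]) != v.ref_allele:
                raise VariantError(f"ref mismatch for deletion at {v.pos}")
            del seq[idx : idx + len(v.ref_allele)]
    return "".join(seq)


def annotate_effect(ref: Orf, variant: Variant) -> str:
    """Coding effect of a variant inside the reference ORF.

    SNPs are synonymous/nonsynonymous by codon comparison under the standard
    code; InDels are inframe_indel when their length is divisible by 3, else
    frameshift.
    """
    if not 1 <= variant.pos <= len(ref.seq):
        raise VariantError(f"variant position {variant.pos} outside ORF of length {len(ref.seq)}")
    if variant.kind != "SNP":
        return "inframe_indel" if variant.length % 3 == 0 else "frameshift"
    codon_idx = (variant.pos - 1) // 3
    offset = (variant.pos - 1) % 3
    codon = ref.seq[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:
        raise VariantError(f"variant at {variant.pos} overlaps a truncated terminal codon")
    mutated = codon[:offset] + variant.alt_allele + codon[offset + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def annotate_all(ref: Orf, variants: list[Variant]) -> list[Variant]:
    for v in variants:
        v.effect = annotate_effect(ref, v)
    return variants


def assign_isoform_group(
    variants: list[Variant],
    insertion_len: int = 12,
    deletion_len: int = 114,
) -> IsoformGroupLabel:
    """Bin a cDNA by its diagnostic block InDels relative to the LTPS-1-type reference.

    A 12-bp insertion marks LTPS-2, a 114-bp deletion marks LTPS-3, neither
    marks LTPS-1; both present is a conflict and raises.
    """
    ins = [v for v in variants if v.kind == "insertion" and v.length == insertion_len]
    dele = [v for v in variants if v.kind == "deletion" and v.length == deletion_len]
    if ins and dele:
        raise VariantError(
            "conflicting isoform signature: both the diagnostic insertion and deletion present"
        )
    if ins:
        return IsoformGroupLabel("LTPS-2", ins)
    if dele:
        return IsoformGroupLabel("LTPS-3", dele)
    return IsoformGroupLabel("LTPS-1", [])


# Default motif patterns.  The NSE/DTE pattern is provisional: the motif is
# named in the literature but not printed as a regular expression.
DEFAULT_MOTIFS: list[dict] = [
    {"name": "RRX8W", "pattern": r"RR.{8}W", "max_start": 80},
    {"name": "RX8W", "pattern": r"R.{8}W", "exclude_overlap": "RRX8W"},
    {"name": "DDXXD", "pattern": r"DD..D"},
    {"name": "NSE/DTE", "pattern": r"[ND]D..[ST]...E"},
]


def scan_motifs(protein: str, patterns: list[dict] | None = None) -> list[MotifHit]:
    """Non-overlapping leftmost matches of each configured motif pattern.

    A hit for a pattern with ``max_start`` must begin within the first
    ``max_start`` residues; a pattern with ``exclude_overlap`` drops matches
    overlapping any hit of the named earlier motif (RX8W is nested inside
    RRX8W and only reported as a separate, downstream occurrence).  If an
    RRX8W hit exists, the region upstream of it is reported as
    ``transit_region`` (plastid transit peptide candidate).
    """
    if not protein:
        raise ValueError("scan_motifs requires a non-empty protein")
    if patterns is None:
        patterns = DEFAULT_MOTIFS
    hits: list[MotifHit] = []
    by_name: dict[str, list[MotifHit]] = {}
    for spec_ in patterns:
        try:
            rx = re.compile(spec_["pattern"])
            name = spec_["name"]
        except (re.error, KeyError, TypeError) as exc:
            raise ValueError(f"malformed motif pattern {spec_!r}") from exc
        found: list[MotifHit] = []
        for m in rx.finditer(protein):
            start, end = m.start() + 1, m.end()
            if "max_start" in spec_ and start > spec_["max_start"]:
                continue
            if "exclude_overlap" in spec_:
                prior = by_name.get(spec_["exclude_overlap"], [])
                if any(h.start <= end and start <= h.end for h in prior):
                    continue
            found.append(MotifHit(name, start, end, m.group(0)))
        by_name[name] = found
        hits.extend(found)
    rr = by_name.get("RRX8W", [])
    if rr and rr[0].start > 1:
        hits.append(MotifHit("transit_region", 1, rr[0].start - 1, protein[: rr[0].start - 1]))
    hits.sort(key=lambda h: (h.start, h.end, h.motif_name))
    return hits


def catalogue_panel(
    ref: Orf,
    queries: list[SequenceRecord],
    ref_id: str = "ref",
    aligner: PairwiseAligner | None = None,
) -> tuple[list[Variant], dict[str, list[Variant]], dict[str, IsoformGroupLabel]]:
    """Call every query against the single reference and merge the catalogues.

    Returns (merged catalogue sorted by position, per-query variant lists,
    per-query isoform group labels).  Merging is by normalized
    (pos, kind, alleles); no consensus multiple alignment is built, which is
    exact for panels differing by isolated SNPs and block InDels.
    """
    per_query: dict[str, list[Variant]] = {}
    groups: dict[str, IsoformGroupLabel] = {}
    merged: dict[tuple, Variant] = {}
    for rec in queries:
        # panel entries are ORF clones: align the record as-is rather than
        # re-finding an ORF (a nonsense SNP must not truncate the alignment)
        variants = call_variants(ref, rec.seq, ref_id=ref_id, aligner=aligner)
        annotate_all(ref, variants)
        per_query[rec.id] = variants
        groups[rec.id] = assign_isoform_group(variants)
        for v in variants:
            merged.setdefault(v.key(), v)
    catalogue = sorted(merged.values(), key=lambda v: (v.pos, v.kind, v.alt_allele))
    return catalogue, per_query, groups
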