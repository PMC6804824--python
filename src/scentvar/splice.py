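"""Spliced mapping of cDNA isoforms onto a single genomic locus.

The mapper is an exact dynamic program over (genomic position, cDNA position)
with two move types: consume one aligned base pair (match/mismatch), or skip a
genomic block of at least ``min_intron`` nt between two consecutive cDNA bases
(an intron).  Intron skips pay a fixed penalty and earn small bonuses when the
skipped block starts with GT and ends with AG, so among equal-coverage
boundary placements the GT-AG-canonical one wins; remaining ties resolve to
the 5'-most placement.  Bonuses and penalties are two orders of magnitude
smaller than the match score, so splice-site preference can never trade away
an aligned base.

Exon coordinates are 1-based inclusive on the forward strand of the locus;
reverse-strand input must be reverse-complemented by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import SequenceRecord

# scoring: primary signal is match/mismatch; intron bookkeeping is sub-match-scale
_MATCH = 1000
_MISMATCH = -2500
_INTRON_PEN = 5000
_CANON_BONUS = 100
_NEG = -(10**9)


class SpliceMapError(ValueError):
    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass
class SpliceParams:
    min_intron: int = 40
    max_mismatch: int = 2  # per exon


@dataclass
class Intron:
    start: int  # 1-based inclusive on gDNA
    end: int
    donor: str  # first two intron bases
    acceptor: str  # last two intron bases

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_gt_ag(self) -> bool:
        return self.donor == "GT" and self.acceptor == "AG"


@dataclass
class GeneModel:
    """Exon/intron structure of one transcript on the genomic locus."""

    gdna_id: str
    cdna_id: str
    exons: list[tuple[int, int]]
    introns: list[Intron]
    n_mismatches: int = 0
    mismatch_positions: list[int] = field(default_factory=list)  # gDNA coords

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 <= e1 < s2 <= e2):
                raise ValueError("exons must be strictly increasing and non-overlapping")
        if self.introns and len(self.introns) != len(self.exons) - 1:
            raise ValueError("intron count must equal exon count - 1")

    def spliced_sequence(self, gdna_seq: str) -> str:
        return "".join(gdna_seq[s - 1 : e] for s, e in self.exons)


@dataclass
class SpliceEvent:
    kind: str  # alt_5prime | alt_3prime | exon_skip | intron_retention
    intron_index: int  # 1-based on the canonical model
    delta_nt: int  # exonic nt gained (+) or lost (-) by the query isoform


def map_cdna(
    gdna: SequenceRecord,
    cdna: SequenceRecord,
    params: SpliceParams | None = None,
) -> GeneModel:
    """Infer the exon chain of ``cdna`` on ``gdna``.

    Raises :class:`SpliceMapError` (with the best partial chain attached) when
    the cDNA cannot be placed within the mismatch tolerance.
    """
    if params is None:
        params = SpliceParams()
    g, c = gdna.seq, cdna.seq
    n, m = len(g), len(c)
    if m > n:
        raise SpliceMapError(f"{cdna.id}: cDNA ({m} nt) longer than locus ({n} nt)")
    min_intron = params.min_intron

    garr = np.frombuffer(g.encode(), dtype=np.uint8)
    # donor bonus for an intron starting at 0-based i'; acceptor bonus for a
    # transition landing on g[i-1] (intron last base g[i-2], acceptor g[i-3:i-1])
    donor = np.zeros(n + 1, dtype=np.int64)
    donor[:-1][(garr == ord("G")) & (np.roll(garr, -1) == ord("T"))] = _CANON_BONUS
    if n >= 1:
        donor[n - 1] = 0  # no room for a dinucleotide at the last base
    acceptor = np.zeros(n + 1, dtype=np.int64)
    ag = (garr == ord("A")) & (np.roll(garr, -1) == ord("G"))
    for i in range(3, n + 1):
        if ag[i - 3]:
            acceptor[i] = _CANON_BONUS

    prev = np.zeros(n + 1, dtype=np.int64)  # column j=0: free leading gDNA
    cur = np.empty(n + 1, dtype=np.int64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    donor_idx = np.zeros((n + 1, m + 1), dtype=np.int32)
    idx = np.arange(n + 1)

    for j in range(1, m + 1):
        base = ord(c[j - 1])
        s_col = np.where(garr == base, _MATCH, _MISMATCH).astype(np.int64)  # for i-1
        cur[0] = _NEG
        diag = np.empty(n + 1, dtype=np.int64)
        diag[0] = _NEG
        diag[1:] = prev[:-1] + s_col
        if j >= 2:
            A = prev + donor
            racc = np.maximum.accumulate(A)
            inc = np.empty(n + 1, dtype=bool)
            inc[0] = True
            inc[1:] = A[1:] > racc[:-1]
            arg = np.maximum.accumulate(np.where(inc, idx, 0))
            intron_val = np.full(n + 1, _NEG, dtype=np.int64)
            dsrc = np.zeros(n + 1, dtype=np.int32)
            t = idx - 1 - min_intron
            valid = t >= 1
            iv = np.where(valid, racc[np.clip(t, 0, n)], _NEG)
            intron_val[1:] = np.where(
                valid[1:],
                iv[1:] + acceptor[1:] - _INTRON_PEN + s_col,
                _NEG,
            )
            dsrc[1:] = np.where(valid[1:], arg[np.clip(t, 0, n)][1:], 0)
            take_intron = intron_val > diag  # strict: ties prefer diagonal (5'-most intron)
            cur[:] = np.where(take_intron, intron_val, diag)
            ptr[:, j] = take_intron
            donor_idx[:, j] = np.where(take_intron, dsrc, 0)
        else:
            cur[:] = diag
            ptr[:, j] = 0
        cur[0] = _NEG
        prev, cur = cur.copy(), prev

    final = prev
    best_i = int(np.argmax(final))  # first (5'-most) maximiser on ties
    if final[best_i] <= _NEG // 2:
        raise SpliceMapError(f"{cdna.id}: no spliced placement found on {gdna.id}")

    # backtrace
    pairs: list[tuple[int, int]] = []  # (0-based g index, 0-based c index)
    i, j = best_i, m
    while j > 0:
        pairs.append((i - 1, j - 1))
        if ptr[i, j]:
            i = int(donor_idx[i, j])
        else:
            i -= 1
        j -= 1
    pairs.reverse()

    exons: list[tuple[int, int]] = []
    start_g = pairs[0][0]
    prev_g = start_g
    for gpos, _ in pairs[1:]:
        if gpos != prev_g + 1:
            exons.append((start_g + 1, prev_g + 1))
            start_g = gpos
        prev_g = gpos
    exons.append((start_g + 1, prev_g + 1))

    introns = [
        Intron(
            start=e1 + 1,
            end=s2 - 1,
            donor=g[e1 : e1 + 2],
            acceptor=g[s2 - 3 : s2 - 1],
        )
        for (_, e1), (s2, _) in zip(exons, exons[1:])
    ]

    mismatch_pos = [gpos + 1 for gpos, cpos in pairs if g[gpos] != c[cpos]]
    model = GeneModel(
        gdna_id=gdna.id,
        cdna_id=cdna.id,
        exons=exons,
        introns=introns,
        n_mismatches=len(mismatch_pos),
        mismatch_positions=mismatch_pos,
    )

    # per-exon mismatch tolerance
    for k, (s, e) in enumerate(exons, 1):
        bad = sum(1 for p in mismatch_pos if s <= p <= e)
        if bad > params.max_mismatch:
            raise SpliceMapError(
                f"{cdna.id}: exon {k} has {bad} mismatches (> {params.max_mismatch}); "
                "cDNA not mappable within tolerance",
                partial=model,
            )
    # exon-concatenation identity (byte-exact when no mismatches were tolerated)
    spliced = model.spliced_sequence(g)
    if model.n_mismatches == 0:
        assert spliced == c, "spliced exons must reproduce the cDNA byte-exactly"
    else:
        assert len(spliced) == len(c)
    return model


def compare_isoforms(canonical: GeneModel, other: GeneModel) -> list[SpliceEvent]:
    """Classify splicing differences of ``other`` relative to ``canonical``.

    Donor moved -> alt_5prime, acceptor moved -> alt_3prime (delta_nt is the
    exonic nt the query gains (+) or loses (-)); a canonical exon absent ->
    exon_skip; a canonical intron transcribed in the query -> intron_retention.
    """
    if canonical.gdna_id != other.gdna_id:
        raise ValueError(
            f"models on different loci: {canonical.gdna_id!r} vs {other.gdna_id!r}"
        )
    events: list[SpliceEvent] = []
    if len(canonical.introns) == len(other.introns):
        for k, (ci, oi) in enumerate(zip(canonical.introns, other.introns), 1):
            if oi.start != ci.start:
                events.append(SpliceEvent("alt_5prime", k, oi.start - ci.start))
            if oi.end != ci.end:
                events.append(SpliceEvent("alt_3prime", k, ci.end - oi.end))
        return events

    canon_keys = {(i.start, i.end) for i in canonical.introns}
    other_keys = {(i.start, i.end) for i in other.introns}
    # canonical intron retained (transcribed) in the query
    for k, ci in enumerate(canonical.introns, 1):
        if (ci.start, ci.end) not in other_keys and any(
            s <= ci.start and ci.end <= e for s, e in other.exons
        ):
            events.append(SpliceEvent("intron_retention", k, ci.length))
    # canonical exon skipped: fully inside a query intron
    for ex_s, ex_e in canonical.exons:
        for k, oi in enumerate(other.introns, 1):
            if oi.start <= ex_s and ex_e <= oi.end and (oi.start, oi.end) not in canon_keys:
                idx = min(k, len(canonical.introns))
                events.append(SpliceEvent("exon_skip", idx, -(ex_e - ex_s + 1)))
                break
    return events


def validate_canonical_sites(model: GeneModel) -> list[tuple[int, str, str, bool]]:
    """Per intron: (1-based index, donor, acceptor, donor=='GT' and acceptor=='AG')."""
    return [
        (k, i.donor, i.acceptor, i.is_gt_ag) for k, i in enumerate(model.introns, 1)
    ]
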