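"""Synthetic study-condition generator.

Emulates the system under study end to end: a ~2.7-kb monoterpene-synthase
locus with 7 exons and 6 GT-AG introns; three splice isoforms (canonical,
an alternative 5' donor retaining the first 12 nt of intron 1, and an
alternative 3' acceptor removing the first 114 nt of exon 4 — both offsets
frame-preserving); cultivar haplotype panels with independently planted
per-site substitutions and a diagnostic 12-bp InDel genotype; and volatile
emission profiles in which one compound depends on the InDel genotype plus
Gaussian noise.  Every fixture carries a ground-truth record that the
pipeline's own operations can be checked against.

All randomness flows from a single seeded generator, so identical seed and
configuration reproduce byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import SequenceRecord, STOP_CODONS
from .volatile import PeakTable

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "TGG"
]
# TGG (Trp) is reserved for planted motifs so R-x8-W scans hit only where planted.

_ARG_CODONS = ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"]
_ASP_CODONS = ["GAT", "GAC"]
_SER_CODONS = ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"]
_GLU_CODONS = ["GAA", "GAG"]
_AG_START_CODONS = ["AGA", "AGG", "AGC", "AGT"]  # first two bases "AG"


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    exon_lengths: tuple[int, ...] = (229, 300, 343, 300, 250, 200, 139)
    intron_lengths: tuple[int, ...] = (150, 150, 150, 150, 150, 150)
    alt5_intron: int = 1
    alt5_offset: int = 12
    alt3_intron: int = 3
    alt3_offset: int = 114
    n_cultivars: int = 23
    per_site_snp_prob: float = 0.005
    indel_freq: float = 0.3
    compounds: tuple[str, ...] = (
        "myrcene",
        "(E)-beta-ocimene",
        "alpha-pinene",
        "eucalyptol",
        "linalool",
    )
    causal_compound: str = "(E)-beta-ocimene"
    causal_site: str = "indel_230"
    baseline: float = 2.0
    effect_size: float = 1.5  # 3 x noise_sd
    noise_sd: float = 0.5
    is_amount_ug: float = 0.8
    is_peak_area: float = 1.0e6
    sample_weight_g: float = 1.5

    def __post_init__(self) -> None:
        if self.alt5_offset % 3 or self.alt3_offset % 3:
            raise ValueError("alternative-splice offsets must preserve frame (divisible by 3)")
        if any(l <= 0 for l in self.exon_lengths + self.intron_lengths):
            raise ValueError("exon and intron lengths must be positive")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one fewer intron than exons")
        if self.n_cultivars < 2:
            raise ValueError("need at least 2 cultivars")
        if not 0 <= self.per_site_snp_prob <= 1 or not 0 <= self.indel_freq <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.causal_compound not in self.compounds:
            raise ValueError("causal compound must be one of the configured compounds")

    @property
    def orf_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def locus_length(self) -> int:
        return self.orf_length + sum(self.intron_lengths)


@dataclass
class LocusTruth:
    """Ground truth for one generated locus and its three isoforms."""

    gdna: SequenceRecord
    cdnas: dict[str, SequenceRecord]  # canonical / alt5 / alt3
    exons: dict[str, list[tuple[int, int]]]  # per isoform, 1-based gDNA coords
    intron_coords: list[tuple[int, int]]  # canonical introns
    alt5_insertion: str  # the 12-nt retained intron-1 head
    config: SimulationConfig


@dataclass
class PanelTruth:
    ids: list[str]
    reference_orf: str
    core_seqs: list[str]  # SNP-only haplotypes, equal length
    variants: dict[str, list[tuple[int, str, str]]]  # id -> [(pos, ref, alt)]
    snp_columns: list[int]  # 1-based segregating columns (truth)
    indel_genotype: np.ndarray  # 0/1 carrier status of the 12-bp insertion
    insertion_seq: str
    insertion_pos: int  # 1-based position of first inserted base
    config: SimulationConfig

    def records(self, with_indel: bool = False) -> list[SequenceRecord]:
        recs = []
        for cid, seq, g in zip(self.ids, self.core_seqs, self.indel_genotype):
            if with_indel and g:
                p = self.insertion_pos - 1
                seq = seq[:p] + self.insertion_seq + seq[p:]
            recs.append(SequenceRecord(cid, seq))
        return recs

    @property
    def expected_pi(self) -> float:
        """Analytic E[pi] under independent per-site substitution.

        A pair differs at a site when exactly one copy mutated, 2p(1-p), or
        both mutated to different alternatives, p^2 * 2/3.
        """
        p = self.config.per_site_snp_prob
        return 2 * p * (1 - p) + (2.0 / 3.0) * p * p


@dataclass
class EmissionsTruth:
    ids: list[str]
    compounds: list[str]
    emissions: np.ndarray  # cultivar x compound, ug/g
    site_labels: list[str]
    site_matrix: np.ndarray  # cultivar x site, 0/1
    causal_site: str
    causal_compound: str
    peak_tables: list[PeakTable] = field(default_factory=list)


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_SENSE_CODONS[k] for k in rng.integers(0, len(_SENSE_CODONS), n)]


def _plant(codons: list[str], idx: int, choices: list[str], rng: np.random.Generator) -> None:
    codons[idx] = choices[int(rng.integers(0, len(choices)))]


def _build_orf(config: SimulationConfig, rng: np.random.Generator) -> str:
    n_codons = config.orf_length // 3  # includes ATG and the stop
    codons = ["ATG"] + _random_codons(rng, n_codons - 2) + ["TAA"]

    # terpene-synthase motif layout (residue index == codon index):
    #   RRX8W at residues 21-31, RX8W at 301-310 (inside the alt-3' deleted
    #   block), DDXXD at 351-355, NSE/DTE-like at 481-489.
    _plant(codons, 20, _ARG_CODONS, rng)
    _plant(codons, 21, _ARG_CODONS, rng)
    codons[30] = "TGG"
    _plant(codons, 300, _ARG_CODONS, rng)
    codons[309] = "TGG"
    _plant(codons, 350, _ASP_CODONS, rng)
    _plant(codons, 351, _ASP_CODONS, rng)
    _plant(codons, 354, _ASP_CODONS, rng)
    _plant(codons, 480, _ASP_CODONS, rng)
    _plant(codons, 481, _ASP_CODONS, rng)
    _plant(codons, 484, _SER_CODONS, rng)
    _plant(codons, 488, _GLU_CODONS, rng)

    # the alternative 3' acceptor lies inside exon 4: plant its AG dinucleotide
    cum3 = sum(config.exon_lengths[: config.alt3_intron])
    ag_pos = cum3 + config.alt3_offset - 2  # 0-based index of the acceptor 'A'
    if ag_pos % 3 == 0:
        _plant(codons, ag_pos // 3, _AG_START_CODONS, rng)
    else:  # fall back: overwrite the two bases inside whichever codons they hit
        orf = list("".join(codons))
        orf[ag_pos : ag_pos + 2] = "AG"
        return _postfix_orf("".join(orf))
    return "".join(codons)


def _postfix_orf(orf: str) -> str:
    return orf


def _has_internal_stop(orf: str) -> bool:
    for i in range(0, len(orf) - 3, 3):
        if orf[i : i + 3] in STOP_CODONS:
            return True
    return False


def _random_intron(rng: np.random.Generator, length: int) -> str:
    body = "".join(_BASES[rng.integers(0, 4, length - 4)])
    return "GT" + body + "AG"


def generate_locus(config: SimulationConfig, rng: np.random.Generator | None = None) -> LocusTruth:
    """Generate the locus, its three isoform cDNAs, and their ground truth.

    Introns begin GT and end AG; intron 1 carries a second GT at offset 12 so
    the alternative donor is itself canonical; exon 4 carries an AG at offsets
    113-114 so the alternative acceptor is canonical.  Codon content is
    redrawn deterministically (bounded retries) if any isoform acquires an
    in-frame stop.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for _attempt in range(100):
        orf = _build_orf(config, rng)
        introns = [_random_intron(rng, l) for l in config.intron_lengths]
        # alternative 5' donor: the retained 12-nt head must be followed by GT
        i5 = config.alt5_intron - 1
        off5 = config.alt5_offset
        introns[i5] = (
            introns[i5][:off5] + "GT" + introns[i5][off5 + 2 :]
        )
        head = introns[i5][:off5]

        cum5 = sum(config.exon_lengths[: config.alt5_intron])
        cum3 = sum(config.exon_lengths[: config.alt3_intron])
        canonical = orf
        alt5 = orf[:cum5] + head + orf[cum5:]
        alt3 = orf[: cum3] + orf[cum3 + config.alt3_offset :]
        ok = all(
            s.startswith("ATG") and s[-3:] in STOP_CODONS and not _has_internal_stop(s)
            for s in (canonical, alt5, alt3)
        )
        if ok:
            break
    else:
        raise GenerationError("could not generate stop-free isoforms in 100 attempts")

    # interleave exons and introns into the locus
    parts = []
    pos = 0
    exon_coords: list[tuple[int, int]] = []
    intron_coords: list[tuple[int, int]] = []
    gpos = 0
    for k, elen in enumerate(config.exon_lengths):
        exon_coords.append((gpos + 1, gpos + elen))
        parts.append(orf[pos : pos + elen])
        pos += elen
        gpos += elen
        if k < len(config.intron_lengths):
            intron_coords.append((gpos + 1, gpos + len(introns[k])))
            parts.append(introns[k])
            gpos += len(introns[k])
    gdna_seq = "".join(parts)

    alt5_exons = list(exon_coords)
    s, e = alt5_exons[i5]
    alt5_exons[i5] = (s, e + off5)
    alt3_exons = list(exon_coords)
    i3 = config.alt3_intron
    s, e = alt3_exons[i3]
    alt3_exons[i3] = (s + config.alt3_offset, e)

    truth = LocusTruth(
        gdna=SequenceRecord("synthetic_locus", gdna_seq),
        cdnas={
            "canonical": SequenceRecord("iso_canonical", canonical),
            "alt5": SequenceRecord("iso_alt5", alt5),
            "alt3": SequenceRecord("iso_alt3", alt3),
        },
        exons={"canonical": exon_coords, "alt5": alt5_exons, "alt3": alt3_exons},
        intron_coords=intron_coords,
        alt5_insertion=head,
        config=config,
    )
    # self-consistency: splicing the locus by the truth coordinates must
    # reproduce each emitted cDNA exactly
    for name, coords in truth.exons.items():
        spliced = "".join(gdna_seq[a - 1 : b] for a, b in coords)
        if spliced != truth.cdnas[{"canonical": "canonical", "alt5": "alt5", "alt3": "alt3"}[name]].seq:
            raise GenerationError(f"ground-truth exon coordinates inconsistent for {name}")
    for a, b in intron_coords:
        if not (gdna_seq[a - 1 : a + 1] == "GT" and gdna_seq[b - 2 : b] == "AG"):
            raise GenerationError("generated intron lacks GT-AG boundaries")
    return truth


def generate_haplotype_panel(
    config: SimulationConfig,
    locus: LocusTruth | None = None,
    rng: np.random.Generator | None = None,
) -> PanelTruth:
    """Cultivar haplotypes from the canonical ORF by independent per-site substitution."""
    if config.n_cultivars < 2:
        raise ValueError("need at least 2 cultivars")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if locus is None:
        locus = generate_locus(config, np.random.default_rng(config.seed))
    ref = locus.cdnas["canonical"].seq
    L = len(ref)
    n = config.n_cultivars
    ref_arr = np.array(list(ref))
    mat = np.tile(ref_arr, (n, 1))
    mutate = rng.random((n, L)) < config.per_site_snp_prob
    # uniform alternative base, never the reference base
    shifts = rng.integers(1, 4, size=(n, L))
    base_idx = np.searchsorted(_BASES, ref_arr)
    alt_idx = (base_idx[None, :] + shifts) % 4
    mat[mutate] = _BASES[alt_idx[mutate]]

    ids = [f"cv{k + 1:02d}" for k in range(n)]
    variants: dict[str, list[tuple[int, str, str]]] = {}
    for i, cid in enumerate(ids):
        cols = np.nonzero(mutate[i])[0]
        variants[cid] = [(int(p) + 1, ref[p], str(mat[i, p])) for p in cols]
    seg = sorted(
        int(p) + 1 for p in range(L) if len(set(mat[:, p])) >= 2
    )
    genotype = (rng.random(n) < config.indel_freq).astype(int)
    cum5 = sum(config.exon_lengths[: config.alt5_intron])
    return PanelTruth(
        ids=ids,
        reference_orf=ref,
        core_seqs=["".join(row) for row in mat],
        variants=variants,
        snp_columns=seg,
        indel_genotype=genotype,
        insertion_seq=locus.alt5_insertion,
        insertion_pos=cum5 + 1,
        config=config,
    )


def generate_emissions(
    config: SimulationConfig,
    panel: PanelTruth,
    rng: np.random.Generator | None = None,
) -> EmissionsTruth:
    """Volatile emissions with one compound driven by the InDel genotype.

    causal emission = baseline + effect_size * genotype + N(0, noise_sd),
    truncated at 0; other compounds are genotype-independent.  Peak tables are
    back-computed so internal-standard quantification recovers the intended
    contents exactly.
    """
    if config.causal_site != "indel_230" and config.causal_site not in {
        f"snp_{p}" for p in panel.snp_columns
    }:
        raise ValueError(f"causal site {config.causal_site!r} not present in panel truth")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(panel.ids)
    compounds = list(config.compounds)
    emissions = np.empty((n, len(compounds)))
    if config.causal_site == "indel_230":
        causal_geno = panel.indel_genotype.astype(float)
    else:
        p = int(config.causal_site.split("_")[1]) - 1
        ref = panel.reference_orf
        causal_geno = np.array([seq[p] != ref[p] for seq in panel.core_seqs], dtype=float)
    for k, name in enumerate(compounds):
        noise = rng.normal(0.0, config.noise_sd, n)
        if name == config.causal_compound:
            vals = config.baseline + config.effect_size * causal_geno + noise
        else:
            vals = config.baseline + noise
        emissions[:, k] = np.clip(vals, 0.0, None)

    site_labels = [f"snp_{p}" for p in panel.snp_columns] + ["indel_230"]
    ref = panel.reference_orf
    incidence = np.zeros((n, len(site_labels)))
    for j, p in enumerate(panel.snp_columns):
        incidence[:, j] = [seq[p - 1] != ref[p - 1] for seq in panel.core_seqs]
    incidence[:, -1] = panel.indel_genotype

    tables = []
    for i, cid in enumerate(panel.ids):
        entries = []
        for k, name in enumerate(compounds):
            content = emissions[i, k]
            area = content * config.sample_weight_g * config.is_peak_area / config.is_amount_ug
            entries.append((name, area))
        tables.append(
            PeakTable(
                cultivar_id=cid,
                entries=entries,
                is_name="3-heptanone",
                is_amount=config.is_amount_ug,
                is_peak_area=config.is_peak_area,
                sample_weight=config.sample_weight_g,
            )
        )
    return EmissionsTruth(
        ids=list(panel.ids),
        compounds=compounds,
        emissions=emissions,
        site_labels=site_labels,
        site_matrix=incidence,
        causal_site=config.causal_site,
        causal_compound=config.causal_compound,
        peak_tables=tables,
    )


def simulate_all(
    config: SimulationConfig,
) -> tuple[LocusTruth, PanelTruth, EmissionsTruth]:
    """Run the three generators off one seeded stream."""
    rng = np.random.default_rng(config.seed)
    locus = generate_locus(config, rng)
    panel = generate_haplotype_panel(config, locus, rng)
    emissions = generate_emissions(config, panel, rng)
    return locus, panel, emissions
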