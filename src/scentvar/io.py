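"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython, tabular data through pandas.  Gene models are
written as GFF3 (gene/mRNA/exon, 1-based inclusive); variant tables as TSV
with VCF-flavoured semantics (1-based positions, left-normalized InDels).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .gra import EmissionMatrix, GrdResult, SiteMatrix
from .popgen import DiversityStats
from .simulate import EmissionsTruth, LocusTruth, PanelTruth
from .splice import GeneModel, SpliceEvent
from .variants import IsoformGroupLabel, SequenceRecord, Variant
from .volatile import ODOR_CLASSES, AromaProfile, OdorMap, PeakTable, VolatileProfile


# ---------------------------------------------------------------- sequences

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[SequenceRecord], path: str | Path, description: str = "") -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description=description) for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------- volatiles

def read_peak_tables(path: str | Path) -> list[PeakTable]:
    """Peak-table CSV: cultivar_id, compound, peak_area, is_name, is_amount_ug,
    is_peak_area, sample_weight_g (internal-standard columns repeated per row)."""
    df = pd.read_csv(path)
    required = {
        "cultivar_id", "compound", "peak_area",
        "is_name", "is_amount_ug", "is_peak_area", "sample_weight_g",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    tables = []
    for cid, grp in df.groupby("cultivar_id", sort=False):
        first = grp.iloc[0]
        tables.append(
            PeakTable(
                cultivar_id=str(cid),
                entries=list(zip(grp["compound"], grp["peak_area"].astype(float))),
                is_name=str(first["is_name"]),
                is_amount=float(first["is_amount_ug"]),
                is_peak_area=float(first["is_peak_area"]),
                sample_weight=float(first["sample_weight_g"]),
            )
        )
    return tables


def write_peak_tables(tables: list[PeakTable], path: str | Path) -> None:
    rows = [
        {
            "cultivar_id": t.cultivar_id,
            "compound": name,
            "peak_area": area,
            "is_name": t.is_name,
            "is_amount_ug": t.is_amount,
            "is_peak_area": t.is_peak_area,
            "sample_weight_g": t.sample_weight,
        }
        for t in tables
        for name, area in t.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_odor_map(path: str | Path | None = None) -> OdorMap:
    """Odor map CSV (compound, odor_class); default is the packaged map."""
    if path is None:
        source = resources.files("scentvar.data").joinpath("odor_map.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return OdorMap(dict(zip(df["compound"], df["odor_class"])))


def read_rules(path: str | Path | None = None) -> list[dict]:
    if path is None:
        source = resources.files("scentvar.data").joinpath("aroma_rules.yaml")
        with resources.as_file(source) as p:
            with open(p) as fh:
                doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    return doc["rules"]


def write_profiles(profiles: list[VolatileProfile], path: str | Path) -> None:
    rows = [
        {
            "cultivar_id": p.cultivar_id,
            "compound": name,
            "content_ug_per_g": p.contents[name],
            "percent": p.percents[name],
        }
        for p in profiles
        for name in p.contents
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[VolatileProfile]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("cultivar_id", sort=False):
        out.append(
            VolatileProfile(
                cultivar_id=str(cid),
                contents=dict(zip(grp["compound"], grp["content_ug_per_g"].astype(float))),
                percents=dict(zip(grp["compound"], grp["percent"].astype(float))),
            )
        )
    return out


def write_aroma(profiles: list[AromaProfile], path: str | Path) -> None:
    rows = [
        {
            "cultivar": a.cultivar_id,
            **{cls: round(pct, 2) for cls, pct in zip(ODOR_CLASSES, a.class_percents)},
            "total": a.total_content,
            "group": a.group,
        }
        for a in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ----------------------------------------------------------------- variants

def write_variants(variants: list[Variant], path: str | Path, coordinate_note: str = "") -> None:
    with open(path, "w") as fh:
        if coordinate_note:
            fh.write(f"# {coordinate_note}\n")
        fh.write("ref_id\tpos\tref\talt\tkind\teffect\n")
        for v in variants:
            fh.write(
                f"{v.ref_id}\t{v.pos}\t{v.ref_allele or '.'}\t{v.alt_allele or '.'}\t"
                f"{v.kind}\t{v.effect or '.'}\n"
            )


def write_groups(groups: dict[str, IsoformGroupLabel], path: str | Path) -> None:
    rows = [
        {
            "query_id": qid,
            "group": g.label,
            "evidence": ";".join(f"{v.kind}:{v.pos}:{v.length}" for v in g.evidence) or ".",
        }
        for qid, g in groups.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- splice

def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model in models:
            gstart = model.exons[0][0]
            gend = model.exons[-1][1]
            gid = f"{model.cdna_id}.gene"
            mid = f"{model.cdna_id}.mRNA"
            fh.write(
                f"{model.gdna_id}\tscentvar\tgene\t{gstart}\t{gend}\t.\t+\t.\tID={gid}\n"
            )
            fh.write(
                f"{model.gdna_id}\tscentvar\tmRNA\t{gstart}\t{gend}\t.\t+\t.\t"
                f"ID={mid};Parent={gid}\n"
            )
            for k, (s, e) in enumerate(model.exons, 1):
                fh.write(
                    f"{model.gdna_id}\tscentvar\texon\t{s}\t{e}\t.\t+\t.\t"
                    f"ID={mid}.exon{k};Parent={mid}\n"
                )


def write_splice_events(events: dict[str, list[SpliceEvent]], path: str | Path) -> None:
    rows = [
        {"cdna_id": cid, "kind": e.kind, "intron_index": e.intron_index, "delta_nt": e.delta_nt}
        for cid, evs in events.items()
        for e in evs
    ]
    pd.DataFrame(rows, columns=["cdna_id", "kind", "intron_index", "delta_nt"]).to_csv(
        path, sep="\t", index=False
    )


# ------------------------------------------------------------------ popgen

def write_diversity(stats: list[DiversityStats], path: str | Path) -> None:
    pd.DataFrame([s.summary_row() for s in stats]).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- GRA

def read_site_matrix(path: str | Path) -> SiteMatrix:
    df = pd.read_csv(path, index_col=0)
    return SiteMatrix(list(df.index.astype(str)), list(df.columns), df.to_numpy(dtype=float))


def read_emission_matrix(path: str | Path) -> EmissionMatrix:
    df = pd.read_csv(path, index_col=0)
    return EmissionMatrix(list(df.index.astype(str)), list(df.columns), df.to_numpy(dtype=float))


def write_grd(result: GrdResult, path: str | Path, long_path: str | Path | None = None) -> None:
    result.as_frame().to_csv(path)
    if long_path is not None:
        rows = []
        for ci, compound in enumerate(result.compounds):
            col = sorted(
                ((s, result.grd[k, ci]) for k, s in enumerate(result.sites)),
                key=lambda p: (-p[1], p[0]),
            )
            for rank, (site, val) in enumerate(col, 1):
                rows.append({"site": site, "compound": compound, "grd": val, "rank": rank})
        pd.DataFrame(rows).to_csv(long_path, sep="\t", index=False)


# ----------------------------------------------------------------- fixtures

def write_fixtures(
    outdir: str | Path,
    locus: LocusTruth,
    panel: PanelTruth,
    emissions: EmissionsTruth,
) -> dict[str, Path]:
    """Emit every synthetic fixture plus a JSON ground-truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_note = f"seed={locus.config.seed}"
    paths = {
        "gdna": outdir / "locus.fasta",
        "isoforms": outdir / "isoforms.fasta",
        "panel": outdir / "panel.fasta",
        "peaks": outdir / "peaks.csv",
        "emissions": outdir / "emissions.csv",
        "sites": outdir / "sites.csv",
        "truth": outdir / "ground_truth.json",
        "truth_gff": outdir / "true_models.gff3",
    }
    write_fasta([locus.gdna], paths["gdna"], description=seed_note)
    write_fasta(list(locus.cdnas.values()), paths["isoforms"], description=seed_note)
    write_fasta(panel.records(with_indel=True), paths["panel"], description=seed_note)
    write_peak_tables(emissions.peak_tables, paths["peaks"])
    pd.DataFrame(
        emissions.emissions, index=emissions.ids, columns=emissions.compounds
    ).to_csv(paths["emissions"])
    pd.DataFrame(
        emissions.site_matrix, index=emissions.ids, columns=emissions.site_labels
    ).to_csv(paths["sites"])
    models = [
        GeneModel(
            gdna_id=locus.gdna.id,
            cdna_id=locus.cdnas[name].id,
            exons=coords,
            introns=[],
        )
        for name, coords in locus.exons.items()
    ]
    write_gff3(models, paths["truth_gff"])
    truth = {
        "seed": locus.config.seed,
        "exons": {k: list(map(list, v)) for k, v in locus.exons.items()},
        "introns": [list(p) for p in locus.intron_coords],
        "alt5_insertion": locus.alt5_insertion,
        "snp_columns": panel.snp_columns,
        "indel_genotype": panel.indel_genotype.tolist(),
        "n_cultivars": len(panel.ids),
        "causal_site": emissions.causal_site,
        "causal_compound": emissions.causal_compound,
        "expected_pi": panel.expected_pi,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
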