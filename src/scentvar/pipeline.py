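"""End-to-end orchestration: simulate -> quantify -> classify -> callvars ->
diversity -> splice -> gra, driven by a YAML config with stage gating.

Each stage writes its outputs before the next stage reads them; the run ends
with a ``report.json`` summarising compound counts, aroma groups, the variant
catalogue, the diversity table, splice events and top GRD sites.  Outputs are
timestamp-free, so re-running with unchanged inputs and seed reproduces them
byte-identically; logs go to standard error only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__, gra, io, popgen, splice, variants, volatile
from .simulate import SimulationConfig, simulate_all

log = logging.getLogger("scentvar")

ALL_STAGES = ("simulate", "quantify", "classify", "callvars", "diversity", "splice", "gra")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a YAML mapping")
    return cfg


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: dict) -> tuple[list[str], dict, SimulationConfig | None]:
    if config.get("schema_version") != 1:
        raise ConfigError("config must declare schema_version: 1")
    stages = config.get("stages", list(ALL_STAGES))
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    inputs = config.get("inputs", {}) or {}
    for key, p in inputs.items():
        if not Path(p).exists():
            raise ConfigError(f"input {key!r} does not exist: {p}")
    sim_cfg = None
    if "simulate" in stages:
        sim_block = config.get("simulate", {}) or {}
        try:
            sim_cfg = SimulationConfig(**sim_block)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid simulate block: {exc}") from exc
    return stages, inputs, sim_cfg


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order and write report.json."""
    stages, inputs, sim_cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.get("params", {}) or {}
    report: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "stages": list(stages),
    }
    paths: dict[str, Path] = {k: Path(v) for k, v in inputs.items()}

    if "simulate" in stages:
        log.info("stage simulate: seed=%s", sim_cfg.seed)
        try:
            locus, panel, emissions = simulate_all(sim_cfg)
            fixture_paths = io.write_fixtures(outdir / "fixtures", locus, panel, emissions)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        paths.update(fixture_paths)
        report["simulate"] = {
            "seed": sim_cfg.seed,
            "n_cultivars": sim_cfg.n_cultivars,
            "true_snp_columns": len(panel.snp_columns),
            "true_indel_carriers": int(panel.indel_genotype.sum()),
        }

    profiles = None
    if "quantify" in stages:
        try:
            tables = io.read_peak_tables(paths["peaks"])
            profiles = [volatile.quantify_content(t) for t in tables]
            io.write_profiles(profiles, outdir / "profiles.csv")
        except KeyError as exc:
            raise PipelineError("quantify", f"missing input {exc}") from exc
        except Exception as exc:
            raise PipelineError("quantify", str(exc)) from exc
        major = volatile.select_major_compounds(profiles, float(params.get("major_threshold", 10.0)))
        report["quantify"] = {
            "n_cultivars": len(profiles),
            "n_compounds": len({c for p in profiles for c in p.contents}),
            "n_major_compounds": len(major),
            "major_compounds": sorted(major),
        }
        log.info("stage quantify: %d cultivars", len(profiles))

    if "classify" in stages:
        try:
            if profiles is None:
                profiles = io.read_profiles(paths["profiles"])
            odor_map = io.read_odor_map(paths.get("odor_map"))
            rules = io.read_rules(paths.get("rules"))
            aromas = []
            for p in profiles:
                a = volatile.aggregate_odor_classes(p, odor_map)
                a.group = volatile.classify_aroma(a, rules)
                aromas.append(a)
            io.write_aroma(aromas, outdir / "aroma.csv")
        except KeyError as exc:
            raise PipelineError("classify", f"missing input {exc}") from exc
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc
        groups_hist: dict[str, int] = {}
        for a in aromas:
            groups_hist[a.group] = groups_hist.get(a.group, 0) + 1
        report["classify"] = {"group_counts": dict(sorted(groups_hist.items()))}
        log.info("stage classify: %s", report["classify"]["group_counts"])

    panel_records = None
    iso_groups = None
    ref_orf = None
    if "callvars" in stages:
        try:
            panel_records = io.read_fasta(paths["panel"])
            if "isoforms" in paths:
                ref_record = io.read_fasta(paths["isoforms"])[0]
            else:
                ref_record = panel_records[0]
            ref_orf = variants.find_orf(ref_record)
            catalogue, per_query, iso_groups = variants.catalogue_panel(
                ref_orf, panel_records, ref_id=ref_record.id
            )
            io.write_variants(
                catalogue,
                outdir / "variants.tsv",
                coordinate_note=(
                    f"positions are 1-based on the reference ORF of {ref_record.id}; "
                    "InDels left-normalized"
                ),
            )
            io.write_groups(iso_groups, outdir / "groups.tsv")
        except KeyError as exc:
            raise PipelineError("callvars", f"missing input {exc}") from exc
        except Exception as exc:
            raise PipelineError("callvars", str(exc)) from exc
        snps = [v for v in catalogue if v.kind == "SNP"]
        indels = [v for v in catalogue if v.kind != "SNP"]
        report["callvars"] = {
            "reference": ref_record.id,
            "n_snps": len(snps),
            "n_indels": len(indels),
            "n_synonymous": sum(1 for v in snps if v.effect == "synonymous"),
            "n_nonsynonymous": sum(1 for v in snps if v.effect == "nonsynonymous"),
            "indel_lengths": sorted(v.length for v in indels),
            "group_counts": {
                g: sum(1 for lab in iso_groups.values() if lab.label == g)
                for g in ("LTPS-1", "LTPS-2", "LTPS-3")
            },
        }
        log.info("stage callvars: %d SNPs, %d InDels", len(snps), len(indels))

    if "diversity" in stages:
        try:
            if panel_records is None:
                panel_records = io.read_fasta(paths["panel"])
            if iso_groups is None:
                ref_record = (
                    io.read_fasta(paths["isoforms"])[0] if "isoforms" in paths else panel_records[0]
                )
                ref_orf = variants.find_orf(ref_record)
                _, _, iso_groups = variants.catalogue_panel(
                    ref_orf, panel_records, ref_id=ref_record.id
                )
            by_group: dict[str, list] = {}
            for rec in panel_records:
                by_group.setdefault(iso_groups[rec.id].label, []).append(rec)
            stats = []
            for label, recs in sorted(by_group.items()):
                if len(recs) < 2:
                    log.info("diversity: skipping %s (n=%d < 2)", label, len(recs))
                    continue
                panel = popgen.HaplotypePanel(label, recs)
                stats.append(
                    popgen.diversity_stats(panel, policy=params.get("missing_policy", "pairwise"))
                )
            io.write_diversity(stats, outdir / "diversity.tsv")
        except KeyError as exc:
            raise PipelineError("diversity", f"missing input {exc}") from exc
        except Exception as exc:
            raise PipelineError("diversity", str(exc)) from exc
        report["diversity"] = [s.summary_row() for s in stats]
        log.info("stage diversity: %d groups", len(stats))

    if "splice" in stages:
        try:
            gdna = io.read_fasta(paths["gdna"])[0]
            cdnas = io.read_fasta(paths["isoforms"])
            sp = splice.SpliceParams(
                min_intron=int(params.get("min_intron", 40)),
                max_mismatch=int(params.get("max_mismatch", 2)),
            )
            models = [splice.map_cdna(gdna, c, sp) for c in cdnas]
            canonical = models[0]
            events = {
                m.cdna_id: splice.compare_isoforms(canonical, m) for m in models[1:]
            }
            io.write_gff3(models, outdir / "models.gff3")
            io.write_splice_events(events, outdir / "events.tsv")
        except KeyError as exc:
            raise PipelineError("splice", f"missing input {exc}") from exc
        except Exception as exc:
            raise PipelineError("splice", str(exc)) from exc
        report["splice"] = {
            "canonical": canonical.cdna_id,
            "n_exons": len(canonical.exons),
            "n_introns": len(canonical.introns),
            "all_gt_ag": all(
                ok for m in models for (_, _, _, ok) in splice.validate_canonical_sites(m)
            ),
            "events": {
                cid: [[e.kind, e.intron_index, e.delta_nt] for e in evs]
                for cid, evs in events.items()
            },
        }
        log.info("stage splice: %d exons", len(canonical.exons))

    if "gra" in stages:
        try:
            sites = io.read_site_matrix(paths["sites"])
            emissions_m = io.read_emission_matrix(paths["emissions"])
            result = gra.grd_matrix(
                sites,
                emissions_m,
                rho=float(params.get("rho", 0.5)),
                normalization=params.get("normalization", "minmax"),
            )
            io.write_grd(result, outdir / "grd.csv", outdir / "grd_long.tsv")
        except KeyError as exc:
            raise PipelineError("gra", f"missing input {exc}") from exc
        except Exception as exc:
            raise PipelineError("gra", str(exc)) from exc
        top = {
            compound: gra.rank_sites(result, compound)[0]
            for compound in result.compounds
        }
        report["gra"] = {
            "rho": result.rho,
            "normalization": result.normalization,
            "n_sites": len(result.sites),
            "n_excluded_constant_sites": len(result.excluded_sites),
            "top_site_per_compound": {c: [s, round(v, 4)] for c, (s, v) in top.items()},
        }
        log.info("stage gra: %d sites x %d compounds", len(result.sites), len(result.compounds))

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
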