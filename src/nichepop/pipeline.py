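"""End-to-end pipeline driven by one YAML config.

Stages: simulate (optional) -> niche model per taxon -> pairwise overlap
tests -> Shannon diversity maps (current + scenario) -> population-genetic
statistics -> haplotype network.  All outputs are written with
deterministic names under the configured output directory and recorded in a
manifest (parameters, derived seeds, per-stage status), which is sufficient
to re-run any single stage in isolation.

Each stage's RNG seed is derived from the global seed by hashing the stage
name (CRC32), so skipping one stage does not shift the randomness of the
others.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nichepop import __version__, diversity, enm, geo_core, haplotypes, overlap, popgen
from nichepop.synthetic_data import SimConfig, gen_alignment, gen_env_layers, gen_genotypes, \
    gen_occurrences

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "stage_seed"]

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "output_dir", "simulate", "inputs", "enm", "overlap", "diversity",
         "popgen", "haplotypes", "stages"},
    "simulate": {
        "grid_rows", "grid_cols", "n_layers", "autocorr_range", "scenario_shift",
        "cellsize", "xllcorner", "yllcorner", "taxa", "n_occurrences",
        "n_populations", "n_individuals", "n_loci", "target_fst", "ibd_strength",
        "missing_fraction", "n_hybrids", "n_diagnostic_loci",
        "n_sequences", "seq_length", "n_snp_sites", "indel_length", "n_haplotypes",
    },
    "inputs": {"env_current", "env_scenario", "occurrences", "genotypes", "samples",
               "alignment"},
    "enm": {"background_size", "reg_multiplier", "max_km"},
    "overlap": {"n_iterations", "alpha", "bandwidth_km"},
    "diversity": {"normalize_per_cell", "min_total"},
    "popgen": {"max_missing", "min_maf", "n_classes", "n_permutations"},
    "haplotypes": set(),
}

_STAGES = ("simulate", "enm", "overlap", "diversity", "popgen", "haplotypes")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults filled in."""

    seed: int = 0
    output_dir: str = "pipeline_out"
    simulate: dict | None = None
    inputs: dict = field(default_factory=dict)
    enm: dict = field(default_factory=lambda: {"background_size": 10_000,
                                               "reg_multiplier": 1.0, "max_km": 50.0})
    overlap: dict = field(default_factory=lambda: {"n_iterations": 100, "alpha": 0.05,
                                                   "bandwidth_km": 200.0})
    diversity: dict = field(default_factory=lambda: {"normalize_per_cell": True,
                                                     "min_total": 1e-12})
    popgen: dict = field(default_factory=lambda: {"max_missing": 0.10, "min_maf": 0.05,
                                                  "n_classes": 20, "n_permutations": 100})
    haplotypes: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: list(_STAGES))


def _reject_unknown(section: str, obj: dict) -> None:
    unknown = set(obj) - _SCHEMA[section]
    if unknown:
        where = f"section {section!r}" if section else "top level"
        raise ValueError(f"unknown config key(s) at {where}: {sorted(unknown)}")


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Parse and schema-validate a YAML pipeline config (unknown keys rejected)."""
    if isinstance(source, dict):
        raw = source
    else:
        raw = yaml.safe_load(Path(source).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a mapping")
    _reject_unknown("", raw)
    cfg = PipelineConfig()
    for key in ("seed", "output_dir", "stages"):
        if key in raw:
            setattr(cfg, key, raw[key])
    for section in ("simulate", "inputs", "enm", "overlap", "diversity", "popgen",
                    "haplotypes"):
        if section in raw:
            sub = raw[section] or {}
            if not isinstance(sub, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            _reject_unknown(section, sub)
            if section == "simulate":
                cfg.simulate = sub
            else:
                merged = dict(getattr(cfg, section))
                merged.update(sub)
                setattr(cfg, section, merged)
    bad_stages = set(cfg.stages) - set(_STAGES)
    if bad_stages:
        raise ValueError(f"unknown stage(s): {sorted(bad_stages)}")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (independent of stage execution order)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _simulate(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    sim_raw = dict(cfg.simulate or {})
    taxa = sim_raw.pop("taxa", None) or {
        "taxonA": [2.0, -1.0, 0.0],
        "taxonB": [-1.0, 2.0, 0.0],
    }
    sim = SimConfig(seed=stage_seed(cfg.seed, "simulate"), **sim_raw)
    env_cur, env_scn = gen_env_layers(sim)
    inp = out / "inputs"
    geo_core.write_env_dir(env_cur, inp / "env_current")
    geo_core.write_env_dir(env_scn, inp / "env_scenario")
    occ_sets = []
    for i, (taxon, coefs) in enumerate(sorted(taxa.items())):
        occ, _truth = gen_occurrences(
            env_cur, np.asarray(coefs, dtype=float), sim.n_occurrences,
            seed=stage_seed(cfg.seed, f"occurrences:{taxon}"), taxon=taxon,
        )
        occ_sets.append(occ)
    geo_core.write_occurrences_csv(occ_sets, inp / "occurrences.csv")
    gm, _truth = gen_genotypes(sim)
    gm.to_csv(inp / "genotypes.csv", inp / "samples.csv")
    aln, _truth = gen_alignment(sim)
    haplotypes.write_fasta_alignment(aln, inp / "alignment.fasta")
    cfg.inputs = {
        "env_current": str(inp / "env_current"),
        "env_scenario": str(inp / "env_scenario"),
        "occurrences": str(inp / "occurrences.csv"),
        "genotypes": str(inp / "genotypes.csv"),
        "samples": str(inp / "samples.csv"),
        "alignment": str(inp / "alignment.fasta"),
    }
    manifest["stages"]["simulate"] = {
        "status": "ok",
        "artifacts": sorted(str(p.relative_to(out)) for p in inp.rglob("*") if p.is_file()),
    }


def run_pipeline(config: PipelineConfig | str | Path | dict) -> dict:
    """Run the configured stages and return (and write) the manifest."""
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        "stages": {},
    }
    failed = False

    def run_stage(name: str, fn) -> None:
        nonlocal failed
        if name not in cfg.stages:
            manifest["stages"][name] = {"status": "skipped"}
            return
        if failed and name in ("overlap", "diversity"):
            manifest["stages"][name] = {"status": "not_run (dependency failed)"}
            return
        try:
            fn()
        except Exception as exc:  # record and halt dependents
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            failed = True

    if cfg.simulate is not None:
        run_stage("simulate", lambda: _simulate(cfg, out, manifest))

    # ---- spatial stages -------------------------------------------------
    state: dict = {}

    def do_enm() -> None:
        env_cur = geo_core.read_env_dir(cfg.inputs["env_current"])
        env_scn = geo_core.read_env_dir(cfg.inputs["env_scenario"])
        occ_sets = geo_core.read_occurrences_csv(cfg.inputs["occurrences"])
        enm_dir = out / "enm"
        enm_dir.mkdir(exist_ok=True)
        artifacts, metrics = [], {}
        maps_cur, maps_scn, occ_clean = {}, {}, {}
        for occ in occ_sets:
            clean, rejections = enm.clean_occurrences(occ, max_km=cfg.enm["max_km"])
            model = enm.fit_maxent(
                env_cur, clean,
                background_size=cfg.enm["background_size"],
                reg_multiplier=cfg.enm["reg_multiplier"],
                seed=stage_seed(cfg.seed, f"enm:{occ.taxon}"),
            )
            cur = enm.project_model(model, env_cur)
            scn = enm.project_model(model, env_scn)
            maps_cur[occ.taxon], maps_scn[occ.taxon], occ_clean[occ.taxon] = cur, scn, clean
            model.to_json(enm_dir / f"{occ.taxon}.model.json")
            geo_core.write_ascii_grid(cur.to_layer(), enm_dir / f"{occ.taxon}.current.asc")
            geo_core.write_ascii_grid(scn.to_layer(), enm_dir / f"{occ.taxon}.scenario.asc")
            metrics[occ.taxon] = {
                "n_occurrences_clean": len(clean),
                "n_rejected": len(rejections),
                "auc": enm.auc(model, env_cur, clean),
                "permutation_importance": enm.permutation_importance(
                    model, env_cur, clean,
                    seed=stage_seed(cfg.seed, f"importance:{occ.taxon}"),
                ),
            }
            artifacts += [f"enm/{occ.taxon}.model.json", f"enm/{occ.taxon}.current.asc",
                          f"enm/{occ.taxon}.scenario.asc"]
        (enm_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
        state.update(env_cur=env_cur, env_scn=env_scn, maps_cur=maps_cur,
                     maps_scn=maps_scn, occ_clean=occ_clean)
        manifest["stages"]["enm"] = {"status": "ok", "artifacts": artifacts + ["enm/metrics.json"],
                                     "metrics": metrics}

    def do_overlap() -> None:
        ov_dir = out / "overlap"
        ov_dir.mkdir(exist_ok=True)
        taxa = sorted(state["occ_clean"])
        artifacts = []
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                a, b = taxa[i], taxa[j]
                res = overlap.background_similarity_test(
                    state["occ_clean"][a], state["occ_clean"][b], state["env_cur"],
                    n_iterations=cfg.overlap["n_iterations"],
                    alpha=cfg.overlap["alpha"],
                    bandwidth_km=cfg.overlap["bandwidth_km"],
                    background_size=cfg.enm["background_size"],
                    reg_multiplier=cfg.enm["reg_multiplier"],
                    seed=stage_seed(cfg.seed, f"overlap:{a}:{b}"),
                )
                p = ov_dir / f"{a}_vs_{b}.json"
                p.write_text(json.dumps(res.to_dict(), indent=2, sort_keys=True))
                artifacts.append(f"overlap/{p.name}")
        manifest["stages"]["overlap"] = {"status": "ok", "artifacts": artifacts}

    def do_diversity() -> None:
        div_dir = out / "diversity"
        div_dir.mkdir(exist_ok=True)
        taxa = sorted(state["maps_cur"])
        norm = cfg.diversity["normalize_per_cell"]
        mt = cfg.diversity["min_total"]
        h_cur = diversity.shannon_map([state["maps_cur"][t] for t in taxa], taxa,
                                      normalize_per_cell=norm, min_total=mt)
        h_scn = diversity.shannon_map([state["maps_scn"][t] for t in taxa], taxa,
                                      normalize_per_cell=norm, min_total=mt)
        _diff, summary = diversity.diversity_difference(h_cur, h_scn)
        for name, dm in (("H_current", h_cur), ("H_scenario", h_scn)):
            layer = geo_core.GridLayer(dm.values, dm.mask, dm.xllcorner, dm.yllcorner,
                                       dm.cellsize)
            geo_core.write_ascii_grid(layer, div_dir / f"{name}.asc")
        sidecar = {"taxa": taxa, "normalize_per_cell": norm, "min_total": mt,
                   "difference_summary": summary}
        (div_dir / "diversity.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        manifest["stages"]["diversity"] = {
            "status": "ok",
            "artifacts": ["diversity/H_current.asc", "diversity/H_scenario.asc",
                          "diversity/diversity.json"],
            "summary": summary,
        }

    def do_popgen() -> None:
        pg_dir = out / "popgen"
        pg_dir.mkdir(exist_ok=True)
        gm = popgen.GenotypeMatrix.from_csv(cfg.inputs["genotypes"],
                                            cfg.inputs.get("samples"))
        filtered, report = popgen.filter_snps(gm, cfg.popgen["max_missing"],
                                              cfg.popgen["min_maf"])
        het = popgen.heterozygosity_percent(filtered)
        het.to_csv(pg_dir / "heterozygosity.csv")
        artifacts = ["popgen/heterozygosity.csv"]
        info: dict = {"filter_report": report}
        if filtered.groups and len(set(filtered.groups)) >= 2:
            fst = popgen.pairwise_fst(filtered)
            fst.to_frame().to_csv(pg_dir / "fst.csv")
            artifacts.append("popgen/fst.csv")
            info["fst_groups"] = fst.group_ids
        if filtered.coords is not None:
            prof = popgen.spatial_autocorrelation(
                filtered, n_classes=cfg.popgen["n_classes"],
                n_permutations=cfg.popgen["n_permutations"],
                seed=stage_seed(cfg.seed, "popgen:autocorr"),
            )
            prof.to_frame().to_csv(pg_dir / "kinship_profile.csv", index=False)
            artifacts.append("popgen/kinship_profile.csv")
            info["kinship_zero_crossing_km"] = prof.zero_crossing_km
            members, cents = popgen.centroid_distances(gm)
            members.to_csv(pg_dir / "centroid_distances.csv", index=False)
            cents.to_csv(pg_dir / "centroids.csv")
            artifacts += ["popgen/centroid_distances.csv", "popgen/centroids.csv"]
        (pg_dir / "popgen.json").write_text(json.dumps(info, indent=2, sort_keys=True,
                                                       default=str))
        artifacts.append("popgen/popgen.json")
        manifest["stages"]["popgen"] = {"status": "ok", "artifacts": artifacts,
                                        "filter_report": report}

    def do_haplotypes() -> None:
        hp_dir = out / "haplotypes"
        hp_dir.mkdir(exist_ok=True)
        aln = haplotypes.read_fasta_alignment(cfg.inputs["alignment"])
        table = haplotypes.call_characters(aln)
        hset = haplotypes.collapse_haplotypes(table)
        net = haplotypes.build_network(hset)
        rows = [
            {"haplotype": i, "count": int(hset.counts[i]), "label": hset.labels()[i],
             "members": ";".join(hset.members[i]),
             "states": "".join(hset.states[i])}
            for i in range(hset.n_haplotypes)
        ]
        pd.DataFrame(rows).to_csv(hp_dir / "haplotypes.csv", index=False)
        haplotypes.write_network(net, hp_dir / "network.graphml", hp_dir / "network.tsv")
        manifest["stages"]["haplotypes"] = {
            "status": "ok",
            "artifacts": ["haplotypes/haplotypes.csv", "haplotypes/network.graphml",
                          "haplotypes/network.tsv"],
            "n_haplotypes": hset.n_haplotypes,
            "n_characters": table.n_characters,
        }

    run_stage("enm", do_enm)
    run_stage("overlap", do_overlap)
    run_stage("diversity", do_diversity)
    run_stage("popgen", do_popgen)
    run_stage("haplotypes", do_haplotypes)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str))
    return manifest
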