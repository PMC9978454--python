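"""End-to-end orchestration: simulate -> atlas -> mutability -> burden ->
targets -> recurrence -> genesets, with a content-hash manifest.

Stage outputs are plain files under the output directory, so any stage can be
re-run independently; rerunning with the same config and seeds reproduces the
manifest hashes byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import burden_enrichment as be
from . import enhancer_atlas as atlas
from . import geneset_enrichment as gse
from . import recurrence as rec
from . import synthetic_data as synth
from . import target_assignment as ta
from .intervals import GenomicInterval, merge_intervals
from .mutability import set_mutability, site_rate_array

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "validate_config", "run_pipeline", "default_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def default_config(seed: int = 0, outdir: str = "regburden_demo") -> dict[str, Any]:
    """Demo configuration: synthetic study with a planted 3x enhancer burden."""
    return {
        "seed": seed,
        "outdir": outdir,
        "simulate": {"burden_multiplier": 3.0},
        "atlas": {"fraction": 0.35},
        "targets": {"alpha": 0.01, "n_perm": 1000},
        "recurrence": {"n_perm": 1000, "min_dnms": 2},
        "genesets": {"pli_cut": 0.9},
    }


def validate_config(config: dict[str, Any]) -> None:
    """Check referenced files exist and stochastic stages have seeds before
    any stage runs."""
    if "seed" not in config:
        raise ValueError("config must declare a seed")
    if "outdir" not in config:
        raise ValueError("config must declare an outdir")
    if "simulate" not in config:
        inputs = config.get("inputs")
        if not inputs:
            raise ValueError("config needs either a 'simulate' block or 'inputs' paths")
        for key, path in inputs.items():
            if not Path(path).exists():
                raise ValueError(f"input file for {key!r} not found: {path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _atlas_to_bed(path: Path, records: list[atlas.EnhancerRecord]) -> None:
    with open(path, "w") as fh:
        for e in sorted(records, key=lambda r: (r.chrom, r.start)):
            z = f"{e.z:.4f}" if e.z is not None else "."
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.id}\t{e.score}\t{z}\n")


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    validate_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    # -- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        sim_params = dict(config.get("simulate", {}))
        scfg = synth.SyntheticConfig(seed=config["seed"], **sim_params)
        study = synth.simulate_study(scfg)
        input_paths = synth.write_study(study, outdir / "inputs")
        for name, path in input_paths.items():
            emit(f"inputs/{name}", Path(path))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    seg = study.segmentations
    tracks = seg.tracks
    window_bp = seg.window_bp
    fetal = scfg.fetal_tissues
    adult = [t for t in scfg.tissues if t not in fetal]

    # -- atlas --------------------------------------------------------------
    stage = "atlas"
    try:
        fraction = config.get("atlas", {}).get("fraction", 0.35)
        fbse = atlas.build_atlas(tracks, fetal, seg.peaks, window_bp, fraction)
        _atlas_to_bed(outdir / "fbse.bed", fbse)
        emit("fbse.bed", outdir / "fbse.bed")
        # per-track fetal selections (for the n=2 side of the t test)
        fetal_sets = {
            t: atlas.build_atlas(tracks, [t], seg.peaks, window_bp, fraction)
            for t in fetal
        }
        # adult enhancer sets: all enhancer windows per adult tissue that fall
        # in open chromatin (specificity selection would be empty by design
        # on this synthetic background)
        adult_sets = {}
        for t in adult:
            enh = atlas.merge_enhancer_windows(tracks[t], window_bp, t)
            enh = atlas.intersect_open_chromatin(enh, seg.peaks)
            adult_sets[t] = enh
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    genome = study.genome
    table = study.rate_table
    fbse_iv = merge_intervals([e.interval for e in fbse])

    # -- mutability ---------------------------------------------------------
    stage = "mutability"
    try:
        genome_rate = sum(float(site_rate_array(genome[c], table).sum()) for c in genome)
        n_case = scfg.n_probands_case
        total_case = len(study.dnms_case)
        # cohort scale calibrated from the observed genome-wide DNM yield
        scale = total_case / (genome_rate * n_case)
        set_rates = {}
        rows = []
        all_sets = {"fbse": fbse_iv}
        for t, records in fetal_sets.items():
            all_sets[f"fetal_{t}"] = merge_intervals([e.interval for e in records])
        for t, records in adult_sets.items():
            all_sets[f"adult_{t}"] = merge_intervals([e.interval for e in records])
        for name, ivs in all_sets.items():
            rate = set_mutability(genome, ivs, table, name)
            set_rates[name] = rate.total_rate
            observed = be.count_overlapping_dnms(study.dnms_case, ivs)
            from .mutability import expected_dnms, poisson_upper_tail

            lam = expected_dnms(rate.total_rate, n_case, scale)
            rows.append(
                {
                    "set": name,
                    "n_regions": rate.n_regions,
                    "total_rate": rate.total_rate,
                    "expected": lam,
                    "observed": observed,
                    "p": poisson_upper_tail(observed, lam),
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "mutability.tsv", sep="\t", index=False)
        emit("mutability.tsv", outdir / "mutability.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- burden -------------------------------------------------------------
    stage = "burden"
    try:
        reference_rate = set_rates["fbse"]
        rows = []
        p_values = []

        def normalized(cohort_dnms, name):
            ivs = all_sets[name]
            obs = be.count_overlapping_dnms(cohort_dnms, ivs)
            return obs, be.normalize_count(obs, set_rates[name], reference_rate)

        for cohort_name, dnms in (("case", study.dnms_case), ("control", study.dnms_control)):
            fetal_norm = [normalized(dnms, f"fetal_{t}")[1] for t in fetal]
            adult_norm = [normalized(dnms, f"adult_{t}")[1] for t in adult]
            if len(fetal_norm) >= 2 and len(adult_norm) >= 2:
                tres = be.fetal_vs_adult_ttest(fetal_norm, adult_norm)
                rows.append(
                    {"set": "fetal_vs_adult", "cohort": cohort_name,
                     "observed": "", "normalized": "",
                     "test": tres.method, "statistic": tres.statistic, "p": tres.p}
                )
                p_values.append(tres.p)
            obs_f = be.count_overlapping_dnms(dnms, all_sets["fbse"])
            adult_union = merge_intervals(
                [iv for t in adult for iv in all_sets[f"adult_{t}"]]
            )
            obs_a = be.count_overlapping_dnms(dnms, adult_union)
            adult_union_rate = set_mutability(genome, adult_union, table, "adult_union").total_rate
            rres = be.poisson_rate_ratio_test(obs_f, reference_rate, obs_a, adult_union_rate)
            rows.append(
                {"set": "fbse_vs_adult_union", "cohort": cohort_name,
                 "observed": obs_f, "normalized": be.normalize_count(obs_f, reference_rate, reference_rate),
                 "test": rres.method, "statistic": rres.statistic, "p": rres.p}
            )
            p_values.append(rres.p)
        # case vs control Fisher on the FBSE set
        ci = be.count_overlapping_dnms(study.dnms_case, all_sets["fbse"])
        co = len(study.dnms_case) - ci
        gi = be.count_overlapping_dnms(study.dnms_control, all_sets["fbse"])
        go = len(study.dnms_control) - gi
        fres = be.celltype_fisher(ci, co, gi, go)
        rows.append(
            {"set": "fbse_case_vs_control", "cohort": "both", "observed": ci,
             "normalized": "", "test": fres.method, "statistic": fres.statistic, "p": fres.p}
        )
        p_values.append(fres.p)
        fdrs = be.fdr_adjust(p_values)
        for row, q in zip(rows, fdrs):
            row["fdr"] = q
        pd.DataFrame(rows).to_csv(outdir / "burden.tsv", sep="\t", index=False)
        emit("burden.tsv", outdir / "burden.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- targets ------------------------------------------------------------
    stage = "targets"
    try:
        tcfg = config.get("targets", {})
        ctx = study.context
        assignments, tally = ta.assign_targets(
            [e.interval for e in fbse],
            tads=ctx.tads,
            genes=ctx.genes,
            fragments=ctx.fragments,
            interactions=ctx.interactions,
            enh_h3k27ac=ctx.enh_h3k27ac,
            prom_h3k27ac=ctx.prom_h3k27ac,
            enh_chromhmm=ctx.enh_chromhmm,
            prom_chromhmm=ctx.prom_chromhmm,
            active_promoters=ctx.active_promoters,
            alpha=tcfg.get("alpha", 0.01),
            n_perm=tcfg.get("n_perm", 1000),
            seed=config["seed"],
        )
        pd.DataFrame(
            [{"enhancer": a.enhancer, "gene": a.gene, "tier": a.tier} for a in assignments]
        ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
        with open(outdir / "targets_tally.json", "w") as fh:
            json.dump(tally, fh, indent=2)
        emit("targets.tsv", outdir / "targets.tsv")
        emit("targets_tally.json", outdir / "targets_tally.json")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- recurrence ---------------------------------------------------------
    stage = "recurrence"
    try:
        rcfg = config.get("recurrence", {})
        enh_map = {e.id: e.interval for e in fbse}
        clusters = rec.build_clusters(assignments, enh_map)
        df = rec.poisson_test_all_clusters(
            clusters, study.dnms_case, genome, table, scfg.n_probands_case, scale
        )
        df.to_csv(outdir / "recurrence.tsv", sep="\t", index=False)
        perm = rec.configuration_permutation_test(
            clusters,
            study.dnms_case,
            min_dnms=rcfg.get("min_dnms", 2),
            n_perm=rcfg.get("n_perm", 1000),
            seed=config["seed"],
        )
        with open(outdir / "recurrence.json", "w") as fh:
            json.dump(perm, fh, indent=2)
        emit("recurrence.tsv", outdir / "recurrence.tsv")
        emit("recurrence.json", outdir / "recurrence.json")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- genesets -----------------------------------------------------------
    stage = "genesets"
    try:
        gcfg = config.get("genesets", {})
        dnm_enh = [
            e for e in fbse
            if be.count_overlapping_dnms(study.dnms_case, [e.interval]) > 0
        ]
        hit_ids = {e.id for e in dnm_enh}
        target_genes = {a.gene for a in assignments if a.enhancer in hit_ids}
        # universe is an explicit choice: all annotated genes (default) or
        # only genes with an assigned enhancer candidate
        if gcfg.get("universe", "all_genes") == "assigned":
            universe = {a.gene for a in assignments}
        else:
            universe = set(study.context.genes.gene)
        results = gse.enrich_many(
            target_genes, study.context.gene_lists, universe
        )
        pli_res = gse.pli_enrichment(
            target_genes, study.context.pli, universe, cutoff=gcfg.get("pli_cut", 0.9)
        )
        rows = [vars(r) for r in results] + [vars(pli_res)]
        pd.DataFrame(rows).to_csv(outdir / "genesets.tsv", sep="\t", index=False)
        emit("genesets.tsv", outdir / "genesets.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "seed": config["seed"],
        "artifacts": {
            name: {"path": path, "sha256": _sha256(Path(path))}
            for name, path in artifacts.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
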