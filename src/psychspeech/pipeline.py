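"""End-to-end pipeline driver.

Runs the full analysis chain on a synthetic cohort (or on user-supplied
inputs written in the package's plain-text formats): gradients and
dispersion, stepwise functional connectivity, semantic graph metrics,
syntactic tree metrics, group statistics, and the brain-language GLMs.
All outputs are TSV tables plus a JSON run manifest carrying the config
hash; a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio
from .gradients import dispersion_between, dispersion_within, fit_cohort_gradients
from .semgraph import analyze_narratives
from .sfc import binarize_fc, combine_subject_group, convergence_step, normalize_map, sfc_degrees
from .stats import brainlang_glm, mann_whitney, mass_univariate, bh_fdr
from .syntree import aggregate, utterance_metrics
from .synthetic import CohortSpec, SyntheticCohort, gen_cohort

logger = logging.getLogger("psychspeech")

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: master seed mixed with a stage-name hash."""
    return (master_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "results"
    n_gradients: int = 10
    keep_fraction: float = 0.10
    kernel: str = "normalized_angle"
    sfc_steps: int = 6
    sfc_q: float = 0.001
    n_null: int = 20
    apen_m: int = 2
    apen_r: float = 0.2
    cohort: dict = field(default_factory=dict)
    stages: tuple = ("simulate", "gradients", "sfc", "semgraph", "syntree", "stats")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _seed_rois(network_labels: list[str], roi_labels: list[str], network: str, n: int = 2):
    """First n ROIs of a network serve as its seed set (core regions)."""
    return [r for r, net in zip(roi_labels, network_labels) if net == network][:n]


def run_pipeline(cfg: RunConfig, cohort: SyntheticCohort | None = None) -> dict:
    """Execute all enabled stages; returns the result bundle.

    Every output table is also written under ``cfg.out_dir`` with the
    config hash recorded in the manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}
    bundle: dict = {}

    if cohort is None:
        if "simulate" not in cfg.stages:
            raise ValueError("no cohort given and the 'simulate' stage is disabled")
        t0 = time.time()
        spec = CohortSpec(**{**cfg.cohort, "seed": stage_seed(cfg.seed, "simulate")})
        cohort = gen_cohort(spec)
        timings["simulate"] = time.time() - t0
        logger.info("simulated cohort: %d subjects, %d ROIs",
                    len(cohort.subjects), len(cohort.roi_labels))
    bundle["cohort"] = cohort
    subjects = cohort.subjects
    part = dict(zip(cohort.roi_labels, cohort.network_labels))
    sub_ids = list(subjects["id"])

    aligned = None
    if "gradients" in cfg.stages:
        t0 = time.time()
        ts_list = [cohort.timeseries[s] for s in sub_ids]
        template, aligned, fcs = fit_cohort_gradients(
            ts_list, roi_labels=cohort.roi_labels, k=cfg.n_gradients,
            keep_fraction=cfg.keep_fraction, kernel=cfg.kernel)
        bundle["template"] = template
        bundle["subject_gradients"] = aligned
        bundle["subject_fcs"] = fcs
        rows = []
        sem_rois = [r for r, net in part.items() if net in ("DMN", "LN")]
        for sid, g in zip(sub_ids, aligned):
            rows.append({
                "id": sid,
                "vn_dmn_g1": dispersion_between(g, part, "VN", "DMN", 0, absolute=True),
                "smn_dmn_g1": dispersion_between(g, part, "SMN", "DMN", 0, absolute=True),
                "vn_smn_g2": dispersion_between(g, part, "VN", "SMN", 1, absolute=True),
                "semnet_g1_within": dispersion_within(g, sem_rois, 0),
            })
        disp = pd.DataFrame(rows).set_index("id")
        bundle["dispersion"] = disp
        disp.to_csv(out / "dispersion.tsv", sep="\t")
        for name in disp.columns:
            hc = disp.loc[subjects.set_index("id")["group"] == "HC", name]
            fep = disp.loc[subjects.set_index("id")["group"] == "FEP", name]
            bundle.setdefault("dispersion_tests", {})[name] = mann_whitney(hc, fep)
        timings["gradients"] = time.time() - t0

    if "sfc" in cfg.stages:
        t0 = time.time()
        if "subject_fcs" not in bundle:
            raise ValueError("sfc stage needs the gradients stage (subject FC matrices)")
        fcs = bundle["subject_fcs"]
        group_fc_values = np.mean([fc.values for fc in fcs], axis=0)
        group_fc = fcs[0].__class__(values=group_fc_values,
                                    roi_labels=cohort.roi_labels,
                                    n_timepoints_used=fcs[0].n_timepoints_used)
        seeds = {net: _seed_rois(cohort.network_labels, cohort.roi_labels, net)
                 for net in ("VN", "SMN")}
        sfc_out = {}
        g_group = binarize_fc(group_fc, q=cfg.sfc_q)
        for net, seed_rois in seeds.items():
            gmap = normalize_map(sfc_degrees(g_group, seed_rois, cfg.sfc_steps))
            step, converged = convergence_step(normalize_map(
                sfc_degrees(g_group, seed_rois, cfg.sfc_steps)))
            per_subject = []
            for fc in fcs:
                smap = normalize_map(sfc_degrees(binarize_fc(fc, q=cfg.sfc_q),
                                                 seed_rois, cfg.sfc_steps))
                per_subject.append(combine_subject_group(smap, gmap))
            sfc_out[net] = {"group_map": gmap, "subject_maps": per_subject,
                            "convergence_step": step, "converged": converged}
            psio.write_matrix_tsv(out / f"sfc_{net}_group.tsv", gmap.degrees,
                                  cohort.roi_labels)
        bundle["sfc"] = sfc_out
        timings["sfc"] = time.time() - t0

    if "semgraph" in cfg.stages:
        t0 = time.time()
        rows = []
        for sid in sub_ids:
            m = analyze_narratives(cohort.embeddings[sid], n_null=cfg.n_null,
                                   seed=stage_seed(cfg.seed, f"semgraph:{sid}"))
            rows.append({"id": sid, "ent_num": m.ent_num, "cc": m.cc, "ge": m.ge,
                         "clustering": m.clustering, "sigma": m.sigma,
                         "threshold": m.threshold})
        sem = pd.DataFrame(rows).set_index("id")
        bundle["semantic_metrics"] = sem
        sem.to_csv(out / "semantic_metrics.tsv", sep="\t")
        timings["semgraph"] = time.time() - t0

    if "syntree" in cfg.stages:
        t0 = time.time()
        rows = []
        for sid in sub_ids:
            per_narr = [[utterance_metrics(t, m=cfg.apen_m, r_factor=cfg.apen_r)
                         for t in narr] for narr in cohort.trees[sid]]
            agg = aggregate(per_narr)
            rows.append({"id": sid, **agg.as_dict()})
        syn = pd.DataFrame(rows).set_index("id")
        bundle["syntax_metrics"] = syn
        syn.to_csv(out / "syntax_metrics.tsv", sep="\t")
        timings["syntree"] = time.time() - t0

    if "stats" in cfg.stages and aligned is not None:
        t0 = time.time()
        g1 = np.vstack([g.coords[:, 0] for g in aligned])
        mu = mass_univariate(g1, subjects)
        mu.index = cohort.roi_labels
        bundle["mass_univariate_g1"] = mu
        mu.to_csv(out / "mass_univariate_g1.tsv", sep="\t")
        language = pd.concat(
            [bundle[k] for k in ("semantic_metrics", "syntax_metrics") if k in bundle],
            axis=1)
        if not language.empty and "dispersion" in bundle:
            language = language.dropna(axis=1, how="any")
            # drop (numerically) constant measures — they alias the intercept
            tol = 1e-10 * (1.0 + language.abs().mean())
            language = language.loc[:, language.std() > tol]
            bl = brainlang_glm(bundle["dispersion"], language,
                               subjects.set_index("id"))
            bundle["brainlang"] = bl
            bl.to_csv(out / "brainlang.tsv", sep="\t", index=False)
        timings["stats"] = time.time() - t0

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_subjects": len(subjects),
        "total_s": round(time.time() - t_start, 3),
    }
    psio.write_manifest(out / "manifest.json", manifest)
    bundle["manifest"] = manifest
    return bundle
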