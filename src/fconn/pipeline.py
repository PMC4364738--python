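"""End-to-end group analysis: simulate/read -> preprocess -> individual
networks -> group backbone + modules (reference from controls) -> metrics
with null-model normalization -> permutation statistics.

Every source of randomness is derived from the single run seed through
named numpy SeedSequences, so two runs with the same configuration produce
numerically identical report bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .cohort import CohortSpec, SubjectRecord, generate_clinical_table, generate_cohort
from .metrics import nodal_efficiency
from .modules import Partition, module_connectivity, module_level_metrics, spectral_partition
from .network import (
    extract_backbone,
    group_mean_network,
    network_to_connectivity,
    pearson_connectivity,
    threshold_to_weighted_network,
)
from .nulls import normalized_efficiencies, small_world_check
from .preprocess import fd_summaries, motion_exclusion_flag, preprocess_timeseries
from .stats import (
    compare_bin_profiles,
    demographics_tests,
    fdr_bh,
    hub_bin_profile,
    module_enrichment,
    nodal_comparison,
    partial_correlation,
    permutation_test,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "PipelineError", "run_group_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; message carries stage and subject id."""


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one analysis run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    synthetic: bool = True
    manifest_path: str | None = None
    data_dir: str | None = None
    output_dir: str | None = None
    # preprocessing
    n_discard: int = 5
    low_hz: float = 0.01
    high_hz: float = 0.1
    global_signal: bool = False
    expand_motion: bool = True
    # network construction
    alpha: float = 0.05
    local_alpha: float = 0.05
    group_average: str = "raw"        # or "thresholded"
    backbone_from: str = "controls"   # or "all"
    # inference
    n_nulls: int = 100
    n_perm: int = 10_000
    n_bins: int = 8
    bin_statistic: str = "e_nodal"    # or "strength"
    fdr_q: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["module_sizes"] = list(d["cohort"]["module_sizes"])
        d["cohort"]["band"] = list(d["cohort"]["band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and not isinstance(d["cohort"], CohortSpec):
            c = dict(d["cohort"])
            if "module_sizes" in c:
                c["module_sizes"] = tuple(c["module_sizes"])
            if "band" in c:
                c["band"] = tuple(c["band"])
            d["cohort"] = CohortSpec(**c)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    config: RunConfig
    manifest: pd.DataFrame
    global_metrics: pd.DataFrame
    nodal_eff: pd.DataFrame       # subjects x nodes
    nodal_strength: pd.DataFrame
    partition: Partition
    backbone_edges: int
    module_connectivity: pd.DataFrame
    module_metrics: pd.DataFrame
    results: dict
    provenance: dict

    def validate(self) -> None:
        """Internal consistency: mean nodal efficiency equals e_glob per subject."""
        mean_nodal = self.nodal_eff.mean(axis=1)
        if not np.allclose(mean_nodal, self.global_metrics["e_glob"], atol=1e-9):
            raise AssertionError("mean nodal efficiency != global efficiency")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *key]))


def _load_subjects(config: RunConfig) -> tuple[list[SubjectRecord], object]:
    if config.synthetic:
        spec = replace(config.cohort, seed=config.seed)
        return generate_cohort(spec)
    if config.manifest_path is None or config.data_dir is None:
        raise PipelineError("stage=load: manifest_path and data_dir required "
                            "when synthetic=False")
    manifest = fio.read_manifest(config.manifest_path)
    data_dir = Path(config.data_dir)
    subjects = []
    for sid, row in manifest.iterrows():
        try:
            ts, _ = fio.read_timeseries(data_dir / f"{sid}_timeseries.tsv")
            motion = fio.read_motion(data_dir / f"{sid}_motion.tsv")
            conf_path = data_dir / f"{sid}_confounds.tsv"
            if conf_path.exists():
                conf, _ = fio.read_timeseries(conf_path)
            else:
                conf = np.zeros((ts.shape[0], 2))
        except (OSError, ValueError) as exc:
            raise PipelineError(f"stage=load subject={sid}: {exc}") from exc
        covs = {k: row[k] for k in manifest.columns if k != "group"}
        subjects.append(SubjectRecord(str(sid), row["group"], ts, motion, conf, covs))
    return subjects, None


def run_group_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and return the report bundle.

    Patients are group A in every contrast; one-tailed directions follow
    the pre-specified defaults (patients < controls for raw efficiencies
    and connectivity; patients > controls for normalized local efficiency).
    """
    t0 = time.time()
    subjects, _truth = _load_subjects(config)
    manifest = generate_clinical_table(subjects) if config.synthetic else (
        pd.DataFrame({s.subject_id: {"group": s.group, **s.covariates}
                      for s in subjects}).T.rename_axis("subject_id")
    )
    logger.info("loaded %d subjects in %.1fs", len(subjects), time.time() - t0)

    # ---- preprocessing -------------------------------------------------
    stage = time.time()
    clean: dict[str, np.ndarray] = {}
    motion_rows = []
    for s in subjects:
        try:
            gs = s.timeseries.mean(axis=1) if config.global_signal else None
            clean[s.subject_id] = preprocess_timeseries(
                s.timeseries, s.motion, config.cohort.tr_seconds,
                wm=s.confounds[:, 0], csf=s.confounds[:, 1], global_signal=gs,
                n_discard=config.n_discard,
                low_hz=config.low_hz, high_hz=config.high_hz,
                expand_motion=config.expand_motion,
            )
        except Exception as exc:
            raise PipelineError(
                f"stage=preprocess subject={s.subject_id}: {exc}") from exc
        fd = fd_summaries(s.motion)
        motion_rows.append({
            "subject_id": s.subject_id, "group": s.group,
            "max_fd": fd.max_fd, "rms_fd": fd.rms_fd, "mean_fd": fd.mean_fd,
            "qc_exclude": motion_exclusion_flag(s.motion),
        })
    motion_df = pd.DataFrame(motion_rows).set_index("subject_id")
    logger.info("preprocessing done in %.1fs", time.time() - stage)

    # ---- individual networks ------------------------------------------
    stage = time.time()
    conn = {sid: pearson_connectivity(ts) for sid, ts in clean.items()}
    nets = {
        sid: threshold_to_weighted_network(cm, alpha=config.alpha)
        for sid, cm in conn.items()
    }
    logger.info("individual networks done in %.1fs", time.time() - stage)

    # ---- group backbone + reference partition -------------------------
    stage = time.time()
    ref_ids = [s.subject_id for s in subjects
               if config.backbone_from == "all" or s.group == "control"]
    if config.group_average == "raw":
        ref_mats = [conn[sid] for sid in ref_ids]
    else:
        ref_mats = [network_to_connectivity(nets[sid], conn[sid].n_effective_timepoints)
                    for sid in ref_ids]
    group_cm = group_mean_network(ref_mats)
    backbone = extract_backbone(group_cm, local_alpha=config.local_alpha)
    partition = spectral_partition(backbone)
    logger.info("backbone (%d edges) + partition (%d modules, Q=%.3f) in %.1fs",
                backbone.k, partition.n_modules, partition.q, time.time() - stage)

    # ---- metrics with null normalization ------------------------------
    stage = time.time()
    rows = []
    nodal_e, nodal_s = {}, {}
    module_rows = []
    for k, s in enumerate(subjects):
        net = nets[s.subject_id]
        gm = normalized_efficiencies(net, _rng(config.seed, 1, k),
                                     n_nulls=config.n_nulls)
        nm = nodal_efficiency(net)
        nodal_e[s.subject_id] = nm.e_nodal
        nodal_s[s.subject_id] = nm.strength
        rows.append({
            "subject_id": s.subject_id, "group": s.group,
            "e_glob": gm.e_glob, "e_loc": gm.e_loc,
            "e_glob_norm": gm.e_glob_norm, "e_loc_norm": gm.e_loc_norm,
            "small_world": small_world_check(gm),
            "n_edges": net.k,
        })
        mm = module_level_metrics(net, partition, _rng(config.seed, 2, k),
                                  n_nulls=config.n_nulls)
        for mod, g in mm.items():
            module_rows.append({
                "subject_id": s.subject_id, "group": s.group, "module": mod,
                "e_glob": g.e_glob, "e_loc": g.e_loc,
                "e_glob_norm": g.e_glob_norm, "e_loc_norm": g.e_loc_norm,
            })
    gm_df = pd.DataFrame(rows).set_index("subject_id").join(
        motion_df.drop(columns="group"))
    nodal_eff = pd.DataFrame(nodal_e).T
    nodal_strength = pd.DataFrame(nodal_s).T
    module_df = pd.DataFrame(module_rows)
    mod_conn = module_connectivity(nets, partition)
    logger.info("metrics + nulls done in %.1fs", time.time() - stage)

    # ---- statistics ----------------------------------------------------
    stage = time.time()
    is_pat = gm_df["group"] == "patient"
    pat_ids = gm_df.index[is_pat]
    con_ids = gm_df.index[~is_pat]
    motion_cov = gm_df.loc[list(pat_ids) + list(con_ids),
                           ["max_fd", "rms_fd", "mean_fd"]].to_numpy()

    def group_vals(frame, col):
        return (frame.loc[pat_ids, col].to_numpy(dtype=float),
                frame.loc[con_ids, col].to_numpy(dtype=float))

    tails = {"e_glob": "less", "e_loc": "less",
             "e_glob_norm": "less", "e_loc_norm": "greater"}
    global_tests = {}
    for ci, (col, tail) in enumerate(tails.items()):
        a, b = group_vals(gm_df, col)
        res = permutation_test(a, b, _rng(config.seed, 3, ci),
                               n_perm=config.n_perm, tail=tail,
                               covariates=motion_cov)
        global_tests[col] = {
            "observed_diff": res.observed_diff,
            "critical_value": res.critical_value,
            "p": res.p_one_tailed, "tail": tail,
        }

    # module connectivity: one BH family over all intra + inter columns
    mc_tests = {}
    pvals = []
    for ci, col in enumerate(mod_conn.columns):
        a = mod_conn.loc[pat_ids, col].to_numpy(dtype=float)
        b = mod_conn.loc[con_ids, col].to_numpy(dtype=float)
        res = permutation_test(a, b, _rng(config.seed, 4, ci),
                               n_perm=config.n_perm, tail="less")
        mc_tests[col] = {"observed_diff": res.observed_diff, "p": res.p_one_tailed}
        pvals.append(res.p_one_tailed)
    rejected = fdr_bh(np.array(pvals), q=config.fdr_q)
    for col, rej in zip(mod_conn.columns, rejected):
        mc_tests[col]["significant"] = bool(rej)

    module_tests = {}
    for mod in sorted(module_df["module"].unique()):
        sub = module_df[module_df["module"] == mod].set_index("subject_id")
        module_tests[int(mod)] = {}
        for ci, (col, tail) in enumerate(tails.items()):
            vals = sub[col].astype(float)
            a = vals.loc[[i for i in pat_ids if i in vals.index]].to_numpy()
            b = vals.loc[[i for i in con_ids if i in vals.index]].to_numpy()
            res = permutation_test(
                a, b, _rng(config.seed, 5, int(mod), ci),
                n_perm=config.n_perm, tail=tail)
            module_tests[int(mod)][col] = {"observed_diff": res.observed_diff,
                                           "p": res.p_one_tailed, "tail": tail}

    flagged, nodal_table = nodal_comparison(
        nodal_eff.loc[pat_ids].to_numpy(), nodal_eff.loc[con_ids].to_numpy(),
        _rng(config.seed, 6), n_perm=config.n_perm, q=config.fdr_q,
        covariates=motion_cov,
    )
    enrich = module_enrichment(flagged, partition.labels,
                               _rng(config.seed, 7), n_draws=config.n_perm)

    bin_source = nodal_eff if config.bin_statistic == "e_nodal" else nodal_strength
    prof = {sid: hub_bin_profile(bin_source.loc[sid].to_numpy(), config.n_bins)
            for sid in gm_df.index}
    bins = compare_bin_profiles([prof[i] for i in pat_ids],
                                [prof[i] for i in con_ids],
                                _rng(config.seed, 8), n_perm=config.n_perm,
                                tail="less")

    # partial correlations within patients, controlling age/sex/motion
    pat_manifest = manifest.loc[pat_ids]
    covs = np.column_stack([
        pat_manifest["age"].to_numpy(dtype=float),
        pat_manifest["sex"].to_numpy(dtype=float),
        gm_df.loc[pat_ids, ["max_fd", "rms_fd", "mean_fd"]].to_numpy(),
    ])
    partial = {}
    for col in ("e_glob", "e_loc", "e_glob_norm", "e_loc_norm"):
        try:
            r, p = partial_correlation(
                gm_df.loc[pat_ids, col].to_numpy(dtype=float),
                pat_manifest["hemoglobin"].to_numpy(dtype=float),
                covariates=covs,
            )
        except ValueError:
            logger.warning("too few patients for the covariate set; "
                           "partial correlation of %s skipped", col)
            r, p = float("nan"), float("nan")
        partial[col] = {"r": r, "p": p, "variable": "hemoglobin"}

    demo = demographics_tests(
        manifest[["group", "sex", "age", "hemoglobin"]].copy())
    logger.info("statistics done in %.1fs", time.time() - stage)

    results = {
        "global_tests": global_tests,
        "module_connectivity_tests": mc_tests,
        "module_topology_tests": module_tests,
        "n_flagged_nodes": int(flagged.size),
        "flagged_nodes": flagged.tolist(),
        "enrichment": {
            "observed": enrich.observed.tolist(),
            "expected": enrich.expected.tolist(),
            "p": enrich.p_empirical.tolist(),
        },
        "hub_bins": bins.reset_index().to_dict(orient="records"),
        "partial_correlations": partial,
        "demographics": demo.reset_index().to_dict(orient="records"),
        "partition": {
            "q": partition.q,
            "n_modules": partition.n_modules,
            "sizes": partition.sizes.tolist(),
        },
        "nodal_table": nodal_table.to_dict(orient="list"),
    }
    provenance = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_nulls": config.n_nulls,
        "elapsed_s": round(time.time() - t0, 1),
    }
    bundle = ReportBundle(
        config=config, manifest=manifest, global_metrics=gm_df,
        nodal_eff=nodal_eff, nodal_strength=nodal_strength,
        partition=partition, backbone_edges=backbone.k,
        module_connectivity=mod_conn, module_metrics=module_df,
        results=results, provenance=provenance,
    )
    bundle.validate()
    if config.output_dir:
        _write_bundle(bundle, backbone)
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return bundle


def _write_bundle(bundle: ReportBundle, backbone) -> None:
    out = Path(bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": bundle.provenance["config_hash"],
            "seed": bundle.provenance["seed"]}
    fio.write_manifest(out / "manifest.tsv", bundle.manifest, provenance=prov)
    fio.write_manifest(out / "global_metrics.tsv", bundle.global_metrics,
                       provenance=prov)
    fio.write_manifest(out / "nodal_efficiency.tsv", bundle.nodal_eff,
                       provenance=prov)
    fio.write_manifest(out / "module_connectivity.tsv",
                       bundle.module_connectivity, provenance=prov)
    fio.write_edge_list(out / "backbone.tsv", backbone, provenance=prov)
    fio.write_partition(out / "partition.tsv", bundle.partition.labels,
                        provenance=prov)
    fio.write_json(out / "results.json",
                   {**bundle.provenance, "results": bundle.results})
    nodal_mean = bundle.nodal_eff.mean(axis=0).to_numpy()
    fio.write_brainnet_files(out / "brainnet", backbone, nodal_mean,
                             bundle.partition.labels,
                             flagged=bundle.results["flagged_nodes"])
    bundle.config.to_file(out / "config.yaml")
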