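"""End-to-end orchestration with reproducible configuration.

``run_pipeline`` executes the stages simulate -> construct -> metrics ->
compare / nbs / correlate -> classify, writing every artifact as a plain
standard format (TSV, JSON, NIfTI) beside a persisted copy of the run
configuration.  One global seed deterministically derives all stage seeds.
Constructed networks are cached per subject, keyed by a digest of the input
voxel values, so re-analyses at different settings skip the KDE/KLS hot path.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import inference, metrics, synthetic
from .network import MorphNetwork, RegionalVoxelSet, build_network, extract_regional_values

logger = logging.getLogger("morphkls")

ALL_STAGES = ("simulate", "construct", "metrics", "compare", "nbs",
              "correlate", "classify")
META_COLUMNS = ("subject_id", "group", "subtype", "age", "gender",
                "education", "updrs3", "hoehn_yahr", "mmse")
CLINICAL_VARS = ("updrs3", "hoehn_yahr", "mmse")
COVARIATES = ("age", "gender", "education")


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    out_dir: str = "morphkls_run"
    stages: tuple[str, ...] = ALL_STAGES
    # simulation
    n_per_group: int = 20
    voxels_per_region: int = 300
    effect_regions: tuple[int, ...] = ()
    effect_magnitude: float = 0.0
    effect_kind: str = "mean_shift"
    write_nifti: bool = False
    # or: pre-existing inputs
    gm_dir: str | None = None
    atlas_path: str | None = None
    metadata_path: str | None = None
    # analysis window
    sparsity_lo: float = 0.10
    sparsity_hi: float = 0.34
    sparsity_step: float = 0.01
    mode: str = "weighted"
    n_nulls: int = 100
    # inference
    n_perm: int = 5000
    nbs_primary_p: float = 0.05
    fdr_q: float = 0.05
    # classification
    svm_feature_kinds: tuple[str, ...] = ("matrix", "metrics")
    svm_n_label_perms: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @property
    def sparsities(self) -> np.ndarray:
        return np.round(np.arange(self.sparsity_lo,
                                  self.sparsity_hi + 1e-9,
                                  self.sparsity_step), 6)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (paths and logging
        excluded, so reruns elsewhere compare equal)."""
        payload = asdict(self)
        for key in ("out_dir", "log_level"):
            payload.pop(key, None)
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["config_hash"] = self.digest()
        Path(path).write_text(json.dumps(payload, indent=2, default=str))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw.pop("config_hash", None)
        for key in ("stages", "effect_regions", "svm_feature_kinds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage integer seed (< 2^31) from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------


def write_metadata(metas: list[synthetic.SubjectMeta], path) -> None:
    pd.DataFrame([asdict(m) for m in metas])[list(META_COLUMNS)].to_csv(
        path, sep="\t", index=False)


def read_metadata(path) -> list[synthetic.SubjectMeta]:
    """Read and validate a subject metadata TSV (strict schema)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: metadata file has no rows")
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    metas = []
    for i, row in df.iterrows():
        try:
            metas.append(synthetic.SubjectMeta(
                subject_id=str(row["subject_id"]), group=str(row["group"]),
                subtype=str(row["subtype"]), age=float(row["age"]),
                gender=int(row["gender"]), education=float(row["education"]),
                updrs3=float(row["updrs3"]),
                hoehn_yahr=float(row["hoehn_yahr"]), mmse=float(row["mmse"])))
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: row {i} invalid: {err}") from err
    return metas


def write_report(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Write a result table as TSV, prefixed with the run's config hash."""
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash: {config.digest()}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _cohort_digest(subject: RegionalVoxelSet) -> str:
    h = hashlib.sha1()
    for bag in subject.region_values:
        h.update(np.sort(bag).tobytes())
    return h.hexdigest()


def _construct_networks(
    cohort: list[RegionalVoxelSet], cache_dir: Path
) -> list[MorphNetwork]:
    cache_dir.mkdir(parents=True, exist_ok=True)
    nets = []
    for subj in cohort:
        digest = _cohort_digest(subj)
        tsv = cache_dir / f"{subj.subject_id}.tsv"
        key = cache_dir / f"{subj.subject_id}.sha1"
        if tsv.exists() and key.exists() and key.read_text().strip() == digest:
            nets.append(MorphNetwork.from_tsv(tsv, subj.subject_id))
            continue
        net = build_network(subj)
        net.to_tsv(tsv)
        key.write_text(digest)
        nets.append(net)
    return nets


@dataclass
class RunResult:
    out_dir: Path
    metas: list = field(default_factory=list)
    networks: list = field(default_factory=list)
    global_aucs: pd.DataFrame | None = None
    nodal_aucs: dict | None = None
    comparison: inference.GroupComparisonReport | None = None
    nbs_results: dict | None = None
    correlations: pd.DataFrame | None = None
    classification: dict | None = None


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the configured stages; returns in-memory results and writes
    all artifacts under ``config.out_dir``."""
    logging.basicConfig(level=config.log_level,
                        format="%(asctime)s %(name)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    res = RunResult(out_dir=out)
    t0 = time.time()

    def _log(stage: str) -> None:
        logger.info("stage %-10s done at +%.1fs", stage, time.time() - t0)

    # --- inputs -----------------------------------------------------------
    cohort: list[RegionalVoxelSet]
    if "simulate" in config.stages:
        design = synthetic.SimulationDesign(
            n_per_group=config.n_per_group,
            voxels_per_region=config.voxels_per_region,
            planted_effect=synthetic.PlantedEffect(
                regions=config.effect_regions,
                magnitude=config.effect_magnitude,
                kind=config.effect_kind),
            seed=stage_seed(config.seed, "simulate"))
        cohort, metas = synthetic.simulate_cohort(design)
        design.to_json(out / "design.json")
        write_metadata(metas, out / "metadata.tsv")
        if config.write_nifti:
            synthetic.write_cohort_nifti(cohort, out / "nifti")
        _log("simulate")
    else:
        if not (config.gm_dir and config.atlas_path and config.metadata_path):
            raise FileNotFoundError(
                "without the simulate stage, gm_dir, atlas_path and "
                "metadata_path must all be provided")
        for p in (config.gm_dir, config.atlas_path, config.metadata_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        metas = read_metadata(config.metadata_path)
        cohort = [
            extract_regional_values(
                str(Path(config.gm_dir) / f"{m.subject_id}_gm.nii"),
                config.atlas_path, m.subject_id)
            for m in metas
        ]
    res.metas = metas
    groups = np.array([m.group for m in metas])
    is_patient = groups == "patient"

    # --- networks ---------------------------------------------------------
    if "construct" in config.stages:
        res.networks = _construct_networks(cohort, out / "networks")
        _log("construct")
    if set(config.stages) & {"metrics", "compare", "nbs", "correlate", "classify"}:
        if not res.networks:
            res.networks = _construct_networks(cohort, out / "networks")
    nets = res.networks
    nets_a = [n for n, p in zip(nets, is_patient) if p]  # patients = group A
    nets_b = [n for n, p in zip(nets, is_patient) if not p]

    # --- graph metrics ----------------------------------------------------
    if set(config.stages) & {"metrics", "compare", "correlate", "classify"}:
        s = config.sparsities
        res.global_aucs = metrics.cohort_global_aucs(
            nets, s, config.mode, config.n_nulls,
            stage_seed(config.seed, "metrics"))
        res.nodal_aucs = metrics.cohort_nodal_aucs(nets, s, config.mode)
        gdf = res.global_aucs.copy()
        gdf.insert(0, "subject_id", gdf.index)
        write_report(gdf, out / "global_aucs.tsv", config)
        for m, df in res.nodal_aucs.items():
            d = df.copy()
            d.insert(0, "subject_id", d.index)
            write_report(d, out / f"nodal_auc_{m}.tsv", config)
        for gname, mask in (("control", ~is_patient), ("patient", is_patient)):
            hubs = metrics.hub_scores(
                {m: df[mask].to_numpy() for m, df in res.nodal_aucs.items()},
                node_labels=list(res.nodal_aucs["degree"].columns))
            write_report(hubs, out / f"hubs_{gname}.tsv", config)
        _log("metrics")

    # --- group comparison -------------------------------------------------
    if "compare" in config.stages:
        res.comparison = inference.compare_groups(
            res.global_aucs[is_patient], res.global_aucs[~is_patient],
            {m: df[is_patient] for m, df in res.nodal_aucs.items()},
            {m: df[~is_patient] for m, df in res.nodal_aucs.items()},
            n_perm=config.n_perm, seed=stage_seed(config.seed, "compare"),
            q=config.fdr_q)
        gt = res.comparison.global_table.reset_index()
        write_report(gt, out / "global_comparison.tsv", config)
        write_report(res.comparison.nodal_table, out / "nodal_comparison.tsv",
                     config)
        write_report(res.comparison.altered_regions,
                     out / "altered_regions.tsv", config)
        _log("compare")

    # --- NBS ----------------------------------------------------------------
    if "nbs" in config.stages:
        ea = np.vstack([n.upper_triangle() for n in nets_a])
        eb = np.vstack([n.upper_triangle() for n in nets_b])
        res.nbs_results = {}
        labels = nets[0].node_labels
        for direction in ("decreased", "increased"):
            r = inference.nbs(ea, eb, nets[0].n_nodes,
                              primary_p=config.nbs_primary_p,
                              n_perm=config.n_perm, direction=direction,
                              seed=stage_seed(config.seed, f"nbs-{direction}"))
            res.nbs_results[direction] = r
            rows = [dict(component=c_i, node_i=labels[i], node_j=labels[j],
                         t_stat=r.t_stats[_edge_index(i, j, nets[0].n_nodes)],
                         size=c.size, p_corrected=c.p_corrected)
                    for c_i, c in enumerate(r.components)
                    for i, j in c.edges]
            write_report(pd.DataFrame(
                rows, columns=["component", "node_i", "node_j", "t_stat",
                               "size", "p_corrected"]),
                out / f"nbs_{direction}.tsv", config)
        _log("nbs")

    # --- clinical correlations (patients only) ------------------------------
    if "correlate" in config.stages:
        res.correlations = clinical_correlations(
            res.nodal_aucs, metas, is_patient)
        write_report(res.correlations, out / "correlations.tsv", config)
        _log("correlate")

    # --- classification -----------------------------------------------------
    if "classify" in config.stages:
        y = is_patient.astype(int)
        cfg = clf.ClassifierConfig(n_label_perms=config.svm_n_label_perms,
                                   seed=stage_seed(config.seed, "classify"))
        res.classification = {}
        for kind in config.svm_feature_kinds:
            if kind == "matrix":
                fs = clf.features_from_networks(nets, y)
            else:
                fs = clf.features_from_metric_aucs(res.global_aucs,
                                                   res.nodal_aucs, y)
            result = clf.nested_cv_svm(fs, cfg)
            p, _ = clf.permutation_significance(fs, cfg, result)
            result.permutation_p = p
            ranking = clf.region_contributions(result, fs)
            res.classification[kind] = (result, ranking)
            summary = pd.DataFrame([dict(
                features=kind, balanced_accuracy=result.balanced_accuracy,
                sensitivity=result.sensitivity,
                specificity=result.specificity, permutation_p=p)])
            write_report(summary, out / f"classification_{kind}.tsv", config)
            write_report(ranking.table, out / f"svm_regions_{kind}.tsv", config)
        _log("classify")
    return res


def _edge_index(i: int, j: int, n: int) -> int:
    """Index of edge (i < j) in upper-triangle row-major order."""
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def clinical_correlations(
    nodal_aucs: dict[str, pd.DataFrame],
    metas: list[synthetic.SubjectMeta],
    patient_mask: np.ndarray,
) -> pd.DataFrame:
    """Partial correlations (age/gender/education-adjusted) between each
    nodal AUC metric and each clinical score, within patients."""
    pts = [m for m, p in zip(metas, patient_mask) if p]
    cov = np.array([[m.age, m.gender, m.education] for m in pts])
    rows = []
    for metric, df in nodal_aucs.items():
        vals = df[patient_mask].to_numpy()
        for var in CLINICAL_VARS:
            y = np.array([getattr(m, var) for m in pts])
            for j, region in enumerate(df.columns):
                pc = inference.partial_correlation(vals[:, j], y, cov)
                rows.append(dict(metric=metric, region=region, clinical=var,
                                 r=pc.r, p=pc.p))
    return pd.DataFrame(rows)
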