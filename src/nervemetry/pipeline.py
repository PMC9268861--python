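"""End-to-end orchestration: phantom -> extraction -> statistics.

:func:`run_pipeline` executes the requested stages into a run directory,
writing per-stage outputs (NIfTI volumes, CSV tables, JSON reports), a
machine-readable event log (JSON lines) and the configuration with its hash.
Every stochastic stage derives its seed deterministically from the global
seed plus the stage name, so re-running the same configuration reproduces
all outputs bit-identically.

Two data routes exist:

* ``table`` (default): the cohort table is synthesized directly by
  :func:`nervemetry.phantom.make_cohort` and fed to the statistics stage —
  fast, used for cohort-level questions.
* ``image``: one phantom volume pair is rendered per subject with
  group-modulated nerve parameters, biomarkers are extracted by the full
  image pipeline, and the measured values replace the table draws.  The
  optional ``reliability`` stage re-reads a subset with a perturbed ROI
  (second rater) and re-renders controls at a different noise seed
  (second scan) to populate the inter-rater and test-retest batteries.

:func:`summarize` renders the run's outputs as a markdown report with
per-group mean +- SD (range) tables and the reliability tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as st
from .io import read_cohort, read_volume, write_cohort, write_volume, MTVolumePair, NerveROI
from .metrics import FCMParams, subject_biomarkers
from .phantom import (
    CohortSpec,
    PhantomSpec,
    attach_clinical,
    dilate_roi,
    make_cohort,
    make_nerve_phantom,
    perturb_roi,
)

__all__ = ["RunConfig", "load_config", "run_pipeline", "summarize"]

_BIOMARKERS = ("mtr", "csa", "circularity")


@dataclass
class RunConfig:
    """Flat configuration of a pipeline run.

    ``phantom_overrides`` / ``cohort_overrides`` / ``fcm_overrides`` are
    key-value overrides applied on top of the corresponding spec defaults;
    ``stats_options`` carries alpha, the outlier threshold, explicit
    exclusions and the ICC/CV variants.
    """

    out_dir: str = "nervemetry_run"
    stages: tuple[str, ...] = ("phantom", "stats")
    mode: str = "table"  # "table" or "image"
    seed: int = 0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 23, "CMT1A": 11, "HNPP": 12}
    )
    phantom_overrides: dict = field(default_factory=dict)
    cohort_overrides: dict = field(default_factory=dict)
    fcm_overrides: dict = field(default_factory=dict)
    stats_options: dict = field(default_factory=dict)
    #: image mode: per-group nerve parameters (mean radius mm, MTR %)
    group_nerve: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "control": {"radius": 3.0, "mtr": 33.0},
            "CMT1A": {"radius": 4.2, "mtr": 29.5},
            "HNPP": {"radius": 3.1, "mtr": 33.0},
        }
    )
    n_raters_subjects: int = 13  # image mode: subjects re-read by rater 2
    n_retest_subjects: int = 7  # image mode: controls re-scanned

    def validate(self) -> None:
        known = {"phantom", "extract", "stats", "reliability"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stage(s) {sorted(bad)}; known: {sorted(known)}")
        if self.mode not in ("table", "image"):
            raise ValueError(f"mode must be 'table' or 'image', got {self.mode!r}")


def load_config(path: str | os.PathLike) -> RunConfig:
    """Load a :class:`RunConfig` from a flat YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF


class _EventLog:
    def __init__(self, path: Path):
        self.path = path

    def emit(self, stage: str, event: str, **payload) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps({"stage": stage, "event": event, **payload}, default=str) + "\n")


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires {path.name}, which the '{produced_by}' stage "
            f"produces; run it first (missing: {path})"
        )
    return path


def _subject_phantom_spec(cfg: RunConfig, group: str, rng: np.random.Generator, seed: int) -> PhantomSpec:
    nerve = cfg.group_nerve[group]
    kw = dict(
        nerve_radius=float(max(1.5, rng.normal(nerve["radius"], 0.3))),
        mtr_nerve=float(np.clip(rng.normal(nerve["mtr"], 1.5), 5.0, 95.0)),
        tilt_deg=float(np.clip(rng.normal(10.0, 5.0), 0.0, 25.0)),
        seed=seed,
    )
    kw.update(cfg.phantom_overrides)
    if "nerve_center" not in kw:
        # random sub-voxel placement: grid-symmetric centers are a degenerate
        # alignment with radius-dependent discretization bias
        gs = kw.get("grid_shape", PhantomSpec.grid_shape)
        vs = kw.get("voxel_spacing", PhantomSpec.voxel_spacing)
        kw["nerve_center"] = (
            gs[0] * vs[0] / 2 + float(rng.uniform(-vs[0] / 2, vs[0] / 2)),
            gs[1] * vs[1] / 2 + float(rng.uniform(-vs[1] / 2, vs[1] / 2)),
        )
    return PhantomSpec(**kw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    (run_dir / "config.yaml").write_text(cfg_text)
    log = _EventLog(run_dir / "events.jsonl")
    log.emit("run", "start", config_sha256=hashlib.sha256(cfg_text.encode()).hexdigest())

    fcm = FCMParams(**{"seed": stage_seed(config.seed, "fcm"), **config.fcm_overrides})

    if "phantom" in config.stages:
        _stage_phantom(config, run_dir, log)
    if "extract" in config.stages:
        _stage_extract(config, run_dir, log, fcm)
    if "reliability" in config.stages:
        _stage_reliability(config, run_dir, log, fcm)
    if "stats" in config.stages:
        _stage_stats(config, run_dir, log)
    log.emit("run", "done")
    return run_dir


def _stage_phantom(config: RunConfig, run_dir: Path, log: _EventLog) -> None:
    seed = stage_seed(config.seed, "phantom")
    if config.mode == "table":
        spec = CohortSpec(**{"n_per_group": config.n_per_group, "seed": seed, **config.cohort_overrides})
        table = make_cohort(spec)
        write_cohort(table, run_dir / "cohort.csv")
        log.emit("phantom", "cohort_written", n=len(table), outlier_id=table.attrs.get("outlier_id"))
        return
    # image mode: demographics/clinical from the cohort generator, biomarker
    # columns to be replaced by extraction.
    spec = CohortSpec(**{"n_per_group": config.n_per_group, "seed": seed, **config.cohort_overrides})
    table = make_cohort(spec)
    write_cohort(table, run_dir / "cohort.csv")
    vol_dir = run_dir / "volumes"
    vol_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    truth_rows = []
    for _, row in table.iterrows():
        sid = row["subject_id"]
        pspec = _subject_phantom_spec(config, row["group"], rng, seed=int(rng.integers(2**31)))
        pair, truth = make_nerve_phantom(pspec)
        write_volume(pair.s_mt, vol_dir / f"{sid}_mt.nii.gz")
        write_volume(pair.s_ref, vol_dir / f"{sid}_ref.nii.gz")
        manual = perturb_roi(
            dilate_roi(truth.roi), boundary_noise=1, seed=int(rng.integers(2**31))
        )
        np.save(vol_dir / f"{sid}_roi.npy", manual.mask)
        truth_rows.append(
            {
                "subject_id": sid,
                "mtr_true": truth.mtr_true,
                "csa_true": truth.csa_true,
                "circularity_true": truth.circularity_true,
                "tilt_deg": truth.tilt_deg,
                "phantom_seed": pspec.seed,
                "slice_lo": truth.roi.slice_range[0],
                "slice_hi": truth.roi.slice_range[1],
            }
        )
    pd.DataFrame(truth_rows).to_csv(run_dir / "truth.csv", index=False)
    log.emit("phantom", "volumes_written", n=len(truth_rows))


def _extract_one(vol_dir: Path, sid: str, slice_range, fcm: FCMParams):
    pair = MTVolumePair(
        s_mt=read_volume(vol_dir / f"{sid}_mt.nii.gz"),
        s_ref=read_volume(vol_dir / f"{sid}_ref.nii.gz"),
    )
    mask = np.load(vol_dir / f"{sid}_roi.npy")
    roi = NerveROI(mask, slice_range)
    return subject_biomarkers(pair, roi, fcm), pair, roi


def _stage_extract(config: RunConfig, run_dir: Path, log: _EventLog, fcm: FCMParams) -> None:
    if config.mode != "image":
        log.emit("extract", "skipped", reason="table mode has no volumes")
        return
    truth = pd.read_csv(_require(run_dir / "truth.csv", "extract", "phantom"))
    cohort = read_cohort(_require(run_dir / "cohort.csv", "extract", "phantom"))
    vol_dir = run_dir / "volumes"
    slice_rows = []
    for _, trow in truth.iterrows():
        sid = trow["subject_id"]
        (subject, slices), _, _ = _extract_one(
            vol_dir, sid, (int(trow["slice_lo"]), int(trow["slice_hi"])), fcm
        )
        for s in slices:
            slice_rows.append({"subject_id": sid, **dataclasses.asdict(s)})
        cohort.loc[cohort["subject_id"] == sid, ["mtr", "csa", "circularity"]] = (
            subject.mtr,
            subject.csa,
            subject.circularity,
        )
        log.emit("extract", "subject_done", subject_id=sid, n_slices=subject.n_slices)
    pd.DataFrame(slice_rows).to_csv(run_dir / "slice_metrics.csv", index=False)
    # Clinical columns are re-derived from the *measured* biomarkers so the
    # biomarker-clinical coupling the statistics probe actually holds.
    cspec = CohortSpec(**{"n_per_group": config.n_per_group, **config.cohort_overrides})
    attach_clinical(cohort, cspec, np.random.default_rng(stage_seed(config.seed, "clinical")))
    write_cohort(cohort, run_dir / "cohort.csv")


def _stage_reliability(config: RunConfig, run_dir: Path, log: _EventLog, fcm: FCMParams) -> None:
    if config.mode != "image":
        log.emit("reliability", "skipped", reason="table mode has no volumes")
        return
    truth = pd.read_csv(_require(run_dir / "truth.csv", "reliability", "phantom"))
    cohort = read_cohort(_require(run_dir / "cohort.csv", "reliability", "extract"))
    if cohort[list(_BIOMARKERS)].isna().any().any():
        raise FileNotFoundError(
            "stage 'reliability' requires extracted biomarkers in cohort.csv; run 'extract' first"
        )
    seed = stage_seed(config.seed, "reliability")
    rng = np.random.default_rng(seed)
    vol_dir = run_dir / "volumes"
    report: dict[str, dict] = {"interrater": {}, "test_retest": {}}

    # Second rater: the same volumes re-read with an independently perturbed ROI.
    subs = truth.head(config.n_raters_subjects)
    rater1 = cohort.set_index("subject_id")
    rater2_rows = []
    for _, trow in subs.iterrows():
        sid = trow["subject_id"]
        sl = (int(trow["slice_lo"]), int(trow["slice_hi"]))
        pair = MTVolumePair(
            s_mt=read_volume(vol_dir / f"{sid}_mt.nii.gz"),
            s_ref=read_volume(vol_dir / f"{sid}_ref.nii.gz"),
        )
        roi = NerveROI(np.load(vol_dir / f"{sid}_roi.npy"), sl)
        roi2 = perturb_roi(roi, boundary_noise=1, seed=int(rng.integers(2**31)))
        subject, _ = subject_biomarkers(pair, roi2, fcm)
        rater2_rows.append({"subject_id": sid, "mtr": subject.mtr, "csa": subject.csa,
                            "circularity": subject.circularity})
    rater2 = pd.DataFrame(rater2_rows).set_index("subject_id")
    for bm in _BIOMARKERS:
        m = np.c_[rater1.loc[rater2.index, bm].to_numpy(), rater2[bm].to_numpy()]
        res = st.interrater_reliability(
            m, bm,
            icc_variant=config.stats_options.get("icc_variant", "two-way-random-absolute-single"),
            cv_method=config.stats_options.get("cv_method", "rms"),
        )
        report["interrater"][bm] = dataclasses.asdict(res)
    log.emit("reliability", "interrater_done", n=len(rater2))

    # Test-retest: controls re-rendered at the same truth, different noise seed.
    controls = truth[truth["subject_id"].str.startswith("control")].head(config.n_retest_subjects)
    retest_rows = []
    for _, trow in controls.iterrows():
        sid = trow["subject_id"]
        sl = (int(trow["slice_lo"]), int(trow["slice_hi"]))
        base = PhantomSpec(
            nerve_radius=float(np.sqrt(trow["csa_true"] / np.pi)),
            mtr_nerve=float(trow["mtr_true"]),
            tilt_deg=float(trow["tilt_deg"]),
            seed=int(rng.integers(2**31)),
            **config.phantom_overrides,
        )
        pair2, truth2 = make_nerve_phantom(base)
        manual2 = perturb_roi(
            dilate_roi(truth2.roi), boundary_noise=1,
            seed=int(rng.integers(2**31)),
        )
        subject2, _ = subject_biomarkers(pair2, manual2, fcm)
        retest_rows.append({"subject_id": sid, "mtr": subject2.mtr, "csa": subject2.csa,
                            "circularity": subject2.circularity})
    scan2 = pd.DataFrame(retest_rows).set_index("subject_id")
    for bm in _BIOMARKERS:
        m = np.c_[rater1.loc[scan2.index, bm].to_numpy(), scan2[bm].to_numpy()]
        res = st.test_retest(
            m, bm,
            icc_variant=config.stats_options.get("icc_variant", "two-way-random-absolute-single"),
            cv_method=config.stats_options.get("cv_method", "rms"),
        )
        report["test_retest"][bm] = dataclasses.asdict(res)
    log.emit("reliability", "retest_done", n=len(scan2))
    (run_dir / "reliability.json").write_text(json.dumps(report, indent=2, default=_jsonable))


def _stage_stats(config: RunConfig, run_dir: Path, log: _EventLog) -> None:
    opts = config.stats_options
    cohort = read_cohort(_require(run_dir / "cohort.csv", "stats", "phantom"))
    sd_threshold = float(opts.get("sd_threshold", 2.5))
    report: dict = {"schema_version": 1, "n": len(cohort)}

    report["group_comparisons"] = {}
    for bm in _BIOMARKERS:
        gc = st.group_compare(cohort, bm)
        report["group_comparisons"][bm] = {
            "kruskal_p": gc.kruskal_p,
            "pairwise_p": {f"{a}|{b}": p for (a, b), p in gc.pairwise_p.items()},
            "median": gc.group_median,
            "n": gc.group_n,
        }

    patients = cohort[cohort["group"] != "control"]
    primary = st.correlate_with_outlier_rule(patients, "cmtes_l", "mtr", sd_threshold)
    exclusions = tuple(opts.get("exclude_ids", primary.outlier_ids))
    log.emit("stats", "outliers_flagged", ids=list(primary.outlier_ids))
    report["correlations"] = {"mtr~cmtes_l": dataclasses.asdict(primary)}
    for x, y, excl in (
        ("cmap", "mtr", exclusions),
        ("mcv", "mtr", exclusions),
        ("cmap", "csa", ()),
        ("mcv", "csa", ()),
        ("cmtes_l", "csa", ()),
    ):
        try:
            res = st.correlate_with_outlier_rule(patients, x, y, sd_threshold, extra_exclusions=excl)
            report["correlations"][f"{y}~{x}"] = dataclasses.asdict(res)
        except ValueError as err:
            report["correlations"][f"{y}~{x}"] = {"error": str(err)}

    controls = cohort[cohort["group"] == "control"]
    try:
        report["demographic_screen"] = st.demographic_screen(controls)
    except ValueError as err:
        report["demographic_screen"] = {"error": str(err)}

    try:
        reg = st.fit_disability_model(
            patients,
            prune_alpha=float(opts.get("alpha", 0.05)),
            exclude_ids=exclusions,
        )
        log.emit("stats", "regression_pruned", pruned=reg.pruned, retained=reg.retained)
        report["disability_model"] = dataclasses.asdict(reg)
    except ValueError as err:
        report["disability_model"] = {"error": str(err)}

    (run_dir / "report.json").write_text(json.dumps(report, indent=2, default=_jsonable))
    log.emit("stats", "report_written")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _mean_sd_range(values: pd.Series) -> str:
    v = values.dropna()
    if v.empty:
        return "-"
    return f"{v.mean():.2f} ± {v.std(ddof=1):.2f} ({v.min():.2f}, {v.max():.2f})"


def summarize(run_dir: str | os.PathLike) -> str:
    """Render a markdown report of a (possibly partial) run directory.

    Sections are emitted only for the outputs that exist; gaps are stated
    explicitly so a partial run yields a partial — never misleading — report.
    """
    run_dir = Path(run_dir)
    lines: list[str] = ["# nervemetry run summary", ""]

    cohort_path = run_dir / "cohort.csv"
    if cohort_path.exists():
        cohort = read_cohort(cohort_path)
        lines += ["## Cohort", ""]
        groups = ["control", "CMT1A", "HNPP"]
        header = "| Metric | " + " | ".join(groups) + " |"
        lines += [header, "|" + "---|" * (len(groups) + 1)]
        counts = {g: int((cohort["group"] == g).sum()) for g in groups}
        lines.append("| n | " + " | ".join(
            str(counts[g]) if counts[g] else "n = 0" for g in groups) + " |")
        for metric, label in [
            ("age", "Age, y"), ("bmi", "BMI, kg/m²"), ("cmtes_l", "CMTES_L"),
            ("mcv", "MCV, m/s"), ("cmap", "CMAP, mV"), ("mtr", "MTR, %"),
            ("csa", "CSA, mm²"), ("circularity", "Circularity"),
        ]:
            cells = [
                _mean_sd_range(cohort.loc[cohort["group"] == g, metric]) if counts[g] else "n = 0"
                for g in groups
            ]
            lines.append(f"| {label} | " + " | ".join(cells) + " |")
        lines.append("")
    else:
        lines += ["## Cohort", "", "_missing: cohort.csv not found in this run_", ""]

    report_path = run_dir / "report.json"
    if report_path.exists():
        rep = json.loads(report_path.read_text())
        lines += ["## Group comparisons (Kruskal-Wallis / pairwise rank-sum)", ""]
        lines += ["| Metric | omnibus p | control vs CMT1A | control vs HNPP | CMT1A vs HNPP |",
                  "|---|---|---|---|---|"]
        for bm, gc in rep.get("group_comparisons", {}).items():
            pw = gc["pairwise_p"]
            lines.append(
                f"| {bm} | {gc['kruskal_p']:.4g} | "
                f"{pw.get('control|CMT1A', float('nan')):.4g} | "
                f"{pw.get('control|HNPP', float('nan')):.4g} | "
                f"{pw.get('CMT1A|HNPP', float('nan')):.4g} |"
            )
        lines.append("")
        if "disability_model" in rep and "coefficients" in rep.get("disability_model", {}):
            dm = rep["disability_model"]
            lines += ["## Disability model (CMTES_L)", ""]
            lines += ["| Term | beta | SE | p |", "|---|---|---|---|"]
            for term, (beta, se, p) in dm["coefficients"].items():
                lines.append(f"| {term} | {beta:.3f} | {se:.3f} | {p:.4g} |")
            lines.append(f"\nPruned terms: {', '.join(dm['pruned']) or 'none'}; "
                         f"adjusted R² = {dm['adjusted_r2']:.3f}")
            lines.append("")
    else:
        lines += ["## Statistics", "", "_missing: report.json (stats stage not run)_", ""]

    rel_path = run_dir / "reliability.json"
    if rel_path.exists():
        rel = json.loads(rel_path.read_text())
        if rel.get("interrater"):
            lines += ["## Inter-rater reliability", ""]
            lines += ["| Metric | Rater 1 | Rater 2 | ICC | CV [%] | paired-t p |",
                      "|---|---|---|---|---|---|"]
            for bm, r in rel["interrater"].items():
                m1, m2 = r["means"]
                s1, s2 = r["sds"]
                tp = r["paired_t_p"]
                lines.append(
                    f"| {bm} | {m1:.2f} ± {s1:.2f} | {m2:.2f} ± {s2:.2f} | "
                    f"{r['icc']:.3f} | {r['cv_percent']:.2f} | "
                    f"{'-' if tp is None or (isinstance(tp, float) and np.isnan(tp)) else f'{tp:.3f}'} |"
                )
            lines.append("")
        if rel.get("test_retest"):
            lines += ["## Test-retest repeatability", ""]
            lines += ["| Metric | LOA (lower, upper) [%] | ICC | CV [%] |", "|---|---|---|---|"]
            for bm, r in rel["test_retest"].items():
                lines.append(
                    f"| {bm} | ({r['loa_lower']:.2f}, {r['loa_upper']:.2f}) | "
                    f"{r['icc']:.3f} | {r['cv_percent']:.2f} |"
                )
            lines.append("")
    return "\n".join(lines)
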