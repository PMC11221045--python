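"""End-to-end orchestration: simulate -> qc -> prep -> rsf -> issf -> report.

Each stage reads its predecessor's artifacts from the output directory,
writes its own (CSV/JSON), and records them in a manifest with content
hashes, row counts and the seeds used, so a rerun with an identical
configuration reproduces byte-identical outputs. All randomness flows
from named per-stage seeds in the configuration; there is no global RNG.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import issf as issf_mod
from . import qc as qc_mod
from . import rsf as rsf_mod
from . import trackprep
from .raster import read_raster, write_raster
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run (defaults mirror the field
    protocol: 95% retention candidates, final cut-off HPE < 25, 48-h
    post-release window, 10-min sampling rate, 10 pseudo-absences, 100
    reruns of 100-point subsets, 100 random steps, 1000 bootstrap
    replicates, 20-strata minimum)."""

    out_dir: str = "pipeline_out"
    positions_csv: str | None = None  # if None, the simulate stage runs
    raster_path: str | None = None
    # qc
    retain: float = 0.95
    cutoff: float = 25.0
    post_release_hours: float = 48.0
    # prep
    rate: float = 600.0
    tolerance: float = 120.0
    # rsf
    ratio: int = 10
    reruns: int = 100
    per_individual: int = 100
    # issf
    n_random_steps: int = 100
    bootstrap_reps: int = 1000
    min_strata: int = 20
    # seeds per stage
    seeds: dict = field(default_factory=lambda: {
        "simulate": 1, "rsf_absences": 2, "rsf_reruns": 3, "issf": 4,
    })
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None,
              float_format="%.10g")


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.stages: dict[str, dict] = {}

    def record(self, stage: str, files: list[Path], **info) -> None:
        self.stages[stage] = {
            "files": {f.name: _sha256(f) for f in files},
            **info,
        }

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=2, sort_keys=True)
        return path


def stage_simulate(cfg: PipelineConfig, out: Path, manifest: _Manifest):
    sim_cfg = SimulationConfig(**cfg.simulation)
    raster, _tracks, fixes = simulate_study(sim_cfg, seed=cfg.seeds["simulate"])
    raster_path = out / "benthoscape.asc"
    write_raster(raster, raster_path)
    fixes_path = out / "positions.csv"
    fixes.to_csv(fixes_path, index=False)
    manifest.record(
        "simulate", [raster_path, fixes_path],
        seed=cfg.seeds["simulate"], n_fixes=len(fixes),
    )
    return raster, fixes


def stage_qc(cfg: PipelineConfig, fixes: pd.DataFrame, out: Path, manifest: _Manifest):
    candidates = qc_mod.deployment_cutoffs(fixes, retain=cfg.retain)
    reports = {
        dep: asdict(qc_mod.cutoff_report(fixes[fixes["deployment_id"] == dep], c))
        for dep, c in candidates.items()
    }
    filtered, counts = qc_mod.filter_positions(
        fixes, cutoff=cfg.cutoff, post_release_hours=cfg.post_release_hours
    )
    filt_path = out / "positions_filtered.csv"
    filtered.to_csv(filt_path, index=False)
    qc_path = out / "qc_report.json"
    with open(qc_path, "w") as fh:
        json.dump(
            {
                "candidate_cutoffs": candidates,
                "deployment_reports": reports,
                "final_cutoff": cfg.cutoff,
                "per_tag_counts": counts.to_dict(orient="index"),
            },
            fh, indent=2, sort_keys=True,
        )
    manifest.record(
        "qc", [filt_path, qc_path],
        n_before=int(counts["n_before"].sum()), n_after=int(counts["n_after"].sum()),
    )
    return filtered


def stage_prep(cfg: PipelineConfig, filtered: pd.DataFrame, raster, out: Path, manifest: _Manifest):
    filtered = trackprep.clip_to_raster(filtered, raster)
    steps = trackprep.steps_from_fixes(filtered, rate=cfg.rate, tolerance=cfg.tolerance)
    steps = trackprep.attach_covariates(steps, raster)
    steps_path = out / "steps.csv"
    _write_csv(steps, steps_path)
    manifest.record("prep", [steps_path], n_steps=len(steps))
    return steps


def stage_rsf(cfg: PipelineConfig, filtered: pd.DataFrame, raster, out: Path, manifest: _Manifest):
    filtered = trackprep.clip_to_raster(filtered, raster)
    data = rsf_mod.build_use_available(
        filtered, raster, ratio=cfg.ratio, seed=cfg.seeds["rsf_absences"]
    )
    coefs = rsf_mod.rsf_resample_fit(
        data, reruns=cfg.reruns, per_individual=cfg.per_individual,
        seed=cfg.seeds["rsf_reruns"], ratio=cfg.ratio,
    )
    rss = rsf_mod.relative_selection_strength(coefs)
    coef_path = out / "rsf_coefficients.csv"
    coefs.to_csv(coef_path, float_format="%.10g")
    rss_path = out / "rsf_rss.json"
    with open(rss_path, "w") as fh:
        json.dump(rss.reset_index().to_dict(orient="records"), fh, indent=2)
    manifest.record(
        "rsf", [coef_path, rss_path],
        seed_absences=cfg.seeds["rsf_absences"], seed_reruns=cfg.seeds["rsf_reruns"],
        n_reruns=len(coefs),
    )
    return coefs, rss


def stage_issf(cfg: PipelineConfig, steps: pd.DataFrame, raster, out: Path, manifest: _Manifest):
    results = {}
    kernels = {}
    ss = np.random.SeedSequence(cfg.seeds["issf"])
    tags = sorted(steps["tag_id"].unique())
    children = ss.spawn(2 * len(tags))
    for i, tag in enumerate(tags):
        sub = steps[steps["tag_id"] == tag]
        try:
            kernel = issf_mod.fit_tentative_kernel(sub)
            strata = issf_mod.draw_random_steps(
                sub, kernel, raster, n_random=cfg.n_random_steps,
                seed=np.random.default_rng(children[2 * i]),
            )
            est = issf_mod.fit_issf(
                strata, B=cfg.bootstrap_reps,
                seed=int(children[2 * i + 1].generate_state(1)[0] % (2**31)),
                min_strata=cfg.min_strata, tag_id=tag,
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("excluding %r from iSSF: %s", tag, exc)
            continue
        results[tag] = est
        kernels[tag] = issf_mod.update_kernel(kernel, est.table())
    if results:
        tables = pd.concat(
            {tag: est.table() for tag, est in results.items()}, names=["tag_id", "term"]
        )
    else:
        tables = pd.DataFrame()
    est_path = out / "issf_estimates.csv"
    tables.to_csv(est_path, float_format="%.10g")
    kern_path = out / "issf_updated_kernels.json"
    with open(kern_path, "w") as fh:
        json.dump(
            {t: k.reset_index().to_dict(orient="records") for t, k in kernels.items()},
            fh, indent=2,
        )
    manifest.record(
        "issf", [est_path, kern_path],
        n_individuals=len(results), seed=cfg.seeds["issf"],
    )
    return results


def write_reports(rsf_rss, issf_results, out: Path, manifest: _Manifest):
    """Figure/table data in the shapes field reports use.

    * an RSS boxplot table (median / quartiles / whiskers per substrate),
    * a per-individual point-estimate + 95% CI table for the iSSF terms,
    * a term x individual estimate/SD matrix in the layout of the
      per-individual term-by-animal tables of field reports.
    """
    files = []
    if rsf_rss is not None:
        box_path = out / "report_rss_boxplot.csv"
        rsf_rss.to_csv(box_path, float_format="%.10g")
        files.append(box_path)
    rows = []
    matrix = []
    for tag, est in (issf_results or {}).items():
        t = est.table().reset_index()
        t.insert(0, "tag_id", tag)
        rows.append(t[["tag_id", "term", "estimate", "se", "wald_lo", "wald_hi",
                       "pct_lo", "pct_hi"]])
        matrix.append(t[["tag_id", "term", "boot_mean", "boot_sd"]])
    ci_path = out / "report_issf_ci.csv"
    (pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["tag_id", "term", "estimate", "se", "wald_lo", "wald_hi",
                 "pct_lo", "pct_hi"])).to_csv(ci_path, index=False, float_format="%.10g")
    files.append(ci_path)
    tab_path = out / "report_issf_estimates.csv"
    if matrix:
        wide = (
            pd.concat(matrix, ignore_index=True)
            .pivot(index="term", columns="tag_id", values=["boot_mean", "boot_sd"])
        )
        wide.to_csv(tab_path, float_format="%.10g")
    else:
        pd.DataFrame({"note": ["zero individuals met the iSSF data requirements"]}).to_csv(
            tab_path, index=False
        )
    files.append(tab_path)
    manifest.record("report", files, n_individuals=len(issf_results or {}))


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage; returns the manifest path.

    Stage failures abort with the stage name and cause; artifacts written
    so far are kept alongside a FAILED marker naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    stage = "configure"
    try:
        if cfg.positions_csv is None:
            stage = "simulate"
            raster, fixes = stage_simulate(cfg, out, manifest)
        else:
            if cfg.raster_path is None or not Path(cfg.raster_path).exists():
                raise FileNotFoundError(
                    f"raster_path {cfg.raster_path!r} does not exist"
                )
            if not Path(cfg.positions_csv).exists():
                raise FileNotFoundError(
                    f"positions_csv {cfg.positions_csv!r} does not exist"
                )
            raster = read_raster(cfg.raster_path)
            fixes = pd.read_csv(
                cfg.positions_csv, parse_dates=["t", "release_t"]
            )
        stage = "qc"
        filtered = stage_qc(cfg, fixes, out, manifest)
        stage = "prep"
        steps = stage_prep(cfg, filtered, raster, out, manifest)
        stage = "rsf"
        _coefs, rss = stage_rsf(cfg, filtered, raster, out, manifest)
        stage = "issf"
        issf_results = stage_issf(cfg, steps, raster, out, manifest)
        stage = "report"
        write_reports(rss, issf_results, out, manifest)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        manifest.write()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    return manifest.write()


def demo_config(out_dir: str, **overrides) -> PipelineConfig:
    """A small, fast synthetic scenario exercising every stage."""
    base = dict(
        out_dir=out_dir,
        reruns=5,
        per_individual=50,
        n_random_steps=20,
        bootstrap_reps=50,
        simulation=dict(
            n_individuals=3,
            n_steps=700,
            n_rows=120,
            n_cols=120,
            beta={2: 0.8, 0: -0.4},
            detection_prob=0.95,
        ),
    )
    base.update(overrides)
    return PipelineConfig(**base)
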