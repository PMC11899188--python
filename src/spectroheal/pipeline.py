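"""End-to-end analysis pipeline: cohort -> T2 inversion -> FT-IR fits ->
PCA/ROC -> probability map, driven by one validated config.

Stages run in a fixed order, every random draw descends from the single
master seed, and each stage writes its tables under its own subdirectory of
the output root.  The run ends with a ``manifest.json`` recording the config,
seed, package versions and the SHA-256 of every written file: in synthetic
mode the manifest is a complete recipe — rerunning the same config and seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

import numpy as np
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__
from .cohort import Cohort, CohortConfig, generate_cohort, read_cohort, write_cohort
from .chemometrics import (
    PCAResult,
    ROCCurve,
    assemble_matrix,
    evolution_vectors,
    fit_pca,
    four_pairings,
    roc_curve,
)
from .ftir import BandFit, average_spectra, deconvolve_region
from .prediction import (
    ClassifierSpec,
    ProbabilityMap,
    predict_grid,
    train_classifier,
)
from .relaxometry import (
    ShiftReport,
    T2Distribution,
    build_t2_grid,
    compare_distributions,
    detect_peaks,
    invert_cpmg,
    select_lambda,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ReportBundle",
    "run_pipeline",
    "validate_config",
]

log = logging.getLogger("spectroheal")


class RelaxometryParams(BaseModel):
    t2_min_ms: float = Field(0.1, gt=0)
    t2_max_ms: float = Field(10_000.0, gt=0)
    n_grid: int = Field(128, ge=8)
    lam: float | Literal["auto"] = "auto"
    soluble_threshold_ms: float = Field(100.0, gt=0)
    min_rel_height: float = Field(0.01, gt=0, le=1)

    @field_validator("lam")
    @classmethod
    def _lam_non_negative(cls, v):
        if v != "auto" and v < 0:
            raise ValueError("regularization weight must be >= 0 or 'auto'")
        return v


class FTIRParams(BaseModel):
    windows: list[tuple[float, float]] = Field(
        default_factory=lambda: [(2700.0, 3800.0), (350.0, 1850.0)]
    )
    n_bands: list[int] = Field(default_factory=lambda: [11, 10])
    fit_targets: Literal["group_means", "none"] = "group_means"


class ChemometricsParams(BaseModel):
    wn_range: tuple[float, float] | None = None
    n_components: int = Field(5, ge=2)


class PredictionParams(BaseModel):
    hidden_layers: tuple[int, ...] = (16, 16)
    activation: Literal["relu", "tanh"] = "relu"
    max_iter: int = Field(2000, ge=1)
    l2_weight: float = Field(1e-4, ge=0)
    resolution: tuple[int, int] = (200, 200)


class PipelineConfig(BaseModel):
    input_mode: Literal["synthetic", "directory"] = "synthetic"
    input_dir: str | None = None
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    relaxometry: RelaxometryParams = Field(default_factory=RelaxometryParams)
    ftir: FTIRParams = Field(default_factory=FTIRParams)
    chemometrics: ChemometricsParams = Field(default_factory=ChemometricsParams)
    prediction: PredictionParams = Field(default_factory=PredictionParams)
    seed: int = 0


def validate_config(document: dict[str, Any]) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a config mapping; returns (config, []) or (None, errors).

    Every error string carries the config path and the reason; this function
    reports rather than raises so a CLI can print the full list at once.
    """
    try:
        cfg = PipelineConfig.model_validate(document)
    except ValidationError as exc:
        errors = [
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        ]
        return None, errors
    if cfg.input_mode == "directory":
        if not cfg.input_dir:
            return None, ["input_dir: required when input_mode is 'directory'"]
        if not Path(cfg.input_dir).is_dir():
            return None, [f"input_dir: {cfg.input_dir!r} is not a directory"]
    return cfg, []


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class ReportBundle:
    out_dir: Path
    cohort: Cohort
    distributions: dict[tuple[str, float], T2Distribution]
    shift_reports: dict[tuple[str, float], ShiftReport]
    band_fits: dict[tuple[str, str], BandFit]  # (spectrum label, window label)
    pca: PCAResult
    evolution: list
    rocs: list[ROCCurve]
    probability_map: ProbabilityMap
    manifest: dict[str, Any] = field(default_factory=dict)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dict__"):
        return o.__dict__
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default) + "\n")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            log.info(json.dumps({"stage": name, "seconds": round(time.perf_counter() - t0, 3)}))
            return out
        return wrapped
    return deco


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

@_stage("cohort")
def _stage_cohort(cfg: PipelineConfig, out: Path) -> Cohort:
    if cfg.input_mode == "synthetic":
        cohort_cfg = cfg.cohort.model_copy(update={"seed": cfg.seed})
        cohort = generate_cohort(cohort_cfg)
    else:
        assert cfg.input_dir is not None
        cohort = read_cohort(cfg.input_dir)
    write_cohort(cohort, out / "cohort")
    return cohort


@_stage("relaxometry")
def _stage_relaxometry(cfg: PipelineConfig, cohort: Cohort, out: Path):
    p = cfg.relaxometry
    grid = build_t2_grid(p.t2_min_ms, p.t2_max_ms, p.n_grid)
    rdir = out / "relaxometry"
    rdir.mkdir(parents=True, exist_ok=True)

    # one lambda per echo time, chosen on the first subject and shared: the
    # noise level is homogeneous across a cohort measured on one instrument
    lam_by_te: dict[float, float] = {}
    te_values = sorted({te for (_, te) in cohort.decays})
    for te in te_values:
        if p.lam == "auto":
            sid0 = min(sid for (sid, t) in cohort.decays if t == te)
            lam_by_te[te] = select_lambda(cohort.decays[(sid0, te)], grid)
        else:
            lam_by_te[te] = float(p.lam)

    dists: dict[tuple[str, float], T2Distribution] = {}
    peak_report: dict[str, dict] = {}
    for (sid, te), decay in sorted(cohort.decays.items()):
        dist = invert_cpmg(decay, grid, lam=lam_by_te[te])
        dists[(sid, te)] = dist
        peaks = detect_peaks(
            dist,
            min_rel_height=p.min_rel_height,
            soluble_threshold_ms=p.soluble_threshold_ms,
        )
        key = f"{sid}_te{te:g}"
        with (rdir / f"{key}_t2dist.csv").open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["T2_ms", "f"])
            for t2, fv in zip(dist.grid.values, dist.f):
                w.writerow([f"{t2:.8g}", f"{fv:.10g}"])
        peak_report[key] = {
            "lambda": lam_by_te[te],
            "fit_residual": dist.fit_residual,
            "peaks": [
                {
                    "position_ms": pk.position_ms,
                    "area_fraction": pk.area_fraction,
                    "width_log10": pk.width_log10,
                    "fraction_class": pk.fraction_class.value,
                }
                for pk in peaks
            ],
        }
    _write_json(rdir / "peaks.json", peak_report)

    shifts: dict[tuple[str, float], ShiftReport] = {}
    pairs = sorted(
        {r.pair_id for r in cohort.records if r.group == "crc_post"},
        key=lambda pid: (len(pid), pid),
    )
    shift_json = {}
    for pid in pairs:
        for te in te_values:
            rep = compare_distributions(
                dists[(f"{pid}_pre", te)],
                dists[(f"{pid}_post", te)],
                min_rel_height=p.min_rel_height,
                soluble_threshold_ms=p.soluble_threshold_ms,
            )
            shifts[(pid, te)] = rep
            shift_json[f"{pid}_te{te:g}"] = {
                "main_peak_shift_decades": rep.main_peak_shift,
                "magnitude_class": rep.magnitude_class.value,
                "n_new_peaks": len(rep.new_peaks),
                "n_vanished_peaks": len(rep.vanished_peaks),
            }
    _write_json(rdir / "shift_reports.json", shift_json)
    return dists, shifts


@_stage("ftir")
def _stage_ftir(cfg: PipelineConfig, cohort: Cohort, out: Path):
    fdir = out / "ftir"
    fdir.mkdir(parents=True, exist_ok=True)
    by_group: dict[str, list] = {"healthy": [], "crc_pre": [], "crc_post": []}
    for rec in cohort.records:
        by_group[rec.group].append(cohort.spectra[rec.subject_id])
    means = {g: average_spectra(sp) for g, sp in by_group.items() if sp}
    from .ftir import write_spectrum_csv

    for g, spec in means.items():
        write_spectrum_csv(spec, fdir / f"mean_{g}.csv")

    fits: dict[tuple[str, str], BandFit] = {}
    if cfg.ftir.fit_targets == "group_means":
        if len(cfg.ftir.windows) != len(cfg.ftir.n_bands):
            raise ValueError("ftir.windows and ftir.n_bands differ in length")
        rows = []
        for g, spec in means.items():
            for (lo, hi), nb in zip(cfg.ftir.windows, cfg.ftir.n_bands):
                wlabel = f"{lo:g}-{hi:g}"
                fit = deconvolve_region(spec, (lo, hi), nb)
                fits[(f"mean_{g}", wlabel)] = fit
                for b in fit.bands:
                    rows.append(
                        [f"mean_{g}", wlabel, f"{b.center:.6g}", f"{b.sigma:.6g}",
                         f"{b.amplitude:.8g}", b.assignment]
                    )
        with (fdir / "band_fits.csv").open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["spectrum", "window", "center_cm1", "sigma_cm1", "amplitude", "assignment"])
            w.writerows(rows)
        _write_json(
            fdir / "band_fit_summary.json",
            {
                f"{k[0]}|{k[1]}": {
                    "r_squared": v.r_squared,
                    "residual_rms": v.residual_rms,
                    "converged": v.converged,
                }
                for k, v in fits.items()
            },
        )
    return fits


@_stage("chemometrics")
def _stage_chemometrics(cfg: PipelineConfig, cohort: Cohort, out: Path):
    cdir = out / "chemometrics"
    cdir.mkdir(parents=True, exist_ok=True)
    matrix = assemble_matrix(
        list(cohort.spectra.values()), cohort.records, wn_range=cfg.chemometrics.wn_range
    )
    n_comp = min(cfg.chemometrics.n_components, matrix.X.shape[0] - 1)
    pca = fit_pca(matrix, n_components=n_comp)

    with (cdir / "scores.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group"] + [f"PC{k + 1}" for k in range(n_comp)])
        for i, sid in enumerate(pca.row_ids):
            w.writerow([sid, pca.groups[i]] + [f"{v:.10g}" for v in pca.scores[i]])
    with (cdir / "loadings.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["wavenumber_cm1"] + [f"PC{k + 1}" for k in range(n_comp)])
        for j, wn in enumerate(matrix.axis):
            w.writerow([f"{wn:.6g}"] + [f"{pca.loadings[k, j]:.10g}" for k in range(n_comp)])
    with (cdir / "explained_variance.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["component", "explained_variance_ratio"])
        for k, ev in enumerate(pca.explained_variance_ratio):
            w.writerow([f"PC{k + 1}", f"{ev:.10g}"])

    evo = evolution_vectors(pca, cohort.records)
    _write_json(
        cdir / "evolution_vectors.json",
        {
            v.patient_id: {
                "pre": v.pre_score,
                "post": v.post_score,
                "direction": v.direction,
                "length": v.length,
            }
            for v in evo
        },
    )

    rocs: list[ROCCurve] = []
    auc_rows = []
    groups = np.array(pca.groups)
    for pairing in four_pairings(cohort.records):
        m = np.isin(groups, list(pairing.positive_labels | pairing.negative_labels))
        y = np.isin(groups[m], list(pairing.positive_labels))
        for k, name in enumerate(["PC1", "PC2"]):
            rc = roc_curve(pca.scores[m, k], y, score_name=name, pairing=pairing.name)
            rocs.append(rc)
            auc_rows.append(
                [pairing.name, name, f"{rc.auc:.6g}", f"{rc.optimal_cutpoint[0]:.4g}",
                 f"{rc.optimal_cutpoint[1]:.4g}", f"{rc.optimal_cutpoint[2]:.6g}",
                 str(rc.partner_positive)]
            )
            with (cdir / f"roc_{pairing.name}_{name}.csv").open("w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["threshold", "sensitivity", "specificity"])
                for t, se, sp in zip(rc.thresholds, rc.sensitivity, rc.specificity):
                    w.writerow([f"{t:.10g}", f"{se:.6g}", f"{sp:.6g}"])
    with (cdir / "auc_table.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pairing", "score", "auc", "cut_sensitivity", "cut_specificity",
                    "cut_threshold", "partner_positive"])
        w.writerows(auc_rows)
    return matrix, pca, evo, rocs


@_stage("prediction")
def _stage_prediction(cfg: PipelineConfig, pca: PCAResult, out: Path):
    pdir = out / "prediction"
    pdir.mkdir(parents=True, exist_ok=True)
    spec = ClassifierSpec(
        hidden_layers=cfg.prediction.hidden_layers,
        activation=cfg.prediction.activation,
        max_iter=cfg.prediction.max_iter,
        seed=cfg.seed,
        l2_weight=cfg.prediction.l2_weight,
    )
    scores2d = pca.scores[:, :2]
    clf = train_classifier(scores2d, pca.groups, spec)
    pmap = predict_grid(
        clf, resolution=cfg.prediction.resolution, train_scores=scores2d
    )
    for ci, cname in enumerate(pmap.classes):
        with (pdir / f"prob_{cname}.csv").open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pc1\\pc2"] + [f"{v:.8g}" for v in pmap.pc2_axis])
            for i, p1 in enumerate(pmap.pc1_axis):
                w.writerow([f"{p1:.8g}"] + [f"{p:.8g}" for p in pmap.probs[i, :, ci]])
    _write_json(
        pdir / "map_meta.json",
        {
            "classes": list(pmap.classes),
            "pc1_range": [float(pmap.pc1_axis[0]), float(pmap.pc1_axis[-1])],
            "pc2_range": [float(pmap.pc2_axis[0]), float(pmap.pc2_axis[-1])],
            "resolution": list(cfg.prediction.resolution),
            "train_accuracy": clf.train_accuracy,
            "final_loss": clf.final_loss,
            "classifier": {
                "hidden_layers": list(spec.hidden_layers),
                "activation": spec.activation,
                "l2_weight": spec.l2_weight,
                "max_iter": spec.max_iter,
                "seed": spec.seed,
            },
        },
    )
    return pmap


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> ReportBundle:
    """Execute all stages; any failure aborts with a stage-tagged error."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _stage_cohort(config, out)
    dists, shifts = _stage_relaxometry(config, cohort, out)
    fits = _stage_ftir(config, cohort, out)
    matrix, pca, evo, rocs = _stage_chemometrics(config, cohort, out)
    pmap = _stage_prediction(config, pca, out)

    import sklearn

    manifest: dict[str, Any] = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "versions": {
            "spectroheal": __version__,
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "files": {},
    }
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest["files"][str(path.relative_to(out))] = digest
    _write_json(out / "manifest.json", manifest)
    return ReportBundle(
        out_dir=out,
        cohort=cohort,
        distributions=dists,
        shift_reports=shifts,
        band_fits=fits,
        pca=pca,
        evolution=evo,
        rocs=rocs,
        probability_map=pmap,
        manifest=manifest,
    )
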