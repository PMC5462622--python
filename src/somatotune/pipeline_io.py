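"""End-to-end orchestration, file formats, and configuration.

Owns the run configuration schema, deterministic seed derivation, all disk
formats (4D NIfTI + JSON cue schedules, CSV trial/metabolite/metric tables,
JSON reports with provenance), and the simulate -> tuning -> JND -> MRS ->
report pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__, mrsquant, psychophys, stats, synthdata, travelwave
from .synthdata import CohortTruth, SimGrid, TOJObserver
from .travelwave import TaskDesign

__all__ = [
    "RunConfig",
    "derive_seed",
    "save_run_nifti",
    "load_run_nifti",
    "read_metrics_csv",
    "compute_tuning_from_run",
    "build_report",
    "run_end_to_end",
]

logger = logging.getLogger(__name__)

METRICS_COLUMNS = ("subject", "gaba_cr", "glu_cr", "tuning", "jnd", "cohort")


@dataclass
class RunConfig:
    """Validated configuration for an end-to-end synthetic run."""

    out_dir: str
    seed: int = 0
    n_subjects: int = 12
    cohort_mode: str = "metric"  # "metric" | "raw"
    path_a: float = 0.7
    path_b: float = -0.6
    path_c_prime: float = 0.0
    noise_sd_m: float = 0.5
    noise_sd_y: float = 0.5
    # raw-mode knobs
    grid_shape: tuple[int, ...] = (3, 3, 1)
    grid_noise_sd: float = 0.35
    tr: float = 1.5
    block_s: float = 8.0
    n_cycles: int = 8
    trials_per_isi: int = 16
    # analysis knobs
    alpha: float = 0.01
    qc_mode: str = "default"
    n_boot: int = 5000
    aggregation: str = "inverse_of_mean"
    write_nifti: bool = False

    def __post_init__(self) -> None:
        if self.cohort_mode not in ("metric", "raw"):
            raise ValueError(f"cohort_mode: expected 'metric' or 'raw', got {self.cohort_mode!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha: must be in (0, 1)")
        if self.n_subjects < 4:
            raise ValueError("n_subjects: must be >= 4")
        if self.qc_mode not in mrsquant.QC_RULES:
            raise ValueError(f"qc_mode: unknown mode {self.qc_mode!r}")
        if self.n_boot < 1000:
            raise ValueError("n_boot: must be >= 1000")
        self.grid_shape = tuple(int(v) for v in self.grid_shape)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(global_seed: int, *labels) -> int:
    """Deterministic per-consumer seed from the global seed and a label path."""
    key = json.dumps([int(global_seed), *map(str, labels)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little")


# ---------------------------------------------------------------------------
# formats


def save_run_nifti(data: np.ndarray, path: str | Path,
                   schedule: list[dict] | None = None,
                   affine: np.ndarray | None = None) -> None:
    """Write a 4D run as NIfTI plus (optionally) its JSON cue schedule."""
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, np.float64), affine), str(path))
    if schedule is not None:
        Path(str(path) + ".schedule.json").write_text(json.dumps(schedule, indent=1))


def load_run_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[dict] | None]:
    img = nib.load(str(path))
    sched_path = Path(str(path) + ".schedule.json")
    schedule = json.loads(sched_path.read_text()) if sched_path.exists() else None
    return np.asarray(img.dataobj), img.affine, schedule


def write_table_csv(df: pd.DataFrame, path: str | Path) -> None:
    """CSV writer with value-exact float round-trip (17 significant digits)."""
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_table_csv(path: str | Path) -> pd.DataFrame:
    """CSV reader paired with :func:`write_table_csv`.

    pandas' default fast float parser is not correctly rounded (can be off
    by one ulp); round_trip parsing restores bit-exact values.
    """
    return pd.read_csv(path, float_precision="round_trip")


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns and c != "cohort"]
    if missing:
        raise ValueError(f"metrics CSV missing required columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# per-subject raw-data analysis


def compute_tuning_from_run(
    data_forward: np.ndarray,
    data_backward: np.ndarray,
    design: TaskDesign,
    alpha: float = 0.01,
    aggregation: str = "inverse_of_mean",
) -> float:
    """Tuning metric from a forward/backward pair of 4D runs."""
    lags = travelwave.default_lag_grid(design)
    maps = {}
    for key, data, direction in (("f", data_forward, "forward"),
                                 ("b", data_backward, "backward")):
        des = TaskDesign(tr=design.tr, block_s=design.block_s,
                         n_cycles=design.n_cycles, digits=design.digits,
                         direction=direction)
        bank = np.stack([travelwave.build_reference_model(des, lag) for lag in lags])
        flat = data.reshape(-1, data.shape[-1])
        r = np.empty((flat.shape[0], lags.size))
        valid = np.empty(flat.shape[0], bool)
        for i in range(flat.shape[0]):
            prof = travelwave.compute_tuning_profile(flat[i], des, lags, models=bank)
            r[i], valid[i] = prof.r, prof.valid
        maps[key] = travelwave.fit_sinusoid_map(
            r.reshape(*data.shape[:-1], lags.size), lags,
            valid.reshape(data.shape[:-1]), cycle_s=design.cycle_s)
    combined = travelwave.combine_runs(maps["f"], maps["b"])
    amp = np.where(combined.converged, combined.amplitude, np.nan)
    roi = travelwave.define_roi(amp, n_timepoints=design.n_volumes, alpha=alpha)
    roi.mask &= combined.converged
    if roi.n_voxels == 0:
        return float("nan")
    return travelwave.tuning_metric(combined.period, roi, aggregation=aggregation)


# ---------------------------------------------------------------------------
# reporting


def build_report(metrics: pd.DataFrame, n_boot: int = 5000, seed: int = 0,
                 alpha: float = 0.05) -> dict:
    """Every statistic of the inferential layer from a per-subject table.

    Pairwise correlations, the GABA-vs-Glu dependent-correlation
    comparisons, the conjunction/omnibus compound test, and (when every
    column is present) the X -> M -> Y mediation.
    """
    report: dict = {"n": int(len(metrics)), "correlations": {}}
    pairs = [("gaba_cr", "tuning"), ("gaba_cr", "jnd"), ("tuning", "jnd"),
             ("glu_cr", "tuning"), ("glu_cr", "jnd")]
    for xcol, ycol in pairs:
        if xcol not in metrics or ycol not in metrics:
            continue
        sub = metrics[[xcol, ycol]].dropna()
        res = stats.pearson_with_p(sub[xcol].to_numpy(), sub[ycol].to_numpy())
        report["correlations"][f"{xcol}__{ycol}"] = {
            "r": res.r, "n": res.n, "p": res.p_two_tailed}

    if "glu_cr" in metrics:
        comparisons = {}
        for target in ("tuning", "jnd"):
            sub = metrics[["gaba_cr", "glu_cr", target]].dropna()
            if len(sub) < 10:
                continue
            cmp_res = stats.hittner_test(
                r_xy=np.corrcoef(sub[target], sub["gaba_cr"])[0, 1],
                r_xz=np.corrcoef(sub[target], sub["glu_cr"])[0, 1],
                r_yz=np.corrcoef(sub["gaba_cr"], sub["glu_cr"])[0, 1],
                n=len(sub))
            comparisons[f"gaba_vs_glu__{target}"] = {
                "z": cmp_res.z_stat, "p_one_tailed": cmp_res.p_one_tailed,
                "p_two_tailed": cmp_res.p_two_tailed}
        report["dependent_comparisons"] = comparisons

        predicted = [v["p"] for k, v in report["correlations"].items()
                     if not k.startswith("glu_cr")]
        unpredicted = [v["p"] for k, v in report["correlations"].items()
                       if k.startswith("glu_cr")]
        if predicted and unpredicted:
            co = stats.conjunction_omnibus(predicted, unpredicted, alpha=alpha)
            report["conjunction_omnibus"] = {
                "conjunction_statistic": co.conjunction_statistic,
                "omnibus_statistic": co.omnibus_statistic,
                "alpha": co.alpha,
                "reject_compound_null": co.reject_compound_null}

        sub = metrics[["gaba_cr", "glu_cr", "tuning"]].dropna()
        if len(sub) >= 5:
            pc = stats.partial_correlation(sub["gaba_cr"].to_numpy(),
                                           sub["tuning"].to_numpy(),
                                           sub["glu_cr"].to_numpy())
            report["partial_gaba_tuning_given_glu"] = {
                "r": pc.r, "n": pc.n, "p": pc.p_two_tailed}

    med_cols = metrics[["gaba_cr", "tuning", "jnd"]].dropna()
    if len(med_cols) >= 10:
        med = stats.mediate(med_cols["gaba_cr"].to_numpy(),
                            med_cols["tuning"].to_numpy(),
                            med_cols["jnd"].to_numpy(),
                            n_boot=n_boot, seed=seed)
        report["mediation"] = {
            "a": med.a, "b": med.b, "c_total": med.c_total,
            "c_prime": med.c_prime, "indirect": med.indirect,
            "boot_ci": list(med.boot_ci), "p_m": med.p_m,
            "sobel_z": med.sobel_z, "sobel_p": med.sobel_p,
            "kappa2": med.kappa2, "n_boot": med.n_boot, "seed": med.seed,
            "warnings": list(med.warnings)}
    return report


def _simulate_subject_metrics(cfg: RunConfig) -> pd.DataFrame:
    truth = CohortTruth(
        n_subjects=cfg.n_subjects, path_a=cfg.path_a, path_b=cfg.path_b,
        path_c_prime=cfg.path_c_prime, noise_sd_m=cfg.noise_sd_m,
        noise_sd_y=cfg.noise_sd_y, seed=derive_seed(cfg.seed, "cohort"))
    latent = synthdata.simulate_cohort(truth)

    mrs = synthdata.simulate_mrs_table(cfg.n_subjects,
                                       seed=derive_seed(cfg.seed, "mrs"))
    glu = []
    for i in range(cfg.n_subjects):
        voxel = mrs[mrs["subject"] == f"S{i:03d}"]
        ratios, _ = mrsquant.metabolite_ratios(voxel, qc_mode=cfg.qc_mode)
        glu.append(ratios["glu_cr"])
    latent["glu_cr"] = glu

    if cfg.cohort_mode == "metric":
        latent["cohort"] = "sim"
        return latent[list(METRICS_COLUMNS)]

    design = TaskDesign(tr=cfg.tr, block_s=cfg.block_s, n_cycles=cfg.n_cycles)
    widths = synthdata.tuning_to_width(latent["tuning"].to_numpy())
    slopes = synthdata.jnd_truth_to_slope(latent["jnd"].to_numpy())
    tuning_meas, jnd_meas = [], []
    for i in range(cfg.n_subjects):
        grid = SimGrid.uniform(cfg.grid_shape, tuning_width=float(widths[i]),
                               noise_sd=cfg.grid_noise_sd,
                               seed=derive_seed(cfg.seed, "grid", i))
        fwd, _ = synthdata.simulate_fmri_run(
            grid, design, "forward", seed=derive_seed(cfg.seed, "fmri_f", i))
        bwd, _ = synthdata.simulate_fmri_run(
            grid, design, "backward", seed=derive_seed(cfg.seed, "fmri_b", i))
        tuning_meas.append(compute_tuning_from_run(
            fwd, bwd, design, alpha=cfg.alpha, aggregation=cfg.aggregation))
        observer = TOJObserver(mu=0.0, slope=float(slopes[i]))
        trials = synthdata.simulate_toj_trials(
            observer, trials_per_isi=cfg.trials_per_isi,
            seed=derive_seed(cfg.seed, "toj", i))
        fit = psychophys.fit_trials(trials)
        jnd_meas.append(fit.jnd if fit.accepted else np.nan)
    out = latent.copy()
    out["tuning"] = tuning_meas
    out["jnd"] = jnd_meas
    out["cohort"] = "sim"
    return out[list(METRICS_COLUMNS)]


def run_end_to_end(cfg: RunConfig) -> dict:
    """Simulate a cohort, compute per-subject metrics, and produce the
    statistics report. Writes metrics.csv and report.json (with provenance)
    under ``cfg.out_dir`` and returns the report."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics = _simulate_subject_metrics(cfg)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.12g",
                   lineterminator="\n")

    usable = metrics.dropna(subset=["gaba_cr", "tuning", "jnd"])
    report = build_report(usable, n_boot=cfg.n_boot,
                          seed=derive_seed(cfg.seed, "boot"))
    report["provenance"] = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "n_subjects_usable": int(len(usable)),
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("end-to-end run complete in %.1fs", time.time() - t0)
    return report
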