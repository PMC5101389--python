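"""End-to-end study orchestration: design → simulate → fit → optimize → validate.

Every artifact is plain CSV/JSON/markdown; a manifest lists each file with a
content hash so a bundle can be verified and every stage rerun from the
previous stage's files.  All randomness flows from the seeds in
:class:`StudyConfig` and is logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .doe import HILIC_FACTORS, FactorDef, build_ccd
from .optimizer import OptimizationCriteria, grid_search
from .pls import coefficient_plot_table, fit_response_models
from .simulator import (
    COMPOUND_NAMES,
    COMPOUND_ROLES,
    NOMINAL_100,
    MethodConditions,
    RetentionGroundTruth,
    default_ground_truth,
    generate_study,
    simulate_calibration,
    simulate_chromatogram,
    simulate_retention,
    simulate_spiked_placebo,
    simulate_tablet_sample,
)
from .validation import (
    ValidationReport,
    assay_tablet,
    assess_accuracy,
    assess_precision,
    assess_selectivity,
    check_specification,
    fit_linearity,
    lod_loq_from_trace,
    recovery_records,
    robustness_ofat,
)

log = logging.getLogger("chromdoe")

RESPONSE_COLUMNS = ("k_M", "k_A", "k_B", "k_C", "k_D", "Rs_AB", "Rs_CD")

#: tablet contents emulated by default: API at 97.5 % of label claim,
#: impurities C/D at 0.68 %/0.87 %, A/B absent (below LOQ)
DEFAULT_TABLET_CONTENT = {"moxonidine": 97.5, "impurity_a": 0.0,
                          "impurity_b": 0.0, "impurity_c": 0.68,
                          "impurity_d": 0.87}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class StudyConfig:
    """Configuration of a full in-silico method-development study."""

    factors: tuple[FactorDef, ...] = HILIC_FACTORS
    n_center: int = 6
    alpha_mode: str = "rotatable"
    seed: int = 1
    noise: bool = True
    sigma_logk: float | None = None     # None -> ground-truth default
    min_resolution: float = 2.0
    max_last_peak_time: float = 12.0
    objective: str = "minimize_run_time"
    grid_points: int = 21
    tablet_content: dict = field(default_factory=lambda: dict(DEFAULT_TABLET_CONTENT))

    def criteria(self) -> OptimizationCriteria:
        return OptimizationCriteria(min_resolution=self.min_resolution,
                                    max_last_peak_time=self.max_last_peak_time,
                                    objective=self.objective)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["factors"] = [dataclasses.asdict(f) for f in self.factors]
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "factors" in d:
            d["factors"] = tuple(FactorDef(**f) for f in d["factors"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def read_responses(path) -> pd.DataFrame:
    """Read a response table CSV, validating columns and every row.

    Tolerates surrounding whitespace; reports malformed rows with their line
    number.
    """
    frame = pd.read_csv(path, skipinitialspace=True)
    frame.columns = [c.strip() for c in frame.columns]
    missing = [c for c in ("run_id",) + RESPONSE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in RESPONSE_COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[values.isna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(f"{path}: malformed value in column {col!r} "
                             f"at line {int(bad[0]) + 2}")
        frame[col] = values
        if (values < 0).any() or not np.isfinite(values).all():
            raise ValueError(f"{path}: column {col!r} must be finite and >= 0")
    return frame


def write_report(report: ValidationReport, path) -> list[Path]:
    """Write a validation report as JSON and markdown next to each other."""
    path = Path(path)
    json_path = path.with_suffix(".json")
    md_path = path.with_suffix(".md")
    report.to_json(json_path)
    md_path.write_text(report.to_markdown())
    return [json_path, md_path]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_validation(
    truth: RetentionGroundTruth,
    config: StudyConfig,
    conditions: MethodConditions | None = None,
) -> ValidationReport:
    """Run the full validation battery on the simulator at given conditions."""
    conditions = conditions or MethodConditions()
    seed = np.random.SeedSequence(config.seed).spawn(1)[0]
    rng = np.random.default_rng(seed)
    report = ValidationReport()

    # linearity ---------------------------------------------------------
    for name in COMPOUND_NAMES:
        cal_seed = int(rng.integers(2**31))
        log.info("calibration seed for %s: %d", name, cal_seed)
        series = simulate_calibration(name, seed=cal_seed)
        report.linearity[name] = fit_linearity(series)

    # sensitivity: S/N of a dilute standard of each impurity --------------
    outcome = simulate_retention(truth, conditions, noise=False)
    for name in COMPOUND_NAMES:
        if COMPOUND_ROLES[name] == "API":
            continue
        conc = 0.12 if name in ("impurity_a", "impurity_b") else 0.24
        single = simulate_retention(truth, conditions, noise=False,
                                    concentrations={name: conc})
        trace_seed = int(rng.integers(2**31))
        log.info("sensitivity trace seed for %s: %d", name, trace_seed)
        trace = simulate_chromatogram(single, truth.baseline_sigma,
                                      seed=trace_seed, include=(name,))
        tr, w = single.tr[name], single.width[name]
        report.sensitivity[name] = lod_loq_from_trace(
            trace, peak_window=(tr - w, tr + w),
            noise_window=(0.2, max(1.5, tr - 3 * w - 1.0)),
            conc=conc, compound=name)

    # accuracy / precision ----------------------------------------------
    records = []
    for name in COMPOUND_NAMES:
        spike_seed = int(rng.integers(2**31))
        log.info("recovery seed for %s: %d", name, spike_seed)
        samples = simulate_spiked_placebo(name, seed=spike_seed)
        records.extend(recovery_records(samples))
    report.recovery = assess_precision(assess_accuracy(records))

    # robustness ----------------------------------------------------------
    report.robustness = robustness_ofat(truth, conditions)

    # selectivity ---------------------------------------------------------
    placebo_seed = int(rng.integers(2**31))
    log.info("placebo trace seed: %d", placebo_seed)
    placebo = simulate_chromatogram(outcome, truth.baseline_sigma,
                                    seed=placebo_seed, include=())
    windows = {n: (outcome.tr[n] - outcome.width[n], outcome.tr[n] + outcome.width[n])
               for n in COMPOUND_NAMES}
    loq_heights = {}
    for n in COMPOUND_NAMES:
        sens = report.sensitivity.get(n)
        loq_conc = sens.loq_conc if sens else 0.1 * NOMINAL_100[n]
        loq_heights[n] = outcome.height[n] / NOMINAL_100[n] * loq_conc \
            if NOMINAL_100[n] else outcome.height[n]
    report.selectivity = assess_selectivity(placebo, windows, loq_heights)

    # tablet assay --------------------------------------------------------
    assay_seed = int(rng.integers(2**31))
    log.info("tablet assay seed: %d", assay_seed)
    sample = simulate_tablet_sample(config.tablet_content, truth=truth,
                                    seed=assay_seed)
    report.assay = assay_tablet(sample, report.linearity, report.sensitivity)
    report.assay_within_spec = check_specification(report.assay)
    return report


def run_study(
    config: StudyConfig,
    outdir,
    truth: RetentionGroundTruth | None = None,
) -> dict:
    """Run the full pipeline and write the artifact bundle to ``outdir``.

    Returns a summary dict with the per-stage objects and the manifest.
    Stage failures raise :class:`StageError` naming the stage; artifacts of
    completed stages are retained on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = truth or default_ground_truth()
    if config.sigma_logk is not None:
        truth = dataclasses.replace(truth, sigma_logk=config.sigma_logk)
    written: list[Path] = []
    summary: dict = {}

    def _write(path: Path, writer) -> Path:
        writer(path)
        written.append(path)
        return path

    stage = "design"
    try:
        design = build_ccd(config.factors, n_center=config.n_center,
                           alpha_mode=config.alpha_mode)
        _write(outdir / "design.csv", design.to_csv)
        (outdir / "factors.yaml").write_text(yaml.safe_dump(
            [dataclasses.asdict(f) for f in config.factors], sort_keys=False))
        written.append(outdir / "factors.yaml")
        summary["design"] = design

        stage = "simulate"
        log.info("study seed: %d", config.seed)
        responses = generate_study(truth, design, seed=config.seed,
                                   noise=config.noise)
        _write(outdir / "responses.csv",
               lambda p: responses.to_csv(p, index=False))
        summary["responses"] = responses

        stage = "fit"
        models = fit_response_models(design, responses.drop(columns="run_id"))
        models_dir = outdir / "models"
        models_dir.mkdir(exist_ok=True)
        coef_tables = []
        for name, model in models.items():
            _write(models_dir / f"{name}.json", model.to_json)
            tab = coefficient_plot_table(model)
            tab.insert(0, "response", name)
            coef_tables.append(tab)
        _write(outdir / "coefficients.csv",
               lambda p: pd.concat(coef_tables).to_csv(p, index=False))
        summary["models"] = models

        stage = "optimize"
        opt = grid_search(models, config.factors, config.criteria(),
                          t0=truth.t0, n_points=config.grid_points)
        _write(outdir / "optimum.csv", lambda p: opt.table.to_csv(p, index=False))
        summary["optimization"] = opt
        # validation runs at the declared method conditions: the analyst
        # rounds the optimizer's suggestion to practical set points, and the
        # shipped defaults (80 % ACN, pH 2.8, 40 mM) are exactly that for the
        # default study
        conditions = MethodConditions()
        summary["method_conditions"] = conditions

        stage = "validate"
        report = run_validation(truth, config, conditions=conditions)
        written.extend(write_report(report, outdir / "validation"))
        summary["validation"] = report
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {p.name if p.parent == outdir else f"{p.parent.name}/{p.name}":
                _sha256(p) for p in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    summary["manifest"] = manifest
    return summary
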