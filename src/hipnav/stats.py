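"""Study-level summaries of navigation errors and the end-to-end runner.

Aggregates per-case navigation errors into the study's descriptive
statistics — mean, sample SD, range, absolute-value mean/SD per metric, and
percentage of cases exceeding 5/10 degree thresholds — plus plot-ready data
exports (boxplot quantiles and scatter pairs) as CSV files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .postop import AssessmentParams, NavigationError, assess_case
from .synthetic import SceneConfig, simulate_case

METRICS = {
    "anteversion": ("d_anteversion", "Anteversion (°)"),
    "inclination": ("d_inclination", "Inclination (°)"),
    "depth": ("d_depth", "Depth (mm)"),
}
_ANGLE_METRICS = ("anteversion", "inclination")


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sd: float
    min: float
    max: float
    abs_mean: float
    abs_sd: float


@dataclass(frozen=True)
class StudySummary:
    """Per-metric summary statistics over all navigation-error rows."""

    n_cases: int
    metrics: dict                   # metric name -> MetricSummary
    exceedance: dict                # metric name -> {threshold_deg: percent}

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "metrics": {k: asdict(v) for k, v in self.metrics.items()},
            "exceedance": {k: {str(t): p for t, p in v.items()}
                           for k, v in self.exceedance.items()},
        }

    def to_table(self) -> pd.DataFrame:
        """Mean/SD table in the layout of the study report
        (rows 'Anteversion (°)' / 'Inclination (°)' / 'Depth (mm)')."""
        rows = []
        for key, (_, label) in METRICS.items():
            m = self.metrics[key]
            rows.append({"Metrics": label, "Mean": round(m.mean, 2),
                         "SD": round(m.sd, 2)})
        return pd.DataFrame(rows)


def exceedance(errors, threshold: float) -> float:
    """Percentage of values with ``|error| > threshold`` (strict)."""
    values = _metric_values(errors)
    if len(values) == 0:
        raise ValueError("empty error list")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float(100.0 * np.count_nonzero(np.abs(values) > threshold)
                 / len(values))


def _metric_values(errors) -> np.ndarray:
    if len(errors) and isinstance(errors[0], NavigationError):
        raise TypeError("pass a sequence of numbers for one metric")
    return np.asarray(errors, dtype=float)


def summarize_errors(errors, thresholds=(5.0, 10.0)) -> StudySummary:
    """Descriptive statistics of navigation errors (sample SD, n-1).

    ``errors`` is a sequence of :class:`NavigationError`; requires n >= 2.
    Exceedance percentages are computed for the angle metrics at the given
    thresholds (degrees), with strict inequality.
    """
    errors = list(errors)
    if len(errors) < 2:
        raise ValueError("need at least 2 error rows (SD undefined otherwise)")
    metrics, exceed = {}, {}
    for key, (attr, _) in METRICS.items():
        x = np.array([getattr(e, attr) for e in errors], dtype=float)
        metrics[key] = MetricSummary(
            mean=float(x.mean()), sd=float(x.std(ddof=1)),
            min=float(x.min()), max=float(x.max()),
            abs_mean=float(np.abs(x).mean()),
            abs_sd=float(np.abs(x).std(ddof=1)),
        )
        if key in _ANGLE_METRICS:
            exceed[key] = {float(t): exceedance(x, float(t))
                           for t in thresholds}
    return StudySummary(len(errors), metrics, exceed)


# -- study runner ----------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """A batch of simulated cases assessed end to end.

    ``scene`` holds the per-case study conditions (its seed is re-derived
    per case from the study seed). The inter-rater design keeps
    ``scene.n_raters`` raters per case and yields one error row per rater
    per case; set ``scene.n_raters = 1`` for the patient-style design.
    """

    seed: int = 0
    n_cases: int = 5
    scene: SceneConfig = field(default_factory=SceneConfig)
    assessment: AssessmentParams = field(default_factory=AssessmentParams)
    thresholds: tuple = (5.0, 10.0)

    def to_yaml(self, path) -> None:
        import yaml

        d = {"seed": self.seed, "n_cases": self.n_cases,
             "thresholds": list(self.thresholds),
             "scene": {**asdict(self.scene),
                       "region_counts": dict(self.scene.region_counts)},
             "assessment": asdict(self.assessment)}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            seed=d.get("seed", 0), n_cases=d.get("n_cases", 5),
            scene=SceneConfig(**d.get("scene", {})),
            assessment=AssessmentParams(**d.get("assessment", {})),
            thresholds=tuple(d.get("thresholds", (5.0, 10.0))),
        )


def case_seed(study_seed: int, index: int) -> int:
    """Per-case seed derived reproducibly from the study seed."""
    return int(np.random.SeedSequence(study_seed,
                                      spawn_key=(index,)).generate_state(1)[0]
               % 2**31)


@dataclass(frozen=True)
class StudyResult:
    cases: pd.DataFrame             # one row per (case, rater)
    summary: StudySummary
    failures: tuple                 # (case_id, message) pairs


def run_study(config: StudyConfig, out_dir=None) -> StudyResult:
    """Simulate and assess all cases; optionally write study outputs.

    Per-case failures are recorded and the study continues. When ``out_dir``
    is given, writes ``cases.csv``, ``summary.json``, ``summary_table.csv``,
    ``boxplot.csv`` (Tukey quantiles per metric) and ``scatter.csv``
    (anteversion/inclination error pairs). Fully deterministic given
    ``config``.
    """
    rows, errors, failures = [], [], []
    for i in range(config.n_cases):
        cid = f"case_{i + 1:03d}"
        try:
            scene = replace(config.scene, seed=case_seed(config.seed, i))
            case = simulate_case(scene)
            assessment = replace(config.assessment,
                                 seed=case_seed(config.seed, i) + 1)
            result = assess_case(case.without_truth(), assessment, case_id=cid)
        except Exception as exc:  # noqa: BLE001 - per-case isolation
            failures.append((cid, f"{type(exc).__name__}: {exc}"))
            continue
        for err, rms in zip(result.errors, result.rater_rms_mm):
            errors.append(err)
            rows.append({
                "case_id": err.case_id, "rater_id": err.rater_id,
                "d_anteversion_deg": err.d_anteversion,
                "d_inclination_deg": err.d_inclination,
                "d_depth_mm": err.d_depth,
                "alignment_rms_mm": rms,
                "postop_accuracy_mm": result.postop_accuracy_mm,
                "accuracy_warning": result.accuracy_warning,
                "seed": scene.seed,
            })
    if len(errors) < 2:
        raise RuntimeError(
            "study produced fewer than 2 error rows; failures: "
            + "; ".join(f"{c}: {m}" for c, m in failures)
        )
    cases = pd.DataFrame(rows)
    summary = summarize_errors(errors, config.thresholds)
    result = StudyResult(cases, summary, tuple(failures))
    if out_dir is not None:
        _write_study(result, Path(out_dir))
    return result


def boxplot_data(cases: pd.DataFrame) -> pd.DataFrame:
    """Tukey boxplot quantities per metric (median, quartiles, whiskers)."""
    rows = []
    for key, (attr, label) in METRICS.items():
        x = cases[f"{attr}_{'mm' if key == 'depth' else 'deg'}"].to_numpy()
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo = x[x >= q1 - 1.5 * iqr].min()
        hi = x[x <= q3 + 1.5 * iqr].max()
        rows.append({"metric": label, "median": med, "q1": q1, "q3": q3,
                     "whisker_low": lo, "whisker_high": hi})
    return pd.DataFrame(rows)


def _write_study(result: StudyResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.cases.to_csv(out / "cases.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump({**result.summary.to_dict(),
                   "failures": list(result.failures)}, fh, indent=2)
    result.summary.to_table().to_csv(out / "summary_table.csv", index=False)
    boxplot_data(result.cases).to_csv(out / "boxplot.csv", index=False)
    result.cases[["case_id", "rater_id", "d_anteversion_deg",
                  "d_inclination_deg"]].to_csv(out / "scatter.csv", index=False)
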