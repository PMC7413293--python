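"""Record formats, configuration, and the end-to-end pipeline driver.

JSON-lines is the canonical record format (one test per line with
nested ear x frequency threshold maps); a flat CSV export with columns
like ``thr_left_500`` is provided for spreadsheet use. Ground truth
from the synthetic generator is written to a separate sidecar file and
never mixed with records.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import analysis as an
from . import calibration as cal
from . import qc
from .cohort import AgeModel, Cohort, CohortConfig, generate_cohort
from .procedure import StaircaseConfig
from .records import EARS, FREQUENCIES, TestRecord, on_grid

logger = logging.getLogger("crowdaudiometry")

SCHEMA_VERSION = "1.0"


# ---------------------------------------------------------------------------
# record serialization


def record_to_dict(rec: TestRecord) -> dict:
    return {
        "record_id": rec.record_id,
        "device_id": rec.device_id,
        "model_id": rec.model_id,
        "timestamp": rec.timestamp,
        "headphone_connected": rec.headphone_connected,
        "thresholds": {
            ear: {str(f): rec.thresholds[(ear, f)] for f in FREQUENCIES if (ear, f) in rec.thresholds}
            for ear in EARS
        },
        "durations": {str(f): d for f, d in sorted(rec.durations.items())},
        "age_entries": list(rec.age_entries),
        "laeq": rec.laeq,
        "country": rec.country,
    }


def record_from_dict(d: dict) -> TestRecord:
    thresholds = {
        (ear, int(f)): float(v)
        for ear, per_ear in d.get("thresholds", {}).items()
        for f, v in per_ear.items()
    }
    return TestRecord(
        record_id=str(d["record_id"]),
        device_id=str(d["device_id"]),
        model_id=str(d["model_id"]),
        timestamp=float(d["timestamp"]),
        headphone_connected=bool(d["headphone_connected"]),
        thresholds=thresholds,
        durations={int(f): float(v) for f, v in d.get("durations", {}).items()},
        age_entries=[int(a) for a in d.get("age_entries", [])],
        laeq=None if d.get("laeq") is None else float(d["laeq"]),
        country=str(d.get("country", "ZZ")),
    )


def records_to_jsonl(records: Sequence[TestRecord]) -> str:
    return "".join(json.dumps(record_to_dict(r), sort_keys=True) + "\n" for r in records)


def write_records(records: Sequence[TestRecord], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        # %.17g keeps float round-tripping exact through the CSV text
        records_to_frame(records).to_csv(path, index=False, float_format="%.17g")
    else:
        path.write_text(records_to_jsonl(records))


def read_records(path: str | Path, require_grid: bool = True) -> list[TestRecord]:
    """Read validated records from a JSONL (or flat CSV) file.

    Malformed lines raise with their line number; thresholds off the
    5 dB grid are rejected. An empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        records = frame_to_records(
            pd.read_csv(path, float_precision="round_trip", dtype={"age_entries": str})
        )
        for i, rec in enumerate(records, start=2):  # header is line 1
            _validate_record(rec, i, require_grid)
        return records
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = record_from_dict(json.loads(line))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
            _validate_record(rec, lineno, require_grid)
            records.append(rec)
    if not records:
        logger.warning("no records found in %s", path)
    return records


def _validate_record(rec: TestRecord, lineno: int, require_grid: bool) -> None:
    if require_grid:
        for (ear, f), thr in rec.thresholds.items():
            if not on_grid(thr):
                raise ValueError(
                    f"line {lineno}: threshold {thr} dB HL at ({ear}, {f} Hz) "
                    f"is off the 5 dB grid"
                )


def records_to_frame(records: Sequence[TestRecord]) -> pd.DataFrame:
    """Flatten records to one row per test (``thr_left_500``, ``dur_500`` ...)."""
    rows = []
    for rec in records:
        row: dict = {
            "record_id": rec.record_id,
            "device_id": rec.device_id,
            "model_id": rec.model_id,
            "timestamp": rec.timestamp,
            "headphone_connected": rec.headphone_connected,
            "country": rec.country,
            "laeq": rec.laeq,
            "age_entries": ";".join(str(a) for a in rec.age_entries),
        }
        for ear in EARS:
            for f in FREQUENCIES:
                row[f"thr_{ear}_{f}"] = rec.thresholds.get((ear, f))
        for f in FREQUENCIES:
            row[f"dur_{f}"] = rec.durations.get(f)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[TestRecord]:
    records = []
    for _, row in df.iterrows():
        thresholds = {}
        for ear in EARS:
            for f in FREQUENCIES:
                v = row.get(f"thr_{ear}_{f}")
                if v is not None and not pd.isna(v):
                    thresholds[(ear, f)] = float(v)
        durations = {}
        for f in FREQUENCIES:
            v = row.get(f"dur_{f}")
            if v is not None and not pd.isna(v):
                durations[f] = float(v)
        ages = []
        raw_age = row.get("age_entries")
        if isinstance(raw_age, str) and raw_age:
            ages = [int(a) for a in raw_age.split(";")]
        laeq = row.get("laeq")
        records.append(
            TestRecord(
                record_id=str(row["record_id"]),
                device_id=str(row["device_id"]),
                model_id=str(row["model_id"]),
                timestamp=float(row["timestamp"]),
                headphone_connected=bool(row["headphone_connected"]),
                thresholds=thresholds,
                durations=durations,
                age_entries=ages,
                laeq=None if laeq is None or pd.isna(laeq) else float(laeq),
                country=str(row["country"]),
            )
        )
    return records


def write_truth(cohort: Cohort, path: str | Path) -> None:
    """Ground-truth sidecar: one line per device with the owner's true
    thresholds, plus one line per device model."""
    lines = []
    for device_id in sorted(cohort.listeners):
        lst = cohort.listeners[device_id]
        lines.append(
            json.dumps(
                {
                    "kind": "listener",
                    "device_id": device_id,
                    "model_id": cohort.device_model[device_id],
                    "age": lst.age,
                    "true_threshold": {
                        ear: {str(f): lst.true_threshold[(ear, f)] for f in FREQUENCIES}
                        for ear in EARS
                    },
                    "psychometric_slope": lst.psychometric_slope,
                    "lapse_rate": lst.lapse_rate,
                    "confusion_prob": lst.confusion_prob,
                    "speed_factor": lst.speed_factor,
                },
                sort_keys=True,
            )
        )
    for model_id in sorted(cohort.models):
        m = cohort.models[model_id]
        lines.append(
            json.dumps(
                {
                    "kind": "model",
                    "model_id": model_id,
                    "true_offset": {str(f): m.true_offset[f] for f in FREQUENCIES},
                    "calibration_coefficient": None
                    if m.calibration_coefficient is None
                    else {str(f): m.calibration_coefficient[f] for f in FREQUENCIES},
                },
                sort_keys=True,
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class QCOptions:
    quantile_level: float = 0.99
    mixture: bool = True
    duration_threshold: Optional[float] = None  # override estimation


@dataclass
class AnalysisOptions:
    power: an.PowerSpec = field(default_factory=an.PowerSpec)
    n_boot: int = 2000
    ci_level: float = 0.95
    reference_laeq: float = an.REFERENCE_LAEQ
    laeq_bin_width: float = 5.0
    adjust_device_model: bool = False


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc: QCOptions = field(default_factory=QCOptions)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    rng_seed: int = 0


def _build(cls, d: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**d)


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "age_model" in d and isinstance(d["age_model"], dict):
        am = dict(d["age_model"])
        for key in ("base", "aging_coeff"):
            if key in am:
                am[key] = {int(f): float(v) for f, v in am[key].items()}
        d["age_model"] = _build(AgeModel, am)
    if "staircase" in d and isinstance(d["staircase"], dict):
        d["staircase"] = _build(StaircaseConfig, d["staircase"])
    if "age_bin_weights" in d:
        d["age_bin_weights"] = tuple(tuple(b) for b in d["age_bin_weights"])
    if "ambient_laeq_range" in d:
        d["ambient_laeq_range"] = tuple(d["ambient_laeq_range"])
    return _build(CohortConfig, d)


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "cohort" in d and isinstance(d["cohort"], dict):
        d["cohort"] = cohort_config_from_dict(d["cohort"])
    if "qc" in d and isinstance(d["qc"], dict):
        d["qc"] = _build(QCOptions, d["qc"])
    if "analysis" in d and isinstance(d["analysis"], dict):
        a = dict(d["analysis"])
        if "power" in a and isinstance(a["power"], dict):
            a["power"] = _build(an.PowerSpec, a["power"])
        d["analysis"] = _build(AnalysisOptions, a)
    return _build(PipelineConfig, d)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    return pipeline_config_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class PipelineResult:
    seed: int
    cohort: Cohort
    duration_threshold: float
    flow: qc.ExclusionFlow
    retained: list[TestRecord]
    prevalence: list[an.PrevalenceEstimate]
    global_prevalence: an.PrevalenceEstimate
    noise: Optional[an.NoiseEffect]
    age_curves: dict[tuple[str, int], tuple[float, float, float]]
    model_country_shift: Optional[dict[str, float]]

    def summary(self) -> dict:
        out = {
            "schema_version": SCHEMA_VERSION,
            "rng_seed": self.seed,
            "duration_threshold_s": self.duration_threshold,
            "exclusion_flow": self.flow.as_dict(),
            "global_prevalence_percent": self.global_prevalence.prevalence,
            "global_prevalence_ci": [
                self.global_prevalence.ci_low,
                self.global_prevalence.ci_high,
            ],
            "n_countries": len(self.prevalence),
            "n_countries_included": sum(p.included for p in self.prevalence),
        }
        if self.noise is not None:
            out["ambient_noise_overall_db"] = self.noise.overall_mean
            out["ambient_noise_overall_sd_db"] = self.noise.overall_sd
            out["ambient_noise_prevalence_reduction_pp"] = self.noise.prevalence_reduction
        if self.model_country_shift is not None and self.model_country_shift:
            shifts = np.array(list(self.model_country_shift.values()))
            out["model_adjustment_country_shift_mean_db"] = float(shifts.mean())
            out["model_adjustment_country_shift_sd_db"] = (
                float(shifts.std(ddof=1)) if shifts.size > 1 else 0.0
            )
        return out


def prevalence_frame(estimates: Sequence[an.PrevalenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "country": e.country,
                "n": e.n,
                "prevalence": e.prevalence,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "included": e.included,
            }
            for e in estimates
        ]
    )


def age_curves_frame(curves: dict[tuple[str, int], tuple[float, float, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "age_group": grp,
                "frequency_hz": f,
                "median_db_hl": med,
                "ci_low": lo,
                "ci_high": hi,
            }
            for (grp, f), (med, lo, hi) in curves.items()
        ]
    )


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    records: Optional[Sequence[TestRecord]] = None,
) -> PipelineResult:
    """Run generate -> filter -> analyze and optionally write outputs.

    Pre-existing records may be supplied to skip generation (the cohort
    ground truth is then unavailable). Reruns with the same config are
    bit-identical.
    """
    seed = config.rng_seed
    if records is None:
        cfg = dataclasses.replace(config.cohort, rng_seed=seed)
        logger.info("generating cohort (n_devices=%d, seed=%d)", cfg.n_devices, seed)
        cohort = generate_cohort(cfg)
        records = cohort.records
    else:
        cohort = Cohort(records=list(records), listeners={}, models={}, device_model={})

    if config.qc.duration_threshold is not None:
        threshold = config.qc.duration_threshold
    else:
        durations = [d for rec in records for d in rec.durations.values()]
        threshold = qc.estimate_duration_threshold(
            durations, config.qc.quantile_level, config.qc.mixture
        )
    logger.info("duration threshold: %.2f s", threshold)
    retained, flow = qc.apply_exclusions(records, threshold)
    if not retained:
        raise RuntimeError("qc_filter: no records survive the exclusion cascade")

    analysis_records: Sequence[TestRecord] = retained
    model_shift: Optional[dict[str, float]] = None
    if config.analysis.adjust_device_model:
        analysis_records, model_shift = cal.apply_model_adjustment(retained)
    else:
        try:
            _, model_shift = cal.apply_model_adjustment(retained)
        except ValueError:
            model_shift = None

    min_n = config.analysis.power.min_n
    prevalence, global_prev = an.country_prevalence(
        analysis_records,
        min_n=min_n,
        n_boot=config.analysis.n_boot,
        ci_level=config.analysis.ci_level,
        rng_seed=seed,
    )
    curves = an.age_median_curves(
        analysis_records,
        n_boot=config.analysis.n_boot,
        ci_level=config.analysis.ci_level,
        rng_seed=seed + 1,
    )
    noise: Optional[an.NoiseEffect] = None
    if any(r.laeq is not None for r in analysis_records):
        try:
            noise = an.noise_effect(
                analysis_records,
                reference_laeq=config.analysis.reference_laeq,
                bin_width=config.analysis.laeq_bin_width,
                rng_seed=seed + 2,
            )
        except ValueError as exc:
            logger.warning("ambient-noise effect not estimable: %s", exc)

    result = PipelineResult(
        seed=seed,
        cohort=cohort,
        duration_threshold=threshold,
        flow=flow,
        retained=retained,
        prevalence=prevalence,
        global_prevalence=global_prev,
        noise=noise,
        age_curves=curves,
        model_country_shift=model_shift,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_records(result.retained, outdir / "retained.jsonl")
    (outdir / "flow.json").write_text(
        json.dumps({"rng_seed": result.seed, **result.flow.as_dict()}, indent=2) + "\n"
    )
    prevalence_frame(result.prevalence).to_csv(outdir / "prevalence.csv", index=False)
    age_curves_frame(result.age_curves).to_csv(outdir / "age_curves.csv", index=False)
    if result.noise is not None:
        (outdir / "noise_effect.json").write_text(
            json.dumps(
                {
                    "rng_seed": result.seed,
                    "per_bin_delta_db": {str(k): v for k, v in result.noise.per_bin_delta.items()},
                    "adjustment_mean_db": result.noise.adjustment_mean,
                    "adjustment_sd_db": result.noise.adjustment_sd,
                    "group_difference_mean_db": result.noise.group_difference_mean,
                    "group_difference_sd_db": result.noise.group_difference_sd,
                    "overall_mean_db": result.noise.overall_mean,
                    "overall_sd_db": result.noise.overall_sd,
                    "prevalence_reduction_pp": result.noise.prevalence_reduction,
                },
                indent=2,
            )
            + "\n"
        )
    (outdir / "summary.json").write_text(json.dumps(result.summary(), indent=2) + "\n")


def render_report(outdir: str | Path, chart: bool = True) -> str:
    """Render a plain-text summary (and a prevalence bar chart) from a
    pipeline output directory; returns the text."""
    outdir = Path(outdir)
    summary = json.loads((outdir / "summary.json").read_text())
    prev = pd.read_csv(outdir / "prevalence.csv")
    lines = [
        "crowdaudiometry pipeline report",
        f"  seed: {summary['rng_seed']}",
        f"  duration threshold: {summary['duration_threshold_s']:.2f} s",
        f"  retained: {summary['exclusion_flow']['n_retained']} of "
        f"{summary['exclusion_flow']['n_total']} tests",
        f"  global prevalence: {summary['global_prevalence_percent']:.1f}% "
        f"(95% CI {summary['global_prevalence_ci'][0]:.1f}-"
        f"{summary['global_prevalence_ci'][1]:.1f})",
        "",
        "  country    n    prevalence%   95% CI        included",
    ]
    for _, row in prev.sort_values("prevalence", ascending=False).iterrows():
        lines.append(
            f"  {row['country']:<7} {int(row['n']):>5}   "
            f"{row['prevalence']:>8.1f}   {row['ci_low']:>5.1f}-{row['ci_high']:<5.1f}   "
            f"{'yes' if row['included'] else 'no'}"
        )
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    if chart:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        shown = prev.sort_values("prevalence", ascending=False)
        ax.bar(shown["country"], shown["prevalence"], color="#4477aa")
        ax.errorbar(
            shown["country"],
            shown["prevalence"],
            yerr=np.vstack(
                [
                    (shown["prevalence"] - shown["ci_low"]).to_numpy(),
                    (shown["ci_high"] - shown["prevalence"]).to_numpy(),
                ]
            ),
            fmt="none",
            ecolor="black",
            capsize=3,
        )
        ax.set_ylabel("hearing-loss prevalence (%)")
        ax.set_title("Prevalence by country (better-ear PTA4 > 25 dB HL)")
        fig.tight_layout()
        fig.savefig(outdir / "prevalence.png", dpi=120)
        plt.close(fig)
    return text
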