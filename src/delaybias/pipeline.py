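"""End-to-end orchestration: simulate -> fit -> compare -> analyze.

A ``RunConfig`` carries one master seed from which every stochastic stage
derives its own child seed, so a full run is reproducible bit-for-bit. The
run directory contains:

    participants.csv   covariates + generating (sim_) parameters
    trials.csv         all simulated choices in the trial CSV dialect
    fits/              one JSON record per participant x model + summary CSV
    comparison.csv     G2 / BIC / cross-validated log loss per model
    analysis.csv       standardized regressions of bias and kappa on
                       log-testosterone controlling for age
    report.txt         human-readable analysis summary
    run.log            stage log with the config hash
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import MODEL_IDS
from .trials import TRIAL_COLUMNS, ChoiceTrial, read_trials_csv
from .fitting import FitConfig, fit_group
from .comparison import ComparisonConfig, compare_models
from .cohort import CohortConfig, simulate_cohort
from .analysis import (
    iqr_outlier_filter,
    quartile_subsample,
    regress_param_on_covariates,
)

__all__ = ["RunConfig", "run_pipeline", "validate_trials_file", "ValidationReport"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    remove_outliers: bool = True
    quartile_subsample: bool = True


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/default"
    models: tuple = MODEL_IDS
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (
            ("cohort", CohortConfig),
            ("fit", FitConfig),
            ("comparison", ComparisonConfig),
            ("analysis", AnalysisConfig),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = _dataclass_from_dict(sub, data[key])
        if "models" in data:
            data["models"] = tuple(data["models"])
            unknown = [m for m in data["models"] if m not in MODEL_IDS]
            if unknown:
                raise ValueError(f"unknown model_id(s) in config: {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _dataclass_from_dict(cls, data: dict):
    import typing

    hints = typing.get_type_hints(cls)
    field_names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in field_names:
            raise ValueError(f"unknown {cls.__name__} field {key!r}")
        if isinstance(value, dict) and dataclasses.is_dataclass(hints.get(key)):
            value = _dataclass_from_dict(hints[key], value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("delaybias")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "setup"
    try:
        log.info(
            "run start: version=%s config_hash=%s seed=%d",
            __version__,
            config.config_hash(),
            config.seed,
        )
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        master = np.random.SeedSequence(config.seed)
        cohort_ss, fit_ss, cmp_ss = master.spawn(3)

        stage = "simulate"
        cohort_cfg = dataclasses.replace(config.cohort, seed=_seed_int(cohort_ss))
        cohort = simulate_cohort(cohort_cfg)
        cohort.write(out / "participants.csv", out / "trials.csv")
        log.info("simulated %d participants", len(cohort.participants))

        stage = "fit"
        fits_dir = out / "fits"
        fits_dir.mkdir(exist_ok=True)
        fit_cfg = dataclasses.replace(config.fit, seed=_seed_int(fit_ss))
        group_fits = {}
        records = []
        for model_id in config.models:
            gf = fit_group(cohort.trials_by_participant, model_id, fit_cfg)
            group_fits[model_id] = gf
            for pid, f in gf.fits.items():
                records.append(f.to_record(pid))
            with open(fits_dir / f"{model_id}.json", "w") as fh:
                json.dump([f.to_record(pid) for pid, f in gf.fits.items()], fh, indent=1)
            log.info(
                "fit %s: %d participants, %d failures",
                model_id,
                len(gf.fits),
                len(gf.failures),
            )
        pd.DataFrame(records).to_csv(fits_dir / "summary.csv", index=False)

        stage = "compare"
        cmp_cfg = dataclasses.replace(
            config.comparison, seed=_seed_int(cmp_ss), fit=fit_cfg
        )
        table = compare_models(cohort.trials_by_participant, config.models, cmp_cfg)
        table.to_csv(out / "comparison.csv")
        with open(out / "comparison.json", "w") as fh:
            json.dump(
                {
                    "best_model": table.best_model,
                    "table": table.table.to_dict(orient="records"),
                },
                fh,
                indent=1,
            )

        stage = "analyze"
        analysis_frames, report_lines = _analyze(cohort, group_fits, config)
        pd.concat(analysis_frames, ignore_index=True).to_csv(
            out / "analysis.csv", index=False
        )
        (out / "report.txt").write_text("\n".join(report_lines) + "\n")
        log.info("run complete")
        return out
    except Exception as exc:
        log.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _analyze(cohort, group_fits, config: RunConfig):
    """Regressions of the bias-model parameters on log-T controlling age."""
    bias_model = "SS_BIAS" if "SS_BIAS" in group_fits else config.models[0]
    gf = group_fits[bias_model]
    pids = [p for p in cohort.participants["participant_id"] if p in gf.fits]
    sub = cohort.participants.set_index("participant_id").loc[pids]
    logt = sub["log_testosterone"].to_numpy()
    age = sub["age_months"].to_numpy()
    frames = []
    lines = [f"Behavioral analysis ({bias_model} parameters, n={len(pids)})", ""]
    for pname in ("bias", "kappa"):
        values = np.array([getattr(gf.fits[p].params, pname, np.nan) for p in pids])
        if np.isnan(values).all():
            continue
        res = regress_param_on_covariates(values, logt, age, outcome=pname)
        frames.append(res.to_frame())
        t = res.predictor("log_testosterone")
        lines.append(
            f"{pname} ~ log(T) + age: b*_T = {t.b:.2f}, "
            f"95% CI [{t.ci_low:.2f}, {t.ci_high:.2f}], p = {t.p:.3f}, "
            f"VIF = {t.vif:.2f}"
        )
        if pname == "bias" and config.analysis.remove_outliers:
            flt = iqr_outlier_filter(values)
            if flt.removed.size and flt.keep_mask.sum() >= 5:
                res_o = regress_param_on_covariates(
                    values, logt, age, subset_mask=flt.keep_mask, outcome="bias_no_outliers"
                )
                frames.append(res_o.to_frame())
                t_o = res_o.predictor("log_testosterone")
                lines.append(
                    f"  after IQR outlier removal (kept {int(flt.keep_mask.sum())}, "
                    f"range [{flt.retained_min:.0f}, {flt.retained_max:.0f}]): "
                    f"b*_T = {t_o.b:.2f}, p = {t_o.p:.3f}"
                )
        if pname == "bias" and config.analysis.quartile_subsample and len(age) >= 10:
            mask = quartile_subsample(age)
            res_q = regress_param_on_covariates(
                values, logt, age, subset_mask=mask, outcome="bias_age_subsample"
            )
            frames.append(res_q.to_frame())
            t_q = res_q.predictor("log_testosterone")
            lines.append(
                f"  middle age quartiles (n={int(mask.sum())}): b*_T = {t_q.b:.2f}, "
                f"p = {t_q.p:.3f}, VIF = {t_q.vif:.2f}"
            )
    return frames, lines


@dataclass
class ValidationReport:
    n_rows: int
    issues: List[str]
    warnings: List[str]
    participants: dict

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_trials_file(path, expected_trials: int = 64) -> ValidationReport:
    """Check a trial CSV: header, dtypes, per-row invariants, trial counts.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers; short participants produce warnings, not errors.
    """
    frame = pd.read_csv(path)
    issues: List[str] = []
    warnings: List[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        return ValidationReport(
            n_rows=len(frame),
            issues=[f"missing columns: {missing}"],
            warnings=[],
            participants={},
        )
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            ChoiceTrial(
                ss=_prospect(row.ss_amount, row.ss_delay_days),
                ll=_prospect(row.ll_amount, row.ll_delay_days),
                chosen=str(row.choice),
                condition=str(row.condition),
            )
        except (ValueError, TypeError) as exc:
            issues.append(f"line {i}: {exc}")
    counts = frame.groupby("participant_id").size().to_dict()
    for pid, n in counts.items():
        if n != expected_trials:
            warnings.append(f"participant {pid}: {n} trials (expected {expected_trials})")
    return ValidationReport(
        n_rows=len(frame), issues=issues, warnings=warnings, participants=counts
    )


def _prospect(amount, delay):
    from .models import Prospect

    return Prospect(float(amount), float(delay))
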