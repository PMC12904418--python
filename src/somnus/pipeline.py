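"""End-to-end pipeline orchestration with config, provenance and manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from zoneinfo import ZoneInfo

import pandas as pd
import yaml

from . import dsem, io_ingest, panel as panel_mod
from .inbed import DetectorParams, detect_inbed, epoch_steps
from .io_ingest import DEFAULT_TIMEZONE, IngestWarnings


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    steps_xml: Path
    sleep_xml: Path
    usage_csv: Path
    output_dir: Path
    study_start: date
    n_days: int = 14
    timezone: str = DEFAULT_TIMEZONE
    detector: DetectorParams = field(default_factory=DetectorParams)
    max_missing_days: int = 7
    imputations: int = 5
    seed: int = 0
    pseudonym_salt: str = "study-salt"
    model: int = 1
    chains: int = 2
    iterations: int = 5000
    fit_model2: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        det = DetectorParams(**{
            **raw.get("detector", {}),
            **({"window_start": time.fromisoformat(raw["detector"]["window_start"])}
               if "window_start" in raw.get("detector", {}) else {}),
            **({"window_end": time.fromisoformat(raw["detector"]["window_end"])}
               if "window_end" in raw.get("detector", {}) else {}),
        })
        cfg = cls(
            steps_xml=Path(raw["steps_xml"]),
            sleep_xml=Path(raw["sleep_xml"]),
            usage_csv=Path(raw["usage_csv"]),
            output_dir=Path(raw.get("output_dir", "results")),
            study_start=date.fromisoformat(str(raw["study_start"])),
            n_days=int(raw.get("n_days", 14)),
            timezone=raw.get("timezone", DEFAULT_TIMEZONE),
            detector=det,
            max_missing_days=int(raw.get("max_missing_days", 7)),
            imputations=int(raw.get("imputations", 5)),
            seed=int(raw.get("seed", 0)),
            pseudonym_salt=str(raw.get("pseudonym_salt", "study-salt")),
            model=int(raw.get("model", 1)),
            chains=int(raw.get("chains", 2)),
            iterations=int(raw.get("iterations", 5000)),
            fit_model2=bool(raw.get("fit_model2", False)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.steps_xml, self.sleep_xml, self.usage_csv):
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if self.n_days < 2:
            raise ConfigError("study must span at least 2 days")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_panel_from_streams(config: RunConfig) -> tuple[pd.DataFrame, dict, list]:
    """Ingest raw streams, detect in-bed intervals and assemble the panel."""
    tz = ZoneInfo(config.timezone)
    from datetime import timedelta

    study_days = [config.study_start + timedelta(days=t) for t in range(config.n_days)]
    window_start = datetime.combine(config.study_start, time(0, 0), tzinfo=tz)
    window_end = datetime.combine(
        config.study_start + timedelta(days=config.n_days + 1), time(0, 0), tzinfo=tz
    )
    warn = IngestWarnings()
    with open(config.steps_xml, "rb") as fh:
        steps = io_ingest.read_steps_xml(
            fh, timezone=config.timezone,
            study_start=window_start, study_end=window_end, warnings=warn)
    with open(config.sleep_xml, "rb") as fh:
        sleep = io_ingest.read_sleep_xml(
            fh, timezone=config.timezone,
            study_start=window_start, study_end=window_end, warnings=warn)
    usage_hours, daily = io_ingest.read_usage_table(str(config.usage_csv), warnings=warn)

    steps = io_ingest.pseudonymize(steps, config.pseudonym_salt)
    sleep = io_ingest.pseudonymize(sleep, config.pseudonym_salt)
    usage_hours = io_ingest.pseudonymize(usage_hours, config.pseudonym_salt)
    daily = io_ingest.pseudonymize(daily, config.pseudonym_salt)

    pids = sorted({r.participant_id for r in steps} |
                  {r.participant_id for r in sleep})
    frames = []
    all_intervals = []
    for pid in pids:
        p_steps = [r for r in steps if r.participant_id == pid]
        p_sleep = [r for r in sleep if r.participant_id == pid]
        p_hours = [r for r in usage_hours if r.participant_id == pid]
        p_daily = [r for r in daily if r.participant_id == pid]
        intervals = []
        if p_steps:
            series = epoch_steps(p_steps, config.detector)
            intervals, _ = detect_inbed(series, config.detector)
        all_intervals.extend(intervals)
        frames.append(
            panel_mod.assemble_panel(
                pid,
                study_days,
                panel_mod.compute_tsu(p_daily),
                panel_mod.compute_suib(p_hours, intervals),
                panel_mod.aggregate_sleep(p_sleep),
            )
        )
    full = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=io_ingest.PANEL_COLUMNS)
    return full, warn.as_dict(), all_intervals


def run_pipeline(config: RunConfig) -> dict:
    """Run ingest -> detect -> panel -> impute -> fit and write artifacts.

    Returns the artifact manifest (path -> sha256). Reruns with identical
    config and seeds are bit-identical for every CSV/JSON artifact.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    full_panel, warnings_dict, intervals = build_panel_from_streams(config)
    filtered, report = panel_mod.filter_missing(
        full_panel, max_missing_days=config.max_missing_days, n_days=config.n_days)

    io_ingest.write_panel(full_panel, out / "panel_raw.csv")
    io_ingest.write_panel(filtered, out / "panel.csv")
    (out / "ingest_warnings.json").write_text(
        json.dumps(warnings_dict, indent=2, sort_keys=True) + "\n")
    (out / "exclusions.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    iv_rows = [
        {"participant": iv.participant_id, "enter": iv.enter.isoformat(),
         "exit": iv.exit.isoformat(), "n_waso": len(iv.waso),
         "waso_minutes": iv.waso_s / 60.0}
        for iv in intervals
    ]
    pd.DataFrame(iv_rows).to_csv(out / "inbed_intervals.tsv", sep="\t", index=False)

    variables = (dsem.MODEL1_VARIABLES if config.model == 1
                 else dsem.MODEL2_VARIABLES)
    imps = panel_mod.impute(filtered, m=config.imputations, seed=config.seed,
                            variables=variables)
    model = dsem.DsemModel(model=config.model, chains=config.chains,
                           iterations=config.iterations, seed=config.seed)
    model.fit(imps)
    model.paths_.to_csv(out / f"model{config.model}_paths.csv", index=False,
                        float_format="%.6f")
    diag = {
        "converged": bool(model.converged_),
        "ppc_mean": {k: float(v) for k, v in model.ppc_.items()},
        "vif": {k: [float(x) for x in v] for k, v in model.vif_.items()},
        "imputation_seed": config.seed,
        "m": config.imputations,
    }

    if config.fit_model2:
        imps2 = panel_mod.impute(filtered, m=config.imputations, seed=config.seed,
                                 variables=dsem.MODEL2_VARIABLES)
        model2 = dsem.DsemModel(model=2, chains=config.chains,
                                iterations=config.iterations, seed=config.seed)
        model2.fit(imps2)
        model2.paths_.to_csv(out / "model2_paths.csv", index=False,
                             float_format="%.6f")
        diff, se = dsem.loo_compare(model2.result_, model.result_,
                                    seed=config.seed)
        diag["loo_model2_vs_model1"] = {"elpd_diff": diff, "se": se}

    (out / "diagnostics.json").write_text(
        json.dumps(diag, indent=2, sort_keys=True) + "\n")

    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
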