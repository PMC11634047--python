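"""End-to-end analysis orchestration and report tables.

``run_full_analysis`` chains the stages — eligibility filter, observation
pairing, fall-rate normalisation, running-average smoothing, model fitting
and selection, rank correlation, fall-expectation thresholds, MCID table,
subgroup report — and returns a bundle whose every number is traceable to a
run manifest (inputs, configuration snapshot, seed, decision flags, stage
timings).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    EligibilityRules,
    ExclusionLog,
    build_pairs,
    filter_eligible,
    load_assessments,
)
from .curve import (
    DEFAULT_HORIZONS,
    DEFAULT_WINDOW,
    MODEL_FAMILIES,
    CurveAssociation,
    FittedModel,
    SmoothedCurve,
    fit_models,
    running_average,
    select_model,
    spearman_on_curve,
    threshold_frs,
)
from .mcid import DEFAULT_EFFECT_SIZES, DEFAULT_REPLICATES, mcid_table
from .subgroups import subgroup_pipeline

logger = logging.getLogger(__name__)

#: Reporting significance level (two-sided).
ALPHA = 0.05


class NoObservationsError(RuntimeError):
    """The cohort yields zero eligible observation pairs."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full pipeline, with study defaults."""

    rules: EligibilityRules = EligibilityRules()
    window: float = DEFAULT_WINDOW
    adaptive_window: bool = False
    families: tuple[str, ...] = MODEL_FAMILIES
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    effect_sizes: tuple[float, ...] = DEFAULT_EFFECT_SIZES
    replicates: int = DEFAULT_REPLICATES
    ci_level: float = 0.95
    bootstrap_by_resident: bool = False
    seed: int | None = None


@dataclass
class RunManifest:
    """Provenance of one analysis run."""

    input_hash: str
    n_input_records: int
    config: dict
    seed: int | None
    software_version: str
    decision_flags: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass
class ReportBundle:
    descriptives: pd.DataFrame
    curve: SmoothedCurve
    models: list[FittedModel]
    selected: FittedModel
    association: CurveAssociation
    thresholds: dict[int, int | None]
    mcid: pd.DataFrame
    subgroups: pd.DataFrame
    manifest: RunManifest
    exclusions: ExclusionLog

    def write(self, outdir: str | Path) -> None:
        """Serialise the bundle: TSV tables, full-precision JSON, manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(out / "descriptives.tsv", sep="\t", index=False)
        self.curve.to_frame().to_csv(out / "smoothed_curve.tsv", sep="\t", index=False)
        self.subgroups.to_csv(out / "subgroups.tsv", sep="\t", index=False)
        self.mcid.to_csv(out / "mcid.tsv", sep="\t", index=False)
        (out / "model.json").write_text(
            json.dumps(
                {
                    "selected": self.selected.to_dict(),
                    "candidates": [m.to_dict() for m in self.models],
                    "association": dataclasses.asdict(self.association),
                    "thresholds": {str(k): v for k, v in self.thresholds.items()},
                    "alpha": ALPHA,
                },
                indent=2,
            )
        )
        (out / "manifest.json").write_text(self.manifest.to_json())
        self.exclusions.to_frame().to_json(
            out / "exclusions.jsonl", orient="records", lines=True
        )


def describe_cohort(pairs: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table over observation pairs (baseline characteristics).

    Continuous variables as mean (sample SD, n-1 denominator; undefined at
    n = 1 and reported as NaN); categorical variables as counts.
    """
    if len(pairs) == 0:
        raise NoObservationsError("no observation pairs to describe")

    def mean_sd(col: str) -> tuple[float, float]:
        if col not in pairs:
            return (np.nan, np.nan)
        v = pd.to_numeric(pairs[col], errors="coerce").dropna()
        return (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else np.nan)

    def count(col: str, predicate=bool) -> float:
        if col not in pairs:
            return np.nan
        return int(pairs[col].map(lambda x: predicate(x) if pd.notna(x) else False).sum())

    rows = [
        ("observations, n", len(pairs), np.nan),
        ("residents, n", pairs["resident_id"].nunique(), np.nan),
        ("women, n", count("gender", lambda g: g == "female"), np.nan),
        ("men, n", count("gender", lambda g: g == "male"), np.nan),
        ("age (years)", *mean_sd("age")),
        ("gait speed (m/s)", *mean_sd("gait_speed")),
        ("dementia, n", count("dementia"), np.nan),
        ("fallers at T1, n", count("fall_history"), np.nan),
        ("using walking aids, n", count("walking_aid"), np.nan),
        ("FRS at T1", *mean_sd("frs_t1")),
        ("FRS at T2", *mean_sd("frs_t2")),
        ("interval T1-T2 (days)", *mean_sd("interval_days")),
        ("falls per week at T2", *mean_sd("rate_per_week")),
    ]
    return pd.DataFrame(rows, columns=["characteristic", "value", "sd"])


def run_full_analysis(
    assessments: pd.DataFrame | str | Path,
    config: AnalysisConfig = AnalysisConfig(),
) -> ReportBundle:
    """Execute the full prognostic-validity pipeline on an assessment table.

    Raises :class:`NoObservationsError` when the eligibility filter and the
    interval window leave zero observation pairs; any stage failure carries
    the stage name in its message.
    """
    timings: dict[str, float] = {}

    def staged(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return _T()

    with staged("load"):
        df = load_assessments(assessments)
        digest = hashlib.sha256(
            pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes()
        ).hexdigest()

    with staged("filter"):
        eligible, exclusions = filter_eligible(df, config.rules)

    with staged("pair"):
        pairs = build_pairs(eligible)
    if len(pairs) == 0:
        raise NoObservationsError(
            "no eligible observation pairs after filtering and pairing"
        )

    with staged("describe"):
        descriptives = describe_cohort(pairs)

    with staged("smooth"):
        curve = running_average(
            pairs["frs_t1"],
            pairs["rate_per_week"],
            window=config.window,
            adaptive=config.adaptive_window,
        )

    with staged("fit"):
        models = fit_models(curve, config.families)
        selected = select_model(models)

    with staged("correlate"):
        association = spearman_on_curve(curve)

    with staged("thresholds"):
        thresholds = (
            {h: threshold_frs(selected, h) for h in config.horizons}
            if selected.family == "quadratic" and selected.coefficients[0] > 0
            else {h: None for h in config.horizons}
        )

    with staged("mcid"):
        mcid = mcid_table(
            pairs["frs_t1"],
            pairs["frs_t2"],
            effect_sizes=config.effect_sizes,
            replicates=config.replicates,
            level=config.ci_level,
            seed=config.seed,
            cluster=pairs["resident_id"] if config.bootstrap_by_resident else None,
        )

    with staged("subgroups"):
        subgroup_report = subgroup_pipeline(
            pairs, window=config.window, families=config.families
        )

    manifest = RunManifest(
        input_hash=digest,
        n_input_records=len(df),
        config=dataclasses.asdict(config),
        seed=config.seed,
        software_version=__version__,
        decision_flags={
            "window_mode": "adaptive" if config.adaptive_window else "fixed",
            "threshold_rounding": "ceil",
            "rmse_tie_break": "fewer-parameters, then linear<quadratic<exponential",
            "bootstrap_unit": "resident" if config.bootstrap_by_resident else "observation",
            "sd_denominator": "n-1",
            "alpha": ALPHA,
            "interval_bin_tie": "round-half-down",
        },
        stage_seconds=timings,
        exclusion_counts=exclusions.counts(),
    )
    return ReportBundle(
        descriptives=descriptives,
        curve=curve,
        models=models,
        selected=selected,
        association=association,
        thresholds=thresholds,
        mcid=mcid,
        subgroups=subgroup_report,
        manifest=manifest,
        exclusions=exclusions,
    )
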