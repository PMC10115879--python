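"""End-to-end orchestration: simulate/ingest -> exclude -> filter ->
transform -> cumulative fits -> reliability curve -> Bayes factors ->
report, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from .inference import (
    BayesFactorResult,
    McmcSettings,
    ModelSpec,
    bayes_factors,
    fit_model,
    posterior_summary,
)
from .preprocessing import TrialPreprocessor, cumulative_subsets
from .reliability import (
    DEFAULT_TARGETS,
    ReliabilityCurve,
    ReliabilitySummary,
    reliability_curve,
    summarize_reliability,
)
from .simulate import (
    BLOCKS_PER_SUPERBLOCK,
    DesignSpec,
    GenerativeParams,
    build_schedule,
    read_trials,
    simulate_dataset,
    write_trials,
)


@dataclass
class PipelineConfig:
    """Configuration of one analysis run.

    Exactly one input source: ``input_csv`` (a trial table on disk) or
    ``design``/``params`` (simulate a dataset).
    """

    out_dir: str = "conflictrt_run"
    seed: int = 0
    input_csv: str | None = None
    design: DesignSpec | None = None
    params: GenerativeParams | None = None
    min_accuracy: float = 0.60
    max_anticipatory_fraction: float = 0.10
    max_nonresponse_fraction: float = 0.10
    correct_only: bool = True
    targets: tuple[float, ...] = DEFAULT_TARGETS
    blocks_per_level: int = BLOCKS_PER_SUPERBLOCK
    n_chains: int = 4
    n_warmup: int = 1000
    n_draws: int = 2500
    compute_bayes_factors: bool = True
    bf_method: str = "savage_dickey"
    save_draws: bool = False
    make_plots: bool = False
    n_aux_seconds: int = 10_000

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.design is None):
            raise ValueError("configure exactly one input source: input_csv or design")
        if any(not 0.0 < t < 1.0 for t in self.targets):
            raise ValueError("reliability targets must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update(overrides)
        if "design" in payload and isinstance(payload["design"], dict):
            payload["design"] = DesignSpec(**payload["design"])
        if "params" in payload and isinstance(payload["params"], dict):
            payload["params"] = GenerativeParams(**payload["params"])
        if "targets" in payload:
            payload["targets"] = tuple(payload["targets"])
        return cls(**payload)

    def snapshot(self) -> dict:
        snap = asdict(self)
        if self.params is not None:
            snap["params"]["practice"] = [float(v) for v in self.params.practice]
        snap["targets"] = list(self.targets)
        return snap


@dataclass
class RunManifest:
    """Everything needed to reproduce and audit a pipeline run."""

    config: dict
    version: str
    seeds: dict
    row_counts: dict
    exclusions: list[dict]
    convergence: list[dict]
    bayes_factors: dict | None
    crossings: dict
    files: dict = field(default_factory=dict)  # name -> sha256
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_json_default)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written to
    ``<out_dir>/manifest.json``).

    Stage failures propagate with the stage name prepended; partial
    outputs written before the failure are preserved on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    root_ss = np.random.SeedSequence(config.seed)
    sim_ss, fit_ss, bf_ss, aux_ss = root_ss.spawn(4)
    seeds: dict = {"global": config.seed}
    row_counts: dict = {}

    stage = "ingest"
    try:
        if config.input_csv is not None:
            trials = read_trials(config.input_csv)
            seeds["simulation"] = None
        else:
            schedule = build_schedule(config.design)
            sim_seed = _child_seed(sim_ss)
            seeds["simulation"] = sim_seed
            trials = simulate_dataset(schedule, config.params or GenerativeParams(), sim_seed)
        write_trials(trials, out / "trials.csv")
        row_counts["trials"] = int(len(trials))

        stage = "preprocess"
        prep = TrialPreprocessor(
            min_accuracy=config.min_accuracy,
            max_anticipatory_fraction=config.max_anticipatory_fraction,
            max_nonresponse_fraction=config.max_nonresponse_fraction,
            correct_only=config.correct_only,
        )
        analysis = prep.fit_transform(trials)
        prep.report_.to_csv(out / "exclusions.csv", index=False)
        row_counts["analysis"] = int(len(analysis))
        row_counts["excluded_subjects"] = len(prep.excluded_subjects_)

        stage = "aggregate"
        subsets = cumulative_subsets(analysis, blocks_per_level=config.blocks_per_level)
        trials_per_block = int(trials["trial"].max())
        row_counts["aggregation_levels"] = len(subsets)

        stage = "fit"
        level_seeds = fit_ss.spawn(len(subsets))
        summaries: list[ReliabilitySummary] = []
        convergence: list[dict] = []
        seeds["fits"] = []
        for k, subset in enumerate(subsets):
            n_blocks_level = int(subset["block"].max())
            available = n_blocks_level * trials_per_block
            seed_k = _child_seed(level_seeds[k])
            seeds["fits"].append(seed_k)
            settings = McmcSettings(
                n_chains=config.n_chains,
                n_warmup=config.n_warmup,
                n_draws=config.n_draws,
                seed=seed_k,
            )
            draws = fit_model(subset, ModelSpec(variant="standard"), settings)
            if config.save_draws:
                draws.to_dataframe().to_csv(out / f"draws_level{available}.csv", index=False)
            convergence.append(
                {
                    "aggregation_level": available,
                    "max_rhat": draws.diagnostics["max_rhat"],
                    "min_ess": draws.diagnostics["min_ess"],
                    "converged": draws.converged,
                    "include_practice": draws.spec.include_practice,
                }
            )
            summaries.append(
                summarize_reliability(
                    draws,
                    trials_available=available,
                    n_aux=config.n_aux_seconds,
                    seed=_child_seed(aux_ss),
                )
            )
        pd.DataFrame([s.to_row() for s in summaries]).to_csv(out / "summaries.csv", index=False)

        stage = "reliability_curve"
        curve = None
        crossings: dict = {}
        if len(summaries) >= 2:
            curve = reliability_curve(summaries, targets=config.targets)
            curve.to_dataframe().to_csv(out / "curve.csv", index=False)
            crossings = {
                str(r): curve.crossings[r] for r in config.targets
            }

        stage = "bayes_factors"
        bf_result: BayesFactorResult | None = None
        if config.compute_bayes_factors and summaries[-1].aggregation_level >= 2 * config.blocks_per_level * trials_per_block:
            settings = McmcSettings(
                n_chains=config.n_chains,
                n_warmup=config.n_warmup,
                n_draws=config.n_draws,
                seed=_child_seed(bf_ss),
            )
            bf_result = bayes_factors(analysis, settings, method=config.bf_method)
            seeds["bayes_factors"] = settings.seed

        stage = "report"
        report = render_report(
            summaries=summaries,
            curve=curve,
            bf=bf_result,
            exclusions=prep.report_,
            correct_only=config.correct_only,
        )
        (out / "report.md").write_text(report)

        stage = "plots"
        if config.make_plots and curve is not None:
            from .plots import plot_reliability_curve, plot_summaries

            plot_reliability_curve(curve, out / "curve.png")
            plot_summaries(summaries, out / "summaries.png")
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    files = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config=config.snapshot(),
        version=_version,
        seeds=seeds,
        row_counts=row_counts,
        exclusions=prep.report_.to_dict("records"),
        convergence=convergence,
        bayes_factors=(
            {
                "bf1": bf_result.bf1,
                "bf2": bf_result.bf2,
                "bf1_log_se": bf_result.bf1_log_se,
                "bf2_log_se": bf_result.bf2_log_se,
                "method": bf_result.method,
                "flagged": bf_result.flagged,
            }
            if bf_result is not None
            else None
        ),
        crossings=crossings,
        files=files,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Report rendering


def interpret_bf(bf: float) -> str:
    """Conventional evidence label for a Bayes factor."""
    if bf > 100:
        return "very strong"
    if bf > 10:
        return "strong"
    if bf > 3:
        return "moderate"
    if bf >= 1:
        return "weak"
    return "favors the comparison model"


def _fmt_crossing(val: float | None) -> str:
    return f"{val:.1f}" if val is not None else "not reached within measured range"


def render_report(
    summaries: list[ReliabilitySummary],
    curve: ReliabilityCurve | None,
    bf: BayesFactorResult | None,
    exclusions: pd.DataFrame | None = None,
    correct_only: bool = True,
) -> str:
    """Human-readable markdown report of a pipeline run."""
    lines = ["# Conflict-task reliability report", ""]
    lines.append(
        f"Responses analyzed: {'correct first responses only' if correct_only else 'all first responses'}."
    )
    lines.append("")

    if exclusions is not None:
        lines.append("## Participant exclusions")
        if exclusions.empty:
            lines.append("No participants excluded.")
        else:
            lines.append("| subject | rule | statistic |")
            lines.append("|---|---|---|")
            for _, row in exclusions.iterrows():
                lines.append(f"| {row['subject']} | {row['rule']} | {row['statistic']:.3f} |")
        lines.append("")

    if not summaries:
        lines.append("## Reliability summaries")
        lines.append("*(no aggregation levels fitted)*")
        lines.append("")
    else:
        lines.append("## Reliability summaries per aggregation level")
        lines.append(
            "| trials | CE (log) | sigma_T | sigma_N | eta | CE (s) |"
        )
        lines.append("|---|---|---|---|---|---|")
        for s in summaries:
            lines.append(
                f"| {s.aggregation_level} "
                f"| {s.conflict_effect_log.median:.3f} [{s.conflict_effect_log.lower:.3f}, {s.conflict_effect_log.upper:.3f}] "
                f"| {s.sigma_T.median:.3f} [{s.sigma_T.lower:.3f}, {s.sigma_T.upper:.3f}] "
                f"| {s.sigma_N.median:.3f} [{s.sigma_N.lower:.3f}, {s.sigma_N.upper:.3f}] "
                f"| {s.eta.median:.3f} [{s.eta.lower:.3f}, {s.eta.upper:.3f}] "
                f"| {s.conflict_effect_seconds.median:.3f} |"
            )
        lines.append("")

    lines.append("## Trials required for target reliability")
    if curve is None:
        lines.append("*(needs at least two aggregation levels)*")
    else:
        for r in curve.targets:
            lo, hi = curve.crossing_intervals[r]
            lines.append(
                f"- r = {r}: crossing at {_fmt_crossing(curve.crossings[r])} trials "
                f"(band: {_fmt_crossing(lo)} to {_fmt_crossing(hi)})"
            )
    lines.append("")

    lines.append("## Practice-effect model checks")
    if bf is None:
        lines.append("*(Bayes factors not computed)*")
    else:
        lines.append(
            f"- BF1 (standard vs. no practice effect) = {bf.bf1:.3g} — {interpret_bf(bf.bf1)}"
            + (" [unstable estimate]" if bf.flagged else "")
        )
        lines.append(
            f"- BF2 (standard vs. practice x conflict interaction) = {bf.bf2:.3g} — {interpret_bf(bf.bf2)}"
            + (" [unstable estimate]" if bf.flagged else "")
        )
        lines.append(f"- method: {bf.method}")
    lines.append("")
    return "\n".join(lines)
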