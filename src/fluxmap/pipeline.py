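"""Bidirectional analysis pipeline.

Orchestrates the full procedure on measured or synthetic bilateral perfusion
data: per-group model identification in both mapping directions (left series
as declared input, then right), evaluation of mapped values against measured
ones (error series and SNR), probing of every fitted model with the common
standard signal, characteristic-cloud construction, and the cross-group
comparison (ranking of distribution centers, amplification relative to the
control group, and a direction-invariance flag).

All artifacts — model JSON files, series CSV dumps, the comparison table, the
cloud scatter figure, the fully resolved configuration echo and the run log —
are written under a chosen output directory, and a rerun with an identical
configuration and seed is bit-identical for synthetic sources.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FluxmapError, StructuralError
from .evaluation import (
    DEFAULT_SNR_EXPONENT,
    SUMMARY_KINDS,
    CharacteristicCloud,
    EvaluationResult,
    compute_characteristic_cloud,
    evaluate_mapping,
    generate_standard_signal,
)
from .protocol import (
    GroupDataset,
    PerfusionSeries,
    ProtocolLayout,
    apply_phase_exclusion,
    dataset_from_series,
    read_series_csv,
    write_series_csv,
)
from .synthetic import GroundTruth, default_truths, simulate_study
from .sysid import (
    DEFAULT_POWER,
    MODES,
    MappingModel,
    build_regression_rows,
    fit_mapping_model,
    map_series,
)

logger = logging.getLogger(__name__)

DIRECTIONS = ("L->R", "R->L")

INTERVENTION_LABEL = {"A": "Acup. Left", "B": "Acup. Right", "C": "No acup."}


@dataclass(frozen=True)
class SyntheticSpec:
    """Synthetic data source: layout, base truth, per-group gains, size."""

    layout: ProtocolLayout = field(default_factory=ProtocolLayout)
    truth: GroundTruth = field(default_factory=GroundTruth)
    gains: Mapping[str, float] = field(
        default_factory=lambda: {"A": 3.0, "B": 9.0, "C": 1.0}
    )
    n_subjects: int = 40
    groups: tuple[str, ...] = ("A", "B", "C")

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for g in self.groups:
            if g not in ("A", "B", "C"):
                raise ConfigurationError(f"unknown group {g!r}")

    def truths(self) -> dict[str, GroundTruth]:
        return default_truths(self.truth, self.gains)


@dataclass(frozen=True)
class AnalysisConfig:
    """Fully resolved configuration of one analysis run.

    ``source`` is either a :class:`SyntheticSpec` or a path to a perfusion CSV.
    Every field is validated on construction, before any computation.
    """

    source: SyntheticSpec | str = field(default_factory=SyntheticSpec)
    mode: str = "regress-and-invert"
    snr_exponent: float = DEFAULT_SNR_EXPONENT
    center_summary: str = "mean-vy"
    k_start: int = 1
    k_end: int = 2400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.center_summary not in SUMMARY_KINDS:
            raise ConfigurationError(
                f"center_summary must be one of {SUMMARY_KINDS}, got {self.center_summary!r}"
            )
        if self.k_start > self.k_end:
            raise ConfigurationError("k_start must not exceed k_end")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        if isinstance(self.source, SyntheticSpec):
            spec = self.source
            source = {
                "synthetic": {
                    "n_subjects": spec.n_subjects,
                    "groups": list(spec.groups),
                    "gains": {k: float(v) for k, v in dict(spec.gains).items()},
                    "layout": {
                        "phases": list(spec.layout.phases),
                        "frames_per_phase": spec.layout.frames_per_phase,
                        "excluded_phases": sorted(spec.layout.excluded_phases),
                    },
                    "truth": dataclasses.asdict(spec.truth),
                }
            }
        else:
            source = {"csv": str(self.source)}
        return {
            "source": source,
            "mode": self.mode,
            "snr_exponent": self.snr_exponent,
            "center_summary": self.center_summary,
            "standard_signal": {"k_start": self.k_start, "k_end": self.k_end},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "AnalysisConfig":
        payload = dict(payload or {})
        raw_source = payload.get("source", {"synthetic": {}})
        if "csv" in raw_source:
            source: SyntheticSpec | str = str(raw_source["csv"])
        elif "synthetic" in raw_source:
            syn = dict(raw_source["synthetic"] or {})
            layout_kw = dict(syn.get("layout") or {})
            if "phases" in layout_kw:
                layout_kw["phases"] = tuple(layout_kw["phases"])
            if "excluded_phases" in layout_kw:
                layout_kw["excluded_phases"] = frozenset(layout_kw["excluded_phases"])
            source = SyntheticSpec(
                layout=ProtocolLayout(**layout_kw),
                truth=GroundTruth(**dict(syn.get("truth") or {})),
                gains=dict(syn.get("gains") or {"A": 3.0, "B": 9.0, "C": 1.0}),
                n_subjects=int(syn.get("n_subjects", 40)),
                groups=tuple(syn.get("groups", ("A", "B", "C"))),
            )
        else:
            raise ConfigurationError(
                "config source must contain either 'csv' or 'synthetic'"
            )
        sig = dict(payload.get("standard_signal") or {})
        return cls(
            source=source,
            mode=payload.get("mode", "regress-and-invert"),
            snr_exponent=float(payload.get("snr_exponent", DEFAULT_SNR_EXPONENT)),
            center_summary=payload.get("center_summary", "mean-vy"),
            k_start=int(sig.get("k_start", 1)),
            k_end=int(sig.get("k_end", 2400)),
            seed=int(payload.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(text) or {})


@dataclass(frozen=True)
class GroupResult:
    """Everything computed for one group in one direction."""

    model: MappingModel
    evaluation: EvaluationResult
    std_output: np.ndarray = field(repr=False)
    cloud: CharacteristicCloud


@dataclass(frozen=True)
class DirectionReport:
    """Per-group results for one mapping direction."""

    direction: str
    results: dict[str, GroupResult]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.results))

    def scalar_centers(self) -> dict[str, float]:
        return {g: r.cloud.scalar_summary for g, r in sorted(self.results.items())}

    def snrs(self) -> dict[str, float | None]:
        return {g: r.evaluation.snr for g, r in sorted(self.results.items())}


@dataclass(frozen=True)
class ComparisonSummary:
    """Cross-group, cross-direction comparison of distribution centers."""

    #: groups ordered by descending scalar center, per direction
    rankings: dict[str, tuple[str, ...]]
    #: whether any centers tie exactly, per direction
    tied: dict[str, bool]
    #: scalar-center ratio of each acupuncture group to the control, per direction
    amplification: dict[str, dict[str, float]]
    #: True when the ranking is identical in both directions
    direction_invariant: bool


def _align_truth(dataset: GroupDataset) -> np.ndarray:
    """Measured output values aligned to the mapped series (drop one lag per block)."""
    out = []
    for _, blk in dataset.blocks():
        out.append(dataset.output_values[blk][1:])
    return np.concatenate(out)


def analyse_group(dataset: GroupDataset, config: AnalysisConfig) -> GroupResult:
    """Fit, evaluate and probe one group dataset in its dataset's direction."""
    X, y = build_regression_rows(dataset, config.mode)
    model = fit_mapping_model(
        X,
        y,
        group=dataset.group,
        direction=dataset.direction,
        mode=config.mode,
        power=DEFAULT_POWER,
    )
    logger.info(
        "fitted %s %s (%s): a=%.6g b=%.6g c=%.6g d=%.6g (n=%d, sse=%.6g)",
        dataset.group,
        dataset.direction,
        config.mode,
        model.a,
        model.b,
        model.c,
        model.d,
        model.n_rows,
        model.residual_sse,
    )

    estimated = map_series(
        model, dataset.input_values, block_sizes=dataset.block_sizes
    )
    if config.mode == "regress-and-invert":
        truth = _align_truth(dataset)
    else:
        # free-run recursion emits one value per input sample
        truth = dataset.output_values
    evaluation = evaluate_mapping(estimated, truth, config.snr_exponent)
    logger.info(
        "evaluated %s %s: snr=%s (exponent %.4g)%s",
        dataset.group,
        dataset.direction,
        "n/a" if evaluation.snr is None else f"{evaluation.snr:.6g}",
        config.snr_exponent,
        " [perfect fit]" if evaluation.perfect_fit else "",
    )

    # probe with the standard signal, seeding the lag at k_start - 1
    probe = generate_standard_signal(config.k_start - 1, config.k_end)
    std_output = map_series(
        model, probe.values[1:], lag_seed_value=float(probe.values[0])
    )
    snr_term = 0.0 if evaluation.perfect_fit else float(evaluation.snr)
    cloud = compute_characteristic_cloud(
        std_output, snr_term, evaluation.errors, summary=config.center_summary
    )
    logger.info(
        "cloud %s %s: center=(%.6g, %.6g), scalar=%.6g (%s)",
        dataset.group,
        dataset.direction,
        cloud.center[0],
        cloud.center[1],
        cloud.scalar_summary,
        cloud.summary_kind,
    )
    return GroupResult(
        model=model, evaluation=evaluation, std_output=std_output, cloud=cloud
    )


def run_direction(
    datasets: Mapping[str, GroupDataset],
    direction: str,
    config: AnalysisConfig,
) -> DirectionReport:
    """Run the full per-group procedure for one mapping direction.

    A stage error in one group is reported with its context and halts that
    group only; the other groups still complete.
    """
    if direction not in DIRECTIONS:
        raise ConfigurationError(f"direction must be one of {DIRECTIONS}")
    results: dict[str, GroupResult] = {}
    failures: dict[str, str] = {}
    for group in sorted(datasets):
        dataset = datasets[group]
        if len(dataset) == 0:
            raise StructuralError(f"group {group} dataset is empty")
        if dataset.direction != direction:
            raise StructuralError(
                f"group {group} dataset direction {dataset.direction} does not "
                f"match report direction {direction}"
            )
        try:
            results[group] = analyse_group(dataset, config)
        except FluxmapError as err:
            failures[group] = f"{type(err).__name__}: {err}"
            logger.error("group %s, direction %s failed: %s", group, direction, err)
    return DirectionReport(direction=direction, results=results, failures=failures)


def compare_groups(
    report_lr: DirectionReport, report_rl: DirectionReport
) -> ComparisonSummary:
    """Rank groups per direction and quantify amplification vs control.

    Ranking and amplification use the *magnitude* of the scalar center: the
    probe's mapped-output mean measures how strongly a fixed standard signal
    is amplified through the fitted mapping, and its sign merely records which
    side of the model's intercept-free level allocation the fit landed on.
    """
    if report_lr.groups != report_rl.groups:
        raise StructuralError(
            f"direction reports cover different groups: "
            f"{report_lr.groups} vs {report_rl.groups}"
        )
    rankings: dict[str, tuple[str, ...]] = {}
    tied: dict[str, bool] = {}
    amplification: dict[str, dict[str, float]] = {}
    for report in (report_lr, report_rl):
        centers = {g: abs(v) for g, v in report.scalar_centers().items()}
        order = tuple(sorted(centers, key=lambda g: (-centers[g], g)))
        values = sorted(centers.values())
        rankings[report.direction] = order
        tied[report.direction] = any(
            values[i] == values[i + 1] for i in range(len(values) - 1)
        )
        amp: dict[str, float] = {}
        if "C" in centers and centers["C"] != 0:
            for g in centers:
                if g != "C":
                    amp[g] = centers[g] / centers["C"]
        amplification[report.direction] = amp
    direction_invariant = (
        rankings[report_lr.direction] == rankings[report_rl.direction]
        and not (tied[report_lr.direction] or tied[report_rl.direction])
    )
    return ComparisonSummary(
        rankings=rankings,
        tied=tied,
        amplification=amplification,
        direction_invariant=direction_invariant,
    )


def comparison_table(
    report_lr: DirectionReport, report_rl: DirectionReport
) -> pd.DataFrame:
    """Six-row summary table: one row per (direction, group), in the layout of
    the study's distribution-center summary (both directions, three groups)."""
    rows = []
    for report in (report_lr, report_rl):
        src, dst = ("L", "R") if report.direction == "L->R" else ("R", "L")
        for group in report.groups:
            res = report.results[group]
            rows.append(
                {
                    "original_input_output": f"f_{group}{src}(k) -> f_{group}{dst}(k)",
                    "direction": report.direction,
                    "group": group,
                    "intervention": INTERVENTION_LABEL.get(group, "?"),
                    "n_rows": res.model.n_rows,
                    "snr": np.nan if res.evaluation.snr is None else res.evaluation.snr,
                    "center_x": res.cloud.center[0],
                    "center_y": res.cloud.center[1],
                    "distribution_center": res.cloud.scalar_summary,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full analysis with artifacts


def _load_group_series(
    config: AnalysisConfig,
) -> dict[str, list[tuple[PerfusionSeries, PerfusionSeries]]]:
    """Simulate or load the study, returning retained per-subject series pairs."""
    if isinstance(config.source, SyntheticSpec):
        spec = config.source
        layout = spec.layout
        pairs = simulate_study(
            layout, spec.truths(), spec.n_subjects, config.seed, spec.groups
        )
    else:
        layout = ProtocolLayout()
        series = read_series_csv(config.source)
        by_key: dict[tuple[str, str], dict[str, PerfusionSeries]] = {}
        for s in series:
            by_key.setdefault((s.group, s.subject_id), {})[s.side] = s
        pairs = []
        for (group, sid), sides in by_key.items():
            if set(sides) != {"L", "R"}:
                raise StructuralError(
                    f"subject {group}/{sid} lacks one side (found {sorted(sides)})"
                )
            pairs.append((sides["L"], sides["R"]))
    grouped: dict[str, list[tuple[PerfusionSeries, PerfusionSeries]]] = {}
    for left, right in pairs:
        retained = (
            apply_phase_exclusion(left, layout),
            apply_phase_exclusion(right, layout),
        )
        grouped.setdefault(left.group, []).append(retained)
    return grouped


def _check_finite(report: DirectionReport) -> None:
    for group, res in report.results.items():
        for name, arr in (
            ("estimated", res.evaluation.estimated),
            ("errors", res.evaluation.errors),
            ("std_output", res.std_output),
            ("v_x", res.cloud.v_x),
            ("v_y", res.cloud.v_y),
        ):
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise StructuralError(
                    f"non-finite values in {name} of group {group}, "
                    f"direction {report.direction}"
                )


def _write_plot(report_lr: DirectionReport, report_rl: DirectionReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharey=False)
    colors = {"A": "tab:blue", "B": "tab:red", "C": "tab:green"}
    for ax, report in zip(axes, (report_lr, report_rl)):
        for group in report.groups:
            cloud = report.results[group].cloud
            ax.scatter(
                cloud.v_x,
                cloud.v_y,
                s=3,
                alpha=0.35,
                label=f"{group} ({INTERVENTION_LABEL.get(group, '?')})",
                color=colors.get(group),
            )
            ax.scatter(*cloud.center, marker="x", s=80, color=colors.get(group))
        ax.set_title(f"{{{report.direction}}} mapped standard-signal output")
        ax.set_xlabel("v_x = sn + d(k)  [PU]")
        ax.set_ylabel("v_y = f''(k)  [PU]")
        ax.legend(markerscale=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass(frozen=True)
class FullAnalysisResult:
    report_lr: DirectionReport
    report_rl: DirectionReport
    comparison: ComparisonSummary
    table: pd.DataFrame


def run_full_analysis(
    config: AnalysisConfig, out_dir: str | Path | None = None
) -> FullAnalysisResult:
    """Execute both mapping directions on the same data and write all artifacts.

    Output layout under ``out_dir`` (when given): ``models/*.json``,
    ``series/*.csv``, ``report/comparison.csv``, ``report/clouds.png``,
    ``config_echo.yaml`` and ``run.log``.
    """
    out = Path(out_dir) if out_dir is not None else None
    handler = None
    root_logger = logging.getLogger("fluxmap")
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        handler.setLevel(logging.INFO)
        root_logger.addHandler(handler)
        if root_logger.level == logging.NOTSET or root_logger.level > logging.INFO:
            root_logger.setLevel(logging.INFO)
    try:
        grouped = _load_group_series(config)
        if not grouped:
            raise StructuralError("no subjects found in the data source")
        reports = {}
        for direction in DIRECTIONS:
            datasets = {
                g: dataset_from_series(pairs, direction=direction)
                for g, pairs in grouped.items()
            }
            reports[direction] = run_direction(datasets, direction, config)
            _check_finite(reports[direction])
        report_lr, report_rl = reports["L->R"], reports["R->L"]
        comparison = compare_groups(report_lr, report_rl)
        table = comparison_table(report_lr, report_rl)
        for direction, ranking in comparison.rankings.items():
            logger.info(
                "ranking %s: %s%s (amplification vs control: %s)",
                direction,
                " > ".join(ranking),
                " [tied]" if comparison.tied[direction] else "",
                {g: round(v, 4) for g, v in comparison.amplification[direction].items()},
            )
        logger.info("direction invariant ranking: %s", comparison.direction_invariant)

        if out is not None:
            (out / "models").mkdir(exist_ok=True)
            (out / "series").mkdir(exist_ok=True)
            (out / "report").mkdir(exist_ok=True)
            for report in (report_lr, report_rl):
                tag = report.direction.replace("->", "_to_")
                for group in report.groups:
                    res = report.results[group]
                    (out / "models" / f"{tag}_{group}.json").write_text(
                        res.model.to_json(), encoding="utf-8"
                    )
                    pd.DataFrame(
                        {
                            "k": np.arange(1, res.evaluation.errors.size + 1),
                            "estimated": res.evaluation.estimated,
                            "error": res.evaluation.errors,
                        }
                    ).to_csv(out / "series" / f"{tag}_{group}_errors.csv", index=False)
                    pd.DataFrame(
                        {
                            "k": np.arange(config.k_start, config.k_end + 1),
                            "std_output": res.std_output,
                        }
                    ).to_csv(out / "series" / f"{tag}_{group}_std_output.csv", index=False)
                    pd.DataFrame(
                        {"v_x": res.cloud.v_x, "v_y": res.cloud.v_y}
                    ).to_csv(out / "series" / f"{tag}_{group}_cloud.csv", index=False)
            table.to_csv(out / "report" / "comparison.csv", index=False)
            _write_plot(report_lr, report_rl, out / "report" / "clouds.png")
            (out / "config_echo.yaml").write_text(config.to_yaml(), encoding="utf-8")
        return FullAnalysisResult(
            report_lr=report_lr,
            report_rl=report_rl,
            comparison=comparison,
            table=table,
        )
    finally:
        if handler is not None:
            root_logger.removeHandler(handler)
            handler.close()


def write_synthetic_csv(config: AnalysisConfig, path: str | Path) -> int:
    """Simulate the configured study and write the raw (pre-exclusion) CSV.

    Returns the number of series written.  Requires a synthetic source.
    """
    if not isinstance(config.source, SyntheticSpec):
        raise ConfigurationError("write_synthetic_csv requires a synthetic source")
    spec = config.source
    pairs = simulate_study(
        spec.layout, spec.truths(), spec.n_subjects, config.seed, spec.groups
    )
    series = [s for pair in pairs for s in pair]
    write_series_csv(series, path)
    return len(series)
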