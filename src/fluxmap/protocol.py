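"""Measurement-protocol layout, perfusion series and paired group datasets.

The measurement protocol records skin perfusion (mean blood flux, MBF, in
arbitrary perfusion units, PU) at both Hegu (LI4) acupoints every 30 minutes
over 180 minutes: three pre-intervention phases and four post-intervention
phases, ten image frames per phase.  The frames of the phase immediately after
the intervention ("post-0") are conventionally excluded from analysis to remove
the nonspecific effect of the needling procedure itself, which leaves 60
retained samples per subject and side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError

DEFAULT_PHASES: tuple[str, ...] = (
    "pre-60",
    "pre-30",
    "pre-0",
    "post-0",
    "post-30",
    "post-60",
    "post-90",
)

GROUPS: tuple[str, ...] = ("A", "B", "C")
SIDES: tuple[str, ...] = ("L", "R")

#: CSV column order of the on-disk long format
CSV_COLUMNS = ("group", "subject_id", "side", "phase", "frame", "mbf_pu")


@dataclass(frozen=True)
class ProtocolLayout:
    """Phase/frame layout of one measurement session.

    Parameters
    ----------
    phases:
        Ordered phase labels.  Labels starting with ``"post"`` are taken to lie
        after the intervention onset.
    frames_per_phase:
        Number of image frames acquired per phase.
    excluded_phases:
        Phases removed before analysis (default: the first post phase).
    """

    phases: tuple[str, ...] = DEFAULT_PHASES
    frames_per_phase: int = 10
    excluded_phases: frozenset[str] = frozenset({"post-0"})

    def __post_init__(self) -> None:
        if self.frames_per_phase < 1:
            raise ConfigurationError("frames_per_phase must be >= 1")
        if len(set(self.phases)) != len(self.phases):
            raise ConfigurationError("phase labels must be unique")
        unknown = set(self.excluded_phases) - set(self.phases)
        if unknown:
            raise ConfigurationError(f"excluded phases not in layout: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        """Samples per subject and side before exclusion."""
        return len(self.phases) * self.frames_per_phase

    @property
    def n_retained(self) -> int:
        """Samples per subject and side after exclusion."""
        return (len(self.phases) - len(self.excluded_phases)) * self.frames_per_phase

    def is_post(self, phase: str) -> bool:
        """Whether *phase* lies after the intervention onset."""
        return phase.startswith("post")

    def is_excluded(self, phase: str) -> bool:
        return phase in self.excluded_phases

    def sample_phases(self) -> list[str]:
        """Phase label of every sample, in acquisition order."""
        return [p for p in self.phases for _ in range(self.frames_per_phase)]

    def sample_frames(self) -> list[int]:
        """1-based frame index of every sample, in acquisition order."""
        return [f + 1 for _ in self.phases for f in range(self.frames_per_phase)]


@dataclass(frozen=True)
class PerfusionSeries:
    """One side's MBF trace for one subject.

    ``values`` are strictly positive perfusion readings in PU, ordered by
    (phase, frame).  ``metadata`` carries generation diagnostics such as the
    number of noise redraws needed to keep values positive.
    """

    group: str
    subject_id: str
    side: str
    phases: tuple[str, ...]
    frames: tuple[int, ...]
    values: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not (len(self.phases) == len(self.frames) == values.size):
            raise StructuralError("phases, frames and values must have equal length")
        if self.side not in SIDES:
            raise StructuralError(f"side must be one of {SIDES}, got {self.side!r}")
        if values.size and not np.all(values > 0):
            raise StructuralError(
                f"MBF values must be strictly positive "
                f"({self.group}/{self.subject_id}/{self.side})"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def validate_against(self, layout: ProtocolLayout) -> None:
        """Raise :class:`StructuralError` unless the series conforms to *layout*."""
        if list(self.phases) != layout.sample_phases() or list(self.frames) != layout.sample_frames():
            missing = set(layout.phases) - set(self.phases)
            if missing:
                raise StructuralError(
                    f"series {self.subject_id}/{self.side} is missing phases {sorted(missing)}"
                )
            raise StructuralError(
                f"series {self.subject_id}/{self.side} does not follow the layout's "
                "(phase, frame) ordering"
            )


def apply_phase_exclusion(series: PerfusionSeries, layout: ProtocolLayout) -> PerfusionSeries:
    """Return a new series with all samples of the layout's excluded phases removed.

    The input series must contain every phase the layout declares; relative
    sample order is preserved and the input is left unmodified.
    """
    present = set(series.phases)
    missing = set(layout.phases) - present
    if missing:
        raise StructuralError(
            f"series {series.subject_id}/{series.side} is missing phases declared "
            f"by the layout: {sorted(missing)}"
        )
    keep = [i for i, p in enumerate(series.phases) if not layout.is_excluded(p)]
    return replace(
        series,
        phases=tuple(series.phases[i] for i in keep),
        frames=tuple(series.frames[i] for i in keep),
        values=series.values[keep],
    )


@dataclass(frozen=True)
class GroupDataset:
    """Concatenated (input, output) PU pairs for one group and one mapping direction.

    ``direction`` is ``"L->R"`` (left series is the declared model input) or
    ``"R->L"``.  ``block_sizes`` partitions the pairs into per-subject blocks so
    that downstream lagging never crosses a subject boundary.
    """

    group: str
    direction: str
    input_values: np.ndarray
    output_values: np.ndarray
    subject_ids: tuple[str, ...]
    block_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        iv = np.asarray(self.input_values, dtype=float)
        ov = np.asarray(self.output_values, dtype=float)
        object.__setattr__(self, "input_values", iv)
        object.__setattr__(self, "output_values", ov)
        if self.direction not in ("L->R", "R->L"):
            raise StructuralError(f"direction must be 'L->R' or 'R->L', got {self.direction!r}")
        if iv.size != ov.size:
            raise StructuralError("input and output series must have equal length")
        if sum(self.block_sizes) != iv.size:
            raise StructuralError("block sizes must partition the pairs")
        if len(self.block_sizes) != len(self.subject_ids):
            raise StructuralError("one block per subject required")
        if iv.size and (not np.all(iv > 0) or not np.all(ov > 0)):
            raise StructuralError("all PU values in a dataset must be strictly positive")

    def __len__(self) -> int:
        return int(self.input_values.size)

    @property
    def n_subjects(self) -> int:
        return len(self.block_sizes)

    def blocks(self) -> Iterator[tuple[str, slice]]:
        """Yield ``(subject_id, slice)`` for each per-subject block."""
        start = 0
        for sid, size in zip(self.subject_ids, self.block_sizes):
            yield sid, slice(start, start + size)
            start += size


def dataset_from_series(
    pairs: Iterable[tuple[PerfusionSeries, PerfusionSeries]],
    direction: str = "L->R",
) -> GroupDataset:
    """Assemble a :class:`GroupDataset` from per-subject ``(left, right)`` series.

    Both series of a pair must belong to the same subject and have equal length;
    the direction decides which side plays the declared model input.
    """
    inputs: list[np.ndarray] = []
    outputs: list[np.ndarray] = []
    sids: list[str] = []
    sizes: list[int] = []
    group = None
    for left, right in pairs:
        if left.subject_id != right.subject_id or left.group != right.group:
            raise StructuralError(
                f"paired series must share subject and group "
                f"({left.group}/{left.subject_id} vs {right.group}/{right.subject_id})"
            )
        if (left.side, right.side) != ("L", "R"):
            raise StructuralError("pairs must be given as (left, right) series")
        if len(left) != len(right):
            raise StructuralError(f"sides of subject {left.subject_id} differ in length")
        group = left.group if group is None else group
        if left.group != group:
            raise StructuralError("all pairs of a dataset must belong to one group")
        src, dst = (left, right) if direction == "L->R" else (right, left)
        inputs.append(src.values)
        outputs.append(dst.values)
        sids.append(left.subject_id)
        sizes.append(len(left))
    if group is None:
        raise StructuralError("cannot build a dataset from zero subjects")
    return GroupDataset(
        group=group,
        direction=direction,
        input_values=np.concatenate(inputs),
        output_values=np.concatenate(outputs),
        subject_ids=tuple(sids),
        block_sizes=tuple(sizes),
    )


def series_to_frame(series: Iterable[PerfusionSeries]) -> pd.DataFrame:
    """Long-format table (one row per sample) for a collection of series."""
    records = []
    for s in series:
        for phase, frame, value in zip(s.phases, s.frames, s.values):
            records.append((s.group, s.subject_id, s.side, phase, int(frame), float(value)))
    return pd.DataFrame(records, columns=list(CSV_COLUMNS))


def write_series_csv(series: Iterable[PerfusionSeries], path) -> None:
    """Write series to a UTF-8 CSV with a header row, one row per sample."""
    series_to_frame(series).to_csv(path, index=False, encoding="utf-8")


def read_series_csv(path) -> list[PerfusionSeries]:
    """Read a long-format perfusion CSV back into :class:`PerfusionSeries` objects.

    Rows are grouped by (group, subject, side) preserving file order within each
    series; schema violations raise :class:`StructuralError` before any fitting.
    """
    frame = pd.read_csv(path, encoding="utf-8")
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise StructuralError(f"perfusion CSV is missing columns: {sorted(missing)}")
    if frame["mbf_pu"].isna().any():
        raise StructuralError("perfusion CSV contains missing MBF values")
    out: list[PerfusionSeries] = []
    for (group, sid, side), sub in frame.groupby(
        ["group", "subject_id", "side"], sort=False
    ):
        out.append(
            PerfusionSeries(
                group=str(group),
                subject_id=str(sid),
                side=str(side),
                phases=tuple(str(p) for p in sub["phase"]),
                frames=tuple(int(f) for f in sub["frame"]),
                values=sub["mbf_pu"].to_numpy(dtype=float),
            )
        )
    return out
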