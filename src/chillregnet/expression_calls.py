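"""Induction/repression calling, wave segmentation and phase assignment.

The calling rules follow the thresholding scheme used for two-channel
log-ratio time courses: a gene is *induced* at a time point when its
log2(treated/control) ratio is >= 1.8 with a per-cell replicate t-test
p < 0.05.  Upregulated genes must be induced at a minimum number of
*consecutive sampled* time points (two for the chilling series, one for the
H2O2 series) and, for the up call, never significantly downregulated.
Phases partition the up-set by the earliest induced hour: phase-1 within the
first 6 h, phase-2 in (6, 24] h, phase-3 after 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourseMatrix",
    "CallConfig",
    "Wave",
    "RegulationCall",
    "OverlapResult",
    "call_upregulated",
    "call_downregulated",
    "call_h2o2_responsive",
    "segment_waves",
    "assign_phase",
    "overlap_sets",
]


class ValidationError(ValueError):
    """Raised when an input matrix or configuration violates its contract."""


def _format_hour(h: float) -> str:
    return f"{h:g}"


@dataclass(frozen=True)
class TimeCourseMatrix:
    """Genes x ordered time points of log2 ratios with per-cell p-values.

    Parameters
    ----------
    timepoints
        Strictly increasing sampling times in hours.
    ratios
        DataFrame indexed by gene id, one column per time point, holding
        log2(treated/control) ratios.
    pvalues
        Same shape as ``ratios``; per-cell significance of the replicate
        ratios (two-sided one-sample t-test).
    """

    timepoints: tuple
    ratios: pd.DataFrame
    pvalues: pd.DataFrame

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tp)
        if len(tp) == 0:
            raise ValidationError("at least one time point required")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValidationError("time points must be strictly increasing")
        if self.ratios.shape != self.pvalues.shape:
            raise ValidationError("ratio and p-value matrices differ in shape")
        if self.ratios.shape[1] != len(tp):
            raise ValidationError("matrix width does not match time points")
        if not self.ratios.index.equals(self.pvalues.index):
            raise ValidationError("gene ids of ratios and p-values differ")
        if self.ratios.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        if self.ratios.isna().any().any() or self.pvalues.isna().any().any():
            raise ValidationError("missing values are forbidden")
        pv = self.pvalues.to_numpy()
        if (pv < 0).any() or (pv > 1).any():
            raise ValidationError("p-values must lie in [0, 1]")

    @property
    def genes(self) -> list:
        return list(self.ratios.index)

    def to_tsv(self, path) -> None:
        """Write the gene_id / ratio_<h> / p_<h> dialect."""
        out = pd.DataFrame(index=self.ratios.index)
        for j, h in enumerate(self.timepoints):
            out[f"ratio_{_format_hour(h)}"] = self.ratios.iloc[:, j]
            out[f"p_{_format_hour(h)}"] = self.pvalues.iloc[:, j]
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "TimeCourseMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        if df.empty:
            raise ValidationError(f"empty expression file: {path}")
        hours = []
        for col in df.columns:
            if col.startswith("ratio_"):
                hours.append(float(col[len("ratio_"):]))
        hours.sort()
        ratios = df[[f"ratio_{_format_hour(h)}" for h in hours]].copy()
        pvals = df[[f"p_{_format_hour(h)}" for h in hours]].copy()
        ratios.columns = hours
        pvals.columns = hours
        return cls(tuple(hours), ratios, pvals)


@dataclass(frozen=True)
class CallConfig:
    """Thresholds for the induction/repression calls.

    ``up_threshold``/``down_threshold`` are log2 units; ``alpha`` is the
    per-cell significance level; ``min_consecutive_up`` is the required run
    length of induced *sampled* time points (adjacent samples count as
    consecutive even on the non-uniform hour grid).  ``require_never_down``
    applies the "not downregulated in any time point" guard of the up call
    (ratio and p); the down call's exclusion of up-crossing values is applied
    on the ratio alone via ``down_excludes_ratio_only``.
    """

    up_threshold: float = 1.8
    down_threshold: float = -1.8
    alpha: float = 0.05
    min_consecutive_up: int = 2
    require_never_down: bool = True
    down_excludes_ratio_only: bool = True
    per_timepoint_alpha: bool = True
    phase_boundaries: tuple = (6.0, 24.0)

    def __post_init__(self) -> None:
        if not (self.up_threshold > 0 > self.down_threshold):
            raise ValidationError("need up_threshold > 0 > down_threshold")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.min_consecutive_up < 1:
            raise ValidationError("min_consecutive_up must be >= 1")


H2O2_CALL_CONFIG = CallConfig(min_consecutive_up=1, require_never_down=False)


@dataclass(frozen=True)
class Wave:
    """Maximal run of consecutive induced time points."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RegulationCall:
    gene: str
    status: str  # "up" | "down" | "neither"
    induced_timepoints: frozenset = frozenset()
    waves: list = field(default_factory=list)
    interrupted: bool = False
    phase: int | None = None


def _induced_mask(matrix: TimeCourseMatrix, config: CallConfig) -> np.ndarray:
    r = matrix.ratios.to_numpy()
    p = matrix.pvalues.to_numpy()
    mask = r >= config.up_threshold
    if config.per_timepoint_alpha:
        mask &= p < config.alpha
    return mask


def _max_run_length(mask: np.ndarray) -> np.ndarray:
    """Per-row longest run of True in a 2-D boolean matrix."""
    n, t = mask.shape
    best = np.zeros(n, dtype=int)
    run = np.zeros(n, dtype=int)
    for j in range(t):
        run = np.where(mask[:, j], run + 1, 0)
        best = np.maximum(best, run)
    return best


def segment_waves(induced: Iterable[float], timepoints: Sequence[float]) -> list:
    """Split induced hours into maximal runs of consecutive sampled points.

    Duration is last hour minus first hour of the run; a single induced
    sample yields a zero-duration wave.
    """
    tp = list(timepoints)
    induced_set = set(induced)
    if not induced_set <= set(tp):
        raise ValidationError("induced time points must be sampled time points")
    waves = []
    run: list = []
    for h in tp:
        if h in induced_set:
            run.append(h)
        elif run:
            waves.append(Wave(run[0], run[-1]))
            run = []
    if run:
        waves.append(Wave(run[0], run[-1]))
    return waves


def assign_phase(call_or_hours, config: CallConfig = CallConfig()) -> int:
    """Phase of an up call from its earliest induced hour.

    t <= 6 -> 1; 6 < t <= 24 -> 2; t > 24 -> 3 (upper bounds inclusive).
    """
    if isinstance(call_or_hours, RegulationCall):
        if call_or_hours.status != "up":
            raise ValidationError(
                f"phase undefined for status={call_or_hours.status!r}"
            )
        hours = call_or_hours.induced_timepoints
    else:
        hours = call_or_hours
    if not hours:
        raise ValidationError("phase undefined without induced time points")
    first = min(hours)
    b1, b2 = config.phase_boundaries
    if first <= b1:
        return 1
    if first <= b2:
        return 2
    return 3


def _build_up_call(gene, mask_row, timepoints, config) -> RegulationCall:
    hours = frozenset(t for t, m in zip(timepoints, mask_row) if m)
    waves = segment_waves(hours, timepoints)
    call = RegulationCall(
        gene=gene,
        status="up",
        induced_timepoints=hours,
        waves=waves,
        interrupted=len(waves) > 1,
    )
    call.phase = assign_phase(call, config)
    return call


def call_upregulated(matrix: TimeCourseMatrix, config: CallConfig = CallConfig()) -> list:
    """Genes induced on >= ``min_consecutive_up`` consecutive sampled points.

    With ``require_never_down`` the gene must have no time point that is
    significantly below ``down_threshold``.  Returns one
    :class:`RegulationCall` (status="up") per qualifying gene, in input
    order.
    """
    if len(matrix.timepoints) < config.min_consecutive_up:
        raise ValidationError("fewer time points than min_consecutive_up")
    induced = _induced_mask(matrix, config)
    qualifies = _max_run_length(induced) >= config.min_consecutive_up
    if config.require_never_down:
        r = matrix.ratios.to_numpy()
        p = matrix.pvalues.to_numpy()
        down_any = ((r <= config.down_threshold) & (p < config.alpha)).any(axis=1)
        qualifies &= ~down_any
    calls = []
    for i, gene in enumerate(matrix.genes):
        if qualifies[i]:
            calls.append(_build_up_call(gene, induced[i], matrix.timepoints, config))
    return calls


def call_downregulated(matrix: TimeCourseMatrix, config: CallConfig = CallConfig()) -> list:
    """Genes significantly below ``down_threshold`` at >= 1 time point.

    A gene is excluded when any ratio reaches ``up_threshold``; by default
    that exclusion looks at the ratio regardless of its p-value
    (``down_excludes_ratio_only``).
    """
    r = matrix.ratios.to_numpy()
    p = matrix.pvalues.to_numpy()
    down = (r <= config.down_threshold) & (p < config.alpha)
    has_down = down.any(axis=1)
    if config.down_excludes_ratio_only:
        crosses_up = (r >= config.up_threshold).any(axis=1)
    else:
        crosses_up = ((r >= config.up_threshold) & (p < config.alpha)).any(axis=1)
    qualifies = has_down & ~crosses_up
    calls = []
    for i, gene in enumerate(matrix.genes):
        if qualifies[i]:
            hours = frozenset(
                t for t, m in zip(matrix.timepoints, down[i]) if m
            )
            waves = segment_waves(hours, matrix.timepoints)
            calls.append(
                RegulationCall(
                    gene=gene,
                    status="down",
                    induced_timepoints=hours,
                    waves=waves,
                    interrupted=len(waves) > 1,
                )
            )
    return calls


def call_h2o2_responsive(
    matrix: TimeCourseMatrix, config: CallConfig = H2O2_CALL_CONFIG
) -> set:
    """Single-time-point induction call used for the oxidative-mimic series."""
    if config.min_consecutive_up != 1 or config.require_never_down:
        config = CallConfig(
            up_threshold=config.up_threshold,
            down_threshold=config.down_threshold,
            alpha=config.alpha,
            min_consecutive_up=1,
            require_never_down=False,
            per_timepoint_alpha=config.per_timepoint_alpha,
            phase_boundaries=config.phase_boundaries,
        )
    return {c.gene for c in call_upregulated(matrix, config)}


@dataclass(frozen=True)
class OverlapResult:
    intersection: frozenset
    only_a: frozenset
    only_b: frozenset

    @property
    def counts(self) -> tuple:
        return (len(self.intersection), len(self.only_a), len(self.only_b))


def overlap_sets(set_a: Iterable, set_b: Iterable) -> OverlapResult:
    """Exact partition of two gene sets into intersection and differences."""
    a = frozenset(set_a)
    b = frozenset(set_b)
    return OverlapResult(a & b, a - b, b - a)


def calls_to_frame(calls: Iterable[RegulationCall]) -> pd.DataFrame:
    """Serialize calls (waves as ``start-end;start-end``) for TSV output."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene": c.gene,
                "status": c.status,
                "phase": c.phase if c.phase is not None else "none",
                "waves": ";".join(
                    f"{_format_hour(w.start)}-{_format_hour(w.end)}" for w in c.waves
                ),
                "interrupted": int(c.interrupted),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "status", "phase", "waves", "interrupted"])
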