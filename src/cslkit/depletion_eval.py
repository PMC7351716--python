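"""Quantitative evaluation of targeted depletion experiments.

Two complementary views of a depletion experiment are implemented:

* **per-base**: the relative base count r_i — treated over control
  coverage, each normalized by a library-size factor computed from
  *untargeted* transcripts (depleting abundant genes changes the total
  read count, so whole-library totals would bias the ratio).  1 − r_i is
  the per-base depletion.
* **per-gene**: depletion efficiency from TPM tables, after undoing the
  renormalization that removing abundant targets induces on everything
  else (rescaling by the median treated/control ratio over reference
  genes).

Plus the supporting statistics: TPM from counts and effective lengths,
expressed-gene counting at a strict threshold, log-scale correlation QC,
and the pooled-variance two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import Interval

__all__ = [
    "CoverageTrack",
    "DepletionProfile",
    "tpm_from_counts",
    "library_size_factors",
    "relative_base_count",
    "depletion_efficiency_from_tpm",
    "count_expressed_genes",
    "correlation_qc",
    "TTestResult",
    "unpaired_t_test",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass
class CoverageTrack:
    """Dense per-base read depth over one transcript."""

    transcript_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1 or len(self.depth) == 0:
            raise ValueError("depth must be a non-empty 1-D array")
        if (self.depth < 0).any():
            raise ValueError(f"negative depth in track {self.transcript_id}")

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def total(self) -> float:
        return float(self.depth.sum())


@dataclass
class DepletionProfile:
    """Per-base relative base count with a missing-value mask (NaN where
    the control fails the minimum-coverage filter)."""

    transcript_id: str
    r: np.ndarray
    targeted_intervals: list[Interval] = field(default_factory=list)

    def efficiency(self, interval: "tuple[int, int] | None" = None) -> float:
        """Per-transcript depletion efficiency 1 − mean(r_i), clipped to
        [0, 1], averaged over ``interval`` (default: the whole transcript).
        Masked positions are ignored."""
        lo, hi = interval if interval is not None else (0, len(self.r))
        window = self.r[lo:hi]
        if np.all(np.isnan(window)):
            return float("nan")
        return float(np.clip(1.0 - np.nanmean(window), 0.0, 1.0))


def tpm_from_counts(
    counts: "pd.Series | np.ndarray", lengths: "pd.Series | np.ndarray"
) -> pd.Series:
    """Transcripts per million from raw counts and effective lengths.

    rate_g = count_g / length_g; TPM_g = 1e6 · rate_g / Σ rates.  The
    column sums to 1e6 whenever any count is nonzero.
    """
    counts = pd.Series(counts, dtype=float) if not isinstance(counts, pd.Series) else counts.astype(float)
    lengths = pd.Series(lengths, index=counts.index, dtype=float) if not isinstance(lengths, pd.Series) else lengths.astype(float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        warnings.warn("all counts are zero: returning an all-zero TPM column", stacklevel=2)
        return rates * 0.0
    return 1e6 * rates / total


def library_size_factors(
    treated: Mapping[str, CoverageTrack],
    control: Mapping[str, CoverageTrack],
    exclude: Iterable[str] = (),
) -> tuple[float, float]:
    """Library-size factors (N_t, N_c) = total depth over transcripts not
    in ``exclude`` (the targeted genes, whose depletion distorts totals)."""
    excl = set(exclude)
    n_t = sum(t.total for tid, t in treated.items() if tid not in excl)
    n_c = sum(t.total for tid, t in control.items() if tid not in excl)
    if n_t <= 0 or n_c <= 0:
        raise ValueError("library-size factors must be positive; check the exclude set")
    return float(n_t), float(n_c)


def relative_base_count(
    treated: CoverageTrack,
    control: CoverageTrack,
    norm: tuple[float, float] = (1.0, 1.0),
    min_cov: int = 10,
    window: int = 1,
    targeted_intervals: "Iterable[Interval] | None" = None,
) -> DepletionProfile:
    """Per-base relative base count r_i = (treated_i/N_t)/(control_i/N_c).

    Positions where the control depth is below ``min_cov`` are masked
    (NaN), never infinite.  ``window`` > 1 applies a centered moving mean
    over unmasked positions.  Scale-invariant: multiplying treated depth
    and N_t by the same constant leaves r unchanged.
    """
    if treated.transcript_id != control.transcript_id:
        raise ValueError(
            f"transcript mismatch: {treated.transcript_id!r} vs {control.transcript_id!r}"
        )
    if len(treated) != len(control):
        raise ValueError(
            f"length mismatch on {treated.transcript_id}: {len(treated)} vs {len(control)}"
        )
    n_t, n_c = norm
    if n_t <= 0 or n_c <= 0:
        raise ValueError("normalization factors must be positive")
    ctrl = control.depth.astype(float)
    trt = treated.depth.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (trt / n_t) / (ctrl / n_c)
    r[ctrl < min_cov] = np.nan
    if window > 1:
        r = (
            pd.Series(r)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return DepletionProfile(
        transcript_id=treated.transcript_id,
        r=r,
        targeted_intervals=list(targeted_intervals or []),
    )


def depletion_efficiency_from_tpm(
    table: pd.DataFrame,
    targets: Iterable[str],
    reference: Iterable[str],
    control_col: str = "control",
    treated_col: str = "treated",
) -> pd.Series:
    """Per-target depletion efficiency from a TPM table.

    Removing abundant targets inflates every other gene's TPM (the column
    still sums to 1e6), so the treated column is first rescaled by the
    median treated/control ratio over the untargeted reference genes;
    efficiency_g = 1 − rescaled ratio, clipped to [0, 1].
    """
    targets = list(targets)
    reference = list(reference)
    if not reference:
        raise ValueError("reference gene set must be non-empty")
    overlap = set(targets) & set(reference)
    if overlap:
        raise ValueError(f"targets and reference must be disjoint: {sorted(overlap)}")
    ref = table.loc[reference]
    usable = ref[control_col] > 0
    if not usable.any():
        raise ValueError("no reference gene has nonzero control TPM")
    scale = float((ref.loc[usable, treated_col] / ref.loc[usable, control_col]).median())
    if scale <= 0:
        raise ValueError("median reference ratio is not positive")
    tgt = table.loc[targets]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (tgt[treated_col] / scale) / tgt[control_col]
    return (1.0 - ratio).clip(0.0, 1.0).rename("depletion_efficiency")


def count_expressed_genes(
    tpm: "pd.DataFrame | pd.Series", threshold: float = 1.0
) -> "pd.Series | int":
    """Genes with TPM strictly greater than ``threshold``, per sample."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if isinstance(tpm, pd.Series):
        return int((tpm > threshold).sum())
    return (tpm > threshold).sum(axis=0)


def correlation_qc(
    a: pd.Series,
    b: pd.Series,
    exclude: Iterable[str] = (),
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """(Spearman, Pearson) over log10(TPM + pseudocount), excluding the
    depleted target genes so the intended signal does not dominate the
    agreement measure.  Requires >= 3 shared genes after exclusion."""
    shared = a.index.intersection(b.index).difference(pd.Index(list(exclude)))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes after exclusion, got {len(shared)}")
    x = np.log10(a.loc[shared].to_numpy(dtype=float) + pseudocount)
    y = np.log10(b.loc[shared].to_numpy(dtype=float) + pseudocount)
    spearman = stats.spearmanr(x, y).statistic
    pearson = stats.pearsonr(x, y).statistic
    return float(spearman), float(pearson)


class TTestResult(NamedTuple):
    t: float
    p: float
    df: int


def unpaired_t_test(group_a: Iterable[float], group_b: Iterable[float]) -> TTestResult:
    """Pooled-variance (Student) two-sample t-test, two-tailed.

    Student rather than Welch so that n = 3 + 3 gives df = 4.  Degenerate
    zero-variance input: equal means → (t=0, p=1); unequal means → t is
    signed infinity with p = 0.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = len(a) + len(b) - 2
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        if diff == 0:
            return TTestResult(0.0, 1.0, df)
        return TTestResult(float(np.sign(diff)) * float("inf"), 0.0, df)
    t = diff / np.sqrt(pooled_var * (1 / len(a) + 1 / len(b)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(p), df)


# ---------------------------------------------------------------------------
# bedGraph interface (0-based half-open, as written by genomecov-style tools)


def read_bedgraph(
    path: "str | Path", lengths: Mapping[str, int]
) -> dict[str, CoverageTrack]:
    """Expand a bedGraph file into dense per-base tracks.

    ``lengths`` supplies each transcript's full length so uncovered tails
    are kept as explicit zeros.
    """
    tracks = {tid: np.zeros(n, dtype=float) for tid, n in lengths.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tid, start, end, value = line.split("\t")[:4]
            if tid not in tracks:
                raise ValueError(f"bedGraph names unknown transcript {tid!r}")
            s, e = int(start), int(end)
            if e > len(tracks[tid]):
                raise ValueError(f"bedGraph interval {tid}:{s}-{e} exceeds length")
            tracks[tid][s:e] = float(value)
    return {tid: CoverageTrack(tid, depth) for tid, depth in tracks.items()}


def write_bedgraph(tracks: Mapping[str, CoverageTrack], path: "str | Path") -> None:
    """Write tracks as run-length-compressed bedGraph (zero runs skipped)."""
    with open(path, "w") as fh:
        for tid in sorted(tracks):
            depth = tracks[tid].depth
            boundaries = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(depth)]))
            for s, e in zip(starts, ends):
                v = depth[s]
                if v != 0:
                    v_repr = int(v) if float(v).is_integer() else v
                    fh.write(f"{tid}\t{s}\t{e}\t{v_repr}\n")
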