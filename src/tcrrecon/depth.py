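"""Rarefaction and the minimum representative subsampling depth.

Rarefying repertoires to a common read depth is required before diversity
comparison, but an arbitrary depth risks collapsing low-frequency clonotypes
into the dominant clones and distorting the measured diversity.  The
algorithm here finds, per sample, the shallowest depth that still represents
the full-depth clone-size distribution:

1. Rarefaction curves are drawn between 100% and 1% of the sample's
   UMI-corrected reads (DCRs) at 1% intervals, subsampling 30 times per
   depth and recording the mean and standard error of the Gini coefficient
   and Shannon entropy, each normalized to its value at 100% depth.
2. The gradient of the mean normalized Gini decline is computed on the
   percent grid with depth expressed as a fraction, so a straight-line
   depreciation from (0, 0) to (1, 1) has gradient exactly 1.  Every percent
   where the gradient exceeds 1.1 (more than 10% steeper than linear) is
   recorded.
3. Qualifying percents are concatenated into maximal runs of consecutive
   integers; the run with the lowest percents is selected, and the largest
   percent in it, plus one, is the sample's minimum representative depth
   (e.g. a run ending at 20% yields 21%).  If no gradient qualifies the
   sample is representative at any depth (minimum 1%).
4. A cohort-level common depth is the read count that maximizes the number
   of samples whose [minimum depth, total reads] interval contains it.

Subsampling draws reads without replacement from the read population — each
clonotype contributes ``count`` indistinguishable reads — i.e. multivariate
hypergeometric sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import gini_coefficient, shannon_entropy
from .io import Clonotype, RepertoireSample

__all__ = [
    "RarefactionConfig",
    "RarefactionCurve",
    "MinDepthResult",
    "CohortDepthResult",
    "subsample_reads",
    "subsample_counts",
    "rarefaction_curve",
    "minimum_representative_depth",
    "cohort_common_depth",
]


@dataclass(frozen=True)
class RarefactionConfig:
    percent_grid: tuple[int, ...] = tuple(range(1, 101))
    replicates: int = 30
    gradient_threshold: float = 1.1
    master_seed: int = 0

    def __post_init__(self) -> None:
        g = self.percent_grid
        if not g or any(b <= a for a, b in zip(g, g[1:])) or g[0] < 1 or g[-1] > 100:
            raise ValueError("percent_grid must be strictly increasing within [1, 100]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def rng_for(self, percent: int, replicate: int) -> np.random.Generator:
        """Deterministic child generator for one (percent, replicate) cell.

        Spawned via a SeedSequence spawn key so results are independent of
        execution order."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.master_seed, spawn_key=(percent, replicate))
        )


@dataclass
class RarefactionCurve:
    """Mean/SE of normalized Gini and Shannon per subsampling percent.

    ``table`` columns: percent, depth_reads, mean_norm_gini, se_norm_gini,
    mean_norm_shannon, se_norm_shannon.  ``degenerate`` is set when the
    full-depth Gini or Shannon is 0, in which case the corresponding
    normalized columns are NaN.
    """

    sample_id: str
    total_reads: int
    table: pd.DataFrame
    full_depth_gini: float
    full_depth_shannon: float
    degenerate: bool = False

    def mean_norm_gini(self) -> pd.Series:
        return self.table.set_index("percent")["mean_norm_gini"]


@dataclass
class MinDepthResult:
    sample_id: str
    total_reads: int
    qualifying_percents: tuple[int, ...]
    runs: tuple[tuple[int, ...], ...]
    selected_run: tuple[int, ...]
    min_percent: int
    min_depth_reads: int


@dataclass
class CohortDepthResult:
    common_depth_reads: int
    included_sample_ids: tuple[str, ...]
    excluded_sample_ids: tuple[str, ...]


def subsample_counts(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Multivariate-hypergeometric draw of ``depth`` reads; same length as
    ``counts``, entries may be zero."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if not 1 <= depth <= total:
        raise ValueError(f"depth must be in [1, {total}], got {depth}")
    return rng.multivariate_hypergeometric(counts, depth)


def subsample_reads(
    sample: RepertoireSample,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> RepertoireSample:
    """Rarefy a sample to ``depth`` reads drawn without replacement.

    Clonotypes drawn zero times are dropped; returned counts sum to
    ``depth`` exactly.  ``seed`` may be an integer or a Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drawn = subsample_counts(sample.counts(), depth, rng)
    kept = [
        Clonotype(
            c.v_call, c.j_call, c.cdr3_nt, int(k),
            cdr3_aa=c.cdr3_aa, v_deletions=c.v_deletions, j_deletions=c.j_deletions,
        )
        for c, k in zip(sample.clonotypes, drawn)
        if k > 0
    ]
    return sample.with_clonotypes(kept)


def depth_for_percent(percent: int, total_reads: int) -> int:
    """Read depth at a subsampling percent: round(p/100 * total), floor 1."""
    return max(1, round(percent / 100 * total_reads))


def rarefaction_curve(sample: RepertoireSample, config: RarefactionConfig | None = None) -> RarefactionCurve:
    """Replicate-subsampled rarefaction curve of normalized Gini and Shannon.

    At each percent of total reads, ``config.replicates`` independent
    subsamples are drawn; the Gini and Shannon of each are divided by their
    full-depth values and summarized as mean and standard error
    (sd/sqrt(replicates)).  At 100% subsampling is the identity, so both
    normalized means are exactly 1 with SE 0.
    """
    config = config or RarefactionConfig()
    counts = sample.counts()
    total = int(counts.sum())
    if total < 100:
        raise ValueError(f"need >= 100 reads for a 1%-grid rarefaction, got {total}")
    g100 = gini_coefficient(counts)
    h100 = shannon_entropy(counts)
    degenerate = g100 == 0.0 or h100 == 0.0

    rows = []
    for p in config.percent_grid:
        depth = depth_for_percent(p, total)
        gs = np.empty(config.replicates)
        hs = np.empty(config.replicates)
        for r in range(config.replicates):
            sub = subsample_counts(counts, depth, config.rng_for(p, r))
            sub = sub[sub > 0]
            gs[r] = gini_coefficient(sub)
            hs[r] = shannon_entropy(sub)
        sqrt_n = math.sqrt(config.replicates)

        def _summ(vals: np.ndarray, ref: float) -> tuple[float, float]:
            if ref == 0.0:
                return (np.nan, np.nan)
            norm = vals / ref
            sd = norm.std(ddof=1) if config.replicates > 1 else 0.0
            return (float(norm.mean()), float(sd / sqrt_n))

        mg, sg = _summ(gs, g100)
        mh, sh = _summ(hs, h100)
        rows.append((p, depth, mg, sg, mh, sh))

    table = pd.DataFrame(
        rows,
        columns=[
            "percent", "depth_reads",
            "mean_norm_gini", "se_norm_gini",
            "mean_norm_shannon", "se_norm_shannon",
        ],
    )
    return RarefactionCurve(
        sample_id=sample.sample_id,
        total_reads=total,
        table=table,
        full_depth_gini=g100,
        full_depth_shannon=h100,
        degenerate=degenerate,
    )


def consecutive_runs(values) -> tuple[tuple[int, ...], ...]:
    """Partition a set of integers into maximal runs of consecutive values,
    ordered by their smallest member."""
    vals = sorted(set(int(v) for v in values))
    runs: list[list[int]] = []
    for v in vals:
        if runs and v == runs[-1][-1] + 1:
            runs[-1].append(v)
        else:
            runs.append([v])
    return tuple(tuple(r) for r in runs)


def min_depth_from_gradient(
    mean_norm_gini: pd.Series,
    total_reads: int,
    sample_id: str = "",
    threshold: float = 1.1,
) -> MinDepthResult:
    """Apply the gradient rule to a mean-normalized-Gini curve.

    ``mean_norm_gini`` must be indexed by percent over the full 1..100 grid.
    The gradient at percent p is the forward difference
    ``(g(p+1) - g(p)) / 0.01`` — depth as a fraction of total — and percents
    with gradient > ``threshold`` qualify.  The lowest run of consecutive
    qualifying percents marks where low-frequency clonotypes start collapsing
    into the top clones; its largest member + 1 is the minimum representative
    percent (1 when nothing qualifies).
    """
    g = mean_norm_gini.sort_index()
    if list(g.index) != list(range(1, 101)):
        raise ValueError("curve must cover the full 1..100 percent grid")
    if g.isna().any():
        raise ValueError(
            f"sample {sample_id!r}: degenerate curve (full-depth Gini or Shannon 0); "
            "exclude the sample or handle it separately"
        )
    vals = g.to_numpy()
    gradient = (vals[1:] - vals[:-1]) / 0.01  # at percents 1..99
    qualifying = tuple(int(p) for p in np.nonzero(gradient > threshold)[0] + 1)
    runs = consecutive_runs(qualifying)
    if runs:
        selected = runs[0]
        min_percent = selected[-1] + 1
    else:
        selected = ()
        min_percent = 1
    min_depth = min(math.ceil(min_percent / 100 * total_reads), total_reads)
    return MinDepthResult(
        sample_id=sample_id,
        total_reads=total_reads,
        qualifying_percents=qualifying,
        runs=runs,
        selected_run=selected,
        min_percent=min_percent,
        min_depth_reads=min_depth,
    )


def minimum_representative_depth(
    curve: RarefactionCurve, config: RarefactionConfig | None = None
) -> MinDepthResult:
    """Minimum representative subsampling depth of one sample's curve."""
    config = config or RarefactionConfig()
    if curve.degenerate:
        raise ValueError(
            f"sample {curve.sample_id!r}: degenerate rarefaction curve; "
            "exclude the sample or handle it separately"
        )
    return min_depth_from_gradient(
        curve.mean_norm_gini(),
        total_reads=curve.total_reads,
        sample_id=curve.sample_id,
        threshold=config.gradient_threshold,
    )


def cohort_common_depth(results: list[MinDepthResult]) -> CohortDepthResult:
    """Common subsampling depth maximizing the number of included samples.

    Sample i is includable at depth D iff
    ``min_depth_reads_i <= D <= total_reads_i``.  The inclusion count only
    changes at interval endpoints, so the search is restricted to the
    candidate set {min_depth_i} ∪ {total_i}; ties go to the largest D
    (more reads retained per included sample).
    """
    if not results:
        raise ValueError("need at least one sample")
    candidates = sorted({r.min_depth_reads for r in results} | {r.total_reads for r in results})
    best_d, best_n = None, -1
    for d in candidates:
        n = sum(1 for r in results if r.min_depth_reads <= d <= r.total_reads)
        if n >= best_n:  # later (larger) candidates win ties
            best_d, best_n = d, n
    included = tuple(
        r.sample_id for r in results if r.min_depth_reads <= best_d <= r.total_reads
    )
    excluded = tuple(r.sample_id for r in results if r.sample_id not in included)
    return CohortDepthResult(
        common_depth_reads=int(best_d),
        included_sample_ids=included,
        excluded_sample_ids=excluded,
    )
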