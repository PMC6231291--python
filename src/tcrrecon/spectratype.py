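"""Virtual spectratypes: CDR3-length profiles per TRBV family.

Classical spectratyping profiles the CDR3 length distribution of each V-beta
family by fluorescent fragment analysis; a healthy polyclonal repertoire
shows many peaks per family in an approximately Gaussian envelope, while an
oligoclonal repertoire collapses to a few spikes.  Sequencing-derived
clonotype tables allow the same profile to be reconstructed directly —
separated into its constituent V subfamilies and at single-nucleotide
resolution — and classified with the clinical three-group scheme
("Abnormal", "Almost normal", "Normal") from two summary statistics: the
median number of peaks per family and the fraction of families whose length
distribution takes an approximately Gaussian form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import median

import numpy as np
from scipy.stats import norm

from .io import RepertoireSample

logger = logging.getLogger(__name__)

__all__ = [
    "SpectratypeThresholds",
    "FamilyProfile",
    "SpectratypeProfile",
    "cdr3_length_distribution",
    "gaussianness_score",
    "classify_spectratype",
    "spectratype_profile",
]

CLASSES = ("Abnormal", "Almost_normal", "Normal")


@dataclass(frozen=True)
class SpectratypeThresholds:
    """Classification cut-offs (clinical-convention defaults, configurable).

    Normal requires a median of at least ``t_peaks`` peaks per family AND a
    fraction of Gaussian-shaped families (score >= ``t_gauss``) of at least
    ``t_frac``; Abnormal is a median of at most ``t_peaks_low`` peaks OR a
    Gaussian fraction of at most ``t_frac_low``; anything else is
    Almost_normal.  All comparisons are inclusive.
    """

    t_peaks: float = 8.0
    t_gauss: float = 0.8
    t_frac: float = 0.75
    t_peaks_low: float = 5.0
    t_frac_low: float = 0.4


@dataclass
class FamilyProfile:
    v_family: str
    length_histogram: dict[int, float]  # CDR3 nt length -> summed sample frequency
    peak_count: int
    gaussian_score: float
    gaussian_degenerate: bool = False

    @property
    def total_frequency(self) -> float:
        return sum(self.length_histogram.values())


@dataclass
class SpectratypeProfile:
    sample_id: str
    families: list[FamilyProfile]
    aggregate_histogram: dict[int, float]
    median_peaks: float
    n_gaussian_families: int
    gaussian_fraction: float
    classification: str | None = None


def gaussianness_score(histogram: dict[int, float]) -> float:
    """How closely a length histogram follows a Gaussian envelope, in [0, 1].

    A Gaussian is fitted by the frequency-weighted mean and SD of the
    lengths, discretized on the arithmetic grid spanned by the observed
    lengths, and compared to the observed shape by L1 distance:
    ``score = 1 - L1/2``, so identical shapes score 1 and disjoint shapes
    score 0.  The grid step is the gcd of the observed length differences
    capped at 3 nt — the codon spacing classical spectratypes resolve — so
    a few distant spikes are charged for the empty bins between them.
    Single-bin (zero-variance) histograms score 0: a lone spike carries no
    evidence of a Gaussian envelope.
    """
    score, _ = _gaussianness(histogram)
    return score


def _gaussianness(histogram: dict[int, float]) -> tuple[float, bool]:
    if not histogram:
        raise ValueError("histogram must have at least one bin")
    lengths = np.asarray(sorted(histogram), dtype=np.float64)
    weights = np.asarray([histogram[int(l)] for l in lengths], dtype=np.float64)
    total = weights.sum()
    if total <= 0:
        raise ValueError("histogram mass must be positive")
    w = weights / total
    if lengths.size == 1:
        return 0.0, True
    mu = float(w @ lengths)
    sd = float(math.sqrt(w @ (lengths - mu) ** 2))
    if sd == 0.0:
        return 0.0, True
    step = min(int(np.gcd.reduce(np.diff(lengths).astype(np.int64))), 3)
    grid = np.arange(int(lengths[0]), int(lengths[-1]) + 1, step, dtype=np.float64)
    fit = norm.pdf(grid, loc=mu, scale=sd)
    fit /= fit.sum()
    obs = np.zeros_like(grid)
    obs[np.searchsorted(grid, lengths)] = w
    return float(1.0 - 0.5 * np.abs(obs - fit).sum()), False


def cdr3_length_distribution(
    sample: RepertoireSample,
    by_family: bool = True,
    peak_floor: float = 0.01,
) -> SpectratypeProfile:
    """Frequency-weighted CDR3 nucleotide-length histograms, per V family.

    A peak is a length bin whose frequency exceeds ``peak_floor`` of its
    family's total frequency.  Clonotypes whose v_call cannot be resolved to
    a TR family are binned under "unassigned" (logged).  Family histograms
    sum to their family's share of the repertoire, and their union is the
    aggregate histogram (total mass 1).  Classification is left unset; see
    :func:`classify_spectratype`.
    """
    total = sample.total_reads
    per_family: dict[str, dict[int, float]] = {}
    aggregate: dict[int, float] = {}
    n_unassigned = 0
    for c in sample.clonotypes:
        fam = c.v_family if by_family else "all"
        if fam == "unassigned":
            n_unassigned += 1
        freq = c.count / total
        length = len(c.cdr3_nt)
        per_family.setdefault(fam, {})
        per_family[fam][length] = per_family[fam].get(length, 0.0) + freq
        aggregate[length] = aggregate.get(length, 0.0) + freq
    if n_unassigned:
        logger.warning(
            "sample %s: %d clonotypes with unresolvable v_call binned as 'unassigned'",
            sample.sample_id, n_unassigned,
        )

    families = []
    for fam in sorted(per_family):
        hist = per_family[fam]
        fam_total = sum(hist.values())
        floor = peak_floor * fam_total
        peaks = sum(1 for v in hist.values() if v > floor)
        score, degenerate = _gaussianness(hist)
        families.append(
            FamilyProfile(
                v_family=fam,
                length_histogram=dict(sorted(hist.items())),
                peak_count=peaks,
                gaussian_score=score,
                gaussian_degenerate=degenerate,
            )
        )
    return SpectratypeProfile(
        sample_id=sample.sample_id,
        families=families,
        aggregate_histogram=dict(sorted(aggregate.items())),
        median_peaks=float(median(f.peak_count for f in families)),
        n_gaussian_families=0,   # filled in by classify_spectratype
        gaussian_fraction=0.0,
    )


def classify_spectratype(
    profile: SpectratypeProfile,
    thresholds: SpectratypeThresholds | None = None,
    t_gauss: float | None = None,
) -> str:
    """Assign the clinical three-group label and annotate the profile.

    Updates ``profile.n_gaussian_families``, ``gaussian_fraction`` and
    ``classification`` in place and returns the label.
    """
    th = thresholds or SpectratypeThresholds()
    gauss_cut = th.t_gauss if t_gauss is None else t_gauss
    if not profile.families:
        raise ValueError("profile has no V families")
    n_gauss = sum(1 for f in profile.families if f.gaussian_score >= gauss_cut)
    frac = n_gauss / len(profile.families)
    profile.n_gaussian_families = n_gauss
    profile.gaussian_fraction = frac
    mp = profile.median_peaks
    if mp >= th.t_peaks and frac >= th.t_frac:
        label = "Normal"
    elif mp <= th.t_peaks_low or frac <= th.t_frac_low:
        label = "Abnormal"
    else:
        label = "Almost_normal"
    profile.classification = label
    return label


def spectratype_profile(
    sample: RepertoireSample,
    thresholds: SpectratypeThresholds | None = None,
    peak_floor: float = 0.01,
) -> SpectratypeProfile:
    """Convenience: length distribution plus classification in one call."""
    profile = cdr3_length_distribution(sample, by_family=True, peak_floor=peak_floor)
    classify_spectratype(profile, thresholds)
    return profile
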