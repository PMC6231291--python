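"""Synthetic TCR-repertoire generator.

Emulates the downstream, UMI-corrected clonotype tables of a beta-chain
repertoire experiment so that every analysis stage is testable without
sequencing data:

* heavy-tailed clone-size distributions spanning the observed diversity
  range — cord-blood-control-like repertoires (Gini well below 0.2,
  Shannon above 12 bits) through post-transplant clonally expanded ones;
* per-V-family CDR3 length distributions — Gaussian envelopes for normal
  polyclonal repertoires, a few spiked lengths for oligoclonal ones;
* longitudinal reconstitution series in which expanded clones persist
  between timepoints with a configurable probability while diversity
  recovers on a monotone schedule.

Reads are drawn multinomially over expected clone frequencies so every
table has exactly the requested read depth; CDR3 nucleotide junctions are
random in-frame sequences with the conserved cysteine/phenylalanine flanks,
so translation invariants hold on all generated data.  Everything is
deterministic under the seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .diversity import gini_coefficient
from .io import Clonotype, RepertoireSample, build_sample

__all__ = [
    "LognormalClones",
    "GeometricClones",
    "NormalLengths",
    "SpikeLengths",
    "SimulationParams",
    "ReconstitutionSeriesParams",
    "simulate_repertoire",
    "calibrate_to_target_gini",
    "simulate_reconstitution_series",
    "cord_control_params",
    "post_transplant_params",
    "normal_spectratype_params",
    "abnormal_spectratype_params",
]

_BASES = "TCAG"
_STOPS = {"TAA", "TAG", "TGA"}
CODONS = tuple(
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in _STOPS
)
_CODON_TABLE = {c: str(Seq(c).translate()) for c in CODONS}

# A realistic spread of human TRBV subfamilies (uniformly weighted by default)
DEFAULT_V_FAMILIES = tuple(
    f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 10, 11, 12, 13, 14, 15, 18, 19, 20, 24, 25, 27, 28, 29)
)
DEFAULT_J_GENES = tuple(
    f"TRBJ{a}-{b}" for a, b in [(1, i) for i in range(1, 7)] + [(2, i) for i in range(1, 8)]
)


# --------------------------------------------------------------------------
# parameter models


@dataclass(frozen=True)
class LognormalClones:
    """Expected clone sizes ~ Lognormal(mu, sigma)."""

    mu: float = 0.0
    sigma: float = 0.5

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.mu, self.sigma, size=n)


@dataclass(frozen=True)
class GeometricClones:
    """Expected clone sizes ~ Geometric(q) (heavier tail for small q)."""

    q: float = 0.1

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.geometric(self.q, size=n).astype(np.float64)


@dataclass(frozen=True)
class NormalLengths:
    """Gaussian CDR3 nt-length profile; mean must be a multiple of 3."""

    mean_nt: int = 45
    sd_nt: float = 6.0

    def __post_init__(self) -> None:
        if self.mean_nt % 3 != 0:
            raise ValueError("mean_nt must be a multiple of 3 for in-frame junctions")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        raw = rng.normal(self.mean_nt, self.sd_nt, size=n)
        lengths = 3 * np.round(raw / 3).astype(np.int64)
        return np.clip(lengths, 15, 75)


@dataclass(frozen=True)
class SpikeLengths:
    """Spiked (oligoclonal-style) length profile over a few fixed lengths."""

    lengths: tuple[int, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.weights) or not self.lengths:
            raise ValueError("lengths and weights must be non-empty and equal length")
        if any(l % 3 != 0 or l < 9 for l in self.lengths):
            raise ValueError("spike lengths must be multiples of 3, >= 9")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("spike weights must sum to 1")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(np.asarray(self.lengths), size=n, p=np.asarray(self.weights))


def _normalized_weights(weights: Mapping[str, float]) -> tuple[tuple[str, ...], np.ndarray]:
    labels = tuple(weights)
    w = np.asarray([weights[k] for k in labels], dtype=np.float64)
    if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("probability weights must be non-negative and sum to 1")
    return labels, w


@dataclass(frozen=True)
class SimulationParams:
    """Full specification of one synthetic repertoire.

    ``expansion_fractions`` are the fixed expected repertoire fractions of
    the clonally expanded clones; the baseline clones share the remaining
    mass in proportion to sizes drawn from ``baseline_distribution``.
    ``cdr3_length_model`` is either one model for all V families or a
    mapping family -> model.
    """

    baseline_richness: int = 2000
    baseline_distribution: LognormalClones | GeometricClones = LognormalClones(0.0, 0.5)
    n_expanded: int = 0
    expansion_fractions: tuple[float, ...] = ()
    v_family_weights: Mapping[str, float] | None = None
    j_weights: Mapping[str, float] | None = None
    cdr3_length_model: object = NormalLengths()
    total_reads: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_richness < 1:
            raise ValueError("baseline_richness must be >= 1")
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")
        if len(self.expansion_fractions) != self.n_expanded:
            raise ValueError("need one expansion fraction per expanded clone")
        if any(not 0 < f < 1 for f in self.expansion_fractions):
            raise ValueError("expansion fractions must lie in (0, 1)")
        if sum(self.expansion_fractions) >= 1:
            raise ValueError("expansion fractions must sum to < 1")
        if self.v_family_weights is not None:
            _normalized_weights(self.v_family_weights)
        if self.j_weights is not None:
            _normalized_weights(self.j_weights)

    @property
    def expansion_mass(self) -> float:
        return float(sum(self.expansion_fractions))


# --------------------------------------------------------------------------
# core simulation


def _expected_frequencies(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Expected clone frequencies: expanded clones first, then baseline."""
    sizes = params.baseline_distribution.draw(rng, params.baseline_richness)
    baseline = sizes / sizes.sum() * (1.0 - params.expansion_mass)
    return np.concatenate([np.asarray(params.expansion_fractions), baseline])


def _simulate_counts(params: SimulationParams, seed: int) -> np.ndarray:
    """Clone counts only (no sequence assignment) — fast path for calibration."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = _expected_frequencies(params, rng)
    return rng.multinomial(params.total_reads, p)


def _length_model_for(params: SimulationParams, family: str):
    model = params.cdr3_length_model
    if isinstance(model, Mapping):
        return model[family]
    return model


def _translate(nt: str) -> str:
    return "".join(_CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt), 3))


def _draw_identity_batch(
    rng: np.random.Generator, n: int, params: SimulationParams
) -> list[tuple[str, str, str, str]]:
    v_weights = params.v_family_weights or {f: 1 / len(DEFAULT_V_FAMILIES) for f in DEFAULT_V_FAMILIES}
    j_weights = params.j_weights or {j: 1 / len(DEFAULT_J_GENES) for j in DEFAULT_J_GENES}
    v_labels, vw = _normalized_weights(v_weights)
    j_labels, jw = _normalized_weights(j_weights)
    fams = rng.choice(len(v_labels), size=n, p=vw)
    js = rng.choice(len(j_labels), size=n, p=jw)
    lengths = np.empty(n, dtype=np.int64)
    for fi in np.unique(fams):
        mask = fams == fi
        lengths[mask] = _length_model_for(params, v_labels[fi]).draw(rng, int(mask.sum()))
    n_mid = lengths // 3 - 2
    codon_idx = rng.integers(0, len(CODONS), size=(n, int(n_mid.max()) if n else 0))
    out = []
    for i in range(n):
        mid = "".join(CODONS[k] for k in codon_idx[i, : n_mid[i]])
        nt = "TGT" + mid + "TTT"
        out.append((f"{v_labels[fams[i]]}-1*01", j_labels[js[i]], nt, _translate(nt)))
    return out


def _draw_identities(
    rng: np.random.Generator,
    n: int,
    params: SimulationParams,
    taken: set[tuple[str, str, str]],
) -> list[tuple[str, str, str, str]]:
    """n distinct (v_call, j_call, cdr3_nt, cdr3_aa) identities, avoiding ``taken``."""
    out: list[tuple[str, str, str, str]] = []
    while len(out) < n:
        for v, j, nt, aa in _draw_identity_batch(rng, n - len(out), params):
            if (v, j, nt) in taken:
                continue  # collision: redrawn in the next batch
            taken.add((v, j, nt))
            out.append((v, j, nt, aa))
    return out


def simulate_repertoire(params: SimulationParams, sample_id: str = "sim", **metadata) -> RepertoireSample:
    """Draw one synthetic repertoire sample.

    Counts sum to ``params.total_reads`` exactly; clones drawn zero times
    are dropped.  Expanded clones are generated distinct from baseline
    clones, so their identities are unambiguous ground truth for tracking
    tests.  Identical params and seed give identical tables.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    p = _expected_frequencies(params, rng)
    counts = rng.multinomial(params.total_reads, p)
    identities = _draw_identities(rng, len(counts), params, set())
    clonotypes = [
        Clonotype(v, j, nt, int(k), cdr3_aa=aa)
        for (v, j, nt, aa), k in zip(identities, counts)
        if k > 0
    ]
    return build_sample(sample_id, clonotypes, **metadata)


# --------------------------------------------------------------------------
# study-condition presets


def cord_control_params(seed: int = 0, total_reads: int = 200_000) -> SimulationParams:
    """Cord-blood-control-like repertoire: rich, even, no clonal expansions.

    Targets the diversity range reported for control cords (Gini below 0.2,
    Shannon above 12 bits at this depth)."""
    return SimulationParams(
        baseline_richness=6000,
        baseline_distribution=LognormalClones(0.0, 0.2),
        n_expanded=0,
        expansion_fractions=(),
        total_reads=total_reads,
        seed=seed,
    )


def post_transplant_params(seed: int = 0, total_reads: int = 100_000) -> SimulationParams:
    """Early post-transplant repertoire: restricted, clonally expanded."""
    fractions = tuple(0.45 * 0.7**i * (1 - 0.7) / (1 - 0.7**12) for i in range(12))
    return SimulationParams(
        baseline_richness=1500,
        baseline_distribution=LognormalClones(0.0, 0.8),
        n_expanded=12,
        expansion_fractions=fractions,
        total_reads=total_reads,
        seed=seed,
    )


def abnormal_spectratype_params(seed: int = 0, total_reads: int = 50_000) -> SimulationParams:
    """Oligoclonal repertoire with 1-3 spiked CDR3 lengths per V family."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xABB)))
    models = {}
    for fam in DEFAULT_V_FAMILIES:
        k = int(rng.integers(1, 4))
        lengths = tuple(int(l) for l in 3 * rng.choice(np.arange(10, 22), size=k, replace=False))
        w = rng.dirichlet(np.ones(k))
        models[fam] = SpikeLengths(lengths=lengths, weights=tuple(float(x) for x in w / w.sum()))
    fractions = tuple(0.6 / 15 for _ in range(15))
    return SimulationParams(
        baseline_richness=120,
        baseline_distribution=LognormalClones(0.0, 1.0),
        n_expanded=15,
        expansion_fractions=fractions,
        cdr3_length_model=models,
        total_reads=total_reads,
        seed=seed,
    )


def normal_spectratype_params(seed: int = 0, total_reads: int = 100_000) -> SimulationParams:
    """Polyclonal repertoire with Gaussian per-family length envelopes."""
    return SimulationParams(
        baseline_richness=4000,
        baseline_distribution=LognormalClones(0.0, 0.3),
        n_expanded=0,
        cdr3_length_model=NormalLengths(45, 6.0),
        total_reads=total_reads,
        seed=seed,
    )


# --------------------------------------------------------------------------
# calibration


def calibrate_to_target_gini(
    target_gini: float,
    template: SimulationParams,
    n_seeds: int = 10,
    tol: float = 0.05,
    max_iter: int = 30,
) -> SimulationParams:
    """Tune total expansion mass so mean simulated Gini hits a target.

    Monotone bisection on the summed expansion fraction (split equally over
    the template's expanded clones); the objective is the Gini averaged over
    ``n_seeds`` simulated repertoires.  Raises with the achievable bracket
    when the target cannot be reached by varying expansion mass alone.
    """
    if not 0 <= target_gini <= 0.9:
        raise ValueError("target_gini must lie in [0, 0.9]")
    n_exp = template.n_expanded if template.n_expanded > 0 else 10

    def with_mass(mass: float) -> SimulationParams:
        if mass <= 0:
            return replace(template, n_expanded=0, expansion_fractions=())
        return replace(
            template,
            n_expanded=n_exp,
            expansion_fractions=tuple(mass / n_exp for _ in range(n_exp)),
        )

    def mean_gini(mass: float) -> float:
        params = with_mass(mass)
        vals = []
        for s in range(n_seeds):
            counts = _simulate_counts(params, seed=template.seed + s)
            vals.append(gini_coefficient(counts[counts > 0]))
        return float(np.mean(vals))

    lo, hi = 0.0, 0.95
    g_lo, g_hi = mean_gini(lo), mean_gini(hi)
    if target_gini < g_lo - tol or target_gini > g_hi + tol:
        raise ValueError(
            f"target Gini {target_gini} unreachable from this template; "
            f"achievable mean Gini bracket is [{g_lo:.3f}, {g_hi:.3f}]"
        )
    if g_lo >= target_gini:
        # baseline inequality already meets/exceeds the target (within tol)
        return with_mass(0.0)
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        g_mid = mean_gini(mid)
        if g_mid < target_gini:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return with_mass((lo + hi) / 2)


# --------------------------------------------------------------------------
# longitudinal series


@dataclass(frozen=True)
class ReconstitutionSeriesParams:
    """Longitudinal cohort for one patient: oligoclonal to diverse.

    Richness, read depth and total expansion mass are interpolated linearly
    in month between ``initial`` and ``final``; each expanded clone identity
    is carried from one timepoint to the next with probability
    ``persistence_fraction`` and replaced by a fresh clone otherwise.
    Baseline clone identities come from a fixed pool so the background
    repertoire is biologically continuous.
    """

    months: tuple[float, ...]
    initial: SimulationParams
    final: SimulationParams
    persistence_fraction: float = 0.7
    seed: int = 0
    patient_id: str = "SIM"

    def __post_init__(self) -> None:
        if len(self.months) < 2:
            raise ValueError("need at least 2 sampling months")
        if any(b <= a for a, b in zip(self.months, self.months[1:])):
            raise ValueError("months must be strictly increasing")
        if not 0 <= self.persistence_fraction <= 1:
            raise ValueError("persistence_fraction must lie in [0, 1]")
        if self.initial.n_expanded == 0 and self.final.expansion_mass > 0:
            raise ValueError(
                "series carries the initial expanded clones forward; give the "
                "initial params at least as many expanded clones as the final"
            )


def simulate_reconstitution_series(
    params: ReconstitutionSeriesParams, with_truth: bool = False
):
    """One sample per month, oligoclonal early and diverse late.

    Returns the list of samples; with ``with_truth=True`` also returns the
    per-month list of expanded-clone identity keys (ground truth for
    tracking tests)."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    init, fin = params.initial, params.final
    m0, m1 = params.months[0], params.months[-1]
    span = m1 - m0

    taken: set[tuple[str, str, str]] = set()
    max_rich = max(init.baseline_richness, fin.baseline_richness)
    pool = _draw_identities(rng, max_rich, fin, taken)
    pool_sizes = fin.baseline_distribution.draw(rng, max_rich)

    n_exp = init.n_expanded
    expanded = _draw_identities(rng, n_exp, init, taken)
    init_mass = init.expansion_mass
    fin_mass = fin.expansion_mass
    rel = (
        np.asarray(init.expansion_fractions) / init_mass
        if init_mass > 0
        else np.full(max(n_exp, 1), 1.0 / max(n_exp, 1))
    )

    samples = []
    truth = []
    for idx, month in enumerate(params.months):
        t = (month - m0) / span
        richness = int(round((1 - t) * init.baseline_richness + t * fin.baseline_richness))
        mass = (1 - t) * init_mass + t * fin_mass
        total_reads = int(round((1 - t) * init.total_reads + t * fin.total_reads))
        if idx > 0 and n_exp:
            kept = rng.random(n_exp) < params.persistence_fraction
            fresh = _draw_identities(rng, int((~kept).sum()), init, taken)
            it = iter(fresh)
            expanded = [e if k else next(it) for e, k in zip(expanded, kept)]

        sizes = pool_sizes[:richness]
        baseline_p = sizes / sizes.sum() * (1 - mass)
        p = np.concatenate([mass * rel[:n_exp], baseline_p]) if n_exp else baseline_p
        counts = rng.multinomial(total_reads, p)
        idents = expanded + pool[:richness]
        clonotypes = [
            Clonotype(v, j, nt, int(k), cdr3_aa=aa)
            for (v, j, nt, aa), k in zip(idents, counts)
            if k > 0
        ]
        samples.append(
            build_sample(
                f"{params.patient_id}_m{month:g}",
                clonotypes,
                patient_id=params.patient_id,
                month_post_tx=float(month),
            )
        )
        truth.append([(v, j, nt) for v, j, nt, _ in expanded])
    return (samples, truth) if with_truth else samples
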