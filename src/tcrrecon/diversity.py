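"""Diversity statistics over clonotype abundance distributions.

Two statistics summarize a repertoire's clone-size distribution:

* **Gini coefficient** — inequality of clonotype frequencies; twice the area
  between the 45-degree line and the Lorenz curve of the abundance
  distribution.  0 means all clonotypes are equally abundant; values toward 1
  mean the repertoire is dominated by a few expanded clones.
* **Shannon entropy** (base 2, bits) — joint measure of richness and
  evenness: ``H = -sum p_i log2 p_i`` with ``p_i`` the proportional abundance
  of clonotype i.

The Gini estimator is the discrete Lorenz form
``G = sum_i (2i - n - 1) x_(i) / (n sum x)`` over counts sorted ascending,
without any small-sample correction, so that equal counts return exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .io import RepertoireSample

__all__ = ["gini_coefficient", "shannon_entropy", "DiversitySummary", "diversity_summary"]


def _as_counts(abundances) -> np.ndarray:
    x = np.asarray(abundances, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("abundance vector must be a non-empty 1-d array")
    if np.any(x <= 0):
        raise ValueError("abundances must be positive; filter zero counts upstream")
    return x


def gini_coefficient(abundances) -> float:
    """Gini coefficient of a clonotype abundance vector, in [0, 1).

    Permutation- and scale-invariant; exactly 0 for equal counts and for the
    degenerate single-clonotype vector (no inequality is expressible between
    fewer than two clonotypes).
    """
    x = np.sort(_as_counts(abundances))
    n = x.size
    i = np.arange(1, n + 1, dtype=np.float64)
    return float(((2.0 * i - n - 1.0) @ x) / (n * x.sum()))


def shannon_entropy(abundances, base: float = 2.0) -> float:
    """Shannon entropy of the abundance distribution (bits when base=2)."""
    if base <= 1:
        raise ValueError(f"logarithm base must exceed 1, got {base}")
    x = _as_counts(abundances)
    return float(_scipy_entropy(x / x.sum(), base=base))


@dataclass
class DiversitySummary:
    """Per-sample diversity report.

    ``degenerate`` flags monoclonal samples, whose Gini and Shannon of 0 must
    not be read as evidence of an even, diverse repertoire.
    """

    sample_id: str
    gini: float
    shannon_bits: float
    richness: int
    total_reads: int
    top_k_fraction: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False


def diversity_summary(
    sample: RepertoireSample, top_k: list[int] = (20,)
) -> DiversitySummary:
    """Gini, base-2 Shannon, and cumulative top-k clonotype frequencies.

    ``top_k_fraction[k]`` is the summed frequency of the k most abundant
    clonotypes (ties broken by lexicographic clonotype key, see
    :func:`tcrrecon.dynamics.top_clonotypes`).
    """
    from .dynamics import top_clonotypes  # avoids an import cycle

    if any(k < 1 for k in top_k):
        raise ValueError("top_k entries must be >= 1")
    counts = sample.counts()
    ranked = top_clonotypes(sample, n=sample.richness)
    freqs = np.asarray([f for _, f in ranked])
    cum = np.cumsum(freqs)
    return DiversitySummary(
        sample_id=sample.sample_id,
        gini=gini_coefficient(counts),
        shannon_bits=shannon_entropy(counts),
        richness=sample.richness,
        total_reads=sample.total_reads,
        top_k_fraction={int(k): float(cum[min(k, len(cum)) - 1]) for k in top_k},
        degenerate=sample.richness == 1,
    )
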