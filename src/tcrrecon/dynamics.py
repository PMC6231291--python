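"""Longitudinal clonotype tracking and antigen annotation.

Tracking follows the most abundant clonotypes of each timepoint across a
patient's serial samples; a clonotype detected at two or more timepoints
(by exact nucleotide identity) is *persistent*.  Annotation matches
clonotype CDR3 amino-acid sequences exactly against a VDJdb-format table
and aggregates, per antigen species, the repertoire fraction carried by
matching clonotypes — the repertoire's *antigen binding potential* for that
species.  Database annotations reflect cross-reactive, chain-unpaired
evidence, so the result is deliberately a "potential", never a claim of
specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import Clonotype, RepertoireSample, VdjdbRecord, v_family

logger = logging.getLogger(__name__)

__all__ = [
    "ClonotypeTrajectory",
    "AnnotationResult",
    "top_clonotypes",
    "track_clonotypes",
    "annotate_vdjdb",
]

MATCH_POLICIES = ("cdr3_aa", "cdr3_aa+v")


def top_clonotypes(sample: RepertoireSample, n: int = 20) -> list[tuple[Clonotype, float]]:
    """The n most abundant clonotypes with their frequencies of total DCRs.

    Ties in count are broken deterministically by lexicographic
    (cdr3_nt, v_call, j_call) ascending.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    total = sample.total_reads
    ranked = sorted(
        sample.clonotypes, key=lambda c: (-c.count, c.cdr3_nt, c.v_call, c.j_call)
    )
    return [(c, c.count / total) for c in ranked[:n]]


@dataclass
class ClonotypeTrajectory:
    """One clonotype's frequency across a patient's timepoints."""

    key: tuple[str, str, str]  # (v_call, j_call, cdr3_nt)
    frequencies: dict[float, float]  # month -> fraction of total DCRs

    @property
    def persistent(self) -> bool:
        return len(self.frequencies) >= 2


def track_clonotypes(
    samples: list[RepertoireSample], n: int = 20
) -> list[ClonotypeTrajectory]:
    """Trajectories of the union of per-timepoint top-n clonotypes.

    Input samples must belong to one patient and chain and carry distinct
    ``month_post_tx`` values; input order is irrelevant (timepoints are
    recovered from the metadata).  A clonotype in the union is looked up at
    every timepoint, so a clone that is top-n early and rare later still has
    its later frequency recorded.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 timepoints to track clonotypes")
    patients = {s.patient_id for s in samples}
    chains = {s.chain for s in samples}
    if len(patients) > 1 or len(chains) > 1:
        raise ValueError(
            f"samples must share one patient and chain, got {patients} / {chains}"
        )
    months = [s.month_post_tx for s in samples]
    if any(m is None for m in months) or len(set(months)) != len(months):
        raise ValueError("samples must carry distinct month_post_tx values")
    ordered = sorted(samples, key=lambda s: s.month_post_tx)

    union: list[tuple[str, str, str]] = []
    seen = set()
    for s in ordered:
        for c, _ in top_clonotypes(s, n=n):
            if c.key not in seen:
                seen.add(c.key)
                union.append(c.key)

    lookup = [
        {c.key: c.count / s.total_reads for c in s.clonotypes} for s in ordered
    ]
    trajectories = []
    for key in union:
        freqs = {
            float(s.month_post_tx): table[key]
            for s, table in zip(ordered, lookup)
            if key in table
        }
        trajectories.append(ClonotypeTrajectory(key=key, frequencies=freqs))
    return trajectories


@dataclass
class AnnotationResult:
    """Database hits per clonotype and binding potential per species.

    A clonotype matching several epitopes of one species contributes its
    frequency once to that species; a clonotype matching two species
    contributes its full frequency to each (overlap is possible, so species
    potentials do not sum to the total annotated fraction).
    """

    hits: dict[tuple[str, str, str], list[tuple[VdjdbRecord, str]]]
    binding_potential: dict[str, float]
    n_skipped_no_aa: int = 0


def annotate_vdjdb(
    sample: RepertoireSample,
    db: list[VdjdbRecord],
    match_policy: str = "cdr3_aa+v",
) -> AnnotationResult:
    """Match clonotypes against a VDJdb-format table by exact CDR3.

    ``cdr3_aa`` matches on the amino-acid junction alone; ``cdr3_aa+v``
    additionally requires the V calls to agree at gene-family resolution
    (records without a V call never match under this policy).  Clonotypes
    lacking an amino-acid junction (out-of-frame) are skipped and counted.
    """
    if not db:
        raise ValueError("annotation database is empty")
    if match_policy not in MATCH_POLICIES:
        raise ValueError(f"match_policy must be one of {MATCH_POLICIES}")

    index: dict[str, list[VdjdbRecord]] = {}
    for rec in db:
        index.setdefault(rec.cdr3_aa, []).append(rec)

    total = sample.total_reads
    hits: dict[tuple[str, str, str], list[tuple[VdjdbRecord, str]]] = {}
    potential: dict[str, float] = {}
    n_skipped = 0
    for c in sample.clonotypes:
        if not c.cdr3_aa:
            n_skipped += 1
            continue
        matched_species = set()
        for rec in index.get(c.cdr3_aa, ()):
            if match_policy == "cdr3_aa+v":
                if rec.v_call is None or v_family(rec.v_call) != c.v_family:
                    continue
                level = "cdr3_aa+v"
            else:
                level = "cdr3_aa"
            hits.setdefault(c.key, []).append((rec, level))
            matched_species.add(rec.antigen_species)
        freq = c.count / total
        for sp in matched_species:
            potential[sp] = potential.get(sp, 0.0) + freq
    if n_skipped:
        logger.info(
            "sample %s: %d clonotypes without cdr3_aa skipped in annotation",
            sample.sample_id, n_skipped,
        )
    return AnnotationResult(
        hits=hits, binding_potential=potential, n_skipped_no_aa=n_skipped
    )
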