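"""Reading, validation and writing of clonotype tables and VDJdb annotations.

Two table dialects are supported:

* ``airr`` — AIRR rearrangement TSV with columns ``v_call``, ``j_call``,
  ``junction`` (nucleotide), ``junction_aa`` and ``duplicate_count``.
* ``decombinator_freq`` — comma-separated five-field classifier output plus a
  count: V, J, V deletions, J deletions, insert sequence, count.  An optional
  tag-to-gene-name map resolves numeric V/J indices to gene names.

A clonotype is identified by the triple (v_call, j_call, cdr3_nt); duplicate
keys are merged by summing their UMI-corrected counts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DIALECTS = ("airr", "decombinator_freq")

AIRR_COLUMNS = ("v_call", "j_call", "junction", "junction_aa", "duplicate_count")

_FAMILY_RE = re.compile(r"^(TR[ABGD][VJ]\d+)")


class FormatError(ValueError):
    """A table does not meet its dialect's column or record contract."""


class ValidationError(ValueError):
    """A clonotype or sample violates a domain invariant."""


def v_family(v_call: str) -> str:
    """IMGT-style subfamily label for a V (or J) gene call.

    ``"TRBV5-1*01"`` -> ``"TRBV5"``.  Calls that do not look like an IMGT
    TR gene name resolve to ``"unassigned"``.
    """
    m = _FAMILY_RE.match(v_call.strip())
    return m.group(1) if m else "unassigned"


def translate_junction(cdr3_nt: str) -> str | None:
    """Translate an in-frame junction; ``None`` if out-of-frame."""
    if len(cdr3_nt) % 3 != 0 or not cdr3_nt:
        return None
    return str(Seq(cdr3_nt).translate())


@dataclass(frozen=True)
class Clonotype:
    """One unique rearrangement with its UMI-corrected abundance (DCR count).

    ``cdr3_aa`` may be absent for out-of-frame junctions.  ``v_deletions`` /
    ``j_deletions`` are carried through from Decombinator-style records but do
    not participate in clonotype identity.
    """

    v_call: str
    j_call: str
    cdr3_nt: str
    count: int
    cdr3_aa: str | None = None
    v_deletions: int = 0
    j_deletions: int = 0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_call, self.j_call, self.cdr3_nt)

    @property
    def v_family(self) -> str:
        return v_family(self.v_call)

    def validate(self) -> None:
        if not self.cdr3_nt:
            raise ValidationError("cdr3_nt must be non-empty")
        if not isinstance(self.count, (int, np.integer)) or self.count < 1:
            raise ValidationError(
                f"count must be a positive integer, got {self.count!r}"
            )
        if self.cdr3_aa is not None and len(self.cdr3_nt) % 3 == 0:
            expected = translate_junction(self.cdr3_nt)
            if expected is not None and self.cdr3_aa != expected:
                raise ValidationError(
                    f"cdr3_aa {self.cdr3_aa!r} does not match the translation "
                    f"{expected!r} of in-frame junction {self.cdr3_nt!r}"
                )


@dataclass
class RepertoireSample:
    """A sample's validated clonotype table plus its metadata."""

    sample_id: str
    clonotypes: list[Clonotype]
    patient_id: str = ""
    month_post_tx: float | None = None
    chain: str = "beta"
    group: str = "patient"
    spectratype_class: str | None = None
    gvhd_grade: int | None = None

    def __post_init__(self) -> None:
        if self.chain not in ("alpha", "beta"):
            raise ValidationError(f"chain must be alpha or beta, got {self.chain!r}")
        if not self.clonotypes:
            raise ValidationError(f"sample {self.sample_id!r} has no clonotypes")

    @property
    def richness(self) -> int:
        return len(self.clonotypes)

    @property
    def total_reads(self) -> int:
        return int(sum(c.count for c in self.clonotypes))

    def counts(self) -> np.ndarray:
        return np.asarray([c.count for c in self.clonotypes], dtype=np.int64)

    def frequencies(self) -> np.ndarray:
        counts = self.counts()
        return counts / counts.sum()

    def frequency_of(self, key: tuple[str, str, str]) -> float | None:
        total = self.total_reads
        for c in self.clonotypes:
            if c.key == key:
                return c.count / total
        return None

    def productive_only(self) -> "RepertoireSample":
        """Copy restricted to in-frame, stop-free clonotypes."""
        kept = [c for c in self.clonotypes if c.cdr3_aa and "*" not in c.cdr3_aa]
        if not kept:
            raise ValidationError(
                f"sample {self.sample_id!r} has no productive clonotypes"
            )
        return replace(self, clonotypes=kept)

    def with_clonotypes(self, clonotypes: list[Clonotype]) -> "RepertoireSample":
        return replace(self, clonotypes=clonotypes)


@dataclass(frozen=True)
class VdjdbRecord:
    """One antigen-annotated CDR3 from a VDJdb-format table."""

    cdr3_aa: str
    epitope: str
    antigen_species: str
    v_call: str | None = None
    j_call: str | None = None


def merge_clonotypes(clonotypes: Iterable[Clonotype]) -> list[Clonotype]:
    """Merge duplicate (v_call, j_call, cdr3_nt) keys by summing counts.

    Zero-count records are dropped with a logged warning.  Order of first
    appearance is preserved so reading is order-insensitive only up to the
    multiset, which is what identity requires.
    """
    merged: dict[tuple[str, str, str], Clonotype] = {}
    n_zero = 0
    for c in clonotypes:
        if c.count == 0:
            n_zero += 1
            continue
        c.validate()
        prev = merged.get(c.key)
        if prev is None:
            merged[c.key] = c
        else:
            merged[c.key] = replace(prev, count=prev.count + c.count)
    if n_zero:
        logger.warning("dropped %d zero-count clonotype rows", n_zero)
    return sorted(merged.values(), key=lambda c: c.key)


def build_sample(sample_id: str, clonotypes: Iterable[Clonotype], **metadata) -> RepertoireSample:
    """Validate and assemble a sample, merging duplicate clonotype keys."""
    return RepertoireSample(sample_id=sample_id, clonotypes=merge_clonotypes(clonotypes), **metadata)


# ---------------------------------------------------------------------------
# clonotype table readers / writers


def _check_counts(series: pd.Series, path: str) -> np.ndarray:
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.isna() | (vals % 1 != 0) | (vals < 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise FormatError(
            f"{path}: non-integer or negative count {series[bad.idxmax()]!r} "
            f"at line {line}"
        )
    return vals.astype(np.int64).to_numpy()


def _read_airr(path: Path) -> list[Clonotype]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory AIRR column(s) {missing}")
    counts = _check_counts(df["duplicate_count"], str(path))
    out = []
    for (v, j, nt, aa), n in zip(
        df[["v_call", "j_call", "junction", "junction_aa"]].itertuples(index=False),
        counts,
    ):
        out.append(Clonotype(v, j, nt, int(n), cdr3_aa=aa or None))
    return out

DECOMBINATOR_FIELDS = ("v", "j", "v_deletions", "j_deletions", "insert", "count")


def _read_decombinator(path: Path, tag_map: Mapping[str, Mapping[int, str]] | None) -> list[Clonotype]:
    df = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    if df.shape[1] != 6:
        raise FormatError(
            f"{path}: decombinator_freq rows need 6 comma-separated fields "
            f"(V, J, V-del, J-del, insert, count), got {df.shape[1]}"
        )
    df.columns = list(DECOMBINATOR_FIELDS)
    counts = _check_counts(df["count"], str(path))

    def resolve(call: str, gene: str) -> str:
        if tag_map and gene in tag_map and call.isdigit():
            try:
                return tag_map[gene][int(call)]
            except KeyError:
                raise FormatError(f"{path}: {gene.upper()} index {call} not in tag map")
        return call

    out, n_empty = [], 0
    for row, n in zip(df.itertuples(index=False), counts):
        if not row.insert:
            n_empty += 1
            continue
        out.append(
            Clonotype(
                resolve(row.v, "v"),
                resolve(row.j, "j"),
                row.insert,
                int(n),
                cdr3_aa=translate_junction(row.insert),
                v_deletions=int(row.v_deletions or 0),
                j_deletions=int(row.j_deletions or 0),
            )
        )
    if n_empty:
        logger.warning("%s: dropped %d rows with empty insert sequence", path, n_empty)
    return out


def read_clonotype_table(
    path: str | Path,
    dialect: str = "airr",
    *,
    tag_map: Mapping[str, Mapping[int, str]] | None = None,
    **metadata,
) -> RepertoireSample:
    """Read and validate one sample's clonotype table.

    Parameters
    ----------
    path
        Input file; its stem is the default sample_id.
    dialect
        ``"airr"`` or ``"decombinator_freq"``.
    tag_map
        Optional ``{"v": {index: name}, "j": {...}}`` mapping for resolving
        Decombinator tag indices to gene names.
    metadata
        Passed through to :class:`RepertoireSample` (patient_id, month_post_tx,
        chain, group, ...); ``sample_id`` overrides the file stem.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "airr":
        raw = _read_airr(path)
    else:
        raw = _read_decombinator(path, tag_map)
    sample_id = metadata.pop("sample_id", path.stem)
    return build_sample(sample_id, raw, **metadata)


def write_clonotype_table(sample: RepertoireSample, path: str | Path, dialect: str = "airr") -> None:
    """Write a validated sample; ``read(write(s))`` reproduces s's clonotype
    multiset and counts exactly (the airr dialect also round-trips cdr3_aa)."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not sample.clonotypes:
        raise ValidationError("refusing to write a sample with no clonotypes")
    rows = sorted(sample.clonotypes, key=lambda c: c.key)
    if dialect == "airr":
        df = pd.DataFrame(
            {
                "v_call": [c.v_call for c in rows],
                "j_call": [c.j_call for c in rows],
                "junction": [c.cdr3_nt for c in rows],
                "junction_aa": [c.cdr3_aa or "" for c in rows],
                "duplicate_count": [c.count for c in rows],
            }
        )
        df.to_csv(path, sep="\t", index=False)
    else:
        df = pd.DataFrame(
            {
                "v": [c.v_call for c in rows],
                "j": [c.j_call for c in rows],
                "v_deletions": [c.v_deletions for c in rows],
                "j_deletions": [c.j_deletions for c in rows],
                "insert": [c.cdr3_nt for c in rows],
                "count": [c.count for c in rows],
            }
        )
        df.to_csv(path, header=False, index=False)


# ---------------------------------------------------------------------------
# VDJdb

VDJDB_CDR3 = "cdr3"
VDJDB_SPECIES = "antigen.species"


def read_vdjdb_table(path: str | Path) -> list[VdjdbRecord]:
    """Read a VDJdb-format TSV of antigen-annotated CDR3s.

    Requires at least the ``cdr3`` and ``antigen.species`` columns; rows with
    an empty CDR3 are dropped (count logged).  The same CDR3 may legitimately
    appear several times, annotated to different epitopes or species.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (VDJDB_CDR3, VDJDB_SPECIES):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory VDJdb column {col!r}")
    records = []
    n_empty = 0
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        if not d[VDJDB_CDR3]:
            n_empty += 1
            continue
        records.append(
            VdjdbRecord(
                cdr3_aa=d[VDJDB_CDR3],
                epitope=d.get("antigen.epitope", ""),
                antigen_species=d[VDJDB_SPECIES],
                v_call=d.get("v.segm") or None,
                j_call=d.get("j.segm") or None,
            )
        )
    if n_empty:
        logger.warning("%s: dropped %d VDJdb rows with empty CDR3", path, n_empty)
    return records
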