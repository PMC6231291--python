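"""One-command cohort analysis.

Ties the stages together for a manifest of samples: per-sample rarefaction
and minimum representative depth, cohort common-depth optimization,
rarefaction of every qualifying sample to the common depth, diversity
summaries at that depth, virtual spectratype classification, optional VDJdb
annotation, and per-patient clonotype trajectories.  Products are tidy TSV
tables (group-level hypothesis testing is deliberately left to external
statistics tools) plus a run log recording the seed, thresholds and package
version.  Output bytes are reproducible under the master seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .depth import (
    RarefactionConfig,
    cohort_common_depth,
    minimum_representative_depth,
    rarefaction_curve,
    subsample_reads,
)
from .diversity import diversity_summary
from .dynamics import annotate_vdjdb, track_clonotypes
from .io import RepertoireSample, read_clonotype_table, read_vdjdb_table
from .spectratype import SpectratypeThresholds, spectratype_profile

logger = logging.getLogger(__name__)

__all__ = ["SampleSpec", "CohortConfig", "CohortReport", "run_cohort_analysis", "load_config"]

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class SampleSpec:
    path: str
    dialect: str = "airr"
    sample_id: str | None = None
    patient_id: str = ""
    month: float | None = None
    group: str = "patient"
    spectratype_class: str | None = None
    gvhd_grade: int | None = None


@dataclass
class CohortConfig:
    samples: list[SampleSpec]
    output_dir: str
    rarefaction: RarefactionConfig = field(default_factory=RarefactionConfig)
    spectratype_thresholds: SpectratypeThresholds = field(default_factory=SpectratypeThresholds)
    vdjdb_path: str | None = None
    match_policy: str = "cdr3_aa+v"
    top_n: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.sample_id or Path(s.path).stem for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique across the manifest")


@dataclass
class CohortReport:
    diversity: pd.DataFrame
    mindepth: pd.DataFrame
    cohort_depth: pd.DataFrame
    spectratype: pd.DataFrame
    trajectories: pd.DataFrame
    annotation: pd.DataFrame
    failures: dict[str, str]
    output_dir: Path


def load_config(path: str | Path) -> CohortConfig:
    """Read a cohort config from a YAML file (paths relative to the file)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def resolve(p):
        return str((base / p).resolve()) if p and not Path(p).is_absolute() else p

    samples = [
        SampleSpec(**{**s, "path": resolve(s["path"])}) for s in raw["samples"]
    ]
    rar = RarefactionConfig(**raw.get("rarefaction", {}))
    thresholds = SpectratypeThresholds(**raw.get("spectratype_thresholds", {}))
    return CohortConfig(
        samples=samples,
        output_dir=resolve(raw["output_dir"]),
        rarefaction=rar,
        spectratype_thresholds=thresholds,
        vdjdb_path=resolve(raw.get("vdjdb_path")),
        match_policy=raw.get("match_policy", "cdr3_aa+v"),
        top_n=raw.get("top_n", 20),
        master_seed=raw.get("master_seed", 0),
    )


def _runs_str(runs) -> str:
    return ";".join(f"{r[0]}-{r[-1]}" for r in runs)


def run_cohort_analysis(config: CohortConfig) -> CohortReport:
    """Run the full cohort pass and write one TSV per product.

    Samples that fail a stage (unreadable table, degenerate rarefaction
    curve, fewer reads than the cohort depth) are recorded and skipped; the
    remaining samples are analyzed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    failures: dict[str, str] = {}

    samples: dict[str, RepertoireSample] = {}
    for spec in config.samples:
        sid = spec.sample_id or Path(spec.path).stem
        try:
            samples[sid] = read_clonotype_table(
                spec.path,
                dialect=spec.dialect,
                sample_id=sid,
                patient_id=spec.patient_id,
                month_post_tx=spec.month,
                group=spec.group,
                spectratype_class=spec.spectratype_class,
                gvhd_grade=spec.gvhd_grade,
            )
        except Exception as exc:  # noqa: BLE001 — per-sample isolation
            failures[sid] = f"read: {exc}"
            logger.error("sample %s failed to read: %s", sid, exc)

    # 1-2. per-sample minimum depth, then the cohort common depth
    mindepth_rows, mindepth_results = [], []
    for sid, sample in samples.items():
        try:
            cfg = dataclasses.replace(
                config.rarefaction,
                master_seed=config.master_seed,
            )
            curve = rarefaction_curve(sample, cfg)
            res = minimum_representative_depth(curve, cfg)
            mindepth_results.append(res)
            mindepth_rows.append(
                {
                    "sample_id": sid,
                    "total_reads": res.total_reads,
                    "qualifying_runs": _runs_str(res.runs),
                    "min_percent": res.min_percent,
                    "min_depth_reads": res.min_depth_reads,
                }
            )
        except Exception as exc:  # noqa: BLE001
            failures[sid] = f"mindepth: {exc}"
            logger.error("sample %s failed min-depth: %s", sid, exc)
    mindepth = pd.DataFrame(
        mindepth_rows,
        columns=["sample_id", "total_reads", "qualifying_runs", "min_percent", "min_depth_reads"],
    )

    if not mindepth_results:
        raise RuntimeError("no sample survived the min-depth stage")
    cohort = cohort_common_depth(mindepth_results)
    cohort_depth = pd.DataFrame(
        [
            {
                "common_depth_reads": cohort.common_depth_reads,
                "n_included": len(cohort.included_sample_ids),
                "included": ",".join(cohort.included_sample_ids),
                "excluded": ",".join(cohort.excluded_sample_ids),
            }
        ]
    )

    # 3-4. rarefy to the common depth and summarize diversity there
    diversity_rows = []
    for i, sid in enumerate(sorted(cohort.included_sample_ids)):
        sample = samples[sid]
        rarefied = subsample_reads(
            sample, cohort.common_depth_reads, seed=config.master_seed + 1_000_003 * (i + 1)
        )
        summ = diversity_summary(rarefied, top_k=[config.top_n])
        diversity_rows.append(
            {
                "sample_id": sid,
                "patient_id": sample.patient_id,
                "month_post_tx": sample.month_post_tx,
                "group": sample.group,
                "depth_reads": cohort.common_depth_reads,
                "gini": summ.gini,
                "shannon_bits": summ.shannon_bits,
                "richness": summ.richness,
                f"top{config.top_n}_fraction": summ.top_k_fraction[config.top_n],
            }
        )
    diversity = pd.DataFrame(diversity_rows)

    # 5. virtual spectratypes on the full-depth tables
    spect_rows = []
    for sid, sample in samples.items():
        if sid in failures:
            continue
        profile = spectratype_profile(sample, config.spectratype_thresholds)
        spect_rows.append(
            {
                "sample_id": sid,
                "median_peaks": profile.median_peaks,
                "n_families": len(profile.families),
                "n_gaussian_families": profile.n_gaussian_families,
                "gaussian_fraction": profile.gaussian_fraction,
                "classification": profile.classification,
                "reported_class": sample.spectratype_class or "",
            }
        )
    spectratype = pd.DataFrame(spect_rows)

    # 6. optional annotation
    ann_rows = []
    if config.vdjdb_path:
        db = read_vdjdb_table(config.vdjdb_path)
        for sid, sample in samples.items():
            if sid in failures:
                continue
            res = annotate_vdjdb(sample, db, match_policy=config.match_policy)
            for species in sorted(res.binding_potential):
                ann_rows.append(
                    {
                        "sample_id": sid,
                        "antigen_species": species,
                        "binding_potential": res.binding_potential[species],
                        "n_matched_clonotypes": sum(
                            1
                            for hits in res.hits.values()
                            if any(r.antigen_species == species for r, _ in hits)
                        ),
                    }
                )
    annotation = pd.DataFrame(
        ann_rows,
        columns=["sample_id", "antigen_species", "binding_potential", "n_matched_clonotypes"],
    )

    # 7. per-patient trajectories (full-depth frequencies)
    traj_rows = []
    by_patient: dict[str, list[RepertoireSample]] = {}
    for sid, sample in samples.items():
        if sid in failures or sample.month_post_tx is None:
            continue
        by_patient.setdefault(sample.patient_id, []).append(sample)
    for patient in sorted(by_patient):
        series = by_patient[patient]
        if len(series) < 2:
            continue
        for traj in track_clonotypes(series, n=config.top_n):
            v, j, nt = traj.key
            for month in sorted(traj.frequencies):
                traj_rows.append(
                    {
                        "patient_id": patient,
                        "v_call": v,
                        "j_call": j,
                        "cdr3_nt": nt,
                        "month_post_tx": month,
                        "frequency": traj.frequencies[month],
                        "persistent": traj.persistent,
                    }
                )
    trajectories = pd.DataFrame(
        traj_rows,
        columns=["patient_id", "v_call", "j_call", "cdr3_nt", "month_post_tx", "frequency", "persistent"],
    )

    report = CohortReport(
        diversity=diversity,
        mindepth=mindepth,
        cohort_depth=cohort_depth,
        spectratype=spectratype,
        trajectories=trajectories,
        annotation=annotation,
        failures=failures,
        output_dir=outdir,
    )
    _write_report(report, config)
    return report


def _write_report(report: CohortReport, config: CohortConfig) -> None:
    from . import __version__

    tables = {
        "diversity.tsv": report.diversity,
        "mindepth.tsv": report.mindepth,
        "cohort_depth.tsv": report.cohort_depth,
        "spectratype.tsv": report.spectratype,
        "trajectories.tsv": report.trajectories,
        "annotation.tsv": report.annotation,
    }
    for name, df in tables.items():
        df.to_csv(report.output_dir / name, sep="\t", index=False, float_format=_FLOAT_FMT)
    lines = [
        f"tcrrecon {__version__}",
        f"master_seed: {config.master_seed}",
        f"replicates: {config.rarefaction.replicates}",
        f"gradient_threshold: {config.rarefaction.gradient_threshold}",
        f"spectratype_thresholds: {config.spectratype_thresholds}",
        f"match_policy: {config.match_policy}",
        f"n_samples: {len(config.samples)}",
        f"failures: {report.failures or 'none'}",
    ]
    (report.output_dir / "run.log").write_text("\n".join(lines) + "\n")
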