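"""End-to-end orchestration: harmonize -> DE -> meta-analysis -> enrichment.

The pipeline can run on files (a :class:`PipelineConfig` naming matrices,
sample sheets, probe maps and a GMT collection — see ``run_pipeline``) or on
in-memory objects (``run_studies``), which is what the tests, the analysis
scripts and the acceptance script use.  Thresholds default to the study
criteria: per-study DEGs at q <= 0.05; meta-analytic inclusion at
q_meta <= 0.01, >= 2 datasets, HetP > 0.05.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from .enrichment import GeneSetCollection, directional_enrichment, read_gmt
from .exceptions import ConfigError, DataError
from .harmonize import ProbeMap, gene_universe, harmonize_study
from .meta import run_meta
from .studies import CASE, CONTROL, ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = ["StudyPaths", "PipelineConfig", "validate_inputs", "run_pipeline", "run_studies"]


@dataclass
class StudyPaths:
    study_id: str
    platform: str
    matrix: str
    samples: str
    probe_map: str


@dataclass
class PipelineConfig:
    """File paths plus the analysis thresholds (defaults = study criteria)."""

    studies: list[StudyPaths]
    gmt: str
    out_dir: str
    per_study_q: float = 0.05
    meta_q: float = 0.01
    hetp: float = 0.05
    min_studies: int = 2
    collapse_rule: str = "max_mean"
    weight_scheme: str = "sqrt_n"
    universe_policy: str = "annotated"
    fdr_scope: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("per_study_q", "meta_q", "hetp"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name}: must be in (0, 1), got {v}")
        if self.min_studies < 1:
            raise ConfigError(f"min_studies: must be >= 1, got {self.min_studies}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        studies = [StudyPaths(**s) for s in raw.pop("studies")]
        return cls(studies=studies, **raw)

    @classmethod
    def from_fixture_dir(cls, fixture_dir: str | Path, out_dir: str | Path,
                         **overrides) -> "PipelineConfig":
        """Configuration pointing at a ``write_fixture_set`` directory."""
        fdir = Path(fixture_dir)
        manifest = pd.read_csv(fdir / "manifest.tsv", sep="\t")
        mats = manifest[manifest["kind"] == "matrix"]
        studies = []
        for _, row in mats.iterrows():
            sid = row["study_id"]
            sheet = pd.read_csv(fdir / f"{sid}_matrix.tsv", sep="\t", nrows=1)
            # platform by dtype probe: integers = rnaseq
            vals = sheet.iloc[:, 1:].to_numpy()
            platform = "rnaseq" if np.allclose(vals, np.round(vals)) else "array"
            studies.append(
                StudyPaths(
                    study_id=sid,
                    platform=platform,
                    matrix=str(fdir / f"{sid}_matrix.tsv"),
                    samples=str(fdir / f"{sid}_samples.tsv"),
                    probe_map=str(fdir / f"{sid}_probes.tsv"),
                )
            )
        return cls(studies=studies, gmt=str(fdir / "gene_sets.gmt"),
                   out_dir=str(out_dir), **overrides)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Check input files for structural problems without modifying anything.

    Returns a list of failure dicts (``stage``, ``study_id``, ``message``);
    an empty list means the inputs look runnable.  Unreadable files raise.
    """
    failures: list[dict] = []

    def fail(stage: str, study_id: str, message: str) -> None:
        failures.append({"stage": stage, "study_id": study_id, "message": message})

    for sp in config.studies:
        mat = pd.read_csv(sp.matrix, sep="\t", index_col=0)
        sheet = pd.read_csv(sp.samples, sep="\t", dtype=str)
        if not {"sample_id", "group"} <= set(sheet.columns):
            fail("samples", sp.study_id, "sample sheet missing sample_id/group columns")
            continue
        sheet_ids = set(sheet["sample_id"])
        for s in mat.columns:
            if s not in sheet_ids:
                fail("samples", sp.study_id, f"sample {s!r} missing from sample sheet")
        bad_groups = set(sheet["group"]) - {CASE, CONTROL}
        if bad_groups:
            fail("samples", sp.study_id, f"unknown group labels {sorted(bad_groups)}")
        if sp.platform == "rnaseq":
            vals = mat.to_numpy()
            bad = ~np.isclose(vals % 1, 0) | (vals < 0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                fail(
                    "matrix", sp.study_id,
                    f"non-integer count {vals[i, j]} at gene {mat.index[i]!r}, "
                    f"sample {mat.columns[j]!r}",
                )
        pm = pd.read_csv(sp.probe_map, sep="\t", dtype=str, keep_default_na=False)
        if not {"probe_id", "symbol"} <= set(pm.columns):
            fail("probe_map", sp.study_id, "probe map missing probe_id/symbol columns")
        elif not set(mat.index.astype(str)) <= set(pm["probe_id"]):
            n = len(set(mat.index.astype(str)) - set(pm["probe_id"]))
            fail("probe_map", sp.study_id, f"{n} matrix features absent from probe map")

    try:
        read_gmt(config.gmt)
    except Exception as exc:  # surfaced as a structured failure, not a raise
        fail("gmt", "", f"unparseable GMT: {exc}")
    return failures


def run_studies(
    studies: list[ExpressionStudy],
    probe_maps: list[ProbeMap],
    collection: GeneSetCollection,
    per_study_q: float = 0.05,
    meta_q: float = 0.01,
    hetp: float = 0.05,
    min_studies: int = 2,
    collapse_rule: str = "max_mean",
    weight_scheme: str = "sqrt_n",
    universe_policy: str = "annotated",
    fdr_scope: str = "all",
) -> dict:
    """Run harmonize -> DE -> meta -> enrichment on in-memory studies.

    Returns a dict with the harmonized studies, per-study DE tables, the
    meta-analysis record table and summary, the three enrichment tables, and
    a compact run report.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    harmonized = [
        harmonize_study(s, pm, collapse_rule=collapse_rule)
        for s, pm in zip(studies, probe_maps)
    ]
    universe, study_counts = gene_universe(harmonized)
    timings["harmonize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    de_tables = [de_mod.run_de(s) for s in harmonized]
    per_study_degs = {
        t["study_id"].iloc[0]: int((t["q"] <= per_study_q).sum()) for t in de_tables
    }
    timings["de"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    records, summary = run_meta(
        de_tables,
        q_threshold=meta_q,
        min_studies=min_studies,
        hetp_threshold=hetp,
        weight_scheme=weight_scheme,
        fdr_scope=fdr_scope,
    )
    timings["meta"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    enrich = directional_enrichment(records, collection, universe_policy=universe_policy)
    timings["enrichment"] = time.perf_counter() - t0

    report = {
        "genes_entered": summary["genes_entered"],
        "universe_size": len(universe),
        "per_study_degs": per_study_degs,
        "included": summary["included"],
        "up": summary["up"],
        "down": summary["down"],
        "excluded_q": summary["excluded_q"],
        "excluded_min_studies": summary["excluded_min_studies"],
        "excluded_heterogeneity": summary["excluded_heterogeneity"],
        "top_sets_all": enrich["all"].head(5)[["set", "p"]].to_dict("records"),
        "top_sets_up": enrich["up"].head(5)[["set", "p"]].to_dict("records"),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    return {
        "harmonized": harmonized,
        "universe": universe,
        "study_counts": study_counts,
        "de_tables": de_tables,
        "meta_records": records,
        "meta_summary": summary,
        "enrichment": enrich,
        "report": report,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline run; writes tables and a report under ``out_dir``.

    Outputs: ``de_<study>.tsv`` per study, ``meta_table.tsv``,
    ``enrichment_{all,up,down}.tsv``, ``report.json`` and ``manifest.tsv``.
    Deterministic given the same inputs and configuration.
    """
    failures = validate_inputs(config)
    if failures:
        f = failures[0]
        raise DataError(
            f"validation failed at stage {f['stage']!r} "
            f"(study {f['study_id']!r}): {f['message']} "
            f"({len(failures)} failure(s) total)"
        )

    studies, probe_maps = [], []
    for sp in config.studies:
        studies.append(
            ExpressionStudy.from_tsv(sp.study_id, sp.platform, sp.matrix, sp.samples)
        )
        probe_maps.append(ProbeMap.from_tsv(sp.probe_map))
    collection = read_gmt(config.gmt)

    result = run_studies(
        studies,
        probe_maps,
        collection,
        per_study_q=config.per_study_q,
        meta_q=config.meta_q,
        hetp=config.hetp,
        min_studies=config.min_studies,
        collapse_rule=config.collapse_rule,
        weight_scheme=config.weight_scheme,
        universe_policy=config.universe_policy,
        fdr_scope=config.fdr_scope,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []

    def write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
        manifest_rows.append({"file": name, "n_rows": len(df), "n_cols": df.shape[1]})

    for table in result["de_tables"]:
        write(table, f"de_{table['study_id'].iloc[0]}.tsv")
    write(result["meta_records"], "meta_table.tsv")
    for key, table in result["enrichment"].items():
        write(table, f"enrichment_{key}.tsv")

    report = dict(result["report"])
    report["config_hash"] = config.config_hash()
    report["seed"] = config.seed
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    manifest_rows.append({"file": "report.json", "n_rows": 1, "n_cols": 0})
    pd.DataFrame(manifest_rows).to_csv(
        out / "manifest.tsv", sep="\t", index=False, lineterminator="\n"
    )
    logger.info("pipeline finished: %s", json.dumps(report["timings_s"]))
    result["report"] = report
    return result
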