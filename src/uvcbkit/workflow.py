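"""Single-config orchestration of the full assessment workflow.

Stages: enumerate -> profile -> match/read-across -> prediction ingest ->
composition -> assessment.  Stages whose inputs are absent are skipped and
logged, never silently.  Every run writes a manifest with package/constants
versions and artifact hashes, so identical configs are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .design_registry import LibraryDesign, load_design, paper_fixture
from .enumerator import enumerate_library, write_csv, write_sdf, write_smiles
from .errors import ConfigurationError, UvcbError
from .predictions import EndpointSpec, PredictionSchema, pod_log_summary, read_prediction_table
from .profiler import match_skeletons, plot_mw_histogram, profile_library, summarize_mw
from .readacross import ReadAcrossInput, genra_predict, bin_pod, load_analog_table
from .risk_assessment import (
    PodType,
    ToxStudy,
    UncertaintyFactors,
    assess_metal_naphthenate,
)
from .salt_composition import (
    KOH_MOLAR_MASS,
    AcidNumberRange,
    composition_range,
    load_metal_registry,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_workflow"]


class PredictionTableConfig(BaseModel):
    path: str
    key_column: str = "skeleton_key"
    source_model: str = ""
    endpoints: dict[str, dict]  # column -> {name, units, scale}


class StudyConfig(BaseModel):
    pod: float
    pod_type: str = "NOAEL"
    substance: str = ""
    citation: str = ""


class AssessmentConfig(BaseModel):
    metal: str
    acid_number: tuple[float, float] = (225.0, 270.0)
    study: StudyConfig | None = None
    ufs: dict[str, float] = Field(default_factory=lambda: {"interspecies": 10, "intrahuman": 10})
    whole_dose: float | None = None
    naphthenate_reference: float | None = 0.25


class RunConfig(BaseModel):
    design: str = "paper"  # path to a design file, or "paper" for the fixture
    output_dir: str = "uvcb_run"
    formats: list[str] = Field(default_factory=lambda: ["csv", "smi"])
    registry_table: str | None = None
    analog_table: str | None = None
    readacross_endpoint: str = "chronic_pod"
    readacross_k: int = 6
    prediction_tables: list[PredictionTableConfig] = Field(default_factory=list)
    assessments: list[AssessmentConfig] = Field(default_factory=list)
    metal_registry: str | None = None
    seed: int = 0
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config root must be a mapping")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config_design(config: RunConfig) -> LibraryDesign:
    if config.design == "paper":
        return paper_fixture()
    return load_design(config.design)


def run_workflow(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run manifest (also written
    to ``<output_dir>/run_manifest.json``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.model_dump(),
        "constants": {"koh_molar_mass": KOH_MOLAR_MASS},
        "stages": {},
        "artifacts": {},
    }

    def record(stage: str, status: str, t0: float | None = None, **extra):
        entry = {"status": status, **extra}
        if t0 is not None:
            entry["seconds"] = round(time.time() - t0, 3)
        manifest["stages"][stage] = entry
        logger.info("stage %s: %s %s", stage, status, extra or "")

    failed = False
    library = None
    profiles = None

    # -- stage 1: enumerate ------------------------------------------------
    t0 = time.time()
    try:
        design = _load_config_design(config)
        result = enumerate_library(design)
        library = result.structures
        if "smi" in config.formats:
            write_smiles(library, out / "library.smi")
        if "csv" in config.formats:
            write_csv(library, out / "library.csv")
        if "sdf" in config.formats:
            write_sdf(library, out / "library.sdf")
        record(
            "enumerate",
            "ok",
            t0,
            n_unique=len(library),
            n_products=result.n_products,
            n_failures=len(result.failures),
        )
    except UvcbError as exc:
        record("enumerate", "failed", t0, error=str(exc))
        failed = True

    # -- stage 2: profile --------------------------------------------------
    if library is not None:
        t0 = time.time()
        profiles = profile_library(library)
        profiles.to_csv(out / "profiles.csv", index=False)
        summary = summarize_mw(profiles["mol_weight"])
        (out / "mw_summary.json").write_text(
            json.dumps(
                {
                    "n": summary.n,
                    "interval": list(summary.interval),
                    "coverage": summary.coverage,
                    "min_mw": float(profiles["mol_weight"].min()),
                    "max_mw": float(profiles["mol_weight"].max()),
                    "min_cyclization": float(profiles["cyclization_degree"].min()),
                    "max_cyclization": float(profiles["cyclization_degree"].max()),
                },
                indent=2,
            )
        )
        if config.plots:
            plot_mw_histogram(summary, out / "mw_histogram.png")
        record("profile", "ok", t0, n=len(profiles))
    else:
        record("profile", "skipped", reason="no library")

    # -- stage 3: skeleton match + read-across -----------------------------
    if config.registry_table and profiles is not None:
        t0 = time.time()
        registry = pd.read_csv(config.registry_table)
        matched = match_skeletons(profiles["skeleton_key"], registry)
        matched.to_csv(out / "matched.csv", index=False)
        record("match", "ok", t0, n_matched=len(matched))
        targets = matched
    else:
        record("match", "skipped", reason="no registry table")
        targets = None

    if config.analog_table and targets is not None and "structure" in targets.columns:
        t0 = time.time()
        analogs = load_analog_table(config.analog_table)
        rows = []
        for structure in targets["structure"]:
            try:
                pred = genra_predict(
                    ReadAcrossInput(target=structure, analogs=analogs, k=config.readacross_k),
                    config.readacross_endpoint,
                )
                label, clamped = bin_pod(pred.value)
                rows.append(
                    {
                        "structure": structure,
                        "endpoint": pred.endpoint,
                        "predicted": pred.value,
                        "bin": label,
                        "clamped": clamped,
                        "n_analogs": len(pred.used),
                    }
                )
            except UvcbError as exc:
                rows.append({"structure": structure, "error": str(exc)})
        pd.DataFrame(rows).to_csv(out / "readacross.csv", index=False)
        record("readacross", "ok", t0, n_targets=len(rows))
    else:
        record("readacross", "skipped", reason="no analog table or no matched targets")

    # -- stage 4: prediction ingest ----------------------------------------
    if config.prediction_tables:
        t0 = time.time()
        summaries = {}
        for tbl in config.prediction_tables:
            schema = PredictionSchema(
                key_column=tbl.key_column,
                endpoints={
                    col: EndpointSpec(**spec) for col, spec in tbl.endpoints.items()
                },
            )
            records, dropped = read_prediction_table(
                tbl.path, schema, source_model=tbl.source_model
            )
            by_endpoint: dict[str, list] = {}
            for r in records:
                by_endpoint.setdefault(r.endpoint, []).append(r)
            for name, recs in by_endpoint.items():
                s = pod_log_summary(recs)
                summaries[name] = {
                    "n": s.n,
                    "log_min": s.log_min,
                    "log_max": s.log_max,
                    "antilog_min": s.antilog_min_reported,
                    "antilog_max": s.antilog_max_reported,
                    "dropped": dropped,
                }
        (out / "prediction_summaries.json").write_text(json.dumps(summaries, indent=2))
        record("predictions", "ok", t0, n_endpoints=len(summaries))
    else:
        record("predictions", "skipped", reason="no prediction tables")

    # -- stages 5+6: composition and assessment ----------------------------
    if config.assessments:
        t0 = time.time()
        registry = load_metal_registry(config.metal_registry)
        reports = []
        for a in config.assessments:
            if a.metal not in registry:
                raise ConfigurationError(f"metal {a.metal!r} not in registry")
            metal = registry[a.metal]
            comp = composition_range(AcidNumberRange(*a.acid_number), metal)
            study = None
            if a.study is not None:
                study = ToxStudy(
                    substance=a.study.substance or f"{a.metal} naphthenate",
                    pod_type=PodType(a.study.pod_type),
                    pod=a.study.pod,
                    citation=a.study.citation,
                )
            ufs = UncertaintyFactors(
                interspecies=a.ufs.get("interspecies", 10),
                intrahuman=a.ufs.get("intrahuman", 10),
                other={
                    k: v
                    for k, v in a.ufs.items()
                    if k not in ("interspecies", "intrahuman")
                },
            )
            result = assess_metal_naphthenate(
                metal,
                comp,
                study=study,
                ufs=ufs,
                whole_dose=a.whole_dose,
                naphthenate_reference=a.naphthenate_reference,
            )
            reports.append(result.to_dict())
        (out / "assessment.json").write_text(json.dumps(reports, indent=2, default=str))
        pd.DataFrame(reports).to_csv(out / "assessment.csv", index=False)
        record("assess", "ok", t0, n=len(reports))
    else:
        record("assess", "skipped", reason="no assessments configured")

    # -- manifest ----------------------------------------------------------
    for p in sorted(out.iterdir()):
        if p.name != "run_manifest.json" and p.is_file():
            manifest["artifacts"][p.name] = _sha256(p)
    manifest["status"] = "FAILED" if failed else "ok"
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if failed:
        (out / "FAILED").write_text("one or more stages failed; see run_manifest.json\n")
    return manifest
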