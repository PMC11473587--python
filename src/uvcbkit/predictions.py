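"""Ingestion and post-processing of external QSAR prediction tables.

External predictors (acute-toxicity consensus models, physicochemical and
ADME suites, repeat-dose POD models) are never executed here; their CSV
exports are parsed into typed records and post-processed: acute oral LD50
values are mapped to EPA and GHS hazard categories, and log10-POD endpoint
collections are summarized as dual log/antilog ranges with density bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignSchemaError
from .rounding import round_sig

logger = logging.getLogger(__name__)

__all__ = [
    "EndpointSpec",
    "PredictionSchema",
    "PredictionRecord",
    "read_prediction_table",
    "epa_category",
    "ghs_category",
    "GHS_UNCLASSIFIED",
    "pod_log_summary",
    "PodSummary",
    "mock_prediction_table",
]

Scale = Literal["arithmetic", "log10"]


@dataclass(frozen=True)
class EndpointSpec:
    """Declares an endpoint column: canonical name, units, and value scale."""

    name: str
    units: str
    scale: Scale = "arithmetic"


@dataclass(frozen=True)
class PredictionSchema:
    """Column mapping for a prediction CSV export."""

    key_column: str
    endpoints: dict  # column name -> EndpointSpec

    def __post_init__(self):
        if not self.endpoints:
            raise ConfigurationError("schema must map at least one endpoint column")


@dataclass(frozen=True)
class PredictionRecord:
    skeleton_key: str
    endpoint: str
    units: str
    scale: Scale
    value: float
    source_model: str = ""


def read_prediction_table(
    path: str | Path,
    schema: PredictionSchema,
    source_model: str = "",
) -> tuple[list[PredictionRecord], int]:
    """Parse a prediction CSV into one record per (row, endpoint).

    Rows with unparseable or missing endpoint values are dropped per
    endpoint with a logged count.  Returns ``(records, n_dropped)``.
    """
    df = pd.read_csv(path)
    if schema.key_column not in df.columns:
        raise DesignSchemaError(
            f"prediction table lacks key column {schema.key_column!r}"
        )
    for col in schema.endpoints:
        if col not in df.columns:
            raise DesignSchemaError(f"prediction table lacks endpoint column {col!r}")
    records: list[PredictionRecord] = []
    dropped = 0
    for _, row in df.iterrows():
        key = str(row[schema.key_column])
        for col, spec in schema.endpoints.items():
            raw = row[col]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                value = float("nan")
            if not np.isfinite(value):
                dropped += 1
                continue
            records.append(
                PredictionRecord(
                    skeleton_key=key,
                    endpoint=spec.name,
                    units=spec.units,
                    scale=spec.scale,
                    value=value,
                    source_model=source_model,
                )
            )
    if dropped:
        logger.info("dropped %d unparseable prediction cells", dropped)
    return records, dropped


# ---------------------------------------------------------------------------
# acute oral hazard categories
#
# Band conventions are upper-inclusive: an LD50 exactly on a threshold falls
# in the more hazardous band (e.g. 2000 mg/kg is GHS category 4, and the
# GHS-5 band is the half-open interval (2000, 5000]).

GHS_UNCLASSIFIED = "unclassified"

_EPA_BANDS = [(50.0, 1), (500.0, 2), (5000.0, 3)]
_GHS_BANDS = [(5.0, 1), (50.0, 2), (300.0, 3), (2000.0, 4), (5000.0, 5)]


def epa_category(ld50: float) -> int:
    """EPA acute oral hazard category 1-4 from a rat oral LD50 (mg/kg)."""
    if ld50 <= 0:
        raise ValueError(f"LD50 must be positive, got {ld50}")
    for ceiling, cat in _EPA_BANDS:
        if ld50 <= ceiling:
            return cat
    return 4


def ghs_category(ld50: float) -> int | str:
    """GHS acute oral category 1-5, or ``"unclassified"`` above 5000 mg/kg."""
    if ld50 <= 0:
        raise ValueError(f"LD50 must be positive, got {ld50}")
    for ceiling, cat in _GHS_BANDS:
        if ld50 <= ceiling:
            return cat
    return GHS_UNCLASSIFIED


# ---------------------------------------------------------------------------
# POD summaries

@dataclass(frozen=True)
class PodSummary:
    endpoint: str
    n: int
    log_min: float
    log_max: float
    antilog_min: float
    antilog_max: float
    antilog_min_reported: float  # rounded to 2 significant figures
    antilog_max_reported: float
    bin_edges: np.ndarray = field(repr=False, default=None)
    counts: np.ndarray = field(repr=False, default=None)


def pod_log_summary(
    records: Sequence[PredictionRecord],
    n_bins: int = 20,
    report_sig: int = 2,
) -> PodSummary:
    """Dual log/antilog range summary with density bins for one endpoint.

    All records must belong to a single endpoint on a single declared
    scale; values on the arithmetic scale are log10-transformed first.
    """
    if not records:
        raise ValueError("no records to summarize")
    endpoints = {r.endpoint for r in records}
    if len(endpoints) > 1:
        raise ConfigurationError(f"records mix endpoints: {sorted(endpoints)}")
    scales = {r.scale for r in records}
    if len(scales) > 1:
        raise ConfigurationError(
            f"records mix scales for endpoint {records[0].endpoint!r}: {sorted(scales)}"
        )
    scale = records[0].scale
    values = np.array([r.value for r in records], dtype=float)
    logs = values if scale == "log10" else np.log10(values)
    lo, hi = float(logs.min()), float(logs.max())
    edges = np.linspace(lo, hi, n_bins + 1) if hi > lo else np.array([lo - 0.05, lo + 0.05])
    counts, edges = np.histogram(logs, bins=edges)
    return PodSummary(
        endpoint=records[0].endpoint,
        n=len(records),
        log_min=lo,
        log_max=hi,
        antilog_min=10 ** lo,
        antilog_max=10 ** hi,
        antilog_min_reported=round_sig(10 ** lo, report_sig),
        antilog_max_reported=round_sig(10 ** hi, report_sig),
        bin_edges=edges,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# fixture generation

def mock_prediction_table(
    keys: Sequence[str],
    path: str | Path,
    seed: int = 0,
    ld50_range: tuple[float, float] = (2000.0, 9011.0),
    dev_pod_log_range: tuple[float, float] = (1.90, 1.98),
    chronic_pod_log_range: tuple[float, float] = (1.4, 1.7),
) -> pd.DataFrame:
    """Write a synthetic prediction CSV covering the standard endpoints.

    Values are drawn uniformly inside the configured ranges with the range
    endpoints always included, so summaries of the mock table reproduce the
    configured bounds exactly.
    """
    rng = np.random.default_rng(seed)
    n = len(keys)
    if n == 0:
        raise ValueError("need at least one key")

    def spanning(low, high, log=False):
        if n == 1:
            return np.array([low])
        if log:
            vals = 10 ** rng.uniform(np.log10(low), np.log10(high), size=n)
        else:
            vals = rng.uniform(low, high, size=n)
        vals[0], vals[-1] = low, high
        return vals

    df = pd.DataFrame(
        {
            "skeleton_key": list(keys),
            "rat_oral_ld50": spanning(*ld50_range, log=True),
            "rat_developmental_pod_log10": spanning(*dev_pod_log_range),
            "rat_chronic_pod_log10": spanning(*chronic_pod_log_range),
        }
    )
    df.to_csv(path, index=False)
    return df
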