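"""Data model, CSV readers/writers and validation shared by all pipeline stages.

All isotope values are stored in per-mil on the conventional reference scales
(V-PDB for δ13C, AIR for δ15N, VSMOW for δ2H); no internal rescaling is ever
applied.  Missing tracer values are explicit ``None``/NaN, never zero: the rule
that specimens lacking a tracer are dropped is applied at fit time so that
screening reports can still count them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

COMMUNITIES = ("fish", "aquatic_invertebrate", "terrestrial_invertebrate")
FEEDING_GROUPS = ("herbivore", "omnivore", "invertebrate_feeder", "piscivore", "unknown")
TROPHIC_CLASSES = ("primary", "secondary", "tertiary", "unknown")

#: physically plausible per-mil ranges used by validation
TRACER_RANGES = {"d13C": (-80.0, 0.0), "d15N": (-10.0, 30.0), "d2H": (-350.0, 100.0)}

DEFAULT_SCHEMA = {
    "sample_id": "sample_id",
    "d13C": "d13C",
    "d15N": "d15N",
    "d2H": "d2H",
    "community": "community",
    "feeding_group": "feeding_group",
    "trophic_class": "trophic_class",
    "standard_length_mm": "standard_length_mm",
}


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class DataError(ValueError):
    """Input rows violate a structural invariant (e.g. duplicate ids)."""


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


@dataclass(frozen=True)
class ConsumerSample:
    """One specimen's tracer values plus group/guild/trophic metadata."""

    sample_id: str
    d13C: float | None
    d15N: float | None
    d2H: float | None = None
    community: str = "fish"
    feeding_group: str = "unknown"
    trophic_class: str = "unknown"
    standard_length_mm: float | None = None

    def tracer(self, name: str) -> float | None:
        return getattr(self, name)

    def has(self, tracers: Iterable[str]) -> bool:
        return all(self.tracer(t) is not None for t in tracers)


@dataclass(frozen=True)
class SourceDistribution:
    """Per-tracer mean/SD for one end-member, with its discrimination factor.

    ``tdf_means``/``tdf_sds`` hold the trophic discrimination factor (λ) applied
    once at consumer level; tracers absent from the maps get λ = 0 ± 0.
    """

    name: str
    tracer_means: Mapping[str, float]
    tracer_sds: Mapping[str, float]
    tdf_means: Mapping[str, float] = field(default_factory=dict)
    tdf_sds: Mapping[str, float] = field(default_factory=dict)

    def mean(self, tracer: str) -> float:
        return float(self.tracer_means[tracer])

    def sd(self, tracer: str) -> float:
        return float(self.tracer_sds[tracer])

    def tdf_mean(self, tracer: str) -> float:
        return float(self.tdf_means.get(tracer, 0.0))

    def tdf_sd(self, tracer: str) -> float:
        return float(self.tdf_sds.get(tracer, 0.0))

    def validate_for_fit(self, tracers: Sequence[str]) -> None:
        for t in tracers:
            if t not in self.tracer_means or t not in self.tracer_sds:
                raise SchemaError(f"source {self.name!r} lacks mean/SD for tracer {t!r}")
            if self.sd(t) <= 0:
                raise DataError(
                    f"source {self.name!r} has non-positive SD for {t!r}; "
                    "fits propagate source variance and require SD > 0"
                )


@dataclass(frozen=True)
class WaterIsotope:
    """Environmental-water hydrogen isotope summary (per-mil vs VSMOW)."""

    d2H_mean: float = 0.0
    d2H_sd: float = 4.2

    def __post_init__(self) -> None:
        if not (-200.0 <= self.d2H_mean <= 100.0):
            raise DataError(f"water δ2H mean {self.d2H_mean} outside [-200, 100]‰")
        if self.d2H_sd < 0:
            raise DataError("water δ2H SD must be ≥ 0")


@dataclass
class AnalysisTable:
    """Consumers + sources + water, with a free-text provenance log.

    Stages never mutate a table in place; they return a copy with an appended
    provenance entry (:meth:`with_provenance`).
    """

    consumers: list[ConsumerSample]
    sources: list[SourceDistribution] = field(default_factory=list)
    water: WaterIsotope | None = None
    provenance: list[str] = field(default_factory=list)

    def with_provenance(self, entry: str, consumers: list[ConsumerSample] | None = None) -> "AnalysisTable":
        return AnalysisTable(
            consumers=list(self.consumers if consumers is None else consumers),
            sources=list(self.sources),
            water=self.water,
            provenance=[*self.provenance, entry],
        )

    def flag_missing(self, tracers: Sequence[str]) -> list[str]:
        """sample_ids lacking any of ``tracers`` (flagged, never dropped here)."""
        return [c.sample_id for c in self.consumers if not c.has(tracers)]


# ---------------------------------------------------------------------------
# consumer CSV I/O
# ---------------------------------------------------------------------------

def read_consumers(path, schema: Mapping[str, str] | None = None
                   ) -> tuple[list[ConsumerSample], list[str]]:
    """Read a consumer table from CSV.

    Parameters
    ----------
    path : file path
        CSV with a header row.  Required columns (after schema mapping):
        ``sample_id``, ``d13C``, ``d15N``.  ``d2H`` and metadata are optional.
    schema : mapping, optional
        canonical-name → column-name map absorbing foreign column layouts.

    Returns
    -------
    (samples, report) where *report* lists missing-tracer flags and
    out-of-range values; blank/NA cells become missing, never zero.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    for canon in ("sample_id", "d13C", "d15N"):
        if schema[canon] not in df.columns:
            raise SchemaError(f"required column {schema[canon]!r} (for {canon!r}) not found")

    report: list[str] = []
    samples: list[ConsumerSample] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row[schema["sample_id"]])
        if sid in seen:
            raise DataError(f"duplicate sample_id {sid!r}")
        seen.add(sid)

        vals: dict[str, float | None] = {}
        for tracer in ("d13C", "d15N", "d2H"):
            col = schema[tracer]
            raw = row[col] if col in df.columns else None
            if _is_missing(raw):
                vals[tracer] = None
                report.append(f"{sid}: missing {tracer}")
            else:
                v = float(raw)
                lo, hi = TRACER_RANGES[tracer]
                if not (lo <= v <= hi):
                    report.append(f"{sid}: {tracer}={v} outside [{lo}, {hi}]‰")
                vals[tracer] = v

        def _meta(canon: str, default: str) -> str:
            col = schema[canon]
            raw = row[col] if col in df.columns else None
            return default if _is_missing(raw) else str(raw)

        length_col = schema["standard_length_mm"]
        raw_len = row[length_col] if length_col in df.columns else None
        samples.append(ConsumerSample(
            sample_id=sid,
            d13C=vals["d13C"],
            d15N=vals["d15N"],
            d2H=vals["d2H"],
            community=_meta("community", "fish"),
            feeding_group=_meta("feeding_group", "unknown"),
            trophic_class=_meta("trophic_class", "unknown"),
            standard_length_mm=None if _is_missing(raw_len) else float(raw_len),
        ))
    return samples, report


def write_consumers(samples: Sequence[ConsumerSample], path) -> None:
    pd.DataFrame([{
        "sample_id": c.sample_id, "d13C": c.d13C, "d15N": c.d15N, "d2H": c.d2H,
        "community": c.community, "feeding_group": c.feeding_group,
        "trophic_class": c.trophic_class, "standard_length_mm": c.standard_length_mm,
    } for c in samples]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# source CSV I/O (long format: name, tracer, mean, sd, tdf_mean, tdf_sd)
# ---------------------------------------------------------------------------

def write_sources(sources: Sequence[SourceDistribution], path) -> None:
    rows = []
    for s in sources:
        for t in s.tracer_means:
            rows.append({"name": s.name, "tracer": t, "mean": s.mean(t), "sd": s.sd(t),
                         "tdf_mean": s.tdf_mean(t), "tdf_sd": s.tdf_sd(t)})
    pd.DataFrame(rows, columns=["name", "tracer", "mean", "sd", "tdf_mean", "tdf_sd"]
                 ).to_csv(path, index=False)


def read_sources(path) -> list[SourceDistribution]:
    df = pd.read_csv(path)
    for col in ("name", "tracer", "mean", "sd"):
        if col not in df.columns:
            raise SchemaError(f"source table lacks column {col!r}")
    out = []
    for name, grp in df.groupby("name", sort=False):
        out.append(SourceDistribution(
            name=str(name),
            tracer_means={r.tracer: float(r.mean) for r in grp.itertuples()},
            tracer_sds={r.tracer: float(r.sd) for r in grp.itertuples()},
            tdf_means={r.tracer: float(getattr(r, "tdf_mean", 0.0) or 0.0) for r in grp.itertuples()},
            tdf_sds={r.tracer: float(getattr(r, "tdf_sd", 0.0) or 0.0) for r in grp.itertuples()},
        ))
    return out


# ---------------------------------------------------------------------------
# posterior-summary CSV I/O (Table-1-shaped: one row per group × source)
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ["group", "source", "median", "sd", "ci2.5", "ci97.5", "rhat", "ess"]


def write_summary(summary: pd.DataFrame, path) -> None:
    """Write a posterior summary (one row per group × source) to CSV.

    The layout mirrors the conventional mixing-model contributions table:
    median, SD and 2.5/97.5% credible-interval bounds per proportion, plus
    the Gelman–Rubin R-hat and effective sample size.
    """
    if summary.empty:
        pd.DataFrame(columns=SUMMARY_COLUMNS).to_csv(path, index=False)
        return
    summary.loc[:, SUMMARY_COLUMNS].round(4).to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"summary table lacks columns {missing}")
    return df
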