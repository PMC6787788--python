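"""Trophic water-compounding correction for consumer δ2H.

A consumer's tissue hydrogen is a mixture of dietary hydrogen and
environmental water, and the water fraction compounds at every trophic step.
With a per-step water contribution ω and τ trophic steps above the primary
source, the measured value relates to the source-scale value via

    δ2H_consumer = ω_compound · δ2H_water + (1 − ω_compound) · δ2H_source
    ω_compound  = 1 − (1 − ω)^τ

Trophic position is estimated from δ15N against a primary-producer baseline
(+5.6‰ here) with a per-step enrichment of 3.4‰; τ = TP − 1.  The correction
inverts the first equation, mapping measured consumer δ2H back to the
primary-source scale so that mixing models compare consumers to producers in
a common frame.  ω is assigned by community: 0.28 for fish, 0.40 for
invertebrates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .io import ConsumerSample, WaterIsotope

#: per-step fraction of tissue H from environmental water, by community
OMEGA_BY_COMMUNITY = {
    "fish": 0.28,
    "aquatic_invertebrate": 0.40,
    "terrestrial_invertebrate": 0.40,
}

D15N_BASELINE = 5.6      # per-mil, primary-producer δ15N
D15N_STEP = 3.4          # per-mil trophic enrichment per step


@dataclass(frozen=True)
class TrophicParams:
    """Parameters of the trophic-position and water-compounding model."""

    omega: float = OMEGA_BY_COMMUNITY["fish"]
    d15N_baseline: float = D15N_BASELINE
    delta15N_step: float = D15N_STEP
    water: WaterIsotope = field(default_factory=WaterIsotope)

    def __post_init__(self) -> None:
        if not (0.0 < self.omega < 1.0):
            raise ValueError(f"omega must lie in (0, 1), got {self.omega}")
        if self.delta15N_step <= 0:
            raise ValueError("delta15N_step must be positive")

    @classmethod
    def for_community(cls, community: str, water: WaterIsotope | None = None,
                      **kwargs) -> "TrophicParams":
        omega = kwargs.pop("omega", OMEGA_BY_COMMUNITY.get(community, OMEGA_BY_COMMUNITY["fish"]))
        return cls(omega=omega, water=water or WaterIsotope(), **kwargs)


def trophic_position(d15N_consumer: float, params: TrophicParams) -> float:
    """TP = 1 + (δ15N_consumer − baseline) / step, clamped to ≥ 1.

    Values below 1 (consumer apparently lighter than the baseline) are
    physically meaningless for compounding and are clamped with a warning.
    """
    tp = 1.0 + (d15N_consumer - params.d15N_baseline) / params.delta15N_step
    if tp < 1.0:
        warnings.warn(
            f"δ15N={d15N_consumer}‰ below baseline {params.d15N_baseline}‰; "
            "trophic position clamped to 1", stacklevel=2)
        tp = 1.0
    return tp


def omega_compound(omega: float, tau: float) -> float:
    """Cumulative water contribution over τ trophic steps: 1 − (1 − ω)^τ."""
    if tau < 0:
        raise ValueError(f"tau must be ≥ 0, got {tau}")
    return 1.0 - (1.0 - omega) ** tau


def forward_d2H(d2H_source: float, omega_c: float, d2H_water: float) -> float:
    """Forward compounding model: measured consumer δ2H from source-scale δ2H."""
    return omega_c * d2H_water + (1.0 - omega_c) * d2H_source


def correct_d2H_to_source(sample: ConsumerSample, params: TrophicParams) -> float:
    """Invert the compounding equation: source-scale δ2H from a measurement.

    Requires the specimen's d2H and d15N; τ is computed from the specimen's
    own δ15N.  Raises on ω_compound ≥ 0.99 (correction numerically undefined).
    """
    if sample.d2H is None or sample.d15N is None:
        raise ValueError(f"{sample.sample_id}: d2H and d15N required for the correction")
    tau = trophic_position(sample.d15N, params) - 1.0
    om_c = omega_compound(params.omega, tau)
    if om_c >= 0.99:
        raise ValueError(f"{sample.sample_id}: ω_compound={om_c:.3f} ≥ 0.99; correction undefined")
    return (sample.d2H - om_c * params.water.d2H_mean) / (1.0 - om_c)


def correct_table(samples, water: WaterIsotope | None = None,
                  omega_by_community: dict[str, float] | None = None,
                  per_group_tau: bool = False) -> pd.DataFrame:
    """Apply the correction to a list of consumers.

    Returns a DataFrame with columns sample_id, TP, tau, omega_compound and
    d2H_source (NaN where d2H or d15N is missing — flagged, not dropped).
    ``per_group_tau`` replaces each specimen's τ with its community's mean τ.
    """
    water = water or WaterIsotope()
    omegas = {**OMEGA_BY_COMMUNITY, **(omega_by_community or {})}
    rows = []
    for c in samples:
        params = TrophicParams(omega=omegas.get(c.community, OMEGA_BY_COMMUNITY["fish"]),
                               water=water)
        if c.d15N is None:
            rows.append({"sample_id": c.sample_id, "community": c.community,
                         "TP": float("nan"), "tau": float("nan"),
                         "omega_compound": float("nan"), "d2H_source": float("nan")})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tp = trophic_position(c.d15N, params)
        rows.append({"sample_id": c.sample_id, "community": c.community,
                     "TP": tp, "tau": tp - 1.0, "omega_compound": float("nan"),
                     "d2H_source": float("nan"), "_d2H": c.d2H, "_omega": params.omega})
    df = pd.DataFrame(rows)
    if per_group_tau:
        df["tau"] = df.groupby("community")["tau"].transform("mean")
        df["TP"] = df["tau"] + 1.0

    for i, row in df.iterrows():
        if pd.isna(row["tau"]) or pd.isna(row.get("_d2H")):
            continue
        om_c = omega_compound(row["_omega"], row["tau"])
        df.at[i, "omega_compound"] = om_c
        if om_c < 0.99:
            df.at[i, "d2H_source"] = (row["_d2H"] - om_c * water.d2H_mean) / (1.0 - om_c)
    return df.drop(columns=["_d2H", "_omega"], errors="ignore")
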