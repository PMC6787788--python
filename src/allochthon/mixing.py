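"""Bayesian compositional source partitioning.

For each level of a grouping factor (community or feeding group) the model
estimates a source-proportion vector p on the simplex with a Dirichlet(α)
prior (α = 1, uninformative).  Each consumer's tracer value is modelled as

    x_t ~ Normal( Σ_k p_k (μ_kt + λ_kt),
                  sqrt( Σ_k p_k² (σ_kt² + τ_kt²) + s_t² ) )

where μ, σ are the source mean/SD, λ, τ the trophic-discrimination mean/SD,
and s_t a per-tracer residual SD (zero under the ``process_only`` error
structure; under ``process_plus_residual`` it gets a weakly informative
half-normal prior scaled to the consumers' spread).  Tracers are δ13C and,
optionally, source-corrected δ2H; δ15N is never used in the likelihood.

Sampling is adaptive random-walk Metropolis on the isometric-log-ratio (ILR)
transform of p (plus log s_t), tuned to 20–40% acceptance during burn-in,
with multiple chains, Gelman–Rubin R-hat and effective sample size via
arviz.  Sources are canonically ordered by name internally, so posterior
summaries are exactly invariant to the order in which sources are supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd

from .io import ConsumerSample, SourceDistribution, SUMMARY_COLUMNS


class DegenerateLikelihoodError(ValueError):
    """Total model variance is zero for some tracer; the density is undefined."""


@dataclass(frozen=True)
class MixingConfig:
    """MCMC and model settings for one fit.

    Defaults reproduce the reference run length: 300,000 iterations per
    chain, 150,000 burn-in, thinning by 50, so each chain retains 3,000
    draws.  Reduced settings (e.g. 30,000/15,000/thin 5) are appropriate for
    desk-scale work.
    """

    tracers: tuple[str, ...] = ("d13C", "d2H")
    group_by: str = "community"
    n_iter: int = 300_000
    n_burn: int = 150_000
    thin: int = 50
    n_chains: int = 3
    seed: int = 0
    error_structure: str = "process_plus_residual"
    dirichlet_alpha: float = 1.0
    tdf_trophic_scale: float = 1.0  # optional multiplier on λ/τ (e.g. a mean TP)

    def __post_init__(self) -> None:
        if not (0 <= self.n_burn < self.n_iter):
            raise ValueError("need 0 ≤ n_burn < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be ≥ 1")
        if self.n_chains < 2:
            raise ValueError("≥2 chains required for convergence diagnostics")
        if self.error_structure not in ("process_only", "process_plus_residual"):
            raise ValueError(f"unknown error structure {self.error_structure!r}")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")

    @property
    def n_keep(self) -> int:
        """Retained draws per chain."""
        return (self.n_iter - self.n_burn) // self.thin


# ---------------------------------------------------------------------------
# isometric log-ratio transform
# ---------------------------------------------------------------------------

def _ilr_basis(k: int) -> np.ndarray:
    """Orthonormal (k-1, k) Helmert-style contrast basis, rows ⟂ 1."""
    psi = np.zeros((k - 1, k))
    for i in range(1, k):
        psi[i - 1, :i] = 1.0 / i
        psi[i - 1, i] = -1.0
        psi[i - 1] *= math.sqrt(i / (i + 1.0))
    return psi


def ilr(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    clr = np.log(p) - np.log(p).mean(axis=-1, keepdims=True)
    return clr @ _ilr_basis(p.shape[-1]).T


def ilr_inv(z: np.ndarray) -> np.ndarray:
    z = np.atleast_2d(np.asarray(z, dtype=float))
    clr = z @ _ilr_basis(z.shape[-1] + 1)
    e = np.exp(clr - clr.max(axis=-1, keepdims=True))
    return np.squeeze(e / e.sum(axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _source_arrays(sources: Sequence[SourceDistribution], tracers: Sequence[str],
                   tdf_scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """(K, T) arrays of TDF-adjusted means and process variances."""
    mu = np.array([[s.mean(t) + tdf_scale * s.tdf_mean(t) for t in tracers] for s in sources])
    var = np.array([[s.sd(t) ** 2 + (tdf_scale * s.tdf_sd(t)) ** 2 for t in tracers]
                    for s in sources])
    return mu, var


def log_likelihood(consumer: ConsumerSample | Mapping[str, float],
                   p: Sequence[float],
                   sources: Sequence[SourceDistribution],
                   resid_sd: Mapping[str, float] | None = None,
                   tracers: Sequence[str] = ("d13C", "d2H"),
                   tdf_trophic_scale: float = 1.0) -> float:
    """Log-density of one consumer's tracer values given proportions ``p``.

    Sum over tracers of Normal log-densities with mixture mean
    Σ p_k (μ_k + λ_k) and variance Σ p_k² (σ_k² + τ_k²) + s_t².
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) != len(sources) or abs(p.sum() - 1.0) > 1e-8 or (p < -1e-12).any():
        raise ValueError("p must be a proportion vector over the sources")
    resid_sd = resid_sd or {}
    mu, var = _source_arrays(sources, tracers, tdf_trophic_scale)
    total = 0.0
    for j, t in enumerate(tracers):
        x = consumer.tracer(t) if isinstance(consumer, ConsumerSample) else consumer[t]
        if x is None:
            raise ValueError(f"consumer lacks tracer {t!r}")
        m = float(p @ mu[:, j])
        v = float((p ** 2) @ var[:, j]) + float(resid_sd.get(t, 0.0)) ** 2
        if v <= 0:
            raise DegenerateLikelihoodError(f"zero total variance for tracer {t!r}")
        total += -0.5 * math.log(2 * math.pi * v) - (float(x) - m) ** 2 / (2 * v)
    return total


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def sample_posterior(x: np.ndarray, sources: Sequence[SourceDistribution],
                     config: MixingConfig, seed_seq: np.random.SeedSequence | None = None
                     ) -> np.ndarray:
    """MCMC draws of source proportions for one group.

    Parameters
    ----------
    x : (n, T) array
        consumer tracer values in the order of ``config.tracers``; ``n`` may
        be zero, in which case the draws recover the Dirichlet(α) prior.

    Returns
    -------
    (n_chains, n_keep, K) array of simplex draws.
    """
    tracers = list(config.tracers)
    for s in sources:
        s.validate_for_fit(tracers)
    K, T = len(sources), len(tracers)
    x = np.asarray(x, dtype=float).reshape(-1, T)
    n = x.shape[0]
    sx, sxx = x.sum(axis=0), (x ** 2).sum(axis=0)

    mu, var = _source_arrays(sources, tracers, config.tdf_trophic_scale)
    sample_resid = config.error_structure == "process_plus_residual"
    # half-normal prior scale: consumer spread per tracer (fallback 1‰)
    if sample_resid:
        h = np.maximum(x.std(axis=0, ddof=1), 1e-3) if n >= 2 else np.ones(T)
    alpha = config.dirichlet_alpha
    dim = (K - 1) + (T if sample_resid else 0)

    def log_post(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized over chains: z is (C, dim). Returns (logp, p)."""
        p = np.atleast_2d(ilr_inv(z[:, :K - 1]))
        logp = alpha * np.log(p).sum(axis=1)  # Dirichlet(α) density + ILR Jacobian
        if sample_resid:
            u = z[:, K - 1:]
            s2 = np.exp(2 * u)
            logp += (u - s2 / (2 * h ** 2)).sum(axis=1)  # half-normal + log-Jacobian
        else:
            s2 = 0.0
        if n > 0:
            m = p @ mu                      # (C, T)
            v = (p ** 2) @ var + s2         # (C, T)
            if np.any(v <= 0):
                raise DegenerateLikelihoodError("zero total variance; give sources SDs "
                                                "or use the residual error structure")
            ll = (-0.5 * n * np.log(2 * np.pi * v)
                  - (sxx - 2 * m * sx + n * m ** 2) / (2 * v)).sum(axis=1)
            logp = logp + ll
        return logp, p

    C = config.n_chains
    rng = np.random.default_rng(seed_seq if seed_seq is not None
                                else np.random.SeedSequence(config.seed))
    z = 0.1 * rng.standard_normal((C, dim))
    if sample_resid:
        z[:, K - 1:] = np.log(h / 2.0) + 0.1 * rng.standard_normal((C, T))
    lp, p_cur = log_post(z)
    step = np.full(C, 0.5)
    acc = np.zeros(C)
    keep = np.empty((C, config.n_keep, K))
    kept = 0
    for it in range(config.n_iter):
        prop = z + step[:, None] * rng.standard_normal((C, dim))
        lp_prop, p_prop = log_post(prop)
        accept = np.log(rng.random(C)) < lp_prop - lp
        z[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        p_cur[accept] = p_prop[accept]
        acc += accept
        in_burn = it < config.n_burn
        if in_burn and (it + 1) % 100 == 0:
            # Robbins–Monro-style tuning toward ~30% acceptance
            rate = acc / 100.0
            step *= np.exp(rate - 0.3)
            acc[:] = 0.0
        if not in_burn and (it - config.n_burn) % config.thin == 0 and kept < config.n_keep:
            keep[:, kept, :] = p_cur
            kept += 1
    return keep[:, :kept, :]


# ---------------------------------------------------------------------------
# fitting and summaries
# ---------------------------------------------------------------------------

def _consumer_matrix(consumers: Sequence[ConsumerSample], tracers: Sequence[str],
                     d2H_override: Mapping[str, float] | None) -> np.ndarray:
    d2H_override = d2H_override or {}
    rows = []
    for c in consumers:
        row = []
        for t in tracers:
            v = d2H_override.get(c.sample_id) if (t == "d2H" and c.sample_id in d2H_override) \
                else c.tracer(t)
            row.append(np.nan if v is None else float(v))
        rows.append(row)
    return np.array(rows, dtype=float).reshape(len(consumers), len(tracers))


@dataclass
class FitResult:
    """Posterior summaries, raw draws and a fit report for one model run."""

    summary: pd.DataFrame                     # group × source rows, Table-1-shaped
    draws: dict[str, np.ndarray]              # group -> (chains, draws, K) simplex draws
    source_names: list[str]
    report: dict = field(default_factory=dict)


def _summarize_group(group: str, draws: np.ndarray, names: Sequence[str]) -> list[dict]:
    rows = []
    pooled = draws.reshape(-1, draws.shape[-1])
    for k, name in enumerate(names):
        chain_draws = draws[:, :, k]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(chain_draws))
            ess = float(az.ess(chain_draws))
        rows.append({
            "group": group, "source": name,
            "median": float(np.median(pooled[:, k])),
            "sd": float(pooled[:, k].std(ddof=1)),
            "ci2.5": float(np.quantile(pooled[:, k], 0.025)),
            "ci97.5": float(np.quantile(pooled[:, k], 0.975)),
            "rhat": rhat, "ess": ess,
        })
    return rows


def fit(consumers: Sequence[ConsumerSample], sources: Sequence[SourceDistribution],
        config: MixingConfig, d2H_override: Mapping[str, float] | None = None
        ) -> FitResult:
    """Fit the mixing model with one independent composition per group level.

    ``consumers`` should already be polygon-screened; specimens missing any
    tracer in ``config.tracers`` are excluded here (and counted in the
    report).  For δ2H-bearing models pass the source-corrected values via
    ``d2H_override`` (sample_id → corrected δ2H).

    Groups with fewer than 3 usable consumers are skipped with a warning;
    R-hat above 1.1 triggers a convergence flag in the report, never an error.
    """
    if len(sources) < 2:
        raise ValueError("≥2 sources required for a mixing fit")
    order = np.argsort([s.name for s in sources], kind="stable")
    canon = [sources[i] for i in order]
    names = [s.name for s in canon]

    tracers = list(config.tracers)
    x_all = _consumer_matrix(consumers, tracers, d2H_override)
    usable = np.all(np.isfinite(x_all), axis=1)
    report: dict = {
        "n_consumers": len(consumers),
        "n_excluded_missing_tracer": int((~usable).sum()),
        "excluded_missing_tracer": [c.sample_id for c, u in zip(consumers, usable) if not u],
        "skipped_groups": [], "convergence_flags": [],
        "tracers": tracers, "error_structure": config.error_structure,
    }

    levels = sorted({getattr(c, config.group_by) for c in consumers})
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(len(levels))
    rows, draws = [], {}
    for seq, level in zip(seeds, levels):
        mask = usable & np.array([getattr(c, config.group_by) == level for c in consumers])
        ng = int(mask.sum())
        if ng < 3:
            warnings.warn(f"group {level!r}: only {ng} usable consumers; skipped", stacklevel=2)
            report["skipped_groups"].append({"group": level, "n": ng})
            continue
        g_draws = sample_posterior(x_all[mask], canon, config, seed_seq=seq)
        draws[level] = g_draws
        g_rows = _summarize_group(level, g_draws, names)
        for r in g_rows:
            if r["rhat"] > 1.1:
                report["convergence_flags"].append(
                    {"group": level, "source": r["source"], "rhat": r["rhat"]})
        rows.extend(g_rows)
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return FitResult(summary=summary, draws=draws, source_names=names, report=report)


# ---------------------------------------------------------------------------
# sensitivity sweep
# ---------------------------------------------------------------------------

def _replace_source_param(sources: Sequence[SourceDistribution], param_path: str,
                          value: float) -> list[SourceDistribution]:
    try:
        src_name, tracer, which = param_path.split(".")
    except ValueError:
        raise ValueError("param_path must be '<source>.<tracer>.<mean|sd>'") from None
    out = []
    hit = False
    for s in sources:
        if s.name == src_name:
            hit = True
            if which == "mean":
                s = replace(s, tracer_means={**s.tracer_means, tracer: value})
            elif which == "sd":
                s = replace(s, tracer_sds={**s.tracer_sds, tracer: value})
            else:
                raise ValueError(f"param_path field must be 'mean' or 'sd', got {which!r}")
        out.append(s)
    if not hit:
        raise ValueError(f"no source named {src_name!r}")
    return out


def sensitivity_sweep(consumers: Sequence[ConsumerSample],
                      sources: Sequence[SourceDistribution],
                      config: MixingConfig, param_path: str,
                      values: Sequence[float],
                      d2H_override: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Refit the model across a sweep of one source parameter.

    Typical use: vary the assumed algal δ2H mean (e.g. −130 to −170‰) to
    check how strongly the algae-vs-terrestrial split depends on the assumed
    end-member.  Returns one row per (value, group, source) with the posterior
    median, plus a ``max_abs_change`` column giving, per group × source, the
    largest |median − central median| where the central fit uses the
    unmodified sources.  Inputs are never mutated.
    """
    if len(values) == 0:
        raise ValueError("values list must not be empty")
    central = fit(consumers, sources, config, d2H_override).summary
    central_idx = central.set_index(["group", "source"])["median"]
    frames = []
    for v in values:
        swept = _replace_source_param(sources, param_path, float(v))
        s = fit(consumers, swept, config, d2H_override).summary
        s.insert(0, "swept_value", float(v))
        frames.append(s)
    table = pd.concat(frames, ignore_index=True)
    delta = np.abs(table["median"].to_numpy()
                   - central_idx.loc[list(zip(table["group"], table["source"]))].to_numpy())
    table["abs_change_vs_central"] = delta
    table["max_abs_change"] = table.groupby(["group", "source"])["abs_change_vs_central"] \
                                   .transform("max")
    return table
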