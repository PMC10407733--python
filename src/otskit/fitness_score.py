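"""Composite relative fitness of a strain versus the plasmid-free background.

Four phenotype parameters — specific growth rate, lag time, growth efficiency
and mean forward-scatter cell size — are turned into background-normalised
ratios oriented so that larger always means fitter (the lag ratio is inverted;
cell-size reduction is a stress marker, so size enters as condition/background).
The composite is their weighted geometric mean, which makes a condition
identical to the background score exactly 1, is unit-free, and satisfies
``composite(A vs B) * composite(B vs A) = 1``.  Conditions that could not be
established are Not Viable (N.V.): composite 0, ratios absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

PARAMETERS = ("r_mu", "r_lag", "r_eff", "r_size")


@dataclass
class ConditionPhenotype:
    """Replicate-averaged phenotype of one condition."""

    condition: str
    mu_per_h: float = float("nan")
    lag_h: float = float("nan")
    efficiency_od: float = float("nan")
    fsc_mean_au: float = float("nan")
    mu_sd: float = 0.0
    lag_sd: float = 0.0
    efficiency_sd: float = 0.0
    fsc_sd: float = 0.0
    n_replicates: int = 1
    viable: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for sd in (self.mu_sd, self.lag_sd, self.efficiency_sd, self.fsc_sd):
            if sd < 0:
                raise ValueError("SDs must be non-negative")


@dataclass
class FitnessProfile:
    condition: str
    ratios: dict[str, float] = field(default_factory=dict)
    composite: float = 0.0
    viable: bool = True

    def render(self) -> str:
        """Heat-map cell text: the composite, or 'N.V.' when not viable."""
        return "N.V." if not self.viable else f"{self.composite:.3f}"


def parameter_ratios(
    cond: ConditionPhenotype,
    background: ConditionPhenotype,
    max_lag_ratio: float = 10.0,
) -> dict[str, float]:
    """Background-normalised ratios oriented so bigger = fitter.

    r_mu = mu_c/mu_bg; r_eff = E_c/E_bg; r_lag = lag_bg/lag_c (a condition with
    a tripled lag scores ~1/3); r_size = FSC_c/FSC_bg.  A zero condition lag is
    capped at ``max_lag_ratio``.  Non-viable conditions return an empty mapping.
    A parameter missing (NaN) on both sides — e.g. no cytometry data — is
    omitted from the mapping rather than poisoning the composite.
    """
    if not background.viable:
        raise ValueError("background phenotype must be viable")
    pairs = {
        "r_mu": (cond.mu_per_h, background.mu_per_h),
        "r_lag": (cond.lag_h, background.lag_h),
        "r_eff": (cond.efficiency_od, background.efficiency_od),
        "r_size": (cond.fsc_mean_au, background.fsc_mean_au),
    }
    used = {
        k: v for k, v in pairs.items()
        if not (math.isnan(v[0]) and math.isnan(v[1]))
    }
    for name, (_, bg_val) in used.items():
        if not bg_val > 0:
            raise ValueError(f"background value for {name} must be positive")
    if not cond.viable:
        return {}
    ratios: dict[str, float] = {}
    for name, (c_val, bg_val) in used.items():
        if name == "r_lag":
            ratios[name] = (
                max_lag_ratio if c_val == 0 else min(bg_val / c_val, max_lag_ratio)
            )
        else:
            ratios[name] = c_val / bg_val
    return ratios


def composite_fitness(
    ratios: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Weighted geometric mean of the oriented ratios; 0 for non-viable input
    (an empty ratio mapping)."""
    if not ratios:
        return 0.0
    if weights is None:
        weights = {k: 1.0 / len(ratios) for k in ratios}
    if set(weights) != set(ratios):
        raise ValueError("weights must cover exactly the ratio keys")
    total_w = sum(weights.values())
    if any(w < 0 for w in weights.values()) or total_w <= 0:
        raise ValueError("weights must be non-negative and sum to a positive value")
    log_sum = 0.0
    for k, r in ratios.items():
        if r <= 0:
            raise ValueError(f"ratio {k} must be positive, got {r}")
        log_sum += (weights[k] / total_w) * math.log(r)
    return math.exp(log_sum)


def fitness_profile(
    cond: ConditionPhenotype,
    background: ConditionPhenotype,
    weights: Mapping[str, float] | None = None,
    max_lag_ratio: float = 10.0,
) -> FitnessProfile:
    ratios = parameter_ratios(cond, background, max_lag_ratio=max_lag_ratio)
    return FitnessProfile(
        condition=cond.condition,
        ratios=ratios,
        composite=composite_fitness(ratios, weights) if ratios else 0.0,
        viable=cond.viable,
    )


# ---------------------------------------------------------------------------
# I/O: combine growth params.tsv + size_summary.tsv into fitness.tsv
# ---------------------------------------------------------------------------

def phenotypes_from_tables(
    growth: pd.DataFrame, size: pd.DataFrame
) -> dict[str, ConditionPhenotype]:
    """Aggregate per-curve growth parameters and per-sample size summaries
    (as written by the growth_kinetics and cytometry_size writers) into one
    replicate-averaged phenotype per condition."""
    phenos: dict[str, ConditionPhenotype] = {}
    g = growth.groupby("condition")
    s = size.groupby("condition") if len(size) else None
    for cond, grp in g:
        cond = str(cond)
        fsc_mean = fsc_sd = float("nan")
        if s is not None and cond in s.groups:
            means = s.get_group(cond)["mean"]
            fsc_mean = float(means.mean())
            fsc_sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
        phenos[cond] = ConditionPhenotype(
            condition=cond,
            mu_per_h=float(grp["mu_per_h"].mean()),
            lag_h=float(grp["lag_h"].mean()),
            efficiency_od=float(grp["efficiency_od"].mean()),
            fsc_mean_au=fsc_mean,
            mu_sd=float(grp["mu_per_h"].std(ddof=1)) if len(grp) > 1 else 0.0,
            lag_sd=float(grp["lag_h"].std(ddof=1)) if len(grp) > 1 else 0.0,
            efficiency_sd=float(grp["efficiency_od"].std(ddof=1)) if len(grp) > 1 else 0.0,
            fsc_sd=fsc_sd,
            n_replicates=int(len(grp)),
        )
    return phenos


def write_fitness_profiles(profiles: list[FitnessProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row = {"condition": p.condition, "composite": p.composite,
               "viable": p.viable, "rendered": p.render()}
        for k in PARAMETERS:
            row[k] = p.ratios.get(k, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
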