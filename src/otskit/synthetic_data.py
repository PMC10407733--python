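"""Seeded generators for every input kind the toxicity-profiling pipeline consumes.

Each generator returns the dataset together with a :class:`TruthRecord` holding the
parameters it was built from, so downstream estimators can be tested against known
ground truth without any external downloads.  All generators take an explicit
``seed`` and draw from a private :class:`numpy.random.Generator`; identical
arguments and seed produce byte-identical output.

The defaults mirror the study conditions of the plate-reader / flow-cytometry /
label-free-proteomics experiments they emulate: OD600 read every 10 min for 16 h,
three biological replicates, one Gaussian chromatographic peak per peptide variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth_kinetics import GrowthCurve
from .cytometry_size import FSCSample
from .msread_quant import ChromatogramRecord, ChromatogramSet, GelQuantTable
from .proteome_stats import QuantTable

OD_FLOOR = 1e-4  # positive floor applied to noisy OD readings


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth attached to a generated dataset.

    ``params`` maps parameter names (or entity ids such as protein ids) to the
    true values used by the generator.
    """

    generator: str
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"key": k, "value": v} for k, v in self.params.items()]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation settings: seed and replicate count (default 3)."""

    seed: int = 0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def simulate_growth_curve(
    od0: float,
    lag_h: float,
    mu: float,
    capacity: float,
    noise_sd: float = 0.0,
    dt_min: float = 10.0,
    duration_h: float = 16.0,
    seed: int = 0,
    condition: str = "sim",
    replicate: str = "1",
) -> tuple[GrowthCurve, TruthRecord]:
    """Three-phase growth model: flat lag, then a logistic rise toward capacity.

    OD(t) = od0 for t < lag_h; afterwards the logistic trajectory
    ``capacity*od0 / (od0 + (capacity-od0)*exp(-mu*(t-lag_h)))`` which starts at
    ``od0`` and has intrinsic (early-exponential) rate ``mu``.  Additive Gaussian
    noise is truncated at a positive floor so log transforms stay defined.
    """
    if od0 <= 0 or capacity <= 0:
        raise ValueError("od0 and capacity must be positive")
    if od0 >= capacity:
        raise ValueError("od0 must be below capacity")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if not 0 <= lag_h < duration_h:
        raise ValueError("lag_h must lie in [0, duration_h)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h * 60.0 + dt_min / 2, dt_min) / 60.0
    od = np.full_like(t, od0)
    grow = t >= lag_h
    tg = t[grow] - lag_h
    od[grow] = capacity * od0 / (od0 + (capacity - od0) * np.exp(-mu * tg))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.size)
    od = np.maximum(od, OD_FLOOR)

    curve = GrowthCurve(times=t, od=od, condition=condition, replicate=replicate)
    truth = TruthRecord(
        "simulate_growth_curve",
        {"od0": od0, "lag_h": lag_h, "mu": mu, "capacity": capacity},
    )
    return curve, truth


# ---------------------------------------------------------------------------
# forward-scatter events
# ---------------------------------------------------------------------------

def simulate_fsc(
    mean_au: float,
    cv: float,
    n_events: int,
    seed: int = 0,
    condition: str = "sim",
    replicate: str = "1",
) -> tuple[FSCSample, TruthRecord]:
    """Log-normal forward-scatter events with arithmetic mean ``mean_au`` and
    coefficient of variation ``cv``.

    The log-normal keeps events strictly positive and right-skewed, matching the
    shape of scatter histograms; it is parameterised here by mean/CV for test
    readability rather than by the underlying log-scale moments.
    """
    if mean_au <= 0:
        raise ValueError("mean_au must be positive")
    if cv <= 0:
        raise ValueError("cv must be positive")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv**2)
    mu_log = np.log(mean_au) - sigma2 / 2.0
    values = rng.lognormal(mean=mu_log, sigma=np.sqrt(sigma2), size=n_events)
    sample = FSCSample(values=values, condition=condition, replicate=replicate)
    truth = TruthRecord("simulate_fsc", {"mean_au": mean_au, "cv": cv, "n_events": n_events})
    return sample, truth


# ---------------------------------------------------------------------------
# label-free proteome tables
# ---------------------------------------------------------------------------

def simulate_proteome(
    n_proteins: int,
    n_reps: int = 3,
    frac_dys: float = 0.0,
    log2_effect: float = 2.0,
    rep_sd_log2: float = 0.25,
    missing_rate: float = 0.0,
    seed: int = 0,
    cond_a: str = "BG",
    cond_b: str = "OTS",
    baseline_mean_log2: float = 25.0,
    baseline_sd_log2: float = 2.5,
) -> tuple[QuantTable, TruthRecord]:
    """Two-condition label-free quantification table with spiked effects.

    Baseline log2 intensities are drawn wide (N(25, 2.5) by default, spanning the
    dynamic range of shotgun LFQ data).  A ``frac_dys`` subset is shifted by
    ``+log2_effect`` (up) or ``-log2_effect`` (down, split evenly) in condition B
    only; replicate noise is N(0, rep_sd_log2) on the log2 scale.  The iBAQ
    channel divides each intensity by a per-protein positive size factor (a
    theoretical-peptide-count surrogate), and cells are dropped uniformly at
    random at ``missing_rate``.  Truth labels every protein up/down/null.
    """
    if not 0 <= frac_dys <= 1:
        raise ValueError("frac_dys must lie in [0, 1]")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    proteins = np.array([f"P{i:05d}" for i in range(n_proteins)])
    n_dys = int(round(frac_dys * n_proteins))
    if frac_dys > 0 and n_dys < 1:
        warnings.warn("frac_dys*n_proteins < 1; generating 0 dysregulated proteins")
    labels = np.array(["null"] * n_proteins, dtype=object)
    effects = np.zeros(n_proteins)
    if n_dys:
        idx = rng.choice(n_proteins, size=n_dys, replace=False)
        half = n_dys // 2
        up_idx, down_idx = idx[: n_dys - half], idx[n_dys - half :]
        labels[up_idx], labels[down_idx] = "up", "down"
        effects[up_idx], effects[down_idx] = log2_effect, -log2_effect

    base = rng.normal(baseline_mean_log2, baseline_sd_log2, size=n_proteins)
    size_factor = np.exp(rng.normal(np.log(20.0), 0.8, size=n_proteins))

    samples_a = [f"{cond_a}_{r + 1}" for r in range(n_reps)]
    samples_b = [f"{cond_b}_{r + 1}" for r in range(n_reps)]
    data = {"protein_id": proteins}
    design: dict[str, str] = {}
    for name, shift, cond in [(s, 0.0, cond_a) for s in samples_a] + [
        (s, 1.0, cond_b) for s in samples_b
    ]:
        log2_int = base + shift * effects + rng.normal(0.0, rep_sd_log2, size=n_proteins)
        lfq = np.exp2(log2_int)
        ibaq = lfq / size_factor
        if missing_rate > 0:
            drop = rng.random(n_proteins) < missing_rate
            lfq = np.where(drop, np.nan, lfq)
            ibaq = np.where(drop, np.nan, ibaq)
        data[f"LFQ.{name}"] = lfq
        data[f"iBAQ.{name}"] = ibaq
        design[name] = cond

    table = QuantTable(frame=pd.DataFrame(data), design=design)
    truth = TruthRecord(
        "simulate_proteome",
        {
            "labels": dict(zip(proteins.tolist(), labels.tolist())),
            "log2_effects": dict(zip(proteins.tolist(), effects.tolist())),
            "frac_dys": frac_dys,
            "log2_effect": log2_effect,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# MS1 chromatograms
# ---------------------------------------------------------------------------

def simulate_chromatograms(
    variant_ratios: Mapping[str, float],
    rt_centers: Mapping[str, float],
    peak_sigma: float = 0.1,
    base_area: float = 1e6,
    noise_sd: float = 0.0,
    area_cv: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    dt_min: float | None = None,
    baseline: float = 0.0,
) -> tuple[ChromatogramSet, TruthRecord]:
    """Per-variant MS1 traces: one Gaussian peak per variant on a flat baseline.

    Each variant x replicate trace carries a Gaussian peak of area
    ``base_area * ratio`` centred at the variant's retention time.  ``area_cv``
    adds multiplicative log-normal replicate-to-replicate area variation (the
    dominant noise mode of label-free peak areas); ``noise_sd`` adds additive
    Gaussian intensity noise along the trace.  Peak boundaries (+/- 4 sigma) are
    included per record.  The pSer variant must be present with ratio 1, since
    downstream ratios are normalised to it.
    """
    if "pSer" not in variant_ratios:
        raise ValueError("variant_ratios must contain the reference variant 'pSer'")
    if abs(variant_ratios["pSer"] - 1.0) > 1e-12:
        raise ValueError("the pSer reference ratio is fixed at 1")
    if peak_sigma <= 0:
        raise ValueError("peak_sigma must be positive")
    missing_rt = set(variant_ratios) - set(rt_centers)
    if missing_rt:
        raise ValueError(f"rt_centers missing for variants: {sorted(missing_rt)}")
    centers = [rt_centers[v] for v in variant_ratios]
    if len(set(centers)) != len(centers):
        raise ValueError("rt centers must be distinct")

    rng = np.random.default_rng(seed)
    if dt_min is None:
        dt_min = peak_sigma / 10.0
    lo = min(centers) - 6.0 * peak_sigma
    hi = max(centers) + 6.0 * peak_sigma
    t = np.arange(lo, hi + dt_min / 2, dt_min)

    records = []
    for variant, ratio in variant_ratios.items():
        if ratio < 0:
            raise ValueError("variant ratios must be non-negative")
        c = rt_centers[variant]
        for rep in range(1, n_reps + 1):
            area = base_area * ratio
            if area_cv > 0 and area > 0:
                s2 = np.log1p(area_cv**2)
                area *= rng.lognormal(-s2 / 2.0, np.sqrt(s2))
            intensity = baseline + area * np.exp(
                -0.5 * ((t - c) / peak_sigma) ** 2
            ) / (peak_sigma * np.sqrt(2.0 * np.pi))
            if noise_sd > 0:
                intensity = intensity + rng.normal(0.0, noise_sd, size=t.size)
            intensity = np.maximum(intensity, 0.0)
            records.append(
                ChromatogramRecord(
                    variant=variant,
                    replicate=str(rep),
                    rt=t.copy(),
                    intensity=intensity,
                    boundary=(c - 4.0 * peak_sigma, c + 4.0 * peak_sigma),
                )
            )
    chromset = ChromatogramSet(records=records)
    truth = TruthRecord(
        "simulate_chromatograms",
        {"ratios": dict(variant_ratios), "base_area": base_area},
    )
    return chromset, truth


# ---------------------------------------------------------------------------
# gel densitometry
# ---------------------------------------------------------------------------

def simulate_densitometry(
    known_ng: Sequence[float],
    response_per_ng: float,
    sample_total_ng: float,
    phos_fraction: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    loaded_volume_ul: float = 7.5,
) -> tuple[GelQuantTable, TruthRecord]:
    """Densitometry of a reporter gel: linear standards plus PhosTag band split.

    Standard intensities follow ``response_per_ng * ng`` plus Gaussian noise; the
    sample's PhosTag upper (phosphorylated) and lower bands split the total-band
    signal by ``phos_fraction``.
    """
    known = np.asarray(known_ng, dtype=float)
    if known.size < 2 or np.unique(known).size < 2:
        raise ValueError("need at least 2 distinct standard masses")
    if not 0 <= phos_fraction <= 1:
        raise ValueError("phos_fraction must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    std_int = response_per_ng * known + rng.normal(0.0, noise_sd, size=known.size)
    total_int = response_per_ng * sample_total_ng + rng.normal(0.0, noise_sd)
    upper = total_int * phos_fraction
    lower = total_int * (1.0 - phos_fraction)
    table = GelQuantTable(
        standard_ng=known,
        standard_intensity=np.maximum(std_int, 0.0),
        total_intensity=max(total_int, 0.0),
        upper_intensity=max(upper, 0.0),
        lower_intensity=max(lower, 0.0),
        loaded_volume_ul=loaded_volume_ul,
    )
    truth = TruthRecord(
        "simulate_densitometry",
        {
            "sample_total_ng": sample_total_ng,
            "phos_fraction": phos_fraction,
            "response_per_ng": response_per_ng,
        },
    )
    return table, truth
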