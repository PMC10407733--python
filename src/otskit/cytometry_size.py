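"""Cell-size phenotyping from flow-cytometry forward-scatter (FSC) event lists.

Forward scatter is used as a proxy for cell size; a sample is summarised by the
mean, SD, median and mode of its event distribution.  The mode is the centre of
the maximal-count bin of an equal-width histogram (256 bins by default),
matching the binned-display convention of cytometry software; median and mode
SDs are bootstrap standard deviations, since no closed form exists for the
binned mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class FSCSample:
    """Per-event forward-scatter values (arbitrary units, strictly positive)."""

    values: np.ndarray
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("FSC sample must be non-empty")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("FSC values must be positive and finite")


@dataclass
class SizeSummary:
    mean: float
    sd: float
    median: float
    mode: float
    median_sd: float | None
    mode_sd: float | None
    n_events: int
    condition: str = ""
    replicate: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": ["mean", "sd", "median", "mode", "median_sd", "mode_sd"],
                "value": [self.mean, self.sd, self.median, self.mode,
                          self.median_sd, self.mode_sd],
            }
        )


def _histogram_mode(values: np.ndarray, n_bins: int) -> float:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    i = int(np.argmax(counts))  # argmax takes the first max -> lowest-valued bin
    return float(0.5 * (edges[i] + edges[i + 1]))


def summarize_fsc(
    sample: FSCSample,
    n_bins: int = 256,
    bootstrap_b: int = 200,
    seed: int = 0,
) -> SizeSummary:
    """Summarise an FSC sample; bootstrap SDs need >= 10 events, otherwise the
    median/mode SDs are flagged unavailable (None)."""
    v = sample.values
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    median = float(np.median(v))
    mode = _histogram_mode(v, n_bins)

    median_sd = mode_sd = None
    if v.size >= 10 and bootstrap_b > 1:
        rng = np.random.default_rng(seed)
        med_b = np.empty(bootstrap_b)
        mod_b = np.empty(bootstrap_b)
        for b in range(bootstrap_b):
            res = v[rng.integers(0, v.size, size=v.size)]
            med_b[b] = np.median(res)
            mod_b[b] = _histogram_mode(res, n_bins)
        median_sd = float(med_b.std(ddof=1))
        mode_sd = float(mod_b.std(ddof=1))

    return SizeSummary(
        mean=mean,
        sd=sd,
        median=median,
        mode=mode,
        median_sd=median_sd,
        mode_sd=mode_sd,
        n_events=int(v.size),
        condition=sample.condition,
        replicate=sample.replicate,
    )


def compare_size(a: SizeSummary, b: SizeSummary) -> tuple[float, pd.DataFrame]:
    """Fold change of means (a/b) plus a per-statistic difference table."""
    fold = a.mean / b.mean
    stats = ["mean", "sd", "median", "mode"]
    table = pd.DataFrame(
        {
            "statistic": stats,
            "a": [getattr(a, s) for s in stats],
            "b": [getattr(b, s) for s in stats],
        }
    )
    table["delta"] = table["a"] - table["b"]
    return fold, table


def read_fsc_events(path: str | Path) -> list[FSCSample]:
    """Read a CSV with columns fsc, condition, replicate (one row per event).

    Native FCS binaries are not parsed; convert upstream.
    """
    df = pd.read_csv(path)
    if not {"fsc", "condition", "replicate"}.issubset(df.columns):
        raise ValueError("event table needs columns fsc, condition, replicate")
    samples = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        samples.append(
            FSCSample(
                values=grp["fsc"].to_numpy(dtype=float),
                condition=str(cond),
                replicate=str(rep),
            )
        )
    return samples


def write_size_summaries(summaries: list[SizeSummary], path: str | Path) -> None:
    rows = [
        {
            "condition": s.condition,
            "replicate": s.replicate,
            "mean": s.mean,
            "sd": s.sd,
            "median": s.median,
            "mode": s.mode,
            "median_sd": s.median_sd,
            "mode_sd": s.mode_sd,
            "n_events": s.n_events,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
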