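"""Site-specific amino-acid incorporation from MS1 reporter chromatograms, and
reporter-protein yield from gel densitometry.

The mass-spectrometry readout assay expresses a reporter peptide whose variable
position is occupied by whichever amino acid was delivered at the target codon;
each variant elutes as its own chromatographic peak.  Incorporation is
quantified as the trapezoidal area under the MS1 trace inside the peak
boundaries (baseline-subtracted), normalised per replicate to the area of the
phosphoserine variant, then averaged across replicates.  Variants whose peak
maximum stays below ``lod_snr`` times the out-of-window noise (a robust
MAD-based estimate) are flagged below the limit of detection and report a
ratio of 0 so ratio tables stay rectangular.

Gel quantification: reporter yield is read off an ordinary-least-squares
standard curve of known protein masses, and phosphoprotein yield is the total
yield scaled by the PhosTag upper-band fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# chromatograms
# ---------------------------------------------------------------------------

@dataclass
class ChromatogramRecord:
    """One variant x replicate MS1 trace with its peak boundary [min]."""

    variant: str
    replicate: str
    rt: np.ndarray
    intensity: np.ndarray
    boundary: tuple[float, float]

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape or self.rt.ndim != 1:
            raise ValueError("rt and intensity must be 1-D arrays of equal length")
        if not np.all(np.diff(self.rt) > 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        lo, hi = self.boundary
        if not (lo < hi):
            raise ValueError("peak boundary must satisfy start < end")

    def window_mask(self) -> np.ndarray:
        lo, hi = self.boundary
        return (self.rt >= lo) & (self.rt <= hi)


@dataclass
class ChromatogramSet:
    records: list[ChromatogramRecord]

    def variants(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.variant, None)
        return list(seen)

    def replicates(self) -> list[str]:
        return sorted({r.replicate for r in self.records})

    def get(self, variant: str, replicate: str) -> ChromatogramRecord:
        for r in self.records:
            if r.variant == variant and r.replicate == replicate:
                return r
        raise KeyError(f"no trace for variant {variant!r}, replicate {replicate!r}")


def integrate_auc(record: ChromatogramRecord, baseline: str = "flat-min") -> float:
    """Trapezoidal area of (intensity - baseline)+ inside the peak boundaries.

    ``baseline='none'`` integrates the raw trace; ``'flat-min'`` (default)
    subtracts the minimum intensity inside the window first.
    """
    mask = record.window_mask()
    if mask.sum() < 2:
        raise ValueError("peak window must contain at least 2 points")
    t = record.rt[mask]
    y = record.intensity[mask]
    if baseline == "flat-min":
        y = y - y.min()
    elif baseline != "none":
        raise ValueError("baseline must be 'none' or 'flat-min'")
    return float(np.trapezoid(np.maximum(y, 0.0), t))


def _noise_mad(record: ChromatogramRecord) -> float:
    """Robust noise level of the trace outside the peak window (1.4826*MAD)."""
    out = record.intensity[~record.window_mask()]
    if out.size < 4:
        return 0.0
    med = np.median(out)
    return float(1.4826 * np.median(np.abs(out - med)))


@dataclass
class IncorporationResults:
    """Per-variant pSer-normalised incorporation ratios."""

    frame: pd.DataFrame  # variant, mean_auc, auc_sd, ratio, ratio_sd, below_lod
    reference: str = "pSer"
    excluded_replicates: list[str] = field(default_factory=list)

    def ratio(self, variant: str) -> float:
        row = self.frame.loc[self.frame["variant"] == variant]
        if row.empty:
            raise KeyError(f"no such variant: {variant!r}")
        return float(row["ratio"].iloc[0])

    def below_lod(self, variant: str) -> bool:
        row = self.frame.loc[self.frame["variant"] == variant]
        return bool(row["below_lod"].iloc[0])

    def summary(self) -> pd.DataFrame:
        return self.frame.copy()

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.frame
        ax.bar(f["variant"], f["ratio"], yerr=f["ratio_sd"].fillna(0.0),
               color="0.5", capsize=3)
        ax.set_ylabel(f"incorporation ratio (variant : {self.reference})")
        return ax


class IncorporationModel:
    """pSer-normalised incorporation from a set of variant chromatograms.

    Per replicate, the ratio of each variant's AUC to the pSer AUC is computed
    (within-sample normalisation); replicate ratios are then averaged.
    Replicates whose pSer area is zero are excluded with a diagnostic.
    """

    def __init__(
        self,
        chromset: ChromatogramSet,
        lod_snr: float = 3.0,
        baseline: str = "flat-min",
        reference: str = "pSer",
    ):
        self.chromset = chromset
        self.lod_snr = lod_snr
        self.baseline = baseline
        self.reference = reference
        if reference not in chromset.variants():
            raise ValueError(f"reference variant {reference!r} missing from the set")

    def fit(self) -> IncorporationResults:
        variants = self.chromset.variants()
        reps = self.chromset.replicates()

        ref_auc: dict[str, float] = {}
        excluded = []
        for rep in reps:
            auc = integrate_auc(self.chromset.get(self.reference, rep), self.baseline)
            if auc <= 0:
                excluded.append(rep)
            else:
                ref_auc[rep] = auc
        if not ref_auc:
            raise ValueError("pSer reference area is zero in every replicate")

        rows = []
        for v in variants:
            aucs, ratios, lod_flags = [], [], []
            for rep, ref in ref_auc.items():
                rec = self.chromset.get(v, rep)
                auc = integrate_auc(rec, self.baseline)
                aucs.append(auc)
                peak_max = float(
                    np.max(rec.intensity[rec.window_mask()])
                    - np.min(rec.intensity[rec.window_mask()])
                )
                noise = _noise_mad(rec)
                below = peak_max < self.lod_snr * noise if noise > 0 else auc == 0.0
                lod_flags.append(below)
                ratios.append(0.0 if below else auc / ref)
            aucs = np.asarray(aucs)
            ratios = np.asarray(ratios)
            below_lod = all(lod_flags)
            rows.append(
                {
                    "variant": v,
                    "mean_auc": float(aucs.mean()),
                    "auc_sd": float(aucs.std(ddof=1)) if aucs.size > 1 else np.nan,
                    "ratio": 0.0 if below_lod else float(ratios.mean()),
                    "ratio_sd": float(ratios.std(ddof=1)) if ratios.size > 1 else np.nan,
                    "below_lod": below_lod,
                    "n_replicates": int(aucs.size),
                }
            )
        return IncorporationResults(
            frame=pd.DataFrame(rows),
            reference=self.reference,
            excluded_replicates=excluded,
        )


def incorporation_profile(
    chromset: ChromatogramSet, lod_snr: float = 3.0, baseline: str = "flat-min"
) -> IncorporationResults:
    """Functional wrapper around :class:`IncorporationModel`."""
    return IncorporationModel(chromset, lod_snr=lod_snr, baseline=baseline).fit()


# ---------------------------------------------------------------------------
# gel densitometry
# ---------------------------------------------------------------------------

@dataclass
class GelQuantTable:
    """Densitometry of a quantitative reporter gel.

    Standards pair known masses [ng] with band intensities; the sample carries
    a total-gel band plus PhosTag upper (phosphorylated) and lower bands.
    ``loaded_volume_ul`` converts an interpolated lane mass to mg/l.
    """

    standard_ng: np.ndarray
    standard_intensity: np.ndarray
    total_intensity: float
    upper_intensity: float
    lower_intensity: float
    loaded_volume_ul: float = 7.5

    def __post_init__(self) -> None:
        self.standard_ng = np.asarray(self.standard_ng, dtype=float)
        self.standard_intensity = np.asarray(self.standard_intensity, dtype=float)
        if self.standard_ng.size < 2 or np.unique(self.standard_ng).size < 2:
            raise ValueError("need at least 2 standards with distinct masses")
        if self.standard_ng.shape != self.standard_intensity.shape:
            raise ValueError("standard mass and intensity arrays must align")
        for v in (self.total_intensity, self.upper_intensity, self.lower_intensity):
            if v < 0:
                raise ValueError("band intensities must be non-negative")


def fit_standard_curve(
    standard_ng: np.ndarray, standard_intensity: np.ndarray
) -> tuple[float, float]:
    """OLS line intensity = slope*ng + intercept; returns (slope, intercept)."""
    ng = np.asarray(standard_ng, dtype=float)
    inten = np.asarray(standard_intensity, dtype=float)
    if np.unique(ng).size < 2:
        raise ValueError("standard masses must not all be identical")
    res = stats.linregress(ng, inten)
    return float(res.slope), float(res.intercept)


def interpolate_mass(intensity: float, slope: float, intercept: float) -> float:
    """Invert the standard curve for a band intensity."""
    if slope == 0:
        raise ValueError("standard curve slope is zero; cannot invert")
    return (intensity - intercept) / slope


def total_yield_mg_per_l(gel: GelQuantTable) -> float:
    """Reporter yield from the total-gel band: interpolated lane mass [ng]
    divided by the loaded culture-equivalent volume [ul] gives mg/l."""
    slope, intercept = fit_standard_curve(gel.standard_ng, gel.standard_intensity)
    ng = interpolate_mass(gel.total_intensity, slope, intercept)
    return ng / gel.loaded_volume_ul


def phosphoprotein_yield(total_yield: float, upper: float, lower: float) -> float:
    """Adjust a total yield by the phosphorylated band fraction upper/(upper+lower)."""
    if upper < 0 or lower < 0:
        raise ValueError("band intensities must be non-negative")
    if upper + lower == 0:
        raise ValueError("upper + lower band intensity must be positive")
    return total_yield * upper / (upper + lower)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chromatograms(
    traces_path: str | Path, bounds_path: str | Path
) -> ChromatogramSet:
    """Long CSV (variant, replicate, rt_min, intensity) plus a boundaries CSV
    (variant, replicate, rt_start, rt_end)."""
    tr = pd.read_csv(traces_path)
    if not {"variant", "replicate", "rt_min", "intensity"}.issubset(tr.columns):
        raise ValueError("trace CSV needs columns variant, replicate, rt_min, intensity")
    bd = pd.read_csv(bounds_path)
    if not {"variant", "replicate", "rt_start", "rt_end"}.issubset(bd.columns):
        raise ValueError("bounds CSV needs columns variant, replicate, rt_start, rt_end")
    bd = bd.assign(replicate=bd["replicate"].astype(str))
    bounds = {
        (row.variant, row.replicate): (row.rt_start, row.rt_end)
        for row in bd.itertuples()
    }
    records = []
    for (variant, rep), grp in tr.groupby(["variant", "replicate"], sort=True):
        key = (str(variant), str(rep))
        if key not in bounds:
            raise ValueError(f"no boundary for variant {variant!r} replicate {rep!r}")
        grp = grp.sort_values("rt_min")
        records.append(
            ChromatogramRecord(
                variant=str(variant),
                replicate=str(rep),
                rt=grp["rt_min"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                boundary=bounds[key],
            )
        )
    return ChromatogramSet(records=records)


def write_chromatograms(
    chromset: ChromatogramSet, traces_path: str | Path, bounds_path: str | Path
) -> None:
    rows, brows = [], []
    for r in chromset.records:
        rows.extend(
            {"variant": r.variant, "replicate": r.replicate, "rt_min": t, "intensity": i}
            for t, i in zip(r.rt, r.intensity)
        )
        brows.append(
            {"variant": r.variant, "replicate": r.replicate,
             "rt_start": r.boundary[0], "rt_end": r.boundary[1]}
        )
    pd.DataFrame(rows).to_csv(traces_path, index=False)
    pd.DataFrame(brows).to_csv(bounds_path, index=False)


def read_gel_table(path: str | Path) -> GelQuantTable:
    """TSV with columns role, band, known_ng, intensity: role='standard' rows
    carry known_ng, role='sample' rows carry band in {total, phos_upper,
    phos_lower}, plus an optional 'loaded_volume_ul' column on any row."""
    df = pd.read_csv(path, sep="\t")
    std = df[df["role"] == "standard"]
    smp = df[df["role"] == "sample"].set_index("band")
    vol = 7.5
    if "loaded_volume_ul" in df.columns and df["loaded_volume_ul"].notna().any():
        vol = float(df["loaded_volume_ul"].dropna().iloc[0])
    return GelQuantTable(
        standard_ng=std["known_ng"].to_numpy(dtype=float),
        standard_intensity=std["intensity"].to_numpy(dtype=float),
        total_intensity=float(smp.loc["total", "intensity"]),
        upper_intensity=float(smp.loc["phos_upper", "intensity"]),
        lower_intensity=float(smp.loc["phos_lower", "intensity"]),
        loaded_volume_ul=vol,
    )


def write_gel_table(gel: GelQuantTable, path: str | Path) -> None:
    rows = [
        {"role": "standard", "band": "", "known_ng": ng, "intensity": it,
         "loaded_volume_ul": gel.loaded_volume_ul}
        for ng, it in zip(gel.standard_ng, gel.standard_intensity)
    ]
    for band, inten in [
        ("total", gel.total_intensity),
        ("phos_upper", gel.upper_intensity),
        ("phos_lower", gel.lower_intensity),
    ]:
        rows.append({"role": "sample", "band": band, "known_ng": np.nan,
                     "intensity": inten, "loaded_volume_ul": gel.loaded_volume_ul})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
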