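"""Label-free proteome statistics: differential abundance with an s0-modified
t-statistic and permutation FDR, iBAQ abundance ranks, and dysregulated-set
algebra.

The differential test follows the volcano-plot procedure common to label-free
proteomics: per protein, a two-sided equal-variance t-test on log2 LFQ
intensities, a softened statistic ``d = delta / (s + s0)`` (``s`` the pooled
standard error, ``s0`` a small constant that damps tiny-variance artefacts),
and a significance cutoff on ``|d|`` calibrated so that the permutation-
estimated false discovery rate stays at or below the configured level — the
"asymptotic lines" of the volcano plot.  A protein is called dysregulated only
when both the raw p-value and the FDR-calibrated cutoff agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class QuantTable:
    """Protein x sample intensity table in a proteinGroups-like dialect.

    ``frame`` holds a ``protein_id`` column plus ``LFQ.<sample>`` and
    ``iBAQ.<sample>`` columns; ``design`` maps each sample to exactly one
    condition.  Missing cells are NaN; present intensities must be positive.
    """

    frame: pd.DataFrame
    design: dict[str, str]

    def __post_init__(self) -> None:
        if "protein_id" not in self.frame.columns:
            raise ValueError("quant table needs a protein_id column")
        for s in self.design:
            if f"LFQ.{s}" not in self.frame.columns:
                raise ValueError(f"missing LFQ column for sample {s!r}")
        lfq = self.frame[[c for c in self.frame.columns if c.startswith("LFQ.")]]
        if (lfq <= 0).any().any():
            raise ValueError("intensities must be positive where present")

    def samples_for(self, condition: str) -> list[str]:
        out = [s for s, c in self.design.items() if c == condition]
        if not out:
            raise ValueError(f"condition {condition!r} absent from the design")
        return out

    def lfq_matrix(self, samples: Iterable[str]) -> np.ndarray:
        return self.frame[[f"LFQ.{s}" for s in samples]].to_numpy(dtype=float)

    def ibaq_matrix(self, samples: Iterable[str]) -> np.ndarray:
        return self.frame[[f"iBAQ.{s}" for s in samples]].to_numpy(dtype=float)

    @property
    def protein_ids(self) -> np.ndarray:
        return self.frame["protein_id"].to_numpy()


@dataclass
class DEConfig:
    p_threshold: float = 0.05
    fdr: float = 0.1
    s0: float = 0.1
    n_permutations: int = 250
    min_valid_per_group: int = 2
    welch: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.n_permutations < 25:
            raise ValueError("n_permutations must be >= 25")


@dataclass
class AbundanceRank:
    """Per-replicate iBAQ rank of one protein (1 = most abundant)."""

    protein: str
    condition: str
    ranks: list[int]
    mean: float
    sd: float

    def __str__(self) -> str:  # the "101 +/- 2" reporting convention
        return f"{self.mean:.0f} ± {self.sd:.0f}"


# ---------------------------------------------------------------------------
# vectorised group statistics
# ---------------------------------------------------------------------------

def _group_stats(X: np.ndarray, cols: np.ndarray):
    """nan-aware per-row count, mean and ddof-1 variance over selected columns."""
    sub = X[:, cols]
    valid = ~np.isnan(sub)
    n = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        s = np.nansum(sub, axis=1)
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        dev2 = np.nansum((sub - mean[:, None]) ** 2, axis=1)
        var = np.where(n > 1, dev2 / np.maximum(n - 1, 1), np.nan)
    return n, mean, var


def _d_statistics(
    X: np.ndarray, cols_a: np.ndarray, cols_b: np.ndarray, s0: float, welch: bool
):
    """Return (delta, t, d, p, df, retained-mask-free arrays) for all rows."""
    na, ma, va = _group_stats(X, cols_a)
    nb, mb, vb = _group_stats(X, cols_b)
    delta = mb - ma
    with np.errstate(invalid="ignore", divide="ignore"):
        if welch:
            se2 = va / na + vb / nb
            se = np.sqrt(se2)
            df = se2**2 / (
                (va / na) ** 2 / np.maximum(na - 1, 1)
                + (vb / nb) ** 2 / np.maximum(nb - 1, 1)
            )
        else:
            df = na + nb - 2
            sp2 = ((na - 1) * va + (nb - 1) * vb) / np.maximum(df, 1)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = delta / se
        d = delta / (se + s0)
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    return delta, t, d, p, na, nb


def _label_assignments(n_total: int, n_a: int, n_permutations: int, rng):
    """Distinct group-A column subsets: exhaustive when few, sampled otherwise."""
    n_all = math.comb(n_total, n_a)
    if n_all <= n_permutations:
        return [np.array(c) for c in combinations(range(n_total), n_a)], True
    assigns = []
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        assigns.append(np.sort(perm[:n_a]))
    return assigns, False


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class DAResults:
    """Per-protein differential-abundance verdicts plus the FDR cutoff."""

    frame: pd.DataFrame
    cutoff_d: float
    config: DEConfig
    cond_a: str
    cond_b: str
    excluded: list[str] = field(default_factory=list)
    exhaustive: bool = False
    n_assignments: int = 0

    def significant_proteins(self, direction: str = "either") -> set[str]:
        f = self.frame
        mask = f["significant"]
        if direction in ("up", "down"):
            mask = mask & (f["direction"] == direction)
        elif direction != "either":
            raise ValueError("direction must be 'up', 'down' or 'either'")
        return set(f.loc[mask, "protein_id"])

    def volcano_frame(self) -> pd.DataFrame:
        """Volcano coordinates (log2 difference, -log10 p) plus the cutoff."""
        out = self.frame[["protein_id", "log2_diff", "p_value", "significant"]].copy()
        out["neg_log10_p"] = -np.log10(out["p_value"])
        out["cutoff_d"] = self.cutoff_d
        return out

    def summary(self) -> pd.DataFrame:
        f = self.frame
        return pd.DataFrame(
            {
                "quantity": [
                    "proteins tested", "significant", "up", "down",
                    "|d| cutoff", "excluded (too few valid values)",
                ],
                "value": [
                    len(f),
                    int(f["significant"].sum()),
                    int((f["direction"] == "up").sum()),
                    int((f["direction"] == "down").sum()),
                    self.cutoff_d,
                    len(self.excluded),
                ],
            }
        )

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.volcano_frame()
        sig = v["significant"]
        ax.scatter(v.loc[~sig, "log2_diff"], v.loc[~sig, "neg_log10_p"],
                   s=6, c="0.6", label="ns")
        ax.scatter(v.loc[sig, "log2_diff"], v.loc[sig, "neg_log10_p"],
                   s=8, c="crimson", label="dysregulated")
        ax.set_xlabel(f"log2({self.cond_b} / {self.cond_a})")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False)
        return ax


class DifferentialAbundanceModel:
    """Pair-wise differential protein abundance between two conditions.

    Built from a :class:`QuantTable`; :meth:`fit` runs the s0-t-statistic with
    permutation-FDR calibration and returns a :class:`DAResults`.
    """

    def __init__(
        self,
        table: QuantTable,
        cond_a: str,
        cond_b: str,
        config: DEConfig | None = None,
    ):
        self.table = table
        self.cond_a = cond_a
        self.cond_b = cond_b
        self.config = config or DEConfig()
        self.samples_a = table.samples_for(cond_a)
        self.samples_b = table.samples_for(cond_b)

    def fit(self, seed: int = 0) -> DAResults:
        cfg = self.config
        samples = self.samples_a + self.samples_b
        X = np.log2(self.table.lfq_matrix(samples))
        ids = self.table.protein_ids
        n_a = len(self.samples_a)
        n_tot = len(samples)
        cols_a = np.arange(n_a)
        cols_b = np.arange(n_a, n_tot)

        delta, t, d, p, na, nb = _d_statistics(X, cols_a, cols_b, cfg.s0, cfg.welch)
        retained = (na >= cfg.min_valid_per_group) & (nb >= cfg.min_valid_per_group)
        if not retained.any():
            raise ValueError("no protein has enough valid values in both groups")
        excluded = ids[~retained].tolist()

        Xr = X[retained]
        d_obs = d[retained]
        abs_obs = np.abs(d_obs)

        rng = np.random.default_rng(seed)
        assigns, exhaustive = _label_assignments(
            n_tot, n_a, cfg.n_permutations, rng
        )
        d_perm = np.empty((len(assigns), Xr.shape[0]))
        all_cols = np.arange(n_tot)
        for j, a_cols in enumerate(assigns):
            b_cols = np.setdiff1d(all_cols, a_cols, assume_unique=True)
            _, _, dp, _, pna, pnb = _d_statistics(Xr, a_cols, b_cols, cfg.s0, cfg.welch)
            ok = (pna >= cfg.min_valid_per_group) & (pnb >= cfg.min_valid_per_group)
            d_perm[j] = np.where(ok, dp, np.nan)

        # per-protein permutation p: share of label assignments with |d| at
        # least as extreme as observed (plain fraction when exhaustive)
        abs_perm = np.abs(d_perm)
        with np.errstate(invalid="ignore"):
            n_valid = np.sum(~np.isnan(abs_perm), axis=0)
            hits = np.nansum(abs_perm >= abs_obs[None, :] - 1e-12, axis=0)
        if exhaustive:
            perm_p = hits / np.maximum(n_valid, 1)
        else:
            perm_p = (hits + 1.0) / (n_valid + 1.0)

        cutoff = self._fdr_cutoff(abs_obs, abs_perm, cfg.fdr)

        direction = np.where(delta > 0, "up", "down")
        significant = retained & (p < cfg.p_threshold) & (np.abs(d) >= cutoff)
        direction = np.where(significant, direction, "ns")

        frame = pd.DataFrame(
            {
                "protein_id": ids[retained],
                "log2_diff": delta[retained],
                "t_stat": t[retained],
                "d_stat": d_obs,
                "p_value": p[retained],
                "perm_p": perm_p,
                "significant": significant[retained],
                "direction": direction[retained],
                "n_valid_a": na[retained],
                "n_valid_b": nb[retained],
            }
        )
        return DAResults(
            frame=frame,
            cutoff_d=cutoff,
            config=cfg,
            cond_a=self.cond_a,
            cond_b=self.cond_b,
            excluded=excluded,
            exhaustive=exhaustive,
            n_assignments=len(assigns),
        )

    @staticmethod
    def _fdr_cutoff(abs_obs: np.ndarray, abs_perm: np.ndarray, fdr: float) -> float:
        """Smallest |d| threshold whose permutation-estimated FDR <= target.

        For each candidate threshold c (the observed |d| values), the expected
        false-positive count is the mean, over label assignments, of permuted
        |d| values at or above c; the FDR estimate is that mean divided by the
        observed count at or above c.
        """
        flat = np.sort(abs_perm[~np.isnan(abs_perm)])
        n_perm = abs_perm.shape[0]
        candidates = np.sort(np.unique(abs_obs))[::-1]
        obs_sorted = np.sort(abs_obs)
        cutoff = np.inf
        for c in candidates:
            r = abs_obs.size - np.searchsorted(obs_sorted, c - 1e-12, side="left")
            v = (flat.size - np.searchsorted(flat, c - 1e-12, side="left")) / n_perm
            if r > 0 and min(v / r, 1.0) <= fdr:
                cutoff = c
            # keep scanning: thresholds are visited from largest to smallest,
            # and we want the smallest one that still controls the FDR; once a
            # smaller threshold fails, earlier (larger) successes stand
        return float(cutoff)


def differential_abundance(
    table: QuantTable,
    cond_a: str,
    cond_b: str,
    config: DEConfig | None = None,
    seed: int = 0,
) -> DAResults:
    """Functional wrapper around :class:`DifferentialAbundanceModel`."""
    return DifferentialAbundanceModel(table, cond_a, cond_b, config).fit(seed=seed)


# ---------------------------------------------------------------------------
# abundance ranks
# ---------------------------------------------------------------------------

def rank_abundance(table: QuantTable, condition: str, protein: str) -> AbundanceRank:
    """Rank of one protein by iBAQ within each replicate of a condition.

    Within a replicate, proteins are sorted by iBAQ descending (rank 1 = most
    abundant); ties share the minimal rank.  Replicates where the protein is
    not quantified contribute no rank.
    """
    samples = table.samples_for(condition)
    ids = table.frame["protein_id"]
    if protein not in set(ids):
        raise ValueError(f"protein {protein!r} not present in the table")
    ranks: list[int] = []
    for s in samples:
        col = table.frame[f"iBAQ.{s}"]
        if col.loc[ids == protein].isna().all():
            continue
        r = col.rank(method="min", ascending=False)
        ranks.append(int(r.loc[ids == protein].iloc[0]))
    if not ranks:
        raise ValueError(f"protein {protein!r} quantified in no replicate of {condition!r}")
    arr = np.asarray(ranks, dtype=float)
    return AbundanceRank(
        protein=protein,
        condition=condition,
        ranks=ranks,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# set algebra over dysregulated proteins
# ---------------------------------------------------------------------------

@dataclass
class OverlapTable:
    """Exact membership of every region of the Venn diagram.

    ``membership`` maps each non-empty combination of condition names (a sorted
    tuple) to the proteins found in exactly those conditions.
    """

    conditions: list[str]
    membership: dict[tuple[str, ...], set[str]]

    def unique(self, condition: str) -> set[str]:
        return self.membership.get((condition,), set())

    @property
    def shared_all(self) -> set[str]:
        return self.membership.get(tuple(sorted(self.conditions)), set())

    def counts(self) -> pd.DataFrame:
        rows = [
            {"conditions": "&".join(k), "n": len(v), "members": ";".join(sorted(v))}
            for k, v in sorted(self.membership.items())
        ]
        return pd.DataFrame(rows)


def overlap_sets(
    results: Mapping[str, "DAResults | set[str]"],
    direction: str = "either",
) -> OverlapTable:
    """Exact set algebra over significant proteins of >= 2 result sets."""
    if len(results) < 2:
        raise ValueError("need at least 2 result sets")
    sets: dict[str, set[str]] = {}
    for name, res in results.items():
        if isinstance(res, DAResults):
            sets[name] = res.significant_proteins(direction)
        else:
            sets[name] = set(res)
    conditions = sorted(sets)
    universe = set().union(*sets.values())
    membership: dict[tuple[str, ...], set[str]] = {}
    for prot in universe:
        key = tuple(sorted(c for c in conditions if prot in sets[c]))
        membership.setdefault(key, set()).add(prot)
    return OverlapTable(conditions=conditions, membership=membership)


def remove_common_core(target: DAResults, core: set[str]) -> DAResults:
    """Drop common-core proteins from a result set, keeping all per-protein
    statistics for the remainder."""
    keep = ~target.frame["protein_id"].isin(core)
    return DAResults(
        frame=target.frame.loc[keep].reset_index(drop=True),
        cutoff_d=target.cutoff_d,
        config=target.config,
        cond_a=target.cond_a,
        cond_b=target.cond_b,
        excluded=list(target.excluded),
        exhaustive=target.exhaustive,
        n_assignments=target.n_assignments,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_quant_table(
    path: str | Path, design: Mapping[str, str], sep: str = "\t"
) -> QuantTable:
    """Read a proteinGroups-like TSV.  Rows flagged as contaminant/reverse in
    an optional ``flags`` column (any '+') are dropped."""
    df = pd.read_csv(path, sep=sep)
    if "flags" in df.columns:
        df = df[~df["flags"].astype(str).str.contains(r"\+", na=False)]
        df = df.drop(columns=["flags"]).reset_index(drop=True)
    return QuantTable(frame=df, design=dict(design))


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path, sep: str = "\t") -> dict[str, str]:
    df = pd.read_csv(path, sep=sep)
    if not {"sample", "condition"}.issubset(df.columns):
        raise ValueError("design table needs columns sample, condition")
    return dict(zip(df["sample"].astype(str), df["condition"].astype(str)))
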