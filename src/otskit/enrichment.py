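"""Over-representation analysis of protein sets against annotation catalogs.

Per category the upper-tail hypergeometric probability P[X >= k] is computed
for k overlap out of a query of size n drawn from a universe of size N that
contains K category members; p-values are Benjamini-Hochberg adjusted across
all tested categories.  Only over-representation is tested.  The default
universe should be the set of quantified proteins, not the whole proteome,
which controls for detection bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationCatalog:
    """category id -> member protein set, with optional display labels."""

    categories: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, members in self.categories.items():
            if not members:
                raise ValueError(f"category {cid!r} is empty")

    def label(self, cid: str) -> str:
        return self.labels.get(cid, cid)


@dataclass
class EnrichmentResult:
    category: str
    label: str
    k: int
    K: int
    n: int
    N: int
    expected: float
    p: float
    q: float


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    catalog: AnnotationCatalog,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Test every category for over-representation in the query; results are
    BH-adjusted and sorted by q then p."""
    if not query:
        raise ValueError("query set is empty")
    if not universe:
        raise ValueError("universe set is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for cid, members in catalog.categories.items():
        m = members & universe
        if not m <= universe:  # pragma: no cover - m is an intersection
            raise ValueError("catalog members must lie in the universe")
        K = len(m)
        if K == 0:
            continue
        k = len(query & m)
        rows.append(
            EnrichmentResult(
                category=cid,
                label=catalog.label(cid),
                k=k,
                K=K,
                n=n,
                N=N,
                expected=n * K / N,
                p=hypergeom_upper_tail(k, N, K, n),
                q=1.0,
            )
        )
    if rows:
        _, q, _, _ = multipletests([r.p for r in rows], method="fdr_bh")
        for r, qi in zip(rows, q):
            r.q = float(qi)
    rows.sort(key=lambda r: (r.q, r.p, r.category))
    return rows


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "label": r.label,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "expected": r.expected,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# catalog readers: two-column TSV or GMT
# ---------------------------------------------------------------------------

def read_catalog_tsv(
    path: str | Path, label_path: str | Path | None = None
) -> AnnotationCatalog:
    """Two-column TSV (category_id, protein_id); optional label file with
    columns category_id, label."""
    df = pd.read_csv(path, sep="\t")
    if not {"category_id", "protein_id"}.issubset(df.columns):
        raise ValueError("catalog TSV needs columns category_id, protein_id")
    cats: dict[str, set[str]] = {}
    for cid, grp in df.groupby("category_id"):
        cats[str(cid)] = set(grp["protein_id"].astype(str))
    labels = {}
    if label_path is not None:
        lab = pd.read_csv(label_path, sep="\t")
        labels = dict(zip(lab["category_id"].astype(str), lab["label"].astype(str)))
    return AnnotationCatalog(categories=cats, labels=labels)


def read_catalog_gmt(path: str | Path) -> AnnotationCatalog:
    """GMT dialect: one category per line, tab-separated
    (id, description, member, member, ...)."""
    cats: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            cid, desc, *members = parts
            cats[cid] = set(m for m in members if m)
            if desc:
                labels[cid] = desc
    return AnnotationCatalog(categories=cats, labels=labels)
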