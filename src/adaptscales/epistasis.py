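"""Dual-stress transcriptional epistasis from bulk RNA-seq counts.

The design is a 2x2 factorial of heat shock (HS) and osmotic shock (NaCl):
unstressed, heat only, salt only, and the dual stress.  Counts are
CPM-normalized with a pseudocount of 1, log2-transformed and replicate
averaged.  For each gene the single-stress log2 fold changes against the
unstressed reference combine, under the assumption of independent
(multiplicative) action of the two stresses, into an expected dual-stress
value ``ev_dual = lfc_heat + lfc_osmo``; the departure of the measured dual
response from this expectation, ``deviation = lfc_dual - ev_dual``, is the
per-gene epistasis score.  Gene sets (heat-shock-response targets, osmotic
HOG targets, ribosomal protein genes, ...) are summarized by their median
fold changes and median deviation, mirroring how such figures report median
bars per set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import BulkCounts

REFERENCE = "-HS/-NaCl"
HEAT = "+HS/-NaCl"
OSMO = "-HS/+NaCl"
DUAL = "+HS/+NaCl"
DESIGN_CONDITIONS = (REFERENCE, HEAT, OSMO, DUAL)


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: tuple

    def __post_init__(self):
        if len(self.gene_ids) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")

    def resolve(self, index: pd.Index) -> tuple[list, list]:
        """Split ids into (present, missing) against an expression index."""
        present = [g for g in self.gene_ids if g in index]
        missing = [g for g in self.gene_ids if g not in index]
        return present, missing


@dataclass
class ExpressionTable:
    """Replicate-averaged log2 CPM per condition (genes x conditions)."""

    log2_cpm: pd.DataFrame
    pseudocount: float = 1.0
    filtered: bool = False
    provenance: dict = field(default_factory=dict)


def condition_label(heat: str, salt: str) -> str:
    return f"{heat}HS/{salt}NaCl"


def normalize_bulk(
    b: BulkCounts,
    pseudocount: float = 1.0,
    min_expression_filter: bool = True,
    min_mean_cpm: float = 1.0,
) -> ExpressionTable:
    """CPM + pseudocount + log2, replicate-averaged per condition.

    The optional expression filter keeps genes whose mean CPM reaches
    ``min_mean_cpm`` in at least one condition.
    """
    counts = b.counts
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    cpm = counts / totals * 1e6
    cond = b.design.apply(
        lambda r: condition_label(r["heat"], r["salt"]), axis=1
    )
    cond = cond.loc[counts.columns]
    missing = [c for c in DESIGN_CONDITIONS if c not in set(cond)]
    if missing:
        raise ValueError(f"design is missing condition(s): {missing}")
    log2 = np.log2(cpm + pseudocount)
    avg = log2.T.groupby(cond).mean().T[list(DESIGN_CONDITIONS)]
    mean_cpm = cpm.T.groupby(cond).mean().T
    filtered = False
    if min_expression_filter:
        keep = (mean_cpm >= min_mean_cpm).any(axis=1)
        avg = avg.loc[keep]
        filtered = True
    return ExpressionTable(
        log2_cpm=avg,
        pseudocount=pseudocount,
        filtered=filtered,
        provenance={
            "normalization": "CPM",
            "pseudocount": pseudocount,
            "min_mean_cpm": min_mean_cpm if min_expression_filter else None,
        },
    )


def fold_changes(e: ExpressionTable, reference: str = REFERENCE) -> pd.DataFrame:
    """log2 fold change of every condition against the reference."""
    if reference not in e.log2_cpm.columns:
        raise ValueError(f"reference condition {reference!r} not present")
    return e.log2_cpm.sub(e.log2_cpm[reference], axis=0)


def expected_dual(lfc_heat: pd.Series, lfc_osmo: pd.Series) -> pd.Series:
    """Expected dual-stress log2 fold change under independence:
    log-additive, i.e. multiplicative on the linear scale."""
    if not lfc_heat.index.equals(lfc_osmo.index):
        raise ValueError("fold-change vectors are not aligned")
    return lfc_heat + lfc_osmo


def epistasis_table(
    e: ExpressionTable,
    reference: str = REFERENCE,
    heat: str = HEAT,
    osmo: str = OSMO,
    dual: str = DUAL,
) -> pd.DataFrame:
    """Per-gene fold changes, independence expectation and deviation.

    Columns: lfc_heat, lfc_osmo, lfc_dual, ev_dual, deviation
    (= lfc_dual - ev_dual).
    """
    lfc = fold_changes(e, reference)
    t = pd.DataFrame(
        {
            "lfc_heat": lfc[heat],
            "lfc_osmo": lfc[osmo],
            "lfc_dual": lfc[dual],
        }
    )
    t["ev_dual"] = expected_dual(t["lfc_heat"], t["lfc_osmo"])
    t["deviation"] = t["lfc_dual"] - t["ev_dual"]
    return t


def epistasis_summary(
    t: pd.DataFrame, sets: list[GeneSet] | None = None
) -> pd.DataFrame:
    """Median fold changes and median deviation per gene set, plus a
    transcriptome-wide ``all_genes`` row.  Unresolved ids are counted."""
    rows = {}

    def _row(sub: pd.DataFrame, n_missing: int) -> dict:
        return {
            "n_genes": len(sub),
            "n_unresolved": n_missing,
            "median_lfc_heat": float(sub["lfc_heat"].median()),
            "median_lfc_osmo": float(sub["lfc_osmo"].median()),
            "median_lfc_dual": float(sub["lfc_dual"].median()),
            "median_ev_dual": float(sub["ev_dual"].median()),
            "median_deviation": float(sub["deviation"].median()),
        }

    rows["all_genes"] = _row(t, 0)
    for gs in sets or []:
        present, missing = gs.resolve(t.index)
        if not present:
            raise ValueError(f"gene set {gs.name!r} resolves to no genes")
        rows[gs.name] = _row(t.loc[present], len(missing))
    return pd.DataFrame(rows).T


def condition_correlation(
    e: ExpressionTable, a: str, b: str
) -> float | None:
    """Pearson correlation of two conditions' log2 expression profiles;
    ``None`` when either column has zero variance."""
    for c in (a, b):
        if c not in e.log2_cpm.columns:
            raise ValueError(f"condition {c!r} not present")
    if len(e.log2_cpm) < 3:
        raise ValueError("need at least 3 genes")
    x = e.log2_cpm[a].to_numpy()
    y = e.log2_cpm[b].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def strain_concordance(
    anc: ExpressionTable, der: ExpressionTable, condition: str
) -> tuple[float, int]:
    """Squared Pearson correlation of per-gene log2 expression between two
    strains in the same condition, over the shared gene universe.

    Returns ``(r_squared, n_shared_genes)``.
    """
    for e in (anc, der):
        if condition not in e.log2_cpm.columns:
            raise ValueError(f"condition {condition!r} not present")
    shared = anc.log2_cpm.index.intersection(der.log2_cpm.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    x = anc.log2_cpm.loc[shared, condition].to_numpy()
    y = der.log2_cpm.loc[shared, condition].to_numpy()
    r = stats.pearsonr(x, y).statistic
    return float(r**2), int(len(shared))
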