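"""Linking cell densities to compartment-specific transcriptomes.

The expression input is a normalized genes (or probes) x samples matrix
from microdissected epithelial or stromal tissue.  Probes mapping to the
same gene are collapsed to the single highest-variance probe.  Each
(gene, subtype-density) pair is scored by Spearman correlation over the
shared samples and flagged at |r| > 0.4 and p < 0.05; candidate genes are
then intersected with user-supplied cell-type gene sets (e.g. scRNA-seq
derived fibroblast/epithelial lists) and optionally with a
secreted/receptor annotation, with named subtype exemptions.

Prognostic value of a gene is assessed by a best-cutoff Kaplan-Meier
scan: patients are dichotomized at each expression quantile on a grid,
a two-group log-rank test is computed at each cutoff, and the cutoff
with the smallest p is reported.  The scan minimizes p over many tests,
so the selected p-value is anti-conservative; the result carries an
explicit caveat and the full scan trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from lifelines.statistics import logrank_test

__all__ = [
    "collapse_probes",
    "correlate_density_expression",
    "filter_by_celltype",
    "km_best_cutoff",
    "KMResult",
]

BEST_CUTOFF_CAVEAT = (
    "best-cutoff selection minimizes p over the quantile scan; the reported "
    "p-value is anti-conservative and exceeds its nominal false-positive rate"
)


def collapse_probes(
    expr: pd.DataFrame, probe_map: Mapping[str, str] | pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse probes to genes, keeping the highest-variance probe per gene.

    ``expr`` is probes x samples; ``probe_map`` maps probe id -> gene
    symbol.  Unmapped probes pass through under their probe id, flagged in
    the log.  Variance ties keep the lexicographically smallest probe id.
    Returns (gene-level matrix, log of per-probe decisions).
    """
    probe_map = pd.Series(probe_map)
    variances = expr.var(axis=1, ddof=1)
    records = []
    keep_rows: dict[str, str] = {}  # gene -> probe
    for probe in expr.index:
        gene = probe_map.get(probe)
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            keep_rows[probe] = probe
            records.append({"probe": probe, "gene": probe, "kept": True, "unmapped": True})
            continue
        prev = keep_rows.get(gene)
        if prev is None:
            keep_rows[gene] = probe
        else:
            v_new, v_old = variances[probe], variances[prev]
            if v_new > v_old or (v_new == v_old and str(probe) < str(prev)):
                keep_rows[gene] = probe
    for probe in expr.index:
        gene = probe_map.get(probe)
        if gene is not None and not (isinstance(gene, float) and np.isnan(gene)):
            records.append(
                {"probe": probe, "gene": gene, "kept": keep_rows[gene] == probe, "unmapped": False}
            )
    genes = sorted(keep_rows)
    collapsed = expr.loc[[keep_rows[g] for g in genes]].copy()
    collapsed.index = genes
    return collapsed, pd.DataFrame.from_records(records)


def correlate_density_expression(
    expr: pd.DataFrame,
    densities: pd.DataFrame,
    subtypes: Sequence[str] | None = None,
    r_min: float = 0.4,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Spearman r and p for every (gene, subtype density) pair.

    Computed over the samples shared between the two matrices (requires at
    least 5).  Each row carries pass flags for ``|r| > r_min`` and
    ``p < p_max`` plus their conjunction and the sign of r; constant genes
    fail with an explicit reason.
    """
    if subtypes is None:
        subtypes = list(densities.columns)
    shared = expr.columns.intersection(densities.index)
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, got {len(shared)}")
    E = expr[shared]
    D = densities.loc[shared]
    records = []
    for gene in E.index:
        x = E.loc[gene].to_numpy(dtype=float)
        constant = np.all(x == x[0])
        for subtype in subtypes:
            y = D[subtype].to_numpy(dtype=float)
            rec = {"gene": gene, "subtype": subtype, "n": len(shared)}
            if constant or np.all(y == y[0]):
                rec.update(r=np.nan, p=np.nan, pass_r=False, pass_p=False, passed=False,
                           sign=0, reason="constant series, Spearman undefined")
            else:
                r, p = scipy.stats.spearmanr(x, y)
                rec.update(
                    r=float(r), p=float(p),
                    pass_r=bool(abs(r) > r_min), pass_p=bool(p < p_max),
                    passed=bool(abs(r) > r_min and p < p_max),
                    sign=int(np.sign(r)), reason="",
                )
            records.append(rec)
    return pd.DataFrame.from_records(records)


def filter_by_celltype(
    genes: Sequence[str],
    allowed: Sequence[str],
    secreted_or_receptor: Sequence[str] | None = None,
    exempt: bool = False,
) -> list[str]:
    """Intersect candidate genes with a compartment gene set, in input order.

    ``allowed`` is the cell-type gene list (scRNA-seq derived, user
    supplied).  When ``secreted_or_receptor`` is given, genes must also be
    on that annotation list — unless ``exempt`` is set (the all-genes
    exemption used for CAF subtypes and the B7H4+ tumor subtype, where the
    full transcriptome is of interest).
    """
    if len(allowed) == 0:
        raise ValueError("empty cell-type gene set")
    allowed_set = set(allowed)
    out = [g for g in genes if g in allowed_set]
    if secreted_or_receptor is not None and not exempt:
        annot = set(secreted_or_receptor)
        out = [g for g in out if g in annot]
    return out


@dataclass
class KMResult:
    gene: str
    cutoff_quantile: float
    cutoff_value: float
    n_low: int
    n_high: int
    chi_square: float
    p: float
    scan: pd.DataFrame = field(repr=False, default=None)
    caveat: str = BEST_CUTOFF_CAVEAT


def km_best_cutoff(
    gene_expr: pd.Series,
    survival: pd.DataFrame,
    quantiles: Sequence[float] | None = None,
    min_group_size: int = 4,
) -> KMResult:
    """Best-cutoff Kaplan-Meier log-rank scan for one gene.

    ``survival`` has columns ``os_months`` and ``event`` indexed by sample;
    expression is dichotomized at each quantile of the default 10%-90%
    (step 5%) grid, cutoffs leaving fewer than ``min_group_size`` patients
    in either arm are skipped, and the cutoff with the smallest log-rank p
    is selected.  The full scan trace ships with the result, along with the
    anti-conservatism caveat.
    """
    if quantiles is None:
        quantiles = np.arange(0.10, 0.901, 0.05)
    shared = gene_expr.index.intersection(survival.index)
    expr = gene_expr.loc[shared].astype(float)
    surv = survival.loc[shared]
    if surv["event"].sum() == 0:
        raise ValueError("all-censored cohort: log-rank test undefined")
    rows = []
    for q in quantiles:
        cut = float(expr.quantile(q))
        low = expr <= cut
        n_low, n_high = int(low.sum()), int((~low).sum())
        if n_low < min_group_size or n_high < min_group_size:
            rows.append({"quantile": float(q), "cutoff": cut, "n_low": n_low,
                         "n_high": n_high, "chi_square": np.nan, "p": np.nan,
                         "skipped": True})
            continue
        res = logrank_test(
            surv.loc[low.values, "os_months"], surv.loc[~low.values, "os_months"],
            event_observed_A=surv.loc[low.values, "event"],
            event_observed_B=surv.loc[~low.values, "event"],
        )
        rows.append({"quantile": float(q), "cutoff": cut, "n_low": n_low, "n_high": n_high,
                     "chi_square": float(res.test_statistic), "p": float(res.p_value),
                     "skipped": False})
    scan = pd.DataFrame(rows)
    valid = scan[~scan["skipped"]]
    if valid.empty:
        raise ValueError("no cutoff leaves both groups at the minimum size")
    best = valid.loc[valid["p"].idxmin()]
    return KMResult(
        gene=str(gene_expr.name),
        cutoff_quantile=best["quantile"],
        cutoff_value=best["cutoff"],
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        chi_square=best["chi_square"],
        p=best["p"],
        scan=scan,
    )
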