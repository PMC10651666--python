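"""Probe-to-gene collapse and cross-cohort replication.

External microarray cohorts arrive as per-probe statistics tables
(gene, probe, log2FC, p-value), one per sex.  Probes collapse to genes
by the significance-first averaging rule: if at least one probe of a
gene is significant (p < alpha), the gene's value is the arithmetic
mean of -log10 p and of log2FC over the significant probes only;
otherwise the mean over all probes.  -log p is base 10, consistent with
the DEG rule -log10 p > 2 <=> p < 0.01.

When a cohort is supplied as a probe x sample log2-expression matrix
instead, per-probe statistics are computed with Welch's t-test on the
old-vs-young contrast (mean difference on the log2 scale as log2FC).

The replication report re-runs the DEG partition and the cross-sex
concordance per cohort on the collapsed gene tables and reports the
female DEG excess 100*(n_f - n_m)/n_m.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .concord import concordance_stats, partition_degs
from .diffexpr import DEResult
from .errors import ValidationError
from .simulate import AGE_GROUPS, SEXES

__all__ = [
    "collapse_probes",
    "probe_de_from_expression",
    "gene_stats_to_de_result",
    "cohort_replication",
]

PROBE_COLUMNS = ["gene", "probe", "log2fc", "p_value"]
GENE_COLUMNS = ["gene", "neg_log10_p", "log2fc", "n_probes_used", "collapse_mode"]


def _validate_probe_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROBE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"probe table missing columns: {missing}")
    if table["gene"].isna().any() or (table["gene"].astype(str).str.strip() == "").any():
        raise ValidationError("every probe row needs a gene symbol")
    p = table["p_value"].to_numpy(dtype=float)
    if not ((p > 0) & (p <= 1)).all():
        raise ValidationError("p-values must lie in (0, 1]")
    dup = table.duplicated(subset=["gene", "probe"])
    if dup.any():
        g, pr = table.loc[dup.idxmax(), ["gene", "probe"]]
        raise ValidationError(f"duplicate (gene, probe) row: ({g!r}, {pr!r})")
    return table


def collapse_probes(table: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Collapse a per-probe table to one row per gene.

    Returns a DataFrame with columns ``gene, neg_log10_p, log2fc,
    n_probes_used, collapse_mode``; mode is ``single`` for one-probe
    genes, ``significant_only`` when the average ran over the p < alpha
    probes, ``all_probes`` otherwise.  Input ``attrs`` (cohort, sex) are
    propagated.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha!r}")
    table = _validate_probe_table(table)
    df = table.assign(neg_log10_p=-np.log10(table["p_value"]))
    rows = []
    for gene, grp in df.groupby("gene", sort=True):
        sig = grp[grp["p_value"] < alpha]
        if len(grp) == 1:
            used, mode = grp, "single"
        elif len(sig):
            used, mode = sig, "significant_only"
        else:
            used, mode = grp, "all_probes"
        rows.append(
            (gene, used["neg_log10_p"].mean(), used["log2fc"].mean(), len(used), mode)
        )
    out = pd.DataFrame(rows, columns=GENE_COLUMNS)
    out.attrs.update(table.attrs)
    return out


def probe_de_from_expression(
    expr: pd.DataFrame, meta: pd.DataFrame, sex: str
) -> pd.DataFrame:
    """Per-probe Welch t statistics from a probe x sample log2 matrix.

    log2FC is the old-minus-young mean difference (the matrix is already
    on the log2 scale).  Returns a probe table whose ``gene`` column
    defaults to the probe identifier when no annotation is attached.
    """
    if sex not in SEXES:
        raise ValidationError(f"unknown sex label {sex!r}")
    vals = expr.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.isfinite(vals).all():
        raise ValidationError("expression matrix must be numeric and finite")
    meta = meta.loc[expr.columns]
    groups = {
        age: expr.columns[(meta["sex"] == sex) & (meta["age_group"] == age)]
        for age in AGE_GROUPS
    }
    if any(len(groups[a]) < 2 for a in AGE_GROUPS):
        raise ValidationError(f"need >= 2 samples per age group for sex={sex!r}")
    young = expr[groups["young"]].to_numpy()
    old = expr[groups["old"]].to_numpy()
    res = stats.ttest_ind(old, young, axis=1, equal_var=False)
    genes = expr.index.to_series().astype(str)
    gene_col = expr.attrs.get("probe_to_gene")
    out = pd.DataFrame(
        {
            "gene": genes.map(gene_col) if gene_col else genes,
            "probe": expr.index.astype(str),
            "log2fc": old.mean(axis=1) - young.mean(axis=1),
            "p_value": np.clip(res.pvalue, 1e-300, 1.0),
        }
    ).reset_index(drop=True)
    out.attrs["sex"] = sex
    return out


def gene_stats_to_de_result(gene_stats: pd.DataFrame, sex: str) -> DEResult:
    """View a collapsed gene table as a DEResult for partition/concordance."""
    missing = [c for c in ("gene", "neg_log10_p", "log2fc") if c not in gene_stats.columns]
    if missing:
        raise ValidationError(f"gene table missing columns: {missing}")
    tab = pd.DataFrame(
        {
            "log2fc": gene_stats["log2fc"].to_numpy(dtype=float),
            "p_value": np.power(10.0, -gene_stats["neg_log10_p"].to_numpy(dtype=float)),
            "neg_log10_p": gene_stats["neg_log10_p"].to_numpy(dtype=float),
            "base_mean": np.nan,
        },
        index=pd.Index(gene_stats["gene"], name="gene"),
    ).sort_index()
    return DEResult(table=tab, sex=sex)


def _set_concordance(de_m: DEResult, de_f: DEResult, genes) -> dict | None:
    genes = sorted(genes)
    if len(genes) < 2:
        return None
    x = de_m.table["log2fc"].reindex(genes).to_numpy()
    y = de_f.table["log2fc"].reindex(genes).to_numpy()
    if np.ptp(x) == 0:
        return None
    return concordance_stats(x, y).to_dict()


def cohort_replication(cohorts: dict[str, dict[str, pd.DataFrame]], alpha: float = 0.01) -> dict:
    """Replication report across cohorts of collapsed gene tables.

    ``cohorts`` maps cohort label -> {'male': GeneStatsTable,
    'female': GeneStatsTable} on a common per-cohort gene universe.
    Per cohort the report carries DEG counts per sex, the female-excess
    percentage, the Venn partition counts and concordance statistics for
    the shared and sex-specific sets (None where fewer than two genes).
    """
    report: dict[str, dict] = {}
    for name, tables in cohorts.items():
        for sex in SEXES:
            if sex not in tables:
                raise ValidationError(f"cohort {name!r} is missing the {sex} table")
        de_m = gene_stats_to_de_result(tables["male"], "male")
        de_f = gene_stats_to_de_result(tables["female"], "female")
        part = partition_degs(de_m, de_f, alpha=alpha)
        thresh = -np.log10(alpha)
        n_m = int((de_m.table["neg_log10_p"] > thresh).sum())
        n_f = int((de_f.table["neg_log10_p"] > thresh).sum())
        report[name] = {
            "alpha": alpha,
            "n_deg_male": n_m,
            "n_deg_female": n_f,
            "female_excess_pct": 100.0 * (n_f - n_m) / n_m if n_m else float("nan"),
            "partition": part.counts(),
            "concordance": {
                s: _set_concordance(de_m, de_f, part.set_for(s))
                for s in ("shared", "male_specific", "female_specific")
            },
        }
    return report
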