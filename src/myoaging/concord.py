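"""Cross-sex direction-of-regulation analysis.

Given per-sex old-vs-young DE tables on a common gene universe, this
module partitions DEGs into shared / male-specific / female-specific /
neither sets (Venn partition at a common alpha) and computes the
direction-concordance statistics used to compare the sexes: the
percentage of genes regulated in the same direction (sign agreement of
the two log2FCs, the Q2+Q3 quadrants of a male-vs-female fold-change
scatter), the Pearson correlation, and the OLS regression of female
log2FC on male log2FC whose slope m reads as the cross-sex magnitude
ratio.

Pairs in which either log2FC is exactly zero carry no direction and are
excluded from the same/opposite percentages (reported separately as
``n_zero``).  The slope is fitted with an intercept, matching the usual
plotted regression-line convention; OLS attenuation under noisy x is
inherited, not corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult
from .errors import StatsUndefinedError, ValidationError

__all__ = [
    "DEGPartition",
    "ConcordanceStats",
    "partition_degs",
    "concordance_stats",
    "geneset_concordance",
    "ranked_logp_profile",
    "pct_upregulated",
]

logger = logging.getLogger(__name__)

SELECTIONS = ("all_in_list", "degs_in_list_either_sex", "degs_in_list_one_sex")


@dataclass(frozen=True)
class DEGPartition:
    """Venn partition of a common gene universe at significance alpha."""

    shared: frozenset
    male_specific: frozenset
    female_specific: frozenset
    neither: frozenset
    alpha: float

    @property
    def universe_size(self) -> int:
        return len(self.shared) + len(self.male_specific) + len(self.female_specific) + len(self.neither)

    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "male_specific": len(self.male_specific),
            "female_specific": len(self.female_specific),
            "neither": len(self.neither),
        }

    def set_for(self, name: str) -> frozenset:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown partition set {name!r}") from None


@dataclass(frozen=True)
class ConcordanceStats:
    """Direction and magnitude agreement of paired (male, female) log2FCs."""

    n_pairs: int
    pct_same_direction: float
    pct_opposite: float
    n_zero: int
    pearson_r: float
    slope_m: float
    intercept: float
    regression_p: float
    n_genes_matched: int | None = field(default=None, compare=False)
    n_genes_listed: int | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        d = {
            "n_pairs": self.n_pairs,
            "pct_same_direction": self.pct_same_direction,
            "pct_opposite": self.pct_opposite,
            "n_zero": self.n_zero,
            "pearson_r": self.pearson_r,
            "slope_m": self.slope_m,
            "intercept": self.intercept,
            "regression_p": self.regression_p,
        }
        if self.n_genes_matched is not None:
            d["n_genes_matched"] = self.n_genes_matched
            d["n_genes_listed"] = self.n_genes_listed
        return d


def _check_universe(de_male: DEResult, de_female: DEResult) -> None:
    gm, gf = set(de_male.genes), set(de_female.genes)
    if gm != gf:
        raise ValidationError(
            f"gene universes differ: symmetric difference of {len(gm ^ gf)} genes"
        )


def partition_degs(de_male: DEResult, de_female: DEResult, alpha: float = 0.01) -> DEGPartition:
    """Partition the common universe by per-sex significance at raw p < alpha."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha!r}")
    _check_universe(de_male, de_female)
    pm = de_male.table["p_value"]
    pf = de_female.table["p_value"].reindex(pm.index)
    sig_m, sig_f = pm < alpha, pf < alpha
    idx = pm.index
    return DEGPartition(
        shared=frozenset(idx[sig_m & sig_f]),
        male_specific=frozenset(idx[sig_m & ~sig_f]),
        female_specific=frozenset(idx[~sig_m & sig_f]),
        neither=frozenset(idx[~sig_m & ~sig_f]),
        alpha=alpha,
    )


def concordance_stats(lfc_male, lfc_female) -> ConcordanceStats:
    """Direction agreement and OLS of female log2FC (y) on male log2FC (x).

    ``pct_same_direction`` is computed over pairs where both values are
    nonzero; R, the slope m, its intercept and two-sided p come from
    ordinary least squares with intercept.
    """
    x = np.asarray(lfc_male, dtype=float)
    y = np.asarray(lfc_female, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("lfc_male and lfc_female must be 1-D and equally long")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("log2FC values must be finite")
    n = len(x)
    if n < 2:
        raise StatsUndefinedError(f"concordance needs >= 2 pairs, got {n}")
    if np.ptp(x) == 0:
        raise StatsUndefinedError("zero variance in male log2FC; regression undefined")
    nz = (x != 0) & (y != 0)
    n_nz = int(nz.sum())
    if n_nz:
        same = float(np.mean(np.sign(x[nz]) == np.sign(y[nz]))) * 100.0
    else:
        same = float("nan")
    fit = stats.linregress(x, y)
    return ConcordanceStats(
        n_pairs=n,
        pct_same_direction=same,
        pct_opposite=100.0 - same if n_nz else float("nan"),
        n_zero=n - n_nz,
        pearson_r=float(fit.rvalue),
        slope_m=float(fit.slope),
        intercept=float(fit.intercept),
        regression_p=float(fit.pvalue),
    )


def concordance_for_genes(de_male: DEResult, de_female: DEResult, genes) -> ConcordanceStats:
    """Concordance of the (male, female) log2FC pairs of ``genes``."""
    genes = pd.Index(sorted(genes))
    x = de_male.table["log2fc"].reindex(genes)
    y = de_female.table["log2fc"].reindex(genes)
    if x.isna().any() or y.isna().any():
        raise ValidationError("some genes are missing from a DE table")
    return concordance_stats(x.to_numpy(), y.to_numpy())


def _match_gene_list(universe: pd.Index, gene_list) -> tuple[pd.Index, int]:
    """Case-insensitive symbol matching; unmatched entries are logged."""
    wanted = {str(g).strip().lower() for g in gene_list if str(g).strip()}
    if not wanted:
        raise ValidationError("gene list is empty")
    lower = pd.Index([str(g).lower() for g in universe])
    hit = lower.isin(wanted)
    matched = universe[hit]
    n_unmatched = len(wanted) - len(set(lower[hit]))
    if n_unmatched:
        logger.warning("%d gene-list entries not found in the DE tables", n_unmatched)
    return matched, len(wanted)


def geneset_concordance(
    de_male: DEResult,
    de_female: DEResult,
    gene_list,
    selection: str = "all_in_list",
    alpha: float = 0.01,
    list_name: str = "gene list",
) -> ConcordanceStats:
    """Concordance restricted to a gene list.

    ``selection`` controls which listed genes enter the pairs: every
    matched gene (``all_in_list``), only those significant in at least
    one sex (``degs_in_list_either_sex``), or only those significant in
    exactly one sex (``degs_in_list_one_sex``).
    """
    if selection not in SELECTIONS:
        raise ValidationError(f"selection must be one of {SELECTIONS}, got {selection!r}")
    _check_universe(de_male, de_female)
    matched, n_listed = _match_gene_list(de_male.genes, gene_list)
    if len(matched) == 0:
        raise ValidationError(f"no genes of {list_name!r} found in the DE tables")
    if selection != "all_in_list":
        part = partition_degs(de_male, de_female, alpha=alpha)
        if selection == "degs_in_list_either_sex":
            keep = part.shared | part.male_specific | part.female_specific
        else:
            keep = part.male_specific | part.female_specific
        matched = pd.Index([g for g in matched if g in keep])
        if len(matched) == 0:
            raise ValidationError(
                f"no DEGs of {list_name!r} under selection {selection!r}"
            )
    cs = concordance_for_genes(de_male, de_female, matched)
    return ConcordanceStats(
        **{**cs.to_dict(), "n_genes_matched": len(matched), "n_genes_listed": n_listed}
    )


def ranked_logp_profile(de_male: DEResult, de_female: DEResult, gene_list) -> pd.DataFrame:
    """Genes of a list ranked by their average -log10 p across the sexes.

    Rows sort descending on (male + female)/2 of -log10 p; ties break
    lexicographically on the gene identifier.
    """
    matched, _ = _match_gene_list(de_male.genes.intersection(de_female.genes), gene_list)
    if len(matched) == 0:
        raise ValidationError("no listed genes present in both DE tables")
    out = pd.DataFrame(
        {
            "neg_log10_p_male": de_male.table["neg_log10_p"].reindex(matched),
            "neg_log10_p_female": de_female.table["neg_log10_p"].reindex(matched),
        }
    )
    out["mean_neg_log10_p"] = (out["neg_log10_p_male"] + out["neg_log10_p_female"]) / 2
    # lexicographic pre-sort + stable descending sort on the key = ties in gene order
    out = out.sort_index(kind="stable").sort_values(
        "mean_neg_log10_p", ascending=False, kind="stable"
    )
    out.index.name = "gene"
    return out.drop(columns="mean_neg_log10_p")


def pct_upregulated(de: DEResult, gene_set, alpha: float = 0.01) -> float:
    """Percentage of DEGs in a set with positive log2FC; NaN if no DEGs."""
    genes = pd.Index(sorted(set(gene_set)))
    if len(genes) == 0:
        raise ValidationError("gene_set is empty")
    sub = de.table.reindex(genes).dropna(subset=["p_value"])
    degs = sub[sub["p_value"] < alpha]
    if len(degs) == 0:
        logger.warning("no DEGs in the gene set at alpha=%s; percentage undefined", alpha)
        return float("nan")
    return 100.0 * float((degs["log2fc"] > 0).mean())
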