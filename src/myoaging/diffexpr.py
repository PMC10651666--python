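"""Per-sex old-vs-young differential expression on count data.

Normalization uses the median-of-ratios construction: the reference
pseudo-sample is the per-gene geometric mean over samples, and a
sample's size factor is the median count ratio against that reference
over genes expressed in every sample (rescaled to geometric mean 1).

The test is a per-gene negative-binomial Wald test on the normalized
old/young mean contrast.  The gene-wise dispersion phi is estimated by
method of moments from the pooled within-group variance
(phi = (s2 - m) / m**2, floored), the log2 fold change is
log2((mean_old + c) / (mean_young + c)) with pseudo-count c, and the
Wald statistic lfc / se(lfc) (delta-method standard error under
var = mu + phi*mu**2) is referred to a t distribution with
n_old + n_young - 2 degrees of freedom to account for the estimated
dispersion at the modest group sizes typical of human biopsy studies.

Differential expression is called at raw p < alpha (default 0.01, i.e.
-log10 p > 2); Benjamini-Hochberg adjusted p-values are reported
alongside but never used for calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import NormalizationError, StatsUndefinedError, ValidationError
from .simulate import AGE_GROUPS, SEXES, CountMatrix

__all__ = ["DEResult", "size_factors", "normalized_counts", "de_test", "summarize_de", "pca_embed"]

#: Pseudo-count (in normalized-count units) added to both group means
#: before taking the log ratio, keeping log2FC finite for sparse genes.
PSEUDOCOUNT = 0.5

#: Lower bound on the method-of-moments dispersion estimate.
MIN_DISPERSION = 1e-8


@dataclass
class DEResult:
    """Old-vs-young statistics for one sex.

    ``table`` is indexed by gene with columns ``log2fc``, ``p_value``,
    ``neg_log10_p``, ``base_mean`` and ``p_adj`` (Benjamini-Hochberg).
    """

    table: pd.DataFrame
    sex: str

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def degs(self, alpha: float = 0.01) -> pd.Index:
        return self.table.index[self.table["p_value"] < alpha]


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with nonzero counts in every sample; if no
    such gene exists normalization is impossible.
    """
    mat = _as_frame(counts)
    if mat.shape[1] < 2:
        raise ValidationError("size factors require at least 2 samples")
    x = mat.to_numpy(dtype=float)
    ref = (x > 0).all(axis=1)
    if not ref.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; cannot form the "
            "median-of-ratios reference"
        )
    logx = np.log(x[ref])
    log_geo = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - log_geo, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def normalized_counts(counts: CountMatrix | pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    mat = _as_frame(counts)
    if factors is None:
        factors = size_factors(mat)
    return mat / factors


def de_test(
    counts: CountMatrix,
    meta: pd.DataFrame | None = None,
    sex: str = "male",
    pseudocount: float = PSEUDOCOUNT,
    factors: pd.Series | None = None,
) -> DEResult:
    """NB Wald test of old vs young within one sex.

    Genes with all-zero counts get log2fc 0 and p 1.  Requires at least
    two samples per age group.  ``factors`` supplies precomputed size
    factors; by default median-of-ratios factors are estimated from the
    same-sex samples.
    """
    if isinstance(counts, CountMatrix):
        mat, meta = counts.counts, counts.sample_meta
    else:
        mat = counts
        if meta is None:
            raise ValidationError("sample metadata is required")
    if sex not in SEXES:
        raise ValidationError(f"unknown sex label {sex!r}; expected one of {SEXES}")
    meta = meta.loc[mat.columns]
    cols = {
        age: mat.columns[(meta["sex"] == sex) & (meta["age_group"] == age)]
        for age in AGE_GROUPS
    }
    n_young, n_old = len(cols["young"]), len(cols["old"])
    if n_young < 2 or n_old < 2:
        raise ValidationError(
            f"need >= 2 samples per age group for sex={sex!r}; "
            f"got young={n_young}, old={n_old}"
        )
    sub = mat[list(cols["young"]) + list(cols["old"])]
    norm = normalized_counts(sub, factors[sub.columns] if factors is not None else None).to_numpy()
    y = norm[:, :n_young]
    o = norm[:, n_young:]

    m_y, m_o = y.mean(axis=1), o.mean(axis=1)
    s2_pooled = ((n_young - 1) * y.var(axis=1, ddof=1) + (n_old - 1) * o.var(axis=1, ddof=1)) / (
        n_young + n_old - 2
    )
    m_bar = (m_y + m_o) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(m_bar > 0, (s2_pooled - m_bar) / np.square(m_bar), 0.0)
    phi = np.maximum(phi, MIN_DISPERSION)

    lfc = np.log2((m_o + pseudocount) / (m_y + pseudocount))
    var_mean_y = (m_y + phi * m_y**2) / n_young
    var_mean_o = (m_o + phi * m_o**2) / n_old
    se = np.sqrt(
        var_mean_y / np.square(m_y + pseudocount) + var_mean_o / np.square(m_o + pseudocount)
    ) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc / se, 0.0)
    p = 2 * stats.t.sf(np.abs(wald), df=n_young + n_old - 2)
    p = np.where(lfc == 0, 1.0, p)
    p = np.clip(p, 1e-300, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
            "base_mean": norm.mean(axis=1),
            "p_adj": multipletests(p, method="fdr_bh")[1],
        },
        index=mat.index,
    )
    return DEResult(table=table, sex=sex)


def summarize_de(de: DEResult, alpha: float = 0.01) -> tuple[int, int]:
    """Counts of up- and downregulated DEGs at raw p < alpha."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha!r}")
    sig = de.table["p_value"] < alpha
    n_up = int((sig & (de.table["log2fc"] > 0)).sum())
    n_down = int((sig & (de.table["log2fc"] < 0)).sum())
    return n_up, n_down


def pca_embed(
    counts: CountMatrix,
    n_top_genes: int = 5000,
    top_by: str = "variance",
    scores: pd.Series | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on centered log2(normalized count + 1).

    Genes are restricted to the ``n_top_genes`` most variable on the
    normalized log scale (``top_by='variance'``, the default) or to the
    highest-``scores`` genes when a precomputed ranking (e.g. DE
    -log10 p) is supplied with ``top_by='scores'``.

    Returns (sample coordinates, explained-variance fractions).
    """
    mat = _as_frame(counts)
    if mat.shape[1] < 3:
        raise ValidationError("PCA requires at least 3 samples")
    if n_top_genes > mat.shape[0]:
        raise ValidationError(
            f"n_top_genes={n_top_genes} exceeds the {mat.shape[0]} genes available"
        )
    logn = np.log2(normalized_counts(mat) + 1.0)
    if top_by == "variance":
        rank = logn.var(axis=1)
    elif top_by == "scores":
        if scores is None:
            raise ValidationError("top_by='scores' requires a scores Series")
        rank = scores.reindex(mat.index).fillna(-np.inf)
    else:
        raise ValidationError(f"unknown top_by {top_by!r}")
    keep = rank.nlargest(n_top_genes).index
    x = logn.loc[keep].to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u * s
    total = np.sum(x**2)
    if total == 0:
        raise StatsUndefinedError("zero variance across samples; PCA undefined")
    frac = s**2 / total
    k = coords.shape[1]
    out = pd.DataFrame(coords, index=mat.columns, columns=[f"PC{i + 1}" for i in range(k)])
    return out, frac
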