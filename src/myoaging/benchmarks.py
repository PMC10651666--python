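"""Canonical simulation scenarios and replicate summaries.

Two standing scenarios exercise the whole DE -> partition -> concordance
chain under the primary study's design (group sizes 13/28 males and
13/26 females, NB dispersion 0.05, baselines log-uniform on [20, 2000],
dominant |log2FC| uniform on [0.5, 2.0]):

``shared_only``
    2,000 genes with identical true effects in both sexes plus 8,000
    null genes — the regime for measuring sign concordance of shared
    DEGs;
``mixed``
    2,000 shared + 700 male-stronger + 2,600 female-stronger genes
    (cross-sex attenuation 0.25) + 7,000 null — an asymmetric regime
    in which more DEGs are called in females than in males.
"""

from __future__ import annotations

import numpy as np

from .concord import concordance_for_genes, partition_degs
from .diffexpr import de_test
from .simulate import SimConfig, simulate_counts

__all__ = ["shared_only_config", "mixed_config", "run_replicate", "replicate_summary"]


def shared_only_config(seed: int) -> SimConfig:
    return SimConfig(
        n_genes_shared=2000,
        n_genes_male_block=0,
        n_genes_female_block=0,
        n_genes_null=8000,
        seed=seed,
    )


def mixed_config(seed: int, attenuation: float = 0.25) -> SimConfig:
    return SimConfig(
        n_genes_shared=2000,
        n_genes_male_block=700,
        n_genes_female_block=2600,
        n_genes_null=7000,
        attenuation_male_block=attenuation,
        attenuation_female_block=attenuation,
        seed=seed,
    )


def run_replicate(config: SimConfig, alpha: float = 0.01) -> dict:
    """Simulate once and collect DEG counts and per-set concordance."""
    cm, _ = simulate_counts(config)
    de_m = de_test(cm, sex="male")
    de_f = de_test(cm, sex="female")
    part = partition_degs(de_m, de_f, alpha=alpha)
    n_m = len(de_m.degs(alpha))
    n_f = len(de_f.degs(alpha))
    out = {
        "seed": config.seed,
        "n_deg_male": n_m,
        "n_deg_female": n_f,
        "female_excess_pct": 100.0 * (n_f - n_m) / n_m if n_m else float("nan"),
    }
    for name in ("shared", "male_specific", "female_specific"):
        genes = part.set_for(name)
        out[f"{name}_pct_same"] = (
            concordance_for_genes(de_m, de_f, genes).pct_same_direction
            if len(genes) >= 2
            else float("nan")
        )
    return out


def replicate_summary(config_fn, seeds, alpha: float = 0.01) -> dict:
    """Mean over replicate seeds of every statistic from :func:`run_replicate`."""
    rows = [run_replicate(config_fn(s), alpha=alpha) for s in seeds]
    keys = [k for k in rows[0] if k != "seed"]
    return {k: float(np.mean([r[k] for r in rows])) for k in keys} | {
        "n_replicates": len(rows)
    }
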