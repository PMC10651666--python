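"""End-to-end pipeline: simulate (or load) -> per-sex DE -> partition ->
concordance (overall and per gene list) -> optional cohort harmonization.

All numbers end up in a single JSON report with provenance (package
version, seed, alpha); every source of randomness derives from the one
configuration seed through named substreams, so a run is reproducible
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .concord import (
    concordance_for_genes,
    geneset_concordance,
    partition_degs,
    pct_upregulated,
)
from .diffexpr import de_test, pca_embed, summarize_de
from .errors import ConfigError, MyoagingError
from .harmonize import cohort_replication, collapse_probes
from .io import (
    read_counts,
    read_gene_list,
    write_counts,
    write_de_result,
    write_gene_list,
    write_json,
    write_sample_meta,
    write_table,
)
from .simulate import SEXES, SimConfig, simulate_cohort, simulate_counts

logger = logging.getLogger(__name__)

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}
_KNOWN_KEYS = {
    "scenario",
    "seed",
    "alpha",
    "counts",
    "sample_meta",
    "simulate",
    "gene_lists",
    "cohorts",
    "n_top_genes_pca",
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration of a full run."""

    alpha: float = 0.01
    seed: int = 0
    scenario: str = "paper-structure"
    counts: str | None = None  # path to a user count matrix (TSV/MTX)
    sample_meta: str | None = None
    simulate: dict = dataclasses.field(default_factory=dict)  # SimConfig overrides
    gene_lists: dict = dataclasses.field(default_factory=dict)  # name -> path
    cohorts: dict = dataclasses.field(default_factory=dict)  # name -> {sex: probe tsv} or int seed
    n_top_genes_pca: int = 5000

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**data)
        if not 0 < cfg.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {cfg.alpha!r}")
        bad = set(cfg.simulate) - _SIM_FIELDS
        if bad:
            raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
        for path in filter(None, [cfg.counts, cfg.sample_meta, *cfg.gene_lists.values()]):
            if not Path(path).exists():
                raise ConfigError(f"referenced path does not exist: {path}")
        return cfg

    def sim_config(self) -> SimConfig:
        over = dict(self.simulate)
        gs = over.pop("group_sizes", None)
        cfg = dataclasses.replace(SimConfig(seed=self.seed), **over)
        if gs:
            cfg = dataclasses.replace(
                cfg, group_sizes={tuple(k.split("/")): v for k, v in gs.items()}
                if isinstance(next(iter(gs)), str) else gs
            )
        return cfg


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis and write the report bundle to ``outdir``.

    Returns the report dict (also written as ``report.json``).  On a
    stage failure, partial outputs remain on disk and ``MANIFEST.json``
    marks the run incomplete with the failing stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"complete": False, "stages_done": []}
    report: dict = {
        "provenance": {
            "package": "myoaging",
            "version": __version__,
            "scenario": config.scenario,
            "seed": config.seed,
            "alpha": config.alpha,
        }
    }
    stage = "setup"
    try:
        stage = "counts"
        if config.counts:
            cm = read_counts(config.counts, config.sample_meta)
            truth = None
        else:
            cm, truth = simulate_counts(config.sim_config())
            write_counts(cm, outdir / "counts.tsv")
            write_sample_meta(cm.sample_meta, outdir / "sample_meta.tsv")
            write_table(truth.table.reset_index(), outdir / "truth.tsv")
        report["n_genes"], report["n_samples"] = cm.counts.shape
        manifest["stages_done"].append(stage)

        stage = "differential_expression"
        de = {}
        for sex in SEXES:
            de[sex] = de_test(cm, sex=sex)
            write_de_result(de[sex], outdir / f"de_{sex}.tsv")
            n_up, n_down = summarize_de(de[sex], config.alpha)
            report[f"de_{sex}"] = {"n_up": n_up, "n_down": n_down, "n_deg": n_up + n_down}
        n_m = len(de["male"].degs(config.alpha))
        n_f = len(de["female"].degs(config.alpha))
        report["female_excess_pct"] = 100.0 * (n_f - n_m) / n_m if n_m else float("nan")
        manifest["stages_done"].append(stage)

        stage = "pca"
        if cm.counts.shape[1] >= 3:
            _, frac = pca_embed(cm, n_top_genes=min(config.n_top_genes_pca, cm.counts.shape[0]))
            report["pca_explained_pct"] = [round(100 * f, 3) for f in frac[:5]]
        manifest["stages_done"].append(stage)

        stage = "partition"
        part = partition_degs(de["male"], de["female"], alpha=config.alpha)
        report["partition"] = part.counts()
        for name in ("shared", "male_specific", "female_specific"):
            write_gene_list(sorted(part.set_for(name)), outdir / f"degs_{name}.txt")
        manifest["stages_done"].append(stage)

        stage = "concordance"
        conc = {}
        for name in ("shared", "male_specific", "female_specific"):
            genes = part.set_for(name)
            conc[name] = (
                concordance_for_genes(de["male"], de["female"], genes).to_dict()
                if len(genes) >= 2
                else None
            )
        report["concordance"] = conc
        if truth is not None:
            pairs = truth.lfc_pairs()
            nz = (pairs["lfc_male"] != 0) & (pairs["lfc_female"] != 0)
            report["truth_sign_concordance_pct"] = (
                100.0
                * float(
                    (np.sign(pairs["lfc_male"][nz]) == np.sign(pairs["lfc_female"][nz])).mean()
                )
                if nz.any()
                else float("nan")
            )
        manifest["stages_done"].append(stage)

        stage = "gene_lists"
        gs = {}
        for name, path in config.gene_lists.items():
            genes = read_gene_list(path)
            gs[name] = {
                "concordance": geneset_concordance(
                    de["male"], de["female"], genes, alpha=config.alpha, list_name=name
                ).to_dict(),
                "pct_upregulated": {
                    sex: pct_upregulated(de[sex], genes, alpha=config.alpha) for sex in SEXES
                },
            }
        if gs:
            report["gene_sets"] = gs
        manifest["stages_done"].append(stage)

        stage = "harmonize"
        if config.cohorts:
            tables = {}
            for name, spec in config.cohorts.items():
                if isinstance(spec, dict) and set(spec) >= set(SEXES):
                    from .io import read_probe_table

                    probe = {sex: read_probe_table(spec[sex]) for sex in SEXES}
                else:  # simulated cohort; spec is a seed offset
                    probe = simulate_cohort(
                        config.sim_config(), seed=config.seed + int(spec), cohort=name
                    )
                tables[name] = {
                    sex: collapse_probes(probe[sex], alpha=config.alpha) for sex in SEXES
                }
            report["cohort_replication"] = cohort_replication(tables, alpha=config.alpha)
        manifest["stages_done"].append(stage)

        manifest["complete"] = True
        return report
    except MyoagingError as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise MyoagingError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        write_json(report, outdir / "report.json")
        write_json(manifest, outdir / "MANIFEST.json")
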