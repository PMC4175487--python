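"""End-to-end pipeline: simulate/load -> quantify -> score -> test ->
correlate -> ratio heatmap -> networks -> permutation comparisons.

Every stage writes plain-text tables so each step can be rerun
independently from intermediate files; ``report.json`` records versions,
seeds, counts, warnings and SHA-256 checksums of every output, making a
rerun with the same configuration and seed byte-verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlate import sign_summary, sign_summary_markdown, stratified_correlations
from .dimorphism import ratio_matrix, write_ratio_matrix
from .emotionality import comparison_group_ids, emotionality_scores
from .errors import ConfigError
from .factorial import anova_all_genes
from .network import build_network, project_reference, properties_table, to_edge_list, write_graphml
from .quant import collapse_replicates, reference_stability_check, relative_expression
from .simulate import (
    FACTORS,
    MALE_LEVEL,
    SimulationConfig,
    config_from_dict,
    generate_dataset,
    write_dataset,
)

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline-level settings.

    Exactly one of ``simulation`` (a :class:`SimulationConfig`) or
    ``inputs`` (paths to ``design``/``ct``/``behavior``/``directions``
    files) must be given.
    """

    simulation: SimulationConfig | None = None
    inputs: dict[str, str] | None = None
    comparison: dict[str, str] = field(
        default_factory=lambda: {"sex_chromosome": "XX", "hormone": "blank"}
    )
    fdr: float = 0.05
    anova_family: str = "per-term"
    tau: float = 0.0
    n_perm: int = 1000
    projection: str = "own"
    network_scale: str = "log2"
    seed: int = 0
    out_dir: str = "fcgnet_out"

    def validate(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of a simulation block or input paths is required"
            )
        if not 0 < self.fdr < 1:
            raise ConfigError("fdr must lie in (0, 1)")
        if not 0 <= self.tau < 1:
            raise ConfigError("tau must lie in [0, 1)")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.projection not in ("own", "male-reference"):
            raise ConfigError("projection must be 'own' or 'male-reference'")
        if self.network_scale not in ("log2", "linear"):
            raise ConfigError("network_scale must be 'log2' or 'linear'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = config_from_dict(d["simulation"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(inputs: dict[str, str]):
    design = pd.read_csv(inputs["design"])
    ct_long = pd.read_csv(inputs["ct"])
    behavior = pd.read_csv(inputs["behavior"])
    with open(inputs["directions"]) as fh:
        directions = {k: int(v) for k, v in yaml.safe_load(fh).items()}
    refs = inputs.get("reference_genes", "Actb,Gapdh")
    if isinstance(refs, str):
        refs = [r.strip() for r in refs.split(",")]
    categories = None
    if "categories" in inputs:
        with open(inputs["categories"]) as fh:
            categories = yaml.safe_load(fh)
    return design, ct_long, behavior, directions, list(refs), categories


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the report dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        sim.validate()
        design, ct_long, behavior, directions, truth = generate_dataset(sim)
        write_dataset(out, design, ct_long, behavior, directions, truth)
        reference_genes = list(sim.reference_genes)
        categories = sim.categories
    else:
        design, ct_long, behavior, directions, reference_genes, categories = (
            _load_inputs(config.inputs)
        )
        if categories is None:
            categories = {
                g: "unknown"
                for g in ct_long["gene"].unique()
                if g not in reference_genes
            }

    # quantification
    ct_mean, n_rep = collapse_replicates(ct_long)
    ranges = reference_stability_check(ct_mean, design, reference_genes)
    for gene, rng in ranges.items():
        if rng > 0.5:
            warnings_log.append(f"reference {gene} group-mean CT range {rng:.2f}")
    expression = relative_expression(ct_mean, reference_genes)
    expression.to_csv(out / "expression.csv")

    # emotionality
    comp_ids = comparison_group_ids(design, **config.comparison)
    emot = emotionality_scores(behavior, directions, comp_ids)
    emot.to_csv(out / "emotionality.csv")

    # factorial ANOVA
    anova = anova_all_genes(
        expression, design, categories,
        fdr=config.fdr, family=config.anova_family,
    )
    anova.to_csv(out / "anova_results.csv", index=False)

    # gene-behavior correlations
    corr = stratified_correlations(
        expression, emot["z_overall"], design, categories, fdr=config.fdr
    )
    corr.to_csv(out / "correlations.csv", index=False)
    summary = sign_summary(corr)
    (out / "sign_summary.md").write_text(sign_summary_markdown(summary))

    # dimorphism ratio matrix
    ratios = ratio_matrix(expression, design, anova, alpha=0.05)
    write_ratio_matrix(ratios, out / "ratio_matrix.tsv")

    # networks per factor; correlations on the log2 scale by default,
    # where expression is approximately Gaussian
    net_expr = (
        np.log2(expression) if config.network_scale == "log2" else expression
    )
    d_idx = design.set_index("sample_id").loc[expression.index]
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for factor in FACTORS:
        male_level = MALE_LEVEL[factor]
        female_level = next(
            l for l in dict.fromkeys(d_idx[factor]) if l != male_level
        )
        ids_m = list(net_expr.index[(d_idx[factor] == male_level).to_numpy()])
        ids_f = list(net_expr.index[(d_idx[factor] == female_level).to_numpy()])
        net_m = build_network(net_expr, ids_m, group=male_level, tau=config.tau)
        net_f = build_network(net_expr, ids_f, group=female_level, tau=config.tau)
        proj_f = project_reference(net_m, net_expr, ids_f, group=female_level)
        for net, name in (
            (net_m, male_level), (net_f, female_level),
            (proj_f, f"{female_level}_on_{male_level}"),
        ):
            safe = name.replace("|", "_").replace("/", "_")
            to_edge_list(net).to_csv(net_dir / f"{safe}.edges.tsv", sep="\t", index=False)
            write_graphml(net, net_dir / f"{safe}.graphml")

    props = properties_table(
        net_expr, design,
        n_perm=config.n_perm, seed=config.seed,
        tau=config.tau, projection=config.projection,
    )
    props.to_csv(out / "network_properties.csv")

    # report
    outputs = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        and p.name != "report.json"
    )
    report = {
        "fcgnet_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_samples": int(len(design)),
        "n_genes": int(expression.shape[1]),
        "n_significant_anova": int(anova["significant"].sum()),
        "n_significant_correlations": int(corr["significant"].sum()),
        "fdr": config.fdr,
        "n_perm": config.n_perm,
        "tau": config.tau,
        "projection": config.projection,
        "network_scale": config.network_scale,
        "warnings": warnings_log,
        "checksums": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
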