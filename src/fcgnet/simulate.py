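"""Seeded synthetic Four Core Genotypes (FCG) datasets.

The FCG mouse model decouples sex chromosome complement (XX vs XY-, where
Y- lacks *Sry*) from gonadal sex (ovaries vs testes, driven by an autosomal
*Sry* transgene).  Crossing those two factors with an adult hormone
manipulation (blank vs testosterone capsule after gonadectomy) gives a
2 x 2 x 2 design with eight groups.  This module generates a complete
in-silico study of that design:

* a design table (one row per mouse, all eight groups),
* raw qPCR cycle-threshold (CT) values in quadruplicate for ~30 target
  genes plus two reference genes, constructed so that the delta-Ct
  quantification in :mod:`fcgnet.quant` is its exact inverse when all
  noise terms are zero,
* anxiety-related behavior measures linearly coupled to chosen genes.

Expression is simulated on the log2 scale: additive main effects for each
sex factor, a gonadal-sex x hormone interaction, and a single latent
factor shared by a configurable gene module that is active only in chosen
groups.  The latent factor induces a controllable within-module
correlation of ``loading**2 / (loading**2 + noise_sd**2)``, emulating the
tightly co-expressed signal-transduction module seen only in "male"
phenotype networks.

All randomness flows from one integer seed; each generation stage draws
from its own deterministic sub-stream, so outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

__all__ = [
    "Gene",
    "SimulationConfig",
    "GroundTruth",
    "default_gene_panel",
    "default_config",
    "generate_design",
    "generate_expression",
    "generate_behavior",
    "generate_dataset",
    "groups_where",
    "group_label",
    "write_dataset",
    "config_from_dict",
    "config_to_dict",
    "load_config",
]

SEX_CHROMOSOME_LEVELS = ("XX", "XY-")
GONADAL_SEX_LEVELS = ("ovaries", "testes")
HORMONE_LEVELS = ("blank", "testosterone")
FACTORS = ("sex_chromosome", "gonadal_sex", "hormone")

#: the "male" level of each factor (used by heatmaps and reference networks)
MALE_LEVEL = {
    "sex_chromosome": "XY-",
    "gonadal_sex": "testes",
    "hormone": "testosterone",
}

#: log2 of the 10,000 arbitrary-unit scale used by delta-Ct quantification
LOG2_SCALE = float(np.log2(10_000.0))

# GABA-related panel: interneuron markers, GABA-A subunits, transporter and
# BDNF signalling, plus Sst/Gad67/Gad65 carried over from a companion study.
GABA_GENES = (
    "Sst", "Gad67", "Gad65", "Npy", "Cst", "Vip", "Calb1", "Cr", "Cck",
    "Pv", "Gat1", "Gabra1", "Gabra2", "Gabra5", "Bdnf", "Trkb",
)
# Serotonin/dopamine receptors and their signal-transduction partners.
MONOAMINE_GENES = (
    "Htr1a", "Htr2a", "Htr2c", "Drd1a", "Adcy1", "Adcy2", "Adcy5",
    "Adcy7", "Cdk5", "Akt1", "Akt2", "Akt3", "App", "Pdyn",
)
REFERENCE_GENES = ("Actb", "Gapdh")

#: signal-transduction genes forming the default co-expression module
SIGNAL_TRANSDUCTION_MODULE = (
    "Adcy1", "Adcy2", "Adcy5", "Adcy7", "Cdk5",
    "Akt1", "Akt2", "Akt3", "Pdyn", "App",
)

#: behavior measure -> (test, direction); direction -1 means a larger raw
#: value reflects *less* anxiety (e.g. more time in the open arms)
BEHAVIOR_MEASURES = {
    "time_open": ("EPM", -1),
    "pct_crosses_open": ("EPM", -1),
    "time_center": ("OF", -1),
    "pct_distance_center": ("OF", -1),
}


@dataclass(frozen=True)
class Gene:
    """A panel entry: gene name, category ('gaba' | 'monoamine' |
    'reference'), and whether it is an internal control."""

    name: str
    category: str
    is_reference: bool = False


def default_gene_panel() -> tuple[Gene, ...]:
    """The 30-gene target panel plus the two reference genes."""
    panel = [Gene(g, "gaba") for g in GABA_GENES]
    panel += [Gene(g, "monoamine") for g in MONOAMINE_GENES]
    panel += [Gene(g, "reference", is_reference=True) for g in REFERENCE_GENES]
    return tuple(panel)


def group_label(sex_chromosome: str, gonadal_sex: str, hormone: str) -> str:
    """Deterministic 1-of-8 group label."""
    return f"{sex_chromosome}|{gonadal_sex}|{hormone}"


def all_group_labels() -> tuple[str, ...]:
    return tuple(
        group_label(c, g, h)
        for c, g, h in itertools.product(
            SEX_CHROMOSOME_LEVELS, GONADAL_SEX_LEVELS, HORMONE_LEVELS
        )
    )


def groups_where(**levels: str) -> tuple[str, ...]:
    """Group labels whose factor levels match all keyword constraints,
    e.g. ``groups_where(gonadal_sex="testes")`` -> the four gonadal-male
    groups."""
    for key in levels:
        if key not in FACTORS:
            raise ConfigError(f"unknown factor {key!r}; expected one of {FACTORS}")
    out = []
    for c, g, h in itertools.product(
        SEX_CHROMOSOME_LEVELS, GONADAL_SEX_LEVELS, HORMONE_LEVELS
    ):
        row = {"sex_chromosome": c, "gonadal_sex": g, "hormone": h}
        if all(row[k] == v for k, v in levels.items()):
            out.append(group_label(c, g, h))
    return tuple(out)


def _default_baselines() -> dict[str, float]:
    # Moderate-abundance transcripts: a few hundred to a few thousand
    # arbitrary units (log2 of 2^8.5 ~ 360 up to 2^11.5 ~ 2900).
    levels = (8.5, 9.5, 10.5, 11.5)
    targets = GABA_GENES + MONOAMINE_GENES
    return {g: levels[i % len(levels)] for i, g in enumerate(targets)}


def _default_beta_chr() -> dict[str, float]:
    # XY- consistently lower than XX across GABA- and monoamine-related genes.
    genes = (
        "Sst", "Gad67", "Gad65", "Vip", "Calb1", "Gat1", "Trkb",
        "Htr1a", "Htr2c", "Drd1a", "Adcy5", "Adcy7", "App",
    )
    return {g: -0.4 for g in genes}


def _default_beta_gon() -> dict[str, float]:
    # Effects of testes relative to ovaries; ovaries-higher genes get a
    # negative coefficient.
    return {"Htr2a": -0.3, "Adcy1": -0.3, "Akt2": -0.3, "Akt3": -0.3}


def _default_beta_act() -> dict[str, float]:
    return {"Calb1": -0.3, "Htr1a": 0.4, "Adcy2": -0.3, "Akt1": -0.3, "Akt3": -0.3}


def _default_beta_gxa() -> dict[str, float]:
    # Testosterone lowers expression mainly in gonadal males.
    genes = ("Htr1a", "Drd1a", "Adcy5", "Cdk5", "Akt1", "Akt3")
    out = {g: -0.5 for g in genes}
    out["Cst"] = 0.5  # testosterone raises Cst in gonadal females only
    return out


def _default_behavior_coupling() -> dict[str, tuple[str, float, float]]:
    # Genes negatively associated with anxiety feed positively into
    # exploration measures (which are themselves anxiety-negative).
    return {
        "Trkb": ("time_open", 12.0, 8.0),
        "Htr2c": ("pct_crosses_open", 6.0, 4.0),
        "Adcy5": ("time_center", 10.0, 8.0),
        "App": ("pct_distance_center", 5.0, 4.0),
    }


def _default_behavior_intercepts() -> dict[str, float]:
    return {
        "time_open": 60.0,
        "pct_crosses_open": 25.0,
        "time_center": 40.0,
        "pct_distance_center": 15.0,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic FCG study.

    Defaults emulate the study conditions: eight groups of seven mice, a
    30-gene two-category panel with two reference genes, XY- main effects
    on a broad gene set, gonadal-sex x hormone interactions, and a
    signal-transduction co-expression module active only in gonadal-male
    groups (loading 0.8 over residual SD 0.5, i.e. within-module r ~ 0.72).
    """

    n_per_group: int = 7
    genes: tuple[Gene, ...] = field(default_factory=default_gene_panel)
    baseline_log2: dict[str, float] = field(default_factory=_default_baselines)
    beta_chr: dict[str, float] = field(default_factory=_default_beta_chr)
    beta_gon: dict[str, float] = field(default_factory=_default_beta_gon)
    beta_act: dict[str, float] = field(default_factory=_default_beta_act)
    beta_gxa: dict[str, float] = field(default_factory=_default_beta_gxa)
    module_genes: tuple[str, ...] = SIGNAL_TRANSDUCTION_MODULE
    module_groups: tuple[str, ...] = field(
        default_factory=lambda: groups_where(gonadal_sex="testes")
    )
    module_loading: float = 0.8
    noise_sd: float = 0.5
    ct_ref_mean: float = 20.0
    replicate_sd: float = 0.15
    behavior_coupling: dict[str, tuple[str, float, float]] = field(
        default_factory=_default_behavior_coupling
    )
    behavior_intercepts: dict[str, float] = field(
        default_factory=_default_behavior_intercepts
    )
    behavior_background_sd: float = 1.0
    seed: int = 0

    # -- convenience views -------------------------------------------------
    @property
    def target_genes(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes if not g.is_reference)

    @property
    def reference_genes(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes if g.is_reference)

    @property
    def categories(self) -> dict[str, str]:
        return {g.name: g.category for g in self.genes if not g.is_reference}

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2 (group variance undefined)")
        if len(self.reference_genes) != 2:
            raise ConfigError("exactly two reference genes are required")
        if not 0 <= self.module_loading and self.module_loading**2 < 1:
            raise ConfigError("module_loading must satisfy 0 <= loading^2 < 1")
        if self.module_loading**2 >= 1:
            raise ConfigError("module_loading^2 must be < 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.replicate_sd < 0:
            raise ConfigError("replicate_sd must be >= 0")
        targets = set(self.target_genes)
        missing = [g for g in self.module_genes if g not in targets]
        if missing:
            raise ConfigError(f"module genes not in gene panel: {missing}")
        known_groups = set(all_group_labels())
        bad = [g for g in self.module_groups if g not in known_groups]
        if bad:
            raise ConfigError(f"unknown module groups: {bad}")
        for gene, (measure, _, nsd) in self.behavior_coupling.items():
            if gene not in targets:
                raise ConfigError(f"behavior coupling refers to unknown gene {gene!r}")
            if measure not in BEHAVIOR_MEASURES:
                raise ConfigError(f"unknown behavior measure {measure!r}")
            if nsd < 0:
                raise ConfigError("behavior coupling noise SD must be >= 0")


def default_config(**overrides) -> SimulationConfig:
    """A validated configuration with study-condition defaults."""
    cfg = dataclasses.replace(SimulationConfig(), **overrides)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """Latent (noise-free-of-technical-error) state behind a dataset."""

    latent_log2: pd.DataFrame  # samples x target genes
    module_factor: pd.Series  # per-sample latent factor F_s
    module_active: pd.Series  # bool per sample
    config: SimulationConfig

    def to_jsonable(self) -> dict:
        return {
            "latent_log2": {
                "index": list(self.latent_log2.index),
                "columns": list(self.latent_log2.columns),
                "values": self.latent_log2.to_numpy().tolist(),
            },
            "module_factor": self.module_factor.to_list(),
            "module_active": [bool(v) for v in self.module_active],
            "betas": {
                "beta_chr": self.config.beta_chr,
                "beta_gon": self.config.beta_gon,
                "beta_act": self.config.beta_act,
                "beta_gxa": self.config.beta_gxa,
            },
            "seed": self.config.seed,
        }


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage sub-stream of the dataset seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), stage)))


def generate_design(n_per_group: int, seed: int = 0) -> pd.DataFrame:
    """Design table: ``8 * n_per_group`` mice, each factor combination
    appearing exactly ``n_per_group`` times.

    The table is a deterministic function of ``n_per_group``; ``seed`` is
    accepted for interface symmetry with the other generators.
    """
    if n_per_group < 2:
        raise ConfigError("n_per_group must be >= 2")
    rows = []
    i = 1
    for c, g, h in itertools.product(
        SEX_CHROMOSOME_LEVELS, GONADAL_SEX_LEVELS, HORMONE_LEVELS
    ):
        for _ in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"m{i:03d}",
                    "sex_chromosome": c,
                    "gonadal_sex": g,
                    "hormone": h,
                    "group": group_label(c, g, h),
                }
            )
            i += 1
    return pd.DataFrame(rows)


def generate_expression(
    design: pd.DataFrame, config: SimulationConfig
) -> tuple[GroundTruth, pd.DataFrame]:
    """Latent log2 expression plus a quadruplicate long-format CT table.

    Latent model per sample *s*, gene *g*::

        latent = baseline_g + bchr_g*[XY-] + bgon_g*[testes] + bact_g*[T]
                 + bgxa_g*[testes]*[T] + loading*F_s*[module] + eps

    CT values are constructed so delta-Ct quantification recovers
    ``2**latent`` exactly at zero technical noise:
    ``CT_target = ct_ref_mean - (latent - log2(10000))`` and reference
    genes sit at ``ct_ref_mean``.
    """
    config.validate()
    rng = _stage_rng(config.seed, 1)

    samples = design["sample_id"].to_numpy()
    n = len(samples)
    targets = list(config.target_genes)
    g_index = {g: i for i, g in enumerate(targets)}

    xy = (design["sex_chromosome"] == "XY-").to_numpy(float)
    te = (design["gonadal_sex"] == "testes").to_numpy(float)
    ho = (design["hormone"] == "testosterone").to_numpy(float)

    base = np.array([config.baseline_log2.get(g, 10.0) for g in targets])
    bc = np.array([config.beta_chr.get(g, 0.0) for g in targets])
    bg = np.array([config.beta_gon.get(g, 0.0) for g in targets])
    ba = np.array([config.beta_act.get(g, 0.0) for g in targets])
    bx = np.array([config.beta_gxa.get(g, 0.0) for g in targets])

    latent = (
        base[None, :]
        + np.outer(xy, bc)
        + np.outer(te, bg)
        + np.outer(ho, ba)
        + np.outer(te * ho, bx)
    )

    factor = rng.standard_normal(n)
    active = design["group"].isin(config.module_groups).to_numpy()
    module_idx = np.array([g_index[g] for g in config.module_genes], dtype=int)
    if module_idx.size:
        latent[:, module_idx] += (
            config.module_loading * factor[:, None] * active[:, None]
        )
    latent += rng.normal(0.0, config.noise_sd, size=latent.shape)

    # CT construction (targets then references, four replicates each)
    ct_target = config.ct_ref_mean - (latent - LOG2_SCALE)
    rep_noise_t = rng.normal(0.0, config.replicate_sd, size=(n, len(targets), 4))
    rep_noise_r = rng.normal(0.0, config.replicate_sd, size=(n, 2, 4))

    records = []
    refs = list(config.reference_genes)
    for si, sid in enumerate(samples):
        for gi, gene in enumerate(targets):
            for r in range(4):
                records.append(
                    (sid, gene, r + 1, ct_target[si, gi] + rep_noise_t[si, gi, r])
                )
        for ri, gene in enumerate(refs):
            for r in range(4):
                records.append(
                    (sid, gene, r + 1, config.ct_ref_mean + rep_noise_r[si, ri, r])
                )
    ct_long = pd.DataFrame(records, columns=["sample_id", "gene", "replicate", "ct"])

    truth = GroundTruth(
        latent_log2=pd.DataFrame(latent, index=samples, columns=targets),
        module_factor=pd.Series(factor, index=samples, name="module_factor"),
        module_active=pd.Series(active, index=samples, name="module_active"),
        config=config,
    )
    return truth, ct_long


def generate_behavior(
    design: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Behavior table (long format) plus the direction map.

    Each measure is ``intercept + sum(slope * latent(gene)) + noise`` over
    the couplings that target it; uncoupled measures get background noise
    only.  Directions come from :data:`BEHAVIOR_MEASURES`.
    """
    config.validate()
    rng = _stage_rng(config.seed, 2)
    samples = design["sample_id"].to_numpy()
    n = len(samples)
    latent = truth.latent_log2

    values: dict[str, np.ndarray] = {}
    for measure, (_test, _direction) in BEHAVIOR_MEASURES.items():
        v = np.full(n, config.behavior_intercepts.get(measure, 0.0))
        coupled = False
        for gene, (m, slope, nsd) in config.behavior_coupling.items():
            if m != measure:
                continue
            coupled = True
            v = v + slope * latent[gene].to_numpy() + rng.normal(0.0, nsd, size=n)
        if not coupled:
            v = v + rng.normal(0.0, config.behavior_background_sd, size=n)
        values[measure] = v

    records = []
    for measure, (test, _direction) in BEHAVIOR_MEASURES.items():
        for si, sid in enumerate(samples):
            records.append((sid, test, measure, values[measure][si]))
    behavior = pd.DataFrame(records, columns=["sample_id", "test", "measure", "value"])
    directions = {m: d for m, (_t, d) in BEHAVIOR_MEASURES.items()}
    return behavior, directions


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, int], GroundTruth]:
    """Convenience wrapper: (design, ct_long, behavior, directions, truth)."""
    config.validate()
    design = generate_design(config.n_per_group, config.seed)
    truth, ct_long = generate_expression(design, config)
    behavior, directions = generate_behavior(design, truth, config)
    return design, ct_long, behavior, directions, truth


# ---------------------------------------------------------------------------
# serialization


def write_dataset(
    out_dir: str | Path,
    design: pd.DataFrame,
    ct_long: pd.DataFrame,
    behavior: pd.DataFrame,
    directions: Mapping[str, int],
    truth: GroundTruth | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design.to_csv(out / "design.csv", index=False)
    ct_long.to_csv(out / "ct_long.csv", index=False)
    behavior.to_csv(out / "behavior.csv", index=False)
    with open(out / "directions.yaml", "w") as fh:
        yaml.safe_dump({k: int(v) for k, v in directions.items()}, fh)
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(truth.to_jsonable(), fh)


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["genes"] = [
        {"name": g.name, "category": g.category, "is_reference": g.is_reference}
        for g in config.genes
    ]
    d["module_genes"] = list(config.module_genes)
    d["module_groups"] = list(config.module_groups)
    d["behavior_coupling"] = {
        g: list(v) for g, v in config.behavior_coupling.items()
    }
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    if "genes" in d:
        d["genes"] = tuple(
            Gene(e["name"], e["category"], bool(e.get("is_reference", False)))
            for e in d["genes"]
        )
    for key in ("module_genes", "module_groups"):
        if key in d:
            d[key] = tuple(d[key])
    if "behavior_coupling" in d:
        d["behavior_coupling"] = {
            g: (v[0], float(v[1]), float(v[2]))
            for g, v in d["behavior_coupling"].items()
        }
    cfg = dataclasses.replace(SimulationConfig(), **d)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML or JSON simulation configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
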