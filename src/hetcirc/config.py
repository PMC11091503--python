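"""Configuration objects for the synthetic reciprocal-cross study generator.

The generator emulates a two-breed reciprocal cross between White Leghorn
(W) and Beijing You (Y) laying hens: purebred groups WW and YY, and the two
cross directions WY (W sire x Y dam) and YW.  Phenotypes are recorded per
bird; expression is profiled per bird x tissue for four tissues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

GROUPS: tuple[str, ...] = ("WW", "YY", "WY", "YW")
PARENTS: tuple[str, ...] = ("WW", "YY")
CROSSES: tuple[str, ...] = ("WY", "YW")
TISSUES: tuple[str, ...] = ("hypothalamus", "liver", "duodenum", "ovary")
TRAITS: tuple[str, ...] = ("MBW", "BWG", "DEM", "DFC", "RFI")

#: inheritance-pattern classes used for planting and classification
PATTERN_CLASSES: tuple[str, ...] = (
    "additive", "dominant", "overdominant", "underdominant",
)


class ConfigError(ValueError):
    """A simulation parameter is missing, inconsistent, or out of range."""


@dataclass
class TraitParams:
    """Group-level phenotype distributions.

    These are package defaults chosen to land group means inside plausible
    laying-hen ranges (daily feed consumption roughly 90-105 g/d, daily egg
    mass roughly 37-53 g/d); they are not measured population values.
    Cross-group means are mid-parent values scaled by the configured
    heterosis deltas.
    """

    bw_mean: dict[str, float] = field(
        default_factory=lambda: {"WW": 1.55, "YY": 1.85})  # kg
    bw_sd: float = 0.12
    bwg_mean: dict[str, float] = field(
        default_factory=lambda: {"WW": 1.5, "YY": 1.5})  # g/day
    bwg_sd: float = 1.0
    dem_mean: dict[str, float] = field(
        default_factory=lambda: {"WW": 48.0, "YY": 38.0})  # g/day
    dem_sd: float = 4.0
    #: DFC = b0 + b1*MBW + b2*BWG + b3*DEM (+ heterosis shift + noise), g/day
    dfc_coef: tuple[float, float, float, float] = (35.0, 30.0, 0.5, 0.4)
    dfc_noise_sd: float = 3.0


@dataclass
class ModuleSpec:
    """A planted co-expression module tied to residual feed intake.

    ``target_r`` is the in-sample Pearson correlation between the module's
    latent factor and each bird's true feed-intake residual; the module
    eigengene inherits it up to expression noise.  The default magnitude
    mirrors a hypothalamus module strongly anti-correlated with RFI.
    """

    n_members: int = 90
    n_circ_members: int = 10
    target_r: float = -0.62
    tissue: str = "hypothalamus"
    effect_log2: float = 2.0  # log2-scale loading per unit latent factor


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with study-design defaults.

    Defaults follow the study design: ~200-250 phenotyped birds per genetic
    group, 8 birds per group per tissue for hypothalamus/liver/duodenum and
    6 for ovary, four genetic groups, negative-binomial counts.
    """

    seed: int = 0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"WW": 198, "YY": 245, "YW": 238, "WY": 223})
    birds_per_group_per_tissue: int = 8
    ovary_birds_per_group: int = 6
    tissues: tuple[str, ...] = TISSUES
    n_circ: int = 300
    n_gene: int = 600
    nb_dispersion: float = 0.1  # Var = mu + alpha*mu^2
    baseline_mean_range: tuple[float, float] = (20.0, 200.0)
    pattern_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "additive": 0.05, "dominant": 0.06,
            "overdominant": 0.02, "underdominant": 0.02,
        })
    lfc_effect: float = 1.5  # planted |log2 fold change| between groups
    heterosis_delta: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "DFC": {"WY": 0.02, "YW": -0.03},
            "DEM": {"WY": 0.04, "YW": 0.0},
        })
    module_spec: ModuleSpec = field(default_factory=ModuleSpec)
    spe_fraction: float = 0.05
    tissue_specific_fraction: float = 0.25
    host_fraction: float = 0.8  # circRNAs with a same-strand host gene
    host_coupling_rho: float = 0.7
    host_coupling_sd: float = 0.5  # log2 sd of the shared circ/host factor
    mean_mapped_reads: float = 3.0e7
    trait_params: TraitParams = field(default_factory=TraitParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be nonnegative")
        if self.birds_per_group_per_tissue < 3:
            raise ConfigError("need at least 3 birds per group per tissue")
        if self.ovary_birds_per_group < 3:
            raise ConfigError("need at least 3 ovary birds per group")
        if self.n_circ < 0 or self.n_gene < 0:
            raise ConfigError("feature counts must be nonnegative")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ConfigError("baseline_mean_range must be positive and ordered")
        total = sum(self.pattern_proportions.values())
        if total > 1 + 1e-12:
            raise ConfigError(
                f"pattern_proportions sum to {total:.3f} > 1")
        unknown = set(self.pattern_proportions) - set(PATTERN_CLASSES)
        if unknown:
            raise ConfigError(f"unknown pattern classes: {sorted(unknown)}")
        if not 0 <= self.host_coupling_rho <= 1:
            raise ConfigError("host_coupling_rho must lie in [0, 1]")
        if not 0 <= self.spe_fraction <= 1:
            raise ConfigError("spe_fraction must lie in [0, 1]")
        ms = self.module_spec
        if ms.n_members > self.n_circ + self.n_gene:
            raise ConfigError("planted module larger than the feature universe")
        if ms.tissue not in self.tissues:
            raise ConfigError(f"module tissue {ms.tissue!r} not simulated")
        if self.trait_params.dfc_noise_sd < 0 or self.trait_params.bw_sd < 0:
            raise ConfigError("variance parameters must be nonnegative")

    def birds_for(self, tissue: str) -> int:
        return (self.ovary_birds_per_group if tissue == "ovary"
                else self.birds_per_group_per_tissue)

    def delta_for(self, trait: str, cross: str) -> float:
        """Fractional mid-parent heterosis planted for a trait in a cross."""
        entry = self.heterosis_delta.get(trait, 0.0)
        if isinstance(entry, Mapping):
            return float(entry.get(cross, 0.0))
        return float(entry)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        if "module_spec" in raw and isinstance(raw["module_spec"], dict):
            raw["module_spec"] = ModuleSpec(**raw["module_spec"])
        if "trait_params" in raw and isinstance(raw["trait_params"], dict):
            raw["trait_params"] = TraitParams(**raw["trait_params"])
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
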