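"""Study-design configuration for the synthetic ASV data generator.

A :class:`StudyDesign` captures everything the generator needs: the factorial
layout (treatments x replicates), how many taxa of each domain survive the
abundance/prevalence screen, the planted correlation modules with their hub
taxa, sequencing depth, and the per-treatment effects on environmental
covariates, plant traits and (optionally) individual taxa.  All randomness
derives from the single ``seed`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class DesignError(ValueError):
    """Raised when a StudyDesign (or filter/threshold config) is invalid."""


#: Soil covariates measured per sample.
ENV_VARS = ("pH", "EC", "AP", "AN", "AK", "TP", "TN", "TC")

#: Plant traits measured per plot.
TRAIT_VARS = ("stem_number", "biomass", "height")

#: Baseline (control-treatment) means for the soil covariates.
#: pH unitless; EC uS/cm; AP, AN, AK mg/kg; TP, TN, TC g/kg.
ENV_BASELINES = {
    "pH": 8.04,
    "EC": 223.30,
    "AP": 15.34,
    "AN": 46.10,
    "AK": 171.91,
    "TP": 0.60,
    "TN": 0.80,
    "TC": 15.0,
}

#: Baseline plant-trait means: stems per m^2, g/m^2, cm.
TRAIT_BASELINES = {"stem_number": 551.70, "biomass": 457.20, "height": 54.68}

# Per-treatment multiplicative shifts (control first).  The non-unit entries
# reproduce the mean ratios observed in a four-level phosphorus-addition
# grassland experiment (e.g. available P rising 58-138% over control).
DEFAULT_ENV_EFFECTS = {
    "pH": (1.0, 1.0012, 1.0050, 1.0062),
    "EC": (1.0, 0.8426, 1.0176, 0.8915),
    "AP": (1.0, 1.5802, 1.6310, 2.3761),
    "AN": (1.0, 1.0245, 1.1746, 1.2247),
    "AK": (1.0, 1.1496, 1.1061, 1.0329),
    "TP": (1.0, 1.0000, 1.1200, 1.2432),
    "TN": (1.0, 1.0, 1.0, 1.0),
    "TC": (1.0, 1.0, 1.0, 1.0),
}

DEFAULT_TRAIT_EFFECTS = {
    "stem_number": (1.0, 1.4369, 1.4690, 1.5496),
    "biomass": (1.0, 1.1020, 1.2248, 1.2404),
    "height": (1.0, 1.1238, 1.1372, 1.2304),
}


@dataclass
class ModuleSpec:
    """One planted correlation module.

    member_taxa may mix bacterial and fungal ids (cross-domain modules);
    hub_taxa are members given extra coupling to the module's latent factor so
    they end up the most-connected nodes of the module.
    """

    member_taxa: list[str]
    latent_correlation: float = 0.95
    hub_taxa: list[str] = field(default_factory=list)
    #: fraction of non-hub members anti-coupled to the module factor, giving
    #: negative co-occurrence edges (mutual-exclusion patterns) of the same
    #: strength; hubs always couple positively.
    negative_fraction: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.negative_fraction <= 1:
            raise DesignError(
                f"negative_fraction must be in [0, 1], got {self.negative_fraction}"
            )
        if not 0 <= self.latent_correlation < 1:
            raise DesignError(
                f"latent_correlation must be in [0, 1), got {self.latent_correlation}"
            )
        if not set(self.hub_taxa) <= set(self.member_taxa):
            extra = set(self.hub_taxa) - set(self.member_taxa)
            raise DesignError(f"hub_taxa not in member_taxa: {sorted(extra)}")
        if len(set(self.member_taxa)) != len(self.member_taxa):
            raise DesignError("duplicate ids in member_taxa")


@dataclass
class StudyDesign:
    """Configuration of one synthetic study.

    Defaults emulate a 4-treatment x 3-replicate phosphorus gradient with
    ~505 bacterial and ~87 fungal taxa surviving the network screen on top of
    a large pool of rare background taxa.
    """

    n_treatments: int = 4
    n_replicates: int = 3
    n_bacteria: int = 505
    n_fungi: int = 87
    n_background: int = 2000
    modules: list[ModuleSpec] = field(default_factory=list)
    sequencing_depth: int = 80_000
    dispersion: float = 0.60  # lognormal sigma of per-sample latent abundance
    env_noise_cv: float = 0.05
    trait_noise_cv: float = 0.03
    env_effects: dict = field(default_factory=lambda: dict(DEFAULT_ENV_EFFECTS))
    trait_effects: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_EFFECTS))
    taxon_effects: dict = field(default_factory=dict)  # taxon id -> per-treatment mult
    seed: int = 0

    # -- derived labels ----------------------------------------------------
    @property
    def treatments(self) -> list[str]:
        return [f"P{i}" for i in range(self.n_treatments)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{t}r{r + 1}" for t in self.treatments for r in range(self.n_replicates)]

    @property
    def bacteria_ids(self) -> list[str]:
        return [f"B{i:04d}" for i in range(1, self.n_bacteria + 1)]

    @property
    def fungi_ids(self) -> list[str]:
        return [f"F{i:04d}" for i in range(1, self.n_fungi + 1)]

    @property
    def background_ids(self) -> list[str]:
        return [f"X{i:04d}" for i in range(1, self.n_background + 1)]

    @property
    def retained_ids(self) -> list[str]:
        return self.bacteria_ids + self.fungi_ids

    def validate(self) -> None:
        for name in ("n_treatments", "n_bacteria", "n_fungi", "sequencing_depth"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_background < 0:
            raise DesignError(f"n_background must be >= 0, got {self.n_background}")
        if self.n_replicates < 2:
            raise DesignError(
                "n_replicates must be >= 2 (replicate variance, and hence any "
                f"correlation or ANOVA, is undefined otherwise), got {self.n_replicates}"
            )
        if self.dispersion < 0:
            raise DesignError(f"dispersion must be >= 0, got {self.dispersion}")
        retained = set(self.retained_ids)
        seen: set[str] = set()
        for k, mod in enumerate(self.modules):
            mod.validate()
            members = set(mod.member_taxa)
            if not members <= retained:
                raise DesignError(
                    f"module {k} references unknown taxa: {sorted(members - retained)[:5]}"
                )
            if members & seen:
                raise DesignError(
                    f"module memberships overlap: {sorted(members & seen)[:5]}"
                )
            seen |= members
        for eff, names in ((self.env_effects, ENV_VARS), (self.trait_effects, TRAIT_VARS)):
            for var, mults in eff.items():
                if var not in names:
                    raise DesignError(f"unknown effect variable {var!r}")
                if len(mults) != self.n_treatments:
                    raise DesignError(
                        f"effect for {var!r} has {len(mults)} entries, "
                        f"expected {self.n_treatments}"
                    )


def default_design(
    n_modules: int = 8,
    hubs_per_module: int = 2,
    latent_correlation: float = 0.99,
    negative_fraction: float = 0.5,
    seed: int = 0,
    **overrides,
) -> StudyDesign:
    """Build the default study design with all retained taxa partitioned into
    cross-domain modules.

    Taxa are dealt round-robin so every module mixes bacteria and fungi in
    roughly the global proportions; the first ``hubs_per_module`` members of
    each module are planted hubs.
    """
    design = StudyDesign(seed=seed, **overrides)
    members: list[list[str]] = [[] for _ in range(n_modules)]
    for i, tid in enumerate(design.retained_ids):
        members[i % n_modules].append(tid)
    design.modules = [
        ModuleSpec(
            member_taxa=mem,
            latent_correlation=latent_correlation,
            hub_taxa=mem[:hubs_per_module],
            negative_fraction=negative_fraction,
        )
        for mem in members
        if mem
    ]
    design.validate()
    return design
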