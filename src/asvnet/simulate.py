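"""Synthetic multi-domain ASV tables with planted correlation structure.

The count model is a lognormal latent-abundance model followed by multinomial
read sampling at a fixed depth, so the data are compositional and
overdispersed like real amplicon counts:

* every taxon has a base relative weight; taxa destined for the network screen
  are abundant (> 0.1 % of reads each), background taxa are rare;
* taxa belonging to the same planted module share a per-sample latent Gaussian
  factor.  Member loadings are chosen via the Gaussian-copula relation
  ``r = 2 sin(pi * rho_s / 6)`` so the *rank* correlation of their latent
  abundances matches the module's ``latent_correlation``; hub taxa load more
  strongly and therefore end up with the highest within-module connectivity;
* per-treatment multiplicative shifts may act on designated taxa, on the soil
  covariates and on the plant traits.

All randomness flows from ``design.seed`` through named child generators, so
two calls with the same design are bit-identical.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .design import (
    ENV_BASELINES,
    ENV_VARS,
    TRAIT_BASELINES,
    TRAIT_VARS,
    DesignError,
    StudyDesign,
)

_BACTERIAL_PHYLA = [
    "Proteobacteria",
    "Actinobacteriota",
    "Acidobacteriota",
    "Chloroflexi",
    "Bacteroidota",
    "Gemmatimonadota",
    "Firmicutes",
    "Myxococcota",
]
_FUNGAL_PHYLA = ["Ascomycota", "Basidiomycota", "Mortierellomycota", "Glomeromycota"]
_FUNGAL_PHYLUM_WEIGHTS = [0.55, 0.20, 0.15, 0.10]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def _spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose rank correlation is rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _latent_field(
    design: StudyDesign, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, float]]:
    """Standard-normal latent matrix (taxa x samples) with planted module
    blocks; returns the field and each module member's coupling sign."""
    taxa = design.retained_ids + design.background_ids
    index = {t: i for i, t in enumerate(taxa)}
    n_samples = len(design.sample_ids)
    g = rng.standard_normal((len(taxa), n_samples))
    signs: dict[str, float] = {}
    for mod in design.modules:
        # Each module factor is an environmental/biotic gradient across
        # samples: evenly spread standard-normal quantiles in random sample
        # order.  An iid draw occasionally clumps (near-tied gradient values),
        # which destroys rank information at small n and produces "dead"
        # modules no analysis could recover.
        z = norm.ppf((rng.permutation(n_samples) + 0.5) / n_samples)
        r = _spearman_to_pearson(mod.latent_correlation)
        hubs = set(mod.hub_taxa)
        for tid in mod.member_taxa:
            a = math.sqrt(r)
            # anti-coupled members give negative co-occurrence edges
            if tid not in hubs and rng.random() < mod.negative_fraction:
                a = -a
            signs[tid] = 1.0 if a >= 0 else -1.0
            i = index[tid]
            g[i] = a * z + math.sqrt(1.0 - r) * g[i]
    return g, signs


# Hubs follow their module's realized share-level consensus (see
# simulate_counts); this is the weight of their residual idiosyncratic noise
# and the factor by which their base abundance exceeds an ordinary member's.
_HUB_NOISE = 0.02
_HUB_ABUNDANCE_BOOST = 8.0


def _plant_hubs(
    design: StudyDesign,
    log_abund: np.ndarray,
    signs: dict[str, float],
    index: dict[str, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Rewrite each hub's abundance profile as its module's consensus.

    Read counts measure per-sample *shares*, and the shared closure term
    displaces every taxon's rank profile away from the latent factor.  A hub
    pinned to the factor alone would therefore not dominate the module, so
    hubs instead track the mean standardized log-share of their (sign-
    corrected, non-hub) module members — the realized centre of the module's
    co-occurrence cloud — plus a little idiosyncratic noise.
    """
    la = log_abund.copy()
    sd = design.dispersion if design.dispersion > 0 else 1.0
    bases = {
        h: log_abund[index[h]].mean() + math.log(_HUB_ABUNDANCE_BOOST)
        for mod in design.modules
        for h in mod.hub_taxa
    }
    hub_noise = {h: rng.standard_normal(la.shape[1]) for h in bases}
    # two fixed-point passes: planting the (more abundant) hubs shifts the
    # per-sample closure, so the consensus is recomputed once under it
    for _ in range(2):
        log_z = logsumexp(la, axis=0)
        # consensus lives in share space; planting happens in absolute
        # abundance space, so the closure is added back to compensate
        closure = log_z - log_z.mean()
        logp = la - log_z[None, :]
        for mod in design.modules:
            if not mod.hub_taxa:
                continue
            plain = [t for t in mod.member_taxa if t not in set(mod.hub_taxa)]
            if not plain:
                continue  # all-hub module: keep factor coupling
            rows = logp[[index[t] for t in plain]]
            std = rows.std(axis=1, keepdims=True)
            std[std == 0] = 1.0
            u = (rows - rows.mean(axis=1, keepdims=True)) / std
            u *= np.array([[signs[t]] for t in plain])
            consensus = u.mean(axis=0)
            c_sd = consensus.std()
            if c_sd == 0:
                continue
            consensus = consensus / c_sd
            for h in mod.hub_taxa:
                i = index[h]
                la[i] = bases[h] + closure + sd * (
                    math.sqrt(1.0 - _HUB_NOISE**2) * consensus
                    + _HUB_NOISE * hub_noise[h]
                )
    return la


def _base_log_weights(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    """Log relative weights: retained taxa comfortably above the 0.1% screen,
    background taxa far below it."""
    n_ret = len(design.retained_ids)
    # Narrow spread keeps every retained taxon's share above the screen even
    # after lognormal per-sample noise; see docs/methods.md.
    retained = rng.uniform(1.6, 2.0, size=n_ret)
    background = np.exp(rng.uniform(np.log(0.005), np.log(0.05), size=design.n_background))
    return np.log(np.concatenate([retained, background]))


def simulate_counts(design: StudyDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an ASV count table and its taxonomy.

    Returns
    -------
    counts : DataFrame, shape (n_taxa, n_samples)
        Non-negative integer reads; taxa as rows, samples as columns.
    taxonomy : DataFrame indexed by taxon id
        Columns ``domain`` (bacteria/fungi) and ranks kingdom..genus.
    """
    design.validate()
    rng_weights, rng_field, rng_counts, rng_tax, _ = _child_rngs(design.seed, 5)

    taxa = design.retained_ids + design.background_ids
    samples = design.sample_ids
    logw = _base_log_weights(design, rng_weights)
    g, signs = _latent_field(design, rng_field)

    log_abund = logw[:, None] + design.dispersion * g
    index = {t: i for i, t in enumerate(taxa)}
    log_abund = _plant_hubs(design, log_abund, signs, index, rng_field)
    # treatment effects on designated taxa
    if design.taxon_effects:
        treat_of_sample = np.repeat(np.arange(design.n_treatments), design.n_replicates)
        for tid, mults in design.taxon_effects.items():
            if tid not in index:
                raise DesignError(f"taxon_effects references unknown taxon {tid!r}")
            if len(mults) != design.n_treatments:
                raise DesignError(
                    f"taxon_effects[{tid!r}] has {len(mults)} entries, "
                    f"expected {design.n_treatments}"
                )
            log_abund[index[tid]] += np.log(np.asarray(mults, float))[treat_of_sample]

    # compositional: per-sample multinomial at the configured depth
    p = np.exp(log_abund - log_abund.max(axis=0, keepdims=True))
    p /= p.sum(axis=0, keepdims=True)
    counts = np.column_stack(
        [rng_counts.multinomial(design.sequencing_depth, p[:, j]) for j in range(len(samples))]
    )
    counts_df = pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"), columns=samples)

    taxonomy = _simulate_taxonomy(design, rng_tax)
    return counts_df, taxonomy


def _simulate_taxonomy(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    # background taxa are split between domains roughly like the retained pool
    frac_bact = design.n_bacteria / max(design.n_bacteria + design.n_fungi, 1)
    for tid in design.retained_ids + design.background_ids:
        if tid.startswith("B"):
            domain = "bacteria"
        elif tid.startswith("F"):
            domain = "fungi"
        else:
            domain = "bacteria" if rng.random() < frac_bact else "fungi"
        if domain == "bacteria":
            phylum = _BACTERIAL_PHYLA[rng.integers(len(_BACTERIAL_PHYLA))]
            kingdom = "Bacteria"
        else:
            phylum = _FUNGAL_PHYLA[rng.choice(len(_FUNGAL_PHYLA), p=_FUNGAL_PHYLUM_WEIGHTS)]
            kingdom = "Fungi"
        rows.append(
            {
                "taxon_id": tid,
                "domain": domain,
                "kingdom": kingdom,
                "phylum": phylum,
                "class": "",
                "order": "",
                "family": "",
                "genus": f"g_{tid}",
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def simulate_env_and_traits(design: StudyDesign) -> pd.DataFrame:
    """Simulate per-sample metadata: treatment labels, soil covariates and
    plant traits.

    Treatment means equal baseline x the configured multiplicative shift;
    replicate noise is multiplicative Gaussian with the design's coefficient
    of variation, so simulated treatment-mean ratios are unbiased for the
    configured effects.  The derived C/N ratio column is TC/TN.
    """
    design.validate()
    *_, rng = _child_rngs(design.seed, 5)

    samples = design.sample_ids
    treat_idx = np.repeat(np.arange(design.n_treatments), design.n_replicates)
    data: dict[str, np.ndarray] = {}
    for var in ENV_VARS:
        mults = np.asarray(design.env_effects.get(var, (1.0,) * design.n_treatments), float)
        mean = ENV_BASELINES[var] * mults[treat_idx]
        noise = 1.0 + design.env_noise_cv * rng.standard_normal(len(samples))
        data[var] = mean * np.clip(noise, 0.05, None)
    for var in TRAIT_VARS:
        mults = np.asarray(design.trait_effects.get(var, (1.0,) * design.n_treatments), float)
        mean = TRAIT_BASELINES[var] * mults[treat_idx]
        noise = 1.0 + design.trait_noise_cv * rng.standard_normal(len(samples))
        data[var] = mean * np.clip(noise, 0.05, None)

    meta = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
    meta.insert(0, "treatment", [design.treatments[t] for t in treat_idx])
    meta["C/N"] = meta["TC"] / meta["TN"]
    return meta
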