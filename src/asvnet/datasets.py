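"""Bundled reference tables from a four-level phosphorus-addition field
experiment (treatments P0-P3, three replicates) in an arid *Leymus chinensis*
grassland.

These small summary tables — per-treatment soil-chemistry and plant-trait
means, alpha-diversity estimates, co-occurrence-network edge/node counts, and
sequencing read totals — are the worked-example inputs for the arithmetic
layers of the package (percent change, topology identities, read
accounting).  Raw sequence data are not bundled; synthetic tables from
:mod:`asvnet.simulate` stand in for them.
"""

from __future__ import annotations

import pandas as pd

TREATMENTS = ("P0", "P1", "P2", "P3")


def soil_chemistry_means() -> pd.DataFrame:
    """Per-treatment soil covariate means (pH unitless, EC uS/cm, AP/AN/AK
    mg/kg)."""
    return pd.DataFrame(
        {
            "pH": [8.04, 8.05, 8.08, 8.09],
            "EC": [223.30, 188.16, 227.23, 199.07],
            "AP": [15.34, 24.24, 25.02, 36.45],
            "AN": [46.10, 47.23, 54.15, 56.46],
            "AK": [171.91, 197.63, 190.15, 177.56],
        },
        index=pd.Index(TREATMENTS, name="treatment"),
    )


def plant_trait_means() -> pd.DataFrame:
    """Per-treatment plant-trait means (stems/m^2, g/m^2, cm)."""
    return pd.DataFrame(
        {
            "stem_number": [551.70, 792.75, 810.47, 854.90],
            "biomass": [457.20, 503.85, 559.97, 567.10],
            "height": [54.68, 61.45, 62.18, 67.28],
        },
        index=pd.Index(TREATMENTS, name="treatment"),
    )


def alpha_diversity_means() -> pd.DataFrame:
    """Per-treatment ACE and Gini-Simpson means for bacteria and fungi."""
    return pd.DataFrame(
        {
            "bacteria_ACE": [1569.41, 1611.93, 1646.28, 1552.56],
            "bacteria_Simpson": [0.998, 0.998, 0.997, 0.997],
            "fungi_ACE": [383.35, 375.72, 384.27, 387.01],
            "fungi_Simpson": [0.956, 0.962, 0.942, 0.963],
        },
        index=pd.Index(TREATMENTS, name="treatment"),
    )


def network_counts() -> pd.DataFrame:
    """Raw co-occurrence-network counts per treatment: edges, positive and
    negative edges, nodes, and the bacteria/fungi node split."""
    return pd.DataFrame(
        {
            "edges": [11846, 12176, 13961, 11978],
            "num_pos_edges": [6173, 6285, 8181, 6026],
            "num_neg_edges": [5673, 5891, 5780, 5952],
            "nodes": [592, 598, 597, 598],
            "bacteria_nodes": [505, 511, 511, 512],
            "fungus_nodes": [87, 87, 86, 86],
        },
        index=pd.Index(TREATMENTS, name="treatment"),
    )


def network_reported_metrics() -> pd.DataFrame:
    """Ratio metrics reported alongside the raw counts (printed precision)."""
    return pd.DataFrame(
        {
            "positive_pct": [52.11, 51.62, 58.60, 50.31],
            "edge_density": [0.068, 0.068, 0.078, 0.067],
            "average_degree": [40.02, 40.72, 46.77, 40.06],
            "average_path_length": [1.78, 1.75, 1.75, 1.77],
        },
        index=pd.Index(TREATMENTS, name="treatment"),
    )


def sequencing_read_counts() -> pd.DataFrame:
    """Total effective and high-quality read counts over the 12 samples."""
    return pd.DataFrame(
        {
            "effective_reads": [959619, 935153],
            "high_quality_reads": [958122, 931844],
        },
        index=pd.Index(["bacteria", "fungi"], name="domain"),
    )


def reported_percent_change_ranges() -> dict[str, tuple[float, float]]:
    """Reported min-max percent increases vs P0 across the P treatments."""
    return {
        "AP": (58.02, 137.61),
        "AN": (2.45, 22.47),
        "stem_number": (43.69, 54.96),
        "biomass": (10.20, 24.04),
        "height": (12.38, 23.04),
    }
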