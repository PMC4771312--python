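"""Bundled reference tables.

Currently one dataset: the published per-lineage trait-depth summary
(consenTRAIT tau_D mean/SD over bootstrap trees) for metal uptake traits in
Roseobacter and SAR11, used to compare trait conservation between the two
lineages with summary-statistic effect sizes (Cohen's d, Welch's t).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_trait_depth_summary", "lineage_comparison"]


def load_trait_depth_summary() -> pd.DataFrame:
    """Trait-depth summary table: trait, substrate, per-lineage mean/SD."""
    ref = resources.files("metaltrait").joinpath("data/trait_depth_two_lineages.tsv")
    with ref.open("rt") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def lineage_comparison(summary: pd.DataFrame | None = None) -> pd.DataFrame:
    """Effect sizes for traits scored in both lineages.

    For every trait with tau_D printed for both lineages, computes Cohen's d
    from the summary means/SDs, classifies it (small < 0.5 < medium < 1 <
    large), and flags which lineage has the deeper (larger mean) trait depth.
    """
    from .phylosignal import classify_effect_size, cohens_d

    df = summary if summary is not None else load_trait_depth_summary()
    shared = df.dropna(subset=["roseobacter_mean", "sar11_mean"]).copy()
    shared["cohens_d"] = [
        cohens_d(r.roseobacter_mean, r.roseobacter_sd, r.sar11_mean, r.sar11_sd)
        for r in shared.itertuples()
    ]
    shared["effect_size"] = shared["cohens_d"].map(classify_effect_size)
    shared["deeper_lineage"] = [
        "SAR11" if r.sar11_mean > r.roseobacter_mean else "Roseobacter"
        for r in shared.itertuples()
    ]
    return shared.reset_index(drop=True)
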