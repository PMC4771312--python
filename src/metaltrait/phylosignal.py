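"""Phylogenetic conservation statistics for binary traits.

Implements consenTRAIT trait depth (tau_D) with a tip-permutation null and
multi-tree (bootstrap set) aggregation, and Fritz & Purvis' phylogenetic
dispersion statistic D with random-shuffle and Brownian-threshold nulls,
plus the summary-statistic comparisons (Cohen's d, Welch's t) used to
contrast trait depths between lineages.

Trait depth: large tau_D means the trait is shared by deep clades and so is
vertically conserved; small tau_D with a non-significant permutation p means
the distribution is indistinguishable from random gain/loss.

D is scaled so that D ~ 1 for a phylogenetically random trait and D ~ 0 for
a trait generated by thresholding Brownian motion on the tree; D < 0 marks
extreme clumping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from ._trees import TreeArrays

__all__ = [
    "ConsentraitConfig",
    "ConsentraitResult",
    "DStatResult",
    "consentrait_depth",
    "consentrait_test",
    "sister_difference_sum",
    "fritz_purvis_D",
    "cohens_d",
    "classify_effect_size",
    "welch_t",
    "signal_table",
]


class DegenerateTraitError(ValueError):
    """Trait is constant (all positive or all negative) across tips."""


class LabelMismatchError(ValueError):
    pass


@dataclass
class ConsentraitConfig:
    positive_fraction: float = 0.90
    n_permutations: int = 1000
    singleton_depth_factor: float = 0.5
    alpha: float = 0.1
    seed: int = 0


@dataclass
class ConsentraitResult:
    trait: str
    tau_D: float
    tau_SD: float
    p_perm: float
    clades: list = field(default_factory=list)


@dataclass
class DStatResult:
    trait: str
    sum_d_obs: float
    D: float
    p_random: float
    p_brownian: float
    n_sim: int


def _align_trait(ta: TreeArrays, trait) -> np.ndarray:
    """Align a trait (Series/dict/array) to the tree's canonical tip order."""
    if isinstance(trait, pd.Series):
        missing = set(ta.tip_labels) - set(trait.index)
        if missing:
            raise LabelMismatchError(f"trait missing tips: {sorted(missing)[:5]}")
        return trait.reindex(ta.tip_labels).to_numpy()
    if isinstance(trait, dict):
        return _align_trait(ta, pd.Series(trait))
    arr = np.asarray(trait)
    if arr.shape[0] != ta.n_tips:
        raise LabelMismatchError("trait length does not match tip count")
    return arr


def consentrait_depth(tree, trait, cfg: ConsentraitConfig | None = None):
    """tau_D for one trait on one tree; returns (tau_D, qualifying clades).

    Qualifying clades are the maximal internal nodes whose tip sets are >=
    ``positive_fraction`` positive; each contributes its mean node-to-tip
    branch-length depth. Positive tips outside all qualifying clades count as
    singletons at ``singleton_depth_factor`` x terminal branch length.
    """
    cfg = cfg or ConsentraitConfig()
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays(tree)
    t = _align_trait(ta, trait).astype(bool)
    if t.sum() == 0:
        raise DegenerateTraitError("trait has zero positive tips")
    tau = ta.consentrait_tau(
        t[:, None], cfg.positive_fraction, cfg.singleton_depth_factor
    )[0]
    clades = _qualifying_clades(ta, t, cfg)
    return float(tau), clades


def _qualifying_clades(ta: TreeArrays, t: np.ndarray, cfg: ConsentraitConfig):
    npos = np.zeros(ta.n_nodes, dtype=np.int64)
    npos[ta.tip_node] = t.astype(np.int64)
    for i in ta.postorder:
        ch = ta.children[i]
        if len(ch):
            npos[i] = npos[ch].sum()
    counts = ta.node_tip_counts()
    depths = ta.mean_tip_depth()
    qual = np.zeros(ta.n_nodes, dtype=bool)
    for i in range(ta.n_nodes):
        if not ta.is_tip[i] and npos[i] > 0:
            qual[i] = npos[i] >= cfg.positive_fraction * counts[i]
    clades = []
    anc = np.zeros(ta.n_nodes, dtype=bool)
    for i in ta.preorder():
        for j in ta.children[i]:
            anc[j] = anc[i] or qual[i]
        if qual[i] and not anc[i]:
            clades.append((int(i), float(depths[i]), int(counts[i])))
    return clades


def consentrait_test(
    trees, trait, cfg: ConsentraitConfig | None = None, trait_name: str = "trait"
) -> ConsentraitResult:
    """tau_D aggregated over a tree set, with a tip-permutation null.

    ``trees`` may be a single tree or a list (e.g. bootstrap replicates); all
    must share the tip label set. tau_D/tau_SD are the mean/SD of per-tree
    depths; p_perm uses the add-one permutation estimator on the mean depth,
    permuting the tip-to-trait assignment.
    """
    cfg = cfg or ConsentraitConfig()
    if isinstance(trees, (dendropy.Tree, TreeArrays)):
        trees = [trees]
    tas = [t if isinstance(t, TreeArrays) else TreeArrays(t) for t in trees]
    labels = tas[0].tip_labels
    for ta in tas[1:]:
        if ta.tip_labels != labels:
            raise LabelMismatchError("trees do not share a tip label set")
    t = _align_trait(tas[0], trait).astype(bool)
    if t.sum() == 0:
        raise DegenerateTraitError("trait has zero positive tips")
    per_tree = np.array(
        [
            ta.consentrait_tau(t[:, None], cfg.positive_fraction, cfg.singleton_depth_factor)[0]
            for ta in tas
        ]
    )
    tau = float(per_tree.mean())
    sd = float(per_tree.std(ddof=1)) if len(per_tree) > 1 else 0.0
    rng = np.random.default_rng(cfg.seed)
    n = len(t)
    perm = np.empty((n, cfg.n_permutations), dtype=np.int8)
    for j in range(cfg.n_permutations):
        perm[:, j] = t[rng.permutation(n)]
    perm_tau = np.zeros(cfg.n_permutations)
    for ta in tas:
        perm_tau += ta.consentrait_tau(
            perm, cfg.positive_fraction, cfg.singleton_depth_factor
        )
    perm_tau /= len(tas)
    p = (1 + int((perm_tau >= tau).sum())) / (1 + cfg.n_permutations)
    clades = [_qualifying_clades(ta, t, cfg) for ta in tas]
    return ConsentraitResult(trait_name, tau, sd, float(p), clades)


def sister_difference_sum(tree, trait) -> float:
    """Sum over internal nodes of |child value differences| (tips -> root means).

    The observed statistic underlying Fritz & Purvis' D. Raises on constant
    traits, for which D is undefined.
    """
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays(tree)
    t = _align_trait(ta, trait).astype(float)
    if len(np.unique(t)) < 2:
        raise DegenerateTraitError("trait is constant across tips")
    return float(ta.sister_difference_sum(t[:, None])[0])


def fritz_purvis_D(
    tree,
    trait,
    n_random: int = 1000,
    n_brownian: int = 1000,
    seed: int = 0,
    trait_name: str = "trait",
) -> DStatResult:
    """Fritz & Purvis' phylogenetic dispersion D for a binary trait.

    D = (sum_d_obs - mean sum_d_Brownian) / (mean sum_d_random - mean
    sum_d_Brownian), where the random null permutes tip labels and the
    Brownian null thresholds simulated Brownian values at the observed
    prevalence. p_random is the fraction of random-null statistics <= the
    observed one (small = more clumped than random); p_brownian likewise.
    """
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays(tree)
    t = _align_trait(ta, trait).astype(np.int8)
    if len(np.unique(t)) < 2:
        raise DegenerateTraitError("trait is constant across tips")
    rng = np.random.default_rng(seed)
    obs = float(ta.sister_difference_sum(t[:, None])[0])
    n = len(t)
    perm = np.empty((n, n_random), dtype=np.int8)
    for j in range(n_random):
        perm[:, j] = t[rng.permutation(n)]
    d_rand = ta.sister_difference_sum(perm)
    bm = ta.brownian_tips(n_brownian, rng)
    bt = ta.threshold_at_count(bm, int(t.sum()))
    d_brown = ta.sister_difference_sum(bt)
    denom = d_rand.mean() - d_brown.mean()
    if denom == 0:
        raise ZeroDivisionError("random and Brownian null distributions coincide")
    D = (obs - d_brown.mean()) / denom
    p_rand = float((d_rand <= obs).mean())
    p_brown = float((d_brown <= obs).mean())
    return DStatResult(trait_name, obs, float(D), p_rand, p_brown, n_random)


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's d from summary statistics: |m1 - m2| / sqrt((sd1^2 + sd2^2)/2)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    if pooled == 0:
        return 0.0 if mean1 == mean2 else float("inf")
    return float(abs(mean1 - mean2) / pooled)


def classify_effect_size(d: float) -> str:
    """Conventional bands: small (< 0.5), medium, large (> 1)."""
    if d < 0.5:
        return "small"
    if d > 1.0:
        return "large"
    return "medium"


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float, float]:
    """Welch's unequal-variance t test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    if se == 0:
        return 0.0, float(n1 + n2 - 2), 1.0
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def signal_table(
    trees,
    traits: pd.DataFrame,
    cfg: ConsentraitConfig | None = None,
    n_random: int = 1000,
    n_brownian: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run consenTRAIT and D for every binary trait column of ``traits``.

    Constant traits are reported with NaN statistics rather than raised, so a
    whole inventory can be screened in one call. Output columns mirror a
    per-lineage trait-depth table: tau_D_mean, tau_D_sd, p_perm, D, p_random,
    p_brownian plus significance flags at the configured levels.
    """
    cfg = cfg or ConsentraitConfig(seed=seed)
    if isinstance(trees, (dendropy.Tree, TreeArrays)):
        trees = [trees]
    rows = []
    for k, col in enumerate(traits.columns):
        tr = (traits[col] > 0).astype(int)
        row = {"trait": col}
        try:
            sub = ConsentraitConfig(
                cfg.positive_fraction,
                cfg.n_permutations,
                cfg.singleton_depth_factor,
                cfg.alpha,
                seed=cfg.seed + k,
            )
            res = consentrait_test(trees, tr, sub, trait_name=col)
            row.update(tau_D_mean=res.tau_D, tau_D_sd=res.tau_SD, p_perm=res.p_perm)
        except DegenerateTraitError:
            row.update(tau_D_mean=np.nan, tau_D_sd=np.nan, p_perm=np.nan)
        try:
            dres = fritz_purvis_D(
                trees[0] if not isinstance(trees[0], TreeArrays) else trees[0],
                tr,
                n_random=n_random,
                n_brownian=n_brownian,
                seed=seed + k,
                trait_name=col,
            )
            row.update(D=dres.D, p_random=dres.p_random, p_brownian=dres.p_brownian)
        except DegenerateTraitError:
            row.update(D=np.nan, p_random=np.nan, p_brownian=np.nan)
        row["tau_significant"] = bool(row["p_perm"] < cfg.alpha) if row["p_perm"] == row["p_perm"] else False
        row["D_significant"] = bool(row["p_random"] < 0.05) if row["p_random"] == row["p_random"] else False
        rows.append(row)
    return pd.DataFrame(rows)
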