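"""Reproducibility, ratio-reconstruction, effect-size and clustering metrics.

These are the comparison instruments of the study: given per-probe result
tables from two technically replicated dataset halves (or from the ratio
and intensity models on the same half), they quantify how well gene
rankings and effect estimates agree.

Rankings order probes by ascending p-value, ties broken lexicographically
by probe id — a stable, documented rule shared by every metric here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .design import ChannelKey, HybridizationDesign
from .models import ResultTable
from .preprocess import ExpressionMatrix


@dataclass(frozen=True)
class OverlapCurve:
    """Fraction of shared top-k genes between two rankings, per list size k."""

    k: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        if len(self.k) != len(self.fraction):
            raise ValueError("k and fraction lengths differ")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("overlap fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k, "overlap_fraction": self.fraction})


def _check_same_probes(r1: ResultTable, r2: ResultTable) -> None:
    if set(r1.probe_ids) != set(r2.probe_ids):
        raise ValueError("result tables cover different probe sets")


def pvalue_reproducibility(
    r1: ResultTable, r2: ResultTable, method: str = "spearman"
) -> float:
    """Correlation between two per-probe p-value vectors.

    ``"spearman"`` (default) is rank-based, hence identical whether applied
    to p or -log10 p.  ``"pearson-neglog10"`` correlates the -log10 p
    vectors linearly instead.
    """
    _check_same_probes(r1, r2)
    if len(r1.probe_ids) < 3:
        raise ValueError("need at least 3 probes for a correlation")
    p1 = r1.frame["p"]
    p2 = r2.frame["p"].reindex(p1.index)
    if method == "spearman":
        rho, _ = stats.spearmanr(p1.to_numpy(), p2.to_numpy())
        return float(rho)
    if method == "pearson-neglog10":
        r, _ = stats.pearsonr(-np.log10(p1.to_numpy()), -np.log10(p2.to_numpy()))
        return float(r)
    raise ValueError(f"unknown method {method!r}")


def bin_overlap(r1: ResultTable, r2: ResultTable, bin_size: int = 1000) -> pd.DataFrame:
    """Overlap of p-value-ranked bins between two result tables.

    Probes are ordered by p-value and cut into consecutive bins of
    ``bin_size``; each bin's overlap is the number of probes both tables
    place in that bin, divided by the bin's size (a trailing partial bin
    uses its own size).
    """
    _check_same_probes(r1, r2)
    n = len(r1.probe_ids)
    if bin_size > n:
        raise ValueError(f"bin_size {bin_size} exceeds probe count {n}")
    order1 = r1.ranking()
    order2 = r2.ranking()
    records = []
    for b, start in enumerate(range(0, n, bin_size)):
        stop = min(start + bin_size, n)
        s1 = set(order1[start:stop])
        s2 = set(order2[start:stop])
        records.append(
            {
                "bin": b + 1,
                "bin_size": stop - start,
                "overlap": len(s1 & s2),
                "overlap_fraction": len(s1 & s2) / (stop - start),
            }
        )
    return pd.DataFrame(records)


def topk_overlap_curve(
    r1: ResultTable,
    r2: ResultTable,
    k_min: int = 10,
    k_max: int = 1000,
    step: int = 10,
) -> OverlapCurve:
    """Proportion of shared genes among the k top-ranked, for a grid of k."""
    _check_same_probes(r1, r2)
    n = len(r1.probe_ids)
    if k_max > n:
        raise ValueError(f"k_max {k_max} exceeds probe count {n}")
    order1 = r1.ranking()
    order2 = r2.ranking()
    ks = np.arange(k_min, k_max + 1, step)
    # incremental set growth: O(n) rather than O(n^2)
    fractions = np.empty(len(ks), dtype=float)
    s1: set = set()
    s2: set = set()
    shared = 0
    pos = 0
    for i, k in enumerate(ks):
        while pos < k:
            g1, g2 = order1[pos], order2[pos]
            if g1 in s2:
                shared += 1
            s1.add(g1)
            if g2 in s1:
                shared += 1
            s2.add(g2)
            pos += 1
        fractions[i] = shared / k
    return OverlapCurve(k=ks, fraction=fractions)


def recall_at_ratio_cutoff(
    r_ratio: ResultTable, r_intensity: ResultTable, k: int = 1000
) -> tuple[float, int]:
    """Sensitivity gain of the intensity model at the ratio model's cutoff.

    Takes the p-value of the k-th most significant probe in the ratio table
    as a cutoff; returns (a) the fraction of the ratio top-k whose intensity
    p-value also passes it, and (b) how many probes *outside* the ratio
    top-k have an intensity p-value strictly below it.
    """
    _check_same_probes(r_ratio, r_intensity)
    n = len(r_ratio.probe_ids)
    if k > n:
        raise ValueError(f"k {k} exceeds probe count {n}")
    order = r_ratio.ranking()
    top_k = order[:k]
    cutoff = float(r_ratio.frame.loc[order[k - 1], "p"])
    p_int = r_intensity.frame["p"]
    recall = float((p_int.loc[top_k] <= cutoff).mean())
    outside = p_int.drop(index=top_k)
    extra = int((outside < cutoff).sum())
    return recall, extra


@dataclass(frozen=True)
class RatioPairing:
    """A direct vs reconstructed comparison of one sample pair.

    ``channel_a``/``channel_b`` are the two samples' single-channel
    measurements on *other* arrays; ``direct_array`` co-hybridized the same
    sample pair, so its within-array log-ratio is the direct measurement.
    """

    channel_a: ChannelKey
    channel_b: ChannelKey
    direct_array: str


def reconstruct_ratios(
    m: ExpressionMatrix,
    design: HybridizationDesign,
    pairings: Sequence[RatioPairing],
) -> pd.DataFrame:
    """Compare directly measured log-ratios with in-silico reconstructed ones.

    For every pairing, the direct M is the log2 difference of the two
    channels co-hybridized on ``direct_array`` (oriented so that the sample
    measured by ``channel_a`` is the numerator) and the reconstructed M is
    the log2 difference of the two off-array channels.  Returns one row per
    pairing with the per-probe Pearson correlation between the two vectors.
    The matrix is expected to be log2-scale and already intensity-filtered.
    """
    if not m.log2:
        raise ValueError("reconstruct_ratios expects a log2-scale matrix")
    if not pairings:
        raise ValueError("no pairings given")
    records = []
    for pairing in pairings:
        for ch in (pairing.channel_a, pairing.channel_b):
            if ch not in m.channels:
                raise KeyError(f"channel {ch} not in matrix")
        direct_channels = [
            r.channel for r in design.rows if r.channel.array_id == pairing.direct_array
        ]
        if len(direct_channels) != 2:
            raise KeyError(f"array {pairing.direct_array!r} does not carry two channels")
        sample_a = design.row_for(pairing.channel_a).sample_id
        d0, d1 = direct_channels
        if design.row_for(d0).sample_id != sample_a:
            d0, d1 = d1, d0
        if design.row_for(d0).sample_id != sample_a:
            raise ValueError(
                f"array {pairing.direct_array!r} does not co-hybridize sample {sample_a!r}"
            )
        for ch in (d0, d1):
            if ch not in m.channels:
                raise KeyError(f"channel {ch} not in matrix")
        direct_m = m.channel_vector(d0) - m.channel_vector(d1)
        recon_m = m.channel_vector(pairing.channel_a) - m.channel_vector(pairing.channel_b)
        r, _ = stats.pearsonr(direct_m, recon_m)
        records.append(
            {
                "direct_array": pairing.direct_array,
                "channel_a": str(pairing.channel_a),
                "channel_b": str(pairing.channel_b),
                "pearson_r": float(r),
            }
        )
    return pd.DataFrame(records)


def effect_size_comparison(
    r_ratio: ResultTable, bandwidth: float | str = "silverman"
) -> tuple[pd.DataFrame, dict[str, stats.gaussian_kde]]:
    """Per-probe treatment vs array effect sizes, with smoothed histograms.

    The treatment effect size of a probe is the mean |M| over all unordered
    treatment pairs; the array effect size is the mean |alpha-hat| over the
    array coefficients.  Returns the per-probe table and Gaussian KDEs
    (Silverman bandwidth by default) of the two size distributions.
    """
    frame = r_ratio.frame
    if "mean_abs_array_effect" not in frame.columns:
        raise ValueError("result table has no array-effect estimates (ratio-model fit needed)")
    m_cols = [c for c in frame.columns if c.startswith("M[")]
    if not m_cols:
        raise ValueError("result table has no M-value columns")
    treatment_size = frame[m_cols].abs().mean(axis=1)
    array_size = frame["mean_abs_array_effect"]
    out = pd.DataFrame(
        {"treatment_effect_size": treatment_size, "array_effect_size": array_size}
    )
    kdes = {
        "treatment": stats.gaussian_kde(treatment_size.dropna().to_numpy(), bw_method=bandwidth),
        "array": stats.gaussian_kde(array_size.dropna().to_numpy(), bw_method=bandwidth),
    }
    return out, kdes


@dataclass
class ChannelDendrogram:
    """Complete-linkage tree over channels with merge heights."""

    linkage: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                name = self.labels[node.id].replace(":", "_").replace(",", "_")
                return f"{name}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist) + ";"


def cluster_channels(m: ExpressionMatrix, metric: str = "correlation") -> ChannelDendrogram:
    """Complete-linkage hierarchical clustering of the channel vectors.

    ``metric`` is ``"correlation"`` (distance 1 - Pearson r, scale-free and
    standard for expression QC) or ``"euclidean"``.  Raises if a channel is
    constant (its correlation is undefined).
    """
    if m.n_channels < 3:
        raise ValueError("need at least 3 channels to cluster")
    X = m.values.T  # channels x probes
    if metric == "correlation":
        sds = X.std(axis=1)
        for j, sd in enumerate(sds):
            if sd == 0:
                raise ValueError(f"channel {m.channels[j]} is constant; correlation undefined")
        corr = np.corrcoef(X)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        condensed = squareform(dist, checks=False)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    linkage = hierarchy.linkage(condensed, method="complete")
    return ChannelDendrogram(linkage=linkage, labels=[str(c) for c in m.channels])


def m_value_reproducibility(
    r1: ResultTable, r2: ResultTable, group_a: str, group_b: str
) -> float:
    """Pearson correlation of per-probe M(group_a vs group_b) between tables."""
    _check_same_probes(r1, r2)
    m1 = r1.m_column(group_a, group_b)
    m2 = r2.m_column(group_a, group_b).reindex(m1.index)
    valid = m1.notna() & m2.notna()
    if valid.sum() < 3:
        raise ValueError(f"contrast {group_a} vs {group_b} not estimable in both tables")
    r, _ = stats.pearsonr(m1[valid].to_numpy(), m2[valid].to_numpy())
    return float(r)
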