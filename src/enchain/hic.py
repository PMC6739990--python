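"""Significant-contact calling on 5-kb intra-chromosomal Hi-C contact lists.

The stage order is the one the analysis runs in:

1. :func:`ice_balance` — iterative correction (ICE) equalises bin marginals
   to strip coverage biases, returning balanced counts and per-bin biases.
2. :func:`fit_distance_decay` — an empirical, monotone distance-decay model
   over equal-occupancy distance bins within [L, U] = [5 kb, 2 Mb].
3. :func:`contact_significance` — upper-tail binomial p-values against the
   decay expectation and Benjamini–Hochberg q-values per tissue.
4. :func:`select_low_expressed_promoters` / :func:`calibrate_flexible_fdr` —
   the flexible-FDR rule: pick the largest q-threshold at which fewer than
   5% of the most repressed, lowly expressed (RPKM < 1) genes show any
   significant promoter contact.

Contacts live in a pandas DataFrame with columns
``chrom, bin_i, bin_j, count`` plus the derived
``balanced, distance, p_value, q_value``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .elements import (
    GeneRecord,
    RegulatoryElement,
    build_interval_trees,
    overlap_bp,
)

logger = logging.getLogger(__name__)

DEFAULT_L = 5000
DEFAULT_U = 2_000_000
DEFAULT_N_DISTANCE_BINS = 200
ICE_MAX_ITER = 200
ICE_TOL = 1e-6
LOW_EXPRESSION_RPKM = 1.0
FLAGGED_FRACTION_LIMIT = 0.05

#: Log-ish threshold grid spanning the per-tissue significance cutoffs the
#: flexible-FDR rule may land on (5e-2 down to 1e-12).
DEFAULT_FDR_GRID: tuple[float, ...] = tuple(
    sorted(
        {m * 10.0 ** e for m in (5, 2, 1) for e in range(-2, -13, -1)} | {0.05},
        reverse=True,
    )
)


@dataclass
class DecayModel:
    """Empirical expected contact probability as a function of distance.

    ``expected_prob`` is monotone non-increasing across the equal-occupancy
    distance bins delimited by ``distance_bin_edges``; ``total_contacts``
    is the balanced-count total the binomial test uses as its sample size.
    Between the bins' representative distances (``knot_distances``) the
    probability is interpolated log-log, so the expectation decays
    smoothly with distance instead of stepping at bin edges.
    """

    distance_bin_edges: np.ndarray
    expected_prob: np.ndarray
    total_contacts: float
    knot_distances: np.ndarray | None = None

    def prob_for_distance(self, distance: np.ndarray) -> np.ndarray:
        """Expected probability per contact; NaN outside the fitted range."""
        d = np.asarray(distance, dtype=float)
        if self.knot_distances is None or len(self.expected_prob) == 1:
            idx = np.searchsorted(self.distance_bin_edges, d, side="right") - 1
            idx = np.clip(idx, 0, len(self.expected_prob) - 1)
            out = self.expected_prob[idx]
        else:
            out = np.exp(
                np.interp(
                    np.log(np.maximum(d, 1.0)),
                    np.log(self.knot_distances),
                    np.log(np.maximum(self.expected_prob, 1e-300)),
                )
            )
        outside = (d < self.distance_bin_edges[0]) | (d > self.distance_bin_edges[-1])
        return np.where(outside, np.nan, out)


@dataclass
class FdrCalibration:
    grid: np.ndarray
    fraction_flagged: np.ndarray
    chosen_threshold: float
    limit: float = FLAGGED_FRACTION_LIMIT


def ice_balance(
    contacts: pd.DataFrame,
    max_iter: int = ICE_MAX_ITER,
    tol: float = ICE_TOL,
) -> tuple[pd.DataFrame, dict[tuple[str, int], float]]:
    """Iterative correction of a raw contact list.

    Counts are interpreted symmetrically; bins are balanced per chromosome
    so every observed bin's marginal converges to the common mean (relative
    tolerance ``tol``).  Bins with zero marginal are masked (they carry no
    contacts, hence no bias estimate).  The balanced totals are rescaled to
    preserve each chromosome's raw total, so biases are defined up to that
    global constant.

    Returns the contact frame with a ``balanced`` column and the per-bin
    bias factors keyed by (chrom, bin_start).
    """
    if contacts.empty or not (contacts["count"] > 0).any():
        raise ValueError("empty matrix: no nonzero contacts to balance")

    out = contacts.copy()
    out["balanced"] = np.nan
    biases: dict[tuple[str, int], float] = {}

    for chrom, sub in out.groupby("chrom", sort=False):
        sub = sub[sub["count"] > 0]
        if sub.empty:
            continue
        all_bins = np.unique(np.concatenate([sub["bin_i"].to_numpy(), sub["bin_j"].to_numpy()]))
        index = {b: k for k, b in enumerate(all_bins)}
        i_idx = sub["bin_i"].map(index).to_numpy()
        j_idx = sub["bin_j"].map(index).to_numpy()
        w = sub["count"].to_numpy(dtype=float)
        nb = len(all_bins)
        bias = np.ones(nb)
        raw_total = sub["count"].sum()
        for _ in range(max_iter):
            marg = np.bincount(i_idx, weights=w, minlength=nb) + np.bincount(
                j_idx, weights=w, minlength=nb
            )
            active = marg > 0
            s = np.ones(nb)
            s[active] = marg[active] / marg[active].mean()
            w = w / (s[i_idx] * s[j_idx])
            bias *= s
            # renormalise each sweep: keeps the iteration finite on degenerate
            # supports (e.g. a path graph) where exact balance is infeasible
            w *= raw_total / w.sum()
            bias /= np.exp(np.mean(np.log(bias[active])))
            if np.abs(s[active] - 1.0).max() < tol:
                break
        w *= raw_total / w.sum()
        out.loc[sub.index, "balanced"] = w
        for b, f in zip(all_bins, bias):
            biases[(chrom, int(b))] = float(f)

    out = out[out["balanced"].notna()].reset_index(drop=True)
    out["distance"] = out["bin_j"] - out["bin_i"]
    return out, biases


def fit_distance_decay(
    contacts: pd.DataFrame,
    L: int = DEFAULT_L,
    U: int = DEFAULT_U,
    n_bins: int = DEFAULT_N_DISTANCE_BINS,
) -> DecayModel:
    """Fit a monotone empirical decay model on balanced counts in [L, U].

    Distances are grouped into roughly equal-occupancy bins (equal numbers
    of contact pairs; ties in distance never straddle a bin edge).  The
    per-bin expected probability is the mean balanced count divided by the
    total balanced count, with monotone non-increase enforced by isotonic
    regression (pool-adjacent-violators).
    """
    if "balanced" not in contacts:
        raise ValueError("contacts must be balanced first (run ice_balance)")
    if "distance" not in contacts:
        contacts = contacts.assign(distance=contacts["bin_j"] - contacts["bin_i"])
    sub = contacts[(contacts["distance"] >= L) & (contacts["distance"] <= U)]
    if sub.empty:
        raise ValueError(f"no contacts within distance range [{L}, {U}]")

    total = float(sub["balanced"].sum())
    per_dist = (
        sub.groupby("distance")["balanced"].agg(["mean", "count", "sum"]).sort_index()
    )
    distances = per_dist.index.to_numpy(dtype=float)
    n_pairs = per_dist["count"].to_numpy()

    # equal-occupancy assignment by cumulative pair count
    n_bins = min(n_bins, len(distances))
    cum = np.cumsum(n_pairs)
    targets = cum[-1] * (np.arange(1, n_bins + 1) / n_bins)
    bin_of = np.searchsorted(targets, cum, side="left")
    bin_of = np.minimum(bin_of, n_bins - 1)

    edges = [distances[0]]
    probs = []
    weights = []
    knots = []
    sums = per_dist["sum"].to_numpy()
    for b in range(n_bins):
        mask = bin_of == b
        if not mask.any():
            continue
        edges.append(distances[mask][-1])
        probs.append(sums[mask].sum() / n_pairs[mask].sum() / total)
        weights.append(n_pairs[mask].sum())
        knots.append(np.average(distances[mask], weights=n_pairs[mask]))

    probs = np.asarray(probs)
    weights = np.asarray(weights, dtype=float)
    iso = IsotonicRegression(increasing=False, y_min=1e-300, y_max=1.0)
    mono = iso.fit_transform(np.arange(len(probs)), probs, sample_weight=weights)
    return DecayModel(
        distance_bin_edges=np.asarray(edges, dtype=float),
        expected_prob=np.asarray(mono),
        total_contacts=total,
        knot_distances=np.asarray(knots, dtype=float),
    )


def contact_significance(
    contacts: pd.DataFrame,
    model: DecayModel,
) -> pd.DataFrame:
    """Attach binomial upper-tail p-values and BH q-values to contacts.

    For a contact with balanced count k at distance d, p = P(X >= round(k))
    for X ~ Binomial(round(total), expected_prob(d)).  Contacts at distances
    outside the model's fitted range are excluded (logged).  BH adjustment
    is applied over all retained contacts (genome-wide, one tissue).
    """
    if "distance" not in contacts:
        contacts = contacts.assign(distance=contacts["bin_j"] - contacts["bin_i"])
    prob = model.prob_for_distance(contacts["distance"].to_numpy())
    keep = ~np.isnan(prob)
    if (~keep).any():
        logger.info("excluding %d contacts outside decay-model range", int((~keep).sum()))
    out = contacts.loc[keep].reset_index(drop=True)
    prob = prob[keep]
    n = int(round(model.total_contacts))
    k = np.rint(out["balanced"].to_numpy()).astype(np.int64)
    out["p_value"] = stats.binom.sf(k - 1, n, prob)
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def select_low_expressed_promoters(
    genes: Sequence[GeneRecord],
    promoters: Sequence[RegulatoryElement],
    h3k27me3: Sequence,
    k: int = 1000,
) -> list[str]:
    """Promoter ids of the top-k lowly expressed (RPKM < 1), most
    H3K27me3-dense genes — the presumed-inactive calibration set.

    Density is H3K27me3-covered bp per bp of promoter window; a gene with
    several promoters scores by its densest one.  Ties break by gene_id.
    """
    low = [g for g in genes if g.rpkm < LOW_EXPRESSION_RPKM]
    if not low:
        raise ValueError("no genes with RPKM below 1.0")
    low_ids = {g.gene_id for g in low}
    trees = build_interval_trees(h3k27me3)
    by_gene: dict[str, tuple[float, list[str]]] = {}
    for p in promoters:
        if p.gene_id not in low_ids:
            continue
        dens = overlap_bp(p.interval, trees) / p.interval.length
        best, ids = by_gene.get(p.gene_id, (-1.0, []))
        ids = ids + [p.element_id]
        by_gene[p.gene_id] = (max(best, dens), ids)
    ranked = sorted(by_gene.items(), key=lambda kv: (-kv[1][0], kv[0]))
    result: list[str] = []
    for gene_id, (_, pids) in ranked[: min(k, len(ranked))]:
        result.extend(sorted(pids))
    return result


def calibrate_flexible_fdr(
    contacts: pd.DataFrame,
    low_expr_promoters: Sequence[str],
    bin_map: Mapping[str, set],
    grid: Sequence[float] = DEFAULT_FDR_GRID,
) -> FdrCalibration:
    """Choose the largest q-threshold flagging < 5% of calibration promoters.

    A promoter is flagged at threshold t if any of its (chrom, bin) bins
    partakes in a contact with q <= t.  ``bin_map`` maps element ids to
    sets of (chrom, bin_start) pairs (see
    :func:`enchain.chains.map_elements_to_chrom_bins`).
    """
    grid = np.asarray(sorted(set(grid), reverse=True), dtype=float)
    if not low_expr_promoters:
        raise ValueError("no calibration promoters supplied")
    if "q_value" not in contacts:
        raise ValueError("contacts carry no q_value; run contact_significance first")

    # minimum q touching each (chrom, bin)
    qi = contacts.groupby(["chrom", "bin_i"])["q_value"].min()
    qj = contacts.groupby(["chrom", "bin_j"])["q_value"].min()
    min_q: dict[tuple[str, int], float] = {}
    for series in (qi, qj):
        for key, q in series.items():
            key = (key[0], int(key[1]))
            min_q[key] = min(q, min_q.get(key, np.inf))

    promoter_min_q = np.array(
        [
            min((min_q.get((c, int(b)), np.inf) for c, b in bin_map.get(pid, ())), default=np.inf)
            for pid in low_expr_promoters
        ]
    )
    fractions = np.array([(promoter_min_q <= t).mean() for t in grid])
    ok = fractions < FLAGGED_FRACTION_LIMIT
    if not ok.any():
        raise ValueError(
            "no threshold satisfies the flexible-FDR constraint; "
            f"minimum achievable flagged fraction is {fractions.min():.3f}"
        )
    chosen = float(grid[np.argmax(ok)])  # grid is decreasing: first True is largest t
    return FdrCalibration(grid=grid, fraction_flagged=fractions, chosen_threshold=chosen)
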