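"""Distance-based community comparison and richness estimation.

Bray–Curtis dissimilarities (optionally on square-root-transformed
relative abundances), a Mantel test between two distance matrices, one-way
and nested PERMANOVA, Hurlbert rarefaction of MOTU richness, and
sample-based MOTU accumulation curves.

All permutation tests use the add-one estimator p = (1 + b) / (1 + m),
where b counts permuted statistics at least as extreme as the observed
one — it never returns zero and is the standard conservative choice.
They are bit-reproducible given (seed, n_perm), and both tests offer an
exact mode that enumerates every label permutation (feasible for n ≤ 8).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from skbio import DistanceMatrix

from .table import MotuTable, ValidationError

_EXACT_LIMIT = 8


class CommunityStatsError(ValueError):
    pass


@dataclass
class PermutationResult:
    """Outcome of a permutation test (reproducible given its seed)."""

    statistic: float
    statistic_name: str
    n_permutations: int
    p_value: float
    seed: int | None = None
    method: str = "monte_carlo"
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# distances


def bray_curtis(
    table: MotuTable,
    transform: str = "none",
    relative: bool = True,
) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarities between samples.

    d(x, y) = 1 - 2 Σ min(x_i, y_i) / (Σ x_i + Σ y_i), computed on
    relative abundances by default (``relative=False`` uses raw counts).
    ``transform="sqrt"`` square-roots the (relative) abundances first —
    the usual moderation of dominant taxa for ordination-style analyses.
    """
    if transform not in ("none", "sqrt"):
        raise CommunityStatsError(f"unknown transform {transform!r}")
    depths = table.sample_depths()
    zero = depths.index[depths == 0].tolist()
    if zero:
        raise CommunityStatsError(f"zero-total samples {zero}")
    mat = table.counts.to_numpy(dtype=float).T  # samples x motus
    if relative:
        mat = mat / mat.sum(axis=1, keepdims=True)
    if transform == "sqrt":
        mat = np.sqrt(mat)
    condensed = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(table.sample_ids))


# ---------------------------------------------------------------------------
# Mantel


def _mantel_stat(c1: np.ndarray, c2: np.ndarray) -> float:
    return float(np.corrcoef(c1, c2)[0, 1])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "monte_carlo",
) -> PermutationResult:
    """Mantel test: Pearson correlation between two distance matrices.

    The statistic is the correlation of the lower-triangle entries;
    significance comes from jointly permuting rows and columns of
    ``d2``, with a one-sided (greater) alternative.  ``method="exact"``
    enumerates all n! permutations instead (n ≤ 8) and returns
    p = #{r_perm ≥ r_obs} / n! (identity included).
    """
    if list(d1.ids) != list(d2.ids):
        raise CommunityStatsError("distance matrices have mismatched labels")
    n = d1.shape[0]
    if n < 4:
        raise CommunityStatsError("Mantel test needs at least 4 samples")
    m1, m2 = d1.data, d2.data
    c1 = squareform(m1, checks=False)
    if np.std(c1) == 0 or np.std(squareform(m2, checks=False)) == 0:
        raise CommunityStatsError("constant distance matrix: r undefined")
    obs = _mantel_stat(c1, squareform(m2, checks=False))

    if method == "exact":
        if n > _EXACT_LIMIT:
            raise CommunityStatsError(f"exact enumeration limited to n<={_EXACT_LIMIT}")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            r = _mantel_stat(c1, squareform(m2[np.ix_(p, p)], checks=False))
            count += r >= obs - 1e-12
            total += 1
        return PermutationResult(obs, "mantel_r", total, count / total,
                                 seed, "exact")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r = _mantel_stat(c1, squareform(m2[np.ix_(p, p)], checks=False))
        hits += r >= obs - 1e-12
    p_value = (1 + hits) / (1 + n_perm)
    return PermutationResult(obs, "mantel_r", n_perm, p_value, seed)


# ---------------------------------------------------------------------------
# PERMANOVA


def _group_codes(grouping: pd.Series, ids) -> np.ndarray:
    g = pd.Series(grouping).reindex(ids)
    if g.isna().any():
        missing = list(g.index[g.isna()])
        raise CommunityStatsError(f"grouping missing for samples {missing}")
    return pd.Categorical(g).codes.astype(np.int64)


def _within_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Sum over groups of (within-group Σ_{i<j} d²) / group size."""
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub.sum() / (2 * len(idx))
    return ss


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int,
              ss_total: float) -> float:
    n = len(codes)
    ss_within = _within_ss(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0 or ss_within <= 0:
        return math.inf
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    dist: DistanceMatrix,
    grouping,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "monte_carlo",
):
    """Permutational multivariate ANOVA on a distance matrix.

    One-way design: ``grouping`` is a Series (or mapping) of group
    labels per sample; returns a single :class:`PermutationResult` with
    the pseudo-F statistic.  Nested design: ``grouping`` is a pair
    ``(outer, inner)`` of Series (e.g. estuary, site-within-estuary);
    sums of squares are partitioned sequentially (Type I, outer fitted
    first) and a result is returned per term, keyed by name.  P-values
    come from unrestricted permutation of sample labels;
    ``method="exact"`` enumerates all permutations (n ≤ 8).
    """
    if isinstance(grouping, (tuple, list)) and len(grouping) == 2:
        return _permanova_nested(dist, grouping[0], grouping[1],
                                 n_perm=n_perm, seed=seed)
    ids = list(dist.ids)
    codes = _group_codes(grouping, ids)
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise CommunityStatsError("PERMANOVA needs at least 2 groups")
    d2 = dist.data.astype(float) ** 2
    n = len(ids)
    ss_total = d2.sum() / (2 * n)
    obs = _pseudo_f(d2, codes, n_groups, ss_total)

    if method == "exact":
        if n > _EXACT_LIMIT:
            raise CommunityStatsError(f"exact enumeration limited to n<={_EXACT_LIMIT}")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            f = _pseudo_f(d2, codes[np.array(perm)], n_groups, ss_total)
            count += f >= obs - 1e-12
            total += 1
        return PermutationResult(obs, "pseudo_F", total, count / total,
                                 seed, "exact",
                                 extra={"df": (int(n_groups - 1), int(n - n_groups))})

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f = _pseudo_f(d2, codes[rng.permutation(n)], n_groups, ss_total)
        hits += f >= obs - 1e-12
    p_value = (1 + hits) / (1 + n_perm)
    return PermutationResult(obs, "pseudo_F", n_perm, p_value, seed,
                             extra={"df": (int(n_groups - 1), int(n - n_groups))})


def _nested_fs(d2, outer_codes, cell_codes, n_outer, n_cells, ss_total, n):
    ss_w_outer = _within_ss(d2, outer_codes, n_outer)
    ss_w_cells = _within_ss(d2, cell_codes, n_cells)
    ss_outer = ss_total - ss_w_outer
    ss_inner = ss_w_outer - ss_w_cells  # sequential: inner after outer
    ss_resid = ss_w_cells
    df_outer = n_outer - 1
    df_inner = n_cells - n_outer
    df_resid = n - n_cells
    if df_resid <= 0 or ss_resid <= 0:
        return math.inf, math.inf, (ss_outer, ss_inner, ss_resid)
    ms_resid = ss_resid / df_resid
    f_outer = (ss_outer / df_outer) / ms_resid if df_outer > 0 else math.nan
    f_inner = (ss_inner / df_inner) / ms_resid if df_inner > 0 else math.nan
    return f_outer, f_inner, (ss_outer, ss_inner, ss_resid)


def _permanova_nested(
    dist: DistanceMatrix,
    outer,
    inner,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict[str, PermutationResult]:
    ids = list(dist.ids)
    outer_s = pd.Series(outer).reindex(ids)
    inner_s = pd.Series(inner).reindex(ids)
    if outer_s.isna().any() or inner_s.isna().any():
        raise CommunityStatsError("grouping missing for some samples")
    # each inner level must belong to exactly one outer level
    span = pd.DataFrame({"o": outer_s, "i": inner_s}).drop_duplicates()
    multi = span["i"][span["i"].duplicated()].unique().tolist()
    if multi:
        raise CommunityStatsError(
            f"inner groups spanning multiple outer levels: {multi}"
        )
    outer_codes = pd.Categorical(outer_s).codes.astype(np.int64)
    cell_codes = pd.Categorical(inner_s).codes.astype(np.int64)
    n_outer = outer_codes.max() + 1
    n_cells = cell_codes.max() + 1
    if n_outer < 2:
        raise CommunityStatsError("nested PERMANOVA needs >= 2 outer groups")
    n = len(ids)
    d2 = dist.data.astype(float) ** 2
    ss_total = d2.sum() / (2 * n)
    f_outer, f_inner, sss = _nested_fs(
        d2, outer_codes, cell_codes, n_outer, n_cells, ss_total, n
    )
    rng = np.random.default_rng(seed)
    hits_o = hits_i = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        fo, fi, _ = _nested_fs(
            d2, outer_codes[p], cell_codes[p], n_outer, n_cells, ss_total, n
        )
        hits_o += fo >= f_outer - 1e-12
        hits_i += fi >= f_inner - 1e-12
    extra = {"ss": {"outer": sss[0], "inner": sss[1], "residual": sss[2]},
             "ss_total": ss_total}
    return {
        "outer": PermutationResult(f_outer, "pseudo_F", n_perm,
                                   (1 + hits_o) / (1 + n_perm), seed,
                                   extra=dict(extra, df=(n_outer - 1, n - n_cells))),
        "inner": PermutationResult(f_inner, "pseudo_F", n_perm,
                                   (1 + hits_i) / (1 + n_perm), seed,
                                   extra=dict(extra, df=(n_cells - n_outer, n - n_cells))),
    }


# ---------------------------------------------------------------------------
# rarefaction


def rarefy_richness(
    counts,
    depth: int = 1000,
    method: str = "expected",
    n_perm: int = 500,
    seed: int | None = None,
) -> float:
    """Expected MOTU richness of one sample at a standard read depth.

    ``method="expected"`` evaluates Hurlbert's closed form
    E[S] = Σ_i [1 − C(N−N_i, depth) / C(N, depth)] (hypergeometric
    probability that taxon i appears in a depth-sized subsample without
    replacement).  ``method="resample"`` averages observed richness over
    ``n_perm`` random subsamples; the two agree within Monte-Carlo error.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise CommunityStatsError(f"depth {depth} exceeds sample total {total}")
    if depth < 1:
        raise CommunityStatsError("depth must be >= 1")
    if method == "expected":
        # log-space binomial ratios to avoid overflow
        def log_comb(n, k):
            return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

        with np.errstate(invalid="ignore"):
            log_absent = log_comb(total - counts, depth) - log_comb(total, depth)
        absent = np.where(total - counts < depth, 0.0, np.exp(log_absent))
        return float(np.sum(1.0 - absent))
    if method == "resample":
        rng = np.random.default_rng(seed)
        richness = np.empty(n_perm)
        for i in range(n_perm):
            draw = rng.multivariate_hypergeometric(counts, depth)
            richness[i] = int((draw > 0).sum())
        return float(richness.mean())
    raise CommunityStatsError(f"unknown method {method!r}")


def accumulation_curve(
    table: MotuTable,
    sample_group=None,
    n_perm: int = 1000,
    rarefy_depth: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample-based MOTU accumulation curve after per-sample rarefaction.

    Each sample is first rarefied (one seeded subsample draw) to
    ``rarefy_depth`` reads; samples below that depth are excluded with a
    warning.  The curve reports, for k = 1..n, the mean ± SD cumulative
    richness over ``n_perm`` random orderings of the rarefied samples.
    Monotone non-decreasing in k; its endpoint equals the pooled
    richness of the rarefied samples.
    """
    ids = list(sample_group) if sample_group is not None else list(table.sample_ids)
    if len(ids) < 2:
        raise CommunityStatsError("accumulation curve needs at least 2 samples")
    rng = np.random.default_rng(seed)
    depths = table.sample_depths()
    incidence = []
    kept = []
    for s in ids:
        if depths[s] < rarefy_depth:
            warnings.warn(
                f"sample {s!r} has {int(depths[s])} reads < rarefy depth "
                f"{rarefy_depth}; excluded from accumulation curve",
                stacklevel=2,
            )
            continue
        col = table.counts[s].to_numpy(dtype=np.int64)
        draw = rng.multivariate_hypergeometric(col, rarefy_depth)
        incidence.append(draw > 0)
        kept.append(s)
    if len(kept) < 2:
        raise CommunityStatsError("fewer than 2 samples at rarefaction depth")
    inc = np.array(incidence)  # samples x motus, boolean
    n = len(kept)
    acc = np.zeros((n_perm, n))
    for rep in range(n_perm):
        order = rng.permutation(n)
        seen = np.zeros(inc.shape[1], dtype=bool)
        for k, idx in enumerate(order):
            seen |= inc[idx]
            acc[rep, k] = seen.sum()
    return pd.DataFrame({
        "k": np.arange(1, n + 1),
        "mean_richness": acc.mean(axis=0),
        "sd_richness": acc.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n),
    })
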