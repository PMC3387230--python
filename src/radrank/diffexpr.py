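"""Differential-expression stage for two-group expression matrices.

Pipeline: log2 transform → quantile normalization → two-sample t-scores →
permutation p-values (Monte Carlo or exhaustive) → Storey q-values →
significance selection at an FDR threshold → probe-to-gene collapsing.

The permutation p-value for a probe is the fraction of group-label
permutations whose |t| is at least the observed |t|.  The same permutation
stream is applied to every probe in a given iteration, preserving the
across-probe correlation structure of the null.  No fold-change cutoff is
applied at any point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .formats_io import LINEAR, LOG2, ExpressionMatrix, GeneSet, ProbeGeneMap

#: Signed sentinel t-value for zero-variance probes with unequal group means.
DEGENERATE_T_SENTINEL = 1e9

#: Floor applied before the log2 transform so zeros never produce -inf.
LOG2_FLOOR = 1.0


@dataclass
class TestConfig:
    """Tuning knobs of the differential-expression stage.

    Defaults follow the published procedure: 10,000 permutations, a
    two-tailed pooled-variance t-test, the plain count/m p-value estimator,
    Storey's pi0 at lambda = 0.5 and an FDR threshold of 20%.
    """

    n_perm: int = 10_000
    seed: int = 0
    variant: str = "student_pooled"  # student_pooled | welch | paired
    p_estimator: str = "plain"  # plain | add_one
    fdr_threshold: float = 0.20
    storey_lambda: float = 0.5
    exhaustive: bool = False
    perm_chunk: int = 512  # permutations vectorized per block

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if not 0 < self.storey_lambda < 1:
            raise ValueError("storey_lambda must lie in (0, 1)")
        if self.variant not in ("student_pooled", "welch", "paired"):
            raise ValueError(f"unknown t-test variant {self.variant!r}")
        if self.p_estimator not in ("plain", "add_one"):
            raise ValueError(f"unknown p estimator {self.p_estimator!r}")


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Log-base-2 transform linear intensities, flooring values at 1.0.

    Raises if the matrix is already on the log2 scale (double-transform
    guard).
    """
    if matrix.scale == LOG2:
        raise ValueError("matrix is already log2 transformed")
    vals = np.log2(np.maximum(matrix.values, LOG2_FLOOR))
    data = pd.DataFrame(vals, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(data=data, scale=LOG2, labels=matrix.labels)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize across all samples.

    Each column's sorted values are replaced by the vector of row means of
    the column-sorted matrix; within-column rank order is preserved.  After
    normalization every sample has an identical value distribution.
    """
    if matrix.n_samples < 2:
        return matrix
    X = matrix.values
    if np.isnan(X).any():
        raise ValueError("missing values are not supported (imputation out of scope)")
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[order[:, j], j] = ref
    data = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(data=data, scale=matrix.scale, labels=matrix.labels)


def _t_from_groups(
    x1: np.ndarray, x2: np.ndarray, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t statistics for (probes × samples) group blocks.

    Returns (t, degenerate_flag).  Zero-variance probes never propagate NaN:
    equal means give t = 0, unequal means give a signed large sentinel.
    """
    n1, n2 = x1.shape[-1], x2.shape[-1]
    m1, m2 = x1.mean(axis=-1), x2.mean(axis=-1)
    diff = m1 - m2
    if variant == "paired":
        if n1 != n2:
            raise ValueError("paired variant requires equal group sizes")
        d = x1 - x2
        sd = d.std(axis=-1, ddof=1)
        denom = sd / math.sqrt(n1)
        diff = d.mean(axis=-1)
    elif variant == "welch":
        v1 = x1.var(axis=-1, ddof=1)
        v2 = x2.var(axis=-1, ddof=1)
        denom = np.sqrt(v1 / n1 + v2 / n2)
    else:  # student_pooled
        v1 = x1.var(axis=-1, ddof=1)
        v2 = x2.var(axis=-1, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    degenerate = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, denom))
    t = np.where(degenerate & (diff != 0), np.sign(diff) * DEGENERATE_T_SENTINEL, t)
    return t, degenerate


def t_scores(matrix: ExpressionMatrix, cfg: TestConfig | None = None) -> pd.DataFrame:
    """Per-probe two-sample t statistics for the matrix's two groups.

    Returns a DataFrame with columns ``t_score``, ``fold_change_log2`` and
    ``degenerate`` indexed by probe id.
    """
    cfg = cfg or TestConfig()
    g1, g2, _ = matrix.group_columns()
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    X = matrix.values
    t, degenerate = _t_from_groups(X[:, g1], X[:, g2], cfg.variant)
    fc = X[:, g2].mean(axis=1) - X[:, g1].mean(axis=1)
    if matrix.scale != LOG2:
        fc = np.log2(
            np.maximum(X[:, g2].mean(axis=1), LOG2_FLOOR)
            / np.maximum(X[:, g1].mean(axis=1), LOG2_FLOOR)
        )
    return pd.DataFrame(
        {"t_score": t, "fold_change_log2": fc, "degenerate": degenerate},
        index=matrix.data.index,
    )


def _all_label_splits(n_total: int, n1: int) -> np.ndarray:
    """All distinct assignments of n1 'group 1' slots among n_total columns."""
    splits = list(combinations(range(n_total), n1))
    return np.array(splits, dtype=np.intp)


def permutation_pvalues(
    matrix: ExpressionMatrix, cfg: TestConfig | None = None
) -> pd.DataFrame:
    """Permutation p-values for the two-group comparison.

    For each probe, p = #{permutations with |t_perm| >= |t_obs|} / m (plain
    estimator) or (count + 1)/(m + 1) (add-one).  Monte-Carlo label
    permutations are drawn uniformly with replacement; ``cfg.exhaustive``
    switches to full enumeration of all C(n, n1) label splits.  The identical
    permutation stream is applied to all probes.

    Returns columns ``t_score``, ``perm_p``, ``fold_change_log2``,
    ``degenerate``.
    """
    cfg = cfg or TestConfig()
    obs = t_scores(matrix, cfg)
    g1, g2, _ = matrix.group_columns()
    X = matrix.values
    n1 = len(g1)
    cols = np.concatenate([g1, g2])
    abs_obs = np.abs(obs["t_score"].to_numpy())
    # tolerance absorbs summation-order rounding when a drawn permutation
    # reproduces the observed split; distinct splits differ macroscopically
    threshold = abs_obs - 1e-9 * np.maximum(abs_obs, 1.0)

    if cfg.exhaustive:
        splits = _all_label_splits(len(cols), n1)
        m = len(splits)
        counts = np.zeros(X.shape[0], dtype=np.int64)
        for split in splits:
            mask = np.zeros(len(cols), dtype=bool)
            mask[split] = True
            p1 = cols[mask]
            p2 = cols[~mask]
            t_perm, _ = _t_from_groups(X[:, p1], X[:, p2], cfg.variant)
            counts += np.abs(t_perm) >= threshold
    else:
        rng = np.random.default_rng(cfg.seed)
        m = cfg.n_perm
        counts = np.zeros(X.shape[0], dtype=np.int64)
        done = 0
        while done < m:
            k = min(cfg.perm_chunk, m - done)
            counts += _count_extreme_chunk(X, cols, n1, threshold, rng, k, cfg.variant)
            done += k

    if cfg.p_estimator == "add_one":
        p = (counts + 1) / (m + 1)
    else:
        p = counts / m
    out = obs.copy()
    out.insert(1, "perm_p", p)
    # degenerate probes are never called significant
    out.loc[out["degenerate"] & (out["t_score"] == 0), "perm_p"] = 1.0
    return out


def _count_extreme_chunk(
    X: np.ndarray,
    cols: np.ndarray,
    n1: int,
    threshold: np.ndarray,
    rng: np.random.Generator,
    k: int,
    variant: str,
) -> np.ndarray:
    """Count permutations in a chunk of k with |t_perm| >= |t_obs| per probe."""
    counts = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(k):
        perm = rng.permutation(cols)
        t_perm, _ = _t_from_groups(X[:, perm[:n1]], X[:, perm[n1:]], variant)
        counts += np.abs(t_perm) >= threshold
    return counts


def storey_qvalues(
    pvalues: np.ndarray | pd.Series, lam: float = 0.5
) -> tuple[np.ndarray, float]:
    """Storey q-values and the pi0 estimate at a fixed lambda.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) * m)); q-values follow the
    step-up recursion q_(m) = min(1, pi0 * p_(m)),
    q_(i) = min(q_(i+1), pi0 * m * p_(i) / i), returned in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < lam < 1:
        raise ValueError("lambda must lie in (0, 1)")
    m = p.size
    pi0 = min(1.0, np.count_nonzero(p > lam) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = np.empty(m)
    q_sorted[-1] = min(1.0, pi0 * ps[-1])
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i + 1], pi0 * m * ps[i] / (i + 1))
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def select_significant(result: pd.DataFrame, fdr_threshold: float = 0.20) -> list[str]:
    """Probe ids with q-value <= the FDR threshold (boundary inclusive).

    Deliberately applies no fold-change filter.
    """
    if "q_value" not in result.columns:
        raise ValueError("q-values not computed; run the pipeline first")
    mask = result["q_value"] <= fdr_threshold
    return list(result.index[mask])


def collapse_probes(sig_probes: list[str] | set[str], pmap: ProbeGeneMap) -> GeneSet:
    """Collapse significant probes onto genes with the any-probe rule.

    A gene is significant iff at least one of its probes is significant.
    Probes absent from the map are dropped (count is logged via the return's
    ``n_lines`` bookkeeping).
    """
    genes: list[str] = []
    dropped = 0
    for probe in sig_probes:
        g = pmap.get(str(probe))
        if g is None:
            dropped += 1
        else:
            genes.append(g)
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "%d significant probes had no gene mapping and were dropped", dropped
        )
    return GeneSet(name="significant", symbols=frozenset(genes), n_lines=len(genes))


def run_diffexpr(
    matrix: ExpressionMatrix, cfg: TestConfig | None = None
) -> pd.DataFrame:
    """Full stage: log2 (if needed) → quantile normalize → permutation test →
    Storey q-values.  Returns the per-probe result table."""
    cfg = cfg or TestConfig()
    m = matrix
    if m.scale == LINEAR:
        m = log2_transform(m)
    m = quantile_normalize(m)
    result = permutation_pvalues(m, cfg)
    q, pi0 = storey_qvalues(result["perm_p"].to_numpy(), lam=cfg.storey_lambda)
    result["q_value"] = q
    result.attrs["pi0"] = pi0
    return result
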