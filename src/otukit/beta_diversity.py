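"""Between-sample composition: Bray-Curtis dissimilarity, permutational
variance partitioning on a continuous covariate, and convergence of each age
bin toward the oldest (adult-like) bin.

The variance test is the distance-matrix analogue of regressing community
composition on age: square the distances, Gower-center them, and partition
the total sum of squares by the hat matrix of the design ``[1, age]``.
Significance comes from permuting the covariate across samples, so no
distributional assumptions are placed on the dissimilarities.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from ._stats import bonferroni, ranksum_test
from .core_io import AnalysisConfig, CountTable, SampleMetadata

__all__ = [
    "PermanovaResult",
    "BinDistanceResult",
    "bray_curtis",
    "permanova_continuous",
    "distances_to_reference",
    "bin_distance_test",
]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    df_model: int
    df_residual: int
    seed: int
    exhaustive: bool = False

    def to_dict(self) -> dict:
        return {
            "pseudo_f": self.pseudo_f,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "df_model": self.df_model,
            "df_residual": self.df_residual,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
        }


@dataclass
class BinDistanceResult:
    age_bin: str
    distances: np.ndarray
    reference_within: np.ndarray
    raw_p: float | None = None
    adjusted_p: float | None = None


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities over raw counts.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); every sample must have a
    positive total.
    """
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count; cannot compute Bray-Curtis")
    vals = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
    return DistanceMatrix(vals, ids=list(table.sample_ids))


def _trace_ss(dm_vals: np.ndarray, covariate: np.ndarray) -> tuple[float, float]:
    """(SS_model, SS_total) from Gower-centered squared distances."""
    n = dm_vals.shape[0]
    a = -0.5 * dm_vals**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    x = np.column_stack([np.ones(n), covariate])
    h = x @ np.linalg.solve(x.T @ x, x.T)
    ss_total = float(np.trace(g))
    ss_model = float(np.sum(h * g))  # tr(HGH) = tr(HG) since H is idempotent
    return ss_model, ss_total


def permanova_continuous(
    dm: DistanceMatrix,
    covariate,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutation test of a continuous covariate against a distance matrix.

    Pseudo-F = (SS_model/df_model) / (SS_residual/df_residual) with
    df_model = 1.  The permutation distribution shuffles the covariate;
    when n! <= n_perm all permutations are enumerated instead and the
    p-value is the exact fraction of permutations (including identity) with
    F >= the observed F.
    """
    cov = np.asarray(covariate, dtype=float)
    n = len(dm.ids)
    if cov.shape != (n,):
        raise ValueError("covariate must have one value per sample in the distance matrix")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant; variance partitioning undefined")
    vals = dm.data
    df_model, df_res = 1, n - 2

    def f_of(c: np.ndarray) -> float:
        ss_model, ss_total = _trace_ss(vals, c)
        ss_res = ss_total - ss_model
        if ss_res <= 1e-12 * abs(ss_total):  # covariate explains everything
            return math.inf
        return (ss_model / df_model) / (ss_res / df_res)

    f_obs = f_of(cov)
    ss_model, ss_total = _trace_ss(vals, cov)
    r2 = ss_model / ss_total

    if math.factorial(n) <= n_perm:
        fs = np.array([f_of(cov[list(p)]) for p in itertools.permutations(range(n))])
        p_value = float(np.mean(fs >= f_obs - 1e-12))
        n_used, exhaustive = len(fs), True
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            if f_of(rng.permutation(cov)) >= f_obs - 1e-12:
                hits += 1
        p_value = (1 + hits) / (1 + n_perm)
        n_used, exhaustive = n_perm, False

    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p_value),
        n_permutations=n_used,
        df_model=df_model,
        df_residual=df_res,
        seed=seed,
        exhaustive=exhaustive,
    )


def distances_to_reference(
    dm: DistanceMatrix, meta: SampleMetadata, reference_bin: str
) -> list[BinDistanceResult]:
    """Collect each bin's distances to every reference-bin member.

    Also collects the within-reference pairwise distances (each unordered
    pair once) that serve as the comparison distribution.  Blanks and
    positive controls are ignored; empty bins are skipped with a warning.
    """
    frame = meta.frame.loc[list(dm.ids)]
    frame = frame[~frame["sample_type"].isin(["blank", "positive_control"])]
    ref_ids = list(frame.loc[frame["age_bin"] == reference_bin, "sample_id"])
    if len(ref_ids) < 2:
        raise ValueError(f"reference bin {reference_bin!r} needs >= 2 samples")
    within = np.array(
        [dm[a, b] for a, b in itertools.combinations(ref_ids, 2)]
    )
    results = []
    for bin_label, grp in frame.groupby("age_bin", sort=False):
        if bin_label == reference_bin:
            continue
        ids = list(grp["sample_id"])
        if not ids:
            warnings.warn(f"age bin {bin_label!r} empty; skipped", stacklevel=2)
            continue
        cross = np.array([dm[a, r] for a in ids for r in ref_ids])
        results.append(
            BinDistanceResult(age_bin=bin_label, distances=cross, reference_within=within)
        )
    return results


def bin_distance_test(
    results: list[BinDistanceResult], cfg: AnalysisConfig | None = None
) -> list[BinDistanceResult]:
    """Rank-sum test of each bin's cross distances vs. within-reference distances.

    Repeated appearances of the same reference individual across pairs are
    treated as independent observations, mirroring the source procedure;
    Bonferroni adjustment runs over the bins tested.
    """
    cfg = cfg or AnalysisConfig()
    raw = []
    for r in results:
        if r.reference_within.size == 0:
            raise ValueError("reference_within is empty")
        _, p = ranksum_test(r.distances, r.reference_within)
        raw.append(p)
    adj = bonferroni(raw)
    for r, p, a in zip(results, raw, adj):
        r.raw_p = float(p)
        r.adjusted_p = float(a)
    return results


def bin_distance_frame(results: list[BinDistanceResult]) -> pd.DataFrame:
    """Summary table: one row per bin with median distance and p-values."""
    return pd.DataFrame(
        [
            {
                "age_bin": r.age_bin,
                "n_distances": int(r.distances.size),
                "median_distance": float(np.median(r.distances)),
                "median_reference_within": float(np.median(r.reference_within)),
                "raw_p": r.raw_p,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ]
    )
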