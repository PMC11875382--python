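"""Haplotype frequency profiles per collection, pooling, and homogeneity tests.

A *haplotype profile* is the vector of relative frequencies of haplotype
classes in one collection — the quantity behind the per-collection pie charts
of marker surveys.  Profiles over a shared label universe can be pooled
(count-wise) and compared.  Surveys usually present profiles descriptively;
this module adds a Monte-Carlo chi-square homogeneity test as minimal
quantitative backing for "markedly different profiles" statements: small
counts and zero cells make the asymptotic chi-square reference invalid, so
the null distribution is built by resampling both collections from their
pooled frequencies, with the add-one correction so p never reaches 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HaplotypeProfile",
    "ProfileComparison",
    "build_profile",
    "pool_profiles",
    "compare_profiles",
    "profile_distance",
]


@dataclass(frozen=True)
class HaplotypeProfile:
    """Haplotype counts and frequencies for one collection.

    ``counts`` covers the full declared label universe, zeros included, so
    profiles from different collections are directly comparable.
    """

    collection_id: str
    counts: Mapping[str, int]
    n: int = field(init=False)

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative haplotype count")
        object.__setattr__(self, "counts", dict(self.counts))
        object.__setattr__(self, "n", int(sum(self.counts.values())))

    @property
    def labels(self) -> tuple:
        return tuple(self.counts)

    @property
    def freqs(self) -> dict:
        """Relative frequencies; undefined (empty dict) when n = 0."""
        if self.n == 0:
            return {}
        return {k: v / self.n for k, v in self.counts.items()}

    def vector(self, universe: Sequence[str] | None = None) -> np.ndarray:
        labels = self.labels if universe is None else tuple(universe)
        return np.array([self.counts.get(k, 0) for k in labels], dtype=float)


@dataclass(frozen=True)
class ProfileComparison:
    statistic: float
    p_value: float
    method: str
    n_resamples: int
    seed: int


def build_profile(
    calls: pd.DataFrame,
    collection_id: str,
    universe: Sequence[str],
    label_column: str = "csh_label",
) -> HaplotypeProfile:
    """Profile of one collection from a typed-call table.

    Only C-strain, non-heterozygous, successfully typed specimens are counted
    (surveys from corn habitat analyze the C-strain only); rows whose label is
    outside the universe — R-strain diagnostics, undetermined calls — are
    excluded from n.
    """
    sub = calls[calls["collection_id"] == collection_id]
    if "status" in sub.columns:
        sub = sub[sub["status"] == "ok"]
    if "strain" in sub.columns:
        sub = sub[sub["strain"] == "C"]
    if "heterozygous" in sub.columns:
        sub = sub[~sub["heterozygous"].astype(bool)]
    labels = sub[label_column].dropna()
    labels = labels[labels.isin(universe)]
    counts = {k: int((labels == k).sum()) for k in universe}
    return HaplotypeProfile(collection_id=collection_id, counts=counts)


def pool_profiles(
    profiles: Sequence[HaplotypeProfile], pooled_id: str
) -> HaplotypeProfile:
    """Label-wise sum of profiles sharing one label universe."""
    if not profiles:
        raise ValueError("nothing to pool")
    universe = set(profiles[0].labels)
    for p in profiles[1:]:
        if set(p.labels) != universe:
            raise ValueError(
                f"label universe mismatch: {sorted(universe)} vs {sorted(p.labels)}"
            )
    counts = {k: sum(p.counts.get(k, 0) for p in profiles) for k in profiles[0].labels}
    return HaplotypeProfile(collection_id=pooled_id, counts=counts)


def _chi2_stat(table: np.ndarray) -> float:
    """Pearson X² for a 2×K table, restricted to columns with nonzero margin."""
    col = table.sum(axis=0)
    keep = col > 0
    t = table[:, keep]
    col = col[keep]
    row = t.sum(axis=1)
    n = t.sum()
    expected = np.outer(row, col) / n
    return float(((t - expected) ** 2 / expected).sum())


def _chi2_stat_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised Pearson X² over B paired count vectors (B×K each)."""
    col = a + b
    n = col.sum(axis=1, keepdims=True)
    na = a.sum(axis=1, keepdims=True)
    nb = n - na
    ea = na * col / n
    eb = nb * col / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(ea > 0, (a - ea) ** 2 / ea, 0.0) + np.where(
            eb > 0, (b - eb) ** 2 / eb, 0.0
        )
    return terms.sum(axis=1)


def compare_profiles(
    a: HaplotypeProfile,
    b: HaplotypeProfile,
    method: str = "montecarlo_chi2",
    n_resamples: int = 9999,
    seed: int = 0,
) -> ProfileComparison:
    """Test homogeneity of two haplotype profiles.

    ``montecarlo_chi2`` — Pearson X² on the 2×K count table; the null
    distribution comes from redrawing both collections (at their observed
    sizes) from the pooled frequencies, and
    p = (1 + #{X²* >= X²}) / (n_resamples + 1).

    ``fisher_exact_2xk`` — exact conditional test; scipy's 2×2 exact test for
    two labels, otherwise Monte-Carlo over fixed-margin random tables ordered
    by table probability.
    """
    if a.n == 0 or b.n == 0:
        raise ValueError("both profiles must have n > 0")
    if set(a.labels) != set(b.labels):
        raise ValueError("profiles must share a label universe")
    labels = sorted(a.labels)
    av = a.vector(labels)
    bv = b.vector(labels)
    pooled = av + bv
    keep = pooled > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 labels with nonzero pooled count")
    av, bv, pooled = av[keep], bv[keep], pooled[keep]
    table = np.vstack([av, bv])

    rng = np.random.default_rng(seed)
    if method == "montecarlo_chi2":
        observed = _chi2_stat(table)
        p_null = pooled / pooled.sum()
        ra = rng.multinomial(int(av.sum()), p_null, size=n_resamples)
        rb = rng.multinomial(int(bv.sum()), p_null, size=n_resamples)
        null = _chi2_stat_batch(ra.astype(float), rb.astype(float))
        p = (1 + int((null >= observed - 1e-12).sum())) / (n_resamples + 1)
        return ProfileComparison(observed, p, method, n_resamples, seed)
    if method == "fisher_exact_2xk":
        if table.shape[1] == 2:
            _, p = stats.fisher_exact(table.astype(int))
            return ProfileComparison(_chi2_stat(table), float(p), method, 0, seed)
        logp_obs = _log_table_prob(table)
        draws = stats.random_table(
            table.sum(axis=1).astype(int), table.sum(axis=0).astype(int)
        ).rvs(n_resamples, random_state=rng)
        logp_null = np.array([_log_table_prob(t) for t in draws])
        p = (1 + int((logp_null <= logp_obs + 1e-12).sum())) / (n_resamples + 1)
        return ProfileComparison(_chi2_stat(table), p, method, n_resamples, seed)
    raise ValueError(f"unknown method {method!r}")


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of a 2×K table given its margins."""
    from scipy.special import gammaln

    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def profile_distance(a: HaplotypeProfile, b: HaplotypeProfile) -> float:
    """Total variation distance between two profiles, in [0, 1]."""
    if a.n == 0 or b.n == 0:
        raise ValueError("both profiles must have n > 0")
    labels = sorted(set(a.labels) | set(b.labels))
    fa = a.freqs
    fb = b.freqs
    return 0.5 * sum(abs(fa.get(k, 0.0) - fb.get(k, 0.0)) for k in labels)
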