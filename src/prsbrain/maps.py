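"""Effect-size brain maps and their spatial comparison.

A brain map here is an ordered vector of regional Cohen's d values for one
contrast — either a published case-control comparison or a high-vs-low
genetic-risk split of a population cohort (continuous PRS dichotomized at
the median).  Two maps over a shared atlas are compared by

* sign concordance: the number of regions where the two effects point the
  same way, tested against Binomial(n, 1/2) with an exact one-sided tail;
* spatial correlation: Pearson r across regions, with a permutation null
  built by shuffling region labels (exhaustive for small n);
* Benjamini-Hochberg FDR across disorders within a modality.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EffectSizeMap:
    """Ordered region -> Cohen's d mapping for one modality/contrast."""

    regions: list[str]
    d: np.ndarray
    modality: str = ""
    contrast: str = ""  # "diagnosis" | "prs_split" | ...
    n_pair: tuple[int, int] | None = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if len(self.regions) != len(self.d):
            raise ValueError("regions and d must have equal length")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region labels")

    def __len__(self) -> int:
        return len(self.regions)

    def to_series(self) -> pd.Series:
        return pd.Series(self.d, index=self.regions, name="d")

    def align(self, other: "EffectSizeMap"):
        """Restrict both maps to their shared regions, in self's order."""
        shared = [r for r in self.regions if r in set(other.regions)]
        if not shared:
            raise ValueError("maps share no regions")
        a = self.to_series()[shared].to_numpy()
        b = other.to_series()[shared].to_numpy()
        return shared, a, b


def cohen_d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d recovered from a two-sample t statistic.

    ``d = t * sqrt(1/n1 + 1/n2)``; the sign of d follows the sign of t.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    return float(t) * math.sqrt(1.0 / n1 + 1.0 / n2)


def median_split(values) -> np.ndarray:
    """Dichotomize a continuous score at its median.

    Returns a boolean array, True = high group (strictly above the
    median); ties at the median fall in the low group.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 values")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no median split")
    return x > np.median(x)


def cohen_d_from_groups(x_high, x_low) -> float:
    """Pooled-SD standardized mean difference (high minus low)."""
    a = np.asarray(x_high, dtype=float)
    b = np.asarray(x_low, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / math.sqrt(sp2))


def prs_split_map(
    measures: pd.DataFrame,
    prs_values,
    modality: str = "",
    contrast: str = "prs_split",
) -> EffectSizeMap:
    """Genetic-risk map: per-region Cohen's d of high- vs low-PRS groups."""
    high = median_split(prs_values)
    d = np.array([
        cohen_d_from_groups(measures.loc[high, r], measures.loc[~high, r])
        for r in measures.columns
    ])
    return EffectSizeMap(
        regions=list(measures.columns), d=d, modality=modality,
        contrast=contrast, n_pair=(int(high.sum()), int((~high).sum())),
    )


def crosswalk(emap: EffectSizeMap, weights: pd.DataFrame) -> EffectSizeMap:
    """Convert a map to a target atlas via weighted averaging.

    ``weights`` is long-format with columns ``target_region,
    source_region, weight``; weights per target must sum to 1.
    """
    required = {"target_region", "source_region", "weight"}
    if not required.issubset(weights.columns):
        raise ValueError(f"crosswalk table needs columns {sorted(required)}")
    src = emap.to_series()
    targets = list(dict.fromkeys(weights["target_region"]))
    out = []
    for tgt in targets:
        rows = weights[weights["target_region"] == tgt]
        total = rows["weight"].sum()
        if total <= 0:
            raise ValueError(f"target region {tgt!r} has zero total weight")
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError(
                f"weights for target region {tgt!r} sum to {total:.6f}, not 1"
            )
        missing = [s for s in rows["source_region"] if s not in src.index]
        if missing:
            raise ValueError(f"unknown source regions {missing} for {tgt!r}")
        out.append(float((rows["weight"].to_numpy()
                          * src[rows["source_region"]].to_numpy()).sum()))
    return EffectSizeMap(
        regions=targets, d=np.array(out),
        modality=emap.modality, contrast=emap.contrast,
    )


def sign_concordance(map_a: EffectSizeMap, map_b: EffectSizeMap):
    """Exact binomial sign-concordance test between two maps.

    Concordant regions satisfy ``d_a * d_b > 0``; regions where either
    effect is exactly zero are excluded from n.  One-sided tail
    ``P(X >= k)`` with ``X ~ Binomial(n, 1/2)``, computed exactly.

    Returns ``(k, n, proportion, p_sign)``.
    """
    _, a, b = map_a.align(map_b)
    nonzero = (a != 0) & (b != 0)
    a, b = a[nonzero], b[nonzero]
    n = len(a)
    if n == 0:
        raise ValueError("no regions with nonzero effects in both maps")
    k = int(np.sum(a * b > 0))
    p_sign = float(stats.binom.sf(k - 1, n, 0.5))
    return k, n, k / n, p_sign


def spatial_correlation(
    map_a: EffectSizeMap,
    map_b: EffectSizeMap,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive_max_n: int = 8,
):
    """Pearson correlation across regions with a permutation null.

    Returns ``(r, halfwidth, p_perm)`` where ``halfwidth =
    1.96 * sqrt((1 - r^2) / (n - 2))`` is the printed interval half-width
    and ``p_perm`` is two-sided on |r|.  For ``n <= exhaustive_max_n`` all
    n! region-label permutations are enumerated and the p-value is the
    exact fraction with ``|r*| >= |r|``; otherwise ``n_perm`` uniformly
    random permutations give ``p = (count + 1) / (n_perm + 1)``.
    ``n_perm=0`` returns ``p_perm = nan``.
    """
    _, a, b = map_a.align(map_b)
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 shared regions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the maps")
    r = float(np.corrcoef(a, b)[0, 1])
    halfwidth = 1.96 * math.sqrt((1.0 - r * r) / (n - 2))

    if n <= exhaustive_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r_star = np.corrcoef(a[list(perm)], b)[0, 1]
            if abs(r_star) >= abs(r) - 1e-12:
                count += 1
            total += 1
        p_perm = count / total
    elif n_perm <= 0:
        p_perm = float("nan")
    else:
        rng = np.random.default_rng(seed)
        az = (a - a.mean()) / a.std(ddof=0)
        bz = (b - b.mean()) / b.std(ddof=0)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r_star = float(az[perm] @ bz) / n
            if abs(r_star) >= abs(r) - 1e-12:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
    return r, halfwidth, p_perm


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ConcordanceResult:
    """One disorder x modality comparison of two effect-size maps."""

    disease: str
    modality: str
    k: int
    n: int
    proportion: float
    p_sign: float
    r: float
    halfwidth: float
    p_perm: float
    q_fdr: float = field(default=float("nan"))


class MapConcordance:
    """Model comparing disease and genetic-risk maps across disorders.

    Parameters
    ----------
    pairs : dict[str, tuple[EffectSizeMap, EffectSizeMap]]
        Per-disorder (diagnosis map, genetic-risk map) pairs over a
        shared atlas, all one modality.
    modality : str
    """

    def __init__(self, pairs: dict, modality: str = ""):
        if not pairs:
            raise ValueError("no map pairs supplied")
        self.pairs = dict(pairs)
        self.modality = modality

    def fit(self, n_perm: int = 10_000, seed: int | None = None):
        """Run concordance + correlation tests; FDR across disorders."""
        results = []
        for disease, (map_dx, map_prs) in self.pairs.items():
            k, n, prop, p_sign = sign_concordance(map_dx, map_prs)
            r, hw, p_perm = spatial_correlation(
                map_dx, map_prs, n_perm=n_perm, seed=seed
            )
            results.append(ConcordanceResult(
                disease=disease, modality=self.modality,
                k=k, n=n, proportion=prop, p_sign=p_sign,
                r=r, halfwidth=hw, p_perm=p_perm,
            ))
        perm_ps = np.array([c.p_perm for c in results])
        if np.isfinite(perm_ps).all():
            q = fdr_adjust(perm_ps)
            for c, qi in zip(results, q):
                c.q_fdr = float(qi)
        return ConcordanceResults(results, modality=self.modality)


class ConcordanceResults:
    """Collection of per-disorder concordance results with a summary table."""

    def __init__(self, results: list[ConcordanceResult], modality: str = ""):
        self.results = results
        self.modality = modality

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.results])

    def summary(self) -> str:
        lines = [f"Map concordance ({self.modality or 'unspecified modality'})"]
        for c in self.results:
            lines.append(
                f"  {c.disease:>6s}: concordance {c.k}/{c.n} "
                f"({100 * c.proportion:.1f}%, p={c.p_sign:.3g}); "
                f"r = {c.r:.2f} +/- {c.halfwidth:.2f} "
                f"(perm p={c.p_perm:.3g}, q={c.q_fdr:.3g})"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of diagnosis vs genetic-risk correlation per disorder."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.table
        ax.errorbar(range(len(tab)), tab["r"], yerr=tab["halfwidth"], fmt="o")
        ax.axhline(0, color="gray", lw=0.8)
        ax.set_xticks(range(len(tab)), tab["disease"], rotation=45)
        ax.set_ylabel("map correlation r")
        return ax
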