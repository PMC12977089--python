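"""Two-sample Mendelian randomization between brain measures and disorders.

Given GWAS summary statistics for an exposure and an outcome, genetic
variants strongly associated with the exposure serve as instruments for
estimating the causal effect b_xy of exposure on outcome.  The module
implements harmonization (allele alignment, palindromic-SNP removal,
optional exclusion regions), instrument selection, five estimators —
inverse-variance weighted (IVW), Egger regression, weighted median,
weighted mode, and GSMR with iterative HEIDI-outlier removal — and
sensitivity analyses (Cochran's Q, Egger intercept, leave-one-out).

Instruments are treated as mutually independent (identity LD): the
package consumes clumped or simulated variants.

The statsmodels-style entry point is :class:`MendelianRandomization`;
:func:`run_bidirectional` orchestrates the forward (brain -> disorder,
odds-ratio scale) and reverse (disorder -> brain, beta scale) scans.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}

GWS_THRESHOLD = 5e-8  # genome-wide significance


@dataclass
class HarmonizedSet:
    """Per-SNP aligned exposure/outcome effects.

    ``data`` columns: SNP, b_x, se_x, p_x, b_y, se_y, p_y, freq.
    """

    data: pd.DataFrame
    flipped: list[str] = field(default_factory=list)
    removed_palindromic: list[str] = field(default_factory=list)
    removed_mismatch: list[str] = field(default_factory=list)
    removed_region: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "HarmonizedSet":
        return HarmonizedSet(
            data=self.data.loc[mask].reset_index(drop=True),
            flipped=self.flipped,
            removed_palindromic=self.removed_palindromic,
            removed_mismatch=self.removed_mismatch,
            removed_region=self.removed_region,
        )

    @property
    def b_x(self) -> np.ndarray:
        return self.data["b_x"].to_numpy(dtype=float)

    @property
    def se_x(self) -> np.ndarray:
        return self.data["se_x"].to_numpy(dtype=float)

    @property
    def b_y(self) -> np.ndarray:
        return self.data["b_y"].to_numpy(dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return self.data["se_y"].to_numpy(dtype=float)

    @property
    def snps(self) -> list[str]:
        return self.data["SNP"].tolist()


@dataclass
class MREstimate:
    """Causal-effect estimate from one MR method."""

    method: str
    beta_hat: float
    se_hat: float
    p: float
    n_iv_used: int
    removed_snps: list[str] = field(default_factory=list)
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def or_hat(self) -> float:
        return math.exp(self.beta_hat)

    @property
    def ci(self) -> tuple[float, float]:
        lo = math.exp(self.beta_hat - 1.96 * self.se_hat)
        hi = math.exp(self.beta_hat + 1.96 * self.se_hat)
        return (lo, hi)

    @property
    def beta_ci(self) -> tuple[float, float]:
        return (self.beta_hat - 1.96 * self.se_hat,
                self.beta_hat + 1.96 * self.se_hat)


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    exclude_regions: pd.DataFrame | None = None,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Allele swaps negate the outcome beta; strand flips are resolved by
    complementing; palindromic (A/T, C/G) SNPs are removed because their
    strand cannot be inferred.  When ``exclude_regions`` (columns chrom,
    start, end) is supplied and the exposure carries ``chr``/``bp``
    columns, SNPs inside any region (e.g. long-range LD blocks such as
    17q21.31) are removed.
    """
    merged = exposure.merge(
        outcome, on="SNP", suffixes=("_x", "_y"), how="inner"
    )
    if len(merged) == 0:
        raise ValueError("exposure and outcome share no SNPs")

    region_mask = np.zeros(len(merged), dtype=bool)
    if exclude_regions is not None:
        if {"chr", "bp"}.issubset(exposure.columns):
            chr_col = "chr_x" if "chr_x" in merged.columns else "chr"
            bp_col = "bp_x" if "bp_x" in merged.columns else "bp"
            chrom = merged[chr_col].astype(str).to_numpy()
            bp = merged[bp_col].to_numpy()
            for _, reg in exclude_regions.iterrows():
                region_mask |= (
                    (chrom == str(reg["chrom"]))
                    & (reg["start"] <= bp) & (bp < reg["end"])
                )
        else:
            logger.warning(
                "exclusion regions supplied but summary stats carry no "
                "chr/bp columns; no positional exclusion applied"
            )

    ex1 = merged["A1_x"].to_numpy()
    ex2 = merged["A2_x"].to_numpy()
    oc1 = merged["A1_y"].to_numpy()
    oc2 = merged["A2_y"].to_numpy()
    comp = np.vectorize(_COMPLEMENT.get)
    pal_mask = np.array([
        _is_palindromic(a, b) or _is_palindromic(c, d)
        for a, b, c, d in zip(ex1, ex2, oc1, oc2)
    ])

    same = (oc1 == ex1) & (oc2 == ex2)
    swap = (oc1 == ex2) & (oc2 == ex1)
    coc1, coc2 = comp(oc1), comp(oc2)
    same_flip = (coc1 == ex1) & (coc2 == ex2) & ~same & ~swap
    swap_flip = (coc1 == ex2) & (coc2 == ex1) & ~same & ~swap
    aligned = same | swap | same_flip | swap_flip
    negate = swap | swap_flip

    keep = aligned & ~pal_mask & ~region_mask
    mismatch_mask = ~aligned & ~pal_mask & ~region_mask

    snps = merged["SNP"].to_numpy()
    data = pd.DataFrame({
        "SNP": snps[keep],
        "b_x": merged["b_x"].to_numpy()[keep],
        "se_x": merged["se_x"].to_numpy()[keep],
        "p_x": merged["p_x"].to_numpy()[keep],
        "b_y": np.where(negate, -merged["b_y"].to_numpy(),
                        merged["b_y"].to_numpy())[keep],
        "se_y": merged["se_y"].to_numpy()[keep],
        "p_y": merged["p_y"].to_numpy()[keep],
        "freq": merged["freq_x"].to_numpy()[keep],
    })
    return HarmonizedSet(
        data=data.reset_index(drop=True),
        flipped=snps[negate & keep].tolist(),
        removed_palindromic=snps[pal_mask & ~region_mask].tolist(),
        removed_mismatch=snps[mismatch_mask].tolist(),
        removed_region=snps[region_mask].tolist(),
    )


def select_instruments(
    harmonized: HarmonizedSet, p_threshold: float = GWS_THRESHOLD
) -> HarmonizedSet:
    """Keep SNPs whose exposure association passes ``p_threshold``."""
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    mask = harmonized.data["p_x"] < p_threshold
    if mask.sum() == 0:
        warnings.warn("no SNP passes the instrument p-value threshold",
                      stacklevel=2)
    return harmonized.subset(mask)


def _drop_zero_bx(h: HarmonizedSet) -> HarmonizedSet:
    zero = h.data["b_x"] == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} SNP(s) with zero exposure effect",
            stacklevel=3,
        )
        return h.subset(~zero)
    return h


def ivw(harmonized: HarmonizedSet) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    Equivalent to weighted regression of b_y on b_x through the origin
    with weights 1/se_y^2: ``beta = sum(b_x b_y / se_y^2) /
    sum(b_x^2 / se_y^2)``, ``se = 1/sqrt(sum(b_x^2 / se_y^2))``.
    """
    h = _drop_zero_bx(harmonized)
    if len(h) < 1:
        raise ValueError("IVW needs at least one instrument")
    w = h.b_x**2 / h.se_y**2
    beta = float(np.sum(w * (h.b_y / h.b_x)) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = beta / se
    return MREstimate(
        method="IVW", beta_hat=beta, se_hat=se,
        p=float(2 * stats.norm.sf(abs(z))), n_iv_used=len(h),
    )


def egger(harmonized: HarmonizedSet) -> MREstimate:
    """Egger regression: weighted fit of b_y on b_x with a free intercept.

    The slope estimates the causal effect under InSIDE; the intercept
    measures directional pleiotropy.  Weights 1/se_y^2; p-values from the
    t distribution with k - 2 degrees of freedom.
    """
    h = _drop_zero_bx(harmonized)
    k = len(h)
    if k < 3:
        raise ValueError("Egger regression needs at least 3 instruments")
    w = 1.0 / h.se_y**2
    X = np.column_stack([np.ones(k), h.b_x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ h.b_y)
    resid = h.b_y - X @ coef
    # dispersion with a floor of 1 (multiplicative random effects, as in
    # standard summary-data MR practice)
    sigma2 = max(float(np.sum(w * resid**2) / (k - 2)), 1.0)
    cov = sigma2 * np.linalg.inv(xtwx)
    se_int, se_slope = np.sqrt(np.diag(cov))
    t_slope = coef[1] / se_slope
    t_int = coef[0] / se_int
    return MREstimate(
        method="Egger", beta_hat=float(coef[1]), se_hat=float(se_slope),
        p=float(2 * stats.t.sf(abs(t_slope), k - 2)), n_iv_used=k,
        intercept=float(coef[0]), intercept_se=float(se_int),
        intercept_p=float(2 * stats.t.sf(abs(t_int), k - 2)),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    below = np.searchsorted(cum, 0.5, side="right") - 1
    below = min(max(below, 0), len(r) - 2)
    # linear interpolation between bracketing order statistics
    c0, c1 = cum[below], cum[below + 1]
    if c1 == c0:
        return float(r[below])
    frac = (0.5 - c0) / (c1 - c0)
    return float(r[below] + frac * (r[below + 1] - r[below]))


def weighted_median(
    harmonized: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MREstimate:
    """Weighted median of per-SNP ratio estimates.

    Consistent when instruments carrying >= 50% of the weight are valid.
    Inverse-variance weights on the first-order ratio variance
    ``se_y^2 / b_x^2``; standard error by parametric bootstrap.
    """
    h = _drop_zero_bx(harmonized)
    k = len(h)
    if k < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    ratios = h.b_y / h.b_x
    weights = h.b_x**2 / h.se_y**2
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx = rng.normal(h.b_x, h.se_x)
        by = rng.normal(h.b_y, h.se_y)
        ok = bx != 0
        boots[i] = _weighted_median_point(by[ok] / bx[ok], bx[ok]**2 / h.se_y[ok]**2)
    se = float(boots.std(ddof=1))
    z = beta / se if se > 0 else np.inf
    return MREstimate(
        method="weighted_median", beta_hat=beta, se_hat=se,
        p=float(2 * stats.norm.sf(abs(z))), n_iv_used=k,
    )


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, bandwidth: float
) -> float:
    w = weights / weights.sum()
    sd = ratios.std(ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(sd, mad if mad > 0 else sd) * len(ratios) ** (-1 / 5)
    h = max(bandwidth * s, 1e-12)
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = (w[:, None] * stats.norm.pdf(grid[None, :], ratios[:, None], h)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def weighted_mode(
    harmonized: HarmonizedSet,
    bandwidth: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MREstimate:
    """Mode of the smoothed weighted density of ratio estimates.

    Consistent when the largest homogeneous subset of instruments is
    valid (ZEMPA).  Normal kernel; ``bandwidth`` scales the modified
    Silverman rule.  Standard error by parametric bootstrap.
    """
    h = _drop_zero_bx(harmonized)
    k = len(h)
    if k < 3:
        raise ValueError("weighted mode needs at least 3 instruments")
    ratios = h.b_y / h.b_x
    weights = h.b_x**2 / h.se_y**2
    if np.ptp(ratios) == 0:
        return MREstimate(
            method="weighted_mode", beta_hat=float(ratios[0]), se_hat=0.0,
            p=0.0 if ratios[0] != 0 else 1.0, n_iv_used=k,
        )
    beta = _weighted_mode_point(ratios, weights, bandwidth)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx = rng.normal(h.b_x, h.se_x)
        by = rng.normal(h.b_y, h.se_y)
        ok = bx != 0
        boots[i] = _weighted_mode_point(
            by[ok] / bx[ok], bx[ok]**2 / h.se_y[ok]**2, bandwidth
        )
    se = float(boots.std(ddof=1))
    z = beta / se if se > 0 else np.inf
    return MREstimate(
        method="weighted_mode", beta_hat=beta, se_hat=se,
        p=float(2 * stats.norm.sf(abs(z))), n_iv_used=k,
    )


def gsmr(
    harmonized: HarmonizedSet,
    heidi_p_threshold: float = 0.01,
    max_iter: int = 100,
) -> MREstimate:
    """GSMR-style estimate with iterative HEIDI-outlier removal.

    Repeats until stable: (1) IVW estimate on the current set; (2) per
    SNP, ``z_j = (ratio_j - beta) / sqrt(var_j)`` with the delta-method
    ratio variance ``var_j = (se_y^2 + ratio_j^2 se_x^2) / b_x^2``;
    (3) remove SNPs with two-sided ``p(z_j) < heidi_p_threshold``.
    LD is treated as identity.  ``heidi_p_threshold = 0`` disables
    removal, reducing exactly to IVW.
    """
    h = _drop_zero_bx(harmonized)
    if len(h) < 1:
        raise ValueError("GSMR needs at least one instrument")
    if len(h) < 10:
        warnings.warn("GSMR with fewer than 10 instruments is fragile",
                      stacklevel=2)
    removed: list[str] = []
    current = h
    for _ in range(max_iter):
        est = ivw(current)
        ratios = current.b_y / current.b_x
        var = (current.se_y**2 + ratios**2 * current.se_x**2) / current.b_x**2
        z = (ratios - est.beta_hat) / np.sqrt(var)
        p_heidi = 2 * stats.norm.sf(np.abs(z))
        outliers = p_heidi < heidi_p_threshold
        if not outliers.any():
            break
        # remove the most extreme outlier(s) this round
        removed.extend(current.data.loc[outliers, "SNP"].tolist())
        current = current.subset(~outliers)
        if len(current) == 0:
            raise ValueError("HEIDI-outlier removed every instrument")
    est = ivw(current)
    return MREstimate(
        method="GSMR", beta_hat=est.beta_hat, se_hat=est.se_hat,
        p=est.p, n_iv_used=len(current), removed_snps=removed,
    )


@dataclass
class SensitivityReport:
    """Heterogeneity and robustness diagnostics for an MR fit."""

    cochran_q: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_p: float
    loo_estimates: pd.DataFrame
    max_deviation_snp: str
    max_deviation: float


def sensitivity(harmonized: HarmonizedSet, estimate: MREstimate) -> SensitivityReport:
    """Cochran's Q, Egger intercept, and leave-one-out IVW series."""
    h = _drop_zero_bx(harmonized)
    k = len(h)
    if k < 3:
        raise ValueError("sensitivity analysis needs at least 3 instruments")
    ratios = h.b_y / h.b_x
    # delta-method ratio variances keep Q close to chi2_{k-1}; the
    # first-order weights se_y^2/b_x^2 alone are anti-conservative
    var = h.se_y**2 / h.b_x**2 + h.b_y**2 * h.se_x**2 / h.b_x**4
    w = 1.0 / var
    beta_ivw = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta_ivw) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))
    eg = egger(h)

    beta_full = ivw(h).beta_hat
    loo_rows = []
    for i in range(k):
        mask = np.ones(k, dtype=bool)
        mask[i] = False
        est_i = ivw(h.subset(mask))
        loo_rows.append({
            "excluded_snp": h.snps[i],
            "beta": est_i.beta_hat,
            "se": est_i.se_hat,
            "deviation": abs(est_i.beta_hat - beta_full),
        })
    loo = pd.DataFrame(loo_rows)
    worst = loo.loc[loo["deviation"].idxmax()]
    return SensitivityReport(
        cochran_q=q, q_df=k - 1, q_p=q_p,
        egger_intercept=eg.intercept, egger_intercept_p=eg.intercept_p,
        loo_estimates=loo,
        max_deviation_snp=str(worst["excluded_snp"]),
        max_deviation=float(worst["deviation"]),
    )


_METHODS = {
    "IVW": ivw,
    "Egger": egger,
    "weighted_median": weighted_median,
    "weighted_mode": weighted_mode,
    "GSMR": gsmr,
}


class MendelianRandomization:
    """Two-sample MR model for one exposure/outcome pair.

    Parameters
    ----------
    exposure, outcome : DataFrame
        GWAS summary tables (columns SNP, A1, A2, freq, b, se, p, N).
    p_threshold : float
        Instrument-selection threshold on the exposure p-value.
    exclude_regions : DataFrame, optional
        BED-like (chrom, start, end) regions removed during harmonization
        when positions are available.
    """

    def __init__(
        self,
        exposure: pd.DataFrame,
        outcome: pd.DataFrame,
        p_threshold: float = GWS_THRESHOLD,
        exclude_regions: pd.DataFrame | None = None,
    ):
        self.harmonized_full = harmonize(exposure, outcome, exclude_regions)
        self.instruments = select_instruments(self.harmonized_full, p_threshold)
        self.p_threshold = p_threshold

    def fit(self, method: str = "GSMR", seed: int | None = 0, **kwargs):
        """Fit one estimator or all five (``method="all"``)."""
        methods = list(_METHODS) if method == "all" else [method]
        estimates: dict[str, MREstimate] = {}
        for m in methods:
            if m not in _METHODS:
                raise ValueError(f"unknown MR method {m!r}")
            fn = _METHODS[m]
            if m in ("weighted_median", "weighted_mode"):
                estimates[m] = fn(self.instruments, seed=seed, **kwargs)
            else:
                estimates[m] = fn(self.instruments, **kwargs)
        sens = None
        if len(self.instruments) >= 3:
            primary = estimates.get("GSMR") or next(iter(estimates.values()))
            sens = sensitivity(self.instruments, primary)
        return MRResults(estimates, self.instruments, sens)


class MRResults:
    """Estimates from one or more MR methods plus sensitivity diagnostics."""

    def __init__(self, estimates, instruments, sensitivity_report=None):
        self.estimates = estimates
        self.instruments = instruments
        self.sensitivity = sensitivity_report

    def __getitem__(self, method: str) -> MREstimate:
        return self.estimates[method]

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for est in self.estimates.values():
            lo, hi = est.ci
            rows.append({
                "method": est.method, "beta": est.beta_hat, "se": est.se_hat,
                "p": est.p, "OR": est.or_hat, "ci_low": lo, "ci_high": hi,
                "n_iv": est.n_iv_used,
                "removed_snps": ",".join(est.removed_snps),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Two-sample MR ({len(self.instruments)} instruments)"]
        for est in self.estimates.values():
            lo, hi = est.ci
            lines.append(
                f"  {est.method:>15s}: beta = {est.beta_hat:+.4f} "
                f"(se {est.se_hat:.4f}), OR = {est.or_hat:.2f} "
                f"[{lo:.2f}, {hi:.2f}], p = {est.p:.3g}"
                + (f", removed {len(est.removed_snps)} outlier(s)"
                   if est.removed_snps else "")
            )
        if self.sensitivity is not None:
            s = self.sensitivity
            lines.append(
                f"  Cochran's Q = {s.cochran_q:.2f} (df {s.q_df}, "
                f"p = {s.q_p:.3g}); Egger intercept = "
                f"{s.egger_intercept:+.2e} (p = {s.egger_intercept_p:.3g})"
            )
            lines.append(
                f"  leave-one-out max deviation {s.max_deviation:.4f} "
                f"({s.max_deviation_snp})"
            )
        return "\n".join(lines)


def mr_tier_thresholds(n_measures: int = 3, n_diseases: int = 13,
                       alpha: float = 0.05) -> dict:
    """Nominal / disease-wise / study-wise thresholds for the MR scan."""
    return {
        "nominal": alpha,
        "disease_wise": alpha / n_measures,
        "study_wise": alpha / (n_measures * n_diseases),
    }


def run_bidirectional(
    pairs: dict,
    method: str = "GSMR",
    p_threshold: float = GWS_THRESHOLD,
    seed: int | None = 0,
    n_measures: int | None = None,
    n_diseases: int | None = None,
) -> pd.DataFrame:
    """Forward and reverse MR over brain-measure x disorder cells.

    ``pairs`` maps ``(measure, disease)`` to a dict with keys
    ``"forward"`` and/or ``"reverse"``, each an ``(exposure, outcome)``
    tuple of summary tables.  Forward cells (brain -> disorder) are
    reported on the OR scale; reverse cells on the beta scale.  Missing
    directions are marked unavailable.  Tier annotation uses
    ``0.05 / n_measures`` (disease-wise) and
    ``0.05 / (n_measures * n_diseases)`` (study-wise).
    """
    from .association import assign_tier

    measures = sorted({m for m, _ in pairs})
    diseases = sorted({d for _, d in pairs})
    thr = mr_tier_thresholds(
        n_measures or len(measures), n_diseases or len(diseases)
    )
    rows = []
    for (measure, disease), directions in pairs.items():
        for direction in ("forward", "reverse"):
            if direction not in directions or directions[direction] is None:
                rows.append({
                    "measure": measure, "disease": disease,
                    "direction": direction, "method": method,
                    "available": False, "beta": np.nan, "se": np.nan,
                    "p": np.nan, "OR": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "n_iv": 0, "tier": "unavailable",
                })
                continue
            exposure, outcome = directions[direction]
            model = MendelianRandomization(exposure, outcome, p_threshold)
            est = model.fit(method=method, seed=seed)[method]
            if direction == "forward":
                lo, hi = est.ci
                or_hat = est.or_hat
            else:
                lo, hi = est.beta_ci
                or_hat = np.nan
            rows.append({
                "measure": measure, "disease": disease,
                "direction": direction, "method": method,
                "available": True, "beta": est.beta_hat, "se": est.se_hat,
                "p": est.p, "OR": or_hat, "ci_low": lo, "ci_high": hi,
                "n_iv": est.n_iv_used, "tier": assign_tier(est.p, thr),
            })
    return pd.DataFrame(rows)
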