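"""Synthetic cohort, GWAS-pair and effect-size-map generators.

Restricted individual-level data (biobank imaging + genotypes) and
consortium summary tables cannot ship with the package, so every analysis
stage is exercised against simulated inputs with known ground truth:

* :func:`generate_cohort` draws a population cohort with covariates,
  per-disease polygenic risk scores (PRS), and regional brain measures
  driven by a shared global-size factor plus small planted PRS effects;
* :func:`generate_diagnoses` adds binary diagnoses from a
  liability-threshold model combining PRS and a global brain deficit;
* :func:`generate_gwas_pair` simulates exposure/outcome GWAS summary
  statistics with a known causal effect and optional pleiotropy for the
  Mendelian-randomization suite;
* :func:`generate_effect_map` builds regional Cohen's d maps with a
  configurable sign pattern.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import CLUSTER_CT, CLUSTER_SA, SUBCORTICAL

#: The 13 neuropsychiatric disorders retained by the association scan
#: (anorexia nervosa excluded for lack of overlap-free discovery GWAS).
DEFAULT_DISEASES: tuple[str, ...] = (
    "ADHD", "ASD", "BPD", "MDD", "OCD", "PTSD", "SZ",
    "TS", "AD", "ALS", "EP", "FTD", "PD",
)

DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "surface_area": CLUSTER_SA,
    "thickness": CLUSTER_CT,
    "subcortical": SUBCORTICAL,
}

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class CohortConfig:
    """Configuration of the synthetic population cohort.

    Attributes
    ----------
    n_participants : int
        Cohort size; the emulated study population is ~33,861.
    diseases : tuple of str
        Disorder labels; one standardized PRS column each.
    regions : dict
        Region names per modality (``surface_area``, ``thickness``,
        ``subcortical``).
    prs_effect : dict[(disease, region), float]
        Planted standardized effects of PRS on regional measures;
        realistic magnitudes are |beta| ~ 0.01-0.05.
    global_factor_sd : float
        SD of the shared latent global-size factor that induces
        inter-regional correlation.
    covariate_effects : dict
        Standardized effects of covariates on every region: keys ``age``
        (per year), ``sex``, ``euler``, ``site`` (length-3 offsets),
        ``pcs`` (scalar applied to PC1).
    noise_sd : float
        Residual SD of each regional measure.
    seed : int
        Seed for the generator; fixed seed reproduces the table exactly.
    """

    n_participants: int = 33_861
    diseases: tuple[str, ...] = DEFAULT_DISEASES
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    prs_effect: dict = field(default_factory=dict)
    global_factor_sd: float = 0.5
    global_loading: float = 1.0
    covariate_effects: dict = field(default_factory=lambda: {
        "age": -0.01, "sex": 0.1, "euler": 0.05,
        "site": (0.0, 0.05, -0.05), "pcs": 0.02,
    })
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.global_factor_sd < 0:
            raise ValueError("global_factor_sd must be >= 0")
        if not self.diseases:
            raise ValueError("diseases must be non-empty")
        for modality, regs in self.regions.items():
            if len(regs) == 0:
                raise ValueError(f"regions[{modality!r}] must be non-empty")
        all_regions = self.region_list()
        for (d, r), beta in self.prs_effect.items():
            if d not in self.diseases:
                raise ValueError(f"prs_effect disease {d!r} not in diseases")
            if r not in all_regions:
                raise ValueError(f"prs_effect region {r!r} not in regions")
            if not np.isfinite(beta):
                raise ValueError(f"prs_effect[{d!r},{r!r}] is not finite")
        site = self.covariate_effects.get("site", (0.0, 0.0, 0.0))
        if len(site) != 3:
            raise ValueError("covariate_effects['site'] must have 3 levels")

    def region_list(self) -> list[str]:
        out: list[str] = []
        for regs in self.regions.values():
            out.extend(regs)
        return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Each regional measure is

    ``intercept + covariate terms + loading * global_factor
    + sum_d prs_effect[d, r] * prs_d + noise``

    with all PRS columns independent standard normals.  Covariates: age
    uniform on 45-82 years, sex Bernoulli with a male-female ratio of
    0.9, three scanner sites, a scan-quality proxy (Euler number
    analogue), and 10 genetic principal components.

    Returns a DataFrame with columns ``id, age, sex, site, euler,
    pc1..pc10, prs_<disease>..., brain region columns..., total_sa,
    mean_ct, icv``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    tab = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": rng.uniform(45.13, 81.83, n),
        "sex": rng.binomial(1, 0.9 / 1.9, n),  # male-female ratio 0.9
        "site": rng.integers(0, 3, n),
        "euler": rng.normal(0.0, 1.0, n),
    })
    pcs = rng.normal(0.0, 1.0, (n, 10))
    for j in range(10):
        tab[f"pc{j + 1}"] = pcs[:, j]

    prs = rng.normal(0.0, 1.0, (n, len(config.diseases)))
    for j, d in enumerate(config.diseases):
        tab[f"prs_{d}"] = prs[:, j]

    eff = config.covariate_effects
    site_off = np.asarray(eff.get("site", (0.0, 0.0, 0.0)), dtype=float)
    cov_term = (
        eff.get("age", 0.0) * (tab["age"].to_numpy() - tab["age"].mean())
        + eff.get("sex", 0.0) * tab["sex"].to_numpy()
        + eff.get("euler", 0.0) * tab["euler"].to_numpy()
        + eff.get("pcs", 0.0) * pcs[:, 0]
        + site_off[tab["site"].to_numpy()]
    )
    g = rng.normal(0.0, config.global_factor_sd, n) if config.global_factor_sd > 0 else np.zeros(n)

    for modality, regs in config.regions.items():
        for r in regs:
            signal = np.zeros(n)
            for j, d in enumerate(config.diseases):
                beta = config.prs_effect.get((d, r), 0.0)
                if beta:
                    signal += beta * prs[:, j]
            tab[r] = (
                cov_term + config.global_loading * g + signal
                + rng.normal(0.0, config.noise_sd, n)
            )

    # global measures derived from the bilaterally combined regions
    sa = config.regions.get("surface_area", ())
    ct = config.regions.get("thickness", ())
    sub = config.regions.get("subcortical", ())
    if sa:
        tab["total_sa"] = tab[list(sa)].sum(axis=1)
    if ct:
        tab["mean_ct"] = tab[list(ct)].mean(axis=1)
    if sub:
        tab["icv"] = tab[list(sub)].sum(axis=1) + rng.normal(0.0, config.noise_sd, n)
    return tab


def liability_threshold_for_prevalence(
    prevalence: float, w_prs: float, w_brain: float
) -> float:
    """Threshold giving a target prevalence under the liability model.

    Liability = ``w_prs * PRS - w_brain * global_brain_z + eps`` with all
    three terms approximately independent unit-variance-or-less normals,
    so prevalence = ``1 - Phi(threshold / sigma)`` with
    ``sigma = sqrt(w_prs**2 + w_brain**2 + 1)``.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    sigma = np.sqrt(w_prs**2 + w_brain**2 + 1.0)
    return float(stats.norm.isf(prevalence) * sigma)


def generate_diagnoses(
    cohort: pd.DataFrame,
    weights: tuple[float, float] = (1.0, 0.5),
    threshold: float = 4.32,
    seed: int = 0,
    diseases: tuple[str, ...] | None = None,
    brain_measure: str = "icv",
) -> pd.DataFrame:
    """Add liability-threshold diagnoses to a cohort table.

    ``diagnosis_d = 1`` iff ``w_prs * prs_d - w_brain * z(brain) + eps >
    threshold`` with independent standard-normal ``eps`` per disease.
    Diagnoses are drawn independently across diseases.  The default
    threshold of 4.32 yields ~0.2% prevalence under the default weights
    (the order of magnitude of severe-disorder diagnoses in a
    community-based imaging cohort); see
    :func:`liability_threshold_for_prevalence`.

    Returns a copy of the cohort with boolean ``dx_<disease>`` columns.
    """
    w_prs, w_brain = weights
    if not (np.isfinite(w_prs) and np.isfinite(w_brain) and np.isfinite(threshold)):
        if not np.isposinf(threshold):
            raise ValueError("weights and threshold must be finite (or threshold +inf)")
    if diseases is None:
        diseases = tuple(
            c[len("prs_"):] for c in cohort.columns if c.startswith("prs_")
        )
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    brain = out[brain_measure].to_numpy(dtype=float)
    brain_z = (brain - brain.mean()) / brain.std(ddof=0)
    for d in diseases:
        liab = (
            w_prs * out[f"prs_{d}"].to_numpy()
            - w_brain * brain_z
            + rng.normal(0.0, 1.0, len(out))
        )
        dx = liab > threshold
        if dx.sum() == 0:
            warnings.warn(
                f"liability threshold produced zero {d} cases at n={len(out)}",
                stacklevel=2,
            )
        out[f"dx_{d}"] = dx
    return out


@dataclass
class GWASPairConfig:
    """Configuration of a simulated exposure/outcome GWAS summary pair.

    ``causal_effect`` is the true effect of the exposure on the outcome
    (b_xy).  A ``pleiotropy_fraction`` of instruments receive direct
    outcome effects drawn from
    ``Normal(pleiotropy_mean, pleiotropy_sd)``, violating the exclusion
    restriction.  Instruments are mutually independent (identity LD).
    """

    n_snps: int = 200
    n_instruments: int = 50
    causal_effect: float = 0.0
    pleiotropy_fraction: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    n_exposure: int = 200_000
    n_outcome: int = 200_000
    include_palindromic: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_instruments > self.n_snps:
            raise ValueError("n_instruments must be <= n_snps")
        if not 0 <= self.pleiotropy_fraction <= 1:
            raise ValueError("pleiotropy_fraction must be in [0, 1]")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if min(self.n_exposure, self.n_outcome) < 2:
            raise ValueError("sample sizes must be >= 2")
        if self.n_instruments < 3:
            warnings.warn(
                "fewer than 3 instruments: Egger and median-based "
                "estimators are unreliable",
                stacklevel=2,
            )


def generate_gwas_pair(
    config: GWASPairConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an exposure/outcome pair of GWAS summary tables.

    The first ``n_instruments`` SNPs carry strong exposure effects
    (non-centrality ~7-12 SD, i.e. genome-wide significant at the stated
    exposure sample size); the rest are null.  Outcome effects are
    ``b_xy * beta_exposure_true + pleiotropy + noise`` with standard
    errors ``1/sqrt(2 f (1-f) N)`` appropriate for a standardized trait.

    Returns ``(exposure, outcome)`` DataFrames with columns
    ``SNP, A1, A2, freq, b, se, p, N``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    k = config.n_instruments

    snp = np.array([f"rs{i + 1:06d}" for i in range(m)])
    pairs = _NONPALINDROMIC_PAIRS + (_PALINDROMIC_PAIRS if config.include_palindromic else ())
    idx = rng.integers(0, len(pairs), m)
    a1 = np.array([pairs[i][0] for i in idx])
    a2 = np.array([pairs[i][1] for i in idx])
    freq = rng.uniform(0.05, 0.95, m)

    se_x = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * config.n_outcome)

    beta_true = np.zeros(m)
    z_true = rng.uniform(7.0, 12.0, k) * rng.choice([-1.0, 1.0], k)
    beta_true[:k] = z_true * se_x[:k]

    pleio = np.zeros(m)
    if config.pleiotropy_fraction > 0:
        n_pleio = int(round(config.pleiotropy_fraction * k))
        which = rng.choice(k, size=n_pleio, replace=False)
        pleio[which] = rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, n_pleio
        )

    b_x = beta_true + rng.normal(0.0, se_x)
    b_y = (
        config.causal_effect * beta_true
        + pleio
        + rng.normal(0.0, se_y)
    )

    def _table(b, se, n):
        p = 2.0 * stats.norm.sf(np.abs(b / se))
        return pd.DataFrame({
            "SNP": snp, "A1": a1, "A2": a2, "freq": freq,
            "b": b, "se": se, "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "N": n,
        })

    return _table(b_x, se_x, config.n_exposure), _table(b_y, se_y, config.n_outcome)


def generate_effect_map(
    regions,
    pattern: str | np.ndarray = "random",
    seed: int | None = None,
    max_abs: float = 0.45,
):
    """Build a synthetic regional Cohen's d map.

    Parameters
    ----------
    regions : sequence of str
    pattern : {"random", "all-negative", "all-positive"} or array of signs
        Sign structure of the map; magnitudes are uniform on
        ``(0.02, max_abs)``.
    seed : int, optional
    max_abs : float
        Magnitude cap; the default matches the scale of published
        case-control maps (|d| <= 0.45).

    Returns
    -------
    EffectSizeMap
    """
    from .maps import EffectSizeMap

    regions = list(regions)
    if not regions:
        raise ValueError("regions must be non-empty")
    rng = np.random.default_rng(seed)
    mag = rng.uniform(0.02, max_abs, len(regions))
    if isinstance(pattern, str):
        if pattern == "all-negative":
            signs = -np.ones(len(regions))
        elif pattern == "all-positive":
            signs = np.ones(len(regions))
        elif pattern == "random":
            signs = rng.choice([-1.0, 1.0], len(regions))
        else:
            raise ValueError(f"unknown pattern {pattern!r}")
    else:
        signs = np.sign(np.asarray(pattern, dtype=float))
        if len(signs) != len(regions):
            raise ValueError("sign pattern length must match regions")
    return EffectSizeMap(regions=regions, d=signs * mag, contrast="synthetic")
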