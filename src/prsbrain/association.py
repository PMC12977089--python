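"""PRS-brain association scan.

Each (disorder, region) pair is tested with a simple linear regression of
the prepared brain measure on the standardized polygenic risk score.
Covariates are removed beforehand by residualization (two-stage fitting),
so the per-pair model has a single predictor.  Results carry a three-tier
significance annotation: nominal (p < 0.05), disease-wise Bonferroni
(p < 0.05 / t_e, with t_e the effective number of independent phenotypes),
and study-wise Bonferroni (p < 0.05 / (t_e * n_diseases)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TIER_ORDER = ("none", "nominal", "disease_wise", "study_wise")


@dataclass
class AssociationResult:
    """OLS slope of one prepared measure on one standardized PRS."""

    disease: str
    region: str
    modality: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    tier: str = "none"


def fit_prs_brain(
    prs_column,
    prepared_measure,
    disease: str = "",
    region: str = "",
    modality: str = "",
) -> AssociationResult:
    """Fit measure ~ standardized PRS by ordinary least squares.

    The PRS is standardized to zero mean / unit SD before fitting, so the
    slope is on the per-SD scale.  Two-sided p from the t distribution
    with n - 2 degrees of freedom.
    """
    x = np.asarray(prs_column, dtype=float)
    y = np.asarray(prepared_measure, dtype=float)
    if len(x) != len(y):
        raise ValueError("PRS and measure must have equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance PRS")
    xz = (x - x.mean()) / sd

    res = stats.linregress(xz, y)
    n = len(x)
    # linregress returns p from t with n-2 df already
    return AssociationResult(
        disease=disease, region=region, modality=modality,
        beta=float(res.slope), se=float(res.stderr),
        t=float(res.slope / res.stderr) if res.stderr > 0 else np.inf,
        p=float(res.pvalue), n=n,
    )


def tier_thresholds(t_e: float, n_diseases: int, alpha: float = 0.05) -> dict:
    """Nominal / disease-wise / study-wise p-value thresholds."""
    if t_e < 1:
        raise ValueError("t_e must be >= 1")
    if n_diseases < 1:
        raise ValueError("n_diseases must be >= 1")
    return {
        "nominal": alpha,
        "disease_wise": alpha / t_e,
        "study_wise": alpha / (t_e * n_diseases),
    }


def assign_tier(p: float, thresholds: dict) -> str:
    if p < thresholds["study_wise"]:
        return "study_wise"
    if p < thresholds["disease_wise"]:
        return "disease_wise"
    if p < thresholds["nominal"]:
        return "nominal"
    return "none"


def significance_tiers(
    results: pd.DataFrame, t_e: float, n_diseases: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Annotate a long-format result table with significance tiers.

    Tiers are nested: every study-wise hit is also disease-wise and
    nominal.  The ``tier`` column records the most stringent tier reached.
    """
    thr = tier_thresholds(t_e, n_diseases, alpha)
    out = results.copy()
    out["tier"] = [assign_tier(p, thr) for p in out["p"]]
    return out


class PRSAssociationScan:
    """Scan model: every disorder PRS against every prepared region.

    Parameters
    ----------
    measures : DataFrame or PreparedMeasures
        Participants x regions matrix of prepared (residualized,
        normal-transformed) brain measures.
    prs : DataFrame
        Participants x disorders matrix of polygenic risk scores; column
        names are disorder labels (a ``prs_`` prefix is stripped).
    modality : str or dict, optional
        Modality label per region (single label, or region -> label).
    """

    def __init__(self, measures, prs: pd.DataFrame, modality="regional"):
        from .prep import PreparedMeasures

        if isinstance(measures, PreparedMeasures):
            measures = measures.data
        if len(measures) != len(prs):
            raise ValueError("measures and prs must cover the same participants")
        self.measures = measures
        self.prs = prs.rename(columns=lambda c: c.removeprefix("prs_"))
        if isinstance(modality, str):
            self.modality = {r: modality for r in measures.columns}
        else:
            self.modality = dict(modality)

    def fit(self, t_e: float | None = None, n_diseases: int | None = None):
        """Run all per-pair regressions; returns :class:`AssociationScanResults`.

        When ``t_e`` is omitted it is estimated from the prepared-measure
        correlation matrix (Li-Ji); ``n_diseases`` defaults to the number
        of PRS columns.
        """
        from .prep import effective_tests

        rows = []
        for d in self.prs.columns:
            x = self.prs[d].to_numpy(dtype=float)
            for r in self.measures.columns:
                res = fit_prs_brain(
                    x, self.measures[r].to_numpy(dtype=float),
                    disease=d, region=r, modality=self.modality.get(r, ""),
                )
                rows.append(res.__dict__)
        table = pd.DataFrame(rows)
        if t_e is None:
            t_e = effective_tests(self.measures.corr()).t_e
        if n_diseases is None:
            n_diseases = self.prs.shape[1]
        table = significance_tiers(table, t_e, n_diseases)
        return AssociationScanResults(table, t_e=t_e, n_diseases=n_diseases)


class AssociationScanResults:
    """Long-format association results with tier annotation."""

    def __init__(self, table: pd.DataFrame, t_e: float, n_diseases: int):
        self.table = table
        self.t_e = t_e
        self.n_diseases = n_diseases
        self.thresholds = tier_thresholds(t_e, n_diseases)

    def beta_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="disease", columns="region", values="beta")

    def summary(self) -> str:
        thr = self.thresholds
        lines = [
            "PRS-brain association scan",
            f"  pairs tested: {len(self.table)} "
            f"({self.n_diseases} disorders x {self.table['region'].nunique()} regions)",
            f"  effective tests t_e = {self.t_e:.2f}",
            f"  thresholds: nominal {thr['nominal']:.3g}, "
            f"disease-wise {thr['disease_wise']:.3g}, "
            f"study-wise {thr['study_wise']:.3g}",
        ]
        counts = self.table["tier"].value_counts()
        for tier in ("study_wise", "disease_wise", "nominal"):
            lines.append(f"  {tier}: {int(counts.get(tier, 0))} pairs")
        top = self.table.nsmallest(5, "p")
        lines.append("  strongest associations:")
        for _, row in top.iterrows():
            lines.append(
                f"    {row.disease:>6s} ~ {row.region:<18s} "
                f"beta={row.beta:+.4f} (se {row.se:.4f}) p={row.p:.3g} [{row.tier}]"
            )
        return "\n".join(lines)

    def plot_heatmap(self, ax=None):
        """Beta heatmap (disorders x regions), tier-annotated."""
        import matplotlib.pyplot as plt

        mat = self.beta_matrix()
        if ax is None:
            _, ax = plt.subplots(figsize=(0.4 * mat.shape[1] + 2, 0.4 * mat.shape[0] + 2))
        vmax = np.nanmax(np.abs(mat.to_numpy()))
        im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
        marks = {"nominal": "*", "disease_wise": "**", "study_wise": "+"}
        lookup = self.table.set_index(["disease", "region"])["tier"]
        for i, d in enumerate(mat.index):
            for j, r in enumerate(mat.columns):
                tier = lookup.get((d, r), "none")
                if tier in marks:
                    ax.text(j, i, marks[tier], ha="center", va="center", fontsize=6)
        ax.figure.colorbar(im, ax=ax, label="beta per PRS SD")
        return ax
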