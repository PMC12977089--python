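"""Quadrant enrichment: are patients over-represented in the
high-genetic-risk / small-brain quadrant?

PRS and a global brain measure are standardized over the full sample,
diagnosed individuals are cross-classified by the signs of the two
z-scores, and the count falling in the (PRS > 0, brain < 0) quadrant is
tested against the 25% chance rate with an exact one-sided binomial test.
The directional hypothesis is that high genetic liability and smaller
brain size are joint risk factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def standardize(values) -> np.ndarray:
    """Z-score over the full sample (cases and non-cases together)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance")
    return (x - x.mean()) / sd


def quadrant_counts(prs_z, brain_z, case_flags) -> pd.DataFrame:
    """2x2 table of case counts by sign(PRS) x sign(brain).

    Values exactly at zero are assigned to the low side (a deterministic
    rule for a measure-zero event on continuous data).  Rows: PRS high /
    low; columns: brain high / low.
    """
    prs_z = np.asarray(prs_z, dtype=float)
    brain_z = np.asarray(brain_z, dtype=float)
    cases = np.asarray(case_flags, dtype=bool)
    if not (len(prs_z) == len(brain_z) == len(cases)):
        raise ValueError("inputs must have equal length")
    if cases.sum() == 0:
        raise ValueError("no cases")
    hi_prs = prs_z[cases] > 0
    hi_brain = brain_z[cases] > 0
    tab = pd.DataFrame(
        [[int(np.sum(hi_prs & hi_brain)), int(np.sum(hi_prs & ~hi_brain))],
         [int(np.sum(~hi_prs & hi_brain)), int(np.sum(~hi_prs & ~hi_brain))]],
        index=pd.Index(["prs_high", "prs_low"]),
        columns=pd.Index(["brain_high", "brain_low"]),
    )
    return tab


def enrichment_test(k_target: int, n_cases: int, p0: float = 0.25) -> float:
    """Exact one-sided upper tail ``P(X >= k)``, ``X ~ Binomial(n, p0)``."""
    if not 0 <= k_target <= n_cases:
        raise ValueError("k_target must lie in [0, n_cases]")
    return float(stats.binom.sf(k_target - 1, n_cases, p0))


@dataclass
class QuadrantResult:
    """Enrichment of one disease in the high-PRS / low-brain quadrant."""

    disease: str
    brain_measure: str
    n_cases: int
    k_target: int
    p_binomial: float
    quadrant_table: pd.DataFrame


class QuadrantEnrichment:
    """Model testing patient enrichment in the risk quadrant.

    Parameters
    ----------
    cohort : DataFrame
        Cohort table with ``prs_<disease>``, ``dx_<disease>`` and global
        brain-measure columns.
    diseases : sequence of str, optional
        Defaults to every disease with a diagnosis column.
    brain_measures : sequence of str
        Global measures to test (e.g. total_sa, mean_ct, icv).
    """

    def __init__(self, cohort: pd.DataFrame, diseases=None,
                 brain_measures=("total_sa", "mean_ct", "icv")):
        self.cohort = cohort
        if diseases is None:
            diseases = [c[len("dx_"):] for c in cohort.columns
                        if c.startswith("dx_")]
        self.diseases = list(diseases)
        self.brain_measures = [m for m in brain_measures if m in cohort.columns]
        if not self.diseases:
            raise ValueError("no diagnosis columns found")
        if not self.brain_measures:
            raise ValueError("no global brain-measure columns found")

    def fit(self, p0: float = 0.25):
        results = []
        for disease in self.diseases:
            prs_z = standardize(self.cohort[f"prs_{disease}"])
            cases = self.cohort[f"dx_{disease}"].to_numpy(dtype=bool)
            if cases.sum() == 0:
                continue
            for measure in self.brain_measures:
                brain_z = standardize(self.cohort[measure])
                tab = quadrant_counts(prs_z, brain_z, cases)
                k = int(tab.loc["prs_high", "brain_low"])
                n = int(tab.to_numpy().sum())
                results.append(QuadrantResult(
                    disease=disease, brain_measure=measure,
                    n_cases=n, k_target=k,
                    p_binomial=enrichment_test(k, n, p0),
                    quadrant_table=tab,
                ))
        return QuadrantResults(results, p0=p0)


class QuadrantResults:
    """Per disease x measure quadrant enrichment results."""

    def __init__(self, results: list[QuadrantResult], p0: float = 0.25):
        self.results = results
        self.p0 = p0

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"disease": r.disease, "brain_measure": r.brain_measure,
             "n_cases": r.n_cases, "k_target": r.k_target,
             "proportion": r.k_target / r.n_cases, "p_binomial": r.p_binomial}
            for r in self.results
        ])

    def summary(self) -> str:
        lines = [f"Quadrant enrichment vs chance rate {self.p0:.2f}"]
        for r in self.results:
            lines.append(
                f"  {r.disease:>6s} x {r.brain_measure:<9s}: "
                f"{r.k_target}/{r.n_cases} cases in high-PRS/low-brain "
                f"quadrant ({100 * r.k_target / r.n_cases:.1f}%), "
                f"p = {r.p_binomial:.3g}"
            )
        return "\n".join(lines)

    def plot(self, disease: str, brain_measure: str, ax=None):
        """Scatter of standardized brain measure vs PRS, cases highlighted."""
        import matplotlib.pyplot as plt

        res = next(r for r in self.results
                   if r.disease == disease and r.brain_measure == brain_measure)
        if ax is None:
            _, ax = plt.subplots()
        ax.axhline(0, color="gray", lw=0.6)
        ax.axvline(0, color="gray", lw=0.6)
        ax.set_xlabel(f"standardized PRS ({disease})")
        ax.set_ylabel(f"standardized {brain_measure}")
        ax.set_title(
            f"{res.k_target}/{res.n_cases} cases in risk quadrant, "
            f"p = {res.p_binomial:.3g}"
        )
        return ax
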