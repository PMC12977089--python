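"""Readers and writers for the package's plain-text formats.

All interchange formats are inspectable text: cohort tables and result
tables as TSV, effect-size maps and crosswalk weights as CSV, GWAS summary
statistics as the common ``SNP A1 A2 freq b se p N`` TSV dialect, and
exclusion regions as BED-like three-column text.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas

logger = logging.getLogger(__name__)

#: Canonical GWAS summary-stat columns and accepted (lowercase) synonyms.
GWAS_COLUMNS = {
    "SNP": ("snp", "rsid", "markername", "id"),
    "A1": ("a1", "effect_allele", "allele1", "ea"),
    "A2": ("a2", "other_allele", "allele2", "oa", "nea"),
    "freq": ("freq", "eaf", "af", "frq", "maf"),
    "b": ("b", "beta", "effect", "es"),
    "se": ("se", "stderr", "standard_error"),
    "p": ("p", "pval", "p_value", "pvalue"),
    "N": ("n", "samplesize", "n_total"),
}
_OPTIONAL = {"chr": ("chr", "chrom", "chromosome"), "bp": ("bp", "pos", "position")}


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    if tab.isna().any().any():
        raise ValueError("cohort table contains missing values")
    return tab


def write_gwas_sumstats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_gwas_sumstats(path) -> pd.DataFrame:
    """Read a GWAS summary TSV, accepting case-insensitive header synonyms.

    Rows violating basic invariants (se <= 0, p outside (0, 1], alleles
    not in {A,C,G,T}, a1 == a2) are dropped with a logged count.  A
    missing required column raises, naming the column.
    """
    tab = pd.read_csv(path, sep="\t")
    rename = {}
    lower = {c.lower(): c for c in tab.columns}
    for canon, synonyms in {**GWAS_COLUMNS, **_OPTIONAL}.items():
        for syn in synonyms:
            if syn in lower:
                rename[lower[syn]] = canon
                break
    tab = tab.rename(columns=rename)
    missing = [c for c in GWAS_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    n0 = len(tab)
    tab["A1"] = tab["A1"].astype(str).str.upper()
    tab["A2"] = tab["A2"].astype(str).str.upper()
    valid = (
        tab["se"].gt(0)
        & tab["p"].gt(0) & tab["p"].le(1)
        & tab["A1"].isin(list("ACGT"))
        & tab["A2"].isin(list("ACGT"))
        & (tab["A1"] != tab["A2"])
        & np.isfinite(tab["b"])
        & tab["freq"].gt(0) & tab["freq"].lt(1)
    )
    dropped = int(n0 - valid.sum())
    if dropped:
        logger.info("dropped %d of %d rows failing summary-stat invariants",
                    dropped, n0)
    return tab.loc[valid].reset_index(drop=True)


def write_effect_map(emap, path) -> None:
    emap.to_series().rename_axis("region").reset_index().to_csv(path, index=False)


def read_effect_map(path, atlas_name: str | None = None, modality: str = "",
                    contrast: str = ""):
    """Read a two-column ``region,d`` CSV into an :class:`EffectSizeMap`.

    When ``atlas_name`` is given, labels are validated against that atlas
    and ordered canonically; regions absent from the file stay absent
    (explicitly incomplete maps, e.g. 6 of 7 subcortical regions, are
    legitimate).
    """
    from .maps import EffectSizeMap

    tab = pd.read_csv(path)
    if not {"region", "d"}.issubset(tab.columns):
        raise ValueError("effect map CSV needs columns 'region' and 'd'")
    regions = atlas.validate_regions(tab["region"], atlas_name)
    d = tab.set_index("region").loc[regions, "d"].to_numpy(dtype=float)
    return EffectSizeMap(regions=list(regions), d=d, modality=modality,
                         contrast=contrast)


def write_correlation(corr: pd.DataFrame, path) -> None:
    corr.to_csv(path)


def read_correlation(path) -> pd.DataFrame:
    tab = pd.read_csv(path, index_col=0)
    if list(tab.index) != list(tab.columns):
        raise ValueError("correlation CSV must have matching row/column labels")
    return tab


def read_crosswalk(path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    required = {"target_region", "source_region", "weight"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"crosswalk CSV missing column(s): {sorted(missing)}")
    return tab


def write_crosswalk(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, index=False)


def read_exclude_regions(path) -> pd.DataFrame:
    """BED-like three-column (chrom, start, end) region file."""
    tab = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                      names=["chrom", "start", "end"],
                      dtype={"chrom": str})
    if (tab["end"] <= tab["start"]).any():
        raise ValueError("region end must exceed start")
    return tab


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
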