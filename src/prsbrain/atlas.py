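"""Region label sets and atlas crosswalks.

Two coordinate systems are used throughout the package:

* a genetically informed cortical parcellation (12 surface-area and 12
  thickness clusters plus global measures) in which the cohort-level
  association scan runs, and
* the Desikan-Killiany (DK) parcellation (34 bilaterally combined cortical
  regions) in which published case-control effect-size maps are reported.

Maps are compared in DK space; a weighted crosswalk converts cluster-level
effect sizes to DK regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: 34 bilaterally combined Desikan-Killiany cortical regions.
DK_CORTICAL: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: Seven subcortical volumes common to published case-control comparisons.
SUBCORTICAL: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

#: 12 genetically clustered surface-area parcels (bilateral).
CLUSTER_SA: tuple[str, ...] = tuple(f"sa_cluster{i:02d}" for i in range(1, 13))
#: 12 genetically clustered thickness parcels (bilateral).
CLUSTER_CT: tuple[str, ...] = tuple(f"ct_cluster{i:02d}" for i in range(1, 13))

#: Global measures: total surface area, mean thickness, intracranial volume.
GLOBAL_MEASURES: tuple[str, ...] = ("total_sa", "mean_ct", "icv")

ATLASES: dict[str, tuple[str, ...]] = {
    "dk_cortical": DK_CORTICAL,
    "subcortical": SUBCORTICAL,
    "cluster_sa": CLUSTER_SA,
    "cluster_ct": CLUSTER_CT,
    "global": GLOBAL_MEASURES,
}


def validate_regions(regions, atlas: str | None = None) -> list[str]:
    """Check region labels against an atlas label set and reject duplicates.

    Parameters
    ----------
    regions : sequence of str
    atlas : str, optional
        Key into :data:`ATLASES`. When given, unknown labels raise.

    Returns
    -------
    list of str
        The labels in canonical atlas order when ``atlas`` is given,
        otherwise in input order.
    """
    regions = list(regions)
    seen = set()
    dups = [r for r in regions if r in seen or seen.add(r)]
    if dups:
        raise ValueError(f"duplicate region labels: {sorted(set(dups))}")
    if atlas is None:
        return regions
    labels = ATLASES[atlas]
    unknown = [r for r in regions if r not in labels]
    if unknown:
        raise ValueError(
            f"region labels not in atlas {atlas!r}: {unknown}"
        )
    order = {r: i for i, r in enumerate(labels)}
    return sorted(regions, key=order.__getitem__)


def block_crosswalk(
    source_regions, target_regions, seed: int | None = None
) -> pd.DataFrame:
    """Build a synthetic many-to-many crosswalk weight table.

    Each target region receives weight from a contiguous block of source
    regions; per-target weights sum to one.  Used to emulate converting a
    clustered parcellation into DK space when no empirically derived
    overlap table is supplied.

    Returns a long-format frame with columns
    ``target_region, source_region, weight``.
    """
    rng = np.random.default_rng(seed)
    source_regions = list(source_regions)
    target_regions = list(target_regions)
    ns = len(source_regions)
    rows = []
    for j, tgt in enumerate(target_regions):
        # anchor each target to a source block, with mild random mixing
        anchor = int(np.floor(j * ns / len(target_regions)))
        members = {anchor, (anchor + 1) % ns}
        raw = rng.uniform(0.5, 1.0, size=len(members)) if seed is not None else np.ones(len(members))
        w = raw / raw.sum()
        for m, wi in zip(sorted(members), w):
            rows.append((tgt, source_regions[m], float(wi)))
    return pd.DataFrame(rows, columns=["target_region", "source_region", "weight"])
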