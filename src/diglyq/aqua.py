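"""Absolute quantification of ubiquitin chain linkages and phospho-Ser65
stoichiometry from heavy-reference (AQUA/PRM) peptide measurements.

A measurement table has one row per (peptide, replicate, condition) with
columns ``peptide``, ``locus``, ``light_area``, ``heavy_area``,
``spike_fmol``, ``replicate``, ``condition``.  Loci follow ubiquitin
nomenclature: chain linkages K6, K11, K27, K29, K33, K48, K63, M1; the
Ser65 pair ``S65_phospho`` / ``S65_unmodified``; and ``total_*`` loci whose
peptides report total ubiquitin.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Marker for not-determined quantities in exports.
ND = "n.d."

LINKAGE_LOCI = ("K6", "K11", "K27", "K29", "K33", "K48", "K63", "M1")


def aqua_abundance(light_area: float, heavy_area: float, spike_fmol: float) -> float:
    """Light-peptide amount: ``(light/heavy) * spike`` fmol.

    The heavy reference is spiked at a known amount, so the light/heavy
    chromatographic area ratio converts directly to femtomoles.
    """
    if heavy_area <= 0:
        raise ValueError("heavy area must be > 0 (peptide unquantifiable)")
    if light_area < 0 or spike_fmol <= 0:
        raise ValueError("light area must be >= 0 and spike > 0")
    return light_area / heavy_area * spike_fmol


def total_ub(locus_fmol: Sequence[float]) -> float:
    """Total ubiquitin: the mean of per-locus total-UB estimates."""
    vals = np.asarray(list(locus_fmol), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one locus measurement")
    return float(vals.mean())


def phospho_stoichiometry(phospho_fmol: float, unmodified_fmol: float) -> Optional[float]:
    """Fraction phosphorylated at a locus: ``phospho / (phospho + unmodified)``.

    Returns ``None`` (not determined) when both amounts are zero.
    """
    if phospho_fmol < 0 or unmodified_fmol < 0:
        raise ValueError("amounts must be >= 0")
    total = phospho_fmol + unmodified_fmol
    if total == 0:
        return None
    return phospho_fmol / total


def linkage_profile(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-condition linkage profile: mean fmol and SEM across replicates.

    Each measurement row is converted to fmol with :func:`aqua_abundance`;
    per (condition, locus) the mean and standard error of the mean over
    replicates are reported, plus the phospho-Ser65 stoichiometry computed
    from the replicate-mean phospho and unmodified amounts, and total
    ubiquitin as the mean over ``total_*`` loci.
    """
    df = measurements.copy()
    df["fmol"] = [
        aqua_abundance(l, h, s)
        for l, h, s in zip(df["light_area"], df["heavy_area"], df["spike_fmol"])
    ]
    rows = []
    for condition, grp in df.groupby("condition", sort=False):
        per_locus = grp.groupby("locus")["fmol"]
        means = per_locus.mean()
        sems = per_locus.sem(ddof=1)
        counts = per_locus.count()
        stoich = phospho_stoichiometry(
            float(means.get("S65_phospho", 0.0)),
            float(means.get("S65_unmodified", 0.0)),
        )
        total_loci = [l for l in means.index if l.startswith("total_")]
        total = total_ub(means.loc[total_loci]) if total_loci else math.nan
        for locus in means.index:
            rows.append(
                {
                    "condition": condition,
                    "locus": locus,
                    "fmol": means[locus],
                    "sem": sems[locus] if counts[locus] > 1 else math.nan,
                    "n_replicates": int(counts[locus]),
                    "total_ub_fmol": total,
                    "s65_stoichiometry": math.nan if stoich is None else stoich,
                }
            )
    return pd.DataFrame(rows)


def linkage_fold_change(
    treated: pd.DataFrame, untreated: pd.DataFrame
) -> pd.DataFrame:
    """Per-locus fold change treated / untreated on the fmol scale.

    Loci with zero baseline are reported not-determined (fold NaN, the
    ``n.d.`` marker in exports) rather than raising.
    """
    t = treated.set_index("locus")["fmol"]
    u = untreated.set_index("locus")["fmol"]
    if (t < 0).any() or (u < 0).any():
        raise ValueError("abundances must be >= 0")
    loci = [l for l in t.index if l in u.index]
    rows = []
    for locus in loci:
        base = u[locus]
        rows.append(
            {
                "locus": locus,
                "treated_fmol": t[locus],
                "untreated_fmol": base,
                "fold": t[locus] / base if base > 0 else math.nan,
                "determined": base > 0,
            }
        )
    return pd.DataFrame(rows)
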