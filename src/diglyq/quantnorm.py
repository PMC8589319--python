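"""Reporter-matrix normalization and abundance metrics.

Quantitative matrices are DataFrames with features in rows and one column
per TMT channel; values are reporter signal-to-noise, ratios to a reference
channel, or log ratios depending on the step.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

#: Average monoisotopic-independent mass of a DNA base pair, g/mol.
MEAN_BASEPAIR_MASS = 615.8771
#: Mouse defaults for the proteomic ruler.
MOUSE_PLOIDY = 2
MOUSE_GENOME_SIZE_BP = 2.7e9


def equal_loading_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each channel so all column sums match, assuming equal loading.

    Each reporter channel is summed across all quantified features and
    rescaled so every column sum equals the mean of the original column
    sums; row and column order are preserved.
    """
    sums = matrix.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"nonpositive column sum for channel(s): {bad}")
    return matrix * (sums.mean() / sums)


def normalize_site_to_protein(
    site_ratios: pd.DataFrame,
    protein_ratios: pd.DataFrame,
    site_to_protein: Mapping[str, str],
) -> Tuple[pd.DataFrame, pd.Series]:
    """Divide each site's channel ratios by its protein's channel ratios.

    Sites whose protein was not quantified in the parallel total proteome
    (or has a zero ratio in any channel) pass through unchanged and are
    flagged not-normalized — mirroring entries reported as "not determined".

    Returns the normalized matrix and a boolean Series ``normalized``.
    """
    out = site_ratios.copy()
    flags = pd.Series(False, index=site_ratios.index, name="normalized")
    for sid in site_ratios.index:
        acc = site_to_protein.get(sid)
        if acc is None or acc not in protein_ratios.index:
            continue
        prot = protein_ratios.loc[acc]
        if (prot == 0).any():
            continue
        out.loc[sid] = site_ratios.loc[sid] / prot
        flags.loc[sid] = True
    return out, flags


def median_center(log_matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-column median from a log-ratio matrix.

    Accounts for sample-to-sample variation; each output column has
    median 0.
    """
    med = log_matrix.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValueError(f"column(s) with no finite values: {bad}")
    return log_matrix - med


def rank_site_abundance(
    sites: pd.DataFrame,
    channels: Sequence[str],
    rank_channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Absolute-scale site abundance by apportioning MS1 intensity.

    The total MS1 precursor intensity of a diGLY peptide reflects the sum of
    all its TMT-labeled forms, so each channel's share of the summed reporter
    S/N apportions it:  ``A(s, c) = MS1(s) * SN(s, c) / sum_c SN(s, c)``.
    The apportionment conserves MS1 mass across channels.

    Ranking (descending, ties broken by protein accession then site) is by
    the mean of ``rank_channels`` (default: all channels).

    Sites with zero summed S/N cannot be apportioned and are excluded with
    a warning.
    """
    channels = list(channels)
    sn = sites[channels].to_numpy(dtype=float)
    total = sn.sum(axis=1)
    ok = total > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} site(s) with zero summed S/N",
            stacklevel=2,
        )
    kept = sites.loc[ok].reset_index(drop=True)
    share = sn[ok] / total[ok, None]
    abundance = kept["ms1_total"].to_numpy(dtype=float)[:, None] * share
    out = kept[["protein", "site"]].copy()
    for j, c in enumerate(channels):
        out[c] = abundance[:, j]
    use = list(rank_channels) if rank_channels is not None else channels
    out["rank_abundance"] = out[use].mean(axis=1)
    out = out.sort_values(
        ["rank_abundance", "protein", "site"], ascending=[False, True, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def protein_molecular_weight(sequence: str) -> float:
    """Average molecular weight (g/mol) of a protein from residue masses."""
    # average residue masses (monoisotopic would understate MW); water added once
    avg = {
        "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
        "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
        "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
        "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
        "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    }
    try:
        return sum(avg[r] for r in sequence) + 18.01528
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def proteomic_ruler_copies(
    intensities: pd.Series,
    molecular_weights: pd.Series,
    histone_accessions: Sequence[str],
    ploidy: int = MOUSE_PLOIDY,
    genome_size_bp: float = MOUSE_GENOME_SIZE_BP,
    basepair_mass: float = MEAN_BASEPAIR_MASS,
) -> pd.DataFrame:
    """Estimate per-cell protein copy numbers with the histone proteomic ruler.

    Histone mass per cell is pinned to DNA mass per cell
    (``ploidy * genome_size_bp * basepair_mass / N_A`` grams, 1:1 ratio), so

    ``copies_i = I_i * N_A * m_DNA / (MW_i * sum_{h in histones} I_h)``.

    The estimate is invariant to global intensity rescaling and linear in
    ploidy.  Returns a table with copies and descending abundance ranks.
    """
    histones = list(histone_accessions)
    if not histones:
        raise ValueError("histone accession set is empty")
    missing = [h for h in histones if h not in intensities.index]
    if missing:
        raise ValueError(f"histone(s) missing from intensity table: {missing}")
    mw = molecular_weights.reindex(intensities.index)
    if mw.isna().any() or (mw <= 0).any():
        bad = list(mw.index[mw.isna() | (mw <= 0)])
        raise ValueError(f"missing or nonpositive molecular weight for: {bad}")
    m_dna = ploidy * genome_size_bp * basepair_mass / Avogadro
    histone_sum = intensities.loc[histones].sum()
    copies = intensities * Avogadro * m_dna / (mw * histone_sum)
    out = pd.DataFrame(
        {
            "protein": intensities.index,
            "molecular_weight": mw.to_numpy(),
            "intensity": intensities.to_numpy(),
            "copies": copies.to_numpy(),
        }
    )
    out["rank"] = (
        out["copies"].rank(ascending=False, method="first").astype(int)
    )
    return out.sort_values("rank").reset_index(drop=True)
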