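"""PSM-level processing: quality filters, target-decoy FDR, site localization,
parsimony protein assembly, and aggregation of diGLY PSMs to protein sites.

PSM tables are pandas DataFrames with the following required columns
(the header contract for the tab-separated on-disk form is identical):

========================  =====================================================
column                    meaning
========================  =====================================================
peptide                   uppercase residue string
proteins                  ``;``-separated candidate accessions (first = razor)
mods                      ``;``-separated ``position:type`` entries, 1-based
                          position within the peptide (e.g. ``"4:glygly"``)
charge                    precursor charge state
score                     search engine score (higher is better)
is_decoy                  bool, reversed-database match
isolation_specificity     fraction of isolation-window signal from the
                          precursor, in [0, 1]
summed_sn                 summed reporter signal-to-noise over all channels
ms1_intensity             MS1 precursor intensity
has_ms3                   bool, an MS3 quantification spectrum exists
ascore                    site localization score (NaN when not applicable)
<channel labels>          one column per TMT channel with reporter S/N
========================  =====================================================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: Localization score above which a site is considered confidently localized;
#: corresponds to 95% confidence for the binomial localization model.
ASCORE_LOCALIZED = 13.0

REQUIRED_COLUMNS = (
    "peptide",
    "proteins",
    "mods",
    "charge",
    "score",
    "is_decoy",
    "isolation_specificity",
    "summed_sn",
    "ms1_intensity",
    "has_ms3",
    "ascore",
)


@dataclass
class FilterThresholds:
    """PSM quality thresholds.

    The exclusion rules are strict "less than": records at the boundary
    (isolation specificity exactly 0.7, summed S/N exactly 150) are kept.
    The charge window applies only to diGLY data, where only precursors with
    charge 3-6 are informative.
    """

    min_isolation_specificity: float = 0.7
    min_summed_sn: float = 150.0
    charge_window: Tuple[int, int] = (3, 6)
    digly_mode: bool = False


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    excluded_by_reason: Dict[str, int] = field(default_factory=dict)
    #: parallel to the input frame: list of reasons per record (empty = kept)
    reasons: List[List[str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_kept


def filter_psms(
    psms: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> Tuple[pd.DataFrame, FilterReport]:
    """Apply the MS3 quantification quality filters.

    A record is kept iff isolation specificity >= 0.7, summed reporter
    S/N >= 150, an MS3 spectrum exists, and (in diGLY mode) the precursor
    charge lies in the 3-6 window.  A record may accumulate several
    exclusion reasons; all are reported.
    """
    t = thresholds or FilterThresholds()
    n = len(psms)
    reasons: List[List[str]] = [[] for _ in range(n)]
    if n:
        spec_bad = psms["isolation_specificity"].to_numpy() < t.min_isolation_specificity
        sn_bad = psms["summed_sn"].to_numpy() < t.min_summed_sn
        ms3_bad = ~psms["has_ms3"].to_numpy().astype(bool)
        charge = psms["charge"].to_numpy()
        lo, hi = t.charge_window
        charge_bad = t.digly_mode & ((charge < lo) | (charge > hi))
        for i in range(n):
            if spec_bad[i]:
                reasons[i].append("isolation_specificity")
            if sn_bad[i]:
                reasons[i].append("summed_sn")
            if ms3_bad[i]:
                reasons[i].append("no_ms3")
            if np.ndim(charge_bad) and charge_bad[i]:
                reasons[i].append("charge")
    keep_mask = np.array([not r for r in reasons], dtype=bool)
    by_reason: Dict[str, int] = {}
    for r in reasons:
        for name in r:
            by_reason[name] = by_reason.get(name, 0) + 1
    kept = psms.loc[keep_mask].copy() if n else psms.copy()
    report = FilterReport(
        n_input=n, n_kept=len(kept), excluded_by_reason=by_reason, reasons=reasons
    )
    return kept, report


def target_decoy_fdr(
    psms: pd.DataFrame, level: float = 0.01, by: str = "psm"
) -> pd.DataFrame:
    """Threshold records at a target-decoy estimated FDR.

    Records (or peptide/protein groups, scored by their best member) are
    sorted by descending score; at each cutoff the FDR is estimated as
    ``#decoys / max(1, #targets)`` above the cutoff, and the largest prefix
    with estimated FDR <= ``level`` is kept.  Decoys are removed from the
    output.

    Parameters
    ----------
    by:
        ``"psm"`` thresholds individual records; ``"peptide"`` and
        ``"protein"`` collapse to the best score per peptide sequence or
        razor protein first and keep every record of a passing target group.
    """
    if not 0 < level < 1:
        if level == 0:
            pass  # level 0 keeps only the leading zero-decoy prefix
        else:
            raise ValueError(f"level must be in [0, 1), got {level}")
    if by not in ("psm", "peptide", "protein"):
        raise ValueError(f"unknown grouping level: {by!r}")
    if psms.empty or not (~psms["is_decoy"]).any():
        return psms.iloc[0:0].copy()

    if by == "psm":
        keys = pd.Series(np.arange(len(psms)), index=psms.index)
    elif by == "peptide":
        keys = psms["peptide"]
    else:
        keys = psms["proteins"].str.split(";").str[0]

    groups = pd.DataFrame(
        {"key": keys, "score": psms["score"], "is_decoy": psms["is_decoy"]}
    )
    best = (
        groups.groupby("key", sort=False)
        .agg(score=("score", "max"), is_decoy=("is_decoy", "all"))
        .reset_index()
    )
    # stable sort: descending score, decoys before targets on ties so the
    # estimate is conservative
    best = best.sort_values(
        ["score", "is_decoy"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    decoy = best["is_decoy"].to_numpy()
    n_decoy = np.cumsum(decoy)
    n_target = np.cumsum(~decoy)
    fdr = n_decoy / np.maximum(1, n_target)
    passing = np.nonzero(fdr <= level)[0]
    if len(passing) == 0:
        return psms.iloc[0:0].copy()
    cut = passing[-1] + 1  # largest qualifying prefix
    kept_keys = set(best.loc[: cut - 1].loc[~decoy[:cut], "key"])
    out = psms.loc[keys.isin(kept_keys) & ~psms["is_decoy"]].copy()
    return out


def ascore(n: int, k: int, p: float) -> float:
    """Binomial localization score ``-10 log10 P(X >= k)``, X ~ Binomial(n, p).

    ``n`` is the number of site-determining fragment ions, ``k`` the number
    matched at the chosen peak depth with match probability ``p``.  A score
    of 13 corresponds to a tail probability of 0.05, i.e. 95% confidence.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    tail = stats.binom.sf(k - 1, n, p)  # P(X >= k)
    if tail <= 0:
        return math.inf
    return -10.0 * math.log10(tail)


def ascore_site(best: float, runner_up: float) -> float:
    """Site score for two candidate isomers: best minus runner-up score."""
    return best - runner_up


def parsimony_protein_groups(
    peptide_to_proteins: Mapping[str, Iterable[str]]
) -> Dict[str, List[str]]:
    """Greedy minimal protein set explaining all peptides (razor assignment).

    Repeatedly selects the protein covering the most still-unexplained
    peptides (ties broken by lexicographic accession order); every peptide
    is assigned to exactly one selected protein.
    """
    remaining: Dict[str, List[str]] = {}
    coverage: Dict[str, set] = {}
    for pep, prots in peptide_to_proteins.items():
        prots = list(prots)
        if not prots:
            raise ValueError(f"peptide {pep!r} has no candidate protein")
        remaining[pep] = prots
        for acc in prots:
            coverage.setdefault(acc, set()).add(pep)
    assigned: Dict[str, List[str]] = {}
    unexplained = set(remaining)
    while unexplained:
        acc = min(
            coverage, key=lambda a: (-len(coverage[a] & unexplained), a)
        )
        covered = coverage[acc] & unexplained
        if not covered:
            break
        assigned[acc] = sorted(covered)
        unexplained -= covered
    return assigned


def _parse_mods(mods: str) -> List[Tuple[int, str]]:
    out = []
    if isinstance(mods, str) and mods:
        for entry in mods.split(";"):
            pos, _, kind = entry.partition(":")
            out.append((int(pos), kind))
    return out


def aggregate_to_sites(
    psms: pd.DataFrame,
    protein_sequences: Mapping[str, str],
    channels: Sequence[str],
    mod_type: str = "glygly",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse diGLY PSMs to protein sites by summing reporter S/N.

    Each PSM's modification position is mapped to a 1-based residue index
    in its razor protein by exact substring search for the peptide (first
    occurrence wins, with a warning on multiple matches).  Per-channel S/N
    vectors and MS1 intensities are summed over all PSMs of a site.

    Returns ``(sites, ambiguous)``: ``ambiguous`` holds sites supported only
    by PSMs whose localization score is below 13; these are excluded from
    the primary table but flagged rather than dropped silently.

    Raises
    ------
    ValueError
        If a peptide cannot be found in its razor protein sequence.
    """
    records: Dict[Tuple[str, int], Dict] = {}
    for idx, row in psms.iterrows():
        acc = row["proteins"].split(";")[0]
        seq = protein_sequences.get(acc)
        if seq is None:
            raise ValueError(f"no sequence for protein {acc!r} (record {idx})")
        start = seq.find(row["peptide"])
        if start < 0:
            raise ValueError(
                f"peptide {row['peptide']!r} not found in protein {acc!r} (record {idx})"
            )
        if seq.find(row["peptide"], start + 1) >= 0:
            warnings.warn(
                f"peptide {row['peptide']!r} occurs more than once in {acc!r}; "
                "using first occurrence",
                stacklevel=2,
            )
        localized = not (
            pd.notna(row["ascore"]) and row["ascore"] < ASCORE_LOCALIZED
        )
        for pos, kind in _parse_mods(row["mods"]):
            if kind != mod_type:
                continue
            site = start + pos  # 1-based protein coordinate
            key = (acc, site)
            rec = records.setdefault(
                key,
                {
                    "protein": acc,
                    "site": site,
                    "residue": seq[site - 1],
                    "ms1_total": 0.0,
                    "n_psms": 0,
                    "n_localized": 0,
                    "sn": np.zeros(len(channels)),
                },
            )
            rec["sn"] += row[list(channels)].to_numpy(dtype=float)
            rec["ms1_total"] += float(row["ms1_intensity"])
            rec["n_psms"] += 1
            rec["n_localized"] += int(localized)

    rows = []
    for rec in records.values():
        row_out = {
            "protein": rec["protein"],
            "site": rec["site"],
            "residue": rec["residue"],
            "ms1_total": rec["ms1_total"],
            "n_psms": rec["n_psms"],
            "localized": rec["n_localized"] > 0,
        }
        for c, v in zip(channels, rec["sn"]):
            row_out[c] = v
        rows.append(row_out)
    cols = ["protein", "site", "residue", "ms1_total", "n_psms", "localized"] + list(
        channels
    )
    table = pd.DataFrame(rows, columns=cols)
    if table.empty:
        return table, table.copy()
    table = table.sort_values(["protein", "site"]).reset_index(drop=True)
    sites = table[table["localized"]].reset_index(drop=True)
    ambiguous = table[~table["localized"]].reset_index(drop=True)
    return sites, ambiguous
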