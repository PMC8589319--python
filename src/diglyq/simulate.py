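"""Synthetic data with planted ground truth for the diGLY TMT-MS3 pipeline.

The generator emulates an 11-plex TMT experiment on neuronal mitochondria:
log-normal protein abundances, diGLY sites on lysines, a responsive
fraction of sites carrying 2- to 8-fold up-regulation on depolarized (AO)
channels — suppressed in PINK1-KO channels when genotype-dependent —
multiplicative log-normal reporter noise, decoy PSMs from a shifted score
null, histone proteins pinned to planted per-cell copy numbers, ortholog
sequence pairs with conserved lysines, and AQUA tables with planted
linkage amounts and phospho stoichiometry.

Channel semantics are carried by the group labels: a channel whose label
contains ``"AO"`` is depolarized, one containing ``"KO"`` is PINK1
knockout.  The defaults reproduce a 5 untreated / 5 AO / 1 spare layout.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .quantnorm import MEAN_BASEPAIR_MASS, protein_molecular_weight
from scipy.constants import Avogadro

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_GROUPS = ["UT"] * 5 + ["AO"] * 5 + ["spare"]
KO_GROUPS = ["WT_UT"] * 3 + ["WT_AO"] * 3 + ["KO_UT"] * 3 + ["KO_AO"] * 2

SUBCOMPARTMENT_WEIGHTS = {
    "MOM": 0.25,
    "MIM": 0.25,
    "Matrix": 0.30,
    "IMS": 0.08,
    "Membrane": 0.07,
    "unknown": 0.05,
}


@dataclass
class SimulationConfig:
    n_channels: int = 11
    group_labels: List[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    n_proteins: int = 200
    n_sites: int = 400
    fraction_responsive: float = 0.15
    effect_log2_range: Tuple[float, float] = (1.0, 3.0)
    fraction_genotype_dependent: float = 0.9
    reporter_cv: float = 0.1
    decoy_fraction: float = 0.1
    histone_count: int = 4
    ploidy: int = 2
    genome_size_bp: float = 2.7e9
    fraction_mitochondrial: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ValueError(f"n_channels must be >= 2, got {self.n_channels}")
        if len(self.group_labels) != self.n_channels:
            raise ValueError(
                f"group_labels must have length n_channels={self.n_channels}, "
                f"got {len(self.group_labels)}"
            )
        for name in (
            "fraction_responsive",
            "fraction_genotype_dependent",
            "decoy_fraction",
            "fraction_mitochondrial",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.effect_log2_range
        if lo < 0 or hi < lo:
            raise ValueError(
                f"effect_log2_range must satisfy 0 <= lo <= hi, got {self.effect_log2_range}"
            )
        if self.n_proteins < 1 or self.n_sites < 1:
            raise ValueError("n_proteins and n_sites must be >= 1")
        if self.reporter_cv < 0:
            raise ValueError(f"reporter_cv must be >= 0, got {self.reporter_cv}")
        if self.histone_count < 1:
            raise ValueError(f"histone_count must be >= 1, got {self.histone_count}")
        if self.ploidy < 1 or self.genome_size_bp <= 0:
            raise ValueError("ploidy must be >= 1 and genome_size_bp > 0")


@dataclass
class GroundTruth:
    #: per site: protein, site, true_log2_effect, responsive, genotype_dependent
    sites: pd.DataFrame
    #: per protein: gene, copies, mitochondrial, subcompartment
    proteins: pd.DataFrame
    channels: List[str]
    group_labels: List[str]

    def to_json(self, path: str) -> None:
        payload = {
            "sites": self.sites.to_dict(orient="records"),
            "proteins": self.proteins.to_dict(orient="records"),
            "channels": self.channels,
            "group_labels": self.group_labels,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def treated_channels(group_labels: Sequence[str]) -> np.ndarray:
    """Boolean mask of depolarized (AO) channels."""
    return np.array(["AO" in g for g in group_labels])


def ko_channels(group_labels: Sequence[str]) -> np.ndarray:
    """Boolean mask of PINK1-knockout channels."""
    return np.array(["KO" in g for g in group_labels])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    seq = rng.choice(list(AMINO_ACIDS), size=length)
    # guarantee a healthy lysine supply for site placement
    n_extra_k = max(3, length // 20)
    pos = rng.choice(length, size=n_extra_k, replace=False)
    seq[pos] = "K"
    return "".join(seq)


def _tryptic_window(seq: str, site0: int, rng: np.random.Generator) -> Tuple[str, int]:
    """A tryptic-like peptide containing the modified residue.

    Cuts after the nearest K/R upstream and at the first K/R at or after the
    site (the modified lysine itself does not cut: the GlyGly remnant blocks
    cleavage).  Returns (peptide, 0-based start in protein).
    """
    start = 0
    for i in range(site0 - 1, -1, -1):
        if seq[i] in "KR":
            start = i + 1
            break
    end = len(seq)
    for i in range(site0 + 1, len(seq)):
        if seq[i] in "KR":
            end = i + 1
            break
    # keep peptides search-engine-plausible in length: extend downstream,
    # then upstream (a missed cleavage), to at least 7 residues
    if end - start < 7:
        end = min(len(seq), start + 7)
    if end - start < 7:
        start = max(0, end - 7)
    return seq[start:end], start


def simulate_experiment(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth, Dict[str, str]]:
    """Generate PSM, protein and annotation tables with known ground truth.

    Returns ``(psm_table, protein_table, annotation_table, truth,
    protein_sequences)``.  The PSM table follows the header contract of
    :mod:`diglyq.psm`; the protein table carries per-channel reporter S/N
    plus a summed ``intensity`` column consistent with the planted copy
    numbers (exactly, so the proteomic ruler round-trips); the annotation
    table is MitoCarta-style (gene, mitochondrial, subcompartment).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    channels = [f"ch{i+1:02d}_{g}" for i, g in enumerate(config.group_labels)]
    treated = treated_channels(config.group_labels)
    ko = ko_channels(config.group_labels)

    # --- proteins -----------------------------------------------------------
    n_prot = config.n_proteins
    accs = [f"P{i+1:05d}" for i in range(n_prot)]
    genes = [f"GENE{i+1:04d}" for i in range(n_prot)]
    lengths = rng.integers(150, 500, n_prot)
    sequences = {acc: _random_protein(rng, int(l)) for acc, l in zip(accs, lengths)}

    n_mito = int(round(config.fraction_mitochondrial * n_prot))
    mito_idx = rng.choice(n_prot, size=n_mito, replace=False)
    is_mito = np.zeros(n_prot, dtype=bool)
    is_mito[mito_idx] = True
    comp_names = list(SUBCOMPARTMENT_WEIGHTS)
    comp_p = np.array(list(SUBCOMPARTMENT_WEIGHTS.values()))
    compartments = np.where(
        is_mito, rng.choice(comp_names, size=n_prot, p=comp_p / comp_p.sum()), "non-mito"
    )

    # histones for the proteomic ruler; copy numbers pinned so that total
    # histone mass equals DNA mass per cell (the ruler's 1:1 anchor)
    hist_accs = [f"HIST{i+1:02d}" for i in range(config.histone_count)]
    hist_genes = [f"HIST{i+1:02d}" for i in range(config.histone_count)]
    hist_seqs = {acc: _random_protein(rng, int(rng.integers(120, 140))) for acc in hist_accs}
    sequences.update(hist_seqs)
    m_dna = config.ploidy * config.genome_size_bp * MEAN_BASEPAIR_MASS / Avogadro
    hist_mw = np.array([protein_molecular_weight(hist_seqs[a]) for a in hist_accs])
    raw = rng.uniform(0.5, 1.5, config.histone_count)
    hist_copies = raw * (m_dna * Avogadro / (raw * hist_mw).sum())
    other_copies = np.exp(rng.uniform(math.log(1e3), math.log(1e7), n_prot))

    all_accs = accs + hist_accs
    all_genes = genes + hist_genes
    all_copies = np.concatenate([other_copies, hist_copies])
    all_mw = np.array([protein_molecular_weight(sequences[a]) for a in all_accs])
    all_mito = np.concatenate([is_mito, np.zeros(config.histone_count, dtype=bool)])
    all_comp = np.concatenate([compartments, ["non-mito"] * config.histone_count])

    # ruler intensity: proportional to copies * MW (noise-free by design so
    # the ruler inversion is exact; reporter noise lives in the S/N columns)
    intensity = all_copies * all_mw * 1e-6

    # per-channel protein S/N: flat across treatment (the proteome barely
    # moves in this system), log-normal abundance, reporter noise
    prot_base = np.exp(rng.normal(math.log(200), 1.0, len(all_accs)))
    prot_sn = prot_base[:, None] * _lognormal_factor(
        rng, config.reporter_cv, (len(all_accs), config.n_channels)
    )
    protein_table = pd.DataFrame(
        {
            "protein": all_accs,
            "gene": all_genes,
            "molecular_weight": all_mw,
            "intensity": intensity,
        }
    )
    for j, c in enumerate(channels):
        protein_table[c] = prot_sn[:, j]

    annotation_table = pd.DataFrame(
        {
            "gene": all_genes,
            "mitochondrial": all_mito,
            "subcompartment": np.where(all_mito, all_comp, ""),
        }
    )

    # --- sites --------------------------------------------------------------
    n_sites = config.n_sites
    n_resp = int(round(config.fraction_responsive * n_sites))
    mom_accs = [a for a, c in zip(accs, compartments) if c == "MOM"]
    site_rows = []
    used: set = set()

    def pick_site(acc: str) -> Optional[int]:
        seq = sequences[acc]
        ks = [i for i, r in enumerate(seq) if r == "K" and (acc, i) not in used]
        if not ks:
            return None
        return int(rng.choice(ks))

    # responsive sites planted on MOM proteins (falling back to any protein
    # if the MOM pool is exhausted)
    for i in range(n_sites):
        responsive = i < n_resp
        pool = mom_accs if responsive and mom_accs else accs
        acc = None
        for _ in range(50):
            cand = str(rng.choice(pool))
            s = pick_site(cand)
            if s is not None:
                acc, site0 = cand, s
                break
        if acc is None:
            acc = str(rng.choice(accs))
            site0 = pick_site(acc)
            if site0 is None:
                continue
        used.add((acc, site0))
        lo, hi = config.effect_log2_range
        effect = float(rng.uniform(lo, hi)) if responsive else 0.0
        gdep = bool(rng.random() < config.fraction_genotype_dependent) if responsive else False
        site_rows.append(
            {
                "protein": acc,
                "site": site0 + 1,
                "true_log2_effect": effect,
                "responsive": responsive,
                "genotype_dependent": gdep,
            }
        )
    truth_sites = pd.DataFrame(site_rows)

    # --- PSMs ---------------------------------------------------------------
    psm_rows = []
    site_base = np.exp(rng.normal(math.log(150), 0.8, len(truth_sites)))
    for i, row in truth_sites.iterrows():
        acc = row["protein"]
        seq = sequences[acc]
        site0 = int(row["site"]) - 1
        peptide, start = _tryptic_window(seq, site0, rng)
        pos_in_pep = site0 - start + 1
        # channel-level true abundance: effect multiplies AO channels, and is
        # silenced on KO channels for genotype-dependent sites
        mult = np.ones(config.n_channels)
        if row["responsive"]:
            active = treated & ~(ko if row["genotype_dependent"] else np.zeros_like(ko))
            mult[active] = 2.0 ** row["true_log2_effect"]
        site_channel = site_base[i] * mult
        n_psms = 1 + int(rng.poisson(0.7))
        shares = rng.dirichlet(np.ones(n_psms) * 5)
        for k in range(n_psms):
            sn = site_channel * shares[k] * n_psms * _lognormal_factor(
                rng, config.reporter_cv, config.n_channels
            )
            summed = float(sn.sum())
            iso = (
                float(rng.uniform(0.75, 1.0))
                if rng.random() > 0.08
                else float(rng.uniform(0.3, 0.7))
            )
            ascore_val = (
                float(20 + rng.exponential(15))
                if rng.random() > 0.1
                else float(rng.uniform(0, 13))
            )
            rec = {
                "peptide": peptide,
                "proteins": acc,
                "mods": f"{pos_in_pep}:glygly",
                "charge": int(rng.choice([2, 3, 4, 5, 6, 7], p=[0.05, 0.45, 0.3, 0.12, 0.05, 0.03])),
                "score": float(rng.normal(4.0, 1.0)),
                "is_decoy": False,
                "isolation_specificity": iso,
                "summed_sn": summed,
                "ms1_intensity": summed * 1e4 * float(_lognormal_factor(rng, config.reporter_cv, ())),
                "has_ms3": bool(rng.random() > 0.03),
                "ascore": ascore_val,
            }
            for c, v in zip(channels, sn):
                rec[c] = float(v)
            psm_rows.append(rec)

    # decoys: reversed-database style records from a shifted score null
    n_decoys = int(round(config.decoy_fraction * len(psm_rows)))
    for d in range(n_decoys):
        peptide = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(8, 20))))
        sn = np.exp(rng.normal(math.log(30), 0.5, config.n_channels))
        rec = {
            "peptide": peptide,
            "proteins": f"DECOY{d+1:05d}",
            "mods": "",
            "charge": int(rng.choice([2, 3, 4, 5])),
            "score": float(rng.normal(2.0, 1.0)),
            "is_decoy": True,
            "isolation_specificity": float(rng.uniform(0.5, 1.0)),
            "summed_sn": float(sn.sum()),
            "ms1_intensity": float(sn.sum() * 1e4),
            "has_ms3": True,
            "ascore": float("nan"),
        }
        for c, v in zip(channels, sn):
            rec[c] = float(v)
        psm_rows.append(rec)

    psm_table = pd.DataFrame(psm_rows)
    gene_of = dict(zip(all_accs, all_genes))
    truth_proteins = pd.DataFrame(
        {
            "protein": all_accs,
            "gene": all_genes,
            "copies": all_copies,
            "mitochondrial": all_mito,
            "subcompartment": all_comp,
        }
    )
    truth_sites = truth_sites.assign(gene=truth_sites["protein"].map(gene_of))
    truth = GroundTruth(
        sites=truth_sites,
        proteins=truth_proteins,
        channels=channels,
        group_labels=list(config.group_labels),
    )
    return psm_table, protein_table, annotation_table, truth, sequences


# --- ortholog pairs ---------------------------------------------------------


def simulate_ortholog_pair(
    length: int,
    identity: float,
    conserved_k_positions: Sequence[int],
    seed: int,
    indels: Optional[Sequence[Tuple[int, int]]] = None,
) -> Tuple[str, str, Dict[int, Optional[int]]]:
    """Generate an ortholog sequence pair with a recorded site correspondence.

    ``seq_a`` is random with lysines forced at ``conserved_k_positions``
    (1-based); ``seq_b`` differs by substitutions (rate ``1 - identity`` at
    non-conserved positions) and short indels.  ``indels`` is a list of
    ``(position_in_a, length)``: positive length inserts residues into b
    after that position, negative deletes that many a-residues starting
    after it.  When omitted, 0-2 random short indels are placed for
    identity < 1.  The returned mapping sends each 1-based a-position to
    its b-position (``None`` for deleted residues) — the correspondence
    actually used in generation.
    """
    if not 0 < identity <= 1:
        raise ValueError(f"identity must be in (0, 1], got {identity}")
    for p in conserved_k_positions:
        if not 1 <= p <= length:
            raise ValueError(f"conserved position {p} outside sequence length {length}")
    rng = np.random.default_rng(seed)
    conserved = set(conserved_k_positions)
    a = [str(rng.choice(list(AMINO_ACIDS))) for _ in range(length)]
    for p in conserved:
        a[p - 1] = "K"
    seq_a = "".join(a)

    if identity == 1.0:
        return seq_a, seq_a, {i: i for i in range(1, length + 1)}

    if indels is None:
        n_ind = int(rng.integers(0, 3))
        indels = []
        for _ in range(n_ind):
            for _ in range(20):
                pos = int(rng.integers(1, length))
                ln = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
                dele = set(range(pos + 1, pos + 1 - ln)) if ln < 0 else set()
                if not (dele & conserved):
                    indels.append((pos, ln))
                    break
    deletions: set = set()
    insertions: Dict[int, int] = {}
    for pos, ln in indels:
        if ln > 0:
            insertions[pos] = insertions.get(pos, 0) + ln
        else:
            span = set(range(pos + 1, pos + 1 - ln))
            if span & conserved:
                raise ValueError("deletion overlaps a conserved lysine position")
            deletions |= span

    sub_rate = 1 - identity
    alphabet = list(AMINO_ACIDS.replace("K", ""))
    b_chars: List[str] = []
    mapping: Dict[int, Optional[int]] = {}
    bpos = 0
    for i in range(1, length + 1):
        if i - 1 in insertions:  # insertion after position i-1 (0 = N-terminal)
            for _ in range(insertions[i - 1]):
                b_chars.append(str(rng.choice(alphabet)))
                bpos += 1
        if i in deletions:
            mapping[i] = None
            continue
        res = seq_a[i - 1]
        if i not in conserved and rng.random() < sub_rate:
            res = str(rng.choice([r for r in alphabet if r != res]))
        b_chars.append(res)
        bpos += 1
        mapping[i] = bpos
    if length in insertions:
        for _ in range(insertions[length]):
            b_chars.append(str(rng.choice(alphabet)))
    seq_b = "".join(b_chars)
    return seq_a, seq_b, mapping


# --- AQUA -------------------------------------------------------------------


def simulate_aqua(
    true_fmol_by_linkage: Mapping[str, float],
    true_phospho_fraction: float,
    heavy_spike_fmol: float,
    noise_cv: float,
    seed: int,
    n_replicates: int = 3,
    condition: str = "AO",
    true_total_ub_fmol: Optional[float] = None,
    n_total_loci: int = 3,
) -> pd.DataFrame:
    """Generate an AQUA/PRM measurement table with planted amounts.

    One row per locus peptide per replicate: chain-linkage peptides from
    ``true_fmol_by_linkage``, ``n_total_loci`` total-ubiquitin locus
    peptides at ``true_total_ub_fmol`` (default: sum of linkage amounts),
    and the Ser65 phospho/unmodified pair partitioning the total by
    ``true_phospho_fraction``.  Light area = heavy area x (fmol / spike) x
    multiplicative log-normal noise (mean 1, CV ``noise_cv``).
    """
    if heavy_spike_fmol <= 0:
        raise ValueError(f"heavy spike must be > 0, got {heavy_spike_fmol}")
    if not 0 <= true_phospho_fraction <= 1:
        raise ValueError(f"phospho fraction must be in [0, 1], got {true_phospho_fraction}")
    for locus, fmol in true_fmol_by_linkage.items():
        if fmol < 0:
            raise ValueError(f"negative amount for locus {locus}: {fmol}")
    rng = np.random.default_rng(seed)
    total = (
        true_total_ub_fmol
        if true_total_ub_fmol is not None
        else float(sum(true_fmol_by_linkage.values()))
    )
    loci: List[Tuple[str, float]] = list(true_fmol_by_linkage.items())
    loci += [(f"total_{i+1}", total) for i in range(n_total_loci)]
    loci.append(("S65_phospho", total * true_phospho_fraction))
    loci.append(("S65_unmodified", total * (1 - true_phospho_fraction)))
    rows = []
    for rep in range(1, n_replicates + 1):
        for locus, fmol in loci:
            heavy = float(np.exp(rng.normal(math.log(1e7), 0.3)))
            noise = float(_lognormal_factor(rng, noise_cv, ()))
            rows.append(
                {
                    "peptide": f"pep_{locus}",
                    "locus": locus,
                    "light_area": heavy * (fmol / heavy_spike_fmol) * noise,
                    "heavy_area": heavy,
                    "spike_fmol": heavy_spike_fmol,
                    "replicate": rep,
                    "condition": condition,
                }
            )
    return pd.DataFrame(rows)
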