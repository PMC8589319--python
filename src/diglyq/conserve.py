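"""Cross-species conservation of ubiquitylation sites.

Sites regulated in two datasets (e.g. mouse cortical neurons and human
iNeurons) are matched by mapping residue positions through a global
pairwise alignment of the ortholog sequences; a site is conserved when the
aligned positions correspond and both residues are lysine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class Alignment:
    """A global pairwise alignment: gapped sequences plus scoring context."""

    gapped_a: str
    gapped_b: str
    score: float
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped sequences must have equal length")

    @property
    def seq_a(self) -> str:
        return self.gapped_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.gapped_b.replace("-", "")

    def reversed(self) -> "Alignment":
        return Alignment(
            self.gapped_b, self.gapped_a, self.score, self.matrix_name,
            self.gap_open, self.gap_extend,
        )


@dataclass
class SiteMapping:
    source_position: int
    target_position: Optional[int]
    source_residue: str
    target_residue: Optional[str]

    @property
    def conserved_lysine(self) -> bool:
        return self.source_residue == "K" and self.target_residue == "K"


def _load_matrix(name: str) -> substitution_matrices.Array:
    m = substitution_matrices.load(name)
    # unknown residue X contributes nothing to the score
    if "X" in m.alphabet:
        for r in m.alphabet:
            m["X", r] = 0.0
            m[r, "X"] = 0.0
    return m


def global_align(
    seq_a: str,
    seq_b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Alignment:
    """Optimal global alignment with affine gap penalties.

    A gap of length L costs ``gap_open + gap_extend * L``; end gaps are
    penalized.  Substitution scores come from the named matrix (default
    BLOSUM62) with any pair involving X scored 0.  Tie-breaking is
    deterministic: among co-optimal tracebacks the first alignment in the
    aligner's canonical order is returned.
    """
    for name, seq in (("a", seq_a), ("b", seq_b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"illegal residue(s) in sequence {name}: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _load_matrix(matrix_name)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    return Alignment(aln[0], aln[1], float(aln.score), matrix_name, gap_open, gap_extend)


def map_site(alignment: Alignment, position_in_a: int) -> SiteMapping:
    """Map a 1-based residue position of sequence a into sequence b.

    Walks the alignment columns; if the source residue is aligned to a gap
    the target is ``None``.
    """
    if position_in_a < 1 or position_in_a > len(alignment.seq_a):
        raise ValueError(
            f"position {position_in_a} outside sequence a (length {len(alignment.seq_a)})"
        )
    count_a = count_b = 0
    for ca, cb in zip(alignment.gapped_a, alignment.gapped_b):
        if ca != "-":
            count_a += 1
        if cb != "-":
            count_b += 1
        if ca != "-" and count_a == position_in_a:
            if cb == "-":
                return SiteMapping(position_in_a, None, ca, None)
            return SiteMapping(position_in_a, count_b, ca, cb)
    raise AssertionError("unreachable: position not found in alignment walk")


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    seq_a: Optional[str] = None
    seq_b: Optional[str] = None


@dataclass
class ConservationThresholds:
    """Inclusion thresholds for regulated sites; both are strict."""

    min_log2: float = 1.0
    max_p: float = 0.05


@dataclass
class OverlapResult:
    a_only_sites: List[Tuple[str, int]]
    shared_sites: List[Tuple[str, int, str, int]]  # gene_a, pos_a, gene_b, pos_b
    b_only_sites: List[Tuple[str, int]]
    a_only_proteins: List[str]
    shared_proteins: List[Tuple[str, str]]
    b_only_proteins: List[str]
    #: ortholog pairs regulated in both species but with no shared site
    shared_protein_distinct_sites: List[Tuple[str, str]] = field(default_factory=list)
    unmappable: List[str] = field(default_factory=list)

    def venn(self) -> Dict[str, Dict[str, int]]:
        return {
            "sites": {
                "a_only": len(self.a_only_sites),
                "shared": len(self.shared_sites),
                "b_only": len(self.b_only_sites),
            },
            "proteins": {
                "a_only": len(self.a_only_proteins),
                "shared": len(self.shared_proteins),
                "b_only": len(self.b_only_proteins),
                "shared_distinct_sites": len(self.shared_protein_distinct_sites),
            },
        }


def _passing(sites: pd.DataFrame, thr: ConservationThresholds) -> pd.DataFrame:
    return sites[(sites["log2_ratio"] > thr.min_log2) & (sites["p"] < thr.max_p)]


def conserved_overlap(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    orthologs: List[OrthologPair],
    thresholds: ConservationThresholds | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> OverlapResult:
    """Venn decomposition of regulated sites across two species.

    Both site sets (columns ``gene``, ``position``, ``log2_ratio``, ``p``)
    are filtered by the strict thresholds (log2 ratio > 1.0, p < 0.05 by
    default).  A site is shared when its position, mapped through the
    global alignment of the ortholog pair, is itself a passing site in the
    other set and both aligned residues are lysine.  Ortholog pairs lacking
    a sequence on either side are reported in ``unmappable`` when they are
    shared candidates (passing sites in both species), never silently
    dropped.
    """
    thr = thresholds or ConservationThresholds()
    pa = _passing(set_a, thr)
    pb = _passing(set_b, thr)
    a_sites = {(g, int(p)) for g, p in zip(pa["gene"], pa["position"])}
    b_sites = {(g, int(p)) for g, p in zip(pb["gene"], pb["position"])}
    a_genes = {g for g, _ in a_sites}
    b_genes = {g for g, _ in b_sites}

    by_gene_a = {o.gene_a: o for o in orthologs}
    shared: List[Tuple[str, int, str, int]] = []
    unmappable: List[str] = []
    aln_cache: Dict[str, Alignment] = {}
    for gene_a, pos_a in sorted(a_sites):
        pair = by_gene_a.get(gene_a)
        if pair is None or pair.gene_b not in b_genes:
            continue
        if not pair.seq_a or not pair.seq_b:
            if gene_a not in unmappable:
                unmappable.append(gene_a)
            continue
        if gene_a not in aln_cache:
            aln_cache[gene_a] = global_align(
                pair.seq_a, pair.seq_b, gap_open=gap_open, gap_extend=gap_extend
            )
        mapping = map_site(aln_cache[gene_a], pos_a)
        if (
            mapping.target_position is not None
            and (pair.gene_b, mapping.target_position) in b_sites
            and mapping.conserved_lysine
        ):
            shared.append((gene_a, pos_a, pair.gene_b, mapping.target_position))

    shared_a = {(g, p) for g, p, _, _ in shared}
    shared_b = {(g, p) for _, _, g, p in shared}
    a_only = sorted(a_sites - shared_a)
    b_only = sorted(b_sites - shared_b)
    shared_genes = sorted({(ga, gb) for ga, _, gb, _ in shared})
    shared_genes_a = {ga for ga, _ in shared_genes}
    shared_genes_b = {gb for _, gb in shared_genes}
    distinct = sorted(
        (o.gene_a, o.gene_b)
        for o in orthologs
        if o.gene_a in a_genes
        and o.gene_b in b_genes
        and o.gene_a not in shared_genes_a
        and o.gene_a not in unmappable
    )
    mapped_b = {o.gene_b: o.gene_a for o in orthologs}
    return OverlapResult(
        a_only_sites=a_only,
        shared_sites=sorted(shared),
        b_only_sites=b_only,
        a_only_proteins=sorted(a_genes - shared_genes_a),
        shared_proteins=shared_genes,
        b_only_proteins=sorted(b_genes - shared_genes_b),
        shared_protein_distinct_sites=distinct,
        unmappable=unmappable,
    )
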