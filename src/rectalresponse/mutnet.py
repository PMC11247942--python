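"""Gene-level mutation comparison and co-occurrence / exclusivity networks.

Group-stratified mutation frequencies with Fisher exact contrasts,
pairwise co-occurrence and mutual-exclusivity calls across the top
mutated genes, the CR-/ICR-specific classification of externally
supplied significance q-values, and the DNA-repair panel fraction
comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import statcore
from .statcore import ContingencyTable2x2, TestResult
from .cohort_io import MutationMatrix

__all__ = [
    "GeneFrequencyRow",
    "GenePairInteraction",
    "GroupSpecificCall",
    "DEFAULT_REPAIR_PANEL",
    "compare_gene_frequencies",
    "select_candidate_genes",
    "pairwise_interactions",
    "count_significant_pairs",
    "classify_group_specific",
    "repair_panel_fraction",
]

logger = logging.getLogger(__name__)

#: DNA-repair genes named in the main-text comparison (MMR, BER, HR, NER)
DEFAULT_REPAIR_PANEL = ("MSH3", "MLH1", "PMS1", "BRCA1", "BARD1", "POLD1", "POLE")


@dataclass(frozen=True)
class GeneFrequencyRow:
    gene: str
    n_mutated_cr: int
    n_total_cr: int
    n_mutated_icr: int
    n_total_icr: int
    p_value: float
    odds_ratio: float

    @property
    def freq_cr(self) -> float:
        return self.n_mutated_cr / self.n_total_cr

    @property
    def freq_icr(self) -> float:
        return self.n_mutated_icr / self.n_total_icr


@dataclass(frozen=True)
class GenePairInteraction:
    """One unordered gene pair with its joint-mutation 2x2 test.

    ``gene_a < gene_b`` lexicographically; the table counts samples
    mutated in both / a only / b only / neither.
    """

    gene_a: str
    gene_b: str
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    label: str  # co-occurring | mutually exclusive | none

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValueError("pair must be in canonical (sorted) order")


@dataclass(frozen=True)
class GroupSpecificCall:
    gene: str
    q_cr: float
    q_icr: float
    category: str  # CR-specific | ICR-specific | shared | neither


def compare_gene_frequencies(matrix: MutationMatrix, group,
                             min_freq: float = 0.05,
                             treated_label: str = "CR") -> list[GeneFrequencyRow]:
    """Fisher exact CR-vs-ICR contrast for genes above a frequency floor.

    A gene is tested when its mutation frequency exceeds ``min_freq``
    in at least one response group.  Rows are sorted by p-value, then
    gene symbol.
    """
    g = np.asarray(group)
    cr = g == treated_label
    n_cr, n_icr = int(cr.sum()), int((~cr).sum())
    if n_cr == 0 or n_icr == 0:
        raise ValueError("both response groups must be non-empty")
    rows = []
    for j, gene in enumerate(matrix.gene_ids):
        col = matrix.incidence[:, j]
        m_cr = int(col[cr].sum())
        m_icr = int(col[~cr].sum())
        if m_cr / n_cr <= min_freq and m_icr / n_icr <= min_freq:
            continue
        res = statcore.fisher_exact_2x2(ContingencyTable2x2(
            m_cr, n_cr - m_cr, m_icr, n_icr - m_icr))
        rows.append(GeneFrequencyRow(gene, m_cr, n_cr, m_icr, n_icr,
                                     res.p_value, res.estimate))
    rows.sort(key=lambda r: (r.p_value, r.gene))
    return rows


def select_candidate_genes(matrix: MutationMatrix, min_freq: float = 0.05,
                           top: int = 25) -> list[str]:
    """Genes above the frequency floor, capped at the most frequent ``top``.

    Matrix gene order is already by descending frequency, so the cap is
    a prefix.
    """
    n = len(matrix.sample_ids)
    freqs = matrix.incidence.mean(axis=0)
    candidates = [g for g, f in zip(matrix.gene_ids, freqs) if f > min_freq]
    return candidates[:top]


def pair_table(matrix: MutationMatrix, gene_a: str, gene_b: str) -> ContingencyTable2x2:
    """Both / a-only / b-only / neither counts across samples."""
    xa = matrix.gene_column(gene_a).astype(bool)
    xb = matrix.gene_column(gene_b).astype(bool)
    return ContingencyTable2x2(int((xa & xb).sum()), int((xa & ~xb).sum()),
                               int((~xa & xb).sum()), int((~xa & ~xb).sum()))


def pairwise_interactions(matrix: MutationMatrix, genes: list[str] | None = None,
                          alpha: float = 0.05,
                          pairs: list[tuple[str, str]] | None = None,
                          adjust: bool = False) -> list[GenePairInteraction]:
    """Fisher exact co-occurrence / exclusivity test for gene pairs.

    Tests every unordered pair of ``genes`` (or the explicit ``pairs``),
    labelling a pair co-occurring when p < alpha with OR > 1 and
    mutually exclusive when p < alpha with OR < 1.  ``adjust`` switches
    the significance rule to Benjamini-Hochberg q < alpha; the default
    mirrors the raw-p convention of maftools-style interaction plots.
    """
    if pairs is None:
        if genes is None:
            genes = list(matrix.gene_ids)
        if len(genes) < 2:
            raise ValueError("need at least 2 genes for pairwise analysis")
        pairs = list(itertools.combinations(sorted(genes), 2))
    results = []
    for a, b in pairs:
        a, b = sorted((a, b))
        t = pair_table(matrix, a, b)
        res = statcore.fisher_exact_2x2(t)
        results.append((a, b, t, res))
    ps = np.array([r[3].p_value for r in results])
    sig_ps = statcore.bh_adjust(ps) if adjust else ps
    out = []
    for (a, b, t, res), sp in zip(results, sig_ps):
        if sp < alpha and res.estimate > 1:
            label = "co-occurring"
        elif sp < alpha and res.estimate < 1:
            label = "mutually exclusive"
        else:
            label = "none"
        out.append(GenePairInteraction(a, b, t, res.estimate, res.p_value, label))
    return out


def count_significant_pairs(interactions: list[GenePairInteraction],
                            label: str) -> int:
    """Number of pairs carrying the given interaction label."""
    return sum(1 for it in interactions if it.label == label)


def classify_group_specific(q_cr: dict[str, float], q_icr: dict[str, float],
                            alpha: float = 0.05) -> list[GroupSpecificCall]:
    """Partition genes by group-specific significance of external q-values.

    CR-specific: q < alpha in CR and q > alpha in ICR; ICR-specific by
    symmetry; shared when both are significant; neither otherwise
    (boundary q == alpha falls into neither — inequalities are strict).
    Genes absent from one table are treated as q = 1 there.
    """
    genes = sorted(set(q_cr) | set(q_icr))
    out = []
    for gene in genes:
        qc = float(q_cr.get(gene, 1.0))
        qi = float(q_icr.get(gene, 1.0))
        for q in (qc, qi):
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"q-value outside [0,1] for {gene}: {q}")
        if qc < alpha and qi > alpha:
            cat = "CR-specific"
        elif qi < alpha and qc > alpha:
            cat = "ICR-specific"
        elif qc < alpha and qi < alpha:
            cat = "shared"
        else:
            cat = "neither"
        out.append(GroupSpecificCall(gene, qc, qi, cat))
    return out


def repair_panel_fraction(matrix: MutationMatrix, group, panel=DEFAULT_REPAIR_PANEL,
                          treated_label: str = "CR"):
    """Per-group fraction of samples with >= 1 mutated panel gene, plus
    a continuity-corrected chi-squared test on the induced 2x2.

    Returns ``(fraction_cr, fraction_icr, TestResult | None)``; the
    test is None when the induced table is degenerate (e.g. the panel
    does not overlap the matrix genes).
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    present = [g for g in panel if g in matrix.gene_ids]
    if not present:
        logger.warning("panel has no overlap with matrix genes")
    g = np.asarray(group)
    cr = g == treated_label
    if present:
        cols = np.column_stack([matrix.gene_column(p) for p in present])
        hit = cols.any(axis=1)
    else:
        hit = np.zeros(len(matrix.sample_ids), dtype=bool)
    n_cr, n_icr = int(cr.sum()), int((~cr).sum())
    h_cr, h_icr = int(hit[cr].sum()), int(hit[~cr].sum())
    frac_cr = h_cr / n_cr if n_cr else 0.0
    frac_icr = h_icr / n_icr if n_icr else 0.0
    try:
        res = statcore.chi2_yates(ContingencyTable2x2(
            h_cr, n_cr - h_cr, h_icr, n_icr - h_icr))
    except (statcore.DegenerateInputError, ValueError):
        res = None
    return frac_cr, frac_icr, res


def interactions_to_frame(interactions: list[GenePairInteraction]) -> pd.DataFrame:
    """Flatten interaction calls to the TSV layout used by the CLI."""
    return pd.DataFrame([{
        "gene_a": it.gene_a, "gene_b": it.gene_b,
        "both": it.table.a, "a_only": it.table.b,
        "b_only": it.table.c, "neither": it.table.d,
        "odds_ratio": it.odds_ratio, "p_value": it.p_value, "label": it.label,
    } for it in interactions])
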