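"""Tumor-microenvironment target profiling from labeled scRNA-seq data.

"Targeting" is operationalized purely as target-gene expression by cell
compartment: for each cell type, the mean (optionally depth-normalized,
log1p) expression of each of a drug's target genes and the fraction of
cells expressing it, summarized into a per-type set score. Comparing the
two profiles of a doublet shows whether its drugs hit different
compartments (e.g. lymphoid vs myeloid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .cohort_io import DrugTargetLibrary, SingleCellMatrix

log = logging.getLogger(__name__)


@dataclass
class TMEProfile:
    drug_name: str
    cell_types: list[str]
    per_gene: pd.DataFrame   # index (cell_type, gene): mean_expr, frac_expressing, n_cells
    set_score: pd.Series     # per cell type: mean over genes_used of mean_expr
    genes_used: list[str]
    genes_absent: list[str]
    available: bool = True
    flags: list[str] = field(default_factory=list)


def _normalized_dense(sc: SingleCellMatrix) -> np.ndarray:
    """Per-cell median-depth scaling followed by log1p."""
    X = sc.values.toarray() if sparse.issparse(sc.values) else np.asarray(
        sc.values, dtype=float)
    X = X.astype(float)
    depth = X.sum(axis=1)
    depth[depth == 0] = 1.0
    target = np.median(depth)
    return np.log1p(X * (target / depth)[:, None])


def profile_drug_tme(
    drug: str,
    sc: SingleCellMatrix,
    library: DrugTargetLibrary,
    normalize: bool = True,
) -> TMEProfile:
    """Per-cell-type expression profile of one drug's target genes."""
    targets = {g.upper() for g in library.targets(drug)}
    gene_index = {}
    for j, g in enumerate(sc.genes):
        gene_index.setdefault(g, []).append(j)
    dup = [g for g, idx in gene_index.items() if len(idx) > 1]
    if dup:
        log.warning("scRNA-seq matrix: %d duplicate gene symbols averaged", len(dup))

    present = sorted(targets & set(gene_index))
    absent = sorted(targets - set(gene_index))
    cell_types = sorted(sc.cell_type.unique())
    if not present:
        return TMEProfile(drug, cell_types, pd.DataFrame(), pd.Series(dtype=float),
                          [], absent, available=False, flags=["no_targets_in_matrix"])

    X = _normalized_dense(sc) if normalize else (
        sc.values.toarray() if sparse.issparse(sc.values)
        else np.asarray(sc.values, dtype=float))
    # collapse duplicate gene columns by mean
    cols = np.column_stack([X[:, gene_index[g]].mean(axis=1) for g in present])

    labels = sc.cell_type.to_numpy()
    rows = []
    set_scores = {}
    for ct in cell_types:
        mask = labels == ct
        block = cols[mask]
        means = block.mean(axis=0)
        fracs = (block > 0).mean(axis=0)
        for g, m, f in zip(present, means, fracs):
            rows.append({"cell_type": ct, "gene": g, "mean_expr": float(m),
                         "frac_expressing": float(f), "n_cells": int(mask.sum())})
        set_scores[ct] = float(means.mean())
    per_gene = pd.DataFrame(rows).set_index(["cell_type", "gene"])
    return TMEProfile(drug, cell_types, per_gene,
                      pd.Series(set_scores).sort_index(), present, absent)


def compare_doublet_tme(
    drug1: str,
    drug2: str,
    sc: SingleCellMatrix,
    library: DrugTargetLibrary,
    normalize: bool = True,
) -> tuple[TMEProfile, TMEProfile, float]:
    """Both profiles plus a divergence score in [0, 1].

    Divergence = 1 - cosine similarity of the two set-score vectors over
    shared cell types (0: identical compartment profile; 1: orthogonal).
    """
    p1 = profile_drug_tme(drug1, sc, library, normalize)
    p2 = profile_drug_tme(drug2, sc, library, normalize)
    if not (p1.available and p2.available):
        raise ValueError("both drugs must profile successfully")
    shared = sorted(set(p1.set_score.index) & set(p2.set_score.index))
    v1 = p1.set_score[shared].to_numpy()
    v2 = p2.set_score[shared].to_numpy()
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return p1, p2, float("nan")
    cos = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    return p1, p2, 1.0 - cos


def tme_heatmap_table(profiles: list[TMEProfile]) -> pd.DataFrame:
    """Long-form (drug, cell_type, gene, mean_expr, frac_expressing)."""
    rows = []
    for p in profiles:
        if not p.available:
            continue
        for (ct, g), r in p.per_gene.iterrows():
            rows.append({"drug": p.drug_name, "cell_type": ct, "gene": g,
                         "mean_expr": r["mean_expr"],
                         "frac_expressing": r["frac_expressing"]})
    return pd.DataFrame(rows)


def tme_violin_table(drug: str, sc: SingleCellMatrix,
                     library: DrugTargetLibrary,
                     normalize: bool = True) -> pd.DataFrame:
    """Per-cell set-level score (drug, cell_type, cell_barcode, score)."""
    targets = {g.upper() for g in library.targets(drug)}
    present_idx = [j for j, g in enumerate(sc.genes) if g in targets]
    if not present_idx:
        return pd.DataFrame(columns=["drug", "cell_type", "cell_barcode", "score"])
    X = _normalized_dense(sc) if normalize else (
        sc.values.toarray() if sparse.issparse(sc.values)
        else np.asarray(sc.values, dtype=float))
    score = X[:, present_idx].mean(axis=1)
    return pd.DataFrame({
        "drug": drug,
        "cell_type": sc.cell_type.to_numpy(),
        "cell_barcode": sc.cells,
        "score": score,
    })
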