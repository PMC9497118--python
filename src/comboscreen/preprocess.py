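"""Cross-cohort batch adjustment and per-drug gene-set coding.

Two summaries feed every downstream survival model:

* the binary mutation indicator — 1 for a patient iff at least one of the
  drug's target genes carries a protein-altering somatic mutation;
* the PC1 score — the first principal component of the (per-gene centered)
  expression of the drug's target genes, a one-dimensional expression
  summary per patient.

Batch adjustment is a per-gene location-scale correction to the pooled
reference: each cohort's gene mean/variance is standardized then rescaled
to the pooled mean/variance. This is the defining mean/variance-equalizing
core of the classic two-batch correction, without empirical-Bayes
shrinkage of the batch parameters — with two large batches and no model
covariates, shrinkage is a second-order refinement (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortBundle, CohortValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Batch adjustment
# ---------------------------------------------------------------------------

def batch_adjust(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Location-scale batch adjustment of two expression matrices.

    Both matrices are restricted to the shared gene universe (dropped counts
    logged). Per shared gene g and cohort c: values are standardized by the
    cohort's mean/sd and rescaled to the pooled gene mean/sd, so that after
    adjustment every gene has identical mean and variance in both cohorts.
    Genes with zero variance in either cohort are passed through centered to
    the pooled mean only, with a warning.
    """
    for nm, e in (("first", expr_a), ("second", expr_b)):
        if e.shape[1] < 2:
            raise CohortValidationError(
                f"batch adjustment needs >=2 patients in the {nm} cohort")
    shared = expr_a.index.intersection(expr_b.index)
    if len(shared) == 0:
        raise CohortValidationError("no shared genes between cohorts")
    dropped = (len(expr_a) - len(shared)) + (len(expr_b) - len(shared))
    if dropped:
        log.info("batch_adjust: %d non-shared gene rows dropped", dropped)
    a = expr_a.loc[shared].to_numpy(dtype=float)
    b = expr_b.loc[shared].to_numpy(dtype=float)

    # pooled reference: grand mean, and the WITHIN-cohort pooled variance —
    # the raw concatenated variance would absorb the batch shift itself
    na, nb = a.shape[1], b.shape[1]
    mu = (a.sum(axis=1) + b.sum(axis=1)) / (na + nb)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sd = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))

    out = []
    degenerate = np.zeros(len(shared), dtype=bool)
    for x in (a, b):
        m = x.mean(axis=1, keepdims=True)
        s = x.std(axis=1, ddof=1, keepdims=True)
        bad = (s[:, 0] == 0.0)
        degenerate |= bad
        s_safe = np.where(s == 0.0, 1.0, s)
        z = (x - m) / s_safe
        sd_t = np.where(bad, 1.0, sd)[:, None]
        adj = z * sd_t + mu[:, None]
        out.append(adj)
    # degenerate genes: center only (cohort mean -> pooled mean), no rescale
    if degenerate.any():
        log.warning("batch_adjust: %d zero-variance genes centered only",
                    int(degenerate.sum()))
        for x, adj in zip((a, b), out):
            m = x.mean(axis=1)
            adj[degenerate, :] = (
                x[degenerate, :] - m[degenerate, None] + mu[degenerate, None])
    adj_a = pd.DataFrame(out[0], index=shared, columns=expr_a.columns)
    adj_b = pd.DataFrame(out[1], index=shared, columns=expr_b.columns)
    return adj_a, adj_b


def batch_adjust_bundles(
    bundle_a: CohortBundle, bundle_b: CohortBundle
) -> tuple[CohortBundle, CohortBundle]:
    """Return copies of two cohort bundles with batch-adjusted expression."""
    adj_a, adj_b = batch_adjust(bundle_a.expression, bundle_b.expression)
    out = []
    for bundle, adj in ((bundle_a, adj_a), (bundle_b, adj_b)):
        out.append(CohortBundle(bundle.name, bundle.clinical,
                                bundle.mutations, adj))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Gene-set coding
# ---------------------------------------------------------------------------

@dataclass
class IndicatorResult:
    """Per-patient 0/1 mutation indicator for one target-gene set."""

    values: pd.Series | None      # indexed by patient; None when unavailable
    genes_used: list[str]
    genes_absent: list[str]
    available: bool
    degenerate: bool = False      # constant vector -> model not estimable

    @property
    def usable(self) -> bool:
        return self.available and not self.degenerate


@dataclass
class Pc1Result:
    """PC1 expression summary of one target-gene set."""

    scores: pd.Series | None      # per patient; None when unavailable
    loadings: pd.Series | None    # per gene, unit norm
    variance_fraction: float
    genes_used: list[str]
    genes_absent: list[str]
    available: bool


@dataclass
class TherapySetSummary:
    """Mutation indicator + PC1 summary for one drug in one cohort."""

    drug_name: str
    cohort: str
    mut: IndicatorResult
    pc1: Pc1Result
    flags: list[str] = field(default_factory=list)


def mutation_indicator(
    bundle: CohortBundle, target_genes: frozenset[str] | set[str]
) -> IndicatorResult:
    """Per-patient indicator: 1 iff any present target gene is mutated.

    Target genes absent from the mutation matrix are ignored (recorded in
    ``genes_absent``); a set with zero present genes yields a flagged
    unavailable result rather than an error, since public drug libraries
    routinely list symbols absent from a given cohort's matrix.
    """
    targets = {g.upper() for g in target_genes}
    present = sorted(targets & set(bundle.mutations.index))
    absent = sorted(targets - set(present))
    if not present:
        return IndicatorResult(None, [], absent, available=False)
    vec = (bundle.mutations.loc[present].to_numpy().any(axis=0)).astype(np.int8)
    series = pd.Series(vec, index=bundle.patients)
    degenerate = bool(series.nunique() == 1)
    return IndicatorResult(series, present, absent, available=True,
                           degenerate=degenerate)


def pc1_summarize(
    expression: pd.DataFrame, target_genes: frozenset[str] | set[str]
) -> Pc1Result:
    """First principal component of a target-gene set's expression.

    Genes are mean-centered (not variance-scaled); PC1 is extracted by SVD
    of the centered genes x patients block. Sign convention: loadings are
    flipped so their sum is positive (ties on exactly zero: the loading of
    the alphabetically first gene is made non-negative), making outputs
    reproducible — the sign is statistically arbitrary and two-sided tests
    are invariant to it. Single-gene sets return the centered gene itself
    with loading +1 and variance fraction 1.
    """
    targets = {g.upper() for g in target_genes}
    present = sorted(targets & set(expression.index))
    absent = sorted(targets - set(present))
    if not present:
        return Pc1Result(None, None, float("nan"), [], absent, available=False)

    X = expression.loc[present].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    if np.allclose(Xc, 0.0):
        return Pc1Result(None, None, float("nan"), present, absent,
                         available=False)
    if len(present) == 1:
        scores = pd.Series(Xc[0], index=expression.columns)
        loadings = pd.Series([1.0], index=present)
        return Pc1Result(scores, loadings, 1.0, present, absent, available=True)

    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    load = U[:, 0]
    sgn = np.sum(load)
    if sgn < 0 or (sgn == 0 and load[0] < 0):
        load = -load
    scores = load @ Xc
    var_frac = float(S[0] ** 2 / np.sum(S ** 2))
    return Pc1Result(
        pd.Series(scores, index=expression.columns),
        pd.Series(load, index=present),
        var_frac, present, absent, available=True,
    )


def summarize_therapy_set(
    bundle: CohortBundle, drug_name: str,
    target_genes: frozenset[str] | set[str], cohort: str | None = None,
) -> TherapySetSummary:
    """Mutation indicator and PC1 summary for one drug in one cohort."""
    mut = mutation_indicator(bundle, target_genes)
    pc1 = pc1_summarize(bundle.expression, target_genes)
    flags = []
    if not mut.available:
        flags.append("mutation_unavailable")
    elif mut.degenerate:
        flags.append("mutation_degenerate")
    if not pc1.available:
        flags.append("expression_unavailable")
    return TherapySetSummary(drug_name, cohort or bundle.name, mut, pc1, flags)


def export_summary_tables(
    summaries: list[TherapySetSummary],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-form per-patient scores and per-gene PC1 loadings tables."""
    score_rows, loading_rows = [], []
    for s in summaries:
        if s.pc1.available:
            for gene, w in s.pc1.loadings.items():
                loading_rows.append(
                    {"drug": s.drug_name, "cohort": s.cohort,
                     "gene": gene, "loading": w})
        idx = (s.pc1.scores.index if s.pc1.available
               else (s.mut.values.index if s.mut.available else []))
        for pid in idx:
            score_rows.append({
                "drug": s.drug_name, "cohort": s.cohort, "patient_id": pid,
                "mut_indicator": (int(s.mut.values[pid])
                                  if s.mut.available else np.nan),
                "pc1_score": (float(s.pc1.scores[pid])
                              if s.pc1.available else np.nan),
            })
    return pd.DataFrame(score_rows), pd.DataFrame(loading_rows)
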