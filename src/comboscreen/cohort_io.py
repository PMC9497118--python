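"""Cohort and drug-library I/O: read, validate and patient-align the inputs.

The internal data model is deliberately thin: validated pandas objects held
in small dataclasses. Gene symbols are upper-cased on ingestion everywhere —
mismatched case across files is the most common silent join failure.

File formats
------------
* Clinical: TSV with columns patient_id, age, sex, os_time, os_event,
  braf_tx, ipi_nivo_tx, genotype_group.
* Mutations: either a genes x patients 0/1 TSV matrix, or a long TSV with
  columns patient_id, gene, protein_altering (rows with 0 are dropped).
* Expression: genes x patients TSV matrix of log-scale values.
* Drug library: standard GMT (name, description/source tag, genes...).
* scRNA-seq: MatrixMarket matrix + genes TSV + barcodes TSV + labels TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

log = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "patient_id", "age", "sex", "os_time", "os_event",
    "braf_tx", "ipi_nivo_tx", "genotype_group",
]
GENOTYPE_GROUPS = ("BRAF", "NRAS", "TripleWT", "other")
KNOWN_SOURCES = ("dsigdb", "hdac_panel", "checkpoint")


class CohortValidationError(ValueError):
    """Raised when an input file violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """One cohort's clinical, mutation and expression data, sample-aligned.

    Invariant: the clinical index, mutation columns and expression columns
    are the same ordered patient list (the intersection of the raw inputs).
    """

    name: str
    clinical: pd.DataFrame   # indexed by patient_id
    mutations: pd.DataFrame  # genes x patients, values in {0, 1}
    expression: pd.DataFrame  # genes x patients, log-scale reals

    @property
    def patients(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    def validate(self) -> "CohortBundle":
        pts = self.patients
        if len(pts) == 0:
            raise CohortValidationError(f"cohort {self.name}: empty patient set")
        if len(set(pts)) != len(pts):
            raise CohortValidationError(f"cohort {self.name}: duplicated patient ids")
        for nm, cols in (("mutations", self.mutations.columns),
                         ("expression", self.expression.columns)):
            if list(cols) != pts:
                raise CohortValidationError(
                    f"cohort {self.name}: {nm} patients not aligned with clinical")
        vals = self.mutations.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise CohortValidationError(
                f"cohort {self.name}: non-binary mutation entries")
        if self.expression.isna().any().any():
            raise CohortValidationError(
                f"cohort {self.name}: missing expression values")
        if (self.clinical["os_time"] <= 0).any():
            raise CohortValidationError(f"cohort {self.name}: os_time must be > 0")
        for c in ("os_event", "braf_tx", "ipi_nivo_tx"):
            if not self.clinical[c].isin([0, 1]).all():
                raise CohortValidationError(f"cohort {self.name}: {c} must be 0/1")
        bad = ~self.clinical["genotype_group"].isin(GENOTYPE_GROUPS)
        if bad.any():
            raise CohortValidationError(
                f"cohort {self.name}: unknown genotype_group "
                f"{sorted(self.clinical['genotype_group'][bad].unique())}")
        return self

    def subset(self, patients: list[str], name: str | None = None) -> "CohortBundle":
        """Bundle restricted to ``patients`` (order preserved)."""
        return CohortBundle(
            name=name or self.name,
            clinical=self.clinical.loc[patients],
            mutations=self.mutations[patients],
            expression=self.expression[patients],
        )


@dataclass
class DrugEntry:
    targets: frozenset[str]
    source: str = "user"


@dataclass
class DrugTargetLibrary:
    """Named drug -> target-gene-set map with source tags."""

    entries: dict[str, DrugEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, drug: str) -> bool:
        return drug in self.entries

    @property
    def drugs(self) -> list[str]:
        return sorted(self.entries)

    def targets(self, drug: str) -> frozenset[str]:
        return self.entries[drug].targets

    def source_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries.values():
            out[e.source] = out.get(e.source, 0) + 1
        return out


@dataclass
class SingleCellMatrix:
    """Labeled cell x gene expression matrix (raw scale until profiled)."""

    values: sparse.spmatrix | np.ndarray  # cells x genes
    cells: list[str]
    genes: list[str]
    cell_type: pd.Series  # indexed by barcode

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sparse.issparse(v) else np.asarray(v)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"clinical table missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise CohortValidationError(f"duplicated patient id: {dup}")
    df = df.set_index("patient_id")
    df.index = df.index.astype(str)
    return df


def _read_gene_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        log.warning("%s: %d duplicate gene rows collapsed by mean",
                    path, int(df.index.duplicated().sum()))
        df = df.groupby(level=0).mean()
    return df


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read mutation calls as a genes x patients 0/1 matrix.

    Accepts either the matrix layout or a long variant TSV with columns
    (patient_id, gene, protein_altering); long rows with
    protein_altering == 0 are dropped before matrix construction.
    """
    head = pd.read_csv(path, sep="\t", nrows=1)
    if {"patient_id", "gene"} <= set(head.columns):
        long = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "gene": str})
        if "protein_altering" in long.columns:
            long = long[long["protein_altering"].astype(int) == 1]
        long["gene"] = long["gene"].str.upper()
        mat = pd.crosstab(long["gene"], long["patient_id"]).clip(upper=1)
        mat.index.name = None
        mat.columns.name = None
        return mat.astype(np.int8)
    mat = _read_gene_matrix(path)
    vals = mat.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        bad = vals[~np.isin(vals, (0, 1))][0]
        raise CohortValidationError(f"non-binary mutation entry: {bad!r}")
    return mat.astype(np.int8)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = _read_gene_matrix(path)
    if df.isna().any().any():
        raise CohortValidationError(f"{path}: expression contains missing values")
    return df.astype(float)


def read_cohort(
    clinical_path: str | Path,
    mutation_path: str | Path,
    expression_path: str | Path,
    name: str,
) -> CohortBundle:
    """Read one cohort and restrict every table to the patient intersection.

    Patients present in clinical but missing omics are dropped (complete-case
    analysis); counts dropped per table are logged.
    """
    clinical = read_clinical(clinical_path)
    mutations = read_mutations(mutation_path)
    expression = read_expression(expression_path)

    shared = [p for p in clinical.index
              if p in set(mutations.columns) and p in set(expression.columns)]
    if not shared:
        raise CohortValidationError(
            f"cohort {name}: empty patient intersection across tables")
    for nm, cols in (("clinical", clinical.index),
                     ("mutations", mutations.columns),
                     ("expression", expression.columns)):
        dropped = len(cols) - len(shared)
        if dropped:
            log.info("cohort %s: dropped %d patients from %s (not in intersection)",
                     name, dropped, nm)
    bundle = CohortBundle(
        name=name,
        clinical=clinical.loc[shared],
        mutations=mutations[shared],
        expression=expression[shared],
    )
    return bundle.validate()


def read_drug_library(
    gmt_path: str | Path,
    forced_sources: dict[str, str] | None = None,
) -> DrugTargetLibrary:
    """Read a drug -> target-genes library from a GMT file.

    The GMT description field carries the source tag when it matches a known
    tag (dsigdb, hdac_panel, checkpoint); anything else becomes ``user``.
    Duplicate drug names are merged by gene-set union with a warning; entries
    with zero genes are skipped with a warning.
    """
    forced_sources = forced_sources or {}
    entries: dict[str, DrugEntry] = {}
    n_lines = 0
    with open(gmt_path) as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw.strip():
                continue
            n_lines += 1
            fields = raw.split("\t")
            name = fields[0].strip()
            desc = fields[1].strip().lower() if len(fields) > 1 else ""
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                log.warning("drug library: %s has zero genes; skipped", name)
                continue
            source = forced_sources.get(name, desc if desc in KNOWN_SOURCES else "user")
            if name in entries:
                log.warning("drug library: duplicate entry %s merged by union", name)
                prev = entries[name]
                entries[name] = DrugEntry(prev.targets | genes, prev.source)
            else:
                entries[name] = DrugEntry(genes, source)
    if n_lines == 0:
        raise CohortValidationError(f"{gmt_path}: empty drug library")
    if not entries:
        raise CohortValidationError(f"{gmt_path}: no usable drug entries")
    return DrugTargetLibrary(entries)


def read_single_cell(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    labels_path: str | Path,
) -> SingleCellMatrix:
    """Read a labeled scRNA-seq matrix (MTX + gene/barcode/label TSVs).

    The matrix is stored cells x genes (transposed automatically if the MTX
    is genes x cells). Values are left untransformed; normalization is the
    TME profiler's job.
    """
    mat = spio.mmread(str(mtx_path)).tocsr()
    genes = [g.upper() for g in
             pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)]
    cells = list(pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str))
    if mat.shape == (len(genes), len(cells)) and len(genes) != len(cells):
        mat = mat.T.tocsr()
    if mat.shape != (len(cells), len(genes)):
        raise CohortValidationError(
            f"matrix dims {mat.shape} do not match {len(cells)} barcodes x "
            f"{len(genes)} genes")
    labels = pd.read_csv(labels_path, sep="\t", header=None,
                         names=["barcode", "cell_type"], dtype=str)
    labels = labels.set_index("barcode")["cell_type"]
    missing = [b for b in cells if b not in labels.index]
    if missing:
        raise CohortValidationError(
            f"{len(missing)} barcodes missing labels; first 10: {missing[:10]}")
    labels = labels.loc[cells]
    if labels.isna().any() or (labels.str.len() == 0).any():
        raise CohortValidationError("empty cell-type labels found")
    return SingleCellMatrix(values=mat, cells=cells, genes=genes, cell_type=labels)


# ---------------------------------------------------------------------------
# Writers (round-trip support)
# ---------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": outdir / f"{bundle.name}_clinical.tsv",
        "mutations": outdir / f"{bundle.name}_mutations.tsv",
        "expression": outdir / f"{bundle.name}_expression.tsv",
    }
    bundle.clinical.reset_index().to_csv(paths["clinical"], sep="\t", index=False)
    bundle.mutations.to_csv(paths["mutations"], sep="\t")
    bundle.expression.to_csv(paths["expression"], sep="\t")
    return paths


def write_drug_library(library: DrugTargetLibrary, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in library.drugs:
            e = library.entries[name]
            fh.write("\t".join([name, e.source, *sorted(e.targets)]) + "\n")
    return path
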