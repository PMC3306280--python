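"""Reading, validation and preprocessing of expression data and annotation files.

File dialects
-------------
* Expression matrix: TSV, genes in rows, header row of sample ids, first
  column gene identifiers (duplicates allowed until :func:`collapse_probes`),
  cells are log-scale expression values; empty cells or the literal ``NA``
  denote missing data.
* Labels: 2-column TSV ``sample_id<TAB>class`` with class in
  {recurrent, non_recurrent, unlabeled}.
* Gene sets: GMT (``set_id<TAB>description<TAB>member...``).
* Interactions: 2-column TSV of gene-symbol pairs, undirected.
* Catalogs: one gene identifier per line.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECURRENT = "recurrent"
NON_RECURRENT = "non_recurrent"
UNLABELED = "unlabeled"
VALID_LABELS = frozenset({RECURRENT, NON_RECURRENT, UNLABELED})

NA_TOKENS = frozenset({"", "NA"})


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


@dataclass
class ExpressionDataset:
    """Gene x sample log-expression matrix with per-sample class labels.

    ``values`` is a pandas DataFrame indexed by gene id (duplicates allowed
    until probes are collapsed) with sample ids as columns.  ``labels`` maps
    every sample id to one of the three recognised classes; samples absent
    from the label file are ``unlabeled``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        missing = [s for s in self.labels.index if s not in self.values.columns]
        if missing:
            raise ParseError(f"label refers to unknown sample(s): {missing}")
        self.labels = self.labels.reindex(self.values.columns, fill_value=UNLABELED)
        bad = sorted(set(self.labels) - VALID_LABELS)
        if bad:
            raise ParseError(f"unknown class label(s): {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_with_label(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionDataset":
        absent = [s for s in sample_ids if s not in self.values.columns]
        if absent:
            raise KeyError(f"samples not in dataset: {absent}")
        return ExpressionDataset(
            values=self.values[list(sample_ids)].copy(),
            labels=self.labels.loc[list(sample_ids)].copy(),
        )

    def with_labels(self, labels: pd.Series) -> "ExpressionDataset":
        return ExpressionDataset(values=self.values, labels=labels)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics); members unique within a set."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise ParseError(f"gene set {sid!r} is empty")
            if len(set(members)) != len(members):
                raise ParseError(f"gene set {sid!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class InteractionNetwork:
    """Undirected protein-interaction edge set; no self-loops, pairs stored once."""

    edges: set[frozenset]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ParseError(f"invalid edge {set(e)}: need two distinct genes")

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def degree(self, gene: str) -> int:
        return sum(1 for e in self.edges if gene in e)

    def degrees(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.edges:
            for g in e:
                out[g] = out.get(g, 0) + 1
        return out

    def edges_within(self, genes) -> list[tuple[str, str]]:
        """Edges with both endpoints in ``genes``, as sorted tuples."""
        gs = set(genes)
        return sorted(
            tuple(sorted(e)) for e in self.edges if all(g in gs for g in e)
        )


@dataclass
class GeneCatalog:
    """A flat gene list with a role tag (known recurrence genes, mutated genes)."""

    genes: set[str]
    annotation: str = "known_recurrence_gene"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ParseError("gene catalog is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_cell(token: str, path, lineno: int, colname: str) -> float:
    token = token.strip()
    if token in NA_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: non-numeric value {token!r} in column {colname!r}"
        ) from None


def read_expression(path, label_path=None) -> ExpressionDataset:
    """Read a TSV expression matrix plus an optional label file.

    Duplicate gene rows (multiple probes) are retained; call
    :func:`collapse_probes` to average them.  Samples missing from the label
    file are marked ``unlabeled``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header or "\t" not in header:
            raise ParseError(f"{path}:1: malformed header (expected tab-delimited sample ids)")
        cols = header.split("\t")[1:]
        if len(set(cols)) != len(cols):
            raise ParseError(f"{path}:1: duplicate sample ids in header")
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols) + 1} fields, got {len(fields)}"
                )
            genes.append(fields[0])
            rows.append(
                [_parse_cell(tok, path, lineno, cols[j]) for j, tok in enumerate(fields[1:])]
            )
    values = pd.DataFrame(rows, index=genes, columns=cols, dtype=float)
    labels = read_labels(label_path, known_samples=cols) if label_path else pd.Series(
        UNLABELED, index=cols, dtype=object
    )
    return ExpressionDataset(values=values, labels=labels)


def read_labels(path, known_samples=None) -> pd.Series:
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            sample, label = fields
            if label not in VALID_LABELS:
                raise ParseError(f"{path}:{lineno}: unknown class {label!r}")
            if known_samples is not None and sample not in set(known_samples):
                raise ParseError(f"{path}:{lineno}: label refers to unknown sample {sample!r}")
            out[sample] = label
    return pd.Series(out, dtype=object)


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a set are dropped with a warning."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}")
            sid, members = fields[0], [m for m in fields[2:] if m]
            seen: list[str] = []
            for m in members:
                if m in seen:
                    warnings.warn(f"{path}:{lineno}: duplicate member {m!r} in set {sid!r}")
                else:
                    seen.append(m)
            if not seen:
                raise ParseError(f"{path}:{lineno}: gene set {sid!r} has no members")
            sets[sid] = seen
    return GeneSetCollection(sets=sets)


def read_interactions(path) -> InteractionNetwork:
    """Parse a 2-column edge list; self-loops dropped with a warning, duplicates merged."""
    path = Path(path)
    edges: set[frozenset] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 fields, got {len(fields)}")
            a, b = fields[0], fields[1]
            if a == b:
                warnings.warn(f"{path}:{lineno}: self-loop {a!r} dropped")
                continue
            edges.add(frozenset((a, b)))
    return InteractionNetwork(edges=edges)


def read_gene_catalog(path, annotation: str = "known_recurrence_gene") -> GeneCatalog:
    path = Path(path)
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g:
                genes.add(g)
    return GeneCatalog(genes=genes, annotation=annotation)


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

def write_expression(ds: ExpressionDataset, path, label_path=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(ds.sample_ids) + "\n")
        for gene, row in zip(ds.values.index, ds.values.to_numpy()):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")
    if label_path is not None:
        write_labels(ds.labels, label_path)


def write_labels(labels: pd.Series, path) -> None:
    with open(Path(path), "w") as fh:
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


def write_gene_sets(sets: GeneSetCollection, path) -> None:
    with open(Path(path), "w") as fh:
        for sid, members in sets:
            fh.write(sid + "\tna\t" + "\t".join(members) + "\n")


def write_interactions(ppi: InteractionNetwork, path) -> None:
    with open(Path(path), "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in ppi.edges):
            fh.write(f"{a}\t{b}\n")


def write_gene_catalog(catalog: GeneCatalog, path) -> None:
    with open(Path(path), "w") as fh:
        for g in sorted(catalog.genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def collapse_probes(ds: ExpressionDataset) -> ExpressionDataset:
    """Average multiple probe rows of the same gene, per sample over observed entries.

    Idempotent; rows that are already unique pass through unchanged.
    """
    if ds.values.index.is_unique:
        return ExpressionDataset(values=ds.values.copy(), labels=ds.labels.copy())
    collapsed = ds.values.groupby(level=0, sort=False).mean()
    # groupby().mean() skips NaN; an all-NaN position stays NaN for impute_knn
    return ExpressionDataset(values=collapsed, labels=ds.labels.copy())


def impute_knn(ds: ExpressionDataset, k: int = 10) -> ExpressionDataset:
    """Fill missing entries with the mean of the k nearest gene rows.

    Nearness is Euclidean distance over mutually observed sample positions,
    scaled by the fraction observed (nan-Euclidean).  Observed entries are
    left bit-identical.  A gene row with no observed value has no defined
    neighbours and raises ``ValueError``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    mat = ds.values.to_numpy(dtype=float)
    if not np.isnan(mat).any():
        return ExpressionDataset(values=ds.values.copy(), labels=ds.labels.copy())
    all_missing = np.isnan(mat).all(axis=1)
    if all_missing.any():
        bad = list(ds.values.index[all_missing])
        raise ValueError(f"gene row(s) entirely missing, cannot impute: {bad}")
    col_missing = np.isnan(mat).all(axis=0)
    if col_missing.any():
        bad = list(ds.values.columns[col_missing])
        raise ValueError(f"sample column(s) entirely missing, cannot impute: {bad}")
    from sklearn.impute import KNNImputer

    filled = KNNImputer(n_neighbors=k).fit_transform(mat)
    observed = ~np.isnan(mat)
    out = mat.copy()
    out[~observed] = filled[~observed]
    values = pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns)
    return ExpressionDataset(values=values, labels=ds.labels.copy())


def apply_sample_filter(
    ds: ExpressionDataset,
    include: list[str] | None = None,
    exclude: list[str] | None = None,
) -> ExpressionDataset:
    """Config-driven sample curation (e.g. dropping higher-stage tumours)."""
    samples = list(ds.sample_ids)
    if include is not None:
        keep = [s for s in samples if s in set(include)]
    else:
        keep = samples
    if exclude is not None:
        keep = [s for s in keep if s not in set(exclude)]
    return ds.subset_samples(keep)


def preprocess(
    ds: ExpressionDataset,
    k: int = 10,
    include: list[str] | None = None,
    exclude: list[str] | None = None,
) -> ExpressionDataset:
    """Standard preprocessing chain: sample filter, probe collapse, kNN imputation."""
    ds = apply_sample_filter(ds, include=include, exclude=exclude)
    ds = collapse_probes(ds)
    return impute_knn(ds, k=k)
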