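"""File input/output for the combined-action pipeline.

All external files are plain tab-separated text (UTF-8, ``NA`` for missing,
no quoting).  Every reader validates its input and returns an in-memory
domain object; downstream modules never touch files directly.

Conventions
-----------
* Expression matrices are genes x samples; the first column holds gene
  symbols.  Values are used exactly as supplied (no re-normalization).
* Gene symbols are matched case-sensitively after whitespace trimming;
  silent case-folding would hide identifier errors.
* Gene-list files hold one symbol per line; ``#`` starts a comment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """The file does not conform to the expected layout."""


class ValidationError(ValueError):
    """The file parsed but violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample matrix of continuous expression values.

    ``data`` is a float DataFrame indexed by gene symbol with sample IDs as
    columns; missing measurements are NaN.  Genes and samples are unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        dup_genes = idx[idx.duplicated()].unique().tolist()
        if dup_genes:
            raise ValidationError(f"duplicate gene symbols: {dup_genes}")
        dup_samples = cols[cols.duplicated()].unique().tolist()
        if dup_samples:
            raise ValidationError(f"duplicate sample IDs: {dup_samples}")
        if self.data.shape[0] == 0:
            raise ValidationError("expression matrix has zero gene rows")
        values = self.data.to_numpy()
        if np.isinf(values).any():
            raise ValidationError("expression matrix contains infinite values")
        all_missing = self.data.index[np.isnan(values).all(axis=1)].tolist()
        if all_missing:
            raise ValidationError(
                f"gene rows entirely missing: {all_missing}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def gene_values(self, gene: str) -> np.ndarray:
        if gene not in self.data.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        return self.data.loc[gene].to_numpy(dtype=float)


@dataclass(frozen=True)
class PhenotypeTable:
    """Sample-by-phenotype table of raw immune-associated phenotype values."""

    data: pd.DataFrame
    degenerate: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        idx = self.data.index
        dup = idx[idx.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate sample IDs: {dup}")
        if self.data.shape[1] == 0:
            raise ValidationError("phenotype table has no phenotype columns")
        # columns with <2 distinct non-missing values cannot be scaled/scored
        degen = frozenset(
            c for c in self.data.columns if self.data[c].dropna().nunique() < 2
        )
        object.__setattr__(self, "degenerate", degen)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"phenotype {name!r} not in table")
        return self.data[name]


@dataclass(frozen=True)
class GeneListPair:
    """Validated TAP and ICP gene sets (ordered, deduplicated)."""

    tap_genes: tuple[str, ...]
    icp_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tap_genes or not self.icp_genes:
            raise ValidationError("TAP and ICP gene lists must be non-empty")

    @classmethod
    def from_lists(
        cls,
        tap: Iterable[str],
        icp: Iterable[str],
        expr: ExpressionMatrix | None = None,
    ) -> "GeneListPair":
        """Build the pair, optionally dropping genes absent from ``expr``."""
        import warnings

        def clean(genes: Iterable[str], label: str) -> tuple[str, ...]:
            seen: dict[str, None] = {}
            for g in genes:
                g = g.strip()
                if g:
                    seen.setdefault(g, None)
            kept = list(seen)
            if expr is not None:
                present = set(expr.genes)
                dropped = [g for g in kept if g not in present]
                if dropped:
                    warnings.warn(
                        f"{label} genes absent from expression matrix, "
                        f"dropped: {dropped}"
                    )
                kept = [g for g in kept if g in present]
            return tuple(kept)

        return cls(clean(tap, "TAP"), clean(icp, "ICP"))


@dataclass(frozen=True)
class LigandReceptorTable:
    """Set of unordered ligand-receptor gene-symbol pairs."""

    pairs: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        for p in self.pairs:
            if len(p) != 2:
                raise ValidationError(f"self-pair or malformed pair: {set(p)}")

    def contains(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.pairs

    def partners(self, gene: str) -> list[str]:
        out = sorted(
            next(iter(p - {gene})) for p in self.pairs if gene in p
        )
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_NA_VALUES = ["NA"]


def read_expression_matrix(
    path: str | Path, transpose_allowed: bool = False
) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    The first column holds gene symbols.  With ``transpose_allowed`` the
    orientation is flipped when the file appears to be samples x genes
    (heuristic: more columns than rows usually means genes across the top is
    not the case for cohort data; here we only transpose on explicit request
    via the flag when the row count is smaller than the column count).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=_NA_VALUES,
            keep_default_na=False,
            dtype_backend="numpy_nullable",
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: header has no sample columns")
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: zero data rows")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression cell: {exc}") from exc
    if transpose_allowed and df.shape[0] < df.shape[1]:
        df = df.T
    return ExpressionMatrix(df)


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read a samples x phenotypes TSV."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=_NA_VALUES,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no phenotype columns")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric phenotype cell: {exc}") from exc
    return PhenotypeTable(df)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; ``#`` comments and blank lines ignored."""
    out: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def read_ligand_receptor_table(path: str | Path) -> LigandReceptorTable:
    """Two-column TSV (partner_a, partner_b) of interacting gene symbols."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (partner_a, partner_b)")
    pairs = set()
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        a, b = str(a).strip(), str(b).strip()
        if a == b:
            continue  # self-pairs carry no pairwise information
        pairs.add(frozenset((a, b)))
    return LigandReceptorTable(frozenset(pairs))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "tap", "icp", "iap", "config", "S", "sign", "M_target", "M_E", "R",
    "p_significance", "Q_significance", "p_specificity", "Q_specificity",
    "passed",
]


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, (float, np.floating)):
        x = float(x)
        if math.isnan(x):
            return "NA"
        return repr(x)  # shortest round-trippable representation
    return str(x)


def write_interaction_table(results: Sequence, path: str | Path) -> None:
    """Write one TSV row per validated TAP-ICP-IAP triple.

    ``results`` are :class:`~coaction.validation.ValidatedInteraction`
    records.  Missing scores and p-values serialize as ``NA``; floats use
    their shortest round-trippable decimal form so a read-back restores
    values exactly.
    """
    lines = ["\t".join(_RESULT_COLUMNS)]
    for r in results:
        row = r.as_record()
        lines.append("\t".join(_fmt(row[c]) for c in _RESULT_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_interaction_table`."""
    df = pd.read_csv(
        path, sep="\t", na_values=_NA_VALUES, keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    if df["passed"].dtype != bool:
        df["passed"] = df["passed"].map(
            {"true": True, "false": False, True: True, False: False}
        )
    return df


def network_to_graph(network) -> nx.Graph:
    """Convert an :class:`~coaction.network.InteractionNetwork` to networkx."""
    g = nx.Graph(iap=network.iap)
    for node in network.nodes:
        g.add_node(
            f"{node.gene}|{node.state}",
            gene=node.gene,
            gene_class=node.gene_class,
            state=node.state,
        )
    for e in network.edges:
        g.add_edge(
            e.node_a,
            e.node_b,
            S=float(e.S),
            Q_significance=float(e.Q_significance),
            Q_specificity=float(e.Q_specificity),
            direction=e.direction,
            is_ligand_receptor=bool(e.is_ligand_receptor),
        )
    return g


def write_network(
    network, path_graphml: str | Path, path_edges: str | Path
) -> None:
    """Serialize a network as GraphML plus a flat edge-list TSV."""
    g = network_to_graph(network)
    nx.write_graphml(g, str(path_graphml))
    cols = [
        "node_a", "node_b", "S", "Q_significance", "Q_specificity",
        "direction", "is_ligand_receptor",
    ]
    lines = ["\t".join(cols)]
    for e in network.edges:
        lines.append(
            "\t".join(
                _fmt(v)
                for v in (
                    e.node_a, e.node_b, e.S, e.Q_significance,
                    e.Q_specificity, e.direction, e.is_ligand_receptor,
                )
            )
        )
    Path(path_edges).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
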