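"""Readers and writers for the pipeline's plain-text formats.

Supported formats:

* expression matrices — probe × sample TSV with a header row, or the data
  block of a GEO series-matrix file (``!series_matrix_table_begin`` /
  ``!series_matrix_table_end`` delimited);
* gene lists — one symbol per line, ``#`` comments, ``COMPLEX:`` prefix for
  protein-complex entries;
* interaction networks — 3/4-column TSV edge lists with per-edge literature
  reference counts, or SIF (``source relation target``);
* ranking tables — TSV mirroring the gene/score/p-value/edge-count layout.

Gene symbols are uppercased on ingest.  Duplicate edges merge by summing
their reference counts (references are cumulative evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG2 = "log2"

#: Marker prefix for protein-complex lines in gene-list files.
COMPLEX_PREFIX = "COMPLEX:"

_EFFECTS = ("inhibitory", "stimulatory", "unspecified")

#: SIF relation keywords mapped onto edge effect labels.
SIF_EFFECT_MAP = {
    "inhibits": "inhibitory",
    "inhibition": "inhibitory",
    "represses": "inhibitory",
    "activates": "stimulatory",
    "activation": "stimulatory",
    "stimulates": "stimulatory",
}


@dataclass
class ExpressionMatrix:
    """Probe × sample intensity matrix with optional two-group labels.

    Parameters
    ----------
    data
        DataFrame indexed by probe id with sample ids as columns.
    scale
        ``"linear"`` or ``"log2"`` — whether values are raw or log2
        intensities.
    labels
        Optional Series mapping sample id -> group label.  Exactly two
        distinct groups are required for differential testing.
    """

    data: pd.DataFrame
    scale: str = LINEAR
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.labels is not None:
            self.labels = pd.Series(self.labels)
            missing = [s for s in self.data.columns if s not in self.labels.index]
            if missing:
                raise ValueError(f"samples without group label: {missing}")
            self.labels = self.labels.reindex(self.data.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def group_columns(self) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
        """Column index arrays of the two groups, in label sorted order."""
        if self.labels is None:
            raise ValueError("expression matrix carries no group labels")
        groups = sorted(pd.unique(self.labels.dropna()))
        if len(groups) != 2:
            raise ValueError(f"exactly two groups required, got {groups}")
        lab = self.labels.to_numpy()
        g1 = np.flatnonzero(lab == groups[0])
        g2 = np.flatnonzero(lab == groups[1])
        return g1, g2, (str(groups[0]), str(groups[1]))


@dataclass(frozen=True)
class GeneSet:
    """Named set of normalized (uppercase) gene symbols with provenance.

    ``complexes`` holds protein-complex names (e.g. DNA-PK) that are not
    gene symbols and are excluded from set intersections.
    """

    name: str
    symbols: frozenset[str]
    complexes: frozenset[str] = frozenset()
    n_lines: int = 0  # raw (pre-dedup) symbol line count, for audit logs

    def __post_init__(self) -> None:
        if any((not s) or (s != s.upper()) for s in self.symbols):
            raise ValueError("symbols must be non-empty and uppercase")
        if self.symbols & self.complexes:
            raise ValueError("complex names must be disjoint from gene symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols


@dataclass(frozen=True)
class ProbeGeneMap:
    """Many-to-one probe id -> gene symbol map (symbols uppercased)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        norm = {str(p): str(g).upper() for p, g in dict(self.mapping).items()}
        if any(not g for g in norm.values()):
            raise ValueError("empty gene symbol in probe map")
        object.__setattr__(self, "mapping", norm)

    def get(self, probe: str) -> str | None:
        return self.mapping.get(probe)

    def __len__(self) -> int:
        return len(self.mapping)


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    scale: str = LINEAR,
) -> ExpressionMatrix:
    """Read an expression matrix from a TSV or GEO series-matrix file.

    The TSV dialect expects a header row of sample ids and probe ids in the
    first column.  The series-matrix dialect reads only the lines between
    the ``!series_matrix_table_begin`` and ``!series_matrix_table_end``
    markers; all surrounding metadata is ignored (group labels come from a
    side file, not GEO metadata).
    """
    path = Path(path)
    if dialect == "tsv":
        lines = path.read_text().splitlines()
    elif dialect == "series_matrix":
        lines = _series_matrix_block(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    rows = [ln.split("\t") for ln in lines if ln.strip()]
    if len(rows) < 2:
        raise ValueError(f"{path}: no data rows")
    header = [_unquote(c) for c in rows[0]]
    sample_ids = header[1:]
    width = len(rows[0])
    probes: list[str] = []
    values: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {width})"
            )
        probe = _unquote(row[0])
        try:
            vals = [float(_unquote(c)) for c in row[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell at line {lineno}: {exc}")
        probes.append(probe)
        values.append(vals)
    data = pd.DataFrame(values, index=probes, columns=sample_ids, dtype=float)
    return ExpressionMatrix(data=data, scale=scale)


def _series_matrix_block(path: Path) -> list[str]:
    lines = path.read_text().splitlines()
    block: list[str] = []
    inside = False
    for ln in lines:
        s = ln.strip()
        if s.lower().startswith("!series_matrix_table_begin"):
            inside = True
            continue
        if s.lower().startswith("!series_matrix_table_end"):
            inside = False
            continue
        if inside:
            block.append(ln)
    if not block:
        raise ValueError(f"{path}: no series_matrix table block found")
    return block


def _unquote(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
        tok = tok[1:-1]
    return tok


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as probe × sample TSV (full float precision)."""
    matrix.data.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample-id / group TSV into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label file needs two tab-separated columns")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if ser.index.duplicated().any():
        raise ValueError(f"{path}: duplicated sample id in label file")
    return ser


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list.

    Blank lines and ``#`` comments are skipped; symbols are uppercased and
    deduplicated.  Lines prefixed ``COMPLEX:`` populate the complex set.
    """
    path = Path(path)
    symbols: list[str] = []
    complexes: set[str] = set()
    for ln in path.read_text().splitlines():
        s = ln.strip()
        if not s or s.startswith("#"):
            continue
        if s.upper().startswith(COMPLEX_PREFIX):
            complexes.add(s[len(COMPLEX_PREFIX):].strip().upper())
            continue
        symbols.append(s.upper())
    if not symbols and not complexes:
        raise ValueError(f"{path}: empty gene list after filtering")
    unique = frozenset(symbols)
    if len(unique) < len(symbols):
        logger.info(
            "%s: %d symbol lines collapsed to %d unique symbols",
            path, len(symbols), len(unique),
        )
    return GeneSet(
        name=name or path.stem,
        symbols=unique,
        complexes=frozenset(complexes),
        n_lines=len(symbols),
    )


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    """Write gene symbols one per line, sorted, uppercased."""
    Path(path).write_text(
        "".join(f"{g.upper()}\n" for g in sorted({str(g) for g in genes}))
    )


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Read a two-column probe-id / gene-symbol TSV."""
    mapping: dict[str, str] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        s = ln.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected probe<TAB>gene")
        mapping[parts[0].strip()] = parts[1].strip()
    return ProbeGeneMap(mapping)


# ---------------------------------------------------------------------------
# interaction networks


def new_network() -> nx.DiGraph:
    return nx.DiGraph()


def add_interaction(
    net: nx.DiGraph,
    source: str,
    target: str,
    ref_count: int = 1,
    effect: str = "unspecified",
) -> None:
    """Add a directed edge, merging duplicates by summing reference counts."""
    source, target = str(source).upper(), str(target).upper()
    if source == target:
        raise ValueError(f"self-loop rejected at node {source!r}")
    if not (isinstance(ref_count, (int, np.integer)) or float(ref_count).is_integer()):
        raise ValueError(f"ref_count must be an integer, got {ref_count!r}")
    ref_count = int(ref_count)
    if ref_count < 1:
        raise ValueError(f"ref_count must be >= 1, got {ref_count}")
    if effect not in _EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    if net.has_edge(source, target):
        old = net[source][target]
        logger.warning(
            "duplicate edge %s->%s: reference counts summed (%d + %d)",
            source, target, old["ref_count"], ref_count,
        )
        old["ref_count"] += ref_count
        if old["effect"] != effect:
            old["effect"] = "unspecified"
    else:
        net.add_edge(source, target, ref_count=ref_count, effect=effect)


def read_edge_list(path: str | Path, dialect: str = "tsv") -> nx.DiGraph:
    """Read a directed interaction network from a TSV or SIF edge list.

    TSV columns: source, target, ref_count, effect (last two optional).
    SIF lines: ``source relation target``; reference count defaults to 1 and
    the relation keyword maps onto the effect label where recognized.
    """
    path = Path(path)
    net = new_network()
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        s = ln.strip()
        if not s or s.startswith("#"):
            continue
        try:
            if dialect == "tsv":
                parts = s.split("\t")
                if len(parts) < 2:
                    raise ValueError("expected at least source<TAB>target")
                source, target = parts[0], parts[1]
                ref = 1
                if len(parts) >= 3 and parts[2].strip():
                    raw = parts[2].strip()
                    try:
                        reff = float(raw)
                    except ValueError:
                        raise ValueError(f"non-numeric ref_count {raw!r}")
                    if not reff.is_integer():
                        raise ValueError(f"ref_count must be an integer, got {raw!r}")
                    ref = int(reff)
                effect = parts[3].strip() if len(parts) >= 4 and parts[3].strip() else "unspecified"
            elif dialect == "sif":
                parts = s.split()
                if len(parts) != 3:
                    raise ValueError("SIF line must have 3 tokens: source relation target")
                source, relation, target = parts
                ref = 1
                effect = SIF_EFFECT_MAP.get(relation.lower(), "unspecified")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            add_interaction(net, source, target, ref_count=ref, effect=effect)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if net.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty edge list")
    return net


def write_edge_list(net: nx.DiGraph, path: str | Path) -> None:
    """Write a network as a 4-column TSV edge list, sorted for determinism."""
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tref_count\teffect\n")
        for u, v, attrs in sorted(net.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{attrs.get('ref_count', 1)}\t"
                f"{attrs.get('effect', 'unspecified')}\n"
            )


# ---------------------------------------------------------------------------
# ranking tables


def write_ranking_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a ranking table as TSV, scores at 6 significant digits.

    The table must carry ``gene``, ``score`` and ``n_edges`` columns; any
    per-source p-value columns are preserved.  Rows are sorted by descending
    score, ties broken lexicographically by symbol, and a 1-based ``rank``
    column is prepended.
    """
    if table.empty:
        raise ValueError("ranking table is empty")
    df = table.copy()
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["score"] = df["score"].map(lambda s: f"{s:.6g}")
    df.to_csv(path, sep="\t", index=False)


def read_ranking_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# packaged fixtures


def load_literature_geneset() -> GeneSet:
    """The packaged literature survey: 221 radiation-response genes plus
    the DNA-PK, HSP70, MRN(95) and RAS complexes."""
    ref = resources.files("radrank.data") / "literature_radiation_genes.txt"
    with resources.as_file(ref) as p:
        gs = read_gene_set(p, name="literature")
    return gs


def load_core_overlap_geneset() -> GeneSet:
    """The packaged 20-gene core set shared by all three evidence sources."""
    ref = resources.files("radrank.data") / "core_overlap_genes.txt"
    with resources.as_file(ref) as p:
        gs = read_gene_set(p, name="core_overlap")
    return gs
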