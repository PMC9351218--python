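"""Readers and writers for the external tables the pipeline consumes.

All formats are plain tab-separated text:

* PPI edge list: ``proteinA<TAB>proteinB[<TAB>interactionType]``; lines
  starting with ``#`` are comments.
* Expression: a probes-by-samples matrix plus a sidecar sample sheet with
  columns ``sample, condition, replicate, timepoint_min``.
* Localization: ``protein<TAB>term<TAB>confidence``.
* Protein lists (e.g. essentiality annotations): one identifier per line.

Identifier matching throughout the package is exact string equality after
whitespace trimming; no alias resolution is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EmptyNetworkError",
    "ParseError",
    "SampleAnnotation",
    "ExpressionTable",
    "LocalizationEntry",
    "read_ppi_edge_list",
    "write_ppi_edge_list",
    "read_sample_sheet",
    "read_expression_table",
    "read_localization_table",
    "read_protein_list",
    "make_label_set",
    "write_embedding_table",
    "read_embedding_table",
    "write_prediction_table",
    "summarize_dataset",
]


class ParseError(ValueError):
    """A malformed row in an input file; the message names the line number."""


class EmptyNetworkError(ValueError):
    """No edges survived parsing/filtering."""


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def read_ppi_edge_list(path: str | Path, interaction_filter: str | None = None) -> nx.Graph:
    """Read a tab-separated edge list into a simple undirected graph.

    Rows whose interaction-type column does not match ``interaction_filter``
    (when one is given) are dropped, as are self-loops; duplicate unordered
    pairs collapse to a single edge of weight 1.

    Raises
    ------
    ParseError
        If a non-comment row has fewer than two columns, or lacks the
        interaction-type column while a filter is requested.
    EmptyNetworkError
        If no edge survives.
    """
    graph = nx.Graph()
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected at least 2 tab-separated columns, got {len(fields)}")
            if interaction_filter is not None:
                if len(fields) < 3:
                    raise ParseError(f"line {lineno}: interaction-type column required by filter is missing")
                if fields[2] != interaction_filter:
                    continue
            a, b = fields[0], fields[1]
            if a == b:  # self-loop
                continue
            graph.add_edge(a, b, weight=1.0)
    if graph.number_of_edges() == 0:
        raise EmptyNetworkError(f"empty network: no edges parsed from {path!s}")
    return graph


def write_ppi_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# proteinA\tproteinB\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            handle.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleAnnotation:
    """Annotation of one expression sample column."""

    condition: str
    replicate: int
    timepoint_min: float


@dataclass
class ExpressionTable:
    """A probes/genes-by-samples expression matrix with annotated columns.

    ``values`` keeps missing measurements as NaN ("absent, not zero"); any
    zero-filling happens later, at tensor assembly.
    """

    values: pd.DataFrame  # rows: probe/gene ids, columns: sample names
    annotations: dict[str, SampleAnnotation]

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.annotations]
        if missing:
            raise ValueError(f"samples without annotation: {missing}")
        tuples = [
            (a.condition, a.replicate, a.timepoint_min) for a in self.annotations.values()
        ]
        if len(set(tuples)) != len(tuples):
            raise ValueError("duplicate (condition, replicate, timepoint) annotation tuples")


def read_sample_sheet(path: str | Path) -> dict[str, SampleAnnotation]:
    """Read the sidecar sample sheet (``sample, condition, replicate, timepoint_min``)."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    required = {"sample", "condition", "replicate", "timepoint_min"}
    missing = required - set(sheet.columns)
    if missing:
        raise ParseError(f"sample sheet missing columns: {sorted(missing)}")
    return {
        str(row["sample"]): SampleAnnotation(
            condition=str(row["condition"]),
            replicate=int(row["replicate"]),
            timepoint_min=float(row["timepoint_min"]),
        )
        for _, row in sheet.iterrows()
    }


def read_expression_table(
    path: str | Path, layout: Mapping[str, SampleAnnotation]
) -> ExpressionTable:
    """Read an expression matrix whose columns are described by ``layout``.

    Non-numeric cells (e.g. ``NA``) become NaN and the row is retained.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str).str.strip()
    missing = [name for name in layout if name not in frame.columns]
    if missing:
        raise ParseError(f"columns named in layout missing from file: {missing}")
    frame = frame[list(layout)]
    frame = frame.apply(pd.to_numeric, errors="coerce")
    return ExpressionTable(values=frame, annotations=dict(layout))


# ---------------------------------------------------------------------------
# Subcellular localization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalizationEntry:
    """One protein-compartment annotation with its confidence score.

    Confidence follows the COMPARTMENTS integrated-channel convention: a
    non-negative score with a conventional ceiling of 5.
    """

    protein: str
    term: str
    confidence: float


def read_localization_table(path: str | Path) -> list[LocalizationEntry]:
    """Read ``protein, term, confidence`` rows, deduplicated on (protein, term).

    Duplicate pairs keep the maximum confidence (strongest evidence).
    Negative confidences are rejected.
    """
    best: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected 3 columns (protein, term, confidence)")
            try:
                conf = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric confidence {fields[2]!r}") from exc
            if conf < 0:
                raise ValueError(f"line {lineno}: negative confidence {conf}")
            key = (fields[0], fields[1])
            if key not in best or conf > best[key]:
                best[key] = conf
    return [
        LocalizationEntry(protein=p, term=t, confidence=c)
        for (p, t), c in sorted(best.items())
    ]


# ---------------------------------------------------------------------------
# Protein / label lists
# ---------------------------------------------------------------------------

def read_protein_list(paths: Sequence[str | Path] | str | Path) -> set[str]:
    """Union of identifiers over one or more one-per-line files."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    ids: set[str] = set()
    for path in paths:
        with open(path, encoding="utf-8") as handle:
            for raw in handle:
                token = raw.strip()
                if token and not token.startswith("#"):
                    ids.add(token)
    return ids


def make_label_set(proteins: Iterable[str], essential: set[str]) -> dict[str, int]:
    """Binary labels (1 = essential) for an ordered protein collection."""
    return {p: int(p in essential) for p in proteins}


# ---------------------------------------------------------------------------
# Artifact plumbing: embeddings and predictions
# ---------------------------------------------------------------------------

def write_embedding_table(embedding: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write node vectors as TSV with 6 decimal places; round-trips to 1e-6."""
    if not embedding:
        raise ValueError("empty embedding")
    dims = {len(np.asarray(v)) for v in embedding.values()}
    if len(dims) != 1:
        raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
    with open(path, "w", encoding="utf-8") as handle:
        for node in sorted(embedding):
            vec = np.asarray(embedding[node], dtype=float)
            handle.write(node + "\t" + "\t".join(f"{x:.6f}" for x in vec) + "\n")


def read_embedding_table(path: str | Path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected node id plus vector")
            out[fields[0]] = np.array([float(x) for x in fields[1:]])
    return out


def write_prediction_table(
    ids: Sequence[str],
    probabilities: Sequence[float],
    labels: Sequence[int],
    path: str | Path,
) -> None:
    probs = np.asarray(probabilities, dtype=float)
    if len(ids) != len(probs) or len(ids) != len(labels):
        raise ValueError("ids, probabilities and labels must align")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("protein\tprobability\tlabel\n")
        for pid, prob, lab in zip(ids, probs, labels):
            handle.write(f"{pid}\t{prob:.6f}\t{int(lab)}\n")


# ---------------------------------------------------------------------------
# Dataset arithmetic
# ---------------------------------------------------------------------------

def summarize_dataset(
    n_nodes: int,
    n_edges: int,
    n_essential: int | None = None,
    n_with_expression: int | None = None,
) -> dict[str, float]:
    """Headline arithmetic for a dataset: class prevalence, coverage, degree.

    ``edges_per_node`` is edges divided by nodes — the convention some PPI
    reports call "average degree" — while ``mean_degree`` is the
    graph-theoretic 2·|E|/|V|.  Both are reported, labeled.
    """
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    out: dict[str, float] = {
        "n_nodes": float(n_nodes),
        "n_edges": float(n_edges),
        "edges_per_node": n_edges / n_nodes,
        "mean_degree": 2 * n_edges / n_nodes,
    }
    if n_essential is not None:
        out["essential_fraction"] = n_essential / n_nodes
    if n_with_expression is not None:
        out["expression_coverage"] = n_with_expression / n_nodes
    return out
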