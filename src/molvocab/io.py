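"""Readers/writers for the interchange formats.

TSV is used throughout (GO term names contain commas); matrices are stored
traits-as-rows, genomes-as-columns with a companion metadata TSV mapping
genome id to superkingdom.  OBO v1.2 subsets are read through obonet, rooted
trees through dendropy (Newick), and every JSON result embeds seed, tool
version, parameter set, and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import dendropy
import networkx as nx
import pandas as pd

from . import __version__
from .census import OccurrenceMatrix
from .timeline import (AgeTable, NAMESPACE_ALIASES, OntologyGraph,
                       TimelineError)
from .wordcloud import TermRecord

log = logging.getLogger("molvocab")


class ParseError(ValueError):
    pass


# --------------------------------------------------------------------------
# occurrence matrices
# --------------------------------------------------------------------------

def write_occurrence_tsv(matrix: OccurrenceMatrix, path: str | Path,
                         metadata_path: str | Path | None = None) -> None:
    path = Path(path)
    df = matrix.counts.copy()
    df.index.name = "trait_id"
    df.to_csv(path, sep="\t")
    meta = Path(metadata_path) if metadata_path else path.with_suffix(".meta.tsv")
    rows = [{"genome_id": g, "superkingdom": matrix.superkingdoms[g]}
            for g in matrix.genomes]
    pd.DataFrame(rows).to_csv(meta, sep="\t", index=False)


def read_occurrence_tsv(path: str | Path,
                        metadata_path: str | Path | None = None) -> OccurrenceMatrix:
    """Read a traits x genomes TSV plus its genome-metadata TSV.

    Parse errors (non-integer or negative cells, ragged rows, duplicate ids)
    report the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: header needs trait id + genome columns")
        genomes = header[1:]
        if len(set(genomes)) != len(genomes):
            raise ParseError(f"{path}:1: duplicate genome ids")
        traits: list[str] = []
        data: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} "
                                 f"columns, got {len(cells)}")
            tid = cells[0]
            if tid in traits:
                raise ParseError(f"{path}:{lineno}: duplicate trait id {tid!r}")
            row: list[int] = []
            for cell in cells[1:]:
                try:
                    val = int(cell)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer cell {cell!r}")
                if val < 0:
                    raise ParseError(f"{path}:{lineno}: negative cell {cell!r}")
                row.append(val)
            traits.append(tid)
            data.append(row)
    meta = Path(metadata_path) if metadata_path else path.with_suffix(".meta.tsv")
    if not meta.exists():
        raise ParseError(f"metadata file not found: {meta}")
    mdf = pd.read_csv(meta, sep="\t", dtype=str)
    if not {"genome_id", "superkingdom"} <= set(mdf.columns):
        raise ParseError(f"{meta}: need columns genome_id, superkingdom")
    sk = dict(zip(mdf["genome_id"], mdf["superkingdom"]))
    counts = pd.DataFrame(data, index=pd.Index(traits, name="trait_id"),
                          columns=genomes, dtype=int)
    return OccurrenceMatrix(counts=counts, superkingdoms=sk)


# --------------------------------------------------------------------------
# age tables and GO-term tables
# --------------------------------------------------------------------------

def write_age_tsv(ages: AgeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tage\n")
        for tid in ages.sorted_ids():
            fh.write(f"{tid}\t{ages[tid]:.6f}\n")


def read_age_tsv(path: str | Path) -> AgeTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "age": float})
    if not {"id", "age"} <= set(df.columns):
        raise ParseError(f"{path}: need columns id, age")
    return AgeTable(dict(zip(df["id"], df["age"])))


def write_terms_tsv(terms: list[TermRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("go_id\tname\tage\tvenn_group\n")
        for t in terms:
            fh.write(f"{t.term_id}\t{t.name}\t{t.age:.6f}\t{t.group}\n")


def read_terms_tsv(path: str | Path) -> list[TermRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"go_id", "name", "age"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(need)}")
    out = []
    for _, row in df.iterrows():
        out.append(TermRecord(term_id=row["go_id"], name=row["name"],
                              age=float(row["age"]),
                              group=row.get("venn_group", "ABE")))
    return out


# --------------------------------------------------------------------------
# OBO and Newick
# --------------------------------------------------------------------------

def read_obo_subset(path: str | Path) -> OntologyGraph:
    """Read an OBO v1.2 subset (id/name/namespace/is_a/relationship stanzas).

    Obsolete terms are skipped with a logged count; a term without a namespace
    or a cyclic is_a relation is an error.
    """
    import obonet

    raw = obonet.read_obo(str(path), ignore_obsolete=False)
    n_obsolete = 0
    g = nx.MultiDiGraph()
    for node, attrs in raw.nodes(data=True):
        if attrs.get("is_obsolete") == "true":
            n_obsolete += 1
            continue
        ns = attrs.get("namespace")
        if ns is None:
            raise ParseError(f"term {node} has no namespace")
        if ns not in NAMESPACE_ALIASES:
            raise ParseError(f"term {node}: unknown namespace {ns!r}")
        g.add_node(node, name=attrs.get("name", node),
                   namespace=NAMESPACE_ALIASES[ns])
    if n_obsolete:
        log.info("skipped %d obsolete terms", n_obsolete)
    for child, parent, key in raw.edges(keys=True):
        if child not in g or parent not in g:
            continue
        if key in ("is_a", "part_of", "regulates"):
            g.add_edge(child, parent, key=key)
    try:
        return OntologyGraph(g)
    except TimelineError as exc:
        raise ParseError(str(exc)) from exc


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree; missing branch lengths default to 1
    (logged)."""
    text = Path(path).read_text()
    if text.count(";") > 1:
        raise ParseError(f"{path}: multiple trees in file")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=False)
    except Exception as exc:
        raise ParseError(f"{path}: newick parse failure: {exc}") from exc
    n_default = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
            n_default += 1
    if n_default:
        log.info("defaulted %d missing branch lengths to 1", n_default)
    tree.is_rooted = True
    return tree


# --------------------------------------------------------------------------
# provenance JSON
# --------------------------------------------------------------------------

def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_result_json(path: str | Path, result: Mapping[str, Any], *,
                      seed: int | None, params: Mapping[str, Any],
                      inputs: Mapping[str, str | Path] = ()) -> None:
    """Write a result payload wrapped in the provenance contract."""
    payload = {
        "tool": "molvocab",
        "version": __version__,
        "seed": seed,
        "parameters": dict(params),
        "input_checksums": {str(k): file_checksum(v)
                            for k, v in dict(inputs).items()},
        "result": _jsonable(result),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dict__") and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if hasattr(obj, "tolist"):
        return obj.tolist()
    try:
        json.dumps(obj)
        return obj
    except TypeError:
        return str(obj)
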