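"""File-format adapters: GMT gene sets, TSV edge lists and matrices,
plain-text ID lists, JSON reports.

All identifiers are uppercased on ingest.  Writers are deterministic
(sorted members/keys) so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError
from .genesets import GeneSet, GeneSetCollection, normalize_id
from .simulate import IntensityMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- GMT

def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Parse a tab-separated GMT file (name, description, members...).

    Lines with fewer than three fields (i.e. no member) raise a
    :class:`ParseError` with the line number; duplicate members within a
    set are deduplicated with a warning.
    """
    path = Path(path)
    collection = GeneSetCollection(name or path.stem)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"expected name, description and >=1 member, "
                                 f"got {len(fields)} fields", line=lineno)
            set_name, description, *members = fields
            members = [normalize_id(m) for m in members if m.strip()]
            if not members:
                raise ParseError("set has no members", line=lineno)
            if len(set(members)) != len(members):
                logger.warning("%s line %d: duplicate members in set %s "
                               "deduplicated", path.name, lineno, set_name)
            collection.add(GeneSet(set_name, description, frozenset(members)))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description,
                                *sorted(gs.members)]) + "\n")


# --------------------------------------------------------- edge lists

def read_edge_list(path, scale_1000: bool = False) -> nx.Graph:
    """Read a 3-column TSV edge list (node1, node2, confidence).

    A header line whose third column is named ``score1000`` (or
    ``scale_1000=True``) divides scores by 1000.  Duplicate pairs keep
    the maximum confidence; self-loops are dropped with a warning.
    """
    path = Path(path)
    g = nx.Graph(tissue_id=path.stem)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"expected 3 columns, got {len(fields)}",
                                 line=lineno)
            a, b, conf_raw = fields[0], fields[1], fields[2]
            if lineno == 1 and not _is_number(conf_raw):
                # header row; honour a 0-1000 score flag in the column name
                if conf_raw.strip().lower() in ("score1000", "combined_score"):
                    scale_1000 = True
                continue
            try:
                conf = float(conf_raw)
            except ValueError as exc:
                raise ParseError(f"unparseable confidence {conf_raw!r}",
                                 line=lineno) from exc
            if scale_1000:
                conf /= 1000.0
            if not 0.0 <= conf <= 1.0:
                raise ParseError(f"confidence {conf} outside [0, 1]",
                                 line=lineno)
            a, b = normalize_id(a), normalize_id(b)
            if a == b:
                logger.warning("%s line %d: self-loop on %s dropped",
                               path.name, lineno, a)
                continue
            if g.has_edge(a, b):
                g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
            else:
                g.add_edge(a, b, confidence=conf)
    return g


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\t{g[u][v].get('confidence', 1.0):g}\n")


def read_tissue_dir(directory) -> list[nx.Graph]:
    """Read every ``*.tsv`` edge list in a directory; filename = tissue ID."""
    return [read_edge_list(p) for p in sorted(Path(directory).glob("*.tsv"))]


# ----------------------------------------------------- matrices, lists

def write_intensity_matrix(matrix: IntensityMatrix, matrix_path, samples_path) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(matrix_path, sep="\t", na_rep="NA", float_format="%.6f")
    matrix.samples.to_csv(samples_path, sep="\t")


def read_intensity_matrix(matrix_path, samples_path) -> IntensityMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA"])
    values.index = [normalize_id(i) for i in values.index]
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return IntensityMatrix(values, samples)


def read_id_list(path) -> list[str]:
    """One uppercase ID per line; blank lines and ``#`` comments skipped."""
    ids = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                ids.append(normalize_id(line))
    return ids


def write_id_list(ids, path) -> None:
    with open(path, "w") as fh:
        for i in sorted({normalize_id(x) for x in ids}):
            fh.write(i + "\n")


# ------------------------------------------------------------- JSON

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = [_jsonable(v) for v in obj]
        return sorted(items, key=str) if isinstance(obj, (set, frozenset)) else items
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    return obj


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, no timestamps."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
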