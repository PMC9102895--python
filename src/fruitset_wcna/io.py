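"""Tabular and graph I/O for the fruit-set network pipeline.

All tables are plain TSV: tab-separated, UTF-8, one header row, lines
starting with ``#`` ignored.  Non-detected measurements (below the
instrument detection limit, e.g. hormone concentrations) are written as
the token ``ND`` and held in memory as NaN.

Every writer is deterministic: the same in-memory object produces a
byte-identical file (fixed float formatting, canonical row order), so
pipeline outputs can be diffed across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

ND_TOKEN = "ND"
LAYERS = ("transcript", "metabolite", "hormone")
TREATMENTS = ("P", "E", "none")

#: canonical float format: 10 significant digits
FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


def _fmt(v: float) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ND_TOKEN
    return FLOAT_FMT % v


@dataclass
class OmicsMatrix:
    """A features x samples abundance table for one omics layer.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns; missing values (non-detects) are NaN.  ``feature_meta`` is
    indexed like ``values`` and carries at least a ``layer`` column
    (transcript / metabolite / hormone).
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dupes[:5]}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        if not self.feature_meta.index.equals(idx):
            self.feature_meta = self.feature_meta.reindex(idx)
        bad = set(self.feature_meta["layer"].dropna()) - set(LAYERS)
        if bad:
            raise FormatError(f"unknown layer tags: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def layer_of(self, feature_id: str) -> str:
        return self.feature_meta.at[feature_id, "layer"]

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.values[list(sample_ids)].copy(), self.feature_meta.copy())

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return OmicsMatrix(self.values.loc[keep].copy(), self.feature_meta.loc[keep].copy())


@dataclass
class SampleDesign:
    """Sample metadata: genotype, stage (days after flowering), treatment
    (P = pollinated, E = emasculated, none = pre-flowering), replicate."""

    table: pd.DataFrame  # index sample_id; columns genotype, stage, treatment, replicate

    def __post_init__(self) -> None:
        t = self.table
        required = {"genotype", "stage", "treatment", "replicate"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        if t.index.duplicated().any():
            raise FormatError("duplicate sample ids in design")
        bad = set(t["treatment"]) - set(TREATMENTS)
        if bad:
            raise FormatError(f"unknown treatment codes: {sorted(bad)}")
        t["stage"] = t["stage"].astype(int)
        t["replicate"] = t["replicate"].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def cell_of(self, sample_id: str) -> tuple[str, int, str]:
        row = self.table.loc[sample_id]
        return (row["genotype"], int(row["stage"]), row["treatment"])

    def subset(self, sample_ids) -> "SampleDesign":
        return SampleDesign(self.table.loc[list(sample_ids)].copy())

    def samples_for(self, genotypes=None, stages=None, treatments=None) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if genotypes is not None:
            mask &= t["genotype"].isin(list(genotypes))
        if stages is not None:
            mask &= t["stage"].isin(list(stages))
        if treatments is not None:
            mask &= t["treatment"].isin(list(treatments))
        return list(t.index[mask])


@dataclass
class GoAnnotation:
    """feature id -> set of GO term ids, plus term id -> human-readable name."""

    feature_terms: dict[str, set[str]]
    term_names: dict[str, str]
    term_namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        referenced = set().union(*self.feature_terms.values()) if self.feature_terms else set()
        unnamed = referenced - set(self.term_names)
        if unnamed:
            raise FormatError(f"GO terms without a name entry: {sorted(unnamed)[:5]}")

    @property
    def features(self) -> set[str]:
        return set(self.feature_terms)

    def terms_of(self, feature_id: str) -> set[str]:
        return self.feature_terms.get(feature_id, set())


# ---------------------------------------------------------------------------
# matrix I/O


def read_matrix(path, layer: str | None = None, feature_meta: pd.DataFrame | None = None) -> OmicsMatrix:
    """Read a features x samples TSV (first column = feature id, header =
    sample ids).  ``ND`` maps to NaN.  ``layer`` tags every feature when no
    explicit ``feature_meta`` is given."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=[ND_TOKEN], dtype=str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path.name}: duplicate feature id(s) {dupes[:5]}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path.name}: duplicate sample ids in header")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric value ({exc})") from exc
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if feature_meta is None:
        if layer is None:
            raise ValueError("either layer or feature_meta must be given")
        feature_meta = pd.DataFrame({"layer": layer}, index=values.index)
    return OmicsMatrix(values, feature_meta)


def write_matrix(m: OmicsMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, m.sample_ids)) + "\n")
        arr = m.values.to_numpy()
        for fid, row in zip(m.feature_ids, arr):
            fh.write(str(fid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["sample_id", "genotype", "stage", "treatment", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"design table missing columns: {missing}")
    df = df.set_index("sample_id")
    return SampleDesign(df[["genotype", "stage", "treatment", "replicate"]].copy())


def write_design(d: SampleDesign, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgenotype\tstage\ttreatment\treplicate\n")
        for sid, row in d.table.iterrows():
            fh.write(f"{sid}\t{row['genotype']}\t{int(row['stage'])}\t{row['treatment']}\t{int(row['replicate'])}\n")


def read_annotation(path) -> GoAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["feature_id", "go_id", "go_name"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing columns: {missing}")
    feature_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for _, row in df.iterrows():
        feature_terms.setdefault(row["feature_id"], set()).add(row["go_id"])
        term_names[row["go_id"]] = row["go_name"]
        if "namespace" in df.columns and isinstance(row.get("namespace"), str):
            namespaces[row["go_id"]] = row["namespace"]
    return GoAnnotation(feature_terms, term_names, namespaces)


def write_annotation(a: GoAnnotation, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\tgo_id\tgo_name\n")
        for fid in sorted(a.feature_terms):
            for term in sorted(a.feature_terms[fid]):
                fh.write(f"{fid}\t{term}\t{a.term_names[term]}\n")


# ---------------------------------------------------------------------------
# network I/O (edge list + GraphML)


def write_edgelist(graph: nx.Graph, path) -> None:
    """Edge-list TSV with columns node_a, node_b, weight; node_a < node_b
    and rows sorted, so output is canonical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = sorted(tuple(sorted((str(u), str(v)))) + (d.get("weight", 1.0),)
                  for u, v, d in graph.edges(data=True))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{_fmt(w)}\n")


def read_edgelist(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"node_a": str, "node_b": str})
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["node_a"], row["node_b"], weight=float(row["weight"]))
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export; node attributes (module, degree, layer) are carried
    through when present on the graph."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # GraphML cannot hold numpy scalars; coerce attribute types.
    g = nx.Graph()
    for n, d in sorted(graph.nodes(data=True)):
        g.add_node(str(n), **{k: (float(v) if isinstance(v, (np.floating, float))
                                  else int(v) if isinstance(v, (np.integer,))
                                  else v) for k, v in sorted(d.items())})
    for u, v, d in sorted(graph.edges(data=True), key=lambda e: tuple(sorted((str(e[0]), str(e[1]))))):
        g.add_edge(str(u), str(v), weight=float(d.get("weight", 1.0)))
    nx.write_graphml(g, str(path), named_key_ids=True)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Canonical TSV dump of a result table (10-significant-digit floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT, na_rep=ND_TOKEN, lineterminator="\n")
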