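"""Readers and writers for all external artifacts.

Every writer/reader pair documented here round-trips losslessly for the
attributes it documents.  Files are UTF-8 TSV with ``.`` decimal point;
taxonomy uses greengenes-style rank prefixes separated by ``;``.  Networks
are exchanged as GraphML (via networkx) or flat edge TSV; supplementary
node/edge tables from spreadsheets are parsed header-name driven.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    KNOWN_VARIABLES,
    OTU_KIND,
    SIGN_COPRESENCE,
    SIGN_EXCLUSION,
    VARIABLE_KIND,
    AbioticTable,
    CooccurrenceNetwork,
    OtuTable,
    Rule,
    RuleSet,
    SeqSimilarityMatrix,
    ValidationError,
)

_SAMPLE_ID_RE = re.compile(r"^S(\d+)R(\d+)$")

OTU_ID_COLUMN = "#OTU ID"
TAXONOMY_COLUMN = "taxonomy"


def _meta_from_sample_ids(sample_ids, n_sites_per_section: int = 4) -> pd.DataFrame:
    """Derive site/replicate/section metadata from ``S<site>R<rep>`` ids."""
    rows = []
    for sid in sample_ids:
        m = _SAMPLE_ID_RE.match(str(sid))
        if m is None:
            raise ValidationError(
                f"sample id {sid!r} is not of the form S<site>R<replicate> and "
                "no metadata sidecar was given"
            )
        site, rep = int(m.group(1)), int(m.group(2))
        rows.append(
            {
                "sample": sid,
                "site": site,
                "replicate": rep,
                "section": 1 if site <= n_sites_per_section else 2,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

def read_otu_table(
    path: str | Path,
    dialect: str = "tsv",
    meta_path: str | Path | None = None,
) -> OtuTable:
    """Read a classic BIOM-TSV OTU table.

    First column ``#OTU ID``, one column per sample, optional trailing
    ``taxonomy`` column.  Sample metadata comes from a sidecar TSV
    (columns sample/site/replicate/section) or, failing that, is parsed from
    ``S<site>R<rep>`` sample ids.
    """
    if dialect not in ("tsv", "biom-tsv"):
        raise ValidationError(f"unknown OTU table dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    if df.columns[0] != OTU_ID_COLUMN:
        raise ValidationError(
            f"malformed header: first column is {df.columns[0]!r}, "
            f"expected {OTU_ID_COLUMN!r}"
        )
    df = df.set_index(OTU_ID_COLUMN)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate OTU id(s) in {path.name}: {dupes}")
    if TAXONOMY_COLUMN in df.columns:
        taxonomy = df[TAXONOMY_COLUMN].astype(str)
        counts = df.drop(columns=[TAXONOMY_COLUMN])
    else:
        taxonomy = pd.Series("", index=df.index, name=TAXONOMY_COLUMN)
        counts = df
    if counts.isna().any().any():
        rows = counts.index[counts.isna().any(axis=1)].tolist()
        raise ValidationError(f"missing count cells for OTU(s) {rows[:5]}")
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in {path.name}: {exc}") from exc
    if (counts.to_numpy() < 0).any():
        arr = counts.to_numpy()
        i, j = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"negative count at row {counts.index[i]!r}, column "
            f"{counts.columns[j]!r}"
        )
    counts = counts.astype(np.int64)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t").set_index("sample")
        meta.index = meta.index.astype(str)
    else:
        meta = _meta_from_sample_ids(counts.columns)
    return OtuTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)


def write_otu_table(table: OtuTable, path: str | Path, meta_path: str | Path | None = None) -> None:
    df = table.counts.copy()
    df[TAXONOMY_COLUMN] = table.taxonomy.loc[df.index]
    df.index.name = OTU_ID_COLUMN
    df.to_csv(path, sep="\t")
    if meta_path is not None:
        table.sample_meta.rename_axis("sample").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Abiotic tables, similarity matrices, rules
# ---------------------------------------------------------------------------

def read_abiotic_table(path: str | Path) -> AbioticTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return AbioticTable(values=df)


def write_abiotic_table(table: AbioticTable, path: str | Path) -> None:
    table.values.rename_axis("variable").to_csv(path, sep="\t")


def read_similarity_matrix(path: str | Path) -> SeqSimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    return SeqSimilarityMatrix(identity=df)


def write_similarity_matrix(mat: SeqSimilarityMatrix, path: str | Path) -> None:
    mat.identity.rename_axis("otu").to_csv(path, sep="\t")


def read_rules(path: str | Path) -> RuleSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rank", "pattern", "category"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"rule table must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    rules = []
    for i, row in df.iterrows():
        try:
            rules.append(Rule(rank=row["rank"], pattern=row["pattern"], category=row["category"]))
        except (ValidationError, TypeError) as exc:
            raise ValidationError(f"malformed rule at line {i + 2}: {exc}") from exc
    return RuleSet(rules=rules)


def write_rules(rules: RuleSet, path: str | Path) -> None:
    pd.DataFrame(
        [{"rank": r.rank, "pattern": r.pattern, "category": r.category} for r in rules.rules]
    ).to_csv(path, sep="\t", index=False)


def bundled_rules() -> RuleSet:
    """The trimmed FAPROTAX-style rule set shipped with the package."""
    return read_rules(Path(__file__).parent / "data" / "faprotax_rules.tsv")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

_JSON_EDGE_ATTRS = ("scores", "pvalues")


def write_network(net: CooccurrenceNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write a network as GraphML (full attributes) or flat edge TSV.

    GraphML carries node attributes (kind, taxonomy, core flag, centrality,
    abundance flag) and edge attributes (sign, per-measure scores/p-values as
    JSON strings, merged q).  The edge TSV is one edge per line:
    ``node1 <tab> node2 <tab> sign <tab> q``.
    """
    path = Path(path)
    if format == "graphml":
        g = net.graph.copy()
        for _, _, data in g.edges(data=True):
            for attr in _JSON_EDGE_ATTRS:
                if attr in data:
                    data[attr] = json.dumps(data[attr], sort_keys=True)
        nx.write_graphml(g, path)
    elif format == "edge-tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node1\tnode2\tsign\tq\n")
            for u, v, data in sorted(net.graph.edges(data=True)):
                q = data.get("q", "")
                fh.write(f"{u}\t{v}\t{data.get('sign', '')}\t{q}\n")
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> CooccurrenceNetwork:
    g = nx.read_graphml(Path(path))
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes()})
    for _, _, data in g.edges(data=True):
        for attr in _JSON_EDGE_ATTRS:
            if attr in data and isinstance(data[attr], str):
                data[attr] = json.loads(data[attr])
    return CooccurrenceNetwork(nx.Graph(g))


# ---------------------------------------------------------------------------
# Supplementary network tables
# ---------------------------------------------------------------------------

_NODE_SYNONYMS = ("node", "name", "id", "otu", "otu id", "otu_id", "label")
_KIND_SYNONYMS = ("kind", "type", "node type", "node_type")
_EDGE_SOURCE_SYNONYMS = ("node1", "source", "from", "otu1")
_EDGE_TARGET_SYNONYMS = ("node2", "target", "to", "otu2")
_SIGN_SYNONYMS = ("sign", "interaction", "association", "direction")

_POSITIVE_SIGNS = {"copresence", "co-presence", "positive", "pos", "+", "1"}
_NEGATIVE_SIGNS = {"exclusion", "mutualexclusion", "mutual exclusion", "negative", "neg", "-", "-1"}


def _find_column(columns, synonyms) -> str | None:
    lowered = {str(c).strip().lower(): c for c in columns}
    for syn in synonyms:
        if syn in lowered:
            return lowered[syn]
    return None


def read_supplementary_network_table(
    path: str | Path,
    section: int,
    column_map: Mapping[str, str] | None = None,
    sheet: int | str = 0,
) -> tuple[CooccurrenceNetwork, pd.DataFrame]:
    """Parse a deposited per-section network table (spreadsheet or TSV).

    The layout of the deposited tables is not standardised, so parsing is
    header-name driven; ``column_map`` may map the logical fields ``node``,
    ``kind``, ``node1``, ``node2``, ``sign`` onto actual column headers.  A
    node table yields a network with nodes only; when edge columns are
    present, edges (with signs, if given) are added.  An unrecognised layout
    raises an error listing the detected headers rather than guessing.
    """
    if section not in (1, 2):
        raise ValidationError("section must be 1 or 2")
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValidationError(f"{path.name}: empty table, no network parsed")
    column_map = dict(column_map or {})

    def resolve(field: str, synonyms) -> str | None:
        if field in column_map:
            if column_map[field] not in df.columns:
                raise ValidationError(
                    f"column map names {column_map[field]!r} for {field!r} but "
                    f"table has columns {list(df.columns)}"
                )
            return column_map[field]
        return _find_column(df.columns, synonyms)

    node_col = resolve("node", _NODE_SYNONYMS)
    src_col = resolve("node1", _EDGE_SOURCE_SYNONYMS)
    dst_col = resolve("node2", _EDGE_TARGET_SYNONYMS)
    net = CooccurrenceNetwork()

    known_vars = {v.lower(): v for v in KNOWN_VARIABLES}
    kind_col = resolve("kind", _KIND_SYNONYMS)

    def classify(name: str, kind_value: str | None) -> str:
        if kind_value is not None:
            return VARIABLE_KIND if "var" in str(kind_value).lower() else OTU_KIND
        return VARIABLE_KIND if str(name).strip().lower() in known_vars else OTU_KIND

    if src_col is not None and dst_col is not None:
        sign_col = resolve("sign", _SIGN_SYNONYMS)
        for _, row in df.iterrows():
            u, v = str(row[src_col]), str(row[dst_col])
            for n in (u, v):
                kind = classify(n, None)
                if kind == VARIABLE_KIND:
                    net.add_variable_node(n)
                else:
                    net.add_otu_node(n)
            sign = SIGN_COPRESENCE
            if sign_col is not None:
                raw = str(row[sign_col]).strip().lower()
                if raw in _NEGATIVE_SIGNS:
                    sign = SIGN_EXCLUSION
                elif raw not in _POSITIVE_SIGNS:
                    raise ValidationError(f"unrecognised edge sign value {raw!r}")
            net.add_edge(u, v, sign=sign)
    elif node_col is not None:
        for _, row in df.iterrows():
            name = str(row[node_col])
            kind_value = row[kind_col] if kind_col is not None else None
            if classify(name, kind_value) == VARIABLE_KIND:
                net.add_variable_node(name)
            else:
                net.add_otu_node(name)
    else:
        raise ValidationError(
            "unrecognised supplementary-table layout; detected column headers: "
            f"{list(df.columns)}; supply a column_map naming 'node' or "
            "'node1'/'node2'"
        )
    counts = net.edge_sign_counts()
    summary = pd.DataFrame(
        {
            "section": [section],
            "n_otu_nodes": [len(net.otu_nodes)],
            "n_variable_nodes": [len(net.variable_nodes)],
            "n_copresence_edges": [counts[SIGN_COPRESENCE] if net.n_edges else 0],
            "n_exclusion_edges": [counts[SIGN_EXCLUSION] if net.n_edges else 0],
        }
    )
    return net, summary


# ---------------------------------------------------------------------------
# Alignments, truth and reports
# ---------------------------------------------------------------------------

def write_alignment(result, path: str | Path) -> None:
    from .containers import AlignmentResult  # local to avoid cycle at import

    assert isinstance(result, AlignmentResult)
    rows = [
        {
            "node1": u,
            "node2": v,
            "score": result.node_scores.get(u, float("nan")),
        }
        for u, v in sorted(result.mapping.items())
    ]
    df = pd.DataFrame(rows, columns=["node1", "node2", "score"])
    with open(path, "w", encoding="utf-8") as fh:
        ec = "" if result.ec is None else f"{result.ec:.6f}"
        ss = "" if result.ss is None else f"{result.ss:.6f}"
        fh.write(f"# alpha={result.alpha}\tEC={ec}\tSS={ss}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_alignment(path: str | Path):
    from .containers import AlignmentResult

    with open(path, encoding="utf-8") as fh:
        header = fh.readline().lstrip("# ").strip()
        fields = dict(item.split("=", 1) for item in header.split("\t"))
        df = pd.read_csv(fh, sep="\t", dtype={"node1": str, "node2": str})
    mapping = dict(zip(df["node1"], df["node2"]))
    scores = dict(zip(df["node1"], df["score"]))
    return AlignmentResult(
        alpha=float(fields["alpha"]),
        mapping=mapping,
        node_scores=scores,
        ec=float(fields["EC"]) if fields.get("EC") else None,
        ss=float(fields["SS"]) if fields.get("SS") else None,
        conserved_edges=[],
    )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Trees and sequences
# ---------------------------------------------------------------------------

def read_tree(path: str | Path):
    """Read a newick tree as an skbio TreeNode."""
    import skbio

    return skbio.TreeNode.read(str(path), format="newick")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"duplicate sequence id {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
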