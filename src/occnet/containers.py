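"""Core data containers shared across the pipeline.

The central objects are :class:`OtuTable` (counts of OTUs x samples with
taxonomy and sample metadata), :class:`AbioticTable` (physicochemical /
nutritional variables x samples) and :class:`CooccurrenceNetwork` (an
undirected signed graph over OTU and VARIABLE nodes).  All containers wrap
pandas / networkx objects rather than reinventing them; the wrappers only add
validation and domain-specific accessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Variable names recognised for abiotic tables and network VARIABLE nodes.
KNOWN_VARIABLES = (
    "pH",
    "Temperature",
    "RelativeHumidity",
    "N_total",
    "C_total",
    "P",
    "S",
    "Cu",
    "Fe",
    "Zn",
    "K",
    "Ca",
    "Na",
    "Mg",
    "NO3",
    "NH4",
    "EC",
)

#: Variables included as network nodes by default (the drivers retained for
#: network construction: pH, humidity, temperature and the nutrients that
#: track the gradient).
DEFAULT_NETWORK_VARIABLES = (
    "pH",
    "RelativeHumidity",
    "Temperature",
    "N_total",
    "C_total",
    "P",
    "S",
    "Cu",
    "Fe",
    "Zn",
)

OTU_KIND = "OTU"
VARIABLE_KIND = "VARIABLE"

SIGN_COPRESENCE = "copresence"
SIGN_EXCLUSION = "exclusion"

TAXONOMIC_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


class ValidationError(ValueError):
    """Raised when an input artifact violates a documented invariant."""


@dataclass
class OtuTable:
    """Counts of OTUs x samples plus per-OTU taxonomy and per-sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, index = OTU ids, columns = sample ids.
    taxonomy
        Series indexed by OTU id holding greengenes-style lineage strings
        (``k__Bacteria; p__Actinobacteria; ...``).
    sample_meta
        DataFrame indexed by sample id with integer columns ``site`` (1-8),
        ``replicate`` (1-3) and ``section`` (1 or 2).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dupes}")
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("counts contain non-finite values")
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at OTU {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        missing = set(counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        for col in ("site", "replicate", "section"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample metadata misses column {col!r}")
        missing_tax = set(counts.index) - set(self.taxonomy.index)
        if missing_tax:
            raise ValidationError(
                f"OTUs without taxonomy: {sorted(missing_tax)[:5]}"
            )

    # -- accessors -------------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def samples_in_section(self, section: int) -> list[str]:
        meta = self.sample_meta.loc[self.sample_ids]
        return list(meta.index[meta["section"] == section])

    def section_slice(self, section: int) -> "OtuTable":
        """Restrict to one section's samples, dropping all-zero OTUs."""
        samples = self.samples_in_section(section)
        counts = self.counts[samples]
        keep = counts.sum(axis=1) > 0
        counts = counts.loc[keep]
        return OtuTable(
            counts=counts,
            taxonomy=self.taxonomy.loc[counts.index],
            sample_meta=self.sample_meta.loc[samples],
        )

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(
            counts=self.counts.loc[list(otu_ids)],
            taxonomy=self.taxonomy.loc[list(otu_ids)],
            sample_meta=self.sample_meta,
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.taxonomy.equals(other.taxonomy)
            and self.sample_meta.equals(other.sample_meta)
        )


@dataclass
class AbioticTable:
    """Real-valued variables x samples table of abiotic measurements."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            raise ValidationError("duplicate variable names")
        unknown = set(df.index) - set(KNOWN_VARIABLES)
        if unknown:
            raise ValidationError(f"unknown abiotic variables: {sorted(unknown)}")
        if "pH" in df.index:
            ph = df.loc["pH"]
            if ((ph < 0) | (ph > 14)).any():
                raise ValidationError("pH outside [0, 14]")
        if "RelativeHumidity" in df.index:
            rh = df.loc["RelativeHumidity"]
            if ((rh < 0) | (rh > 100)).any():
                raise ValidationError("RelativeHumidity outside [0, 100]")

    @property
    def variables(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, variables: Iterable[str], samples: Iterable[str]) -> pd.DataFrame:
        variables = [v for v in variables if v in self.values.index]
        df = self.values.loc[variables, list(samples)]
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise ValidationError(
                f"missing abiotic values for variables used in inference: {bad}"
            )
        return df


@dataclass
class SeqSimilarityMatrix:
    """Symmetric pairwise 16S sequence-identity matrix over OTU ids."""

    identity: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.identity
        if list(df.index) != list(df.columns):
            raise ValidationError("identity matrix index and columns differ")
        arr = df.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-9):
            raise ValidationError("identity matrix is not symmetric")
        if not np.allclose(np.diag(arr), 1.0):
            raise ValidationError("identity matrix diagonal is not 1")
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise ValidationError("identity values outside [0, 1]")

    def lookup(self, a: str, b: str) -> float:
        return float(self.identity.at[a, b])


@dataclass
class Rule:
    """One taxon-pattern -> function-category rule at a stated rank."""

    rank: str
    pattern: str
    category: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValidationError("empty rule pattern")
        if self.rank not in TAXONOMIC_RANKS:
            raise ValidationError(f"unknown rank {self.rank!r}")


@dataclass
class RuleSet:
    """Collection of taxonomy->function annotation rules."""

    rules: list[Rule] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rule in self.rules:
            key = (rule.pattern, rule.category)
            if key in seen:
                raise ValidationError(f"duplicate rule {key}")
            seen.add(key)

    @property
    def categories(self) -> list[str]:
        out: list[str] = []
        for rule in self.rules:
            if rule.category not in out:
                out.append(rule.category)
        return out

    def __len__(self) -> int:
        return len(self.rules)


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    characteristic_path_length: float
    density: float
    heterogeneity: float
    degree_sequence: list[int]
    degree_distribution_verdict: str = "inconclusive"


class CooccurrenceNetwork:
    """Undirected signed graph over OTU and VARIABLE nodes.

    Thin wrapper around :class:`networkx.Graph`.  Node attributes: ``kind``
    (OTU/VARIABLE), ``taxonomy`` (OTU only), optional ``core``/``centrality``/
    ``abundant`` flags.  Edge attributes: ``sign`` (copresence/exclusion),
    ``scores`` (per-measure observed score), ``pvalues`` (per-measure
    permutation p), ``q`` (merged BH q-value).
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self.validate()

    def validate(self) -> None:
        g = self.graph
        if any(u == v for u, v in g.edges()):
            raise ValidationError("self-loop in network")
        for u, v, data in g.edges(data=True):
            q = data.get("q")
            if q is not None and not (0.0 <= q <= 1.0):
                raise ValidationError(f"q-value outside [0,1] on edge ({u},{v})")
            sign = data.get("sign")
            if sign is not None and sign not in (SIGN_COPRESENCE, SIGN_EXCLUSION):
                raise ValidationError(f"unknown edge sign {sign!r}")

    # -- construction ----------------------------------------------------
    def add_otu_node(self, otu_id: str, taxonomy: str = "", **attrs) -> None:
        self.graph.add_node(otu_id, kind=OTU_KIND, taxonomy=taxonomy, **attrs)

    def add_variable_node(self, name: str, **attrs) -> None:
        self.graph.add_node(name, kind=VARIABLE_KIND, **attrs)

    def add_edge(self, u: str, v: str, sign: str, **attrs) -> None:
        if u == v:
            raise ValidationError("self-loop edge rejected")
        if sign not in (SIGN_COPRESENCE, SIGN_EXCLUSION):
            raise ValidationError(f"unknown edge sign {sign!r}")
        self.graph.add_edge(u, v, sign=sign, **attrs)

    # -- accessors -------------------------------------------------------
    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind]

    @property
    def otu_nodes(self) -> list[str]:
        return self.nodes_of_kind(OTU_KIND)

    @property
    def variable_nodes(self) -> list[str]:
        return self.nodes_of_kind(VARIABLE_KIND)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_sign_counts(self) -> dict[str, int]:
        out = {SIGN_COPRESENCE: 0, SIGN_EXCLUSION: 0}
        for _, _, data in self.graph.edges(data=True):
            sign = data.get("sign")
            if sign in out:
                out[sign] += 1
        return out

    def edges_as_set(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges()}

    def copy(self) -> "CooccurrenceNetwork":
        return CooccurrenceNetwork(self.graph.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CooccurrenceNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class EdgeTestResult:
    """Permutation + bootstrap evidence for one candidate edge and measure."""

    measure: str
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    ci_low: float
    ci_high: float
    killed: bool = False

    @property
    def observed_outside_ci(self) -> bool:
        return not (self.ci_low <= self.observed <= self.ci_high)


@dataclass
class AlignmentResult:
    """Injective node mapping between two networks with quality scores."""

    alpha: float
    mapping: dict[str, str]
    node_scores: dict[str, float]
    ec: float | None
    ss: float | None
    conserved_edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        targets = list(self.mapping.values())
        if len(set(targets)) != len(targets):
            raise ValidationError("alignment mapping is not injective")
        for score in (self.ec, self.ss):
            if score is not None and not (0.0 <= score <= 100.0):
                raise ValidationError("EC/SS outside [0, 100]")

    @property
    def n_aligned(self) -> int:
        return len(self.mapping)

    @property
    def n_aligned_to_self(self) -> int:
        return sum(1 for u, v in self.mapping.items() if u == v)


@dataclass
class CoreDecomposition:
    core: set[str]
    noncore1: set[str]
    noncore2: set[str]

    def __post_init__(self) -> None:
        if self.core & self.noncore1 or self.core & self.noncore2:
            raise ValidationError("core and noncore sets overlap")


@dataclass
class FunctionProfile:
    """Per-category relative-abundance shares for a group of OTUs.

    ``per_site`` holds one row per site and one column per category; shares
    are fractions of whole-sample abundance, so an OTU carrying several
    category labels contributes to each and columns need not sum to one.
    """

    group: str
    per_site: pd.DataFrame
    mean: pd.Series = field(init=False)
    sd: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if (self.per_site.to_numpy() < -1e-12).any():
            raise ValidationError("negative function share")
        self.mean = self.per_site.mean(axis=0)
        self.sd = self.per_site.std(axis=0, ddof=1)
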