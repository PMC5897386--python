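"""Core/noncore decomposition, node characterisation and rule-based
functional profiling.

Core OTUs are those present in both section networks; noncore OTUs belong to
exactly one.  Node flags follow the conventions used for annotated network
figures: hubs are the top decile of degree centrality within a network,
abundant OTUs exceed 0.1% mean relative abundance, and an OTU is
environment-correlated with a variable when its correlation is significant
(p < 0.05) and |rho| reaches the 90th percentile of the significant values.
Function profiles assign each OTU the categories whose taxon rules match its
lineage and report, per site, the summed relative abundance of the group's
OTUs carrying each category (denominator: whole-sample abundance).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CooccurrenceNetwork,
    CoreDecomposition,
    FunctionProfile,
    OtuTable,
    RuleSet,
    ValidationError,
)
from .profiles import env_correlation, relative_abundance

_RANK_PREFIX = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
}


# ---------------------------------------------------------------------------
# Core / noncore
# ---------------------------------------------------------------------------

def core_decompose(
    net1: CooccurrenceNetwork, net2: CooccurrenceNetwork
) -> CoreDecomposition:
    """Set intersection/differences over OTU-kind nodes (variables excluded)."""
    s1, s2 = set(net1.otu_nodes), set(net2.otu_nodes)
    return CoreDecomposition(core=s1 & s2, noncore1=s1 - s2, noncore2=s2 - s1)


def aligned_to_self(result, core: set[str]) -> tuple[int, float]:
    """Count and fraction of core OTUs mapped to themselves by an alignment.

    An empty core leaves the fraction undefined (nan)."""
    count = sum(1 for u, v in result.mapping.items() if u == v and u in core)
    fraction = count / len(core) if core else float("nan")
    return count, fraction


# ---------------------------------------------------------------------------
# Node flags
# ---------------------------------------------------------------------------

@dataclass
class NodeFlags:
    is_hub: dict[str, bool]
    is_abundant: dict[str, bool]
    env_correlated: dict[str, set[str]] = field(default_factory=dict)


def flag_nodes(
    net: CooccurrenceNetwork,
    table: OtuTable,
    abiotic=None,
    decile: float = 0.10,
    abundance_cut: float = 0.001,
    p_threshold: float = 0.05,
) -> NodeFlags:
    """Hub / abundance / environment-correlation flags for a network's OTUs."""
    otus = net.otu_nodes
    missing = [o for o in otus if o not in table.counts.index]
    if missing:
        raise ValidationError(f"abundance table misses network OTUs: {missing[:5]}")
    # strictly above the (1 - decile) quantile, so that in a star of 11 nodes
    # only the centre qualifies at the default decile
    degrees = {o: net.graph.degree(o) for o in otus}
    cutoff = np.quantile(list(degrees.values()), 1.0 - decile) if otus else 0.0
    is_hub = {o: degrees[o] > cutoff for o in otus}

    rel = relative_abundance(table)
    mean_rel = rel.loc[otus].mean(axis=1)
    is_abundant = {o: bool(mean_rel[o] > abundance_cut) for o in otus}

    env: dict[str, set[str]] = {o: set() for o in otus}
    if abiotic is not None:
        samples = table.sample_ids
        for var in abiotic.variables:
            v = abiotic.values.loc[var, samples].to_numpy(dtype=float)
            rhos, pvals = {}, {}
            for o in otus:
                rho, p = env_correlation(rel.loc[o, samples].to_numpy(), v)
                rhos[o], pvals[o] = rho, p
            significant = [o for o in otus if np.isfinite(pvals[o]) and pvals[o] < p_threshold]
            if not significant:
                continue
            thr = np.quantile([abs(rhos[o]) for o in significant], 1.0 - decile)
            for o in significant:
                if abs(rhos[o]) >= thr:
                    env[o].add(var)
    return NodeFlags(is_hub=is_hub, is_abundant=is_abundant, env_correlated=env)


# ---------------------------------------------------------------------------
# Function rules
# ---------------------------------------------------------------------------

def apply_rules(rules: RuleSet, taxonomy: pd.Series) -> dict[str, set[str]]:
    """Map each OTU to the function categories whose rule pattern matches its
    lineage at the rule's rank.  Multiple categories per OTU are allowed."""
    parsed: dict[str, dict[str, str]] = {}
    for otu, lineage in taxonomy.items():
        fields = {}
        for part in str(lineage).split(";"):
            part = part.strip()
            m = re.match(r"([kpcofg])__(.*)", part)
            if m:
                fields[m.group(1)] = part
        parsed[otu] = fields
    labels: dict[str, set[str]] = {otu: set() for otu in taxonomy.index}
    for rule in rules.rules:
        prefix = _RANK_PREFIX[rule.rank]
        key = prefix[0]
        pattern = rule.pattern if rule.pattern.startswith(prefix) else prefix + rule.pattern
        for otu, fields in parsed.items():
            if fields.get(key) == pattern:
                labels[otu].add(rule.category)
    return labels


def function_profile(
    otu_set,
    table: OtuTable,
    labels: dict[str, set[str] | list[str]],
    sites,
    group: str = "",
    categories=None,
    normalize: str = "sample",
) -> FunctionProfile:
    """Per-site function-category shares of a set of OTUs.

    For each site, a category's share is the summed relative abundance
    (averaged over the site's replicates) of the set's OTUs labelled with
    that category.  With ``normalize='sample'`` (default) the denominator is
    whole-sample abundance, so shares of disjoint sets add up; with
    ``normalize='set'`` it is the set's own abundance, so the community value
    is a weighted mixture of its subgroups' values.
    """
    if normalize not in ("sample", "set"):
        raise ValidationError(f"unknown normalization {normalize!r}")
    otu_set = [o for o in otu_set if o in table.counts.index]
    rel = relative_abundance(table)
    if normalize == "set" and otu_set:
        set_total = rel.loc[otu_set].sum(axis=0)
        rel = rel / set_total
    meta = table.sample_meta.loc[table.sample_ids]
    if categories is None:
        categories = sorted({c for cats in labels.values() for c in cats})
    by_cat = {
        c: [o for o in otu_set if c in labels.get(o, ())] for c in categories
    }
    rows = {}
    for site in sites:
        samples = list(meta.index[meta["site"] == site])
        if not samples:
            raise ValidationError(f"no samples for site {site}")
        rows[site] = {
            c: float(rel.loc[by_cat[c], samples].to_numpy().sum(axis=0).mean())
            if by_cat[c]
            else 0.0
            for c in categories
        }
    per_site = pd.DataFrame.from_dict(rows, orient="index")[list(categories)]
    return FunctionProfile(group=group, per_site=per_site)


def compare_profiles(groups: list[FunctionProfile]) -> pd.DataFrame:
    """Per-category tests across groups: one-way ANOVA for >= 3 groups plus
    the pairwise two-sample t-test for two; p-values reported uncorrected.
    Categories with zero variance in every group are skipped (flagged)."""
    if len(groups) < 2:
        raise ValidationError("need at least two profiles to compare")
    categories = sorted(set().union(*(set(g.per_site.columns) for g in groups)))
    rows = []
    for cat in categories:
        samples = [
            g.per_site[cat].to_numpy() if cat in g.per_site.columns else np.zeros(len(g.per_site))
            for g in groups
        ]
        if any(len(s) < 2 for s in samples):
            raise ValidationError("need >= 2 sites per group")
        if all(np.allclose(s, s.mean()) for s in samples):
            rows.append(
                {"category": cat, "test": "skipped", "statistic": np.nan, "p": np.nan}
            )
            continue
        if len(groups) >= 3:
            stat, p = stats.f_oneway(*samples)
            rows.append({"category": cat, "test": "anova", "statistic": stat, "p": p})
        else:
            stat, p = stats.ttest_ind(samples[0], samples[1])
            rows.append({"category": cat, "test": "t-test", "statistic": stat, "p": p})
    return pd.DataFrame(rows).set_index("category")


def phylum_core_shares(
    decomposition: CoreDecomposition, taxonomy: pd.Series
) -> pd.DataFrame:
    """Per-phylum core composition reported both ways, since the natural
    denominator is ambiguous: core OTUs of the phylum over the phylum's
    network OTUs (``core_per_phylum``) and over all core OTUs
    (``phylum_per_core``)."""
    def phylum_of(otu):
        m = re.search(r"p__([^;]+)", str(taxonomy.get(otu, "")))
        return m.group(1).strip() if m else "unknown"

    all_otus = decomposition.core | decomposition.noncore1 | decomposition.noncore2
    rows = {}
    for phylum in sorted({phylum_of(o) for o in all_otus}):
        members = {o for o in all_otus if phylum_of(o) == phylum}
        core_members = members & decomposition.core
        rows[phylum] = {
            "n_network_otus": len(members),
            "n_core": len(core_members),
            "core_per_phylum": len(core_members) / len(members) if members else np.nan,
            "phylum_per_core": (
                len(core_members) / len(decomposition.core)
                if decomposition.core
                else np.nan
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
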