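"""Signed co-occurrence network inference by multi-measure ensemble scoring.

Procedure (per section): drop OTUs occurring in fewer than ``minocc``
samples; score every eligible node pair with four measures — Pearson and
Spearman correlation of relative-abundance profiles, Bray-Curtis and
symmetrised Kullback-Leibler dissimilarity of per-OTU normalized profiles;
rank each measure and keep the pairs that fall in every applicable measure's
strongest ``n_pos`` co-presence / ``n_neg`` exclusion selections; test each
candidate with renormalized permutation and bootstrap resampling; merge the
per-measure permutation p-values with Brown's method and control the FDR
across edges by Benjamini-Hochberg.

The permutation null shuffles one member's counts across samples and then
restores the compositional totals (each sample's denominator becomes
``total - x + x_permuted``) before recomputing the measure, so the null
carries the same compositional coupling as the observed score.  Abiotic
variable profiles are z-standardized and excluded from the renormalization:
they are measurements, not counts.  Pairs involving a variable are scored
with the two correlation measures only, since dissimilarities of signed
z-scores are not meaningful.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq, minimize_scalar
from statsmodels.stats.multitest import multipletests

from .containers import (
    DEFAULT_NETWORK_VARIABLES,
    SIGN_COPRESENCE,
    SIGN_EXCLUSION,
    AbioticTable,
    CooccurrenceNetwork,
    EdgeTestResult,
    NetworkStats,
    OtuTable,
    ValidationError,
)
from .profiles import filter_min_samples

MEASURES = ("pearson", "spearman", "bray_curtis", "kullback_leibler")
CORRELATION_MEASURES = ("pearson", "spearman")
DISSIMILARITY_MEASURES = ("bray_curtis", "kullback_leibler")


# ---------------------------------------------------------------------------
# Pairwise measures
# ---------------------------------------------------------------------------

def pair_score(x, y, measure: str) -> float:
    """Score one pair of profiles with a single measure.

    Correlations are computed on the profiles as given; Bray-Curtis on
    per-profile normalized vectors; Kullback-Leibler symmetrised,
    ``0.5*[KL(p||q) + KL(q||p)]``, on +1-pseudocounted normalized profiles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("profiles must have equal length >= 4")
    if measure == "pearson":
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise ValidationError("constant profile: correlation undefined")
        return float(stats.pearsonr(x, y)[0])
    if measure == "spearman":
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise ValidationError("constant profile: correlation undefined")
        return float(stats.spearmanr(x, y)[0])
    if measure == "bray_curtis":
        u = x / x.sum() if x.sum() > 0 else x
        v = y / y.sum() if y.sum() > 0 else y
        return float(0.5 * np.abs(u - v).sum())
    if measure == "kullback_leibler":
        p = (x + 1.0) / (x + 1.0).sum()
        q = (y + 1.0) / (y + 1.0).sum()
        return float(0.5 * (np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))))
    raise ValidationError(f"unknown measure {measure!r}")


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching rows of two (r x n) arrays."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return _rowwise_pearson(
        stats.rankdata(a, axis=1), stats.rankdata(b, axis=1)
    )


def _rowwise_bray_curtis(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    asum = a.sum(axis=1, keepdims=True)
    bsum = b.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(asum > 0, a / asum, a)
        v = np.where(bsum > 0, b / bsum, b)
    return 0.5 * np.abs(u - v).sum(axis=1)


def _rowwise_sym_kl(a_counts: np.ndarray, b_counts: np.ndarray) -> np.ndarray:
    p = a_counts + 1.0
    p = p / p.sum(axis=1, keepdims=True)
    q = b_counts + 1.0
    q = q / q.sum(axis=1, keepdims=True)
    logr = np.log(p) - np.log(q)
    return 0.5 * ((p * logr).sum(axis=1) - (q * logr).sum(axis=1))


# ---------------------------------------------------------------------------
# Scoring context
# ---------------------------------------------------------------------------

@dataclass
class _Context:
    """Precomputed per-section matrices shared by candidate selection and
    edge testing."""

    names: list[str]
    is_variable: np.ndarray
    counts: np.ndarray  # OTU rows only (m x n)
    totals: np.ndarray
    rel: np.ndarray
    var_values: np.ndarray  # z-scored variable rows (k x n)
    taxonomy: dict[str, str]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def profile(self, i: int) -> np.ndarray:
        """Correlation profile of node i (relative abundance or z-score)."""
        if self.is_variable[i]:
            return self.var_values[i - self.n_otus]
        return self.rel[i]


def make_context(
    table: OtuTable,
    abiotic: AbioticTable | None = None,
    variables=DEFAULT_NETWORK_VARIABLES,
) -> _Context:
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValidationError(f"zero-total sample(s): {bad}")
    rel = counts / totals
    names = list(table.otu_ids)
    var_rows = []
    var_names = []
    if abiotic is not None:
        sub = abiotic.subset(variables, table.sample_ids)
        for var in sub.index:
            vals = sub.loc[var].to_numpy(dtype=float)
            sd = vals.std(ddof=0)
            var_rows.append((vals - vals.mean()) / sd if sd > 0 else vals * 0.0)
            var_names.append(var)
    var_values = np.array(var_rows) if var_rows else np.empty((0, counts.shape[1]))
    is_variable = np.array([False] * len(names) + [True] * len(var_names))
    return _Context(
        names=names + var_names,
        is_variable=is_variable,
        counts=counts,
        totals=totals,
        rel=rel,
        var_values=var_values,
        taxonomy={o: t for o, t in zip(table.otu_ids, table.taxonomy)},
    )


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    u: str
    v: str
    i: int
    j: int
    sign: str
    measures: tuple[str, ...]
    observed: dict[str, float]


def select_candidates(
    table: OtuTable,
    abiotic: AbioticTable | None = None,
    n_pos: int = 1000,
    n_neg: int = 1000,
    minocc: int = 10,
    variables=DEFAULT_NETWORK_VARIABLES,
) -> list[Candidate]:
    """Rank all eligible pairs under every measure and keep the pairs found in
    each applicable measure's strongest ``n_pos`` co-presence / ``n_neg``
    exclusion selections, tagged with the agreed sign.

    OTU rows occurring in fewer than ``minocc`` samples are removed first.
    OTU-OTU pairs require agreement of all four measures; pairs involving an
    abiotic variable use Pearson and Spearman only.
    """
    occ = (table.counts > 0).sum(axis=1)
    kept = list(table.counts.index[occ >= minocc])
    table = table.subset_otus(kept)
    ctx = make_context(table, abiotic, variables)
    m = ctx.n_otus
    n_nodes = len(ctx.names)

    profiles = np.vstack([ctx.rel, ctx.var_values]) if ctx.var_values.size else ctx.rel
    sd = profiles.std(axis=1)
    valid = sd > 0

    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = np.corrcoef(profiles)
        spearman = np.corrcoef(stats.rankdata(profiles, axis=1))
    for mat in (pearson, spearman):
        mat[~valid, :] = np.nan
        mat[:, ~valid] = np.nan

    # dissimilarities among OTUs only
    p_norm = ctx.rel / np.maximum(ctx.rel.sum(axis=1, keepdims=True), 1e-300)
    bc = 0.5 * np.abs(p_norm[:, None, :] - p_norm[None, :, :]).sum(axis=2)
    qc = ctx.counts + 1.0
    qc = qc / qc.sum(axis=1, keepdims=True)
    a_mat = qc @ np.log(qc).T
    kl = 0.5 * (np.diag(a_mat)[:, None] - a_mat + np.diag(a_mat)[None, :] - a_mat.T)

    iu, ju = np.triu_indices(n_nodes, k=1)
    pair_is_otu = (iu < m) & (ju < m)

    def top_pairs(values: np.ndarray, n: int, largest: bool) -> set[int]:
        finite = np.flatnonzero(np.isfinite(values))
        if finite.size == 0:
            return set()
        if finite.size < n:
            warnings.warn(
                f"only {finite.size} rankable pairs available for a threshold "
                f"of {n}; using all",
                stacklevel=3,
            )
            return set(finite)
        vals = values[finite]
        order = np.argsort(-vals if largest else vals, kind="stable")
        return set(finite[order[:n]])

    pearson_f = pearson[iu, ju]
    spearman_f = spearman[iu, ju]
    bc_f = np.where(pair_is_otu, bc[np.minimum(iu, m - 1), np.minimum(ju, m - 1)], np.nan)
    kl_f = np.where(pair_is_otu, kl[np.minimum(iu, m - 1), np.minimum(ju, m - 1)], np.nan)

    pos_sets = {
        "pearson": top_pairs(pearson_f, n_pos, largest=True),
        "spearman": top_pairs(spearman_f, n_pos, largest=True),
        "bray_curtis": top_pairs(bc_f, n_pos, largest=False),
        "kullback_leibler": top_pairs(kl_f, n_pos, largest=False),
    }
    neg_sets = {
        "pearson": top_pairs(pearson_f, n_neg, largest=False),
        "spearman": top_pairs(spearman_f, n_neg, largest=False),
        "bray_curtis": top_pairs(bc_f, n_neg, largest=True),
        "kullback_leibler": top_pairs(kl_f, n_neg, largest=True),
    }

    candidates: list[Candidate] = []
    for idx in range(iu.size):
        i, j = int(iu[idx]), int(ju[idx])
        measures = MEASURES if pair_is_otu[idx] else CORRELATION_MEASURES
        in_pos = all(idx in pos_sets[ms] for ms in measures)
        in_neg = all(idx in neg_sets[ms] for ms in measures)
        if in_pos == in_neg:  # neither, or contradictory
            continue
        # sign conservation: both correlations must agree with the tag
        pr, sr = pearson_f[idx], spearman_f[idx]
        if in_pos and not (pr > 0 and sr > 0):
            continue
        if in_neg and not (pr < 0 and sr < 0):
            continue
        observed = {"pearson": float(pr), "spearman": float(sr)}
        if pair_is_otu[idx]:
            observed["bray_curtis"] = float(bc_f[idx])
            observed["kullback_leibler"] = float(kl_f[idx])
        candidates.append(
            Candidate(
                u=ctx.names[i],
                v=ctx.names[j],
                i=i,
                j=j,
                sign=SIGN_COPRESENCE if in_pos else SIGN_EXCLUSION,
                measures=tuple(measures),
                observed=observed,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# ReBoot-style edge testing
# ---------------------------------------------------------------------------

def _gaussian_p(obs: float, null: np.ndarray) -> tuple[float, float, float]:
    null = null[np.isfinite(null)]
    if null.size < 10:
        return np.nan, np.nan, 1.0
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0:
        return mu, sd, 1.0 if obs == mu else 0.0
    z = (obs - mu) / sd
    return mu, sd, float(special.erfc(abs(z) / np.sqrt(2.0)))


def _empirical_p(obs: float, null: np.ndarray) -> float:
    null = null[np.isfinite(null)]
    if null.size == 0:
        return 1.0
    mu = null.mean()
    extreme = np.sum(np.abs(null - mu) >= abs(obs - mu))
    return float((1 + extreme) / (null.size + 1))


def _measure_rows(measure, kind, xk, yk, totals_k):
    """Measure value per resample row.

    ``xk``/``yk`` are (r x n) count rows for OTUs, value rows for variables;
    ``totals_k`` the matching renormalized column totals (None for
    variable-variable pairs).
    """
    if kind == "otu-otu":
        px, py = xk / totals_k, yk / totals_k
        if measure == "pearson":
            return _rowwise_pearson(px, py)
        if measure == "spearman":
            return _rowwise_spearman(px, py)
        if measure == "bray_curtis":
            return _rowwise_bray_curtis(px, py)
        if measure == "kullback_leibler":
            return _rowwise_sym_kl(xk, yk)
        raise ValidationError(f"unknown measure {measure!r}")
    # variable profiles are used as-is
    px = xk / totals_k if totals_k is not None else xk
    if measure == "pearson":
        return _rowwise_pearson(px, yk)
    if measure == "spearman":
        return _rowwise_spearman(px, yk)
    raise ValidationError(f"measure {measure!r} not defined for variable pairs")


def _reboot_pair(
    x: np.ndarray,
    y: np.ndarray,
    totals: np.ndarray | None,
    kind: str,
    measures,
    n: int,
    rng,
    empirical: bool = False,
) -> dict[str, EdgeTestResult]:
    """Permutation + bootstrap evidence for one pair, all measures at once.

    ``kind``: ``otu-otu`` (x, y counts; renormalized), ``otu-var`` (x counts
    renormalized, y z-values fixed) or ``var-var`` (both plain values).
    """
    nsamp = x.size
    perm_idx = np.argsort(rng.random((n, nsamp)), axis=1)
    boot_idx = rng.integers(0, nsamp, size=(n, nsamp))

    if kind in ("otu-otu", "otu-var"):
        # depth-matched permutation: shuffle the OTU's relative abundances
        # across samples, regenerate counts binomially at each sample's
        # sequencing depth (so unequal depths keep their own noise scale),
        # then restore the compositional totals
        rel = x / totals
        xp = rng.binomial(totals.astype(np.int64)[None, :], rel[perm_idx])
        t2 = totals[None, :] - x[None, :] + xp
    else:
        xp = x[perm_idx]
        t2 = None
    yb_fixed = np.broadcast_to(y, (n, nsamp))

    xb = x[boot_idx]
    yb = y[boot_idx]
    tb = totals[boot_idx] if totals is not None else None

    x1 = x[None, :]
    y1 = y[None, :]
    t1 = totals[None, :] if totals is not None else None

    results: dict[str, EdgeTestResult] = {}
    for measure in measures:
        obs = float(_measure_rows(measure, kind, x1, y1, t1)[0])
        null = _measure_rows(measure, kind, xp, yb_fixed, t2)
        mu, sd, p = _gaussian_p(obs, null)
        if empirical:
            p = _empirical_p(obs, null)
        boot = _measure_rows(measure, kind, xb, yb, tb)
        boot = boot[np.isfinite(boot)]
        if boot.size >= 10:
            lo, hi = np.percentile(boot, [2.5, 97.5])
        else:
            lo, hi = -np.inf, np.inf
        killed = bool(np.isfinite(mu) and lo <= mu <= hi)
        results[measure] = EdgeTestResult(
            measure=measure,
            observed=obs,
            null_mean=mu,
            null_sd=sd,
            p_value=p,
            ci_low=float(lo),
            ci_high=float(hi),
            killed=killed,
        )
    return results


def reboot_edge_test(
    x,
    y,
    measure: str = "pearson",
    n: int = 1000,
    seed: int = 0,
    totals=None,
    kind: str = "otu-otu",
    empirical: bool = False,
) -> EdgeTestResult:
    """Renormalized permutation + bootstrap test for one candidate pair.

    ``x``/``y`` are count profiles (OTUs) or value profiles (variables);
    ``totals`` the per-sample column totals of the full table (defaults to
    ``x + y`` for a stand-alone pair, which treats the pair as its own
    compositional context).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if totals is None and kind != "var-var":
        totals = x + y
    else:
        totals = np.asarray(totals, dtype=float) if totals is not None else None
    rng = np.random.default_rng(seed)
    return _reboot_pair(x, y, totals, kind, (measure,), n, rng, empirical)[measure]


# ---------------------------------------------------------------------------
# Merging and correction
# ---------------------------------------------------------------------------

def _brown_merge(pmat: np.ndarray) -> np.ndarray:
    """Merge each row of p-values with Brown's method (Fisher with an
    empirical covariance correction across the measure columns)."""
    k = pmat.shape[1]
    chi = -2.0 * np.log(np.clip(pmat, 1e-300, 1.0))
    stat = chi.sum(axis=1)
    if k == 1:
        return pmat[:, 0]
    if pmat.shape[0] >= 10:
        cov = np.cov(chi, rowvar=False)
        var = 4.0 * k + 2.0 * np.triu(cov, 1).sum()
        var = max(var, 1e-9)
    else:
        var = 4.0 * k  # too few edges to estimate covariance: plain Fisher
    mean = 2.0 * k
    c = var / (2.0 * mean)
    df = 2.0 * mean**2 / var
    return stats.chi2.sf(stat / c, df)


def merge_and_correct(
    edge_tests: list[dict[str, EdgeTestResult]],
    alpha: float = 0.05,
    drop_killed: bool = True,
) -> pd.DataFrame:
    """Brown-merge per-edge measure p-values, then Benjamini-Hochberg across
    edges.  Returns a frame with merged p, q and a ``keep`` flag (q < alpha
    and at least one non-killed measure)."""
    merged = np.ones(len(edge_tests))
    alive = np.zeros(len(edge_tests), dtype=bool)
    groups: dict[tuple[str, ...], list[int]] = {}
    pvals: list[dict[str, float]] = []
    for e, tests in enumerate(edge_tests):
        usable = {
            ms: t for ms, t in tests.items() if not (drop_killed and t.killed)
        }
        pvals.append({ms: t.p_value for ms, t in usable.items()})
        if usable:
            alive[e] = True
            groups.setdefault(tuple(sorted(usable)), []).append(e)
    for measures, idx in groups.items():
        pmat = np.array([[pvals[e][ms] for ms in measures] for e in idx])
        merged[np.array(idx)] = _brown_merge(pmat)
    if len(merged):
        _, qvals, _, _ = multipletests(merged, alpha=alpha, method="fdr_bh")
    else:
        qvals = merged
    return pd.DataFrame(
        {
            "p_merged": merged,
            "q": qvals,
            "keep": alive & (qvals < alpha),
        }
    )


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _pair_seed(seed: int, u: str, v: str) -> int:
    return (int(seed) * 31 + zlib.crc32(f"{u}|{v}".encode())) % (2**31 - 1)


def build_network(
    table: OtuTable,
    abiotic: AbioticTable | None = None,
    section: int | None = None,
    variables=DEFAULT_NETWORK_VARIABLES,
    min_samples: int = 5,
    minocc: int = 10,
    n_pos: int = 1000,
    n_neg: int = 1000,
    n_perm: int = 1000,
    q_threshold: float = 0.05,
    seed: int = 0,
    empirical_p: bool = False,
    drop_isolated: bool = True,
) -> CooccurrenceNetwork:
    """Infer one section's signed co-occurrence network end to end.

    When ``drop_isolated`` is set (default), only nodes incident to at least
    one retained edge appear in the network, matching how deposited
    co-occurrence networks are reported; with it unset, every OTU surviving
    the filters plus every configured variable is a node.
    """
    if section is not None:
        table = table.section_slice(section)
    table = filter_min_samples(table, min_samples)
    candidates = select_candidates(
        table, abiotic, n_pos=n_pos, n_neg=n_neg, minocc=minocc, variables=variables
    )
    occ = (table.counts > 0).sum(axis=1)
    surviving = list(table.counts.index[occ >= minocc])
    ctx = make_context(table.subset_otus(surviving), abiotic, variables)

    tests: list[dict[str, EdgeTestResult]] = []
    for cand in candidates:
        kind = _pair_kind(ctx, cand)
        x, y, totals = _pair_profiles(ctx, cand, kind)
        rng = np.random.default_rng(_pair_seed(seed, cand.u, cand.v))
        tests.append(
            _reboot_pair(x, y, totals, kind, cand.measures, n_perm, rng, empirical_p)
        )
    verdicts = merge_and_correct(tests, alpha=q_threshold)

    net = CooccurrenceNetwork()
    if not drop_isolated:
        for otu in surviving:
            net.add_otu_node(otu, taxonomy=ctx.taxonomy.get(otu, ""))
        for var in ctx.names[ctx.n_otus :]:
            net.add_variable_node(var)
    for k, cand in enumerate(candidates):
        if not verdicts["keep"].iloc[k]:
            continue
        for node in (cand.u, cand.v):
            if node in ctx.taxonomy:
                net.add_otu_node(node, taxonomy=ctx.taxonomy[node])
            else:
                net.add_variable_node(node)
        net.add_edge(
            cand.u,
            cand.v,
            sign=cand.sign,
            scores=cand.observed,
            pvalues={ms: t.p_value for ms, t in tests[k].items()},
            q=float(verdicts["q"].iloc[k]),
        )
    if not candidates or net.n_edges == 0:
        warnings.warn("no edge survived permutation testing and FDR control")
    return net


def _pair_kind(ctx: _Context, cand: Candidate) -> str:
    iv, jv = ctx.is_variable[cand.i], ctx.is_variable[cand.j]
    if iv and jv:
        return "var-var"
    if iv or jv:
        return "otu-var"
    return "otu-otu"


def _pair_profiles(ctx: _Context, cand: Candidate, kind: str):
    if kind == "otu-otu":
        return ctx.counts[cand.i], ctx.counts[cand.j], ctx.totals
    if kind == "var-var":
        return (
            ctx.var_values[cand.i - ctx.n_otus],
            ctx.var_values[cand.j - ctx.n_otus],
            None,
        )
    # otu-var: the OTU is permuted/renormalized, the variable profile is fixed
    if ctx.is_variable[cand.i]:
        otu_idx, var_idx = cand.j, cand.i
    else:
        otu_idx, var_idx = cand.i, cand.j
    return ctx.counts[otu_idx], ctx.var_values[var_idx - ctx.n_otus], ctx.totals


# ---------------------------------------------------------------------------
# Network statistics
# ---------------------------------------------------------------------------

def network_stats(net: CooccurrenceNetwork, verdict: bool = False) -> NetworkStats:
    """Whole-graph statistics: mean local clustering (0 for degree < 2),
    characteristic path length over reachable pairs, density ``2E/(N(N-1))``
    and degree heterogeneity ``sd(degree)/mean(degree)``."""
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    degrees = [d for _, d in g.degree()]
    clustering = nx.average_clustering(g) if n else 0.0
    total_dist, total_pairs = 0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total_dist += sum(dists.values())
            total_pairs += len(dists) - 1  # excludes the source itself
    path_length = total_dist / total_pairs if total_pairs else float("nan")
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    mean_deg = np.mean(degrees) if degrees else 0.0
    heterogeneity = float(np.std(degrees) / mean_deg) if mean_deg > 0 else 0.0
    stats_ = NetworkStats(
        n_nodes=n,
        n_edges=e,
        clustering_coefficient=float(clustering),
        characteristic_path_length=float(path_length),
        density=float(density),
        heterogeneity=heterogeneity,
        degree_sequence=sorted(degrees, reverse=True),
    )
    if verdict:
        stats_.degree_distribution_verdict = degree_distribution_verdict(net)
    return stats_


def degree_distribution_verdict(net: CooccurrenceNetwork | list[int]) -> str:
    """Classify the degree distribution as Erdos-Renyi-like (Poisson) or
    power-law-like by a normalized log-likelihood-ratio test on degrees >= 1
    (zero-truncated Poisson vs discrete power law with xmin = 1);
    ``inconclusive`` when fewer than 30 nodes or |normalized LR| < 2."""
    if isinstance(net, CooccurrenceNetwork):
        degrees = np.array([d for _, d in net.graph.degree()])
    else:
        degrees = np.asarray(net)
    if degrees.size < 30:
        return "inconclusive"
    d = degrees[degrees >= 1].astype(float)
    if d.size < 30 or np.all(d == d[0]):
        return "inconclusive"
    m = d.mean()

    lam = brentq(lambda L: L / (1.0 - np.exp(-L)) - m, 1e-9, max(10.0, 3 * m))
    ll_pois = (
        d * np.log(lam) - lam - special.gammaln(d + 1) - np.log(1.0 - np.exp(-lam))
    )

    def neg_ll_zeta(a: float) -> float:
        return float(a * np.log(d).sum() + d.size * np.log(special.zeta(a, 1)))

    res = minimize_scalar(neg_ll_zeta, bounds=(1.01, 12.0), method="bounded")
    a_hat = float(res.x)
    ll_pl = -a_hat * np.log(d) - np.log(special.zeta(a_hat, 1))

    # sign test on the per-node log-likelihood differences: robust to the
    # huge single-point contributions a heavy tail produces
    diff = ll_pois - ll_pl
    n_pos = int((diff > 0).sum())
    n_neg = int((diff < 0).sum())
    n_inf = n_pos + n_neg
    if n_inf == 0:
        return "inconclusive"
    norm_lr = (n_pos - n_neg) / np.sqrt(n_inf)
    if abs(norm_lr) < 2.0:
        return "inconclusive"
    return "erdos-renyi-like" if norm_lr > 0 else "power-law-like"


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------

def randomize_network(net: CooccurrenceNetwork, seed: int = 0) -> CooccurrenceNetwork:
    """Edge-shuffling null: as many moves as there are edges; each move picks
    a random edge (n_i, n_j) and re-draws it between two random nodes other
    than n_i and n_j, rejecting self-loops and duplicate edges.  Node set and
    edge count are preserved."""
    rng = np.random.default_rng(seed)
    g = net.graph.copy()
    nodes = sorted(g.nodes())
    n_moves = g.number_of_edges()
    if n_moves == 0 or len(nodes) < 4:
        return CooccurrenceNetwork(g)
    edges = [(u, v, data) for u, v, data in g.edges(data=True)]
    present = {frozenset((u, v)) for u, v, _ in edges}
    for _ in range(n_moves):
        k = int(rng.integers(len(edges)))
        u, v, data = edges[k]
        for _attempt in range(1000):
            i, j = rng.choice(len(nodes), size=2, replace=False)
            a, b = nodes[int(i)], nodes[int(j)]
            if a in (u, v) or b in (u, v) or frozenset((a, b)) in present:
                continue
            present.discard(frozenset((u, v)))
            present.add(frozenset((a, b)))
            edges[k] = (a, b, data)
            break
    g.remove_edges_from(list(g.edges()))
    for u, v, data in edges:
        g.add_edge(u, v, **data)
    return CooccurrenceNetwork(g)
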