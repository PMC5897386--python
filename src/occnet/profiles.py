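"""Pre-network filtering and diversity statistics.

The pipeline applies, in order: the replicate-consistency filter (an OTU must
be seen in at least two of the three replicates of some site), the
occurrence filter (at least five samples), and — inside network inference —
the row occurrence threshold of ten samples.  Rarefaction is used for
diversity only; networks are inferred from unrarefied tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OtuTable, ValidationError


def filter_replicate_consistency(table: OtuTable, min_reps: int = 2) -> OtuTable:
    """Keep OTUs present (count > 0) in >= ``min_reps`` replicates of at least
    one site.  All samples are retained."""
    meta = table.sample_meta.loc[table.sample_ids]
    presence = table.counts.to_numpy() > 0
    keep = np.zeros(len(table.otu_ids), dtype=bool)
    for site, group in meta.groupby("site"):
        cols = [table.sample_ids.index(s) for s in group.index]
        if len(cols) < min_reps:
            raise ValidationError(
                f"site {site} has {len(cols)} replicates, fewer than "
                f"min_reps={min_reps}"
            )
        keep |= presence[:, cols].sum(axis=1) >= min_reps
    kept = [otu for otu, k in zip(table.otu_ids, keep) if k]
    return table.subset_otus(kept)


def filter_min_samples(table: OtuTable, min_samples: int = 5) -> OtuTable:
    """Discard OTUs occurring (count > 0) in fewer than ``min_samples``
    samples of the table passed in."""
    occ = (table.counts > 0).sum(axis=1)
    kept = list(table.counts.index[occ >= min_samples])
    return table.subset_otus(kept)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Column-wise proportions; every sample must have a positive total."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"zero-total sample(s): {zero}")
    return table.counts / totals


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy of one sample's counts (bits by default)."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValidationError("sample total must be positive")
    p = arr[arr > 0] / total
    return float(-np.sum(p * np.log(p)) / np.log(base))


def faith_pd(tree, present_otus) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    subtree spanning the present tips and the root.

    ``tree`` is an skbio TreeNode; tip not found -> error.
    """
    present = set(present_otus)
    if not present:
        return 0.0
    tips = {t.name: t for t in tree.tips()}
    missing = present - set(tips)
    if missing:
        raise ValidationError(f"tips not in tree: {sorted(missing)}")
    counted = set()
    total = 0.0
    for name in present:
        node = tips[name]
        while node is not None and id(node) not in counted:
            counted.add(id(node))
            if node.length is not None:
                total += float(node.length)
            node = node.parent
    return total


@dataclass
class DiversityReport:
    """Per-sample diversity plus rarefaction curves (depth -> mean, sd)."""

    richness: pd.Series
    shannon: pd.Series
    faith_pd: pd.Series | None
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    excluded_samples: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        out = {
            "richness": self.richness.to_dict(),
            "shannon": self.shannon.to_dict(),
            "excluded_samples": list(self.excluded_samples),
        }
        if self.faith_pd is not None:
            out["faith_pd"] = self.faith_pd.to_dict()
        out["curves"] = {
            metric: df.reset_index().to_dict(orient="list")
            for metric, df in self.curves.items()
        }
        return out


def _subsample_without_replacement(counts: np.ndarray, depth: int, rng) -> np.ndarray:
    return rng.multivariate_hypergeometric(counts, depth)


def _metric_value(metric: str, counts: np.ndarray, tree=None, otu_ids=None) -> float:
    if metric == "richness":
        return float((counts > 0).sum())
    if metric == "shannon":
        return shannon(counts)
    if metric == "faith_pd":
        present = [otu_ids[i] for i in np.flatnonzero(counts > 0)]
        return faith_pd(tree, present)
    raise ValidationError(f"unknown metric {metric!r}")


def rarefaction(
    table: OtuTable,
    max_depth: int = 3900,
    step: int = 389,
    iters: int = 10,
    metric: str = "richness",
    seed: int = 0,
    tree=None,
) -> DiversityReport:
    """Serial subsampling without replacement in ``step`` increments up to
    ``max_depth``, ``iters`` independent subsamples per increment.  Samples
    whose total is below ``max_depth`` are excluded."""
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    included = [s for s in table.sample_ids if totals[s] >= max_depth]
    excluded = [s for s in table.sample_ids if totals[s] < max_depth]
    depths = list(range(step, max_depth + 1, step))
    if depths[-1] != max_depth:
        depths.append(max_depth)
    otu_ids = table.otu_ids
    rows = []
    for depth in depths:
        vals_mean, vals_sd = [], []
        for s in included:
            counts = table.counts[s].to_numpy()
            vals = [
                _metric_value(
                    metric,
                    _subsample_without_replacement(counts, depth, rng),
                    tree=tree,
                    otu_ids=otu_ids,
                )
                for _ in range(iters)
            ]
            vals_mean.append(np.mean(vals))
            vals_sd.append(np.std(vals, ddof=1) if iters > 1 else 0.0)
        rows.append(
            {
                "depth": depth,
                "mean": float(np.mean(vals_mean)) if included else np.nan,
                "sd": float(np.mean(vals_sd)) if included else np.nan,
            }
        )
    curve = pd.DataFrame(rows).set_index("depth")
    rich = pd.Series(
        {s: float((table.counts[s] > 0).sum()) for s in table.sample_ids}
    )
    shan = pd.Series({s: shannon(table.counts[s]) for s in table.sample_ids})
    pd_series = None
    if tree is not None:
        pd_series = pd.Series(
            {
                s: faith_pd(
                    tree,
                    [o for o, c in zip(otu_ids, table.counts[s]) if c > 0],
                )
                for s in table.sample_ids
            }
        )
    return DiversityReport(
        richness=rich,
        shannon=shan,
        faith_pd=pd_series,
        curves={metric: curve},
        excluded_samples=excluded,
    )


def env_correlation(x, v, method: str = "spearman") -> tuple[float, float]:
    """Rank (or linear) correlation between an abundance profile and an
    abiotic variable profile.  Constant input yields (nan, nan) — undefined,
    flagged rather than coerced to zero."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if x.size != v.size or x.size < 4:
        raise ValidationError("need >= 4 paired observations")
    if np.all(x == x[0]) or np.all(v == v[0]):
        return float("nan"), float("nan")
    if method == "spearman":
        rho, p = stats.spearmanr(x, v)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, v)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(rho), float(p)
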