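"""Group-comparison statistics and locus enrichment.

Implements the comparisons used throughout the study's figure panels —
two-tailed t tests, one-way ANOVA with pairwise Bonferroni post-tests,
Kruskal–Wallis with Dunn's multiple-comparison test, two-way ANOVA — plus
the timepoint-paired per-bin wave comparison and the hypergeometric /
permutation locus enrichment statistic applied to differential-expression
gene lists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["group_compare", "paired_wave_test", "locus_enrichment",
           "EnrichmentResult", "dunn_posthoc"]


def _groups(data: pd.DataFrame):
    if not {"value", "group"} <= set(data.columns):
        raise ValueError("data needs 'value' and 'group' columns")
    groups = {g: sub["value"].to_numpy(dtype=float)
              for g, sub in data.groupby("group", sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty group")
    return groups


def _safe_ttest_ind(a, b):
    # identical constant samples: no evidence of a difference
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b)
    return float(t), float(p)


def dunn_posthoc(groups: dict[str, np.ndarray],
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal–Wallis.

    Uses midranks with the standard tie correction; z statistics are
    referred to the normal distribution and adjusted across the reported
    pairs (Bonferroni by default).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)  # midranks
    mean_rank, start = {}, 0
    for g in names:
        k = len(groups[g])
        mean_rank[g] = ranks[start:start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    for g1, g2 in pairs:
        se = np.sqrt(var_base * (1.0 / len(groups[g1]) + 1.0 / len(groups[g2])))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_1": g1, "group_2": g2, "z": z, "p": p,
                     "p_adjusted": min(1.0, p * m) if adjust == "bonferroni"
                     else p})
    return pd.DataFrame(rows)


def group_compare(data: pd.DataFrame, method: str) -> dict:
    """Run a named group comparison on a tidy value/group table.

    ``method`` is one of ``t_test``, ``anova_bonferroni``, ``kruskal_dunn``
    or ``two_way_anova`` (the last requires a ``factor`` column; it reports
    both main effects and the interaction).  Returns a dict with an
    ``omnibus`` table and, for the post-hoc methods, a ``posthoc`` table of
    adjusted pairwise p values.
    """
    if method == "two_way_anova":
        return _two_way_anova(data)
    groups = _groups(data)
    arrays = list(groups.values())

    if method == "t_test":
        if len(groups) != 2:
            raise ValueError("t_test needs exactly 2 groups")
        if any(len(a) < 2 for a in arrays):
            raise ValueError("t test needs ≥ 2 observations per group")
        t, p = _safe_ttest_ind(*arrays)
        omnibus = pd.DataFrame([{"method": "t_test", "statistic": t, "p": p}])
        return {"omnibus": omnibus}

    if method == "anova_bonferroni":
        if any(len(a) < 2 for a in arrays):
            raise ValueError("ANOVA needs ≥ 2 observations per group")
        f, p = sps.f_oneway(*arrays)
        omnibus = pd.DataFrame([{"method": "one_way_anova",
                                 "statistic": float(f), "p": float(p)}])
        pairs = list(itertools.combinations(groups, 2))
        rows = []
        for g1, g2 in pairs:
            t, pp = _safe_ttest_ind(groups[g1], groups[g2])
            rows.append({"group_1": g1, "group_2": g2, "t": t, "p": pp,
                         "p_adjusted": min(1.0, pp * len(pairs))})
        return {"omnibus": omnibus, "posthoc": pd.DataFrame(rows)}

    if method == "kruskal_dunn":
        h, p = sps.kruskal(*arrays)
        omnibus = pd.DataFrame([{"method": "kruskal_wallis",
                                 "statistic": float(h), "p": float(p)}])
        return {"omnibus": omnibus, "posthoc": dunn_posthoc(groups)}

    raise ValueError(f"unknown method {method!r}")


def _two_way_anova(data: pd.DataFrame) -> dict:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if not {"value", "group", "factor"} <= set(data.columns):
        raise ValueError("two-way ANOVA needs 'value', 'group' and 'factor'")
    model = ols("value ~ C(group) * C(factor)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2).reset_index()
    table = table.rename(columns={"index": "term", "PR(>F)": "p"})
    table["term"] = table["term"].replace({
        "C(group)": "group", "C(factor)": "factor",
        "C(group):C(factor)": "group:factor"})
    return {"omnibus": table[["term", "sum_sq", "df", "F", "p"]]}


def paired_wave_test(waves_a: list, waves_b: list,
                     directions=("distal", "proximal")) -> pd.DataFrame:
    """Timepoint-paired two-tailed t test per (direction, bin).

    For each bin, the across-neuron mean value at every timepoint is formed
    per group; the two mean series, paired by timepoint, feed a paired
    two-tailed t test of the mean group difference.  Both groups must share
    the timepoint grid.
    """
    def tidy(waves, grp):
        frames = []
        for i, w in enumerate(waves):
            t = w.table.copy()
            t["neuron"] = i
            t["grp"] = grp
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    grids = {tuple(np.round(w.timepoints, 9)) for w in waves_a + waves_b}
    if len(grids) != 1:
        raise ValueError("mismatched timepoint grids across waves")

    both = pd.concat([tidy(waves_a, "A"), tidy(waves_b, "B")],
                     ignore_index=True)
    both = both[both["direction"].isin(directions) & ~both["truncated"]]
    rows = []
    for (direction, b), sub in both.groupby(["direction", "bin"], sort=True):
        mean_a = sub[sub.grp == "A"].groupby("time_s")["value"].mean()
        mean_b = sub[sub.grp == "B"].groupby("time_s")["value"].mean()
        common = mean_a.index.intersection(mean_b.index)
        if len(common) < 2:
            continue
        diff = (mean_b[common] - mean_a[common]).to_numpy()
        if np.ptp(diff) == 0:
            t, p = (0.0, 1.0) if diff[0] == 0 else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(mean_b[common], mean_a[common])
        rows.append({"direction": direction, "bin": b,
                     "t": float(t), "p": float(p),
                     "mean_diff": float(diff.mean())})
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    """Gene-level hypergeometric and locus-level permutation enrichment."""

    universe_size: int       # N
    n_de: int                # K
    n_target: int            # n (target genes in universe)
    overlap: int             # k
    gene_level_p: float      # P(X >= k), X ~ Hypergeom(N, K, n)
    locus_observed: int | None = None   # loci with >= 1 DE gene
    locus_expected: float | None = None
    locus_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    flags: list[str] = field(default_factory=list)


def locus_enrichment(universe, de_genes, loci: dict[str, list] | None = None,
                     target_set=None, n_permutations: int = 10000,
                     seed: int = 0) -> EnrichmentResult:
    """Test a DE-gene list for enrichment in a target set or in loci.

    The gene-level statistic is the upper-tail hypergeometric probability of
    the observed overlap between the DE genes and the target set (the union
    of locus genes when ``loci`` is given).  The locus-level statistic
    counts loci containing at least one DE gene and compares it against the
    null obtained by redrawing the DE set uniformly from the universe
    ``n_permutations`` times: ``p = (1 + #{null >= observed}) /
    (n_permutations + 1)``.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uset = set(universe)
    de = set(de_genes) & uset
    if loci is None and target_set is None:
        raise ValueError("provide loci or a target_set")
    loci_in = ({name: sorted(set(g) & uset) for name, g in loci.items()}
               if loci is not None else None)
    if target_set is not None:
        target = set(target_set) & uset
    else:
        target = set().union(*loci_in.values()) if loci_in else set()

    n_universe, n_de_genes, n_target = len(uset), len(de), len(target)
    k = len(de & target)
    if k > min(n_de_genes, n_target):
        raise ValueError("overlap exceeds set sizes")
    gene_p = float(sps.hypergeom.sf(k - 1, n_universe, n_de_genes, n_target))

    result = EnrichmentResult(universe_size=n_universe, n_de=n_de_genes,
                              n_target=n_target, overlap=k,
                              gene_level_p=gene_p)
    if loci_in is None:
        return result

    index = {g: i for i, g in enumerate(universe)}
    locus_idx = [np.array([index[g] for g in genes], dtype=int)
                 for genes in loci_in.values() if len(genes)]
    de_mask = np.zeros(n_universe, dtype=bool)
    de_mask[[index[g] for g in de]] = True
    observed = int(sum(de_mask[ix].any() for ix in locus_idx))

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=int)
    mark = np.zeros(n_universe, dtype=bool)
    for i in range(n_permutations):
        mark[:] = False
        mark[rng.choice(n_universe, size=n_de_genes, replace=False)] = True
        null[i] = sum(mark[ix].any() for ix in locus_idx)
    result.locus_observed = observed
    result.locus_expected = float(null.mean())
    result.locus_p = float((1 + (null >= observed).sum())
                           / (n_permutations + 1))
    result.n_permutations = n_permutations
    result.seed = seed
    if not locus_idx:
        result.flags.append("no locus genes in universe")
    return result
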