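"""Self-contained pre-ranked GSEA coupled to 3CA scoring.

The signed temporal component ``t`` of selected features is used directly
as the ranking metric (RNK semantics).  Enrichment is the standard
weighted Kolmogorov-Smirnov running sum; the null is gene-label
permutation (random sets of the same size drawn from the ranked universe),
with the usual NES normalisation (ES divided by the mean magnitude of
same-sign permutation ES), a +1-corrected nominal p from the same-sign
tail, and the NES-pooling FDR of the reference GSEA implementation
(Benjamini-Hochberg offered as an alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import benjamini_hochberg

__all__ = [
    "make_ranked_list",
    "build_ranked_list",
    "enrichment_score",
    "gsea_preranked",
    "wilcoxon_set_shift",
]


def make_ranked_list(genes, metrics) -> pd.Series:
    """Build a ranked list: metric descending, ties broken by gene symbol.

    Returns a Series (index gene symbol, values signed metric), strictly
    ordered and with unique symbols.
    """
    genes = np.asarray(list(genes), dtype=object)
    metrics = np.asarray(list(metrics), dtype=float)
    if len(genes) != len(metrics):
        raise ValueError("genes and metrics lengths differ")
    if len(genes) == 0:
        raise ValueError("ranked list is empty")
    if not np.isfinite(metrics).all():
        raise ValueError("ranked-list metrics must be finite")
    dup = pd.Index(genes).duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene symbols in ranked list: "
                         f"{sorted(set(genes[dup]))[:5]}")
    # sort by (-metric, symbol): descending metric, lexicographic on ties
    order = np.lexsort((genes.astype(str), -metrics))
    return pd.Series(metrics[order], index=pd.Index(genes[order], name="gene"),
                     name="metric")


def build_ranked_list(st: pd.DataFrame, selected_only: bool = True) -> pd.Series:
    """Ranked list of signed t from a gene-level score table.

    ``selected_only`` restricts to the 1-SD 3CA selection (the pre-filtering
    step); the full table is ranked otherwise.
    """
    df = st
    if selected_only:
        if "selected" not in df.columns:
            raise ValueError("score table has no 'selected' column; "
                             "run sd_select first or pass selected_only=False")
        df = df[df["selected"]]
        if len(df) == 0:
            raise ValueError("no features are selected; cannot build a "
                             "pre-filtered ranked list")
    if len(df) == 0:
        raise ValueError("score table is empty")
    return make_ranked_list(df.index, df["t"].to_numpy())


def _es_from_hits(weights: np.ndarray, n_genes: int, positions: np.ndarray,
                  ) -> tuple[float, int]:
    """ES and extremum position from sorted hit positions.

    ``weights`` are |metric|^p at the hit positions (same order).  The
    running sum only attains candidate extrema immediately after a hit
    (local max of an up-step) or immediately before one (trough of a miss
    stretch), so the walk is evaluated there in O(k).  On an exact tie
    between the positive and negative extreme magnitudes the positive one
    wins (deterministic tie-break).
    Returns (ES, extremum rank position).
    """
    k = len(positions)
    n_miss = n_genes - k
    if n_miss == 0:
        raise ValueError("gene set covers the entire ranked universe")
    nr = weights.sum()
    if nr > 0:
        hit_cum = np.cumsum(weights) / nr
    else:
        # all-zero metrics inside the set: fall back to equal hit increments
        hit_cum = np.arange(1, k + 1) / k
    miss_before = (positions - np.arange(k)) / n_miss  # misses before hit i
    peaks = hit_cum - (positions + 1 - np.arange(1, k + 1)) / n_miss
    troughs = np.concatenate(([0.0], hit_cum[:-1])) - miss_before
    pos_max = peaks.max()
    neg_min = troughs.min()
    if pos_max >= -neg_min:
        i = int(np.argmax(peaks))
        return float(pos_max), int(positions[i])
    i = int(np.argmin(troughs))
    return float(neg_min), int(positions[i]) - 1


def enrichment_score(rl: pd.Series, gene_set, exponent_p: float = 1.0,
                     return_running_sum: bool = False):
    """Weighted KS enrichment score of a gene set on a ranked list.

    Hits step up by ``|metric|^p / N_R`` (N_R the sum over in-set hits),
    misses step down by ``1/(N - N_hits)``; ES is the signed maximum
    deviation of the running sum from zero.

    Returns ES, or ``(ES, running_sum)`` with the full length-N walk when
    ``return_running_sum`` is set.
    """
    if exponent_p < 0:
        raise ValueError("exponent_p must be >= 0")
    genes = rl.index.to_numpy()
    metrics = rl.to_numpy(dtype=float)
    n = len(genes)
    in_set = np.isin(genes, list(gene_set))
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set has empty intersection with the universe")
    if k == n:
        raise ValueError("gene set covers the entire ranked universe")
    positions = np.flatnonzero(in_set)
    w = np.abs(metrics[positions]) ** exponent_p
    es, _ = _es_from_hits(w, n, positions)
    if not return_running_sum:
        return es
    nr = w.sum()
    steps = np.full(n, -1.0 / (n - k))
    steps[positions] = (w / nr) if nr > 0 else (1.0 / k)
    return es, np.cumsum(steps)


@dataclass
class GseaResult:
    """Per-set pre-ranked GSEA results as a DataFrame plus the log."""

    table: pd.DataFrame
    skipped: dict

    def __iter__(self):  # convenience: unpack like (table, skipped)
        return iter((self.table, self.skipped))


def gsea_preranked(rl: pd.Series, gene_sets: dict, n_perm: int = 1000,
                   min_size: int = 15, max_size: int = 500,
                   exponent_p: float = 1.0, seed: int = 0,
                   fdr_method: str = "gsea") -> GseaResult:
    """Pre-ranked GSEA with a gene-label permutation null.

    ``gene_sets`` maps set name -> iterable of gene symbols.  Sets are
    intersected with the ranked universe and filtered to
    ``min_size <= size <= max_size``.  For each retained size class,
    ``n_perm`` random same-size sets are drawn from the universe; NES,
    nominal p (same-sign tail, +1 correction, never exactly 0) and FDR q
    follow the usual pre-ranked GSEA conventions.  Deterministic given
    ``seed``.

    Returns a :class:`GseaResult` whose table has one row per retained set:
    ``name, size, es, nes, p_nominal, fdr_q, leading_edge``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if fdr_method not in ("gsea", "bh"):
        raise ValueError("fdr_method must be 'gsea' or 'bh'")
    genes = rl.index.to_numpy()
    metrics = rl.to_numpy(dtype=float)
    n = len(genes)
    abs_w = np.abs(metrics) ** exponent_p
    gene_pos = {g: i for i, g in enumerate(genes)}

    retained, skipped = [], {}
    for name, members in gene_sets.items():
        pos = np.array(sorted(gene_pos[g] for g in set(members) if g in gene_pos),
                       dtype=int)
        size = len(pos)
        if size == 0:
            skipped[name] = "empty intersection with ranked universe"
        elif size < min_size:
            skipped[name] = f"size {size} < min_size {min_size}"
        elif size > max_size:
            skipped[name] = f"size {size} > max_size {max_size}"
        elif size == n:
            skipped[name] = "set covers the entire universe"
        else:
            retained.append((name, pos))
    if not retained:
        warnings.warn("all gene sets were filtered out", UserWarning, stacklevel=2)
        empty = pd.DataFrame(columns=["name", "size", "es", "nes", "p_nominal",
                                      "fdr_q", "leading_edge"])
        return GseaResult(empty, skipped)

    rng = np.random.default_rng(seed)
    sizes = sorted({len(pos) for _, pos in retained})
    perm_es_by_size: dict[int, np.ndarray] = {}
    for size in sizes:
        es_perm = np.empty(n_perm)
        for j in range(n_perm):
            pos = np.sort(rng.choice(n, size=size, replace=False))
            es_perm[j], _ = _es_from_hits(abs_w[pos], n, pos)
        perm_es_by_size[size] = es_perm

    def _nes(es_val, perm):
        same = perm[np.sign(perm) == np.sign(es_val)] if es_val != 0 else perm
        denom = np.abs(same).mean() if len(same) else np.abs(perm).mean()
        return es_val / denom if denom > 0 else 0.0

    rows = []
    all_perm_nes = []
    for name, pos in retained:
        size = len(pos)
        perm = perm_es_by_size[size]
        es, ext = _es_from_hits(abs_w[pos], n, pos)
        same = perm[np.sign(perm) == np.sign(es)] if es != 0 else perm
        n_same = len(same)
        p_nom = ((np.abs(same) >= abs(es)).sum() + 1) / (n_same + 1)
        nes = _nes(es, perm)
        if es >= 0:
            lead = [genes[i] for i in pos if i <= ext]
        else:
            lead = [genes[i] for i in pos if i > ext]
        rows.append({"name": name, "size": size, "es": es, "nes": nes,
                     "p_nominal": p_nom, "leading_edge": lead})
        all_perm_nes.append(np.array([_nes(e, perm) for e in perm]))

    table = pd.DataFrame(rows)
    if fdr_method == "bh":
        table["fdr_q"] = benjamini_hochberg(table["p_nominal"].to_numpy())
    else:
        pooled = np.concatenate(all_perm_nes)
        obs = table["nes"].to_numpy()
        q = np.empty(len(obs))
        for i, nes in enumerate(obs):
            if nes >= 0:
                perm_side = pooled[pooled >= 0]
                obs_side = obs[obs >= 0]
                num = (perm_side >= nes).mean() if len(perm_side) else 1.0
                den = (obs_side >= nes).mean() if len(obs_side) else 1.0
            else:
                perm_side = pooled[pooled < 0]
                obs_side = obs[obs < 0]
                num = (perm_side <= nes).mean() if len(perm_side) else 1.0
                den = (obs_side <= nes).mean() if len(obs_side) else 1.0
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        table["fdr_q"] = q
    table = table[["name", "size", "es", "nes", "p_nominal", "fdr_q",
                   "leading_edge"]]
    return GseaResult(table, skipped)


def wilcoxon_set_shift(set_scores, background_scores) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of a set's scores vs background.

    Exact null when combined n <= 25 and the data are tie-free; normal
    approximation with tie correction otherwise.  All values tied across
    both groups gives p = 1 by convention.
    """
    x = np.asarray(list(set_scores), dtype=float)
    y = np.asarray(list(background_scores), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    if np.unique(combined).size == 1:
        return float(len(x) * len(y) / 2), 1.0
    has_ties = np.unique(combined).size < len(combined)
    method = "exact" if (len(combined) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))
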