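"""Baseline paired-design statistics and enrichment plumbing.

The classical alternative to 3CA on a paired longitudinal design: compare
intra-individual changes (late minus early within each subject) against an
inter-individual background (differences between age-matched subjects),
per feature, with Benjamini-Hochberg FDR control.  A generic one-sided
Fisher's exact over-representation test is included so set-level summaries
can be produced from any annotation collection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import PairedMatrix

__all__ = [
    "PairingPlan",
    "build_pairing",
    "intra_vs_inter_test",
    "benjamini_hochberg",
    "fisher_enrichment",
]


@dataclass
class PairingPlan:
    """Intra-individual pairs plus the age-matched inter-individual background.

    ``intra`` rows: (subject, pair_id).  ``inter`` rows: (subject_older,
    subject_younger, timepoint, age_diff) — each unordered subject pair with
    an age difference at the chosen timepoint within the tolerance, oriented
    older-minus-younger (lexicographic on exact-age ties).
    """

    intra: pd.DataFrame
    inter: pd.DataFrame
    max_age_diff: float = 2.0


def build_pairing(meta: pd.DataFrame, max_age_diff: float = 2.0,
                  timepoint: str = "early") -> PairingPlan:
    """Enumerate intra pairs and the age-matched inter-individual background.

    ``meta`` is indexed by pair id with columns ``subject``, ``age_early``,
    ``age_late``.  Inter pairs are all unordered subject pairs whose ages at
    ``timepoint`` ("early", "late", or "both" for the union over both
    timepoints) differ by at most ``max_age_diff`` years.
    """
    if timepoint not in ("early", "late", "both"):
        raise ValueError("timepoint must be 'early', 'late' or 'both'")
    if meta["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    intra = pd.DataFrame({"subject": meta["subject"].to_numpy(),
                          "pair_id": meta.index.to_numpy()})
    tps = ["early", "late"] if timepoint == "both" else [timepoint]
    rows = []
    for tp in tps:
        ages = meta.set_index("subject")[f"age_{tp}"]
        for a, b in itertools.combinations(sorted(ages.index), 2):
            diff = abs(ages[a] - ages[b])
            if diff <= max_age_diff:
                if ages[a] > ages[b] or (ages[a] == ages[b] and a < b):
                    older, younger = a, b
                else:
                    older, younger = b, a
                rows.append({"subject_older": older, "subject_younger": younger,
                             "timepoint": tp, "age_diff": float(diff)})
    if not rows:
        raise ValueError(
            f"no inter-individual pairs within {max_age_diff} years at "
            f"timepoint(s) {tps}; consider a larger max_age_diff"
        )
    inter = pd.DataFrame(rows)
    return PairingPlan(intra=intra, inter=inter, max_age_diff=max_age_diff)


def intra_vs_inter_test(m: PairedMatrix, plan: PairingPlan,
                        test: str = "wilcoxon_ranksum",
                        log_transform: bool = True,
                        pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-feature test of intra- vs inter-individual expression changes.

    Intra changes are late minus early per subject on the log scale; inter
    changes are older-minus-younger differences between age-matched subjects
    at the matched timepoint.  A two-sample test (Wilcoxon rank-sum by
    default, Welch's t by flag) compares the two change sets per feature;
    q-values are Benjamini-Hochberg.  Constant features get p = 1 and are
    flagged in the ``constant`` column.
    """
    if test not in ("wilcoxon_ranksum", "welch_t"):
        raise ValueError("test must be 'wilcoxon_ranksum' or 'welch_t'")
    if len(plan.intra) < 2 or len(plan.inter) < 2:
        raise ValueError("need at least 2 intra and 2 inter pairs")
    x, y = m.working_values(log_transform=log_transform, pseudocount=pseudocount)
    pair_col = {p: j for j, p in enumerate(m.pair_ids)}
    subj_pair = dict(zip(plan.intra["subject"], plan.intra["pair_id"]))

    intra_cols = [pair_col[p] for p in plan.intra["pair_id"]]
    intra = y[:, intra_cols] - x[:, intra_cols]  # (F, n_intra)

    inter_cols = []
    for _, r in plan.inter.iterrows():
        tp_mat = x if r["timepoint"] == "early" else y
        jo = pair_col[subj_pair[r["subject_older"]]]
        jy = pair_col[subj_pair[r["subject_younger"]]]
        inter_cols.append(tp_mat[:, jo] - tp_mat[:, jy])
    inter = np.column_stack(inter_cols)  # (F, n_inter)

    pvals = np.ones(m.n_features)
    constant = np.zeros(m.n_features, dtype=bool)
    for i in range(m.n_features):
        a, b = intra[i], inter[i]
        if np.unique(np.concatenate([a, b])).size == 1:
            constant[i] = True
            continue
        if test == "wilcoxon_ranksum":
            pvals[i] = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            pvals[i] = sps.ttest_ind(a, b, equal_var=False).pvalue
    pvals = np.nan_to_num(pvals, nan=1.0)
    q = benjamini_hochberg(pvals)
    return pd.DataFrame({"p": pvals, "q": q, "constant": constant},
                        index=pd.Index(m.feature_ids, name="feature"))


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(selected, universe, annotations: dict) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation of a selection.

    For each annotation set S (intersected with the universe), tests whether
    ``selected`` contains more of S than expected under hypergeometric
    sampling (alternative='greater').  Returns per set: k (selected in S),
    K (S in universe), n (selected), N (universe), odds ratio, p, BH q.
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise ValueError("universe is empty")
    if not selected <= universe:
        extra = sorted(selected - universe)[:5]
        raise ValueError(f"selected genes outside the universe: {extra}")
    n, N = len(selected), len(universe)
    rows = []
    for name, members in annotations.items():
        S = set(members) & universe
        K = len(S)
        k = len(selected & S)
        table = [[k, n - k], [K - k, (N - n) - (K - k)]]
        odds, p = sps.fisher_exact(table, alternative="greater")
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out
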