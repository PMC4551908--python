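"""Three-component analysis (3CA) of paired longitudinal data.

Each feature (gene, transcript, binned genomic window) is observed in the
same subjects at two time points.  Plotting each subject's pair as a point
(early, late) in a plane, three geometric components summarise the feature:

* ``v`` — variance radius: RMS Euclidean distance of the pair-points from
  their centroid; inter-individual variability of the paired signal.
* ``s`` — signal strength: length of the vector from the origin to the
  centroid; guards against low-intensity artifacts.
* ``t`` — temporal distance: signed perpendicular distance of the centroid
  from the 45-degree identity line (the no-change null); positive means an
  increase with age/time.

The three components are rank-aggregated with equal weights into a single
score (lower = more significant), features within 1 SD of the best score
are selected, and per-component contributions diagnose what drives a
feature's rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "PairedMatrix",
    "compute_components",
    "combine_score",
    "sd_select",
    "component_contribution",
    "shuffled_control",
    "collapse_to_genes",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class PairedMatrix:
    """Feature x subject-pair matrix of nonnegative intensities.

    ``early`` and ``late`` are aligned (n_features, n_pairs) arrays; ``meta``
    is indexed by ``pair_ids`` with columns ``subject``, ``age_early``,
    ``age_late``.  ``scale`` says whether stored values are linear
    intensities (RPKM-like, must be >= 0) or already log-scale ratios.
    """

    feature_ids: np.ndarray
    pair_ids: np.ndarray
    early: np.ndarray
    late: np.ndarray
    scale: str = "linear"
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.pair_ids = np.asarray(self.pair_ids, dtype=object)
        self.early = np.asarray(self.early, dtype=float)
        self.late = np.asarray(self.late, dtype=float)
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be 'linear' or 'log', got {self.scale!r}")
        if self.early.shape != self.late.shape:
            raise ValueError(
                f"early {self.early.shape} and late {self.late.shape} shapes differ"
            )
        if self.early.ndim != 2:
            raise ValueError("early/late must be 2-D (features x pairs)")
        nf, npair = self.early.shape
        if len(self.feature_ids) != nf:
            raise ValueError("feature_ids length does not match matrix rows")
        if len(self.pair_ids) != npair:
            raise ValueError("pair_ids length does not match matrix columns")
        if len(set(self.feature_ids)) != nf:
            raise ValueError("feature_ids contains duplicates")
        if len(set(self.pair_ids)) != npair:
            raise ValueError("pair_ids contains duplicates")
        for name, arr in (("early", self.early), ("late", self.late)):
            bad = ~np.isfinite(arr)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-finite value in {name} at feature "
                    f"{self.feature_ids[i]!r}, pair {self.pair_ids[j]!r}"
                )
            if self.scale == "linear" and (arr < 0).any():
                i, j = np.argwhere(arr < 0)[0]
                raise ValueError(
                    f"negative value in {name} (linear scale) at feature "
                    f"{self.feature_ids[i]!r}, pair {self.pair_ids[j]!r}"
                )
        if self.meta is not None:
            missing = [c for c in ("subject", "age_early", "age_late")
                       if c not in self.meta.columns]
            if missing:
                raise ValueError(f"pair metadata missing columns: {missing}")
            ae = self.meta["age_early"].to_numpy(dtype=float)
            al = self.meta["age_late"].to_numpy(dtype=float)
            if not np.all(al > ae):
                bad = self.meta.index[~(al > ae)][0]
                raise ValueError(f"age_late must exceed age_early (pair {bad!r})")

    @property
    def n_features(self) -> int:
        return self.early.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.early.shape[1]

    def working_values(self, log_transform: bool = True,
                       pseudocount: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinates on the analysis scale.

        Log-scale input is used as-is.  Linear input is log2(x + pseudocount)
        transformed when ``log_transform`` is set, raw otherwise.
        """
        if self.scale == "log" or not log_transform:
            return self.early, self.late
        if pseudocount <= 0 and self.early.min() <= 0:
            raise ValueError("pseudocount must be > 0 to log-transform linear data")
        return np.log2(self.early + pseudocount), np.log2(self.late + pseudocount)


def compute_components(m: PairedMatrix, log_transform: bool = True,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-feature components (v, s, t) and centroid from a paired matrix.

    With pair-points ``p_i = (x_i, y_i)`` on the working scale and centroid
    ``c = (mean x, mean y)``:

    * ``s = sqrt(cx^2 + cy^2)``
    * ``t = (cy - cx) / sqrt(2)``  (signed; + means increase with time)
    * ``v = sqrt(mean_i ((x_i - cx)^2 + (y_i - cy)^2))``

    Returns a DataFrame indexed by feature with columns
    ``v, s, t, cx, cy``.
    """
    if m.n_pairs == 0:
        raise ValueError("matrix has zero pairs")
    x, y = m.working_values(log_transform=log_transform, pseudocount=pseudocount)
    cx = x.mean(axis=1)
    cy = y.mean(axis=1)
    s = np.hypot(cx, cy)
    t = (cy - cx) / _SQRT2
    v = np.sqrt(((x - cx[:, None]) ** 2 + (y - cy[:, None]) ** 2).mean(axis=1))
    return pd.DataFrame(
        {"v": v, "s": s, "t": t, "cx": cx, "cy": cy},
        index=pd.Index(m.feature_ids, name="feature"),
    )


def _component_ranks(cs: pd.DataFrame) -> pd.DataFrame:
    """Average ranks: v ascending, s descending, |t| descending (rank 1 best)."""
    return pd.DataFrame(
        {
            "rank_v": rankdata(cs["v"].to_numpy()),
            "rank_s": rankdata(-cs["s"].to_numpy()),
            "rank_t": rankdata(-np.abs(cs["t"].to_numpy())),
        },
        index=cs.index,
    )


def combine_score(cs: pd.DataFrame,
                  weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                  ) -> pd.DataFrame:
    """Rank-aggregate components into a single 3CA score (lower = better).

    Each component is ranked over all features (lowest variance, highest
    signal, largest |temporal change| each get rank 1; ties get average
    ranks) and the score is the weighted mean of the three ranks.  Equal
    weights are the default: with temporal change and signal tied between
    two features, the one with lower inter-individual variance wins.
    """
    if len(cs) < 2:
        raise ValueError("combine_score needs at least 2 features")
    w = np.asarray(weights, dtype=float)
    if w.min() < 0 or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    out = cs[["v", "s", "t"]].copy()
    ranks = _component_ranks(cs)
    out[["rank_v", "rank_s", "rank_t"]] = ranks
    out["score"] = (
        w[0] * out["rank_v"] + w[1] * out["rank_s"] + w[2] * out["rank_t"]
    )
    sign = np.sign(out["t"].to_numpy())
    out["direction"] = np.where(sign > 0, "up", np.where(sign < 0, "down", "flat"))
    if out["score"].nunique() == 1 and len(out) > 1:
        warnings.warn("all features tie on every component; scores are all equal",
                      UserWarning, stacklevel=2)
    return out


def sd_select(st: pd.DataFrame, k_sd: float = 1.0) -> pd.DataFrame:
    """Select features within ``k_sd`` SD of the best (minimum) score.

    ``z_sd = (score - min score) / SD(scores)`` with the sample SD
    (n-1 denominator); ``selected = z_sd <= k_sd``.  The returned frame
    carries diagnostics in ``.attrs['selection']``: fraction selected and
    whether the best-2%-of-scores set falls entirely inside the selection
    (the "top 2% within 1 SD" check).
    """
    if k_sd < 0:
        raise ValueError("k_sd must be >= 0")
    if len(st) < 2:
        raise ValueError("sd_select needs at least 2 features")
    scores = st["score"].to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    sd = scores.std(ddof=1)
    if sd == 0:
        warnings.warn("all scores identical (SD = 0); selecting every feature",
                      UserWarning, stacklevel=2)
        z = np.zeros_like(scores)
    else:
        z = (scores - scores.min()) / sd
    out = st.copy()
    out["z_sd"] = z
    out["selected"] = z <= k_sd
    top2_cut = np.quantile(scores, 0.02)
    top2_mask = scores <= top2_cut
    out.attrs["selection"] = {
        "k_sd": float(k_sd),
        "n_selected": int(out["selected"].sum()),
        "fraction_selected": float(out["selected"].mean()),
        "top2pct_within_selection": bool(out["selected"].to_numpy()[top2_mask].all()),
    }
    return out


def component_contribution(cs: pd.DataFrame, subset=None,
                           group: str | None = None) -> pd.DataFrame:
    """Percentage contribution of each component via inverse ranks.

    Ranks are computed over *all* features (same conventions as
    ``combine_score``); the inverse rank is ``N + 1 - rank`` and the
    contribution of component k is its inverse rank divided by the sum of
    the three.  A feature ranking identically on all three components gets
    exactly (1/3, 1/3, 1/3).  Percentages are reported for ``subset``
    (all features when None); ``group`` labels the rows (e.g. ``top``,
    ``random``, ``shuffled``) for comparison plots.
    """
    n = len(cs)
    if n == 0:
        raise ValueError("no features")
    ranks = _component_ranks(cs)
    inv = n + 1 - ranks
    total = inv.sum(axis=1)
    pct = inv.div(total, axis=0)
    pct.columns = ["pct_v", "pct_s", "pct_t"]
    if subset is not None:
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("subset is empty")
        missing = [f for f in subset if f not in pct.index]
        if missing:
            raise KeyError(f"features not in component table: {missing[:5]}")
        pct = pct.loc[subset]
    if group is not None:
        pct = pct.copy()
        pct["group"] = group
    return pct


def shuffled_control(m: PairedMatrix, seed: int) -> PairedMatrix:
    """Permute the early/late sample assignment across pairs.

    All 2*n_pairs sample columns are pooled and randomly reassigned (the
    same permutation for every feature), destroying the intra-subject
    pairing while preserving each feature's multiset of values.  Used to
    build the shuffled control group for the contribution diagnostic.
    """
    if m.n_pairs < 2:
        raise ValueError("need at least 2 pairs to shuffle")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([m.early, m.late], axis=1)  # (F, 2P)
    perm = rng.permutation(pooled.shape[1])
    shuffled = pooled[:, perm]
    npair = m.n_pairs
    return PairedMatrix(
        feature_ids=m.feature_ids.copy(),
        pair_ids=m.pair_ids.copy(),
        early=shuffled[:, :npair],
        late=shuffled[:, npair:],
        scale=m.scale,
        meta=None if m.meta is None else m.meta.copy(),
    )


def collapse_to_genes(st: pd.DataFrame, mapping, mode: str = "min_score",
                      ) -> pd.DataFrame:
    """Collapse a transcript-level score table to one row per gene symbol.

    ``mapping`` maps transcript id -> gene symbol (dict or Series).
    ``mode='min_score'`` keeps the transcript with the minimal 3CA score
    (score-based selection); ``mode='max_abs_t'`` keeps the one with the
    largest |t| (GSEA ranking).  Ties break lexicographically by transcript
    id.  Unmapped transcripts are dropped; the count is stored in
    ``.attrs['n_unmapped']``.
    """
    if mode not in ("min_score", "max_abs_t"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    mapping = pd.Series(dict(mapping) if not isinstance(mapping, pd.Series)
                        else mapping)
    if len(mapping) == 0:
        raise ValueError("empty transcript-to-gene mapping")
    df = st.copy()
    df["transcript"] = df.index.astype(str)
    df["gene"] = df["transcript"].map(mapping)
    n_unmapped = int(df["gene"].isna().sum())
    df = df.dropna(subset=["gene"])
    if len(df) == 0:
        raise ValueError("no transcripts could be mapped to gene symbols")
    if mode == "min_score":
        df = df.sort_values(["score", "transcript"], kind="mergesort")
    else:
        df = df.assign(_abs_t=df["t"].abs()).sort_values(
            ["_abs_t", "transcript"], ascending=[False, True], kind="mergesort"
        ).drop(columns="_abs_t")
    out = df.groupby("gene", sort=True).head(1).set_index("gene").sort_index()
    out.index.name = "feature"
    out.attrs["n_unmapped"] = n_unmapped
    return out
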