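"""Synthetic paired-design data with known ground truth.

Emulates the study design the scoring method targets: 10 subjects, each
sampled twice 12-19 years apart, lognormal-scale intensities with
gene-specific inter-individual variability, and planted coordinated
up/down temporal effects in designated gene sets.  Everything is
deterministic given a single seed, and a truth table aligned with the
emitted matrix records what was planted where.

Generative model (log2 scale), per gene g and subject i:

    b_gi   = baseline_g + u_gi,          u_gi ~ N(0, inter_sd_g)
    early  = b_gi + e1,  late = b_gi + effect_g + e2,   e ~ N(0, noise_sd)

with baseline_g ~ N(baseline_mean, baseline_sd) and inter_sd_g drawn
half-normal.  Values are emitted on the linear scale as 2**log2value.
The subject effect u_gi is shared by the two time points, so it cancels in
the intra-subject change; the per-time-point noise is what limits the
temporal component.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import PairedMatrix

__all__ = [
    "PlantedSet",
    "SimulationConfig",
    "simulate_paired_expression",
    "simulate_probe_tracks",
]


class PlantedSet(BaseModel):
    """A gene set with a planted coordinated temporal effect (log2 units)."""

    model_config = ConfigDict(extra="forbid")

    name: str
    n_genes: int = Field(gt=0)
    effect: float
    effect_sd: float = Field(default=0.0, ge=0)


class SimulationConfig(BaseModel):
    """Study-design parameters for the paired-expression simulator.

    Defaults mirror the target design: 10 subject pairs sampled 12-19
    years apart, 5,000 genes with lognormal intensities (baseline log2
    mean 6, sd 2), gene-specific inter-individual sd drawn half-normal
    with scale 0.5, per-time-point noise sd 0.25, and one 100-gene
    coordinately down-regulated set at log2 effect -1.
    """

    model_config = ConfigDict(extra="forbid")

    n_genes: int = Field(default=5000, ge=1)
    n_pairs: int = Field(default=10, ge=2)
    gap_years: tuple[float, float] = (12.0, 19.0)
    age_min: float = 35.0
    age_max: float = 75.0
    baseline_mean: float = 6.0
    baseline_sd: float = Field(default=2.0, ge=0)
    inter_sd_scale: float = Field(default=0.5, ge=0)
    noise_sd: float = Field(default=0.25, ge=0)
    planted_sets: list[PlantedSet] = Field(
        default_factory=lambda: [PlantedSet(name="translation_down",
                                            n_genes=100, effect=-1.0)]
    )
    intensity_variance_coupling: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.gap_years[0] > self.gap_years[1] or self.gap_years[0] < 0:
            raise ValueError("gap_years must be an ascending nonnegative pair")
        if self.age_min + self.gap_years[1] > self.age_max:
            raise ValueError("age range cannot accommodate the maximum gap")
        total = sum(ps.n_genes for ps in self.planted_sets)
        if total > self.n_genes:
            raise ValueError(
                f"planted sets need {total} genes but only {self.n_genes} exist"
            )
        names = [ps.name for ps in self.planted_sets]
        if len(set(names)) != len(names):
            raise ValueError("planted set names must be unique")
        return self


def simulate_paired_expression(cfg: SimulationConfig | None = None,
                               seed: int | None = None,
                               ) -> tuple[PairedMatrix, pd.DataFrame]:
    """Draw a paired expression matrix plus its ground-truth table.

    ``seed`` overrides ``cfg.seed`` when given.  Returns a linear-scale
    :class:`~threeca.core.PairedMatrix` and a truth DataFrame indexed by
    gene with columns ``planted_set`` (empty string for background),
    ``effect``, ``baseline``, ``inter_sd``.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    G, P = cfg.n_genes, cfg.n_pairs

    genes = np.array([f"G{i:05d}" for i in range(G)], dtype=object)
    subjects = np.array([f"S{i:02d}" for i in range(P)], dtype=object)
    gaps = rng.uniform(*cfg.gap_years, size=P)
    age_early = rng.uniform(cfg.age_min, cfg.age_max - gaps)
    meta = pd.DataFrame({"subject": subjects, "age_early": age_early,
                         "age_late": age_early + gaps},
                        index=pd.Index(subjects, name="pair_id"))

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=G)
    inter_sd = np.abs(rng.normal(0.0, cfg.inter_sd_scale, size=G))

    effect = np.zeros(G)
    planted = np.full(G, "", dtype=object)
    # planted genes occupy a random disjoint block assignment
    pool = rng.permutation(G)
    offset = 0
    for ps in cfg.planted_sets:
        idx = pool[offset:offset + ps.n_genes]
        offset += ps.n_genes
        planted[idx] = ps.name
        effect[idx] = ps.effect if ps.effect_sd == 0 else rng.normal(
            ps.effect, ps.effect_sd, size=ps.n_genes)

    noise_sd = np.full(G, cfg.noise_sd)
    if cfg.intensity_variance_coupling:
        # dim genes are noisier: measurement error grows as intensity drops
        noise_sd = noise_sd * (1.0 + np.exp(-(baseline - cfg.baseline_mean)
                                            / 2.0)) / 2.0

    subject_eff = rng.normal(0.0, 1.0, size=(G, P)) * inter_sd[:, None]
    b = baseline[:, None] + subject_eff
    early_log = b + rng.normal(0.0, 1.0, size=(G, P)) * noise_sd[:, None]
    late_log = (b + effect[:, None]
                + rng.normal(0.0, 1.0, size=(G, P)) * noise_sd[:, None])

    matrix = PairedMatrix(feature_ids=genes, pair_ids=subjects,
                          early=np.exp2(early_log), late=np.exp2(late_log),
                          scale="linear", meta=meta)
    truth = pd.DataFrame({"planted_set": planted, "effect": effect,
                          "baseline": baseline, "inter_sd": inter_sd},
                         index=pd.Index(genes, name="feature"))
    return matrix, truth


def simulate_probe_tracks(region_length: int = 50_000, n_probes: int = 500,
                          base_level: float = 1.0,
                          effect_regions: list[tuple[int, int, float]] = (),
                          noise_sd: float = 0.3, n_pairs: int = 10,
                          probe_length: int = 50, chrom: str = "chr1",
                          seed: int = 0):
    """Matched early/late probe tracks for the binning -> scoring path.

    Probes are placed uniformly at random along the region; each probe's
    early log2 ratio is the regional base level plus noise, and its late
    ratio additionally carries the effect of any ``(start, end, effect)``
    region containing the probe midpoint.  Returns ``(tracks, truth)``
    where ``tracks[(subject, timepoint)]`` is a probe-track DataFrame and
    ``truth`` records the effect layout.
    """
    if n_probes < 1 or region_length <= probe_length:
        raise ValueError("need at least one probe and region > probe length")
    density = n_probes / region_length
    if density * 500 < 1:
        import warnings
        warnings.warn("probe density too low for any window to reach the "
                      "default probe minimum", UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(0, region_length - probe_length,
                                  size=n_probes))
    mids = starts + probe_length / 2.0
    truth_effect = np.zeros(n_probes)
    for (rs, re, eff) in effect_regions:
        truth_effect[(mids >= rs) & (mids < re)] += eff
    tracks = {}
    for i in range(n_pairs):
        subject = f"S{i:02d}"
        for tp, eff in (("early", 0.0), ("late", 1.0)):
            ratios = (base_level + eff * truth_effect
                      + rng.normal(0.0, noise_sd, size=n_probes))
            tracks[(subject, tp)] = pd.DataFrame(
                {"chrom": chrom, "start": starts,
                 "end": starts + probe_length, "ratio": ratios})
    truth = pd.DataFrame(effect_regions, columns=["start", "end", "effect"]) \
        if effect_regions else pd.DataFrame(columns=["start", "end", "effect"])
    return tracks, truth
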