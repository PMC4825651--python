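"""Bootstrap enrichment/depletion statistics for genomic feature tracks.

For a feature track and an experimental site set with N matched control
replicates, the statistic is built from raw overlap counts (a site overlaps
a feature if they share at least 1 bp):

* enrichment ratio — the mean over control sets of
  ``x_exp / x_ctrl_i`` (control sets with zero overlap are excluded from the
  mean and tallied separately);
* empirical P-values — ``p_enrich`` is the fraction of control sets whose
  count reaches or exceeds the experimental count, ``p_deplete`` the fraction
  at or below it. Ties count toward both, so ``p_enrich + p_deplete >= 1``.
  No add-one correction is applied: with N sets the smallest reportable
  P-value is 0, reported as "< 1/N".

The conventional significance threshold applied downstream is P = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_core import FeatureTrack, _overlap_mask, as_intervals, overlap_count
from .matched_controls import ControlSetCollection

SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class EnrichmentResult:
    feature: str
    x_exp: int
    control_counts: np.ndarray
    ratio: float  # NaN when every control set has zero overlap
    p_enrich: float
    p_deplete: float
    n_zero_control_sets: int

    @property
    def n_sets(self) -> int:
        return len(self.control_counts)

    def p_enrich_label(self) -> str:
        if self.p_enrich == 0.0:
            return f"< {1 / self.n_sets:g}"
        return f"{self.p_enrich:g}"


def _control_counts(controls: ControlSetCollection, track: FeatureTrack) -> np.ndarray:
    merged = track.merged_arrays()
    counts = np.zeros(controls.n_sets, dtype=np.int64)
    for i, per_chrom in enumerate(controls.set_arrays()):
        c = 0
        for chrom, arr in per_chrom.items():
            m = merged.get(chrom)
            if m is None or m[0].size == 0:
                continue
            c += int(_overlap_mask(arr[:, 0], arr[:, 1], m[0], m[1]).sum())
        counts[i] = c
    return counts


def enrichment(
    sites, controls: ControlSetCollection, track: FeatureTrack
) -> EnrichmentResult:
    """Bootstrap enrichment statistic for one feature track."""
    if controls.n_sets == 0:
        raise ValueError("control collection is empty")
    x_exp = overlap_count(sites, track)
    ctrl = _control_counts(controls, track)
    nonzero = ctrl > 0
    n_zero = int((~nonzero).sum())
    if nonzero.any():
        ratio = float(np.mean(x_exp / ctrl[nonzero]))
    else:
        ratio = math.nan  # undefined: every control set had zero overlap
    p_enrich = float((ctrl >= x_exp).mean())
    p_deplete = float((ctrl <= x_exp).mean())
    return EnrichmentResult(
        feature=track.name,
        x_exp=x_exp,
        control_counts=ctrl,
        ratio=ratio,
        p_enrich=p_enrich,
        p_deplete=p_deplete,
        n_zero_control_sets=n_zero,
    )


def enrichment_panel(
    sites, controls: ControlSetCollection, tracks: list[FeatureTrack],
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Apply :func:`enrichment` to a panel of tracks; tidy one-row-per-feature
    table. ``bh_adjust`` adds Benjamini-Hochberg columns (off by default:
    each feature is judged against its own matched null, so unadjusted
    empirical P-values are the primary report)."""
    results = [enrichment(sites, controls, t) for t in tracks]
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "x_exp": [r.x_exp for r in results],
            "ratio": [r.ratio for r in results],
            "p_enrich": [r.p_enrich for r in results],
            "p_deplete": [r.p_deplete for r in results],
            "n_zero_control_sets": [r.n_zero_control_sets for r in results],
        }
    )
    if bh_adjust:
        for col in ("p_enrich", "p_deplete"):
            df[f"{col}_bh"] = _benjamini_hochberg(df[col].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m, dtype=float)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def chromosome_distribution(
    sites, controls: ControlSetCollection
) -> pd.DataFrame:
    """Per-chromosome observed site counts vs control mean and sd."""
    ivs = as_intervals(sites)
    chroms = sorted(
        {iv.chrom for iv in ivs}
        | {c for per in controls.set_arrays() for c in per}
    )
    obs = {c: 0 for c in chroms}
    for iv in ivs:
        obs[iv.chrom] += 1
    ctrl = np.zeros((controls.n_sets, len(chroms)), dtype=np.int64)
    index = {c: j for j, c in enumerate(chroms)}
    for i, per_chrom in enumerate(controls.set_arrays()):
        for chrom, arr in per_chrom.items():
            ctrl[i, index[chrom]] = arr.shape[0]
    return pd.DataFrame(
        {
            "chrom": chroms,
            "observed": [obs[c] for c in chroms],
            "control_mean": ctrl.mean(axis=0),
            "control_sd": ctrl.std(axis=0, ddof=1) if controls.n_sets > 1
            else np.zeros(len(chroms)),
        }
    )
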