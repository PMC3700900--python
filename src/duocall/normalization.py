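"""Per-marker two-channel intensity scaling.

Each marker/channel pair has its own fluorescence sensitivity, so raw
channel A and B intensities are not comparable until scaled. The scale
for channel A is taken from the candidate AA homozygotes (channel B from
the BB candidates), identified from provisional BAF bands on the raw
data. Rather than using the candidate centroid, the scale is the
*weighted mode* of the candidate intensity distribution — the maximum of
w(x)·density(x) with w(x) = x — so that at markers where the candidate
pool mixes diploid and hemizygous-deletion samples the scale locks onto
the full-dose (upper) cluster instead of drifting to the mixture mean.
When a homozygote arm has too few candidates, heterozygote intensities
are used instead (their per-channel signal is about half a homozygote's,
the ``het_target``), which keeps low-MAF markers normalizable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .config import NormConfig
from .types import IntensityMatrix


@dataclass
class ScalingFactors:
    """Per-marker, per-channel scales and their provenance."""

    scale_a: float
    scale_b: float
    source_a: str  # 'homozygote' | 'heterozygote' | 'none'
    source_b: str
    n_candidates_a: int = 0
    n_candidates_b: int = 0

    @property
    def unnormalizable(self) -> bool:
        return self.source_a == "none" and self.source_b == "none"


def provisional_baf(raw_a: np.ndarray, raw_b: np.ndarray) -> np.ndarray:
    """Two-channel angle (2/pi)*atan2(b, a) on raw intensities."""
    with np.errstate(invalid="ignore"):
        theta = (2.0 / np.pi) * np.arctan2(raw_b, raw_a)
    theta = np.clip(theta, 0.0, 1.0)
    both_zero = (raw_a == 0) & (raw_b == 0)
    theta[both_zero] = np.nan
    return theta


def candidate_partition(
    raw_a: np.ndarray, raw_b: np.ndarray, config: NormConfig | None = None
) -> dict[str, np.ndarray]:
    """Split samples into candidate AA / AB / BB index sets.

    Membership is by provisional BAF band; samples whose total raw
    intensity falls below ``intensity_floor_frac`` of the marker median
    (or whose intensities are missing) enter no set.
    """
    config = config or NormConfig()
    raw_a = np.asarray(raw_a, dtype=float)
    raw_b = np.asarray(raw_b, dtype=float)
    total = raw_a + raw_b
    with np.errstate(invalid="ignore"):
        floor = config.intensity_floor_frac * np.nanmedian(total)
    usable = np.isfinite(total) & (total >= floor)
    baf = provisional_baf(raw_a, raw_b)
    usable &= np.isfinite(baf)
    low, high = config.ratio_bounds
    return {
        "cand_AA": np.flatnonzero(usable & (baf <= low)),
        "cand_AB": np.flatnonzero(usable & (baf > low) & (baf < high)),
        "cand_BB": np.flatnonzero(usable & (baf >= high)),
        "excluded": np.flatnonzero(~usable),
    }


def weighted_mode_scale(values: np.ndarray, config: NormConfig | None = None) -> float:
    """Scale from the weighted candidate-intensity distribution.

    The candidate values are smoothed into a KDE density and weighted by
    intensity (w(x) = x). The returned scale is the highest-intensity
    local maximum of the weighted curve whose height reaches
    ``mode_frac`` of the curve maximum: at markers where the candidate
    pool mixes a half-dose (hemizygous-deletion) cluster with the
    full-dose cluster, this locks onto the full-dose mode even when the
    deletion cluster is the more frequent one, which a global maximum of
    any mildly increasing weight would not.

    Raises ValueError below ``min_candidates`` (the caller falls back to
    the heterozygote arm). Degenerate (near-constant) samples return
    their common value.
    """
    config = config or NormConfig()
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < config.min_candidates:
        raise ValueError(
            f"{len(values)} candidates < min_candidates={config.min_candidates}"
        )
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12 or np.std(values) < 1e-12:
        return float(np.median(values))
    if config.bandwidth == "silverman":
        # robust Silverman: the plain rule oversmooths bimodal candidate
        # pools (half-dose + full-dose clusters) and erases the minor
        # full-dose mode; the IQR-based sigma keeps it resolvable
        sd = float(np.std(values, ddof=1))
        q75, q25 = np.percentile(values, [75, 25])
        sigma = min(sd, (q75 - q25) / 1.349) or sd
        bw = 0.9 * sigma * len(values) ** (-0.2) / sd
    else:
        bw = config.bandwidth
    kde = gaussian_kde(values, bw_method=bw)
    grid = np.linspace(lo, hi, config.grid_points)
    curve = grid * kde(grid)
    left = np.r_[-np.inf, curve[:-1]]
    right = np.r_[curve[1:], -np.inf]
    modes = np.flatnonzero((curve >= left) & (curve >= right))
    strong = modes[curve[modes] >= config.mode_frac * curve.max()]
    return float(grid[strong[-1]])


def heterozygote_fallback_scale(
    ab_values_a: np.ndarray, ab_values_b: np.ndarray, config: NormConfig | None = None
) -> tuple[float, float]:
    """Per-channel scales from heterozygote candidates: the weighted mode
    of each channel divided by ``het_target``."""
    config = config or NormConfig()
    scale_a = weighted_mode_scale(ab_values_a, config) / config.het_target
    scale_b = weighted_mode_scale(ab_values_b, config) / config.het_target
    return scale_a, scale_b


def compute_scaling_factors(
    raw_a: np.ndarray, raw_b: np.ndarray, config: NormConfig | None = None
) -> ScalingFactors:
    """Derive both channel scales for one marker.

    Each channel tries its homozygote arm first, then the heterozygote
    fallback; a channel with neither is left unscaled (source 'none')."""
    config = config or NormConfig()
    parts = candidate_partition(raw_a, raw_b, config)
    raw_a = np.asarray(raw_a, dtype=float)
    raw_b = np.asarray(raw_b, dtype=float)

    def one_channel(values_hom: np.ndarray, values_het: np.ndarray) -> tuple[float, str, int]:
        try:
            return weighted_mode_scale(values_hom, config), "homozygote", len(values_hom)
        except ValueError:
            pass
        try:
            scale = weighted_mode_scale(values_het, config) / config.het_target
            return scale, "heterozygote", len(values_het)
        except ValueError:
            return 1.0, "none", 0

    scale_a, source_a, n_a = one_channel(
        raw_a[parts["cand_AA"]], raw_a[parts["cand_AB"]]
    )
    scale_b, source_b, n_b = one_channel(
        raw_b[parts["cand_BB"]], raw_b[parts["cand_AB"]]
    )
    # a zero scale would blow up the division; treat as unusable
    if source_a != "none" and not scale_a > 0:
        scale_a, source_a = 1.0, "none"
    if source_b != "none" and not scale_b > 0:
        scale_b, source_b = 1.0, "none"
    return ScalingFactors(scale_a, scale_b, source_a, source_b, n_a, n_b)


def normalize_marker(
    raw_a: np.ndarray, raw_b: np.ndarray, factors: ScalingFactors
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each channel by its scale (unscaled pass-through when the
    channel's source is 'none')."""
    norm_a = np.asarray(raw_a, dtype=float) / (
        factors.scale_a if factors.source_a != "none" else 1.0
    )
    norm_b = np.asarray(raw_b, dtype=float) / (
        factors.scale_b if factors.source_b != "none" else 1.0
    )
    return norm_a, norm_b


def normalize_matrix(
    intens: IntensityMatrix, config: NormConfig | None = None
) -> tuple[IntensityMatrix, list[ScalingFactors]]:
    """Normalize every marker of an intensity matrix; returns the scaled
    matrix (``normalized=True``) and the per-marker factors."""
    config = config or NormConfig()
    norm_a = np.empty_like(intens.chan_a)
    norm_b = np.empty_like(intens.chan_b)
    all_factors: list[ScalingFactors] = []
    for i in range(intens.shape[0]):
        factors = compute_scaling_factors(intens.chan_a[i], intens.chan_b[i], config)
        norm_a[i], norm_b[i] = normalize_marker(intens.chan_a[i], intens.chan_b[i], factors)
        all_factors.append(factors)
    out = IntensityMatrix(
        intens.markers.copy(), intens.samples.copy(), norm_a, norm_b, normalized=True
    )
    return out, all_factors
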