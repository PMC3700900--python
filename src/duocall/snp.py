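"""BAF-clustering SNP genotyper.

Per marker, normalized channel intensities are transformed to B-allele
frequencies (the two-channel angle) and absolute intensities (channel
sum). Zero-copy samples are split off by a gap search over the sorted
absolute intensities; the remaining BAF values are histogrammed into a
density curve whose peaks (up to three, found greedily by height with a
minimum separation) are the genotype cluster centres. Boundaries between
consecutive centres sit at the density minima; when fewer than three
peaks are found each cluster is re-histogrammed at finer resolution to
pick up sub-clusters (the channel-imbalance pathology where AB and a
homozygote merge at coarse binning). Every non-zero, non-missing sample
is then genotyped by interval membership, and two quality measures are
attached: a per-marker global score (mean within-cluster BAF SD) and a
per-call score (distance to the assigned centre over the distance to the
nearest neighbouring centre).
"""

from __future__ import annotations

import numpy as np

from .config import SnpConfig
from .types import AA, AB, BB, NOCALL, ZERO, BafProfile

_ANCHORS = np.array([0.0, 0.5, 1.0])  # canonical AA / AB / BB positions


def baf_transform(norm_a: np.ndarray, norm_b: np.ndarray) -> BafProfile:
    """BAF = (2/pi)*atan2(b, a) clipped to [0,1]; absolute intensity a+b.

    Samples with both channels zero get NaN BAF and absolute intensity 0;
    missing channels propagate to NaN in both fields.
    """
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    with np.errstate(invalid="ignore"):
        baf = np.clip((2.0 / np.pi) * np.arctan2(b, a), 0.0, 1.0)
    both_zero = (a == 0) & (b == 0)
    baf[both_zero] = np.nan
    return BafProfile(baf=baf, abs_intensity=a + b)


def zero_threshold(
    abs_intensity: np.ndarray, config: SnpConfig | None = None
) -> tuple[float | None, np.ndarray]:
    """Find the absolute-intensity threshold under which samples carry
    zero copies.

    The intensities are sorted and consecutive differences computed; a
    gap whose lower value lies in the expected threshold range and whose
    size exceeds ``zero_gap_factor`` times the median consecutive
    difference fixes the threshold at the gap midpoint. Returns
    (threshold-or-None, zero mask over all samples).
    """
    config = config or SnpConfig()
    x = np.asarray(abs_intensity, dtype=float)
    mask = np.zeros(x.shape, dtype=bool)
    finite = np.isfinite(x)
    vals = np.sort(x[finite])
    if len(vals) < 2:
        return None, mask
    diffs = np.diff(vals)
    lo, hi = config.zero_expected_range
    in_range = (vals[:-1] >= lo) & (vals[:-1] <= hi)
    if not in_range.any():
        return None, mask
    cand = np.where(in_range, diffs, -np.inf)
    best = int(np.argmax(cand))
    # null scale: typical consecutive spacing, the candidate gap excluded
    others = np.delete(diffs, best)
    med = float(np.median(others)) if len(others) else 0.0
    if not cand[best] > config.zero_gap_factor * med or cand[best] <= 0:
        return None, mask
    threshold = float((vals[best] + vals[best + 1]) / 2.0)
    mask[finite] = x[finite] <= threshold
    return threshold, mask


def baf_pdf(
    baf: np.ndarray, n_bins: int, support: tuple[float, float] = (0.0, 1.0)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled histogram of BAF values over ``support``.

    Returns (bin centres, density integrating to 1, raw counts).
    """
    baf = np.asarray(baf, dtype=float)
    baf = baf[np.isfinite(baf)]
    counts, edges = np.histogram(baf, bins=n_bins, range=support)
    centres = (edges[:-1] + edges[1:]) / 2.0
    width = edges[1] - edges[0]
    total = counts.sum()
    density = counts / (total * width) if total > 0 else counts.astype(float)
    return centres, density, counts


def smooth_density(density: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving-average smoothing of a histogram density (zero-padded at
    the edges); suppresses single-bin sampling noise before peak search.
    """
    if window <= 1:
        return np.asarray(density, dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(np.asarray(density, dtype=float), kernel, mode="same")


def find_peaks(
    centres: np.ndarray,
    density: np.ndarray,
    config: SnpConfig | None = None,
    counts: np.ndarray | None = None,
    min_count: int = 1,
    max_peaks: int = 3,
    existing: np.ndarray | None = None,
    anchor_unique: bool = True,
) -> np.ndarray:
    """Greedy peak search over a density curve.

    Candidate bins must be local maxima with density at least
    ``min_peak_frac`` of the curve maximum (and, when ``counts`` is
    given, at least ``min_count`` samples). Candidates are taken in
    descending height (ties: lower BAF), each kept only if at least
    ``min_separation`` away from every already-accepted peak (including
    ``existing`` ones); the search stops at ``max_peaks`` accepted peaks.
    Returned sorted ascending.

    With ``anchor_unique`` (the coarse global pass) at most one peak may
    claim each genotype anchor {0, 0.5, 1}: wide hemizygous-deletion
    clusters put heavy shoulders next to a homozygote peak, and without
    this rule a shoulder bump can steal the heterozygote slot. The
    refinement pass disables it, since sub-clusters merged by channel
    imbalance legitimately share an anchor.
    """
    config = config or SnpConfig()
    density = np.asarray(density, dtype=float)
    if density.size == 0 or density.max() <= 0:
        return np.empty(0)
    n = len(density)
    left = np.r_[-np.inf, density[:-1]]
    right = np.r_[density[1:], -np.inf]
    is_max = (density >= left) & (density >= right) & (density > 0)
    is_max &= density >= config.min_peak_frac * density.max()
    if counts is not None:
        # a peak must carry real samples within its smoothing window
        # (smoothing can move plateau maxima onto empty bins)
        win = max(1, config.smooth_window)
        wc = np.convolve(np.asarray(counts, dtype=float), np.ones(win), mode="same")
        is_max &= wc >= max(min_count, 1)
    cand = np.flatnonzero(is_max)
    if cand.size == 0:
        return np.empty(0)
    # descending height, ties resolved toward lower BAF
    order = np.lexsort((centres[cand], -density[cand]))
    accepted: list[float] = []
    prior = list(existing) if existing is not None else []
    claimed: set[int] = set()
    for idx in cand[order]:
        c = centres[idx]
        if not all(abs(c - p) >= config.min_separation for p in accepted + prior):
            continue
        if anchor_unique:
            nearest = int(np.argmin(np.abs(_ANCHORS - c)))
            if nearest in claimed:
                continue
            claimed.add(nearest)
        accepted.append(float(c))
        if len(accepted) >= max_peaks:
            break
    return np.sort(np.asarray(accepted))


def genotype_limits(
    centres: np.ndarray, density: np.ndarray, peaks: np.ndarray
) -> np.ndarray:
    """Boundary per consecutive peak pair at the density minimum strictly
    between them.

    When several bins tie at the minimum (typically an empty plateau
    between well-separated clusters) the boundary sits at the centre of
    the first contiguous minimal run, so a symmetric empty valley yields
    the midpoint rather than hugging the lower cluster's tail.
    """
    peaks = np.asarray(peaks, dtype=float)
    bounds = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        between = np.flatnonzero((centres > p0) & (centres < p1))
        if between.size == 0:
            bounds.append((p0 + p1) / 2.0)
            continue
        d = density[between]
        at_min = np.flatnonzero(d == d.min())
        # the boundary sits at the midpoint of the longest contiguous run
        # of minimal bins (the inter-cluster gap), not at an isolated
        # empty bin inside a cluster tail; first run wins length ties
        runs = np.split(at_min, np.flatnonzero(np.diff(at_min) > 1) + 1)
        run = max(runs, key=len)
        span = between[run[0]], between[run[-1]]
        bounds.append(float((centres[span[0]] + centres[span[1]]) / 2.0))
    return np.asarray(bounds)


def refine_subclusters(
    baf: np.ndarray,
    peaks: np.ndarray,
    limits: np.ndarray,
    config: SnpConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-analyze each genotype interval at finer binning to split merged
    clusters; no-op when three peaks already exist.

    Each interval's in-interval samples are re-histogrammed with
    ``refine_factor`` times the bin density and searched again; splits
    are accepted (interval peak replaced by its sub-peaks) only while the
    global total stays at three or fewer. Limits are recomputed globally
    on the fine histogram afterwards.
    """
    config = config or SnpConfig()
    baf = np.asarray(baf, dtype=float)
    baf = baf[np.isfinite(baf)]
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) >= 3 or len(peaks) == 0:
        return peaks, limits
    n_bins = config.bins_for(len(baf))
    edges = np.r_[0.0, limits, 1.0]
    new_peaks: list[float] = []
    total = len(peaks)
    for j, peak in enumerate(peaks):
        lo, hi = edges[j], edges[j + 1]
        sel = baf[(baf >= lo) & (baf <= hi)]
        fine_bins = max(4, int(round(n_bins * config.refine_factor * (hi - lo))))
        centres, density, counts = baf_pdf(sel, fine_bins, support=(lo, hi))
        density = smooth_density(density, config.smooth_window)
        sub = find_peaks(
            centres,
            density,
            config,
            counts=counts,
            min_count=config.refine_min_count,
            max_peaks=3,
            anchor_unique=False,
        )
        if len(sub) >= 2 and total - 1 + len(sub) <= 3:
            new_peaks.extend(sub.tolist())
            total += len(sub) - 1
        else:
            new_peaks.append(float(peak))
    new_peaks_arr = np.sort(np.asarray(new_peaks))
    if len(new_peaks_arr) == len(peaks):
        return peaks, limits
    fine_global = max(8, n_bins * config.refine_factor)
    centres, density, _ = baf_pdf(baf, fine_global)
    density = smooth_density(density, config.smooth_window)
    return new_peaks_arr, genotype_limits(centres, density, new_peaks_arr)


def label_peaks(peaks: np.ndarray) -> np.ndarray:
    """Map peak positions to genotype codes.

    Three peaks map ascending to AA, AB, BB. Fewer peaks are assigned to
    the anchor set {0, 0.5, 1} by total distance over order-preserving
    assignments, ties broken toward homozygotes.
    """
    peaks = np.asarray(peaks, dtype=float)
    k = len(peaks)
    if k == 3:
        return np.array([AA, AB, BB])
    if k == 1:
        d = np.abs(_ANCHORS - peaks[0])
        # ties toward homozygote: visit homozygote anchors first
        order = [0, 2, 1]
        best = min(order, key=lambda i: (d[i], order.index(i)))
        return np.array([[AA, AB, BB][best]])
    if k == 2:
        options = [(AA, AB), (AA, BB), (AB, BB)]
        anchor_pos = {AA: 0.0, AB: 0.5, BB: 1.0}
        costs = [
            abs(peaks[0] - anchor_pos[g0]) + abs(peaks[1] - anchor_pos[g1])
            for g0, g1 in options
        ]
        # tie-break preference: assignments using homozygote anchors first
        pref = {(AA, BB): 0, (AA, AB): 1, (AB, BB): 2}
        best = min(range(3), key=lambda i: (costs[i], pref[options[i]]))
        return np.array(list(options[best]))
    return np.empty(0, dtype=int)


def assign_genotypes(
    baf: np.ndarray,
    peaks: np.ndarray,
    limits: np.ndarray,
    zero_mask: np.ndarray,
) -> np.ndarray:
    """Label every sample: ZERO by mask, NOCALL for missing BAF, else the
    genotype of the BAF interval the sample falls in."""
    baf = np.asarray(baf, dtype=float)
    out = np.full(baf.shape, NOCALL, dtype=np.int8)
    codes = label_peaks(peaks)
    valid = np.isfinite(baf) & ~zero_mask
    if len(codes):
        idx = np.searchsorted(np.asarray(limits, dtype=float), baf[valid], side="right")
        out[valid] = codes[idx]
    out[zero_mask] = ZERO
    return out


def quality_scores(
    baf: np.ndarray, genotypes: np.ndarray, peaks: np.ndarray
) -> tuple[float, np.ndarray]:
    """Global score = mean within-cluster BAF SD over occupied clusters;
    call score = |baf - own centre| / distance to the nearest adjacent
    centre (1 when the marker has a single centre). Lower is better."""
    baf = np.asarray(baf, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    codes = label_peaks(peaks)
    call_scores = np.full(baf.shape, np.nan)
    sds = []
    if len(peaks) == 1:
        denoms = np.array([1.0])
    else:
        gaps = np.diff(peaks)
        denoms = np.array(
            [
                min(
                    gaps[j - 1] if j > 0 else np.inf,
                    gaps[j] if j < len(gaps) else np.inf,
                )
                for j in range(len(peaks))
            ]
        )
    for j, code in enumerate(codes):
        members = (genotypes == code) & np.isfinite(baf)
        if members.any():
            sds.append(float(np.std(baf[members])))
            call_scores[members] = np.abs(baf[members] - peaks[j]) / denoms[j]
    global_score = float(np.mean(sds)) if sds else np.nan
    return global_score, call_scores


def call_marker(
    norm_a: np.ndarray, norm_b: np.ndarray, config: SnpConfig | None = None
) -> dict:
    """Run the full per-marker SNP pipeline on normalized intensities.

    Returns a dict with the BafProfile, peaks, limits, genotypes and
    quality scores; all samples NOCALL when fewer than ``min_samples``
    usable BAF values remain after zero-copy removal.
    """
    config = config or SnpConfig()
    profile = baf_transform(norm_a, norm_b)
    threshold, zmask = zero_threshold(profile.abs_intensity, config)
    profile.zero_threshold = threshold
    profile.zero_mask = zmask
    usable = np.isfinite(profile.baf) & ~zmask
    n_usable = int(usable.sum())
    result = {
        "profile": profile,
        "peaks": np.empty(0),
        "limits": np.empty(0),
        "genotypes": np.full(profile.baf.shape, NOCALL, dtype=np.int8),
        "global_score": np.nan,
        "call_scores": np.full(profile.baf.shape, np.nan),
    }
    if n_usable < config.min_samples:
        result["genotypes"][zmask] = ZERO
        return result
    baf = profile.baf[usable]
    n_bins = config.bins_for(n_usable)
    centres, density, counts = baf_pdf(baf, n_bins)
    density = smooth_density(density, config.smooth_window)
    peaks = find_peaks(centres, density, config, counts=counts)
    if len(peaks) == 0:
        result["genotypes"][zmask] = ZERO
        return result
    limits = genotype_limits(centres, density, peaks)
    peaks, limits = refine_subclusters(baf, peaks, limits, config)
    genotypes = assign_genotypes(profile.baf, peaks, limits, zmask)
    global_score, call_scores = quality_scores(profile.baf, genotypes, peaks)
    result.update(
        peaks=peaks,
        limits=limits,
        genotypes=genotypes,
        global_score=global_score,
        call_scores=call_scores,
    )
    return result
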