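"""Four-arm copy-number genotyper.

Copy-number information at a marker lives in the single channel that
carries the called allele, so each SNP genotype cluster is analyzed on
its informative channel only: channel A of the AA homozygotes, channel B
of the BB homozygotes, and both channels of the heterozygotes (four
independent arms). Each arm's intensities are fitted with a
one-component Gaussian (closed form) and a two-component mixture (EM);
the two-component model is kept only when every selection requirement
holds (BIC improvement beyond a margin, minimum component weight, mean
separation in pooled-SD units, EM convergence). Selected components are
mapped to allele doses using the component weights and the presence of
zero-copy samples at the marker: the frequent component is diploid dose,
and a minor *high* component is an amplification only when no zero-copy
samples argue for a deletion allele segregating. Samples far outside the
selected model (|z| > z_cut) are flagged as low/high outliers and scored
at the capped deletion/amplification value. The final per-sample score S
in [0, 3] is the posterior-weighted allele dose (summed over the two
channels for heterozygotes) and is binned at 0.5 / 1.5 / 2.5 into CN0,
CN1, CN2 and CN3+ categories; amplifications are one pooled category
because fluorescence saturates at high dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import CnvConfig
from .types import (
    AA,
    AB,
    BB,
    ZERO,
    CnvScoreSet,
    GmmFit,
    SnpCallSet,
    bin_scores,
)

ARM_IDS = ("AA_on_A", "BB_on_B", "AB_on_A", "AB_on_B")


@dataclass
class AnalysisArm:
    """One genotype-cluster x channel analysis unit."""

    arm_id: str
    sample_idx: np.ndarray  # indices into the marker's sample axis
    intensities: np.ndarray
    fit1: GmmFit | None = None
    fit2: GmmFit | None = None
    selected: str | None = None  # 'one' | 'two' | None (skipped)
    labels: np.ndarray | None = None  # per-component dose (see label_components)
    outlier_low: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    outlier_high: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def is_het(self) -> bool:
        return self.arm_id.startswith("AB")


def partition_arms(
    genotypes: np.ndarray, norm_a: np.ndarray, norm_b: np.ndarray
) -> list[AnalysisArm]:
    """Split one marker's samples into the four analysis arms.

    ZERO-called samples enter no arm (they are already resolved);
    heterozygotes appear once per channel.
    """
    genotypes = np.asarray(genotypes)
    aa = np.flatnonzero(genotypes == AA)
    bb = np.flatnonzero(genotypes == BB)
    het = np.flatnonzero(genotypes == AB)
    return [
        AnalysisArm("AA_on_A", aa, np.asarray(norm_a, dtype=float)[aa]),
        AnalysisArm("BB_on_B", bb, np.asarray(norm_b, dtype=float)[bb]),
        AnalysisArm("AB_on_A", het, np.asarray(norm_a, dtype=float)[het]),
        AnalysisArm("AB_on_B", het, np.asarray(norm_b, dtype=float)[het]),
    ]


# ---------------------------------------------------------------------------
# Gaussian fits


def _gauss_loglik(x: np.ndarray, mean: float, var: float) -> float:
    return float(np.sum(norm.logpdf(x, loc=mean, scale=np.sqrt(var))))


def fit_one_component(x: np.ndarray, var_floor: float = 1e-4) -> GmmFit:
    """Closed-form single Gaussian: sample mean and (floored) variance."""
    x = np.asarray(x, dtype=float)
    mean = float(np.mean(x))
    var = max(float(np.var(x)), var_floor)
    return GmmFit(
        n_components=1,
        weights=np.array([1.0]),
        means=np.array([mean]),
        variances=np.array([var]),
        loglik=_gauss_loglik(x, mean, var),
        posteriors=np.ones((len(x), 1)),
    )


def _em_once(
    x: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    weights: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, bool, int, list[float]]:
    """Plain univariate 2-component EM from a given start.

    Returns (weights, means, variances, posteriors, loglik, converged,
    n_iter, loglik trace).
    """
    n = len(x)
    loglik = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    resp = np.full((n, 2), 0.5)
    for it in range(1, max_iter + 1):
        # E step (log-space for stability)
        logp = norm.logpdf(x[:, None], loc=means[None, :], scale=np.sqrt(variances)[None, :])
        logp = logp + np.log(weights)[None, :]
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        new_loglik = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        trace.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * (abs(loglik) + 1e-12):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
        # M step
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():  # a component died
            break
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
    order = np.argsort(means)
    return (
        weights[order],
        means[order],
        variances[order],
        resp[:, order],
        loglik,
        converged,
        it,
        trace,
    )


def fit_two_component(
    x: np.ndarray,
    n_restarts: int = 9,
    tol: float = 1e-6,
    max_iter: int = 200,
    var_floor: float = 1e-4,
    seed: int | np.random.Generator = 0,
    return_trace: bool = False,
) -> GmmFit:
    """Two-component univariate Gaussian mixture by EM, best of
    ``n_restarts`` starts (one deterministic below/above-median split,
    the rest random seeded splits). Components reported mean-ascending.
    """
    x = np.asarray(x, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = []
    # deterministic quantile-split starts cover minor-component weights
    # on either side; extra restarts are seeded random two-point starts
    for q in (0.5, 0.25, 0.75, 0.1, 0.9, 0.35, 0.65, 0.15, 0.85)[: max(1, n_restarts)]:
        cut = np.quantile(x, q)
        lo, hi = x[x <= cut], x[x > cut]
        if len(lo) == 0 or len(hi) == 0:
            continue
        starts.append(
            (
                np.array([lo.mean(), hi.mean()]),
                np.maximum(np.array([lo.var(), hi.var()]), var_floor),
                np.array([len(lo), len(hi)]) / len(x),
            )
        )
    for _ in range(max(0, n_restarts - len(starts))):
        centres = rng.choice(x, size=2, replace=False)
        centres = np.sort(centres)
        var0 = max(float(np.var(x)) / 4.0, var_floor)
        starts.append((centres.astype(float), np.array([var0, var0]), np.array([0.5, 0.5])))

    best = None
    for means0, vars0, weights0 in starts:
        out = _em_once(x, means0.copy(), vars0.copy(), weights0.copy(), tol, max_iter, var_floor)
        if best is None or out[4] > best[4]:
            best = out
    weights, means, variances, resp, loglik, converged, n_iter, trace = best
    fit = GmmFit(
        n_components=2,
        weights=weights / weights.sum(),
        means=means,
        variances=variances,
        loglik=loglik,
        posteriors=resp / resp.sum(axis=1, keepdims=True),
        converged=converged,
        n_iter=n_iter,
    )
    if return_trace:
        fit.loglik_trace = trace  # type: ignore[attr-defined]
    return fit


def select_model(fit1: GmmFit, fit2: GmmFit | None, config: CnvConfig | None = None) -> str:
    """Keep the two-component model only when all requirements hold:
    BIC improvement beyond ``bic_margin``, minimum component weight,
    mean separation >= ``sep_factor`` pooled within-component SDs, and
    EM convergence. Otherwise 'one'."""
    config = config or CnvConfig()
    if fit2 is None or not fit2.converged:
        return "one"
    n = fit2.posteriors.shape[0]
    if not fit2.bic(n) < fit1.bic(n) - config.bic_margin:
        return "one"
    if fit2.weights.min() < config.min_weight:
        return "one"
    pooled_sd = float(np.sqrt(np.sum(fit2.weights * fit2.variances)))
    if abs(fit2.means[1] - fit2.means[0]) < config.sep_factor * pooled_sd:
        return "one"
    return "two"


def label_components(fit2: GmmFit, is_het_arm: bool, zero_present: bool) -> np.ndarray:
    """Assign a per-sample dose to each mixture component (ascending-mean
    order).

    Homozygote arms use total-copy doses {1: hemizygous deletion,
    2: diploid, 3: amplification}; the disambiguation keys on which
    component is the frequent one and on whether zero-copy samples were
    seen at the marker (a segregating deletion allele makes the low
    component a deletion; without it a minor high component is an
    amplification). Heterozygote arms use per-allele doses {1: normal,
    2: amplified}: an AB call guarantees one copy of each allele, so no
    component may be labelled as an allele deletion, and the majority
    component is always the normal dose — only a *minor, higher*
    component reads as an allele amplification.
    """
    if is_het_arm:
        w_low, w_high = fit2.weights
        if w_high < w_low:
            return np.array([1.0, 2.0])
        return np.array([1.0, 1.0])
    w_low, w_high = fit2.weights
    if w_high >= w_low:
        # frequent high component: diploid over a deletion cluster
        return np.array([1.0, 2.0])
    if zero_present:
        # minor high component but deletions segregate: still diploid/deletion
        return np.array([1.0, 2.0])
    # minor high component, no zero-copy evidence: amplification over diploid
    return np.array([2.0, 3.0])


def detect_outliers(
    x: np.ndarray, fit: GmmFit, z_cut: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag samples beyond ``z_cut`` SDs of their maximum-posterior
    component; returns (low mask, high mask)."""
    x = np.asarray(x, dtype=float)
    comp = np.argmax(fit.posteriors, axis=1) if len(x) else np.empty(0, dtype=int)
    mu = fit.means[comp]
    sd = np.sqrt(fit.variances[comp])
    z = (x - mu) / sd
    return z < -z_cut, z > z_cut


def process_arm(
    arm: AnalysisArm,
    zero_present: bool,
    config: CnvConfig,
    rng,
    het_ref: float | None = None,
) -> AnalysisArm:
    """Fit, select, label and outlier-screen a single arm in place.

    ``het_ref`` is the heterozygote per-allele intensity on the arm's
    channel. A one-component homozygote arm is normally labelled diploid,
    but when deletions segregate at the marker (zero-copy samples seen)
    and the arm mean sits near 1x the heterozygote per-allele signal
    instead of 2x, the whole "homozygote" cluster carries a single
    allele copy — the low-MAF case where every called homozygote is in
    fact hemizygous — and is labelled as a deletion cluster.
    """
    if len(arm.intensities) < config.min_arm_size:
        arm.selected = None
        return arm
    em = config.em
    arm.fit1 = fit_one_component(arm.intensities, var_floor=em.var_floor)
    arm.fit2 = fit_two_component(
        arm.intensities,
        n_restarts=em.restarts,
        tol=em.tol,
        max_iter=em.max_iter,
        var_floor=em.var_floor,
        seed=rng,
    )
    arm.selected = select_model(arm.fit1, arm.fit2, config)
    fit = arm.fit2 if arm.selected == "two" else arm.fit1
    if arm.selected == "two":
        arm.labels = label_components(arm.fit2, arm.is_het, zero_present)
    elif arm.is_het:
        arm.labels = np.array([1.0])
    elif (
        zero_present
        and het_ref is not None
        and het_ref > 0
        and arm.fit1.means[0] < 1.5 * het_ref
    ):
        arm.labels = np.array([1.0])  # hemizygous cluster, not diploid
    else:
        arm.labels = np.array([2.0])
    arm.outlier_low, arm.outlier_high = detect_outliers(arm.intensities, fit, config.z_cut)
    return arm


def score_samples(
    arms: list[AnalysisArm], genotypes: np.ndarray, zero_mask: np.ndarray
) -> np.ndarray:
    """Combine arm fits into a per-sample score S in [0, 3].

    ZERO samples score 0. Homozygote samples take the posterior-weighted
    dose of their arm (2 when the arm was skipped or one-component);
    low/high outliers are capped at 1/3. Heterozygote samples sum a
    per-allele dose from each channel arm (1 per channel when skipped or
    one-component; channel outliers contribute 0 low / 2 high).
    """
    genotypes = np.asarray(genotypes)
    n = len(genotypes)
    scores = np.full(n, np.nan)
    hom_arms = {a.arm_id: a for a in arms}

    def arm_doses(arm: AnalysisArm, default: float) -> np.ndarray:
        """Per-sample posterior-weighted dose over one arm."""
        k = len(arm.sample_idx)
        if arm.selected is None:
            return np.full(k, default)
        fit = arm.fit2 if arm.selected == "two" else arm.fit1
        doses = (fit.posteriors * arm.labels[None, :]).sum(axis=1)
        if arm.is_het:
            doses[arm.outlier_low] = 0.0
            doses[arm.outlier_high] = 2.0
        else:
            doses[arm.outlier_low] = 1.0
            doses[arm.outlier_high] = 3.0
        return doses

    for arm_id, default in (("AA_on_A", 2.0), ("BB_on_B", 2.0)):
        arm = hom_arms[arm_id]
        if len(arm.sample_idx):
            scores[arm.sample_idx] = arm_doses(arm, default)

    het_a, het_b = hom_arms["AB_on_A"], hom_arms["AB_on_B"]
    if len(het_a.sample_idx):
        scores[het_a.sample_idx] = arm_doses(het_a, 1.0) + arm_doses(het_b, 1.0)

    scores[np.asarray(zero_mask, dtype=bool)] = 0.0
    return np.clip(scores, 0.0, 3.0, out=scores)


def call_marker_cnv(
    genotypes: np.ndarray,
    norm_a: np.ndarray,
    norm_b: np.ndarray,
    zero_mask: np.ndarray,
    config: CnvConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[AnalysisArm]]:
    """Run the four-arm analysis for one marker; returns (scores, arms)."""
    config = config or CnvConfig()
    rng = rng or np.random.default_rng(config.seed)
    zero_present = bool(np.asarray(zero_mask).any())
    arms = partition_arms(genotypes, norm_a, norm_b)
    by_id = {a.arm_id: a for a in arms}
    # heterozygote arms first: their medians give the per-allele signal
    # reference the homozygote-arm labeling cross-checks against
    het_refs: dict[str, float | None] = {"A": None, "B": None}
    for chan in ("A", "B"):
        arm = by_id[f"AB_on_{chan}"]
        process_arm(arm, zero_present, config, rng)
        if len(arm.intensities) >= config.min_arm_size:
            het_refs[chan] = float(np.median(arm.intensities))
    process_arm(by_id["AA_on_A"], zero_present, config, rng, het_ref=het_refs["A"])
    process_arm(by_id["BB_on_B"], zero_present, config, rng, het_ref=het_refs["B"])
    scores = score_samples(arms, genotypes, zero_mask)
    return scores, arms


def marker_summary_row(arms: list[AnalysisArm]) -> dict:
    row: dict = {}
    for arm in arms:
        row[f"model_{arm.arm_id}"] = arm.selected or "skipped"
        row[f"n_{arm.arm_id}"] = len(arm.sample_idx)
        row[f"outliers_{arm.arm_id}"] = int(arm.outlier_low.sum() + arm.outlier_high.sum())
    return row


def build_score_set(
    markers: np.ndarray,
    samples: np.ndarray,
    scores: np.ndarray,
    marker_info: pd.DataFrame | None = None,
) -> CnvScoreSet:
    return CnvScoreSet(markers, samples, scores, bin_scores(scores), marker_info)
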