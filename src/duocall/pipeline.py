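"""End-to-end orchestration: normalize -> SNP call -> CNV call.

Markers are processed independently in manifest order (no cross-marker
state beyond the global seed scheme, so chunked or parallel execution
gives identical results). Per-marker EM seeds derive from the global
seed plus the marker index.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from . import snp as snp_mod
from .config import PipelineConfig
from .normalization import compute_scaling_factors, normalize_marker
from .types import CnvScoreSet, GENOTYPE_CODES, IntensityMatrix, SnpCallSet, bin_scores

logger = logging.getLogger(__name__)


def call_dataset(
    intens: IntensityMatrix, config: PipelineConfig | None = None
) -> tuple[SnpCallSet, CnvScoreSet, IntensityMatrix]:
    """Run the whole genotyping pipeline on a raw intensity matrix.

    Returns the SNP call set, the CNV score set and the normalized
    intensity matrix.
    """
    config = config or PipelineConfig()
    n_m, n_s = intens.shape
    if intens.normalized:
        raise ValueError("expected raw (unnormalized) intensities")

    genotypes = np.empty((n_m, n_s), dtype=np.int8)
    call_scores = np.full((n_m, n_s), np.nan)
    global_scores = np.full(n_m, np.nan)
    zero_thresholds = np.full(n_m, np.nan)
    peaks_list, limits_list = [], []
    scores = np.full((n_m, n_s), np.nan)
    info_rows = []
    norm_a = np.empty((n_m, n_s))
    norm_b = np.empty((n_m, n_s))

    t0 = time.perf_counter()
    for i in range(n_m):
        raw_a, raw_b = intens.chan_a[i], intens.chan_b[i]
        factors = compute_scaling_factors(raw_a, raw_b, config.norm)
        na, nb = normalize_marker(raw_a, raw_b, factors)
        norm_a[i], norm_b[i] = na, nb

        snp_res = snp_mod.call_marker(na, nb, config.snp)
        genotypes[i] = snp_res["genotypes"]
        call_scores[i] = snp_res["call_scores"]
        global_scores[i] = snp_res["global_score"]
        if snp_res["profile"].zero_threshold is not None:
            zero_thresholds[i] = snp_res["profile"].zero_threshold
        peaks_list.append(snp_res["peaks"])
        limits_list.append(snp_res["limits"])

        rng = np.random.default_rng([config.seed, i])
        marker_scores, arms = cnv_mod.call_marker_cnv(
            snp_res["genotypes"], na, nb, snp_res["profile"].zero_mask, config.cnv, rng
        )
        scores[i] = marker_scores
        row = cnv_mod.marker_summary_row(arms)
        row["norm_source_a"] = factors.source_a
        row["norm_source_b"] = factors.source_b
        row["n_peaks"] = len(snp_res["peaks"])
        info_rows.append(row)
    logger.info("called %d markers x %d samples in %.2fs", n_m, n_s, time.perf_counter() - t0)

    snp_set = SnpCallSet(
        intens.markers.copy(),
        intens.samples.copy(),
        genotypes,
        peaks_list,
        limits_list,
        global_scores,
        call_scores,
        zero_thresholds,
    )
    cnv_set = CnvScoreSet(
        intens.markers.copy(),
        intens.samples.copy(),
        scores,
        bin_scores(scores),
        pd.DataFrame(info_rows),
    )
    normalized = IntensityMatrix(
        intens.markers.copy(), intens.samples.copy(), norm_a, norm_b, normalized=True
    )
    return snp_set, cnv_set, normalized


def genotype_concordance(snp: SnpCallSet, truth_snp_genotype: np.ndarray) -> dict:
    """Concordance of SNP calls against truth labels ('AA'/'AB'/'BB'/
    'ZERO'); returns call rate and accuracy over called genotypes (%)."""
    truth_codes = np.vectorize(GENOTYPE_CODES.get)(truth_snp_genotype)
    called = snp.genotypes != GENOTYPE_CODES["NOCALL"]
    n_total = snp.genotypes.size
    n_called = int(called.sum())
    n_correct = int((called & (snp.genotypes == truth_codes)).sum())
    return {
        "call_rate_pct": 100.0 * n_called / n_total,
        "accuracy_pct": 100.0 * n_correct / max(1, n_called),
        "global_accuracy_pct": 100.0 * n_correct / n_total,
    }


def category_concordance(cnv: CnvScoreSet, truth_cn: np.ndarray) -> float:
    """Per-sample copy-number category concordance (%) against true
    copy numbers (capped at 3 to match the pooled amplification bin)."""
    truth = np.minimum(np.asarray(truth_cn, dtype=int), 3)
    called = cnv.categories >= 0
    match = (cnv.categories == truth) & called
    return 100.0 * int(match.sum()) / max(1, int(called.sum()))
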