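"""Concordance, association-power and LD-mining metrics.

Three layers: (i) per-locus concordance of copy-number calls against an
external reference set, as the maximum r^2 over the markers inside each
locus; (ii) pairwise-population chi-square association with the
-log10 P ratio summary (fraction of loci whose method-vs-reference
association-strength ratio lands in a window around 1); (iii) LD mining:
SNP-CNV candidate pairing under distance/r^2/annotation filters and
multi-marker CNV locus construction over genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .config import EvalConfig
from .types import (
    AnnotationIntervals,
    CnvScoreSet,
    MarkerManifest,
    ReferenceLocusSet,
)


def genotype_r2(calls_x: np.ndarray, calls_y: np.ndarray) -> float:
    """Squared Pearson correlation of two paired copy-number vectors.

    Missing entries (negative or NaN) are dropped pairwise. A
    zero-variance side makes r^2 undefined (NaN); callers maximizing
    over markers treat NaN as 0.
    """
    x = np.asarray(calls_x, dtype=float)
    y = np.asarray(calls_y, dtype=float)
    if len(x) != len(y):
        raise ValueError("call vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y) & (x >= 0) & (y >= 0)
    if not ok.any():
        raise ValueError("no shared non-missing samples")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class ConcordanceResult:
    locus_id: np.ndarray
    best_marker_id: np.ndarray  # '' when uncovered
    best_r2: np.ndarray  # NaN when uncovered
    n_markers_in_region: np.ndarray
    r2_per_marker: list  # list of (marker_id, r2) tuples per locus

    def stratify(self, bins: tuple[float, ...] = (0.8, 0.9)) -> pd.DataFrame:
        """Percentage of loci per best-r^2 stratum (plus 'uncovered' and
        'undetected' for NaN-best covered loci)."""
        edges = sorted(bins)
        labels = [f"<{edges[0]}"] + [
            f"{lo}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])
        ] + [f">{edges[-1]}"]
        counts = dict.fromkeys(["uncovered", "undetected", *labels], 0)
        for n_m, r2 in zip(self.n_markers_in_region, self.best_r2):
            if n_m == 0:
                counts["uncovered"] += 1
            elif not np.isfinite(r2):
                counts["undetected"] += 1
            else:
                counts[labels[int(np.searchsorted(edges, r2, side="left"))]] += 1
        total = max(1, len(self.locus_id))
        return pd.DataFrame(
            {"stratum": list(counts), "pct": [100.0 * c / total for c in counts.values()]}
        )


def best_marker_per_locus(
    ref: ReferenceLocusSet,
    scores: CnvScoreSet,
    manifest: MarkerManifest,
    min_shared: int = 10,
) -> ConcordanceResult:
    """For each reference locus, the marker (1-based inclusive position
    inside the locus) whose categories are in maximum LD with the
    reference calls."""
    sample_map = {s: j for j, s in enumerate(scores.samples)}
    shared = [s for s in ref.samples if s in sample_map]
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared samples (< {min_shared})")
    ref_cols = np.array([list(ref.samples).index(s) for s in shared])
    call_cols = np.array([sample_map[s] for s in shared])

    best_marker, best_r2, n_in, per_marker = [], [], [], []
    for k in range(ref.n_loci):
        inside = np.flatnonzero(
            (manifest.chrom == ref.chrom[k])
            & (manifest.pos >= ref.start[k])
            & (manifest.pos <= ref.end[k])
        )
        n_in.append(len(inside))
        pairs = []
        for i in inside:
            try:
                r2 = genotype_r2(
                    scores.categories[i, call_cols], ref.calls[k, ref_cols]
                )
            except ValueError:
                r2 = float("nan")
            pairs.append((manifest.marker_id[i], r2))
        per_marker.append(pairs)
        if pairs:
            vals = np.array([0.0 if np.isnan(r) else r for _, r in pairs])
            j = int(np.argmax(vals))
            # a locus where every marker is undefined counts as undetected
            if all(np.isnan(r) for _, r in pairs):
                best_marker.append(pairs[j][0])
                best_r2.append(float("nan"))
            else:
                best_marker.append(pairs[j][0])
                best_r2.append(float(vals[j]))
        else:
            best_marker.append("")
            best_r2.append(float("nan"))
    return ConcordanceResult(
        ref.locus_id.copy(),
        np.asarray(best_marker, dtype=object),
        np.asarray(best_r2),
        np.asarray(n_in),
        per_marker,
    )


# ---------------------------------------------------------------------------
# population association


def _pool_rare_categories(table: np.ndarray) -> np.ndarray:
    """Drop empty categories and pool categories with any expected count
    < 1 into their nearest neighbour (keeps the chi-square valid on
    sparse tables)."""
    table = table[table.sum(axis=1) > 0]
    while table.shape[0] > 2:
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        bad = np.flatnonzero((expected < 1.0).any(axis=1))
        if bad.size == 0:
            break
        i = bad[0]
        j = i - 1 if i > 0 else i + 1
        table[j] += table[i]
        table = np.delete(table, i, axis=0)
    return table


def population_association(
    calls: np.ndarray, population: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Chi-square test of independence of copy-number category vs
    population for one locus.

    Returns (contingency table, statistic, p). Missing calls (<0 / NaN)
    are dropped; degenerate tables (one category or one population)
    give p = 1.
    """
    c = np.asarray(calls, dtype=float)
    p = np.asarray(population)
    ok = np.isfinite(c) & (c >= 0)
    c, p = c[ok].astype(int), p[ok]
    pops = np.unique(p)
    cats = np.unique(c)
    table = np.zeros((len(cats), len(pops)), dtype=float)
    for i, cat in enumerate(cats):
        for j, pop in enumerate(pops):
            table[i, j] = np.sum((c == cat) & (p == pop))
    if len(cats) < 2 or len(pops) < 2:
        return table, 0.0, 1.0
    pooled = _pool_rare_categories(table.copy())
    if pooled.shape[0] < 2:
        return table, 0.0, 1.0
    stat, pval, _, _ = chi2_contingency(pooled, correction=False)
    return table, float(stat), float(pval)


def association_scan(
    categories: np.ndarray, population: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker chi-square scan: returns (chi2, p) arrays over the
    marker axis of a categories matrix (markers x samples)."""
    stats = np.empty(categories.shape[0])
    pvals = np.empty(categories.shape[0])
    for i in range(categories.shape[0]):
        _, stats[i], pvals[i] = population_association(categories[i], population)
    return stats, pvals


def locus_min_p(
    pvals: np.ndarray, manifest: MarkerManifest, ref: ReferenceLocusSet
) -> np.ndarray:
    """Best (minimum) per-marker p inside each reference locus; NaN for
    uncovered loci."""
    out = np.full(ref.n_loci, np.nan)
    for k in range(ref.n_loci):
        inside = (
            (manifest.chrom == ref.chrom[k])
            & (manifest.pos >= ref.start[k])
            & (manifest.pos <= ref.end[k])
        )
        if inside.any():
            out[k] = np.nanmin(pvals[inside])
    return out


def pvalue_ratio_metric(
    method_p: np.ndarray,
    ref_p: np.ndarray,
    window: tuple[float, float] = (0.9, 1.1),
    alpha: float = 0.05,
) -> tuple[np.ndarray, float, float]:
    """Per-locus ratio of -log10 association strengths and its summary.

    Only loci where the reference is significant (ref p < alpha; ratios
    are undefined at ref p = 1) are kept. Returns (ratios over those K
    loci, pct in window, pct missed) where missed means the method is
    non-significant at a reference-significant locus. Uncovered loci
    (NaN method p) count as missed with ratio 0.
    """
    mp = np.asarray(method_p, dtype=float)
    rp = np.asarray(ref_p, dtype=float)
    keep = np.isfinite(rp) & (rp < alpha) & (rp > 0)
    mp, rp = mp[keep], rp[keep]
    mp_safe = np.where(np.isfinite(mp) & (mp > 0), mp, 1.0)
    ratios = np.log10(mp_safe) / np.log10(rp)
    k = len(ratios)
    if k == 0:
        return ratios, float("nan"), float("nan")
    lo, hi = window
    pct_in = 100.0 * np.mean((ratios >= lo) & (ratios <= hi))
    missed = ~np.isfinite(mp) | (mp > alpha)
    return ratios, float(pct_in), float(100.0 * np.mean(missed))


# ---------------------------------------------------------------------------
# LD mining


def reference_frequency_filter(ref: ReferenceLocusSet, maf_min: float = 0.02) -> ReferenceLocusSet:
    """Drop reference loci whose minor (non-modal) call frequency is
    below ``maf_min``."""
    keep = []
    for k in range(ref.n_loci):
        calls = ref.calls[k][ref.calls[k] >= 0]
        if len(calls) == 0:
            keep.append(False)
            continue
        _, counts = np.unique(calls, return_counts=True)
        keep.append(1.0 - counts.max() / counts.sum() >= maf_min)
    m = np.asarray(keep)
    return ReferenceLocusSet(
        ref.locus_id[m], ref.chrom[m], ref.start[m], ref.end[m], ref.samples, ref.calls[m]
    )


def _nearest_gene_distance(
    chrom: str, pos: int, genes: AnnotationIntervals
) -> float:
    same = np.asarray(genes.chrom) == chrom
    if not same.any():
        return float("inf")
    start, end = genes.start[same], genes.end[same]
    inside = (pos >= start) & (pos <= end)
    if inside.any():
        return 0.0
    return float(np.minimum(np.abs(start - pos), np.abs(end - pos)).min())


def _spans_interval(chrom: str, pos: int, intervals: AnnotationIntervals) -> bool:
    same = np.asarray(intervals.chrom) == chrom
    return bool(
        ((pos >= intervals.start[same]) & (pos <= intervals.end[same])).any()
    )


def ld_pair_candidates(
    snp_genotypes: dict[str, np.ndarray],
    cnv: CnvScoreSet,
    manifest: MarkerManifest,
    annotations: AnnotationIntervals,
    population: np.ndarray | None = None,
    config: EvalConfig | None = None,
) -> pd.DataFrame:
    """Candidate SNP-CNV pairs under the catalog filters.

    snp_genotypes maps SNP marker id -> per-sample B-allele dosage
    (0/1/2; NaN missing) aligned to ``cnv.samples``. CNV markers are
    prefiltered by non-diploid frequency; a pair passes when the markers
    are within ``snp_cnv_max_dist``, r^2 exceeds ``r2_min`` in at least
    one population, and the CNV marker is within ``gene_max_dist`` of a
    gene or spans a TF-binding interval. Repeated pairings of one SNP
    are deduplicated keeping the max-r^2 row.
    """
    config = config or EvalConfig()
    genes = annotations.of_kind("gene")
    tf = annotations.of_kind("tf_binding")
    idx = manifest.index_of()
    freqs = cnv.non_diploid_freq
    pops = (
        np.unique(population) if population is not None else np.array(["ALL"], dtype=object)
    )
    rows = []
    cnv_ok = {}
    for snp_id, dosage in snp_genotypes.items():
        if snp_id not in idx:
            continue
        si = idx[snp_id]
        for ci, cnv_id in enumerate(cnv.markers):
            if cnv_id == snp_id:
                continue
            if not (np.isfinite(freqs[ci]) and freqs[ci] > config.freq_min):
                continue
            if manifest.chrom[idx[cnv_id]] != manifest.chrom[si]:
                continue
            cnv_pos = manifest.pos[idx[cnv_id]]
            if abs(int(cnv_pos) - int(manifest.pos[si])) > config.snp_cnv_max_dist:
                continue
            r2_by_pop = {}
            for pop in pops:
                sel = (
                    np.ones(len(cnv.samples), dtype=bool)
                    if population is None
                    else np.asarray(population) == pop
                )
                try:
                    r2_by_pop[f"r2_{pop}"] = genotype_r2(
                        np.asarray(dosage, dtype=float)[sel], cnv.categories[ci][sel]
                    )
                except ValueError:
                    r2_by_pop[f"r2_{pop}"] = float("nan")
            best = np.nanmax(list(r2_by_pop.values()) + [float("-inf")])
            if not best > config.r2_min:
                continue
            if cnv_id not in cnv_ok:
                chrom = manifest.chrom[idx[cnv_id]]
                near_gene = (
                    _nearest_gene_distance(chrom, int(cnv_pos), genes)
                    <= config.gene_max_dist
                )
                cnv_ok[cnv_id] = near_gene or _spans_interval(chrom, int(cnv_pos), tf)
            if not cnv_ok[cnv_id]:
                continue
            rows.append(
                {
                    "snp_id": snp_id,
                    "cnv_id": cnv_id,
                    "chrom": manifest.chrom[si],
                    "snp_pos": int(manifest.pos[si]),
                    "cnv_pos": int(cnv_pos),
                    "best_r2": float(best),
                    **r2_by_pop,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "cnv_id", "chrom", "snp_pos", "cnv_pos", "best_r2"]
        + [f"r2_{p}" for p in pops],
    )
    if len(df):
        df = (
            df.sort_values("best_r2", ascending=False)
            .drop_duplicates(subset="snp_id", keep="first")
            .sort_values(["chrom", "snp_pos"])
            .reset_index(drop=True)
        )
    return df


def cnv_locus_builder(
    cnv: CnvScoreSet,
    manifest: MarkerManifest,
    genes: AnnotationIntervals,
    config: EvalConfig | None = None,
) -> pd.DataFrame:
    """Build multi-marker CNV loci over genes.

    CNV markers (non-diploid frequency above ``freq_min``) near a gene
    (< ``locus_gene_dist``) are chained by position with inter-marker
    gaps <= ``locus_gap``; a chain of >= ``locus_min_size`` markers whose
    pairwise category r^2 all exceed ``locus_r2_min`` is a locus. When
    several loci span one gene, the one with the greatest mean pairwise
    r^2 is kept.
    """
    config = config or EvalConfig()
    genes = genes.of_kind("gene") if "gene" in set(np.asarray(genes.kind)) else genes
    idx = manifest.index_of()
    freqs = cnv.non_diploid_freq
    cand = [
        (str(m), i)
        for i, m in enumerate(cnv.markers)
        if np.isfinite(freqs[i]) and freqs[i] > config.freq_min
    ]
    # prefilter: within locus_gene_dist of some gene
    cand = [
        (m, i)
        for m, i in cand
        if _nearest_gene_distance(
            manifest.chrom[idx[m]], int(manifest.pos[idx[m]]), genes
        )
        <= config.locus_gene_dist
    ]
    cand.sort(key=lambda t: (manifest.chrom[idx[t[0]]], int(manifest.pos[idx[t[0]]])))

    chains: list[list[tuple[str, int]]] = []
    for m, i in cand:
        chrom, pos = manifest.chrom[idx[m]], int(manifest.pos[idx[m]])
        if chains:
            lm, _ = chains[-1][-1]
            if (
                manifest.chrom[idx[lm]] == chrom
                and pos - int(manifest.pos[idx[lm]]) <= config.locus_gap
            ):
                chains[-1].append((m, i))
                continue
        chains.append([(m, i)])

    rows = []
    for chain in chains:
        if len(chain) < config.locus_min_size:
            continue
        r2s = []
        ok = True
        for a in range(len(chain)):
            for b in range(a + 1, len(chain)):
                try:
                    r2 = genotype_r2(
                        cnv.categories[chain[a][1]], cnv.categories[chain[b][1]]
                    )
                except ValueError:
                    r2 = float("nan")
                if not r2 > config.locus_r2_min:
                    ok = False
                r2s.append(r2)
        if not ok:
            continue
        members = [m for m, _ in chain]
        positions = [int(manifest.pos[idx[m]]) for m in members]
        chrom = manifest.chrom[idx[members[0]]]
        spanned = [
            str(name)
            for name, gc, gs, ge in zip(genes.name, genes.chrom, genes.start, genes.end)
            if gc == chrom
            and min(
                0 if positions[0] <= ge and positions[-1] >= gs else float("inf"),
                min(abs(gs - p) for p in positions),
                min(abs(ge - p) for p in positions),
            )
            <= config.locus_gene_dist
        ]
        rows.append(
            {
                "chrom": chrom,
                "start": positions[0],
                "end": positions[-1],
                "n_markers": len(members),
                "markers": ",".join(members),
                "mean_r2": float(np.nanmean(r2s)),
                "genes": ",".join(spanned),
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_markers", "markers", "mean_r2", "genes"]
    )
    if not len(df):
        return df
    # per gene keep the best-mean-r2 locus
    keep = set()
    best_for_gene: dict[str, tuple[float, int]] = {}
    for irow, row in df.iterrows():
        gene_list = [g for g in str(row["genes"]).split(",") if g]
        if not gene_list:
            keep.add(irow)
            continue
        for g in gene_list:
            cur = best_for_gene.get(g)
            if cur is None or row["mean_r2"] > cur[0]:
                best_for_gene[g] = (row["mean_r2"], irow)
    keep |= {irow for _, irow in best_for_gene.values()}
    return df.loc[sorted(keep)].reset_index(drop=True)
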