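"""Synthetic two-channel intensity generator with known ground truth.

Emulates the cluster geometry an Infinium-style assay produces at one
marker: each sample carries two haplotypes, each an allele symbol from
{A, B, deletion, duplicated A/B} drawn under Hardy-Weinberg from the
marker's allele/deletion/amplification frequencies. Channel means are
proportional to the per-allele dose through a channel sensitivity (the
source of the merged-cluster pathology when the two sensitivities
differ), with amplified doses compressed toward a saturation level
(amplifications are hard to resolve on real arrays); per-channel
Gaussian noise is truncated at zero. Every draw is deterministic under
the MarkerSpec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import IntensityMatrix, MarkerManifest

#: fraction of the excess dose above 2 that survives saturation
SATURATION_SLOPE = 0.3


@dataclass
class MarkerSpec:
    """Generative parameters for one marker."""

    maf: float = 0.3  # B-allele frequency among allele-carrying haplotypes
    del_freq: float = 0.0  # deletion haplotype frequency
    amp_freq: float = 0.0  # duplicated-haplotype frequency
    sens_a: float = 1.0
    sens_b: float = 1.0
    noise_sd: float = 0.05  # per channel, intensity units
    saturation_level: float = 2.6  # cap on the per-channel effective dose
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")
        if self.del_freq + self.amp_freq > 1.0:
            raise ValueError("del_freq + amp_freq must be <= 1")


@dataclass
class TruthSet:
    """Per marker x sample generative truth."""

    markers: np.ndarray
    samples: np.ndarray
    genotype: np.ndarray  # haplotype strings, e.g. 'A/B', '-/A', 'AA/B'
    copy_number: np.ndarray  # total allele copies
    snp_genotype: np.ndarray  # observable SNP class: AA/AB/BB/ZERO
    marker_specs: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        n_m, n_s = self.copy_number.shape
        mm, ss = np.meshgrid(np.arange(n_m), np.arange(n_s), indexing="ij")
        return pd.DataFrame(
            {
                "marker_id": self.markers[mm.ravel()],
                "sample_id": self.samples[ss.ravel()],
                "genotype": self.genotype.ravel(),
                "copy_number": self.copy_number.ravel(),
                "snp_genotype": self.snp_genotype.ravel(),
            }
        )


_COPIES = {"-": (0, 0), "A": (1, 0), "B": (0, 1), "AA": (2, 0), "BB": (0, 2)}


def _draw_haplotypes(
    spec: MarkerSpec,
    n: int,
    event_rng: np.random.Generator,
    allele_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """(n, 2) haplotype symbols from {'A','B','-','AA','BB'}.

    The CNV event class of each haplotype (deletion / amplification /
    normal) and the allele identity are drawn from separate generators
    so that a block of markers can share one event draw while alleles
    stay marker-specific.
    """
    allele_rng = allele_rng or event_rng
    u = event_rng.random((n, 2))
    is_del = u < spec.del_freq
    is_amp = (u >= spec.del_freq) & (u < spec.del_freq + spec.amp_freq)
    is_b = allele_rng.random((n, 2)) < spec.maf
    haps = np.where(is_b, "B", "A").astype(object)
    haps[is_amp & is_b] = "BB"
    haps[is_amp & ~is_b] = "AA"
    haps[is_del] = "-"
    return haps


def _effective_dose(dose: np.ndarray, saturation_level: float) -> np.ndarray:
    """Compress per-channel doses above 2 toward the saturation cap."""
    eff = np.where(dose > 2, 2.0 + (dose - 2.0) * SATURATION_SLOPE, dose.astype(float))
    return np.minimum(eff, saturation_level)


def _haps_to_marker(spec: MarkerSpec, haps: np.ndarray, noise_rng: np.random.Generator) -> dict:
    """Turn a haplotype matrix into intensity vectors and truth fields."""
    n = haps.shape[0]
    per_hap = np.array([_COPIES[h] for h in haps.ravel()], dtype=np.int64).reshape(n, 2, 2)
    copies_a = per_hap[:, :, 0].sum(axis=1)
    copies_b = per_hap[:, :, 1].sum(axis=1)
    mean_a = spec.sens_a * _effective_dose(copies_a, spec.saturation_level) / 2.0
    mean_b = spec.sens_b * _effective_dose(copies_b, spec.saturation_level) / 2.0
    raw_a = np.maximum(0.0, mean_a + noise_rng.normal(0.0, spec.noise_sd, n))
    raw_b = np.maximum(0.0, mean_b + noise_rng.normal(0.0, spec.noise_sd, n))
    genotype = np.array(["/".join(sorted(h)) for h in haps], dtype=object)
    cn = copies_a + copies_b
    snp_geno = np.where(
        cn == 0, "ZERO", np.where(copies_b == 0, "AA", np.where(copies_a == 0, "BB", "AB"))
    ).astype(object)
    return {
        "raw_a": raw_a,
        "raw_b": raw_b,
        "genotype": genotype,
        "copy_number": cn,
        "snp_genotype": snp_geno,
        "copies_a": copies_a,
        "copies_b": copies_b,
    }


def simulate_marker(
    spec: MarkerSpec, n_samples: int, rng: np.random.Generator | None = None
) -> dict:
    """Simulate one marker; returns raw channel vectors and truth fields."""
    rng = rng or np.random.default_rng(spec.seed)
    haps = _draw_haplotypes(spec, n_samples, rng)
    return _haps_to_marker(spec, haps, rng)


#: default class mixture of simulate_dataset (fractions over marker classes)
DEFAULT_MIXTURE = {
    "plain": 0.8,
    "deletion": 0.1,
    "amplification": 0.02,
    "monomorphic": 0.04,
    "imbalanced": 0.04,
}

#: per-class base MarkerSpec overrides
CLASS_SPECS = {
    "plain": {},
    "deletion": {"del_freq": 0.3},
    "amplification": {"amp_freq": 0.3},
    "monomorphic": {"maf": 0.0},
    "imbalanced": {"sens_b": 0.6},
}


def simulate_dataset(
    n_markers: int,
    n_samples: int,
    mixture: dict[str, float] | None = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
    noise_sd: float = 0.05,
    populations: dict[str, dict] | None = None,
    pop_sizes: dict[str, int] | None = None,
    spacing: int = 1000,
    chrom: str = "1",
    block_size: int = 1,
    seed: int = 0,
) -> tuple[IntensityMatrix, MarkerManifest, TruthSet, np.ndarray | None]:
    """Simulate a whole marker panel with ground truth.

    mixture assigns marker fractions to the classes in
    :data:`CLASS_SPECS`. ``populations`` maps population label ->
    MarkerSpec field overrides applied to the CNV classes (e.g. a
    different del_freq per population), with per-population sizes from
    ``pop_sizes`` (each defaulting to n_samples split evenly).
    ``block_size`` > 1 makes runs of ``block_size`` consecutive CNV-class
    markers share one event draw (pairwise truth r^2 = 1 inside a
    block). Positions are ``spacing`` apart on one synthetic chromosome.
    Fully deterministic under ``seed``.
    """
    mixture = mixture or DEFAULT_MIXTURE
    classes = list(mixture)
    fracs = np.array([mixture[c] for c in classes], dtype=float)
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * n_markers).astype(int)
    while counts.sum() < n_markers:
        counts[int(np.argmax(fracs * n_markers - counts))] += 1
    marker_classes = np.repeat(classes, counts)[:n_markers]

    if populations:
        pop_sizes = pop_sizes or {p: n_samples // len(populations) for p in populations}
        pop_names = list(populations)
        pop_labels = np.concatenate(
            [np.repeat(p, pop_sizes[p]) for p in pop_names]
        ).astype(object)
        n_total = len(pop_labels)
    else:
        pop_names = [None]
        pop_labels = None
        n_total = n_samples

    samples = np.array([f"S{j:04d}" for j in range(n_total)], dtype=object)
    marker_ids = np.array([f"mk{i:05d}" for i in range(n_markers)], dtype=object)
    manifest = MarkerManifest(
        marker_ids,
        np.repeat(chrom, n_markers),
        np.arange(1, n_markers + 1) * spacing,
        np.repeat("A", n_markers),
        np.repeat("C", n_markers),
    )

    chan_a = np.empty((n_markers, n_total))
    chan_b = np.empty((n_markers, n_total))
    genotype = np.empty((n_markers, n_total), dtype=object)
    cn = np.empty((n_markers, n_total), dtype=np.int64)
    snp_geno = np.empty((n_markers, n_total), dtype=object)
    specs = []

    maf_rng = np.random.default_rng([seed, 1])
    for i, cls in enumerate(marker_classes):
        base = dict(CLASS_SPECS[cls])
        if cls != "monomorphic":
            base.setdefault("maf", float(maf_rng.uniform(*maf_range)))
        spec = MarkerSpec(noise_sd=noise_sd, seed=seed + i, **base)
        specs.append(spec)
        shared_block = block_size > 1 and cls in ("deletion", "amplification")
        for pop_idx, pop in enumerate(pop_names):
            sel = np.ones(n_total, dtype=bool) if pop is None else pop_labels == pop
            spec_i = (
                replace(spec, **populations[pop])
                if (pop is not None and cls in ("deletion", "amplification"))
                else spec
            )
            allele_rng = np.random.default_rng([seed, 2, i, pop_idx])
            noise_rng = np.random.default_rng([seed, 3, i, pop_idx])
            if shared_block:
                # one event draw per (population, block)
                event_rng = np.random.default_rng([seed, 4, i // block_size, pop_idx])
            else:
                event_rng = np.random.default_rng([seed, 5, i, pop_idx])
            haps = _draw_haplotypes(spec_i, int(sel.sum()), event_rng, allele_rng)
            res = _haps_to_marker(spec_i, haps, noise_rng)
            chan_a[i, sel] = res["raw_a"]
            chan_b[i, sel] = res["raw_b"]
            genotype[i, sel] = res["genotype"]
            cn[i, sel] = res["copy_number"]
            snp_geno[i, sel] = res["snp_genotype"]

    intens = IntensityMatrix(marker_ids.copy(), samples, chan_a, chan_b, normalized=False)
    truth = TruthSet(marker_ids.copy(), samples, genotype, cn, snp_geno, specs)
    return intens, manifest, truth, pop_labels
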