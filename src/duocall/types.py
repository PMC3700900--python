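"""Core in-memory containers shared by every stage of the pipeline.

All matrices are oriented markers x samples. Genotypes and copy-number
categories are stored as small integer codes (see :data:`GENOTYPE_CODES`
and :data:`CATEGORY_CODES`) so that whole call sets stay compact; the
string labels are used at the file boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# SNP genotype codes
AA, AB, BB, ZERO, NOCALL = 0, 1, 2, 3, 4
GENOTYPE_CODES = {"AA": AA, "AB": AB, "BB": BB, "ZERO": ZERO, "NOCALL": NOCALL}
GENOTYPE_LABELS = {v: k for k, v in GENOTYPE_CODES.items()}

# Copy-number categories (bins of the continuous score S)
CN0, CN1, CN2, CN3PLUS = 0, 1, 2, 3
CATEGORY_CODES = {"CN0": CN0, "CN1": CN1, "CN2": CN2, "CN3PLUS": CN3PLUS}
CATEGORY_LABELS = {v: k for k, v in CATEGORY_CODES.items()}
MISSING_CATEGORY = -1

#: Fixed boundaries of the score -> category binning (right-closed on the
#: left edge: S=0.5 -> CN1, S=1.5 -> CN2, S=2.5 -> CN3PLUS).
CATEGORY_BOUNDARIES = (0.5, 1.5, 2.5)


def bin_scores(scores: np.ndarray) -> np.ndarray:
    """Map continuous copy-number scores S in [0,3] to integer categories.

    NaN scores map to :data:`MISSING_CATEGORY`.
    """
    s = np.asarray(scores, dtype=float)
    cat = np.digitize(s, CATEGORY_BOUNDARIES, right=False).astype(np.int8)
    cat[np.isnan(s)] = MISSING_CATEGORY
    return cat


@dataclass
class MarkerManifest:
    """Marker coordinates and allele labels, in array design order."""

    marker_id: np.ndarray  # str
    chrom: np.ndarray  # str
    pos: np.ndarray  # int, 1-based
    allele_a: np.ndarray  # str, single nucleotide
    allele_b: np.ndarray  # str, single nucleotide

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        ids, counts = np.unique(self.marker_id, return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate marker_id {dup!r} in manifest")
        if (self.pos < 1).any():
            raise ValueError("manifest positions must be >= 1 (1-based)")
        if (self.allele_a == self.allele_b).any():
            bad = self.marker_id[self.allele_a == self.allele_b][0]
            raise ValueError(f"allele_a == allele_b at marker {bad!r}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def index_of(self) -> dict:
        return {m: i for i, m in enumerate(self.marker_id)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
            }
        )


@dataclass
class IntensityMatrix:
    """Two-channel fluorescence, markers x samples.

    Missing observations are NaN; everything present must be finite and
    >= 0. ``normalized`` records whether per-marker scaling has been
    applied.
    """

    markers: np.ndarray
    samples: np.ndarray
    chan_a: np.ndarray
    chan_b: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=object)
        self.samples = np.asarray(self.samples, dtype=object)
        self.chan_a = np.asarray(self.chan_a, dtype=float)
        self.chan_b = np.asarray(self.chan_b, dtype=float)
        shape = (len(self.markers), len(self.samples))
        if self.chan_a.shape != shape or self.chan_b.shape != shape:
            raise ValueError(
                f"channel shape {self.chan_a.shape}/{self.chan_b.shape} "
                f"does not match {shape}"
            )
        for name, ch in (("A", self.chan_a), ("B", self.chan_b)):
            present = ~np.isnan(ch)
            if np.isinf(ch[present]).any():
                raise ValueError(f"non-finite intensity in channel {name}")
            if (ch[present] < 0).any():
                raise ValueError(f"negative intensity in channel {name}")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.markers), len(self.samples))


@dataclass
class BafProfile:
    """Per-sample BAF and absolute intensity for one marker.

    ``baf`` is the two-channel angle (2/pi)*atan2(b, a) in [0,1] (NaN when
    both channels are zero or missing); ``abs_intensity`` is a+b on the
    normalized sum scale. ``zero_threshold``/``zero_mask`` mark samples
    called as carrying zero copies.
    """

    baf: np.ndarray
    abs_intensity: np.ndarray
    zero_threshold: float | None = None
    zero_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.baf = np.asarray(self.baf, dtype=float)
        self.abs_intensity = np.asarray(self.abs_intensity, dtype=float)
        if self.zero_mask is None:
            self.zero_mask = np.zeros(self.baf.shape, dtype=bool)
        valid = ~np.isnan(self.baf)
        if ((self.baf[valid] < 0) | (self.baf[valid] > 1)).any():
            raise ValueError("BAF outside [0,1]")


@dataclass
class SnpCallSet:
    """Genotype calls plus cluster geometry and quality scores.

    genotypes: int8 codes, markers x samples.
    peaks / limits: per-marker BAF centres and internal boundaries.
    global_score: per-marker quality (mean within-cluster BAF SD; lower
    is better). call_scores: per-call normalized distance to the assigned
    centre (lower is better).
    """

    markers: np.ndarray
    samples: np.ndarray
    genotypes: np.ndarray
    peaks: list = field(default_factory=list)
    limits: list = field(default_factory=list)
    global_score: np.ndarray | None = None
    call_scores: np.ndarray | None = None
    zero_thresholds: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.markers), len(self.samples))

    def genotype_labels(self) -> pd.DataFrame:
        lab = np.vectorize(GENOTYPE_LABELS.get)(self.genotypes)
        return pd.DataFrame(lab, index=self.markers, columns=self.samples)


@dataclass
class GmmFit:
    """A 1- or 2-component univariate Gaussian mixture fit."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    posteriors: np.ndarray  # n_samples x n_components
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_1d(np.asarray(self.variances, dtype=float))
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")
        if self.n_components == 2 and not self.means[0] <= self.means[1]:
            raise ValueError("two-component means must be ascending")

    def bic(self, n: int) -> float:
        k = 2 if self.n_components == 1 else 5
        return k * np.log(n) - 2.0 * self.loglik


@dataclass
class CnvScoreSet:
    """Continuous copy-number scores and their discrete categories.

    scores: S in [0,3] (NaN = not scored), markers x samples.
    categories: int8 bins of S (MISSING_CATEGORY where S is NaN).
    marker_info: per-marker frame with model choices per arm, labels,
    outlier counts and non-diploid frequency.
    """

    markers: np.ndarray
    samples: np.ndarray
    scores: np.ndarray
    categories: np.ndarray
    marker_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        expect = bin_scores(self.scores)
        if not np.array_equal(expect, self.categories):
            raise ValueError("categories are not the binning of scores")

    @property
    def non_diploid_freq(self) -> np.ndarray:
        called = self.categories != MISSING_CATEGORY
        n_called = called.sum(axis=1)
        non2 = ((self.categories != CN2) & called).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, non2 / np.maximum(n_called, 1), np.nan)


@dataclass
class ReferenceLocusSet:
    """External copy-number call set over genomic loci (the gold standard)."""

    locus_id: np.ndarray
    chrom: np.ndarray
    start: np.ndarray  # 1-based inclusive
    end: np.ndarray
    samples: np.ndarray
    calls: np.ndarray  # loci x samples, integer copy number (-1 = missing)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if (self.start > self.end).any():
            raise ValueError("locus start > end")

    @property
    def n_loci(self) -> int:
        return len(self.locus_id)


@dataclass
class AnnotationIntervals:
    """Typed genomic intervals (genes, TF-binding regions), 1-based inclusive."""

    kind: np.ndarray  # 'gene' | 'tf_binding'
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    name: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if (self.start > self.end).any():
            raise ValueError("annotation start > end")

    def of_kind(self, kind: str) -> "AnnotationIntervals":
        m = np.asarray(self.kind) == kind
        return AnnotationIntervals(
            np.asarray(self.kind)[m],
            np.asarray(self.chrom)[m],
            self.start[m],
            self.end[m],
            np.asarray(self.name)[m],
        )
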