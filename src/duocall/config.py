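"""Tunable parameters for every pipeline stage.

Defaults are the package's documented operating point (see
docs/methods.md); everything here can be overridden from a YAML config
file or CLI flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass
class NormConfig:
    """Per-marker intensity normalization.

    ratio_bounds: provisional-BAF bands delimiting candidate AA (<= low)
    and BB (>= high) homozygotes; the open middle band holds candidate
    heterozygotes.
    intensity_floor_frac: samples with a+b below this fraction of the
    marker median a+b enter no candidate set.
    het_target: expected per-channel signal of a heterozygote relative
    to a homozygote (used by the fallback scale).
    """

    ratio_bounds: tuple[float, float] = (0.25, 0.75)
    het_target: float = 0.5
    min_candidates: int = 5
    bandwidth: str | float = "silverman"
    grid_points: int = 512
    intensity_floor_frac: float = 0.05
    mode_frac: float = 0.1  # weighted-curve height a mode needs to set the scale


@dataclass
class SnpConfig:
    """BAF clustering and genotype assignment."""

    n_bins: int = 50  # for n < 500 samples; else ceil(n/10)
    refine_factor: int = 4
    min_separation: float = 0.12  # BAF units between accepted peaks
    zero_gap_factor: float = 10.0
    zero_expected_range: tuple[float, float] = (0.0, 0.5)
    min_samples: int = 5
    min_peak_frac: float = 0.01  # peak density relative to curve maximum
    refine_min_count: int = 2  # samples required in a refined sub-peak bin
    smooth_window: int = 3  # moving-average bins applied before peak search (1 = off)

    def bins_for(self, n_samples: int) -> int:
        if n_samples < 500:
            return self.n_bins
        return int(-(-n_samples // 10))


@dataclass
class EmConfig:
    restarts: int = 9  # deterministic quantile-split starts; >9 adds seeded random
    tol: float = 1e-6  # relative loglik change
    max_iter: int = 200
    var_floor: float = 1e-4


@dataclass
class CnvConfig:
    """Four-arm copy-number genotyping."""

    min_arm_size: int = 10
    bic_margin: float = 10.0
    min_weight: float = 0.03
    sep_factor: float = 2.5  # mean separation in pooled within-SD units
    z_cut: float = 4.0
    seed: int = 0
    em: EmConfig = field(default_factory=EmConfig)


@dataclass
class EvalConfig:
    min_shared_samples: int = 10
    freq_min: float = 0.01  # non-diploid frequency defining a CNV marker
    snp_cnv_max_dist: int = 50_000
    r2_min: float = 0.7
    gene_max_dist: int = 100_000
    locus_gene_dist: int = 15_000
    locus_gap: int = 5_000
    locus_min_size: int = 3
    locus_r2_min: float = 0.7
    ratio_window: tuple[float, float] = (0.9, 1.1)
    alpha: float = 0.05
    ref_maf_min: float = 0.02


@dataclass
class PipelineConfig:
    norm: NormConfig = field(default_factory=NormConfig)
    snp: SnpConfig = field(default_factory=SnpConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for section_name, values in d.items():
            if section_name == "seed":
                cfg.seed = int(values)
                continue
            section = getattr(cfg, section_name)
            if not isinstance(values, dict):
                raise ValueError(f"config section {section_name!r} must be a mapping")
            known = {f.name for f in fields(section)}
            for key, val in values.items():
                if key == "em" and isinstance(val, dict):
                    section.em = replace(section.em, **val)
                    continue
                if key not in known:
                    raise KeyError(f"unknown config key {section_name}.{key}")
                if isinstance(getattr(section, key), tuple):
                    val = tuple(val)
                setattr(section, key, val)
        return cfg
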