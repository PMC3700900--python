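"""Readers and writers for manifests, intensity tables, call sets and loci.

Two intensity dialects are accepted: a plain long-format TSV
(marker_id, sample_id, chan_a, chan_b) and a GenomeStudio-style "Final
Report" (bracketed [Header]/[Data] sections, columns "SNP Name",
"Sample ID", "X Raw"/"X", "Y Raw"/"Y"). Outputs are classic PLINK
PED/MAP for SNP genotypes, TSV matrices for copy-number scores, a
per-marker summary TSV and an optional VCF 4.2 file with symbolic
<DEL>/<DUP> records.

Coordinates are 1-based inclusive everywhere internally and converted
to 0-based half-open only at the BED boundary.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AA,
    AB,
    BB,
    NOCALL,
    ZERO,
    AnnotationIntervals,
    CnvScoreSet,
    IntensityMatrix,
    MarkerManifest,
    ReferenceLocusSet,
    SnpCallSet,
    bin_scores,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["marker_id", "chrom", "pos", "allele_a", "allele_b"]


def read_manifest(path: str | Path) -> MarkerManifest:
    """Read a marker manifest TSV, preserving row order.

    Raises ValueError naming the offending marker/line on duplicate ids
    or non-integer positions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna() | (pos != pos.round())
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"non-integer pos at line {line} of {path}")
    return MarkerManifest(
        df["marker_id"].to_numpy(),
        df["chrom"].to_numpy(),
        pos.astype(np.int64).to_numpy(),
        df["allele_a"].to_numpy(),
        df["allele_b"].to_numpy(),
    )


def write_manifest(manifest: MarkerManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)


def _read_final_report(path: Path) -> pd.DataFrame:
    """Parse the [Data] section of a Final Report into long columns."""
    with open(path) as fh:
        first = fh.readline()
        if not first.strip().startswith("[Header]"):
            raise ValueError(f"{path}: Final Report must start with [Header]")
        # skip to the [Data] marker
        for line in fh:
            if line.strip().startswith("[Data]"):
                break
        else:
            raise ValueError(f"{path}: no [Data] section found")
        df = pd.read_csv(fh, sep="\t", dtype=str)
    rename = {"SNP Name": "marker_id", "Sample ID": "sample_id"}
    for raw, plain, dest in (("X Raw", "X", "chan_a"), ("Y Raw", "Y", "chan_b")):
        if raw in df.columns:
            rename[raw] = dest
        elif plain in df.columns:
            rename[plain] = dest
        else:
            raise ValueError(f"{path}: neither {raw!r} nor {plain!r} column present")
    df = df.rename(columns=rename)
    return df[["marker_id", "sample_id", "chan_a", "chan_b"]]


def read_intensities(
    path: str | Path,
    manifest: MarkerManifest,
    dialect: str = "auto",
) -> IntensityMatrix:
    """Read a two-channel intensity table aligned to manifest order.

    dialect 'auto' sniffs a leading "[Header]" line; pairs absent from
    the file become NaN; markers absent from the manifest are skipped
    with a warning.
    """
    path = Path(path)
    if dialect == "auto":
        with open(path) as fh:
            dialect = (
                "final_report" if fh.readline().strip().startswith("[Header]") else "long_tsv"
            )
    if dialect == "final_report":
        df = _read_final_report(path)
    elif dialect == "long_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = ["marker_id", "sample_id", "chan_a", "chan_b"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValueError(f"{path} lacks columns {missing}")
        df = df[need]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    dup = df.duplicated(subset=["marker_id", "sample_id"])
    if dup.any():
        m, s = df.loc[dup.idxmax(), ["marker_id", "sample_id"]]
        raise ValueError(f"duplicated (marker,sample) pair ({m!r},{s!r}) in {path}")

    idx = manifest.index_of()
    known = df["marker_id"].map(idx.__contains__)
    n_skipped = int((~known).sum())
    if n_skipped:
        warnings.warn(
            f"{n_skipped} rows with markers absent from manifest skipped",
            stacklevel=2,
        )
        df = df[known]

    samples = np.asarray(pd.unique(df["sample_id"]), dtype=object)
    samples = np.asarray(sorted(samples), dtype=object)
    s_idx = {s: j for j, s in enumerate(samples)}
    shape = (manifest.n_markers, len(samples))
    chan_a = np.full(shape, np.nan)
    chan_b = np.full(shape, np.nan)
    rows = df["marker_id"].map(idx).to_numpy(dtype=np.intp)
    cols = df["sample_id"].map(s_idx).to_numpy(dtype=np.intp)
    a = pd.to_numeric(df["chan_a"].replace(".", np.nan)).to_numpy(dtype=float)
    b = pd.to_numeric(df["chan_b"].replace(".", np.nan)).to_numpy(dtype=float)
    for name, v in (("chan_a", a), ("chan_b", b)):
        neg = v < 0
        if neg.any():
            raise ValueError(f"negative intensity in {name} at row {int(neg.argmax())}")
    chan_a[rows, cols] = a
    chan_b[rows, cols] = b
    n_missing = int(np.isnan(chan_a).sum())
    if n_missing:
        logger.info("%d (marker,sample) pairs missing from %s", n_missing, path)
    return IntensityMatrix(manifest.marker_id.copy(), samples, chan_a, chan_b, normalized=False)


def write_intensities_long(intens: IntensityMatrix, path: str | Path) -> None:
    """Write the long-format TSV dialect ("." for missing)."""
    n_m, n_s = intens.shape
    mm, ss = np.meshgrid(np.arange(n_m), np.arange(n_s), indexing="ij")
    df = pd.DataFrame(
        {
            "marker_id": intens.markers[mm.ravel()],
            "sample_id": intens.samples[ss.ravel()],
            "chan_a": intens.chan_a.ravel(),
            "chan_b": intens.chan_b.ravel(),
        }
    )
    df = df[~(df["chan_a"].isna() & df["chan_b"].isna())]
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


# ---------------------------------------------------------------------------
# call-set writers


def _check_universes(snp: SnpCallSet, cnv: CnvScoreSet) -> None:
    if not (
        np.array_equal(snp.markers, cnv.markers) and np.array_equal(snp.samples, cnv.samples)
    ):
        raise ValueError("SNP and CNV call sets have mismatched marker/sample universes")


def recode_ped_genotypes(snp: SnpCallSet, manifest: MarkerManifest) -> list[list[str]]:
    """Recode genotype codes to PED allele pairs ('0 0' = missing/zero-copy)."""
    out = []
    for i in range(len(snp.markers)):
        a, b = manifest.allele_a[i], manifest.allele_b[i]
        row_map = {AA: f"{a} {a}", AB: f"{a} {b}", BB: f"{b} {b}", ZERO: "0 0", NOCALL: "0 0"}
        out.append([row_map[g] for g in snp.genotypes[i]])
    return out


def write_calls(
    snp: SnpCallSet,
    cnv: CnvScoreSet,
    manifest: MarkerManifest,
    out_prefix: str | Path,
    vcf_freq_threshold: float | None = None,
) -> dict[str, Path]:
    """Write PED/MAP, the score matrix, the per-marker summary and
    (optionally) a symbolic-SV VCF; returns the emitted paths."""
    _check_universes(snp, cnv)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    map_path = prefix.with_suffix(".map")
    manifest.to_frame().assign(cm=0)[["chrom", "marker_id", "cm", "pos"]].to_csv(
        map_path, sep="\t", header=False, index=False
    )
    paths["map"] = map_path

    ped_path = prefix.with_suffix(".ped")
    geno = recode_ped_genotypes(snp, manifest)
    with open(ped_path, "w") as fh:
        for j, sample in enumerate(snp.samples):
            lead = [str(sample), str(sample), "0", "0", "0", "-9"]
            fh.write("\t".join(lead + [geno[i][j] for i in range(len(snp.markers))]) + "\n")
    paths["ped"] = ped_path

    score_path = prefix.parent / (prefix.name + ".scores.tsv")
    pd.DataFrame(cnv.scores, index=cnv.markers, columns=cnv.samples).to_csv(
        score_path, sep="\t", index_label="marker_id", na_rep=".", float_format="%.6f"
    )
    paths["scores"] = score_path

    summary_path = prefix.parent / (prefix.name + ".markers.tsv")
    summary = pd.DataFrame(
        {
            "marker_id": snp.markers,
            "peaks": [",".join(f"{p:.4f}" for p in pk) for pk in snp.peaks],
            "global_score": snp.global_score,
            "non_diploid_freq": cnv.non_diploid_freq,
        }
    )
    if cnv.marker_info is not None:
        summary = pd.concat([summary, cnv.marker_info.reset_index(drop=True)], axis=1)
    summary.to_csv(summary_path, sep="\t", index=False, na_rep=".", float_format="%.6f")
    paths["summary"] = summary_path

    if vcf_freq_threshold is not None:
        vcf_path = prefix.with_suffix(".vcf")
        write_sv_vcf(cnv, manifest, vcf_path, freq_threshold=vcf_freq_threshold)
        paths["vcf"] = vcf_path
    return paths


def write_sv_vcf(
    cnv: CnvScoreSet,
    manifest: MarkerManifest,
    path: str | Path,
    freq_threshold: float = 0.01,
) -> int:
    """Emit VCF 4.2 symbolic <DEL>/<DUP> records for markers whose
    non-diploid frequency exceeds ``freq_threshold``; returns the record
    count. Per-sample CN carries the rounded copy-number category."""
    freqs = cnv.non_diploid_freq
    cats = cnv.categories
    n_rec = 0
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=NDF,Number=1,Type=Float,Description="Non-diploid frequency">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">\n')
        for chrom in pd.unique(manifest.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, cnv.samples))
            + "\n"
        )
        for i in range(len(cnv.markers)):
            if not np.isfinite(freqs[i]) or freqs[i] <= freq_threshold:
                continue
            called = cats[i][cats[i] >= 0]
            n_del = int((called < 2).sum())
            n_dup = int((called > 2).sum())
            alt, svtype = ("<DEL>", "DEL") if n_del >= n_dup else ("<DUP>", "DUP")
            info = f"SVTYPE={svtype};END={int(manifest.pos[i])};NDF={freqs[i]:.4f}"
            cn_fields = ["." if c < 0 else str(int(c)) for c in cats[i]]
            fh.write(
                f"{manifest.chrom[i]}\t{int(manifest.pos[i])}\t{manifest.marker_id[i]}"
                f"\tN\t{alt}\t.\tPASS\t{info}\tCN\t" + "\t".join(cn_fields) + "\n"
            )
            n_rec += 1
    return n_rec


def read_score_matrix(path: str | Path) -> CnvScoreSet:
    df = pd.read_csv(path, sep="\t", index_col="marker_id", na_values=".")
    scores = df.to_numpy(dtype=float)
    return CnvScoreSet(
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        scores,
        bin_scores(scores),
    )


# ---------------------------------------------------------------------------
# reference loci and annotations


def read_reference_loci(bed_path: str | Path, calls_path: str | Path) -> ReferenceLocusSet:
    """Read evaluation loci (BED, 0-based half-open) plus a per-sample
    copy-number call TSV (locus_id x samples, "." or -1 = missing)."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, names=["chrom", "start0", "end", "locus_id"], dtype=str
    )
    calls = pd.read_csv(calls_path, sep="\t", index_col="locus_id", na_values=".")
    calls = calls.reindex(bed["locus_id"])
    arr = calls.to_numpy(dtype=float)
    arr = np.where(np.isnan(arr), -1, arr).astype(np.int64)
    return ReferenceLocusSet(
        bed["locus_id"].to_numpy(dtype=object),
        bed["chrom"].to_numpy(dtype=object),
        bed["start0"].astype(np.int64).to_numpy() + 1,  # to 1-based inclusive
        bed["end"].astype(np.int64).to_numpy(),
        calls.columns.to_numpy(dtype=object),
        arr,
    )


def write_reference_loci(
    ref: ReferenceLocusSet, bed_path: str | Path, calls_path: str | Path
) -> None:
    pd.DataFrame(
        {
            "chrom": ref.chrom,
            "start0": ref.start - 1,
            "end": ref.end,
            "locus_id": ref.locus_id,
        }
    ).to_csv(bed_path, sep="\t", header=False, index=False)
    calls = pd.DataFrame(ref.calls, index=ref.locus_id, columns=ref.samples)
    calls = calls.replace(-1, np.nan)
    calls.to_csv(calls_path, sep="\t", index_label="locus_id", na_rep=".", float_format="%.0f")


def read_annotations(path: str | Path) -> AnnotationIntervals:
    """Read typed intervals from a BED-style TSV: chrom, start0, end,
    name, kind ('gene' or 'tf_binding')."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start0", "end", "name", "kind"], dtype=str
    )
    return AnnotationIntervals(
        df["kind"].to_numpy(dtype=object),
        df["chrom"].to_numpy(dtype=object),
        df["start0"].astype(np.int64).to_numpy() + 1,
        df["end"].astype(np.int64).to_numpy(),
        df["name"].to_numpy(dtype=object),
    )
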