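import numpy as np
import pandas as pd
import pytest

from duocall.types import MarkerManifest


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_manifest():
    return MarkerManifest(
        marker_id=["rs1", "rs2", "rs3"],
        chrom=["1", "1", "2"],
        pos=[1000, 2000, 500],
        allele_a=["A", "G", "C"],
        allele_b=["C", "T", "T"],
    )


@pytest.fixture
def manifest_file(tmp_path, small_manifest):
    path = tmp_path / "manifest.tsv"
    small_manifest.to_frame().to_csv(path, sep="\t", index=False)
    return path


def make_long_tsv(tmp_path, rows, name="intens.tsv"):
    path = tmp_path / name
    df = pd.DataFrame(rows, columns=["marker_id", "sample_id", "chan_a", "chan_b"])
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def long_tsv_factory(tmp_path):
    return lambda rows, name="intens.tsv": make_long_tsv(tmp_path, rows, name)
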