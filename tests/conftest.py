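import numpy as np
import pandas as pd
import pytest

from exonsplice.model_io import (
    IntensityMatrix,
    ProbeAnnotation,
    SampleDesign,
)
from exonsplice.synthetic import SimulationConfig, simulate_experiment


def make_annotation(rows):
    """Helper: rows of (probe, probeset, transcript, gene, exon, xhyb, kind)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "probeset_id",
            "transcript_id",
            "gene_id",
            "exon_index",
            "cross_hyb_flag",
            "probe_kind",
        ],
    )
    df["exon_index"] = df["exon_index"].astype("Int64")
    for col in ("probeset_id", "transcript_id", "gene_id"):
        df[col] = df[col].where(df[col].notna(), np.nan)
    return ProbeAnnotation(df)


@pytest.fixture
def toy_annotation():
    """Two transcripts, three probesets, plus two background probes."""
    return make_annotation(
        [
            ("p1", "ps1", "t1", "g1", 1, False, "genomic"),
            ("p2", "ps1", "t1", "g1", 1, False, "genomic"),
            ("p3", "ps2", "t1", "g1", 2, True, "genomic"),
            ("p4", "ps3", "t2", "g2", 1, False, "genomic"),
            ("p5", "ps3", "t2", "g2", 1, False, "genomic"),
            ("b1", None, None, None, None, False, "background"),
            ("b2", None, None, None, None, False, "background"),
        ]
    )


@pytest.fixture
def toy_design():
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "condition": ["A", "A", "B", "B"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )


def make_matrix(values, probes, samples, corrected=False):
    return IntensityMatrix(
        pd.DataFrame(values, index=probes, columns=samples, dtype=float),
        is_background_corrected=corrected,
    )


@pytest.fixture(scope="session")
def sim_default():
    """A moderate simulated experiment shared by read-only tests."""
    cfg = SimulationConfig(
        n_transcripts=80,
        frac_de_transcripts=0.1,
        frac_as_transcripts=0.15,
        frac_cross_hyb_probes=0.05,
        frac_absent_transcripts=0.1,
        seed=123,
    )
    return cfg, simulate_experiment(cfg)
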