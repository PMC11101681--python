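import numpy as np
import pandas as pd
import pytest

from replibio import io, pipeline, synthetic


def build_matrix(counts, intensity=None, flags=None, unique_peptides=None, log_transformed=False):
    """Construct a small QuantMatrix from {sample: [values]} dicts."""
    counts = pd.DataFrame(counts, dtype=float)
    n = len(counts)
    counts.index = pd.Index([f"P{i + 1}" for i in range(n)], name="group_id")
    if intensity is None:
        intensity = counts * 1000.0
    else:
        intensity = pd.DataFrame(intensity, dtype=float)
        intensity.index = counts.index
    flags = flags or {}
    proteins = pd.DataFrame(
        {
            "accessions": counts.index,
            "gene_symbol": [f"G{i + 1}" for i in range(n)],
            "is_reverse": flags.get("is_reverse", [False] * n),
            "is_contaminant": flags.get("is_contaminant", [False] * n),
            "only_by_site": flags.get("only_by_site", [False] * n),
            "unique_peptides": unique_peptides if unique_peptides is not None else [5] * n,
        },
        index=counts.index,
    )
    return io.QuantMatrix(proteins, counts, intensity, log_transformed)


def make_design(rows_spec):
    """rows_spec: list of (sample_id, source_token, condition, bio_rep, tech_rep)."""
    rows = []
    for sid, token, condition, bio, tech in rows_spec:
        if token in io.CONTROL_SOURCES:
            source, bait = token, None
        else:
            source, bait = "bait", token
        rows.append(io.SampleDesign(sid, source, bait, condition, bio, tech))
    return rows


def biorep_design(label, condition, n=3):
    """One condition-group of n biological replicates (already tech-averaged)."""
    return make_design([(f"{label}.{condition}.b{i}", label, condition, i, 1) for i in range(1, n + 1)])


@pytest.fixture(scope="session")
def study():
    return synthetic.simulate(synthetic.SimulationConfig())


@pytest.fixture(scope="session")
def biorep_study(study):
    q_nt, _ = io.filter_rows(study.q_nt)
    q_hu, _ = io.filter_rows(study.q_hu)
    q_nt, d_nt = io.average_tech_reps(q_nt, study.design)
    q_hu, d_hu = io.average_tech_reps(q_hu, study.design)
    return q_nt, q_hu, d_nt + d_hu


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    manifest = pipeline.run_all(pipeline.PipelineConfig(), outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def null_pipeline_run(tmp_path_factory):
    """Same study conditions but no treatment effect (hu_fold = 1)."""
    outdir = tmp_path_factory.mktemp("null_run")
    cfg = pipeline.PipelineConfig()
    cfg.simulation.hu_fold = 1.0
    manifest = pipeline.run_all(cfg, outdir)
    return outdir, manifest
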