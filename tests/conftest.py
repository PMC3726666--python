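import numpy as np
import pandas as pd
import pytest

from sagescope import (
    SimulationManifest,
    count_library,
    extract_virtual_tags,
    simulate_abundances,
    simulate_library,
    simulate_transcriptome,
)
from sagescope.tagdb import TranscriptRecord

SEED = 1307


@pytest.fixture(scope="session")
def toy_db():
    """Five-entry database (tag length 10) with one gene-ambiguous tag."""
    transcripts = [
        TranscriptRecord("t1", "geneA", "TTTTTTCATGAAAAAA"),
        TranscriptRecord("t2", "geneB", "GGGGGGCATGCCCCCC"),
        TranscriptRecord("t3", "geneC", "AAAACATGGGGGGGTT"),
        TranscriptRecord("t4", "geneD", "CCCCCATGTTTTTTAA"),
        # geneE and geneF share a tag -> ambiguous entry
        TranscriptRecord("t5", "geneE", "TACGTACGCATGACGTACGT"),
        TranscriptRecord("t6", "geneF", "GGCCGGCCCATGACGTACGT"),
    ]
    return extract_virtual_tags(transcripts, tag_length=10)


@pytest.fixture(scope="session")
def small_sim():
    """200-gene, 3e5-tag, error-free paired simulation for fast checks."""
    manifest = SimulationManifest(
        seed=SEED,
        n_genes=200,
        n_tags_per_library=300_000,
        per_base_error_rate=0.0,
        n_de_per_class={"4.0": 10, "0.25": 10},
    )
    transcriptome = simulate_transcriptome(manifest)
    db = extract_virtual_tags(transcriptome, manifest.tag_length)
    abundances = simulate_abundances(manifest)
    profiles = {}
    for condition in ("control", "treated"):
        obs, _ = simulate_library(transcriptome, manifest, condition, abundances)
        profiles[condition], _ = count_library(obs, db, 2, condition)
    return manifest, transcriptome, db, abundances, profiles


@pytest.fixture(scope="session")
def frozen_ct_fixture():
    """Frozen 4-gene x 6-sample Ct table (3 controls, 3 treated, duplicates).

    Values are arbitrary but fixed; oracles recompute expectations with
    plain spreadsheet-style arithmetic.
    """
    rows = []
    ct_values = {
        # gene: {sample: (rep1, rep2)}
        "tgt1": {"C1": (24.1, 24.3), "C2": (24.8, 24.6), "C3": (24.2, 24.4),
                 "S1": (22.0, 22.2), "S2": (23.1, 22.9), "S3": (21.5, 21.7)},
        "tgt2": {"C1": (28.0, 28.2), "C2": (27.6, 27.8), "C3": (28.3, 28.1),
                 "S1": (28.9, 29.1), "S2": (28.4, 28.6), "S3": (29.0, 28.8)},
        "ref1": {"C1": (18.0, 18.2), "C2": (18.4, 18.2), "C3": (18.1, 18.3),
                 "S1": (18.2, 18.0), "S2": (18.5, 18.3), "S3": (18.0, 18.2)},
        "ref2": {"C1": (20.5, 20.7), "C2": (20.9, 20.7), "C3": (20.6, 20.8),
                 "S1": (20.8, 20.6), "S2": (21.0, 20.8), "S3": (20.5, 20.7)},
    }
    for gene, samples in ct_values.items():
        for sample, reps in samples.items():
            group = "control" if sample.startswith("C") else "treated"
            for i, ct in enumerate(reps, start=1):
                rows.append(
                    {"gene": gene, "sample": sample, "group": group,
                     "replicate": i, "ct": ct}
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
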