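import numpy as np
import pytest

from bovlnc.models import AnnotationSet, TranscriptModel
from bovlnc.pipeline import run_identify
from bovlnc.synthetic_data import (
    SimConfig,
    generate_annotation,
    generate_counts,
    generate_sequences,
)

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """One full synthetic dataset shared across the suite."""
    reference, assembled, truth = generate_annotation(sim_config)
    seqs = generate_sequences(sim_config, truth)
    counts, design = generate_counts(sim_config, truth)
    return {
        "cfg": sim_config,
        "reference": reference,
        "assembled": assembled,
        "truth": truth,
        "seqs": seqs,
        "counts": counts,
        "design": design,
    }


def training_set(sim_data):
    tx = sim_data["truth"].transcripts
    ref = tx[tx["kind"].str.startswith("reference")]
    seqs = sim_data["seqs"]
    return [seqs[i] for i in ref.index], list(ref["coding_label"])


@pytest.fixture(scope="session")
def identify_result(sim_data):
    train_seqs, train_labels = training_set(sim_data)
    return run_identify(
        sim_data["assembled"],
        sim_data["reference"],
        sim_data["seqs"],
        train_seqs,
        train_labels,
    )


def random_annotation(rng: np.random.Generator, n_genes: int = 12, chroms=("chr1", "chr2")):
    """A random multi-exon reference annotation for oracle comparisons."""
    ann = AnnotationSet()
    for g in range(n_genes):
        chrom = chroms[g % len(chroms)]
        start = int(rng.integers(0, 50_000))
        n_ex = int(rng.integers(1, 6))
        exons = []
        pos = start
        for i in range(n_ex):
            if i:
                pos += int(rng.integers(50, 2000))
            ln = int(rng.integers(50, 500))
            exons.append((pos, pos + ln))
            pos += ln
        strand = "+" if rng.random() < 0.5 else "-"
        ann.add(TranscriptModel(f"R{g:03d}.T1", chrom, strand, tuple(exons)), f"R{g:03d}")
    return ann


def random_transcript(rng: np.random.Generator, tid: str, chroms=("chr1", "chr2")):
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    start = int(rng.integers(0, 60_000))
    n_ex = int(rng.integers(1, 5))
    exons = []
    pos = start
    for i in range(n_ex):
        if i:
            pos += int(rng.integers(30, 1500))
        ln = int(rng.integers(40, 600))
        exons.append((pos, pos + ln))
        pos += ln
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel(tid, chrom, strand, tuple(exons))
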