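import pytest

from spliceflank.events import TranscriptModel, build_events
from spliceflank.simulate import (SimulationConfig, make_genome_annotation,
                                  simulate_quant, write_fasta, write_gtf)


@pytest.fixture
def ri_transcripts():
    """Two-isoform gene realizing one retained-intron event (intron
    [100,200); isoform B retains it)."""
    return [
        TranscriptModel("txA", "g1", "chr1", "+", ((0, 100), (200, 300))),
        TranscriptModel("txB", "g1", "chr1", "+", ((0, 300),)),
    ]


@pytest.fixture
def a5_transcripts():
    """Alternative-donor gene: donors at 500 and 560, shared acceptor 800."""
    return [
        TranscriptModel("txShort", "g2", "chr1", "+", ((400, 500), (800, 900))),
        TranscriptModel("txLong", "g2", "chr1", "+", ((400, 560), (800, 900))),
    ]


@pytest.fixture
def ri_event(ri_transcripts):
    (event,) = build_events(ri_transcripts)
    return event


@pytest.fixture
def a5_event(a5_transcripts):
    (event,) = build_events(a5_transcripts)
    return event


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SimulationConfig(
        seed=13, n_genes=50,
        events_per_type={"RI": 6, "A3": 5, "A5": 4, "SE": 3},
    )
    genome, transcripts, truth = make_genome_annotation(cfg)
    quant, cond = simulate_quant(transcripts, truth, cfg)
    return {
        "cfg": cfg, "genome": genome, "transcripts": transcripts,
        "truth": truth, "quant": quant, "conditions": cond,
        "events": build_events(transcripts),
    }


@pytest.fixture(scope="session")
def small_sim_files(small_sim, tmp_path_factory):
    """The small synthetic dataset written to disk (FASTA/GTF/TSVs)."""
    d = tmp_path_factory.mktemp("sim")
    write_fasta(small_sim["genome"], str(d / "genome.fa"))
    write_gtf(small_sim["transcripts"], str(d / "annotation.gtf"))
    small_sim["quant"].to_csv(d / "tpm.tsv", sep="\t")
    small_sim["conditions"].to_csv(d / "conditions.tsv", sep="\t", index=False)
    return d
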