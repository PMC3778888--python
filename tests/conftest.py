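"""Shared fixtures: one toy genome and a few simulated libraries per session."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from crac_atlas import align, readprep, syndata
from crac_atlas.align import MappedRead
from crac_atlas.annotation import Annotation


@pytest.fixture(scope="session")
def toy():
    """Deterministic toy genome + annotation (2 x 50 kb, ~60 transcripts)."""
    genome, annotation = syndata.generate_genome(syndata.GenomeSpec(seed=1))
    return genome, annotation


@pytest.fixture(scope="session")
def genome(toy):
    return toy[0]


@pytest.fixture(scope="session")
def annotation(toy) -> Annotation:
    return toy[1]


@pytest.fixture(scope="session")
def contig_lengths(genome):
    return {n: len(s) for n, s in genome.items()}


@pytest.fixture(scope="session")
def genome_index(genome):
    return align.GenomeIndex(genome)


@dataclass
class Library:
    """A simulated library carried through preprocessing, mapping and dedup."""

    protein: str
    reads: list
    truth: object
    processed: list
    mapped: list
    unmapped: dict
    dedup: list


def make_library(genome, annotation, index, protein, n_fragments, seed,
                 pcr_dup_mean=1.0, **kw) -> Library:
    model = syndata.protein_preset(protein)
    reads, truth = syndata.simulate_library(
        genome, annotation, model, n_fragments,
        pcr_dup_mean=pcr_dup_mean, seed=seed, **kw
    )
    streams, _ = readprep.preprocess(
        reads, syndata.ADAPTOR_3P, {syndata.BARCODES[0]: protein}
    )
    mapped, unmapped = align.align_reads(streams[protein], index)
    dedup, _ = readprep.collapse_duplicates(mapped)
    return Library(protein, reads, truth, streams[protein], mapped,
                   dict(unmapped), dedup)


@pytest.fixture(scope="session")
def pab1_lib(genome, annotation, genome_index):
    return make_library(genome, annotation, genome_index, "pab1", 4000, seed=5)


@pytest.fixture(scope="session")
def hrp1_lib(genome, annotation, genome_index):
    return make_library(genome, annotation, genome_index, "hrp1", 2500, seed=6)


@pytest.fixture(scope="session")
def mtr4_lib(genome, annotation, genome_index):
    return make_library(genome, annotation, genome_index, "mtr4", 3000, seed=7)


def mk_read(start, end, strand="+", contig="chrI", rid="r", tail="", dels=(),
            tag="ACG", sample="s", adaptor=True, seq=None):
    """Hand-built MappedRead for arithmetic-level tests."""
    n = (end - start) - len(dels) + len(tail)
    return MappedRead(
        id=rid, contig=contig, strand=strand, start=start, end=end,
        deletions=tuple(dels), clipped_tail=tail, random_tag=tag, sample=sample,
        adaptor_found=adaptor, seq=seq if seq is not None else "N" * n,
    )
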