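"""End-to-end orchestration from a single YAML/JSON configuration.

Stages run in dependency order (simulate -> preprocess -> align -> count ->
profiles / tails -> pA sites / motifs), writing TSV/SAM/BED outputs plus a
manifest recording seeds, parameters and input checksums.  A single global
seed fans out to per-stage seeds through a hash so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from ._util import stage_seed
from .annotation import Annotation
from . import syndata, readprep, align, annot_hits, profiles, tails, pasites, motifs

_KNOWN_KEYS = {
    "outdir", "seed", "genome_fasta", "annotation_gtf", "samples",
    "n_fragments", "pcr_dup_mean", "read_length", "quality_min",
    "pa_sample", "motif_sample", "motif_k",
}


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    genome_fasta: str | None = None      # None -> simulate a toy genome
    annotation_gtf: str | None = None
    samples: list = field(default_factory=lambda: [
        {"name": "pab1", "protein": "pab1"},
        {"name": "hrp1", "protein": "hrp1"},
        {"name": "mtr4", "protein": "mtr4"},
    ])
    n_fragments: int = 1500
    pcr_dup_mean: float = 2.0
    read_length: int = 54
    quality_min: int = 20
    pa_sample: str | None = "pab1"
    motif_sample: str | None = "hrp1"
    motif_k: int = 6

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.outdir:
            raise ValueError("outdir required")
        for key in ("genome_fasta", "annotation_gtf"):
            path = getattr(self, key)
            if path is not None and not os.path.exists(path):
                raise ValueError(f"{key} path does not exist: {path}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to outdir)."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
        "inputs": {},
    }

    def stage(name):
        manifest["stages"][name] = {"seed": stage_seed(config.seed, name)}
        return manifest["stages"][name]

    # --- genome -----------------------------------------------------------
    st = stage("genome")
    if config.genome_fasta:
        genome = syndata.read_fasta(config.genome_fasta)
        annotation = Annotation.read_gtf(config.annotation_gtf)
        manifest["inputs"]["genome_fasta"] = _sha256(config.genome_fasta)
        manifest["inputs"]["annotation_gtf"] = _sha256(config.annotation_gtf)
    else:
        spec = syndata.GenomeSpec(seed=st["seed"])
        genome, annotation = syndata.generate_genome(spec)
        fa = os.path.join(config.outdir, "genome.fa")
        gtf = os.path.join(config.outdir, "annotation.gtf")
        bed = os.path.join(config.outdir, "lncRNA_classes.bed")
        syndata.write_fasta(genome, fa)
        annotation.write_gtf(gtf)
        annotation.write_class_bed(bed)
        manifest["inputs"]["genome_fasta"] = _sha256(fa)
    contig_lengths = {n: len(s) for n, s in genome.items()}

    # --- simulate + preprocess + align per sample ------------------------
    index = align.GenomeIndex(genome)
    per_sample: dict[str, list] = {}
    truth_frames = []
    barcode_table = {}
    for i, s in enumerate(config.samples):
        barcode_table[syndata.BARCODES[i % len(syndata.BARCODES)]] = s["name"]
    for i, s in enumerate(config.samples):
        name, protein = s["name"], s.get("protein", s["name"])
        st = stage(f"simulate:{name}")
        model = syndata.protein_preset(protein)
        reads, truth = syndata.simulate_library(
            genome, annotation, model,
            n_fragments=int(s.get("n_fragments", config.n_fragments)),
            pcr_dup_mean=config.pcr_dup_mean, seed=st["seed"], sample=name,
            barcode=syndata.BARCODES[i % len(syndata.BARCODES)],
            read_length=config.read_length,
        )
        fq = os.path.join(config.outdir, f"{name}.fastq")
        syndata.write_fastq(reads, fq)
        truth_frames.append(truth)

        streams, report = readprep.preprocess(
            reads, syndata.ADAPTOR_3P, barcode_table, quality_min=config.quality_min
        )
        st["preprocess"] = report
        mapped, unmapped = align.align_reads(streams[name], index)
        dedup, dreport = readprep.collapse_duplicates(mapped)
        st["align"] = {"mapped": len(mapped), **dict(unmapped)}
        st["dedup"] = dreport
        align.write_sam(dedup, genome, os.path.join(config.outdir, f"{name}.sam"))
        per_sample[name] = dedup

    pd.concat(truth_frames).to_csv(
        os.path.join(config.outdir, "truth.tsv"), sep="\t", index=False
    )

    # --- hit tables + breakdown + metagene -------------------------------
    for name, dedup in per_sample.items():
        ht = annot_hits.normalize_hpm(
            annot_hits.count_hits(dedup, annotation, dataset=name), "polII_all"
        )
        ht.table.to_csv(os.path.join(config.outdir, f"{name}.hits.tsv"), sep="\t")
        bd = annot_hits.class_breakdown(dedup, annotation)
        bd.to_csv(os.path.join(config.outdir, f"{name}.classes.tsv"), sep="\t",
                  header=["proportion"])
        prof = profiles.metagene(dedup, annotation, contig_lengths, dataset=name)
        pd.DataFrame({"bin": range(120), "density": prof.values}).to_csv(
            os.path.join(config.outdir, f"{name}.metagene.tsv"), sep="\t", index=False
        )
        manifest["stages"][f"analyse:{name}"] = {
            "hits": int(ht.table["raw"].sum()),
            "metagene_transcripts": prof.n_transcripts,
        }

    # --- tails + pA sites -------------------------------------------------
    if config.pa_sample and config.pa_sample in per_sample:
        dedup = per_sample[config.pa_sample]
        calls = tails.call_atails(dedup)
        hist = tails.tail_length_distribution(calls)
        hist.to_csv(os.path.join(config.outdir, f"{config.pa_sample}.tails.tsv"),
                    sep="\t", header=["count"])
        sites, preport = pasites.call_pa_sites(calls, dedup, annotation, genome)
        pasites.write_pa_bed(sites, annotation,
                             os.path.join(config.outdir, f"{config.pa_sample}.pa.bed"))
        manifest["stages"]["pa_sites"] = {
            "n_sites": len(sites),
            "n_major": sum(s.is_major for s in sites),
            **preport,
        }

    # --- motifs -----------------------------------------------------------
    if config.motif_sample and config.motif_sample in per_sample:
        st = stage("motifs")
        df = motifs.kmer_zscores(
            per_sample[config.motif_sample], annotation, genome,
            k=config.motif_k, seed=st["seed"],
        )
        df.to_csv(os.path.join(config.outdir, f"{config.motif_sample}.kmers.tsv"),
                  sep="\t", index=False)
        st["top_kmer"] = str(df.iloc[0]["kmer"])

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
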