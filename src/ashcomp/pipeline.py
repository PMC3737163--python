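"""End-to-end pipeline: simulate -> assemble -> scaffold -> compare ->
synteny/features -> score against the planted truth.

One global seed fans out to per-stage random streams, so every stage is
independently re-runnable and a rerun of the whole pipeline is bit-identical.
Each run writes a manifest with content hashes, JSON-lines stage logs, and a
scorecard summarising simulator-vs-pipeline agreement.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import assembler, comparator, features, scaffolder, synteny
from .io_formats import (AnnotatedGenome, SeqRecord, write_annotations, write_bed,
                         write_fasta, write_fastq, write_ortholog_table, write_variants)
from .simulate import (SimulationConfig, TruthSet, derive_species, derive_strain,
                       generate_ancestor, simulate_reads, write_ortholog_rows)

CONFIG_VERSION = "1"


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    overlap_floor: int = 20
    min_branch_support: int = 2
    min_branch_quality: int = 2
    min_links: int = 3
    window_fine: int = 1_000
    window_coarse: int = 100_000
    introgression_threshold: float = 0.98
    introgression_min_windows: int = 3
    max_skip: int = 2
    max_intervening: int = 1
    config_version: str = CONFIG_VERSION

    def validate(self) -> None:
        self.simulation.validate()
        if self.overlap_floor < 5:
            raise ValueError("overlap_floor too small")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_raw) - sim_fields
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        if "tandem_events" in sim_raw:
            sim_raw["tandem_events"] = [tuple(t) for t in sim_raw["tandem_events"]]
        for tup_field in ("seq_error_rate_by_quality_class", "quality_class_probs",
                          "quality_class_phred"):
            if tup_field in sim_raw:
                sim_raw[tup_field] = tuple(sim_raw[tup_field])
        pipe_fields = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(raw) - pipe_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=SimulationConfig(**sim_raw), **raw)

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["simulation"]["tandem_events"] = [list(t) for t in
                                               data["simulation"]["tandem_events"]]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class Scorecard:
    snp_precision: float = 0.0
    snp_recall: float = 0.0
    indel_precision: float = 0.0
    indel_recall: float = 0.0
    introgression_boundary_error: Optional[int] = None
    breakpoints_found: int = 0
    breakpoints_planted: int = 0
    arrays_matched: float = 0.0
    assembly_contig_count: int = 0
    assembly_identity: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class _StageLogger:
    def __init__(self, outdir: str):
        self.path = os.path.join(outdir, "stages.jsonl")
        self._fh = open(self.path, "w")

    def log(self, stage: str, **info) -> None:
        rec = {"stage": stage, **info}
        self._fh.write(json.dumps(rec) + "\n")
        self._fh.flush()
        print(f"[{stage}] " + " ".join(f"{k}={v}" for k, v in info.items()),
              file=sys.stderr)

    def close(self):
        self._fh.close()


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


_TYPE_MAP = {"SNP": "SNP", "ins": "insertion", "del": "deletion"}


def _truth_keys(truth: TruthSet):
    snps, indels = set(), set()
    for chrom, pos, ref, alt, vtype in truth.variants:
        if vtype == "SNP":
            snps.add((chrom, pos, ref, alt))
        else:
            seq = ref if vtype == "del" else alt
            indels.add((chrom, pos, _TYPE_MAP[vtype], seq))
    return snps, indels


def _called_keys(variants):
    snps, indels = set(), set()
    for v in variants:
        if v.type == "SNP":
            snps.add((v.chromosome, v.position, v.ref_allele, v.alt_allele))
        else:
            seq = v.ref_allele if v.type == "deletion" else v.alt_allele
            indels.add((v.chromosome, v.position, v.type, seq))
    return snps, indels


def _pr(called: set, truth: set) -> tuple[float, float]:
    if not called and not truth:
        return 1.0, 1.0
    tp = len(called & truth)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def score_variants(variants, truth: TruthSet) -> tuple[float, float, float, float]:
    called_snps, called_indels = _called_keys(variants)
    true_snps, true_indels = _truth_keys(truth)
    sp, sr = _pr(called_snps, true_snps)
    ip, ir = _pr(called_indels, true_indels)
    return sp, sr, ip, ir


def _exact_fraction(contigs, genome_seqs: dict[str, str]) -> float:
    """Fraction of contig bases (contigs >= 2 read lengths) that lie in
    contigs occurring exactly in the source genome (either strand)."""
    from .io_formats import revcomp
    haystack = "$".join(genome_seqs[c] for c in sorted(genome_seqs))
    total = good = 0
    for c in contigs:
        total += len(c.sequence)
        if c.sequence in haystack or revcomp(c.sequence) in haystack:
            good += len(c.sequence)
    return good / total if total else 0.0


def run_all(config: PipelineConfig, outdir: str) -> Scorecard:
    """Run the full pipeline into a run directory; returns the scorecard."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    log = _StageLogger(outdir)
    t0 = time.time()
    sim = config.simulation
    manifest: dict[str, str] = {}

    def emit(name: str, writer) -> str:
        path = os.path.join(outdir, name)
        writer(path)
        manifest[name] = _sha256(path)
        return path

    try:
        # --- simulate -------------------------------------------------------
        ancestor = generate_ancestor(sim)
        strain_a, _ = derive_strain(ancestor, sim, "A")
        strain_b, truth_b = derive_strain(ancestor, sim, "B")
        species, truth_sp = derive_species(ancestor, sim)
        singles, mates1, mates2 = simulate_reads(strain_b, sim)
        emit("strainA.fasta", lambda p: write_fasta(strain_a.records, p))
        emit("strainB.fasta", lambda p: write_fasta(strain_b.records, p))
        emit("species.fasta", lambda p: write_fasta(species.records, p))
        emit("strainA.gff3", lambda p: write_annotations(strain_a.genes, p))
        emit("species.gff3", lambda p: write_annotations(species.genes, p))
        emit("reads_single.fastq", lambda p: write_fastq(singles, p))
        emit("mates_1.fastq", lambda p: write_fastq(mates1, p))
        emit("mates_2.fastq", lambda p: write_fastq(mates2, p))
        emit("orthologs.tsv",
             lambda p: write_ortholog_table(write_ortholog_rows(strain_a, species), p))
        log.log("simulate", seconds=round(time.time() - t0, 1),
                n_single_reads=len(singles), n_mate_pairs=len(mates1),
                planted_variants=len(truth_b.variants),
                planted_breakpoints=len(truth_sp.breakpoints))

        # --- assemble strain B from its reads ------------------------------
        t = time.time()
        acfg = assembler.AssemblerConfig(sim.read_length, config.overlap_floor,
                                         config.min_branch_support,
                                         config.min_branch_quality)
        read_pairs = [(rec.sequence, assembler.phred_to_class(ph))
                      for rec, ph in singles]
        assembly = assembler.assemble(read_pairs, acfg)
        contig_records = [SeqRecord(c.id, c.sequence) for c in assembly.contigs]
        emit("contigs.fasta", lambda p: write_fasta(contig_records, p))
        identity = _exact_fraction(assembly.contigs,
                                   {r.id: r.sequence for r in strain_b.records})
        log.log("assemble", seconds=round(time.time() - t, 1),
                contigs=len(assembly.contigs), n50=assembly.n50(),
                exact_fraction=round(identity, 4))

        # --- scaffold contigs against the reference strain ------------------
        t = time.time()
        scfg = scaffolder.ScaffoldConfig(insert_mean=sim.insert_mean,
                                         insert_sd=sim.insert_sd,
                                         min_links=config.min_links,
                                         mate_orientation=sim.mate_orientation)
        big = [r for r in contig_records if len(r.sequence) >= scfg.k]
        placements = scaffolder.anchor_contigs(big, strain_a.records, scfg)
        links = scaffolder.link_mate_pairs(mates1, mates2, big, scfg)
        scaffolds = scaffolder.build_scaffolds(placements, links, strain_a.records,
                                               big, scfg)
        emit("scaffolds.fasta", lambda p: write_fasta(
            [scaffolder.scaffold_sequence(s, big) for s in scaffolds], p))
        emit("scaffolds.agp", lambda p: scaffolder.write_agp(scaffolds, big, p))
        log.log("scaffold", seconds=round(time.time() - t, 1),
                scaffolds=len(scaffolds), links=len(links))

        # --- compare the two strain genomes ---------------------------------
        t = time.time()
        alignment = comparator.align_genomes(strain_a, strain_b)
        variants = comparator.call_variants(alignment, strain_a)
        comparator.classify_coding(variants, strain_a.genes, strain_a)
        track_fine = comparator.identity_track(alignment, config.window_fine)
        segments = comparator.detect_introgression(
            track_fine, variants, config.introgression_threshold,
            config.introgression_min_windows)
        emit("variants.vcf", lambda p: write_variants(variants, p))
        emit("identity_1kb.bed", lambda p: write_bed(
            [(w.chromosome, w.start, w.end,
              f"{w.identity:.4f}" if w.identity is not None else "NA")
             for w in track_fine], p))
        emit("introgression.bed", lambda p: write_bed(
            [(s.chromosome, s.start, s.end, f"id={s.mean_identity:.3f};snps={s.n_snps}")
             for s in segments], p))
        log.log("compare", seconds=round(time.time() - t, 1),
                snps=sum(1 for v in variants if v.type == "SNP"),
                indels=sum(1 for v in variants if v.type != "SNP"),
                segments=len(segments))

        # --- synteny: species vs reference strain ---------------------------
        t = time.time()
        ortho_rows = write_ortholog_rows(strain_a, species)
        order_sp, order_a, mapping = synteny.build_gene_orders(
            species.genes, strain_a.genes, [(a, b, f) for a, b, f in ortho_rows],
            name_a="species", name_b="strainA")
        bps = synteny.find_breakpoints(order_sp, order_a, mapping, config.max_skip)
        og_order = synteny.GeneOrder(
            "outgroup",
            {c: [(g.gene_id, g.strand) for g in sorted(
                (g for g in ancestor.genes if g.chromosome == c),
                key=lambda g: g.start)]
             for c in sorted({g.chromosome for g in ancestor.genes})})
        og_map = {g.gene_id: g.gene_id for g in species.genes
                  if g.gene_id in {x.gene_id for x in ancestor.genes}}
        synteny.classify_ancestry(bps, order_sp, order_a, mapping, og_order,
                                  og_map, config.max_skip)
        fams_a = {g.gene_id: g.ortholog_label for g in strain_a.genes
                  if g.ortholog_label and g.ortholog_label.startswith("fam")}
        fams_sp = {g.gene_id: g.ortholog_label for g in species.genes
                   if g.ortholog_label and g.ortholog_label.startswith("fam")}
        arrays_a = synteny.find_tandem_arrays(strain_a.genes, fams_a,
                                              config.max_intervening,
                                              strain_a, "strainA")
        arrays_sp = synteny.find_tandem_arrays(species.genes, fams_sp,
                                               config.max_intervening,
                                               species, "species")
        array_table = synteny.compare_arrays(arrays_a, arrays_sp, fams_a, fams_sp)

        def _write_bps(p):
            with open(p, "w") as fh:
                fh.write("chromosome\tleft_gene\tright_gene\tpartner_chromosomes\t"
                         "type\tancestry\tevent\n")
                for bp in bps:
                    fh.write(f"{bp.chromosome}\t{bp.left_gene}\t{bp.right_gene}\t"
                             f"{','.join(bp.partner_chromosomes_in_b)}\t{bp.type}\t"
                             f"{bp.ancestry}\t{bp.event_id}\n")
        emit("breakpoints.tsv", _write_bps)

        def _write_arrays(p):
            with open(p, "w") as fh:
                fh.write("family\tcount_strainA\tcount_species\tdiffers\n")
                for fam, ca, cb, differs in array_table:
                    fh.write(f"{fam}\t{ca}\t{cb}\t{differs}\n")
        emit("tandem_arrays.tsv", _write_arrays)
        log.log("synteny", seconds=round(time.time() - t, 1),
                breakpoints=len(bps), events=synteny.count_events(bps),
                arrays=len(array_table))

        # --- annotation features --------------------------------------------
        t = time.time()
        introns = features.collect_introns(strain_a.genes, strain_a)
        stats = features.intron_stats(introns)
        overlaps = features.find_convergent_overlaps(strain_a.genes)

        def _write_introns(p):
            with open(p, "w") as fh:
                fh.write("gene\tchromosome\tstart\tend\tlength\tdonor\tclass\n")
                for rec in introns:
                    fh.write(f"{rec.gene_id}\t{rec.chromosome}\t{rec.start}\t"
                             f"{rec.end}\t{rec.length}\t{rec.donor_site}\t"
                             f"{rec.location_class}\n")
        emit("introns.tsv", _write_introns)
        if introns:
            cons = features.splice_consensus(introns, strain_a)

            def _write_cons(p):
                with open(p, "w") as fh:
                    for name in ("donor", "branch", "acceptor"):
                        m = getattr(cons, f"{name}_matrix")
                        fh.write(f"#{name}\tconsensus={cons.consensus_string(name)}\n")
                        for ri, base in enumerate("ACGT"):
                            row = "\t".join(f"{x:.4f}" for x in m[ri])
                            fh.write(f"{base}\t{row}\n")
            emit("splice_consensus.tsv", _write_cons)
        log.log("features", seconds=round(time.time() - t, 1),
                introns=len(introns),
                mean_intron_length=stats["mean_length"],
                overlaps=len(overlaps))

        # --- scorecard -------------------------------------------------------
        sp, sr, ip, ir = score_variants(variants, truth_b)
        boundary_err = None
        if truth_b.introgression is not None and segments:
            chrom, ts, te = truth_b.introgression
            match = [s for s in segments if s.chromosome == chrom]
            if match:
                seg = min(match, key=lambda s: abs(s.start - ts))
                boundary_err = max(abs(seg.start - ts), abs(seg.end - te))
        truth_flanks = {(bp[1], bp[2]) for bp in truth_sp.breakpoints}
        called_flanks = {(bp.left_gene, bp.right_gene) for bp in bps}
        planted_counts = {fam: (ca, cb) for fam, ca, cb in
                          ((f, a, b) for f, a, b in sim.tandem_events)}
        called_counts = {fam: (ca, cb) for fam, ca, cb, _d in array_table}
        matched = sum(1 for fam, counts in planted_counts.items()
                      if called_counts.get(fam, (1, 1) if max(counts) < 2 else None)
                      == counts)
        card = Scorecard(
            snp_precision=sp, snp_recall=sr,
            indel_precision=ip, indel_recall=ir,
            introgression_boundary_error=boundary_err,
            breakpoints_found=len(truth_flanks & called_flanks),
            breakpoints_planted=len(truth_flanks),
            arrays_matched=matched / len(planted_counts) if planted_counts else 1.0,
            assembly_contig_count=len(assembly.contigs),
            assembly_identity=identity,
        )
        emit("scorecard.json", lambda p: _dump_json(card.to_dict(), p))

        def _write_card(p):
            with open(p, "w") as fh:
                for k, v in card.to_dict().items():
                    fh.write(f"{k}\t{v}\n")
        emit("scorecard.tsv", _write_card)
        _dump_json(manifest, os.path.join(outdir, "manifest.json"))
        log.log("done", seconds=round(time.time() - t0, 1))
        return card
    finally:
        log.close()


def _dump_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
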