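"""End-to-end orchestration: detect -> classify -> families -> annotate ->
phylogeny -> clade-assign -> report, per species, with a reproducible
manifest.

The per-species analyses share one reference panel and, at the
annotation stage, a cross-species scan library assembled from every
species' cluster-derived families (orphans are excluded from the scan
library because their single copies may carry contaminant fragments;
they re-enter at assignment time). Copies assignable only to another
species' families are promoted to new annotation-derived families when
they carry a translatable RT/RNaseH domain, and all copies are then
re-assigned against the augmented library.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .align import ReferencePanel, classify_superfamily
from .annotate import (AnnotatedCopy, LibraryIndex, ScanParams, assign_copies,
                       copies_to_gff3, copies_to_tsv, defragment,
                       genomic_proportion, promote_annotation_families, scan_genome)
from .detect import DetectionParams, LTRCandidate, candidates_to_gff3, candidates_to_tsv, detect_genome
from .families import (DiscardRecord, Family, FamilyParams, TECopy, build_families,
                       families_to_files)
from .io import ensure_dir, read_fasta, revcomp, write_fasta
from .phylo import (CladeCall, DomainSeq, PhyloParams, align_domains,
                    bootstrap_support, clades_to_tsv, define_clades, extract_domain)
from .clades import CladeAssignParams, assign_by_similarity, assignments_to_tsv
from .report import (clade_family_table, clade_relative_proportions,
                     superfamily_composition)


@dataclass
class SpeciesConfig:
    name: str
    fasta: str
    taxon_class: str = "unknown"


@dataclass
class RunConfig:
    species: list[SpeciesConfig]
    panel_fasta: str
    panel_labels: str
    outdir: str
    rng_seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    family: FamilyParams = field(default_factory=FamilyParams)
    scan: ScanParams = field(default_factory=ScanParams)
    phylo: PhyloParams = field(default_factory=PhyloParams)
    clade_assign: CladeAssignParams = field(default_factory=CladeAssignParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        species = [SpeciesConfig(**s) for s in raw.pop("species")]
        blocks = {}
        for key, klass in (("detection", DetectionParams), ("family", FamilyParams),
                           ("scan", ScanParams), ("phylo", PhyloParams),
                           ("clade_assign", CladeAssignParams)):
            if key in raw:
                blocks[key] = klass(**raw.pop(key))
        return cls(species=species, **raw, **blocks)

    def validate(self) -> None:
        for p in (self.panel_fasta, self.panel_labels):
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input: {p}")
        for sp in self.species:
            if not Path(sp.fasta).exists():
                raise FileNotFoundError(f"missing genome FASTA for {sp.name}: {sp.fasta}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = ensure_dir(config.outdir)
    panel = ReferencePanel.from_files(config.panel_fasta, config.panel_labels)
    panel_slim = panel.one_per_clade()  # classification / envelope extraction
    manifest: dict = {"seed": config.rng_seed, "species": {}, "parameters": {
        "detection": asdict(config.detection), "family": asdict(config.family),
        "scan": asdict(config.scan), "phylo": asdict(config.phylo),
        "clade_assign": asdict(config.clade_assign)}}

    genomes: dict[str, dict[str, str]] = {}
    species_stage: dict[str, dict] = {}

    # stage 1-3: detection, classification, family building (per species)
    for sp in config.species:
        spdir = ensure_dir(outdir / sp.name)
        genome = read_fasta(sp.fasta)
        genomes[sp.name] = genome
        candidates = detect_genome(genome, config.detection)
        candidates_to_gff3(candidates, spdir / "candidates.gff3")
        candidates_to_tsv(candidates, spdir / "candidates.tsv")
        copies, structural_counts = _classify_candidates(
            sp.name, genome, candidates, panel_slim)
        families, discards = build_families(copies, panel_slim, config.family)
        families_to_files(families, spdir / "families.fa", spdir / "family_members.tsv")
        with open(spdir / "discards.tsv", "w") as fh:
            fh.write("copy_id\treason\n")
            for d in discards:
                fh.write(f"{d.copy_id}\t{d.reason}\n")
        species_stage[sp.name] = {
            "candidates": candidates, "copies": copies, "families": families,
            "discards": discards, "structural_copies": structural_counts,
            "genome_length": sum(len(s) for s in genome.values())}
        manifest["species"][sp.name] = {
            "contigs": len(genome), "genome_length": species_stage[sp.name]["genome_length"],
            "candidates": len(candidates), "classified_copies": len(copies),
            "families_structural": len(families), "orphan_discards": len(discards)}

    # stage 4: genome annotation with the cross-species cluster library
    scan_library = [f for st in species_stage.values()
                    for f in st["families"] if f.origin == "cluster"]
    assign_library = [f for st in species_stage.values() for f in st["families"]]
    scan_index = LibraryIndex(scan_library, config.scan.seed_k) if scan_library else None
    for sp in config.species:
        st = species_stage[sp.name]
        spdir = outdir / sp.name
        genome = genomes[sp.name]
        hits = scan_genome(genome, scan_index, config.scan) if scan_index else []
        copies = defragment(hits, config.scan.merge_gap_max)
        copies = assign_copies(copies, genome, assign_library, sp.name, config.scan)
        cross = [c for c in copies if c.status == "cross_species_candidate"]
        counters: dict[tuple[str, str], int] = {}
        for fam in st["families"]:
            key = (fam.superfamily, fam.species)
            counters[key] = counters.get(key, 0) + 1
        new_fams = promote_annotation_families(cross, genome, panel_slim, sp.name,
                                               config.family, start_index=counters)
        if new_fams:
            st["families"] = st["families"] + new_fams
            augmented = assign_library + new_fams
            copies = assign_copies(copies, genome, augmented, sp.name, config.scan)
        st["annotated"] = copies
        copies_to_tsv(copies, spdir / "annotation.tsv")
        copies_to_gff3(copies, spdir / "annotation.gff3")
        manifest["species"][sp.name].update({
            "scan_hits": len(hits), "annotated_copies": len(copies),
            "annotation_families_new": len(new_fams),
            "families_total": len(st["families"]),
            "unassigned_copies": sum(1 for c in copies if c.status == "unassigned")})

    # stage 5: per-superfamily phylogeny over all species, with panel references
    all_families = [f for st in species_stage.values() for f in st["families"]]
    clade_of: dict[str, str] = {}
    all_calls: list[CladeCall] = []
    phylo_dir = ensure_dir(outdir / "phylogeny")
    by_sf: dict[str, list[Family]] = {}
    for f in all_families:
        by_sf.setdefault(f.superfamily, []).append(f)
    excluded: list[tuple[str, str]] = []
    domains_by_family: dict[str, DomainSeq] = {}
    for sf, fams in sorted(by_sf.items()):
        domains: list[DomainSeq] = []
        for fam in fams:
            dom, reason = extract_domain(fam, panel_slim, min_len=config.family.min_domain_aa)
            if dom is None:
                excluded.append((fam.family_id, reason))
            else:
                domains.append(dom)
                domains_by_family[fam.family_id] = dom
        refs = [DomainSeq(e.entry_id, f"ref:{e.clade}", e.aa_seq)
                for e in panel.entries if e.superfamily == sf]
        if len(domains) + len(refs) < 3 or not domains:
            continue
        msa = align_domains(domains + refs)
        with open(phylo_dir / f"{sf}.aln.fa", "w") as fh:
            for name, row in msa.items():
                fh.write(f">{name}\n{row}\n")
        stree = bootstrap_support(msa, config.phylo)
        (phylo_dir / f"{sf}.nwk").write_text(stree.newick() + "\n")
        species_of = {d.family_id: d.species for d in domains}
        ref_labels = {e.entry_id: e.clade for e in panel.entries
                      if e.superfamily == sf and e.clade}
        calls, other = define_clades(stree, species_of, config.phylo,
                                     reference_clades=ref_labels or None)
        for call in calls:
            all_calls.append(call)
            for m in call.members:
                clade_of[m] = call.name
    clades_to_tsv(all_calls, [f.family_id for f in all_families
                              if f.family_id not in clade_of], phylo_dir / "clades.tsv")

    # stage 6: similarity route for families the trees left unplaced
    classified_db = [(fid, domains_by_family[fid].aa_seq, clade_of[fid])
                     for fid in clade_of if fid in domains_by_family]
    classified_db += [(e.entry_id, e.aa_seq, e.clade)
                      for e in panel.entries if e.clade]
    similarity_results = []
    for fam in all_families:
        if fam.family_id in clade_of or fam.family_id not in domains_by_family:
            continue
        res = assign_by_similarity(domains_by_family[fam.family_id], classified_db,
                                   config.clade_assign)
        similarity_results.append(res)
        if res.clade:
            clade_of[fam.family_id] = res.clade
    assignments_to_tsv(similarity_results, outdir / "similarity_assignments.tsv")
    manifest["clades"] = {
        "phylogenetic_calls": len(all_calls),
        "similarity_assigned": sum(1 for r in similarity_results if r.clade),
        "families_in_clades": len(clade_of),
        "families_other": len(all_families) - len(clade_of),
        "domain_excluded": len(excluded)}

    # stage 7: reports
    species_results = {
        sp.name: {"copies": species_stage[sp.name].get("annotated", []),
                  "families": species_stage[sp.name]["families"],
                  "structural_copies": species_stage[sp.name]["structural_copies"],
                  "genome_length": species_stage[sp.name]["genome_length"]}
        for sp in config.species}
    comp = superfamily_composition(species_results)
    comp.to_csv(outdir / "superfamily_composition.tsv", sep="\t", index=False)
    source_of = {f.family_id: "genome" for f in all_families}
    census = clade_family_table(all_families, clade_of, source_of)
    census.table.to_csv(outdir / "clade_census.tsv", sep="\t", index=False)
    for sp in config.species:
        st = species_stage[sp.name]
        props = clade_relative_proportions(st.get("annotated", []), clade_of, sp.name)
        props.to_csv(outdir / sp.name / "clade_proportions.tsv", sep="\t", index=False)
    manifest["families_total"] = len(all_families)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _classify_candidates(species: str, genome: Mapping[str, str],
                         candidates: list[LTRCandidate], panel: ReferencePanel
                         ) -> tuple[list[TECopy], dict[str, int]]:
    """Superfamily-classify structural candidates; drop unclassified ones
    (artefactual repeat pairs) and resolve strand from the best frame."""
    from .align import mask_tandem_repeats

    copies: list[TECopy] = []
    counts: dict[str, int] = {}
    for i, cand in enumerate(candidates, 1):
        seq = cand.sequence(genome[cand.contig])
        label, strand, _hit = classify_superfamily(seq, panel)
        if label == "unclassified":
            continue
        masked, _ivals = mask_tandem_repeats(seq)
        if strand == "-":
            masked = revcomp(masked)
        counts[label] = counts.get(label, 0) + 1
        copies.append(TECopy(
            copy_id=f"{species}_{cand.contig}_{cand.element_span[0]}",
            species=species, superfamily=label, seq=masked, strand=strand,
            contig=cand.contig, span=cand.element_span, provenance="structural"))
    return copies, counts
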