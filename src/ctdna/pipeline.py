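"""End-to-end run orchestration: simulate -> phase -> analyze -> report.

A run is a pure function of its configuration (including all seeds); outputs
carry no timestamps, so identical configurations produce byte-identical run
directories.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import dating, indels, insertion_site, phasing, phylo, repeats, simulate


class RunConfig(BaseModel):
    """Schema-validated configuration of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = 0
    # simulation
    n_accessions: int = 20
    coverage: float = 30.0
    read_error_rate: float = 0.0
    p_heterozygous: float = 0.58
    p_cross_clade: float = 0.5
    p_rearranged_lineage: float = 1.0
    n_homoplasy: int = 0
    insertion_age: float = 15e6
    substitution_rate: float = 6.5e-9
    dating_convention: str = "paper"
    # phasing
    min_identity: float = 0.85
    min_overlap: int = 100
    min_coverage: float = 10.0
    # catalog
    min_indel_len: int = 3
    hypervariable_window: int = 15
    hypervariable_min_events: int = 4
    marker_min_count: int = 3
    # tree
    n_bootstrap: int = 100
    gap_threshold: float = 0.2

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            seed=self.seed,
            n_accessions=self.n_accessions,
            coverage=self.coverage,
            read_error_rate=self.read_error_rate,
            p_heterozygous=self.p_heterozygous,
            p_cross_clade=self.p_cross_clade,
            p_rearranged_lineage=self.p_rearranged_lineage,
            n_homoplasy=self.n_homoplasy,
            insertion_age=self.insertion_age,
            substitution_rate=self.substitution_rate,
            dating_convention=self.dating_convention,
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_fastq(path) -> list[tuple[str, str]]:
    reads = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i in range(0, len(lines) - 3, 4):
        reads.append((lines[i][1:], lines[i + 1]))
    return reads


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage, writing one reproducible run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name):
        log.append(name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    (out / "run_log.txt").write_text("\n".join(log) + f"\nFAILED: {name}\n")
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    # -- simulate ----------------------------------------------------------
    with stage("simulate"):
        sim_cfg = config.simulation_config()
        refmap, pop = simulate.simulate_population(sim_cfg)
        paths = simulate.write_population(pop, out / "sim")
        (out / "config_echo.json").write_text(
            json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n"
        )

    # -- phase --------------------------------------------------------------
    with stage("phase"):
        phased: list[phasing.PhasedAllele] = []
        for rec in pop.records:
            reads = _read_fastq(Path(paths["reads_dir"]) / f"{rec.accession}.fastq")
            rs = phasing.recruit_reads(
                reads, refmap, rec.accession, config.min_identity, config.min_overlap
            )
            phased.extend(phasing.phase_alleles(rs, refmap, min_coverage=config.min_coverage))
        fasta = [(p.allele_id, p.sequence) for p in phased if p.sequence]
        simulate.write_fasta(out / "phased_alleles.fa", fasta)
        with open(out / "phasing_report.tsv", "w") as fh:
            fh.write("accession\tallele_id\tstatus\tmean_depth\tsupporting_reads\tvariant_columns\n")
            for p in phased:
                fh.write(
                    f"{p.accession}\t{p.allele_id}\t{p.status}\t{p.mean_depth:.2f}\t"
                    f"{p.supporting_reads}\t{p.n_variant_columns}\n"
                )

    analysis_seqs = dict(fasta)
    if pop.outgroup is not None:
        for a in pop.outgroup.alleles:
            analysis_seqs[a.allele_id] = a.sequence  # assembled input, not phased

    # -- repeats / structure / gene scan -------------------------------------
    with stage("structure"):
        pairs = {}
        with open(out / "repeats.tsv", "w") as fh:
            fh.write("allele_id\tidentity\tdivergence\taligned_columns\tresolved\n")
            for aid in sorted(analysis_seqs):
                pair = repeats.extract_repeats(analysis_seqs[aid], refmap, aid)
                pairs[aid] = pair
                fh.write(
                    f"{aid}\t{pair.identity:.3f}\t{pair.divergence:.5f}\t"
                    f"{pair.aligned_columns}\t{pair.resolved}\n"
                )
        with open(out / "structure.tsv", "w") as fh:
            fh.write("allele_id\tclass\tbreakpoint_deletions\n")
            for aid in sorted(analysis_seqs):
                call = repeats.classify_structure(analysis_seqs[aid], refmap, aid)
                dels = ",".join(map(str, call.breakpoint_deletions))
                fh.write(f"{aid}\t{call.structural_class}\t{dels}\n")
        with open(out / "disruptions.tsv", "w") as fh:
            fh.write("allele_id\tgene\tkind\tposition\tcontext\n")
            for aid in sorted(analysis_seqs):
                for d in repeats.scan_gene_disruptions(analysis_seqs[aid], refmap, aid):
                    fh.write(f"{aid}\t{d.gene}\t{d.kind}\t{d.position}\t{d.context}\n")

    # -- indel catalog --------------------------------------------------------
    with stage("indels"):
        events_by_allele = {}
        for aid, seq in analysis_seqs.items():
            if aid.startswith("out"):
                continue  # the rearranged lineage is cataloged structurally
            evs = indels.call_indels(seq, refmap, min_len=config.min_indel_len)
            events_by_allele[aid] = indels.classify_events(evs, seq, refmap)
        catalog = indels.aggregate_catalog(events_by_allele)
        catalog.to_csv(out / "indel_catalog.tsv", sep="\t", index=False)
        regions = indels.report_hypervariable_regions(
            catalog, config.hypervariable_window, config.hypervariable_min_events
        )
        (out / "hypervariable_regions.bed").write_text(indels.regions_to_bed(regions))

    # -- insertion site --------------------------------------------------------
    with stage("site"):
        empty = simulate.empty_site_sequence(refmap, sim_cfg.tsd_len)
        calls = insertion_site.align_empty_vs_filled(empty, refmap.sequence)
        with open(out / "insertion_site.tsv", "w") as fh:
            fh.write("insert_id\tkind\tstart\tend\tlength\ttsd\tterminal_ir_length\tterminal_ir\n")
            for call in calls:
                carrier = refmap.sequence if call.kind == "filled_only" else empty
                call = insertion_site.detect_tsd(call, carrier)
                call = insertion_site.detect_terminal_ir(call, carrier)
                fh.write(
                    f"{call.insert_id}\t{call.kind}\t{call.start}\t{call.end}\t{call.length}\t"
                    f"{call.tsd}\t{call.terminal_ir_length}\t{call.terminal_ir_seq}\n"
                )

    # -- dating -----------------------------------------------------------------
    with stage("date"):
        ages = []
        with open(out / "dating.tsv", "w") as fh:
            fh.write("allele_id\tdivergence\tage_years\tci_low\tci_high\tconvention\n")
            for aid in sorted(analysis_seqs):
                pair = pairs[aid]
                if not pair.resolved:
                    continue
                res = dating.date_insertion(
                    pair, mu=config.substitution_rate, convention=config.dating_convention
                )
                ages.append(res.age)
                fh.write(
                    f"{aid}\t{res.divergence:.5f}\t{res.age:.0f}\t{res.age_ci[0]:.0f}\t"
                    f"{res.age_ci[1]:.0f}\t{res.convention}\n"
                )

    # -- tree and concordance -----------------------------------------------------
    with stage("tree"):
        tree_report = None
        spans = None
        if pop.outgroup is not None and len(analysis_seqs) >= 4:
            og = pop.outgroup.alleles[0].allele_id
            msa = phylo.align_alleles(analysis_seqs, gap_threshold=config.gap_threshold)
            tree = phylo.build_tree(msa, og, n_bootstrap=config.n_bootstrap, seed=config.seed)
            (out / "tree.nwk").write_text(tree.newick + "\n")
            markers = phylo.marker_matrix_from_catalog(
                catalog, [a for a in sorted(analysis_seqs) if a != og], config.marker_min_count
            )
            markers.to_csv(out / "marker_matrix.tsv", sep="\t")
            tree_report = phylo.assign_groups(tree, markers)
            by_acc: dict[str, list[str]] = {}
            for p in phased:
                if p.sequence:
                    by_acc.setdefault(p.accession, []).append(p.allele_id)
            spans = phylo.pair_spans(tree_report, by_acc)
            spans.to_csv(out / "pair_spans.tsv", sep="\t", index=False)
            with open(out / "groups.tsv", "w") as fh:
                fh.write("allele_id\tgroup\tsubgroup\n")
                for aid in sorted(tree_report.groups):
                    fh.write(f"{aid}\t{tree_report.groups[aid]}\t{tree_report.subgroups[aid]}\n")

    # -- summary --------------------------------------------------------------
    with stage("summary"):
        n_unique = sum(1 for p in phased if p.status == "unique")
        n_paired_acc = len({p.accession for p in phased if p.status == "paired"})
        n_insuff = sum(1 for p in phased if p.status == "insufficient")
        summary = {
            "accessions": config.n_accessions,
            "unique_accessions": n_unique,
            "paired_accessions": n_paired_acc,
            "insufficient_accessions": n_insuff,
            "alleles": n_unique + 2 * n_paired_acc,
            "catalog_rows": int(len(catalog)),
            "mean_age_years": float(pd.Series(ages).mean()) if ages else None,
            "group_counts": (
                pd.Series(list(tree_report.groups.values())).value_counts().to_dict()
                if tree_report
                else {}
            ),
            "n_exceptions": len(tree_report.exceptions) if tree_report else None,
            "cross_group_pairs": int(spans["cross_group"].sum()) if spans is not None else None,
            "digests": {
                p.name: _digest(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        (out / "run_log.txt").write_text("\n".join(log) + "\nOK\n")
    return out
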