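"""End-to-end orchestration of the motif survey.

Stage order: load -> join -> (pare) -> trim -> catalytic-His verification
(failures retained in the per-record table with a disposition, but
excluded from downstream analysis) -> alignment to the reference ->
region annotation -> motif scan + groupings -> MCF calling -> statistics
suite -> trees. When no multiple sequence alignment is supplied, tree
distances are computed on a reference-projected pseudo-MSA (each kept
query mapped onto reference columns by its pairwise alignment).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


import pandas as pd

from fechsurvey import __version__, stats
from fechsurvey.io_metadata import Dataset, ProteinRecord, pare_genomes
from fechsurvey.motif_engine import (
    CONSENSUS_2FE2S,
    GroupingFlags,
    MCFCall,
    compile_pattern,
    call_mcf,
    detect_groupings,
    hits_table_rows,
    scan,
)
from fechsurvey.phylogeny import (
    bootstrap_trees,
    distance_matrix_from_msa,
    majority_consensus,
    neighbor_joining,
    write_newick,
)
from fechsurvey.reference_mapping import (
    ReferenceProfile,
    RegionAnnotation,
    annotate_regions,
    global_align,
    his_status_from_alignment,
    project_to_reference,
    prune_gap_columns,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline thresholds and toggles (paths are handled by the CLI)."""

    min_insertion: int = 15
    min_tail: int = 10
    gap_threshold: float = 0.95
    his_rich_threshold: float = 0.15
    cys_bins: tuple = stats.DEFAULT_CYS_BINS
    bootstrap_replicates: int = 100
    tree_seed: int = 95549
    consensus_threshold: float = 0.5
    do_pare: bool = False
    per_order_cap: int = 10
    do_tree: bool = True
    do_core_tree: bool = True

    def validate(self) -> None:
        if not 0 < self.gap_threshold <= 1:
            raise ValueError("gap_threshold must be in (0, 1]")
        if not 0 <= self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must be in [0, 1]")
        if self.min_insertion < 1 or self.min_tail < 1:
            raise ValueError("region length thresholds must be positive")


@dataclass
class RecordResult:
    """Everything computed for one input record."""

    record: ProteinRecord
    disposition: str  # kept | dropped:no_his
    his_ok: bool
    his_query_pos: int | None
    his_reason: str
    regions: RegionAnnotation | None = None
    hits: tuple = ()
    groupings: GroupingFlags | None = None
    mcf: MCFCall | None = None
    profile: stats.CysteineProfile | None = None
    projected_row: str = ""


@dataclass
class ReportBundle:
    """All pipeline outputs, serializable as a TSV/JSON/Newick bundle."""

    per_record: pd.DataFrame
    results: dict[str, RecordResult]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    bin_likelihoods: list = field(default_factory=list)
    logistic: stats.LogisticFit | None = None
    gc_means: dict = field(default_factory=dict)
    length_cys_r: tuple[float, bool] = (float("nan"), False)
    env_group_shares: dict = field(default_factory=dict)
    tree_newick: str = ""
    core_tree_newick: str = ""
    consensus_newick: str = ""
    counts: dict = field(default_factory=dict)
    notices: list = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_record.to_csv(out / "per_record.tsv", sep="\t", index=False)
        for name, df in self.tables.items():
            df.to_csv(out / f"table_{name}.tsv", sep="\t", index=False)
        hit_rows = []
        for rid in sorted(self.results):
            rr = self.results[rid]
            if rr.mcf is not None:
                hit_rows.extend(
                    hits_table_rows(
                        rid, "consensus_2fe2s", [h for h, _ in rr.mcf.all_hits],
                        rr.mcf.all_hits, rr.mcf.is_mcf,
                    )
                )
        pd.DataFrame(
            hit_rows,
            columns=[
                "record_id", "pattern", "start", "end",
                "literal_positions", "location", "is_mcf",
            ],
        ).to_csv(out / "hits.tsv", sep="\t", index=False)
        summary = {
            "version": __version__,
            "counts": self.counts,
            "gc_means": self.gc_means,
            "length_cys_pearson_r": self.length_cys_r[0],
            "length_cys_r_defined": self.length_cys_r[1],
            "env_group_shares": self.env_group_shares,
            "bin_likelihoods": [dataclasses.asdict(b) for b in self.bin_likelihoods],
            "logistic": dataclasses.asdict(self.logistic) if self.logistic else None,
            "notices": self.notices,
            "config": self.config_echo,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        if self.tree_newick:
            (out / "tree.nwk").write_text(self.tree_newick)
        if self.core_tree_newick:
            (out / "core_tree.nwk").write_text(self.core_tree_newick)
        if self.consensus_newick:
            (out / "consensus.nwk").write_text(self.consensus_newick)


def process_record(
    record: ProteinRecord,
    ref: ReferenceProfile,
    config: PipelineConfig,
    pattern=None,
) -> RecordResult:
    """Align, verify, annotate and scan one record."""
    pattern = pattern or compile_pattern(CONSENSUS_2FE2S)
    seq = record.trimmed_sequence
    aln = global_align(seq, ref.sequence)
    his_ok, his_pos, reason = his_status_from_alignment(aln, ref)
    rr = RecordResult(
        record=record,
        disposition="kept" if his_ok else "dropped:no_his",
        his_ok=his_ok,
        his_query_pos=his_pos,
        his_reason=reason,
    )
    if not his_ok:
        return rr
    regions = annotate_regions(aln, ref, config.min_insertion, config.min_tail)
    hits = scan(seq, pattern)
    rr.regions = regions
    rr.hits = tuple(hits)
    rr.groupings = detect_groupings(seq, regions, config.his_rich_threshold)
    rr.mcf = call_mcf(hits, regions)
    rr.profile = stats.cysteine_profile(record)
    rr.projected_row = project_to_reference(aln, ref)
    return rr


def run_pipeline(
    dataset: Dataset,
    ref: ReferenceProfile,
    config: PipelineConfig | None = None,
    msa: tuple[Sequence[str], Sequence[str]] | None = None,
) -> ReportBundle:
    """Run the full survey on an in-memory dataset.

    ``msa``, when given, is ``(labels, rows)`` of a precomputed multiple
    sequence alignment used for the tree stage instead of the
    reference-projected rows.
    """
    config = config or PipelineConfig()
    config.validate()
    dataset.validate_join()
    n_input = len(dataset.records)

    if config.do_pare:
        keep = pare_genomes(list(dataset.genomes.values()), config.per_order_cap)
        dataset = dataset.subset_genomes(keep)

    pattern = compile_pattern(CONSENSUS_2FE2S)
    results: dict[str, RecordResult] = {}
    for record in dataset.records:
        results[record.record_id] = process_record(record, ref, config, pattern)

    kept = [rr for rr in results.values() if rr.disposition == "kept"]
    dropped = [rr for rr in results.values() if rr.disposition != "kept"]
    if config.do_pare:
        n_input = len(dataset.records)
    assert len(kept) + len(dropped) == len(dataset.records), "record conservation"

    per_rows = []
    for rid in sorted(results):
        rr = results[rid]
        row = {
            "record_id": rid,
            "genome_id": rr.record.genome_id,
            "disposition": rr.disposition,
            "his_reason": rr.his_reason,
            "his_query_pos": rr.his_query_pos,
            "length": len(rr.record.trimmed_sequence),
        }
        if rr.disposition == "kept":
            row.update(
                {
                    "n_ext": _span_str(rr.regions.n_ext),
                    "insertions": ";".join(
                        _span_str(s) for s in rr.regions.insertions
                    ),
                    "c_tail": _span_str(rr.regions.c_tail),
                    "cys_count": rr.profile.cys_count,
                    "n_hits": len(rr.hits),
                    "is_mcf": int(rr.mcf.is_mcf),
                    "mcf_location": rr.mcf.qualifying_location,
                    "mcf_reason": rr.mcf.reason,
                    "his_rich_tail": int(rr.groupings.his_rich_tail),
                    "has_exxnxr": int(rr.groupings.has_exxnxr),
                }
            )
        per_rows.append(row)
    per_record = pd.DataFrame(per_rows)

    bundle = ReportBundle(per_record=per_record, results=results)
    bundle.config_echo = dataclasses.asdict(config)
    bundle.counts = {
        "input_records": n_input,
        "kept_records": len(kept),
        "dropped_no_his": len(dropped),
        "input_genomes": len(dataset.genomes),
    }

    # genomes survive as long as one functional record remains
    kept_records = [rr.record for rr in kept]
    kept_genomes = {r.genome_id for r in kept_records}
    analysis = Dataset(
        records=kept_records,
        genomes={g: m for g, m in dataset.genomes.items() if g in kept_genomes},
    )
    bundle.counts["kept_genomes"] = len(analysis.genomes)
    mcf_by_record = {
        rr.record.record_id: rr.mcf.is_mcf for rr in kept
    }
    loc_by_record = {
        rr.record.record_id: rr.mcf.qualifying_location for rr in kept
    }
    bundle.counts["mcf_records"] = sum(mcf_by_record.values())
    bundle.counts["mcf_genomes"] = sum(
        stats.species_mcf_status(analysis, mcf_by_record).values()
    )

    if not kept:
        bundle.notices.append("no records passed the His filter; stats skipped")
        return bundle

    profiles = [rr.profile for rr in kept]
    bundle.bin_likelihoods = stats.binned_likelihood(
        profiles, mcf_by_record, config.cys_bins
    )
    xs = [p.cys_count for p in profiles]
    ys = [int(mcf_by_record[p.record_id]) for p in profiles]
    try:
        bundle.logistic = stats.logistic_fit(xs, ys)
    except ValueError as exc:
        bundle.notices.append(f"logistic regression skipped: {exc}")
    bundle.tables["phylum"] = stats.crosstab(
        analysis, mcf_by_record, "phylum", "per_row_total"
    )
    bundle.tables["environment"] = stats.crosstab(
        analysis, mcf_by_record, "environment", "mcf_total"
    )
    bundle.env_group_shares = stats.environment_group_shares(
        bundle.tables["environment"]
    )
    bundle.tables["temperature"] = stats.temperature_table(analysis, mcf_by_record)
    bundle.tables["oxygen"] = stats.crosstab(
        analysis, mcf_by_record, "oxygen_req", "per_row_total"
    )
    bundle.tables["cooccurrence"] = stats.cooccurrence(analysis, mcf_by_record)
    bundle.gc_means = stats.gc_summary(analysis, mcf_by_record, loc_by_record)
    bundle.length_cys_r = stats.length_cys_correlation(profiles)

    if config.do_tree and len(kept) >= 4:
        if msa is not None:
            labels, rows = list(msa[0]), list(msa[1])
        else:
            labels = [rr.record.record_id for rr in kept]
            rows = [rr.projected_row for rr in kept]
        rows, removed = prune_gap_columns(rows, config.gap_threshold)
        if removed:
            bundle.notices.append(f"pruned {len(removed)} gap columns")
        dm = distance_matrix_from_msa(labels, rows, on_saturation="cap")
        tree = neighbor_joining(dm)
        bundle.tree_newick = write_newick(tree)
        if config.bootstrap_replicates > 0:
            reps = bootstrap_trees(
                labels, rows, config.bootstrap_replicates, config.tree_seed
            )
            consensus = majority_consensus(reps, config.consensus_threshold)
            bundle.consensus_newick = write_newick(consensus.tree)
        if config.do_core_tree:
            if msa is None:
                # slice the unpruned projections so reference coordinates apply
                lo, hi = ref.core_span
                core_labels = [rr.record.record_id for rr in kept]
                core_rows = [rr.projected_row[lo - 1 : hi] for rr in kept]
            else:
                core_labels, core_rows = labels, rows
            core_rows, _ = prune_gap_columns(core_rows, config.gap_threshold)
            core_dm = distance_matrix_from_msa(
                core_labels, core_rows, on_saturation="cap"
            )
            bundle.core_tree_newick = write_newick(neighbor_joining(core_dm))
    elif config.do_tree:
        bundle.notices.append("fewer than 4 kept records; tree stage skipped")

    return bundle


def _span_str(span: tuple[int, int] | None) -> str:
    return f"{span[0]}-{span[1]}" if span else ""
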