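"""Sequence and genome-metadata IO, dataset joining, and genome paring.

Candidate ferrochelatase sequences travel as :class:`ProteinRecord` objects
(one or more per genome), genome physiology as :class:`GenomeMeta`. The
paring sampler codifies the survey's oversampling control: one genome per
genus, then at most ten genomes per order distributed evenly across
families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 20 canonical amino acids plus X for ambiguity.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

OXYGEN_LEVELS = (
    "strictly_aerobic",
    "aerobic",
    "microaerophilic",
    "facultative",
    "anaerobic",
    "strictly_anaerobic",
    "no_data",
)

TEMP_RANGES = (
    "psychrophile",
    "psychrotolerant",
    "mesophile",
    "thermophile",
    "hyperthermophile",
    "no_data",
)

#: Habitat categories, grouped as aquatic / terrestrial / host / industry.
ENVIRONMENTS = (
    "aquatic_freshwater",
    "aquatic_marine",
    "aquatic_hot_spring",
    "aquatic_undefined",
    "terrestrial_soil",
    "terrestrial_geological",
    "host_human",
    "host_bovine",
    "host_plants",
    "host_other",
    "industry_acid_mine",
    "industry_wastewater",
    "industry_food",
    "industry_other",
    "other",
    "no_data",
)

TAXONOMY_RANKS = ("phylum", "class_", "order", "family", "genus", "species")

# Free-text spellings seen in genome-portal exports, mapped onto the closed enums.
_OXYGEN_ALIASES = {
    "strictly aerobic": "strictly_aerobic",
    "strict aerobic": "strictly_aerobic",
    "strict aerobe": "strictly_aerobic",
    "obligate aerobic": "strictly_aerobic",
    "obligate aerobe": "strictly_aerobic",
    "aerobic": "aerobic",
    "aerobe": "aerobic",
    "microaerophilic": "microaerophilic",
    "microaerophile": "microaerophilic",
    "facultative": "facultative",
    "facultative anaerobic": "facultative",
    "facultative anaerobe": "facultative",
    "anaerobic": "anaerobic",
    "anaerobe": "anaerobic",
    "strictly anaerobic": "strictly_anaerobic",
    "strict anaerobic": "strictly_anaerobic",
    "obligate anaerobic": "strictly_anaerobic",
    "obligate anaerobe": "strictly_anaerobic",
}

_TEMP_ALIASES = {
    "psychrophile": "psychrophile",
    "psychrophilic": "psychrophile",
    "psychrotolerant": "psychrotolerant",
    "mesophile": "mesophile",
    "mesophilic": "mesophile",
    "thermophile": "thermophile",
    "thermophilic": "thermophile",
    "hyperthermophile": "hyperthermophile",
    "hyperthermophilic": "hyperthermophile",
}

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}
_FALSE_STRINGS = {"0", "false", "no", "n", "f", ""}


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate ferrochelatase sequence with its genome linkage.

    ``trim_span`` is a 1-based inclusive span to retain before analysis;
    it handles known fusion proteins (e.g. a ferrochelatase-coproheme
    decarboxylase fusion) where only part of the ORF is the ferrochelatase.
    """

    record_id: str
    genome_id: str
    sequence: str
    trim_span: tuple[int, int] | None = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in AMINO_ALPHABET:
                raise ValueError(
                    f"record {self.record_id!r}: illegal character "
                    f"{ch!r} at position {pos}"
                )
        if self.trim_span is not None:
            lo, hi = self.trim_span
            if not (1 <= lo <= hi <= len(self.sequence)):
                raise ValueError(
                    f"record {self.record_id!r}: trim_span {self.trim_span} "
                    f"outside [1, {len(self.sequence)}]"
                )

    @property
    def trimmed_sequence(self) -> str:
        """Sequence after applying ``trim_span`` (identity when absent)."""
        if self.trim_span is None:
            return self.sequence
        lo, hi = self.trim_span
        return self.sequence[lo - 1 : hi]


@dataclass(frozen=True)
class GenomeMeta:
    """Genome-level metadata: taxonomy, GC%, physiology and curation flags."""

    genome_id: str
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""
    gc_percent: float = float("nan")
    oxygen_req: str = "no_data"
    temp_range: str = "no_data"
    environment: str = "no_data"
    has_cog0633: bool = False
    is_type_strain: bool = False
    has_characterized_fech: bool = False

    def __post_init__(self) -> None:
        if self.oxygen_req not in OXYGEN_LEVELS:
            raise ValueError(f"unknown oxygen_req {self.oxygen_req!r}")
        if self.temp_range not in TEMP_RANGES:
            raise ValueError(f"unknown temp_range {self.temp_range!r}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.gc_percent == self.gc_percent:  # not NaN
            if not 0.0 <= self.gc_percent <= 100.0:
                raise ValueError(
                    f"genome {self.genome_id!r}: gc_percent {self.gc_percent} "
                    "outside [0, 100]"
                )


@dataclass
class Dataset:
    """Joined container: protein records plus the genome table they map into."""

    records: list[ProteinRecord] = field(default_factory=list)
    genomes: dict[str, GenomeMeta] = field(default_factory=dict)

    def validate_join(self) -> None:
        """Every record's genome_id must resolve to a GenomeMeta entry."""
        missing = sorted(
            {r.genome_id for r in self.records} - set(self.genomes)
        )
        if missing:
            raise KeyError(
                f"records reference unknown genome ids: {', '.join(missing)}"
            )

    def subset_genomes(self, keep: Iterable[str]) -> "Dataset":
        keep_set = set(keep)
        return Dataset(
            records=[r for r in self.records if r.genome_id in keep_set],
            genomes={g: m for g, m in self.genomes.items() if g in keep_set},
        )


def _parse_header(header: str) -> tuple[str, str]:
    parts = header.split("|")
    record_id = parts[0].strip()
    genome_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else record_id
    return record_id, genome_id


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA; headers are ``record_id`` or ``record_id|genome_id``.

    Sequences are uppercased and a single terminal stop ``*`` is stripped.
    Letters outside the 20-amino-acid alphabet plus X are rejected with the
    record and 1-based position. Duplicate record ids and empty files are
    errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        record_id, genome_id = _parse_header(rec.description)
        if record_id in seen:
            raise FastaFormatError(f"duplicate record id {record_id!r}")
        seen.add(record_id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FastaFormatError(f"record {record_id!r}: empty sequence")
        for pos, ch in enumerate(seq, start=1):
            if ch not in AMINO_ALPHABET:
                raise FastaFormatError(
                    f"record {record_id!r}: illegal character {ch!r} "
                    f"at position {pos}"
                )
        records.append(
            ProteinRecord(record_id=record_id, genome_id=genome_id, sequence=seq)
        )
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as ``>record_id|genome_id`` FASTA (60-column wrap)."""
    seqrecords = [
        SeqRecord(
            Seq(r.sequence), id=f"{r.record_id}|{r.genome_id}", description=""
        )
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def _norm_enum(
    raw: object, aliases: Mapping[str, str], allowed: Sequence[str], what: str
) -> str:
    if raw is None or (isinstance(raw, float) and raw != raw):
        return "no_data"
    text = str(raw).strip().lower().replace("-", " ")
    if not text or text in {"no data", "no_data", "na", "nan", "unknown"}:
        return "no_data"
    key = text.replace(" ", "_")
    if key in allowed:
        return key
    if text in aliases:
        return aliases[text]
    logger.warning("unrecognized %s value %r mapped to no_data", what, raw)
    return "no_data"


def _norm_bool(raw: object) -> bool:
    if isinstance(raw, bool):
        return raw
    if raw is None or (isinstance(raw, float) and raw != raw):
        return False
    text = str(raw).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    logger.warning("unrecognized boolean value %r treated as False", raw)
    return False


def read_metadata(path: str | Path) -> dict[str, GenomeMeta]:
    """Read the tab-delimited genome table into GenomeMeta entries.

    Recognized columns: genome_id (mandatory), phylum, class, order, family,
    genus, species, gc_percent, oxygen_req, temp_range, environment,
    has_cog0633, is_type_strain, has_characterized_fech. Unknown category
    spellings fall back to ``no_data`` with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if "genome_id" not in df.columns:
        raise ValueError(f"metadata table {path} lacks mandatory column genome_id")
    genomes: dict[str, GenomeMeta] = {}
    for _, row in df.iterrows():
        gid = str(row["genome_id"]).strip()
        if not gid:
            raise ValueError("empty genome_id in metadata table")
        if gid in genomes:
            raise ValueError(f"duplicate genome_id {gid!r} in metadata table")

        def col(name: str, default: str = "") -> str:
            return str(row[name]).strip() if name in df.columns else default

        gc_raw = col("gc_percent")
        try:
            gc = float(gc_raw) if gc_raw else float("nan")
        except ValueError as exc:
            raise ValueError(f"genome {gid!r}: bad gc_percent {gc_raw!r}") from exc
        genomes[gid] = GenomeMeta(
            genome_id=gid,
            phylum=col("phylum"),
            class_=col("class"),
            order=col("order"),
            family=col("family"),
            genus=col("genus"),
            species=col("species"),
            gc_percent=gc,
            oxygen_req=_norm_enum(
                col("oxygen_req"), _OXYGEN_ALIASES, OXYGEN_LEVELS, "oxygen_req"
            ),
            temp_range=_norm_enum(
                col("temp_range"), _TEMP_ALIASES, TEMP_RANGES, "temp_range"
            ),
            environment=_norm_enum(col("environment"), {}, ENVIRONMENTS, "environment"),
            has_cog0633=_norm_bool(col("has_cog0633")),
            is_type_strain=_norm_bool(col("is_type_strain")),
            has_characterized_fech=_norm_bool(col("has_characterized_fech")),
        )
    return genomes


def write_metadata(genomes: Mapping[str, GenomeMeta], path: str | Path) -> None:
    """Write GenomeMeta entries as the TSV dialect read_metadata accepts."""
    rows = []
    for gid in sorted(genomes):
        m = genomes[gid]
        rows.append(
            {
                "genome_id": m.genome_id,
                "phylum": m.phylum,
                "class": m.class_,
                "order": m.order,
                "family": m.family,
                "genus": m.genus,
                "species": m.species,
                "gc_percent": f"{m.gc_percent:.1f}" if m.gc_percent == m.gc_percent else "",
                "oxygen_req": m.oxygen_req,
                "temp_range": m.temp_range,
                "environment": m.environment,
                "has_cog0633": int(m.has_cog0633),
                "is_type_strain": int(m.is_type_strain),
                "has_characterized_fech": int(m.has_characterized_fech),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _priority_key(m: GenomeMeta) -> tuple[int, int, str]:
    # Preferred genomes sort first: characterized enzyme, then type strain,
    # then lexicographically smallest genome id.
    return (
        0 if m.has_characterized_fech else 1,
        0 if m.is_type_strain else 1,
        m.genome_id,
    )


def pare_genomes(
    genomes: Sequence[GenomeMeta], per_order_cap: int = 10
) -> list[str]:
    """Down-sample genomes to control phylogenetic oversampling.

    Stage 1 keeps one genome per genus, preferring genomes with a
    characterized ferrochelatase, then type strains, then the smallest
    genome id. Stage 2 caps each order at ``per_order_cap`` genomes,
    filled round-robin over that order's families (families cycled in
    ascending name order, each family yielding its genomes by the same
    priority) so that representation is as even across families as the
    cap allows. Missing ranks act as singleton pseudo-groups.

    Returns the retained genome ids in ascending order. The sampler is a
    deterministic total order, so it is idempotent and independent of the
    input ordering.
    """
    # stage 1: one per genus
    by_genus: dict[str, list[GenomeMeta]] = {}
    for m in genomes:
        genus_key = m.genus if m.genus else f"__singleton__{m.genome_id}"
        by_genus.setdefault(genus_key, []).append(m)
    genus_reps = [min(members, key=_priority_key) for members in by_genus.values()]

    # stage 2: per-order cap, round-robin over families
    by_order: dict[str, list[GenomeMeta]] = {}
    for m in genus_reps:
        order_key = m.order if m.order else f"__singleton__{m.genome_id}"
        by_order.setdefault(order_key, []).append(m)

    kept: list[str] = []
    for members in by_order.values():
        if len(members) <= per_order_cap:
            kept.extend(m.genome_id for m in members)
            continue
        families: dict[str, list[GenomeMeta]] = {}
        for m in members:
            fam_key = m.family if m.family else f"__singleton__{m.genome_id}"
            families.setdefault(fam_key, []).append(m)
        queues = {
            fam: sorted(ms, key=_priority_key) for fam, ms in families.items()
        }
        fam_cycle = sorted(queues)
        taken = 0
        while taken < per_order_cap:
            progressed = False
            for fam in fam_cycle:
                if queues[fam]:
                    kept.append(queues[fam].pop(0).genome_id)
                    taken += 1
                    progressed = True
                    if taken >= per_order_cap:
                        break
            if not progressed:
                break
    return sorted(kept)


def apply_trim_spans(
    records: Sequence[ProteinRecord], spans: Mapping[str, tuple[int, int]]
) -> list[ProteinRecord]:
    """Attach trim spans (by record id) to records; unknown ids are errors."""
    unknown = set(spans) - {r.record_id for r in records}
    if unknown:
        raise KeyError(f"trim spans reference unknown records: {sorted(unknown)}")
    return [
        replace(r, trim_span=spans[r.record_id]) if r.record_id in spans else r
        for r in records
    ]
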