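"""Labeled synthetic ferrochelatase cohorts with exact ground truth.

The generator emits FASTA + metadata TSV datasets that emulate the
structure of a curated ferrochelatase survey: a conserved core derived
from a reference (catalytic His at reference position 263), an optional
N-terminal extension, an optional internal 22-34 residue insertion, an
optional C-terminal tail, planted CX(1,11)CX(1,11)C motifs restricted to
the insertion or the tail, background cysteines, and genome metadata with
an MCF-aerobe association. Every record carries labels (regions, motif
location, cysteine count, MCF status) that are guaranteed consistent with
the emitted sequence: background cysteine placements are rejection-
sampled so that no consensus cysteine triple exists anywhere except the
planted motif.

The cysteine/motif association is constructed so that motif presence is
exactly logistic in the total cysteine count: motif status is drawn
first (from the region-conditional motif probabilities) and the total
cysteine count is then drawn from class-conditional Poisson laws with
rate ratio exp(logistic_b1). Defaults reproduce the survey's observed
conditions: ~2.8% of records missing the catalytic His, extension /
insertion / tail frequencies of roughly 12% / 13% / 45%, motif
probability 0.95 given an insertion and 0.13 given (only) a tail, a mean
of ~4.4 cysteines per sequence and an odds ratio of 2.61 per added
cysteine.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fechsurvey.io_metadata import Dataset, GenomeMeta, ProteinRecord
from fechsurvey.reference_mapping import (
    ReferenceProfile,
    annotate_regions,
    global_align,
    his_status_from_alignment,
)

# 19 letters: the 20 canonical amino acids minus cysteine, so that all
# cysteines in generated sequences are placed deliberately.
_NON_CYS = "ADEFGHIKLMNPQRSTVWY"

_REFERENCE_SEED = 202_263  # fixed: the reference is a constant, not per-dataset

_MIN_MOTIF_FOOTPRINT = 5  # C X C X C with single-residue spacers

_MAX_CONTENT_TRIES = 50


def _labels_recoverable(
    seq: str,
    ref: ReferenceProfile,
    has_his: bool,
    n_ext_span: tuple[int, int] | None,
    ins_spans: tuple[tuple[int, int], ...],
    tail_span: tuple[int, int] | None,
    motif_location: str,
    motif_abs: tuple[int, ...],
) -> bool:
    """Check that alignment-based annotation recovers the planted labels.

    Uses the package's own reference alignment at the default region
    thresholds: His status must agree, region presence flags must match,
    and planted motif cysteines must fall inside the annotated qualifying
    region. Exact span boundaries may wobble by a residue or two with
    alignment gap placement; presence and motif containment are what the
    labels guarantee.
    """
    aln = global_align(seq, ref.sequence)
    his_ok, _, _ = his_status_from_alignment(aln, ref)
    if his_ok != has_his:
        return False
    if not has_his:
        return True  # dropped before region annotation downstream
    regions = annotate_regions(aln, ref)
    if (regions.n_ext is not None) != (n_ext_span is not None):
        return False
    if len(regions.insertions) != len(ins_spans):
        return False
    if (regions.c_tail is not None) != (tail_span is not None):
        return False
    if motif_location == "insertion":
        return any(
            all(lo <= p <= hi for p in motif_abs) for lo, hi in regions.insertions
        )
    if motif_location == "c_terminal":
        lo, hi = regions.c_tail
        return all(lo <= p <= hi for p in motif_abs)
    return True


def make_synthetic_reference() -> ReferenceProfile:
    """Deterministic synthetic stand-in for the human reference ferrochelatase.

    A real reference sequence is not bundled; this synthetic profile has
    the same shape: a targeting-sequence prefix (1-62), a conserved core
    span of 63-423 with the catalytic histidine at position 263, and a
    C-terminal extension beyond the core (424-453) so that query tails
    have reference context to align against. The sequence is
    cysteine-free so cohort cysteine counts are fully controlled by the
    generator.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    letters = rng.choice(list(_NON_CYS), size=453)
    seq = "".join(letters)
    seq = seq[:262] + "H" + seq[263:]
    return ReferenceProfile(sequence=seq, catalytic_his_pos=263, core_span=(63, 423))


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generation parameters (defaults = the survey's conditions)."""

    n_records: int = 500
    seed: int = 1
    # curation
    p_drop_his: float = 14 / 497
    # region frequencies
    p_n_ext: float = 56 / 482
    p_insertion: float = 63 / 482
    p_ctail: float = 215 / 482
    n_ext_length_range: tuple[int, int] = (20, 60)
    insertion_length_range: tuple[int, int] = (22, 34)
    ctail_length_range: tuple[int, int] = (15, 60)
    # motif model
    p_motif_given_insertion: float = 60 / 63
    p_motif_given_ctail: float = 29 / 215
    p_xccx: float = 0.5
    # cysteine model: lambda0 = background_cys_rate * core length;
    # lambda1 = lambda0 * exp(logistic_b1)
    background_cys_rate: float = 3.4 / 361
    logistic_b1: float = math.log(2.61)
    # sequence divergence
    mutation_rate: float = 0.03
    lineage_divergence: float = 0.12
    # C-terminal character of motif-free tails
    p_his_rich_tail: float = 0.05
    p_exxnxr_tail: float = 0.05
    # metadata associations
    p_aerobic_given_mcf: float = 0.72
    p_aerobic_given_nonmcf: float = 0.44
    p_cog0633: float = 273 / 414
    # duplicate-ferrochelatase genomes (second, motif-free copy)
    duplicate_fraction: float = 0.0
    max_rejection_tries: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "p_drop_his", "p_n_ext", "p_insertion", "p_ctail",
            "p_motif_given_insertion", "p_motif_given_ctail", "p_xccx",
            "p_his_rich_tail", "p_exxnxr_tail", "p_aerobic_given_mcf",
            "p_aerobic_given_nonmcf", "p_cog0633", "duplicate_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.insertion_length_range
        if not (15 <= lo <= hi <= 60):
            raise ValueError("insertion_length_range must lie within [15, 60]")
        if self.n_records < 1:
            raise ValueError("n_records must be positive")

    @property
    def implied_logistic_b0(self) -> float:
        """Intercept implied by the mixture construction.

        With motif prevalence pi and class-conditional Poisson rates
        (lam0, lam1 = lam0 e^{b1}), Bayes' rule gives a logistic
        P(motif|x) with slope b1 and intercept
        ln(pi/(1-pi)) - (lam1 - lam0).
        """
        pi = (
            self.p_insertion * self.p_motif_given_insertion
            + (1 - self.p_insertion) * self.p_ctail * self.p_motif_given_ctail
        )
        lam0 = self.background_cys_rate * 361
        lam1 = lam0 * math.exp(self.logistic_b1)
        return math.log(pi / (1 - pi)) - (lam1 - lam0)


@dataclass
class RecordTruth:
    """Ground-truth labels for one generated record."""

    record_id: str
    genome_id: str
    has_his: bool
    n_ext: tuple[int, int] | None
    insertions: tuple[tuple[int, int], ...]
    c_tail: tuple[int, int] | None
    motif_location: str  # none | insertion | c_terminal
    motif_positions: tuple[int, ...]
    cys_count: int
    is_mcf: bool
    clade: str  # insertion_lineage | base


@dataclass
class TruthLabels:
    """Per-record and per-genome ground truth for a generated cohort."""

    records: dict[str, RecordTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            rid: dataclasses.asdict(t) for rid, t in sorted(self.records.items())
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=list))

    @property
    def n_mcf(self) -> int:
        return sum(t.is_mcf for t in self.records.values())


def plant_motif(
    span: str, rng: np.random.Generator, xccx: bool = False, margin: int = 2
) -> tuple[str, tuple[int, ...]]:
    """Write one consensus motif instance into a region sequence.

    Plants three cysteines C X(s1) C X(s2) C with spacers drawn uniformly
    from [1, 11] (clipped to fit), at a uniform offset keeping ``margin``
    residues clear of both region edges. With ``xccx`` a fourth cysteine
    is planted adjacent to the second, realizing the XCCX arrangement of
    all four coordinating cysteines. Returns the modified region and the
    1-based cysteine positions within it.
    """
    n = len(span)
    extra = 1 if xccx else 0
    if n < _MIN_MOTIF_FOOTPRINT + extra + 2 * margin:
        raise ValueError(f"region of length {n} too short for a motif")
    budget = n - 2 * margin - (3 + extra)  # residues available for spacers
    hi1 = min(11, budget - 1)
    s1 = int(rng.integers(1, hi1 + 1))
    hi2 = min(11 - extra, budget - s1)
    s2 = int(rng.integers(1, hi2 + 1))
    footprint = 3 + extra + s1 + s2
    offset = int(rng.integers(margin, n - footprint - margin + 1))
    positions = [offset + 1, offset + 1 + s1 + 1]
    if xccx:
        positions.append(positions[-1] + 1)
    positions.append(positions[-1] + s2 + 1)
    chars = list(span)
    for p in positions:
        chars[p - 1] = "C"
    return "".join(chars), tuple(positions)


def _mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protect: frozenset[int] = frozenset(),
) -> str:
    """Point-mutate within the cysteine-free alphabet; 0-based protect set."""
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        if int(i) in protect:
            continue
        choices = [a for a in _NON_CYS if a != chars[i]]
        chars[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


# extensions, insertions and tails are disordered segments; their
# composition is biased toward loop-forming residues (G/S/P/E/K/N/D/T/A),
# as in real low-complexity extensions
_LOOP_POOL = list("GGGSSSPPPEEEKKKNNDDTTAAQRHLIVFMWY")


def _random_seq(n: int, rng: np.random.Generator, style: str = "loop") -> str:
    if style == "his_rich":
        # cyanobacterial-style His-rich tail: ~40% histidine
        pool = list(_NON_CYS) + ["H"] * 12
    elif style == "loop":
        pool = _LOOP_POOL
    else:
        pool = list(_NON_CYS)
    idx = rng.integers(0, len(pool), size=n)
    return "".join(pool[int(i)] for i in idx)


def _consensus_triples(c_positions: list[int]) -> list[tuple[int, int, int]]:
    """All CX(1,11)CX(1,11)C literal triples among cysteine positions."""
    out = []
    cs = sorted(c_positions)
    for i, a in enumerate(cs):
        for j in range(i + 1, len(cs)):
            b = cs[j]
            if not 1 <= b - a - 1 <= 11:
                continue
            for k in range(j + 1, len(cs)):
                c = cs[k]
                if 1 <= c - b - 1 <= 11:
                    out.append((a, b, c))
    return out


# metadata category splits (survey censuses), conditional on MCF status
_AERO_SPLIT = {True: (14 / 63, 49 / 63), False: (18 / 150, 132 / 150)}
_NONAERO_LEVELS = (
    "microaerophilic", "facultative", "anaerobic", "strictly_anaerobic", "no_data"
)
_NONAERO_SPLIT = {
    True: (4 / 25, 4 / 25, 3 / 25, 4 / 25, 10 / 25),
    False: (16 / 176, 51 / 176, 54 / 176, 5 / 176, 50 / 176),
}
_TEMP_LEVELS = (
    "psychrophile", "psychrotolerant", "mesophile", "thermophile",
    "hyperthermophile", "no_data",
)
_TEMP_SPLIT = {
    True: (3 / 88, 2 / 88, 71 / 88, 4 / 88, 0.0, 8 / 88),
    False: (6 / 326, 1 / 326, 229 / 326, 45 / 326, 4 / 326, 41 / 326),
}
_ENV_LEVELS = (
    "aquatic_freshwater", "aquatic_marine", "aquatic_hot_spring",
    "aquatic_undefined", "terrestrial_soil", "terrestrial_geological",
    "host_human", "host_bovine", "host_plants", "host_other",
    "industry_acid_mine", "industry_wastewater", "industry_food",
    "industry_other", "other", "no_data",
)
_ENV_SPLIT = {
    True: tuple(
        v / 89
        for v in (18, 15, 3, 1, 23, 0, 2, 0, 3, 11, 0, 1, 1, 0, 2, 9)
    ),
    False: tuple(
        v / 325
        for v in (51, 42, 21, 9, 48, 4, 27, 6, 8, 24, 4, 6, 6, 8, 5, 56)
    ),
}
_GC_PARAMS = {  # mean, sd by (is_mcf, location)
    ("insertion"): (45.0, 7.0),
    ("c_terminal"): (56.0, 6.0),
    ("none"): (51.0, 8.0),
}


def _choice(rng: np.random.Generator, levels, probs) -> str:
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return str(levels[int(rng.choice(len(levels), p=p))])


def generate_dataset(
    config: GeneratorConfig | None = None,
    reference: ReferenceProfile | None = None,
) -> tuple[Dataset, TruthLabels, ReferenceProfile]:
    """Generate a labeled cohort; deterministic given ``config.seed``.

    Returns the dataset (records + genome metadata), the ground-truth
    labels and the reference profile the cohort was derived from.
    """
    config = config or GeneratorConfig()
    ref = reference or make_synthetic_reference()
    rng = np.random.default_rng(config.seed)

    core_lo, core_hi = ref.core_span
    base_core = ref.sequence[core_lo - 1 : core_hi]
    core_his_idx = ref.catalytic_his_pos - core_lo  # 0-based within core
    # protect the catalytic His and the outermost core residues; the
    # latter anchor the core/extension boundaries in the alignment
    n_core = len(base_core)
    protected = frozenset({core_his_idx, 0, 1, n_core - 2, n_core - 1})
    # a shared divergent lineage provides the insertion-bearing clade
    lineage_core = _mutate(
        base_core, config.lineage_divergence, rng, protect=protected
    )
    lam0 = config.background_cys_rate * len(base_core)
    lam1 = lam0 * math.exp(config.logistic_b1)

    dataset = Dataset()
    truth = TruthLabels()

    for i in range(config.n_records):
        genome_id = f"g{i:04d}"
        record_id = f"r{i:04d}"
        rec, rt = _generate_record(
            record_id, genome_id, config, rng, ref,
            base_core, lineage_core, core_his_idx, lam0, lam1,
        )
        dataset.records.append(rec)
        truth.records[record_id] = rt
        if config.duplicate_fraction > 0 and rng.random() < config.duplicate_fraction:
            dup_id = f"r{i:04d}b"
            dup, dup_rt = _generate_record(
                dup_id, genome_id, config, rng, ref,
                base_core, lineage_core, core_his_idx, lam0, lam1,
                force_no_motif=True,
            )
            dataset.records.append(dup)
            truth.records[dup_id] = dup_rt

        genome_mcf = rt.is_mcf
        dataset.genomes[genome_id] = _generate_genome(
            genome_id, i, genome_mcf, rt.motif_location, rt.clade, config, rng
        )

    dataset.validate_join()
    return dataset, truth, ref


def _generate_record(
    record_id: str,
    genome_id: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    ref: ReferenceProfile,
    base_core: str,
    lineage_core: str,
    core_his_idx: int,
    lam0: float,
    lam1: float,
    force_no_motif: bool = False,
) -> tuple[ProteinRecord, RecordTruth]:
    # region presence
    has_insertion = rng.random() < config.p_insertion
    has_tail = rng.random() < config.p_ctail
    has_next = rng.random() < config.p_n_ext

    # motif decision, conditional on regions
    if force_no_motif:
        motif_location = "none"
    elif has_insertion and rng.random() < config.p_motif_given_insertion:
        motif_location = "insertion"
    elif (not has_insertion) and has_tail and rng.random() < config.p_motif_given_ctail:
        motif_location = "c_terminal"
    else:
        motif_location = "none"
    is_mcf = motif_location != "none"
    xccx = is_mcf and rng.random() < config.p_xccx

    # total cysteine count: class-conditional Poisson (rate ratio e^b1)
    n_planted = (4 if xccx else 3) if is_mcf else 0
    lam = lam1 if is_mcf else lam0
    cys_total = int(rng.poisson(lam))
    while cys_total < n_planted:
        cys_total = int(rng.poisson(lam))

    has_his = rng.random() >= config.p_drop_his
    clade = "insertion_lineage" if has_insertion else "base"
    n_core = len(base_core)
    protected = frozenset(
        {core_his_idx, 0, 1, 2, n_core - 3, n_core - 2, n_core - 1}
    )

    # structural draws (lengths, insertion point) are fixed once; the
    # random content (core point mutations, segment sequences) is redrawn
    # until the emitted sequence maps back onto the labels through the
    # package's own reference alignment
    next_len = int(rng.integers(*config.n_ext_length_range)) if has_next else 0
    ins_len = (
        int(
            rng.integers(
                config.insertion_length_range[0],
                config.insertion_length_range[1] + 1,
            )
        )
        if has_insertion
        else 0
    )
    if has_tail:
        t_lo, t_hi = config.ctail_length_range
        if motif_location == "c_terminal":
            t_lo = max(t_lo, 30)  # room for the widest motif plus margins
        tail_len = int(rng.integers(t_lo, t_hi + 1))
        his_rich = (
            motif_location != "c_terminal"
            and rng.random() < config.p_his_rich_tail
        )
        want_exxnxr = (
            motif_location != "c_terminal"
            and rng.random() < config.p_exxnxr_tail
            and tail_len >= 8
        )
    else:
        tail_len = 0
        his_rich = False
        want_exxnxr = False
    if has_insertion:
        # insertion point: core interior, away from edges and the His site
        while True:
            cut = int(rng.integers(40, n_core - 40))
            if abs(cut - core_his_idx) > 8:
                break
    else:
        cut = 0

    for _ in range(_MAX_CONTENT_TRIES):
        core_seq = _mutate(
            lineage_core if has_insertion else base_core,
            config.mutation_rate,
            rng,
            protect=protected,
        )
        if not has_his:
            repl = "L" if core_seq[core_his_idx] != "L" else "V"
            core_seq = (
                core_seq[:core_his_idx] + repl + core_seq[core_his_idx + 1 :]
            )
        n_ext_seq = _random_seq(next_len, rng)
        insertion_seq = _random_seq(ins_len, rng)
        tail_seq = _random_seq(
            tail_len, rng, style="his_rich" if his_rich else "loop"
        )
        if want_exxnxr:
            # CAB-domain style EXXNXR near the tail end
            o = tail_len - 8
            tail_seq = (
                tail_seq[:o] + "E" + tail_seq[o + 1 : o + 3] + "N"
                + tail_seq[o + 4] + "R" + tail_seq[o + 6 :]
            )

        motif_rel: tuple[int, ...] = ()
        if motif_location == "insertion":
            insertion_seq, motif_rel = plant_motif(insertion_seq, rng, xccx=xccx)
        elif motif_location == "c_terminal":
            tail_seq, motif_rel = plant_motif(tail_seq, rng, xccx=xccx)

        core_with_ins = (
            core_seq[:cut] + insertion_seq + core_seq[cut:]
            if has_insertion
            else core_seq
        )
        a = len(n_ext_seq)
        seq = n_ext_seq + core_with_ins + tail_seq
        n_ext_span = (1, a) if a else None
        ins_spans: tuple[tuple[int, int], ...] = ()
        if has_insertion:
            ins_spans = ((a + cut + 1, a + cut + len(insertion_seq)),)
        tail_span = (a + len(core_with_ins) + 1, len(seq)) if tail_seq else None
        his_pos_final = (
            a + core_his_idx + 1
            + (len(insertion_seq) if has_insertion and cut <= core_his_idx else 0)
        )

        if motif_location == "insertion":
            motif_abs = tuple(p + ins_spans[0][0] - 1 for p in motif_rel)
        elif motif_location == "c_terminal":
            motif_abs = tuple(p + tail_span[0] - 1 for p in motif_rel)
        else:
            motif_abs = ()

        # background cysteines, rejection-sampled so the planted motif is
        # the only consensus triple anywhere in the sequence
        n_bg = cys_total - n_planted
        planted = set(motif_abs)
        forbidden = planted | {his_pos_final}
        candidates = [p for p in range(1, len(seq) + 1) if p not in forbidden]
        placed: list[int] | None = None
        for _try in range(config.max_rejection_tries):
            trial = sorted(
                int(p) for p in rng.choice(candidates, size=n_bg, replace=False)
            )
            all_c = sorted(planted | set(trial))
            if all(set(t) <= planted for t in _consensus_triples(all_c)):
                placed = trial
                break
        if placed is None:
            raise RuntimeError(
                f"{record_id}: could not place {n_bg} background cysteines "
                f"without accidental motifs in {config.max_rejection_tries} tries"
            )
        chars = list(seq)
        for p in placed:
            chars[p - 1] = "C"
        seq = "".join(chars)

        assert seq.count("C") == cys_total
        assert (seq[his_pos_final - 1] == "H") == has_his
        if _labels_recoverable(
            seq, ref, has_his, n_ext_span, ins_spans, tail_span,
            motif_location, motif_abs,
        ):
            break
    else:
        raise RuntimeError(
            f"{record_id}: no label-consistent segment content found in "
            f"{_MAX_CONTENT_TRIES} tries"
        )

    rec = ProteinRecord(record_id=record_id, genome_id=genome_id, sequence=seq)
    rt = RecordTruth(
        record_id=record_id,
        genome_id=genome_id,
        has_his=has_his,
        n_ext=n_ext_span,
        insertions=ins_spans,
        c_tail=tail_span,
        motif_location=motif_location,
        motif_positions=motif_abs,
        cys_count=cys_total,
        is_mcf=is_mcf,
        clade=clade,
    )
    return rec, rt


def _generate_genome(
    genome_id: str,
    index: int,
    is_mcf: bool,
    motif_location: str,
    clade: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> GenomeMeta:
    p_aero = config.p_aerobic_given_mcf if is_mcf else config.p_aerobic_given_nonmcf
    if rng.random() < p_aero:
        strict_frac, _ = _AERO_SPLIT[is_mcf]
        oxygen = "strictly_aerobic" if rng.random() < strict_frac else "aerobic"
    else:
        oxygen = _choice(rng, _NONAERO_LEVELS, _NONAERO_SPLIT[is_mcf])
    temp = _choice(rng, _TEMP_LEVELS, _TEMP_SPLIT[is_mcf])
    env = _choice(rng, _ENV_LEVELS, _ENV_SPLIT[is_mcf])
    gc_mean, gc_sd = _GC_PARAMS[motif_location if is_mcf else "none"]
    gc = float(np.clip(rng.normal(gc_mean, gc_sd), 20.0, 80.0))
    phylum = "Insertia" if clade == "insertion_lineage" else f"Phylum{index % 6:02d}"
    return GenomeMeta(
        genome_id=genome_id,
        phylum=phylum,
        class_=f"class{index % 12:02d}",
        order=f"order{index % 25:02d}",
        family=f"fam{index % 60:02d}",
        genus=f"genus{index:04d}",
        species=f"species {index:04d}",
        gc_percent=round(gc, 1),
        oxygen_req=oxygen,
        temp_range=temp,
        environment=env,
        has_cog0633=bool(rng.random() < config.p_cog0633),
        is_type_strain=bool(rng.random() < 0.5),
        has_characterized_fech=bool(rng.random() < 0.02),
    )
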