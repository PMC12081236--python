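"""Fixture and simulation generators.

Everything here is deterministic under a seed and emits plain-text formats
(FASTA/GTF/VCF/evidence TSV), so every other module is testable with no
downloads:

* sampled transcripts whose exons satisfy the splicing checklist (motifs
  drawn from the bundled consensus frequency tables);
* a hand-designed fixture transcript whose five introns reach every
  narrated heuristic subgroup;
* targeted variant panels (the inverse of classification: an SNV built to
  route to a requested subgroup);
* labeled evidence tables with per-subgroup Bernoulli labels and
  multi-label outcomes with known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from heurosplice import site_strength
from heurosplice.evidence import (
    LabeledVariantTable,
    NORMAL,
    SPLICE_ALTERING,
    region_for_relpos,
)
from heurosplice.heuristics import (
    RuleTable,
    SubgroupAssignment,
    classify_snv,
    default_rule_table,
)
from heurosplice.transcript_model import (
    TranscriptModel,
    VariantRecord,
    extract_splice_context,
    fetch_sequence,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"

DEFAULT_OUTCOME_MAP = {
    "exon_skipping": 0.513,
    "exon_truncation": 0.363,
    "intron_retention": 0.174,
    "exon_extension": 0.162,
}
DEFAULT_MULTI_OUTCOME_RATE = 0.191


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the fixture generator; same seed => byte-identical output."""

    seed: int = 0
    n_transcripts: int = 1
    exon_count: Tuple[int, int] = (3, 5)
    intron_length: Tuple[int, int] = (120, 400)
    first_exon_length: Tuple[int, int] = (60, 150)
    internal_exon_length: Tuple[int, int] = (80, 200)
    last_exon_length: Tuple[int, int] = (150, 300)
    flank: int = 150
    strand: Optional[str] = None  # None -> random per transcript
    degenerate: bool = False  # uniform sampling; produces checklist failures
    ppt_pyrimidine_prob: float = 0.85
    spliceogenicity_map: Optional[Mapping[str, float]] = None  # fractions
    outcome_map: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_MAP))
    multi_outcome_rate: float = DEFAULT_MULTI_OUTCOME_RATE

    def __post_init__(self) -> None:
        if self.intron_length[0] < 60:
            raise ValueError("introns shorter than 60 nt cannot host the "
                             "donor and acceptor windows")
        for lo, hi in (self.exon_count, self.intron_length,
                       self.first_exon_length, self.internal_exon_length,
                       self.last_exon_length):
            if hi < lo:
                raise ValueError("infeasible length range")
        for p in self.outcome_map.values():
            if not 0 <= p <= 1:
                raise ValueError("outcome probabilities must be in [0,1]")


@dataclass
class GeneratedData:
    genome: Dict[str, str]
    transcripts: List[TranscriptModel]
    truth: Dict[str, dict]  # per transcript: planted features


# ---------------------------------------------------------------------------
# Sampled checklist-compliant transcripts
# ---------------------------------------------------------------------------


def _choice(rng: np.random.Generator, freqs: Mapping[str, float]) -> str:
    p = np.array([freqs[b] for b in _BASES], dtype=float)
    return _BASES[rng.choice(4, p=p / p.sum())]


def _uniform_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _pyrimidine(rng: np.random.Generator) -> str:
    return "CT"[rng.integers(0, 2)]


def _sample_acceptor_region(rng: np.random.Generator,
                            cfg: GeneratorConfig) -> Tuple[str, dict]:
    """A 50-nt -50..-1 region with planted branchpoint, PPT and clean
    AG-exclusion zone (unless degenerate)."""
    if cfg.degenerate:
        return _uniform_seq(rng, 50), {}
    region = list(_uniform_seq(rng, 50))
    # pyrimidine bias upstream of the PPT
    for i in range(0, 26):  # -50..-25
        if rng.random() < 0.6:
            region[i] = _pyrimidine(rng)
    bp_distance = int(rng.integers(19, 41))  # A at -bp_distance
    a_idx = 50 - bp_distance
    region[a_idx - 2] = "T"
    region[a_idx] = "A"
    for i in range(26, 46):  # -24..-5
        if i == a_idx or i == a_idx - 2:
            continue
        if rng.random() < cfg.ppt_pyrimidine_prob:
            region[i] = _pyrimidine(rng)
    freqs = site_strength.pwm_frequencies(site_strength.ACCEPTOR)
    region[46] = _choice(rng, freqs[16])  # -4
    region[47] = _pyrimidine(rng) if rng.random() < 0.95 else "A"  # -3
    region[48] = "A"
    region[49] = "G"
    # scrub AG dinucleotides whose A falls in the exclusion zone -13..-6
    for k in range(13, 5, -1):
        i = 50 - k
        if region[i] == "A" and region[i + 1] == "G":
            region[i + 1] = _pyrimidine(rng)
    return "".join(region), {"branchpoint_distance": bp_distance}


def _sample_donor_intron_start(rng: np.random.Generator,
                               cfg: GeneratorConfig) -> str:
    """The +1..+6 bases of an intron."""
    freqs = site_strength.pwm_frequencies(site_strength.DONOR)
    if cfg.degenerate:
        return _uniform_seq(rng, 6)
    return "GT" + "".join(_choice(rng, freqs[i]) for i in range(5, 9))


def _sample_exon(rng: np.random.Generator, cfg: GeneratorConfig, length: int,
                 category: str) -> str:
    donor_freqs = site_strength.pwm_frequencies(site_strength.DONOR)
    acc_freqs = site_strength.pwm_frequencies(site_strength.ACCEPTOR)
    if cfg.degenerate:
        return _uniform_seq(rng, length)
    middle = _uniform_seq(rng, length)
    start = end = ""
    if category != "first":
        start = "".join(_choice(rng, acc_freqs[i]) for i in (20, 21, 22))
    if category != "last":
        end = "".join(_choice(rng, donor_freqs[i]) for i in (0, 1, 2))
    core = middle[len(start):len(middle) - len(end)]
    return start + core + end


def generate_compliant_transcript(config: GeneratorConfig,
                                  rng: Optional[np.random.Generator] = None,
                                  transcript_index: int = 0,
                                  ) -> Tuple[TranscriptModel, str, str, dict]:
    """One sampled transcript on its own contig.

    Returns (transcript, contig_name, contig_sequence, planted truth).
    Generated exons satisfy the manual checklist with high probability:
    donor/acceptor dinucleotides, branchpoints, and PPTs are planted, the
    AG-exclusion zone is scrubbed, and lengths respect the minima.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_exons = int(rng.integers(config.exon_count[0], config.exon_count[1] + 1))
    strand = config.strand or ("+" if rng.random() < 0.5 else "-")
    contig = f"synth{transcript_index + 1}"

    parts: List[str] = [_uniform_seq(rng, config.flank)]
    offset = config.flank
    exon_intervals: List[Tuple[int, int]] = []  # sense-block coordinates
    truth: dict = {"introns": [], "strand": strand}

    for i in range(n_exons):
        if i == 0:
            lo, hi = config.first_exon_length
            cat = "first"
        elif i == n_exons - 1:
            lo, hi = config.last_exon_length
            cat = "last"
        else:
            lo, hi = config.internal_exon_length
            cat = "internal"
        length = int(rng.integers(lo, hi + 1))
        parts.append(_sample_exon(rng, config, length, cat))
        exon_intervals.append((offset, offset + length))
        offset += length
        if i < n_exons - 1:
            ilen = int(rng.integers(config.intron_length[0],
                                    config.intron_length[1] + 1))
            donor6 = _sample_donor_intron_start(rng, config)
            acceptor50, planted = _sample_acceptor_region(rng, config)
            middle = _uniform_seq(rng, ilen - 56)
            parts.append(donor6 + middle + acceptor50)
            truth["introns"].append({"length": ilen, **planted})
            offset += ilen
    parts.append(_uniform_seq(rng, config.flank))
    block = "".join(parts)

    if strand == "+":
        seq = block
        genomic = exon_intervals
    else:
        seq = reverse_complement(block)
        L = len(block)
        genomic = [(L - e, L - s) for s, e in exon_intervals]
    tx = TranscriptModel(
        transcript_id=f"SYNT{transcript_index + 1:04d}",
        gene_id=f"SYNG{transcript_index + 1:04d}",
        chrom=contig, strand=strand, exons=tuple(genomic))
    return tx, contig, seq, truth


def generate_genome(config: GeneratorConfig) -> GeneratedData:
    """A set of sampled transcripts, one contig each."""
    rng = np.random.default_rng(config.seed)
    genome: Dict[str, str] = {}
    transcripts: List[TranscriptModel] = []
    truth: Dict[str, dict] = {}
    for i in range(config.n_transcripts):
        tx, contig, seq, planted = generate_compliant_transcript(
            config, rng, transcript_index=i)
        genome[contig] = seq
        transcripts.append(tx)
        truth[tx.transcript_id] = planted
    return GeneratedData(genome=genome, transcripts=transcripts, truth=truth)


# ---------------------------------------------------------------------------
# The designed fixture: every narrated subgroup reachable, by construction
# ---------------------------------------------------------------------------

_ACC_SIMPLE = ("TCTCTCTCTCTCTCTCTC" "TGA" "TCTTC"
               "TTCTTTACTTC" "TTCCGTTCC" "TCAG")
_ACC_STRONG = ("TCTCTCTCTCTCTCTCTC" "TGA" "TCTTC"
               "TTTTTTTTTTT" "TTTCTTTCC" "TCAG")
_ACC_WEAK = ("TCTCTCTCTCTCTCTCTC" "TGA" "TCTTC"
             "TCTATCTTATA" "TTCATTTCC" "AAAG")
_ACC_NOBP = ("TCTCTCTCTCTCTCTCTCTCTCTCTC"
             "TTATACTTCTT" "TTCCTTTCC" "TCAG")

_INTRON_MIDDLE = "CT" * 32  # 64 nt, free of A/G: no stray AG or branchpoints


def _designed_exon(length: int, start: str, end: str) -> str:
    filler = ("GCCACCTTCA" * 40)[:length - len(start) - len(end)]
    return start + filler + end


def designed_fixture() -> Tuple[Dict[str, str], TranscriptModel, dict]:
    """A deterministic six-exon + strand transcript whose introns reach
    every narrated heuristic subgroup.

    intron 1: GT donor with E-1=G; acceptor with an AG-creation site in the
    exclusion zone (-10 C / -9 G) and one 14 nt upstream (-18 A / -17 C).
    intron 2: GT donor with E-1=C, +3=A; strong-PPT acceptor.
    intron 3: GT donor with E-1=A, +3=C/+4=A; weak-PPT acceptor with a
    purine at -3. intron 4: GT donor with +5=A. intron 5: GC donor.
    """
    exons = [
        _designed_exon(60, "ATG", "CAG"),
        _designed_exon(90, "G", "CAC"),
        _designed_exon(90, "G", "CAA"),
        _designed_exon(90, "G", "CAG"),
        _designed_exon(90, "G", "CTG"),
        _designed_exon(150, "G", ""),
    ]
    donors = ["GTAAGT", "GTAAGT", "GTCAGT", "GTAAAT", "GCAAGT"]
    acceptors = [_ACC_SIMPLE, _ACC_STRONG, _ACC_WEAK, _ACC_NOBP, _ACC_SIMPLE]
    for acc in acceptors:
        assert len(acc) == 50

    flank = "TACG" * 25
    parts = [flank]
    offset = len(flank)
    intervals = []
    for i, exon in enumerate(exons):
        parts.append(exon)
        intervals.append((offset, offset + len(exon)))
        offset += len(exon)
        if i < len(donors):
            intron = donors[i] + _INTRON_MIDDLE + acceptors[i]
            parts.append(intron)
            offset += len(intron)
    parts.append(flank)
    seq = "".join(parts)
    tx = TranscriptModel(
        transcript_id="DESIGN1", gene_id="DGENE1", chrom="chrD",
        strand="+", exons=tuple(intervals))
    info = {
        "introns": [
            {"donor": d, "acceptor": a} for d, a in zip(donors, acceptors)
        ],
    }
    return {"chrD": seq}, tx, info


def mirror_fixture(genome: Dict[str, str], tx: TranscriptModel,
                   ) -> Tuple[Dict[str, str], TranscriptModel]:
    """Reverse-complement mirror of a single-contig fixture: the same
    transcript on the opposite strand."""
    seq = genome[tx.chrom]
    L = len(seq)
    new_strand = "-" if tx.strand == "+" else "+"
    new_exons = tuple((L - e, L - s) for s, e in tx.exons)
    mirrored = TranscriptModel(
        transcript_id=tx.transcript_id, gene_id=tx.gene_id, chrom=tx.chrom,
        strand=new_strand, exons=new_exons,
        intron_classes=tx.intron_classes)
    return {tx.chrom: reverse_complement(seq)}, mirrored


def mirror_variant(variant: VariantRecord, contig_length: int,
                   ) -> VariantRecord:
    """The same edit expressed on the mirrored contig."""
    end0 = variant.pos - 1 + len(variant.ref)
    new_pos0 = contig_length - end0
    return VariantRecord(
        chrom=variant.chrom, pos=new_pos0 + 1,
        ref=reverse_complement(variant.ref),
        alt=reverse_complement(variant.alt),
        variant_id=variant.variant_id)


# ---------------------------------------------------------------------------
# Targeted variant panels
# ---------------------------------------------------------------------------


def enumerate_window_snvs(transcript: TranscriptModel, genome,
                          ) -> Iterator[VariantRecord]:
    """Every possible SNV at every position routed to the disruption
    heuristics, across all introns of a transcript."""
    seen = set()
    for i in range(transcript.n_introns):
        ctx = extract_splice_context(transcript, i, genome)
        positions = []
        if transcript.strand == "+":
            d0 = ctx.donor_boundary
            positions += [d0 - 3, d0 - 2, d0 - 1]          # E-3..E-1
            positions += [d0 + k for k in range(6)]        # +1..+6
            a0 = ctx.acceptor_boundary
            positions += [a0 - k for k in range(50)]       # -50..-1
            positions += [a0 + 1]                          # E+1
        else:
            d0 = ctx.donor_boundary
            positions += [d0 + 3, d0 + 2, d0 + 1]
            positions += [d0 - k for k in range(6)]
            a0 = ctx.acceptor_boundary
            positions += [a0 + k for k in range(50)]
            positions += [a0 - 1]
        for g0 in positions:
            if g0 in seen or g0 < 0:
                continue
            seen.add(g0)
            ref = fetch_sequence(genome, transcript.chrom, g0, g0 + 1)
            if ref not in _BASES:
                continue
            for alt in _BASES:
                if alt != ref:
                    yield VariantRecord(chrom=transcript.chrom, pos=g0 + 1,
                                        ref=ref, alt=alt)


def generate_variant_panel(transcripts, genome,
                           targets: Iterable[str],
                           rule_table: Optional[RuleTable] = None,
                           ) -> Tuple[Dict[str, Tuple[VariantRecord,
                                                      SubgroupAssignment]],
                                      List[str]]:
    """Construct one SNV per requested ``RULE:subgroup`` target.

    Inverse of classification: candidate SNVs are enumerated across the
    heuristic windows and classified; the first hit per target is kept
    (and therefore verified by construction). Unreachable targets are
    skipped with a diagnostic.
    """
    table = rule_table or default_rule_table()
    if isinstance(transcripts, TranscriptModel):
        transcripts = [transcripts]
    wanted = list(targets)
    found: Dict[str, Tuple[VariantRecord, SubgroupAssignment]] = {}
    for tx in transcripts:
        remaining = [t for t in wanted if t not in found]
        if not remaining:
            break
        for var in enumerate_window_snvs(tx, genome):
            assignment = classify_snv(var, tx, genome, table)
            if not assignment.assigned:
                continue
            key = f"{assignment.rule_id}:{assignment.subgroup}"
            if key in remaining and key not in found:
                found[key] = (var, assignment)
                if len(found) == len(wanted):
                    break
    skipped = [t for t in wanted if t not in found]
    for t in skipped:
        logger.warning("subgroup %s unreachable on the supplied transcripts",
                       t)
    return found, skipped


# ---------------------------------------------------------------------------
# Labeled evidence tables
# ---------------------------------------------------------------------------


def default_spliceogenicity_map(rule_table: Optional[RuleTable] = None,
                                ) -> Dict[str, float]:
    """Bundled per-subgroup true spliceogenicities as fractions."""
    table = rule_table or default_rule_table()
    return {key: ann.p / 100.0 for key, ann in table.annotations.items()}


def make_outcome_sampler(outcome_map: Mapping[str, float],
                         multi_rate: float):
    """Sampler of per-SAV outcome sets.

    Each SAV reports two distinct outcomes with probability ``multi_rate``
    (drawn without replacement from the normalized marginals) and one
    otherwise; the single-outcome distribution is solved so the realized
    marginals track ``outcome_map`` closely.
    """
    names = [k for k, v in outcome_map.items() if v > 0]
    p = np.array([outcome_map[k] for k in names], dtype=float)
    q = p / p.sum()
    # exact pair-inclusion probability under weighted sampling w/o replacement
    d = np.empty_like(q)
    for i in range(len(q)):
        others = [j for j in range(len(q)) if j != i]
        d[i] = q[i] + sum(q[j] * q[i] / (1 - q[j]) for j in others)
    if multi_rate > 0 and len(names) >= 2:
        s = np.maximum(p - multi_rate * d, 0.0)
    else:
        s = p.copy()
    s = s / s.sum()

    def draw(rng: np.random.Generator) -> Tuple[str, ...]:
        if len(names) >= 2 and rng.random() < multi_rate:
            first = int(rng.choice(len(q), p=q))
            rest = np.delete(np.arange(len(q)), first)
            w = np.delete(q, first)
            second = int(rng.choice(rest, p=w / w.sum()))
            return (names[first], names[second])
        return (names[int(rng.choice(len(s), p=s))],)

    return draw


def adaptive_replicate_size(p_true: float, base_n: int,
                            information_floor: float = 10.0) -> int:
    """Replicate size guaranteeing enough information for a Wald CI.

    The normal approximation behind the Wald interval needs n*p*(1-p)
    above a floor; extreme subgroup spliceogenicities (99.9%) therefore
    get proportionally larger simulated tables.
    """
    if not 0 < p_true < 1:
        return base_n
    import math
    return max(base_n, math.ceil(information_floor / (p_true * (1 - p_true))))


def simulate_subgroup_table(subgroup: str, n: int, p_true: float,
                            rng: np.random.Generator,
                            outcome_map: Optional[Mapping[str, float]] = None,
                            multi_rate: float = DEFAULT_MULTI_OUTCOME_RATE,
                            relpos: str = "+1",
                            with_outcomes: bool = True) -> pd.DataFrame:
    """n rows with Bernoulli(p_true) labels for one subgroup.

    ``with_outcomes=False`` skips outcome sampling (vectorized; used by
    large label-only coverage simulations).
    """
    if not with_outcomes:
        labels = rng.random(n) < p_true
        return pd.DataFrame({
            "chrom": "synth1",
            "pos": np.arange(1, n + 1),
            "ref": "G",
            "alt": "A",
            "genome_build": "synthetic",
            "classification": np.where(labels, SPLICE_ALTERING, NORMAL),
            "outcomes": [()] * n,
            "method": "simulation",
            "subgroup": subgroup,
            "relative_position": relpos,
            "region": region_for_relpos(relpos),
        })
    sampler = make_outcome_sampler(outcome_map or DEFAULT_OUTCOME_MAP,
                                   multi_rate)
    labels = rng.random(n) < p_true
    rows = []
    for i, sav in enumerate(labels):
        rows.append({
            "chrom": "synth1",
            "pos": i + 1,
            "ref": "G",
            "alt": "A",
            "genome_build": "synthetic",
            "classification": SPLICE_ALTERING if sav else NORMAL,
            "outcomes": sampler(rng) if sav else (),
            "method": "simulation",
            "subgroup": subgroup,
            "relative_position": relpos,
            "region": region_for_relpos(relpos),
        })
    return pd.DataFrame(rows)


def generate_labeled_table(panel: Mapping[str, Tuple[VariantRecord,
                                                     SubgroupAssignment]],
                           config: GeneratorConfig,
                           n_per_subgroup: int = 50,
                           ) -> LabeledVariantTable:
    """A labeled evidence table over a classified variant panel.

    Each panel entry is replicated ``n_per_subgroup`` times with labels
    drawn Bernoulli(p_subgroup) from the configured (default: bundled)
    spliceogenicity map, and multi-label outcomes for the SAV rows.
    """
    rng = np.random.default_rng(config.seed)
    p_map = dict(config.spliceogenicity_map
                 or default_spliceogenicity_map())
    frames = []
    for key, (var, assignment) in sorted(panel.items()):
        p_true = p_map[key]
        df = simulate_subgroup_table(
            key, n_per_subgroup, p_true, rng,
            outcome_map=config.outcome_map,
            multi_rate=config.multi_outcome_rate,
            relpos=assignment.relative_position or "+1")
        df["chrom"] = var.chrom
        df["pos"] = var.pos
        df["ref"] = var.ref
        df["alt"] = var.alt
        frames.append(df)
    if not frames:
        raise ValueError("empty panel")
    return LabeledVariantTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Plain-text writers
# ---------------------------------------------------------------------------


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(transcripts: Iterable[TranscriptModel], path,
              canonical: bool = True) -> None:
    tag = '; tag "Ensembl_canonical"' if canonical else ""
    with open(path, "w") as fh:
        fh.write("##provider: heurosplice-synthetic\n")
        for tx in transcripts:
            lo, hi = tx.span
            attrs = (f'gene_id "{tx.gene_id}"; transcript_id '
                     f'"{tx.transcript_id}"; gene_type "protein_coding"'
                     f"{tag}")
            fh.write("\t".join([
                tx.chrom, "heurosplice", "transcript", str(lo + 1), str(hi),
                ".", tx.strand, ".", attrs + ";"]) + "\n")
            for i, (s, e) in enumerate(sorted(tx.exons)):
                fh.write("\t".join([
                    tx.chrom, "heurosplice", "exon", str(s + 1), str(e),
                    ".", tx.strand, ".",
                    attrs + f'; exon_number "{i + 1}";']) + "\n")


def write_vcf(variants: Iterable[VariantRecord], genome: Mapping[str, str],
              path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome:
            fh.write(f"##contig=<ID={name},length={len(genome[name])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t"
                     f"{v.alt}\t.\t.\t.\n")


def write_evidence_tsv(table: LabeledVariantTable, path) -> None:
    table.to_tsv(path)
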