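"""Deep-intronic variant assessment: pseudoexon mechanism attribution and
partner-splice-site search.

A deep intronic variant (outside every disruption-heuristic window) can
promote pseudoexon inclusion by creating a canonical GT/AG dinucleotide,
strengthening a pre-existing cryptic site, or producing a candidate site by
other means (PPT strengthening, AG-exclusion-zone removal). Partner sites
pairing with a created site must imply an exon of 31-750 nt and either
score at least 75% of the model maximum or, within 200 nt, at least 3 bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from heurosplice import site_strength
from heurosplice.checklist import (
    ChecklistConfig,
    DEFAULT_CONFIG,
    check_agez,
    count_ppt,
)
from heurosplice.heuristics import resolve_sites
from heurosplice.site_strength import ACCEPTOR, DONOR, ScoreModel
from heurosplice.transcript_model import (
    TranscriptModel,
    VariantRecord,
    fetch_sequence,
    map_to_relative,
    reverse_complement,
    IntergenicPositionError,
)

CREATED_DONOR_GT = "created_donor_GT"
CREATED_ACCEPTOR_AG = "created_acceptor_AG"
STRENGTHENED = "strengthened_existing_site"
NEW_CANDIDATE_OTHER = "new_candidate_other"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class PseudoexonConfig:
    min_exon_nt: int = 31
    max_exon_nt: int = 750
    strength_fraction: float = 0.75
    relax_distance_nt: int = 200
    relax_min_bits: float = 3.0
    candidate_min_bits: float = 3.0  # viability floor for cryptic sites
    strengthen_delta_bits: float = 0.1
    scan_radius_nt: int = 800


DEFAULT_PSEUDOEXON_CONFIG = PseudoexonConfig()


@dataclass(frozen=True)
class MechanismCall:
    """Why a deep intronic variant could activate a splice site."""

    category: str
    site_type: Optional[str] = None  # donor_9mer | acceptor_23mer
    site_position: Optional[int] = None  # region-local boundary index
    site_position_genomic: Optional[int] = None  # 1-based
    ref_score: Optional[float] = None
    alt_score: Optional[float] = None
    notes: tuple = ()


@dataclass(frozen=True)
class PseudoexonCandidate:
    """A (acceptor, donor) pairing implying an includable exon."""

    acceptor_pos: int  # region-local index of the first exonic base
    donor_pos: int     # region-local index of the G of the GT
    exon_length: int
    acceptor_score: Optional[float]
    donor_score: Optional[float]
    passed_filters: dict
    inclusion_interval: Tuple[int, int]  # region-local [start, end)

    def __post_init__(self) -> None:
        if not 31 <= self.exon_length <= 750:
            raise ValueError("pseudoexon candidates must imply a 31-750 nt exon")


@dataclass(frozen=True)
class PseudoexonPrediction:
    mechanism: Optional[MechanismCall]
    candidates: tuple
    top: Optional[PseudoexonCandidate]
    flags: frozenset = frozenset()
    region_start: Optional[int] = None  # genomic 0-based of region index 0
    strand: str = "+"


@dataclass(frozen=True)
class _Region:
    """A sense-strand intronic slice with its genomic anchor."""

    seq: str
    genomic_start: int  # 0-based genomic coordinate of seq[0] (+ strand)
    genomic_end: int
    strand: str
    variant_index: int  # index of the edited base (start of change)

    def to_genomic(self, idx: int) -> int:
        """1-based genomic coordinate of a region-local index."""
        if self.strand == "+":
            return self.genomic_start + idx + 1
        return self.genomic_end - idx


class NotDeepIntronicError(ValueError):
    """Variant sits inside the disruption-heuristic windows; redirect."""


def _extract_region(variant: VariantRecord, transcript: TranscriptModel,
                    genome, radius: int) -> _Region:
    mapped = map_to_relative(variant.pos, transcript)
    if not mapped.primary.is_intronic:
        raise NotDeepIntronicError("variant is exonic")
    s, e = transcript.intron_interval(mapped.intron_index)
    g0 = variant.pos - 1
    lo = max(s, g0 - radius)
    hi = min(e, g0 + radius + len(variant.ref))
    plus = fetch_sequence(genome, variant.chrom, lo, hi)
    if transcript.strand == "+":
        return _Region(seq=plus, genomic_start=lo, genomic_end=hi,
                       strand="+", variant_index=g0 - lo)
    return _Region(seq=reverse_complement(plus), genomic_start=lo,
                   genomic_end=hi, strand="-",
                   variant_index=hi - 1 - (g0 + len(variant.ref) - 1))


def _apply_to_region(region: _Region, variant: VariantRecord) -> str:
    """Alt sequence of the region (sense strand)."""
    if region.strand == "+":
        i = region.variant_index
        ref, alt = variant.ref, variant.alt
    else:
        i = region.variant_index
        ref = reverse_complement(variant.ref)
        alt = reverse_complement(variant.alt)
    if region.seq[i:i + len(ref)].upper() != ref:
        raise ValueError(
            f"region/REF mismatch at {variant.chrom}:{variant.pos}")
    return region.seq[:i] + alt + region.seq[i + len(ref):]


def _score_at(seq: str, pos: int, site_type: str,
              model: ScoreModel) -> Optional[float]:
    """Score the window anchored at a boundary position, if it fits."""
    if site_type == DONOR:
        lo, hi = pos - 3, pos + 6
    else:
        a = pos - 2  # pos is the first exonic base; A of the AG at pos-2
        lo, hi = a - 18, a + 5
    if lo < 0 or hi > len(seq):
        return None
    score = site_strength._score_window(seq[lo:hi], model)
    return score.value


def _viable(seq: str, pos: int, site_type: str, model: ScoreModel,
            cfg: PseudoexonConfig) -> bool:
    sc = _score_at(seq, pos, site_type, model)
    return sc is not None and sc >= cfg.candidate_min_bits


def _dinuc_positions(seq: str, dinuc: str) -> set:
    out = set()
    i = seq.find(dinuc)
    while i != -1:
        out.add(i)
        i = seq.find(dinuc, i + 1)
    return out


def _models(models) -> Tuple[ScoreModel, ScoreModel]:
    if models is None:
        return (site_strength.load_pwm_model(DONOR),
                site_strength.load_pwm_model(ACCEPTOR))
    return models


def attribute_mechanism(variant: VariantRecord, transcript: TranscriptModel,
                        genome, models=None,
                        config: PseudoexonConfig = DEFAULT_PSEUDOEXON_CONFIG,
                        ) -> Tuple[MechanismCall, _Region, str]:
    """Attribute a deep intronic variant to a pseudoexon mechanism.

    Precedence: creation of a canonical dinucleotide at the edit site, then
    strengthening of a pre-existing viable candidate, then a candidate
    present only in the alt sequence (PPT strengthened / AGEZ cleared /
    score newly viable), then unresolved.

    Returns the call together with the analysis region and the alt
    sequence (reused by the partner search).
    """
    if resolve_sites(variant.pos, transcript):
        raise NotDeepIntronicError(
            "variant lies in a disruption-heuristic window; use the DD/DA "
            "pathway")
    donor_model, acceptor_model = _models(models)
    region = _extract_region(variant, transcript, genome,
                             config.scan_radius_nt)
    ref_seq = region.seq.upper()
    alt_seq = _apply_to_region(region, variant).upper()

    edit_len = max(len(variant.ref), len(variant.alt))
    vlo = region.variant_index - 1
    vhi = region.variant_index + edit_len

    # 1. created canonical dinucleotides overlapping the edit
    created_calls = []
    for dinuc, site_type, category in (
            ("GT", DONOR, CREATED_DONOR_GT),
            ("AG", ACCEPTOR, CREATED_ACCEPTOR_AG)):
        created = sorted(_dinuc_positions(alt_seq, dinuc)
                         - _dinuc_positions(ref_seq, dinuc))
        for i in [c for c in created if vlo <= c <= vhi]:
            boundary = i if site_type == DONOR else i + 2
            alt_sc = _score_at(alt_seq, boundary, site_type,
                               donor_model if site_type == DONOR
                               else acceptor_model)
            created_calls.append(MechanismCall(
                category=category, site_type=site_type,
                site_position=boundary,
                site_position_genomic=region.to_genomic(boundary),
                ref_score=None, alt_score=alt_sc))
    if created_calls:
        created_calls.sort(
            key=lambda c: (c.alt_score if c.alt_score is not None
                           else float("-inf")),
            reverse=True)
        call = created_calls[0]
        if len(created_calls) > 1:
            others = tuple(
                f"also {c.category} at region index {c.site_position}"
                for c in created_calls[1:])
            call = MechanismCall(
                category=call.category, site_type=call.site_type,
                site_position=call.site_position,
                site_position_genomic=call.site_position_genomic,
                ref_score=call.ref_score, alt_score=call.alt_score,
                notes=others)
        return call, region, alt_seq

    # 2. strengthened pre-existing candidate (viable in ref and alt)
    best = None
    for dinuc, site_type, model in (("GT", DONOR, donor_model),
                                    ("AG", ACCEPTOR, acceptor_model)):
        shared = _dinuc_positions(ref_seq, dinuc) & _dinuc_positions(
            alt_seq, dinuc)
        for i in sorted(shared):
            boundary = i if site_type == DONOR else i + 2
            ref_sc = _score_at(ref_seq, boundary, site_type, model)
            alt_sc = _score_at(alt_seq, boundary, site_type, model)
            if ref_sc is None or alt_sc is None:
                continue
            if alt_sc - ref_sc < config.strengthen_delta_bits:
                continue
            if ref_sc < config.candidate_min_bits:
                continue
            if best is None or alt_sc > best.alt_score:
                best = MechanismCall(
                    category=STRENGTHENED, site_type=site_type,
                    site_position=boundary,
                    site_position_genomic=region.to_genomic(boundary),
                    ref_score=ref_sc, alt_score=alt_sc)
    if best is not None:
        return best, region, alt_seq

    # 3. candidate only in alt: newly viable score, PPT strengthening, or
    #    AGEZ removal around a pre-existing acceptor
    for dinuc, site_type, model in (("GT", DONOR, donor_model),
                                    ("AG", ACCEPTOR, acceptor_model)):
        shared = _dinuc_positions(ref_seq, dinuc) & _dinuc_positions(
            alt_seq, dinuc)
        for i in sorted(shared):
            boundary = i if site_type == DONOR else i + 2
            ref_sc = _score_at(ref_seq, boundary, site_type, model)
            alt_sc = _score_at(alt_seq, boundary, site_type, model)
            if ref_sc is None or alt_sc is None:
                continue
            notes = []
            if (alt_sc >= config.candidate_min_bits
                    and ref_sc < config.candidate_min_bits):
                notes.append("score newly above viability floor")
            if site_type == ACCEPTOR and boundary >= 50:
                ref_up = ref_seq[boundary - 50:boundary]
                alt_up = alt_seq[boundary - 50:boundary]
                ref_agez = check_agez(ref_up)
                alt_agez = check_agez(alt_up)
                if not ref_agez["pass"] and alt_agez["pass"]:
                    notes.append("AGEZ violation removed")
                ref_ppt = count_ppt(ref_up)
                alt_ppt = count_ppt(alt_up)
                if (alt_ppt["passes_minimum"]
                        and not ref_ppt["passes_minimum"]):
                    notes.append("PPT strengthened past minimum")
            if notes:
                return (MechanismCall(
                    category=NEW_CANDIDATE_OTHER, site_type=site_type,
                    site_position=boundary,
                    site_position_genomic=region.to_genomic(boundary),
                    ref_score=ref_sc, alt_score=alt_sc,
                    notes=tuple(notes)), region, alt_seq)

    return (MechanismCall(category=UNRESOLVED,
                          notes=("no candidate sites in Alt",)),
            region, alt_seq)


def find_partner_sites(created_site: Tuple[int, str], alt_sequence: str,
                       models=None,
                       config: PseudoexonConfig = DEFAULT_PSEUDOEXON_CONFIG,
                       checklist_config: ChecklistConfig = DEFAULT_CONFIG,
                       ) -> List[PseudoexonCandidate]:
    """Partner splice sites pairing with a created site.

    ``created_site`` is (boundary index, site_type): for a created donor,
    the index of the G of the GT; for a created acceptor, the index of the
    first exonic base. Partners must imply an exon of 31-750 nt, pass the
    acceptor-side checklist items computable from sequence (PPT minimum and
    AG-exclusion zone), and either reach 75% of the model maximum or >= 3
    bits within 200 nt. Sorted by score then proximity.
    """
    donor_model, acceptor_model = _models(models)
    boundary, site_type = created_site
    alt_sequence = alt_sequence.upper()
    out: List[PseudoexonCandidate] = []

    if site_type == DONOR:
        # partner acceptors upstream: exon = [AG+2 .. boundary-1]
        partner_model = acceptor_model
        max_score = site_strength.model_max_score(partner_model)
        for i in sorted(_dinuc_positions(alt_sequence, "AG")):
            acc_pos = i + 2
            length = boundary - acc_pos
            if not config.min_exon_nt <= length <= config.max_exon_nt:
                continue
            score = _score_at(alt_sequence, acc_pos, ACCEPTOR, partner_model)
            if score is None:
                continue
            ok_checklist = _acceptor_side_ok(alt_sequence, acc_pos,
                                             checklist_config)
            strong = score >= config.strength_fraction * max_score
            relaxed = (length <= config.relax_distance_nt
                       and score >= config.relax_min_bits)
            if ok_checklist and (strong or relaxed):
                donor_score = _score_at(alt_sequence, boundary, DONOR,
                                        donor_model)
                out.append(PseudoexonCandidate(
                    acceptor_pos=acc_pos, donor_pos=boundary,
                    exon_length=length,
                    acceptor_score=round(score, 4),
                    donor_score=(round(donor_score, 4)
                                 if donor_score is not None else None),
                    passed_filters={"checklist": ok_checklist,
                                    "strength_75pct": strong,
                                    "proximity_relaxation": relaxed},
                    inclusion_interval=(acc_pos, boundary)))
        out.sort(key=lambda c: (-c.acceptor_score, c.exon_length))
    else:
        # partner donors downstream: exon = [boundary .. GT-1]
        partner_model = donor_model
        max_score = site_strength.model_max_score(partner_model)
        acc_score = _score_at(alt_sequence, boundary, ACCEPTOR, acceptor_model)
        acc_checklist = _acceptor_side_ok(alt_sequence, boundary,
                                          checklist_config)
        for i in sorted(_dinuc_positions(alt_sequence, "GT")):
            length = i - boundary
            if not config.min_exon_nt <= length <= config.max_exon_nt:
                continue
            score = _score_at(alt_sequence, i, DONOR, partner_model)
            if score is None:
                continue
            strong = score >= config.strength_fraction * max_score
            relaxed = (length <= config.relax_distance_nt
                       and score >= config.relax_min_bits)
            if acc_checklist and (strong or relaxed):
                out.append(PseudoexonCandidate(
                    acceptor_pos=boundary, donor_pos=i,
                    exon_length=length,
                    acceptor_score=(round(acc_score, 4)
                                    if acc_score is not None else None),
                    donor_score=round(score, 4),
                    passed_filters={"checklist": acc_checklist,
                                    "strength_75pct": strong,
                                    "proximity_relaxation": relaxed},
                    inclusion_interval=(boundary, i)))
        out.sort(key=lambda c: (-c.donor_score, c.exon_length))
    return out


def _acceptor_side_ok(seq: str, acc_pos: int,
                      config: ChecklistConfig) -> bool:
    """PPT minimum and AGEZ items for an acceptor whose first exonic base
    is at ``acc_pos``; insufficient upstream sequence fails closed."""
    upstream = seq[:acc_pos]
    if len(upstream) < -config.ppt_window[0]:
        return False
    ppt = count_ppt(upstream, config)
    agez = check_agez(upstream, config)
    return bool(ppt["passes_minimum"]) and bool(agez["pass"])


def predict_pseudoexon(variant: VariantRecord, transcript: TranscriptModel,
                       genome, models=None,
                       config: PseudoexonConfig = DEFAULT_PSEUDOEXON_CONFIG,
                       checklist_config: ChecklistConfig = DEFAULT_CONFIG,
                       ) -> PseudoexonPrediction:
    """Mechanism attribution plus partner search for one variant.

    Variants inside the disruption-heuristic windows return a
    ``redirect_to_disruption`` flag instead of a prediction.
    """
    try:
        mech, region, alt_seq = attribute_mechanism(
            variant, transcript, genome, models, config)
    except NotDeepIntronicError:
        return PseudoexonPrediction(
            mechanism=None, candidates=(), top=None,
            flags=frozenset({"redirect_to_disruption"}))
    except IntergenicPositionError:
        return PseudoexonPrediction(
            mechanism=None, candidates=(), top=None,
            flags=frozenset({"intergenic"}))

    candidates: List[PseudoexonCandidate] = []
    if mech.category in (CREATED_DONOR_GT, CREATED_ACCEPTOR_AG,
                         STRENGTHENED, NEW_CANDIDATE_OTHER):
        if mech.site_position is not None:
            candidates = find_partner_sites(
                (mech.site_position, mech.site_type), alt_seq, models,
                config, checklist_config)
    top = candidates[0] if candidates else None
    return PseudoexonPrediction(
        mechanism=mech, candidates=tuple(candidates), top=top,
        region_start=region.genomic_start, strand=region.strand)
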