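"""The splicing-requirements checklist.

Evaluates whether a candidate exon (or splice-site pair) satisfies the
minimal sequence, spacing, and strength requirements for recognition by the
major (U2) spliceosome: canonical donor/acceptor motifs, a polypyrimidine
tract of at least nine pyrimidines in -24..-5, a branchpoint 17-50 nt
upstream of the acceptor, an AG-free zone at -13..-6 (AG tolerated at -5),
flanking introns of >= 80 nt, and exon-length minima of 30/31/119 nt for
first/internal/last exons.

A manual mode applies motif checks directly; an in-silico mode replaces the
motif items with score thresholds (thresholds are configurable; defaults
are placeholders and flagged at runtime).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from heurosplice import site_strength
from heurosplice.transcript_model import (
    RelativePosition,
    KIND_INTRON_ACCEPTOR,
    TranscriptModel,
    extract_splice_context,
)

PASS = "pass"
FAIL = "fail"
INDETERMINATE = "indeterminate"
SKIPPED = "skipped"

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

# GC-exon-specific donor consensus used when the +1/+2 dinucleotide is GC.
GC_DONOR_CONSENSUS = "CAGGCAAGT"


@dataclass(frozen=True)
class ChecklistConfig:
    """Thresholds and windows of the splicing-requirements checklist.

    Windows are inclusive relative-position ranges, written (near, far)
    as offsets upstream of the acceptor boundary.
    """

    min_intron_nt: int = 80
    low_risk_bp_to_donor_nt: int = 60
    min_bp_to_donor_nt: int = 45
    bp_window_nt: Tuple[int, int] = (17, 50)
    min_exon_nt: Mapping[str, int] = field(
        default_factory=lambda: {"first": 30, "internal": 31, "last": 119})
    ppt_window: Tuple[int, int] = (-24, -5)
    ppt_min_pyrimidines: int = 9
    strong_ppt_consecutive: int = 12
    strong_ppt_total: int = 17
    strong_ppt_window: Tuple[int, int] = (-24, -4)
    agez_window: Tuple[int, int] = (-13, -6)
    branchpoint_motif: str = "TNA"  # or "YNA"
    gc_donor_min_matches: int = 8
    # in-silico thresholds (log2 bits). The published figure prints specific
    # values that are not machine-readable here; defaults are placeholders.
    in_silico_donor_min_bits: float = 0.0
    in_silico_acceptor_min_bits: float = 0.0
    in_silico_thresholds_are_placeholders: bool = True
    in_silico_keep_agez: bool = True
    in_silico_keep_branchpoint: bool = True


DEFAULT_CONFIG = ChecklistConfig()


@dataclass(frozen=True)
class ItemVerdict:
    status: str
    measured: object = None

    def __bool__(self) -> bool:
        return self.status == PASS


@dataclass(frozen=True)
class ChecklistResult:
    """Itemized pass/fail verdicts with the measured quantities behind them."""

    items: Mapping[str, ItemVerdict]
    mode: str
    overall: str
    gc_donor: bool = False

    @property
    def passed(self) -> bool:
        return self.overall == PASS

    def failed_items(self) -> List[str]:
        return [k for k, v in self.items.items() if v.status == FAIL]


@dataclass(frozen=True)
class BranchpointCandidate:
    """An adenosine matching the branchpoint motif within 17-50 nt of the
    acceptor boundary."""

    position: RelativePosition  # -d, the A of the branchpoint
    motif_window: str  # 3-mer ending at the A
    distance: int
    motif_matched: str  # TNA | YNA

    def __post_init__(self) -> None:
        if not 17 <= self.distance <= 50:
            raise ValueError("branchpoint candidates must sit 17-50 nt "
                             "upstream of the acceptor")


@dataclass(frozen=True)
class ExonContext:
    """Sequence context required to run the checklist on one exon.

    Acceptor-side fields are ``None`` for a first exon, donor-side fields
    for a last exon. All sequences are sense strand; ``acceptor_intronic``
    ends at -1 and ``donor_intronic`` starts at +1.
    """

    exon_category: str
    exon_length: int
    acceptor_intronic: Optional[str] = None
    acceptor_exonic: Optional[str] = None
    donor_exonic: Optional[str] = None
    donor_intronic: Optional[str] = None
    upstream_intron_length: Optional[int] = None
    downstream_intron_length: Optional[int] = None

    @property
    def donor_window9(self) -> Optional[str]:
        if self.donor_exonic is None or self.donor_intronic is None:
            return None
        return self.donor_exonic[-3:] + self.donor_intronic[:6]

    @property
    def acceptor_window23(self) -> Optional[str]:
        if self.acceptor_intronic is None or self.acceptor_exonic is None:
            return None
        return self.acceptor_intronic[-20:] + self.acceptor_exonic[:3]


def exon_context_from_transcript(transcript: TranscriptModel, exon_index: int,
                                 genome, intron_window: int = 50,
                                 ) -> ExonContext:
    """Build the checklist context for one exon of a transcript."""
    cat = transcript.exon_category(exon_index)
    up_ctx = dn_ctx = None
    if exon_index > 0:
        up_ctx = extract_splice_context(
            transcript, exon_index - 1, genome, intron_window=intron_window)
    if exon_index < transcript.n_exons - 1:
        dn_ctx = extract_splice_context(
            transcript, exon_index, genome, intron_window=intron_window)
    return ExonContext(
        exon_category=cat,
        exon_length=transcript.exon_length(exon_index),
        acceptor_intronic=up_ctx.acceptor_intronic if up_ctx else None,
        acceptor_exonic=up_ctx.acceptor_exonic if up_ctx else None,
        donor_exonic=dn_ctx.donor_exonic if dn_ctx else None,
        donor_intronic=dn_ctx.donor_intronic if dn_ctx else None,
        upstream_intron_length=(
            transcript.intron_length(exon_index - 1) if exon_index > 0
            else None),
        downstream_intron_length=(
            transcript.intron_length(exon_index)
            if exon_index < transcript.n_exons - 1 else None),
    )


# ---------------------------------------------------------------------------
# Individual checklist operations
# ---------------------------------------------------------------------------


def _slice_upstream(acceptor_intronic: str, near: int, far: int) -> str:
    """Slice positions far..near (e.g. -24..-5) from a sequence ending
    at -1. Offsets are negative, near > far."""
    n = len(acceptor_intronic)
    lo = n + far  # index of position `far`
    hi = n + near + 1
    if lo < 0:
        raise ValueError(
            f"window {far}..{near} needs {-far} nt, region has {n}")
    return acceptor_intronic[lo:hi]


def count_ppt(acceptor_intronic: str,
              config: ChecklistConfig = DEFAULT_CONFIG) -> dict:
    """Pyrimidine accounting for the polypyrimidine tract.

    The minimum-count window is ``config.ppt_window`` (-24..-5); the
    strength window is ``config.strong_ppt_window`` (-24..-4). A PPT is
    strong when it has >= 12 consecutive or >= 17 total pyrimidines in the
    strength window. Both windows deliberately retain their off-by-one
    difference.
    """
    far, near = config.ppt_window[0], config.ppt_window[1]
    min_seq = _slice_upstream(acceptor_intronic, near, far).upper()
    sfar, snear = config.strong_ppt_window
    strength_seq = _slice_upstream(acceptor_intronic, snear, sfar).upper()

    indeterminate = "N" in min_seq or "N" in strength_seq
    pyr_min = sum(1 for b in min_seq if b in PYRIMIDINES)
    pyr_total = sum(1 for b in strength_seq if b in PYRIMIDINES)

    max_consec = run = 0
    max_purine = purine_run = 0
    for b in strength_seq:
        run = run + 1 if b in PYRIMIDINES else 0
        purine_run = purine_run + 1 if b in PURINES else 0
        max_consec = max(max_consec, run)
        max_purine = max(max_purine, purine_run)
    t_content = (strength_seq.count("T") / len(strength_seq)
                 if strength_seq else 0.0)

    return {
        "pyrimidines_in_window": pyr_min,
        "total_in_strength_window": pyr_total,
        "max_consecutive": max_consec,
        "is_strong": (max_consec >= config.strong_ppt_consecutive
                      or pyr_total >= config.strong_ppt_total),
        "passes_minimum": pyr_min >= config.ppt_min_pyrimidines,
        "indeterminate": indeterminate,
        # reported-only metrics; never gate the checklist
        "max_uninterrupted_purines": max_purine,
        "t_content": round(t_content, 4),
    }


def find_branchpoints(acceptor_intronic: str,
                      config: ChecklistConfig = DEFAULT_CONFIG,
                      motif: Optional[str] = None) -> List[BranchpointCandidate]:
    """Adenosines matching the branchpoint motif 17-50 nt upstream of the
    acceptor boundary.

    An empty list means "no motif evidence", which the checklist treats as
    indeterminate rather than fail (the motif captures only a minority of
    true branchpoints).
    """
    motif = (motif or config.branchpoint_motif).upper()
    if motif not in ("TNA", "YNA"):
        raise ValueError(f"unsupported branchpoint motif {motif!r}")
    lo, hi = config.bp_window_nt
    seq = acceptor_intronic.upper()
    n = len(seq)
    out: List[BranchpointCandidate] = []
    for d in range(lo, hi + 1):
        i = n - d  # index of the A at position -d
        if i < 2:
            break
        if seq[i] != "A":
            continue
        first = seq[i - 2]
        if motif == "TNA" and first != "T":
            continue
        if motif == "YNA" and first not in PYRIMIDINES:
            continue
        out.append(BranchpointCandidate(
            position=RelativePosition(KIND_INTRON_ACCEPTOR, d),
            motif_window=seq[i - 2:i + 1],
            distance=d,
            motif_matched=motif,
        ))
    return out


def check_agez(acceptor_intronic: str,
               config: ChecklistConfig = DEFAULT_CONFIG) -> dict:
    """AG-exclusion-zone check: an AG whose A sits in -13..-6 violates;
    an AG with its A at -5 is tolerated."""
    far, near = config.agez_window  # (-13, -6)
    seq = acceptor_intronic.upper()
    n = len(seq)
    violations: List[int] = []
    indeterminate = False
    for a_off in range(-near, -far + 1):  # 6..13
        i = n - a_off
        if i < 0 or i + 1 >= n + 1:
            continue
        if i + 1 >= n:
            continue
        pair = seq[i:i + 2]
        if "N" in pair:
            indeterminate = True
            continue
        if pair == "AG":
            violations.append(-a_off)
    return {
        "violating_AG_positions": sorted(violations),
        "pass": not violations,
        "indeterminate": indeterminate,
    }


def theoretical_intron_minimum(config: ChecklistConfig = DEFAULT_CONFIG) -> dict:
    """Smallest intron lengths implied by the spacing constraints.

    The branchpoint must lie at least ``bp_window_nt[0]`` nt from the
    acceptor and at least ``min_bp_to_donor_nt`` (low risk:
    ``low_risk_bp_to_donor_nt``) nt from the upstream donor.
    """
    bp_min = config.bp_window_nt[0]
    return {
        "absolute_min_nt": config.min_bp_to_donor_nt + bp_min,
        "low_risk_min_nt": config.low_risk_bp_to_donor_nt + bp_min,
    }


# ---------------------------------------------------------------------------
# Full checklist
# ---------------------------------------------------------------------------


def _motif_matches(window: str, consensus: str) -> int:
    return sum(1 for a, b in zip(window, consensus) if a == b)


def _donor_item(ctx: ExonContext, config: ChecklistConfig,
                mode: str) -> Tuple[ItemVerdict, bool]:
    window = ctx.donor_window9
    if window is None or len(window) < 9:
        return ItemVerdict(INDETERMINATE, window), False
    window = window.upper()
    if "N" in window:
        return ItemVerdict(INDETERMINATE, window), False
    dinuc = window[3:5]
    gc = dinuc == "GC"
    if mode == "in_silico":
        if dinuc not in ("GT", "GC"):
            return ItemVerdict(FAIL, {"window": window, "dinucleotide": dinuc}), gc
        score = site_strength.score_donor(window).value
        ok = score >= config.in_silico_donor_min_bits
        return ItemVerdict(PASS if ok else FAIL,
                           {"window": window, "bits": round(score, 4)}), gc
    if dinuc == "GT":
        return ItemVerdict(PASS, {"window": window, "dinucleotide": "GT"}), False
    if gc:
        matches = _motif_matches(window, GC_DONOR_CONSENSUS)
        ok = matches >= config.gc_donor_min_matches
        return ItemVerdict(
            PASS if ok else FAIL,
            {"window": window, "dinucleotide": "GC",
             "gc_consensus_matches": matches}), True
    return ItemVerdict(FAIL, {"window": window, "dinucleotide": dinuc}), False


def _acceptor_item(ctx: ExonContext, config: ChecklistConfig,
                   mode: str) -> ItemVerdict:
    intronic = ctx.acceptor_intronic
    if intronic is None or len(intronic) < 2:
        return ItemVerdict(INDETERMINATE, intronic)
    dinuc = intronic[-2:].upper()
    if "N" in dinuc:
        return ItemVerdict(INDETERMINATE, dinuc)
    if mode == "in_silico":
        window = ctx.acceptor_window23
        if window is None or len(window) < 23 or "N" in window.upper():
            return ItemVerdict(INDETERMINATE, window)
        if dinuc != "AG":
            return ItemVerdict(FAIL, {"window": window, "dinucleotide": dinuc})
        score = site_strength.score_acceptor(window).value
        ok = score >= config.in_silico_acceptor_min_bits
        return ItemVerdict(PASS if ok else FAIL,
                           {"window": window, "bits": round(score, 4)})
    return ItemVerdict(PASS if dinuc == "AG" else FAIL,
                       {"dinucleotide": dinuc})


def evaluate_checklist(ctx: ExonContext,
                       config: ChecklistConfig = DEFAULT_CONFIG,
                       mode: str = "manual") -> ChecklistResult:
    """Run the splicing-requirements checklist on one exon context.

    First exons skip the acceptor-side items and last exons the donor-side
    items. Missing sequence yields indeterminate items, never a silent
    pass. An absent branchpoint motif is indeterminate (non-gating); every
    other indeterminate gating item makes the overall verdict
    indeterminate.
    """
    if mode not in ("manual", "in_silico"):
        raise ValueError(f"unknown checklist mode {mode!r}")
    if mode == "in_silico" and config.in_silico_thresholds_are_placeholders:
        warnings.warn(
            "in-silico checklist thresholds are placeholder defaults; "
            "set in_silico_donor_min_bits / in_silico_acceptor_min_bits "
            "to transcribed values", stacklevel=2)

    items: Dict[str, ItemVerdict] = {}
    gc_donor = False

    has_acceptor = ctx.exon_category != "first"
    has_donor = ctx.exon_category != "last"

    # donor side ------------------------------------------------------------
    if has_donor:
        items["donor_motif"], gc_donor = _donor_item(ctx, config, mode)
        dn_len = ctx.downstream_intron_length
        if dn_len is None:
            items["intron_length_downstream"] = ItemVerdict(INDETERMINATE, None)
        else:
            items["intron_length_downstream"] = ItemVerdict(
                PASS if dn_len >= config.min_intron_nt else FAIL, dn_len)
    else:
        items["donor_motif"] = ItemVerdict(SKIPPED)
        items["intron_length_downstream"] = ItemVerdict(SKIPPED)

    # acceptor side ---------------------------------------------------------
    if has_acceptor:
        items["acceptor_motif"] = _acceptor_item(ctx, config, mode)
        intronic = ctx.acceptor_intronic or ""
        if len(intronic) >= -config.ppt_window[0]:
            ppt = count_ppt(intronic, config)
            items["ppt"] = ItemVerdict(
                INDETERMINATE if ppt["indeterminate"]
                else (PASS if ppt["passes_minimum"] else FAIL), ppt)
        else:
            items["ppt"] = ItemVerdict(INDETERMINATE, None)

        keep_agez = mode == "manual" or config.in_silico_keep_agez
        if keep_agez:
            if len(intronic) >= -config.agez_window[0]:
                agez = check_agez(intronic, config)
                items["agez"] = ItemVerdict(
                    INDETERMINATE if (agez["indeterminate"] and agez["pass"])
                    else (PASS if agez["pass"] else FAIL), agez)
            else:
                items["agez"] = ItemVerdict(INDETERMINATE, None)
        else:
            items["agez"] = ItemVerdict(SKIPPED)

        keep_bp = mode == "manual" or config.in_silico_keep_branchpoint
        if keep_bp:
            if len(intronic) >= config.bp_window_nt[0] + 2:
                bps = find_branchpoints(intronic, config)
                items["branchpoint"] = ItemVerdict(
                    PASS if bps else INDETERMINATE,
                    {"n_candidates": len(bps),
                     "distances": [b.distance for b in bps]})
            else:
                items["branchpoint"] = ItemVerdict(INDETERMINATE, None)
        else:
            items["branchpoint"] = ItemVerdict(SKIPPED)

        up_len = ctx.upstream_intron_length
        if up_len is None:
            items["intron_length_upstream"] = ItemVerdict(INDETERMINATE, None)
        else:
            items["intron_length_upstream"] = ItemVerdict(
                PASS if up_len >= config.min_intron_nt else FAIL, up_len)
    else:
        for name in ("acceptor_motif", "ppt", "agez", "branchpoint",
                     "intron_length_upstream"):
            items[name] = ItemVerdict(SKIPPED)

    # exon length -----------------------------------------------------------
    minimum = config.min_exon_nt[ctx.exon_category]
    items["exon_length"] = ItemVerdict(
        PASS if ctx.exon_length >= minimum else FAIL,
        {"length": ctx.exon_length, "minimum": minimum})

    if any(v.status == FAIL for v in items.values()):
        overall = FAIL
    elif any(v.status == INDETERMINATE for k, v in items.items()
             if k != "branchpoint"):
        overall = INDETERMINATE
    else:
        overall = PASS
    return ChecklistResult(items=items, mode=mode, overall=overall,
                           gc_donor=gc_donor)
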