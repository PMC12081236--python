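"""Donor-disruption (DD) and acceptor-disruption (DA) decision trees.

The trees are a declarative rule engine over a fixed predicate vocabulary;
the rules themselves (positions, branch order, predicates) and the
per-subgroup spliceogenicity annotations ship as a versioned data file
(``data/rules.json``). Each classified variant receives exactly one primary
subgroup per (transcript, site class), together with the annotation
(p, 95% CI, n) and a predicate-by-predicate trace.

Variants outside every heuristic window are flagged (deep intronic ->
pseudoexon pathway; mid-exon -> SRE not covered), never silently dropped.
U12 introns are detected and flagged as unsupported.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from heurosplice.checklist import (
    ChecklistConfig,
    DEFAULT_CONFIG,
    count_ppt,
    find_branchpoints,
)
from heurosplice.transcript_model import (
    KIND_EXON_END,
    KIND_INTRON_ACCEPTOR,
    KIND_INTRON_DONOR,
    MappedPosition,
    RelativePosition,
    SpliceContext,
    TranscriptModel,
    VariantRecord,
    apply_variant,
    check_variant_ref,
    extract_splice_context,
    fetch_sequence,
    map_to_relative,
    trim_variant,
    IntergenicPositionError,
)

DONOR_SITE = "donor"
ACCEPTOR_SITE = "acceptor"

# widest windows routed to the disruption trees
DONOR_EXONIC_REACH = 3      # E-1..E-3
DONOR_INTRONIC_REACH = 6    # +1..+6
ACCEPTOR_INTRONIC_REACH = 50  # -1..-50
ACCEPTOR_EXONIC_REACH = 1   # E+1

MORE_PREFERRED = "more_preferred"
LESS_PREFERRED = "less_preferred"
EQUAL = "equal"

_KNOWN_OPS = {
    "true", "ref_base_is", "alt_base_is", "context_base", "cascade_compare",
    "creates_ag_in", "creates_ag_bp_context", "creates_donor_pair",
    "gc_donor", "donor_is_gt", "alt_creates_gt_donor",
    "alt_motif_match_count", "ppt_is_strong", "in_branchpoint_motif",
    "any_of",
}


class RuleTableError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Base cascades
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaseCascade:
    """A total preorder over {A,C,G,T}: ordered preference levels, ties
    within a level."""

    cascade_id: str
    levels: tuple  # tuple of frozensets, most preferred first

    def __post_init__(self) -> None:
        seen = set()
        for level in self.levels:
            seen |= set(level)
        if seen != set("ACGT"):
            raise ValueError(f"cascade {self.cascade_id} must cover ACGT")

    def rank(self, base: str) -> int:
        for i, level in enumerate(self.levels):
            if base in level:
                return i
        raise KeyError(base)


def cascade_compare(ref_base: str, alt_base: str,
                    cascade: BaseCascade) -> Optional[str]:
    """Compare the alternative base to the reference under a cascade.

    Returns how the *alt* base stands relative to ref: ``less_preferred``,
    ``more_preferred`` or ``equal``; ``None`` (indeterminate) for N bases.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in "ACGT" or alt_base not in "ACGT":
        return None
    r, a = cascade.rank(ref_base), cascade.rank(alt_base)
    if a > r:
        return LESS_PREFERRED
    if a < r:
        return MORE_PREFERRED
    return EQUAL


def creates_dinucleotide(ref_context: str, alt_context: str,
                         motif: str) -> List[int]:
    """Positions (0-based, indexing the first base) where ``motif`` exists
    in the alt context but not the ref context.

    The two contexts are compared positionally; for equal-length contexts
    (SNVs) indices are directly comparable.
    """
    motif = motif.upper()
    ref_hits = _motif_positions(ref_context.upper(), motif)
    alt_hits = _motif_positions(alt_context.upper(), motif)
    return sorted(alt_hits - ref_hits)


def _motif_positions(seq: str, motif: str) -> set:
    out = set()
    i = seq.find(motif)
    while i != -1:
        out.add(i)
        i = seq.find(motif, i + 1)
    return out


# ---------------------------------------------------------------------------
# Rule table
# ---------------------------------------------------------------------------

_WINDOW_RE = re.compile(r"^(E?[+-])(\d+)(?:\.\.(E?[+-])(\d+))?$")


@dataclass(frozen=True)
class WindowSpec:
    kind: str
    lo: int
    hi: int

    def contains(self, rel: RelativePosition) -> bool:
        return rel.kind == self.kind and self.lo <= rel.offset <= self.hi


def _parse_window(text: str) -> WindowSpec:
    m = _WINDOW_RE.match(text.strip())
    if not m:
        raise RuleTableError(f"bad window spec {text!r}")
    k1, o1, k2, o2 = m.groups()
    if k2 is not None and k2 != k1:
        raise RuleTableError(f"mixed kinds in window spec {text!r}")
    a = int(o1)
    b = int(o2) if o2 is not None else a
    return WindowSpec(kind=k1, lo=min(a, b), hi=max(a, b))


@dataclass(frozen=True)
class SpliceogenicityAnnotation:
    """Percent splice-altering with 95% CI and supporting count."""

    p: float
    ci: Tuple[float, float]
    n: int
    source: str = "paper_table"  # paper_table | figure_estimate | user_estimate
    text_verified: bool = True

    def __post_init__(self) -> None:
        low, high = self.ci
        if not 0 <= low <= self.p <= high <= 100:
            raise ValueError(
                f"annotation out of order: p={self.p}, ci=({low},{high})")

    def __str__(self) -> str:
        return f"{self.p}% [{self.ci[0]}-{self.ci[1]}] (n={self.n})"


@dataclass(frozen=True)
class RuleBranch:
    subgroup: str
    predicates: tuple  # raw predicate dicts


@dataclass(frozen=True)
class HeuristicRule:
    rule_id: str
    site_class: str
    windows: tuple  # WindowSpec
    context_windows: tuple
    branches: tuple  # RuleBranch

    def applies_to(self, rel: RelativePosition) -> bool:
        return any(w.contains(rel) for w in self.windows)


@dataclass(frozen=True)
class RuleTable:
    rules: tuple
    annotations: Dict[str, SpliceogenicityAnnotation]
    cascades: Dict[str, BaseCascade]
    gc_donor_consensus: str
    version: str = "unversioned"

    def rule(self, rule_id: str) -> HeuristicRule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    def annotation(self, rule_id: str, subgroup: str) -> SpliceogenicityAnnotation:
        return self.annotations[f"{rule_id}:{subgroup}"]


def _validate_predicates(preds: Sequence[dict], rule: dict,
                         declared: List[WindowSpec]) -> None:
    for pred in preds:
        op = pred.get("op")
        if op not in _KNOWN_OPS:
            raise RuleTableError(
                f"rule {rule['rule_id']}: unknown predicate op {op!r}")
        if op == "any_of":
            _validate_predicates(pred.get("predicates", ()), rule, declared)
        if "pos" in pred:
            rel = RelativePosition.parse(pred["pos"])
            if not any(w.contains(rel) for w in declared):
                raise RuleTableError(
                    f"rule {rule['rule_id']}: predicate references "
                    f"undeclared context position {pred['pos']}")


def _bundled_rule_path():
    return resources.files("heurosplice.data") / "rules.json"


def load_rule_table(rule_file=None) -> RuleTable:
    """Load and validate a rule table (bundled table by default).

    Validation: predicate ops must be in the vocabulary, referenced context
    positions must be declared, and every subgroup annotation must rest on
    at least 10 validated variants.
    """
    if rule_file is None:
        with _bundled_rule_path().open() as fh:
            data = json.load(fh)
    elif isinstance(rule_file, (str,)):
        with open(rule_file) as fh:
            data = json.load(fh)
    else:
        data = json.load(rule_file)

    cascades = {
        name: BaseCascade(cascade_id=name,
                          levels=tuple(frozenset(level) for level in levels))
        for name, levels in data.get("cascades", {}).items()
    }

    annotations: Dict[str, SpliceogenicityAnnotation] = {}
    for key, raw in data.get("annotations", {}).items():
        ann = SpliceogenicityAnnotation(
            p=float(raw["p"]), ci=tuple(raw["ci"]), n=int(raw["n"]),
            source=raw.get("source", "paper_table"),
            text_verified=bool(raw.get("text_verified", True)))
        if ann.n < 10:
            raise RuleTableError(
                f"annotation {key} has n={ann.n} < 10; subgroups must be "
                f"informed by at least 10 validated variants")
        annotations[key] = ann

    rules = []
    for raw in data.get("rules", ()):
        windows = tuple(_parse_window(w) for w in raw["window"])
        context = tuple(_parse_window(w)
                        for w in raw.get("context_positions", ()))
        declared = list(windows) + list(context)
        branches = []
        for b in raw["branches"]:
            _validate_predicates(b["predicates"], raw, declared)
            key = f"{raw['rule_id']}:{b['subgroup']}"
            if key not in annotations:
                raise RuleTableError(f"no annotation for branch {key}")
            branches.append(RuleBranch(
                subgroup=b["subgroup"],
                predicates=tuple(b["predicates"])))
        if raw["site_class"] not in (DONOR_SITE, ACCEPTOR_SITE):
            raise RuleTableError(
                f"rule {raw['rule_id']}: bad site_class {raw['site_class']!r}")
        rules.append(HeuristicRule(
            rule_id=raw["rule_id"],
            site_class=raw["site_class"],
            windows=windows,
            context_windows=context,
            branches=tuple(branches)))

    return RuleTable(
        rules=tuple(rules),
        annotations=annotations,
        cascades=cascades,
        gc_donor_consensus=data.get("gc_donor_consensus", "CAGGCAAGT"),
        version=str(data.get("version", "unversioned")),
    )


@lru_cache(maxsize=1)
def default_rule_table() -> RuleTable:
    return load_rule_table()


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------


def in_heuristic_windows(rel: RelativePosition) -> Optional[str]:
    """Site class whose routed window contains ``rel``, or ``None``."""
    if rel.kind == KIND_INTRON_DONOR:
        return DONOR_SITE if rel.offset <= DONOR_INTRONIC_REACH else None
    if rel.kind == KIND_INTRON_ACCEPTOR:
        return ACCEPTOR_SITE if rel.offset <= ACCEPTOR_INTRONIC_REACH else None
    if rel.kind == KIND_EXON_END:
        return DONOR_SITE if rel.offset <= DONOR_EXONIC_REACH else None
    return ACCEPTOR_SITE if rel.offset <= ACCEPTOR_EXONIC_REACH else None


def route(variant_relpos: RelativePosition,
          rule_table: Optional[RuleTable] = None) -> List[str]:
    """Applicable rule ids for a relative position, in flowchart order.

    Empty for positions outside every heuristic window (deep intronic or
    mid-exonic; those go to the pseudoexon or SRE pathway).
    """
    table = rule_table or default_rule_table()
    if in_heuristic_windows(variant_relpos) is None:
        return []
    return [r.rule_id for r in table.rules if r.applies_to(variant_relpos)]


# ---------------------------------------------------------------------------
# Classification context & predicate evaluation
# ---------------------------------------------------------------------------


@dataclass
class _ClassificationContext:
    """Everything predicates may inspect for one (variant, site) pairing."""

    relpos: RelativePosition
    site_class: str
    ref_base: Optional[str]  # sense strand; None for a deleted base
    alt_base: Optional[str]
    ref_ctx: SpliceContext
    alt_ctx: SpliceContext
    table: RuleTable
    config: ChecklistConfig = DEFAULT_CONFIG
    _cache: dict = field(default_factory=dict)

    # -- cached sequence features ------------------------------------------
    def donor_dinucleotide(self, which: str = "ref") -> Optional[str]:
        ctx = self.ref_ctx if which == "ref" else self.alt_ctx
        seq = ctx.donor_intronic[:2].upper()
        return seq if len(seq) == 2 else None

    def created_ag_offsets(self) -> set:
        """Offsets k (A at -k) of AG dinucleotides present in the alt
        acceptor region but not the ref region."""
        if "created_ag" not in self._cache:
            ref = self.ref_ctx.acceptor_intronic.upper()
            alt = self.alt_ctx.acceptor_intronic.upper()
            ref_ags = {len(ref) - i for i in _motif_positions(ref, "AG")}
            alt_ags = {len(alt) - i for i in _motif_positions(alt, "AG")}
            self._cache["created_ag"] = alt_ags - ref_ags
        return self._cache["created_ag"]

    def branchpoints(self, motif: str):
        key = f"bp:{motif}"
        if key not in self._cache:
            self._cache[key] = find_branchpoints(
                self.ref_ctx.acceptor_intronic, self.config, motif=motif)
        return self._cache[key]

    def ppt_strong(self) -> Optional[bool]:
        if "ppt" not in self._cache:
            seq = self.ref_ctx.acceptor_intronic
            if len(seq) < -self.config.strong_ppt_window[0]:
                self._cache["ppt"] = None
            else:
                ppt = count_ppt(seq, self.config)
                self._cache["ppt"] = (None if ppt["indeterminate"]
                                      else ppt["is_strong"])
        return self._cache["ppt"]

    def context_base(self, pos_text: str) -> Optional[str]:
        rel = RelativePosition.parse(pos_text)
        base = self.ref_ctx.base_at(rel)
        if base is None or base.upper() not in "ACGT":
            return None
        return base.upper()


def _eval_predicate(pred: dict, ctx: _ClassificationContext) -> Optional[bool]:
    op = pred["op"]
    result = _eval_predicate_inner(op, pred, ctx)
    if pred.get("negate"):
        return None if result is None else (not result)
    return result


def _eval_predicate_inner(op: str, pred: dict,
                          ctx: _ClassificationContext) -> Optional[bool]:
    if op == "true":
        return True
    if op == "ref_base_is":
        if ctx.ref_base is None:
            return None
        return ctx.ref_base in pred["bases"]
    if op == "alt_base_is":
        if ctx.alt_base is None:
            return False  # a deleted base is no base at all
        if ctx.alt_base == "N":
            return None
        return ctx.alt_base in pred["bases"]
    if op == "context_base":
        base = ctx.context_base(pred["pos"])
        if base is None:
            return None
        return base in pred["bases"]
    if op == "cascade_compare":
        cascade = ctx.table.cascades[pred["cascade"]]
        if ctx.ref_base is None:
            return None
        if ctx.alt_base is None:
            # deletion: absence is maximally un-preferred
            cmp = LESS_PREFERRED
        else:
            cmp = cascade_compare(ctx.ref_base, ctx.alt_base, cascade)
            if cmp is None:
                return None
        relation = pred["relation"]
        if relation == "alt_less":
            return cmp == LESS_PREFERRED
        if relation == "alt_more":
            return cmp == MORE_PREFERRED
        if relation == "equal":
            return cmp == EQUAL
        raise RuleTableError(f"unknown cascade relation {relation!r}")
    if op == "creates_ag_in":
        lo, hi = pred["a_range"]  # e.g. [-13, -6]
        created = ctx.created_ag_offsets()
        return any(lo <= -k <= hi for k in created)
    if op == "creates_ag_bp_context":
        created = ctx.created_ag_offsets()
        bps = ctx.branchpoints(pred.get("motif", "YNA"))
        min_sep = pred.get("min_separation", 3)
        for k in created:
            upstream = [b.distance - k for b in bps if b.distance > k]
            if upstream and min(upstream) >= min_sep:
                return True
        return False
    if op == "creates_donor_pair":
        at = RelativePosition.parse(pred["at"])
        nxt = RelativePosition(at.kind, at.offset + 1)
        ref_pair = (ctx.ref_ctx.base_at(at) or "?") + (ctx.ref_ctx.base_at(nxt) or "?")
        alt_pair = (ctx.alt_ctx.base_at(at) or "?") + (ctx.alt_ctx.base_at(nxt) or "?")
        if "N" in ref_pair or "N" in alt_pair:
            return None
        return alt_pair in pred["motifs"] and alt_pair != ref_pair
    if op == "gc_donor":
        pair = ctx.donor_dinucleotide("ref")
        if pair is None or "N" in pair:
            return None
        return pair == "GC"
    if op == "donor_is_gt":
        pair = ctx.donor_dinucleotide("ref")
        if pair is None or "N" in pair:
            return None
        return pair == "GT"
    if op == "alt_creates_gt_donor":
        ref_pair = ctx.donor_dinucleotide("ref")
        alt_pair = ctx.donor_dinucleotide("alt")
        if alt_pair is None or "N" in (alt_pair or "NN"):
            return None
        return alt_pair == "GT" and alt_pair != ref_pair
    if op == "alt_motif_match_count":
        window = ctx.alt_ctx.donor_window9.upper()
        if len(window) < 9 or "N" in window:
            return None
        consensus = ctx.table.gc_donor_consensus
        matches = sum(1 for a, b in zip(window, consensus) if a == b)
        return matches >= pred["min"]
    if op == "ppt_is_strong":
        return ctx.ppt_strong()
    if op == "in_branchpoint_motif":
        if ctx.relpos.kind != KIND_INTRON_ACCEPTOR:
            return False
        bps = ctx.branchpoints(pred.get("motif", "TNA"))
        k = ctx.relpos.offset
        role = pred.get("role", "A")
        if role == "A":
            return any(b.distance == k for b in bps)
        if role == "T":
            return any(b.distance + 2 == k for b in bps)
        return any(b.distance <= k <= b.distance + 2 for b in bps)
    if op == "any_of":
        saw_none = False
        for sub in pred["predicates"]:
            r = _eval_predicate(sub, ctx)
            if r is True:
                return True
            if r is None:
                saw_none = True
        return None if saw_none else False
    raise RuleTableError(f"unknown predicate op {op!r}")


def _describe(pred: dict) -> str:
    op = pred["op"]
    extras = {k: v for k, v in pred.items() if k != "op"}
    return f"{op}({extras})" if extras else op


# ---------------------------------------------------------------------------
# Assignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubgroupAssignment:
    """Outcome of classifying one variant against one splice site."""

    rule_id: Optional[str]
    subgroup: Optional[str]
    site_class: Optional[str]
    annotation: Optional[SpliceogenicityAnnotation]
    trace: tuple
    flags: FrozenSet[str] = frozenset()
    relative_position: Optional[str] = None
    variant: Optional[VariantRecord] = None
    transcript_id: Optional[str] = None

    @property
    def assigned(self) -> bool:
        return self.rule_id is not None and self.subgroup is not None

    @property
    def label(self) -> str:
        if self.assigned:
            return f"{self.rule_id} {self.subgroup}"
        return ",".join(sorted(self.flags)) or "unassigned"


def _unassigned(flags, relpos=None, variant=None, transcript=None,
                trace=()) -> SubgroupAssignment:
    return SubgroupAssignment(
        rule_id=None, subgroup=None, site_class=None, annotation=None,
        trace=tuple(trace), flags=frozenset(flags),
        relative_position=str(relpos) if relpos else None,
        variant=variant,
        transcript_id=transcript.transcript_id if transcript else None)


class _Indeterminate(Exception):
    def __init__(self, rule_id, trace):
        self.rule_id = rule_id
        self.trace = trace


def _evaluate_rules(ctx: _ClassificationContext, rule_ids: List[str],
                    ) -> Optional[Tuple[str, str, list]]:
    """First (rule, subgroup) whose predicates all hold, with trace.

    Raises :class:`_Indeterminate` when an N base blocks a decision.
    """
    trace: list = []
    for rid in rule_ids:
        rule = ctx.table.rule(rid)
        if rule.site_class != ctx.site_class:
            continue
        for branch in rule.branches:
            ok = True
            for pred in branch.predicates:
                result = _eval_predicate(pred, ctx)
                trace.append(
                    f"{rid} {branch.subgroup}: {_describe(pred)} -> "
                    f"{'indeterminate' if result is None else result}")
                if result is None:
                    raise _Indeterminate(rid, trace)
                if not result:
                    ok = False
                    break
            if ok:
                trace.append(f"=> {rid} {branch.subgroup}")
                return rid, branch.subgroup, trace
    return None


# ---------------------------------------------------------------------------
# Site resolution
# ---------------------------------------------------------------------------


def _site_for_label(rel: RelativePosition, mapped: MappedPosition,
                    transcript: TranscriptModel,
                    ) -> Optional[Tuple[str, int]]:
    """(site_class, intron_index) reachable from one relative label."""
    if rel.kind == KIND_INTRON_DONOR:
        if rel.offset <= DONOR_INTRONIC_REACH:
            return DONOR_SITE, mapped.intron_index
        return None
    if rel.kind == KIND_INTRON_ACCEPTOR:
        if rel.offset <= ACCEPTOR_INTRONIC_REACH:
            return ACCEPTOR_SITE, mapped.intron_index
        return None
    if rel.kind == KIND_EXON_END:
        if (rel.offset <= DONOR_EXONIC_REACH
                and rel.exon_index < transcript.n_exons - 1):
            return DONOR_SITE, rel.exon_index
        return None
    if rel.offset <= ACCEPTOR_EXONIC_REACH and rel.exon_index > 0:
        return ACCEPTOR_SITE, rel.exon_index - 1
    return None


def resolve_sites(variant_pos: int, transcript: TranscriptModel,
                  ) -> List[Tuple[RelativePosition, str, int]]:
    """All (relpos, site_class, intron_index) pairings a genomic position
    can be classified against (both for short exons)."""
    mapped = map_to_relative(variant_pos, transcript)
    labels = [mapped.primary]
    if mapped.secondary is not None:
        labels.append(mapped.secondary)
    out = []
    for rel in labels:
        hit = _site_for_label(rel, mapped, transcript)
        if hit is not None:
            out.append((rel, hit[0], hit[1]))
    return out


def _sense(base: str, strand: str) -> str:
    if strand == "-":
        return base.translate(str.maketrans("ACGTN", "TGCAN"))
    return base


# ---------------------------------------------------------------------------
# SNV classification
# ---------------------------------------------------------------------------


def classify_snv(variant: VariantRecord, transcript: TranscriptModel,
                 genome, rule_table: Optional[RuleTable] = None,
                 site_class: Optional[str] = None,
                 config: ChecklistConfig = DEFAULT_CONFIG,
                 check_ref: bool = True) -> SubgroupAssignment:
    """Classify an SNV against one transcript.

    Returns the primary :class:`SubgroupAssignment`; variants outside the
    heuristic windows come back unassigned with an explanatory flag
    (``deep_intronic``, ``SRE_not_covered``, ``intergenic``) and U12
    introns with ``U12_unsupported``.
    """
    if variant.variant_class != "SNV":
        raise ValueError("classify_snv handles SNVs; use classify_indel")
    table = rule_table or default_rule_table()
    if check_ref:
        check_variant_ref(variant, genome)

    try:
        mapped = map_to_relative(variant.pos, transcript)
    except IntergenicPositionError:
        return _unassigned({"intergenic"}, variant=variant,
                           transcript=transcript)

    sites = resolve_sites(variant.pos, transcript)
    if site_class is not None:
        sites = [s for s in sites if s[1] == site_class]
    if not sites:
        rel = mapped.primary
        if rel.is_intronic:
            flags = {"deep_intronic", "pseudoexon_pathway"}
        else:
            flags = {"SRE_not_covered"}
        return _unassigned(flags, relpos=rel, variant=variant,
                           transcript=transcript)

    rel, sclass, intron_index = sites[0]
    if transcript.intron_classes[intron_index] == "U12":
        return _unassigned({"U12_unsupported"}, relpos=rel, variant=variant,
                           transcript=transcript)

    ref_ctx = extract_splice_context(transcript, intron_index, genome)
    edited = apply_variant(ref_ctx, variant)
    ctx = _ClassificationContext(
        relpos=rel,
        site_class=sclass,
        ref_base=_sense(variant.ref, transcript.strand),
        alt_base=_sense(variant.alt, transcript.strand),
        ref_ctx=edited.ref,
        alt_ctx=edited.alt,
        table=table,
        config=config,
    )

    rule_ids = route(rel, table)
    try:
        hit = _evaluate_rules(ctx, rule_ids)
    except _Indeterminate as ind:
        return SubgroupAssignment(
            rule_id=ind.rule_id, subgroup=None, site_class=sclass,
            annotation=None, trace=tuple(ind.trace),
            flags=frozenset({"indeterminate"}),
            relative_position=str(rel), variant=variant,
            transcript_id=transcript.transcript_id)
    if hit is None:
        return _unassigned({"not_covered"}, relpos=rel, variant=variant,
                           transcript=transcript)
    rid, subgroup, trace = hit
    flags = set()
    if ctx.donor_dinucleotide("ref") == "GC" and sclass == DONOR_SITE:
        flags.add("gc_donor")
    ann = table.annotation(rid, subgroup)
    if not ann.text_verified:
        flags.add("annotation_is_estimate")
    return SubgroupAssignment(
        rule_id=rid, subgroup=subgroup, site_class=sclass,
        annotation=ann, trace=tuple(trace), flags=frozenset(flags),
        relative_position=str(rel), variant=variant,
        transcript_id=transcript.transcript_id)


def classify_all_sites(variant: VariantRecord, transcript: TranscriptModel,
                       genome, rule_table: Optional[RuleTable] = None,
                       ) -> List[SubgroupAssignment]:
    """One assignment per reachable site class (short exons can hit both)."""
    out = []
    for sclass in (DONOR_SITE, ACCEPTOR_SITE):
        hits = [s for s in resolve_sites(variant.pos, transcript)
                if s[1] == sclass]
        if hits:
            out.append(classify_snv(variant, transcript, genome, rule_table,
                                    site_class=sclass))
    if not out:
        out.append(classify_snv(variant, transcript, genome, rule_table))
    return out


# ---------------------------------------------------------------------------
# Indel classification
# ---------------------------------------------------------------------------


def classify_indel(variant: VariantRecord, transcript: TranscriptModel,
                   genome, rule_table: Optional[RuleTable] = None,
                   config: ChecklistConfig = DEFAULT_CONFIG,
                   check_ref: bool = True,
                   ) -> Tuple[List[SubgroupAssignment], SubgroupAssignment]:
    """Classify an insertion/deletion by per-position decomposition.

    Every destroyed reference position inside a heuristic window is
    evaluated independently (deleted bases count as maximally un-preferred);
    creation predicates see the full alt context. Returns all matches plus
    a summary assignment with the maximum spliceogenicity.
    """
    if variant.variant_class == "SNV":
        raise ValueError("use classify_snv for SNVs")
    table = rule_table or default_rule_table()
    if check_ref:
        check_variant_ref(variant, genome)
    start0, removed, added = trim_variant(variant)
    start = start0 + 1

    # an indel spanning an entire exon is outside the disruption trees
    for s, e in transcript.exons:
        if start - 1 <= s and start - 1 + len(removed) >= e:
            return [], _unassigned({"not_covered", "exon_deleted"},
                                   variant=variant, transcript=transcript)

    if removed:
        anchor_positions = list(range(start, start + len(removed)))
        deleted = True
    else:
        anchor_positions = [start - 1, start]
        deleted = False

    matches: List[SubgroupAssignment] = []
    seen = set()
    for gpos in anchor_positions:
        try:
            sites = resolve_sites(gpos, transcript)
        except IntergenicPositionError:
            continue
        for rel, sclass, intron_index in sites:
            key = (str(rel), sclass, intron_index)
            if key in seen:
                continue
            seen.add(key)
            if transcript.intron_classes[intron_index] == "U12":
                matches.append(_unassigned({"U12_unsupported"}, relpos=rel,
                                           variant=variant,
                                           transcript=transcript))
                continue
            ref_ctx = extract_splice_context(transcript, intron_index, genome)
            try:
                edited = apply_variant(ref_ctx, variant)
            except ValueError:
                continue
            base = fetch_sequence(genome, variant.chrom, gpos - 1, gpos)
            ctx = _ClassificationContext(
                relpos=rel,
                site_class=sclass,
                ref_base=_sense(base, transcript.strand) or None,
                alt_base=None if deleted else _sense(base, transcript.strand),
                ref_ctx=edited.ref,
                alt_ctx=edited.alt,
                table=table,
                config=config,
            )
            try:
                hit = _evaluate_rules(ctx, route(rel, table))
            except _Indeterminate as ind:
                matches.append(SubgroupAssignment(
                    rule_id=ind.rule_id, subgroup=None, site_class=sclass,
                    annotation=None, trace=tuple(ind.trace),
                    flags=frozenset({"indeterminate"}),
                    relative_position=str(rel), variant=variant,
                    transcript_id=transcript.transcript_id))
                continue
            if hit is None:
                continue
            rid, subgroup, trace = hit
            ann = table.annotation(rid, subgroup)
            flags = {"indel_decomposition"}
            if not ann.text_verified:
                flags.add("annotation_is_estimate")
            matches.append(SubgroupAssignment(
                rule_id=rid, subgroup=subgroup, site_class=sclass,
                annotation=ann, trace=tuple(trace), flags=frozenset(flags),
                relative_position=str(rel), variant=variant,
                transcript_id=transcript.transcript_id))

    assigned = [m for m in matches if m.assigned]
    if assigned:
        summary = max(assigned, key=lambda m: m.annotation.p)
    elif matches:
        summary = matches[0]
    else:
        summary = _unassigned({"deep_intronic", "pseudoexon_pathway"},
                              variant=variant, transcript=transcript)
    return matches, summary
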