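"""Transcript coordinate arithmetic, relative-position nomenclature, and
strand-normalized sequence extraction.

Conventions
-----------
* Internal coordinates are 0-based half-open genomic intervals; VCF and GTF
  are 1-based at I/O boundaries only.
* Exons of a :class:`TranscriptModel` are stored in transcript (5'->3')
  order: ascending genomic coordinates on ``+``, descending on ``-``.
* Relative positions follow the +k / -k / E+k / E-k nomenclature: the first
  base of an exon is E+1, the penultimate base is E-2, the third base of the
  intron downstream of a donor is +3.
* All extracted sequence is reported on the transcript sense strand
  (reverse-complemented for ``-`` strand transcripts).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, TextIO, Union

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_STRANDS = {"+", "-"}
INTRON_CLASSES = {"U2", "U12", "unknown"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Relative positions
# ---------------------------------------------------------------------------

KIND_INTRON_DONOR = "+"      # +k, k-th intron base after the donor boundary
KIND_INTRON_ACCEPTOR = "-"   # -k, k-th intron base before the acceptor boundary
KIND_EXON_START = "E+"       # E+k, k-th exon base from its 5' end
KIND_EXON_END = "E-"         # E-k, k-th exon base from its 3' end

_REL_RE = re.compile(r"^(E?)([+-])(\d+)$")


@dataclass(frozen=True)
class RelativePosition:
    """A position expressed relative to the nearest exon-intron boundary."""

    kind: str  # one of '+', '-', 'E+', 'E-'
    offset: int  # >= 1
    exon_index: int = 0  # anchoring exon (transcript order, 0-based)
    exon_category: str = "internal"  # first | internal | last

    def __post_init__(self) -> None:
        if self.kind not in (KIND_INTRON_DONOR, KIND_INTRON_ACCEPTOR,
                             KIND_EXON_START, KIND_EXON_END):
            raise ValueError(f"bad relative-position kind {self.kind!r}")
        if self.offset < 1:
            raise ValueError("relative-position offset must be >= 1")

    # -- serialization ------------------------------------------------------
    def __str__(self) -> str:
        return f"{self.kind}{self.offset}"

    @classmethod
    def parse(cls, text: str, exon_index: int = 0,
              exon_category: str = "internal") -> "RelativePosition":
        m = _REL_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse relative position {text!r}")
        e, sign, k = m.groups()
        return cls(kind=e + sign, offset=int(k), exon_index=exon_index,
                   exon_category=exon_category)

    # -- semantics ----------------------------------------------------------
    @property
    def is_intronic(self) -> bool:
        return self.kind in (KIND_INTRON_DONOR, KIND_INTRON_ACCEPTOR)

    @property
    def is_exonic(self) -> bool:
        return not self.is_intronic

    def exonic_twin(self, exon_length: int) -> "RelativePosition":
        """The equivalent label counted from the other exon end.

        For an exon of length L, E+k and E-(L-k+1) denote the same base.
        """
        if not self.is_exonic:
            raise ValueError("exonic_twin only defined for exonic positions")
        twin_offset = exon_length - self.offset + 1
        twin_kind = KIND_EXON_END if self.kind == KIND_EXON_START else KIND_EXON_START
        return replace(self, kind=twin_kind, offset=twin_offset)


def parse_relative(text: str) -> RelativePosition:
    return RelativePosition.parse(text)


# ---------------------------------------------------------------------------
# Transcript model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware ordered exon structure with per-intron spliceosome class.

    ``exons`` are (start, end) 0-based half-open genomic intervals in
    transcript order.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    intron_classes: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError("transcript needs at least one exon")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(f"empty exon ({s},{e})")
        # transcript order: ascending for +, descending for -
        genomic_sorted = sorted(exons)
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if exons != tuple(expected):
            raise ValueError("exons not in transcript (5'->3') order")
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 < e1:
                raise ValueError("overlapping exons")
            if s2 == e1:
                raise ValueError("zero-length intron between adjacent exons")
        classes = self.intron_classes or ("U2",) * (len(exons) - 1)
        classes = tuple(classes)
        if len(classes) != len(exons) - 1:
            raise ValueError("intron_classes length must be exon count - 1")
        for c in classes:
            if c not in INTRON_CLASSES:
                raise ValueError(f"unknown intron class {c!r}")
        object.__setattr__(self, "intron_classes", classes)

    # -- structure ----------------------------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exon_length(self, i: int) -> int:
        s, e = self.exons[i]
        return e - s

    def intron_interval(self, i: int) -> tuple:
        """Genomic 0-based half-open interval of intron ``i`` (between
        transcript exons i and i+1)."""
        if not 0 <= i < self.n_introns:
            raise IndexError(f"intron index {i} out of range")
        a, b = self.exons[i], self.exons[i + 1]
        if self.strand == "+":
            return (a[1], b[0])
        return (b[1], a[0])

    def intron_length(self, i: int) -> int:
        s, e = self.intron_interval(i)
        return e - s

    @property
    def span(self) -> tuple:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return (min(starts), max(ends))

    def exon_category(self, i: int) -> str:
        if self.n_exons == 1:
            return "first"
        if i == 0:
            return "first"
        if i == self.n_exons - 1:
            return "last"
        return "internal"

    # -- relative <-> genomic ----------------------------------------------
    def rel_to_genomic(self, rel: RelativePosition,
                       intron_index: Optional[int] = None) -> int:
        """0-based genomic coordinate of a relative position.

        Intronic kinds anchor on ``intron_index`` when given, otherwise on
        the intron implied by ``rel.exon_index`` (downstream intron for +k,
        upstream intron for -k).
        """
        k = rel.offset
        if rel.kind == KIND_EXON_START:
            s, e = self.exons[rel.exon_index]
            return s + (k - 1) if self.strand == "+" else e - k
        if rel.kind == KIND_EXON_END:
            s, e = self.exons[rel.exon_index]
            return e - k if self.strand == "+" else s + (k - 1)
        if rel.kind == KIND_INTRON_DONOR:
            i = intron_index if intron_index is not None else rel.exon_index
            s, e = self.intron_interval(i)
            return s + (k - 1) if self.strand == "+" else e - k
        # KIND_INTRON_ACCEPTOR
        i = intron_index if intron_index is not None else rel.exon_index - 1
        s, e = self.intron_interval(i)
        return e - k if self.strand == "+" else s + (k - 1)


@dataclass(frozen=True)
class MappedPosition:
    """Result of mapping a genomic position into a transcript."""

    primary: RelativePosition
    secondary: Optional[RelativePosition] = None  # the other exonic label
    intron_index: Optional[int] = None  # set for intronic positions

    def __str__(self) -> str:
        return str(self.primary)


class IntergenicPositionError(ValueError):
    """Raised when a position lies outside the transcript span."""


def map_to_relative(variant_pos: int, transcript: TranscriptModel) -> MappedPosition:
    """Map a 1-based genomic position to relative-boundary nomenclature.

    Exonic positions report both E+k and E-k (smaller offset primary; tie
    resolved to E+k). Intronic positions within the donor half of the intron
    (midpoint ties included) use +k, else -k.
    """
    g = variant_pos - 1
    lo, hi = transcript.span
    if not lo <= g < hi:
        raise IntergenicPositionError(
            f"position {variant_pos} outside transcript span of "
            f"{transcript.transcript_id}")

    for i, (s, e) in enumerate(transcript.exons):
        if s <= g < e:
            if transcript.strand == "+":
                k1 = g - s + 1
            else:
                k1 = e - g
            length = e - s
            k2 = length - k1 + 1
            cat = transcript.exon_category(i)
            start_label = RelativePosition(KIND_EXON_START, k1, i, cat)
            end_label = RelativePosition(KIND_EXON_END, k2, i, cat)
            if k1 <= k2:
                return MappedPosition(primary=start_label, secondary=end_label)
            return MappedPosition(primary=end_label, secondary=start_label)

    for i in range(transcript.n_introns):
        s, e = transcript.intron_interval(i)
        if s <= g < e:
            if transcript.strand == "+":
                d_donor = g - s + 1
            else:
                d_donor = e - g
            length = e - s
            d_acc = length - d_donor + 1
            if d_donor <= d_acc:  # midpoint tie -> donor side
                rel = RelativePosition(
                    KIND_INTRON_DONOR, d_donor, i,
                    transcript.exon_category(i))
            else:
                rel = RelativePosition(
                    KIND_INTRON_ACCEPTOR, d_acc, i + 1,
                    transcript.exon_category(i + 1))
            return MappedPosition(primary=rel, intron_index=i)

    raise IntergenicPositionError(
        f"position {variant_pos} falls in no exon or intron of "
        f"{transcript.transcript_id}")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A VCF-style variant: 1-based position, explicit ref/alt sequences."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_id: str = "."

    def __post_init__(self) -> None:
        if not self.ref and not self.alt:
            raise ValueError("ref and alt cannot both be empty")
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) < len(self.alt) and self.alt.startswith(self.ref):
            return "insertion"
        if len(self.ref) > len(self.alt) and self.ref.startswith(self.alt):
            return "deletion"
        return "delins"

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference allele."""
        return self.pos + len(self.ref) - 1


class RefMismatchError(ValueError):
    """Variant REF does not match the genome sequence at its position."""


def check_variant_ref(variant: VariantRecord, genome) -> None:
    """Raise :class:`RefMismatchError` unless the genome matches REF."""
    observed = fetch_sequence(genome, variant.chrom, variant.pos - 1,
                              variant.pos - 1 + len(variant.ref))
    if observed.upper() != variant.ref:
        raise RefMismatchError(
            f"{variant.chrom}:{variant.pos} expected REF {variant.ref!r} "
            f"but genome has {observed!r}")


# ---------------------------------------------------------------------------
# Genome access
# ---------------------------------------------------------------------------


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) from a genome object (0-based half-open).

    Accepts a pyfaidx.Fasta, a plain mapping of chrom -> sequence string, or
    anything with a ``fetch(chrom, start, end)`` method. Windows running off
    either contig end are truncated (caller checks lengths).
    """
    if start < 0:
        start = 0
    if end <= start:
        return ""
    if hasattr(genome, "fetch"):
        return str(genome.fetch(chrom, start, end)).upper()
    try:
        contig = genome[chrom]
    except KeyError:
        raise KeyError(f"contig {chrom!r} not found in genome") from None
    seq = contig[start:end]
    return str(seq).upper()


def contig_length(genome, chrom: str) -> Optional[int]:
    try:
        return len(genome[chrom])
    except Exception:
        return None


# ---------------------------------------------------------------------------
# Splice context extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpliceContext:
    """Sense-strand windows around one intron's donor and acceptor sites.

    ``donor_exonic`` is the tail of the upstream exon (..E-1], sense order;
    ``donor_intronic`` is [+1..]; ``acceptor_intronic`` is [..-1] (ending at
    the last intron base); ``acceptor_exonic`` is [E+1..] of the downstream
    exon.
    """

    transcript_id: str
    chrom: str
    strand: str
    intron_index: int
    donor_exonic: str
    donor_intronic: str
    acceptor_intronic: str
    acceptor_exonic: str
    exon_window: int = 50
    intron_window: int = 50
    truncated: bool = False
    windows_overlap: bool = False
    # genomic (0-based) coordinate of the first intron base and last intron base
    donor_boundary: int = 0
    acceptor_boundary: int = 0
    edits: tuple = ()  # applied variants, most recent last

    # -- derived windows ----------------------------------------------------
    @property
    def donor_window9(self) -> str:
        """The 9-mer E-3..+6 spanning the donor boundary."""
        return self.donor_exonic[-3:] + self.donor_intronic[:6]

    @property
    def acceptor_window23(self) -> str:
        """The 23-mer -20..E+3 spanning the acceptor boundary."""
        return self.acceptor_intronic[-20:] + self.acceptor_exonic[:3]

    def acceptor_region(self, upstream: int = 50) -> str:
        """Intronic -upstream..-1 sequence (may be shorter when truncated)."""
        return self.acceptor_intronic[-upstream:]

    def base_at(self, rel: RelativePosition) -> Optional[str]:
        """Sense-strand base at a relative position within the windows."""
        k = rel.offset
        try:
            if rel.kind == KIND_INTRON_DONOR:
                if k > len(self.donor_intronic):
                    return None
                return self.donor_intronic[k - 1]
            if rel.kind == KIND_INTRON_ACCEPTOR:
                if k > len(self.acceptor_intronic):
                    return None
                return self.acceptor_intronic[-k]
            if rel.kind == KIND_EXON_END:
                if k > len(self.donor_exonic):
                    return None
                return self.donor_exonic[-k]
            if k > len(self.acceptor_exonic):
                return None
            return self.acceptor_exonic[k - 1]
        except IndexError:  # pragma: no cover - guarded above
            return None


def extract_splice_context(transcript: TranscriptModel, intron_index: int,
                           genome, exon_window: int = 50,
                           intron_window: int = 50) -> SpliceContext:
    """Extract sense-strand windows around intron ``intron_index``.

    The donor window includes at least E-3..+6 and the acceptor window
    -50..E+3 at default sizes. Windows extending past a contig end are
    truncated and flagged; an intron shorter than twice the intron window
    yields overlapping donor/acceptor windows, flagged but both returned.
    """
    if not 0 <= intron_index < transcript.n_introns:
        raise IndexError(f"intron index {intron_index} out of range")
    chrom = transcript.chrom
    up_s, up_e = transcript.exons[intron_index]
    dn_s, dn_e = transcript.exons[intron_index + 1]
    in_s, in_e = transcript.intron_interval(intron_index)
    intron_len = in_e - in_s

    if transcript.strand == "+":
        donor_exonic = fetch_sequence(
            genome, chrom, max(up_s, up_e - exon_window), up_e)
        donor_intronic = fetch_sequence(
            genome, chrom, in_s, min(in_e, in_s + intron_window))
        acceptor_intronic = fetch_sequence(
            genome, chrom, max(in_s, in_e - intron_window), in_e)
        acceptor_exonic = fetch_sequence(
            genome, chrom, dn_s, min(dn_e, dn_s + exon_window))
        donor_boundary = in_s
        acceptor_boundary = in_e - 1
    else:
        donor_exonic = reverse_complement(fetch_sequence(
            genome, chrom, up_s, min(up_e, up_s + exon_window)))
        donor_intronic = reverse_complement(fetch_sequence(
            genome, chrom, max(in_s, in_e - intron_window), in_e))
        acceptor_intronic = reverse_complement(fetch_sequence(
            genome, chrom, in_s, min(in_e, in_s + intron_window)))
        acceptor_exonic = reverse_complement(fetch_sequence(
            genome, chrom, max(dn_s, dn_e - exon_window), dn_e))
        donor_boundary = in_e - 1
        acceptor_boundary = in_s

    truncated = (
        len(donor_exonic) < min(exon_window, up_e - up_s)
        or len(acceptor_exonic) < min(exon_window, dn_e - dn_s)
        or len(donor_intronic) < min(intron_window, intron_len)
        or len(acceptor_intronic) < min(intron_window, intron_len))

    return SpliceContext(
        transcript_id=transcript.transcript_id,
        chrom=chrom,
        strand=transcript.strand,
        intron_index=intron_index,
        donor_exonic=donor_exonic,
        donor_intronic=donor_intronic,
        acceptor_intronic=acceptor_intronic,
        acceptor_exonic=acceptor_exonic,
        exon_window=exon_window,
        intron_window=intron_window,
        truncated=truncated,
        windows_overlap=intron_len < 2 * intron_window,
        donor_boundary=donor_boundary,
        acceptor_boundary=acceptor_boundary,
    )


# ---------------------------------------------------------------------------
# Variant application (ref -> alt context editing)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditedContext:
    """Ref and alt splice contexts after applying a variant."""

    ref: SpliceContext
    alt: SpliceContext
    variant: VariantRecord
    length_shift: int  # alt length minus ref length


def trim_variant(variant: VariantRecord) -> tuple:
    """Strip the shared prefix/suffix of REF/ALT.

    Returns (0-based genomic start of the change, removed, added); VCF
    padding bases vanish so indel edits carry minimal coordinates.
    """
    ref, alt = variant.ref, variant.alt
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    s = 0
    while (s < len(ref) - p and s < len(alt) - p
           and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]):
        s += 1
    return variant.pos - 1 + p, ref[p:len(ref) - s], alt[p:len(alt) - s]


def _edit_window(seq: str, win_gstart: int, win_gend: int, strand: str,
                 variant: VariantRecord, start0: int, removed: str,
                 added: str) -> str:
    """Apply a trimmed edit (genomic coordinates) to a sense-strand window
    covering genomic [win_gstart, win_gend). Edits extending past the
    window are clipped; the inserted text lands in the window containing
    the edit start."""
    r_s, r_e = start0, start0 + len(removed)
    overlaps_removal = removed and r_e > win_gstart and r_s < win_gend
    pure_insertion = not removed and win_gstart <= start0 < win_gend
    if not overlaps_removal and not pure_insertion:
        return seq
    plus = seq if strand == "+" else reverse_complement(seq)
    lo = max(r_s, win_gstart)
    hi = min(r_e, win_gend)
    i, j = lo - win_gstart, max(hi - win_gstart, lo - win_gstart)
    expected = removed[lo - r_s:hi - r_s] if removed else ""
    if plus[i:j].upper() != expected:
        raise RefMismatchError(
            f"{variant.chrom}:{variant.pos} window has {plus[i:j]!r}, "
            f"variant REF implies {expected!r}")
    repl = added if win_gstart <= r_s < win_gend or pure_insertion else ""
    edited = plus[:i] + repl + plus[j:]
    return edited if strand == "+" else reverse_complement(edited)


def apply_variant(context: SpliceContext, variant: VariantRecord) -> EditedContext:
    """Apply a variant to a splice context, returning ref and alt contexts.

    The variant must overlap at least one window; REF mismatches raise
    :class:`RefMismatchError` naming the position.
    """
    if variant.chrom != context.chrom:
        raise ValueError(
            f"variant on {variant.chrom} but context on {context.chrom}")
    strand = context.strand
    windows = _window_coords(context)
    start0, removed, added = trim_variant(variant)
    new_seqs = {}
    touched = False
    r_s, r_e = start0, start0 + max(len(removed), 1)
    for name, (seq, gs, ge) in windows.items():
        if r_e > gs and r_s < ge:
            touched = True
            new_seqs[name] = _edit_window(seq, gs, ge, strand, variant,
                                          start0, removed, added)
        else:
            new_seqs[name] = seq
    if not touched:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} does not overlap the "
            f"splice context windows of intron {context.intron_index}")
    alt = replace(
        context,
        donor_exonic=new_seqs["donor_exonic"],
        donor_intronic=new_seqs["donor_intronic"],
        acceptor_intronic=new_seqs["acceptor_intronic"],
        acceptor_exonic=new_seqs["acceptor_exonic"],
        edits=context.edits + (variant,),
    )
    return EditedContext(ref=context, alt=alt, variant=variant,
                         length_shift=len(variant.alt) - len(variant.ref))


def _window_coords(ctx: SpliceContext) -> Mapping[str, tuple]:
    """Genomic [start, end) of each window, keyed by attribute name."""
    out = {}
    if ctx.strand == "+":
        de = (ctx.donor_exonic, ctx.donor_boundary - len(ctx.donor_exonic),
              ctx.donor_boundary)
        di = (ctx.donor_intronic, ctx.donor_boundary,
              ctx.donor_boundary + len(ctx.donor_intronic))
        ai = (ctx.acceptor_intronic,
              ctx.acceptor_boundary + 1 - len(ctx.acceptor_intronic),
              ctx.acceptor_boundary + 1)
        ae = (ctx.acceptor_exonic, ctx.acceptor_boundary + 1,
              ctx.acceptor_boundary + 1 + len(ctx.acceptor_exonic))
    else:
        de = (ctx.donor_exonic, ctx.donor_boundary + 1,
              ctx.donor_boundary + 1 + len(ctx.donor_exonic))
        di = (ctx.donor_intronic, ctx.donor_boundary + 1 - len(ctx.donor_intronic),
              ctx.donor_boundary + 1)
        ai = (ctx.acceptor_intronic, ctx.acceptor_boundary,
              ctx.acceptor_boundary + len(ctx.acceptor_intronic))
        ae = (ctx.acceptor_exonic,
              ctx.acceptor_boundary - len(ctx.acceptor_exonic),
              ctx.acceptor_boundary)
    out["donor_exonic"] = de
    out["donor_intronic"] = di
    out["acceptor_intronic"] = ai
    out["acceptor_exonic"] = ae
    return out


# ---------------------------------------------------------------------------
# Annotation loading (GTF / exon table) and U12 intervals
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict:
    attrs: dict = {}
    for key, value in _GTF_ATTR_RE.findall(text):
        if key == "tag":
            attrs.setdefault("tags", []).append(value)
        else:
            attrs[key] = value
    return attrs


def load_transcript_annotation(source: Union[str, TextIO],
                               canonical_only: bool = False,
                               u12_intervals: Optional[Sequence[tuple]] = None,
                               ) -> list:
    """Load transcripts from a GENCODE-dialect GTF or a TSV exon table.

    GTF: ``exon`` features with ``transcript_id``/``gene_id`` attributes;
    ``canonical_only`` keeps transcripts tagged ``Ensembl_canonical``.
    Exon table: tab-separated ``chrom start end strand transcript_id
    [gene_id]`` with 1-based inclusive start.

    Transcripts with overlapping exons or an unknown strand are rejected
    with a logged diagnostic. Intron classes default to U2 unless a U12
    interval list (``(chrom, start0, end0)``) overlaps an intron.
    """
    close = False
    if isinstance(source, str):
        handle = open(source)
        close = True
    else:
        handle = source
    per_tx: dict = {}
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 9 and fields[2]:
                # GTF row
                if fields[2] != "exon":
                    continue
                chrom, _, _, start, end, _, strand, _, attr_text = fields[:9]
                attrs = _parse_gtf_attributes(attr_text)
                tid = attrs.get("transcript_id")
                if tid is None:
                    continue
                gid = attrs.get("gene_id", "")
                canonical = "Ensembl_canonical" in attrs.get("tags", ())
                rec = per_tx.setdefault(
                    tid, {"gene_id": gid, "chrom": chrom, "strand": strand,
                          "exons": [], "canonical": False})
                rec["canonical"] = rec["canonical"] or canonical
                rec["exons"].append((int(start) - 1, int(end)))
            elif 5 <= len(fields) <= 6:
                chrom, start, end, strand, tid = fields[:5]
                gid = fields[5] if len(fields) == 6 else ""
                rec = per_tx.setdefault(
                    tid, {"gene_id": gid, "chrom": chrom, "strand": strand,
                          "exons": [], "canonical": True})
                rec["exons"].append((int(start) - 1, int(end)))
            else:
                raise ValueError(f"unrecognized annotation row: {line!r}")
    finally:
        if close:
            handle.close()

    out = []
    for tid, rec in per_tx.items():
        if canonical_only and not rec["canonical"]:
            continue
        strand = rec["strand"]
        if strand not in VALID_STRANDS:
            logger.warning("rejecting %s: unknown strand %r", tid, strand)
            continue
        exons = sorted(rec["exons"])
        if strand == "-":
            exons = exons[::-1]
        try:
            tx = TranscriptModel(
                transcript_id=tid, gene_id=rec["gene_id"],
                chrom=rec["chrom"], strand=strand, exons=tuple(exons))
        except ValueError as exc:
            logger.warning("rejecting %s: %s", tid, exc)
            continue
        if u12_intervals:
            classes = []
            for i in range(tx.n_introns):
                s, e = tx.intron_interval(i)
                cls = "U2"
                for uc, us, ue in u12_intervals:
                    if uc == tx.chrom and us < e and ue > s:
                        cls = "U12"
                        break
                classes.append(cls)
            tx = replace(tx, intron_classes=tuple(classes))
        out.append(tx)
    return out


def load_u12_bed(source: Union[str, TextIO]) -> list:
    """Read a BED file of U12 intron intervals -> [(chrom, start0, end0)]."""
    close = False
    if isinstance(source, str):
        handle = open(source)
        close = True
    else:
        handle = source
    out = []
    try:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    finally:
        if close:
            handle.close()
    return out


def load_vcf(source: Union[str, TextIO], genome=None) -> list:
    """Read variants from an (uncompressed) VCF. Multi-allelic rows are
    split; REF is checked against ``genome`` when one is supplied."""
    close = False
    if isinstance(source, str):
        handle = open(source)
        close = True
    else:
        handle = source
    out = []
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"malformed VCF row: {line!r}")
            chrom, pos, vid, ref, alts = f[0], int(f[1]), f[2], f[3], f[4]
            for alt in alts.split(","):
                if alt in (".", "*", "<NON_REF>"):
                    continue
                var = VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                    variant_id=vid)
                if genome is not None:
                    check_variant_ref(var, genome)
                out.append(var)
    finally:
        if close:
            handle.close()
    return out
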