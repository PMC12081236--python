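"""Re-estimation of spliceogenicity and outcome profiles from labeled
variant tables.

A labeled table holds experimentally validated variants with a binary
splice-altering/normal label and optional multi-label splicing outcomes
(exon skipping, truncation, extension, intron retention, pseudoexon
inclusion). Spliceogenicity per subgroup is the splice-altering proportion
with a clamped Wald 95% CI; outcome profiles are multi-label percentages
gated at more than 20 reported SAVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Union

import pandas as pd

SPLICE_ALTERING = "splice-altering"
NORMAL = "normal"

OUTCOME_VOCABULARY = (
    "exon_skipping",
    "exon_truncation",
    "exon_extension",
    "intron_retention",
    "pseudoexon_inclusion",
)

EVIDENCE_COLUMNS = ("chrom", "pos", "ref", "alt", "genome_build",
                    "classification", "outcomes", "method")

Z_95 = 1.96


class EvidenceError(ValueError):
    pass


@dataclass(frozen=True)
class SpliceogenicityEstimate:
    """k-of-n splice-altering proportion with a 95% Wald CI, in percent."""

    k: int
    n: int
    source: str = "user_estimate"

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n or self.n <= 0:
            raise ValueError(f"bad counts k={self.k}, n={self.n}")

    @property
    def p(self) -> float:
        return round(100.0 * self.k / self.n, 1)

    @property
    def ci(self) -> tuple:
        phat = self.k / self.n
        half = Z_95 * math.sqrt(phat * (1 - phat) / self.n)
        lo = max(0.0, (phat - half) * 100.0)
        hi = min(100.0, (phat + half) * 100.0)
        return (round(lo, 1), round(hi, 1))

    def __str__(self) -> str:
        lo, hi = self.ci
        return f"{self.p}% [{lo}-{hi}] (n={self.n})"


@dataclass(frozen=True)
class OutcomeProfile:
    """Multi-label outcome percentages for one splice region.

    Percentages are per reported SAV and may sum past 100; profiles with 20
    or fewer reporting SAVs are not reportable.
    """

    region: str
    n_reported: int
    percentages: Mapping[str, float]
    multi_outcome_rate: float

    @property
    def reportable(self) -> bool:
        return self.n_reported > 20


class LabeledVariantTable:
    """SpliceVarDB-like evidence rows.

    Thin wrapper over a DataFrame with the documented column set; rows with
    labels outside {splice-altering, normal} are dropped at load (the
    high-confidence filter) unless ``strict`` makes them an error.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("classification", "outcomes") if c not in df]
        if missing:
            raise EvidenceError(f"evidence table missing columns {missing}")
        bad = set(df["classification"]) - {SPLICE_ALTERING, NORMAL}
        if bad:
            raise EvidenceError(f"non-binary labels present: {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_splice_altering(self) -> int:
        return int((self.df["classification"] == SPLICE_ALTERING).sum())

    @classmethod
    def from_tsv(cls, path, strict: bool = False) -> "LabeledVariantTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                         keep_default_na=False)
        missing = [c for c in ("classification", "outcomes")
                   if c not in df.columns]
        if missing:
            raise EvidenceError(f"evidence TSV missing columns {missing}")
        known = df["classification"].isin([SPLICE_ALTERING, NORMAL])
        if strict and not known.all():
            unknown = sorted(set(df.loc[~known, "classification"]))
            raise EvidenceError(f"unknown labels in strict mode: {unknown}")
        df = df[known].copy()
        df["outcomes"] = df["outcomes"].map(_parse_outcomes)
        return cls(df)

    def to_tsv(self, path) -> None:
        df = self.df.copy()
        df["outcomes"] = df["outcomes"].map(
            lambda xs: ",".join(xs) if xs else "")
        df.to_csv(path, sep="\t", index=False)


def _parse_outcomes(cell) -> tuple:
    if isinstance(cell, (list, tuple)):
        return tuple(cell)
    text = str(cell).strip()
    if not text or text == ".":
        return ()
    out = []
    for token in text.split(","):
        token = token.strip()
        if token not in OUTCOME_VOCABULARY:
            raise EvidenceError(f"unknown outcome {token!r}")
        out.append(token)
    return tuple(out)


# ---------------------------------------------------------------------------
# Spliceogenicity estimation
# ---------------------------------------------------------------------------


def estimate_spliceogenicity(table: LabeledVariantTable,
                             grouping: Union[str, Sequence[str]] = "subgroup",
                             exclude_u12: bool = True,
                             ) -> Dict[str, SpliceogenicityEstimate]:
    """Per-subgroup splice-altering proportions with 95% CIs.

    ``grouping`` is either a column name of the table or a sequence of
    subgroup labels aligned with its rows. Rows flagged U12 (boolean
    ``u12`` column) are excluded; empty subgroups are simply absent.
    """
    df = table.df
    if isinstance(grouping, str):
        if grouping not in df.columns:
            raise EvidenceError(f"no grouping column {grouping!r}")
        labels = df[grouping]
    else:
        if len(grouping) != len(df):
            raise EvidenceError("grouping length does not match table")
        labels = pd.Series(list(grouping), index=df.index)
    mask = labels.notna() & (labels != "")
    if exclude_u12 and "u12" in df.columns:
        mask &= ~df["u12"].astype(bool)
    sub = df[mask]
    labels = labels[mask]
    out: Dict[str, SpliceogenicityEstimate] = {}
    for name, idx in labels.groupby(labels).groups.items():
        rows = sub.loc[idx]
        k = int((rows["classification"] == SPLICE_ALTERING).sum())
        out[str(name)] = SpliceogenicityEstimate(k=k, n=len(rows))
    return out


def validate_subgroups(estimates: Mapping[str, SpliceogenicityEstimate],
                       min_n: int = 10,
                       min_separation_pct: float = 15.0) -> pd.DataFrame:
    """Flag subgroups that violate the inclusion rules.

    ``insufficient_n``: fewer than 10 supporting variants.
    ``poor_separation``: a context subgroup less than 15 percentage points
    from its rule's standard subgroup.
    """
    rows = []
    for key, est in sorted(estimates.items()):
        rule, _, subgroup = key.partition(":")
        flags = []
        if est.n < min_n:
            flags.append("insufficient_n")
        if subgroup == "context":
            std = estimates.get(f"{rule}:standard")
            if std is not None and abs(std.p - est.p) < min_separation_pct:
                flags.append("poor_separation")
        rows.append({
            "subgroup": key, "k": est.k, "n": est.n, "p": est.p,
            "ci_low": est.ci[0], "ci_high": est.ci[1],
            "flags": ";".join(flags),
            "valid": not flags,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Outcome aggregation
# ---------------------------------------------------------------------------

# splice-region windows used to facet outcome profiles
def region_for_relpos(relpos: Optional[str]) -> str:
    """Map a relative-position label to an outcome-reporting region."""
    if not relpos:
        return "other"
    from heurosplice.transcript_model import RelativePosition
    rel = RelativePosition.parse(relpos)
    if rel.kind == "+":
        return "donor_site" if rel.offset <= 6 else "deep_intronic"
    if rel.kind == "-":
        if rel.offset <= 4:
            return "acceptor_motif"
        if rel.offset <= 24:
            return "ppt"
        if rel.offset <= 50:
            return "branchpoint_region"
        return "deep_intronic"
    if rel.kind == "E-":
        return "donor_site" if rel.offset <= 3 else "exonic"
    return "acceptor_motif" if rel.offset <= 1 else "exonic"


def aggregate_outcomes(table: LabeledVariantTable,
                       grouping: Union[str, Sequence[str], None] = None,
                       ) -> Dict[str, OutcomeProfile]:
    """Multi-label outcome percentages per splice region, SAV rows only.

    The denominator is the number of SAVs with at least one reported
    outcome; a multi-outcome SAV counts once per region. Profiles need
    more than 20 reporting SAVs to be reportable.
    """
    df = table.df
    if grouping is None:
        if "region" in df.columns:
            labels = df["region"]
        elif "relative_position" in df.columns:
            labels = df["relative_position"].map(region_for_relpos)
        else:
            labels = pd.Series(["all"] * len(df), index=df.index)
    elif isinstance(grouping, str):
        labels = df[grouping]
    else:
        labels = pd.Series(list(grouping), index=df.index)

    sav = df["classification"] == SPLICE_ALTERING
    reported = df["outcomes"].map(len) > 0
    keep = sav & reported
    out: Dict[str, OutcomeProfile] = {}
    for name, idx in labels[keep].groupby(labels[keep]).groups.items():
        rows = df.loc[idx, "outcomes"]
        n = len(rows)
        counts = {o: 0 for o in OUTCOME_VOCABULARY}
        multi = 0
        for outcomes in rows:
            if len(set(outcomes)) > 1:
                multi += 1
            for o in set(outcomes):
                counts[o] += 1
        out[str(name)] = OutcomeProfile(
            region=str(name),
            n_reported=n,
            percentages={o: round(100.0 * c / n, 1)
                         for o, c in counts.items()},
            multi_outcome_rate=round(100.0 * multi / n, 1),
        )
    return out
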