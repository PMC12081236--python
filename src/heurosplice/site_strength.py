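"""Splice-site strength scoring.

Two model families share one interface:

* ``pwm_first_order`` — a bundled per-position log-odds model built from
  published splice-site frequency tables (zero downloads, always available).
* ``maxent`` — a scorer compatible with the published maximum-entropy
  scheme; the standard distribution matrix files are read from an external
  plug-in directory (``me2x5`` for the donor, ``me2x3acc1..9`` for the
  acceptor).

All scores are log2 odds in bits. Donor windows are exactly 9 nt spanning
E-3..+6; acceptor windows are exactly 23 nt spanning -20..E+3.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import product
from typing import Dict, List, Optional

PWM_FIRST_ORDER = "pwm_first_order"
MAXENT = "maxent"

DONOR = "donor_9mer"
ACCEPTOR = "acceptor_23mer"

WINDOW_LENGTHS = {DONOR: 9, ACCEPTOR: 23}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# Background and consensus-dinucleotide probabilities of the published
# maximum-entropy scorer.
_ME_BGD = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
_ME_CONS5 = ({"G": 0.9903}, {"T": 0.9884})
_ME_CONS5_OTHER = ((1 - 0.9903) / 3, (1 - 0.9884) / 3)
_ME_CONS3 = ({"A": 0.9903}, {"G": 0.9903})
_ME_CONS3_OTHER = ((1 - 0.9903) / 3, (1 - 0.9903) / 3)

# Acceptor factorization over the 21-mer that remains after removing the
# invariant AG (positions 18,19 of the 23-mer): (offset, length, sign).
_ACC_FACTORS = (
    (0, 7, +1), (7, 7, +1), (14, 7, +1), (4, 7, +1), (11, 7, +1),
    (4, 3, -1), (7, 4, -1), (11, 3, -1), (14, 4, -1),
)


class ScoreModelError(ValueError):
    pass


@dataclass(frozen=True)
class SiteScore:
    """A splice-site strength in log2 bits.

    ``value`` is ``None`` when the window contained an N (indeterminate).
    ``position`` is a caller-supplied boundary coordinate (genomic or
    region-relative), when applicable.
    """

    value: Optional[float]
    site_type: str
    model_kind: str
    position: Optional[int] = None

    @property
    def indeterminate(self) -> bool:
        return self.value is None

    def __repr__(self) -> str:  # compact, 4 dp per reporting convention
        v = "NA" if self.value is None else f"{self.value:.4f}"
        return f"SiteScore({v} bits, {self.site_type}, {self.model_kind})"


@dataclass(frozen=True)
class ScoreModel:
    """Parameter container for one site type under one model family."""

    model_kind: str
    site_type: str
    # pwm: log2-odds matrix, rows = window positions, columns = ACGT
    log_odds: Optional[tuple] = None
    position_labels: Optional[tuple] = None
    # maxent: flat probability tables from the distribution files
    me_donor_table: Optional[tuple] = None
    me_acceptor_tables: Optional[tuple] = None

    @property
    def window_length(self) -> int:
        return WINDOW_LENGTHS[self.site_type]


# ---------------------------------------------------------------------------
# Model loading
# ---------------------------------------------------------------------------


def _load_frequency_json() -> dict:
    path = resources.files("heurosplice.data") / "pwm_frequencies.json"
    with path.open() as fh:
        return json.load(fh)


@lru_cache(maxsize=None)
def load_pwm_model(site_type: str) -> ScoreModel:
    """Bundled first-order position-weight log-odds model."""
    if site_type not in WINDOW_LENGTHS:
        raise ScoreModelError(f"unknown site type {site_type!r}")
    data = _load_frequency_json()
    bgd = data["background"]
    table = data[site_type]
    rows = []
    for freqs in table["frequencies"]:
        rows.append(tuple(math.log2(freqs[b] / bgd[b]) for b in _BASES))
    return ScoreModel(
        model_kind=PWM_FIRST_ORDER,
        site_type=site_type,
        log_odds=tuple(rows),
        position_labels=tuple(table["positions"]),
    )


def pwm_frequencies(site_type: str) -> List[Dict[str, float]]:
    """The raw bundled frequency table (used by the synthetic generator)."""
    return _load_frequency_json()[site_type]["frequencies"]


def _read_me_table(path: str) -> tuple:
    with open(path) as fh:
        return tuple(float(line.strip()) for line in fh if line.strip())


def load_maxent_model(site_type: str, maxent_dir: str) -> ScoreModel:
    """Load matrices in the standard MaxEntScan distribution layout."""
    if site_type == DONOR:
        path = os.path.join(maxent_dir, "me2x5")
        if not os.path.exists(path):
            raise ScoreModelError(f"donor matrix file not found: {path}")
        table = _read_me_table(path)
        if len(table) != 4 ** 7:
            raise ScoreModelError(
                f"me2x5 should have {4**7} rows, found {len(table)}")
        return ScoreModel(model_kind=MAXENT, site_type=DONOR,
                          me_donor_table=table)
    if site_type == ACCEPTOR:
        tables = []
        for i in range(1, 10):
            path = os.path.join(maxent_dir, f"me2x3acc{i}")
            if not os.path.exists(path):
                raise ScoreModelError(f"acceptor matrix file not found: {path}")
            tables.append(_read_me_table(path))
        for tab, (_, length, _) in zip(tables, _ACC_FACTORS):
            if len(tab) != 4 ** length:
                raise ScoreModelError(
                    f"acceptor table has {len(tab)} rows, expected {4**length}")
        return ScoreModel(model_kind=MAXENT, site_type=ACCEPTOR,
                          me_acceptor_tables=tuple(tables))
    raise ScoreModelError(f"unknown site type {site_type!r}")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _kmer_index(kmer: str) -> int:
    idx = 0
    for b in kmer:
        idx = idx * 4 + _BASE_INDEX[b]
    return idx


def _score_pwm(window: str, model: ScoreModel) -> float:
    return sum(row[_BASE_INDEX[b]] for row, b in zip(model.log_odds, window))


def _score_maxent_donor(window: str, model: ScoreModel) -> float:
    c1 = _ME_CONS5[0].get(window[3], _ME_CONS5_OTHER[0])
    c2 = _ME_CONS5[1].get(window[4], _ME_CONS5_OTHER[1])
    rest = window[:3] + window[5:]
    me = model.me_donor_table[_kmer_index(rest)]
    return math.log2(c1 * c2 * me / (_ME_BGD[window[3]] * _ME_BGD[window[4]]))


def _score_maxent_acceptor(window: str, model: ScoreModel) -> float:
    c1 = _ME_CONS3[0].get(window[18], _ME_CONS3_OTHER[0])
    c2 = _ME_CONS3[1].get(window[19], _ME_CONS3_OTHER[1])
    rest = window[:18] + window[20:]
    log_me = 0.0
    for table, (off, length, sign) in zip(model.me_acceptor_tables,
                                          _ACC_FACTORS):
        p = table[_kmer_index(rest[off:off + length])]
        if p <= 0:
            return -math.inf
        log_me += sign * math.log2(p)
    return (math.log2(c1 * c2 / (_ME_BGD[window[18]] * _ME_BGD[window[19]]))
            + log_me)


def _score_window(window: str, model: ScoreModel,
                  position: Optional[int] = None) -> SiteScore:
    expected = model.window_length
    window = window.upper()
    if len(window) != expected:
        raise ScoreModelError(
            f"{model.site_type} window must be {expected} nt, "
            f"got {len(window)}")
    if any(b not in _BASE_INDEX for b in window):
        return SiteScore(value=None, site_type=model.site_type,
                         model_kind=model.model_kind, position=position)
    if model.model_kind == PWM_FIRST_ORDER:
        value = _score_pwm(window, model)
    elif model.site_type == DONOR:
        value = _score_maxent_donor(window, model)
    else:
        value = _score_maxent_acceptor(window, model)
    return SiteScore(value=value, site_type=model.site_type,
                     model_kind=model.model_kind, position=position)


def score_donor(window: str, model: Optional[ScoreModel] = None,
                position: Optional[int] = None) -> SiteScore:
    """Score a 9-mer donor window (E-3..+6)."""
    model = model or load_pwm_model(DONOR)
    if model.site_type != DONOR:
        raise ScoreModelError("score_donor requires a donor model")
    return _score_window(window, model, position)


def score_acceptor(window: str, model: Optional[ScoreModel] = None,
                   position: Optional[int] = None) -> SiteScore:
    """Score a 23-mer acceptor window (-20..E+3)."""
    model = model or load_pwm_model(ACCEPTOR)
    if model.site_type != ACCEPTOR:
        raise ScoreModelError("score_acceptor requires an acceptor model")
    return _score_window(window, model, position)


def combined_intron_strength(donor: SiteScore, acceptor: SiteScore) -> float:
    """Combined splice-site strength across an intron: donor + acceptor."""
    if donor.model_kind != acceptor.model_kind:
        raise ScoreModelError(
            f"cannot combine {donor.model_kind} with {acceptor.model_kind}")
    if donor.indeterminate or acceptor.indeterminate:
        raise ScoreModelError("cannot combine indeterminate scores")
    return donor.value + acceptor.value


# ---------------------------------------------------------------------------
# Model maximum (exact, never sampled)
# ---------------------------------------------------------------------------


def model_max_score(model: ScoreModel) -> float:
    """Maximum achievable score over all N-free windows.

    Factorized (pwm) models maximize per position. Maxent models use the
    table maximum (donor) or dynamic programming over the maximum-entropy
    factorization (acceptor); both are exact.
    """
    if model.model_kind == PWM_FIRST_ORDER:
        return sum(max(row) for row in model.log_odds)
    if model.site_type == DONOR:
        best_me = max(model.me_donor_table)
        cons = max(_ME_CONS5[0].get(b, _ME_CONS5_OTHER[0]) / _ME_BGD[b]
                   for b in _BASES)
        cons *= max(_ME_CONS5[1].get(b, _ME_CONS5_OTHER[1]) / _ME_BGD[b]
                    for b in _BASES)
        return math.log2(cons * best_me)
    return _maxent_acceptor_max(model)


def _maxent_acceptor_max(model: ScoreModel) -> float:
    """Exact max of the acceptor factorization by frontier DP.

    The 21-mer factors all span at most 7 consecutive positions, so a
    max-product sweep keeping the best score per 6-base frontier is exact.
    """
    logs = []
    for table in model.me_acceptor_tables:
        logs.append(tuple(math.log2(p) if p > 0 else -math.inf
                          for p in table))
    by_end: Dict[int, list] = {}
    for fi, (off, length, sign) in enumerate(_ACC_FACTORS):
        by_end.setdefault(off + length - 1, []).append((fi, length, sign))

    # enumerate 6-base prefixes, then extend one position at a time
    dp = {prefix: 0.0 for prefix in product(range(4), repeat=6)}
    for pos in range(6, 21):
        nxt: Dict[tuple, float] = {}
        factors = by_end.get(pos, ())
        for frontier, score in dp.items():
            for nb in range(4):
                window7 = frontier + (nb,)
                s = score
                for fi, length, sign in factors:
                    idx = 0
                    for b in window7[7 - length:]:
                        idx = idx * 4 + b
                    s += sign * logs[fi][idx]
                key = window7[1:]
                if s > nxt.get(key, -math.inf):
                    nxt[key] = s
        dp = nxt
    best_me = max(dp.values())
    cons = max(_ME_CONS3[0].get(b, _ME_CONS3_OTHER[0]) / _ME_BGD[b]
               for b in _BASES)
    cons *= max(_ME_CONS3[1].get(b, _ME_CONS3_OTHER[1]) / _ME_BGD[b]
                for b in _BASES)
    return math.log2(cons) + best_me


# ---------------------------------------------------------------------------
# Candidate-site scanning
# ---------------------------------------------------------------------------


def scan_sites(sequence: str, site_type: str,
               model: Optional[ScoreModel] = None) -> List[SiteScore]:
    """Score every canonical dinucleotide in a sense-strand region.

    Donor: every GT whose 9-mer window (GT at window indices 3-4) fits;
    ``position`` is the 0-based index of the G — the first intron base.
    Acceptor: every AG whose 23-mer window (AG at window indices 18-19)
    fits; ``position`` is the 0-based index of the first exonic base
    (two past the A).
    """
    sequence = sequence.upper()
    if model is None:
        model = load_pwm_model(site_type)
    if model.site_type != site_type:
        raise ScoreModelError("model does not match requested site type")
    out: List[SiteScore] = []
    if site_type == DONOR:
        dinuc, lead, tail = "GT", 3, 6
    else:
        dinuc, lead, tail = "AG", 18, 5
    i = sequence.find(dinuc)
    while i != -1:
        if i >= lead and i + tail <= len(sequence):
            window = sequence[i - lead:i + tail]
            if site_type == DONOR:
                pos = i
            else:
                pos = i + 2
            out.append(_score_window(window, model, position=pos))
        i = sequence.find(dinuc, i + 1)
    return out
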