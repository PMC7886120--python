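"""Pairwise association-rule mining over patient-item matrices.

For an ordered code pair (X, Y) the 2x2 contingency counts over the
cohort of size t are: a (both), b (X only), c (Y only), d (neither),
with a + b + c + d = t.  The three rule indices are

    support    = a / t
    confidence = a / (a + b)
    lift       = {a / (a + b)} / {(a + c) / t}

Lift is 1 under independence of X and Y.  Frequent unordered pairs are
found with the Apriori pruning step — a pair is only counted when both
singleton codes reach the count threshold, which is sound because a
pair's joint count never exceeds either marginal — and both directed
rules of every frequent pair are evaluated, since confidence and lift
are direction-dependent.

The second mining stage restricts the cohort to the stratum of patients
carrying a chosen pre-window antecedent pair and mines the post-window
(complication) matrix of that subset, with t equal to the stratum size.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .claims_io import PatientItemMatrix, PatientJourney, binarize
from .errors import ConfigError, UndefinedIndexError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 co-occurrence counts for an ordered code pair."""

    a: int  # both X and Y
    b: int  # X only
    c: int  # Y only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def t(self) -> int:
        """Cohort size; always a + b + c + d."""
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationRule:
    """Directed rule X -> Y with its contingency count and indices."""

    x_code: str
    y_code: str
    count_a: int
    support: float
    confidence: float
    lift: float


@dataclass(frozen=True)
class RuleFilterConfig:
    """Rule-retention thresholds.

    Defaults follow the study convention for claims cohorts: pairs
    observed in 50 or fewer patients are discarded as infrequent
    (``min_pair_count`` = 51) and only rules with confidence >= 0.5 are
    reported.  ``top_k`` optionally truncates the sorted table for
    reporting.
    """

    min_pair_count: int = 51
    min_confidence: float = 0.5
    top_k: int | None = None

    def __post_init__(self) -> None:
        if self.min_pair_count < 0:
            raise ConfigError("min_pair_count must be >= 0")
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ConfigError("min_confidence must lie in [0, 1]")
        if self.top_k is not None and self.top_k < 1:
            raise ConfigError("top_k must be >= 1 when set")


def contingency(matrix: PatientItemMatrix, x: str, y: str) -> ContingencyTable:
    """Count the 2x2 table of codes x (antecedent) and y over all rows."""
    if x == y:
        raise ValueError("contingency requires two distinct codes")
    xv = matrix.column(x)
    yv = matrix.column(y)
    a = int(np.count_nonzero(xv & yv))
    b = int(np.count_nonzero(xv & ~yv))
    c = int(np.count_nonzero(~xv & yv))
    d = matrix.t - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def rule_indices(ct: ContingencyTable) -> tuple[float, float, float]:
    """Compute (support, confidence, lift) from a contingency table.

    Raises :class:`UndefinedIndexError` when a denominator vanishes:
    confidence needs a + b > 0 (the antecedent occurs) and lift
    additionally needs a + c > 0 (the consequent occurs).
    """
    if ct.t == 0:
        raise ValueError("empty cohort: t = 0")
    support = ct.a / ct.t
    if ct.a + ct.b == 0:
        raise UndefinedIndexError("antecedent never occurs (a + b = 0)")
    confidence = ct.a / (ct.a + ct.b)
    if ct.a + ct.c == 0:
        raise UndefinedIndexError("consequent never occurs (a + c = 0)")
    lift = confidence / ((ct.a + ct.c) / ct.t)
    return support, confidence, lift


def frequent_pairs(
    matrix: PatientItemMatrix, min_count: int
) -> list[tuple[str, str, int]]:
    """All unordered code pairs with joint count >= ``min_count``.

    Apriori pruning: only codes whose singleton count reaches the
    threshold are candidates for pairing.  Pairs are returned with
    x < y lexicographically, sorted by (x, y).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    singles = matrix.values.sum(axis=0)
    keep = np.flatnonzero(singles >= min_count)
    if keep.size < 2:
        return []
    sub = matrix.values[:, keep].astype(np.int64)
    joint = sub.T @ sub  # joint[i, j] = count of patients with both codes
    out: list[tuple[str, str, int]] = []
    for ii in range(keep.size):
        for jj in range(ii + 1, keep.size):
            cnt = int(joint[ii, jj])
            if cnt >= min_count:
                out.append((matrix.codes[keep[ii]], matrix.codes[keep[jj]], cnt))
    return out


def mine_rules(
    matrix: PatientItemMatrix, filt: RuleFilterConfig | None = None
) -> list[AssociationRule]:
    """Mine directed association rules from one window's matrix.

    Both orientations of every frequent unordered pair are evaluated;
    a directed rule survives iff its joint count reaches
    ``filt.min_pair_count`` and its confidence reaches
    ``filt.min_confidence``.  Output is sorted by support descending,
    then confidence descending, then (x_code, y_code); truncated to
    ``top_k`` when set.
    """
    filt = filt or RuleFilterConfig()
    if matrix.t == 0:
        raise ValueError("empty cohort: t = 0")
    t = matrix.t
    singles = {c: int(n) for c, n in zip(matrix.codes, matrix.values.sum(axis=0))}
    rules: list[AssociationRule] = []
    for x, y, cnt in frequent_pairs(matrix, max(filt.min_pair_count, 1)):
        for ante, cons in ((x, y), (y, x)):
            n_ante = singles[ante]
            n_cons = singles[cons]
            # cnt >= 1 guarantees both denominators are positive
            support = cnt / t
            confidence = cnt / n_ante
            lift = confidence / (n_cons / t)
            if cnt >= filt.min_pair_count and confidence >= filt.min_confidence:
                rules.append(
                    AssociationRule(ante, cons, cnt, support, confidence, lift)
                )
    rules.sort(key=lambda r: (-r.support, -r.confidence, r.x_code, r.y_code))
    if filt.top_k is not None:
        rules = rules[: filt.top_k]
    return rules


def stratified_rules(
    journeys: Sequence[PatientJourney],
    antecedent: tuple[str, str],
    filt: RuleFilterConfig | None = None,
) -> tuple[int, list[AssociationRule]]:
    """Second-stage mining of post-window rules within a pre-window stratum.

    The stratum is the subset of journeys carrying both antecedent codes
    in their pre-window set; its size equals the contingency ``a`` of the
    antecedent pair on the pre matrix and becomes the t of the stratified
    analysis.  Returns ``(stratum_size, rules)``; an empty stratum yields
    ``(0, [])``.
    """
    x, y = antecedent
    if x == y:
        raise ValueError("antecedent codes must be distinct")
    subset = [j for j in journeys if x in j.pre_codes and y in j.pre_codes]
    if not subset:
        logger.info("stratum (%s, %s) is empty; no rules mined", x, y)
        return 0, []
    post = binarize(subset, "post")
    return len(subset), mine_rules(post, filt)


_HEADER = [
    "rule_index",
    "antecedent",
    "consequent",
    "support_pct",
    "confidence_pct",
    "lift",
    "count_a",
    "support_exact",
    "confidence_exact",
    "lift_exact",
]


def write_rule_table(rules: Sequence[AssociationRule], path: str | Path) -> None:
    """Write a rule table CSV.

    Display columns round support/confidence to one decimal percent and
    lift to one decimal, matching the conventional presentation of rule
    tables; the ``*_exact`` columns keep full precision (shortest float
    repr, so a round-trip read reproduces the values bit-for-bit).
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        for i, r in enumerate(rules, start=1):
            w.writerow(
                [
                    i,
                    r.x_code,
                    r.y_code,
                    f"{r.support * 100:.1f}",
                    f"{r.confidence * 100:.1f}",
                    f"{r.lift:.1f}",
                    r.count_a,
                    repr(r.support),
                    repr(r.confidence),
                    repr(r.lift),
                ]
            )


def read_rule_table(path: str | Path) -> list[AssociationRule]:
    """Read back a rule table written by :func:`write_rule_table`."""
    rules: list[AssociationRule] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ConfigError(f"rule table missing column(s): {sorted(missing)}")
        for row in reader:
            rules.append(
                AssociationRule(
                    x_code=row["antecedent"],
                    y_code=row["consequent"],
                    count_a=int(row["count_a"]),
                    support=float(row["support_exact"]),
                    confidence=float(row["confidence_exact"]),
                    lift=float(row["lift_exact"]),
                )
            )
    return rules
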