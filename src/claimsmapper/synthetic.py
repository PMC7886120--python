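"""Synthetic claims generator with planted co-occurrence structure.

Real claims databases are proprietary, so the pipeline is exercised on
synthetic cohorts whose association structure is known exactly.  Each
patient receives one index-diagnosis claim at a random calendar date;
diagnosis categories are then planted in the pre- and post-index windows
either independently (background codes) or as dependent pairs
(:class:`PlantedRule`: X ~ Bernoulli(p_x), Y | X ~ Bernoulli(conf),
Y | not-X ~ Bernoulli(p_y_base)).  The closed-form rule indices of a
planted pair follow directly:

    support    = p_x * conf
    confidence = conf
    lift       = conf / (p_x * conf + (1 - p_x) * p_y_base)

so mined estimates can be compared against ground truth.  A second-stage
construct, :class:`StratifiedPlantedRule`, plants a post-window pair only
inside the stratum of patients carrying a given pre-window code pair
(outside the stratum X and Y are independent), which is what stratified
rule mining is meant to detect.

Event dates are uniform strictly inside their window; the analysis
discards within-window timing, so the date distribution only exercises
the windowing code.  Each present code is emitted once by default
(`claims_per_code` adds exact duplicate rows for duplicate-handling
tests).  Generation is fully reproducible from the mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .claims_io import ClaimsTable
from .errors import ConfigError, UndefinedIndexError

#: earliest index date and span (days) over which index dates are uniform;
#: leaves room for two full 730-day windows inside a 2005--2018 observation
#: period, mimicking a multi-year enrollment database.
_INDEX_EPOCH = date(2007, 1, 1)
_INDEX_SPAN_DAYS = 3318  # through 2016-02-01


def _check_prob(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class PlantedRule:
    """A dependent code pair planted in one window."""

    x_code: str
    y_code: str
    p_x: float
    conf: float
    p_y_base: float
    window: Literal["pre", "post"] = "pre"

    def __post_init__(self) -> None:
        _check_prob(self.p_x, "p_x")
        _check_prob(self.conf, "conf")
        _check_prob(self.p_y_base, "p_y_base")
        if self.x_code == self.y_code:
            raise ConfigError("planted rule requires distinct codes")
        if self.window not in ("pre", "post"):
            raise ConfigError(f"window must be 'pre' or 'post', got {self.window!r}")


@dataclass(frozen=True)
class StratifiedPlantedRule:
    """A post-window pair that exists only inside a pre-window stratum.

    Patients with both ``pre_x`` and ``pre_y`` in their pre-window set
    receive the post-window rule as planted; for everyone else X and Y
    are drawn independently (Y at rate ``rule.p_y_base``), so the pair's
    confidence is diluted unless mining is restricted to the stratum.
    """

    pre_x: str
    pre_y: str
    rule: PlantedRule

    def __post_init__(self) -> None:
        if self.rule.window != "post":
            raise ConfigError("stratified planted rule must target the post window")
        if self.pre_x == self.pre_y:
            raise ConfigError("stratum antecedent codes must be distinct")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    n_patients: int = 5000
    background_codes: Mapping[str, float] = field(default_factory=dict)
    planted_rules: tuple[PlantedRule, ...] = ()
    stratified_rules: tuple[StratifiedPlantedRule, ...] = ()
    index_code: str = "F32"
    pre_window_days: int = 730
    post_window_days: int = 730
    claims_per_code: int = 1

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.claims_per_code < 1:
            raise ConfigError("claims_per_code must be >= 1")
        for code, p in self.background_codes.items():
            _check_prob(p, f"background probability of {code}")
        planted = set()
        for r in self.planted_rules:
            planted.update((r.x_code, r.y_code))
        for s in self.stratified_rules:
            planted.update((s.rule.x_code, s.rule.y_code))
        clash = planted & set(self.background_codes)
        if clash:
            raise ConfigError(
                f"planted codes must be disjoint from background codes: {sorted(clash)}"
            )
        if self.index_code in planted or self.index_code in self.background_codes:
            raise ConfigError("index_code cannot be planted or background")


def expected_indices(rule: PlantedRule) -> tuple[float, float, float]:
    """Closed-form (support, confidence, lift) of a planted pair.

    Raises :class:`UndefinedIndexError` when the consequent is impossible
    (marginal P(Y) = 0), in which case lift has a zero denominator.
    """
    support = rule.p_x * rule.conf
    p_y = rule.p_x * rule.conf + (1.0 - rule.p_x) * rule.p_y_base
    if p_y == 0.0:
        raise UndefinedIndexError(
            f"consequent {rule.y_code} has zero marginal probability; lift undefined"
        )
    return support, rule.conf, rule.conf / p_y


def _draw_pair(
    rng: np.random.Generator, n: int, p_x: float, conf: float, p_y_base: float
) -> tuple[np.ndarray, np.ndarray]:
    x = rng.random(n) < p_x
    y = np.where(x, rng.random(n) < conf, rng.random(n) < p_y_base)
    return x, y


def generate_claims(config: SyntheticConfig) -> ClaimsTable:
    """Generate a synthetic :class:`~claimsmapper.claims_io.ClaimsTable`.

    Every patient gets exactly one index claim; planted and background
    codes are materialised as claims at uniform random dates strictly
    inside their window.  The output is deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patient_ids = np.array([f"P{i:06d}" for i in range(n)])
    index_offsets = rng.integers(0, _INDEX_SPAN_DAYS + 1, size=n)
    index_dates = np.array(
        [_INDEX_EPOCH + timedelta(days=int(d)) for d in index_offsets]
    )

    # presence[window][code] = bool mask over patients; draw order is fixed
    # (planted rules, stratified rules, background in sorted code order) so
    # identical seeds give identical cohorts.
    presence: dict[str, dict[str, np.ndarray]] = {"pre": {}, "post": {}}

    def _add(window: str, code: str, mask: np.ndarray) -> None:
        prev = presence[window].get(code)
        presence[window][code] = mask if prev is None else (prev | mask)

    for r in config.planted_rules:
        x, y = _draw_pair(rng, n, r.p_x, r.conf, r.p_y_base)
        _add(r.window, r.x_code, x)
        _add(r.window, r.y_code, y)

    for s in config.stratified_rules:
        r = s.rule
        x, y_in = _draw_pair(rng, n, r.p_x, r.conf, r.p_y_base)
        y_out = rng.random(n) < r.p_y_base  # independent outside the stratum
        pre_x = presence["pre"].get(s.pre_x, np.zeros(n, dtype=bool))
        pre_y = presence["pre"].get(s.pre_y, np.zeros(n, dtype=bool))
        stratum = pre_x & pre_y
        _add("post", r.x_code, x)
        _add("post", r.y_code, np.where(stratum, y_in, y_out))

    for code in sorted(config.background_codes):
        p = config.background_codes[code]
        _add("pre", code, rng.random(n) < p)
        _add("post", code, rng.random(n) < p)

    frames = [
        pd.DataFrame(
            {
                "patient_id": patient_ids,
                "code": config.index_code,
                "date": pd.to_datetime(index_dates),
            }
        )
    ]
    window_days = {"pre": config.pre_window_days, "post": config.post_window_days}
    sign = {"pre": -1, "post": 1}
    for window in ("pre", "post"):
        for code in sorted(presence[window]):
            mask = presence[window][code]
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            offsets = rng.integers(1, window_days[window] + 1, size=idx.size)
            dates = [
                index_dates[i] + timedelta(days=sign[window] * int(o))
                for i, o in zip(idx, offsets)
            ]
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": patient_ids[idx],
                        "code": code,
                        "date": pd.to_datetime(dates),
                    }
                )
            )

    df = pd.concat(frames, ignore_index=True)
    if config.claims_per_code > 1:
        df = pd.concat([df] * config.claims_per_code, ignore_index=True)
    df = df.sort_values(["patient_id", "date", "code"], kind="mergesort").reset_index(
        drop=True
    )
    return ClaimsTable(df)


def write_ground_truth(config: SyntheticConfig, path: str | Path) -> None:
    """Write planted rules and their closed-form indices as JSON."""
    def _entry(rule: PlantedRule) -> dict:
        support, conf, lift = expected_indices(rule)
        return {
            **asdict(rule),
            "expected_support": support,
            "expected_confidence": conf,
            "expected_lift": lift,
        }

    doc = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "index_code": config.index_code,
        "planted_rules": [_entry(r) for r in config.planted_rules],
        "stratified_rules": [
            {"pre_x": s.pre_x, "pre_y": s.pre_y, "rule": _entry(s.rule)}
            for s in config.stratified_rules
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


#: background category probabilities for the default study cohort: ~50
#: common ambulatory ICD-10 categories with geometrically decaying
#: per-window prevalence (0.30 down to ~0.01), giving each patient a
#: realistic multi-code history.
_DEFAULT_BACKGROUND = {
    code: round(0.30 * 0.93**i, 4)
    for i, code in enumerate(
        [
            "J06", "M54", "I10", "E78", "J20", "H52", "B34", "L20", "N39",
            "R51", "K59", "J02", "J03", "M25", "S93", "H66", "J01", "R11",
            "T14", "L30", "H04", "E11", "M79", "K02", "K05", "J45", "N76",
            "R42", "M17", "D22", "L98", "H25", "B00", "K12", "R05", "J11",
            "N30", "E03", "M75", "G43", "F43", "H81", "L50", "R00", "K63",
            "E04", "M62", "H35", "L70", "R10",
        ]
    )
}


def default_study_config(seed: int, n_patients: int = 5000) -> SyntheticConfig:
    """The package's default synthetic study cohort.

    Emulates an index-diagnosis depression cohort: F32 index claims, a
    few thousand patients, ~80 distinct categories, and a dozen planted
    pre-onset pairs whose closed-form indices sit in the range reported
    for common claims cohorts (support 2-9%, confidence 0.5-0.75, lift
    1.1-6): anxiety -> sleep disorder, gastroenteritis -> gastritis,
    reflux -> dyspepsia, conjunctivitis -> allergic rhinitis, and eight
    further organ-system pairs.  One stratified post-onset pair (common
    cold -> gastric ulcer at confidence 0.59) exists only inside the
    anxiety+sleep-disorder stratum, exercising the second mining stage.
    """
    planted = (
        PlantedRule("F41", "G47", p_x=0.180, conf=0.550, p_y_base=0.35, window="pre"),
        PlantedRule("A09", "K29", p_x=0.162, conf=0.505, p_y_base=0.31, window="pre"),
        PlantedRule("K21", "K30", p_x=0.124, conf=0.582, p_y_base=0.30, window="pre"),
        PlantedRule("H10", "J30", p_x=0.117, conf=0.520, p_y_base=0.20, window="pre"),
        PlantedRule("E66", "E14", p_x=0.100, conf=0.550, p_y_base=0.15, window="pre"),
        PlantedRule("I20", "I25", p_x=0.060, conf=0.700, p_y_base=0.08, window="pre"),
        PlantedRule("M51", "M47", p_x=0.090, conf=0.600, p_y_base=0.18, window="pre"),
        PlantedRule("H40", "H53", p_x=0.070, conf=0.650, p_y_base=0.12, window="pre"),
        PlantedRule("J32", "J33", p_x=0.110, conf=0.560, p_y_base=0.22, window="pre"),
        PlantedRule("N94", "N95", p_x=0.050, conf=0.720, p_y_base=0.06, window="pre"),
        PlantedRule("L23", "L24", p_x=0.080, conf=0.580, p_y_base=0.10, window="pre"),
        PlantedRule("G44", "G50", p_x=0.060, conf=0.660, p_y_base=0.09, window="pre"),
    )
    stratified = (
        StratifiedPlantedRule(
            "F41",
            "G47",
            PlantedRule("J00", "K25", p_x=0.28, conf=0.593, p_y_base=0.33, window="post"),
        ),
    )
    return SyntheticConfig(
        seed=seed,
        n_patients=n_patients,
        background_codes=_DEFAULT_BACKGROUND,
        planted_rules=planted,
        stratified_rules=stratified,
    )
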