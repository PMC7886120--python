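"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's vectorised code paths: everything
is a plain double loop over codes and rows, so agreement with the fast
implementations is meaningful.
"""

from __future__ import annotations

import numpy as np

from claimsmapper.claims_io import PatientItemMatrix


def make_matrix(code_sets: list[set[str]]) -> PatientItemMatrix:
    """Build a PatientItemMatrix directly from per-patient code sets."""
    codes = tuple(sorted(set().union(*code_sets) if code_sets else set()))
    values = np.zeros((len(code_sets), len(codes)), dtype=bool)
    for i, s in enumerate(code_sets):
        for j, c in enumerate(codes):
            values[i, j] = c in s
    return PatientItemMatrix(
        patient_ids=tuple(f"p{i}" for i in range(len(code_sets))),
        codes=codes,
        values=values,
    )


def brute_force_pairs(
    matrix: PatientItemMatrix, min_count: int
) -> list[tuple[str, str, int]]:
    """Exhaustive enumeration of unordered pairs with joint count >= min_count."""
    out = []
    codes = matrix.codes
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            cnt = 0
            for row in range(matrix.t):
                if matrix.values[row, i] and matrix.values[row, j]:
                    cnt += 1
            if cnt >= min_count:
                out.append((codes[i], codes[j], cnt))
    return out


def brute_force_rules(
    matrix: PatientItemMatrix, min_count: int, min_confidence: float
) -> list[tuple[str, str, int, float, float, float]]:
    """Exhaustive directed-rule enumeration with direct index formulas.

    Returns (x, y, a, support, confidence, lift) for every ordered pair
    with a >= min_count and a/(a+b) >= min_confidence, unsorted.
    """
    out = []
    codes = matrix.codes
    t = matrix.t
    for i in range(len(codes)):
        for j in range(len(codes)):
            if i == j:
                continue
            a = b = c = 0
            for row in range(t):
                xi, yj = matrix.values[row, i], matrix.values[row, j]
                if xi and yj:
                    a += 1
                elif xi:
                    b += 1
                elif yj:
                    c += 1
            if a < min_count or a == 0:
                continue
            support = a / t
            confidence = a / (a + b)
            lift = confidence / ((a + c) / t)
            if confidence >= min_confidence:
                out.append((codes[i], codes[j], a, support, confidence, lift))
    return out


def random_matrix(rng: np.random.Generator, n_codes: int, n_patients: int) -> PatientItemMatrix:
    """A random binary matrix with heterogeneous column prevalences."""
    probs = rng.uniform(0.05, 0.7, size=n_codes)
    values = rng.random((n_patients, n_codes)) < probs
    codes = tuple(f"C{i:02d}" for i in range(n_codes))
    return PatientItemMatrix(
        patient_ids=tuple(f"p{i}" for i in range(n_patients)),
        codes=codes,
        values=values,
    )
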