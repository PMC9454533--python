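"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive enumeration, literal rule
transcription, textbook formulas.  None of it shares code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

PATHOGENIC_ALPHABET = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_ALPHABET = ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
FULL_ALPHABET = PATHOGENIC_ALPHABET + BENIGN_ALPHABET


def acmg_oracle(codes) -> str:
    """Literal transcription of the 2015 combining-rule table."""
    codes = set(codes)
    pvs1 = "PVS1" in codes
    ps = len([c for c in codes if c[:2] == "PS"])
    pm = len([c for c in codes if c[:2] == "PM"])
    pp = len([c for c in codes if c[:2] == "PP"])
    ba1 = "BA1" in codes
    bs = len([c for c in codes if c[:2] == "BS"])
    bp = len([c for c in codes if c[:2] == "BP"])

    pathogenic_rules = [
        pvs1 and ps >= 1,
        pvs1 and pm >= 2,
        pvs1 and pm == 1 and pp >= 1,
        pvs1 and pp >= 2,
        ps >= 2,
        ps == 1 and pm >= 3,
        ps == 1 and pm == 2 and pp >= 2,
        ps == 1 and pm == 1 and pp >= 4,
    ]
    likely_pathogenic_rules = [
        pvs1 and pm == 1,
        ps == 1 and pm in (1, 2),
        ps == 1 and pp >= 2,
        pm >= 3,
        pm == 2 and pp >= 2,
        pm == 1 and pp >= 4,
    ]
    benign_rules = [ba1, bs >= 2]
    likely_benign_rules = [bs == 1 and bp >= 1, bp >= 2]

    path_side = any(pathogenic_rules) or any(likely_pathogenic_rules)
    benign_side = any(benign_rules) or any(likely_benign_rules)
    if path_side and benign_side:
        return "VUS"
    if any(pathogenic_rules):
        return "pathogenic"
    if any(likely_pathogenic_rules):
        return "likely_pathogenic"
    if any(benign_rules):
        return "benign"
    if any(likely_benign_rules):
        return "likely_benign"
    return "VUS"


def all_code_subsets(max_size: int = 3):
    for k in range(max_size + 1):
        yield from itertools.combinations(FULL_ALPHABET, k)


def wilcoxon_exact_enum(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns.

    Requires nonzero differences with untied magnitudes.
    """
    d = np.asarray(diffs, dtype=float)
    assert (d != 0).all()
    absd = np.abs(d)
    assert len(set(absd)) == len(absd), "oracle requires untied magnitudes"
    ranks = absd.argsort().argsort() + 1.0
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_lo, w_hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_lo or w >= w_hi:
            count += 1
    return count / 2 ** len(d)


def midrank(values) -> np.ndarray:
    """Mid-ranks (average ranks for ties), computed by sorting from scratch."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Spearman rho as the Pearson correlation of mid-ranks."""
    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def chi2_2x2_closed_form(a, b, c, d) -> float:
    """Pearson chi-square for a 2x2 table, textbook closed form."""
    n = a + b + c + d
    return (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))


def enumerate_equivalent_representations(sequence: str, pos: int, ref: str, alt: str):
    """All (pos, ref, alt) triples that perform the same edit on ``sequence``.

    ``sequence`` is the chromosome context with 1-based coordinates.  The
    canonical representation is the minimal-total-allele-length one at the
    smallest position.
    """
    target = sequence[: pos - 1] + alt + sequence[pos - 1 + len(ref) :]
    reps = []
    for p in range(1, len(sequence) + 1):
        for ref_len in range(0, len(sequence) - p + 2):
            cand_ref = sequence[p - 1 : p - 1 + ref_len]
            alt_len = len(target) - (len(sequence) - ref_len)
            if alt_len < 0:
                continue
            cand_alt = target[p - 1 : p - 1 + alt_len]
            edited = sequence[: p - 1] + cand_alt + sequence[p - 1 + ref_len :]
            if edited == target and cand_ref != cand_alt and cand_ref and cand_alt:
                reps.append((p, cand_ref, cand_alt))
    return reps


def canonical_representation(sequence: str, pos: int, ref: str, alt: str):
    reps = enumerate_equivalent_representations(sequence, pos, ref, alt)
    return min(reps, key=lambda r: (len(r[1]) + len(r[2]), r[0]))
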