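"""Random-involvement null model for telomere fusions.

The null is a uniform choice over unordered pairs of distinct telomeres
(no self-pairing, no sister-chromatid pairing).  Marginal involvement is
then proportional to category member count, which yields the standard
expected frequencies for the 16-telomere complements (males: A 50%,
XL 6.25%, XR 6.25%, 4th 25%, Y 12.5%; females: A 50%, XL 12.5%, XR 12.5%,
4th 25%).

Two independent routes are provided: closed-form combinatorics on the
census, and brute-force enumeration of the full pair space
(:func:`enumerate_pair_space` plus the ``pair_space_*`` marginal helpers).
All rational quantities are returned as :class:`fractions.Fraction` so
identities hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Mapping

import pandas as pd

from .karyotype import KaryotypeConfig, KaryotypeError, telomere_census

__all__ = [
    "NullExpectation",
    "expected_involvement_frequencies",
    "expected_counts",
    "ring_probability",
    "enumerate_pair_space",
    "pair_space_marginals",
    "pair_space_ring_fraction",
    "null_expectation",
    "expectations_table",
]

Conditioning = Literal["given_Y_fusion", "given_Y_het_partner"]
Space = Literal["per_telomere", "per_pair"]


@dataclass(frozen=True)
class NullExpectation:
    """Per-category expectations under random involvement.

    ``ring_prob_given_Y`` / ``ring_prob_given_Y_het_partner`` are ``None``
    for karyotypes without a Y chromosome.
    """

    freq: Mapping[str, Fraction]
    expected_counts: Mapping[str, Fraction] | None
    ring_prob_given_Y: Fraction | None
    ring_prob_given_Y_het_partner: Fraction | None


def expected_involvement_frequencies(karyotype: KaryotypeConfig) -> dict[str, Fraction]:
    """Expected fraction of fused telomeres per category.

    Equals ``member_count / total_telomeres`` for each category; values sum
    to 1 exactly.
    """
    n = karyotype.total_telomeres
    if n < 2:
        raise KaryotypeError("need at least 2 telomeres for a fusion null model")
    return {c: Fraction(m, n) for c, m in telomere_census(karyotype).items()}


def expected_counts(
    total_fts: int | float, freq: Mapping[str, Fraction | float]
) -> dict[str, Fraction]:
    """Expected FT counts per category for a given total number of fused
    telomeres: ``total_fts * freq_c``; values sum to ``total_fts``."""
    if total_fts < 0:
        raise ValueError("total_fts must be non-negative")
    return {c: Fraction(total_fts) * Fraction(f) for c, f in freq.items()}


def _y_telomeres(karyotype: KaryotypeConfig):
    ys = [t for t in karyotype.telomeres if t.chromosome == "Y"]
    if not ys:
        raise KaryotypeError("karyotype has no Y chromosome")
    return ys


def ring_probability(
    karyotype: KaryotypeConfig,
    conditioning: Conditioning,
    *,
    space: Space = "per_telomere",
) -> Fraction:
    """Probability that a Y-involving fusion closes a ring (YL-YS of one Y).

    ``space="per_telomere"`` (default) conditions per fusing Y telomere:
    its partner is uniform over the eligible partners, exactly one of which
    is the other arm of the same Y.  For the wildtype male complement this
    gives 1/15 (``given_Y_fusion``: any of the other 15 telomeres) and 1/6
    (``given_Y_het_partner``: the 6 heterochromatin-associated partners).

    ``space="per_pair"`` conditions on the set of Y-involving unordered
    pairs instead (1/29 and 1/11 for the male complement); exposed for
    comparison, not the default.
    """
    ys = _y_telomeres(karyotype)
    telomeres = karyotype.telomeres
    n = len(telomeres)

    def is_ring_partner(a, b) -> bool:
        return a.chromosome == b.chromosome == "Y" and a.homolog == b.homolog and a is not b

    def eligible(anchor, partner) -> bool:
        if partner is anchor:
            return False
        if conditioning == "given_Y_fusion":
            return True
        if conditioning == "given_Y_het_partner":
            return partner.het_associated
        raise ValueError(f"unknown conditioning {conditioning!r}")

    if space == "per_telomere":
        probs = []
        for anchor in ys:
            partners = [p for p in telomeres if eligible(anchor, p)]
            if not partners:
                continue
            rings = sum(is_ring_partner(anchor, p) for p in partners)
            probs.append(Fraction(rings, len(partners)))
        if not probs:
            raise KaryotypeError("no eligible partners for any Y telomere")
        return sum(probs, Fraction(0)) / len(probs)

    if space == "per_pair":
        num = den = 0
        for i, a in enumerate(telomeres):
            for b in telomeres[i + 1 :]:
                y_end = a.chromosome == "Y" or b.chromosome == "Y"
                if not y_end:
                    continue
                # pair is in the conditioning set if either Y end sees the
                # other end as an eligible partner
                ok = (a.chromosome == "Y" and eligible(a, b)) or (
                    b.chromosome == "Y" and eligible(b, a)
                )
                if not ok:
                    continue
                den += 1
                num += is_ring_partner(a, b)
        if den == 0:
            raise KaryotypeError("empty conditioning set for ring probability")
        return Fraction(num, den)

    raise ValueError(f"unknown space {space!r}")


def enumerate_pair_space(karyotype: KaryotypeConfig) -> pd.DataFrame:
    """All C(n, 2) unordered telomere pairs with category and ring annotations.

    Serves as the brute-force oracle for the closed-form expectations.
    Columns: ``a``/``b`` (telomere labels), ``category_a``/``category_b``,
    ``het_a``/``het_b`` (heterochromatin-associated flags), ``is_ring``
    (both ends of the same chromosome copy) and ``y_count`` (number of Y
    telomeres in the pair).
    """
    telomeres = karyotype.telomeres
    rows = []
    for i, a in enumerate(telomeres):
        for b in telomeres[i + 1 :]:
            rows.append(
                {
                    "a": str(a),
                    "b": str(b),
                    "category_a": a.category,
                    "category_b": b.category,
                    "het_a": a.het_associated,
                    "het_b": b.het_associated,
                    "is_ring": a.chromosome == b.chromosome and a.homolog == b.homolog,
                    "y_count": (a.chromosome == "Y") + (b.chromosome == "Y"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "a",
            "b",
            "category_a",
            "category_b",
            "het_a",
            "het_b",
            "is_ring",
            "y_count",
        ],
    )


def pair_space_marginals(pair_space: pd.DataFrame) -> dict[str, Fraction]:
    """Exact per-category involvement marginals of a uniform pair choice."""
    slots = 2 * len(pair_space)
    counts: dict[str, int] = {}
    for col in ("category_a", "category_b"):
        for cat, k in pair_space[col].value_counts().items():
            counts[cat] = counts.get(cat, 0) + int(k)
    from .karyotype import CATEGORIES

    return {c: Fraction(counts[c], slots) for c in CATEGORIES if c in counts}


def pair_space_ring_fraction(
    pair_space: pd.DataFrame,
    conditioning: Conditioning,
    *,
    space: Space = "per_telomere",
) -> Fraction:
    """Conditional YL-YS ring fraction computed from the enumerated table.

    ``per_telomere`` expands each pair into its Y-anchored ordered versions
    (one per Y end whose partner satisfies the conditioning) so that the
    conditioning matches :func:`ring_probability`'s default definition.
    """
    a_is_y = pair_space["category_a"] == "Y"
    b_is_y = pair_space["category_b"] == "Y"
    if conditioning == "given_Y_fusion":
        ok_a, ok_b = a_is_y, b_is_y
    elif conditioning == "given_Y_het_partner":
        ok_a = a_is_y & pair_space["het_b"]
        ok_b = b_is_y & pair_space["het_a"]
    else:
        raise ValueError(f"unknown conditioning {conditioning!r}")

    if space == "per_telomere":
        weights = ok_a.astype(int) + ok_b.astype(int)
        den = int(weights.sum())
        num = int(weights[pair_space["is_ring"]].sum())
    elif space == "per_pair":
        in_set = ok_a | ok_b
        den = int(in_set.sum())
        num = int((in_set & pair_space["is_ring"]).sum())
    else:
        raise ValueError(f"unknown space {space!r}")
    if den == 0:
        raise KaryotypeError("empty conditioning set in pair space")
    return Fraction(num, den)


def null_expectation(
    karyotype: KaryotypeConfig, total_fts: int | None = None
) -> NullExpectation:
    """Bundle the full null expectation for a karyotype."""
    freq = expected_involvement_frequencies(karyotype)
    counts = expected_counts(total_fts, freq) if total_fts is not None else None
    if karyotype.has_chromosome("Y"):
        ring_y = ring_probability(karyotype, "given_Y_fusion")
        ring_het = ring_probability(karyotype, "given_Y_het_partner")
    else:
        ring_y = ring_het = None
    return NullExpectation(
        freq=freq,
        expected_counts=counts,
        ring_prob_given_Y=ring_y,
        ring_prob_given_Y_het_partner=ring_het,
    )


def expectations_table(
    karyotype: KaryotypeConfig, total_fts: int | None = None
) -> pd.DataFrame:
    """Tabular export: category, member_count, expected_freq, expected_pct
    (and expected_count when a total is supplied)."""
    census = telomere_census(karyotype)
    freq = expected_involvement_frequencies(karyotype)
    table = pd.DataFrame(
        {
            "category": list(census),
            "member_count": [census[c] for c in census],
            "expected_freq": [str(freq[c]) for c in census],
            "expected_pct": [float(freq[c] * 100) for c in census],
        }
    )
    if total_fts is not None:
        table["expected_count"] = [float(freq[c] * total_fts) for c in census]
    return table
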