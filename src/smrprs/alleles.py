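"""Strand-agnostic allele harmonization of summary-statistic records.

All joins across GWAS, QTL and genotype files orient every record to a
common effect allele: when a record's alleles are swapped relative to the
reference orientation its effect size is negated and its frequency
complemented; strand flips (A<->T, C<->G) are resolved by complementing;
palindromic variants (A/T, C/G) are kept only when allele frequency is
informative enough (|eaf - 0.5| > 0.08 on both sides) to orient them.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["HarmonizeResult", "harmonize"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}

PALINDROME_FREQ_MARGIN = 0.08


@dataclass(frozen=True)
class HarmonizeResult:
    """Outcome of orienting one record against a reference allele pair."""

    ok: bool
    flip: bool = False  # True: negate effect, complement frequency
    reason: str | None = None  # set when ok is False


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC


def harmonize(
    a1: str,
    a2: str,
    ref_a1: str,
    ref_a2: str,
    eaf: float | None = None,
    ref_eaf: float | None = None,
    trust_strand: bool = False,
) -> HarmonizeResult:
    """Orient the (a1, a2, effect, eaf) record onto (ref_a1, ref_a2).

    Returns ``flip=True`` when the record's effect allele matches the
    reference *other* allele (the caller negates the effect and replaces
    eaf by 1-eaf).  Unreconcilable allele pairs, and palindromic pairs that
    frequency cannot orient, come back with ``ok=False``.

    ``trust_strand=True`` matches allele labels at face value (no strand
    complementing, no frequency check) — appropriate when both sides come
    from the same genotype resource, as when scoring a cohort with a
    weight file expressed on the same build and strand.
    """
    a1, a2, ref_a1, ref_a2 = (x.upper() for x in (a1, a2, ref_a1, ref_a2))
    if a1 == a2 or ref_a1 == ref_a2:
        return HarmonizeResult(False, reason="degenerate allele pair")

    if trust_strand:
        if (a1, a2) == (ref_a1, ref_a2):
            return HarmonizeResult(True, flip=False)
        if (a1, a2) == (ref_a2, ref_a1):
            return HarmonizeResult(True, flip=True)
        return HarmonizeResult(False, reason="allele mismatch")

    if _is_palindromic(a1, a2):
        if {a1, a2} != {ref_a1, ref_a2}:
            return HarmonizeResult(False, reason="allele mismatch")
        if eaf is None or ref_eaf is None:
            return HarmonizeResult(False, reason="palindromic without frequencies")
        if (
            abs(eaf - 0.5) <= PALINDROME_FREQ_MARGIN
            or abs(ref_eaf - 0.5) <= PALINDROME_FREQ_MARGIN
        ):
            return HarmonizeResult(False, reason="palindromic near 0.5 frequency")
        # allele labels cannot fix strand for palindromes; frequency is the
        # only usable signal: align the minor/major pattern
        flip = (eaf > 0.5) != (ref_eaf > 0.5)
        return HarmonizeResult(True, flip=flip)

    # direct match
    if (a1, a2) == (ref_a1, ref_a2):
        return HarmonizeResult(True, flip=False)
    if (a1, a2) == (ref_a2, ref_a1):
        return HarmonizeResult(True, flip=True)
    # strand flip
    ca1, ca2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
    if ca1 is None or ca2 is None:
        return HarmonizeResult(False, reason="non-ACGT allele")
    if (ca1, ca2) == (ref_a1, ref_a2):
        return HarmonizeResult(True, flip=False)
    if (ca1, ca2) == (ref_a2, ref_a1):
        return HarmonizeResult(True, flip=True)
    return HarmonizeResult(False, reason="allele mismatch")
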