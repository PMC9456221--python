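"""Motif equivalence algebra for microsatellite classification.

A microsatellite motif is a short DNA word of 1-6 bp. Two motifs describe
the same repeat tract whenever one is a cyclic rotation of the other
(reading the tract in a different frame) or lies on the opposite strand
(reverse complement). Motifs are therefore collapsed into equivalence
classes under the group generated by rotation and strand exchange, and each
class is named by its canonical representative: the lexicographically
smallest member (A < C < G < T).

Only *atomic* motifs - those that are not a whole-number repetition of a
shorter word - are admitted, so that a poly-A tract is classed as "A" and
never as "AA".

For periods 1..6 the number of classes is 2, 4, 10, 33, 102 and 350.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")

#: Strand-symmetry conventions. "revcomp" (the standard in the SSR
#: literature) identifies a motif with its reverse complement;
#: "complement" identifies it with the plain (unreversed) complement,
#: provided for replication of surveys that used that convention.
STRAND_CONVENTIONS = ("revcomp", "complement")


class MotifError(ValueError):
    """Raised for motifs outside the {A,C,G,T} alphabet or non-atomic input."""


def _validate(motif: str) -> None:
    if not motif:
        raise MotifError("motif must be non-empty")
    bad = set(motif) - _ALPHABET
    if bad:
        raise MotifError(f"motif {motif!r} contains non-ACGT characters: {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def is_atomic(motif: str) -> bool:
    """True iff ``motif`` is not u repeated k>=2 times for any shorter u."""
    _validate(motif)
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class MotifClass:
    """An equivalence class of atomic motifs under rotation + strand symmetry."""

    representative: str
    period: int
    members: frozenset[str]

    def __contains__(self, motif: str) -> bool:
        return motif in self.members


def _strand_mate(motif: str, strand: str) -> str:
    if strand == "revcomp":
        return reverse_complement(motif)
    if strand == "complement":
        return complement(motif)
    raise ValueError(f"unknown strand convention {strand!r}; expected one of {STRAND_CONVENTIONS}")


@lru_cache(maxsize=None)
def canonical_representative(motif: str, strand: str = "revcomp") -> str:
    """Lexicographically smallest rotation of ``motif`` or its strand mate.

    ``motif`` must be atomic; reduce the period first otherwise.
    """
    if not is_atomic(motif):
        raise MotifError(
            f"motif {motif!r} is not atomic; reduce to its smallest period before classifying"
        )
    return min(rotations(motif) + rotations(_strand_mate(motif, strand)))


def canonical_class(motif: str, strand: str = "revcomp") -> MotifClass:
    """The full equivalence class containing ``motif``."""
    rep = canonical_representative(motif, strand)
    members = frozenset(rotations(rep) + rotations(_strand_mate(rep, strand)))
    return MotifClass(representative=rep, period=len(rep), members=members)


@lru_cache(maxsize=None)
def enumerate_classes(period: int, strand: str = "revcomp") -> tuple[MotifClass, ...]:
    """All motif classes of a given period, sorted by representative.

    Class counts for periods 1..6 are 2, 4, 10, 33, 102 and 350.
    """
    if not 1 <= period <= 6:
        raise ValueError(f"period must be in 1..6, got {period}")
    reps: dict[str, MotifClass] = {}
    for letters in itertools.product("ACGT", repeat=period):
        motif = "".join(letters)
        if not is_atomic(motif):
            continue
        rep = canonical_representative(motif, strand)
        if rep not in reps:
            reps[rep] = canonical_class(rep, strand)
    return tuple(reps[r] for r in sorted(reps))


def class_table(max_period: int = 6, strand: str = "revcomp") -> list[dict]:
    """Flat rows (representative, period, members) for TSV export."""
    rows = []
    for p in range(1, max_period + 1):
        for cls in enumerate_classes(p, strand):
            rows.append(
                {
                    "representative": cls.representative,
                    "period": cls.period,
                    "members": ",".join(sorted(cls.members)),
                }
            )
    return rows
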