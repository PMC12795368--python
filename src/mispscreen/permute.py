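"""Enumeration of modification-induced sequence permutations (MISPs).

A MISP is an alternative peptide sequence that is mass-indistinguishable
from an observed peptide once deamidation (N→D, +0.984 Da; Q→E, +0.984 Da)
and N-terminal pyroglutamate formation (Q−NH3 ≡ pyroGlu ≡ E−H2O) are taken
into account.  Because search software reports the peptide only as a letter
sequence plus a modification count, every assignment of those modifications
to eligible residues — and every *mis*assignment that another genome would
explain as an unmodified residue — is an equally valid reading of the same
observed mass.

The engine applies three substitution stages:

1. **Deamidation**: every subset of N/Q positions, of size up to the number
   of deamidation events the search software detected, is substituted
   N→D / Q→E.  The N-terminal Q is excluded when a Gln→pyroGlu modification
   is present (that residue's modification state is already spoken for).
2. **Reverse deamidation**: on each stage-1 result, every subset of the
   original D/E positions is substituted D→N / E→Q, never touching a
   position altered in stage 1 (automatic here, since stage-1 sites are N/Q
   letters and stage-2 sites are D/E letters of the *input* sequence).
   The N-terminal E is excluded when a Glu→pyroGlu modification is present.
3. **PyroGlu swap**: when an N-terminal pyroGlu modification is present,
   each stage-2 result additionally spawns the variant with the first
   letter swapped (Q→E or E→Q); both forms are kept.

Stages operate on disjoint positions, so distinct substitution choices give
distinct sequences and the de-duplication step is a formality.  The closed
form in :func:`expected_count` therefore equals the enumerated set size
whenever no cap is hit, and serves as an independent oracle in tests.

The permutation set includes the unchanged input sequence whenever at least
one substitutable site exists, and is empty otherwise; downstream reporting
excludes the identity from LCA comparisons but keeps it in MISP counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterator, Optional

from pyteomics import mass as _pyteomics_mass

from .ingest import AMINO_ACIDS, ModificationProfile

#: monoisotopic mass gained by deamidation (N→D or Q→E), Da
DEAMIDATION_SHIFT = 0.98402

_STAGE1 = {"N": "D", "Q": "E"}
_STAGE2 = {"D": "N", "E": "Q"}

DEFAULT_CAP = 1_000_000


class PermutationExplosionError(RuntimeError):
    """Raised in strict mode when a peptide exceeds the permutation cap."""


@dataclass(frozen=True)
class SiteMap:
    """Positions (1-based) eligible for each substitution stage."""

    stage1_sites: tuple[int, ...]  # N/Q positions, deamidatable
    stage2_sites: tuple[int, ...]  # D/E positions, reverse-deamidatable
    pyroglu_site: Optional[str] = None  # "QE" or "EQ" swap at position 1

    def __post_init__(self) -> None:
        if set(self.stage1_sites) & set(self.stage2_sites):
            raise ValueError("stage-1 and stage-2 sites must be disjoint")
        if self.pyroglu_site not in (None, "QE", "EQ"):
            raise ValueError("pyroglu_site must be None, 'QE' or 'EQ'")


@dataclass(frozen=True)
class Permutation:
    """One MISP with full substitution provenance."""

    sequence: str
    stage1_subset: frozenset[int] = frozenset()
    stage2_subset: frozenset[int] = frozenset()
    pyroglu_applied: bool = False

    @property
    def is_identity(self) -> bool:
        return (
            not self.stage1_subset
            and not self.stage2_subset
            and not self.pyroglu_applied
        )


@dataclass(frozen=True)
class PermutationSet:
    """Deduplicated MISPs for one input peptide, lexicographic by sequence."""

    input_sequence: str
    permutations: tuple[Permutation, ...]
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.permutations)

    def __iter__(self) -> Iterator[Permutation]:
        return iter(self.permutations)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(p.sequence for p in self.permutations)

    def non_identity(self) -> tuple[Permutation, ...]:
        return tuple(p for p in self.permutations if not p.is_identity)


@dataclass(frozen=True)
class MassModel:
    """Monoisotopic residue masses used for the isobaric invariants."""

    residue_masses: dict = field(
        default_factory=lambda: dict(_pyteomics_mass.std_aa_mass)
    )
    water_mass: float = _pyteomics_mass.calculate_mass(formula="H2O")
    deamidation_shift: float = DEAMIDATION_SHIFT


DEFAULT_MASS_MODEL = MassModel()


def substitutable_sites(sequence: str, profile: ModificationProfile) -> SiteMap:
    """Map a validated peptide to its stage-1/stage-2/pyroGlu sites.

    Position 1 is excluded from stage 1 when it is a Q carrying pyroGlu, and
    from stage 2 when it is an E carrying pyroGlu: that residue's alternate
    reading is handled by the stage-3 swap instead.
    """
    stage1 = []
    stage2 = []
    for pos, letter in enumerate(sequence, start=1):
        if letter in _STAGE1:
            if pos == 1 and letter == "Q" and profile.pyroglu_from_q:
                continue
            stage1.append(pos)
        elif letter in _STAGE2:
            if pos == 1 and letter == "E" and profile.pyroglu_from_e:
                continue
            stage2.append(pos)
    pyroglu_site = None
    if profile.pyroglu_from_q and sequence.startswith("Q"):
        pyroglu_site = "QE"
    elif profile.pyroglu_from_e and sequence.startswith("E"):
        pyroglu_site = "EQ"
    return SiteMap(tuple(stage1), tuple(stage2), pyroglu_site)


def expected_count(site_map: SiteMap, deamidation_count: int) -> int:
    """Closed-form size of the deduplicated permutation set (identity included).

    Zero when no substitutable site exists; otherwise
    ``sum_{k=0..min(d, |s1|)} C(|s1|, k) * 2**|s2| * (2 if pyroGlu else 1)``.
    """
    s1 = len(site_map.stage1_sites)
    s2 = len(site_map.stage2_sites)
    k_max = min(deamidation_count, s1)
    if k_max == 0 and s2 == 0 and site_map.pyroglu_site is None:
        return 0
    stage1_choices = sum(comb(s1, k) for k in range(k_max + 1))
    return stage1_choices * (2**s2) * (2 if site_map.pyroglu_site else 1)


def _apply(sequence: str, positions: frozenset[int], table: dict) -> str:
    chars = list(sequence)
    for pos in positions:
        chars[pos - 1] = table[chars[pos - 1]]
    return "".join(chars)


def enumerate_misps(
    sequence: str,
    profile: ModificationProfile,
    cap: Optional[int] = DEFAULT_CAP,
    strict: bool = False,
) -> PermutationSet:
    """Enumerate the full MISP set for one peptide under the three stages.

    Returns an empty set when the peptide has no substitutable sites (no
    effective stage-1 site, no D/E and no pyroGlu); otherwise the identity
    sequence is always a member.  When the closed-form count exceeds ``cap``
    the set is truncated (``truncated=True``) unless ``strict``, in which
    case :class:`PermutationExplosionError` reports the expected size.
    """
    if cap is not None and cap < 1:
        raise ValueError("cap must be >= 1")
    site_map = substitutable_sites(sequence, profile)
    total = expected_count(site_map, profile.deamidation_count)
    if total == 0:
        return PermutationSet(sequence, ())
    if cap is not None and total > cap and strict:
        raise PermutationExplosionError(
            f"{sequence!r} would generate {total} permutations (cap {cap})"
        )

    k_max = min(profile.deamidation_count, len(site_map.stage1_sites))
    swap_first = {"QE": {"Q": "E"}, "EQ": {"E": "Q"}}.get(site_map.pyroglu_site or "")

    by_sequence: dict[str, Permutation] = {}
    truncated = False
    for k in range(k_max + 1):
        for s1 in combinations(site_map.stage1_sites, k):
            s1_set = frozenset(s1)
            seq1 = _apply(sequence, s1_set, _STAGE1)
            for r in range(len(site_map.stage2_sites) + 1):
                for s2 in combinations(site_map.stage2_sites, r):
                    s2_set = frozenset(s2)
                    seq2 = _apply(seq1, s2_set, _STAGE2)
                    variants = [(seq2, False)]
                    if swap_first is not None:
                        # position 1 is never a stage-1/2 site when pyroGlu
                        # is set, so seq2[0] is still the original Q or E
                        variants.append((swap_first[seq2[0]] + seq2[1:], True))
                    for seq_out, pyro in variants:
                        if cap is not None and len(by_sequence) >= cap:
                            truncated = True
                            break
                        by_sequence.setdefault(
                            seq_out, Permutation(seq_out, s1_set, s2_set, pyro)
                        )
                    if truncated:
                        break
                if truncated:
                    break
            if truncated:
                break
        if truncated:
            break

    ordered = tuple(by_sequence[s] for s in sorted(by_sequence))
    return PermutationSet(sequence, ordered, truncated)


def base_monoisotopic_mass(
    sequence: str, model: MassModel = DEFAULT_MASS_MODEL
) -> float:
    """Neutral monoisotopic peptide mass: residue masses plus one water."""
    if not sequence:
        raise ValueError("empty sequence")
    unknown = sorted(set(sequence) - AMINO_ACIDS)
    if unknown:
        raise ValueError(f"unknown residues {unknown!r} in {sequence!r}")
    return sum(model.residue_masses[a] for a in sequence) + model.water_mass


def isobaric_shift_multiple(
    input_sequence: str,
    misp: Permutation,
    model: MassModel = DEFAULT_MASS_MODEL,
    tolerance: float = 1e-3,
) -> int:
    """Integer number of deamidation shifts separating a MISP from its input.

    Each N→D/Q→E adds one shift, each D→N/E→Q removes one, and the pyroGlu
    first-letter swap adds one (Q→E) or removes one (E→Q).  The mass
    difference must be that multiple of 0.98402 Da within ``tolerance``;
    a residual beyond tolerance indicates an engine bug and raises.
    """
    delta = base_monoisotopic_mass(misp.sequence, model) - base_monoisotopic_mass(
        input_sequence, model
    )
    m = round(delta / model.deamidation_shift)
    if abs(delta - m * model.deamidation_shift) > tolerance:
        raise RuntimeError(
            f"mass difference {delta:.6f} Da between {input_sequence!r} and "
            f"{misp.sequence!r} is not an integer multiple of the deamidation shift"
        )
    return int(m)
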