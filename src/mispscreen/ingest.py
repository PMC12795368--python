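"""Reading peptide tables and parsing variable-modification strings.

Search engines report identified peptides together with free-text variable
modification annotations.  Two export dialects are supported directly —
Mascot result CSVs (``Sequence`` / ``Modifications``, comma separated) and
MaxQuant ``evidence.txt`` files (tab separated, with either the MaxQuant
column names or the Mascot-style ``pep_seq`` / ``pep_var_mod`` pair) — plus
minimal user-made tables that use either column-name pair.

Only two modification families matter downstream: deamidation of Asn/Gln
(``Deamidated (NQ)`` in Mascot, ``Deamidation (NQ)`` in MaxQuant) and
N-terminal pyroglutamate formation from Gln or Glu.  Everything else is
preserved verbatim in :attr:`ModificationProfile.ignored_mods` so nothing is
silently discarded.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: accepted (sequence, modification) column-name pairs, in preference order
_COLUMN_PAIRS = (("Sequence", "Modifications"), ("pep_seq", "pep_var_mod"))


class IngestError(ValueError):
    """Unusable input: missing columns, undecodable rows, bad sequences."""


@dataclass(frozen=True)
class PeptideRecord:
    """One input row: peptide sequence plus its raw modification text."""

    sequence: str
    raw_modifications: str = ""
    row_index: int = 0


@dataclass(frozen=True)
class ModificationProfile:
    """Parsed modification state of one peptide record.

    ``deamidation_count`` is the number of Deamidated (NQ) events the search
    software reported; it bounds how many N→D / Q→E substitutions the
    permutation engine may apply.  The two pyroGlu flags are mutually
    exclusive because a peptide N-terminus is a single residue.
    """

    deamidation_count: int = 0
    pyroglu_from_q: bool = False
    pyroglu_from_e: bool = False
    ignored_mods: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.deamidation_count < 0:
            raise ValueError("deamidation_count must be >= 0")
        if self.pyroglu_from_q and self.pyroglu_from_e:
            raise ValueError("pyroGlu cannot derive from both Q and E on one peptide")

    @property
    def has_pyroglu(self) -> bool:
        return self.pyroglu_from_q or self.pyroglu_from_e


@dataclass(frozen=True)
class Dialect:
    """A recognised input table dialect."""

    name: str  # "mascot", "maxquant" or "generic"
    sequence_column: str
    modification_column: str
    separator: str


# Vendor spellings, lower-cased; "→" is normalised to "->" before matching.
_DEAMIDATION_TOKENS = frozenset({"deamidated (nq)", "deamidation (nq)"})
_PYROGLU_Q_TOKENS = frozenset({"gln->pyro-glu (n-term q)", "gln->pyro-glu"})
_PYROGLU_E_TOKENS = frozenset({"glu->pyro-glu (n-term e)", "glu->pyro-glu"})

_MULTIPLICITY_RE = re.compile(r"^(\d+)\s+(.*)$")


def detect_dialect(
    header_row: Iterable[str], separator_hint: Optional[str] = None
) -> Dialect:
    """Pick the dialect from a header row.

    Prefers the ("Sequence", "Modifications") pair and falls back to
    ("pep_seq", "pep_var_mod"); raises :class:`IngestError` when no
    recognised sequence/modification column pair is present.
    """
    header = list(header_row)
    if not header:
        raise IngestError("empty header row")
    for seq_col, mod_col in _COLUMN_PAIRS:
        if seq_col in header and mod_col in header:
            sep = separator_hint or ("," if seq_col == "Sequence" else "\t")
            if sep == "," and seq_col == "Sequence":
                name = "mascot"
            elif sep == "\t":
                name = "maxquant"
            else:
                name = "generic"
            return Dialect(name, seq_col, mod_col, sep)
    raise IngestError(
        "no recognised peptide columns in header "
        f"{header!r}; expected one of {_COLUMN_PAIRS}"
    )


def _sniff_separator(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_peptide_table(
    source: Union[str, Path, TextIO],
    dialect: Union[Dialect, str] = "auto",
) -> tuple[list[PeptideRecord], Dialect]:
    """Read a peptide table, returning records in file order plus the dialect.

    ``source`` may be a path or an open text stream.  UTF-8 byte-order marks
    are tolerated.  Empty modification cells yield ``raw_modifications=""``.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8-sig")
    else:
        text = source.read()
        if text.startswith("﻿"):
            text = text[1:]
    if not text.strip():
        raise IngestError("input table is empty")

    header_line = text.splitlines()[0]
    if dialect == "auto":
        sep = _sniff_separator(header_line)
        dialect = detect_dialect(header_line.split(sep), separator_hint=sep)
    elif not isinstance(dialect, Dialect):
        raise TypeError("dialect must be a Dialect or 'auto'")

    try:
        frame = pd.read_csv(
            io.StringIO(text), sep=dialect.separator, dtype=str, engine="python"
        )
    except pd.errors.ParserError as exc:
        raise IngestError(f"could not parse input table: {exc}") from exc

    for col in (dialect.sequence_column, dialect.modification_column):
        if col not in frame.columns:
            raise IngestError(
                f"required column {col!r} missing from input "
                f"(found {list(frame.columns)!r})"
            )

    records = []
    seqs = frame[dialect.sequence_column].tolist()
    mods_col = frame[dialect.modification_column].tolist()
    for row_index, (seq, mods) in enumerate(zip(seqs, mods_col)):
        if seq is None or pd.isna(seq) or not str(seq).strip():
            raise IngestError(f"row {row_index}: missing peptide sequence")
        mods = "" if mods is None or pd.isna(mods) else str(mods).strip()
        records.append(PeptideRecord(str(seq).strip(), mods, row_index))
    return records, dialect


def parse_modifications(
    text: Optional[str], dialect: Optional[Dialect] = None
) -> ModificationProfile:
    """Parse a free-text modification cell into a profile.

    Total by design: unknown tokens land in ``ignored_mods`` and never raise.
    A leading integer on a deamidation token is its multiplicity ("3
    Deamidated (NQ)" means three events); a bare token counts one.  Several
    deamidation tokens in one cell are summed.
    """
    profile_d = 0
    pyro_q = False
    pyro_e = False
    ignored: list[str] = []
    if text:
        normalised = str(text).replace("→", "->")
        tokens = [
            t.strip()
            for part in normalised.split(";")
            for t in part.split(",")
            if t.strip()
        ]
        for token in tokens:
            mult = 1
            body = token
            m = _MULTIPLICITY_RE.match(token)
            if m:
                mult = int(m.group(1))
                body = m.group(2).strip()
            key = body.lower()
            if key in _DEAMIDATION_TOKENS:
                profile_d += mult
            elif key in _PYROGLU_Q_TOKENS:
                pyro_q = True
            elif key in _PYROGLU_E_TOKENS:
                pyro_e = True
            else:
                ignored.append(token)
    if pyro_q and pyro_e:
        # impossible on a single N-terminus; keep neither, note both
        logger.warning("both Gln- and Glu-derived pyroGlu in %r; ignoring both", text)
        ignored.extend(["Gln->pyro-Glu", "Glu->pyro-Glu"])
        pyro_q = pyro_e = False
    return ModificationProfile(profile_d, pyro_q, pyro_e, tuple(ignored))


def validate_record(
    record: PeptideRecord, profile: ModificationProfile
) -> tuple[PeptideRecord, ModificationProfile]:
    """Normalise and sanity-check one (record, profile) pair.

    Sequences are upper-cased; a pyroGlu flag contradicting the first residue
    is cleared with a warning (batch runs should not die on one bad row), but
    non-alphabet characters are a hard error.
    """
    sequence = record.sequence.upper()
    if not sequence:
        raise IngestError(f"row {record.row_index}: empty sequence")
    bad = sorted(set(sequence) - AMINO_ACIDS)
    if bad:
        raise IngestError(
            f"row {record.row_index}: sequence {record.sequence!r} contains "
            f"non-standard characters {bad!r}"
        )
    if profile.pyroglu_from_q and not sequence.startswith("Q"):
        logger.warning(
            "row %d: Gln->pyroGlu flagged but %r does not start with Q; flag cleared",
            record.row_index,
            sequence,
        )
        profile = ModificationProfile(
            profile.deamidation_count, False, profile.pyroglu_from_e, profile.ignored_mods
        )
    if profile.pyroglu_from_e and not sequence.startswith("E"):
        logger.warning(
            "row %d: Glu->pyroGlu flagged but %r does not start with E; flag cleared",
            record.row_index,
            sequence,
        )
        profile = ModificationProfile(
            profile.deamidation_count, profile.pyroglu_from_q, False, profile.ignored_mods
        )
    return PeptideRecord(sequence, record.raw_modifications, record.row_index), profile


def write_generic_csv(records: Iterable[PeptideRecord], path: Union[str, Path]) -> None:
    """Write records back out as a minimal generic CSV (round-trip support)."""
    frame = pd.DataFrame(
        [
            {"Sequence": r.sequence, "Modifications": r.raw_modifications}
            for r in records
        ],
        columns=["Sequence", "Modifications"],
    )
    frame.to_csv(path, index=False, lineterminator="\n")
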