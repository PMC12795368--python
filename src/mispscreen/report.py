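"""Per-peptide summaries, the manual-check flag, dataset statistics, outputs.

The screening result for one input peptide is a :class:`SummaryRecord`:
its own LCA, how many MISPs it generates (identity-inclusive), which of the
non-identity MISPs resolved to an LCA, whether all LCAs agree, the rolled-up
taxonomic category, and whether the peptide needs manual verification of
deamidation positions.

The manual-check flag captures a blind spot of sequence-level screening:
the engine does not see MS2 ion coverage, so when the search software
reported fewer deamidation events than the peptide has deamidatable N/Q
residues, the events could sit at several positions and some generated
MISPs may be unsupported by the actual spectrum.  A peptide is flagged iff

* deamidation events < deamidatable N/Q residues (excluding an N-terminal
  Q claimed by a pyroGlu modification), and
* at least one deamidation event was detected, and
* its MISPs resolved to two or more distinct LCAs.

Three artifacts are written per run — a results summary CSV (one row per
input peptide), a permutations CSV (one row per MISP) and a nested JSON —
byte-stable across runs for a given input.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .ingest import ModificationProfile, PeptideRecord
from .lca_backend import LcaResult, format_lineage
from .permute import PermutationSet
from .taxonomy import PeptideCategory, all_identical, categorize_peptide

JSON_SCHEMA_VERSION = 1

#: separators used inside CSV list cells
_ITEM_SEP = ";"
_PAIR_SEP = "="


@dataclass(frozen=True)
class SummaryRecord:
    """Screening outcome for one input peptide."""

    input_sequence: str
    raw_modifications: str
    input_lca: Optional[LcaResult]
    total_misps: int  # identity-inclusive
    misps_with_lca: tuple[tuple[str, LcaResult], ...]  # identity excluded
    all_lcas_identical: bool  # over {input LCA} ∪ MISP LCAs
    manual_check_required: bool
    category: PeptideCategory
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.total_misps == 0 and (self.misps_with_lca or self.manual_check_required):
            raise ValueError("a peptide without MISPs cannot carry MISP LCAs or flags")
        if len(self.misps_with_lca) > self.total_misps:
            raise ValueError("more MISP LCAs than MISPs")


@dataclass(frozen=True)
class DatasetStats:
    n_peptides: int
    n_with_misps: int
    n_without_misps: int
    total_misps_sum: int
    median_misps: float
    mode_misps: int
    mean_misps: float
    n_with_alternate_lca: int


def count_deamidatable_sites(sequence: str, profile: ModificationProfile) -> int:
    """N+Q residues, excluding an N-terminal Q claimed by pyroGlu."""
    n = sum(1 for c in sequence if c in "NQ")
    if profile.pyroglu_from_q and sequence.startswith("Q"):
        n -= 1
    return n


def needs_manual_check(
    record: PeptideRecord,
    profile: ModificationProfile,
    misp_lcas: Sequence[LcaResult],
) -> bool:
    """Three-conjunct flag for peptides with ambiguous deamidation positions.

    ``misp_lcas`` must exclude the identity permutation's LCA.
    """
    d = profile.deamidation_count
    sites = count_deamidatable_sites(record.sequence, profile)
    distinct = {lca.taxon_id for lca in misp_lcas}
    return d != 0 and d < sites and len(distinct) >= 2


def build_summary(
    record: PeptideRecord,
    profile: ModificationProfile,
    permutation_set: PermutationSet,
    lca_map: dict[str, Optional[LcaResult]],
    unresolved: Optional[dict[str, str]] = None,
) -> SummaryRecord:
    """Assemble the summary for one peptide from its MISPs and LCA lookups.

    ``lca_map`` must cover the input sequence and every non-identity MISP
    (values may be ``None`` for no-match).  Unresolved lookups are noted,
    never silently dropped.
    """
    unresolved = unresolved or {}
    input_lca = lca_map.get(record.sequence)
    notes: list[str] = []
    if record.sequence in unresolved:
        notes.append(f"input LCA unresolved: {unresolved[record.sequence]}")

    misps_with_lca: list[tuple[str, LcaResult]] = []
    for perm in permutation_set.non_identity():
        if perm.sequence not in lca_map:
            raise KeyError(f"LCA map does not cover MISP {perm.sequence!r}")
        if perm.sequence in unresolved:
            notes.append(f"MISP {perm.sequence} unresolved: {unresolved[perm.sequence]}")
            continue
        lca = lca_map[perm.sequence]
        if lca is not None:
            misps_with_lca.append((perm.sequence, lca))
    misps_with_lca.sort(key=lambda item: item[0])

    misp_lcas = [lca for _, lca in misps_with_lca]
    category = categorize_peptide(input_lca, misp_lcas)
    if input_lca is None and misp_lcas:
        notes.append("MISP LCAs found but input peptide has no LCA")
    comparison_set = ([input_lca] if input_lca else []) + misp_lcas
    return SummaryRecord(
        input_sequence=record.sequence,
        raw_modifications=record.raw_modifications,
        input_lca=input_lca,
        total_misps=len(permutation_set),
        misps_with_lca=tuple(misps_with_lca),
        all_lcas_identical=all_identical(comparison_set),
        manual_check_required=needs_manual_check(record, profile, misp_lcas),
        category=category,
        notes=tuple(notes),
    )


def dataset_statistics(summaries: Sequence[SummaryRecord]) -> DatasetStats:
    """Whole-dataset MISP count statistics, zeros included.

    Conventions: median is the lower middle for even n; mode breaks ties by
    the smallest value; the mean is truncated (not rounded) to one decimal.
    """
    counts = sorted(s.total_misps for s in summaries)
    if not counts:
        return DatasetStats(0, 0, 0, 0, 0.0, 0, 0.0, 0)
    n = len(counts)
    median = float(counts[(n - 1) // 2])
    frequency = Counter(counts)
    best = max(frequency.values())
    mode = min(v for v, c in frequency.items() if c == best)
    mean = math.floor(sum(counts) / n * 10) / 10
    alternate = sum(
        1
        for s in summaries
        if s.category
        in (
            PeptideCategory.DIFFERENT,
            PeptideCategory.MORE_SPECIFIC,
            PeptideCategory.LESS_SPECIFIC,
        )
    )
    return DatasetStats(
        n_peptides=n,
        n_with_misps=sum(1 for c in counts if c > 0),
        n_without_misps=sum(1 for c in counts if c == 0),
        total_misps_sum=sum(counts),
        median_misps=median,
        mode_misps=mode,
        mean_misps=mean,
        n_with_alternate_lca=alternate,
    )


# ---------------------------------------------------------------------------
# output writers


def _lca_cell(lca: Optional[LcaResult]) -> str:
    if lca is None:
        return ""
    return f"{lca.taxon_name} (taxon {lca.taxon_id}, {lca.taxon_rank})"


def _csv_escape(value: str) -> str:
    if any(c in value for c in ',"\n'):
        return '"' + value.replace('"', '""') + '"'
    return value


_SUMMARY_COLUMNS = (
    "input_sequence",
    "modifications",
    "input_lca",
    "total_misps",
    "n_misps_with_lca",
    "misps_with_lca",
    "misp_lcas",
    "all_lcas_identical",
    "manual_check_required",
    "category",
    "notes",
)

_PERMUTATION_COLUMNS = (
    "input_sequence",
    "modifications",
    "misp_sequence",
    "is_identity",
    "misp_lca",
)


def summary_to_json_obj(summary: SummaryRecord, profile: ModificationProfile,
                        permutation_set: PermutationSet,
                        lca_map: dict[str, Optional[LcaResult]]) -> dict:
    """Nested JSON object for one peptide (superset of the CSV row)."""
    return {
        "input_sequence": summary.input_sequence,
        "modifications": summary.raw_modifications,
        "profile": {
            "deamidation_count": profile.deamidation_count,
            "pyroglu_from_q": profile.pyroglu_from_q,
            "pyroglu_from_e": profile.pyroglu_from_e,
            "ignored_mods": list(profile.ignored_mods),
        },
        "input_lca": _lca_json(summary.input_lca),
        "total_misps": summary.total_misps,
        "misps": [
            {
                "sequence": perm.sequence,
                "is_identity": perm.is_identity,
                "lca": None if perm.is_identity else _lca_json(lca_map.get(perm.sequence)),
            }
            for perm in permutation_set
        ],
        "all_lcas_identical": summary.all_lcas_identical,
        "manual_check_required": summary.manual_check_required,
        "category": summary.category.value,
        "notes": list(summary.notes),
    }


def _lca_json(lca: Optional[LcaResult]) -> Optional[dict]:
    if lca is None:
        return None
    return {
        "taxon_id": lca.taxon_id,
        "taxon_name": lca.taxon_name,
        "taxon_rank": lca.taxon_rank,
        "lineage": format_lineage(lca.lineage),
    }


def write_outputs(
    summaries: Sequence[SummaryRecord],
    json_objects: Sequence[dict],
    out_dir: Union[str, Path],
    stem: str,
) -> tuple[Path, Path, Path]:
    """Write the three output artifacts; returns (results, permutations, json).

    The permutations CSV includes the identity sequence flagged
    ``is_identity=True`` with its LCA cell blank (it duplicates the input
    LCA), keeping ``total_misps`` reconcilable with the file contents.
    Outputs are byte-stable: fixed column order, fixed row order (input file
    order; MISPs lexicographic), LF line endings.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise NotADirectoryError(f"output directory {out_dir} does not exist")
    results_path = out_dir / f"{stem}_results.csv"
    permutations_path = out_dir / f"{stem}_permutations.csv"
    json_path = out_dir / f"{stem}_results.json"

    results_lines = [",".join(_SUMMARY_COLUMNS)]
    for s in summaries:
        row = (
            s.input_sequence,
            s.raw_modifications,
            _lca_cell(s.input_lca),
            str(s.total_misps),
            str(len(s.misps_with_lca)),
            _ITEM_SEP.join(seq for seq, _ in s.misps_with_lca),
            _ITEM_SEP.join(
                f"{seq}{_PAIR_SEP}{_lca_cell(lca)}" for seq, lca in s.misps_with_lca
            ),
            str(s.all_lcas_identical),
            str(s.manual_check_required),
            s.category.value,
            _ITEM_SEP.join(s.notes),
        )
        results_lines.append(",".join(_csv_escape(v) for v in row))

    permutation_lines = [",".join(_PERMUTATION_COLUMNS)]
    for obj in json_objects:
        for misp in obj["misps"]:
            lca = misp["lca"]
            row = (
                obj["input_sequence"],
                obj["modifications"],
                misp["sequence"],
                str(misp["is_identity"]),
                "" if lca is None else f"{lca['taxon_name']} (taxon {lca['taxon_id']}, {lca['taxon_rank']})",
            )
            permutation_lines.append(",".join(_csv_escape(v) for v in row))

    payload = {"schema_version": JSON_SCHEMA_VERSION, "peptides": list(json_objects)}

    results_path.write_text("\n".join(results_lines) + "\n", encoding="utf-8")
    permutations_path.write_text(
        "\n".join(permutation_lines) + "\n", encoding="utf-8"
    )
    json_path.write_text(
        json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )
    return results_path, permutations_path, json_path


def stats_to_json(stats: DatasetStats) -> dict:
    return {
        "n_peptides": stats.n_peptides,
        "n_with_misps": stats.n_with_misps,
        "n_without_misps": stats.n_without_misps,
        "total_misps_sum": stats.total_misps_sum,
        "median_misps": stats.median_misps,
        "mode_misps": stats.mode_misps,
        "mean_misps": stats.mean_misps,
        "n_with_alternate_lca": stats.n_with_alternate_lca,
    }
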