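"""Self-contained synthetic inputs for network-free pipeline testing.

Real screening runs depend on a live taxonomic service, which makes them
unsuitable as test oracles.  This module generates everything the pipeline
consumes — a toy taxonomy tree, an offline peptide→LCA table derived from
it, and a peptide table with controlled modification structure — together
with a *manifest* of expected per-peptide outcomes (MISP totals, category,
manual-check flag) computed analytically from the closed-form permutation
count and direct tree-ancestry checks, never by running the pipeline.
An end-to-end run over a generated fixture must reproduce its manifest
exactly.

The generator oversamples N/Q/D/E residues relative to a uniform amino-acid
draw (default 40% of positions) so multi-site permutation logic is actually
exercised; uniform random peptides rarely have more than one or two sites.
What it does not emulate: real protein sequence structure, database search
noise, or the uneven taxon coverage of UniProtKB — passing tests show the
screening logic is correct, not that any particular organism is detectable.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .ingest import ModificationProfile
from .lca_backend import CANONICAL_RANKS, LcaResult, Lineage, write_offline_table
from .permute import enumerate_misps, expected_count, substitutable_sites
from .report import count_deamidatable_sites

#: ranks assigned to successive tree levels (root first)
_LEVEL_RANKS = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_SITE_LETTERS = "NQDE"
_OTHER_LETTERS = "ACFGHIKLMPRSTVWY"


@dataclass(frozen=True)
class ToyTaxonomy:
    """A rooted tree of taxa with ranks in canonical ancestor order."""

    nodes: dict  # taxon_id -> (name, rank, parent_id or None)
    root_id: int

    def parent(self, taxon_id: int) -> Optional[int]:
        return self.nodes[taxon_id][2]

    def path_to_root(self, taxon_id: int) -> list[int]:
        """Taxon ids from root down to ``taxon_id`` inclusive."""
        if taxon_id not in self.nodes:
            raise KeyError(f"unknown taxon {taxon_id}")
        path = []
        current: Optional[int] = taxon_id
        while current is not None:
            path.append(current)
            current = self.parent(current)
        return path[::-1]

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff ``a`` is a proper ancestor of ``b``."""
        return a != b and a in self.path_to_root(b)

    def lineage(self, taxon_id: int) -> Lineage:
        entries = []
        for node in self.path_to_root(taxon_id):
            name, rank, _ = self.nodes[node]
            entries.append((rank, node, name))
        return Lineage(tuple(entries))

    def lca_result(self, peptide: str, taxon_id: int) -> LcaResult:
        name, rank, _ = self.nodes[taxon_id]
        return LcaResult(peptide, taxon_id, name, rank, self.lineage(taxon_id))

    def leaves(self) -> list[int]:
        parents = {p for _, _, p in self.nodes.values() if p is not None}
        return sorted(t for t in self.nodes if t not in parents)

    def nodes_at_level(self, level: int) -> list[int]:
        return sorted(
            t for t in self.nodes if len(self.path_to_root(t)) == level + 1
        )


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic-data generator."""

    seed: int = 0
    n_peptides: int = 40
    length_range: tuple[int, int] = (7, 16)
    site_density: float = 0.4
    deamidation_range: tuple[int, int] = (0, 3)
    pyroglu_probability: float = 0.15
    taxonomy_shape: tuple[int, int] = (4, 3)  # (depth incl. root, branching)

    def __post_init__(self) -> None:
        if not (0 <= self.site_density <= 1 and 0 <= self.pyroglu_probability <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 2:
            raise ValueError("invalid length_range")
        if self.deamidation_range[0] > self.deamidation_range[1]:
            raise ValueError("invalid deamidation_range")


def build_toy_taxonomy(
    shape: tuple[int, int] = (4, 3), seed: int = 0
) -> ToyTaxonomy:
    """Deterministic full ``branching``-ary tree of ``depth`` levels.

    Node count is ``sum(branching**level for level in range(depth))``; ids
    are assigned breadth-first starting at 1.  ``seed`` only shuffles names.
    """
    depth, branching = shape
    if depth < 2 or branching < 1:
        raise ValueError("depth must be >= 2 and branching >= 1")
    if depth > len(_LEVEL_RANKS):
        raise ValueError(f"depth must be <= {len(_LEVEL_RANKS)}")
    rng = random.Random(seed)
    nodes: dict[int, tuple[str, str, Optional[int]]] = {}
    next_id = 1
    frontier = [None]
    for level in range(depth):
        rank = _LEVEL_RANKS[level]
        new_frontier = []
        for parent in frontier:
            width = 1 if parent is None else branching
            for _ in range(width):
                suffix = rng.randrange(1000, 9999)
                nodes[next_id] = (f"{rank.capitalize()}_{next_id}_{suffix}", rank, parent)
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    return ToyTaxonomy(nodes, root_id=1)


def tree_lca(taxonomy: ToyTaxonomy, taxa: set[int]) -> int:
    """Deepest node that is ancestor-or-self of every taxon in ``taxa``."""
    if not taxa:
        raise ValueError("taxa must be non-empty")
    paths = [taxonomy.path_to_root(t) for t in taxa]
    lca = None
    for level_nodes in zip(*paths):
        if len(set(level_nodes)) == 1:
            lca = level_nodes[0]
        else:
            break
    assert lca is not None  # all paths start at the root
    return lca


def _tree_relation(taxonomy: ToyTaxonomy, input_id: int, other_id: int) -> str:
    if input_id == other_id:
        return "identical"
    if taxonomy.is_ancestor(input_id, other_id):
        return "more_specific"
    if taxonomy.is_ancestor(other_id, input_id):
        return "less_specific"
    return "different"


def _expected_category(
    taxonomy: ToyTaxonomy, input_id: Optional[int], misp_ids: list[int]
) -> str:
    if not misp_ids:
        return "no_alternate"
    if input_id is None:
        return "different"
    relations = {_tree_relation(taxonomy, input_id, m) for m in misp_ids}
    if relations == {"identical"}:
        return "all_identical"
    if "less_specific" in relations:
        return "less_specific"
    if "different" in relations:
        return "different"
    return "more_specific"


_SCENARIOS = (
    "none",
    "identical",
    "different",
    "more_specific",
    "less_specific",
    "mixed",
)


def _random_peptide(rng: random.Random, spec: FixtureSpec) -> str:
    length = rng.randint(*spec.length_range)
    return "".join(
        rng.choice(_SITE_LETTERS)
        if rng.random() < spec.site_density
        else rng.choice(_OTHER_LETTERS)
        for _ in range(length)
    )


def _modification_text(d: int, pyro_q: bool, pyro_e: bool) -> str:
    parts = []
    if d == 1:
        parts.append("Deamidated (NQ)")
    elif d > 1:
        parts.append(f"{d} Deamidated (NQ)")
    if pyro_q:
        parts.append("Gln->pyro-Glu (N-term Q)")
    if pyro_e:
        parts.append("Glu->pyro-Glu (N-term E)")
    return "; ".join(parts)


def generate_fixture(
    spec: FixtureSpec, out_dir: Union[str, Path]
) -> tuple[Path, Path, Path]:
    """Generate a peptide CSV, an offline LCA TSV and an expected-outcome manifest.

    Each peptide is planted into one taxonomic scenario (no MISP LCAs, all
    identical, different, more specific, less specific, or a less+more mix)
    by assigning its input sequence and a subset of its non-identity MISPs
    to nodes of the toy taxonomy.  The manifest records, per peptide, the
    analytically expected total MISP count, category, manual-check flag and
    LCA-agreement flag.  Byte-identical output for a fixed spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    taxonomy = build_toy_taxonomy(spec.taxonomy_shape, spec.seed)
    leaves = taxonomy.leaves()
    depth = spec.taxonomy_shape[0]

    table: dict[str, LcaResult] = {}
    used_sequences: set[str] = set()
    rows: list[tuple[str, str]] = []
    manifest: list[dict] = []

    attempts = 0
    while len(rows) < spec.n_peptides:
        attempts += 1
        if attempts > spec.n_peptides * 200:
            raise RuntimeError("fixture generation failed to find fresh sequences")
        sequence = _random_peptide(rng, spec)
        pyro_q = pyro_e = False
        if rng.random() < spec.pyroglu_probability:
            first = rng.choice("QE")
            sequence = first + sequence[1:]
            pyro_q = first == "Q"
            pyro_e = first == "E"
        d = rng.randint(*spec.deamidation_range)
        profile = ModificationProfile(d, pyro_q, pyro_e)
        site_map = substitutable_sites(sequence, profile)
        total = expected_count(site_map, d)
        perm_set = enumerate_misps(sequence, profile)
        assert len(perm_set) == total
        all_seqs = {sequence} | set(perm_set.sequences)
        if all_seqs & used_sequences:
            continue
        used_sequences |= all_seqs

        non_identity = [p.sequence for p in perm_set.non_identity()]
        scenario = rng.choice(_SCENARIOS) if non_identity else "none"

        input_id: Optional[int] = None
        misp_assignments: dict[str, int] = {}
        if scenario == "none":
            input_id = rng.choice(leaves)
        elif scenario == "identical":
            input_id = rng.choice(leaves)
            for seq in _pick(rng, non_identity):
                misp_assignments[seq] = input_id
        elif scenario == "different":
            # two distinct leaves of a full tree are never ancestor-related
            input_id = rng.choice(leaves)
            others = [leaf for leaf in leaves if leaf != input_id]
            for seq in _pick(rng, non_identity):
                misp_assignments[seq] = rng.choice(others)
        elif scenario == "more_specific":
            # input LCA is an internal node, MISPs sit strictly below it
            internal = taxonomy.nodes_at_level(rng.randint(1, depth - 2))
            input_id = rng.choice(internal)
            descendants = [
                leaf for leaf in leaves if taxonomy.is_ancestor(input_id, leaf)
            ]
            for seq in _pick(rng, non_identity):
                misp_assignments[seq] = rng.choice(descendants)
        elif scenario == "less_specific":
            input_id = rng.choice(leaves)
            ancestors = taxonomy.path_to_root(input_id)[:-1]
            for seq in _pick(rng, non_identity):
                misp_assignments[seq] = rng.choice(ancestors)
        elif scenario == "mixed":
            internal = taxonomy.nodes_at_level(rng.randint(1, depth - 2))
            input_id = rng.choice(internal)
            descendants = [
                leaf for leaf in leaves if taxonomy.is_ancestor(input_id, leaf)
            ]
            ancestors = taxonomy.path_to_root(input_id)[:-1]
            chosen = _pick(rng, non_identity, minimum=2)
            if len(chosen) < 2:
                scenario = "more_specific"
                for seq in chosen:
                    misp_assignments[seq] = rng.choice(descendants)
            else:
                misp_assignments[chosen[0]] = rng.choice(ancestors)
                for seq in chosen[1:]:
                    misp_assignments[seq] = rng.choice(descendants)

        table[sequence] = taxonomy.lca_result(sequence, input_id)
        for seq, taxon in misp_assignments.items():
            table[seq] = taxonomy.lca_result(seq, taxon)

        mods = _modification_text(d, pyro_q, pyro_e)
        rows.append((sequence, mods))
        misp_ids = [misp_assignments[s] for s in sorted(misp_assignments)]
        distinct = set(misp_ids)
        manifest.append(
            {
                "sequence": sequence,
                "modifications": mods,
                "expected_total_misps": total,
                "expected_n_misps_with_lca": len(misp_assignments),
                "expected_category": _expected_category(taxonomy, input_id, misp_ids),
                "expected_manual_check": (
                    d != 0
                    and d < count_deamidatable_sites(sequence, profile)
                    and len(distinct) >= 2
                ),
                "expected_all_lcas_identical": len({input_id} | distinct) <= 1,
            }
        )

    peptides_path = out_dir / "peptides.csv"
    table_path = out_dir / "lca_table.tsv"
    manifest_path = out_dir / "manifest.json"
    lines = ["Sequence,Modifications"]
    for sequence, mods in rows:
        cell = f'"{mods}"' if "," in mods else mods
        lines.append(f"{sequence},{cell}")
    peptides_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    write_offline_table(table, table_path)
    manifest_path.write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return peptides_path, table_path, manifest_path


def _pick(
    rng: random.Random, candidates: list[str], minimum: int = 1
) -> list[str]:
    """Choose 1–3 MISP sequences (stable order) to receive planted LCAs."""
    if not candidates:
        return []
    k = min(len(candidates), rng.randint(minimum, 3))
    return sorted(rng.sample(candidates, k))


# ---------------------------------------------------------------------------
# hand-authored worked scenario (synthetic lineages over real taxon names)
#
# The classic dairy ambiguity: deamidation of the sheep whey peptide
# TPEVDNEALEK makes it indistinguishable from the cattle-lineage peptide
# TPEVDDEALEK, so a detected TPEVDDEALEK could come from either subfamily.

WORKED_PEPTIDES_CSV = """\
Sequence,Modifications
TPEVDDEALEK,
QEVGGEALGR,Gln->pyro-Glu (N-term Q)
GGGPGAGGLR,
"""

_BOVIDAE = (
    "superkingdom:2759:Eukaryota|kingdom:33208:Metazoa|phylum:7711:Chordata"
    "|class:40674:Mammalia|order:91561:Artiodactyla|family:9895:Bovidae"
)

WORKED_LCA_TSV = (
    "peptide\ttaxon_id\ttaxon_name\ttaxon_rank\tlineage\n"
    f"TPEVDDEALEK\t27592\tBovinae\tsubfamily\t{_BOVIDAE}|subfamily:27592:Bovinae\n"
    f"TPEVDNEALEK\t9935\tOvis\tgenus\t{_BOVIDAE}|subfamily:9963:Caprinae|genus:9935:Ovis\n"
    "QEVGGEALGR\t9813\tHippopotamus amphibius\tspecies\t"
    "superkingdom:2759:Eukaryota|kingdom:33208:Metazoa|phylum:7711:Chordata"
    "|superclass:8287:Sarcopterygii"
    "|class:40674:Mammalia|order:91561:Artiodactyla|family:9836:Hippopotamidae"
    "|genus:9812:Hippopotamus|species:9813:Hippopotamus amphibius\n"
    "EEVGGEALGR\t8287\tSarcopterygii\tsuperclass\t"
    "superkingdom:2759:Eukaryota|kingdom:33208:Metazoa|phylum:7711:Chordata"
    "|superclass:8287:Sarcopterygii\n"
)


def write_worked_example(out_dir: Union[str, Path]) -> tuple[Path, Path]:
    """Write the static worked scenario used in the documentation."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    peptides = out_dir / "worked_peptides.csv"
    table = out_dir / "worked_lca_table.tsv"
    peptides.write_text(WORKED_PEPTIDES_CSV, encoding="utf-8")
    table.write_text(WORKED_LCA_TSV, encoding="utf-8")
    return peptides, table
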