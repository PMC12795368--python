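"""Resolving peptides to taxonomic lowest common ancestors (LCAs).

Two interchangeable backends sit behind one contract:

* **unipept** — the public Unipept ``pept2lca`` service, which maps a
  peptide to the LCA of all UniProtKB proteins containing it.  Queries are
  batched, distributed over worker threads with one persistent session per
  lane, and retried with exponential backoff on transient failures.
* **offline** — a local TSV lookup table (peptide → LCA + lineage), which
  makes the whole pipeline runnable with no network access and backs all
  tests.

Every queried peptide appears in the result: matched peptides carry an
:class:`LcaResult`; peptides the backend does not know map to ``None``
(no-match); peptides whose batches failed after all retries are recorded
separately as *unresolved* — conflating the two would silently change
"MISPs which yielded LCAs" counts downstream.
"""

from __future__ import annotations

import json
import logging
import threading
import time
import urllib.error
import urllib.parse
import urllib.request
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Union

logger = logging.getLogger(__name__)

#: canonical rank order used for lineages (NCBI/Unipept convention, root→leaf)
CANONICAL_RANKS = (
    "superkingdom",
    "kingdom",
    "subkingdom",
    "superphylum",
    "phylum",
    "subphylum",
    "superclass",
    "class",
    "subclass",
    "superorder",
    "order",
    "suborder",
    "infraorder",
    "superfamily",
    "family",
    "subfamily",
    "tribe",
    "subtribe",
    "genus",
    "subgenus",
    "species_group",
    "species_subgroup",
    "species",
    "subspecies",
    "strain",
    "varietas",
    "forma",
)
_RANK_INDEX = {rank: i for i, rank in enumerate(CANONICAL_RANKS)}

DEFAULT_API_URL = "https://api.unipept.ugent.be/api/v2/pept2lca.json"


class OfflineTableError(ValueError):
    """Malformed offline LCA lookup table."""


class BackendConfigurationError(RuntimeError):
    """Non-transient backend failure (bad request, bad configuration)."""


@dataclass(frozen=True)
class Lineage:
    """Ordered root→leaf taxon chain; unranked levels are simply absent."""

    entries: tuple[tuple[str, int, str], ...] = ()  # (rank, taxon_id, name)

    def __post_init__(self) -> None:
        ids = [taxon_id for _, taxon_id, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate taxon ids within one lineage")
        ranks = [r for r, _, _ in self.entries]
        indices = [_RANK_INDEX[r] for r in ranks if r in _RANK_INDEX]
        if indices != sorted(indices):
            raise ValueError(f"lineage ranks out of canonical order: {ranks}")

    def taxon_ids(self) -> tuple[int, ...]:
        return tuple(taxon_id for _, taxon_id, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class LcaResult:
    """LCA assignment for one peptide, with the lineage used for comparison."""

    peptide: str
    taxon_id: int
    taxon_name: str
    taxon_rank: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if self.lineage.entries and self.lineage.entries[-1][1] != self.taxon_id:
            raise ValueError("taxon_id must be the last entry of the lineage")


@dataclass(frozen=True)
class BackendConfig:
    mode: str = "unipept"  # "unipept" or "offline"
    api_url: str = DEFAULT_API_URL
    batch_size: int = 90
    threads: int = 8
    max_retries: int = 3
    backoff_base: float = 1.0
    equate_il: bool = False
    timeout: float = 30.0
    min_peptide_length: int = 5
    max_peptide_length: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("unipept", "offline"):
            raise ValueError(f"unknown backend mode {self.mode!r}")
        if self.batch_size < 1 or self.threads < 1 or self.max_retries < 0:
            raise ValueError("batch_size/threads must be >= 1, max_retries >= 0")


@dataclass
class LcaLookup:
    """Outcome of one fetch: per-peptide results plus unresolved reasons.

    ``results`` covers every queried peptide (``None`` = backend has no
    match); ``unresolved`` maps peptides whose lookups failed (exhausted
    retries, length limits) to a human-readable reason.
    """

    results: dict[str, Optional[LcaResult]] = field(default_factory=dict)
    unresolved: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# offline backend


def format_lineage(lineage: Lineage) -> str:
    """Serialise a lineage as pipe-separated ``rank:taxon_id:name`` triples."""
    return "|".join(f"{r}:{t}:{n}" for r, t, n in lineage.entries)


def parse_lineage(text: str) -> Lineage:
    """Parse the pipe-separated triple format; inverse of :func:`format_lineage`."""
    text = text.strip()
    if not text:
        return Lineage(())
    entries = []
    for triple in text.split("|"):
        parts = triple.split(":", 2)
        if len(parts) != 3 or not parts[1].strip().isdigit():
            raise OfflineTableError(f"malformed lineage triple {triple!r}")
        rank, taxon_id, name = parts
        entries.append((rank.strip(), int(taxon_id), name.strip()))
    return Lineage(tuple(entries))


_OFFLINE_COLUMNS = ("peptide", "taxon_id", "taxon_name", "taxon_rank", "lineage")


def load_offline_table(path: Union[str, Path]) -> dict[str, LcaResult]:
    """Load a peptide→LCA lookup from TSV.

    Columns: peptide, taxon_id, taxon_name, taxon_rank, lineage (pipe-
    separated rank:taxon_id:name triples, root→leaf).  Duplicate peptides:
    the last row wins, with a warning.
    """
    lookup: dict[str, LcaResult] = {}
    with open(path, encoding="utf-8-sig") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != _OFFLINE_COLUMNS:
            raise OfflineTableError(
                f"offline table header must be {_OFFLINE_COLUMNS}, got {tuple(header)}"
            )
        for line_number, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_OFFLINE_COLUMNS):
                raise OfflineTableError(
                    f"line {line_number}: expected {len(_OFFLINE_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            peptide, taxon_id, taxon_name, taxon_rank, lineage_text = fields
            try:
                lineage = parse_lineage(lineage_text)
                result = LcaResult(
                    peptide, int(taxon_id), taxon_name, taxon_rank, lineage
                )
            except (OfflineTableError, ValueError) as exc:
                raise OfflineTableError(f"line {line_number}: {exc}") from exc
            if peptide in lookup:
                logger.warning(
                    "line %d: duplicate peptide %r overrides earlier row",
                    line_number,
                    peptide,
                )
            lookup[peptide] = result
    if not lookup:
        logger.warning("offline table %s contains no data rows", path)
    return lookup


def write_offline_table(
    lookup: dict[str, LcaResult], path: Union[str, Path]
) -> None:
    """Write a lookup back to the TSV format read by :func:`load_offline_table`."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(_OFFLINE_COLUMNS) + "\n")
        for peptide in sorted(lookup):
            r = lookup[peptide]
            handle.write(
                f"{peptide}\t{r.taxon_id}\t{r.taxon_name}\t{r.taxon_rank}\t"
                f"{format_lineage(r.lineage)}\n"
            )


# ---------------------------------------------------------------------------
# live backend


def parse_pept2lca_response(payload: list[dict]) -> dict[str, LcaResult]:
    """Build LcaResults from a pept2lca JSON body (``extra=true&names=true``)."""
    out: dict[str, LcaResult] = {}
    for item in payload:
        entries = []
        for rank in CANONICAL_RANKS:
            taxon_id = item.get(f"{rank}_id")
            if taxon_id is None:
                continue
            name = item.get(f"{rank}_name") or ""
            entries.append((rank, int(taxon_id), name))
        lineage = Lineage(tuple(entries))
        taxon_id = int(item["taxon_id"])
        if not lineage.entries or lineage.entries[-1][1] != taxon_id:
            # LCA at an unranked level (e.g. root or "cellular organisms"):
            # append it so the lineage invariant holds
            if taxon_id not in lineage.taxon_ids():
                lineage = Lineage(
                    lineage.entries + ((item.get("taxon_rank", "no rank"), taxon_id, item.get("taxon_name", "")),)
                )
            else:
                lineage = Lineage(
                    tuple(
                        e
                        for e in lineage.entries
                        if lineage.taxon_ids().index(e[1])
                        <= lineage.taxon_ids().index(taxon_id)
                    )
                )
        out[item["peptide"]] = LcaResult(
            peptide=item["peptide"],
            taxon_id=taxon_id,
            taxon_name=item.get("taxon_name", ""),
            taxon_rank=item.get("taxon_rank", "no rank"),
            lineage=lineage,
        )
    return out


def _http_transport(config: BackendConfig) -> Callable[[list[str]], list[dict]]:
    """Default transport: POST one batch to the pept2lca endpoint."""
    # one opener per worker lane gives each lane a persistent session
    local = threading.local()

    def post(batch: list[str]) -> list[dict]:
        if not hasattr(local, "opener"):
            local.opener = urllib.request.build_opener()
        params = [("input[]", p) for p in batch]
        params.append(("extra", "true"))
        params.append(("names", "true"))
        if config.equate_il:
            params.append(("equate_il", "true"))
        data = urllib.parse.urlencode(params).encode()
        request = urllib.request.Request(
            config.api_url,
            data=data,
            headers={"Accept": "application/json"},
            method="POST",
        )
        with local.opener.open(request, timeout=config.timeout) as response:
            return json.loads(response.read().decode())

    return post


class TransientBackendError(RuntimeError):
    """Retryable failure: timeout, connection reset, 5xx, rate limit."""


def _classify_http_error(exc: Exception) -> Exception:
    if isinstance(exc, urllib.error.HTTPError):
        if exc.code >= 500 or exc.code == 429:
            return TransientBackendError(f"HTTP {exc.code}")
        return BackendConfigurationError(f"HTTP {exc.code}: {exc.reason}")
    if isinstance(exc, (urllib.error.URLError, TimeoutError, ConnectionError, OSError)):
        return TransientBackendError(str(exc))
    return exc


def _query_batch_with_retries(
    batch: list[str],
    transport: Callable[[list[str]], list[dict]],
    config: BackendConfig,
    sleep: Callable[[float], None],
) -> dict[str, LcaResult]:
    attempt = 0
    while True:
        try:
            return parse_pept2lca_response(transport(batch))
        except Exception as exc:  # noqa: BLE001 — classified below
            classified = _classify_http_error(exc)
            if isinstance(classified, BackendConfigurationError):
                raise classified from exc
            if not isinstance(classified, TransientBackendError):
                raise
            attempt += 1
            if attempt > config.max_retries:
                raise TransientBackendError(
                    f"batch failed after {config.max_retries} retries: {classified}"
                ) from exc
            wait = config.backoff_base * 2 ** (attempt - 1)
            logger.warning(
                "transient backend failure (%s); retry %d/%d in %.2fs",
                classified,
                attempt,
                config.max_retries,
                wait,
            )
            sleep(wait)


def fetch_lcas(
    peptides: Iterable[str],
    config: BackendConfig = BackendConfig(),
    offline_table: Optional[dict[str, LcaResult]] = None,
    transport: Optional[Callable[[list[str]], list[dict]]] = None,
    sleep: Callable[[float], None] = time.sleep,
) -> LcaLookup:
    """Resolve a set of peptides to LCAs.

    Duplicates are queried once.  In offline mode ``offline_table`` is the
    lookup; in unipept mode peptides outside the service's length limits are
    reported unresolved without being sent, and failed batches mark their
    peptides unresolved while the run continues.  ``transport`` and
    ``sleep`` exist for testing the batching/retry contract.
    """
    unique = sorted(set(peptides))
    if not unique:
        raise ValueError("no peptides to query")
    lookup = LcaLookup()

    if config.mode == "offline":
        if offline_table is None:
            raise BackendConfigurationError("offline mode requires an offline table")
        for peptide in unique:
            lookup.results[peptide] = offline_table.get(peptide)
        return lookup

    sendable = []
    for peptide in unique:
        if not (
            config.min_peptide_length <= len(peptide) <= config.max_peptide_length
        ):
            lookup.results[peptide] = None
            lookup.unresolved[peptide] = (
                f"length {len(peptide)} outside "
                f"[{config.min_peptide_length}, {config.max_peptide_length}]"
            )
        else:
            sendable.append(peptide)

    transport = transport or _http_transport(config)
    batches = [
        sendable[i : i + config.batch_size]
        for i in range(0, len(sendable), config.batch_size)
    ]

    def run_batch(batch: list[str]) -> tuple[list[str], Optional[dict], Optional[str]]:
        try:
            return batch, _query_batch_with_retries(batch, transport, config, sleep), None
        except TransientBackendError as exc:
            return batch, None, str(exc)

    if batches:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            outcomes = list(pool.map(run_batch, batches))
        for batch, matched, error in outcomes:
            if error is not None:
                logger.error("LCA batch of %d peptides unresolved: %s", len(batch), error)
                for peptide in batch:
                    lookup.results[peptide] = None
                    lookup.unresolved[peptide] = error
            else:
                for peptide in batch:
                    lookup.results[peptide] = matched.get(peptide)
    return lookup
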