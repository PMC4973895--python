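"""Resolve gene symbols and fetch protein domain architectures.

Two remote services are consumed, always through an injectable
``fetch(url) -> str`` callable so the whole module can run against
recorded documents with no network:

* the UniProt REST query interface, to turn an HGNC gene symbol into a
  reviewed (SwissProt) accession, and
* a Pfam-style "graphics" endpoint serving a JSON description of one
  protein's length, Pfam-A domains and predicted motifs.

Responses are cached on disk keyed by ``(service, identifier)`` so
repeated runs are deterministic and fast; a local JSON document can be
supplied instead of either service for fully offline use.

Coordinates are 1-based inclusive residue ranges throughout (the Pfam
convention); conversion to pixels happens only in the layout engine.
"""

from __future__ import annotations

import json
import logging
import os
import re
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from .errors import (
    ArchitectureParseError,
    NotFoundError,
    ResolutionError,
    TransportError,
)

log = logging.getLogger(__name__)

Fetch = Callable[[str], str]

#: Closed set of structural-motif kinds the renderer understands.
MOTIF_KINDS = frozenset(
    {"disorder", "low_complexity", "sig_p", "coiled_coil", "transmembrane"}
)

#: UniProt accession syntax (the official pattern, old and new style).
ACCESSION_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

_HEX_COLOR_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")

UNIPROT_SEARCH_URL = (
    "https://rest.uniprot.org/uniprotkb/search"
    "?query=gene_exact:{symbol}+AND+reviewed:true"
    "&fields=accession,organism_id&format=json"
)
PFAM_GRAPHICS_URL = "https://pfam-graphics.invalid/protein/{accession}/graphic"

#: Human taxon, preferred when a symbol matches several organisms.
_HUMAN_TAXON = 9606

#: Fallback fill colors for domains whose document omits a colour,
#: cycled in document order.  Muted qualitative palette.
_DOMAIN_PALETTE = (
    "#2E86AB", "#A23B72", "#F18F01", "#C73E1D", "#3B7A57",
    "#6B5B95", "#88B04B", "#92A8D1",
)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DomainRegion:
    """One curated Pfam-A domain placed on the protein backbone."""

    pfam_accession: str
    short_name: str
    description: str
    start: int
    end: int
    color: str

    def __post_init__(self) -> None:
        if not self.short_name:
            raise ValueError("DomainRegion.short_name must be non-empty")
        if not _HEX_COLOR_RE.match(self.color):
            raise ValueError(f"DomainRegion.color {self.color!r} is not #RRGGBB")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"DomainRegion {self.short_name}: bad range {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class MotifRegion:
    """A predicted structural region (disorder, low complexity, ...)."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in MOTIF_KINDS:
            raise ValueError(f"MotifRegion.kind {self.kind!r} not in {sorted(MOTIF_KINDS)}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"MotifRegion {self.kind}: bad range {self.start}..{self.end}")


@dataclass(frozen=True)
class ProteinArchitecture:
    """One protein's length plus its domains and motifs, ready to draw."""

    accession: str
    gene_symbol: str
    length: int
    domains: tuple[DomainRegion, ...] = ()
    motifs: tuple[MotifRegion, ...] = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("ProteinArchitecture.length must be >= 1")
        for region in (*self.domains, *self.motifs):
            if region.end > self.length:
                raise ValueError(
                    f"region {region} extends past protein length {self.length}"
                )
        ordered = sorted(self.domains, key=lambda d: (d.start, d.end))
        if list(ordered) != list(self.domains):
            object.__setattr__(self, "domains", tuple(ordered))
        object.__setattr__(self, "motifs", tuple(self.motifs))


# ---------------------------------------------------------------------------
# transport & cache


def default_fetch(url: str, timeout: float = 30.0) -> str:
    """Fetch *url* over HTTP(S), mapping failures onto package errors.

    A 404/410 becomes :class:`NotFoundError`; any other failure (DNS,
    refused, timeout, 5xx) becomes :class:`TransportError` so callers
    can distinguish "no such record" from "the network is down".
    """
    request = urllib.request.Request(url, headers={"Accept": "application/json"})
    try:
        with urllib.request.urlopen(request, timeout=timeout) as response:
            return response.read().decode("utf-8")
    except urllib.error.HTTPError as exc:
        if exc.code in (404, 410):
            raise NotFoundError(f"{url}: HTTP {exc.code}") from exc
        raise TransportError(f"{url}: HTTP {exc.code}") from exc
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise TransportError(f"{url}: {exc}") from exc


class DiskCache:
    """Tiny on-disk response cache keyed by ``(service, identifier)``.

    No expiry logic: a cached document is reused verbatim until the
    directory is cleared, which keeps repeat renders byte-identical.
    """

    def __init__(self, root: Optional[Path] = None, enabled: bool = True) -> None:
        if root is None:
            base = os.environ.get("XDG_CACHE_HOME") or os.path.join(
                os.path.expanduser("~"), ".cache"
            )
            root = Path(base) / "needleplot"
        self.root = Path(root)
        self.enabled = enabled

    def _path(self, service: str, identifier: str) -> Path:
        safe = re.sub(r"[^A-Za-z0-9._-]", "_", identifier)
        return self.root / service / f"{safe}.json"

    def get(self, service: str, identifier: str) -> Optional[str]:
        if not self.enabled:
            return None
        path = self._path(service, identifier)
        if path.is_file():
            return path.read_text(encoding="utf-8")
        return None

    def put(self, service: str, identifier: str, body: str) -> None:
        if not self.enabled:
            return
        path = self._path(service, identifier)
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(body, encoding="utf-8")
        tmp.replace(path)


# ---------------------------------------------------------------------------
# operations


def resolve_accession(
    symbol: str,
    fetch: Fetch = default_fetch,
    cache: Optional[DiskCache] = None,
) -> str:
    """Resolve an HGNC gene *symbol* to a reviewed UniProt accession.

    Only reviewed (SwissProt) entries are considered; human entries are
    preferred, and remaining ties break lexicographically by accession
    so the result is deterministic across runs.
    """
    symbol = symbol.strip()
    if not symbol:
        raise ResolutionError("empty gene symbol")
    url = UNIPROT_SEARCH_URL.format(symbol=urllib.parse.quote(symbol))

    body = cache.get("uniprot", symbol) if cache else None
    fetched = body is None
    if body is None:
        body = fetch(url)

    try:
        payload = json.loads(body)
        results = payload["results"]
        candidates = []
        for entry in results:
            accession = entry["primaryAccession"]
            taxon = int(entry.get("organism", {}).get("taxonId", 0))
            entry_type = entry.get("entryType", "reviewed")
            if "reviewed" not in entry_type.lower():
                continue
            candidates.append((taxon != _HUMAN_TAXON, accession))
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ArchitectureParseError(
            f"unparseable UniProt response for {symbol!r}: {exc}"
        ) from exc

    if not candidates:
        raise ResolutionError(f"no reviewed UniProt entry matches symbol {symbol!r}")
    if fetched and cache:
        cache.put("uniprot", symbol, body)
    return min(candidates)[1]


def fetch_architecture(
    accession: str,
    fetch: Fetch = default_fetch,
    cache: Optional[DiskCache] = None,
) -> ProteinArchitecture:
    """Fetch and parse the graphics document for a UniProt *accession*."""
    accession = accession.strip().upper()
    if not ACCESSION_RE.match(accession):
        raise NotFoundError(f"{accession!r} is not a syntactically valid UniProt accession")
    url = PFAM_GRAPHICS_URL.format(accession=accession)

    body = cache.get("pfam", accession) if cache else None
    fetched = body is None
    if body is None:
        body = fetch(url)

    architecture = load_architecture_json(body)
    if fetched and cache:
        cache.put("pfam", accession, body)
    return architecture


def _coerce_pos(value: object, path: str) -> int:
    """Pfam graphics documents serve coordinates as ints or numeric strings."""
    try:
        number = int(str(value))
    except (TypeError, ValueError):
        raise ArchitectureParseError(f"{path}: {value!r} is not an integer position")
    return number


def load_architecture_json(document: str) -> ProteinArchitecture:
    """Parse a Pfam-graphics-dialect JSON *document* into an architecture.

    The dialect (see ``docs/pfam_graphics_schema.json``): a top-level
    object — or a one-element array of objects, as the historical Pfam
    endpoint served — with a residue ``length``, optional ``metadata``
    (``identifier`` gene symbol, ``accession``), a ``regions`` list of
    Pfam-A domains (``text``, ``start``, ``end``, ``colour``,
    ``metadata.description`` / ``metadata.accession``) and a ``motifs``
    list of typed structural regions.  Region entries whose
    ``metadata.type`` is not ``pfama`` are treated as motifs; motif
    types outside the closed kind set are dropped with a warning rather
    than failing the plot.  The parse is all-or-nothing: any structural
    problem raises :class:`ArchitectureParseError` naming the offending
    path, never a partial architecture.
    """
    try:
        payload = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ArchitectureParseError(f"document is not well-formed JSON: {exc}") from exc

    if isinstance(payload, list):
        if len(payload) != 1 or not isinstance(payload[0], dict):
            raise ArchitectureParseError(
                "$: expected an object or a one-element array of objects"
            )
        payload = payload[0]
    if not isinstance(payload, dict):
        raise ArchitectureParseError("$: expected a JSON object")

    if "length" not in payload:
        raise ArchitectureParseError("$.length: missing required field")
    length = _coerce_pos(payload["length"], "$.length")
    if length < 1:
        raise ArchitectureParseError(f"$.length: {length} must be >= 1")

    metadata = payload.get("metadata") or {}
    gene_symbol = str(metadata.get("identifier", "") or "")
    accession = str(metadata.get("accession", "") or "")

    domains: list[DomainRegion] = []
    motif_entries: list[tuple[str, int, int, str]] = []

    for index, region in enumerate(payload.get("regions") or []):
        path = f"$.regions[{index}]"
        if not isinstance(region, dict):
            raise ArchitectureParseError(f"{path}: expected an object")
        start = _coerce_pos(region.get("start"), f"{path}.start")
        end = _coerce_pos(region.get("end"), f"{path}.end")
        if end < start:
            raise ArchitectureParseError(f"{path}: end {end} < start {start}")
        if start < 1 or end > length:
            raise ArchitectureParseError(
                f"{path}: range {start}..{end} outside protein 1..{length}"
            )
        region_meta = region.get("metadata") or {}
        region_type = str(region_meta.get("type", "pfama")).lower()
        if region_type != "pfama":
            motif_entries.append((region_type, start, end, path))
            continue
        short_name = str(region.get("text", "") or "")
        if not short_name:
            raise ArchitectureParseError(f"{path}.text: Pfam-A region needs a name")
        color = str(region.get("colour") or region.get("color") or "")
        if not color:
            color = _DOMAIN_PALETTE[len(domains) % len(_DOMAIN_PALETTE)]
        if not _HEX_COLOR_RE.match(color):
            raise ArchitectureParseError(f"{path}.colour: {color!r} is not #RRGGBB")
        domains.append(
            DomainRegion(
                pfam_accession=str(region_meta.get("accession", "") or ""),
                short_name=short_name,
                description=str(region_meta.get("description", "") or short_name),
                start=start,
                end=end,
                color=color.upper(),
            )
        )

    for index, motif in enumerate(payload.get("motifs") or []):
        path = f"$.motifs[{index}]"
        if not isinstance(motif, dict):
            raise ArchitectureParseError(f"{path}: expected an object")
        start = _coerce_pos(motif.get("start"), f"{path}.start")
        end = _coerce_pos(motif.get("end"), f"{path}.end")
        if end < start:
            raise ArchitectureParseError(f"{path}: end {end} < start {start}")
        if start < 1 or end > length:
            raise ArchitectureParseError(
                f"{path}: range {start}..{end} outside protein 1..{length}"
            )
        motif_entries.append((str(motif.get("type", "")).lower(), start, end, path))

    motifs: list[MotifRegion] = []
    for kind, start, end, path in motif_entries:
        if kind not in MOTIF_KINDS:
            log.warning("%s: dropping motif of unknown kind %r", path, kind)
            continue
        motifs.append(MotifRegion(kind=kind, start=start, end=end))

    domains.sort(key=lambda d: (d.start, d.end))
    motifs.sort(key=lambda m: (m.start, m.end, m.kind))
    return ProteinArchitecture(
        accession=accession,
        gene_symbol=gene_symbol,
        length=length,
        domains=tuple(domains),
        motifs=tuple(motifs),
    )


def dump_architecture_json(architecture: ProteinArchitecture) -> str:
    """Serialize an architecture back to the graphics dialect.

    Deterministic (sorted keys, canonical separators), and an exact
    fixed point under :func:`load_architecture_json`.
    """
    payload = {
        "length": architecture.length,
        "metadata": {
            "accession": architecture.accession,
            "identifier": architecture.gene_symbol,
        },
        "regions": [
            {
                "text": d.short_name,
                "start": d.start,
                "end": d.end,
                "colour": d.color,
                "metadata": {
                    "accession": d.pfam_accession,
                    "description": d.description,
                    "type": "pfama",
                },
            }
            for d in architecture.domains
        ],
        "motifs": [
            {"type": m.kind, "start": m.start, "end": m.end}
            for m in architecture.motifs
        ],
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def load_architecture_file(path: str | Path) -> ProteinArchitecture:
    """Load a local graphics-dialect document (the offline ``-local`` path)."""
    return load_architecture_json(Path(path).read_text(encoding="utf-8"))
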