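"""Deterministic synthetic inputs so every module is testable offline.

Two generators produce Pfam-graphics-dialect architecture documents and
variant spec lists from a seed; identical seeds give byte-identical
output.  The module also exposes two hand-curated bundled documents —
a TP53-like and an FGA-like architecture — plus a synthetic UniProt
search response, used as replay stand-ins for the live services.
"""

from __future__ import annotations

import json
import random
from importlib import resources

from .errors import GenerationError

_AA = "ACDEFGHIKLMNPQRSTVWY"
_MOTIF_KINDS = ("disorder", "low_complexity", "sig_p", "coiled_coil", "transmembrane")
_PALETTE = (
    "#2E86AB", "#A23B72", "#F18F01", "#C73E1D", "#3B7A57",
    "#6B5B95", "#88B04B", "#92A8D1",
)

#: Bundled synthetic replay documents (see ``needleplot/data/``).
_BUNDLED = {
    "tp53": "architecture_tp53_synthetic.json",
    "fga": "architecture_fga_synthetic.json",
    "uniprot_tp53": "uniprot_search_tp53_synthetic.json",
    "uniprot_empty": "uniprot_search_empty_synthetic.json",
}


def bundled_document(name: str) -> str:
    """Return the text of a bundled synthetic replay document.

    Known names: ``tp53``, ``fga`` (architecture documents) and
    ``uniprot_tp53``, ``uniprot_empty`` (symbol-search responses).
    """
    try:
        filename = _BUNDLED[name]
    except KeyError:
        raise KeyError(f"no bundled document {name!r}; have {sorted(_BUNDLED)}") from None
    return (
        resources.files("needleplot.data").joinpath(filename).read_text(encoding="utf-8")
    )


def _token(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("abcdefghijklmnopqrstuvwxyz") for _ in range(length))


def generate_architecture(
    seed: int,
    n_domains: int = 3,
    n_motifs: int = 2,
    length: int = 400,
) -> str:
    """Generate a random architecture document in the graphics dialect.

    Domains are non-overlapping intervals placed along the backbone.
    In half the seeds the domain names share a common underscore
    prefix (exercising the label abbreviation path); motifs are drawn
    from the closed structural-kind set and may overlap anything, as
    in real annotations.  Requires ``length >= 10*(n_domains+1)``.
    """
    if n_domains < 0 or n_motifs < 0:
        raise GenerationError("n_domains and n_motifs must be >= 0")
    if length < 10 * (n_domains + 1):
        raise GenerationError(
            f"length {length} too short to pack {n_domains} domains "
            f"(need >= {10 * (n_domains + 1)})"
        )
    rng = random.Random(seed)

    # 2*n distinct sorted cut points give n disjoint inclusive intervals.
    if 2 * n_domains > length:
        raise GenerationError("cannot pack domains: protein too short")
    cuts = sorted(rng.sample(range(1, length + 1), 2 * n_domains))
    intervals = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(n_domains)]

    shared = rng.random() < 0.5
    prefix = _token(rng, 3).capitalize() if shared else None
    names = []
    for i in range(n_domains):
        suffix = _token(rng, rng.randint(2, 6))
        if shared:
            names.append(f"{prefix}_{suffix}")
        elif rng.random() < 0.5:
            names.append(f"{_token(rng, 3).capitalize()}_{suffix}")
        else:
            names.append(suffix.capitalize())

    regions = [
        {
            "text": name,
            "start": start,
            "end": end,
            "colour": _PALETTE[i % len(_PALETTE)],
            "metadata": {
                "accession": f"PF{rng.randint(0, 99999):05d}",
                "description": f"{name} family domain",
                "type": "pfama",
            },
        }
        for i, (name, (start, end)) in enumerate(zip(names, intervals))
    ]

    motifs = []
    for _ in range(n_motifs):
        start = rng.randint(1, length)
        end = min(length, start + rng.randint(0, max(1, length // 8)))
        motifs.append({"type": rng.choice(_MOTIF_KINDS), "start": start, "end": end})
    motifs.sort(key=lambda m: (m["start"], m["end"], m["type"]))

    payload = {
        "length": length,
        "metadata": {
            "accession": f"Q{rng.randint(0, 9)}{_token(rng, 3).upper()}{rng.randint(0, 9)}",
            "identifier": f"GENE{seed % 1000}",
        },
        "regions": regions,
        "motifs": motifs,
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def generate_variants(
    seed: int,
    n: int,
    length: int = 400,
    decorate: bool = False,
) -> list[str]:
    """Generate *n* parseable variant spec strings.

    Positions are uniform on ``[1, length]``.  With *decorate*, a
    random subset gains ``#RRGGBB`` color and/or ``@magnitude``
    suffixes.  Identical seed, identical list.
    """
    if n < 0:
        raise GenerationError("n must be >= 0")
    rng = random.Random(seed)
    specs = []
    for _ in range(n):
        position = rng.randint(1, length)
        ref = rng.choice(_AA)
        tail = rng.choice([rng.choice(_AA), "*", "fs", "del", "dup"])
        spec = f"{ref}{position}{tail}"
        if decorate:
            if rng.random() < 0.4:
                spec += "#{:06X}".format(rng.randrange(0x1000000))
            if rng.random() < 0.4:
                spec += f"@{rng.randint(1, 60)}"
        specs.append(spec)
    return specs
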